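pollutant,avg_period,bp_lo,bp_hi,iaqi_lo,iaqi_hi
so2,24h,0,50,0,50
so2,24h,50,150,50,100
so2,24h,150,475,100,150
so2,24h,475,800,150,200
so2,24h,800,1600,200,300
so2,24h,1600,2100,300,400
so2,24h,2100,2620,400,500
no2,24h,0,40,0,50
no2,24h,40,80,50,100
no2,24h,80,180,100,150
no2,24h,180,280,150,200
no2,24h,280,565,200,300
no2,24h,565,750,300,400
no2,24h,750,940,400,500
pm10,24h,0,50,0,50
pm10,24h,50,150,50,100
pm10,24h,150,250,100,150
pm10,24h,250,350,150,200
pm10,24h,350,420,200,300
pm10,24h,420,500,300,400
pm10,24h,500,600,400,500
co,24h,0,2,0,50
co,24h,2,4,50,100
co,24h,4,14,100,150
co,24h,14,24,150,200
co,24h,24,36,200,300
co,24h,36,48,300,400
co,24h,48,60,400,500
o3,8h,0,100,0,50
o3,8h,100,160,50,100
o3,8h,160,215,100,150
o3,8h,215,265,150,200
o3,8h,265,800,200,300
o3,1h,0,160,0,50
o3,1h,160,200,50,100
o3,1h,200,300,100,150
o3,1h,300,400,150,200
o3,1h,400,800,200,300
o3,1h,800,1000,300,400
o3,1h,1000,1200,400,500
pm25,24h,0,35,0,50
pm25,24h,35,75,50,100
pm25,24h,75,115,100,150
pm25,24h,115,150,150,200
pm25,24h,150,250,200,300
pm25,24h,250,350,300,400
pm25,24h,350,500,400,500
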