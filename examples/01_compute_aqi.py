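"""Composite AQI for one day's pollutant concentrations.

Each pollutant is mapped to a sub-index (IAQI) by piecewise-linear
interpolation between the Chinese-standard breakpoints; the AQI is the
maximum sub-index, and pollutants attaining it are "primary".
"""

from aqilag import compute_aqi, load_breakpoints

table = load_breakpoints()  # GB3095-2012 limits, 8-h ozone window

# a moderately polluted day (units: ug/m3, CO in mg/m3)
conc = {"pm25": 62.0, "pm10": 95.0, "no2": 38.0, "so2": 9.0, "o3": 130.0, "co": 0.9}
res = compute_aqi(conc, table)

print("sub-indices:", res.iaqi)
print(f"AQI = {res.aqi} ({res.category}); primary pollutant(s): {res.primary_pollutant}")
# The AQI equals the largest sub-index; a value in (50, 100] is "good"
# air with the named pollutant(s) driving the index.
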