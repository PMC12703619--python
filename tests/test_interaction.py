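"""2x2 interaction measures: arithmetic identities, closed forms, symmetry."""

import warnings

import numpy as np
import pytest

from aqilag import (
    InteractionInput,
    InteractionTruth,
    SimulationTruth,
    dichotomize,
    fit_interaction,
    simulate_series,
)


def make_input(rng, means, n_per_cell=200):
    """Day-level 2x2 data with given Poisson cell means (m00, m10, m01, m11)."""
    m00, m10, m01, m11 = means
    e1 = np.repeat([0, 1, 0, 1], n_per_cell)
    e2 = np.repeat([0, 0, 1, 1], n_per_cell)
    mu = np.repeat([m00, m10, m01, m11], n_per_cell)
    y = rng.poisson(mu).astype(float)
    cells = {f"({i},{j})": n_per_cell for i in (0, 1) for j in (0, 1)}
    return InteractionInput(y=y, e1=e1, e2=e2, cell_days=cells)


class TestArithmetic:
    def test_identical_cells_give_null_measures(self):
        e1 = np.repeat([0, 1, 0, 1], 5)
        e2 = np.repeat([0, 0, 1, 1], 5)
        y = np.full(20, 4.0)
        inp = InteractionInput(y=y, e1=e1, e2=e2, cell_days={})
        res = fit_interaction(inp)
        assert res.irr == pytest.approx(1.0, abs=1e-9)
        assert res.reri == pytest.approx(0.0, abs=1e-9)
        assert res.ap == pytest.approx(0.0, abs=1e-9)
        assert res.verdict == "none"

    def test_constructed_cells_match_direct_arithmetic(self):
        # cell means 10, 12, 13, 20 -> RR10 = 1.2, RR01 = 1.3, RR11 = 2.0
        e1 = np.repeat([0, 1, 0, 1], 3)
        e2 = np.repeat([0, 0, 1, 1], 3)
        y = np.repeat([10.0, 12.0, 13.0, 20.0], 3)
        res = fit_interaction(InteractionInput(y=y, e1=e1, e2=e2, cell_days={}))
        assert res.rr10 == pytest.approx(1.2, abs=1e-9)
        assert res.rr01 == pytest.approx(1.3, abs=1e-9)
        assert res.rr11 == pytest.approx(2.0, abs=1e-9)
        assert res.reri == pytest.approx(2.0 - 1.2 - 1.3 + 1.0, abs=1e-12)
        assert res.ap == pytest.approx(0.5 / 2.0, abs=1e-12)
        assert res.irr == pytest.approx(2.0 / (1.2 * 1.3), abs=1e-9)

    def test_internal_identities_to_1e12(self):
        rng = np.random.default_rng(31)
        res = fit_interaction(make_input(rng, (20, 26, 24, 35)))
        assert res.irr == pytest.approx(res.rr11 / (res.rr01 * res.rr10), abs=1e-12)
        assert res.reri == pytest.approx(res.rr11 - res.rr10 - res.rr01 + 1, abs=1e-12)
        assert res.ap * res.rr11 == pytest.approx(res.reri, abs=1e-12)


class TestClosedForm:
    def test_saturated_fit_reproduces_cell_mean_ratios(self):
        rng = np.random.default_rng(32)
        inp = make_input(rng, (15, 20, 18, 30))
        res = fit_interaction(inp)
        mean = lambda i, j: inp.y[(inp.e1 == i) & (inp.e2 == j)].mean()
        assert res.rr10 == pytest.approx(mean(1, 0) / mean(0, 0), abs=1e-8)
        assert res.rr01 == pytest.approx(mean(0, 1) / mean(0, 0), abs=1e-8)
        assert res.rr11 == pytest.approx(mean(1, 1) / mean(0, 0), abs=1e-8)

    def test_exposure_label_exchange_leaves_measures(self):
        rng = np.random.default_rng(33)
        inp = make_input(rng, (15, 20, 18, 30))
        a = fit_interaction(inp)
        swapped = InteractionInput(y=inp.y, e1=inp.e2, e2=inp.e1, cell_days=inp.cell_days)
        b = fit_interaction(swapped)
        assert a.irr == pytest.approx(b.irr, abs=1e-10)
        assert a.reri == pytest.approx(b.reri, abs=1e-10)
        assert a.ap == pytest.approx(b.ap, abs=1e-10)

    def test_bootstrap_ci_close_to_delta_method(self):
        rng = np.random.default_rng(34)
        inp = make_input(rng, (20, 26, 24, 40), n_per_cell=300)
        delta = fit_interaction(inp)
        boot = fit_interaction(inp, bootstrap=200, seed=9)
        assert boot.reri_ci[0] == pytest.approx(delta.reri_ci[0], abs=0.15)
        assert boot.reri_ci[1] == pytest.approx(delta.reri_ci[1], abs=0.15)


class TestDichotomize:
    def test_threshold_above_max_names_empty_cell(self, default_series):
        series, _ = default_series
        with pytest.raises(ValueError, match=r"\(1,"):
            dichotomize(series, "wind_mean", 2.0, aqi_threshold=1e5)

    def test_median_turning_point_halves_days(self, default_series):
        series, _ = default_series
        met = series.column("wind_mean")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            inp = dichotomize(
                series, "wind_mean", float(np.median(met)), aqi_threshold=80.0
            )
        low = inp.cell_days["(0,0)"] + inp.cell_days["(1,0)"]
        high = inp.cell_days["(0,1)"] + inp.cell_days["(1,1)"]
        assert abs(low - high) <= len(series) * 0.02

    def test_cell_counts_match_brute_force(self, default_series):
        series, _ = default_series
        aqi, met = series.column("aqi"), series.column("humidity_mean")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            inp = dichotomize(series, "humidity_mean", 76.0, aqi_threshold=80.0)
        for i in (0, 1):
            for j in (0, 1):
                want = int(np.sum(((aqi > 80.0) == i) & ((met > 76.0) == j)))
                assert inp.cell_days[f"({i},{j})"] == want

    def test_sparse_polluted_cell_warns(self, default_series):
        series, _ = default_series
        # threshold at the 99.5th percentile leaves ~13 polluted days,
        # mirroring how few days exceed the policy cutoff in clean air
        thr = float(np.quantile(series.column("aqi"), 0.995))
        with pytest.warns(UserWarning, match="polluted days"):
            dichotomize(series, "wind_mean", 2.0, aqi_threshold=thr)


class TestRecovery:
    def test_antagonistic_gamma_recovered(self):
        truth = SimulationTruth(
            aqi_slope=0.0,
            interaction=InteractionTruth(
                met_var="wind_mean", gamma=np.log(0.93), met_effect=-0.03, aqi_effect=0.04
            ),
        )
        irrs = []
        for k in range(20):
            series, _ = simulate_series(2557, seed=700 + k, truth=truth)
            aqi, met = series.column("aqi"), series.column("wind_mean")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                inp = dichotomize(
                    series, "wind_mean", float(np.median(met)), float(np.median(aqi))
                )
            irrs.append(fit_interaction(inp).irr)
        assert np.mean(irrs) == pytest.approx(0.93, rel=0.02)
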