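"""Gravimetric workflow: soak correction, wear-rate regression, exact
Kruskal-Wallis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cupwear as cw
from cupwear.gravimetry import (
    GravimetryError,
    WeightSeries,
    _rank_partitions,
    kruskal_wallis,
    read_weight_series_csv,
    soak_correct,
    wear_rate,
    write_weight_series_csv,
)


def series(weights, controls, cycles=(0, 0.4, 0.8, 1.2, 1.6, 2.0)):
    return WeightSeries("S1", "other", np.asarray(cycles, float),
                        np.asarray(weights, float), np.asarray(controls, float))


def hand_ols_slope(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return float(np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2))


class TestSoakCorrect:
    def test_flat_control_pure_loss(self):
        s = series([100, 99, 98, 97, 96, 95], [50] * 6)
        np.testing.assert_allclose(soak_correct(s), [0, 1, 2, 3, 4, 5])

    def test_flat_specimen_pure_soak(self):
        s = series([100] * 6, [50, 50.5, 51, 51.5, 51.8, 52])
        np.testing.assert_allclose(soak_correct(s), [0, 0.5, 1, 1.5, 1.8, 2])

    def test_simulated_series_recovers_linear_loss_exactly(self):
        """With a noiseless generator the control gain cancels the specimen's
        soak term at every stop, leaving exactly rate * cycles."""
        s = cw.simulate_weight_series(
            5.0, soak_params=cw.SoakParams(1.0, 0.3), balance_sd=0.0
        )
        np.testing.assert_allclose(soak_correct(s), 5.0 * s.cycles, atol=1e-10)

    @settings(derandomize=True, max_examples=25)
    @given(shift=st.floats(-50, 50, allow_nan=False))
    def test_additive_shift_invariance(self, shift):
        w = np.array([100.0, 99.2, 98.1, 97.3, 96.0, 95.5])
        c = np.array([50.0, 50.3, 50.5, 50.6, 50.65, 50.7])
        base = soak_correct(series(w, c))
        shifted = soak_correct(series(w + shift, c))
        np.testing.assert_allclose(shifted, base, atol=1e-9)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(GravimetryError, match="control grid"):
            WeightSeries("S", "other", [0, 0.4], [10, 9], [5, 5, 5])


class TestWearRate:
    def test_exact_linear(self):
        losses = [0, 2.04, 4.08, 6.12, 8.16, 10.2]
        slope, r2 = wear_rate(losses, [0, 0.4, 0.8, 1.2, 1.6, 2.0])
        assert slope == pytest.approx(5.1, rel=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_xlpe_means_match_hand_ols(self):
        """Steady-state slope of the XLPE material means against a
        closed-form OLS oracle."""
        t1 = cw.load_table1()
        xlpe = t1[t1.material == "XLPE"].sort_values("cycles_Mc")
        cycles = np.concatenate([[0.0], xlpe.cycles_Mc.to_numpy()])
        losses = np.concatenate([[0.0], xlpe.mean_loss_mg.to_numpy()])
        slope, _ = wear_rate(losses, cycles, steady_state_from=0.4)
        oracle = hand_ols_slope(xlpe.cycles_Mc, xlpe.mean_loss_mg)
        assert slope == pytest.approx(oracle, rel=1e-12)
        assert slope == pytest.approx(5.15, abs=0.005)

    def test_constant_losses_give_zero_slope(self):
        slope, r2 = wear_rate([3.0] * 5, [0.4, 0.8, 1.2, 1.6, 2.0])
        assert slope == 0.0 and r2 == 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(GravimetryError):
            wear_rate([0, 1], [0, 0.4], steady_state_from=0.4)


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([[5, 5, 5], [5, 5, 5], [5, 5, 5]])
        assert res.H == 0.0 and res.p_value == 1.0

    def test_fully_separated_groups_exact(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.method == "exact"
        assert res.H == pytest.approx(7.2, abs=1e-9)
        assert res.p_value == pytest.approx(6 / 1680, rel=1e-12)

    def test_enumeration_covers_all_partitions(self):
        ranks = np.arange(1.0, 10.0)
        assert sum(1 for _ in _rank_partitions(ranks, [3, 3, 3])) == 1680

    def test_exact_close_to_chi_square_at_n15(self):
        """In the tail region (where significance decisions live) the
        chi-square approximation tracks the exact permutation p-value."""
        rng = np.random.default_rng(8)
        groups = [list(rng.normal(size=5)) for _ in range(3)]
        exact = kruskal_wallis(groups, exact_max_n=15)
        approx = kruskal_wallis(groups, exact_max_n=0)
        assert exact.method == "exact" and approx.method == "chi-square"
        assert exact.H == pytest.approx(approx.H)
        assert abs(exact.p_value - approx.p_value) < 0.02

    @pytest.mark.parametrize("transform", [np.exp, lambda x: x**3, lambda x: 10 * x + 2])
    def test_exact_p_invariant_under_monotone_transform(self, transform):
        groups = [[1.0, 4.0, 2.5], [3.0, 6.0, 5.0], [8.0, 7.0, 9.5]]
        base = kruskal_wallis(groups)
        mapped = kruskal_wallis([[float(transform(v)) for v in g] for g in groups])
        assert mapped.p_value == pytest.approx(base.p_value, rel=1e-12)
        assert mapped.H == pytest.approx(base.H, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(GravimetryError, match="empty group"):
            kruskal_wallis([[1, 2], []])


class TestCsvRoundTrip:
    def test_write_read_round_trip(self, tmp_path):
        s1 = cw.simulate_weight_series(5.0, seed=1, specimen_id="A", material_label="XLPE")
        s2 = cw.simulate_weight_series(10.0, seed=2, specimen_id="B", material_label="STD_PE")
        path = tmp_path / "series.csv"
        write_weight_series_csv(path, [s1, s2])
        back = read_weight_series_csv(path)
        assert [s.specimen_id for s in back] == ["A", "B"]
        np.testing.assert_allclose(back[0].weights, s1.weights)
        np.testing.assert_allclose(back[1].control_weights, s2.control_weights)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("specimen_id,cycles_Mc\nA,0\n")
        with pytest.raises(GravimetryError, match="missing columns"):
            read_weight_series_csv(p)
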