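import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wormtrack.screen import (
    basic_features,
    feature_correlations,
    feature_f_statistic,
    hedges_d,
    mean_abs_effect,
    modal_correlation,
)
from wormtrack.tracking import Trajectory, TrackEntry


def _traj(positions, n=13, length=24.0, curvature=0.0):
    """Straight or circular-arc worm translated along ``positions``."""
    s = np.linspace(-length / 2, length / 2, n)
    if curvature == 0:
        base = np.column_stack([s, np.zeros(n)])
    else:
        r = 1.0 / curvature
        ang = s / r
        base = np.column_stack([r * np.sin(ang), r * (1 - np.cos(ang))])
    return Trajectory(
        worm_id=0,
        entries=[
            TrackEntry(frame=t, skeleton=base + np.asarray(p))
            for t, p in enumerate(positions)
        ],
    )


class TestBasicFeatures:
    def test_stationary_speed_zero(self):
        tr = _traj([(0.0, 0.0)] * 10)
        table = basic_features({"w1": [tr]}, fps=25.0)
        assert table.loc["w1", "midbody_speed"] == 0.0

    def test_straight_worm_zero_curvature(self):
        tr = _traj([(0.0, 0.0)] * 10)
        table = basic_features({"w1": [tr]}, fps=25.0)
        assert table.loc["w1", "tail_curvature"] == pytest.approx(0.0, abs=1e-12)

    def test_translating_speed(self):
        v = 1.7  # px/frame
        tr = _traj([(v * t, 0.0) for t in range(20)])
        table = basic_features({"w1": [tr]}, fps=25.0)
        assert table.loc["w1", "midbody_speed"] == pytest.approx(v * 25.0, rel=0.02)

    def test_curved_worm_curvature(self):
        tr = _traj([(0.0, 0.0)] * 5, curvature=0.05)
        table = basic_features({"w1": [tr]}, fps=25.0)
        assert table.loc["w1", "tail_curvature"] == pytest.approx(0.05, rel=0.1)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            basic_features({}, fps=25.0)
        with pytest.raises(ValueError):
            basic_features({"w": [_traj([(0.0, 0.0)])]}, fps=25.0)


class TestFeatureCorrelations:
    def _table(self, data, **meta):
        df = pd.DataFrame(data)
        for k, v in meta.items():
            df[k] = v
        return df

    def test_identical_tables_r1(self):
        rng = np.random.default_rng(0)
        a = self._table({f"f{i}": rng.normal(0, 1, 20) for i in range(5)})
        r = feature_correlations(a, a.copy())
        np.testing.assert_allclose(r.to_numpy(), 1.0, atol=1e-12)

    def test_negated_tables_r_minus1(self):
        rng = np.random.default_rng(1)
        a = self._table({f"f{i}": rng.normal(0, 1, 20) for i in range(5)})
        b = -a
        r = feature_correlations(a, b)
        np.testing.assert_allclose(r.to_numpy(), -1.0, atol=1e-12)

    def test_too_few_wells_flagged(self):
        a = self._table({"f": [1.0, 2.0]})
        r = feature_correlations(a, a.copy())
        assert np.isnan(r["f"])

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        a = self._table({"f": rng.normal(0, 1, 30)})
        b = self._table({"f": a["f"] + rng.normal(0, 0.5, 30)})
        r1 = feature_correlations(a, b)["f"]
        r2 = feature_correlations(a * 3.0 + 7.0, b)["f"]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_attenuation_closed_form(self):
        # shared signal s plus independent noise in each table: expected r is
        # sqrt(s2/(s2+v1)) * sqrt(s2/(s2+v2))
        rng = np.random.default_rng(3)
        n_wells, n_feats = 60, 400
        s2, v1, v2 = 1.0, 0.5, 0.25
        signal = rng.normal(0, np.sqrt(s2), (n_wells, n_feats))
        a = self._table(
            {f"f{i}": signal[:, i] + rng.normal(0, np.sqrt(v1), n_wells) for i in range(n_feats)}
        )
        b = self._table(
            {f"f{i}": signal[:, i] + rng.normal(0, np.sqrt(v2), n_wells) for i in range(n_feats)}
        )
        r = feature_correlations(a, b)
        expected = np.sqrt(s2 / (s2 + v1)) * np.sqrt(s2 / (s2 + v2))
        assert r.mean() == pytest.approx(expected, abs=3.0 / np.sqrt(n_wells * n_feats) + 0.02)

    def test_modal_correlation(self):
        r = np.concatenate([np.full(50, 0.71), np.random.default_rng(4).uniform(-1, 1, 50)])
        mode = modal_correlation(r, bin_width=0.05)
        assert abs(mode - 0.71) <= 0.05


class TestFStatistic:
    def _table(self, values):
        return pd.DataFrame({"f": values})

    def test_identical_group_means_zero(self):
        table = self._table([1.0, 2.0, 1.0, 2.0])
        f = feature_f_statistic(table, ["a", "a", "b", "b"])
        assert f["f"] == 0.0

    def test_zero_within_variance_inf(self):
        table = self._table([0.0, 0.0, 1.0, 1.0])
        f = feature_f_statistic(table, ["a", "a", "b", "b"])
        assert np.isinf(f["f"])

    def test_matches_scipy_oneway(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            sizes = rng.integers(2, 8, k)
            groups = [rng.normal(rng.normal(), 1.0, s) for s in sizes]
            table = self._table(np.concatenate(groups))
            labels = np.concatenate([[f"g{i}"] * s for i, s in enumerate(sizes)])
            ours = feature_f_statistic(table, labels)["f"]
            expected = stats.f_oneway(*groups).statistic
            assert ours == pytest.approx(expected, abs=1e-10, rel=1e-10)

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, 12)
        labels = ["a"] * 6 + ["b"] * 6
        f1 = feature_f_statistic(self._table(vals), labels)["f"]
        f2 = feature_f_statistic(self._table(vals + 1000.0), labels)["f"]
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            feature_f_statistic(self._table([1.0, 2.0]), ["a", "a"])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            feature_f_statistic(self._table([1.0, 2.0, 3.0]), ["a", "a", "b"])


class TestHedgesD:
    def test_identical_zero(self):
        assert hedges_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_closed_form_fixture(self):
        # treated [0,2] vs control [1,3]: Cohen's d = -1/sqrt(2), J = 4/7
        d = hedges_d([0.0, 2.0], [1.0, 3.0])
        assert abs(d) == pytest.approx(0.70710678 * 4.0 / 7.0, abs=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        t, c = rng.normal(1, 1, 10), rng.normal(0, 1, 12)
        assert hedges_d(t, c) == pytest.approx(hedges_d(t * 5, c * 5), abs=1e-12)

    def test_correction_factor(self):
        # J < 1 always; J -> 1 as n grows
        rng = np.random.default_rng(8)

        def cohen(t, c):
            nt, nc = len(t), len(c)
            sp = np.sqrt(
                ((nt - 1) * np.var(t, ddof=1) + (nc - 1) * np.var(c, ddof=1))
                / (nt + nc - 2)
            )
            return (np.mean(t) - np.mean(c)) / sp

        for n in (3, 10, 100):
            t = rng.normal(1, 1, n)
            c = rng.normal(0, 1, n)
            j = hedges_d(t, c) / cohen(t, c)
            assert j < 1.0
            assert j == pytest.approx(1 - 3 / (4 * 2 * n - 9), abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="pooled variance"):
            hedges_d([1.0, 1.0], [1.0, 1.0])

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            hedges_d([1.0], [1.0, 2.0])


class TestMeanAbsEffect:
    def _screen_table(self, rng, shift, sigma, n_doses=3, n_wells=6):
        rows = []
        for i in range(n_wells * 2):
            rows.append({"drug": "DMSO", "dose": 0.0, "is_control": True,
                         "feat": rng.normal(0.0, sigma)})
        for dose in range(1, n_doses + 1):
            for i in range(n_wells):
                rows.append({"drug": "X", "dose": float(dose), "is_control": False,
                             "feat": rng.normal(shift, sigma)})
        return pd.DataFrame(rows)

    def test_mean_over_doses(self):
        rng = np.random.default_rng(9)
        table = self._screen_table(rng, shift=1.0, sigma=0.5)
        eff = mean_abs_effect(table, "X")
        assert eff["feat"] > 0

    def test_narrower_distribution_larger_effect(self):
        # same mean shift, 2x smaller within-group spread -> ~2x larger |d|
        rng = np.random.default_rng(10)
        wide = self._screen_table(rng, shift=1.0, sigma=1.0, n_wells=200)
        rng = np.random.default_rng(10)
        narrow = self._screen_table(rng, shift=1.0, sigma=0.5, n_wells=200)
        e_wide = mean_abs_effect(wide, "X")["feat"]
        e_narrow = mean_abs_effect(narrow, "X")["feat"]
        assert e_narrow == pytest.approx(2.0 * e_wide, rel=0.15)
        assert e_narrow > e_wide  # points fall below the diagonal

    def test_missing_controls_error(self):
        table = pd.DataFrame(
            {"drug": ["X"] * 4, "dose": [1.0] * 4, "is_control": [False] * 4,
             "feat": [1.0, 2.0, 3.0, 4.0]}
        )
        with pytest.raises(ValueError):
            mean_abs_effect(table, "X")
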