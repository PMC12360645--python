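"""Metric tests, each checked against an independent brute-force oracle."""

import itertools

import numpy as np
import pytest

from wormtrack.metrics import (
    TrackMatchResult,
    classify_failure,
    detection_recall,
    nearest_segment_distance,
    rmsd,
    tracking_fidelity,
)
from wormtrack.tracking import Trajectory, TrackEntry


# ---------------------------------------------------------------- oracles


def rmsd_oracle(a, b):
    """Explicit loop over both orientations and all points."""
    best = None
    for cand in (a, a[::-1]):
        total = 0.0
        for p, q in zip(cand, b):
            total += (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2
        val = (total / len(b)) ** 0.5
        best = val if best is None else min(best, val)
    return best


def nsd_oracle(pred, truth):
    """Per-point distance to every segment, via explicit projection."""
    dists = []
    for p in pred:
        best = np.inf
        for a, b in zip(truth[:-1], truth[1:]):
            ab = b - a
            denom = float(ab @ ab)
            t = 0.0 if denom == 0 else float((p - a) @ ab) / denom
            t = min(max(t, 0.0), 1.0)
            best = min(best, float(np.linalg.norm(a + t * ab - p)))
        dists.append(best)
    return float(np.mean(dists))


def fidelity_oracle(pred_trajs, truth_trajs, max_dist=np.inf):
    """Brute-force: per-frame optimal matching by permutation enumeration,
    mismatch = matched ID differs from the ID at first match."""
    gt, pr = {}, {}
    for tr in truth_trajs:
        for e in tr.entries:
            gt.setdefault(e.frame, []).append((tr.worm_id, e.skeleton))
    for tr in pred_trajs:
        for e in tr.entries:
            pr.setdefault(e.frame, []).append((tr.worm_id, e.skeleton))

    def dist(a, b):
        f = np.mean(np.linalg.norm(a - b, axis=1))
        r = np.mean(np.linalg.norm(a[::-1] - b, axis=1))
        return min(f, r)

    ref, mme, g = {}, 0, 0
    for t in sorted(gt):
        gobjs, pobjs = gt[t], pr.get(t, [])
        g += len(gobjs)
        best, best_cost = None, np.inf
        indices = list(range(len(pobjs)))
        for r in range(min(len(gobjs), len(pobjs)), -1, -1):
            for chosen_g in itertools.combinations(range(len(gobjs)), r):
                for perm in itertools.permutations(indices, r):
                    cost = 0.0
                    ok = True
                    for gi, pj in zip(chosen_g, perm):
                        d = dist(gobjs[gi][1], pobjs[pj][1])
                        if d > max_dist:
                            ok = False
                            break
                        cost += d
                    # prefer maximal matchings, then minimal cost
                    if ok and (best is None or r > len(best) or (r == len(best) and cost < best_cost)):
                        if best is not None and r < len(best):
                            continue
                        best, best_cost = list(zip(chosen_g, perm)), cost
            if best is not None and len(best) == r:
                break
        matched = {gobjs[gi][0]: pobjs[pj][0] for gi, pj in (best or [])}
        for gid, _ in gobjs:
            pid = matched.get(gid)
            if pid is None:
                mme += 1
            elif gid not in ref:
                ref[gid] = pid
            elif ref[gid] != pid:
                mme += 1
    return 1.0 - mme / g


def _skel(x, y, angle=0.0, length=20.0, n=9):
    s = np.linspace(-length / 2, length / 2, n)
    return np.column_stack([x + s * np.cos(angle), y + s * np.sin(angle)])


def _traj(wid, positions):
    return Trajectory(
        worm_id=wid,
        entries=[
            TrackEntry(frame=t, skeleton=_skel(x, y)) for t, (x, y) in positions
        ],
    )


# ---------------------------------------------------------------- rmsd


class TestRmsd:
    def test_identical_zero(self):
        s = _skel(10, 20, 0.3)
        assert rmsd(s, s) == 0.0

    def test_perpendicular_translation(self):
        s = _skel(0, 0)
        assert rmsd(s + np.array([0.0, 3.0]), s) == pytest.approx(3.0, abs=1e-12)

    def test_symmetry(self):
        a, b = _skel(0, 0, 0.2), _skel(1, 2, 0.5)
        assert rmsd(a, b) == pytest.approx(rmsd(b, a), abs=1e-12)

    def test_orientation_minimised(self):
        s = _skel(0, 0, 0.7)
        assert rmsd(s[::-1], s) == 0.0

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(3, 30)
            a = rng.normal(0, 10, (n, 2))
            b = rng.normal(0, 10, (n, 2))
            assert rmsd(a, b, orientation="min") == pytest.approx(
                rmsd_oracle(a, b), abs=1e-10
            )

    def test_mismatched_points_error(self):
        with pytest.raises(ValueError, match="same point count"):
            rmsd(_skel(0, 0, n=9), _skel(0, 0, n=11))

    def test_resample_to_fixes_mismatch(self):
        val = rmsd(_skel(0, 0, n=9), _skel(0, 3, n=11), resample_to=13)
        assert val == pytest.approx(3.0, abs=1e-6)


# ------------------------------------------------- nearest segment distance


class TestNearestSegmentDistance:
    def test_identical_zero(self):
        s = _skel(5, 5, 0.4)
        assert nearest_segment_distance(s, s) == 0.0

    def test_collinear_overshoot(self):
        # hand geometry: truth spans y in [0, 10]; prediction overshoots the
        # end by 5 along the same line -> points inside map to 0, the
        # overshooting endpoint maps to the truth endpoint
        truth = np.array([[0.0, 0.0], [0.0, 5.0], [0.0, 10.0]])
        pred = np.array([[0.0, 5.0], [0.0, 10.0], [0.0, 15.0]])
        val = nearest_segment_distance(pred, truth)
        assert val == pytest.approx(5.0 / 3.0, abs=1e-12)
        assert 0 < val < rmsd(pred, truth)

    def test_asymmetry(self):
        truth = np.array([[0.0, 0.0], [0.0, 10.0]])
        pred = np.array([[0.0, 0.0], [0.0, 10.0], [0.0, 20.0]])
        assert nearest_segment_distance(pred, truth) != pytest.approx(
            nearest_segment_distance(truth, pred), abs=1e-9
        )

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            pred = rng.normal(0, 5, (rng.integers(2, 15), 2))
            truth = rng.normal(0, 5, (rng.integers(2, 15), 2))
            assert nearest_segment_distance(pred, truth) == pytest.approx(
                nsd_oracle(pred, truth), abs=1e-10
            )

    def test_never_exceeds_rmsd(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(3, 20)
            a = rng.normal(0, 5, (n, 2))
            b = rng.normal(0, 5, (n, 2))
            assert nearest_segment_distance(a, b) <= rmsd(a, b) + 1e-12

    def test_degenerate_truth_errors(self):
        with pytest.raises(ValueError):
            nearest_segment_distance(_skel(0, 0), np.array([[1.0, 1.0]]))


# ---------------------------------------------------------------- failures


class TestClassifyFailure:
    def test_dtc_below_threshold(self):
        ok, _ = classify_failure("dtc", {"confidences": [0.49, 0.2]})
        assert not ok

    def test_dtc_above_threshold(self):
        ok, _ = classify_failure("dtc", {"confidences": [0.51]})
        assert ok

    def test_dtc_empty(self):
        assert not classify_failure("dtc", {"confidences": []})[0]

    def test_paf_13_points_fails(self):
        assert not classify_failure("paf", {"points": np.zeros((13, 2))})[0]

    def test_paf_14_points_ok(self):
        assert classify_failure("paf", {"points": np.zeros((14, 2))})[0]

    @staticmethod
    def _worm_contour(length=30.0, width=2.0, n_side=15):
        # slender outline with sharp single-vertex head and tail: the two
        # long sides plus one apex vertex at each end
        xs = np.linspace(0.0, length, n_side)
        top = np.column_stack([xs, np.full(n_side, width / 2)])
        bottom = np.column_stack([xs[::-1], np.full(n_side, -width / 2)])
        head = np.array([[length + width, 0.0]])
        tail = np.array([[-width, 0.0]])
        return np.vstack([top, head, bottom, tail])

    def test_tierpsy_two_ends_ok(self):
        contour = self._worm_contour()
        widths = np.array([1.8, 2.0, 2.2])
        ok, reason = classify_failure(
            "tierpsy", {"contour": contour, "widths": widths}
        )
        assert ok, reason

    def test_tierpsy_coil_fails_width_ratio(self):
        contour = self._worm_contour()
        ok, reason = classify_failure(
            "tierpsy", {"contour": contour, "widths": np.array([0.5, 2.0, 4.0])}
        )
        assert not ok and "width" in reason

    def test_omnipose_uses_tierpsy_rule(self):
        # circle: no high-curvature points -> fail under the shared rule
        t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        circle = np.column_stack([np.cos(t), np.sin(t)]) * 10
        ok_t = classify_failure("tierpsy", {"contour": circle})
        ok_o = classify_failure("omnipose", {"contour": circle})
        assert ok_t == ok_o
        assert not ok_o[0]

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown method"):
            classify_failure("sleap", {})


# ---------------------------------------------------------------- fidelity


class TestTrackingFidelity:
    def test_perfect_tracks(self):
        truth = [
            _traj("A", [(t, (10.0 * t, 0.0)) for t in range(10)]),
            _traj("B", [(t, (10.0 * t, 100.0)) for t in range(10)]),
        ]
        pred = [
            _traj(0, [(t, (10.0 * t, 0.0)) for t in range(10)]),
            _traj(1, [(t, (10.0 * t, 100.0)) for t in range(10)]),
        ]
        res = tracking_fidelity(pred, truth)
        assert res.fidelity == 1.0
        assert res.mme_t.sum() == 0

    def test_swap_halfway_gives_half(self):
        # 2 worms x 10 frames, identities swapped from frame 6 onward:
        # mme = 2/frame x 5 frames = 10, sum g = 20 -> fidelity 0.5
        truth = [
            _traj("A", [(t, (0.0, 0.0)) for t in range(10)]),
            _traj("B", [(t, (0.0, 100.0)) for t in range(10)]),
        ]
        pred = [
            _traj(
                0,
                [(t, (0.0, 0.0)) for t in range(5)]
                + [(t, (0.0, 100.0)) for t in range(5, 10)],
            ),
            _traj(
                1,
                [(t, (0.0, 100.0)) for t in range(5)]
                + [(t, (0.0, 0.0)) for t in range(5, 10)],
            ),
        ]
        res = tracking_fidelity(pred, truth)
        assert res.g_t.sum() == 20
        assert res.mme_t.sum() == 10
        assert res.fidelity == 0.5

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(3)
        for trial in range(100):
            n_worms = int(rng.integers(1, 5))
            n_frames = int(rng.integers(3, 20))
            truth, pred = [], []
            for w in range(n_worms):
                pos = [
                    (t, (float(rng.uniform(0, 100)), float(rng.uniform(0, 100))))
                    for t in range(n_frames)
                ]
                truth.append(_traj(f"g{w}", pos))
                # predictions: jittered copies with occasional dropouts and
                # random id structure
                keep = rng.random(n_frames) > 0.2
                jpos = [
                    (t, (p[0] + rng.normal(0, 0.5), p[1] + rng.normal(0, 0.5)))
                    for (t, p), k in zip(pos, keep)
                    if k
                ]
                if jpos:
                    pred.append(_traj(100 + w, jpos))
            if not pred:
                continue
            ours = tracking_fidelity(pred, truth).fidelity
            oracle = fidelity_oracle(pred, truth)
            assert ours == pytest.approx(oracle, abs=1e-10), f"trial {trial}"

    def test_monotone_in_switches(self):
        truth = [
            _traj("A", [(t, (0.0, 0.0)) for t in range(12)]),
            _traj("B", [(t, (0.0, 100.0)) for t in range(12)]),
        ]

        def swapped_from(k):
            a = [(t, (0.0, 0.0)) for t in range(k)] + [
                (t, (0.0, 100.0)) for t in range(k, 12)
            ]
            b = [(t, (0.0, 100.0)) for t in range(k)] + [
                (t, (0.0, 0.0)) for t in range(k, 12)
            ]
            return [_traj(0, a), _traj(1, b)]

        fids = [tracking_fidelity(swapped_from(k), truth).fidelity for k in (11, 8, 5)]
        assert fids[0] > fids[1] > fids[2]

    def test_bounds(self):
        truth = [_traj("A", [(t, (5.0 * t, 0.0)) for t in range(5)])]
        pred = [_traj(0, [(t, (5.0 * t, 0.0)) for t in range(5)])]
        res = tracking_fidelity(pred, truth)
        assert 0.0 <= res.fidelity <= 1.0

    def test_empty_truth_errors(self):
        with pytest.raises(ValueError, match="empty ground truth"):
            tracking_fidelity([], [])

    def test_result_invariants(self):
        with pytest.raises(ValueError):
            TrackMatchResult(frames=[0], mme_t=[2], g_t=[1])


def test_detection_recall_counts_matches():
    class D:
        def __init__(self, skeleton):
            self.skeleton = skeleton

    truth = [_skel(0, 0), _skel(100, 100)]
    dets = [D(_skel(0.5, 0.0))]
    assert detection_recall(dets, truth, max_dist=5.0) == 0.5
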