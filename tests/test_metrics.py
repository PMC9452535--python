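"""Thresholding, sensitivity, random masks, the Predictive Index and
mutual similarity."""

import numpy as np
import pytest
import scipy.stats as st
from scipy.ndimage import label

import ezbattery as ez
from ezbattery import metrics
from ezbattery._grow import grow_region
from ezbattery._rng import substream
from ezbattery.metrics import PIResult, n_suprathreshold
from ezbattery.volumes import BinaryVolume, LabeledVolume, VolumeGrid

from conftest import make_volume


class TestThreshold:
    def test_distinct_values_keep_exact_top_decile(self, grid10, cube_brain):
        rng = np.random.default_rng(0)
        vals = rng.permutation(1000).reshape(10, 10, 10).astype(float)
        t = metrics.threshold_map(make_volume(grid10, vals), cube_brain, 90.0)
        assert t.n90 == 100
        kept = vals[t.mask]
        excluded = vals[~t.mask]
        assert kept.min() > excluded.max()

    def test_constant_map_tie_break_exact_size(self, grid10, cube_brain):
        t = metrics.threshold_map(
            make_volume(grid10, np.zeros((10, 10, 10))), cube_brain, 90.0
        )
        assert t.n90 == 100
        # deterministic tie-break: the 100 lowest linear indices
        np.testing.assert_array_equal(t.member_flat(), np.arange(100))

    def test_p50_keeps_top_half(self):
        grid = VolumeGrid.isotropic((10, 1, 1), 2.0)
        brain = BinaryVolume(grid=grid, mask=np.ones((10, 1, 1), bool))
        vals = np.array([3, 1, 4, 1.5, 5, 9, 2, 6, 5.5, 3.5]).reshape(10, 1, 1)
        t = metrics.threshold_map(make_volume(grid, vals), brain, 50.0)
        top5 = set(np.argsort(vals.ravel())[-5:])
        assert set(t.member_flat()) == top5

    def test_percentile_over_brain_not_box(self, grid10):
        """The percentile counts in-brain voxels only."""
        brain_mask = np.zeros((10, 10, 10), bool)
        brain_mask[:5] = True  # 500 in-brain voxels
        brain = BinaryVolume(grid=grid10, mask=brain_mask)
        vals = np.random.default_rng(1).normal(size=(10, 10, 10))
        t = metrics.threshold_map(make_volume(grid10, vals), brain, 90.0)
        assert t.n90 == n_suprathreshold(500, 90.0) == 50
        assert not np.any(t.mask & ~brain_mask)

    def test_too_few_finite_voxels(self, grid10, cube_brain):
        vals = np.full((10, 10, 10), np.nan)
        vals[0, 0, 0] = 1.0
        with pytest.raises(ValueError, match="finite"):
            metrics.threshold_map(make_volume(grid10, vals), cube_brain, 90.0)

    def test_bad_percentile(self, grid10, cube_brain):
        with pytest.raises(ValueError):
            metrics.threshold_map(
                make_volume(grid10, np.zeros((10, 10, 10))), cube_brain, 0.0
            )


class TestSensitivity:
    def _tmap(self, grid, mask):
        return metrics.ThresholdedMap("s", "m", 90.0, mask, grid)

    def test_covering_resection_gives_one(self, grid10):
        tmask = np.zeros((10, 10, 10), bool)
        tmask[:5] = True
        res = np.zeros((10, 10, 10), bool)
        res[0, :5, :] = True  # 50 voxels, all inside tmask
        r = metrics.sensitivity(
            self._tmap(grid10, tmask), BinaryVolume(grid=grid10, mask=res)
        )
        assert r.sen == 1.0
        assert r.tp == 50

    def test_disjoint_gives_zero(self, grid10):
        tmask = np.zeros((10, 10, 10), bool)
        tmask[:2] = True
        res = np.zeros((10, 10, 10), bool)
        res[5:] = True
        assert metrics.sensitivity(
            self._tmap(grid10, tmask), BinaryVolume(grid=grid10, mask=res)
        ).sen == 0.0

    def test_partial_overlap_arithmetic(self, grid10):
        tmask = np.zeros((10, 10, 10), bool)
        tmask[0, :5, :5] = True  # 25 voxels
        res = np.zeros((10, 10, 10), bool)
        res[0] = True  # 100 voxels, overlap 25
        r = metrics.sensitivity(
            self._tmap(grid10, tmask), BinaryVolume(grid=grid10, mask=res)
        )
        assert r.sen == pytest.approx(0.25)
        assert r.tp + r.fp == tmask.sum()

    def test_empty_resection_rejected(self, grid10):
        tmask = np.ones((10, 10, 10), bool)
        with pytest.raises(ValueError, match="empty resection"):
            metrics.sensitivity(
                self._tmap(grid10, tmask),
                BinaryVolume(grid=grid10, mask=np.zeros((10, 10, 10), bool)),
            )


class TestRandomMask:
    def test_size_one_is_single_in_brain_voxel(self, cube_brain):
        m = metrics.generate_random_mask(cube_brain, 1, substream(0, "x"))
        assert m.n_members == 1
        assert not np.any(m.mask & ~cube_brain.mask)

    def test_full_size_is_whole_brain(self, slab_brain):
        m = metrics.generate_random_mask(slab_brain, 36, substream(1, "x"))
        np.testing.assert_array_equal(m.mask, slab_brain.mask)

    def test_connected_exact_size(self, cube_brain):
        m = metrics.generate_random_mask(cube_brain, 137, substream(2, "x"))
        assert m.n_members == 137
        assert label(m.mask)[1] == 1

    def test_oversized_rejected(self, slab_brain):
        with pytest.raises(ValueError):
            metrics.generate_random_mask(slab_brain, 37, substream(3, "x"))

    def test_seed_voxel_uniform_over_brain(self):
        """χ² goodness-of-fit of seed-voxel counts to uniformity."""
        grid = VolumeGrid.isotropic((10, 10, 2), 2.0)
        brain = BinaryVolume(grid=grid, mask=np.ones((10, 10, 2), bool))
        rng = substream(4, "seeds")
        n_draws = 8000
        counts = np.zeros(200)
        for _ in range(n_draws):
            m = metrics.generate_random_mask(brain, 10, rng)
            flat = np.ravel_multi_index(m.seed_voxel, (10, 10, 2))
            counts[flat] += 1
        chi2 = ((counts - n_draws / 200) ** 2 / (n_draws / 200)).sum()
        p = st.chi2.sf(chi2, df=199)
        assert p > 0.01

    def test_grower_matches_reference_implementation(self):
        """The compiled region grower equals a plain-python re-implementation
        driven by the same uniform stream."""
        shape = (5, 5, 3)
        allowed = np.ones(shape, bool)
        allowed[2, 2, 1] = False
        seed_flat = 0
        size = 20
        rand = np.random.default_rng(5).random(size)

        class _FixedRng:
            def __init__(self, seq):
                self.seq = list(seq)

            def random(self, n):
                out = np.array(self.seq[:n])
                del self.seq[:n]
                return out

        got = grow_region(allowed, np.array([seed_flat]), size, _FixedRng(rand))

        # reference: same algorithm, straightforward python data structures
        def neighbours(idx):
            x, y, z = np.unravel_index(idx, shape)
            for dx, dy, dz in ((-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0),
                               (0, 0, -1), (0, 0, 1)):
                xx, yy, zz = x + dx, y + dy, z + dz
                if 0 <= xx < shape[0] and 0 <= yy < shape[1] and 0 <= zz < shape[2]:
                    if allowed[xx, yy, zz]:
                        yield int(np.ravel_multi_index((xx, yy, zz), shape))

        region = [seed_flat]
        in_region = {seed_flat}
        frontier = []
        in_frontier = set()
        for nb in neighbours(seed_flat):
            frontier.append(nb)
            in_frontier.add(nb)
        for r in rand:
            pick = min(int(r * len(frontier)), len(frontier) - 1)
            idx = frontier[pick]
            frontier[pick] = frontier[-1]
            frontier.pop()
            in_frontier.discard(idx)
            region.append(idx)
            in_region.add(idx)
            for nb in neighbours(idx):
                if nb not in in_region and nb not in in_frontier:
                    frontier.append(nb)
                    in_frontier.add(nb)
            if len(region) == size:
                break
        assert sorted(got) == sorted(region)
        assert list(got) == region


class TestPredictiveIndex:
    def test_sen0_one_gives_pi_one(self, cube_brain):
        tmask = np.zeros((10, 10, 10), bool)
        tmask[:3] = True
        res = np.zeros((10, 10, 10), bool)
        res[0, :5, :5] = True  # inside tmask
        r = metrics.predictive_index(
            metrics.ThresholdedMap("s", "m", 90.0, tmask, cube_brain.grid),
            BinaryVolume(grid=cube_brain.grid, mask=res, role="resection"),
            cube_brain, [0.2], k=200, rng=substream(0, "pi"),
        )
        assert r.sen0 == 1.0
        assert r.pi == 1.0

    def test_whole_brain_threshold_degenerate(self, slab_brain):
        t = metrics.ThresholdedMap("s", "m", 90.0, slab_brain.mask, slab_brain.grid)
        res = np.zeros((6, 6, 1), bool)
        res[2:4, 2:4, 0] = True
        r = metrics.predictive_index(
            t, BinaryVolume(grid=slab_brain.grid, mask=res, role="resection"),
            slab_brain, [0.032], k=100, rng=substream(1, "pi"),
        )
        assert r.sen0 == 1.0
        assert (r.null_sens == 1.0).all()
        assert r.pi == 1.0

    def test_pi_monotone_in_sen0_with_fixed_null(self):
        null = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        pis = [PIResult(sen0=s, null_sens=null, k=5).pi
               for s in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)]
        assert all(b >= a for a, b in zip(pis, pis[1:]))
        assert pis[-1] == 1.0

    def test_default_k_is_1000(self, cube_brain):
        tmask = np.zeros((10, 10, 10), bool)
        tmask[:1] = True
        res = np.zeros((10, 10, 10), bool)
        res[5] = True
        r = metrics.predictive_index(
            metrics.ThresholdedMap("s", "m", 90.0, tmask, cube_brain.grid),
            BinaryVolume(grid=cube_brain.grid, mask=res, role="resection"),
            cube_brain, [0.1], rng=substream(2, "pi"),
        )
        assert r.k == 1000
        assert len(r.null_sens) == 1000


def exhaustive_domino_pi(t_mask_2d, sen0):
    """Exact PI over all size-2 connected masks on a 6×6 slab.

    Under uniform-seed, uniform-frontier growth the probability of the
    domino {u, v} is (1/36)(1/deg(u)) + (1/36)(1/deg(v)) with deg the
    in-slab 4-neighbour count — computed analytically, independent of the
    sampler.
    """
    def deg(x, y):
        return sum(
            1 for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if 0 <= x + dx < 6 and 0 <= y + dy < 6
        )

    total_exceed = 0.0
    total = 0.0
    for x in range(6):
        for y in range(6):
            for dx, dy in ((1, 0), (0, 1)):
                u, v = (x, y), (x + dx, y + dy)
                if v[0] >= 6 or v[1] >= 6:
                    continue
                prob = (1 / 36) * (1 / deg(*u)) + (1 / 36) * (1 / deg(*v))
                total += prob
                sen = (t_mask_2d[u] + t_mask_2d[v]) / 2
                if sen > sen0:
                    total_exceed += prob
    assert total == pytest.approx(1.0)
    return 1.0 - total_exceed


class TestEnumerationOracle:
    def test_monte_carlo_pi_matches_exhaustive_placement(self, slab_brain):
        """MC PI at K = 10000 agrees with the enumerated placement null."""
        rng0 = np.random.default_rng(42)
        vals = rng0.normal(size=(6, 6, 1))
        vol = make_volume(slab_brain.grid, vals)
        t = metrics.threshold_map(vol, slab_brain, 90.0)  # N90 = 4
        # resection: one suprathreshold voxel + one neighbour outside
        top = np.argwhere(t.mask)[0]
        res = np.zeros((6, 6, 1), bool)
        res[tuple(top)] = True
        nb = (top[0] + 1, top[1], 0) if top[0] < 5 else (top[0] - 1, top[1], 0)
        res[nb] = True
        resection = BinaryVolume(grid=slab_brain.grid, mask=res, role="resection")
        sen0 = metrics.sensitivity(t, resection).sen
        pi_exact = exhaustive_domino_pi(t.mask[:, :, 0], sen0)
        pool = [2 * slab_brain.grid.voxel_volume_cm3]
        r = metrics.predictive_index(
            t, resection, slab_brain, pool, k=10_000, rng=substream(7, "mc")
        )
        assert abs(r.pi - pi_exact) <= 0.02


class TestMutualSimilarity:
    def _tmap(self, grid, flat_members, n=36):
        mask = np.zeros(grid.dims, bool)
        mask.ravel()[list(flat_members)] = True
        return metrics.ThresholdedMap("s", "m", 90.0, mask, grid)

    def test_identity_is_one(self, slab_grid):
        a = self._tmap(slab_grid, range(4))
        assert metrics.mutual_similarity(a, a) == 1.0

    def test_disjoint_is_zero(self, slab_grid):
        a = self._tmap(slab_grid, range(4))
        b = self._tmap(slab_grid, range(10, 14))
        assert metrics.mutual_similarity(a, b) == 0.0

    def test_arithmetic_and_symmetry(self, slab_grid):
        a = self._tmap(slab_grid, range(10))
        b = self._tmap(slab_grid, range(3, 13))
        assert metrics.mutual_similarity(a, b) == pytest.approx(0.7)
        assert metrics.mutual_similarity(b, a) == metrics.mutual_similarity(a, b)

    def test_mismatched_n90_rejected(self, slab_grid):
        a = self._tmap(slab_grid, range(4))
        b = self._tmap(slab_grid, range(5))
        with pytest.raises(ValueError, match="common N90"):
            metrics.mutual_similarity(a, b)


def _cohort_from_values(values_by_cell, grid, brain_mask, res_mask):
    """Build an in-memory cohort from explicit per-cell value arrays."""
    subjects = sorted({s for s, _ in values_by_cell})
    methods = sorted({m for _, m in values_by_cell})
    maps = {
        (s, m): LabeledVolume(grid=grid, values=v, label=m, subject=s)
        for (s, m), v in values_by_cell.items()
    }
    brain = BinaryVolume(grid=grid, mask=brain_mask)
    res = BinaryVolume(grid=grid, mask=res_mask, role="resection")
    return ez.Cohort(subjects, methods,
                     maps, {s: res for s in subjects}, {s: brain for s in subjects})


class TestSimilarityMatrix:
    def test_mean_over_subjects(self, grid10):
        rng = np.random.default_rng(3)
        brain = np.ones((10, 10, 10), bool)
        res = np.zeros((10, 10, 10), bool)
        res[0, 0, :2] = True
        cells = {
            (s, m): rng.normal(size=(10, 10, 10))
            for s in ("s1", "s2") for m in ("a", "b")
        }
        cohort = _cohort_from_values(cells, grid10, brain, res)
        sim = ez.average_similarity_matrix(cohort)
        t = metrics.threshold_cohort(cohort)
        expected = np.mean([
            metrics.mutual_similarity(t[("s1", "a")], t[("s1", "b")]),
            metrics.mutual_similarity(t[("s2", "a")], t[("s2", "b")]),
        ])
        assert sim.values.loc["a", "b"] == pytest.approx(expected)
        assert sim.counts.loc["a", "b"] == 2
        assert sim.values.loc["a", "a"] == 1.0

    def test_duplicate_methods_have_similarity_one(self, grid10):
        vals = np.random.default_rng(4).normal(size=(10, 10, 10))
        brain = np.ones((10, 10, 10), bool)
        res = np.zeros((10, 10, 10), bool)
        res[0, 0, :2] = True
        cohort = _cohort_from_values(
            {("s1", "a"): vals, ("s1", "b"): vals.copy()}, grid10, brain, res
        )
        sim = ez.average_similarity_matrix(cohort)
        assert sim.values.loc["a", "b"] == 1.0

    def test_never_coobserved_pair_is_missing(self, grid10):
        rng = np.random.default_rng(5)
        brain = np.ones((10, 10, 10), bool)
        res = np.zeros((10, 10, 10), bool)
        res[0, 0, :2] = True
        cells = {
            ("s1", "a"): rng.normal(size=(10, 10, 10)),
            ("s2", "b"): rng.normal(size=(10, 10, 10)),
        }
        cohort = _cohort_from_values(cells, grid10, brain, res)
        sim = ez.average_similarity_matrix(cohort)
        assert np.isnan(sim.values.loc["a", "b"])
        assert sim.counts.loc["a", "b"] == 0


class TestPITable:
    def test_cell_count_and_missing(self):
        spec = ez.CohortSpec(
            n_subjects=3,
            methods=[ez.MethodSpec("a", 0.5), ez.MethodSpec("b", 0.5)],
            seed=20,
        )
        syn = ez.generate_cohort(spec)
        pi = ez.compute_pi_table(syn.cohort, k=50, seed=20)
        assert pi.shape == (3, 2)
        assert pi.notna().to_numpy().sum() == 6

    def test_determinism_and_cell_independence(self):
        spec = ez.CohortSpec(
            n_subjects=2,
            methods=[ez.MethodSpec("a", 0.5), ez.MethodSpec("b", 0.5)],
            seed=21,
        )
        syn = ez.generate_cohort(spec)
        pi1 = ez.compute_pi_table(syn.cohort, k=50, seed=21)
        pi2 = ez.compute_pi_table(syn.cohort, k=50, seed=21)
        np.testing.assert_array_equal(pi1.to_numpy(), pi2.to_numpy())
        # removing a method leaves the other cells untouched
        spec_b = ez.CohortSpec(
            n_subjects=2, methods=[ez.MethodSpec("a", 0.5)], seed=21
        )
        syn_b = ez.generate_cohort(spec_b)
        pi_b = ez.compute_pi_table(syn_b.cohort, k=50, seed=21)
        np.testing.assert_array_equal(pi_b["a"].to_numpy(), pi1["a"].to_numpy())
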