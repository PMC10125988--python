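"""G/F/K estimators, CSR-on-lattice configurations, and the clustering permutation."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from glomnet.spatial import (
    InsufficientEventsError,
    InvalidMaskError,
    PointPattern,
    csr_envelope,
    f_function,
    g_function,
    generate_clustered_configuration,
    generate_random_configuration,
    k_function,
)


def _pattern(points, events=None):
    pts = np.asarray(points, dtype=float)
    mask = np.ones(len(pts), dtype=bool) if events is None else np.asarray(events)
    return PointPattern(pts, mask)


class TestGFunction:
    def test_hand_enumerated_nearest_neighbours(self):
        # events at 0, 3, 7 on a line (plus hull-filling corners, unselected)
        pts = [(0, 0), (3, 0), (7, 0), (0, 10), (10, 10)]
        pat = _pattern(pts, [True, True, True, False, False])
        est = g_function(pat, np.array([2.9, 3.0, 3.9, 4.0, 100.0]))
        assert est.values == pytest.approx([0, 2 / 3, 2 / 3, 1.0, 1.0])

    def test_two_events_step(self):
        pat = _pattern([(0, 0), (5, 0), (0, 9), (9, 9)], [True, True, False, False])
        est = g_function(pat, np.array([4.999, 5.0, 5.001]))
        assert est.values == pytest.approx([0.0, 1.0, 1.0])

    def test_requires_two_events(self):
        pat = _pattern([(0, 0), (1, 1), (2, 0)], [True, False, False])
        with pytest.raises(InsufficientEventsError):
            g_function(pat, np.array([1.0]))

    def test_monotone_and_bounded(self, small_lattice):
        mask = generate_random_configuration(small_lattice, 0.3, seed=1)
        est = g_function(small_lattice.with_mask(mask), np.linspace(0, 30, 60))
        assert (np.diff(est.values) >= 0).all()
        assert est.values[0] >= 0 and est.values[-1] == 1.0


class TestFFunction:
    def test_single_event_distances_by_hand(self):
        # one event at the square center; reference points land in the hull
        pts = [(0, 0), (10, 0), (10, 10), (0, 10), (5, 5)]
        pat = _pattern(pts, [False, False, False, False, True])
        est = f_function(pat, np.array([0.0, 8.0]), n_ref_points=200, seed=3)
        # max distance from any hull point to center is sqrt(50) ~ 7.07 < 8
        assert est.values[-1] == 1.0
        refs_dists_oracle = est.values[0]
        assert refs_dists_oracle == 0.0

    def test_seed_determinism(self, small_lattice):
        mask = generate_random_configuration(small_lattice, 0.3, seed=2)
        pat = small_lattice.with_mask(mask)
        grid = np.linspace(0, 10, 20)
        a = f_function(pat, grid, seed=7)
        b = f_function(pat, grid, seed=7)
        assert (a.values == b.values).all()

    def test_zero_events_rejected(self, small_lattice):
        pat = small_lattice.with_mask(np.zeros(len(small_lattice.coordinates), bool))
        with pytest.raises(InsufficientEventsError):
            f_function(pat, np.array([1.0]))


class TestKFunction:
    def test_two_event_hand_value(self):
        pts = [(0, 0), (1, 0), (0, 5), (5, 5), (5, 0)]
        pat = _pattern(pts, [True, True, False, False, False])
        area = pat.area
        est = k_function(pat, np.array([0.5, 1.0, 1.5]))
        # strict inequality: pair at distance exactly 1 not counted at r=1
        assert est.values == pytest.approx([0.0, 0.0, area / 2])

    def test_zero_at_zero(self, small_lattice):
        mask = generate_random_configuration(small_lattice, 0.2, seed=4)
        est = k_function(small_lattice.with_mask(mask), np.array([0.0, 5.0]))
        assert est.values[0] == 0.0
        assert (np.diff(est.values) >= 0).all()

    def test_agrees_with_bruteforce_oracle(self):
        """Exact agreement with a double-loop evaluation on small patterns."""
        rng = np.random.default_rng(5)
        for n in (10, 30, 50):
            pts = rng.uniform(0, 100, size=(n, 2))
            pat = _pattern(pts)
            radii = np.linspace(0, 60, 13)
            est = k_function(pat, radii)
            area = pat.area
            lam = n / area
            oracle = []
            for r in radii:
                count = 0
                for i in range(n):
                    for j in range(n):
                        if i != j and np.hypot(*(pts[i] - pts[j])) < r:
                            count += 1
                oracle.append(count / (lam * n))
            assert est.values == pytest.approx(oracle)


class TestRandomConfiguration:
    def test_bernoulli_count_and_determinism(self, small_lattice):
        n = len(small_lattice.coordinates)
        mask = generate_random_configuration(small_lattice, 0.3, seed=6)
        sd = np.sqrt(n * 0.3 * 0.7)
        assert abs(mask.sum() - 0.3 * n) < 5 * sd
        mask2 = generate_random_configuration(small_lattice, 0.3, seed=6)
        assert (mask == mask2).all()

    def test_fraction_bounds(self, small_lattice):
        with pytest.raises(ValueError):
            generate_random_configuration(small_lattice, 0.0, seed=0)
        with pytest.raises(ValueError):
            generate_random_configuration(small_lattice, 1.0, seed=0)


class TestClusteredConfiguration:
    def test_zero_trials_identity(self, small_lattice):
        mask = generate_random_configuration(small_lattice, 0.3, seed=8)
        out = generate_clustered_configuration(small_lattice, mask, trials=0, seed=9)
        assert (out == mask).all()

    def test_count_conserved_and_nn_shrinks(self, small_lattice):
        mask = generate_random_configuration(small_lattice, 0.3, seed=10)
        out = generate_clustered_configuration(
            small_lattice, mask, trials=20000, seed=11
        )
        assert out.sum() == mask.sum()

        def mean_nn(m):
            ev = small_lattice.coordinates[m]
            d, _ = cKDTree(ev).query(ev, k=2)
            return d[:, 1].mean()

        assert mean_nn(out) < mean_nn(mask)

    def test_invalid_masks(self, small_lattice):
        n = len(small_lattice.coordinates)
        with pytest.raises(InvalidMaskError):
            generate_clustered_configuration(small_lattice, np.zeros(n, bool), seed=0)
        with pytest.raises(InvalidMaskError):
            generate_clustered_configuration(small_lattice, np.ones(n, bool), seed=0)

    def test_clustered_escapes_csr_envelope_random_stays_inside(self, small_lattice):
        """G of a clustered mask exceeds the CSR envelope at small distances."""
        grid = np.linspace(0.5, 10, 20)
        env = csr_envelope(small_lattice, 0.3, grid, kind="G", n_sim=50, seed=12)
        rand_mask = generate_random_configuration(small_lattice, 0.3, seed=13)
        clus_mask = generate_clustered_configuration(
            small_lattice, rand_mask, trials=20000, seed=14
        )
        g_rand = g_function(small_lattice.with_mask(rand_mask), grid).values
        g_clus = g_function(small_lattice.with_mask(clus_mask), grid).values
        hi = env["hi"].to_numpy()
        lo = env["lo"].to_numpy()
        # pointwise 95% envelope: the random config stays inside nearly everywhere
        inside = (g_rand >= lo) & (g_rand <= hi)
        assert inside.mean() >= 0.85
        # the clustered config escapes above at small d
        assert (g_clus > hi)[:10].sum() >= 5


def test_pattern_csv_roundtrip(tmp_path, small_lattice):
    mask = generate_random_configuration(small_lattice, 0.25, seed=15)
    pat = small_lattice.with_mask(mask)
    path = tmp_path / "somas.csv"
    pat.to_csv(path)
    back = PointPattern.from_csv(path)
    assert np.allclose(back.coordinates, pat.coordinates)
    assert (back.event_mask == pat.event_mask).all()
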