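"""Coarse-graining machinery: pairing, hierarchy, scaling observables."""

import numpy as np
import pytest

from brainprg import prg, synthetic as syn
from brainprg.core import BinaryRaster
from brainprg.signals import pairwise_pearson


def greedy_pairing_oracle(s):
    """Reference re-execution of the greedy rule with explicit argmax loops."""
    s = s.copy().astype(float)
    n = s.shape[0]
    alive = set(range(n))
    pairs = []
    while len(alive) >= 2:
        best = None
        for i in sorted(alive):
            for j in sorted(alive):
                if j <= i:
                    continue
                if best is None or s[i, j] > best[0]:
                    best = (s[i, j], i, j)
        _, i, j = best
        pairs.append((i, j))
        alive -= {i, j}
    leftover = alive.pop() if alive else None
    return pairs, leftover


class TestPairGreedy:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("n", [4, 7, 12])
    def test_matches_exhaustive_greedy_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        s = rng.uniform(-1, 1, (n, n))
        s = 0.5 * (s + s.T)
        p = prg.pair_greedy(s)
        pairs, leftover = greedy_pairing_oracle(s)
        assert list(p.pairs) == pairs
        assert p.leftover == leftover

    def test_odd_count_leaves_one_leftover(self):
        s = np.array([[0, 0.9, 0.1], [0.9, 0, 0.2], [0.1, 0.2, 0]])
        p = prg.pair_greedy(s)
        assert p.pairs == ((0, 1),) and p.leftover == 2

    def test_ties_broken_by_smallest_first_index(self):
        s = np.zeros((4, 4))
        s[0, 1] = s[1, 0] = 0.5
        s[2, 3] = s[3, 2] = 0.5
        p = prg.pair_greedy(s)
        assert p.pairs[0] == (0, 1)


class TestCoarseGrainRaster:
    def test_paired_rows_summed(self):
        r = BinaryRaster(values=np.array([[0, 1, 0], [1, 1, 0]]), level=0)
        out = prg.coarse_grain_raster(r, prg.Pairing(pairs=((0, 1),)))
        assert np.array_equal(out.values, [[1, 2, 0]])
        assert out.level == 1

    def test_total_activity_conserved_without_leftover(self):
        r = syn.generate_independent_raster(16, 50, 0.3, seed=40)
        p = prg.pair_greedy(pairwise_pearson(r))
        out = prg.coarse_grain_raster(r, p)
        assert np.array_equal(out.values.sum(axis=0), r.values.sum(axis=0))

    def test_level_k_entries_equal_member_sums(self):
        r = syn.generate_independent_raster(32, 200, 0.3, seed=41)
        h = prg.run_prg(r, k_max=3)
        for k in range(4):
            for var, members in enumerate(h.memberships[k]):
                assert np.array_equal(h.rasters[k].values[var],
                                      r.values[members].sum(axis=0))


class TestCoarseGrainConnectivity:
    def test_four_cross_weights_averaged(self):
        C = np.zeros((4, 4))
        C[0, 2], C[0, 3], C[1, 2], C[1, 3] = 0.2, 0.1, 0.3, 0.4
        C = C + C.T
        out = prg.coarse_grain_connectivity(C, prg.Pairing(pairs=((0, 1), (2, 3))))
        assert out[0, 1] == pytest.approx(0.25)
        assert out[0, 0] == 0.0

    def test_uniform_matrix_stays_uniform(self):
        C = np.full((8, 8), 0.3)
        np.fill_diagonal(C, 0.0)
        p = prg.Pairing(pairs=((0, 1), (2, 3), (4, 5), (6, 7)))
        out = prg.coarse_grain_connectivity(C, p)
        off = out[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.3)

    def test_level_k_weight_is_mean_of_4k_original_cross_weights(self):
        """Structural identity of connectivity coarse-graining: at level k
        each coarse weight equals the exact mean of the 4^k cross-pair
        weights of the original matrix."""
        rng = np.random.default_rng(42)
        n = 64
        C0 = rng.random((n, n))
        C0 = 0.5 * (C0 + C0.T)
        np.fill_diagonal(C0, 0.0)
        raster = syn.generate_independent_raster(n, 200, 0.3, seed=43)
        h = prg.run_prg(raster, k_max=4, mode="connectivity", C=C0)
        for k in (2, 3, 4):
            Ck = h.connectivities[k]
            members = h.memberships[k]
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    expected = C0[np.ix_(members[a], members[b])].mean()
                    assert Ck[a, b] == pytest.approx(expected, abs=1e-12)


class TestRunPrg:
    def test_kmax_zero_is_identity(self):
        r = syn.generate_independent_raster(8, 100, 0.2, seed=44)
        h = prg.run_prg(r, k_max=0)
        assert h.k_max == 0
        assert np.array_equal(h.rasters[0].values, r.values)

    def test_fully_correlated_stays_perfectly_correlated(self):
        r = syn.generate_fully_correlated_raster(32, 400, 0.3, seed=45)
        h = prg.run_prg(r, k_max=3)
        for level in range(1, 4):
            c = pairwise_pearson(h.rasters[level])
            assert np.allclose(c, 1.0)

    def test_retained_counts_follow_floor_halving(self):
        r = syn.generate_independent_raster(100, 700, 0.3, seed=46)
        h = prg.run_prg(r, k_max=5)
        counts = [ras.n_nodes for ras in h.rasters]
        assert counts == [100, 50, 25, 12, 6, 3]
        assert [d.size for d in h.discarded] == [0, 0, 4, 0, 0]

    def test_insufficient_frames_rejected_with_admissible_depth(self):
        r = syn.generate_independent_raster(200, 100, 0.3, seed=47)
        with pytest.raises(ValueError, match="2\\^3"):
            prg.run_prg(r, k_max=6)

    def test_duplicate_pairs_group_with_their_twins(self):
        rng = np.random.default_rng(48)
        base = (rng.random((5, 600)) < 0.4).astype(np.int8)
        values = np.vstack([base, base])  # node i duplicates node i+5
        r = BinaryRaster(values=values, level=0)
        h = prg.run_prg(r, k_max=1)
        assert all(j == i + 5 for i, j in h.pairings[0].pairs)

    def test_connectivity_pairing_ignores_the_raster(self, edr_small):
        r1 = syn.generate_independent_raster(64, 400, 0.3, seed=49)
        r2 = syn.generate_powerlaw_correlated_raster(
            syn.generate_positions(64, seed=50), 0.5, n_frames=400, seed=51)
        h1 = prg.run_prg(r1, k_max=3, mode="connectivity", C=edr_small)
        h2 = prg.run_prg(r2, k_max=3, mode="connectivity", C=edr_small)
        for p1, p2 in zip(h1.pairings, h2.pairings):
            assert p1.pairs == p2.pairs

    def test_membership_is_a_partition(self):
        r = syn.generate_independent_raster(50, 400, 0.3, seed=52)
        h = prg.run_prg(r, k_max=3)
        members = np.concatenate(h.memberships[3])
        dropped = (np.concatenate(h.discarded)
                   if any(d.size for d in h.discarded) else np.array([], int))
        all_ids = np.sort(np.concatenate([members, dropped]))
        assert members.size == len(h.memberships[3]) * 8
        assert np.array_equal(np.unique(members), np.sort(members))
        assert np.array_equal(all_ids, np.arange(50))


class TestObservables:
    def test_variance_curve_normalized_at_one(self):
        r = syn.generate_independent_raster(64, 1000, 0.25, seed=53)
        curve, _ = prg.variance_curve(prg.run_prg(r, k_max=3))
        assert curve.values[0] == pytest.approx(1.0)

    def test_silence_of_fully_correlated_raster_is_scale_free(self):
        r = syn.generate_fully_correlated_raster(64, 1000, 0.3, seed=54)
        curve, fit = prg.silence_curve(prg.run_prg(r, k_max=3))
        assert np.allclose(curve.values, 1.0)
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_silence_reference_matches_direct_count(self):
        r = syn.generate_independent_raster(64, 1000, 0.25, seed=55)
        curve, _ = prg.silence_curve(prg.run_prg(r, k_max=2))
        assert curve.reference == pytest.approx(
            np.log((r.values == 0).mean()))

    def test_all_silent_raster_rejected(self):
        r = BinaryRaster(values=np.zeros((16, 200), dtype=np.int8), level=0)
        with pytest.raises(ValueError):
            prg.silence_curve(prg.run_prg(r, k_max=2))

    def test_fully_correlated_spectrum_has_single_mode(self):
        r = syn.generate_fully_correlated_raster(64, 1500, 0.3, seed=56)
        h = prg.run_prg(r, k_max=4)
        spectra, _ = prg.eigenspectrum_curve(h, K_set=(8, 16))
        for K, spec in spectra.items():
            assert spec[0] > 0
            assert np.all(np.abs(spec[1:]) < 1e-10 * spec[0])

    def test_independent_spectrum_is_flat(self):
        r = syn.generate_independent_raster(64, 4000, 0.3, seed=57)
        h = prg.run_prg(r, k_max=4)
        _, fit = prg.eigenspectrum_curve(h, K_set=(8, 16))
        assert abs(fit.exponent) < 0.15

    def test_cluster_eigenvalues_match_direct_decomposition(self):
        r = syn.generate_independent_raster(32, 500, 0.3, seed=58)
        h = prg.run_prg(r, k_max=4)
        spectra, _ = prg.eigenspectrum_curve(h, K_set=(8, 16))
        acc = np.zeros(8)
        v0 = r.values.astype(float)
        for members in h.memberships[3]:
            x = v0[members]
            xc = x - x.mean(axis=1, keepdims=True)
            cov = xc @ xc.T / x.shape[1]
            acc += np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(spectra[8], acc / len(h.memberships[3]), atol=1e-10)


class TestMuEtaRelation:
    @pytest.mark.parametrize("D,eta,expected", [
        (3.0, 0.513, 0.829), (3.0, 0.0, 1.0), (3.0, 3.0, 0.0)])
    def test_arithmetic(self, D, eta, expected):
        assert prg.mu_eta_relation(D, eta) == pytest.approx(expected, abs=1e-3)

    def test_eta_exceeding_dimension_rejected(self):
        with pytest.raises(ValueError):
            prg.mu_eta_relation(3.0, 3.5)


class TestSubsample:
    def test_full_fraction_reproduces_full_exponents(self):
        r = syn.generate_independent_raster(80, 700, 0.3, seed=59)
        full = prg.run_prg(r, k_max=4)
        _, afit = prg.variance_curve(full)
        sub = prg.subsample_prg(r, fraction=1.0, k_max=4)
        assert sub["alpha"] == pytest.approx(afit.exponent)

    def test_same_seed_same_subset(self):
        r = syn.generate_independent_raster(80, 700, 0.3, seed=60)
        a = prg.subsample_prg(r, fraction=0.5, seed=61, k_max=4)
        b = prg.subsample_prg(r, fraction=0.5, seed=61, k_max=4)
        assert np.array_equal(a["nodes"], b["nodes"])
        assert a["alpha"] == b["alpha"]

    def test_too_small_subset_rejected(self):
        r = syn.generate_independent_raster(80, 700, 0.3, seed=62)
        with pytest.raises(ValueError):
            prg.subsample_prg(r, fraction=0.1, k_max=4)
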