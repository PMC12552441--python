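"""Fluctuation comparison, peak cutoff, mode matching, LMI and RV2."""

import itertools

import numpy as np
import pytest
from conftest import transform_structure
from phosdyn.dynamics import (classify_coupling_change, compare_couplings,
                              compare_fluctuations, derive_peak_cutoff,
                              find_peaks_1d, fluctuation_correlations,
                              global_flexibility_test, lmi_matrix,
                              local_fluctuation_calls, match_modes,
                              neighborhood_fluctuation_test,
                              residue_communities, rmsip, rv2_coefficient,
                              window_mode_similarity)
from phosdyn.enm import ModeSet, build_atomistic_enm, rtb_modes
from phosdyn.synthetic import SyntheticSpec, two_state_ensemble


def random_orthonormal(dim, k, seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(dim, k)))
    return q


class TestFluctuationProfiles:
    def test_identical_profiles_r_one(self, small_ensemble):
        corr = fluctuation_correlations(small_ensemble)
        assert all(-1 <= v <= 1 for vals in corr.values() for v in vals)

    def test_pearson_matches_direct_formula(self):
        a = np.array([1, 2, 5, 2, 1, 1, 2, 8, 2, 1.0])
        b = np.array([1, 2, 1, 2, 5, 1, 2, 1, 8, 1.0])
        am, bm = a - a.mean(), b - b.mean()
        want = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(want)

    def test_global_ks_identical_medians(self, small_ensemble):
        res = global_flexibility_test(small_ensemble)
        assert 0 <= res.p_value <= 1

    def test_global_ks_disjoint_supports(self):
        from phosdyn.stats import ks_two_sample
        a = np.linspace(0, 1, 20)
        res = ks_two_sample(a, a + 5.0)
        assert res.statistic_value == pytest.approx(1.0)


class TestPeakCutoff:
    def test_strict_local_maxima(self):
        prof = np.array([0, 2, 1, 3, 3, 1, 0.5])
        peaks = find_peaks_1d(prof)
        assert (1, 2.0) in peaks
        assert (3, 3.0) in peaks          # leftmost of the plateau
        assert all(i != 4 for i, _ in peaks)

    def test_constant_profiles_error(self):
        with pytest.raises(ValueError):
            derive_peak_cutoff([np.ones(10)])

    def test_no_outlier_hand_computed(self):
        # peaks engineered at heights 1..5 with no IQR outliers
        profiles = [np.array([0, h, 0]) for h in (1, 2, 3, 4, 5.0)]
        got = derive_peak_cutoff(profiles)
        h = np.array([1, 2, 3, 4, 5.0])
        assert got == pytest.approx(np.median(h) + 6 * np.std(h))

    def test_outlier_removed_before_cutoff(self):
        heights = [1, 1.1, 1.2, 0.9, 1.0, 40.0]
        profiles = [np.array([0, h, 0]) for h in heights]
        got = derive_peak_cutoff(profiles)
        h = np.array(heights)
        q1, q3 = np.percentile(h, [25, 75])
        iqr = q3 - q1
        keep = h[(h >= q1 - 1.5 * iqr) & (h <= q3 + 1.5 * iqr)]
        assert 40.0 not in keep
        assert got == pytest.approx(np.median(keep) + 6 * np.std(keep))

    def test_peak_exactly_at_cutoff_not_significant(self, small_ensemble):
        comp = compare_fluctuations(small_ensemble)
        if not comp.peaks:
            pytest.skip("no peaks in this ensemble")
        top = max(h for _, h in comp.peaks)
        comp = local_fluctuation_calls(comp, cutoff=top)
        assert all(h > top for _, h in comp.significant_peaks)
        assert (0, top) not in comp.significant_peaks


class TestNeighborhood:
    def test_neighborhood_membership_by_cb_rule(self, small_ensemble):
        from phosdyn.dynamics import phosphosite_neighborhood
        site = sorted(small_ensemble.group.site_indices)[0]
        neigh = phosphosite_neighborhood(small_ensemble, site)
        assert neigh is not None
        # brute-force oracle: union over structures of the 12 A Cbeta rule
        want = set()
        for recs in (small_ensemble.group.phospho_structures,
                     small_ensemble.group.nonphospho_structures):
            for rec in recs:
                if rec.structure_id not in small_ensemble.core_positions:
                    continue  # dropped by the redundancy filter
                positions = small_ensemble.core_positions[rec.structure_id]
                residues = [rec.residues[p] for p in positions]
                site_res = next(r for r in residues
                                if r.author_index == site)
                anchor = site_res.atoms["CB"] if site_res.aa3 != "GLY" \
                    else site_res.atoms["CA"]
                for ci, r in enumerate(residues):
                    a = r.atoms.get("CB") if r.aa3 != "GLY" \
                        else r.atoms.get("CA")
                    if a is not None and \
                            np.linalg.norm(a - anchor) <= 12.0:
                        want.add(ci)
        assert neigh == want
        # neighborhood is local: a contiguous patch around the site
        core_site = next(
            ci for ci, p in enumerate(small_ensemble.core_positions[
                small_ensemble.phospho_ids[0]])
            if small_ensemble.group.phospho_structures[0]
            .residues[p].author_index == site)
        assert core_site in neigh
        assert len(neigh) < small_ensemble.n_core

    def test_site_missing_in_one_state_skipped(self, small_group):
        from phosdyn.enm import ensemble_nma
        import copy
        g = copy.deepcopy(small_group)
        site = sorted(g.site_indices)[0]
        # truncate every non-phospho structure before the site residue,
        # leaving no reference point in that state
        for rec in g.nonphospho_structures:
            rec.models[0] = [r for r in rec.residues
                             if r.author_index < site]
        ens = ensemble_nma(g)
        assert neighborhood_fluctuation_test(ens, site) is None

    def test_perturbed_site_rejects(self, small_ensemble):
        site = sorted(small_ensemble.group.site_indices)[0]
        r = neighborhood_fluctuation_test(small_ensemble, site)
        assert r is not None and 0.0 <= r.p_value <= 1.0


class TestRmsip:
    def test_identical_subsets_one(self):
        q = random_orthonormal(60, 10, 0)
        assert rmsip(q, q) == pytest.approx(1.0)

    def test_orthogonal_modes_zero(self):
        q = random_orthonormal(60, 20, 1)
        assert rmsip(q[:, :10], q[:, 10:]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_sum(self):
        a = random_orthonormal(300, 20, 2)
        b = random_orthonormal(300, 20, 3)
        brute = np.sqrt(sum((a[:, i] @ b[:, j]) ** 2
                            for i in range(20) for j in range(20)) / 20)
        assert rmsip(a, b) == pytest.approx(brute)

    def test_subset_of_containing_basis_is_one(self):
        q = random_orthonormal(40, 40, 4)
        assert rmsip(q[:, 5:10], q) == pytest.approx(1.0)


def _modeset(vecs, eigs=None):
    k = vecs.shape[1]
    n_res = vecs.shape[0] // 3
    return ModeSet(np.arange(1, k + 1.0) if eigs is None else eigs,
                   vecs, np.repeat(np.arange(n_res), 1),
                   np.zeros(n_res), list(range(n_res)))


class TestModeMatching:
    def test_identity_on_identical_sets(self):
        q = random_orthonormal(30, 8, 5)
        m = match_modes(_modeset(q), _modeset(q), k=8)
        assert np.array_equal(m.permutation, np.arange(8))
        assert np.allclose(m.pair_similarity, 1.0)

    def test_swapped_modes_recovered(self):
        q = random_orthonormal(30, 6, 6)
        swapped = q[:, [0, 1, 3, 2, 4, 5]]
        m = match_modes(_modeset(q), _modeset(swapped), k=6)
        assert list(m.permutation) == [0, 1, 3, 2, 4, 5]

    def test_sign_flip_handled(self):
        q = random_orthonormal(30, 5, 7)
        m = match_modes(_modeset(q), _modeset(-q), k=5)
        assert np.allclose(m.pair_similarity, 1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        k, dim = 5, 24
        a = random_orthonormal(dim, k, seed * 2)
        b = random_orthonormal(dim, k, seed * 2 + 1)
        m = match_modes(_modeset(a), _modeset(b), k=k)
        sim = np.abs(a.T @ b)
        best = max(itertools.permutations(range(k)),
                   key=lambda p: sum(sim[i, p[i]] for i in range(k)))
        got = sum(sim[i, m.permutation[i]] for i in range(k))
        want = sum(sim[i, best[i]] for i in range(k))
        assert got == pytest.approx(want)

    def test_window_partition(self):
        q = random_orthonormal(240, 80, 8)
        m = match_modes(_modeset(q), _modeset(q), k=80)
        summary = window_mode_similarity([m], n_modes=80)
        assert set(summary) == {"global", "LF", "LTIF", "HF"}
        assert all(v == pytest.approx(1.0) for v in summary.values())


class TestLmi:
    def test_diagonal_one_and_symmetric(self, small_ensemble):
        ms = next(iter(small_ensemble.mode_sets.values()))
        mi = lmi_matrix(ms)
        assert np.allclose(np.diag(mi), 1.0)
        assert np.allclose(mi, mi.T)
        assert mi.min() >= 0 and mi.max() <= 1 + 1e-12

    def test_perfectly_coupled_pair(self):
        # two residues forced to move identically in every mode
        rng = np.random.default_rng(0)
        k = 6
        block = rng.normal(size=(3, k))
        vecs = np.vstack([block, block, rng.normal(size=(3, k))])
        vecs, _ = np.linalg.qr(vecs)
        ms = _modeset(vecs[:, :k])
        mi = lmi_matrix(ms)
        assert mi[0, 1] > 0.99

    def test_independent_blocks_zero(self):
        # block-diagonal mode components: no cross-residue covariance
        vecs = np.zeros((6, 6))
        vecs[:3, :3] = np.linalg.qr(
            np.random.default_rng(1).normal(size=(3, 3)))[0]
        vecs[3:, 3:] = np.linalg.qr(
            np.random.default_rng(2).normal(size=(3, 3)))[0]
        mi = lmi_matrix(_modeset(vecs))
        assert mi[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_invariant_under_structure_rotation(self, helix20):
        moved = transform_structure(helix20, seed=21)
        m1 = lmi_matrix(_ca_modes(helix20))
        m2 = lmi_matrix(_ca_modes(moved))
        assert np.allclose(m1, m2, atol=1e-6)


def _ca_modes(rec):
    """Cα-restricted full mode set of a single structure (test helper)."""
    from phosdyn.enm import _restrict_to_core_ca
    net = build_atomistic_enm(rec)
    ms = rtb_modes(net)
    return _restrict_to_core_ca(ms, net, list(net.residue_positions))


class TestRv2:
    def test_self_similarity_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 20))
        X = X + X.T
        assert rv2_coefficient(X, X) == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 15))
        X = X + X.T
        assert rv2_coefficient(X, 3.7 * X) == pytest.approx(1.0)

    def test_null_mean_near_zero_and_less_inflated_than_rv(self):
        rng = np.random.default_rng(2)
        rv2s, rvs = [], []
        for _ in range(300):
            X = rng.normal(size=(30, 30))
            Y = rng.normal(size=(30, 30))
            X, Y = X + X.T, Y + Y.T
            rv2s.append(rv2_coefficient(X, Y))
            xt, yt = X @ X.T, Y @ Y.T
            rvs.append((xt * yt).sum()
                       / np.sqrt((xt * xt).sum() * (yt * yt).sum()))
        assert abs(np.mean(rv2s)) < 0.03
        assert np.mean(np.abs(rv2s)) < np.mean(np.abs(rvs))

    def test_zero_matrix_flagged(self):
        with pytest.raises(ValueError):
            rv2_coefficient(np.zeros((5, 5)), np.eye(5))


class TestCouplingClassification:
    def test_rule_order_and_exhaustiveness(self):
        ctx = [0.0, 0.01, -0.01, 0.005, -0.005]
        assert classify_coupling_change(0.5, 0.99, ctx) == "tensioning"
        assert classify_coupling_change(-0.5, 0.99, ctx) == "relaxation"
        assert classify_coupling_change(0.0, 0.5, ctx) == "rewiring"
        assert classify_coupling_change(0.0, 0.99, ctx) == "unchanged"

    def test_every_point_classified(self):
        rng = np.random.default_rng(3)
        ctx = rng.normal(0, 0.01, 50)
        for _ in range(100):
            c = classify_coupling_change(rng.normal(0, 0.05),
                                         rng.uniform(-1, 1), ctx)
            assert c in {"tensioning", "relaxation", "rewiring", "unchanged"}

    def test_group_coupling_summary(self, small_ensemble):
        coup = compare_couplings(small_ensemble)
        assert -1 <= coup.rv2_between <= 1
        assert coup.median_mi_p.shape == coup.median_mi_np.shape


class TestCommunities:
    def test_two_perfect_blocks(self):
        n = 16
        mi = np.eye(n)
        mi[:8, :8] = 0.95
        mi[8:, 8:] = 0.95
        np.fill_diagonal(mi, 1.0)
        labels = residue_communities(mi)
        assert len(set(labels[:8])) == 1
        assert len(set(labels[8:])) == 1
        assert labels[0] != labels[8]

    def test_identity_matrix_no_communities(self):
        labels = residue_communities(np.eye(12))
        # no couplings: nothing forms a genuine community
        assert len(set(labels) - {-1}) <= 1

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        n = 14
        mi = np.eye(n)
        mi[:7, :7] = 0.9
        mi[7:, 7:] = 0.9
        np.fill_diagonal(mi, 1.0)
        perm = rng.permutation(n)
        l1 = residue_communities(mi)
        l2 = residue_communities(mi[np.ix_(perm, perm)])
        # same partition up to relabeling
        def canon(labels):
            groups = {}
            return [groups.setdefault(x, len(groups)) for x in labels]
        assert canon(l1[perm]) == canon(l2)
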