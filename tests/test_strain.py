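"""Finite-strain fields, site aggregation, bootstrap, manifolds."""

import numpy as np
import pytest

from conftest import transform_structure
from phosdyn.strain import (StrainField, bootstrap_site_significance,
                            co_straining_classification,
                            correlation_dimension, high_strain_manifold,
                            manifold_representation, principal_stretches,
                            site_mean_strain, strain_field)
from phosdyn.synthetic import (SyntheticSpec, apply_region_deformation,
                               generate_backbone, two_state_ensemble)


class TestPrincipalStretches:
    def test_identity(self):
        assert principal_stretches(np.eye(3)) == pytest.approx((1, 1, 1))

    def test_uniaxial(self):
        lam = principal_stretches(np.diag([2.0, 1.0, 1.0]))
        assert lam == pytest.approx((1.0, 1.0, 2.0))

    def test_simple_shear_closed_form(self):
        F = np.eye(3)
        F[0, 1] = 1.0   # shear gamma = 1
        lam = principal_stretches(F)
        assert lam[2] == pytest.approx(np.sqrt((3 + np.sqrt(5)) / 2))
        # shear is volume-preserving: product of stretches is 1
        assert np.prod(lam) == pytest.approx(1.0)

    def test_rotation_no_strain(self):
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        assert principal_stretches(q) == pytest.approx((1, 1, 1))

    def test_singular_raises(self):
        with pytest.raises(ValueError):
            principal_stretches(np.diag([1.0, 1.0, 0.0]))


class TestStrainField:
    def test_rigid_copy_unstrained(self, helix30):
        moved = transform_structure(helix30, seed=4)
        field = strain_field(helix30, moved)
        lam3 = field.lambda3[field.scored()]
        assert np.allclose(lam3, 1.0, atol=1e-6)

    def test_global_affine_recovered_exactly(self):
        rec = generate_backbone(60, "helix", seed=2)
        F = np.diag([1.2, 1.0, 1.0])
        deformed = apply_region_deformation(rec, (1, 60), F)
        field = strain_field(rec, deformed)
        lam3 = field.lambda3[field.scored()]
        assert np.allclose(lam3, 1.2, atol=1e-6)

    def test_local_deformation_localised(self):
        rec = generate_backbone(60, "helix", seed=2)
        F = np.diag([1.2, 1.0, 1.0])
        deformed = apply_region_deformation(rec, (20, 30), F)
        field = strain_field(rec, deformed)
        lam3 = field.lambda3
        authors = np.array(field.author_indices)
        inside = (authors >= 22) & (authors <= 28)
        far = (authors <= 8) | (authors >= 45)
        assert np.nanmean(lam3[inside]) > 1.05
        assert np.allclose(lam3[far][~np.isnan(lam3[far])], 1.0, atol=0.01)

    def test_invariance_under_independent_rigid_motions(self, helix30):
        ref2 = transform_structure(helix30, seed=6)
        dfm = generate_backbone(30, "helix", seed=12)
        dfm2 = transform_structure(dfm, seed=7)
        f1 = strain_field(helix30, dfm)
        f2 = strain_field(ref2, dfm2)
        ok = f1.scored() & f2.scored()
        assert np.allclose(f1.lambdas[ok], f2.lambdas[ok], atol=1e-6)


def _uniform_field(lam3_values, authors=None):
    n = len(lam3_values)
    lam = np.column_stack([np.ones(n), np.ones(n),
                           np.asarray(lam3_values, float)])
    return StrainField("r", "d", lam, np.full(n, 10),
                       list(authors or range(1, n + 1)))


class TestSiteAggregation:
    def test_uniform_field_returns_constant(self):
        f = _uniform_field([1.4] * 20)
        assert site_mean_strain([f], [3, 4, 5]) == pytest.approx(1.4)

    def test_geometric_mean_within_field(self):
        f = _uniform_field([1.0, 4.0] + [1.0] * 10)
        assert site_mean_strain([f], [1, 2]) == pytest.approx(2.0)

    def test_arithmetic_mean_across_fields(self):
        f1 = _uniform_field([1.1] * 10)
        f2 = _uniform_field([1.3] * 10)
        assert site_mean_strain([f1, f2], [2, 3]) == pytest.approx(1.2)

    def test_scaling_property(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.9, 1.4, 30)
        f1 = _uniform_field(vals)
        f2 = _uniform_field(vals * 1.7)
        s1 = site_mean_strain([f1], [5, 6, 7])
        s2 = site_mean_strain([f2], [5, 6, 7])
        assert s2 == pytest.approx(1.7 * s1)

    def test_absent_site_raises(self):
        with pytest.raises(ValueError):
            site_mean_strain([_uniform_field([1.0] * 5)], [99])


class TestBootstrap:
    def test_uniform_field_not_significant(self):
        rng = np.random.default_rng(1)
        f = _uniform_field(rng.uniform(1.0, 1.05, 80))
        res = bootstrap_site_significance([f], [10, 11, 12], seed=0)
        assert not res.significant

    def test_designed_deformation_detected(self):
        # clear strain at the site, homogeneous elsewhere
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vals = rng.normal(1.0, 0.01, 120)
            vals[58:63] += 0.3
            f = _uniform_field(vals)
            res = bootstrap_site_significance([f], [59, 60, 61, 62, 63],
                                              seed=seed)
            assert res.significant

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(2)
        f = _uniform_field(rng.uniform(1.0, 1.3, 60))
        a = bootstrap_site_significance([f], [20, 21, 22], seed=77)
        b = bootstrap_site_significance([f], [20, 21, 22], seed=77)
        assert a.bootstrap_mean == b.bootstrap_mean
        assert a.significant == b.significant

    def test_too_few_draws_raises(self):
        f = _uniform_field([1.0] * 30)
        with pytest.raises(ValueError):
            bootstrap_site_significance([f], [5], n=1)


class TestCoStraining:
    def _result(self, site, significant):
        from phosdyn.strain import SiteStrainResult
        return SiteStrainResult(list(site), 1.2, 1.0, 0.05, significant, 50)

    def test_both_significant_co_strained(self):
        co = co_straining_classification(self._result([5, 6], True),
                                         self._result([20, 21], True))
        assert co.co_strained

    def test_one_not_significant(self):
        co = co_straining_classification(self._result([5, 6], True),
                                         self._result([20, 21], False))
        assert not co.co_strained

    def test_overlap_flag_and_zero_distance(self, helix30):
        co = co_straining_classification(self._result([10], True),
                                         self._result([10, 11], True),
                                         structure=helix30)
        assert co.overlap
        assert co.distance == pytest.approx(0.0)

    def test_distance_matches_bruteforce(self, helix30):
        psite, fsite = [3, 4], [20, 21, 22]
        co = co_straining_classification(self._result(psite, True),
                                         self._result(fsite, True),
                                         structure=helix30)
        by = {r.author_index: r.atoms["CA"] for r in helix30.residues}
        want = min(np.linalg.norm(by[a] - by[b])
                   for a in psite for b in fsite)
        assert co.distance == pytest.approx(want)


class TestCorrelationDimension:
    def test_line(self):
        rng = np.random.default_rng(0)
        pts = np.zeros((200, 3))
        pts[:, 0] = rng.uniform(0, 50, 200)
        assert correlation_dimension(pts) == pytest.approx(1.0, abs=0.15)

    def test_disc(self):
        rng = np.random.default_rng(1)
        r = np.sqrt(rng.uniform(0, 1, 400)) * 25
        th = rng.uniform(0, 2 * np.pi, 400)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th),
                               np.zeros(400)])
        assert correlation_dimension(pts) == pytest.approx(2.0, abs=0.2)

    def test_ball(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(2000, 3))
        pts = pts[np.linalg.norm(pts, axis=1) < 1.0][:500] * 25
        assert correlation_dimension(pts) == pytest.approx(3.0, abs=0.25)

    def test_identical_points_zero(self):
        assert correlation_dimension(np.zeros((20, 3))) == 0.0


class TestManifold:
    def _slab_field(self, seed=0):
        # 10x10x10 lattice; high strain on one z-slab (planar manifold)
        grid = np.array([[x, y, z] for x in range(10) for y in range(10)
                         for z in range(10)], float) * 3.0
        rng = np.random.default_rng(seed)
        lam3 = 1.0 + rng.normal(0, 0.005, len(grid))
        slab = grid[:, 2] == 12.0
        lam3[slab] += 0.5
        lam = np.column_stack([np.ones_like(lam3), np.ones_like(lam3), lam3])
        field = StrainField("r", "d", lam, np.full(len(grid), 10),
                            list(range(1, len(grid) + 1)))
        return field, grid, slab

    def test_planar_slab_recovered(self):
        field, grid, slab = self._slab_field()
        res = high_strain_manifold(field, grid)
        member = np.zeros(len(grid), bool)
        member[[a - 1 for a in res.residues]] = True
        assert member[slab].sum() >= 0.9 * member.sum()
        assert res.nu < 2.5
        assert res.nu < correlation_dimension(grid)

    def test_manifold_is_top_n_by_lambda3(self):
        field, grid, _ = self._slab_field(seed=1)
        res = high_strain_manifold(field, grid)
        order = np.argsort(-field.lambda3)
        want = sorted(field.author_indices[i] for i in order[:res.size])
        assert res.residues == want

    def test_uniform_strain_deterministic_tie(self):
        rng = np.random.default_rng(3)
        grid = rng.uniform(0, 30, size=(200, 3))
        lam3 = 1.0 + rng.normal(0, 0.01, 200)
        lam = np.column_stack([np.ones(200), np.ones(200), lam3])
        field = StrainField("r", "d", lam, np.full(200, 10),
                            list(range(1, 201)))
        a = high_strain_manifold(field, grid)
        b = high_strain_manifold(field, grid)
        assert a.size == b.size and a.residues == b.residues

    def test_representation_counting(self):
        from phosdyn.strain import ManifoldResult
        m1 = ManifoldResult([1, 2, 3, 4], 4, 2.0)
        m2 = ManifoldResult([3, 4, 5, 6], 4, 2.0)
        assert manifold_representation([3, 4], [m1, m2]) == 1.0
        assert manifold_representation([1, 2, 3, 4], [m2]) == 0.5
        assert manifold_representation([1], [m1, m2]) == pytest.approx(0.5)


def test_group_strain_on_two_state_ensemble():
    spec = SyntheticSpec(n_residues=80, phosphosite=40,
                         shift_region=(35, 45), shift_vector=(0, 0, 0),
                         deform_region=(35, 45),
                         deform_F=np.diag([1.0, 1.0, 1.3]),
                         n_phospho=2, n_nonphospho=3, seed=4)
    g = two_state_ensemble(spec)
    from phosdyn.strain import group_strain_fields
    fields = group_strain_fields(g)
    assert len(fields) == 6
    site = site_mean_strain(fields, [38, 39, 40, 41, 42])
    background = site_mean_strain(fields, [5, 6, 7, 8, 9])
    assert site > background + 0.05
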