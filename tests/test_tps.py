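"""Thin-plate splines, bending energy, and semilandmark sliding."""

import numpy as np
import pytest

from dentomorph.datatypes import LandmarkConfiguration, ShapeDataset, SpecimenMetadata
from dentomorph.gpa import procrustes_distance
from dentomorph.synthetic import CohortSpec, GroupSpec, generate_cohort, make_template
from dentomorph.tps import (
    Curve,
    CurveTemplate,
    SingularityError,
    bending_energy_matrix,
    edj_curve_template,
    fit_tps,
    slide_semilandmarks,
    tps_warp,
)


def kernel_sum_oracle(source, target, query):
    """Direct evaluation of the TPS from its defining linear system."""
    k, dim = source.shape
    d = np.linalg.norm(source[:, None] - source[None, :], axis=-1)
    if dim == 3:
        km = d
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            km = np.where(d > 0, d**2 * np.log(d), 0.0)
    p = np.hstack([np.ones((k, 1)), source])
    lmat = np.zeros((k + dim + 1, k + dim + 1))
    lmat[:k, :k] = km
    lmat[:k, k:] = p
    lmat[k:, :k] = p.T
    sol = np.linalg.solve(lmat, np.vstack([target, np.zeros((dim + 1, dim))]))
    w, a = sol[:k], sol[k:]
    dq = np.linalg.norm(query[:, None] - source[None, :], axis=-1)
    if dim == 3:
        kq = dq
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            kq = np.where(dq > 0, dq**2 * np.log(dq), 0.0)
    return kq @ w + np.hstack([np.ones((len(query), 1)), query]) @ a


class TestBendingEnergy:
    @pytest.mark.parametrize("dim", [2, 3])
    def test_symmetric_psd_with_affine_null_space(self, rng, dim):
        ref = rng.normal(size=(12, dim))
        b = bending_energy_matrix(ref)
        np.testing.assert_allclose(b, b.T, atol=1e-12)
        assert np.linalg.eigvalsh(b).min() >= -1e-9
        # any affine displacement of the reference has zero energy
        amat = rng.normal(size=(dim, dim))
        shift = rng.normal(size=dim)
        disp = ref @ amat.T + shift
        for d in range(dim):
            assert abs(disp[:, d] @ b @ disp[:, d]) < 1e-9

    def test_bump_energy_matches_interpolation_identity(self):
        """Quadratic form equals the energy of the fitted interpolant.

        For a single bumped point on a planar grid, the bending energy of
        the fitted TPS (computed independently from the kernel formula,
        E = w^T K w per dimension) must equal d^T B d.
        """
        gx, gy = np.meshgrid(np.arange(5.0), np.arange(5.0))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        target = grid.copy()
        target[12] += [0.3, -0.2]
        b = bending_energy_matrix(grid)
        disp = target - grid
        form = sum(disp[:, d] @ b @ disp[:, d] for d in range(2))
        # independent route: solve for warp coefficients, E = sum w' K w
        k = len(grid)
        dmat = np.linalg.norm(grid[:, None] - grid[None, :], axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            km = np.where(dmat > 0, dmat**2 * np.log(dmat), 0.0)
        p = np.hstack([np.ones((k, 1)), grid])
        lmat = np.zeros((k + 3, k + 3))
        lmat[:k, :k] = km
        lmat[:k, k:] = p
        lmat[k:, :k] = p.T
        sol = np.linalg.solve(lmat, np.vstack([target, np.zeros((3, 2))]))
        w = sol[:k]
        direct = sum(w[:, d] @ km @ w[:, d] for d in range(2))
        assert form == pytest.approx(direct, rel=1e-8)

    def test_degenerate_reference_rejected(self):
        line = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        with pytest.raises(SingularityError):
            bending_energy_matrix(line)


class TestWarp:
    def test_interpolation_property(self, rng):
        src = rng.normal(size=(10, 3))
        dst = src + 0.1 * rng.normal(size=(10, 3))
        model = fit_tps(src, dst)
        np.testing.assert_allclose(tps_warp(model, src), dst, atol=1e-10)
        assert model.bending_energy >= -1e-12

    def test_affine_target_gives_affine_map_and_zero_energy(self, rng):
        src = rng.normal(size=(8, 3))
        amat = rng.normal(size=(3, 3))
        shift = rng.normal(size=3)
        dst = src @ amat.T + shift
        model = fit_tps(src, dst)
        q = rng.normal(size=(20, 3))
        np.testing.assert_allclose(tps_warp(model, q), q @ amat.T + shift, atol=1e-8)
        assert abs(model.bending_energy) < 1e-9

    @pytest.mark.parametrize("dim", [2, 3])
    def test_matches_kernel_sum_oracle(self, rng, dim):
        src = rng.normal(size=(9, dim))
        dst = src + 0.2 * rng.normal(size=(9, dim))
        q = rng.normal(size=(15, dim))
        model = fit_tps(src, dst)
        np.testing.assert_allclose(
            tps_warp(model, q), kernel_sum_oracle(src, dst, q), atol=1e-9
        )

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_tps(rng.normal(size=(6, 3)), rng.normal(size=(6, 3)))
        with pytest.raises(ValueError, match="dimension"):
            tps_warp(model, rng.normal(size=(4, 2)))


def _pair_dataset(pts_a, pts_b):
    cfgs = [
        LandmarkConfiguration("A", "ldm2", "dentinal_crown", pts_a),
        LandmarkConfiguration("B", "ldm2", "dentinal_crown", pts_b),
    ]
    meta = [
        SpecimenMetadata("A", "other", tooth_classes_present={"ldm2"}),
        SpecimenMetadata("B", "other", tooth_classes_present={"ldm2"}),
    ]
    return ShapeDataset(cfgs, meta)


class TestSliding:
    def test_identical_specimens_are_a_noop(self):
        tmpl = make_template("ldm2", "dentinal_crown")
        ds = _pair_dataset(tmpl.points.copy(), tmpl.points.copy())
        res = slide_semilandmarks(ds, outer_iters=3)
        np.testing.assert_allclose(res.dataset.coords(), ds.coords(), atol=1e-10)

    def test_reparameterized_pair_collapses(self):
        """Two samplings of one geometric curve become nearly the same shape."""
        tmpl = make_template("ldm2", "dentinal_crown")
        curve = edj_curve_template("ldm2").curves[0]
        pts_a = tmpl.points.copy()
        pts_b = pts_a.copy()
        seq = list(curve.indices)
        for pos, j in enumerate(seq):
            if j in curve.slidable:
                nxt = seq[(pos + 1) % len(seq)]
                pts_b[j] = pts_a[j] + 0.4 * (pts_a[nxt] - pts_a[j])
        d_pre = procrustes_distance(pts_a, pts_b)
        res = slide_semilandmarks(_pair_dataset(pts_a, pts_b), outer_iters=8)
        out = res.dataset.coords()
        d_post = procrustes_distance(out[0], out[1])
        assert d_post <= 0.1 * d_pre

    @pytest.mark.parametrize("seed", [7, 11, 23])
    def test_energy_non_increasing(self, seed):
        spec = CohortSpec(
            tooth_class="ldm2",
            feature_set="dentinal_crown",
            groups=[GroupSpec("Baka", 8)],
            noise_sd=0.02,
            seed=seed,
        )
        res = slide_semilandmarks(generate_cohort(spec), outer_iters=5)
        e = res.energy_history
        assert all(e[i + 1] <= e[i] + 1e-12 for i in range(len(e) - 1))

    def test_anchors_fixed_and_points_on_polyline(self):
        spec = CohortSpec(
            tooth_class="udm2",
            feature_set="dentinal_crown",
            groups=[GroupSpec("Baka", 6)],
            noise_sd=0.02,
            seed=3,
        )
        ds = generate_cohort(spec)
        curve = edj_curve_template("udm2").curves[0]
        res = slide_semilandmarks(ds, outer_iters=3)
        pre, post = ds.coords(), res.dataset.coords()
        anchors = sorted(curve.anchors)
        np.testing.assert_allclose(post[:, anchors], pre[:, anchors], atol=0)
        # slid points still lie on the original polyline
        for i in range(len(ds)):
            poly = pre[i][list(curve.indices)]
            for j in curve.slidable:
                p = post[i][j]
                dmin = min(
                    _point_segment_distance(p, poly[s], poly[(s + 1) % len(poly)])
                    for s in range(len(poly))
                )
                assert dmin < 1e-9

    def test_second_pass_moves_little_after_convergence(self):
        """Sliding is idempotent: a converged dataset barely moves again.

        The second pass shares the first pass's reference polylines (the
        specimens' digitized curves) and its converged consensus.
        """
        spec = CohortSpec(
            tooth_class="ldm2",
            feature_set="dentinal_crown",
            groups=[GroupSpec("Baka", 6)],
            noise_sd=0.01,
            seed=5,
        )
        ds = generate_cohort(spec)
        first = slide_semilandmarks(
            ds, outer_iters=300, displacement_tol=1e-7, update_reference=True
        )
        second = slide_semilandmarks(
            first.dataset, outer_iters=2, update_reference=True,
            polylines=first.polylines,
        )
        assert second.max_displacements[0] < 1e-6

    def test_custom_template_requires_slidable(self):
        with pytest.raises(ValueError):
            Curve((0, 1, 2), frozenset())


def _point_segment_distance(p, a, b):
    e = b - a
    denom = e @ e
    t = 0.0 if denom == 0 else np.clip((p - a) @ e / denom, 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * e)))


def test_curve_template_layout_matches_tooth_templates():
    for tc, n_curve in (("ldm2", 23), ("udm2", 47)):
        ct = edj_curve_template(tc)
        curve = ct.curves[0]
        assert len(curve.slidable) == n_curve
        # the polyline visits every anchor and every semilandmark exactly once
        assert len(set(curve.indices)) == len(curve.indices)
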