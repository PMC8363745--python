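"""Centroid size, mirroring, Procrustes superimposition, and distances."""

import numpy as np
import pytest

from dentomorph.datatypes import LandmarkConfiguration
from dentomorph.gpa import (
    DegenerateConfigurationError,
    centroid_size,
    generalized_procrustes,
    ln_centroid_size,
    mirror_to_left,
    procrustes_distance,
)

def random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestCentroidSize:
    def test_unit_square(self):
        sq = np.array([[0.5, 0.5, 0], [-0.5, 0.5, 0], [-0.5, -0.5, 0], [0.5, -0.5, 0]])
        assert centroid_size(sq) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_homogeneity(self, rng):
        pts = rng.normal(size=(55, 3))
        assert centroid_size(3.0 * pts) == pytest.approx(3.0 * centroid_size(pts))
        assert ln_centroid_size(3.0 * pts) == pytest.approx(
            ln_centroid_size(pts) + np.log(3.0)
        )

    def test_matches_two_pass_oracle(self, rng):
        pts = rng.normal(size=(55, 3))
        c = pts.mean(axis=0)
        oracle = np.sqrt(sum(np.sum((p - c) ** 2) for p in pts))
        assert centroid_size(pts) == pytest.approx(oracle, abs=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateConfigurationError):
            centroid_size(np.ones((10, 3)))


class TestMirror:
    def _config(self, rng, side="right"):
        return LandmarkConfiguration(
            "sp", "ldm2", "dentinal_crown", rng.normal(size=(55, 3)), side=side
        )

    def test_involution(self, rng):
        cfg = self._config(rng)
        m = mirror_to_left(cfg)
        m.side = "right"  # pretend it is a right tooth again
        back = mirror_to_left(m)
        np.testing.assert_allclose(back.points, cfg.points, atol=1e-15)

    def test_isometry(self, rng):
        cfg = self._config(rng)
        assert centroid_size(mirror_to_left(cfg)) == pytest.approx(centroid_size(cfg))

    def test_mirrored_right_matches_symmetric_left_antimere(self, rng):
        """A perfectly symmetric left/right pair superimposes exactly."""
        left = self._config(rng, side="left")
        right_pts = left.points.copy()
        right_pts[:, 1] *= -1  # the anatomical reflection
        right = LandmarkConfiguration(
            "sp_r", "ldm2", "dentinal_crown", right_pts, side="right"
        )
        mirrored = mirror_to_left(right)
        assert procrustes_distance(mirrored, left) < 1e-12

    def test_left_input_warns_and_is_noop(self, rng):
        cfg = self._config(rng, side="left")
        with pytest.warns(UserWarning, match="already"):
            out = mirror_to_left(cfg)
        np.testing.assert_allclose(out.points, cfg.points)


class TestGPA:
    def test_identical_configurations(self, rng):
        pts = rng.normal(size=(55, 3))
        res = generalized_procrustes(np.stack([pts, pts.copy()]))
        assert np.linalg.norm(res.aligned[0] - res.aligned[1]) < 1e-12
        np.testing.assert_allclose(res.consensus, res.aligned[0], atol=1e-12)

    def test_similarity_invariance(self, rng):
        pts = rng.normal(size=(55, 3))
        rot = random_rotation(rng)
        copy = 2.5 * pts @ rot.T + np.array([4.0, -2.0, 1.0])
        res = generalized_procrustes(np.stack([pts, copy]))
        assert np.linalg.norm(res.aligned[0] - res.aligned[1]) < 1e-10

    def test_output_invariant_under_input_transforms(self, rng):
        """Pre-transforming any input leaves the superimposition unchanged."""
        data = rng.normal(size=(5, 20, 3)) * 0.1 + rng.normal(size=(20, 3))
        res1 = generalized_procrustes(data)
        moved = data.copy()
        moved[2] = 1.7 * moved[2] @ random_rotation(rng).T + np.array([1.0, 2.0, 3.0])
        res2 = generalized_procrustes(moved)
        # align the two consensus frames before comparing
        from dentomorph.gpa import optimal_rotation

        r = optimal_rotation(res2.consensus, res1.consensus)
        np.testing.assert_allclose(res2.consensus @ r, res1.consensus, atol=1e-9)
        np.testing.assert_allclose(res2.aligned[2] @ r, res1.aligned[2], atol=1e-9)

    def test_consensus_stability_one_iteration(self, small_cohort):
        res = generalized_procrustes(small_cohort)
        again = generalized_procrustes(res.aligned)
        assert again.iterations <= 2  # converged immediately
        np.testing.assert_allclose(again.consensus, res.consensus, atol=1e-9)

    def test_triangle_mean_matches_eigenvector_oracle(self, rng):
        """Full-Procrustes-fitting consensus equals the closed-form mean.

        For planar shapes the full Procrustes mean is the leading
        eigenvector of the sum of complex preshape outer products.
        """
        tris = rng.normal(size=(3, 3, 2))
        # closed-form oracle in the complex representation
        zs = []
        for t in tris:
            z = t[:, 0] + 1j * t[:, 1]
            z = z - z.mean()
            zs.append(z / np.linalg.norm(z))
        smat = sum(np.outer(z, z.conj()) for z in zs)
        w, vecs = np.linalg.eigh(smat)
        mu = vecs[:, -1]
        mu = mu - mu.mean()
        mu /= np.linalg.norm(mu)

        res = generalized_procrustes(tris, scale_refine=True, tol=1e-13)
        zc = res.consensus[:, 0] + 1j * res.consensus[:, 1]
        zc = zc - zc.mean()
        zc /= np.linalg.norm(zc)
        # remove the arbitrary global rotation (complex phase)
        phase = np.vdot(mu, zc)
        phase /= abs(phase)
        assert np.linalg.norm(zc / phase - mu) < 1e-8

    def test_scale_only_mode_does_not_rotate(self, outline_cohort):
        res = generalized_procrustes(outline_cohort, mode="scale_only")
        pre = outline_cohort.coords()
        for i, pts in enumerate(pre):
            centered = pts - pts.mean(axis=0)
            centered /= np.linalg.norm(centered)
            np.testing.assert_allclose(res.aligned[i], centered, atol=1e-12)

    def test_nonconvergence_warns(self, rng):
        data = rng.normal(size=(6, 10, 3))
        with pytest.warns(UserWarning, match="converge"):
            res = generalized_procrustes(data, tol=1e-30, max_iter=2)
        assert not res.converged


class TestTangent:
    def test_consensus_maps_to_zero_and_mean_centered(self, small_cohort):
        res = generalized_procrustes(small_cohort, tol=1e-12)
        # the consensus itself projects to the zero tangent vector
        mu = res.consensus.ravel()
        assert np.linalg.norm(mu - (mu @ mu) * mu) < 1e-12
        t = res.tangent_coords
        assert np.abs(t.mean(axis=0)).max() < 1e-10

    def test_tangent_distance_approximates_procrustes_distance(self, rng):
        """For small shape differences the linearization is within 1 percent."""
        base = rng.normal(size=(30, 3))
        data = np.stack([base + rng.normal(scale=1e-3, size=(30, 3)) for _ in range(6)])
        res = generalized_procrustes(data, tol=1e-13)
        t = res.tangent_coords
        for i in range(3):
            for j in range(i + 1, 6):
                pd = procrustes_distance(data[i], data[j])
                td = np.linalg.norm(t[i] - t[j])
                assert td == pytest.approx(pd, rel=0.01)


class TestProcrustesDistance:
    def test_identity_and_symmetry(self, rng):
        a, b = rng.normal(size=(2, 20, 3))
        assert procrustes_distance(a, a) == pytest.approx(0.0, abs=1e-12)
        assert procrustes_distance(a, b) == pytest.approx(
            procrustes_distance(b, a), abs=1e-12
        )

    def test_matches_rotation_grid_oracle(self):
        """Planar pair: brute-force search over rotation angles agrees."""
        eq = np.array([[1, 0], [-0.5, np.sqrt(3) / 2], [-0.5, -np.sqrt(3) / 2]])
        col = np.array([[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0]])

        def preshape(x):
            c = x - x.mean(axis=0)
            return c / np.linalg.norm(c)

        za, zb = preshape(eq), preshape(col)
        # ||za R(ang) - zb||^2 = 2 - 2 tr(R(ang)^T za^T zb), searched on a grid
        m = za.T @ zb
        ang = np.linspace(0, 2 * np.pi, 4_000_001)
        tr = np.cos(ang) * (m[0, 0] + m[1, 1]) + np.sin(ang) * (m[1, 0] - m[0, 1])
        best = np.sqrt(np.maximum(2 - 2 * tr, 0.0)).min()
        a3 = np.column_stack([eq, np.zeros(3)])
        b3 = np.column_stack([col, np.zeros(3)])
        assert procrustes_distance(a3, b3) == pytest.approx(best, abs=1e-6)

    def test_triangle_inequality(self, rng):
        for _ in range(20):
            a, b, c = rng.normal(size=(3, 10, 3))
            dab = procrustes_distance(a, b)
            dbc = procrustes_distance(b, c)
            dac = procrustes_distance(a, c)
            assert dac <= dab + dbc + 1e-9
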