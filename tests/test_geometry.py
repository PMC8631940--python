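"""Procrustes alignment, object symmetry, asymmetry ANOVA, residualization."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import special_ortho_group

from mgpmap.geometry import (
    DegenerateShapeError,
    GeometryError,
    LandmarkArray,
    SymmetryPairing,
    _opa_rotation,
    _reflect_relabel,
    directional_asymmetry_test,
    gpa,
    load_landmarks,
    load_pairing,
    residualize_shape,
    symmetrize,
    write_landmarks,
    write_pairing,
)
from mgpmap.simulate import default_pairing, shape_template

K = 12
TEMPLATE = shape_template(K)
PAIRING = default_pairing(K)


def noisy_sample(n, noise, seed, template=TEMPLATE):
    rng = np.random.default_rng(seed)
    coords = template[None] + rng.standard_normal((n, template.shape[0], 3)) * noise
    return LandmarkArray([f"s{i}" for i in range(n)], coords)


def rigid_copies(base, n, seed):
    rng = np.random.default_rng(seed)
    out = np.empty((n, base.shape[0], 3))
    for i in range(n):
        R = special_ortho_group.rvs(3, random_state=seed + i)
        out[i] = base @ R * (0.5 + 2 * rng.random()) + rng.standard_normal(3) * 5
    return LandmarkArray([f"c{i}" for i in range(n)], out)


class TestGPA:
    def test_rigid_copies_superimpose_exactly(self):
        space = gpa(rigid_copies(TEMPLATE, 8, 1))
        d = space.aligned - space.aligned[0]
        assert np.abs(d).max() < 1e-8

    def test_two_specimens_mean_is_midpoint(self):
        space = gpa(noisy_sample(2, 0.05, 2))
        mid = space.aligned.mean(axis=0)
        mid3 = mid.reshape(-1, 3)
        mid3 = mid3 - mid3.mean(axis=0)
        mid3 = mid3 / np.linalg.norm(mid3)
        np.testing.assert_allclose(space.mean_shape, mid3.reshape(-1), atol=1e-8)

    def test_unit_centroid_size_and_centering(self):
        space = gpa(noisy_sample(6, 0.05, 3))
        conf = space.aligned.reshape(6, K, 3)
        np.testing.assert_allclose(conf.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(
            np.sqrt((conf ** 2).sum(axis=(1, 2))), 1.0, atol=1e-12)

    def test_residual_sum_matches_pairwise_opa_oracle(self):
        lma = noisy_sample(10, 0.01, 4)
        space = gpa(lma)
        ss = ((space.aligned - space.mean_shape) ** 2).sum()

        def opa_d2(A, B):
            A = A - A.mean(0)
            B = B - B.mean(0)
            A = A / np.linalg.norm(A)
            B = B / np.linalg.norm(B)
            return ((A @ _opa_rotation(A, B) - B) ** 2).sum()

        total = sum(opa_d2(lma.coords[i], lma.coords[j])
                    for i in range(10) for j in range(10) if i != j)
        assert abs(ss - total / 20) < 1e-6

    def test_invariant_to_reordering_and_pretransform(self):
        lma = noisy_sample(10, 0.03, 5)
        base = gpa(lma)
        rng = np.random.default_rng(6)
        perm = rng.permutation(10)
        reordered = gpa(LandmarkArray(
            [lma.specimen_ids[i] for i in perm], lma.coords[perm]))
        assert np.abs(base.aligned[perm] - reordered.aligned).max() < 1e-8
        transformed = np.empty_like(lma.coords)
        for i in range(10):
            R = special_ortho_group.rvs(3, random_state=100 + i)
            transformed[i] = (lma.coords[i] @ R) * (0.5 + 2 * rng.random()) + 3.0
        again = gpa(LandmarkArray(lma.specimen_ids, transformed))
        assert np.abs(base.aligned - again.aligned).max() < 1e-8

    def test_degenerate_configuration_names_specimen(self):
        coords = np.stack([TEMPLATE, TEMPLATE])
        coords[1] = np.outer(np.arange(K), np.array([1.0, 0, 0]))  # collinear
        with pytest.raises(DegenerateShapeError, match="bad"):
            gpa(LandmarkArray(["ok", "bad"], coords))


class TestSymmetrize:
    def test_symmetric_input_has_zero_asymmetry(self):
        lma = LandmarkArray(["a", "b"], np.stack([TEMPLATE, 1.1 * TEMPLATE + 0.2]))
        space = symmetrize(lma, PAIRING)
        assert np.abs(space.asymmetric).max() < 1e-8

    def test_decomposition_is_exact(self):
        space = symmetrize(noisy_sample(8, 0.03, 7), PAIRING)
        np.testing.assert_array_equal(
            space.symmetric + space.asymmetric, space.aligned)

    def test_idempotent_on_asymmetry_free_sample(self):
        # shapes varying only in their symmetric component (plus rigid
        # transforms): the decomposition is a numerical fixed point
        rng = np.random.default_rng(8)
        perm = PAIRING.permutation()
        coords = np.empty((10, K, 3))
        for i in range(10):
            pert = rng.standard_normal((K, 3)) * 0.05
            refl = pert[perm].copy()
            refl[:, 0] = -refl[:, 0]
            sym_shape = TEMPLATE + 0.5 * (pert + refl)
            R = special_ortho_group.rvs(3, random_state=200 + i)
            coords[i] = sym_shape @ R * (1 + 0.1 * i) + rng.standard_normal(3)
        first = symmetrize(LandmarkArray([f"s{i}" for i in range(10)], coords),
                           PAIRING)
        assert np.abs(first.asymmetric).max() < 1e-12
        second = symmetrize(LandmarkArray(
            first.specimen_ids, first.symmetric.reshape(10, K, 3)), PAIRING)
        assert np.abs(second.symmetric - first.symmetric).max() < 1e-8
        assert np.abs(second.asymmetric).max() < 1e-10

    def test_idempotence_error_decays_quadratically(self):
        # on generic data the second pass differs at O(asymmetry^2):
        # rescaling and consensus re-estimation are second-order effects
        errs = []
        for noise in (1e-2, 1e-3):
            a = symmetrize(noisy_sample(10, noise, 9), PAIRING)
            b = symmetrize(LandmarkArray(a.specimen_ids,
                                         a.symmetric.reshape(10, K, 3)), PAIRING)
            errs.append(np.abs(b.symmetric - a.symmetric).max())
        assert errs[1] < errs[0] * 1e-1  # ~1e-2 expected for quadratic decay

    def test_planted_pair_asymmetry_recovered_after_alignment(self):
        # a pure left/right pair perturbation: the asymmetric field equals
        # the planted asymmetry with its rigid-rotation component removed
        # (registration absorbs that part), to first order in the offset
        delta = 0.01
        pert = np.zeros((K, 3))
        pert[0, 1] = delta
        pert[1, 1] = -delta
        X0 = TEMPLATE + pert
        space = symmetrize(LandmarkArray(
            [f"s{i}" for i in range(6)], np.stack([X0] * 6)), PAIRING)
        A = space.asymmetric.reshape(6, K, 3)[0]
        M = TEMPLATE - TEMPLATE.mean(0)
        M = M / np.linalg.norm(M)
        Gy = np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], dtype=float)
        Gz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], dtype=float)
        Q, _ = np.linalg.qr(np.column_stack([(M @ Gy.T).ravel(),
                                             (M @ Gz.T).ravel()]))
        perm = PAIRING.permutation()
        Xc = X0 - X0.mean(0)
        Xc = Xc / np.linalg.norm(Xc)
        pn = Xc - M
        a = 0.5 * (pn - _reflect_relabel(pn, perm)).ravel()
        oracle = (a - Q @ (Q.T @ a)).reshape(K, 3)
        oracle = oracle @ _opa_rotation(M, space.mean_shape.reshape(K, 3))
        rel = np.linalg.norm(A - oracle) / np.linalg.norm(oracle)
        assert rel < 1e-4
        # exact sign mirroring across the pair: left = -mirror(right)
        right_mirrored = A[1].copy()
        right_mirrored[0] = -right_mirrored[0]
        np.testing.assert_allclose(A[0], -right_mirrored, atol=1e-12)

    def test_pairing_must_cover_data(self):
        with pytest.raises(GeometryError, match="pairing covers"):
            symmetrize(noisy_sample(3, 0.01, 10), default_pairing(14))


class TestPairingValidation:
    def test_overlapping_indices_rejected(self):
        with pytest.raises(GeometryError, match="overlap"):
            SymmetryPairing([(1, 2), (2, 3)], [4])

    def test_self_pair_rejected(self):
        with pytest.raises(GeometryError, match="itself"):
            SymmetryPairing([(1, 1)], [2])

    def test_coverage_must_be_contiguous(self):
        with pytest.raises(GeometryError, match="cover"):
            SymmetryPairing([(1, 2)], [5])


class TestDirectionalAsymmetry:
    def test_zero_asymmetry_is_degenerate(self):
        lma = LandmarkArray(["a", "b", "c"],
                            np.stack([TEMPLATE, TEMPLATE, TEMPLATE]))
        space = symmetrize(lma, PAIRING)
        with pytest.raises(DegenerateShapeError):
            directional_asymmetry_test(space)

    def test_requires_symmetry_decomposition(self):
        space = gpa(noisy_sample(5, 0.02, 11))
        with pytest.raises(GeometryError, match="symmetrize"):
            directional_asymmetry_test(space)

    def test_detects_planted_directional_offset(self):
        # mean asymmetric offset of 3 coordinate SDs, n = 8: near-certain
        # rejection at alpha = 0.05
        noise = 0.02
        rng = np.random.default_rng(12)
        da = rng.standard_normal((K, 3))
        refl = da[PAIRING.permutation()].copy()
        refl[:, 0] = -refl[:, 0]
        da = 0.5 * (da - refl)  # purely asymmetric direction
        da = da / np.abs(da).max()
        rejections = 0
        for rep in range(200):
            r = np.random.default_rng(1000 + rep)
            coords = (TEMPLATE[None] + r.standard_normal((8, K, 3)) * noise
                      + 3 * noise * da[None])
            space = symmetrize(LandmarkArray(
                [f"s{i}" for i in range(8)], coords), PAIRING)
            if directional_asymmetry_test(space).p < 0.05:
                rejections += 1
        assert rejections >= 190

    def test_df_convention(self):
        space = symmetrize(noisy_sample(30, 0.02, 13), PAIRING)
        res = directional_asymmetry_test(space)
        assert res.df_den == 29 * res.df_num
        assert 0.0 <= res.p <= 1.0


class TestResidualize:
    def test_null_design_is_identity(self):
        space = symmetrize(noisy_sample(6, 0.03, 14), PAIRING)
        cov = pd.DataFrame({
            "specimen": space.specimen_ids,
            "generation": ["g1"] * 6,
            "sex": ["F"] * 6,
        })
        out, coef = residualize_shape(space, cov)
        np.testing.assert_allclose(out.symmetric, space.symmetric, atol=1e-12)

    def test_two_group_means_coincide(self):
        space = symmetrize(noisy_sample(8, 0.02, 15), PAIRING)
        delta = np.zeros(3 * K)
        delta[4] = 0.3
        shifted = space.symmetric.copy()
        shifted[4:] += delta
        shifted_space = type(space)(
            specimen_ids=space.specimen_ids, aligned=space.aligned,
            centroid_sizes=space.centroid_sizes, mean_shape=space.mean_shape,
            symmetric=shifted, asymmetric=space.asymmetric)
        cov = pd.DataFrame({
            "specimen": space.specimen_ids,
            "sex": ["F"] * 4 + ["M"] * 4,
        })
        out, _ = residualize_shape(shifted_space, cov)
        g1 = out.symmetric[:4].mean(axis=0)
        g2 = out.symmetric[4:].mean(axis=0)
        assert np.linalg.norm(g1 - g2) < 1e-10

    def test_residuals_orthogonal_to_design_and_mean_preserved(self):
        space = symmetrize(noisy_sample(50, 0.02, 16), PAIRING)
        rng = np.random.default_rng(17)
        cov = pd.DataFrame({
            "specimen": space.specimen_ids,
            "generation": rng.choice(["g1", "g2", "g3"], 50),
            "sex": rng.choice(["F", "M"], 50),
        })
        grand = space.symmetric.mean(axis=0)
        out, coef = residualize_shape(space, cov)
        resid = out.symmetric - grand
        D = pd.get_dummies(cov.set_index("specimen")).to_numpy(dtype=float)
        assert np.abs(D.T @ resid).max() < 1e-8
        np.testing.assert_allclose(out.symmetric.mean(axis=0), grand, atol=1e-10)

    def test_aliased_design_is_error(self):
        space = symmetrize(noisy_sample(6, 0.02, 18), PAIRING)
        cov = pd.DataFrame({
            "specimen": space.specimen_ids,
            "generation": ["g1", "g1", "g1", "g2", "g2", "g2"],
            "sex": ["F", "F", "F", "M", "M", "M"],  # confounded with generation
        })
        with pytest.raises(GeometryError, match="aliased"):
            residualize_shape(space, cov)


class TestIO:
    def test_landmark_csv_round_trip(self, tmp_path):
        lma = noisy_sample(3, 0.02, 19)
        path = tmp_path / "lm.csv"
        write_landmarks(lma, path)
        back = load_landmarks(path)
        assert back.specimen_ids == lma.specimen_ids
        np.testing.assert_allclose(back.coords, lma.coords, atol=1e-9)

    def test_pairing_round_trip(self, tmp_path):
        path = tmp_path / "pairing.csv"
        write_pairing(PAIRING, path)
        back = load_pairing(path)
        assert back.pairs == PAIRING.pairs
        assert back.midline == PAIRING.midline
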