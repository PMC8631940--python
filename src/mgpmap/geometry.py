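"""Landmark preprocessing: Procrustes alignment, object symmetry, covariates.

Shapes enter as n x K x 3 landmark configurations. Generalized Procrustes
Analysis (GPA) removes translation, scale and rotation (proper rotations
only); for bilaterally symmetric structures the object-symmetry
construction reflects each configuration, relabels paired landmarks, and
aligns the doubled sample, splitting every shape into a symmetric and an
asymmetric component. Directional asymmetry is tested with a Procrustes
ANOVA F-ratio, and nuisance covariates (generation, sex) are regressed
out coordinate-wise with the grand mean restored.

Aligned configurations carry centroid at the origin and unit centroid
size; no tangent-space projection is applied — downstream analyses
operate on the aligned coordinates directly. After convergence the
consensus is rotated into a canonical principal-axes frame so GPA output
does not depend on specimen order or on arbitrary pre-rotations of the
input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GPA_TOL = 1e-10
GPA_MAX_ITER = 200


class GeometryError(ValueError):
    pass


class DegenerateShapeError(GeometryError):
    """A test or decomposition has no variation to work with."""


@dataclass
class LandmarkArray:
    """n specimens x K landmarks x 3 coordinates, no missing values."""

    specimen_ids: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise GeometryError(f"coords must be n x K x 3, got {self.coords.shape}")
        if self.coords.shape[0] != len(self.specimen_ids):
            raise GeometryError("specimen ids do not match coordinate rows")
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("missing or non-finite coordinates")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]


def load_landmarks(path) -> LandmarkArray:
    """Read the landmark CSV dialect: header ``specimen,L1_x,L1_y,L1_z,...``."""
    df = pd.read_csv(path, dtype={"specimen": str})
    ncoord = df.shape[1] - 1
    if ncoord % 3:
        raise GeometryError(f"{path}: coordinate count {ncoord} not divisible by 3")
    coords = df.iloc[:, 1:].to_numpy(dtype=float).reshape(len(df), ncoord // 3, 3)
    return LandmarkArray(df["specimen"].tolist(), coords)


def write_landmarks(lma: LandmarkArray, path) -> None:
    K = lma.n_landmarks
    header = "specimen," + ",".join(
        f"L{k + 1}_{ax}" for k in range(K) for ax in "xyz"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        flat = lma.coords.reshape(lma.n_specimens, -1)
        for sid, row in zip(lma.specimen_ids, flat):
            fh.write(sid + "," + ",".join(format(v, ".10g") for v in row) + "\n")


@dataclass
class SymmetryPairing:
    """Bilateral landmark pairing: (left, right) pairs plus midline, 1-based."""

    pairs: list[tuple[int, int]]
    midline: list[int]

    def __post_init__(self) -> None:
        if any(l == r for l, r in self.pairs):
            raise GeometryError("a landmark cannot pair with itself")
        used = [i for pair in self.pairs for i in pair] + list(self.midline)
        if len(used) != len(set(used)):
            raise GeometryError("pairing indices overlap")
        if min(used, default=1) < 1:
            raise GeometryError("pairing indices are 1-based")
        self.n_landmarks = len(used)
        if set(used) != set(range(1, self.n_landmarks + 1)):
            raise GeometryError("pairing must jointly cover 1..K exactly")

    def permutation(self) -> np.ndarray:
        """0-based landmark permutation swapping left and right labels."""
        perm = np.arange(self.n_landmarks)
        for l, r in self.pairs:
            perm[l - 1], perm[r - 1] = r - 1, l - 1
        return perm


def load_pairing(path) -> SymmetryPairing:
    """Read pairing: ``left,right`` lines, then a ``midline`` line and indices."""
    pairs, midline = [], []
    section = "pairs"
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.lower() == "midline":
                section = "midline"
                continue
            if section == "pairs":
                l, r = line.split(",")
                pairs.append((int(l), int(r)))
            else:
                midline.append(int(line))
    return SymmetryPairing(pairs, midline)


def write_pairing(pairing: SymmetryPairing, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for l, r in pairing.pairs:
            fh.write(f"{l},{r}\n")
        fh.write("midline\n")
        for m in pairing.midline:
            fh.write(f"{m}\n")


@dataclass
class ShapeSpace:
    """Procrustes-aligned shapes, flat n x 3K, with optional symmetry split.

    ``symmetric + asymmetric = aligned`` holds exactly as stored when the
    symmetry decomposition is present.
    """

    specimen_ids: list[str]
    aligned: np.ndarray
    centroid_sizes: np.ndarray
    mean_shape: np.ndarray
    symmetric: np.ndarray | None = None
    asymmetric: np.ndarray | None = None
    n_landmarks: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_landmarks == 0:
            self.n_landmarks = self.aligned.shape[1] // 3

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    def shape_matrix(self, component: str = "auto") -> np.ndarray:
        """Analysis matrix: the symmetric component when present ('auto')."""
        if component == "auto":
            component = "symmetric" if self.symmetric is not None else "aligned"
        mat = getattr(self, component)
        if mat is None:
            raise GeometryError(f"component {component!r} not available")
        return mat


def _center_and_scale(coords: np.ndarray, specimen_ids) -> tuple[np.ndarray, np.ndarray]:
    X = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt((X ** 2).sum(axis=(1, 2)))
    for i, s in enumerate(sizes):
        if s < 1e-12:
            raise DegenerateShapeError(f"specimen {specimen_ids[i]}: zero centroid size")
    X = X / sizes[:, None, None]
    for i in range(X.shape[0]):
        if np.linalg.matrix_rank(X[i], tol=1e-10) < 2:
            raise DegenerateShapeError(
                f"specimen {specimen_ids[i]}: degenerate (collinear) configuration"
            )
    return X, sizes


def _opa_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||A @ R - B|| (Kabsch)."""
    U, _, Vt = np.linalg.svd(A.T @ B)
    d = np.sign(np.linalg.det(U @ Vt))
    return (U * np.array([1.0, 1.0, d])) @ Vt


def _rotate_all(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        out[i] = X[i] @ _opa_rotation(X[i], M)
    return out


def _axis_sign(M: np.ndarray, v: np.ndarray) -> float:
    proj = M @ v
    j = int(np.argmax(np.abs(proj)))
    return 1.0 if proj[j] >= 0 else -1.0


def _canonical_rotation(M: np.ndarray) -> np.ndarray:
    """Rotation taking the consensus to its principal-axes frame.

    Axes ordered by decreasing landmark variance; the sign of the first
    two axes makes the largest-|projection| landmark positive, the third
    completes a right-handed frame. Nearly spherical consensus shapes
    make this frame ill-conditioned; that degeneracy is documented, not
    resolved.
    """
    w, V = np.linalg.eigh(M.T @ M)
    order = np.argsort(w)[::-1]
    v1 = V[:, order[0]] * _axis_sign(M, V[:, order[0]])
    v2 = V[:, order[1]] * _axis_sign(M, V[:, order[1]])
    v3 = np.cross(v1, v2)
    return np.column_stack([v1, v2, v3])


def gpa(landmarks: LandmarkArray, tol: float = GPA_TOL,
        max_iter: int = GPA_MAX_ITER) -> ShapeSpace:
    """Generalized Procrustes Analysis with proper rotations only.

    Iterates rotate-to-consensus / re-estimate-consensus until the
    consensus moves by less than ``tol`` (default 1e-10) or ``max_iter``
    iterations; the consensus is kept at unit centroid size, and the
    converged sample is rotated into the canonical principal-axes frame.
    """
    if landmarks.n_specimens < 2:
        raise GeometryError("GPA needs at least 2 specimens")
    if landmarks.n_landmarks < 3:
        raise GeometryError("GPA needs at least 3 landmarks")
    X, sizes = _center_and_scale(landmarks.coords, landmarks.specimen_ids)
    M = X.mean(axis=0)
    M /= np.linalg.norm(M)
    for _ in range(max_iter):
        X = _rotate_all(X, M)
        Mn = X.mean(axis=0)
        Mn -= Mn.mean(axis=0)
        Mn /= np.linalg.norm(Mn)
        delta = np.linalg.norm(Mn - M)
        M = Mn
        if delta < tol:
            break
    R = _canonical_rotation(M)
    M = M @ R
    X = X @ R
    n = landmarks.n_specimens
    return ShapeSpace(
        specimen_ids=list(landmarks.specimen_ids),
        aligned=X.reshape(n, -1),
        centroid_sizes=sizes,
        mean_shape=M.reshape(-1),
    )


def _reflect_relabel(X: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Mirror the first coordinate axis and swap left/right labels."""
    out = X[..., perm, :].copy()
    out[..., 0] = -out[..., 0]
    return out


def _symmetry_plane_rotation(M: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Rotation placing the consensus symmetry plane at x = 0.

    For an intrinsically symmetric consensus, reflect-and-relabel equals a
    rotation U of the consensus; U composed with the mirror is a
    reflection across the true symmetry plane, whose unit normal is its
    eigenvector with eigenvalue -1. Putting that normal on the x axis
    makes reflect-relabel an exact elementwise symmetry.
    """
    TM = _reflect_relabel(M, perm)
    Q = _opa_rotation(TM, M)  # TM @ Q ~ M  =>  TM ~ M @ Q.T
    U = Q.T
    S = U @ np.diag([-1.0, 1.0, 1.0])
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    normal = V[:, int(np.argmin(w))]
    # complete an orthonormal right-handed frame with `normal` first
    basis = np.linalg.svd(normal[None, :])[2][1:]
    b2 = basis[0]
    return np.column_stack([normal, b2, np.cross(normal, b2)])


def _inplane_canonical_rotation(M: np.ndarray) -> np.ndarray:
    """Canonical in-plane (y, z) orientation; leaves the x axis fixed."""
    yz = M[:, 1:]
    w, V = np.linalg.eigh(yz.T @ yz)
    order = np.argsort(w)[::-1]
    v1 = V[:, order[0]]
    proj = yz @ v1
    j = int(np.argmax(np.abs(proj)))
    if proj[j] < 0:
        v1 = -v1
    v2 = np.array([-v1[1], v1[0]])  # +90 degrees, proper 2-D rotation
    R = np.eye(3)
    R[1:, 1:] = np.column_stack([v1, v2])
    return R


def symmetrize(landmarks: LandmarkArray, pairing: SymmetryPairing,
               tol: float = GPA_TOL, max_iter: int = GPA_MAX_ITER) -> ShapeSpace:
    """Object-symmetry GPA: split each shape into symmetric + asymmetric.

    Each configuration is joined with its reflected, left/right-relabeled
    copy and the doubled sample is superimposed. The consensus is forced
    into the frame where the symmetry plane is exactly x = 0; there the
    reflected copy of an aligned shape is itself aligned, so the doubled
    GPA reduces to aligning originals against a consensus that is
    re-symmetrized each iteration. Symmetric component = average of the
    aligned original and its reflected copy; asymmetric = remainder.
    """
    if pairing.n_landmarks != landmarks.n_landmarks:
        raise GeometryError(
            f"pairing covers {pairing.n_landmarks} landmarks, data has "
            f"{landmarks.n_landmarks}"
        )
    perm = pairing.permutation()
    X, sizes = _center_and_scale(landmarks.coords, landmarks.specimen_ids)
    M = X.mean(axis=0)
    M /= np.linalg.norm(M)
    M = M @ _symmetry_plane_rotation(M, perm)
    M = 0.5 * (M + _reflect_relabel(M, perm))  # exact elementwise symmetry
    nrm = np.linalg.norm(M)
    if nrm < 0.1:
        raise DegenerateShapeError("consensus collapses under symmetrization")
    M /= nrm
    for _ in range(max_iter):
        X = _rotate_all(X, M)
        Mn = X.mean(axis=0)
        Mn -= Mn.mean(axis=0)
        Mn = 0.5 * (Mn + _reflect_relabel(Mn, perm))
        Mn /= np.linalg.norm(Mn)
        delta = np.linalg.norm(Mn - M)
        M = Mn
        if delta < tol:
            break
    R = _inplane_canonical_rotation(M)  # preserves the x = 0 symmetry plane
    M = M @ R
    X = X @ R
    refl = _reflect_relabel(X, perm)
    sym = 0.5 * (X + refl)
    n = landmarks.n_specimens
    aligned = X.reshape(n, -1)
    symmetric = sym.reshape(n, -1)
    return ShapeSpace(
        specimen_ids=list(landmarks.specimen_ids),
        aligned=aligned,
        centroid_sizes=sizes,
        mean_shape=M.reshape(-1),
        symmetric=symmetric,
        asymmetric=aligned - symmetric,
    )


@dataclass
class AsymmetryTest:
    F: float
    df_num: int
    df_den: int
    p: float
    ss_directional: float
    ss_fluctuating: float


def directional_asymmetry_test(space: ShapeSpace) -> AsymmetryTest:
    """Procrustes ANOVA for directional asymmetry.

    Tests whether the mean asymmetric component differs from zero against
    fluctuating asymmetry: SS_DA = n * ||mean asymmetry||^2 on df equal to
    the empirical rank of the asymmetric subspace, SS_FA = within-sample
    deviation on (n - 1) * rank; their mean-square ratio is referred to an
    F distribution. Requires a symmetry decomposition and n >= 3.
    """
    if space.asymmetric is None:
        raise GeometryError("no asymmetric component: run symmetrize first")
    A = space.asymmetric
    n = A.shape[0]
    if n < 3:
        raise GeometryError("asymmetry test needs n >= 3")
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[0] < 1e-14:
        raise DegenerateShapeError("asymmetric components are all zero")
    df_num = int(np.sum(sv > sv[0] * 1e-7))
    mean_a = A.mean(axis=0)
    ss_da = n * float(mean_a @ mean_a)
    resid = A - mean_a
    ss_fa = float((resid ** 2).sum())
    if ss_fa <= 0:
        raise DegenerateShapeError("no fluctuating asymmetry: F undefined")
    df_den = (n - 1) * df_num
    F = (ss_da / df_num) / (ss_fa / df_den)
    p = float(stats.f.sf(F, df_num, df_den))
    return AsymmetryTest(float(F), df_num, df_den, p, ss_da, ss_fa)


def _design_matrix(covariates: pd.DataFrame, specimen_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    df = covariates.copy()
    if "specimen" in df.columns:
        df = df.set_index("specimen")
    try:
        df = df.loc[specimen_ids]
    except KeyError as exc:
        raise GeometryError(f"covariates missing specimens: {exc}") from exc
    cols, names = [np.ones(len(df))], ["intercept"]
    for col in df.columns:
        dummies = pd.get_dummies(df[col].astype("category"), drop_first=True)
        for level in dummies.columns:
            cols.append(dummies[level].to_numpy(dtype=float))
            names.append(f"{col}[{level}]")
    D = np.column_stack(cols)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        _, Rq = np.linalg.qr(D)
        aliased = [names[j] for j in range(D.shape[1])
                   if abs(Rq[j, j]) < 1e-8 * abs(Rq[0, 0])]
        raise GeometryError(
            "rank-deficient covariate design; aliased terms: " + ", ".join(aliased)
        )
    return D, names


def residualize_shape(
    space: ShapeSpace,
    covariates: pd.DataFrame,
    component: str = "auto",
) -> tuple[ShapeSpace, pd.DataFrame]:
    """Regress shape on dummy-coded covariates; keep residuals + grand mean.

    Used to strip generation and sex structure from the symmetric shapes
    before genotype-phenotype fitting. Returns the new ShapeSpace (the
    chosen component replaced, grand mean preserved) plus the fitted
    coefficients for audit.
    """
    Y = space.shape_matrix(component)
    D, names = _design_matrix(covariates, space.specimen_ids)
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    grand = Y.mean(axis=0)
    out = resid + grand
    comp = component if component != "auto" else (
        "symmetric" if space.symmetric is not None else "aligned"
    )
    new = ShapeSpace(
        specimen_ids=list(space.specimen_ids),
        aligned=out if comp == "aligned" else space.aligned.copy(),
        centroid_sizes=space.centroid_sizes.copy(),
        mean_shape=grand.copy(),
        symmetric=out if comp == "symmetric" else
        (None if space.symmetric is None else space.symmetric.copy()),
        asymmetric=None if space.asymmetric is None else space.asymmetric.copy(),
    )
    coef = pd.DataFrame(beta, index=names)
    return new, coef
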