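"""Mutant effect directions and morphospace projection.

Mutant and reference (e.g. Diversity Outbred) specimens are registered
together so their coordinates live in one shape space; a mutant's effect
direction is the mutant-minus-reference mean difference per coordinate —
exactly the coefficient vector of a group-indicator multivariate linear
model, used as a direction only. Process and mutant effects can be drawn
in the principal-component plane of the pooled sample, magnified for
visibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mgpmap.geometry import (
    LandmarkArray,
    ShapeSpace,
    SymmetryPairing,
    gpa,
    symmetrize,
)
from mgpmap.inference import EffectVector


class MutantError(ValueError):
    pass


@dataclass
class MutantContrast:
    """Mutant-vs-reference mean-difference direction in shape space."""

    label: str
    direction: np.ndarray
    n_mutant: int
    n_reference: int

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        if not np.all(np.isfinite(self.direction)):
            raise MutantError("non-finite contrast direction")
        if self.n_mutant < 1 or self.n_reference < 1:
            raise MutantError("both groups must be non-empty")

    def as_effect(self) -> EffectVector:
        return EffectVector(self.direction, self.label, kind="mutant")


def joint_registration(
    reference: LandmarkArray,
    mutants: LandmarkArray,
    pairing: SymmetryPairing | None = None,
) -> ShapeSpace:
    """Pooled superimposition of reference and mutant specimens.

    Size is removed (unit centroid size) as in any GPA here; with a
    pairing the pooled sample is also symmetrized, the default space for
    mutant contrasts.
    """
    if reference.n_landmarks != mutants.n_landmarks:
        raise MutantError(
            f"landmark count mismatch: {reference.n_landmarks} vs "
            f"{mutants.n_landmarks}"
        )
    dup = set(reference.specimen_ids) & set(mutants.specimen_ids)
    if dup:
        raise MutantError(f"specimen ids appear in both groups: {sorted(dup)}")
    pooled = LandmarkArray(
        specimen_ids=list(reference.specimen_ids) + list(mutants.specimen_ids),
        coords=np.concatenate([reference.coords, mutants.coords], axis=0),
    )
    if pairing is None:
        return gpa(pooled)
    return symmetrize(pooled, pairing)


def mutant_direction(
    space: ShapeSpace,
    reference_ids: list[str],
    mutant_ids: list[str],
    label: str = "mutant",
    component: str = "auto",
) -> MutantContrast:
    """Mutant group mean minus reference group mean, per flat coordinate."""
    if not reference_ids or not mutant_ids:
        raise MutantError("both groups must be non-empty")
    index = {s: i for i, s in enumerate(space.specimen_ids)}
    try:
        ref_idx = [index[s] for s in reference_ids]
        mut_idx = [index[s] for s in mutant_ids]
    except KeyError as exc:
        raise MutantError(f"specimen not in shape space: {exc}") from exc
    mat = space.shape_matrix(component)
    direction = mat[mut_idx].mean(axis=0) - mat[ref_idx].mean(axis=0)
    return MutantContrast(
        label=label, direction=direction,
        n_mutant=len(mut_idx), n_reference=len(ref_idx),
    )


@dataclass
class MorphospaceProjection:
    pc_scores: np.ndarray          # n x n_pcs specimen scores
    effect_tips: np.ndarray        # len(effects) x 2, displacement from ref mean
    reference_score: np.ndarray    # PC1/PC2 score of the reference mean
    variance_fractions: np.ndarray
    ellipse_center: np.ndarray
    ellipse_axes: np.ndarray       # semi-axis lengths of the 95% data ellipse
    ellipse_angle: float           # radians, first axis vs PC1
    effect_labels: list[str] = field(default_factory=list)


def project_onto_morphospace(
    space: ShapeSpace,
    effects: list[EffectVector],
    magnify: float = 4.0,
    reference_ids: list[str] | None = None,
    component: str = "aligned",
    n_pcs: int = 2,
) -> MorphospaceProjection:
    """Project effect vectors into the pooled sample's PC1/PC2 plane.

    Each effect is drawn from the reference-group mean; its tip
    displacement is the effect scaled by ``magnify`` projected onto the
    PC loadings (projection is linear in the effect). Also returns the
    normal-theory 95% data ellipse of the reference group (chi-square
    quantile, 2 df).
    """
    mat = space.shape_matrix(component)
    n = mat.shape[0]
    if n < 3:
        raise MutantError("morphospace needs at least 3 specimens")
    center = mat.mean(axis=0)
    Xc = mat - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(Vt.shape[0]):  # reproducible PC signs
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    W = Vt[:n_pcs].T
    scores = Xc @ W
    var_frac = (s ** 2) / float((s ** 2).sum())
    if reference_ids is None:
        ref_idx = list(range(n))
    else:
        index = {sid: i for i, sid in enumerate(space.specimen_ids)}
        ref_idx = [index[sid] for sid in reference_ids]
    ref_score = scores[ref_idx, :2].mean(axis=0)
    tips = np.array([magnify * (e.values @ W[:, :2]) for e in effects]) \
        if effects else np.empty((0, 2))
    ref2 = scores[ref_idx, :2]
    cov = np.cov(ref2, rowvar=False)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    chi2 = stats.chi2.ppf(0.95, df=2)
    axes = np.sqrt(np.maximum(w, 0.0) * chi2)
    angle = float(np.arctan2(V[1, 0], V[0, 0]))
    return MorphospaceProjection(
        pc_scores=scores,
        effect_tips=tips,
        reference_score=ref_score,
        variance_fractions=var_frac[:n_pcs],
        ellipse_center=ref2.mean(axis=0),
        ellipse_axes=axes,
        ellipse_angle=angle,
        effect_labels=[e.label for e in effects],
    )
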