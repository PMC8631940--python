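"""Inference over regularized PLS fits.

Variance explained by a process gene set is calibrated against an
LD-matched permutation null built from random gene sets of the same
size; effect directions are compared by vector correlation (Pearson over
shape-coordinate loadings); stability is probed by dropping the
highest-loading genes; and a battery of process effects is summarized by
an absolute-correlation matrix, hierarchical clustering and the
cophenetic correlation of the resulting dendrogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from mgpmap.annotations import GeneRecord, GeneSet
from mgpmap.genotypes import (
    FounderProbArray,
    GenotypeError,
    MarkerMap,
    N_FOUNDERS,
    gene_probability_block,
    select_flanking_markers,
)
from mgpmap.spls_core import _fit_core, _standardize

logger = logging.getLogger(__name__)


class InferenceError(ValueError):
    pass


@dataclass
class EffectVector:
    """A length-3K shape direction comparable across analyses."""

    values: np.ndarray
    label: str
    kind: str = "process"  # process | mutant | pc

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise InferenceError(f"effect {self.label!r} has non-finite entries")
        if self.kind not in {"process", "mutant", "pc"}:
            raise InferenceError(f"unknown effect kind {self.kind!r}")


@dataclass
class NullDistribution:
    observed_r2: float
    null_r2: np.ndarray
    p_value: float
    n_permutations: int
    ld_tolerance: float
    seed: int


@dataclass
class VectorCorrelation:
    r: float
    t: float
    df: int
    p: float


def vector_correlation(a, b, landmarks: list[int] | None = None) -> VectorCorrelation:
    """Pearson correlation between two shape-effect vectors.

    ``landmarks`` optionally restricts the comparison to a subset of
    landmarks (1-based indices; each contributes its x, y, z entries) —
    used e.g. for palate-only correlations. t = r * sqrt(df / (1 - r^2))
    with df = L - 2 entries, two-sided p.
    """
    av = a.values if isinstance(a, EffectVector) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, EffectVector) else np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise InferenceError("effect vectors differ in length")
    if landmarks is not None:
        idx = np.concatenate([[3 * (l - 1), 3 * (l - 1) + 1, 3 * (l - 1) + 2]
                              for l in landmarks]).astype(int)
        av, bv = av[idx], bv[idx]
    L = len(av)
    if L < 3:
        raise InferenceError("need at least 3 entries")
    if av.std() == 0 or bv.std() == 0:
        raise InferenceError("zero-variance effect vector: correlation undefined")
    r = float(np.corrcoef(av, bv)[0, 1])
    df = L - 2
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    return VectorCorrelation(r, float(t), df, p)


@dataclass
class _GenePrecompute:
    """Per-gene pieces reused across thousands of permutation refits."""

    symbols: list[str]
    blocks_std: dict[str, np.ndarray]      # n x 8 standardized founder tracks
    c_blocks: dict[str, np.ndarray]        # 8 x 3K cross-correlation slices
    x_means: dict[str, np.ndarray]
    x_scales: dict[str, np.ndarray]
    ld: pd.DataFrame                       # gene x gene max-founder r^2
    Yc: np.ndarray
    tr_y: float
    n: int


def _precompute_genes(
    genes: list[GeneRecord],
    probs: FounderProbArray,
    marker_map: MarkerMap,
    Y: np.ndarray,
) -> _GenePrecompute:
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    Ys, y_std = _standardize(Y)
    Yc = Y - y_std.means
    tr_y = float((Yc ** 2).sum())
    blocks_std, c_blocks, x_means, x_scales, symbols = {}, {}, {}, {}, []
    for gene in genes:
        try:
            up, down = select_flanking_markers(gene, marker_map)
        except GenotypeError:
            logger.warning("gene %s has no mappable markers; skipped", gene.symbol)
            continue
        block = gene_probability_block(probs, up, down)
        bs, std = _standardize(block)
        symbols.append(gene.symbol)
        blocks_std[gene.symbol] = bs
        c_blocks[gene.symbol] = np.clip(bs.T @ Ys / (n - 1), -1.0, 1.0)
        x_means[gene.symbol] = std.means
        x_scales[gene.symbol] = std.scales
    # gene-level LD: max over founders of squared track correlation
    G = len(symbols)
    stacked = np.stack([blocks_std[s] for s in symbols])  # G x n x 8
    ld = np.zeros((G, G))
    for f in range(N_FOUNDERS):
        tracks = stacked[:, :, f]  # G x n, standardized (or all-zero)
        corr = tracks @ tracks.T / (n - 1)
        ld = np.maximum(ld, corr ** 2)
    np.fill_diagonal(ld, 1.0)
    ld_df = pd.DataFrame(ld, index=symbols, columns=symbols)
    return _GenePrecompute(symbols, blocks_std, c_blocks, x_means, x_scales,
                           ld_df, Yc, tr_y, n)


def _fit_gene_subset(pre: _GenePrecompute, symbols: list[str], lambda_: float):
    """Fit from precomputed per-gene slices; identical to fit_spls by
    construction (column standardization is per-column, so the stacked
    cross-correlation equals the full-block computation exactly)."""
    C = np.vstack([pre.c_blocks[s] for s in symbols])
    Xs = np.hstack([pre.blocks_std[s] for s in symbols])
    u, v, d, t, b = _fit_core(Xs, pre.Yc, C, lambda_)
    tc = t - t.mean()
    r2 = min(float(tc @ tc) * float(b @ b) / pre.tr_y, 1.0) if pre.tr_y > 0 else 0.0
    return u, v, d, t, b, r2


def _mean_within_set_ld(pre: _GenePrecompute, symbols: list[str]) -> float:
    if len(symbols) < 2:
        return 0.0
    sub = pre.ld.loc[symbols, symbols].to_numpy()
    iu = np.triu_indices(len(symbols), k=1)
    return float(sub[iu].mean())


def permutation_null(
    gene_set: GeneSet,
    catalog: list[GeneRecord],
    probs: FounderProbArray,
    marker_map: MarkerMap,
    Y: np.ndarray,
    lambda_: float,
    n_perm: int = 10_000,
    ld_tol: float = 0.05,
    seed: int = 0,
) -> NullDistribution:
    """LD-matched permutation null for the trace-ratio R^2.

    Each replicate draws |gene_set| catalog genes without replacement,
    rejecting draws whose mean within-set LD differs from the observed
    set's by more than ``ld_tol`` (after 50 rejections the closest match
    is accepted), and refits with the identical penalty. The one-sided
    empirical p uses the add-one estimator, so p is never zero.
    """
    if len(catalog) <= len(gene_set):
        raise InferenceError(
            f"catalog ({len(catalog)} genes) must exceed the gene set "
            f"({len(gene_set)})"
        )
    observed_symbols = gene_set.symbols
    by_symbol = {g.symbol: g for g in catalog}
    pool_genes = list(catalog)
    for g in gene_set.genes:  # ensure observed genes are precomputed too
        if g.symbol not in by_symbol:
            pool_genes.append(g)
    pre = _precompute_genes(pool_genes, probs, marker_map, Y)
    obs_syms = [s for s in observed_symbols if s in pre.blocks_std]
    if not obs_syms:
        raise InferenceError("observed gene set has no mappable genes")
    *_, obs_r2 = _fit_gene_subset(pre, obs_syms, lambda_)
    obs_ld = _mean_within_set_ld(pre, obs_syms)
    pool = [s for s in pre.symbols if s in {g.symbol for g in catalog}]
    size = len(obs_syms)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        best_syms, best_gap = None, np.inf
        for _ in range(51):  # <= 50 rejections, then keep the best match
            draw = [pool[j] for j in rng.choice(len(pool), size=size, replace=False)]
            gap = abs(_mean_within_set_ld(pre, draw) - obs_ld)
            if gap < best_gap:
                best_syms, best_gap = draw, gap
            if gap <= ld_tol:
                break
        *_, r2 = _fit_gene_subset(pre, best_syms, lambda_)
        null[i] = r2
    p = (1 + int(np.sum(null >= obs_r2))) / (1 + n_perm)
    return NullDistribution(
        observed_r2=float(obs_r2), null_r2=null, p_value=float(p),
        n_permutations=n_perm, ld_tolerance=float(ld_tol), seed=seed,
    )


def gene_drop(
    gene_set: GeneSet,
    probs: FounderProbArray,
    marker_map: MarkerMap,
    Y: np.ndarray,
    lambda_: float,
    max_drop: int,
) -> pd.DataFrame:
    """Sensitivity to removing the most heavily loaded genes.

    Gene importance is the Euclidean norm of the gene's 8 founder
    loadings in the full fit; genes are removed cumulatively in
    full-model importance order. Each row reports the refit R^2 and the
    absolute vector correlation of the refit phenotypic axis with the
    full-model axis (0 with a flag if the refit saturates to zero).
    """
    if max_drop >= len(gene_set):
        raise InferenceError("max_drop must be smaller than the gene set")
    pre = _precompute_genes(gene_set.genes, probs, marker_map, Y)
    syms = list(pre.symbols)
    u_full, v_full, d_full, _, _, r2_full = _fit_gene_subset(pre, syms, lambda_)
    norms = {
        s: float(np.linalg.norm(u_full[8 * i: 8 * i + 8]))
        for i, s in enumerate(syms)
    }
    order = sorted(syms, key=lambda s: (-norms[s], s))
    rows = [{"k_removed": 0, "gene_removed": "", "r2": r2_full,
             "corr_with_full": 1.0, "saturated": bool(d_full == 0.0)}]
    remaining = list(syms)
    for k in range(1, max_drop + 1):
        gene = order[k - 1]
        remaining = [s for s in remaining if s != gene]
        _, v_k, d_k, _, _, r2_k = _fit_gene_subset(pre, remaining, lambda_)
        if d_k == 0.0:
            corr, saturated = 0.0, True
        else:
            corr = abs(vector_correlation(v_k, v_full).r)
            saturated = False
        rows.append({"k_removed": k, "gene_removed": gene, "r2": r2_k,
                     "corr_with_full": corr, "saturated": saturated})
    return pd.DataFrame(rows)


def pairwise_process_matrix(effects: list[EffectVector]) -> pd.DataFrame:
    """Absolute vector-correlation matrix across process effects."""
    if len(effects) < 2:
        raise InferenceError("need at least 2 effects")
    labels = [e.label for e in effects]
    m = len(effects)
    out = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = abs(vector_correlation(effects[i], effects[j]).r)
    return pd.DataFrame(out, index=labels, columns=labels)


@dataclass
class CopheneticResult:
    linkage: np.ndarray
    cophenetic_matrix: np.ndarray
    r: float
    t: float
    df: int
    p: float
    labels: list[str] = field(default_factory=list)


def cluster_and_cophenetic(
    corr, linkage_method: str = "complete"
) -> CopheneticResult:
    """Agglomerative clustering of 1 - |r| distances + cophenetic stability.

    The cophenetic distance of a pair is the dendrogram height at which
    they merge; its Pearson correlation with the original distances over
    the strictly-lower-triangle pairs (df = n_pairs - 2) measures how
    faithfully the tree preserves the similarity structure.
    """
    labels = list(corr.index) if isinstance(corr, pd.DataFrame) else []
    M = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise InferenceError("correlation matrix must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise InferenceError("correlation matrix must be symmetric")
    if linkage_method not in {"single", "complete", "average"}:
        raise InferenceError(f"unsupported linkage {linkage_method!r}")
    D = 1.0 - np.abs(M)
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage_method)
    coph = hierarchy.cophenet(Z)
    n_pairs = len(condensed)
    r, _ = stats.pearsonr(coph, condensed)
    df = n_pairs - 2
    r = float(r)
    if abs(r) >= 1.0:
        t, p = (np.inf if r > 0 else -np.inf), 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    return CopheneticResult(
        linkage=Z, cophenetic_matrix=squareform(coph), r=r, t=float(t),
        df=df, p=p, labels=labels,
    )


def dendrogram_newick(result: CopheneticResult) -> str:
    """Serialize the merge tree as Newick text with merge-height branch lengths."""
    tree = hierarchy.to_tree(result.linkage)
    labels = result.labels or [str(i) for i in range(result.linkage.shape[0] + 1)]

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.10g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
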