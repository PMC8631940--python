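"""Founder-probability handling and per-gene genotype-block assembly.

In an eight-founder multiparental population every marker carries, per
specimen, an 8-vector of estimated diplotype contributions (a point on
the probability simplex). For a gene set we pick the two markers
flanking each gene's midpoint, average their probability vectors, and
concatenate the per-gene 8-column blocks into the genotype matrix used
by the regularized PLS. Also provides the LD summary used for
permutation matching and the genotype-correlation kinship screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mgpmap.annotations import GeneRecord, GeneSet

logger = logging.getLogger(__name__)

FOUNDERS = "ABCDEFGH"
N_FOUNDERS = 8
SIMPLEX_TOL = 1e-6


class GenotypeError(ValueError):
    pass


class ZeroVarianceError(GenotypeError):
    """LD is undefined when a dosage track has no variance."""


@dataclass
class MarkerMap:
    """Ordered marker map: ids, chromosomes and bp positions.

    Positions must be strictly increasing within each chromosome and ids
    unique; any map size is accepted.
    """

    ids: list[str]
    chromosomes: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if len(self.ids) != len(set(self.ids)):
            raise GenotypeError("marker ids not unique")
        if not (len(self.ids) == len(self.chromosomes) == len(self.positions)):
            raise GenotypeError("marker map fields have unequal lengths")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        ids_arr = np.asarray(self.ids, dtype=object)
        for chrom in pd.unique(self.chromosomes):
            sel = self.chromosomes == chrom
            pos = self.positions[sel]
            if np.any(np.diff(pos) <= 0):
                raise GenotypeError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
            self._by_chrom[str(chrom)] = (ids_arr[sel], pos)

    def __len__(self) -> int:
        return len(self.ids)

    def chromosome_markers(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self._by_chrom:
            raise GenotypeError(f"chromosome {chrom} absent from marker map")
        return self._by_chrom[chrom]


def load_marker_map(path) -> MarkerMap:
    """Read a 3-column TSV (marker, chromosome, bp position)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["marker", "chrom", "bp"],
                     comment="#", dtype={"marker": str, "chrom": str})
    return MarkerMap(df["marker"].tolist(), df["chrom"].to_numpy(),
                     df["bp"].to_numpy())


def write_marker_map(mm: MarkerMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mid, chrom, pos in zip(mm.ids, mm.chromosomes, mm.positions):
            fh.write(f"{mid}\t{chrom}\t{pos}\n")


@dataclass
class FounderProbArray:
    """specimens x markers x 8 founder probabilities on the simplex."""

    specimen_ids: list[str]
    marker_ids: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        n, m = len(self.specimen_ids), len(self.marker_ids)
        if self.probs.shape != (n, m, N_FOUNDERS):
            raise GenotypeError(
                f"probs shape {self.probs.shape} != ({n}, {m}, {N_FOUNDERS})"
            )
        if np.any(self.probs < -SIMPLEX_TOL):
            raise GenotypeError("negative founder probabilities")
        sums = self.probs.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > SIMPLEX_TOL):
            bad = np.argwhere(np.abs(sums - 1.0) > SIMPLEX_TOL)[0]
            raise GenotypeError(
                f"probabilities do not sum to 1 at specimen {bad[0]}, marker {bad[1]}"
            )
        self._marker_index = {m_: i for i, m_ in enumerate(self.marker_ids)}

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)

    def marker_probs(self, marker_id: str) -> np.ndarray:
        if marker_id not in self._marker_index:
            raise GenotypeError(f"unknown marker {marker_id}")
        return self.probs[:, self._marker_index[marker_id], :]


def load_founder_probs(path) -> FounderProbArray:
    """Read founder probabilities; auto-detects HDF5 vs long-format TSV.

    The TSV dialect has a header ``specimen  marker  pA..pH``; the HDF5
    container holds datasets ``specimens``, ``markers`` and ``probs``.
    """
    import h5py

    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as fh:
            specs = [s.decode() if isinstance(s, bytes) else str(s)
                     for s in fh["specimens"][()]]
            marks = [m.decode() if isinstance(m, bytes) else str(m)
                     for m in fh["markers"][()]]
            probs = fh["probs"][()]
        return FounderProbArray(specs, marks, probs)
    df = pd.read_csv(path, sep="\t", dtype={"specimen": str, "marker": str})
    cols = ["p" + f for f in FOUNDERS]
    specs = list(dict.fromkeys(df["specimen"]))
    marks = list(dict.fromkeys(df["marker"]))
    si = {s: i for i, s in enumerate(specs)}
    mi = {m: i for i, m in enumerate(marks)}
    probs = np.full((len(specs), len(marks), N_FOUNDERS), np.nan)
    probs[df["specimen"].map(si), df["marker"].map(mi), :] = df[cols].to_numpy()
    if np.isnan(probs).any():
        raise GenotypeError(f"{path}: incomplete specimen x marker grid")
    return FounderProbArray(specs, marks, probs)


def write_founder_probs(fpa: FounderProbArray, path) -> None:
    """Write the long-format TSV dialect, deterministically formatted."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("specimen\tmarker\t" + "\t".join("p" + f for f in FOUNDERS) + "\n")
        for i, spec in enumerate(fpa.specimen_ids):
            for j, mark in enumerate(fpa.marker_ids):
                vals = "\t".join(format(v, ".10g") for v in fpa.probs[i, j])
                fh.write(f"{spec}\t{mark}\t{vals}\n")


@dataclass
class GenotypeBlock:
    """Concatenated per-gene 8-column founder-probability blocks.

    ``columns`` labels each column as (gene_symbol, founder letter);
    each gene's 8 columns sum row-wise to 1.
    """

    X: np.ndarray
    columns: list[tuple[str, str]]
    gene_to_markers: dict[str, tuple[str, str]]
    specimen_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[1] != len(self.columns):
            raise GenotypeError("column labels do not match matrix width")
        if len(self.columns) != N_FOUNDERS * len(self.gene_to_markers):
            raise GenotypeError("column count != 8 x number of genes")

    @property
    def genes(self) -> list[str]:
        return list(self.gene_to_markers)

    def gene_block(self, symbol: str) -> np.ndarray:
        idx = [i for i, (g, _) in enumerate(self.columns) if g == symbol]
        if not idx:
            raise GenotypeError(f"gene {symbol} not in block")
        return self.X[:, idx]


def select_flanking_markers(gene: GeneRecord, marker_map: MarkerMap) -> tuple[str, str]:
    """Closest markers flanking the gene midpoint, in bp coordinates.

    Upstream = largest position <= center; downstream = smallest position
    > center. A gene beyond the terminal marker clamps to that nearest
    marker for both slots (degenerate single-marker block).
    """
    ids, pos = marker_map.chromosome_markers(gene.chromosome)
    c = gene.center_bp
    k = int(np.searchsorted(pos, c, side="right"))  # markers [0, k) are <= c
    if k == 0:
        return str(ids[0]), str(ids[0])
    if k == len(pos):
        return str(ids[-1]), str(ids[-1])
    return str(ids[k - 1]), str(ids[k])


def gene_probability_block(
    probs: FounderProbArray, up: str, down: str
) -> np.ndarray:
    """Elementwise mean of the two flanking markers' 8-vectors."""
    return 0.5 * (probs.marker_probs(up) + probs.marker_probs(down))


def assemble_genotype_block(
    gene_set: GeneSet, probs: FounderProbArray, marker_map: MarkerMap
) -> GenotypeBlock:
    """Concatenate per-gene averaged blocks in gene order.

    Genes on chromosomes without markers are dropped with a warning;
    genes sharing identical flanking pairs are retained per-gene, since
    loadings are reported per gene. All genes dropped is an error.
    """
    if len(gene_set) == 0:
        raise GenotypeError("empty gene set")
    blocks, columns, gene_to_markers = [], [], {}
    dropped = []
    for gene in gene_set.genes:
        try:
            up, down = select_flanking_markers(gene, marker_map)
        except GenotypeError:
            dropped.append(gene.symbol)
            continue
        blocks.append(gene_probability_block(probs, up, down))
        columns.extend((gene.symbol, f) for f in FOUNDERS)
        gene_to_markers[gene.symbol] = (up, down)
    if dropped:
        logger.warning("dropped %d gene(s) without mappable markers: %s",
                       len(dropped), ", ".join(dropped))
    if not blocks:
        raise GenotypeError("all genes dropped: no chromosome has markers")
    return GenotypeBlock(
        X=np.hstack(blocks),
        columns=columns,
        gene_to_markers=gene_to_markers,
        specimen_ids=list(probs.specimen_ids),
    )


def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of two per-specimen dosage tracks."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise GenotypeError("dosage vectors must be equal-length 1-D")
    if len(a) < 3:
        raise GenotypeError("need at least 3 specimens for LD")
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        raise ZeroVarianceError("zero-variance dosage track: LD undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return min(r * r, 1.0)


def ld_r2_blocks(block_a: np.ndarray, block_b: np.ndarray) -> float:
    """Gene-level LD: max over founders of the track-wise squared correlation.

    Each gene block is n x 8; founder probability tracks are the natural
    dosage analogue in an 8-founder population. Founders monomorphic in
    either block are skipped; all-monomorphic pairs raise.
    """
    best = None
    for f in range(N_FOUNDERS):
        try:
            r2 = ld_r2(block_a[:, f], block_b[:, f])
        except ZeroVarianceError:
            continue
        best = r2 if best is None else max(best, r2)
    if best is None:
        raise ZeroVarianceError("no polymorphic founder track shared")
    return best


def kinship_matrix(probs: FounderProbArray) -> tuple[np.ndarray, float, float]:
    """Genotype-correlation kinship screen.

    Flattens each specimen's probability array, centers columns across
    specimens, and correlates specimen rows. Returns the n x n matrix plus
    the mean and SD of its off-diagonal entries — the screening statistics
    used to decide whether a relatedness adjustment is warranted.
    """
    n = probs.n_specimens
    if n < 2:
        raise GenotypeError("kinship needs at least 2 specimens")
    flat = probs.probs.reshape(n, -1)
    flat = flat - flat.mean(axis=0, keepdims=True)
    keep = flat.std(axis=0) > 0
    K = np.corrcoef(flat[:, keep])
    off = K[~np.eye(n, dtype=bool)]
    return K, float(off.mean()), float(off.std())
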