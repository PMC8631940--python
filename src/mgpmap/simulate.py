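"""Synthetic multiparental data generator.

Emulates the statistical structure the mapping method assumes: each
specimen's genome is a mosaic of 8 founder haplotypes with linkage along
chromosomes (two independent founder-state Markov chains per chromosome,
averaged into diplotype probabilities, optionally softened toward the
uniform simplex to mimic reconstruction uncertainty); genes occupy
random non-overlapping intervals with a causal-process ontology term;
shapes are a deterministic bilaterally symmetric 3-D template plus a
sparse additive genetic effect along one symmetric unit direction plus
isotropic Gaussian coordinate noise. Founder coefficients are zero-sum,
so genetic effects are contrasts among founders, and the effect
amplitude is calibrated so the genetic share of total coordinate
variance equals the configured target exactly (on the realized sample).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from mgpmap.annotations import load_gene_catalog
from mgpmap.genotypes import (
    FOUNDERS,
    FounderProbArray,
    MarkerMap,
    N_FOUNDERS,
    gene_probability_block,
    select_flanking_markers,
    write_founder_probs,
    write_marker_map,
)
from mgpmap.geometry import LandmarkArray, SymmetryPairing, write_landmarks, write_pairing

CAUSAL_TERM_ID = "GO:SIM0001"
CAUSAL_TERM_NAME = "causal_process"


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults are the reference conditions used throughout the test suite:
    800 specimens on a scaled-down genome of 20 chromosomes x 50 evenly
    spaced markers, a 2% founder switch probability per marker interval
    with 5% probability softening, a 600-gene catalog whose 20-gene
    causal term carries 2 causal genes, a genetic variance share of 5%,
    coordinate noise SD 0.05 on a unit-scale template, and the
    54-landmark bilaterally symmetric reference configuration. The
    catalog is kept large relative to the causal footprint so random
    gene sets rarely tag the causal loci, as in a genome-wide pool.
    """

    n_specimens: int = 800
    n_chromosomes: int = 20
    markers_per_chromosome: int = 50
    marker_spacing_bp: int = 1_000_000
    switch_prob: float = 0.02
    prob_softening: float = 0.05
    n_genes: int = 600
    causal_genes: tuple = ("gene001", "gene002")
    causal_term_size: int = 20
    n_decoy_terms: int = 3
    effect_direction_seed: int | None = None
    effect_size: float = 0.05
    noise_sd: float = 0.05
    n_landmarks: int = 54
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.switch_prob <= 1.0:
            raise SimulationError("switch_prob must be in [0, 1]")
        if not 0.0 <= self.prob_softening < 1.0:
            raise SimulationError("prob_softening must be in [0, 1)")
        if not 0.0 <= self.effect_size < 1.0:
            raise SimulationError("effect_size must be in [0, 1)")
        if self.causal_term_size < len(self.causal_genes):
            raise SimulationError("causal term smaller than its causal genes")
        if self.causal_term_size > self.n_genes:
            raise SimulationError("causal term larger than the gene catalog")
        symbols = {f"gene{i + 1:03d}" for i in range(self.n_genes)}
        if not set(self.causal_genes) <= symbols:
            raise SimulationError("causal_genes must be simulated gene symbols")


def default_pairing(n_landmarks: int) -> SymmetryPairing:
    """Canonical pairing for a generated template: K = 2p + m landmarks.

    Midline count is 2 for even K and 3 for odd K; paired landmarks come
    first (left then right, interleaved), midline landmarks last.
    """
    m = 2 + (n_landmarks % 2)
    p = (n_landmarks - m) // 2
    if p < 1:
        raise SimulationError(f"too few landmarks ({n_landmarks}) for a pairing")
    pairs = [(2 * i + 1, 2 * i + 2) for i in range(p)]
    midline = list(range(2 * p + 1, n_landmarks + 1))
    return SymmetryPairing(pairs, midline)


def shape_template(n_landmarks: int) -> np.ndarray:
    """Deterministic symmetric template on an ellipsoid, K x 3.

    Left/right pairs sit mirrored across the x = 0 plane on a
    golden-angle spiral; midline landmarks lie in the plane. Scale is
    order 1 so the default noise SD of 0.05 is a few percent of size.
    """
    pairing = default_pairing(n_landmarks)
    p, m = len(pairing.pairs), len(pairing.midline)
    coords = np.zeros((n_landmarks, 3))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for i, (l, r) in enumerate(pairing.pairs):
        frac = (i + 0.5) / p
        theta = golden * i
        z = 1.0 - 2.0 * frac
        rad = np.sqrt(max(1.0 - z * z, 0.0))
        x = 0.25 + 0.75 * rad * abs(np.cos(theta))
        y = 1.3 * rad * np.sin(theta)
        coords[l - 1] = (x, y, 0.8 * z)
        coords[r - 1] = (-x, y, 0.8 * z)
    for j, mid in enumerate(pairing.midline):
        frac = (j + 0.5) / m
        coords[mid - 1] = (0.0, 1.5 * (frac - 0.5), 0.9 * np.cos(np.pi * frac))
    return coords


def simulate_founder_mosaic(config: SimConfig) -> tuple[FounderProbArray, MarkerMap]:
    """Two-haplotype founder mosaics with linkage along chromosomes.

    Each haplotype is a Markov chain over the 8 founders: uniform initial
    state, switching to a uniformly random *other* founder with
    probability ``switch_prob`` per marker interval. The diplotype
    probability vector is the average of the two haplotype indicators,
    optionally mixed with the uniform simplex by ``prob_softening``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_specimens
    ids, chroms, positions = [], [], []
    for c in range(config.n_chromosomes):
        for j in range(config.markers_per_chromosome):
            ids.append(f"chr{c + 1}_m{j + 1:03d}")
            chroms.append(f"chr{c + 1}")
            positions.append((j + 1) * config.marker_spacing_bp)
    marker_map = MarkerMap(ids, np.array(chroms, dtype=object),
                           np.array(positions, dtype=np.int64))
    m_per = config.markers_per_chromosome
    total = config.n_chromosomes * m_per
    states = np.empty((n, 2, total), dtype=np.int64)
    for c in range(config.n_chromosomes):
        sl = slice(c * m_per, (c + 1) * m_per)
        cur = rng.integers(0, N_FOUNDERS, size=(n, 2))
        chain = np.empty((n, 2, m_per), dtype=np.int64)
        chain[:, :, 0] = cur
        for j in range(1, m_per):
            switch = rng.random(size=(n, 2)) < config.switch_prob
            offset = rng.integers(1, N_FOUNDERS, size=(n, 2))
            cur = np.where(switch, (cur + offset) % N_FOUNDERS, cur)
            chain[:, :, j] = cur
        states[:, :, sl] = chain
    onehot = np.eye(N_FOUNDERS)
    probs = 0.5 * (onehot[states[:, 0, :]] + onehot[states[:, 1, :]])
    if config.prob_softening > 0:
        s = config.prob_softening
        probs = (1.0 - s) * probs + s / N_FOUNDERS
    specimen_ids = [f"spec{i + 1:04d}" for i in range(n)]
    return FounderProbArray(specimen_ids, ids, probs), marker_map


def simulate_annotation(config: SimConfig, marker_map: MarkerMap, max_retries: int = 1000):
    """Gene catalog and ontology fixtures over the simulated marker map.

    Genes occupy random non-overlapping intervals inside the marker span;
    roughly a third get a second, shorter transcript so the
    longest-transcript rule is exercised. The causal term holds the
    configured causal genes plus decoys up to ``causal_term_size``;
    additional decoy-only terms are added. Returns (catalog_rows,
    ontology_rows) as lists of column tuples matching the TSV formats.
    """
    rng = np.random.default_rng(config.seed + 1)
    chrom_names = sorted({str(c) for c in marker_map.chromosomes})
    spans = {}
    for c in chrom_names:
        _, pos = marker_map.chromosome_markers(c)
        spans[c] = (int(pos[0]), int(pos[-1]))
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    catalog_rows = []
    for i in range(config.n_genes):
        symbol = f"gene{i + 1:03d}"
        for attempt in range(max_retries):
            c = chrom_names[int(rng.integers(0, len(chrom_names)))]
            lo, hi = spans[c]
            length = int(rng.integers(10_000, 200_000))
            if hi - lo <= length:
                continue
            start = int(rng.integers(lo, hi - length))
            end = start + length
            if all(end < s or start > e for s, e in placed[c]):
                placed[c].append((start, end))
                break
        else:
            raise SimulationError(f"could not place {symbol} after {max_retries} tries")
        catalog_rows.append((symbol, f"{symbol}.t1", c, start, end, "+"))
        if i % 3 == 0:  # shorter secondary transcript
            sub = int(rng.integers(start, start + length // 2))
            catalog_rows.append((symbol, f"{symbol}.t2", c, sub,
                                 sub + length // 3, "-"))
    all_symbols = [f"gene{i + 1:03d}" for i in range(config.n_genes)]
    causal = list(config.causal_genes)
    decoy_pool = [s for s in all_symbols if s not in causal]
    term_members = causal + decoy_pool[: config.causal_term_size - len(causal)]
    ontology_rows = [(CAUSAL_TERM_ID, CAUSAL_TERM_NAME, s) for s in term_members]
    for t in range(config.n_decoy_terms):
        size = int(rng.integers(3, max(4, config.n_genes // 4)))
        members = rng.choice(decoy_pool, size=min(size, len(decoy_pool)),
                             replace=False)
        go_id = f"GO:SIM{t + 2:04d}"
        ontology_rows.extend((go_id, f"decoy_process_{t + 1}", s)
                             for s in sorted(members))
    return catalog_rows, ontology_rows


def _symmetric_direction(n_landmarks: int, pairing: SymmetryPairing,
                         rng: np.random.Generator) -> np.ndarray:
    """Random unit direction in the symmetric subspace of the pairing."""
    w = rng.standard_normal((n_landmarks, 3))
    perm = pairing.permutation()
    refl = w[perm].copy()
    refl[:, 0] = -refl[:, 0]
    w = 0.5 * (w + refl)
    flat = w.reshape(-1)
    nrm = np.linalg.norm(flat)
    if nrm < 1e-12:
        raise SimulationError("degenerate effect direction")
    return flat / nrm


def simulate_shapes(
    config: SimConfig,
    probs: FounderProbArray,
    marker_map: MarkerMap,
    catalog,
) -> tuple[LandmarkArray, dict]:
    """Template + sparse additive founder effects + isotropic noise.

    Every causal gene contributes a zero-sum per-founder coefficient
    vector; all causal genes push along one shared symmetric unit
    direction ``w`` (a rank-1 genotype-phenotype map). The amplitude is
    calibrated on the realized founder probabilities so the genetic share
    of total coordinate variance equals ``effect_size``. Returns the
    landmarks plus a truth record (direction, per-gene coefficients and
    variance shares, calibration constants) for recovery tests.
    """
    by_symbol = {g.symbol: g for g in catalog}
    missing = [s for s in config.causal_genes if s not in by_symbol]
    if missing:
        raise SimulationError(f"causal genes not in catalog: {missing}")
    K = config.n_landmarks
    pairing = default_pairing(K)
    template = shape_template(K)
    n = probs.n_specimens
    dir_seed = (config.effect_direction_seed
                if config.effect_direction_seed is not None
                else config.seed + 2)
    rng_dir = np.random.default_rng(dir_seed)
    w = _symmetric_direction(K, pairing, rng_dir)
    rng = np.random.default_rng(config.seed + 3)
    founder_coefs: dict[str, np.ndarray] = {}
    gene_scores = np.zeros((n, len(config.causal_genes)))
    for gi, symbol in enumerate(config.causal_genes):
        up, down = select_flanking_markers(by_symbol[symbol], marker_map)
        block = gene_probability_block(probs, up, down)
        a = rng.standard_normal(N_FOUNDERS)
        a -= a.mean()  # zero-sum: effects are contrasts among founders
        score = block @ a
        sd = float(score.std(ddof=1))
        if sd <= 0:
            raise SimulationError(f"causal gene {symbol} has no genotypic variance")
        # equal analytic contribution per causal gene: unit-variance scores
        a /= sd
        founder_coefs[symbol] = a
        gene_scores[:, gi] = score / sd
    s_total = gene_scores.sum(axis=1)
    var_s = float(s_total.var(ddof=1)) if config.causal_genes else 0.0
    noise_trace = 3 * K * config.noise_sd ** 2
    if config.effect_size > 0:
        if var_s <= 0:
            raise SimulationError("causal genes carry no genotypic variance")
        if noise_trace > 0:
            amp = np.sqrt(
                config.effect_size / (1.0 - config.effect_size)
                * noise_trace / var_s
            )
        else:
            # noiseless: the variance share is 1 regardless of amplitude,
            # so no calibration applies; unit amplitude on the standardized
            # genetic score
            amp = 1.0
    else:
        amp = 0.0
    noise = rng.standard_normal((n, K, 3)) * config.noise_sd
    coords = template[None, :, :] + noise
    coords += (amp * s_total)[:, None, None] * w.reshape(1, K, 3)
    genetic_var = amp ** 2 * var_s
    per_gene_share = {
        s: float(amp ** 2 * gene_scores[:, gi].var(ddof=1)
                 / (genetic_var + noise_trace)) if amp > 0 else 0.0
        for gi, s in enumerate(config.causal_genes)
    }
    truth = {
        "w": w.tolist(),
        "causal_genes": list(config.causal_genes),
        "founder_coefficients": {s: a.tolist() for s, a in founder_coefs.items()},
        "amplitude": float(amp),
        "genetic_variance": genetic_var,
        "noise_trace": noise_trace,
        "genetic_share": (genetic_var / (genetic_var + noise_trace)
                          if noise_trace > 0 else 0.0),
        "per_gene_share": per_gene_share,
        "seed": config.seed,
    }
    return LandmarkArray(list(probs.specimen_ids), coords), truth


@dataclass
class SimulatedStudy:
    """An in-memory study bundle: genotypes, annotation, shapes, truth."""

    probs: FounderProbArray
    marker_map: MarkerMap
    records: dict
    landmarks: LandmarkArray
    truth: dict
    gene_set: "GeneSet"
    catalog: list


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate a complete study and resolve the causal-process gene set."""
    from mgpmap.annotations import GeneRecord, GeneSet

    probs, marker_map = simulate_founder_mosaic(config)
    catalog_rows, ontology_rows = simulate_annotation(config, marker_map)
    best: dict = {}
    for sym, _t, c, s, e, _st in catalog_rows:
        key = (-(e - s), s)
        if sym not in best or key < best[sym][0]:
            best[sym] = (key, GeneRecord(sym, c, s, e))
    records = {k: v[1] for k, v in best.items()}
    landmarks, truth = simulate_shapes(config, probs, marker_map,
                                       list(records.values()))
    members = [g for (go, _t, g) in ontology_rows if go == CAUSAL_TERM_ID]
    gene_set = GeneSet(
        CAUSAL_TERM_NAME, [CAUSAL_TERM_ID],
        sorted((records[m] for m in members),
               key=lambda g: (g.chromosome, g.start_bp, g.symbol)),
    )
    return SimulatedStudy(probs, marker_map, records, landmarks, truth,
                          gene_set, list(records.values()))


def make_fixture(config: SimConfig, out_dir) -> dict:
    """Write a complete analysis bundle; byte-deterministic given the seed.

    Emits landmarks.csv, founder_probs.tsv, marker_map.tsv,
    gene_catalog.tsv, ontology.tsv, pairing.csv, covariates.csv,
    config.json and truth.json; returns the file paths. Covariates
    (generation, sex) are drawn at random and carry no shape effect.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probs, marker_map = simulate_founder_mosaic(config)
    catalog_rows, ontology_rows = simulate_annotation(config, marker_map)
    catalog_path = out / "gene_catalog.tsv"
    with open(catalog_path, "w", encoding="utf-8") as fh:
        for row in catalog_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    ontology_path = out / "ontology.tsv"
    with open(ontology_path, "w", encoding="utf-8") as fh:
        for row in ontology_rows:
            fh.write("\t".join(row) + "\n")
    catalog = load_gene_catalog(catalog_path)
    landmarks, truth = simulate_shapes(config, probs, marker_map, catalog)
    paths = {
        "landmarks": out / "landmarks.csv",
        "founder_probs": out / "founder_probs.tsv",
        "marker_map": out / "marker_map.tsv",
        "gene_catalog": catalog_path,
        "ontology": ontology_path,
        "pairing": out / "pairing.csv",
        "covariates": out / "covariates.csv",
        "config": out / "config.json",
        "truth": out / "truth.json",
    }
    write_landmarks(landmarks, paths["landmarks"])
    write_founder_probs(probs, paths["founder_probs"])
    write_marker_map(marker_map, paths["marker_map"])
    write_pairing(default_pairing(config.n_landmarks), paths["pairing"])
    rng = np.random.default_rng(config.seed + 4)
    generations = rng.integers(10, 15, size=config.n_specimens)
    sexes = rng.choice(["F", "M"], size=config.n_specimens)
    with open(paths["covariates"], "w", encoding="utf-8") as fh:
        fh.write("specimen,generation,sex\n")
        for sid, g, s in zip(probs.specimen_ids, generations, sexes):
            fh.write(f"{sid},{g},{s}\n")
    with open(paths["config"], "w", encoding="utf-8") as fh:
        json.dump(asdict(config), fh, sort_keys=True, indent=1)
        fh.write("\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
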