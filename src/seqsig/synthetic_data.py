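"""Ground-truth synthetic datasets with the generative structure the
pipeline assumes.

Each simulated gene owns a 2,004-bp TSS window tiled into 334 six-bp
segments.  A hidden peak/dip path is drawn from a persistent two-state
Markov chain; peak segments emit 6-mers from a peak-specific
distribution and dip segments from a promoter-like GC-rich background.
ChIP-style reads are placed so the extended-read pileup has
segment-conditional Poisson means, and expression follows a logistic
link in the TSS-proximal peak arrangement with Gaussian noise.  A second
cell type shares each peak run with a configurable probability and
otherwise has its own independently drawn peaks.

Each cell type owns a genome-wide 6-mer log-preference field (clipped
Gaussian); the two fields are partially anti-correlated, emulating
differentiation: sequences recognized by one cell type's acetylation
machinery tend not to be acetylated in the other.  A small set of named
driver 6-mers is strongly enriched in both cell types (universal
promoter-activation motifs).  Segment sequences are drawn from the
joint state: a segment acetylated in both cell types is enriched for
both fields, a cell-specific peak only for its own field.  The field
spread is chosen so a single segment carries roughly the
discriminability observed for real promoter-proximal histone-mark data
(segment-level AUC about 0.9 after decoding).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coverage_peaks
from .kmer_spectrum import ALL_KMERS, N_KMERS, kmer_index
from .region_io import (
    ExpressionTable,
    GeneRecord,
    N_SEGMENTS,
    SEGMENT_LENGTH,
    TssWindow,
    WINDOW_LENGTH,
    extract_tss_windows,
    reverse_complement,
    write_expression,
    write_fasta,
    write_regions_bed,
)

CELL_A = "cellA"
CELL_B = "cellB"

# driver 6-mers planted with maximal peak enrichment; chosen to match known
# pluripotency-factor motif cores (Zfx, Oct4, Nanog, KLF4, Myc fragments)
DEFAULT_DRIVERS = ("TAAAGC", "ATGCGC", "CTTGTC", "CGGTGT", "GCGCGT")


@dataclass
class GeneratorConfig:
    """All knobs of the simulator; one seed drives every random draw."""

    n_genes: int = 2000
    seed: int = 0
    # hidden chain
    a_mm: float = 0.97
    a_dd: float = 0.99
    # emissions
    emission_log_sd: float = 1.75
    emission_log_clip: float = 2.0
    driver_kmers: tuple[str, ...] = DEFAULT_DRIVERS
    driver_delta: float = 2.5
    field_correlation: float = -0.8
    gc_content: float = 0.55
    # coverage
    lambda_peak: float = 20.0
    lambda_dip: float = 1.0
    read_length: int = 36
    fragment_length: int = 150
    # expression link
    link_slope: float = 8.0
    link_center: float = 0.5
    noise_sd: float = 0.4       # SD of the log2-scale expression noise
    max_log_level: float = 10.0
    expression_independent: bool = False
    # second cell type
    shared_fraction: float = 0.3
    # layout
    chrom: str = "chrS"
    spacer_length: int = 498
    margin: int = 2004
    minus_strand_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.lambda_dip >= self.lambda_peak:
            raise ValueError(
                "lambda_dip >= lambda_peak: states are unidentifiable from coverage"
            )
        if self.lambda_dip < 0:
            raise ValueError("coverage rates must be non-negative")
        for name in ("a_mm", "a_dd", "shared_fraction", "minus_strand_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.spacer_length % SEGMENT_LENGTH or self.margin % SEGMENT_LENGTH:
            raise ValueError("spacer_length and margin must be multiples of 6")

    @property
    def transition_matrix(self) -> np.ndarray:
        return np.array(
            [[self.a_mm, 1.0 - self.a_mm], [1.0 - self.a_dd, self.a_dd]]
        )

    @property
    def stationary(self) -> np.ndarray:
        a_md, a_dm = 1.0 - self.a_mm, 1.0 - self.a_dd
        if a_md + a_dm == 0:
            return np.array([0.5, 0.5])
        return np.array([a_dm, a_md]) / (a_md + a_dm)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover.

    ``log_ratio`` is cell A's *marginal* planted log(p(k|peak)/p(k|dip)),
    i.e. the mixture over the other cell type's co-occurring states that
    cell A's spectrum estimator actually sees; ``log_ratio_b`` likewise
    for cell B.  ``fields`` holds the underlying per-cell 6-mer
    log-preference fields.
    """

    gene_ids: list[str]
    states: dict[str, np.ndarray]           # cell -> (n_genes x 334) bool
    fpkm: dict[str, np.ndarray]             # cell -> per-gene FPKM
    log_ratio: np.ndarray                   # cell A marginal log-ratio, 4096
    log_ratio_b: np.ndarray
    fields: dict[str, np.ndarray]           # cell -> planted field, 4096
    p_peak: np.ndarray                      # cell A marginal peak emission
    p_dip: np.ndarray                       # cell A marginal dip emission
    transition_matrix: np.ndarray
    stationary: np.ndarray
    driver_kmers: tuple[str, ...]

    def locus_classes(self) -> np.ndarray:
        """Truth three-way class per (gene, segment) from the two state paths."""
        a = self.states[CELL_A]
        b = self.states[CELL_B]
        cls = np.full(a.shape, "unclassified", dtype=object)
        cls[a & b] = "common"
        cls[a & ~b] = "typeA_specific"
        cls[~a & b] = "typeB_specific"
        return cls


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    genome: dict[str, str]
    genes: list[GeneRecord]
    reads: dict[str, list[tuple[str, int, int, str]]]
    expression: dict[str, ExpressionTable]
    truth: GroundTruth

    def windows(self) -> list[TssWindow]:
        return extract_tss_windows(self.genes, self.genome)

    def write(self, outdir) -> dict[str, Path]:
        """Write FASTA / BED / bedGraph / TSV outputs; byte-stable per seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["genome"] = outdir / "genome.fa"
        write_fasta(self.genome, paths["genome"])
        paths["genes"] = outdir / "genes.bed"
        write_regions_bed(self.genes, paths["genes"])
        chrom = self.config.chrom
        chrom_len = len(self.genome[chrom])
        for cell, reads in self.reads.items():
            p = outdir / f"reads_{cell}.bed"
            with open(p, "w") as fh:
                for c, s, e, strand in reads:
                    fh.write(f"{c}\t{s}\t{e}\tread\t0\t{strand}\n")
            paths[f"reads_{cell}"] = p
            extended = coverage_peaks.extend_reads(
                reads, length=self.config.fragment_length,
                chrom_sizes={chrom: chrom_len},
            )
            track = coverage_peaks.pileup(extended, (chrom, 0, chrom_len))
            pg = outdir / f"coverage_{cell}.bedgraph"
            coverage_peaks.write_bedgraph(track, pg)
            paths[f"coverage_{cell}"] = pg
        for cell, table in self.expression.items():
            p = outdir / f"expression_{cell}.tsv"
            write_expression(table, p)
            paths[f"expression_{cell}"] = p
        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "gene_ids": self.truth.gene_ids,
                    "driver_kmers": list(self.truth.driver_kmers),
                    "transition_matrix": self.truth.transition_matrix.tolist(),
                    "states": {
                        c: s.astype(int).tolist() for c, s in self.truth.states.items()
                    },
                },
                fh,
            )
        return paths


def _build_emissions(cfg: GeneratorConfig, rng: np.random.Generator):
    """Base-composition dip distribution and the two cells' preference fields.

    Returns (joint_tables, field_a, field_b, composition) where
    joint_tables[(a, b)] is the normalized emission distribution for a
    segment acetylated in cell A iff a and in cell B iff b:
    p(k | a, b) ∝ composition(k) * exp(a*field_a[k] + b*field_b[k]).
    """
    gc = cfg.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    comp = np.ones(N_KMERS)
    for pos in range(SEGMENT_LENGTH):
        digit = (np.arange(N_KMERS) // (4 ** (SEGMENT_LENGTH - 1 - pos))) % 4
        comp *= base_p[digit]
    comp /= comp.sum()
    s = cfg.emission_log_sd
    if s > 0:
        z_a = rng.normal(0.0, 1.0, N_KMERS)
        z_shared = rng.normal(0.0, 1.0, N_KMERS)
        rho = cfg.field_correlation
        z_b = rho * z_a + np.sqrt(max(1.0 - rho ** 2, 0.0)) * z_shared
        field_a = np.clip(s * z_a, -cfg.emission_log_clip, cfg.emission_log_clip)
        field_b = np.clip(s * z_b, -cfg.emission_log_clip, cfg.emission_log_clip)
    else:
        rng.normal(0.0, 1.0, 2 * N_KMERS)  # keep the stream position stable
        field_a = np.zeros(N_KMERS)
        field_b = np.zeros(N_KMERS)
    for k in cfg.driver_kmers:
        field_a[kmer_index(k)] = cfg.driver_delta
        field_b[kmer_index(k)] = cfg.driver_delta
    tables = {}
    for a in (0, 1):
        for b in (0, 1):
            t = comp * np.exp(a * field_a + b * field_b)
            tables[(a, b)] = t / t.sum()
    return tables, field_a, field_b, comp


def _marginal_log_ratios(
    tables: dict, states_a: np.ndarray, states_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exact per-cell marginal peak/dip emission mixtures for this dataset.

    Uses the empirical joint-state segment counts, so the returned
    log-ratios are exactly what an infinite-read spectrum estimator
    applied to these state paths would converge to.
    """
    a = states_a.ravel()
    b = states_b.ravel()
    n = {(i, j): float(((a == i) & (b == j)).sum()) for i in (0, 1) for j in (0, 1)}

    def mix(pairs):
        tot = sum(n[p] for p in pairs)
        return sum(n[p] * tables[p] for p in pairs) / tot

    peak_a = mix([(1, 0), (1, 1)])
    dip_a = mix([(0, 0), (0, 1)])
    peak_b = mix([(0, 1), (1, 1)])
    dip_b = mix([(0, 0), (1, 0)])
    return (
        np.log(peak_a) - np.log(dip_a),
        np.log(peak_b) - np.log(dip_b),
        peak_a,
        dip_a,
    )


def _simulate_states(
    cfg: GeneratorConfig, rng: np.random.Generator, n: int, t: int
) -> np.ndarray:
    """n Markov chains of length t over {peak=True, dip=False}."""
    pi_m = cfg.stationary[0]
    states = np.empty((n, t), dtype=bool)
    states[:, 0] = rng.random(n) < pi_m
    u = rng.random((n, t - 1))
    for i in range(1, t):
        stay = np.where(states[:, i - 1], cfg.a_mm, 1.0 - cfg.a_dd)
        states[:, i] = u[:, i - 1] < stay
    return states


def _share_peak_runs(
    rng: np.random.Generator,
    states_a: np.ndarray,
    states_b: np.ndarray,
    shared_fraction: float,
) -> np.ndarray:
    """Overlay cell A's peak runs onto B's independent path w.p. shared."""
    out = states_b.copy()
    for g in range(states_a.shape[0]):
        row = states_a[g]
        # maximal runs of True
        edges = np.flatnonzero(np.diff(np.concatenate(([0], row.view(np.int8), [0]))))
        for lo, hi in zip(edges[::2], edges[1::2]):
            if rng.random() < shared_fraction:
                out[g, lo:hi] = True
    return out


def _sample_segments(
    rng: np.random.Generator,
    states_a: np.ndarray,
    states_b: np.ndarray,
    tables: dict,
) -> np.ndarray:
    """Per-segment 6-mer indices drawn from the joint-state distribution."""
    u = rng.random(states_a.shape).ravel()
    joint = (states_a.astype(int) * 2 + states_b.astype(int)).ravel()
    idx = np.empty(u.shape, dtype=np.int64)
    for code, (a, b) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
        sel = joint == a * 2 + b
        if sel.any():
            idx[sel] = np.searchsorted(np.cumsum(tables[(a, b)]), u[sel])
    return np.minimum(idx, N_KMERS - 1).reshape(states_a.shape)


def _indices_to_sequence(idx_row: np.ndarray) -> str:
    return "".join(ALL_KMERS[i] for i in idx_row)


def _expression_from_states(
    cfg: GeneratorConfig, rng: np.random.Generator, states: np.ndarray
) -> np.ndarray:
    """FPKM via a logistic link in the TSS-proximal peak arrangement.

    The 200 bp downstream of the TSS (5' end of the gene) is weighted most
    heavily; the 100 bp immediately upstream contributes at 40% weight.
    """
    t = states.shape[1]
    centre = t // 2
    w = np.zeros(t)
    down = 200 // SEGMENT_LENGTH
    up = 100 // SEGMENT_LENGTH
    w[centre : centre + down] = 1.0
    w[centre - up : centre] = 0.4
    z = states @ w / w.sum()
    p = 1.0 / (1.0 + np.exp(-cfg.link_slope * (z - cfg.link_center)))
    if cfg.expression_independent:
        p = rng.permutation(p)
    # multiplicative (log-scale) measurement noise, floored at zero FPKM
    log_level = np.maximum(
        cfg.max_log_level * p + rng.normal(0.0, cfg.noise_sd, len(p)), 0.0
    )
    return np.exp2(log_level) - 1.0


def _place_reads(
    cfg: GeneratorConfig, rng: np.random.Generator, lam: np.ndarray
) -> list[tuple[str, int, int, str]]:
    """Reads whose 150-bp extensions pile up to the target per-base rates."""
    frag, rl = cfg.fragment_length, cfg.read_length
    L = len(lam)
    centre = np.minimum(np.arange(L - frag) + frag // 2, L - 1)
    rate = lam[centre] / frag
    counts = rng.poisson(rate)
    starts = np.repeat(np.flatnonzero(counts), counts[counts > 0])
    strands = rng.random(len(starts)) < 0.5
    reads: list[tuple[str, int, int, str]] = []
    for x, plus in zip(starts, strands):
        if plus:
            reads.append((cfg.chrom, int(x), int(x) + rl, "+"))
        else:
            reads.append((cfg.chrom, int(x) + frag - rl, int(x) + frag, "-"))
    return reads


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a complete two-cell-type dataset from the generative model."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tables, field_a, field_b, comp = _build_emissions(cfg, rng)

    n, t = cfg.n_genes, N_SEGMENTS
    states_a = _simulate_states(cfg, rng, n, t)
    states_b_own = _simulate_states(cfg, rng, n, t)
    states_b = _share_peak_runs(rng, states_a, states_b_own, cfg.shared_fraction)

    # one genome; both cell types read the same sequence
    seg_idx = _sample_segments(rng, states_a, states_b, tables)
    lr_a, lr_b, marg_peak_a, marg_dip_a = _marginal_log_ratios(
        tables, states_a, states_b
    )

    gene_ids = [f"g{i:05d}" for i in range(n)]
    strands = np.where(rng.random(n) < cfg.minus_strand_fraction, "-", "+")

    block = WINDOW_LENGTH + cfg.spacer_length
    genome_len = 2 * cfg.margin + n * block
    lam = {
        CELL_A: np.full(genome_len, cfg.lambda_dip, dtype=float),
        CELL_B: np.full(genome_len, cfg.lambda_dip, dtype=float),
    }

    cum_dip = np.cumsum(tables[(0, 0)])

    def background(n_kmers: int) -> str:
        idx = np.minimum(
            np.searchsorted(cum_dip, rng.random(n_kmers)), N_KMERS - 1
        )
        return _indices_to_sequence(idx)

    parts: list[str] = [background(cfg.margin // SEGMENT_LENGTH)]
    genes: list[GeneRecord] = []
    for g in range(n):
        start = cfg.margin + g * block
        oriented = _indices_to_sequence(seg_idx[g])
        if strands[g] == "+":
            parts.append(oriented)
            tss = start + WINDOW_LENGTH // 2
        else:
            parts.append(reverse_complement(oriented))
            tss = start + WINDOW_LENGTH // 2 - 1
        parts.append(background(cfg.spacer_length // SEGMENT_LENGTH))
        genes.append(
            GeneRecord(
                gene_id=gene_ids[g], chrom=cfg.chrom, tss=tss,
                strand=str(strands[g]),
                body=(tss, tss + 200) if strands[g] == "+" else (tss - 199, tss + 1),
            )
        )
        end = start + WINDOW_LENGTH
        for cell, st in ((CELL_A, states_a), (CELL_B, states_b)):
            for i in np.flatnonzero(st[g]):
                if strands[g] == "+":
                    s = start + i * SEGMENT_LENGTH
                else:
                    s = end - (i + 1) * SEGMENT_LENGTH
                lam[cell][s : s + SEGMENT_LENGTH] = cfg.lambda_peak
    parts.append(background(cfg.margin // SEGMENT_LENGTH))
    genome = {cfg.chrom: "".join(parts)}

    reads = {cell: _place_reads(cfg, rng, lam[cell]) for cell in (CELL_A, CELL_B)}

    fpkm = {
        CELL_A: _expression_from_states(cfg, rng, states_a),
        CELL_B: _expression_from_states(cfg, rng, states_b),
    }
    expression = {
        cell: ExpressionTable(pd.Series(v, index=gene_ids))
        for cell, v in fpkm.items()
    }

    truth = GroundTruth(
        gene_ids=gene_ids,
        states={CELL_A: states_a, CELL_B: states_b},
        fpkm=fpkm,
        log_ratio=lr_a,
        log_ratio_b=lr_b,
        fields={CELL_A: field_a, CELL_B: field_b},
        p_peak=marg_peak_a,
        p_dip=marg_dip_a,
        transition_matrix=cfg.transition_matrix,
        stationary=cfg.stationary,
        driver_kmers=tuple(cfg.driver_kmers),
    )
    return SyntheticDataset(
        config=cfg, genome=genome, genes=genes, reads=reads,
        expression=expression, truth=truth,
    )


def truth_eval(outputs: dict, truth: GroundTruth) -> dict:
    """Score pipeline outputs against the ground truth.

    Recognized keys in ``outputs`` (all optional, all for cell A unless
    stated): ``gene_ids``; ``gamma`` (n x 334 posteriors); ``log_ratio``
    (estimated 4096-vector); ``transition_matrix``; ``expression_pred``
    (per-gene predicted log level); ``locus_classes`` (n x 334 labels).
    """
    from scipy import stats as sps
    from sklearn.metrics import roc_auc_score

    if "gene_ids" in outputs and list(outputs["gene_ids"]) != list(truth.gene_ids):
        raise ValueError("gene id mismatch between outputs and ground truth")
    report: dict[str, float] = {}
    states = truth.states[CELL_A]
    if "gamma" in outputs:
        gamma = np.asarray(outputs["gamma"], dtype=float)
        if gamma.shape != states.shape:
            raise ValueError("gamma shape does not match truth states")
        report["state_auc"] = float(
            roc_auc_score(states.ravel(), gamma.ravel())
        )
    if "log_ratio" in outputs:
        est = np.asarray(outputs["log_ratio"], dtype=float)
        report["spectrum_logratio_pearson"] = float(
            sps.pearsonr(est, truth.log_ratio)[0]
        )
    if "transition_matrix" in outputs:
        report["transition_max_abs_error"] = float(
            np.abs(np.asarray(outputs["transition_matrix"]) - truth.transition_matrix).max()
        )
    if "expression_pred" in outputs:
        pred = np.asarray(outputs["expression_pred"], dtype=float)
        true_level = np.log2(truth.fpkm[CELL_A] + 1.0)
        report["expression_spearman"] = float(sps.spearmanr(pred, true_level)[0])
        detected = truth.fpkm[CELL_A] > 1.0
        if detected.any() and not detected.all():
            report["expression_auc"] = float(roc_auc_score(detected, pred))
    if "locus_classes" in outputs:
        pred_cls = np.asarray(outputs["locus_classes"], dtype=object)
        true_cls = truth.locus_classes()
        if pred_cls.shape != true_cls.shape:
            raise ValueError("locus class shapes differ")
        for name, key in (
            ("typeA_specific", "recall_typeA_specific"),
            ("typeB_specific", "recall_typeB_specific"),
        ):
            sel = true_cls == name
            if sel.any():
                report[key] = float((pred_cls[sel] == name).mean())
    return report


def config_to_json(cfg: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        d = asdict(cfg)
        d["driver_kmers"] = list(d["driver_kmers"])
        json.dump(d, fh, indent=2)


def config_from_json(path) -> GeneratorConfig:
    with open(path) as fh:
        d = json.load(fh)
    d["driver_kmers"] = tuple(d["driver_kmers"])
    return GeneratorConfig(**d)
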