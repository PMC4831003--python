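"""End-to-end orchestration: coverage → spectrum → HMM → expression.

Glue over the analysis modules so the full inference chain (normalized
peak heights, weighted 6-mer spectrum, transition estimation,
forward-backward signatures, and the signature-based expression model)
can be run on any dataset that provides a genome, gene records, mapped
reads and an expression table — in particular on the synthetic
generator's output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import coverage_peaks, expression_models, hmm_signature, kmer_spectrum
from .region_io import ExpressionTable, GeneRecord, TssWindow, extract_tss_windows

PEAK_CALL_THRESHOLD = 0.5


@dataclass
class PipelineResult:
    windows: list[TssWindow]
    heights: np.ndarray                 # genes x 334 normalized peak heights
    enriched: np.ndarray                # genes x 334 segment enrichment flags
    spectrum: kmer_spectrum.KmerSpectrum
    model: hmm_signature.HmmModel
    gamma: np.ndarray                   # genes x 334 posteriors
    predictor: expression_models.ExpressionPredictor | None
    gene_ids: list[str]


def chip_segment_heights(
    genome: dict[str, str],
    windows: list[TssWindow],
    reads: list[tuple[str, int, int, str]],
    fragment_length: int = coverage_peaks.DEFAULT_READ_EXTENSION,
    min_reads: int = coverage_peaks.DEFAULT_MIN_READS,
) -> tuple[np.ndarray, np.ndarray]:
    """Extended-read pileup → normalized local peak heights per segment.

    Returns (heights, enriched) as genes x 334 arrays.
    """
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    by_chrom: dict[str, list] = {}
    for r in coverage_peaks.extend_reads(reads, length=fragment_length,
                                         chrom_sizes=chrom_sizes):
        by_chrom.setdefault(r[0], []).append(r)
    profiles: dict[str, coverage_peaks.PeakHeightProfile] = {}
    for chrom, size in chrom_sizes.items():
        track = coverage_peaks.pileup(by_chrom.get(chrom, []), (chrom, 0, size))
        profiles[chrom] = coverage_peaks.peak_height(track, min_reads=min_reads)
    heights = np.stack(
        [coverage_peaks.segment_heights(profiles[w.chrom], w) for w in windows]
    )
    enriched = np.stack(
        [coverage_peaks.segment_enriched(profiles[w.chrom], w) for w in windows]
    )
    return heights, enriched


def fit_signature_model(
    windows: list[TssWindow],
    heights: np.ndarray,
    pseudocount: float = 1.0,
    dip_source: str = "non_enriched_only",
    enriched: np.ndarray | None = None,
    peak_call_threshold: float = PEAK_CALL_THRESHOLD,
) -> hmm_signature.HmmModel:
    """Estimate emissions from weighted 6-mer counts and transitions from
    thresholded ChIP peak calls."""
    peak_counts, dip_counts = kmer_spectrum.count_weighted_kmers(
        windows, list(heights), dip_source=dip_source,
        enriched=list(enriched) if enriched is not None else None,
    )
    spectrum = kmer_spectrum.estimate_spectrum(
        peak_counts, dip_counts, pseudocount=pseudocount
    )
    calls = [np.asarray(h) > peak_call_threshold for h in heights]
    A, pi = hmm_signature.estimate_transitions(calls)
    return hmm_signature.HmmModel(pi=pi, A=A, spectrum=spectrum)


def run_pipeline(
    genome: dict[str, str],
    genes: list[GeneRecord],
    reads: list[tuple[str, int, int, str]],
    expression: ExpressionTable | None = None,
    seed: int = 0,
    fit_expression: bool = True,
) -> PipelineResult:
    """Run the full DNA → signature → expression inference chain."""
    windows = extract_tss_windows(genes, genome)
    heights, enriched = chip_segment_heights(genome, windows, reads)
    model = fit_signature_model(windows, heights, enriched=enriched)
    profiles = hmm_signature.posterior_batch(
        model, [w.segments for w in windows], gene_ids=[w.gene_id for w in windows]
    )
    gamma = np.stack([p.gamma for p in profiles])
    gene_ids = [w.gene_id for w in windows]
    predictor = None
    if fit_expression and expression is not None:
        y = expression.log_level.loc[gene_ids].to_numpy()
        detected = expression.detected.loc[gene_ids].to_numpy()
        ae = expression_models.fit_autoencoder(gamma, latent=2, seed=seed)
        predictor = expression_models.fit_expression_net(
            ae, gamma, y, detected=detected, seed=seed
        )
    return PipelineResult(
        windows=windows, heights=heights, enriched=enriched,
        spectrum=model.spectrum, model=model, gamma=gamma,
        predictor=predictor, gene_ids=gene_ids,
    )
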