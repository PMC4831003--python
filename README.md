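# seqsig

Infers cell-type-specific **H3K27ac sequence signatures** around
transcription start sites from primary DNA, and predicts gene
expression from them.

H3K27ac (acetylation of histone H3 lysine 27) marks active promoters
and enhancers. `seqsig` is built around the observation that the DNA
sequence immediately around a TSS carries enough information to infer
where this mark sits, cell type by cell type. It is aimed at
regulatory-genomics researchers who have a genome, gene annotations,
H3K27ac ChIP-seq, and RNA-seq for one or more cell types — or who want
a fully synthetic, ground-truthed test bed for this class of method.

## The model

Each gene contributes a 2,004-bp window centred on its TSS, tiled into
T = 334 non-overlapping 6-bp segments (oriented 5′→3′ along the gene).
A two-state hidden Markov chain runs over the segments with states
M (inside an H3K27ac peak) and d (depleted):

- **Emissions.** For each of the 4⁶ = 4,096 possible 6-mers *s*,
  p(s | M) and p(s | d) are estimated by probability-weighted counting:
  a segment whose normalized ChIP peak height is *h* ∈ [0, 1]
  contributes weight *h* to the peak spectrum and weight 1 − *h* to the
  dip spectrum. Peak heights come from extended-read pileups (reads
  extended to 150 bp from their 5′ ends), thresholded at ≥ 5 reads per
  base and normalized by the local maximum in the adjacent 2-kbp
  region. Normalizing peak frequencies by dip frequencies from the same
  TSS neighbourhoods cancels their GC-rich composition.
- **Transitions.** A[M→M] is the fraction of ChIP-called peak segments
  whose adjacent segment is also a peak — the cooperative persistence
  of acetylation; no EM is involved.
- **Decoding.** The forward-backward recursions (per-step scaled for
  T = 334) give the posterior γᵢ(M) = αᵢ(M)βᵢ(M) / Σₛ αᵢ(s)βᵢ(s) —
  the *sequence signature*: the probability, read from DNA alone, that
  segment *i* is acetylated. Signatures are banded very-high / high /
  medium / low at 0.9 / 0.5 / 0.1.

Downstream of the signature:

- a **fractional logistic model** P(expressed) = σ(β₀ + Σₖ βₖXₖ) maps
  measured peak heights in 200-bp windows around the TSS to expression
  (targets are log₂(FPKM+1) rescaled to [0, 1]);
- an **autoencoder-initialized network** (334 → 2 → 1, sigmoid hidden
  layer) maps the 334 signatures to log expression, its encoder
  warm-started from a 334 → 2 → 334 reconstruction autoencoder;
- **association screens** (MIC and Pearson, with permutation nulls)
  relate factor enrichment in 200-bp sliding windows to mRNA levels;
- a **cell-type comparison** classifies loci as common or
  cell-type-specific (probability > 0.5 in one type, < 0.1 in the
  other) and summarizes expression log₂ fold changes per class.

A first-class synthetic-data generator (`seqsig.synthetic_data`)
produces genomes, reads, and expression tables with planted ground
truth for every stage.

## Worked example

```python
import numpy as np
from sklearn.metrics import roc_auc_score
from seqsig import synthetic_data as sd, pipeline, kmer_spectrum as ks

cfg = sd.GeneratorConfig(n_genes=300, seed=1)
ds = sd.generate(cfg)
res = pipeline.run_pipeline(ds.genome, ds.genes, ds.reads["cellA"],
                            ds.expression["cellA"], seed=1)

print(ks.enrichment_report(res.spectrum, 5).to_string(index=False))
auc = roc_auc_score(ds.truth.states["cellA"].ravel(), res.gamma.ravel())
print(f"state-detection AUC: {auc:.3f}")
m = res.predictor.metrics
print(f"expression validation: Spearman rho = {m['spearman']:.2f}, AUC = {m['auc']:.2f}")
```

prints

```
  kmer   p_peak    p_dip     ratio
CTTGTC 0.007477 0.000484 15.452798
TAAAGC 0.006297 0.000470 13.407516
ATGCGC 0.008842 0.000669 13.219440
GCGCGT 0.010492 0.000840 12.496287
CGGTGT 0.007858 0.000669 11.748354
state-detection AUC: 0.983
expression validation: Spearman rho = 0.71, AUC = 0.97
```

The five top-ranked 6-mers are exactly the generator's planted driver
motifs; the AUC measures how well the DNA-decoded posteriors γ separate
planted peak segments from dip segments; the validation metrics compare
predicted and simulated expression on held-out genes.

The same steps are available as a command-line tool:

```bash
seqsig simulate --seed 3 --n-genes 300 --out data/
seqsig infer --fasta data/genome.fa --genes data/genes.bed \
             --reads data/reads_cellA.bed --out signatures.tsv
seqsig predict-expression --signatures signatures.tsv \
             --expression data/expression_cellA.tsv --seed 3 --out pred.tsv
seqsig compare --sig-a sigA.tsv --sig-b sigB.tsv \
             --expr-a data/expression_cellA.tsv --expr-b data/expression_cellB.tsv \
             --out calls.tsv
```

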