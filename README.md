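# polarity

Toolkit for analysing the **early transcriptome response of bacteria to
translation-inhibiting antibiotics**, where two posttranscriptional
mechanisms shape mRNA levels within minutes:

* **premature transcription termination (PTT)** — when ribosomes stall,
  transcription decouples from translation and Rho terminates elongating
  polymerases, so distal genes in operons lose signal in a 5′→3′ polar
  fashion;
* **mRNA stabilization** — stalled ribosomes shield transcripts from
  degradation, raising steady-state levels genome-wide.

The net effect is a characteristic polar expression pattern: genes at the
beginning of operons (and short monocistronic genes) go **up** roughly by
the stabilization factor, while genes deeper in operons go **down** once
termination dominates. `polarity` implements the full desk-scale analysis
used to detect and quantify this pattern, plus a synthetic-data generator
with planted ground truth so every stage is verifiable without sequencing
data.

## What it computes

| Stage | Module | Method |
|---|---|---|
| TSS calling | `polarity.tss` | sharp 5′-end peaks from paired TEX+/TEX− tracks; a peak must be high, sharp (step factor vs upstream background) and not diminished by terminator-exonuclease treatment |
| TSS classes | `polarity.tss` | gTSS (intergenic / operon start) vs iTSS (inside an upstream same-strand gene); genes linked to the highest TSS within 200 nt of the start codon |
| Differential expression | `polarity.de` | negative-binomial Wald test: median-of-ratios size factors, method-of-moments dispersion with shrinkage, Student-t reference, Benjamini–Hochberg; DEG = \|log₂FC\| > 1 and p_adj ≤ 0.01 |
| Positional analysis | `polarity.binning` | 25 × 100-nt bins anchored at each TSS, bin-level DE (p_adj ≤ 0.05), operon assignment and polarity summaries |
| Decay kinetics | `polarity.decay` | Pfaffl efficiency-corrected quantification against a spike-in, amounts anchored at 100 % at t = 0, half-life t½ = ln 2 / (−slope) from an OLS fit of ln A vs t, no-decay flagging, replicate reconciliation, stabilization fold t½(+Tc)/t½(−Tc) |
| Simulation | `polarity.simulate` | steady-state operon model L(x) ∝ k_ini · exp(−λ·max(0, x−d₀)) / (k_deg/s), TEX± peak tracks, NB counts, Cq decay series — all with emitted ground truth |

Coverage is read from bedGraph or wiggle, annotation from GFF3, counts
from TSV, Cq tables from CSV. Library-size normalization follows the
tnoar convention: divide by a library's total aligned reads, multiply by
the smallest total among the libraries being compared.

## Worked example

Simulate a rifampicin decay experiment for a transcript with a true
half-life of 77 s (three replicates, Cq noise 0.15 cycles), then fit it:

```
$ polarity simulate decay --gene metZ --t-half 77 --sigma 0.15 --reps 3 --seed 7 --out cq.csv
3 replicates x 6 timepoints -> cq.csv
$ polarity halflife --cq cq.csv --out halflife.tsv
1 gene/condition half-lives -> halflife.tsv
$ cat halflife.tsv
# polarity v0.1.0 cv_threshold=0.5
gene_id condition       half_life       needs_second_primer
metZ    -Tc     74 ± 2  False
```

The three replicate fits agree (74 ± 2 s against the planted 77 s), so
the mean ± sd is reported; had a replicate shown no decay or a wildly
different value, the raw list would be printed and the gene flagged for
re-measurement with a second primer pair.

Simulate 20 polar operons (termination hazard 0.002 nt⁻¹ beyond a 200-nt
protected prefix, 3× stabilization) and test for differential expression:

```
$ polarity simulate counts --n-operons 20 --seed 7 --out-dir sim
80 genes x 6 samples -> sim
$ polarity de --counts sim/counts.tsv --samples sim/samples.csv --out de.tsv
78 DEGs of 80 features -> de.tsv
$ grep ^op1_ de.tsv | cut -f1,3,7
op1_g1  2.709956298345065   True
op1_g2  1.2535288195027343  True
op1_g3  -1.2510045491848134 True
op1_g4  -3.6831074095331933 True
```

The polar signature is recovered: the promoter-proximal gene is up, and
log₂ fold change decreases monotonically with position in the operon.

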