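# Methods

## The steady-state operon model

The simulator and the positional analyses rest on one closed form. A
transcription unit initiates at its TSS at rate `k_ini` (initiations/s).
Elongation is protected over the first `d0` nucleotides (default 200 nt),
where transcription remains coupled to translation of the first cistron.
Beyond `d0`, under a translation inhibitor, polymerases terminate
prematurely with a constant per-nucleotide hazard `λ` (default 0.002
nt⁻¹ under treatment, 0 without), so the fraction of polymerases
reaching transcript offset `x` is `exp(-λ·max(0, x - d0))`. Transcripts
decay at rate `k_deg` (default 0.01 s⁻¹, a ~70 s half-life, typical of
fast-growing bacteria); treatment divides `k_deg` by a stabilization
factor `s` (default 3, consistent with the 3–5-fold stabilizations seen
for short bacterial mRNAs under tetracycline-class inhibitors). The
steady-state level at offset `x` is

    L(x) = k_ini · exp(-λ·max(0, x - d0)) / (k_deg / s)

A gene's expected level is the mean of `L` over its body; its true fold
change under treatment is therefore `s · ⟨exp(-λ·(x - d0))⟩`, which is
strictly decreasing in the gene's mean offset whenever `λ > 0` — the
polar pattern is literal in the generator, not an emergent statistic.
Optional internal TSSs add an independent `L`-shaped contribution
starting at their offset.

This is a deliberate simplification: no stochastic polymerase traffic,
no sequence-dependent termination (rut-site strength is folded into a
single hazard), no transcript-specific decay differences unless
specified, and stabilization is uniform rather than ribosome-density
dependent. It reproduces the phenomenology the analyses are built to
detect (proximal genes up ≈ `s`, distal genes down) while giving exact
per-gene oracles.

### Default study set

`polar_operon_set` generates 50 operons, each a short 300-nt first gene
(mirroring the enrichment of small genes among the strongest
responders), three 800-nt cistrons, 50-nt intergenic gaps, a 20-nt
leader, and log-normal (σ = 0.3) promoter-strength variation. With the
default hazard and stabilization, true log₂ fold changes run from
about +1.5 (first gene) to −4.8 (fourth gene).

### Noise layers

Noise enters in three places, kept orthogonal so each is testable alone:

* coverage: per-nucleotide Poisson around `depth · L(x)`;
* counts: gamma–Poisson (negative binomial) with dispersion `α`
  injected only at the count stage (default 0.01 for parameter-recovery
  studies, 0.05 for null-calibration studies);
* qPCR: additive Gaussian noise on the Cq scale (default σ = 0.15
  cycles, i.e. ~11 % multiplicative noise on amounts), independent for
  target and spike-in.

TEX± tracks place Poisson-height peaks on Poisson background (mean 1).
Genuine TSSs appear in the TEX-treated library at full height and
5-fold reduced without treatment; processed 5′-monophosphate ends —
which the exonuclease degrades — appear at full height in the untreated
library and 5-fold depleted in the treated one, so their TEX ratio sits
near 0.2 and the "not diminished" criterion excludes them.

What the generator does **not** emulate: mappability artifacts, strand
bleed-through, fragment-length effects, operon-internal promoter
regulation, condition-dependent processing, or dose–response (hazard
and stabilization are free parameters, not calibrated to an antibiotic
concentration). Passing tests show the estimators recover the model's
truth under these idealized noise models, not that they are robust to
every artifact of real libraries.

## TSS calling and classification

A position is called a TSS when, on library-size-normalized tracks,

1. TEX+ height ≥ `min_height` (default 10 normalized reads),
2. step factor = height / max(mean of the 5 nt immediately upstream,
   pseudocount 0.25) ≥ `min_step` (default 3) — the operational meaning
   of a "sharp" 5′ peak,
3. TEX+/TEX− height ratio ≥ `min_tex_ratio` (default 1.0, i.e. not
   diminished by exonuclease treatment; raise it to demand enrichment).

Within a merge window (default 3 nt) only the highest candidate is
kept. These are declared, transparent thresholds, not a reproduction of
any published predictor's scoring.

Classification is positional: a TSS inside the body of a same-strand
gene (strictly downstream of that gene's own start codon, so leaderless
starts stay gTSS) is an iTSS; everything else, including TSSs inside
antisense genes, is a gTSS. Gene–TSS linkage searches the window 0–200
nt upstream of the start codon (distance 0 = leaderless counts;
distance 201 does not), takes the highest peak, and breaks ties toward
the smaller distance. The gTSS/iTSS peak-ratio table searches up to 10
kb upstream for the strongest same-strand gTSS; the bound prevents
cross-operon matches on gene-dense genomes and is configurable.

## Differential expression

The count engine is intentionally small — the claims it supports are
about procedure shape and parameter recovery, not bit-compatibility
with a full RNA-seq framework:

* **size factors**: median-of-ratios over zero-free features, rescaled
  to geometric mean 1; falls back to a +0.5 pseudo-reference when no
  zero-free feature exists. Like all compositional normalizations it
  assumes most features are unchanged; on a matrix where everything
  shifts (e.g. an all-polar simulated gene set with no null background)
  fold changes are displaced by the median fold, which is why
  parameter-recovery tests embed planted effects in a null background.
* **dispersion**: per-feature method of moments on normalized counts,
  pooled within conditions so true fold changes do not inflate it,
  floored at 1e−8 and shrunk 20 % toward the across-feature mean.
* **test**: Wald statistic on log₂ of pseudocounted (+0.5) normalized
  group means, SE from the NB variance `m + αm²` by the delta method,
  referred to a Student t with `n − 2` degrees of freedom. The t
  reference is the natural small-sample correction at triplicate scale,
  where a normal reference is visibly anticonservative; it converges to
  the normal for large designs.
* **multiplicity**: Benjamini–Hochberg within the tested family only
  (all-zero features are excluded first); genes and bins are separate
  families. DEG calling is strict: |log₂FC| > 1 exclusive, p_adj ≤ 0.01
  for genes and ≤ 0.05 for bins, both configurable.

Omitted on purpose: outlier filtering, independent filtering, posterior
fold-change shrinkage, GLMs with covariates, multi-condition contrasts.
A cross-check test compares fold-change estimates against an
independent NB framework (pyDESeq2) on a planted matrix.

## Bins and operon summaries

Each TSS anchors 25 contiguous 100-nt bins running downstream along its
strand (2,500 nt, enough to cover any gene shorter than 2.5 kb); bins
running off the chromosome are truncated with a warning. Bin counts are
rounded depth sums divided by a configurable read length (default 1:
depth-sum pseudo-counts, the faithful desk-scale analogue of per-bin
read counting when only coverage is available). Bins overlapping
neighboring transcription units are counted — no masking — which is a
declared choice; an operon-aware masking pass could be added where
annotation quality supports it.

Operon assignment groups same-strand gene runs with intergenic gaps ≤
200 nt and no intervening gTSS, promoter-proximal gene first (index 1),
anchored to the strongest gTSS within the −200 window of the first
gene. This is an approximation used for summaries and simulations;
curated operon tables should take precedence when available.

## Decay kinetics

Amounts are computed by efficiency-corrected relative quantification
against the spike-in:

    A(t) = E_t^(Cq_t(0) − Cq_t(t)) / E_s^(Cq_s(0) − Cq_s(t)) × 100

so t = 0 is 100 % by construction and uniform spike-in drift cancels.
Primer efficiencies live in (1, 2] and default to 2.0 (perfect
doubling) with a warning when a table omits them.

The half-life comes from OLS on ln A vs t over all timepoints
(default grid 0, 60, 120, 240, 360, 480 s). The intercept is free:
A(0) = 100 is a fitted point, not a constraint, which keeps the fit
robust to t = 0 noise. Non-positive amounts (Cq underflow) are dropped
with a warning; at least three points are required. **No decay** is
declared when the slope is ≥ 0 or not significantly negative (one-sided
p > 0.05) — a reproducible stand-in for the judgment call usually made
by eye on the linear-log plot. On noiseless exponentials the estimator
is exact to numerical precision for any half-life.

Replicates are reconciled in the style of a published half-life table:
mean ± sd when all replicates decay and their CV ≤ 0.5 (the declared
operationalization of "very different"); otherwise the raw replicate
list is reported verbatim (no-decay entries as "n.dc.") and the gene is
flagged for re-measurement with an independent primer pair. The
stabilization fold is the ratio of treated to untreated half-lives,
undefined (and flagged) when either side shows no decay.

## Numerical and design notes

* Internal coordinates are 1-based inclusive everywhere; bedGraph's
  0-based half-open convention is converted exactly once at file
  boundaries. On the minus strand "upstream" means larger coordinates,
  and all window logic is strand-symmetric.
* Library sizes are supplied (sample sheet / track metadata), never
  inferred from coverage mass.
* All randomness flows through `numpy.random.default_rng(seed)`; a
  fixed seed gives bit-identical outputs.
* Readers reject malformed input (naming the line or cell) rather than
  repairing it silently.
* Problem sizes in the test suite (e.g. 50 operons × 3+3 replicates,
  100 random TSS layouts, 100-seed decay recoveries) were chosen as the
  smallest sets at which the binomial error of the measured proportions
  is well below the margins being asserted.

## Known limitations

* The NB engine's t-reference Wald test is slightly conservative at
  n = 3; exact small-sample calibration would need permutation or
  likelihood-ratio machinery out of scope here.
* `assign_operons` cannot see internal promoters that fire only under
  some conditions; polarity summaries on real data are only as good as
  the TSS set they are given.
* The decay estimator assumes single-exponential decay; biphasic decay
  (e.g. processing intermediates) will fit poorly and should be caught
  by the r² column.
* The simulator's uniform stabilization and constant hazard make the
  polar pattern cleaner than real operons, where rut-site placement and
  ribosome occupancy vary along the transcript.
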