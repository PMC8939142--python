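# Methods

## Coordinate model and interval algebra

All genomic coordinates are 0-based, half-open (BED convention); 1-based
inputs (GTF) are converted at the I/O boundary. A DSB is a single base
`[p, p+1)`. Region sets are canonical: merged, sorted, pairwise-disjoint,
with abutting intervals coalesced, so `total_bp` is exact and membership
queries are binary searches. Overlap counting, extension, subtraction and
union are implemented directly on sorted integer arrays and are tested
against brute-force all-pairs / per-base oracles on every operation.

Window semantics: "an 8-nt window centred on a break" is a *total-width*
window `[p − w/2, p + w/2)`, i.e. 4 bases on each side of the half-open
point. The symmetric-distance reading (`|q − p| ≤ w/2`, width `w + 1`) is
available via `extend_breaks(..., symmetric=True)` but is off by default,
so printed widths are preserved exactly. Windows are clamped at 0 and,
when chromosome lengths are known, at the chromosome end.

Duplicate break records at one (chrom, pos) are retained by default;
deduplication is an explicit toggle (`BreakSet.deduplicate()`), since
whether recurrent breakage at a base should count once is a property of
the upstream caller, not of this analysis.

## Feature classes

- **Promoters**: TSS ± `flank_bp` (default 2,000) of genes whose
  expression in the reference sample is ≥ the threshold (default
  FPKM ≥ 1 — a conventional "expressed" cutoff; the definition itself
  does not prescribe one), merged.
- **Enhancers**: scored H3K27ac peaks lying *entirely* more than
  `min_tss_distance_bp` (2,000) from every TSS — distance measured from
  the nearest peak edge to the TSS point, strictly greater-than — then
  the top `top_n` (default 25,000) by descending score, ties broken by
  (chrom, start) for determinism. Filtering precedes ranking so the
  output is the set of top *distal* peaks, the most literal reading of
  the definition.
- **Insulators**: CTCF peaks with zero base overlap against promoters and
  enhancers (half-open: an abutting peak shares no base and is retained),
  then top `top_n` (default 50,000).
- **ARE partition**: a promoter/enhancer interval is ARE⁺ iff it contains
  the *start* coordinate of ≥ 1 motif hit. Deciding membership by the hit
  start makes the partition exact even for hits straddling a region
  boundary: ARE⁺ and ARE⁻ are disjoint and their `total_bp` sums to the
  parent's exactly, which the four-set density comparison relies on.

## Motif scanning

Log-odds scores are `log2(((n_b + pc·bg_b)/(N + pc)) / bg_b)` per column,
with pseudocount 0.8 split by background and a uniform background by
default. Scans run on both strands (minus-strand hits are scored on the
reverse-complemented matrix and reported in forward coordinates); windows
containing N are unscoreable and skipped; regions shorter than the motif
are skipped and counted. The reporting threshold is a fraction of the
achievable score range, `min + f·(max − min)`; `f = 1.0` reports
consensus-exact matches only and is the pipeline default on synthetic
data, where the generator embeds the exact consensus. Comparisons allow a
1e-9 absolute tolerance so a threshold set to the exact maximum is not
defeated by floating-point summation order. Overlapping hits are all
reported; deduplication is left to callers.

The shipped ARE matrix (`synthetic_are_pfm`) is a **synthetic stand-in**
built around the canonical 15-bp ARE consensus AGAACA-nnn-TGTTCT: strong
counts at the half-sites, softer but uniquely-argmaxed counts at the
spacer. It matches the length and shape of the curated ARE profile but is
not the measured matrix; real scans should supply the curated PFM file.

## Enrichment statistics

- `sample_overlap_fraction(query, target, w)`: fraction of query breaks
  whose centred window contains ≥ 1 target break; monotonically
  non-decreasing in `w` (a property test, mirroring the qualitative
  behaviour expected of two related break maps).
- `break_density`: exact integers (count, total_bp) retained; density is
  their quotient per kb, invariant to splitting regions into abutting
  pieces.
- Profiles: strand-oriented bins around TSSs (upstream negative),
  unstranded around site midpoints. A break within range of two anchors
  counts once per anchor in the bins (metagene convention) but once total
  in `per_100kb`, which counts over the *merged* union of windows —
  both are reported because the two conventions answer different
  questions (shape vs regional rate).
- `motif_proximity`: a break at `p` counts if some hit `[s, e)` has
  gap ≤ `d`, i.e. `s − d ≤ p < e + d`; implemented by widening and
  merging hits, then point-membership counting.
- Enrichment ratios are reported alongside raw densities with no attached
  significance test, as is conventional for these descriptive panels.

## Signature scoring

log2(x+1), per-gene z-score across samples (sample standard deviation,
ddof = 1), score = per-sample mean of z over the signature set. Genes with
zero variance are dropped and counted rather than set to z = 0, to avoid
diluting scores with non-informative rows. Scores are invariant to any
per-gene affine transform of raw expression. Pearson correlation uses
scipy; FDR control uses the Benjamini–Hochberg step-up (statsmodels),
verified against the literal step-up definition on exhaustive small
p-vector grids.

Quartile dichotomisation uses linear-interpolation quantiles; a sample is
"high" iff strictly above Q3 and "low" iff strictly below Q1 (for 101
distinct values this yields exactly 25/25). With heavy ties the extreme
groups can be empty, which is reported as an error rather than resolved
by jitter. Signature gene lists are user-supplied files; the synthetic
pipeline ships stand-in lists drawn from its own gene universe.

## qPCR model

`Ct = intercept + slope·log10(copies)`, least squares on the dilution
series (scipy linregress), technical replicates averaged on the Ct scale
before fitting. Efficiency `E = 10^(−1/slope) − 1`; a fitted curve must
have negative slope, and efficiencies outside (0.8, 1.1] trigger a
warning but not an error. Inversion is `copies = 10^((Ct − b)/m)` divided
by cells per reaction (a user input — no universal per-cell constant
exists). ΔΔCt relative quantification (`fold = 2^(−ΔΔCt)`) is provided as
a helper for normaliser-gene workflows.

## Synthetic study conditions

Defaults (the conditions the tests and the acceptance script run under):

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 5 Mb | desk-scale; runs in seconds |
| n_genes | 500 | non-overlapping bodies of 2–20 kb, gaps multinomial |
| expression | lognormal(μ=1, σ=1.5), 20 samples | FPKM-like; ~75% of genes pass FPKM ≥ 1 |
| frac_are_promoters | 0.3 | promoters given an embedded ARE consensus |
| frac_are_enhancer_peaks | 0.3 | TSS-distal peaks given an embedded ARE |
| background_rate λ | 0.01 /bp | ~100,000 breaks over 10 Mb |
| ρ_TSS | 10 | rate multiplier in TSS ± 200 bp of the top 100 expressed genes |
| ρ_ARE | 2 | rate multiplier inside ARE⁺ promoters |
| qPCR | E = 0.95, intercept 36, σ_Ct = 0.1 per reading, 8 ten-fold points in technical triplicate | sample Cts averaged over 3 experiments × 3 replicates |
| stoichiometry truth | 2,100 lncRNA and 1,000 miR copies/cell, 100 cells/reaction, 2 sites/molecule, 80% silencing, 650 turnover | all four unknowns interpolate inside the dilution range |

Breaks are drawn exactly from the piecewise-constant inhomogeneous
Poisson process: per constant-rate segment, a Poisson count then uniform
placement. Enrichment factors multiply where regions overlap
(TSS window inside an ARE⁺ promoter gets λ·ρ_TSS·ρ_ARE). ARE placement is
independent of expression rank, so in expectation the ARE factor cancels
from the top-vs-rest TSS ratio and the TSS factor cancels from the
ARE⁺/ARE⁻ ratio; the recovery estimators are therefore
`per_100kb(top-q TSSs) / per_100kb(remaining TSSs) → ρ_TSS` and
`density(ARE⁺ promoters) / density(ARE⁻ promoters) → ρ_ARE`. Dividing by
*all* genes instead of the complement would measure the mixture ratio,
not the injected parameter. Merged promoters spanning one ARE⁺ and one
ARE⁻ gene dilute the measured ARE ratio slightly downward; at the default
gene density this bias is a few percent, well inside the 20% recovery
band the tests assert. Null configurations (ρ = 1) are checked against 1
within 4 standard errors of the log-ratio (delta method on the two
Poisson counts).

What the generator does **not** emulate: chromatin context and mappability
structure, sequence-composition biases of break calling, correlated
replicate structure, transcript-level annotation complexity, batch
effects in expression, and inter-assay qPCR efficiency differences.
Passing recovery tests therefore demonstrates the estimators are
consistent for the stated sampling model — not that real break maps obey
it.

## Numerical and degenerate-input conventions

Empty query break sets make overlap/proximity fractions undefined
(errors, not zeros); empty region sets give density errors but a
fraction-in-regions of 0 when breaks exist. Score ties in peak ranking
are broken by (chrom, start). Random draws all flow through a single
`numpy.random.default_rng` stream per run in a fixed call order, so a
config plus seed reproduces outputs byte-identically across platforms;
the pipeline's manifest records config hash and input checksums but no
timestamps for the same reason.

## Scale choices

Tests and the acceptance script use the default 10 Mb / ~10⁵-break
conditions for recovery checks and a 600 kb / 40-gene configuration for
end-to-end pipeline checks — sizes chosen so each estimator's sampling
error is a few percent, comfortably inside the asserted bands, while the
whole suite completes in seconds.
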