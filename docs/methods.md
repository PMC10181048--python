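# Methods

## Model and assumptions

The Selection Index of Ideal Genotype is an ideal-point (TOPSIS-family)
multi-criteria score applied to a genotype × trait table of plot or
entry means. It assumes:

- traits are measured without missing cells (the matrix is complete);
- each trait has a declared orientation — benefit (larger is better) or
  cost (smaller is better) — chosen by the breeder, not inferred from
  the data;
- the relevant "ideal" is the best value *observed in the trial*, not an
  external target: the ideal profile is assembled per trait from the
  directed extrema of the normalized columns. The index is therefore
  relative to the entry set; adding or removing genotypes can move every
  score.

Columns are normalized by their root-sum-of-squares, which makes every
column unit-norm. Two consequences matter in practice: the index is
invariant to positive rescaling of any trait (days, cm, g and kg/ha are
commensurable after normalization), and because all raw trait values here
are positive, normalized values are positive, both distances are bounded,
and the closeness coefficient lands in [0, 1]. The square root in the
normalizer is essential for both properties; a plain sum of squares in
the denominator would destroy scale invariance and deflate all scores
for long columns.

No trait weights are used. Equal implicit weighting is a design feature
of the index — it is aimed at early-generation screening where economic
weights are unavailable — but it also means a trait with small relative
spread contributes little, and a redundant pair of correlated traits
effectively counts twice. Users who need weighting should pre-scale
columns deliberately or use a weighted MCDM method; this package does
not offer a weight parameter.

## Parameters and defaults

- **Trait directions** (`DirectionSpec`): required for every trait in
  the matrix; extra declarations warn rather than fail. The bundled
  `warm-barley` preset encodes selection for warm, short-season
  environments: DHE cost, DMA cost (early maturity escapes terminal
  heat/drought), PLH cost (lodging avoidance under irrigation), GFP
  benefit (a longer grain fill protects kernel weight), TKW and YLD
  benefit. Presets live in `siig/data/presets.yaml`.
- **Group breakpoints** (`GroupScheme`, default 0.70/0.60/0.50/0.40):
  lower-closed bins on the SIIG scale; a score equal to a breakpoint
  belongs to the higher class, so SIIG = 0.70 is group 1 and the
  "superior" selection SIIG ≥ 0.60 is exactly groups 1–2.
- **Rank ties** (`rank_method`): `ordinal` (default) breaks ties by
  input order so ranks are a permutation of 1..n, matching how trial
  tables print distinct ranks; `average` assigns mid-ranks and is the
  right choice when ranks feed a correlation.
- **Display precision**: 3 decimals by default for scores and distances,
  the customary precision in published SIIG tables; full precision is
  kept internally.

## Numerical choices and degenerate inputs

- All accumulation is in double precision; column norms use ordinary
  summation (trial sizes are at most thousands of rows, far below where
  compensated summation would matter).
- An all-zero trait column has no norm and is rejected by name.
- If every genotype is identical on every trait, d⁺ + d⁻ = 0 and the
  score is defined as 0.5 with a warning — the genotype is simultaneously
  ideal and non-ideal, and inventing an ordering would be arbitrary.
- Negative trait values are accepted with a warning: the algebra is
  well-defined but the [0, 1] bound and the meaning of "ideal" rest on
  positive columns.
- Correlation p-values use the exact t transform
  t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom, two-sided, with
  two-tier stars (* p<0.05, ** p<0.01) and no multiple-testing
  correction — the convention of agronomic correlation heat maps.

## Bundled trial tables

Two tables from a four-location warm-region barley trial (111 entries)
ship as package data and are checksum-verified on load. `table3` holds
per-environment grain yield, SIIG and rank; `table4` holds
across-environment trait means with the published SIIG and ranks. Two
printed-table artifacts are preserved as printed and validated only up
to rounding:

- GFP equals DMA − DHE only to ±1 day, because each trait mean averages
  a different subset of environments and is rounded independently;
- the printed rank columns are consistent with descending SIIG but their
  tie-breaks are not reproducible, so validation checks monotonicity
  rather than exact rank equality.

Recomputing SIIG from the printed (rounded) trait means reproduces the
published ordering to Spearman ρ ≈ 0.999 and the published top score to
about ±0.006 (0.720 vs 0.726 for the leading genotype); exact equality
is unattainable from rounded inputs, and tolerances in the tests reflect
that.

## Synthetic data

`simulate_traits` draws genotypes from a multivariate normal with
user-specified per-trait means and standard deviations and an inter-trait
correlation matrix (symmetric PSD with unit diagonal, enforced; an
eigendecomposition factor handles exactly singular matrices). The
`barley_like_config` preset uses the trial's grand means (DHE 101.8 d,
DMA 135.7 d, GFP 32.5 d, PLH 84.6 cm, TKW 38.4 g, YLD 3750 kg/ha),
spreads comparable to the observed genotype means, and a correlation
pattern in which heading and maturity are tightly coupled (0.70), the
grain-filling period runs against heading (−0.40) and with maturity
(0.35), and yield ties positively to grain fill (0.35) and kernel weight
(0.25).

The optional planted winner overwrites the first genotype with the
directed extremum of every trait pushed 3 sd further, which guarantees
strict dominance and hence SIIG = 1 at rank 1; recovering it exercises
the full chain with a known answer. What the simulator deliberately does
**not** model: genotype × environment interaction, non-Gaussian trait
distributions, integer day counts (a `round_days` flag restores them;
SIIG itself is scale-free so the default leaves values continuous), and
any REML-recoverable variance structure. Passing simulation tests
therefore demonstrates correctness of the scoring chain, not robustness
to the messiness of real multi-environment data.

## Design choices where the design was open

- **Bin notation**: published SIIG class tables are written with
  internally inconsistent interval notation; this package reads them as
  lower-closed bins with the top bin closed at 1.00, matching the prose
  definition of group 1 as SIIG ≥ 0.70.
- **Empty classes** are reported with count 0 and absent means rather
  than renumbered; `drop_empty` restores display parity with tables
  that omit them.
- **Genotype IDs are strings** even when tables print integers, so named
  check cultivars mix freely with numbered entries.
- **Input means**: the recomputation treats the bundled trait-mean table
  as given; whether the original scores were computed from raw location
  means or BLUP-adjusted means is not recoverable from the printed
  tables, and the rank-correlation tolerance absorbs the difference.

## Problem sizes in the test and acceptance runs

Fixture computations use the full 111-genotype tables. Property suites
run on randomly drawn matrices up to 12 × 6 (50 configurations) plus an
exhaustive small-matrix sweep up to 4 × 3 against a pure-Python loop
reference; planted-winner recovery uses 100 simulated trials of 5–120
genotypes; simulator moment-recovery checks use 10,000 genotypes. The
whole suite completes in a few seconds.

## Known limitations

- The index is trial-relative: scores are not comparable across trials
  with different entry sets.
- Equal implicit weighting; correlated traits double-count.
- The per-environment class means of the original trial are not
  recomputable from published data (the per-environment trait tables
  were never released), so only the mean-of-environments grouping is
  validated end to end.
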