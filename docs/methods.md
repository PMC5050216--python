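# Methods

## Design coding

Samples are stratified by an age cutoff (default 64 years: age > 64 is
Older, age ≤ 64 is Younger, so a 64-year-old is Younger) and by binary sex,
giving the coded cells A⁻B⁻ (Younger Men), A⁻B⁺ (Younger Women), A⁺B⁻
(Older Men), A⁺B⁺ (Older Women) with i, j ∈ {−1, +1}. Sex labels are
accepted case-insensitively from {male, female, m, f}; anything else is an
error, because the design is strictly binary.

## Factorial statistics

Every statistic is computed per probe on the log2 scale; probe-set
summarization is deliberately absent (its assumptions — uniform probe
efficiency, one transcript per probe set, no cross-hybridization — fail
often enough that collapsing probes discards real signal), so gene symbols
attach to probes only when reporting.

* Cell medians use the standard even-size convention (mean of the two
  central order statistics).
* The interaction effect is the half-contrast of cell medians
  ½[(M₊₊ + M₋₋) − (M₊₋ + M₋₊)]. Note that on a balanced design the OLS
  interaction coefficient γ of the bi-linear model is the *quarter*
  contrast of cell means; the half-contrast of medians and the fitted γ are
  related but distinct quantities, and both are reported side by side in
  the effect table rather than reconciled into one number.
* The super-ratio is computed from log2-scale medians, consistent with the
  explicit log2 in the pure-effect ratios; its two algebraic routes (ratio
  of age-ratios and ratio of sex-ratios) agree to machine precision and the
  identity is asserted in the tests at 1e-12 relative error.
* Ratio guard: a probe enters the ratio statistics only if every median
  involved exceeds `MIN_RATIO_MEDIAN` = 1.0 log2 unit. A median at the
  detection floor makes the ratio denominator numerically meaningless (a
  probe with median 0.2 can show a Super-Ratio\* of 10⁷ that carries no
  biology); on RMA-scale data expressed probes sit well above 1, and the
  guard excludes < 0.1% of default synthetic probes. Guarded probes are
  flagged and reported, never silently dropped, and remain in the
  interaction-effect and OLS statistics, which need no positivity.

## Null deconvolution and block FDR

Each factor's score distribution (interaction effect; Age Ratio#;
Sex Ratio#) is deconvolved separately: Freedman–Diaconis histogram, mode
located on a 3-bin moving average, fit window = contiguous bins with
smoothed count ≥ 50% of the modal count widened symmetrically to at least
20 bins, least-squares Gaussian A·exp(−(x−μ₀)²/2σ₀²) on the raw counts in
the window, one refit after re-centering the window on the fitted mean.
All knobs (bin rule fallback, half-maximum fraction, bin floor, smoothing
width) are function parameters. If the fit fails, μ₀ = median and
σ₀ = 1.4826·MAD are used and flagged. σ₀ is capped at the sample SD:
deconvolution narrows the null, never widens it.

Tail calling evaluates, at every observed score t beyond μ₀,
FDR(t) = n·Φ̄((t−μ₀)/σ₀) / #{observed beyond t} (mirrored for the lower
tail) and takes the least extreme t with FDR ≤ target; comparison at the
threshold is inclusive, so ties are all called. The two tails are searched
independently — up/down call counts are allowed to be asymmetric. The FDR
is a *block* property of the whole call class, not a per-probe q-value.
When no threshold qualifies the class is empty and the minimum FDR achieved
is reported.

The Super-Ratio\* significance thresholds are induced, per tail, as the
least extreme Super-Ratio\* among interaction-called probes; the
interaction effect (not SR\*) decides significance, SR\* serves
interpretation.

On pure-null Gaussian scores the realized false-call fraction — defined as
called probes over total probes, the only fraction that is well defined
when every call is false — averages far below the nominal target (the
threshold search needs an extreme score whose local exceedance beats the
target, which pure noise rarely provides). For ratio-based scores on data
with heterogeneous baselines the null is a scale mixture, slightly heavier
tailed than the fitted Gaussian; the tests therefore bound false calls on
truly null probes at 0.5% of the cohort rather than exactly at the block
FDR.

### Cross-factor leakage

A probe carrying a pure interaction effect genuinely shifts the pooled
age/sex medians when the design is unbalanced (15 Older Men vs 14 Older
Women: the pooled older median of a bimodal probe sits off-center), so
affected probes may appear under more than one factor. This is a property
of pooled ratio statistics, not a caller defect; classes are therefore
judged per factor-and-sign on the truly affected probes, and the
intersection QC (below) quantifies the within-factor analogue.

### Incidence QC

Because genes have multiple probes, a gene can appear in both tails of one
factor. The incidence ratio |genes(up) ∩ genes(down)| / |genes(up) ∪
genes(down)| (as %) is compared against the class-size-weighted mean block
FDR; an incidence clearly above the weighted FDR indicates real multi-probe
discordance rather than false positives. On default synthetic data with 5%
discordant probe signs the incidence is ~10–14% against a weighted FDR of
~4.8%, reproducing the direction of that argument.

## Networks

The nucleus is the interactome subgraph induced on called genes (isolated
called genes kept; genes absent from the interactome reported).
Augmentation adds any non-called interactome node with ≥ `min_links`
(default 2) distinct measured neighbors, plus its edges to measured nodes;
added nodes are flagged, the added fraction is reported but not enforced,
and the rule is idempotent. `min_links` = 2 is the weakest evidence that
still interconnects modules through a shared neighbor; 1 would promote
every pendant neighbor. The SCC stage takes the largest strongly connected
component with pp edges counted in both directions (largest connected
component for a purely undirected graph), ties broken toward the component
containing the lexicographically smallest symbol. An optional undirected
k-core filter (off by default) provides a labeled density reduction; it is
not a path-motif analysis. Node identity is the upper-cased,
whitespace-stripped symbol.

## Enrichment

Per-term p is the exact hypergeometric upper tail P[X ≥ overlap] with the
term intersected against the declared universe; correction across tested
terms is Benjamini–Hochberg by default (Bonferroni and none available,
since the aggregation that follows is method-agnostic). Subgroup summaries
are weighted arithmetic means of corrected p-values; the default weight is
the number of query genes annotated to the term — the most literal reading
of weighting by how frequently an ontology class appeared in the analysis —
with a uniform mode for sensitivity checks (when every member term has zero
overlap the frequency weights degenerate and uniform weights are used).
The fold-frequency ratio of two aggregated probabilities (max/min, with an
orientation flag toward the smaller = more frequent one) reproduces the
arithmetic of comparing a process between two conditions; whether such a
ratio *is* an event-frequency ratio is an interpretation this package does
not take a position on — only the arithmetic is implemented and tested.

## Synthetic data

The generator emulates a log2-scale (RMA-like) probe × sample matrix over
the 2×2 design with group sizes (9, 9, 15, 14) by default. Per probe:
baseline ~ N(7, 1.5²) log2 units, i.i.d. noise SD 0.5, and for affected
probes a single coefficient on the ±1-coded axis of its factor, magnitude
|N(2, 0.25²)| log2 units — four times the noise SD, a clearly detectable
spike-in. Defaults: 20 000 probes over 12 000 genes (1–4 probes each), 5%
of probes per factor, up:down asymmetry 1.75:1 for age (Older-up), 2:1 for
sex (Women-up), interaction symmetric. Factor assignment happens at the
gene level so a gene's probes share a factor; each affected probe flips
sign with probability 0.05 (`p_discordant`), which is what exercises the
incidence QC. Class fractions therefore match the configured fractions in
expectation over genes; the exact realized per-class counts are recorded at
generation time. Intensities are clipped positive; ages are drawn uniformly
inside each stratum.

What the generator does **not** emulate: probe-sequence effects and
cross-hybridization, correlated noise across probes of one array,
intensity-dependent variance, batch structure, and any real annotation or
interactome topology (the interactome is typed Erdős–Rényi; gene sets are
random subsets). Passing tests demonstrate the estimators and the caller
behave correctly under the assumed additive-Gaussian model with
heavy-tailed contamination — they do not certify performance on real array
data.

## Problem sizes and numerical choices

The test suite and the acceptance script use the generator's default sizes
(20 000 probes, 47 samples) for the headline checks, 50 000 draws for the
mixture deconvolution, 20 replicates of 20 000 for FDR calibration, and
reduced cohorts (2 000–6 000 probes) for plumbing tests; these sizes give
stable statistics in seconds. Oracle comparisons (medians, OLS, SCC,
hypergeometric) are exact or at 1e-10–1e-12 tolerances; Monte-Carlo bounds
use fixed seeds throughout. Degenerate inputs (zero-variance scores, < 100
scores, empty design cells, rank-deficient designs, non-positive
probabilities) raise errors rather than degrade silently.

## Known limitations

* The deconvolution window/fit protocol is this package's reconstruction of
  the Q-GDEMAR idea; the original procedure is specified elsewhere and
  equivalence is not claimed.
* Block FDR is exact only under the fitted Gaussian null; scale-mixture
  nulls (ratio scores with heterogeneous baselines) inflate realized false
  calls somewhat, as documented above.
* No moderated variance modeling, no covariates beyond the 2×2 design, no
  permutation FDR, no real ontology/interactome data shipped.
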