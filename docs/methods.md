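# Methods

This note documents the models implemented in `gscpipe`, their
assumptions, the defaults that matter, what the synthetic data does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Fold-change track construction (`tracks`)

Reads are counted per 500 bp non-overlapping bin (a read overlapping two
bins is counted in both — interval-overlap semantics).  For a ChIP/Input
pair, bins with zero reads in either sample are discarded from both; no
pseudocounts are used anywhere, since the zero-discard rule makes them
unnecessary.  The fold-change FC = ChIP/Input of each retained bin is
divided by the sample's median FC and log10-transformed.  Because the
median is scale-equivariant, the transform is exactly invariant to
rescaling either sample's counts, and the median of 10^value is exactly 1
by construction.

For a single ChIP/Input pair the median normalization divides by that
pair's own median FC; when several ChIP samples share a bin grid,
`median_of_ratios_factors` provides DESeq-style size factors (median of
each sample's ratios to the per-bin geometric mean).  Whether ChIP and
Input should instead be normalized jointly is not determinable from the
procedure's description; the per-pair choice is the default and the
multi-sample helper is provided separately.

Coordinates are 0-based half-open everywhere (BED convention), including
bedGraph I/O.  Two euchromatin-limit presets are stored: arm bounds at
fine scale, and bounds rounded to the 250 kb grid for coarse profiling.

## Three-state Gaussian HMM (`hmm_segment`)

The model assumes the log10 normalized fold-change of each bin is emitted
by one of three Gaussian states (depleted, no-difference, enriched) whose
means are strictly ordered; this ordering is an invariant of the
parameter type, so state identities can never silently swap.

*Initialization.*  "Semi-informed" is realized as: uniform initial and
transition probabilities; emission means at the 10th/50th/90th
percentiles of the observed signal; a single shared emission SD equal to
the overall SD (floored at 1e-3).  This is parameter-free and guarantees
the ordering on any non-degenerate signal; an all-constant signal is
nudged apart by 1e-3 with a warning.

*Decoding.*  Viterbi in log space, with chromosomes as independent
chains (the chain re-enters the initial distribution at every chromosome
boundary; no transition across a chromosome end is meaningful).  Ties
break toward the lowest state index, making decoding deterministic.

*Training.*  Viterbi training (segmental k-means): decode, then
re-estimate initial probabilities from path starts, transitions from path
bigram frequencies, and per-state emission mean/SD from the bins assigned
to each state; repeat until the path log-likelihood changes by less than
`tol` (default 1e-6 log units) or the path stops changing, capped at
`max_iter` = 1000.  The path log-likelihood is non-decreasing across
iterations (segmental k-means monotonicity) and this is asserted in the
tests on every run.  Degenerate updates are handled without division by
zero: a state with no assigned bins is re-seeded to its extreme quantile
with the global SD; per-state SDs are floored at 1e-4; means that
collapse are nudged apart by 1e-6 and states are re-sorted by mean if
training reorders them.  Initial probabilities are re-estimated along
with everything else; with few chromosomes they are supported by few path
starts, which is accepted rather than smoothed.

*Domains.*  Maximal runs of same-state retained bins merge into
intervals; a discarded bin interrupts coordinate adjacency and therefore
splits a run.  Re-labelling bins from the domain set inverts the
construction exactly.

Correctness is established against an independent brute-force oracle
that enumerates all 3^n paths and scores them by direct summation; the
decoder must match it on a thousand random instances of up to 10 bins.
Full Baum–Welch (posterior/EM) training is deliberately out of scope.

## Coarse heterochromatin profiling (`het_profile`)

Default bin width 250 kb.  Background elimination is subtractive —
value = max(0, CPM_chip − CPM_input) — rather than divisive, because
subtraction preserves the additive bin arithmetic that the subsequent
between-stage euchromatin normalization relies on; a ratio mode is
available via `mode="ratio"` and the choice is recorded in the call.
Cross-stage normalization divides each stage by the arithmetic mean
(median available) of its bins lying *fully* inside the euchromatin
limits; straddling bins are conservatively excluded from the
denominator.  The operation is idempotent.  Repeat enrichment divides the
depth-scaled, background-eliminated per-repeat signal by the same
quantity in the reference stage; zero-reference repeats are flagged
missing, never reported as infinite.

## Transposition screen simulation (`lineage_sim`)

Assumptions: stem cells contribute progeny equally (uniform multinomial)
— the 5–10 % per-stem-cell cluster arithmetic assumes this; insertions
are independent, never revert, and copy to both daughters at every
division (replicative vs pre-replication insertion is not distinguished,
as only heritability matters for cluster counting); the default lineage
is the illustrative one (two cyst divisions, one meiotic division, eight
sperm), with two meiotic divisions available for realistic
spermatogenesis.  Replication-timing insertion preference is represented
only through the per-stage rate dials, not mechanistically.

The stage rate for `gsc` is interpreted as the probability that a stem
cell carries the insertion throughout the sampled period (the
per-stem-cell cluster arithmetic assumes a mutant stem cell contributes
all along); per-cycle acquisition within the stem-cell stage is not
modelled.  Per-male sperm pools are sized to ~1.5× the expected demand
(progeny / survival), and each male uses an independent child RNG stream,
so one male's draws never shift another's.

Sperm survival is applied by comparing pre-drawn uniforms against the
survival probability.  Under a fixed seed, lowering survival therefore
only removes carriers of any insertion event; this monotonicity is exact
on the per-event surviving-carrier counts (reported as
`surviving_carriers`) and is tested there.  After survivors are
subsampled to the fixed progeny count, the *observed* cluster sizes are
not deterministically monotone in survival (the subsample is a different
random set), which is why the invariant is stated before subsampling.

Detection efficiency (enhancer trapping and insertion sequencing are not
exhaustive) is exposed as an independent thinning parameter rather than
estimated; the screen's published single/doublet totals depend on it and
are not reproduced here.

## Growth model (`growth`)

OLS fit (statsmodels) of log10 V = a0·x + a1·x·c1 + a2·x·c2 + b0 + b1·c1
+ b2·c2 with c1 = [stage ≥ 6], c2 = [stage ≥ 8].  The indicators are
independent — c2 does not imply anything about c1 in the design matrix —
matching the printed two-indicator design; stages above 10 are excluded
from fitting with a logged count since the condition definitions cover
stages 1–10 only.  Standard errors are the usual OLS ones; the residual
SD is reported.  The meaning of the intercept depends on the upstream
normalization of log2 DNA content (what DNA amount maps to 0), which the
module treats as given.

LOESS uses the nearest ⌈span·n⌉ points (span 0.75, degree 2 by default),
tricube weights on distance scaled by the neighbourhood radius, and no
robustness iterations (only span and degree are specified for the
procedure being mirrored).  Locally rank-deficient designs (duplicate x)
fall back to a lower degree with a warning.  Degree-≤2 polynomials are
reproduced to machine precision, and each fitted value matches an
independent per-point weighted-least-squares oracle to 1e-8.

## Expression filters (`expression_metrics`)

expressed ⇔ mean TPM > 1 and SD/mean < 0.67 (sample SD, ddof 1); off ⇔
mean ≤ 1; otherwise variable.  A zero mean is off without evaluating the
CV.  A detection floor of 0.1 TPM — below the expression threshold, so it
only affects silent genes — guards ratio denominators.

The second Polycomb-dependence criterion ("downregulated at least 20 %
less in the knockdown") is interpreted as: the GSC→stage-6 decrease under
knockdown is ≤ 80 % of the wild-type decrease, with both decreases
required positive.  This is the only reading under which the factor
*contributes to* downregulation; the threshold is configurable.  The
percent contribution is defined as the rescued fraction of the wild-type
decrease, 100·(glkd − wt)/(gsc − wt) clamped to [0, 100]; the source
analyses never state their formula, so this definition is an
interpretation and is documented as such.  Filters operate on group
means; whether the original gene lists applied them to means or to
replicate-level fits is unknown.

## Synthetic data (`synthgen`)

What it emulates: the *distributional* structure of each input — hidden
three-state Markov structure with Gaussian log10 FC emissions on top of
Poisson counts (Input ~ Poisson(depth); ChIP ~ Poisson(depth·10^e), the
simplest model that yields near-Gaussian log10 FC at moderate depth);
flat-plus-centric coarse profiles at matched ChIP/Input depth; repeat
counts as background + factor·base; follicle volumes from the reference
growth coefficients plus Gaussian noise; log-normal TPM replicates
parameterized by (mean, CV), which are nonnegative with directly
controllable CV.

What it does not emulate: read-level artifacts (mappability, GC bias,
duplicates), alignment, spike-ins, replicate batch effects, overdispersed
counts, or genuinely correlated gene expression.  Passing tests therefore
demonstrate algorithmic correctness and parameter recovery under the
stated noise models, not robustness to real-data pathologies.

Defaults chosen once as realistic study conditions: ChIP mean depth 500
reads/bin for segmentation-recovery tests (10,000 bins; emission means
−0.5/0/+0.5, SD 0.05 — separation ≥ 5 SD); follicle simulations with
n = 500, residual SD 0.15, log2 DNA uniform on [0,4] (stages 1–5), [3,7]
(stages 6–7), [6,10] (stages 8–10) — overlapping within condition
segments to keep the design identifiable; screen simulations at 10,000
males for convergence checks (the ~15,000-male scale is the default for
production use).  All generators are bit-reproducible given a seed, and
every generator returns a truth record (state path, ratios, coefficients,
class labels) sufficient for recovery testing.

## Known limitations

- Viterbi training converges to a local optimum of the path likelihood;
  the semi-informed initializer makes the fit deterministic but not
  globally optimal.  No multi-start is attempted.
- The subtractive background model can floor heavily-backgrounded bins at
  zero, biasing euchromatic means slightly downward at very low
  signal-to-noise.
- The screen simulator's equal-contribution and fixed-pool assumptions
  ignore stem-cell loss/replacement dynamics over a male's reproductive
  life.
- LOESS is O(n·q) per query set and intended for the hundreds-of-points
  scale of follicle datasets, not genome-scale tracks.
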