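# Methods

## Data model and normalization

Input is a proteins × runs LFQ intensity matrix in the MaxQuant
`proteinGroups` dialect: one `LFQ intensity <run>` column per MS run, a raw
value of 0 (or an empty cell) meaning the protein was not quantified in
that run. Zeros are mapped to an explicit missing marker (NaN) at read
time; nothing downstream ever treats 0 as a measured intensity.
Intensities are log2-transformed (log base is a convention choice: it only
rescales t statistics by a constant that cancels in p-values, and log2
keeps effect sizes in fold-change units). Sample metadata carries, per
run: subject, diagnosis group (`control`/`autism`), a `day`/`night` label
and the hour of death in [0, 24). The day/night label is always taken
from the metadata, never re-derived from the death time.

Z-scores are computed per subject *across proteins* (after replicate
averaging), so each subject contributes a distribution with mean 0 and
unit sd; the group test then compares relative abundance, which removes
per-subject loading differences. The sd uses the unbiased (n−1)
denominator.

## Monte-Carlo presence and contrast

Missingness in LFQ data is informative (left-censored) but which subjects
observe a protein is fixed data; only the *values* behind singly-missing
replicates are uncertain. The procedure separates the two:

1. **Observedness** — a subject observes a protein when ≥ 1 of its
   replicate runs is non-missing. Counting observed subjects per contrast
   side with threshold m = 3 yields the category: `Missing` (both sides
   < 3), `OnlyA`/`OnlyB` (exactly one side < 3), `Modulated` (both ≥ 3).
   The boundary count 3 itself qualifies as present. Observedness never
   changes across simulations, so the category and the confidence score
   are deterministic; this is asserted over many seeds in the tests.
2. **Imputation** — per simulation, each missing replicate of an observed
   subject is drawn from a normal fit (mean, sd) to the run's observed
   log2 values. Run statistics are fitted once on observed data, not
   re-estimated after imputation. Subjects with no observed replicate are
   never imputed.
3. **Testing** — per simulation, a two-sided pooled-variance Student
   t-test on subject Z-scores (Welch and raw-log variants are config
   switches). Degenerate zero-variance cases use a declared convention:
   equal means → p = 1, unequal → p = 0. Across `n_sims = 2000`
   simulations (200 in the committed tests and the acceptance script,
   which is ample for a 95% percentile interval of a smooth p
   distribution), the central 2.5/97.5 empirical percentiles give
   [p_low, p_high]; significance requires p_high < α = 0.05.

Because the *upper* interval bound must clear α, the rule is conservative
by construction; on a global-null synthetic cohort the significant
fraction is about 1%, well under the nominal 5%. Note the rule controls
per-test error, not the false-discovery rate: with many nulls and modest
power the realized FDP among significant calls can exceed α (the pilot
run at the default configuration measured 0.148), and no multiple-testing
correction is applied in this branch by design.

The exclusive-presence confidence score is
(f − g)/(f + g) with f = (N_obs,i − 3)/(N_tot,i − 3) and g = N_obs,j/2,
defined as 0 when f = g = 0, where i is the present and j the absent
side. It is bounded in [−1, 1], rises with support on the present side
and falls with stray observations on the absent side (checked
exhaustively up to 25 subjects per side). The source formula's typeset is
ambiguous about g (N_obs,j/2 vs N_obs,j²); both readings are implemented
(`confidence_variant="half"` default, `"squared"` optional) without
asserting which was intended.

Per-simulation random substreams are spawned from the global seed by
simulation index, so results are independent of execution order and
byte-reproducible.

## JTK-style rhythmicity test

For candidate period P (default {24 h}, a single-cycle design cannot
resolve periods far from one day) and lag grid at 1 h resolution, the
reference is r_j = cos(2π(t_j − lag)/P), consumed only through its rank
ordering. The statistic is Kendall's
S = Σ_{j<k} sign(v_k − v_j)·sign(r_k − r_j) over pairs non-missing and
untied in both vectors; replicates sharing a time stamp are tied in the
reference and contribute no pair.

**Exact null.** Under random permutation of distinct values against a
reference with tie groups of sizes (n_1, …, n_g), the
Jonckheere–Terpstra count J = (S + M)/2 (M = cross-block pairs)
decomposes into independent Mann–Whitney components, one per merge of a
new block into the preceding ones. Each component pmf is computed by the
classic integer-count recurrence, and their convolution gives the exact
pmf of S — identical to enumeration over all n! permutations, verified
for every tie pattern of every n ≤ 8. The reported p is the two-sided
tail P(|S_null| ≥ |S_obs|) for the best (period, lag) — the one
maximizing |S|, ties broken toward smaller lag then smaller period —
multiplied (by default) by the number of grid points. Without that
Bonferroni factor the best-of-grid selection inflates the nominal 1%
rate to ≈ 5%; with it the realized null rate is ≈ 0.3%, i.e. the
conventional, conservative behaviour of this algorithm family. Constant
series report p = 1.

**Dataset-level FDR.** Each permutation round independently shuffles every
protein's values across its time points and re-runs the full scan; the
FDR estimate at a threshold is mean null passers / observed passers,
reported as undefined (NaN, with the zero count) when nothing passes.

## Bayesian generalized Lomb–Scargle

Model at angular frequency ω: y_i = A cos(ωt_i) + B sin(ωt_i) + γ + ε_i,
ε_i Gaussian with relative precision w_i (uniform default). The basis is
orthogonalized by the phase θ with tan 2θ = Σw sin 2ωt / Σw cos 2ωt, after
which (A, B, γ) integrate out in closed form. Two noise treatments:

* `noise="fixed"`: weights are absolute precisions; the log marginal keeps
  all constants and equals the literal triple integral — validated against
  Gauss–Legendre quadrature over a ±10-sd box to 1e−6.
* `noise="marginalized"` (default): the overall noise scale is unknown and
  integrated out under a Jeffreys prior, giving the Student-form marginal
  log M = −½ log det G − ((n−3)/2) log χ²_min + const. This is the form
  used in the pipeline because it makes the posterior argmax invariant
  under value scaling and lets a noiseless sinusoid concentrate all mass
  at its true period; with fixed unit weights the log-det term would
  dominate the tiny χ² differences across the narrow window and neither
  property would hold. Validated against 1-D quadrature over the noise
  scale of the fixed form. χ²_min is floored at 1e−25 of the data's sum
  of squares so that numerically perfect fits stay finite.

The period grid is 101 points over 23–24 h (0.01 h steps; the window is a
design input, the resolution a choice). Computation is in the log domain
with log-sum-exp normalization, and the matrix scan shares the
per-frequency design across proteins with the same missingness pattern.

**Decision rule.** The source procedure reports a rhythmic-protein count
for this method but not its cutoff, so the call here is an explicitly
surrogate criterion: flag when max − median log posterior exceeds 0.22, a
threshold frozen once from a null calibration (5000 synthetic null series
with the generator's timing and noise defaults, 99th percentile of the
statistic) targeting a 1% false-positive rate. One caveat is structural:
over a single day the 23–24 h window spans far less than one frequency
resolution element (1/T ≈ 0.042 cycles/h vs 0.0018 across the window), so
posteriors are nearly flat and the statistic has limited power at
moderate amplitudes — consistent with this detector flagging by far the
fewest proteins of the three.

## Consensus and PPI projection

The three flagged sets (JTK passes, BGLS flags, Monte-Carlo significant ∪
exclusive) are partitioned into the seven exclusive Venn regions. For
network context, each modulated/exclusive protein is mapped to its lead
gene symbol (first token of the protein-group id, upper-cased), labeled
day or night (exclusive side, or the sign of the mean t statistic), and
the induced subgraph of a concatenated binary PPI edge-list union is
summarized: nodes, edges, connected components, fraction of projected
proteins inside the largest linked component, and label composition
overall and within that component. Edge lists are two-column TSVs;
duplicate edges collapse keeping per-file provenance, self-loops are
dropped with a log line, malformed rows fail loudly with file and line.

## Synthetic cohorts

The generator emulates the study design: 18 control + 7 case subjects,
2 technical replicates, death times in a midday cluster N(14, 2.5²) and a
small-hours cluster N(2, 2.5²) mod 24 (uniform sampling is a flag),
protein log2 baselines N(27, 2²) matching the mid-to-high abundance bulk
of real LFQ distributions. Protein classes and defaults: 5% day-up step,
5% night-up step (±1 log2 unit per side, total difference 2.0), 5%
sinusoidal (amplitude 2.0, period uniform in [23, 24] h, random phase),
5% only-day, 5% only-night, 2% only-control, remainder null. Noise:
between-subject sd 0.5, replicate sd 0.2 — so a step of 2.0 is roughly a
4-sd effect at the subject level, a clearly-detectable but not trivial
planted signal for a 9-vs-9 contrast. Missingness: run-specific
left-censoring (logistic dropout centred at each run's 5% intensity
quantile, width 0.5 log2 units) plus 1% MCAR; exclusive classes are
force-masked in the opposing condition after stochastic dropout.

What the generator does *not* emulate: peptide-level structure,
match-between-runs artefacts, batch effects beyond run-level censoring,
correlated proteins (complex stoichiometry), or heavy-tailed noise.
Passing recovery tests therefore demonstrates the statistical machinery
under the design's sampling geometry, not robustness to every real-data
pathology.

Two known limitations surfaced by the synthetic studies: (i) clustered
death times make sinusoids whose phase renders the two clusters
equal-valued nearly invisible to every detector — JTK recall at the
default amplitude plateaus around 0.8 for exactly this reason; (ii) the
BGLS window-concentration statistic has low power at moderate amplitude
(see above).

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds through
`numpy.random.Generator`; the Monte-Carlo engine spawns per-simulation
substreams by index. Two runs with the same seed produce byte-identical
output files. The committed tests and the acceptance script use 200
Monte-Carlo simulations, 2000–5000-protein cohorts, 20 FDR permutation
rounds and 25-point periodogram series — sizes chosen so the full
statistical battery (exact-null enumeration to n = 8, quadrature oracles,
two null cohorts, recovery cohorts) completes in a few minutes while
keeping every Monte-Carlo band far narrower than the effects asserted.
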