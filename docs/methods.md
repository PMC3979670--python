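# Methods

## Scope and data model

A *session* is one recorded encounter: two same-age males in an arena
for 60 minutes (or one male for the single-male controls, whose first
and last 5 minutes are discarded, leaving a 50-minute window).  Scored
behavior is a list of per-subject bouts `(behavior, onset_s,
offset_s)` at video-frame resolution (1/30 s).  The analysis ethogram
has 16 mutually exclusive behaviors in four categories; six raw
low-intensity aggressive acts (chop, uppercut, back kick, head butt,
fencing, boxing) are collapsed into the single code `Lo` at read time
because each is individually rare.  `Immobilized` (I) is a first-class
behavior in transition analysis but is excluded from occurrence-rate
ontogeny comparisons, since it merely mirrors the opponent's hold.

Reading rules that shape downstream counts:

- Per subject, bouts must be non-overlapping; contiguous same-behavior
  records (touching within half a frame) are merged into one bout.
- Uncoded gaps are allowed.  They count toward total observation time
  but toward no behavior, and they neither break transition chains nor
  turn a resumed behavior into a "change": sequence extraction
  collapses consecutive duplicates, so a bout of walking, a gap, and
  more walking contributes one sequence element and no self-transition.
- Transitions are counted within subject within session only; session
  boundaries always break the chain (each fly is used once).

## Quasi-independence analysis

Transition counts pooled over a cohort form a k×k matrix with a
structural-zero diagonal.  The quasi-independence model `m_ij = a_i b_j`
(i ≠ j) is fitted by iterative proportional scaling from a uniform
positive off-diagonal start; convergence is declared when the largest
absolute margin discrepancy falls below `tol` (default 1e-10, maximum
10 000 sweeps — convergence takes ~15 sweeps on the packaged
matrices).  All-zero rows or columns fit trivially to zero and emit a
warning rather than an error.

The likelihood-ratio statistic uses the convention that cells with
`n_ij = 0` contribute zero (the `n ln n → 0` limit), and the residual
degrees of freedom are `k² − 3k + 1`: `k² − k` informative cells minus
`2k − 1` free parameters.  For k = 16 this gives df = 209.

Cell-level inference uses Freeman–Tukey deviates,
`z = √n + √(n+1) − √(4m+1)`, with significance declared for positive
deviates above the simultaneous criterion `c = √(χ²₁₋α,df / n_cells)`.
This rule apportions the α-level chi-square budget across the 240
informative cells and reproduces, cell for cell, the 55-transition
significance pattern of the fully printed day-3 cohort matrix,
including each borderline cell (the smallest significant count is a 2
with deviate 1.012 against c = 1.008).  Only excesses count: the
question asked of each cell is whether the transition occurs *more*
often than chance.

### Cross-cohort tests

Margins-by-age uses the ordinary two-way G test of independence on the
k×5 table of first-position (or second-position) totals, df =
(k−1)(a−1) = 60.

For transition-structure heterogeneity we use the classical test for
homogeneity of Markov transition matrices: within each source behavior
the cohort-specific transition probabilities are compared against the
pooled row-normalized probabilities,

    G = 2 Σ_c Σ_i Σ_{j≠i} n_cij ln( p̂_c(j|i) / p̂_pool(j|i) ),

with df = (a−1)·k·(k−2) (each row has k−1 admissible cells, hence k−2
free probabilities), i.e. 896 for k = 16, a = 5.  This construction is
calibrated for chain-generated data — its Monte-Carlo type-I error at
α = 0.05 sits in the nominal band — which is why it was chosen over
additive-G constructions whose nominal df does not match the
statistic's actual dispersion.  Degrees-of-freedom conventions for
three-way log-linear interactions vary across software
parameterizations, so printed χ² values from other implementations are
not directly comparable.

### Persistence classes

Given per-cohort significant-transition sets for ages 1, 2, 3, 4, 6,
the partition is: `common_all` (present at every age);
`appears_from_day d` (absent at every age before d, present at d and
all later ages); `disappears_after_day d` (present at d and all
earlier ages, absent afterward); everything else `other`.  A
transition seen only at the first age is classified as disappearing
after day 1 — the classifier is purely set-theoretic and makes no
judgment about biological relevance.

## Companion statistics

- **Kruskal–Wallis** (tie-corrected, χ² tail) for occurrence rates
  (bouts·h⁻¹·individual⁻¹) and bout durations across cohorts.
  All-identical data return H = 0, p = 1 rather than an error.
- **Dunn's post-hoc**: mean-rank differences with the tie-corrected
  standard error, Bonferroni-adjusted over all k(k−1)/2 pairs (the
  construction underlying the tabled critical values), plus a compact
  letter display.
- **Arcsine proportion comparisons**: p′ = arcsin √p in radians (not
  the Anscombe variant), variance 1/(4n) with n = pooled observation
  minutes, pairwise q statistics against the studentized range with
  infinite df.
- **Dominance**: per pair, the split `n1 / n_total` of a focal behavior
  (retreats; or hold+lunge with an eligibility filter of ≥2
  occurrences).  The observed histogram over 11 equal-width bins of
  [0, 1] (boundaries to the lower bin, 1.0 to the top bin — 11 bins
  chosen so df = 10) is compared by χ² to the expected histogram
  obtained by pushing each pair's Binomial(n_i, ½) mass through the
  same binning.  With few pairs or very small per-pair counts the
  sparse extreme bins make this χ² mildly anticonservative; with the
  full 55-pair design (all five cohorts pooled) it is well calibrated.
- **Escalation**: per cohort, Kruskal–Wallis across the five
  consecutive 10-min intervals (first/last 5 min trimmed; a bout
  belongs to the half-open interval containing its onset) on per-pair
  hold+lunge counts.

## Kinematic diagrams

Node symbol size encodes the behavior's share of all transitions
(first-position margin / total) in five classes: <1%, 1–5%, 5–10%,
10–15%, >15%.  Bin edges are half-open with the boundary in the upper
class, one fixed rule for labels that overlap at their endpoints.  The
row margin was chosen over the column margin (they differ by at most a
few counts per behavior — only a subject's first and last bouts of a
session break the symmetry).  Edges are the significant transitions,
classed by deviate: [c, 5) low/black, [5, 10) intermediate/orange,
≥10 high/red.  Export is deterministic DOT text: nodes in ethogram
order, edges sorted, so identical fits yield byte-identical files.

## The synthetic-session generator

The generator exists because the study's raw scored data were never
deposited; it emulates the study design so that every pipeline stage
is exercised under known truth.

Each fly is an independent semi-Markov process: bout identities follow
an embedded first-order chain with zero diagonal; bout durations are
log-normal for the four long non-interactive states (walking,
standing, grooming, upside-down; means 12/25/18/8 s, sd = 0.6·mean)
and short draws for everything else (lunge 0.2–0.5 s, wrestle
0.5–3.5 s, retreat 0.3–1 s, avoid 0.5–2 s, jump 0.2–0.5 s, others
0.2–3 s).  Hold durations are log-normal with an age-dependent mean
rising from 2.0 s (day 1) to 8.2 s (day 6).

The embedded chain is constructed from target bout rates: a symmetric
flow matrix with zero diagonal and row sums proportional to the rates
is obtained by iterative proportional scaling with symmetrization
(starting from the product form), and rows are normalized into
transition probabilities.  The resulting chain is reversible, as close
to quasi-independence as the margins allow, and — the property that
matters — its stationary bout-frequency distribution equals the
normalized rate vector exactly.  A chain that never repeats a state
cannot give any behavior more than half of all bouts, which bounds the
feasible rate vectors; the defaults respect this.

Two couplings tie a pair together.  Every hold in one fly splices an
equal-interval immobilized bout into its opponent's timeline
(overlapping holds are resolved by keeping the earlier one), so hold
and immobilized counts mirror exactly per session.  An approach can
elicit a brief avoid or retreat response from the opponent with
age-dependent probabilities.  Retreats otherwise arise independently
in each fly at equal rates, so each retreat belongs to either pair
member with probability ½ — the no-dominance null.  Rates are
constant within a session — the no-escalation null.  Single-male mode
silences the interactive behaviors, bobbing, and jump (bobbing never
occurs in isolated males, jump almost never), and lengthens walking
bouts by 40% — both the smaller repertoire and the structural bout-
share bound require it.

Per-age defaults encode the published qualitative ontogeny as explicit
parameters, not emergent behavior: high-intensity rates rise with age
(lunge 0.5→6, hold 0.3→3.8, wrestle 0.8→6 h⁻¹·ind⁻¹), low-intensity
aggression and avoid fall, retreat rises, walking/standing time share
falls while grooming/upside-down rises, with the four major states
always ≥96% of session time.  The day-6 hold rate is capped near
4 h⁻¹ because the published structural claims are jointly binding:
with 8.2 s holds each mirrored as immobilized time, a higher rate
would push the four-state budget below its documented 96.4% floor.
Every session is generated from one seeded generator; cohort seeds
derive from a base seed by a fixed increment.

What the generator does *not* emulate: genuine behavioral reaction
chains beyond the two couplings, inter-fly response latencies,
non-stationarity, observer error, or arena geometry.  Passing tests on
generated data therefore validate the statistical machinery under the
study's design and nulls, not any biological claim about real flies.

### Reconstructed cohort matrices

Only the day-3 transition matrix was published in full; the day
1/2/4/6 matrices existed only in an undeposited supplement.  The
packaged `transitions_day{1,2,4,6}_synthetic.tsv` files are
deterministic reconstructions produced by
`ethoseq.synthetic.engineer_significance_matrix`: starting from the
day-3 matrix rescaled to each cohort's published transition total
(5075, 5990, 5203, 7206), counts are shifted between cells until the
quasi-independence pipeline flags exactly a prescribed set of cells.
The prescribed sets realize the published structure — 38/58/54/53
significant transitions, 10/26/16/18 involving high-intensity
behaviors, 20 transitions common to all five cohorts, 8 appearing from
day 2, 5 from day 3, 4 on days 4+6 only, 3 on day 6 only, and the
three eliminated transitions — using individually named transitions
from the published record where they are mutually consistent (the
published per-day lists do not reconcile exactly with the printed
per-day totals, so totals and class sizes take precedence).  These
files are labelled synthetic in their names; cross-cohort results
computed from them validate the pipeline, not the study's unpublished
data.

## Verification strategy and problem sizes

The printed day-3 matrix makes the core pipeline exactly checkable:
margins, G, df, the criterion, all 55 significant cells and their
high-intensity classification are asserted against the published
values.  IPF is cross-checked against an independent brute-force
alternating-scaling oracle to 1e-9 on random 4×4 matrices, and the
G test's type-I error is verified by parametric bootstrap (500
replicates, k = 6).  Monte-Carlo checks of the generator use: 200
two-hour decoupled sessions for embedded-chain recovery (rows with
≥10 000 observed transitions recovered within ±0.02); 100 cohorts of
11 pairs for the 20×-enrichment power check; 200 replicates of the
full 55-pair study design for the escalation and dominance null
calibrations; and smaller simulations (25–40 replicates) for
directional power checks.  These sizes put each check's sampling error
well inside the asserted tolerance while keeping the default test run
to about a minute of compute.

## Known limitations

- The simultaneous Freeman–Tukey criterion is one defensible reading
  of "significance at α = 0.05" for cell-level deviates; borderline
  cells (deviates within ~0.01 of the criterion) could flip under
  other reasonable rules.
- The dominance χ² inherits the usual sparse-bin anticonservatism of
  goodness-of-fit tests when pairs are few or counts tiny.
- The generator's inter-fly couplings perturb the embedded chain
  slightly (spliced immobilized bouts and responses add transitions),
  which is why parameter-recovery checks use the decoupled
  configuration.
- Uncoded-gap handling (gaps do not break chains) follows the
  instantaneous-transition description of the source data; scoring
  conventions with long gaps might warrant a chain break that the
  package does not implement.
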