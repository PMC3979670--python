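# ethoseq

Behavioral sequence analysis for dyadic agonistic encounters: from
ethogram-coded event logs to first-order transition matrices,
quasi-independence log-linear inference with Freeman–Tukey deviates,
kinematic diagrams, nonparametric ontogeny / dominance / escalation
statistics, and a semi-Markov simulator of paired-male encounter
sessions.

The package targets quantitative ethologists analyzing staged
encounters between pairs of animals — the motivating system is
male–male aggression in flesh flies, where socially naïve, same-age
males are filmed for an hour in an arena, every behavior is scored
against a 16-behavior ethogram, and the question is how the temporal
organization of behavior (not just behavior frequencies) changes as
the flies mature.

## The model

For a cohort of encounters, every change of behavior is tabulated in a
k×k matrix of counts `n_ij` (behavior *i* immediately followed by
behavior *j*).  Self-transitions cannot occur — only changes are
scored — so the diagonal is a structural zero.  The null model is
**quasi-independence**: the first and second behavior of a transition
are independent over the off-diagonal cells,

```
m_ij = a_i · b_j   (i ≠ j),    m_ii = 0,
```

fitted by iterative proportional scaling so that expected row and
column margins equal the observed margins.  Overall departure is
measured by the likelihood-ratio statistic

```
G = 2 Σ_{i≠j} n_ij ln(n_ij / m_ij),    df = k² − 3k + 1,
```

and each cell by its Freeman–Tukey deviate

```
z_ij = √n_ij + √(n_ij + 1) − √(4 m_ij + 1),
```

approximately standard normal under the model.  A transition is
*significant* (occurs more often than chance) when its deviate exceeds
the simultaneous criterion `c = √(χ²₁₋α,df / n_cells)` with α = 0.05 —
about 1.008 for the default 16-behavior analysis with 240 informative
cells.  Significant transitions become the arrows of a kinematic
diagram (exported as DOT), with node sizes binned by behavior
frequency and arrow classes binned by deviate strength.

Around this core the package provides the study's companion
statistics: Kruskal–Wallis with Dunn's post-hoc for occurrence rates
and bout durations across age cohorts, Tukey-type comparisons of
arcsine-transformed time-budget proportions, a binomial goodness-of-fit
test for dominance (is a behavior performed evenly by the two
opponents?), and a per-cohort Kruskal–Wallis across successive 10-min
intervals for escalation.

## Worked example

The packaged day-3 cohort matrix (printed in full in the source study)
is analyzed in a few lines:

```python
from importlib import resources
import ethoseq as es

ethogram = es.default_ethogram()                 # the 16-behavior repertoire
with resources.as_file(es.packaged_matrix_path(3)) as path:
    counts = es.read_transition_matrix(path, ethogram, age_days=3)

result = es.QuasiIndependence(counts, alpha=0.05).fit()
print(result.summary())
```

```
Quasi-independence log-linear fit
============================================
Behaviors (k):           16
Transitions (N):         5098
G statistic:             3642.3
df:                      209
p-value:                 0
alpha:                   0.05
FT criterion:            1.0077
Significant transitions: 55
--------------------------------------------
  from     to      n   deviate
    Ap     Av    154     12.54
    Ap      I      8      2.67
    ...
```

The model is overwhelmingly rejected (G = 3642 on 209 df): behavior
sequences are highly structured.  Exactly 55 transitions exceed the
simultaneous criterion.  Their involvement with the four
full-body-contact behaviors (lunge L, hold H, wrestle Wr,
immobilized I) summarizes how aggression is embedded in the repertoire:

```python
summary = result.classify_hi_involvement()
# involving_hi=18, hi_to_hi=6, 5 transitions into L, 5 into Wr,
# 6 distinct non-aggressive behaviors act as precursors to aggression
```

and `es.export_dot(result, ethogram)` renders the kinematic diagram.

Synthetic cohorts with the study's design (11 pairs, 60-min sessions)
are one call away and feed every pipeline stage:

```python
logs = es.generate_cohort(3, n_pairs=11, seed=1)   # day-3 defaults
tc = es.build_transition_counts(logs, ethogram)
```

A command-line interface mirrors the library: `ethoseq analyze`,
`ethoseq matrix`, `ethoseq simulate`, `ethoseq stats`.

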