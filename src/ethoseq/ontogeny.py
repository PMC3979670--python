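"""Cross-cohort and within-encounter nonparametric statistics.

Occurrence rates and bout durations are compared across age cohorts with
the Kruskal-Wallis test and Dunn's nonparametric multiple-comparison
post-hoc; pooled time-budget proportions with Tukey-type multiple
comparisons of arcsine-transformed proportions; dominance with a
binomial goodness-of-fit on the per-pair split of a focal behavior; and
escalation with per-cohort Kruskal-Wallis across successive 10-min
intervals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .events import EventLog, interval_counts

#: behaviors entering the occurrence-rate ontogeny comparisons; immobilized
#: is excluded because it merely mirrors the opponent's hold
RATE_ONTOGENY_BEHAVIORS = ["L", "H", "Wr", "Lo", "Av", "R", "T", "Ap", "J", "Sti", "B"]


@dataclass
class GroupedSamples:
    """Per-group vectors of per-individual (or per-pair) values."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}

    @property
    def labels(self) -> list[str]:
        return list(self.groups)


def kruskal_wallis(gs: GroupedSamples) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square tail p-value.

    All-identical data give H = 0, p = 1 rather than an error.
    """
    samples = [v for v in gs.groups.values() if v.size > 0]
    if len(samples) < 2:
        raise ValueError("need at least two non-empty groups")
    df = len(samples) - 1
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    H, p = stats.kruskal(*samples)
    return float(H), df, float(p)


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    p_adjusted: float
    significant: bool


@dataclass
class MultipleComparisonResult:
    comparisons: list[PairwiseComparison]
    letters: dict[str, str]

    def significant_pairs(self) -> set[tuple[str, str]]:
        return {(c.group_a, c.group_b) for c in self.comparisons if c.significant}


def _letter_display(labels: Sequence[str], distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not distinguishable."""
    # greedy insert-and-absorb over cliques of mutually non-distinct groups
    columns: list[set[str]] = []
    for lab in labels:
        placed = False
        for col in columns:
            if all((lab, other) not in distinct and (other, lab) not in distinct for other in col):
                col.add(lab)
                placed = True
        if not placed:
            columns.append({lab})
    # drop columns fully contained in another
    columns = [
        c for i, c in enumerate(columns)
        if not any(i != j and c < other for j, other in enumerate(columns))
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lab: "" for lab in labels}
    for letter, col in zip(alphabet, columns):
        for lab in col:
            letters[lab] += letter
    return letters


def dunn_posthoc(gs: GroupedSamples, alpha: float = 0.05) -> MultipleComparisonResult:
    """Dunn's nonparametric multiple comparisons on mean ranks.

    Q = |mean rank difference| / SE with the tie-corrected SE, compared
    to the standard normal with a Bonferroni adjustment over all
    k(k-1)/2 pairs (the construction behind the tabled critical values).
    """
    labels = gs.labels
    if len(labels) < 3:
        raise ValueError("Dunn's test needs >= 3 groups; use a two-sample comparison")
    sizes = {lab: gs.groups[lab].size for lab in labels}
    pooled = np.concatenate([gs.groups[lab] for lab in labels])
    ranks = stats.rankdata(pooled)
    N = pooled.size
    mean_ranks = {}
    offset = 0
    for lab in labels:
        n = sizes[lab]
        mean_ranks[lab] = ranks[offset : offset + n].mean()
        offset += n
    # tie correction term: sum of (t^3 - t) over tie groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    n_pairs = len(labels) * (len(labels) - 1) // 2
    comparisons = []
    distinct: set[tuple[str, str]] = set()
    for a, b in itertools.combinations(labels, 2):
        se = math.sqrt(
            (N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1)))
            * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        Q = abs(mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * stats.norm.sf(Q) * n_pairs)
        sig = p < alpha
        comparisons.append(PairwiseComparison(a, b, Q, p, sig))
        if sig:
            distinct.add((a, b))
    return MultipleComparisonResult(comparisons, _letter_display(labels, distinct))


def arcsine_proportion_comparisons(
    budgets: Mapping[str, tuple[float, float]], alpha: float = 0.05
) -> MultipleComparisonResult:
    """Tukey-type multiple comparisons among arcsine-transformed proportions.

    ``budgets`` maps cohort label to (amount in behavior, total amount),
    both in the same units (the study used minutes).  p' = arcsin(sqrt p)
    in radians has approximate variance 1/(4n); pairwise q statistics are
    referred to the studentized range with infinite df.
    """
    labels = list(budgets)
    props = {}
    ns = {}
    for lab, (x, n) in budgets.items():
        if n <= 0:
            raise ValueError(f"cohort {lab!r}: nonpositive total")
        p = x / n
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"cohort {lab!r}: proportion {p} outside [0, 1]")
        props[lab] = math.asin(math.sqrt(p))
        ns[lab] = n
    kgroups = len(labels)
    q_crit = float(stats.studentized_range.ppf(1.0 - alpha, kgroups, 1e7))
    comparisons = []
    distinct: set[tuple[str, str]] = set()
    for a, b in itertools.combinations(labels, 2):
        se = math.sqrt(0.5 * (1.0 / (4.0 * ns[a]) + 1.0 / (4.0 * ns[b])))
        q = abs(props[a] - props[b]) / se if se > 0 else 0.0
        p_adj = float(stats.studentized_range.sf(q, kgroups, 1e7))
        sig = q > q_crit
        comparisons.append(PairwiseComparison(a, b, q, p_adj, sig))
        if sig:
            distinct.add((a, b))
    return MultipleComparisonResult(comparisons, _letter_display(labels, distinct))


@dataclass
class PairRetreatRecord:
    """Per-pair split of a focal behavior between the two opponents."""

    pair_id: str
    n1: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n1 <= self.n_total:
            raise ValueError(f"pair {self.pair_id}: n1={self.n1} outside [0, {self.n_total}]")

    @property
    def proportion(self) -> float:
        if self.n_total == 0:
            raise ValueError(f"pair {self.pair_id}: proportion undefined (no occurrences)")
        return self.n1 / self.n_total


def pair_split_records(
    logs: Sequence[EventLog], behaviors: Iterable[str]
) -> list[PairRetreatRecord]:
    """Per-session counts of focal behaviors split by pair member.

    Individual 1 is the lexicographically first subject id of the
    session (the fly designated first when the pair was placed).
    """
    behaviors = set(behaviors)
    out = []
    for log in logs:
        subjects = sorted(log.subjects)
        counts = {s: 0 for s in subjects}
        for r in log.records:
            if r.behavior in behaviors:
                counts[r.subject_id] += 1
        total = sum(counts.values())
        n1 = counts[subjects[0]] if subjects else 0
        out.append(PairRetreatRecord(pair_id=log.session_id, n1=n1, n_total=total))
    return out


@dataclass
class DominanceTestResult:
    mean: float
    sem: float
    chi2: float
    df: int
    pvalue: float
    observed: np.ndarray
    expected: np.ndarray


def dominance_test(
    records: Sequence[PairRetreatRecord],
    bins: int = 11,
    min_occurrences: int = 1,
) -> DominanceTestResult:
    """Goodness of fit of the per-pair behavior split to Binomial(n, 1/2).

    The observed histogram of per-pair proportions over ``bins``
    equal-width bins of [0, 1] is compared to the expected histogram
    obtained by summing each eligible pair's Binomial(n_i, 1/2) mass
    mapped through x/n_i; chi-square with df = bins - 1.  Boundary
    values fall in the lower bin except 1.0, which goes to the top bin.
    """
    eligible = [r for r in records if r.n_total >= max(min_occurrences, 1)]
    if not eligible:
        raise ValueError("no eligible pairs")
    props = np.array([r.proportion for r in eligible])
    mean = float(props.mean())
    sem = float(props.std(ddof=1) / math.sqrt(props.size)) if props.size > 1 else 0.0

    def bin_of(p: float) -> int:
        return min(int(p * bins), bins - 1)

    observed = np.zeros(bins)
    for p in props:
        observed[bin_of(p)] += 1
    expected = np.zeros(bins)
    for r in eligible:
        ks = np.arange(r.n_total + 1)
        pmf = stats.binom.pmf(ks, r.n_total, 0.5)
        for k, mass in zip(ks, pmf):
            expected[bin_of(k / r.n_total)] += mass
    live = expected > 0
    chi2 = float(np.sum((observed[live] - expected[live]) ** 2 / expected[live]))
    if np.any(~live & (observed > 0)):
        chi2 = float("inf")
    df = bins - 1
    return DominanceTestResult(
        mean=mean,
        sem=sem,
        chi2=chi2,
        df=df,
        pvalue=float(stats.chi2.sf(chi2, df)),
        observed=observed,
        expected=expected,
    )


def escalation_test(
    logs_by_cohort: Mapping[int, Sequence[EventLog]],
    behaviors: Iterable[str] = ("H", "L"),
    interval_s: float = 600.0,
    trim_s: float = 300.0,
) -> dict[int, tuple[float, int, float]]:
    """Per-cohort Kruskal-Wallis across successive intervals of aggression counts.

    For each cohort, per-pair hold+lunge counts in the five consecutive
    10-min intervals (first/last 5 min trimmed) form the five groups; a
    significant H indicates within-encounter escalation (or decline).
    """
    out = {}
    for cohort, logs in logs_by_cohort.items():
        table = np.array([interval_counts(log, behaviors, interval_s, trim_s) for log in logs])
        if table.shape[1] < 2:
            raise ValueError("need at least two intervals")
        gs = GroupedSamples({f"interval{i + 1}": table[:, i] for i in range(table.shape[1])})
        out[cohort] = kruskal_wallis(gs)
    return out
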