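"""Quasi-independence log-linear analysis of transition matrices.

The model
---------
For a k x k transition matrix with structural-zero diagonal, the
quasi-independence model posits expected frequencies

    m_ij = a_i * b_j   for i != j,       m_ii = 0,

i.e. independence of the first and second behavior in a transition,
restricted to the off-diagonal cells.  The row and column effects are
fitted by iterative proportional scaling so that expected margins equal
observed margins.  Departure from the model is measured by the
likelihood-ratio statistic

    G = 2 * sum_{i != j, n_ij > 0} n_ij * ln(n_ij / m_ij)

on df = k^2 - 3k + 1 (k^2 - k cells minus 2k - 1 free parameters), and
cell-wise by Freeman-Tukey deviates

    z_ij = sqrt(n_ij) + sqrt(n_ij + 1) - sqrt(4 m_ij + 1),

approximately standard normal under the model.  A transition is declared
to occur *more often than expected by chance* when its deviate exceeds
the simultaneous criterion

    c = sqrt(chi2_{1 - alpha, df} / n_cells),

which apportions the alpha-level chi-square budget across the k^2 - k
informative cells; only positive deviates (excesses) qualify.

Usage follows the model/results idiom::

    model = QuasiIndependence(tc)          # tc: TransitionCounts
    res = model.fit()                      # QuasiIndependenceResults
    res.significant_transitions()
    print(res.summary())
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .ethogram import Ethogram
from .transitions import TransitionCounts

HIGH_INTENSITY_DEFAULT = frozenset({"L", "H", "Wr", "I"})


class ConvergenceError(RuntimeError):
    pass


def fit_quasi_independence(
    tc: TransitionCounts, tol: float = 1e-10, max_iter: int = 10_000
) -> np.ndarray:
    """Expected matrix under quasi-independence, by iterative proportional scaling.

    Alternates row and column rescaling of a uniform off-diagonal start
    until the largest absolute margin discrepancy is below ``tol``.
    All-zero rows or columns fit trivially to zero (with a warning).
    """
    n = np.asarray(tc.n, dtype=float)
    k = tc.k
    r = n.sum(axis=1)
    c = n.sum(axis=0)
    if np.any(r == 0) or np.any(c == 0):
        dead = [tc.labels[i] for i in range(k) if r[i] == 0 or c[i] == 0]
        warnings.warn(
            f"behaviors with empty margins fit trivially to zero: {dead}",
            stacklevel=2,
        )
    m = np.ones((k, k))
    np.fill_diagonal(m, 0.0)
    for it in range(max_iter):
        rs = m.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            m *= np.where(rs > 0, r[:, None] / np.where(rs > 0, rs, 1.0), 0.0)
        cs = m.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            m *= np.where(cs > 0, c[None, :] / np.where(cs > 0, cs, 1.0), 0.0)
        disc = max(
            np.abs(m.sum(axis=1) - r).max(),
            np.abs(m.sum(axis=0) - c).max(),
        )
        if disc < tol:
            return m
    raise ConvergenceError(
        f"IPF did not converge in {max_iter} iterations; final discrepancy {disc:.3e}"
    )


def g_statistic(tc: TransitionCounts, expected: np.ndarray) -> tuple[float, int, float]:
    """Likelihood-ratio G against the fitted expecteds; returns (G, df, p).

    Cells with n_ij = 0 contribute zero (the n ln n -> 0 limit).
    """
    n = np.asarray(tc.n, dtype=float)
    if expected.shape != n.shape:
        raise ValueError(f"shape mismatch: {expected.shape} vs {n.shape}")
    mask = n > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mask, n * np.log(np.where(mask, n, 1.0) / np.where(mask, expected, 1.0)), 0.0)
    G = float(2.0 * terms.sum())
    k = tc.k
    df = k * k - 3 * k + 1
    p = float(stats.chi2.sf(G, df))
    return G, df, p


def freeman_tukey_deviates(tc: TransitionCounts, expected: np.ndarray) -> np.ndarray:
    """Freeman-Tukey deviate for each off-diagonal cell; NaN on the diagonal."""
    n = np.asarray(tc.n, dtype=float)
    if np.any(expected < 0):
        raise ValueError("expected frequencies must be nonnegative")
    z = np.sqrt(n) + np.sqrt(n + 1.0) - np.sqrt(4.0 * expected + 1.0)
    np.fill_diagonal(z, np.nan)
    return z


def significance_criterion(alpha: float, df: int, n_cells: int) -> float:
    """Simultaneous Freeman-Tukey criterion c = sqrt(chi2_{1-alpha, df} / n_cells)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(np.sqrt(stats.chi2.ppf(1.0 - alpha, df) / n_cells))


@dataclass
class HighIntensitySummary:
    """Counts of significant transitions by high-intensity involvement."""

    involving_hi: int
    hi_to_hi: int
    to_hi: int
    from_hi: int
    distinct_non_hi_precursors: int
    to_behavior: dict[str, int]


class QuasiIndependenceResults:
    """Fit of the quasi-independence model to one transition matrix.

    Attributes
    ----------
    counts : TransitionCounts
    expected : ndarray, fitted expected frequencies (zero diagonal)
    G, df, pvalue : likelihood-ratio test of the model
    deviates : ndarray of Freeman-Tukey deviates (NaN diagonal)
    alpha, criterion : significance level and simultaneous threshold
    significant : boolean mask, True where deviate > criterion off-diagonal
    """

    def __init__(self, counts: TransitionCounts, expected: np.ndarray, alpha: float):
        self.counts = counts
        self.expected = expected
        self.alpha = alpha
        self.G, self.df, self.pvalue = g_statistic(counts, expected)
        self.deviates = freeman_tukey_deviates(counts, expected)
        k = counts.k
        self.n_cells = k * k - k
        self.criterion = significance_criterion(alpha, self.df, self.n_cells)
        with np.errstate(invalid="ignore"):
            self.significant = np.nan_to_num(self.deviates, nan=-np.inf) > self.criterion
        np.fill_diagonal(self.significant, False)

    @property
    def labels(self) -> list[str]:
        return self.counts.labels

    def significant_transitions(self) -> set[tuple[str, str]]:
        """Ordered (from, to) pairs occurring more often than expected by chance."""
        labels = self.labels
        ii, jj = np.nonzero(self.significant)
        return {(labels[i], labels[j]) for i, j in zip(ii, jj)}

    def classify_hi_involvement(
        self, high_intensity: frozenset[str] | set[str] = HIGH_INTENSITY_DEFAULT
    ) -> HighIntensitySummary:
        """Summarize how significant transitions involve high-intensity behaviors."""
        sig = self.significant_transitions()
        return classify_hi_involvement(sig, high_intensity)

    def deviate(self, src: str, dst: str) -> float:
        return float(self.deviates[self.counts.index(src), self.counts.index(dst)])

    def to_report(self) -> dict:
        """JSON-serializable fit report."""
        sig = sorted(self.significant_transitions())
        return {
            "k": self.counts.k,
            "total_transitions": self.counts.total,
            "G": self.G,
            "df": self.df,
            "pvalue": self.pvalue,
            "alpha": self.alpha,
            "criterion": self.criterion,
            "n_significant": len(sig),
            "significant_transitions": [
                {"from": a, "to": b, "n": self.counts[a, b], "deviate": self.deviate(a, b)}
                for a, b in sig
            ],
        }

    def summary(self) -> str:
        """Readable fit summary in the style of a model-results table."""
        rep = self.to_report()
        lines = [
            "Quasi-independence log-linear fit",
            "=" * 44,
            f"Behaviors (k):           {rep['k']}",
            f"Transitions (N):         {rep['total_transitions']}",
            f"G statistic:             {rep['G']:.1f}",
            f"df:                      {rep['df']}",
            f"p-value:                 {rep['pvalue']:.3g}",
            f"alpha:                   {rep['alpha']}",
            f"FT criterion:            {rep['criterion']:.4f}",
            f"Significant transitions: {rep['n_significant']}",
            "-" * 44,
            f"{'from':>6} {'to':>6} {'n':>6} {'deviate':>9}",
        ]
        for t in rep["significant_transitions"]:
            lines.append(f"{t['from']:>6} {t['to']:>6} {t['n']:>6} {t['deviate']:>9.2f}")
        return "\n".join(lines)


class QuasiIndependence:
    """Model object: quasi-independence with a structural-zero diagonal.

    Parameters
    ----------
    counts : TransitionCounts
        Pooled cohort transition counts.
    alpha : float
        Significance level for the simultaneous Freeman-Tukey criterion.
    """

    def __init__(self, counts: TransitionCounts, alpha: float = 0.05):
        self.counts = counts
        self.alpha = alpha

    @classmethod
    def from_logs(cls, logs: Iterable, ethogram: Ethogram, alpha: float = 0.05):
        from .transitions import build_transition_counts

        return cls(build_transition_counts(logs, ethogram), alpha=alpha)

    def fit(self, tol: float = 1e-10, max_iter: int = 10_000) -> QuasiIndependenceResults:
        expected = fit_quasi_independence(self.counts, tol=tol, max_iter=max_iter)
        return QuasiIndependenceResults(self.counts, expected, self.alpha)


def classify_hi_involvement(
    sig: set[tuple[str, str]],
    high_intensity: frozenset[str] | set[str] = HIGH_INTENSITY_DEFAULT,
) -> HighIntensitySummary:
    """Counts of significant transitions to/from high-intensity behaviors."""
    hi = set(high_intensity)
    involving = {(a, b) for a, b in sig if a in hi or b in hi}
    both = {(a, b) for a, b in involving if a in hi and b in hi}
    to_hi = {(a, b) for a, b in sig if b in hi}
    from_hi = {(a, b) for a, b in sig if a in hi}
    precursors = {a for a, b in sig if b in hi and a not in hi}
    to_behavior: dict[str, int] = {}
    for _, b in sig:
        to_behavior[b] = to_behavior.get(b, 0) + 1
    return HighIntensitySummary(
        involving_hi=len(involving),
        hi_to_hi=len(both),
        to_hi=len(to_hi),
        from_hi=len(from_hi),
        distinct_non_hi_precursors=len(precursors),
        to_behavior=to_behavior,
    )


@dataclass
class CohortSet:
    """Transition matrices for several age cohorts with shared labels."""

    matrices: dict[int, TransitionCounts]

    def __post_init__(self) -> None:
        labels = None
        for age, tc in self.matrices.items():
            if labels is None:
                labels = tc.labels
            elif tc.labels != labels:
                raise ValueError(f"cohort {age} labels differ from the others")

    @property
    def a(self) -> int:
        return len(self.matrices)

    @property
    def ages(self) -> list[int]:
        return sorted(self.matrices)

    @property
    def labels(self) -> list[str]:
        return next(iter(self.matrices.values())).labels


def _g_table(observed: np.ndarray) -> tuple[float, int]:
    """Likelihood-ratio G test of independence in a two-way table."""
    obs = np.asarray(observed, dtype=float)
    r = obs.sum(axis=1, keepdims=True)
    c = obs.sum(axis=0, keepdims=True)
    N = obs.sum()
    if N <= 0 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("degenerate table")
    exp = r @ c / N
    mask = obs > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        G = 2.0 * np.where(mask, obs * np.log(np.where(mask, obs, 1.0) / exp), 0.0).sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return float(G), df


def marginal_by_age_test(cs: CohortSet, axis: str = "first") -> tuple[float, int, float]:
    """G test of behavior-by-age interaction on transition-matrix margins.

    ``axis='first'`` uses row margins (behavior in first position),
    ``axis='second'`` column margins.  df = (k - 1)(a - 1).
    """
    if cs.a < 2:
        raise ValueError("need at least two cohorts")
    if axis not in ("first", "second"):
        raise ValueError("axis must be 'first' or 'second'")
    cols = []
    for age in cs.ages:
        tc = cs.matrices[age]
        cols.append(tc.row_sums if axis == "first" else tc.col_sums)
    table = np.column_stack(cols)  # k x a
    G, df = _g_table(table)
    return G, df, float(stats.chi2.sf(G, df))


def homogeneity_across_ages(cs: CohortSet) -> tuple[float, int, float]:
    """Test whether the embedded transition probabilities differ among cohorts.

    Classical homogeneity test for Markov transition matrices: within each
    row (first behavior), cohort-specific transition probabilities are
    compared against the pooled row-normalized probabilities,

        G = 2 sum_c sum_i sum_{j != i} n_cij ln( p_c(j|i) / p_pool(j|i) ),

    df = (a - 1) * k * (k - 2) for a structural-zero diagonal (each row has
    k - 1 cells, hence k - 2 free probabilities).  Rows with zero total in
    a cohort contribute nothing.
    """
    if cs.a < 2:
        raise ValueError("need at least two cohorts")
    labels = cs.labels
    k = len(labels)
    pooled = np.zeros((k, k), dtype=float)
    for tc in cs.matrices.values():
        pooled += tc.n
    pooled_rows = pooled.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_pool = np.where(pooled_rows > 0, pooled / np.where(pooled_rows > 0, pooled_rows, 1.0), 0.0)
    G = 0.0
    for tc in cs.matrices.values():
        n = np.asarray(tc.n, dtype=float)
        rows = n.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_c = np.where(rows > 0, n / np.where(rows > 0, rows, 1.0), 0.0)
            mask = (n > 0) & (p_pool > 0)
            G += 2.0 * np.where(mask, n * np.log(np.where(mask, p_c, 1.0) / np.where(mask, p_pool, 1.0)), 0.0).sum()
    df = (cs.a - 1) * k * (k - 2)
    return float(G), df, float(stats.chi2.sf(G, df))


@dataclass
class PersistenceClasses:
    """Partition of the union of significant transitions across age cohorts."""

    common_all: set[tuple[str, str]]
    appears_from_day: dict[int, set[tuple[str, str]]]
    disappears_after_day: dict[int, set[tuple[str, str]]]
    other: set[tuple[str, str]]


def cohort_persistence_classes(
    fits: Mapping[int, QuasiIndependenceResults]
) -> PersistenceClasses:
    """Classify significant transitions by their persistence across ages.

    ``common_all``: significant at every age.  ``appears_from_day[d]``:
    absent at all ages < d, present at all ages >= d.
    ``disappears_after_day[d]``: present at all ages <= d, absent after.
    Everything else significant somewhere goes to ``other``.
    """
    if len(fits) < 2:
        raise ValueError("need fits for at least two cohorts")
    ages = sorted(fits)
    sig = {age: fits[age].significant_transitions() for age in ages}
    union: set[tuple[str, str]] = set().union(*sig.values())
    common = set.intersection(*sig.values())
    appears: dict[int, set] = {d: set() for d in ages[1:]}
    disappears: dict[int, set] = {d: set() for d in ages[:-1]}
    other: set[tuple[str, str]] = set()
    for t in union:
        if t in common:
            continue
        present = [t in sig[a] for a in ages]
        first_true = present.index(True)
        if all(present[first_true:]) and first_true > 0:
            appears[ages[first_true]].add(t)
            continue
        last_true = len(present) - 1 - present[::-1].index(True)
        if all(present[: last_true + 1]) and last_true < len(ages) - 1:
            disappears[ages[last_true]].add(t)
            continue
        other.add(t)
    return PersistenceClasses(
        common_all=common,
        appears_from_day=appears,
        disappears_after_day=disappears,
        other=other,
    )
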