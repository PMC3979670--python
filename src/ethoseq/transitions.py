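"""First-order behavioral transition matrices with structural-zero diagonals.

A transition matrix tabulates, for one age cohort, how often each behavior
was immediately followed by each other behavior, pooled over every subject
and session in the cohort.  Self-transitions cannot occur (only *changes*
of behavior are coded), so the diagonal is structurally zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .ethogram import Ethogram, EthogramError

MARGIN_LABEL = "Σ"  # Σ


class MatrixIntegrityError(ValueError):
    """Raised when a matrix file's printed margins disagree with its cells."""


@dataclass
class TransitionCounts:
    """k x k matrix of transition counts ``n[i, j]`` with zero diagonal.

    ``labels`` gives the behavior code for each row/column (identical
    ordering on both axes).
    """

    labels: list[str]
    n: np.ndarray
    age_days: int | None = None

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n)
        k = len(self.labels)
        if self.n.shape != (k, k):
            raise ValueError(f"matrix shape {self.n.shape} does not match {k} labels")
        if np.any(self.n < 0):
            raise ValueError("transition counts must be nonnegative")
        if np.any(np.diag(self.n) != 0):
            bad = [self.labels[i] for i in np.nonzero(np.diag(self.n))[0]]
            raise ValueError(f"nonzero diagonal for behaviors: {bad}")
        if not np.issubdtype(self.n.dtype, np.integer):
            if not np.allclose(self.n, np.round(self.n)):
                raise ValueError("transition counts must be integers")
            self.n = self.n.astype(np.int64)

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def total(self) -> int:
        return int(self.n.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.n.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.n.sum(axis=0)

    def index(self, code: str) -> int:
        return self.labels.index(code)

    def __getitem__(self, pair: tuple[str, str]) -> int:
        i, j = pair
        return int(self.n[self.index(i), self.index(j)])


def extract_sequence(log, subject_id: str) -> list[str]:
    """Temporal sequence of behavior codes for one subject.

    Consecutive codes are always distinct: contiguous same-behavior
    records are merged at read, and a behavior resumed after an uncoded
    gap is not a change of behavior, so it is collapsed here rather than
    counted as a self-transition.
    """
    if subject_id not in log.subjects:
        raise KeyError(f"unknown subject {subject_id!r}; have {sorted(log.subjects)}")
    recs = [r for r in log.records if r.subject_id == subject_id]
    recs.sort(key=lambda r: (r.onset_s, r.offset_s))
    seq: list[str] = []
    for r in recs:
        if not seq or seq[-1] != r.behavior:
            seq.append(r.behavior)
    return seq


def build_transition_counts(
    logs: Iterable, ethogram: Ethogram, age_days: int | None = None
) -> TransitionCounts:
    """Pool transition counts over all subjects and sessions of a cohort.

    Each consecutive pair of behaviors within one subject's sequence
    contributes one count; chains never cross subjects or sessions.
    """
    labels = ethogram.codes
    idx = {c: i for i, c in enumerate(labels)}
    n = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for log in logs:
        for subject in sorted(log.subjects):
            seq = extract_sequence(log, subject)
            for a, b in zip(seq, seq[1:]):
                if a not in idx or b not in idx:
                    missing = a if a not in idx else b
                    raise EthogramError(f"code {missing!r} absent from ethogram")
                if a != b:
                    n[idx[a], idx[b]] += 1
    return TransitionCounts(labels=labels, n=n, age_days=age_days)


def write_transition_matrix(
    tc: TransitionCounts, path: Union[str, Path], margins: bool = True
) -> None:
    """Write a transition matrix as TSV (optionally with Σ margin row/column)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        header = [""] + tc.labels + ([MARGIN_LABEL] if margins else [])
        fh.write("\t".join(header) + "\n")
        for i, lab in enumerate(tc.labels):
            cells = [lab] + [str(int(x)) for x in tc.n[i]]
            if margins:
                cells.append(str(int(tc.row_sums[i])))
            fh.write("\t".join(cells) + "\n")
        if margins:
            cells = [MARGIN_LABEL] + [str(int(x)) for x in tc.col_sums] + [str(tc.total)]
            fh.write("\t".join(cells) + "\n")


def read_transition_matrix(
    path: Union[str, Path], ethogram: Ethogram | None = None, age_days: int | None = None
) -> TransitionCounts:
    """Read a transition-matrix TSV; verify any printed Σ margins.

    The first cell of the header is empty; an optional final Σ row and
    column carry margins, which must equal the recomputed sums.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    col_labels = [h for h in header[1:] if h]
    has_margin_col = bool(col_labels) and col_labels[-1] == MARGIN_LABEL
    if has_margin_col:
        col_labels = col_labels[:-1]
    rows: list[tuple[str, list[int]]] = []
    margin_row: list[int] | None = None
    for ln in lines[1:]:
        cells = ln.split("\t")
        lab, values = cells[0], cells[1:]
        values = [int(v) if v not in ("", "-", "–") else 0 for v in values]
        if lab == MARGIN_LABEL:
            margin_row = values
        else:
            rows.append((lab, values))
    row_labels = [lab for lab, _ in rows]
    if row_labels != col_labels:
        raise MatrixIntegrityError(
            f"{path}: row labels {row_labels} differ from column labels {col_labels}"
        )
    k = len(row_labels)
    n = np.zeros((k, k), dtype=np.int64)
    printed_row_sums: list[int | None] = []
    for i, (lab, values) in enumerate(rows):
        if has_margin_col:
            if len(values) != k + 1:
                raise MatrixIntegrityError(f"{path}: row {lab!r} has {len(values)} cells")
            n[i] = values[:k]
            printed_row_sums.append(values[k])
        else:
            n[i] = values[:k]
            printed_row_sums.append(None)
    tc = TransitionCounts(labels=row_labels, n=n, age_days=age_days)
    for i, printed in enumerate(printed_row_sums):
        if printed is not None and printed != tc.row_sums[i]:
            raise MatrixIntegrityError(
                f"{path}: printed row margin for {row_labels[i]!r} is {printed}, "
                f"recomputed {int(tc.row_sums[i])}"
            )
    if margin_row is not None:
        printed_cols = margin_row[:k]
        for j, printed in enumerate(printed_cols):
            if printed != tc.col_sums[j]:
                raise MatrixIntegrityError(
                    f"{path}: printed column margin for {row_labels[j]!r} is {printed}, "
                    f"recomputed {int(tc.col_sums[j])}"
                )
        if len(margin_row) > k and margin_row[k] != tc.total:
            raise MatrixIntegrityError(
                f"{path}: printed grand total {margin_row[k]} != {tc.total}"
            )
    if ethogram is not None:
        if set(row_labels) != set(ethogram.codes):
            raise EthogramError(
                f"{path}: matrix labels do not match ethogram codes: "
                f"{sorted(set(row_labels) ^ set(ethogram.codes))}"
            )
    return tc
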