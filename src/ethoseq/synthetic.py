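"""Semi-Markov generator of dyadic (and single-male) encounter logs.

Each fly alternates behavior bouts: the bout identity follows an
embedded first-order Markov chain with a structural-zero diagonal, and
the bout duration is drawn from a behavior-specific distribution
(log-normal for the four long non-interactive states; brief fixed-range
draws for interactive and point behaviors).  Two couplings tie the pair
together: every *hold* bout in one fly produces an equal-length
*immobilized* bout in its opponent (spliced into the opponent's
timeline), and an *approach* can elicit a brief *avoid* or *retreat*
response from the opponent.  Aggression rates are stationary across the
session, and each retreat belongs to either pair member with equal
probability (the two flies run identical, independent chains), so the
generated data are null for both escalation and dominance.

The per-age defaults mimic the study's qualitative ontogeny: rising
high-intensity aggression and hold duration, falling walking/standing
share, rising grooming/upside-down share, with the four major states
occupying at least 96% of session time at every age.  They are invented
mimics, not fits to the (undeposited) raw data.
"""

from __future__ import annotations

import bisect
import math
import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import yaml

from .ethogram import Ethogram, default_ethogram
from .events import EventLog, EventRecord, make_event_log

#: canonical behavior order for embedded matrices (matches the default ethogram)
LABELS = ["U", "B", "G", "I", "J", "T", "H", "Wr", "Av", "W", "Ap", "Lo", "L", "R", "Sti", "Sta"]

MAJOR_STATES = ("W", "Sta", "G", "U")

DEFAULT_AGES = (1, 2, 3, 4, 6)

#: fraction of session time allotted to each major state, by age
_BUDGET = {
    1: {"W": 0.360, "Sta": 0.400, "G": 0.200, "U": 0.010},
    2: {"W": 0.330, "Sta": 0.330, "G": 0.290, "U": 0.020},
    3: {"W": 0.310, "Sta": 0.250, "G": 0.370, "U": 0.040},
    4: {"W": 0.290, "Sta": 0.210, "G": 0.375, "U": 0.090},
    6: {"W": 0.273, "Sta": 0.172, "G": 0.383, "U": 0.160},
}

#: mean bout duration (s) of the major states
_DWELL_MEAN = {"W": 12.0, "Sta": 25.0, "G": 18.0, "U": 8.0}

#: occurrences / hour / individual for the brief behaviors, by age
_BRIEF_RATES = {
    #        1     2     3     4     6
    "L":   (0.5,  1.5,  3.0,  5.0,  6.0),
    "H":   (0.3,  1.5,  2.5,  3.2,  3.8),
    "Wr":  (0.8,  2.5,  4.0,  5.0,  6.0),
    "Lo":  (3.0,  2.5,  1.5,  1.2,  1.0),
    "Av":  (8.0,  7.0,  6.0,  5.0,  4.0),
    "R":   (2.0,  3.0,  4.0,  5.0,  6.0),
    "T":   (3.0,  3.0,  3.0,  3.0,  3.0),
    "Ap":  (15.0, 15.0, 15.0, 15.0, 15.0),
    "J":   (0.5,  1.0,  2.0,  1.5,  1.2),
    "Sti": (3.0,  2.5,  2.0,  1.5,  1.0),
    "B":   (0.5,  1.5,  2.5,  2.0,  1.8),
}

#: mean hold-bout duration (s) by age (rises ~2 s -> ~8.2 s)
_HOLD_MEAN = {1: 2.0, 2: 3.0, 3: 5.0, 4: 6.5, 6: 8.2}

#: opponent response probabilities to an approach, by age
_APPROACH_RESPONSE = {
    1: {"Av": 0.25, "R": 0.05, "none": 0.70},
    2: {"Av": 0.20, "R": 0.10, "none": 0.70},
    3: {"Av": 0.15, "R": 0.15, "none": 0.70},
    4: {"Av": 0.12, "R": 0.18, "none": 0.70},
    6: {"Av": 0.10, "R": 0.20, "none": 0.70},
}

#: brief-duration ranges (s); holds are log-normal, handled separately
_BRIEF_RANGE = {
    "L": (0.2, 0.5),
    "Wr": (0.5, 3.5),
    "R": (0.3, 1.0),
    "Av": (0.5, 2.0),
    "J": (0.2, 0.5),
}
_BRIEF_DEFAULT_RANGE = (0.2, 3.0)


@dataclass
class SynthConfig:
    """Age-indexed semi-Markov parameters for session generation."""

    age_days: int
    labels: list[str]
    embedded: np.ndarray  # k x k, zero diagonal, rows sum to 1
    bout_rates_per_hour: dict[str, float]
    dwell_mean_s: dict[str, float]
    dwell_sd_s: dict[str, float]
    approach_response: dict[str, float]
    hold_duration_mean_s: float
    hold_triggers_immobilized: bool = True
    session_s: float = 3600.0

    def __post_init__(self) -> None:
        self.embedded = np.asarray(self.embedded, dtype=float)
        k = len(self.labels)
        if self.embedded.shape != (k, k):
            raise ValueError("embedded matrix shape does not match labels")
        if np.any(np.diag(self.embedded) != 0):
            raise ValueError("embedded diagonal must be zero")
        if np.any(self.embedded < 0) or np.any(self.embedded > 1):
            raise ValueError("embedded probabilities must lie in [0, 1]")
        rows = self.embedded.sum(axis=1)
        live = rows > 0
        if np.any(np.abs(rows[live] - 1.0) > 1e-9):
            raise ValueError("embedded rows must sum to 1")
        if any(v <= 0 for v in self.dwell_mean_s.values()):
            raise ValueError("dwell means must be positive")
        resp = self.approach_response
        if abs(sum(resp.values()) - 1.0) > 1e-9 or any(not 0 <= p <= 1 for p in resp.values()):
            raise ValueError("approach_response must be a probability distribution")

    @property
    def hi_rate_per_hour(self) -> float:
        """Configured occurrences/hour/individual of lunge + hold + wrestle."""
        r = self.bout_rates_per_hour
        return r.get("L", 0.0) + r.get("H", 0.0) + r.get("Wr", 0.0)

    def decoupled(self) -> "SynthConfig":
        """Copy with inter-fly couplings off (no holds, no approach responses).

        With couplings silenced each fly's sequence is exactly the
        embedded chain, which is what parameter-recovery checks need.
        """
        rates = dict(self.bout_rates_per_hour)
        rates["H"] = 0.0
        return replace(
            self,
            embedded=_embedded_from_rates(self.labels, rates),
            bout_rates_per_hour=rates,
            approach_response={"Av": 0.0, "R": 0.0, "none": 1.0},
        )

    def with_bout_rates(self, **rates: float) -> "SynthConfig":
        """Copy with some bout rates replaced; the embedded chain is rebuilt."""
        r = {**self.bout_rates_per_hour, **rates}
        return replace(
            self, embedded=_embedded_from_rates(self.labels, r), bout_rates_per_hour=r
        )

    def enriched(self, src: str, dst: str, factor: float) -> "SynthConfig":
        """Copy with one embedded transition probability multiplied by ``factor``.

        The source row is renormalized, so the marked transition occurs
        ``factor`` times more often than under quasi-independence.
        """
        emb = self.embedded.copy()
        i, j = self.labels.index(src), self.labels.index(dst)
        emb[i, j] *= factor
        emb[i] /= emb[i].sum()
        return replace(self, embedded=emb)

    def to_dict(self) -> dict:
        return {
            "age_days": self.age_days,
            "labels": list(self.labels),
            "embedded": self.embedded.tolist(),
            "bout_rates_per_hour": dict(self.bout_rates_per_hour),
            "dwell_mean_s": dict(self.dwell_mean_s),
            "dwell_sd_s": dict(self.dwell_sd_s),
            "approach_response": dict(self.approach_response),
            "hold_duration_mean_s": self.hold_duration_mean_s,
            "hold_triggers_immobilized": self.hold_triggers_immobilized,
            "session_s": self.session_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        return cls(**{**d, "embedded": np.asarray(d["embedded"], dtype=float)})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _embedded_from_rates(labels: Sequence[str], rates: dict[str, float]) -> np.ndarray:
    """Embedded chain whose stationary bout frequencies equal the given rates.

    Builds a symmetric flow matrix S with zero diagonal and row sums
    proportional to the rates (iterative proportional scaling with
    symmetrization, starting from the product form), then sets
    P(i -> j) = S_ij / row_i.  The resulting chain is reversible, as
    close to quasi-independence as the margins allow, and its stationary
    bout-frequency distribution is exactly the normalized rate vector.
    Feasible only when no behavior holds more than half of all bouts
    (structural bound for a chain that never repeats a state).

    *Immobilized* never occurs spontaneously (rate 0); it arises only
    through the hold coupling.
    """
    f = np.array([rates.get(lab, 0.0) for lab in labels], dtype=float)
    if np.any(f < 0):
        raise ValueError("bout rates must be nonnegative")
    total = f.sum()
    if total <= 0:
        raise ValueError("at least one positive bout rate required")
    rho = f / total
    if rho.max() >= 0.5:
        lab = labels[int(rho.argmax())]
        raise ValueError(
            f"behavior {lab!r} holds {rho.max():.3f} of all bouts; a chain that "
            "never repeats a state cannot exceed 0.5"
        )
    live = rho > 0
    S = np.outer(rho, rho)
    np.fill_diagonal(S, 0.0)
    for _ in range(10_000):
        rs = S.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(rs > 0, rho / np.where(rs > 0, rs, 1.0), 0.0)
        S = S * scale[:, None]
        S = 0.5 * (S + S.T)
        disc = np.abs(S.sum(axis=1) - rho)[live].max()
        if disc < 1e-12:
            break
    rs = S.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(rs > 0, S / np.where(rs > 0, rs, 1.0), 0.0)
    return P


def default_parameters(age_days: int) -> SynthConfig:
    """Documented default :class:`SynthConfig` for one study age cohort."""
    if age_days not in DEFAULT_AGES:
        raise ValueError(f"unsupported age {age_days}; supported: {DEFAULT_AGES}")
    col = DEFAULT_AGES.index(age_days)
    rates = {b: v[col] for b, v in _BRIEF_RATES.items()}
    for state in MAJOR_STATES:
        rates[state] = 3600.0 * _BUDGET[age_days][state] / _DWELL_MEAN[state]
    rates["I"] = 0.0
    dwell_mean = dict(_DWELL_MEAN)
    dwell_sd = {s: 0.6 * m for s, m in dwell_mean.items()}
    return SynthConfig(
        age_days=age_days,
        labels=list(LABELS),
        embedded=_embedded_from_rates(LABELS, rates),
        bout_rates_per_hour=rates,
        dwell_mean_s=dwell_mean,
        dwell_sd_s=dwell_sd,
        approach_response=dict(_APPROACH_RESPONSE[age_days]),
        hold_duration_mean_s=_HOLD_MEAN[age_days],
    )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    mu = math.log(mean * mean / math.sqrt(var + mean * mean))
    sigma = math.sqrt(math.log(1.0 + var / (mean * mean)))
    return mu, sigma


def _simulate_chain(config: SynthConfig, rng: random.Random) -> list[tuple[str, float, float]]:
    """One fly's (behavior, onset, offset) stream, truncated at session end."""
    labels = config.labels
    emb = config.embedded
    cumrows = [list(np.cumsum(emb[i])) for i in range(len(labels))]
    live = [i for i in range(len(labels)) if cumrows[i] and cumrows[i][-1] > 0]
    # start from the long-run bout frequencies of the quasi-independent chain
    start_weights = [config.bout_rates_per_hour.get(lab, 0.0) for lab in labels]
    total_w = sum(start_weights)
    u = rng.random() * total_w
    acc = 0.0
    state = live[0]
    for i, w in enumerate(start_weights):
        acc += w
        if u <= acc and w > 0:
            state = i
            break
    ln_cache = {
        s: _lognormal_params(config.dwell_mean_s[s], config.dwell_sd_s[s])
        for s in config.dwell_mean_s
    }
    hold_mu, hold_sigma = _lognormal_params(
        config.hold_duration_mean_s, 0.5 * config.hold_duration_mean_s
    )
    session = config.session_s
    t = 0.0
    out: list[tuple[str, float, float]] = []
    while t < session:
        code = labels[state]
        if code in ln_cache:
            mu, sigma = ln_cache[code]
            d = rng.lognormvariate(mu, sigma)
        elif code == "H":
            d = rng.lognormvariate(hold_mu, hold_sigma)
        else:
            lo, hi = _BRIEF_RANGE.get(code, _BRIEF_DEFAULT_RANGE)
            d = rng.uniform(lo, hi)
        end = min(t + d, session)
        out.append((code, t, end))
        t = end
        row = cumrows[state]
        if row[-1] <= 0:
            break
        u = rng.random() * row[-1]
        state = bisect.bisect_left(row, u)
    return out


def _splice(
    stream: list[tuple[str, float, float]], code: str, t0: float, t1: float
) -> list[tuple[str, float, float]]:
    """Insert a bout [t0, t1] into a fly's stream, clipping what it overlaps."""
    out: list[tuple[str, float, float]] = []
    inserted = False
    for b, s, e in stream:
        if e <= t0 or s >= t1:
            out.append((b, s, e))
            continue
        if s < t0:
            out.append((b, s, t0))
        if not inserted:
            out.append((code, t0, t1))
            inserted = True
        if e > t1:
            out.append((b, t1, e))
    if not inserted:
        out.append((code, t0, t1))
    out.sort(key=lambda r: r[1])
    return out


def generate_session(
    config: SynthConfig,
    seed: int,
    session_id: str = "s0",
    n_subjects: int = 2,
    ethogram: Ethogram | None = None,
) -> EventLog:
    """Generate one session; identical config + seed give identical logs.

    ``n_subjects=1`` emulates the single-male controls: interactive
    behaviors, bobbing, and jump are silenced, and no couplings apply.
    """
    rng = random.Random(seed)
    if n_subjects == 1:
        rates = dict(config.bout_rates_per_hour)
        for b in ("Ap", "T", "Av", "R", "Lo", "L", "H", "Wr", "B", "J"):
            rates[b] = 0.0
        # without an opponent, walking runs in longer uninterrupted bouts
        dwell_mean = dict(config.dwell_mean_s)
        dwell_mean["W"] = 1.4 * dwell_mean["W"]
        rates["W"] = rates["W"] / 1.4
        config = replace(
            config,
            embedded=_embedded_from_rates(config.labels, rates),
            bout_rates_per_hour=rates,
            dwell_mean_s=dwell_mean,
            dwell_sd_s={s: 0.6 * m for s, m in dwell_mean.items()},
            approach_response={"Av": 0.0, "R": 0.0, "none": 1.0},
        )
        streams = [_simulate_chain(config, rng)]
    elif n_subjects == 2:
        streams = [_simulate_chain(config, rng), _simulate_chain(config, rng)]
        streams = _apply_couplings(streams, config, rng)
    else:
        raise ValueError("n_subjects must be 1 or 2")

    records = []
    for idx, stream in enumerate(streams, start=1):
        for code, s, e in stream:
            if e - s <= 0 and code not in ("J",):  # drop zero-length clipping residues
                continue
            records.append(
                EventRecord(
                    session_id=session_id,
                    cohort_age_days=config.age_days,
                    subject_id=str(idx),
                    behavior=code,
                    onset_s=round(s, 6),
                    offset_s=round(e, 6),
                )
            )
    return make_event_log(
        records,
        session_duration_s=config.session_s,
        ethogram=ethogram,
        session_id=session_id,
        cohort_age_days=config.age_days,
    )


def _apply_couplings(
    streams: list[list[tuple[str, float, float]]],
    config: SynthConfig,
    rng: random.Random,
) -> list[list[tuple[str, float, float]]]:
    """Hold -> immobilized mirroring and approach responses between flies."""
    # 1. keep a non-overlapping set of holds across both flies
    holds: list[tuple[float, float, int]] = []  # (t0, t1, fly_index)
    for fly, stream in enumerate(streams):
        for code, s, e in stream:
            if code == "H":
                holds.append((s, e, fly))
    holds.sort()
    kept: list[tuple[float, float, int]] = []
    dropped: set[tuple[int, float]] = set()
    last_end = -1.0
    for s, e, fly in holds:
        if s >= last_end:
            kept.append((s, e, fly))
            last_end = e
        else:
            dropped.add((fly, s))
    if dropped:
        for fly in range(2):
            streams[fly] = [
                (b, s, e)
                for b, s, e in streams[fly]
                if not (b == "H" and (fly, s) in dropped)
            ]
    # 2. splice the opponent's immobilized bout for each kept hold
    if config.hold_triggers_immobilized:
        for s, e, fly in kept:
            other = 1 - fly
            streams[other] = _splice(streams[other], "I", s, e)
    # 3. approach responses
    resp = config.approach_response
    p_av, p_r = resp.get("Av", 0.0), resp.get("R", 0.0)
    if p_av + p_r > 0:
        blocked = [(s, e) for s, e, _ in kept]
        for fly in range(2):
            other = 1 - fly
            for code, s, e in list(streams[fly]):
                if code != "Ap":
                    continue
                u = rng.random()
                if u < p_av:
                    response = "Av"
                elif u < p_av + p_r:
                    response = "R"
                else:
                    continue
                lo, hi = _BRIEF_RANGE.get(response, _BRIEF_DEFAULT_RANGE)
                d = rng.uniform(lo, hi)
                t0 = e
                t1 = min(t0 + d, config.session_s)
                if t1 <= t0 or any(t0 < he and t1 > hs for hs, he in blocked):
                    continue
                streams[other] = _splice(streams[other], response, t0, t1)
    return streams


def engineer_significance_matrix(
    base,
    significant: set[tuple[str, str]],
    total: int,
    alpha: float = 0.05,
    margin: float = 0.15,
    max_rounds: int = 600,
):
    """Construct a count matrix with a prescribed set of significant cells.

    Starting from ``base`` (a TransitionCounts whose labels define the
    layout), counts are shifted between cells until, under the
    quasi-independence fit and the simultaneous Freeman-Tukey criterion
    at ``alpha``, exactly the cells in ``significant`` exceed the
    criterion — each with at least ``margin`` of clearance on the
    deviate scale — and the grand total equals ``total``.  Adjustments
    move counts from "safe" cells (far below the criterion) of the same
    row or column, mirroring how excesses and deficits must balance
    within the fitted margins; every behavior keeps a nonzero row and
    column.

    Deterministic; intended for building test matrices with known
    significance structure (e.g. reconstructions of unpublished cohort
    matrices, or enrichment scenarios).
    """
    from .quasi_independence import QuasiIndependence
    from .transitions import TransitionCounts

    labels = list(base.labels)
    k = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    want = np.zeros((k, k), dtype=bool)
    for a, b in significant:
        if a == b:
            raise ValueError("diagonal cells cannot be significant")
        want[idx[a], idx[b]] = True
    n = np.asarray(base.n, dtype=float)
    n = np.maximum(np.round(n * total / n.sum()), 0.0)
    n[want & (n == 0)] = 1.0
    np.fill_diagonal(n, 0.0)
    off = ~np.eye(k, dtype=bool)

    def donors_for(i, j, z, c, axis):
        """Safe donor cells in row i (axis=0) or column j (axis=1)."""
        cells = []
        if axis == 0:
            for s in range(k):
                if s != i and s != j and not want[i, s] and z[i, s] < c - 0.4 and n[i, s] > 0:
                    cells.append((i, s))
        else:
            for r in range(k):
                if r != i and r != j and not want[r, j] and z[r, j] < c - 0.4 and n[r, j] > 0:
                    cells.append((r, j))
        cells.sort(key=lambda rc: -n[rc])
        return cells

    def take(cells, amount):
        """Remove up to ``amount`` counts from donor cells; return taken."""
        got = 0.0
        for r, s in cells:
            if got >= amount:
                break
            avail = n[r, s]
            if n[r].sum() - avail == 0 or n[:, s].sum() - avail == 0:
                avail -= 1.0  # keep the behavior observed
            step = min(avail, max(1.0, round(0.3 * n[r, s])), amount - got)
            if step > 0:
                n[r, s] -= step
                got += step
        return got

    for _ in range(max_rounds):
        tc = TransitionCounts(labels=labels, n=n.astype(np.int64))
        res = QuasiIndependence(tc, alpha=alpha).fit(tol=1e-8)
        z = np.nan_to_num(res.deviates, nan=-np.inf)
        c = res.criterion
        m = res.expected
        low = want & (z < c + margin) & off
        high = ~want & (z > c - margin) & off
        diff = total - int(n.sum())
        if not low.any() and not high.any() and diff == 0:
            return tc
        for i, j in np.argwhere(low):
            need = max(1.0, np.round(0.12 * (m[i, j] + 1.0)))
            got = take(donors_for(i, j, z, c, axis=0), need)
            if got < need:
                got += take(donors_for(i, j, z, c, axis=1), need - got)
            n[i, j] += max(got, 1.0)
        row_tot = n.sum(axis=1)
        col_tot = n.sum(axis=0)
        for i, j in np.argwhere(high):
            step = min(n[i, j], max(1.0, round(0.15 * n[i, j])))
            if row_tot[i] - step <= 0 or col_tot[j] - step <= 0:
                step = min(step, n[i, j] - 1.0)
            if step > 0:
                n[i, j] -= step
                # re-deposit on a safe cell of the same row to keep mass local
                for r, s in donors_for(i, j, z, c, axis=0)[::-1]:
                    if z[r, s] < c - 0.8:
                        n[r, s] += step
                        break
            if n[i, j] > 0 and m[i, j] < 0.75:
                # a lone count on a near-zero expectation stays flagged no
                # matter what; grow the column margin to dilute the deviate
                grow = [
                    r
                    for r in np.argsort(-row_tot)
                    if r != i and r != j and not want[r, j] and z[r, j] < c - 0.6
                ][:2]
                for r in grow:
                    n[r, j] += 1.0
        # restore the grand total through the deepest safe cells
        diff = total - int(n.sum())
        if diff != 0:
            safe = np.argwhere(~want & off & (z < c - 0.8) & (m > 0.5))
            safe = sorted(map(tuple, safe), key=lambda rc: -m[rc])
            sign = 1.0 if diff > 0 else -1.0
            remaining = abs(diff)
            for r, s in safe:
                if remaining == 0:
                    break
                room = max(1, int(0.2 * np.sqrt(m[r, s] + 1.0)))
                step = min(remaining, room)
                if sign < 0:
                    step = min(step, int(n[r, s]) - 1)
                if step > 0:
                    n[r, s] += sign * step
                    remaining -= step
    raise RuntimeError("could not realize the requested significance pattern")


def generate_cohort(
    age_days_or_config,
    n_pairs: int,
    seed: int,
    session_prefix: str | None = None,
    n_subjects: int = 2,
    ethogram: Ethogram | None = None,
) -> list[EventLog]:
    """Generate ``n_pairs`` independent sessions of one cohort.

    Accepts either an age (uses :func:`default_parameters`) or an explicit
    :class:`SynthConfig`.  Session seeds are derived from ``seed`` by a
    fixed increment, so a cohort is reproducible from one integer.
    """
    if isinstance(age_days_or_config, SynthConfig):
        config = age_days_or_config
    else:
        config = default_parameters(int(age_days_or_config))
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    prefix = session_prefix or f"day{config.age_days}"
    return [
        generate_session(
            config,
            seed=seed + i,
            session_id=f"{prefix}_p{i:03d}",
            n_subjects=n_subjects,
            ethogram=ethogram,
        )
        for i in range(n_pairs)
    ]
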