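"""Kaplan–Meier estimation, log-rank testing, and the multi-sampling screen.

A candidate gene set is screened for survival relevance by splitting
patients into G1 (at least ``frac`` of the set's genes up-regulated, i.e.
normalized expression >= ``tau_up``) versus G2 (every gene of the set at
normal expression, below ``tau_up``); patients satisfying neither rule are
excluded.  The two groups' survivor curves are compared by the log-rank
statistic in its observed-versus-expected form,

    X^2 = (O1 - E1)^2 / E1 + (O2 - E2)^2 / E2,

referred to chi-square with one degree of freedom.  The variance-normalized
Mantel–Haenszel form is available behind a flag for cross-validation
against standard survival packages.  Because G1 and G2 can be badly
imbalanced, the screen repeats the test on repeated equal-size random
subsamples and requires a pass fraction, rather than trusting one test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalRecord",
    "GroupSplit",
    "KMCurve",
    "LogRankResult",
    "assign_groups",
    "km_estimate",
    "logrank_test",
    "multisample_survival_test",
    "km_curve_to_tsv",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in months and whether death was observed."""

    sample_id: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.sample_id}")


@dataclass(frozen=True)
class GroupSplit:
    g1: tuple[str, ...]
    g2: tuple[str, ...]
    excluded: tuple[str, ...]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survivor curve: S(t) evaluated at the distinct event times."""

    times: np.ndarray
    surv: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.surv[idx])


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    o1: float
    e1: float
    o2: float
    e2: float


def _as_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    """Accept SurvivalRecord sequences, (times, events) pairs, or DataFrames."""
    if isinstance(records, tuple) and len(records) == 2:
        t, e = records
        return np.asarray(t, dtype=float), np.asarray(e, dtype=bool)
    if isinstance(records, pd.DataFrame):
        return records["time"].to_numpy(float), records["event"].to_numpy(bool)
    t = np.array([rec.time for rec in records], dtype=float)
    e = np.array([rec.event for rec in records], dtype=bool)
    return t, e


def assign_groups(
    gene_set,
    V_norm: pd.DataFrame,
    tau_up: float = 0.5,
    frac: float = 0.8,
) -> GroupSplit:
    """Split samples by how much of the gene set is up-regulated.

    A gene counts as up-regulated in a sample when its normalized value is
    >= ``tau_up``.  G1: fraction of up-regulated set genes >= ``frac``.
    G2: that fraction is exactly 0 (all genes normal).  Everything else is
    excluded from the comparison.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in V_norm.index]
    if missing:
        raise KeyError(f"genes absent from the expression matrix: {sorted(missing)}")
    up = (V_norm.loc[genes] >= tau_up).mean(axis=0)
    g1 = tuple(up.index[up >= frac])
    g2 = tuple(up.index[up == 0])
    excluded = tuple(up.index[(up > 0) & (up < frac)])
    # a sample with frac == 0 could satisfy both rules only if frac <= 0
    return GroupSplit(g1=g1, g2=g2, excluded=excluded)


def km_estimate(records) -> KMCurve:
    """Product-limit estimator S(t_i) = S(t_{i-1}) (1 - d_i / n_i).

    Censored patients leave the risk set after their censoring time; ties
    between an event and a censoring at the same time are resolved by
    processing the event first (the standard convention).
    """
    t, e = _as_arrays(records)
    if t.size == 0:
        raise ValueError("no survival records")
    event_times = np.unique(t[e])
    surv = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, tt in enumerate(event_times):
        n_i = int(np.sum(t >= tt))
        d_i = int(np.sum((t == tt) & e))
        s *= 1.0 - d_i / n_i
        surv[i] = s
        at_risk[i] = n_i
    return KMCurve(times=event_times, surv=surv, at_risk=at_risk)


def _logrank_tables(t1, e1, t2, e2):
    """Per-event-time risk/death tables over the pooled distinct event times."""
    times = np.unique(np.concatenate([t1[e1], t2[e2]]))
    n1 = (t1[None, :] >= times[:, None]).sum(axis=1).astype(float)
    n2 = (t2[None, :] >= times[:, None]).sum(axis=1).astype(float)
    d1 = ((t1[None, :] == times[:, None]) & e1[None, :]).sum(axis=1).astype(float)
    d2 = ((t2[None, :] == times[:, None]) & e2[None, :]).sum(axis=1).astype(float)
    return times, n1, n2, d1, d2


def logrank_test(a, b, variance_normalized: bool = False) -> LogRankResult:
    """Two-group log-rank test.

    Default statistic is (O1-E1)^2/E1 + (O2-E2)^2/E2 against chi2(1).
    With ``variance_normalized`` the Mantel–Haenszel form
    (O1-E1)^2 / Var(O1-E1) is used instead (the form standard packages
    implement).
    """
    t1, e1 = _as_arrays(a)
    t2, e2 = _as_arrays(b)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (e1.any() or e2.any()):
        raise ValueError("no events in either group")
    _, n1, n2, d1, d2 = _logrank_tables(t1, e1, t2, e2)
    n = n1 + n2
    d = d1 + d2
    e1_exp = (d * n1 / n).sum()
    e2_exp = (d * n2 / n).sum()
    o1, o2 = d1.sum(), d2.sum()
    if variance_normalized:
        with np.errstate(invalid="ignore", divide="ignore"):
            var = np.where(
                n > 1, d * (n1 / n) * (n2 / n) * (n - d) / (n - 1), 0.0
            ).sum()
        if var <= 0:
            raise ValueError("log-rank variance is zero; groups degenerate")
        stat = (o1 - e1_exp) ** 2 / var
    else:
        if e1_exp <= 0 or e2_exp <= 0:
            bad = "G1" if e1_exp <= 0 else "G2"
            raise ValueError(f"zero expected events in group {bad}; statistic undefined")
        stat = (o1 - e1_exp) ** 2 / e1_exp + (o2 - e2_exp) ** 2 / e2_exp
    return LogRankResult(
        statistic=float(stat),
        p_value=float(sps.chi2.sf(stat, df=1)),
        o1=float(o1),
        e1=float(e1_exp),
        o2=float(o2),
        e2=float(e2_exp),
    )


def multisample_survival_test(
    g1,
    g2,
    reps: int = 100,
    alpha: float = 0.05,
    pass_frac: float = 0.8,
    seed: int = 0,
) -> tuple[bool, float]:
    """Repeated equal-size log-rank screen of G1 versus G2.

    Each repetition keeps the smaller group whole and draws, without
    replacement, an equally sized subsample from the larger group, then
    runs the log-rank test.  The screen passes when the fraction of
    repetitions with p < alpha exceeds ``pass_frac``.  Repetitions whose
    subsample is degenerate (no events, or zero expected events in a
    group) count as non-significant.
    """
    t1, e1 = _as_arrays(g1)
    t2, e2 = _as_arrays(g2)
    if t1.size < 2 or t2.size < 2:
        raise ValueError("both groups need at least 2 samples")
    rng = np.random.default_rng(seed)
    k = min(t1.size, t2.size)
    hits = 0
    n_degenerate = 0
    for _ in range(reps):
        i1 = rng.choice(t1.size, size=k, replace=False) if t1.size > k else np.arange(k)
        i2 = rng.choice(t2.size, size=k, replace=False) if t2.size > k else np.arange(k)
        try:
            res = logrank_test((t1[i1], e1[i1]), (t2[i2], e2[i2]))
        except ValueError:
            n_degenerate += 1
            continue
        if res.p_value < alpha:
            hits += 1
    if n_degenerate:
        logger.info("%d/%d degenerate log-rank repetitions counted non-significant",
                    n_degenerate, reps)
    pass_rate = hits / reps
    return pass_rate > pass_frac, pass_rate


def km_curve_to_tsv(curve: KMCurve) -> str:
    lines = ["time\tsurvival\tat_risk"]
    for t, s, n in zip(curve.times, curve.surv, curve.at_risk):
        lines.append(f"{t:.6g}\t{s:.6g}\t{int(n)}")
    return "\n".join(lines) + "\n"
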