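"""Monitoring summaries and the Remedy Confirmation Clause (RCC) decision.

Fish monitoring is performed on composites (three individuals pooled per
laboratory analysis); the composite analysis, not the individual fish, is the
statistical unit.  Water nondetects are substituted at half the method
detection limit.  Station summaries are reported as mean +/- 2 SEM.

The RCC decision against a station's risk-based target is implemented as two
one-sided one-sample Student's t-tests at level alpha:

* success      - mean significantly below the target (H1: mu < target),
* failure      - mean significantly above the target (H1: mu > target),
* inconclusive - neither margin is statistically significant.

Each station carries its own clause, so no multiplicity adjustment is applied
across stations.  Evidence of decline from pre-remedy concentrations uses a
one-sided Welch two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CompositeSample",
    "RCCSpec",
    "RCCDecision",
    "substitute_nondetects",
    "summarize",
    "rcc_test",
    "decline_test",
]


@dataclass(frozen=True)
class CompositeSample:
    """One composite analysis (n_fish individuals pooled)."""

    station: str
    species: str
    date: str
    concentration: float
    n_fish: int = 3
    basis: str = "whole_body"  # or "fillet"

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")
        if self.basis not in ("whole_body", "fillet"):
            raise ValueError(f"unknown basis {self.basis!r}")


#: default station targets (mg/kg) and measurement basis
DEFAULT_TARGETS = {
    "CBVP": (2.3, "whole_body"),
    "RCVP": (0.9, "whole_body"),
    "RC43": (0.2, "fillet"),
}


@dataclass(frozen=True)
class RCCSpec:
    """Compliance targets and test configuration."""

    targets: dict = field(default_factory=lambda: dict(DEFAULT_TARGETS))
    alpha: float = 0.05
    review_interval_yr: float = 5.0
    min_composites: int = 3

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for st, (tgt, _basis) in self.targets.items():
            if tgt <= 0:
                raise ValueError(f"target for {st} must be positive")


@dataclass(frozen=True)
class RCCDecision:
    outcome: str  # success | failure | inconclusive
    station: str
    target: float
    mean: float
    sem: float
    t_statistic: float
    p_below: float   # one-sided p for H1: mu < target
    p_above: float   # one-sided p for H1: mu > target
    n: int


def substitute_nondetects(values, detected, mdl):
    """Replace nondetects with MDL/2; detects pass through unchanged."""
    v = np.asarray(values, dtype=float)
    det = np.asarray(detected, dtype=bool)
    mdl = np.broadcast_to(np.asarray(mdl, dtype=float), v.shape)
    if np.any(~det & ~(mdl > 0)):
        raise ValueError("nondetect without a positive MDL")
    return np.where(det, v, mdl / 2.0)


def summarize(values):
    """Arithmetic mean, SEM and the mean +/- 2 SEM interval.

    The inputs are composite analyses; with fewer than two the interval is
    undefined and flagged via ``sem = nan``.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0:
        raise ValueError("no samples")
    mean = float(v.mean())
    if n < 2:
        return {"mean": mean, "sem": float("nan"), "n": n,
                "interval": (float("nan"), float("nan")), "undefined_interval": True}
    sem = float(v.std(ddof=1) / np.sqrt(n))
    return {"mean": mean, "sem": sem, "n": n,
            "interval": (mean - 2 * sem, mean + 2 * sem),
            "undefined_interval": False}


def rcc_test(samples, spec: RCCSpec, station: str) -> RCCDecision:
    """Three-outcome compliance decision for one station.

    ``samples`` is a sequence of :class:`CompositeSample` (their basis must
    match the station target's basis) or a plain array of composite values.
    """
    target, basis = spec.targets[station]
    if len(samples) and isinstance(samples[0], CompositeSample):
        for s in samples:
            if s.basis != basis:
                raise ValueError(
                    f"basis mismatch at {station}: sample {s.basis} vs target {basis}")
        values = np.array([s.concentration for s in samples], dtype=float)
    else:
        values = np.asarray(samples, dtype=float)
    n = len(values)
    if n < spec.min_composites:
        raise ValueError(f"need >= {spec.min_composites} composites, got {n}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    sem = sd / np.sqrt(n)
    if sem == 0:
        t = -np.inf if mean < target else (np.inf if mean > target else 0.0)
    else:
        t = (mean - target) / sem
    p_below = float(stats.t.cdf(t, df=n - 1))   # H1: mu < target
    p_above = float(stats.t.sf(t, df=n - 1))    # H1: mu > target
    if p_below < spec.alpha:
        outcome = "success"
    elif p_above < spec.alpha:
        outcome = "failure"
    else:
        outcome = "inconclusive"
    return RCCDecision(outcome=outcome, station=station, target=target,
                       mean=mean, sem=float(sem), t_statistic=float(t),
                       p_below=p_below, p_above=p_above, n=n)


def decline_test(pre, post, alpha: float = 0.05):
    """One-sided Welch t-test for decline (H1: post < pre)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) < 2 or len(post) < 2:
        raise ValueError("both groups need n >= 2")
    res = stats.ttest_ind(post, pre, equal_var=False, alternative="less")
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "significant": bool(res.pvalue < alpha)}
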