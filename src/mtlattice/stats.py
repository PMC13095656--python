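"""Per-condition summaries and two-group comparison of lattice spacings.

The unit of replication is the microtubule: each measurement is one
microtubule's average protomer spacing (from its summed power spectrum),
and group statistics pool microtubules within a condition.  Intervals use
the Student t distribution; the two-group comparison is an unpaired
Welch (unequal-variance) t test with a Welch-Satterthwaite confidence
interval on the difference of means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "SpacingMeasurement",
    "GroupStats",
    "GroupComparison",
    "group_stats",
    "compare_groups",
]


@dataclass
class SpacingMeasurement:
    """One microtubule's measured protomer spacing."""

    mt_id: str
    condition: str
    spacing: float | None  # Å; None when unusable
    n_segments: int = 0
    usable: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spacing is None:
            self.usable = False
        elif self.usable and not self.spacing > 0:
            raise ValueError(
                f"{self.mt_id}: usable measurement needs positive spacing, got {self.spacing}"
            )


@dataclass
class GroupStats:
    """Mean, s.d. and 95% CI of per-microtubule spacings in one condition."""

    condition: str
    n: int
    mean: float
    sd: float
    ci95: tuple[float, float]


@dataclass
class GroupComparison:
    """Welch two-sample comparison of per-microtubule spacings."""

    difference: float  # mean(a) - mean(b), Å
    ci95: tuple[float, float]
    t: float
    df: float
    p: float
    test: str = "Welch two-sample t (unpaired, per-microtubule)"


def _usable_values(measurements: list[SpacingMeasurement]) -> np.ndarray:
    vals = [m.spacing for m in measurements if m.usable and m.spacing is not None]
    dropped = len(measurements) - len(vals)
    if dropped:
        logger.info("excluded %d unusable measurement(s)", dropped)
    return np.asarray(vals, dtype=float)


def group_stats(
    measurements: list[SpacingMeasurement], condition: str | None = None
) -> GroupStats:
    """Sample mean, s.d. (n-1 denominator) and t-based 95% CI.

    Unusable measurements are excluded (and logged); at least two usable
    measurements are required.
    """
    vals = _usable_values(measurements)
    n = len(vals)
    if n < 2:
        raise ValueError(f"need >= 2 usable measurements, got {n}")
    if condition is None:
        conds = {m.condition for m in measurements if m.usable}
        condition = conds.pop() if len(conds) == 1 else "mixed"
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    half = float(sps.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    return GroupStats(condition=condition, n=n, mean=mean, sd=sd, ci95=(mean - half, mean + half))


def compare_groups(
    a: list[SpacingMeasurement], b: list[SpacingMeasurement]
) -> GroupComparison:
    """Welch t test on unpaired per-microtubule spacings (a minus b)."""
    va, vb = _usable_values(a), _usable_values(b)
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("each group needs >= 2 usable measurements")
    na, nb = len(va), len(vb)
    ma, mb = va.mean(), vb.mean()
    sa2, sb2 = va.var(ddof=1), vb.var(ddof=1)
    se2 = sa2 / na + sb2 / nb
    diff = float(ma - mb)
    if se2 == 0:
        # degenerate: both groups constant
        p = 1.0 if diff == 0 else 0.0
        t_stat, df = 0.0 if diff == 0 else np.inf, float(na + nb - 2)
        return GroupComparison(difference=diff, ci95=(diff, diff), t=t_stat, df=df, p=p)
    se = float(np.sqrt(se2))
    t_stat = diff / se
    df = float(se2**2 / ((sa2 / na) ** 2 / (na - 1) + (sb2 / nb) ** 2 / (nb - 1)))
    p = float(2.0 * sps.t.sf(abs(t_stat), df))
    half = float(sps.t.ppf(0.975, df)) * se
    return GroupComparison(
        difference=diff, ci95=(diff - half, diff + half), t=float(t_stat), df=df, p=p
    )
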