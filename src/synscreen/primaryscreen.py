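"""Primary combination screen: Bliss excess at fixed EC25 doses.

Every unordered pair of compounds is tested at a single dose per drug (the
EC25, a deliberately modest effect level so neither drug saturates the
response).  Synergy is read from the Bliss independence excess

    excess = V(A+B) - V(A) * V(B)

computed on viability fractions per technical replicate; negative values
indicate stronger-than-independent killing.  Significance is a one-sample
t-test of the replicate excesses against zero, and a pair is a hit when
p < alpha with a negative mean excess.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CombinationMeasurement",
    "BlissExcessResult",
    "enumerate_pairs",
    "bliss_excess",
    "evaluate_pair",
    "select_hits",
]


@dataclasses.dataclass(frozen=True)
class CombinationMeasurement:
    """Replicate viabilities for one pair: each drug alone and combined,
    at fixed EC25 doses."""

    pair: tuple[str, str]
    va: tuple[float, ...]
    vb: tuple[float, ...]
    vab: tuple[float, ...]
    dose_a: float = float("nan")
    dose_b: float = float("nan")

    def __post_init__(self):
        if self.pair[0] == self.pair[1]:
            raise ValueError(f"pair members must be distinct: {self.pair}")
        for name, arm in (("va", self.va), ("vb", self.vb), ("vab", self.vab)):
            if len(arm) == 0:
                raise ValueError(f"replicate arm {name} is empty")
            if not np.isfinite(arm).all():
                raise ValueError(f"non-finite viability in arm {name}")


@dataclasses.dataclass(frozen=True)
class BlissExcessResult:
    pair: tuple[str, str]
    excesses: tuple[float, ...]
    mean_excess: float
    t_stat: float
    p_value: float
    n_replicates: int
    is_hit: bool
    degenerate: bool = False


def enumerate_pairs(compounds: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered pairs of distinct compounds, n(n-1)/2 of them, in
    deterministic lexicographic order."""
    if len(set(compounds)) != len(compounds):
        dupes = sorted({c for c in compounds if list(compounds).count(c) > 1})
        raise ValueError(f"duplicate compound identifiers: {dupes}")
    return list(itertools.combinations(sorted(compounds), 2))


def bliss_excess(va: float, vb: float, vab: float) -> float:
    """Bliss independence excess on viability fractions:
    vab - va * vb.  Symmetric in the two single agents; zero under exact
    probabilistic independence."""
    for v in (va, vb, vab):
        if not (0.0 <= v <= 1.2):
            logger.warning("viability %.4g outside the expected [0, 1.2] range", v)
            break
    return vab - va * vb


def evaluate_pair(m: CombinationMeasurement, alpha: float = 0.05) -> BlissExcessResult:
    """Per-replicate Bliss excesses with a one-sample t-test against zero.

    Replicates are paired by index across the three arms (technical
    replicates on one plate).  The test is two-sided; the hit call is
    directional: p < alpha AND mean excess < 0.
    """
    if not (len(m.va) == len(m.vb) == len(m.vab)):
        raise ValueError(
            f"{m.pair}: replicate arms must have equal length, got "
            f"{len(m.va)}/{len(m.vb)}/{len(m.vab)}"
        )
    n = len(m.va)
    if n < 2:
        raise ValueError(f"{m.pair}: need >= 2 replicates, got {n}")
    ex = np.array(
        [bliss_excess(a, b, ab) for a, b, ab in zip(m.va, m.vb, m.vab)]
    )
    mean = float(ex.mean())
    degenerate = False
    if np.ptp(ex) == 0.0:
        # zero-variance excesses: t-test undefined; report the limit
        if mean == 0.0:
            t, p = 0.0, 1.0
        else:
            t = math_inf_signed(mean)
            p = 0.0
            degenerate = True
    else:
        t, p = stats.ttest_1samp(ex, 0.0)
        t, p = float(t), float(p)
    return BlissExcessResult(
        pair=m.pair,
        excesses=tuple(float(e) for e in ex),
        mean_excess=mean,
        t_stat=t,
        p_value=p,
        n_replicates=n,
        is_hit=bool(p < alpha and mean < 0),
        degenerate=degenerate,
    )


def math_inf_signed(x: float) -> float:
    return float("inf") if x > 0 else float("-inf")


def select_hits(
    results: Sequence[BlissExcessResult], alpha: float = 0.05
) -> list[BlissExcessResult]:
    """Significant synergistic pairs (p < alpha, mean excess < 0), most
    synergistic first; ties broken by pair identifiers for stability."""
    if len(results) == 0:
        raise ValueError("no results to select hits from")
    hits = [r for r in results if r.p_value < alpha and r.mean_excess < 0]
    return sorted(hits, key=lambda r: (r.mean_excess, r.pair))


def antagonistic_significant(
    results: Sequence[BlissExcessResult], alpha: float = 0.05
) -> list[BlissExcessResult]:
    """Significant positive-excess pairs, reported separately, never as hits."""
    anti = [r for r in results if r.p_value < alpha and r.mean_excess > 0]
    return sorted(anti, key=lambda r: (-r.mean_excess, r.pair))
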