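"""Two-trial repeatability statistics: relative difference and agreement limits.

The field protocol measures every subject twice, 10–15 minutes apart, and uses
the averaged values for analysis.  Repeatability of any quantity x is
summarised by the percentage relative difference

    RD = 100 · |x₁ − x₂| / |(x₁ + x₂)/2|

together with the SD of the raw differences, the fraction of pairs with
RD ≤ 15%, and the fraction of differences outside the mean ± 1.96 SD limits
of agreement (the Bland–Altman outlier rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import QualityError, UndefinedRDError
from .stiffness import StiffnessPanel

__all__ = ["TrialPair", "RDSummary", "relative_difference", "rd_summary", "trial_average"]


@dataclass(frozen=True)
class TrialPair:
    """Two consecutive stiffness measurements of the same subject."""

    subject_id: str
    first: StiffnessPanel
    second: StiffnessPanel

    def values(self, index_name: str) -> tuple[float, float]:
        return getattr(self.first, index_name), getattr(self.second, index_name)


@dataclass(frozen=True)
class RDSummary:
    """Cohort repeatability summary for one quantity."""

    n: int
    mean_rd: float  # percent
    sd_diff: float  # units of the quantity
    frac_within: float  # fraction of pairs with RD <= threshold
    loa_outlier_frac: float  # fraction outside mean ± 1.96 SD of differences
    rd_threshold: float  # percent


def relative_difference(x1: float, x2: float) -> float:
    """Percentage relative difference of two readings.

    Symmetric and scale-invariant; undefined (raises) when the pair mean is
    exactly zero — which cannot occur for physiologic positive quantities, so
    a zero mean flags suspect data rather than being mapped to 0 or infinity.
    """
    mean = (x1 + x2) / 2.0
    if mean == 0.0:
        raise UndefinedRDError("relative difference undefined for zero-mean pair")
    return 100.0 * abs(x1 - x2) / abs(mean)


def _rd_stats(x1: np.ndarray, x2: np.ndarray, rd_threshold: float) -> RDSummary:
    if x1.size < 2:
        raise QualityError("need at least two pairs for a repeatability summary")
    rd = 100.0 * np.abs(x1 - x2) / np.abs((x1 + x2) / 2.0)
    diff = x1 - x2
    sd = float(np.std(diff, ddof=1))
    mean_diff = float(np.mean(diff))
    if sd > 0.0:
        outliers = np.abs(diff - mean_diff) > 1.96 * sd
        loa_frac = float(np.mean(outliers))
    else:
        loa_frac = 0.0
    return RDSummary(
        n=int(x1.size),
        mean_rd=float(np.mean(rd)),
        sd_diff=sd,
        frac_within=float(np.mean(rd <= rd_threshold)),
        loa_outlier_frac=loa_frac,
        rd_threshold=rd_threshold,
    )


def rd_summary(
    pairs: Sequence[TrialPair] | tuple[np.ndarray, np.ndarray],
    index_name: str | None = None,
    *,
    rd_threshold: float = 15.0,
) -> RDSummary:
    """Repeatability summary over a cohort of two-trial pairs.

    ``pairs`` may be a sequence of :class:`TrialPair` (with ``index_name``
    naming the panel attribute, e.g. ``"beta"`` or ``"dd"``) or a plain
    ``(x1, x2)`` pair of arrays.
    """
    if isinstance(pairs, tuple) and len(pairs) == 2:
        x1 = np.asarray(pairs[0], dtype=float)
        x2 = np.asarray(pairs[1], dtype=float)
    else:
        if index_name is None:
            raise QualityError("index_name required for TrialPair input")
        vals = [p.values(index_name) for p in pairs]
        if not vals:
            raise QualityError("empty pair list")
        x1 = np.array([v[0] for v in vals])
        x2 = np.array([v[1] for v in vals])
    return _rd_stats(x1, x2, rd_threshold)


def trial_average(pair: TrialPair, index_name: str) -> float:
    """The (x₁ + x₂)/2 value downstream analyses use."""
    a, b = pair.values(index_name)
    return (a + b) / 2.0
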