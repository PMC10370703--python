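"""Genetic sex assignment from X/autosome read-rate ratios (Rx).

For each autosome i the ratio (reads_X / weight_X) / (reads_i / weight_i)
is computed; Rx is the mean of the 22 ratios with a normal-approximation
95% CI.  An XY individual has a single X copy, so Rx sits near 0.5; an XX
individual near 1.0.  Weights are chromosome lengths for shotgun data; for
capture data the per-chromosome target counts are the appropriate weights —
the caller chooses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .samio import AlignedRead
from .simulate import AUTOSOMES, GRCH37_MB

logger = logging.getLogger(__name__)

DEFAULT_MALE_MAX = 0.6
DEFAULT_FEMALE_MIN = 0.8


@dataclass(frozen=True)
class RxReport:
    """Per-autosome X/autosome ratios, their mean Rx and 95% CI."""

    ratios: tuple[float, ...]
    rx: float
    ci95: tuple[float, float]
    sample: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= self.rx <= hi:
            raise ValueError("CI does not bracket the Rx point estimate")


def count_reads_by_chromosome(reads: Iterable[AlignedRead]) -> dict[str, int]:
    """Read counts per reference chromosome (apply filters beforehand)."""
    counts: dict[str, int] = {}
    for r in reads:
        counts[r.chromosome] = counts.get(r.chromosome, 0) + 1
    return counts


def compute_rx(
    counts: dict[str, int],
    weights: dict[str, float] | None = None,
    sample: str = "",
) -> RxReport:
    """Rx report from per-chromosome read counts.

    ``counts`` must cover X and all 22 autosomes (absent autosomes are an
    error, not silently zero).  The CI is rx ± 1.96 * SE where SE combines
    the spread of the 22 per-autosome ratios with the binomial sampling
    variance of the shared X count (rx^2 / n_X) — the X term is common to
    every ratio, so the across-autosome spread alone would understate the
    uncertainty.  With only 22 ratios this remains an approximation,
    which is logged.
    """
    if weights is None:
        weights = dict(GRCH37_MB)
    for c in AUTOSOMES + ["X"]:
        if weights.get(c, 0) <= 0:
            raise ValueError(f"weight for chromosome {c} must be positive")
    x_rate = counts.get("X", 0) / weights["X"]
    ratios = []
    for c in AUTOSOMES:
        n = counts.get(c, 0)
        if n <= 0:
            raise ValueError(f"zero read count on autosome {c}")
        ratios.append(x_rate / (n / weights[c]))
    arr = np.array(ratios)
    rx = float(arr.mean())
    se_spread = float(arr.std(ddof=1) / np.sqrt(len(arr)))
    n_x = counts.get("X", 0)
    se_x = rx / np.sqrt(n_x) if n_x > 0 else 0.0
    se = float(np.hypot(se_spread, se_x))
    logger.debug(
        "compute_rx: normal-approximation CI over %d autosome ratios", len(arr)
    )
    return RxReport(tuple(ratios), rx, (rx - 1.96 * se, rx + 1.96 * se), sample)


def assign_sex(
    report: RxReport,
    male_max: float = DEFAULT_MALE_MAX,
    female_min: float = DEFAULT_FEMALE_MIN,
) -> str:
    """Classify a report as XY, XX or indeterminate.

    XY when the whole CI sits below ``male_max``; XX when it sits above
    ``female_min``; indeterminate otherwise.
    """
    if not 0 < male_max < female_min:
        raise ValueError("need 0 < male_max < female_min")
    lo, hi = report.ci95
    if hi < male_max:
        return "XY"
    if lo > female_min:
        return "XX"
    return "indeterminate"


def rx_from_point(rx: float, se: float = 0.005, sample: str = "") -> RxReport:
    """RxReport from a published point estimate and a nominal SE.

    Convenience for classifying literature Rx values for which the
    per-autosome ratios are not available; all 22 ratios are set to the
    point value and the CI to rx ± 1.96 * se.
    """
    return RxReport(
        tuple([rx] * 22), rx, (rx - 1.96 * se, rx + 1.96 * se), sample
    )
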