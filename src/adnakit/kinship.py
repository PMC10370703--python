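"""Pairwise-mismatch-rate (PMR) kinship inference on pseudo-haploid calls.

For two individuals, PMR is the fraction of jointly covered panel sites at
which their single sampled alleles differ.  Under random allele sampling
with no inbreeding the expected PMR of a pair with relatedness coefficient
r is baseline * (1 - r/2), where the baseline is the unrelated-pair rate:
identical individuals/twins (r = 1) sit at half the baseline, first-degree
relatives (r = 0.5) at 3/4, second-degree (r = 0.25) at 7/8.

Pairs with too few overlapping sites (default < 10,000) are reported but
left undetermined, since the PMR estimate is then too noisy to separate
adjacent degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np

from .eigenstrat import MISSING, GenotypeMatrix

DEFAULT_MIN_OVERLAP = 10_000

#: degree label -> relatedness coefficient r
DEGREE_R = {
    "identical": 1.0,
    "first": 0.5,
    "second": 0.25,
    "unrelated": 0.0,
}


@dataclass(frozen=True)
class PMRResult:
    """PMR for one unordered pair: overlap, mismatches, rate, degree call."""

    pair: tuple[str, str]
    n_overlap: int
    n_mismatch: int
    pmr: float
    degree: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_mismatch <= self.n_overlap:
            raise ValueError("mismatch count out of range")
        if self.n_overlap > 0 and not np.isclose(
            self.pmr, self.n_mismatch / self.n_overlap
        ):
            raise ValueError("pmr inconsistent with counts")


@dataclass(frozen=True)
class BaselineEstimate:
    """Unrelated-pair PMR baseline and how it was obtained."""

    value: float
    method: str
    n_pairs_used: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.value < 1.0:
            raise ValueError(f"baseline {self.value} outside (0, 1)")


def compute_pmr(
    calls: GenotypeMatrix,
    pair: tuple[str, str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> PMRResult:
    """PMR for one pair of pseudo-haploid individuals.

    Sites missing in either individual are excluded from both counts.
    When the overlap is below ``min_overlap`` the degree is fixed to
    "undetermined"; otherwise it is left unset for later classification.
    """
    if calls.ploidy_mode != "pseudohaploid":
        raise ValueError("PMR requires pseudo-haploid calls")
    i, j = calls.index_of(pair[0]), calls.index_of(pair[1])
    a, b = calls.calls[i], calls.calls[j]
    both = (a != MISSING) & (b != MISSING)
    n_overlap = int(both.sum())
    n_mismatch = int((a[both] != b[both]).sum())
    pmr = n_mismatch / n_overlap if n_overlap else float("nan")
    degree = "undetermined" if n_overlap < min_overlap else None
    return PMRResult((pair[0], pair[1]), n_overlap, n_mismatch, pmr, degree)


def pairwise_pmr(
    calls: GenotypeMatrix,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    baseline: "BaselineEstimate | float | None" = None,
) -> list[PMRResult]:
    """PMR for every unordered pair; classified when a baseline is given."""
    if calls.n_individuals < 2:
        raise ValueError("need at least two individuals")
    results = [
        compute_pmr(calls, (x, y), min_overlap)
        for x, y in combinations(calls.individuals, 2)
    ]
    if baseline is not None:
        results = [
            r if r.degree == "undetermined"
            else replace(r, degree=classify_relatedness(r, baseline))
            for r in results
        ]
    return results


def expected_pmr(r: float, baseline: float) -> float:
    """Expected PMR of a pair with relatedness r: baseline * (1 - r/2)."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    if not 0.0 < baseline < 1.0:
        raise ValueError("baseline must lie in (0, 1)")
    return baseline * (1.0 - r / 2.0)


def estimate_baseline(
    results: list[PMRResult] | None = None,
    freqs: np.ndarray | None = None,
    method: str = "auto",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> BaselineEstimate:
    """Unrelated-pair baseline PMR.

    Methods: "cohort-median" (median PMR over qualifying pairs — robust to
    a few related pairs in the cohort), "known-unrelated-mean" (mean over
    pairs asserted unrelated), "frequency-expected" (analytic
    mean of 2 p (1-p) over panel frequencies).  "auto" picks
    cohort-median when results are supplied, else frequency-expected.
    """
    if method == "auto":
        method = "cohort-median" if results is not None else "frequency-expected"
    if method == "frequency-expected":
        if freqs is None:
            raise ValueError("frequency-expected baseline needs freqs")
        p = np.asarray(freqs, dtype=float)
        return BaselineEstimate(float(np.mean(2.0 * p * (1.0 - p))), method, 0)
    if method not in ("cohort-median", "known-unrelated-mean"):
        raise ValueError(f"unknown baseline method {method!r}")
    if not results:
        raise ValueError("cohort baseline needs PMR results")
    rates = [r.pmr for r in results if r.n_overlap >= min_overlap]
    if not rates:
        raise ValueError("no pairs meet the overlap threshold")
    value = float(np.median(rates) if method == "cohort-median" else np.mean(rates))
    return BaselineEstimate(value, method, len(rates))


def classify_relatedness(
    result: PMRResult, baseline: BaselineEstimate | float
) -> str:
    """Assign the degree whose expected PMR is nearest the observed one.

    Ties are broken toward the more distant relationship (smaller r),
    the conservative choice.  An undetermined overlap propagates.
    """
    if result.degree == "undetermined":
        return "undetermined"
    b = baseline.value if isinstance(baseline, BaselineEstimate) else float(baseline)
    best, best_dist, best_r = None, np.inf, np.inf
    for degree, r in DEGREE_R.items():
        dist = abs(result.pmr - expected_pmr(r, b))
        if dist < best_dist - 1e-15 or (
            abs(dist - best_dist) <= 1e-15 and r < best_r
        ):
            best, best_dist, best_r = degree, dist, r
    return best
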