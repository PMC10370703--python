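"""Terminal deamination profiling, read filtering and end trimming.

Post-mortem cytosine deamination leaves excess C→T mismatches at the 5'
end of sequenced molecules and, in double-stranded library preparations,
mirrored G→A at the 3' end, decaying roughly exponentially with distance
from the terminus.  The profile here conditions on the reconstructed
reference base, counts in molecule orientation (reverse-strand alignments
are re-oriented first), and compares terminal frequencies to an interior
mismatch baseline to recommend how many bases to trim before genotyping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .samio import AlignedRead

DEFAULT_MIN_LENGTH = 30
DEFAULT_MIN_MAPQ = 30
DEFAULT_K = 25


@dataclass(frozen=True)
class FilterCounts:
    """Bookkeeping for apply_read_filters removals."""

    n_input: int
    n_retained: int
    n_short: int
    n_low_mapq: int


@dataclass
class DamageProfile:
    """Per-terminal-position substitution frequencies.

    ``ct5[i-1]`` is the C→T frequency at 5' position i given a reference
    C there; ``ga3`` the mirrored G→A from the 3' end.  Frequencies are
    NaN where a position had zero opportunities.  ``interior_baseline``
    is the mean mismatch frequency over positions more than K from both
    ends.
    """

    positions: np.ndarray
    ct5: np.ndarray
    ga3: np.ndarray
    ct5_opportunities: np.ndarray
    ga3_opportunities: np.ndarray
    interior_baseline: float
    interior_bases: int
    n_reads_used: int

    def __post_init__(self) -> None:
        for arr in (self.ct5, self.ga3):
            vals = arr[~np.isnan(arr)]
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError("frequencies must lie in [0, 1]")


def apply_read_filters(
    reads: Iterable[AlignedRead],
    min_length: int = DEFAULT_MIN_LENGTH,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    mapq_strict: bool = False,
) -> tuple[list[AlignedRead], FilterCounts]:
    """Length and mapping-quality filters.

    A read is retained iff length >= ``min_length`` and MAPQ >= ``min_mapq``
    (with ``mapq_strict``, MAPQ must strictly exceed the threshold).
    """
    kept: list[AlignedRead] = []
    n_short = n_low = n_in = 0
    for r in reads:
        n_in += 1
        if r.length < min_length:
            n_short += 1
            continue
        ok = r.mapq > min_mapq if mapq_strict else r.mapq >= min_mapq
        if not ok:
            n_low += 1
            continue
        kept.append(r)
    return kept, FilterCounts(n_in, len(kept), n_short, n_low)


def compute_damage(
    reads: Iterable[AlignedRead], K: int = DEFAULT_K
) -> DamageProfile:
    """Damage profile over the first/last K positions of each molecule.

    Counts are conditional on the reference base: the denominator of
    ct5[i] is the number of reads with a reference C at 5' position i.
    Masked (N) read bases are excluded from numerator and denominator
    alike.  Positions within K of *both* ends contribute to both curves;
    the interior baseline pools all columns more than K from each end.
    """
    ct5_opp = np.zeros(K, dtype=np.int64)
    ct5_hit = np.zeros(K, dtype=np.int64)
    ga3_opp = np.zeros(K, dtype=np.int64)
    ga3_hit = np.zeros(K, dtype=np.int64)
    int_bases = 0
    int_mm = 0
    n_reads = 0
    for r in reads:
        n_reads += 1
        read, ref = r.molecule_sequences()
        L = len(read)
        rd = np.frombuffer(read.encode(), dtype=np.uint8)
        rf = np.frombuffer(ref.encode(), dtype=np.uint8)
        usable = rd != ord("N")
        k5 = min(K, L)
        m5 = usable[:k5] & (rf[:k5] == ord("C"))
        ct5_opp[:k5] += m5
        ct5_hit[:k5] += m5 & (rd[:k5] == ord("T"))
        k3 = min(K, L)
        tail_rd = rd[L - k3 :][::-1]
        tail_rf = rf[L - k3 :][::-1]
        m3 = usable[L - k3 :][::-1] & (tail_rf == ord("G"))
        ga3_opp[:k3] += m3
        ga3_hit[:k3] += m3 & (tail_rd == ord("A"))
        if L > 2 * K:
            mid_rd = rd[K : L - K]
            mid_rf = rf[K : L - K]
            mid_use = mid_rd != ord("N")
            int_bases += int(mid_use.sum())
            int_mm += int((mid_use & (mid_rd != mid_rf)).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        ct5 = np.where(ct5_opp > 0, ct5_hit / np.maximum(ct5_opp, 1), np.nan)
        ga3 = np.where(ga3_opp > 0, ga3_hit / np.maximum(ga3_opp, 1), np.nan)
    baseline = int_mm / int_bases if int_bases else 0.0
    return DamageProfile(
        positions=np.arange(1, K + 1),
        ct5=ct5,
        ga3=ga3,
        ct5_opportunities=ct5_opp,
        ga3_opportunities=ga3_opp,
        interior_baseline=baseline,
        interior_bases=int_bases,
        n_reads_used=n_reads,
    )


def recommend_trim(profile: DamageProfile, tolerance_sd: float = 2.0) -> int:
    """Smallest per-end trim that flattens the terminal curves.

    For each end, the recommended t is the smallest value such that every
    position beyond t has frequency <= baseline + tolerance_sd * SE, where
    SE is the binomial standard error of the baseline at that position's
    opportunity count.  The result is the max over the two ends, so one
    symmetric trim suffices.
    """
    if np.all(np.isnan(profile.ct5)) and np.all(np.isnan(profile.ga3)):
        raise ValueError("profile has no observed frequencies")
    b = profile.interior_baseline

    def end_trim(freqs: np.ndarray, opps: np.ndarray) -> int:
        t = 0
        for i in range(len(freqs) - 1, -1, -1):  # find last offending position
            f, n = freqs[i], opps[i]
            if math.isnan(f) or n == 0:
                continue
            se = math.sqrt(b * (1.0 - b) / n)
            if f > b + tolerance_sd * se:
                t = i + 1
                break
        return t

    return max(
        end_trim(profile.ct5, profile.ct5_opportunities),
        end_trim(profile.ga3, profile.ga3_opportunities),
    )


def trim_ends(reads: Iterable[AlignedRead], t: int) -> list[AlignedRead]:
    """Mask t bases at each end of every read (N-substitution).

    Masking rather than hard-clipping preserves alignment coordinates;
    masked bases are ignored by genotype calling and by
    :func:`compute_damage`.  Reads with length <= 2 t are dropped outright.
    """
    if t < 0:
        raise ValueError("trim length must be non-negative")
    out: list[AlignedRead] = []
    for r in reads:
        if r.length <= 2 * t:
            continue
        out.append(r.mask_ends(t))
    return out
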