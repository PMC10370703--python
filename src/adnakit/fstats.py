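"""Outgroup f3 and f4 statistics with block-jackknife standard errors.

f3(O; A, B) averages (o - a)(o - b) over sites and measures the shared
genetic drift of A and B relative to the outgroup O — larger means closer.
f4(A, B; C, D) averages (a - b)(c - d) and tests treeness: it is zero in
expectation when (A, B) and (C, D) are clades with no cross-gene-flow.
Standard errors come from a weighted delete-one-block jackknife over
contiguous genomic blocks, which absorbs linkage between nearby sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .eigenstrat import MISSING, GenotypeMatrix, SnpPanel

logger = logging.getLogger(__name__)

DEFAULT_BLOCK_BP = 5_000_000
FALLBACK_N_BLOCKS = 20


@dataclass
class PopulationFrequencies:
    """Per-population alternate-allele frequencies with allele counts.

    ``freqs[p, s]`` is NaN where ``counts[p, s]`` is zero.
    """

    panel: SnpPanel
    populations: list[str]
    freqs: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.populations), self.panel.n_sites)
        if self.freqs.shape != shape or self.counts.shape != shape:
            raise ValueError("frequency/count arrays do not match panel")
        ok = self.counts > 0
        vals = self.freqs[ok]
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("frequencies outside [0, 1]")
        if not np.all(np.isnan(self.freqs[~ok])):
            raise ValueError("frequency present where allele count is zero")

    def row(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None


@dataclass(frozen=True)
class FStatResult:
    """One f-statistic with its jackknife SE and Z-score."""

    statistic: str
    populations: tuple[str, ...]
    value: float
    jackknife_se: float
    z: float
    n_blocks: int
    n_sites: int

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("need at least two jackknife blocks")


def estimate_frequencies(
    matrix: GenotypeMatrix, assignment: dict[str, str]
) -> PopulationFrequencies:
    """Alternate-allele frequencies per population.

    A diploid call contributes two alleles per covered site, a
    pseudo-haploid call exactly one (the sampled allele) — there is no
    heterozygote state to weight.  EIGENSTRAT codes count the reference
    allele, so the alternate dosage of code c is (ploidy - c * ploidy/2).
    """
    pops = sorted(set(assignment.values()))
    for label in assignment:
        matrix.index_of(label)  # raises on unknown labels
    n_sites = matrix.panel.n_sites
    freqs = np.full((len(pops), n_sites), np.nan)
    counts = np.zeros((len(pops), n_sites), dtype=np.int64)
    per_call = 1 if matrix.ploidy_mode == "pseudohaploid" else 2
    for p_idx, pop in enumerate(pops):
        rows = [
            matrix.index_of(l) for l, p in assignment.items() if p == pop
        ]
        if not rows:
            raise ValueError(f"population {pop!r} is empty")
        sub = matrix.calls[rows]
        observed = sub != MISSING
        if matrix.ploidy_mode == "pseudohaploid":
            alt = np.where(observed & (sub == 0), 1, 0)
        else:
            alt = np.where(observed, 2 - sub, 0)
        n_alleles = observed.sum(axis=0) * per_call
        alt_total = alt.sum(axis=0)
        counts[p_idx] = n_alleles
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[p_idx] = np.where(
                n_alleles > 0, alt_total / np.maximum(n_alleles, 1), np.nan
            )
    return PopulationFrequencies(matrix.panel, pops, freqs, counts)


def frequencies_from_table(
    panel: SnpPanel, table: dict[str, np.ndarray], n_alleles: int = 1_000_000
) -> PopulationFrequencies:
    """Wrap exact per-population frequency vectors (e.g. simulator output).

    ``n_alleles`` is the nominal allele count attached to every site; the
    default is large so finite-sample corrections vanish.
    """
    pops = sorted(table)
    freqs = np.vstack([np.asarray(table[p], dtype=float) for p in pops])
    counts = np.full(freqs.shape, n_alleles, dtype=np.int64)
    return PopulationFrequencies(panel, pops, freqs, counts)


def _blocks_for(panel: SnpPanel, usable: np.ndarray, block_bp: int) -> np.ndarray:
    """Block id per usable site: contiguous block_bp windows per chromosome."""
    ids = np.zeros(int(usable.sum()), dtype=np.int64)
    chroms = panel.chromosomes[usable]
    pos = panel.positions[usable]
    next_id = 0
    for c in dict.fromkeys(chroms):  # preserve order
        mask = chroms == c
        win = pos[mask] // block_bp
        _, local = np.unique(win, return_inverse=True)
        ids[mask] = local + next_id
        next_id = ids[mask].max() + 1
    return ids


def _equal_count_blocks(n: int, n_blocks: int) -> np.ndarray:
    return np.minimum(
        (np.arange(n) * n_blocks) // max(n, 1), n_blocks - 1
    ).astype(np.int64)


def block_jackknife(
    terms: np.ndarray, block_ids: np.ndarray
) -> tuple[float, float, int]:
    """Weighted delete-one-block jackknife of a per-site mean.

    Handles unequal block sizes with the standard weighted formula.
    Returns (estimate, SE, number of blocks).
    """
    terms = np.asarray(terms, dtype=float)
    n = len(terms)
    uniq, inv = np.unique(block_ids, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("fewer than 2 usable jackknife blocks")
    m = np.bincount(inv).astype(float)
    block_sums = np.bincount(inv, weights=terms)
    total = terms.sum()
    theta = total / n
    theta_del = (total - block_sums) / (n - m)
    h = n / m
    theta_jack = g * theta - np.sum((1.0 - m / n) * theta_del)
    resid = h * theta - (h - 1.0) * theta_del - theta_jack
    var = np.sum(resid**2 / (h - 1.0)) / g
    return float(theta), float(np.sqrt(var)), g


def _site_blocks(
    panel: SnpPanel, usable: np.ndarray, block_bp: int | None
) -> np.ndarray:
    n_usable = int(usable.sum())
    ids = _blocks_for(panel, usable, block_bp or DEFAULT_BLOCK_BP)
    if len(np.unique(ids)) < 2:
        logger.warning(
            "position-based blocking yielded <2 blocks; "
            "falling back to %d equal-count blocks",
            FALLBACK_N_BLOCKS,
        )
        ids = _equal_count_blocks(n_usable, min(FALLBACK_N_BLOCKS, n_usable))
    return ids


def f3_outgroup(
    pf: PopulationFrequencies,
    outgroup: str,
    a: str,
    b: str,
    block_bp: int | None = None,
) -> FStatResult:
    """Outgroup f3(O; A, B) with jackknife SE.

    The per-site term (o - a)(o - b) is corrected for the outgroup's
    finite-sample variance by subtracting h_O / n_O with
    h_O = o (1 - o) n_O / (n_O - 1), wherever the outgroup allele count
    is at least 2; single-allele outgroup sites use the raw product (a
    warning is logged once per call).
    """
    io, ia, ib = pf.row(outgroup), pf.row(a), pf.row(b)
    usable = (pf.counts[io] > 0) & (pf.counts[ia] > 0) & (pf.counts[ib] > 0)
    if not usable.any():
        raise ValueError("no sites with data in all three populations")
    o, pa, pb = pf.freqs[io, usable], pf.freqs[ia, usable], pf.freqs[ib, usable]
    no = pf.counts[io, usable].astype(float)
    terms = (o - pa) * (o - pb)
    correctable = no >= 2
    if not correctable.all():
        logger.warning(
            "f3: %d sites have a single outgroup allele; "
            "finite-sample correction skipped there",
            int((~correctable).sum()),
        )
    corr = np.where(correctable, o * (1.0 - o) / np.maximum(no - 1.0, 1.0), 0.0)
    terms = terms - corr
    ids = _site_blocks(pf.panel, usable, block_bp)
    value, se, g = block_jackknife(terms, ids)
    z = value / se if se > 0 else float("inf") * np.sign(value)
    return FStatResult(
        "f3", (outgroup, a, b), value, se, float(z), g, int(usable.sum())
    )


def f4(
    pf: PopulationFrequencies,
    a: str,
    b: str,
    c: str,
    d: str,
    block_bp: int | None = None,
) -> FStatResult:
    """f4(A, B; C, D) with jackknife SE and Z-score."""
    rows = [pf.row(x) for x in (a, b, c, d)]
    usable = np.all(pf.counts[rows] > 0, axis=0)
    if not usable.any():
        raise ValueError("no sites with data in all four populations")
    fa, fb, fc, fd = (pf.freqs[r, usable] for r in rows)
    terms = (fa - fb) * (fc - fd)
    ids = _site_blocks(pf.panel, usable, block_bp)
    value, se, g = block_jackknife(terms, ids)
    z = value / se if se > 0 else 0.0
    return FStatResult(
        "f4", (a, b, c, d), value, se, float(z), g, int(usable.sum())
    )
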