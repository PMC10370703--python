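"""Synthetic data with the statistical structure the analyses assume.

Every generator is deterministic for a fixed seed.  The pieces mirror the
data-generating processes of a low-coverage ancient-DNA capture study:

* Hardy–Weinberg founders on a SNP panel with a stated allele-frequency
  law, plus Mendelian pedigrees realizing relatedness r in {1, 0.5, 0.25, 0};
* pseudo-haploid sampling (one random allele per covered site) with
  per-individual missingness;
* sex-dependent X/autosome read allocation (multinomial over chromosome
  weights, with the X weight halved for XY);
* reads carrying exponentially decaying terminal deamination, 5' C→T and
  3' G→A, serialized as text SAM with consistent MD tags;
* populations drifting on a tree, giving an additive oracle for
  f-statistics.

No linkage is simulated: sites are independent, which is exactly the
regime in which the pairwise-mismatch-rate ratio law 1 − r/2 is an
analytic statement rather than an approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .eigenstrat import MISSING, GenotypeMatrix, SnpPanel
from .samio import AlignedRead, write_sam

# GRCh37 chromosome lengths, megabase scale; used as default read-allocation
# weights.  Config, not hard-coded truth: any positive weights may be passed.
GRCH37_MB = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171,
    "7": 159, "8": 146, "9": 141, "10": 136, "11": 135, "12": 134,
    "13": 115, "14": 107, "15": 103, "16": 90, "17": 81, "18": 78,
    "19": 59, "20": 63, "21": 48, "22": 51, "X": 155,
}

AUTOSOMES = [str(i) for i in range(1, 23)]

MECHANISM_R = {
    "duplicate": 1.0,
    "parent-offspring": 0.5,
    "full-sib": 0.5,
    "half-sib": 0.25,
    "grandparent": 0.25,
    "unrelated": 0.0,
}


def split_seed(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# allele frequencies and panels


def simulate_allele_frequencies(
    n_sites: int,
    freq_law: str = "uniform",
    a: float = 0.05,
    b: float = 0.95,
    alpha: float = 1.0,
    beta: float = 1.0,
    seed: int | np.random.Generator = 0,
    spacing_bp: int = 20_000,
) -> tuple[np.ndarray, SnpPanel]:
    """Draw per-site alternate-allele frequencies and a matching panel.

    ``freq_law`` is "uniform" on [a, b] (a == b gives the constant) or
    "beta" with shapes (alpha, beta).  Sites are laid out on autosomes
    1..22 proportionally to chromosome size, ``spacing_bp`` apart, so
    position-based jackknife blocking behaves sensibly.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = _rng(seed)
    if freq_law == "uniform":
        if a > b or not (0 <= a <= 1 and 0 <= b <= 1):
            raise ValueError(f"invalid uniform bounds ({a}, {b})")
        freqs = rng.uniform(a, b, n_sites) if a < b else np.full(n_sites, float(a))
    elif freq_law == "beta":
        if alpha <= 0 or beta <= 0:
            raise ValueError("beta shapes must be positive")
        freqs = rng.beta(alpha, beta, n_sites)
        freqs = np.clip(freqs, 1e-6, 1 - 1e-6)
    else:
        raise ValueError(f"unknown frequency law {freq_law!r}")
    panel = _autosomal_panel(n_sites, rng, spacing_bp)
    return freqs, panel


def _autosomal_panel(
    n_sites: int, rng: np.random.Generator, spacing_bp: int
) -> SnpPanel:
    sizes = np.array([GRCH37_MB[c] for c in AUTOSOMES], dtype=float)
    per_chrom = np.floor(sizes / sizes.sum() * n_sites).astype(int)
    while per_chrom.sum() < n_sites:
        per_chrom[int(np.argmax(sizes - per_chrom / n_sites))] += 1
        sizes = sizes * 0.999  # nudge so top-ups spread out
    chroms: list[str] = []
    positions: list[int] = []
    for c, k in zip(AUTOSOMES, per_chrom):
        chroms.extend([c] * int(k))
        positions.extend(range(spacing_bp, spacing_bp * (int(k) + 1), spacing_bp))
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n_sites)]
    alt_offset = rng.integers(1, 4, n_sites)
    alt = bases[(np.searchsorted(bases, ref) + alt_offset) % 4]
    ids = [f"rs{i:07d}" for i in range(n_sites)]
    return SnpPanel(ids, chroms, positions, ref, alt)


# ---------------------------------------------------------------------------
# pedigrees


@dataclass
class PedigreeSpec:
    """A pedigree as a parents map plus annotated pairs of interest.

    ``parents`` maps each individual to ``None`` (founder) or a tuple of
    two parent labels.  ``relationships`` lists (pair, r, mechanism)
    entries; r must agree with the mechanism's expectation.
    """

    parents: dict[str, tuple[str, str] | None]
    relationships: list[tuple[tuple[str, str], float, str]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        for child, par in self.parents.items():
            if par is not None:
                if len(par) != 2:
                    raise ValueError(f"{child}: need exactly two parents")
                for p in par:
                    if p not in self.parents:
                        raise ValueError(f"{child}: unknown parent {p!r}")
        for (x, y), r, mech in self.relationships:
            if mech not in MECHANISM_R:
                raise ValueError(f"unknown mechanism {mech!r}")
            if not math.isclose(r, MECHANISM_R[mech]):
                raise ValueError(
                    f"pair ({x},{y}): r={r} inconsistent with {mech!r}"
                )
            for label in (x, y):
                if label not in self.parents:
                    raise ValueError(f"relationship names unknown label {label!r}")
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(node: str, stack: tuple[str, ...]) -> None:
            if state.get(node) == 2:
                return
            if node in stack:
                raise ValueError(f"pedigree contains a cycle through {node!r}")
            state[node] = 1
            par = self.parents[node]
            if par is not None:
                for p in par:
                    visit(p, stack + (node,))
            state[node] = 2
            order.append(node)

        for label in self.parents:
            visit(label, ())
        return order


def pair_pedigree(mechanism: str, tag: str = "") -> PedigreeSpec:
    """Canonical minimal pedigree realizing one related pair.

    The pair of interest is always ("{tag}A", "{tag}B").
    """
    t = tag
    a, b = f"{t}A", f"{t}B"
    r = MECHANISM_R[mechanism]
    if mechanism == "unrelated":
        parents = {a: None, b: None}
    elif mechanism == "duplicate":
        # handled at genotype time: B is a literal copy of A
        parents = {a: None, b: None}
    elif mechanism == "parent-offspring":
        parents = {a: None, f"{t}S": None, b: (a, f"{t}S")}
    elif mechanism == "full-sib":
        parents = {f"{t}F": None, f"{t}M": None, a: (f"{t}F", f"{t}M"),
                   b: (f"{t}F", f"{t}M")}
    elif mechanism == "half-sib":
        parents = {f"{t}F": None, f"{t}M1": None, f"{t}M2": None,
                   a: (f"{t}F", f"{t}M1"), b: (f"{t}F", f"{t}M2")}
    elif mechanism == "grandparent":
        parents = {a: None, f"{t}S": None, f"{t}C": (a, f"{t}S"),
                   f"{t}S2": None, b: (f"{t}C", f"{t}S2")}
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    return PedigreeSpec(parents, [((a, b), r, mechanism)])


def simulate_pedigree_genotypes(
    freqs: np.ndarray,
    panel: SnpPanel,
    pedigree: PedigreeSpec,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Diploid genotypes: HWE founders, Mendelian transmission.

    Genotypes are stored as two haplotype vectors per individual (1 = ref
    allele) summed to the EIGENSTRAT reference-allele count.  A child
    receives one uniformly chosen allele from each parent, independently
    per site (no linkage).  'duplicate' pairs from :func:`pair_pedigree`
    are realized by copying both haplotypes.
    """
    rng = _rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    n_sites = len(freqs)
    if panel.n_sites != n_sites:
        raise ValueError("frequency vector and panel disagree in length")
    order = pedigree.topological_order()
    haplo: dict[str, np.ndarray] = {}
    duplicates = {
        pair[1]: pair[0]
        for pair, _r, mech in pedigree.relationships
        if mech == "duplicate"
    }
    for label in order:
        if label in duplicates:
            haplo[label] = haplo[duplicates[label]].copy()
            continue
        par = pedigree.parents[label]
        if par is None:
            # founder: two independent Bernoulli(1-p) ... stored as ref counts
            haplo[label] = (rng.random((2, n_sites)) < (1.0 - freqs)).astype(np.int8)
        else:
            rows = []
            for p in par:
                pick = rng.integers(0, 2, n_sites)
                rows.append(haplo[p][pick, np.arange(n_sites)])
            haplo[label] = np.array(rows, dtype=np.int8)
    labels = list(pedigree.parents)
    calls = np.array([haplo[l].sum(axis=0) for l in labels], dtype=np.int8)
    return GenotypeMatrix(panel, labels, calls, "diploid")


def pseudo_haploidize(
    matrix: GenotypeMatrix,
    missingness: float | dict[str, float] = 0.0,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Sample one allele per site and apply i.i.d. per-site missingness.

    At heterozygous sites the reference allele is drawn with probability
    1/2; homozygous sites keep their allele.  ``missingness`` is a single
    rate or a per-individual mapping, each in [0, 1).
    """
    if matrix.ploidy_mode != "diploid":
        raise ValueError("input must be diploid")
    rng = _rng(seed)
    if isinstance(missingness, dict):
        rates = np.array([missingness[l] for l in matrix.individuals], float)
    else:
        rates = np.full(matrix.n_individuals, float(missingness))
    if np.any((rates < 0) | (rates >= 1)):
        raise ValueError("missingness must lie in [0, 1)")
    calls = matrix.calls.copy()
    het = calls == 1
    sample_ref = rng.random(calls.shape) < 0.5
    calls[het] = np.where(sample_ref[het], 2, 0).astype(np.int8)
    drop = rng.random(calls.shape) < rates[:, None]
    calls[drop] = MISSING
    return GenotypeMatrix(
        matrix.panel, matrix.individuals, calls, "pseudohaploid"
    )


# ---------------------------------------------------------------------------
# sex-dependent read allocation


@dataclass
class SexReadModel:
    """Multinomial read-allocation model over 22 autosomes plus X.

    ``weights`` are per-chromosome base weights (defaults to GRCh37 Mb
    lengths); an XY karyotype halves the effective X weight relative to
    XX, reflecting a single X copy.
    """

    sex: str
    total_reads: int
    weights: dict[str, float] = field(default_factory=lambda: dict(GRCH37_MB))

    def __post_init__(self) -> None:
        if self.sex not in ("XX", "XY"):
            raise ValueError(f"sex must be 'XX' or 'XY', got {self.sex!r}")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        for c in AUTOSOMES + ["X"]:
            if c not in self.weights:
                raise ValueError(f"missing weight for chromosome {c}")
            if self.weights[c] <= 0:
                raise ValueError(f"non-positive weight for chromosome {c}")

    def effective_weights(self) -> dict[str, float]:
        w = {c: float(self.weights[c]) for c in AUTOSOMES}
        w["X"] = float(self.weights["X"]) * (0.5 if self.sex == "XY" else 1.0)
        return w


def simulate_sex_read_counts(
    model: SexReadModel, seed: int | np.random.Generator = 0
) -> dict[str, int]:
    """Multinomial per-chromosome read counts under the sex model."""
    rng = _rng(seed)
    w = model.effective_weights()
    chroms = AUTOSOMES + ["X"]
    p = np.array([w[c] for c in chroms])
    p = p / p.sum()
    counts = rng.multinomial(model.total_reads, p)
    return dict(zip(chroms, (int(x) for x in counts)))


# ---------------------------------------------------------------------------
# damaged reads


@dataclass
class DamageModel:
    """Exponentially decaying terminal deamination.

    The probability of a C→T at molecule 5' position i (1-based from the
    end) is d0 * lam**(i-1); G→A mirrors it at the 3' end.
    """

    d0: float = 0.3
    lam: float = 0.5
    max_positions: int = 25

    def __post_init__(self) -> None:
        if not 0.0 <= self.d0 <= 1.0:
            raise ValueError("d0 must lie in [0, 1]")
        if not 0.0 < self.lam < 1.0:
            raise ValueError("lambda must lie in (0, 1)")
        if self.max_positions < 1:
            raise ValueError("max_positions must be >= 1")

    def rate(self, position: np.ndarray | int) -> np.ndarray | float:
        return self.d0 * self.lam ** (np.asarray(position) - 1)


def simulate_damaged_reads(
    n_reads: int,
    damage: DamageModel,
    mean_length: float = 70.0,
    sd_length: float = 8.0,
    min_length: int = 35,
    mapq_law: tuple = ("fixed", 37),
    error_rate: float = 0.0,
    reverse_fraction: float = 0.5,
    chromosome: str = "1",
    seed: int | np.random.Generator = 0,
    out=None,
) -> list[AlignedRead]:
    """Reads over a uniform-random reference with planted terminal damage.

    Read lengths are a discretized normal truncated at ``min_length``.
    ``mapq_law`` is ("fixed", q) or ("choice", values, probs).  A fraction
    of reads is emitted on the reverse strand: their stored sequences are
    reverse-complemented, so the damage signature only reads correctly
    after molecule re-orientation — exercising strand-awareness downstream.
    ``error_rate`` adds uniform base miscalls away from the planted
    signature, giving the profile a non-zero interior baseline.  When
    ``out`` is given the reads are also serialized as text SAM.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    rng = _rng(seed)
    lengths = np.maximum(
        np.rint(rng.normal(mean_length, sd_length, n_reads)).astype(int),
        min_length,
    )
    if mapq_law[0] == "fixed":
        mapqs = np.full(n_reads, int(mapq_law[1]))
    elif mapq_law[0] == "choice":
        mapqs = rng.choice(mapq_law[1], size=n_reads, p=mapq_law[2])
    else:
        raise ValueError(f"unknown mapq law {mapq_law[0]!r}")
    is_rev = rng.random(n_reads) < reverse_fraction
    bases = np.array(list("ACGT"))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    reads: list[AlignedRead] = []
    pos_cursor = 1
    for k in range(n_reads):
        L = int(lengths[k])
        ref = bases[rng.integers(0, 4, L)]
        read = ref.copy()
        idx = np.arange(1, L + 1)
        p5 = damage.rate(idx)
        p3 = damage.rate(idx[::-1])
        u = rng.random(L)
        ct = (ref == "C") & (u < p5)
        ga = (ref == "G") & (u < p3)
        read[ct] = "T"
        read[ga] = "A"
        if error_rate > 0:
            hit = (rng.random(L) < error_rate) & ~ct & ~ga
            if hit.any():
                n_hit = int(hit.sum())
                shift = rng.integers(1, 4, n_hit)
                cur = np.searchsorted(bases, read[hit])
                read[hit] = bases[(cur + shift) % 4]
        read_s, ref_s = "".join(read), "".join(ref)
        strand = "-" if is_rev[k] else "+"
        if strand == "-":
            read_s = "".join(comp[b] for b in reversed(read_s))
            ref_s = "".join(comp[b] for b in reversed(ref_s))
        reads.append(
            AlignedRead(
                name=f"read{k:06d}",
                flags=0,
                chromosome=chromosome,
                start=pos_cursor,
                mapq=int(mapqs[k]),
                read_sequence=read_s,
                reference_sequence=ref_s,
                strand=strand,
            )
        )
        pos_cursor += L + 1
    if out is not None:
        write_sam(reads, out)
    return reads


# ---------------------------------------------------------------------------
# drifted populations (f-statistics oracle)


@dataclass
class DriftNode:
    """Node of a population-drift tree; leaves carry population names."""

    name: str | None = None
    drift: float = 0.0
    children: list["DriftNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


def drift_tree(spec) -> DriftNode:
    """Build a DriftNode tree from nested (drift, spec) structure.

    A leaf is ("name", drift); an internal node is (drift, [children]).
    The root has drift 0 by convention.
    """
    def build2(node_spec) -> DriftNode:
        # internal: (drift, [child, ...]); leaf: ("name", drift)
        if (
            isinstance(node_spec, tuple)
            and len(node_spec) == 2
            and isinstance(node_spec[0], str)
            and isinstance(node_spec[1], (int, float))
        ):
            return DriftNode(name=node_spec[0], drift=float(node_spec[1]))
        if (
            isinstance(node_spec, tuple)
            and len(node_spec) == 2
            and isinstance(node_spec[1], (list, tuple))
        ):
            node = DriftNode(drift=float(node_spec[0]))
            node.children = [build2(c) for c in node_spec[1]]
            if not node.children:
                raise ValueError("internal node with no children")
            return node
        raise ValueError(f"malformed tree node {node_spec!r}")

    return build2(spec)


def simulate_drifted_populations(
    tree: DriftNode,
    base_freqs: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Per-population frequencies after tree-structured drift.

    Each branch with drift d perturbs the parent's frequencies by
    N(0, d * p0 (1-p0)) where p0 are the root (base) frequencies, then
    clamps to (0, 1).  Scaling every branch's noise by the *root*
    heterozygosity keeps expected f2 between two leaves equal to the sum
    of branch drifts on their path — the additivity oracle used by the
    f-statistics tests.  Keep drifts small and base frequencies interior
    so clamping stays negligible.
    """
    rng = _rng(seed)
    base = np.asarray(base_freqs, dtype=float)
    if np.any((base <= 0) | (base >= 1)):
        raise ValueError("base frequencies must lie strictly in (0, 1)")
    scale = np.sqrt(base * (1.0 - base))
    out: dict[str, np.ndarray] = {}

    def walk(node: DriftNode, freqs: np.ndarray) -> None:
        if node.drift < 0:
            raise ValueError("branch drift must be non-negative")
        if node.drift > 0:
            freqs = freqs + rng.normal(0.0, math.sqrt(node.drift) * scale)
            freqs = np.clip(freqs, 1e-6, 1 - 1e-6)
        if node.is_leaf:
            if node.name is None:
                raise ValueError("leaf without a population name")
            if node.name in out:
                raise ValueError(f"duplicate population name {node.name!r}")
            out[node.name] = freqs
        else:
            for child in node.children:
                walk(child, freqs)

    walk(tree, base.copy())
    return out


def sample_population_genotypes(
    pop_freqs: dict[str, np.ndarray],
    panel: SnpPanel,
    n_per_pop: int = 10,
    ploidy_mode: str = "diploid",
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """HWE genotypes for each drifted population, plus a label→pop map."""
    rng = _rng(seed)
    labels: list[str] = []
    rows: list[np.ndarray] = []
    assignment: dict[str, str] = {}
    for pop, freqs in pop_freqs.items():
        for i in range(n_per_pop):
            label = f"{pop}_{i}"
            alt_dose = rng.binomial(2, freqs)
            rows.append((2 - alt_dose).astype(np.int8))  # ref-allele count
            labels.append(label)
            assignment[label] = pop
    gm = GenotypeMatrix(panel, labels, np.array(rows, dtype=np.int8), "diploid")
    if ploidy_mode == "pseudohaploid":
        gm = pseudo_haploidize(gm, 0.0, rng)
    return gm, assignment
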