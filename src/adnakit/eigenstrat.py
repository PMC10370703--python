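"""EIGENSTRAT genotype I/O and the in-memory genotype containers.

The geno/snp/ind triple is the lingua franca of SNP-capture ancient-DNA
work (the 1240k ecosystem).  Genotype codes count *reference* alleles:
2 = hom-ref, 1 = het, 0 = hom-alt, 9 = missing.  Pseudo-haploid calls,
where a single sequencing allele is sampled per site, use only {0, 2, 9}:
a sampled reference allele is written 2, a sampled alternate 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MISSING = 9

VALID_CHROMOSOMES = [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]

# EIGENSTRAT numeric chromosome codes for the non-autosomes
_CHROM_TO_CODE = {"X": "23", "Y": "24", "MT": "90"}
_CODE_TO_CHROM = {v: k for k, v in _CHROM_TO_CODE.items()}

_IUPAC_BASES = set("ACGT")


class FormatError(ValueError):
    """Raised when an on-disk file violates the format contract."""


@dataclass
class SnpPanel:
    """A SNP panel: the ordered set of sites genotypes are called on.

    Positions are 1-based and must be strictly increasing within a
    chromosome; site identifiers are unique; ref and alt alleles differ.
    """

    site_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    ref_alleles: np.ndarray
    alt_alleles: np.ndarray

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref_alleles = np.asarray(self.ref_alleles, dtype=object)
        self.alt_alleles = np.asarray(self.alt_alleles, dtype=object)
        n = len(self.site_ids)
        for name in ("chromosomes", "positions", "ref_alleles", "alt_alleles"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"panel field {name!r} has wrong length")
        if len(set(self.site_ids)) != n:
            raise ValueError("site_ids are not unique")
        for c in set(self.chromosomes):
            if c not in VALID_CHROMOSOMES:
                raise ValueError(f"invalid chromosome label {c!r}")
        for r, a in zip(self.ref_alleles, self.alt_alleles):
            if r not in _IUPAC_BASES or a not in _IUPAC_BASES:
                raise ValueError(f"invalid allele pair ({r!r}, {a!r})")
            if r == a:
                raise ValueError("ref and alt allele must differ")
        # strictly increasing positions within each chromosome
        for c in set(self.chromosomes):
            pos = self.positions[self.chromosomes == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def __len__(self) -> int:
        return self.n_sites

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpPanel):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in (
                "site_ids",
                "chromosomes",
                "positions",
                "ref_alleles",
                "alt_alleles",
            )
        )


@dataclass
class GenotypeMatrix:
    """Genotype calls for a set of individuals on a SNP panel.

    ``calls`` is individuals x sites, int8, with EIGENSTRAT coding
    (reference-allele count; 9 = missing).  ``ploidy_mode`` is either
    ``"diploid"`` ({0,1,2,9}) or ``"pseudohaploid"`` ({0,2,9}).
    """

    panel: SnpPanel
    individuals: list[str]
    calls: np.ndarray
    ploidy_mode: str = "diploid"
    sexes: list[str] | None = field(default=None)
    populations: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.individuals = list(self.individuals)
        if self.ploidy_mode not in ("diploid", "pseudohaploid"):
            raise ValueError(f"unknown ploidy_mode {self.ploidy_mode!r}")
        if self.calls.shape != (len(self.individuals), self.panel.n_sites):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {self.panel.n_sites} sites"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual labels are not unique")
        valid = {0, 1, 2, MISSING}
        observed = set(np.unique(self.calls).tolist())
        if not observed <= valid:
            raise ValueError(f"invalid genotype codes {observed - valid}")
        if self.ploidy_mode == "pseudohaploid" and 1 in observed:
            raise ValueError("pseudo-haploid matrix contains heterozygote code 1")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def index_of(self, label: str) -> int:
        try:
            return self.individuals.index(label)
        except ValueError:
            raise KeyError(f"unknown individual label {label!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.panel == other.panel
            and self.individuals == other.individuals
            and self.ploidy_mode == other.ploidy_mode
            and np.array_equal(self.calls, other.calls)
        )


def _chrom_to_file(label: str) -> str:
    return _CHROM_TO_CODE.get(label, label)


def _chrom_from_file(token: str) -> str:
    label = _CODE_TO_CHROM.get(token, token)
    if label not in VALID_CHROMOSOMES:
        raise FormatError(f"unrecognized chromosome token {token!r}")
    return label


def write_eigenstrat(matrix: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``prefix``.geno/.snp/.ind.

    Output is byte-stable for a fixed matrix: .geno holds one line per
    site with one genotype character per individual.
    """
    prefix = Path(prefix)
    panel = matrix.panel
    with open(f"{prefix}.snp", "w") as fh:
        for sid, chrom, pos, ref, alt in zip(
            panel.site_ids,
            panel.chromosomes,
            panel.positions,
            panel.ref_alleles,
            panel.alt_alleles,
        ):
            fh.write(f"{sid}\t{_chrom_to_file(chrom)}\t0.0\t{pos}\t{ref}\t{alt}\n")
    sexes = matrix.sexes or ["U"] * matrix.n_individuals
    pops = matrix.populations or ["POP"] * matrix.n_individuals
    with open(f"{prefix}.ind", "w") as fh:
        for label, sex, pop in zip(matrix.individuals, sexes, pops):
            fh.write(f"{label}\t{sex}\t{pop}\n")
    # sites are rows on disk: transpose the individuals x sites matrix
    codes = matrix.calls.T.astype("U1")
    with open(f"{prefix}.geno", "w") as fh:
        for row in codes:
            fh.write("".join(row) + "\n")


def read_eigenstrat(
    prefix: str | Path, ploidy_mode: str | None = None
) -> GenotypeMatrix:
    """Read a ``prefix``.geno/.snp/.ind triple into a GenotypeMatrix.

    ``ploidy_mode`` may be given explicitly; by default it is inferred
    as pseudo-haploid when no heterozygote code appears (the file format
    itself does not record the calling mode).
    """
    prefix = Path(prefix)
    snp_path, ind_path, geno_path = (
        f"{prefix}.snp",
        f"{prefix}.ind",
        f"{prefix}.geno",
    )
    site_ids, chroms, positions, refs, alts = [], [], [], [], []
    with open(snp_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{snp_path}:{lineno}: expected 6 columns")
            site_ids.append(fields[0])
            chroms.append(_chrom_from_file(fields[1]))
            positions.append(int(fields[3]))
            refs.append(fields[4])
            alts.append(fields[5])
    individuals, sexes, pops = [], [], []
    with open(ind_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            individuals.append(fields[0])
            sexes.append(fields[1] if len(fields) > 1 else "U")
            pops.append(fields[2] if len(fields) > 2 else "POP")
    n_ind, n_sites = len(individuals), len(site_ids)
    calls = np.full((n_ind, n_sites), MISSING, dtype=np.int8)
    with open(geno_path) as fh:
        row = -1
        for row, line in enumerate(fh):
            line = line.rstrip("\n")
            if row >= n_sites:
                raise FormatError(
                    f"{geno_path}: more genotype lines than {snp_path} sites"
                )
            if len(line) != n_ind:
                raise FormatError(
                    f"{geno_path}:{row + 1}: {len(line)} genotype characters "
                    f"but {ind_path} lists {n_ind} individuals"
                )
            try:
                calls[:, row] = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
            except ValueError as exc:
                raise FormatError(f"{geno_path}:{row + 1}: {exc}") from None
        if row + 1 != n_sites:
            raise FormatError(
                f"{geno_path}: {row + 1} genotype lines but {snp_path} "
                f"lists {n_sites} sites"
            )
    bad = ~np.isin(calls, (0, 1, 2, MISSING))
    if bad.any():
        site = int(np.argwhere(bad.any(axis=0))[0][0])
        raise FormatError(f"{geno_path}:{site + 1}: invalid genotype character")
    panel = SnpPanel(site_ids, chroms, positions, refs, alts)
    if ploidy_mode is None:
        ploidy_mode = "diploid" if (calls == 1).any() else "pseudohaploid"
    return GenotypeMatrix(
        panel, individuals, calls, ploidy_mode, sexes=sexes, populations=pops
    )
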