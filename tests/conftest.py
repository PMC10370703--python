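import numpy as np
import pytest

from adnakit.eigenstrat import GenotypeMatrix, SnpPanel


def make_panel(n_sites: int, chromosome: str = "1") -> SnpPanel:
    """Small single-chromosome panel for hand fixtures."""
    return SnpPanel(
        site_ids=[f"s{i}" for i in range(n_sites)],
        chromosomes=[chromosome] * n_sites,
        positions=np.arange(1, n_sites + 1) * 1000,
        ref_alleles=["A"] * n_sites,
        alt_alleles=["G"] * n_sites,
    )


def pseudo_matrix(rows: dict[str, list[int]]) -> GenotypeMatrix:
    """Pseudo-haploid matrix from per-individual code lists (0/2/9)."""
    labels = list(rows)
    calls = np.array([rows[l] for l in labels], dtype=np.int8)
    return GenotypeMatrix(
        make_panel(calls.shape[1]), labels, calls, "pseudohaploid"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
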