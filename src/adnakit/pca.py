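"""PCA of reference genotypes with least-squares projection of ancient samples.

Low-coverage ancient individuals cannot be co-fitted in a PCA (their
missingness would dominate), so the standard device is to fit components
on complete-ish reference genotypes and then solve, per ancient sample, a
least-squares problem restricted to that sample's non-missing sites —
the 'lsqproject' idea.  Sites are mean-centered and scaled by the
binomial standard deviation sqrt(p (1 - p)) of the site mean frequency;
sites monomorphic in the reference carry no information and are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eigenstrat import MISSING, GenotypeMatrix

DEFAULT_MIN_PROJECTION_SITES = 50


@dataclass
class PcaModel:
    """Fitted reference PCA: site stats, loadings and reference scores."""

    site_index: np.ndarray  # panel indices of the sites the model uses
    site_means: np.ndarray  # mean alt-allele dosage in [0, 1] per site
    site_scales: np.ndarray  # sqrt(p (1 - p)) per site
    loadings: np.ndarray  # components x sites, orthonormal rows
    explained_variances: np.ndarray
    reference_individuals: list[str]
    reference_coordinates: np.ndarray  # individuals x components

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def _alt_dosage(matrix: GenotypeMatrix) -> np.ndarray:
    """Alternate-allele dosage in [0, 1]; NaN where missing."""
    calls = matrix.calls.astype(float)
    dose = (2.0 - calls) / 2.0
    dose[matrix.calls == MISSING] = np.nan
    return dose


def fit_pca(reference: GenotypeMatrix, n_components: int = 2) -> PcaModel:
    """Fit components on reference genotypes (missing values mean-imputed).

    Components are ordered by explained variance; loadings are orthonormal
    over the retained (polymorphic) sites.
    """
    dose = _alt_dosage(reference)
    means = np.nanmean(dose, axis=0)
    observed_any = ~np.isnan(means)
    poly = observed_any & (means > 0) & (means < 1)
    if not poly.any():
        raise ValueError("no polymorphic sites in the reference")
    site_index = np.flatnonzero(poly)
    sub = dose[:, site_index]
    means = means[site_index]
    # mean imputation, then smartpca-style normalization
    nan_mask = np.isnan(sub)
    sub[nan_mask] = np.broadcast_to(means, sub.shape)[nan_mask]
    scales = np.sqrt(means * (1.0 - means))
    X = (sub - means) / scales
    max_rank = min(X.shape)
    if n_components > max_rank:
        raise ValueError(
            f"requested {n_components} components but rank is at most {max_rank}"
        )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = Vt[:n_components]
    scores = X @ loadings.T
    explained = (s[:n_components] ** 2) / max(X.shape[0] - 1, 1)
    return PcaModel(
        site_index=site_index,
        site_means=means,
        site_scales=scales,
        loadings=loadings,
        explained_variances=explained,
        reference_individuals=list(reference.individuals),
        reference_coordinates=scores,
    )


def project_sample(
    model: PcaModel,
    calls: np.ndarray,
    min_sites: int = DEFAULT_MIN_PROJECTION_SITES,
) -> np.ndarray:
    """Least-squares coordinates for one call vector on the full panel.

    ``calls`` is an EIGENSTRAT-coded vector over the model's original
    panel (pseudo-haploid or diploid).  Only the sample's non-missing
    sites among the model sites enter the solve; below ``min_sites`` of
    them the projection is refused.
    """
    calls = np.asarray(calls)
    sub = calls[model.site_index]
    observed = sub != MISSING
    n_obs = int(observed.sum())
    if n_obs < min_sites:
        raise ValueError(
            f"only {n_obs} usable sites overlap the model "
            f"(minimum {min_sites})"
        )
    dose = (2.0 - sub[observed].astype(float)) / 2.0
    x = (dose - model.site_means[observed]) / model.site_scales[observed]
    L = model.loadings[:, observed]
    coords, *_ = np.linalg.lstsq(L.T, x, rcond=None)
    return coords


def project_matrix(
    model: PcaModel,
    matrix: GenotypeMatrix,
    min_sites: int = DEFAULT_MIN_PROJECTION_SITES,
) -> dict[str, np.ndarray]:
    """Project every individual of a matrix sharing the model's panel."""
    return {
        label: project_sample(model, matrix.calls[i], min_sites)
        for i, label in enumerate(matrix.individuals)
    }
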