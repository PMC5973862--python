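"""Inbreeding (Wright's F) and principal-component structure diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lrldkit.errors import ConfigurationError
from lrldkit.genotype_io import (
    MISSING,
    GenotypeDataset,
    filter_markers,
    filter_samples,
)
from lrldkit.ld_core import ld_prune


@dataclass(frozen=True)
class InbreedingResult:
    f_mean: float
    per_marker_f: list[tuple[str, float]]
    n_markers: int
    n_samples: int


def wrights_f(
    dataset: GenotypeDataset,
    maf_min: float = 0.2,
    hwe_p_min: float = 0.001,
    sample_call_rate_min: float = 0.99,
    marker_ids: list[str] | None = None,
) -> InbreedingResult:
    """Mean population inbreeding coefficient F = 1 - Ho/He over markers.

    Samples below the per-individual call-rate threshold are removed
    first, then markers are filtered by MAF and HWE; F per marker uses
    observed heterozygote frequency Ho and plug-in He = 2p(1-p).
    ``marker_ids`` optionally restricts to a cross-cohort common set.
    """
    ds = filter_samples(dataset, sample_call_rate_min)
    if marker_ids is not None:
        present = [m for m in marker_ids if m in {mk.id for mk in ds.markers}]
        ds = ds.subset_markers(present)
    ds = filter_markers(ds, maf_min=maf_min, hwe_p_min=hwe_p_min)
    if ds.n_markers == 0:
        raise ConfigurationError("no markers survive the inbreeding filters")
    per_marker: list[tuple[str, float]] = []
    for m in ds.markers:
        g = ds.genotypes(m.id)
        obs = g[g != MISSING]
        p = float(obs.mean()) / 2.0
        he = 2.0 * p * (1.0 - p)
        ho = float(np.count_nonzero(obs == 1)) / obs.size
        per_marker.append((m.id, 1.0 - ho / he))
    fs = [f for _, f in per_marker]
    return InbreedingResult(
        f_mean=float(np.mean(fs)),
        per_marker_f=per_marker,
        n_markers=ds.n_markers,
        n_samples=ds.n_samples,
    )


def principal_components(
    dataset: GenotypeDataset,
    n_components: int,
    prune_r2: float = 0.3,
    prune_window: int = 50,
    prune_step: int = 5,
) -> np.ndarray:
    """Top principal components of the standardized genotype matrix.

    Markers are LD-pruned at r2 < ``prune_r2`` first. Missing calls are
    replaced by the marker mean; each marker column is mean-centered and
    scaled by sqrt(2p(1-p)). Returns an (n_samples, n_components) array;
    signs are fixed by making each component's largest-magnitude sample
    loading positive.
    """
    if dataset.n_markers == 0 or dataset.n_samples == 0:
        raise ConfigurationError("empty dataset")
    keep = ld_prune(dataset, r2_max=prune_r2, window_markers=prune_window,
                    step_markers=prune_step)
    ds = dataset.subset_markers(keep)
    X = ds.calls.astype(float)
    X[ds.calls == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    p = col_mean / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    informative = scale > 0
    X = (X[:, informative] - col_mean[informative]) / scale[informative]
    if X.shape[1] == 0 or not np.any(X != 0):
        raise ConfigurationError("degenerate (constant) genotype matrix")
    if n_components > min(X.shape):
        raise ConfigurationError(
            f"n_components {n_components} exceeds min(n_samples, n_markers)"
        )
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    pcs = U[:, :n_components] * S[:n_components]
    for k in range(pcs.shape[1]):
        j = np.argmax(np.abs(pcs[:, k]))
        if pcs[j, k] < 0:
            pcs[:, k] = -pcs[:, k]
    return pcs
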