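"""Case-control association tests: allelic 2x2, additive logistic, strata.

The allelic test compares counted-allele counts between cases and
controls with a Pearson chi-square (df=1) on the uncorrected table; the
OR and its Wald 95% CI use a Haldane-Anscombe 0.5 correction only when a
zero cell occurs. The logistic model is fit by iteratively reweighted
least squares with the genotype coded additively (0/1/2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from lrldkit.apoe_strata import (
    ApoeDiplotype,
    StratumAssignment,
    call_dataset,
    is_e4_carrier,
)
from lrldkit.errors import FitError, UndefinedStatsError
from lrldkit.genotype_io import MISSING, GenotypeDataset
from lrldkit.meta_analysis import Z_95


@dataclass(frozen=True)
class AssocResult:
    or_: float
    ci_low: float
    ci_high: float
    p: float
    model: str
    n_cases: int
    n_controls: int


def allelic_assoc(
    case_minor: int, case_major: int, ctrl_minor: int, ctrl_major: int
) -> AssocResult:
    """Allelic 2x2 association test from the four allele counts."""
    counts = np.array(
        [[case_minor, case_major], [ctrl_minor, ctrl_major]], dtype=float
    )
    if (counts < 0).any():
        raise ValueError("allele counts must be non-negative")
    if counts.sum(axis=1).min() == 0 or counts.sum(axis=0).min() == 0:
        raise UndefinedStatsError("zero row or column total; test undefined")
    # Pearson chi-square on the uncorrected table
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    n = counts.sum()
    expected = np.outer(row, col) / n
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, 1))
    # OR/CI on the (possibly Haldane-corrected) table
    t = counts + 0.5 if (counts == 0).any() else counts
    log_or = math.log(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    se = math.sqrt((1.0 / t).sum())
    return AssocResult(
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        p=p,
        model="allelic",
        n_cases=int(case_minor + case_major) // 2,
        n_controls=int(ctrl_minor + ctrl_major) // 2,
    )


def allele_counts(
    genotypes: np.ndarray, is_case: np.ndarray
) -> tuple[int, int, int, int]:
    """(case_minor, case_major, ctrl_minor, ctrl_major) counted-allele
    tallies from per-sample genotype values; missing calls skipped."""
    g = np.asarray(genotypes)
    ok = g != MISSING
    gc = g[ok & is_case]
    gt = g[ok & ~is_case]
    return (
        int(gc.sum()),
        int(2 * gc.size - gc.sum()),
        int(gt.sum()),
        int(2 * gt.size - gt.sum()),
    )


def allelic_assoc_marker(dataset: GenotypeDataset, marker: str) -> AssocResult:
    """Allelic test of one marker using dataset phenotypes."""
    phe = dataset.phenotype_codes()
    keep = phe != MISSING
    g = dataset.genotypes(marker)
    cm, cM, tm, tM = allele_counts(g[keep], phe[keep] == 1)
    return allelic_assoc(cm, cM, tm, tM)


def _irls_logit(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
    beta_max: float = 15.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Newton/IRLS logistic fit; returns (beta, cov, n_iter).

    Raises FitError on non-convergence or detected separation
    (any |beta| > beta_max)."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -math.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300)))
        w = mu * (1.0 - mu)
        if np.abs(beta).max() > beta_max:
            raise FitError(
                f"separation suspected: max|beta| = {np.abs(beta).max():.2f} "
                f"at iteration {it}"
            )
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
        XtW = X.T * w
        hess = XtW @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix: {exc}") from exc
        beta = beta + step
    else:
        raise FitError(f"IRLS did not converge in {max_iter} iterations")
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, cov, it


def logistic_additive(
    dataset: GenotypeDataset,
    marker: str,
    covariates: tuple[str, ...] = (),
    rs429358: str | None = None,
    rs7412: str | None = None,
) -> AssocResult:
    """Additive-model logistic regression of case status on a marker.

    ``covariates`` may include "sex", "age" and "e4_carrier"; the last
    requires the two APOE marker ids to derive carrier status. Age is
    centered before fitting. Complete-case rows only.
    """
    phe = dataset.phenotype_codes()
    g = dataset.genotypes(marker).astype(float)
    keep = (phe != MISSING) & (dataset.genotypes(marker) != MISSING)
    cols = [g]
    for cov in covariates:
        if cov == "sex":
            sex = np.array(
                [{"M": 0.0, "F": 1.0}.get(s.sex, np.nan) for s in dataset.samples]
            )
            keep &= ~np.isnan(sex)
            cols.append(sex)
        elif cov == "age":
            age = np.array(
                [np.nan if s.age is None else float(s.age) for s in dataset.samples]
            )
            keep &= ~np.isnan(age)
            cols.append(age)
        elif cov == "e4_carrier":
            if rs429358 is None or rs7412 is None:
                raise ValueError("e4_carrier covariate needs rs429358/rs7412 ids")
            diplos, _ = call_dataset(dataset, rs429358, rs7412)
            e4 = np.array(
                [
                    np.nan if d is ApoeDiplotype.UNKNOWN else float(is_e4_carrier(d))
                    for d in diplos
                ]
            )
            keep &= ~np.isnan(e4)
            cols.append(e4)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    y = (phe[keep] == 1).astype(float)
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    if n_cases < 10 or n_controls < 10:
        raise UndefinedStatsError(
            f"need >= 10 cases and controls, got {n_cases}/{n_controls}"
        )
    design = [np.ones(keep.sum())]
    for j, c in enumerate(cols):
        c = c[keep]
        if j > 0 and covariates[j - 1] == "age":
            c = c - c.mean()
        design.append(c)
    X = np.column_stack(design)
    beta, cov_mat, _ = _irls_logit(X, y)
    b = beta[1]
    se = math.sqrt(cov_mat[1, 1])
    z = b / se
    return AssocResult(
        or_=math.exp(b),
        ci_low=math.exp(b - Z_95 * se),
        ci_high=math.exp(b + Z_95 * se),
        p=float(2.0 * stats.norm.sf(abs(z))),
        model="logistic_additive",
        n_cases=n_cases,
        n_controls=n_controls,
    )


def stratified_assoc(
    dataset: GenotypeDataset,
    marker: str,
    strata: list[StratumAssignment],
) -> dict[StratumAssignment, AssocResult]:
    """Allelic association run independently inside each analysis stratum.

    EXCLUDED_E2E4 and UNASSIGNED samples are omitted; strata without both
    cases and controls (or with a degenerate allele table) are skipped
    with a warning."""
    if len(strata) != dataset.n_samples:
        raise ValueError("strata length must equal n_samples")
    phe = dataset.phenotype_codes()
    g = dataset.genotypes(marker)
    out: dict[StratumAssignment, AssocResult] = {}
    analyzed = (
        StratumAssignment.E2_CARRIER,
        StratumAssignment.E4_CARRIER,
        StratumAssignment.E3E3,
    )
    strata_arr = np.array([s.value for s in strata])
    for stratum in analyzed:
        mask = (strata_arr == stratum.value) & (phe != MISSING)
        if not mask.any():
            warnings.warn(f"stratum {stratum.value}: no samples; skipped")
            continue
        try:
            cm, cM, tm, tM = allele_counts(g[mask], phe[mask] == 1)
            out[stratum] = allelic_assoc(cm, cM, tm, tM)
        except UndefinedStatsError as exc:
            warnings.warn(f"stratum {stratum.value}: {exc}; skipped")
    return out
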