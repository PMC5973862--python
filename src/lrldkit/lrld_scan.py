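"""Long-range LD procedures: call rule, MAF-matched bootstrap null,
sliding-window chromosome LD profile, and the e2-carrier marker scan."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from lrldkit.errors import ConfigurationError, EmptyTableError, MonomorphicLocusError
from lrldkit.genotype_io import MISSING, GenotypeDataset, marker_stats
from lrldkit.ld_core import LDResult, ld_pair


@dataclass(frozen=True)
class WindowLD:
    chrom: str
    start_bp: int
    end_bp: int
    n_pairs: int
    mean_abs_dprime: float
    mean_r2: float


@dataclass(frozen=True)
class BootstrapNullResult:
    anchor_id: str
    target_id: str
    observed_abs_dprime: float
    B: int
    n_used: int
    n_exceed: int
    empirical_p: float
    seed: int


@dataclass(frozen=True)
class ScanHit:
    marker_id: str
    chi2: float
    p: float
    p_bonferroni: float


def lrld_decision(ld: LDResult, dprime_min: float = 0.2, p_max: float = 0.05) -> bool:
    """Long-range LD call: |D'| >= dprime_min and p < p_max."""
    return abs(ld.dprime) >= dprime_min and ld.p < p_max


def bootstrap_null_pvalue(
    dataset: GenotypeDataset,
    anchor: str,
    target: str,
    B: int = 10_000,
    maf_min: float = 0.20,
    maf_max: float = 0.40,
    seed: int = 0,
    exclude_chroms: tuple[str, ...] | None = None,
) -> BootstrapNullResult:
    """Empirical p-value of the observed anchor-target |D'| against a
    MAF-matched null of B markers drawn with replacement.

    Eligible null markers have MAF in [maf_min, maf_max] and do not lie
    on the excluded chromosomes (default: the anchor's and target's own
    chromosomes). Null draws where LD is undefined are skipped, so
    n_used may be below B. empirical_p = (n_exceed + 1) / (n_used + 1).
    """
    observed = abs(ld_pair(dataset, anchor, target).dprime)
    if exclude_chroms is None:
        ja = dataset.marker_index(anchor)
        jt = dataset.marker_index(target)
        exclude_chroms = (dataset.markers[ja].chrom, dataset.markers[jt].chrom)
    pool = []
    for m in dataset.markers:
        if m.chrom in exclude_chroms or m.id in (anchor, target):
            continue
        try:
            st = marker_stats(dataset, m.id)
        except Exception:
            continue
        if maf_min <= st.maf <= maf_max:
            pool.append(m.id)
    if not pool:
        raise ConfigurationError(
            f"no eligible null markers (MAF in [{maf_min}, {maf_max}], "
            f"off chromosomes {exclude_chroms})"
        )
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(pool), size=B)
    n_used = 0
    n_exceed = 0
    for k in draws:
        try:
            d = abs(ld_pair(dataset, anchor, pool[k]).dprime)
        except (MonomorphicLocusError, EmptyTableError):
            continue
        n_used += 1
        if d >= observed:
            n_exceed += 1
    return BootstrapNullResult(
        anchor_id=anchor,
        target_id=target,
        observed_abs_dprime=observed,
        B=B,
        n_used=n_used,
        n_exceed=n_exceed,
        empirical_p=(n_exceed + 1) / (n_used + 1),
        seed=seed,
    )


def sliding_window_ld(
    dataset: GenotypeDataset,
    chrom: str,
    window_bp: int = 1_700_000,
    step_bp: int = 100_000,
    min_sep_bp: int = 50_000,
    max_sep_bp: int = 500_000,
    maf_min: float = 0.2,
) -> list[WindowLD]:
    """Per-window mean |D'| and r2 along a chromosome.

    Windows of ``window_bp`` start at the chromosome's first marker
    position and advance by ``step_bp``. Within a window, every pair of
    common markers (MAF >= maf_min) separated by between ``min_sep_bp``
    and ``max_sep_bp`` contributes; windows with no pairs are omitted.
    """
    elig = []
    for m in dataset.markers:
        if m.chrom != chrom:
            continue
        try:
            if marker_stats(dataset, m.id).maf >= maf_min:
                elig.append(m)
        except Exception:
            continue
    if not elig:
        return []
    elig.sort(key=lambda m: m.bp)
    positions = [m.bp for m in elig]
    first, last = positions[0], positions[-1]
    cache: dict[tuple[str, str], LDResult | None] = {}

    def pair_ld(a, b):
        key = (a.id, b.id)
        if key not in cache:
            try:
                cache[key] = ld_pair(dataset, a.id, b.id)
            except (MonomorphicLocusError, EmptyTableError):
                cache[key] = None
        return cache[key]

    out: list[WindowLD] = []
    start = first
    while start <= last:
        end = start + window_bp - 1
        inside = [m for m in elig if start <= m.bp <= end]
        dps, r2s = [], []
        for i in range(len(inside)):
            for j in range(i + 1, len(inside)):
                sep = abs(inside[j].bp - inside[i].bp)
                if min_sep_bp <= sep <= max_sep_bp:
                    ld = pair_ld(inside[i], inside[j])
                    if ld is not None:
                        dps.append(abs(ld.dprime))
                        r2s.append(ld.r2)
        if dps:
            out.append(
                WindowLD(
                    chrom=chrom,
                    start_bp=start,
                    end_bp=end,
                    n_pairs=len(dps),
                    mean_abs_dprime=float(np.mean(dps)),
                    mean_r2=float(np.mean(r2s)),
                )
            )
        start += step_bp
    return out


def e2_association_scan(
    dataset: GenotypeDataset,
    e2_carrier: np.ndarray,
    alpha: float = 0.05,
) -> list[ScanHit]:
    """Per-marker 2x2 allelic chi-square of counted-allele counts in
    e2 carriers vs non-carriers, Bonferroni-corrected over the markers
    actually tested; sorted by p ascending."""
    e2_carrier = np.asarray(e2_carrier, dtype=bool)
    if e2_carrier.size != dataset.n_samples:
        raise ConfigurationError("e2_carrier length must equal n_samples")
    if e2_carrier.all() or not e2_carrier.any():
        raise ConfigurationError("both carrier classes must be non-empty")
    hits = []
    for m in dataset.markers:
        g = dataset.genotypes(m.id)
        ok = g != MISSING
        gc = g[ok & e2_carrier].astype(np.int64)
        gn = g[ok & ~e2_carrier].astype(np.int64)
        if gc.size == 0 or gn.size == 0:
            continue
        table = np.array(
            [
                [gc.sum(), 2 * gc.size - gc.sum()],
                [gn.sum(), 2 * gn.size - gn.sum()],
            ],
            dtype=float,
        )
        if table.sum(axis=0).min() == 0:
            continue  # monomorphic overall
        row, col = table.sum(axis=1), table.sum(axis=0)
        expected = np.outer(row, col) / table.sum()
        chi2 = float(((table - expected) ** 2 / expected).sum())
        hits.append((m.id, chi2, float(stats.chi2.sf(chi2, 1))))
    m_tested = len(hits)
    out = [
        ScanHit(marker_id=mid, chi2=c, p=p, p_bonferroni=min(1.0, p * m_tested))
        for mid, c, p in hits
    ]
    out.sort(key=lambda h: (h.p, h.marker_id))
    return out
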