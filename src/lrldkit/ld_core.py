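"""Two-locus haplotype frequency EM and linkage-disequilibrium statistics.

Estimates haplotype frequencies from unphased diploid genotypes, in which
only the double-heterozygote cell is phase-ambiguous, and derives the
signed disequilibrium coefficient D, signed D', r-squared and the df=1
chi-square LD significance test (chi2 = 2 N r2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from lrldkit.errors import EmptyTableError, MonomorphicLocusError
from lrldkit.genotype_io import MISSING, GenotypeDataset

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000


@dataclass(frozen=True)
class TwoLocusTable:
    """3x3 genotype cross-table over samples non-missing at both loci.

    ``counts[i][j]`` is the number of samples carrying i copies of the
    counted allele at locus A and j copies at locus B.
    """

    counts: np.ndarray
    n_samples: int

    @staticmethod
    def from_counts(counts) -> "TwoLocusTable":
        c = np.asarray(counts, dtype=np.int64)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("counts must be a non-negative 3x3 matrix")
        n = int(c.sum())
        if n < 1:
            raise EmptyTableError("two-locus table is empty")
        return TwoLocusTable(counts=c, n_samples=n)


@dataclass(frozen=True)
class HaplotypeFreqs:
    """EM-estimated two-locus haplotype frequencies.

    A/a denote the counted/other allele at locus 1, B/b at locus 2.
    """

    pAB: float
    pAb: float
    paB: float
    pab: float
    loglik: float
    n_iter: int
    converged: bool

    @property
    def pA(self) -> float:
        return self.pAB + self.pAb

    @property
    def pB(self) -> float:
        return self.pAB + self.paB


@dataclass(frozen=True)
class LDResult:
    D: float
    dprime: float
    r2: float
    chi2: float
    p: float
    n_samples: int


def two_locus_table(dataset: GenotypeDataset, m1: str, m2: str) -> TwoLocusTable:
    """Cross-tabulate two markers over pairwise-complete samples."""
    g1 = dataset.genotypes(m1)
    g2 = dataset.genotypes(m2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    if not ok.any():
        raise EmptyTableError(f"no jointly non-missing samples for {m1}, {m2}")
    idx = g1[ok].astype(np.int64) * 3 + g2[ok].astype(np.int64)
    counts = np.bincount(idx, minlength=9).reshape(3, 3)
    return TwoLocusTable(counts=counts, n_samples=int(counts.sum()))


def _loglik(counts: np.ndarray, pAB: float, pAb: float, paB: float, pab: float) -> float:
    probs = (
        pab * pab, 2 * paB * pab, paB * paB,
        2 * pAb * pab, 2 * (pAB * pab + pAb * paB), 2 * pAB * paB,
        pAb * pAb, 2 * pAB * pAb, pAB * pAB,
    )
    ll = 0.0
    flat = counts.ravel()  # row i = copies at A, col j = copies at B
    for n, pr in zip(flat, probs):
        if n:
            if pr <= 0.0:
                return -math.inf
            ll += n * math.log(pr)
    return ll


def _polish_boundary(counts, pAB, pAb, paB, pab):
    """Snap a vanishing haplotype frequency to exactly 0 when the MLE sits
    on the simplex boundary (EM approaches such points only geometrically).

    Moving mass pX from one haplotype to its two single-switch neighbours
    (and out of the opposite corner) preserves both allele-frequency
    marginals; the move is kept only if it does not lower the likelihood.
    """
    freqs = [pAB, pAb, paB, pab]
    opposite = {0: 3, 1: 2, 2: 1, 3: 0}
    for k in range(4):
        eps = freqs[k]
        if 0.0 < eps < 1e-6:
            cand = list(freqs)
            cand[k] = 0.0
            for j in range(4):
                if j != k and j != opposite[k]:
                    cand[j] += eps
            cand[opposite[k]] -= eps
            if cand[opposite[k]] >= 0.0 and _loglik(counts, *cand) >= _loglik(
                counts, *freqs
            ) - 1e-12:
                freqs = cand
    return tuple(freqs)


def em_haplotype_freqs(
    table: TwoLocusTable,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    trace: list | None = None,
) -> HaplotypeFreqs:
    """EM fixed point of the two-locus phase-ambiguity model.

    Initialized at linkage equilibrium (products of observed allele
    frequencies); each iteration splits the double-heterozygote cell in
    ratio pAB*pab : pAb*paB. Stops when the largest absolute frequency
    change drops below ``tol`` or after ``max_iter`` iterations.
    """
    n = table.counts
    N = table.n_samples
    nA = 2 * n[2, :].sum() + n[1, :].sum()
    nB = 2 * n[:, 2].sum() + n[:, 1].sum()
    if nA == 0 or nA == 2 * N or nB == 0 or nB == 2 * N:
        raise MonomorphicLocusError("a locus is monomorphic; LD undefined")
    pA = nA / (2.0 * N)
    pB = nB / (2.0 * N)
    pAB, pAb, paB, pab = pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)

    # phase-known haplotype contributions (everything but the n[1][1] cell)
    kAB = 2 * n[2, 2] + n[2, 1] + n[1, 2]
    kAb = 2 * n[2, 0] + n[2, 1] + n[1, 0]
    kaB = 2 * n[0, 2] + n[0, 1] + n[1, 2]
    kab = 2 * n[0, 0] + n[0, 1] + n[1, 0]
    ndh = n[1, 1]
    denom = 2.0 * N

    if ndh == 0:
        # no phase ambiguity: direct gamete counts are the exact MLE
        pAB, pAb, paB, pab = kAB / denom, kAb / denom, kaB / denom, kab / denom
        ll = _loglik(n, pAB, pAb, paB, pab)
        if trace is not None:
            trace.append(ll)
        return HaplotypeFreqs(
            pAB=pAB, pAb=pAb, paB=paB, pab=pab, loglik=ll, n_iter=1, converged=True
        )

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        coupling = pAB * pab
        repulsion = pAb * paB
        tot = coupling + repulsion
        x = 0.5 if tot <= 0.0 else coupling / tot
        new = (
            (kAB + ndh * x) / denom,
            (kAb + ndh * (1 - x)) / denom,
            (kaB + ndh * (1 - x)) / denom,
            (kab + ndh * x) / denom,
        )
        delta = max(
            abs(new[0] - pAB), abs(new[1] - pAb), abs(new[2] - paB), abs(new[3] - pab)
        )
        pAB, pAb, paB, pab = new
        if trace is not None:
            trace.append(_loglik(n, pAB, pAb, paB, pab))
        if delta < tol:
            converged = True
            break
    pAB, pAb, paB, pab = _polish_boundary(n, pAB, pAb, paB, pab)
    return HaplotypeFreqs(
        pAB=pAB,
        pAb=pAb,
        paB=paB,
        pab=pab,
        loglik=_loglik(n, pAB, pAb, paB, pab),
        n_iter=it,
        converged=converged,
    )


def ld_from_haplofreqs(h: HaplotypeFreqs, n_samples: int) -> LDResult:
    """Derive D, signed D', r2 and the chi-square LD test from haplotype
    frequencies. chi2 = 2 * n_samples * r2 with one degree of freedom."""
    pA, pB = h.pA, h.pB
    if not (0.0 < pA < 1.0) or not (0.0 < pB < 1.0):
        raise MonomorphicLocusError("monomorphic marginal; LD undefined")
    D = h.pAB - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if D == 0.0 else D / dmax
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    chi2 = 2.0 * n_samples * r2
    return LDResult(
        D=D,
        dprime=dprime,
        r2=r2,
        chi2=chi2,
        p=chi2_upper_tail_p(chi2, 1),
        n_samples=n_samples,
    )


def ld_pair(
    dataset: GenotypeDataset,
    m1: str,
    m2: str,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> LDResult:
    """Pairwise LD between two markers: table -> EM -> LD statistics."""
    table = two_locus_table(dataset, m1, m2)
    h = em_haplotype_freqs(table, tol=tol, max_iter=max_iter)
    return ld_from_haplofreqs(h, table.n_samples)


def chi2_upper_tail_p(chi2: float, df: int) -> float:
    """Upper-tail chi-square probability (survival function)."""
    if chi2 < 0:
        raise ValueError(f"chi2 must be >= 0, got {chi2}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(stats.chi2.sf(chi2, df))


def ld_prune(
    dataset: GenotypeDataset,
    r2_max: float = 0.3,
    window_markers: int = 50,
    step_markers: int = 5,
) -> list[str]:
    """Greedy left-to-right LD pruning within sliding marker windows.

    Whenever a retained pair inside a window has r2 > ``r2_max``, the
    later-positioned marker is dropped. Markers monomorphic among
    pairwise-complete samples contribute r2 = 0 (never pruned for LD).
    """
    n = dataset.n_markers
    removed = np.zeros(n, dtype=bool)
    start = 0
    while start < n:
        stop = min(start + window_markers, n)
        live = [j for j in range(start, stop) if not removed[j]]
        for a in range(len(live)):
            i = live[a]
            if removed[i]:
                continue
            for b in range(a + 1, len(live)):
                j = live[b]
                if removed[j]:
                    continue
                try:
                    r2 = ld_pair(dataset, dataset.markers[i].id, dataset.markers[j].id).r2
                except (MonomorphicLocusError, EmptyTableError):
                    continue
                if r2 > r2_max:
                    removed[j] = True
        if stop == n:
            break
        start += step_markers
    return [m.id for j, m in enumerate(dataset.markers) if not removed[j]]
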