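"""PLINK-format genotype I/O, per-marker statistics and filters.

Genotype calls count copies of the .bim A1 allele (``allele_counted``).
Missing calls are stored as :data:`MISSING` (-1) in an int8 matrix of
shape (n_samples, n_markers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from lrldkit.errors import ConsistencyError, FormatError, UndefinedStatsError

MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# two-bit PLINK codes -> copies of A1; 0b01 is the missing code
_CODE_TO_CALL = np.array([2, MISSING, 1, 0], dtype=np.int8)
_CALL_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


@dataclass(frozen=True)
class MarkerInfo:
    """One biallelic marker; positions are 1-based as in .bim files."""

    id: str
    chrom: str
    bp: int
    allele_counted: str
    allele_other: str
    build: str = ""

    def __post_init__(self) -> None:
        if self.bp < 1:
            raise ValueError(f"marker {self.id}: bp must be >= 1, got {self.bp}")
        if self.allele_counted == self.allele_other:
            raise ValueError(f"marker {self.id}: alleles must differ")


@dataclass(frozen=True)
class SampleInfo:
    """Sample metadata; phenotype is 'case', 'control' or None (missing)."""

    id: str
    phenotype: str | None = None
    sex: str | None = None
    age: float | None = None


@dataclass
class GenotypeDataset:
    """Samples x markers matrix of unphased minor-allele counts.

    Attributes
    ----------
    markers : list of MarkerInfo, ordered as the matrix columns
    samples : list of SampleInfo, ordered as the matrix rows
    calls : int8 ndarray (n_samples, n_markers) with entries {0,1,2,MISSING}
    """

    markers: list[MarkerInfo]
    samples: list[SampleInfo]
    calls: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ConsistencyError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.markers)})"
            )
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("genotype calls must be in {0, 1, 2, missing}")
        self._reindex()

    def _reindex(self) -> None:
        self._index = {m.id: j for j, m in enumerate(self.markers)}
        if len(self._index) != len(self.markers):
            raise ConsistencyError("duplicate marker ids in dataset")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"marker {marker_id!r} not in dataset") from None

    def genotypes(self, marker_id: str) -> np.ndarray:
        """Calls for one marker across all samples (int8 vector)."""
        return self.calls[:, self.marker_index(marker_id)]

    def phenotype_codes(self) -> np.ndarray:
        """Per-sample phenotype as 1 (case), 0 (control) or MISSING."""
        out = np.full(self.n_samples, MISSING, dtype=np.int8)
        for i, s in enumerate(self.samples):
            if s.phenotype == "case":
                out[i] = 1
            elif s.phenotype == "control":
                out[i] = 0
        return out

    def subset_samples(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeDataset(
            markers=list(self.markers),
            samples=[self.samples[i] for i in keep],
            calls=self.calls[keep, :].copy(),
        )

    def subset_markers(self, keep_ids: Iterable[str]) -> "GenotypeDataset":
        idx = [self.marker_index(mid) for mid in keep_ids]
        return GenotypeDataset(
            markers=[self.markers[j] for j in idx],
            samples=list(self.samples),
            calls=self.calls[:, idx].copy(),
        )

    def sort_markers(self) -> None:
        """Sort markers by (chrom, bp) in place; numeric chroms first."""

        def key(j: int):
            m = self.markers[j]
            numeric = m.chrom.isdigit()
            return (0, int(m.chrom)) if numeric else (1, 0), m.chrom, m.bp

        order = sorted(range(len(self.markers)), key=key)
        self.markers = [self.markers[j] for j in order]
        self.calls = self.calls[:, order]
        self._reindex()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.markers == other.markers
            and self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
        )


@dataclass(frozen=True)
class MarkerStats:
    maf: float
    call_rate: float
    het_obs: float
    hwe_p: float


# ---------------------------------------------------------------------------
# PLINK v1 binary I/O
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK v1 fileset (prefix.bed/.bim/.fam) into a dataset.

    The .bed must be SNP-major. Calls count copies of the .bim A1 allele.
    Phenotype codes map 1 -> control, 2 -> case, anything else -> missing.
    Markers are sorted by (chrom, bp) after loading.
    """
    prefix = Path(prefix)
    bim = _read_bim(prefix.with_suffix(".bim"))
    fam = _read_fam(prefix.with_suffix(".fam"))
    raw = prefix.with_suffix(".bed").read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != _SNP_MAJOR:
        raise FormatError(f"{prefix}.bed: only SNP-major mode (0x01) supported")
    n_samples, n_markers = len(fam), len(bim)
    bytes_per_marker = (n_samples + 3) // 4
    expected = 3 + bytes_per_marker * n_markers
    if len(raw) != expected:
        raise ConsistencyError(
            f"{prefix}.bed: size {len(raw)} != expected {expected} "
            f"for {n_samples} samples x {n_markers} markers"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if n_markers:
        body = body.reshape(n_markers, bytes_per_marker)
        # unpack 2-bit codes, sample s in bits (2s mod 8)..(2s mod 8 + 1)
        shifts = np.arange(4, dtype=np.uint8) * 2
        codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
        codes = codes.reshape(n_markers, -1)[:, :n_samples]
        calls = _CODE_TO_CALL[codes].T
    else:
        calls = np.zeros((n_samples, 0), dtype=np.int8)
    ds = GenotypeDataset(markers=bim, samples=fam, calls=calls)
    ds.sort_markers()
    return ds


def write_plink(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write a dataset as PLINK v1 .bed/.bim/.fam (SNP-major, bit-exact)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with prefix.with_suffix(".bim").open("w") as fh:
        for m in dataset.markers:
            fh.write(f"{m.chrom}\t{m.id}\t0\t{m.bp}\t{m.allele_counted}\t{m.allele_other}\n")
    with prefix.with_suffix(".fam").open("w") as fh:
        for s in dataset.samples:
            sex = {"M": 1, "F": 2}.get(s.sex, 0)
            phe = {"control": 1, "case": 2}.get(s.phenotype, -9)
            fh.write(f"{s.id}\t{s.id}\t0\t0\t{sex}\t{phe}\n")
    n_samples, n_markers = dataset.n_samples, dataset.n_markers
    bytes_per_marker = (n_samples + 3) // 4
    out = bytearray(_BED_MAGIC + bytes([_SNP_MAJOR]))
    lut = np.zeros(256, dtype=np.uint8)
    for call, code in _CALL_TO_CODE.items():
        lut[call & 0xFF] = code
    codes = lut[dataset.calls.astype(np.uint8)]  # (n_samples, n_markers)
    padded = np.full((bytes_per_marker * 4, n_markers), 0b00, dtype=np.uint8)
    padded[:n_samples, :] = codes
    shifts = np.arange(4, dtype=np.uint8) * 2
    grouped = padded.T.reshape(n_markers, bytes_per_marker, 4)
    packed = (grouped << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    out += packed.tobytes()
    prefix.with_suffix(".bed").write_bytes(bytes(out))


def _read_bim(path: Path) -> list[MarkerInfo]:
    markers: list[MarkerInfo] = []
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 6:
            raise FormatError(f"{path}:{line_no}: expected 6 columns")
        chrom, mid, _cm, bp, a1, a2 = parts
        markers.append(
            MarkerInfo(id=mid, chrom=chrom, bp=int(bp), allele_counted=a1, allele_other=a2)
        )
    return markers


def _read_fam(path: Path) -> list[SampleInfo]:
    samples: list[SampleInfo] = []
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 6:
            raise FormatError(f"{path}:{line_no}: expected 6 columns")
        _fid, iid, _f, _m, sex, phe = parts
        samples.append(
            SampleInfo(
                id=iid,
                phenotype={"1": "control", "2": "case"}.get(phe),
                sex={"1": "M", "2": "F"}.get(sex),
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Per-marker statistics
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom_counted: int, n_het: int, n_hom_other: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Two-sided by probability mass: sums the conditional probabilities of
    all heterozygote counts (at the observed allele counts) no more
    likely than the observed one. Returns 1.0 for monomorphic tables.
    """
    if min(n_hom_counted, n_het, n_hom_other) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_counted + n_het + n_hom_other
    if n == 0:
        raise UndefinedStatsError("empty genotype table")
    n_rare = 2 * min(n_hom_counted, n_hom_other) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # log P(n_het | allele counts) up to a constant, via the hypergeometric-like
    # recurrence; het count has the parity of n_rare
    hets = list(range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2))
    logp = {}
    h0 = hets[0]
    logp[h0] = 0.0
    for h in hets[1:]:
        # P(h)/P(h-2) = (rare_hom(h-2) * common_hom(h-2) * 4) / (h * (h-1))
        prev = h - 2
        rare_hom = (n_rare - prev) // 2
        common_hom = n - prev - rare_hom
        logp[h] = logp[prev] + math.log(4.0 * rare_hom * common_hom) - math.log(h * (h - 1))
    mx = max(logp.values())
    probs = {h: math.exp(lp - mx) for h, lp in logp.items()}
    total = sum(probs.values())
    obs = probs[n_het]
    p = sum(v for v in probs.values() if v <= obs * (1.0 + 1e-12)) / total
    return min(1.0, p)


def marker_stats(dataset: GenotypeDataset, marker_id: str) -> MarkerStats:
    """MAF, call rate, observed heterozygosity and HWE exact p for a marker."""
    g = dataset.genotypes(marker_id)
    obs = g[g != MISSING]
    if obs.size == 0:
        raise UndefinedStatsError(f"marker {marker_id}: all calls missing")
    p = float(obs.mean()) / 2.0
    maf = min(p, 1.0 - p)
    het = float(np.count_nonzero(obs == 1)) / obs.size
    n2 = int(np.count_nonzero(obs == 2))
    n1 = int(np.count_nonzero(obs == 1))
    n0 = int(np.count_nonzero(obs == 0))
    return MarkerStats(
        maf=maf,
        call_rate=obs.size / g.size,
        het_obs=het,
        hwe_p=hwe_exact_p(n2, n1, n0),
    )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_markers(
    dataset: GenotypeDataset,
    maf_min: float = 0.0,
    hwe_p_min: float = 0.0,
    call_rate_min: float = 0.0,
) -> GenotypeDataset:
    """Retain markers with maf > maf_min, hwe_p > hwe_p_min and
    call_rate >= call_rate_min. Markers with no non-missing calls are
    dropped unless all thresholds are zero."""
    keep = []
    for m in dataset.markers:
        try:
            st = marker_stats(dataset, m.id)
        except UndefinedStatsError:
            if maf_min == hwe_p_min == call_rate_min == 0.0:
                keep.append(m.id)
            continue
        if st.maf > maf_min and st.hwe_p > hwe_p_min and st.call_rate >= call_rate_min:
            keep.append(m.id)
    return dataset.subset_markers(keep)


def filter_samples(dataset: GenotypeDataset, call_rate_min: float = 0.99) -> GenotypeDataset:
    """Remove individuals with per-individual call rate below the threshold."""
    if dataset.n_markers == 0:
        return dataset.subset_samples(np.arange(dataset.n_samples))
    rates = (dataset.calls != MISSING).mean(axis=1)
    return dataset.subset_samples(rates >= call_rate_min)
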