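"""Synthetic genotype datasets with controlled LD and case-control labels.

Markers are simulated as haplotype blocks: each two-marker block draws
two haplotypes per individual from specified haplotype frequencies (so a
target signed D' is hit exactly in expectation), unlisted markers draw
binomial(2, maf) genotypes under HWE, and an APOE-like block over
(rs429358, rs7412) has the T-T haplotype frequency fixed at zero. Case
and control labels come from rejection sampling against an additive
logistic disease model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from lrldkit.errors import ConfigurationError, SimulationError
from lrldkit.genotype_io import MISSING, GenotypeDataset, MarkerInfo, SampleInfo
from lrldkit.ld_core import HaplotypeFreqs


@dataclass(frozen=True)
class MarkerSpec:
    id: str
    chrom: str
    bp: int
    maf: float


@dataclass(frozen=True)
class PairSpec:
    """Two markers simulated jointly at a target signed D'."""

    id_a: str
    id_b: str
    target_dprime: float


@dataclass(frozen=True)
class ApoeSpec:
    """Two-SNP APOE-like block; the T-T (e1) haplotype has frequency 0."""

    rs429358_id: str = "rs429358"
    rs7412_id: str = "rs7412"
    chrom: str = "19"
    bp_429358: int = 50_103_781
    bp_7412: int = 50_103_919
    p_e4: float = 0.14  # haplotype T-C (counted at rs429358 only)
    p_e2: float = 0.07  # haplotype C-T (counted at rs7412 only)

    @property
    def p_e3(self) -> float:
        return 1.0 - self.p_e4 - self.p_e2


@dataclass(frozen=True)
class EffectSpec:
    """Additive logistic disease model on APOE allele counts and one SNP."""

    beta0: float = -1.0
    beta_e4: float = 0.0
    beta_e2: float = 0.0
    beta_snp: float = 0.0
    snp_id: str | None = None


@dataclass
class SimConfig:
    n_samples: int
    chrom_map: list[MarkerSpec] = field(default_factory=list)
    pair_specs: list[PairSpec] = field(default_factory=list)
    apoe_spec: ApoeSpec | None = None
    effect_spec: EffectSpec | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        ids = [m.id for m in self.chrom_map]
        if self.apoe_spec is not None:
            ids += [self.apoe_spec.rs429358_id, self.apoe_spec.rs7412_id]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate marker ids in simulation config")


def haplofreqs_from_dprime(
    mafA: float, mafB: float, target_dprime: float
) -> HaplotypeFreqs:
    """Invert the signed D' definition to two-locus haplotype frequencies.

    The counted-allele frequencies are set to the two MAFs; D is
    target_dprime times the sign-matched Dmax.
    """
    if not (0.0 < mafA <= 0.5 and 0.0 < mafB <= 0.5):
        raise ConfigurationError("MAFs must be in (0, 0.5]")
    if abs(target_dprime) > 1.0:
        raise ConfigurationError("|target D'| must be <= 1")
    pA, pB = mafA, mafB
    if target_dprime > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    D = target_dprime * dmax
    pAB = pA * pB + D
    pAb = pA * (1 - pB) - D
    paB = (1 - pA) * pB - D
    pab = (1 - pA) * (1 - pB) + D
    freqs = (pAB, pAb, paB, pab)
    if min(freqs) < -1e-12 or max(freqs) > 1.0 + 1e-12:
        raise ConfigurationError(
            f"infeasible haplotype frequencies for MAFs ({mafA}, {mafB}) "
            f"at D' = {target_dprime}"
        )
    pAB, pAb, paB, pab = (min(1.0, max(0.0, f)) for f in freqs)
    return HaplotypeFreqs(
        pAB=pAB, pAb=pAb, paB=paB, pab=pab,
        loglik=math.nan, n_iter=0, converged=True,
    )


def _draw_block(rng: np.ndarray, probs: list[float], n: int) -> np.ndarray:
    """Two iid haplotype draws per individual -> (n, 2) category indices."""
    return rng.choice(len(probs), size=(n, 2), p=np.asarray(probs) / sum(probs))


def _generate_candidates(config: SimConfig, rng, n: int):
    """Genotype matrix for n candidate individuals plus APOE allele counts.

    Returns (calls (n, n_markers) int8, marker list, n_e4, n_e2).
    """
    markers: list[MarkerInfo] = []
    columns: list[np.ndarray] = []
    n_e4 = np.zeros(n, dtype=np.int8)
    n_e2 = np.zeros(n, dtype=np.int8)

    spec_by_id = {m.id: m for m in config.chrom_map}
    paired_ids = set()
    for ps in config.pair_specs:
        paired_ids.update((ps.id_a, ps.id_b))
        for mid in (ps.id_a, ps.id_b):
            if mid not in spec_by_id:
                raise ConfigurationError(f"pair marker {mid!r} missing from chrom_map")

    if config.apoe_spec is not None:
        a = config.apoe_spec
        # haplotype categories over (rs429358, rs7412): e3=(C,C), e4=(T,C), e2=(C,T)
        haps = _draw_block(rng, [a.p_e3, a.p_e4, a.p_e2], n)
        g4 = (haps == 1).sum(axis=1).astype(np.int8)
        g2 = (haps == 2).sum(axis=1).astype(np.int8)
        n_e4, n_e2 = g4.copy(), g2.copy()
        markers.append(MarkerInfo(a.rs429358_id, a.chrom, a.bp_429358, "T", "C"))
        columns.append(g4)
        markers.append(MarkerInfo(a.rs7412_id, a.chrom, a.bp_7412, "T", "C"))
        columns.append(g2)

    for ps in config.pair_specs:
        ma, mb = spec_by_id[ps.id_a], spec_by_id[ps.id_b]
        h = haplofreqs_from_dprime(ma.maf, mb.maf, ps.target_dprime)
        # categories: AB, Ab, aB, ab (counted allele = A/B)
        haps = _draw_block(rng, [h.pAB, h.pAb, h.paB, h.pab], n)
        ga = np.isin(haps, (0, 1)).sum(axis=1).astype(np.int8)
        gb = np.isin(haps, (0, 2)).sum(axis=1).astype(np.int8)
        markers.append(MarkerInfo(ma.id, ma.chrom, ma.bp, "A", "G"))
        columns.append(ga)
        markers.append(MarkerInfo(mb.id, mb.chrom, mb.bp, "A", "G"))
        columns.append(gb)

    for m in config.chrom_map:
        if m.id in paired_ids:
            continue
        g = rng.binomial(2, m.maf, size=n).astype(np.int8)
        markers.append(MarkerInfo(m.id, m.chrom, m.bp, "A", "G"))
        columns.append(g)

    calls = np.column_stack(columns) if columns else np.zeros((n, 0), dtype=np.int8)
    return calls.astype(np.int8), markers, n_e4, n_e2


def _case_probability(config: SimConfig, calls, markers, n_e4, n_e2) -> np.ndarray:
    eff = config.effect_spec or EffectSpec()
    eta = eff.beta0 + eff.beta_e4 * n_e4.astype(float) + eff.beta_e2 * n_e2.astype(float)
    if eff.snp_id is not None and eff.beta_snp != 0.0:
        idx = {m.id: j for j, m in enumerate(markers)}
        if eff.snp_id not in idx:
            raise ConfigurationError(f"effect SNP {eff.snp_id!r} not simulated")
        eta = eta + eff.beta_snp * calls[:, idx[eff.snp_id]].astype(float)
    return 1.0 / (1.0 + np.exp(-eta))


def simulate_dataset(config: SimConfig) -> GenotypeDataset:
    """Simulate a genotype dataset from a :class:`SimConfig`.

    With ``n_cases``/``n_controls`` set, candidates are drawn in batches
    and accepted as cases with the logistic model probability until both
    quotas are filled (cap: 1000 x the total target); otherwise
    ``n_samples`` individuals are generated and labeled by a single
    Bernoulli draw each (no label when no effect model is configured).
    """
    rng = np.random.default_rng(config.seed)

    if config.n_cases is None and config.n_controls is None:
        calls, markers, n_e4, n_e2 = _generate_candidates(config, rng, config.n_samples)
        if config.effect_spec is not None:
            prob = _case_probability(config, calls, markers, n_e4, n_e2)
            is_case = rng.random(config.n_samples) < prob
            phenos = ["case" if c else "control" for c in is_case]
        else:
            phenos = [None] * config.n_samples
    else:
        if config.n_cases is None or config.n_controls is None:
            raise ConfigurationError("set both n_cases and n_controls or neither")
        total = config.n_cases + config.n_controls
        cap = 1000 * total
        drawn = 0
        rows_case: list[np.ndarray] = []
        rows_ctrl: list[np.ndarray] = []
        markers = None
        while (
            (len(rows_case) < config.n_cases or len(rows_ctrl) < config.n_controls)
            and drawn < cap
        ):
            batch = min(max(total, 1024), cap - drawn)
            calls, markers, n_e4, n_e2 = _generate_candidates(config, rng, batch)
            prob = _case_probability(config, calls, markers, n_e4, n_e2)
            is_case = rng.random(batch) < prob
            drawn += batch
            for i in range(batch):
                if is_case[i] and len(rows_case) < config.n_cases:
                    rows_case.append(calls[i])
                elif not is_case[i] and len(rows_ctrl) < config.n_controls:
                    rows_ctrl.append(calls[i])
        if len(rows_case) < config.n_cases or len(rows_ctrl) < config.n_controls:
            raise SimulationError(
                f"could not reach {config.n_cases} cases / "
                f"{config.n_controls} controls within {cap} draws"
            )
        calls = np.vstack(rows_case + rows_ctrl).astype(np.int8)
        phenos = ["case"] * config.n_cases + ["control"] * config.n_controls

    if config.missing_rate > 0.0 and calls.size:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = calls.copy()
        calls[mask] = MISSING

    samples = [
        SampleInfo(id=f"S{i + 1:06d}", phenotype=ph)
        for i, ph in enumerate(phenos)
    ]
    ds = GenotypeDataset(markers=list(markers), samples=samples, calls=calls)
    ds.sort_markers()
    return ds


def default_background(
    n_markers: int = 200,
    seed: int = 0,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    exclude_chrom: str = "19",
) -> list[MarkerSpec]:
    """Background markers with MAFs ~ Uniform(maf_low, maf_high), spread
    over autosomes other than ``exclude_chrom``."""
    rng = np.random.default_rng(seed)
    chroms = [str(c) for c in range(1, 23) if str(c) != exclude_chrom]
    out = []
    for i in range(n_markers):
        out.append(
            MarkerSpec(
                id=f"bg{i + 1:05d}",
                chrom=chroms[i % len(chroms)],
                bp=1_000_000 + (i // len(chroms)) * 1_000_000,
                maf=float(rng.uniform(maf_low, maf_high)),
            )
        )
    return out


def simulate_apoe_cc_study(
    n_cases: int,
    n_controls: int,
    or_e4: float,
    or_e2: float,
    seed: int = 0,
    or_snp: float = 1.0,
    n_background: int = 200,
    missing_rate: float = 0.0,
) -> GenotypeDataset:
    """Case-control study with an APOE-like block, a CD33-like null (or
    effect) SNP on chromosome 19, and MAF-matched background markers."""
    if or_e4 <= 0 or or_e2 <= 0 or or_snp <= 0:
        raise ConfigurationError("odds ratios must be positive")
    cd33 = MarkerSpec(id="rs3865444", chrom="19", bp=56_419_774, maf=0.30)
    config = SimConfig(
        n_samples=n_cases + n_controls,
        chrom_map=[cd33] + default_background(n_background, seed=seed + 1),
        apoe_spec=ApoeSpec(),
        effect_spec=EffectSpec(
            beta0=-1.0,
            beta_e4=math.log(or_e4),
            beta_e2=math.log(or_e2),
            beta_snp=math.log(or_snp),
            snp_id="rs3865444" if or_snp != 1.0 else None,
        ),
        n_cases=n_cases,
        n_controls=n_controls,
        missing_rate=missing_rate,
        seed=seed,
    )
    return simulate_dataset(config)
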