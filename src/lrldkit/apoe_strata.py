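"""APOE epsilon diplotype calling and analysis-stratum assignment.

Diplotypes are called from the minor-allele counts of rs429358 (T defines
the e4 allele) and rs7412 (T defines the e2 allele) under the assumption
that the rs429358-T / rs7412-T haplotype (the rare e1 allele) is absent —
consistent with signed D' = -1 between the two SNPs. Input combinations
that would require a T-T haplotype are returned as UNKNOWN.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from lrldkit.genotype_io import MISSING, GenotypeDataset


class ApoeDiplotype(str, Enum):
    E2E2 = "E2E2"
    E2E3 = "E2E3"
    E2E4 = "E2E4"
    E3E3 = "E3E3"
    E3E4 = "E3E4"
    E4E4 = "E4E4"
    UNKNOWN = "UNKNOWN"


class StratumAssignment(str, Enum):
    E2_CARRIER = "E2_CARRIER"
    E4_CARRIER = "E4_CARRIER"
    E3E3 = "E3E3"
    EXCLUDED_E2E4 = "EXCLUDED_E2E4"
    UNASSIGNED = "UNASSIGNED"


_DIPLOTYPE_MAP = {
    (0, 0): ApoeDiplotype.E3E3,
    (1, 0): ApoeDiplotype.E3E4,
    (2, 0): ApoeDiplotype.E4E4,
    (0, 1): ApoeDiplotype.E2E3,
    (0, 2): ApoeDiplotype.E2E2,
    (1, 1): ApoeDiplotype.E2E4,
    # combinations requiring a T-T (e1) haplotype
    (2, 1): ApoeDiplotype.UNKNOWN,
    (2, 2): ApoeDiplotype.UNKNOWN,
    (1, 2): ApoeDiplotype.UNKNOWN,
}

_STRATUM_MAP = {
    ApoeDiplotype.E2E2: StratumAssignment.E2_CARRIER,
    ApoeDiplotype.E2E3: StratumAssignment.E2_CARRIER,
    ApoeDiplotype.E3E4: StratumAssignment.E4_CARRIER,
    ApoeDiplotype.E4E4: StratumAssignment.E4_CARRIER,
    ApoeDiplotype.E3E3: StratumAssignment.E3E3,
    ApoeDiplotype.E2E4: StratumAssignment.EXCLUDED_E2E4,
    ApoeDiplotype.UNKNOWN: StratumAssignment.UNASSIGNED,
}


def call_apoe_diplotype(g429358: int, g7412: int) -> ApoeDiplotype:
    """Call the epsilon diplotype from the two minor-allele counts.

    Either input missing, or any combination implying a T-T haplotype,
    yields UNKNOWN.
    """
    for g in (g429358, g7412):
        if g != MISSING and g not in (0, 1, 2):
            raise ValueError(f"genotype value {g!r} out of range")
    if g429358 == MISSING or g7412 == MISSING:
        return ApoeDiplotype.UNKNOWN
    return _DIPLOTYPE_MAP[(int(g429358), int(g7412))]


def assign_strata(d: ApoeDiplotype) -> StratumAssignment:
    """Map a diplotype to the three-stratum scheme (e2/e4 carriers, e3e3);
    E2E4 is always excluded."""
    return _STRATUM_MAP[d]


def is_e4_carrier(d: ApoeDiplotype) -> bool:
    """Whether the diplotype carries at least one e4 allele (E2E4 included)."""
    return d in (ApoeDiplotype.E3E4, ApoeDiplotype.E4E4, ApoeDiplotype.E2E4)


def is_e2_carrier(d: ApoeDiplotype) -> bool:
    """Whether the diplotype carries at least one e2 allele (E2E4 included)."""
    return d in (ApoeDiplotype.E2E2, ApoeDiplotype.E2E3, ApoeDiplotype.E2E4)


def call_dataset(
    dataset: GenotypeDataset, rs429358: str, rs7412: str
) -> tuple[list[ApoeDiplotype], list[StratumAssignment]]:
    """Call diplotypes and strata for every sample in a dataset."""
    g1 = dataset.genotypes(rs429358)
    g2 = dataset.genotypes(rs7412)
    diplos = [call_apoe_diplotype(int(a), int(b)) for a, b in zip(g1, g2)]
    return diplos, [assign_strata(d) for d in diplos]


def e4_dosage(diplos: list[ApoeDiplotype]) -> np.ndarray:
    """Copies of the e4 allele per sample; MISSING for UNKNOWN diplotypes."""
    dose = {
        ApoeDiplotype.E4E4: 2,
        ApoeDiplotype.E3E4: 1,
        ApoeDiplotype.E2E4: 1,
        ApoeDiplotype.E3E3: 0,
        ApoeDiplotype.E2E3: 0,
        ApoeDiplotype.E2E2: 0,
        ApoeDiplotype.UNKNOWN: MISSING,
    }
    return np.array([dose[d] for d in diplos], dtype=np.int8)
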