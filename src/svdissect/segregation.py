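"""Co-segregation of a genotyped variant with affection status in a pedigree.

Counts are restricted to genotyped individuals with known affection status;
perfect co-segregation means every genotyped affected individual carries
the variant and no genotyped unaffected individual does (and at least one
genotyped affected individual exists). A transmission check flags carrier
children whose parents are both genotyped non-carriers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .synthgenome import Pedigree


@dataclass
class SegregationResult:
    n_affected_genotyped: int
    n_affected_carriers: int
    n_unaffected_genotyped: int
    n_unaffected_carriers: int

    def __post_init__(self) -> None:
        if self.n_affected_carriers > self.n_affected_genotyped:
            raise ValueError("more affected carriers than genotyped affected")
        if self.n_unaffected_carriers > self.n_unaffected_genotyped:
            raise ValueError("more unaffected carriers than genotyped unaffected")

    @property
    def perfect_cosegregation(self) -> bool:
        return (
            self.n_affected_genotyped > 0
            and self.n_affected_carriers == self.n_affected_genotyped
            and self.n_unaffected_carriers == 0
        )


def cosegregation_counts(pedigree: Pedigree) -> SegregationResult:
    """Carrier counts among genotyped affected/unaffected individuals.

    Untested individuals and individuals of unknown affection status are
    excluded from all denominators.
    """
    n_aff = c_aff = n_un = c_un = 0
    for iid, _sex, _f, _m, affected in pedigree.individuals:
        status = pedigree.status(iid)
        if status == "untested" or affected == "unknown":
            continue
        if affected == "yes":
            n_aff += 1
            c_aff += status == "carrier"
        else:
            n_un += 1
            c_un += status == "carrier"
    return SegregationResult(n_aff, c_aff, n_un, c_un)


@dataclass
class TransmissionViolation:
    child_id: str
    father_id: str
    mother_id: str


def transmission_check(pedigree: Pedigree) -> tuple[list[TransmissionViolation], int]:
    """Dominant-transmission consistency.

    Returns (violations, carrier-parent -> carrier-child transmissions).
    A violation is a carrier child both of whose parents are genotyped
    non-carriers (de novo event or genotyping inconsistency).
    """
    violations: list[TransmissionViolation] = []
    transmissions = 0
    for iid, _sex, father, mother, _aff in pedigree.individuals:
        if pedigree.status(iid) != "carrier":
            continue
        parent_status = [
            pedigree.status(p) for p in (father, mother) if p is not None
        ]
        if any(s == "carrier" for s in parent_status):
            transmissions += 1
        elif len(parent_status) == 2 and all(s == "non_carrier" for s in parent_status):
            violations.append(TransmissionViolation(iid, father, mother))
    return violations, transmissions


def write_result_json(path: str | Path, result: SegregationResult) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "n_affected_genotyped": result.n_affected_genotyped,
                "n_affected_carriers": result.n_affected_carriers,
                "n_unaffected_genotyped": result.n_unaffected_genotyped,
                "n_unaffected_carriers": result.n_unaffected_carriers,
                "perfect_cosegregation": result.perfect_cosegregation,
            },
            indent=2,
        )
    )
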