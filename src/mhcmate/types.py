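"""Shared domain types for the amplicon genotyping / mate-choice pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Mapping, Optional, Tuple

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class AlleleSequence:
    """One nucleotide haplotype with a stable identifier."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("allele id must be non-empty")
        if not self.seq:
            raise ValueError(f"allele {self.id!r}: empty sequence")
        bad = set(self.seq) - set("ACGTN-")
        if bad:
            raise ValueError(
                f"allele {self.id!r}: illegal characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class IndividualGenotype:
    """A validated allele set carried by one individual.

    ``allele_ids`` is an unordered set because duplicated loci cannot be
    resolved from amplicon data; ``true_loci`` optionally records the
    simulated locus-resolved truth for testing and is never used by the
    analysis code.
    """

    individual_id: str
    allele_ids: FrozenSet[str]
    population_id: str = "pop1"
    sex: str = "unknown"
    allele_depths: Optional[Mapping[str, int]] = None
    true_loci: Optional[Tuple[Tuple[str, str], ...]] = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "allele_ids", frozenset(self.allele_ids))
        if not self.allele_ids:
            raise ValueError(
                f"individual {self.individual_id!r}: empty allele set"
            )
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"invalid sex {self.sex!r}")

    @property
    def n_alleles(self) -> int:
        return len(self.allele_ids)


@dataclass(frozen=True)
class BreedingPair:
    """A male/female genotype pairing, the unit of the mate-choice tests."""

    male: IndividualGenotype
    female: IndividualGenotype

    def __post_init__(self) -> None:
        if self.male.sex == "female" or self.female.sex == "male":
            raise ValueError(
                f"pair ({self.male.individual_id}, "
                f"{self.female.individual_id}): sexes inconsistent with roles"
            )


@dataclass(frozen=True)
class AmpliconVariantRecord:
    """One observed read-variant within an individual x run amplicon."""

    individual_id: str
    run_id: str
    sequence: str
    depth: int
    mean_quality: float

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("variant depth must be >= 1")
        if not self.sequence or set(self.sequence) - _NUCLEOTIDES:
            raise ValueError("variant sequence must be a non-empty ACGT string")
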