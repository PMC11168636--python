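"""Readers and writers for the pipeline's plain-text formats.

Conventions: tab-separated tables with header rows, allele sets
serialized semicolon-joined, 0-based half-open coordinates, and a
``# key=value`` comment header carrying seed/config provenance.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import List, Mapping, Optional, Sequence, Tuple

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .selection import CodonPartition
from .types import (
    AlleleSequence,
    AmpliconVariantRecord,
    BreedingPair,
    IndividualGenotype,
)


def read_fasta(path) -> List[AlleleSequence]:
    """Load allele sequences; IDs must be unique, sequences non-empty
    ACGTN strings (case-insensitive, line wrapping accepted)."""
    alleles: List[AlleleSequence] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {rec.id!r}")
        alleles.append(AlleleSequence(id=rec.id, seq=seq))
    if not alleles:
        raise ValueError(f"no FASTA records in {path}")
    return alleles


def write_fasta(path, alleles: Sequence[AlleleSequence], wrap: int = 70) -> None:
    records = [SeqRecord(Seq(a.seq), id=a.id, description="")
               for a in alleles]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def _read_table(path) -> Tuple[List[str], List[List[str]]]:
    header: Optional[List[str]] = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
            else:
                rows.append(parts)
    if header is None:
        raise ValueError(f"empty table {path}")
    return header, rows


def _header_lines(meta: Optional[Mapping[str, object]]) -> List[str]:
    if not meta:
        return []
    return [f"# {k}={v}" for k, v in meta.items()]


def write_genotypes(
    path, genotypes: Sequence[IndividualGenotype],
    meta: Optional[Mapping[str, object]] = None,
) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("individual_id\tpopulation_id\tsex\talleles\tdepths\n")
        for g in genotypes:
            alleles = sorted(g.allele_ids)
            depths = ";".join(
                str(g.allele_depths.get(a, ".")) for a in alleles
            ) if g.allele_depths else "."
            fh.write(f"{g.individual_id}\t{g.population_id}\t{g.sex}\t"
                     f"{';'.join(alleles)}\t{depths}\n")


def read_genotypes(
    path,
    alleles: Optional[Sequence[AlleleSequence]] = None,
    max_alleles: int = 4,
) -> List[IndividualGenotype]:
    """Genotype table with referential-integrity checks against an
    optional allele FASTA."""
    header, rows = _read_table(path)
    required = {"individual_id", "population_id", "sex", "alleles"}
    missing = required - set(header)
    if missing:
        raise ValueError(f"genotype table missing columns {sorted(missing)}")
    col = {name: header.index(name) for name in header}
    known = {a.id for a in alleles} if alleles is not None else None
    out = []
    for row in rows:
        ind = row[col["individual_id"]]
        allele_ids = [a for a in row[col["alleles"]].split(";") if a]
        if len(allele_ids) > max_alleles:
            raise ValueError(
                f"individual {ind!r} lists {len(allele_ids)} alleles "
                f"(maximum {max_alleles})"
            )
        if known is not None:
            unknown = sorted(set(allele_ids) - known)
            if unknown:
                raise ValueError(
                    f"individual {ind!r} references unknown alleles {unknown}"
                )
        depths = None
        if "depths" in col and row[col["depths"]] != ".":
            parts = row[col["depths"]].split(";")
            if len(parts) == len(allele_ids) and all(
                p.isdigit() for p in parts
            ):
                depths = dict(zip(sorted(allele_ids), parts))
                depths = {k: int(v) for k, v in depths.items()}
        out.append(IndividualGenotype(
            individual_id=ind,
            allele_ids=frozenset(allele_ids),
            population_id=row[col["population_id"]],
            sex=row[col["sex"]],
            allele_depths=depths,
        ))
    return out


def write_pairs(
    path, pairs: Sequence[BreedingPair],
    meta: Optional[Mapping[str, object]] = None,
) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("male_id\tfemale_id\n")
        for p in pairs:
            fh.write(f"{p.male.individual_id}\t{p.female.individual_id}\n")


def read_pairs(
    path, genotypes: Sequence[IndividualGenotype]
) -> List[BreedingPair]:
    header, rows = _read_table(path)
    if header[:2] != ["male_id", "female_id"]:
        raise ValueError("pairs table must have columns male_id, female_id")
    by_id = {g.individual_id: g for g in genotypes}
    offenders = sorted(
        {i for row in rows for i in row[:2] if i not in by_id}
    )
    if offenders:
        raise ValueError(f"pairs reference unknown individuals: {offenders}")
    return [BreedingPair(male=by_id[row[0]], female=by_id[row[1]])
            for row in rows]


def write_variants(
    path, records: Sequence[AmpliconVariantRecord],
    meta: Optional[Mapping[str, object]] = None,
) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("individual_id\trun_id\tsequence\tdepth\tmean_quality\n")
        for r in records:
            fh.write(f"{r.individual_id}\t{r.run_id}\t{r.sequence}\t"
                     f"{r.depth}\t{r.mean_quality}\n")


def read_variants(path) -> List[AmpliconVariantRecord]:
    header, rows = _read_table(path)
    required = ["individual_id", "run_id", "sequence", "depth",
                "mean_quality"]
    if header[:5] != required:
        raise ValueError(f"variant table must have columns {required}")
    return [
        AmpliconVariantRecord(
            individual_id=row[0], run_id=row[1], sequence=row[2],
            depth=int(row[3]), mean_quality=float(row[4]),
        )
        for row in rows
    ]


def read_mask(path) -> CodonPartition:
    """PBR codon mask config: frame_offset, total_codons, pbr_codons."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return CodonPartition(
        frame_offset=int(data["frame_offset"]),
        pbr_codons=frozenset(int(i) for i in data["pbr_codons"]),
        total_codons=int(data["total_codons"]),
    )


def write_mask(path, partition: CodonPartition) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "frame_offset": partition.frame_offset,
                "total_codons": partition.total_codons,
                "pbr_codons": sorted(partition.pbr_codons),
            },
            fh, sort_keys=False,
        )


def default_mask_path() -> Path:
    return Path(str(resources.files("mhcmate") / "data" / "pbr_mask.yaml"))


def default_partition() -> CodonPartition:
    return read_mask(default_mask_path())


def config_hash(config: Mapping[str, object]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
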