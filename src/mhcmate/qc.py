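"""Read/variant/allele filtering for replicated amplicon genotyping.

The pipeline mirrors a standard amplicon allele-calling cascade:

1. ``clean_variants``      drop low-quality and anomalous-length variants
2. ``consolidate_errors``  merge putative error variants into their parents
3. ``flag_chimeras``       remove splices of two abundant parents
4. ``combine_runs``        sum depths across sequencing runs
5. ``call_genotype``       frequency/depth/replication/ORF filters, cap at
                           ``max_alleles_per_individual``
"""

from __future__ import annotations

import hashlib
import math
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner

from .selection import STOP_CODONS
from .types import AmpliconVariantRecord, IndividualGenotype


@dataclass(frozen=True)
class QCConfig:
    min_mean_quality: float = 30.0
    expected_length_nt: int = 298
    substitution_error_rate: float = 0.005
    indel_error_rate: float = 0.01
    min_amplicon_freq: float = 0.01
    chimera_freq_threshold: float = 0.05
    min_singleton_reads: int = 200
    max_alleles_per_individual: int = 4
    frame_offset: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_error_rate", "indel_error_rate",
                     "min_amplicon_freq", "chimera_freq_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("expected_length_nt", "min_singleton_reads",
                     "max_alleles_per_individual"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be in {0, 1, 2}")

    @property
    def max_substitutions(self) -> int:
        return max(1, math.floor(self.substitution_error_rate
                                 * self.expected_length_nt))

    @property
    def max_indels(self) -> int:
        return max(1, math.floor(self.indel_error_rate
                                 * self.expected_length_nt))


@dataclass(frozen=True)
class CombinedVariant:
    individual_id: str
    sequence: str
    depth: int
    runs: FrozenSet[str]


@dataclass(frozen=True)
class GenotypeRejection:
    individual_id: str
    reason: str


GenotypeCall = Union[IndividualGenotype, GenotypeRejection]


def clean_variants(
    records: Sequence[AmpliconVariantRecord], cfg: QCConfig
) -> List[AmpliconVariantRecord]:
    """Drop variants with mean quality < threshold (strict) or a length
    different from the expected amplicon size; order-stable otherwise."""
    return [
        r for r in records
        if r.mean_quality >= cfg.min_mean_quality
        and len(r.sequence) == cfg.expected_length_nt
    ]


_ALIGNER = PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 1.0
_ALIGNER.mismatch_score = -1.0
# slight preference for substitutions over gap pairs keeps counts stable
_ALIGNER.open_gap_score = -1.2
_ALIGNER.extend_gap_score = -1.2


def pairwise_differences(a: str, b: str) -> Tuple[int, int]:
    """(substitutions, indel bases) under a global pairwise alignment."""
    if len(a) == len(b):
        xa = np.frombuffer(a.encode(), np.uint8)
        xb = np.frombuffer(b.encode(), np.uint8)
        return int((xa != xb).sum()), 0
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    return int(counts.mismatches), int(counts.gaps)


def _group_by_amplicon(records):
    groups = defaultdict(list)
    for r in records:
        groups[(r.individual_id, r.run_id)].append(r)
    return groups


def consolidate_errors(
    records: Sequence[AmpliconVariantRecord], cfg: QCConfig
) -> List[AmpliconVariantRecord]:
    """Merge low-abundance error variants into more abundant parents.

    Within each individual x run amplicon, a variant merges its depth
    into a strictly deeper parent when their pairwise alignment shows at
    most ``max(1, floor(sub_rate*L))`` substitutions and
    ``max(1, floor(indel_rate*L))`` indel bases. Parents are visited from
    most to least abundant; total amplicon depth is conserved.
    """
    out: List[AmpliconVariantRecord] = []
    for (_ind, _run), group in _group_by_amplicon(records).items():
        order = sorted(group, key=lambda r: (-r.depth, r.sequence))
        depths = [r.depth for r in order]
        merged = [False] * len(order)
        extra = [0] * len(order)  # absorbed depth per surviving parent
        for i in range(len(order)):
            if merged[i]:
                continue
            for j in range(i + 1, len(order)):
                if merged[j] or depths[j] >= depths[i]:
                    continue
                if abs(len(order[j].sequence) - len(order[i].sequence)) \
                        > cfg.max_indels:
                    continue
                subs, indels = pairwise_differences(
                    order[i].sequence, order[j].sequence
                )
                if subs <= cfg.max_substitutions and indels <= cfg.max_indels:
                    merged[j] = True
                    extra[i] += depths[j] + extra[j]
                    extra[j] = 0
        for i, r in enumerate(order):
            if not merged[i]:
                out.append(replace(r, depth=r.depth + extra[i]))
    return out


def flag_chimeras(
    records: Sequence[AmpliconVariantRecord], cfg: QCConfig
) -> List[AmpliconVariantRecord]:
    """Remove variants explainable as a single-breakpoint splice of two
    distinct, abundant (frequency >= threshold), deeper parents."""
    out: List[AmpliconVariantRecord] = []
    for (_ind, _run), group in _group_by_amplicon(records).items():
        total = sum(r.depth for r in group)
        for r in group:
            parents = [
                p for p in group
                if p.sequence != r.sequence
                and p.depth > r.depth
                and p.depth / total >= cfg.chimera_freq_threshold
                and len(p.sequence) == len(r.sequence)
            ]
            if not _is_splice(r.sequence, parents):
                out.append(r)
    return out


def _is_splice(seq: str, parents) -> bool:
    L = len(seq)
    for p1 in parents:
        # longest prefix of seq matching p1
        l1 = 0
        s1 = p1.sequence
        while l1 < L and seq[l1] == s1[l1]:
            l1 += 1
        if l1 == 0:
            continue
        for p2 in parents:
            if p2.sequence == p1.sequence:
                continue
            s2 = p2.sequence
            s2_suffix = 0
            while s2_suffix < L and seq[L - 1 - s2_suffix] == s2[L - 1 - s2_suffix]:
                s2_suffix += 1
            # need breakpoint b with 1 <= b <= l1 and b >= L - s2_suffix
            if max(1, L - s2_suffix) <= l1:
                return True
    return False


def combine_runs(
    records: Sequence[AmpliconVariantRecord], cfg: QCConfig
) -> List[CombinedVariant]:
    """Sum depths per (individual, sequence), retaining run presence."""
    acc: Dict[Tuple[str, str], Dict] = {}
    for r in records:
        key = (r.individual_id, r.sequence)
        if key not in acc:
            acc[key] = {"depth": 0, "runs": set()}
        acc[key]["depth"] += r.depth
        acc[key]["runs"].add(r.run_id)
    return [
        CombinedVariant(individual_id=ind, sequence=seq,
                        depth=v["depth"], runs=frozenset(v["runs"]))
        for (ind, seq), v in sorted(acc.items())
    ]


def _orf_ok(seq: str, frame_offset: int) -> bool:
    n_codons = (len(seq) - frame_offset) // 3
    for i in range(n_codons):
        if seq[frame_offset + 3 * i: frame_offset + 3 * i + 3] in STOP_CODONS:
            return False
    return True


def _variant_allele_id(seq: str,
                       catalog: Optional[Mapping[str, str]]) -> str:
    if catalog is not None and seq in catalog:
        return catalog[seq]
    return "novel-" + hashlib.sha1(seq.encode()).hexdigest()[:8]


def call_genotype(
    variants: Sequence[CombinedVariant],
    cfg: QCConfig,
    allele_catalog: Optional[Mapping[str, str]] = None,
    population_id: str = "pop1",
    sex: str = "unknown",
) -> GenotypeCall:
    """Final allele call for one individual's combined variant table.

    Keeps variants with amplicon frequency >= ``min_amplicon_freq``
    (inclusive); single-run individuals additionally need
    ``min_singleton_reads`` per variant, two-run individuals need presence
    in both runs OR ``min_singleton_reads``; length and stop-free ORF are
    validated; at most ``max_alleles_per_individual`` deepest variants are
    retained (ties broken lexicographically). Rejection is a typed
    outcome, not an exception.
    """
    if not variants:
        return GenotypeRejection("?", "no variants")
    individual_id = variants[0].individual_id
    if any(v.individual_id != individual_id for v in variants):
        raise ValueError("call_genotype expects a single individual's table")
    total = sum(v.depth for v in variants)
    runs_seen = frozenset().union(*(v.runs for v in variants))
    multi_run = len(runs_seen) >= 2
    kept = []
    for v in variants:
        if v.depth / total < cfg.min_amplicon_freq:
            continue
        if multi_run:
            if len(v.runs) < 2 and v.depth < cfg.min_singleton_reads:
                continue
        else:
            if v.depth < cfg.min_singleton_reads:
                continue
        if len(v.sequence) != cfg.expected_length_nt:
            continue
        if not _orf_ok(v.sequence, cfg.frame_offset):
            continue
        kept.append(v)
    if not kept:
        return GenotypeRejection(individual_id, "no variant passed filters")
    kept.sort(key=lambda v: (-v.depth, v.sequence))
    kept = kept[:cfg.max_alleles_per_individual]
    ids = {_variant_allele_id(v.sequence, allele_catalog): v.depth
           for v in kept}
    return IndividualGenotype(
        individual_id=individual_id,
        allele_ids=frozenset(ids),
        population_id=population_id,
        sex=sex,
        allele_depths=ids,
    )


def run_pipeline(
    records: Sequence[AmpliconVariantRecord],
    cfg: QCConfig,
    allele_catalog: Optional[Mapping[str, str]] = None,
    metadata: Optional[Mapping[str, Tuple[str, str]]] = None,
) -> Tuple[List[IndividualGenotype], List[GenotypeRejection], Dict[str, int]]:
    """clean -> consolidate -> de-chimera -> combine -> call, with a
    per-filter drop-count report."""
    report: Dict[str, int] = {"input_variants": len(records)}
    cleaned = clean_variants(records, cfg)
    report["dropped_clean"] = len(records) - len(cleaned)
    consolidated = consolidate_errors(cleaned, cfg)
    report["merged_errors"] = len(cleaned) - len(consolidated)
    no_chim = flag_chimeras(consolidated, cfg)
    report["dropped_chimeras"] = len(consolidated) - len(no_chim)
    combined = combine_runs(no_chim, cfg)
    report["combined_variants"] = len(combined)
    by_ind = defaultdict(list)
    for v in combined:
        by_ind[v.individual_id].append(v)
    genotypes, rejections = [], []
    for ind in sorted(by_ind):
        pop, sex = ("pop1", "unknown")
        if metadata and ind in metadata:
            pop, sex = metadata[ind]
        call = call_genotype(by_ind[ind], cfg, allele_catalog,
                             population_id=pop, sex=sex)
        if isinstance(call, GenotypeRejection):
            rejections.append(call)
        else:
            genotypes.append(call)
    report["individuals_called"] = len(genotypes)
    report["individuals_rejected"] = len(rejections)
    return genotypes, rejections, report


@dataclass(frozen=True)
class GenotypeSummary:
    size_counts: Dict[int, int]
    size_percent: Dict[int, float]
    population_allele_counts: Dict[str, int]
    population_unique_percent: Dict[str, float]
    allele_table: pd.DataFrame


def genotype_summary(
    genotypes: Sequence[IndividualGenotype],
) -> GenotypeSummary:
    """Alleles-per-individual distribution, per-population allele counts
    and uniqueness, and the global allele frequency table."""
    if not genotypes:
        raise ValueError("need at least one genotype")
    n = len(genotypes)
    size_counts: Dict[int, int] = defaultdict(int)
    pop_alleles: Dict[str, set] = defaultdict(set)
    carriers: Dict[str, int] = defaultdict(int)
    for g in genotypes:
        size_counts[g.n_alleles] += 1
        pop_alleles[g.population_id] |= g.allele_ids
        for a in g.allele_ids:
            carriers[a] += 1
    size_percent = {k: 100.0 * v / n for k, v in size_counts.items()}
    pop_counts = {p: len(s) for p, s in pop_alleles.items()}
    unique_pct = {}
    for p, s in pop_alleles.items():
        others = set().union(*(v for q, v in pop_alleles.items() if q != p)) \
            if len(pop_alleles) > 1 else set()
        unique = s - others
        unique_pct[p] = 100.0 * len(unique) / len(s) if s else 0.0
    total_occ = sum(carriers.values())
    table = pd.DataFrame(
        sorted(carriers.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["allele_id", "n_carriers"],
    )
    table["carrier_freq"] = table["n_carriers"] / n
    table["occurrence_freq"] = table["n_carriers"] / total_occ
    return GenotypeSummary(
        size_counts=dict(sorted(size_counts.items())),
        size_percent=dict(sorted(size_percent.items())),
        population_allele_counts=pop_counts,
        population_unique_percent=unique_pct,
        allele_table=table,
    )
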