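"""Synthetic allele pools, genotypes, breeding pairs and replicated
amplicon read tables with the statistical structure of the study design:
a skewed allele-frequency spectrum over ~99 alleles, up to four alleles
per individual (two unresolvable duplicated loci), 44 breeding pairs, and
two sequencing runs per individual carrying substitution/indel errors and
single-breakpoint chimeras.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from . import matechoice
from .selection import CodonPartition, SENSE_CODONS, STOP_CODONS
from .types import (
    AlleleSequence,
    AmpliconVariantRecord,
    BreedingPair,
    IndividualGenotype,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class AllelePool:
    """A pool of distinct, equal-length, stop-free allele sequences."""

    alleles: List[AlleleSequence]
    length_nt: int
    frame_offset: int
    pbr_mask: FrozenSet[int]

    def __post_init__(self) -> None:
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be in {0, 1, 2}")
        seqs = [a.seq for a in self.alleles]
        if any(len(s) != self.length_nt for s in seqs):
            raise ValueError("all pool sequences must have length_nt bases")
        if len(set(seqs)) != len(seqs):
            raise ValueError("pool sequences must be distinct")
        n_codons = (self.length_nt - self.frame_offset) // 3
        for a in self.alleles:
            for i in range(n_codons):
                codon = a.seq[self.frame_offset + 3 * i:
                              self.frame_offset + 3 * i + 3]
                if codon in STOP_CODONS:
                    raise ValueError(
                        f"allele {a.id!r} carries stop codon at codon {i}"
                    )
        bad = [i for i in self.pbr_mask if not 0 <= i < n_codons]
        if bad:
            raise ValueError(f"pbr_mask indices out of range: {sorted(bad)}")
        object.__setattr__(self, "pbr_mask", frozenset(self.pbr_mask))

    @property
    def n_codons(self) -> int:
        return (self.length_nt - self.frame_offset) // 3

    @property
    def allele_ids(self) -> List[str]:
        return [a.id for a in self.alleles]

    def sequences_by_id(self) -> Dict[str, str]:
        return {a.id: a.seq for a in self.alleles}

    def partition(self) -> CodonPartition:
        return CodonPartition(
            frame_offset=self.frame_offset,
            pbr_codons=self.pbr_mask,
            total_codons=self.n_codons,
        )


@dataclass(frozen=True)
class MatingRegime:
    mode: str = "random"  # random | assortative | disassortative
    strength: float = 0.0
    metric_name: str = "band_sharing"

    def __post_init__(self) -> None:
        if self.mode not in ("random", "assortative", "disassortative"):
            raise ValueError(f"unknown mating mode {self.mode!r}")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")


@dataclass(frozen=True)
class ReadSimulationConfig:
    depth_mean: float = 500.0
    substitution_error_rate: float = 0.005
    indel_error_rate: float = 0.01
    chimera_fraction: float = 0.0
    n_runs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_error_rate", "indel_error_rate",
                     "chimera_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def generate_allele_pool(
    n_alleles: int,
    length_nt: int,
    frame_offset: int = 0,
    pbr_fraction: float = 0.25,
    seed: int = 0,
    divergence_codons: Optional[float] = None,
) -> AllelePool:
    """Distinct stop-free random sequences plus a random PBR codon mask.

    With ``divergence_codons`` set, alleles are derived from a common
    random base sequence by replacing on average that many codons with
    random sense codons, emulating a pool of mutationally related alleles;
    otherwise every allele is an independent random codon string.

    Raises if the requested number of distinct stop-free sequences cannot
    exist at the requested length.
    """
    if n_alleles < 2:
        raise ValueError("n_alleles must be >= 2")
    if length_nt < 3:
        raise ValueError("length_nt must be >= 3")
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be in {0, 1, 2}")
    if not 0.0 <= pbr_fraction <= 1.0:
        raise ValueError("pbr_fraction must be in [0, 1]")
    n_codons = (length_nt - frame_offset) // 3
    if n_codons < 1:
        raise ValueError("length_nt too short for a complete codon")
    loose = length_nt - 3 * n_codons  # frame prefix + trailing partial codon
    capacity = len(SENSE_CODONS) ** n_codons * 4 ** loose
    if capacity < n_alleles:
        raise ValueError(
            f"cannot place {n_alleles} distinct stop-free sequences of "
            f"length {length_nt} (capacity {capacity})"
        )
    rng = np.random.default_rng(seed)

    def _random_seq() -> str:
        prefix = "".join(rng.choice(list(_BASES), size=frame_offset))
        body = "".join(
            SENSE_CODONS[i]
            for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)
        )
        tail_len = length_nt - frame_offset - 3 * n_codons
        tail = "".join(rng.choice(list(_BASES), size=tail_len))
        return prefix + body + tail

    base = _random_seq() if divergence_codons is not None else None
    seqs: List[str] = []
    seen = set()
    max_attempts = 1000 * n_alleles + 1000
    attempts = 0
    while len(seqs) < n_alleles:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("exhausted attempts generating distinct pool")
        if base is None:
            seq = _random_seq()
        else:
            # geometric draw: same mean, fatter spread of divergences
            k = min(int(rng.geometric(1.0 / divergence_codons)), n_codons)
            sites = rng.choice(n_codons, size=k, replace=False)
            codons = [base[frame_offset + 3 * i: frame_offset + 3 * i + 3]
                      for i in range(n_codons)]
            for s in sites:
                old = codons[int(s)]
                alts = [c for c in SENSE_CODONS if c != old]
                codons[int(s)] = alts[int(rng.integers(0, len(alts)))]
            seq = (base[:frame_offset] + "".join(codons)
                   + base[frame_offset + 3 * n_codons:])
        if seq not in seen:
            seen.add(seq)
            seqs.append(seq)
    alleles = [
        AlleleSequence(id=f"Alal-DAB*{i + 1:03d}", seq=s)
        for i, s in enumerate(seqs)
    ]
    n_pbr = int(round(pbr_fraction * n_codons))
    mask = frozenset(
        int(i) for i in rng.choice(n_codons, size=n_pbr, replace=False)
    )
    return AllelePool(alleles=alleles, length_nt=length_nt,
                      frame_offset=frame_offset, pbr_mask=mask)


def rank_geometric_freqs(n_alleles: int, skew: float) -> np.ndarray:
    """Frequency of rank r proportional to skew**r, renormalized."""
    if skew <= 0:
        raise ValueError("skew must be positive")
    log_w = np.arange(1, n_alleles + 1) * math.log(skew)
    w = np.exp(log_w - log_w.max())
    return w / w.sum()


def top_k_share(n_alleles: int, skew: float, k: int = 4) -> float:
    """Expected share of draws carried by the top-k ranked alleles."""
    f = rank_geometric_freqs(n_alleles, skew)
    return float(f[:k].sum())


def solve_skew_for_top_share(
    n_alleles: int, target_share: float, k: int = 4
) -> float:
    """Decay parameter whose top-k expected share equals ``target_share``."""
    lo, hi = 1e-9, 1.0 - 1e-12
    if not top_k_share(n_alleles, hi, k) < target_share < top_k_share(n_alleles, lo, k):
        raise ValueError(
            f"target share {target_share} unreachable with {n_alleles} alleles"
        )
    return float(brentq(
        lambda s: top_k_share(n_alleles, s, k) - target_share, lo, hi,
        xtol=1e-12,
    ))


def assign_genotypes(
    pool: AllelePool,
    n_individuals: int,
    n_loci: int = 2,
    freq_skew: float = 0.9,
    seed: int = 0,
    population_props: Optional[Mapping[str, float]] = None,
    sex_props: Optional[Mapping[str, float]] = None,
) -> List[IndividualGenotype]:
    """Draw two alleles per locus from a rank-geometric frequency law.

    The stored genotype is the SET of distinct alleles drawn (duplicated
    loci are unresolvable); the locus-resolved draws are kept as hidden
    ``true_loci`` metadata for tests.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not pool.alleles:
        raise ValueError("pool must be non-empty")
    rng = np.random.default_rng(seed)
    ids = pool.allele_ids
    freqs = rank_geometric_freqs(len(ids), freq_skew)

    def _labels(props: Optional[Mapping[str, float]], default: str):
        if not props:
            return [default] * n_individuals
        names = list(props)
        p = np.asarray([props[k] for k in names], dtype=float)
        p = p / p.sum()
        return [names[i] for i in rng.choice(len(names), size=n_individuals, p=p)]

    pops = _labels(population_props, "pop1")
    sexes = _labels(sex_props, "unknown")
    genotypes = []
    for i in range(n_individuals):
        loci = []
        for _ in range(n_loci):
            a, b = rng.choice(len(ids), size=2, p=freqs)
            loci.append((ids[int(a)], ids[int(b)]))
        allele_set = frozenset(a for locus in loci for a in locus)
        genotypes.append(IndividualGenotype(
            individual_id=f"ind{i + 1:04d}",
            allele_ids=allele_set,
            population_id=pops[i],
            sex=sexes[i],
            true_loci=tuple(loci),
        ))
    return genotypes


def _split_by_sex(
    genotypes: Sequence[IndividualGenotype],
) -> Tuple[List[IndividualGenotype], List[IndividualGenotype]]:
    males = [g for g in genotypes if g.sex == "male"]
    females = [g for g in genotypes if g.sex == "female"]
    if not males and not females:
        # sexless input: split the list in half, first half as males
        half = len(genotypes) // 2
        males = list(genotypes[:half])
        females = list(genotypes[half:2 * half])
    if not males or not females:
        raise ValueError("need at least one male and one female")
    return males, females


def form_pairs(
    genotypes: Sequence[IndividualGenotype],
    regime: MatingRegime = MatingRegime(),
    seed: int = 0,
    translations: Optional[matechoice.AlleleTranslations] = None,
) -> List[BreedingPair]:
    """Match males to females; each individual is used at most once.

    ``random`` mode (or strength 0) draws a uniform perfect matching.
    Assortative/disassortative modes pick, for each male in random order,
    a remaining female with probability proportional to
    exp(+/- strength * metric).
    """
    males, females = _split_by_sex(genotypes)
    rng = np.random.default_rng(seed)
    n_pairs = min(len(males), len(females))
    males = list(males)
    females = list(females)
    rng.shuffle(males)
    rng.shuffle(females)
    males = males[:n_pairs]

    if regime.mode == "random" or regime.strength == 0.0:
        return [BreedingPair(male=m, female=f)
                for m, f in zip(males, females[:n_pairs])]

    metric = _resolve_metric(regime.metric_name)
    sign = 1.0 if regime.mode == "assortative" else -1.0
    remaining = list(females)
    pairs = []
    for m in males:
        values = np.array([
            _metric_value(metric, m, f, translations) for f in remaining
        ])
        logw = sign * regime.strength * values
        w = np.exp(logw - logw.max())
        w = w / w.sum()
        j = int(rng.choice(len(remaining), p=w))
        pairs.append(BreedingPair(male=m, female=remaining.pop(j)))
    return pairs


def _resolve_metric(name: str) -> matechoice.PairMetric:
    for metric in matechoice.CANONICAL_METRICS + (
        matechoice.PairMetric("het_diff_signed"),
    ):
        if metric.key == name:
            return metric
    raise ValueError(f"unknown metric name {name!r}")


def _metric_value(
    metric: matechoice.PairMetric,
    male: IndividualGenotype,
    female: IndividualGenotype,
    translations: Optional[matechoice.AlleleTranslations],
) -> float:
    pair = BreedingPair(male=male, female=female)
    if metric.name == "band_sharing":
        return matechoice.band_sharing(pair)
    if metric.name == "het_diff_abs":
        return abs(male.n_alleles - female.n_alleles)
    if metric.name == "het_diff_signed":
        return male.n_alleles - female.n_alleles
    if translations is None:
        raise ValueError(f"metric {metric.key!r} requires translations")
    return matechoice.aa_dissimilarity(
        pair, metric.region, metric.name.split("_")[1], translations
    )


def _corrupt(seq: str, sub_rate: float, indel_rate: float,
             rng: np.random.Generator) -> str:
    """Per-base substitution and indel corruption of one read.

    An indel event at a base (deletion of the base or insertion after it,
    equiprobable) takes precedence over a substitution at the same base.
    """
    L = len(seq)
    draws = rng.random((2, L))
    indel = draws[0] < indel_rate
    sub = draws[1] < sub_rate
    events = np.nonzero(indel | sub)[0]
    if events.size == 0:
        return seq
    parts = []
    prev = 0
    for pos in events:
        parts.append(seq[prev:int(pos)])
        base = seq[int(pos)]
        if indel[pos]:
            if rng.random() >= 0.5:  # insertion after base, else deletion
                parts.append(base + _BASES[rng.integers(0, 4)])
        else:
            alts = _BASES.replace(base, "")
            parts.append(alts[rng.integers(0, 3)])
        prev = int(pos) + 1
    parts.append(seq[prev:])
    return "".join(parts)


def simulate_reads(
    genotypes: Sequence[IndividualGenotype],
    pool: AllelePool,
    cfg: ReadSimulationConfig,
) -> List[AmpliconVariantRecord]:
    """Replicated amplicon variant tables with errors and chimeras.

    Per individual x run, every true allele receives a Poisson depth
    around ``depth_mean``; each read is independently corrupted per base,
    and identical observed sequences collapse into one variant record.
    Chimeric variants splice two true alleles of the same individual at a
    uniform breakpoint with relative abundance ``chimera_fraction``.
    """
    rng = np.random.default_rng(cfg.seed)
    seq_of = pool.sequences_by_id()
    records: List[AmpliconVariantRecord] = []
    L = pool.length_nt
    p_clean = ((1.0 - cfg.substitution_error_rate) ** L
               * (1.0 - cfg.indel_error_rate) ** L)
    for g in genotypes:
        alleles = sorted(g.allele_ids)
        for a in alleles:
            if a not in seq_of:
                raise KeyError(f"allele {a!r} absent from pool")
        for run in range(1, cfg.n_runs + 1):
            run_id = f"run{run}"
            variants: Dict[str, int] = {}
            for a in alleles:
                true_seq = seq_of[a]
                depth = int(rng.poisson(cfg.depth_mean))
                if depth == 0:
                    continue
                n_err = int(rng.binomial(depth, 1.0 - p_clean))
                if depth - n_err > 0:
                    variants[true_seq] = variants.get(true_seq, 0) + depth - n_err
                for _ in range(n_err):
                    read = _corrupt(true_seq, cfg.substitution_error_rate,
                                    cfg.indel_error_rate, rng)
                    variants[read] = variants.get(read, 0) + 1
            if cfg.chimera_fraction > 0 and len(alleles) >= 2:
                i, j = rng.choice(len(alleles), size=2, replace=False)
                p1, p2 = seq_of[alleles[int(i)]], seq_of[alleles[int(j)]]
                b = int(rng.integers(1, L))
                chimera = p1[:b] + p2[b:]
                depth = int(rng.poisson(cfg.chimera_fraction * cfg.depth_mean))
                if depth > 0 and chimera not in (p1, p2):
                    variants[chimera] = variants.get(chimera, 0) + depth
            for seq, depth in sorted(variants.items()):
                quality = float(np.clip(rng.normal(37.0, 1.0), 10.0, 42.0))
                records.append(AmpliconVariantRecord(
                    individual_id=g.individual_id, run_id=run_id,
                    sequence=seq, depth=depth,
                    mean_quality=round(quality, 2),
                ))
    return records
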