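"""Pair-compatibility metrics and the Monte Carlo re-pairing test.

Six canonical tests are run against a permutation null obtained by
re-matching the observed females to the fixed male list uniformly at
random: absolute heterozygosity difference, band sharing, and the
additive and maximum amino-acid dissimilarities each in the whole-fragment
and PBR contexts. Because duplicated loci cannot be resolved, the
amino-acid metrics aggregate over ALL cross-mate allele combinations
(identical alleles contribute zero); a best-match variant is available
behind ``pairing="best_match"`` for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .selection import CodonPartition, codons_of, translate_codon
from .types import BreedingPair, IndividualGenotype

FAMILY_SIZE = 6  # het_diff, band_sharing, aa_{sum,max} x {whole, pbr}


@dataclass(frozen=True)
class PairMetric:
    name: str  # het_diff_abs, het_diff_signed, band_sharing, aa_sum, aa_max
    region: str = "whole"  # whole | pbr (ignored for het/band metrics)
    direction: str = "assortative_high"

    @property
    def key(self) -> str:
        if self.name in ("aa_sum", "aa_max"):
            return f"{self.name}_{self.region}"
        return self.name


CANONICAL_METRICS: Tuple[PairMetric, ...] = (
    PairMetric("het_diff_abs", direction="assortative_low"),
    PairMetric("band_sharing", direction="assortative_high"),
    PairMetric("aa_sum", "whole", direction="assortative_low"),
    PairMetric("aa_sum", "pbr", direction="assortative_low"),
    PairMetric("aa_max", "whole", direction="assortative_low"),
    PairMetric("aa_max", "pbr", direction="assortative_low"),
)


@dataclass(frozen=True)
class RandomizationResult:
    metric: PairMetric
    observed_mean: float
    null_means: np.ndarray
    p_two_sided: float
    lower_tail_2_5: float
    upper_tail_97_5: float
    B: int
    seed: int

    @property
    def outside_tails(self) -> bool:
        return (self.observed_mean < self.lower_tail_2_5
                or self.observed_mean > self.upper_tail_97_5)


@dataclass(frozen=True)
class FamilyResults:
    results: Dict[str, RandomizationResult]
    alpha_adjusted: float
    significant: Dict[str, bool]
    directions: Dict[str, str]


class AlleleTranslations:
    """Precomputed amino-acid arrays per allele, whole and PBR contexts."""

    def __init__(
        self,
        allele_seqs: Mapping[str, str],
        partition: CodonPartition,
    ) -> None:
        self.partition = partition
        self._aa: Dict[str, np.ndarray] = {}
        self._diff_cache: Dict[Tuple[str, str, str], int] = {}
        pbr = sorted(partition.pbr_codons)
        self._pbr_idx = np.asarray(pbr, dtype=int)
        for allele_id, seq in allele_seqs.items():
            codons = codons_of(seq, partition.frame_offset)
            if len(codons) != partition.total_codons:
                raise ValueError(
                    f"allele {allele_id!r}: {len(codons)} codons, partition "
                    f"expects {partition.total_codons}"
                )
            aa = np.frombuffer(
                "".join(translate_codon(c) for c in codons).encode(), np.uint8
            )
            self._aa[allele_id] = aa

    def aa_difference(self, a: str, b: str, region: str) -> int:
        if a > b:
            a, b = b, a
        key = (a, b, region)
        cached = self._diff_cache.get(key)
        if cached is not None:
            return cached
        try:
            aa_a, aa_b = self._aa[a], self._aa[b]
        except KeyError as exc:
            raise KeyError(f"allele {exc.args[0]!r} absent from pool") from exc
        if region == "pbr":
            aa_a, aa_b = aa_a[self._pbr_idx], aa_b[self._pbr_idx]
        elif region != "whole":
            raise ValueError(f"unknown region {region!r}")
        out = int((aa_a != aa_b).sum())
        self._diff_cache[key] = out
        return out


def heterozygosity(genotype: IndividualGenotype) -> int:
    """Distinct-allele count, the observable heterozygosity proxy."""
    return genotype.n_alleles


def band_sharing(pair: BreedingPair) -> float:
    """2*|shared| / (|A| + |B|) over the mates' distinct-allele sets."""
    a, b = pair.male.allele_ids, pair.female.allele_ids
    return 2.0 * len(a & b) / (len(a) + len(b))


def aa_dissimilarity(
    pair: BreedingPair,
    region: str,
    mode: str,
    translations: AlleleTranslations,
    pairing: str = "all_pairs",
) -> float:
    """Amino-acid difference between mates' alleles.

    ``all_pairs`` aggregates every cross-mate allele combination (sum or
    max); ``best_match`` greedily assigns each male allele its most
    similar unmatched female allele first, then aggregates the matched
    differences only.
    """
    if mode not in ("sum", "max"):
        raise ValueError(f"unknown mode {mode!r}")
    males = sorted(pair.male.allele_ids)
    females = sorted(pair.female.allele_ids)
    if pairing == "all_pairs":
        diffs = [translations.aa_difference(a, b, region)
                 for a in males for b in females]
    elif pairing == "best_match":
        remaining = list(females)
        diffs = []
        for a in males:
            if not remaining:
                break
            best = min(remaining,
                       key=lambda b: (translations.aa_difference(a, b, region), b))
            diffs.append(translations.aa_difference(a, best, region))
            remaining.remove(best)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    if mode == "sum":
        return float(sum(diffs))
    return float(max(diffs))


def _metric_matrix(
    males: Sequence[IndividualGenotype],
    females: Sequence[IndividualGenotype],
    metric: PairMetric,
    translations: Optional[AlleleTranslations],
) -> np.ndarray:
    """Metric value for every male x female combination.

    Integer-valued metrics keep an integer dtype so permutation-null means
    are exact (sums of equal integer multisets divide identically).
    """
    n_m, n_f = len(males), len(females)
    if metric.name == "het_diff_signed":
        hm = np.array([heterozygosity(g) for g in males], dtype=np.int64)
        hf = np.array([heterozygosity(g) for g in females], dtype=np.int64)
        return hm[:, None] - hf[None, :]
    if metric.name == "het_diff_abs":
        hm = np.array([heterozygosity(g) for g in males], dtype=np.int64)
        hf = np.array([heterozygosity(g) for g in females], dtype=np.int64)
        return np.abs(hm[:, None] - hf[None, :])
    if metric.name == "band_sharing":
        out = np.empty((n_m, n_f))
        for i, m in enumerate(males):
            for j, f in enumerate(females):
                out[i, j] = (2.0 * len(m.allele_ids & f.allele_ids)
                             / (m.n_alleles + f.n_alleles))
        return out
    if metric.name in ("aa_sum", "aa_max"):
        if translations is None:
            raise ValueError(
                f"metric {metric.name!r} requires allele translations"
            )
        mode = metric.name.split("_")[1]
        out = np.empty((n_m, n_f))
        for i, m in enumerate(males):
            for j, f in enumerate(females):
                out[i, j] = aa_dissimilarity(
                    BreedingPair(male=m, female=f), metric.region, mode,
                    translations,
                )
        return out
    raise ValueError(f"unknown metric {metric.name!r}")


def randomization_test(
    pairs: Sequence[BreedingPair],
    metric: PairMetric,
    B: int = 10_000,
    seed: int = 0,
    translations: Optional[AlleleTranslations] = None,
    _matrix: Optional[np.ndarray] = None,
) -> RandomizationResult:
    """Monte Carlo re-pairing test of one pair-compatibility metric.

    Each iteration permutes the female list against the fixed male list
    (a uniform random perfect matching) and records the mean metric; the
    empirical two-sided p uses the +1 correction
    ``p = min(1, 2*min(1+#{null<=obs}, 1+#{null>=obs})/(B+1))``.
    """
    if len(pairs) < 3:
        raise ValueError("randomization test requires >= 3 pairs")
    if B < 99:
        raise ValueError("B must be >= 99")
    males = [p.male for p in pairs]
    females = [p.female for p in pairs]
    M = _matrix if _matrix is not None else _metric_matrix(
        males, females, metric, translations
    )
    n = len(pairs)
    rows = np.arange(n)
    observed = M[rows, rows].sum() / n
    rng = np.random.default_rng(seed)
    perms = rng.random((B, n)).argsort(axis=1)  # B uniform permutations
    null_sums = M[rows[None, :], perms].sum(axis=1)
    null_means = null_sums / n
    r_low = 1 + int((null_means <= observed).sum())
    r_high = 1 + int((null_means >= observed).sum())
    p = min(1.0, 2.0 * min(r_low, r_high) / (B + 1))
    lo, hi = np.percentile(null_means, [2.5, 97.5])
    return RandomizationResult(
        metric=metric, observed_mean=float(observed),
        null_means=null_means, p_two_sided=p,
        lower_tail_2_5=float(lo), upper_tail_97_5=float(hi),
        B=B, seed=seed,
    )


def run_all_tests(
    pairs: Sequence[BreedingPair],
    translations: AlleleTranslations,
    B: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> FamilyResults:
    """The six canonical randomization tests with Bonferroni control."""
    alpha_adjusted = alpha / FAMILY_SIZE
    results: Dict[str, RandomizationResult] = {}
    significant: Dict[str, bool] = {}
    directions: Dict[str, str] = {}
    rng = np.random.default_rng(seed)
    for metric in CANONICAL_METRICS:
        sub_seed = int(rng.integers(0, 2**63 - 1))
        res = randomization_test(
            pairs, metric, B=B, seed=sub_seed, translations=translations
        )
        results[metric.key] = res
        significant[metric.key] = res.p_two_sided < alpha_adjusted
        if res.observed_mean > res.upper_tail_97_5:
            side = "high"
        elif res.observed_mean < res.lower_tail_2_5:
            side = "low"
        else:
            side = "within"
        if side == "within":
            directions[metric.key] = "random"
        elif (side == "high") == (metric.direction == "assortative_high"):
            directions[metric.key] = "assortative"
        else:
            directions[metric.key] = "disassortative"
    return FamilyResults(
        results=results, alpha_adjusted=alpha_adjusted,
        significant=significant, directions=directions,
    )


@dataclass(frozen=True)
class SensitivityRow:
    n_pairs: int
    reps: int
    concordance: float


def sensitivity_curve(
    pairs: Sequence[BreedingPair],
    metric: PairMetric,
    n_grid: Sequence[int],
    reps_per_n: int = 20,
    B: int = 1000,
    seed: int = 0,
    translations: Optional[AlleleTranslations] = None,
    alpha: float = 0.05,
) -> List[SensitivityRow]:
    """Verdict-concordance of subsampled tests versus the full-data test."""
    if any(n > len(pairs) for n in n_grid):
        raise ValueError("subsample sizes must not exceed the pair count")
    if any(n < 3 for n in n_grid):
        raise ValueError("subsample sizes must be >= 3")
    rng = np.random.default_rng(seed)
    full = randomization_test(
        pairs, metric, B=B, seed=int(rng.integers(0, 2**63 - 1)),
        translations=translations,
    )
    full_verdict = full.p_two_sided < alpha
    rows = []
    pairs = list(pairs)
    for n_sub in n_grid:
        agree = 0
        for _ in range(reps_per_n):
            idx = rng.choice(len(pairs), size=n_sub, replace=False)
            sub = [pairs[i] for i in idx]
            res = randomization_test(
                sub, metric, B=B, seed=int(rng.integers(0, 2**63 - 1)),
                translations=translations,
            )
            agree += int((res.p_two_sided < alpha) == full_verdict)
        rows.append(SensitivityRow(n_pairs=n_sub, reps=reps_per_n,
                                   concordance=agree / reps_per_n))
    return rows
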