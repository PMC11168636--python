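"""Modified Nei-Gojobori dN/dS with Jukes-Cantor correction and a
codon-bootstrap Z-test of positive selection on PBR vs non-PBR codons.

The transition/transversion ratio ``R`` follows the count-ratio
convention: R = 0.5 corresponds to equal per-mutation weights (the
unmodified method), so each transition mutation receives weight 2R
against weight 1 for each transversion. Mutational paths passing through
stop codons are excluded and the remaining weights renormalized, keeping
N_sites + S_sites = 3 for every sense codon.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy.stats import norm

from .popgen import AlleleAlignment

_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
GENETIC_CODE: Dict[str, str] = dict(_TABLE.forward_table)
SENSE_CODONS = tuple(sorted(GENETIC_CODE))

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = "ACGT"


def translate_codon(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return GENETIC_CODE[codon]


@dataclass(frozen=True)
class CodonPartition:
    """Disjoint, exhaustive split of codon positions into PBR / non-PBR."""

    frame_offset: int
    pbr_codons: FrozenSet[int]
    total_codons: int

    def __post_init__(self) -> None:
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        object.__setattr__(self, "pbr_codons", frozenset(self.pbr_codons))
        if self.total_codons < 1:
            raise ValueError("total_codons must be positive")
        bad = [i for i in self.pbr_codons
               if not 0 <= i < self.total_codons]
        if bad:
            raise ValueError(f"pbr codon indices out of range: {sorted(bad)}")

    @property
    def non_pbr_codons(self) -> FrozenSet[int]:
        return frozenset(range(self.total_codons)) - self.pbr_codons

    def region_codons(self, region: str) -> FrozenSet[int]:
        if region == "pbr":
            return self.pbr_codons
        if region == "non_pbr":
            return self.non_pbr_codons
        if region == "whole":
            return frozenset(range(self.total_codons))
        raise ValueError(f"unknown region {region!r}")


@dataclass(frozen=True)
class PairwiseDnDs:
    pN: float
    pS: float
    dN: float  # NaN when pN >= 3/4 (Jukes-Cantor saturated)
    dS: float
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float

    @property
    def omega(self) -> float:
        if self.dS > 0 and not math.isnan(self.dN):
            return self.dN / self.dS
        return math.nan


@dataclass(frozen=True)
class DnDsResult:
    region: str
    dN: float
    dS: float
    omega: float
    Z: float
    p_one_tailed: float
    n_bootstrap: int
    seed: int
    n_codons: int
    n_pairs: int


@lru_cache(maxsize=None)
def ng_site_counts(codon: str, R: float = 2.0) -> Tuple[float, float]:
    """Potential nonsynonymous/synonymous site counts for a sense codon.

    Each position contributes weighted fractions of synonymous change over
    its non-stop single-base mutants (transition weight 2R, transversion
    weight 1), so the per-codon counts always sum to 3.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    if len(codon) != 3 or set(codon) - set(_BASES):
        raise ValueError(f"invalid codon {codon!r}")
    if R <= 0:
        raise ValueError("R must be > 0")
    aa = GENETIC_CODE[codon]
    s_total = 0.0
    for pos in range(3):
        syn_w = tot_w = 0.0
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            w = 2.0 * R if _TRANSITION[codon[pos]] == alt else 1.0
            tot_w += w
            if GENETIC_CODE[mutant] == aa:
                syn_w += w
        if tot_w > 0:
            s_total += syn_w / tot_w
    return 3.0 - s_total, s_total


@lru_cache(maxsize=None)
def codon_path_counts(codon_a: str, codon_b: str) -> Tuple[float, float]:
    """Observed (nonsynonymous, synonymous) difference counts for a codon
    pair, averaged with equal weight over all substitution orderings whose
    intermediate codons are not stops.

    Falls back to averaging over all orderings if every path is blocked.
    """
    for c in (codon_a, codon_b):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c!r} in coding sequence")
        if len(c) != 3 or set(c) - set(_BASES):
            raise ValueError(f"invalid codon {c!r}")
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0

    def walk(order: Sequence[int]) -> Optional[Tuple[int, int]]:
        nd = sd = 0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                return None
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return nd, sd

    results = [walk(order) for order in itertools.permutations(positions)]
    open_paths = [r for r in results if r is not None]
    if not open_paths:  # all paths cross a stop; count steps anyway
        open_paths = []
        for order in itertools.permutations(positions):
            nd = sd = 0
            cur = codon_a
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
                a1 = translate_codon(cur)
                a2 = translate_codon(nxt)
                if a1 == a2:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            open_paths.append((nd, sd))
    nd = sum(r[0] for r in open_paths) / len(open_paths)
    sd = sum(r[1] for r in open_paths) / len(open_paths)
    return nd, sd


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - 4p/3); NaN marks saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def codons_of(seq: str, frame_offset: int) -> List[str]:
    """Complete codons of ``seq`` starting at ``frame_offset``; the
    trailing partial codon is ignored."""
    usable = (len(seq) - frame_offset) // 3
    return [seq[frame_offset + 3 * i: frame_offset + 3 * i + 3]
            for i in range(usable)]


def _pair_codon_arrays(
    codons_a: Sequence[str], codons_b: Sequence[str],
    indices: Iterable[int], R: float,
):
    nd = sd = n_sites = s_sites = 0.0
    for j in indices:
        ca, cb = codons_a[j], codons_b[j]
        dn, ds = codon_path_counts(ca, cb)
        na, sa = ng_site_counts(ca, R)
        nb, sb = ng_site_counts(cb, R)
        nd += dn
        sd += ds
        n_sites += 0.5 * (na + nb)
        s_sites += 0.5 * (sa + sb)
    return nd, sd, n_sites, s_sites


def ng_pairwise(
    seq_a: str,
    seq_b: str,
    partition: Optional[CodonPartition] = None,
    R: float = 2.0,
) -> Dict[str, PairwiseDnDs]:
    """Per-region (pN, pS) and Jukes-Cantor corrected (dN, dS) for one
    sequence pair. With no partition a single ``whole`` region is used."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    frame = partition.frame_offset if partition else 0
    codons_a = codons_of(seq_a, frame)
    codons_b = codons_of(seq_b, frame)
    if not codons_a:
        raise ValueError("no complete codons in sequences")
    if partition is None:
        regions = {"whole": range(len(codons_a))}
    else:
        if partition.total_codons != len(codons_a):
            raise ValueError(
                f"partition covers {partition.total_codons} codons but "
                f"sequences have {len(codons_a)}"
            )
        regions = {"pbr": sorted(partition.pbr_codons),
                   "non_pbr": sorted(partition.non_pbr_codons)}
    out = {}
    for name, idx in regions.items():
        nd, sd, n_sites, s_sites = _pair_codon_arrays(
            codons_a, codons_b, idx, R
        )
        pN = nd / n_sites if n_sites > 0 else 0.0
        pS = sd / s_sites if s_sites > 0 else 0.0
        out[name] = PairwiseDnDs(
            pN=pN, pS=pS, dN=jukes_cantor(pN), dS=jukes_cantor(pS),
            N_sites=n_sites, S_sites=s_sites, Nd=nd, Sd=sd,
        )
    return out


def _codon_level_matrices(
    seqs: Sequence[str], region_idx: Sequence[int], frame: int, R: float
):
    """Per-pair, per-codon Nd/Sd/N-sites/S-sites matrices for bootstrap."""
    codon_lists = [codons_of(s, frame) for s in seqs]
    n = len(seqs)
    pairs = [(i, j) for i in range(n - 1) for j in range(i + 1, n)]
    C = len(region_idx)
    Nd = np.zeros((len(pairs), C))
    Sd = np.zeros((len(pairs), C))
    Ns = np.zeros((len(pairs), C))
    Ss = np.zeros((len(pairs), C))
    site_cache = {}
    for p, (i, j) in enumerate(pairs):
        ci, cj = codon_lists[i], codon_lists[j]
        for k, idx in enumerate(region_idx):
            ca, cb = ci[idx], cj[idx]
            dn, ds = codon_path_counts(ca, cb)
            key = (ca, cb)
            if key not in site_cache:
                na, sa = ng_site_counts(ca, R)
                nb, sb = ng_site_counts(cb, R)
                site_cache[key] = (0.5 * (na + nb), 0.5 * (sa + sb))
            ns, ss = site_cache[key]
            Nd[p, k], Sd[p, k], Ns[p, k], Ss[p, k] = dn, ds, ns, ss
    return Nd, Sd, Ns, Ss


def _mean_d(Nd, Sd, Ns, Ss, cols=None):
    """Pairwise-averaged (dN, dS) given codon-column selection."""
    if cols is not None:
        Nd, Sd, Ns, Ss = Nd[:, cols], Sd[:, cols], Ns[:, cols], Ss[:, cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        pN = Nd.sum(1) / Ns.sum(1)
        pS = Sd.sum(1) / Ss.sum(1)
        dN = np.where(pN < 0.75, -0.75 * np.log1p(-4.0 * pN / 3.0), np.nan)
        dS = np.where(pS < 0.75, -0.75 * np.log1p(-4.0 * pS / 3.0), np.nan)
    return float(np.nanmean(dN)), float(np.nanmean(dS))


def z_test_positive_selection(
    alignment: AlleleAlignment,
    partition: CodonPartition,
    region: str = "pbr",
    R: float = 2.0,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> DnDsResult:
    """One-tailed codon-bootstrap Z-test of dN > dS within a codon region.

    dN and dS are averaged over all sequence pairs restricted to the
    region's codons; the standard error of (dN - dS) comes from resampling
    codon columns with replacement ``n_bootstrap`` times.
    """
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    region_idx = sorted(partition.region_codons(region))
    if len(region_idx) < 3:
        raise ValueError(
            f"region {region!r} has {len(region_idx)} codons; need >= 3"
        )
    seqs = [s.seq for s in alignment.sequences]
    Nd, Sd, Ns, Ss = _codon_level_matrices(
        seqs, region_idx, partition.frame_offset, R
    )
    dN, dS = _mean_d(Nd, Sd, Ns, Ss)
    rng = np.random.default_rng(seed)
    C = len(region_idx)
    stats = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        cols = rng.integers(0, C, size=C)
        bdN, bdS = _mean_d(Nd, Sd, Ns, Ss, cols)
        stats[b] = bdN - bdS
    se = float(np.nanstd(stats, ddof=1))
    diff = dN - dS
    Z = diff / se if se > 0 else (0.0 if diff == 0 else math.inf * np.sign(diff))
    p = float(norm.sf(Z))
    omega = dN / dS if dS > 0 else math.nan
    return DnDsResult(
        region=region, dN=dN, dS=dS, omega=omega, Z=float(Z),
        p_one_tailed=p, n_bootstrap=n_bootstrap, seed=seed,
        n_codons=C, n_pairs=Nd.shape[0],
    )
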