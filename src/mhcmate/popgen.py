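"""Nucleotide-diversity summary statistics and sliding-window Tajima's D.

All statistics operate on an equal-length alignment of allele sequences.
Gap/ambiguity columns are handled according to the alignment's
``site_handling`` policy:

``complete_deletion``
    columns containing any symbol outside {A,C,G,T} are excluded globally
    (the DNAsp default).
``pairwise_deletion``
    each sequence pair is compared over the columns where both members are
    unambiguous nucleotides.
``none``
    every column is used; any symbol mismatch (including gap vs. base)
    counts as a difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .types import AlleleSequence

_VALID_SITE_HANDLING = ("complete_deletion", "pairwise_deletion", "none")


@dataclass(frozen=True)
class AlleleAlignment:
    """An equal-length nucleotide alignment with a site-handling policy."""

    sequences: List[AlleleSequence]
    site_handling: str = "complete_deletion"

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("alignment requires at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.site_handling not in _VALID_SITE_HANDLING:
            raise ValueError(f"unknown site_handling {self.site_handling!r}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def matrix(self) -> np.ndarray:
        """Alignment as an (n, L) uint8 matrix of ASCII codes."""
        return np.frombuffer(
            "".join(s.seq for s in self.sequences).encode("ascii"), np.uint8
        ).reshape(self.n, self.length)


@dataclass(frozen=True)
class PopGenSummary:
    h: int
    S: int
    eta: int
    pi: float
    theta_w: float
    K: float
    n_sequences: int
    length: int
    length_effective: int
    site_handling: str


@dataclass(frozen=True)
class WindowD:
    start: int
    end: int
    S: int
    pi: float
    D: float  # NaN when undefined (S == 0)


@dataclass(frozen=True)
class TajimaResult:
    D: float
    S: int
    K: float
    n_sequences: int
    windows: Optional[List[WindowD]] = None


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i (Watterson's normalizer for n sequences)."""
    return sum(1.0 / i for i in range(1, n))


def _site_state_counts(mat: np.ndarray) -> np.ndarray:
    """Number of distinct A/C/G/T states observed in each column."""
    counts = np.zeros(mat.shape[1], dtype=np.int64)
    for base in b"ACGT":
        counts += (mat == base).any(axis=0)
    return counts


def _effective_columns(mat: np.ndarray, site_handling: str) -> np.ndarray:
    if site_handling == "complete_deletion":
        valid = np.isin(mat, np.frombuffer(b"ACGT", np.uint8))
        return np.nonzero(valid.all(axis=0))[0]
    if site_handling == "pairwise_deletion":
        valid = np.isin(mat, np.frombuffer(b"ACGT", np.uint8))
        return np.nonzero(valid.sum(axis=0) >= 2)[0]
    return np.arange(mat.shape[1])


def _pair_differences(mat: np.ndarray, site_handling: str):
    """Per-pair difference counts and per-pair effective lengths."""
    n = mat.shape[0]
    valid = np.isin(mat, np.frombuffer(b"ACGT", np.uint8))
    diffs, lengths = [], []
    for i in range(n - 1):
        for j in range(i + 1, n):
            if site_handling == "pairwise_deletion":
                both = valid[i] & valid[j]
                diffs.append(int((mat[i][both] != mat[j][both]).sum()))
                lengths.append(int(both.sum()))
            else:
                diffs.append(int((mat[i] != mat[j]).sum()))
                lengths.append(mat.shape[1])
    return np.asarray(diffs, float), np.asarray(lengths, float)


def summarize(alignment: AlleleAlignment) -> PopGenSummary:
    """Haplotype count, segregating sites, Eta, pi, Watterson's theta and K.

    ``S`` counts columns with >= 2 observed nucleotide states, ``eta`` sums
    (states - 1) over columns; both are evaluated on the effective columns
    of the site-handling policy. ``K`` is the mean pairwise difference
    count, ``pi`` the per-site mean pairwise difference, and
    ``theta_w = S / (a_n * L_effective)``.
    """
    mat = alignment.matrix()
    cols = _effective_columns(mat, alignment.site_handling)
    sub = mat[:, cols]
    states = _site_state_counts(sub)
    S = int((states >= 2).sum())
    eta = int(np.maximum(states - 1, 0).sum())
    h = len({s.seq for s in alignment.sequences})

    if alignment.site_handling == "pairwise_deletion":
        diffs, lengths = _pair_differences(mat, "pairwise_deletion")
        K = float(diffs.mean())
        with np.errstate(invalid="ignore"):
            fracs = np.where(lengths > 0, diffs / np.maximum(lengths, 1), 0.0)
        pi = float(fracs.mean())
        L_eff = len(cols)
    else:
        diffs, _ = _pair_differences(sub, alignment.site_handling)
        K = float(diffs.mean())
        L_eff = sub.shape[1]
        pi = K / L_eff if L_eff else 0.0

    a_n = harmonic(alignment.n)
    theta_w = S / (a_n * L_eff) if L_eff else 0.0
    return PopGenSummary(
        h=h, S=S, eta=eta, pi=pi, theta_w=theta_w, K=K,
        n_sequences=alignment.n, length=alignment.length,
        length_effective=int(L_eff), site_handling=alignment.site_handling,
    )


def tajima_constants(n: int) -> dict:
    """Tajima's (1989) variance constants a1, a2, b1, b2, c1, c2, e1, e2."""
    if n < 2:
        raise ValueError("n must be >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _tajima_d_from(S: int, K: float, n: int) -> float:
    if S == 0:
        return math.nan
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return math.nan
    return (K - S / c["a1"]) / math.sqrt(var)


def _window_stats(mat: np.ndarray, site_handling: str):
    # D uses total (not per-site) pairwise diversity, i.e. K.
    sub = mat[:, _effective_columns(mat, site_handling)]
    diffs, _ = _pair_differences(sub, "none")
    S = int((_site_state_counts(sub) >= 2).sum())
    return S, float(diffs.mean()) if diffs.size else 0.0, sub.shape[1]


def tajimas_d(
    alignment: AlleleAlignment,
    window_nt: Optional[int] = None,
    step_nt: Optional[int] = None,
) -> TajimaResult:
    """Overall Tajima's D, plus a per-window track when a window is given.

    Windows are 0-based half-open nucleotide intervals [start, start+w)
    advanced by ``step_nt``; only complete windows are reported. A window
    (or the whole alignment) with S = 0 yields D = NaN rather than 0.
    """
    if alignment.n < 4:
        raise ValueError("Tajima's D requires at least 4 sequences")
    if window_nt is not None:
        if window_nt <= 0 or (step_nt is not None and step_nt <= 0):
            raise ValueError("window and step must be positive")
    mat = alignment.matrix()
    S, K, _ = _window_stats(mat, alignment.site_handling)
    D = _tajima_d_from(S, K, alignment.n)

    windows = None
    if window_nt is not None:
        step = step_nt or window_nt
        windows = []
        for start in range(0, alignment.length - window_nt + 1, step):
            wmat = mat[:, start:start + window_nt]
            wS, wK, _ = _window_stats(wmat, alignment.site_handling)
            windows.append(
                WindowD(start=start, end=start + window_nt, S=wS,
                        pi=wK / window_nt,
                        D=_tajima_d_from(wS, wK, alignment.n))
            )
    return TajimaResult(D=D, S=S, K=K, n_sequences=alignment.n,
                        windows=windows)
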