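"""Affine-gap pairwise alignment of DNA and protein sequences.

Implements Needleman-Wunsch / Smith-Waterman with Gotoh's three-state
recurrences and EMBOSS gap semantics: a gap of length L costs
``gap_open + (L - 1) * gap_extend`` (defaults 10 / 0.5, so half-integer
scores are allowed and the dynamic programme runs in floats).  The
traceback tie-break is fixed (diagonal > up > left) so alignments are
deterministic.  On top of the kernels the module provides percent
identity/similarity, VISTA-style sliding-window identity profiles, and a
Karlin-Altschul E-value surrogate for local-alignment scores.

``N`` is treated as a universal mismatch: it scores like a mismatch and is
never counted as an identity, even against another ``N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import brentq
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentParams",
    "PairwiseAlignment",
    "IdentityProfile",
    "global_align",
    "local_align",
    "identity_and_similarity",
    "sliding_identity_profile",
    "evalue",
    "karlin_altschul_params",
]

_DNA_ALPHABET = "ACGTN"
_DNA_INDEX = {c: i for i, c in enumerate(_DNA_ALPHABET)}

_NEG = -1.0e30  # effectively -inf inside the DP


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

@dataclass
class AlignmentParams:
    """Scoring parameters for the alignment kernels.

    ``gap_open``/``gap_extend`` are penalties (subtracted), EMBOSS-style.
    ``ka_lambda``/``ka_K`` are Karlin-Altschul statistics for the DNA
    match/mismatch scores; when left unset they are solved numerically on
    first use (ungapped system at equal base frequencies) and cached.
    """

    gap_open: float = 10.0
    gap_extend: float = 0.5
    dna_match: float = 5.0
    dna_mismatch: float = -4.0
    protein_matrix: str = "BLOSUM62"
    ka_lambda: float | None = None
    ka_K: float | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")
        if self.dna_match <= 0 or self.dna_mismatch >= 0:
            raise ValueError("require dna_match > 0 and dna_mismatch < 0")
        if self.ka_lambda is not None and self.ka_lambda <= 0:
            raise ValueError("ka_lambda must be positive")
        if self.ka_K is not None and self.ka_K <= 0:
            raise ValueError("ka_K must be positive")

    def dna_score_matrix(self) -> np.ndarray:
        """5x5 score matrix over ACGTN; N is a universal mismatch."""
        if "dna" not in self._cache:
            s = np.full((5, 5), self.dna_mismatch, dtype=np.float64)
            for i in range(4):
                s[i, i] = self.dna_match
            self._cache["dna"] = s
        return self._cache["dna"]

    def protein_score_matrix(self) -> tuple[np.ndarray, dict[str, int]]:
        if "protein" not in self._cache:
            mat = substitution_matrices.load(self.protein_matrix)
            alphabet = str(mat.alphabet)
            index = {c: i for i, c in enumerate(alphabet)}
            self._cache["protein"] = (np.asarray(mat, dtype=np.float64), index)
        return self._cache["protein"]

    def karlin_altschul(self) -> tuple[float, float]:
        """(lambda, K) for the ungapped DNA scoring system (approximate
        when applied to gapped scores)."""
        if self.ka_lambda is None or self.ka_K is None:
            lam, K, _ = karlin_altschul_params(self.dna_match, self.dna_mismatch)
            if self.ka_lambda is None:
                self.ka_lambda = lam
            if self.ka_K is None:
                self.ka_K = K
        return self.ka_lambda, self.ka_K


# --------------------------------------------------------------------------
# Alignment containers
# --------------------------------------------------------------------------

@dataclass
class PairwiseAlignment:
    """A gapped pair of equal-length strings plus summary statistics.

    ``a_start``/``b_start`` are 0-based offsets of the first aligned
    residue in the original sequences (always 0 for global alignments);
    for an empty local alignment both aligned strings are empty and the
    score is 0.
    """

    aligned_a: str
    aligned_b: str
    score: float
    mode: str  # "global" | "local"
    molecule: str  # "dna" | "protein"
    identity_pct: float
    similarity_pct: float
    a_start: int = 0
    b_start: int = 0

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-" and y == "-":
                raise ValueError("gap-gap column in alignment")

    def __len__(self) -> int:
        return len(self.aligned_a)


@dataclass
class IdentityProfile:
    """Sliding-window percent identity in first-sequence coordinates.

    ``windows`` holds (start, end, identity_pct) with 1-based closed
    coordinates; windows with no aligned columns are omitted.
    """

    windows: list[tuple[int, int, float]]
    window_size: int
    step: int


# --------------------------------------------------------------------------
# Encoding helpers
# --------------------------------------------------------------------------

def _encode_dna(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq.upper()):
        try:
            out[i] = _DNA_INDEX[c]
        except KeyError:
            raise ValueError(f"non-ACGTN character {c!r} in DNA sequence") from None
    return out


def _encode_protein(seq: str, index: dict[str, int]) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq.upper()):
        if c not in index:
            c = "X" if "X" in index else "*"
        out[i] = index[c]
    return out


def _encode(seq: str, molecule: str, params: AlignmentParams):
    if molecule == "dna":
        return _encode_dna(seq), params.dna_score_matrix()
    if molecule == "protein":
        mat, index = params.protein_score_matrix()
        return _encode_protein(seq, index), mat
    raise ValueError(f"unknown molecule type {molecule!r}")


# --------------------------------------------------------------------------
# Gotoh kernels (numba)
# --------------------------------------------------------------------------
# State codes used in the traceback matrices: 0 = from M (diagonal),
# 1 = from Ix (gap in b, vertical), 2 = from Iy (gap in a, horizontal),
# 3 = alignment start (local mode only).  Ties are broken M > Ix > Iy.

@njit(cache=True)
def _gotoh_fill(a, b, S, go, ge, local):  # pragma: no cover - numba
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)
    Iy = np.full((n + 1, m + 1), _NEG)
    tM = np.zeros((n + 1, m + 1), dtype=np.int8)
    tX = np.zeros((n + 1, m + 1), dtype=np.int8)
    tY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    if not local:
        for i in range(1, n + 1):
            Ix[i, 0] = -(go + (i - 1) * ge)
            tX[i, 0] = 1
        tX[1, 0] = 0
        for j in range(1, m + 1):
            Iy[0, j] = -(go + (j - 1) * ge)
            tY[0, j] = 2
        tY[0, 1] = 0
    else:
        for i in range(n + 1):
            M[i, 0] = 0.0
            tM[i, 0] = 3
        for j in range(m + 1):
            M[0, j] = 0.0
            tM[0, j] = 3
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: diagonal step
            v = M[i - 1, j - 1]
            c = 0
            if Ix[i - 1, j - 1] > v:
                v = Ix[i - 1, j - 1]
                c = 1
            if Iy[i - 1, j - 1] > v:
                v = Iy[i - 1, j - 1]
                c = 2
            sc = v + S[a[i - 1], b[j - 1]]
            if local and sc < 0.0:
                sc = 0.0
                c = 3
            M[i, j] = sc
            tM[i, j] = c
            # Ix: gap in b (consume a_i)
            v = M[i - 1, j] - go
            c = 0
            if Ix[i - 1, j] - ge > v:
                v = Ix[i - 1, j] - ge
                c = 1
            if Iy[i - 1, j] - go > v:
                v = Iy[i - 1, j] - go
                c = 2
            Ix[i, j] = v
            tX[i, j] = c
            # Iy: gap in a (consume b_j)
            v = M[i, j - 1] - go
            c = 0
            if Ix[i, j - 1] - go > v:
                v = Ix[i, j - 1] - go
                c = 1
            if Iy[i, j - 1] - ge > v:
                v = Iy[i, j - 1] - ge
                c = 2
            Iy[i, j] = v
            tY[i, j] = c
            if local and M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    if not local:
        best = M[n, m]
        bi = n
        bj = m
        state = 0
        if Ix[n, m] > best:
            best = Ix[n, m]
            state = 1
        if Iy[n, m] > best:
            best = Iy[n, m]
            state = 2
    else:
        state = 0
    # traceback
    cap = n + m + 1
    pa = np.empty(cap, dtype=np.int64)
    pb = np.empty(cap, dtype=np.int64)
    k = 0
    i = bi
    j = bj
    while True:
        if local and state == 0 and tM[i, j] == 3 and k > 0:
            break
        if not local and i == 0 and j == 0:
            break
        if state == 0:
            if local and tM[i, j] == 3 and k == 0:
                break
            prev = tM[i, j]
            pa[k] = i - 1
            pb[k] = j - 1
            i -= 1
            j -= 1
        elif state == 1:
            prev = tX[i, j]
            pa[k] = i - 1
            pb[k] = -1
            i -= 1
        else:
            prev = tY[i, j]
            pa[k] = -1
            pb[k] = j - 1
            j -= 1
        k += 1
        state = prev
        if local and i == 0 and j == 0:
            break
    return best, pa[:k][::-1].copy(), pb[:k][::-1].copy(), i, j


def _run_alignment(a: str, b: str, params: AlignmentParams, molecule: str,
                   local: bool) -> PairwiseAlignment:
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ca, S = _encode(a, molecule, params)
    cb, _ = _encode(b, molecule, params)
    score, pa, pb, a0, b0 = _gotoh_fill(
        ca, cb, S, float(params.gap_open), float(params.gap_extend), local
    )
    if local and score <= 0.0:
        return PairwiseAlignment("", "", 0.0, "local", molecule, 0.0, 0.0)
    aligned_a = "".join(a[i] if i >= 0 else "-" for i in pa)
    aligned_b = "".join(b[j] if j >= 0 else "-" for j in pb)
    aln = PairwiseAlignment(
        aligned_a, aligned_b, float(score),
        "local" if local else "global", molecule, 0.0, 0.0,
        a_start=int(a0), b_start=int(b0),
    )
    aln.identity_pct, aln.similarity_pct = identity_and_similarity(aln, params)
    return aln


def global_align(a: str, b: str, params: AlignmentParams | None = None,
                 molecule: str = "dna") -> PairwiseAlignment:
    """Optimal affine-gap global (Needleman-Wunsch-Gotoh) alignment.

    End gaps are penalised like internal gaps.  Raises ``ValueError`` on
    an empty input sequence.
    """
    return _run_alignment(a, b, params or AlignmentParams(), molecule, local=False)


def local_align(a: str, b: str, params: AlignmentParams | None = None,
                molecule: str = "dna") -> PairwiseAlignment:
    """Optimal affine-gap local (Smith-Waterman-Gotoh) alignment.

    When no positive-scoring pairing exists the empty alignment with
    score 0 is returned.
    """
    return _run_alignment(a, b, params or AlignmentParams(), molecule, local=True)


# --------------------------------------------------------------------------
# Identity / similarity / profiles
# --------------------------------------------------------------------------

def identity_and_similarity(alignment: PairwiseAlignment,
                            params: AlignmentParams | None = None,
                            ) -> tuple[float, float]:
    """Percent identity and similarity over all aligned columns.

    Identity counts columns with identical non-gap, non-N characters; gap
    columns stay in the denominator.  For proteins, similarity counts
    columns whose substitution-matrix score is positive (EMBOSS
    semantics); for DNA, similarity equals identity.
    """
    params = params or AlignmentParams()
    ncol = len(alignment)
    if ncol == 0:
        raise ValueError("empty alignment")
    ident = 0
    simil = 0
    if alignment.molecule == "protein":
        mat, index = params.protein_score_matrix()
        xi = index.get("X", None)
        for x, y in zip(alignment.aligned_a, alignment.aligned_b):
            if x == "-" or y == "-":
                continue
            if x == y and x != "X":
                ident += 1
            i = index.get(x, xi)
            j = index.get(y, xi)
            if i is not None and j is not None and mat[i, j] > 0:
                simil += 1
        return 100.0 * ident / ncol, 100.0 * simil / ncol
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x == y and x not in ("-", "N"):
            ident += 1
    pct = 100.0 * ident / ncol
    return pct, pct


def sliding_identity_profile(alignment: PairwiseAlignment,
                             window_size: int = 100,
                             step: int = 25) -> IdentityProfile:
    """VISTA-style windowed identity along the first sequence.

    Windows are 1-based closed intervals in first-sequence coordinates;
    a column contributes to the window containing its first-sequence
    position (columns that are gaps in the first sequence carry no
    coordinate and are skipped).  Windows with zero aligned columns are
    omitted from the result.
    """
    if not (window_size >= step >= 1):
        raise ValueError("require window_size >= step >= 1")
    a = np.frombuffer(alignment.aligned_a.encode(), dtype="S1")
    b = np.frombuffer(alignment.aligned_b.encode(), dtype="S1")
    in_a = a != b"-"
    if not in_a.any():
        return IdentityProfile([], window_size, step)
    match = (a == b) & in_a & (a != b"N")
    # 0-based first-sequence coordinate of each column that has one
    coords = alignment.a_start + np.cumsum(in_a) - 1
    length = int(coords[-1]) + 1
    covered = np.zeros(length, dtype=np.int64)
    matched = np.zeros(length, dtype=np.int64)
    covered[coords[in_a]] = 1
    matched[coords[in_a & match]] = 1
    ccov = np.concatenate(([0], np.cumsum(covered)))
    cmat = np.concatenate(([0], np.cumsum(matched)))
    windows: list[tuple[int, int, float]] = []
    start = 0
    while start < length:
        end = min(start + window_size - 1, length - 1)
        tot = int(ccov[end + 1] - ccov[start])
        if tot > 0:
            idn = int(cmat[end + 1] - cmat[start])
            windows.append((start + 1, end + 1, 100.0 * idn / tot))
        if end == length - 1:
            break
        start += step
    return IdentityProfile(windows, window_size, step)


# --------------------------------------------------------------------------
# Karlin-Altschul statistics
# --------------------------------------------------------------------------

def karlin_altschul_params(match: float, mismatch: float,
                           base_freqs: np.ndarray | None = None,
                           ) -> tuple[float, float, float]:
    """Solve the ungapped Karlin-Altschul system for a match/mismatch
    scoring scheme; returns (lambda, K, H).

    lambda is the positive root of ``sum_ij p_i p_j exp(lambda s_ij) = 1``;
    K is computed by the lattice-score series (iterated convolution of the
    per-column score distribution).  Scores must be integers for the K
    computation (the defaults 5/-4 are).
    """
    if base_freqs is None:
        base_freqs = np.full(4, 0.25)
    base_freqs = np.asarray(base_freqs, dtype=float)
    p_match = float(np.sum(base_freqs ** 2))
    p_mis = 1.0 - p_match
    if not (match > 0 > mismatch):
        raise ValueError("need match > 0 > mismatch")

    def f(lam: float) -> float:
        return p_match * math.exp(lam * match) + p_mis * math.exp(lam * mismatch) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    lam = float(brentq(f, 1e-12, hi, xtol=1e-14))

    im, imm = int(round(match)), int(round(mismatch))
    if im != match or imm != mismatch:
        raise ValueError("K computation requires integer scores")
    delta = math.gcd(im, -imm)
    lo, hi_s = imm, im
    # per-column score distribution on the integer lattice [lo, hi_s]
    probs = np.zeros(hi_s - lo + 1)
    probs[im - lo] = p_match
    probs[imm - lo] = p_mis
    av = p_match * im * math.exp(lam * im) + p_mis * imm * math.exp(lam * imm)
    H = lam * av
    # sigma = sum_k 1/k * ( E[e^{lam S_k}; S_k < 0] + P(S_k >= 0) )
    sigma = 0.0
    dist = np.array([1.0])  # distribution of S_0 = 0, offset 0
    offset = 0
    for k in range(1, 64):
        dist = np.convolve(dist, probs)
        offset += lo
        scores = offset + np.arange(dist.size)
        neg = scores < 0
        term = float(np.sum(dist[neg] * np.exp(lam * scores[neg])) + np.sum(dist[~neg]))
        sigma += term / k
        if term / k < 1e-12:
            break
    K = delta * math.exp(-2.0 * sigma) / (av * (1.0 - math.exp(-lam * delta)))
    return lam, K, H


def evalue(score: float, query_len: int, target_len: int,
           params: AlignmentParams | None = None) -> float:
    """Karlin-Altschul expected number of chance hits: E = K m n e^(-lambda S).

    Uses ungapped (lambda, K) for the DNA scoring system as an approximate
    surrogate for gapped local-alignment scores.
    """
    if query_len <= 0 or target_len <= 0:
        raise ValueError("sequence lengths must be positive")
    if score < 0:
        raise ValueError("score must be >= 0")
    params = params or AlignmentParams()
    lam, K = params.karlin_altschul()
    return K * query_len * target_len * math.exp(-lam * score)
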