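"""Pairwise Ka/Ks estimation under codon substitution models.

Two routes are provided and kept deliberately independent:

* :func:`estimate_gy94` — maximum-likelihood estimation under the
  Goldman-Yang (1994) codon model with F3x4 codon frequencies, the
  convention used by PAML's CODEML for pairwise comparisons.  The model
  has three free parameters: branch length ``t`` (expected substitutions
  per codon), transition/transversion rate ratio ``kappa`` and selection
  parameter ``omega`` (= Ka/Ks).  Ks and Ka are derived from the fitted
  parameters by partitioning the substitution flow through the rate
  matrix into synonymous and non-synonymous components and dividing by
  the corresponding (mutational-opportunity, omega = 1) site fractions.

* :func:`estimate_ng86` — Nei-Gojobori (1986) pathway counting with
  Jukes-Cantor correction, a model-light counting estimator that serves
  as an independent cross-check of the likelihood machinery.

Both consume a :class:`CodonAlignment` built by protein-guided alignment
of two coding sequences (:func:`build_codon_alignment`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize
from Bio.Seq import Seq

from .pairwise_align import AlignmentParams, global_align

__all__ = [
    "CodonAlignment",
    "KaKsEstimate",
    "SaturationError",
    "build_codon_alignment",
    "f3x4_frequencies",
    "gy94_rate_matrix",
    "estimate_gy94",
    "estimate_ng86",
    "simulate_codon_pair",
]

MIN_CODONS = 10

# ---- genetic code tables (standard/universal; 61 sense codons) -----------

_BASES = "TCAG"
_CODONS_ALL = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS: list[str] = [c for c in _CODONS_ALL if c not in _STOPS]
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID: dict[str, str] = {c: str(Seq(c).translate()) for c in SENSE_CODONS}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _build_change_tables():
    """For each ordered sense-codon pair differing at one position:
    is it a transition, is it synonymous."""
    n = len(SENSE_CODONS)
    diff_pos = np.full((n, n), -1, dtype=np.int8)
    is_ts = np.zeros((n, n), dtype=bool)
    is_syn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) == 1:
                k = diffs[0]
                diff_pos[i, j] = k
                is_ts[i, j] = (ci[k], cj[k]) in _TRANSITIONS
                is_syn[i, j] = AMINO_ACID[ci] == AMINO_ACID[cj]
    return diff_pos, is_ts, is_syn


_DIFF_POS, _IS_TS, _IS_SYN = _build_change_tables()
_SINGLE = _DIFF_POS >= 0


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Gap-free aligned sense-codon pairs from two coding sequences."""

    codon_pairs: list[tuple[str, str]]
    source_gene_ids: tuple[str, str] = ("a", "b")

    def __post_init__(self) -> None:
        if len(self.codon_pairs) < MIN_CODONS:
            raise ValueError(
                f"insufficient alignable codons ({len(self.codon_pairs)} < {MIN_CODONS})")
        for ca, cb in self.codon_pairs:
            if ca not in CODON_INDEX or cb not in CODON_INDEX:
                raise ValueError(f"invalid codon pair ({ca}, {cb})")

    @property
    def n_codons(self) -> int:
        return len(self.codon_pairs)

    def index_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        ia = np.array([CODON_INDEX[a] for a, _ in self.codon_pairs])
        ib = np.array([CODON_INDEX[b] for _, b in self.codon_pairs])
        return ia, ib

    def p_distance(self) -> float:
        """Proportion of codon sites whose codons differ."""
        return sum(a != b for a, b in self.codon_pairs) / self.n_codons


@dataclass
class KaKsEstimate:
    """Per-pair evolutionary estimates (GY94 or NG86)."""

    Ks: float
    Ka: float
    kappa: float
    omega: float
    t: float
    lnL: float
    S_sites: float
    N_sites: float
    codon_freqs: np.ndarray = field(repr=False)
    method: str = "GY94"
    n_codons: int = 0
    gene_id_a: str = "a"
    gene_id_b: str = "b"
    converged: bool = True

    def __post_init__(self) -> None:
        if self.Ks < 0 or self.Ka < 0:
            raise ValueError("Ks and Ka must be non-negative")

    def as_record(self) -> dict:
        return {
            "gene_id_a": self.gene_id_a, "gene_id_b": self.gene_id_b,
            "n_codons": self.n_codons, "ks": self.Ks, "ka": self.Ka,
            "omega": self.omega, "kappa": self.kappa, "t": self.t,
            "lnL": self.lnL, "method": self.method,
        }


class SaturationError(ValueError):
    """Divergence too high for a meaningful estimate."""


# --------------------------------------------------------------------------
# Codon alignment construction
# --------------------------------------------------------------------------

def _clean_cds(cds: str, gene_id: str) -> str:
    """Trim trailing partial codon and terminal stop; drop internal stop
    codons (at most one tolerated)."""
    cds = cds.upper()
    cds = cds[: len(cds) - len(cds) % 3]
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    internal = [c for c in codons if c in _STOPS]
    if len(internal) > 1:
        raise ValueError(f"CDS {gene_id} has {len(internal)} internal stop codons")
    return "".join(codons)


def build_codon_alignment(cds_a: str, cds_b: str,
                          gene_ids: tuple[str, str] = ("a", "b"),
                          params: AlignmentParams | None = None,
                          ) -> CodonAlignment:
    """Protein-guided codon alignment of two CDSs.

    The CDSs are translated, the proteins globally aligned, and the
    alignment back-mapped to codons; columns containing gaps, N bases or
    stop codons are dropped.  Fewer than 10 clean codon pairs raises
    ``ValueError`` ("insufficient alignable codons").
    """
    ca = _clean_cds(cds_a, gene_ids[0])
    cb = _clean_cds(cds_b, gene_ids[1])
    cod_a = [ca[i:i + 3] for i in range(0, len(ca), 3)]
    cod_b = [cb[i:i + 3] for i in range(0, len(cb), 3)]
    prot_a = "".join("X" if c in _STOPS or "N" in c else AMINO_ACID[c] for c in cod_a)
    prot_b = "".join("X" if c in _STOPS or "N" in c else AMINO_ACID[c] for c in cod_b)
    if not prot_a or not prot_b:
        raise ValueError("insufficient alignable codons (empty translation)")
    aln = global_align(prot_a, prot_b, params, molecule="protein")
    pairs: list[tuple[str, str]] = []
    i = j = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y != "-":
            codon_a, codon_b = cod_a[i], cod_b[j]
            if codon_a in CODON_INDEX and codon_b in CODON_INDEX:
                pairs.append((codon_a, codon_b))
        if x != "-":
            i += 1
        if y != "-":
            j += 1
    if len(pairs) < MIN_CODONS:
        raise ValueError(
            f"insufficient alignable codons ({len(pairs)} < {MIN_CODONS})")
    return CodonAlignment(pairs, source_gene_ids=gene_ids)


# --------------------------------------------------------------------------
# GY94 machinery
# --------------------------------------------------------------------------

FREQ_FLOOR = 1e-6


def f3x4_frequencies(codons: list[str]) -> np.ndarray:
    """F3x4 codon frequencies from observed codons (both sequences pooled):
    the product of the per-codon-position nucleotide frequencies,
    renormalised over sense codons with a small pseudo-frequency floor."""
    pos_freq = np.zeros((3, 4))  # positions x TCAG
    base_idx = {b: i for i, b in enumerate(_BASES)}
    for c in codons:
        for k in range(3):
            pos_freq[k, base_idx[c[k]]] += 1
    pos_freq = (pos_freq + 1e-9) / (pos_freq + 1e-9).sum(axis=1, keepdims=True)
    pi = np.array([pos_freq[0, base_idx[c[0]]]
                   * pos_freq[1, base_idx[c[1]]]
                   * pos_freq[2, base_idx[c[2]]] for c in SENSE_CODONS])
    pi = np.maximum(pi / pi.sum(), FREQ_FLOOR)
    return pi / pi.sum()


def gy94_rate_matrix(kappa: float, omega: float, codon_freqs: np.ndarray,
                     ) -> np.ndarray:
    """GY94 instantaneous rate matrix over the 61 sense codons.

    q_ij is non-zero only for single-nucleotide changes and equals
    pi_j * kappa^[transition] * omega^[non-synonymous]; rows sum to zero
    and the matrix is scaled so the expected substitution rate
    ``-sum_i pi_i q_ii`` is one per codon per unit branch length.
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    pi = np.maximum(np.asarray(codon_freqs, dtype=float), FREQ_FLOOR)
    pi = pi / pi.sum()
    Q = np.zeros((61, 61))
    Q[_SINGLE] = pi[np.where(_SINGLE)[1]]
    Q[_SINGLE & _IS_TS] *= kappa
    Q[_SINGLE & ~_IS_SYN] *= omega
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.sum(pi * np.diag(Q))
    if scale > 0:
        Q /= scale
    return Q


def _transition_matrix(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via symmetrised eigendecomposition (Q reversible)."""
    sq = np.sqrt(pi)
    B = (Q * sq[:, None]) / sq[None, :]
    B = (B + B.T) / 2.0
    w, U = eigh(B)
    P = (U * np.exp(w * t)) @ U.T
    P = P / sq[:, None] * sq[None, :]
    return np.clip(P, 1e-300, None)


def _flow_fractions(kappa: float, omega: float, pi: np.ndarray,
                    ) -> tuple[float, float]:
    """(synonymous, non-synonymous) fractions of the substitution flow
    through the scaled GY94 matrix at the given parameters."""
    Q = gy94_rate_matrix(kappa, omega, pi)
    flow = pi[:, None] * Q
    syn = float(flow[_SINGLE & _IS_SYN].sum())
    non = float(flow[_SINGLE & ~_IS_SYN].sum())
    tot = syn + non
    return syn / tot, non / tot


def estimate_gy94(aln: CodonAlignment, initial_kappa: float = 2.0,
                  initial_omega: float = 0.4, n_restarts: int = 3,
                  seed: int = 0) -> KaKsEstimate:
    """Maximum-likelihood pairwise Ka/Ks under the GY94 model.

    Optimises (log t, log kappa, log omega) by bounded quasi-Newton from
    a p-distance-based start, with seeded random restarts on failure.
    Identical sequences short-circuit to Ks = Ka = 0; codon p-distance
    above 0.75 raises :class:`SaturationError`.
    """
    ia, ib = aln.index_pairs()
    pooled = [c for pair in aln.codon_pairs for c in pair]
    pi = f3x4_frequencies(pooled)
    n = aln.n_codons
    pdist = aln.p_distance()
    if pdist > 0.75:
        raise SaturationError(f"codon p-distance {pdist:.3f} > 0.75")
    # sufficient statistics: counts per (i, j) codon-state pair
    counts: dict[tuple[int, int], int] = {}
    for i, j in zip(ia, ib):
        counts[(i, j)] = counts.get((i, j), 0) + 1
    keys = np.array(list(counts.keys()))
    cnt = np.array(list(counts.values()), dtype=float)
    ki, kj = keys[:, 0], keys[:, 1]
    log_pi = np.log(pi)

    if pdist == 0.0:
        lnL = float(np.sum(cnt * log_pi[ki]))  # t -> 0 limit
        sf1, nf1 = _flow_fractions(initial_kappa, 1.0, pi)
        S = 3 * n * sf1
        return KaKsEstimate(Ks=0.0, Ka=0.0, kappa=initial_kappa, omega=initial_omega,
                            t=0.0, lnL=lnL, S_sites=S, N_sites=3 * n - S,
                            codon_freqs=pi, method="GY94", n_codons=n,
                            gene_id_a=aln.source_gene_ids[0],
                            gene_id_b=aln.source_gene_ids[1])

    def nll(x: np.ndarray) -> float:
        t, kappa, omega = np.exp(x)
        Q = gy94_rate_matrix(kappa, omega, pi)
        P = _transition_matrix(Q, pi, t)
        ll = np.sum(cnt * (log_pi[ki] + np.log(P[ki, kj])))
        return -float(ll)

    bounds = [(math.log(1e-6), math.log(50.0)),
              (math.log(0.02), math.log(100.0)),
              (math.log(1e-4), math.log(100.0))]
    x0 = np.log([max(3.0 * pdist, 1e-4), initial_kappa, initial_omega])
    rng = np.random.default_rng(seed)
    best = None
    converged = True
    for attempt in range(1 + n_restarts):
        start = x0 if attempt == 0 else x0 + rng.normal(0, 0.5, size=3)
        start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if res.success:
            break
    else:
        converged = False
    t, kappa, omega = np.exp(best.x)
    sf, nf = _flow_fractions(kappa, omega, pi)
    sf1, nf1 = _flow_fractions(kappa, 1.0, pi)
    S_sites = 3 * n * sf1
    N_sites = 3 * n * nf1
    Ks = t * sf / (3 * sf1)
    Ka = t * nf / (3 * nf1)
    return KaKsEstimate(Ks=Ks, Ka=Ka, kappa=float(kappa), omega=float(omega),
                        t=float(t), lnL=-float(best.fun), S_sites=S_sites,
                        N_sites=N_sites, codon_freqs=pi, method="GY94",
                        n_codons=n, gene_id_a=aln.source_gene_ids[0],
                        gene_id_b=aln.source_gene_ids[1], converged=converged)


# --------------------------------------------------------------------------
# NG86 counting
# --------------------------------------------------------------------------

def _ng86_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts of one codon: per position
    the fraction of the three possible changes that are synonymous
    (changes to stop codons counted as non-synonymous)."""
    syn = 0.0
    aa = AMINO_ACID[codon]
    for k in range(3):
        for b in _BASES:
            if b == codon[k]:
                continue
            alt = codon[:k] + b + codon[k + 1:]
            if alt not in _STOPS and AMINO_ACID[alt] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _ng86_diff_counts(ca: str, cb: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two codons,
    averaged over all minimal mutational pathways; pathways passing
    through a stop codon are excluded (unless all do)."""
    diffs = [k for k in range(3) if ca[k] != cb[k]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur = ca
        syn = non = 0.0
        blocked = False
        for k in order:
            nxt = cur[:k] + cb[k] + cur[k + 1:]
            if nxt in _STOPS:
                blocked = True
                break
            if AMINO_ACID[cur] == AMINO_ACID[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if not blocked:
            paths.append((syn, non))
    if not paths:  # all pathways blocked by stops: count through them anyway
        for order in itertools.permutations(diffs):
            cur = ca
            syn = non = 0.0
            for k in order:
                nxt = cur[:k] + cb[k] + cur[k + 1:]
                if nxt in _STOPS or AMINO_ACID.get(cur, "*") != AMINO_ACID.get(nxt, "*"):
                    non += 1
                else:
                    syn += 1
                cur = nxt
            paths.append((syn, non))
    syn = sum(p[0] for p in paths) / len(paths)
    non = sum(p[1] for p in paths) / len(paths)
    return syn, non


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion of differences {p:.3f} >= 0.75")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def estimate_ng86(aln: CodonAlignment) -> KaKsEstimate:
    """Nei-Gojobori (1986) counting estimate of Ks and Ka.

    Site counts are averaged over the two sequences; differences are
    averaged over minimal mutational pathways; pS and pN are
    Jukes-Cantor corrected.  pS or pN >= 0.75 raises
    :class:`SaturationError`.
    """
    S = N = 0.0
    sd = nd = 0.0
    for ca, cb in aln.codon_pairs:
        sa, na = _ng86_site_counts(ca)
        sb, nb = _ng86_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        s, nn = _ng86_diff_counts(ca, cb)
        sd += s
        nd += nn
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(pS)
    Ka = _jukes_cantor(pN)
    pooled = [c for pair in aln.codon_pairs for c in pair]
    omega = Ka / Ks if Ks > 0 else float("nan")
    return KaKsEstimate(Ks=Ks, Ka=Ka, kappa=float("nan"), omega=omega,
                        t=float("nan"), lnL=float("nan"), S_sites=S, N_sites=N,
                        codon_freqs=f3x4_frequencies(pooled), method="NG86",
                        n_codons=aln.n_codons,
                        gene_id_a=aln.source_gene_ids[0],
                        gene_id_b=aln.source_gene_ids[1])


# --------------------------------------------------------------------------
# Simulation (used by synthetic_data and the recovery tests)
# --------------------------------------------------------------------------

def simulate_codon_path(codons: np.ndarray, Q: np.ndarray, t: float,
                        rng: np.random.Generator,
                        ) -> tuple[np.ndarray, int, int]:
    """Evolve codon states along a branch of length ``t`` by sampling the
    continuous-time Markov jump chain; returns (new states, realised
    synonymous jumps, realised non-synonymous jumps)."""
    rates = -np.diag(Q)
    jump = Q / rates[:, None]
    np.fill_diagonal(jump, 0.0)
    cum = np.cumsum(jump, axis=1)
    out = codons.copy()
    syn = non = 0
    for idx in range(out.size):
        state = out[idx]
        remaining = t
        while True:
            r = rates[state]
            if r <= 0:
                break
            wait = rng.exponential(1.0 / r)
            if wait > remaining:
                break
            remaining -= wait
            u = rng.random()
            nxt = int(np.searchsorted(cum[state], u * cum[state, -1]))
            if _IS_SYN[state, nxt]:
                syn += 1
            else:
                non += 1
            state = nxt
        out[idx] = state
    return out, syn, non


def simulate_codon_pair(n_codons: int, t: float, kappa: float, omega: float,
                        codon_freqs: np.ndarray | None = None,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[CodonAlignment, dict]:
    """Simulate a pair of coding sequences diverged by total distance
    ``t`` (two branches of t/2 from a common ancestor drawn from the
    stationary distribution).  Returns the codon alignment and a truth
    dict with realised substitution counts and site counts."""
    rng = rng or np.random.default_rng()
    pi = (np.full(61, 1.0 / 61) if codon_freqs is None
          else np.asarray(codon_freqs, dtype=float))
    Q = gy94_rate_matrix(kappa, omega, pi)
    anc = rng.choice(61, size=n_codons, p=pi / pi.sum())
    a, syn_a, non_a = simulate_codon_path(anc, Q, t / 2.0, rng)
    b, syn_b, non_b = simulate_codon_path(anc, Q, t / 2.0, rng)
    pairs = [(SENSE_CODONS[i], SENSE_CODONS[j]) for i, j in zip(a, b)]
    sf1, _ = _flow_fractions(kappa, 1.0, pi)
    S_sites = 3 * n_codons * sf1
    N_sites = 3 * n_codons - S_sites
    truth = {
        "t": t, "kappa": kappa, "omega": omega,
        "syn_subs": syn_a + syn_b, "non_subs": non_a + non_b,
        "S_sites": S_sites, "N_sites": N_sites,
        "realised_ks": (syn_a + syn_b) / S_sites,
        "realised_ka": (non_a + non_b) / N_sites,
    }
    sf, nf = _flow_fractions(kappa, omega, pi)
    truth["expected_ks"] = t * sf / (3 * sf1)
    truth["expected_ka"] = t * nf / (3 * (1 - sf1))
    return CodonAlignment(pairs), truth
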