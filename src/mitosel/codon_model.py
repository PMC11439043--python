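"""Goldman–Yang (GY94-style) codon substitution model.

The instantaneous rate from codon i to codon j is nonzero only when the
codons differ at exactly one nucleotide position:

    q_ij = pi_j            synonymous transversion
    q_ij = kappa * pi_j    synonymous transition
    q_ij = omega * pi_j    nonsynonymous transversion
    q_ij = omega * kappa * pi_j    nonsynonymous transition

over the sense codons of the bound genetic code (stop codons are excluded
from the state space).  The chain is time-reversible with stationary
distribution pi.  Transition matrices exp(Qt) are computed through the
eigendecomposition of the pi-symmetrized generator, which is cached so
that many branch lengths reuse one decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .seqio import CodonAlignment, GeneticCode, GAP_CODON, _expand_ambiguous

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_NUCS = "ACGT"


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


@lru_cache(maxsize=8)
def _code_structure(table_id: int):
    """Single-nucleotide-change structure arrays for one genetic code."""
    code = GeneticCode.from_table_id(table_id)
    codons = code.sense_codons
    n = len(codons)
    idx = {c: i for i, c in enumerate(codons)}
    pairs_i, pairs_j, is_ts, is_nonsyn = [], [], [], []
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            pairs_i.append(i)
            pairs_j.append(j)
            is_ts.append(_is_transition(*diffs[0]))
            is_nonsyn.append(code.codon_to_aa[ci] != code.codon_to_aa[cj])
    return {
        "code": code,
        "codons": codons,
        "index": idx,
        "n": n,
        "i": np.array(pairs_i),
        "j": np.array(pairs_j),
        "ts": np.array(is_ts, dtype=bool),
        "nonsyn": np.array(is_nonsyn, dtype=bool),
    }


@dataclass
class CodonRateModel:
    """Parameters of a single-omega GY94 process."""

    kappa: float
    omega: float
    codon_freqs: np.ndarray  # over sense codons, sums to 1
    code: GeneticCode

    def __post_init__(self):
        if self.kappa < 0 or self.omega < 0:
            raise ValueError("kappa and omega must be >= 0")
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.codon_freqs.shape != (len(self.code.sense_codons),):
            raise ValueError("codon_freqs length must match sense-codon count")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-8:
            raise ValueError("codon_freqs must sum to 1")


def build_generator(model: CodonRateModel, scale: bool = True) -> np.ndarray:
    """GY94 rate generator over sense codons.

    With ``scale=True`` the generator is normalized so the expected number
    of substitutions per codon site at equilibrium is 1 (branch lengths in
    substitutions per codon site).
    """
    s = _code_structure(model.code.table_id)
    n = s["n"]
    rates = model.codon_freqs[s["j"]].copy()
    rates[s["ts"]] *= model.kappa
    rates[s["nonsyn"]] *= model.omega
    Q = np.zeros((n, n))
    Q[s["i"], s["j"]] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        rate = substitution_rate(Q, model.codon_freqs)
        if rate <= 0:
            raise ValueError("degenerate generator: zero total rate")
        Q = Q / rate
    return Q


def substitution_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per site per unit time, -sum_i pi_i q_ii."""
    return float(-(pi * np.diag(Q)).sum())


class SpectralGenerator:
    """Eigendecomposition of a reversible generator for fast exp(Qt).

    Uses the similarity transform S = D^{1/2} Q D^{-1/2} with
    D = diag(pi), which is symmetric for reversible Q, so that
    exp(Qt) = D^{-1/2} U exp(L t) U^T D^{1/2}.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = Q
        self.pi = pi
        sqrt_pi = np.sqrt(pi)
        S = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        S = 0.5 * (S + S.T)  # symmetrize against round-off
        lam, U = np.linalg.eigh(S)
        self.lam = lam
        self.left = U / sqrt_pi[:, None]  # D^{-1/2} U
        self.right = (U * sqrt_pi[:, None]).T  # U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        P = (self.left * np.exp(self.lam * t)) @ self.right
        np.maximum(P, 0.0, out=P)
        return P

    def dP_dt(self, t: float) -> np.ndarray:
        return (self.left * (self.lam * np.exp(self.lam * t))) @ self.right


# -- codon frequency schemes ------------------------------------------------

def _freqs_from_counts(nuc_counts, code: GeneticCode, positional: bool) -> np.ndarray:
    codons = code.sense_codons
    if positional:
        probs = [c / c.sum() for c in nuc_counts]
        raw = np.array(
            [np.prod([probs[p][_NUCS.index(c[p])] for p in range(3)]) for c in codons]
        )
    else:
        p = nuc_counts / nuc_counts.sum()
        raw = np.array([np.prod([p[_NUCS.index(ch)] for ch in c]) for c in codons])
    raw = raw + 1e-9  # guard against unobserved states
    return raw / raw.sum()


def empirical_codon_freqs(aln: CodonAlignment, scheme: str = "F3x4") -> np.ndarray:
    """Equilibrium codon frequencies estimated from alignment counts.

    ``F3x4``: position-specific nucleotide frequencies (default);
    ``F1x4``: pooled nucleotide frequencies; ``F61``: observed codon
    frequencies; ``uniform``: equal over sense codons.
    """
    code = aln.code
    codons = code.sense_codons
    scheme = scheme.upper() if scheme.lower() != "uniform" else "uniform"
    if scheme == "uniform":
        return np.full(len(codons), 1.0 / len(codons))
    flat = aln.codons.ravel()
    if scheme in ("F3X4", "F1X4"):
        counts = np.zeros((3, 4))
        for codon in flat:
            if codon == GAP_CODON:
                continue
            for p, ch in enumerate(codon):
                if ch in _NUCS:
                    counts[p, _NUCS.index(ch)] += 1
        if counts.sum() == 0:
            raise ValueError("no unambiguous codons to estimate frequencies")
        if scheme == "F1X4":
            return _freqs_from_counts(counts.sum(axis=0), code, positional=False)
        return _freqs_from_counts(counts, code, positional=True)
    if scheme == "F61":
        idx = {c: i for i, c in enumerate(codons)}
        counts = np.zeros(len(codons))
        for codon in flat:
            if codon in idx:
                counts[idx[codon]] += 1
        counts = counts + 1e-9
        return counts / counts.sum()
    raise ValueError(f"unknown frequency scheme {scheme!r}")


def tip_partials(aln: CodonAlignment) -> np.ndarray:
    """Tip likelihood indicators, shape (n_taxa, n_sites, n_sense_codons).

    Unambiguous codons map to a single 1; IUPAC-ambiguous codons get a 1
    for every compatible sense codon (marginalization); gap codons are all
    ones (missing data).  Stop codons are rejected.
    """
    s = _code_structure(aln.code.table_id)
    idx, n = s["index"], s["n"]
    out = np.zeros((aln.n_taxa, aln.n_sites, n))
    for i in range(aln.n_taxa):
        for j in range(aln.n_sites):
            codon = aln.codons[i, j]
            if codon in idx:
                out[i, j, idx[codon]] = 1.0
            elif codon == GAP_CODON:
                out[i, j, :] = 1.0
            else:
                compatible = [idx[c] for c in _expand_ambiguous(codon) if c in idx]
                if not compatible:
                    raise ValueError(
                        f"codon {codon} of {aln.taxa[i]} at site {j + 1} "
                        "is stop-only under the genetic code"
                    )
                out[i, j, compatible] = 1.0
    return out
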