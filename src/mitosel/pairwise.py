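"""Pairwise dN/dS estimation between two in-frame codon sequences.

Two estimators are provided:

``ML``
    Maximum likelihood under the single-omega GY94 model: the two-sequence
    likelihood ``sum_sites log(pi_i P_ij(t))`` is maximized over the
    divergence ``t`` (substitutions per codon), ``kappa`` and ``omega``,
    and dN/dS are read off the fitted rate matrix using the
    mutational-opportunity site proportions evaluated at omega = 1.

``NG86``
    The Nei–Gojobori (1986) counting estimator with equal-weight pathway
    averaging and Jukes–Cantor correction.  It shares no code with the
    likelihood path and serves as an independent cross-check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .codon_model import (
    CodonRateModel,
    SpectralGenerator,
    _code_structure,
    build_generator,
    substitution_rate,
)
from .seqio import GAP_CODON, GeneticCode


@dataclass
class PairwiseRates:
    dN: float
    dS: float
    omega: float | None  # None when dS = 0 (undefined)
    method: str
    t: float | None = None
    kappa: float | None = None

    @property
    def omega_undefined(self) -> bool:
        return self.omega is None


def _codons_of(seq, code: GeneticCode) -> list[str]:
    if isinstance(seq, str):
        if len(seq) % 3:
            raise ValueError("sequence length not divisible by 3")
        seq = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    out = [str(c).upper() for c in seq]
    for c in out:
        if c != GAP_CODON and c in code.codon_to_aa and code.codon_to_aa[c] == "*":
            raise ValueError(f"stop codon {c} in pairwise input")
    return out


def _syn_proportions(kappa, omega, pi, code):
    """(rho_syn at omega, site proportion syn at omega=1) for scaled GY94."""
    s = _code_structure(code.table_id)
    Q = build_generator(CodonRateModel(kappa, omega, pi, code), scale=True)
    flux = pi[s["i"]] * Q[s["i"], s["j"]]
    rho_s = flux[~s["nonsyn"]].sum() / flux.sum()
    Q1 = build_generator(CodonRateModel(kappa, 1.0, pi, code), scale=False)
    flux1 = pi[s["i"]] * Q1[s["i"], s["j"]]
    s_prop = flux1[~s["nonsyn"]].sum() / flux1.sum()
    return float(rho_s), float(s_prop)


def pairwise_rates(
    seqA,
    seqB,
    code: GeneticCode | None = None,
    method: str = "ML",
    codon_freqs: np.ndarray | None = None,
) -> PairwiseRates:
    """Estimate dN, dS and omega between two equal-length codon sequences.

    Sites containing a gap or ambiguity in either sequence are dropped.
    When no synonymous divergence is observed, omega is flagged undefined
    rather than divided by zero.
    """
    code = code or GeneticCode.from_table_id(5)
    ca, cb = _codons_of(seqA, code), _codons_of(seqB, code)
    if len(ca) != len(cb):
        raise ValueError("sequences have different codon counts")
    s = _code_structure(code.table_id)
    idx = s["index"]
    pairs = [
        (a, b) for a, b in zip(ca, cb) if a in idx and b in idx
    ]
    if not pairs:
        raise ValueError("no comparable codon sites")
    method = method.upper()
    if method == "NG86":
        return _ng86(pairs, code)
    if method != "ML":
        raise ValueError(f"unknown method {method!r}")
    return _ml_pairwise(pairs, code, codon_freqs)


# -- maximum likelihood ------------------------------------------------------

def _ml_pairwise(pairs, code, codon_freqs=None) -> PairwiseRates:
    s = _code_structure(code.table_id)
    idx, n = s["index"], s["n"]
    counts = np.zeros((n, n))
    for a, b in pairs:
        counts[idx[a], idx[b]] += 1
    if codon_freqs is None:
        obs = counts.sum(axis=1) + counts.sum(axis=0) + 1e-9
        pi = obs / obs.sum()
    else:
        pi = np.asarray(codon_freqs, dtype=float)
    ii, jj = np.nonzero(counts)
    ww = counts[ii, jj]

    if all(a == b for a, b in pairs):
        return PairwiseRates(0.0, 0.0, None, "ML", t=0.0, kappa=None)

    def neg_lnl(theta):
        t, kappa, omega = np.exp(theta)
        Q = build_generator(CodonRateModel(kappa, omega, pi, code), scale=True)
        P = SpectralGenerator(Q, pi).transition_matrix(t)
        lik = pi[ii] * P[ii, jj]
        if np.any(lik <= 0):
            return 1e12
        return -float(ww @ np.log(lik))

    best = None
    for t0, w0 in [(0.3, 0.5), (1.0, 0.2), (0.1, 1.0)]:
        res = optimize.minimize(
            neg_lnl,
            np.log([t0, 2.0, w0]),
            method="L-BFGS-B",
            bounds=[(np.log(1e-5), np.log(50)), (np.log(0.01), np.log(100)),
                    (np.log(1e-4), np.log(99))],
        )
        if best is None or res.fun < best.fun:
            best = res
    t, kappa, omega = np.exp(best.x)
    rho_s, s_prop = _syn_proportions(kappa, omega, pi, code)
    dS = t * rho_s / (3.0 * s_prop)
    dN = t * (1.0 - rho_s) / (3.0 * (1.0 - s_prop))
    om = None if dS <= 1e-9 else float(dN / dS)
    return PairwiseRates(float(dN), float(dS), om, "ML", t=float(t), kappa=float(kappa))


# -- Nei-Gojobori 1986 -------------------------------------------------------

_NUCS = "ACGT"


def _ng86_site_counts(codon: str, code: GeneticCode) -> float:
    """Synonymous site count of one codon (out of 3)."""
    syn_sites = 0.0
    aa = code.codon_to_aa[codon]
    for pos in range(3):
        syn = tot = 0
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if code.codon_to_aa[mut] == "*":
                continue  # changes to stop codons are disregarded
            tot += 1
            if code.codon_to_aa[mut] == aa:
                syn += 1
        if tot:
            syn_sites += syn / tot
    return syn_sites


def _ng86_diff_counts(a: str, b: str, code: GeneticCode) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, pathway-averaged."""
    diff_pos = [p for p in range(3) if a[p] != b[p]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur, sd, nd, ok = a, 0, 0, True
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if code.codon_to_aa[nxt] == "*":
                ok = False
                break
            if code.codon_to_aa[nxt] == code.codon_to_aa[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:  # all pathways cross a stop: count them anyway
        for order in itertools.permutations(diff_pos):
            cur, sd, nd = a, 0, 0
            for p in order:
                nxt = cur[:p] + b[p] + cur[p + 1 :]
                if code.codon_to_aa[nxt] == code.codon_to_aa[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = float(np.mean([p[0] for p in paths]))
    nd = float(np.mean([p[1] for p in paths]))
    return sd, nd


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"proportion {p:.3f} >= 3/4: Jukes-Cantor correction diverges")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def _ng86(pairs, code) -> PairwiseRates:
    S = Sd = Nd = 0.0
    for a, b in pairs:
        S += 0.5 * (_ng86_site_counts(a, code) + _ng86_site_counts(b, code))
        sd, nd = _ng86_diff_counts(a, b, code)
        Sd += sd
        Nd += nd
    N = 3.0 * len(pairs) - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc_correct(pS) if pS > 0 else 0.0
    dN = _jc_correct(pN) if pN > 0 else 0.0
    om = None if dS <= 0 else float(dN / dS)
    return PairwiseRates(float(dN), float(dS), om, "NG86")
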