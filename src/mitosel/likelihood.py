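"""Felsenstein pruning likelihood for the branch-site mixture (Model A).

The mixture has four site classes with proportions
``(p0, p1, p2a, p2b)`` where ``p2a/p2b = p0/p1``:

    class 0 : background omega0, foreground omega0
    class 1 : background 1,      foreground 1
    class 2a: background omega0, foreground omega2
    class 2b: background 1,      foreground omega2

Foreground branches are the marked branches of the phylogeny; in the null
model omega2 is fixed at 1.  The engine compresses sites to unique
patterns, prunes all four classes in one batched pass, scales partials
per node against underflow, and exposes analytic branch-length
derivatives (inside/outside passes) used by the fitter; the few global
parameters are differentiated numerically, recomputing only the classes
they touch.

Branch lengths handled by the engine are in units of expected
substitutions per codon site at omega = 1; fitted values are converted to
mixture-averaged substitutions per site for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codon_model import (
    CodonRateModel,
    SpectralGenerator,
    build_generator,
    empirical_codon_freqs,
    substitution_rate,
    tip_partials,
)
from .seqio import CodonAlignment
from .trees import Phylogeny

N_CLASSES = 4
ALL_CLASSES = (0, 1, 2, 3)


def class_priors(p0: float, p1: float) -> np.ndarray:
    """Mixture proportions (p0, p1, p2a, p2b) of Model A."""
    if p0 < 0 or p1 < 0 or p0 + p1 > 1 + 1e-12 or p0 + p1 <= 0:
        raise ValueError("invalid site-class proportions")
    p2 = max(1.0 - p0 - p1, 0.0)
    return np.array(
        [p0, p1, p2 * p0 / (p0 + p1), p2 * p1 / (p0 + p1)], dtype=float
    )


def class_omegas(w0: float, w2: float) -> tuple[np.ndarray, np.ndarray]:
    """(background, foreground) omega per class."""
    bg = np.array([w0, 1.0, w0, 1.0])
    fg = np.array([w0, 1.0, w2, w2])
    return bg, fg


@dataclass
class ClassLikelihoods:
    """Per-class per-pattern log-likelihoods plus bookkeeping."""

    log_site: np.ndarray  # (4, n_patterns)
    pattern_weights: np.ndarray
    pattern_of_site: np.ndarray

    def mixture_lnl(self, priors: np.ndarray) -> float:
        a = np.log(np.maximum(priors, 1e-300))[:, None] + self.log_site
        m = a.max(axis=0)
        lnl_pat = m + np.log(np.exp(a - m).sum(axis=0))
        return float(self.pattern_weights @ lnl_pat)

    def with_classes(self, log_site_sub: np.ndarray, classes) -> "ClassLikelihoods":
        log_site = self.log_site.copy()
        log_site[list(classes)] = log_site_sub
        return ClassLikelihoods(log_site, self.pattern_weights, self.pattern_of_site)

    def class_posteriors(self, priors: np.ndarray) -> np.ndarray:
        """Per-site posterior over the four classes, shape (4, n_sites)."""
        a = np.log(np.maximum(priors, 1e-300))[:, None] + self.log_site
        a -= a.max(axis=0)
        w = np.exp(a)
        w /= w.sum(axis=0)
        return w[:, self.pattern_of_site]


class BranchSiteEngine:
    """Pruning likelihood engine bound to one alignment and tree."""

    def __init__(
        self,
        aln: CodonAlignment,
        phylo: Phylogeny,
        codon_freqs: np.ndarray | None = None,
        freq_scheme: str = "F3x4",
        require_foreground: bool = True,
    ):
        self.aln = aln
        self.code = aln.code
        self.tree = phylo.to_index(aln.taxa)
        if require_foreground and not self.tree.foreground.any():
            raise ValueError("no foreground branch marked on the tree")
        self.pi = (
            np.asarray(codon_freqs, dtype=float)
            if codon_freqs is not None
            else empirical_codon_freqs(aln, freq_scheme)
        )
        tips = tip_partials(aln)  # (n_taxa, n_sites, n_codons)
        keys = np.array(["|".join(aln.codons[:, j]) for j in range(aln.n_sites)])
        uniq, first, inverse, counts = np.unique(
            keys, return_index=True, return_inverse=True, return_counts=True
        )
        self.pattern_of_site = inverse
        self.pattern_weights = counts.astype(float)
        self.n_patterns = len(uniq)
        self.n_codons = tips.shape[2]
        # (n_taxa, 4, n_codons, n_patterns): class axis broadcast up front
        base = np.ascontiguousarray(tips[:, first, :].transpose(0, 2, 1))
        self.tips = np.ascontiguousarray(
            np.broadcast_to(base[:, None, :, :], (aln.n_taxa, N_CLASSES) + base.shape[1:])
        )
        self._spec_cache: dict = {}

    # -- generator handling ------------------------------------------------
    def _spec(self, kappa: float, omega: float) -> SpectralGenerator:
        key = (round(float(kappa), 14), round(float(omega), 14))
        if key not in self._spec_cache:
            if len(self._spec_cache) > 64:
                self._spec_cache.clear()
            ref = build_generator(
                CodonRateModel(kappa, 1.0, self.pi, self.code), scale=False
            )
            r1 = substitution_rate(ref, self.pi)
            Q = build_generator(
                CodonRateModel(kappa, omega, self.pi, self.code), scale=False
            )
            self._spec_cache[key] = SpectralGenerator(Q / r1, self.pi)
        return self._spec_cache[key]

    def mixture_rate_factor(self, kappa, w0, w2, p0, p1) -> float:
        """Expected substitutions per site (background mixture) per unit of
        the engine's omega=1 branch-length scale."""
        priors = class_priors(p0, p1)
        bg, _ = class_omegas(w0, w2)
        return float(
            sum(
                priors[c] * substitution_rate(self._spec(kappa, bg[c]).Q, self.pi)
                for c in range(N_CLASSES)
            )
        )

    def _omega_of(self, w0, w2, classes) -> np.ndarray:
        """omega per (class, node) given the foreground marks."""
        bg, fg = class_omegas(w0, w2)
        T = self.tree
        out = np.empty((len(classes), T.n_nodes))
        for k, c in enumerate(classes):
            out[k] = np.where(self.tree.foreground, fg[c], bg[c])
        return out

    def _matrices(self, kappa, w0, w2, lengths, classes, derivs: bool = False):
        """Stacked transition matrices P (nc, n_nodes, n, n) (+ dP/dt)."""
        omega_of = self._omega_of(w0, w2, classes)
        return self._matrices_for(kappa, omega_of, lengths, derivs)

    def _matrices_for(self, kappa, omega_of, lengths, derivs: bool = False):
        T = self.tree
        nc = len(omega_of)
        P = np.empty((nc, T.n_nodes, self.n_codons, self.n_codons))
        dP = np.empty_like(P) if derivs else None
        cache: dict = {}
        for k in range(nc):
            for v in range(T.n_nodes - 1):
                key = (omega_of[k, v], lengths[v])
                if key not in cache:
                    spec = self._spec(kappa, omega_of[k, v])
                    Pm = spec.transition_matrix(lengths[v])
                    Dm = spec.dP_dt(lengths[v]) if derivs else None
                    cache[key] = (Pm, Dm)
                P[k, v], Dm = cache[key][0], cache[key][1]
                if derivs:
                    dP[k, v] = Dm
        return P, dP

    # -- likelihood --------------------------------------------------------
    def _prune(self, P: np.ndarray, nc: int):
        """Batched postorder pass over all classes at once."""
        T = self.tree
        partial: list = [None] * T.n_nodes
        message: list = [None] * T.n_nodes
        logscale = np.zeros((nc, self.n_patterns))
        for v in range(T.n_nodes):
            if T.tip_taxon[v] >= 0:
                partial[v] = self.tips[T.tip_taxon[v], :nc]
            else:
                prod = None
                for c in T.children[v]:
                    message[c] = P[:, c] @ partial[c]
                    prod = message[c] if prod is None else prod * message[c]
                m = prod.max(axis=1)
                safe = np.where(m > 0, m, 1.0)
                partial[v] = prod / safe[:, None, :]
                logscale += np.where(m > 0, np.log(safe), -np.inf)
        return partial, message, logscale

    def log_site(self, kappa, w0, w2, lengths, classes=ALL_CLASSES) -> np.ndarray:
        """Per-class per-pattern log-likelihoods for a subset of classes.

        Classes whose omega assignment coincides (e.g. 2b and 1 in the
        null model) are pruned once and expanded afterwards.
        """
        omega_of = self._omega_of(w0, w2, classes)
        uniq, inverse = np.unique(omega_of, axis=0, return_inverse=True)
        P, _ = self._matrices_for(kappa, uniq, lengths)
        partial, _, logscale = self._prune(P, len(uniq))
        site = (partial[self.tree.root] * self.pi[None, :, None]).sum(axis=1)
        with np.errstate(divide="ignore"):
            return (np.log(site) + logscale)[inverse]

    def class_logliks(self, kappa, w0, w2, lengths) -> ClassLikelihoods:
        return ClassLikelihoods(
            self.log_site(kappa, w0, w2, lengths),
            self.pattern_weights,
            self.pattern_of_site,
        )

    def lnl(self, kappa, w0, w2, p0, p1, lengths) -> float:
        return self.class_logliks(kappa, w0, w2, lengths).mixture_lnl(
            class_priors(p0, p1)
        )

    # -- likelihood + gradients -------------------------------------------
    def lnl_branch_grad(self, kappa, w0, w2, p0, p1, lengths):
        """lnL with analytic d lnL/d t_b for every branch.

        Returns ``(lnl, grad_t, class_logliks)`` where ``grad_t`` is
        indexed by node (branch above node; root entry 0).
        """
        T = self.tree
        priors = class_priors(p0, p1)
        npat = self.n_patterns
        omega_all = self._omega_of(w0, w2, ALL_CLASSES)
        uniq, inverse = np.unique(omega_all, axis=0, return_inverse=True)
        nu = len(uniq)
        P, dP = self._matrices_for(kappa, uniq, lengths, derivs=True)
        partial, message, logscale = self._prune(P, nu)
        site = (partial[T.root] * self.pi[None, :, None]).sum(axis=1)
        with np.errstate(divide="ignore"):
            log_site = np.log(site) + logscale
        safe_site = np.where(site > 0, site, 1.0)

        ratio = np.zeros((nu, T.n_nodes, npat))
        outside: list = [None] * T.n_nodes
        outside[T.root] = np.broadcast_to(
            self.pi[None, :, None], (nu, self.n_codons, npat)
        )
        for u in range(T.n_nodes - 1, -1, -1):
            kids = T.children[u]
            if not kids:
                continue
            prod = None
            for v in kids:
                prod = message[v] if prod is None else prod * message[v]
            m = prod.max(axis=1)
            scale_u = np.where(m > 0, m, 1.0)
            for v in kids:
                up = np.array(outside[u], copy=True)
                for s in kids:
                    if s is not v:
                        up *= message[s]
                up /= scale_u[:, None, :]
                dsite = (up * (dP[:, v] @ partial[v])).sum(axis=1)
                ratio[:, v] = dsite / safe_site
                outside[v] = np.matmul(P[:, v].transpose(0, 2, 1), up)

        cl = ClassLikelihoods(
            log_site[inverse], self.pattern_weights, self.pattern_of_site
        )
        a = np.log(np.maximum(priors, 1e-300))[:, None] + log_site[inverse]
        m = a.max(axis=0)
        lnl_pat = m + np.log(np.exp(a - m).sum(axis=0))
        lnl = float(self.pattern_weights @ lnl_pat)
        W = np.exp(a - lnl_pat)  # (4, npat) class responsibilities
        # fold duplicate classes onto their shared pruning pass
        Wu = np.zeros((nu, npat))
        for c in range(N_CLASSES):
            Wu[inverse[c]] += W[c]
        grad_t = (Wu[:, None, :] * ratio).sum(axis=0) @ self.pattern_weights
        return lnl, grad_t, cl


def log_likelihood(aln: CodonAlignment, phylo: Phylogeny, fit) -> float:
    """Model A mixture log-likelihood at given parameter values.

    ``fit`` is any object with attributes kappa, omega0, omega2, p0, p1 and
    ``branch_lengths_internal`` (engine-scale lengths per postorder node).
    """
    engine = BranchSiteEngine(aln, phylo, codon_freqs=getattr(fit, "codon_freqs", None))
    return engine.lnl(
        fit.kappa, fit.omega0, fit.omega2, fit.p0, fit.p1, fit.branch_lengths_internal
    )
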