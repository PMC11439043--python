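"""Independent test oracles, deliberately sharing no code with the engine.

The enumeration oracle computes the Model A mixture likelihood by summing
over every assignment of codon states to internal nodes, using transition
matrices obtained from scipy's expm — not from the engine's spectral path.
"""

import itertools

import numpy as np
from scipy.linalg import expm

from mitosel.codon_model import CodonRateModel, _code_structure, build_generator
from mitosel.likelihood import class_omegas, class_priors


def enumeration_lnl(aln, tree_index, kappa, w0, w2, p0, p1, lengths, pi):
    """Mixture lnL by exhaustive enumeration of internal-node states."""
    s = _code_structure(aln.code.table_id)
    idx, n = s["index"], s["n"]
    code = aln.code
    T = tree_index
    ref = build_generator(CodonRateModel(kappa, 1.0, pi, code), scale=False)
    r1 = -(pi * np.diag(ref)).sum()
    bg, fg = class_omegas(w0, w2)
    priors = class_priors(p0, p1)
    P = {}
    for w in set(np.concatenate([bg, fg])):
        Q = build_generator(CodonRateModel(kappa, w, pi, code), scale=False) / r1
        for v in range(T.n_nodes - 1):
            P[(w, v)] = expm(Q * lengths[v])
    internal = [v for v in range(T.n_nodes) if T.tip_taxon[v] < 0]
    tips = [v for v in range(T.n_nodes) if T.tip_taxon[v] >= 0]
    lnl = 0.0
    for site in range(aln.n_sites):
        tipstate = {v: idx[aln.codons[T.tip_taxon[v], site]] for v in tips}
        site_lik = 0.0
        for c in range(4):
            omega_v = [
                (fg[c] if T.foreground[v] else bg[c]) for v in range(T.n_nodes)
            ]
            lik = 0.0
            for assign in itertools.product(range(n), repeat=len(internal)):
                st = dict(zip(internal, assign))
                st.update(tipstate)
                p = pi[st[T.n_nodes - 1]]
                for v in range(T.n_nodes - 1):
                    p *= P[(omega_v[v], v)][st[T.parent[v]], st[v]]
                lik += p
            site_lik += priors[c] * lik
        lnl += np.log(site_lik)
    return lnl


def fitch_candidates_bruteforce(tree_adj, root, leaf_states, alphabet):
    """States at ``root`` attaining the minimum parsimony score, by explicit
    enumeration of all internal-node labelings of a rooted tree.

    ``tree_adj`` maps node id -> list of children; leaves carry states.
    """
    nodes = []

    def collect(v):
        nodes.append(v)
        for c in tree_adj.get(v, []):
            collect(c)

    collect(root)
    internal = [v for v in nodes if tree_adj.get(v)]
    best: dict[str, int] = {}
    for assign in itertools.product(alphabet, repeat=len(internal)):
        labels = dict(zip(internal, assign))
        labels.update(leaf_states)
        score = sum(
            labels[v] != labels[c] for v in internal for c in tree_adj[v]
        )
        r = labels[root]
        if r not in best or score < best[r]:
            best[r] = score
    overall = min(best.values())
    return {state for state, score in best.items() if score == overall}
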