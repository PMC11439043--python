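"""Fixed derived nonsynonymous substitution (FdNs) scanning.

A site carries an FdNs for a designated clade when every clade member
shares one amino acid, that amino acid is derived (it differs from every
candidate ancestral state reconstructed from the outgroups), and — at the
codon level — the change is attributable to a single nucleotide
substitution.  Convergent recurrence of the derived state in a distant
outgroup does not by itself disqualify a site (fixation and derivedness
are what define the event); strict outgroup exclusivity is available as
an option.

Ancestral states are reconstructed by Fitch parsimony over the outgroup
part of the tree, evaluated at the clade's attachment point.  Ambiguous
reconstructions are first intersected with the Fitch set of the clade's
sister lineage, then resolved by frequency among observed outgroup states
(alphabetical as the final tie-break); the full candidate set and an
ambiguity flag are retained on every record.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .seqio import CodonAlignment
from .trees import Phylogeny, TreeNode

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

CHEMICAL_CLASSES = {
    **{a: "nonpolar" for a in "GAVLIPFMW"},
    **{a: "polar" for a in "STCYNQ"},
    **{a: "positive" for a in "KRH"},
    **{a: "negative" for a in "DE"},
}


class FdnsError(ValueError):
    pass


@dataclass(frozen=True)
class CladeSpec:
    """A labelled foreground clade; all remaining taxa are outgroups."""

    label: str
    foreground: frozenset

    def outgroups(self, taxa) -> list[str]:
        return [t for t in taxa if t not in self.foreground]


@dataclass
class AncestralCall:
    state: str | None  # tie-broken representative, None if no information
    candidates: frozenset
    ambiguous: bool


def _fitch2(a: frozenset, b: frozenset) -> frozenset:
    inter = a & b
    return inter if inter else a | b


_WILD = frozenset(AA20)


def infer_ancestral_aa(
    column: dict[str, str], clade: CladeSpec, phylo: Phylogeny
) -> AncestralCall:
    """Outgroup-parsimony ancestral amino acid at a clade's attachment.

    ``column`` maps every taxon to its amino acid ('-' or 'X' treated as
    missing; missing is tolerated only in outgroups).  Raises
    :class:`FdnsError` when no ungapped outgroup remains.
    """
    fg = set(clade.foreground)
    mrca = phylo.mrca(fg)
    if phylo.clade_leaves(mrca) != fg:
        raise FdnsError(f"clade {clade.label} is not monophyletic on the tree")

    def leaf_set(label: str) -> frozenset:
        aa = column.get(label, "-").upper()
        return frozenset([aa]) if aa in AA20 else _WILD

    observed = [
        column[t].upper()
        for t in clade.outgroups(phylo.leaf_labels())
        if column.get(t, "-").upper() in AA20
    ]
    if not observed:
        raise FdnsError("all outgroups are gapped: no ancestral information")

    def down(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return leaf_set(node.label)
        out = None
        for c in node.children:
            s = down(c)
            out = s if out is None else _fitch2(out, s)
        return out

    # up-sets: Fitch set of everything outside each node's subtree
    parent_of: dict[int, TreeNode] = {}
    for node in phylo.postorder():
        for c in node.children:
            parent_of[id(c)] = node
    down_cache: dict[int, frozenset] = {}

    def down_c(node) -> frozenset:
        if id(node) not in down_cache:
            down_cache[id(node)] = down(node)
        return down_cache[id(node)]

    def up(node: TreeNode) -> frozenset | None:
        if id(node) not in parent_of:
            return None
        parent = parent_of[id(node)]
        pieces = [down_c(s) for s in parent.children if s is not node]
        u = up(parent)
        if u is not None:
            pieces.append(u)
        out = None
        for s in pieces:
            out = s if out is None else _fitch2(out, s)
        return out if out is not None else _WILD

    attach = parent_of.get(id(mrca))
    if attach is None:
        raise FdnsError("foreground clade spans the whole tree")
    sisters = [down_c(s) for s in attach.children if s is not mrca]
    pieces = list(sisters)
    u = up(attach)
    if u is not None:
        pieces.append(u)
    candidates = None
    for s in pieces:
        candidates = s if candidates is None else _fitch2(candidates, s)
    candidates = frozenset(candidates) & frozenset(observed) or frozenset(candidates)

    ambiguous = len(candidates) > 1
    resolved = candidates
    if ambiguous and sisters:
        sister_all = None
        for s in sisters:
            sister_all = s if sister_all is None else _fitch2(sister_all, s)
        inter = resolved & sister_all
        if inter:
            resolved = inter
    freq = Counter(observed)
    state = max(resolved, key=lambda a: (freq.get(a, 0), -ord(a)))
    return AncestralCall(state=state, candidates=frozenset(candidates), ambiguous=ambiguous)


@dataclass
class FdNsRecord:
    """One clade-fixed derived nonsynonymous substitution."""

    site: int  # 1-based codon site in the analysis alignment
    branch: str
    ancestral_aa: str
    derived_aa: str
    chemistry: tuple[str, str]
    polarity_crossing: bool
    ambiguous_ancestral: bool = False
    ancestral_candidates: frozenset = field(default_factory=frozenset)
    single_snp: bool | None = None
    syn_variation: bool | None = None
    gene: str = ""
    comparator_site: int | None = None

    def __post_init__(self):
        if self.ancestral_aa == self.derived_aa:
            raise FdnsError("ancestral and derived amino acids must differ")


def classify_chemistry(ancestral_aa: str, derived_aa: str) -> tuple[tuple[str, str], bool]:
    """Chemical-class pair and polarity-crossing flag for a substitution.

    Classes: nonpolar {G,A,V,L,I,P,F,M,W}, polar {S,T,C,Y,N,Q}, positive
    {K,R,H}, negative {D,E}.  A substitution crosses polarity iff exactly
    one side is nonpolar.
    """
    pair = []
    for aa in (ancestral_aa.upper(), derived_aa.upper()):
        if aa not in CHEMICAL_CLASSES:
            raise FdnsError(f"nonstandard amino acid symbol {aa!r}")
        pair.append(CHEMICAL_CLASSES[aa])
    crossing = (pair[0] == "nonpolar") != (pair[1] == "nonpolar")
    return (pair[0], pair[1]), crossing


def _scan_columns(
    taxa: list[str],
    aa_of, codon_of,
    n_sites: int,
    phylo: Phylogeny,
    clade: CladeSpec,
    require_absent_in_outgroups: bool,
    gene: str,
) -> list[FdNsRecord]:
    fg_taxa = sorted(clade.foreground)
    out_taxa = clade.outgroups(taxa)
    if phylo.clade_leaves(phylo.mrca(set(fg_taxa))) != set(fg_taxa):
        raise FdnsError(f"clade {clade.label} is not monophyletic on the tree")
    records = []
    for j in range(1, n_sites + 1):
        fg_aas = {aa_of(t, j) for t in fg_taxa}
        if len(fg_aas) != 1:
            continue
        a_f = fg_aas.pop()
        if a_f not in AA20:
            continue  # foreground gap/ambiguity disqualifies the column
        column = {t: aa_of(t, j) for t in taxa}
        try:
            anc = infer_ancestral_aa(column, clade, phylo)
        except FdnsError:
            continue
        if a_f in anc.candidates:
            continue  # not unambiguously derived
        if require_absent_in_outgroups and any(
            column[t] == a_f for t in out_taxa
        ):
            continue
        single_snp = syn_var = None
        if codon_of is not None:
            fg_codons = {codon_of(t, j) for t in fg_taxa}
            anc_codons = {
                codon_of(t, j)
                for t in out_taxa
                if column[t] == anc.state
            }
            if anc_codons:
                single_snp = (
                    min(
                        sum(x != y for x, y in zip(ca, cf))
                        for ca in anc_codons
                        for cf in fg_codons
                    )
                    == 1
                )
            syn_var = len(fg_codons) > 1
        chemistry, crossing = classify_chemistry(anc.state, a_f)
        records.append(
            FdNsRecord(
                site=j,
                branch=clade.label,
                ancestral_aa=anc.state,
                derived_aa=a_f,
                chemistry=chemistry,
                polarity_crossing=crossing,
                ambiguous_ancestral=anc.ambiguous,
                ancestral_candidates=anc.candidates,
                single_snp=single_snp,
                syn_variation=syn_var,
                gene=gene,
            )
        )
    return records


def detect_fdns(
    aln: CodonAlignment,
    phylo: Phylogeny,
    clade: CladeSpec,
    require_absent_in_outgroups: bool = False,
    gene: str = "",
) -> list[FdNsRecord]:
    """Scan a codon alignment for clade-fixed derived substitutions.

    Columns with a foreground gap or irreducible ambiguity are
    disqualified (fixation cannot be asserted).  ``single_snp`` is set
    when some observed ancestral-encoding outgroup codon is one nucleotide
    from some foreground codon; ``syn_variation`` when the foreground
    codons for the fixed amino acid are not all identical.
    """
    prot = aln.to_protein()
    return _scan_columns(
        aln.taxa,
        lambda t, j: prot[t][j - 1].upper(),
        lambda t, j: aln.codons[aln.taxa.index(t), j - 1],
        aln.n_sites,
        phylo,
        clade,
        require_absent_in_outgroups,
        gene,
    )


def detect_fdns_protein(
    sequences: dict[str, str],
    phylo: Phylogeny,
    clade: CladeSpec,
    require_absent_in_outgroups: bool = False,
    gene: str = "",
) -> list[FdNsRecord]:
    """Amino-acid-level FdNs scan (codon flags left unset)."""
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise FdnsError("protein sequences have unequal lengths")
    taxa = list(sequences)
    return _scan_columns(
        taxa,
        lambda t, j: sequences[t][j - 1].upper(),
        None,
        lengths.pop(),
        phylo,
        clade,
        require_absent_in_outgroups,
        gene,
    )


def summarize_by_branch(records: list[FdNsRecord]) -> pd.DataFrame:
    """Counts per (gene, branch): total, polarity-crossing, syn-variation.

    Includes a grand-total row with branch label 'all'.
    """
    rows = [
        {
            "gene": r.gene,
            "branch": r.branch,
            "crossing": bool(r.polarity_crossing),
            "syn_variation": bool(r.syn_variation),
        }
        for r in records
    ]
    if not rows:
        return pd.DataFrame(
            [{"gene": "all", "branch": "all", "n": 0, "n_crossing": 0, "n_syn_variation": 0}]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["gene", "branch"])
        .agg(n=("crossing", "size"), n_crossing=("crossing", "sum"),
             n_syn_variation=("syn_variation", "sum"))
        .reset_index()
    )
    total = pd.DataFrame(
        [
            {
                "gene": "all",
                "branch": "all",
                "n": len(df),
                "n_crossing": int(df.crossing.sum()),
                "n_syn_variation": int(df.syn_variation.sum()),
            }
        ]
    )
    return pd.concat([out, total], ignore_index=True)


def records_to_frame(records: list[FdNsRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "branch": r.branch,
                "site": r.site,
                "comparator_site": r.comparator_site,
                "ancestral_aa": r.ancestral_aa,
                "derived_aa": r.derived_aa,
                "ancestral_candidates": "".join(sorted(r.ancestral_candidates)),
                "ambiguous_ancestral": r.ambiguous_ancestral,
                "single_snp": r.single_snp,
                "syn_variation": r.syn_variation,
                "chemistry": "-".join(r.chemistry),
                "polarity_crossing": r.polarity_crossing,
            }
            for r in records
        ]
    )
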