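"""Bundled reference datasets: the 10-taxon COX substitution panel.

The package ships (i) the curated per-site amino-acid state patterns at
the published positively selected COX1/COX2/COX3 sites for the 10-taxon
nematode/outgroup comparison panel, (ii) the corresponding species tree
(with the two Diploscapter species placed within Rhabditina, as supported
by nuclear phylogenomics), and (iii) a small synthetic example channel
annotation.  These drive the desk-scale reconstruction of the FdNs scan.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .fdns import CladeSpec
from .seqio import GeneticCode
from .structure import read_channel_annotation
from .trees import Phylogeny

TAXA10 = [
    "Bos_taurus",
    "Homo_sapiens",
    "Caenorhabditis_elegans",
    "Diploscapter_pachys",
    "Diploscapter_coronatus",
    "Bursaphelenchus_xylophilus",
    "Panagrellus_redivivus",
    "Halicephalobus_mephisto",
    "Halicephalobus_gingivalis",
    "Halicephalobus_consperatus",
]

#: Mitochondrial protein-coding gene order used for concatenation.
GENE_ORDER = [
    "COX1", "COX2", "ND3", "ND5", "ND6", "ND4L",
    "ND1", "ATP6", "ND2", "CYTB", "COX3", "ND4",
]


def _data_path(name: str):
    return resources.files("mitosel.data").joinpath(name)


def load_cox_site_patterns() -> pd.DataFrame:
    """Curated substitution-site state patterns for the 10-taxon panel."""
    with resources.as_file(_data_path("cox_site_patterns.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    bad = df[df.states.str.len() != len(TAXA10)]
    if not bad.empty:
        raise ValueError("malformed state pattern rows in bundled data")
    return df


def nematode_tree() -> Phylogeny:
    """The 10-taxon species tree underlying the panel."""
    with resources.as_file(_data_path("nematode10.nwk")) as p:
        return Phylogeny.from_file(p)


def cox_clades() -> dict[str, CladeSpec]:
    """Foreground clade definitions B, C, D on the 10-taxon tree.

    D: divergence of Tylenchina; C: diversification of Panagrolaimidae;
    B: the common Halicephalobus ancestor.
    """
    halicephalobus = {
        "Halicephalobus_mephisto",
        "Halicephalobus_gingivalis",
        "Halicephalobus_consperatus",
    }
    c = halicephalobus | {"Panagrellus_redivivus"}
    d = c | {"Bursaphelenchus_xylophilus"}
    return {
        "B": CladeSpec("B", frozenset(halicephalobus)),
        "C": CladeSpec("C", frozenset(c)),
        "D": CladeSpec("D", frozenset(d)),
    }


def patterns_to_protein(
    df: pd.DataFrame | None = None, gene: str | None = None
) -> dict[str, dict[str, str]]:
    """Per-gene protein mini-alignments built from the state patterns.

    Column k of gene g is the k-th pattern row of that gene; the
    alignment's 1-based column index corresponds to the row order (map
    back to published coordinates via the ``ref_site`` column).
    """
    df = load_cox_site_patterns() if df is None else df
    out: dict[str, dict[str, str]] = {}
    for g, sub in df.groupby("gene", sort=False):
        if gene is not None and g != gene:
            continue
        out[g] = {
            taxon: "".join(states[i] for states in sub.states)
            for i, taxon in enumerate(TAXA10)
        }
    return out


def patterns_to_codons(
    df: pd.DataFrame | None = None, table_id: int = 5
) -> dict[str, dict[str, str]]:
    """Deterministic codon back-translation of the state patterns.

    Each amino acid maps to its alphabetically first sense codon under the
    genetic code, giving valid in-frame nucleotide mini-alignments for
    exercising codon-level plumbing (the bundled data is amino-acid level,
    so codon-derived flags on these fixtures are not meaningful).
    """
    code = GeneticCode.from_table_id(table_id)
    first_codon: dict[str, str] = {}
    for codon in code.sense_codons:  # sorted, so first occurrence wins
        first_codon.setdefault(code.codon_to_aa[codon], codon)
    prot = patterns_to_protein(df)
    return {
        g: {t: "".join(first_codon[aa] for aa in seq) for t, seq in seqs.items()}
        for g, seqs in prot.items()
    }


def example_channels():
    """Small synthetic example channel annotation (template numbering)."""
    with resources.as_file(_data_path("example_channels_synthetic.tsv")) as p:
        return read_channel_annotation(p)
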