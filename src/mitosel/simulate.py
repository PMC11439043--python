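"""Synthetic data with known ground truth for every pipeline input class.

Covers: codon alignments evolved under the branch-site (Model A) mixture
on a marked tree; planted clade-fixed nonsynonymous substitutions; toy 3-D
structures with designated channel residue sets; and OCR plate time
courses with injection-response plateaus and Gaussian noise.

All generators take an explicit seed and are fully deterministic: the same
seed and configuration reproduce byte-identical outputs.  The alignment
simulator shares its rate-generator code with the inference engine
(single source of truth) and draws per-branch transitions from exp(Qt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_model import (
    CodonRateModel,
    SpectralGenerator,
    _code_structure,
    build_generator,
    substitution_rate,
)
from .likelihood import class_omegas, class_priors
from .ocr import OCRPlate
from .seqio import CodonAlignment, GeneticCode
from .structure import ChannelAnnotation, Residue, StructureModel
from .trees import Phylogeny

CLASS_NAMES = ("0", "1", "2a", "2b")

# Default fixture tree: two distant outgroups plus eight ingroup taxa with
# nested clades labelled D (5 taxa), C (4) and B (3), structurally
# mirroring the nematode panel the FdNs scan is designed for.
DEFAULT_TREE_10 = (
    "((out1:0.5,out2:0.5):0.2,(near1:0.4,(near2:0.3,near3:0.3):0.2):0.15,"
    "(d1:0.3,(c1:0.25,(b1:0.15,(b2:0.1,b3:0.1):0.08):0.1):0.12)D:0.2);"
)


@dataclass
class SimulationConfig:
    """Ground-truth regime for the branch-site alignment simulator."""

    newick: str
    n_sites: int
    seed: int
    kappa: float = 2.0
    omega0: float = 0.1
    omega2: float = 1.0
    p0: float = 0.7
    p1: float = 0.2
    table_id: int = 5
    codon_freqs: np.ndarray | str = "uniform"

    def __post_init__(self):
        class_priors(self.p0, self.p1)  # validates proportions
        if self.seed is None:
            raise ValueError("an explicit seed is mandatory")


def _resolve_freqs(cfg: SimulationConfig, n: int) -> np.ndarray:
    if isinstance(cfg.codon_freqs, str):
        if cfg.codon_freqs != "uniform":
            raise ValueError("explicit frequency vectors or 'uniform' only")
        return np.full(n, 1.0 / n)
    pi = np.asarray(cfg.codon_freqs, dtype=float)
    if pi.shape != (n,) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("codon_freqs must be a length-n simplex vector")
    return pi


def simulate_alignment(
    cfg: SimulationConfig, site_classes: np.ndarray | None = None
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve a codon alignment under Model A along a marked tree.

    Branch lengths of the input tree are expected substitutions per codon
    site under the background mixture.  Returns the alignment and the true
    per-site class labels (values '0', '1', '2a', '2b').

    ``site_classes`` optionally fixes the class of every site (array of
    the label strings above) instead of drawing them from the mixture —
    used to plant known selected sites while keeping branch-length
    scaling identical to an ordinary draw under the same config.
    """
    code = GeneticCode.from_table_id(cfg.table_id)
    s = _code_structure(cfg.table_id)
    codons, n = s["codons"], s["n"]
    pi = _resolve_freqs(cfg, n)
    phylo = Phylogeny.from_newick(cfg.newick)
    if phylo.foreground_node is None and cfg.omega2 != 1.0:
        raise ValueError("omega2 != 1 requires a foreground mark (#1) on the tree")
    taxa = phylo.leaf_labels()
    T = phylo.to_index(taxa)

    rng = np.random.default_rng(cfg.seed)
    priors = class_priors(cfg.p0, cfg.p1)
    bg, fg = class_omegas(cfg.omega0, cfg.omega2)
    # generators scaled so tree branch lengths are mixture substitutions/site
    spec = {}
    for w in set(map(float, np.concatenate([bg, fg]))):
        spec[w] = build_generator(
            CodonRateModel(cfg.kappa, w, pi, code), scale=False
        )
    mix_rate = sum(priors[c] * substitution_rate(spec[float(bg[c])], pi) for c in range(4))
    spectral = {w: SpectralGenerator(Q / mix_rate, pi) for w, Q in spec.items()}

    if site_classes is None:
        site_class = rng.choice(4, size=cfg.n_sites, p=priors)
    else:
        if len(site_classes) != cfg.n_sites:
            raise ValueError("site_classes length must equal n_sites")
        site_class = np.array([CLASS_NAMES.index(c) for c in site_classes])
    states = np.empty((T.n_nodes, cfg.n_sites), dtype=int)
    states[T.root] = rng.choice(n, size=cfg.n_sites, p=pi)
    for v in range(T.n_nodes - 2, -1, -1):  # preorder: parents first
        parent_states = states[T.parent[v]]
        out = np.empty(cfg.n_sites, dtype=int)
        for c in range(4):
            sites = np.flatnonzero(site_class == c)
            if sites.size == 0:
                continue
            w = fg[c] if T.foreground[v] else bg[c]
            P = spectral[float(w)].transition_matrix(T.lengths[v])
            P = P / P.sum(axis=1, keepdims=True)
            ps = parent_states[sites]
            for state in np.unique(ps):
                rows = sites[ps == state]
                out[rows] = rng.choice(n, size=rows.size, p=P[state])
        states[v] = out

    mat = np.empty((len(taxa), cfg.n_sites), dtype="<U3")
    codon_arr = np.array(codons)
    for v in range(T.n_nodes):
        if T.tip_taxon[v] >= 0:
            mat[T.tip_taxon[v]] = codon_arr[states[v]]
    aln = CodonAlignment(taxa=list(taxa), codons=mat, code=code)
    labels = np.array([CLASS_NAMES[c] for c in site_class])
    return aln, labels


# -- planted FdNs ------------------------------------------------------------

@dataclass
class PlantedFdns:
    """One scheduled clade-fixed derived nonsynonymous substitution."""

    site: int  # 1-based codon site
    clade_taxa: frozenset
    ancestral_codon: str
    derived_codon: str
    syn_scatter: bool = False


def plant_fdns(
    aln: CodonAlignment,
    schedule: list[PlantedFdns],
    seed: int = 0,
) -> tuple[CodonAlignment, pd.DataFrame]:
    """Overwrite scheduled columns with clade-fixed derived substitutions.

    Foreground taxa receive the derived codon (with random synonymous
    scatter when requested, guaranteeing at least two distinct codons);
    outgroup taxa receive the ancestral codon.  Returns the modified
    alignment and a truth table.
    """
    rng = np.random.default_rng(seed)
    code = aln.code
    syn_of = {}
    for codon in code.sense_codons:
        syn_of.setdefault(code.codon_to_aa[codon], []).append(codon)
    mat = aln.codons.copy()
    rows = []
    for item in schedule:
        if not 1 <= item.site <= aln.n_sites:
            raise ValueError(f"scheduled site {item.site} outside alignment")
        anc, der = item.ancestral_codon.upper(), item.derived_codon.upper()
        if anc == der:
            raise ValueError("derived codon equals ancestral codon")
        if sum(a != b for a, b in zip(anc, der)) != 1:
            raise ValueError("derived codon must be one nucleotide from ancestral")
        anc_aa, der_aa = code.codon_to_aa[anc], code.codon_to_aa[der]
        if "*" in (anc_aa, der_aa) or anc_aa == der_aa:
            raise ValueError("planted substitution must be nonsynonymous and sense")
        fg_rows = [i for i, t in enumerate(aln.taxa) if t in item.clade_taxa]
        if len(fg_rows) != len(item.clade_taxa):
            missing = set(item.clade_taxa) - set(aln.taxa)
            raise ValueError(f"clade taxa not in alignment: {sorted(missing)}")
        j = item.site - 1
        for i in range(aln.n_taxa):
            mat[i, j] = der if i in fg_rows else anc
        if item.syn_scatter and len(syn_of[der_aa]) > 1 and len(fg_rows) > 1:
            alt = [c for c in syn_of[der_aa] if c != der]
            mat[fg_rows[-1], j] = alt[rng.integers(len(alt))]
        rows.append(
            {
                "site": item.site,
                "ancestral_aa": anc_aa,
                "derived_aa": der_aa,
                "ancestral_codon": anc,
                "derived_codon": der,
                "clade": ",".join(sorted(item.clade_taxa)),
                "syn_scatter": item.syn_scatter,
            }
        )
    out = CodonAlignment(list(aln.taxa), mat, code, dict(aln.gene_ranges))
    return out, pd.DataFrame(rows)


# -- toy structures ----------------------------------------------------------

def toy_structure(
    n_residues: int,
    geometry: str = "helix",
    channel_residues: dict[str, list[int]] | None = None,
    seed: int = 0,
    chain: str = "A",
) -> tuple[StructureModel, dict[str, ChannelAnnotation], dict]:
    """Synthetic single-chain structure with designated channel residues.

    ``geometry``: "helix" (ideal alpha-helix CA trace, 1.5 A rise, 100 deg
    twist) or "coil" (self-avoiding-ish random walk, 3.8 A steps).  Each
    residue carries CA and a pseudo-CB heavy atom.  Returns the model, the
    channel annotations (query frame) and, as ground truth, the minimum
    heavy-atom distance from every residue to each channel computed by a
    plain exhaustive loop.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    if geometry == "helix":
        i = np.arange(n_residues)
        theta = np.deg2rad(100.0) * i
        ca = np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i], axis=1)
    elif geometry == "coil":
        steps = rng.normal(size=(n_residues - 1, 3))
        steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
        ca = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    aas = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n_residues)
    residues = []
    for k in range(n_residues):
        offset = rng.normal(size=3)
        offset = 1.5 * offset / np.linalg.norm(offset)
        residues.append(
            Residue(
                number=k + 1,
                aa=str(aas[k]),
                atoms={"CA": ca[k], "CB": ca[k] + offset},
            )
        )
    model = StructureModel(chains={chain: residues}, name="toy")
    if channel_residues is None:
        members = sorted(rng.choice(n_residues, size=min(3, n_residues), replace=False) + 1)
        channel_residues = {"H": [int(m) for m in members]}
    channels = {
        name: ChannelAnnotation(name, [(chain, r) for r in nums], frame="query")
        for name, nums in channel_residues.items()
    }
    truth: dict = {}
    for k in range(n_residues):
        truth[k + 1] = {}
        for name, nums in channel_residues.items():
            best = np.inf
            for m in nums:
                for xa in residues[k].atoms.values():
                    for xb in residues[m - 1].atoms.values():
                        d = float(np.sqrt(((xa - xb) ** 2).sum()))
                        best = min(best, d)
            truth[k + 1][name] = best
    return model, channels, truth


# -- OCR plates --------------------------------------------------------------

@dataclass
class OCRWellSpec:
    well: str
    group: str  # FCCP | DMSO | background
    worms: int
    plateaus: tuple[float, float, float]  # untreated, post-injection-1, post-azide


@dataclass
class OCRPlateConfig:
    wells: list[OCRWellSpec]
    sigma: float = 0.0
    seed: int = 0
    n_cycles: int = 32
    injections: tuple[int, int] = (8, 28)
    background_level: float = 0.0

    @classmethod
    def default(
        cls,
        dmso_plateaus=(20.0, 18.0, 4.0),
        fccp_plateaus=(20.0, 45.0, 4.0),
        worms: int = 70,
        sigma: float = 0.0,
        seed: int = 0,
        background_level: float = 2.0,
        n_replicates: int = 3,
    ) -> "OCRPlateConfig":
        """Three FCCP wells, three vehicle wells, two background wells."""
        wells = []
        for k in range(n_replicates):
            wells.append(OCRWellSpec(f"F{k + 1}", "FCCP", worms, tuple(fccp_plateaus)))
            wells.append(OCRWellSpec(f"D{k + 1}", "DMSO", worms, tuple(dmso_plateaus)))
        for k in range(2):
            lvl = background_level
            wells.append(OCRWellSpec(f"B{k + 1}", "background", 1, (lvl, lvl, lvl)))
        return cls(wells=wells, sigma=sigma, seed=seed, background_level=background_level)


def simulate_ocr_plate(cfg: OCRPlateConfig) -> tuple[OCRPlate, dict]:
    """Simulate plateau-shaped OCR traces and return the plate plus truth.

    Cycles 1..inj1 sit at the untreated plateau, inj1+1..inj2 at the
    post-injection-1 plateau, and the remainder at the post-azide plateau,
    with i.i.d. Gaussian noise of standard deviation sigma.  True metrics
    are computed arithmetically from the configured plateaus.
    """
    if any(min(w.plateaus) < 0 for w in cfg.wells):
        raise ValueError("plateau levels must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    inj1, inj2 = cfg.injections
    rows_w, rows_m = [], []
    for w in cfg.wells:
        role = "background" if w.group == "background" else "sample"
        rows_w.append({"well": w.well, "group": w.group, "worms": w.worms, "role": role})
        for cycle in range(1, cfg.n_cycles + 1):
            level = (
                w.plateaus[0]
                if cycle <= inj1
                else w.plateaus[1] if cycle <= inj2 else w.plateaus[2]
            )
            rows_m.append(
                {
                    "well": w.well,
                    "cycle": cycle,
                    "time_min": 7.0 * (cycle - 1),
                    "ocr": level + (rng.normal(0, cfg.sigma) if cfg.sigma > 0 else 0.0),
                }
            )
    plate = OCRPlate(
        wells=pd.DataFrame(rows_w),
        measurements=pd.DataFrame(rows_m),
        injections=cfg.injections,
    )
    samples = [w for w in cfg.wells if w.group != "background"]
    bg = cfg.background_level

    def norm(w, phase):
        return (w.plateaus[phase] - bg) / w.worms

    dmso = float(np.mean([norm(w, 1) for w in samples if w.group == "DMSO"]))
    fccp = float(np.mean([norm(w, 1) for w in samples if w.group == "FCCP"]))
    azide = float(np.mean([norm(w, 2) for w in samples]))
    untreated = float(np.mean([norm(w, 0) for w in samples]))
    truth = {
        "basal": dmso - azide,
        "maximal": fccp - azide,
        "spare": fccp - dmso,
        "untreated": untreated,
        "non_mitochondrial": azide,
    }
    return plate, truth
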