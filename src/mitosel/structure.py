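"""Structure mapping: residue numbering transfer, channel distances, RMSD.

Substituted residues detected at the sequence level are projected into a
3-D model, their minimum heavy-atom distance to annotated proton-channel
residue sets (H- and K-pathway) is measured, and each residue is classed
as within 4 A, within 13 A, or distal (thresholds inclusive and
configurable).  Channel annotations may be expressed in a template
structure's numbering (e.g. the bovine crystal structure) and are
projected onto the query model through a pairwise-alignment residue
mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from Bio.SeqUtils import seq1
from Bio.SVDSuperimposer import SVDSuperimposer


class StructureError(ValueError):
    pass


@dataclass
class Residue:
    number: int  # author numbering, 1-based
    aa: str  # one-letter
    atoms: dict[str, np.ndarray]  # heavy atoms only

    def coords(self) -> np.ndarray:
        return np.array(list(self.atoms.values()))


@dataclass
class StructureModel:
    chains: dict[str, list[Residue]]
    name: str = ""

    def residue(self, chain: str, number: int) -> Residue:
        for r in self.chains.get(chain, []):
            if r.number == number:
                return r
        raise KeyError(f"residue {chain}/{number} not in structure {self.name}")

    def chain_sequence(self, chain: str) -> str:
        return "".join(r.aa for r in self.chains[chain])

    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())


def _check_coordinate_fields(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise StructureError(
                            f"malformed coordinate field at line {lineno} of {path}"
                        ) from None


def read_structure(path, name: str | None = None) -> StructureModel:
    """Parse a PDB coordinate file.

    Only the first model is read; hydrogens are excluded and for
    disordered atoms the highest-occupancy altloc is kept.
    """
    _check_coordinate_fields(path)
    parser = PDBParser(QUIET=True)
    struct = parser.get_structure(name or "model", str(path))
    models = list(struct.get_models())
    if not models:
        raise StructureError(f"no coordinate records in {path}")
    chains: dict[str, list[Residue]] = {}
    for chain in models[0]:
        residues = []
        for res in chain:
            if not is_aa(res, standard=True):
                continue
            atoms = {}
            for atom in res:
                if atom.element in ("H", "D"):
                    continue
                # disordered atoms return their highest-occupancy child here
                atoms[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
            if atoms:
                residues.append(
                    Residue(number=res.id[1], aa=seq1(res.get_resname()), atoms=atoms)
                )
        if residues:
            chains[chain.id] = residues
    if not chains:
        raise StructureError(f"no ATOM records for standard residues in {path}")
    return StructureModel(chains=chains, name=name or str(path))


def write_structure(model: StructureModel, path) -> None:
    """Write a minimal PDB coordinate file (used for synthetic fixtures)."""
    from Bio.SeqUtils import seq3

    serial = 1
    with open(path, "w") as fh:
        for chain_id, residues in model.chains.items():
            for res in residues:
                resname = seq3(res.aa).upper()
                for aname, xyz in res.atoms.items():
                    elem = aname[0]
                    fh.write(
                        f"ATOM  {serial:5d} {aname:^4s} {resname:3s} {chain_id:1s}"
                        f"{res.number:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {elem:>2s}\n"
                    )
                    serial += 1
        fh.write("END\n")


# -- residue numbering transfer ---------------------------------------------

@dataclass
class ResidueMapping:
    """Position pairs induced by a global pairwise protein alignment.

    Positions are 1-based; the mapping is strictly increasing and
    injective in both coordinates.  Gap-aligned positions are unmapped.
    """

    pairs: list[tuple[int, int]]
    a2b: dict[int, int] = field(init=False)
    b2a: dict[int, int] = field(init=False)

    def __post_init__(self):
        self.a2b = dict(self.pairs)
        self.b2a = {b: a for a, b in self.pairs}
        cols_a = [a for a, _ in self.pairs]
        cols_b = [b for _, b in self.pairs]
        if sorted(cols_a) != cols_a or sorted(cols_b) != cols_b:
            raise ValueError("mapping is not strictly increasing")
        if len(set(cols_a)) != len(cols_a) or len(set(cols_b)) != len(cols_b):
            raise ValueError("mapping is not injective")

    @classmethod
    def from_sequences(
        cls,
        seqA: str,
        seqB: str,
        matrix: str = "BLOSUM62",
        open_gap: float = -11.0,
        extend_gap: float = -1.0,
    ) -> "ResidueMapping":
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load(matrix)
        aligner.open_gap_score = open_gap
        aligner.extend_gap_score = extend_gap
        aligner.mode = "global"
        aln = aligner.align(seqA, seqB)[0]
        pairs = []
        for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
            for k in range(a_end - a_start):
                pairs.append((a_start + k + 1, b_start + k + 1))
        return cls(pairs)


def map_residue_coordinates(
    seqA: str, seqB: str, posA: int, **aligner_kwargs
) -> int | None:
    """Map a 1-based position in sequence A to its aligned partner in B.

    Returns None when the position aligns to a gap.
    """
    if not 1 <= posA <= len(seqA):
        raise IndexError(f"position {posA} outside sequence A (length {len(seqA)})")
    mapping = ResidueMapping.from_sequences(seqA, seqB, **aligner_kwargs)
    return mapping.a2b.get(posA)


# -- channel annotation and distances ---------------------------------------

@dataclass
class ChannelAnnotation:
    """Residues lining one proton-translocation pathway."""

    pathway: str  # e.g. "H" or "K"
    members: list[tuple[str, int]]  # (chain, residue number)
    frame: str = "query"  # numbering frame: "query" or "template"

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"channel {self.pathway} has no member residues")
        if self.frame not in ("query", "template"):
            raise ValueError("frame must be 'query' or 'template'")


def read_channel_annotation(path) -> dict[str, ChannelAnnotation]:
    """Read a channel TSV with columns: pathway, chain, residue, frame."""
    groups: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("pathway\t"):
                continue
            pathway, chain, residue, frame = line.split("\t")[:4]
            g = groups.setdefault(pathway, {"members": [], "frame": frame})
            g["members"].append((chain, int(residue)))
    return {
        p: ChannelAnnotation(p, g["members"], g["frame"]) for p, g in groups.items()
    }


def project_channel(
    channel: ChannelAnnotation, mapping: ResidueMapping
) -> ChannelAnnotation:
    """Project template-numbered channel members into query numbering.

    Members whose template position aligns to a gap are dropped; an empty
    projection raises.
    """
    if channel.frame != "template":
        return channel
    members = []
    for chain, num in channel.members:
        q = mapping.a2b.get(num)
        if q is not None:
            members.append((chain, q))
    if not members:
        raise ValueError(f"no channel {channel.pathway} members map into the query")
    return ChannelAnnotation(channel.pathway, members, frame="query")


def min_channel_distance(
    structure: StructureModel,
    residue: tuple[str, int],
    channel: ChannelAnnotation,
) -> tuple[float, tuple[str, int]]:
    """Minimum heavy-atom distance (A) from a residue to any channel member.

    Returns ``(distance, nearest_member)``.  All channel members must be
    resolvable in the structure.
    """
    chain, number = residue
    target = structure.residue(chain, number)
    missing = []
    best = (np.inf, None)
    tcoords = target.coords()
    for member in channel.members:
        try:
            mres = structure.residue(*member)
        except KeyError:
            missing.append(member)
            continue
        d = np.linalg.norm(
            tcoords[:, None, :] - mres.coords()[None, :, :], axis=-1
        ).min()
        if d < best[0]:
            best = (float(d), member)
    if missing:
        raise KeyError(
            f"channel {channel.pathway} members missing from structure: {missing}"
        )
    return best


@dataclass
class ProximityRecord:
    """A residue's distances to each pathway and its proximity class."""

    residue: tuple[str, int]
    distances: dict[str, float]
    nearest: dict[str, tuple[str, int]]
    proximity_class: str  # within4 | within13 | distal
    thresholds: tuple[float, float] = (4.0, 13.0)


def classify_proximity(
    distances: dict[str, float],
    residue: tuple[str, int] = ("A", 0),
    nearest: dict[str, tuple[str, int]] | None = None,
    within4: float = 4.0,
    within13: float = 13.0,
) -> ProximityRecord:
    """Class a residue by its minimum per-pathway distance.

    Thresholds are inclusive: exactly 4.0 A is within4, exactly 13.0 A is
    within13.
    """
    for p, d in distances.items():
        if d < 0:
            raise ValueError(f"negative distance {d} for pathway {p}")
    dmin = min(distances.values())
    if dmin <= within4:
        cls = "within4"
    elif dmin <= within13:
        cls = "within13"
    else:
        cls = "distal"
    return ProximityRecord(
        residue=residue,
        distances=dict(distances),
        nearest=dict(nearest or {}),
        proximity_class=cls,
        thresholds=(within4, within13),
    )


def proximity_report(
    structure: StructureModel,
    residues: list[tuple[str, int]],
    channels: dict[str, ChannelAnnotation],
    mapping: ResidueMapping | None = None,
    within4: float = 4.0,
    within13: float = 13.0,
) -> list[ProximityRecord]:
    """Distance + proximity class of each residue against every pathway."""
    projected = {}
    for name, ch in channels.items():
        if ch.frame == "template":
            if mapping is None:
                raise ValueError("template-frame channels require a residue mapping")
            projected[name] = project_channel(ch, mapping)
        else:
            projected[name] = ch
    records = []
    for res in residues:
        dists, nearest = {}, {}
        for name, ch in projected.items():
            d, member = min_channel_distance(structure, res, ch)
            dists[name] = d
            nearest[name] = member
        records.append(
            classify_proximity(dists, res, nearest, within4=within4, within13=within13)
        )
    return records


# -- superposition -----------------------------------------------------------

def superpose_rmsd(coordsA: np.ndarray, coordsB: np.ndarray) -> float:
    """RMSD after optimal proper rigid-body superposition (Kabsch/SVD).

    Requires equal-length matched coordinate lists of at least 3
    non-collinear points; reflections are disallowed.
    """
    A = np.asarray(coordsA, dtype=float)
    B = np.asarray(coordsB, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"coordinate shapes differ: {A.shape} vs {B.shape}")
    if A.ndim != 2 or A.shape[1] != 3 or A.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    for X in (A, B):
        if np.linalg.matrix_rank(X - X.mean(axis=0), tol=1e-9) < 2:
            raise ValueError("points are collinear: rotation is underdetermined")
    sup = SVDSuperimposer()
    sup.set(A, B)
    sup.run()
    return float(sup.get_rms())
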