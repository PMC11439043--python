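"""Sequence, alignment and genome-composition I/O.

Codon alignments are the central container of the package: an in-frame
matrix of trinucleotides over a set of taxa, bound to a genetic code.
Mitochondrial protein-coding genes of nematodes use NCBI translation
table 5 (invertebrate mitochondrial: ATA=Met, AGA/AGG=Ser, TGA=Trp),
which is the package default throughout.

Coordinates are 1-based inclusive in every user-facing field; internal
indices are 0-based.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable, IUPACData
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GAP_CODON = "---"

_NUCS = "ACGT"


class AlignmentError(ValueError):
    """Raised for malformed alignments (unequal rows, duplicate taxa...)."""


class FrameError(AlignmentError):
    """Raised when sequences violate codon-frame integrity."""


def _expand_ambiguous(codon: str) -> list[str]:
    """All unambiguous ACGT codons compatible with an IUPAC codon."""
    values = IUPACData.ambiguous_dna_values
    try:
        sets = [values[c.upper()] for c in codon]
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide in codon {codon!r}") from exc
    return ["".join(p) for p in itertools.product(*sets)]


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table as an explicit 64-codon map."""

    table_id: int
    codon_to_aa: dict[str, str]  # 64 entries, '*' marks stop

    @classmethod
    def from_table_id(cls, table_id: int = 5) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        if len(mapping) != 64:
            raise ValueError(f"translation table {table_id} is not a 64-codon table")
        return cls(table_id=table_id, codon_to_aa=mapping)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa == "*"))

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa != "*"))

    def translate_codon(self, codon: str) -> str:
        """Translate one codon; ambiguity resolved when all expansions agree.

        Gap codons translate to '-'; irreducibly ambiguous codons to 'X'.
        """
        codon = codon.upper()
        if codon == GAP_CODON:
            return "-"
        if codon in self.codon_to_aa:
            return self.codon_to_aa[codon]
        aas = {self.codon_to_aa[c] for c in _expand_ambiguous(codon)}
        return aas.pop() if len(aas) == 1 else "X"

    def is_stop(self, codon: str) -> bool:
        codon = codon.upper()
        if codon in self.codon_to_aa:
            return self.codon_to_aa[codon] == "*"
        return all(self.codon_to_aa[c] == "*" for c in _expand_ambiguous(codon))


def translate(codons, code: GeneticCode) -> str:
    """Translate an in-frame codon sequence to amino acids.

    Accepts a nucleotide string (length divisible by 3) or an iterable of
    codons.  A terminal stop is tolerated and dropped; an internal stop
    raises :class:`FrameError` naming the 1-based codon site.
    """
    if isinstance(codons, str):
        if len(codons) % 3:
            raise FrameError(f"sequence length {len(codons)} not divisible by 3")
        codons = [codons[i : i + 3] for i in range(0, len(codons), 3)]
    codons = [str(c).upper() for c in codons]
    out = []
    for i, codon in enumerate(codons):
        aa = code.translate_codon(codon)
        if aa == "*":
            if i == len(codons) - 1:
                break
            raise FrameError(f"internal stop codon {codon} at codon site {i + 1}")
        out.append(aa)
    return "".join(out)


@dataclass
class CodonAlignment:
    """In-frame codon matrix [taxon x codon site] with a genetic-code binding.

    ``codons`` is a 2-D array of 3-character strings; ambiguity characters
    are preserved, gap codons are ``---``.  ``gene_ranges`` records 1-based
    inclusive codon-site ranges of concatenated genes.
    """

    taxa: list[str]
    codons: np.ndarray  # dtype <U3, shape (n_taxa, n_sites)
    code: GeneticCode
    gene_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype="<U3")
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise AlignmentError("codon matrix shape does not match taxon list")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codons[self.taxa.index(taxon)]

    def sequence(self, taxon: str) -> str:
        return "".join(self.row(taxon))

    def column(self, site: int) -> dict[str, str]:
        """Codon states at a 1-based codon site."""
        return {t: self.codons[i, site - 1] for i, t in enumerate(self.taxa)}

    def to_protein(self) -> dict[str, str]:
        """Per-taxon amino-acid sequences (gaps as '-', ambiguity as 'X')."""
        return {
            t: "".join(self.code.translate_codon(c) for c in self.codons[i])
            for i, t in enumerate(self.taxa)
        }

    def validate_frame(self, allow_terminal_stop: bool = False) -> None:
        for i, taxon in enumerate(self.taxa):
            for j, codon in enumerate(self.codons[i]):
                if codon == GAP_CODON or "-" in codon:
                    continue
                if self.code.is_stop(codon):
                    if allow_terminal_stop and j == self.n_sites - 1:
                        continue
                    raise FrameError(
                        f"in-frame stop codon {codon} in {taxon} at codon site {j + 1}"
                    )


def _to_codon_rows(records: list[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise AlignmentError(f"sequences have unequal lengths: {sorted(lengths)}")
    (length,) = lengths
    if length % 3:
        raise FrameError(f"alignment length {length} not divisible by 3")
    taxa = [name for name, _ in records]
    mat = np.array(
        [[s[i : i + 3].upper() for i in range(0, length, 3)] for _, s in records],
        dtype="<U3",
    )
    return taxa, mat


def read_codon_alignment(
    path,
    code: GeneticCode | None = None,
    strip_terminal_stops: bool = True,
) -> CodonAlignment:
    """Read an in-frame codon alignment from FASTA.

    A terminal codon column that is stop (or gap) in every taxon is stripped
    by default and the action logged, so downstream concatenation never
    carries stop columns.
    """
    code = code or GeneticCode.from_table_id(5)
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    taxa, mat = _to_codon_rows(records)
    aln = CodonAlignment(taxa=taxa, codons=mat, code=code)
    if strip_terminal_stops and aln.n_sites:
        last = aln.codons[:, -1]
        if all(c == GAP_CODON or code.is_stop(c) for c in last):
            logger.info("stripping terminal stop codon column from %s", path)
            aln = CodonAlignment(taxa, aln.codons[:, :-1], code, dict(aln.gene_ranges))
    aln.validate_frame()
    return aln


def write_codon_alignment(aln: CodonAlignment, path) -> None:
    records = [
        SeqRecord(Seq("".join(aln.codons[i])), id=t, description="")
        for i, t in enumerate(aln.taxa)
    ]
    SeqIO.write(records, str(path), "fasta")


def excise_gaps(aln: CodonAlignment) -> CodonAlignment:
    """Remove every codon column containing a gap in any taxon.

    Gaps must align to codon boundaries: a codon mixing gap and nucleotide
    characters raises :class:`FrameError`.  Column removal is
    order-preserving, so the output columns are a subsequence of the input.
    """
    keep = []
    for j in range(aln.n_sites):
        col = aln.codons[:, j]
        has_gap = False
        for i, codon in enumerate(col):
            if "-" in codon:
                if codon != GAP_CODON:
                    raise FrameError(
                        f"partial gap codon {codon!r} in {aln.taxa[i]} "
                        f"at codon site {j + 1} is not codon-aligned"
                    )
                has_gap = True
        if not has_gap:
            keep.append(j)
    return CodonAlignment(list(aln.taxa), aln.codons[:, keep], aln.code)


def concatenate_genes(
    alignments: dict[str, CodonAlignment] | list[CodonAlignment],
) -> CodonAlignment:
    """Concatenate gene alignments sharing one taxon set.

    Row order follows the first alignment; a per-gene 1-based site-range
    index is retained in ``gene_ranges``.
    """
    if isinstance(alignments, dict):
        items = list(alignments.items())
    else:
        items = [(f"gene{i + 1}", a) for i, a in enumerate(alignments)]
    if not items:
        raise AlignmentError("no alignments to concatenate")
    first = items[0][1]
    ref_taxa = list(first.taxa)
    blocks, ranges, pos = [], {}, 0
    for name, aln in items:
        missing = set(ref_taxa) ^ set(aln.taxa)
        if missing:
            raise AlignmentError(
                f"taxon set mismatch in gene {name}: {sorted(missing)}"
            )
        order = [aln.taxa.index(t) for t in ref_taxa]
        blocks.append(aln.codons[order])
        ranges[name] = (pos + 1, pos + aln.n_sites)
        pos += aln.n_sites
    return CodonAlignment(
        ref_taxa, np.concatenate(blocks, axis=1), first.code, ranges
    )


@dataclass(frozen=True)
class Feature:
    """Annotated region with 1-based inclusive coordinates."""

    name: str
    start: int
    end: int
    strand: str = "+"
    type: str = "region"


@dataclass
class GenomeRecord:
    sequence: str
    features: list[Feature] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        for f in self.features:
            if not (1 <= f.start <= f.end <= len(self.sequence)):
                raise ValueError(
                    f"feature {f.name} [{f.start},{f.end}] outside sequence bounds"
                )

    def region(self, name: str) -> str:
        for f in self.features:
            if f.name == name:
                return self.sequence[f.start - 1 : f.end]
        raise KeyError(f"unknown region {name!r}")


def read_genome(fasta_path, features_path=None, name: str | None = None) -> GenomeRecord:
    """Load a genome FASTA plus an optional feature TSV.

    The TSV carries columns ``name  start  end  strand  type`` with 1-based
    inclusive coordinates; lines starting with '#' are skipped.
    """
    recs = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not recs:
        raise ValueError(f"no FASTA records in {fasta_path}")
    rec = recs[0]
    features = []
    if features_path is not None:
        with open(features_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                fname, start, end = parts[0], int(parts[1]), int(parts[2])
                strand = parts[3] if len(parts) > 3 else "+"
                ftype = parts[4] if len(parts) > 4 else "region"
                features.append(Feature(fname, start, end, strand, ftype))
    return GenomeRecord(str(rec.seq).upper(), features, name or rec.id)


def composition_stats(rec: GenomeRecord | str, region: str | None = None) -> dict:
    """AT/GC composition of a genome or of one named annotated region.

    Percentages are computed over unambiguous A/C/G/T characters so that
    AT% + GC% = 100 exactly; ambiguous characters are counted separately.
    """
    if isinstance(rec, str):
        rec = GenomeRecord(rec.upper())
    seq = rec.region(region) if region else rec.sequence
    counts = {n: seq.count(n) for n in _NUCS}
    unamb = sum(counts.values())
    if unamb == 0:
        raise ValueError("no unambiguous nucleotides in sequence")
    at = 100.0 * (counts["A"] + counts["T"]) / unamb
    return {
        "region": region or "genome",
        "length": len(seq),
        "at_percent": at,
        "gc_percent": 100.0 - at,
        "n_ambiguous": len(seq) - unamb,
    }
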