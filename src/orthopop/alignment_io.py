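"""Reading, writing and concatenating per-gene multiple-sequence alignments.

Alignments are aligned multi-FASTA files, one file per gene, one record per
accession.  The first whitespace-delimited token of each FASTA header is the
accession identifier; the remainder of the header is ignored.

Alphabet after normalization is the six symbols ``A C G T - N``: uppercase
base calls, ``-`` for an alignment gap, ``N`` for anything missing or
ambiguous (all IUPAC ambiguity codes are folded into ``N``; ``U`` is read as
``T``).  All coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import AlignmentFormatError, EmptyDataError, InputError, MetadataError

logger = logging.getLogger(__name__)

#: valid symbols after normalization
ALPHABET = frozenset((b"A", b"C", b"G", b"T", b"-", b"N"))
BASES = (b"A", b"C", b"G", b"T")
GAP = b"-"
MISSING = b"N"

_NORMALIZE = np.full(256, ord("N"), dtype=np.uint8)
for _c in b"ACGT-":
    _NORMALIZE[_c] = _c
    _NORMALIZE[ord(chr(_c).lower())] = _c
_NORMALIZE[ord("U")] = ord("T")
_NORMALIZE[ord("u")] = ord("T")


def normalize_residues(raw: str | bytes) -> np.ndarray:
    """Map a raw sequence to the 6-symbol alphabet as a 1-D byte array."""
    if isinstance(raw, str):
        raw = raw.encode("ascii")
    arr = np.frombuffer(raw, dtype=np.uint8)
    return _NORMALIZE[arr].view("S1")


@dataclass
class GeneAlignment:
    """One gene's aligned sequences over a set of accessions.

    ``matrix`` is a (n_accessions, length) byte array over ``A C G T - N``.
    """

    gene_id: str
    accessions: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise AlignmentFormatError(f"{self.gene_id}: matrix must be 2-D")
        if self.matrix.shape[0] != len(self.accessions):
            raise AlignmentFormatError(
                f"{self.gene_id}: {len(self.accessions)} accessions but "
                f"{self.matrix.shape[0]} matrix rows"
            )
        if self.matrix.shape[1] < 1:
            raise AlignmentFormatError(f"{self.gene_id}: empty alignment")
        if len(set(self.accessions)) != len(self.accessions):
            raise MetadataError(f"{self.gene_id}: duplicate accession IDs")
        bad = set(np.unique(self.matrix).tolist()) - ALPHABET
        if bad:
            raise AlignmentFormatError(
                f"{self.gene_id}: invalid residues {sorted(bad)} (normalize first)"
            )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return self.matrix.shape[1]

    def row(self, accession: str) -> np.ndarray:
        return self.matrix[self.accessions.index(accession)]

    def subset(self, accessions: list[str]) -> "GeneAlignment":
        """Restrict to the given accessions (those present), preserving order."""
        keep = [a for a in accessions if a in self.accessions]
        idx = [self.accessions.index(a) for a in keep]
        return GeneAlignment(self.gene_id, keep, self.matrix[idx])

    def fraction_called(self, accession: str) -> float:
        """Fraction of columns that are not N for this accession."""
        return float(np.mean(self.row(accession) != MISSING))


@dataclass
class SpeciesPanel:
    """Accession -> species mapping with derived per-species accession lists."""

    species_of: dict[str, str]

    def __post_init__(self) -> None:
        if not self.species_of:
            raise MetadataError("empty sample sheet")
        by_species: dict[str, list[str]] = {}
        for acc, sp in self.species_of.items():
            by_species.setdefault(sp, []).append(acc)
        self._by_species = by_species

    @property
    def species(self) -> list[str]:
        return list(self._by_species)

    def accessions_of(self, species: str) -> list[str]:
        if species not in self._by_species:
            raise MetadataError(f"unknown species {species!r}")
        return list(self._by_species[species])

    def __contains__(self, accession: str) -> bool:
        return accession in self.species_of

    def require(self, accessions) -> None:
        missing = [a for a in accessions if a not in self.species_of]
        if missing:
            raise MetadataError(f"accessions not in sample sheet: {missing}")


@dataclass
class ConcatenatedAlignment:
    """Cross-gene concatenation with per-gene column offsets.

    ``offsets`` maps gene_id -> (start, end), 0-based half-open, contiguous in
    gene order.  Accessions missing a gene are N-filled over its span.
    """

    gene_ids: list[str]
    offsets: dict[str, tuple[int, int]]
    accessions: list[str]
    matrix: np.ndarray
    missing_gene: dict[str, set[str]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def gene_slice(self, gene_id: str) -> np.ndarray:
        s, e = self.offsets[gene_id]
        return self.matrix[:, s:e]


def read_gene_alignment(path: str | Path, gene_id: str | None = None) -> GeneAlignment:
    """Parse one aligned multi-FASTA file into a :class:`GeneAlignment`.

    Residues are normalized (uppercase, U->T, ambiguity codes -> N); gaps are
    preserved.  Raises :class:`AlignmentFormatError` on ragged records,
    :class:`MetadataError` on duplicate accession IDs, :class:`InputError` on
    an empty file.
    """
    path = Path(path)
    if gene_id is None:
        gene_id = path.stem
    names: list[str] = []
    rows: list[np.ndarray] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id.split()[0]
        if acc in names:
            raise MetadataError(f"{path}: duplicate accession {acc!r}")
        names.append(acc)
        rows.append(normalize_residues(str(rec.seq)))
    if not rows:
        raise InputError(f"{path}: no FASTA records")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentFormatError(
            f"{path}: records have unequal lengths {sorted(lengths)}"
        )
    return GeneAlignment(gene_id, names, np.vstack(rows))


def read_gene_directory(genes_dir: str | Path) -> list[GeneAlignment]:
    """Read every ``<gene_id>.fasta`` in a directory, sorted by gene id."""
    genes_dir = Path(genes_dir)
    paths = sorted(genes_dir.glob("*.fasta")) + sorted(genes_dir.glob("*.fa"))
    if not paths:
        raise InputError(f"{genes_dir}: no .fasta files found")
    return [read_gene_alignment(p) for p in paths]


def read_sample_sheet(path: str | Path) -> SpeciesPanel:
    """Read a tab-separated sample sheet with header columns accession, species."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i_acc = header.index("accession")
            i_sp = header.index("species")
        except ValueError as exc:
            raise InputError(
                f"{path}: header must contain 'accession' and 'species' columns"
            ) from exc
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            acc, sp = fields[i_acc], fields[i_sp]
            if acc in mapping and mapping[acc] != sp:
                raise MetadataError(
                    f"{path}:{lineno}: accession {acc!r} listed with conflicting "
                    f"species {mapping[acc]!r} and {sp!r}"
                )
            mapping[acc] = sp
    if not mapping:
        raise InputError(f"{path}: no data rows")
    return SpeciesPanel(mapping)


def write_sample_sheet(panel: SpeciesPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tspecies\n")
        for acc, sp in panel.species_of.items():
            fh.write(f"{acc}\t{sp}\n")


def gene_passes_presence_filter(
    gene: GeneAlignment,
    panel: SpeciesPanel,
    min_presence: int,
    min_called_fraction: float = 0.5,
) -> bool:
    """A gene is retained iff every species has >= ``min_presence`` accessions
    with >= ``min_called_fraction`` non-N columns in this gene."""
    for sp in panel.species:
        n_ok = 0
        for acc in panel.accessions_of(sp):
            if acc in gene.accessions and gene.fraction_called(acc) >= min_called_fraction:
                n_ok += 1
        if n_ok < min_presence:
            return False
    return True


def concatenate(
    genes: list[GeneAlignment],
    panel: SpeciesPanel,
    min_presence: int = 0,
    min_called_fraction: float = 0.5,
) -> ConcatenatedAlignment:
    """Concatenate gene alignments across a shared accession panel.

    Genes failing the per-species presence filter (fewer than ``min_presence``
    accessions with >= 50% non-N columns in any species) are dropped and
    logged; ``min_presence=0`` disables the filter.  Accessions absent from a
    retained gene are N-padded over its span.
    """
    if not genes:
        raise InputError("concatenate: empty gene list")
    retained = []
    for g in genes:
        if min_presence > 0 and not gene_passes_presence_filter(
            g, panel, min_presence, min_called_fraction
        ):
            logger.warning("gene %s dropped: presence filter (<%d per species)",
                           g.gene_id, min_presence)
            continue
        retained.append(g)
    if not retained:
        raise EmptyDataError("concatenate: all genes removed by the presence filter")

    accessions = sorted({a for g in retained for a in g.accessions},
                        key=lambda a: (panel.species_of.get(a, ""), a))
    total = sum(g.length for g in retained)
    matrix = np.full((len(accessions), total), MISSING, dtype="S1")
    offsets: dict[str, tuple[int, int]] = {}
    missing_gene: dict[str, set[str]] = {}
    pos = 0
    acc_index = {a: i for i, a in enumerate(accessions)}
    for g in retained:
        start, end = pos, pos + g.length
        offsets[g.gene_id] = (start, end)
        for acc, row in zip(g.accessions, g.matrix):
            matrix[acc_index[acc], start:end] = row
        absent = set(accessions) - set(g.accessions)
        if absent:
            missing_gene[g.gene_id] = absent
        pos = end
    return ConcatenatedAlignment(
        gene_ids=[g.gene_id for g in retained],
        offsets=offsets,
        accessions=accessions,
        matrix=matrix,
        missing_gene=missing_gene,
    )


def write_concatenated(aln: ConcatenatedAlignment, fasta_path: str | Path,
                       offsets_path: str | Path | None = None) -> None:
    """Write a concatenated alignment as multi-FASTA plus an offsets TSV sidecar.

    The sidecar has one row per retained gene: gene_id, start, end (0-based,
    half-open).  ``write_concatenated`` then ``read_concatenated`` round-trips.
    """
    if aln.matrix.size == 0 or not aln.gene_ids:
        raise EmptyDataError("write_concatenated: empty alignment")
    fasta_path = Path(fasta_path)
    if offsets_path is None:
        offsets_path = fasta_path.with_suffix(".offsets.tsv")
    with open(fasta_path, "w") as fh:
        for acc, row in zip(aln.accessions, aln.matrix):
            fh.write(f">{acc}\n{row.tobytes().decode('ascii')}\n")
    with open(offsets_path, "w") as fh:
        fh.write("gene_id\tstart\tend\n")
        for gid in aln.gene_ids:
            s, e = aln.offsets[gid]
            fh.write(f"{gid}\t{s}\t{e}\n")


def read_concatenated(fasta_path: str | Path,
                      offsets_path: str | Path | None = None) -> ConcatenatedAlignment:
    """Inverse of :func:`write_concatenated`."""
    fasta_path = Path(fasta_path)
    if offsets_path is None:
        offsets_path = fasta_path.with_suffix(".offsets.tsv")
    g = read_gene_alignment(fasta_path, gene_id="concat")
    gene_ids: list[str] = []
    offsets: dict[str, tuple[int, int]] = {}
    with open(offsets_path) as fh:
        fh.readline()
        for line in fh:
            gid, s, e = line.rstrip("\n").split("\t")
            gene_ids.append(gid)
            offsets[gid] = (int(s), int(e))
    return ConcatenatedAlignment(
        gene_ids=gene_ids, offsets=offsets,
        accessions=g.accessions, matrix=g.matrix,
    )


def split_concatenated(aln: ConcatenatedAlignment) -> list[GeneAlignment]:
    """Recover per-gene alignments (N-padded rows included) from a concatenation."""
    return [GeneAlignment(gid, list(aln.accessions), aln.gene_slice(gid))
            for gid in aln.gene_ids]
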