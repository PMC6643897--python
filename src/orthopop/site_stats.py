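"""Per-column classification of alignment sites, within and across species.

This is the shared substrate for the diversity, trans-specific and HKA
stages.  Conventions:

* a base is only counted when the call is in ``{A,C,G,T}`` (not gap, not N);
* a column with any gap in the focal species is excluded from that species'
  SNP statistics (indels are tallied separately, never in S);
* a site is evaluable for a species when it has >= 2 non-missing, non-gap
  calls there (a singleton sample cannot segregate);
* multiallelic sites count once toward S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import BASES, GAP, MISSING, GeneAlignment, SpeciesPanel
from .errors import MetadataError

CLASSES = ("monomorphic", "biallelic_snp", "multiallelic_snp", "indel", "missing")


@dataclass
class SiteProfile:
    """Allele bookkeeping for one alignment column.

    ``species_counts`` maps species -> {base: count} over called bases only;
    ``species_n`` maps species -> number of called (non-gap, non-N) samples;
    ``species_gaps`` maps species -> gap count.  ``classification`` describes
    the column over ALL accessions pooled.
    """

    gene_id: str
    column: int
    species_counts: dict[str, dict[bytes, int]]
    species_n: dict[str, int]
    species_gaps: dict[str, int]
    classification: str

    def pooled_counts(self) -> dict[bytes, int]:
        pooled: dict[bytes, int] = {}
        for counts in self.species_counts.values():
            for b, c in counts.items():
                pooled[b] = pooled.get(b, 0) + c
        return pooled

    def segregating_in(self, species: str) -> bool:
        """Does this column segregate within ``species`` (>=2 distinct bases,
        n>=2, no gap)?"""
        if self.species_gaps.get(species, 0) > 0:
            return False
        counts = self.species_counts.get(species, {})
        return sum(counts.values()) >= 2 and len(counts) >= 2

    def evaluable_in(self, species: str) -> bool:
        """Is this column usable for ``species`` SNP statistics (n>=2, no gap)?"""
        return (self.species_gaps.get(species, 0) == 0
                and self.species_n.get(species, 0) >= 2)


@dataclass
class SpeciesSiteTable:
    """Segregating-site summary for one species over a set of profiles."""

    species: str
    n_segregating: int  # S
    n_evaluable: int    # L
    segregating_columns: list[tuple[str, int]]

    @property
    def S(self) -> int:
        return self.n_segregating

    @property
    def L(self) -> int:
        return self.n_evaluable


def _classify_pooled(n_bases_distinct: int, n_called: int, n_gaps: int) -> str:
    if n_gaps > 0:
        return "indel"
    if n_called == 0:
        return "missing"
    if n_bases_distinct <= 1:
        return "monomorphic"
    if n_bases_distinct == 2:
        return "biallelic_snp"
    return "multiallelic_snp"


def profile_sites(aln: GeneAlignment, panel: SpeciesPanel) -> list[SiteProfile]:
    """Build one :class:`SiteProfile` per alignment column.

    Deterministic; bases are only counted for non-gap, non-N calls.  Every
    accession of ``aln`` must resolve to a species in ``panel``.
    """
    panel.require(aln.accessions)
    species_rows: dict[str, np.ndarray] = {}
    for sp in panel.species:
        idx = [i for i, a in enumerate(aln.accessions)
               if panel.species_of[a] == sp]
        if idx:
            species_rows[sp] = aln.matrix[idx]

    profiles: list[SiteProfile] = []
    # vectorized per-species per-base count matrices: species -> (4, L)
    base_counts = {
        sp: np.stack([(rows == b).sum(axis=0) for b in BASES])
        for sp, rows in species_rows.items()
    }
    gap_counts = {sp: (rows == GAP).sum(axis=0) for sp, rows in species_rows.items()}

    for col in range(aln.length):
        counts: dict[str, dict[bytes, int]] = {}
        ns: dict[str, int] = {}
        gaps: dict[str, int] = {}
        pooled_distinct = set()
        total_called = 0
        total_gaps = 0
        for sp in species_rows:
            c = {b: int(base_counts[sp][k, col])
                 for k, b in enumerate(BASES) if base_counts[sp][k, col] > 0}
            counts[sp] = c
            ns[sp] = sum(c.values())
            gaps[sp] = int(gap_counts[sp][col])
            pooled_distinct.update(c)
            total_called += ns[sp]
            total_gaps += gaps[sp]
        profiles.append(SiteProfile(
            gene_id=aln.gene_id,
            column=col,
            species_counts=counts,
            species_n=ns,
            species_gaps=gaps,
            classification=_classify_pooled(len(pooled_distinct), total_called,
                                            total_gaps),
        ))
    return profiles


def profile_gene_set(genes: list[GeneAlignment],
                     panel: SpeciesPanel) -> list[SiteProfile]:
    """Concatenate profiles over a list of genes."""
    out: list[SiteProfile] = []
    for g in genes:
        out.extend(profile_sites(g, panel))
    return out


def species_site_table(profiles: list[SiteProfile], species: str) -> SpeciesSiteTable:
    """Count evaluable sites L and segregating sites S for one species.

    L counts columns with n >= 2 called samples and no gap in the species;
    S counts the subset with >= 2 distinct bases (multiallelic counts once).
    """
    if profiles and all(species not in p.species_n for p in profiles):
        raise MetadataError(f"species {species!r} absent from profiles")
    L = 0
    seg: list[tuple[str, int]] = []
    for p in profiles:
        if not p.evaluable_in(species):
            continue
        L += 1
        if p.segregating_in(species):
            seg.append((p.gene_id, p.column))
    return SpeciesSiteTable(species, len(seg), L, seg)


def count_indel_events(aln: GeneAlignment, panel: SpeciesPanel) -> dict[str, int]:
    """Count indel events per species.

    A maximal run of consecutive gap columns in one sequence is one event;
    events are deduplicated by (species, start, end) across accessions sharing
    an identical gap run.
    """
    panel.require(aln.accessions)
    events: dict[str, set[tuple[int, int]]] = {sp: set() for sp in panel.species}
    for acc, row in zip(aln.accessions, aln.matrix):
        sp = panel.species_of[acc]
        is_gap = row == GAP
        if not is_gap.any():
            continue
        # run-length boundaries of gap stretches
        padded = np.concatenate(([False], is_gap, [False]))
        diffs = np.flatnonzero(padded[1:] != padded[:-1])
        for start, end in zip(diffs[::2], diffs[1::2]):
            events[sp].add((int(start), int(end)))
    return {sp: len(ev) for sp, ev in events.items()}


def write_site_tsv(profiles: list[SiteProfile], panel: SpeciesPanel, path) -> None:
    """Per-site dump: gene, column (1-based), species, n, alleles, class."""
    with open(path, "w") as fh:
        fh.write("gene\tcolumn\tspecies\tn\talleles\tclass\n")
        for p in profiles:
            for sp in panel.species:
                if sp not in p.species_n:
                    continue
                alleles = ",".join(
                    f"{b.decode()}:{c}" for b, c in sorted(p.species_counts[sp].items())
                )
                fh.write(f"{p.gene_id}\t{p.column + 1}\t{sp}\t{p.species_n[sp]}"
                         f"\t{alleles}\t{p.classification}\n")
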