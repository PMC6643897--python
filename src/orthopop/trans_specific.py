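"""Detection and classification of trans-specific polymorphisms.

A column qualifies for a species when that species is strictly biallelic
there (exactly two bases among >= 2 called samples, no gap); a trans-specific
locus is a column where >= 2 species qualify with the identical unordered
allele pair.  Loci are classified by allele pair with complement folding:
A/G with T/C, A/C with T/G; A/T and C/G are self-complementary.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

from .alignment_io import SpeciesPanel
from .errors import InputError
from .site_stats import SiteProfile

#: mutation classes in reporting order
MUTATION_CLASSES = ("AG_TC", "AC_TG", "AT_TA", "CG_GC")

_CLASS_OF_PAIR = {
    frozenset("AG"): ("AG_TC", True),
    frozenset("TC"): ("AG_TC", True),
    frozenset("AC"): ("AC_TG", False),
    frozenset("TG"): ("AC_TG", False),
    frozenset("AT"): ("AT_TA", False),
    frozenset("CG"): ("CG_GC", False),
}


def classify_mutation(pair: tuple[str, str]) -> tuple[str, bool]:
    """Return (mutation class, is_transition) for an unordered base pair."""
    a, b = (p.decode() if isinstance(p, bytes) else str(p) for p in pair)
    a, b = a.upper(), b.upper()
    if a == b:
        raise ValueError(f"classify_mutation: identical bases {a!r}")
    key = frozenset((a, b))
    if key not in _CLASS_OF_PAIR:
        raise ValueError(f"classify_mutation: invalid pair {a}/{b}")
    return _CLASS_OF_PAIR[key]


@dataclass
class TransSpecificLocus:
    """A column segregating for the same allele pair in >= 2 species."""

    gene_id: str
    column: int
    allele_pair: tuple[str, str]   # sorted unordered pair, e.g. ("A", "G")
    species: frozenset[str]
    mutation_class: str
    is_transition: bool

    @property
    def k(self) -> int:
        return len(self.species)


def _qualifying_pair(profile: SiteProfile, species: str) -> frozenset[str] | None:
    """The allele pair for which ``species`` qualifies at this column, if any.

    Strictly biallelic: exactly 2 distinct bases, each observed >= 1 time,
    n >= 2, no gap in the species.  A third allele disqualifies the species
    only, not the column.
    """
    if profile.species_gaps.get(species, 0) > 0:
        return None
    counts = profile.species_counts.get(species, {})
    if len(counts) != 2 or sum(counts.values()) < 2:
        return None
    return frozenset(b.decode() for b in counts)


def detect_trans_specific(profiles: list[SiteProfile],
                          panel: SpeciesPanel) -> list[TransSpecificLocus]:
    """Emit one locus per (gene, column, allele pair) shared by >= 2 species."""
    if len(panel.species) < 2:
        raise InputError("detect_trans_specific requires >= 2 species")
    loci: list[TransSpecificLocus] = []
    for p in profiles:
        by_pair: dict[frozenset[str], set[str]] = {}
        for sp in p.species_n:
            pair = _qualifying_pair(p, sp)
            if pair is not None:
                by_pair.setdefault(pair, set()).add(sp)
        for pair, species in sorted(by_pair.items(), key=lambda kv: sorted(kv[0])):
            if len(species) < 2:
                continue
            ordered = tuple(sorted(pair))
            cls, is_ts = classify_mutation(ordered)
            loci.append(TransSpecificLocus(
                gene_id=p.gene_id,
                column=p.column,
                allele_pair=ordered,
                species=frozenset(species),
                mutation_class=cls,
                is_transition=is_ts,
            ))
    return loci


@dataclass
class TransSpecificSummary:
    """Aggregate views over a locus list (per-gene, by k, by class, by pair)."""

    total: int
    per_gene: dict[str, int]
    gene_histogram: dict[int, int]        # locus count -> number of genes
    by_k: dict[int, int]                  # sharing-set size -> loci
    by_class: dict[str, int]
    by_species_pair: dict[tuple[str, str], int]
    attribution: str


def summarize_trans_specific(loci: list[TransSpecificLocus],
                             attribution: str = "combinatorial",
                             ) -> TransSpecificSummary:
    """Summary tables for a locus list.

    ``attribution`` controls the species-pair table: ``combinatorial`` credits
    a locus with sharing set of size k to all C(k,2) unordered pairs (so the
    pair-table total exceeds the locus count when any k > 2);
    ``primary`` credits only the lexicographically first pair.
    """
    if attribution not in ("combinatorial", "primary"):
        raise ValueError(f"unknown attribution {attribution!r}")
    per_gene = Counter(l.gene_id for l in loci)
    by_k = Counter(l.k for l in loci)
    by_class = Counter(l.mutation_class for l in loci)
    by_pair: Counter[tuple[str, str]] = Counter()
    for l in loci:
        pairs = itertools.combinations(sorted(l.species), 2)
        if attribution == "primary":
            pairs = itertools.islice(pairs, 1)
        for pr in pairs:
            by_pair[pr] += 1
    return TransSpecificSummary(
        total=len(loci),
        per_gene=dict(per_gene),
        gene_histogram=dict(Counter(per_gene.values())),
        by_k=dict(by_k),
        by_class={c: by_class.get(c, 0) for c in MUTATION_CLASSES},
        by_species_pair=dict(by_pair),
        attribution=attribution,
    )


def write_loci_tsv(loci: list[TransSpecificLocus], path) -> None:
    """Loci dump: gene, column (1-based), pair, k, class, species list."""
    with open(path, "w") as fh:
        fh.write("gene\tcolumn\tallele_pair\tk\tclass\ttransition\tspecies\n")
        for l in sorted(loci, key=lambda l: (l.gene_id, l.column, l.allele_pair)):
            fh.write(f"{l.gene_id}\t{l.column + 1}\t{'/'.join(l.allele_pair)}"
                     f"\t{l.k}\t{l.mutation_class}\t{int(l.is_transition)}"
                     f"\t{','.join(sorted(l.species))}\n")


def write_summary_tsvs(summary: TransSpecificSummary, prefix) -> None:
    """Write the by-k, by-class and by-species-pair tables next to ``prefix``."""
    with open(f"{prefix}.by_k.tsv", "w") as fh:
        fh.write("k\tn_loci\n")
        for k in sorted(summary.by_k):
            fh.write(f"{k}\t{summary.by_k[k]}\n")
    with open(f"{prefix}.by_class.tsv", "w") as fh:
        fh.write("class\tn_loci\n")
        for c in MUTATION_CLASSES:
            fh.write(f"{c}\t{summary.by_class.get(c, 0)}\n")
    with open(f"{prefix}.by_pair.tsv", "w") as fh:
        fh.write("species_a\tspecies_b\tn_loci\n")
        for (a, b), c in sorted(summary.by_species_pair.items()):
            fh.write(f"{a}\t{b}\t{c}\n")
        fh.write(f"# attribution={summary.attribution}; with combinatorial "
                 "attribution the column total exceeds the locus count\n")
    with open(f"{prefix}.per_gene.tsv", "w") as fh:
        fh.write("gene\tn_loci\n")
        for g in sorted(summary.per_gene):
            fh.write(f"{g}\t{summary.per_gene[g]}\n")
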