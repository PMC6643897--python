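"""Watterson's theta and nucleotide diversity pi per species over a gene set."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

from .alignment_io import GeneAlignment, SpeciesPanel
from .errors import EmptyDataError, OrthopopError
from .site_stats import SiteProfile, SpeciesSiteTable, profile_sites, species_site_table

logger = logging.getLogger(__name__)


@dataclass
class DiversityEstimate:
    """One species' diversity summary (per-bp theta and pi)."""

    species: str
    n_individuals: int
    n_genes: int
    total_length: int
    n_segregating: int
    theta: float
    pi: float


@lru_cache(maxsize=None)
def harmonic_numbers(n: int) -> tuple[float, float]:
    """Return (a_n, b_n) = (sum_{i=1}^{n-1} 1/i, sum_{i=1}^{n-1} 1/i^2).

    a_n is the Watterson normalizer; b_n enters the variance of S.
    """
    if n < 2:
        raise ValueError(f"harmonic_numbers requires n >= 2, got {n}")
    a = sum(1.0 / i for i in range(1, n))
    b = sum(1.0 / (i * i) for i in range(1, n))
    return a, b


def watterson_theta(table: SpeciesSiteTable, n_eff: int) -> float:
    """Watterson's estimator theta = S / (a_{n_eff} * L), per bp."""
    if table.L == 0:
        raise EmptyDataError(f"{table.species}: no evaluable sites")
    if n_eff < 2:
        raise ValueError(f"n_eff must be >= 2, got {n_eff}")
    a, _ = harmonic_numbers(n_eff)
    return table.S / (a * table.L)


def nucleotide_diversity_pi(profiles: list[SiteProfile], species: str) -> float:
    """Nucleotide diversity per bp from per-site unbiased heterozygosity.

    For each evaluable site with allele counts {c_a}, n = sum c_a:
    h = n/(n-1) * (1 - sum (c_a/n)^2); pi = sum h / L over the L evaluable
    sites.  With complete data this equals the mean pairwise difference per
    site.  Site-specific n handles missing data without dropping columns.
    """
    total_h = 0.0
    L = 0
    for p in profiles:
        if not p.evaluable_in(species):
            continue
        L += 1
        counts = p.species_counts[species]
        n = sum(counts.values())
        sumsq = sum((c / n) ** 2 for c in counts.values())
        total_h += (n / (n - 1)) * (1.0 - sumsq)
    if L == 0:
        raise EmptyDataError(f"{species}: no evaluable sites for pi")
    return total_h / L


def gene_counted_for_species(gene: GeneAlignment, panel: SpeciesPanel,
                             species: str, min_called_fraction: float = 0.5) -> bool:
    """A gene counts for a species if >= 2 of its accessions are present with
    >= 50% non-missing columns."""
    n_ok = sum(
        1 for acc in panel.accessions_of(species)
        if acc in gene.accessions
        and gene.fraction_called(acc) >= min_called_fraction
    )
    return n_ok >= 2


def diversity_report(genes: list[GeneAlignment], panel: SpeciesPanel,
                     per_site_n: bool = False) -> list[DiversityEstimate]:
    """One diversity row per species, pooling S and L over the genes counted
    for that species.

    By default a_n uses the species' nominal accession count (single reported
    n); ``per_site_n=True`` instead uses the mean per-site sample size,
    rounded, for a_n.  Species with < 2 accessions are skipped with a warning.
    """
    rows: list[DiversityEstimate] = []
    for sp in panel.species:
        accs = panel.accessions_of(sp)
        if len(accs) < 2:
            logger.warning("species %s skipped: <2 accessions", sp)
            continue
        used = [g for g in genes if gene_counted_for_species(g, panel, sp)]
        if not used:
            logger.warning("species %s skipped: no genes pass inclusion", sp)
            continue
        profiles: list[SiteProfile] = []
        for g in used:
            profiles.extend(profile_sites(g.subset(accs), panel))
        table = species_site_table(profiles, sp)
        if table.L == 0:
            logger.warning("species %s skipped: no evaluable sites", sp)
            continue
        if per_site_n:
            ns = [p.species_n[sp] for p in profiles if p.evaluable_in(sp)]
            n_eff = max(2, round(sum(ns) / len(ns)))
        else:
            n_eff = len(accs)
        theta = watterson_theta(table, n_eff)
        pi = nucleotide_diversity_pi(profiles, sp)
        rows.append(DiversityEstimate(
            species=sp,
            n_individuals=len(accs),
            n_genes=len(used),
            total_length=table.L,
            n_segregating=table.S,
            theta=theta,
            pi=pi,
        ))
    if not rows:
        raise OrthopopError("diversity_report: no species with usable data")
    return rows


def write_diversity_tsv(rows: list[DiversityEstimate], path) -> None:
    """TSV mirroring the per-species diversity table (4-decimal theta/pi)."""
    with open(path, "w") as fh:
        fh.write("species\tn_individuals\tn_genes\ttotal_length_bp\tn_snps"
                 "\ttheta\tpi\n")
        for r in rows:
            fh.write(f"{r.species}\t{r.n_individuals}\t{r.n_genes}"
                     f"\t{r.total_length}\t{r.n_segregating}"
                     f"\t{r.theta:.4f}\t{r.pi:.4f}\n")
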