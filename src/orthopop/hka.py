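"""Two-species multilocus HKA test of neutral evolution.

For loci i = 1..L with within-species segregating-site counts S_A_i, S_B_i
and between-species divergence D_i (mean pairwise difference count), the
neutral model has per-locus scale parameters theta_i, a relative population
size f for species B, and a scaled divergence time T, with moments

    E[S_A_i] = theta_i * a(n_A_i)        Var = E + theta_i^2        * b(n_A_i)
    E[S_B_i] = f * theta_i * a(n_B_i)    Var = E + (f*theta_i)^2    * b(n_B_i)
    E[D_i]   = theta_i * (T + (1+f)/2)   Var = E + (theta_i*(1+f)/2)^2

where (a, b) are the partial harmonic sums of :func:`~orthopop.diversity.
harmonic_numbers`.  Parameters solve the moment equations; the goodness-of-
fit statistic is the sum of 3L standardized squared deviations, referred to
chi-square with 2L - 2 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alignment_io import GeneAlignment, SpeciesPanel
from .errors import ConvergenceError, InsufficientDataError
from .diversity import harmonic_numbers
from .site_stats import profile_sites, species_site_table

logger = logging.getLogger(__name__)


@dataclass
class HKALocus:
    """Observations for one locus."""

    gene_id: str
    S_A: float
    S_B: float
    D: float
    L: int          # compared sites
    n_A: int
    n_B: int


@dataclass
class HKAInput:
    species_a: str
    species_b: str
    loci: list[HKALocus]
    dropped: dict[str, str] = field(default_factory=dict)  # gene -> reason


@dataclass
class HKAFit:
    """Fitted HKA parameters and goodness of fit."""

    input: HKAInput
    theta: np.ndarray        # per-locus theta_i (locus scale, not per bp)
    f: float
    T: float
    components: np.ndarray   # per-locus X^2 contribution (3 terms summed)
    x2: float
    df: int
    p_value: float
    n_iter: int


def _mean_pairwise_divergence(gene: GeneAlignment, accs_a, accs_b) -> tuple[float, int]:
    """Mean cross-species pairwise difference count with pairwise deletion,
    and the number of columns where both species have >= 1 called base."""
    from .alignment_io import BASES
    rows = {a: gene.matrix[gene.accessions.index(a)] for a in accs_a + accs_b}
    called = {a: np.isin(rows[a], BASES) for a in rows}
    any_a = np.zeros(gene.length, dtype=bool)
    any_b = np.zeros(gene.length, dtype=bool)
    for a in accs_a:
        any_a |= called[a]
    for b in accs_b:
        any_b |= called[b]
    shared = int((any_a & any_b).sum())
    diffs = []
    for a in accs_a:
        for b in accs_b:
            both = called[a] & called[b]
            if both.any():
                diffs.append(int((rows[a][both] != rows[b][both]).sum()))
    if not diffs:
        return 0.0, 0
    return float(np.mean(diffs)), shared


def build_hka_input(genes: list[GeneAlignment], panel: SpeciesPanel,
                    species_a: str, species_b: str,
                    min_called_fraction: float = 0.5) -> HKAInput:
    """Per-gene HKA observations for one species pair.

    A gene is dropped (and logged with a reason) when either species has < 2
    accessions with >= ``min_called_fraction`` called sites, when there are no
    comparable sites, or when it carries no information (both species
    monomorphic and D = 0).
    """
    loci: list[HKALocus] = []
    dropped: dict[str, str] = {}
    for gene in genes:
        use: dict[str, list[str]] = {}
        for sp in (species_a, species_b):
            use[sp] = [acc for acc in panel.accessions_of(sp)
                       if acc in gene.accessions
                       and gene.fraction_called(acc) >= min_called_fraction]
        if len(use[species_a]) < 2 or len(use[species_b]) < 2:
            dropped[gene.gene_id] = "fewer than 2 evaluable accessions in a species"
            continue
        sub_a = gene.subset(use[species_a])
        sub_b = gene.subset(use[species_b])
        S_A = species_site_table(profile_sites(sub_a, panel), species_a).S
        S_B = species_site_table(profile_sites(sub_b, panel), species_b).S
        D, shared = _mean_pairwise_divergence(gene, use[species_a], use[species_b])
        if shared == 0:
            dropped[gene.gene_id] = "no comparable sites between species"
            continue
        if S_A == 0 and S_B == 0 and D == 0.0:
            dropped[gene.gene_id] = "zero information (monomorphic, D=0)"
            continue
        loci.append(HKALocus(gene.gene_id, float(S_A), float(S_B), D, shared,
                             len(use[species_a]), len(use[species_b])))
    for gid, why in dropped.items():
        logger.info("hka %s/%s: gene %s dropped: %s",
                    species_a, species_b, gid, why)
    if len(loci) < 2:
        raise InsufficientDataError(
            f"HKA {species_a}/{species_b}: only {len(loci)} usable loci (need >= 2)")
    return HKAInput(species_a, species_b, loci, dropped)


def fit_hka(inp: HKAInput, tol: float = 1e-10, max_iter: int = 10_000) -> HKAFit:
    """Solve the HKA moment equations by fixed-point iteration.

    Iteration: given (f, T), theta_i = (S_A_i + S_B_i + D_i) / (a_A_i +
    f*a_B_i + T + (1+f)/2); given theta, f = sum S_B / sum theta_i a_B_i and
    T = sum D / sum theta - (1+f)/2.  f is initialized from the ratio of
    summed per-locus polymorphism.  At the fixed point all three aggregate
    estimating equations hold (the per-locus equations imply the S_A one).
    """
    loci = inp.loci
    L = len(loci)
    if L < 2:
        raise InsufficientDataError("fit_hka requires >= 2 loci")
    S_A = np.array([l.S_A for l in loci])
    S_B = np.array([l.S_B for l in loci])
    D = np.array([l.D for l in loci])
    a_A = np.array([harmonic_numbers(l.n_A)[0] for l in loci])
    b_A = np.array([harmonic_numbers(l.n_A)[1] for l in loci])
    a_B = np.array([harmonic_numbers(l.n_B)[0] for l in loci])
    b_B = np.array([harmonic_numbers(l.n_B)[1] for l in loci])
    total = S_A + S_B + D

    if total.sum() == 0:
        raise InsufficientDataError("fit_hka: degenerate data, all observations zero")

    poly_a = float((S_A / a_A).sum())
    poly_b = float((S_B / a_B).sum())
    if poly_a == 0.0:
        raise InsufficientDataError("fit_hka: species A shows no polymorphism at any locus")
    f = max(poly_b / poly_a, 1e-8)
    theta0 = np.maximum(S_A / a_A, total / (a_A + f * a_B + 1.0))
    T = max(float(D.sum()) / float(theta0.sum()) - (1.0 + f) / 2.0, 1e-8)

    theta = theta0
    last = (f, T, theta)
    for it in range(1, max_iter + 1):
        denom = a_A + f * a_B + T + (1.0 + f) / 2.0
        if np.any(denom <= 0):
            raise ConvergenceError("fit_hka: non-positive denominator",
                                   last_iterate=last)
        theta_new = total / denom
        sum_theta = float(theta_new.sum())
        if sum_theta <= 0:
            raise InsufficientDataError("fit_hka: sum of theta collapsed to zero")
        f_new = float(S_B.sum()) / float((theta_new * a_B).sum())
        T_new = float(D.sum()) / sum_theta - (1.0 + f_new) / 2.0
        delta = max(
            abs(f_new - f) / max(abs(f), 1e-12),
            abs(T_new - T) / max(abs(T), 1e-12),
            float(np.max(np.abs(theta_new - theta) / np.maximum(np.abs(theta), 1e-12))),
        )
        f, T, theta = f_new, T_new, theta_new
        last = (f, T, theta)
        if delta < tol:
            # also require the aggregate estimating equations themselves to
            # hold tightly (absolute, in count units)
            resid = max(
                abs(float(S_A.sum()) - float((theta * a_A).sum())),
                abs(float(S_B.sum()) - f * float((theta * a_B).sum())),
                abs(float(D.sum()) - (T + (1.0 + f) / 2.0) * float(theta.sum())),
            )
            if resid < 1e-9:
                break
    else:
        raise ConvergenceError(
            f"fit_hka: no convergence after {max_iter} iterations", last_iterate=last)

    e_SA = theta * a_A
    v_SA = e_SA + theta ** 2 * b_A
    e_SB = f * theta * a_B
    v_SB = e_SB + (f * theta) ** 2 * b_B
    e_D = theta * (T + (1.0 + f) / 2.0)
    v_D = e_D + (theta * (1.0 + f) / 2.0) ** 2

    comp = ((S_A - e_SA) ** 2 / v_SA
            + (S_B - e_SB) ** 2 / v_SB
            + (D - e_D) ** 2 / v_D)
    x2 = float(comp.sum())
    df = 2 * L - 2
    p = float(stats.chi2.sf(x2, df))
    return HKAFit(inp, theta, f, T, comp, x2, df, p, it)


@dataclass
class HKAReport:
    rows: list[dict]
    summary: list[dict]
    n_components: int
    n_flagged: int
    flagged_fraction: float


def hka_report(fits: dict[tuple[str, str], HKAFit], alpha: float = 0.05) -> HKAReport:
    """Tabulate fits; flag per-locus components exceeding the chi-square(1)
    quantile at ``alpha`` (per-gene significance proxy)."""
    if not fits:
        raise InsufficientDataError("hka_report: no fits")
    crit = float(stats.chi2.ppf(1.0 - alpha, df=1))
    rows, summary = [], []
    n_flag = 0
    n_comp = 0
    for (sa, sb), fit in fits.items():
        for locus, theta_i, comp in zip(fit.input.loci, fit.theta, fit.components):
            flagged = bool(comp > crit)
            n_flag += flagged
            n_comp += 1
            rows.append({
                "species_pair": f"{sa}/{sb}", "gene": locus.gene_id,
                "S_A": locus.S_A, "S_B": locus.S_B, "D": round(locus.D, 4),
                "L": locus.L, "n_A": locus.n_A, "n_B": locus.n_B,
                "theta_hat": round(float(theta_i), 6),
                "component": round(float(comp), 6), "flag": int(flagged),
            })
        summary.append({
            "species_pair": f"{sa}/{sb}", "n_loci": len(fit.input.loci),
            "X2": round(fit.x2, 6), "df": fit.df, "p_value": round(fit.p_value, 6),
            "f_hat": round(fit.f, 6), "T_hat": round(fit.T, 6),
        })
    return HKAReport(rows, summary, n_comp, n_flag,
                     n_flag / n_comp if n_comp else 0.0)


def write_hka_tsvs(report: HKAReport, prefix) -> None:
    with open(f"{prefix}.loci.tsv", "w") as fh:
        cols = ["species_pair", "gene", "S_A", "S_B", "D", "L", "n_A", "n_B",
                "theta_hat", "component", "flag"]
        fh.write("\t".join(cols) + "\n")
        for r in report.rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
    with open(f"{prefix}.summary.tsv", "w") as fh:
        cols = ["species_pair", "n_loci", "X2", "df", "p_value", "f_hat", "T_hat"]
        fh.write("\t".join(cols) + "\n")
        for r in report.summary:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
        fh.write(f"# flagged {report.n_flagged}/{report.n_components} "
                 f"({100 * report.flagged_fraction:.1f}%) per-locus components\n")
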