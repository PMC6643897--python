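"""Multispecies-coalescent generator of orthologous gene alignments.

Genealogies are sampled Hudson-style: Kingman coalescent within each
population, lineage sets merged at species-split times, coalescence finishing
in ancestral populations.  Time is measured in coalescent units of 2N
generations of a reference population with per-bp ``theta_ref = 4*N*mu``;
a population with per-bp theta_p has relative size f_p = theta_p/theta_ref
and pair-coalescence rate 1/f_p.  Mutations fall on branches as a Poisson
process with rate theta_ref/2 per site per unit time.

Two mutation modes: ``infinite_sites`` (default; every mutation opens a new
column, clean truth bookkeeping) and ``jc`` (finite sites, Jukes-Cantor-style
repeat hits, for exercising distance corrections).

Closed forms used to validate the simulator (and then to use it as an
oracle): within a species with per-bp theta and n samples over L sites,
E[S] = theta * a_n * L; for two species split tau units ago with ancestral
relative size f_anc, the expected per-site divergence of a cross-species
pair is theta_ref * (tau + f_anc).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .alignment_io import GeneAlignment, SpeciesPanel, write_sample_sheet
from .errors import InputError

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    n_samples: int
    theta: float  # per bp


@dataclass(frozen=True)
class Join:
    """At ``time`` (coalescent units), lineages of ``source`` and ``dest``
    continue in population ``dest``."""

    time: float
    source: str
    dest: str


@dataclass(frozen=True)
class SimConfig:
    species: tuple[SpeciesSpec, ...]
    joins: tuple[Join, ...]
    gene_lengths: tuple[int, ...]
    theta_ref: float
    ancestral_theta: dict[str, float] = field(default_factory=dict)
    missing_gene_prob: float = 0.0
    mask_rate: float = 0.0
    mode: str = "infinite_sites"           # or "jc"
    base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self):
        if not self.species:
            raise InputError("SimConfig: no species")
        if self.theta_ref < 0:
            raise InputError("SimConfig: theta_ref must be >= 0")
        for sp in self.species:
            if sp.theta < 0 or sp.n_samples < 1:
                raise InputError(f"SimConfig: bad spec for {sp.name}")
        if any(l < 1 for l in self.gene_lengths):
            raise InputError("SimConfig: gene lengths must be >= 1")
        for p in (self.missing_gene_prob, self.mask_rate):
            if not 0.0 <= p <= 1.0:
                raise InputError("SimConfig: probabilities must be in [0,1]")
        if self.mode not in ("infinite_sites", "jc"):
            raise InputError(f"SimConfig: unknown mode {self.mode!r}")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise InputError("SimConfig: base_freqs must sum to 1")
        times = [j.time for j in self.joins]
        if any(t < 0 for t in times):
            raise InputError("SimConfig: join times must be >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_lengths)

    def pop_theta(self, pop: str) -> float:
        for sp in self.species:
            if sp.name == pop:
                return sp.theta
        if pop in self.ancestral_theta:
            return self.ancestral_theta[pop]
        raise InputError(f"SimConfig: no theta for population {pop!r}")

    def panel(self) -> SpeciesPanel:
        mapping = {}
        for sp in self.species:
            for k in range(sp.n_samples):
                mapping[f"{sp.name}_{k:02d}"] = sp.name
        return SpeciesPanel(mapping)


@dataclass
class Mutation:
    column: int
    derived: str
    carriers: frozenset[str]   # accessions carrying the derived allele


@dataclass
class SimTruth:
    """Per-gene ground truth: genealogy, mutations and sharing flags."""

    gene_id: str
    newick: str
    tree_length: float
    mutations: list[Mutation]

    def ancestrally_shared(self, panel: SpeciesPanel) -> list[Mutation]:
        """Mutations polymorphic (0 < carriers < n) within >= 2 species."""
        n_of = {sp: len(panel.accessions_of(sp)) for sp in panel.species}
        out = []
        for m in self.mutations:
            poly = 0
            for sp in panel.species:
                c = sum(1 for a in m.carriers if panel.species_of[a] == sp)
                if 0 < c < n_of[sp]:
                    poly += 1
            if poly >= 2:
                out.append(m)
        return out


class _Node:
    __slots__ = ("name", "time", "children", "leaves")

    def __init__(self, name, time, children=()):
        self.name = name
        self.time = time
        self.children = list(children)
        self.leaves = (frozenset([name]) if not children
                       else frozenset().union(*(c.leaves for c in children)))

    def newick(self, parent_time=None) -> str:
        if self.children:
            inner = ",".join(c.newick(self.time) for c in self.children)
            label = f"({inner})"
        else:
            label = self.name
        if parent_time is None:
            return label + ";"
        return f"{label}:{parent_time - self.time:.6g}"


def _sample_genealogy(cfg: SimConfig, rng: np.random.Generator) -> _Node:
    """One multispecies-coalescent genealogy over all sampled accessions."""
    lineages: dict[str, list[_Node]] = {}
    for sp in cfg.species:
        lineages[sp.name] = [_Node(f"{sp.name}_{k:02d}", 0.0)
                             for k in range(sp.n_samples)]
    joins = sorted(cfg.joins, key=lambda j: j.time)
    t = 0.0
    k_join = 0
    counter = 0

    def pop_rate(pop: str) -> float:
        k = len(lineages.get(pop, ()))
        if k < 2:
            return 0.0
        # theta_ref = 0 disables mutation; population sizes then default to 1
        f = cfg.pop_theta(pop) / cfg.theta_ref if cfg.theta_ref > 0 else 1.0
        if f == 0.0:
            return float("inf")
        return k * (k - 1) / 2.0 / f

    while True:
        rates = {p: pop_rate(p) for p in lineages}
        # instantaneous coalescence for zero-size populations
        inf_pops = [p for p, r in rates.items() if r == float("inf")]
        if inf_pops:
            p = inf_pops[0]
            idx = rng.choice(len(lineages[p]), size=2, replace=False)
            _merge(lineages, p, idx, t, counter)
            counter += 1
            continue
        total = sum(rates.values())
        next_join = joins[k_join].time if k_join < len(joins) else None
        if total > 0.0:
            dt = rng.exponential(1.0 / total)
        else:
            dt = float("inf")
        if next_join is not None and t + dt >= next_join:
            t = next_join
            j = joins[k_join]
            k_join += 1
            moved = lineages.pop(j.source, [])
            lineages.setdefault(j.dest, []).extend(moved)
            continue
        if total == 0.0:
            break
        t += dt
        pick = rng.uniform(0.0, total)
        acc = 0.0
        for p, r in rates.items():
            acc += r
            if pick <= acc:
                idx = rng.choice(len(lineages[p]), size=2, replace=False)
                _merge(lineages, p, idx, t, counter)
                counter += 1
                break

    remaining = [n for pop in lineages.values() for n in pop]
    if len(remaining) != 1:
        raise InputError(
            "SimConfig: species tree does not merge all populations into one "
            f"({len(remaining)} lineages left after all joins)")
    return remaining[0]


def _merge(lineages, pop, idx, t, counter):
    i, j = sorted(int(v) for v in idx)
    b = lineages[pop].pop(j)
    a = lineages[pop].pop(i)
    lineages[pop].append(_Node(f"anc{counter}", t, (a, b)))


def _branches(root: _Node):
    """Yield (child_node, branch_length)."""
    stack = [root]
    while stack:
        node = stack.pop()
        for c in node.children:
            yield c, node.time - c.time
            stack.append(c)


def gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    """Independent, reproducible stream for one gene."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(gene_index,)))


def simulate_gene(cfg: SimConfig, gene_index: int,
                  rng: np.random.Generator | None = None,
                  ) -> tuple[GeneAlignment, SimTruth]:
    """Simulate one gene alignment (pre-masking) plus its ground truth."""
    if rng is None:
        rng = gene_rng(cfg.seed, gene_index)
    L = cfg.gene_lengths[gene_index]
    gene_id = f"gene{gene_index:04d}"
    root = _sample_genealogy(cfg, rng)
    branches = list(_branches(root))
    tree_length = sum(bl for _, bl in branches)
    accessions = sorted(root.leaves)
    acc_index = {a: i for i, a in enumerate(accessions)}

    freqs = np.asarray(cfg.base_freqs)
    ancestral = rng.choice(_BASES, size=L, p=freqs)
    matrix = np.tile(ancestral, (len(accessions), 1))
    mutations: list[Mutation] = []

    rate_per_site = cfg.theta_ref / 2.0
    n_per_branch = rng.poisson([bl * rate_per_site * L for _, bl in branches])
    n_mut = int(n_per_branch.sum())

    if cfg.mode == "infinite_sites":
        if n_mut > L:
            raise InputError(
                f"{gene_id}: {n_mut} mutations exceed {L} sites; use mode='jc'")
        cols = rng.choice(L, size=n_mut, replace=False)
        ci = 0
        for (child, _), k in zip(branches, n_per_branch):
            for _ in range(int(k)):
                col = int(cols[ci])
                ci += 1
                anc = ancestral[col]
                others = _BASES[_BASES != anc]
                derived = rng.choice(others)
                rows = [acc_index[a] for a in child.leaves]
                matrix[rows, col] = derived
                mutations.append(Mutation(col, derived.decode(),
                                          frozenset(child.leaves)))
    else:  # finite-sites, JC-style repeat hits applied root-to-tip
        per_branch_cols = [rng.integers(0, L, size=int(k)) for k in n_per_branch]
        seqs = {id(root): ancestral.copy()}
        order = sorted(range(len(branches)),
                       key=lambda i: -branches[i][0].time)  # parents first
        parent_of = {}
        for node in _iter_nodes(root):
            for c in node.children:
                parent_of[id(c)] = id(node)
        for i in order:
            child, _ = branches[i]
            seq = seqs[parent_of[id(child)]].copy()
            for col in per_branch_cols[i]:
                cur = seq[col]
                others = _BASES[_BASES != cur]
                new = rng.choice(others)
                seq[col] = new
                mutations.append(Mutation(int(col), new.decode(),
                                          frozenset(child.leaves)))
            seqs[id(child)] = seq
        for node in _iter_nodes(root):
            if not node.children:
                matrix[acc_index[node.name]] = seqs[id(node)]

    aln = GeneAlignment(gene_id, accessions, matrix)
    truth = SimTruth(gene_id, root.newick(), tree_length, mutations)
    return aln, truth


def _iter_nodes(root: _Node):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def apply_masking(aln: GeneAlignment, cfg: SimConfig,
                  rng: np.random.Generator) -> GeneAlignment:
    """Drop whole rows (missing gene) and N-mask one contiguous segment per
    accession at ``mask_rate`` of the gene length."""
    keep = [a for a in aln.accessions
            if rng.random() >= cfg.missing_gene_prob]
    if not keep:  # never emit an empty file
        keep = [aln.accessions[int(rng.integers(len(aln.accessions)))]]
    sub = aln.subset(keep)
    matrix = sub.matrix.copy()
    span = int(round(cfg.mask_rate * aln.length))
    if span > 0:
        for i in range(matrix.shape[0]):
            start = int(rng.integers(0, max(1, aln.length - span + 1)))
            matrix[i, start:start + span] = b"N"
    return GeneAlignment(aln.gene_id, sub.accessions, matrix)


def simulate_panel(cfg: SimConfig, out_dir: str | Path,
                   ) -> tuple[Path, Path, list[SimTruth]]:
    """Write a gene-FASTA directory, sample sheet, and truth sidecars.

    Returns (genes_dir, sample_sheet_path, truths).  Byte-reproducible from
    ``cfg.seed``.
    """
    out_dir = Path(out_dir)
    genes_dir = out_dir / "genes"
    genes_dir.mkdir(parents=True, exist_ok=True)
    panel = cfg.panel()
    truths: list[SimTruth] = []
    for gi in range(cfg.n_genes):
        rng = gene_rng(cfg.seed, gi)
        aln, truth = simulate_gene(cfg, gi, rng)
        masked = apply_masking(aln, cfg, rng)
        with open(genes_dir / f"{aln.gene_id}.fasta", "w") as fh:
            for acc, row in zip(masked.accessions, masked.matrix):
                fh.write(f">{acc}\n{row.tobytes().decode('ascii')}\n")
        truths.append(truth)
    sheet = out_dir / "samples.tsv"
    write_sample_sheet(panel, sheet)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump([{
            "gene_id": t.gene_id,
            "newick": t.newick,
            "tree_length": t.tree_length,
            "n_mutations": len(t.mutations),
            "shared_columns": sorted(m.column
                                     for m in t.ancestrally_shared(panel)),
        } for t in truths], fh, indent=1)
    return genes_dir, sheet, truths


def ancestral_sharing_mode(cfg: SimConfig, enabled: bool,
                           time_scale: float = 0.1,
                           ancestral_theta_factor: float = 5.0) -> SimConfig:
    """Shrink split times and inflate ancestral theta so shared ancestral
    polymorphism survives into multiple descendant species.  With
    ``enabled=False`` the config is returned unchanged."""
    if not enabled:
        return cfg
    joins = tuple(Join(j.time * time_scale, j.source, j.dest) for j in cfg.joins)
    anc = {k: v * ancestral_theta_factor for k, v in cfg.ancestral_theta.items()}
    return replace(cfg, joins=joins, ancestral_theta=anc)


def expected_pair_divergence(cfg: SimConfig, species_a: str, species_b: str) -> float:
    """Closed-form expected per-site divergence of one cross-species pair:
    theta_ref * (tau_split + f_ancestor)."""
    # walk the join sequence to find where the two species' lineages first share
    member: dict[str, set[str]] = {sp.name: {sp.name} for sp in cfg.species}
    for j in sorted(cfg.joins, key=lambda j: j.time):
        merged = member.get(j.dest, {j.dest}) | member.pop(j.source, {j.source})
        member[j.dest] = merged
        if species_a in merged and species_b in merged:
            f_anc = cfg.pop_theta(j.dest) / cfg.theta_ref
            return cfg.theta_ref * (j.time + f_anc)
    raise InputError(f"{species_a} and {species_b} never share an ancestor")


def hka_observations_from_truth(cfg: SimConfig, truth: SimTruth,
                                species_a: str, species_b: str,
                                ) -> tuple[int, int, float]:
    """(S_A, S_B, D) for one simulated gene straight from its mutation record.

    Valid under infinite sites with complete data: a mutation segregates in a
    species iff 0 < carriers < n; the mean cross-pair divergence D sums, per
    mutation, the fraction of cross pairs whose carrier status differs.
    """
    panel = cfg.panel()
    accs_a = panel.accessions_of(species_a)
    accs_b = panel.accessions_of(species_b)
    n_a, n_b = len(accs_a), len(accs_b)
    S_A = S_B = 0
    D = 0.0
    for m in truth.mutations:
        c_a = sum(1 for x in accs_a if x in m.carriers)
        c_b = sum(1 for x in accs_b if x in m.carriers)
        if 0 < c_a < n_a:
            S_A += 1
        if 0 < c_b < n_b:
            S_B += 1
        D += (c_a * (n_b - c_b) + (n_a - c_a) * c_b) / (n_a * n_b)
    return S_A, S_B, D


def two_species_config(theta: float = 0.003, tau: float = 2.0,
                       n_a: int = 10, n_b: int = 10,
                       n_genes: int = 10, gene_length: int = 1000,
                       ancestral_theta: float | None = None,
                       seed: int = 0, **kw) -> SimConfig:
    """Convenience config: two species splitting tau units ago."""
    anc = theta if ancestral_theta is None else ancestral_theta
    return SimConfig(
        species=(SpeciesSpec("spA", n_a, theta), SpeciesSpec("spB", n_b, theta)),
        joins=(Join(tau, "spB", "ancAB"), Join(tau, "spA", "ancAB")),
        gene_lengths=(gene_length,) * n_genes,
        theta_ref=theta,
        ancestral_theta={"ancAB": anc},
        seed=seed,
        **kw,
    )


def study_like_config(seed: int = 0, n_genes: int = 52, **kw) -> SimConfig:
    """Eight species, 10-15 samples each, per-species theta in 0.001-0.004,
    split depths giving between-species distances roughly 0.01-0.05."""
    theta_ref = 0.003
    species = (
        SpeciesSpec("sp1", 15, 0.0011),
        SpeciesSpec("sp2", 12, 0.0022),
        SpeciesSpec("sp3", 11, 0.0040),
        SpeciesSpec("sp4", 10, 0.0031),
        SpeciesSpec("sp5", 12, 0.0016),
        SpeciesSpec("sp6", 12, 0.0033),
        SpeciesSpec("sp7", 12, 0.0027),
        SpeciesSpec("sp8", 10, 0.0025),
    )
    joins = (
        Join(2.6, "sp2", "sp1"),    # close pair -> d ~ 0.009
        Join(4.0, "sp4", "sp3"),
        Join(7.0, "sp5", "sp3"),
        Join(8.0, "sp7", "sp6"),
        Join(9.0, "sp6", "sp3"),
        Join(11.0, "sp8", "sp3"),
        Join(13.0, "sp1", "sp3"),
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10**6,)))
    lengths = tuple(int(v) for v in rng.integers(500, 1501, size=n_genes))
    anc = {}
    # after each join the destination population represents the ancestor;
    # keep ancestral sizes at the reference scale
    return SimConfig(
        species=species, joins=joins, gene_lengths=lengths,
        theta_ref=theta_ref, ancestral_theta=anc, seed=seed, **kw,
    )
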