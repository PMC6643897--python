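"""Tajima-Nei ("equal input") distances, between-species means, and a
neighbor-joining tree.

Distances are computed per accession pair on the concatenated alignment with
pairwise deletion (only columns where both calls are in {A,C,G,T} are
compared), then averaged over all cross-species pairs for the between-group
mean.  Pairs where the log correction is undefined (p >= b) are flagged, never
clamped.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .alignment_io import BASES, ConcatenatedAlignment, SpeciesPanel
from .errors import InputError

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: the 6 unordered base pairs, index order used for the x vector
MISMATCH_PAIRS = tuple(itertools.combinations(range(4), 2))


@dataclass
class TajimaNeiTerms:
    """Intermediate quantities of the equal-input distance for one pair.

    p: proportion of differing sites among compared sites; g: average base
    frequencies of the two sequences; x: the 6 unordered mismatch-type
    relative frequencies (sum = p); h = sum x_ij^2/(2 g_i g_j);
    b = (1 - sum g_i^2 + p^2/h)/2; d = -b*ln(1 - p/b).
    """

    n_compared: int
    p: float
    g: np.ndarray
    x: np.ndarray
    h: float | None
    b: float | None
    d: float | None

    @property
    def defined(self) -> bool:
        return self.d is not None


def tajima_nei_pair(seq1: np.ndarray, seq2: np.ndarray) -> TajimaNeiTerms:
    """Equal-input distance between two aligned residue rows.

    Comparison is restricted to columns where both calls are unambiguous
    bases (pairwise deletion).  With p = 0 the distance is 0 by convention
    (h undefined); with p >= b the distance is flagged undefined; with no
    comparable columns the result is flagged undefined rather than raising.
    """
    seq1 = np.asarray(seq1, dtype="S1")
    seq2 = np.asarray(seq2, dtype="S1")
    if seq1.shape != seq2.shape:
        raise InputError("tajima_nei_pair: sequences differ in length")
    called1 = np.isin(seq1, BASES)
    called2 = np.isin(seq2, BASES)
    both = called1 & called2
    n = int(both.sum())
    if n < 1:
        return TajimaNeiTerms(0, math.nan, np.full(4, math.nan),
                              np.full(6, math.nan), None, None, None)
    s1, s2 = seq1[both], seq2[both]
    counts1 = np.array([(s1 == b).sum() for b in BASES], dtype=float)
    counts2 = np.array([(s2 == b).sum() for b in BASES], dtype=float)
    g = (counts1 + counts2) / (2.0 * n)

    diff = s1 != s2
    p = float(diff.mean())
    x = np.zeros(6)
    if diff.any():
        i1 = np.array([_BASE_INDEX[b] for b in s1[diff].tolist()])
        i2 = np.array([_BASE_INDEX[b] for b in s2[diff].tolist()])
        lo, hi = np.minimum(i1, i2), np.maximum(i1, i2)
        for k, (i, j) in enumerate(MISMATCH_PAIRS):
            x[k] = np.sum((lo == i) & (hi == j)) / n

    if p == 0.0:
        return TajimaNeiTerms(n, 0.0, g, x, None, None, 0.0)

    h = 0.0
    for k, (i, j) in enumerate(MISMATCH_PAIRS):
        if x[k] > 0.0:
            h += x[k] ** 2 / (2.0 * g[i] * g[j])
    b = 0.5 * (1.0 - float(np.sum(g ** 2)) + p ** 2 / h)
    if p >= b:
        return TajimaNeiTerms(n, p, g, x, h, b, None)
    d = -b * math.log(1.0 - p / b)
    return TajimaNeiTerms(n, p, g, x, h, b, d)


@dataclass
class GroupDistance:
    mean_d: float | None
    n_pairs: int
    n_undefined: int


def between_group_distance(aln: ConcatenatedAlignment, panel: SpeciesPanel,
                           species_a: str, species_b: str) -> GroupDistance:
    """Arithmetic mean of pairwise distances over all cross-species accession
    pairs (between-group mean convention); undefined pairs are excluded and
    counted."""
    rows = {a: aln.matrix[i] for i, a in enumerate(aln.accessions)}
    accs_a = [a for a in panel.accessions_of(species_a) if a in rows]
    accs_b = [a for a in panel.accessions_of(species_b) if a in rows]
    if not accs_a or not accs_b:
        raise InputError(
            f"no accessions for {species_a!r} or {species_b!r} in alignment")
    ds = []
    n_undef = 0
    for a in accs_a:
        for b in accs_b:
            if a == b:
                continue
            t = tajima_nei_pair(rows[a], rows[b])
            if t.defined:
                ds.append(t.d)
            else:
                n_undef += 1
    if not ds:
        return GroupDistance(None, 0, n_undef)
    return GroupDistance(float(np.mean(ds)), len(ds), n_undef)


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with undefined entries tracked separately."""

    labels: list[str]
    matrix: np.ndarray          # nan where undefined
    n_sites: np.ndarray         # comparison-site or pair counts

    @property
    def size(self) -> int:
        return len(self.labels)

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.size):
            for j in range(i + 1, self.size):
                if math.isnan(self.matrix[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def distance_matrix(aln: ConcatenatedAlignment, panel: SpeciesPanel,
                    level: str = "species") -> DistanceMatrix:
    """Full symmetric Tajima-Nei distance matrix at accession or species level.

    Species level uses the between-group mean; entries that cannot be computed
    are NaN.
    """
    if level == "accession":
        labels = list(aln.accessions)
        n = len(labels)
        mat = np.zeros((n, n))
        nsite = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(i + 1, n):
                t = tajima_nei_pair(aln.matrix[i], aln.matrix[j])
                mat[i, j] = mat[j, i] = t.d if t.defined else math.nan
                nsite[i, j] = nsite[j, i] = t.n_compared
        return DistanceMatrix(labels, mat, nsite)
    if level == "species":
        labels = [sp for sp in panel.species
                  if any(a in aln.accessions for a in panel.accessions_of(sp))]
        n = len(labels)
        mat = np.zeros((n, n))
        npair = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(i + 1, n):
                gd = between_group_distance(aln, panel, labels[i], labels[j])
                mat[i, j] = mat[j, i] = gd.mean_d if gd.mean_d is not None else math.nan
                npair[i, j] = npair[j, i] = gd.n_pairs
        return DistanceMatrix(labels, mat, npair)
    raise InputError(f"unknown level {level!r}")


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining (Saitou-Nei) tree from a distance matrix, as Newick.

    Deterministic: on equal Q scores the lowest-index pair is joined.
    Branch lengths follow the standard NJ formulas; the final three (or two)
    nodes are joined into an unrooted multifurcation at the root.
    """
    bad = dm.undefined_pairs()
    if bad:
        raise InputError(f"nj_tree: undefined distances for pairs {bad}")
    if dm.size < 3:
        raise InputError("nj_tree requires >= 3 labels")
    d = dm.matrix.astype(float).copy()
    nodes = [f"{lab}" for lab in dm.labels]
    lengths: dict[int, float] = {}
    active = list(range(dm.size))
    newick = {i: nodes[i] for i in active}

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        # new internal node
        k = d.shape[0]
        newrow = np.zeros((1, k))
        for am in range(m):
            u = active[am]
            if u in (i, j):
                continue
            newrow[0, u] = 0.5 * (d[i, u] + d[j, u] - dij)
        d = np.vstack([d, newrow])
        d = np.hstack([d, np.append(newrow, 0.0).reshape(-1, 1)])
        newick[k] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        active = [u for u in active if u not in (i, j)] + [k]

    i, j = active
    return f"({newick[i]}:{d[i, j] / 2:.10g},{newick[j]}:{d[i, j] / 2:.10g});"


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    """Lower-triangular TSV layout with labels on both axes."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(dm.labels) + "\n")
        for i, lab in enumerate(dm.labels):
            cells = []
            for j in range(len(dm.labels)):
                v = dm.matrix[i, j]
                cells.append("NA" if math.isnan(v) else f"{v:.3f}")
            fh.write(lab + "\t" + "\t".join(cells) + "\n")


def write_phylip(dm: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{dm.size}\n")
        for i, lab in enumerate(dm.labels):
            vals = " ".join(f"{v:.6f}" for v in dm.matrix[i])
            fh.write(f"{lab:<12s}{vals}\n")
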