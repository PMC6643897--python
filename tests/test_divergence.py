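import itertools
import math
import random

import dendropy
import numpy as np
import pytest

from orthopop.alignment_io import SpeciesPanel, concatenate
from orthopop.divergence import (
    DistanceMatrix,
    between_group_distance,
    distance_matrix,
    nj_tree,
    tajima_nei_pair,
)
from orthopop.errors import InputError

from conftest import aln_from_strings


def seq_pair(s1: str, s2: str):
    a = np.frombuffer(s1.encode(), dtype="S1")
    b = np.frombuffer(s2.encode(), dtype="S1")
    return a, b


def walkthrough_tajima_nei(s1: str, s2: str) -> float:
    """Independent spreadsheet-style evaluation of the equal-input distance."""
    pairs = [(c1, c2) for c1, c2 in zip(s1, s2)
             if c1 in "ACGT" and c2 in "ACGT"]
    n = len(pairs)
    diff = [(c1, c2) for c1, c2 in pairs if c1 != c2]
    p = len(diff) / n
    if p == 0:
        return 0.0
    g = {}
    for base in "ACGT":
        g[base] = (sum(c1 == base for c1, _ in pairs)
                   + sum(c2 == base for _, c2 in pairs)) / (2 * n)
    x = {}
    for c1, c2 in diff:
        key = frozenset((c1, c2))
        x[key] = x.get(key, 0) + 1 / n
    h = sum(v**2 / (2 * g[tuple(k)[0]] * g[tuple(k)[1]]) for k, v in x.items())
    b = 0.5 * (1 - sum(v**2 for v in g.values()) + p**2 / h)
    return -b * math.log(1 - p / b)


class TestTajimaNeiPair:
    def test_identical(self):
        t = tajima_nei_pair(*seq_pair("ACGTACGT", "ACGTACGT"))
        assert t.d == 0.0
        assert t.p == 0.0

    def test_jukes_cantor_limit(self):
        # equal base frequencies and uniform mismatch spectrum
        mism1, mism2 = "AAACCG", "CGTGTT"
        match = "ACGT" * 10
        t = tajima_nei_pair(*seq_pair(mism1 + match, mism2 + match))
        n = len(mism1) + len(match)
        p = 6 / n
        assert np.allclose(t.g, 0.25, atol=1e-15)
        assert t.b == pytest.approx(0.75, abs=1e-12)
        expected_jc = -0.75 * math.log(1 - 4 * p / 3)
        assert t.d == pytest.approx(expected_jc, abs=1e-12)

    def test_60bp_toy_matches_walkthrough_oracle(self):
        rng = random.Random(2024)
        s1 = "".join(rng.choice("ACGT") for _ in range(60))
        s2 = "".join(c if rng.random() > 0.15 else rng.choice("ACGT")
                     for c in s1)
        t = tajima_nei_pair(*seq_pair(s1, s2))
        assert t.d == pytest.approx(walkthrough_tajima_nei(s1, s2), abs=1e-12)

    def test_random_pairs_match_walkthrough(self):
        rng = random.Random(5)
        for _ in range(25):
            s1 = "".join(rng.choice("ACGTN-") for _ in range(80))
            s2 = "".join(rng.choice("ACGTN-") for _ in range(80))
            t = tajima_nei_pair(*seq_pair(s1, s2))
            comparable = sum(a in "ACGT" and b in "ACGT"
                             for a, b in zip(s1, s2))
            if comparable == 0:
                assert not t.defined
                continue
            if t.defined:
                assert t.d == pytest.approx(
                    walkthrough_tajima_nei(s1, s2), abs=1e-12)
            else:
                assert t.p >= t.b  # log correction out of domain

    def test_pairwise_deletion(self):
        s1, s2 = "ACGTNN--AC", "ACNTAG-TAC"
        t = tajima_nei_pair(*seq_pair(s1, s2))
        assert t.n_compared == sum(
            a in "ACGT" and b in "ACGT" for a, b in zip(s1, s2))
        assert t.n_compared == 5

    def test_symmetry(self):
        rng = random.Random(9)
        s1 = "".join(rng.choice("ACGT") for _ in range(50))
        s2 = "".join(rng.choice("ACGT") for _ in range(50))
        t12 = tajima_nei_pair(*seq_pair(s1, s2))
        t21 = tajima_nei_pair(*seq_pair(s2, s1))
        assert t12.d == pytest.approx(t21.d, abs=1e-15)

    def test_d_at_least_p(self):
        rng = random.Random(13)
        for _ in range(20):
            s1 = "".join(rng.choice("ACGT") for _ in range(100))
            s2 = "".join(c if rng.random() > 0.1 else rng.choice("ACGT")
                         for c in s1)
            t = tajima_nei_pair(*seq_pair(s1, s2))
            if t.defined and t.p > 0:
                assert t.d >= t.p

    def test_saturated_pair_flagged_undefined(self):
        # maximally divergent: p is far above b
        t = tajima_nei_pair(*seq_pair("ACGT" * 10, "CATG" * 10))
        assert not t.defined

    def test_no_comparable_sites(self):
        t = tajima_nei_pair(*seq_pair("NNNN", "ACGT"))
        assert not t.defined
        assert t.n_compared == 0

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            tajima_nei_pair(*seq_pair("ACGT", "ACG"))


class TestBetweenGroup:
    def test_identical_singletons(self):
        panel = SpeciesPanel({"a1": "spA", "b1": "spB"})
        g = aln_from_strings("g", {"a1": "ACGTACGT", "b1": "ACGTACGT"})
        cat = concatenate([g], panel)
        gd = between_group_distance(cat, panel, "spA", "spB")
        assert gd.mean_d == 0.0
        assert gd.n_pairs == 1

    def test_mean_over_cross_pairs(self):
        panel = SpeciesPanel({"a1": "spA", "a2": "spA", "b1": "spB"})
        rows = {"a1": "ACGTACGTAA", "a2": "ACGTACGTAC", "b1": "ACGTACTTAA"}
        g = aln_from_strings("g", rows)
        cat = concatenate([g], panel)
        gd = between_group_distance(cat, panel, "spA", "spB")
        expected = np.mean([
            walkthrough_tajima_nei(rows["a1"], rows["b1"]),
            walkthrough_tajima_nei(rows["a2"], rows["b1"]),
        ])
        assert gd.mean_d == pytest.approx(expected, abs=1e-12)
        assert gd.n_pairs == 2

    def test_relabeling_invariance(self):
        rng = random.Random(21)
        rows = {f"x{i}": "".join(rng.choice("ACGT") for _ in range(60))
                for i in range(6)}
        panel1 = SpeciesPanel({"x0": "A", "x1": "A", "x2": "A",
                               "x3": "B", "x4": "B", "x5": "B"})
        g = aln_from_strings("g", rows)
        cat = concatenate([g], panel1)
        d1 = between_group_distance(cat, panel1, "A", "B").mean_d
        # permute accession order in the alignment
        order = ["x5", "x2", "x4", "x0", "x1", "x3"]
        g2 = aln_from_strings("g", {a: rows[a] for a in order})
        cat2 = concatenate([g2], panel1)
        d2 = between_group_distance(cat2, panel1, "A", "B").mean_d
        assert d1 == pytest.approx(d2, abs=1e-15)


class TestDistanceMatrix:
    def test_single_species(self):
        panel = SpeciesPanel({"a1": "spA", "a2": "spA"})
        g = aln_from_strings("g", {"a1": "ACGT", "a2": "ACGT"})
        cat = concatenate([g], panel)
        dm = distance_matrix(cat, panel, level="species")
        assert dm.labels == ["spA"]
        assert dm.matrix.shape == (1, 1)
        assert dm.matrix[0, 0] == 0.0

    def test_symmetric_zero_diagonal(self):
        rng = random.Random(8)
        panel = SpeciesPanel({f"a{i}": "spA" for i in range(3)}
                             | {f"b{i}": "spB" for i in range(3)}
                             | {f"c{i}": "spC" for i in range(3)})
        rows = {a: "".join(rng.choice("ACGT") for _ in range(100))
                for a in panel.species_of}
        cat = concatenate([aln_from_strings("g", rows)], panel)
        dm = distance_matrix(cat, panel, level="species")
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0.0)

    def test_accession_permutation_invariance(self):
        rng = random.Random(31)
        rows = {f"x{i}": "".join(rng.choice("ACGT") for _ in range(80))
                for i in range(4)}
        panel = SpeciesPanel({"x0": "A", "x1": "A", "x2": "B", "x3": "B"})
        cat1 = concatenate([aln_from_strings("g", rows)], panel)
        shuffled = {a: rows[a] for a in ["x3", "x1", "x0", "x2"]}
        cat2 = concatenate([aln_from_strings("g", shuffled)], panel)
        dm1 = distance_matrix(cat1, panel, level="species")
        dm2 = distance_matrix(cat2, panel, level="species")
        assert dm1.labels == dm2.labels
        assert np.allclose(dm1.matrix, dm2.matrix, atol=1e-15)


def patristic_from_newick(newick: str) -> dict[frozenset, float]:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1, t2 in itertools.combinations(tree.taxon_namespace, 2):
        out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    return out


class TestNJTree:
    def test_additive_four_taxon_exact(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) -> additive distances
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ], dtype=float)
        dm = DistanceMatrix(labels, d, np.zeros_like(d, dtype=int))
        newick = nj_tree(dm)
        pat = patristic_from_newick(newick)
        for i, j in itertools.combinations(range(4), 2):
            key = frozenset((labels[i], labels[j]))
            assert pat[key] == pytest.approx(d[i, j], abs=1e-9)
        # sister structure: A with B, C with D
        assert ("(A:" in newick or ":2,B" in newick.replace(" ", ""))

    def test_three_taxa(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        dm = DistanceMatrix(["A", "B", "C"], d, np.zeros_like(d, dtype=int))
        pat = patristic_from_newick(nj_tree(dm))
        assert pat[frozenset(("A", "B"))] == pytest.approx(2.0)
        assert pat[frozenset(("A", "C"))] == pytest.approx(3.0)

    def test_ultrametric_sister_pairing(self):
        # (A,B) at height 1, (C,D) at height 1, root at height 3
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 2, 6, 6],
            [2, 0, 6, 6],
            [6, 6, 0, 2],
            [6, 6, 2, 0],
        ], dtype=float)
        dm = DistanceMatrix(labels, d, np.zeros_like(d, dtype=int))
        tree = dendropy.Tree.get(data=nj_tree(dm), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        # enumeration over the 3 topologies: A-B must be closer than A-C/A-D
        assert pdm.path_edge_count(taxa["A"], taxa["B"]) < \
            pdm.path_edge_count(taxa["A"], taxa["C"])
        assert pdm.path_edge_count(taxa["C"], taxa["D"]) < \
            pdm.path_edge_count(taxa["B"], taxa["C"])

    def test_too_few_labels(self):
        d = np.zeros((2, 2))
        with pytest.raises(InputError):
            nj_tree(DistanceMatrix(["A", "B"], d, d.astype(int)))

    def test_undefined_entries_named(self):
        d = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(InputError, match="A.*C"):
            nj_tree(DistanceMatrix(["A", "B", "C"], d, np.zeros((3, 3), int)))
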