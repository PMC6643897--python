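import numpy as np
import pytest

from orthopop.alignment_io import GeneAlignment, SpeciesPanel


def aln_from_strings(gene_id, rows: dict[str, str]) -> GeneAlignment:
    """Build a GeneAlignment from {accession: sequence-string}."""
    accs = list(rows)
    matrix = np.array([list(rows[a].encode()) for a in accs], dtype=np.uint8)
    return GeneAlignment(gene_id, accs, matrix.view("S1"))


@pytest.fixture
def two_species_panel():
    return SpeciesPanel({
        "a1": "spA", "a2": "spA", "a3": "spA",
        "b1": "spB", "b2": "spB", "b3": "spB",
    })


@pytest.fixture
def toy_gene(two_species_panel):
    # 12 columns exercising: monomorphic, biallelic within/between species,
    # multiallelic, gaps, missing, singletons
    return aln_from_strings("g1", {
        "a1": "AAGATTACGGCN",
        "a2": "AAGGTTACG-CN",
        "a3": "ACGATAACGGCN",
        "b1": "AAGGTTCCGGAN",
        "b2": "AAGGTTCGGGAN",
        "b3": "TAGGNTCCGGAN",
    })
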