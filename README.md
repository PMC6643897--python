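# orthopop

Population-genetic analysis of multi-species orthologous gene alignments:

* **alignment_io** — per-gene aligned multi-FASTA + sample-sheet reading,
  per-species presence filtering, cross-gene concatenation with offset
  bookkeeping (alphabet `A C G T - N`; ambiguity codes fold to `N`).
* **site_stats** — per-column allele profiles within/across species;
  segregating-site (S) and evaluable-length (L) tallies; indel events.
* **diversity** — Watterson's θ and nucleotide diversity π per species over a
  gene set, with missing data handled by site-specific sample sizes.
* **divergence** — Tajima–Nei ("equal input") pairwise distances with
  pairwise deletion, between-species group means, and a Saitou–Nei
  neighbor-joining tree in Newick.
* **trans_specific** — detection of sites segregating for the identical
  unordered allele pair in ≥ 2 species, with transition/transversion
  classification (complement folding) and per-gene / per-k / per-class /
  per-species-pair summaries.
* **hka** — two-species multilocus Hudson–Kreitman–Aguadé neutrality test:
  moment-equation fit (per-locus θ̂ᵢ, relative size f̂, scaled time T̂),
  X² goodness of fit vs χ²(2L−2), per-locus components flagged vs χ²(1).
* **synthetic** — multispecies-coalescent simulator (infinite-sites or
  finite-sites JC mode) with species trees, per-population θ, missing-data
  masking, truth bookkeeping of every mutation, and closed-form validation
  hooks (E[S] = θ·aₙ·L, E[d] = θ·(τ+1)).
* **cli** — `orthopop` command with subcommands
  `simulate, diversity, divergence, njtree, transspec, hka, run-all`.

## CLI quick start

```sh
# simulate an 8-species panel (built-in preset), then analyse it
orthopop simulate --out panel --seed 1
orthopop diversity  --genes-dir panel/genes --samples panel/samples.tsv --out reports
orthopop divergence --genes-dir panel/genes --samples panel/samples.tsv --out reports --min-presence 2
orthopop njtree     --genes-dir panel/genes --samples panel/samples.tsv --out reports --min-presence 2
orthopop transspec  --genes-dir panel/genes --samples panel/samples.tsv --out reports
orthopop hka        --genes-dir panel/genes --samples panel/samples.tsv --out reports --focal-species sp1
orthopop run-all    --genes-dir panel/genes --samples panel/samples.tsv --out reports --min-presence 2
```

Inputs are a directory of `<gene_id>.fasta` aligned multi-FASTA files (one
record per accession; first header token = accession ID) and a tab-separated
sample sheet with `accession` and `species` columns.  `simulate` also accepts
an INI config (`--config`) with `[sim]`, `[species]`, `[joins]` and
`[ancestral]` sections; see `tests/test_cli.py` for a worked example.

Exit codes: 0 success, 2 input error, 3 insufficient data, 4 non-convergence.

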