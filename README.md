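# sialevo

Comparative sequence analysis of the metazoan **sialidase (neuraminidase)
protein family** — the glycohydrolases (NEU1–NEU4 in vertebrates, plus the
ancestral-intermediate NEU5 form found in early deuterostomes) that remove
terminal sialic acids from glycoconjugates.

The package is aimed at molecular evolutionists studying protein
subfamilies.  Given a protein multiple alignment with subfamily and
taxonomic metadata, predicted phosphorylation sites, and exon-junction
tables, it runs the full comparative workflow:

- **Subfamily assignment** by reciprocal best hit (RBH) over
  Smith–Waterman/BLOSUM62 local-alignment scores, plus subfamily-logo-style
  detection of subgroup-specific residues by frequency contrast.
- **Divergence and phylogeny** under the WAG+Γ model: pairwise
  maximum-likelihood distances, mean between-subgroup divergence with
  site-bootstrap SEs, Felsenstein-pruning tree likelihood, NJ/BioNJ
  starting trees, NNI search, bootstrap bipartition supports, and
  gamma-shape estimation.
- **Phospho-site conservation statistics**: per-column exact binomial test
  of S/T/Y conservation against the alignment-wide background, Fisher
  exact tests for subgroup- and taxon-specific conservation, Bonferroni
  correction, and ≥60 % / ≥90 % conservation flags.
- **Sequence features**: Asp-box (`SxDxGxxW/F`) and N-terminal
  (`T/FYRI/VP`) motif scanning, catalytic-residue conservation (R21, D46,
  E218, R237, R304, Y334 in human NEU2 numbering), active-site loop
  lengths, and exon-junction mapping into alignment coordinates.
- A **synthetic-data generator** that emulates a realistic family dataset
  (83 sequences over five clades, WAG+Γ evolution, planted motifs,
  conserved columns, loop insertions and exon structures) with full truth
  tables, so every stage is testable end to end without downloads.

## The model in brief

Substitution follows a reversible CTMC with rate matrix
`Q_ij = S_ij π_j` (WAG exchangeabilities `S`, stationary frequencies `π`),
scaled so branch lengths are expected substitutions per site.  Across-site
rate variation uses Yang's discrete gamma with K = 5 equiprobable
categories (shape α = 5 for divergence estimates, α = 2.6845 for tree
inference).  Conservation of a phospho-column is tested as
P(X ≥ k), X ~ Bin(N, p), with k the column's S/T/Y count, N the number of
sequences and p the alignment-wide S/T/Y frequency; group-specific
conservation uses the two-sided Fisher exact test on the
(group vs rest) × (S/T/Y vs other) table.  See `docs/methods.md` for the
complete account, parameter defaults and limitations.

## Worked example

```python
import sialevo as sv

# a full-size synthetic family: 83 sequences, five clades, planted truth
bundle = sv.generate_family_scenario(sv.ScenarioConfig(seed=17))
aln = bundle.alignment

p, total = sv.background_frequency(aln)
cols = sv.map_sites_to_columns(bundle.phospho_sites, aln)
stats = sv.compute_column_stats(aln, cols, alpha=0.01)

m, g5 = sv.SubstitutionModel.wag(), sv.GammaRates.discrete(5.0, 5)
d, se = sv.between_group_divergence(aln, aln.subgroup_ids("NEU3"),
                                    aln.subgroup_ids("NEU4"), m, g5,
                                    n_bootstrap=100, seed=0)
```

Output of the accompanying print statements:

```
alignment: 83 sequences x 1012 columns
S/T/Y background: 0.1723 over 82652 residues
columns with >=50% coverage: 1000
distinct phospho columns: 29
globally conserved >=60% / >=90%: 7 / 4
subgroup-only sites: 20
NEU3-NEU4 divergence: 1.04 (SE 0.04) substitutions/site
catalytic residues fully conserved: True
NEU1 Asp-box locations: 5
```

Reading the numbers: the S/T/Y background (0.1723) is the per-residue
frequency the binomial test uses; 29 distinct alignment columns carry a
predicted phospho-site, of which 7 are significantly conserved family-wide
at ≥60 % (4 at ≥90 %) and 20 are significantly conserved only within
particular subfamilies (the 13 planted ones plus columns conserved by
shared descent within a clade).  The NEU3–NEU4 mean pairwise ML distance
of 1.04 substitutions/site matches the planted between-clade separation;
the six catalytic positions and the five NEU1 Asp-box locations are
recovered exactly as planted.

## Command-line pipeline

```sh
sialevo simulate --out bundle/ --seed 3                  # synthetic dataset
sialevo all --bundle bundle/ --out results/ --seed 1     # whole workflow
# or stage by stage:
sialevo assign     --alignment aln.fasta --metadata meta.tsv --out out/assign
sialevo divergence --alignment aln.fasta --metadata meta.tsv --out out/div
sialevo tree       --alignment aln.fasta --out out/tree --bootstrap 100
sialevo phospho    --alignment aln.fasta --metadata meta.tsv \
                   --sites sites.tsv --out out/phospho
sialevo features   --alignment aln.fasta --metadata meta.tsv \
                   --exons exons.tsv --reference HsaNEU2 --out out/features
```

Each stage writes TSV artifacts plus a `run.json` with parameters, seed and
a config hash; `--config file` presets any option (`key = value` lines) and
explicit flags win.

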