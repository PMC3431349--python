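# Methods

`sialevo` re-implements, as a tested library and CLI, the comparative
analysis workflow used to characterise the metazoan sialidase (neuraminidase)
protein family: subfamily assignment of candidate sequences, evolutionary
divergence and phylogeny under an empirical amino-acid model,
conservation statistics for predicted phosphorylation sites, and
sequence-feature analyses of the family's structural signatures.  This note
records the models, the parameter choices and their rationale, what the
synthetic data generator does and does not emulate, and the numerical
decisions a maintainer would want to know.

## Data model and coordinates

The central object is a protein multiple sequence alignment with
per-sequence metadata: a subfamily label (NEU1–NEU5) and a taxonomic group
(mammals ⊂ vertebrates ⊂ deuterostomes, plus early metazoans outside the
nesting).  All coordinates are 1-based and inclusive.  Positions on a
particular protein (catalytic residues, loop boundaries, phospho-sites,
exon junctions) are translated to global alignment columns through a
`CoordinateMap`; by convention the reference for structural features is the
human cytosolic sialidase NEU2, whose crystal structure defines the loop and
catalytic-residue numbering.

Gap character is `-` only; `.` is rejected at read time so that mixed gap
dialects fail loudly.  Ambiguity letters (X, B, Z, …) are treated as missing
data: excluded from coverage numerators, from residue counts in statistics,
and from likelihoods (never a 21st state).  *Site coverage* of a column is
the fraction of sequences with an unambiguous residue there; by default the
divergence stage keeps columns with coverage strictly greater than 0.70
(only well-populated columns inform distance averages) and the phylogeny
stage keeps columns with coverage at least 0.50 (a looser cut, since the
pruning likelihood handles missing data natively).

## Subfamily assignment

Candidate sequences are assigned by reciprocal best hit (RBH): a query
inherits the subgroup label of its top-scoring reference only if it is, in
turn, that reference's top-scoring query; otherwise it is flagged
unassigned.  The similarity ranking uses Smith–Waterman local alignment
with BLOSUM62 and affine gap penalties (open 11, extend 1, the protein-BLAST
defaults) — BLAST itself is not re-implemented because RBH needs only a
consistent ranking, not E-values.  Score ties are broken toward the
lexicographically first identifier, with a warning.  Note that strict
reciprocity can leave correctly-placed queries unassigned (only mutual
pairs are labelled); the package therefore reports both the precision among
assigned queries and the best-hit label accuracy over all queries.

Subgroup-specific residues are operationalised as a frequency contrast, the
statistic behind subfamily-logo analyses: at each column, the modal residue
of the in-group is called specific if its in-group frequency is at least
`in_threshold` (default 0.7) and its out-group frequency at most
`out_threshold` (default 0.2).  The comparison scheme follows the family
structure: NEU1 and NEU5 are each contrasted with NEU2+NEU3+NEU4 pooled;
NEU2, NEU3 and NEU4 each with the other two pooled.  Calls are reported in
the coordinates of a designated in-group reference (e.g. the human member).

## WAG+Gamma phylogenetics

Substitution follows a reversible continuous-time Markov chain
`Q_ij = S_ij π_j` with the WAG exchangeability matrix `S` and its published
stationary frequencies `π`, scaled so the expected rate at stationarity is
one (branch lengths are expected substitutions per site).  Rate variation
across sites uses Yang's discrete-gamma approximation with K = 5
equiprobable categories whose rates are the conditional category means
(the category-median variant is available by option).  Two shape values are
stage defaults: α = 5 for pairwise divergence estimates and α = 2.6845
(a value typical of maximum-likelihood estimates on real sialidase
alignments) for tree inference; the two are stage-specific conventions and
are deliberately not reconciled.  Transition matrices
are computed by symmetric eigendecomposition of `D^{1/2} Q D^{-1/2}`
(D = diag π), with round-off negatives clamped to zero.

Pairwise distances maximise the likelihood of the aligned residue-pair
counts over d ∈ [1e-8, 50] by bounded scalar optimization (tolerance 1e-6);
columns gapped or ambiguous in either row are skipped pairwise.
Between-subgroup divergence is the mean distance over all cross pairs on
the coverage-filtered columns, with a standard error from a site bootstrap
(columns resampled with replacement; 500 replicates by default — an
analytic SE was not reproducible, so the bootstrap is used and labelled as
such).

Tree inference: pairwise ML distances feed neighbour joining and BioNJ
(both implemented on a shared agglomeration core; BioNJ uses Gascuel's
variance-weighted reduction), branch lengths are optimised coordinate-wise
by Brent search against cached pruning messages (a sweep that fails to
improve the exact log-likelihood is rolled back, so the search is
monotone), and the topology is refined by nearest-neighbour-interchange
hill climbing; with `start="both"` the higher-likelihood result wins.  The
likelihood engine is standard Felsenstein pruning with site-pattern
compression, per-site scaling against underflow, and per-site averaging
over the equal-probability gamma categories.  Bootstrap supports resample
alignment columns, rebuild a tree per replicate, and report the percentage
of replicates containing each bipartition of the point tree.  All
stochastic steps take explicit seeds and are deterministic given them.

## Phosphorylation-site conservation

Predicted phospho-sites (an upstream predictor's output, consumed as a
TSV of protein / position / residue) are mapped to alignment columns;
equivalent positions across proteins collapse.  A column counts as
phosphorylatable in a sequence if S, T or Y occurs there, regardless of
which residue was predicted.

Three tests are applied per column:

- **Global conservation** — one-sided exact binomial: k = number of S/T/Y
  residues in the column, N = number of sequences (constant across columns,
  gaps counting as non-phosphorylatable — this is the faithful convention;
  an alternative non-gap-N mode is available), p = the alignment-wide S/T/Y
  frequency over all non-gap residues.  The upper tail P(X ≥ k) is computed
  from the exact distribution, never a normal approximation.
- **Subgroup-specific conservation** — two-sided Fisher exact test on the
  2×2 table (subgroup vs the four others pooled) × (phosphorylatable vs
  not), by the point-probability rule.
- **Taxon-specific conservation** — the same Fisher construction for each
  nested taxonomic group against all remaining sequences.

All p-values are Bonferroni-corrected with family size m = the number of
distinct tested columns, applied separately to the binomial family and to
each Fisher grouping scheme (the family partition is configurable, since it
is a genuine analysis choice).  Flags are raised only for columns that are
both significant (corrected p < 0.01) and conserved at ≥ 60 % (or ≥ 90 %)
in the relevant group; "subgroup-only" calls additionally exclude globally
conserved columns.

The background is always computed from the input alignment itself (S/T/Y
count over all non-gap residues); for typical protein composition it lands
near 0.16, and the WAG stationary value is 0.166.

## Sequence features

- **Motifs.**  The Asp-box `S-x-D-x-G-x-x-(W/F)` and the N-terminal
  `(T/F)-Y-R-(I/V)-P` signature are scanned on ungapped sequences with all
  overlapping starts reported.  Hits are grouped into aligned locations by
  single-linkage over column-span overlap (≥ 1 shared column), and per
  subgroup the fraction of sequences with an intact motif at each location
  is reported.
- **Catalytic residues.**  The six essential positions (arginine triad
  R21/R237/R304, nucleophile pair Y334/E218, acid/base D46, in human NEU2
  numbering) are checked for strict identity with the reference in the
  aligned column — identity, not similarity class, because complete
  conservation is the biological expectation.  The same machinery accepts
  any position/residue table (e.g. the NEU1–cathepsin-A interaction
  residues).
- **Loop lengths.**  A loop defined by reference residues [s, e] is
  measured in another sequence as the number of its residues strictly
  between the alignment columns of the reference flanks s−1 and e+1, so
  insertions inside the loop are counted; loops touching a reference
  terminus fall back to the loop's own columns, with a warning.  The
  shipped defaults are the ten active-site loops of the NEU2 structure
  (including the overlapping Loop 0/Loop 1 variants, both retained as
  published).
- **Exon junctions.**  Junction residues (protein coordinates) are mapped
  to alignment columns so exon structures of different genes can be
  compared in a common frame.

## The synthetic-data generator

`generate_family_scenario` produces a fully truth-tabled dataset with the
statistical structure the analysis assumes.  Defaults mirror a real
metazoan sialidase dataset: 83 sequences partitioned 37/8/19/11/8 over
five clades (the subgroup sizes of the curated family after filtering
incomplete sequences), a rooted family tree
(NEU1, (NEU5, (NEU2, (NEU3, NEU4)))) whose stem lengths give between-clade
divergences of the observed magnitudes (≈ 2.4–2.6 substitutions/site from
NEU1 to anything, ≈ 1.0–1.2 among NEU2/3/4, ≈ 1.5–1.7 from NEU5), ~1000
columns evolved under WAG+G (α = 2.6845, 5 categories), and planted
features:

- Asp-boxes at five aligned locations in the NEU1-like clade; boxes 2 and 3
  family-wide, box 4 also in NEU5 (echoing the partial ancestral
  conservation), an N-terminal motif everywhere;
- the six catalytic columns frozen in every sequence;
- phosphorylatable columns: 4 planted at 95 % global conservation, 2 at
  75 % (a 6-above-60 % / 4-above-90 % split of globally conserved sites),
  13 subgroup-specific at 95 % in / 2 % out, and 20 background columns;
- a 12-residue Loop 6 insertion in the NEU5-like clade and Loop 3/4
  deletions in the NEU1-like clade (the only sources of gaps — there is no
  general indel process);
- exon structures of 6/2/2/3 exons for NEU1/2/3/4 and heterogeneous 3–5
  for NEU5.

Catalytic and motif columns are overwritten after simulation rather than
evolved under site-specific selection; this is deliberately non-biological
but sufficient for testing detectors, and it is what the truth tables
describe.  Everything is bit-for-bit reproducible from (config, seed).
Passing tests on this generator therefore demonstrate correctness of the
detectors and estimators under the assumed generating process; they do not
demonstrate robustness to alignment error, compositional heterogeneity,
long-branch attraction or realistic indel patterns, none of which the
generator produces.

## Problem sizes and numerical choices

The test suite and the reproduction script run everything at sizes chosen
to keep a full run comfortably interactive on one CPU: distance-recovery
checks use 10,000-site pairs, topology-recovery uses 6-taxon trees at 400
sites (50 seeded replicates in the tests, 25 in the script), power checks
for the planted-column detector use 200 replicates of an 83 × 84 column
layout, the full-family tree is optimised once with an NJ start and a
single capped NNI round, and site-bootstrap SEs in the script use 100
replicates (the library default is 500).  Branch lengths live in
[1e-9, 20]; distances in [1e-8, 50]; scalar optimizations use bounded Brent
with tolerances 1e-6 (distances), 1e-7 (branch lengths), 1e-4 (gamma
shape).  Statistical acceptance bands are three standard errors of the
replicate mean, with SEs measured from seed sweeps.

## Known limitations

- The RBH stage automates only the reciprocal-best-hit core; the manual
  confirmations analysts typically add (similarity-matrix inspection, tree
  placement, visual checks) are exposed as reports, not automated rules.
- The NNI search is a local hill-climb from NJ/BioNJ starts; it can stop in
  local optima that SPR/TBR would escape.
- Bonferroni family partitioning (one family per grouping scheme) is a
  choice, not a law; the family size is configurable.
- The bootstrap SE for between-group divergence is a site bootstrap, not
  the analytic SE some tools print; agreement with such values is
  approximate.
- Model selection is out of scope: WAG+G is fixed (with config overrides)
  rather than chosen by information criterion at run time.
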