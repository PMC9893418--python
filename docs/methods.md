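# Methods

This note documents the statistics the package computes, the conventions
and numerical choices behind them, and what the synthetic-data generator
does and does not emulate.

## Sequence model and conventions

A coding sequence is stored over `{A,C,G,T}` (U is normalized to T on
input; reports render codons with U, the codon-table convention). The
genetic code is the standard table: 61 sense codons, 3 stops. Validation
is report-only and distinguishes frame violations, internal stops and
IUPAC ambiguity codes; ambiguous codons are skipped by codon-level
statistics rather than guessed. All positions in reports are 1-based and
inclusive.

## Codon usage, RSCU and CAI

For amino acid *i* with degeneracy *n<sub>i</sub>* and codon counts
*x<sub>ij</sub>*,

    RSCU_ij = n_i x_ij / Σ_j x_ij .

A codon of an amino acid absent from the sequence leaves 0/0; it is
reported as 0, which keeps the "unused codon" reading (count 0 ⇒ RSCU 0)
consistent. Preferred codons are strictly RSCU &gt; 1; by construction RSCU
sums to *n<sub>i</sub>* over each present family and Met/Trp sit at exactly 1.

CAI follows the Sharp–Li geometric-mean form: relative adaptiveness
*w<sub>ij</sub> = f<sub>ij</sub> / max<sub>j</sub> f<sub>ij</sub>* from a
reference usage table, geometric mean of *w* over the query's codons, with
Met, Trp and stops excluded (they carry no synonymous choice). Reference
codons with frequency exactly zero are floored at 0.5 occurrences-
equivalent on the table's own scale — the standard guard that keeps
log *w* finite — with a warning. Tables are read from the Kazusa text
layout (`UUU 17.6( 714298)` runs) or a two-column TSV.

The expected-CAI null answers "how large a CAI would base composition
alone produce?": a first-order Markov nucleotide chain is fitted to the
query's mono- and dinucleotide composition (one pseudocount per
transition), `n_reps` random sequences of the query's length are drawn
(default 500), and the null mean, s.d. and upper 95% quantile of their CAI
are reported. The chain, pseudocount and quantile are this package's
choices; they are seeded and recorded in every result object.

## Site classification and entropy

A column is *conserved* (one state), *parsimony-informative* (≥2 states,
each in ≥2 sequences) or a *singleton* (variable, not informative). Two
identities hold on every input and are property-tested: conserved +
variable = columns, informative + singleton = variable. Strict mode
excludes gap/ambiguity columns and reports their indices; the default
treats such characters as extra states (the target data are ungapped).

Column entropy is −Σ p ln p over observed state frequencies, in nats by
default. The choice of natural log matters for comparability: over eight
sequences the most even attainable state multisets (2,2,2,1,1) and
(4,1,1,1,1) give 1.56 and 1.39 nats (2.25 and 2.00 in bits). The base is
an argument. Summation is over sorted counts so row order cannot perturb
the value in the last bit. The summary reports the mean, the zero-column
count, positions ranked by entropy (descending, ties by index — the
ranking beyond clear gaps is otherwise arbitrary) and maximal zero-entropy
runs *strictly longer* than the threshold (default 10 residues).

Logo matrices use information content log2(20) − H(bits) without a
small-sample correction — an eight-row alignment would otherwise be
dominated by the correction term — and letter heights are frequency ×
column information, so heights sum to the column's information.

## Physico-chemical indices

Average (not monoisotopic) residue masses; MW reported in kDa at 2
decimals. The isoelectric point solves net charge = 0 with
Henderson–Hasselbalch terms for both termini and D, E, C, Y, H, K, R by
bisection on [0, 14] to 10⁻³ pH (the charge is monotone, so bisection
cannot fail; a 100-iteration guard exists anyway). The default pKa set is
the Bjellqvist/Expasy one, including its residue-specific terminal pKas;
an EMBOSS-style set is selectable because published pI values are
pKa-set-dependent — tools differ by up to ~0.2 pH on real proteins.
The instability index is (10/L) Σ over consecutive dipeptides of the
Guruprasad weights (the published 20×20 table, taken at runtime from
Biopython's data module); &lt; 40 is labeled stable. The aliphatic index is
X_A + 2.9 X_V + 3.9 (X_I + X_L) in mole percent, GRAVY is the mean
Kyte–Doolittle value. The hydrophobic/hydrophilic split is configurable
({A,C,F,I,L,M,V,W} vs the rest by default) because published grids use
tool-specific partitions that are rarely documented; those two columns
should be read as descriptive. Charged fractions default to −R = {D,E},
+R = {K,R,H}. Extinction at 280 nm is 5500·W + 1490·Y, plus 125 per
cystine pair in the oxidized form.

## Distances, neighbor joining, bootstrap

Protein distances use the 20-state Jukes–Cantor correction
d = −(19/20) ln(1 − 20p/19) on the mismatch proportion p. At p ≥ 19/20
the correction diverges; a sentinel distance of 10 substitutions/site is
recorded with a warning rather than NaN so downstream code never sees
non-finite values.

Neighbor joining is the standard Saitou–Nei agglomeration. Two conventions
make it deterministic: ties in the Q-criterion are broken on the
lexicographically smallest pair of cluster labels (a cluster is labeled by
its smallest leaf), and negative branch-length estimates are clamped to
zero with the deficit moved to the sibling edge, preserving the pair's
summed length. The result is unrooted (trifurcating root). NJ is exact on
additive matrices, which the tests exploit: path-length matrices of random
trees must be recovered with RF distance 0 and matching edge lengths.

Bootstrap supports resample alignment columns with replacement, rebuild
the tree per replicate, and attach to each internal node the percentage of
replicates containing its bipartition (canonicalized as the side not
containing the alphabetically first taxon). Supports are stored as
internal-node names, the convention Newick viewers expect.

## Hydropathy and topology

The hydropathy profile is an unweighted sliding mean of Kyte–Doolittle
values over an odd window, positions at window centers. Transmembrane
calling takes maximal runs of centers above the threshold, drops runs
shorter than `min_len`, then merges surviving runs separated by fewer than
`min_gap` residues, in that order (the order is part of the contract;
with clean profiles it is equivalent to merging first). Defaults — window
19, threshold 1.6, min_len 15, min_gap 5 — are the classic conservative
Kyte–Doolittle settings for transmembrane helices; all are arguments and
are recorded in outputs. Loops between segments alternate labels starting
from the N-terminal side (extracellular by default, the mitochondrial-
carrier convention), so an even helix count puts both termini on the same
side: six helices give four extracellular and three cytoplasmic regions.
Exact boundary agreement with structure-based predictors is not claimed —
only segment counts and alternation are asserted.

## The synthetic-data generator

`simdata` emulates the *shape* of the study input: eight taxa, 308 codons
(307 sense + a fixed terminal stop ⇒ 924-nt CDS, 307-aa protein), strong
third-position G+C bias (target 0.88, matching the GC3-richest real avian
families), and a divergence level (branch scale 0.05 expected
substitutions/site per edge) that leaves roughly three quarters of
nucleotide sites conserved — the mix observed in the real family. Trees
are Yule topologies with i.i.d. exponential branch lengths. The root is
drawn codon-by-codon with P(third base ∈ {G,C}) = the GC3 target;
evolution proposes per-site changes with probability 1 − e^(−t) per
branch, transition:transversion weighted by κ (default 2), rejects
proposals creating stops, and accepts nonsynonymous proposals with
probability `omega_like` (default 0.2, i.e. strong purifying selection).

What it is not: a rigorous codon rate-matrix model. Each branch applies at
most one change per site, `omega_like` is an acceptance probability rather
than a rate ratio, and codon bias is imposed only at the root. Passing
tests on simulated families therefore demonstrate that the pipeline's
statistics behave correctly on data with known tree signal, GC3 bias and
conservation structure — not that any biological inference about real
sequences is calibrated. Real-data properties the generator does not
reproduce include hydropathy architecture (random-composition proteins
have no transmembrane segments; a separate synthetic six-helix carrier
covers that stage) and gradual GC3 erosion along branches (mutation is
unbiased, so leaf GC3 drifts a few points below the root target at the
default divergence).

A consequence documented here deliberately: with exponential branch
lengths and ~15% of nucleotide hits visible at the protein level (the
product of the nonsynonymous fraction and the acceptance probability),
sampled trees regularly contain internal edges with zero protein-visible
substitutions. Exact topology recovery from protein distances then fails
for reasons no estimator can overcome; measured recovery at 1,000 codons
is 81–88% across branch scales 0.05–0.2. Recovery is 100% on fixed trees
whose internal edges are resolvable, which the test suite checks
separately.

## Problem sizes used in tests and the acceptance script

Simulated families are 8 × 308 codons (the study shape) for profile-level
tests, 1,000 codons for recovery experiments, and 100 bootstrap/500
expected-CAI replicates — the same replicate counts the analyses use by
default. The full suite and the acceptance script each run in well under a
minute on one CPU.
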