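# Methods

## Problem and data model

A complex is a pair of protein chains; each chain is an ordered residue
list with a gap-free positional index (used by windows and matrices) and
the author residue numbering from the source file (used for reporting).
Structures are read from PDB files (first model only): hydrogens are
discarded, alternate conformations keep the highest-occupancy atom,
waters and non-amino-acid ligands are dropped, HETATM amino acids such as
selenomethionine are kept (MSE → M, other nonstandard residues → X via a
fixed name table). Residues present without coordinates stay in the
sequence, contribute sequence features, are excluded from geometry and
are labelled non-contact but remain eligible as sampled negatives.

A cross-chain residue pair is a **contact** when the minimum distance over
all heavy-atom pairs is strictly below 6.0 Å. The contact map is computed
by exact all-atom minimisation (verified in tests against a brute-force
double loop) and is the single source of ground truth everywhere,
including for the synthetic generator.

## Residue features

Sequence features per residue (64 values): identity one-hot over the
22-symbol alphabet (20 standard residues alphabetically, then X, then the
gap symbol used only for window padding), 20 profile log-odds, 20 profile
frequencies, information content, and conservation defined as
1 − H(f)/log 20 of the frequency column. Profiles come from PSI-BLAST
ASCII PSSM files when available; otherwise a deterministic pseudo-profile
uses the residue's BLOSUM62 row as log-odds and the background-weighted
softmax f<sub>b</sub> ∝ q<sub>b</sub>·2<sup>s<sub>b</sub></sup> as
frequencies (background: Robinson & Robinson).

Structural features per residue (15 values): an 8-class secondary
structure one-hot (H, G, I, E, B, T, S, –) from an internal Kabsch–
Sander-style assigner (electrostatic backbone H-bond criterion at
−0.5 kcal/mol, n-turns → helices, bridge patterns → strands, bends by the
70° C-α angle rule); relative solvent accessibility from an internal
Shrake–Rupley implementation (probe 1.4 Å, 120 sphere points, standard
van-der-Waals radii, normalised by the Tien et al. theoretical per-residue
maxima and clipped to [0, 1]); half-sphere exposure up/down counts and
contact number over C-α neighbours within 12 Å, with the hemisphere axis
along C-α→C-β (backbone-bisector pseudo-C-β for glycine); and three
scalar descriptors — Kyte–Doolittle hydrophobicity, a protrusion proxy
(neighbour-count deficit relative to the most buried residue of the
chain) and a depth proxy (normalised proximity of the C-α to the chain
centroid). These replace the external feature binaries of comparable
pipelines; every provider is swappable and file readers can ingest
externally computed profiles instead.

## Environments

* **Sequential:** an 11-residue sliding window concatenates the sequence
  features of positions i−5 … i+5; out-of-range slots hold a padding
  vector whose gap one-hot is set, so vector lengths are constant.
* **Structural:** two residues are neighbours when their cells share a
  facet in the Voronoi diagram of all the chain's C-α atoms, computed as
  the dual Delaunay tessellation (scipy). Up to four points the graph is
  the complete graph; coplanar degeneracies are resolved by a seeded
  jitter of 10⁻⁴ Å; residues without C-α are neighbourless and flagged.
  Each real single-residue feature contributes its neighbourhood (sum,
  mean, max, min); each one-hot contributes its element-wise neighbour
  sum; an empty neighbourhood yields zeros plus a missing flag. The
  diagram is computed per chain (features are per-partner), and hull
  edges are not pruned.
* **Pairwise (step 2 only):** for a pair (i, j) with score matrix F, the
  same four aggregations are applied to F(r, j) over r ∈ N<sub>i</sub>,
  to F(i, s) over s ∈ N<sub>j</sub>, and to F(r, s) over
  N<sub>i</sub> × N<sub>j</sub> (mean divided by |N<sub>i</sub>|·|N<sub>j</sub>|)
  — 12 values per pair.

A structural residue block is therefore 11×64 window columns + 15
structural singles + 226 Voronoi-environment columns + 2 missing-data
flags = 947 columns; sequence-only mode uses the 704 window columns.
Column names follow `family.detail.stat` so importance can be pooled per
family. A pair vector concatenates the two residue blocks in pair order.

## Two-step classifier

Both steps are XGBoost binary-logistic boosters (defaults: depth 6, 500
rounds, learning rate 0.1, subsample 1.0, single thread, `hist` trees;
all overridable). Because (α, β) and (β, α) name the same pair, each
sampled pair enters training in both orders, and at prediction the two
orders' scores are averaged — end-to-end prediction is exactly symmetric
under chain swap, by construction. Training rows are canonically sorted
by (complex, i, j, ordering) so results are invariant to input row order.

Class imbalance: all contacts are kept and 3× as many non-contacts are
drawn per complex, uniformly without replacement, from a per-complex RNG
substream keyed by a hash of the complex id (adding a complex never
shifts another's draw). Evaluation never samples.

Step-2 features are the step-1 features plus the pair's symmetry-averaged
step-1 score and its 12 pairwise-environment values (score only in
sequence mode); for the BA ordering the "neighbours of the first residue"
block refers to β, so the two 4-blocks are swapped, keeping the mirror
symmetry exact. During training the step-1 scores come from K-fold
out-of-fold prediction over complexes (default K = 5) so step 2 never
sees scores from a model that saw the same complex. This is a design
choice; it introduces a mild distribution shift (out-of-fold scores at
training time, full-model scores at test time) that is visible on easy
data (see limitations).

## Pair → site scoring

With all n = |A|·|B| pair scores sorted descending, Is(α) sums, for
i = 0 … ⌊log₂ n⌋, the count of pairs containing α among the top-2^i pairs
divided by 2^i. Buckets are tie-inclusive: a bucket counts every pair
scoring at least as high as its 2^i-th ranked pair. For distinct scores
this is the plain top-2^i bucket; under ties it is deterministic and makes
a symmetric homodimer matrix yield identical profiles for both chains,
which a positional tie-break cannot guarantee. The score depends only on
the score ordering (rank-based) and is monotone: raising any pair score
involving α never lowers Is(α).

Site scores are smoothed along the sequence with weights (¼, ½, ¼),
termini renormalised, then optionally mapped to an expected precision by
isotonic regression (pool-adjacent-violators, clipped to [0, 1]) fitted
on out-of-fold site scores versus interface labels; smoothing precedes
calibration. The mean- and max-pair-score baselines are provided for
comparison.

## Evaluation

Leave-one-complex-out: for each complex both steps are retrained on all
other complexes' sampled pairs and the left-out complex is scored over
every pair. Pair metrics: ROC-AUC averaged over complexes (unweighted
mean over complexes with ≥ 1 contact; single-class complexes are skipped
from the average but kept in pooling) and pooled over all scores, plus
pooled PR-AUC (step-wise interpolation, i.e. average precision).
Site metrics: the same AUCs over per-residue scores and labels (a residue
is interface when it has ≥ 1 contact), plus MCC, precision, recall,
specificity and NPV at the threshold maximising MCC (scan over all
distinct scores, prediction score ≥ t, ties resolved to the lowest
threshold). ROC-AUC is cross-checked against the Mann–Whitney rank
formulation to 10⁻¹².

Partner specificity: chains are grouped into equivalent proteins by
global-alignment sequence identity > 90 % (BLOSUM62, gap −10/−0.5,
identity over aligned length). For each protein seen in ≥ 2 interactions,
the scores of its own interface residues form the specific sample, and
the scores of residues that are interfaces only in the protein's other
interactions (mapped through the alignment) form the non-specific sample;
the pooled samples are compared with a two-sided Mann–Whitney U test
(exact enumeration when both samples ≤ 8 without ties, otherwise the
normal approximation with tie correction; the all-tied degenerate case
reports p = 1).

## Synthetic data generator

The generator emulates just enough of a real complex for the pipeline to
be exercised end to end: ideal-geometry backbones (N, CA, C, O and an
ideal C-β except glycine) built from canonical φ/ψ templates (helix
−57/−47, strand −139/135, coil −78/149), with chain A aligned along x and
chain B rigidly placed crossing above it. The crossing height, angle and
roll are scanned over a deterministic grid until the residues within the
6.0 Å rule are exactly a designated contiguous block per chain (an
infeasible request raises an error; the benchmark redraws a fresh recipe
deterministically). Ground truth is always recomputed from the emitted
coordinates. Two crossing helices cannot produce a contiguous contact
block (faces alternate around the helix axis), so benchmark sets default
to strand and coil templates; the helix template remains available for
backbone/secondary-structure fixtures.

Synthetic profiles emulate conservation: interface residues draw, with
probability equal to the informativeness parameter, a frequency column
concentrated on their own amino acid (Dirichlet α = 25 on the residue,
0.2 elsewhere), and otherwise the same near-uniform column (Dirichlet
α = 2) as non-interface residues; at informativeness 0 the classes are
generated identically. Columns are quantised to integer percentages
summing to 100 so the PSI-BLAST ASCII writer/reader round-trips them
losslessly; integer log-odds are 2·log₂(f/q) rounded and clipped.

What passing tests on this generator do **not** show: the features are
conditionally independent given interface membership, interfaces are
contiguous sequence blocks, chains are short (14–22 residues) and there
is no homology, flexibility or experimental noise — so absolute metric
values on the synthetic benchmark say nothing about performance on real
complexes; only the mechanics (encodings, stacking, scoring, evaluation
protocol) are validated.

## Problem sizes and numerical choices

The test suite and the acceptance script run the leave-one-out study on
12 synthetic complexes at informativeness 0.9 with a reduced boosting
budget (120 rounds, depth 4, 4 stacking folds) — the package's desk-scale
configuration; library defaults remain 500/6/5. Calibration requires ≥ 4
complexes and ≥ 2 site classes, else it is skipped. Seeds propagate
through `numpy.random.SeedSequence` substreams (per complex, per
benchmark slot), XGBoost runs single-threaded with a fixed seed, and
retraining with identical inputs reproduces scores to ≤ 10⁻⁹.

## Known limitations

* The internal secondary-structure assigner approximates the reference
  eight-class algorithm; class boundaries can differ near chain termini
  and irregular geometry.
* On the synthetic benchmark step 1 is already near its ceiling (pooled
  pair ROC-AUC ≈ 0.99); in that regime the step-2 re-scoring and the
  rank-based site score show no headroom over step 1 or over the
  max-score baseline — their advantages are tied to the noisy-score
  regime they were designed for. The corresponding ordering checks in the
  acceptance tests document this honestly rather than being relaxed.
* Sequence-only mode restricts features to the windowed sequence block;
  geometric modules (Voronoi environments, HSE, SASA) require
  coordinates.
* mmCIF assemblies, symmetry expansion and multi-model averaging are out
  of scope (first model only).
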