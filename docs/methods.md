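# Methods

## Genomic model

Coordinates are 0-based half-open internally (BED convention); files
printed 1-based inclusive are converted on read and can be rendered
back (`to_inclusive`).  Gap regions are the complement of the sorted,
non-overlapping TADs of one chromosome: gap 1 runs from the chromosome
origin to the first TAD start, and each later gap sits between two
consecutive TADs.  Zero-length gaps (abutting TADs) are dropped and do
not consume an ordinal; the count of dropped gaps is reported because
roughly half of real TAD calls abut.  The region after the last TAD is
not a gap by default (configurable).  A gene belongs to a domain only
when its body is entirely contained in exactly one TAD or gap; genes
touching two domains or a boundary are excluded and carry a reason
code.  Genomic distance between genes is measured midpoint-to-midpoint
(rounded down; interval start is available as an alternative anchor).
Strand is ignored throughout.

## GO similarity

The OBO reader (via obonet) keeps `is_a` and `part_of` edges, collapses
any other relation to `is_a`, resolves `alt_id`s and skips obsolete
terms.  Annotations are filtered to the six experimental evidence codes
EXP, IDA, IPI, IMP, IGI, IEP, and the three namespace roots are
removed, since a root annotation carries no information.

Term similarity is the Wang hybrid semantic-value scheme: term *t*'s
S-value over its ancestor closure is S_t(t) = 1 and
S_t(a) = max over children c of a on paths to t of w_e · S_t(c), and

    sim(t1, t2) = Σ_{a ∈ anc(t1) ∩ anc(t2)} (S_t1(a) + S_t2(a))
                  / (SV(t1) + SV(t2)).

Two edge-weight backends exist.  `wang` uses fixed decay weights
(is_a 0.8, part_of 0.6).  The default `topo` weight is
w = 1/(c + n_children(parent)) + w₀ with c = 0.67 and w₀ = 0.4 (is_a)
or 0.3 (part_of), capped just below 1 — edges into sparsely branching
terms decay less, in the spirit of GOGO-class tools; exact parity with
any external binary is not claimed, which is why the backend is
pluggable.  Gene pairs are aggregated by best-match-average over their
two filtered term sets within one namespace (the average-of-directional
-means variant is selectable); a gene with no terms in the namespace
makes the pair undefined and it is dropped with a logged count.

## Pair statistics

Intra-domain pairs are all unordered pairs of genes assigned to the
same TAD (or gap); inter-domain pairs are seeded uniform samples of
pairs from different domains of the same kind.  Likely duplicates
(identity > 90 % — strictly — and e-value < 0.01) are removed from both
sets, which are then down-sampled to equal size.  Distance bins are
half-open [k·s, (k+1)·s).  Distributions are compared by the two-sided
Wilcoxon rank-sum (Mann–Whitney U) test, normal approximation with tie
correction, with significance tiers at 0.0001 / 0.001 / 0.05.  GESS is
computed on log2(count+1) scales, normalised by the dataset's log-range
and clipped to [0, 1]; the functional-vs-expression correlation is
Pearson's r over pairs with functional similarity above a threshold
(default 0.2), requiring ≥ 3 surviving pairs.

## FSN communities

An FSN has an edge when the pair's similarity is ≥ the threshold
(inclusive; thresholds 0.5, 0.7 and 1.0 are exercised).  Genes without
scores are absent, not isolated.  Communities come from divisive
Girvan–Newman removal with *unweighted* edge betweenness, cutting the
dendrogram at maximum modularity (ties toward fewer communities;
connected components are the coarsest candidate partition).  The
same-TAD-belonging ratio divides the number of distinct TADs
represented in a community by its member count; members without a TAD
assignment are dropped with a log line.  Random baselines draw
size-matched node sets uniformly without replacement.

## Spatial networks

Gene-pair contact counts sum the binned matrix over all unordered bin
pairs in which the two gene bodies overlap (≥ 1 bp) — a mean-per-bin-
pair variant sits behind a flag.  Raw counts build the networks;
normalised maps are reserved for long-range detection.  HiC-GGSI keeps
pairs with contacts ≥ t₁ and distance ≥ t₂ (both inclusive); isolated
genes are not nodes.  HiC-TAD-GGSI keeps every HiC-GGSI edge and adds
same-TAD pairs beyond a (separately configurable) distance threshold,
with per-edge provenance.  Topology metrics (degree, clustering,
closeness within components, shortest-path histogram) use standard
definitions on the undirected simple graph.

## Linear graph autoencoder

The encoder is the single linear map Z = ÃW on
Ã = D^{−1/2}AD^{−1/2} (zero-degree rows stay zero; self-loops are NOT
added before normalisation by default, matching the equation as
stated — an A+I flag exists).  The decoder is Â = σ(ZZᵀ).  Edges are
split 7:2:1 (val = ⌊0.2 m⌋, test = ⌊0.1 m⌋, remainder to train) with
disjoint, size-matched non-edge samples for validation and test; all
remaining non-edges act as training negatives through the dense
training adjacency.

The objective is the *total* (summed over all node pairs) binary
cross-entropy between Â and the training adjacency, with positives
up-weighted by (#pairs − #edges)/#edges.  The sum scaling is a
deliberate numerical choice: with a per-pair mean, full-batch plain
gradient descent at the default learning rate 0.001 produces vanishing
updates at these network sizes, while the summed objective trains to
convergence within the default 200 epochs.  `loss_curve_` reports the
per-pair mean for readability.  Weights are Glorot-uniform initialised
from the seed; training is deterministic given the seed, and a
non-finite loss raises a divergence error.  Defaults: d = 128,
lr = 0.001, 200 epochs, full batch.  Held-out positives and negatives
are scored by their Â entries; AUC is the rank-based ROC area and AP
the step-interpolated precision–recall area (scikit-learn).  The
repeat protocol re-splits with a derived per-repeat seed 10 times and
reports mean ± t_{0.975, n−1}·s/√n.

## Function inference

Reconstructed networks keep pairs with Â strictly above 0.6.  For a
central gene (its own annotations hidden), every term annotating a
radius-one neighbour is scored by its occurrence count — the number of
neighbours carrying it, annotations de-duplicated per gene.  Edge
confidences do not enter the score; they only break ties (summed
confidence of the supporting edges, then term id).  Top-k evaluation
takes, per gene, the maximum semantic similarity over the k predicted ×
true term grid and averages over all genes used once as the centre;
genes with no true terms or no predictions are excluded with a log
line.  Top-4 can never score below top-1.

## Long-range regions

Bin pairs of the normalised matrix at distance ≥ the threshold
(presets 3.2 / 6.4 / 9.6 / 40 Mbp; distance = difference of bin start
coordinates) are labelled strong (≥ 10) or weak (0 < c ≤ 0.2); other
pairs are dropped.  A bin's gene group is every gene overlapping it by
≥ 1 bp; a gene in both bins joins both groups but never pairs with
itself.  Group similarity is the symmetric average-of-best: each
gene's best cross-group pair similarity, the two directional means
averaged — the symmetric form was chosen because a one-directional
"average of the best" is ambiguous.  Pairs scoring ≥ 0.5 are reported
with their member genes.  Inter-chromosomal gene pairs are ranked by
raw contact count (ties by id).

## Synthetic data

The generator emulates one desk-scale chromosome: 10 TADs with mean
length 0.8 Mbp (sd 0.15 Mbp), separated by exponential gaps of which
half are zero-length; ~300 genes (exponential bodies, mean 15 kbp)
placed proportionally to domain length, plus a 4 % boundary-straddling
fraction that assignment must exclude.  Each TAD owns a functional
module — a coherent six-term subtree of a random BPO DAG (40 background
terms; small CCO/MFO trees complete the three namespaces).  A gene
draws each of its 3 terms from its TAD's module with probability
p_intra = 0.7, otherwise from the background (gap genes hit a random
module with p_inter = 0.15); 15 % of annotations carry the IEA code to
exercise the evidence filter, and no annotation uses a root term.

Hi-C expected counts are c₀·d^(−α) with c₀ = 200, α = 1 in bin units at
40 kbp resolution, multiplied by β = 4 within TADs, plus flat blocks
(strength 400 and 300) between two planted loop TAD pairs whose TADs
share one module; raw counts are Poisson draws and normalisation is a
single global rescale by the mean nonzero count — deliberately simple,
but sufficient to exercise the ≥ 10 / ≤ 0.2 thresholds.  Expression is
a module-specific base (2^U(3,10)) times lognormal noise (σ = 0.25), so
same-module pairs have higher expected GESS.  Three percent of genes
form planted duplicate pairs (identity > 90, e-value ≪ 0.01) over a
background of sub-threshold pairs.

The negative control (`SimConfig.negative_control()`) sets
p_intra = p_inter, β = 1, removes the loops *and* assigns modules to
genes at random, independently of TADs — without the last step a gene's
module draws still concentrate on its own TAD's module and residual
intra-TAD coherence survives, so the decoupling is what makes intra and
inter pairs exchangeable under the null.

All stage randomness derives from one master seed through stable
per-stage seeds (`derive_seed(master, stage, repeat)`).

What the generator does not emulate: read-level Hi-C noise and matrix
balancing (ICE/KR), realistic GO term depth and annotation sparsity,
inter-chromosomal contact structure, overlapping/nested TAD
hierarchies, and sequence-level duplication.  Passing recovery tests
therefore show that the pipeline detects the planted relationships at
realistic effect directions and scales — not that the effect sizes
match any particular organism.

## Problem sizes and tolerances

Tests and recovery checks run on the 10-TAD / ~300-gene chromosome with
similarity computations capped at a few hundred pairs per set and FSN
construction at 120 genes — sizes chosen so the whole suite exercises
every stage in well under a minute of similarity math and a few seconds
of autoencoder training per network.  The Wilcoxon comparison uses the
asymptotic tie-corrected form (exact enumeration is the test oracle at
small n).  Degenerate inputs fail loudly: empty samples, max = min
expression ranges, < 3 correlation points, < 10 edges to split,
non-symmetric adjacencies and absent central genes all raise typed
errors rather than returning defaults.
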