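# Methods

`ptmct` predicts whether two post-translationally modified sites on the
same protein take part in a crosstalk event. The prediction is the
weighted combination of three base classifiers that see the pair through
different representations: a cross-attention network over sequence-embedding
windows plus attention-map pair features, a graph isomorphism network (GIN)
over the sites' structural microenvironments, and a random forest over
hand-crafted geometric and network descriptors.

## The model

### Sequence classifier

For a site pair (i, j), two 11-row windows `X_i`, `X_j` of residue
embeddings (positions p−5..p+5, zero rows beyond the termini) are fused by
a two-layer cross-attention network. Each layer computes, per head m of 5,

    Q_i = H^{l-1} W_Q + b_Q,  K_j = X_j W_K + b_K,  V_j = X_j W_V + b_V
    H_m^l = softmax(Q_i K_j^T / sqrt(d)) V_j,            d = 256

concatenates the heads, projects them back to the embedding width, adds the
residual and applies per-row layer normalisation. The centre row `h1` of the
final output is concatenated with the pair feature `X_ij` — the scores
(A[i,j], A[j,i]) taken from every attention map of the language model; with
the reference 33-layer/20-head geometry that is 660 maps and 1320 values —
and classified by `softmax(LeakyReLU(BatchNorm(h2 W1 + b1)) W2 + b2)`.
The head is exactly this composition of two affine maps around batch norm
+ LeakyReLU (sometimes loosely described as a three-layer fully connected
network; the formula is authoritative here).

The formulas are asymmetric in (i, j). The N-terminal site always provides
the query stream; pairs are stored in canonical position order so the
output is deterministic. Users wanting a symmetric score can average both
orders.

### Graph classifier

Each site's microenvironment is its 10 nearest residues by Cα distance
(ties broken towards lower residue numbers). The pair graph joins the two
sites and both microenvironments with three edge kinds only: site–site,
site–own microenvironment, and chemically interconnected residues *within*
one microenvironment. "Chemically interconnected" is concretised as a
minimum heavy-atom distance of at most 5 Å (configurable), capturing
covalent neighbours and tight non-covalent contacts. Node features are the per-row
normalised structural embeddings.

The GIN update is
`h_v ← f_Θ(h_v + max_u h_u)` with an affine `f_Θ` and elementwise max
aggregation — a deliberate variant of the canonical GIN, which would use
sum aggregation with a (1+ε) self-weighting. The readout concatenates the final node
features into a fixed 22-slot layout (site i, site j, the two
microenvironments by ascending distance). Variable node counts are handled
by zero-filling absent slots and letting a node shared by both
microenvironments fill each of its slots; the concat readout needs a fixed
input width, and zero-fill/duplicate-fill is the package's convention.
Training minimises the flooded cross-entropy `|L − b| + b` with flood level
b = 0.017, which bounds every training loss below by b.

### Descriptor classifier

Ten residue-level descriptors are computed per site:

* **circular variance** (radius 10 Å over heavy atoms, own residue
  excluded): `1 − ‖Σ u_k‖/n` over unit vectors to the neighbours; 0 =
  protruding, 1 = enclosed.
* **OPD chirality index** for N ∈ {5, 7, 10, 15} nearest Cα (target
  included): the Osipov–Pickup–Dunmur G0 pseudoscalar averaged over all
  ordered quadruples, with unit-normalised displacements. Exhaustive
  enumeration is exact and cheap (C(15,4) = 1365 quadruples). Zero for
  coplanar points, negated by reflection.
* **accessible shell volume / minimum inaccessible radius / pocketness**:
  multiscale grid-probe measures (grid 1.0 Å, probes 2–10 Å, van der Waals
  radii per element). A grid point's clearance is the largest probe that
  can sit there; a point is *coverable* by probe r if it lies inside some
  validly placed r-sphere (computed with a Euclidean distance transform).
  The shell volume counts small-probe-accessible points within 10 Å of the
  Cα; the minimum inaccessible radius is a graded burial depth,
  `(r_max + 1) − r*` with r* the largest probe that can touch the residue
  (1 = fully exposed, r_max + 1 = sealed); pocketness is the mean fraction
  of larger probes that cannot cover a small-probe-accessible shell point.
  These three algorithms follow the standard multiscale grid-probe
  constructions and are fully specified by the parameters above; other
  implementations of the same descriptor names may differ in detail. The grid
  is built in the principal-axis frame of the atom cloud, making the values
  rigid-motion invariant up to floating-point error (axes are oriented by
  the sign of the third moment; near-symmetric structures may flip an axis,
  which changes the values only at discretisation level).
* **Ollivier–Ricci curvature** on the Cα contact graph (8 Å cutoff):
  κ(x,y) = 1 − W1(μ_x, μ_y)/d(x,y) with uniform neighbour measures, no
  laziness, hop metric, and W1 solved exactly as a linear program — graphs
  are small enough that no Sinkhorn approximation is needed. The node value
  averages the incident edges.
* **multifractal (sandbox) dimension**: least-squares slope of log |B(v,r)|
  against log r, r = 1..min(5, eccentricity), where B(v,r) is the
  shortest-path ball.

The pair feature vector takes (max, min, mean) over the two sites for each
residue descriptor plus the inter-site shortest path distance
(disconnected pairs are capped at L+1 to stay finite) — 31 values — and is
classified by a 500-tree random forest (other forest hyperparameters at
library defaults). All four OPD neighbourhood sizes enter as separate
features.

### Integration

    P_str = α P_graph + (1 − α) P_site
    P     = β P_seq   + (1 − β) P_str

with α = β = 0.65 and decision cutoff 0.15 as the default weighting. The
cutoff is small because negatives heavily outnumber positives in real site
tables. A pair exactly at the cutoff is called crosstalk (a fixed
convention); all three constants are configurable.

## Embedding providers

All embeddings flow through one provider contract (residue embeddings,
attention maps, structural embeddings, fixed layout descriptor). Real
protein-language/structure models plug in behind the same contract; the
package ships a deterministic synthetic provider whose residue embeddings
are seeded functions of (position, residue), whose attention rows are
seeded positive vectors normalised to sum one, and whose structural
embeddings combine a soft Cα-distance histogram (exactly rigid-motion
invariant) with a seeded residue-identity code. The pair-feature layout is
versioned (layer-major, head, then A_ij before A_ji) and models refuse to
load against a provider with a different layout hash.

## Evaluation protocol

Negative candidates are all site pairs within a protein minus those whose
*both* sites occur in the positive set. Cross-validation is 10-fold, either
sample-based or protein-based (all pairs of a protein share a fold, so
validation proteins are unseen). Seven metrics are reported (AUC, AUPR,
MCC, F1, recall, precision, ACC) at the 0.15 cutoff. The significance test
draws ten stratified 70% subsamples, computes AUC/AUPR per method, checks
both value vectors with Anderson–Darling at 0.05 and applies a paired
t-test when both pass, otherwise a Wilcoxon rank-sum test — the pairing of
a paired test with an unpaired alternative is deliberate: with non-normal
values the resample-wise pairing is not relied upon.
Control sets (Set-random, Seq-control, Str-control) keep all positives and
draw equally many negatives, either uniformly or matched to the positives'
sequence/structural distance distribution by decile bins with nearest-bin
fallback. Decile matching leaves a small within-bin residual, so a pure
distance feature drops towards — but not exactly to — chance on its
matched control.

## Synthetic study conditions

The generator emulates the reported directional properties of crosstalk
pairs without imitating real chemistry. Structures are ideal α-helices
(rise 1.5 Å, 100°/residue, radius 2.3 Å) or self-avoiding coils (3.8 Å
steps, 4 Å non-consecutive clearance) with a minimal 4-atom backbone.
Per protein (defaults): 14 PTM sites, 12 positive and 38 negative pairs,
40 proteins ≈ 2000 pairs. Three planted effects:

* **proximity** — positive pairs concentrate on a "crosstalk hub" of at
  most 8 sites chosen so the hub's pair-distance mean tracks the configured
  shift; an exponentially tilted sampler, calibrated by bisection against a
  Monte-Carlo estimate of the subset mean, makes the negative-minus-positive
  mean Cα distance match the configured 12 Å. Negatives never have both
  sites in the positive-site set, mirroring the real negative-generation
  rule.
* **embedding shift** — residue and structural embeddings of positive-hub
  sites are displaced by 3.0 along fixed seeded unit directions. With
  unit-variance embedding noise this puts the Bayes-optimal AUC of the
  embedding channel alone near 0.98, i.e. the planted signal is strong by
  construction and the end-to-end test measures whether the models recover
  it, not whether the generator hands it to them.
* **attention bias** — attention scores between residues closer than 12 Å
  are inflated (strength 3.0) before row normalisation, so the pair feature
  carries a proximity signal as described for real language models.

With all effect sizes zero the positive and negative distance
distributions are statistically indistinguishable (verified by a KS test).

What passing the planted-signal benchmark shows: the full pipeline can
extract a strong, cleanly planted signal from held-out proteins. What it
does not show: performance on real proteins, where embeddings are not
linearly separable, structures carry prediction error, and effect sizes
are far smaller and heterogeneous.

## Problem sizes and training settings

The default learning rates (1e-5 sequence, 5e-6 graph) target real-data
scale. The end-to-end synthetic benchmark trains with learning rate
1e-3 and small epoch budgets (15 sequence / 40 graph epochs, batch 32,
early stopping on a stratified 10% validation split by AUPR with patience
5) — the configuration that converges at this data scale, chosen as part
of the study conditions. The held-out set uses 20 freshly generated
proteins (~1000 pairs) from the same generating process and the same
provider. Mini-batch size (32) and the validation fraction are package
choices.

## Numerical choices and degenerate inputs

* Attention scaling uses sqrt(d); LeakyReLU slope 0.01; batch norm uses
  batch statistics in training and running statistics at inference.
* Neighbour ties in microenvironments and OPD neighbourhoods break towards
  lower residue positions; max-aggregation over an empty neighbour set is
  defined as the zero vector (unreachable by construction).
* Circular variance with zero neighbours returns 0 (maximum exposure) with
  a warning; disconnected shortest paths are encoded as L+1.
* The two neural classifiers run on a small in-package reverse-mode
  automatic-differentiation engine over numpy, verified against central
  finite differences in the test suite; optimisation is Adam
  (β = 0.9/0.999, ε = 1e-8), fully seeded.

## Known limitations

* Single chains only; no inter-protein crosstalk; no PTM-aware structures.
* No mapping layer between sequence numbering and structure numbering:
  positions follow the coordinate file.
* The pocket descriptors measure clearance and coverability without a
  solvent-connectivity check; an interior cavity large enough to hold a
  probe counts as accessible space.
* The protein-based generalisation of the graph and descriptor classifiers
  depends strongly on how informative the structural embedding is; with
  the synthetic provider this is controlled by the planted effects.
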