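# Methods

## Model

The network is a layered directed graphical model whose structure
copies a single-scale-band HMAX: grids of nodes alternate between
*simple* stages (template selectivity) and *complex* stages
(position-invariant pooling), with one top node over object
categories. A node represents the feature content of one location: a
discrete variable whose K states are the features codable there and
whose distribution is the sum-normalised response across those
features. Arrows point downward (parents are the layer above), so the
model is generative: a category state explains fragment states, which
explain orientation states, which explain the image.

Inference is loopy belief propagation. Each node combines bottom-up
likelihoods λ (products of child messages) and top-down priors π
(weighted sums of parent messages through the conditional tables) into
a belief Bel = α·λ·π, and emits messages computed from the same
quantities. Loops arise because receptive fields overlap (stride <
pooling size), giving nodes multiple parents; propagation is run on a
fixed layerwise schedule rather than to convergence (see Schedules).

### Input front end

A bank of four 9x9 Gabor kernels (wavelength 3.5 px, envelope width
2.8 px, aspect ratio 0.3, cosine phase, zero-mean, unit L2 norm) is
applied in valid mode; absolute responses are sum-normalised over
orientation at each pixel and emitted as the λ messages of dummy input
nodes. Dummy nodes hold no belief. Locations with negligible total
energy (relative threshold 1e-9 of the image maximum, with an absolute
floor) emit the flat distribution — blank regions carry no
information, they do not carry evidence *against* features. A 140x140
image yields a 132x132 valid response map; the 125x125 input grid
(derived top-down, below) is centred on it and the surplus border is
discarded symmetrically.

### Architecture and grid chain

Grid sizes are never free parameters: they are derived top-down from
the single top node via `child = step*(parent-1) + size` per axis,
which guarantees that every pooling window fits exactly. With the
reference parameters (S3 pools 6x6 C2; C2 pools 6x6 S2 at stride 3; S2
pools 4x4 C1 at stride 1; C1 pools 10x10 S1 at stride 5) the chain is
1 → 6 → 21 → 24 → 125. All nodes of a layer share one table set,
indexed by the child's relative position inside a parent's receptive
field; sharing is by reference, so a layer pair's parameter count is
`size² · K_child · K_parent` — linear in the parent count of any single
child, thanks to the per-parent (ICI) factorisation below.

Complex-layer states come in contiguous *groups* of `k_group` states,
one group per state of the child simple layer (e.g. 40 C1 states = 4
orientation groups of 10). The contiguous layout is a design choice
(any assignment would do); it makes `group_of_state` pure arithmetic.

### Approximations

1. **Flooring.** Before multiplicative combination every message is
   floored: entries below ε_min are raised to ε_min and the added mass
   is removed proportionally from the rest, preserving normalisation.
   Default ε_min = 1e-12 — far below any meaningful probability at
   K ≤ 2500, yet high enough to keep the next bound useful.
2. **Message-count bound.** The normalisation constant of a product of
   N floored messages is at most ε_min^(−N); requiring it to stay
   below the float ceiling r_max gives
   N_max = ⌊log r_max / (−log ε_min)⌋ (≈ 25 at the defaults). When a
   node's fan-in exceeds N_max, only the N_max messages with the
   highest entry variance are multiplied. Variance is the population
   variance of the message entries; flat (uninformative) messages have
   zero variance and are dropped first, so little information is lost.
   Messages are floored before the variance ranking (the alternative
   order is not distinguishable in practice; flooring barely changes a
   message's variance). Internally the selected product is evaluated
   in the log domain purely as a numerical device — the algorithm is
   still the floored product, not a log-domain reformulation.
3. **Belief as top-down message.** The outgoing π message to every
   child is the node's belief; the exact rule would divide out the
   destination child's own λ contribution, a 1/(P+C) effect at the
   fan-ins used here. (The exact rule is retained in the tree oracle.)
4. **Sampling in π combination.** π(x) is a weighted sum over parents
   of per-parent table columns: only the m_pi highest-variance parent
   messages enter (default 16, which covers every fan-in in the
   reference architecture, so it is effectively off there), and of
   each selected message only its m_states most probable states
   (default 10). Ties in both rankings break toward the lower index
   for determinism. Parent weights are uniform w = 1/P.
5. **Multi-parent tables.** A child with P parents stores one
   K_child x K_parent table per parent (per relative position) instead
   of a joint table over all parent configurations; λ messages to a
   given parent use only that parent's table
   (λ_X(u_i=p) = Σ_x λ(x)·P_i(x|p)). This is the
   independence-of-causal-influences assumption; a Noisy-OR gate would
   not apply because the states are categorical (features), not
   ordinal.

Degenerate cases: an all-zero λ·π product (possible only under
contradictory hard evidence) maps to the uniform distribution with a
logged warning — the same "blank means uninformed" convention as the
front end.

### Learning

Training is bottom-up, greedy and layerwise: each stage freezes the
layers below, propagates the training images through them, and fits
the next table set. During learning a node is treated as parentless
when computing its belief (so beliefs equal bottom-up likelihoods; no
untrained priors enter) and single-parented when emitting messages.
There is no expectation-maximisation refinement.

* **Invariance (simple → complex), e.g. S1→C1 and S2→C2.** For each
  child state f, all stride-1 patches of the response map of f whose
  peak exceeds the threshold t (default 0.3) are clustered with
  k-means into k_group centres, using a refined start: 10 subsample
  clusterings (10% each) are pooled and themselves clustered to seed
  the final run. Everything is driven by one seed; identical seeds
  give bit-identical tables. If fewer distinct patches than clusters
  exist, the group is padded with empty prototypes (flat columns) and
  a warning is raised. Centres convert to tables by
  `column = w·onehot(f) + (1−w)·uniform(K)` at each child position —
  the linear interpolation is our resolution of the conversion rule;
  it reproduces both defining endpoints (w=1 → one-hot, w=0 → flat).
  S2→C2 learning thresholds on beliefs (for S1→C1, beliefs and λ
  coincide during learning).
* **Selectivity (complex → simple above it), C1→S2.** Prototypes are
  defined over child *groups*: the group-summed response maps are
  scanned (image order, then row-major location — fixed for
  determinism) and a patch is stored when its Euclidean distance to
  every stored prototype exceeds d_min; after each full scan d_min
  drops by 5% of its initial value and the scan repeats until K_S2
  prototypes are stored. d_min starts at the maximum pairwise distance
  over a 256-patch subsample. At d_min = 0 exact duplicates are still
  excluded; if K_S2 cannot be reached even there, the dataset is too
  small and the learner raises. Conversion replicates each group
  weight across the group's states and sum-normalises each column
  (all-zero columns become flat).
* **Top layer (supervised, one-shot).** The prototype of category c is
  the 6x6 grid of group-summed C2 beliefs for c's single training
  image, converted like any selectivity table. Duplicate labels are an
  error; identical prototypes for different categories raise a
  warning.

### Schedules

* **Feedforward categorisation**: one bottom-up pass (S1→C1→S2→C2→S3)
  with flat priors; the category is the argmax of the top belief
  (lowest index on ties, with a warning).
* **Feedback**: S1-C1-S2-C2-S3-C2-S2-C1-S1 — one full up-then-down
  sweep. Downward steps send beliefs as π messages and recompute each
  layer's belief as λ·π, retaining the λ of the upward pass (the
  schedule is sequential; λ depends only on the fixed input evidence,
  so re-running the upward pass changes nothing and one sweep is the
  default; a convergence check — max L1 belief change < 1e-6 — stops
  additional sweeps). The "post-feedback" state is read once the
  downward pass reaches S1; the top node is not re-updated afterwards.
* **Attention**: clamp the top node to the attended category and
  update top-down only (S3-C2-S2-C1-S1); intermediate layers start
  from flat likelihoods, and at S1 the descending prior multiplies the
  image evidence. A clamped node's belief and outgoing messages are a
  delta distribution, immune to every update. On a blank image this
  schedule coincides exactly with mental imagery (feedback sweep with
  a clamped top node), since all likelihoods are flat.

## Synthetic data

The generator emulates the study conditions: binary object silhouettes
(dark on white, 140x140, area 9–42% of the frame, centred up to a
±10 px placement jitter), one image per category, and a test set of
5 variations x 7 distortions per category (1050 images at 30
categories): rectangular occlusion removing 18–22% of the object's
pixels (searched occluder size; five anchor positions), 5%/10% uniform
pixel noise (exactly round(f·H·W) redrawn pixels, seeded per
variation), 10/20 px translations (up/down/left/right/diagonal, border
content cropped), and 10%/20% size reductions (nearest-neighbour,
five paste anchors). Categories cycle through ten parametric families
(square, disc, triangle, stars, cross, bars, L-shape, blobs) with
seeded jitter, rejection-sampled so every pair of categories has pixel
IoU < 0.75. Category 0 is always a plain square of side 64 — the shape
the feedback experiments reference. Everything is a pure function of
(parameters, seed).

What the generator does **not** emulate: natural-image statistics,
texture and grey-level variation inside objects, rotations or 3-D pose
changes, clutter, or any particular published photograph set. Passing
tests therefore show that the architecture learns and generalises over
silhouette shape under the seven distortions — not performance on
natural images.

The feedback stimuli: a Kanizsa square (four pacman discs with the
inner quadrants carved by the square's interior; default size 64,
radius 28, matching the square category's scale) whose ground-truth
illusory-edge pixels are the mid-gap locations at least one filter
half-width (4 px) away from the disc mouths, so they carry no
luminance gradient of their own; and pixel-wise unions of two
silhouettes for the attention experiment.

## Problem sizes used in the test suite

The unit tests run on the toy three-layer network (15+3+1 nodes),
whose tables reproduce the hand-computed messages exactly. The
end-to-end tests train one scaled-down network — 10 categories,
K_S2 = 100, K_C2 = 1000, all other parameters at the reference values,
seed 1 — and reuse it for the categorisation and feedback checks; at
this size training takes seconds and the full 350-image distorted
evaluation under a minute, while leaving the behaviour of interest
intact (100% one-shot self-consistency; every distortion far above
chance). The oracle-equivalence check runs 100 random singly-connected
networks with up to 10 nodes and 2–6 states per node, capped at ~3e5
joint-table entries so brute-force enumeration stays cheap.

## Known limitations

* **Saturated beliefs.** Multiplying tens of floored messages drives
  beliefs toward one-hot distributions. Winner identities are
  reliable, but graded structure is compressed: compared with a direct
  max-pool of the orientation maps, group-summed C1 beliefs correlate
  strongly on axis-aligned contours (r ≈ 0.95 with both sides
  expressed as orientation distributions) while on curved or diagonal
  contours only the winning orientation agrees (>84% of informative
  locations), not the graded values.
* **Short-range contour completion.** Because near-delta λ dominates π
  wherever any real contrast enters a receptive field, top-down
  feedback can only fill gaps whose interior is blank at the C1
  pooling scale — roughly one pooling cell beyond the inducing edges.
  The default Kanizsa geometry respects this; much wider gaps are not
  completed.
* **Translation robustness** degrades at 20 px (most of a C2 pooling
  cell), with large spread across displacement directions — the price
  of approximating max-pooling with learned group patterns.
* Single scale band, hard-wired Gabor front end, no EM refinement of
  the tables, no spatial-attention priors; schedules are fixed rather
  than run-to-convergence.
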