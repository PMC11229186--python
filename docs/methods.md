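# Methods

`pocketseg` predicts ligand-binding pockets from protein 3-D structure by
volumetric semantic segmentation: the structure is voxelized into an
18-channel feature grid, a dual-path encoder-decoder network assigns every
voxel a pocket probability, and connected components of the thresholded
probability grid become discrete pockets that are scored with the standard
binding-site metrics (DCC, DCA, DVO).

## Structure cleaning

Input PDB files are reduced to "pure protein" heavy-atom sets before
featurization:

* water residues (HOH/WAT/DOD and anything gemmi tabulates as water) are
  removed;
* hydrogen and deuterium atoms are removed — the feature set below counts
  heavy neighbours and has no hydrogen channel, so a heavy-atom
  representation is the consistent choice;
* HETATM records that are not part of the polypeptide (ligands, ions, buffer
  molecules) are removed, while tabulated modified amino acids such as
  selenomethionine are kept: deleting them would punch artificial holes into
  the protein body;
* for atoms with alternate locations, the first altloc is kept — a
  deterministic convention, not an occupancy-based choice.

A structure-level filter (`check_chain_limit`, default 7 chains) mirrors the
dataset curation rule that excludes complex polymeric assemblies; it is
available but not wired into the default training path, since it is a
dataset-construction filter rather than a model requirement.

## Voxel featurization

A cubic grid of 36 voxel centres per axis spanning 70 Å (centre-to-centre),
i.e. 2 Å spacing, is centred on the protein's unweighted heavy-atom
centroid. Reading the 70 Å as the per-axis extent (rather than a 70 Å
half-width) keeps voxels at pocket-scale resolution; the convention is
configurable (`GridConfig`). Each atom maps to the voxel whose centre is
nearest; exact half-way ties go to the lower index. Atoms outside the grid
are dropped with a logged count. Because the grid re-centres with the
protein, featurization is exactly translation-equivariant (tested).

Channels 0–8 are mutually exclusive element classes — B, C, N, O, P, S, Se,
halogen (F, Cl, Br, I) and metal (Li, Be, Na, Mg, Al and atomic numbers
19–32, 37–51, 55–84, 87–104) — incremented by one per atom so the channel
sum counts atoms. Channels 9–17 carry chemical properties perceived with
RDKit:

| channel | definition | encoding |
|---|---|---|
| hybridization | orbital hybridization | SP=1, SP2=2, SP3=3, SP3D=4, SP3D2=5, other=0 |
| hydrophobic | apolar carbon | SMARTS `[#6;+0;!$([#6]~[#7,#8,#9])]` |
| partial charge | Gasteiger charge | real value (non-finite values -> 0) |
| heteroatoms | attached non-C, non-H atoms | count |
| non-hydrogens | attached heavy atoms | count |
| acceptor | H-bond acceptor | standard pharmacophore SMARTS |
| aromatic | aromatic perception | 0/1 |
| donor | H-bond donor | standard pharmacophore SMARTS |
| ring | ring membership | 0/1 |

When several atoms share a voxel all channels accumulate by summation,
which preserves atom counts. The donor/acceptor SMARTS are the widely used
pharmacophore definitions (see `featurizer.py`); the exact numeric encodings
of any particular featurization program are not reproduced, so bit-parity
with tensors produced by other tools is not claimed.

Reference pockets arrive as 3-D point sets; a voxel of the label grid is 1
iff at least one pocket point maps to it. Feature and label grids share
origin and spacing exactly.

## Network

The segmentation network is a V-Net-style encoder-decoder with a second,
shallow encoder pathway and attention-based global-context layers:

* **V path**: per-stage stacks of 5×5×5 convolutions (PReLU, slope 0.25 at
  init) with stage-internal residual additions; stages are separated by
  strided 2×2×2 downsampling convolutions that double the channel width.
  Stage depths default to (1, 2, 3, 3, …): counting the downsampling
  convolutions, eight convolutions precede the attention layer of the
  default 4-stage encoder. A 2×2×1 downsampling variant exists behind a
  config switch, but the cubic kernel is the default because the grid is
  cubic.
* **L path**: one 5×5×5 convolution per stage plus the same downsampling —
  few enough nonlinear local mixings that global layout survives to the
  bottleneck.
* **Global-context ("Former") layers**: a 1×1×1 convolution followed by
  multi-head self-attention (softmax(QKᵀ/√d_k)V per head, heads
  concatenated through an output map, bias-free projections) over the
  flattened spatial positions — each voxel is a token and the channels are
  its embedding — with a residual addition of the layer input. One such
  layer sits at the middle stage of each path (9³ = 729 tokens for the
  36-voxel grid). Flattening positions into tokens, rather than channels,
  keeps d_k small and lets attention relate distant regions directly. No
  positional encodings are used: the surrounding convolutions already carry
  position information, and the residual path preserves it.
* **Exchange and fusion**: after both attention layers the V-path tensor is
  concatenated into the L path (one-way exchange, mixed back by a 1×1×1
  convolution); the final tensors of both paths are concatenated as the
  decoder input.
* **Decoder**: transpose convolutions (kernel = stride) with PReLU,
  concatenation of the V-path skip tensor at each resolution, and residual
  conv stages mirroring the encoder depths; the head is a 1×1×1 convolution
  + sigmoid, giving per-voxel probabilities in (0, 1).

Odd grid extents are floored by downsampling and restored by zero-padding
the upsampled tensor to its skip tensor's size; this defines the padding
rule that makes 36 → 18 → 9 → 4 → 2 work. Weights use fan-in-scaled normal
initialisation from a seeded generator, so construction is bit-reproducible.

The network, its attention layers and the training loop run on a compact
reverse-mode autodiff engine over numpy arrays (`pocketseg.nn`):
convolutions are im2col matrix products chunked over depth, and the three
convolution variants (same-padded, block-downsampling, block-upsampling)
have hand-written adjoints verified against finite differences in the test
suite.

## Training

The loss is the smoothed Dice loss
`1 − (2 Σ y·t + ε) / (Σ (y + t) + ε)`, averaged over the batch, with
ε = 1e-6 by default — small enough not to distort the loss at 36³ scale
while keeping the empty-empty case defined (loss 0). As ε → 0 the loss
converges to 1 − Dice coefficient (tested at ε = 1e-9 to 1e-6).

Optimisation is Adam (β = 0.9/0.999). The full-scale default learning rate
is 1e-4 with batch size 10; fine-tuning runs tenfold lower (1e-5) with all
layers trainable. The reduced toy-scale experiments (below) train at
1e-3/1e-4 — the small model both tolerates and needs a larger step over its
short epoch budget. The optimiser is a documented default; no claim is made
that it matches any particular previous implementation.

Validation uses a grouped split: all structures sharing a protein identity
(group key) land on one side, and the validation side approximates 1/10 of
the entries as closely as whole groups allow. The checkpoint with minimal
validation loss is tagged best. Checkpoints store parameters, Adam state,
epoch, the shuffling RNG state and the loss history, so an interrupted run
resumed from a checkpoint reproduces the uninterrupted history exactly
(breakpoint continuation; tested bit-for-bit).

Transfer learning: a baseline model is fine-tuned per protein fold class
(all α, all β, α+β, α/β — supplied as labels; no classifier is included)
with per-class epoch budgets defaulting to 100/200/400/500.

## Pocket extraction and evaluation

Probabilities are thresholded at 0.5 (configurable), components are
labelled under 26-connectivity, components below `min_voxels` (default 1)
are dropped, and pockets are ranked by mean probability (ties: larger
volume, then lowest linear voxel index) — deterministic by construction.
Pocket centres are unweighted centroids of member voxel centres (a
probability-weighted option exists).

* **DCC** — Euclidean distance between predicted and true centres; success
  at ≤ 4 Å. The boundary counts as a success (inclusive comparison) and is
  configurable.
* **DCA** — minimum distance from the predicted centre to any ligand atom;
  same threshold.
* **DVO** — Jaccard index of predicted and true voxel sets, computed for
  pockets whose DCC ≤ 4 Å. Both-empty Dice/DVO are defined as 1.
* **Success rate** — fraction of pockets meeting the criterion.

Because a model may emit several pockets per protein and the scoring rule
for that case is genuinely open, evaluation reports two modes side by side:
`top` (the top-ranked pocket is "the" prediction) and `any` (the best
pocket per reference after greedy one-to-one matching by centre distance).

## Synthetic data

Real corpora cannot ship with the package, so every experiment runs on
generated fixtures:

* **Toy complexes** — heavy atoms on a jittered golden-spiral shell
  (radius 12 Å, 160 atoms, elements drawn from
  {C: 0.6, N: 0.15, O: 0.15, S: 0.05, P: 0.05}) around an internal cavity
  (radius 5 Å); the cavity's 1 Å interior lattice is the ground-truth
  pocket and 1–5 pseudo-ligand atoms sit near its centre. Two shapes —
  spherical and prolate (z-axis × 1.8) — emulate distinct fold classes.
  The golden-spiral layout keeps inter-atom distances above typical bonding
  range so chemistry perception sees isolated atoms rather than spurious
  molecules.
* **Grid pairs** — feature/label pairs built directly in voxel space: a
  compact blob label (sphere or volume-matched prolate ellipsoid, radius
  side/5 voxels, jittered centre) surrounded by a 2-voxel shell of
  atom-like channel activations, plus sparse background noise. The mapping
  from features to label is learnable but not an identity.

These fixtures emulate the geometry of the task (a cavity surrounded by
protein density, imbalanced foreground) but none of real proteins'
chemistry, fold diversity, or label noise; passing the toy-scale tests
demonstrates that the pipeline's machinery — featurization geometry,
optimisation, checkpointing, extraction, scoring — is correct, not that the
default model generalises to real structures.

## Toy-scale study conditions

The reference experiments (`pocketseg.experiments`, also run by
`scripts/acceptance.py`) use a reduced configuration chosen so everything
runs in minutes on one CPU: grid 16, base width 4, two stages, two
attention heads.

* **Overfitting/trainability** — 8 grid pairs, batch 8, lr 1e-3, early stop
  at training Dice loss 0.2 within a 200-epoch budget; every training
  example's top pocket must then lie within 4 Å (2 voxels) of the true
  blob centre.
* **Transfer direction** — baseline: 10 epochs on 6 spherical + 6 elongated
  pairs (deliberately short of convergence, as a pre-trained starting
  point); fine-tune: 30 epochs on the spherical pairs at lr 1e-4; metric:
  mean Dice loss on 4 held-out spherical pairs, fine-tuned vs baseline.
  The direction (fine-tuning helps within-class) is asserted on a majority
  of seeds, not per-seed, since it is a stochastic property.
* **Breakpoint continuation** — 6 epochs, interrupted at 3, resumed;
  histories must match exactly.

## Known limitations

* CPU-only; the full-size default configuration (~5.6e7 parameters) is
  practical for inference and small fine-tuning runs, not for corpus-scale
  training.
* Chemistry perception of PDB input relies on RDKit's proximity bonding;
  exotic chemistry may fall back to partial sanitisation (rings/valence
  only).
* The fold-class labels are inputs; no structural classifier is provided.
* mmCIF, assemblies and protonation are out of scope.
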