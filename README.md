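# pocketseg

Volumetric prediction of protein–ligand binding pockets.

Knowing *where* a ligand binds is the first step of structure-based drug
design. `pocketseg` treats pocket detection as 3-D semantic segmentation:
a protein structure is voxelized into a cubic grid of chemical features, a
dual-path encoder–decoder network labels every voxel with a pocket
probability, and connected high-probability regions become discrete pocket
predictions with real-space centres and volumes. The package is aimed at
structural bioinformaticians who want a fully inspectable, CPU-runnable
implementation of this pipeline — featurization, network, training with
fold-class transfer learning, pocket extraction and evaluation — with every
step unit-tested against independent oracles.

## Method in brief

* **Featurization.** Heavy atoms of the cleaned protein (waters, hydrogens
  and non-polymer HETATM fragments removed) are mapped onto a
  36×36×36 grid spanning 70 Å per axis (2 Å voxels) centred on the protein
  centroid. Each voxel carries 18 channels: 9 element-class counts
  (B, C, N, O, P, S, Se, halogen, metal) and 9 RDKit-perceived properties
  (hybridization, hydrophobicity, Gasteiger charge, hetero/heavy neighbour
  counts, acceptor, aromatic, donor, ring).
* **Network.** A deep V-Net-style path (5×5×5 convolutions, PReLU,
  residual stages, strided downsampling) runs alongside a shallow
  global-information path; at the middle stage both paths pass through a
  hybrid layer combining a 1×1×1 convolution with multi-head
  self-attention over all voxel positions,

      Attention(Q, K, V) = softmax(QKᵀ/√d_k) V,

  after which the deep path's tensor is concatenated into the shallow one.
  The fused encoder output is decoded with transpose convolutions and skip
  connections to a per-voxel sigmoid probability.
* **Training.** Smoothed Dice loss
  `1 − (2Σ y·t + ε)/(Σ(y+t) + ε)` with Adam, grouped 1/10 validation
  splitting (all structures of one protein stay together), exact
  checkpoint/resume, and per-fold-class fine-tuning (all α / all β / α+β /
  α/β) from a baseline checkpoint.
* **Evaluation.** DCC (centre–centre distance), DCA (centre to nearest
  ligand atom), DVO (Jaccard overlap of voxel sets) and success rates at
  the 4 Å threshold, reported for the top-ranked pocket and for the
  best-matching pocket.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Generate four toy complexes (shell-of-atoms around a known cavity), train
a reduced model briefly, and predict pockets:

```bash
pocketseg make-toy --out toy --n 4 --side 16 --span 30 --seed 1
printf 'grid_side: 16\nbase_width: 4\nn_stages: 2\nattention_heads: 2\n' > net.yaml
pocketseg train toy/manifest.tsv --out run --config net.yaml \
    --epochs 40 --batch-size 3 --learning-rate 1e-3 --val-fraction 0.25 --seed 0
pocketseg predict toy/toy_sphere_1_features.npz \
    --checkpoint run/last.npz --out pred --threshold 0.5
cat pred/pockets.tsv
```

The training command prints its result summary,

```
{"epochs": 40, "best_epoch": 29, "best_val_loss": 0.13480162620544434}
```

and the final pocket table reads

```
source                  rank  volume  mean_prob  cx      cy      cz
toy_sphere_1_features   1     88      0.9985     0.204   -0.600  -0.559
```

— a single predicted pocket of 88 voxels whose centre sits 0.85 Å (well
under one 2 Å voxel) from the toy cavity's true centre at the origin. The
training label is the cavity's interior lattice, so a well-trained model
recovers the cavity as one connected component. The same objects are
available from Python:

```python
from pocketseg import (ToyComplexSpec, make_toy_complex, voxelize,
                       voxelize_label, GridConfig, extract_pockets, dcc)
from pocketseg.featurizer import protein_center

toy = make_toy_complex(ToyComplexSpec(seed=1))
grid = voxelize(toy.structure, GridConfig())           # (36, 36, 36, 18)
label = voxelize_label(toy.truth_points, GridConfig(),
                       center=protein_center(toy.structure))
```

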