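# comodseg

CPU-only implementation of a reverse co-attention, multi-modality interactive
feature learning network for 3D brain tumor segmentation, together with a
synthetic-phantom data generator so the entire pipeline is trainable and
testable without external data.

Four co-registered MR modalities (T1, T1c, T2, FLAIR) are split into two
pairs — g1 = (T1, T1c), g2 = (T2, FLAIR) — and encoded by one shared-parameter
five-level 3D encoder. A partial decoder aggregates the high-level features
(levels 3–5) of each pair into a per-pair global region-logit map. A cascade
over levels 5→4→3 turns each pair's current map into a reverse attention
weight `R = 1 − σ(M)`, averages the two pairs' weights (reverse co-attention),
gates each pair's features (`f·R̄ + 1`), fuses them channel-wise and emits
side-output maps used for deep supervision. Training minimizes
`0.7·Dice + 0.3·(weighted-BCE over the global + three side maps)` with Adam.
Evaluation reports hard Dice and the 95th-percentile Hausdorff distance per
hierarchical region (WT ⊇ TC ⊇ ET).

Everything runs on numpy/scipy: the package ships a minimal reverse-mode
autodiff core (`comodseg.autograd`) with 3D convolution, trilinear resampling
and instance normalization, verified against numerical gradients and
scalar-loop oracles.

## CLI

```bash
comodseg simulate --n 25 --out-dir data/ --seed 1 --grid 32
comodseg train    --data-dir data/ --out run/ --seed 1 --steps 200
comodseg predict  --checkpoint run/checkpoint.npz --in data/ --out pred/
comodseg evaluate --pred pred/ --gt data/ --out eval/
comodseg ablate   --modes full,g1_only,g2_only,average_fusion --data-dir data/ --out abl/ --seed 1
```

Subject layout: `<subject>/{t1,t1c,t2,flair,seg}.nii.gz` with BraTS-style
label codes (0 background, 1 NCR/NET, 2 ED, 4 ET). Training emits a
`checkpoint.npz` (config + parameters) and a JSONL loss history; evaluation
emits per-subject CSV (`subject,region,dice,hd95`) plus an aggregate JSON.

Ablation modes mirror the design study: `full`, `g1_only`, `g2_only`,
`average_fusion` (mean of the two single-pair probability maps),
`no_coattention` (independent per-pair reverse attention) and
`saliency_attention` (forward attention `σ(M)` instead of reverse).

## Defaults worth knowing

- Desk profile: 32³ volumes, base 4 filters, batch 2, 200 Adam steps at
  lr 3e-3, float32 compute — converges to held-out WT Dice ≳ 0.9 on the
  default phantom cohort in ~2 min on one CPU. The reference-scale settings
  (128³ patches, base 16, lr 1e-4) are plain config values.
- Normalization: per modality, zero mean / unit variance over nonzero (brain)
  voxels, population std; background stays 0.
- HD95: max of the two directed 95th-percentile nearest-voxel Euclidean
  distances over all foreground voxels, spacing-scaled, linear-interpolated
  percentile; undefined (NaN) when a mask is empty.
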