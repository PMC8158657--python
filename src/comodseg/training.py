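"""Dataset splitting, patch sampling, the optimization loop and ablations."""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path

import numpy as np

from . import autograd as ag
from . import metrics as metrics_mod
from . import nn
from .network import (NetworkConfig, SegmentationNetwork, binarize_prediction,
                      study_to_pair_stacks)
from .objectives import total_loss
from .phantoms import PhantomSpec, generate_cohort
from .volume_io import (HierarchicalMasks, MultiModalStudy, map_labels,
                        normalize_study)

ABLATION_MODES = ("full", "g1_only", "g2_only", "average_fusion",
                  "no_coattention", "saliency_attention")


@dataclasses.dataclass
class TrainConfig:
    """Optimization settings. Reference scale: lr 1e-4, patch 128^3, base 16.

    The desk profile (default here) trains a 32^3 / base-4 model on one CPU.
    """

    learning_rate: float = 1e-4
    patch_size: tuple = (32, 32, 32)
    batch_size: int = 2
    steps: int = 200
    split_fraction: float = 0.8
    p_foreground: float = 0.5
    alpha: float = 0.7
    master_seed: int = 0
    ablation_mode: str = "full"
    compute_dtype: str = "float32"  # float32 halves memory traffic on CPU
    network: NetworkConfig = dataclasses.field(default_factory=NetworkConfig)

    def validate(self):
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split fraction must be in (0, 1)")
        if any(s % 16 for s in self.patch_size):
            raise ValueError(f"patch dims must be divisible by 16, got {self.patch_size}")
        if self.ablation_mode not in ABLATION_MODES:
            raise ValueError(f"unknown ablation mode {self.ablation_mode!r}")


def desk_profile(master_seed: int = 0, steps: int = 200, **overrides) -> TrainConfig:
    """CPU-friendly profile: 32^3 patches, base 4 filters, a fast Adam rate."""
    cfg = TrainConfig(learning_rate=3e-3, steps=steps, master_seed=master_seed,
                      network=NetworkConfig(base_filters=4, seed=master_seed),
                      **overrides)
    cfg.validate()
    return cfg


def split_dataset(subject_ids, fraction: float, seed: int):
    """Disjoint, exhaustive, seed-reproducible split; |train| = round(f*n)."""
    ids = list(subject_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 subjects to split")
    n_train = int(round(fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError(f"split {fraction} of {n} leaves an empty train or test set")
    order = np.random.default_rng(seed).permutation(n)
    train = [ids[i] for i in sorted(order[:n_train])]
    test = [ids[i] for i in sorted(order[n_train:])]
    return train, test


def sample_patch(study: MultiModalStudy, masks: HierarchicalMasks,
                 patch_size, rng, p_foreground: float = 0.5):
    """Axis-aligned crop applied to all modalities and masks.

    With probability p_foreground the patch center is a uniformly drawn WT
    voxel (clamped so the patch stays inside the volume).
    """
    shape = study.shape
    ps = tuple(int(p) for p in patch_size)
    if any(p > s for p, s in zip(ps, shape)):
        raise ValueError(f"patch {ps} larger than volume {shape}")
    use_fg = rng.random() < p_foreground
    fg = np.argwhere(np.asarray(masks.wt, bool)) if use_fg else None
    if fg is not None and len(fg) > 0:
        center = fg[rng.integers(len(fg))]
        start = [int(np.clip(c - p // 2, 0, s - p))
                 for c, p, s in zip(center, ps, shape)]
    else:
        start = [int(rng.integers(0, s - p + 1)) for p, s in zip(ps, shape)]
    sl = tuple(slice(st, st + p) for st, p in zip(start, ps))
    vols = {m: v[sl] for m, v in study.volumes().items()}
    patch_study = dataclasses.replace(study, **vols)
    patch_masks = HierarchicalMasks(wt=masks.wt[sl], tc=masks.tc[sl], et=masks.et[sl])
    return patch_study, patch_masks


def _network_for_mode(mode: str, base: NetworkConfig) -> NetworkConfig:
    cfg = dataclasses.replace(base)
    if mode in ("full", "average_fusion"):
        pass
    elif mode == "g1_only":
        cfg = dataclasses.replace(cfg, pairs=("g1",))
    elif mode == "g2_only":
        cfg = dataclasses.replace(cfg, pairs=("g2",))
    elif mode == "no_coattention":
        cfg = dataclasses.replace(cfg, coattention=False)
    elif mode == "saliency_attention":
        cfg = dataclasses.replace(cfg, attention_mode="saliency")
    else:
        raise ValueError(f"unknown ablation mode {mode!r}")
    return cfg


@dataclasses.dataclass
class Checkpoint:
    network_config: NetworkConfig
    state: dict
    train_config: dict | None = None

    def build(self) -> SegmentationNetwork:
        model = SegmentationNetwork(self.network_config)
        model.load_state_dict(self.state)
        return model

    def save(self, path):
        payload = dict(self.state)
        payload["__config__"] = np.frombuffer(json.dumps({
            "network": self.network_config.to_dict(),
            "train": self.train_config,
        }).encode(), dtype=np.uint8)
        np.savez(path, **payload)

    @classmethod
    def load(cls, path):
        with np.load(path) as data:
            meta = json.loads(bytes(data["__config__"].tobytes()).decode())
            state = {k: data[k] for k in data.files if k != "__config__"}
        return cls(network_config=NetworkConfig.from_dict(meta["network"]),
                   state=state, train_config=meta.get("train"))


def _prepare(cohort):
    """Normalize studies and derive region masks once."""
    prepared = []
    for study, labels in cohort:
        prepared.append((normalize_study(study), map_labels(labels)))
    return prepared


def train(config: TrainConfig, cohort, log_stream: io.TextIOBase | None = None):
    """Adam on the composite loss; returns (Checkpoint, history list)."""
    config.validate()
    if not cohort:
        raise ValueError("training cohort is empty")
    with ag.use_dtype(config.compute_dtype):
        return _train_inner(config, cohort, log_stream)


def _train_inner(config, cohort, log_stream):
    net_cfg = _network_for_mode(config.ablation_mode, config.network)
    model = SegmentationNetwork(net_cfg)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 0xC0DE]))
    prepared = _prepare(cohort)
    history = []
    for step in range(config.steps):
        stacks = {pid: [] for pid in net_cfg.pairs}
        targets = []
        for _ in range(config.batch_size):
            study, masks = prepared[rng.integers(len(prepared))]
            pstudy, pmasks = sample_patch(study, masks, config.patch_size, rng,
                                          config.p_foreground)
            per_pair = study_to_pair_stacks(pstudy)
            for pid in net_cfg.pairs:
                stacks[pid].append(per_pair[pid][0])
            targets.append(pmasks.stack())
        batch = {pid: np.stack(v) for pid, v in stacks.items()}
        target = np.stack(targets)
        out = model(batch)
        breakdown = total_loss(out.prediction,
                               {"m_g": out.m_g, **out.side_maps}, target,
                               alpha=config.alpha)
        if not np.isfinite(breakdown.l_total):
            raise FloatingPointError(
                f"non-finite loss {breakdown.l_total} at step {step}: diverged")
        opt.zero_grad()
        breakdown.total.backward()
        opt.step()
        rec = {"step": step, **breakdown.to_record()}
        history.append(rec)
        if log_stream is not None:
            log_stream.write(json.dumps(rec) + "\n")
    ckpt = Checkpoint(network_config=net_cfg, state=model.state_dict(),
                      train_config=dataclasses.asdict(config) | {
                          "network": net_cfg.to_dict(),
                          "patch_size": list(config.patch_size)})
    return ckpt, history


# -- inference -----------------------------------------------------------

def _tile_starts(size: int, patch: int, stride: int):
    if size <= patch:
        return [0]
    starts = list(range(0, size - patch + 1, stride))
    if starts[-1] != size - patch:
        starts.append(size - patch)
    return starts


def predict_probabilities(model: SegmentationNetwork, study: MultiModalStudy,
                          patch_size=None) -> np.ndarray:
    """(3, D, H, W) probabilities via tiled forward passes with mean overlap."""
    shape = study.shape
    ps = tuple(patch_size) if patch_size is not None else shape
    if any(s % 16 for s in ps):
        raise ValueError(f"tile dims must be divisible by 16, got {ps}")
    stacks = study_to_pair_stacks(study)
    if ps == tuple(shape):
        out = model({pid: stacks[pid] for pid in model.cfg.pairs})
        return out.prediction.data[0]
    acc = np.zeros((3,) + tuple(shape))
    cnt = np.zeros(shape)
    strides = [max(p // 2, 16) for p in ps]
    for i0 in _tile_starts(shape[0], ps[0], strides[0]):
        for j0 in _tile_starts(shape[1], ps[1], strides[1]):
            for k0 in _tile_starts(shape[2], ps[2], strides[2]):
                sl = (slice(i0, i0 + ps[0]), slice(j0, j0 + ps[1]),
                      slice(k0, k0 + ps[2]))
                tile = {pid: stacks[pid][:, :, sl[0], sl[1], sl[2]]
                        for pid in model.cfg.pairs}
                out = model(tile)
                acc[(slice(None),) + sl] += out.prediction.data[0]
                cnt[sl] += 1.0
    return acc / cnt


def predict_study(checkpoint: Checkpoint, study: MultiModalStudy,
                  patch_size=None, normalized: bool = False,
                  compute_dtype: str = "float32") -> HierarchicalMasks:
    if not normalized:
        study = normalize_study(study)
    with ag.use_dtype(compute_dtype):
        model = checkpoint.build()
        probs = predict_probabilities(model, study, patch_size)
    return binarize_prediction(probs, threshold=checkpoint.network_config.threshold)


def predict_average(ck_a: Checkpoint, ck_b: Checkpoint, study: MultiModalStudy,
                    patch_size=None, normalized: bool = False,
                    compute_dtype: str = "float32") -> HierarchicalMasks:
    """The "f_g1+2" construction: mean of two single-pair probability maps."""
    if not normalized:
        study = normalize_study(study)
    with ag.use_dtype(compute_dtype):
        pa = predict_probabilities(ck_a.build(), study, patch_size)
        pb = predict_probabilities(ck_b.build(), study, patch_size)
    return binarize_prediction(0.5 * (pa.astype(np.float64) + pb.astype(np.float64)))


# -- ablations -----------------------------------------------------------

def evaluate_checkpoints(checkpoints: dict, mode: str, test_set,
                         patch_size=None):
    """Per-subject MetricReports for one ablation mode on a held-out set."""
    reports = []
    for study, labels in test_set:
        gt = map_labels(labels)
        if mode == "average_fusion":
            pred = predict_average(checkpoints["g1_only"], checkpoints["g2_only"],
                                   study, patch_size)
        else:
            pred = predict_study(checkpoints[mode], study, patch_size)
        reports.append(metrics_mod.evaluate_study(pred, gt, study.spacing,
                                                  subject_id=study.subject_id))
    return reports


def run_ablation(modes, config: TrainConfig, cohort, test_set=None):
    """Train each requested mode at an identical budget and evaluate it.

    average_fusion reuses the g1_only/g2_only checkpoints (no training of its
    own). Returns {mode: {"reports": [...], "summary": {...}}} plus the
    checkpoints under "__checkpoints__".
    """
    modes = list(modes)
    if test_set is None:
        ids = list(range(len(cohort)))
        train_ids, test_ids = split_dataset(ids, config.split_fraction,
                                            config.master_seed)
        train_set = [cohort[i] for i in train_ids]
        test_set = [cohort[i] for i in test_ids]
    else:
        train_set = cohort
    need_train = set(modes) - {"average_fusion"}
    if "average_fusion" in modes:
        need_train |= {"g1_only", "g2_only"}
    checkpoints = {}
    for mode in sorted(need_train):
        cfg = dataclasses.replace(config, ablation_mode=mode)
        checkpoints[mode], _ = train(cfg, train_set)
    results = {"__checkpoints__": checkpoints}
    for mode in modes:
        reports = evaluate_checkpoints(checkpoints, mode, test_set)
        results[mode] = {"reports": reports,
                         "summary": metrics_mod.aggregate_reports(reports)}
    return results


def simulate_cohort(n: int, master_seed: int, spec: PhantomSpec | None = None):
    return generate_cohort(n, spec=spec, master_seed=master_seed)


def save_history(history, path):
    Path(path).write_text("".join(json.dumps(rec) + "\n" for rec in history))
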