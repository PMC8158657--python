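"""Segmentation network: shared pair encoder, partial decoder, reverse
co-attention and feature fusing cascade.

Topology
--------
Each modality pair (2 channels) runs through ONE shared-parameter encoder that
emits a five-level feature pyramid (dyadic halving, channel doubling). A shared
partial decoder aggregates levels 3-5 of each pair's pyramid into a per-pair
global region-logit map ``M_g`` at level-3 resolution. A cascade over levels
5, 4, 3 then (a) turns each pair's current map into a reverse attention weight
``R = 1 - sigmoid(M)``, (b) averages the two pairs' weights into the reverse
co-attention weight, (c) gates each pair's level feature, concatenates the
gated pairs channel-wise, mixes them convolutionally together with the deeper
fused feature and emits a side-output logit map ``M_i``. The final prediction
is the sigmoid of ``M_3`` upsampled to full resolution.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor
from .volume_io import HierarchicalMasks, MultiModalStudy, split_modality_pairs

LEVELS = 5
HIGH_LEVELS = (3, 4, 5)


@dataclasses.dataclass
class NetworkConfig:
    """Architecture knobs. Reference scale uses base_filters 16; desk default is 4."""

    base_filters: int = 4
    levels: int = LEVELS
    region_channels: int = 3
    residual_mode: str = "literal_plus_one"  # or "map_residual"
    attention_mode: str = "reverse"          # or "saliency" (the "w AT" ablation)
    coattention: bool = True                 # False = independent per-pair attention
    attention_reduce: str = "mean"           # or "max" over region channels
    pairs: tuple = ("g1", "g2")              # single-pair ablations: ("g1",) / ("g2",)
    negative_slope: float = 0.1
    upsample: str = "trilinear"              # align_corners=False; fixed
    threshold: float = 0.5
    seed: int = 0

    def validate(self):
        if self.levels != LEVELS:
            raise ValueError("the feature pyramid is fixed at five levels")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.residual_mode not in ("literal_plus_one", "map_residual"):
            raise ValueError(f"unknown residual_mode {self.residual_mode!r}")
        if self.attention_mode not in ("reverse", "saliency"):
            raise ValueError(f"unknown attention_mode {self.attention_mode!r}")
        if self.attention_reduce not in ("mean", "max"):
            raise ValueError(f"unknown attention_reduce {self.attention_reduce!r}")
        if not self.pairs or any(p not in ("g1", "g2") for p in self.pairs):
            raise ValueError(f"pairs must be drawn from g1/g2, got {self.pairs}")

    def level_channels(self, level: int) -> int:
        return self.base_filters * 2 ** (level - 1)

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["pairs"] = list(self.pairs)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["pairs"] = tuple(d.get("pairs", ("g1", "g2")))
        return cls(**d)


@dataclasses.dataclass
class FeaturePyramid:
    """Per-pair features f1..f5; level k at 1/2^(k-1) resolution."""

    f1: Tensor
    f2: Tensor
    f3: Tensor
    f4: Tensor
    f5: Tensor

    def level(self, k: int) -> Tensor:
        return getattr(self, f"f{k}")


@dataclasses.dataclass
class ForwardOutputs:
    """Everything the loss needs from one forward pass."""

    global_maps: dict            # pair_id -> level-3 logit Tensor
    side_maps: dict              # {"m3", "m4", "m5"} logit Tensors at own level
    prediction: Tensor           # (N, 3, D, H, W) probabilities at full resolution
    m_g: Tensor                  # mean of per-pair global maps (deep supervision)


# -- elementary ops (usable standalone) ----------------------------------

def reverse_attention(m: Tensor) -> Tensor:
    """R = 1 - sigmoid(M), elementwise; values strictly in (0, 1)."""
    return 1.0 - ag.sigmoid(ag.as_tensor(m))


def saliency_attention(m: Tensor) -> Tensor:
    """Forward (saliency) attention sigma(M) — the "w AT" ablation."""
    return ag.sigmoid(ag.as_tensor(m))


def co_attention_average(r_g1: Tensor, r_g2: Tensor) -> Tensor:
    """Elementwise mean of the two pairs' attention weights."""
    r_g1, r_g2 = ag.as_tensor(r_g1), ag.as_tensor(r_g2)
    if r_g1.shape != r_g2.shape:
        raise ValueError(f"shape mismatch: {r_g1.shape} vs {r_g2.shape}")
    return (r_g1 + r_g2) * 0.5


def attend_features(f: Tensor, r: Tensor, residual_mode: str = "literal_plus_one") -> Tensor:
    """Gate a feature grid: f*r + 1 (literal) or f*r (map_residual adds the map
    to the side-output logits instead)."""
    out = ag.as_tensor(f) * ag.as_tensor(r)
    if residual_mode == "literal_plus_one":
        out = out + 1.0
    return out


def resize_map(m: Tensor, from_level: int, to_level: int) -> Tensor:
    """Move a map between pyramid levels: trilinear x2 up / 2x mean-pool down."""
    t = ag.as_tensor(m)
    for _ in range(from_level - to_level):
        t = ag.upsample2x(t)
    for _ in range(to_level - from_level):
        t = ag.avgpool2(t)
    return t


# -- modules -------------------------------------------------------------

class PairEncoder(nn.Module):
    """Shared 5-level encoder: two ConvBlocks per level, strided downsampling."""

    def __init__(self, cfg: NetworkConfig, rng):
        self.stages = []
        in_ch = 2
        for level in range(1, cfg.levels + 1):
            out_ch = cfg.level_channels(level)
            stride = 1 if level == 1 else 2
            self.stages.append(nn.Sequential(
                nn.ConvBlock(in_ch, out_ch, stride=stride, rng=rng, slope=cfg.negative_slope),
                nn.ConvBlock(out_ch, out_ch, stride=1, rng=rng, slope=cfg.negative_slope),
            ))
            in_ch = out_ch

    def forward(self, x: Tensor) -> FeaturePyramid:
        spatial = x.shape[2:]
        if any(s % 16 for s in spatial):
            raise ValueError(f"spatial dims must be divisible by 16, got {spatial}")
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return FeaturePyramid(*feats)


class PartialDecoder(nn.Module):
    """Aggregate levels 3-5 in cascade into f_Dp and the global map M_g."""

    def __init__(self, cfg: NetworkConfig, rng):
        c = cfg.level_channels(3)
        self.reduce = {lvl: nn.ConvBlock(cfg.level_channels(lvl), c, rng=rng,
                                         slope=cfg.negative_slope)
                       for lvl in HIGH_LEVELS}
        self.mix = nn.ConvBlock(3 * c, c, rng=rng, slope=cfg.negative_slope)
        self.head = nn.Conv3d(c, cfg.region_channels, kernel_size=1, rng=rng)

    def forward(self, pyramid: FeaturePyramid) -> tuple[Tensor, Tensor]:
        f3, f4, f5 = pyramid.f3, pyramid.f4, pyramid.f5
        for a, b in ((f3, f4), (f4, f5)):
            if tuple(2 * s for s in b.shape[2:]) != a.shape[2:]:
                raise ValueError("pyramid levels are not dyadically nested")
        g5 = self.reduce[5](f5)
        g4 = self.reduce[4](f4) * ag.upsample2x(g5)
        g3 = self.reduce[3](f3) * ag.upsample2x(g4)
        stacked = ag.concat([g3, ag.upsample2x(g4), ag.upsample2x(ag.upsample2x(g5))], axis=1)
        f_dp = self.mix(stacked)
        return f_dp, self.head(f_dp)


class FuseBlock(nn.Module):
    """Gate each pair's level-i feature, fuse channel-wise, emit side map M_i."""

    def __init__(self, cfg: NetworkConfig, level: int, rng):
        c = cfg.level_channels(level)
        self.level = level
        self.cfg = cfg
        self.pair_mix = [nn.ConvBlock(c, c, rng=rng, slope=cfg.negative_slope)
                         for _ in cfg.pairs]
        self.fuse = nn.ConvBlock(len(cfg.pairs) * c, c, rng=rng, slope=cfg.negative_slope)
        self.carry_mix = None if level == 5 else nn.ConvBlock(
            c + cfg.level_channels(level + 1), c, rng=rng, slope=cfg.negative_slope)
        self.head = nn.Conv3d(c, cfg.region_channels, kernel_size=1, rng=rng)

    def forward(self, features, attns, prev_map=None, carry=None):
        """features: per-pair level-i Tensors; attns: one shared weight or one
        per pair; prev_map: deeper logit map at level-i resolution (used by
        map_residual); carry: fused feature from the deeper block."""
        if len(attns) == 1:
            attns = attns * len(features)
        gated = [attend_features(f, r, self.cfg.residual_mode)
                 for f, r in zip(features, attns)]
        mixed = [blk(g) for blk, g in zip(self.pair_mix, gated)]
        z = self.fuse(ag.concat(mixed, axis=1)) if len(mixed) > 1 else self.fuse(mixed[0])
        if carry is not None:
            z = self.carry_mix(ag.concat([z, ag.upsample2x(carry)], axis=1))
        m = self.head(z)
        if self.cfg.residual_mode == "map_residual" and prev_map is not None:
            m = m + prev_map
        return z, m


class SegmentationNetwork(nn.Module):
    """Full model; ablations are expressed through NetworkConfig flags."""

    def __init__(self, cfg: NetworkConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = PairEncoder(cfg, rng)           # shared across pairs
        self.partial_decoder = PartialDecoder(cfg, rng)  # shared across pairs
        self.fuse_blocks = {lvl: FuseBlock(cfg, lvl, rng) for lvl in (5, 4, 3)}

    # single-pair fuse blocks have len(pairs)==1 channel widths by construction

    def _attention(self, m: Tensor) -> Tensor:
        att = saliency_attention(m) if self.cfg.attention_mode == "saliency" \
            else reverse_attention(m)
        if self.cfg.attention_reduce == "mean":
            return att.mean(axis=1, keepdims=True)
        # max over region channels, kept differentiable via the identity
        # max(a) = a at argmax; implemented with a stop-gradient mask
        data = att.data
        mask = (data == data.max(axis=1, keepdims=True)).astype(np.float64)
        mask /= mask.sum(axis=1, keepdims=True)
        return (att * ag.Tensor(mask)).sum(axis=1, keepdims=True)

    def forward(self, pair_stacks: dict) -> ForwardOutputs:
        """pair_stacks: pair_id -> (N, 2, D, H, W) array or Tensor."""
        cfg = self.cfg
        pyramids, global_maps = {}, {}
        for pid in cfg.pairs:
            x = ag.as_tensor(np.asarray(pair_stacks[pid], dtype=np.float64)
                             if not isinstance(pair_stacks[pid], Tensor)
                             else pair_stacks[pid])
            pyr = self.encoder(x)
            pyramids[pid] = pyr
            _, m_g = self.partial_decoder(pyr)
            global_maps[pid] = m_g

        # per-pair current maps live at level-3 resolution
        current = {pid: global_maps[pid] for pid in cfg.pairs}
        carry = None
        side = {}
        for lvl in (5, 4, 3):
            rs = []
            for pid in cfg.pairs:
                m_at_lvl = resize_map(current[pid], 3, lvl)
                rs.append(self._attention(m_at_lvl))
            if cfg.coattention and len(rs) == 2:
                attns = [co_attention_average(rs[0], rs[1])]
            else:
                attns = rs
            prev = None
            if cfg.residual_mode == "map_residual":
                prev_src = current[cfg.pairs[0]]
                if len(cfg.pairs) == 2:
                    prev_src = (current[cfg.pairs[0]] + current[cfg.pairs[1]]) * 0.5
                prev = resize_map(prev_src, 3, lvl)
            feats = [pyramids[pid].level(lvl) for pid in cfg.pairs]
            carry, m_i = self.fuse_blocks[lvl](feats, attns, prev_map=prev, carry=carry)
            side[f"m{lvl}"] = m_i
            current = {pid: resize_map(m_i, lvl, 3) for pid in cfg.pairs}

        prediction = ag.sigmoid(ag.upsample2x(ag.upsample2x(side["m3"])))
        if len(cfg.pairs) == 2:
            m_g_mean = (global_maps["g1"] + global_maps["g2"]) * 0.5
        else:
            m_g_mean = global_maps[cfg.pairs[0]]
        return ForwardOutputs(global_maps=global_maps, side_maps=side,
                              prediction=prediction, m_g=m_g_mean)


# -- convenience wrappers ------------------------------------------------

def encode_pair(stack, model_or_cfg) -> FeaturePyramid:
    """Run one 2-channel stack through the (shared) encoder."""
    model = model_or_cfg if isinstance(model_or_cfg, SegmentationNetwork) \
        else SegmentationNetwork(model_or_cfg)
    arr = stack.channels if hasattr(stack, "channels") else np.asarray(stack)
    if arr.ndim == 4:
        arr = arr[None]
    return model.encoder(ag.Tensor(np.asarray(arr, dtype=np.float64)))


def partial_decode(model: SegmentationNetwork, pyramid: FeaturePyramid):
    return model.partial_decoder(pyramid)


def fuse_features(model: SegmentationNetwork, level: int, f_g1, f_g2, r_bar,
                  prev_map=None, carry=None):
    return model.fuse_blocks[level]([f_g1, f_g2], [r_bar], prev_map=prev_map,
                                    carry=carry)


def study_to_pair_stacks(study: MultiModalStudy) -> dict:
    g1, g2 = split_modality_pairs(study)
    return {"g1": g1.channels[None], "g2": g2.channels[None]}


def forward_segment(study: MultiModalStudy, cfg_or_model) -> ForwardOutputs:
    """Full pipeline on one (normalized) study."""
    model = cfg_or_model if isinstance(cfg_or_model, SegmentationNetwork) \
        else SegmentationNetwork(cfg_or_model)
    stacks = study_to_pair_stacks(study)
    return model({pid: stacks[pid] for pid in model.cfg.pairs})


def binarize_prediction(probabilities: np.ndarray, threshold: float = 0.5) -> HierarchicalMasks:
    """Threshold (>= threshold -> 1) then enforce nesting by intersection."""
    probs = np.asarray(probabilities, dtype=np.float64)
    if probs.ndim == 5:
        if probs.shape[0] != 1:
            raise ValueError("binarize_prediction expects a single study")
        probs = probs[0]
    if probs.shape[0] != 3:
        raise ValueError(f"expected 3 region channels, got {probs.shape[0]}")
    if probs.min() < 0.0 or probs.max() > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    hard = probs >= threshold
    wt = hard[0]
    tc = hard[1] & wt
    et = hard[2] & tc
    masks = HierarchicalMasks(wt=wt.astype(np.uint8), tc=tc.astype(np.uint8),
                              et=et.astype(np.uint8))
    masks.validate()
    return masks
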