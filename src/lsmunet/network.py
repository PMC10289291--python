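"""LSMU-Net: hybrid 2.5D/3D residual encoder-decoder for lumbar muscle CT.

The network consumes a preprocessed L3 slab of shape ``1x1x8xHxW``
(batch x channel x depth x height x width) and emits per-slice class
scores ``8x5xHxW``:

* **2.5D backbone** — the 8 axial slices are permuted into the batch axis
  and processed by a 2-D residual U-Net: five ``Block2D`` encoder stages
  with four 2x max-poolings, then four decoder stages of 2x upsampling,
  skip concatenation and ``Block2D``.
* **3D encoding branch** — three layers, each of (all-axis 2x max-pooling,
  ``Block3D``, texture attention enhancement), operating on the intact
  volume so sagittal/coronal context can disambiguate axial boundaries.
  Depths shrink 8 -> 4 -> 2 -> 1 across the layers.
* **Texture attention enhancement** — squeeze-and-excitation channel
  weights combined additively with a pixel weight ``x * (1 - x)`` of the
  sigmoid activation, which peaks at probability 0.5 and therefore
  emphasises uncertain (edge) voxels.
* **Fusion** — the decoder-final feature (32 ch), a 1x1 projection of the
  first encoder feature (8 ch) and the upsampled, batch-duplicated 3-D
  hierarchical features (16+32+64 = 112 ch) concatenate to 152 channels,
  followed by a 1x1 convolution onto the 5 classes.

The implementation is functional: ``LSMUNet.apply(params, volume)`` is a
pure function of a nested parameter dict, differentiable with autograd.
Feature maps are channels-last internally; public tensors follow the
channels-first convention documented above.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import autograd.numpy as anp
import numpy as np

from .nn import core as L

FULL_BACKBONE = (8, 16, 32, 64, 128)
FULL_DECODER = (64, 32, 16, 32)
FULL_BRANCH3D = (16, 32, 64)
FULL_SKIP_PROJ = 8

ATTENTION_MODES = ("texture", "se", "none")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and ablation switches.

    The printed channel totals of the reference design are invariants: at
    full width the three 3-D branch layers contribute 112 channels and the
    fused feature holds 152 (= 32 decoder-final + 8 skip projection + 112).
    ``scaled`` produces reduced-width variants preserving those ratios for
    desk-scale experiments.
    """

    in_plane_size: tuple[int, int] = (512, 512)
    depth: int = 8
    n_classes: int = 5
    backbone_widths: tuple[int, ...] = FULL_BACKBONE
    decoder_widths: tuple[int, ...] = FULL_DECODER
    skip_proj_channels: int = FULL_SKIP_PROJ
    branch3d_widths: tuple[int, ...] = FULL_BRANCH3D
    use_3d_branch: bool = True
    attention: str = "texture"
    use_residual: bool = True
    fc_reduction: int = 16
    leaky_slope: float = 0.01
    upsample_mode: str = "nearest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attention not in ATTENTION_MODES:
            raise ValueError(f"attention must be one of {ATTENTION_MODES}")
        if self.upsample_mode not in ("nearest", "bilinear"):
            raise ValueError("upsample_mode must be 'nearest' or 'bilinear'")
        if len(self.backbone_widths) != 5 or len(self.decoder_widths) != 4:
            raise ValueError("backbone takes 5 encoder and 4 decoder stages")
        if len(self.branch3d_widths) != 3:
            raise ValueError("the 3-D branch has exactly 3 layers")
        if self.n_classes != 5:
            raise ValueError("the segmentation task has 5 classes")
        h, w = self.in_plane_size
        if h % 16 or w % 16:
            raise ValueError("in-plane size must be divisible by 16 (4 poolings)")
        if self.depth != 8:
            raise ValueError("network depth is fixed at 8 slices")
        if self.backbone_widths == FULL_BACKBONE and self.use_3d_branch:
            if sum(self.branch3d_widths) != 112:
                raise ValueError(
                    "full-width configuration requires 112 total 3-D branch channels"
                )
            if self.fusion_channels != 152:
                raise ValueError(
                    "full-width configuration requires 152 fused channels"
                )

    @property
    def fusion_channels(self) -> int:
        n = self.decoder_widths[-1] + self.skip_proj_channels
        if self.use_3d_branch:
            n += sum(self.branch3d_widths)
        return n

    @classmethod
    def full(cls, **kw) -> "NetworkConfig":
        return cls(**kw)

    @classmethod
    def scaled(cls, factor: int, in_plane_size=(64, 64), **kw) -> "NetworkConfig":
        """Reduced-width config: every channel count divided by ``factor``."""
        s = lambda widths: tuple(max(1, wdt // factor) for wdt in widths)
        return cls(
            in_plane_size=in_plane_size,
            backbone_widths=s(FULL_BACKBONE),
            decoder_widths=s(FULL_DECODER),
            skip_proj_channels=max(1, FULL_SKIP_PROJ // factor),
            branch3d_widths=s(FULL_BRANCH3D),
            **kw,
        )

    def with_ablation(self, name: str) -> "NetworkConfig":
        """Architecture part of the ablation axes; 'noweights' is a loss flag."""
        if name in ("full", "noweights"):
            return self
        if name == "no3d":
            return replace(self, use_3d_branch=False, attention="none")
        if name == "noattn":
            return replace(self, attention="none")
        if name == "nores":
            return replace(self, use_residual=False)
        if name == "se":
            return replace(self, attention="se")
        raise ValueError(f"unknown ablation {name!r}")


# --- slice/batch permutation ------------------------------------------------


def permute_slices_to_batch(volume, depth: int = 8):
    """(1, 1, depth, H, W) -> (depth, 1, H, W): slices become batch elements."""
    if volume.ndim != 5 or volume.shape[0] != 1 or volume.shape[1] != 1:
        raise ValueError(f"expected shape (1, 1, {depth}, H, W), got {volume.shape}")
    if volume.shape[2] != depth:
        raise ValueError(
            f"depth {volume.shape[2]} != {depth}; pad the slab to {depth} slices first"
        )
    d, h, w = volume.shape[2:]
    return anp.reshape(volume, (d, 1, h, w))


def unpermute_batch_to_slices(batch):
    """(depth, 1, H, W) -> (1, 1, depth, H, W); inverse of the permutation."""
    if batch.ndim != 4 or batch.shape[1] != 1:
        raise ValueError(f"expected shape (depth, 1, H, W), got {batch.shape}")
    d, _, h, w = batch.shape
    return anp.reshape(batch, (1, 1, d, h, w))


# --- residual blocks --------------------------------------------------------


def _basic_init(rng, conv_init, c_in, c_out):
    return {"conv": conv_init(rng, c_in, c_out), "norm": L.instance_norm_init(c_out)}


def _basic(params, conv, x, slope):
    return L.leaky_relu(L.instance_norm(params["norm"], conv(params["conv"], x)), slope)


def block2d_init(rng, c_in: int, c_out: int) -> dict:
    return {
        "pre": _basic_init(rng, L.conv2d_init, c_in, c_out),
        "r1": _basic_init(rng, L.conv2d_init, c_out, c_out),
        "r2": _basic_init(rng, L.conv2d_init, c_out, c_out),
    }


def block2d(params: dict, x, slope: float = 0.01, use_residual: bool = True):
    """Block2D: transition conv then a two-conv residual group (3 convs).

    Channel-preserving when ``c_in == c_out``; spatial size is preserved
    (same padding).  ``use_residual=False`` drops the jump connection.
    """
    h1 = _basic(params["pre"], L.conv2d, x, slope)
    h = _basic(params["r1"], L.conv2d, h1, slope)
    h = _basic(params["r2"], L.conv2d, h, slope)
    return h + h1 if use_residual else h


def block3d_init(rng, c_in: int, c_out: int) -> dict:
    return {
        "pre": _basic_init(rng, L.conv3d_init, c_in, c_out),
        "r1": _basic_init(rng, L.conv3d_init, c_out, c_out),
        "r2": _basic_init(rng, L.conv3d_init, c_out, c_out),
        "r3": _basic_init(rng, L.conv3d_init, c_out, c_out),
    }


def block3d(params: dict, x, slope: float = 0.01, use_residual: bool = True):
    """Block3D: transition conv then a three-conv residual group (4 convs)."""
    h1 = _basic(params["pre"], L.conv3d, x, slope)
    h = _basic(params["r1"], L.conv3d, h1, slope)
    h = _basic(params["r2"], L.conv3d, h, slope)
    h = _basic(params["r3"], L.conv3d, h, slope)
    return h + h1 if use_residual else h


# --- texture attention enhancement -----------------------------------------


def texture_attention_map(x):
    """Pixel attention ``x * (1 - x)`` for a probability map in [0, 1].

    Peaks (0.25) at x = 0.5 and vanishes at saturated probabilities, so
    uncertain edge voxels receive the largest weight.
    """
    return x * (1.0 - x)


def attention_block_init(rng, c: int, fc_reduction: int = 16) -> dict:
    hidden = max(1, c // fc_reduction)
    return {
        "fc1": L.dense_init(rng, c, hidden),
        "fc2": L.dense_init(rng, hidden, c),
        "squeeze": L.conv1x1_init(rng, c, c),
    }


def _attention_forward(params, x, attention, out_hw, depth_batch, slope):
    """Channels-last core: x (1, D', H', W', C) -> (depth_batch, H, W, C)."""
    g = anp.mean(x, axis=(1, 2, 3))  # (1, C)
    z = L.relu(L.dense(params["fc1"], g))
    s = L.sigmoid(L.dense(params["fc2"], z))
    s = anp.reshape(s, (1, 1, 1, 1, -1))
    if attention == "texture":
        a = texture_attention_map(L.sigmoid(x))
        e = x * s + x * a
    elif attention == "se":
        e = x * s
    else:
        e = x
    m = anp.mean(e, axis=1)  # squeeze depth -> (1, H', W', C)
    m = L.resize_bilinear(m, out_hw)
    m = L.conv1x1(params["squeeze"], m)
    return anp.repeat(m, depth_batch, axis=0)


def texture_attention_block(
    params: dict,
    x,
    attention: str = "texture",
    out_hw: tuple[int, int] | None = None,
    depth_batch: int = 8,
    slope: float = 0.01,
):
    """Public wrapper on channels-first input (1, C, D', H', W').

    Returns the rank-4 fusion contribution (depth_batch, C, H, W): channel
    (SE-style) and pixel (texture) weights applied to the 3-D feature,
    depth-squeezed, upsampled in-plane and duplicated across the slice
    batch.
    """
    if x.ndim != 5:
        raise ValueError("expected rank-5 feature (1, C, D, H, W)")
    if out_hw is None:
        out_hw = (x.shape[3], x.shape[4])
    xl = anp.transpose(x, (0, 2, 3, 4, 1))
    out = _attention_forward(params, xl, attention, out_hw, depth_batch, slope)
    out = anp.transpose(out, (0, 3, 1, 2))
    if isinstance(out, np.ndarray) and not np.isfinite(out).all():
        raise FloatingPointError("non-finite activations in attention block")
    return out


# --- the full model ---------------------------------------------------------


class LSMUNet:
    """Functional LSMU-Net model: config + parameter tree."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.params = self._init_params(np.random.default_rng(config.seed))
        #: shapes of the branch/fusion tensors from the last plain-numpy
        #: forward pass (inference only; not populated under autograd)
        self.intermediate_shapes: dict[str, tuple] = {}

    def _init_params(self, rng) -> dict:
        cfg = self.config
        bw = cfg.backbone_widths
        dw = cfg.decoder_widths
        enc = []
        c_in = 1
        for c_out in bw:
            enc.append(block2d_init(rng, c_in, c_out))
            c_in = c_out
        dec = []
        c_prev = bw[-1]
        for j, c_out in enumerate(dw):
            skip = bw[3 - j]
            dec.append(block2d_init(rng, c_prev + skip, c_out))
            c_prev = c_out
        params = {
            "enc": enc,
            "dec": dec,
            "proj": L.conv1x1_init(rng, bw[0], cfg.skip_proj_channels),
            "head": L.conv1x1_init(rng, cfg.fusion_channels, cfg.n_classes),
        }
        if cfg.use_3d_branch:
            branch = []
            c3 = 1
            for c_out in cfg.branch3d_widths:
                branch.append(
                    {
                        "block": block3d_init(rng, c3, c_out),
                        "att": attention_block_init(rng, c_out, cfg.fc_reduction),
                    }
                )
                c3 = c_out
            params["branch"] = branch
        return params

    @property
    def n_parameters(self) -> int:
        from autograd.misc import flatten

        return flatten(self.params)[0].size

    def apply(self, params: dict, volume):
        """Pure forward pass: (1, 1, 8, H, W) -> logits (8, 5, H, W)."""
        cfg = self.config
        slope = cfg.leaky_slope
        slices = permute_slices_to_batch(volume, cfg.depth)  # (8, 1, H, W)
        x = anp.transpose(slices, (0, 2, 3, 1))  # channels-last

        feats = []
        for i, stage in enumerate(params["enc"]):
            if i > 0:
                x = L.maxpool2d(x)
            x = block2d(stage, x, slope, cfg.use_residual)
            feats.append(x)

        d = feats[-1]
        for j, stage in enumerate(params["dec"]):
            if cfg.upsample_mode == "nearest":
                d = L.upsample2x_nearest(d)
            else:
                d = L.resize_bilinear(d, (d.shape[1] * 2, d.shape[2] * 2))
            d = anp.concatenate([d, feats[3 - j]], axis=-1)
            d = block2d(stage, d, slope, cfg.use_residual)

        parts = [d, L.conv1x1(params["proj"], feats[0])]

        if cfg.use_3d_branch:
            h, w = volume.shape[3], volume.shape[4]
            x3 = anp.reshape(volume, (1, cfg.depth, h, w, 1))
            for layer in params["branch"]:
                x3 = L.maxpool3d(x3)
                x3 = block3d(layer["block"], x3, slope, cfg.use_residual)
                parts.append(
                    _attention_forward(
                        layer["att"], x3, cfg.attention, (h, w), cfg.depth, slope
                    )
                )

        fused = anp.concatenate(parts, axis=-1)
        logits = L.conv1x1(params["head"], fused)
        if isinstance(fused, np.ndarray):
            # channels-first shapes, matching the documented conventions
            b, hh, ww, cc = fused.shape
            self.intermediate_shapes["fused"] = (b, cc, hh, ww)
            if cfg.use_3d_branch:
                c3 = sum(p.shape[-1] for p in parts[2:])
                self.intermediate_shapes["branch3d"] = (b, c3, hh, ww)
        return anp.transpose(logits, (0, 3, 1, 2))

    def forward(self, volume: np.ndarray) -> np.ndarray:
        """Deterministic inference forward pass on plain arrays."""
        vol = np.asarray(volume, dtype=np.float32)
        out = self.apply(self.params, vol)
        if not np.isfinite(out).all():
            raise FloatingPointError("non-finite activations in forward pass")
        return out


def build_lsmu_net(config: NetworkConfig) -> LSMUNet:
    """Construct an LSMU-Net; width constraints are validated by the config."""
    model = LSMUNet(config)
    # fusion arithmetic re-checked at build time
    expected = config.decoder_widths[-1] + config.skip_proj_channels + (
        sum(config.branch3d_widths) if config.use_3d_branch else 0
    )
    assert config.fusion_channels == expected
    return model


def predict_labels(model: LSMUNet, slab) -> "LabelVolume":
    """Argmax segmentation of a preprocessed (normalized + padded) slab.

    Ties break toward the lowest class index.  Padded slices are retained
    in the output and flagged via ``n_true_slices``.
    """
    from .ioprep import LabelVolume

    v = np.asarray(slab.voxels)
    if v.shape[0] != model.config.depth:
        raise ValueError("slab must be padded to the network depth first")
    if v.min() < 0.0 or v.max() > 1.0:
        raise ValueError("slab must be intensity-normalized to [0, 1] first")
    logits = model.forward(v[None, None])
    labels = np.argmax(logits, axis=1).astype(np.int64)  # (8, H, W)
    return LabelVolume(
        labels=labels,
        spacing_mm=slab.spacing_mm,
        n_true_slices=slab.n_true_slices,
        patient_id=slab.patient_id,
    )
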