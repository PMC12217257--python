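"""Detection phase: per-modality feature extraction and multimodal fusion.

Three aligned 3-channel views of a patch — the RGB image, the predicted
tissue mask rendered through a fixed class palette, and the predicted
noise map — are passed through a convolutional backbone whose final
feature grid is flattened into a token sequence and projected to a
common embedding width. Token bundles are then fused by one of four
mechanisms (simple concatenation of pooled features, joint
self-attention, single cross-attention, or a full transformer decoder
with self-attention on the query stream, cross-attention to the other
modalities, feed-forward sublayers, residuals, layer norm and positional
encodings) and classified normal/cancer by a linear head.

The default backbone is a small strided CNN; an MBConv backbone with
inverted bottleneck blocks and swish activation (the compound-scaled
efficient-CNN building block) is available via ``backbone="mbconv"``.
One backbone is shared across modalities by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import Tensor
from .denoiser import sinusoidal_time_embedding
from .sampler import SegmentationResult

logger = logging.getLogger("histodiff")

__all__ = [
    "ModalityFeatures",
    "FusionConfig",
    "DetectionResult",
    "DetectorTrainSettings",
    "DetectorModel",
    "MASK_PALETTE",
    "prepare_modality_inputs",
    "build_backbone",
    "extract_features",
    "fuse",
    "classify",
    "build_detector",
    "train_detector",
]

MODALITIES = ("image", "mask", "noise")

# fixed rendering palette for mask classes 0..7 (RGB in [0,1])
MASK_PALETTE = np.array([
    [0.0, 0.0, 0.0],
    [1.0, 0.0, 0.0],
    [0.0, 1.0, 0.0],
    [0.0, 0.0, 1.0],
    [1.0, 1.0, 0.0],
    [1.0, 0.0, 1.0],
    [0.0, 1.0, 1.0],
    [1.0, 1.0, 1.0],
])


@dataclass(frozen=True)
class ModalityFeatures:
    """A token sequence (L, D) extracted from one modality input."""

    tokens: np.ndarray
    modality_tag: str

    def __post_init__(self):
        if self.modality_tag not in MODALITIES:
            raise ValueError(f"unknown modality tag {self.modality_tag!r}")
        if np.asarray(self.tokens).ndim != 2 or not np.all(np.isfinite(self.tokens)):
            raise ValueError("tokens must be a finite (L, D) array")


@dataclass
class FusionConfig:
    """Fusion mechanism and the modalities it consumes.

    ``modalities`` must include "image"; a single-modality configuration
    (concat mode) serves as the image-only ablation baseline.
    """

    mode: str = "transformer_decoder"
    modalities: tuple[str, ...] = ("image", "mask", "noise")
    embed_dim: int = 32
    heads: int = 4
    layers: int = 1
    query_modality: str = "image"
    positional_encoding: bool = True

    def __post_init__(self):
        if self.mode not in ("concat", "self_attention", "cross_attention",
                             "transformer_decoder"):
            raise ValueError(f"unknown fusion mode {self.mode!r}")
        self.modalities = tuple(self.modalities)
        if "image" not in self.modalities:
            raise ValueError("modalities must include 'image'")
        if any(m not in MODALITIES for m in self.modalities):
            raise ValueError(f"modalities must be a subset of {MODALITIES}")
        if len(set(self.modalities)) != len(self.modalities):
            raise ValueError("duplicate modality")
        if self.embed_dim % self.heads:
            raise ValueError(f"heads={self.heads} must divide embed_dim={self.embed_dim}")
        if self.query_modality not in self.modalities:
            raise ValueError(f"query_modality {self.query_modality!r} not among modalities")
        if self.mode in ("cross_attention", "transformer_decoder") and len(self.modalities) < 2:
            raise ValueError(f"{self.mode} needs at least two modalities")

    @property
    def fused_dim(self) -> int:
        return self.embed_dim * len(self.modalities) if self.mode == "concat" else self.embed_dim


@dataclass(frozen=True)
class DetectionResult:
    """Binary decision with the cancer probability that produced it."""

    label: str
    score: float

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")
        if self.label not in ("normal", "cancer"):
            raise ValueError(f"label must be 'normal' or 'cancer', got {self.label!r}")


# ---------------------------------------------------------------------------
# modality preparation
# ---------------------------------------------------------------------------

def prepare_modality_inputs(image: np.ndarray, seg: SegmentationResult):
    """Three aligned H×W×3 maps: image, palette-rendered mask, noise.

    The noise map keeps its first three channels when K >= 3 and cycles
    channels otherwise, then each channel is standardised to mean 0 /
    sd 1 (constant channels map to 0)."""
    image = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"image must be H×W×3, got {image.shape}")
    if image.shape[:2] != seg.mask.shape:
        raise ValueError(
            f"size mismatch: image {image.shape[:2]} vs segmentation {seg.mask.shape}")
    mask_rgb = MASK_PALETTE[seg.mask.labels % len(MASK_PALETTE)]
    K = seg.noise_map.shape[2]
    noise = seg.noise_map[:, :, [c % K for c in range(3)]].astype(np.float64)
    mu = noise.mean(axis=(0, 1), keepdims=True)
    sd = noise.std(axis=(0, 1), keepdims=True)
    noise = np.where(sd > 0, (noise - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return image, mask_rgb, noise


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------

class SmallCNNBackbone(_nn.Module):
    """Strided conv → GroupNorm → SiLU stages; stride = 2**stages."""

    def __init__(self, rng, stages: int = 3, base_channels: int = 16):
        chans = [3] + [min(base_channels * 2**i, 64) for i in range(stages)]
        self.convs = [_nn.Conv2d(chans[i], chans[i + 1], 3, rng, stride=2)
                      for i in range(stages)]
        self.norms = [_nn.GroupNorm(8, chans[i + 1]) for i in range(stages)]
        self.out_channels = chans[-1]
        self.stride = 2**stages

    def __call__(self, x: Tensor) -> Tensor:
        for conv, norm in zip(self.convs, self.norms):
            x = norm(conv(x)).silu()
        return x


class _MBConv(_nn.Module):
    """Inverted bottleneck: expand 1×1, depthwise 3×3, project 1×1."""

    def __init__(self, c_in: int, c_out: int, rng, stride: int = 1, expand: int = 4):
        ce = c_in * expand
        self.expand = _nn.Conv2d(c_in, ce, 1, rng, pad=0)
        self.norm1 = _nn.GroupNorm(8, ce)
        self.dw = _nn.Conv2d(ce, ce, 3, rng, stride=stride, groups=ce)
        self.norm2 = _nn.GroupNorm(8, ce)
        self.project = _nn.Conv2d(ce, c_out, 1, rng, pad=0)
        self.norm3 = _nn.GroupNorm(8, c_out)
        self.residual = stride == 1 and c_in == c_out

    def __call__(self, x: Tensor) -> Tensor:
        h = self.norm1(self.expand(x)).silu()
        h = self.norm2(self.dw(h)).silu()
        h = self.norm3(self.project(h))
        return x + h if self.residual else h


class MBConvBackbone(_nn.Module):
    """Stem conv plus a stack of stride-2 MBConv stages (swish activation)."""

    def __init__(self, rng, stages: int = 3, base_channels: int = 16):
        self.stem = _nn.Conv2d(3, base_channels, 3, rng, stride=2)
        self.stem_norm = _nn.GroupNorm(8, base_channels)
        chans = [base_channels] + [min(base_channels * 2**i, 64) for i in range(1, stages)]
        self.blocks = [_MBConv(chans[i], chans[i + 1], rng, stride=2)
                       for i in range(stages - 1)]
        self.out_channels = chans[-1]
        self.stride = 2**stages

    def __call__(self, x: Tensor) -> Tensor:
        x = self.stem_norm(self.stem(x)).silu()
        for block in self.blocks:
            x = block(x)
        return x


class FeatureExtractor(_nn.Module):
    """Backbone plus linear projection of grid cells to embed_dim tokens."""

    def __init__(self, backbone, embed_dim: int, rng):
        self.backbone = backbone
        self.proj = _nn.Linear(backbone.out_channels, embed_dim, rng)
        self.embed_dim = embed_dim

    def tokens(self, x: Tensor) -> Tensor:
        h = self.backbone(x)  # B,C,h,w
        B, C, hh, ww = h.shape
        return self.proj(h.reshape(B, C, hh * ww).transpose(0, 2, 1))  # B,L,D


def build_backbone(kind: str, embed_dim: int, rng_seed: int,
                   stages: int = 3) -> FeatureExtractor:
    rng = np.random.default_rng(int(rng_seed))
    if kind == "small":
        backbone = SmallCNNBackbone(rng, stages=stages)
    elif kind == "mbconv":
        backbone = MBConvBackbone(rng, stages=stages)
    else:
        raise ValueError(f"unknown backbone kind {kind!r}")
    return FeatureExtractor(backbone, embed_dim, rng)


def extract_features(extractor: FeatureExtractor, input_map: np.ndarray,
                     modality_tag: str = "image") -> ModalityFeatures:
    """Tokenise one H×W×3 map; spatial size must divide the backbone stride."""
    arr = np.asarray(input_map, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"input must be H×W×3, got {arr.shape}")
    stride = extractor.backbone.stride
    if arr.shape[0] % stride or arr.shape[1] % stride:
        raise ValueError(f"spatial size {arr.shape[:2]} not divisible by stride {stride}")
    toks = extractor.tokens(Tensor(arr.transpose(2, 0, 1)[None]))
    return ModalityFeatures(tokens=toks.data[0], modality_tag=modality_tag)


# ---------------------------------------------------------------------------
# fusion mechanisms
# ---------------------------------------------------------------------------

class _DecoderLayer(_nn.Module):
    """Pre-norm transformer decoder layer: self-attn, cross-attn, FFN."""

    def __init__(self, dim: int, heads: int, rng):
        self.self_attn = _nn.MultiheadAttention(dim, heads, rng)
        self.cross_attn = _nn.MultiheadAttention(dim, heads, rng)
        self.norm1 = _nn.LayerNorm(dim)
        self.norm2 = _nn.LayerNorm(dim)
        self.norm3 = _nn.LayerNorm(dim)
        self.ff1 = _nn.Linear(dim, 4 * dim, rng)
        self.ff2 = _nn.Linear(4 * dim, dim, rng)

    def __call__(self, q: Tensor, memory: Tensor) -> Tensor:
        h = self.norm1(q)
        q = q + self.self_attn(h, h)
        q = q + self.cross_attn(self.norm2(q), memory)
        return q + self.ff2(self.ff1(self.norm3(q)).silu())


class FusionModule(_nn.Module):
    """Parameterised fusion of modality token bundles into one vector."""

    def __init__(self, config: FusionConfig, rng_seed: int):
        rng = np.random.default_rng(int(rng_seed))
        self.config = config
        D = config.embed_dim
        # learned per-modality embedding so attention can tell streams apart
        self.modality_embed = Tensor(rng.normal(0.0, 0.02, (len(MODALITIES), D)),
                                     requires_grad=True)
        if config.mode == "self_attention":
            self.attn = [_nn.MultiheadAttention(D, config.heads, rng)
                         for _ in range(config.layers)]
            self.norms = [_nn.LayerNorm(D) for _ in range(config.layers)]
        elif config.mode == "cross_attention":
            self.attn = [_nn.MultiheadAttention(D, config.heads, rng)]
            self.norms = [_nn.LayerNorm(D)]
        elif config.mode == "transformer_decoder":
            self.decoder_layers = [_DecoderLayer(D, config.heads, rng)
                                   for _ in range(config.layers)]

    def _embed(self, toks: Tensor, tag: str) -> Tensor:
        D = self.config.embed_dim
        idx = MODALITIES.index(tag)
        h = toks + self.modality_embed.slice_axis(0, idx, idx + 1)
        if self.config.positional_encoding:
            L = toks.shape[1]
            pos = sinusoidal_time_embedding(np.arange(L, dtype=np.float64), D)
            h = h + Tensor(pos.reshape(1, L, D))
        return h

    def __call__(self, bundles: dict[str, Tensor]) -> Tensor:
        cfg = self.config
        missing = [m for m in cfg.modalities if m not in bundles]
        if missing:
            raise ValueError(f"missing modality features: {missing}")
        if cfg.mode == "concat":
            pooled = [bundles[m].mean(axis=1) for m in cfg.modalities]
            return _nn.concat(pooled, axis=-1)
        embedded = {m: self._embed(bundles[m], m) for m in cfg.modalities}
        if cfg.mode == "self_attention":
            h = _nn.concat([embedded[m] for m in cfg.modalities], axis=1)
            for attn, norm in zip(self.attn, self.norms):
                hn = norm(h)
                h = h + attn(hn, hn)
            return h.mean(axis=1)
        q = embedded[cfg.query_modality]
        memory = _nn.concat([embedded[m] for m in cfg.modalities
                             if m != cfg.query_modality], axis=1)
        if cfg.mode == "cross_attention":
            h = q + self.attn[0](self.norms[0](q), memory)
            return h.mean(axis=1)
        for layer in self.decoder_layers:  # transformer_decoder
            q = layer(q, memory)
        return q.mean(axis=1)


class ClassifierHead(_nn.Module):
    def __init__(self, in_dim: int, rng):
        self.fc = _nn.Linear(in_dim, 2, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc(x)


def fuse(features: list[ModalityFeatures], config: FusionConfig,
         handle: FusionModule) -> np.ndarray:
    """Fuse token bundles into a single fixed-dimension vector."""
    bundles = {f.modality_tag: Tensor(np.asarray(f.tokens)[None]) for f in features}
    return handle(bundles).data[0]


def classify(fused: np.ndarray, head: ClassifierHead,
             threshold: float = 0.5) -> DetectionResult:
    """Softmax score for the cancer class, thresholded (cancer at >=)."""
    logits = head(Tensor(np.asarray(fused, dtype=np.float64)[None])).data[0]
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    z = logits - logits.max()
    p = np.exp(z) / np.exp(z).sum()
    score = float(p[1])
    return DetectionResult(label="cancer" if score >= threshold else "normal", score=score)


# ---------------------------------------------------------------------------
# detector assembly and training
# ---------------------------------------------------------------------------

@dataclass
class DetectorTrainSettings:
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 32
    weight_decay: float = 0.01
    augment: bool = True  # random dihedral (flip/rot90) transforms


def _dihedral(batch: np.ndarray, k: int, flip: bool) -> np.ndarray:
    """Apply one of the 8 square symmetries to a B×C×H×W batch."""
    out = np.rot90(batch, k, axes=(2, 3))
    if flip:
        out = out[:, :, :, ::-1]
    return np.ascontiguousarray(out)


class DetectorModel(_nn.Module):
    """Backbone(s) + fusion + head; the trainable detection stack."""

    def __init__(self, fusion_config: FusionConfig, rng_seed: int,
                 backbone: str = "small", stages: int = 3, shared_backbone: bool = True):
        self.config = fusion_config
        self.seed = int(rng_seed)
        if shared_backbone:
            ext = build_backbone(backbone, fusion_config.embed_dim, rng_seed, stages)
            self.extractors = {m: ext for m in fusion_config.modalities}
            self._extractor_list = [ext]
        else:
            self._extractor_list = [
                build_backbone(backbone, fusion_config.embed_dim, rng_seed + i, stages)
                for i, _ in enumerate(fusion_config.modalities)]
            self.extractors = dict(zip(fusion_config.modalities, self._extractor_list))
        self.fusion = FusionModule(fusion_config, rng_seed + 101)
        self.head = ClassifierHead(fusion_config.fused_dim,
                                   np.random.default_rng(rng_seed + 202))

    def forward(self, inputs: dict[str, np.ndarray]) -> Tensor:
        bundles = {m: self.extractors[m].tokens(Tensor(inputs[m]))
                   for m in self.config.modalities}
        return self.head(self.fusion(bundles))

    def predict_scores(self, inputs: dict[str, np.ndarray]) -> np.ndarray:
        logits = self.forward(inputs).data
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p[:, 1] / p.sum(axis=1)


def build_detector(fusion_config: FusionConfig, rng_seed: int,
                   backbone: str = "small", stages: int = 3,
                   shared_backbone: bool = True) -> DetectorModel:
    return DetectorModel(fusion_config, rng_seed, backbone=backbone,
                         stages=stages, shared_backbone=shared_backbone)


def _cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    m = logits.data.max(axis=1, keepdims=True)  # constant shift for stability
    z = logits - Tensor(m)
    lse = z.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(y)), y] = 1.0
    picked = (z * Tensor(onehot)).sum(axis=1, keepdims=True)
    return (lse - picked).mean()


def modality_batches(patches, segs, modalities):
    """Stack prepared modality maps for a list of patches into B×3×H×W."""
    prepared = [prepare_modality_inputs(p.image, s) for p, s in zip(patches, segs)]
    stacked = {}
    for i, tag in enumerate(MODALITIES):
        if tag in modalities:
            stacked[tag] = np.stack([pr[i].transpose(2, 0, 1) for pr in prepared])
    return stacked


def train_detector(data, segs, detector: DetectorModel,
                   settings: DetectorTrainSettings | None = None,
                   rng_seed: int = 0):
    """Fit the detection stack on (patch, label) pairs with frozen masks.

    ``segs`` are the precomputed segmentation results of the frozen
    diffusion stage (one per patch, in order); no gradient reaches the
    segmenter. Returns (detector, per-epoch accuracy trace).
    """
    settings = settings or DetectorTrainSettings()
    patches = [d[0] for d in data]
    labels = [d[1] for d in data]
    for lab in labels:
        if lab not in ("normal", "cancer"):
            raise ValueError(f"label must be 'normal' or 'cancer', got {lab!r}")
    y = np.array([1 if lab == "cancer" else 0 for lab in labels], dtype=np.int64)
    inputs = modality_batches(patches, segs, detector.config.modalities)
    n = len(patches)
    logger.info("train_detector: %d samples, %d epochs, seed=%d", n, settings.epochs, rng_seed)
    rng = np.random.default_rng(int(rng_seed))
    opt = _nn.AdamW(detector.parameters(), lr=settings.lr,
                    weight_decay=settings.weight_decay)
    acc_trace = []
    for _epoch in range(settings.epochs):
        order = rng.permutation(n)
        correct = 0
        for start in range(0, n, settings.batch_size):
            idx = order[start:start + settings.batch_size]
            batch = {m: inputs[m][idx] for m in inputs}
            if settings.augment:
                k = int(rng.integers(0, 4))
                flip = bool(rng.integers(0, 2))
                batch = {m: _dihedral(v, k, flip) for m, v in batch.items()}
            logits = detector.forward(batch)
            loss = _cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            correct += int(np.sum(np.argmax(logits.data, axis=1) == y[idx]))
        acc_trace.append(correct / n)
    return detector, acc_trace


def evaluate_detector(detector: DetectorModel, data, segs, threshold: float = 0.5):
    """Scores, predicted labels and accuracy on held-out (patch, label) pairs."""
    patches = [d[0] for d in data]
    y = np.array([1 if d[1] == "cancer" else 0 for d in data], dtype=np.int64)
    inputs = modality_batches(patches, segs, detector.config.modalities)
    scores = detector.predict_scores(inputs)
    pred = (scores >= threshold).astype(np.int64)
    return scores, pred, float(np.mean(pred == y))


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

ABLATION_SCENARIOS = (
    ("image_only", "concat", ("image",)),
    ("simple_fusion_three", "concat", ("image", "mask", "noise")),
    ("self_attention_three", "self_attention", ("image", "mask", "noise")),
    ("cross_attention_three", "cross_attention", ("image", "mask", "noise")),
    ("transformer_decoder_two", "transformer_decoder", ("image", "mask")),
    ("transformer_decoder_three", "transformer_decoder", ("image", "mask", "noise")),
)


def run_fusion_ablation(train_data, train_segs, test_data, test_segs,
                        settings: DetectorTrainSettings | None = None,
                        rng_seed: int = 0, embed_dim: int = 32,
                        backbone: str = "small", stages: int = 3):
    """Train and score every fusion mode / modality-subset scenario.

    Returns a list of row dicts (scenario, mode, modalities, accuracy,
    95% CI bounds, PR-AUC) — one comparison table over the same data and
    frozen segmentations.
    """
    from .metrics import binomial_ci, pr_auc  # local import: avoid cycle

    rows = []
    y_test = np.array([1 if d[1] == "cancer" else 0 for d in test_data], dtype=np.int64)
    for i, (name, mode, modalities) in enumerate(ABLATION_SCENARIOS):
        cfg = FusionConfig(mode=mode, modalities=modalities, embed_dim=embed_dim)
        detector = build_detector(cfg, rng_seed + 10 * i, backbone=backbone, stages=stages)
        detector, _ = train_detector(train_data, train_segs, detector, settings,
                                     rng_seed=rng_seed + 10 * i + 1)
        scores, _, acc = evaluate_detector(detector, test_data, test_segs)
        lo, hi = binomial_ci(acc, len(y_test))
        auc = pr_auc(scores, y_test) if y_test.any() else float("nan")
        rows.append({"scenario": name, "mode": mode,
                     "modalities": "+".join(modalities),
                     "accuracy": acc, "ci_lo": lo, "ci_hi": hi, "pr_auc": auc})
    return rows


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_detector(path, detector: DetectorModel, backbone: str = "small",
                  stages: int = 3) -> None:
    import json

    cfg = detector.config
    meta = json.dumps({
        "fusion": {"mode": cfg.mode, "modalities": list(cfg.modalities),
                   "embed_dim": cfg.embed_dim, "heads": cfg.heads,
                   "layers": cfg.layers, "query_modality": cfg.query_modality,
                   "positional_encoding": cfg.positional_encoding},
        "backbone": backbone, "stages": stages, "seed": detector.seed,
    })
    np.savez(str(path), __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **detector.state_dict())


def load_detector(path) -> DetectorModel:
    import json

    with np.load(str(path)) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    f = meta["fusion"]
    cfg = FusionConfig(mode=f["mode"], modalities=tuple(f["modalities"]),
                       embed_dim=f["embed_dim"], heads=f["heads"], layers=f["layers"],
                       query_modality=f["query_modality"],
                       positional_encoding=f["positional_encoding"])
    detector = build_detector(cfg, meta["seed"], backbone=meta["backbone"],
                              stages=meta["stages"])
    detector.load_state_dict(state)
    return detector
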