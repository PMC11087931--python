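"""Compact 3D residual UNet segmenter: loss, training, inference, pipeline.

The network maps the two window/level-normalised channels of a heart-centred
crop to five classes (background + RightAtrium, AorticValveRoot, LCA, RCA) and
is trained with a weighted multiclass soft Dice loss and Adam. Cases are split
80/20 into training and validation by a seeded shuffle. Training runs on the
CPU and is fully deterministic given the seed (single-threaded execution).

The weighted multiclass soft Dice loss over per-voxel class probabilities
p_c and one-hot targets g_c is

    D_c  = (2 * sum p_c g_c + eps) / (sum p_c + sum g_c + eps)
    loss = 1 - sum_c w_c D_c / sum_c w_c            in [0, 1].

Class weights default to uniform: the per-class normalisation inside the Dice
terms already prevents the background from swamping the thin coronary tubes,
and an inverse-volume weighting (provided as an option) destabilises training
by starving the background term.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import CapabilityError, ParameterError
from .nn import Adam, UNet3D
from .postprocess import assemble_caa, clean_structure, pad_to_original
from .preprocess import (
    DEFAULT_CROP_SIZE,  # noqa: F401  (re-exported: part of the segmenter surface)
    DEFAULT_WINDOWS,
    crop_volume,
    localize_heart,
    normalize_channels,
    remove_metal_artifacts,
)
from .volume_io import LABEL_REGISTRY, NUM_CLASSES, ImageVolume, StructureSet


#: Crop used with desk-scale phantoms: the heart fits with margin at (3, 3, 6) mm.
DESK_CROP_SIZE = (48, 48, 24)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the compact residual UNet (all knobs config-exposed)."""

    in_channels: int = 2
    num_classes: int = NUM_CLASSES
    depth: int = 3
    base_features: int = 16
    residual: bool = True
    norm: str = "instance"
    upsample: str = "trilinear"

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ParameterError("encoder depth must be >= 2")
        if self.num_classes != NUM_CLASSES:
            raise ParameterError(
                f"num_classes must equal the label registry size ({NUM_CLASSES})"
            )

    @classmethod
    def desk(cls) -> "ModelConfig":
        """Small profile for CPU-budget phantom experiments."""
        return cls(base_features=4)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; the seed covers split, init and shuffling."""

    train_fraction: float = 0.8
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 1
    class_weights: tuple | None = None  # None -> uniform (see default_class_weights)
    eps: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ParameterError("train fraction must be in (0,1)")
        if self.eps <= 0:
            raise ParameterError("Dice smoothing eps must be > 0")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            if (w < 0).any() or not (w > 0).any():
                raise ParameterError("class weights must be >= 0 and not all zero")

    @classmethod
    def desk(cls, seed: int = 0) -> "TrainConfig":
        return cls(epochs=30, learning_rate=3e-3, seed=seed)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def dice_loss(
    probs: np.ndarray,
    target_onehot: np.ndarray,
    weights: Sequence[float] | None = None,
    eps: float = 1e-5,
) -> float:
    """Weighted multiclass soft Dice loss; ``probs`` and ``target_onehot`` are
    (C, ...) with per-voxel probabilities summing to 1."""
    loss, _ = _dice_loss_grad(probs, target_onehot, weights, eps, need_grad=False)
    return loss


def _dice_loss_grad(probs, target, weights, eps, need_grad=True):
    probs = np.asarray(probs)
    target = np.asarray(target)
    if probs.shape != target.shape:
        raise ParameterError(f"shape mismatch: probs {probs.shape} vs target {target.shape}")
    c = probs.shape[0]
    p = probs.reshape(c, -1).astype(np.float64)
    g = target.reshape(c, -1).astype(np.float64)
    w = np.ones(c) if weights is None else np.asarray(weights, dtype=np.float64)
    if w.shape != (c,):
        raise ParameterError(f"need {c} class weights, got shape {w.shape}")
    wbar = w / w.sum()
    inter = (p * g).sum(axis=1)
    denom = p.sum(axis=1) + g.sum(axis=1) + eps
    d_c = (2.0 * inter + eps) / denom
    loss = float(1.0 - (wbar * d_c).sum())
    if not need_grad:
        return loss, None
    # d(loss)/dp_ci = -wbar_c * (2 g_ci * denom_c - (2 inter_c + eps)) / denom_c^2
    grad = -wbar[:, None] * (2.0 * g * denom[:, None] - (2.0 * inter + eps)[:, None]) / (
        denom[:, None] ** 2
    )
    return loss, grad.reshape(probs.shape).astype(np.float32)


def _loss_and_logit_grad(logits, target_onehot, weights, eps):
    p = softmax(logits, axis=0)
    loss, dp = _dice_loss_grad(p, target_onehot, weights, eps)
    # softmax backward: dz = p * (dp - sum_c dp_c p_c)
    inner = (dp * p).sum(axis=0, keepdims=True)
    dz = p * (dp - inner)
    return loss, dz.astype(np.float32), p


def _one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    return (np.arange(num_classes)[:, None, None, None] == labels[None]).astype(np.float32)


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------


def default_class_weights(num_classes: int = NUM_CLASSES) -> np.ndarray:
    """Uniform class weights (sum-normalised).

    Per-class soft Dice already normalises each class by its own volume, so
    uniform weights keep the thin coronary classes on an equal footing with
    the large ones while leaving the background term enough influence to
    suppress background probability inside the structures — volume-derived
    weightings starve that term and can stall training in a
    diffuse-probability plateau (see the methods note).
    """
    return np.full(num_classes, 1.0 / num_classes)


def inverse_volume_weights(
    label_maps: Sequence[np.ndarray], num_classes: int = NUM_CLASSES, power: float = 1.0
) -> np.ndarray:
    """Inverse mean per-class voxel volume (optionally tempered), sum-normalised."""
    counts = np.zeros(num_classes, dtype=np.float64)
    for y in label_maps:
        counts += np.bincount(np.asarray(y).reshape(-1), minlength=num_classes)[:num_classes]
    mean = counts / len(label_maps)
    w = (1.0 / np.maximum(mean, 1.0)) ** power
    return w / w.sum()


def split_cases(n: int, train_fraction: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Seeded case-level shuffle split; always leaves >= 1 case on each side."""
    if n < 2:
        raise ParameterError("need at least 2 cases to split into train/validation")
    order = rng.permutation(n)
    n_train = int(np.clip(round(train_fraction * n), 1, n - 1))
    return order[:n_train], order[n_train:]


def train(
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(),
) -> tuple[UNet3D, dict]:
    """Train a UNet on (input tensor, label map) pairs.

    Returns the trained model and a history dict with per-epoch mean training
    and validation Dice loss, the case split, and the class weights used.
    """
    cfg = train_config
    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx = split_cases(len(dataset), cfg.train_fraction, rng)
    weights = (
        np.asarray(cfg.class_weights, dtype=np.float64)
        if cfg.class_weights is not None
        else default_class_weights(model_config.num_classes)
    )
    model = UNet3D(
        in_channels=model_config.in_channels,
        num_classes=model_config.num_classes,
        depth=model_config.depth,
        base_features=model_config.base_features,
        residual=model_config.residual,
        norm=model_config.norm,
        upsample=model_config.upsample,
        seed=int(rng.integers(2**31 - 1)),
    )
    opt = Adam(model.params(), lr=cfg.learning_rate)
    onehots = {i: _one_hot(np.asarray(dataset[i][1]), model_config.num_classes) for i in range(len(dataset))}

    history: dict = {
        "train_loss": [],
        "val_loss": [],
        "train_cases": train_idx.tolist(),
        "val_cases": val_idx.tolist(),
        "class_weights": weights.tolist(),
    }
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(train_idx))
        losses = []
        pending = 0
        model.zero_grad()
        for j, k in enumerate(order):
            i = train_idx[k]
            x = np.ascontiguousarray(dataset[i][0], dtype=np.float32)
            logits = model.forward(x)
            loss, dz, _ = _loss_and_logit_grad(logits, onehots[i], weights, cfg.eps)
            model.backward(dz)
            losses.append(loss)
            pending += 1
            if pending == cfg.batch_size or j == len(order) - 1:
                if pending > 1:
                    for _, grad in model.params():
                        grad /= pending
                opt.step()
                model.zero_grad()
                pending = 0
        val_losses = []
        for i in val_idx:
            x = np.ascontiguousarray(dataset[i][0], dtype=np.float32)
            p = softmax(model.forward(x), axis=0)
            val_losses.append(dice_loss(p, onehots[i], weights, cfg.eps))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(np.mean(val_losses)))
    return model, history


def infer(model: UNet3D, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class probability maps and argmax label map for one input tensor.

    Ties in the argmax resolve to the lowest class index (deterministic).
    """
    x = np.ascontiguousarray(x, dtype=np.float32)
    if x.ndim != 4 or x.shape[0] != model.enc[0].conv1.cin:
        raise ParameterError(
            f"input must be (C={model.enc[0].conv1.cin}, D, H, W), got {x.shape}"
        )
    probs = softmax(model.forward(x), axis=0)
    return probs, np.argmax(probs, axis=0).astype(np.uint8)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_model(model: UNet3D, config: ModelConfig, path: str | Path) -> Path:
    """Bundle weights + ModelConfig into one .npz checkpoint."""
    path = Path(path)
    arrays = {f"param_{i}": p for i, (p, _) in enumerate(model.params())}
    np.savez_compressed(path, __config__=np.frombuffer(json.dumps(asdict(config)).encode(), dtype=np.uint8), **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_model(path: str | Path) -> tuple[UNet3D, ModelConfig]:
    with np.load(Path(path), allow_pickle=False) as data:
        config = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = UNet3D(
            in_channels=config.in_channels,
            num_classes=config.num_classes,
            depth=config.depth,
            base_features=config.base_features,
            residual=config.residual,
            norm=config.norm,
            upsample=config.upsample,
            seed=0,
        )
        for i, (p, _) in enumerate(model.params()):
            p[...] = data[f"param_{i}"]
    return model, config


def export_onnx(model: UNet3D, path: str | Path) -> None:
    """Export the trained network as an ONNX graph (optional feature).

    This build computes with a NumPy backend and ships no ONNX exporter; the
    operation raises :class:`CapabilityError` so the core pipeline is
    unaffected by the missing optional runtime.
    """
    raise CapabilityError(
        "ONNX export is not available: no ONNX exporter/runtime is installed for "
        "the NumPy compute backend"
    )


# ---------------------------------------------------------------------------
# end-to-end case pipeline
# ---------------------------------------------------------------------------


def prepare_case(
    ct: ImageVolume,
    label_map: np.ndarray | None = None,
    crop_size: tuple[int, int, int] = DEFAULT_CROP_SIZE,
    windows=DEFAULT_WINDOWS,
    centre: tuple[int, int, int] | None = None,
):
    """Preprocess one CT (localise -> crop -> de-metal -> normalise).

    Returns ``(x, region)`` or ``(x, y, region)`` when a label map is given;
    ``x`` is the stacked channel tensor on the crop grid.
    """
    if centre is None:
        centre = localize_heart(ct)
    cropped, region = crop_volume(ct, centre, crop_size)
    cropped = remove_metal_artifacts(cropped)
    x = normalize_channels(cropped, windows)
    if label_map is None:
        return x, region
    y_vol, _ = crop_volume(
        ImageVolume(np.asarray(label_map), ct.spacing, ct.origin, "LABEL"), centre, crop_size, fill_hu=0
    )
    return x, y_vol.voxels.astype(np.uint8), region


def segment_case(
    ct: ImageVolume,
    model: UNet3D,
    crop_size: tuple[int, int, int] = DEFAULT_CROP_SIZE,
    windows=DEFAULT_WINDOWS,
    opening_mm: float | None = None,
    min_component_cc: float = 0.05,
) -> StructureSet:
    """Full inference pipeline on one CT: preprocess, infer, clean, assemble
    the CAA and restore the original grid. Returns an ``"auto"`` structure set
    containing the four substructures plus the CAA."""
    x, region = prepare_case(ct, crop_size=crop_size, windows=windows)
    _, labels = infer(model, x)
    cleaned = {}
    for name, value in LABEL_REGISTRY.items():
        mask = (labels == value).astype(np.uint8)
        mask = clean_structure(mask, ct.spacing, opening_mm=opening_mm, min_component_cc=min_component_cc)
        cleaned[name] = mask
    caa = assemble_caa(cleaned)
    out = StructureSet(grid=ct.grid, structures={}, observer="auto")
    for name, mask in cleaned.items():
        out.add(name, pad_to_original(mask, region))
    out.add("CAA", pad_to_original(caa, region))
    return out
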