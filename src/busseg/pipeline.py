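"""End-to-end orchestration: train / evaluate / predict plus the
resolution and ablation sweeps, on directory datasets or generated
phantoms.  Every run is fully seeded and writes its resolved configuration
next to its outputs so it can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nn
from .augment import expand_training_set
from .data import load_directory, resize_pair
from .metrics import MetricsReport, evaluate_masks, dice_coefficient, iou
from .models import ModelConfig, SegmentationNet, build_model, forward
from .phantom import SamplePair, generate_dataset

__all__ = [
    "RunConfig",
    "SplitManifest",
    "TrainResult",
    "default_batch_size",
    "prepare_data",
    "train",
    "evaluate",
    "predict",
    "resolution_sweep",
    "ablation_sweep",
]

SWEEP_SIDES = (64, 96, 128, 256)
SWEEP_VARIANTS = ("rau", "dau", "rdu", "rdau")


def default_batch_size(input_side: int) -> int:
    """32 for sides up to 128, 16 at 256."""
    return 32 if input_side <= 128 else 16


@dataclass
class RunConfig:
    variant: str = "rdau"
    input_side: int = 128
    batch_size: int | None = None      # None -> resolution-dependent default
    epochs: int = 300
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    augment: bool = False
    seed: int = 0
    out_dir: str | None = None
    threshold: float = 0.5
    # data source: either a directory of image/mask pairs with optional
    # val/test directories, or a synthetic phantom benchmark
    data_dir: str | None = None
    val_dir: str | None = None
    test_dir: str | None = None
    synthetic: dict = field(default_factory=dict)  # n_train/n_val/n_test/mix
    # channel-schedule overrides (None -> the standard schedules); mainly
    # for fast desk-scale experiments
    encoder_filters: list | None = None
    decoder_filters: list | None = None

    def __post_init__(self):
        if self.batch_size is None:
            self.batch_size = default_batch_size(self.input_side)
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def model_config(self) -> ModelConfig:
        kwargs = dict(input_side=self.input_side, seed=self.seed)
        if self.encoder_filters is not None:
            kwargs["encoder_filters"] = tuple(self.encoder_filters)
        if self.decoder_filters is not None:
            kwargs["decoder_filters"] = tuple(self.decoder_filters)
        return ModelConfig.for_variant(self.variant, **kwargs)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class SplitManifest:
    """Disjoint train/validation/test listings with per-item checksums."""

    train: list = field(default_factory=list)
    validation: list = field(default_factory=list)
    test: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for split in ("train", "validation", "test"):
            for ident, digest in getattr(self, split):
                rows.append({"split": split, "item": ident, "sha256": digest})
        return pd.DataFrame(rows)


def _checksum(sample: SamplePair) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(sample.image).tobytes())
    h.update(np.ascontiguousarray(sample.mask).tobytes())
    return h.hexdigest()[:16]


def _listing(samples, prefix):
    return [(f"{prefix}_{i:04d}", _checksum(s)) for i, s in enumerate(samples)]


def prepare_data(config: RunConfig):
    """Resolve the configured data source into resized train/val/test lists.

    Synthetic mode generates disjoint splits from one seed; directory mode
    loads ``data_dir`` (plus optional ``val_dir``/``test_dir``; without
    them, an 80/10/10 split of the sorted listing is used).
    """
    side = config.input_side
    if config.data_dir:
        pairs = load_directory(config.data_dir)
        if config.val_dir and config.test_dir:
            tr = pairs
            va = load_directory(config.val_dir)
            te = load_directory(config.test_dir)
        else:
            n = len(pairs)
            n_va, n_te = max(n // 10, 1), max(n // 10, 1)
            tr = pairs[: n - n_va - n_te]
            va = pairs[n - n_va - n_te: n - n_te]
            te = pairs[n - n_te:]
    else:
        syn = dict(config.synthetic)
        n_tr = int(syn.get("n_train", 100))
        n_va = int(syn.get("n_val", 20))
        n_te = int(syn.get("n_test", 20))
        mix = float(syn.get("mix", 0.5))
        samples, _ = generate_dataset(n_tr + n_va + n_te, side=side, mix=mix,
                                      seed=config.seed)
        # interleave kinds across splits: benign-first ordering would
        # otherwise put all malignant-like phantoms in one split
        order = np.random.default_rng(config.seed + 1).permutation(len(samples))
        samples = [samples[i] for i in order]
        tr = samples[:n_tr]
        va = samples[n_tr: n_tr + n_va]
        te = samples[n_tr + n_va:]
    tr = [resize_pair(s, side) for s in tr]
    va = [resize_pair(s, side) for s in va]
    te = [resize_pair(s, side) for s in te]
    manifest = SplitManifest(train=_listing(tr, "train"),
                             validation=_listing(va, "val"),
                             test=_listing(te, "test"))
    return tr, va, te, manifest


def _stack(samples):
    images = np.stack([s.image for s in samples])[..., None].astype(np.float32)
    masks = np.stack([s.mask for s in samples])[..., None].astype(np.float32)
    return images, masks


def _infer(model: SegmentationNet, images: np.ndarray, batch_size: int):
    outs = []
    for i in range(0, len(images), batch_size):
        outs.append(forward(model, images[i: i + batch_size]))
    return np.concatenate(outs)


@dataclass
class TrainResult:
    model: SegmentationNet
    history: pd.DataFrame
    best_epoch: int
    best_val_dice: float
    manifest: SplitManifest
    wall_time_s: float


def _epoch_row(prefix: str, report: MetricsReport) -> dict:
    r = report.to_row()
    r.pop("AUC-PR")
    r.pop("AUC")  # per-epoch curves track the eight loss/overlap scores
    return {f"{prefix}_{k}": v for k, v in r.items()}


def train(config: RunConfig, data=None) -> TrainResult:
    """Train a model under ``config``, minimizing soft Dice loss.

    ``data`` may pre-resolve (train, val, test, manifest); otherwise the
    configured source is used.  Logs the per-epoch train/val metric set,
    keeps the best-validation-Dice weights, and (if ``out_dir`` is set)
    writes the frozen config, history CSV, split manifest and weights.
    """
    t_start = time.time()
    tr, va, te, manifest = data if data is not None else prepare_data(config)
    if not tr or not va:
        raise ValueError("training requires non-empty train and val sets")
    if config.augment:
        tr, _ = expand_training_set(tr, seed=config.seed)
    desc, model = build_model(config.model_config())
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    x_tr, y_tr = _stack(tr)
    va_images = np.stack([s.image for s in va])
    va_masks = [s.mask for s in va]

    history_rows = []
    best_state, best_epoch, best_val_dice = None, -1, -np.inf
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(x_tr))
        losses = []
        train_probs = np.empty(
            (len(x_tr),) + x_tr.shape[1:3], dtype=np.float32)
        for i in range(0, len(order), config.batch_size):
            idx = order[i: i + config.batch_size]
            out = model(nn.Tensor(x_tr[idx]))
            loss = nn.soft_dice_loss(out, y_tr[idx])
            loss.backward()
            opt.step()
            opt.zero_grad()
            losses.append(loss.item())
            train_probs[idx] = np.asarray(out.data)[..., 0]
        train_report = evaluate_masks([s.mask for s in tr], list(train_probs),
                                      threshold=config.threshold)
        model.eval()
        val_probs = _infer(model, va_images, config.batch_size)
        val_report = evaluate_masks(va_masks, list(val_probs),
                                    threshold=config.threshold)
        row = {"epoch": epoch + 1, "train_batch_loss": float(np.mean(losses))}
        row.update(_epoch_row("train", train_report))
        row.update(_epoch_row("val", val_report))
        history_rows.append(row)
        if val_report.dc > best_val_dice:
            best_val_dice = val_report.dc
            best_epoch = epoch + 1
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    history = pd.DataFrame(history_rows)
    result = TrainResult(model=model, history=history, best_epoch=best_epoch,
                         best_val_dice=float(best_val_dice),
                         manifest=manifest,
                         wall_time_s=time.time() - t_start)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "run_config.yaml")
        history.to_csv(out / "history.csv", index=False)
        manifest.to_frame().to_csv(out / "split_manifest.csv", index=False)
        np.savez(out / "weights.npz", **model.state_dict())
        with open(out / "network.txt", "w") as fh:
            for layer in desc.layers:
                fh.write(f"{layer.kind}\t{layer.input_shape}\t"
                         f"{layer.output_shape}\t{layer.n_params}\n")
            fh.write(f"total\t\t\t{desc.total_params}\n")
    return result


def load_weights(config: RunConfig, weights_path) -> SegmentationNet:
    _, model = build_model(config.model_config())
    with np.load(weights_path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def evaluate(model: SegmentationNet, test_samples, threshold: float = 0.5,
             batch_size: int = 16):
    """Nine-score report over a test set, plus per-image scores and the
    pooled ROC / precision-recall curve points."""
    if not test_samples:
        raise ValueError("evaluate requires a non-empty test set")
    side = model.config.input_side
    for s in test_samples:
        if s.image.shape != (side, side):
            raise ValueError(
                f"test image shape {s.image.shape} does not match model "
                f"resolution {side}x{side}")
    images = np.stack([s.image for s in test_samples])
    gold = [s.mask for s in test_samples]
    probs = _infer(model, images, batch_size)
    report = evaluate_masks(gold, list(probs), threshold=threshold)

    per_image = pd.DataFrame([
        {
            "index": i,
            "dice_soft": dice_coefficient(g, p),
            "dice_binary": dice_coefficient(g, (p >= threshold).astype(np.uint8)),
            "iou": iou(g, (p >= threshold).astype(np.uint8)),
            "lesion_pixels": int(g.sum()),
        }
        for i, (g, p) in enumerate(zip(gold, probs))
    ])

    from sklearn.metrics import precision_recall_curve, roc_curve
    y = np.concatenate([g.ravel() for g in gold])
    s = np.concatenate([p.ravel() for p in probs])
    fpr, tpr, _ = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    curves = {"roc": pd.DataFrame({"fpr": fpr, "tpr": tpr}),
              "pr": pd.DataFrame({"recall": rec, "precision": prec})}
    return report, per_image, curves


def predict(model: SegmentationNet, images, threshold: float = 0.5):
    """Probability maps, binarized masks and contour overlays for a batch."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    probs = _infer(model, images, batch_size=16)
    masks = (probs >= threshold).astype(np.uint8)
    from scipy.ndimage import binary_erosion
    overlays = []
    for img, m in zip(images, masks):
        contour = m.astype(bool) & ~binary_erosion(m.astype(bool))
        ov = img.copy()
        ov[contour] = 1.0
        overlays.append(ov)
    return probs, masks, np.stack(overlays)


def _sweep(config: RunConfig, axis_name: str, values, configure) -> pd.DataFrame:
    rows = []
    for value in values:
        cfg = configure(config, value)
        result = train(cfg)
        _, _, te, _ = prepare_data(cfg)
        report, _, _ = evaluate(result.model, te, threshold=cfg.threshold,
                                batch_size=cfg.batch_size)
        row = {axis_name: value}
        row.update(report.to_row())
        row["Train(s)"] = round(result.wall_time_s, 1)
        row["Params"] = build_model(cfg.model_config())[0].total_params
        rows.append(row)
    return pd.DataFrame(rows)


def resolution_sweep(config: RunConfig, sides=SWEEP_SIDES) -> pd.DataFrame:
    """One train+evaluate row per input resolution."""
    def configure(base, side):
        d = asdict(base)
        d.update(input_side=side, batch_size=default_batch_size(side))
        if base.out_dir:
            d["out_dir"] = str(Path(base.out_dir) / f"side_{side}")
        return RunConfig(**d)
    return _sweep(config, "Input Size", list(sides), configure)


def ablation_sweep(config: RunConfig, variants=SWEEP_VARIANTS) -> pd.DataFrame:
    """One train+evaluate row per architecture variant."""
    def configure(base, variant):
        d = asdict(base)
        d.update(variant=variant)
        if base.out_dir:
            d["out_dir"] = str(Path(base.out_dir) / f"variant_{variant}")
        return RunConfig(**d)
    return _sweep(config, "Experimental Model", list(variants), configure)
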