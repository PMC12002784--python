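"""Modality-specific 2D radial-plane segmentation networks.

One network is trained per ultrasound modality (B-mode, CEUS).  Each network
is a U-Net-style encoder–decoder that receives three input channels — the
central radial plane plus its two parallel context planes — and emits two
sigmoid output channels: the prostate location and the zone discrimination
(probability of transition zone).  The peripheral zone is derived downstream
by composing the two channels (see :mod:`trusseg.reconstruction`).

Training uses fivefold cross-validation with early stopping: up to
``max_iterations`` epochs, halting once the validation metric (mean
validation Dice) has not improved for ``patience`` consecutive epochs; the
best-epoch weights are retained.  A single master seed drives fold
assignment, weight initialisation and data order.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Adam, UNet2D, dice_bce_loss, unet_parameter_count
from .radial_geometry import RadialGeometry, RadialPlaneStack, extract_stack, slice_mask
from .seg_metrics import dice

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "PlanePrediction",
    "CasePlanes",
    "SegModel",
    "build_network",
    "stopping_epoch",
    "train_fold",
    "crossval",
    "predict_stack",
    "case_planes_from_phantom",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of one modality-specific plane segmentation network."""

    in_channels: int = 3  # central plane + two context planes
    out_channels: int = 2  # prostate; zone discrimination (TZ probability)
    depth: int = 3  # encoder levels
    base_width: int = 8  # first-level feature count
    modality: str = "bmode"

    def __post_init__(self) -> None:
        if self.in_channels != 3:
            raise ValueError("the network takes exactly 3 input channels")
        if self.out_channels != 2:
            raise ValueError("the network has exactly 2 output channels")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_width < 4:
            raise ValueError("base_width must be >= 4")
        if self.modality not in ("bmode", "ceus"):
            raise ValueError("modality must be 'bmode' or 'ceus'")


@dataclass(frozen=True)
class TrainConfig:
    n_folds: int = 5
    max_iterations: int = 60  # epochs
    patience: int = 10  # epochs without validation improvement
    batch_size: int = 8
    learning_rate: float = 3e-3
    seed: int = 0


@dataclass
class PlanePrediction:
    """Two per-plane probability maps for one radial plane."""

    prostate_prob: np.ndarray
    zone_prob: np.ndarray  # probability of transition zone
    plane_index: int
    geometry: RadialGeometry | None = None

    def __post_init__(self) -> None:
        for name, arr in (("prostate_prob", self.prostate_prob),
                          ("zone_prob", self.zone_prob)):
            if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
                raise ValueError(f"{name} outside [0, 1]")


@dataclass
class CasePlanes:
    """Precomputed plane stack of one case, network-ready.

    ``x`` is (n_planes, 3, H, W): channels are (center, context-, context+);
    ``y`` is (n_planes, 2, H, W): targets (prostate mask, TZ mask).
    """

    case_id: str
    x: np.ndarray
    y: np.ndarray
    geometry: RadialGeometry | None = None


class SegModel:
    """A built network plus its preprocessing contract.

    Inputs are standardised per plane and channel (zero mean, unit SD) and
    reflect-padded to a multiple of ``2**depth`` before the forward pass;
    outputs are cropped back and squashed through a sigmoid.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
        self.net = UNet2D(config.in_channels, config.out_channels,
                          config.depth, config.base_width, rng)
        self.geometry: RadialGeometry | None = None  # recorded at training time

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters

    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        step = 2**self.config.depth
        h, w = x.shape[2], x.shape[3]
        if h < step or w < step:
            raise ValueError(f"plane {h}x{w} smaller than 2^depth = {step} per side")
        ph = (-h) % step
        pw = (-w) % step
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        return x, (h, w)

    @staticmethod
    def _normalize(x: np.ndarray) -> np.ndarray:
        x = x.astype(np.float32)
        mean = x.mean(axis=(2, 3), keepdims=True)
        sd = x.std(axis=(2, 3), keepdims=True)
        return (x - mean) / (sd + 1e-6)

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits on the padded grid (training path; no crop)."""
        xp, _ = self._pad(self._normalize(x))
        return self.net.forward(xp, train=train)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Probabilities (N, 2, H, W) in [0, 1] for a raw plane batch."""
        xp, (h, w) = self._pad(self._normalize(np.asarray(x)))
        logits = self.net.forward(xp, train=False)
        probs = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
        return probs[:, :, :h, :w]


def build_network(cfg: ModelConfig, seed: int = 0) -> SegModel:
    """Build an untrained network; its reported parameter count equals the
    architectural closed form (:func:`trusseg._nn.unet_parameter_count`)."""
    model = SegModel(cfg, seed=seed)
    expected = unet_parameter_count(cfg.in_channels, cfg.out_channels,
                                    cfg.depth, cfg.base_width)
    assert model.n_parameters == expected
    return model


def stopping_epoch(metrics, patience: int, max_iterations: int) -> int:
    """Epoch at which training halts for a given validation-metric sequence.

    Training stops after the first epoch that completes ``patience`` epochs
    without strict improvement over the best metric so far, or at
    ``max_iterations``, whichever is earlier.
    """
    best = -np.inf
    best_epoch = 0
    for epoch, m in enumerate(metrics[:max_iterations], start=1):
        if m > best:
            best, best_epoch = m, epoch
        if epoch - best_epoch >= patience:
            return epoch
    return min(len(metrics), max_iterations)


def _pad_target(y: np.ndarray, depth: int) -> np.ndarray:
    step = 2**depth
    ph = (-y.shape[2]) % step
    pw = (-y.shape[3]) % step
    if ph or pw:
        y = np.pad(y, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
    return y


def validation_dice(model: SegModel, val_cases: list[CasePlanes],
                    threshold: float = 0.5, batch: int = 16) -> float:
    """Mean plane-wise Dice over both output channels of the validation set
    (the training loop's early-stopping metric)."""
    scores = []
    for case in val_cases:
        for i0 in range(0, len(case.x), batch):
            probs = model.predict(case.x[i0 : i0 + batch])
            truth = case.y[i0 : i0 + batch]
            for p, t in zip(probs, truth):
                for c in range(p.shape[0]):
                    scores.append(dice(p[c] > threshold, t[c] > 0.5))
    return float(np.mean(scores))


def train_fold(
    model: SegModel,
    train_cases: list[CasePlanes],
    val_cases: list[CasePlanes],
    cfg: TrainConfig,
    val_metric_fn=None,
) -> tuple[SegModel, list[dict]]:
    """Train one fold with early stopping; returns the model (best-epoch
    weights restored) and the per-epoch history.

    ``val_metric_fn(model, epoch) -> float`` may replace the default mean
    validation Dice (used by tests to exercise the stopping rule).
    """
    if not train_cases:
        raise ValueError("empty training set")
    x = np.concatenate([c.x for c in train_cases]).astype(np.float32)
    y = np.concatenate([c.y for c in train_cases]).astype(np.float32)
    y = _pad_target(y, model.config.depth)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7E57]))
    opt = Adam(model.net.params(), lr=cfg.learning_rate)
    history: list[dict] = []
    best = -np.inf
    best_epoch = 0
    best_state = model.net.state()
    for epoch in range(1, cfg.max_iterations + 1):
        perm = rng.permutation(len(x))
        losses = []
        for i0 in range(0, len(perm), cfg.batch_size):
            idx = perm[i0 : i0 + cfg.batch_size]
            logits = model.forward_logits(x[idx], train=True)
            loss, dlogits = dice_bce_loss(logits, y[idx])
            model.net.zero_grad()
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
        if val_metric_fn is not None:
            metric = float(val_metric_fn(model, epoch))
        else:
            metric = validation_dice(model, val_cases)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_dsc": metric})
        if metric > best:
            best, best_epoch = metric, epoch
            best_state = model.net.state()
        if epoch - best_epoch >= cfg.patience:
            break
    model.net.load_state(best_state)
    if train_cases[0].geometry is not None:
        model.geometry = train_cases[0].geometry
    return model, history


@dataclass
class CrossValResult:
    models: list[SegModel]
    fold_assignment: dict[str, int]  # case_id -> fold index in which it validated
    histories: list[list[dict]]
    oof_predictions: dict[str, np.ndarray]  # case_id -> (n_planes, 2, H, W)


def crossval(
    cases: list[CasePlanes],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    train_fn=train_fold,
) -> CrossValResult:
    """Fivefold (by default) cross-validation.

    Fold assignment is a seeded permutation split into ``n_folds`` nearly
    equal parts; every case is in the validation set of exactly one fold and
    receives its out-of-fold prediction from that fold's model.
    """
    if len(cases) < train_cfg.n_folds:
        raise ValueError(
            f"need at least {train_cfg.n_folds} cases, got {len(cases)}")
    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 0xF01D]))
    perm = rng.permutation(len(cases))
    folds = np.array_split(perm, train_cfg.n_folds)
    models, histories = [], []
    assignment: dict[str, int] = {}
    oof: dict[str, np.ndarray] = {}
    for fi, val_idx in enumerate(folds):
        val_set = set(int(i) for i in val_idx)
        train_cases = [c for i, c in enumerate(cases) if i not in val_set]
        val_cases = [cases[i] for i in sorted(val_set)]
        model = build_network(model_cfg, seed=train_cfg.seed * 31 + fi)
        model, hist = train_fn(model, train_cases, val_cases, train_cfg)
        models.append(model)
        histories.append(hist)
        for i in sorted(val_set):
            case = cases[i]
            assignment[case.case_id] = fi
            oof[case.case_id] = model.predict(case.x)
    return CrossValResult(models=models, fold_assignment=assignment,
                          histories=histories, oof_predictions=oof)


def predict_stack(model: SegModel, stack: RadialPlaneStack) -> list[PlanePrediction]:
    """Run inference on a full radial plane stack (deterministic)."""
    if model.geometry is not None:
        g, t = stack.geometry, model.geometry
        if (g.angular_interval != t.angular_interval
                or len(g.s_coords) != len(t.s_coords)
                or len(g.z_coords) != len(t.z_coords)):
            raise ValueError("stack geometry does not match training geometry")
    x = np.stack([
        np.stack([centre.pixels, ctx_m.pixels, ctx_p.pixels])
        for centre, ctx_m, ctx_p in stack.planes
    ]).astype(np.float32)
    probs = model.predict(x)
    return [
        PlanePrediction(prostate_prob=probs[k, 0], zone_prob=probs[k, 1],
                        plane_index=k, geometry=stack.geometry)
        for k in range(len(stack.planes))
    ]


def case_planes_from_phantom(case, geom: RadialGeometry, modality: str = "bmode") -> CasePlanes:
    """Build network-ready training planes from a phantom case: modality
    image triples as inputs, resliced ground-truth masks as targets."""
    vol = case.bmode if modality == "bmode" else case.ceus
    stack = extract_stack(vol, geom, source_id=case.case_id)
    x = np.stack([
        np.stack([c.pixels, m.pixels, p.pixels]) for c, m, p in stack.planes
    ]).astype(np.float32)
    y = np.stack([
        np.stack([
            slice_mask(case.prostate_mask, geom, k),
            slice_mask(case.tz_mask, geom, k),
        ]) for k in range(geom.n_planes)
    ]).astype(np.float32)
    return CasePlanes(case_id=case.case_id, x=x, y=y, geometry=geom)


def save_model(model: SegModel, path: str | Path) -> None:
    """Save weights plus config as an ``.npz`` checkpoint."""
    path = Path(path)
    state = model.net.state()
    meta = json.dumps(asdict(model.config))
    np.savez(path, meta=np.array(meta), n=np.array(len(state)),
             **{f"p{i}": s for i, s in enumerate(state)})


def load_model(path: str | Path) -> SegModel:
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig(**json.loads(str(data["meta"])))
        model = SegModel(cfg)
        state = [data[f"p{i}"] for i in range(int(data["n"]))]
    model.net.load_state(state)
    return model
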