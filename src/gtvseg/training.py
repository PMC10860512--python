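"""Dice-loss training, transfer-learning fine-tuning, volume prediction.

Training minimizes the soft Dice loss (the complement of the soft Dice
index, computed per image and averaged over the batch) with Adam over
shuffled 2D slice batches.  Validation is split at the subject level so no
patient contributes slices to both sides.  Fine-tuning continues training of
all weights from a checkpoint on a new cohort, with early stopping on the
new-domain validation loss as a guard against catastrophic forgetting, and
can track source-domain validation Dice per epoch so forgetting is
measurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .imaging import NORMALIZED, Volume, to_slices, window_normalize
from .nn.layers import DTYPE, Adam
from .nn.unet import AttentionUNet, NetworkConfig
from .phantom import Subject


@dataclass
class TrainConfig:
    epochs_max: int = 300
    batch_size: int = 6
    learning_rate: float = 1e-6
    val_fraction: float = 0.10
    seed: int = 0
    smooth: float = 1.0
    early_stop_patience: int | None = None
    include_empty: bool = True
    #: cap the number of tumour-free slices at this multiple of the tumour
    #: slices (None keeps them all); lets training see empty anatomy without
    #: the epoch being dominated by it
    max_empty_ratio: float | None = None
    #: normalize with the pretrained running batch-norm moments instead of
    #: batch statistics (catastrophic-forgetting guard for fine-tuning)
    freeze_bn_stats: bool = False
    threshold: float = 0.5

    def validate(self) -> None:
        if not 0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must lie in (0, 0.5)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs_max < 0:
            raise ValueError("epochs_max must be >= 0")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    source_val_dice: list[float] = field(default_factory=list)
    stopping_reason: str = "max_epochs"
    best_epoch: int = -1

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Checkpoint:
    """Network weights + architecture config + training provenance."""

    state: dict[str, np.ndarray]
    config: NetworkConfig
    provenance: dict = field(default_factory=dict)

    def build(self) -> AttentionUNet:
        net = AttentionUNet(self.config)
        net.load_state_dict(self.state)
        return net

    def save(self, path) -> None:
        net = self.build()
        net.save(path, provenance=self.provenance)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        net, prov = AttentionUNet.load(path)
        return cls(state=net.state_dict(), config=net.config, provenance=prov)

    @classmethod
    def from_net(cls, net: AttentionUNet, provenance: dict | None = None) -> "Checkpoint":
        return cls(state=net.state_dict(), config=net.config, provenance=provenance or {})


def dice_loss(pred, target, smooth: float = 1.0) -> float:
    """Soft Dice loss: 1 - (2*sum(p*t)+s) / (sum(p)+sum(t)+s), batch-averaged.

    Accepts single images (H, W) or batches (N, H, W); always in [0, 1] for
    predictions in [0, 1].
    """
    loss, _ = _dice_loss_grad(pred, target, smooth, need_grad=False)
    return loss


def _dice_loss_grad(pred, target, smooth: float, need_grad: bool = True):
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    single = p.ndim == 2
    if single:
        p, t = p[None], t[None]
    inter = (p * t).sum(axis=(1, 2))
    sums = p.sum(axis=(1, 2)) + t.sum(axis=(1, 2))
    dice = (2.0 * inter + smooth) / (sums + smooth)
    loss = float(np.mean(1.0 - dice))
    grad = None
    if need_grad:
        # d/dp_i [ -(2A+s)/(B+s) ] = -(2 t_i (B+s) - (2A+s)) / (B+s)^2
        denom = (sums + smooth)[:, None, None]
        grad = (-(2.0 * t * denom - (2.0 * inter + smooth)[:, None, None]) / denom ** 2) / p.shape[0]
        grad = grad.astype(DTYPE)
    return loss, grad


def split_subjects(cohort: list[Subject], val_fraction: float, seed: int):
    """Subject-level train/validation split; |val| = round(f*n), minimum 1."""
    n = len(cohort)
    if n < 2:
        raise ValueError("cohort must contain at least 2 subjects to split")
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must lie in (0, 1)")
    order = np.random.default_rng(seed).permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx = set(order[:n_val].tolist())
    train = [cohort[i] for i in range(n) if i not in val_idx]
    val = [cohort[i] for i in range(n) if i in val_idx]
    return train, val


def preprocess_subject(subject: Subject) -> Subject:
    """Canonicalize orientation and window-normalize a subject's volume."""
    sub = subject.canonical()
    if sub.volume.intensity_state == NORMALIZED:
        return sub
    from dataclasses import replace
    return replace(sub, volume=window_normalize(sub.volume))


def cohort_to_arrays(subjects: list[Subject], include_empty: bool = True,
                     max_empty_ratio: float | None = None, seed: int = 0):
    """Stack all (preprocessed) subjects' slices into (X, y) arrays.

    With ``max_empty_ratio`` set, tumour-free slices are subsampled
    (deterministically per seed) to at most that multiple of the tumour
    slices.
    """
    imgs, masks, is_empty = [], [], []
    for sub in subjects:
        sub = preprocess_subject(sub)
        for pair in to_slices(sub.volume, sub.truth_mask, sub.id, include_empty=include_empty):
            imgs.append(pair.image)
            masks.append(pair.mask)
            is_empty.append(pair.mask.sum() == 0)
    if not imgs:
        raise ValueError("no training slices (empty cohort?)")
    if include_empty and max_empty_ratio is not None:
        empty_idx = [i for i, e in enumerate(is_empty) if e]
        pos_idx = [i for i, e in enumerate(is_empty) if not e]
        n_keep = min(len(empty_idx), int(round(max_empty_ratio * len(pos_idx))))
        rng = np.random.default_rng(seed)
        kept = set(rng.choice(empty_idx, size=n_keep, replace=False).tolist()) if n_keep else set()
        sel = sorted(set(pos_idx) | kept)
        imgs = [imgs[i] for i in sel]
        masks = [masks[i] for i in sel]
    return np.stack(imgs).astype(DTYPE), np.stack(masks).astype(DTYPE)


def _epoch_metrics(net: AttentionUNet, X, y, smooth, threshold, batch: int = 12):
    """Inference-mode loss and mean hard Dice over a slice set."""
    losses, dices = [], []
    for i in range(0, len(X), batch):
        p = net.forward(X[i:i + batch], train=False)
        t = y[i:i + batch]
        losses.append(dice_loss(p, t, smooth) * len(t))
        hard = (p >= threshold).astype(np.float64)
        inter = (hard * t).sum(axis=(1, 2))
        sums = hard.sum(axis=(1, 2)) + t.sum(axis=(1, 2))
        dices.extend(np.where(sums > 0, 2 * inter / np.maximum(sums, 1e-12), 1.0).tolist())
    return float(np.sum(losses) / len(X)), float(np.mean(dices))


def fit_network(
    net: AttentionUNet,
    X_train: np.ndarray,
    y_train: np.ndarray,
    cfg: TrainConfig,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    source_val: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainingHistory:
    """Run the Adam/Dice-loss loop in place; returns the epoch history.

    The network is left holding the weights of the best validation-loss
    epoch (or the final weights when no validation set is given).  Early
    stopping triggers when validation loss has not improved for
    ``early_stop_patience`` epochs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(lr=cfg.learning_rate)
    net.set_bn_frozen(cfg.freeze_bn_stats)
    hist = TrainingHistory()
    n = len(X_train)
    if n == 0:
        raise ValueError("empty training set")
    best_loss, best_state, since_best = np.inf, None, 0
    for epoch in range(cfg.epochs_max):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            p = net.forward(X_train[idx], train=True)
            loss, grad = _dice_loss_grad(p, y_train[idx], cfg.smooth)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}: divergence")
            net.backward(grad)
            opt.step(net.parameters(), net.gradients())
            epoch_loss += loss * len(idx)
        hist.train_loss.append(epoch_loss / n)
        if X_val is not None and len(X_val):
            vloss, vdice = _epoch_metrics(net, X_val, y_val, cfg.smooth, cfg.threshold)
            hist.val_loss.append(vloss)
            hist.val_dice.append(vdice)
            if source_val is not None:
                _, sdice = _epoch_metrics(net, source_val[0], source_val[1], cfg.smooth, cfg.threshold)
                hist.source_val_dice.append(sdice)
            if vloss < best_loss - 1e-9:
                best_loss, best_state, since_best = vloss, net.state_dict(), 0
                hist.best_epoch = epoch
            else:
                since_best += 1
                if cfg.early_stop_patience is not None and since_best >= cfg.early_stop_patience:
                    hist.stopping_reason = "early_stop"
                    break
    if best_state is not None:
        net.load_state_dict(best_state)
    net.set_bn_frozen(False)
    return hist


def train(model: AttentionUNet | NetworkConfig, cohort: list[Subject], cfg: TrainConfig):
    """Pretrain on a cohort with a subject-level validation split.

    Returns (Checkpoint, TrainingHistory); the checkpoint holds the
    best-validation-loss weights.
    """
    net = AttentionUNet(model) if isinstance(model, NetworkConfig) else model
    train_subs, val_subs = split_subjects(cohort, cfg.val_fraction, cfg.seed)
    X_tr, y_tr = cohort_to_arrays(train_subs, cfg.include_empty, cfg.max_empty_ratio, cfg.seed)
    X_va, y_va = cohort_to_arrays(val_subs, include_empty=True)
    hist = fit_network(net, X_tr, y_tr, cfg, X_va, y_va)
    prov = {
        "phase": "pretrain",
        "n_subjects": len(cohort),
        "cohort": cohort[0].domain if cohort else "",
        "epochs_seen": len(hist.train_loss),
        "train_config": _cfg_dict(cfg),
    }
    return Checkpoint.from_net(net, prov), hist


def fine_tune(
    checkpoint: Checkpoint,
    new_cohort: list[Subject],
    cfg: TrainConfig,
    source_val_cohort: list[Subject] | None = None,
):
    """Transfer-train all weights from a checkpoint on a new-domain cohort.

    No layers are frozen; the guard against catastrophic forgetting is early
    stopping on new-domain validation loss plus the best-checkpoint rule.
    When ``source_val_cohort`` is given, source-domain validation Dice is
    recorded per epoch so forgetting can be inspected in the history.
    With ``epochs_max == 0`` the checkpoint is returned unchanged.
    """
    net = checkpoint.build()
    if cfg.epochs_max == 0:
        hist = TrainingHistory(stopping_reason="max_epochs")
        prov = dict(checkpoint.provenance)
        prov.update({"phase": "fine_tune", "epochs_seen": 0, "train_config": _cfg_dict(cfg)})
        return Checkpoint.from_net(net, prov), hist
    train_subs, val_subs = split_subjects(new_cohort, cfg.val_fraction, cfg.seed)
    X_tr, y_tr = cohort_to_arrays(train_subs, cfg.include_empty, cfg.max_empty_ratio, cfg.seed)
    X_va, y_va = cohort_to_arrays(val_subs, include_empty=True)
    source_val = None
    if source_val_cohort:
        source_val = cohort_to_arrays(source_val_cohort, include_empty=True)
    hist = fit_network(net, X_tr, y_tr, cfg, X_va, y_va, source_val=source_val)
    prov = {
        "phase": "fine_tune",
        "pretrained_from": checkpoint.provenance.get("cohort", ""),
        "n_subjects": len(new_cohort),
        "cohort": new_cohort[0].domain if new_cohort else "",
        "epochs_seen": len(hist.train_loss),
        "train_config": _cfg_dict(cfg),
    }
    return Checkpoint.from_net(net, prov), hist


def predict_volume(model, v: Volume, threshold: float = 0.5, batch: int = 12) -> np.ndarray:
    """Slice-wise inference on a normalized volume, restacked in slice order.

    No inter-slice post-processing is applied.  Returns a uint8 mask volume
    of the same shape.
    """
    if v.intensity_state != NORMALIZED:
        raise ValueError("predict_volume expects a normalized volume")
    net = model.build() if isinstance(model, Checkpoint) else model
    v = v.canonicalize()
    out = np.zeros(v.shape, dtype=np.uint8)
    for i in range(0, v.n_slices, batch):
        p = net.forward(v.data[i:i + batch], train=False)
        out[i:i + batch] = (p >= threshold).astype(np.uint8)
    return out


def _cfg_dict(cfg: TrainConfig) -> dict:
    return json.loads(json.dumps(asdict(cfg)))


#: Training presets.  ``paper_faithful`` mirrors the full-scale protocol
#: (512 px inputs, lr 1e-6, 300-epoch pretrain / 150-epoch fine-tune cap);
#: ``desk_scale`` is the one-CPU study profile used by the shipped pipeline.
PRESETS: dict[str, dict] = {
    "paper_faithful": {
        "pretrain": dict(epochs_max=300, batch_size=6, learning_rate=1e-6, val_fraction=0.10),
        "fine_tune": dict(epochs_max=150, batch_size=6, learning_rate=1e-6, val_fraction=0.10,
                          early_stop_patience=15),
    },
    "desk_scale": {
        "pretrain": dict(epochs_max=30, batch_size=6, learning_rate=1e-3, val_fraction=0.10,
                         max_empty_ratio=1.0),
        "fine_tune": dict(epochs_max=25, batch_size=6, learning_rate=2e-4, val_fraction=0.20,
                          early_stop_patience=10, max_empty_ratio=1.0, freeze_bn_stats=True),
    },
}
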