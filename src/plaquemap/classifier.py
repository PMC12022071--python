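"""CNN plaque-morphotype classifier: CGP vs CP vs DP from amyloid microscopy.

Patches are standardised to 120 x 120 grayscale with percentile contrast
stretching, augmented with random rotation / flips / isotropic scaling, and
classified by an ensemble of three networks trained under three-fold
cross-validation whose softmax outputs are averaged.  Evaluation reports a
confusion matrix with accuracy and per-class precision / recall / F1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .nn import Adam, SmallCNN

__all__ = [
    "CLASS_ORDER",
    "TrainConfig",
    "EvalReport",
    "ClassifierEnsemble",
    "preprocess_patch",
    "augment_patch",
    "split_train_test",
    "stratified_folds",
    "train_crossval",
    "predict_ensemble",
    "classification_metrics",
    "reconstruct_confusion",
    "save_ensemble",
    "load_ensemble",
]

#: Fixed class order; argmax ties resolve to the earliest entry.
CLASS_ORDER = ("CGP", "CP", "DP")

PATCH_SIZE = 120


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the three-fold ensemble training."""

    k_folds: int = 3
    learning_rate: float = 1e-3
    decay_factor: float = 0.96
    decay_every_epochs: int = 10
    batch_size: int = 32
    epochs: int = 30
    patience: int = 5  # early stop on validation loss
    rotation_deg: float = 20.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    flip_p: float = 0.5
    filters: tuple[int, ...] = (32, 64, 128)
    dense_units: int = 128
    dropout: float = 0.5
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if min(self.learning_rate, self.decay_factor, self.batch_size,
               self.epochs) <= 0:
            raise ValueError("hyperparameters must be positive")


# ---------------------------------------------------------------------------
# patch preparation
# ---------------------------------------------------------------------------

def preprocess_patch(raw: np.ndarray, size: int = PATCH_SIZE) -> np.ndarray:
    """Grayscale, bilinear-resize to ``size`` x ``size``, stretch contrast.

    Multichannel input is reduced by channel mean; the 1st/99th intensity
    percentiles map to [0, 1] (clipped); constant patches map to zeros.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty input image")
    if raw.ndim == 3:
        raw = raw.mean(axis=2)
    if raw.ndim != 2:
        raise ValueError("expected a 2-D image or HxWxC stack")
    if raw.shape != (size, size):
        raw = resize(raw, (size, size), order=1, anti_aliasing=False,
                     preserve_range=True)
    lo, hi = np.percentile(raw, [1.0, 99.0])
    if hi <= lo:
        return np.zeros((size, size), dtype=np.float32)
    return np.clip((raw - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)


def augment_patch(
    patch: np.ndarray,
    rng: np.random.Generator,
    rotation_deg: float = 20.0,
    scale_range: tuple[float, float] = (0.9, 1.1),
    flip_p: float = 0.5,
    angle: float | None = None,
    flip_h: bool | None = None,
    flip_v: bool | None = None,
    scale: float | None = None,
) -> np.ndarray:
    """Random rotation, horizontal/vertical flips and isotropic rescale.

    The ``angle``/``flip_h``/``flip_v``/``scale`` keyword hooks pin
    individual transforms for testing; unset ones are drawn from ``rng``.
    Output is re-cropped/padded to the input shape; the label is unchanged
    by construction.
    """
    patch = np.asarray(patch, dtype=np.float32)
    size = patch.shape[0]
    if angle is None:
        angle = rng.uniform(-rotation_deg, rotation_deg)
    if flip_h is None:
        flip_h = rng.random() < flip_p
    if flip_v is None:
        flip_v = rng.random() < flip_p
    if scale is None:
        scale = rng.uniform(*scale_range)
    out = patch
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    if angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="constant")
    if scale != 1.0:
        scaled = resize(out, (max(1, round(size * scale)),) * 2, order=1,
                        anti_aliasing=False, preserve_range=True)
        if scaled.shape[0] >= size:  # centre crop
            off = (scaled.shape[0] - size) // 2
            out = scaled[off : off + size, off : off + size]
        else:  # centre pad
            out = np.zeros((size, size), dtype=np.float32)
            off = (size - scaled.shape[0]) // 2
            out[off : off + scaled.shape[0], off : off + scaled.shape[1]] = scaled
    return np.ascontiguousarray(out, dtype=np.float32)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def split_train_test(patches, labels, test_fraction: float = 0.2, seed: int = 0,
                     min_members: int = 4):
    """Stratified random train/test split.

    Each class contributes ``round(test_fraction * n_class)`` test members
    (round-half-up), so the achieved test size can differ by a patch or two
    from ``test_fraction * n`` depending on per-class rounding; the achieved
    counts are returned alongside the split.
    """
    labels = np.asarray(labels)
    patches = np.asarray(patches)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < min_members:
            raise ValueError(
                f"class {cls!r} has {idx.size} members; need >= {min_members}"
            )
        rng.shuffle(idx)
        n_test = int(test_fraction * idx.size + 0.5)
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    train_idx = np.sort(np.asarray(train_idx, dtype=int))
    test_idx = np.sort(np.asarray(test_idx, dtype=int))
    return (patches[train_idx], labels[train_idx],
            patches[test_idx], labels[test_idx])


def stratified_folds(labels, k: int, seed: int = 0) -> np.ndarray:
    """Assign each sample a fold id 0..k-1, stratified by class.

    Fold sizes differ by at most one per class; every sample validates in
    exactly one fold.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(labels.size, dtype=int)
    offset = 0
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        rng.shuffle(idx)
        assignment = (np.arange(idx.size) + offset) % k
        folds[idx] = assignment
        offset += idx.size  # balances fold totals across classes
    return folds


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

@dataclass
class ClassifierEnsemble:
    """K fold-trained networks predicting by softmax averaging."""

    members: list
    class_order: tuple = CLASS_ORDER
    config: TrainConfig = field(default_factory=TrainConfig)
    fold_history: list = field(default_factory=list)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches, dtype=np.float32)
        if patches.ndim == 2:
            patches = patches[None]
        expected = self.members[0].input_size
        if patches.shape[1:3] != (expected, expected):
            raise ValueError(
                f"patch shape {patches.shape[1:3]} does not match the "
                f"model input {expected}x{expected}"
            )
        probs = np.mean([m.predict_proba(patches) for m in self.members], axis=0)
        return probs

    def predict(self, patches: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(patches)
        # np.argmax takes the first maximum: ties resolve to CGP < CP < DP
        return np.asarray(self.class_order)[probs.argmax(axis=1)]


def predict_ensemble(ensemble: ClassifierEnsemble, patch: np.ndarray) -> np.ndarray:
    """Class-probability vector for one preprocessed patch (members averaged)."""
    return ensemble.predict_proba(patch)[0]


def _onehot(labels, class_order):
    index = {c: i for i, c in enumerate(class_order)}
    out = np.zeros((len(labels), len(class_order)), dtype=np.float32)
    for i, lab in enumerate(labels):
        out[i, index[lab]] = 1.0
    return out


def _train_one(x, y1h, xv, yv1h, cfg: TrainConfig, seed: int, input_size: int):
    model = SmallCNN(n_classes=y1h.shape[1], filters=cfg.filters,
                     dense_units=cfg.dense_units, dropout=cfg.dropout,
                     input_size=input_size, seed=seed)
    opt = Adam(model.params, lr=cfg.learning_rate, decay=cfg.decay_factor,
               decay_every=cfg.decay_every_epochs)
    rng = np.random.default_rng(seed + 1)
    best_state, best_key, since_best = None, (-1.0, -np.inf), 0
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb = x[sel]
            if cfg.augment:
                xb = np.stack([
                    augment_patch(p, rng, cfg.rotation_deg, cfg.scale_range,
                                  cfg.flip_p)
                    for p in xb
                ])
            loss = model.loss_and_grad(xb[..., None], y1h[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (loss={loss}) at epoch {epoch}; "
                    "lower the learning rate"
                )
            opt.step(model.grads, epoch)
            losses.append(loss)
        probs = model.predict_proba(xv[..., None])
        val_loss = float(-np.log(np.clip(
            (probs * yv1h).sum(axis=1), 1e-12, None)).mean())
        val_acc = float((probs.argmax(1) == yv1h.argmax(1)).mean())
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss, "val_acc": val_acc})
        # keep the epoch with the best validation accuracy (loss tie-break)
        key = (val_acc, -val_loss)
        if key > best_key:
            best_key, since_best = key, 0
            best_state = model.get_state()
        else:
            since_best += 1
        if val_acc >= 1.0 or since_best >= cfg.patience:
            break
    if best_state is not None:
        model.set_state(best_state)
    return model, history


def train_crossval(patches, labels, cfg: TrainConfig = TrainConfig()
                   ) -> ClassifierEnsemble:
    """Three-fold (k-fold) cross-validated training of the ensemble.

    Member ``f`` trains on all folds except ``f`` (with augmentation) and
    validates on fold ``f`` under an early stop on validation loss; the
    learning rate decays by ``decay_factor`` every ``decay_every_epochs``.
    Returns the ensemble with per-fold validation histories attached.
    """
    patches = np.asarray(patches, dtype=np.float32)
    labels = np.asarray(labels)
    class_order = tuple(c for c in CLASS_ORDER if c in set(labels))
    if len(class_order) < 2:
        raise ValueError("need at least two classes to train")
    y1h = _onehot(labels, class_order)
    folds = stratified_folds(labels, cfg.k_folds, seed=cfg.seed)
    members, histories = [], []
    input_size = patches.shape[1]
    for f in range(cfg.k_folds):
        tr, va = folds != f, folds == f
        model, hist = _train_one(patches[tr], y1h[tr], patches[va], y1h[va],
                                 cfg, seed=cfg.seed + 1000 * f,
                                 input_size=input_size)
        members.append(model)
        histories.append(hist)
    return ClassifierEnsemble(members=members, class_order=class_order,
                              config=cfg, fold_history=histories)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Confusion matrix (rows true, columns predicted) with derived metrics."""

    confusion: np.ndarray
    class_order: tuple
    accuracy: float
    precision: dict
    recall: dict
    f1: dict

    @property
    def n_test(self) -> int:
        return int(self.confusion.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.confusion))


def classification_metrics(confusion, class_order=CLASS_ORDER) -> EvalReport:
    """Accuracy and per-class precision / recall / F1 from a confusion matrix.

    A class never predicted (zero column) has undefined precision, reported
    as ``None`` with a warning; F1 is ``None`` whenever precision + recall
    is undefined or zero.
    """
    M = np.asarray(confusion)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(M < 0) or not np.issubdtype(M.dtype, np.number):
        raise ValueError("confusion matrix must hold nonnegative counts")
    if M.sum() == 0:
        raise ValueError("confusion matrix is empty")
    class_order = tuple(class_order[: M.shape[0]])
    accuracy = float(np.trace(M) / M.sum())
    precision, recall, f1 = {}, {}, {}
    for i, cls in enumerate(class_order):
        row, col = M[i, :].sum(), M[:, i].sum()
        recall[cls] = float(M[i, i] / row) if row > 0 else 0.0
        if col > 0:
            precision[cls] = float(M[i, i] / col)
        else:
            warnings.warn(f"class {cls}: never predicted; precision undefined")
            precision[cls] = None
        if precision[cls] is None or precision[cls] + recall[cls] == 0:
            f1[cls] = None
        else:
            f1[cls] = 2 * precision[cls] * recall[cls] / (precision[cls] + recall[cls])
    return EvalReport(confusion=M, class_order=class_order, accuracy=accuracy,
                      precision=precision, recall=recall, f1=f1)


def reconstruct_confusion(
    total: int = 78,
    correct: int = 72,
    recall: tuple = (0.90, 0.95, 0.88),
    precision: tuple = (0.82, 0.91, 1.00),
    f1: tuple = (0.86, 0.93, 0.94),
    accuracy: float = 0.923,
    decimals: int = 2,
) -> list[np.ndarray]:
    """All 3x3 confusion matrices consistent with a printed metrics panel.

    Searches integer matrices with the given total and trace whose per-class
    recall, precision and F1 — and overall accuracy — reproduce the printed
    values after rounding to ``decimals``.  Off-diagonal mass is enumerated
    exactly; diagonals are pruned per class before combination.
    """
    k = len(recall)
    misses = total - correct

    def rounds_to(x, target):
        return round(x, decimals) == round(target, decimals)

    if not rounds_to(correct / total, accuracy) and \
       round(100 * correct / total, 1) != round(100 * accuracy, 1):
        return []

    def off_diagonal_fillings():
        cells = [(i, j) for i in range(k) for j in range(k) if i != j]

        def rec(pos, remaining, current):
            if pos == len(cells):
                if remaining == 0:
                    yield dict(zip(cells, current))
                return
            for v in range(remaining + 1):
                yield from rec(pos + 1, remaining - v, current + [v])

        yield from rec(0, misses, [])

    found = []
    for off in off_diagonal_fillings():
        o_row = [sum(off[(i, j)] for j in range(k) if j != i) for i in range(k)]
        o_col = [sum(off[(j, i)] for j in range(k) if j != i) for i in range(k)]
        candidates = []
        for i in range(k):
            ok = [
                d for d in range(correct + 1)
                if (d + o_row[i]) > 0 and (d + o_col[i]) > 0
                and rounds_to(d / (d + o_row[i]), recall[i])
                and rounds_to(d / (d + o_col[i]), precision[i])
                and rounds_to(
                    2 * d / (2 * d + o_row[i] + o_col[i]), f1[i])
            ]
            candidates.append(ok)
        for d0 in candidates[0]:
            for d1 in candidates[1]:
                d2 = correct - d0 - d1
                if d2 in candidates[2]:
                    M = np.zeros((k, k), dtype=int)
                    M[0, 0], M[1, 1], M[2, 2] = d0, d1, d2
                    for (i, j), v in off.items():
                        M[i, j] = v
                    found.append(M)
    uniq, seen = [], set()
    for M in found:
        key = M.tobytes()
        if key not in seen:
            seen.add(key)
            uniq.append(M)
    return uniq


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: ClassifierEnsemble, directory) -> None:
    """Save member weights (npz) + preprocessing/config spec (JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = asdict(ensemble.config)
    spec = {
        "class_order": list(ensemble.class_order),
        "input_size": ensemble.members[0].input_size,
        "patch_size": PATCH_SIZE,
        "config": cfg,
        "n_members": len(ensemble.members),
    }
    (directory / "spec.json").write_text(json.dumps(spec, indent=2))
    for i, m in enumerate(ensemble.members):
        np.savez(directory / f"member{i}.npz",
                 *[np.asarray(a) for a in m.get_state()])


def load_ensemble(directory) -> ClassifierEnsemble:
    directory = Path(directory)
    spec = json.loads((directory / "spec.json").read_text())
    cfg_dict = spec["config"]
    for key in ("scale_range", "filters"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = TrainConfig(**cfg_dict)
    members = []
    for i in range(spec["n_members"]):
        with np.load(directory / f"member{i}.npz") as data:
            state = [data[k] for k in data.files]
        model = SmallCNN(n_classes=len(spec["class_order"]), filters=cfg.filters,
                         dense_units=cfg.dense_units, dropout=cfg.dropout,
                         input_size=spec["input_size"], seed=cfg.seed)
        model.set_state(state)
        members.append(model)
    return ClassifierEnsemble(members=members,
                              class_order=tuple(spec["class_order"]), config=cfg)
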