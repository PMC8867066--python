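"""Binary trait classification of fruit images and Grad-CAM region relevance.

Trains the numpy CNN with flip/rotation augmentation, checkpoints the
epoch of minimum validation loss, evaluates with a confusion matrix and a
rank-statistic ROC-AUC, computes Grad-CAM relevance maps from the last
convolutional layer, and aggregates mean relevance per fruit region over
correctly predicted prediction-set images with a between-class rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.transform import resize

from citrusect.cnn import AdamOptimizer, SmallCNN
from citrusect.regions import REGION_NAMES, RegionMasks

__all__ = [
    "TrainConfig",
    "TrainResult",
    "split_dataset",
    "train_classifier",
    "evaluate_classifier",
    "gradcam",
    "region_relevance",
    "region_relevance_table",
    "compare_classes",
]

#: Regions quantified for relevance (Whole excluded).
RELEVANCE_REGIONS: tuple[str, ...] = tuple(r for r in REGION_NAMES if r != "Whole")


@dataclass
class TrainConfig:
    input_size: int = 224
    augment: tuple[str, ...] = ("hflip", "vflip", "rot90")
    optimizer: str = "adam"
    learning_rate: float = 1e-5
    batch_size: int = 30
    epochs: int = 50
    splits: tuple[float, float, float] = (0.7, 0.15, 0.15)  # train/val/prediction
    seed: int = 0
    channels: tuple[int, int, int] = (8, 16, 32)

    def __post_init__(self) -> None:
        if abs(sum(self.splits) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")

    @classmethod
    def test_profile(cls, **overrides) -> "TrainConfig":
        """Fast desk-scale profile: 64x64 inputs, lr 1e-3, small batches.

        A from-scratch CNN needs more optimizer steps than a fine-tuned
        backbone, so the fast profile trades batch size for update count.
        """
        kw = dict(input_size=64, learning_rate=1e-3, batch_size=10, epochs=40)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class TrainResult:
    model: SmallCNN
    history: pd.DataFrame             # epoch, train_loss, val_loss, val_accuracy
    best_epoch: int
    splits: dict[str, np.ndarray]     # index arrays: train / val / prediction


def _prepare(images: list[np.ndarray] | np.ndarray, size: int) -> np.ndarray:
    out = np.empty((len(images), size, size, 3), dtype=np.float64)
    for i, im in enumerate(images):
        im = np.asarray(im)
        if im.shape[0] != size or im.shape[1] != size:
            im = resize(im, (size, size, 3), anti_aliasing=True, preserve_range=True)
        out[i] = im / 255.0
    return out


def split_dataset(labels: np.ndarray, fractions: tuple[float, float, float],
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Stratified train/val/prediction split indices."""
    labels = np.asarray(labels)
    idx = {k: [] for k in ("train", "val", "prediction")}
    for cls in np.unique(labels):
        members = rng.permutation(np.nonzero(labels == cls)[0])
        n = len(members)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        idx["train"].extend(members[:n_tr])
        idx["val"].extend(members[n_tr : n_tr + n_va])
        idx["prediction"].extend(members[n_tr + n_va :])
    return {k: np.sort(np.asarray(v, dtype=int)) for k, v in idx.items()}


def _augment_batch(x: np.ndarray, augment: tuple[str, ...],
                   rng: np.random.Generator) -> np.ndarray:
    x = x.copy()
    for i in range(len(x)):
        if "hflip" in augment and rng.random() < 0.5:
            x[i] = x[i, :, ::-1]
        if "vflip" in augment and rng.random() < 0.5:
            x[i] = x[i, ::-1]
        if "rot90" in augment and rng.random() < 0.5:
            x[i] = np.rot90(x[i])
    return x


def train_classifier(
    images, labels, config: TrainConfig,
    splits: dict[str, np.ndarray] | None = None,
) -> TrainResult:
    """Train the CNN; returns the checkpoint with minimum validation loss."""
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(config.seed)
    x = _prepare(images, config.input_size)
    if splits is None:
        splits = split_dataset(labels, config.splits, rng)
    for part in ("train", "val"):
        if len(np.unique(labels[splits[part]])) < 2:
            raise ValueError(f"stratification error: {part} split holds one class")

    model = SmallCNN(input_size=config.input_size, channels=config.channels,
                     seed=config.seed)
    opt = AdamOptimizer(model.params, lr=config.learning_rate)
    xt, yt = x[splits["train"]], labels[splits["train"]]
    xv, yv = x[splits["val"]], labels[splits["val"]]

    history = []
    best_state, best_loss, best_epoch = model.state_dict(), np.inf, -1
    for epoch in range(config.epochs):
        order = rng.permutation(len(xt))
        losses = []
        for i in range(0, len(order), config.batch_size):
            sel = order[i : i + config.batch_size]
            xb = _augment_batch(xt[sel], config.augment, rng)
            loss, grads = model.loss_and_grads(xb, yt[sel])
            opt.step(model.params, grads)
            losses.append(loss)
        val_loss = model.loss(xv, yv)
        val_acc = float(np.mean(model.predict_proba(xv).argmax(axis=1) == yv))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss, "val_accuracy": val_acc})
        if val_loss < best_loss:
            best_loss, best_state, best_epoch = val_loss, model.state_dict(), epoch
    model.load_state_dict(best_state)
    return TrainResult(model=model, history=pd.DataFrame(history),
                       best_epoch=best_epoch, splits=splits)


def evaluate_classifier(model: SmallCNN, images, labels) -> dict:
    """Confusion matrix at the 0.5 threshold, accuracy, and rank-based AUC."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) == 0 or len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: prediction set must contain both classes")
    x = _prepare(images, model.input_size)
    scores = model.predict_proba(x)[:, 1]
    pred = (scores >= 0.5).astype(int)
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(labels, pred):
        cm[t, p] += 1
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1)
    return {
        "confusion_matrix": cm,
        "accuracy": float((pred == labels).mean()),
        "auc": float(auc),
        "scores": scores,
        "predicted": pred,
    }


def gradcam(model: SmallCNN, image: np.ndarray, target_class: int,
            layer: str | None = None) -> np.ndarray:
    """Grad-CAM relevance map at input resolution, normalized to max 1.

    Channel weights are the spatial averages of the target-class logit
    gradient on the last conv feature maps; the map is the rectified
    weighted sum, bilinearly upsampled.  An identically-zero map stays zero.
    """
    layer = layer or model.last_conv
    x = _prepare([image], model.input_size)
    acts, grad = model.conv_activation_and_gradient(x, target_class, layer)
    alpha = grad.mean(axis=(2, 3))                      # (1, C)
    fmap = np.maximum((alpha[:, :, None, None] * acts).sum(axis=1), 0.0)[0]
    up = resize(fmap, (model.input_size, model.input_size), order=1,
                anti_aliasing=False, preserve_range=True)
    m = up.max()
    return up / m if m > 0 else up


def region_relevance(relevance: np.ndarray, masks: RegionMasks) -> dict[str, float]:
    """Mean relevance inside each of the 7 non-Whole regions.

    Masks are resampled to the map's resolution if needed; empty regions are
    reported as NaN (missing), not 0.
    """
    out: dict[str, float] = {}
    for r in RELEVANCE_REGIONS:
        mask = masks[r]
        if mask.shape != relevance.shape:
            mask = resize(mask.astype(float), relevance.shape, order=0,
                          anti_aliasing=False, preserve_range=True) > 0.5
        out[r] = float(relevance[mask].mean()) if mask.any() else float("nan")
    return out


def region_relevance_table(
    model: SmallCNN, images, labels, masks_list: list[RegionMasks],
    indices: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-image region relevance means for correctly predicted images only.

    The Grad-CAM target is each image's true (= predicted) class, mirroring
    relevance quantification on the prediction dataset.
    """
    labels = np.asarray(labels, dtype=int)
    if indices is None:
        indices = np.arange(len(labels))
    ev_imgs = [images[i] for i in indices]
    x = _prepare(ev_imgs, model.input_size)
    pred = model.predict_proba(x).argmax(axis=1)
    rows = []
    for k, i in enumerate(indices):
        if pred[k] != labels[i]:
            continue
        rel = gradcam(model, images[i], int(labels[i]))
        row = {"image": int(i), "label": int(labels[i])}
        row.update(region_relevance(rel, masks_list[i]))
        rows.append(row)
    return pd.DataFrame(rows)


def compare_classes(table: pd.DataFrame, class_col: str = "label",
                    alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided Mann-Whitney test per region between the two classes.

    Reports raw p-values plus Benjamini-Hochberg adjusted ones across the 7
    regions; the test statistic is accompanied by the median difference
    (class 1 minus class 0).
    """
    classes = np.sort(table[class_col].unique())
    if len(classes) != 2:
        raise ValueError("need exactly two classes to compare")
    a = table[table[class_col] == classes[0]]
    b = table[table[class_col] == classes[1]]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 correctly predicted images per class")
    rows = []
    for r in RELEVANCE_REGIONS:
        va = a[r].dropna().to_numpy()
        vb = b[r].dropna().to_numpy()
        if len(va) < 3 or len(vb) < 3:
            rows.append({"region": r, "statistic": np.nan, "pvalue": np.nan,
                         "median_diff": np.nan})
            continue
        res = stats.mannwhitneyu(vb, va, alternative="two-sided")
        rows.append({
            "region": r,
            "statistic": float(res.statistic),
            "pvalue": float(res.pvalue),
            "median_diff": float(np.median(vb) - np.median(va)),
        })
    out = pd.DataFrame(rows).set_index("region")
    # Benjamini-Hochberg over the regions actually tested
    mask = out["pvalue"].notna()
    p = out.loc[mask, "pvalue"].to_numpy()
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_i in range(m - 1, -1, -1):
        val = p[order[rank_i]] * m / (rank_i + 1)
        prev = min(prev, val)
        adj[order[rank_i]] = prev
    out.loc[mask, "pvalue_adjusted"] = adj
    out["significant"] = out["pvalue"] < alpha
    return out
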