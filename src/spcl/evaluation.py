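"""Downstream protocols: linear evaluation, fine-tuning, metrics, 2-D
embedding projection and slide-level prediction heatmaps.

Linear evaluation freezes the pretrained backbone and trains only a linear
classification head on its features — the standard probe of representation
quality.  Fine-tuning updates the whole network.  Both monitor validation
macro-F1 with early stopping and return the best checkpoint.  Metrics are
accuracy, macro-F1 and macro one-vs-rest ROC AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score

from . import nn
from .contrastive import PretrainResult, encode, _views_to_nchw
from .errors import DataError, ParameterError
from .tiling import compute_otsu_mask, sliding_window_tiles, extract_tile
from .errors import DegenerateHistogramError

__all__ = [
    "EvalProtocol", "MetricReport", "PatchClassifier", "train_classifier",
    "compute_metrics", "embed_and_project", "predict_wsi_heatmap",
    "DEFAULT_CLASS_COLORS",
]

# fixed class -> colour map for heatmaps (blue/red/green/yellow first, as is
# conventional for epithelium/necrosis/tumour/stroma legends)
DEFAULT_CLASS_COLORS: tuple[tuple[int, int, int], ...] = (
    (60, 80, 230), (220, 50, 50), (60, 180, 75), (240, 200, 40),
    (145, 30, 180), (70, 240, 240), (245, 130, 48), (128, 128, 0),
)
_NEUTRAL = (225, 225, 225)


@dataclass(frozen=True)
class EvalProtocol:
    mode: str = "linear"           # "linear" | "fine_tune"
    epochs: int = 60
    patience: int = 5              # early stopping on val macro-F1
    lr: float = 0.05
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("linear", "fine_tune"):
            raise ParameterError(f"unknown protocol mode {self.mode!r}")
        if self.epochs < 1 or self.patience < 1:
            raise ParameterError("epochs and patience must be >= 1")


@dataclass
class MetricReport:
    acc: float
    auc: float
    f1: float
    per_class_f1: np.ndarray
    confusion: np.ndarray

    def as_dict(self) -> dict:
        return {"acc": self.acc, "auc": self.auc, "f1": self.f1,
                "per_class_f1": self.per_class_f1.tolist(),
                "confusion": self.confusion.tolist()}


@dataclass
class PatchClassifier:
    """Pretrained backbone plus a trained K-way classification head."""

    pretrained: PretrainResult
    head: nn.Module
    classes: np.ndarray
    protocol: EvalProtocol
    val_trace: list[float] = field(default_factory=list)

    def predict_proba(self, patches: np.ndarray, batch_size: int = 256) -> np.ndarray:
        feats = encode(self.pretrained, patches, batch_size=batch_size)
        self.head.train(False)
        logits = self.head(nn.Tensor(feats)).data
        logits = logits - logits.max(axis=1, keepdims=True)
        expo = np.exp(logits)
        return expo / expo.sum(axis=1, keepdims=True)

    def predict(self, patches: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(patches)
        return self.classes[np.argmax(proba, axis=1)]


def _softmax_ce(logits: nn.Tensor, onehot: np.ndarray) -> nn.Tensor:
    row_max = logits.data.max(axis=1, keepdims=True)
    lse = (logits - row_max).exp().sum(axis=1, keepdims=True).log() + row_max
    correct = (logits * onehot).sum(axis=1, keepdims=True)
    return (lse - correct).mean()


def train_classifier(pretrained: PretrainResult, train_data: tuple, val_data: tuple,
                     protocol: EvalProtocol = EvalProtocol()) -> PatchClassifier:
    """Train a classification head (linear) or the whole network (fine_tune).

    `train_data` / `val_data` are (patches, labels).  Training monitors the
    validation macro-F1; if it fails to improve for `patience` consecutive
    epochs, training stops and the best-scoring parameters are restored.
    In linear mode the encoder is never touched (asserted by checksum).
    """
    X_train, y_train = train_data
    X_val, y_val = val_data
    classes = np.unique(y_train)
    if len(classes) < 2:
        raise DataError("need at least 2 classes in the training set")
    missing = set(np.unique(y_val)) - set(classes)
    if missing:
        raise DataError(f"val classes {sorted(missing)} missing from train")
    k = len(classes)
    class_index = {c: i for i, c in enumerate(classes)}
    yt = np.array([class_index[c] for c in y_train])
    yv = np.array([class_index[c] for c in y_val])

    rng = np.random.default_rng(protocol.seed)
    head = nn.Linear(pretrained.encoder.feature_dim, k, rng)
    linear = protocol.mode == "linear"
    encoder_checksum = None
    if linear:
        feats_train = encode(pretrained, X_train)
        feats_val = encode(pretrained, X_val)
        params = head.parameters()
        encoder_checksum = _state_checksum(pretrained.encoder)
        opt = nn.Adam(params, lr=protocol.lr)
    else:
        params = head.parameters() + pretrained.encoder.parameters()
        opt = nn.Adam(params, lr=min(protocol.lr, 1e-3))
        arr_train = _prep(X_train)
        arr_val = _prep(X_val)

    onehot_all = np.eye(k)[yt]
    best_f1, best_state, best_head = -1.0, None, None
    since_best = 0
    trace: list[float] = []
    for _ in range(protocol.epochs):
        order = rng.permutation(len(yt))
        for start in range(0, len(yt), protocol.batch_size):
            idx = order[start:start + protocol.batch_size]
            if linear:
                x = nn.Tensor(feats_train[idx])
            else:
                pretrained.encoder.train(True)
                x = pretrained.encoder(nn.Tensor(_views_to_nchw(
                    arr_train[idx], pretrained.input_mean, pretrained.input_std)))
            logits = head(x)
            loss = _softmax_ce(logits, onehot_all[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
        # validation macro-F1
        if linear:
            head.train(False)
            val_logits = head(nn.Tensor(feats_val)).data
        else:
            pretrained.encoder.train(False)
            val_feats = np.concatenate([
                pretrained.encoder(nn.Tensor(_views_to_nchw(
                    arr_val[s:s + 256], pretrained.input_mean,
                    pretrained.input_std))).data
                for s in range(0, len(arr_val), 256)])
            val_logits = head(nn.Tensor(val_feats)).data
        f1 = f1_score(yv, np.argmax(val_logits, axis=1), average="macro",
                      labels=np.arange(k), zero_division=0)
        trace.append(float(f1))
        if f1 > best_f1:
            best_f1 = f1
            best_head = head.state_dict()
            best_state = None if linear else pretrained.encoder.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= protocol.patience:
                break
    head.load_state_dict(best_head)
    if best_state is not None:
        pretrained.encoder.load_state_dict(best_state)
    if linear:
        assert _state_checksum(pretrained.encoder) == encoder_checksum, \
            "linear evaluation must not mutate the encoder"
    return PatchClassifier(pretrained=pretrained, head=head, classes=classes,
                           protocol=protocol, val_trace=trace)


def _prep(X: np.ndarray) -> np.ndarray:
    arr = np.asarray(X)
    return arr.astype(np.float64) / 255.0 if arr.dtype == np.uint8 else arr


def _state_checksum(module: nn.Module) -> tuple:
    return tuple((name, v.tobytes()) for name, v in sorted(module.state_dict().items()))


def compute_metrics(y_true: np.ndarray, y_prob: np.ndarray) -> MetricReport:
    """Accuracy, macro one-vs-rest ROC AUC, macro-F1 and the confusion matrix.

    `y_prob` rows must sum to one; predicted labels are the argmax with ties
    broken toward the lowest class index.
    """
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    k = y_prob.shape[1]
    if k < 2:
        raise ParameterError("need at least 2 classes of scores")
    if np.any((y_true < 0) | (y_true >= k)):
        raise ParameterError(f"labels must lie in [0, {k})")
    if np.any(np.abs(y_prob.sum(axis=1) - 1.0) > 1e-5):
        raise ParameterError("score rows must sum to 1")
    y_pred = np.argmax(y_prob, axis=1)
    acc = float(np.mean(y_pred == y_true))
    labels = np.arange(k)
    f1_per = f1_score(y_true, y_pred, average=None, labels=labels, zero_division=0)
    present = np.unique(y_true)
    if len(present) == 2 and k == 2:
        auc = float(roc_auc_score(y_true, y_prob[:, 1]))
    else:
        # macro OVR over classes present in y_true
        aucs = [roc_auc_score((y_true == c).astype(int), y_prob[:, c])
                for c in present if 0 < np.mean(y_true == c) < 1]
        auc = float(np.mean(aucs)) if aucs else float("nan")
    return MetricReport(
        acc=acc, auc=auc, f1=float(np.mean(f1_per)),
        per_class_f1=np.asarray(f1_per),
        confusion=confusion_matrix(y_true, y_pred, labels=labels))


def embed_and_project(pretrained: PretrainResult, patches: np.ndarray,
                      labels: np.ndarray | None = None, seed: int = 0,
                      n_neighbors: int = 15) -> np.ndarray:
    """Backbone features projected to 2-D with UMAP (seeded, deterministic).

    Returns (n, 2) coordinates; pair them with `labels` for plotting.
    """
    patches = np.asarray(patches)
    if len(patches) < 10:
        raise ParameterError("need at least 10 samples to project")
    import umap

    feats = encode(pretrained, patches)
    reducer = umap.UMAP(n_components=2, random_state=seed,
                        n_neighbors=min(n_neighbors, len(patches) - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(feats)
    return np.asarray(coords, dtype=np.float64)


def predict_wsi_heatmap(classifier: PatchClassifier, slide_image: np.ndarray,
                        tile_size: int, stride: int | None = None,
                        min_tissue_fraction: float = 0.5,
                        class_colors=DEFAULT_CLASS_COLORS,
                        slide_id: str = "slide"):
    """Colour a slide by per-tile predicted class, skipping background tiles.

    Otsu masking separates tissue from background; tiles below the tissue
    cutoff render neutral.  If the slide has no intensity contrast at all,
    the mask degenerates and every tile is treated as tissue (a warning is
    emitted).  Returns (heatmap RGB, predicted tile grid, manifest); grid
    cells without a prediction hold -1.
    """
    h, w = slide_image.shape[:2]
    if tile_size > min(h, w):
        raise ParameterError("slide smaller than tile_size")
    stride = stride or tile_size
    try:
        mask = compute_otsu_mask(slide_image, source_id=slide_id)
    except DegenerateHistogramError:
        warnings.warn("degenerate Otsu histogram: treating the whole slide as tissue")
        from .tiling import TissueMask
        mask = TissueMask(mask=np.ones((h, w), dtype=bool), threshold=255.0,
                          source_id=slide_id)
    manifest = sliding_window_tiles(mask, tile_size, stride, min_tissue_fraction)
    rows = (h - tile_size) // stride + 1
    cols = (w - tile_size) // stride + 1
    grid = np.full((rows, cols), -1, dtype=np.int64)
    if manifest.records:
        tiles = np.stack([extract_tile(slide_image, r) for r in manifest.records])
        preds = classifier.predict(tiles)
        for rec, p in zip(manifest.records, preds):
            grid[rec.y // stride, rec.x // stride] = p
    heatmap = np.empty((h, w, 3), dtype=np.uint8)
    heatmap[:] = _NEUTRAL
    for gy in range(rows):
        for gx in range(cols):
            label = grid[gy, gx]
            if label < 0:
                continue
            color = class_colors[int(label) % len(class_colors)]
            y0, x0 = gy * stride, gx * stride
            heatmap[y0:y0 + tile_size, x0:x0 + tile_size] = color
    return heatmap, grid, manifest
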