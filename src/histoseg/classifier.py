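"""Residual patch classifier: patch -> (background, GM, WM) scores.

The network is a small residual CNN.  Incoming patches are average-pooled
to a fixed working resolution (a parameter-free stem), then passed through
residual stages whose skip connections are 1x1-convolution projections
rather than identities.  Global average pooling yields the patch
*embedding* — the fixed-length descriptor consumed by the CRF layer — and
a linear head maps it to the three class scores.

The backbone scale is configurable; the default "tiny" two-stage variant
trains on a single CPU in minutes.  Training uses Adam with a weighted
multi-class cross-entropy whose class weights come from
:func:`histoseg.patches.compute_class_weights`, batch size 16 and initial
learning rate 1e-3, keeping the checkpoint with the best validation
accuracy (per-epoch checkpoint selection as an early-stopping rule).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn.autograd import Tensor, concat
from .nn.layers import Adam, Conv2d, Linear, Module, avg_pool2d, global_avg_pool
from .patches import ClassWeights, PatchSample

__all__ = ["ArchSpec", "TrainConfig", "ClassifierModel", "train_classifier",
           "predict_patch", "extract_embedding"]

NUM_CLASSES = 3


@dataclass(frozen=True)
class ArchSpec:
    """Architecture descriptor (serialized next to checkpoints)."""
    patch_size: int = 256
    working_resolution: int = 32       # stem average-pools patches to this
    channels: tuple = (8, 16)          # one residual stage per entry
    num_classes: int = NUM_CLASSES

    @property
    def embedding_dim(self) -> int:
        # global + center-pooled halves (the label is the *center* pixel,
        # so the descriptor keeps a center-localized component)
        return 2 * self.channels[-1]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    class_weights: ClassWeights | None = None
    max_epochs: int = 8
    seed: int = 0
    augment: bool = True
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class _ResBlock(Module):
    def __init__(self, c_in: int, c_out: int, *, rng):
        self.conv1 = Conv2d(c_in, c_out, 3, padding=1, rng=rng)
        self.conv2 = Conv2d(c_out, c_out, 3, padding=1, rng=rng)
        self.proj = Conv2d(c_in, c_out, 1, rng=rng)   # 1x1 projection skip

    def __call__(self, x: Tensor) -> Tensor:
        main = self.conv2(self.conv1(x).relu())
        return (main + self.proj(x)).relu()


class ClassifierModel(Module):
    def __init__(self, arch: ArchSpec = ArchSpec(), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.arch = arch
        self.stem = Conv2d(3, arch.channels[0], 3, padding=1, rng=rng)
        self.blocks = [
            _ResBlock(arch.channels[max(0, i - 1)], c, rng=rng)
            for i, c in enumerate(arch.channels)
        ]
        self.head = Linear(arch.embedding_dim, arch.num_classes, rng=rng)

    @property
    def embedding_dim(self) -> int:
        return self.arch.embedding_dim

    # -- forward -------------------------------------------------------------
    def pool_patches(self, patches: np.ndarray) -> np.ndarray:
        """uint8 (n,s,s,3) -> pooled float array (n,3,r,r), the stem input.

        The stem is a parameter-free block average; flips and right-angle
        rotations commute with it, so augmentation may run on either side.
        """
        s = patches.shape[1]
        if s != self.arch.patch_size:
            raise ValueError(
                f"patch size {s} != model patch size {self.arch.patch_size}")
        r = self.arch.working_resolution
        f = s // r
        x = patches.astype(np.float64) / 255.0 - 0.5
        x = x.transpose(0, 3, 1, 2)
        if f > 1:
            n, c = x.shape[:2]
            x = x.reshape(n, c, r, f, r, f).mean(axis=(3, 5))
        return x

    def forward(self, patches: np.ndarray, *, pooled: bool = False,
                return_features: bool = False, feature_layer: int = -1):
        """Return (logits, embedding[, feature_map]) for a patch batch.

        ``feature_layer`` picks which block's activations are reported as
        the feature map (-1: last; used by the saliency tooling).
        """
        x = Tensor(patches if pooled else self.pool_patches(patches))
        h = self.stem(x).relu()
        per_block = []
        for block in self.blocks:
            h = block(h)
            per_block.append(h)
            h = avg_pool2d(h, 2)
        features = per_block[feature_layer]   # convolutional activations
        hh, hw = h.shape[2], h.shape[3]
        cy, cx = hh // 2, hw // 2
        center = h[:, :, cy - 1:cy + 1, cx - 1:cx + 1]
        emb = concat([global_avg_pool(h), global_avg_pool(center)], axis=1)
        logits = self.head(emb)
        if return_features:
            return logits, emb, features
        return logits, emb

    # -- persistence ---------------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.state_dict())
        meta = asdict(self.arch)
        meta["channels"] = list(self.arch.channels)
        (directory / "arch.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "ClassifierModel":
        directory = Path(directory)
        meta = json.loads((directory / "arch.json").read_text())
        meta["channels"] = tuple(meta["channels"])
        model = cls(ArchSpec(**meta))
        with np.load(directory / "weights.npz") as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model


# -- inference ----------------------------------------------------------------

def predict_batch(model: ClassifierModel,
                  patches: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(scores, labels) for a stack of patches; ties -> lower class index."""
    logits, _ = model.forward(patches)
    scores = logits.data
    return scores, np.argmax(scores, axis=1)


def predict_patch(model: ClassifierModel,
                  patch: np.ndarray) -> tuple[np.ndarray, int]:
    scores, labels = predict_batch(model, patch[None])
    return scores[0], int(labels[0])


def embed_batch(model: ClassifierModel, patches: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """(embeddings, logits) for a stack of patches, one forward pass."""
    logits, emb = model.forward(patches)
    return emb.data, logits.data


def extract_embedding(model: ClassifierModel, patch: np.ndarray) -> np.ndarray:
    emb, _ = embed_batch(model, patch[None])
    return emb[0]


# -- training ------------------------------------------------------------------

def weighted_cross_entropy(logits: Tensor, labels: np.ndarray,
                           weights: np.ndarray) -> Tensor:
    """Weighted mean of -log p(true class); constant weights == unweighted."""
    logp = logits.log_softmax(axis=1)
    n = labels.shape[0]
    picked = logp[np.arange(n), labels]
    w = weights[labels]
    return -(picked * w).sum() * (1.0 / w.sum())


def _augment(rng, pooled: np.ndarray) -> np.ndarray:
    """Random flips/right-angle rotation of one pooled (3, r, r) patch."""
    if rng.random() < 0.5:
        pooled = pooled[:, :, ::-1]
    if rng.random() < 0.5:
        pooled = pooled[:, ::-1, :]
    return np.rot90(pooled, k=int(rng.integers(0, 4)), axes=(1, 2))


def train_classifier(train: list[PatchSample], val: list[PatchSample],
                     cfg: TrainConfig,
                     arch: ArchSpec = ArchSpec()) -> tuple["ClassifierModel",
                                                           list[dict]]:
    """Train and return (best-validation-accuracy model, per-epoch log)."""
    if not train or not val:
        raise ValueError("train and validation splits must be non-empty")
    train_labels = np.array([p.label for p in train])
    if np.unique(train_labels).size < 2:
        raise ValueError("degenerate training set: fewer than 2 classes")

    rng = np.random.default_rng(cfg.seed)
    model = ClassifierModel(arch, seed=int(rng.integers(0, 2 ** 31)))
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    weights = (cfg.class_weights.as_array() if cfg.class_weights is not None
               else np.ones(NUM_CLASSES))

    # pool once; augmentation commutes with the parameter-free stem
    train_x = model.pool_patches(np.stack([p.pixels for p in train]))
    val_x = model.pool_patches(np.stack([p.pixels for p in val]))
    val_y = np.array([p.label for p in val])

    log: list[dict] = []
    best_state, best_acc, best_epoch = None, -1.0, -1
    n = len(train)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pix = np.stack([
                _augment(rng, train_x[i]) if cfg.augment else train_x[i]
                for i in idx])
            labels = train_labels[idx]
            logits, _ = model.forward(pix, pooled=True)
            loss = weighted_cross_entropy(logits, labels, weights)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
            correct += int((np.argmax(logits.data, axis=1) == labels).sum())
        val_logits, _ = model.forward(val_x, pooled=True)
        val_pred = np.argmax(val_logits.data, axis=1)
        val_loss = weighted_cross_entropy(
            Tensor(val_logits.data), val_y, weights)
        val_acc = float((val_pred == val_y).mean())
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "val_loss": float(val_loss.data),
                 "train_acc": correct / n, "val_acc": val_acc}
        log.append(entry)
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = model.state_dict()
        if cfg.checkpoint_dir is not None:
            ckpt = Path(cfg.checkpoint_dir) / f"epoch_{epoch:03d}"
            model.save(ckpt)
    model.load_state_dict(best_state)
    if cfg.checkpoint_dir is not None:
        model.save(Path(cfg.checkpoint_dir) / "best")
        logpath = Path(cfg.checkpoint_dir) / "training_log.csv"
        header = "epoch,train_loss,val_loss,train_acc,val_acc"
        rows = [",".join(str(e[k]) for k in header.split(","))
                for e in log]
        logpath.write_text("\n".join([header] + rows) + "\n")
    return model, log
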