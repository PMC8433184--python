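"""Three-class developmental-stage patch classifier.

Classifies 200 x 200 px incubator patches into {Empty, PreBean, Bean}.
Patches are downscaled to a small grayscale input and min-max normalised
to [0, 1] (illumination varies across lanes), then passed through a small
fully connected network with ReLU hidden layers and a softmax output.
Training runs through scikit-learn's MLP optimiser; the fitted weights
are frozen into a self-contained :class:`ClassifierModel` whose forward
pass is pure NumPy, deterministic and serialisable to a single checkpoint
file with an embedded JSON header.

Per-frame classifications drive two transition detectors: the hatch frame
(first persistent run of Empty — the larva has left the incubator) and the
bean frame (first persistent PreBean -> Bean switch).  ``persistence``
debounces single-frame misclassifications.
"""

from __future__ import annotations

import io as _io
import json
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

__all__ = [
    "CLASS_ORDER",
    "ClassifierModel",
    "train_classifier",
    "classify_patch",
    "classify_series",
    "detect_hatch_frame",
    "detect_bean_frame",
    "save_model",
    "load_model",
]

#: Fixed class ordering, serialised with every model.
CLASS_ORDER = ("Empty", "PreBean", "Bean")

#: Labels that imply an embryo is present in the incubator.
EMBRYO_PRESENT = frozenset({"PreBean", "Bean"})


@dataclass
class ClassifierModel:
    """Frozen feed-forward classifier (weights + preprocessing spec)."""

    weights: list  # list of (n_in, n_out) arrays
    biases: list
    classes: tuple = CLASS_ORDER
    resize_to: int = 48
    patch_size_px: int = 200
    seed: int = 0
    holdout_accuracy: Optional[float] = None

    @property
    def architecture(self) -> str:
        sizes = [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]
        return "mlp:" + "-".join(str(s) for s in sizes)

    def preprocess(self, patch: np.ndarray) -> np.ndarray:
        """Downscale + min-max normalise one patch to a feature vector."""
        patch = np.asarray(patch, dtype=float)
        if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
            raise ValueError("patch must be a square single-channel image")
        if patch.shape[0] != self.patch_size_px:
            raise ValueError(
                f"patch is {patch.shape[0]} px, model expects {self.patch_size_px} px"
            )
        small = resize(patch, (self.resize_to, self.resize_to), anti_aliasing=True)
        lo, hi = small.min(), small.max()
        if hi > lo:
            small = (small - lo) / (hi - lo)
        else:
            small = np.zeros_like(small)
        return small.ravel()

    def forward(self, features: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for a (n, d) feature batch."""
        a = np.atleast_2d(features)
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ w + b, 0.0)
        z = a @ self.weights[-1] + self.biases[-1]
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def train_classifier(
    patches: np.ndarray,
    labels: Sequence[str],
    epochs: int = 300,
    seed: int = 0,
    hidden: tuple[int, ...] = (64,),
    resize_to: int = 48,
) -> ClassifierModel:
    """Fit the patch classifier on a labelled set.

    A stratified 20% split is held out and its accuracy stored on the
    returned model.  Class imbalance (as in real annotated sets) is
    handled by seeded oversampling of minority classes to the majority
    count, the resampling analogue of inverse-frequency loss weighting.
    Training is reproducible for a fixed seed.
    """
    patches = np.asarray(patches)
    labels = np.asarray(labels)
    if patches.shape[0] == 0:
        raise ValueError("empty training set")
    present = np.unique(labels)
    if present.size < 2:
        raise ValueError("training needs at least two classes")
    unknown = set(present) - set(CLASS_ORDER)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    for cls in present:
        if np.sum(labels == cls) < 10:
            raise ValueError(f"class {cls!r} has fewer than 10 patches")

    model = ClassifierModel(
        weights=[], biases=[], resize_to=resize_to,
        patch_size_px=patches.shape[1], seed=seed,
    )
    feats = np.stack([model.preprocess(p) for p in patches])
    y = np.array([CLASS_ORDER.index(l) for l in labels])

    x_tr, x_te, y_tr, y_te = train_test_split(
        feats, y, test_size=0.2, random_state=seed, stratify=y
    )
    # oversample minority classes to balance the training split
    rng = np.random.default_rng(seed)
    counts = np.bincount(y_tr, minlength=len(CLASS_ORDER))
    target = counts.max()
    idx = [np.nonzero(y_tr == k)[0] for k in range(len(CLASS_ORDER))]
    extra = [
        rng.choice(ix, size=target - ix.size, replace=True)
        for ix in idx if 0 < ix.size < target
    ]
    if extra:
        add = np.concatenate(extra)
        x_tr = np.concatenate([x_tr, x_tr[add]])
        y_tr = np.concatenate([y_tr, y_tr[add]])

    # L-BFGS: deterministic full-batch optimisation, much more stable than
    # SGD variants at this data size (hundreds of patches per class)
    clf = MLPClassifier(
        hidden_layer_sizes=hidden,
        solver="lbfgs",
        max_iter=epochs,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(x_tr, y_tr)

    model.weights = [w.copy() for w in clf.coefs_]
    model.biases = [b.copy() for b in clf.intercepts_]
    # classes absent from training still occupy output slots only if the
    # label map was complete; MLP outputs follow sorted present classes
    if not np.array_equal(clf.classes_, np.arange(len(CLASS_ORDER))):
        # expand output layer to the full class ordering
        w_out = np.zeros((model.weights[-1].shape[0], len(CLASS_ORDER)))
        b_out = np.full(len(CLASS_ORDER), -1e3)
        for j, k in enumerate(clf.classes_):
            w_out[:, k] = model.weights[-1][:, j]
            b_out[k] = model.biases[-1][j]
        model.weights[-1] = w_out
        model.biases[-1] = b_out
    model.holdout_accuracy = float(np.mean(clf.predict(x_te) == y_te))
    return model


def classify_patch(model: ClassifierModel, patch: np.ndarray) -> np.ndarray:
    """Class probability vector (ordered as ``model.classes``) for one patch."""
    return model.forward(model.preprocess(patch))[0]


def classify_series(model: ClassifierModel, series: np.ndarray) -> np.ndarray:
    """Per-frame class probabilities, shape ``(n_frames, n_classes)``."""
    feats = np.stack([model.preprocess(p) for p in np.asarray(series)])
    return model.forward(feats)


def _labels(model: ClassifierModel, series: np.ndarray) -> np.ndarray:
    return np.asarray(model.classes)[classify_series(model, series).argmax(axis=1)]


def detect_hatch_frame(
    model: ClassifierModel, series: np.ndarray, persistence: int = 3
) -> Optional[int]:
    """First frame of a >= ``persistence``-long run of Empty classifications.

    Returns ``None`` when the embryo never disappears (the late-hatching
    precondition).
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    labels = _labels(model, series)
    empty = labels == "Empty"
    run = 0
    for t, e in enumerate(empty):
        run = run + 1 if e else 0
        if run >= persistence:
            return t - persistence + 1
    return None


def _runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """Maximal constant runs as (label, start, length)."""
    out = []
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            out.append((str(labels[start]), start, t - start))
            start = t
    return out


def detect_bean_frame(
    model: ClassifierModel,
    series: np.ndarray,
    persistence: int = 3,
    end_frame: Optional[int] = None,
) -> Optional[int]:
    """First persistent PreBean -> Bean switch, or ``None`` for "unclear".

    Searches only run starts before ``end_frame`` (usually the twitch
    frame).  A series with no persistent PreBean run before its first
    persistent Bean run — the embryo was already past the bean stage, or
    never clearly reached it — has no observable transition and is
    reported unclear.
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    labels = _labels(model, series)
    end = len(labels) if end_frame is None else int(end_frame)
    prebean_seen = False
    for label, start, length in _runs(labels):
        if start >= end:
            break
        if length < persistence:
            continue
        if label == "PreBean":
            prebean_seen = True
        elif label == "Bean":
            return start if prebean_seen else None
    return None


def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Serialise to a single checkpoint (zip of JSON header + weight arrays)."""
    header = {
        "architecture": model.architecture,
        "classes": list(model.classes),
        "resize_to": model.resize_to,
        "patch_size_px": model.patch_size_px,
        "seed": model.seed,
        "holdout_accuracy": model.holdout_accuracy,
        "n_layers": len(model.weights),
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("header.json", json.dumps(header, indent=2))
        for i, (w, b) in enumerate(zip(model.weights, model.biases)):
            for name, arr in ((f"w{i}", w), (f"b{i}", b)):
                buf = _io.BytesIO()
                np.save(buf, arr)
                zf.writestr(f"{name}.npy", buf.getvalue())


def load_model(path: str | Path) -> ClassifierModel:
    with zipfile.ZipFile(path) as zf:
        header = json.loads(zf.read("header.json"))
        weights, biases = [], []
        for i in range(header["n_layers"]):
            weights.append(np.load(_io.BytesIO(zf.read(f"w{i}.npy"))))
            biases.append(np.load(_io.BytesIO(zf.read(f"b{i}.npy"))))
    return ClassifierModel(
        weights=weights,
        biases=biases,
        classes=tuple(header["classes"]),
        resize_to=header["resize_to"],
        patch_size_px=header["patch_size_px"],
        seed=header["seed"],
        holdout_accuracy=header["holdout_accuracy"],
    )
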