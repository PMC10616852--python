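"""Crop preprocessing, augmentation, PCA features and the RBF-SVM classifier.

A 24x10 crop anchored on a blob is normalized so the four central pixels of
the top blob average to 1 (the normalization constant *k* is kept as an
extra feature), mirror-symmetrized to a 24x5 = 120-value half-crop, and
projected onto 20 principal components.  The 20 coefficients plus *k* are
standardized and fed to a 4-class RBF-kernel SVM (three target classes plus
a noise class for bottom-blob crops and false detections).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

NOISE_LABEL = "noise"

#: the "four central pixels of the top blob": the 2x2 block at the crop
#: anchor — rows 1-2, cols 4-5 (0-based), tied to the detection anchor.
ANCHOR_BLOCK = (slice(1, 3), slice(4, 6))

CROP_SHAPE = (24, 10)
HALF_SHAPE = (24, 5)
N_HALF = HALF_SHAPE[0] * HALF_SHAPE[1]


def _edge_pixels(crop: np.ndarray) -> np.ndarray:
    return np.concatenate([crop[0, :], crop[-1, :], crop[1:-1, 0], crop[1:-1, -1]])


def symmetrize(crop: np.ndarray) -> np.ndarray:
    """Fold a 24x10 crop into its 24x5 mirror-symmetric right half.

    The horizontally flipped crop is added to the original and only the right
    half kept, halving 240 pixels to 120.
    """
    crop = np.asarray(crop, dtype=float)
    if crop.shape != CROP_SHAPE:
        raise ValueError(f"expected {CROP_SHAPE} crop, got {crop.shape}")
    s = crop + crop[:, ::-1]
    return s[:, CROP_SHAPE[1] // 2:]


@dataclass(frozen=True)
class PreparedCrop:
    """Preprocessed crop: 120-value symmetrized half plus normalization k."""

    half: np.ndarray | None
    k: float
    rejected: bool = False
    reason: str = ""


def preprocess_crop(crop: np.ndarray) -> PreparedCrop:
    """Edge-median background subtraction, k-normalization, symmetrization.

    The median of the crop-edge pixels is subtracted; if that makes any of
    the four anchor pixels negative the crop is discarded, otherwise other
    negative pixels are zeroed.  The crop is divided by k = mean of the four
    anchor pixels (so their mean becomes exactly 1) and symmetrized.
    """
    crop = np.asarray(crop, dtype=float)
    if crop.shape != CROP_SHAPE:
        raise ValueError(f"expected {CROP_SHAPE} crop, got {crop.shape}")
    x = crop - np.median(_edge_pixels(crop))
    anchor = x[ANCHOR_BLOCK]
    if np.any(anchor < 0):
        return PreparedCrop(None, 0.0, rejected=True, reason="negative anchor")
    x = np.clip(x, 0.0, None)
    k = float(x[ANCHOR_BLOCK].mean())
    if k <= 0.0:
        return PreparedCrop(None, 0.0, rejected=True, reason="flat crop")
    return PreparedCrop(symmetrize(x / k).ravel(), k)


def prepare_crops(crops: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`preprocess_crop` over a crop array (n, 24, 10).

    Returns ``(halves, k, kept_mask)`` where ``halves`` is (n_kept, 120).
    """
    crops = np.asarray(crops, dtype=float)
    n = crops.shape[0]
    if crops.shape[1:] != CROP_SHAPE:
        raise ValueError(f"expected (n, {CROP_SHAPE[0]}, {CROP_SHAPE[1]}) crops")
    edges = np.concatenate([crops[:, 0, :], crops[:, -1, :],
                            crops[:, 1:-1, 0], crops[:, 1:-1, -1]], axis=1)
    x = crops - np.median(edges, axis=1)[:, None, None]
    anchors = x[:, ANCHOR_BLOCK[0], ANCHOR_BLOCK[1]]
    kept = ~np.any(anchors < 0, axis=(1, 2))
    x = np.clip(x, 0.0, None)
    k = x[:, ANCHOR_BLOCK[0], ANCHOR_BLOCK[1]].mean(axis=(1, 2))
    kept &= k > 0
    xs = x[kept] / k[kept, None, None]
    sym = xs + xs[:, :, ::-1]
    halves = sym[:, :, CROP_SHAPE[1] // 2:].reshape(-1, N_HALF)
    return halves, k[kept], kept


def augment(crops: np.ndarray, labels: np.ndarray, n_extra: int = 2,
            noise_sd: float = 0.05, seed: int = 0,
            mir_only: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Expand a labeled crop set with weak-noise copies (default x3).

    Each crop contributes itself plus ``n_extra`` copies perturbed by
    pixel-wise Gaussian noise whose SD is ``noise_sd`` times the crop's
    anchor-block mean (i.e. weak noise relative to the top-blob brightness).
    With ``mir_only`` the noise-class crops are copied without perturbation,
    keeping the output size at (1+n_extra) times the input either way.
    """
    if n_extra < 0 or noise_sd < 0:
        raise ValueError("n_extra and noise_sd must be >= 0")
    crops = np.asarray(crops, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    scale = np.abs(crops[:, ANCHOR_BLOCK[0], ANCHOR_BLOCK[1]]).mean(axis=(1, 2))
    scale = np.where(scale > 0, scale, np.abs(crops).max(axis=(1, 2)) + 1e-12)
    out_c = [crops]
    out_l = [labels]
    for _ in range(n_extra):
        noise = rng.standard_normal(crops.shape) * (noise_sd * scale)[:, None, None]
        if mir_only:
            noise[labels == NOISE_LABEL] = 0.0
        out_c.append(crops + noise)
        out_l.append(labels)
    return np.concatenate(out_c), np.concatenate(out_l)


@dataclass
class FeatureModel:
    """PCA components over half-crops plus standardization of (coeffs, k)."""

    pca: object          # sklearn PCA
    scaler: object       # sklearn StandardScaler over 21 features
    n_components: int = 20

    def transform(self, halves: np.ndarray, k: np.ndarray) -> np.ndarray:
        coeffs = self.pca.transform(halves)
        feats = np.column_stack([coeffs, np.asarray(k, dtype=float)])
        return self.scaler.transform(feats)


def fit_feature_model(halves: np.ndarray, k: np.ndarray,
                      n_components: int = 20, seed: int = 0) -> FeatureModel:
    """PCA of the 120-value half-crops + joint standardization with k.

    The feature vector is the ``n_components`` PCA coefficients plus the
    normalization constant k, standardized to zero mean / unit variance over
    the training set.
    """
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    halves = np.asarray(halves, dtype=float)
    if halves.shape[0] < n_components:
        raise ValueError("fewer training crops than PCA components")
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    coeffs = pca.fit_transform(halves)
    feats = np.column_stack([coeffs, np.asarray(k, dtype=float)])
    scaler = StandardScaler().fit(feats)
    return FeatureModel(pca, scaler, n_components)


@dataclass(frozen=True)
class ClassifyConfig:
    """Classifier hyperparameters (all exposed; defaults are the package's)."""

    n_components: int = 20
    svm_c: float = 10.0
    gamma: str | float = "scale"
    val_fraction: float = 0.1
    n_extra: int = 2
    noise_sd: float = 0.05


@dataclass
class ClassifierModel:
    """Trained feature model + probability-calibrated RBF-SVM."""

    feature_model: FeatureModel
    svm: object
    classes: list[str]
    config: ClassifyConfig
    seed: int
    validation: dict = field(default_factory=dict)

    @property
    def n_support(self) -> np.ndarray:
        """Support-vector count per class of the underlying SVM."""
        return self.svm.calibrated_classifiers_[0].estimator.n_support_

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ClassifierModel":
        import joblib

        return joblib.load(path)


def train_classifier(features: np.ndarray, labels: np.ndarray,
                     feature_model: FeatureModel,
                     cfg: ClassifyConfig | None = None,
                     seed: int = 0) -> ClassifierModel:
    """Train the 4-class probability-calibrated RBF-SVM on standardized features.

    A seeded stratified 90/10 train/validation split is used; the validation
    confusion matrix and accuracy are stored on the model.
    """
    from sklearn.calibration import CalibratedClassifierCV
    from sklearn.metrics import confusion_matrix as _sk_confusion
    from sklearn.model_selection import train_test_split
    from sklearn.svm import SVC

    cfg = cfg or ClassifyConfig()
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = pd.Series(labels).value_counts()
    if counts.min() < 2:
        raise ValueError(f"class {counts.idxmin()!r} has fewer than 2 examples")

    X_tr, X_val, y_tr, y_val = train_test_split(
        features, labels, test_size=cfg.val_fraction, random_state=seed,
        stratify=labels)
    base = SVC(kernel="rbf", C=cfg.svm_c, gamma=cfg.gamma, random_state=seed)
    # 5-fold Platt-style probability calibration around the RBF-SVM
    svm = CalibratedClassifierCV(base, method="sigmoid", cv=5, ensemble=False)
    svm.fit(X_tr, y_tr)
    proba = svm.predict_proba(X_val)
    y_pred = np.asarray(svm.classes_)[np.argmax(proba, axis=1)]
    val_conf = _sk_confusion(y_val, y_pred, labels=classes)
    model = ClassifierModel(feature_model, svm, classes, cfg, seed,
                            validation={"confusion": val_conf,
                                        "classes": classes,
                                        "n_val": len(y_val),
                                        "accuracy": float((y_pred == y_val).mean())})
    log.info("validation accuracy %.3f on %d crops",
             model.validation["accuracy"], len(y_val))
    return model


def predict_proba(model: ClassifierModel, features: np.ndarray) -> pd.DataFrame:
    """Per-class probability vectors (rows sum to 1), columns in class order."""
    proba = model.svm.predict_proba(features)
    cols = list(model.svm.classes_)
    return pd.DataFrame(proba, columns=cols)[model.classes]


def predict(model: ClassifierModel, features: np.ndarray) -> np.ndarray:
    """Predicted labels, defined as the argmax of the calibrated probabilities.

    Defining ``predict`` through the probability vector guarantees that the
    label and probability interfaces never disagree (plain SVM decision
    functions do not guarantee this).
    """
    proba = predict_proba(model, features)
    return proba.columns.to_numpy()[np.argmax(proba.to_numpy(), axis=1)]


def train_from_crops(crops: np.ndarray, labels: np.ndarray,
                     cfg: ClassifyConfig | None = None,
                     seed: int = 0) -> ClassifierModel:
    """Full training path: augment, preprocess, fit features, train the SVM."""
    cfg = cfg or ClassifyConfig()
    aug_c, aug_l = augment(crops, labels, cfg.n_extra, cfg.noise_sd, seed=seed)
    halves, k, kept = prepare_crops(aug_c)
    if kept.sum() < len(kept):
        log.info("training: %d augmented crops rejected in preprocessing",
                 int(len(kept) - kept.sum()))
    fm = fit_feature_model(halves, k, cfg.n_components, seed=seed)
    feats = fm.transform(halves, k)
    return train_classifier(feats, aug_l[kept], fm, cfg, seed=seed)


def classify_crops(model: ClassifierModel, crops: np.ndarray,
                   return_proba: bool = False):
    """Classify raw crops; crops rejected in preprocessing are labeled noise.

    Returns the label array, or ``(labels, proba, kept_mask)`` with
    ``return_proba`` (probability rows for rejected crops are all-NaN).
    """
    halves, k, kept = prepare_crops(crops)
    labels = np.full(crops.shape[0], NOISE_LABEL, dtype=object)
    if kept.any():
        feats = model.feature_model.transform(halves, k)
        labels[kept] = predict(model, feats)
    if not return_proba:
        return labels
    proba = pd.DataFrame(np.nan, index=np.arange(crops.shape[0]),
                         columns=model.classes)
    if kept.any():
        proba.loc[kept, :] = predict_proba(model, feats).to_numpy()
    return labels, proba, kept


def empirical_psf(crops: np.ndarray) -> np.ndarray:
    """Pixel-wise median over many crops of one species.

    Averaging tens of thousands of noisy crops of the same barcode gives a
    high-SNR empirical PSF with its two blobs clearly visible — a reporting
    and QC utility, not part of the classification path.
    """
    crops = np.asarray(crops, dtype=float)
    if crops.ndim != 3:
        raise ValueError("expected a (n, rows, cols) crop array")
    return np.median(crops, axis=0)


def pr_curve(scores: np.ndarray, y_true: np.ndarray,
             thresholds: np.ndarray | None = None) -> tuple[pd.DataFrame, float]:
    """Precision-recall curve by thresholding one class's probability P_i.

    A sample is predicted positive when its score is >= the threshold, which
    is swept over [0, 1]; the area under the curve is the average precision
    (step integral over the ranking).  Points where no sample is predicted
    positive carry an undefined (NaN) precision.
    """
    from sklearn.metrics import average_precision_score

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true).astype(bool)
    if not y.any():
        raise ValueError("no positive examples")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    rows = []
    n_pos = int(y.sum())
    for t in thresholds:
        pred = scores >= t
        tp = int((pred & y).sum())
        rows.append({"threshold": float(t),
                     "precision": tp / pred.sum() if pred.any() else np.nan,
                     "recall": tp / n_pos})
    curve = pd.DataFrame(rows)
    return curve, float(average_precision_score(y, scores))
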