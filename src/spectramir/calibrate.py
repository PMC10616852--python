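"""Confusion-matrix calibration of class counts and resampling uncertainty.

The classifier's predicted class counts ``h`` relate to the true counts
``h'`` through the conditional error rates of the classifier: ``h = Ĉ h'``
with ``Ĉ_ij = P(predicted = i | true = j)`` estimated from a labeled subset.
Inverting Ĉ ("unconfusion") recovers the best estimate of the true counts.
Dividing the corrected counts of an unknown mixture by those of a known
equidistributed (1:1:1) reference cancels every per-class multiplicative
bias shared by the two experiments — capture efficiency, detection and
classification bias — leaving the relative abundances.

Uncertainty is propagated by paired multinomial resampling of the confusion
matrix plus Gaussian perturbation of the counts, summarized by a 2-D
Gaussian fit on the ternary-composition plane.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

COND_LIMIT = 1e8


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer counts C[i, j] = number of samples with true class i predicted j."""

    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.classes):
            raise ValueError("confusion matrix must be square and match classes")
        if np.any(c < 0):
            raise ValueError("confusion counts must be >= 0")
        object.__setattr__(self, "counts", c.astype(float))

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion(true_labels, predicted_labels, classes: list[str]) -> ConfusionMatrix:
    """Exact cross-tabulation of true vs predicted labels."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    unknown = (set(t) | set(p)) - set(classes)
    if unknown:
        raise ValueError(f"unknown label(s): {sorted(unknown)}")
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)))
    for ti, pi in zip(t, p):
        counts[idx[ti], idx[pi]] += 1
    return ConfusionMatrix(counts, list(classes))


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class recall r_i and precision p_j; NaN flags an undefined value."""

    recall: pd.Series
    precision: pd.Series


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Recall r_i = C_ii / row-sum_i and precision p_j = C_jj / col-sum_j.

    Classes with an empty row (no true occurrences) or empty column (never
    predicted) get NaN, never a silent 0.
    """
    c = cm.counts
    rows = c.sum(axis=1)
    cols = c.sum(axis=0)
    diag = np.diag(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(rows > 0, diag / np.where(rows > 0, rows, 1), np.nan)
        p = np.where(cols > 0, diag / np.where(cols > 0, cols, 1), np.nan)
    return ClassMetrics(pd.Series(r, index=cm.classes, name="recall"),
                        pd.Series(p, index=cm.classes, name="precision"))


def normalized_confusion(cm: ConfusionMatrix,
                         convention: str = "generative") -> np.ndarray:
    """Ĉ with Ĉ_ij = P(predicted = i | true = j) (columns sum to 1).

    The generative convention is the unique one under which ``h = Ĉ h'``
    holds exactly.  ``convention="paper"`` instead applies the literal
    column-normalization formula Ĉ_ij = C_ij / Σ_k C_kj for comparison.
    """
    c = cm.counts
    if convention == "generative":
        rows = c.sum(axis=1)
        if np.any(rows == 0):
            raise ValueError("confusion matrix has an empty true class")
        return (c / rows[:, None]).T
    if convention == "paper":
        cols = c.sum(axis=0)
        if np.any(cols == 0):
            raise ValueError("confusion matrix has an empty predicted class")
        return c / cols[None, :]
    raise ValueError(f"unknown convention {convention!r}")


def unconfuse(cm: ConfusionMatrix, h, convention: str = "generative",
              clip_negative: bool = True) -> np.ndarray:
    """Corrected counts h' = Ĉ⁻¹ h.

    Raises on an ill-conditioned Ĉ (condition number above 1e8).  Negative
    corrected components — possible with a noisy confusion matrix — are
    clipped to zero with a warning.
    """
    h = np.asarray(h, dtype=float)
    chat = normalized_confusion(cm, convention)
    cond = np.linalg.cond(chat)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise ValueError(f"normalized confusion matrix is ill-conditioned "
                         f"(cond={cond:.3g})")
    log.debug("unconfuse: cond(Chat) = %.3g", cond)
    h_prime = np.linalg.solve(chat, h)
    if clip_negative and np.any(h_prime < 0):
        warnings.warn("negative corrected counts clipped to zero")
        h_prime = np.clip(h_prime, 0.0, None)
    return h_prime


# ---------------------------------------------------------------------------
# ternary-composition geometry
# ---------------------------------------------------------------------------

def _simplex_basis() -> np.ndarray:
    """Orthonormal 2x3 basis of the sum-zero plane of 3-compositions."""
    b1 = np.array([1.0, -1.0, 0.0]) / np.sqrt(2.0)
    b2 = np.array([1.0, 1.0, -2.0]) / np.sqrt(6.0)
    return np.vstack([b1, b2])


_B = _simplex_basis()


def composition_to_plane(comp: np.ndarray) -> np.ndarray:
    """Isometric 2-D coordinates of 3-part compositions (centroid at origin)."""
    comp = np.asarray(comp, dtype=float)
    return (comp - 1.0 / 3.0) @ _B.T


def plane_to_composition(xy: np.ndarray) -> np.ndarray:
    """Inverse of :func:`composition_to_plane`."""
    return 1.0 / 3.0 + np.asarray(xy, dtype=float) @ _B


@dataclass(frozen=True)
class RatioEstimate:
    """Normalized 3-class composition with optional 2-SD half-widths.

    ``composition`` sums to 1 over the three target classes (noise excluded);
    ``half_widths`` are per-class 95% (two standard deviation) half-widths in
    composition units, obtained by projecting the ensemble covariance on the
    centroid-to-vertex directions of the ternary plane.
    """

    classes: tuple[str, ...]
    composition: np.ndarray
    half_widths: np.ndarray | None = None
    mean_xy: np.ndarray | None = None
    cov_xy: np.ndarray | None = None
    n_reps: int = 0
    count_cv: float = 0.0
    seed: int | None = None
    n_redrawn: int = 0

    def parts_of(self, total: float = 10.0) -> np.ndarray:
        return self.composition * total

    def to_dict(self) -> dict:
        out = {"classes": list(self.classes),
               "composition": self.composition.tolist(),
               "n_reps": self.n_reps, "count_cv": self.count_cv,
               "seed": self.seed, "n_redrawn": self.n_redrawn}
        if self.half_widths is not None:
            out["half_widths"] = self.half_widths.tolist()
            out["mean_xy"] = self.mean_xy.tolist()
            out["cov_xy"] = self.cov_xy.tolist()
        return out


def _composition_from_counts(h_mix: np.ndarray, h_ref: np.ndarray,
                             keep: np.ndarray) -> np.ndarray:
    ratio = h_mix[..., keep] / h_ref[..., keep]
    return ratio / ratio.sum(axis=-1, keepdims=True)


def ratio_estimate(h_mix_prime, h_ref_prime, classes: list[str],
                   noise_label: str = "noise") -> RatioEstimate:
    """Point estimate of the mixture composition.

    Element-wise division of the corrected mixture counts by the corrected
    counts of the 1:1:1 reference, dropping the noise class and normalizing
    the remaining entries to sum to 1.
    """
    h_mix_prime = np.asarray(h_mix_prime, dtype=float)
    h_ref_prime = np.asarray(h_ref_prime, dtype=float)
    keep = np.array([c != noise_label for c in classes])
    if keep.sum() != 3:
        raise ValueError("expected exactly three non-noise classes")
    if np.any(h_ref_prime[keep] <= 0):
        bad = [c for c, k, v in zip(classes, keep, h_ref_prime) if k and v <= 0]
        raise ValueError(f"reference class unobserved: {bad}")
    comp = _composition_from_counts(h_mix_prime, h_ref_prime, keep)
    return RatioEstimate(tuple(np.asarray(classes)[keep]), comp)


def _resample_rows(counts: np.ndarray, rng: np.random.Generator,
                   size: int) -> np.ndarray:
    """Draw ``size`` multinomial resamples of each row of a count matrix."""
    k = counts.shape[0]
    out = np.empty((size, k, k))
    for i in range(k):
        n = counts[i].sum()
        p = counts[i] / n
        out[:, i, :] = rng.multinomial(int(round(n)), p, size=size)
    return out


def estimate_uncertainty(cm: ConfusionMatrix, h_ref, h_mix,
                         n_reps: int = 10_000, count_cv: float = 0.05,
                         seed: int = 0, noise_label: str = "noise",
                         max_redraw_rounds: int = 8) -> RatioEstimate:
    """Resampling-based composition estimate with 95% (2-SD) intervals.

    Per repetition, the confusion matrix is replaced by a *pair* of matrices
    whose rows are multinomial resamples of the observed rows, and the two
    raw count vectors are perturbed with Gaussian noise of standard deviation
    ``count_cv`` times their means.  Each perturbed count vector is
    unconfused with its own resampled matrix, the corrected counts are
    divided and normalized, and a 2-D Gaussian is fit to the resulting
    ensemble on the ternary plane.  Reported are the ensemble-mean
    composition and per-class two-standard-deviation half-widths from the
    covariance projected onto the class-vertex directions.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    h_ref = np.asarray(h_ref, dtype=float)
    h_mix = np.asarray(h_mix, dtype=float)
    classes = cm.classes
    keep = np.array([c != noise_label for c in classes])
    if keep.sum() != 3:
        raise ValueError("expected exactly three non-noise classes")
    rng = np.random.default_rng(seed)
    rows = cm.counts.sum(axis=1)
    if np.any(rows == 0):
        raise ValueError("confusion matrix has an empty true class")

    comps = np.empty((n_reps, 3))
    filled = 0
    n_redrawn = 0
    for round_no in range(max_redraw_rounds):
        need = n_reps - filled
        if need <= 0:
            break
        c1 = _resample_rows(cm.counts, rng, need)
        c2 = _resample_rows(cm.counts, rng, need)
        chat1 = np.swapaxes(c1 / c1.sum(axis=2, keepdims=True), 1, 2)
        chat2 = np.swapaxes(c2 / c2.sum(axis=2, keepdims=True), 1, 2)
        hr = h_ref[None] * (1.0 + count_cv * rng.standard_normal((need, h_ref.size)))
        hm = h_mix[None] * (1.0 + count_cv * rng.standard_normal((need, h_mix.size)))
        try:
            hr_p = np.linalg.solve(chat1, hr[..., None])[..., 0]
            hm_p = np.linalg.solve(chat2, hm[..., None])[..., 0]
        except np.linalg.LinAlgError:
            n_redrawn += need
            continue
        hr_p = np.clip(hr_p, 0.0, None)
        hm_p = np.clip(hm_p, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            batch = _composition_from_counts(hm_p, hr_p, keep)
        ok = np.all(np.isfinite(batch), axis=1)
        n_ok = int(ok.sum())
        comps[filled:filled + n_ok] = batch[ok]
        n_redrawn += need - n_ok
        filled += n_ok
    if filled < n_reps:
        raise RuntimeError("too many degenerate resampling repetitions")
    if n_redrawn:
        log.info("estimate_uncertainty: %d repetitions redrawn", n_redrawn)

    xy = composition_to_plane(comps)
    mean_xy = xy.mean(axis=0)
    cov_xy = np.cov(xy, rowvar=False)
    mean_comp = plane_to_composition(mean_xy)
    # class-vertex directions in the plane: p_k = 1/3 + v_k . xy with v_k = B e_k
    v = _B.T  # (3, 2)
    sd = np.sqrt(np.einsum("kj,jl,kl->k", v, cov_xy, v))
    return RatioEstimate(tuple(np.asarray(classes)[keep]), mean_comp,
                         half_widths=2.0 * sd, mean_xy=mean_xy, cov_xy=cov_xy,
                         n_reps=n_reps, count_cv=count_cv, seed=seed,
                         n_redrawn=n_redrawn)


def count_vector(labels, classes: list[str]) -> np.ndarray:
    """Predicted class counts h in the given class order."""
    labels = np.asarray(labels)
    return np.array([(labels == c).sum() for c in classes], dtype=float)
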