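"""Stack preprocessing: median background removal, outlier-FOV pruning and a
pluggable denoising slot.

The excitation background is constant across FOVs, so the pixel-wise median
over the FOV axis estimates it robustly; subtracting it leaves zero-mean
noise plus molecules.  FOVs whose residuals are atypical (bubbles, drifted
background) are pruned by a quantile rule on two robust per-FOV statistics.
Denoising is a plugin slot — the pipeline is fully functional with the
identity method, and a self-supervised or external denoiser can be plugged
in through an array-in/array-out contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .scene import FOVStack


def median_background(stack: FOVStack | np.ndarray) -> np.ndarray:
    """Pixel-wise median across the FOV axis."""
    data = stack.data if isinstance(stack, FOVStack) else np.asarray(stack)
    if data.ndim != 3 or data.shape[0] < 3:
        raise ValueError("median background needs a stack of >= 3 FOVs")
    return np.median(data, axis=0)


def subtract_median(stack: FOVStack) -> FOVStack:
    """Subtract the pixel-wise median background from every FOV."""
    bg = median_background(stack)
    return FOVStack(stack.data - bg[None], stack.fov_ids,
                    {**stack.meta, "median_subtracted": True})


@dataclass(frozen=True)
class PruneReport:
    """Per-FOV residual statistics and keep decisions."""

    table: pd.DataFrame          # fov_id, mean_positive, mean_negative_abs, stat, keep
    threshold: float
    keep_fraction: float


def subtract_and_prune(stack: FOVStack,
                       keep_fraction: float = 0.8) -> tuple[FOVStack, PruneReport]:
    """Prune outlier FOVs of a median-subtracted stack.

    For each FOV compute the mean of the positive pixels and the absolute
    mean of the negative pixels; combine them as their maximum and keep the
    ``ceil(keep_fraction * n_fov)`` FOVs with the smallest combined statistic
    (ties broken by FOV order).  The threshold is therefore the keep-fraction
    quantile of the combined statistic.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must be in (0, 1]")
    data = stack.data
    n = data.shape[0]
    flat = data.reshape(n, -1).astype(float)
    pos_cnt = np.maximum((flat > 0).sum(axis=1), 1)
    neg_cnt = np.maximum((flat < 0).sum(axis=1), 1)
    mean_pos = np.clip(flat, 0, None).sum(axis=1) / pos_cnt
    mean_neg = np.abs(np.clip(flat, None, 0).sum(axis=1)) / neg_cnt
    stat = np.maximum(mean_pos, mean_neg)

    n_keep = min(n, math.ceil(keep_fraction * n))
    order = np.argsort(stat, kind="stable")
    keep_idx = np.sort(order[:n_keep])
    keep = np.zeros(n, dtype=bool)
    keep[keep_idx] = True
    threshold = float(stat[order[n_keep - 1]])

    table = pd.DataFrame({"fov_id": stack.fov_ids, "mean_positive": mean_pos,
                          "mean_negative_abs": mean_neg, "stat": stat,
                          "keep": keep})
    return stack.select(keep), PruneReport(table, threshold, keep_fraction)


# ---------------------------------------------------------------------------
# denoising slot
# ---------------------------------------------------------------------------

def _denoise_none(data: np.ndarray) -> np.ndarray:
    return data.copy()


def _denoise_gaussian(data: np.ndarray, sigma: float = 0.8) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    return np.stack([gaussian_filter(f, sigma) for f in data])


def _denoise_median(data: np.ndarray, size: int = 3) -> np.ndarray:
    from scipy.ndimage import median_filter

    return np.stack([median_filter(f, size=size) for f in data])


_DENOISERS: dict[str, Callable[..., np.ndarray]] = {
    "none": _denoise_none,
    "gaussian": _denoise_gaussian,
    "median": _denoise_median,
}


def register_denoiser(name: str, fn: Callable[..., np.ndarray]) -> None:
    """Plug in an external denoiser: ``fn(stack_array, **kwargs) -> array``
    of identical shape."""
    _DENOISERS[name] = fn


def available_denoisers() -> list[str]:
    return sorted(_DENOISERS)


def denoise(stack: FOVStack, method: str = "none", **kwargs) -> FOVStack:
    """Apply the named denoiser to every FOV ("none" is the identity)."""
    if method not in _DENOISERS:
        raise ValueError(f"unknown denoiser {method!r}; "
                         f"available: {available_denoisers()}")
    out = _DENOISERS[method](stack.data, **kwargs)
    if np.shape(out) != stack.data.shape:
        raise ValueError(f"denoiser {method!r} changed the stack shape")
    return FOVStack(out, stack.fov_ids, {**stack.meta, "denoise": method})
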