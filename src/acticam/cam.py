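"""Class activation mapping over the GAP + linear classifier head.

With ``S_k(x)`` the last-conv activation of channel ``k`` at position ``x``
and ``w_k`` the classifier weight of channel ``k``, the class score is the
pooled weighted sum ``g = sum_k w_k f_k`` (with ``f_k`` the positional mean
of ``S_k``) and the activation map is ``M(x) = sum_k w_k S_k(x)``: the
per-position contribution of the input to the class evidence.  For the
single-logit binary head the positive class uses ``w`` and the negative
class ``-w`` (a softmax over {z, 0} reduces to exactly this sign flip).

Exemplars for visual inspection are the correctly classified windows with
the five highest and five lowest absolute raw logits per predicted class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .models import FeatureMap, Model
from .prep import LabelledWindow

logger = logging.getLogger(__name__)


@dataclass
class CAMResult:
    M: np.ndarray  # per-position map over the last-conv length T
    upsampled: np.ndarray  # per-sample map over the window length L
    logit: float
    predicted_class: int
    confidence: float  # sigmoid(|logit|)
    window: LabelledWindow | None = None


@dataclass
class ExemplarSet:
    """Per predicted class: the most and least confident correct windows."""

    highest: dict[int, list[CAMResult]]
    lowest: dict[int, list[CAMResult]]


def class_score(fmap: FeatureMap, weights: np.ndarray) -> float:
    """g = sum_k w_k f_k; equals the model logit minus the head bias."""
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (fmap.S.shape[0],):
        raise ValueError(f"weight length {weights.shape} does not match {fmap.S.shape[0]} channels")
    return float(weights @ fmap.f)


def compute_cam(fmap: FeatureMap, weights: np.ndarray) -> np.ndarray:
    """M(x) = sum_k w_k S_k(x); linear in both the activations and the weights."""
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (fmap.S.shape[0],):
        raise ValueError(f"weight length {weights.shape} does not match {fmap.S.shape[0]} channels")
    return weights @ fmap.S.astype(np.float64)


def upsample_cam(m: np.ndarray, length: int, mode: str = "linear") -> np.ndarray:
    """Stretch a length-T map onto ``length`` uniformly spaced sample positions.

    Linear interpolation preserves the endpoints; ``mode="nearest"`` snaps to
    the closest map position instead.
    """
    m = np.asarray(m, dtype=np.float64)
    if length < 1:
        raise ValueError("target length must be >= 1")
    t = m.shape[0]
    if t == 1:
        return np.full(length, m[0])
    src = np.linspace(0.0, t - 1.0, length)
    if mode == "nearest":
        return m[np.round(src).astype(int)]
    return np.interp(src, np.arange(t), m)


def cam_for_window(model: Model, window: LabelledWindow, threshold: float = 0.5, mode: str = "linear") -> CAMResult:
    """Compute the CAM of a window for its *predicted* class."""
    logit, fmap, w, _bias = model.forward_with_features(window.values.astype(np.float32))
    prob = 1.0 / (1.0 + np.exp(-logit))
    predicted = int(prob >= threshold)
    class_w = w if predicted == 1 else -w
    m = compute_cam(fmap, class_w)
    return CAMResult(
        M=m,
        upsampled=upsample_cam(m, window.values.shape[1], mode=mode),
        logit=logit,
        predicted_class=predicted,
        confidence=float(1.0 / (1.0 + np.exp(-abs(logit)))),
        window=window,
    )


def rank_by_logit(windows: list[LabelledWindow], logits: np.ndarray) -> list[int]:
    """Indices ordered by descending |logit|; ties broken by (drive, offset)."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    keys = sorted(
        range(len(windows)),
        key=lambda i: (-abs(logits[i]), windows[i].drive_id, windows[i].start_index),
    )
    return keys


def select_exemplars(
    model: Model,
    windows: list[LabelledWindow],
    logits: np.ndarray,
    n: int = 5,
    threshold: float = 0.5,
) -> ExemplarSet:
    """Top-n and bottom-n |logit| correctly classified windows per predicted class."""
    probs = 1.0 / (1.0 + np.exp(-np.asarray(logits, dtype=np.float64)))
    preds = (probs >= threshold).astype(int)
    highest: dict[int, list[CAMResult]] = {}
    lowest: dict[int, list[CAMResult]] = {}
    for cls in (0, 1):
        idx = [i for i in range(len(windows)) if preds[i] == cls and windows[i].label == cls]
        sub_windows = [windows[i] for i in idx]
        order = rank_by_logit(sub_windows, np.asarray(logits)[idx])
        if len(order) < 2 * n:
            warnings.warn(
                f"class {cls}: only {len(order)} correctly classified windows; "
                f"highest/lowest exemplar sets may overlap",
                stacklevel=2,
            )
        top = order[:n]
        bottom = [i for i in reversed(order[-n:])]
        highest[cls] = [cam_for_window(model, sub_windows[i], threshold) for i in top]
        lowest[cls] = [cam_for_window(model, sub_windows[i], threshold) for i in bottom]
    return ExemplarSet(highest=highest, lowest=lowest)


def panel_ylim(channel_values: np.ndarray) -> tuple[float, float]:
    """Vertical range of one plot panel: channel mean +- 0.5 g (constant 1-g scale)."""
    mean = float(np.mean(channel_values))
    return mean - 0.5, mean + 0.5


def render_cam_plot(window: LabelledWindow, cam: CAMResult, path, sample_rate: float = 20.0) -> None:
    """Three stacked panels (x, y, z), line colour encoding the CAM value.

    Each panel's vertical range is the channel mean +- 0.5 g, giving a
    constant 1-g scale.  The CAM is min-max normalized per window before
    colour mapping; a constant map renders at the colour-scale midpoint.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    values = window.values
    m = cam.upsampled
    span = m.max() - m.min()
    colours = (m - m.min()) / span if span > 0 else np.full_like(m, 0.5)

    t = np.arange(values.shape[1]) / sample_rate
    fig, axes = plt.subplots(3, 1, figsize=(9, 6), sharex=True)
    for ch, (ax, name) in enumerate(zip(axes, ("x", "y", "z"))):
        points = np.stack([t, values[ch]], axis=1)[:, None, :]
        segments = np.concatenate([points[:-1], points[1:]], axis=1)
        lc = LineCollection(segments, cmap="jet", norm=plt.Normalize(0.0, 1.0))
        lc.set_array(0.5 * (colours[:-1] + colours[1:]))
        lc.set_linewidth(1.0)
        ax.add_collection(lc)
        ax.set_xlim(t[0], t[-1])
        ax.set_ylim(*panel_ylim(values[ch]))
        ax.set_ylabel(f"{name} (g)")
    axes[-1].set_xlabel("time (s)")
    cbar = fig.colorbar(lc, ax=axes, fraction=0.03, pad=0.02)
    cbar.set_label("strength of prediction")
    fig.suptitle(f"class {cam.predicted_class}, logit {cam.logit:+.2f}")
    fig.savefig(path, dpi=120)
    plt.close(fig)
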