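"""Interpretable outputs: RSS vectors, bar-charts and Perceptual Relevance Maps.

For every prediction the ensemble exposes three artifacts:

1. the class prediction itself;
2. one Relative Similarity Score (RSS) per perceptual feature map — the
   univariate sub-network outputs in [-1, 1] whose signed sum (plus the
   intercept) *is* the pre-link decision score, rendered as red/green
   horizontal bars;
3. one Perceptual Relevance Map (PRM) per sub-network, locating the image
   regions that drive its RSS. A PRM is built from the feature maps of a
   mid-depth convolutional layer: maps are scored by Shannon entropy, the
   most informative half is averaged, and the average is refined by a
   maximum-entropy (Kapur) threshold that separates salient foreground from
   background, then up-sampled to the input size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .model import EPUModel

__all__ = [
    "RSSVector",
    "PRM",
    "GlobalChart",
    "ExplainResult",
    "shannon_entropy",
    "entropic_threshold",
    "compute_prm",
    "explain",
    "global_chart",
    "render_bar_chart",
    "render_prm_overlay",
    "render_global_chart",
]

DEFAULT_ENTROPY_BINS = 64
DEFAULT_PRM_LAYER = 5  # mid-depth convolutional layer (ablation winner)


class DegenerateMapError(ValueError):
    """Raised when a constant map admits no foreground/background split."""


@dataclass
class RSSVector:
    """The N univariate sub-network outputs explaining one prediction.

    Binary sign convention: positive RSS pulls toward class 1, negative
    toward class 0. Multiclass values are each sub-network's squashed score
    margin toward the predicted class (tanh of predicted-class score minus
    the best other class).
    """

    values: np.ndarray
    pfm_names: tuple[str, ...]
    predicted_class: int
    class_convention: str = "binary: sign>0 -> class 1, sign<0 -> class 0"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.pfm_names),):
            raise ValueError("one RSS value per PFM name required")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("RSS values must lie in [-1, 1]")

    def as_dict(self) -> dict:
        return {n: float(v) for n, v in zip(self.pfm_names, self.values)}


@dataclass
class PRM:
    """Per-sub-network relevance map aligned to the input image."""

    map: np.ndarray          # H x W nonnegative relevance (sub-threshold zeroed)
    mask: np.ndarray         # H x W boolean, map >= threshold
    threshold: float
    source_layer: int
    pfm_name: str


@dataclass
class GlobalChart:
    """Per-class mean and spread of each RSS component over a labeled set."""

    per_class_mean: dict
    per_class_std: dict
    n_per_class: dict
    pfm_names: tuple[str, ...]

    def to_records(self):
        rows = []
        for cls in sorted(self.per_class_mean):
            for j, name in enumerate(self.pfm_names):
                rows.append({
                    "class": cls, "pfm": name,
                    "mean": self.per_class_mean[cls][j],
                    "std": self.per_class_std[cls][j],
                    "n": self.n_per_class[cls],
                })
        return rows


@dataclass
class ExplainResult:
    prediction: float | np.ndarray
    predicted_class: int
    rss: RSSVector
    prms: list = field(default_factory=list)

    def to_json(self, label=None, prm_paths=None) -> str:
        rec = {
            "prediction": (
                float(self.prediction) if np.ndim(self.prediction) == 0
                else [float(v) for v in np.atleast_1d(self.prediction)]
            ),
            "predicted_class": int(self.predicted_class),
            "label": label,
            "rss": self.rss.as_dict(),
            "prm_paths": prm_paths or [],
        }
        return json.dumps(rec, indent=2)


def shannon_entropy(feature_map: np.ndarray, bins: int = DEFAULT_ENTROPY_BINS) -> float:
    """Shannon entropy (bits) of the normalized intensity histogram.

    Histogram spans the map's own min-max range; a constant map carries no
    information and returns 0. Bounded by log2(bins).
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    m = np.asarray(feature_map, dtype=np.float64).ravel()
    if not np.all(np.isfinite(m)):
        raise ValueError("feature map contains non-finite values")
    lo, hi = m.min(), m.max()
    if hi - lo == 0.0:
        return 0.0
    counts, _ = np.histogram(m, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / m.size
    return float(-(p * np.log2(p)).sum())


def entropic_threshold(m: np.ndarray, bins: int = 256) -> float:
    """Maximum-entropy (Kapur) threshold of a nonnegative map.

    Finds the gray level t* maximizing psi(t) = H_background(t) +
    H_foreground(t) over the map's histogram — the split with maximum
    information transfer between the two populations. Returns the threshold
    *value* (upper edge of the background's last bin), so ``m >= t*`` is the
    foreground mask.
    """
    m = np.asarray(m, dtype=np.float64).ravel()
    lo, hi = m.min(), m.max()
    if hi - lo == 0.0:
        raise DegenerateMapError("constant map has no foreground/background split")
    counts, edges = np.histogram(m, bins=bins, range=(lo, hi))
    p = counts / counts.sum()
    cum = np.cumsum(p)
    plogp = np.zeros_like(p)
    nz = p > 0
    plogp[nz] = p[nz] * np.log(p[nz])
    cum_plogp = np.cumsum(plogp)
    total_plogp = cum_plogp[-1]

    best_psi, best_t = -np.inf, 0
    for t in range(bins - 1):
        p0, p1 = cum[t], 1.0 - cum[t]
        if p0 <= 0 or p1 <= 0:
            continue
        h_bg = np.log(p0) - cum_plogp[t] / p0
        h_fg = np.log(p1) - (total_plogp - cum_plogp[t]) / p1
        psi = h_bg + h_fg
        if psi > best_psi:
            best_psi, best_t = psi, t
    return float(edges[best_t + 1])


def select_informative(fmaps: np.ndarray, bins: int = DEFAULT_ENTROPY_BINS):
    """Rank feature maps by Shannon entropy and keep the most informative
    half (ceil(n/2); ties break stably toward the lower map index).

    Returns ``(selected_indices, aggregate)`` where aggregate is the
    elementwise mean of the selected maps — the initial relevance estimate
    before thresholding. Discarded maps never influence the aggregate.
    """
    fmaps = np.asarray(fmaps)
    n = fmaps.shape[0]
    k = int(np.ceil(n / 2))
    entropies = np.array([shannon_entropy(fm, bins) for fm in fmaps])
    selected = np.sort(np.argsort(-entropies, kind="stable")[:k])
    return selected, fmaps[selected].mean(axis=0).astype(np.float64)


def compute_prm(model: EPUModel, stack, subnet_index: int,
                layer: int = DEFAULT_PRM_LAYER,
                bins: int = DEFAULT_ENTROPY_BINS,
                interpolation_order: int = 1) -> PRM:
    """Build the Perceptual Relevance Map of one sub-network.

    Pipeline: capture the n feature maps of convolutional layer ``layer``
    (1-based registry index); score each by Shannon entropy; keep the
    ceil(n/2) highest-entropy maps (stable tie-break: lower map index wins);
    average them; zero values below the maximum-entropy threshold; up-sample
    to the input image size. Deterministic given weights and input.
    """
    if not 0 <= subnet_index < model.n:
        raise ValueError(f"subnet_index {subnet_index} out of range (N={model.n})")
    sn = model.subnetworks[subnet_index]
    if not 1 <= layer <= sn.n_conv_layers:
        raise ValueError(
            f"layer {layer} not in registry (1..{sn.n_conv_layers})"
        )
    stacks = model._check_stack(stack)
    if stacks.shape[0] != 1:
        raise ValueError("compute_prm explains a single image at a time")
    _, feats = sn.forward(stacks[:, subnet_index : subnet_index + 1],
                          capture_layers=[layer])
    fmaps = feats[layer][0]  # (n, h, w)
    _, s = select_informative(fmaps, bins)

    h, w = stacks.shape[2], stacks.shape[3]
    if np.ptp(s) == 0.0:
        # featureless layer output: empty relevance, no threshold applicable
        zero = np.zeros((h, w))
        return PRM(map=zero, mask=zero.astype(bool), threshold=float("nan"),
                   source_layer=layer, pfm_name=model.pfm_names[subnet_index])
    thr = entropic_threshold(s)
    refined = np.where(s >= thr, s, 0.0)
    up_map = resize(refined, (h, w), order=interpolation_order, mode="edge",
                    anti_aliasing=False, preserve_range=True)
    up_mask = resize((s >= thr).astype(float), (h, w), order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True) >= 0.5
    return PRM(map=up_map, mask=up_mask, threshold=thr, source_layer=layer,
               pfm_name=model.pfm_names[subnet_index])


def explain(model: EPUModel, stack, layer: int = DEFAULT_PRM_LAYER,
            with_prms: bool = True) -> ExplainResult:
    """Bundle the three interpretable outputs for one image: prediction,
    RSS vector, and one PRM per sub-network."""
    import warnings

    if not model.trained:
        warnings.warn("explaining an untrained model; outputs reflect the "
                      "random initialization", stacklevel=2)
    p, rss = model.forward(stack)
    if model.link == "sigmoid":
        prediction = float(p[0])
        predicted_class = int(prediction >= 0.5)
        values = rss[0]
        convention = "binary: sign>0 -> class 1, sign<0 -> class 0"
    else:
        prediction = p[0]
        predicted_class = int(np.argmax(p[0]))
        scores = rss[0]  # (N, n_classes)
        others = np.delete(scores, predicted_class, axis=1).max(axis=1)
        values = np.tanh(scores[:, predicted_class] - others)
        convention = ("multiclass: tanh margin of predicted-class score over "
                      "best other class")
    rss_vec = RSSVector(values=values, pfm_names=model.pfm_names,
                        predicted_class=predicted_class,
                        class_convention=convention)
    prms = (
        [compute_prm(model, stack, i, layer) for i in range(model.n)]
        if with_prms else []
    )
    return ExplainResult(prediction=prediction, predicted_class=predicted_class,
                         rss=rss_vec, prms=prms)


def global_chart(model: EPUModel, stacks, labels) -> GlobalChart:
    """Average the RSSs per class over a labeled set (mean and standard
    deviation of each component)."""
    stacks = np.asarray(stacks, dtype=np.float32)
    labels = np.asarray(labels)
    if stacks.shape[0] != labels.shape[0]:
        raise ValueError("one label per stack required")
    classes = np.unique(labels)
    if classes.size < 1:
        raise ValueError("empty dataset")
    _, rss = model.forward(stacks)
    if rss.ndim == 3:  # multiclass: use margin toward the true class
        rss = rss.max(axis=2)
    mean, std, counts = {}, {}, {}
    for cls in classes:
        sel = rss[labels == cls]
        if sel.shape[0] == 0:
            raise ValueError(f"no samples for class {cls}")
        mean[int(cls)] = sel.mean(axis=0)
        std[int(cls)] = sel.std(axis=0)
        counts[int(cls)] = int(sel.shape[0])
    return GlobalChart(per_class_mean=mean, per_class_std=std,
                       n_per_class=counts, pfm_names=model.pfm_names)


# -- rendering -------------------------------------------------------------

def render_bar_chart(rss: RSSVector, path, class_names=("class 0", "class 1")) -> None:
    """Horizontal signed bars, red toward class 0 and green toward class 1."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = rss.values
    colors = ["#2e9e4f" if v >= 0 else "#c23b22" for v in vals]
    fig, ax = plt.subplots(figsize=(4, 2.4))
    ypos = np.arange(len(vals))[::-1]
    ax.barh(ypos, vals, color=colors)
    ax.set_yticks(ypos, rss.pfm_names)
    ax.set_xlim(-1, 1)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel(f"RSS  ({class_names[0]} < 0 < {class_names[1]})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_prm_overlay(image: np.ndarray, prm: PRM, path, alpha: float = 0.55) -> None:
    """Overlay the PRM on the image with an orange-to-yellow colormap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(image)
    overlay = np.ma.masked_where(~prm.mask, prm.map)
    ax.imshow(overlay, cmap="autumn", alpha=alpha)
    ax.set_title(prm.pfm_name, fontsize=9)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_global_chart(chart: GlobalChart, png_path=None, csv_path=None) -> None:
    """Global per-class RSS bar-chart (mean +/- std) as PNG and/or CSV."""
    if csv_path is not None:
        import pandas as pd

        pd.DataFrame(chart.to_records()).to_csv(csv_path, index=False)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        classes = sorted(chart.per_class_mean)
        x = np.arange(len(chart.pfm_names))
        width = 0.8 / len(classes)
        fig, ax = plt.subplots(figsize=(5, 3))
        for j, cls in enumerate(classes):
            ax.bar(x + j * width, chart.per_class_mean[cls], width,
                   yerr=chart.per_class_std[cls], capsize=3,
                   label=f"class {cls}")
        ax.set_xticks(x + width * (len(classes) - 1) / 2, chart.pfm_names)
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("mean RSS")
        ax.legend()
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
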