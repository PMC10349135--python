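"""Quantitative interpretability metrics.

Two metrics are provided:

* **Interpretability accuracy** — on a task where every perceptual cue
  points the same way (e.g. both color and shape separate the classes), a
  correct explanation should have all RSS signs agreeing with the class
  label. The ground-truth interpretability label is (+1, ..., +1) for class
  1 and (-1, ..., -1) for class 0; the predicted label is the elementwise
  sign of the RSS vector; accuracy is the average Jaccard agreement between
  the two over a labeled set, in percent.

* **ROAD (Remove and Debias)** — a faithfulness score for saliency maps.
  Two perturbed copies of the image are built: R_low removes (imputes) the
  least-salient fraction of pixels, isolating that low-importance
  information away, and R_high removes the most-salient fraction; imputation
  is noisy linear interpolation from the retained neighbors. With f(.) the
  model confidence for the originally predicted class,
  cc_low = f(R_low) - f(I) and cc_high = f(R_high) - f(I); the score is
  (cc_low - cc_high) / 2. For a faithful map, removing unimportant pixels
  barely changes the confidence while removing the salient ones collapses
  it (cc_high << cc_low <= 0), so higher scores mean more accurate
  interpretations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

from .pfm import PFMConfig, extract_pfms

__all__ = [
    "InterpLabel",
    "ROADRecord",
    "interp_ground_truth",
    "interp_predicted",
    "interpretability_accuracy",
    "road_perturb",
    "road_score",
    "road_score_explanation",
]


@dataclass
class InterpLabel:
    """N-dimensional sign vector used by the interpretability-accuracy metric."""

    signs: np.ndarray
    source: str  # 'ground_truth' | 'predicted'

    def __post_init__(self):
        self.signs = np.asarray(self.signs, dtype=np.int8)
        if not np.all(np.isin(self.signs, (-1, 1))):
            raise ValueError("interpretability labels contain only -1 / +1")


@dataclass
class ROADRecord:
    f_original: float
    f_low: float
    f_high: float

    @property
    def cc_low(self) -> float:
        return self.f_low - self.f_original

    @property
    def cc_high(self) -> float:
        return self.f_high - self.f_original

    @property
    def score(self) -> float:
        return (self.cc_low - self.cc_high) / 2.0


def interp_ground_truth(y: int, n: int) -> InterpLabel:
    """All-plus-ones vector for class y=1, all-minus-ones for y=0."""
    if y not in (0, 1):
        raise ValueError(f"binary class label expected, got {y!r}")
    sign = 1 if y == 1 else -1
    return InterpLabel(signs=np.full(n, sign, dtype=np.int8), source="ground_truth")


def interp_predicted(rss) -> InterpLabel:
    """Elementwise sign of the RSS vector; sign(0) -> +1 by convention."""
    values = np.asarray(getattr(rss, "values", rss), dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("RSS values must be finite")
    return InterpLabel(signs=np.where(values >= 0, 1, -1).astype(np.int8),
                       source="predicted")


def _jaccard(a: np.ndarray, b: np.ndarray, variant: str) -> float:
    agree = int(np.sum(a == b))
    n = a.size
    if variant == "agreement":
        return agree / n
    if variant == "signed_multiset":
        # sets of (position, sign) pairs: |intersection| = agreements,
        # |union| = 2N - agreements
        return agree / (2 * n - agree)
    raise ValueError(f"unknown Jaccard variant {variant!r}")


def interpretability_accuracy(pairs, variant: str = "agreement") -> float:
    """Average Jaccard agreement between ground-truth and predicted sign
    vectors, in percent (0-100).

    ``pairs`` is a sequence of (InterpLabel, InterpLabel) or raw sign-vector
    tuples. The default ``agreement`` variant counts the fraction of
    components with matching sign; ``signed_multiset`` treats each vector as
    the set of its (position, sign) pairs.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("pairs must be nonempty")
    scores = []
    for gt, pred in pairs:
        a = np.asarray(getattr(gt, "signs", gt))
        b = np.asarray(getattr(pred, "signs", pred))
        if a.shape != b.shape:
            raise ValueError(f"label length mismatch: {a.shape} vs {b.shape}")
        scores.append(_jaccard(a, b, variant))
    return float(np.mean(scores)) * 100.0


def _impute_linear(channel: np.ndarray, retained: np.ndarray,
                   rng: np.random.Generator, noise: float) -> np.ndarray:
    """Fill non-retained pixels so each equals the mean of its 4-neighbors
    (a discrete Laplace system with retained pixels as boundary values),
    plus a small Gaussian debiasing noise."""
    h, w = channel.shape
    imputed = ~retained
    if not imputed.any():
        return channel.copy()
    idx = -np.ones((h, w), dtype=np.int64)
    ys, xs = np.nonzero(imputed)
    idx[ys, xs] = np.arange(ys.size)
    mean_retained = float(channel[retained].mean()) if retained.any() else 0.5

    rows, cols, vals = [], [], []
    rhs = np.zeros(ys.size)
    eps = 1e-6  # anchors components with no retained neighbors
    for p, (y, x) in enumerate(zip(ys, xs)):
        deg = 0
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ny, nx = y + dy, x + dx
            if not (0 <= ny < h and 0 <= nx < w):
                continue
            deg += 1
            if imputed[ny, nx]:
                rows.append(p)
                cols.append(idx[ny, nx])
                vals.append(-1.0)
            else:
                rhs[p] += channel[ny, nx]
        rows.append(p)
        cols.append(p)
        vals.append(deg + eps)
        rhs[p] += eps * mean_retained
    a = csr_matrix((vals, (rows, cols)), shape=(ys.size, ys.size))
    x = spsolve(a, rhs)
    out = channel.astype(np.float64).copy()
    out[ys, xs] = x + rng.normal(0.0, noise, size=ys.size)
    return np.clip(out, 0.0, 1.0)


def road_perturb(image: np.ndarray, saliency: np.ndarray, fraction: float,
                 seed: int = 0, noise: float = 0.01, mode: str = "linear"):
    """Build the (R_low, R_high) perturbed image pair.

    R_low imputes the bottom ``fraction`` least-salient pixels (retaining
    the rest); R_high imputes the top ``fraction`` most-salient pixels. As
    fraction -> 0 both approach the original image. Ranking ties break by
    pixel index (stable sort). ``mode='linear'`` solves the noisy 4-neighbor
    interpolation system; ``mode='mean'`` fills with the retained mean.
    Returns images in the dtype of the input.
    """
    sal = np.asarray(getattr(saliency, "map", saliency), dtype=np.float64)
    img = np.asarray(image)
    if sal.shape != img.shape[:2]:
        raise ValueError(f"saliency {sal.shape} not aligned to image {img.shape[:2]}")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly in (0, 1)")
    if np.ptp(sal) == 0.0:
        raise ValueError("constant saliency map cannot rank pixels")

    was_int = np.issubdtype(img.dtype, np.integer)
    chans = (img.astype(np.float64) / 255.0) if was_int else img.astype(np.float64)
    if chans.ndim == 2:
        chans = chans[..., None]

    order = np.argsort(sal.ravel(), kind="stable")
    k = int(round(fraction * sal.size))
    retained_low = np.ones(sal.size, dtype=bool)
    retained_low[order[:k]] = False  # remove the k least salient
    retained_high = np.ones(sal.size, dtype=bool)
    retained_high[order[sal.size - k :]] = False  # remove the k most salient
    retained_low = retained_low.reshape(sal.shape)
    retained_high = retained_high.reshape(sal.shape)

    results = []
    for which, retained in (("low", retained_low), ("high", retained_high)):
        rng = np.random.default_rng(seed if which == "low" else seed + 1)
        out = np.empty_like(chans)
        for c in range(chans.shape[-1]):
            if mode == "linear":
                out[..., c] = _impute_linear(chans[..., c], retained, rng, noise)
            elif mode == "mean":
                fill = chans[..., c][retained].mean()
                ch = chans[..., c].copy()
                ch[~retained] = np.clip(
                    fill + rng.normal(0, noise, int((~retained).sum())), 0, 1
                )
                out[..., c] = ch
            else:
                raise ValueError(f"unknown imputation mode {mode!r}")
        if img.ndim == 2:
            out = out[..., 0]
        results.append(
            np.clip(np.round(out * 255), 0, 255).astype(img.dtype) if was_int else out
        )
    return results[0], results[1]


def _confidence(model, image, pfm_config: PFMConfig, target_class=None):
    stack = extract_pfms(image, pfm_config)
    p = model.predict_proba(stack.maps[None])
    if model.link == "sigmoid":
        p1 = float(p[0])
        cls = int(p1 >= 0.5) if target_class is None else target_class
        return (p1 if cls == 1 else 1.0 - p1), cls
    cls = int(np.argmax(p[0])) if target_class is None else target_class
    return float(p[0][cls]), cls


def road_score(model, image, saliency, fraction: float = 0.2,
               pfm_config: PFMConfig | None = None, seed: int = 0,
               noise: float = 0.01, mode: str = "linear") -> ROADRecord:
    """ROAD faithfulness of one saliency map on one image.

    The confidence f(.) is taken for the class the model predicts on the
    *original* image, so a drop after removing salient pixels shows up as a
    negative cc_high and a positive score.
    """
    pfm_config = pfm_config or PFMConfig()
    f_orig, cls = _confidence(model, image, pfm_config)
    r_low, r_high = road_perturb(image, saliency, fraction, seed=seed,
                                 noise=noise, mode=mode)
    f_low, _ = _confidence(model, r_low, pfm_config, target_class=cls)
    f_high, _ = _confidence(model, r_high, pfm_config, target_class=cls)
    return ROADRecord(f_original=f_orig, f_low=f_low, f_high=f_high)


def road_score_explanation(model, image, prms, fraction: float = 0.2,
                           pfm_config: PFMConfig | None = None, seed: int = 0,
                           noise: float = 0.01, mode: str = "linear") -> float:
    """Per-prediction ROAD: the mean score over all PRMs of that prediction
    (degenerate all-constant PRMs are skipped)."""
    scores = []
    for prm in prms:
        sal = np.asarray(getattr(prm, "map", prm))
        if np.ptp(sal) == 0.0:
            continue
        scores.append(
            road_score(model, image, sal, fraction, pfm_config, seed, noise, mode).score
        )
    if not scores:
        raise ValueError("no usable (non-constant) saliency maps")
    return float(np.mean(scores))
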