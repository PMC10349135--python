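"""Opponent perceptual feature maps (PFMs).

An RGB image is decomposed into four maps, each exposing one humanly
perceivable opponent property:

* ``light_dark``  — the final-level approximation of a multilevel 2D discrete
  wavelet transform of the CIE-Lab lightness plane L (default: 3rd level),
  a smoothed luminance antagonism map;
* ``coarse_fine`` — the highest-frequency detail band of the 1st-level 2D DWT
  of L (default: the diagonal subband), an edge-density / texture map;
* ``blue_yellow`` — the CIE-Lab ``b`` plane (b > 0 yellowness, b < 0 blueness);
* ``green_red``   — the CIE-Lab ``a`` plane (a > 0 redness, a < 0 greenness).

Wavelet maps are computed with decimated multilevel DWT (dyadic halving per
level) and up-sampled back to the input size so every map is H x W. The four
maps, in this fixed order, form the N x H x W input tensor of the ensemble.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pywt
from skimage import color
from skimage.transform import resize

__all__ = [
    "DEFAULT_PFM_NAMES",
    "LabPlanes",
    "PFMConfig",
    "PFMStack",
    "rgb_to_lab",
    "lab_to_rgb",
    "dwt2_multilevel",
    "extract_pfms",
    "extract_stacks",
]

DEFAULT_PFM_NAMES = ("light_dark", "coarse_fine", "blue_yellow", "green_red")

_INTERP_ORDER = {"nearest": 0, "bilinear": 1, "bicubic": 3}


@dataclass
class LabPlanes:
    """The three CIE-Lab planes of an image (D65/sRGB)."""

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray


@dataclass
class PFMConfig:
    """Settings for PFM extraction.

    wavelet: PyWavelets family name; Haar (db1) is the default quadrature
        mirror filter pair.
    approximation_level: DWT depth for the light_dark map (default 3).
    detail_level: DWT depth whose finest band gives coarse_fine (default 1).
    detail_band: 'diagonal' | 'horizontal' | 'vertical' | 'sum'
        ('sum' = |H|+|V|+|D| of the finest level).
    interpolation: up-sampling scheme for the wavelet maps.
    mode: DWT signal-extension mode; 'periodization' keeps exact dyadic
        halving for even sizes.
    drop_constant_pfms: drop chroma maps when the image is achromatic.
    """

    wavelet: str = "haar"
    approximation_level: int = 3
    detail_level: int = 1
    detail_band: str = "diagonal"
    interpolation: str = "bilinear"
    mode: str = "periodization"
    drop_constant_pfms: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PFMConfig":
        return cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})


@dataclass
class PFMStack:
    """N x H x W stack of perceptual feature maps for one image."""

    maps: np.ndarray
    names: tuple[str, ...]
    normalization: dict = field(default_factory=dict)

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=np.float32)
        self.names = tuple(self.names)
        if self.maps.ndim != 3:
            raise ValueError("maps must be a 3-D (N, H, W) array")
        if self.maps.shape[0] != len(self.names):
            raise ValueError("number of maps must equal number of names")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("PFM stack contains non-finite values")

    @property
    def n(self) -> int:
        return self.maps.shape[0]

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path, maps=self.maps, names=np.array(self.names), **{
                f"norm_{k}": np.array(str(v)) for k, v in self.normalization.items()
            }
        )

    def save_tiff(self, path) -> None:
        """Multi-page 32-bit float TIFF, one page per map, for inspection."""
        import tifffile

        tifffile.imwrite(path, self.maps.astype(np.float32))


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {image.shape}")
    if image.shape[0] < 8 or image.shape[1] < 8:
        raise ValueError("image must be at least 8 x 8 for three dyadic decomposition levels")
    if np.issubdtype(image.dtype, np.integer):
        image = image.astype(np.float64) / 255.0
    else:
        image = image.astype(np.float64)
        if image.min() < -1e-9 or image.max() > 1 + 1e-9:
            raise ValueError("float RGB images must lie in [0, 1]")
    return np.clip(image, 0.0, 1.0)


def rgb_to_lab(image: np.ndarray) -> LabPlanes:
    """sRGB -> CIE-Lab under the D65 illuminant (deterministic)."""
    rgb = _validate_rgb(image)
    lab = color.rgb2lab(rgb)
    return LabPlanes(L=lab[..., 0], a=lab[..., 1], b=lab[..., 2])


def lab_to_rgb(planes: LabPlanes) -> np.ndarray:
    """Inverse conversion; returns float RGB in [0, 1]."""
    lab = np.stack([planes.L, planes.a, planes.b], axis=-1)
    return color.lab2rgb(lab)


def dwt2_multilevel(plane: np.ndarray, levels: int, wavelet: str = "haar",
                    mode: str = "periodization") -> dict:
    """Decimated multilevel 2D DWT of one plane.

    Returns ``{"approximation": cA_levels, "details": [lvl1, ..., lvlN]}``
    where each per-level entry is ``{"horizontal", "vertical", "diagonal"}``
    and level 1 is the finest (highest-frequency) scale. Each level halves
    the spatial resolution (dyadic down-sampling).
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError("plane must be 2-D")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if 2 ** levels > min(plane.shape):
        raise ValueError(
            f"{levels} dyadic levels need min(H, W) >= {2 ** levels}, got {min(plane.shape)}"
        )
    coeffs = pywt.wavedec2(plane, wavelet, mode=mode, level=levels)
    approximation = coeffs[0]
    details = []
    # wavedec2 orders detail tuples coarsest-first; re-index finest-first
    for ch, cv, cd in reversed(coeffs[1:]):
        details.append({"horizontal": ch, "vertical": cv, "diagonal": cd})
    return {"approximation": approximation, "details": details}


def _upsample(m: np.ndarray, shape: tuple[int, int], interpolation: str) -> np.ndarray:
    if m.shape == shape:
        return m
    return resize(
        m, shape, order=_INTERP_ORDER[interpolation], mode="edge",
        anti_aliasing=False, preserve_range=True,
    )


def _minmax01(m: np.ndarray) -> tuple[np.ndarray, str]:
    lo, hi = float(m.min()), float(m.max())
    if hi - lo < 1e-12:
        return np.zeros_like(m), f"minmax[{lo:.4g},{hi:.4g}]->const0"
    return (m - lo) / (hi - lo), f"minmax[{lo:.4g},{hi:.4g}]"


def _maxabs(m: np.ndarray) -> tuple[np.ndarray, str]:
    s = float(np.abs(m).max())
    if s < 1e-12:
        return np.zeros_like(m), "maxabs->const0"
    return m / s, f"maxabs[{s:.4g}]"


def extract_pfms(image: np.ndarray, config: PFMConfig | None = None) -> PFMStack:
    """Decompose an RGB image into its opponent perceptual feature maps.

    Deterministic: identical inputs give byte-identical stacks. The maps are
    normalized per the recorded scheme — light_dark min-max to [0, 1] per
    image, coarse_fine by its maximum absolute value to a zero-centred
    [-1, 1], chroma by the fixed global affine (x + 128) / 255.
    """
    config = config or PFMConfig()
    lab = rgb_to_lab(image)
    h, w = lab.L.shape
    if 2 ** config.approximation_level > min(h, w):
        raise ValueError(
            f"image {h}x{w} too small for {config.approximation_level} decomposition levels"
        )

    approx = dwt2_multilevel(
        lab.L, config.approximation_level, config.wavelet, config.mode
    )["approximation"]
    finest = dwt2_multilevel(
        lab.L, config.detail_level, config.wavelet, config.mode
    )["details"][0]
    if config.detail_band == "sum":
        detail = sum(np.abs(finest[k]) for k in ("horizontal", "vertical", "diagonal"))
    elif config.detail_band in finest:
        detail = finest[config.detail_band]
    else:
        raise ValueError(f"unknown detail_band {config.detail_band!r}")

    light, norm_light = _minmax01(_upsample(approx, (h, w), config.interpolation))
    coarse, norm_coarse = _maxabs(_upsample(detail, (h, w), config.interpolation))
    blue_yellow = (lab.b + 128.0) / 255.0
    green_red = (lab.a + 128.0) / 255.0

    maps = [light, coarse, blue_yellow, green_red]
    names = list(DEFAULT_PFM_NAMES)
    normalization = {
        "light_dark": norm_light,
        "coarse_fine": norm_coarse,
        "blue_yellow": "(b+128)/255",
        "green_red": "(a+128)/255",
    }

    if config.drop_constant_pfms:
        keep = [
            i for i, m in enumerate(maps)
            # chroma of an achromatic image is constant up to conversion
            # round-off (~1e-5 on the normalized scale)
            if not (names[i] in ("blue_yellow", "green_red") and np.ptp(m) < 1e-3)
        ]
        maps = [maps[i] for i in keep]
        dropped = [names[i] for i in range(4) if i not in keep]
        names = [names[i] for i in keep]
        for d in dropped:
            normalization[d] = "dropped(constant)"

    stack = np.stack(maps).astype(np.float32)
    return PFMStack(maps=stack, names=tuple(names), normalization=normalization)


def extract_stacks(images, config: PFMConfig | None = None) -> np.ndarray:
    """Vectorize extraction over a list of images -> (B, N, H, W) float32."""
    stacks = [extract_pfms(img, config).maps for img in images]
    return np.stack(stacks)
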