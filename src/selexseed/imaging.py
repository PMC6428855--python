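"""Planar fluorescence-reflectance imaging (FRI) ratio quantification.

Semi-quantitative tumour-targeting readout: subtract the camera's intrinsic
background, normalise images to a common exposure time, subtract the
animal's pre-injection autofluorescence via the same ROI on the t0 image,
and report the ratio of mean tumour fluorescence to a healthy reference
zone (or muscle, for ex-vivo images). Group comparison uses an unpaired
t-test with a single pooled standard deviation across all groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats


@dataclass
class PlanarImage:
    """Exposure-stamped 2D intensity raster.

    ``timepoint_min`` is minutes post injection; 0 marks the pre-injection
    (autofluorescence) frame.
    """

    pixels: np.ndarray
    exposure_ms: float
    timepoint_min: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")
        if not self.exposure_ms > 0:
            raise ValueError(f"exposure_ms must be positive, got {self.exposure_ms}")

    @classmethod
    def from_tiff(cls, path: str | Path, exposure_ms: float, timepoint_min: float = 0.0):
        import tifffile

        return cls(tifffile.imread(path), exposure_ms, timepoint_min)


@dataclass
class ROIMask:
    """Named boolean pixel mask (tumour / healthy / muscle / custom)."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.name!r} has no pixels")


def normalize_image(
    img: PlanarImage,
    camera_background: float | np.ndarray,
    reference_exposure_ms: float,
) -> PlanarImage:
    """Background-subtract (clipping at 0) and rescale to a common exposure.

    ``camera_background`` may be a scalar dark level or a per-pixel dark
    frame of the same shape.
    """
    if reference_exposure_ms <= 0:
        raise ValueError("reference exposure must be positive")
    background = np.asarray(camera_background, dtype=float)
    if background.ndim not in (0, 2):
        raise ValueError("camera_background must be a scalar or a 2D grid")
    if background.ndim == 2 and background.shape != img.pixels.shape:
        raise ValueError("background frame shape does not match the image")
    pixels = np.maximum(img.pixels - background, 0.0) * (reference_exposure_ms / img.exposure_ms)
    return PlanarImage(pixels, reference_exposure_ms, img.timepoint_min)


def roi_mean(img: PlanarImage, mask: ROIMask | np.ndarray) -> float:
    """Arithmetic mean intensity over the ROI's true pixels."""
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    if m.shape != img.pixels.shape:
        raise ValueError("mask shape does not match the image")
    if not m.any():
        raise ValueError("ROI mask is empty")
    return float(img.pixels[m].mean())


@dataclass
class RatioResult:
    tumour_mean: float
    reference_mean: float
    ratio: float | None  # None when the reference signal is non-positive
    timepoint_min: float
    degenerate: bool = False


def tumour_ratio(
    img_t: PlanarImage,
    img_t0: PlanarImage | None,
    tumour_mask: ROIMask | np.ndarray,
    reference_mask: ROIMask | np.ndarray,
    camera_background: float | np.ndarray = 0.0,
    reference_exposure_ms: float | None = None,
) -> RatioResult:
    """Tumour-over-reference mean fluorescence ratio at one timepoint.

    Both images are normalised to a common exposure, then the pre-injection
    (t0) ROI means are subtracted from the corresponding post-injection
    means — the autofluorescence correction, applied with the identical
    mask. Ex-vivo mode: pass ``img_t0=None`` and a muscle reference mask;
    no autofluorescence subtraction is applied. A non-positive reference
    mean yields a flagged degenerate result rather than a silent infinity.
    """
    ref_exp = reference_exposure_ms if reference_exposure_ms is not None else img_t.exposure_ms
    norm_t = normalize_image(img_t, camera_background, ref_exp)
    tumour_mean = roi_mean(norm_t, tumour_mask)
    reference_mean = roi_mean(norm_t, reference_mask)
    if img_t0 is not None:
        norm_t0 = normalize_image(img_t0, camera_background, ref_exp)
        tumour_mean -= roi_mean(norm_t0, tumour_mask)
        reference_mean -= roi_mean(norm_t0, reference_mask)
    if reference_mean <= 0:
        return RatioResult(tumour_mean, reference_mean, None, img_t.timepoint_min, degenerate=True)
    return RatioResult(
        tumour_mean, reference_mean, tumour_mean / reference_mean, img_t.timepoint_min
    )


@dataclass
class PairwiseTest:
    group_a: int
    group_b: int
    t: float
    p: float
    degenerate: bool = False


def pooled_sd_ttest(groups: list[np.ndarray] | list[list[float]]) -> list[PairwiseTest]:
    """Pairwise unpaired t-tests sharing one pooled SD across all groups.

    The pooled SD is the one-way-ANOVA residual SD,
    ``sqrt(sum_g sum_i (x_gi - mean_g)^2 / (N - k))``, and each pair is
    compared with ``t = (mean_a - mean_b) / (sd * sqrt(1/n_a + 1/n_b))`` on
    ``N - k`` degrees of freedom (Fisher's LSD). Zero pooled variance with
    unequal means is flagged degenerate with p = 0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValueError("need at least two groups with n >= 2 each")
    N = sum(len(g) for g in arrays)
    df = N - len(arrays)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in arrays)
    sd_pooled = np.sqrt(ss_within / df)
    results = []
    for a in range(len(arrays)):
        for b in range(a + 1, len(arrays)):
            diff = arrays[a].mean() - arrays[b].mean()
            se = sd_pooled * np.sqrt(1 / len(arrays[a]) + 1 / len(arrays[b]))
            if se == 0:
                if diff == 0:
                    results.append(PairwiseTest(a, b, 0.0, 1.0))
                else:
                    results.append(
                        PairwiseTest(a, b, np.inf if diff > 0 else -np.inf, 0.0, degenerate=True)
                    )
                continue
            t = float(diff / se)
            p = float(2 * stats.t.sf(abs(t), df))
            results.append(PairwiseTest(a, b, t, p))
    return results


def make_synthetic_fri(
    shape: tuple[int, int] = (128, 128),
    blobs: list[dict] | None = None,
    autofluorescence: float = 50.0,
    noise_sd: float = 0.0,
    exposure_ms: float = 1000.0,
    seed: int = 0,
) -> tuple[PlanarImage, PlanarImage, dict[str, ROIMask]]:
    """Build a (t0, t) synthetic image pair with tumour/healthy masks.

    Each blob spec is ``{"center": (row, col), "sigma": px, "amplitude": x,
    "name": roi-name}``; blobs are Gaussian bumps added on a flat
    autofluorescence background present in both frames, plus i.i.d.
    Gaussian noise. The ROI for each named blob is the disc within
    2 sigma of its centre.
    """
    rng = np.random.default_rng(seed)
    if blobs is None:
        blobs = [
            {"center": (40, 40), "sigma": 8.0, "amplitude": 300.0, "name": "tumour"},
            {"center": (88, 88), "sigma": 8.0, "amplitude": 100.0, "name": "healthy"},
        ]
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    base = np.full(shape, float(autofluorescence))
    signal = np.zeros(shape)
    masks: dict[str, ROIMask] = {}
    for blob in blobs:
        r0, c0 = blob["center"]
        sigma = float(blob["sigma"])
        dist2 = (rows - r0) ** 2 + (cols - c0) ** 2
        signal += blob["amplitude"] * np.exp(-dist2 / (2 * sigma**2))
        masks[blob["name"]] = ROIMask(blob["name"], dist2 <= (2 * sigma) ** 2)
    noise0 = rng.normal(0, noise_sd, shape) if noise_sd > 0 else 0.0
    noise1 = rng.normal(0, noise_sd, shape) if noise_sd > 0 else 0.0
    img_t0 = PlanarImage(np.maximum(base + noise0, 0), exposure_ms, timepoint_min=0.0)
    img_t = PlanarImage(np.maximum(base + signal + noise1, 0), exposure_ms, timepoint_min=180.0)
    return img_t0, img_t, masks
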