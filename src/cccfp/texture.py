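"""Second-order (grey-level co-occurrence) texture analysis.

Texture variables are computed from a grey-level co-occurrence matrix
(GLCM) accumulated over one-pixel horizontal and vertical offsets inside a
circular region of interest covering the whole plate (ROI 0-100 % of the
plate radius).  Fifteen second-order statistics are produced per
fingerprint; four of them carry the analysis weight:

* ``entropy`` — information content (randomness of the intensity
  distribution): complex fingerprints score higher;
* ``cluster_shade`` — skewness/asymmetry of the grey-level distribution;
* ``diagonal_moment`` — sign-carrying roughness measure: positive values
  mean the bright areas are rough and the dark areas smooth;
* ``kappa`` — chance-corrected diagonal agreement of the co-occurrence
  matrix, a consistency measure.

The remaining eleven are the standard Haralick-style set, giving the
correlation-filter stage a realistic candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthesis import FingerprintImage

DEFAULT_OFFSETS = ((0, 1), (1, 0))
DEFAULT_LEVELS = 32

TEXTURE_VARIABLES = (
    "entropy", "cluster_shade", "diagonal_moment", "kappa",
    "energy", "contrast", "correlation", "variance",
    "inverse_difference_moment", "sum_average", "sum_variance",
    "sum_entropy", "difference_variance", "difference_entropy",
    "cluster_prominence",
)


class TextureError(ValueError):
    pass


@dataclass(frozen=True)
class RegionOfInterest:
    """Annulus/disc in percent of the plate radius, measured from centre."""

    r_lo_pct: float = 0.0
    r_hi_pct: float = 100.0

    def __post_init__(self):
        if not 0 <= self.r_lo_pct < self.r_hi_pct <= 100:
            raise TextureError(
                f"ROI percentages must satisfy 0 <= lo < hi <= 100, "
                f"got ({self.r_lo_pct}, {self.r_hi_pct})"
            )


def roi_mask(image: FingerprintImage, roi: RegionOfInterest) -> np.ndarray:
    """Boolean mask: lo <= 100*dist/plate_radius < hi (<= hi at hi=100)."""
    rows, cols = image.pixels.shape
    yy, xx = np.ogrid[:rows, :cols]
    dist = np.sqrt((yy - image.centre[0]) ** 2.0 + (xx - image.centre[1]) ** 2.0)
    pct = 100.0 * dist / image.plate_radius
    upper = pct <= roi.r_hi_pct if roi.r_hi_pct == 100 else pct < roi.r_hi_pct
    return (pct >= roi.r_lo_pct) & upper


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Normalised, symmetrised grey-level joint probability matrix."""

    p: np.ndarray
    levels: int
    offsets: tuple = DEFAULT_OFFSETS

    def __post_init__(self):
        total = self.p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise TextureError(f"GLCM must sum to 1, got {total}")
        if (self.p < 0).any():
            raise TextureError("GLCM entries must be non-negative")

    @property
    def p_x(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def p_y(self) -> np.ndarray:
        return self.p.sum(axis=0)

    @property
    def mu_x(self) -> float:
        return float(np.arange(self.levels) @ self.p_x)

    @property
    def mu_y(self) -> float:
        return float(np.arange(self.levels) @ self.p_y)

    @property
    def sigma_x(self) -> float:
        i = np.arange(self.levels)
        return float(np.sqrt((i - self.mu_x) ** 2 @ self.p_x))

    @property
    def sigma_y(self) -> float:
        j = np.arange(self.levels)
        return float(np.sqrt((j - self.mu_y) ** 2 @ self.p_y))


def quantise(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Linear binning of 8-bit grey values into ``levels`` bins."""
    if levels < 2:
        raise TextureError("levels must be >= 2")
    return (pixels.astype(np.int64) * levels) // 256


def compute_glcm(image: FingerprintImage, roi: RegionOfInterest = RegionOfInterest(),
                 levels: int = DEFAULT_LEVELS,
                 offsets: tuple = DEFAULT_OFFSETS) -> CooccurrenceMatrix:
    """Accumulate symmetrised pair counts over the offsets inside the ROI.

    A pair is counted only when both pixels lie inside the ROI mask; each
    pair (i, j) is counted in both orders, and the accumulated counts over
    all offsets are normalised to sum 1.
    """
    q = quantise(image.pixels, levels)
    mask = roi_mask(image, roi)
    counts = np.zeros((levels, levels), dtype=np.int64)
    for dr, dc in offsets:
        rows, cols = q.shape
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        np.add.at(counts, (a[valid], b[valid]), 1)
        np.add.at(counts, (b[valid], a[valid]), 1)
    total = counts.sum()
    if total < 2:
        raise TextureError("ROI contains fewer than 2 valid pixel pairs")
    return CooccurrenceMatrix(p=counts / total, levels=levels,
                              offsets=tuple(offsets))


@dataclass(frozen=True)
class TextureFeatures:
    """The 15 second-order texture variables of one fingerprint."""

    values: dict
    degenerate_kappa: bool = False

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_row(self, plate_id: "str | None" = None) -> dict:
        row = {} if plate_id is None else {"plate_id": plate_id}
        row.update({k: self.values[k] for k in TEXTURE_VARIABLES})
        return row


def texture_features(glcm: CooccurrenceMatrix) -> TextureFeatures:
    """Evaluate the 15 second-order statistics of a normalised GLCM."""
    p = glcm.p
    G = glcm.levels
    i = np.arange(G)[:, None]
    j = np.arange(G)[None, :]
    mu_x, mu_y = glcm.mu_x, glcm.mu_y
    sig_x, sig_y = glcm.sigma_x, glcm.sigma_y

    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())

    centred = i + j - mu_x - mu_y
    cluster_shade = float((centred ** 3 * p).sum())
    cluster_prominence = float((centred ** 4 * p).sum())
    diagonal_moment = float((np.abs(i - j) * centred * p).sum())

    p_o = float(np.trace(p))
    p_e = float(glcm.p_x @ glcm.p_y)
    degenerate = np.isclose(p_e, 1.0)
    kappa = 0.0 if degenerate else (p_o - p_e) / (1.0 - p_e)

    energy = float((p ** 2).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    if sig_x > 0 and sig_y > 0:
        correlation = float((((i - mu_x) * (j - mu_y) * p).sum()) / (sig_x * sig_y))
    else:
        correlation = 0.0
    variance = float(((i - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())

    # distributions of i+j (k = 0..2G-2) and |i-j| (k = 0..G-1)
    p_sum = np.zeros(2 * G - 1)
    np.add.at(p_sum, (i + j).ravel(), p.ravel())
    p_diff = np.zeros(G)
    np.add.at(p_diff, np.abs(i - j).ravel(), p.ravel())

    k_sum = np.arange(2 * G - 1)
    sum_average = float(k_sum @ p_sum)
    sum_variance = float((k_sum - sum_average) ** 2 @ p_sum)
    nz_s = p_sum[p_sum > 0]
    sum_entropy = float(-(nz_s * np.log(nz_s)).sum())

    k_diff = np.arange(G)
    diff_mean = float(k_diff @ p_diff)
    difference_variance = float((k_diff - diff_mean) ** 2 @ p_diff)
    nz_d = p_diff[p_diff > 0]
    difference_entropy = float(-(nz_d * np.log(nz_d)).sum())

    values = {
        "entropy": entropy,
        "cluster_shade": cluster_shade,
        "diagonal_moment": diagonal_moment,
        "kappa": float(kappa),
        "energy": energy,
        "contrast": contrast,
        "correlation": correlation,
        "variance": variance,
        "inverse_difference_moment": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "cluster_prominence": cluster_prominence,
    }
    return TextureFeatures(values=values, degenerate_kappa=bool(degenerate))


def texture_features_for_image(image: FingerprintImage,
                               roi: RegionOfInterest = RegionOfInterest(),
                               levels: int = DEFAULT_LEVELS,
                               offsets: tuple = DEFAULT_OFFSETS) -> TextureFeatures:
    """Convenience: GLCM construction plus feature evaluation."""
    return texture_features(compute_glcm(image, roi, levels, offsets))
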