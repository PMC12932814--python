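"""Synthetic dendritic-fingerprint generation.

Real crystallisation fingerprints are ramified needle patterns grown from
the plate centre; laboratory scans are rarely shareable, so this module
provides a fully synthetic test bed with the
same factorial statistical structure.

Two modes share one configuration grammar (:class:`EffectSpec`):

* **direct mode** draws the seven analysis variables straight from a
  linear model (factor contrasts scaled to standardised effect sizes,
  additive day/batch offsets, Gaussian residual), which makes statistical
  properties cheap to test at scale;
* **image mode** renders greyscale plates whose latent growth parameters
  (needle length scale, branching, texture grain) differ across factor
  groups, exercising the full image-analysis chain end to end.

The growth model is deliberately phenomenological: needles are random
walks with small angular diffusion from radially-oriented seeds, and
branching spawns a child needle at a fixed relative angle with jitter.
This gives direct control over needle length — the quantity the structure
variables measure — which diffusion-limited aggregation would not.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .design import DesignTable

#: the seven analysis variables of the evaluation
VARIABLES = ("kappa", "diagonal_moment", "entropy", "cluster_shade",
             "lend", "l220", "l250")

#: two-level contrasts addressable by an EffectSpec: name -> (factor
#: column, level coded +1/2, level coded -1/2); rows at other levels get 0.
CONTRASTS = {
    "subspecies": ("subspecies", "VAA", "VAAu"),
    "deciduous": ("host_tree", "apple", "oak"),
    "blending": ("blending", "machine", "hand"),
    "batch": ("batch", 2109, 2204),
}

#: baseline (grand-mean) values used in direct mode; arbitrary scale,
#: roughly plausible magnitudes for plate-sized fingerprints.
DIRECT_BASELINES = {
    "kappa": 0.4, "diagonal_moment": 2.0, "entropy": 6.0,
    "cluster_shade": 50.0, "lend": 400.0, "l220": 60.0, "l250": 40.0,
}


class SynthesisError(ValueError):
    pass


@dataclass(frozen=True)
class GrowthParams:
    """Latent parameters of the needle-growth model (units: pixels)."""

    n_seeds: int = 24
    length_scale: float = 26.0     # mean needle length
    length_shape: float = 0.35     # lognormal sigma of needle length
    branch_prob: float = 0.12      # per-step side-branch probability
    needle_width: float = 2.0
    texture_grain: float = 0.08    # multiplicative speckle amplitude
    grain_length: float = 2.0      # speckle correlation length
    background_level: int = 40
    foreground_level: int = 215
    plate_radius: int = 128
    angle_diffusion: float = 0.09  # rad per step

    def __post_init__(self):
        if self.plate_radius < 64:
            raise SynthesisError("plate_radius must be >= 64")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise SynthesisError("branch_prob must lie in [0, 1]")
        for name in ("n_seeds", "length_scale", "length_shape", "needle_width",
                     "texture_grain", "grain_length"):
            if getattr(self, name) < 0:
                raise SynthesisError(f"{name} must be non-negative")


@dataclass(frozen=True)
class FingerprintImage:
    """One plate: 8-bit greyscale raster with known centre and radius."""

    pixels: np.ndarray
    centre: tuple
    plate_radius: int

    def __post_init__(self):
        if self.pixels.dtype != np.uint8 or self.pixels.ndim != 2:
            raise SynthesisError("pixels must be a 2-D uint8 raster")


@dataclass(frozen=True)
class EffectSpec:
    """Group-difference specification shared by both generation modes.

    ``effects`` maps a target (one of the seven variables in direct mode,
    a :class:`GrowthParams` field in image mode) to ``{contrast: d}``
    where ``d`` is the standardised difference between the two contrast
    levels (first level minus second, in units of ``residual_sigma``).
    ``day_effects`` / ``batch_effects`` are additive offsets on the
    variable scale (direct mode) or on log(length_scale) (image mode).
    """

    effects: dict = field(default_factory=dict)
    residual_sigma: float = 1.0
    day_effects: dict = field(default_factory=dict)
    batch_effects: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.residual_sigma <= 0:
            raise SynthesisError("residual_sigma must be positive")
        for target, contrasts in self.effects.items():
            for cname, d in contrasts.items():
                if cname not in CONTRASTS:
                    raise SynthesisError(f"unknown contrast {cname!r}")
                if not np.isfinite(d):
                    raise SynthesisError(f"effect size for {target}:{cname} not finite")


def _plate_seed(master: int, plate_id: str, salt: int = 0) -> np.random.SeedSequence:
    """Stable per-plate seed: adding plates never perturbs existing ones."""
    return np.random.SeedSequence([int(master) & 0x7FFFFFFF,
                                   zlib.crc32(plate_id.encode()), salt])


def _contrast_shift(row, contrasts: dict, sigma: float) -> float:
    shift = 0.0
    for cname, d in contrasts.items():
        col, hi, lo = CONTRASTS[cname]
        val = row[col]
        if val == hi:
            shift += d * sigma / 2.0
        elif val == lo:
            shift -= d * sigma / 2.0
    return shift


def generate_feature_table(design: DesignTable, spec: EffectSpec,
                           seed: "int | None" = None) -> pd.DataFrame:
    """Draw the seven variables from the factorial linear model.

    value = baseline + contrast shifts (d x residual_sigma) + day offset
    + batch offset + Normal(0, residual_sigma); one row per plate,
    reproducible for a fixed (design, spec, seed).
    """
    for target in spec.effects:
        if target not in VARIABLES:
            raise SynthesisError(f"unknown variable {target!r} in direct mode")
    master = spec.seed if seed is None else seed
    df = design.frame
    rows = []
    for rec in df.itertuples(index=False):
        rng = np.random.default_rng(_plate_seed(master, rec.plate_id))
        noise = rng.normal(0.0, spec.residual_sigma, size=len(VARIABLES))
        row = {"plate_id": rec.plate_id}
        rowd = rec._asdict()
        for k, var in enumerate(VARIABLES):
            value = DIRECT_BASELINES[var]
            value += _contrast_shift(rowd, spec.effects.get(var, {}),
                                     spec.residual_sigma)
            value += spec.day_effects.get(rec.day, 0.0)
            value += spec.batch_effects.get(rec.batch, 0.0)
            row[var] = value + noise[k]
        rows.append(row)
    return pd.DataFrame(rows, columns=["plate_id", *VARIABLES])


def simulate_fingerprint(params: GrowthParams, seed: int) -> FingerprintImage:
    """Grow and render one synthetic plate; bit-identical per (params, seed).

    Primary needles nucleate on a small ring around the plate centre and
    grow outward as angular random walks; side branches nucleate with
    probability ``branch_prob`` per unit step at a fixed relative angle
    with jitter, inheriting a fraction of the parent's remaining length.
    Rendering stamps the needle mask, applies multiplicative correlated
    speckle, and quantises to 8 bits; pixels outside the plate radius are
    exactly ``background_level``.
    """
    rng = np.random.default_rng(seed)
    R = params.plate_radius
    size = 2 * R + 1
    centre = (R, R)
    if params.n_seeds > 0 and R < 8:
        raise SynthesisError("plate too small to place seeds")

    mask = np.zeros((size, size), dtype=bool)
    # stack of (row, col, angle, remaining_length); depth-first growth
    stack = []
    for k in range(params.n_seeds):
        theta = 2 * np.pi * k / max(params.n_seeds, 1) + rng.normal(0, 0.15)
        r0 = R * rng.uniform(0.08, 0.18)
        y = centre[0] + r0 * np.sin(theta)
        x = centre[1] + r0 * np.cos(theta)
        if params.length_shape > 0:
            length = rng.lognormal(np.log(max(params.length_scale, 1e-9)),
                                   params.length_shape)
        else:
            length = params.length_scale
        stack.append((y, x, theta, length))

    max_steps = 200_000  # hard cap keeps pathological configs bounded
    steps = 0
    while stack and steps < max_steps:
        y, x, ang, remaining = stack.pop()
        while remaining > 0 and steps < max_steps:
            iy, ix = int(round(y)), int(round(x))
            if (iy - centre[0]) ** 2 + (ix - centre[1]) ** 2 >= (R - 1) ** 2:
                break
            mask[iy, ix] = True
            if params.branch_prob > 0 and rng.random() < params.branch_prob:
                side = rng.choice((-1.0, 1.0))
                child_ang = ang + side * (0.65 + rng.normal(0, 0.2))
                child_len = remaining * rng.uniform(0.4, 0.8)
                stack.append((y, x, child_ang, child_len))
            ang += rng.normal(0.0, params.angle_diffusion)
            y += np.sin(ang)
            x += np.cos(ang)
            remaining -= 1.0
            steps += 1

    if params.needle_width > 1:
        radius = max(int(round((params.needle_width - 1) / 2)), 1)
        yy, xx = np.ogrid[-radius:radius + 1, -radius:radius + 1]
        mask = ndimage.binary_dilation(mask, yy ** 2 + xx ** 2 <= radius ** 2)

    img = np.full((size, size), float(params.background_level))
    img[mask] = params.foreground_level
    if params.texture_grain > 0:
        noise = rng.normal(0.0, 1.0, (size, size))
        noise = ndimage.gaussian_filter(noise, params.grain_length)
        sd = noise.std()
        if sd > 0:
            noise /= sd
        img *= 1.0 + params.texture_grain * noise
    yy, xx = np.ogrid[:size, :size]
    outside = (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 > R ** 2
    img[outside] = params.background_level
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return FingerprintImage(pixels=pixels, centre=centre, plate_radius=R)


#: GrowthParams fields an image-mode EffectSpec may target
_LATENT_FIELDS = {f.name for f in fields(GrowthParams)}


def latent_params_for_plate(base: GrowthParams, spec: EffectSpec, row: dict,
                            latent_sigma: float = 0.0,
                            rng: "np.random.Generator | None" = None) -> GrowthParams:
    """Resolve the growth parameters of one plate under an EffectSpec.

    Contrast shifts act multiplicatively (on the log scale) with relative
    amplitude ``d x residual_sigma`` interpreted as a log-scale offset;
    day/batch offsets act additively on log(length_scale).
    """
    updates = {}
    for target, contrasts in spec.effects.items():
        if target not in _LATENT_FIELDS:
            raise SynthesisError(f"unknown GrowthParams field {target!r}")
        shift = _contrast_shift(row, contrasts, spec.residual_sigma)
        base_val = getattr(base, target)
        updates[target] = type(base_val)(base_val * np.exp(shift))
    log_off = (spec.day_effects.get(row.get("day"), 0.0)
               + spec.batch_effects.get(row.get("batch"), 0.0))
    if latent_sigma > 0 and rng is not None:
        log_off += rng.normal(0.0, latent_sigma)
    if log_off != 0.0:
        ls = updates.get("length_scale", base.length_scale)
        updates["length_scale"] = ls * np.exp(log_off)
    return replace(base, **updates) if updates else base


def generate_image_set(design: DesignTable, latent_spec: EffectSpec,
                       seed: "int | None" = None,
                       base_params: "GrowthParams | None" = None,
                       out_dir=None):
    """Render one image per plate; returns (images, metadata DataFrame).

    The realised latent parameters of every plate are recorded in the
    metadata so downstream measurements can be checked against ground
    truth.  With ``out_dir`` set, images are written as 8-bit greyscale
    PNGs named ``<plate_id>.png``.
    """
    base = base_params or GrowthParams()
    master = latent_spec.seed if seed is None else seed
    images, meta = [], []
    for rec in design.frame.itertuples(index=False):
        ss = _plate_seed(master, rec.plate_id, salt=1)
        rng = np.random.default_rng(ss)
        params = latent_params_for_plate(base, latent_spec, rec._asdict(),
                                         latent_sigma=0.0, rng=rng)
        img_seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
        img = simulate_fingerprint(params, img_seed)
        images.append(img)
        row = {"plate_id": rec.plate_id, "image_seed": img_seed}
        row.update({f"latent_{f.name}": getattr(params, f.name)
                    for f in fields(GrowthParams)})
        meta.append(row)
        if out_dir is not None:
            from PIL import Image
            Image.fromarray(img.pixels, mode="L").save(
                f"{out_dir}/{rec.plate_id}.png")
    return images, pd.DataFrame(meta)
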