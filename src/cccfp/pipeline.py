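"""End-to-end orchestration: design -> fingerprints -> features -> statistics.

A run takes one of three modes:

* ``synthetic-direct`` — draw the seven analysis variables straight from
  the factorial linear model (fast statistical test bed);
* ``synthetic-image`` — render synthetic plates and push them through the
  full image-analysis chain;
* ``from-images`` — ingest a directory of 8-bit greyscale scans plus a
  plate-metadata CSV.

Every run emits the design table, the feature tables, the three
sensitivity-test summaries with LSD companions, and a manifest recording
configuration hash, row counts and warnings.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import DesignTable, build_verum_design
from .randomise import RotationPlan, build_rotation
from .stats import correlation_filter, run_sensitivity_test
from .structure import (STRUCTURE_ROI, dump_bin_edges,
                        structure_features_for_image)
from .synthesis import (EffectSpec, FingerprintImage, GrowthParams,
                        generate_feature_table, generate_image_set)
from .texture import (DEFAULT_LEVELS, DEFAULT_OFFSETS, RegionOfInterest,
                      texture_features_for_image)

MODES = ("synthetic-direct", "synthetic-image", "from-images")

#: texture variables feeding the analysis set
_TEXTURE_PICK = ("kappa", "diagonal_moment", "entropy", "cluster_shade")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    mode: str = "synthetic-direct"
    out_dir: str = "cccfp_run"
    seed: "int | None" = 0
    n_days: int = 6
    image_dir: "str | None" = None
    metadata_csv: "str | None" = None
    effects: dict = field(default_factory=dict)
    residual_sigma: float = 1.0
    day_effects: dict = field(default_factory=dict)
    batch_effects: dict = field(default_factory=dict)
    growth: dict = field(default_factory=dict)
    texture_levels: int = DEFAULT_LEVELS
    texture_roi: tuple = (0.0, 100.0)
    structure_roi: tuple = (STRUCTURE_ROI.r_lo_pct, STRUCTURE_ROI.r_hi_pct)
    alpha: float = 0.01
    correlation_threshold: float = 0.7

    def __post_init__(self):
        if self.mode not in MODES:
            raise PipelineError(f"unknown mode {self.mode!r}")
        if self.mode.startswith("synthetic") and self.seed is None:
            raise PipelineError("seed is mandatory in synthetic modes")
        if self.mode == "from-images":
            for p in (self.image_dir, self.metadata_csv):
                if p is None or not Path(p).exists():
                    raise PipelineError(f"missing input path: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        # YAML keys for day/batch offsets arrive as strings; coerce
        for key in ("day_effects", "batch_effects"):
            if key in doc:
                doc[key] = {int(k): float(v) for k, v in doc[key].items()}
        if "texture_roi" in doc:
            doc["texture_roi"] = tuple(doc["texture_roi"])
        if "structure_roi" in doc:
            doc["structure_roi"] = tuple(doc["structure_roi"])
        return cls(**doc)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def effect_spec(self) -> EffectSpec:
        return EffectSpec(effects=self.effects,
                          residual_sigma=self.residual_sigma,
                          day_effects=self.day_effects,
                          batch_effects=self.batch_effects,
                          seed=self.seed or 0)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    mode: str
    seed: "int | None"
    row_counts: dict = field(default_factory=dict)
    wall_clock_s: float = 0.0
    warnings: list = field(default_factory=list)
    skipped: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def ingest_images(image_dir, metadata_csv):
    """Load scans named ``<plate_id>.png`` next to a plate-metadata CSV.

    Yields (DesignTable, list of FingerprintImage, skipped records).  An
    image file without a metadata row is an error (orphan image); a
    metadata row without an image file is skipped and recorded.  RGB input
    is converted by luminance with a warning; the plate centre and radius
    are taken from ``centre_row``/``centre_col``/``plate_radius`` columns
    when present, else estimated as the brightest-disc fit (centroid and
    equivalent radius of the above-median pixels).
    """
    from PIL import Image

    image_dir = Path(image_dir)
    meta = pd.read_csv(metadata_csv)
    design = DesignTable(meta)
    files = {p.stem: p for p in sorted(image_dir.glob("*.png"))}
    orphans = set(files) - set(meta["plate_id"].astype(str))
    if orphans:
        raise PipelineError(
            f"images without metadata rows: {sorted(orphans)}")

    images, kept_rows, skipped = [], [], []
    for idx, row in meta.iterrows():
        pid = str(row["plate_id"])
        path = files.get(pid)
        if path is None:
            skipped.append({"plate_id": pid, "reason": "no image file"})
            continue
        try:
            im = Image.open(path)
            if im.mode not in ("L", "I;16", "I"):
                warnings.warn(f"{pid}: non-greyscale input converted by luminance",
                              stacklevel=2)
                im = im.convert("L")
            arr = np.asarray(im)
            if arr.dtype != np.uint8:
                arr = (arr / arr.max() * 255).astype(np.uint8)
        except Exception as exc:  # unreadable file: record and continue
            skipped.append({"plate_id": pid, "reason": f"unreadable: {exc}"})
            continue
        if {"centre_row", "centre_col", "plate_radius"} <= set(meta.columns):
            centre = (int(row["centre_row"]), int(row["centre_col"]))
            radius = int(row["plate_radius"])
        else:
            bright = arr > np.median(arr)
            if bright.any():
                ys, xs = np.nonzero(bright)
                centre = (int(ys.mean()), int(xs.mean()))
                radius = int(np.sqrt(bright.sum() / np.pi))
            else:
                centre = (arr.shape[0] // 2, arr.shape[1] // 2)
                radius = min(arr.shape) // 2
            radius = max(radius, min(arr.shape) // 4)
        images.append(FingerprintImage(pixels=arr, centre=centre,
                                       plate_radius=radius))
        kept_rows.append(row)
    kept = DesignTable(pd.DataFrame(kept_rows)) if kept_rows else design
    return kept, images, skipped


def measure_images(design: DesignTable, images: list, config: RunConfig):
    """Texture + structure features for every plate; returns the analysis
    feature table (seven variables) plus the two full per-stage tables."""
    t_roi = RegionOfInterest(*config.texture_roi)
    s_roi = RegionOfInterest(*config.structure_roi)
    tex_rows, struct_rows = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rec, img in zip(design.frame.itertuples(index=False), images):
            tex = texture_features_for_image(img, t_roi, config.texture_levels)
            stc = structure_features_for_image(img, s_roi)
            tex_rows.append(tex.as_row(rec.plate_id))
            struct_rows.append(stc.as_row(rec.plate_id))
    texture = pd.DataFrame(tex_rows)
    structure = pd.DataFrame(struct_rows)
    analysis = texture[["plate_id", *_TEXTURE_PICK]].merge(
        structure[["plate_id", "lend", "l220", "l250"]], on="plate_id")
    return analysis, texture, structure


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute a full run and write all artefacts under ``config.out_dir``."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.digest(), version=__version__,
                           mode=config.mode, seed=config.seed)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rotation = (build_rotation(n_days=6, seed=config.seed)
                    if config.n_days == 6 else RotationPlan.cyclic(config.n_days))

        if config.mode == "from-images":
            design, images, skipped = ingest_images(config.image_dir,
                                                    config.metadata_csv)
            manifest.skipped = skipped
            features, texture, structure = measure_images(design, images, config)
        else:
            design = build_verum_design(config.n_days, rotation=rotation)
            spec = config.effect_spec()
            if config.mode == "synthetic-direct":
                features = generate_feature_table(design, spec)
                texture = structure = None
            else:
                base = GrowthParams(**config.growth)
                images, meta = generate_image_set(design, spec,
                                                  base_params=base)
                meta.to_csv(out / "latent_params.csv", index=False)
                features, texture, structure = measure_images(design, images,
                                                              config)

        design.to_csv(out / "design.csv")
        features.to_csv(out / "features.csv", index=False)
        if texture is not None:
            texture.to_csv(out / "texture_features.csv", index=False)
            structure.to_csv(out / "structure_features.csv", index=False)
            dump_bin_edges(out / "bin_edges.json")

        report = correlation_filter(features,
                                    threshold=config.correlation_threshold)
        report.correlation.to_csv(out / "correlation_matrix.csv")
        (out / "correlation_filter.json").write_text(json.dumps(
            {"kept": list(report.kept), "dropped": report.dropped,
             "threshold": report.threshold}, indent=1))

        manifest.row_counts["design"] = len(design)
        manifest.row_counts["features"] = len(features)
        for test_id in ("subspecies", "deciduous", "blending"):
            try:
                results = run_sensitivity_test(features, design, test_id,
                                               alpha=config.alpha)
            except Exception as exc:
                raise PipelineError(f"stage evaluate/{test_id}: {exc}") from exc
            results.summary().to_csv(out / f"sensitivity_{test_id}.csv",
                                     index=False)
            results.lsd_tables().to_csv(out / f"lsd_{test_id}.csv", index=False)
            manifest.row_counts[f"rows_{test_id}"] = len(results.model.data)

        manifest.warnings = sorted({str(w.message) for w in caught})

    manifest.wall_clock_s = round(time.time() - t0, 3)
    manifest.to_json(out / "manifest.json")
    return manifest
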