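"""Synthetic fingerprint generator: determinism, effect-size fidelity,
image-mode monotonicity."""

import math

import numpy as np
import pandas as pd
import pytest

from cccfp.design import build_verum_design
from cccfp.stats import cohens_d
from cccfp.structure import structure_features_for_image
from cccfp.synthesis import (EffectSpec, GrowthParams, SynthesisError,
                             VARIABLES, generate_feature_table,
                             generate_image_set, simulate_fingerprint)


class TestSimulateFingerprint:
    def test_unbranched_needle_skeleton_two_endpoints(self):
        from cccfp.structure import endpoints, skeletonise
        params = GrowthParams(n_seeds=1, branch_prob=0.0, length_scale=30,
                              length_shape=0.0, needle_width=1.0,
                              texture_grain=0.0)
        img = simulate_fingerprint(params, seed=3)
        skel = skeletonise(img.pixels > 128)
        assert endpoints(skel).sum() == 2

    def test_different_seeds_different_rasters(self):
        params = GrowthParams(n_seeds=3)
        a = simulate_fingerprint(params, seed=7)
        b = simulate_fingerprint(params, seed=8)
        assert (a.pixels != b.pixels).any()

    def test_bit_identical_for_same_seed(self):
        params = GrowthParams(n_seeds=8, branch_prob=0.2)
        a = simulate_fingerprint(params, seed=5)
        b = simulate_fingerprint(params, seed=5)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_branching_adds_endpoints(self):
        from cccfp.structure import endpoints, skeletonise
        params = GrowthParams(n_seeds=5, branch_prob=0.3, length_scale=30,
                              length_shape=0.0, needle_width=1.0,
                              texture_grain=0.0)
        img = simulate_fingerprint(params, seed=1)
        skel = skeletonise(img.pixels > 128)
        assert endpoints(skel).sum() >= 10

    def test_outside_plate_is_background(self):
        params = GrowthParams(background_level=40)
        img = simulate_fingerprint(params, seed=2)
        yy, xx = np.ogrid[:img.pixels.shape[0], :img.pixels.shape[1]]
        outside = ((yy - img.centre[0]) ** 2 + (xx - img.centre[1]) ** 2
                   > img.plate_radius ** 2)
        assert (img.pixels[outside] == 40).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(SynthesisError):
            GrowthParams(plate_radius=32)
        with pytest.raises(SynthesisError):
            GrowthParams(branch_prob=1.5)


class TestGenerateFeatureTable:
    def test_null_model_group_differences_near_zero(self, full_design):
        feats = generate_feature_table(full_design, EffectSpec(seed=42))
        merged = full_design.frame.merge(feats, on="plate_id")
        for var in VARIABLES:
            a = merged.loc[merged["subspecies"] == "VAA", var]
            b = merged.loc[merged["subspecies"] == "VAAu", var]
            assert abs(cohens_d(a, b)) < 0.35

    def test_specified_d_recovered_within_sampling_error(self, full_design):
        spec = EffectSpec(effects={"l250": {"subspecies": 2.0}}, seed=10)
        feats = generate_feature_table(full_design, spec)
        merged = full_design.frame.merge(feats, on="plate_id")
        a = merged.loc[merged["subspecies"] == "VAA", "l250"]
        b = merged.loc[merged["subspecies"] == "VAAu", "l250"]
        assert cohens_d(a, b) == pytest.approx(2.0, abs=0.35)

    def test_effect_size_fidelity_over_replicates(self, full_design):
        # mean recovered d within 2 SE of the specified value over R reps
        true_d, R = 1.0, 200
        spec = EffectSpec(effects={"l220": {"deciduous": true_d}}, seed=0)
        ds = []
        for rep in range(R):
            feats = generate_feature_table(full_design, spec, seed=rep)
            merged = full_design.frame.merge(feats, on="plate_id")
            a = merged.loc[merged["host_tree"] == "apple", "l220"]
            b = merged.loc[merged["host_tree"] == "oak", "l220"]
            ds.append(cohens_d(a, b))
        se = np.std(ds, ddof=1) / math.sqrt(R)
        assert abs(np.mean(ds) - true_d) <= 2 * se

    def test_day_effects_shift_only_day_means(self, full_design):
        spec = EffectSpec(day_effects={1: 5.0}, seed=6)
        feats = generate_feature_table(full_design, spec)
        merged = full_design.frame.merge(feats, on="plate_id")
        day1 = merged.loc[merged["day"] == 1, "entropy"].mean()
        rest = merged.loc[merged["day"] != 1, "entropy"].mean()
        assert day1 - rest == pytest.approx(5.0, abs=0.5)

    def test_reproducible_per_seed(self, full_design):
        spec = EffectSpec(effects={"lend": {"blending": 0.5}}, seed=9)
        a = generate_feature_table(full_design, spec)
        b = generate_feature_table(full_design, spec)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_variable_rejected(self, full_design):
        with pytest.raises(SynthesisError, match="unknown variable"):
            generate_feature_table(full_design,
                                   EffectSpec(effects={"sparkle": {}}))

    def test_unknown_contrast_rejected(self):
        with pytest.raises(SynthesisError, match="unknown contrast"):
            EffectSpec(effects={"l250": {"altitude": 1.0}})


class TestGenerateImageSet:
    def test_single_plate_one_image_one_row(self, full_design):
        one = type(full_design)(full_design.frame.iloc[:1])
        images, meta = generate_image_set(one, EffectSpec(seed=1),
                                          base_params=GrowthParams(plate_radius=64))
        assert len(images) == 1 and len(meta) == 1
        assert meta["plate_id"].iloc[0] == full_design.frame["plate_id"].iloc[0]

    def test_deterministic_outputs(self, full_design):
        small = type(full_design)(full_design.frame.iloc[:4])
        spec = EffectSpec(seed=3)
        base = GrowthParams(plate_radius=64)
        im1, m1 = generate_image_set(small, spec, base_params=base)
        im2, m2 = generate_image_set(small, spec, base_params=base)
        for a, b in zip(im1, im2):
            np.testing.assert_array_equal(a.pixels, b.pixels)
        pd.testing.assert_frame_equal(m1, m2)

    def test_length_scale_contrast_shifts_l250_downstream(self, full_design):
        # machine-blended plates grow longer needles -> higher l250 counts
        small = type(full_design)(full_design.frame.iloc[:48])
        spec = EffectSpec(effects={"length_scale": {"blending": 0.8}}, seed=4)
        base = GrowthParams(plate_radius=80, n_seeds=16)
        images, _ = generate_image_set(small, spec, base_params=base)
        counts = {"machine": [], "hand": []}
        for rec, img in zip(small.frame.itertuples(index=False), images):
            feats = structure_features_for_image(img)
            counts[rec.blending].append(feats.as_row()["l250"])
        assert np.mean(counts["machine"]) > np.mean(counts["hand"])

    def test_length_scale_sweep_monotone_in_measured_length(self):
        # rank correlation > 0 across a 5-level latent sweep
        from cccfp.structure import decompose_needles, skeletonise
        scales = [14, 18, 24, 32, 42]
        mean_lengths = []
        for ls in scales:
            params = GrowthParams(n_seeds=10, branch_prob=0.0, length_scale=ls,
                                  length_shape=0.1, needle_width=1.0,
                                  texture_grain=0.0, plate_radius=96)
            lengths = []
            for seed in range(4):
                img = simulate_fingerprint(params, seed=seed)
                segs = decompose_needles(skeletonise(img.pixels > 128))
                lengths += [s.length for s in segs if s.length >= 2]
            mean_lengths.append(np.mean(lengths))
        from scipy.stats import spearmanr
        rho, _ = spearmanr(scales, mean_lengths)
        assert rho > 0

    def test_metadata_records_latent_truth(self, full_design):
        sub = full_design.frame.groupby("host_tree").head(3)
        small = type(full_design)(sub)
        spec = EffectSpec(effects={"length_scale": {"subspecies": 1.0}}, seed=2)
        _, meta = generate_image_set(small, spec,
                                     base_params=GrowthParams(plate_radius=64))
        merged = small.frame.merge(meta, on="plate_id")
        vaa = merged.loc[merged["subspecies"] == "VAA", "latent_length_scale"]
        vaau = merged.loc[merged["subspecies"] == "VAAu", "latent_length_scale"]
        assert vaa.mean() > vaau.mean()

    def test_unknown_latent_field_rejected(self, full_design):
        one = type(full_design)(full_design.frame.iloc[:1])
        with pytest.raises(SynthesisError, match="GrowthParams"):
            generate_image_set(one, EffectSpec(effects={"hue": {"batch": 1.0}}),
                               base_params=GrowthParams(plate_radius=64))
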