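"""Simulator contracts: treatment model, rendering, plate organisation."""

import dataclasses

import numpy as np
import pytest
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import skeletonize

from platescreen import (
    CompoundModel, MorphologyParams, PlateEffect, PlateEffectSampler,
    SeverityLabel, WellSpec, generate_plate, render_well, severity_from_treatment,
)
from platescreen.synthetic import LPS_CONCENTRATIONS, render_tile


class TestSeverityModel:
    def test_class_anchors_map_to_concentration_ladder(self):
        assert [SeverityLabel(i).lps_ug_per_ml for i in range(6)] == list(LPS_CONCENTRATIONS)
        assert SeverityLabel(0).base_severity == 0.0
        assert SeverityLabel(5).base_severity == 1.0
        sevs = [SeverityLabel(i).base_severity for i in range(6)]
        assert sevs == sorted(sevs)

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            SeverityLabel(6)

    def test_control_has_zero_severity(self):
        assert severity_from_treatment(SeverityLabel(0)) == 0.0

    def test_zero_dose_gives_no_rescue(self):
        c = CompoundModel(ec50=1.0, hill=2.0, max_rescue=1.0)
        assert severity_from_treatment(SeverityLabel(5), dose=0.0, compound=c) == 1.0

    def test_ec50_dose_halves_severity(self):
        # Hill formula by hand: dose^h / (dose^h + ec50^h) = 1/2 at dose = ec50
        c = CompoundModel(ec50=2.0, hill=1.0, max_rescue=1.0)
        got = severity_from_treatment(SeverityLabel(1), dose=2.0, compound=c)
        assert got == pytest.approx(SeverityLabel(1).base_severity / 2)

    def test_rescue_monotone_in_dose(self):
        c = CompoundModel(ec50=1.0, hill=1.7, max_rescue=0.8)
        rescues = [c.rescue(d) for d in (0, 0.1, 0.5, 1, 2, 10, 100)]
        assert rescues == sorted(rescues)
        assert rescues[0] == 0.0
        assert rescues[-1] <= 0.8

    def test_negative_dose_rejected(self):
        c = CompoundModel(ec50=1.0)
        with pytest.raises(ValueError):
            severity_from_treatment(SeverityLabel(1), dose=-0.1, compound=c)


class TestRenderWell:
    def test_shape_and_range_contract(self, params):
        tiles = render_well(0.5, params, PlateEffect(), tile_size=80, seed=0)
        assert len(tiles) == 9
        for t in tiles:
            assert t.shape == (80, 80, 3)
            assert t.min() >= 0.0 and t.max() <= 1.0

    def test_same_seed_is_bit_identical(self, params):
        a = render_well(0.5, params, PlateEffect(), tile_size=80, seed=7)
        b = render_well(0.5, params, PlateEffect(), tile_size=80, seed=7)
        assert all((x == y).all() for x, y in zip(a, b))

    def test_tiny_tile_rejected(self, params):
        with pytest.raises(ValueError):
            render_well(0.5, params, PlateEffect(), tile_size=32, seed=0)

    def test_plate_effect_is_affine_clip(self, params):
        clean = render_well(0.4, params, PlateEffect(), tile_size=80, seed=5)
        eff = PlateEffect(gain=(1.5, 0.8, 1.0), offset=(0.1, 0.0, 0.05))
        shifted = render_well(0.4, params, eff, tile_size=80, seed=5)
        gain = np.array(eff.gain)
        off = np.array(eff.offset)
        for c, s in zip(clean, shifted):
            assert np.allclose(s, np.clip(c * gain + off, 0, 1), atol=1e-12)

    def test_morphology_monotone_in_severity(self, params):
        """Ameboid rendering is rounder and less ramified than ramified.

        Mean microglia circularity (4 pi A / P^2) must rise, and skeleton
        length per object fall, from severity 0 to 1 over >= 20 seeds,
        measured on the pre-noise foreground masks.
        """
        def measure(severity, seed):
            rng = np.random.default_rng(seed)
            _, masks = render_tile(severity, params, 120, rng, return_masks=True)
            m = masks["microglia"]
            props = [p for p in regionprops(cc_label(m)) if p.area >= 8]
            if not props:
                return np.nan, np.nan
            circ = np.mean([4 * np.pi * p.area / p.perimeter ** 2
                            for p in props if p.perimeter > 0])
            return circ, skeletonize(m).sum() / len(props)

        lo = np.array([measure(0.0, s) for s in range(20)])
        hi = np.array([measure(1.0, s) for s in range(20)])
        assert np.nanmean(hi[:, 0]) > np.nanmean(lo[:, 0])   # rounder
        assert np.nanmean(hi[:, 1]) < np.nanmean(lo[:, 1])   # less ramified


class TestMorphologyParams:
    def test_interpolation_respects_ordinal_direction(self, params):
        a = params.at(0.0)
        b = params.at(1.0)
        assert b["microglia_soma_radius_px"] >= a["microglia_soma_radius_px"]
        assert b["microglia_process_count"] <= a["microglia_process_count"]
        assert b["neurite_length_px"] <= a["neurite_length_px"]

    def test_inverted_direction_rejected(self):
        with pytest.raises(ValueError):
            MorphologyParams(microglia_soma_radius_px=(9.0, 4.0))
        with pytest.raises(ValueError):
            MorphologyParams(neurite_length_px=(10.0, 20.0))

    def test_severity_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            params.at(1.5)


class TestPlateGeneration:
    def test_default_layout_counts(self, params):
        layout = [WellSpec(f"C{c}W{r}", SeverityLabel(c))
                  for c in range(6) for r in range(5)]
        plate = generate_plate("P1", layout, params, PlateEffectSampler(),
                               seed=1, tile_size=64)
        assert len(plate.wells) == 30
        n_tiles = sum(len(plate.render_well(w.well_id)) for w in plate.wells[:3])
        assert n_tiles == 27  # 9 per well; 30 wells -> 270 total by arithmetic
        assert len(plate.manifest()) == 30

    def test_duplicate_well_rejected(self, params):
        layout = [WellSpec("A1", SeverityLabel(0)), WellSpec("A1", SeverityLabel(1))]
        with pytest.raises(ValueError):
            generate_plate("P1", layout, params, PlateEffectSampler(), seed=1)

    def test_plate_effect_is_only_plate_level_draw(self, params):
        """Same geometry seed, different plate seed: identical cells, new effect."""
        layout = [WellSpec("A1", SeverityLabel(2))]
        sampler = PlateEffectSampler(blur_max_px=0.0)
        p1 = generate_plate("P1", layout, params, sampler, seed=5, plate_seed=100,
                            tile_size=64)
        p2 = generate_plate("P2", layout, params, sampler, seed=5, plate_seed=200,
                            tile_size=64)
        assert p1.effect != p2.effect
        # neutralizing the effects exposes identical underlying geometry
        q1 = dataclasses.replace(p1, effect=PlateEffect())
        q2 = dataclasses.replace(p2, effect=PlateEffect())
        for a, b in zip(q1.render_well("A1"), q2.render_well("A1")):
            assert (a == b).all()

    def test_zero_rescue_compound_is_pixel_identical_to_lps(self, params):
        inert = CompoundModel(ec50=1.0, hill=1.0, max_rescue=0.0)
        plain = [WellSpec("A1", SeverityLabel(1))]
        dosed = [WellSpec("A1", SeverityLabel(1), compound="x", dose=5.0)]
        sampler = PlateEffectSampler()
        p1 = generate_plate("P1", plain, params, sampler, seed=9, tile_size=64)
        p2 = generate_plate("P1", dosed, params, sampler, seed=9, tile_size=64,
                            compounds={"x": inert})
        for a, b in zip(p1.render_well("A1"), p2.render_well("A1")):
            assert (a == b).all()

    def test_plate_effects_confound_mean_intensity(self, params):
        """Distinct per-plate gains separate plate mean intensities.

        Max pairwise difference of plate means exceeds 3x the within-plate
        spread of well means — the signature a plate-naive classifier latches
        onto.
        """
        layout = [WellSpec(f"W{r}", SeverityLabel(0)) for r in range(4)]
        sampler = PlateEffectSampler(gain_log_sd=0.4)
        well_means = {}
        for i in range(4):
            p = generate_plate(f"P{i}", layout, params, sampler,
                               seed=50, plate_seed=60 + i, tile_size=64)
            well_means[p.plate_id] = [
                np.mean([t.mean() for t in p.render_well(w.well_id)])
                for w in p.wells]
        plate_means = {k: np.mean(v) for k, v in well_means.items()}
        within_sd = np.mean([np.std(v) for v in well_means.values()])
        diffs = [abs(a - b) for i, a in enumerate(plate_means.values())
                 for b in list(plate_means.values())[i + 1:]]
        assert max(diffs) > 3 * within_sd
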