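import numpy as np
import pytest

from platescreen import (
    CropGridSpec, MorphologyParams, PlateEffect, crops_from_tiles, render_well,
)


@pytest.fixture(scope="session")
def params():
    return MorphologyParams()


@pytest.fixture(scope="session")
def well_tiles(params):
    """Nine clean-ish tiles of one mid-severity well (identity plate effect)."""
    return render_well(0.3, params, PlateEffect(), tile_size=100, seed=3)


@pytest.fixture(scope="session")
def well_crops(well_tiles):
    """The 15 uint8 crops of that well."""
    return crops_from_tiles(
        well_tiles, CropGridSpec(crop_size=128),
        plate_id="P1", well_id="W1", class_index=2)


@pytest.fixture(scope="session")
def extreme_features():
    """Features of control-extreme vs inflamed-extreme crops (severity 0 vs 1).

    30 crops per class from two wells each, identity plate effect: the
    morphology contrast is maximal, so the two clouds are linearly separable.
    """
    from platescreen import feature_matrix

    p = MorphologyParams()
    spec = CropGridSpec(crop_size=96)
    out = {}
    for sev, key in ((0.0, "ctl"), (1.0, "lps")):
        crops = []
        for seed in (11, 12):
            tiles = render_well(sev, p, PlateEffect(), tile_size=80, seed=seed)
            crops.extend(crops_from_tiles(tiles, spec, plate_id="P", well_id=f"W{seed}",
                                          class_index=0))
        out[key] = feature_matrix(crops)
    return out
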