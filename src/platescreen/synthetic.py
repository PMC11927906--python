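"""Synthetic plate-organized fluorescence microscopy.

Renders three-channel well images (red = Iba-1/microglia, green =
MAP2/neuron, blue = DAPI/nucleus) whose morphology varies ordinally with an
inflammation-severity scalar in [0, 1]:

* microglia shift from ramified (small soma, many long processes) to
  ameboid (large round soma, few/no processes) as severity rises;
* neurons retract neurites (fewer branches, shorter dendrites);
* nuclei are severity-independent filled ellipses.

Each well is a 3x3 montage of tiles.  A per-plate intensity batch effect
(multiplicative gain, additive offset, optional blur) is applied uniformly
to every tile of a plate, confounding intensity with plate identity the way
real plate-to-plate staining variability does.  Compound treatment rescues
severity toward the control phenotype through a Hill dose-response curve.

All geometry derives from a single integer seed; identical (params, seed)
yield bit-identical pixels.  Morphology numerics are simulator choices (the
defaults are documented in ``MorphologyParams``), not measured values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse, disk, line_aa

__all__ = [
    "LPS_CONCENTRATIONS",
    "CHANNEL_ROLES",
    "SeverityLabel",
    "MorphologyParams",
    "PlateEffect",
    "PlateEffectSampler",
    "CompoundModel",
    "WellSpec",
    "PlateData",
    "severity_from_treatment",
    "render_tile",
    "render_well",
    "generate_plate",
    "default_layout",
    "generate_experiment",
]

#: Ordinal LPS concentration ladder (ug/ml); class index i maps to entry i.
LPS_CONCENTRATIONS = (0.0, 0.005, 0.05, 0.5, 5.0, 20.0)

#: Fixed channel-role assignment used throughout the pipeline.
CHANNEL_ROLES = {"red": "Iba-1/microglia", "green": "MAP2/neuron", "blue": "DAPI/nucleus"}
ROLE_INDEX = {"microglia": 0, "neuron": 1, "nucleus": 2}

#: Geometry reference tile side in pixels; all lengths scale with tile/_REF.
_REF_TILE = 200


@dataclass(frozen=True)
class SeverityLabel:
    """Ordinal inflammation class: 0 = control up to 5 = 20 ug/ml LPS."""

    class_index: int

    def __post_init__(self) -> None:
        if not 0 <= int(self.class_index) <= 5:
            raise ValueError(f"class_index must be in 0..5, got {self.class_index}")

    @property
    def lps_ug_per_ml(self) -> float:
        return LPS_CONCENTRATIONS[self.class_index]

    @property
    def base_severity(self) -> float:
        """Linear interpolation of class anchors: class 0 -> 0.0, class 5 -> 1.0."""
        return self.class_index / 5.0


def _lerp(pair: tuple[float, float], severity: float) -> float:
    lo, hi = pair
    return lo + (hi - lo) * severity


@dataclass(frozen=True)
class MorphologyParams:
    """Tunable per-cell-type rendering parameters.

    Severity-dependent fields are (value_at_severity_0, value_at_severity_1)
    pairs interpolated linearly.  Lengths and radii are in pixels at the
    200-px reference tile and scale proportionally with tile size.  These
    defaults are simulator choices tuned for a visually plausible culture at
    10x-like density.
    """

    nuclei_count_mean: float = 14.0
    nucleus_radius_px: float = 5.0
    neuron_count_mean: float = 6.0
    #: primary neurites per neuron, decreasing with severity (retraction)
    neurite_branches: tuple[float, float] = (4.0, 1.0)
    #: neurite length in px, decreasing with severity
    neurite_length_px: tuple[float, float] = (45.0, 12.0)
    microglia_count_mean: float = 5.0
    #: soma radius, increasing with severity (ramified -> ameboid)
    microglia_soma_radius_px: tuple[float, float] = (4.0, 9.0)
    #: radiating processes per microglia, decreasing with severity
    microglia_process_count: tuple[float, float] = (5.0, 0.0)
    #: process length in px, decreasing with severity
    microglia_process_length_px: tuple[float, float] = (32.0, 6.0)
    #: mean foreground intensity per channel (red, green, blue) on [0, 1]
    intensity_base: tuple[float, float, float] = (0.55, 0.50, 0.60)
    #: additive Gaussian noise standard deviation
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        for name in ("nuclei_count_mean", "neuron_count_mean", "microglia_count_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nucleus_radius_px <= 0:
            raise ValueError("nucleus_radius_px must be > 0")
        for name in (
            "neurite_length_px",
            "microglia_soma_radius_px",
            "microglia_process_length_px",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi <= 0:
                raise ValueError(f"{name} entries must be > 0")
        if self.microglia_soma_radius_px[1] < self.microglia_soma_radius_px[0]:
            raise ValueError("microglia soma radius must be non-decreasing in severity")
        for name in ("microglia_process_count", "microglia_process_length_px",
                     "neurite_length_px", "neurite_branches"):
            lo, hi = getattr(self, name)
            if hi > lo:
                raise ValueError(f"{name} must be non-increasing in severity")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def at(self, severity: float) -> dict[str, float]:
        """Concrete geometry at one severity (unscaled reference pixels)."""
        if not 0.0 <= severity <= 1.0:
            raise ValueError(f"severity must be in [0, 1], got {severity}")
        return {
            "neurite_branches": _lerp(self.neurite_branches, severity),
            "neurite_length_px": _lerp(self.neurite_length_px, severity),
            "microglia_soma_radius_px": _lerp(self.microglia_soma_radius_px, severity),
            "microglia_process_count": _lerp(self.microglia_process_count, severity),
            "microglia_process_length_px": _lerp(self.microglia_process_length_px, severity),
        }


@dataclass(frozen=True)
class PlateEffect:
    """Plate-level intensity batch effect: pixel -> clip(gain*pixel + offset)."""

    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    blur_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gain):
            raise ValueError("gain must be > 0 per channel")
        if any(not 0.0 <= o < 1.0 for o in self.offset):
            raise ValueError("offset must be in [0, 1) per channel")
        if self.blur_sigma_px < 0:
            raise ValueError("blur_sigma_px must be >= 0")

    def apply(self, img: np.ndarray) -> np.ndarray:
        out = img
        if self.blur_sigma_px > 0:
            out = ndimage.gaussian_filter(out, sigma=(self.blur_sigma_px, self.blur_sigma_px, 0))
        gain = np.asarray(self.gain, dtype=img.dtype)
        offset = np.asarray(self.offset, dtype=img.dtype)
        return np.clip(out * gain + offset, 0.0, 1.0)


@dataclass(frozen=True)
class PlateEffectSampler:
    """Distribution over :class:`PlateEffect`.

    Per channel: gain ~ LogNormal(0, gain_log_sd); offset ~ Uniform(0, offset_max);
    blur sigma ~ Uniform(0, blur_max_px).  ``gain_log_sd`` around 0.25 gives
    mild plate effects; 0.5+ gives the strong confound used in the
    batch-effect-mitigation experiments.
    """

    gain_log_sd: float = 0.25
    offset_max: float = 0.08
    blur_max_px: float = 0.8

    def sample(self, rng: np.random.Generator) -> PlateEffect:
        gain = tuple(np.exp(rng.normal(0.0, self.gain_log_sd, size=3)))
        offset = tuple(rng.uniform(0.0, self.offset_max, size=3))
        blur = float(rng.uniform(0.0, self.blur_max_px))
        return PlateEffect(gain=gain, offset=offset, blur_sigma_px=blur)


@dataclass(frozen=True)
class CompoundModel:
    """Hill-type rescue of LPS severity toward the control phenotype."""

    ec50: float
    hill: float = 1.0
    max_rescue: float = 1.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")
        if not 0.0 <= self.max_rescue <= 1.0:
            raise ValueError("max_rescue must be in [0, 1]")

    def rescue(self, dose: float) -> float:
        """Fractional rescue in [0, max_rescue]; rescue(0) = 0."""
        if dose < 0:
            raise ValueError("dose must be >= 0")
        if dose == 0:
            return 0.0
        dh = dose ** self.hill
        return self.max_rescue * dh / (dh + self.ec50 ** self.hill)


def severity_from_treatment(
    label: SeverityLabel,
    dose: float | None = None,
    compound: CompoundModel | None = None,
) -> float:
    """Effective severity of a well: base class severity scaled down by rescue.

    effective = base_severity(class) * (1 - rescue(dose)).  With no compound
    (or dose None) the base severity is returned unchanged.
    """
    base = label.base_severity
    if compound is None or dose is None:
        return base
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return base * (1.0 - compound.rescue(dose))


# ---------------------------------------------------------------------------
# rendering primitives


def _clamp(v: int, hi: int) -> int:
    return 0 if v < 0 else (hi if v > hi else v)


def _draw_walk(
    canvas: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    y: float,
    x: float,
    heading: float,
    length: float,
    step: float = 3.0,
    jitter: float = 0.35,
) -> None:
    """Anti-aliased random-walk polyline from (y, x); used for processes/neurites."""
    h, w = mask.shape
    n_steps = max(1, int(round(length / step)))
    for _ in range(n_steps):
        heading += rng.normal(0.0, jitter)
        y2 = y + step * np.sin(heading)
        x2 = x + step * np.cos(heading)
        rr, cc, val = line_aa(
            _clamp(int(round(y)), h - 1), _clamp(int(round(x)), w - 1),
            _clamp(int(round(y2)), h - 1), _clamp(int(round(x2)), w - 1),
        )
        np.maximum.at(canvas, (rr, cc), val)
        mask[rr, cc] |= val > 0.25
        y, x = y2, x2


def _draw_soma(canvas: np.ndarray, mask: np.ndarray, y: float, x: float, r: float) -> None:
    rr, cc = disk((y, x), max(r, 1.0), shape=mask.shape)
    canvas[rr, cc] = 1.0
    mask[rr, cc] = True


def render_tile(
    severity: float,
    params: MorphologyParams,
    tile_size: int,
    rng: np.random.Generator,
    return_masks: bool = False,
):
    """Render one clean (no noise, no plate effect) 3-channel tile on [0, 1].

    With ``return_masks=True`` also returns the pre-intensity boolean
    foreground masks per channel, for morphometric assertions on geometry.
    """
    if tile_size < 64:
        raise ValueError("tile_size must be >= 64")
    scale = tile_size / _REF_TILE
    geo = params.at(severity)
    soma_r = geo["microglia_soma_radius_px"] * scale
    if 2.0 * soma_r >= tile_size:
        raise ValueError("tile_size too small to contain one microglia soma")

    shape = (tile_size, tile_size)
    channels = [np.zeros(shape, dtype=np.float64) for _ in range(3)]
    masks = [np.zeros(shape, dtype=bool) for _ in range(3)]
    margin = max(4.0, 2.0 * soma_r)

    def _pos() -> tuple[float, float]:
        return (rng.uniform(margin, tile_size - margin),
                rng.uniform(margin, tile_size - margin))

    # nuclei: filled ellipses, severity-independent
    for _ in range(rng.poisson(params.nuclei_count_mean)):
        y, x = _pos()
        r = params.nucleus_radius_px * scale
        ry = r * rng.uniform(0.8, 1.2)
        rx = r * rng.uniform(0.8, 1.2)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(y, x, ry, rx, shape=shape, rotation=rot)
        channels[2][rr, cc] = 1.0
        masks[2][rr, cc] = True

    # neurons: small soma plus retracting branched neurites
    n_branch = int(round(geo["neurite_branches"]))
    n_len = geo["neurite_length_px"] * scale
    for _ in range(rng.poisson(params.neuron_count_mean)):
        y, x = _pos()
        _draw_soma(channels[1], masks[1], y, x, 0.9 * params.nucleus_radius_px * scale)
        for _ in range(n_branch):
            theta = rng.uniform(0, 2 * np.pi)
            _draw_walk(channels[1], masks[1], rng, y, x, theta, n_len)
            if n_branch >= 2:  # one child branch: shallow binary tree
                _draw_walk(channels[1], masks[1], rng, y, x, theta + rng.choice([-0.7, 0.7]),
                           n_len / 2.0)

    # microglia: disc soma with radiating processes (ramified -> ameboid)
    n_proc = int(round(geo["microglia_process_count"]))
    p_len = geo["microglia_process_length_px"] * scale
    for _ in range(rng.poisson(params.microglia_count_mean)):
        y, x = _pos()
        _draw_soma(channels[0], masks[0], y, x, soma_r)
        for k in range(n_proc):
            theta = 2 * np.pi * k / max(n_proc, 1) + rng.normal(0.0, 0.3)
            y0 = y + soma_r * np.sin(theta)
            x0 = x + soma_r * np.cos(theta)
            _draw_walk(channels[0], masks[0], rng, y0, x0, theta, p_len)

    img = np.stack(channels, axis=-1)
    # per-tile intensity jitter around each channel's base level
    base = np.asarray(params.intensity_base)
    levels = base * rng.uniform(0.75, 1.25, size=3)
    img = img * levels
    if return_masks:
        return img, {"microglia": masks[0], "neuron": masks[1], "nucleus": masks[2]}
    return img


def render_well(
    severity: float,
    params: MorphologyParams,
    plate_effect: PlateEffect,
    tile_size: int = _REF_TILE,
    seed: int = 0,
) -> list[np.ndarray]:
    """Render the nine 3x3 montage tiles of one well.

    Noise is added per tile, then the plate effect is applied as
    pixel -> clip(gain*pixel + offset) after any plate-level blur.
    Identical (severity, params, tile_size, seed) give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    tiles = []
    for _ in range(9):
        img = render_tile(severity, params, tile_size, rng)
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 1.0)
        tiles.append(plate_effect.apply(img))
    return tiles


# ---------------------------------------------------------------------------
# plate-level organisation


@dataclass(frozen=True)
class WellSpec:
    """One well's treatment: a severity class, optionally compound + dose."""

    well_id: str
    label: SeverityLabel
    compound: str | None = None
    dose: float = 0.0


@dataclass
class PlateData:
    """A plate: layout plus the single batch effect drawn for it.

    Tiles are rendered lazily and deterministically from ``seed`` so a
    full multi-plate experiment never has to hold all pixels in memory.
    """

    plate_id: str
    wells: list[WellSpec]
    params: MorphologyParams
    effect: PlateEffect
    seed: int
    compounds: Mapping[str, CompoundModel] = field(default_factory=dict)
    tile_size: int = _REF_TILE

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "plate_id": self.plate_id,
                "well_id": w.well_id,
                "class_index": w.label.class_index,
                "lps_ug_per_ml": w.label.lps_ug_per_ml,
                "compound": w.compound or "",
                "dose": w.dose,
            }
            for w in self.wells
        ]
        return pd.DataFrame(rows)

    def well_severity(self, spec: WellSpec) -> float:
        compound = self.compounds.get(spec.compound) if spec.compound else None
        return severity_from_treatment(spec.label, spec.dose if compound else None, compound)

    def _well_seed(self, index: int) -> np.random.SeedSequence:
        return np.random.SeedSequence([self.seed, index])

    def render_well(self, well_id: str) -> list[np.ndarray]:
        index = next(i for i, w in enumerate(self.wells) if w.well_id == well_id)
        spec = self.wells[index]
        seed = self._well_seed(index)
        rng = np.random.default_rng(seed)
        sev = self.well_severity(spec)
        tiles = []
        for _ in range(9):
            img = render_tile(sev, self.params, self.tile_size, rng)
            if self.params.noise_sd > 0:
                img = img + rng.normal(0.0, self.params.noise_sd, size=img.shape)
            tiles.append(self.effect.apply(np.clip(img, 0.0, 1.0)))
        return tiles

    def iter_wells(self) -> Iterator[tuple[WellSpec, list[np.ndarray]]]:
        for w in self.wells:
            yield w, self.render_well(w.well_id)


def generate_plate(
    plate_id: str,
    layout: Sequence[WellSpec],
    params: MorphologyParams,
    effect_sampler: PlateEffectSampler,
    seed: int,
    plate_seed: int | None = None,
    compounds: Mapping[str, CompoundModel] | None = None,
    tile_size: int = _REF_TILE,
) -> PlateData:
    """Assemble one plate: draw its single batch effect and bind the layout.

    ``seed`` drives well geometry; ``plate_seed`` (defaults to ``seed``)
    drives only the batch-effect draw, so two plates sharing ``seed`` but
    differing in ``plate_seed`` have identical cell geometry under different
    gain/offset — the pure batch-effect contrast.
    """
    ids = [w.well_id for w in layout]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate well_id in plate {plate_id}")
    if plate_seed is None:
        plate_seed = seed
    effect_rng = np.random.default_rng(np.random.SeedSequence([plate_seed, 0xE]))
    effect = effect_sampler.sample(effect_rng)
    return PlateData(
        plate_id=plate_id,
        wells=list(layout),
        params=params,
        effect=effect,
        seed=seed,
        compounds=dict(compounds or {}),
        tile_size=tile_size,
    )


def default_layout(
    wells_per_class: int = 5, classes: Sequence[int] = range(6)
) -> list[WellSpec]:
    """Standard training layout: each severity class replicated across wells."""
    wells = []
    for ci in classes:
        for r in range(wells_per_class):
            wells.append(WellSpec(well_id=f"C{ci}W{r}", label=SeverityLabel(ci)))
    return wells


def generate_experiment(
    n_plates: int = 7,
    wells_per_class: int = 5,
    params: MorphologyParams | None = None,
    effect_sampler: PlateEffectSampler | None = None,
    seed: int = 0,
    tile_size: int = _REF_TILE,
) -> list[PlateData]:
    """The default multi-plate design: n_plates x (6 classes x wells_per_class).

    Each plate gets its own geometry seed and batch effect, both derived
    from the single experiment seed.
    """
    params = params or MorphologyParams()
    effect_sampler = effect_sampler or PlateEffectSampler()
    layout = default_layout(wells_per_class)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_plates).astype(np.int64) % (2**31)
    plates = []
    for p in range(n_plates):
        plates.append(
            generate_plate(
                plate_id=f"P{p + 1}",
                layout=layout,
                params=params,
                effect_sampler=effect_sampler,
                seed=int(child_seeds[2 * p]),
                plate_seed=int(child_seeds[2 * p + 1]),
                tile_size=tile_size,
            )
        )
    return plates
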