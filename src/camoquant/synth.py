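"""Synthetic study generator: spectra, images, trajectories and trial tables.

Emulates the structure of the colour-change experiments so every pipeline
stage is testable without the original photographs: three uniform
backgrounds (flat dark grey ~12%, flat light grey ~72%, and an orange
long-pass of intermediate luminance), trial photographs of a fish blob with
two embedded grey standards behind a per-channel affine camera model,
fluorescence photos with a known number of supra-threshold pixels,
exponential-approach luminance trajectories sampled at the experiment-2
time points, and long-format trial tables with known fixed effects and
fish-level random variation.  Every generator is a pure function of
(config, seed) and returns ground truth alongside the data.

Default effect magnitudes, dispersions and sample sizes are set to the
scales of the study itself (24 + 18 fish; luminance differences between
backgrounds of order 0.02-0.06; fluorescent-area differences of order
1000-4500 pixels) so that recovery tests run at realistic signal-to-noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .images import ROI, StandardPatch, TrialImage
from .fluorescence import FluorescenceImage
from .kinetics import STANDARD_TIMES_S, Trajectory
from .observers import Observer, builtin_observer
from .spectra import Spectrum, WavelengthGrid, cone_catch, standard_illuminant_d65

__all__ = [
    "SimConfig",
    "make_background_spectra",
    "body_reflectance",
    "observer_catches",
    "simulate_trial_table",
    "render_trial_image",
    "render_fluorescence_image",
    "simulate_trajectories",
]

BACKGROUNDS = ("dark_grey", "medium_orange", "light_grey")
SPECIES = ("S_maderensis", "S_porcus")
TRIAL_OBSERVERS = ("triplefin", "goby")


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator."""

    seed: int = 0
    # design
    n_fish: dict = field(default_factory=lambda: {"S_maderensis": 24, "S_porcus": 18})
    n_fish_fluor: dict = field(default_factory=lambda: {"S_maderensis": 21, "S_porcus": 16})
    n_fish_kinetics: dict = field(default_factory=lambda: {"S_maderensis": 9, "S_porcus": 14})
    # backgrounds: two flat greys bracketing the standards, one orange long-pass
    dark_reflectance: float = 0.12
    light_reflectance: float = 0.72
    orange_low: float = 0.04
    orange_high: float = 0.65
    orange_half_rise_nm: float = 560.0
    orange_width_nm: float = 20.0
    # body luminance model (response scale): baseline level per species and
    # additive background responses, magnitudes as in the study's effect tables
    baseline_level: dict = field(default_factory=lambda: {
        "S_maderensis": 0.100, "S_porcus": 0.082})
    background_level_effect: dict = field(default_factory=lambda: {
        "S_maderensis": {"dark_grey": 0.0, "medium_orange": 0.024, "light_grey": 0.054},
        "S_porcus": {"dark_grey": 0.0, "medium_orange": 0.017, "light_grey": 0.042},
    })
    observer_level_effect: dict = field(default_factory=lambda: {
        "triplefin": 0.0, "goby": 0.010})
    # body redness (long-pass weight) per species and background
    baseline_redness: dict = field(default_factory=lambda: {
        "S_maderensis": 0.30, "S_porcus": 0.24})
    background_redness_effect: dict = field(default_factory=lambda: {
        "dark_grey": 0.0, "medium_orange": 0.10, "light_grey": 0.04})
    # random variation and noise
    fish_sd_log: float = 0.20          # between-fish intercept sd, log scale
    fish_slope_sd_log: float = 0.05    # between-fish background-slope sd, log scale
    residual_cv: float = 0.05          # within-cell gamma noise (CV)
    fish_redness_sd: float = 0.02
    hue_fish_sd: float = 0.020
    hue_residual_sd: float = 0.005
    timepoint_jitter_log: float = 0.01  # minute-1 vs minute-5 wobble
    # trial images
    image_shape: tuple = (96, 128)
    scale_px_per_cm: float = 10.0
    camera_gain_range: tuple = (0.5, 2.0)
    camera_offset_range: tuple = (0.0, 0.2)
    pixel_noise_sd: float = 0.0
    # fluorescence
    fluor_baseline_count: dict = field(default_factory=lambda: {
        "S_maderensis": 5000, "S_porcus": 3000})
    fluor_background_effect: dict = field(default_factory=lambda: {
        "S_maderensis": {"dark_grey": 0.0, "medium_orange": 2245.0, "light_grey": 4457.0},
        "S_porcus": {"dark_grey": 0.0, "medium_orange": 1364.0, "light_grey": 2308.0},
    })
    fluor_fish_sd_log: float = 0.30
    fluor_image_shape: tuple = (256, 320)
    fluor_supra_value: float = 150.0
    fluor_sub_value: float = 20.0
    fluor_reference_shutter_s: float = 0.01
    fluor_shutter_factor_range: tuple = (0.5, 1.5)
    # kinetics: exponential approach with species-specific half-times
    kinetics_half_time_s: dict = field(default_factory=lambda: {
        "S_maderensis": 10.0, "S_porcus": 5.0})
    kinetics_l0: float = 0.10
    kinetics_l60: float = 0.35
    kinetics_noise_sd: float = 0.02

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


# ---------------------------------------------------------------------------
# spectra

def _longpass(wl: np.ndarray, half_rise: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(wl - half_rise) / width))


def make_background_spectra(cfg: SimConfig,
                            grid: WavelengthGrid | None = None) -> dict[str, Spectrum]:
    """The three experimental backgrounds as reflectance spectra.

    dark_grey and light_grey are spectrally flat; medium_orange is a
    logistic long-pass whose luminance (for the scorpionfish 530 nm channel)
    lies between the two greys.
    """
    grid = grid or WavelengthGrid()
    wl = grid.wavelengths
    orange = cfg.orange_low + (cfg.orange_high - cfg.orange_low) * _longpass(
        wl, cfg.orange_half_rise_nm, cfg.orange_width_nm)
    spectra = {
        "dark_grey": Spectrum.flat(cfg.dark_reflectance, grid, name="dark_grey"),
        "medium_orange": Spectrum(wl, orange, kind="reflectance", name="medium_orange"),
        "light_grey": Spectrum.flat(cfg.light_reflectance, grid, name="light_grey"),
    }
    # the backgrounds must all be luminance-discriminable to the scorpionfish
    from .rnl import ConeCatchVector, achromatic_jnd

    sf = builtin_observer("scorpionfish")
    catch = {k: ConeCatchVector(sf, tuple(observer_catches(s, sf, grid)))
             for k, s in spectra.items()}
    names = list(spectra)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if achromatic_jnd(catch[a], catch[b]) < 1.0:
                raise ValueError(
                    f"backgrounds {a} and {b} are not luminance-discriminable "
                    "to the scorpionfish; adjust config"
                )
    return spectra


def body_reflectance(level: float, redness: float,
                     cfg: SimConfig, grid: WavelengthGrid | None = None) -> Spectrum:
    """Fish skin as a flat base plus a long-pass (reddish) component.

    ``level`` sets overall reflectance; ``redness`` in [0, 1) shifts weight
    into the long-pass component without changing the flat-part scale used
    to steer luminance.
    """
    grid = grid or WavelengthGrid()
    wl = grid.wavelengths
    r = level * ((1.0 - redness) + 2.0 * redness * _longpass(
        wl, cfg.orange_half_rise_nm, cfg.orange_width_nm))
    return Spectrum(wl, r, kind="reflectance", name="body")


def observer_catches(reflectance: Spectrum, observer: Observer,
                     grid: WavelengthGrid | None = None) -> np.ndarray:
    """Von Kries cone catches of a reflectance under D65 for an observer."""
    grid = grid or WavelengthGrid()
    ill = standard_illuminant_d65(grid)
    return np.array([
        cone_catch(reflectance, ill, s) for s in observer.sensitivities(grid)
    ])


# ---------------------------------------------------------------------------
# trial table (direct statistical simulation)

def _cell_luminance(cfg: SimConfig, species: str, background: str, observer: str) -> float:
    return (cfg.baseline_level[species]
            + cfg.background_level_effect[species][background]
            + cfg.observer_level_effect[observer])


def _cell_hue(cfg: SimConfig, species: str, background: str, observer: str) -> float:
    # hue of the median fish, computed through the spectral model
    level = _cell_luminance(cfg, species, background, "triplefin")
    redness = cfg.baseline_redness[species] + cfg.background_redness_effect[background]
    refl = body_reflectance(level, redness, cfg)
    obs = builtin_observer(observer)
    q = observer_catches(refl, obs)
    sw, mw, lw = q
    return ((lw + mw) - sw) / (lw + mw + sw)


def simulate_trial_table(cfg: SimConfig) -> tuple["pandas.DataFrame", dict]:
    """Long-format trial table with known ground-truth cell means.

    Luminance is generated as a Gamma response with log-link structure:
    log-normal fish intercepts and background slopes around log cell means,
    multiplicative gamma noise of the configured CV.  Hue is gaussian.
    Background order is balanced across fish within species.  Returns
    (table, ground_truth) where ground_truth holds the response-scale cell
    means of the median fish and the generating parameters.
    """
    import itertools

    import pandas as pd

    rng = cfg.rng(salt=101)
    rows = []
    orders = list(itertools.permutations(BACKGROUNDS))
    shape = 1.0 / cfg.residual_cv**2
    for species in SPECIES:
        for i in range(cfg.n_fish[species]):
            fish_id = f"{species}_{i:02d}"
            u = rng.normal(0.0, cfg.fish_sd_log)
            slope_dev = {bg: rng.normal(0.0, cfg.fish_slope_sd_log)
                         for bg in BACKGROUNDS[1:]}
            slope_dev[BACKGROUNDS[0]] = 0.0
            u_hue = rng.normal(0.0, cfg.hue_fish_sd)
            order = orders[i % len(orders)]
            for background in order:
                for observer in TRIAL_OBSERVERS:
                    eta = (np.log(_cell_luminance(cfg, species, background, observer))
                           + u + slope_dev[background])
                    mu = np.exp(eta)
                    lum = rng.gamma(shape, mu / shape)
                    hue = (_cell_hue(cfg, species, background, observer)
                           + u_hue + rng.normal(0.0, cfg.hue_residual_sd))
                    rows.append({
                        "fish_id": fish_id, "species": species,
                        "background": background, "observer": observer,
                        "luminance": lum, "hue": hue,
                    })
    table = pd.DataFrame(rows)
    truth = {
        "luminance_cell_means": {
            f"{sp}|{bg}|{ob}": _cell_luminance(cfg, sp, bg, ob)
            for sp in SPECIES for bg in BACKGROUNDS for ob in TRIAL_OBSERVERS
        },
        "hue_cell_means": {
            f"{sp}|{bg}|{ob}": _cell_hue(cfg, sp, bg, ob)
            for sp in SPECIES for bg in BACKGROUNDS for ob in TRIAL_OBSERVERS
        },
        "fish_sd_log": cfg.fish_sd_log,
        "residual_cv": cfg.residual_cv,
    }
    return table, truth


# ---------------------------------------------------------------------------
# trial images

def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  radii: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return ((yy - center[0]) / radii[0]) ** 2 + ((xx - center[1]) / radii[1]) ** 2 <= 1.0


def render_trial_image(cfg: SimConfig, body_catches: np.ndarray,
                       background_catches: np.ndarray,
                       rng: np.random.Generator | None = None
                       ) -> tuple[TrialImage, dict[str, ROI], dict]:
    """Render one camera-linear trial image with known ground truth.

    The scene: uniform background at the background catches, an elliptical
    fish blob at the body catches, and the two grey standards (flat 12% and
    72% reflectances, hence equal catches in every cone).  A per-channel
    affine camera (gain, offset) distorts the values;
    :func:`camoquant.images.normalize_with_standards` must invert it.
    """
    rng = rng or np.random.default_rng(0)
    body_catches = np.asarray(body_catches, dtype=float)
    background_catches = np.asarray(background_catches, dtype=float)
    if body_catches.shape != background_catches.shape:
        raise ValueError("body and background catch vectors must align")
    H, W = cfg.image_shape
    C = body_catches.size

    std12 = StandardPatch(bbox=(4, 16, 4, 24), nominal_reflectance=0.12)
    std72 = StandardPatch(bbox=(4, 16, 32, 52), nominal_reflectance=0.72)
    fish_center, fish_radii = (int(H * 0.62), int(W * 0.5)), (int(H * 0.22), int(W * 0.26))
    fish = _ellipse_mask((H, W), fish_center, fish_radii)
    for std in (std12, std72):
        if (fish & std.mask((H, W))).any():
            raise ValueError("fish blob overlaps a grey standard; adjust layout")

    img = np.empty((H, W, C))
    img[:] = background_catches
    img[fish] = body_catches
    img[std12.mask((H, W))] = std12.nominal_reflectance
    img[std72.mask((H, W))] = std72.nominal_reflectance

    gain = rng.uniform(*cfg.camera_gain_range, size=C)
    offset = rng.uniform(*cfg.camera_offset_range, size=C)
    pixels = img * gain + offset
    if cfg.pixel_noise_sd > 0:
        pixels = pixels + rng.normal(0.0, cfg.pixel_noise_sd, size=pixels.shape)

    trial = TrialImage(pixels=pixels, channel_meaning="camera-linear",
                       scale_px_per_cm=cfg.scale_px_per_cm,
                       standards=(std12, std72))
    bg_mask = np.zeros((H, W), dtype=bool)
    bg_mask[20:44, int(W * 0.82):W - 4] = True
    bg_mask &= ~fish
    rois = {"body": ROI(fish, "body"), "background": ROI(bg_mask, "background")}
    truth = {"body_catches": body_catches, "background_catches": background_catches,
             "gain": gain, "offset": offset}
    return trial, rois, truth


# ---------------------------------------------------------------------------
# fluorescence images

def render_fluorescence_image(cfg: SimConfig, true_count: int,
                              rng: np.random.Generator | None = None
                              ) -> tuple[FluorescenceImage, dict]:
    """Fluorescence photo with exactly ``true_count`` supra-threshold pixels.

    The stored red channel is scaled by the (randomized) shutter relative to
    the reference shutter, so the true count is only recovered after
    exposure equalization.
    """
    rng = rng or np.random.default_rng(0)
    H, W = cfg.fluor_image_shape
    mask = _ellipse_mask((H, W), (H * 0.5, W * 0.5), (H * 0.4, W * 0.4))
    n_mask = int(mask.sum())
    if not 0 <= true_count <= n_mask:
        raise ValueError(f"true_count {true_count} impossible for mask of {n_mask} px")
    red_true = np.full((H, W), 5.0)
    red_true[mask] = cfg.fluor_sub_value
    idx = np.flatnonzero(mask)
    chosen = rng.choice(idx, size=true_count, replace=False)
    red_true.flat[chosen] = cfg.fluor_supra_value

    factor = rng.uniform(*cfg.fluor_shutter_factor_range)
    shutter = cfg.fluor_reference_shutter_s * factor
    stored = np.clip(red_true * factor, 0.0, 255.0)
    img = FluorescenceImage(red_channel=stored, body_mask=mask, shutter_s=shutter)
    return img, {"true_count": true_count, "shutter_factor": factor}


def simulate_fluorescence_counts(cfg: SimConfig) -> tuple["pandas.DataFrame", dict]:
    """Per-fish true supra-threshold counts with fish-level variation."""
    import pandas as pd

    rng = cfg.rng(salt=202)
    rows = []
    for species in SPECIES:
        for i in range(cfg.n_fish_fluor[species]):
            fish_id = f"{species}_{i:02d}"
            u = rng.normal(0.0, cfg.fluor_fish_sd_log)
            for background in BACKGROUNDS:
                mean = (cfg.fluor_baseline_count[species]
                        + cfg.fluor_background_effect[species][background])
                count = int(round(mean * np.exp(u)))
                rows.append({"fish_id": fish_id, "species": species,
                             "background": background, "true_count": count})
    truth = {
        f"{sp}|{bg}": cfg.fluor_baseline_count[sp] + cfg.fluor_background_effect[sp][bg]
        for sp in SPECIES for bg in BACKGROUNDS
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# kinetics

def simulate_trajectories(cfg: SimConfig, species: str | None = None,
                          n: int | None = None,
                          half_time_s: float | None = None,
                          noise_sd: float | None = None,
                          rng: np.random.Generator | None = None
                          ) -> tuple[list[Trajectory], dict]:
    """Exponential-approach luminance trajectories at the standard times.

    L(t) = L60 + (L0 - L60) exp(-k t) with k = ln2 / half-time, plus
    gaussian sampling noise on every time point except t=0 and t=60 (whose
    values anchor the proportional-change normalization).
    """
    rng = rng or cfg.rng(salt=303)
    species_list = [species] if species else list(SPECIES)
    out, truth = [], {}
    for sp in species_list:
        ht = half_time_s if half_time_s is not None else cfg.kinetics_half_time_s[sp]
        k = np.log(2.0) / ht
        nsp = n if n is not None else cfg.n_fish_kinetics[sp]
        sd = cfg.kinetics_noise_sd if noise_sd is None else noise_sd
        truth[sp] = {"half_time_s": ht, "rate_constant": k, "n": nsp}
        for i in range(nsp):
            t = np.asarray(STANDARD_TIMES_S)
            clean = cfg.kinetics_l60 + (cfg.kinetics_l0 - cfg.kinetics_l60) * np.exp(-k * t)
            noise = rng.normal(0.0, sd, size=t.size)
            noise[0] = 0.0
            noise[-1] = 0.0
            lum = np.maximum(clean + noise, 1e-4)
            out.append(Trajectory(f"{sp}_k{i:02d}", sp, tuple(t), tuple(lum)))
    return out, truth
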