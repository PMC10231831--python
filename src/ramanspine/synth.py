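"""Forward model for fiber-probe Raman acquisitions on vertebral tissue.

Generates labeled raw spectra whose structure follows the measured data:
narrow Gaussian Raman bands placed from the band-assignment table with
amplitudes proportional to the ordinal star scores, a broad tissue
autofluorescence baseline, Poisson shot noise, detector dark counts, and
an optional smooth instrument-response vector.  Datasets emulate the
ex vivo study geometry (six balanced tissue classes, sites cycling over
three animals) and the in vivo drilling experiment (depth-ordered
trajectories in 1 mm steps with tissue mixing at layer interfaces).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BAND_TABLE, CONNECTIVE_TWEAKS, TISSUES, Band

_GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Drilling-trajectory layer labels and the tissue whose spectrum each
#: produces.  Interfaces are convex mixtures of their neighbours.
LAYER_TISSUE = {
    "cortical_bone": "bone",
    "trabecular_bone": "bone",
    "epidural": "fat",
    "spinal_cord": "spinal_cord",
}

#: Typical per-accumulation integration times (s) by tissue; bone and cord
#: are fast scatterers, the rest sit mid-range of the 0.4-20 s protocol.
DEFAULT_INTEGRATION_TIME = {
    "bone": 1.0,
    "spinal_cord": 0.8,
    "fat": 2.0,
    "cartilage": 2.0,
    "ligament": 2.0,
    "muscle": 2.0,
}


class InvalidArgumentError(ValueError):
    """Raised when an operation precondition is violated."""


@dataclass(frozen=True)
class SpectralAxis:
    """Common wavenumber grid, strictly increasing, in cm^-1."""

    wavenumbers: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        if wn.ndim != 1 or wn.size < 2:
            raise InvalidArgumentError("axis needs at least two bins")
        if np.any(np.diff(wn) <= 0):
            raise InvalidArgumentError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])


def make_axis(lo: float = 400.0, hi: float = 2000.0,
              resolution: float = 1.75) -> SpectralAxis:
    """Evenly spaced wavenumber axis: ``floor((hi-lo)/resolution)+1`` bins.

    The default covers the 400-2000 cm^-1 fingerprint window at 1.75 cm^-1
    spacing, giving 915 bins (>900, resolution ~1.8 cm^-1).
    """
    if resolution <= 0:
        raise InvalidArgumentError("resolution must be positive")
    if lo >= hi:
        raise InvalidArgumentError("lo must be below hi")
    n = int(np.floor((hi - lo) / resolution)) + 1
    wn = lo + resolution * np.arange(n)
    return SpectralAxis(wavenumbers=wn, resolution=resolution)


@dataclass
class GeneratorConfig:
    """Everything that parameterizes the synthetic forward model.

    amplitude_per_star scales the unit-area Gaussian of a 1-star band into
    integrated detector counts; the autofluorescence baseline is a wide
    positive Gaussian bump (characteristic width >> any Raman band);
    class_jitter is the fractional per-spectrum amplitude variability.
    """

    band_table: tuple[Band, ...] = BAND_TABLE
    amplitude_per_star: float = 1600.0
    baseline_amplitude: float = 1500.0
    baseline_center: float = 1100.0
    baseline_fwhm: float = 900.0
    baseline_offset_fraction: float = 0.2
    shot_noise: bool = True
    dark_mean: float = 100.0
    dark_sd: float = 5.0
    class_jitter: float = 0.10
    n_accumulations: int = 3
    response: np.ndarray | None = None
    mixing_fraction: float = 0.5
    connective_tweaks: dict[str, dict[float, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in CONNECTIVE_TWEAKS.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_per_star <= 0:
            raise InvalidArgumentError("amplitude_per_star must be positive")
        if self.class_jitter < 0:
            raise InvalidArgumentError("class_jitter must be >= 0")
        if self.baseline_fwhm <= 10 * max(b.width for b in self.band_table):
            raise InvalidArgumentError(
                "baseline width must be much larger than any Raman band")


@dataclass
class RawAcquisition:
    """Detector counts for one measurement site: one row per accumulation."""

    counts: np.ndarray          # (n_accumulations, n_bins)
    dark: np.ndarray            # (n_bins,) laser-off frame
    integration_time: float
    tissue_label: str
    site_metadata: dict
    axis: SpectralAxis

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        self.dark = np.asarray(self.dark, dtype=float)
        if np.any(self.counts < 0):
            raise InvalidArgumentError("counts must be non-negative")
        if self.counts.shape[1] != len(self.axis):
            raise InvalidArgumentError("counts/axis length mismatch")


@dataclass
class Trajectory:
    """Depth-ordered drilling acquisitions with ground-truth layers."""

    depths: np.ndarray                  # mm, strictly increasing 1 mm steps
    acquisitions: list[RawAcquisition]
    true_layers: list[str]
    breach_depth: float | None          # first spinal-cord step, mm

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        if not np.allclose(np.diff(d), 1.0):
            raise InvalidArgumentError("depths must increase in 1 mm steps")
        self.depths = d

    def __len__(self) -> int:
        return len(self.acquisitions)


def _gaussian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-area Gaussian profile."""
    sigma = fwhm * _GAUSS_FWHM_TO_SIGMA
    return np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def pure_profile(tissue: str, axis: SpectralAxis,
                 config: GeneratorConfig | None = None) -> np.ndarray:
    """Noiseless Raman emission of one tissue: the star-weighted band sum.

    Each table band contributes ``stars x amplitude_per_star`` times a
    unit-area Gaussian at the band center (range centers collapse to their
    midpoint); zero-star bands contribute nothing.  Cartilage/ligament
    perturbations from the config are applied multiplicatively per band.
    """
    config = config or GeneratorConfig()
    if tissue not in TISSUES:
        raise InvalidArgumentError(f"unknown tissue {tissue!r}")
    wn = axis.wavenumbers
    out = np.zeros_like(wn)
    tweaks = config.connective_tweaks.get(tissue, {})
    for band in config.band_table:
        stars = band.stars.get(tissue, 0)
        if stars == 0:
            continue
        scale = tweaks.get(band.center, 1.0)
        out += stars * config.amplitude_per_star * scale * _gaussian(
            wn, band.center, band.width)
    return out


def baseline_profile(axis: SpectralAxis, config: GeneratorConfig) -> np.ndarray:
    """Broad smooth autofluorescence background (counts)."""
    wn = axis.wavenumbers
    bump = np.exp(-0.5 * ((wn - config.baseline_center)
                          / (config.baseline_fwhm * _GAUSS_FWHM_TO_SIGMA)) ** 2)
    return config.baseline_amplitude * (config.baseline_offset_fraction + bump)


def _acquire(profile: np.ndarray, tissue: str, axis: SpectralAxis,
             config: GeneratorConfig, rng: np.random.Generator,
             site_metadata: dict | None = None) -> RawAcquisition:
    """Core detector model shared by single-tissue and mixed-layer spectra."""
    baseline = baseline_profile(axis, config)
    response = (np.ones(len(axis)) if config.response is None
                else np.asarray(config.response, dtype=float))
    if response.shape != (len(axis),) or np.any(response <= 0):
        raise InvalidArgumentError("response must be positive, axis-length")
    jitter = 1.0 + config.class_jitter * rng.standard_normal() if config.class_jitter else 1.0
    jitter = max(jitter, 0.05)
    lam = response * (profile * jitter + baseline)
    rows = []
    for _ in range(config.n_accumulations):
        signal = rng.poisson(lam).astype(float) if config.shot_noise else lam.copy()
        if config.dark_mean or config.dark_sd:
            signal = signal + np.maximum(
                np.round(rng.normal(config.dark_mean, config.dark_sd, len(axis))), 0.0)
        rows.append(np.maximum(signal, 0.0))
    if config.dark_mean or config.dark_sd:
        dark = np.maximum(
            np.round(rng.normal(config.dark_mean, config.dark_sd, len(axis))), 0.0)
    else:
        dark = np.zeros(len(axis))
    return RawAcquisition(
        counts=np.vstack(rows), dark=dark,
        integration_time=DEFAULT_INTEGRATION_TIME.get(tissue, 2.0),
        tissue_label=tissue, site_metadata=site_metadata or {}, axis=axis)


def generate_acquisition(tissue: str, config: GeneratorConfig, seed: int,
                         axis: SpectralAxis | None = None,
                         site_metadata: dict | None = None) -> RawAcquisition:
    """One seeded raw acquisition (>=3 accumulations) for *tissue*."""
    axis = axis or make_axis()
    rng = np.random.default_rng(seed)
    return _acquire(pure_profile(tissue, axis, config), tissue, axis, config,
                    rng, site_metadata)


@dataclass
class SpectraDataset:
    """Labeled collection of raw acquisitions on a shared axis."""

    acquisitions: list[RawAcquisition]
    axis: SpectralAxis

    @property
    def labels(self) -> np.ndarray:
        return np.array([a.tissue_label for a in self.acquisitions])

    def __len__(self) -> int:
        return len(self.acquisitions)


def generate_dataset(n_per_class: int = 27,
                     config: GeneratorConfig | None = None,
                     seed: int | None = None,
                     axis: SpectralAxis | None = None) -> SpectraDataset:
    """Balanced six-class dataset; default 27/class = 162 acquisitions.

    Sites cycle over three synthetic animals (one vertebra each), matching
    the ex vivo sampling pattern of roughly eight sites per tissue per
    vertebra across three animals.
    """
    if n_per_class < 2:
        raise InvalidArgumentError("n_per_class must be >= 2")
    config = config or GeneratorConfig()
    axis = axis or make_axis()
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    children = ss.spawn(n_per_class * len(TISSUES))
    acqs: list[RawAcquisition] = []
    k = 0
    for tissue in TISSUES:
        for i in range(n_per_class):
            animal = i % 3 + 1
            meta = {"animal": animal, "vertebra": animal, "site": i // 3 + 1}
            rng = np.random.default_rng(children[k])
            k += 1
            acqs.append(_acquire(pure_profile(tissue, axis, config), tissue,
                                 axis, config, rng, meta))
    return SpectraDataset(acquisitions=acqs, axis=axis)


# --- drilling trajectories -------------------------------------------------

#: Layer plans for the four in vivo drill trajectories (12, 12, 12 and 8
#: one-mm steps; 44 spectra total).  The 12-step plan walks cortical bone,
#: the cortical/trabecular interface, trabecular bone, the far cortex, the
#: epidural space and breaches the cord at 9 mm; the 8-step plan breaches
#: at 7 mm.
PLAN_12: tuple[tuple[str, int], ...] = (
    ("cortical_bone", 1), ("interface", 1), ("trabecular_bone", 3),
    ("interface", 1), ("cortical_bone", 1), ("epidural", 1), ("spinal_cord", 4))
PLAN_8: tuple[tuple[str, int], ...] = (
    ("cortical_bone", 1), ("trabecular_bone", 3), ("cortical_bone", 1),
    ("epidural", 1), ("spinal_cord", 2))


def in_vivo_plans() -> list[tuple[tuple[str, int], ...]]:
    """The default four-trajectory in vivo layer plans."""
    return [PLAN_12, PLAN_12, PLAN_12, PLAN_8]


def _expand_plan(layer_plan) -> list[str]:
    layers: list[str] = []
    for layer, n in layer_plan:
        if n < 1:
            raise InvalidArgumentError("layer step counts must be >= 1")
        layers.extend([layer] * n)
    if not layers:
        raise InvalidArgumentError("layer plan is empty")
    return layers


def generate_trajectory(layer_plan, config: GeneratorConfig | None = None,
                        seed: int = 0,
                        axis: SpectralAxis | None = None) -> Trajectory:
    """Depth-ordered synthetic drilling trajectory at 1 mm steps.

    ``interface`` steps emit a convex mixture (``mixing_fraction`` toward
    the deeper layer) of the adjacent layers' pure profiles, emulating the
    physical mixing of tissue in the drilling cavity; other layers emit
    their mapped tissue profile.  ``breach_depth`` is the depth of the
    first spinal-cord step, or ``None``.
    """
    config = config or GeneratorConfig()
    axis = axis or make_axis()
    layers = _expand_plan(layer_plan)
    children = np.random.SeedSequence(seed).spawn(len(layers))
    depths = np.arange(1.0, len(layers) + 1.0)
    acqs, breach = [], None
    for i, layer in enumerate(layers):
        if layer == "interface":
            prev_l = next((layers[j] for j in range(i - 1, -1, -1)
                           if layers[j] != "interface"), None)
            next_l = next((layers[j] for j in range(i + 1, len(layers))
                           if layers[j] != "interface"), None)
            if prev_l is None or next_l is None:
                raise InvalidArgumentError("interface needs two neighbour layers")
            m = config.mixing_fraction
            profile = ((1 - m) * pure_profile(LAYER_TISSUE[prev_l], axis, config)
                       + m * pure_profile(LAYER_TISSUE[next_l], axis, config))
            tissue = LAYER_TISSUE[prev_l]  # label the dominant shallow side
        else:
            if layer not in LAYER_TISSUE:
                raise InvalidArgumentError(f"unknown layer {layer!r}")
            tissue = LAYER_TISSUE[layer]
            profile = pure_profile(tissue, axis, config)
        if layer == "spinal_cord" and breach is None:
            breach = float(depths[i])
        rng = np.random.default_rng(children[i])
        acqs.append(_acquire(profile, tissue, axis, config, rng,
                             {"depth_mm": float(depths[i]), "layer": layer}))
    return Trajectory(depths=depths, acquisitions=acqs, true_layers=layers,
                      breach_depth=breach)


def noiseless_config(**overrides) -> GeneratorConfig:
    """Config with all stochastic terms switched off (testing aid)."""
    base = dict(shot_noise=False, baseline_amplitude=0.0, dark_mean=0.0,
                dark_sd=0.0, class_jitter=0.0)
    base.update(overrides)
    return GeneratorConfig(**base)
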