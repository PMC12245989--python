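"""Synthetic leaf-reflectance campaigns with the study's hierarchical design.

The generative model is a deliberately simple leaf optical stand-in (not a
physical PROSPECT implementation): reflectance is a smooth NIR plateau
attenuated by Gaussian absorption features tied to four abstract
constituent pools::

    R(lambda) = P(lambda) * exp(-sum_i c_i * a_i(lambda)) + eps(lambda)

where ``P`` is high in the NIR and declines into the SWIR, ``a_i`` are sums
of Gaussian features (chlorophyll absorbing in the blue and red, carotenoids
in the blue-green shoulder, water at 1450/1940 nm, dry matter in the SWIR)
and ``eps`` is white measurement noise.  Output is clipped to [0, 1].

A campaign draws tree-level, tree-by-date-level and leaf-level (dominant)
random effects on the *log* concentrations - multiplicative biology that
keeps concentrations positive - plus analogous effects on the log plateau
amplitude, which carry the broadband (integrated-reflectance) variability.
Elevated CO2 is expressed by default as a raised carotenoid:chlorophyll
ratio plus a small broadband brightening.

One global seed drives a splittable random stream: every tree, date cell
and leaf gets its own spawned substream, so enlarging the design does not
perturb effects already drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .spectra import GRID, Spectrum, SpectrumMeta, SpectrumSet, TREATMENTS

PIGMENTS = ("chlorophyll", "carotenoid", "water", "dry_matter")


@dataclass(frozen=True)
class AbsorptionFeature:
    """One Gaussian absorption feature: centre (nm), width (Gaussian sigma,
    nm) and absorbance strength per unit concentration."""

    center: float
    width: float
    strength: float

    def __post_init__(self) -> None:
        if not (350.0 <= self.center <= 2500.0):
            raise ValueError(f"feature centre {self.center} outside [350, 2500]")
        if self.width <= 0:
            raise ValueError("feature width must be > 0")
        if self.strength < 0:
            raise ValueError("feature strength must be >= 0")


#: Fixed package constants: absorption features per constituent pool.
#: Centres follow the qualitative leaf-optics picture - chlorophyll Soret
#: (~430 nm) and red (~680 nm) bands, a carotenoid blue-green shoulder
#: (~490 nm), water overtones at 1450/1940 nm and dry-matter (cellulose
#: and related) bands at 1720/2100/2300 nm.  They are not fitted to any
#: external coefficient library.
DEFAULT_FEATURES: dict[str, tuple[AbsorptionFeature, ...]] = {
    "chlorophyll": (
        AbsorptionFeature(390.0, 40.0, 0.085),
        AbsorptionFeature(430.0, 60.0, 0.48),
        AbsorptionFeature(620.0, 42.0, 0.39),
        AbsorptionFeature(680.0, 38.0, 0.30),
    ),
    "carotenoid": (
        AbsorptionFeature(490.0, 32.0, 0.70),
    ),
    "water": (
        AbsorptionFeature(1450.0, 100.0, 0.78),
        AbsorptionFeature(1940.0, 85.0, 0.74),
    ),
    "dry_matter": (
        AbsorptionFeature(1720.0, 60.0, 0.05),
        AbsorptionFeature(2100.0, 90.0, 0.26),
        AbsorptionFeature(2300.0, 80.0, 0.56),
    ),
}


def _absorbance_curves(features=None) -> dict[str, np.ndarray]:
    feats = DEFAULT_FEATURES if features is None else features
    curves = {}
    for pigment, fs in feats.items():
        a = np.zeros(GRID.size)
        for f in fs:
            a += f.strength * np.exp(-0.5 * ((GRID - f.center) / f.width) ** 2)
        curves[pigment] = a
    return curves


_DEFAULT_CURVES = _absorbance_curves()


def plateau(amplitude: float = 0.46, center: float = 1060.0,
            width: float = 630.0, floor: float = 0.025) -> np.ndarray:
    """Smooth absorption-free baseline: high NIR, declining into the SWIR."""
    shape = np.exp(-0.5 * ((GRID - center) / width) ** 2)
    return np.clip(amplitude * ((1.0 - floor) * shape + floor), 0.0, 1.0)


def simulate_leaf_spectrum(c_chl: float, c_car: float, c_w: float, c_dm: float,
                           plateau_params: dict | None = None,
                           noise_sd: float = 0.0,
                           rng: np.random.Generator | None = None,
                           meta: SpectrumMeta | None = None) -> Spectrum:
    """Simulate one leaf spectrum from constituent concentrations.

    Concentrations are non-negative abstract units; ``plateau_params`` are
    passed to :func:`plateau`.  With ``noise_sd`` > 0 an ``rng`` must be
    supplied (determinism is the caller's contract).
    """
    conc = dict(zip(PIGMENTS, (c_chl, c_car, c_w, c_dm)))
    for name, c in conc.items():
        if c < 0:
            raise ValueError(f"negative concentration for {name}: {c}")
    base = plateau(**(plateau_params or {}))
    absorbance = np.zeros(GRID.size)
    for name, c in conc.items():
        absorbance += c * _DEFAULT_CURVES[name]
    refl = base * np.exp(-absorbance)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        refl = refl + rng.normal(0.0, noise_sd, size=GRID.size)
    return Spectrum(np.clip(refl, 0.0, 1.0), meta)


@dataclass
class LeafSimConfig:
    """Generative parameters for a simulated campaign.

    Defaults emulate the measured study design: 2 treatments x 2 arrays per
    treatment x 2 trees per array x 4 dates x 30 leaves (960 spectra;
    set ``treatment_totals`` to realized per-treatment totals, e.g.
    ``{"aCO2": 469, "eCO2": 463}``, to drop leaves round-robin and match an
    actual campaign's 932).  Variance-component SDs act on log
    concentrations / log plateau amplitude; the leaf level dominates.
    """

    n_arrays_per_treatment: int = 2
    n_trees_per_array: int = 2
    dates: tuple[str, ...] = (
        "2023-07-25", "2023-08-10", "2023-08-24", "2023-10-06",
    )
    n_leaves_per_tree_per_date: int = 30
    treatment_totals: dict | None = None
    seed: int = 0

    # mean concentrations (abstract units)
    chlorophyll: float = 5.0
    carotenoid: float = 1.0
    water: float = 1.1
    dry_matter: float = 1.0

    # eCO2 multipliers on mean concentrations (default: carotenoid up ->
    # raised carotenoid:chlorophyll ratio)
    eco2_multipliers: dict = field(default_factory=lambda: {"carotenoid": 1.28})

    # hierarchy SDs on log concentrations (per pigment, independent draws)
    sigma_tree: float = 0.077
    sigma_tree_date: float = 0.096
    sigma_leaf: float = 0.275

    # plateau (absorption-free baseline) and its hierarchy on log amplitude
    plateau_amplitude: float = 0.46
    plateau_center: float = 1060.0
    plateau_width: float = 630.0
    plateau_floor: float = 0.025
    eco2_plateau_multiplier: float = 1.03
    plateau_sigma_tree: float = 0.02
    plateau_sigma_tree_date: float = 0.044
    plateau_sigma_leaf: float = 0.139

    # white spectral noise SD (reflectance fraction)
    noise_sd: float = 0.004

    def __post_init__(self) -> None:
        if self.n_arrays_per_treatment < 1 or self.n_trees_per_array < 1:
            raise ValueError("need at least one array and one tree per array")
        if len(self.dates) < 1:
            raise ValueError("need at least one measurement date")
        if self.n_leaves_per_tree_per_date < 1:
            raise ValueError("need at least one leaf per tree per date")
        for name in ("sigma_tree", "sigma_tree_date", "sigma_leaf",
                     "plateau_sigma_tree", "plateau_sigma_tree_date",
                     "plateau_sigma_leaf", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in PIGMENTS:
            if getattr(self, name) <= 0:
                raise ValueError(f"mean {name} concentration must be > 0")
        for key in self.eco2_multipliers:
            if key not in PIGMENTS:
                raise ValueError(f"unknown pigment in eco2_multipliers: {key}")
        if self.treatment_totals is not None:
            bad = set(self.treatment_totals) - set(TREATMENTS)
            if bad:
                raise ValueError(f"unknown treatments in treatment_totals: {bad}")

    # -- serialization --------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["dates"] = list(d["dates"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "LeafSimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "dates" in d:
            d["dates"] = tuple(d["dates"])
        return cls(**d)

    # -- derived quantities ---------------------------------------------
    @property
    def plateau_params(self) -> dict:
        return {
            "amplitude": self.plateau_amplitude,
            "center": self.plateau_center,
            "width": self.plateau_width,
            "floor": self.plateau_floor,
        }

    def mean_concentrations(self, treatment: str) -> dict:
        conc = {p: getattr(self, p) for p in PIGMENTS}
        if treatment == "eCO2":
            for p, m in self.eco2_multipliers.items():
                conc[p] = conc[p] * m
        return conc


def _leaf_allocation(config: LeafSimConfig) -> dict:
    """Leaves per (treatment, tree, date) cell.

    With ``treatment_totals`` set, the total for each treatment is spread
    round-robin over its tree x date cells (cells listed in (tree, date)
    order get the remainder leaves first), exactly reproducing a realized
    unbalanced campaign size.
    """
    n_trees = config.n_arrays_per_treatment * config.n_trees_per_array
    n_cells = n_trees * len(config.dates)
    alloc = {}
    for trt in TREATMENTS:
        if config.treatment_totals and trt in config.treatment_totals:
            total = int(config.treatment_totals[trt])
            base, extra = divmod(total, n_cells)
            counts = [base + (1 if i < extra else 0) for i in range(n_cells)]
        else:
            counts = [config.n_leaves_per_tree_per_date] * n_cells
        alloc[trt] = counts
    return alloc


def simulate_campaign(config: LeafSimConfig) -> SpectrumSet:
    """Draw a full labelled campaign; bit-reproducible under ``config.seed``."""
    curves = _DEFAULT_CURVES
    log_mean = {}
    for trt in TREATMENTS:
        conc = config.mean_concentrations(trt)
        log_mean[trt] = np.array([np.log(conc[p]) for p in PIGMENTS])
    log_plateau_amp = {
        "aCO2": np.log(config.plateau_amplitude),
        "eCO2": np.log(config.plateau_amplitude * config.eco2_plateau_multiplier),
    }
    base_shape = plateau(amplitude=1.0, center=config.plateau_center,
                         width=config.plateau_width, floor=config.plateau_floor)

    alloc = _leaf_allocation(config)
    n_trees_per_trt = config.n_arrays_per_treatment * config.n_trees_per_array
    root = np.random.SeedSequence(config.seed)
    tree_seeds = root.spawn(2 * n_trees_per_trt)

    spectra = []
    for t_idx, trt in enumerate(TREATMENTS):
        prefix = "A" if trt == "aCO2" else "E"
        cell_counts = alloc[trt]
        for tree_i in range(n_trees_per_trt):
            array_i = tree_i // config.n_trees_per_array
            array_id = f"{prefix}{array_i + 1}"
            tree_id = f"{array_id}-T{tree_i % config.n_trees_per_array + 1}"
            tree_ss = tree_seeds[t_idx * n_trees_per_trt + tree_i]
            # substream 0: tree effects; substreams 1..: one per date
            date_seeds = tree_ss.spawn(len(config.dates) + 1)
            tree_rng = np.random.default_rng(date_seeds[0])
            tree_eff = tree_rng.normal(0.0, config.sigma_tree, size=len(PIGMENTS))
            tree_plateau_eff = tree_rng.normal(0.0, config.plateau_sigma_tree)
            for d_idx, date in enumerate(config.dates):
                n_leaves = cell_counts[tree_i * len(config.dates) + d_idx]
                cell_ss = date_seeds[d_idx + 1]
                # substream 0: tree-by-date effects; substreams 1..: leaves
                leaf_seeds = cell_ss.spawn(n_leaves + 1)
                cell_rng = np.random.default_rng(leaf_seeds[0])
                td_eff = cell_rng.normal(0.0, config.sigma_tree_date,
                                         size=len(PIGMENTS))
                td_plateau_eff = cell_rng.normal(0.0, config.plateau_sigma_tree_date)
                for leaf_i in range(n_leaves):
                    leaf_rng = np.random.default_rng(leaf_seeds[leaf_i + 1])
                    leaf_eff = leaf_rng.normal(0.0, config.sigma_leaf,
                                               size=len(PIGMENTS))
                    leaf_plateau_eff = leaf_rng.normal(
                        0.0, config.plateau_sigma_leaf)
                    logc = log_mean[trt] + tree_eff + td_eff + leaf_eff
                    conc = np.exp(logc)
                    amp = np.exp(log_plateau_amp[trt] + tree_plateau_eff
                                 + td_plateau_eff + leaf_plateau_eff)
                    absorb = np.zeros(GRID.size)
                    for p_idx, p in enumerate(PIGMENTS):
                        absorb += conc[p_idx] * curves[p]
                    refl = np.clip(amp, 0.0, None) * base_shape * np.exp(-absorb)
                    if config.noise_sd > 0:
                        refl = refl + leaf_rng.normal(0.0, config.noise_sd,
                                                      size=GRID.size)
                    meta = SpectrumMeta(
                        treatment=trt, array_id=array_id, tree_id=tree_id,
                        date=date, leaf_index=leaf_i + 1,
                    )
                    spectra.append(Spectrum(np.clip(refl, 0.0, 1.0), meta))
    return SpectrumSet(spectra)
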