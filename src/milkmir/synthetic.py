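"""Synthetic milk-spectra trials with the structure the analysis assumes.

No raw spectra from the tie-rail trial are deposited, so this module
generates datasets with the same statistical and spectroscopic anatomy:

* a blocked 2-period trial — 48 cows, 4 treatments (TR1-TR4), 2 start
  periods of 6 blocks with one cow per treatment per block, 10 weekly
  samples per cow;
* concentration-driven spectra — each analyte contributes a sum of
  pseudo-Voigt bands (centers from the molecule band library) scaled
  linearly by concentration (Beer-Lambert mixing) on top of a fixed smooth
  milk background, plus white instrument noise;
* injected treatment effects — multiplicative concentration shifts,
  by default raising BHB, acetone, citrate and free fatty acids and
  lowering lactose for TR3 (the negative-energy-balance signature);
* a composition table (fat, protein, lactose, urea, BHB) derived from the
  same concentrations used to build the spectra.

All randomness flows from one seed through a per-cow generator hierarchy,
so identical seeds give bit-identical trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidArgumentError
from .grid import WavenumberGrid, make_instrument_grid
from .interpret import pseudo_voigt
from .spectra import SpectraSet

__all__ = [
    "ComponentModel",
    "TrialConfig",
    "DEFAULT_COMPONENTS",
    "component_spectrum",
    "base_milk_spectrum",
    "simulate_trial",
    "simulate_spiking_series",
]


@dataclass(frozen=True)
class ComponentModel:
    """Spectral signature of one milk component.

    ``bands`` holds ``(center cm^-1, fwhh cm^-1, eta, intensity)`` tuples,
    where intensity is absorbance per concentration unit at band center.
    """

    name: str
    bands: tuple
    baseline: float
    units: str

    def __post_init__(self):
        for center, fwhh, eta, intensity in self.bands:
            if fwhh <= 0 or not 0 <= eta <= 1 or intensity < 0:
                raise InvalidArgumentError(f"invalid band in {self.name}: "
                                           f"({center}, {fwhh}, {eta}, {intensity})")


def _cm(name, bands, baseline, units):
    return ComponentModel(name=name, bands=tuple(bands), baseline=baseline, units=units)


#: Default component signatures.  Band centers of the minor components come
#: from the spiked-milk band library; per-band relative intensities weight
#: each molecule's most prominent milk band highest (1405 for BHB, 1239 for
#: acetone).  Major-component band positions are the classical milk MIR
#: assignments (fat esters/CH stretch, protein amide I/II, lactose C-O).
DEFAULT_COMPONENTS = {
    "fat": _cm("fat", [(2919, 30, 0.4, 0.050), (2851, 25, 0.4, 0.035),
                       (1745, 20, 0.4, 0.045), (1460, 20, 0.5, 0.012)],
               4.0, "pct"),
    "protein": _cm("protein", [(1650, 50, 0.5, 0.055), (1548, 45, 0.5, 0.040)],
                   3.4, "pct"),
    "lactose": _cm("lactose", [(1040, 35, 0.5, 0.055), (1076, 30, 0.5, 0.050),
                               (1157, 30, 0.5, 0.020)],
                   4.6, "pct"),
    "urea": _cm("urea", [(1457, 25, 0.5, 0.0008), (1156, 25, 0.5, 0.0006)],
                14.0, "mg/dL"),
    "bhb": _cm("bhb", [(1405, 18, 0.5, 0.30), (1316, 16, 0.5, 0.20),
                       (1554, 18, 0.5, 0.15), (1077, 16, 0.5, 0.12),
                       (2926, 20, 0.5, 0.08)],
               0.055, "mmol/L"),
    "acetone": _cm("acetone", [(1239, 16, 0.5, 0.30), (1373, 14, 0.5, 0.18),
                               (1414, 14, 0.5, 0.15), (1690, 16, 0.5, 0.10)],
                   0.05, "mmol/L"),
    "citrate": _cm("citrate", [(1394, 20, 0.5, 0.0020), (1557, 20, 0.5, 0.0015),
                               (1248, 18, 0.5, 0.0012), (1078, 16, 0.5, 0.0010),
                               (2926, 20, 0.5, 0.0005)],
                   9.0, "mmol/L"),
    "free_fatty_acids": _cm("free_fatty_acids",
                            [(1716, 22, 0.5, 0.020), (3008, 14, 0.5, 0.010),
                             (2927, 20, 0.5, 0.012), (2857, 18, 0.5, 0.008)],
                            0.8, "mmol/L"),
    # Broad "matrix" constituents standing in for the many other milk
    # components that vary from cow to cow.  They give every retained
    # wavenumber correlated biological variance (real milk spectra are
    # structure-dominated: the top components explain ~95% of variance),
    # carry no treatment information and do not appear in the composition
    # table.
    "matrix_a": _cm("matrix_a", [(1012, 40, 0.5, 0.020), (1488, 30, 0.5, 0.015),
                                 (2950, 35, 0.4, 0.012)], 1.0, "au"),
    "matrix_b": _cm("matrix_b", [(1120, 35, 0.5, 0.018), (1345, 28, 0.5, 0.014),
                                 (1765, 25, 0.5, 0.010)], 1.0, "au"),
    "matrix_c": _cm("matrix_c", [(1185, 30, 0.5, 0.015), (1602, 35, 0.5, 0.012),
                                 (2835, 30, 0.4, 0.010)], 1.0, "au"),
    "matrix_d": _cm("matrix_d", [(965, 35, 0.5, 0.014), (1270, 26, 0.5, 0.012),
                                 (1790, 24, 0.5, 0.008), (3035, 30, 0.4, 0.008)],
                    1.0, "au"),
    "matrix_e": _cm("matrix_e", [(1060, 30, 0.5, 0.016), (1520, 32, 0.5, 0.012),
                                 (2885, 30, 0.4, 0.010)], 1.0, "au"),
    "matrix_f": _cm("matrix_f", [(1218, 28, 0.5, 0.013), (1430, 26, 0.5, 0.012),
                                 (1755, 24, 0.5, 0.008)], 1.0, "au"),
}

ANALYTE_ORDER = list(DEFAULT_COMPONENTS)

#: analyte -> composition-table column
COMPOSITION_MAP = {
    "fat": "fat_pct",
    "protein": "protein_pct",
    "lactose": "lactose_pct",
    "urea": "urea_mgdl",
    "bhb": "bhb_mmoll",
}


def component_spectrum(model: ComponentModel, concentration: float,
                       grid: WavenumberGrid) -> np.ndarray:
    """Absorbance contribution of one component at a given concentration."""
    if concentration < 0:
        raise InvalidArgumentError("concentration must be >= 0")
    out = np.zeros(len(grid))
    for center, fwhh, eta, intensity in model.bands:
        out += pseudo_voigt(grid.points, center, intensity, fwhh, eta)
    return concentration * out


def base_milk_spectrum(grid: WavenumberGrid) -> np.ndarray:
    """Fixed smooth milk background (water association, broad matrix bands).

    Only relative spectral changes matter to the pipeline, so the
    background is a deterministic sum of very broad bands plus a gentle
    slope; it carries no information about treatments.
    """
    x = grid.points
    bg = (
        0.40 * np.exp(-0.5 * ((x - 1640) / 220.0) ** 2)
        + 0.15 * np.exp(-0.5 * ((x - 1080) / 180.0) ** 2)
        + 0.10 * np.exp(-0.5 * ((x - 2900) / 260.0) ** 2)
        + 0.05 * (x - x[0]) / (x[-1] - x[0])
        + 0.30
    )
    return bg


@dataclass
class TrialConfig:
    """Configuration of a synthetic blocked tie-rail trial.

    The defaults are the trial's design: 48 cows on 4 treatments, 2 start
    periods with 6 blocks each (one cow per treatment per block), 10 weekly
    samples.  ``effect_map`` gives per-treatment multiplicative
    concentration shifts, e.g. ``{"TR3": {"bhb": 1.15, "lactose": 0.85}}``.
    """

    seed: int
    n_cows: int = 48
    treatments: tuple = ("TR1", "TR2", "TR3", "TR4")
    n_starts: int = 2
    blocks_per_start: int = 6
    weeks: int = 10
    effect_map: dict = field(default_factory=dict)
    cow_effect_sd: float = 0.10
    week_drift: float = 0.003
    noise_sd: float = 0.0001
    # broad per-cow instrumental/matrix factors that vector normalization
    # and the first derivative are designed to remove: multiplicative
    # intensity (path length / scatter), additive offset, baseline tilt
    intensity_sd: float = 0.02
    offset_sd: float = 0.01
    tilt_sd: float = 0.005
    components: dict = field(default_factory=lambda: dict(DEFAULT_COMPONENTS))

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        g = len(self.treatments)
        if self.n_cows != self.n_starts * self.blocks_per_start * g:
            raise ConfigError(
                f"n_cows = {self.n_cows} incompatible with "
                f"{self.n_starts} starts x {self.blocks_per_start} blocks x {g} treatments"
            )
        if self.cow_effect_sd < 0 or self.noise_sd < 0:
            raise ConfigError("dispersion parameters must be >= 0")
        for trt, shifts in self.effect_map.items():
            if trt not in self.treatments:
                raise ConfigError(f"effect for unknown treatment {trt!r}")
            for analyte, mult in shifts.items():
                if analyte not in self.components:
                    raise ConfigError(f"effect on unknown analyte {analyte!r}")
                if mult < 0:
                    raise ConfigError("effect multipliers must be >= 0")

    @classmethod
    def default(cls, seed: int, effect_scale: float = 1.5, **kwargs) -> "TrialConfig":
        """Standard study conditions.

        The TR3 concentration shift is ``effect_scale`` times the
        cow-to-cow SD (delta = effect_scale * cow_effect_sd), up for the
        negative-energy-balance markers and down for lactose;
        ``effect_scale=0`` gives a null trial.
        """
        cow_sd = kwargs.get("cow_effect_sd", 0.10)
        delta = effect_scale * cow_sd
        effect_map = {} if delta == 0 else {"TR3": {
            "bhb": 1 + delta, "acetone": 1 + delta, "citrate": 1 + delta,
            "free_fatty_acids": 1 + delta, "lactose": 1 - delta,
        }}
        return cls(seed=seed, effect_map=effect_map, **kwargs)


def _design(config: TrialConfig) -> pd.DataFrame:
    """Deterministic cow-level design: RCBD, one cow per treatment per block."""
    rows = []
    cow = 0
    n_blocks_total = config.n_starts * config.blocks_per_start
    n_primi_blocks = max(1, round(n_blocks_total / 4))  # ~12 of 48 cows primiparous
    dims = ["early", "mid", "late"]
    b_global = 0
    for start in range(1, config.n_starts + 1):
        for block in range(1, config.blocks_per_start + 1):
            parity = "primiparous" if b_global < n_primi_blocks else "multiparous"
            dim_class = dims[b_global % 3]
            for trt in config.treatments:
                cow += 1
                rows.append({
                    "cow_id": f"C{cow:02d}", "treatment": trt, "start": start,
                    "block": f"B{block}", "parity": parity, "dim_class": dim_class,
                })
            b_global += 1
    return pd.DataFrame(rows)


def simulate_trial(config: TrialConfig):
    """Generate one synthetic trial.

    Returns ``(spectra, metadata, composition)``: a raw
    :class:`~milkmir.spectra.SpectraSet` with one sample per cow-week on the
    1060-point instrument grid, the per-sample metadata table, and the
    analyzer-style composition table derived from the same concentrations
    that built the spectra (before spectral noise).
    """
    grid = make_instrument_grid(1060, 925, 5008)
    analytes = list(config.components)
    unit = np.vstack([
        component_spectrum(config.components[a], 1.0, grid) for a in analytes
    ])
    base = base_milk_spectrum(grid)
    baselines = np.array([config.components[a].baseline for a in analytes])

    design = _design(config)
    children = np.random.SeedSequence(config.seed).spawn(len(design))

    ramp = (grid.points - grid.points.mean()) / (grid.points[-1] - grid.points[0])
    sample_ids, values, meta_rows, comp_rows = [], [], [], []
    for (_, cow), child in zip(design.iterrows(), children):
        rng = np.random.default_rng(child)
        cow_fx = np.exp(rng.normal(0.0, config.cow_effect_sd, size=len(analytes)))
        gain = np.exp(rng.normal(0.0, config.intensity_sd))
        offset = rng.normal(0.0, config.offset_sd)
        tilt = rng.normal(0.0, config.tilt_sd)
        shifts = np.array([
            config.effect_map.get(cow["treatment"], {}).get(a, 1.0) for a in analytes
        ])
        noise = rng.normal(0.0, config.noise_sd, size=(config.weeks, len(grid)))
        for week in range(1, config.weeks + 1):
            conc = baselines * cow_fx * (1.0 + config.week_drift * week) * shifts
            sid = f"{cow['cow_id']}_w{week:02d}"
            sample_ids.append(sid)
            values.append(gain * (base + conc @ unit) + offset + tilt * ramp
                          + noise[week - 1])
            meta_rows.append({
                "sample_id": sid, "cow_id": cow["cow_id"], "week": week,
                "treatment": cow["treatment"], "start": cow["start"],
                "block": cow["block"], "parity": cow["parity"],
                "dim_class": cow["dim_class"],
            })
            comp = {"cow_id": cow["cow_id"], "week": week}
            for a, c in zip(analytes, conc):
                col = COMPOSITION_MAP.get(a)
                if col:
                    comp[col] = float(c)
            comp_rows.append(comp)

    spectra = SpectraSet(sample_ids=sample_ids, grid=grid,
                         values=np.vstack(values), pretreatment="raw")
    return spectra, pd.DataFrame(meta_rows), pd.DataFrame(comp_rows)


def simulate_spiking_series(molecule: str, levels, grid: WavenumberGrid | None = None,
                            seed: int = 0, noise_sd: float = 0.0005,
                            components: dict | None = None):
    """Emulate the spiking experiment: base milk plus increasing additions.

    ``levels`` are added concentrations (same units as the component's
    baseline), strictly increasing, at least 3.  Returns
    ``(spectra, series_metadata)`` where the metadata frame carries the
    concentration of each sample in order.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size < 3 or not np.all(np.diff(levels) > 0):
        raise InvalidArgumentError("need >= 3 strictly increasing levels")
    components = components or DEFAULT_COMPONENTS
    if molecule not in components:
        raise InvalidArgumentError(f"unknown molecule {molecule!r}")
    if grid is None:
        grid = make_instrument_grid(1060, 925, 5008)
    model = components[molecule]
    base = base_milk_spectrum(grid)
    rng = np.random.default_rng(seed)
    rows, ids = [], []
    for i, level in enumerate(levels):
        rows.append(base + component_spectrum(model, level, grid)
                    + rng.normal(0.0, noise_sd, size=len(grid)))
        ids.append(f"{molecule}_L{i}")
    spectra = SpectraSet(sample_ids=ids, grid=grid, values=np.vstack(rows),
                         pretreatment="raw")
    meta = pd.DataFrame({"sample_id": ids, "concentration": levels})
    return spectra, meta
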