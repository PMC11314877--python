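"""Synthetic wheat-canopy spectra with a known SPAD -> reflectance encoding.

The generator emulates the qualitative physics of chlorophyll in canopy
reflectance so every downstream stage (smoothing, fractional
differentiation, band selection, calibration) can be exercised against a
known ground truth:

* a low visible baseline rising through a logistic *red edge* to an NIR
  plateau, with the red-edge inflection shifting to longer wavelengths as
  SPAD rises (stress therefore "blue-shifts" the edge);
* chlorophyll absorption wells at 450 nm and 680 nm (the *red valley*)
  whose depth saturates with SPAD as ``d_max * spad / (spad + K)``;
* a Gaussian *green peak* at 550 nm whose height falls as SPAD rises, so
  stressed (low-SPAD) canopies show the taller green peak;
* weak water-absorption dips near 970 and 1200 nm;
* additive Gaussian channel noise plus optional "burr" spikes.

SPAD values per treatment group are truncated-normal draws whose default
means, SDs and ranges match the four CO2-leakage treatments of the study
design (control and 1/3/5 L min^-1).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import NamedTuple

import numpy as np

from .dataset import SpectraSet, Spectrum

__all__ = [
    "GroupParams",
    "SyntheticConfig",
    "sample_spad",
    "generate_spectrum",
    "generate_dataset",
    "add_burr_noise",
]


class GroupParams(NamedTuple):
    """Truncated-normal SPAD distribution for one treatment group."""

    spad_mean: float
    spad_sd: float
    spad_min: float
    spad_max: float


#: Per-treatment SPAD statistics (mean, SD, min, max) of the study design.
DEFAULT_GROUP_PARAMS: dict[str, GroupParams] = {
    "control": GroupParams(59.5, 3.7, 51.1, 65.5),
    "1L": GroupParams(42.9, 15.6, 10.2, 62.0),
    "3L": GroupParams(36.6, 17.7, 5.5, 60.1),
    "5L": GroupParams(35.3, 18.3, 7.0, 60.2),
}

# Spectral shape constants (reflectance units / nm).  The absolute levels
# are generic green-vegetation values; what matters downstream is the
# monotone SPAD encoding documented in the module docstring.
VIS_BASE = 0.30  # visible-region baseline reflectance
NIR_PLATEAU = 0.55  # near-infrared plateau reflectance
RED_EDGE_WIDTH = 4.0  # logistic width of the red edge, nm
GREEN_PEAK_CENTER = 550.0
GREEN_PEAK_SIGMA = 20.0
GREEN_PEAK_MAX = 0.12  # green-peak height at SPAD -> 0
GREEN_PEAK_K = 25.0  # SPAD scale of green-peak decay
WELL_BLUE = (450.0, 20.0, 0.15)  # centre nm, sigma nm, max depth
WELL_RED = (680.0, 15.0, 0.22)
DEPTH_K = 20.0  # SPAD half-saturation of well depth
WATER_DIPS = ((970.0, 25.0, 0.04), (1200.0, 30.0, 0.06))
REFLECTANCE_CLIP = (0.0, 1.2)


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic experiment.

    Defaults reproduce the study conditions: four treatment groups with
    the SPAD statistics above, 30 samples per group, a 350-1350 nm grid
    at 1 nm, red edge at 700 nm + 0.4 nm per SPAD unit, and mild channel
    noise.
    """

    group_params: dict[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS)
    )
    n_per_group: int = 30
    wavelength_lo: float = 350.0
    wavelength_hi: float = 1350.0
    step: float = 1.0
    noise_sd: float = 0.01
    burr_rate: float = 0.0
    burr_amplitude: float = 0.1
    red_edge_base: float = 700.0
    red_edge_shift_per_spad: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_params = {
            g: GroupParams(*p) for g, p in self.group_params.items()
        }
        for g, p in self.group_params.items():
            if not p.spad_min < p.spad_max:
                raise ValueError(f"group {g!r}: spad_min must be < spad_max")
            if p.spad_sd < 0:
                raise ValueError(f"group {g!r}: spad_sd must be >= 0")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.burr_rate <= 1:
            raise ValueError("burr_rate must be in [0, 1]")
        if not self.wavelength_lo < self.wavelength_hi:
            raise ValueError("wavelength_lo must be < wavelength_hi")

    def grid(self) -> np.ndarray:
        n = int(round((self.wavelength_hi - self.wavelength_lo) / self.step)) + 1
        return self.wavelength_lo + self.step * np.arange(n)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["group_params"] = {g: GroupParams(*p) for g, p in raw["group_params"].items()}
        return cls(**raw)


def sample_spad(
    group: str, n: int, config: SyntheticConfig, seed: int
) -> np.ndarray:
    """Draw ``n`` SPAD values for ``group`` from its truncated normal.

    Sampling is by rejection from the parent normal, so draws are exact
    truncated-normal variates and deterministic given ``seed``.
    """
    if group not in config.group_params:
        raise KeyError(
            f"unknown treatment group {group!r}; "
            f"known groups: {sorted(config.group_params)}"
        )
    if n < 1:
        raise ValueError("n must be >= 1")
    mean, sd, lo, hi = config.group_params[group]
    if sd == 0:
        return np.full(n, mean)
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    while out.size < n:
        draw = rng.normal(mean, sd, size=max(n, 64))
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[:n]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _gaussian(w: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((w - center) / sigma) ** 2)


def _clean_reflectance(spad: float, grid: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Noise-free reflectance curve for one SPAD value."""
    edge = config.red_edge_base + config.red_edge_shift_per_spad * spad
    p = _sigmoid((grid - edge) / RED_EDGE_WIDTH)
    r = VIS_BASE + (NIR_PLATEAU - VIS_BASE) * p
    sat = spad / (spad + DEPTH_K)
    for center, sigma, depth in (WELL_BLUE, WELL_RED):
        # wells act on the visible side only; fade them out across the edge
        r -= depth * sat * _gaussian(grid, center, sigma) * (1.0 - p)
    green = GREEN_PEAK_MAX * GREEN_PEAK_K / (GREEN_PEAK_K + spad)
    r += green * _gaussian(grid, GREEN_PEAK_CENTER, GREEN_PEAK_SIGMA)
    for center, sigma, depth in WATER_DIPS:
        r -= depth * _gaussian(grid, center, sigma)
    return r


def generate_spectrum(
    spad: float, config: SyntheticConfig, seed: int
) -> Spectrum:
    """Generate one canopy spectrum for a given SPAD value.

    The noise-free curve encodes SPAD monotonically (green-peak height
    decreasing, red-edge inflection increasing); Gaussian noise of SD
    ``config.noise_sd`` is added per channel and the result clipped to
    the physical reflectance range [0, 1.2].
    """
    if spad < 0:
        raise ValueError("spad must be >= 0")
    grid = config.grid()
    r = _clean_reflectance(spad, grid, config)
    if config.noise_sd > 0:
        r = r + np.random.default_rng(seed).normal(0.0, config.noise_sd, grid.size)
    r = np.clip(r, *REFLECTANCE_CLIP)
    return Spectrum(grid, r, spad=float(spad))


def add_burr_noise(
    spectrum: Spectrum, rate: float, amplitude: float, seed: int
) -> Spectrum:
    """Add +/-``amplitude`` spikes independently per channel with probability ``rate``."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    hit = rng.random(spectrum.n_channels) < rate
    sign = rng.choice([-1.0, 1.0], size=spectrum.n_channels)
    out = spectrum.copy()
    out.reflectance = out.reflectance + hit * sign * amplitude
    return out


def generate_dataset(config: SyntheticConfig) -> SpectraSet:
    """Generate ``n_per_group`` samples for every configured group.

    All randomness (SPAD draws, channel noise, burr spikes) derives from
    ``config.seed``, so identical configs give bit-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    spectra: list[Spectrum] = []
    for group in config.group_params:
        spad = sample_spad(
            group, config.n_per_group, config, int(rng.integers(2**31 - 1))
        )
        for j, value in enumerate(spad):
            s = generate_spectrum(value, config, int(rng.integers(2**31 - 1)))
            if config.burr_rate > 0:
                s = add_burr_noise(
                    s,
                    config.burr_rate,
                    config.burr_amplitude,
                    int(rng.integers(2**31 - 1)),
                )
                s.reflectance = np.clip(s.reflectance, *REFLECTANCE_CLIP)
            s.sample_id = f"{group}_{j:03d}"
            s.group = group
            spectra.append(s)
    return SpectraSet.from_spectra(spectra)
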