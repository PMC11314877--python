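"""In-memory containers for canopy reflectance spectra.

A :class:`Spectrum` is one sample's reflectance curve on a strictly
increasing wavelength grid; a :class:`SpectraSet` is a stack of spectra
sharing one grid, together with the measured SPAD value and treatment
group of every sample.  On disk a SpectraSet is a wide CSV: the columns
``sample_id, group, spad`` followed by one reflectance column per
wavelength, named by its position in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "SpectraSet"]


def _wavelength_label(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else repr(float(w))


@dataclass
class Spectrum:
    """One sample's reflectance curve.

    Parameters
    ----------
    wavelengths : array of float
        Strictly increasing wavelength grid in nm.
    reflectance : array of float
        Reflectance (unitless), same length as ``wavelengths``.
    sample_id : str
        Identifier of the sample.
    group : str
        Treatment label (e.g. CO2 leakage rate).
    spad : float or None
        Measured SPAD reading, if available.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    sample_id: str = ""
    group: str = ""
    spad: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1 or self.reflectance.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-D")
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError(
                "wavelengths and reflectance must have equal length "
                f"({self.wavelengths.size} != {self.reflectance.size})"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.wavelengths.size

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.wavelengths.copy(),
            self.reflectance.copy(),
            self.sample_id,
            self.group,
            self.spad,
        )


@dataclass
class SpectraSet:
    """Sample x wavelength reflectance matrix with per-sample metadata."""

    wavelengths: np.ndarray
    reflectance: np.ndarray  # shape (n_samples, n_channels)
    sample_ids: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)
    spad: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        n = self.reflectance.shape[0]
        if self.reflectance.shape[1] != self.wavelengths.size:
            raise ValueError("reflectance columns must match wavelength grid")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(n)]
        if not self.groups:
            self.groups = [""] * n
        if len(self.sample_ids) != n or len(self.groups) != n:
            raise ValueError("sample_ids/groups length must equal sample count")
        if self.spad is not None:
            self.spad = np.asarray(self.spad, dtype=float)
            if self.spad.size != n:
                raise ValueError("spad length must equal sample count")
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.wavelengths.size

    def spectrum(self, i: int) -> Spectrum:
        """Return sample ``i`` as a standalone :class:`Spectrum`."""
        return Spectrum(
            self.wavelengths.copy(),
            self.reflectance[i].copy(),
            self.sample_ids[i],
            self.groups[i],
            None if self.spad is None else float(self.spad[i]),
        )

    def subset(self, index) -> "SpectraSet":
        """Row subset by integer indices or boolean mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpectraSet(
            self.wavelengths.copy(),
            self.reflectance[index],
            [self.sample_ids[i] for i in index],
            [self.groups[i] for i in index],
            None if self.spad is None else self.spad[index],
        )

    def group_mask(self, group: str) -> np.ndarray:
        return np.asarray([g == group for g in self.groups])

    # ---- wide-CSV round trip -------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "sample_id": self.sample_ids,
            "group": self.groups,
            "spad": self.spad if self.spad is not None else np.full(len(self), np.nan),
        }
        frame = pd.DataFrame(cols)
        refl = pd.DataFrame(
            self.reflectance, columns=[_wavelength_label(w) for w in self.wavelengths]
        )
        return pd.concat([frame, refl], axis=1)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SpectraSet":
        meta = {"sample_id", "group", "spad"}
        wave_cols = [c for c in frame.columns if c not in meta]
        wavelengths = np.asarray([float(c) for c in wave_cols])
        spad = frame["spad"].to_numpy(dtype=float) if "spad" in frame else None
        if spad is not None and np.all(np.isnan(spad)):
            spad = None
        return cls(
            wavelengths,
            frame[wave_cols].to_numpy(dtype=float),
            [str(s) for s in frame.get("sample_id", frame.index)],
            [str(g) for g in frame.get("group", [""] * len(frame))],
            spad,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "SpectraSet":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def from_spectra(cls, spectra: list[Spectrum]) -> "SpectraSet":
        if not spectra:
            raise ValueError("no spectra given")
        grid = spectra[0].wavelengths
        for s in spectra[1:]:
            if s.wavelengths.shape != grid.shape or not np.allclose(
                s.wavelengths, grid
            ):
                raise ValueError("all spectra must share one wavelength grid")
        spad = [s.spad for s in spectra]
        return cls(
            grid.copy(),
            np.vstack([s.reflectance for s in spectra]),
            [s.sample_id for s in spectra],
            [s.group for s in spectra],
            None if any(v is None for v in spad) else np.asarray(spad, dtype=float),
        )
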