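"""Core containers for leaf reflectance spectra.

A campaign of leaf-clip spectroradiometer measurements is represented as a
:class:`SpectrumSet` of :class:`Spectrum` objects, each a reflectance fraction
sampled on the common integer-nanometre grid 350..2500 nm (2151 points) with
experimental metadata (CO2 treatment, array, tree, measurement date, leaf
index) attached.  Raw instrument output, recorded by three overlapping
detectors, lives in :class:`RawSpectrum` until it has been stitched,
resampled and panel-calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Common wavelength grid, inclusive integer nanometres.
GRID_MIN = 350
GRID_MAX = 2500
GRID = np.arange(GRID_MIN, GRID_MAX + 1)
N_GRID = GRID.size  # 2151

#: Controlled vocabulary for the CO2 treatment label.
TREATMENTS = ("aCO2", "eCO2")

#: Detector segment nominal ranges (nm) of the field spectroradiometer:
#: VNIR 350-1000 @1.5 nm, SWIR1 1000-1890 @3.8 nm, SWIR2 1890-2500 @2.5 nm.
DETECTOR_RANGES = {
    "VNIR": (350.0, 1000.0),
    "SWIR1": (1000.0, 1890.0),
    "SWIR2": (1890.0, 2500.0),
}

#: Detector sweeps overlap their nominal boundaries by a few samples; a
#: segment may exceed its nominal range by at most this much (nm).
SEGMENT_RANGE_SLACK_NM = 15.0


class SpectralError(Exception):
    """Base class for spectral-processing failures."""


class ParseError(SpectralError):
    """Raised when a spectrum file cannot be parsed."""


class StitchError(SpectralError):
    """Raised when detector segments cannot be stitched."""


class CoverageError(SpectralError):
    """Raised when a spectrum does not cover the required wavelength range."""


@dataclass(frozen=True)
class SpectrumMeta:
    """Provenance metadata attached to every spectrum.

    ``treatment`` must be one of :data:`TREATMENTS` (or None for ad-hoc
    spectra outside a designed campaign).  ``(tree_id, date, leaf_index)``
    must be unique within a :class:`SpectrumSet`.
    """

    treatment: str | None = None
    array_id: str | None = None
    tree_id: str | None = None
    date: str | None = None
    leaf_index: int | None = None
    source_file: str | None = None

    def __post_init__(self) -> None:
        if self.treatment is not None and self.treatment not in TREATMENTS:
            raise ValueError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )

    def as_dict(self) -> dict:
        return {
            "treatment": self.treatment,
            "array_id": self.array_id,
            "tree_id": self.tree_id,
            "date": self.date,
            "leaf_index": self.leaf_index,
            "source_file": self.source_file,
        }


@dataclass(frozen=True)
class RawSpectrum:
    """Unprocessed multi-detector spectrum.

    ``segments`` is a list of ``(detector_id, wavelengths, values)`` tuples
    with wavelengths strictly increasing within each segment and values
    finite and non-negative (relative reflectance fractions).
    """

    segments: tuple[tuple[str, np.ndarray, np.ndarray], ...]
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("RawSpectrum needs at least one segment")
        for det, wl, vals in self.segments:
            if det not in DETECTOR_RANGES:
                raise ValueError(f"unknown detector id {det!r}")
            wl = np.asarray(wl, dtype=float)
            vals = np.asarray(vals, dtype=float)
            if wl.shape != vals.shape or wl.ndim != 1:
                raise ValueError(f"segment {det}: wavelength/value shape mismatch")
            if wl.size < 2:
                raise ValueError(f"segment {det}: needs at least two samples")
            if not np.all(np.diff(wl) > 0):
                raise ValueError(f"segment {det}: wavelengths not strictly increasing")
            lo, hi = DETECTOR_RANGES[det]
            slack = SEGMENT_RANGE_SLACK_NM
            if wl[0] < lo - slack or wl[-1] > hi + slack:
                raise ValueError(
                    f"segment {det}: wavelengths [{wl[0]}, {wl[-1]}] outside "
                    f"detector range [{lo}, {hi}] (+/- {slack} nm overlap slack)"
                )
            if not np.all(np.isfinite(vals)) or np.any(vals < 0):
                raise ValueError(f"segment {det}: values must be finite and >= 0")


class Spectrum:
    """A reflectance spectrum on the common 1-nm grid.

    Reflectance is stored as a fraction.  Values are clipped to [0, 1.5]:
    leaf-clip measurements can legitimately exceed 1 relative to the
    reference panel, so values above 1 are retained and flagged
    (``over_unity``) rather than destroyed; negatives are floored at 0.
    """

    __slots__ = ("reflectance", "meta", "over_unity")

    def __init__(self, reflectance: np.ndarray, meta: SpectrumMeta | None = None):
        refl = np.asarray(reflectance, dtype=float)
        if refl.shape != (N_GRID,):
            raise ValueError(
                f"reflectance must have shape ({N_GRID},), got {refl.shape}"
            )
        if not np.all(np.isfinite(refl)):
            raise ValueError("reflectance must be finite")
        self.over_unity = bool(np.any(refl > 1.0))
        self.reflectance = np.clip(refl, 0.0, 1.5)
        self.meta = meta if meta is not None else SpectrumMeta()

    @property
    def grid(self) -> np.ndarray:
        return GRID

    def with_reflectance(self, reflectance: np.ndarray) -> "Spectrum":
        """New spectrum with the same metadata (transforms never drop meta)."""
        return Spectrum(reflectance, self.meta)

    def with_meta(self, **kwargs) -> "Spectrum":
        return Spectrum(self.reflectance, replace(self.meta, **kwargs))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Spectrum(tree={self.meta.tree_id}, date={self.meta.date}, "
            f"leaf={self.meta.leaf_index}, mean={self.reflectance.mean():.3f})"
        )


@dataclass(frozen=True)
class PanelCalibration:
    """Laboratory-calibrated reflectance of the leaf-clip reference panel.

    Multiplying a relative spectrum by the interpolated panel curve converts
    it to absolute reflectance.
    """

    wavelengths: np.ndarray
    panel_reflectance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        pr = np.asarray(self.panel_reflectance, dtype=float)
        if wl.shape != pr.shape or wl.ndim != 1 or wl.size < 2:
            raise ValueError("panel calibration needs matching 1-D arrays")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("panel wavelengths must be strictly increasing")
        if np.any(pr <= 0) or np.any(pr > 1.05):
            raise ValueError("panel reflectance must lie in (0, 1.05]")
        if wl[0] > GRID_MIN or wl[-1] < GRID_MAX:
            raise CoverageError(
                f"panel must cover [{GRID_MIN}, {GRID_MAX}] nm, "
                f"covers [{wl[0]}, {wl[-1]}]"
            )
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "panel_reflectance", pr)

    def on_grid(self) -> np.ndarray:
        """Panel curve linearly interpolated onto the common grid."""
        return np.interp(GRID, self.wavelengths, self.panel_reflectance)


class SpectrumSet:
    """An ordered collection of grid-aligned spectra with a design table."""

    def __init__(self, spectra: Sequence[Spectrum]):
        spectra = list(spectra)
        if not spectra:
            raise ValueError("SpectrumSet must be non-empty")
        keys = set()
        for s in spectra:
            if not isinstance(s, Spectrum):
                raise TypeError("SpectrumSet holds Spectrum objects only")
            k = (s.meta.tree_id, s.meta.date, s.meta.leaf_index)
            if all(v is not None for v in k):
                if k in keys:
                    raise ValueError(f"duplicate (tree, date, leaf) key {k}")
                keys.add(k)
        self.spectra = spectra

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    def meta_frame(self) -> pd.DataFrame:
        """One metadata row per spectrum, in set order."""
        return pd.DataFrame([s.meta.as_dict() for s in self.spectra])

    def design(self) -> pd.DataFrame:
        """Counts of spectra per treatment / array / tree / date."""
        df = self.meta_frame()
        return (
            df.groupby(["treatment", "array_id", "tree_id", "date"], dropna=False)
            .size()
            .rename("n_spectra")
            .reset_index()
        )

    def treatment_counts(self) -> dict:
        df = self.meta_frame()
        return df["treatment"].value_counts().to_dict()

    def to_matrix(self) -> np.ndarray:
        """(n_spectra, 2151) reflectance matrix in set order."""
        return np.vstack([s.reflectance for s in self.spectra])

    def to_wide_frame(self) -> pd.DataFrame:
        """Wide table: metadata columns followed by one column per nm."""
        meta = self.meta_frame()
        refl = pd.DataFrame(self.to_matrix(), columns=[str(w) for w in GRID])
        return pd.concat([meta, refl], axis=1)

    @classmethod
    def from_wide_frame(cls, df: pd.DataFrame) -> "SpectrumSet":
        wl_cols = [str(w) for w in GRID]
        missing = [c for c in wl_cols if c not in df.columns]
        if missing:
            raise ParseError(
                f"wide table is missing {len(missing)} wavelength columns "
                f"(first: {missing[0]})"
            )
        spectra = []
        for _, row in df.iterrows():
            li = row.get("leaf_index")
            meta = SpectrumMeta(
                treatment=_none_if_na(row.get("treatment")),
                array_id=_none_if_na(row.get("array_id")),
                tree_id=_none_if_na(row.get("tree_id")),
                date=_none_if_na(row.get("date")),
                leaf_index=None if pd.isna(li) else int(li),
                source_file=_none_if_na(row.get("source_file")),
            )
            spectra.append(Spectrum(row[wl_cols].to_numpy(dtype=float), meta))
        return cls(spectra)

    def to_csv(self, path) -> None:
        self.to_wide_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectrumSet":
        return cls.from_wide_frame(pd.read_csv(path))


def _none_if_na(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return v
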