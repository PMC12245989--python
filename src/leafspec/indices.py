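"""Vegetation indices and integrated reflectance.

The eight classical leaf-level indices computed here, with rho_L the
reflectance fraction at L nm on the 1-nm grid:

    NDVI  = (rho800 - rho670) / (rho800 + rho670)
    MCARI = [(rho700 - rho670) - 0.2 (rho700 - rho550)] * (rho700 / rho670)
    PRI   = (rho570 - rho530) / (rho570 + rho530)
    PSRI  = (rho680 - rho500) / rho750
    NDNI  = [log(1/rho1510) - log(1/rho1680)] / [log(1/rho1510) + log(1/rho1680)]
    NDLI  = [log(1/rho1754) - log(1/rho1680)] / [log(1/rho1754) + log(1/rho1680)]
    NDWI  = (rho860 - rho1240) / (rho860 + rho1240)
    NPQI  = (rho415 - rho435) / (rho415 + rho435)

NDNI/NDLI use natural logs; their ratio structure makes the value
independent of the log base.  Integrated reflectance is the trapezoidal
integral of the fractional reflectance over 350-2500 nm (units
fraction x nm), a scalar brightness summary per leaf.

Indices whose formula is undefined for a spectrum (zero denominator, or a
non-positive band under a log) are returned flagged undefined (NaN value),
never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import GRID_MAX, GRID_MIN, Spectrum, SpectrumMeta, SpectrumSet

INDEX_NAMES = ("NDVI", "MCARI", "PRI", "PSRI", "NDNI", "NDLI", "NDWI", "NPQI")
INTEGRATED = "INTEGRATED"


@dataclass(frozen=True)
class IndexResult:
    """A single index value with provenance; ``defined`` is False when the
    formula could not be evaluated (value is then NaN)."""

    index_name: str
    value: float
    meta: SpectrumMeta
    defined: bool = True


def band(spectrum: Spectrum, wavelength_nm: float) -> float:
    """Reflectance at the nearest integer-nm grid point."""
    lam = int(round(float(wavelength_nm)))
    if not (GRID_MIN <= lam <= GRID_MAX):
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside [{GRID_MIN}, {GRID_MAX}]"
        )
    return float(spectrum.reflectance[lam - GRID_MIN])


def normalized_difference(spectrum: Spectrum, lam_a: float, lam_b: float) -> float:
    """(rho_a - rho_b) / (rho_a + rho_b); NaN when the denominator is 0."""
    a, b = band(spectrum, lam_a), band(spectrum, lam_b)
    denom = a + b
    if denom == 0.0:
        return math.nan
    return (a - b) / denom


def _log_reciprocal_nd(spectrum: Spectrum, lam_a: float, lam_b: float) -> float:
    a, b = band(spectrum, lam_a), band(spectrum, lam_b)
    if a <= 0.0 or b <= 0.0:
        return math.nan
    la, lb = math.log(1.0 / a), math.log(1.0 / b)
    denom = la + lb
    if denom == 0.0:
        # flat positive spectrum: both logs equal, difference is exactly 0
        return 0.0 if la == lb else math.nan
    return (la - lb) / denom


def _ndvi(s):
    return normalized_difference(s, 800, 670)


def _mcari(s):
    r700, r670, r550 = band(s, 700), band(s, 670), band(s, 550)
    if r670 == 0.0:
        return math.nan
    return ((r700 - r670) - 0.2 * (r700 - r550)) * (r700 / r670)


def _pri(s):
    return normalized_difference(s, 570, 530)


def _psri(s):
    r750 = band(s, 750)
    if r750 == 0.0:
        return math.nan
    return (band(s, 680) - band(s, 500)) / r750


def _ndni(s):
    return _log_reciprocal_nd(s, 1510, 1680)


def _ndli(s):
    return _log_reciprocal_nd(s, 1754, 1680)


def _ndwi(s):
    return normalized_difference(s, 860, 1240)


def _npqi(s):
    return normalized_difference(s, 415, 435)


INDEX_REGISTRY = {
    "NDVI": _ndvi,
    "MCARI": _mcari,
    "PRI": _pri,
    "PSRI": _psri,
    "NDNI": _ndni,
    "NDLI": _ndli,
    "NDWI": _ndwi,
    "NPQI": _npqi,
}


def compute_index(spectrum: Spectrum, name: str) -> IndexResult:
    """Evaluate one registered index (or INTEGRATED) for a spectrum."""
    if name == INTEGRATED:
        return integrated_reflectance(spectrum)
    if name not in INDEX_REGISTRY:
        raise KeyError(
            f"unknown index {name!r}; available: "
            f"{', '.join((*INDEX_REGISTRY, INTEGRATED))}"
        )
    value = INDEX_REGISTRY[name](spectrum)
    defined = math.isfinite(value)
    return IndexResult(name, value if defined else math.nan, spectrum.meta, defined)


def integrated_reflectance(spectrum: Spectrum) -> IndexResult:
    """Trapezoidal integral of reflectance over 350-2500 nm (fraction x nm)."""
    value = float(np.trapezoid(spectrum.reflectance, dx=1.0))
    return IndexResult(INTEGRATED, value, spectrum.meta, True)


def index_table(spectrum_set: SpectrumSet,
                names: tuple[str, ...] | list[str] = INDEX_NAMES) -> pd.DataFrame:
    """Long-format table: one row per spectrum x index.

    Rows are ordered deterministically by (tree, date, leaf, index).
    Undefined values carry NaN with ``defined`` False.
    """
    for name in names:
        if name != INTEGRATED and name not in INDEX_REGISTRY:
            raise KeyError(
                f"unknown index {name!r}; available: "
                f"{', '.join((*INDEX_REGISTRY, INTEGRATED))}"
            )
    rows = []
    for s in spectrum_set:
        for name in names:
            res = compute_index(s, name)
            rows.append(
                {
                    "treatment": s.meta.treatment,
                    "array_id": s.meta.array_id,
                    "tree_id": s.meta.tree_id,
                    "date": s.meta.date,
                    "leaf_index": s.meta.leaf_index,
                    "index_name": name,
                    "value": res.value,
                    "defined": res.defined,
                }
            )
    df = pd.DataFrame(rows)
    order = {n: i for i, n in enumerate(names)}
    df["_io"] = df["index_name"].map(order)
    df = (
        df.sort_values(["tree_id", "date", "leaf_index", "_io"], kind="mergesort")
        .drop(columns="_io")
        .reset_index(drop=True)
    )
    return df
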