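"""Reading, stitching, resampling and calibrating raw field spectra.

The field spectroradiometer records each leaf as three overlapping detector
segments (VNIR 350-1000 nm, SWIR1 1000-1890 nm, SWIR2 1890-2500 nm).  The
preprocessing chain is::

    read_spectrum_file -> stitch -> resample_1nm -> to_absolute

`stitch` supports two documented overlap policies (the instrument literature
does not pin one down):

``cut`` (default)
    detector-priority cut: VNIR points are kept below 1000 nm, SWIR1 points
    on [1000, 1890), SWIR2 from 1890 nm.  Deterministic, never alters values.
``rescale``
    multiplicative jump correction: SWIR1 (then SWIR2) is rescaled so that
    segment means agree over the overlap window, then the cut is applied.
    Removes detector steps at the cost of touching SWIR absolute levels.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import (
    DETECTOR_RANGES,
    GRID,
    GRID_MAX,
    GRID_MIN,
    SEGMENT_RANGE_SLACK_NM,
    CoverageError,
    PanelCalibration,
    ParseError,
    RawSpectrum,
    Spectrum,
    SpectrumMeta,
    SpectrumSet,
    StitchError,
)

_DETECTOR_ORDER = ("VNIR", "SWIR1", "SWIR2")

#: Largest tolerated gap (nm) between adjacent detector segments.
MAX_SEGMENT_GAP_NM = 5.0

#: Largest tolerated shortfall (nm) at either end of the 350-2500 range.
MAX_EDGE_SHORTFALL_NM = 5.0

_META_KEYS = ("treatment", "array_id", "tree_id", "date", "leaf_index", "source_file")


# ---------------------------------------------------------------------------
# readers / writers for single spectra
# ---------------------------------------------------------------------------

def read_spectrum_file(path, dialect: str = "auto",
                       meta: SpectrumMeta | None = None) -> RawSpectrum:
    """Read one spectrum file into a :class:`RawSpectrum`.

    Two dialects are supported:

    ``svc``
        SVC-style text: an optional header block of ``key = value`` lines
        (``/*`` comment lines ignored), then two columns (whitespace or
        comma separated) of wavelength and relative reflectance.  Detector
        segments are recovered from wavelength resets (a wavelength lower
        than its predecessor starts a new segment) and otherwise partitioned
        at the 1000 / 1890 nm detector boundaries.
    ``csv``
        the package's own dialect: ``# key: value`` metadata comment lines
        followed by a CSV with ``wavelength_nm,reflectance`` columns.

    ``auto`` sniffs: files whose first non-blank line starts with ``#`` or
    whose header row is ``wavelength_nm,reflectance`` are read as ``csv``,
    anything else as ``svc``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("auto", "svc", "csv"):
        raise ParseError(f"unsupported spectrum file dialect {dialect!r}")
    text = path.read_text()
    if dialect == "auto":
        dialect = _sniff_dialect(text)
    header_meta, wl, vals = (
        _parse_csv_dialect(text, path) if dialect == "csv"
        else _parse_svc_dialect(text, path)
    )
    if meta is None:
        meta = _meta_from_header(header_meta, path)
    segments = _partition_segments(wl, vals, path)
    return RawSpectrum(segments=segments, meta=meta)


def _sniff_dialect(text: str) -> str:
    for line in text.splitlines():
        s = line.strip()
        if not s:
            continue
        if s.startswith("#") or s.replace(" ", "").lower().startswith(
            "wavelength_nm,reflectance"
        ):
            return "csv"
        return "svc"
    raise ParseError("empty spectrum file")


def _parse_svc_dialect(text: str, path):
    meta: dict = {}
    wl, vals = [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("/*") or s.startswith("//"):
            continue
        if "=" in s and not s[0].isdigit():
            key, _, value = s.partition("=")
            meta[key.strip().lower()] = value.strip()
            continue
        parts = s.replace(",", " ").split()
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected two columns, got {s!r}")
        try:
            w, v = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric data row {s!r}") from exc
        wl.append(w)
        vals.append(v)
    if not wl:
        raise ParseError(f"{path}: no data rows found")
    return meta, np.asarray(wl), np.asarray(vals)


def _parse_csv_dialect(text: str, path):
    meta: dict = {}
    data_lines = []
    for line in text.splitlines():
        s = line.strip()
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip().lower()] = value.strip()
        elif s:
            data_lines.append(s)
    if not data_lines:
        raise ParseError(f"{path}: no data rows found")
    reader = csv.reader(data_lines)
    header = next(reader)
    header = [h.strip().lower() for h in header]
    try:
        wi = header.index("wavelength_nm")
        ri = header.index("reflectance")
    except ValueError as exc:
        raise ParseError(
            f"{path}: csv dialect requires 'wavelength_nm' and 'reflectance' columns"
        ) from exc
    wl, vals = [], []
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        try:
            wl.append(float(row[wi]))
            vals.append(float(row[ri]))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: bad data row {row!r}") from exc
    if not wl:
        raise ParseError(f"{path}: no data rows found")
    return meta, np.asarray(wl), np.asarray(vals)


def _meta_from_header(header: dict, path) -> SpectrumMeta:
    kwargs = {}
    for key in _META_KEYS:
        if key in header:
            kwargs[key] = header[key]
    if "leaf_index" in kwargs:
        kwargs["leaf_index"] = int(kwargs["leaf_index"])
    kwargs.setdefault("source_file", str(path))
    return SpectrumMeta(**kwargs)


def _partition_segments(wl: np.ndarray, vals: np.ndarray, path):
    """Split a flat wavelength series into detector segments.

    A decrease in wavelength marks the start of the next detector's sweep,
    so each monotone run is one detector (assigned by overlap with the
    nominal ranges).  A single run spanning several detector ranges - e.g. a
    file already stitched upstream - is partitioned at the 1000 / 1890 nm
    boundaries instead.  Duplicate wavelengths within a run are a parse
    error.
    """
    breaks = [0]
    for i in range(1, wl.size):
        if wl[i] < wl[i - 1]:
            breaks.append(i)
    breaks.append(wl.size)
    runs = [(wl[a:b], vals[a:b]) for a, b in zip(breaks[:-1], breaks[1:])]

    segments: list[tuple[str, np.ndarray, np.ndarray]] = []
    for rwl, rvals in runs:
        dup = np.nonzero(np.diff(rwl) == 0)[0]
        if dup.size:
            raise ParseError(
                f"{path}: duplicated wavelength {rwl[dup[0]]:g} nm"
            )
        slack = SEGMENT_RANGE_SLACK_NM
        crossed = [
            DETECTOR_RANGES[det][1]
            for det in ("VNIR", "SWIR1")
            if rwl[0] < DETECTOR_RANGES[det][1] - slack
            and rwl[-1] > DETECTOR_RANGES[det][1] + slack
        ]
        if not crossed:
            # whole run belongs to one detector: pick the largest overlap
            det = max(
                _DETECTOR_ORDER,
                key=lambda d: min(rwl[-1], DETECTOR_RANGES[d][1])
                - max(rwl[0], DETECTOR_RANGES[d][0]),
            )
            segments.append((det, rwl, rvals))
        else:
            edges = [rwl[0] - 1.0] + crossed + [rwl[-1] + 1.0]
            for lo, hi in zip(edges[:-1], edges[1:]):
                m = (rwl >= lo) & (rwl < hi)
                if m.sum() < 2:
                    continue
                det = max(
                    _DETECTOR_ORDER,
                    key=lambda d: min(rwl[m][-1], DETECTOR_RANGES[d][1])
                    - max(rwl[m][0], DETECTOR_RANGES[d][0]),
                )
                segments.append((det, rwl[m], rvals[m]))
    if not segments:
        raise ParseError(f"{path}: no usable wavelength rows")
    segments.sort(key=lambda s: s[1][0])
    return tuple(segments)


def write_spectrum_csv(spectrum_or_raw, path) -> None:
    """Write a spectrum in the package CSV dialect (metadata as comments)."""
    if isinstance(spectrum_or_raw, Spectrum):
        meta = spectrum_or_raw.meta
        wl = GRID.astype(float)
        vals = spectrum_or_raw.reflectance
    else:
        meta = spectrum_or_raw.meta
        wl = np.concatenate([s[1] for s in spectrum_or_raw.segments])
        vals = np.concatenate([s[2] for s in spectrum_or_raw.segments])
    lines = []
    for key, value in meta.as_dict().items():
        if value is not None and key != "source_file":
            lines.append(f"# {key}: {value}")
    lines.append("wavelength_nm,reflectance")
    for w, v in zip(wl, vals):
        lines.append(f"{w:g},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# stitching / resampling / calibration
# ---------------------------------------------------------------------------

def stitch(raw: RawSpectrum, policy: str = "cut") -> tuple[np.ndarray, np.ndarray]:
    """Combine detector segments into one strictly-increasing series.

    Returns ``(wavelengths, values)`` on the instrument's irregular grid.
    See the module docstring for the two policies.
    """
    if policy not in ("cut", "rescale"):
        raise StitchError(f"unknown stitch policy {policy!r}")
    segs = sorted(raw.segments, key=lambda s: s[1][0])
    for det, wl, vals in segs:
        if not np.all(np.isfinite(vals)):
            raise StitchError(f"segment {det}: non-finite values")

    # check adjacency: next segment must start within MAX_SEGMENT_GAP_NM of
    # the previous segment's end
    for (d1, w1, _), (d2, w2, _) in zip(segs[:-1], segs[1:]):
        gap = w2[0] - w1[-1]
        if gap > MAX_SEGMENT_GAP_NM:
            raise StitchError(
                f"gap of {gap:.1f} nm between {d1} and {d2} exceeds "
                f"{MAX_SEGMENT_GAP_NM} nm"
            )

    values = [vals.astype(float).copy() for _, _, vals in segs]
    if policy == "rescale":
        for i in range(1, len(segs)):
            _, wl_prev, _ = segs[i - 1]
            _, wl_next, _ = segs[i]
            lo, hi = wl_next[0], wl_prev[-1]
            if hi <= lo:  # abutting, nothing to match
                continue
            prev_mask = (wl_prev >= lo) & (wl_prev <= hi)
            next_mask = (wl_next >= lo) & (wl_next <= hi)
            m_prev = values[i - 1][prev_mask].mean()
            m_next = values[i][next_mask].mean()
            if m_next > 0:
                values[i] *= m_prev / m_next
            # subsequent segments are matched to the already-rescaled one

    # detector-priority cut at the nominal boundaries
    out_wl, out_vals = [], []
    for j, (det, wl, _) in enumerate(segs):
        lo = wl[0] if j == 0 else DETECTOR_RANGES[det][0]
        hi = np.inf if j == len(segs) - 1 else DETECTOR_RANGES[det][1]
        keep = (wl >= lo) & (wl < hi) if j < len(segs) - 1 else (wl >= lo)
        out_wl.append(wl[keep])
        out_vals.append(values[j][keep])
    swl = np.concatenate(out_wl)
    svals = np.concatenate(out_vals)
    # drop exact duplicates at boundaries (keep the later detector's point)
    keep = np.ones(swl.size, dtype=bool)
    keep[:-1] = np.diff(swl) > 0
    swl, svals = swl[keep], svals[keep]
    if not np.all(np.diff(swl) > 0):
        raise StitchError("stitched wavelengths are not strictly increasing")
    return swl, svals


def resample_1nm(stitched: tuple[np.ndarray, np.ndarray],
                 meta: SpectrumMeta | None = None) -> Spectrum:
    """Linearly interpolate a stitched series onto the 350..2500 nm grid.

    No extrapolation: beyond the measured range the edge value is held, and
    a shortfall of more than 5 nm at either end is a coverage error.
    """
    wl, vals = stitched
    wl = np.asarray(wl, dtype=float)
    vals = np.asarray(vals, dtype=float)
    if wl[0] > GRID_MIN + MAX_EDGE_SHORTFALL_NM:
        raise CoverageError(
            f"spectrum starts at {wl[0]:.1f} nm, more than "
            f"{MAX_EDGE_SHORTFALL_NM} nm above {GRID_MIN} nm"
        )
    if wl[-1] < GRID_MAX - MAX_EDGE_SHORTFALL_NM:
        raise CoverageError(
            f"spectrum ends at {wl[-1]:.1f} nm, more than "
            f"{MAX_EDGE_SHORTFALL_NM} nm below {GRID_MAX} nm"
        )
    refl = np.interp(GRID, wl, vals)  # holds edge values outside the range
    return Spectrum(refl, meta if meta is not None else SpectrumMeta())


def to_absolute(spectrum: Spectrum, panel: PanelCalibration) -> Spectrum:
    """Convert relative to absolute reflectance via the panel curve."""
    return spectrum.with_reflectance(spectrum.reflectance * panel.on_grid())


def preprocess_raw(raw: RawSpectrum, panel: PanelCalibration | None = None,
                   policy: str = "cut") -> Spectrum:
    """Full chain stitch -> 1 nm resample -> optional panel calibration."""
    spec = resample_1nm(stitch(raw, policy=policy), meta=raw.meta)
    if panel is not None:
        spec = to_absolute(spec, panel)
    return spec


# ---------------------------------------------------------------------------
# panel and manifest I/O
# ---------------------------------------------------------------------------

def read_panel_csv(path) -> PanelCalibration:
    """Panel calibration CSV with columns wavelength_nm, panel_reflectance."""
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "panel_reflectance"):
        if col not in df.columns:
            raise ParseError(f"{path}: panel CSV needs a {col!r} column")
    return PanelCalibration(
        wavelengths=df["wavelength_nm"].to_numpy(dtype=float),
        panel_reflectance=df["panel_reflectance"].to_numpy(dtype=float),
    )


def load_set(manifest_path, panel: PanelCalibration | None = None,
             dialect: str = "auto", policy: str = "cut") -> SpectrumSet:
    """Load and preprocess a campaign described by a manifest CSV.

    The manifest maps file paths to metadata with columns
    ``path, treatment, array_id, tree_id, date, leaf_index``; relative paths
    are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    if df.empty:
        raise ParseError(f"{manifest_path}: manifest is empty")
    required = ["path", "treatment", "array_id", "tree_id", "date", "leaf_index"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{manifest_path}: manifest missing columns {missing_cols}")
    incomplete = df[df[required].isna().any(axis=1)]
    if not incomplete.empty:
        raise ParseError(
            f"{manifest_path}: metadata missing for files: "
            + ", ".join(map(str, incomplete["path"].tolist()))
        )
    spectra = []
    for _, row in df.iterrows():
        fpath = Path(row["path"])
        if not fpath.is_absolute():
            fpath = manifest_path.parent / fpath
        meta = SpectrumMeta(
            treatment=str(row["treatment"]),
            array_id=str(row["array_id"]),
            tree_id=str(row["tree_id"]),
            date=str(row["date"]),
            leaf_index=int(row["leaf_index"]),
            source_file=str(fpath),
        )
        raw = read_spectrum_file(fpath, dialect=dialect, meta=meta)
        spectra.append(preprocess_raw(raw, panel=panel, policy=policy))
    return SpectrumSet(spectra)
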