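"""Container and file formats for sets of near-infrared spectra.

A :class:`SpectrumSet` bundles a shared wavenumber grid (stored in
instrument order, high to low) with one intensity row per recorded
spectrum, the sample label of each row, and the known analyte content
of each sample (w/w%, NaN for unknowns).  Every stage of the pipeline
consumes and produces this object.

Intensities are either percent transmittance (``mode="transmittance"``,
values in (0, 100]) or absorbance (``mode="absorbance"``, A = 2 -
log10(%T)).  All modeling downstream happens in absorbance, where
Beer-Lambert additivity makes mixture spectra linear in composition;
:func:`to_absorbance` performs the conversion.

The nominal instrument resolution (2, 4 or 8 cm^-1) is carried as
metadata; it is deliberately decoupled from the grid step, which is
whatever the file provides (typically 1 cm^-1).
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MODE_TRANSMITTANCE = "transmittance"
MODE_ABSORBANCE = "absorbance"
_MODES = (MODE_TRANSMITTANCE, MODE_ABSORBANCE)

#: comparison slack for wavenumber boundary tests (grids are >= 0.1 cm^-1 apart)
_WTOL = 1e-6


@dataclass(frozen=True, eq=False)
class SpectrumSet:
    """An immutable set of spectra on a common, strictly decreasing grid.

    Parameters
    ----------
    wavenumbers : array, shape (p,)
        Wavenumber grid in cm^-1, strictly monotonically decreasing.
    intensities : array, shape (n, p)
        One spectrum per row, %T or absorbance depending on ``mode``.
    sample_ids : sequence of str, length n
        Physical-sample label per row; replicate spectra share a label.
    fractions : array, shape (n,)
        Known analyte content in w/w% (0-100); NaN marks unknowns.
    resolution : float
        Nominal instrument resolution in cm^-1 (metadata, not grid step).
    mode : str
        ``"transmittance"`` or ``"absorbance"``.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_ids: tuple[str, ...]
    fractions: np.ndarray
    resolution: float = 4.0
    mode: str = MODE_TRANSMITTANCE

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        x = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        ids = tuple(str(s) for s in self.sample_ids)
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", x)
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "fractions", f)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("wavenumbers must be a non-empty 1-D vector")
        if np.unique(w).size != w.size:
            raise ValueError("duplicate wavenumber in grid")
        if w.size > 1 and not np.all(np.diff(w) < 0):
            raise ValueError("wavenumbers must be strictly decreasing")
        if x.shape[1] != w.size:
            raise ValueError(
                f"intensity rows have {x.shape[1]} points, grid has {w.size}"
            )
        if len(ids) != x.shape[0]:
            raise ValueError("one sample id required per spectrum row")
        if f.shape != (x.shape[0],):
            raise ValueError("one fraction (or NaN) required per spectrum row")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.mode == MODE_TRANSMITTANCE:
            if not np.all((x > 0) & (x <= 100 + 1e-12)):
                raise ValueError("%T values must lie in (0, 100]")
        known = f[~np.isnan(f)]
        if known.size and (known.min() < 0 or known.max() > 100):
            raise ValueError("fractions must lie in [0, 100] w/w%")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    @property
    def has_known_fractions(self) -> bool:
        return bool(np.all(~np.isnan(self.fractions)))

    def replace(self, **kw) -> "SpectrumSet":
        return dataclasses.replace(self, **kw)

    def __eq__(self, other: object) -> bool:  # field-by-field, NaN-aware
        if not isinstance(other, SpectrumSet):
            return NotImplemented
        return (
            np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.intensities, other.intensities)
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.fractions, other.fractions, equal_nan=True)
            and self.resolution == other.resolution
            and self.mode == other.mode
        )


def to_absorbance(sset: SpectrumSet) -> SpectrumSet:
    """Convert percent transmittance to absorbance, A = 2 - log10(%T)."""
    if sset.mode == MODE_ABSORBANCE:
        return sset
    if np.any(sset.intensities <= 0):
        raise ValueError("cannot take absorbance of nonpositive %T")
    return sset.replace(
        intensities=2.0 - np.log10(sset.intensities), mode=MODE_ABSORBANCE
    )


def slice_by_wavenumber(
    sset: SpectrumSet, hi: float, lo: float, include_lo: bool = False
) -> SpectrumSet:
    """Retain grid points with hi >= nu > lo (nu >= lo when ``include_lo``).

    The half-open convention makes adjacent slices tile a shared-endpoint
    grid exactly; the final interval of a partition is taken closed so the
    lowest grid point is not dropped.
    """
    if hi <= lo:
        raise ValueError("require hi > lo")
    w = sset.wavenumbers
    if hi > w[0] + _WTOL or lo < w[-1] - _WTOL:
        raise ValueError("slice bounds fall outside the grid span")
    if include_lo:
        mask = (w <= hi + _WTOL) & (w >= lo - _WTOL)
    else:
        mask = (w <= hi + _WTOL) & (w > lo + _WTOL)
    if not mask.any():
        raise ValueError(f"empty slice [{hi}, {lo}]")
    return sset.replace(wavenumbers=w[mask], intensities=sset.intensities[:, mask])


def concat_regions(parts: Sequence[SpectrumSet]) -> SpectrumSet:
    """Concatenate disjoint wavenumber regions of the same samples.

    Parts may arrive in any order; output wavenumbers are globally
    decreasing.  Sample ids, fractions, mode and resolution must agree.
    """
    if not parts:
        raise ValueError("no regions to concatenate")
    first = parts[0]
    for p in parts[1:]:
        if p.sample_ids != first.sample_ids:
            raise ValueError("sample mismatch between regions")
        if p.mode != first.mode or p.resolution != first.resolution:
            raise ValueError("mode/resolution mismatch between regions")
        if not np.array_equal(p.fractions, first.fractions, equal_nan=True):
            raise ValueError("fraction mismatch between regions")
    ordered = sorted(parts, key=lambda s: -s.wavenumbers[0])
    for a, b in zip(ordered, ordered[1:]):
        if b.wavenumbers[0] >= a.wavenumbers[-1]:
            raise ValueError("overlapping wavenumber regions")
    return first.replace(
        wavenumbers=np.concatenate([s.wavenumbers for s in ordered]),
        intensities=np.concatenate([s.intensities for s in ordered], axis=1),
    )


# ---------------------------------------------------------------------------
# on-disk format: wide CSV + sidecar metadata CSV
# ---------------------------------------------------------------------------

_META_COLUMNS = ["spectrum_id", "sample_id", "fraction_pct", "resolution_cm1", "mode"]


def default_metadata_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + "_meta" + p.suffix)


def write_spectra_csv(
    sset: SpectrumSet, path: str | Path, metadata_path: str | Path | None = None
) -> tuple[Path, Path]:
    """Write a wide spectra CSV (wavenumber + one column per spectrum) plus
    a sidecar metadata CSV.  Floats are written at full repr precision so
    ``read_spectra_csv`` round-trips losslessly."""
    path = Path(path)
    metadata_path = (
        default_metadata_path(path) if metadata_path is None else Path(metadata_path)
    )
    spectrum_ids = [f"s{i:03d}" for i in range(sset.n_spectra)]
    wide = pd.DataFrame({"wavenumber": sset.wavenumbers})
    for sid, row in zip(spectrum_ids, sset.intensities):
        wide[sid] = row
    wide.to_csv(path, index=False, float_format="%.17g")
    meta = pd.DataFrame(
        {
            "spectrum_id": spectrum_ids,
            "sample_id": list(sset.sample_ids),
            "fraction_pct": sset.fractions,
            "resolution_cm1": sset.resolution,
            "mode": sset.mode,
        }
    )
    meta.to_csv(metadata_path, index=False, float_format="%.17g")
    return path, metadata_path


def read_spectra_csv(path: str | Path, metadata_path: str | Path) -> SpectrumSet:
    """Read a wide spectra CSV and its metadata sidecar into a SpectrumSet.

    The first CSV column is the wavenumber grid; every remaining column id
    must appear in the metadata table, which supplies the sample id, known
    fraction (blank for unknowns), resolution and intensity mode.
    """
    wide = pd.read_csv(path, float_precision="round_trip")
    if wide.shape[1] < 2:
        raise ValueError("spectra CSV needs a wavenumber column plus spectra")
    meta = pd.read_csv(metadata_path, float_precision="round_trip")
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata CSV missing columns: {missing}")
    meta = meta.set_index("spectrum_id")
    spectrum_ids = list(wide.columns[1:])
    unknown = [c for c in spectrum_ids if c not in meta.index]
    if unknown:
        raise ValueError(f"spectra columns absent from metadata: {unknown}")
    w = wide.iloc[:, 0].to_numpy(dtype=float)
    if np.unique(w).size != w.size:
        raise ValueError("duplicate wavenumber in spectra CSV")
    sub = meta.loc[spectrum_ids]
    resolution = sub["resolution_cm1"].unique()
    mode = sub["mode"].unique()
    if len(resolution) != 1 or len(mode) != 1:
        raise ValueError("metadata mixes resolutions or intensity modes")
    return SpectrumSet(
        wavenumbers=w,
        intensities=wide.iloc[:, 1:].to_numpy(dtype=float).T,
        sample_ids=tuple(str(s) for s in sub["sample_id"]),
        fractions=sub["fraction_pct"].to_numpy(dtype=float),
        resolution=float(resolution[0]),
        mode=str(mode[0]),
    )


# ---------------------------------------------------------------------------
# minimal JCAMP-DX reader (XYDATA, linear abscissa only)
# ---------------------------------------------------------------------------

def read_jcamp_xy(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read one spectrum from a JCAMP-DX file with an AFFN ``(X++(Y..Y))``
    XYDATA block on a linear abscissa.  Returns (x, y) as stored (after
    XFACTOR/YFACTOR scaling), in file order."""
    header: dict[str, str] = {}
    ys: list[float] = []
    in_table = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                in_table = True
                continue
            if key == "END":
                break
            header[key] = val.strip()
            in_table = False
            continue
        if in_table:
            toks = re.split(r"[,\s]+", line)
            vals = [float(t) for t in toks if t]
            ys.extend(vals[1:])  # first token is the line's X value
    if not ys:
        raise ValueError("no XYDATA table found")
    npoints = int(float(header.get("NPOINTS", len(ys))))
    if npoints != len(ys):
        raise ValueError(f"NPOINTS={npoints} but {len(ys)} Y values read")
    firstx = float(header["FIRSTX"])
    lastx = float(header["LASTX"])
    xfac = float(header.get("XFACTOR", 1.0))
    yfac = float(header.get("YFACTOR", 1.0))
    x = np.linspace(firstx, lastx, npoints) * xfac
    return x, np.asarray(ys) * yfac
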