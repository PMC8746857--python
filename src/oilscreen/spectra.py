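"""Domain containers and file I/O for 1D proton NMR data.

Two in-memory objects travel through the pipeline:

``FID``
    The raw complex free-induction decay together with the acquisition
    metadata needed to turn it into a chemical-shift axis (dwell time,
    spectrometer frequency, and the ppm value at the centre of the
    spectral window).

``Spectrum1D``
    A real, phased spectrum: intensity against a strictly descending ppm
    axis (the display convention in NMR, high field to the right).  Every
    processing step appends a line to ``meta["history"]`` so a spectrum
    carries its own provenance.

On disk both live in plain, diff-friendly text formats:

* tabular spectra: CSV ``ppm,intensity`` with optional ``# key=value``
  header lines;
* tabular FIDs: CSV ``t,real,imag`` with mandatory ``# dwell_time=...``
  and ``# spectrometer_freq=...`` headers;
* JCAMP-DX (subset) for spectra, so fixtures interoperate with common
  NMR viewers.

All readers validate monotonicity and reject NaN/Inf, and every
writer/reader pair round-trips to better than 1e-9.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "FID",
    "Spectrum1D",
    "SpectrumFormatError",
    "SpectrumValidationError",
    "read_spectrum",
    "write_spectrum",
    "read_fid",
    "write_fid",
]


class SpectrumFormatError(ValueError):
    """A file could not be parsed under the requested dialect."""


class SpectrumValidationError(ValueError):
    """Parsed or constructed data violate a container invariant."""


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise SpectrumValidationError(
            f"{name} contains a non-finite value at index {bad}"
        )


@dataclass
class FID:
    """Complex time-domain NMR signal with acquisition metadata.

    Parameters
    ----------
    points:
        Complex amplitudes sampled every ``dwell_time`` seconds starting
        at t = 0.
    dwell_time:
        Seconds per point; the reciprocal of the sweep width in Hz.
    spectrometer_freq:
        Proton Larmor frequency in MHz (400.13 for the 400 MHz system
        this package emulates).
    ppm_offset:
        Chemical shift, in ppm, of the carrier / centre of the spectral
        window after Fourier transform.
    """

    points: np.ndarray
    dwell_time: float
    spectrometer_freq: float
    ppm_offset: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=complex)
        if self.points.ndim != 1 or self.points.size < 2:
            raise SpectrumValidationError("FID needs at least 2 points")
        if not (self.dwell_time > 0):
            raise SpectrumValidationError("dwell_time must be positive")
        if not (self.spectrometer_freq > 0):
            raise SpectrumValidationError("spectrometer_freq must be positive")
        _check_finite("FID real part", self.points.real)
        _check_finite("FID imaginary part", self.points.imag)
        self.meta.setdefault("history", [])

    @property
    def n_points(self) -> int:
        return int(self.points.size)

    @property
    def sweep_hz(self) -> float:
        return 1.0 / self.dwell_time

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, t = 0 ... (n-1)*dwell."""
        return np.arange(self.n_points) * self.dwell_time

    def copy(self) -> "FID":
        return FID(
            points=self.points.copy(),
            dwell_time=self.dwell_time,
            spectrometer_freq=self.spectrometer_freq,
            ppm_offset=self.ppm_offset,
            meta={**self.meta, "history": list(self.meta.get("history", []))},
        )


@dataclass
class Spectrum1D:
    """Real 1D spectrum on a strictly descending ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise SpectrumValidationError(
                "ppm axis and intensity must be 1D arrays of equal length"
            )
        _check_finite("ppm axis", self.ppm)
        _check_finite("intensity", self.intensity)
        d = np.diff(self.ppm)
        if np.any(d >= 0):
            raise SpectrumValidationError(
                "ppm axis must be strictly monotone descending"
            )
        self.meta.setdefault("history", [])

    def with_history(self, entry: str) -> "Spectrum1D":
        """Return self after appending one provenance line (in place)."""
        self.meta["history"].append(entry)
        return self

    def copy(self) -> "Spectrum1D":
        return Spectrum1D(
            ppm=self.ppm.copy(),
            intensity=self.intensity.copy(),
            meta={**self.meta, "history": list(self.meta.get("history", []))},
        )

    def window(self, low_ppm: float, high_ppm: float) -> "Spectrum1D":
        """Slice to low_ppm <= ppm <= high_ppm (bounds in either order)."""
        lo, hi = min(low_ppm, high_ppm), max(low_ppm, high_ppm)
        mask = (self.ppm >= lo) & (self.ppm <= hi)
        if not mask.any():
            raise SpectrumValidationError(
                f"window [{lo}, {hi}] ppm does not intersect the axis"
            )
        return Spectrum1D(self.ppm[mask], self.intensity[mask],
                          meta={"history": list(self.meta["history"])})


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

def _parse_header(lines: Iterable[str]) -> tuple[dict, list[tuple[int, str]]]:
    """Split '#'-prefixed key=value headers from data rows.

    Returns (meta, [(line_number, row_text), ...]).
    """
    meta: dict = {}
    rows: list[tuple[int, str]] = []
    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                key = key.strip()
                value = value.strip()
                if key == "history":
                    try:
                        meta["history"] = json.loads(value)
                    except json.JSONDecodeError:
                        meta["history"] = [value]
                else:
                    meta[key] = value
            continue
        rows.append((i, line))
    return meta, rows


def _meta_header_lines(meta: Mapping) -> list[str]:
    lines = []
    for key, value in meta.items():
        if key == "history":
            lines.append(f"# history={json.dumps(value)}")
        else:
            lines.append(f"# {key}={value}")
    return lines


def _read_tabular_spectrum(path: Path) -> Spectrum1D:
    meta, rows = _parse_header(path.read_text().splitlines())
    ppm, intensity = [], []
    for lineno, row in rows:
        parts = row.split(",")
        if len(parts) != 2:
            raise SpectrumFormatError(
                f"{path}:{lineno}: expected 'ppm,intensity', got {row!r}"
            )
        try:
            ppm.append(float(parts[0]))
            intensity.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}:{lineno}: {exc}") from exc
    if len(ppm) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 data rows")
    return _finalize_axis(np.array(ppm), np.array(intensity), meta)


def _finalize_axis(ppm: np.ndarray, intensity: np.ndarray, meta: dict) -> Spectrum1D:
    """Normalise axis direction to descending; record a reversal."""
    _check_finite("ppm axis", ppm)
    _check_finite("intensity", intensity)
    d = np.diff(ppm)
    if np.all(d > 0):  # ascending input: flip
        ppm, intensity = ppm[::-1].copy(), intensity[::-1].copy()
        meta = dict(meta)
        meta["history"] = list(meta.get("history", [])) + [
            "axis reversed to descending ppm order"
        ]
    elif not np.all(d < 0):
        raise SpectrumValidationError("ppm axis is not strictly monotone")
    meta.setdefault("history", [])
    return Spectrum1D(ppm, intensity, meta=meta)


def _write_tabular_spectrum(spectrum: Spectrum1D, path: Path) -> None:
    lines = _meta_header_lines(spectrum.meta)
    lines += [
        f"{p:.12e},{y:.12e}" for p, y in zip(spectrum.ppm, spectrum.intensity)
    ]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# JCAMP-DX (subset: XYPOINTS, AFFN)
# ---------------------------------------------------------------------------

def _write_jcamp(spectrum: Spectrum1D, path: Path) -> None:
    n = spectrum.ppm.size
    header = [
        "##TITLE= oilscreen 1D 1H spectrum",
        "##JCAMP-DX= 5.01",
        "##DATA TYPE= NMR SPECTRUM",
        "##DATA CLASS= XYPOINTS",
        "##XUNITS= PPM",
        "##YUNITS= ARBITRARY UNITS",
        f"##NPOINTS= {n}",
        f"##FIRSTX= {spectrum.ppm[0]:.12e}",
        f"##LASTX= {spectrum.ppm[-1]:.12e}",
        "##XFACTOR= 1.0",
        "##YFACTOR= 1.0",
        f"##$OILSCREENMETA= {json.dumps(spectrum.meta)}",
        "##XYPOINTS= (XY..XY)",
    ]
    body = [
        f"{p:.12e}, {y:.12e}" for p, y in zip(spectrum.ppm, spectrum.intensity)
    ]
    path.write_text("\n".join(header + body + ["##END="]) + "\n")


def _read_jcamp(path: Path) -> Spectrum1D:
    records: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    in_points = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("$$"):
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.strip().upper().replace(" ", "")
            records[label] = value.strip()
            in_points = label == "XYPOINTS"
            if label == "END":
                break
            continue
        if in_points:
            parts = line.replace(";", ",").split(",")
            if len(parts) % 2 != 0:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: odd number of values in XY pair line"
                )
            try:
                vals = [float(v) for v in parts]
            except ValueError as exc:
                raise SpectrumFormatError(f"{path}:{lineno}: {exc}") from exc
            xs.extend(vals[0::2])
            ys.extend(vals[1::2])
    if "XYPOINTS" not in records:
        raise SpectrumFormatError(f"{path}: no ##XYPOINTS= record found")
    if len(xs) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 XY points")
    xf = float(records.get("XFACTOR", "1.0"))
    yf = float(records.get("YFACTOR", "1.0"))
    ppm = np.array(xs) * xf
    intensity = np.array(ys) * yf
    meta: dict = {}
    if "$OILSCREENMETA" in records:
        try:
            meta = json.loads(records["$OILSCREENMETA"])
        except json.JSONDecodeError:
            meta = {}
    n_declared = records.get("NPOINTS")
    if n_declared is not None and int(n_declared) != ppm.size:
        raise SpectrumFormatError(
            f"{path}: NPOINTS={n_declared} but {ppm.size} points present"
        )
    return _finalize_axis(ppm, intensity, meta)


# ---------------------------------------------------------------------------
# public spectrum API
# ---------------------------------------------------------------------------

_SPECTRUM_READERS = {"tabular": _read_tabular_spectrum, "jcamp": _read_jcamp}
_SPECTRUM_WRITERS = {"tabular": _write_tabular_spectrum, "jcamp": _write_jcamp}


def read_spectrum(path: str | Path, format: str = "tabular") -> Spectrum1D:
    """Read a 1D spectrum; the returned axis is always descending.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"tabular"`` (CSV ``ppm,intensity`` with ``#`` headers) or
        ``"jcamp"`` (JCAMP-DX XYPOINTS subset).
    """
    path = Path(path)
    try:
        reader = _SPECTRUM_READERS[format]
    except KeyError:
        raise ValueError(f"unknown spectrum format {format!r}") from None
    if not path.exists():
        raise FileNotFoundError(path)
    return reader(path)


def write_spectrum(spectrum: Spectrum1D, path: str | Path,
                   format: str = "tabular") -> Path:
    """Write a spectrum so that :func:`read_spectrum` recovers it."""
    path = Path(path)
    try:
        writer = _SPECTRUM_WRITERS[format]
    except KeyError:
        raise ValueError(f"unknown spectrum format {format!r}") from None
    writer(spectrum, path)
    return path


# ---------------------------------------------------------------------------
# FID I/O (tabular only; vendor 1D directories are out of core scope)
# ---------------------------------------------------------------------------

_REQUIRED_FID_META = ("dwell_time", "spectrometer_freq", "ppm_offset")


def read_fid(path: str | Path, format: str = "tabular") -> FID:
    """Read a complex FID from the tabular ``t,real,imag`` dialect.

    The header must carry ``dwell_time`` (s), ``spectrometer_freq``
    (MHz) and ``ppm_offset`` (ppm); missing metadata raises rather than
    defaulting silently.
    """
    if format != "tabular":
        raise ValueError(f"unsupported FID format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta, rows = _parse_header(path.read_text().splitlines())
    for key in _REQUIRED_FID_META:
        if key not in meta:
            raise SpectrumFormatError(
                f"{path}: missing required FID header '# {key}=...'"
            )
    re_parts, im_parts = [], []
    for lineno, row in rows:
        parts = row.split(",")
        if len(parts) != 3:
            raise SpectrumFormatError(
                f"{path}:{lineno}: expected 't,real,imag', got {row!r}"
            )
        try:
            re_parts.append(float(parts[1]))
            im_parts.append(float(parts[2]))
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}:{lineno}: {exc}") from exc
    dwell = float(meta.pop("dwell_time"))
    freq = float(meta.pop("spectrometer_freq"))
    offset = float(meta.pop("ppm_offset"))
    return FID(
        points=np.array(re_parts) + 1j * np.array(im_parts),
        dwell_time=dwell,
        spectrometer_freq=freq,
        ppm_offset=offset,
        meta=meta,
    )


def write_fid(fid: FID, path: str | Path) -> Path:
    """Write a FID in the tabular dialect read back by :func:`read_fid`."""
    path = Path(path)
    meta = {
        "dwell_time": repr(fid.dwell_time),
        "spectrometer_freq": repr(fid.spectrometer_freq),
        "ppm_offset": repr(fid.ppm_offset),
        **{k: v for k, v in fid.meta.items()},
    }
    lines = _meta_header_lines(meta)
    t = fid.times
    lines += [
        f"{ti:.12e},{p.real:.17e},{p.imag:.17e}"
        for ti, p in zip(t, fid.points)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path
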