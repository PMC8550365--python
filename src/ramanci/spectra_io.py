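"""Containers and text I/O for Raman spectra and PXRD diffractograms.

The package stores every trace with a strictly ascending axis (wavenumbers
in cm^-1 for Raman, degrees 2-theta for diffraction). Files written with
the axis descending — a common Raman instrument convention — are reversed
on ingestion and the original direction is recorded.

Supported on-disk formats are two-column delimited text (CSV/TSV/
whitespace, optional single header line, ``#`` comments) and JCAMP-DX 4.24
``##XYDATA=(X++(Y..Y))`` tables with AFFN-encoded values.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, ParseError, RangeError, ValidationError

__all__ = [
    "Spectrum",
    "Diffractogram",
    "SpectrumSet",
    "read_xy_table",
    "read_jcampdx",
    "write_xy_table",
    "resample",
]

PROBES = ("MR", "PHAT", "OTHER")
STATES = ("AS_RECEIVED", "MILLED", "SYNTHETIC")


def _validate_axis_pair(axis: np.ndarray, values: np.ndarray, what: str) -> None:
    if axis.ndim != 1 or values.ndim != 1:
        raise ValidationError(f"{what}: axis and values must be 1-D")
    if axis.size != values.size:
        raise ValidationError(
            f"{what}: axis length {axis.size} != values length {values.size}"
        )
    if axis.size < 2:
        raise ValidationError(f"{what}: need at least 2 points, got {axis.size}")
    if not np.all(np.isfinite(axis)):
        raise ValidationError(f"{what}: non-finite axis value")
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{what}: non-finite intensity value")
    d = np.diff(axis)
    if np.any(d == 0):
        raise ValidationError(f"{what}: duplicate axis values")
    if not np.all(d > 0):
        raise ValidationError(f"{what}: axis must be strictly increasing")


@dataclass(frozen=True)
class Spectrum:
    """A wavenumber-indexed Raman intensity trace.

    ``wavenumbers`` are cm^-1, strictly increasing; ``intensities`` are
    arbitrary detector units (dimensionless after pre-processing).
    ``processing_tags`` records the ordered transforms already applied.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""
    probe: str = "OTHER"
    state: str = "SYNTHETIC"
    replicate: int = 1
    processing_tags: tuple[str, ...] = ()
    source_descending: bool = False

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        _validate_axis_pair(wn, it, "Spectrum")
        if self.probe not in PROBES:
            raise ValidationError(f"unknown probe {self.probe!r}; expected one of {PROBES}")
        if self.state not in STATES:
            raise ValidationError(f"unknown state {self.state!r}; expected one of {STATES}")
        if int(self.replicate) < 1:
            raise ValidationError("replicate must be >= 1")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", it)
        object.__setattr__(self, "processing_tags", tuple(self.processing_tags))

    # -- convenience -------------------------------------------------------
    @property
    def axis(self) -> np.ndarray:
        return self.wavenumbers

    def value_at(self, wavenumber: float) -> float:
        """Linearly interpolated intensity at ``wavenumber`` (must lie in span)."""
        wn = self.wavenumbers
        if not (wn[0] <= wavenumber <= wn[-1]):
            raise RangeError(
                f"wavenumber {wavenumber} outside axis span [{wn[0]}, {wn[-1]}]"
            )
        return float(np.interp(wavenumber, wn, self.intensities))

    def with_intensities(self, intensities: np.ndarray, add_tag: str | None = None) -> "Spectrum":
        tags = self.processing_tags + ((add_tag,) if add_tag else ())
        return replace(self, intensities=np.asarray(intensities, dtype=float),
                       processing_tags=tags)

    def same_grid(self, other: "Spectrum") -> bool:
        return (self.wavenumbers.shape == other.wavenumbers.shape
                and bool(np.array_equal(self.wavenumbers, other.wavenumbers)))


@dataclass(frozen=True)
class Diffractogram:
    """A 2-theta-indexed PXRD counts trace."""

    two_theta: np.ndarray
    counts: np.ndarray
    sample_id: str = ""
    blank_subtracted: bool = False
    source_descending: bool = False

    def __post_init__(self) -> None:
        tt = np.asarray(self.two_theta, dtype=float)
        ct = np.asarray(self.counts, dtype=float)
        _validate_axis_pair(tt, ct, "Diffractogram")
        object.__setattr__(self, "two_theta", tt)
        object.__setattr__(self, "counts", ct)

    @property
    def axis(self) -> np.ndarray:
        return self.two_theta


@dataclass
class SpectrumSet:
    """An ordered collection of spectra sharing one wavenumber grid."""

    items: list[Spectrum] = field(default_factory=list)
    grouping_key: str = "sample_id"

    def __post_init__(self) -> None:
        self.items = list(self.items)
        if self.items:
            ax = self.items[0].wavenumbers
            for i, s in enumerate(self.items[1:], start=1):
                if not (s.wavenumbers.shape == ax.shape and np.array_equal(s.wavenumbers, ax)):
                    raise ValidationError(
                        f"SpectrumSet member {i} is on a different wavenumber grid"
                    )

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    @property
    def common_axis(self) -> np.ndarray:
        if not self.items:
            raise ValidationError("empty SpectrumSet has no axis")
        return self.items[0].wavenumbers

    def intensity_matrix(self) -> np.ndarray:
        """Rows = spectra, columns = wavenumber grid points."""
        if not self.items:
            raise ValidationError("empty SpectrumSet")
        return np.vstack([s.intensities for s in self.items])


# ---------------------------------------------------------------------------
# delimited text
# ---------------------------------------------------------------------------

_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _split_line(line: str, delimiter: str | None) -> list[str]:
    if delimiter is None:
        # try comma, then tab, then any whitespace
        for d in (",", "\t"):
            if d in line:
                return [f.strip() for f in line.split(d)]
        return line.split()
    return [f.strip() for f in line.split(delimiter)]


def read_xy_table(
    path: str | os.PathLike,
    kind: str = "spectrum",
    delimiter: str | None = None,
    **meta,
):
    """Read a two-column numeric table as a :class:`Spectrum` or
    :class:`Diffractogram`.

    Comment lines start with ``#``; one leading non-numeric header line is
    tolerated. Descending axes are reversed (recorded in
    ``source_descending``). Extra columns, duplicate axis values, non-numeric
    cells and tables shorter than two rows are rejected.
    """
    if kind not in ("spectrum", "diffractogram"):
        raise ValidationError(f"kind must be 'spectrum' or 'diffractogram', got {kind!r}")
    xs: list[float] = []
    ys: list[float] = []
    header_seen = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_line(line, delimiter)
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, found {len(fields)}"
                )
            if not (_NUMBER_RE.match(fields[0]) and _NUMBER_RE.match(fields[1])):
                # a single leading header line (non-numeric x column) is fine
                if not xs and not header_seen and not _NUMBER_RE.match(fields[0]):
                    header_seen = True
                    continue
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric cell in {fields!r}"
                )
            xs.append(float(fields[0]))
            ys.append(float(fields[1]))
    if len(xs) < 2:
        raise ValidationError(f"{path}: fewer than 2 numeric rows")
    x = np.array(xs)
    y = np.array(ys)
    descending = bool(np.all(np.diff(x) < 0))
    if descending:
        x, y = x[::-1], y[::-1]
    if np.any(np.diff(x) == 0):
        raise ValidationError(f"{path}: duplicate axis values")
    if kind == "spectrum":
        return Spectrum(x, y, source_descending=descending, **meta)
    return Diffractogram(x, y, source_descending=descending, **meta)


def write_xy_table(trace, path: str | os.PathLike, delimiter: str = ",") -> None:
    """Write a trace as two-column text with full float round-trip precision."""
    axis = trace.axis
    values = trace.intensities if isinstance(trace, Spectrum) else trace.counts
    with open(path, "w", encoding="utf-8") as fh:
        for x, y in zip(axis, values):
            fh.write(f"{x:.17g}{delimiter}{y:.17g}\n")


# ---------------------------------------------------------------------------
# JCAMP-DX (AFFN X++(Y..Y) only)
# ---------------------------------------------------------------------------

_LDR_RE = re.compile(r"^##([^=]+)=(.*)$")


def read_jcampdx(path: str | os.PathLike, **meta) -> Spectrum:
    """Read a JCAMP-DX 4.24 spectrum stored as an AFFN ``(X++(Y..Y))`` table.

    The axis is reconstructed from ``##FIRSTX``/``##DELTAX`` (or
    ``##LASTX``/``##NPOINTS``) and scaled by ``##XFACTOR``; intensities are
    the stored Y values times ``##YFACTOR``. Compressed encodings (DIFDUP,
    PAC, SQZ) are rejected. The leading X value of each data line is checked
    against the reconstructed grid.
    """
    records: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("$$")[0].rstrip()
            if not line:
                continue
            m = _LDR_RE.match(line)
            if m:
                label = m.group(1).strip().upper().replace(" ", "")
                value = m.group(2).strip()
                if label == "XYDATA":
                    if value.replace(" ", "") != "(X++(Y..Y))":
                        raise FormatError(
                            f"{path}: unsupported ##XYDATA form {value!r}; "
                            "only AFFN (X++(Y..Y)) is supported"
                        )
                    in_data = True
                    continue
                if label == "END":
                    in_data = False
                records[label] = value
                continue
            if in_data:
                data_lines.append(line)
    if not data_lines:
        raise FormatError(f"{path}: no ##XYDATA=(X++(Y..Y)) table found")

    def _need(label: str) -> float:
        if label not in records:
            raise FormatError(f"{path}: missing required ##{label}= record")
        try:
            return float(records[label])
        except ValueError as exc:
            raise FormatError(f"{path}: ##{label}= is not numeric") from exc

    xfactor = float(records.get("XFACTOR", "1") or 1)
    yfactor = float(records.get("YFACTOR", "1") or 1)
    firstx = _need("FIRSTX")

    ys: list[float] = []
    line_first_x: list[tuple[int, float]] = []
    for line in data_lines:
        toks = line.replace(",", " ").split()
        for tok in toks:
            if not _NUMBER_RE.match(tok):
                raise FormatError(
                    f"{path}: non-AFFN token {tok!r} in data table "
                    "(compressed encodings are not supported)"
                )
        vals = [float(t) for t in toks]
        if len(vals) < 2:
            raise FormatError(f"{path}: data line with no Y values: {line!r}")
        line_first_x.append((len(ys), vals[0]))
        ys.extend(vals[1:])

    n = len(ys)
    if n < 2:
        raise FormatError(f"{path}: fewer than 2 data points")
    if "DELTAX" in records:
        deltax = _need("DELTAX")
    elif "LASTX" in records and "NPOINTS" in records:
        npoints = int(_need("NPOINTS"))
        if npoints != n:
            raise FormatError(f"{path}: ##NPOINTS={npoints} but {n} Y values read")
        deltax = (_need("LASTX") - firstx) / (npoints - 1)
    else:
        raise FormatError(f"{path}: need ##DELTAX or ##LASTX/##NPOINTS")
    if deltax == 0:
        raise FormatError(f"{path}: DELTAX must be non-zero")

    # X-sequence check: the leading X of each line must match the grid.
    for idx, x0 in line_first_x:
        expected = firstx + deltax * idx
        if abs(x0 - expected) > abs(deltax) * 0.5 + 1e-9 * max(1.0, abs(expected)):
            raise FormatError(
                f"{path}: X-sequence mismatch at point {idx}: "
                f"line starts at {x0}, expected {expected}"
            )

    x = (firstx + deltax * np.arange(n)) * xfactor
    y = np.array(ys) * yfactor
    descending = x[0] > x[-1]
    if descending:
        x, y = x[::-1], y[::-1]
    return Spectrum(x, y, source_descending=bool(descending), **meta)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample(trace: Spectrum, grid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation).

    Resampling onto a subset of the original axis is exact.
    """
    grid = np.asarray(grid, dtype=float)
    wn = trace.wavenumbers
    if grid.size and (grid.min() < wn[0] or grid.max() > wn[-1]):
        raise RangeError(
            f"target grid [{grid.min()}, {grid.max()}] exceeds axis span "
            f"[{wn[0]}, {wn[-1]}]"
        )
    new_int = np.interp(grid, wn, trace.intensities)
    return replace(trace, wavenumbers=grid, intensities=new_int,
                   processing_tags=trace.processing_tags + ("resample",))
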