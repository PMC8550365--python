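"""Crystallinity indices for semi-crystalline cellulose.

Two routes are implemented:

* the **380-method**: a univariate Raman estimate. The measured spectrum is
  treated as a superposition of a crystalline and an amorphous
  contribution; an amorphous reference spectrum (from a ball-milled,
  amorphized sample) is scaled to the sample at 857 cm^-1 and subtracted
  at the 380 and 1096 cm^-1 bands. The band ratio

      R = (I_380 - I_380_am) / (I_1096 - I_1096_am)

  maps to a crystallinity index through a linear calibration
  %CI = (R - c) / m. Because the mapping is instrument-dependent, three
  calibrations are built in (``ORIGINAL`` for the FT-Raman system the
  method was developed on, ``MR`` and ``PHAT`` for small-spot and
  large-spot non-contact probe systems) and new ones can be fitted against
  PXRD.

* the **Segal peak-height PXRD index**: 100 * (I_200 - I_am) / I_200, with
  I_200 the mean counts in a narrow window on the cellulose 200 reflection
  (22.55-22.65 deg 2-theta) and I_am the mean counts on the amorphous
  scatter (18.65-18.75 deg 2-theta).
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    FitError,
    RangeError,
    ValidationError,
)
from .preprocess import scale_to_match_857
from .spectra_io import Diffractogram, Spectrum, SpectrumSet, resample

__all__ = [
    "BAND_CRYSTALLINE",
    "BAND_REFERENCE",
    "AmorphousReference",
    "CalibrationLine",
    "SegalWindows",
    "BatchCIResult",
    "peak_intensity",
    "build_amorphous_reference",
    "amorphous_subtracted_ratio",
    "ci_from_ratio",
    "segal_ci",
    "fit_calibration",
    "batch_ci",
    "builtin_calibration",
    "builtin_amorphous_stats",
    "save_calibration",
    "load_calibration",
    "save_amorphous_reference",
    "load_amorphous_reference",
    "spot_area_mm2",
]

#: Crystallinity-sensitive band (CCC/CO skeletal bending region), cm^-1.
BAND_CRYSTALLINE = 380.0
#: Internal-standard band (CC/CO stretch), cm^-1, largely order-insensitive.
BAND_REFERENCE = 1096.0

SCHEMA_VERSION = 1


def peak_intensity(s: Spectrum, center: float, half_window: float = 5.0) -> float:
    """Band intensity: maximum over grid points within ``center ± half_window``.

    A small window makes the read-off robust to wavenumber-calibration
    shifts of a couple of cm^-1. With ``half_window=0`` the linearly
    interpolated value exactly at ``center`` is returned.
    """
    wn = s.wavenumbers
    if half_window < 0:
        raise ValidationError("half_window must be >= 0")
    if half_window == 0:
        return s.value_at(center)
    lo, hi = center - half_window, center + half_window
    if hi < wn[0] or lo > wn[-1]:
        raise RangeError(
            f"window [{lo}, {hi}] cm^-1 does not intersect axis span "
            f"[{wn[0]}, {wn[-1]}]"
        )
    mask = (wn >= lo) & (wn <= hi)
    if not np.any(mask):
        raise RangeError(f"no grid points within [{lo}, {hi}] cm^-1")
    return float(np.max(s.intensities[mask]))


# ---------------------------------------------------------------------------
# amorphous reference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmorphousReference:
    """Averaged pre-processed amorphous spectrum with band statistics.

    ``i380``/``i1096`` are the mean and sample standard deviation of the
    per-spectrum band intensities across the ``n_spectra`` amorphous
    spectra averaged. ``spectrum`` may be ``None`` when only the band
    statistics are known (e.g. published instrument values); subtraction
    with 857-scaling then is unavailable.
    """

    spectrum: Spectrum | None
    i380_mean: float
    i380_sd: float
    i1096_mean: float
    i1096_sd: float
    n_spectra: int = 1
    probe: str = "OTHER"
    half_window: float = 5.0

    def __post_init__(self) -> None:
        if self.n_spectra < 1:
            raise ValidationError("n_spectra must be >= 1")
        if self.i380_sd < 0 or self.i1096_sd < 0:
            raise ValidationError("band-intensity sd must be >= 0")


#: Published averaged-amorphous band intensities (mean, sd) at 380 and
#: 1096 cm^-1 for the two probe systems, from pre-processed milled-MCC
#: spectra (MR: n = 70 spectra; PhAT: n = 55).
_AMORPHOUS_STATS = {
    "MR": {"i380": (0.627, 0.246), "i1096": (2.745, 0.489), "n": 70},
    "PHAT": {"i380": (1.194, 0.277), "i1096": (2.607, 0.277), "n": 55},
}


def builtin_amorphous_stats(probe: str) -> AmorphousReference:
    """Band-statistics-only amorphous reference for a built-in probe system."""
    key = probe.upper()
    if key not in _AMORPHOUS_STATS:
        raise ValidationError(
            f"no built-in amorphous statistics for probe {probe!r} "
            f"(available: {sorted(_AMORPHOUS_STATS)})"
        )
    st = _AMORPHOUS_STATS[key]
    return AmorphousReference(
        spectrum=None,
        i380_mean=st["i380"][0], i380_sd=st["i380"][1],
        i1096_mean=st["i1096"][0], i1096_sd=st["i1096"][1],
        n_spectra=st["n"], probe=key,
    )


def build_amorphous_reference(
    milled_set: SpectrumSet,
    probe: str = "OTHER",
    half_window: float = 5.0,
    require_tags: bool = True,
) -> AmorphousReference:
    """Average a set of pre-processed amorphous spectra into a reference.

    The reference spectrum is the pointwise mean; the 380/1096 cm^-1
    statistics are the mean and sample sd (n-1; zero for a single
    spectrum) of the per-spectrum band intensities.
    """
    if len(milled_set) == 0:
        raise ValidationError("cannot build an amorphous reference from an empty set")
    if require_tags:
        for i, s in enumerate(milled_set):
            if "baseline" not in s.processing_tags:
                raise ValidationError(
                    f"spectrum {i} ({s.sample_id!r}) is not pre-processed "
                    "(no 'baseline' tag); pass require_tags=False to override"
                )
    mat = milled_set.intensity_matrix()
    mean_spec = Spectrum(
        milled_set.common_axis, mat.mean(axis=0),
        sample_id="amorphous_reference", probe=probe, state="MILLED",
        processing_tags=milled_set[0].processing_tags + ("average",),
    )
    i380 = np.array([peak_intensity(s, BAND_CRYSTALLINE, half_window) for s in milled_set])
    i1096 = np.array([peak_intensity(s, BAND_REFERENCE, half_window) for s in milled_set])
    n = len(milled_set)
    sd = (lambda v: float(np.std(v, ddof=1))) if n > 1 else (lambda v: 0.0)
    return AmorphousReference(
        spectrum=mean_spec,
        i380_mean=float(i380.mean()), i380_sd=sd(i380),
        i1096_mean=float(i1096.mean()), i1096_sd=sd(i1096),
        n_spectra=n, probe=probe, half_window=half_window,
    )


def amorphous_subtracted_ratio(
    sample: Spectrum,
    ref: AmorphousReference,
    scale_at_857: bool = True,
    half_window: float = 5.0,
) -> float:
    """The amorphous-subtracted 380/1096 band ratio of a sample spectrum.

    With ``scale_at_857`` on (default), the reference spectrum is first
    rescaled to match the sample at 857 cm^-1 and the amorphous band
    intensities are re-read from the scaled reference; with it off, the
    stored band statistics are used as-is.
    """
    i380 = peak_intensity(sample, BAND_CRYSTALLINE, half_window)
    i1096 = peak_intensity(sample, BAND_REFERENCE, half_window)
    if scale_at_857:
        if ref.spectrum is None:
            raise ValidationError(
                "857-scaling requires a reference spectrum; this reference "
                "holds band statistics only (use scale_at_857=False)"
            )
        refspec = ref.spectrum
        if not sample.same_grid(refspec):
            refspec = resample(refspec, sample.wavenumbers)
        scaled = scale_to_match_857(sample, refspec)
        i380_am = peak_intensity(scaled, BAND_CRYSTALLINE, half_window)
        i1096_am = peak_intensity(scaled, BAND_REFERENCE, half_window)
    else:
        i380_am = ref.i380_mean
        i1096_am = ref.i1096_mean
    denom = i1096 - i1096_am
    if abs(denom) < 1e-12:
        raise DegenerateInputError(
            "sample is indistinguishable from the amorphous reference at "
            "1096 cm^-1 (zero denominator)"
        )
    return (i380 - i380_am) / denom


# ---------------------------------------------------------------------------
# calibration lines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationLine:
    """Linear map between the amorphous-subtracted band ratio and %CI.

    The stored model is the classical-calibration direction,
    ``ratio = m * %CI + c``; prediction inverts it as
    ``%CI = (ratio - c) / m``.
    """

    slope: float
    intercept: float
    label: str = "CUSTOM"
    pearson_r: float | None = None
    n_points: int | None = None
    fitted_on: str | None = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValidationError("calibration slope must be non-zero")
        if self.n_points is not None and self.n_points < 3:
            raise ValidationError("a fitted calibration needs >= 3 points")
        if self.pearson_r is not None and not (-1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12):
            raise ValidationError("pearson_r must lie in [-1, 1]")

    def ratio_at(self, ci: float) -> float:
        return self.slope * ci + self.intercept


#: Built-in calibrations: the original FT-Raman constants and the two
#: probe-specific re-calibrations against Segal PXRD crystallinity.
_BUILTIN_CALIBRATIONS = {
    "ORIGINAL": CalibrationLine(0.0065, 0.0286, label="ORIGINAL"),
    "MR": CalibrationLine(0.005, -0.134, label="MR"),
    "PHAT": CalibrationLine(0.005, -0.129, label="PHAT"),
}


def builtin_calibration(name: str) -> CalibrationLine:
    key = name.upper()
    if key not in _BUILTIN_CALIBRATIONS:
        raise ValidationError(
            f"unknown built-in calibration {name!r} "
            f"(available: {sorted(_BUILTIN_CALIBRATIONS)})"
        )
    return _BUILTIN_CALIBRATIONS[key]


def ci_from_ratio(ratio: float, cal: CalibrationLine, clip: bool = False) -> float:
    """Map a band ratio to %CI via ``(ratio - c) / m``.

    Not clipped by default: negative values diagnose a sample more
    amorphous than the reference. ``clip=True`` bounds the result to
    [0, 100] (a warning is the caller's concern via the returned value).
    """
    ci = (ratio - cal.intercept) / cal.slope
    if clip:
        import warnings

        if ci < 0 or ci > 100:
            warnings.warn(
                f"%CI {ci:.2f} clipped to [0, 100]", stacklevel=2
            )
        ci = min(max(ci, 0.0), 100.0)
    return float(ci)


def fit_calibration(pairs, label: str = "CUSTOM") -> CalibrationLine:
    """Fit ``ratio = m * %CI + c`` by ordinary least squares.

    ``pairs`` is a sequence of ``(ratio, ci_pxrd)`` tuples. The classical
    direction (ratio regressed on %CI) is used so that prediction inverts
    as %CI = (ratio - c)/m.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise FitError(f"need >= 3 calibration pairs, got {len(pairs)}")
    ratio = np.array([p[0] for p in pairs], dtype=float)
    ci = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(ci) == 0:
        raise FitError("all %CI values are equal: rank-deficient design")
    m, c = np.polyfit(ci, ratio, 1)
    if np.ptp(ratio) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(ci, ratio)[0, 1])
    return CalibrationLine(
        slope=float(m), intercept=float(c), label=label,
        pearson_r=r, n_points=len(pairs),
        fitted_on=_dt.date.today().isoformat(),
    )


# ---------------------------------------------------------------------------
# Segal PXRD index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegalWindows:
    """2-theta windows for the Segal peak-height crystallinity index."""

    crystalline_window: tuple[float, float] = (22.55, 22.65)
    amorphous_window: tuple[float, float] = (18.65, 18.75)

    def __post_init__(self) -> None:
        c, a = self.crystalline_window, self.amorphous_window
        if not (c[0] < c[1] and a[0] < a[1]):
            raise ValidationError("Segal windows must be non-empty intervals")
        if max(c[0], a[0]) <= min(c[1], a[1]):
            raise ValidationError("Segal windows must not overlap")


def _window_mean(d: Diffractogram, window: tuple[float, float], name: str) -> float:
    tt = d.two_theta
    if window[0] < tt[0] or window[1] > tt[-1]:
        raise RangeError(
            f"{name} window {window} outside diffractogram span "
            f"[{tt[0]}, {tt[-1]}]"
        )
    mask = (tt >= window[0]) & (tt <= window[1])
    if not np.any(mask):
        raise RangeError(f"{name} window {window} contains no grid points")
    return float(np.mean(d.counts[mask]))


def segal_ci(
    d: Diffractogram,
    windows: SegalWindows | None = None,
    blank: Diffractogram | None = None,
) -> float:
    """Segal peak-height crystallinity index, as a percentage.

    ``100 * (I_200 - I_am) / I_200`` with I_200 the mean counts over the
    crystalline (200-reflection) window and I_am over the amorphous-halo
    window. An optional blank diffractogram (sample holder only) is
    subtracted first. Invariant to scaling all counts by a positive
    constant.
    """
    w = windows or SegalWindows()
    counts = d.counts
    if blank is not None:
        if blank.two_theta.shape == d.two_theta.shape and np.array_equal(
            blank.two_theta, d.two_theta
        ):
            bcounts = blank.counts
        else:
            tt = d.two_theta
            if tt[0] < blank.two_theta[0] or tt[-1] > blank.two_theta[-1]:
                raise RangeError("blank does not cover the diffractogram span")
            bcounts = np.interp(tt, blank.two_theta, blank.counts)
        counts = counts - bcounts
        d = Diffractogram(d.two_theta, counts, sample_id=d.sample_id,
                          blank_subtracted=True)
    i200 = _window_mean(d, w.crystalline_window, "crystalline")
    iam = _window_mean(d, w.amorphous_window, "amorphous")
    if i200 <= 0:
        raise DegenerateInputError(
            f"crystalline-window intensity {i200} <= 0 after blank subtraction"
        )
    return 100.0 * (i200 - iam) / i200


# ---------------------------------------------------------------------------
# batch aggregation
# ---------------------------------------------------------------------------

@dataclass
class BatchCIResult:
    """Per-batch %CI aggregate over replicate spectra."""

    mean: float
    sd: float
    values: list[float]
    replicate_ids: list[str]
    n_failed: int = 0
    failures: list[str] = field(default_factory=list)


def batch_ci(
    replicates: SpectrumSet,
    ref: AmorphousReference,
    cal: CalibrationLine,
    scale_at_857: bool = True,
    half_window: float = 5.0,
    clip: bool = False,
) -> BatchCIResult:
    """%CI per replicate, aggregated as mean ± sample sd (sd 0 for n=1).

    A replicate whose ratio is degenerate (indistinguishable from the
    amorphous reference) is flagged and excluded; aggregation covers the
    remainder and the failure count is reported.
    """
    if len(replicates) == 0:
        raise ValidationError("batch_ci needs at least one replicate")
    values: list[float] = []
    ids: list[str] = []
    failures: list[str] = []
    for s in replicates:
        rid = f"{s.sample_id}/r{s.replicate}"
        try:
            ratio = amorphous_subtracted_ratio(s, ref, scale_at_857, half_window)
        except DegenerateInputError as exc:
            failures.append(f"{rid}: {exc}")
            continue
        values.append(ci_from_ratio(ratio, cal, clip=clip))
        ids.append(rid)
    if not values:
        raise DegenerateInputError(
            "every replicate failed the ratio computation: " + "; ".join(failures)
        )
    arr = np.asarray(values)
    sd = float(np.std(arr, ddof=1)) if len(values) > 1 else 0.0
    return BatchCIResult(
        mean=float(arr.mean()), sd=sd, values=values, replicate_ids=ids,
        n_failed=len(failures), failures=failures,
    )


# ---------------------------------------------------------------------------
# instrument geometry
# ---------------------------------------------------------------------------

def spot_area_mm2(diameter_um: float) -> float:
    """Irradiated spot area (mm^2) of a probe with the given nominal beam
    diameter (µm) at focus: pi * d^2 / 4."""
    if diameter_um <= 0:
        raise ValidationError("beam diameter must be positive")
    d_mm = diameter_um / 1000.0
    return math.pi * d_mm * d_mm / 4.0


# ---------------------------------------------------------------------------
# serialization (JSON, schema-versioned)
# ---------------------------------------------------------------------------

def save_calibration(cal: CalibrationLine, path: str | os.PathLike) -> None:
    doc = {
        "schema": "ramanci.calibration", "schema_version": SCHEMA_VERSION,
        "slope": cal.slope, "intercept": cal.intercept, "label": cal.label,
        "pearson_r": cal.pearson_r, "n_points": cal.n_points,
        "fitted_on": cal.fitted_on,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_calibration(path: str | os.PathLike) -> CalibrationLine:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("schema") != "ramanci.calibration":
        raise ValidationError(f"{path}: not a calibration file")
    return CalibrationLine(
        slope=doc["slope"], intercept=doc["intercept"],
        label=doc.get("label", "CUSTOM"), pearson_r=doc.get("pearson_r"),
        n_points=doc.get("n_points"), fitted_on=doc.get("fitted_on"),
    )


def save_amorphous_reference(ref: AmorphousReference, path: str | os.PathLike) -> None:
    doc = {
        "schema": "ramanci.amorphous_reference", "schema_version": SCHEMA_VERSION,
        "i380_mean": ref.i380_mean, "i380_sd": ref.i380_sd,
        "i1096_mean": ref.i1096_mean, "i1096_sd": ref.i1096_sd,
        "n_spectra": ref.n_spectra, "probe": ref.probe,
        "half_window": ref.half_window,
        "spectrum": None if ref.spectrum is None else {
            "wavenumbers": ref.spectrum.wavenumbers.tolist(),
            "intensities": ref.spectrum.intensities.tolist(),
            "processing_tags": list(ref.spectrum.processing_tags),
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def load_amorphous_reference(path: str | os.PathLike) -> AmorphousReference:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("schema") != "ramanci.amorphous_reference":
        raise ValidationError(f"{path}: not an amorphous-reference file")
    spec = None
    if doc.get("spectrum") is not None:
        sd = doc["spectrum"]
        spec = Spectrum(
            np.asarray(sd["wavenumbers"]), np.asarray(sd["intensities"]),
            sample_id="amorphous_reference", probe=doc.get("probe", "OTHER"),
            state="MILLED", processing_tags=tuple(sd.get("processing_tags", ())),
        )
    return AmorphousReference(
        spectrum=spec,
        i380_mean=doc["i380_mean"], i380_sd=doc["i380_sd"],
        i1096_mean=doc["i1096_mean"], i1096_sd=doc["i1096_sd"],
        n_spectra=doc["n_spectra"], probe=doc.get("probe", "OTHER"),
        half_window=doc.get("half_window", 5.0),
    )
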