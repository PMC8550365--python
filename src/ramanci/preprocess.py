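"""Spectral pre-processing: anchor-point baseline, SNV, 857 cm^-1 matching.

Fluorescence drift is removed by subtracting a piecewise-linear baseline
drawn through the spectrum's own intensities at fixed anchor wavenumbers;
residual multiplicative intensity differences are removed by standard
normal variate (SNV) scaling. Both are idempotent, and the pipeline is
invariant to multiplicative gain and to any background that is linear
between the anchors.

The default anchors are 200, 260, 550, 632, 743, 857, 952, 1200 and
1500 cm^-1, chosen to sit in band-free regions of the cellulose spectrum.
The 857 cm^-1 point doubles as the normalization point used when matching
an amorphous reference spectrum to a sample before spectral subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, RangeError, ValidationError
from .spectra_io import Spectrum

__all__ = [
    "DEFAULT_ANCHORS",
    "AnchorList",
    "anchor_baseline",
    "snv",
    "preprocess_pipeline",
    "scale_to_match_857",
]

#: Band-free anchor wavenumbers for the piecewise-linear fluorescence baseline.
DEFAULT_ANCHORS: tuple[float, ...] = (1500, 1200, 952, 857, 743, 632, 550, 260, 200)

MATCH_WAVENUMBER = 857.0


@dataclass(frozen=True)
class AnchorList:
    """A validated, ascending-sorted list of baseline anchor wavenumbers."""

    wavenumbers: tuple[float, ...] = DEFAULT_ANCHORS

    def __post_init__(self) -> None:
        wn = tuple(sorted(float(w) for w in self.wavenumbers))
        if len(wn) < 2:
            raise ValidationError("need at least 2 baseline anchors")
        if len(set(wn)) != len(wn):
            raise ValidationError("baseline anchors must be distinct")
        object.__setattr__(self, "wavenumbers", wn)

    def check_span(self, s: Spectrum) -> None:
        lo, hi = s.wavenumbers[0], s.wavenumbers[-1]
        for w in self.wavenumbers:
            if not (lo <= w <= hi):
                raise RangeError(
                    f"anchor {w} cm^-1 outside spectrum span [{lo}, {hi}]"
                )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.wavenumbers, dtype=float)


def _as_anchor_list(anchors) -> AnchorList:
    if anchors is None:
        return AnchorList()
    if isinstance(anchors, AnchorList):
        return anchors
    return AnchorList(tuple(anchors))


def anchor_baseline(s: Spectrum, anchors=None) -> Spectrum:
    """Subtract the piecewise-linear baseline through the anchor intensities.

    The baseline passes through ``(a_i, I(a_i))`` with off-grid anchor
    intensities read by linear interpolation; beyond the outermost anchors
    it continues flat at the terminal anchor value. The corrected spectrum
    is zero at every anchor, and a second application is a no-op.
    """
    al = _as_anchor_list(anchors)
    al.check_span(s)
    a = al.as_array()
    anchor_int = np.interp(a, s.wavenumbers, s.intensities)
    baseline = np.interp(s.wavenumbers, a, anchor_int)
    return s.with_intensities(s.intensities - baseline, add_tag="baseline")


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: subtract the spectrum mean, divide by its
    sample standard deviation (n-1), over the full stored axis."""
    mean = float(np.mean(s.intensities))
    sd = float(np.std(s.intensities, ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise DegenerateInputError(
            "SNV undefined: spectrum has zero intensity variance"
        )
    return s.with_intensities((s.intensities - mean) / sd, add_tag="snv")


def preprocess_pipeline(s: Spectrum, anchors=None, do_snv: bool = True) -> Spectrum:
    """Anchor-point baseline subtraction followed (by default) by SNV."""
    out = anchor_baseline(s, anchors)
    if do_snv:
        out = snv(out)
    return out


def scale_to_match_857(
    target: Spectrum,
    reference: Spectrum,
    match_wavenumber: float = MATCH_WAVENUMBER,
) -> Spectrum:
    """Rescale ``reference`` so its intensity at ``match_wavenumber`` equals
    the target's.

    Used to normalize an amorphous reference spectrum to a sample spectrum
    before amorphous subtraction: the 857 cm^-1 intensity is insensitive to
    crystalline order, so equalizing there puts both traces on one scale.
    """
    if not target.same_grid(reference):
        raise ValidationError("target and reference must share a wavenumber grid")
    t_val = target.value_at(match_wavenumber)
    r_val = reference.value_at(match_wavenumber)
    if r_val == 0 or not np.isfinite(r_val):
        raise DegenerateInputError(
            f"reference intensity at {match_wavenumber} cm^-1 is zero; "
            "cannot scale"
        )
    factor = t_val / r_val
    return reference.with_intensities(
        reference.intensities * factor, add_tag=f"scale@{match_wavenumber:g}"
    )
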