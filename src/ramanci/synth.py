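"""Synthetic Raman spectra and PXRD diffractograms with known crystallinity.

Semi-crystalline cellulose spectra are emulated as near-convex mixtures of
a crystalline and an amorphous component with a quadratic (Scheffe-type)
blend-interaction term,

    s(nu) = g * ( chi * C(nu) + (1 - chi) * A(nu)
                  + chi * (1 - chi) * I(nu) + B(nu) ) + eps,

with chi the crystalline mass fraction, g a log-normal multiplicative gain
(detector/focus variation, removed by SNV), B a smooth fluorescence
background (removed approximately by the anchor baseline; deliberately not
piecewise-linear over the anchors) and eps additive Gaussian noise scaled
to the clean signal maximum.

The interaction term models the mass-nonlinearity of Raman signal mixing
in binary powder compacts (differential scattering and sampling between
the fine milled and coarser unmilled particles). It vanishes at both
endmembers and defaults to a deficit at the crystallinity-sensitive
380 cm^-1 band. It is essential to the realism of the calibration study:
for an exactly mass-linear mixture whose amorphous endmember is also the
subtraction reference, the amorphous-subtracted 380/1096 ratio is
provably independent of chi (the subtraction removes the amorphous part
identically, leaving the crystalline component's fixed band contrast), so
no ratio-vs-crystallinity calibration line could exist. The observed
instrument calibrations demonstrate that real blends do not mix
mass-linearly; the quadratic term is the standard first-order model of
that nonideality. Set ``blend_nonideality = 0`` for an exactly linear
mixture. The component line shapes are sums of
analytic peaks at the ten wavenumbers known to track cellulose order (380,
437, 458, 521, 1096, 1120, 1330, 1340, 1380, 1475 cm^-1); the amorphous
component uses the same centers 2.5x broader, with the 380 band strongly
suppressed and the 1096 band moderately reduced.

Diffractograms carry a crystalline 200 reflection at 22.7 deg 2-theta and
an amorphous halo seen equally by both Segal windows, with amplitudes
normalized so the Segal index is linear in chi (see docs/methods.md).

Every generator output is a pure function of (config, arguments, seed);
per-spectrum random streams are derived from the master seed through a
counter scheme (``SeedSequence(master, spawn_key=counters)``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .spectra_io import Diffractogram, Spectrum, SpectrumSet

__all__ = [
    "PeakSpec",
    "SynthConfig",
    "GroundTruth",
    "DEFAULT_BLEND_FRACTIONS",
    "render_component",
    "synth_raman",
    "synth_blend_series",
    "synth_diffractogram",
    "synth_diffraction_blank",
    "synth_batch_panel",
]

#: The seven calibration-blend crystalline mass fractions (w/w).
DEFAULT_BLEND_FRACTIONS: tuple[float, ...] = (1.0, 0.83, 0.72, 0.58, 0.44, 0.33, 0.22)

_4LN2 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class PeakSpec:
    """An analytic line shape: gaussian, lorentzian or pseudo-Voigt."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"
    eta: float = 0.5  # pseudo-Voigt Lorentzian fraction

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValidationError("peak fwhm must be > 0")
        if self.amplitude <= 0:
            raise ValidationError("peak amplitude must be > 0")
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ValidationError(f"unknown peak shape {self.shape!r}")
        if not (0.0 <= self.eta <= 1.0):
            raise ValidationError("pseudo-Voigt eta must be in [0, 1]")

    def profile(self, x: np.ndarray) -> np.ndarray:
        u = (x - self.center) / self.fwhm
        gauss = np.exp(-_4LN2 * u * u)
        if self.shape == "gaussian":
            return self.amplitude * gauss
        lor = 1.0 / (1.0 + 4.0 * u * u)
        if self.shape == "lorentzian":
            return self.amplitude * lor
        return self.amplitude * (self.eta * lor + (1.0 - self.eta) * gauss)


def _peaks(*rows) -> tuple[PeakSpec, ...]:
    return tuple(PeakSpec(*r) for r in rows)


# Crystalline cellulose component: 1096 strongest, 380 strong.
DEFAULT_CRYSTALLINE_PEAKS = _peaks(
    (380.0, 14.0, 12.0),
    (437.0, 12.0, 2.5),
    (458.0, 12.0, 2.8),
    (521.0, 12.0, 2.2),
    (1096.0, 16.0, 12.0),
    (1120.0, 16.0, 4.0),
    (1330.0, 20.0, 2.5),
    (1340.0, 20.0, 2.5),
    (1380.0, 18.0, 2.0),
    (1475.0, 20.0, 2.5),
)

# Amorphous component: same centers, 2-3x broader; 380 strongly suppressed,
# 1096 reduced and broadened (order-sensitive bands collapse on milling),
# other bands roughly halved.
DEFAULT_AMORPHOUS_PEAKS = _peaks(
    (380.0, 35.0, 0.9),
    (437.0, 30.0, 1.25),
    (458.0, 30.0, 1.4),
    (521.0, 30.0, 1.1),
    (1096.0, 30.0, 3.0),
    (1120.0, 45.0, 1.2),
    (1330.0, 50.0, 1.25),
    (1340.0, 50.0, 1.25),
    (1380.0, 45.0, 1.0),
    (1475.0, 50.0, 1.25),
)

# PXRD: cellulose-I-like reflections; the 200 reflection at 22.7 deg.
DEFAULT_DIFFRACTION_PEAKS = _peaks(
    (14.9, 1.5, 6000.0),
    (16.4, 1.5, 4500.0),
    (22.7, 1.5, 10000.0),
)

#: Amorphous halo centered midway between the two Segal windows so both
#: windows see it equally; amplitude auto-normalized at render time.
DEFAULT_HALO = PeakSpec(20.65, 8.0, 1.0)


@dataclass(frozen=True)
class SynthConfig:
    """Defaults defining the simulated study conditions."""

    grid_min: float = 200.0
    grid_max: float = 1500.0
    grid_step: float = 1.0
    crystalline_peaks: tuple[PeakSpec, ...] = DEFAULT_CRYSTALLINE_PEAKS
    amorphous_peaks: tuple[PeakSpec, ...] = DEFAULT_AMORPHOUS_PEAKS
    #: fluorescence background polynomial coefficients in (nu - grid_min):
    #: B = c0 + c1*(nu-min) + c2*(nu-min)^2  (gentle upward curvature)
    background_coeffs: tuple[float, ...] = (0.8, 1.2e-3, 6.0e-7)
    #: overall strength of the quadratic blend-interaction term (same
    #: intensity units as the peak tables); 0 = exactly mass-linear mixing
    blend_nonideality: float = 16.0
    #: unit shape of the interaction deficit: a loss at the 380 band with a
    #: proportional smaller loss at 1096, balanced so the interaction is
    #: invisible to the amorphous-subtracted 1096 internal-standard read
    #: (see docs/methods.md); amplitudes are relative to blend_nonideality
    interaction_peaks: tuple[PeakSpec, ...] = (
        PeakSpec(380.0, 14.0, 1.0),
        PeakSpec(1096.0, 16.0, 0.15),
    )
    gain_sigma: float = 0.1          # log-normal gain spread
    noise_sd_frac: float = 0.01      # additive noise sd / max clean intensity
    #: per-probe amplitude multipliers for the (380, 1096) bands
    probe_effect: tuple[tuple[str, float, float], ...] = (
        ("MR", 1.0, 1.0),
        ("PHAT", 0.8, 1.15),
    )
    seed: int = 0
    # --- diffraction ---
    diffraction_grid: tuple[float, float, float] = (10.0, 30.0, 0.01)
    diffraction_peaks: tuple[PeakSpec, ...] = DEFAULT_DIFFRACTION_PEAKS
    halo: PeakSpec = DEFAULT_HALO
    diffraction_baseline: float = 10.0
    diffraction_noise: bool = True
    #: Segal windows used for halo-amplitude normalization
    segal_crystalline_window: tuple[float, float] = (22.55, 22.65)
    segal_amorphous_window: tuple[float, float] = (18.65, 18.75)

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)

    def diffraction_axis(self) -> np.ndarray:
        lo, hi, step = self.diffraction_grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    def probe_multipliers(self, probe: str) -> tuple[float, float]:
        for name, m380, m1096 in self.probe_effect:
            if name == probe:
                return (m380, m1096)
        return (1.0, 1.0)

    def background(self, grid: np.ndarray) -> np.ndarray:
        u = grid - self.grid_min
        out = np.zeros_like(grid)
        for k, c in enumerate(self.background_coeffs):
            out += c * u**k
        return out


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually produced for one trace."""

    chi: float
    probe: str = "MR"
    sample_id: str = ""
    replicate: int = 1
    gain: float = 1.0
    seed_counters: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.chi <= 1.0):
            raise ValidationError(f"crystalline fraction {self.chi} outside [0, 1]")


def _rng(master_seed: int, *counters: int) -> np.random.Generator:
    """Counter-derived random stream: stream (c1, c2, ...) of the master seed."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(c) for c in counters))
    return np.random.default_rng(ss)


def render_component(peaks, grid, **meta) -> Spectrum:
    """Sum of analytic line shapes on a grid (deterministic).

    An empty peak list renders an all-zero spectrum.
    """
    grid = np.asarray(grid, dtype=float)
    total = np.zeros_like(grid)
    for pk in peaks:
        total += pk.profile(grid)
    meta.setdefault("state", "SYNTHETIC")
    return Spectrum(grid, total, **meta)


def _apply_probe(peaks, cfg: SynthConfig, probe: str):
    m380, m1096 = cfg.probe_multipliers(probe)
    out = []
    for pk in peaks:
        if abs(pk.center - 380.0) < 2.0:
            pk = replace(pk, amplitude=pk.amplitude * m380)
        elif abs(pk.center - 1096.0) < 2.0:
            pk = replace(pk, amplitude=pk.amplitude * m1096)
        out.append(pk)
    return tuple(out)


def synth_raman(
    chi: float,
    cfg: SynthConfig | None = None,
    rng: np.random.Generator | None = None,
    probe: str = "MR",
    sample_id: str = "synthetic",
    replicate: int = 1,
    noise_sd_frac: float | None = None,
    fixed_gain: float | None = None,
    seed_counters: tuple[int, ...] = (),
) -> tuple[Spectrum, GroundTruth]:
    """One synthetic Raman spectrum with crystalline fraction ``chi``.

    ``fixed_gain`` pins the multiplicative gain (otherwise log-normal);
    ``noise_sd_frac`` overrides the config's noise level (0 for noise-free).
    """
    if not (0.0 <= chi <= 1.0):
        raise ValidationError(f"crystalline fraction {chi} outside [0, 1]")
    cfg = cfg or SynthConfig()
    if rng is None:
        rng = _rng(cfg.seed, *seed_counters)
    grid = cfg.grid()
    C = render_component(_apply_probe(cfg.crystalline_peaks, cfg, probe), grid).intensities
    A = render_component(_apply_probe(cfg.amorphous_peaks, cfg, probe), grid).intensities
    B = cfg.background(grid)
    inter = np.zeros_like(grid)
    for pk in cfg.interaction_peaks:
        inter -= cfg.blend_nonideality * pk.profile(grid)
    clean = chi * C + (1.0 - chi) * A + chi * (1.0 - chi) * inter + B
    gain = float(fixed_gain) if fixed_gain is not None else float(
        np.exp(rng.normal(0.0, cfg.gain_sigma))
    )
    frac = cfg.noise_sd_frac if noise_sd_frac is None else noise_sd_frac
    if frac < 0:
        raise ValidationError("noise_sd_frac must be >= 0")
    sd = frac * float(clean.max())
    eps = rng.normal(0.0, sd, size=grid.size) if sd > 0 else 0.0
    spec = Spectrum(
        grid, gain * clean + eps, sample_id=sample_id, probe=probe,
        state="SYNTHETIC", replicate=replicate,
    )
    truth = GroundTruth(chi=chi, probe=probe, sample_id=sample_id,
                        replicate=replicate, gain=gain,
                        seed_counters=tuple(seed_counters))
    return spec, truth


def synth_blend_series(
    fractions=DEFAULT_BLEND_FRACTIONS,
    n_replicates: int = 3,
    cfg: SynthConfig | None = None,
    probe: str = "MR",
    noise_sd_frac: float | None = None,
    fixed_gain: float | None = None,
    seed_stream: int = 1,
) -> tuple[SpectrumSet, list[GroundTruth]]:
    """Replicated blend series at the given crystalline fractions.

    Per-spectrum seeds are derived from the master seed with counters
    ``(seed_stream, blend_index, replicate)``; use distinct streams for
    independent series (e.g. the amorphous-reference replicates).
    """
    cfg = cfg or SynthConfig()
    items: list[Spectrum] = []
    truths: list[GroundTruth] = []
    for bi, chi in enumerate(fractions):
        for r in range(1, n_replicates + 1):
            s, t = synth_raman(
                chi, cfg, probe=probe,
                sample_id=f"blend_{int(round(100 * chi)):03d}",
                replicate=r, noise_sd_frac=noise_sd_frac,
                fixed_gain=fixed_gain, seed_counters=(seed_stream, bi, r),
            )
            items.append(s)
            truths.append(t)
    return SpectrumSet(items), truths


# ---------------------------------------------------------------------------
# diffraction
# ---------------------------------------------------------------------------

def _window_mean(axis: np.ndarray, values: np.ndarray, window) -> float:
    mask = (axis >= window[0]) & (axis <= window[1])
    return float(values[mask].mean())


def _halo_amplitude(cfg: SynthConfig, grid: np.ndarray, crystalline: np.ndarray) -> float:
    """Normalize the halo so both endmembers give equal mean counts in the
    Segal windows; the Segal index then varies linearly with chi."""
    unit = cfg.halo.profile(grid) / cfg.halo.amplitude
    target = _window_mean(grid, crystalline, cfg.segal_crystalline_window)
    base = _window_mean(grid, unit, cfg.segal_crystalline_window)
    return target / base


def synth_diffractogram(
    chi: float,
    cfg: SynthConfig | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "synthetic",
    noise: bool | None = None,
    seed_counters: tuple[int, ...] = (),
) -> tuple[Diffractogram, GroundTruth]:
    """Synthetic PXRD diffractogram with crystalline fraction ``chi``.

    Counts = chi * reflections + (1-chi) * halo + baseline + noise, with
    Gaussian noise of sd sqrt(max(counts, 1)) (Poisson approximation).
    """
    if not (0.0 <= chi <= 1.0):
        raise ValidationError(f"crystalline fraction {chi} outside [0, 1]")
    cfg = cfg or SynthConfig()
    if rng is None:
        rng = _rng(cfg.seed, *seed_counters)
    grid = cfg.diffraction_axis()
    cryst = np.zeros_like(grid)
    for pk in cfg.diffraction_peaks:
        cryst += pk.profile(grid)
    halo = cfg.halo.profile(grid) / cfg.halo.amplitude * _halo_amplitude(cfg, grid, cryst)
    clean = chi * cryst + (1.0 - chi) * halo + cfg.diffraction_baseline
    use_noise = cfg.diffraction_noise if noise is None else noise
    counts = clean
    if use_noise:
        counts = clean + rng.normal(0.0, np.sqrt(np.maximum(clean, 1.0)))
    d = Diffractogram(grid, counts, sample_id=sample_id)
    truth = GroundTruth(chi=chi, sample_id=sample_id,
                        seed_counters=tuple(seed_counters))
    return d, truth


def synth_diffraction_blank(
    cfg: SynthConfig | None = None,
    rng: np.random.Generator | None = None,
    noise: bool | None = None,
    seed_counters: tuple[int, ...] = (9,),
) -> Diffractogram:
    """Blank diffractogram (sample holder only): the flat baseline + noise."""
    cfg = cfg or SynthConfig()
    if rng is None:
        rng = _rng(cfg.seed, *seed_counters)
    grid = cfg.diffraction_axis()
    clean = np.full_like(grid, cfg.diffraction_baseline)
    use_noise = cfg.diffraction_noise if noise is None else noise
    counts = clean
    if use_noise:
        counts = clean + rng.normal(0.0, np.sqrt(np.maximum(clean, 1.0)))
    return Diffractogram(grid, counts, sample_id="blank")


# ---------------------------------------------------------------------------
# batch panel
# ---------------------------------------------------------------------------

@dataclass
class BatchPanel:
    """A multi-batch, multi-probe spectrum panel with ground truth."""

    spectra: SpectrumSet
    truths: list[GroundTruth]
    batch_of: list[str] = field(default_factory=list)

    def chi(self) -> np.ndarray:
        return np.array([t.chi for t in self.truths])

    def probes(self) -> list[str]:
        return [t.probe for t in self.truths]


def synth_batch_panel(
    n_batches: int = 30,
    ci_range: tuple[float, float] = (0.62, 0.74),
    replicates_per_probe: dict[str, int] | None = None,
    cfg: SynthConfig | None = None,
    position_jitter: float = 0.3,
    amplitude_jitter_sigma: float = 0.01,
) -> BatchPanel:
    """Emulate a panel of commercial batches measured with both probes.

    Per-batch crystalline fractions are drawn uniformly in ``ci_range``
    (default: the narrow spread typical of commercial semi-crystalline
    cellulose batches); each batch gets small peak-position jitter
    (<= ``position_jitter`` cm^-1) and log-normal amplitude jitter
    emulating material variability. Replicate counts per probe default to
    MR: 3, PHAT: 2. For model-calibration studies pass a deliberately
    spanned ``ci_range`` (e.g. 0.5-0.9), as one would design a
    calibration set.
    """
    if n_batches < 2:
        raise ValidationError("need at least 2 batches")
    cfg = cfg or SynthConfig()
    if replicates_per_probe is None:
        replicates_per_probe = {"MR": 3, "PHAT": 2}
    lo, hi = ci_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValidationError(f"ci_range {ci_range} outside [0, 1]")
    if lo == hi:
        warnings.warn("degenerate ci_range: all batches share one crystalline "
                      "fraction", stacklevel=2)
    batch_rng = _rng(cfg.seed, 2)
    chis = batch_rng.uniform(lo, hi, size=n_batches)
    items: list[Spectrum] = []
    truths: list[GroundTruth] = []
    batch_of: list[str] = []
    for b in range(n_batches):
        jit_rng = _rng(cfg.seed, 3, b)
        def _jitter(peaks):
            out = []
            for pk in peaks:
                dc = jit_rng.uniform(-position_jitter, position_jitter)
                fa = float(np.exp(jit_rng.normal(0.0, amplitude_jitter_sigma)))
                out.append(replace(pk, center=pk.center + dc,
                                   amplitude=pk.amplitude * fa))
            return tuple(out)

        bcfg = replace(cfg,
                       crystalline_peaks=_jitter(cfg.crystalline_peaks),
                       amorphous_peaks=_jitter(cfg.amorphous_peaks))
        bid = f"batch_{b + 1:02d}"
        for probe, n_rep in replicates_per_probe.items():
            for r in range(1, n_rep + 1):
                s, t = synth_raman(
                    float(chis[b]), bcfg, probe=probe, sample_id=bid,
                    replicate=r, seed_counters=(4, b, 0 if probe == "MR" else 1, r),
                )
                items.append(s)
                truths.append(t)
                batch_of.append(bid)
    return BatchPanel(SpectrumSet(items), truths, batch_of)
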