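"""User-facing workflows: pre-processing, 380-method %CI, calibration
against PXRD, PLS model fit/predict, and PCA exploration.

Each workflow takes a :class:`RunConfig`, reads the referenced files,
writes CSV result tables plus a JSON provenance block (input hashes,
echoed configuration, package version) into the output directory, and
returns its in-memory result. The command-line interface in
:mod:`ramanci.cli` is a thin wrapper over these functions.

The module also provides :func:`calibration_study`, the synthetic
end-to-end calibration experiment: a replicated blend series with matched
diffractograms, Segal indices, a fitted ratio-vs-%CI line and per-blend
380-method predictions. It mirrors the bench procedure of calibrating the
380-method against PXRD on binary crystalline/amorphous blends.
"""

from __future__ import annotations

import dataclasses
import glob as _glob
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, DegenerateInputError, RamanCIError
from .spectra_io import Spectrum, SpectrumSet, read_jcampdx, read_xy_table
from .preprocess import AnchorList, preprocess_pipeline
from .crystallinity import (
    AmorphousReference,
    CalibrationLine,
    SegalWindows,
    amorphous_subtracted_ratio,
    batch_ci,
    build_amorphous_reference,
    builtin_calibration,
    ci_from_ratio,
    fit_calibration,
    load_amorphous_reference,
    load_calibration,
    save_calibration,
    segal_ci,
)
from .chemometrics import (
    build_data_matrix,
    correlation_loadings,
    grouped_segments,
    load_pls_model,
    nipals_pca,
    pca_cv_variance,
    pls1_fit,
    pls_cv_rmse,
    pls_predict,
    regression_metrics,
    save_pls_model,
)
from .synth import (
    DEFAULT_BLEND_FRACTIONS,
    SynthConfig,
    synth_blend_series,
    synth_diffraction_blank,
    synth_diffractogram,
)

__all__ = [
    "RunConfig",
    "CalibrationStudy",
    "calibration_study",
    "workflow_ci380",
    "workflow_calibrate",
    "workflow_model",
    "workflow_pca",
    "load_spectra",
]


# ---------------------------------------------------------------------------
# configuration and provenance
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration shared by the command-line workflows."""

    inputs: list[str] = field(default_factory=list)
    probe: str = "OTHER"
    anchors: tuple[float, ...] | None = None
    do_snv: bool = True
    calibration: str | None = None       # builtin name or file path
    amorphous_ref: str | None = None     # file path
    model_file: str | None = None
    y_table: str | None = None           # CSV with sample_id,ci columns
    out_dir: str = "."
    seed: int = 0
    max_factors: int = 10
    n_factors: int | None = None
    scale_at_857: bool = True
    clip: bool = False


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_provenance(cfg: RunConfig, out_dir: str, workflow: str, extra=None) -> None:
    doc = {
        "workflow": workflow,
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "inputs": {p: _sha256(p) for p in cfg.inputs if os.path.isfile(p)},
    }
    if extra:
        doc.update(extra)
    with open(os.path.join(out_dir, f"{workflow}_provenance.json"), "w",
              encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _expand_inputs(patterns) -> list[str]:
    paths: list[str] = []
    for pat in patterns:
        hits = sorted(_glob.glob(pat)) if any(ch in pat for ch in "*?[") else [pat]
        paths.extend(hits)
    if not paths:
        raise ConfigError(f"no input files match {list(patterns)!r}")
    missing = [p for p in paths if not os.path.isfile(p)]
    if missing:
        raise ConfigError(f"missing input files: {missing}")
    return paths


def load_spectra(paths, probe: str = "OTHER") -> SpectrumSet:
    """Read spectra (CSV/TSV or JCAMP-DX by extension) onto one grid."""
    items = []
    for p in paths:
        sid = os.path.splitext(os.path.basename(p))[0]
        if p.lower().endswith((".jdx", ".dx", ".jcm")):
            s = read_jcampdx(p, sample_id=sid, probe=probe, state="AS_RECEIVED")
        else:
            s = read_xy_table(p, "spectrum", sample_id=sid, probe=probe,
                              state="AS_RECEIVED")
        items.append(s)
    return SpectrumSet(items)


def _resolve_calibration(cfg: RunConfig) -> CalibrationLine:
    if not cfg.calibration:
        raise ConfigError("no calibration specified (built-in name or file)")
    if os.path.isfile(cfg.calibration):
        return load_calibration(cfg.calibration)
    try:
        return builtin_calibration(cfg.calibration)
    except RamanCIError as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# the synthetic calibration study (blends + PXRD -> calibration -> %CI)
# ---------------------------------------------------------------------------

@dataclass
class CalibrationStudy:
    """Result of the end-to-end synthetic blend calibration experiment."""

    fractions: tuple[float, ...]
    segal_ci: np.ndarray              # per blend, %
    mean_ratio: np.ndarray            # per blend
    calibration: CalibrationLine
    predicted_ci: np.ndarray          # per blend, mean over replicates, %
    replicate_ci: list[list[float]]   # per blend, per replicate
    reference: AmorphousReference

    def recovery_error(self) -> np.ndarray:
        """Predicted minus generated crystallinity, % points, per blend."""
        return self.predicted_ci - 100.0 * np.asarray(self.fractions)


def calibration_study(
    cfg: SynthConfig | None = None,
    fractions=DEFAULT_BLEND_FRACTIONS,
    n_replicates: int = 3,
    n_reference: int = 30,
    noise_sd_frac: float | None = None,
    scale_at_857: bool = True,
    anchors=None,
) -> CalibrationStudy:
    """Run the full synthetic 380-method calibration pipeline.

    Generates the replicated blend series and a matched diffractogram per
    blend, pre-processes everything, builds the amorphous reference from
    ``n_reference`` fraction-0 spectra (a generously averaged reference,
    as is standard practice), computes Segal %CI per blend (with blank
    subtraction), fits the ratio-vs-%CI calibration on per-blend mean
    ratios and predicts %CI for every replicate.
    """
    cfg = cfg or SynthConfig()
    if len(fractions) < 3:
        raise ConfigError("need at least 3 blend fractions to calibrate")
    blends, truths = synth_blend_series(
        fractions, n_replicates, cfg, noise_sd_frac=noise_sd_frac, seed_stream=1
    )
    refs, _ = synth_blend_series(
        [0.0], n_reference, cfg, noise_sd_frac=noise_sd_frac, seed_stream=2
    )
    pp = SpectrumSet([preprocess_pipeline(s, anchors) for s in blends])
    ref = build_amorphous_reference(
        SpectrumSet([preprocess_pipeline(s, anchors) for s in refs])
    )
    chi = np.array([t.chi for t in truths])
    ratios = np.array(
        [amorphous_subtracted_ratio(s, ref, scale_at_857=scale_at_857) for s in pp]
    )
    use_noise = (cfg.noise_sd_frac if noise_sd_frac is None else noise_sd_frac) > 0
    blank = synth_diffraction_blank(cfg, noise=use_noise)
    segal = np.empty(len(fractions))
    mean_ratio = np.empty(len(fractions))
    for bi, frac in enumerate(fractions):
        d, _ = synth_diffractogram(frac, cfg, noise=use_noise, seed_counters=(5, bi))
        segal[bi] = segal_ci(d, blank=blank)
        mean_ratio[bi] = ratios[chi == frac].mean()
    cal = fit_calibration(list(zip(mean_ratio, segal)), label="SYNTH")
    pred = np.array([ci_from_ratio(r, cal) for r in ratios])
    predicted = np.array([pred[chi == f].mean() for f in fractions])
    per_rep = [[float(v) for v in pred[chi == f]] for f in fractions]
    return CalibrationStudy(
        fractions=tuple(fractions), segal_ci=segal, mean_ratio=mean_ratio,
        calibration=cal, predicted_ci=predicted, replicate_ci=per_rep,
        reference=ref,
    )


# ---------------------------------------------------------------------------
# file-driven workflows
# ---------------------------------------------------------------------------

def workflow_ci380(cfg: RunConfig) -> pd.DataFrame:
    """380-method %CI for every input spectrum, aggregated per sample.

    Spectra failing pre-processing or with a degenerate amorphous
    denominator are flagged; the run continues and the summary carries a
    warning count.
    """
    paths = _expand_inputs(cfg.inputs)
    cal = _resolve_calibration(cfg)
    if not cfg.amorphous_ref:
        raise ConfigError("ci380 requires an amorphous reference file")
    ref = load_amorphous_reference(cfg.amorphous_ref)
    spectra = load_spectra(paths, probe=cfg.probe)
    anchors = AnchorList(cfg.anchors) if cfg.anchors else None
    rows = []
    n_warn = 0
    for p, s in zip(paths, spectra):
        row = {"path": p, "sample_id": s.sample_id, "probe": cfg.probe,
               "calibration": cal.label}
        try:
            pp = preprocess_pipeline(s, anchors, do_snv=cfg.do_snv)
            ratio = amorphous_subtracted_ratio(
                pp, ref, scale_at_857=cfg.scale_at_857 and ref.spectrum is not None
            )
            row["ratio"] = ratio
            row["ci_pct"] = ci_from_ratio(ratio, cal, clip=cfg.clip)
            row["flag"] = ""
        except RamanCIError as exc:
            row.update(ratio=np.nan, ci_pct=np.nan, flag=str(exc))
            n_warn += 1
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[table["flag"] == ""]
    agg = (ok.groupby("sample_id")["ci_pct"]
             .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
                  n="count")
             .reset_index())
    os.makedirs(cfg.out_dir, exist_ok=True)
    table.to_csv(os.path.join(cfg.out_dir, "ci380_per_spectrum.csv"), index=False)
    agg.to_csv(os.path.join(cfg.out_dir, "ci380_per_sample.csv"), index=False)
    _write_provenance(cfg, cfg.out_dir, "ci380",
                      {"warnings": n_warn, "anchor_list": list(
                          (anchors or AnchorList()).wavenumbers)})
    return table


def workflow_calibrate(cfg: RunConfig, diffractograms: list[str],
                       blank: str | None = None) -> CalibrationLine:
    """Fit a ratio-vs-%CI calibration from blend spectra + diffractograms.

    ``cfg.inputs`` are blend spectra (replicates share a sample_id prefix
    before the last ``_rN``); ``diffractograms`` is one XY file per blend,
    matched to the blends by sorted sample id.
    """
    paths = _expand_inputs(cfg.inputs)
    dpaths = _expand_inputs(diffractograms)
    if not cfg.amorphous_ref:
        raise ConfigError("calibrate requires an amorphous reference file")
    ref = load_amorphous_reference(cfg.amorphous_ref)
    spectra = load_spectra(paths, probe=cfg.probe)
    anchors = AnchorList(cfg.anchors) if cfg.anchors else None
    by_blend: dict[str, list[float]] = {}
    for s in spectra:
        blend_id = s.sample_id.rsplit("_r", 1)[0]
        pp = preprocess_pipeline(s, anchors)
        ratio = amorphous_subtracted_ratio(
            pp, ref, scale_at_857=cfg.scale_at_857 and ref.spectrum is not None
        )
        by_blend.setdefault(blend_id, []).append(ratio)
    blends = sorted(by_blend)
    if len(blends) < 3:
        raise ConfigError(f"need >= 3 blends, got {len(blends)}")
    if len(dpaths) != len(blends):
        raise ConfigError(
            f"{len(blends)} blends but {len(dpaths)} diffractograms"
        )
    blank_d = read_xy_table(blank, "diffractogram") if blank else None
    pairs = []
    report_rows = []
    for blend_id, dpath in zip(blends, sorted(dpaths)):
        d = read_xy_table(dpath, "diffractogram", sample_id=blend_id)
        ci = segal_ci(d, blank=blank_d)
        ratio = float(np.mean(by_blend[blend_id]))
        pairs.append((ratio, ci))
        report_rows.append({"blend": blend_id, "mean_ratio": ratio,
                            "segal_ci_pct": ci,
                            "n_replicates": len(by_blend[blend_id])})
    cal = fit_calibration(pairs, label=cfg.probe or "CUSTOM")
    os.makedirs(cfg.out_dir, exist_ok=True)
    pd.DataFrame(report_rows).to_csv(
        os.path.join(cfg.out_dir, "calibration_pairs.csv"), index=False)
    save_calibration(cal, os.path.join(cfg.out_dir, "calibration.json"))
    _write_provenance(cfg, cfg.out_dir, "calibrate",
                      {"pearson_r": cal.pearson_r, "n_points": cal.n_points})
    return cal


def workflow_model(cfg: RunConfig, mode: str = "fit",
                   groups=None) -> pd.DataFrame:
    """Fit a PLS crystallinity model or predict with a stored one.

    Fit mode requires ``cfg.y_table`` (CSV with ``sample_id`` and ``ci``
    columns); writes the model file plus per-factor statistics. Predict
    mode requires ``cfg.model_file``; writes predictions and, when the y
    table is supplied, validation metrics.
    """
    paths = _expand_inputs(cfg.inputs)
    spectra = load_spectra(paths, probe=cfg.probe)
    anchors = AnchorList(cfg.anchors) if cfg.anchors else None
    pp = SpectrumSet([preprocess_pipeline(s, anchors) for s in spectra])
    ids = [s.sample_id for s in pp]
    X = build_data_matrix(pp, groups=groups)
    os.makedirs(cfg.out_dir, exist_ok=True)
    if mode == "fit":
        if not cfg.y_table:
            raise ConfigError("fit mode requires a y table (sample_id, ci)")
        ytab = pd.read_csv(cfg.y_table).set_index("sample_id")["ci"]
        try:
            y = np.array([float(ytab[i]) for i in ids])
        except KeyError as exc:
            raise ConfigError(f"y table misses sample {exc}") from exc
        model = pls1_fit(X, y, cfg.max_factors)
        if len(set(X.groups)) >= 2:
            segs = grouped_segments(X.groups)
            model.rmsecv = pls_cv_rmse(X, y, segs, cfg.max_factors)
        save_pls_model(model, os.path.join(cfg.out_dir, "pls_model.json"))
        stats = pd.DataFrame({
            "n_factors": np.arange(1, model.max_factors + 1),
            "rmsec": model.rmsec,
            "explained_cal_pct": model.explained_cal,
            "bias": model.bias_cal,
            "rmsecv": model.rmsecv if model.rmsecv is not None
            else [np.nan] * model.max_factors,
        })
        stats.to_csv(os.path.join(cfg.out_dir, "pls_factor_stats.csv"),
                     index=False)
        _write_provenance(cfg, cfg.out_dir, "pls_fit")
        return stats
    if mode != "predict":
        raise ConfigError(f"unknown model mode {mode!r}")
    if not cfg.model_file:
        raise ConfigError("predict mode requires a model file")
    model = load_pls_model(cfg.model_file)
    k = cfg.n_factors or model.max_factors
    try:
        yhat = pls_predict(model, X, k)
    except RamanCIError as exc:
        raise ConfigError(str(exc)) from exc
    out = pd.DataFrame({"sample_id": ids, "predicted_ci_pct": yhat,
                        "n_factors": k})
    extra = {}
    if cfg.y_table:
        ytab = pd.read_csv(cfg.y_table).set_index("sample_id")["ci"]
        y = np.array([float(ytab[i]) for i in ids])
        out["reference_ci_pct"] = y
        extra = regression_metrics(y, yhat)
        extra = {"rmsep": extra["rmse"], "bias": extra["bias"],
                 "explained_val_pct": extra["explained_variance_pct"],
                 "pearson_r": extra["pearson_r"]}
    out.to_csv(os.path.join(cfg.out_dir, "pls_predictions.csv"), index=False)
    _write_provenance(cfg, cfg.out_dir, "pls_predict", extra or None)
    return out


def workflow_pca(cfg: RunConfig, n_components: int = 2,
                 groups=None) -> pd.DataFrame:
    """PCA exploration: scores, loadings, correlation loadings, variances."""
    paths = _expand_inputs(cfg.inputs)
    spectra = load_spectra(paths, probe=cfg.probe)
    anchors = AnchorList(cfg.anchors) if cfg.anchors else None
    pp = SpectrumSet([preprocess_pipeline(s, anchors) for s in spectra])
    X = build_data_matrix(pp, groups=groups)
    model = nipals_pca(X, n_components)
    val = None
    if len(set(X.groups)) >= 2:
        segs = grouped_segments(X.groups)
        val = pca_cv_variance(X, segs, n_components)
    else:
        import warnings

        warnings.warn("single group: cross-validation skipped", stacklevel=2)
    C, flagged = correlation_loadings(model, X)
    os.makedirs(cfg.out_dir, exist_ok=True)
    cols = [f"PC{k + 1}" for k in range(n_components)]
    scores = pd.DataFrame(model.scores, columns=cols)
    scores.insert(0, "sample_id", X.sample_ids)
    scores.insert(1, "group", X.groups)
    scores.to_csv(os.path.join(cfg.out_dir, "pca_scores.csv"), index=False)
    pd.DataFrame(model.loadings.T, columns=cols).assign(
        wavenumber=X.wavenumbers
    ).to_csv(os.path.join(cfg.out_dir, "pca_loadings.csv"), index=False)
    pd.DataFrame(C, columns=cols).assign(
        wavenumber=X.wavenumbers, zero_variance=flagged
    ).to_csv(os.path.join(cfg.out_dir, "pca_correlation_loadings.csv"),
             index=False)
    summary = pd.DataFrame({
        "component": cols,
        "explained_cal_pct": model.explained_cal,
        "explained_val_pct": val if val is not None
        else [np.nan] * n_components,
    })
    summary.to_csv(os.path.join(cfg.out_dir, "pca_variance.csv"), index=False)
    _write_provenance(cfg, cfg.out_dir, "pca")
    return scores
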