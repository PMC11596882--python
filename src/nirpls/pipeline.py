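"""End-to-end orchestration of the quantification procedure.

Stage order for one resolution:

1. convert transmittance to absorbance;
2. full-spectrum cross-validated RMSECV curve, plus the fixed 3-component
   full-spectrum RMSECV used as the iPLS baseline;
3. iPLS: split into k equal-width subintervals, cross-validate each,
   keep those beating the baseline, reconstruct the retained region;
4. for every pretreatment chain in the screening grid: fit the chain on
   the reconstructed calibration data, cross-validate, pick a component
   count, refit on all calibration spectra;
5. choose the winning chain by smallest RMSECV (ties: fewer components,
   then lower LOD), fit the predicted-vs-reference calibration curve and
   the 3.3sigma/s / 10sigma/s limits;
6. predict the independent validation series and the replicate sets.

Model selection never sees validation data; everything is deterministic
given the configuration and inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ipls, metrics, pls
from .preprocess import (PreprocessConfig, apply_chain, chain_from_name,
                         config_from_yaml, config_to_yaml, default_chain_grid,
                         fit_apply_chain)
from .spectra import SpectrumSet, to_absorbance

log = logging.getLogger("nirpls")


@dataclass(frozen=True)
class PipelineConfig:
    interval_count: int = 12
    baseline_components: int = 3
    chain_names: tuple[str, ...] = tuple(default_chain_grid())
    max_components: int = 10
    component_tol_rel: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chain_names:
            raise ValueError("preprocessing grid must be non-empty")
        if self.interval_count < 2:
            raise ValueError("interval count must be >= 2")
        if self.baseline_components < 1 or self.max_components < 1:
            raise ValueError("component counts must be >= 1")


@dataclass
class CalibrationResult:
    """One screened pretreatment chain with its fitted model and merits."""

    chain_name: str
    chain: PreprocessConfig
    model: pls.PLSModel
    n_components: int
    rmsecv: float
    rmsec: float
    curve: metrics.CalibrationCurve
    limits: metrics.DetectionLimits


@dataclass
class ResolutionReport:
    resolution: float
    full_rmsecv_curve: list[float]
    baseline_rmsecv: float
    interval_results: list[ipls.IntervalResult]
    selected_indices: tuple[int, ...]
    reconstructed_span: tuple[float, float]
    chain_results: list[CalibrationResult]
    winner: CalibrationResult
    validation: metrics.ValidationReport | None

    def to_dict(self) -> dict:
        def chain_dict(c: CalibrationResult) -> dict:
            return {
                "chain": c.chain_name,
                "n_components": c.n_components,
                "rmsecv": c.rmsecv,
                "rmsec": c.rmsec,
                "slope": c.curve.slope,
                "intercept": c.curve.intercept,
                "r_squared": c.curve.r_squared,
                "sigma": c.limits.sigma,
                "lod": c.limits.lod,
                "loq": c.limits.loq,
            }

        return {
            "resolution": self.resolution,
            "full_rmsecv_curve": list(self.full_rmsecv_curve),
            "baseline_rmsecv": self.baseline_rmsecv,
            "intervals": [
                {"index": r.index, "hi": r.hi, "lo": r.lo,
                 "best_n_components": r.best_n_components, "rmsecv": r.rmsecv}
                for r in self.interval_results
            ],
            "selected_indices": list(self.selected_indices),
            "reconstructed_span": list(self.reconstructed_span),
            "chains": [chain_dict(c) for c in self.chain_results],
            "winner": chain_dict(self.winner),
            "validation": None if self.validation is None
            else self.validation.to_dict(),
        }


@dataclass
class RunReport:
    """Per-resolution reports of one study run."""

    per_resolution: dict[float, ResolutionReport] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {str(k): v.to_dict() for k, v in sorted(self.per_resolution.items())}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _blank_sigma(predicted: np.ndarray, fractions: np.ndarray) -> float:
    """SD of the predicted contents of the blank (lowest-content)
    calibration sample's replicate spectra."""
    blank = fractions == fractions.min()
    vals = predicted[blank]
    return float(vals.std(ddof=1)) if vals.size > 1 else 0.0


def _evaluate_chain(
    name: str,
    recon: SpectrumSet,
    y: np.ndarray,
    groups: np.ndarray,
    config: PipelineConfig,
) -> CalibrationResult:
    chain = chain_from_name(name)
    fitted, Z = fit_apply_chain(chain, recon)
    curve = pls.cross_validate(Z.intensities, y, config.max_components, groups)
    n = pls.select_n_components(curve, config.component_tol_rel)
    model = pls.fit_pls(Z.intensities, y, n)
    train_pred = pls.predict(model, Z.intensities)
    cal_curve = metrics.fit_calibration_curve(y, train_pred)
    sigma = _blank_sigma(train_pred, y)
    limits = metrics.detection_limits(sigma, cal_curve.slope)
    log.info("chain %-9s N=%d RMSECV=%.4f", name, n, curve[n - 1])
    return CalibrationResult(
        chain_name=name,
        chain=fitted,
        model=model,
        n_components=n,
        rmsecv=float(curve[n - 1]),
        rmsec=metrics.rmse(y, train_pred),
        curve=cal_curve,
        limits=limits,
    )


def run_full_pipeline(
    config: PipelineConfig,
    calibration: SpectrumSet,
    validation: SpectrumSet | None = None,
    replicate_sets: dict[str, SpectrumSet] | None = None,
) -> ResolutionReport:
    """Run the complete procedure on one calibration (+validation) set."""
    if not calibration.has_known_fractions:
        raise PipelineError("input", "calibration fractions must all be known")
    cal = to_absorbance(calibration)
    y = cal.fractions
    groups = np.asarray(cal.sample_ids)

    try:
        full_curve = pls.cross_validate(
            cal.intensities, y, config.max_components, groups)
        baseline = ipls.full_spectrum_baseline(
            cal, y, config.baseline_components, groups)
    except ValueError as e:
        raise PipelineError("full-spectrum", str(e)) from e
    log.info("full-spectrum baseline RMSECV (%d comps) = %.4f",
             config.baseline_components, baseline)

    try:
        intervals = ipls.split_intervals(cal, config.interval_count)
        iresults = ipls.evaluate_intervals(
            intervals, y, config.max_components, groups, config.component_tol_rel)
        selection = ipls.select_and_reconstruct(iresults, baseline, cal)
    except ValueError as e:
        raise PipelineError("ipls", str(e)) from e
    recon = selection.reconstructed
    log.info("selected intervals %s -> %.0f-%.0f cm^-1",
             selection.selected_indices,
             recon.wavenumbers[0], recon.wavenumbers[-1])

    try:
        chain_results = [
            _evaluate_chain(name, recon, y, groups, config)
            for name in config.chain_names
        ]
    except ValueError as e:
        raise PipelineError("preprocessing-grid", str(e)) from e
    winner = min(
        chain_results,
        key=lambda c: (c.rmsecv, c.n_components, c.limits.lod),
    )
    log.info("winner: %s (N=%d, RMSECV=%.4f)", winner.chain_name,
             winner.n_components, winner.rmsecv)

    validation_report = None
    if validation is not None:
        try:
            k = config.interval_count
            val_recon = ipls.reconstruct(
                to_absorbance(validation), selection.selected_indices, k)
            reps = {}
            for key, s in (replicate_sets or {}).items():
                reps[key] = ipls.reconstruct(
                    to_absorbance(s), selection.selected_indices, k)
            validation_report = metrics.validate_model(
                winner.model, winner.chain, val_recon,
                precision_set=reps.get("precision"),
                repeatability_set=reps.get("repeatability"),
                stability_set=reps.get("stability"),
            )
            log.info("validation RMSEP = %.4f", validation_report.rmsep)
        except ValueError as e:
            raise PipelineError("validation", str(e)) from e

    return ResolutionReport(
        resolution=calibration.resolution,
        full_rmsecv_curve=[float(v) for v in full_curve],
        baseline_rmsecv=float(baseline),
        interval_results=iresults,
        selected_indices=selection.selected_indices,
        reconstructed_span=(float(recon.wavenumbers[0]),
                            float(recon.wavenumbers[-1])),
        chain_results=chain_results,
        winner=winner,
        validation=validation_report,
    )


def run_study(
    config: PipelineConfig,
    resolutions: tuple[float, ...] = (2.0, 4.0, 8.0),
    grid_step: float = 1.0,
    noise=None,
) -> RunReport:
    """Simulate the full study (one synthetic dataset per resolution)
    and run the pipeline on each."""
    from . import simulate

    grid = simulate.default_grid(grid_step)
    report = RunReport()
    for i, res in enumerate(resolutions):
        nm = noise or simulate.NoiseModel()
        nm = dataclasses.replace(nm, seed=nm.seed + 100 * i)
        cal = simulate.generate_mixture_set(
            grid=grid, resolution=res, noise=nm)
        val, reps = simulate.make_validation_and_replicate_sets(
            grid=grid, resolution=res, noise=nm)
        report.per_resolution[res] = run_full_pipeline(config, cal, val, reps)
    return report


# ---------------------------------------------------------------------------
# markdown report
# ---------------------------------------------------------------------------

def report_to_markdown(report: RunReport | ResolutionReport,
                       path: str | Path | None = None) -> str:
    """Render the winning models and validation predictions as markdown
    tables (4-decimal, half-up rounding)."""
    if isinstance(report, ResolutionReport):
        report = RunReport(per_resolution={report.resolution: report})
    r4 = lambda v: f"{metrics.round_half_up(v, 4):.4f}"  # noqa: E731
    lines = ["# Quantification report", "",
             "## Optimal models per resolution", "",
             "| Pretreatment | Resolution | N | RMSECV (%) | RMSEP (%) | "
             "RMSEC (%) | R^2 | LOD | LOQ |",
             "|---|---|---|---|---|---|---|---|---|"]
    for res, rep in sorted(report.per_resolution.items()):
        w = rep.winner
        rmsep = "" if rep.validation is None else r4(rep.validation.rmsep)
        lines.append(
            f"| {w.chain_name} | {res:g} cm-1 | {w.n_components} | "
            f"{r4(w.rmsecv)} | {rmsep} | {r4(w.rmsec)} | "
            f"{r4(w.curve.r_squared)} | {r4(w.limits.lod)} | "
            f"{r4(w.limits.loq)} |")
    has_validation = any(r.validation is not None
                         for r in report.per_resolution.values())
    if has_validation:
        lines += ["", "## Validation predictions", ""]
        header = "| Sample | Reference (%) |" + "".join(
            f" {r.winner.chain_name} ({res:g} cm-1) |"
            for res, r in sorted(report.per_resolution.items())
            if r.validation is not None)
        reps = [r for _, r in sorted(report.per_resolution.items())
                if r.validation is not None]
        lines.append(header)
        lines.append("|---|---|" + "---|" * len(reps))
        nval = reps[0].validation.n
        for i in range(nval):
            row = (f"| V{i + 1} | {r4(reps[0].validation.reference[i])} |"
                   + "".join(f" {r4(r.validation.predicted[i])} |"
                             for r in reps))
            lines.append(row)
        for label, attr in (("Precision (RSD%)", "rsd_precision"),
                            ("Repeatability (RSD%)", "rsd_repeatability"),
                            ("Stability (RSD%)", "rsd_stability")):
            vals = [getattr(r.validation, attr) for r in reps]
            if all(v is None for v in vals):
                continue
            lines.append("| " + label + " | |" + "".join(
                f" {'' if v is None else r4(v)} |" for v in vals))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# model bundle (chain + PLS model + band selection) for predict/validate
# ---------------------------------------------------------------------------

def save_model_bundle(result: CalibrationResult,
                      selected_indices: tuple[int, ...],
                      interval_count: int,
                      path: str | Path) -> None:
    payload = {
        "format_version": 1,
        "chain_name": result.chain_name,
        "chain_yaml": config_to_yaml(result.chain),
        "model": pls.model_to_dict(result.model),
        "selected_indices": list(selected_indices),
        "interval_count": interval_count,
        "calibration_curve": dataclasses.asdict(result.curve),
        "detection_limits": dataclasses.asdict(result.limits),
        "rmsecv": result.rmsecv,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_model_bundle(path: str | Path) -> dict:
    data = json.loads(Path(path).read_text())
    if data.get("format_version") != 1:
        raise ValueError("unsupported model bundle format")
    data["chain"] = config_from_yaml(data.pop("chain_yaml"))
    data["model"] = pls.model_from_dict(data["model"])
    data["selected_indices"] = tuple(data["selected_indices"])
    return data


def predict_unknowns(bundle: dict, sset: SpectrumSet) -> np.ndarray:
    """Predict contents of unknown spectra with a saved model bundle."""
    recon = ipls.reconstruct(to_absorbance(sset), bundle["selected_indices"],
                             bundle["interval_count"])
    return pls.predict(bundle["model"],
                       apply_chain(bundle["chain"], recon).intensities)
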