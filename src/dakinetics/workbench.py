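"""End-to-end experiment: cohorts → averages → fits → genotype contrast.

``run_experiment`` reproduces the analysis applied to the in vivo data:
generate (or, with zero noise/CV, deterministically simulate) one evoked
recording per animal and genotype, compute per-animal trace metrics,
compare clearance half-times between genotypes with Welch's t-test,
average recordings within genotype, fit the model to each average with
Vm and DAP free, and report the percent reductions of both parameters in
the knockout.

Everything an invocation used — seeds, parameters, integrator settings —
is written to a provenance log; wall-clock timestamps are confined to that
log, so two runs with the same config produce byte-identical result files.
"""

from __future__ import annotations

import hashlib
import json
import math
import time as _time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import (
    DEFAULT_BOUNDS,
    FitResult,
    GenotypeComparison,
    compare_genotypes,
    fit_trace,
    midpoint_start,
)
from .io import ParseError, parameters_from_dict, protocol_from_dict, write_recording
from .metrics import trace_metrics, welch_t
from .model import DEFAULT_DT, StimulusProtocol, ValidationError
from .synthetic import (
    DEFAULT_DURATION,
    DEFAULT_SAMPLE_RATE,
    CohortSpec,
    animal_seed,
    average_recordings,
    generate_cohort,
)

__all__ = ["ExperimentConfig", "load_experiment_config", "run_experiment"]

_COHORT_KEYS = {"parameters", "n_animals", "between_animal_cv", "noise_sd_um"}
_RECORDING_KEYS = {"duration_s", "sample_rate_hz", "dt_s"}
_FITTING_KEYS = {"free", "bounds"}


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated configuration for one WT-vs-KO experiment."""

    protocol: StimulusProtocol
    wt: CohortSpec
    ko: CohortSpec
    free: tuple
    bounds: dict
    dt: float
    seed: int

    def to_dict(self) -> dict:
        def cohort_block(spec: CohortSpec) -> dict:
            p = spec.mean_params.as_dict()
            return {
                "parameters": p,
                "n_animals": spec.n_animals,
                "between_animal_cv": spec.between_animal_cv,
                "noise_sd_um": spec.noise_sd,
            }

        return {
            "seed": self.seed,
            "protocol": {
                "n_pulses": self.protocol.n_pulses,
                "frequency_hz": self.protocol.frequency,
                "current_ma": self.protocol.current,
                "onset_s": self.protocol.onset,
            },
            "recording": {
                "duration_s": self.wt.duration,
                "sample_rate_hz": self.wt.sample_rate,
                "dt_s": self.dt,
            },
            "cohorts": {"wt": cohort_block(self.wt), "ko": cohort_block(self.ko)},
            "fitting": {
                "free": list(self.free),
                "bounds": {k: list(v) for k, v in self.bounds.items()},
            },
        }


def _build_config(raw: dict, origin: str = "config") -> ExperimentConfig:
    if not isinstance(raw, dict):
        raise ParseError(f"{origin}: config must be a mapping")
    unknown = set(raw) - {"seed", "protocol", "recording", "cohorts", "fitting"}
    if unknown:
        raise ParseError(f"{origin}: unknown top-level key(s): {sorted(unknown)}")
    seed = int(raw.get("seed", 0))
    protocol = protocol_from_dict(raw.get("protocol", {}))

    rec_block = dict(raw.get("recording", {}))
    unknown = set(rec_block) - _RECORDING_KEYS
    if unknown:
        raise ParseError(f"{origin}: unknown recording key(s): {sorted(unknown)}")
    duration = float(rec_block.get("duration_s", DEFAULT_DURATION))
    sample_rate = float(rec_block.get("sample_rate_hz", DEFAULT_SAMPLE_RATE))
    dt = float(rec_block.get("dt_s", DEFAULT_DT))

    cohorts = raw.get("cohorts", {})
    unknown = set(cohorts) - {"wt", "ko"}
    if unknown:
        raise ParseError(f"{origin}: unknown cohort key(s): {sorted(unknown)}")
    specs = {}
    for idx, genotype in enumerate(("wt", "ko")):
        block = dict(cohorts.get(genotype, {}))
        bad = set(block) - _COHORT_KEYS
        if bad:
            raise ParseError(f"{origin}: unknown {genotype} cohort key(s): {sorted(bad)}")
        params = parameters_from_dict(block.get("parameters", {}))
        specs[genotype] = CohortSpec(
            genotype=genotype,
            mean_params=params,
            n_animals=int(block.get("n_animals", 5)),
            between_animal_cv=float(block.get("between_animal_cv", 0.0)),
            noise_sd=float(block.get("noise_sd_um", 0.0)),
            sample_rate=sample_rate,
            duration=duration,
            seed=animal_seed(seed, idx),  # per-genotype stream from the global seed
        )

    fit_block = dict(raw.get("fitting", {}))
    unknown = set(fit_block) - _FITTING_KEYS
    if unknown:
        raise ParseError(f"{origin}: unknown fitting key(s): {sorted(unknown)}")
    free = tuple(fit_block.get("free", ["vm", "dap"]))
    bounds = {**DEFAULT_BOUNDS}
    for name, pair in dict(fit_block.get("bounds", {})).items():
        if name not in DEFAULT_BOUNDS:
            raise ParseError(f"{origin}: bounds given for unknown parameter {name!r}")
        bounds[name] = (float(pair[0]), float(pair[1]))

    return ExperimentConfig(
        protocol=protocol,
        wt=specs["wt"],
        ko=specs["ko"],
        free=free,
        bounds=bounds,
        dt=dt,
        seed=seed,
    )


def load_experiment_config(path) -> ExperimentConfig:
    """Load and validate an experiment YAML config."""
    raw = yaml.safe_load(Path(path).read_text())
    return _build_config(raw, origin=str(path))


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _welch_on_half_times(wt_vals, ko_vals) -> dict:
    """Welch test on per-animal t½, degenerate noise-free case handled.

    With zero noise and zero between-animal CV every t½ is identical; the
    Welch statistic is then undefined (zero variance), and the comparison
    degenerates to t = 0, p = 1 when the group values all coincide.
    """
    wt = np.asarray(wt_vals, dtype=float)
    ko = np.asarray(ko_vals, dtype=float)
    if wt.var(ddof=1) == 0 and ko.var(ddof=1) == 0:
        df = float(wt.size + ko.size - 2)
        if ko.mean() == wt.mean():
            return {"t": 0.0, "df": df, "p": 1.0, "degenerate": True}
        t = math.inf if ko.mean() > wt.mean() else -math.inf
        return {"t": t, "df": df, "p": 0.0, "degenerate": True}
    t, df, p = welch_t(ko, wt)  # direction: KO − WT (KO slower → t > 0)
    return {"t": t, "df": df, "p": p, "degenerate": False}


def run_experiment(config: ExperimentConfig, outdir) -> tuple[GenotypeComparison, dict]:
    """Run the full pipeline and write all result files under ``outdir``."""
    outdir = Path(outdir)
    (outdir / "recordings").mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"dakinetics {__version__} experiment run",
        f"started: {_time.strftime('%Y-%m-%dT%H:%M:%S')}",
        "config_sha256: "
        + hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        f"global_seed: {config.seed}",
        f"integrator: rk4 fixed-step dt={config.dt} s, zero initial state",
    ]
    timings = {}
    report: dict = {"config": config.to_dict()}

    def _stage(name):
        timings[name] = _time.perf_counter()

    def _stage_done(name):
        log_lines.append(f"stage {name}: {_time.perf_counter() - timings[name]:.2f} s")

    try:
        _stage("generate")
        cohorts = {}
        manifest_rows = []
        for spec in (config.wt, config.ko):
            recs = generate_cohort(spec, config.protocol, dt=config.dt)
            cohorts[spec.genotype] = recs
            log_lines.append(f"cohort {spec.genotype}: seed={spec.seed} n={spec.n_animals}")
            for i, rec in enumerate(recs):
                write_recording(rec, outdir / "recordings" / f"{spec.genotype}_{i:02d}.csv")
                row = {
                    "animal": f"{spec.genotype}_{i:02d}",
                    "genotype": spec.genotype,
                    "seed": rec.metadata["seed"],
                }
                row.update(
                    {
                        k.removeprefix("param_"): v
                        for k, v in rec.metadata.items()
                        if k.startswith("param_")
                    }
                )
                manifest_rows.append(row)
        pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.csv", index=False)
        _stage_done("generate")

        _stage("metrics")
        metric_rows = []
        half_times = {"wt": [], "ko": []}
        for genotype, recs in cohorts.items():
            for i, rec in enumerate(recs):
                m = trace_metrics(rec, config.protocol)
                half_times[genotype].append(m.t_half)
                metric_rows.append(
                    {
                        "animal": f"{genotype}_{i:02d}",
                        "genotype": genotype,
                        "peak_um": m.peak_amplitude,
                        "peak_time_s": m.peak_time,
                        "t_half_s": m.t_half,
                        "baseline_um": m.baseline,
                    }
                )
        metrics_df = pd.DataFrame(metric_rows)
        metrics_df.to_csv(outdir / "metrics.csv", index=False, float_format="%.12g")
        welch = _welch_on_half_times(half_times["wt"], half_times["ko"])
        _json_dump(welch, outdir / "welch_t_half.json")
        report["welch_t_half"] = welch
        report["metrics"] = metric_rows
        _stage_done("metrics")

        _stage("fit")
        fits: dict[str, FitResult] = {}
        for spec in (config.wt, config.ko):
            avg = average_recordings(cohorts[spec.genotype])
            write_recording(avg, outdir / f"averaged_{spec.genotype}.csv")
            init = spec.mean_params.with_values(
                free=frozenset(config.free),
                **midpoint_start(config.free, config.bounds),
            )
            fit = fit_trace(
                avg, config.protocol, init, bounds=config.bounds, dt=config.dt
            )
            fits[spec.genotype] = fit
            _json_dump(fit.as_dict(), outdir / f"fit_{spec.genotype}.json")
            log_lines.append(
                f"fit {spec.genotype}: converged={fit.converged} "
                f"nfev={fit.n_evaluations} rss={fit.rss:.6g}"
            )
        _stage_done("fit")

        comparison = compare_genotypes(fits["wt"], fits["ko"])
        _json_dump(comparison.as_dict(), outdir / "comparison.json")
        report["comparison"] = comparison.as_dict()
        report["fits"] = {g: f.as_dict() for g, f in fits.items()}
    except (ValidationError, ParseError) as exc:
        log_lines.append(f"FAILED: {type(exc).__name__}: {exc}")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise

    log_lines.append(f"finished: {_time.strftime('%Y-%m-%dT%H:%M:%S')}")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return comparison, report
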