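"""Nonlinear least-squares fitting of the kinetic model to FSCV recordings.

The fit minimises the unweighted sum of squared residuals between a
recording and the simulated electrode dopamine sampled on the recording's
grid, over the parameters named in the free mask (default: ``vm`` and
``dap``, mirroring the two parameters that differ between genotypes).

Optimisation runs in log10 space under box bounds with scipy's bounded
trust-region-reflective least squares: the problem is smooth and
low-dimensional, so a deterministic single start suffices and keeps
results bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .metrics import r_squared
from .model import (
    DEFAULT_DT,
    FSCVRecording,
    KineticParameters,
    StimulusProtocol,
    ValidationError,
    observable,
    simulate,
)

__all__ = [
    "FitResult",
    "GenotypeComparison",
    "ComparisonError",
    "DEFAULT_BOUNDS",
    "midpoint_start",
    "fit_trace",
    "compare_genotypes",
]

#: Default box bounds per fittable parameter (same units as the parameter).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "vm": (0.01, 50.0),
    "dap": (0.001, 10.0),
    "km": (0.01, 10.0),
    "L": (0.01, 1.0),
    "ks": (0.1, 100.0),
    "ke": (0.1, 100.0),
    "k1ads": (1e-4, 10.0),
    "k2ads": (1e-4, 10.0),
    "k3ads": (1e-4, 10.0),
}


class ComparisonError(ValueError):
    """Two fits are not comparable (mismatched fixed parameters or failed fit)."""


@dataclass(frozen=True)
class FitResult:
    """Outcome of one trace fit.

    ``params`` carries the fitted values substituted into the free fields;
    ``rss`` is in μM², ``r2`` is computed against the fitted recording.
    """

    params: KineticParameters
    r2: float
    rss: float
    n_evaluations: int
    converged: bool
    free_names: tuple
    message: str = ""

    def as_dict(self) -> dict:
        return {
            "params": self.params.as_dict(),
            "r2": self.r2,
            "rss": self.rss,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "free_names": list(self.free_names),
            "message": self.message,
        }


@dataclass(frozen=True)
class GenotypeComparison:
    """WT-vs-KO contrast of the two genotype-defining parameters.

    Percent reductions are ``100 · (WT − KO) / WT``.
    """

    vm_wt: float
    vm_ko: float
    dap_wt: float
    dap_ko: float

    @property
    def pct_reduction_vm(self) -> float:
        if self.vm_wt <= 0:
            raise ComparisonError("percent reduction undefined for WT Vm <= 0")
        return 100.0 * (self.vm_wt - self.vm_ko) / self.vm_wt

    @property
    def pct_reduction_dap(self) -> float:
        if self.dap_wt <= 0:
            raise ComparisonError("percent reduction undefined for WT DAP <= 0")
        return 100.0 * (self.dap_wt - self.dap_ko) / self.dap_wt

    def as_dict(self) -> dict:
        return {
            "vm_wt": self.vm_wt,
            "vm_ko": self.vm_ko,
            "dap_wt": self.dap_wt,
            "dap_ko": self.dap_ko,
            "pct_reduction_vm": round(self.pct_reduction_vm, 1),
            "pct_reduction_dap": round(self.pct_reduction_dap, 1),
            "pct_reduction_vm_rounded": round(self.pct_reduction_vm),
            "pct_reduction_dap_rounded": round(self.pct_reduction_dap),
        }


def midpoint_start(free_names, bounds=None) -> dict:
    """Default initial guess: midpoint of each parameter's bounds in log space."""
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    return {
        name: math.sqrt(bounds[name][0] * bounds[name][1]) for name in free_names
    }


def fit_trace(
    rec: FSCVRecording,
    protocol: StimulusProtocol,
    init: KineticParameters,
    bounds: dict | None = None,
    dt: float = DEFAULT_DT,
    max_nfev: int = 200,
) -> FitResult:
    """Fit the model to one recording over the free parameters of ``init``.

    ``init`` supplies both the fixed-parameter values and the starting point
    for the free ones.  Non-convergence is reported through
    ``FitResult.converged``, never raised.
    """
    free = sorted(init.free)
    if not free:
        raise ValidationError("free mask is empty: nothing to fit")
    if len(rec.time) < 3:
        raise ValidationError("recording too short to fit")
    duration = float(rec.time[-1])
    if duration <= protocol.end:
        raise ValidationError("recording ends before the stimulus does")
    sample_rate = rec.sample_rate

    merged_bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    lo = np.array([merged_bounds[name][0] for name in free])
    hi = np.array([merged_bounds[name][1] for name in free])
    x0 = np.array([getattr(init, name) for name in free], dtype=float)
    x0 = np.clip(x0, lo, hi)

    def model_signal(values: np.ndarray) -> np.ndarray:
        params = init.with_values(**dict(zip(free, values)))
        trace = simulate(params, protocol, duration=duration, dt=dt)
        pred = observable(trace, sample_rate=sample_rate)
        if pred.signal.shape != rec.signal.shape:
            raise ValidationError(
                "simulated observable does not align with the recording grid"
            )
        return pred.signal

    def residual(log_x: np.ndarray) -> np.ndarray:
        return model_signal(10.0 ** log_x) - rec.signal

    result = least_squares(
        residual,
        x0=np.log10(x0),
        bounds=(np.log10(lo), np.log10(hi)),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=max_nfev,
    )
    fitted_values = 10.0 ** result.x
    params = init.with_values(**dict(zip(free, fitted_values)))
    pred = FSCVRecording(time=rec.time, signal=model_signal(fitted_values))
    rss = float(result.fun @ result.fun)
    r2 = r_squared(rec, pred)
    return FitResult(
        params=params,
        r2=r2,
        rss=rss,
        n_evaluations=int(result.nfev),
        converged=bool(result.status > 0),
        free_names=tuple(free),
        message=str(result.message),
    )


def compare_genotypes(fit_wt: FitResult, fit_ko: FitResult) -> GenotypeComparison:
    """Contrast two converged genotype fits on Vm and DAP.

    Both fits must share the same fixed-parameter values; otherwise the
    percent reductions would confound the genotype contrast with a
    configuration difference.
    """
    if not (fit_wt.converged and fit_ko.converged):
        raise ComparisonError("both fits must have converged")
    if fit_wt.params.fixed_values() != fit_ko.params.fixed_values():
        raise ComparisonError(
            "fits used different fixed parameter values and are not comparable"
        )
    return GenotypeComparison(
        vm_wt=fit_wt.params.vm,
        vm_ko=fit_ko.params.vm,
        dap_wt=fit_wt.params.dap,
        dap_ko=fit_ko.params.dap,
    )
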