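"""Synthetic FSCV recordings and genotype cohorts.

The in vivo experiment design records one evoked transient per animal, with
4–5 animals per genotype, then averages within genotype before fitting.
No recordings are publicly deposited, so this module generates them:

* measurement noise — additive i.i.d. Gaussian on the sampled observable
  (magnitude in μM, or conveniently expressed as a fraction of the
  simulated peak);
* between-animal variability — the free parameters of each animal are
  drawn log-normally around the cohort median, preserving positivity,
  with a specified coefficient of variation (CV);
* seeding — every animal's parameter draw and noise stream derive
  deterministically from the cohort seed and the animal index through
  ``numpy.random.SeedSequence(cohort_seed, spawn_key=(index,))``, so
  enlarging a cohort never reshuffles earlier animals.

Defaults emulate the stated experiment: a single burst of 30 pulses at
50 Hz and 0.4 mA, a 12 s recording at 10 Hz (rate and duration chosen to
render the published transient shape; both configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

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
    "DEFAULT_DURATION",
    "DEFAULT_SAMPLE_RATE",
    "CohortSpec",
    "animal_seed",
    "generate_recording",
    "generate_cohort",
    "average_recordings",
]

DEFAULT_DURATION = 12.0  # s
DEFAULT_SAMPLE_RATE = 10.0  # Hz


@dataclass(frozen=True)
class CohortSpec:
    """One genotype cohort: median parameters plus sampling structure."""

    genotype: str
    mean_params: KineticParameters
    n_animals: int = 5
    between_animal_cv: float = 0.1
    noise_sd: float = 0.05  # μM
    sample_rate: float = DEFAULT_SAMPLE_RATE
    duration: float = DEFAULT_DURATION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValidationError("n_animals must be >= 1")
        if self.between_animal_cv < 0:
            raise ValidationError("between_animal_cv must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def animal_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-animal seed below 2^31, stable under cohort growth."""
    ss = np.random.SeedSequence(entropy=int(cohort_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def generate_recording(
    params: KineticParameters,
    protocol: StimulusProtocol,
    noise_sd: float = 0.0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    duration: float = DEFAULT_DURATION,
    dt: float = DEFAULT_DT,
    genotype: str = "",
) -> FSCVRecording:
    """Simulate, downsample and noise one recording; fully seeded.

    With ``noise_sd = 0`` the recording equals the downsampled model
    observable exactly.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    trace = simulate(params, protocol, duration=duration, dt=dt)
    rec = observable(trace, sample_rate=sample_rate)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rec.signal = rec.signal + rng.normal(0.0, noise_sd, size=rec.signal.shape)
    rec.metadata.update(
        {
            "genotype": genotype,
            "seed": int(seed),
            "noise_sd_um": float(noise_sd),
            "sample_rate_hz": float(sample_rate),
            **{f"param_{k}": v for k, v in params.as_dict().items() if k != "free"},
        }
    )
    return rec


def generate_cohort(
    spec: CohortSpec, protocol: StimulusProtocol, dt: float = DEFAULT_DT
) -> list[FSCVRecording]:
    """One recording per animal with log-normally drawn free parameters.

    The log-normal is parameterised so the *median* equals the cohort value
    and the coefficient of variation equals ``between_animal_cv``
    (``sigma = sqrt(ln(1 + cv²))``).  Fixed parameters are shared.
    """
    sigma = math.sqrt(math.log1p(spec.between_animal_cv**2))
    free = sorted(spec.mean_params.free)
    recordings = []
    for i in range(spec.n_animals):
        ss = np.random.SeedSequence(entropy=int(spec.seed), spawn_key=(int(i),))
        param_seq, noise_seq = ss.spawn(2)
        draws = {}
        if sigma > 0:
            rng = np.random.default_rng(param_seq)
            for name in free:
                median = getattr(spec.mean_params, name)
                draws[name] = float(median * math.exp(rng.normal(0.0, sigma)))
        params_i = spec.mean_params.with_values(**draws) if draws else spec.mean_params
        seed_i = int(noise_seq.generate_state(1, dtype=np.uint32)[0] % (2**31))
        rec = generate_recording(
            params_i,
            protocol,
            noise_sd=spec.noise_sd,
            sample_rate=spec.sample_rate,
            seed=seed_i,
            duration=spec.duration,
            dt=dt,
            genotype=spec.genotype,
        )
        rec.metadata["animal_index"] = i
        rec.metadata["cohort_seed"] = int(spec.seed)
        recordings.append(rec)
    return recordings


def average_recordings(recs: list[FSCVRecording]) -> FSCVRecording:
    """Pointwise mean of recordings sharing one time grid."""
    if not recs:
        raise ValidationError("cannot average an empty list of recordings")
    t0 = recs[0].time
    for k, rec in enumerate(recs[1:], start=1):
        if rec.time.shape != t0.shape or not np.allclose(
            rec.time, t0, rtol=0, atol=1e-9
        ):
            raise ValidationError(f"recording {k} is not on the same time grid")
    mean_signal = np.mean([rec.signal for rec in recs], axis=0)
    meta = {
        "n_source_recordings": len(recs),
        "genotype": recs[0].metadata.get("genotype", ""),
        "sample_rate_hz": recs[0].metadata.get("sample_rate_hz"),
    }
    return FSCVRecording(time=t0.copy(), signal=mean_signal, metadata=meta)
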