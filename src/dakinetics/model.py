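"""Kinetic model of stimulated dopamine release, reuptake and FSCV detection.

The model describes a burst-stimulation FSCV experiment in the dorsal
striatum with three coupled state variables on a common time grid:

* ``[DA]_S`` — striatal extracellular dopamine (μM).  Electrical burst
  stimulation of midbrain dopaminergic neurons releases ``DAP`` μM of
  dopamine per pulse and per mA of stimulating current; the dopamine
  transporter (DAT) clears it with Michaelis–Menten kinetics
  (``Vm``, ``Km``).  A loss factor ``L ≤ 1`` attenuates release for
  diffusion through the dead space of tissue damaged by the electrode::

      d[DA]_S/dt = DAP · I · f · S(t) · L  −  Vm · [DA]_S / ([DA]_S + Km)

* ``[DA]_E`` — dopamine seen by the carbon-fiber electrode (μM).  The
  electrode responds slowly; first-order transfer in from the striatum
  (``kS``) and out (``kE``), plus re-contribution of adsorbed dopamine
  with rate transfer ``kGamma``::

      d[DA]_E/dt = kS · [DA]_S − kE · [DA]_E + kGamma · Γ_DA

* ``Γ_DA`` — dopamine adsorbed to the carbon surface (μM-equivalent),
  with adsorption rate ``k1ads`` and desorption rates ``k2ads``
  (concentration-coupled) and ``k3ads``::

      dΓ_DA/dt = k1ads · [DA]_E − k2ads · [DA]_E · Γ_DA − k3ads · Γ_DA

``S(t)`` is a sum of Heaviside window functions, one per burst: 1 while a
burst of ``NP`` pulses at frequency ``f`` is on, 0 otherwise.  The burst is
modelled as a continuous release at rate ``DAP·I·f·L`` for ``NP/f`` seconds,
not as per-pulse deltas.

Units are fixed package-wide: seconds, μM, mA, Hz.  Initial conditions are
the zero state (traces are background-subtracted).

Integration is fixed-step classical Runge–Kutta 4 at ``dt = 1e-3`` s by
default.  The stimulus level handed to the RK4 stages is the envelope
evaluated at each step's midpoint, so the right-hand side is smooth within
every step whenever burst edges fall on grid nodes (they do for the
standard protocol of 30 pulses at 50 Hz with millisecond steps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ValidationError",
    "IntegrationError",
    "ResolutionError",
    "StimulusProtocol",
    "KineticParameters",
    "ConcentrationTrace",
    "FSCVRecording",
    "FREE_PARAMETER_NAMES",
    "stimulus_envelope",
    "reuptake_rate",
    "state_derivative",
    "simulate",
    "observable",
]

DEFAULT_DT = 1e-3  # s


class ValidationError(ValueError):
    """An input violates a model invariant; the message names it."""


class IntegrationError(RuntimeError):
    """The ODE state became non-finite during integration."""


class ResolutionError(ValueError):
    """Requested acquisition rate exceeds the simulation resolution."""


#: Parameter fields that may be declared free for fitting.
FREE_PARAMETER_NAMES = frozenset(
    {"dap", "vm", "km", "L", "ks", "ke", "k1ads", "k2ads", "k3ads"}
)


@dataclass(frozen=True)
class StimulusProtocol:
    """Electrical burst-stimulation protocol.

    Parameters
    ----------
    n_pulses:
        Pulses per burst (NP).
    frequency:
        Intra-burst pulse frequency f, Hz.
    current:
        Stimulating current I, mA.
    onset:
        Start time of the first burst, s.
    n_bursts:
        Number of bursts (default 1).
    inter_burst_interval:
        Gap between burst end and next burst onset, s; only used when
        ``n_bursts > 1``.
    """

    n_pulses: int = 30
    frequency: float = 50.0
    current: float = 0.4
    onset: float = 1.0
    n_bursts: int = 1
    inter_burst_interval: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValidationError("n_pulses must be >= 1")
        if self.frequency <= 0:
            raise ValidationError("frequency must be > 0")
        if self.current < 0:
            raise ValidationError("current must be >= 0")
        if self.onset < 0:
            raise ValidationError("onset must be >= 0")
        if self.n_bursts < 1:
            raise ValidationError("n_bursts must be >= 1")
        if self.n_bursts > 1 and self.inter_burst_interval < 0:
            raise ValidationError("inter_burst_interval must be >= 0")

    @property
    def burst_duration(self) -> float:
        """Length of one burst, NP/f, in seconds."""
        return self.n_pulses / self.frequency

    @property
    def burst_onsets(self) -> np.ndarray:
        """Start times of every burst, s."""
        period = self.burst_duration + self.inter_burst_interval
        return self.onset + period * np.arange(self.n_bursts)

    @property
    def end(self) -> float:
        """End time of the last burst, s."""
        return float(self.burst_onsets[-1] + self.burst_duration)


@dataclass(frozen=True)
class KineticParameters:
    """Full parameter vector of the release/reuptake/electrode model.

    Defaults for ``vm`` and ``dap`` are the wild-type fitted values; the
    remaining defaults are declared implementation choices (standard
    striatal DAT affinity scale for ``km``, unit loss factor, symmetric
    electrode transfer) — they are shared between simulation and fitting,
    so they cancel out of self-consistent recovery experiments.

    ``free`` names the fields adjusted during fitting; everything else is
    held fixed.
    """

    dap: float = 0.67  # μM released per pulse per mA
    vm: float = 7.4  # μM/s maximal reuptake velocity
    km: float = 0.2  # μM reuptake affinity constant
    L: float = 1.0  # dimensionless dead-space loss factor, 0 < L <= 1
    ks: float = 5.0  # 1/s transfer striatum -> electrode
    ke: float = 5.0  # 1/s transfer away from electrode
    kgamma: float = 1.0  # 1/s rate transfer of adsorption into [DA]_E
    k1ads: float = 0.1  # 1/s adsorption rate constant
    k2ads: float = 0.05  # 1/(μM·s) concentration-coupled desorption
    k3ads: float = 0.1  # 1/s first-order desorption
    free: frozenset = field(default_factory=lambda: frozenset({"vm", "dap"}))

    def __post_init__(self) -> None:
        for name in ("dap", "vm", "km", "L", "ks", "ke", "kgamma", "k1ads", "k2ads", "k3ads"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.km <= 0:
            raise ValidationError("km must be > 0")
        if not 0 < self.L <= 1:
            raise ValidationError("L must lie in (0, 1]")
        free = frozenset(self.free)
        object.__setattr__(self, "free", free)
        unknown = free - FREE_PARAMETER_NAMES
        if unknown:
            raise ValidationError(
                f"free mask contains unknown parameter(s): {sorted(unknown)}"
            )

    def with_values(self, **values: float) -> "KineticParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **values)

    def as_dict(self) -> dict:
        """All numeric fields as a plain dict (free mask as sorted list)."""
        d = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "free"}
        d["free"] = sorted(self.free)
        return d

    def fixed_values(self) -> dict:
        """Numeric fields not in the free mask, for cross-fit comparisons."""
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "free" and f.name not in self.free
        }


@dataclass(frozen=True)
class ConcentrationTrace:
    """Simulated state trajectories on a uniform time grid (all μM)."""

    time: np.ndarray
    da_s: np.ndarray
    da_e: np.ndarray
    gamma: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.da_s) == len(self.da_e) == len(self.gamma) == n):
            raise ValidationError("all state series must match the time grid length")
        if n >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0) or not np.allclose(steps, self.dt, rtol=0, atol=1e-12):
                raise ValidationError("time must increase with constant spacing dt")


@dataclass
class FSCVRecording:
    """A measured (or synthetic) dopamine time series with metadata.

    ``signal`` is electrode dopamine in μM on the acquisition grid
    ``time`` (s).  ``metadata`` carries acquisition provenance (genotype,
    sample rate, seed, generating parameters, ...) as flat key/value pairs.
    """

    time: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValidationError("time and signal must have equal length")
        if len(self.time) >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")

    @property
    def sample_rate(self) -> float:
        """Acquisition rate inferred from the grid, Hz."""
        if len(self.time) < 2:
            raise ValidationError("sample rate undefined for < 2 samples")
        return 1.0 / float(np.median(np.diff(self.time)))


def stimulus_envelope(t, protocol: StimulusProtocol):
    """Burst indicator S(t): 1 inside any burst window, else 0.

    Windows are closed at both ends (Heaviside convention θ(0) = 1), so the
    exact onset and offset instants count as "on".  Accepts a scalar or an
    array of times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("t must be >= 0")
    on = np.zeros(t_arr.shape, dtype=bool)
    for t0 in protocol.burst_onsets:
        on |= (t_arr >= t0) & (t_arr <= t0 + protocol.burst_duration)
    out = on.astype(float)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def reuptake_rate(da_s, params: KineticParameters):
    """Michaelis–Menten DAT reuptake velocity Vm·[DA]_S/([DA]_S + Km), μM/s."""
    da_arr = np.asarray(da_s, dtype=float)
    if np.any(da_arr < 0):
        raise ValidationError("da_s must be >= 0")
    out = params.vm * da_arr / (da_arr + params.km)
    return float(out) if np.isscalar(da_s) or da_arr.ndim == 0 else out


def state_derivative(
    state: tuple, release_rate: float, p: KineticParameters
) -> tuple:
    """Right-hand side of the three-state ODE system.

    ``state`` is ``([DA]_S, [DA]_E, Γ_DA)`` and ``release_rate`` is the
    current source level ``DAP·I·f·L·S(t)`` in μM/s.
    """
    a, e, g = state
    d_a = release_rate - p.vm * a / (a + p.km)
    d_e = p.ks * a - p.ke * e + p.kgamma * g
    d_g = p.k1ads * e - p.k2ads * e * g - p.k3ads * g
    return (d_a, d_e, d_g)


def simulate(
    params: KineticParameters,
    protocol: StimulusProtocol,
    duration: float,
    dt: float = DEFAULT_DT,
) -> ConcentrationTrace:
    """Integrate the model from the zero state over ``[0, duration]``.

    Fixed-step classical RK4.  Returns all three state trajectories; the
    FSCV observable is the ``da_e`` series.

    Raises
    ------
    ValidationError
        If ``duration`` does not extend past the stimulation or ``dt <= 0``.
    IntegrationError
        If any state becomes non-finite, reporting the first bad time.
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    if duration <= protocol.end:
        raise ValidationError(
            f"duration ({duration} s) must exceed the stimulation end ({protocol.end} s)"
        )
    n_steps = int(round(duration / dt))
    time = np.arange(n_steps + 1) * dt

    # Constant stimulus level per step: envelope at the step midpoint.
    midpoints = time[:-1] + 0.5 * dt
    base_rate = params.dap * protocol.current * protocol.frequency * params.L
    step_rate = base_rate * stimulus_envelope(midpoints, protocol)

    vm, km = params.vm, params.km
    ks, ke, kg = params.ks, params.ke, params.kgamma
    k1, k2, k3 = params.k1ads, params.k2ads, params.k3ads

    da_s = np.empty(n_steps + 1)
    da_e = np.empty(n_steps + 1)
    gamma = np.empty(n_steps + 1)
    a = e = g = 0.0
    da_s[0] = da_e[0] = gamma[0] = 0.0
    half = 0.5 * dt
    sixth = dt / 6.0

    # Convert to plain floats: float64 warns on overflow, Python floats are
    # faster in the loop, and the finiteness check below turns any blow-up
    # into IntegrationError either way.
    step_rate_list = [float(v) for v in step_rate]
    for i in range(n_steps):
        r = step_rate_list[i]

        a1 = r - vm * a / (a + km)
        e1 = ks * a - ke * e + kg * g
        g1 = k1 * e - k2 * e * g - k3 * g

        ay = a + half * a1
        ey = e + half * e1
        gy = g + half * g1
        a2 = r - vm * ay / (ay + km)
        e2 = ks * ay - ke * ey + kg * gy
        g2 = k1 * ey - k2 * ey * gy - k3 * gy

        ay = a + half * a2
        ey = e + half * e2
        gy = g + half * g2
        a3 = r - vm * ay / (ay + km)
        e3 = ks * ay - ke * ey + kg * gy
        g3 = k1 * ey - k2 * ey * gy - k3 * gy

        ay = a + dt * a3
        ey = e + dt * e3
        gy = g + dt * g3
        a4 = r - vm * ay / (ay + km)
        e4 = ks * ay - ke * ey + kg * gy
        g4 = k1 * ey - k2 * ey * gy - k3 * gy

        a += sixth * (a1 + 2.0 * (a2 + a3) + a4)
        e += sixth * (e1 + 2.0 * (e2 + e3) + e4)
        g += sixth * (g1 + 2.0 * (g2 + g3) + g4)

        if not (math.isfinite(a) and math.isfinite(e) and math.isfinite(g)):
            raise IntegrationError(
                f"non-finite state at t = {time[i + 1]:.6g} s "
                f"(da_s={a!r}, da_e={e!r}, gamma={g!r})"
            )
        da_s[i + 1] = a
        da_e[i + 1] = e
        gamma[i + 1] = g

    return ConcentrationTrace(time=time, da_s=da_s, da_e=da_e, gamma=gamma, dt=dt)


def observable(trace: ConcentrationTrace, sample_rate: float) -> FSCVRecording:
    """Downsample ``[DA]_E`` to the acquisition grid.

    Samples are taken at ``j / sample_rate`` for ``j = 0 ..
    floor(duration · sample_rate)`` by nearest-grid-point selection.
    """
    if sample_rate <= 0:
        raise ValidationError("sample_rate must be > 0")
    if sample_rate > 1.0 / trace.dt * (1 + 1e-9):
        raise ResolutionError(
            f"sample_rate {sample_rate} Hz exceeds simulation resolution "
            f"{1.0 / trace.dt:.6g} Hz"
        )
    duration = float(trace.time[-1])
    n_samples = int(math.floor(duration * sample_rate + 1e-9)) + 1
    sample_times = np.arange(n_samples) / sample_rate
    idx = np.rint(sample_times / trace.dt).astype(int)
    idx = np.clip(idx, 0, len(trace.time) - 1)
    return FSCVRecording(
        time=sample_times,
        signal=trace.da_e[idx],
        metadata={"sample_rate_hz": float(sample_rate)},
    )
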