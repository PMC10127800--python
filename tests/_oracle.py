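"""Independent brute-force oracles for the kinetic model tests.

A deliberately naive fixed-step forward-Euler integrator, written from the
model equations directly, with point-evaluated stimulus.  Slow and simple
on purpose: it shares no code path with ``dakinetics.model.simulate``.
"""

from __future__ import annotations

import numpy as np


def euler_simulate(params, protocol, duration: float, dt: float = 1e-5):
    """Forward-Euler integration of the three-state system.

    Returns ``(time, da_s, da_e, gamma)`` arrays.
    """
    n = int(round(duration / dt))
    time = np.arange(n + 1) * dt

    onsets = [
        protocol.onset
        + k * (protocol.n_pulses / protocol.frequency + protocol.inter_burst_interval)
        for k in range(protocol.n_bursts)
    ]
    width = protocol.n_pulses / protocol.frequency

    def stim(t: float) -> float:
        for t0 in onsets:
            if t0 <= t <= t0 + width:
                return 1.0
        return 0.0

    rate = params.dap * protocol.current * protocol.frequency * params.L
    a = e = g = 0.0
    da_s = np.empty(n + 1)
    da_e = np.empty(n + 1)
    gamma = np.empty(n + 1)
    da_s[0] = da_e[0] = gamma[0] = 0.0
    for i in range(n):
        t = time[i]
        d_a = rate * stim(t) - params.vm * a / (a + params.km)
        d_e = params.ks * a - params.ke * e + params.kgamma * g
        d_g = params.k1ads * e - params.k2ads * e * g - params.k3ads * g
        a += dt * d_a
        e += dt * d_e
        g += dt * d_g
        da_s[i + 1] = a
        da_e[i + 1] = e
        gamma[i + 1] = g
    return time, da_s, da_e, gamma


def permutation_p_value(a, b, n_perm: int = 999, seed: int = 0) -> float:
    """Two-sided permutation p-value for a difference in group means."""
    rng = np.random.default_rng(seed)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[: a.size].mean() - perm[a.size :].mean()) >= observed - 1e-15:
            count += 1
    return (count + 1) / (n_perm + 1)
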