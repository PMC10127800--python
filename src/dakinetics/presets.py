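"""Reference parameter sets and the standard stimulation protocol.

The genotype presets carry the fitted values reported for 3-month-old
wild-type and auxilin-knockout mice: the KO transient is explained by a
~73% lower maximal reuptake velocity Vm together with ~54% lower release
per pulse DAP.  All other parameters are package defaults shared between
genotypes.
"""

from __future__ import annotations

from .model import KineticParameters, StimulusProtocol

__all__ = ["standard_protocol", "wt_parameters", "ko_parameters"]

#: Fitted (Vm, DAP) per genotype: μM/s and μM/mA.
WT_VM, WT_DAP = 7.4, 0.67
KO_VM, KO_DAP = 2.0, 0.31


def standard_protocol(onset: float = 1.0) -> StimulusProtocol:
    """Single burst of 30 pulses at 50 Hz (0.6 s) and 0.4 mA."""
    return StimulusProtocol(n_pulses=30, frequency=50.0, current=0.4, onset=onset)


def wt_parameters(**overrides) -> KineticParameters:
    """Wild-type parameter vector (Vm = 7.4 μM/s, DAP = 0.67 μM/mA)."""
    return KineticParameters(vm=WT_VM, dap=WT_DAP, **overrides)


def ko_parameters(**overrides) -> KineticParameters:
    """Auxilin-KO parameter vector (Vm = 2.0 μM/s, DAP = 0.31 μM/mA)."""
    return KineticParameters(vm=KO_VM, dap=KO_DAP, **overrides)
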