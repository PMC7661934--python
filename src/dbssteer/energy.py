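"""IPG battery current-draw model.

Closed-form current draw from battery for the three activation paradigms of a
current-controlled implantable pulse generator:

    MICC:          I = I_ov(f)   + sum_i I_Ei * PW * f * V_max / V_bat
    Interleaving:  I = I_ov(N f) + sum_i I_Ei * PW * f * V_Ei  / V_bat
    Coactivation:  I = I_ov(f)   + I_tot * PW * f * V_eq  / V_bat

with V_max = max_i I_Ei * Z_Ei, V_Ei = I_Ei * Z_Ei and
V_eq = I_tot / sum_i (1 / Z_Ei).  The overhead current is modelled as a
constant per active program (4.9 uA, so N * 4.9 uA for N interleaved
programs) since the pulse frequency is fixed in this study.

Units contract: amplitudes in mA (magnitudes), impedances in kOhm, results in
uA.  Internal computation is in SI; values are rounded (to 0.1 uA) only when
explicitly requested for reporting.  V_max may exceed V_bat (charge-pump
regime) and the formulas still apply.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["EnergyParams", "v_max", "v_eq", "current_draw_micc",
           "current_draw_interleaving", "current_draw_coactivation",
           "round_report"]


@dataclass(frozen=True)
class EnergyParams:
    """Pulse and IPG parameters (PW us, f Hz, V_bat V, overhead uA/program)."""

    pulse_width_us: float = 60.0
    frequency_hz: float = 130.0
    battery_voltage_v: float = 2.8
    overhead_uA_per_program: float = 4.9

    def __post_init__(self) -> None:
        if min(self.pulse_width_us, self.frequency_hz, self.battery_voltage_v,
               self.overhead_uA_per_program) <= 0:
            raise ValueError("all energy parameters must be positive")


def _amps(amplitudes_mA: Sequence[float]) -> np.ndarray:
    a = np.atleast_1d(np.asarray(amplitudes_mA, float))
    if a.size == 0:
        raise ValueError("at least one electrode amplitude is required")
    if np.any(a < 0):
        raise ValueError("amplitudes are cathodic magnitudes, must be >= 0")
    return a


def _impedances(impedances_kohm: Sequence[float], n: int) -> np.ndarray:
    z = np.atleast_1d(np.asarray(impedances_kohm, float))
    if z.size != n:
        raise ValueError("amplitudes and impedances must have equal length")
    if np.any(z <= 0):
        raise ValueError("impedances must be positive")
    return z


def v_max(amplitudes_mA: Sequence[float], impedances_kohm: Sequence[float]) -> float:
    """Maximum per-electrode voltage, max_i I_Ei * Z_Ei, in volts."""
    a = _amps(amplitudes_mA)
    z = _impedances(impedances_kohm, a.size)
    return float(np.max(a * z))  # mA * kOhm = V


def v_eq(total_amplitude_mA: float, impedances_kohm: Sequence[float]) -> float:
    """Equivalent voltage of a coactivated contact configuration, in volts."""
    z = np.atleast_1d(np.asarray(impedances_kohm, float))
    if z.size == 0 or np.any(z <= 0):
        raise ValueError("impedances must be positive and non-empty")
    return float(total_amplitude_mA / np.sum(1.0 / z))


def _stim_term_uA(sum_IV_mAV: float, params: EnergyParams) -> float:
    # sum_i I_Ei[V term already folded] in mA*V; PW us, f Hz -> result uA:
    # (mA*1e-3 A) * (us*1e-6 s) * f * V / V_bat * 1e6 uA/A = mA*us*f*1e-3
    return sum_IV_mAV * params.pulse_width_us * params.frequency_hz * 1e-3 \
        / params.battery_voltage_v


def current_draw_micc(amplitudes_mA: Sequence[float],
                      impedances_kohm: Sequence[float],
                      params: EnergyParams | None = None) -> float:
    """Current draw from battery for simultaneous multi-source activation, uA."""
    params = params or EnergyParams()
    a = _amps(amplitudes_mA)
    vm = v_max(a, impedances_kohm)
    return params.overhead_uA_per_program + _stim_term_uA(float(a.sum()) * vm, params)


def current_draw_interleaving(amplitudes_mA: Sequence[float],
                              impedances_kohm: Sequence[float],
                              params: EnergyParams | None = None) -> float:
    """Current draw for N alternately-active programs (one per electrode), uA."""
    params = params or EnergyParams()
    a = _amps(amplitudes_mA)
    z = _impedances(impedances_kohm, a.size)
    n = a.size
    return n * params.overhead_uA_per_program \
        + _stim_term_uA(float(np.sum(a * (a * z))), params)


def current_draw_coactivation(total_amplitude_mA: float,
                              impedances_kohm: Sequence[float],
                              params: EnergyParams | None = None) -> float:
    """Current draw for single-source coactivation of the listed contacts, uA."""
    params = params or EnergyParams()
    if total_amplitude_mA < 0:
        raise ValueError("total amplitude must be >= 0")
    veq = v_eq(total_amplitude_mA, impedances_kohm)
    return params.overhead_uA_per_program \
        + _stim_term_uA(total_amplitude_mA * veq, params)


def round_report(value_uA: float) -> float:
    """Round to the 0.1 uA reporting precision."""
    return float(np.round(value_uA, 1))
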