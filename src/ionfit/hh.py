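"""Squid-axon Hodgkin-Huxley reference currents for voltage-clamp checks.

The classic delayed-rectifier potassium current iK = gK n^4 (V - EK) and
fast sodium current iNa = gNa m^3 h (V - ENa) at the original 6.3 degC
rates, expressed in the modern sign convention (resting potential near
-65 mV, depolarisation positive, outward current positive).  These serve
as an external reference when checking that sums of simple two-gate
currents can reproduce higher-order (n^4, m^3 h) gating kinetics under a
voltage step.

Constants (modern convention):

    gK  = 36  mS/cm^2    EK  = -77 mV
    gNa = 120 mS/cm^2    ENa = +50 mV
    alpha_n = 0.01 (V+55) / (1 - exp(-(V+55)/10))   ms^-1
    beta_n  = 0.125 exp(-(V+65)/80)
    alpha_m = 0.1 (V+40) / (1 - exp(-(V+40)/10))
    beta_m  = 4 exp(-(V+65)/18)
    alpha_h = 0.07 exp(-(V+65)/20)
    beta_h  = 1 / (1 + exp(-(V+35)/10))

All outputs are converted to nA/cm^2 (1 mS/cm^2 x 1 mV = 1 uA/cm^2 =
1000 nA/cm^2) to match the generic model's units.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hh_rates", "hh_gate_steady", "hh_reference_current", "HH_CONSTANTS"]

HH_CONSTANTS = {
    "gK_mS_cm2": 36.0,
    "EK_mV": -77.0,
    "gNa_mS_cm2": 120.0,
    "ENa_mV": 50.0,
    "temperature_C": 6.3,
}


def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    safe = np.where(small, 1.0, x)
    return np.where(small, y * (1.0 + x / (2.0 * y)), safe / (1.0 - np.exp(-safe / y)))


def hh_rates(V, gate: str) -> tuple[np.ndarray, np.ndarray]:
    """(alpha, beta) in s^-1 for gate 'n', 'm' or 'h' at potential V (mV)."""
    V = np.asarray(V, dtype=float)
    if gate == "n":
        a = 0.01 * _vtrap(V + 55.0, 10.0)
        b = 0.125 * np.exp(-(V + 65.0) / 80.0)
    elif gate == "m":
        a = 0.1 * _vtrap(V + 40.0, 10.0)
        b = 4.0 * np.exp(-(V + 65.0) / 18.0)
    elif gate == "h":
        a = 0.07 * np.exp(-(V + 65.0) / 20.0)
        b = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    else:
        raise ValueError(f"unknown HH gate {gate!r}")
    return a * 1e3, b * 1e3  # ms^-1 -> s^-1


def hh_gate_steady(V, gate: str) -> tuple[np.ndarray, np.ndarray]:
    """Steady state and time constant (s) of an HH gate at potential V."""
    a, b = hh_rates(V, gate)
    return a / (a + b), 1.0 / (a + b)


def hh_reference_current(
    kind: str,
    step: tuple[float, float] = (-60.0, 40.0),
    duration: float | None = None,
    dt: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """Voltage-clamp current for a step from holding to test potential.

    ``kind`` is ``"iK_n4"`` (sigmoidal activation, gK n^4 (V - EK)) or
    ``"iNa_m3h"`` (activate-then-inactivate, gNa m^3 h (V - ENa)).  Gates
    start at steady state for the holding potential.  Returns ``(t, i)``
    with t in seconds and i in nA/cm^2.
    """
    hold, test = step
    if duration is None:
        duration = 0.015 if kind == "iK_n4" else 0.008
    t = np.arange(0.0, duration + dt / 2, dt)

    def relax(gate: str) -> np.ndarray:
        g0, _ = hh_gate_steady(hold, gate)
        ginf, tau = hh_gate_steady(test, gate)
        return ginf + (g0 - ginf) * np.exp(-t / tau)

    if kind == "iK_n4":
        n = relax("n")
        i_uA = HH_CONSTANTS["gK_mS_cm2"] * n**4 * (test - HH_CONSTANTS["EK_mV"])
    elif kind == "iNa_m3h":
        m = relax("m")
        h = relax("h")
        i_uA = HH_CONSTANTS["gNa_mS_cm2"] * m**3 * h * (test - HH_CONSTANTS["ENa_mV"])
    else:
        raise ValueError(f"unknown reference current kind {kind!r}")
    return t, i_uA * 1e3
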