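"""Generic N-current Hodgkin-Huxley-type membrane model.

The cell is described by a membrane equation

    dEm/dt = -(i_stim + i_L + sum_j i_j) / Cm,

with N time-dependent ionic currents, each gated by two first-order
Hodgkin-Huxley gates ``p`` and ``q``,

    i_j = gmax_j * p_j * q_j * (Em - Erev_j),
    dp/dt = alpha_p (1 - p) - beta_p p     (and likewise for q),

and a time-independent leak ``i_L = gL * (Em - ErevL)``.  Every opening and
closing rate is a sigmoidal function of membrane potential,

    rate(Em) = k / (1 + exp(s * (Em - E50))),

with the half-activation potential E50 shared between the alpha/beta pair
of each gate.  A model with N currents therefore has 2N + 1 state
variables (Em plus 2N gates) and 12N + 2 free parameters (12 per current
plus the leak conductance and reversal; Cm is fixed, not fitted).

Units: time s, potential mV, rates s^-1, slopes mV^-1, conductance
uS/cm^2, capacitance uF/cm^2; currents come out in nA/cm^2 and dEm/dt in
mV/s with no hidden conversion factors.

No structural distinction is imposed between the p and q gate of a
current: activation or inactivation roles emerge from the fitted signs of
the slope parameters, and swapping the p and q parameter blocks of a
current yields an identical model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateParameters",
    "GateParameters",
    "CurrentParameters",
    "ModelParameters",
    "CellState",
    "rate",
    "gate_derivative",
    "gate_equilibrium",
    "ionic_current",
    "leak_current",
    "state_derivative",
    "voltage_clamp_gates",
    "voltage_clamp_current",
    "PARAM_KINDS",
    "DEFAULT_BOUNDS",
]

# Exponent clamp: the optimiser explores extreme s*(Em - E50) products and
# exp must never overflow to inf.
_EXP_CLIP = 500.0


@dataclass(frozen=True)
class RateParameters:
    """One sigmoidal voltage-dependent rate.

    Parameters
    ----------
    k : float
        Maximum rate (s^-1); the sigmoid saturates at ``k``.
    s : float
        Slope (mV^-1).  Negative slope gives a rate that grows with
        depolarisation, positive slope one that shuts off.
    E50 : float
        Half-activation potential (mV); rate(E50) == k / 2.
    """

    k: float
    s: float
    E50: float

    def __post_init__(self) -> None:
        if not (self.k >= 0.0):
            raise ValueError(f"maximum rate k must be >= 0, got {self.k}")
        if not (math.isfinite(self.s) and math.isfinite(self.E50)):
            raise ValueError("slope and E50 must be finite")


@dataclass(frozen=True)
class GateParameters:
    """Opening (alpha) and closing (beta) rates of one gate.

    The half-activation potential is shared between the pair, so the two
    :class:`RateParameters` must carry the same ``E50``.
    """

    alpha: RateParameters
    beta: RateParameters

    def __post_init__(self) -> None:
        if self.alpha.E50 != self.beta.E50:
            raise ValueError(
                "alpha and beta of a gate share one E50; got "
                f"{self.alpha.E50} != {self.beta.E50}"
            )


@dataclass(frozen=True)
class CurrentParameters:
    """One two-gate ionic current: conductance, reversal and gate kinetics."""

    gmax: float
    Erev: float
    p_gate: GateParameters
    q_gate: GateParameters

    def __post_init__(self) -> None:
        if not (self.gmax >= 0.0):
            raise ValueError(f"gmax must be >= 0, got {self.gmax}")


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of an N-current cell model.

    ``currents`` is ordered; the state-vector layout and the flat
    optimisation-parameter layout both follow this order.
    """

    currents: tuple[CurrentParameters, ...]
    gL: float
    ErevL: float
    Cm: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "currents", tuple(self.currents))
        if not (self.Cm > 0.0):
            raise ValueError(f"Cm must be > 0, got {self.Cm}")
        if not (self.gL >= 0.0):
            raise ValueError(f"gL must be >= 0, got {self.gL}")

    @property
    def n_currents(self) -> int:
        return len(self.currents)

    @property
    def n_states(self) -> int:
        """Number of state variables: Em plus two gates per current."""
        return 2 * self.n_currents + 1

    @property
    def n_parameters(self) -> int:
        """Number of optimisable parameters: 12 per current plus leak g and Erev."""
        return 12 * self.n_currents + 2

    # -- flat parameter layout -------------------------------------------------

    def parameter_names(self) -> list[str]:
        """Names of the 12N+2 optimisable parameters, in vector order."""
        names: list[str] = []
        for j in range(1, self.n_currents + 1):
            names += [f"i{j}_g", f"i{j}_Erev"]
            for gate in ("p", "q"):
                names += [
                    f"i{j}_{gate}_k_alpha",
                    f"i{j}_{gate}_s_alpha",
                    f"i{j}_{gate}_k_beta",
                    f"i{j}_{gate}_s_beta",
                    f"i{j}_{gate}_E50",
                ]
        names += ["leak_g", "leak_Erev"]
        return names

    def to_vector(self) -> np.ndarray:
        """Flatten to the 12N+2 optimisation vector (order of parameter_names)."""
        vec: list[float] = []
        for cp in self.currents:
            vec += [cp.gmax, cp.Erev]
            for gp in (cp.p_gate, cp.q_gate):
                vec += [gp.alpha.k, gp.alpha.s, gp.beta.k, gp.beta.s, gp.alpha.E50]
        vec += [self.gL, self.ErevL]
        return np.asarray(vec, dtype=float)

    @classmethod
    def from_vector(cls, vec: np.ndarray, *, Cm: float = 1.0) -> "ModelParameters":
        vec = np.asarray(vec, dtype=float)
        if (vec.size - 2) % 12 != 0:
            raise ValueError(f"vector length {vec.size} is not 12N+2")
        n = (vec.size - 2) // 12
        currents = []
        for j in range(n):
            b = vec[12 * j : 12 * (j + 1)]
            gates = []
            for g in range(2):
                ka, sa, kb, sb, e50 = b[2 + 5 * g : 7 + 5 * g]
                gates.append(
                    GateParameters(
                        RateParameters(ka, sa, e50), RateParameters(kb, sb, e50)
                    )
                )
            currents.append(CurrentParameters(b[0], b[1], gates[0], gates[1]))
        return cls(tuple(currents), gL=vec[-2], ErevL=vec[-1], Cm=Cm)

    def parameter_kinds(self) -> list[str]:
        """Kind tag ('g', 'Erev', 'k', 's', 'E50') per flat parameter."""
        kinds: list[str] = []
        for _ in range(self.n_currents):
            kinds += ["g", "Erev"] + ["k", "s", "k", "s", "E50"] * 2
        kinds += ["g", "Erev"]
        return kinds

    # -- serialisation ---------------------------------------------------------

    def to_dict(self) -> dict:
        def gate(gp: GateParameters) -> dict:
            return {
                "k_a": float(gp.alpha.k),
                "s_a": float(gp.alpha.s),
                "k_b": float(gp.beta.k),
                "s_b": float(gp.beta.s),
                "E50": float(gp.alpha.E50),
            }

        return {
            "N": self.n_currents,
            "Cm": float(self.Cm),
            "leak": {"g": float(self.gL), "Erev": float(self.ErevL)},
            "currents": [
                {
                    "g": float(cp.gmax),
                    "Erev": float(cp.Erev),
                    "p": gate(cp.p_gate),
                    "q": gate(cp.q_gate),
                }
                for cp in self.currents
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        def gate(g: dict) -> GateParameters:
            return GateParameters(
                RateParameters(float(g["k_a"]), float(g["s_a"]), float(g["E50"])),
                RateParameters(float(g["k_b"]), float(g["s_b"]), float(g["E50"])),
            )

        currents = tuple(
            CurrentParameters(float(c["g"]), float(c["Erev"]), gate(c["p"]), gate(c["q"]))
            for c in d["currents"]
        )
        if "N" in d and int(d["N"]) != len(currents):
            raise ValueError(
                f"declared N={d['N']} does not match {len(currents)} currents"
            )
        leak = d["leak"]
        return cls(
            currents,
            gL=float(leak["g"]),
            ErevL=float(leak["Erev"]),
            Cm=float(d.get("Cm", 1.0)),
        )

    def with_conductances(
        self, gmax: "np.ndarray | list[float]", gL: float | None = None
    ) -> "ModelParameters":
        """Copy with the per-current maximum conductances (and optionally gL) replaced."""
        gmax = list(gmax)
        if len(gmax) != self.n_currents:
            raise ValueError("need one gmax per current")
        currents = tuple(
            CurrentParameters(float(g), cp.Erev, cp.p_gate, cp.q_gate)
            for g, cp in zip(gmax, self.currents)
        )
        return ModelParameters(
            currents, gL=self.gL if gL is None else float(gL),
            ErevL=self.ErevL, Cm=self.Cm,
        )


@dataclass(frozen=True)
class CellState:
    """Instantaneous state: membrane potential and gate values (p1,q1,...,pN,qN)."""

    Em: float
    gates: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        gates = np.asarray(self.gates, dtype=float)
        object.__setattr__(self, "gates", gates)
        if gates.ndim != 1 or gates.size % 2 != 0:
            raise ValueError("gates must be a flat (p1,q1,...,pN,qN) array")
        if gates.size and (gates.min() < -1e-12 or gates.max() > 1 + 1e-12):
            raise ValueError("gate values must lie in [0, 1]")

    @property
    def n_currents(self) -> int:
        return self.gates.size // 2

    def to_vector(self) -> np.ndarray:
        return np.concatenate([[self.Em], self.gates])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "CellState":
        y = np.asarray(y, dtype=float)
        return cls(Em=float(y[0]), gates=np.clip(y[1:], 0.0, 1.0))


# ---------------------------------------------------------------------------
# Elementary evaluations


def rate(Em, rp: RateParameters):
    """Sigmoidal rate k / (1 + exp(s (Em - E50))) in s^-1.

    Vectorised over ``Em``.  The exponent is clamped so extreme products
    saturate to 0 or k instead of overflowing.
    """
    x = np.clip(rp.s * (np.asarray(Em, dtype=float) - rp.E50), -_EXP_CLIP, _EXP_CLIP)
    return rp.k / (1.0 + np.exp(x))


def gate_derivative(g, a, b):
    """dg/dt = a (1 - g) - b g for opening rate a and closing rate b (s^-1)."""
    return a * (1.0 - np.asarray(g, dtype=float)) - b * g


def gate_equilibrium(Em: float, gp: GateParameters) -> tuple[float, float]:
    """Steady state and time constant of a gate held at fixed potential.

    Returns ``(g_inf, tau)`` with g_inf = a/(a+b) and tau = 1/(a+b) seconds.
    """
    a = float(rate(Em, gp.alpha))
    b = float(rate(Em, gp.beta))
    tot = a + b
    if tot <= 0.0:
        # both rates vanish: the gate is frozen; steady state undefined,
        # report the open fraction 0.5 with infinite time constant
        return 0.5, np.inf
    return a / tot, 1.0 / tot


def ionic_current(Em, p, q, cp: CurrentParameters):
    """i = gmax p q (Em - Erev); uS/cm^2 x mV = nA/cm^2."""
    return cp.gmax * np.asarray(p, dtype=float) * q * (Em - cp.Erev)


def leak_current(Em, gL: float, ErevL: float):
    """Time-independent leak gL (Em - ErevL) in nA/cm^2."""
    return gL * (np.asarray(Em, dtype=float) - ErevL)


# ---------------------------------------------------------------------------
# Packed arrays for the ODE right-hand side


class PackedModel:
    """Array view of a :class:`ModelParameters` for fast RHS evaluation."""

    __slots__ = ("Cm", "gmax", "Erev", "gL", "ErevL", "ka", "sa", "kb", "sb", "e50", "n")

    def __init__(self, params: ModelParameters):
        self.n = params.n_currents
        self.Cm = params.Cm
        self.gL = params.gL
        self.ErevL = params.ErevL
        self.gmax = np.array([c.gmax for c in params.currents])
        self.Erev = np.array([c.Erev for c in params.currents])
        # gate arrays ordered p1, q1, p2, q2, ...
        gates = [g for c in params.currents for g in (c.p_gate, c.q_gate)]
        self.ka = np.array([g.alpha.k for g in gates])
        self.sa = np.array([g.alpha.s for g in gates])
        self.kb = np.array([g.beta.k for g in gates])
        self.sb = np.array([g.beta.s for g in gates])
        self.e50 = np.array([g.alpha.E50 for g in gates])

    def rhs(self, y: np.ndarray, istim: float) -> np.ndarray:
        """Time derivative of the packed state vector (Em, p1, q1, ...)."""
        Em = y[0]
        g = y[1:]
        dv = Em - self.e50
        a = self.ka / (1.0 + np.exp(np.clip(self.sa * dv, -_EXP_CLIP, _EXP_CLIP)))
        b = self.kb / (1.0 + np.exp(np.clip(self.sb * dv, -_EXP_CLIP, _EXP_CLIP)))
        dg = a * (1.0 - g) - b * g
        gc = np.clip(g, 0.0, 1.0)
        i_ion = self.gmax * gc[0::2] * gc[1::2] * (Em - self.Erev)
        i_leak = self.gL * (Em - self.ErevL)
        dEm = -(istim + i_leak + i_ion.sum()) / self.Cm
        out = np.empty_like(y)
        out[0] = dEm
        out[1:] = dg
        return out

    def currents(self, Em, gates) -> np.ndarray:
        """Per-current time courses: shape (N, len(Em)) in nA/cm^2."""
        Em = np.atleast_1d(np.asarray(Em, dtype=float))
        gates = np.atleast_2d(gates)
        p = gates[:, 0::2].T
        q = gates[:, 1::2].T
        return self.gmax[:, None] * p * q * (Em[None, :] - self.Erev[:, None])


def state_derivative(
    state: CellState, params: ModelParameters, istim: float = 0.0
) -> np.ndarray:
    """Time derivative (dEm/dt, dp1/dt, dq1/dt, ...) of the state vector.

    dEm/dt comes out in mV/s, gate derivatives in s^-1.  ``istim`` is in
    nA/cm^2; a negative (inward) stimulus depolarises.
    """
    if state.n_currents != params.n_currents:
        raise ValueError(
            f"state has {state.n_currents} currents, model has {params.n_currents}"
        )
    return PackedModel(params).rhs(state.to_vector(), istim)


# ---------------------------------------------------------------------------
# Voltage clamp (closed form)


def voltage_clamp_gates(
    cp: CurrentParameters, hold: float, test: float, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gate time courses for a step from holding to test potential.

    Gates start at their steady state for the holding potential and relax
    exponentially, g(t) = g_inf + (g0 - g_inf) exp(-t/tau), at the test
    potential.  Returns ``(p(t), q(t))``.
    """
    t = np.asarray(t, dtype=float)
    out = []
    for gp in (cp.p_gate, cp.q_gate):
        g0, _ = gate_equilibrium(hold, gp)
        ginf, tau = gate_equilibrium(test, gp)
        if np.isfinite(tau):
            out.append(ginf + (g0 - ginf) * np.exp(-t / tau))
        else:
            out.append(np.full_like(t, g0))
    return out[0], out[1]


def voltage_clamp_current(
    params: ModelParameters, hold: float, test: float, t: np.ndarray
) -> np.ndarray:
    """Total membrane current (nA/cm^2) under a voltage step, closed form.

    All gates start at steady state for ``hold`` and relax at ``test``;
    the leak contributes a constant offset.  Used for voltage-clamp
    fitting, where no ODE integration is needed.
    """
    t = np.asarray(t, dtype=float)
    total = np.full_like(t, leak_current(test, params.gL, params.ErevL), dtype=float)
    for cp in params.currents:
        p, q = voltage_clamp_gates(cp, hold, test, t)
        total += ionic_current(test, p, q, cp)
    return total


# Default box bounds per parameter kind, used by the fitting layer.  The
# caps mirror where fitted values pile up in practice: rates saturate just
# below 5000 s^-1 and conductances below 4e4 uS/cm^2; potentials are kept
# within the physiological +-100 mV window and slopes within +-5 mV^-1.
PARAM_KINDS = ("g", "Erev", "k", "s", "E50")
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "g": (0.0, 4.0e4),
    "Erev": (-100.0, 100.0),
    "k": (0.0, 5000.0),
    "s": (-5.0, 5.0),
    "E50": (-100.0, 100.0),
}


def default_bounds(params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Default (lower, upper) box bounds for the flat parameter vector."""
    kinds = params.parameter_kinds()
    lo = np.array([DEFAULT_BOUNDS[k][0] for k in kinds])
    hi = np.array([DEFAULT_BOUNDS[k][1] for k in kinds])
    return lo, hi


__all__.append("PackedModel")
__all__.append("default_bounds")
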