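"""Stimulus protocols, forward simulation and action-potential features.

The simulator integrates the generic model with a stiff-capable adaptive
method, restarting the integration at every stimulus edge so that the
discontinuous applied current is never smoothed over by the step-size
controller.  Traces are sampled on a uniform output grid (20 kHz by
default, mirroring intracellular microelectrode acquisition) or on
caller-supplied sample times, which is what the fitting layer uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import CellState, ModelParameters, PackedModel

__all__ = [
    "StimulusProtocol",
    "Trace",
    "APFeatures",
    "SimulationError",
    "stimulus_value",
    "simulate",
    "phase_plot",
    "rms_error",
    "extract_features",
]


class SimulationError(RuntimeError):
    """Raised when the integrator fails or produces a non-finite state."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Applied-current protocol: rectangular pulses of fixed amplitude.

    ``amplitude`` is the stated pulse magnitude in uA/cm^2; internally the
    stimulus is delivered as a negative (inward, depolarising) current of
    ``-amplitude * 1000`` nA/cm^2 during each half-open window
    ``[onset, onset + pulse_width)``.
    """

    kind: str  # "spontaneous" | "uniform" | "sequence"
    amplitude: float = 0.0
    pulse_width: float = 0.0
    onsets: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.kind not in ("spontaneous", "uniform", "sequence"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if self.amplitude < 0:
            raise ValueError("amplitude is a magnitude, must be >= 0")
        if self.kind != "spontaneous":
            if not (self.pulse_width > 0):
                raise ValueError("paced protocols need pulse_width > 0")
            if onsets.size and np.any(np.diff(onsets) <= 0):
                raise ValueError("onsets must be strictly increasing")

    @classmethod
    def spontaneous(cls) -> "StimulusProtocol":
        return cls(kind="spontaneous")

    @classmethod
    def uniform(
        cls,
        pacing_interval: float,
        n_pulses: int,
        amplitude: float,
        pulse_width: float = 2e-3,
        first_onset: float | None = None,
    ) -> "StimulusProtocol":
        """Uniform pacing: pulses every ``pacing_interval`` seconds.

        The first pulse lands one pacing interval in unless ``first_onset``
        is given.
        """
        t0 = pacing_interval if first_onset is None else first_onset
        onsets = t0 + pacing_interval * np.arange(n_pulses)
        return cls("uniform", amplitude, pulse_width, onsets)

    @classmethod
    def sequence(
        cls, onsets, amplitude: float, pulse_width: float = 2e-3
    ) -> "StimulusProtocol":
        """Arbitrary (e.g. randomly generated) pulse-onset sequence."""
        return cls("sequence", amplitude, pulse_width, np.asarray(onsets, dtype=float))

    def edges(self, duration: float) -> np.ndarray:
        """All stimulus discontinuity times inside (0, duration)."""
        if self.kind == "spontaneous" or self.onsets.size == 0:
            return np.empty(0)
        e = np.concatenate([self.onsets, self.onsets + self.pulse_width])
        e = np.unique(e)
        return e[(e > 0) & (e < duration)]

    def artifact_windows(self, pad: float = 1e-3) -> list[tuple[float, float]]:
        """Stimulus-artifact masking windows [onset, onset + width + pad]."""
        return [(float(o), float(o + self.pulse_width + pad)) for o in self.onsets]

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind != "spontaneous":
            d["amplitude_uA_cm2"] = float(self.amplitude)
            d["width_ms"] = float(self.pulse_width * 1e3)
            d["onsets_ms"] = [float(o * 1e3) for o in self.onsets]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        kind = d["kind"]
        if kind == "spontaneous":
            return cls.spontaneous()
        amplitude = float(d["amplitude_uA_cm2"])
        width = float(d["width_ms"]) * 1e-3
        if "onsets_ms" in d:
            onsets = np.asarray(d["onsets_ms"], dtype=float) * 1e-3
            return cls(kind, amplitude, width, onsets)
        pi = float(d["PI_ms"]) * 1e-3
        return cls.uniform(pi, int(d["n_pulses"]), amplitude, width)


def stimulus_value(protocol: StimulusProtocol, t) -> np.ndarray | float:
    """Applied current (nA/cm^2) at time(s) t; negative during a pulse."""
    t = np.asarray(t, dtype=float)
    if protocol.kind == "spontaneous" or protocol.onsets.size == 0:
        out = np.zeros_like(t)
        return float(out) if out.ndim == 0 else out
    idx = np.searchsorted(protocol.onsets, t, side="right") - 1
    idx = np.clip(idx, 0, protocol.onsets.size - 1)
    inside = (t >= protocol.onsets[idx]) & (t < protocol.onsets[idx] + protocol.pulse_width)
    out = np.where(inside, -protocol.amplitude * 1e3, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class Trace:
    """Sampled time course of membrane potential with optional extras.

    ``weights`` are per-sample nonnegative fit weights (zero masks a
    sample out, e.g. over a stimulus artifact).  ``currents`` is an
    optional (N, n_samples) array of per-current time courses and
    ``gates`` an optional (n_samples, 2N) array.
    """

    t: np.ndarray
    Em: np.ndarray
    weights: np.ndarray | None = None
    currents: np.ndarray | None = None
    gates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.Em = np.asarray(self.Em, dtype=float)
        if self.weights is None:
            self.weights = np.ones_like(self.t)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        if self.t.size != self.Em.size or self.t.size != self.weights.size:
            raise ValueError("t, Em and weights must have equal length")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.t, "Em_mV": self.Em, "weight": self.weights})
        if self.currents is not None:
            for j in range(self.currents.shape[0]):
                df[f"i{j + 1}_nA_cm2"] = self.currents[j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        df = pd.read_csv(path)
        w = df["weight"].to_numpy() if "weight" in df else None
        cur_cols = [c for c in df.columns if c.startswith("i") and c.endswith("_nA_cm2")]
        cur = df[cur_cols].to_numpy().T if cur_cols else None
        return cls(df["time_s"].to_numpy(), df["Em_mV"].to_numpy(), w, cur)


def simulate(
    params: ModelParameters,
    x0: CellState,
    protocol: StimulusProtocol,
    duration: float,
    dt_out: float = 5e-5,
    *,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    method: str = "LSODA",
    record_currents: bool = False,
    record_gates: bool = False,
) -> Trace:
    """Integrate the model and return the sampled membrane potential.

    The integration is restarted at every stimulus edge; within a segment
    the applied current is constant.  ``t_eval`` overrides the uniform
    output grid (used when fitting against recorded sample times).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if x0.n_currents != params.n_currents:
        raise ValueError("initial state does not match the model's current count")
    if t_eval is None:
        n_out = int(round(duration / dt_out))
        t_eval = np.arange(n_out + 1) * dt_out
        t_eval[-1] = min(t_eval[-1], duration)
    else:
        t_eval = np.asarray(t_eval, dtype=float)
        if t_eval[0] < -1e-12 or t_eval[-1] > duration + 1e-12:
            raise ValueError("t_eval must lie within [0, duration]")

    packed = PackedModel(params)
    seg_bounds = np.concatenate([[0.0], protocol.edges(duration), [duration]])
    y = x0.to_vector()
    out = np.empty((t_eval.size, y.size))
    filled = 0
    n_seg = seg_bounds.size - 1
    for k in range(n_seg):
        t0, t1 = seg_bounds[k], seg_bounds[k + 1]
        istim = float(stimulus_value(protocol, (t0 + t1) / 2))
        # each segment owns the output points in [t0, t1); the final
        # segment takes every remaining point
        if k == n_seg - 1:
            stop = t_eval.size
        else:
            stop = int(np.searchsorted(t_eval, t1, side="left"))
        seg_eval = np.clip(t_eval[filled:stop], t0, t1)
        needs_tail = seg_eval.size == 0 or seg_eval[-1] < t1
        te = np.append(seg_eval, t1) if needs_tail else seg_eval

        def fun(t, yv, _istim=istim):
            return packed.rhs(yv, _istim)

        sol = solve_ivp(
            fun, (t0, t1), y, method=method, t_eval=te, rtol=rtol, atol=atol
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise SimulationError(
                f"integration failed in segment [{t0:g}, {t1:g}] s: {sol.message}"
            )
        ys = sol.y.T
        out[filled:stop] = ys[: seg_eval.size]
        y = ys[-1]
        filled = stop

    Em = out[:, 0]
    gates = np.clip(out[:, 1:], 0.0, 1.0)
    trace = Trace(t_eval, Em)
    if record_currents:
        trace.currents = packed.currents(Em, gates)
    if record_gates:
        trace.gates = gates
    return trace


def phase_plot(trace: Trace) -> tuple[np.ndarray, np.ndarray]:
    """(Em, dEm/dt) pairs with the derivative from first-order differences."""
    if len(trace) < 2:
        raise ValueError("phase plot needs at least two samples")
    dv = np.diff(trace.Em) / np.diff(trace.t)
    return trace.Em[:-1], dv


def rms_error(model: Trace, data: Trace) -> float:
    """Weighted RMS difference in mV; zero-weight samples are excluded.

    Weights are taken from ``data``; the two traces must share a sample
    grid.
    """
    if len(model) != len(data) or not np.allclose(model.t, data.t):
        raise ValueError("model and data traces must share the same sample grid")
    w = data.weights
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("all-zero weights: nothing to compare")
    return float(np.sqrt(np.sum(w * (model.Em - data.Em) ** 2) / wsum))


@dataclass
class APFeatures:
    """Per-cycle action-potential descriptors.

    Cycles are delimited by consecutive upstroke detections; arrays have
    one entry per complete cycle.  ``current_peaks`` has shape
    (n_cycles, N): the maximum absolute value of each current within the
    cycle, in nA/cm^2.
    """

    upstroke_times: np.ndarray
    cycle_length: np.ndarray
    max_diastolic_potential: np.ndarray
    overshoot: np.ndarray
    max_upstroke: np.ndarray
    apd90: np.ndarray | None = None
    current_peaks: np.ndarray | None = None

    @property
    def n_cycles(self) -> int:
        return self.cycle_length.size

    def mean_current_peak(self, j: int) -> float:
        """Mean over cycles of the peak magnitude of current j (1-based)."""
        if self.current_peaks is None:
            raise ValueError("trace was simulated without record_currents")
        return float(self.current_peaks[:, j - 1].mean())


def _empty_features() -> APFeatures:
    z = np.empty(0)
    return APFeatures(z, z, z, z, z)


def extract_features(
    trace: Trace,
    *,
    upstroke_threshold: float = 500.0,
    discard: float = 1.0,
    min_separation: float = 0.05,
) -> APFeatures:
    """Segment a trace into AP cycles and compute per-cycle features.

    Upstrokes are upward crossings of ``dEm/dt > upstroke_threshold``
    (mV/s), at least ``min_separation`` seconds apart; samples before
    ``discard`` seconds are ignored so initial transients do not bias
    periodic features.  A trace with fewer than two detected upstrokes
    yields an empty feature set.
    """
    if len(trace) < 3:
        return _empty_features()
    dv = np.diff(trace.Em) / np.diff(trace.t)
    tmid = trace.t[:-1]
    above = dv > upstroke_threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    times = tmid[crossings]
    times = times[times >= discard]
    # debounce: one upstroke per AP
    keep: list[float] = []
    for u in times:
        if not keep or u - keep[-1] >= min_separation:
            keep.append(float(u))
    if len(keep) < 2:
        return _empty_features()
    ups = np.asarray(keep)

    ncyc = ups.size - 1
    mdp = np.empty(ncyc)
    overshoot = np.empty(ncyc)
    vmax = np.empty(ncyc)
    apd90 = np.empty(ncyc)
    peaks = None
    if trace.currents is not None:
        peaks = np.empty((ncyc, trace.currents.shape[0]))
    for c in range(ncyc):
        sel = (trace.t >= ups[c]) & (trace.t < ups[c + 1])
        tc, vc = trace.t[sel], trace.Em[sel]
        mdp[c] = vc.min()
        overshoot[c] = vc.max()
        dsel = (tmid >= ups[c]) & (tmid < ups[c + 1])
        vmax[c] = dv[dsel].max()
        # APD90: time from the upstroke until Em first falls below the
        # 90%-repolarisation level after the peak
        level = overshoot[c] - 0.9 * (overshoot[c] - mdp[c])
        ipk = int(np.argmax(vc))
        below = np.flatnonzero(vc[ipk:] <= level)
        apd90[c] = (tc[ipk + below[0]] - tc[0]) if below.size else np.nan
        if peaks is not None:
            peaks[c] = np.abs(trace.currents[:, sel]).max(axis=1)
    return APFeatures(ups[:-1], np.diff(ups), mdp, overshoot, vmax, apd90, peaks)
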