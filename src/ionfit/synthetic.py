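"""Synthetic AP datasets with the statistical structure of microelectrode
recordings, plus voltage-clamp fitting against reference currents.

The generator simulates a known model, adds sampling noise scaled to a
target peak-to-peak level (intracellular sharp-electrode recordings at
20 kHz show roughly +-1 mV of peak-to-peak noise), optionally injects
square stimulus-artifact deflections, and attaches a zero-weight mask
over the artifact windows.  The generating parameters travel with the
dataset so recovery tests can compare against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hh import hh_reference_current
from .model import (
    CellState,
    ModelParameters,
    default_bounds,
    voltage_clamp_current,
)
from .multiobjective import DatasetSpec
from .fitting import FitOptions, FitResult, ResidualFunction, optimise
from .protocols import StimulusProtocol, Trace, simulate

__all__ = [
    "NoiseSpec",
    "RandomPacingSpec",
    "generate_pacing_sequence",
    "generate_ap_dataset",
    "perturbed_start",
    "voltage_clamp_residual",
    "fit_voltage_clamp",
    "clamp_fit_start",
    "hh_reference_current",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive recording noise.

    ``peak_to_peak`` is the full swing in mV (a +-0.96 mV band is a
    peak-to-peak of 1.92 mV).  The default distribution is uniform, since
    noise is usually quoted as a +- band rather than a standard
    deviation; gaussian is available.
    """

    peak_to_peak: float = 1.92
    distribution: str = "uniform"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.peak_to_peak < 0:
            raise ValueError("peak_to_peak must be >= 0")
        if self.distribution not in ("uniform", "gaussian"):
            raise ValueError(f"unknown noise distribution {self.distribution!r}")

    def sample(self, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
        """Draw n samples rescaled so the empirical peak-to-peak matches."""
        if self.peak_to_peak == 0 or n == 0:
            return np.zeros(n)
        if rng is None:
            rng = np.random.default_rng(self.seed)
        if self.distribution == "uniform":
            raw = rng.uniform(-0.5, 0.5, n)
        else:
            raw = rng.standard_normal(n)
        span = raw.max() - raw.min()
        if span == 0:
            return np.zeros(n)
        return raw * (self.peak_to_peak / span)


@dataclass(frozen=True)
class RandomPacingSpec:
    """Randomly paced stimulus train: normally distributed pacing intervals.

    Defaults follow the randomly paced atrial protocol: 100 pulses with
    pacing intervals drawn from Normal(275 ms, 69 ms), truncated below at
    ``min_PI`` (120 ms, about 2.25 SD below the mean, so truncation is
    negligible while excluding unphysiologically early pulses).
    """

    n_pulses: int = 100
    mean_PI: float = 0.275
    sd_PI: float = 0.069
    min_PI: float = 0.120
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.mean_PI > self.min_PI > 0):
            raise ValueError("need mean_PI > min_PI > 0")
        if self.sd_PI < 0 or self.n_pulses < 1:
            raise ValueError("invalid pacing spec")


def generate_pacing_sequence(spec: RandomPacingSpec) -> np.ndarray:
    """Pulse onset times (s): cumulative sums of truncated-normal intervals."""
    rng = np.random.default_rng(spec.seed)
    intervals = rng.normal(spec.mean_PI, spec.sd_PI, spec.n_pulses)
    intervals = np.maximum(intervals, spec.min_PI)
    return np.cumsum(intervals)


def generate_ap_dataset(
    params: ModelParameters,
    x0: CellState,
    protocol: StimulusProtocol,
    duration: float,
    noise: NoiseSpec | None = None,
    *,
    artifact: bool = False,
    artifact_amplitude: float = 15.0,
    artifact_pad: float = 1e-3,
    dt_out: float = 5e-5,
    label: str = "synthetic",
    **sim_options,
) -> DatasetSpec:
    """Simulate, contaminate and package one synthetic recording.

    With ``artifact=True`` a square deflection of ``artifact_amplitude``
    mV is added during each stimulus pulse and the window
    [onset, onset + width + pad] gets weight zero, mirroring how stimulus
    artifacts are masked out of real fits.
    """
    noise = noise or NoiseSpec(peak_to_peak=0.0)
    clean = simulate(params, x0, protocol, duration, dt_out, **sim_options)
    Em = clean.Em + noise.sample(len(clean))
    weights = np.ones_like(Em)
    if artifact and protocol.kind != "spontaneous":
        in_pulse = np.zeros(len(clean), dtype=bool)
        masked = np.zeros(len(clean), dtype=bool)
        for lo, hi in protocol.artifact_windows(artifact_pad):
            in_pulse |= (clean.t >= lo) & (clean.t < lo + protocol.pulse_width)
            masked |= (clean.t >= lo) & (clean.t <= hi)
        Em = Em + artifact_amplitude * in_pulse
        weights[masked] = 0.0
    data = Trace(clean.t.copy(), Em, weights)
    return DatasetSpec(
        data=data,
        protocol=protocol,
        initial_state=x0,
        label=label,
        true_parameters=params,
    )


def perturbed_start(
    params: ModelParameters,
    fraction: float = 0.2,
    seed: int | None = None,
) -> np.ndarray:
    """True parameter vector with every entry perturbed by a uniform
    relative factor in [-fraction, +fraction], projected onto the default
    bounds.  Standard starting point for recovery experiments."""
    rng = np.random.default_rng(seed)
    vec = params.to_vector()
    factors = 1.0 + rng.uniform(-fraction, fraction, vec.size)
    lo, hi = default_bounds(params)
    return np.clip(vec * factors, lo, hi)


# ---------------------------------------------------------------------------
# Voltage-clamp fitting (used for the higher-order-kinetics reference check)


def voltage_clamp_residual(
    t: np.ndarray,
    i_target: np.ndarray,
    hold: float,
    test: float,
    n_currents: int,
    Cm: float = 1.0,
) -> ResidualFunction:
    """Residual of a generic N-current model against a clamp current trace.

    Under clamp the gates relax in closed form, so evaluation needs no
    ODE solve.  Residuals are normalised by the target's peak magnitude,
    making the objective the squared fractional error.
    """
    t = np.asarray(t, dtype=float)
    i_target = np.asarray(i_target, dtype=float)
    peak = float(np.max(np.abs(i_target)))
    if peak <= 0:
        raise ValueError("target current is identically zero")
    template = ModelParameters.from_vector(
        np.zeros(12 * n_currents + 2), Cm=Cm
    )
    lo, hi = default_bounds(template)

    def fn(p):
        params = ModelParameters.from_vector(p, Cm=Cm)
        return (voltage_clamp_current(params, hold, test, t) - i_target) / peak

    return ResidualFunction(
        fn, names=template.parameter_names(), lower=lo, upper=hi
    )


def clamp_fit_start(
    n_currents: int,
    hold: float,
    test: float,
    i_target: np.ndarray,
    duration: float,
    seed: int | None = None,
) -> np.ndarray:
    """Heuristic start for clamp fits: activating p gates with staggered
    time constants spanning the trace, q gates near-sustained, reversal
    potentials on the far side of the test potential so each current can
    carry the target's sign, conductances sized from the target peak."""
    rng = np.random.default_rng(seed)
    peak = float(np.max(np.abs(i_target)))
    sign = 1.0 if i_target[np.argmax(np.abs(i_target))] > 0 else -1.0
    erev = test - sign * 80.0
    erev = float(np.clip(erev, -100.0, 100.0))
    g0 = peak / (abs(test - erev) * n_currents)
    mid = 0.5 * (hold + test)
    taus = np.geomspace(duration / 50.0, duration / 2.0, n_currents)
    vec: list[float] = []
    for tau in taus:
        k_fast = float(np.clip(1.0 / tau, 10.0, 5000.0))
        jitter = rng.uniform(0.8, 1.25, 4)
        vec += [min(g0, 4e4), erev]
        # p gate: closed at hold, opening at test with time constant ~tau
        vec += [k_fast * jitter[0], -0.15, k_fast * 0.25 * jitter[1], 0.15, mid]
        # q gate: slowly inactivating, mostly open
        vec += [50.0 * jitter[2], -0.05, 20.0 * jitter[3], 0.05, mid]
    vec += [0.0, test]  # leak off at start
    return np.asarray(vec)


def fit_voltage_clamp(
    t: np.ndarray,
    i_target: np.ndarray,
    hold: float,
    test: float,
    n_currents: int,
    options: FitOptions | None = None,
    p0: np.ndarray | None = None,
    seed: int | None = None,
    n_starts: int = 6,
) -> tuple[FitResult, float]:
    """Fit N generic currents to a clamp current trace.

    The clamp response is evaluated in closed form, so runs are cheap:
    the fit is repeated from ``n_starts`` independently jittered
    heuristic starts (uniform-in-bounds restarts are hopeless in this
    heavily redundant parameterisation), the best run wins, and the
    winner is polished with progressively finer finite-difference steps
    (1e-6, then 1e-7 relative), which releases the plateaus the coarse
    default step cannot resolve.  Returns the best fit result and its
    RMS error as a fraction of the target's peak magnitude.
    """
    import dataclasses

    rf = voltage_clamp_residual(t, i_target, hold, test, n_currents)
    opts = options or FitOptions(max_iterations=300)
    opts.restarts = 0
    duration = float(t[-1] - t[0])
    rng = np.random.default_rng(seed)
    starts = [p0] if p0 is not None else []
    while len(starts) < (1 if p0 is not None else n_starts):
        starts.append(
            clamp_fit_start(
                n_currents, hold, test, i_target, duration,
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    best: FitResult | None = None
    for start in starts:
        res = optimise(rf, start, opts)
        if best is None or res.objective < best.objective:
            best = res
    assert best is not None
    for step in (1e-6, 1e-7):
        polish_opts = dataclasses.replace(opts, jac_rel_step=step)
        res = optimise(rf, best.p, polish_opts)
        if res.objective < best.objective:
            best = res
    rms_frac = float(np.sqrt(best.objective / len(np.asarray(t))))
    return best, rms_frac
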