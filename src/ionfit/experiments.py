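"""Self-contained reproduction workflows.

Each function runs one of the package's headline computations end to end
— simulating fixture models, generating synthetic recordings, fitting —
and returns the measured quantities.  They are used by the regression
suite and by ``scripts/acceptance.py``, and double as worked examples of
the API.

Problem sizes are chosen so the full set runs on a laptop in minutes:
recovery fits use a 1 s record fitted on a 2 kHz decimation of the
20 kHz synthetic trace, and clamp fits use the closed-form clamp
response, which needs no ODE integration.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import io
from .fitting import FitOptions, optimise
from .model import ModelParameters
from .multiobjective import DatasetSpec, MultiFitProblem, SharingScheme
from .protocols import StimulusProtocol, Trace, extract_features, rms_error, simulate
from .synthetic import (
    NoiseSpec,
    RandomPacingSpec,
    fit_voltage_clamp,
    generate_ap_dataset,
    generate_pacing_sequence,
    perturbed_start,
)
from .hh import hh_reference_current

__all__ = [
    "drug_block_reconstruction",
    "pacing_statistics",
    "csan_recovery",
    "hh_refit",
    "structure_counts",
]


def drug_block_reconstruction(
    duration: float = 5.0, discard: float = 1.0
) -> dict[str, float]:
    """Simulate the four-current pSAN model under control and iKr-block
    conditions and measure the reconstructed i3 (iKr) peaks.

    Returns mean per-cycle peak |i3| in uA/cm^2 for both conditions, plus
    mean APD90 (s) and mean maximum diastolic potential (mV).
    """
    out: dict[str, float] = {}
    for cond in ("control", "e4031"):
        params, x0 = io.drug_model(cond)
        trace = simulate(
            params, x0, StimulusProtocol.spontaneous(), duration,
            record_currents=True,
        )
        feats = extract_features(trace, discard=discard)
        out[f"peak_i3_{cond}_uA_cm2"] = feats.mean_current_peak(3) / 1e3
        out[f"apd90_{cond}_s"] = float(np.nanmean(feats.apd90))
        out[f"mdp_{cond}_mV"] = float(feats.max_diastolic_potential.mean())
    return out


def pacing_statistics(n_seeds: int = 50, base_seed: int = 0) -> dict[str, float]:
    """Sample mean/SD of randomly generated pacing-interval sequences.

    Each sequence is 100 intervals from Normal(275 ms, 69 ms) truncated
    at 120 ms; statistics are averaged over ``n_seeds`` sequences.
    """
    means, sds, skews = [], [], []
    for k in range(n_seeds):
        spec = RandomPacingSpec(seed=base_seed + k)
        onsets = generate_pacing_sequence(spec)
        intervals = np.diff(np.concatenate([[0.0], onsets]))
        means.append(intervals.mean())
        sds.append(intervals.std(ddof=1))
        skews.append(stats.skew(intervals))
    return {
        "mean_PI_ms": float(np.mean(means) * 1e3),
        "sd_PI_ms": float(np.mean(sds) * 1e3),
        "mean_abs_skewness": float(np.mean(np.abs(skews))),
    }


def csan_recovery(
    seed: int = 11,
    duration: float = 1.0,
    noise_ptp: float = 1.92,
    perturbation: float = 0.2,
    decimation: int = 10,
    max_iterations: int = 60,
) -> dict[str, float]:
    """Round-trip parameter recovery on a synthetic cSAN recording.

    A 20 kHz spontaneous trace is generated from the two-current cSAN
    model with uniform noise of the given peak-to-peak level; the fit
    starts from the true parameters perturbed by a uniform +-20% relative
    factor and runs on a 2 kHz decimation of the record.  Reported RMS
    values are measured on the full 20 kHz grid.
    """
    params, x0 = io.minimal_cell("cSAN")
    protocol = StimulusProtocol.spontaneous()
    ds = generate_ap_dataset(
        params, x0, protocol, duration, noise=NoiseSpec(noise_ptp, seed=seed)
    )
    sub = Trace(
        ds.data.t[::decimation], ds.data.Em[::decimation], ds.data.weights[::decimation]
    )
    problem = MultiFitProblem(
        [DatasetSpec(sub, protocol, x0, label="cSAN")], SharingScheme("shared"), params
    )
    p0 = perturbed_start(params, perturbation, seed=seed)

    def full_grid_rms(vec: np.ndarray) -> float:
        fitted = ModelParameters.from_vector(vec, Cm=params.Cm)
        tr = simulate(fitted, x0, protocol, duration, t_eval=ds.data.t)
        return rms_error(tr, ds.data)

    start_rms = full_grid_rms(p0)
    res = optimise(
        problem.residual_function(), p0, FitOptions(max_iterations=max_iterations, tol=1e-10)
    )
    return {
        "start_rms_mV": float(start_rms),
        "final_rms_mV": float(full_grid_rms(res.p)),
        "noise_floor_mV": float(noise_ptp / np.sqrt(12.0)),
        "iterations": float(res.n_iterations),
    }


def hh_refit(kind: str, n_currents: int, seed: int = 7) -> dict[str, float]:
    """Fit N generic two-gate currents to a reference Hodgkin-Huxley
    voltage-clamp current (step -60 -> +40 mV) and report the RMS error
    as a percentage of the reference peak."""
    t, i = hh_reference_current(kind)
    res, rms_frac = fit_voltage_clamp(
        t, i, -60.0, 40.0, n_currents,
        options=FitOptions(max_iterations=250),
        seed=seed,
    )
    return {
        "rms_percent_of_peak": 100.0 * rms_frac,
        "iterations": float(res.n_iterations),
    }


def structure_counts(n_currents: tuple[int, ...] = (2, 5, 7)) -> dict[str, float]:
    """State-variable and parameter counts for models of several sizes."""
    out: dict[str, float] = {}
    for n in n_currents:
        m = ModelParameters.from_vector(np.zeros(12 * n + 2))
        out[f"n_states_N{n}"] = float(m.n_states)
        out[f"n_parameters_N{n}"] = float(m.n_parameters)
    return out
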