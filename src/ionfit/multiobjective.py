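"""Simultaneous fitting of several AP recordings with parameter sharing.

R datasets are fitted at once by appending their weighted residuals into
one stacked residual vector.  Three sharing schemes are supported:

* ``shared`` — one parameter set for all datasets (n global parameters);
* ``independent`` — every dataset has its own full set (n * R);
* ``mixed`` — S named parameters take a distinct value per dataset while
  the rest are shared, giving n + (R - 1) * S globals.  This is the
  scheme behind drug-block scenarios (one conductance differs between
  control and drug) and tissue-heterogeneity scenarios (all conductances
  differ between cell types, kinetics shared).

Each dataset carries its own stimulus protocol and fixed initial state;
initial states are inputs, not fitted (an explicit design choice — they
can be promoted to data-specific free parameters by the caller, but that
is off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CellState, ModelParameters, default_bounds
from .fitting import FitOptions, FitResult, ResidualFunction, optimise
from .protocols import SimulationError, StimulusProtocol, Trace, rms_error, simulate

__all__ = [
    "DatasetSpec",
    "SharingScheme",
    "MultiFitResult",
    "global_parameter_layout",
    "project",
    "stacked_residual",
    "residual_function",
    "fit_multiobjective",
    "predict_rms",
]


@dataclass
class DatasetSpec:
    """One recording to fit: samples, the protocol that produced them, and
    the model's initial state for that record."""

    data: Trace
    protocol: StimulusProtocol
    initial_state: CellState
    label: str = ""
    true_parameters: ModelParameters | None = None  # set by the generator


@dataclass(frozen=True)
class SharingScheme:
    """How parameters are shared across datasets."""

    mode: str  # "shared" | "independent" | "mixed"
    specific_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("shared", "independent", "mixed"):
            raise ValueError(f"unknown sharing mode {self.mode!r}")
        names = tuple(self.specific_names)
        object.__setattr__(self, "specific_names", names)
        if len(set(names)) != len(names):
            raise ValueError("duplicate data-specific parameter names")
        if self.mode == "mixed" and not names:
            raise ValueError("mixed mode needs at least one data-specific parameter")


def global_parameter_layout(
    base_names: list[str], R: int, scheme: SharingScheme
) -> list[str]:
    """Ordered names of the global parameter vector.

    shared: the n base names; independent: n * R names in per-dataset
    blocks; mixed: the n base names (serving dataset 0) followed by one
    block of the S specific names per additional dataset, giving
    n + (R - 1) * S entries.
    """
    if R < 1:
        raise ValueError("need at least one dataset")
    if scheme.mode == "shared":
        return list(base_names)
    if scheme.mode == "independent":
        return [f"{nm}[{d}]" for d in range(R) for nm in base_names]
    missing = set(scheme.specific_names) - set(base_names)
    if missing:
        raise ValueError(f"specific names not in the model: {sorted(missing)}")
    out = list(base_names)
    for d in range(1, R):
        out += [f"{nm}[{d}]" for nm in scheme.specific_names]
    return out


def project(
    global_p: np.ndarray,
    dataset_index: int,
    scheme: SharingScheme,
    base_names: list[str],
    R: int,
) -> np.ndarray:
    """Per-dataset parameter vector from the global vector."""
    global_p = np.asarray(global_p, dtype=float)
    n = len(base_names)
    if not 0 <= dataset_index < R:
        raise IndexError(f"dataset index {dataset_index} out of range (R={R})")
    if scheme.mode == "shared":
        return global_p.copy()
    if scheme.mode == "independent":
        return global_p[dataset_index * n : (dataset_index + 1) * n].copy()
    p = global_p[:n].copy()
    if dataset_index > 0:
        S = len(scheme.specific_names)
        block = global_p[n + (dataset_index - 1) * S : n + dataset_index * S]
        idx = [base_names.index(nm) for nm in scheme.specific_names]
        p[idx] = block
    return p


@dataclass
class MultiFitProblem:
    """Stacked-residual fitting problem over R datasets.

    ``template`` fixes the model structure (N, Cm); parameter values come
    from the global vector at evaluation time.
    """

    datasets: list[DatasetSpec]
    scheme: SharingScheme
    template: ModelParameters
    rtol: float = 1e-6
    atol: float = 1e-8
    method: str = "LSODA"
    # optionally append each dataset's initial state (Em plus 2N gates)
    # to the global vector as data-specific free parameters
    fit_initial_states: bool = False

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("need at least one dataset")
        self._base_names = self.template.parameter_names()

    @property
    def R(self) -> int:
        return len(self.datasets)

    @property
    def base_names(self) -> list[str]:
        return list(self._base_names)

    def _n_param_global(self) -> int:
        return len(global_parameter_layout(self._base_names, self.R, self.scheme))

    def layout(self) -> list[str]:
        names = global_parameter_layout(self._base_names, self.R, self.scheme)
        if self.fit_initial_states:
            state_names = ["x0_Em"] + [
                f"x0_{g}{j + 1}" for j in range(self.template.n_currents)
                for g in ("p", "q")
            ]
            for d in range(self.R):
                names += [f"{nm}[{d}]" for nm in state_names]
        return names

    def n_global(self) -> int:
        return len(self.layout())

    def model_for(self, global_p: np.ndarray, d: int) -> ModelParameters:
        np_glob = self._n_param_global()
        vec = project(global_p[:np_glob], d, self.scheme, self._base_names, self.R)
        return ModelParameters.from_vector(vec, Cm=self.template.Cm)

    def state_for(self, global_p: np.ndarray, d: int) -> CellState:
        if not self.fit_initial_states:
            return self.datasets[d].initial_state
        ns = self.template.n_states
        tail = np.asarray(global_p)[self._n_param_global() :]
        block = tail[d * ns : (d + 1) * ns]
        return CellState(Em=float(block[0]), gates=np.clip(block[1:], 0.0, 1.0))

    def dataset_residual(self, global_p: np.ndarray, d: int) -> np.ndarray:
        ds = self.datasets[d]
        try:
            params = self.model_for(global_p, d)
            trace = simulate(
                params,
                self.state_for(global_p, d),
                ds.protocol,
                duration=float(ds.data.t[-1]),
                t_eval=ds.data.t,
                rtol=self.rtol,
                atol=self.atol,
                method=self.method,
            )
        except (SimulationError, ValueError) as err:
            raise SimulationError(f"dataset {ds.label or d}: {err}") from err
        return (trace.Em - ds.data.Em) * np.sqrt(ds.data.weights)

    def residual(self, global_p: np.ndarray) -> np.ndarray:
        """Stacked weighted residual; length = total samples across datasets."""
        return np.concatenate(
            [self.dataset_residual(global_p, d) for d in range(self.R)]
        )

    def m_total(self) -> int:
        return sum(len(ds.data) for ds in self.datasets)

    def global_from_base(self, base_vec: np.ndarray) -> np.ndarray:
        """Tile a single model's parameter vector into the global layout."""
        base_vec = np.asarray(base_vec, dtype=float)
        n = len(self._base_names)
        if base_vec.size != n:
            raise ValueError("base vector does not match the model")
        if self.scheme.mode == "shared":
            out = base_vec.copy()
        elif self.scheme.mode == "independent":
            out = np.tile(base_vec, self.R)
        else:
            idx = [self._base_names.index(nm) for nm in self.scheme.specific_names]
            out = np.concatenate([base_vec] + [base_vec[idx]] * (self.R - 1))
        if self.fit_initial_states:
            out = np.concatenate(
                [out] + [ds.initial_state.to_vector() for ds in self.datasets]
            )
        return out

    def global_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = default_bounds(self.template)
        if self.scheme.mode == "independent":
            lo, hi = np.tile(lo, self.R), np.tile(hi, self.R)
        elif self.scheme.mode == "mixed":
            idx = [self._base_names.index(nm) for nm in self.scheme.specific_names]
            reps = self.R - 1
            lo = np.concatenate([lo] + [lo[idx]] * reps)
            hi = np.concatenate([hi] + [hi[idx]] * reps)
        if self.fit_initial_states:
            ns = self.template.n_states
            s_lo = np.concatenate([[-100.0], np.zeros(ns - 1)])
            s_hi = np.concatenate([[100.0], np.ones(ns - 1)])
            lo = np.concatenate([lo] + [s_lo] * self.R)
            hi = np.concatenate([hi] + [s_hi] * self.R)
        return lo, hi

    def residual_function(self) -> ResidualFunction:
        """Optimiser-facing residual; solver failures become +inf residuals
        so a bad probe point is rejected instead of aborting the fit."""
        m = self.m_total()

        def fn(global_p):
            try:
                return self.residual(global_p)
            except SimulationError:
                return np.full(m, np.inf)

        lo, hi = self.global_bounds()
        return ResidualFunction(fn, names=self.layout(), lower=lo, upper=hi)

    def per_dataset_rms(self, global_p: np.ndarray) -> dict[str, float]:
        out = {}
        for d, ds in enumerate(self.datasets):
            r = self.dataset_residual(global_p, d)
            w = ds.data.weights
            out[ds.label or str(d)] = float(np.sqrt((r**2).sum() / w.sum()))
        return out


def stacked_residual(
    datasets: list[DatasetSpec],
    params_global: np.ndarray,
    scheme: SharingScheme,
    template: ModelParameters,
    **sim_options,
) -> np.ndarray:
    """Functional wrapper around :meth:`MultiFitProblem.residual`."""
    return MultiFitProblem(datasets, scheme, template, **sim_options).residual(
        params_global
    )


def residual_function(
    datasets: list[DatasetSpec],
    scheme: SharingScheme,
    template: ModelParameters,
    **sim_options,
) -> ResidualFunction:
    return MultiFitProblem(datasets, scheme, template, **sim_options).residual_function()


@dataclass
class MultiFitResult:
    """Fit outcome plus the per-dataset RMS errors (mV) at the optimum."""

    fit: FitResult
    per_dataset_rms: dict[str, float]
    layout: list[str] = field(default_factory=list)

    @property
    def p(self) -> np.ndarray:
        return self.fit.p


def fit_multiobjective(
    datasets: list[DatasetSpec],
    scheme: SharingScheme,
    p0_global: np.ndarray,
    template: ModelParameters,
    options: FitOptions | None = None,
    **sim_options,
) -> MultiFitResult:
    """Run the curvilinear optimiser on the stacked residual."""
    problem = MultiFitProblem(datasets, scheme, template, **sim_options)
    res = optimise(problem.residual_function(), np.asarray(p0_global, float), options)
    return MultiFitResult(res, problem.per_dataset_rms(res.p), problem.layout())


def predict_rms(
    params: ModelParameters,
    dataset: DatasetSpec,
    **sim_options,
) -> float:
    """RMS of a frozen model against a dataset it was not fitted to.

    This is the protocol-substitution validation: same parameters, a new
    stimulus protocol and initial state.
    """
    trace = simulate(
        params,
        dataset.initial_state,
        dataset.protocol,
        duration=float(dataset.data.t[-1]),
        t_eval=dataset.data.t,
        **sim_options,
    )
    return rms_error(trace, dataset.data)
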