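"""Global criticality measures and scaling sweeps of the recurrence.

Training changes mostly the *scale* of the recurrent connectivity, so the
network's distance from its critical point is probed by replacing the
trained matrix ``K_tr`` with ``sigma * K_tr`` and tracking, as a function
of the scaling factor ``sigma``:

* the entropy term of the objective (without regularization),
* the Euler convergence time on a silent stimulus (critical slowing down),
* the population-vector magnitude of the silent attractor (spontaneous
  symmetry breaking into a bump),
* the mean squared pairwise correlation of responses across a fixed
  evaluation stimulus set.

The critical scale is ``sigma_c = 4 / rho(K_tr)``: the factor at which the
spectral radius of the scaled recurrence reaches 4, the instability
boundary for the logistic gain bound ``max g' = 1/4``.  The operating point
of a trained network is ``sigma = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dynamics import (
    NetworkParams,
    default_initial_state,
    integrate_euler,
    spectral_radius,
    steady_state,
)
from .learning import CriticalityError, _entropy_term, jacobian_chi


def population_vector_magnitude(s: np.ndarray) -> float:
    """Modulus of the population vector ``1/N sum_k s_k exp(i 2 pi k / N)``.

    Output neurons are assigned equally spaced angles on the circle; the
    modulus vanishes for a uniform activity profile and grows when the
    profile breaks symmetry into a localized bump.
    """
    s = np.asarray(s, dtype=float)
    n = s.size
    phases = 2.0 * np.pi * np.arange(1, n + 1) / n
    return float(np.abs(np.mean(s * np.exp(1j * phases))))


def mean_squared_pairwise_correlation(responses: np.ndarray) -> float:
    """Mean of squared Pearson correlations over all output-neuron pairs.

    ``responses`` is (samples, N).  Neurons with zero variance across the
    sample set carry no correlation information and are excluded.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.ndim != 2 or responses.shape[0] < 2:
        raise ValueError("need a (samples >= 2, neurons) response matrix")
    valid = responses.std(axis=0) > 0
    if int(valid.sum()) < 2:
        raise ValueError("fewer than 2 neurons with nonzero variance")
    r = np.corrcoef(responses[:, valid], rowvar=False)
    iu = np.triu_indices_from(r, k=1)
    return float(np.mean(r[iu] ** 2))


def convergence_time(
    params: NetworkParams,
    x: np.ndarray,
    dt: float = 0.1,
    tol: float = 1e-6,
    max_steps: int = 1_000_000,
) -> int:
    """Euler step count to convergence, from the recurrence-free state."""
    res = integrate_euler(
        params, x, s0=default_initial_state(params, x), dt=dt, tol=tol, max_steps=max_steps
    )
    return res.iterations


@dataclass
class SweepReport:
    """Per-sigma table of global measures from a scaling sweep."""

    sigma_grid: np.ndarray
    objective_noreg: np.ndarray
    convergence_time: np.ndarray
    popvec_magnitude: np.ndarray
    mean_sq_correlation: np.ndarray
    critical_sigma: float
    operating_point: float = 1.0
    meta: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sigma": self.sigma_grid,
                "objective_noreg": self.objective_noreg,
                "convergence_time": self.convergence_time,
                "popvec_magnitude": self.popvec_magnitude,
                "mean_sq_correlation": self.mean_sq_correlation,
            }
        )

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for key, val in {"critical_sigma": self.critical_sigma, **self.meta}.items():
                fh.write(f"# {key}: {val}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)


def default_sigma_grid(critical_sigma: float, n_points: int = 60) -> np.ndarray:
    """Log-spaced scaling grid spanning sub- and supercritical regimes."""
    return np.geomspace(0.05, 1.5 * critical_sigma, n_points)


def scale_sweep(
    params: NetworkParams,
    eval_stimuli: np.ndarray,
    sigma_grid: Optional[np.ndarray] = None,
    silent_stimulus: Optional[np.ndarray] = None,
    dt: float = 0.1,
    euler_tol: float = 1e-6,
    max_steps: int = 200_000,
    noise_scale: float = 1e-3,
    rng: Optional[np.random.Generator] = None,
    check_stability: bool = True,
) -> SweepReport:
    """Evaluate the four global measures for each recurrence scaling factor.

    For each ``sigma`` the trained recurrence is replaced by
    ``sigma * K_tr``.  The entropy term and pairwise correlations use the
    fixed evaluation stimulus set; convergence time integrates the silent
    stimulus from the recurrence-free state; the population vector is taken
    on the silent attractor reached from a weakly noise-perturbed start, so
    a symmetry-broken bump can be found when the homogeneous state is
    unstable.  Per-sigma solver failures are recorded as NaN rather than
    aborting the sweep.
    """
    eval_stimuli = np.atleast_2d(np.asarray(eval_stimuli, dtype=float))
    if silent_stimulus is None:
        silent_stimulus = np.zeros(params.n_inputs)
    rng = np.random.default_rng() if rng is None else rng
    rho = spectral_radius(params.K)
    critical_sigma = np.inf if rho == 0 else 4.0 / rho
    if sigma_grid is None:
        sigma_grid = default_sigma_grid(critical_sigma if np.isfinite(critical_sigma) else 1.0)
    sigma_grid = np.asarray(sigma_grid, dtype=float)

    k_tr = params.K
    obj = np.full(sigma_grid.size, np.nan)
    conv = np.full(sigma_grid.size, np.nan)
    popvec = np.full(sigma_grid.size, np.nan)
    corr = np.full(sigma_grid.size, np.nan)
    # one shared perturbation so popvec varies smoothly across sigma
    silent_init_noise = rng.uniform(0.0, 1.0, size=params.n_outputs)

    for i, sigma in enumerate(sigma_grid):
        scaled = params.copy()
        scaled.K = sigma * k_tr

        conv[i] = convergence_time(
            scaled, silent_stimulus, dt=dt, tol=euler_tol, max_steps=max_steps
        )

        s0 = default_initial_state(scaled, silent_stimulus) + noise_scale * silent_init_noise
        attractor = integrate_euler(
            scaled, silent_stimulus, s0=s0, dt=dt, tol=euler_tol, max_steps=max_steps
        )
        popvec[i] = population_vector_magnitude(attractor.s)

        ent = 0.0
        n_ok = 0
        resp = np.full((eval_stimuli.shape[0], params.n_outputs), np.nan)
        for j, x in enumerate(eval_stimuli):
            res = steady_state(
                scaled, x, check_stability=check_stability,
                euler_dt=dt, euler_tol=euler_tol, euler_max_steps=max_steps,
            )
            if not res.converged:
                continue
            resp[j] = res.s
            try:
                chi, _ = jacobian_chi(scaled, res)
                ent += _entropy_term(chi)
                n_ok += 1
            except CriticalityError:
                pass
        if n_ok:
            obj[i] = ent / n_ok
        ok_rows = ~np.any(np.isnan(resp), axis=1)
        if int(ok_rows.sum()) >= 2:
            try:
                corr[i] = mean_squared_pairwise_correlation(resp[ok_rows])
            except ValueError:
                pass

    return SweepReport(
        sigma_grid=sigma_grid,
        objective_noreg=obj,
        convergence_time=conv,
        popvec_magnitude=popvec,
        mean_sq_correlation=corr,
        critical_sigma=float(critical_sigma),
        meta={"rho_K": rho, "n_eval": eval_stimuli.shape[0]},
    )
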