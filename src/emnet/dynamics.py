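"""Network state, steady-state solvers and linearized stability.

The model is a recurrent rate network with first-order dynamics

    tau ds_i/dt = -s_i + g(sum_j W_ij x_j + sum_k K_ik s_k - T_i),

where ``g(h) = 1 / (1 + exp(-h))`` is the logistic activation, ``W`` the
feed-forward weights (N x M), ``K`` the recurrent weights (N x N) and ``T``
the thresholds.  Responses to a stimulus are steady states of these
dynamics, i.e. solutions of ``s = g(Wx + Ks - T)``, found either by
Newton-Raphson iteration on the fixed-point equation or by explicit Euler
integration of the dynamics.

A steady state is linearly stable iff every eigenvalue of ``I - G K`` has a
positive real part, where ``G = diag(g'(h))``.  Since ``max g' = 1/4``, a
spectral radius ``rho(K) < 4`` guarantees stability; ``rho(K) = 4`` marks
the network's critical point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import expit


def activation(h: np.ndarray) -> np.ndarray:
    """Logistic activation ``g(h) = 1 / (1 + exp(-h))``, saturating safely."""
    return expit(h)


def activation_deriv(h: np.ndarray) -> np.ndarray:
    """``g'(h) = g(h) (1 - g(h))``, in ``(0, 1/4]``."""
    g = expit(h)
    return g * (1.0 - g)


def activation_second_deriv(h: np.ndarray) -> np.ndarray:
    """``g''(h) = g'(h) (1 - 2 g(h))``."""
    g = expit(h)
    return g * (1.0 - g) * (1.0 - 2.0 * g)


@dataclass
class NetworkParams:
    """Connectivity and thresholds of the recurrent network.

    Attributes
    ----------
    W : (N, M) array
        Feed-forward weights from input channels to output neurons.
    K : (N, N) array
        Recurrent weights between output neurons (zero diagonal during
        training: autapses are truncated).
    T : (N,) array
        Output thresholds.
    tau : float
        Time constant of the rate dynamics (arbitrary units).
    meta : dict
        Free-form provenance (seed, training phase, hyper-parameters).
    """

    W: np.ndarray
    K: np.ndarray
    T: np.ndarray
    tau: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        n, m = self.W.shape
        if self.K.shape != (n, n):
            raise ValueError(f"K must be ({n}, {n}), got {self.K.shape}")
        if self.T.shape != (n,):
            raise ValueError(f"T must be ({n},), got {self.T.shape}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def n_inputs(self) -> int:
        return self.W.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.W.shape[0]

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.W.copy(), self.K.copy(), self.T.copy(), self.tau, dict(self.meta)
        )

    def net_input(self, x: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Net input ``h = Wx + Ks - T``."""
        return self.W @ x + self.K @ s - self.T

    def save(self, path) -> None:
        """Serialize to a portable ``.npz`` container with a metadata record."""
        meta = dict(self.meta)
        meta.update(M=self.n_inputs, N=self.n_outputs, tau=self.tau)
        np.savez(
            path, W=self.W, K=self.K, T=self.T, meta=np.bytes_(json.dumps(meta))
        )

    @classmethod
    def load(cls, path) -> "NetworkParams":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            tau = float(meta.pop("tau", 1.0))
            meta.pop("M", None)
            meta.pop("N", None)
            return cls(data["W"], data["K"], data["T"], tau=tau, meta=meta)


@dataclass
class SteadyStateResult:
    """Outcome of a steady-state solve.

    ``s`` is the activity vector, ``h`` the net input at the fixed point,
    ``gain`` the per-neuron slope ``g'(h)`` (the diagonal of ``G``),
    ``residual`` the infinity-norm of ``s - g(h)``.
    """

    s: np.ndarray
    h: np.ndarray
    gain: np.ndarray
    method: str
    iterations: int
    converged: bool
    residual: float


def _result(params: NetworkParams, x, s, method, iterations, converged) -> SteadyStateResult:
    h = params.net_input(x, s)
    residual = float(np.max(np.abs(s - activation(h))))
    return SteadyStateResult(
        s=s, h=h, gain=activation_deriv(h), method=method,
        iterations=iterations, converged=converged, residual=residual,
    )


def default_initial_state(params: NetworkParams, x: np.ndarray) -> np.ndarray:
    """The recurrence-free response ``g(Wx - T)``, used to seed the solvers."""
    return activation(params.W @ x - params.T)


def steady_state_newton(
    params: NetworkParams,
    x: np.ndarray,
    s_init: Optional[np.ndarray] = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> SteadyStateResult:
    """Solve the fixed-point equation ``s = g(Wx + Ks - T)`` by Newton-Raphson.

    Iterates ``s <- s - (I - GK)^{-1} (s - g(h))`` until the infinity-norm
    residual drops below ``tol``.  A singular Jacobian or exhausted
    iteration budget yields ``converged=False`` (never an exception); the
    caller may fall back to Euler integration.
    """
    n = params.n_outputs
    s = default_initial_state(params, x) if s_init is None else np.asarray(s_init, float).copy()
    eye = np.eye(n)
    for it in range(max_iter):
        h = params.net_input(x, s)
        f = s - activation(h)
        if np.max(np.abs(f)) <= tol:
            return _result(params, x, s, "newton", it, True)
        jac = eye - activation_deriv(h)[:, None] * params.K
        try:
            step = np.linalg.solve(jac, f)
        except np.linalg.LinAlgError:
            return _result(params, x, s, "newton", it, False)
        if not np.all(np.isfinite(step)):
            return _result(params, x, s, "newton", it, False)
        s = np.clip(s - step, 1e-15, 1.0 - 1e-15)
    return _result(params, x, s, "newton", max_iter, False)


def integrate_euler(
    params: NetworkParams,
    x: np.ndarray,
    s0: Optional[np.ndarray] = None,
    dt: float = 0.1,
    tol: float = 1e-6,
    max_steps: int = 1_000_000,
) -> SteadyStateResult:
    """Integrate the rate dynamics with explicit Euler until they settle.

    The convergence criterion is ``max |delta s| < tol`` over one step; the
    step count is the convergence-time measure used in the scaling sweeps
    (critical slowing down shows up as a diverging count).  An exhausted
    step budget is reported as a non-converged result with
    ``iterations = max_steps``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = default_initial_state(params, x) if s0 is None else np.asarray(s0, float).copy()
    rate = dt / params.tau
    for step in range(max_steps):
        ds = rate * (activation(params.net_input(x, s)) - s)
        if np.max(np.abs(ds)) < tol:
            return _result(params, x, s, "euler", step, True)
        s = s + ds
    return _result(params, x, s, "euler", max_steps, False)


def steady_state(
    params: NetworkParams,
    x: np.ndarray,
    s_init: Optional[np.ndarray] = None,
    tol: float = 1e-10,
    max_iter: int = 200,
    check_stability: bool = False,
    euler_dt: float = 0.1,
    euler_tol: float = 1e-6,
    euler_max_steps: int = 1_000_000,
    fallback_noise: float = 1e-3,
    rng: Optional[np.random.Generator] = None,
) -> SteadyStateResult:
    """Newton solve with an Euler fallback.

    Euler integration takes over when Newton fails to converge or — with
    ``check_stability`` — when it lands on a linearly unstable fixed point
    (as the homogeneous state is in the supercritical regime).  The fallback
    start is perturbed by ``fallback_noise`` so the dynamics can leave an
    unstable point and relax to a stable, typically symmetry-broken
    attractor; ``rng`` seeds the perturbation (a fixed default keeps
    repeated calls deterministic).
    """
    res = steady_state_newton(params, x, s_init=s_init, tol=tol, max_iter=max_iter)
    unstable = False
    if res.converged and check_stability:
        eigs = np.linalg.eigvals(linearized_matrix(params, res))
        unstable = bool(np.min(eigs.real) < 0)
    if res.converged and not unstable:
        return res
    s0 = default_initial_state(params, x) if s_init is None else np.asarray(s_init, float)
    if fallback_noise:
        rng = np.random.default_rng(0) if rng is None else rng
        s0 = s0 + fallback_noise * rng.uniform(0.0, 1.0, s0.size)
    euler = integrate_euler(
        params, x, s0=s0, dt=euler_dt, tol=euler_tol, max_steps=euler_max_steps
    )
    return replace(euler, method="newton-then-euler")


def linearized_matrix(
    params: NetworkParams, steady: SteadyStateResult
) -> np.ndarray:
    """Linearized fixed-point matrix ``I - G K`` with ``G = diag(gain)``."""
    return linearized_matrix_from_gain(params.K, steady.gain)


def linearized_matrix_from_gain(K: np.ndarray, gain) -> np.ndarray:
    """``I - G K`` for an explicit gain diagonal (scalar or length-N)."""
    K = np.asarray(K, dtype=float)
    gain = np.broadcast_to(np.asarray(gain, dtype=float), (K.shape[0],))
    return np.eye(K.shape[0]) - gain[:, None] * K


def spectral_radius(K: np.ndarray) -> float:
    """Largest eigenvalue modulus of a square matrix."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("spectral_radius expects a square matrix")
    return float(np.max(np.abs(np.linalg.eigvals(K))))
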