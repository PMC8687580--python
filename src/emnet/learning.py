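"""Regularized entropy-maximization objective, gradients and training.

The network is trained, unsupervised, to maximize the entropy of its
steady-state output representation.  For a steady state ``s`` the
susceptibility (input-output Jacobian) is

    chi = d s / d x = phi W,      phi = (I - G K)^{-1} G,

and the per-sample loss being minimized is

    eps = -1/2 log det(chi^T chi) + reg(W) + reg(K),

averaged over stimuli.  In the overcomplete case (N > M) ``chi`` is tall
and its pseudo-inverse ``chi+ = (chi^T chi)^{-1} chi^T`` enters the exact
gradient-descent updates:

    dW = eta ( phi^T ((chi+)^T + y x^T) - lambda_W S(W) )
    dK = eta ( phi^T (chi chi+ + y s^T) - lambda_K K )
    dT = eta ( -phi^T y )

with ``y_l = (chi chi+ phi)_ll g''(h_l) / g'(h_l)^3`` and ``S(A) = sign(A)``
elementwise (``sign(0) = 0``).  The ``-lambda_K K`` term is the l2 weight
decay; an l1 variant replaces it with ``-lambda_K S(K)`` (and symmetrically
for W).  These rules account for the full dependence of the steady state on
the parameters; they are validated against finite differences of the
objective in the test suite.

Training follows a three-phase schedule: (1) feed-forward weights and
thresholds on clean stimuli with the recurrence clamped to zero, (2) the
recurrent weights alone on clean stimuli, (3) the recurrent weights alone
on attenuated stimuli (sensory deprivation).  Autapses (diagonal of K) are
truncated to zero after every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    NetworkParams,
    SteadyStateResult,
    spectral_radius,
    steady_state_newton,
)
from .stimuli import AttenuationProfile, StimulusModel, apply_attenuation, generate_stimulus


class CriticalityError(RuntimeError):
    """Raised when the linearized matrix is singular (network at criticality)."""


@dataclass(frozen=True)
class LearningConfig:
    """Hyper-parameters of one training phase."""

    eta: float = 0.001
    lambda_w: float = 0.001
    lambda_k: float = 0.226
    ff_norm: str = "l1"
    rec_norm: str = "l2"
    n_iterations: int = 100_000
    train_W: bool = False
    train_K: bool = True
    train_T: bool = False
    newton_tol: float = 1e-10
    trace_every: int = 1000
    max_failure_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.lambda_w < 0 or self.lambda_k < 0:
            raise ValueError("regularization coefficients must be >= 0")
        if self.ff_norm not in ("l1", "l2") or self.rec_norm not in ("l1", "l2"):
            raise ValueError("norms must be 'l1' or 'l2'")
        if not (self.train_W or self.train_K or self.train_T):
            raise ValueError("at least one of train_W/train_K/train_T must be set")


@dataclass
class GradientBundle:
    """Update directions (already negated: apply as ``param += eta * d*``)."""

    dW: np.ndarray
    dK: np.ndarray
    dT: np.ndarray
    chi: np.ndarray
    phi: np.ndarray
    y: np.ndarray


def _sign(a: np.ndarray) -> np.ndarray:
    return np.sign(a)


def jacobian_chi(
    params: NetworkParams, steady: SteadyStateResult
) -> tuple[np.ndarray, np.ndarray]:
    """Susceptibility ``chi = phi W`` and ``phi = (I - GK)^{-1} G``.

    Raises :class:`CriticalityError` if ``I - GK`` is numerically singular,
    in which case the sample must not drive a weight update.
    """
    n = params.n_outputs
    jac = np.eye(n) - steady.gain[:, None] * params.K
    try:
        phi = np.linalg.solve(jac, np.diag(steady.gain))
    except np.linalg.LinAlgError as exc:
        raise CriticalityError("I - GK is singular: network at criticality") from exc
    if not np.all(np.isfinite(phi)):
        raise CriticalityError("I - GK solve produced non-finite susceptibility")
    return phi @ params.W, phi


def _entropy_term(chi: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(chi.T @ chi)
    if sign <= 0 or not np.isfinite(logdet):
        raise CriticalityError("chi^T chi is singular; log-determinant undefined")
    return -0.5 * float(logdet)


def _reg_terms(params: NetworkParams, config: LearningConfig) -> tuple[float, float]:
    if config.ff_norm == "l1":
        reg_w = config.lambda_w * float(np.sum(np.abs(params.W)))
    else:
        reg_w = 0.5 * config.lambda_w * float(np.sum(params.W**2))
    if config.rec_norm == "l1":
        reg_k = config.lambda_k * float(np.sum(np.abs(params.K)))
    else:
        reg_k = 0.5 * config.lambda_k * float(np.sum(params.K**2))
    return reg_w, reg_k


def objective(
    params: NetworkParams,
    batch: np.ndarray,
    config: LearningConfig,
    newton_tol: Optional[float] = None,
) -> tuple[float, float, tuple[float, float]]:
    """Regularized objective over a batch of stimuli.

    Returns ``(total, entropy_term, (reg_W, reg_K))`` where the entropy term
    is ``-1/2 <log det(chi^T chi)>`` averaged over the batch.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[0] == 0:
        raise ValueError("batch must be nonempty")
    tol = config.newton_tol if newton_tol is None else newton_tol
    ent = 0.0
    for idx, x in enumerate(batch):
        steady = steady_state_newton(params, x, tol=tol)
        if not steady.converged:
            raise CriticalityError(f"steady-state solve failed for sample {idx}")
        chi, _ = jacobian_chi(params, steady)
        try:
            ent += _entropy_term(chi)
        except CriticalityError as exc:
            raise CriticalityError(f"sample {idx}: {exc}") from exc
    ent /= batch.shape[0]
    reg_w, reg_k = _reg_terms(params, config)
    return ent + reg_w + reg_k, ent, (reg_w, reg_k)


def gradients(
    params: NetworkParams,
    x: np.ndarray,
    steady: SteadyStateResult,
    config: LearningConfig,
    include_entropy: bool = True,
) -> GradientBundle:
    """Exact single-sample update directions for W, K and T.

    The returned directions are descent directions on the regularized
    objective, i.e. ``-d eps / d param``; the learning rate is applied by
    the caller.  The recurrent direction includes the diagonal; autapse
    truncation happens at update time.
    """
    chi, phi = jacobian_chi(params, steady)
    n, m = params.W.shape
    if include_entropy:
        gram = chi.T @ chi
        try:
            chi_pinv = np.linalg.solve(gram, chi.T)  # (M, N)
        except np.linalg.LinAlgError as exc:
            raise CriticalityError("chi^T chi singular; gradients undefined") from exc
        proj = chi @ chi_pinv  # symmetric projection chi chi+
        gain = steady.gain
        # y_l = (chi chi+ phi)_ll g''(h_l) / g'(h_l)^3, with g''/g'^3 = (1-2s)/g'^2
        y = np.sum(proj * phi.T, axis=1) * (1.0 - 2.0 * steady.s) / gain**2
        dW = phi.T @ (chi_pinv.T + np.outer(y, x))
        dK = phi.T @ (proj + np.outer(y, steady.s))
        dT = -phi.T @ y
    else:
        dW = np.zeros((n, m))
        dK = np.zeros((n, n))
        dT = np.zeros(n)
        y = np.zeros(n)
    dW = dW - config.lambda_w * (_sign(params.W) if config.ff_norm == "l1" else params.W)
    dK = dK - config.lambda_k * (_sign(params.K) if config.rec_norm == "l1" else params.K)
    return GradientBundle(dW=dW, dK=dK, dT=dT, chi=chi, phi=phi, y=y)


class TrainingAborted(RuntimeError):
    """Raised when too many steady-state solves fail during a phase.

    A high failure rate means the recurrence has crossed into the
    supercritical regime where fixed points are unstable or absent.  The
    partial parameters and trace at abort time are attached so sweeps can
    still record the (near-critical) state that was reached.
    """

    def __init__(self, message: str, params: "NetworkParams", trace: pd.DataFrame):
        super().__init__(message)
        self.params = params
        self.trace = trace


def train_phase(
    params: NetworkParams,
    config: LearningConfig,
    stimulus_model: StimulusModel,
    rng: np.random.Generator,
    attenuation: Optional[AttenuationProfile] = None,
    callback: Optional[Callable[[int, NetworkParams], None]] = None,
) -> tuple[NetworkParams, pd.DataFrame]:
    """Run one online training phase and return updated params plus a trace.

    Stimuli are drawn i.i.d. from ``stimulus_model`` (optionally attenuated)
    and each drives a single-sample gradient update.  Samples whose
    steady-state solve fails are skipped and counted; the phase aborts if
    the failure rate exceeds ``config.max_failure_rate`` within any
    10,000-sample window.  The diagonal of K is truncated to zero after
    every update.  The trace records the running objective pieces and
    ``rho(K)`` every ``config.trace_every`` iterations.
    """
    params = params.copy()
    rows = []
    failures_window = 0
    window = 10_000
    failures_total = 0
    for it in range(config.n_iterations):
        x = generate_stimulus(stimulus_model, rng)
        if attenuation is not None:
            x = apply_attenuation(x, attenuation)
        try:
            steady = steady_state_newton(params, x, tol=config.newton_tol)
            if not steady.converged:
                raise CriticalityError("Newton failed to converge")
            grads = gradients(params, x, steady, config)
        except CriticalityError:
            failures_window += 1
            failures_total += 1
            if failures_window > config.max_failure_rate * window:
                raise TrainingAborted(
                    f"{failures_window} solver failures within the last "
                    f"{window} samples at iteration {it}",
                    params,
                    pd.DataFrame(rows),
                )
            continue
        if config.train_W:
            params.W += config.eta * grads.dW
        if config.train_K:
            params.K += config.eta * grads.dK
            np.fill_diagonal(params.K, 0.0)
        if config.train_T:
            params.T += config.eta * grads.dT
        if (it + 1) % window == 0:
            failures_window = 0
        if config.trace_every and (it % config.trace_every == 0 or it == config.n_iterations - 1):
            ent = _entropy_term(grads.chi)
            reg_w, reg_k = _reg_terms(params, config)
            rows.append(
                {
                    "iteration": it,
                    "entropy_term": ent,
                    "reg_W": reg_w,
                    "reg_K": reg_k,
                    "objective": ent + reg_w + reg_k,
                    "rho_K": spectral_radius(params.K),
                    "failures": failures_total,
                }
            )
        if callback is not None:
            callback(it, params)
    params.meta["failures"] = failures_total
    return params, pd.DataFrame(rows)


def init_feedforward_tonotopic(
    m: int,
    n: int,
    amplitude: float = 0.5,
    width: float = 1.0,
    threshold: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Weak ordered Gaussian feed-forward profiles seeding the tonotopy.

    Row ``i`` (1-based) of W is a Gaussian bump on the channel axis centered
    at ``i * M / N``, so preferred frequencies increase with output index.
    Thresholds start at a constant.
    """
    if n < m:
        raise ValueError("overcomplete network requires N >= M")
    channels = np.arange(1, m + 1, dtype=float)
    centers = np.arange(1, n + 1, dtype=float) * m / n
    W = amplitude * np.exp(-0.5 * ((channels[None, :] - centers[:, None]) / width) ** 2)
    T = np.full(n, float(threshold))
    return W, T


@dataclass(frozen=True)
class Phase:
    """One entry of a training schedule."""

    config: LearningConfig
    attenuation: Optional[AttenuationProfile] = None
    name: str = ""


def default_schedule(
    attenuation: AttenuationProfile,
    phase1_iters: int = 50_000,
    phase2_iters: int = 100_000,
    phase3_iters: int = 100_000,
    eta1: float = 0.1,
    eta23: float = 0.001,
    lambda_w: float = 0.001,
    lambda_k: float = 0.226,
    ff_norm: str = "l1",
    rec_norm: str = "l2",
    include_phase2: bool = True,
) -> list[Phase]:
    """The three-phase schedule: feed-forward, recurrent, deprived recurrent.

    Phase 1 trains W and T on clean stimuli with K clamped at zero; phases 2
    and 3 train only K, without and with input attenuation respectively.
    ``include_phase2=False`` gives the no-pretraining variant in which the
    recurrence develops only under deprivation.
    """
    common = dict(lambda_w=lambda_w, lambda_k=lambda_k, ff_norm=ff_norm, rec_norm=rec_norm)
    phases = [
        Phase(
            LearningConfig(
                eta=eta1, n_iterations=phase1_iters,
                train_W=True, train_K=False, train_T=True, **common,
            ),
            None,
            "phase1_feedforward",
        )
    ]
    if include_phase2:
        phases.append(
            Phase(
                LearningConfig(
                    eta=eta23, n_iterations=phase2_iters,
                    train_W=False, train_K=True, train_T=False, **common,
                ),
                None,
                "phase2_recurrent",
            )
        )
    phases.append(
        Phase(
            LearningConfig(
                eta=eta23, n_iterations=phase3_iters,
                train_W=False, train_K=True, train_T=False, **common,
            ),
            attenuation,
            "phase3_deprived",
        )
    )
    return phases


def run_schedule(
    schedule: Sequence[Phase],
    params: NetworkParams,
    stimulus_model: StimulusModel,
    rng: np.random.Generator,
) -> list[tuple[NetworkParams, pd.DataFrame]]:
    """Execute a training schedule, returning a checkpoint after each phase.

    An empty schedule returns just the initial parameters (with an empty
    trace).  Each checkpoint's ``meta`` records the phase name.
    """
    checkpoints = []
    if not schedule:
        return [(params.copy(), pd.DataFrame())]
    current = params
    for phase in schedule:
        current, trace = train_phase(
            current, phase.config, stimulus_model, rng, attenuation=phase.attenuation
        )
        current.meta["phase"] = phase.name
        checkpoints.append((current.copy(), trace))
    return checkpoints
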