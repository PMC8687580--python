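"""End-to-end analyses: deprivation experiment, sweeps, audiograms, scoring.

This module turns the building blocks (stimuli, dynamics, learning,
criticality) into the full study pipeline: train the network on clean
stimuli, attenuate a frequency band and retrain the recurrence, then
characterize connectivity (tonotopy, aligned Mexican-hat profiles, deprived
vs non-deprived zones), spontaneous activity (hallucination scoring against
the pre-deprivation silent baseline), criticality (scaling sweeps before
and after deprivation) and sensitivity (simulated audiograms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .config import RunConfig
from .criticality import (
    SweepReport,
    default_sigma_grid,
    population_vector_magnitude,
    scale_sweep,
)
from .dynamics import (
    NetworkParams,
    activation,
    integrate_euler,
    spectral_radius,
    steady_state,
)
from .learning import (
    LearningConfig,
    Phase,
    TrainingAborted,
    default_schedule,
    init_feedforward_tonotopic,
    run_schedule,
    train_phase,
)
from .stimuli import (
    AttenuationProfile,
    StimulusModel,
    apply_attenuation,
    band_attenuation,
    calibrate_normalization,
    pure_tone_probe,
    sigmoid_attenuation,
    stimulus_batch,
)


def preferred_frequency(W: np.ndarray) -> np.ndarray:
    """Preferred input channel (1-based) of each output neuron.

    The preferred frequency is the argmax of the neuron's feed-forward row;
    ties break toward the lowest channel.  All-zero rows have no preference
    and are flagged with -1.
    """
    W = np.asarray(W, dtype=float)
    pf = np.argmax(W, axis=1) + 1
    pf[np.all(W == 0, axis=1)] = -1
    return pf


def aligned_row_profile(
    matrix: np.ndarray,
    pf: np.ndarray,
    subset: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average presynaptic profile aligned on preferred-frequency offsets.

    For each postsynaptic neuron in ``subset``, the presynaptic entries of
    its row are re-indexed by the offset ``pf[pre] - pf[post]`` (the
    log-scaled difference in preferred frequency, since channels are
    log-spaced) and averaged per offset bin across neurons.

    Returns ``(offsets, mean_profile, counts)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    pf = np.asarray(pf)
    n = matrix.shape[0]
    subset = np.arange(n) if subset is None else np.asarray(subset)
    if subset.size == 0:
        raise ValueError("subset must be nonempty")
    defined = pf > 0
    m_max = int(pf[defined].max()) if defined.any() else 0
    offsets = np.arange(-(m_max - 1), m_max)
    sums = np.zeros(offsets.size)
    counts = np.zeros(offsets.size, dtype=int)
    for post in subset:
        if not defined[post]:
            continue
        for pre in range(n):
            if pre == post or not defined[pre]:
                continue
            off = int(pf[pre] - pf[post])
            idx = off + m_max - 1
            sums[idx] += matrix[post, pre]
            counts[idx] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return offsets, mean, counts


@dataclass
class ZoneLabels:
    """Deprived / non-deprived classification of output neurons."""

    preferred_frequency: np.ndarray
    zone: np.ndarray  # array of "deprived" / "non_deprived"

    @property
    def deprived(self) -> np.ndarray:
        return np.flatnonzero(self.zone == "deprived")

    @property
    def non_deprived(self) -> np.ndarray:
        return np.flatnonzero(self.zone == "non_deprived")


def classify_zones(
    pf: np.ndarray, profile: AttenuationProfile, cutoff: float = 0.5
) -> ZoneLabels:
    """Label neurons by the attenuation at their preferred frequency.

    A neuron is *deprived* iff ``a(pf) < cutoff``.  Neurons without a
    defined preferred frequency are labelled non-deprived.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    pf = np.asarray(pf)
    zone = np.full(pf.size, "non_deprived", dtype=object)
    defined = pf > 0
    zone[defined] = np.where(
        profile.at_channel(pf[defined]) < cutoff, "deprived", "non_deprived"
    )
    return ZoneLabels(preferred_frequency=pf, zone=zone.astype(str))


def silent_attractor(
    params: NetworkParams,
    rng: np.random.Generator,
    noise_scale: float = 1e-3,
    dt: float = 0.1,
    tol: float = 1e-6,
    max_steps: int = 1_000_000,
):
    """Stable activity under zero input, from a weakly perturbed start.

    The initial state is the recurrence-free silent response ``g(-T)`` plus
    small uniform noise, letting the dynamics break symmetry when the
    homogeneous state is unstable (supercritical regime).
    """
    x = np.zeros(params.n_inputs)
    s0 = activation(-params.T) + noise_scale * rng.uniform(0.0, 1.0, params.n_outputs)
    return integrate_euler(params, x, s0=s0, dt=dt, tol=tol, max_steps=max_steps)


@dataclass
class HallucinationReport:
    score: float
    peak_neuron: int  # 0-based output index of the maximal elevation
    is_hallucinating: bool
    popvec_magnitude: float
    threshold: float
    converged: bool
    activity: np.ndarray
    n_peaks: int = 0
    smoothed_peak_neuron: int = -1
    smoothed_elevation: Optional[np.ndarray] = None


def _circular_smooth(v: np.ndarray, window: int) -> np.ndarray:
    pad = window // 2
    ext = np.r_[v[-pad:], v, v[:pad]] if pad else v
    return np.convolve(ext, np.ones(window) / window, mode="valid")


def count_elevation_peaks(
    elevation: np.ndarray, window: Optional[int] = None
) -> tuple[int, int, np.ndarray]:
    """Dominant-bump count of an elevation profile over the output ring.

    The profile is smoothed with a circular moving average (window of about
    an eighth of the ring by default, matching the recurrent bump width so
    per-neuron baseline heterogeneity does not masquerade as extra peaks),
    and contiguous regions above half the smoothed maximum are counted.

    Returns ``(n_peaks, peak_neuron, smoothed)``.
    """
    elevation = np.asarray(elevation, dtype=float)
    n = elevation.size
    if window is None:
        window = max(3, n // 8)
    sm = _circular_smooth(elevation, window)
    if sm.max() <= 0:
        return 0, int(np.argmax(sm)), sm
    above = sm > 0.5 * sm.max()
    idx = np.flatnonzero(above)
    runs = 1 + int(np.sum(np.diff(idx) > 1)) if idx.size else 0
    if idx.size and above[0] and above[-1] and runs > 1:
        runs -= 1  # the ring wraps: first and last runs are one region
    return runs, int(np.argmax(sm)), sm


def hallucination_score(
    params: NetworkParams,
    spontaneous_baseline: np.ndarray,
    rng: np.random.Generator,
    threshold: Optional[float] = None,
    noise_scale: float = 1e-3,
    dt: float = 0.1,
    tol: float = 1e-6,
    max_steps: int = 1_000_000,
) -> HallucinationReport:
    """Score stimulus-independent activity against the spontaneous baseline.

    The baseline is the pre-deprivation network's silent response (per
    neuron).  The score is the maximal elevation of the silent attractor
    above it; since activities live in (0, 1), the default detection
    threshold is an elevation of 0.1 — a tenth of the dynamic range, far
    above solver tolerance yet small against a saturated bump.  The raw
    score and threshold are both reported so users can re-threshold.
    """
    baseline = np.asarray(spontaneous_baseline, dtype=float)
    res = silent_attractor(
        params, rng, noise_scale=noise_scale, dt=dt, tol=tol, max_steps=max_steps
    )
    elevation = res.s - baseline
    score = float(np.max(elevation))
    peak = int(np.argmax(elevation))
    if threshold is None:
        threshold = 0.1
    n_peaks, smoothed_peak, smoothed = count_elevation_peaks(elevation)
    return HallucinationReport(
        score=score,
        peak_neuron=peak,
        is_hallucinating=bool(score > threshold),
        popvec_magnitude=population_vector_magnitude(res.s),
        threshold=float(threshold),
        converged=res.converged,
        activity=res.s,
        n_peaks=n_peaks,
        smoothed_peak_neuron=smoothed_peak,
        smoothed_elevation=smoothed,
    )


def bisect_threshold(
    f: Callable[[float], float],
    target: float,
    lo: float = 0.0,
    hi: float = 100.0,
    tol: float = 1e-6,
) -> tuple[float, bool]:
    """Smallest argument where ``f`` crosses ``target``, by bisection.

    Assumes ``f(lo) < target``.  Returns ``(threshold, reached)``;
    ``reached`` is False (and the threshold is the ceiling ``hi``) when
    even ``f(hi)`` stays below the target.
    """
    if f(hi) < target:
        return hi, False
    a, b = lo, hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        if f(mid) < target:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b), True


@dataclass
class Audiogram:
    """Per-channel probe amplitudes producing a just-noticeable response."""

    thresholds: np.ndarray
    reached: np.ndarray
    target: float = 0.01
    tolerance: float = 1e-6
    search_interval: tuple[float, float] = (0.0, 100.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": np.arange(1, self.thresholds.size + 1),
                "threshold": self.thresholds,
                "reached": self.reached,
            }
        )


def simulate_audiogram(
    params: NetworkParams,
    target: float = 0.01,
    tol: float = 1e-6,
    max_amplitude: float = 100.0,
    probe_width: Optional[float] = None,
    attenuation: Optional[AttenuationProfile] = None,
    check_stability: bool = True,
) -> Audiogram:
    """Simulated hearing thresholds from single-frequency probes.

    For each input channel, bisection finds the probe amplitude at which
    the steady-state response differs from the silent response by
    ``target`` in the infinity norm.  With ``attenuation`` given, probes
    pass through the attenuated periphery first (hearing loss is a property
    of the input pathway, so an impaired system is probed through it).
    Channels where even the maximal amplitude fails the criterion are
    flagged as at ceiling.
    """
    m = params.n_inputs
    silent = steady_state(params, np.zeros(m), check_stability=check_stability)
    thresholds = np.zeros(m)
    reached = np.zeros(m, dtype=bool)
    for k in range(1, m + 1):
        def response_diff(a: float, k=k) -> float:
            probe = pure_tone_probe(k, a, m, width=probe_width)
            if attenuation is not None:
                probe = apply_attenuation(probe, attenuation)
            res = steady_state(params, probe, check_stability=check_stability)
            return float(np.max(np.abs(res.s - silent.s)))

        thresholds[k - 1], reached[k - 1] = bisect_threshold(
            response_diff, target, 0.0, max_amplitude, tol
        )
    return Audiogram(
        thresholds=thresholds,
        reached=reached,
        target=target,
        tolerance=tol,
        search_interval=(0.0, max_amplitude),
    )


def make_attenuation(config: RunConfig) -> AttenuationProfile:
    if config.attenuation_kind == "sigmoid":
        return sigmoid_attenuation(config.k0, config.beta, config.m)
    if config.attenuation_kind == "band":
        return band_attenuation(config.k1, config.k2, config.beta, config.m)
    raise ValueError(f"unknown attenuation kind {config.attenuation_kind!r}")


def make_stimulus_model(
    config: RunConfig, rng: np.random.Generator
) -> StimulusModel:
    model = StimulusModel(
        n_channels=config.m,
        min_tones=config.min_tones,
        max_tones=config.max_tones,
        amp_range=config.amp_range,
        width_scale=config.width_scale,
        noise_range=config.noise_range,
    )
    return calibrate_normalization(model, config.calibration_samples, rng)


def initial_network(config: RunConfig) -> NetworkParams:
    W, T = init_feedforward_tonotopic(
        config.m, config.n, amplitude=config.init_amplitude, width=config.init_width
    )
    return NetworkParams(W, np.zeros((config.n, config.n)), T, tau=config.tau)


def lambda_sweep(
    config: RunConfig,
    lambda_grid: Sequence[float],
    rng: np.random.Generator,
    with_deprivation: bool = True,
    phase1_checkpoint: Optional[NetworkParams] = None,
    stimulus_model: Optional[StimulusModel] = None,
    drop_level: float = 3.0,
) -> tuple[pd.DataFrame, Optional[tuple[float, float]]]:
    """Spectral radius of the trained recurrence across lambda_K values.

    All grid points share one phase-1 checkpoint (only the recurrent
    regularization varies).  For each lambda_K, phase 2 is run from that
    checkpoint and — optionally — phase 3 under attenuation; the spectral
    radius ``rho(K)`` is recorded at each phase end.  The *hallucination
    interval* is the lambda range where the clean-trained network is
    subcritical but the deprived network is near-critical: the borders are
    the interpolated lambdas at which the pre- and post-deprivation
    ``rho(K)`` curves cross ``drop_level`` (the midpoint of the sharp drop
    from near 4 to well below it).
    """
    if len(lambda_grid) == 0:
        raise ValueError("lambda grid must be nonempty")
    if stimulus_model is None:
        stimulus_model = make_stimulus_model(config, rng)
    if phase1_checkpoint is None:
        phase1 = LearningConfig(
            eta=config.eta1, lambda_w=config.lambda_w, lambda_k=config.lambda_k,
            ff_norm=config.ff_norm, rec_norm=config.rec_norm,
            n_iterations=config.phase1_iters,
            train_W=True, train_K=False, train_T=True,
        )
        phase1_checkpoint, _ = train_phase(
            initial_network(config), phase1, stimulus_model, rng
        )
    attenuation = make_attenuation(config)
    rows = []
    for lam in lambda_grid:
        row = {
            "lambda_k": float(lam), "rho_pre": np.nan, "rho_post": np.nan,
            "aborted_pre": False, "aborted_post": False,
        }
        cfg2 = LearningConfig(
            eta=config.eta23, lambda_w=config.lambda_w, lambda_k=float(lam),
            ff_norm=config.ff_norm, rec_norm=config.rec_norm,
            n_iterations=config.phase2_iters,
            train_W=False, train_K=True, train_T=False,
        )
        try:
            pre, _ = train_phase(
                phase1_checkpoint.copy(), cfg2, stimulus_model,
                np.random.default_rng(rng.integers(2**31)),
            )
        except TrainingAborted as exc:
            # supercritical escape: record the near-critical state reached
            pre = exc.params
            row["aborted_pre"] = True
        row["rho_pre"] = spectral_radius(pre.K)
        if with_deprivation:
            cfg3 = dc_replace(cfg2, n_iterations=config.phase3_iters)
            try:
                post, _ = train_phase(
                    pre, cfg3, stimulus_model,
                    np.random.default_rng(rng.integers(2**31)),
                    attenuation=attenuation,
                )
            except TrainingAborted as exc:
                post = exc.params
                row["aborted_post"] = True
            row["rho_post"] = spectral_radius(post.K)
        rows.append(row)
    table = pd.DataFrame(rows)
    interval = None
    if with_deprivation and table["rho_pre"].notna().all() and table["rho_post"].notna().all():
        lo = _crossing(table["lambda_k"].values, table["rho_pre"].values, drop_level)
        hi = _crossing(table["lambda_k"].values, table["rho_post"].values, drop_level)
        if lo is not None and hi is not None and hi > lo:
            interval = (lo, hi)
    return table, interval


def _crossing(lams: np.ndarray, rhos: np.ndarray, level: float) -> Optional[float]:
    """Interpolated lambda at which a decreasing rho(lambda) crosses `level`."""
    order = np.argsort(lams)
    lams, rhos = lams[order], rhos[order]
    for i in range(len(lams) - 1):
        a, b = rhos[i], rhos[i + 1]
        if (a - level) * (b - level) <= 0 and a != b:
            return float(lams[i] + (level - a) / (b - a) * (lams[i + 1] - lams[i]))
    return None


@dataclass
class DeprivationResult:
    """Everything the full deprivation experiment produces."""

    config: RunConfig
    stimulus_model: StimulusModel
    attenuation: AttenuationProfile
    checkpoints: dict  # phase name -> NetworkParams
    traces: dict  # phase name -> DataFrame
    zones: ZoneLabels
    spontaneous_baseline: np.ndarray
    sweep_pre: SweepReport
    sweep_post: SweepReport
    hallucination: HallucinationReport
    audiogram_pre: Audiogram
    audiogram_post: Audiogram
    profiles: dict = field(default_factory=dict)

    @property
    def pre(self) -> NetworkParams:
        key = "phase2_recurrent" if "phase2_recurrent" in self.checkpoints else "phase1_feedforward"
        return self.checkpoints[key]

    @property
    def post(self) -> NetworkParams:
        return self.checkpoints["phase3_deprived"]


def deprivation_experiment(
    config: RunConfig,
    out_dir: Optional[Path] = None,
    sigma_grid: Optional[np.ndarray] = None,
) -> DeprivationResult:
    """Run the full pipeline: train, deprive, retrain and measure.

    Everything is seeded from ``config.seed``; with ``out_dir`` given, all
    checkpoints, tables and metadata are written there.
    """
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(6)]
    stim_rng, train_rng, eval_rng, sweep_rng, hall_rng, _ = rngs

    stimulus_model = make_stimulus_model(config, stim_rng)
    attenuation = make_attenuation(config)
    params0 = initial_network(config)

    schedule = default_schedule(
        attenuation,
        phase1_iters=config.phase1_iters,
        phase2_iters=config.phase2_iters,
        phase3_iters=config.phase3_iters,
        eta1=config.eta1,
        eta23=config.eta23,
        lambda_w=config.lambda_w,
        lambda_k=config.lambda_k,
        ff_norm=config.ff_norm,
        rec_norm=config.rec_norm,
        include_phase2=config.include_phase2,
    )
    checkpoints = {}
    traces = {}
    current = params0
    for phase, (ckpt, trace) in zip(
        schedule, run_schedule(schedule, params0, stimulus_model, train_rng)
    ):
        checkpoints[phase.name] = ckpt
        traces[phase.name] = trace
        current = ckpt

    pre = checkpoints.get("phase2_recurrent", checkpoints["phase1_feedforward"])
    post = checkpoints["phase3_deprived"]

    pf = preferred_frequency(post.W)
    zones = classify_zones(pf, attenuation, cutoff=config.zone_cutoff)

    baseline = steady_state(
        pre, np.zeros(config.m), check_stability=True,
        euler_dt=config.euler_dt, euler_tol=config.euler_tol,
        euler_max_steps=config.euler_max_steps,
    ).s

    eval_stimuli = stimulus_batch(stimulus_model, config.n_eval_stimuli, eval_rng)
    grid = sigma_grid
    sweep_pre = scale_sweep(
        pre, eval_stimuli,
        sigma_grid=grid if grid is not None else default_sigma_grid(
            4.0 / max(spectral_radius(pre.K), 1e-9), config.sigma_points
        ),
        dt=config.euler_dt, euler_tol=config.euler_tol,
        max_steps=config.euler_max_steps,
        rng=np.random.default_rng(sweep_rng.integers(2**31)),
    )
    sweep_post = scale_sweep(
        post, eval_stimuli,
        sigma_grid=grid if grid is not None else default_sigma_grid(
            4.0 / max(spectral_radius(post.K), 1e-9), config.sigma_points
        ),
        dt=config.euler_dt, euler_tol=config.euler_tol,
        max_steps=config.euler_max_steps,
        rng=np.random.default_rng(sweep_rng.integers(2**31)),
    )

    hallucination = hallucination_score(
        post, baseline, hall_rng,
        dt=config.euler_dt, tol=config.euler_tol,
        max_steps=config.euler_max_steps,
    )

    audiogram_pre = simulate_audiogram(
        pre, target=config.audiogram_target, tol=config.audiogram_tol,
        max_amplitude=config.audiogram_max_amplitude,
    )
    audiogram_post = simulate_audiogram(
        post, target=config.audiogram_target, tol=config.audiogram_tol,
        max_amplitude=config.audiogram_max_amplitude, attenuation=attenuation,
    )

    profiles = {}
    off, prof, cnt = aligned_row_profile(pre.K, preferred_frequency(pre.W))
    profiles["pre_all"] = (off, prof, cnt)
    for name, subset in (("deprived", zones.deprived), ("non_deprived", zones.non_deprived)):
        if subset.size:
            profiles[f"post_{name}"] = aligned_row_profile(post.K, pf, subset)

    result = DeprivationResult(
        config=config,
        stimulus_model=stimulus_model,
        attenuation=attenuation,
        checkpoints=checkpoints,
        traces=traces,
        zones=zones,
        spontaneous_baseline=baseline,
        sweep_pre=sweep_pre,
        sweep_post=sweep_post,
        hallucination=hallucination,
        audiogram_pre=audiogram_pre,
        audiogram_post=audiogram_post,
        profiles=profiles,
    )
    if out_dir is not None:
        save_result(result, Path(out_dir))
    return result


def save_result(result: DeprivationResult, out_dir: Path) -> None:
    """Write checkpoints, measure tables and metadata into a run directory."""
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, ckpt in result.checkpoints.items():
        ckpt.save(out_dir / f"{name}.npz")
    for name, trace in result.traces.items():
        trace.to_csv(out_dir / f"trace_{name}.tsv", sep="\t", index=False)
    result.sweep_pre.save_tsv(out_dir / "sweep_pre.tsv")
    result.sweep_post.save_tsv(out_dir / "sweep_post.tsv")
    result.audiogram_pre.to_dataframe().to_csv(out_dir / "audiogram_pre.tsv", sep="\t", index=False)
    result.audiogram_post.to_dataframe().to_csv(out_dir / "audiogram_post.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "neuron": np.arange(result.zones.zone.size),
            "preferred_frequency": result.zones.preferred_frequency,
            "zone": result.zones.zone,
            "spontaneous_baseline": result.spontaneous_baseline,
            "silent_activity_post": result.hallucination.activity,
        }
    ).to_csv(out_dir / "zones.tsv", sep="\t", index=False)
    for name, (off, prof, cnt) in result.profiles.items():
        pd.DataFrame({"offset": off, "mean_weight": prof, "count": cnt}).to_csv(
            out_dir / f"profile_{name}.tsv", sep="\t", index=False
        )
    meta = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in result.config.__dict__.items()
        },
        "norm_scale": result.stimulus_model.norm_scale,
        "rho_pre": spectral_radius(result.pre.K),
        "rho_post": spectral_radius(result.post.K),
        "critical_sigma_pre": result.sweep_pre.critical_sigma,
        "critical_sigma_post": result.sweep_post.critical_sigma,
        "hallucination_score": result.hallucination.score,
        "hallucination_peak_neuron": result.hallucination.peak_neuron,
        "is_hallucinating": result.hallucination.is_hallucinating,
    }
    (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=2))
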