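"""Summary figures from a finished run directory (matplotlib, headless)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _read_sweep(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def render_report(run_dir: Path, out_dir: Path) -> list[Path]:
    """Render connectivity-profile, sweep and audiogram figures."""
    run_dir, out_dir = Path(run_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    profile_paths = sorted(run_dir.glob("profile_*.tsv"))
    if profile_paths:
        fig, ax = plt.subplots(figsize=(6, 4))
        for p in profile_paths:
            prof = pd.read_csv(p, sep="\t")
            ax.plot(prof["offset"], prof["mean_weight"], label=p.stem.removeprefix("profile_"))
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("preferred-frequency offset (channels)")
        ax.set_ylabel("mean recurrent weight")
        ax.legend()
        path = out_dir / "aligned_profiles.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    sweeps = [(run_dir / f"sweep_{tag}.tsv", tag) for tag in ("pre", "post")]
    sweeps = [(p, tag) for p, tag in sweeps if p.exists()]
    if sweeps:
        fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
        labels = ["objective_noreg", "convergence_time", "popvec_magnitude", "mean_sq_correlation"]
        for ax, col in zip(axes.ravel(), labels):
            for p, tag in sweeps:
                df = _read_sweep(p)
                ax.plot(df["sigma"], df[col], label=tag)
            ax.axvline(1.0, color="gray", ls=":", lw=0.8)
            ax.set_ylabel(col)
        for ax in axes[-1]:
            ax.set_xlabel("recurrence scaling factor sigma")
        axes[0, 0].legend()
        path = out_dir / "scale_sweep.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    grams = [(run_dir / f"audiogram_{tag}.tsv", tag) for tag in ("pre", "post")]
    grams = [(p, tag) for p, tag in grams if p.exists()]
    if grams:
        fig, ax = plt.subplots(figsize=(6, 4))
        for p, tag in grams:
            df = pd.read_csv(p, sep="\t")
            ax.plot(df["channel"], df["threshold"], marker="o", label=tag)
        ax.set_xlabel("input channel (log frequency)")
        ax.set_ylabel("probe threshold amplitude")
        ax.legend()
        path = out_dir / "audiograms.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    zones_path = run_dir / "zones.tsv"
    if zones_path.exists():
        df = pd.read_csv(zones_path, sep="\t")
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(df["neuron"], df["silent_activity_post"], label="silent response (post)")
        ax.plot(df["neuron"], df["spontaneous_baseline"], "k--", label="spontaneous baseline (pre)")
        deprived = df["zone"] == "deprived"
        if deprived.any():
            lo, hi = df.loc[deprived, "neuron"].min(), df.loc[deprived, "neuron"].max()
            ax.axvspan(lo, hi, color="orange", alpha=0.15, label="deprived zone")
        ax.set_xlabel("output neuron")
        ax.set_ylabel("activity")
        ax.legend()
        path = out_dir / "hallucination.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    return written
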