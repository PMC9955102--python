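"""Summary tables and diagnostic plots for classified window tracks."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["stage_summary", "plot_track", "run_report"]


def stage_summary(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-stage-label medians of the complexity features.

    Expects a classified track frame (columns ``pe``, ``nmp_norm``,
    ``mean_icp_mmhg``, ``stage_label``).  Only labels actually present get
    a row.  Medians use the standard even/odd definition.
    """
    if frame.empty:
        raise ValueError("cannot summarize an empty track")
    g = frame.groupby("stage_label", sort=True)
    out = g.agg(
        n_windows=("pe", "size"),
        median_pe=("pe", "median"),
        median_nmp_norm=("nmp_norm", "median"),
        median_mean_icp_mmhg=("mean_icp_mmhg", "median"),
    ).reset_index()
    return out


def plot_track(frame: pd.DataFrame, outdir: str | Path, *, fmt: str = "png") -> list[Path]:
    """Write the three standard diagnostic figures; returns the file paths.

    1. window-mean ICP with PE overlaid (twin axis);
    2. window-mean ICP with normalized NMP overlaid;
    3. box plot of normalized NMP per stage label (if labels present).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = frame["t_start_s"].to_numpy()
    written: list[Path] = []

    for feat, label, fname in (
        ("pe", "permutation entropy", f"icp_vs_pe.{fmt}"),
        ("nmp_norm", "normalized NMP", f"icp_vs_nmp.{fmt}"),
    ):
        fig, ax1 = plt.subplots(figsize=(9, 4))
        ax1.plot(t, frame["mean_icp_mmhg"], color="tab:blue", lw=1.2)
        ax1.set_xlabel("time (s)")
        ax1.set_ylabel("mean ICP (mmHg)", color="tab:blue")
        ax2 = ax1.twinx()
        ax2.plot(t, frame[feat], color="tab:red", lw=1.2)
        ax2.set_ylabel(label, color="tab:red")
        ax2.set_ylim(0, 1)
        fig.tight_layout()
        path = outdir / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if "stage_label" in frame.columns:
        labels = sorted(frame["stage_label"].unique())
        data = [frame.loc[frame["stage_label"] == lab, "nmp_norm"].to_numpy() for lab in labels]
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel("normalized NMP")
        ax.set_ylim(0, 1.05)
        fig.tight_layout()
        path = outdir / f"nmp_boxplot.{fmt}"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def run_report(frame: pd.DataFrame, outdir: str | Path) -> tuple[pd.DataFrame, list[Path]]:
    """Summary CSV plus figures for a classified track; returns both."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = stage_summary(frame)
    summary.to_csv(outdir / "stage_summary.csv", index=False, float_format="%.6g")
    figures = plot_track(frame, outdir)
    return summary, figures
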