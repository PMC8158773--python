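"""Bland-Altman and error-grid figures for an evaluation report."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import AgreementReport, ErrorGridResult

__all__ = ["bland_altman_plot", "error_grid_plot", "save_report_plots"]


def bland_altman_plot(report: AgreementReport, ax=None):
    """Classic agreement plot: per-pair mean vs difference with bias and LoA."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(report.means, report.diffs, s=12, alpha=0.6, color="#2c5f8a")
    for y, style, label in (
        (report.bias, "-", f"bias {report.bias:.2f}"),
        (report.loa_low, "--", f"-1.96 SD {report.loa_low:.2f}"),
        (report.loa_high, "--", f"+1.96 SD {report.loa_high:.2f}"),
    ):
        ax.axhline(y, linestyle=style, color="crimson", linewidth=1)
        ax.annotate(label, (1.01, y), xycoords=("axes fraction", "data"),
                    fontsize=7, va="center")
    ax.set_xlabel(f"mean of methods, {report.target.upper()} (mmHg)")
    ax.set_ylabel("cuffless - cuff (mmHg)")
    ax.set_title(f"Bland-Altman, {report.target.upper()} (n={report.n})")
    return ax


def error_grid_plot(grid: ErrorGridResult, ax=None):
    """Reference (x) vs predicted (y) scatter with zone-boundary overlays."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 5.5))
    ref = np.asarray(grid.reference)
    lo = min(40.0, ref.min() * 0.5) if ref.size else 40.0
    hi = max(220.0, ref.max() * 1.6) if ref.size else 220.0
    xs = np.linspace(max(lo, 1.0), hi, 200)
    for frac in grid.fractions:
        ax.plot(xs, xs * (1 - frac), color="grey", linewidth=0.7)
        ax.plot(xs, xs * (1 + frac), color="grey", linewidth=0.7)
    ax.plot(xs, xs, color="black", linewidth=0.8)
    ax.scatter(grid.reference, grid.predicted, s=12, alpha=0.6,
               color="#2c5f8a")
    ax.set_xlabel(f"cuff {grid.target.upper()} (mmHg)")
    ax.set_ylabel(f"cuffless {grid.target.upper()} (mmHg)")
    pct = ", ".join(f"{z}: {grid.percentages[z]:.1f}%"
                    for z in ("A", "B", "C", "D", "E"))
    ax.set_title(f"Zonal error grid ({pct})", fontsize=8)
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    return ax


def save_report_plots(report, out_dir: str | Path) -> list[Path]:
    """Write Bland-Altman and error-grid PNGs for both targets."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for target in ("sbp", "dbp"):
        ax = bland_altman_plot(report.agreement[target])
        p = out_dir / f"bland_altman_{target}.png"
        ax.figure.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(p)
        ax = error_grid_plot(report.grid[target])
        p = out_dir / f"error_grid_{target}.png"
        ax.figure.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(p)
    return written
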