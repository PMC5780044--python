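"""Figure-style report rendering.

Collects artifacts from the analysis modules — kymograms, velocity traces,
state propensities, calcium rasters, burst tables and spectra, statistical
comparisons — into PNG panels plus one markdown summary listing every
parameter used.  Panels are only emitted for the artifacts present.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .calcium import GroupSummary
from .ephys import BurstEvent
from .posture import CurvatureKymogram, STATES, VelocityTrace
from .stats import ComparisonResult

__all__ = ["render_report"]


def _save(fig, outdir: Path, name: str, written: list[str]) -> None:
    path = outdir / name
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(name)


def render_report(outdir: str | Path, *,
                  kymogram: CurvatureKymogram | None = None,
                  wave_speed: float | None = None,
                  velocity: VelocityTrace | None = None,
                  propensities: dict[str, dict[str, float]] | None = None,
                  calcium: GroupSummary | None = None,
                  bursts: list[BurstEvent] | None = None,
                  spectrum: tuple[np.ndarray, np.ndarray] | None = None,
                  comparisons: list[ComparisonResult] | None = None,
                  parameters: dict | None = None) -> list[str]:
    """Render the panels available and a markdown summary.

    Returns the list of files written (relative to ``outdir``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    if kymogram is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        vmax = np.nanmax(np.abs(kymogram.values)) or 1.0
        im = ax.imshow(kymogram.values, aspect="auto", cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax,
                       extent=(kymogram.body_coords[0], kymogram.body_coords[-1],
                               kymogram.times[-1], 0))
        ax.set_xlabel("body coordinate (head=0, tail=1)")
        ax.set_ylabel("time (s)")
        title = "curvature kymogram"
        if wave_speed is not None:
            direction = "head->tail" if wave_speed > 0 else "tail->head"
            title += f"\nwave speed {wave_speed:+.3f} bodycoord/s ({direction})"
        ax.set_title(title, fontsize=9)
        fig.colorbar(im, ax=ax, label="curvature (rad/bodycoord)")
        fig.tight_layout()
        _save(fig, outdir, "kymogram.png", written)

    if velocity is not None:
        fig, ax = plt.subplots(figsize=(5, 3))
        v = velocity.values
        ax.hist(v[np.isfinite(v)], bins=40, color="steelblue")
        ax.axvline(-1, color="k", ls="--", lw=0.8)
        ax.axvline(+1, color="k", ls="--", lw=0.8)
        ax.set_xlabel("mid-point velocity (px/s, + toward head)")
        ax.set_ylabel("frames")
        fig.tight_layout()
        _save(fig, outdir, "velocity_hist.png", written)

    if propensities:
        fig, ax = plt.subplots(figsize=(5, 3))
        groups = list(propensities)
        x = np.arange(len(groups))
        width = 0.25
        for j, state in enumerate(STATES):
            vals = [propensities[g].get(state, 0.0) for g in groups]
            ax.bar(x + (j - 1) * width, vals, width, label=state)
        ax.set_xticks(x, groups)
        ax.set_ylabel("propensity (fraction of frames)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        _save(fig, outdir, "propensity.png", written)

    if calcium is not None:
        fig, ax = plt.subplots(figsize=(5, 3))
        for row, times in enumerate(calcium.raster):
            ax.vlines(times, row + 0.6, row + 1.4, color="k", lw=1)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("animal")
        ax.set_title(
            f"Ca oscillation raster: {calcium.mean_frequency:.2f} "
            f"+- {calcium.sem_frequency:.2f} events/min (n={calcium.n})",
            fontsize=9)
        fig.tight_layout()
        _save(fig, outdir, "calcium_raster.png", written)

    if bursts is not None or spectrum is not None:
        fig, axes = plt.subplots(1, 2, figsize=(8, 3))
        if bursts:
            axes[0].bar(range(len(bursts)), [b.discharge for b in bursts],
                        color="darkred")
            axes[0].set_xlabel("burst #")
            axes[0].set_ylabel("discharge (pC)")
        axes[0].set_title("rPSC bursts", fontsize=9)
        if spectrum is not None:
            f, p = spectrum
            axes[1].semilogy(f, p)
            axes[1].set_xlim(0, 20)
            axes[1].set_xlabel("frequency (Hz)")
            axes[1].set_ylabel("power (pA^2/Hz)")
            axes[1].set_title("frequency power spectrum", fontsize=9)
        fig.tight_layout()
        _save(fig, outdir, "ephys_panels.png", written)

    lines = ["# Analysis report", ""]
    if parameters:
        lines += ["## Parameters", ""]
        lines += [f"- {k}: {v}" for k, v in parameters.items()]
        lines.append("")
    if comparisons:
        lines += ["## Statistical comparisons", ""]
        for c in comparisons:
            lines.append(
                f"- {c.test}: statistic={c.statistic:.4g}, p={c.p_value:.3g} "
                f"({c.stars})")
            for (x, y), (raw, adj, stars) in c.pairwise.items():
                lines.append(f"  - {x} vs {y}: raw p={raw:.3g}, "
                             f"Bonferroni p={adj:.3g} ({stars})")
        lines.append("")
    if written:
        lines += ["## Panels", ""] + [f"- {w}" for w in written]
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
    written.append("report.md")
    return written
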