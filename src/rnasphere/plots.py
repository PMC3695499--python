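"""The five standard visualizations of sphere-RMSD profiles.

All renderers are headless (Agg backend) and are pure functions of the
profile data and a :class:`PlotStyle`: the plotted series are built by
small, separately testable helpers (``multi_model_series`` etc.), so tests
assert on numbers, never on pixels.

The five views:

* **multi-model** — per-residue RMSD at one fixed radius, one line per
  model, Y axis scaled to the worst model so curves are comparable;
* **averaged** — mean sphere RMSD as a function of radius, one line per
  model (local quality on the left, global on the right);
* **2D map** — residue × radius heat map for a single model, blue = low
  RMSD (good), red = high RMSD (bad), gaps in a neutral gray;
* **3D** — the same grid as a surface with RMSD-colored faces;
* **cutoff** — per radius, the percentage of residues at or below a fixed
  RMSD threshold, one line per model, Y axis locked to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colormaps

from .profiles import AveragedCurve, CutoffCurve, ProfileMatrix, format_residue_key

__all__ = [
    "PlotStyle",
    "multi_model_series",
    "shared_color_limits",
    "render_multi_model",
    "render_averaged",
    "render_2d_map",
    "render_3d",
    "render_cutoff",
]


@dataclass(frozen=True)
class PlotStyle:
    """Deterministic styling shared by all renderers.

    ``colormap`` must run from blue (low RMSD, good) to red (high RMSD,
    bad).  Per-model line colors are assigned from ``palette`` by the
    model's position in the sorted model-id list, so the same model set
    always gets the same colors regardless of ordering.
    """

    colormap: str = "coolwarm"
    palette: str = "tab10"
    image_format: str = "png"
    gap_color: str = "0.85"
    log_radius: bool = False
    rmsd_label: str = "RMSD (Å)"
    residue_label: str = "nucleotide (sequential order)"
    radius_label: str = "sphere radius (Å)"

    def model_color(self, model_id: str, model_ids: Sequence[str]) -> tuple:
        ordered = sorted(set(model_ids))
        palette = colormaps[self.palette]
        index = ordered.index(model_id)
        return palette(index % palette.N)


def _check_same_residue_order(profiles: Sequence[ProfileMatrix]) -> None:
    first = profiles[0].residue_order
    for p in profiles[1:]:
        if p.residue_order != first:
            raise ValueError(
                f"profiles {profiles[0].model_id!r} and {p.model_id!r} "
                "have mismatched residue order"
            )


def multi_model_series(
    profiles: Sequence[ProfileMatrix], radius: float
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Series behind the multi-model plot: x positions and one y per model.

    x is 1-based sequential residue position; gaps stay NaN, which
    matplotlib renders as line breaks.
    """
    if not profiles:
        raise ValueError("no profiles given")
    _check_same_residue_order(profiles)
    x = np.arange(1, profiles[0].n_residues + 1)
    series = {p.model_id: p.column(radius).copy() for p in profiles}
    return x, series


def shared_color_limits(profiles: Sequence[ProfileMatrix]) -> tuple[float, float]:
    """Common (vmin, vmax) across a compared model set: data min and max."""
    finite = np.concatenate([p.values[~np.isnan(p.values)].ravel() for p in profiles])
    if finite.size == 0:
        return (0.0, 1.0)
    vmin = float(finite.min())
    vmax = float(finite.max())
    if vmax == vmin:
        vmax = vmin + 1e-9
    return vmin, vmax


def _save(fig, path: str | Path, style: PlotStyle) -> None:
    fig.savefig(Path(path), format=style.image_format, dpi=110)
    plt.close(fig)


def render_multi_model(
    profiles: Sequence[ProfileMatrix],
    radius: float,
    style: PlotStyle,
    path: str | Path,
) -> None:
    """Per-residue RMSD at one radius, one line per model.

    The Y axis is scaled to the worst (highest-RMSD) model so that all
    curves share one frame of reference.
    """
    x, series = multi_model_series(profiles, radius)
    model_ids = list(series)
    fig, ax = plt.subplots(figsize=(8, 4))
    worst = 0.0
    for model_id, y in series.items():
        ax.plot(x, y, label=model_id, color=style.model_color(model_id, model_ids))
        finite = y[~np.isnan(y)]
        if finite.size:
            worst = max(worst, float(finite.max()))
    ax.set_xlabel(style.residue_label)
    ax.set_ylabel(style.rmsd_label)
    ax.set_title(f"sphere radius {radius:g} Å")
    ax.set_ylim(0, worst * 1.05 if worst > 0 else 1.0)
    ax.legend(fontsize="small")
    fig.tight_layout()
    _save(fig, path, style)


def render_averaged(
    curves: Sequence[AveragedCurve], style: PlotStyle, path: str | Path
) -> None:
    """Mean sphere RMSD versus radius, one line per model."""
    if not curves:
        raise ValueError("no averaged curves given")
    model_ids = [c.model_id for c in curves]
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.plot(
            list(curve.radii),
            curve.mean_rmsd,
            marker="o",
            label=curve.model_id,
            color=style.model_color(curve.model_id, model_ids),
        )
    if style.log_radius:
        ax.set_xscale("log")
    ax.set_xlabel(style.radius_label)
    ax.set_ylabel(f"mean {style.rmsd_label}")
    ax.legend(fontsize="small")
    fig.tight_layout()
    _save(fig, path, style)


def render_2d_map(
    profile: ProfileMatrix,
    style: PlotStyle,
    path: str | Path,
    vmin: float | None = None,
    vmax: float | None = None,
) -> None:
    """Residue × radius heat map for one model, blue = good to red = bad.

    Pass ``vmin``/``vmax`` from :func:`shared_color_limits` to put several
    models on one color scale.  Radius rows are drawn as uniform-height
    bands (the vector need not be evenly spaced); gaps use a neutral color.
    """
    data = np.ma.masked_invalid(profile.values.T)  # radius rows, residue columns
    if vmin is None or vmax is None:
        auto_min, auto_max = shared_color_limits([profile])
        vmin = auto_min if vmin is None else vmin
        vmax = auto_max if vmax is None else vmax
    cmap = plt.get_cmap(style.colormap).copy()
    cmap.set_bad(style.gap_color)
    fig, ax = plt.subplots(figsize=(8, 3.2))
    mesh = ax.pcolormesh(
        np.arange(0.5, profile.n_residues + 0.5 + 1),
        np.arange(len(profile.radii) + 1),
        data,
        cmap=cmap,
        vmin=vmin,
        vmax=vmax,
    )
    ax.set_xlabel(style.residue_label)
    ax.set_ylabel(style.radius_label)
    ax.set_yticks(np.arange(len(profile.radii)) + 0.5)
    ax.set_yticklabels([f"{r:g}" for r in profile.radii])
    ax.set_title(profile.model_id)
    fig.colorbar(mesh, ax=ax, label=style.rmsd_label)
    fig.tight_layout()
    _save(fig, path, style)


def render_3d(
    profile: ProfileMatrix,
    style: PlotStyle,
    path: str | Path,
    vmin: float | None = None,
    vmax: float | None = None,
) -> None:
    """The profile grid as a 3D surface with RMSD-colored faces."""
    if vmin is None or vmax is None:
        auto_min, auto_max = shared_color_limits([profile])
        vmin = auto_min if vmin is None else vmin
        vmax = auto_max if vmax is None else vmax
    cmap = plt.get_cmap(style.colormap)
    x = np.arange(1, profile.n_residues + 1)
    y = np.arange(len(profile.radii))
    xx, yy = np.meshgrid(x, y)
    zz = np.ma.masked_invalid(profile.values.T)
    span = max(vmax - vmin, 1e-12)
    normalized = np.clip((zz - vmin) / span, 0.0, 1.0)
    face_colors = cmap(normalized.filled(0.0))
    face_colors[normalized.mask] = matplotlib.colors.to_rgba(style.gap_color)
    fig = plt.figure(figsize=(7, 5))
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(
        xx,
        yy,
        zz.filled(0.0),
        facecolors=face_colors,
        rstride=1,
        cstride=1,
        shade=False,
    )
    ax.set_xlabel(style.residue_label)
    ax.set_ylabel(style.radius_label)
    ax.set_zlabel(style.rmsd_label)
    ax.set_yticks(y)
    ax.set_yticklabels([f"{r:g}" for r in profile.radii])
    ax.set_title(profile.model_id)
    _save(fig, path, style)


def render_cutoff(
    curves: Sequence[CutoffCurve], style: PlotStyle, path: str | Path
) -> None:
    """Percentage of residues at or below the threshold versus radius.

    All curves must carry the same threshold; mixing thresholds in one
    frame would make the lines incomparable, so it is an error.
    """
    if not curves:
        raise ValueError("no cutoff curves given")
    thresholds = {c.threshold for c in curves}
    if len(thresholds) > 1:
        raise ValueError(f"curves mix cutoff thresholds: {sorted(thresholds)}")
    threshold = curves[0].threshold
    model_ids = [c.model_id for c in curves]
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.plot(
            list(curve.radii),
            curve.percent_below,
            marker="o",
            label=curve.model_id,
            color=style.model_color(curve.model_id, model_ids),
        )
    if style.log_radius:
        ax.set_xscale("log")
    ax.set_ylim(0, 100)
    ax.set_xlabel(style.radius_label)
    ax.set_ylabel(f"nucleotides with RMSD ≤ {threshold:g} Å (%)")
    ax.set_title(f"cutoff threshold {threshold:g} Å")
    ax.legend(fontsize="small")
    fig.tight_layout()
    _save(fig, path, style)
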