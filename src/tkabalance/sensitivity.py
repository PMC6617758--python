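"""One-at-a-time sensitivity sweeps of the surgical variables.

Each surgical parameter is swept over its planning grid while all
others stay at the neutral plan (angles zero, 3 deg posterior slope),
crossed with the gap grid.  For every (value, gap) cell the components
are re-placed, the ligament elongation is traced over every gait cycle,
and only the peak strain is kept — the conservative summary for
soft-tissue safety.  Results are rendered as heat maps on a diverging
colour scale clamped at +/-10% strain (the assumed threshold for
irreversible ligament damage): dark aquamarine at or below -10%
(slack), white at zero strain, dark red at or above +10%; raw unclamped
strains are always retained alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, TkaError
from .knee_model import LowerLimbModel
from .ligament import ElongationTrace, elongation_trace
from .surgery import compute_cut_planes, neutral_params, place_components

__all__ = ["SweepGrid", "HeatMap", "peak_elongation", "run_sweep",
           "render_heatmap", "DEFAULT_GRIDS"]

log = logging.getLogger(__name__)

CLAMP = 0.10
DEFAULT_GAPS = tuple(np.arange(18.0, 29.0, 2.0))        # 18..28 step 2 mm
DEFAULT_GRIDS = {
    "vv_femur": tuple(np.arange(-3.0, 4.0, 1.0)),       # -3..3 step 1 deg
    "vv_tibia": tuple(np.arange(-3.0, 4.0, 1.0)),
    "ext_rot_femur": tuple(np.arange(0.0, 7.0, 1.0)),   # 0..6 step 1 deg
    "post_slope": tuple(np.arange(3.0, 6.0, 1.0)),      # 3..5 step 1 deg
}


@dataclass(frozen=True)
class SweepGrid:
    """Value grid for one surgical parameter, crossed with the gap grid."""

    parameter: str
    values: tuple = None
    gaps: tuple = DEFAULT_GAPS

    def __post_init__(self):
        if self.parameter not in DEFAULT_GRIDS:
            raise ParameterError(
                f"unknown sweep parameter {self.parameter!r}; "
                f"choose from {sorted(DEFAULT_GRIDS)}")
        if self.values is None:
            object.__setattr__(self, "values", DEFAULT_GRIDS[self.parameter])
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        object.__setattr__(self, "gaps", tuple(float(g) for g in self.gaps))


@dataclass(frozen=True)
class HeatMap:
    """Peak-strain matrix over (parameter value x gap).

    ``raw`` keeps the unclamped strains (NaN for failed cells); the
    ``clamped`` property applies the rendering bounds.
    """

    parameter: str
    ligament: str
    values: tuple              # row labels (deg or mm)
    gaps: tuple                # column labels (mm)
    raw: np.ndarray            # (len(values), len(gaps))
    aggregation: str = "max"
    cell_params: tuple = ()    # per-cell SurgicalParams dicts (row-major)
    clamp_bounds: tuple = (-CLAMP, CLAMP)

    def __post_init__(self):
        raw = np.asarray(self.raw, dtype=float)
        if raw.shape != (len(self.values), len(self.gaps)):
            raise ParameterError("heat-map shape mismatch")
        object.__setattr__(self, "raw", raw)

    @property
    def clamped(self) -> np.ndarray:
        lo, hi = self.clamp_bounds
        return np.clip(self.raw, lo, hi)

    @property
    def n_cells(self) -> int:
        return self.raw.size


def peak_elongation(trace: ElongationTrace) -> float:
    """Peak strain over the cycle — the per-configuration summary."""
    return float(np.max(trace.strain))


def run_sweep(model: LowerLimbModel, trials, grid: SweepGrid,
              ligament: str = "MCL", aggregation: str = "max") -> HeatMap:
    """Sweep one surgical parameter against the gap grid.

    For each cell the components are placed with the swept value (all
    other parameters neutral), the elongation of ``ligament`` is traced
    over every trial, and the per-trial peaks are aggregated with
    ``max`` (worst case, default) or ``mean``.  A placement failure
    leaves the cell NaN and the sweep continues.
    """
    if ligament not in model.ligaments:
        raise ParameterError(f"model has no ligament {ligament!r}")
    if aggregation not in ("max", "mean"):
        raise ParameterError("aggregation must be 'max' or 'mean'")
    agg = np.max if aggregation == "max" else np.mean
    neutral = neutral_params(model.anatomy)
    lig = model.ligaments[ligament]
    raw = np.full((len(grid.values), len(grid.gaps)), np.nan)
    cell_params = []
    for i, value in enumerate(grid.values):
        for j, gap in enumerate(grid.gaps):
            params = neutral.replace(**{grid.parameter: value, "gap": gap})
            cell_params.append(params.to_dict())
            try:
                cuts = compute_cut_planes(params, model)
                postop = place_components(cuts, params, model)
                peaks = [peak_elongation(elongation_trace(postop, tr, lig,
                                                          params.to_dict()))
                         for tr in trials]
                raw[i, j] = float(agg(peaks))
            except TkaError as exc:            # pragma: no cover - defensive
                log.warning("cell (%s=%s, gap=%s) failed: %s",
                            grid.parameter, value, gap, exc)
    return HeatMap(parameter=grid.parameter, ligament=ligament,
                   values=grid.values, gaps=grid.gaps, raw=raw,
                   aggregation=aggregation, cell_params=tuple(cell_params))


def render_heatmap(heatmap: HeatMap, out_path) -> dict:
    """Write ``<out>.png`` (clamped diverging render) and ``<out>.csv``
    (raw strains).  Returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, TwoSlopeNorm
    import pandas as pd

    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    csv_path = out.with_suffix(".csv")
    png_path = out.with_suffix(".png")

    df = pd.DataFrame(heatmap.raw, index=list(heatmap.values),
                      columns=list(heatmap.gaps))
    df.index.name = heatmap.parameter
    df.to_csv(csv_path)

    cmap = LinearSegmentedColormap.from_list(
        "ligament_strain", ["#1b7f79", "#ffffff", "#8b0000"])
    lo, hi = heatmap.clamp_bounds
    norm = TwoSlopeNorm(vmin=lo, vcenter=0.0, vmax=hi)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    data = np.ma.masked_invalid(heatmap.clamped)
    im = ax.imshow(data, cmap=cmap, norm=norm, aspect="auto", origin="lower")
    if np.any(~np.isfinite(heatmap.raw)):
        bad = np.argwhere(~np.isfinite(heatmap.raw))
        for i, j in bad:
            ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1, hatch="//",
                                       fill=False, edgecolor="grey"))
    ax.set_xticks(range(len(heatmap.gaps)),
                  [f"{g:g}" for g in heatmap.gaps])
    ax.set_yticks(range(len(heatmap.values)),
                  [f"{v:g}" for v in heatmap.values])
    ax.set_xlabel("gap between cut planes (mm)")
    unit = "mm" if heatmap.parameter == "gap" else "deg"
    ax.set_ylabel(f"{heatmap.parameter} ({unit})")
    ax.set_title(f"{heatmap.ligament} peak strain ({heatmap.aggregation} "
                 f"over trials)")
    fig.colorbar(im, ax=ax, label="peak strain (clamped at ±10%)")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return {"csv": str(csv_path), "png": str(png_path)}
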