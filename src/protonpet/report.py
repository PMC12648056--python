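"""Run reporting: per-line and per-clip tables, the group-comparison
table (clip vs control, shallow vs deep), BEV map images and a
machine-readable JSON summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ranges import ClipRecord, DeltaR50Map
from .stats import group_summary, independent_t_test

SIGNIFICANCE_LEVEL = 0.05  # reported, never used to gate computation


def dr50_map_to_frame(m: DeltaR50Map) -> pd.DataFrame:
    """Long-format (iu, iv, u_mm, v_mm, dr50_mm, valid) table of a map."""
    iu, iv = np.meshgrid(np.arange(m.grid.shape[0]), np.arange(m.grid.shape[1]),
                         indexing="ij")
    return pd.DataFrame({
        "iu": iu.ravel(),
        "iv": iv.ravel(),
        "u_mm": m.grid.u_anchors[iu.ravel()],
        "v_mm": m.grid.v_anchors[iv.ravel()],
        "dr50_mm": m.values.ravel(),
        "valid": m.valid.ravel(),
    })


def _fmt_cell(values: list[float]) -> str:
    if len(values) == 0:
        return ""
    g = group_summary(values)
    if g.n < 2:
        return f"{g.mean_mm:.2f} mm (n={g.n})"
    return f"{g.mean_mm:.2f} ± {g.sd_mm:.2f} mm (n={g.n})"


def _safe_p(a: list[float], b: list[float], variant: str) -> float:
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    return independent_t_test(a, b, variant=variant).p_two_sided


def group_comparison(
    clip_records: list[ClipRecord], variant: str = "pooled"
) -> tuple[pd.DataFrame, dict]:
    """Clip-vs-control / shallow-vs-deep comparison table.

    Rows are the clip ROIs and their shifted control ROIs; columns are
    the depth groups (skin depth < 2 cm vs > 2 cm); cells are
    mean +/- SD of per-clip mean dR50, with cross p values from the
    independent-samples t-test (shallow vs deep along rows, clip vs
    control along columns).
    """
    groups: dict[tuple[str, str], list[float]] = {
        (row, col): [] for row in ("clips", "control") for col in ("lt2cm", "gt2cm")
    }
    for rec in clip_records:
        if np.isfinite(rec.mean_dr50_mm):
            groups[("clips", rec.group)].append(rec.mean_dr50_mm)
        if np.isfinite(rec.control_mean_dr50_mm):
            groups[("control", rec.group)].append(rec.control_mean_dr50_mm)

    table = pd.DataFrame(
        {
            "lt2cm": [_fmt_cell(groups[("clips", "lt2cm")]),
                      _fmt_cell(groups[("control", "lt2cm")])],
            "gt2cm": [_fmt_cell(groups[("clips", "gt2cm")]),
                      _fmt_cell(groups[("control", "gt2cm")])],
        },
        index=["Clips", "Control"],
    )
    p_row = {
        "clips_lt_vs_gt": _safe_p(groups[("clips", "lt2cm")],
                                  groups[("clips", "gt2cm")], variant),
        "control_lt_vs_gt": _safe_p(groups[("control", "lt2cm")],
                                    groups[("control", "gt2cm")], variant),
        "lt2cm_clips_vs_control": _safe_p(groups[("clips", "lt2cm")],
                                          groups[("control", "lt2cm")], variant),
        "gt2cm_clips_vs_control": _safe_p(groups[("clips", "gt2cm")],
                                          groups[("control", "gt2cm")], variant),
    }
    stats = {}
    for (row, col), vals in groups.items():
        if vals:
            g = group_summary(vals)
            stats[f"{row}_{col}"] = {"n": g.n, "mean_mm": g.mean_mm, "sd_mm": g.sd_mm}
    return table, {"groups": stats, "p_values": p_row, "t_variant": variant,
                   "significance_level": SIGNIFICANCE_LEVEL}


def plot_dr50_map(m: DeltaR50Map, path: Path,
                  clip_footprint: np.ndarray | None = None) -> None:
    """Render a BEV dR50 map to PNG, optionally outlining a clip
    footprint (the BEV projection of the Ti-clip ROI)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = np.where(m.valid, m.values, np.nan)
    extent = [m.grid.v_anchors[0], m.grid.v_anchors[-1],
              m.grid.u_anchors[-1], m.grid.u_anchors[0]]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(shown, extent=extent, cmap="RdBu_r", aspect="equal")
    fig.colorbar(im, ax=ax, label=r"$\Delta R_{50}$ (mm)")
    if clip_footprint is not None and clip_footprint.any():
        ax.contour(m.grid.v_anchors, m.grid.u_anchors,
                   clip_footprint.astype(float), levels=[0.5], colors="red")
    ax.set_xlabel("v (mm)")
    ax.set_ylabel("u (mm)")
    ax.set_title("BEV range-difference map")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def build_report(
    out_dir,
    line_table: pd.DataFrame | None = None,
    clip_records: list[ClipRecord] | None = None,
    dr50_map: DeltaR50Map | None = None,
    clip_footprint: np.ndarray | None = None,
    config: dict | None = None,
    t_variant: str = "pooled",
    make_png: bool = True,
) -> dict:
    """Assemble a run report directory and return the JSON summary.

    Writes per-line and per-clip CSVs, the group-comparison table, a
    BEV map CSV (+ PNG with the clip-footprint outline) and
    ``summary.json``. Re-running on identical inputs produces a
    byte-identical JSON summary. With zero clips the summary notes the
    fact and emits no group statistics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"n_clips": 0}
    if config is not None:
        summary["config"] = config

    if line_table is not None:
        line_table.to_csv(out / "lines.csv", index=False)
    if dr50_map is not None:
        dr50_map_to_frame(dr50_map).to_csv(out / "dr50_map.csv", index=False)
        summary["field"] = {
            "n_valid_lines": dr50_map.n_valid,
            "mean_dr50_mm": dr50_map.mean_mm,
            "sd_dr50_mm": dr50_map.sd_mm,
        }
        if make_png:
            plot_dr50_map(dr50_map, out / "dr50_map.png", clip_footprint)

    if clip_records:
        summary["n_clips"] = len(clip_records)
        rows = [
            {
                "clip_id": r.clip_id,
                "centroid_x_mm": r.centroid_mm[0],
                "centroid_y_mm": r.centroid_mm[1],
                "centroid_z_mm": r.centroid_mm[2],
                "skin_depth_mm": r.skin_depth_mm,
                "group": r.group,
                "mean_dr50_mm": r.mean_dr50_mm,
                "control_mean_dr50_mm": r.control_mean_dr50_mm,
                "n_lines": r.n_lines,
                "n_control_lines": r.n_control_lines,
            }
            for r in clip_records
        ]
        pd.DataFrame(rows).to_csv(out / "clips.csv", index=False)
        table, comparison = group_comparison(clip_records, variant=t_variant)
        table.to_csv(out / "group_table.csv")
        summary["comparison"] = comparison
    else:
        summary["note"] = "zero clips; no group statistics emitted"

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return summary
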