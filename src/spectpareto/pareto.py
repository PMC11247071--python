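"""Pareto fronts of bias versus precision.

A setting is Pareto optimal when no other setting achieves both a lower (or
equal) absolute mean relative error and a lower (or equal) CV with at least
one strictly lower.  Points with identical coordinates share front
membership.  Fronts are computed separately per VOI and total acquisition
time, pooling all projection counts and reconstruction schemes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quantify import QuantRecord

__all__ = ["pareto_front", "records_to_frame", "flag_fronts", "front_composition", "plot_fronts"]


def pareto_front(points) -> np.ndarray:
    """Boolean front flags for (error, CV) points, minimizing both.

    Implemented by a lexicographic sort and sweep; duplicates of a front
    point are all on the front.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.zeros(0, dtype=bool)
    if pts.ndim != 2 or pts.shape[1] != 2 or not np.all(np.isfinite(pts)):
        raise ValueError("points must be a finite (n, 2) array")
    n = pts.shape[0]
    order = np.lexsort((pts[:, 1], pts[:, 0]))  # by error, then CV
    flags = np.zeros(n, dtype=bool)
    best_cv = np.inf
    i = 0
    while i < n:
        # group of equal error values
        j = i
        e = pts[order[i], 0]
        while j < n and pts[order[j], 0] == e:
            j += 1
        group = order[i:j]
        cv_min = pts[group, 1].min()
        if cv_min < best_cv:
            flags[group[pts[group, 1] == cv_min]] = True
            best_cv = cv_min
        i = j
    return flags


def records_to_frame(records: list[QuantRecord]) -> pd.DataFrame:
    """Tabulate QuantRecords (one row per record)."""
    rows = []
    for r in records:
        rows.append(
            {
                "phantom": r.phantom,
                "voi": r.voi,
                "num_projections": r.num_projections,
                "total_time_min": r.total_time_min,
                "num_subsets": r.num_subsets,
                "num_iterations": r.num_iterations,
                "updates": r.updates,
                "c_est_mean": r.c_est_mean,
                "c_est_sd": r.c_est_sd,
                "c_ref": r.c_ref,
                "n_realizations": r.n_realizations,
                "cv": r.cv,
                "abs_mean_rel_error": r.abs_mean_rel_error,
                "valid": r.valid,
                "median_zero": r.median_zero,
                "n_outliers": r.n_outliers,
            }
        )
    return pd.DataFrame(rows)


def flag_fronts(frame: pd.DataFrame) -> pd.DataFrame:
    """Append an ``on_front`` column, per (phantom, voi, total_time_min) group."""
    frame = frame.copy()
    frame["on_front"] = False
    usable = frame["valid"] & np.isfinite(frame["cv"]) & np.isfinite(frame["abs_mean_rel_error"])
    for _, idx in frame[usable].groupby(
        ["phantom", "voi", "total_time_min"], sort=False
    ).groups.items():
        pts = frame.loc[idx, ["abs_mean_rel_error", "cv"]].to_numpy()
        frame.loc[idx, "on_front"] = pareto_front(pts)
    return frame


def front_composition(frame: pd.DataFrame) -> pd.DataFrame:
    """Summarize each Pareto front: update range and extreme-point subsets.

    One row per (phantom, voi, total_time_min): min/max updates on the front,
    the subset count at the lowest-CV and lowest-error front points, and the
    projection counts represented.
    """
    rows = []
    front = frame[frame["on_front"]]
    for (phantom, voi, t), g in front.groupby(["phantom", "voi", "total_time_min"], sort=False):
        low_cv = g.loc[g["cv"].idxmin()]
        low_err = g.loc[g["abs_mean_rel_error"].idxmin()]
        rows.append(
            {
                "phantom": phantom,
                "voi": voi,
                "total_time_min": t,
                "n_front": len(g),
                "min_updates": int(g["updates"].min()),
                "max_updates": int(g["updates"].max()),
                "subsets_at_low_cv": int(low_cv["num_subsets"]),
                "subsets_at_low_error": int(low_err["num_subsets"]),
                "projection_counts": sorted(g["num_projections"].unique().tolist()),
            }
        )
    return pd.DataFrame(rows)


def plot_fronts(
    frame: pd.DataFrame,
    out_path,
    cap_error_percent: float | None = None,
    title: str | None = None,
):
    """Scatter of CV vs error per (voi, time); front points coloured by subsets.

    Points above ``cap_error_percent`` are hidden from the axes (never removed
    from the table). Writes one figure file and returns its path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(frame.groupby(["voi", "total_time_min"], sort=True))
    n = max(len(groups), 1)
    ncol = min(3, n)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(5 * ncol, 4 * nrow), squeeze=False)
    markers = ["o", "^", "s", "P", "D", "p", "X"]
    for ax in axes.ravel()[len(groups):]:
        ax.set_visible(False)
    for ax, ((voi, t), g) in zip(axes.ravel(), groups):
        off = g[~g["on_front"]]
        ax.scatter(
            100 * off["abs_mean_rel_error"], 100 * off["cv"],
            marker="*", c="0.6", s=12, label="_dominated",
        )
        on = g[g["on_front"]]
        proj_counts = sorted(frame["num_projections"].unique())
        for k, npr in enumerate(proj_counts):
            sel = on[on["num_projections"] == npr]
            if len(sel) == 0:
                continue
            sc = ax.scatter(
                100 * sel["abs_mean_rel_error"], 100 * sel["cv"],
                c=sel["num_subsets"], cmap="viridis",
                vmin=frame["num_subsets"].min(), vmax=frame["num_subsets"].max(),
                marker=markers[k % len(markers)], s=36,
                label=f"{npr} proj.",
            )
        if cap_error_percent is not None:
            ax.set_xlim(0, cap_error_percent)
        ax.set_xlabel("absolute mean relative error (%)")
        ax.set_ylabel("CV (%)")
        ax.set_title(f"{voi}, {t:g} min")
        ax.legend(fontsize=7)
    if len(groups) and "sc" in locals():
        fig.colorbar(sc, ax=axes.ravel().tolist(), label="subsets", shrink=0.8)
    if title:
        fig.suptitle(title)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
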