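"""Group-level statistics, plots, and the output bundle.

Treatment groups are compared with the Kruskal–Wallis H-test (rank
based, no normality assumption), significant at p < alpha (default
0.05). Pairwise treatment-versus-control comparisons are reported
unadjusted, with a clearly labelled Bonferroni column alongside for
users who prefer a multiplicity correction.

Plot rendering is side-effect only: every number that appears in a
plot also exists in a table, so downstream consumers never need to
parse images.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from . import behavior
from .arenas import ArenaLayout, TrajectorySet, save_trajectories
from .config_io import RunConfig, write_config

__all__ = ["kruskal_wallis", "compare_groups", "analyze", "render_outputs", "GroupComparison"]


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal–Wallis H and p over two or more samples.

    H is computed on mid-ranks with tie correction; p comes from the
    chi-square distribution with k-1 degrees of freedom. The degenerate
    case where every value is identical across all groups carries no
    rank information and is reported as (0, 1).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 values")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


@dataclass
class GroupComparison:
    """Result of one rank-based comparison."""

    statistic_name: str
    groups: dict[str, np.ndarray]
    H: float
    p: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def per_fly_mean_distance(distances: pd.DataFrame) -> pd.Series:
    """Per-fly summary: mean distance per bin (px), indexed by arena."""
    return distances.groupby("arena")["distance_px"].mean()


def compare_groups(
    distances: pd.DataFrame,
    group_table: pd.DataFrame,
    alpha: float = 0.05,
    control_group: str | None = None,
    statistic_name: str = "mean_distance_per_bin",
) -> tuple[GroupComparison, pd.DataFrame]:
    """Omnibus and pairwise-vs-control comparisons of locomotor activity.

    The per-fly summary is the mean distance per bin. Returns the
    omnibus result and a tidy table of all comparisons including each
    treatment against the control (default: the first group label in
    table order), with unadjusted and Bonferroni-adjusted p-values.
    """
    summary = per_fly_mean_distance(distances)
    groups: dict[str, np.ndarray] = {}
    for label, members in group_table.groupby("group", sort=False)["fly_id"]:
        vals = summary.reindex(members.astype(int)).dropna().to_numpy()
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 flies with data")
        groups[label] = vals
    h, p = kruskal_wallis(*groups.values())
    omnibus = GroupComparison(statistic_name, groups, h, p, alpha)

    labels = list(groups)
    if control_group is None:
        control_group = labels[0]
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not in group table")
    rows = [
        {
            "statistic": statistic_name,
            "comparison": "omnibus",
            "groups": "|".join(labels),
            "H": h,
            "p": p,
            "significant": p < alpha,
        }
    ]
    treatments = [g for g in labels if g != control_group]
    for t in treatments:
        ht, pt = kruskal_wallis(groups[control_group], groups[t])
        rows.append(
            {
                "statistic": statistic_name,
                "comparison": f"{t}_vs_{control_group}",
                "groups": f"{control_group}|{t}",
                "H": ht,
                "p": pt,
                "significant": pt < alpha,
            }
        )
    table = pd.DataFrame(rows)
    n_pair = max(1, len(treatments))
    table["p_bonferroni"] = np.where(
        table["comparison"] == "omnibus", table["p"], np.minimum(1.0, table["p"] * n_pair)
    )
    return omnibus, table


# ---------------------------------------------------------------------------
# full analysis + output bundle


def analyze(traj: TrajectorySet, layout: ArenaLayout, group_table: pd.DataFrame,
            config: RunConfig) -> dict:
    """Run every behavioral statistic and the group comparisons."""
    if len(group_table) == 0:
        raise ValueError("empty group table")
    distances = behavior.bin_distances(traj, config.dist_bin, config.mm_per_px)
    bouts = behavior.detect_sleep(traj, config.sleep_min_duration, config.eps_still)
    sleep = behavior.sleep_status(bouts, group_table, config.sleep_bin, traj.fps, traj.frame_count)
    angles = behavior.angle_change(traj, config.eps_still, config.angle_mode)
    angle_means = behavior.mean_angle_change(traj, config.eps_still, config.angle_mode)
    heatmaps = behavior.occupancy_heatmap(traj, layout, config.heatmap_remove_sleep, bouts)
    group_maps = behavior.group_heatmap(heatmaps, group_table)
    regional = behavior.regional_preference(traj, layout, config.region_bins)
    if group_table["group"].nunique() >= 2:
        omnibus, stats_table = compare_groups(
            distances, group_table, config.alpha, config.control_group
        )
    else:  # single-group run: nothing to compare
        omnibus = None
        stats_table = pd.DataFrame(
            columns=["statistic", "comparison", "groups", "H", "p", "significant", "p_bonferroni"]
        )
    return {
        "distances": distances,
        "bouts": bouts,
        "sleep": sleep,
        "angles": angles,
        "angle_means": angle_means,
        "heatmaps": heatmaps,
        "group_heatmaps": group_maps,
        "regional": regional,
        "omnibus": omnibus,
        "stats_table": stats_table,
    }


def _group_of(group_table: pd.DataFrame) -> dict[int, str]:
    return dict(zip(group_table["fly_id"].astype(int), group_table["group"]))


def render_outputs(
    results: dict,
    traj: TrajectorySet,
    layout: ArenaLayout,
    group_table: pd.DataFrame,
    config: RunConfig,
    out_dir: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """Write the five plot families, tables, arrays, and the config echo.

    Returns a manifest DataFrame listing every written file with a role
    tag. Rendering is deterministic for a fixed seed and rerunning into
    the same directory reproduces the identical file set.
    """
    out_dir = Path(out_dir if out_dir is not None else config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def record(path: Path, role: str) -> None:
        manifest.append({"file": str(path.relative_to(out_dir)), "role": role})

    gmap = _group_of(group_table)
    fps = traj.fps

    # -- tables -------------------------------------------------------------
    distances: pd.DataFrame = results["distances"]
    p = out_dir / "distance_per_bin.csv"
    distances.to_csv(p, index=False)
    record(p, "table")

    bout_rows = [
        {"arena": a, "start_frame": s, "end_frame": e,
         "start_s": s / fps, "duration_s": (e - s) / fps}
        for a, bouts in enumerate(results["bouts"]) for s, e in bouts
    ]
    p = out_dir / "sleep_bouts.csv"
    pd.DataFrame(bout_rows, columns=["arena", "start_frame", "end_frame", "start_s", "duration_s"]).to_csv(p, index=False)
    record(p, "table")

    p = out_dir / "sleep_status_per_bin.csv"
    results["sleep"].to_csv(p, index=False)
    record(p, "table")

    p = out_dir / "angle_change.csv"
    am = results["angle_means"].rename("mean_change_deg_per_s").rename_axis("arena").reset_index()
    am.to_csv(p, index=False)
    record(p, "table")

    p = out_dir / "regional_preference.csv"
    results["regional"].to_csv(p, index=False)
    record(p, "table")

    p = out_dir / "stats_summary.csv"
    results["stats_table"].to_csv(p, index=False)
    record(p, "table")

    # -- arrays -------------------------------------------------------------
    paths = save_trajectories(traj, out_dir)
    record(paths["npy"], "array")
    record(paths["csv"], "table")
    hm = np.stack([results["heatmaps"][a] for a in sorted(results["heatmaps"])])
    p = out_dir / "heatmaps.npy"
    np.save(p, hm)
    record(p, "array")

    # -- plots --------------------------------------------------------------
    groups_sorted = list(dict.fromkeys(group_table["group"]))

    # locomotor activity: mean distance per bin per group over time
    fig, ax = plt.subplots(figsize=(7, 4))
    d = distances.copy()
    d["group"] = d["arena"].map(gmap)
    for g in groups_sorted:
        sub = d[d["group"] == g].groupby("bin").agg(t=("start_s", "first"), m=("distance_px", "mean"))
        ax.plot(sub["t"] / 60.0, sub["m"], marker="o", label=g)
    ax.set_xlabel("time (min)")
    ax.set_ylabel(f"distance per {config.dist_bin / 60:g}-min bin (px)")
    ax.set_title("Locomotor activity")
    ax.legend()
    p = out_dir / "locomotor_activity.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    record(p, "plot")

    # sleep status
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for g in groups_sorted:
        sub = results["sleep"][results["sleep"]["group"] == g]
        axes[0].plot(sub["start_s"] / 60.0, sub["mean_sleep_s"], marker="o", label=g)
        axes[1].plot(sub["start_s"] / 60.0, sub["frac_asleep"], marker="o", label=g)
    axes[0].set_ylabel("mean sleep (s) per fly")
    axes[1].set_ylabel("fraction of flies asleep")
    for ax in axes:
        ax.set_xlabel("time (min)")
        ax.legend()
    fig.suptitle("Sleep status")
    p = out_dir / "sleep_status.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    record(p, "plot")

    # heatmaps: per-fly panel + per-group panel
    hms = results["heatmaps"]
    n = len(hms)
    ncols = min(6, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(2.2 * ncols, 2.2 * nrows), squeeze=False)
    for a in range(nrows * ncols):
        ax = axes[a // ncols][a % ncols]
        ax.axis("off")
        if a < n:
            ax.imshow(behavior.normalize_heatmap(hms[a]), cmap="jet")
            ax.set_title(f"fly {a}", fontsize=8)
    fig.suptitle("Occupancy heatmap per fly")
    p = out_dir / "heatmap_per_fly.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    record(p, "plot")

    gm = results["group_heatmaps"]
    fig, axes = plt.subplots(1, max(1, len(gm)), figsize=(3 * max(1, len(gm)), 3), squeeze=False)
    for i, g in enumerate(gm):
        axes[0][i].imshow(behavior.normalize_heatmap(gm[g]), cmap="jet")
        axes[0][i].set_title(g)
        axes[0][i].axis("off")
    fig.suptitle("Grouped occupancy heatmap")
    p = out_dir / "heatmap_grouped.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    record(p, "plot")

    # angle change per group
    fig, ax = plt.subplots(figsize=(6, 4))
    data, labels = [], []
    for g in groups_sorted:
        members = [a for a, lbl in gmap.items() if lbl == g]
        vals = results["angle_means"].reindex(members).dropna().to_numpy()
        data.append(vals if len(vals) else np.array([np.nan]))
        labels.append(g)
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("mean angle change (deg/s)")
    ax.set_title("Angle change")
    p = out_dir / "angle_change.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    record(p, "plot")

    # regional preference per group
    reg = results["regional"].copy()
    reg["group"] = reg["arena"].map(gmap)
    fig, ax = plt.subplots(figsize=(6, 4))
    k = int(reg["radial_bin"].max()) + 1
    width = 0.8 / max(1, len(groups_sorted))
    for i, g in enumerate(groups_sorted):
        sub = reg[reg["group"] == g].groupby("radial_bin")["fraction"].mean()
        ax.bar(np.arange(k) + i * width, sub.reindex(range(k)).fillna(0), width, label=g)
    ax.set_xticks(np.arange(k) + 0.4 - width / 2)
    ax.set_xticklabels([f"bin {b}" for b in range(k)])
    ax.set_xlabel("radial bin (center → rim)")
    ax.set_ylabel("occupancy fraction")
    ax.set_title("Regional preference")
    ax.legend()
    p = out_dir / "regional_preference.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    record(p, "plot")

    # -- config echo --------------------------------------------------------
    p = write_config(config, out_dir / "config_echo.yaml")
    record(p, "config")

    mdf = pd.DataFrame(manifest).sort_values(["role", "file"]).reset_index(drop=True)
    mdf.to_csv(out_dir / "manifest.csv", index=False)
    return mdf
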