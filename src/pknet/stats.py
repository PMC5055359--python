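"""Circular statistics for angle populations, one-way ANOVA, and reporting.

Angle populations (acute alpha, obtuse beta) are summarised with directional
statistics: the circular mean is the direction of the summed unit vectors and
the circular SD is sqrt(-2 ln R) of the mean resultant length R, both in
degrees.  Linear mean +/- SD is reported alongside, since published angle
summaries are often linear.  Group comparisons across stacks use a one-way
ANOVA at alpha = 0.05.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CircularStats",
    "AnovaResult",
    "circular_mean_sd",
    "circular_stats",
    "anova_oneway",
    "boxplot_stats",
    "make_report",
]


@dataclass
class CircularStats:
    """Directional summary of an angle sample (degrees)."""

    mean: float  # circular mean in [0, 360); NaN when undefined
    sd: float  # sqrt(-2 ln R) in degrees
    resultant_length: float  # R in [0, 1]
    n: int
    linear_mean: float
    linear_sd: float

    @property
    def mean_defined(self) -> bool:
        return not math.isnan(self.mean)


def circular_stats(angles_deg) -> CircularStats:
    """Circular mean/SD of angles in degrees (flagging R ~ 0 as undefined)."""
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle sample")
    if not np.all(np.isfinite(angles)):
        raise ValueError("non-finite angles")
    radians = np.radians(angles)
    resultant = np.array([np.cos(radians).mean(), np.sin(radians).mean()])
    r = float(np.linalg.norm(resultant))
    if r < 1e-12:
        mean = float("nan")  # antipodally balanced sample: direction undefined
    else:
        mean = float(np.degrees(np.arctan2(resultant[1], resultant[0]))) % 360.0
        if mean >= 360.0:  # -1e-16 % 360 rounds to 360.0
            mean = 0.0
    sd = float(np.degrees(np.sqrt(max(0.0, -2.0 * np.log(r))))) if r > 0 else float("inf")
    return CircularStats(
        mean=mean,
        sd=sd,
        resultant_length=r,
        n=int(angles.size),
        linear_mean=float(angles.mean()),
        linear_sd=float(angles.std(ddof=1)) if angles.size > 1 else 0.0,
    )


def circular_mean_sd(angles_deg) -> tuple[float, float]:
    """(circular mean, circular SD) in degrees."""
    cs = circular_stats(angles_deg)
    return cs.mean, cs.sd


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    significant: bool  # at alpha = 0.05


def anova_oneway(groups: list) -> AnovaResult:
    """One-way ANOVA over >= 2 groups of >= 2 observations each."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    f_stat, p = sps.f_oneway(*arrays)
    n_total = sum(a.size for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    # identical groups: scipy emits a degenerate-data warning and NaN; the
    # between-group sum of squares is exactly zero there, so F = 0, p = 1
    if math.isnan(f_stat):
        grand = np.concatenate(arrays).mean()
        ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
        if ssb == 0.0:
            f_stat, p = 0.0, 1.0
    return AnovaResult(
        F=float(f_stat),
        p=float(p),
        df_between=df_between,
        df_within=df_within,
        significant=bool(p < 0.05),
    )


def boxplot_stats(values) -> dict:
    """Quartiles/median/extremes matching the boxplot convention used in figures."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q25, median, q75 = np.percentile(v, [25, 50, 75])
    return {
        "q25": float(q25),
        "median": float(median),
        "q75": float(q75),
        "min": float(v.min()),
        "max": float(v.max()),
        "n": int(v.size),
    }


def make_report(stack_results: list[dict], out_dir: str | Path, plots: bool = True) -> dict:
    """Assemble per-stack CSV/JSON outputs and summary figures.

    ``stack_results`` holds one dict per stack as produced by the pipeline
    (branch stats, alpha/beta angle lists, complexity metrics, null-model
    verdicts).  Writes ``report.csv``, ``angles_alpha.csv``/``angles_beta.csv``,
    ``summary.json`` and, when ``plots`` is true, figure PNGs.  File content
    is deterministic given identical inputs.
    """
    if not stack_results:
        raise ValueError("no stacks analysed")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    alpha_rows = []
    beta_rows = []
    all_branch_lengths: list[float] = []
    for res in stack_results:
        row = {
            "stack_id": res["stack_id"],
            "n_nodes": res["metrics"]["n_nodes"],
            "n_edges": res["metrics"]["n_edges"],
            "n_branches": res["branches"]["n"],
            "branch_mean_um": res["branches"]["mean"],
            "branch_median_um": res["branches"]["median"],
            "GE": res["metrics"]["G.E"],
            "LE": res["metrics"]["L.E"],
            "CPL": res["metrics"]["C.P.Length"],
            "degree_mean": res["metrics"]["Degree.mean"],
            "assortativity": res["metrics"]["Assort"],
            "small_world": res.get("small_world", "not_computed"),
        }
        for pop, sink in (("alpha", alpha_rows), ("beta", beta_rows)):
            angles = res.get(f"angles_{pop}", [])
            for angle in angles:
                sink.append({"stack_id": res["stack_id"], "angle_deg": angle})
            if angles:
                cs = circular_stats(angles)
                row[f"{pop}_circ_mean"] = cs.mean
                row[f"{pop}_circ_sd"] = cs.sd
                row[f"{pop}_n"] = cs.n
        all_branch_lengths.extend(res.get("branch_lengths", []))
        rows.append(row)

    report = pd.DataFrame(rows)
    report.to_csv(out / "report.csv", index=False)
    pd.DataFrame(alpha_rows).to_csv(out / "angles_alpha.csv", index=False)
    pd.DataFrame(beta_rows).to_csv(out / "angles_beta.csv", index=False)

    assort = report["assortativity"].astype(float)
    summary = {
        "n_stacks": len(stack_results),
        "n_negative_assortativity": int((assort < 0).sum()),
        "n_small_world": int((report["small_world"] == "small_world").sum()),
        "n_indeterminate_small_world": int((report["small_world"] == "indeterminate").sum()),
        "alpha": _population_summary(alpha_rows),
        "beta": _population_summary(beta_rows),
    }
    if all_branch_lengths:
        lengths = np.asarray(all_branch_lengths)
        summary["branch_length"] = {
            "n": int(lengths.size),
            "mean": float(lengths.mean()),
            "median": float(np.median(lengths)),
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    if plots:
        _make_plots(out, stack_results, all_branch_lengths)
    return summary


def _population_summary(rows: list[dict]) -> dict | None:
    if not rows:
        return None
    angles = [r["angle_deg"] for r in rows]
    cs = circular_stats(angles)
    return {**asdict(cs), **{"box": boxplot_stats(angles)}}


def _make_plots(out: Path, stack_results: list[dict], branch_lengths: list[float]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if branch_lengths:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        upper = max(300.0, float(np.ceil(max(branch_lengths) / 25.0) * 25.0))
        ax.hist(branch_lengths, bins=np.arange(0, upper + 12.5, 25.0), color="tab:blue")
        ax.set_xlabel("branch length (um)")
        ax.set_ylabel("count")
        fig.tight_layout()
        fig.savefig(out / "branch_length_hist.png", dpi=120)
        plt.close(fig)

    for pop in ("alpha", "beta"):
        data = [res.get(f"angles_{pop}", []) for res in stack_results]
        labels = [res["stack_id"] for res in stack_results]
        keep = [(d, l) for d, l in zip(data, labels) if d]
        if not keep:
            continue
        fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(keep)), 3.2))
        ax.boxplot([d for d, _ in keep], tick_labels=[l for _, l in keep], whis=(0, 100))
        ax.set_ylabel(f"{pop} angle (deg)")
        ax.tick_params(axis="x", rotation=90)
        fig.tight_layout()
        fig.savefig(out / f"angles_{pop}_boxplot.png", dpi=120)
        plt.close(fig)

    hists = [res["metrics"].get("Betweenness.hist") for res in stack_results]
    hists = [h for h in hists if h]
    if hists:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for res, h in zip(stack_results, hists):
            centres = 0.5 * (np.array(h["edges"][:-1]) + np.array(h["edges"][1:]))
            ax.plot(centres, h["counts"], alpha=0.6, label=res["stack_id"])
        ax.set_xlabel("normalised betweenness")
        ax.set_ylabel("count")
        fig.tight_layout()
        fig.savefig(out / "betweenness_hist.png", dpi=120)
        plt.close(fig)
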