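"""Group summaries and comparison procedures for biomechanical profiles.

Continuous per-worm metrics are compared across genotype groups with the
non-parametric Kruskal-Wallis omnibus test (tie-corrected) followed by Dunn's
pairwise rank test with a family-wise adjustment (Holm-Sidak by default).
Normalized curvature profiles are compared position-by-position with Welch
two-sample t tests under a Holm-Sidak step-down correction across positions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "ComparisonResult",
    "profiles_to_dataframe",
    "summarize_groups",
    "percent_change",
    "format_percent",
    "dunn_test",
    "compare_groups",
    "profile_position_tests",
    "render_report",
]

METRICS = ["length_mm", "speed_mm_s", "frequency_hz", "force_nN", "power_pW"]


@dataclass
class ComparisonResult:
    """Omnibus + pairwise post-hoc comparison of one metric across groups."""

    statistic: float
    pvalue: float
    pairwise: pd.DataFrame  # group1, group2, z, p_raw, p_adj, significant
    procedure: str
    alpha: float


def profiles_to_dataframe(profiles: Sequence) -> pd.DataFrame:
    """One row per BiomechanicalProfile (the cohort profile CSV layout)."""
    rows = []
    for p in profiles:
        rows.append({
            "worm_id": p.worm_id, "group": p.group, "stage": p.stage,
            "length_mm": p.length_mm, "speed_mm_s": p.speed_mm_s,
            "frequency_hz": p.frequency_hz, "force_nN": p.force_nN,
            "power_pW": p.power_pW, "wavelength_mm": p.wavelength_mm,
            "net_force_nN": p.net_force_nN, "drag_model": p.drag_model,
            "mu_mPa_s": p.mu_mPa_s, "flags": ";".join(p.flags),
        })
    return pd.DataFrame(rows)


def summarize_groups(profiles: pd.DataFrame, metrics: Sequence[str] = METRICS) -> pd.DataFrame:
    """Per (group, stage): n, mean and sample SD of each metric.

    Accepts a per-worm profile table (one row per accepted worm).  Groups with
    a single worm get mean = that worm's value and SD = NaN (flagged); empty
    groups present in the categorical index are listed with n = 0.
    """
    if "stage" not in profiles.columns:
        profiles = profiles.assign(stage="")
    rows = []
    for (group, stage), sub in profiles.groupby(["group", "stage"], observed=False, sort=True):
        rec = {"group": group, "stage": stage, "n": len(sub)}
        for m in metrics:
            if m not in sub.columns or len(sub) == 0:
                rec[f"{m}_mean"], rec[f"{m}_sd"] = float("nan"), float("nan")
                continue
            vals = pd.to_numeric(sub[m], errors="coerce").dropna()
            rec[f"{m}_mean"] = float(vals.mean()) if len(vals) else float("nan")
            rec[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        rows.append(rec)
    # categorical group levels with no members are listed with n = 0
    if isinstance(profiles["group"].dtype, pd.CategoricalDtype):
        seen = {r["group"] for r in rows}
        for cat in profiles["group"].cat.categories:
            if cat not in seen:
                rec = {"group": cat, "stage": "", "n": 0}
                rec.update({f"{m}_{s}": float("nan") for m in metrics for s in ("mean", "sd")})
                rows.append(rec)
    return pd.DataFrame(rows)


def percent_change(mean_early: float, mean_late: float) -> float:
    """Signed percent change 100*(late - early)/early, full precision."""
    if mean_early == 0:
        raise ValidationError("mean_early", "percent change undefined for a zero baseline")
    return 100.0 * (mean_late - mean_early) / mean_early


def format_percent(value: float) -> str:
    """Display rounding (half-up, so 62.5 -> '+63%'), isolated from storage."""
    rounded = int(math.floor(abs(value) + 0.5))
    sign = "+" if value >= 0 else "-"
    return f"{sign}{rounded}%"


def _round_half_up(value: float) -> int:
    return int(math.copysign(math.floor(abs(value) + 0.5), value))


def dunn_test(
    groups: Mapping[str, np.ndarray],
    adjust: str = "holm-sidak",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dunn's pairwise rank comparison (tie-corrected) after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tied values; two-sided normal p values with the
    requested family-wise adjustment.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start:start + len(a)].mean())
        sizes.append(len(a))
        start += len(a)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_base -= tie_term / (12.0 * (n_total - 1))
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group1": names[i], "group2": names[j], "z": z, "p_raw": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if len(table):
        with warnings.catch_warnings():
            # p_raw of exactly 1 makes the Sidak log1p term -inf; harmless
            warnings.simplefilter("ignore", RuntimeWarning)
            reject, p_adj, _, _ = multipletests(table["p_raw"], alpha=alpha, method=adjust)
        table["p_adj"] = np.maximum(p_adj, table["p_raw"])  # step-down never below raw
        table["significant"] = reject
    return table


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    procedure: str = "dunn",
    adjust: str = "holm-sidak",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Kruskal-Wallis omnibus plus Dunn's post-hoc pairwise comparisons.

    ``procedure`` accepts "dunn" and, for compatibility with mixed naming in
    the literature, "dunnett" (a parametric test incompatible with rank data),
    which is mapped to Dunn with a Sidak-family correction and a warning.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValidationError("values_by_group", "need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValidationError("values_by_group", f"group {g!r} has n < 2")
    if procedure == "dunnett":
        warnings.warn(
            "Dunnett's test is parametric and incompatible with Kruskal-Wallis; "
            "using Dunn's rank test with a Sidak-family correction instead"
        )
        procedure, adjust = "dunn", "holm-sidak"
    if procedure != "dunn":
        raise ValidationError("procedure", f"unknown post-hoc procedure {procedure!r}")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        stat, p = 0.0, 1.0
        pairwise = pd.DataFrame(
            [
                {"group1": a, "group2": b, "z": 0.0, "p_raw": 1.0, "p_adj": 1.0,
                 "significant": False}
                for i, a in enumerate(groups)
                for b in list(groups)[i + 1:]
            ]
        )
    else:
        stat, p = sps.kruskal(*groups.values())
        pairwise = dunn_test(groups, adjust=adjust, alpha=alpha)
    return ComparisonResult(statistic=float(stat), pvalue=float(p),
                            pairwise=pairwise, procedure=f"kruskal-{procedure}",
                            alpha=alpha)


def profile_position_tests(
    profiles_a: np.ndarray,
    profiles_b: np.ndarray,
    sigma: np.ndarray,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-position two-sample t tests (Welch by default) between two groups
    of normalized curvature profiles, Holm-Sidak adjusted across positions.

    ``profiles_a``/``profiles_b`` are (n_worms, n_positions) arrays on a
    common ``sigma`` grid.  Positions where both groups are constant (e.g. the
    head position, which is 1 by construction) get p = 1 when equal.
    """
    a = np.asarray(profiles_a, dtype=float)
    b = np.asarray(profiles_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValidationError("profiles", "need (n, m) arrays on a common grid")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValidationError("profiles", "each group needs n >= 2 worms")
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant positions (e.g. the head, 1 by construction) trip
        # scipy's precision-loss warning; they are resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    const = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    same = np.isclose(a.mean(axis=0), b.mean(axis=0))
    t = np.where(const, 0.0, t)
    p = np.where(const & same, 1.0, p)
    p = np.where(const & ~same, 0.0, p)
    p = np.nan_to_num(p, nan=1.0)
    with warnings.catch_warnings():
        # p = 1 at constant positions makes the Sidak log1p term -inf; the
        # adjusted value is still the correct 1.0
        warnings.simplefilter("ignore", RuntimeWarning)
        reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm-sidak")
    p_adj = np.maximum(p_adj, p)
    return pd.DataFrame({
        "sigma": np.asarray(sigma, dtype=float),
        "t": t, "p_raw": p, "p_adj": p_adj, "significant": reject,
    })


def render_report(
    outdir,
    group_table: pd.DataFrame,
    comparisons: Optional[Mapping[str, ComparisonResult]] = None,
    percent_changes: Optional[pd.DataFrame] = None,
) -> dict:
    """Write the group table, comparisons, percent changes and a text summary.

    Output is deterministic (fixed float formatting, no timestamps), so
    regenerating from identical inputs yields byte-identical files.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = outdir / "group_table.csv"
    group_table.to_csv(p, index=False, float_format="%.6g", lineterminator="\n")
    paths["group_table"] = p

    if comparisons:
        frames = []
        for metric, res in comparisons.items():
            tab = res.pairwise.copy()
            tab.insert(0, "metric", metric)
            tab["omnibus_statistic"] = res.statistic
            tab["omnibus_p"] = res.pvalue
            tab["procedure"] = res.procedure
            frames.append(tab)
        comp = pd.concat(frames, ignore_index=True)
        p = outdir / "comparisons.csv"
        comp.to_csv(p, index=False, float_format="%.6g", lineterminator="\n")
        paths["comparisons"] = p

    if percent_changes is not None and len(percent_changes):
        p = outdir / "percent_changes.csv"
        percent_changes.to_csv(p, index=False, float_format="%.6g", lineterminator="\n")
        paths["percent_changes"] = p

    lines = ["Biomechanical profile report", "=" * 28, ""]
    lines.append(group_table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    if percent_changes is not None and len(percent_changes):
        lines += ["", "Stage-to-stage percent changes (group means):"]
        for _, row in percent_changes.iterrows():
            lines.append(
                f"  {row['group']:<16} {row['metric']:<14} {format_percent(row['percent'])}"
            )
    lines.append("")
    p = outdir / "report.txt"
    p.write_text("\n".join(lines))
    paths["report"] = p
    return paths
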