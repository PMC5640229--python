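"""Significance fingerprints: per-parameter tests across networks and the
heat-map matrix.

Because every value is first normalized within its own network (native =
100%), the paired comparison of a treated episode against native reduces
algebraically to a one-sample t-test of the normalized values against 100.
Cells are colored on the t-test alone at tiers 0.05 / 0.01 / 0.001; a
repeated-measures ANOVA across concentrations is reported per parameter as
an omnibus companion but never gates the cells. No multiple-testing
correction is applied; output metadata says so.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import AnalysisConfig
from .parameters import registry

log = logging.getLogger(__name__)

__all__ = [
    "HeatMapCell",
    "paired_vs_native",
    "unpaired_compare",
    "anova_across_concentrations",
    "build_heatmap",
    "render_heatmap",
]

TIERS = (0.05, 0.01, 0.001)


def significance_tier(p: float, tiers: tuple[float, ...] = TIERS) -> str:
    """'none', '0.05', '0.01' or '0.001' (strictest tier containing p)."""
    if np.isnan(p):
        return "none"
    tier = "none"
    for a in sorted(tiers, reverse=True):
        if p <= a:
            tier = f"{a:g}"
    return tier


@dataclass(frozen=True)
class HeatMapCell:
    parameter: str
    concentration: float  # molar
    mean_pct: float
    n: int
    t_stat: float
    p_value: float
    tier: str  # "none" | "0.05" | "0.01" | "0.001"

    @property
    def effect_size_color(self) -> float:
        """Signed % change from native, defined only for significant cells."""
        return self.mean_pct - 100.0 if self.tier != "none" else float("nan")


def _cell_values(matrix: pd.DataFrame, parameter: str, concentration: float) -> np.ndarray:
    sel = matrix[
        (matrix["parameter_name"] == parameter)
        & (matrix["concentration_M"] == concentration)
    ]
    return sel["normalized_pct"].dropna().to_numpy(float)


def paired_vs_native(
    matrix: pd.DataFrame, parameter: str, concentration: float
) -> HeatMapCell:
    """Paired test of one parameter at one concentration against native.

    One-sample two-sided t of normalized values against 100 (the exact
    paired t after within-network normalization). Zero-variance zero-effect
    data gets p = 1 by convention; n < 2 yields an untestable 'none' cell.
    """
    x = _cell_values(matrix, parameter, concentration)
    n = x.size
    if n < 2:
        return HeatMapCell(parameter, concentration,
                           float(np.mean(x)) if n else float("nan"),
                           n, float("nan"), float("nan"), "none")
    if np.allclose(x, 100.0):
        return HeatMapCell(parameter, concentration, float(np.mean(x)), n, 0.0, 1.0, "none")
    t, p = sps.ttest_1samp(x, 100.0)
    return HeatMapCell(
        parameter, concentration, float(np.mean(x)), n, float(t), float(p),
        significance_tier(float(p)),
    )


def unpaired_compare(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    parameter: str,
    concentration: float,
) -> dict:
    """Welch two-sample t between two compounds' normalized values at one
    concentration. Groups with n < 2 are flagged untestable."""
    a = _cell_values(matrix_a, parameter, concentration)
    b = _cell_values(matrix_b, parameter, concentration)
    if a.size < 2 or b.size < 2:
        return {
            "parameter": parameter, "concentration": concentration,
            "n_a": int(a.size), "n_b": int(b.size),
            "t_stat": float("nan"), "p_value": float("nan"),
            "tier": "none", "testable": False,
        }
    if np.array_equal(np.sort(a), np.sort(b)) and np.std(a) == 0:
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return {
        "parameter": parameter, "concentration": concentration,
        "n_a": int(a.size), "n_b": int(b.size),
        "t_stat": float(t), "p_value": float(p),
        "tier": significance_tier(float(p)), "testable": True,
    }


def anova_across_concentrations(matrix: pd.DataFrame, parameter: str) -> float:
    """Omnibus one-way repeated-measures ANOVA p across all episodes
    (networks as subjects). NaN when the design is unbalanced or degenerate."""
    sel = matrix[matrix["parameter_name"] == parameter][
        ["network_id", "concentration_M", "normalized_pct"]
    ].dropna()
    if sel["concentration_M"].nunique() < 2 or sel["network_id"].nunique() < 2:
        return float("nan")
    counts = sel.groupby("network_id")["concentration_M"].nunique()
    complete = counts[counts == sel["concentration_M"].nunique()].index
    sel = sel[sel["network_id"].isin(complete)]
    if sel["network_id"].nunique() < 2:
        return float("nan")
    try:
        from statsmodels.stats.anova import AnovaRM

        res = AnovaRM(
            sel, depvar="normalized_pct", subject="network_id",
            within=["concentration_M"],
        ).fit()
        return float(res.anova_table["Pr > F"].iloc[0])
    except Exception as exc:  # unbalanced / singular designs
        log.debug("ANOVA failed for %s: %s", parameter, exc)
        return float("nan")


def build_heatmap(
    matrix: pd.DataFrame,
    compound: str | None = None,
    cfg: AnalysisConfig | None = None,
    with_anova: bool = True,
) -> pd.DataFrame:
    """Significance heat map over the 40 registry parameters x applied
    concentrations.

    One row per (parameter, nonzero concentration) with the normalized mean,
    n, t, p and tier; ``color_value`` is the signed % change and is NaN for
    non-significant cells (they stay uncolored). The frame's ``attrs`` note
    that no multiple-testing correction is applied.
    """
    if compound is not None:
        matrix = matrix[matrix["compound"].isin([compound, "native"])]
    concs = sorted(c for c in matrix["concentration_M"].unique() if c > 0)
    rows = []
    for desc in registry():
        anova_p = (
            anova_across_concentrations(matrix, desc.name) if (with_anova and concs) else float("nan")
        )
        for c in concs:
            cell = paired_vs_native(matrix, desc.name, c)
            rows.append(
                {
                    "parameter": desc.name,
                    "category": desc.category,
                    "concentration_M": c,
                    "mean_pct": cell.mean_pct,
                    "n": cell.n,
                    "t": cell.t_stat,
                    "p": cell.p_value,
                    "tier": cell.tier,
                    "anova_p": anova_p,
                    "color_value": cell.effect_size_color,
                }
            )
    hm = pd.DataFrame(
        rows,
        columns=[
            "parameter", "category", "concentration_M", "mean_pct",
            "n", "t", "p", "tier", "anova_p", "color_value",
        ],
    )
    hm.attrs["multiple_testing_correction"] = "none"
    return hm


def render_heatmap(heatmap: pd.DataFrame, path: str) -> None:
    """Render a heat map TSV as a PNG: diverging scale centered at 100%,
    non-significant cells left blank."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = heatmap.pivot(index="parameter", columns="concentration_M", values="color_value")
    order = [d.name for d in registry() if d.name in set(pivot.index)]
    pivot = pivot.loc[order]
    data = np.ma.masked_invalid(pivot.to_numpy(float))
    vmax = max(np.nanmax(np.abs(pivot.to_numpy(float))), 1.0) if np.isfinite(
        pivot.to_numpy(float)
    ).any() else 100.0
    fig, ax = plt.subplots(figsize=(1.2 + 0.5 * pivot.shape[1], 0.25 * pivot.shape[0] + 1.5))
    mesh = ax.pcolormesh(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(np.arange(pivot.shape[1]) + 0.5)
    ax.set_xticklabels([f"{c:.3g}" for c in pivot.columns], rotation=90, fontsize=7)
    ax.set_yticks(np.arange(pivot.shape[0]) + 0.5)
    ax.set_yticklabels(pivot.index, fontsize=6)
    ax.set_xlabel("concentration (M)")
    ax.invert_yaxis()
    fig.colorbar(mesh, ax=ax, label="change vs native (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
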