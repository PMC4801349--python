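"""Figures and tables summarising inequality–productivity analyses.

Static matplotlib output only: Lorenz-curve panels per plot, the
δ-per-response bar chart with 95% Wald error bars, and coefficient tables
as CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .metrics import lorenz_points, tree_basal_area
from .model import COEF_NAMES, FitResult

__all__ = [
    "trait_correlation",
    "lorenz_panel",
    "delta_bar_chart",
    "coefficient_table",
    "render_reports",
]


def trait_correlation(delta_table: pd.DataFrame, trait_table: pd.DataFrame):
    """Spearman rank correlation between per-species δ and a trait index.

    ``delta_table`` needs columns (species, delta); ``trait_table``
    (species, trait) — e.g. a 1–5 shade-tolerance score.  Returns
    (rho, p); (nan, nan) when the trait is constant (correlation
    undefined), which callers should report as such.
    """
    merged = delta_table.merge(trait_table, on="species")
    if len(merged) < 3:
        raise ValueError(f"need >= 3 shared species, got {len(merged)}")
    if merged["trait"].nunique() == 1:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(merged["delta"], merged["trait"])
    return float(rho), float(p)


def lorenz_panel(
    tree_tables: dict[str, pd.DataFrame], path: str | Path
) -> Path:
    """Lorenz-curve facets (one per plot), trees ranked descending by size."""
    n = len(tree_tables)
    ncol = min(n, 4)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow),
                             squeeze=False)
    for ax, (plot_id, trees) in zip(axes.ravel(), tree_tables.items()):
        g = tree_basal_area(trees["c130_cm"].to_numpy())
        pts = lorenz_points(g)
        from .metrics import gini_index

        ax.plot(pts[:, 0], pts[:, 1], "-", color="forestgreen")
        ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
        ax.set_title(f"{plot_id}  Gini = {gini_index(g):.2f}", fontsize=9)
        ax.set_xlabel("cumulative tree fraction", fontsize=8)
        ax.set_ylabel("cumulative basal-area fraction", fontsize=8)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def delta_bar_chart(fits: dict[str, FitResult], path: str | Path) -> Path:
    """δ per response with 95% confidence bars (estimate ± 1.96·SE)."""
    names = list(fits)
    est = [fits[r].params["gini"] for r in names]
    se = [fits[r].bse["gini"] for r in names]
    fig, ax = plt.subplots(figsize=(1.2 * len(names) + 2, 3.5))
    xs = np.arange(len(names))
    ax.bar(xs, est, yerr=1.96 * np.asarray(se), capsize=4, color="steelblue")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(xs, names)
    ax.set_ylabel("δ (effect of basal-area Gini)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def coefficient_table(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Long-format coefficient table across responses."""
    rows = []
    for resp, fit in fits.items():
        for name, value in fit.params.items():
            rows.append(
                {
                    "response": resp,
                    "coefficient": COEF_NAMES.get(name, name),
                    "estimate": value,
                    "se": fit.bse[name],
                    "p": fit.pvalues[name],
                    "n": fit.n,
                    "aic": fit.aic,
                }
            )
    return pd.DataFrame(rows)


def render_reports(
    out_dir: str | Path,
    fits: dict[str, FitResult] | None = None,
    tree_tables: dict[str, pd.DataFrame] | None = None,
) -> dict[str, Path]:
    """Write all available figures/tables; says so when nothing to plot."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if not fits and not tree_tables:
        (out / "EMPTY.txt").write_text("nothing to plot: no fits or plots given\n")
        written["empty"] = out / "EMPTY.txt"
        return written
    if tree_tables:
        written["lorenz"] = lorenz_panel(tree_tables, out / "lorenz.png")
    if fits:
        gini_fits = {r: f for r, f in fits.items() if "gini" in f.params}
        if gini_fits:
            written["delta_chart"] = delta_bar_chart(gini_fits, out / "delta.png")
        table = coefficient_table(fits)
        table.to_csv(out / "coefficients.csv", index=False)
        written["coefficients"] = out / "coefficients.csv"
        (out / "fits.json").write_text(
            json.dumps({r: f.report() for r, f in fits.items()}, indent=2)
        )
        written["fits_json"] = out / "fits.json"
    return written
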