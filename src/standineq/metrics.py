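"""Per-plot stand structure and productivity metrics from tree-level records.

A plot inventory is a table with one row per tree (circumference at breast
height ``c130_cm``, 5-year radial increment ``ir5_cm``, per-hectare weight
``weight_per_ha``, and a ``status`` in {alive, dead, recruited, simplified}).
This module derives from it the quantities the production model consumes:

* stand basal area ``G`` (m²/ha), now and reconstructed five years earlier,
* quadratic mean diameter ``Dq`` (m),
* the Gini coefficient of individual tree basal areas (and Lorenz curves),
* the mean annual basal-area increment ``dG`` (m²/ha/yr) over the 5-year
  census interval, reconstructed from radial increments with dead and
  recruited trees handled explicitly,
* the monospecificity share used to filter plots,
* growth imputation for "simplified" trees whose increment was not measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TreeRecord",
    "StandMetrics",
    "DEFAULT_CENSUS_THRESHOLD_CM",
    "tree_basal_area",
    "circumference_to_diameter_m",
    "plot_state",
    "annual_basal_area_increment",
    "gini_index",
    "lorenz_points",
    "monospecific_share",
    "impute_simplified_trees",
    "stand_metrics",
    "metrics_table",
]

#: Minimum circumference (cm) for a tree to enter the census (7.5 cm dbh).
DEFAULT_CENSUS_THRESHOLD_CM = 23.5

_ALIVE_NOW = ("alive", "recruited", "simplified")
_ALIVE_PRIOR = ("alive", "dead", "simplified")
_STATUSES = ("alive", "dead", "recruited", "simplified")


@dataclass
class TreeRecord:
    """One measured tree.

    Attributes
    ----------
    c130 : float
        Circumference at breast height (1.30 m), cm.
    ir5 : float or None
        Radial increment over 5 years, cm; ``None`` for simplified trees
        until imputed.
    weight : float
        Trees per hectare this record represents (concentric-subplot design).
    status : str
        One of ``alive``, ``dead``, ``recruited``, ``simplified``.
    """

    tree_id: str
    species: str
    c130: float
    ir5: float | None
    weight: float
    status: str = "alive"

    def __post_init__(self) -> None:
        if self.c130 <= 0:
            raise ValueError(f"tree {self.tree_id}: c130 must be > 0")
        if self.weight <= 0:
            raise ValueError(f"tree {self.tree_id}: weight must be > 0")
        if self.status not in _STATUSES:
            raise ValueError(f"tree {self.tree_id}: unknown status {self.status!r}")
        if self.ir5 is not None and self.ir5 < 0:
            raise ValueError(f"tree {self.tree_id}: ir5 must be >= 0")


@dataclass
class StandMetrics:
    """Per-plot derived quantities."""

    G: float  # m²/ha, current
    G_prior: float  # m²/ha, five years earlier
    Dq: float  # m
    gini: float  # dimensionless in [0, 1)
    dG: float  # m²/ha/yr
    n_trees: int


def tree_basal_area(c130_cm):
    """Stem cross-section area at breast height, m², from circumference in cm.

    g = 1e-4 · c² / (4π).  Vectorised over array input.
    """
    c = np.asarray(c130_cm, dtype=float)
    if np.any(c <= 0):
        raise ValueError("circumference must be > 0")
    g = 1e-4 * c**2 / (4.0 * np.pi)
    return float(g) if np.isscalar(c130_cm) else g


def circumference_to_diameter_m(c130_cm):
    """Diameter in metres from circumference in cm."""
    return np.asarray(c130_cm, dtype=float) / (100.0 * np.pi)


def _require_columns(trees: pd.DataFrame) -> None:
    missing = {"c130_cm", "weight_per_ha", "status"} - set(trees.columns)
    if missing:
        raise ValueError(f"tree table missing columns: {sorted(missing)}")


def _prior_circumference(trees: pd.DataFrame) -> pd.Series:
    """Back-project circumference 5 years: c_prior = c130 − 2π·ir5.

    Dead trees keep their recorded circumference (no increment is available
    for them; they were alive, at that size, at the prior census).
    """
    c_prior = trees["c130_cm"].astype(float).copy()
    grows = trees["status"].isin(("alive", "recruited", "simplified"))
    ir5 = trees.loc[grows, "ir5_cm"]
    if ir5.isna().any():
        bad = trees.loc[grows & trees["ir5_cm"].isna()]
        not_simplified = bad[bad["status"] != "simplified"]
        if len(not_simplified):
            ids = not_simplified.get("tree_id", not_simplified.index).tolist()
            raise ValueError(f"missing ir5 on non-simplified tree(s) {ids}")
        ids = bad.get("tree_id", bad.index).tolist()
        raise ValueError(
            f"simplified tree(s) {ids} lack ir5; run impute_simplified_trees first"
        )
    c_prior.loc[grows] = c_prior.loc[grows] - 2.0 * np.pi * ir5.astype(float)
    return c_prior


def plot_state(
    trees: pd.DataFrame,
    at: str = "now",
    census_threshold_cm: float = DEFAULT_CENSUS_THRESHOLD_CM,
) -> tuple[float, float, int]:
    """Stand state (G in m²/ha, Dq in m, n) now or five years prior.

    ``now`` uses trees alive at the end of the interval (alive, recruited,
    simplified); ``five_years_prior`` reconstructs the earlier stand from
    back-projected circumferences of surviving trees plus dead trees at
    their recorded size, excluding recruits that were then below the census
    threshold.
    """
    _require_columns(trees)
    if at == "now":
        sel = trees[trees["status"].isin(_ALIVE_NOW)]
        c = sel["c130_cm"].astype(float)
        w = sel["weight_per_ha"].astype(float)
    elif at in ("five_years_prior", "prior"):
        c_prior = _prior_circumference(trees)
        keep = trees["status"].isin(_ALIVE_PRIOR) | (
            (trees["status"] == "recruited") & (c_prior >= census_threshold_cm)
        )
        c = c_prior[keep]
        w = trees.loc[keep, "weight_per_ha"].astype(float)
    else:
        raise ValueError(f"unknown state {at!r}; use 'now' or 'five_years_prior'")

    if len(c) == 0 or not (c > 0).any():
        warnings.warn(f"no live trees in state {at!r}; G = 0", stacklevel=2)
        return 0.0, float("nan"), 0
    valid = c > 0
    c, w = c[valid], w[valid]
    G = float((tree_basal_area(c.to_numpy()) * w.to_numpy()).sum())
    d = circumference_to_diameter_m(c.to_numpy())
    Dq = float(np.sqrt(np.sum(w.to_numpy() * d**2) / np.sum(w.to_numpy())))
    return G, Dq, int(len(c))


def annual_basal_area_increment(
    trees: pd.DataFrame,
    census_threshold_cm: float = DEFAULT_CENSUS_THRESHOLD_CM,
    recruit_convention: str = "above_threshold",
    years: float = 5.0,
) -> float:
    """Mean annual plot basal-area increment, m²/ha/yr.

    dG = (1/years) Σ_i 1e-4/(4π) · (c_i² − c_prior_i²) · w_i over trees
    alive at the end of the interval.  Dead trees contribute no growth.
    Recruited trees contribute, under the default ``above_threshold``
    convention, only the growth accrued above the census-entry
    circumference; the ``full`` convention counts their whole increment.
    """
    _require_columns(trees)
    sel = trees[trees["status"].isin(_ALIVE_NOW)].copy()
    if len(sel) == 0:
        return 0.0
    if sel["ir5_cm"].isna().any():
        bad = sel[sel["ir5_cm"].isna()]
        ids = bad.get("tree_id", bad.index).tolist()
        raise ValueError(f"missing ir5 on tree(s) {ids}")
    c = sel["c130_cm"].astype(float).to_numpy()
    ir5 = sel["ir5_cm"].astype(float).to_numpy()
    w = sel["weight_per_ha"].astype(float).to_numpy()
    c_prior = c - 2.0 * np.pi * ir5

    alive = (sel["status"] != "recruited").to_numpy()
    if np.any(alive & (c_prior <= 0)):
        ids = sel.loc[alive & (c_prior <= 0)].get("tree_id", sel.index).tolist()
        raise ValueError(f"2π·ir5 exceeds c130 for alive tree(s) {ids}")

    if recruit_convention == "above_threshold":
        floor = np.where(alive, c_prior, np.maximum(c_prior, census_threshold_cm))
    elif recruit_convention == "full":
        floor = np.maximum(c_prior, 0.0)
    else:
        raise ValueError(f"unknown recruit convention {recruit_convention!r}")

    terms = 1e-4 / (4.0 * np.pi) * (c**2 - floor**2) * w
    return float(terms.sum() / years)


def gini_index(basal_areas, weights=None) -> float:
    """Gini coefficient of individual tree basal areas.

    Unweighted (default): sort ascending and evaluate
    ``2·Σ i·g_i / (n·G) − (n+1)/n``, which is 0 when all trees are equal
    and approaches (n−1)/n under maximal inequality.

    With ``weights`` (trees/ha frequency weights), the sorted
    frequency-weight generalisation is used: with cumulative weight shares
    p and cumulative value shares L, Gini = 1 − Σ (p_k − p_{k−1})(L_k + L_{k−1}).
    """
    g = np.asarray(basal_areas, dtype=float)
    if g.size < 2:
        raise ValueError("Gini requires at least 2 trees")
    if np.any(g <= 0):
        raise ValueError("basal areas must be > 0")
    order = np.argsort(g, kind="stable")
    g = g[order]
    if weights is None:
        n = g.size
        i = np.arange(1, n + 1)
        return float(2.0 * np.sum(i * g) / (n * g.sum()) - (n + 1) / n)
    w = np.asarray(weights, dtype=float)[order]
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    p = np.concatenate([[0.0], np.cumsum(w) / w.sum()])
    L = np.concatenate([[0.0], np.cumsum(w * g) / np.sum(w * g)])
    return float(1.0 - np.sum(np.diff(p) * (L[1:] + L[:-1])))


def lorenz_points(basal_areas, ascending: bool = False) -> np.ndarray:
    """Lorenz curve of the basal-area distribution.

    Returns an (n+1, 2) array of (cumulative tree fraction, cumulative
    basal-area fraction) from (0, 0) to (1, 1).  Trees are ranked by size
    in descending order by default, so the curve lies on or above the
    diagonal; ``ascending=True`` mirrors it below.
    """
    g = np.sort(np.asarray(basal_areas, dtype=float))
    if g.size < 1:
        raise ValueError("need at least one tree")
    if not ascending:
        g = g[::-1]
    n = g.size
    x = np.arange(n + 1) / n
    y = np.concatenate([[0.0], np.cumsum(g) / g.sum()])
    y[-1] = 1.0
    return np.column_stack([x, y])


def monospecific_share(trees: pd.DataFrame) -> tuple[str, float, bool]:
    """Dominant species, its share of weighted basal area, and the ≥80% filter.

    The share is computed on currently live trees; a plot passes the
    monospecificity filter when a single species holds at least 80 % of
    the weighted basal area (inclusive threshold).
    """
    _require_columns(trees)
    sel = trees[trees["status"].isin(_ALIVE_NOW)]
    gw = tree_basal_area(sel["c130_cm"].to_numpy()) * sel["weight_per_ha"].to_numpy()
    by_species = pd.Series(gw).groupby(sel["species"].to_numpy()).sum()
    dominant = by_species.idxmax()
    share = float(by_species.max() / by_species.sum())
    return str(dominant), share, share >= 0.80


def impute_simplified_trees(
    trees: pd.DataFrame,
    class_width_cm: float = 10.0,
) -> pd.DataFrame:
    """Fill ``ir5_cm`` for simplified trees from measured conspecifics.

    A simplified tree receives the mean increment of measured live trees of
    the same species in the same circumference class (default 10 cm wide).
    Fallback cascade when the cell is empty: nearest non-empty class of the
    same species (equidistant ties averaged) → species mean → plot mean.
    Operates per plot when a ``plot_id`` column is present.

    Returns a copy; input is never mutated.
    """
    _require_columns(trees)
    out = trees.copy()
    if "plot_id" in out.columns:
        orig_index = out.index
        out = out.reset_index(drop=True)
        parts = [
            _impute_one_plot(grp, class_width_cm)
            for _, grp in out.groupby("plot_id", sort=False)
        ]
        res = pd.concat(parts).sort_index()
        res.index = orig_index
        return res
    return _impute_one_plot(out, class_width_cm)


def _impute_one_plot(trees: pd.DataFrame, class_width_cm: float) -> pd.DataFrame:
    out = trees.copy()
    simplified = out["status"].eq("simplified") & out["ir5_cm"].isna()
    if not simplified.any():
        return out
    measured = out[out["status"].isin(("alive", "recruited")) & out["ir5_cm"].notna()]
    if len(measured) == 0:
        raise ValueError("no measured trees available for imputation")
    cls = (measured["c130_cm"] // class_width_cm).astype(int)
    cell_means = measured.groupby([measured["species"], cls])["ir5_cm"].mean()
    species_means = measured.groupby("species")["ir5_cm"].mean()
    plot_mean = float(measured["ir5_cm"].mean())

    for idx in out.index[simplified]:
        sp = out.at[idx, "species"]
        k = int(out.at[idx, "c130_cm"] // class_width_cm)
        if (sp, k) in cell_means.index:
            val = cell_means[(sp, k)]
        elif sp in species_means.index:
            sp_classes = np.array(
                [c for s, c in cell_means.index if s == sp], dtype=int
            )
            dist = np.abs(sp_classes - k)
            nearest = sp_classes[dist == dist.min()]
            val = float(np.mean([cell_means[(sp, int(c))] for c in nearest]))
        else:
            val = plot_mean
        out.at[idx, "ir5_cm"] = val
    return out


def stand_metrics(
    trees: pd.DataFrame,
    census_threshold_cm: float = DEFAULT_CENSUS_THRESHOLD_CM,
    recruit_convention: str = "above_threshold",
) -> StandMetrics:
    """All per-plot derived quantities for one plot's tree table.

    Gini is computed on current individual basal areas of live trees,
    unweighted over the sampled trees.
    """
    G, Dq, n = plot_state(trees, "now", census_threshold_cm)
    G_prior, _, _ = plot_state(trees, "five_years_prior", census_threshold_cm)
    live = trees[trees["status"].isin(_ALIVE_NOW)]
    gini = gini_index(tree_basal_area(live["c130_cm"].to_numpy()))
    dG = annual_basal_area_increment(trees, census_threshold_cm, recruit_convention)
    return StandMetrics(G=G, G_prior=G_prior, Dq=Dq, gini=gini, dG=dG, n_trees=n)


def metrics_table(
    trees: pd.DataFrame,
    plots: pd.DataFrame | None = None,
    census_threshold_cm: float = DEFAULT_CENSUS_THRESHOLD_CM,
    min_monospecific_share: float = 0.80,
    impute: bool = True,
) -> pd.DataFrame:
    """Per-plot metrics table for a whole inventory collection.

    Applies simplified-tree imputation, drops plots with fewer than two
    live trees or failing the monospecificity filter, and joins the plot
    table's climate covariates when given.  Columns: plot_id, species, n,
    G, G_prior, Dq, gini, dG (+ wb_mm, sgdd when available).
    """
    if impute:
        trees = impute_simplified_trees(trees)
    rows = []
    for plot_id, grp in trees.groupby("plot_id", sort=False):
        if len(grp[grp["status"].isin(_ALIVE_NOW)]) < 2:
            continue
        dominant, share, passes = monospecific_share(grp)
        if not passes or share < min_monospecific_share:
            continue
        m = stand_metrics(grp, census_threshold_cm)
        rows.append(
            {
                "plot_id": plot_id,
                "species": dominant,
                "n": m.n_trees,
                "G": m.G,
                "G_prior": m.G_prior,
                "Dq": m.Dq,
                "gini": m.gini,
                "dG": m.dG,
            }
        )
    table = pd.DataFrame(rows)
    if plots is not None and len(table):
        keep = [c for c in ("plot_id", "wb_mm", "sgdd") if c in plots.columns]
        table = table.merge(plots[keep], on="plot_id", how="left")
    return table
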