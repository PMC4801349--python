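"""Synthetic forest-inventory generator.

Generates collections of monospecific plots whose structure spans the range
observed in large national inventories — diameter distributions from
strongly reverse-J (basal-area Gini > 0.6) to single-cohort unimodal
(Gini < 0.1), basal areas of roughly 1–100 m²/ha, quadratic mean diameters
of 0.06–1.2 m — together with climate covariates (water budget WB in mm,
growing-degree-day sum SGDD in °C·day) and plot growth drawn from the
multiplicative production model

    dG = exp(α0 + α1·WB + α2·SGDD) · G^β · exp(γ·Dq) · exp(δ·Gini) · exp(ε),

with ε ~ Normal(0, σ²) on the log scale.  The implied 5-year basal-area
growth is partitioned across trees proportionally to g^η (η > 1 mimics
asymmetric competition) and converted to per-tree radial increments, so
that recomputing dG from the tree records round-trips exactly when σ = 0.
The true parameters are emitted alongside every dataset for recovery tests.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import DEFAULT_CENSUS_THRESHOLD_CM, gini_index, tree_basal_area

__all__ = [
    "TrueParams",
    "DiameterLaw",
    "GeneratorConfig",
    "TrueParamRecord",
    "sample_diameter_distribution",
    "assign_growth",
    "generate_dataset",
    "generate_plot_table",
    "compute_sgdd",
    "write_dataset",
]

#: Per-hectare weights mimicking a concentric-subplot design: small trees
#: measured on a 6 m radius circle, medium on 10 m, large on 15 m.
SUBPLOT_WEIGHTS = ((70.5, 10000.0 / (np.pi * 6.0**2)),
                   (117.5, 10000.0 / (np.pi * 10.0**2)),
                   (np.inf, 10000.0 / (np.pi * 15.0**2)))


@dataclass(frozen=True)
class TrueParams:
    """Generative parameters of the multiplicative production model."""

    alpha0: float = -2.5      # log-scale intercept
    alpha1: float = 2e-3      # per mm of water budget
    alpha2: float = 1e-4      # per °C·day of SGDD
    beta: float = 0.55        # basal-area (stocking) exponent
    gamma: float = -0.5       # per m of quadratic mean diameter
    delta: float = -0.12      # per unit Gini (size inequality)

    def log_alpha(self, wb, sgdd):
        return self.alpha0 + self.alpha1 * np.asarray(wb) + self.alpha2 * np.asarray(sgdd)

    def expected_dG(self, G, Dq, gini, wb, sgdd):
        """Noise-free dG (m²/ha/yr) at the given plot state."""
        return np.exp(
            self.log_alpha(wb, sgdd)
            + self.beta * np.log(np.asarray(G, dtype=float))
            + self.gamma * np.asarray(Dq)
            + self.delta * np.asarray(gini)
        )


@dataclass(frozen=True)
class DiameterLaw:
    """Circumference distribution of a plot (cm at breast height).

    Families: ``weibull`` (shape < ~1.5 gives reverse-J structure),
    ``weibull_mixture`` (two components, e.g. a regenerating understory
    below an older cohort) and ``uniform_class`` (a single even-aged
    class of width ``class_width`` centred on ``scale``).
    """

    family: str = "weibull"
    shape: float = 1.8
    scale: float = 60.0       # cm circumference
    shape2: float = 6.0
    scale2: float = 150.0
    mix: float = 0.7          # weight of the first component
    class_width: float = 0.0  # uniform_class only

    def __post_init__(self):
        if self.family not in ("weibull", "weibull_mixture", "uniform_class"):
            raise ValueError(f"unknown diameter-law family {self.family!r}")
        if self.scale <= 0 or self.scale2 <= 0:
            raise ValueError("diameter-law scale must be > 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full recipe for a synthetic plot collection.

    Defaults emulate the structural and climatic envelope of the study
    system: Gini of basal areas spanning ~0–0.8 across plots, basal areas
    ~1–100 m²/ha, WB 0–130 mm, SGDD 400–3500 °C·day.
    """

    n_plots: int = 100
    species_label: str = "FagSyl"
    diameter_law: DiameterLaw = field(default_factory=DiameterLaw)
    randomize_structure: bool = True   # vary shape/scale across plots
    stems_per_ha_range: tuple[float, float] = (80.0, 1200.0)
    true_params: TrueParams = field(default_factory=TrueParams)
    noise_sigma: float = 0.3           # SD of log-scale error
    eta: float = 1.4                   # growth-partitioning asymmetry g^η
    wb_range: tuple[float, float] = (0.0, 130.0)
    sgdd_range: tuple[float, float] = (400.0, 3500.0)
    death_rate: float = 0.0
    recruit_rate: float = 0.0
    simplified_rate: float = 0.0
    min_circumference_cm: float = DEFAULT_CENSUS_THRESHOLD_CM
    seed: int = 0

    def __post_init__(self):
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if min(self.stems_per_ha_range) <= 0:
            raise ValueError("stems_per_ha_range must be positive")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class TrueParamRecord:
    """Provenance sidecar emitted with every generated dataset."""

    true_params: TrueParams
    seed: int
    config_hash: str

    def to_json(self) -> str:
        return json.dumps(
            {"true_params": asdict(self.true_params), "seed": self.seed,
             "config_hash": self.config_hash},
            indent=2,
        )


def sample_diameter_distribution(
    law: DiameterLaw,
    n_trees: int,
    rng: np.random.Generator,
    min_circumference_cm: float = DEFAULT_CENSUS_THRESHOLD_CM,
) -> np.ndarray:
    """Draw ``n_trees`` circumferences (cm) truncated below the census threshold.

    Weibull draws use inverse-CDF sampling conditioned on exceeding the
    threshold, so reverse-J shapes keep their small-tree mass just above it.
    """
    if n_trees < 2:
        raise ValueError("a plot needs at least 2 trees")
    cmin = min_circumference_cm
    if law.family == "uniform_class":
        half = law.class_width / 2.0
        lo = max(law.scale - half, cmin)
        hi = max(law.scale + half, lo)
        if hi == lo:
            return np.full(n_trees, lo)
        return rng.uniform(lo, hi, size=n_trees)
    if law.family == "weibull":
        return _truncated_weibull(law.shape, law.scale, cmin, n_trees, rng)
    n1 = rng.binomial(n_trees, law.mix)
    c = np.concatenate([
        _truncated_weibull(law.shape, law.scale, cmin, n1, rng),
        _truncated_weibull(law.shape2, law.scale2, cmin, n_trees - n1, rng),
    ])
    return rng.permutation(c)


def _truncated_weibull(shape, scale, cmin, n, rng):
    if n == 0:
        return np.empty(0)
    F0 = stats.weibull_min.cdf(cmin, shape, scale=scale)
    u = rng.uniform(F0, 1.0, size=n)
    return stats.weibull_min.ppf(u, shape, scale=scale)


def _subplot_weight(c130: np.ndarray) -> np.ndarray:
    w = np.empty_like(c130, dtype=float)
    prev = 0.0
    for upper, weight in SUBPLOT_WEIGHTS:
        w[(c130 > prev) & (c130 <= upper)] = weight
        prev = upper
    return w


def _plot_skeleton(config: GeneratorConfig, rng: np.random.Generator):
    """Circumferences + weights for one plot, hitting a stems/ha target."""
    law = config.diameter_law
    if config.randomize_structure and law.family == "weibull":
        law = DiameterLaw(
            family="weibull",
            shape=float(rng.uniform(0.9, 7.0)),
            scale=float(rng.uniform(35.0, 180.0)),
        )
    target = rng.uniform(*config.stems_per_ha_range)
    # draw in batches until cumulative per-ha weight reaches the target
    c_all = []
    total_w = 0.0
    while total_w < target or len(c_all) < 2:
        c = sample_diameter_distribution(law, 8, rng, config.min_circumference_cm)
        for ci in c:
            wi = _subplot_weight(np.array([ci]))[0]
            c_all.append(ci)
            total_w += wi
            if total_w >= target and len(c_all) >= 2:
                break
    c = np.array(c_all)
    return c, _subplot_weight(c)


def assign_growth(
    c130: np.ndarray,
    weight: np.ndarray,
    wb: float,
    sgdd: float,
    true_params: TrueParams,
    eta: float,
    noise_sigma: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Per-tree 5-year radial increments consistent with the production model.

    Draws the plot's dG from the model (log-normal error), converts it to a
    5-year per-hectare basal-area growth, partitions it across trees
    proportionally to g^η, and inverts each share to a radial increment
    via c_prior = sqrt(c² − 4π·Δg[cm²]).  Returns (ir5 array in cm, the
    drawn dG in m²/ha/yr).  Shares that would drive a tree's prior
    circumference to zero are capped (with a warning) and the remainder
    redistributed over the other trees.
    """
    g = tree_basal_area(c130)  # m² per tree
    G = float(np.sum(g * weight))
    d = c130 / (100.0 * np.pi)
    Dq = float(np.sqrt(np.sum(weight * d**2) / np.sum(weight)))
    gini = gini_index(g) if len(g) >= 2 else 0.0

    eps = rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0
    dG = float(true_params.expected_dG(G, Dq, gini, wb, sgdd) * np.exp(eps))
    total_growth = 5.0 * dG  # m²/ha over the census interval

    share = g**eta * weight
    delta_g = total_growth * share / share.sum() / weight  # m² per tree

    # cap shares that would imply a non-positive prior circumference
    g_cm2 = c130**2 / (4.0 * np.pi)
    cap = 0.95 * g_cm2 * 1e-4
    for _ in range(len(c130)):
        over = delta_g > cap
        if not over.any():
            break
        excess = float(np.sum((delta_g[over] - cap[over]) * weight[over]))
        delta_g[over] = cap[over]
        room = ~over
        if not room.any():
            warnings.warn("growth cap hit on every tree; dG truncated", stacklevel=2)
            break
        warnings.warn("growth share capped to keep prior circumference positive",
                      stacklevel=2)
        redist = share * room
        delta_g[room] += excess * redist[room] / redist[room].sum() / weight[room]

    c_prior = np.sqrt(np.maximum(c130**2 - 4.0 * np.pi * delta_g * 1e4, 0.0))
    ir5 = (c130 - c_prior) / (2.0 * np.pi)
    return ir5, dG


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TrueParamRecord]:
    """Generate a full tree-level collection.

    Returns ``(trees, plots, record)``: the tree table (plot_id, tree_id,
    species, c130_cm, ir5_cm, weight_per_ha, status), the plot table
    (plot_id, species, wb_mm, sgdd, plus the generative truth dG_true),
    and the true-parameter sidecar.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    tree_rows, plot_rows = [], []
    for p in range(config.n_plots):
        plot_id = f"P{p:05d}"
        c130, weight = _plot_skeleton(config, rng)
        wb = float(rng.uniform(*config.wb_range))
        sgdd = float(rng.uniform(*config.sgdd_range))

        if config.recruit_rate > 0:
            n_rec = rng.binomial(len(c130), config.recruit_rate)
            if n_rec:
                lo = config.min_circumference_cm
                c_rec = rng.uniform(lo, lo + 4.0, size=n_rec)
                c130 = np.concatenate([c130, c_rec])
                weight = np.concatenate([weight, _subplot_weight(c_rec)])

        ir5, dG = assign_growth(
            c130, weight, wb, sgdd, config.true_params,
            config.eta, config.noise_sigma, rng,
        )
        c_prior = c130 - 2.0 * np.pi * ir5
        status = np.where(
            c_prior < config.min_circumference_cm, "recruited", "alive"
        ).astype(object)

        if config.simplified_rate > 0:
            mask = (rng.uniform(size=len(c130)) < config.simplified_rate) & (
                status == "alive"
            )
            if mask.sum() < len(c130):  # keep at least one measured tree
                status[mask] = "simplified"

        ir5_out = ir5.astype(object)
        ir5_out[status == "simplified"] = None

        for t in range(len(c130)):
            tree_rows.append(
                (plot_id, f"{plot_id}-T{t:04d}", config.species_label,
                 float(c130[t]), ir5_out[t], float(weight[t]), status[t])
            )

        if config.death_rate > 0:
            n_dead = rng.binomial(len(c130), config.death_rate)
            c_dead = sample_diameter_distribution(
                config.diameter_law, max(n_dead, 2), rng,
                config.min_circumference_cm,
            )[:n_dead]
            for t, cd in enumerate(c_dead):
                tree_rows.append(
                    (plot_id, f"{plot_id}-D{t:04d}", config.species_label,
                     float(cd), None, float(_subplot_weight(np.array([cd]))[0]),
                     "dead")
                )

        plot_rows.append((plot_id, config.species_label, wb, sgdd, dG))

    trees = pd.DataFrame(
        tree_rows,
        columns=["plot_id", "tree_id", "species", "c130_cm", "ir5_cm",
                 "weight_per_ha", "status"],
    )
    trees["ir5_cm"] = trees["ir5_cm"].astype(float)
    plots = pd.DataFrame(
        plot_rows, columns=["plot_id", "species", "wb_mm", "sgdd", "dG_true"]
    )
    record = TrueParamRecord(config.true_params, config.seed, config.config_hash())
    return trees, plots, record


def generate_plot_table(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Plot-level dataset (G, Dq, gini, wb, sgdd, dG) without tree records.

    Draws the same diameter, weight and climate distributions as
    :func:`generate_dataset` and the same log-normal growth model, but
    skips materialising per-tree increments; the tree-level path's exact
    σ=0 round trip makes the two equivalent for model-fitting studies.
    Used for replicated parameter-recovery and test-calibration runs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for _ in range(config.n_plots):
        c130, weight = _plot_skeleton(config, rng)
        wb = float(rng.uniform(*config.wb_range))
        sgdd = float(rng.uniform(*config.sgdd_range))
        g = tree_basal_area(c130)
        G = float(np.sum(g * weight))
        d = c130 / (100.0 * np.pi)
        Dq = float(np.sqrt(np.sum(weight * d**2) / np.sum(weight)))
        gini = gini_index(g)
        eps = rng.normal(0.0, config.noise_sigma) if config.noise_sigma > 0 else 0.0
        dG = float(
            config.true_params.expected_dG(G, Dq, gini, wb, sgdd) * np.exp(eps)
        )
        rows.append((G, Dq, gini, wb, sgdd, dG))
    tab = pd.DataFrame(rows, columns=["G", "Dq", "gini", "wb_mm", "sgdd", "dG"])
    tab.insert(0, "plot_id", [f"P{i:05d}" for i in range(len(tab))])
    return tab


def compute_sgdd(
    daily_mean_temperatures,
    threshold_c: float = 5.56,
    convention: str = "degree_days",
) -> float:
    """Growing-degree-day sum (°C·day) from a year of daily mean temperatures.

    Default ``degree_days`` convention: Σ max(T_d − threshold, 0).  The
    ``raw_sum`` alternative sums the raw temperatures of days exceeding
    the threshold.
    """
    t = np.asarray(daily_mean_temperatures, dtype=float)
    if t.size == 0:
        raise ValueError("empty temperature series")
    if t.size not in (365, 366):
        warnings.warn(f"expected a full year, got {t.size} days", stacklevel=2)
    if convention == "degree_days":
        return float(np.sum(np.maximum(t - threshold_c, 0.0)))
    if convention == "raw_sum":
        return float(np.sum(t[t > threshold_c]))
    raise ValueError(f"unknown SGDD convention {convention!r}")


def write_dataset(
    trees: pd.DataFrame,
    plots: pd.DataFrame,
    record: TrueParamRecord,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the tree/plot CSVs and the true-parameter JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trees": out / "trees.csv",
        "plots": out / "plots.csv",
        "true_params": out / "true_params.json",
    }
    trees.to_csv(paths["trees"], index=False)
    plots.to_csv(paths["plots"], index=False)
    paths["true_params"].write_text(record.to_json())
    return paths
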