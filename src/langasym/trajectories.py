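"""Per-pair hemispheric age-trajectory fits and FDR screening.

For every homotopic pair, fit the factor-smooth model of
:mod:`langasym.gam` to the two hemispheres' normalized gradient values,
test the Hemisphere x Age interaction, correct across pairs by
Benjamini-Hochberg, and extract the demeaned asymmetry trajectory with a
pointwise confidence band on a common age grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .atlas import pair_regions
from .gam import FactorSmoothGAM, GamError

DEFAULT_GRID_SIZE = 100


class TrajectoryError(ValueError):
    pass


@dataclass
class RegionTrajectoryFit:
    """Fitted hemispheric trajectories and interaction test for one pair."""

    pair_id: str
    model: FactorSmoothGAM
    statistic: float
    df: float
    p_value: float
    q_value: float | None = None
    age_grid: np.ndarray | None = None
    curve: pd.DataFrame | None = None  # age, asymmetry, lo, hi

    @property
    def smooth_endpoints(self) -> tuple[float, float]:
        """Demeaned asymmetry at the first and last grid age (the youngest-
        and oldest-age summaries of the trajectory)."""
        if self.curve is None:
            raise TrajectoryError("no trajectory curve computed")
        a = self.curve["asymmetry"]
        return float(a.iloc[0]), float(a.iloc[-1])


def fit_region_gamm(data: pd.DataFrame, k: int = 6) -> RegionTrajectoryFit:
    """Fit one pair's long table (subject, hemisphere, age, sex, site,
    value) and run the interaction test."""
    model = FactorSmoothGAM(k=k).fit(data)
    pair_id = str(data["pair_id"].iloc[0]) if "pair_id" in data.columns else ""
    try:
        stat, df, p = model.interaction_test()
    except GamError:
        stat, df, p = np.nan, np.nan, np.nan
    return RegionTrajectoryFit(
        pair_id=pair_id, model=model, statistic=stat, df=df, p_value=p
    )


def test_interaction(fit: RegionTrajectoryFit) -> float:
    """Interaction p-value of a fitted pair (recomputed from the model)."""
    return fit.model.interaction_test()[2]


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise TrajectoryError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def asymmetry_trajectory(
    fit: RegionTrajectoryFit, age_grid: np.ndarray, level: float = 0.95
) -> pd.DataFrame:
    """Demeaned L-R trajectory with pointwise CI on ``age_grid``."""
    curve = fit.model.asymmetry_curve(age_grid, level=level)
    fit.age_grid = np.asarray(age_grid, dtype=float)
    fit.curve = curve
    return curve


def build_pair_table(
    g1: pd.DataFrame,
    atlas: pd.DataFrame,
    phenotype: pd.DataFrame,
    pair_id: str,
) -> pd.DataFrame:
    """Long table for one pair from the (subjects x regions) gradient
    table and the phenotype covariates."""
    left_id, right_id = pair_regions(atlas, pair_id)
    for rid in (left_id, right_id):
        if rid not in g1.columns:
            raise TrajectoryError(
                f"pair {pair_id!r}: region {rid!r} missing from gradient table"
            )
    pheno = phenotype.set_index("subject_id").loc[g1.index]
    rows = []
    for hemi, rid in (("L", left_id), ("R", right_id)):
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": g1.index,
                    "pair_id": pair_id,
                    "hemisphere": hemi,
                    "age": pheno["age"].to_numpy(),
                    "sex": pheno["sex"].to_numpy(),
                    "site": pheno["site"].to_numpy(),
                    "value": g1[rid].to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def fit_all_pairs(
    g1: pd.DataFrame,
    atlas: pd.DataFrame,
    phenotype: pd.DataFrame,
    pair_ids: list[str],
    k: int = 6,
    fdr_alpha: float = 0.05,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> tuple[dict[str, RegionTrajectoryFit], pd.DataFrame]:
    """Fit every pair, FDR-correct the interaction tests, and evaluate
    demeaned asymmetry trajectories on a common age grid.

    Returns ``(fits, summary)`` where ``summary`` has one row per pair
    (p, q, significant flag, trajectory endpoints).
    """
    ages = phenotype.set_index("subject_id").loc[g1.index, "age"]
    grid = np.linspace(ages.min(), ages.max(), grid_size)
    fits: dict[str, RegionTrajectoryFit] = {}
    for pair_id in pair_ids:
        table = build_pair_table(g1, atlas, phenotype, pair_id)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_region_gamm(table, k=k)
        asymmetry_trajectory(fit, grid)
        fits[pair_id] = fit
    pvals = np.array([fits[p].p_value for p in pair_ids])
    qvals = bh_fdr(pvals)
    rows = []
    for pair_id, q in zip(pair_ids, qvals):
        fit = fits[pair_id]
        fit.q_value = float(q)
        start, end = fit.smooth_endpoints
        rows.append(
            {
                "pair_id": pair_id,
                "statistic": fit.statistic,
                "df": fit.df,
                "p_value": fit.p_value,
                "q_value": fit.q_value,
                "significant": bool(q < fdr_alpha),
                "asym_youngest": start,
                "asym_oldest": end,
            }
        )
    return fits, pd.DataFrame(rows)


def trajectory_curves(fits: dict[str, RegionTrajectoryFit]) -> pd.DataFrame:
    """Stack per-pair curves into one long frame (pair, age, asymmetry,
    lo, hi)."""
    frames = []
    for pair_id, fit in fits.items():
        if fit.curve is None:
            raise TrajectoryError(f"pair {pair_id!r} has no evaluated curve")
        c = fit.curve.copy()
        c.insert(0, "pair_id", pair_id)
        frames.append(c)
    return pd.concat(frames, ignore_index=True)
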