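"""Homotopic-pair asymmetry tables.

Asymmetry is always left minus right: positive values mean leftward
asymmetry, negative values rightward.  Gradient asymmetry is the difference
of normalized G1 values; volume asymmetry is the difference of
TIV-normalized regional volumes (a proportion difference, chosen for
consistency with the gradient definition; a laterality quotient
``(L-R)/(L+R)`` is available via ``method='quotient'``).
"""

from __future__ import annotations

import pandas as pd

from .atlas import validate_atlas


class AsymmetryError(ValueError):
    pass


ASYMMETRY_COLUMNS = [
    "subject_id",
    "pair_id",
    "left",
    "right",
    "asymmetry",
    "measure",
]


def gradient_asymmetry(g1: pd.DataFrame, atlas: pd.DataFrame) -> pd.DataFrame:
    """Long-format gradient asymmetry per subject and homotopic pair.

    Parameters
    ----------
    g1 : DataFrame, subjects x regions
        Aligned, 0-100-normalized first-gradient values.
    atlas : DataFrame
        Homotopic region atlas.
    """
    validate_atlas(atlas)
    rows = []
    for pair_id, grp in atlas.groupby("pair_id"):
        left_id = grp.loc[grp["hemisphere"] == "L", "region_id"].iloc[0]
        right_id = grp.loc[grp["hemisphere"] == "R", "region_id"].iloc[0]
        for rid in (left_id, right_id):
            if rid not in g1.columns:
                raise AsymmetryError(
                    f"pair {pair_id!r}: region {rid!r} missing from gradient table"
                )
        left = g1[left_id]
        right = g1[right_id]
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": g1.index,
                    "pair_id": pair_id,
                    "left": left.to_numpy(),
                    "right": right.to_numpy(),
                    "asymmetry": left.to_numpy() - right.to_numpy(),
                    "measure": "gradient",
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[ASYMMETRY_COLUMNS]


def volume_asymmetry(
    volumes: pd.DataFrame, atlas: pd.DataFrame, method: str = "difference"
) -> pd.DataFrame:
    """TIV-normalized volume asymmetry per subject and homotopic pair.

    ``volumes`` is wide: one row per subject with a ``tiv`` column and one
    column per region id.  ``method='difference'`` gives
    ``vL/TIV - vR/TIV``; ``method='quotient'`` gives ``(vL-vR)/(vL+vR)``.
    """
    validate_atlas(atlas)
    if "tiv" not in volumes.columns:
        raise AsymmetryError("volume table must contain a 'tiv' column")
    tiv = volumes["tiv"]
    if (tiv <= 0).any():
        bad = volumes.loc[tiv <= 0, "subject_id"].tolist()
        raise AsymmetryError(f"non-positive TIV for subjects: {bad}")
    rows = []
    for pair_id, grp in atlas.groupby("pair_id"):
        left_id = grp.loc[grp["hemisphere"] == "L", "region_id"].iloc[0]
        right_id = grp.loc[grp["hemisphere"] == "R", "region_id"].iloc[0]
        for rid in (left_id, right_id):
            if rid not in volumes.columns:
                raise AsymmetryError(
                    f"pair {pair_id!r}: region {rid!r} missing from volume table"
                )
        left = volumes[left_id] / tiv
        right = volumes[right_id] / tiv
        if method == "difference":
            asym = left - right
        elif method == "quotient":
            asym = (volumes[left_id] - volumes[right_id]) / (
                volumes[left_id] + volumes[right_id]
            )
        else:
            raise AsymmetryError(f"unknown method {method!r}")
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": volumes["subject_id"].to_numpy(),
                    "pair_id": pair_id,
                    "left": left.to_numpy(),
                    "right": right.to_numpy(),
                    "asymmetry": asym.to_numpy(),
                    "measure": "normalized_volume",
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[ASYMMETRY_COLUMNS]


def asymmetry_long_to_wide(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Pivot one measure of a long asymmetry table to subjects x pairs."""
    sub = table[table["measure"] == measure]
    return sub.pivot(index="subject_id", columns="pair_id", values="asymmetry")
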