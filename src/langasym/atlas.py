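"""Homotopic region atlases.

A region atlas maps each parcel to a hemisphere and a homotopic pair, and
flags the pairs belonging to the network of interest (an extended language
network with language-specific, episodic-memory and shared regions).  The
atlas is an *input* to the pipeline, never recomputed from data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ATLAS_COLUMNS = ["region_id", "hemisphere", "pair_id", "network", "name"]

#: network labels carried by pairs of interest
NETWORK_LABELS = ("language", "memory", "both")


class AtlasError(ValueError):
    """Raised when an atlas table violates the homotopic-pairing contract."""


def validate_atlas(atlas: pd.DataFrame) -> pd.DataFrame:
    """Check the homotopic pairing structure of an atlas table.

    Every pair id must map to exactly one left and one right region, and
    every region must carry a hemisphere label in {L, R}.  Returns the
    validated frame (unchanged) for chaining.
    """
    missing = [c for c in ATLAS_COLUMNS if c not in atlas.columns]
    if missing:
        raise AtlasError(f"atlas is missing columns: {missing}")
    bad_hemi = set(atlas["hemisphere"]) - {"L", "R"}
    if bad_hemi:
        raise AtlasError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
    if atlas["region_id"].duplicated().any():
        dup = atlas.loc[atlas["region_id"].duplicated(), "region_id"].tolist()
        raise AtlasError(f"duplicated region ids: {dup}")
    for pair_id, grp in atlas.groupby("pair_id"):
        hemis = sorted(grp["hemisphere"])
        if hemis != ["L", "R"]:
            raise AtlasError(
                f"pair {pair_id!r} is not a valid homotopic pair "
                f"(hemispheres {hemis}); each pair needs exactly one L and one R region"
            )
    return atlas


def make_atlas(
    n_regions: int,
    n_pairs_of_interest: int,
    network_split: tuple[int, int, int] | None = None,
) -> pd.DataFrame:
    """Build a synthetic homotopic atlas with ``n_regions`` parcels.

    Regions come in L/R pairs (``n_regions`` must be even).  The first
    ``n_pairs_of_interest`` pairs are flagged with network labels
    (language / memory / both following ``network_split``); the remainder
    are labelled ``other``.
    """
    if n_regions % 2 != 0:
        raise AtlasError("n_regions must be even (regions come in L/R pairs)")
    n_pairs = n_regions // 2
    if n_pairs_of_interest > n_pairs:
        raise AtlasError(
            f"n_pairs_of_interest={n_pairs_of_interest} exceeds total pairs {n_pairs}"
        )
    if network_split is None:
        # proportions of the reference 10/19/8 language/memory/both split
        n_lang = max(1, round(n_pairs_of_interest * 10 / 37))
        n_both = max(0, round(n_pairs_of_interest * 8 / 37))
        n_mem = n_pairs_of_interest - n_lang - n_both
        network_split = (n_lang, n_mem, n_both)
    if sum(network_split) != n_pairs_of_interest:
        raise AtlasError("network_split must sum to n_pairs_of_interest")
    labels = (
        ["language"] * network_split[0]
        + ["memory"] * network_split[1]
        + ["both"] * network_split[2]
        + ["other"] * (n_pairs - n_pairs_of_interest)
    )
    rows = []
    for p in range(n_pairs):
        pair_id = f"pair{p:03d}"
        for hemi in ("L", "R"):
            rows.append(
                {
                    "region_id": f"{pair_id}{hemi}",
                    "hemisphere": hemi,
                    "pair_id": pair_id,
                    "network": labels[p],
                    "name": f"Region {p} ({hemi})",
                }
            )
    return validate_atlas(pd.DataFrame(rows, columns=ATLAS_COLUMNS))


def make_reference_atlas() -> pd.DataFrame:
    """Full-scale synthetic stand-in atlas: 384 parcels, 37 network pairs.

    Mirrors the shape of a whole-cortex homotopic parcellation carrying an
    extended language-and-memory network (10 language, 19 memory, 8 shared
    pairs).  Region names are synthetic placeholders, not anatomical labels.
    """
    return make_atlas(384, 37, network_split=(10, 19, 8))


def pairs_of_interest(atlas: pd.DataFrame) -> list[str]:
    """Pair ids flagged with a network label (the analysis set)."""
    mask = atlas["network"].isin(NETWORK_LABELS)
    return sorted(atlas.loc[mask, "pair_id"].unique())


def pair_regions(atlas: pd.DataFrame, pair_id: str) -> tuple[str, str]:
    """Return (left region id, right region id) for a pair."""
    grp = atlas[atlas["pair_id"] == pair_id]
    if grp.empty:
        raise AtlasError(f"pair {pair_id!r} not in atlas")
    left = grp.loc[grp["hemisphere"] == "L", "region_id"].iloc[0]
    right = grp.loc[grp["hemisphere"] == "R", "region_id"].iloc[0]
    return left, right
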