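"""Plain-text dataset I/O and schema validation.

All tables are CSV (TSV for time series) with a header row, so every
artifact diffs cleanly in version control.  A cohort directory holds::

    atlas.csv            region_id, hemisphere, pair_id, network, name
    phenotype.csv        subject_id, age, sex, site, mmse
    volumes.csv          subject_id, tiv, <region volume columns>
    behavior.csv         subject_id, <behavior scores>
    ground_truth.json    planted-truth record (synthetic cohorts only)
    timeseries/<id>.tsv  rows = timepoints, columns = region ids
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import validate_atlas
from .simulate import CohortData, CohortSpec, GroundTruth


class InputError(ValueError):
    pass


def write_cohort(data: CohortData, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    data.atlas.to_csv(out / "atlas.csv", index=False)
    data.phenotype.to_csv(out / "phenotype.csv", index=False)
    data.volumes.to_csv(out / "volumes.csv", index=False)
    data.behavior.to_csv(out / "behavior.csv", index=False)
    (out / "ground_truth.json").write_text(data.ground_truth.to_json())
    for sid, ts in data.timeseries.items():
        ts.to_csv(out / "timeseries" / f"{sid}.tsv", sep="\t", index=False)
    return out


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    spec = CohortSpec.from_dict(d["spec"])
    return GroundTruth(
        spec=spec,
        pair_positions=d["pair_positions"],
        cluster_labels=d["cluster_labels"],
        crossover_age=d["crossover_age"],
        mode_scores=pd.Series(d["mode_scores"], name="mode_score"),
        mode_weights=d["mode_weights"],
        behavior_weights=np.asarray(d["behavior_weights"], dtype=float),
        shape_gamma=d["shape_gamma"],
    )


def read_cohort(in_dir: str | Path) -> CohortData:
    """Load and validate a cohort directory."""
    root = Path(in_dir)
    for name in ("atlas.csv", "phenotype.csv", "volumes.csv"):
        if not (root / name).exists():
            raise InputError(f"{root / name}: file not found")
    atlas = pd.read_csv(root / "atlas.csv")
    try:
        validate_atlas(atlas)
    except ValueError as err:
        raise InputError(f"{root / 'atlas.csv'}: {err}") from err
    phenotype = pd.read_csv(root / "phenotype.csv")
    _require_columns(phenotype, ["subject_id", "age", "sex", "site", "mmse"],
                     root / "phenotype.csv")
    volumes = pd.read_csv(root / "volumes.csv")
    _require_columns(volumes, ["subject_id", "tiv"], root / "volumes.csv")
    behavior_path = root / "behavior.csv"
    behavior = pd.read_csv(behavior_path) if behavior_path.exists() else pd.DataFrame()
    ts_dir = root / "timeseries"
    timeseries: dict[str, pd.DataFrame] = {}
    if ts_dir.exists():
        for f in sorted(ts_dir.glob("*.tsv")):
            timeseries[f.stem] = pd.read_csv(f, sep="\t")
    pheno_subjects = set(phenotype["subject_id"])
    ts_subjects = set(timeseries)
    missing = sorted(ts_subjects - pheno_subjects)
    if missing:
        raise InputError(
            f"{root / 'phenotype.csv'}: subjects with time series but no "
            f"phenotype row: {missing}"
        )
    missing_ts = sorted(pheno_subjects - ts_subjects) if timeseries else []
    if missing_ts:
        raise InputError(
            f"{ts_dir}: phenotype subjects without time series: {missing_ts}"
        )
    vol_subjects = set(volumes["subject_id"])
    if vol_subjects != pheno_subjects:
        diff = sorted(pheno_subjects ^ vol_subjects)
        raise InputError(
            f"{root / 'volumes.csv'}: subject mismatch with phenotype: {diff}"
        )
    for rid in atlas["region_id"]:
        if rid not in volumes.columns:
            raise InputError(
                f"{root / 'volumes.csv'}: missing volume column for region "
                f"{rid!r}"
            )
    gt_path = root / "ground_truth.json"
    ground_truth = read_ground_truth(gt_path) if gt_path.exists() else None
    spec = ground_truth.spec if ground_truth is not None else CohortSpec(
        n_subjects=len(phenotype),
        n_regions=len(atlas),
        n_pairs_of_interest=1,
    )
    return CohortData(
        spec=spec,
        atlas=atlas,
        phenotype=phenotype,
        timeseries=timeseries,
        volumes=volumes,
        behavior=behavior,
        ground_truth=ground_truth,
    )


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
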