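"""Synthetic cohorts with planted hemispheric-specialization structure.

The generator emulates, at desk scale, a cross-sectional adult-lifespan
resting-state cohort: parcellated regional BOLD time series whose
correlation structure carries a unimodal-to-transmodal principal gradient,
hemisphere-specific smooth age drifts forming two trajectory clusters (plus
null pairs), TIV-normalized regional volumes with planted asymmetries, and
behavior scores linearly coupled to a latent subject-level brain mode.

Every quantity planted here is recorded in a :class:`GroundTruth` so each
downstream stage (gradients, asymmetry, trajectories, clustering, CCA) can
be tested as a recovery problem.

Construction of the connectivity gradient
-----------------------------------------
Each region r has a planted gradient position ``g_r(hemisphere, age, subject)``
on a 0-100 scale, mapped to an angle ``theta = g/100 * pi/2``.  Region time
series are ``cos(theta) * s1 + sin(theta) * s2 + noise``, with s1, s2 shared
standard-normal latent series per subject.  The expected inter-regional
correlation is then ``cos(theta_i - theta_j) / (1 + noise_sd**2)`` — a smooth
one-dimensional manifold whose diffusion-map parametrization is monotone in
the planted position, so gradient recovery is an oracle-checkable property.
(A single shared factor would not work: all correlation-matrix rows become
proportional, row sparsification leaves them collinear, and the affinity
matrix degenerates to a constant.)
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .atlas import make_atlas, pairs_of_interest

CLUSTER_LABELS = ("cluster1", "cluster2", "null")
BEHAVIOR_COLUMNS = [
    "naming_accuracy",
    "tot_ratio_inverted",
    "comprehension_accuracy",
    "comprehension_rt_inverted",
]

# distinct rng streams per generator, so each call is reproducible on its own
_STREAM_COHORT = 11
_STREAM_TIMESERIES = 13
_STREAM_VOLUMES = 17
_STREAM_BEHAVIOR = 19
_STREAM_MODE = 23
_STREAM_JITTER = 29


class SpecError(ValueError):
    """Raised for an invalid cohort specification."""


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``effect_size`` is the maximal planted asymmetry drift over the age
    range, in normalized gradient units (0-100 scale).  ``noise_sd`` is the
    regional noise standard deviation relative to a unit-variance shared
    signal (0.5 means a 4:1 signal-to-noise variance ratio).
    """

    n_subjects: int = 200
    age_range: tuple[float, float] = (18.0, 88.0)
    n_sites: int = 3
    seed: int = 0
    n_regions: int = 48
    n_pairs_of_interest: int = 16
    cluster_assignment: dict[str, str] | None = None
    crossover_age: float = 53.0
    effect_size: float = 10.0
    noise_sd: float = 0.5
    n_timepoints: int = 200
    #: sd of per-subject random offsets of region gradient positions
    position_jitter_sd: float = 2.0
    # secondary knobs (volumes, behavior, subject-level brain mode)
    mode_strength: float = 2.0
    behavior_weights: tuple[float, ...] = (0.8, 0.6, 0.3, 0.2)
    behavior_noise_sd: float = 1.0
    volume_asymmetry: float = 0.002
    volume_mode_strength: float = 0.0005
    null_pair_asymmetry: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise SpecError("n_subjects must be positive")
        if self.n_regions % 2 != 0 or self.n_regions < 2 * self.n_pairs_of_interest:
            raise SpecError(
                "n_regions must be even and at least 2 * n_pairs_of_interest"
            )
        lo, hi = self.age_range
        if not lo < hi:
            raise SpecError("age_range must be (min, max) with min < max")
        if self.n_sites <= 0 or self.n_timepoints <= 0:
            raise SpecError("n_sites and n_timepoints must be positive")
        if not lo < self.crossover_age < hi:
            raise SpecError("crossover_age must lie inside age_range")
        if self.cluster_assignment is None:
            self.cluster_assignment = self._default_clusters()
        pairs = [f"pair{p:03d}" for p in range(self.n_pairs_of_interest)]
        assigned = set(self.cluster_assignment)
        if assigned != set(pairs):
            raise SpecError(
                "cluster_assignment must assign every pair of interest exactly once"
            )
        bad = set(self.cluster_assignment.values()) - set(CLUSTER_LABELS)
        if bad:
            raise SpecError(f"unknown cluster labels: {sorted(bad)}")

    def _default_clusters(self) -> dict[str, str]:
        # ~40% cluster1, ~40% cluster2, remainder null, deterministic
        k = self.n_pairs_of_interest
        n1 = max(1, round(0.4 * k))
        n2 = max(1, round(0.4 * k))
        labels = ["cluster1"] * n1 + ["cluster2"] * n2 + ["null"] * (k - n1 - n2)
        return {f"pair{p:03d}": labels[p] for p in range(k)}

    def atlas(self) -> pd.DataFrame:
        return make_atlas(self.n_regions, self.n_pairs_of_interest)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        d["behavior_weights"] = list(self.behavior_weights)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "behavior_weights" in d:
            d["behavior_weights"] = tuple(d["behavior_weights"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Record of everything planted in a synthetic cohort."""

    spec: CohortSpec
    #: base gradient position (0-100) per pair, shared by both hemispheres
    pair_positions: dict[str, float]
    #: cluster label per pair of interest
    cluster_labels: dict[str, str]
    crossover_age: float
    #: subject-level latent brain-mode score, index = subject id
    mode_scores: pd.Series
    #: signed brain-mode weight per pair of interest (gradient units)
    mode_weights: dict[str, float]
    behavior_weights: np.ndarray
    #: shape-curve coefficient (0 when crossover is the age-range midpoint)
    shape_gamma: float
    #: per subject x region planted position at the subject's age
    loadings: pd.DataFrame | None = None

    def asymmetry_curve(self, pair_id: str, ages: np.ndarray) -> np.ndarray:
        """Planted left-minus-right gradient asymmetry of a pair vs age."""
        ages = np.asarray(ages, dtype=float)
        label = self.cluster_labels.get(pair_id)
        if label is None or label == "null":
            return np.full(ages.shape, self.spec.null_pair_asymmetry)
        u = _shape_curve(ages, self.crossover_age, self.shape_gamma, self.spec.age_range)
        half = self.spec.effect_size / 2.0
        return -half * u if label == "cluster1" else half * u

    def region_position(
        self, pair_id: str, hemisphere: str, ages: np.ndarray
    ) -> np.ndarray:
        """Planted gradient position of one region of a pair vs age."""
        ages = np.asarray(ages, dtype=float)
        base = self.pair_positions[pair_id]
        asym = self.asymmetry_curve(pair_id, ages)
        label = self.cluster_labels.get(pair_id)
        if label == "cluster1":
            # right hemisphere moves, left stays
            return np.full(ages.shape, base) if hemisphere == "L" else base - asym
        if label == "cluster2":
            return base + asym if hemisphere == "L" else np.full(ages.shape, base)
        sign = 1.0 if hemisphere == "L" else -1.0
        return base + sign * asym / 2.0

    def to_json(self) -> str:
        d = {
            "spec": self.spec.to_dict(),
            "pair_positions": self.pair_positions,
            "cluster_labels": self.cluster_labels,
            "crossover_age": self.crossover_age,
            "mode_scores": self.mode_scores.to_dict(),
            "mode_weights": self.mode_weights,
            "behavior_weights": self.behavior_weights.tolist(),
            "shape_gamma": self.shape_gamma,
        }
        return json.dumps(d, sort_keys=True, indent=1)


def _shape_curve(
    ages: np.ndarray, crossover: float, gamma: float, age_range: tuple[float, float]
) -> np.ndarray:
    """Mean-zero drift shape with a single root at the crossover age.

    ``u(a) = (a - c) + gamma (a - c)^2`` with gamma chosen (at spec build
    time) so the integral of u over the age range vanishes; scaled to max
    absolute value 1.  Mean-zero matters because downstream trajectories are
    demeaned before cluster-mean intersection is located.
    """
    lo, hi = age_range
    a = np.asarray(ages, dtype=float)
    u = (a - crossover) + gamma * (a - crossover) ** 2
    grid = np.linspace(lo, hi, 512)
    ug = (grid - crossover) + gamma * (grid - crossover) ** 2
    return u / np.max(np.abs(ug))


def _solve_shape_gamma(crossover: float, age_range: tuple[float, float]) -> float:
    lo, hi = age_range
    if not lo < crossover < hi:
        raise SpecError("crossover_age must lie inside age_range")
    m1 = ((hi - crossover) ** 2 - (lo - crossover) ** 2) / 2.0
    m2 = ((hi - crossover) ** 3 - (lo - crossover) ** 3) / 3.0
    gamma = -m1 / m2
    # second root of u is at c - 1/gamma; it must fall outside the age range
    if gamma != 0.0:
        other = crossover - 1.0 / gamma
        if lo <= other <= hi:
            raise SpecError(
                "crossover_age too close to the age-range boundary for a "
                "single-crossing drift shape"
            )
    return gamma


def _mode_scores(spec: CohortSpec, subject_ids: list[str]) -> pd.Series:
    rng = np.random.default_rng([spec.seed, _STREAM_MODE])
    z = rng.standard_normal(len(subject_ids))
    return pd.Series(z, index=subject_ids, name="mode_score")


def _pair_positions(spec: CohortSpec) -> dict[str, float]:
    """Deterministic base gradient positions, one per homotopic pair.

    Positions are evenly spaced over [0, 100], giving a uniform sampling of
    the unimodal-to-transmodal continuum (which keeps the recovered
    diffusion coordinate close to linear in the planted position).  Pairs
    of interest take the most central slots — where that mapping is most
    uniform, so planted asymmetry drifts translate into comparable
    trajectory amplitudes — while filler pairs extend to the gradient
    poles and anchor per-subject min-max normalization.  Within the pairs
    of interest, slots alternate round-robin across the cluster labels so
    every cluster spans the occupied range.
    """
    n_pairs = spec.n_regions // 2
    pos = np.linspace(0.0, 100.0, n_pairs) if n_pairs > 1 else np.array([50.0])
    order = np.argsort(np.abs(pos - 50.0), kind="stable")
    interest = [f"pair{p:03d}" for p in range(spec.n_pairs_of_interest)]
    filler = [f"pair{p:03d}" for p in range(spec.n_pairs_of_interest, n_pairs)]
    by_cluster: dict[str, list[str]] = {c: [] for c in CLUSTER_LABELS}
    for p in interest:
        by_cluster[spec.cluster_assignment[p]].append(p)
    round_robin: list[str] = []
    queues = [list(v) for v in by_cluster.values() if v]
    while any(queues):
        for q in queues:
            if q:
                round_robin.append(q.pop(0))
    positions: dict[str, float] = {}
    for slot, pair in zip(order[: len(round_robin)], round_robin):
        positions[pair] = float(pos[slot])
    for slot, pair in zip(order[len(round_robin):], filler):
        positions[pair] = float(pos[slot])
    return positions


def build_ground_truth(spec: CohortSpec, phenotype: pd.DataFrame | None = None) -> GroundTruth:
    """Assemble the planted-truth record for a spec (and optionally the
    per-subject planted loadings at each subject's age)."""
    gamma = _solve_shape_gamma(spec.crossover_age, spec.age_range)
    positions = _pair_positions(spec)
    clusters = dict(spec.cluster_assignment)
    weights = {}
    for pair, label in clusters.items():
        if label == "cluster1":
            weights[pair] = spec.mode_strength
        elif label == "cluster2":
            weights[pair] = -spec.mode_strength
        else:
            weights[pair] = 0.0
    subject_ids = (
        list(phenotype["subject_id"]) if phenotype is not None else
        [f"sub{i:04d}" for i in range(spec.n_subjects)]
    )
    gt = GroundTruth(
        spec=spec,
        pair_positions=positions,
        cluster_labels=clusters,
        crossover_age=spec.crossover_age,
        mode_scores=_mode_scores(spec, subject_ids),
        mode_weights=weights,
        behavior_weights=np.asarray(spec.behavior_weights, dtype=float),
        shape_gamma=gamma,
    )
    if phenotype is not None:
        gt.loadings = _subject_loadings(spec, gt, phenotype)
    return gt


def _subject_loadings(
    spec: CohortSpec, gt: GroundTruth, phenotype: pd.DataFrame
) -> pd.DataFrame:
    atlas = spec.atlas()
    ages = phenotype["age"].to_numpy(dtype=float)
    z = gt.mode_scores.loc[phenotype["subject_id"]].to_numpy()
    jitter_rng = np.random.default_rng([spec.seed, _STREAM_JITTER])
    jitter = jitter_rng.normal(
        0.0, spec.position_jitter_sd, (len(phenotype), len(atlas))
    )
    cols = {}
    for j, (_, row) in enumerate(atlas.iterrows()):
        pos = gt.region_position(row["pair_id"], row["hemisphere"], ages)
        w = gt.mode_weights.get(row["pair_id"], 0.0)
        sign = 0.5 if row["hemisphere"] == "L" else -0.5
        cols[row["region_id"]] = np.clip(pos + sign * w * z + jitter[:, j], 0.0, 100.0)
    return pd.DataFrame(cols, index=pd.Index(phenotype["subject_id"], name="subject_id"))


# ---------------------------------------------------------------------------
# generators


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Phenotype table: subject id, age, sex, site, MMSE.

    Ages are uniform over the age range (trajectory fits are then equally
    constrained everywhere); MMSE is drawn from a truncated distribution
    concentrated at 28-30, as in a healthy adult screening sample.
    """
    rng = np.random.default_rng([spec.seed, _STREAM_COHORT])
    n = spec.n_subjects
    lo, hi = spec.age_range
    mmse_support = np.arange(24, 31)
    mmse_probs = np.array([0.01, 0.01, 0.02, 0.06, 0.25, 0.30, 0.35])
    return pd.DataFrame(
        {
            "subject_id": [f"sub{i:04d}" for i in range(n)],
            "age": rng.uniform(lo, hi, n),
            "sex": rng.choice(["F", "M"], n),
            "site": rng.integers(1, spec.n_sites + 1, n),
            "mmse": rng.choice(mmse_support, n, p=mmse_probs / mmse_probs.sum()),
        }
    )


def generate_regional_timeseries(
    spec: CohortSpec,
    phenotype: pd.DataFrame,
    ground_truth: GroundTruth | None = None,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Per-subject regional time-series tables (timepoints x regions).

    Each region's series is a planted-angle mixture of two shared latent
    series plus independent Gaussian noise; see the module docstring.
    """
    import warnings

    if ground_truth is None:
        ground_truth = build_ground_truth(spec, phenotype)
    elif ground_truth.loadings is None:
        ground_truth.loadings = _subject_loadings(spec, ground_truth, phenotype)
    if spec.n_timepoints < spec.n_regions + 1:
        warnings.warn(
            "n_timepoints < n_regions + 1: subject correlation matrices will "
            "be rank deficient",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng([spec.seed, _STREAM_TIMESERIES])
    region_ids = list(ground_truth.loadings.columns)
    out: dict[str, pd.DataFrame] = {}
    for sid in phenotype["subject_id"]:
        g = ground_truth.loadings.loc[sid].to_numpy()
        theta = g / 100.0 * (np.pi / 2.0)
        latents = rng.standard_normal((spec.n_timepoints, 2))
        signal = latents @ np.vstack([np.cos(theta), np.sin(theta)])
        noise = spec.noise_sd * rng.standard_normal((spec.n_timepoints, len(theta)))
        out[sid] = pd.DataFrame(signal + noise, columns=region_ids)
    return out, ground_truth


def generate_volumes(
    spec: CohortSpec,
    phenotype: pd.DataFrame,
    ground_truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Regional volume table (one row per subject, wide) plus TIV.

    Volumes are lognormal around a per-pair typical size; pairs of interest
    carry a planted leftward normalized-volume asymmetry plus a brain-mode
    component shared with behavior.
    """
    if ground_truth is None:
        ground_truth = build_ground_truth(spec, phenotype)
    rng = np.random.default_rng([spec.seed, _STREAM_VOLUMES])
    atlas = spec.atlas()
    n = len(phenotype)
    z = ground_truth.mode_scores.loc[phenotype["subject_id"]].to_numpy()
    tiv = np.exp(rng.normal(np.log(1.45e6), 0.08, n))
    data: dict[str, np.ndarray] = {"subject_id": phenotype["subject_id"].to_numpy(), "tiv": tiv}
    interest = set(pairs_of_interest(atlas))
    pair_ids = sorted(atlas["pair_id"].unique())
    for k, pair in enumerate(pair_ids):
        base = 2500.0 * (1.0 + 0.5 * np.sin(1.0 + 2.1 * k))  # typical pair size, mm^3
        subject_base = base * np.exp(rng.normal(0.0, 0.10, n))
        if pair in interest:
            asym = spec.volume_asymmetry + spec.volume_mode_strength * z
        else:
            asym = np.zeros(n)
        asym = asym + rng.normal(0.0, 2e-4, n)  # measurement noise, normalized units
        v_left = subject_base + asym * tiv / 2.0
        v_right = subject_base - asym * tiv / 2.0
        data[f"{pair}L"] = np.maximum(v_left, 1.0)
        data[f"{pair}R"] = np.maximum(v_right, 1.0)
    return pd.DataFrame(data)


def generate_behavior(
    spec: CohortSpec,
    phenotype: pd.DataFrame,
    ground_truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Four language scores linearly coupled to the latent brain mode.

    All scores are oriented so that values near zero mean worse performance
    (reaction-time-like scores are stored already inverted).
    """
    if ground_truth is None:
        ground_truth = build_ground_truth(spec, phenotype)
    rng = np.random.default_rng([spec.seed, _STREAM_BEHAVIOR])
    z = ground_truth.mode_scores.loc[phenotype["subject_id"]].to_numpy()
    w = ground_truth.behavior_weights
    n = len(phenotype)
    scores = np.outer(z, w) + spec.behavior_noise_sd * rng.standard_normal((n, len(w)))
    out = pd.DataFrame(scores, columns=BEHAVIOR_COLUMNS[: len(w)])
    out.insert(0, "subject_id", phenotype["subject_id"].to_numpy())
    return out


@dataclass
class CohortData:
    """Bundle of all simulated inputs plus the planted truth."""

    spec: CohortSpec
    atlas: pd.DataFrame
    phenotype: pd.DataFrame
    timeseries: dict[str, pd.DataFrame]
    volumes: pd.DataFrame
    behavior: pd.DataFrame
    ground_truth: GroundTruth


def simulate_cohort(spec: CohortSpec) -> CohortData:
    """Run every generator and return the full synthetic dataset."""
    phenotype = generate_cohort(spec)
    ground_truth = build_ground_truth(spec, phenotype)
    timeseries, ground_truth = generate_regional_timeseries(spec, phenotype, ground_truth)
    volumes = generate_volumes(spec, phenotype, ground_truth)
    behavior = generate_behavior(spec, phenotype, ground_truth)
    return CohortData(
        spec=spec,
        atlas=spec.atlas(),
        phenotype=phenotype,
        timeseries=timeseries,
        volumes=volumes,
        behavior=behavior,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# direct per-pair harness (bypasses the imaging pipeline)


def generate_pair_long_table(
    n_subjects: int,
    f_left: Callable[[np.ndarray], np.ndarray],
    f_right: Callable[[np.ndarray], np.ndarray],
    subject_sd: float = 1.0,
    noise_sd: float = 1.0,
    age_range: tuple[float, float] = (18.0, 88.0),
    n_sites: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Long table (two rows per subject) for a single homotopic pair.

    ``value = f_hemi(age) + subject intercept + noise``; used by trajectory
    calibration and power simulations where the imaging pipeline is not the
    object under test.
    """
    rng = np.random.default_rng(seed)
    ages = rng.uniform(age_range[0], age_range[1], n_subjects)
    sex = rng.choice(["F", "M"], n_subjects)
    site = rng.integers(1, n_sites + 1, n_subjects)
    b = rng.normal(0.0, subject_sd, n_subjects)
    rows = []
    for hemi, f in (("L", f_left), ("R", f_right)):
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": [f"sub{i:04d}" for i in range(n_subjects)],
                    "hemisphere": hemi,
                    "age": ages,
                    "sex": sex,
                    "site": site,
                    "value": f(ages) + b + rng.normal(0.0, noise_sd, n_subjects),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# direct CCA harness (bypasses the imaging pipeline)


def generate_cca_dataset(
    n: int,
    weights_x: np.ndarray,
    weights_y: np.ndarray,
    target_r: float,
    noise_x: float = 1.0,
    noise_y: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Two variable sets sharing one latent mode with a known population
    canonical correlation.

    ``x = a u + Ex`` and ``y = b v + Ey`` with corr(u, v) chosen in closed
    form so the population first canonical correlation equals ``target_r``:
    for isotropic noise the attainable maximum is
    ``m_x m_y = sqrt(|a|^2/(|a|^2+sx^2)) * sqrt(|b|^2/(|b|^2+sy^2))``,
    and corr(u, v) = target_r / (m_x m_y).

    Returns (x, y, latent_corr_used).
    """
    a = np.asarray(weights_x, dtype=float)
    b = np.asarray(weights_y, dtype=float)
    m_x = np.sqrt(a @ a / (a @ a + noise_x**2))
    m_y = np.sqrt(b @ b / (b @ b + noise_y**2))
    rho = target_r / (m_x * m_y)
    if not 0.0 <= rho <= 1.0:
        raise SpecError(
            f"target_r={target_r} unattainable with these weights/noise "
            f"(max {m_x * m_y:.3f})"
        )
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n)
    v = rho * u + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    x = np.outer(u, a) + noise_x * rng.standard_normal((n, a.size))
    y = np.outer(v, b) + noise_y * rng.standard_normal((n, b.size))
    return x, y, float(rho)
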