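"""Synthetic staged vessel-profile studies.

Emulates the statistical structure of a wheel-throwing field study: a small
number of expert potters from two workshop communities each throw several
specimens of shared traditional vessel types.  Each trial is a sequence of
*stages* — the clay outline after each fashioning gesture — starting from a
potter-specific pre-formed shape (t = 0) and converging onto the shared
type-specific final form carrying only a small individual signature.

Profiles come from a parametric superellipse family: the radius r(y) rises
from the base radius to the maximal diameter (at a controllable relative
height) and falls to the aperture radius, with a bulge exponent controlling
wall curvature (2 = circular arcs, large = near-cylindrical) and an optional
rim groove just below the lip.  At bulge_exponent = 2 with on-axis ends the
family reproduces a sphere exactly, which anchors closed-form geometry
checks.

Morphogenesis routes are piecewise-linear paths through parameter space from
the pre-form through idiosyncratic waypoints to the potter's personal final
target (shared final times a small multiplicative signature).  Stage-level
trial noise is multiplicative Gaussian on the parameters, truncated to the
valid domain; inter-gesture times are gamma distributed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .outline import Profile

__all__ = [
    "VesselParams",
    "PotterArchetype",
    "StudyConfig",
    "TrialStage",
    "Trial",
    "StudyDataset",
    "ParameterError",
    "ConfigurationError",
    "make_profile",
    "simulate_trial",
    "simulate_study",
    "default_study_config",
    "write_dataset",
    "dataset_to_frame",
]

GENERATOR_VERSION = "1.0"

_PARAM_FIELDS = (
    "height_cm",
    "max_diameter_cm",
    "max_diameter_rel_height",
    "aperture_radius_cm",
    "base_radius_cm",
    "bulge_exponent",
    "rim_depth_cm",
)


class ParameterError(ValueError):
    """A vessel parameter violates its domain invariant."""


class ConfigurationError(ValueError):
    """An invalid study configuration (e.g. duplicate potter ids)."""


@dataclass(frozen=True)
class VesselParams:
    """Parametric description of an axisymmetric vessel form.

    All lengths in cm.  ``max_diameter_rel_height`` is the fraction of the
    total height at which the diameter is maximal; ``bulge_exponent``
    controls wall curvature between base, belly and aperture (2 gives
    circular arcs, larger values flatten towards a cylinder);
    ``rim_depth_cm`` is the depth of the groove under the lip.
    """

    height_cm: float
    max_diameter_cm: float
    max_diameter_rel_height: float
    aperture_radius_cm: float
    base_radius_cm: float
    bulge_exponent: float = 2.0
    rim_depth_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.height_cm <= 0:
            raise ParameterError("height_cm must be > 0")
        if self.max_diameter_cm <= 0:
            raise ParameterError("max_diameter_cm must be > 0")
        if not (0.0 < self.max_diameter_rel_height < 1.0):
            raise ParameterError("max_diameter_rel_height must lie in (0, 1)")
        r_max = self.max_diameter_cm / 2.0
        if self.aperture_radius_cm < 0 or self.aperture_radius_cm > r_max + 1e-9:
            raise ParameterError("aperture_radius_cm must lie in [0, max_diameter_cm/2]")
        if self.base_radius_cm < 0 or self.base_radius_cm > r_max + 1e-9:
            raise ParameterError("base_radius_cm must lie in [0, max_diameter_cm/2]")
        if self.bulge_exponent <= 0:
            raise ParameterError("bulge_exponent must be > 0")
        if self.rim_depth_cm < 0:
            raise ParameterError("rim_depth_cm must be >= 0")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _PARAM_FIELDS], dtype=float)

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "VesselParams":
        v = _clip_to_domain(np.asarray(v, dtype=float))
        return cls(**dict(zip(_PARAM_FIELDS, v)))


def _clip_to_domain(v: np.ndarray) -> np.ndarray:
    """Truncate a raw parameter vector into the valid domain."""
    v = v.copy()
    v[0] = max(v[0], 1e-3)                    # height
    v[1] = max(v[1], 1e-3)                    # max diameter
    v[2] = float(np.clip(v[2], 0.02, 0.98))   # relative belly height
    r_max = v[1] / 2.0
    v[3] = float(np.clip(v[3], 0.0, r_max))   # aperture radius
    v[4] = float(np.clip(v[4], 0.0, r_max))   # base radius
    v[5] = max(v[5], 0.2)                     # bulge exponent
    v[6] = max(v[6], 0.0)                     # rim depth
    return v


@dataclass(frozen=True)
class PotterArchetype:
    """An individual potter's morphogenesis style.

    ``route_waypoints`` are idiosyncratic intermediate shape targets visited
    on the way from the pre-form to the final form; ``final_offset_scale``
    sets the relative size of the potter's fixed signature on the shared
    final shape; ``trial_noise_scale`` the relative stage-to-stage trial
    noise; ``gesture_interval_s`` the (shape, scale) of the gamma
    distribution of inter-gesture times.
    """

    potter_id: str
    community: str
    preform_params: VesselParams
    route_waypoints: tuple[VesselParams, ...] = ()
    n_gestures_range: tuple[int, int] = (6, 9)
    gesture_interval_s: tuple[float, float] = (6.0, 2.0)
    final_offset_scale: float = 0.04
    trial_noise_scale: float = 0.035

    def __post_init__(self) -> None:
        lo, hi = self.n_gestures_range
        if not (3 <= lo <= hi <= 20):
            raise ParameterError("n_gestures_range must lie within [3, 20]")
        if self.final_offset_scale < 0 or self.trial_noise_scale < 0:
            raise ParameterError("noise scales must be >= 0")
        if min(self.gesture_interval_s) <= 0:
            raise ParameterError("gesture_interval_s (shape, scale) must be positive")


@dataclass(frozen=True)
class StudyConfig:
    """Full factorial design: every archetype throws every vessel type
    ``n_trials_per_type`` times."""

    vessel_types: tuple[tuple[str, VesselParams], ...]
    archetypes: tuple[PotterArchetype, ...]
    n_trials_per_type: int = 5
    profile_points: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_type < 2:
            raise ConfigurationError("n_trials_per_type must be >= 2")
        if len(self.archetypes) < 2:
            raise ConfigurationError("need at least 2 archetypes")
        ids = [a.potter_id for a in self.archetypes]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate potter_id in archetypes: {ids}")
        if len(self.vessel_types) < 1:
            raise ConfigurationError("need at least one vessel type")


@dataclass(frozen=True)
class TrialStage:
    gesture_index: int
    time_s: float
    profile: Profile
    params: VesselParams | None = None


@dataclass(frozen=True)
class Trial:
    """One vessel throw: ordered stages from pre-form (t = 0) to final."""

    trial_id: str
    potter_id: str
    community: str
    vessel_type: str
    stages: tuple[TrialStage, ...]

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ParameterError("a trial needs at least 2 stages")
        gi = [s.gesture_index for s in self.stages]
        ts = [s.time_s for s in self.stages]
        if gi[0] != 0 or any(b <= a for a, b in zip(gi, gi[1:])):
            raise ParameterError("gesture_index must increase strictly from 0")
        if ts[0] != 0.0 or any(b <= a for a, b in zip(ts, ts[1:])):
            raise ParameterError("stage times must increase strictly from 0")

    @property
    def n_gestures(self) -> int:
        return self.stages[-1].gesture_index

    @property
    def duration_s(self) -> float:
        return self.stages[-1].time_s


@dataclass(frozen=True)
class StudyDataset:
    trials: tuple[Trial, ...]
    config: StudyConfig
    provenance: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# profile family


def make_profile(params: VesselParams, n_points: int = 256) -> Profile:
    """Evaluate the superellipse radius function of a vessel form.

    Returns ``n_points`` points ordered from the base (y = 0) to the rim
    (y = height).  The radius equals ``max_diameter/2`` exactly at the belly
    height and ``aperture_radius`` at the top.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    h = params.height_cm
    r_max = params.max_diameter_cm / 2.0
    y_b = params.max_diameter_rel_height * h
    k = params.bulge_exponent
    y = np.linspace(0.0, h, n_points)
    r = np.empty_like(y)

    lower = y <= y_b
    u = np.clip(y[lower] / y_b, 0.0, 1.0)
    r[lower] = params.base_radius_cm + (r_max - params.base_radius_cm) * (
        1.0 - (1.0 - u) ** k
    ) ** (1.0 / k)
    upper = ~lower
    v = np.clip((y[upper] - y_b) / (h - y_b), 0.0, 1.0)
    r[upper] = params.aperture_radius_cm + (r_max - params.aperture_radius_cm) * (
        1.0 - v**k
    ) ** (1.0 / k)

    if params.rim_depth_cm > 0:
        # inward groove under the lip, vanishing at the rim itself
        y_r = h * 0.92
        w = np.clip((y - y_r) / (h - y_r), 0.0, 1.0)
        r = r - params.rim_depth_cm * np.sin(np.pi * w)
    return Profile(x=np.maximum(r, 0.0), y=y)


# --------------------------------------------------------------------------
# trial and study simulation


def _potter_signature(potter_id: str, scale: float) -> np.ndarray:
    """Fixed multiplicative signature a potter imprints on the final form.

    Deterministic in the potter id so that it is identical across trials
    and studies — it is part of the potter's identity, not of trial noise.
    The signature combines a common size factor (potters work with
    self-selected quantities of clay, so final *size* varies much more
    between potters than final shape) with small per-parameter shape
    offsets of relative magnitude ``scale``; the size component has three
    times that spread and multiplies all length parameters equally, so it
    leaves the normalized shape untouched.
    """
    seed = int.from_bytes(
        hashlib.blake2s(potter_id.encode(), digest_size=4).digest(), "big"
    )
    rng = np.random.default_rng(seed)
    size_factor = float(np.exp(3.0 * scale * rng.standard_normal()))
    z = rng.standard_normal(len(_PARAM_FIELDS))
    sig = 1.0 + scale * z
    sig[2] = 1.0 + 0.5 * scale * z[2]  # relative belly height: shape only, keep subtle
    for i in (0, 1, 3, 4, 6):  # all length parameters share the size factor
        sig[i] *= size_factor
    return sig


def _interpolate_path(controls: list[np.ndarray], u: float) -> np.ndarray:
    """Piecewise-linear interpolation through control parameter vectors."""
    m = len(controls) - 1
    if m == 0:
        return controls[0]
    s = u * m
    j = min(int(np.floor(s)), m - 1)
    frac = s - j
    return (1.0 - frac) * controls[j] + frac * controls[j + 1]


def trial_seed(config_seed: int, potter_id: str, vessel_type: str, trial_index: int) -> int:
    """Deterministic per-trial seed from study seed and trial identity."""
    key = f"{config_seed}|{potter_id}|{vessel_type}|{trial_index}".encode()
    return int.from_bytes(hashlib.blake2s(key, digest_size=4).digest(), "big") % (2**31)


def simulate_trial(
    arch: PotterArchetype,
    final: VesselParams,
    seed: int,
    n_points: int = 256,
    vessel_type: str = "vessel",
    trial_id: str | None = None,
) -> Trial:
    """Simulate one throw: pre-form -> waypoints -> potter's final target.

    Stage 0 is the pre-formed shape at t = 0; each subsequent stage is the
    outline after one fashioning gesture.  The same seed yields an
    identical trial.
    """
    rng = np.random.default_rng(seed)
    n_g = int(rng.integers(arch.n_gestures_range[0], arch.n_gestures_range[1] + 1))
    shape_p, scale_p = arch.gesture_interval_s
    intervals = np.maximum(rng.gamma(shape_p, scale_p, size=n_g), 1e-3)
    times = np.concatenate([[0.0], np.cumsum(intervals)])

    target = _clip_to_domain(
        final.as_vector() * _potter_signature(arch.potter_id, arch.final_offset_scale)
    )
    controls = (
        [arch.preform_params.as_vector()]
        + [w.as_vector() for w in arch.route_waypoints]
        + [target]
    )
    stages = []
    for j in range(n_g + 1):
        u = j / n_g
        v = _interpolate_path(controls, u)
        if arch.trial_noise_scale > 0:
            v = v * (1.0 + arch.trial_noise_scale * rng.standard_normal(v.size))
        params = VesselParams.from_vector(v)
        stages.append(
            TrialStage(
                gesture_index=j,
                time_s=float(times[j]),
                profile=make_profile(params, n_points=n_points),
                params=params,
            )
        )
    return Trial(
        trial_id=trial_id or f"{arch.potter_id}-{vessel_type}-s{seed}",
        potter_id=arch.potter_id,
        community=arch.community,
        vessel_type=vessel_type,
        stages=tuple(stages),
    )


def simulate_study(config: StudyConfig) -> StudyDataset:
    """Simulate the full factorial study described by ``config``."""
    trials = []
    for type_label, final in config.vessel_types:
        for arch in config.archetypes:
            for i in range(config.n_trials_per_type):
                s = trial_seed(config.seed, arch.potter_id, type_label, i)
                trials.append(
                    simulate_trial(
                        arch,
                        final,
                        seed=s,
                        n_points=config.profile_points,
                        vessel_type=type_label,
                        trial_id=f"{arch.potter_id}-{type_label}-t{i + 1}",
                    )
                )
    return StudyDataset(
        trials=tuple(trials),
        config=config,
        provenance={"seed": config.seed, "generator_version": GENERATOR_VERSION},
    )


# --------------------------------------------------------------------------
# default study: seven potters, two workshop communities


def _vp(h, md, rel, ap, base, k, rim) -> VesselParams:
    return VesselParams(h, md, rel, ap, base, k, rim)


def default_archetypes() -> tuple[PotterArchetype, ...]:
    """Seven expert potters, four from a stick-wheel workshop (PR) and three
    from a kick-wheel workshop (MK), with distinctive pre-forms and routes:
    near-cylindrical starts, elongated or wide barrels, an early
    sphere-like start with a wide rimmed aperture, and one potter who
    approaches the final form almost immediately."""
    return (
        PotterArchetype(
            "GA", "PR", _vp(10.0, 11.0, 0.50, 5.2, 5.2, 8.0, 0.35),
            route_waypoints=(_vp(13.0, 12.0, 0.52, 4.5, 4.8, 4.0, 0.3),),
            n_gestures_range=(6, 9), gesture_interval_s=(6.0, 2.2),
        ),
        PotterArchetype(
            "KA", "PR", _vp(13.0, 10.0, 0.50, 4.0, 4.5, 3.0, 0.2),
            n_gestures_range=(6, 9), gesture_interval_s=(6.0, 2.4),
        ),
        PotterArchetype(
            "BA", "PR", _vp(9.0, 11.5, 0.45, 5.0, 5.0, 5.0, 0.3),
            n_gestures_range=(8, 12), gesture_interval_s=(6.0, 2.6),
        ),
        PotterArchetype(
            "AR", "PR", _vp(12.0, 12.5, 0.50, 3.5, 4.5, 2.5, 0.3),
            n_gestures_range=(5, 6), gesture_interval_s=(6.0, 1.9),
        ),
        PotterArchetype(
            "KD", "MK", _vp(9.5, 13.5, 0.50, 5.5, 5.5, 6.0, 0.2),
            route_waypoints=(_vp(12.0, 13.8, 0.48, 4.0, 5.0, 4.0, 0.25),),
            n_gestures_range=(6, 8), gesture_interval_s=(6.0, 1.6),
        ),
        PotterArchetype(
            "NA", "MK", _vp(10.5, 10.5, 0.50, 4.8, 4.8, 6.0, 0.2),
            n_gestures_range=(6, 9), gesture_interval_s=(6.0, 2.0),
        ),
        PotterArchetype(
            "YA", "MK", _vp(12.0, 14.5, 0.42, 6.0, 5.0, 2.5, 0.6),
            route_waypoints=(_vp(14.5, 15.5, 0.45, 4.5, 4.8, 2.2, 0.5),),
            n_gestures_range=(10, 11), gesture_interval_s=(6.0, 1.8),
        ),
    )


def default_vessel_types() -> tuple[tuple[str, VesselParams], ...]:
    """Shared final targets; the money-bank is a near-spherical closed form
    with a narrow aperture."""
    return (
        ("money-bank", _vp(15.8, 13.7, 0.55, 1.8, 4.0, 2.2, 0.25)),
    )


def default_study_config(
    seed: int = 0,
    n_trials_per_type: int = 5,
    profile_points: int = 256,
    vessel_types: tuple[tuple[str, VesselParams], ...] | None = None,
) -> StudyConfig:
    """The default study: 7 potters x 5 trials per vessel type."""
    return StudyConfig(
        vessel_types=vessel_types or default_vessel_types(),
        archetypes=default_archetypes(),
        n_trials_per_type=n_trials_per_type,
        profile_points=profile_points,
        seed=seed,
    )


# --------------------------------------------------------------------------
# serialization


def dataset_to_frame(ds: StudyDataset) -> pd.DataFrame:
    """Long-format profile points: one row per digitised point."""
    rows = []
    for tr in ds.trials:
        for st in tr.stages:
            n = st.profile.n_points
            rows.append(
                pd.DataFrame(
                    {
                        "trial_id": tr.trial_id,
                        "stage_index": st.gesture_index,
                        "time_s": st.time_s,
                        "point_index": np.arange(n),
                        "x_cm": st.profile.x,
                        "y_cm": st.profile.y,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def dataset_metadata(ds: StudyDataset) -> dict:
    meta = {
        "generator_version": ds.provenance.get("generator_version", GENERATOR_VERSION),
        "seed": ds.provenance.get("seed"),
        "n_trials": len(ds.trials),
        "trials": [
            {
                "trial_id": tr.trial_id,
                "potter_id": tr.potter_id,
                "community": tr.community,
                "vessel_type": tr.vessel_type,
                "n_gestures": tr.n_gestures,
                "duration_s": tr.duration_s,
                "stage_times_s": [s.time_s for s in tr.stages],
            }
            for tr in ds.trials
        ],
    }
    return meta


def write_dataset(ds: StudyDataset, csv_path, json_path) -> None:
    """Write the profile-point CSV and the trial metadata JSON."""
    dataset_to_frame(ds).to_csv(csv_path, index=False, float_format="%.17g")
    with open(json_path, "w") as fh:
        json.dump(dataset_metadata(ds), fh, indent=1, sort_keys=True)
        fh.write("\n")
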