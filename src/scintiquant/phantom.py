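"""Synthetic phantoms and cohorts with known ground truth.

Two generators make the whole pipeline testable without any patient data:

* :func:`render_phantom` draws the four planar views of a study as count
  grids: a flat soft-tissue background, one flat reference-bone patch per
  view (skull, sacrum, distal radius, distal tibia), and one Gaussian-profile
  hotspot per joint whose ROI mean — relative to the reference ROI mean — is
  *exactly* the requested target ratio in the noise-free image.  Optional
  Poisson noise draws each pixel independently with the noise-free value as
  its mean, the counting statistics of a gamma camera.

* :func:`simulate_cohort` draws a labelled per-joint cohort table: per-area
  Bernoulli affected flags, log-normal true uptake ratios per group
  (log-normal because ratios are positive and right-skewed), two readers'
  ordinal 1-3 grades from a latent-threshold model (true ratio plus Gaussian
  reader noise, cut at t1 < t2), per-reader measured ratios with small
  Gaussian measurement error, an X-ray erosion covariate, and rare
  arthroplasty exclusions.

Default cohort conditions reproduce the observed study structure: 93
patients, per-area affected prevalences, and per-group ratio means +/- SDs
(overall affected 1.79 +/- 0.95, nonaffected 1.06 +/- 0.64, prevalence 12.3%).
All randomness flows through explicit integer seeds; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .joint_schema import (
    AREAS,
    View,
    joints_for_view,
    list_joints,
    reference_bone_for,
)
from .quantify import SquareRoi
from .scintigram_io import PlanarScintigram, StudyBundle

__all__ = [
    "PhantomSpec",
    "PhantomStudy",
    "GroupMoments",
    "AreaCondition",
    "ReaderModel",
    "ErosionModel",
    "CohortSpec",
    "PhantomError",
    "fit_lognormal_from_moments",
    "lognormal_pair_auc",
    "render_phantom",
    "default_rois",
    "simulate_cohort",
    "TABLE_CONDITIONS",
]


class PhantomError(ValueError):
    pass


# ---------------------------------------------------------------------------
# log-normal moment fitting


def fit_lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Solve the unique log-normal (mu, sigma) with the given mean and SD.

    sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2; the round-trip
    moments match to ~1e-12 relative.
    """
    if not (mean > 0 and sd > 0):
        raise PhantomError("log-normal moment fit requires mean > 0 and sd > 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def lognormal_pair_auc(
    affected: "tuple[float, float]", nonaffected: "tuple[float, float]"
) -> float:
    """P(X > Y) for independent X ~ LN(affected), Y ~ LN(nonaffected).

    Both arguments are (mean, sd) on the natural scale.  log X - log Y is
    normal, so the probability has the closed form
    Phi((mu_x - mu_y) / sqrt(sg_x^2 + sg_y^2)) — the AUC a perfect scorer of
    the true ratio attains between the two groups.
    """
    mu_a, sg_a = fit_lognormal_from_moments(*affected)
    mu_n, sg_n = fit_lognormal_from_moments(*nonaffected)
    return float(norm.cdf((mu_a - mu_n) / math.hypot(sg_a, sg_n)))


# ---------------------------------------------------------------------------
# phantom image rendering


@dataclass(frozen=True)
class PhantomSpec:
    """Rendering parameters for one four-view phantom study.

    ``target_ratios`` maps joint_id -> desired joint-to-bone uptake ratio;
    joints not listed use ``default_ratio``.  Levels are counts/pixel.
    """

    patient_id: str = "phantom"
    background_level: float = 20.0
    bone_level: float = 400.0
    default_ratio: float = 1.0
    target_ratios: Mapping[str, float] = field(default_factory=dict)
    blob_sigma_px: float = 3.0
    poisson_noise: bool = False
    seed: int = 0
    exclusions: frozenset = frozenset()
    anterior_shape: tuple[int, int] = (1024, 256)
    spot_shape: tuple[int, int] = (256, 256)
    joint_half_width: int = 5
    digit_half_width: int = 2

    def __post_init__(self) -> None:
        if not (self.background_level > 0 and self.bone_level > 0):
            raise PhantomError("background_level and bone_level must be positive")
        ratios = dict(self.target_ratios)
        known = {j.joint_id for j in list_joints()}
        for jid, r in ratios.items():
            if jid not in known:
                raise PhantomError(f"target_ratios references unknown joint_id {jid!r}")
            if r < 0:
                raise PhantomError("target ratios must be nonnegative")
        if self.default_ratio < 0:
            raise PhantomError("default_ratio must be nonnegative")

    def ratio_for(self, joint_id: str) -> float:
        return float(self.target_ratios.get(joint_id, self.default_ratio))


class PhantomStudy(NamedTuple):
    bundle: StudyBundle
    rois: list[SquareRoi]
    truth: pd.DataFrame  # joint_id, target_ratio, excluded


# Fixed, deliberately schematic ROI layout (row, col) per view.  Positions
# only need to be disjoint and in-bounds; anatomical realism is a non-goal.
def _layout(spec: PhantomSpec) -> dict[View, dict[str, tuple[int, int, int]]]:
    hw, dw = spec.joint_half_width, spec.digit_half_width
    right_cols = [30, 52, 74, 96, 118]
    left_cols = [138, 160, 182, 204, 226]

    def digits(area: str, row: int, ds: "list[int]") -> dict[str, tuple[int, int, int]]:
        out = {}
        for i, d in enumerate(ds):
            out[f"{area}_R{d}"] = (row, right_cols[i], dw)
            out[f"{area}_L{d}"] = (row, left_cols[i], dw)
        return out

    anterior: dict[str, tuple[int, int, int]] = {
        "skull": (60, 128, hw),
        "shoulder_R": (160, 64, hw),
        "shoulder_L": (160, 192, hw),
        "sternoclavicular_R": (200, 104, hw),
        "sternoclavicular_L": (200, 152, hw),
        "elbow_R": (330, 48, hw),
        "elbow_L": (330, 208, hw),
        "knee_R": (700, 88, hw),
        "knee_L": (700, 168, hw),
    }
    pelvis: dict[str, tuple[int, int, int]] = {
        "sacrum": (128, 128, hw),
        "sacroiliac_R": (120, 88, hw),
        "sacroiliac_L": (120, 168, hw),
    }
    feet: dict[str, tuple[int, int, int]] = {
        "distal_tibia": (30, 128, hw),
        "ankle_R": (64, 80, hw),
        "ankle_L": (64, 176, hw),
        "tarsal_R": (96, 80, hw),
        "tarsal_L": (96, 176, hw),
    }
    feet.update(digits("mtp", 150, [1, 2, 3, 4, 5]))
    feet.update(digits("toe_ip", 190, [1, 2, 3, 4, 5]))
    hands: dict[str, tuple[int, int, int]] = {
        "distal_radius": (36, 128, hw),
        "wrist_R": (72, 70, hw),
        "wrist_L": (72, 186, hw),
        "thumb_ip_R1": (170, 16, dw),
        "thumb_ip_L1": (170, 240, dw),
    }
    hands.update(digits("mcp", 120, [1, 2, 3, 4, 5]))
    hands.update({k: v for k, v in digits("hand_pip", 170, [2, 3, 4, 5]).items()})
    hands.update({k: v for k, v in digits("hand_dip", 200, [2, 3, 4, 5]).items()})
    return {
        View.ANTERIOR_WHOLE_BODY: anterior,
        View.POSTERIOR_PELVIS: pelvis,
        View.FEET_SPOT: feet,
        View.HANDS_SPOT: hands,
    }


def default_rois(spec: PhantomSpec | None = None, patient_id: str | None = None) -> list[SquareRoi]:
    """The ROI table matching the fixed phantom layout."""
    spec = spec or PhantomSpec()
    rois: list[SquareRoi] = []
    for view, placements in _layout(spec).items():
        ref_name = reference_bone_for(view).value
        for rid, (row, col, hw) in placements.items():
            rois.append(
                SquareRoi(
                    roi_id=rid,
                    view=view,
                    center_row=row,
                    center_col=col,
                    half_width=hw,
                    kind="reference" if rid == ref_name else "joint",
                )
            )
    return rois


def _gauss_kernel(half_width: int, sigma: float) -> np.ndarray:
    ax = np.arange(-half_width, half_width + 1, dtype=float)
    rr, cc = np.meshgrid(ax, ax, indexing="ij")
    return np.exp(-(rr**2 + cc**2) / (2.0 * sigma**2))


def render_phantom(spec: PhantomSpec) -> PhantomStudy:
    """Render the four views of a phantom study with exact known ratios.

    Each joint's hotspot is a Gaussian profile truncated to its own ROI
    window, with amplitude solved so that the noise-free ROI mean equals
    ``target_ratio * bone_level`` exactly; because hotspots never leave their
    window, disjoint ROI windows guarantee no cross-talk.
    """
    layout = _layout(spec)
    rng = np.random.default_rng(spec.seed)
    shapes = {
        View.ANTERIOR_WHOLE_BODY: spec.anterior_shape,
        View.POSTERIOR_PELVIS: spec.spot_shape,
        View.HANDS_SPOT: spec.spot_shape,
        View.FEET_SPOT: spec.spot_shape,
    }
    _check_disjoint(layout, shapes)

    views: dict[View, PlanarScintigram] = {}
    truth_rows = []
    for view, placements in layout.items():
        shape = shapes[view]
        img = np.full(shape, float(spec.background_level))
        ref_name = reference_bone_for(view).value
        for rid, (row, col, hw) in placements.items():
            win = (slice(row - hw, row + hw + 1), slice(col - hw, col + hw + 1))
            if rid == ref_name:
                img[win] = spec.bone_level
                continue
            if rid in spec.exclusions:
                truth_rows.append({"joint_id": rid, "target_ratio": np.nan, "excluded": True})
                continue
            target = spec.ratio_for(rid)
            kernel = _gauss_kernel(hw, spec.blob_sigma_px)
            # amplitude solved from the window mean -> ratio exact noise-free
            amp = (target * spec.bone_level - spec.background_level) / kernel.mean()
            patch = spec.background_level + amp * kernel
            if patch.min() < 0:
                raise PhantomError(
                    f"target ratio {target} for {rid!r} is unreachable: pixels would "
                    "go negative (lower background_level or raise the target)"
                )
            img[win] = patch
            truth_rows.append({"joint_id": rid, "target_ratio": target, "excluded": False})
        if spec.poisson_noise:
            img = rng.poisson(img).astype(float)
        views[view] = PlanarScintigram(img, view, patient_id=spec.patient_id)

    order = {j.joint_id: i for i, j in enumerate(list_joints())}
    truth = (
        pd.DataFrame(truth_rows)
        .sort_values("joint_id", key=lambda s: s.map(order))
        .reset_index(drop=True)
    )
    bundle = StudyBundle(spec.patient_id, views, exclusions=frozenset(spec.exclusions))
    return PhantomStudy(bundle=bundle, rois=default_rois(spec), truth=truth)


def _check_disjoint(layout, shapes) -> None:
    for view, placements in layout.items():
        nrow, ncol = shapes[view]
        taken = np.zeros((nrow, ncol), dtype=bool)
        for rid, (row, col, hw) in placements.items():
            if row - hw < 0 or col - hw < 0 or row + hw >= nrow or col + hw >= ncol:
                raise PhantomError(f"ROI {rid!r} leaves the {view.value} grid {shapes[view]}")
            win = (slice(row - hw, row + hw + 1), slice(col - hw, col + hw + 1))
            if taken[win].any():
                raise PhantomError(f"ROI {rid!r} overlaps another ROI on {view.value}")
            taken[win] = True


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class GroupMoments:
    mean: float
    sd: float

    def lognormal_params(self) -> tuple[float, float]:
        return fit_lognormal_from_moments(self.mean, self.sd)


@dataclass(frozen=True)
class AreaCondition:
    """Per-area prevalence and ratio distributions for the two groups."""

    prevalence: float
    affected: GroupMoments
    nonaffected: GroupMoments

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise PhantomError("prevalence must lie in [0, 1]")


@dataclass(frozen=True)
class ReaderModel:
    """Latent-threshold visual grading plus quantitative re-measurement noise.

    Each reader grades a joint by binning (true ratio + N(bias, grade_noise))
    at thresholds t1 < t2 into grades 1/2/3, and re-measures the ratio with
    additive N(0, ratio_noise) error (floored at 0).
    """

    thresholds: tuple[float, float] = (1.2, 2.0)
    grade_noise_sd: tuple[float, float] = (0.35, 0.45)
    grade_bias: tuple[float, float] = (0.0, 0.05)
    ratio_noise_sd: tuple[float, float] = (0.08, 0.08)

    def __post_init__(self) -> None:
        t1, t2 = self.thresholds
        if not t1 < t2:
            raise PhantomError("grade thresholds must satisfy t1 < t2")


@dataclass(frozen=True)
class ErosionModel:
    """Erosion covariate: only a random subset of joints gets an X-ray."""

    xray_fraction: float = 0.396
    p_given_affected: float = 0.30
    p_given_nonaffected: float = 0.04


# Observed per-area study conditions: prevalence and group ratio moments.
TABLE_CONDITIONS: dict[str, AreaCondition] = {
    "shoulder": AreaCondition(30 / 186, GroupMoments(1.73, 0.76), GroupMoments(1.54, 0.72)),
    "sternoclavicular": AreaCondition(5 / 186, GroupMoments(3.17, 0.21), GroupMoments(2.95, 1.42)),
    "elbow": AreaCondition(20 / 183, GroupMoments(1.48, 0.95), GroupMoments(0.93, 0.38)),
    "knee": AreaCondition(37 / 178, GroupMoments(2.02, 0.80), GroupMoments(1.23, 0.41)),
    "sacroiliac": AreaCondition(4 / 186, GroupMoments(1.23, 0.09), GroupMoments(1.10, 0.18)),
    "ankle": AreaCondition(27 / 186, GroupMoments(2.49, 0.75), GroupMoments(1.57, 0.48)),
    "tarsal": AreaCondition(15 / 186, GroupMoments(2.36, 0.80), GroupMoments(1.43, 0.42)),
    "mtp": AreaCondition(64 / 930, GroupMoments(1.38, 1.06), GroupMoments(0.88, 0.39)),
    "toe_ip": AreaCondition(10 / 930, GroupMoments(0.78, 0.18), GroupMoments(0.63, 0.26)),
    "wrist": AreaCondition(100 / 186, GroupMoments(2.76, 1.07), GroupMoments(1.82, 0.50)),
    "thumb_ip": AreaCondition(26 / 186, GroupMoments(1.44, 0.52), GroupMoments(1.17, 0.41)),
    "mcp": AreaCondition(179 / 930, GroupMoments(1.73, 0.69), GroupMoments(1.20, 0.41)),
    "hand_pip": AreaCondition(158 / 744, GroupMoments(1.37, 0.67), GroupMoments(0.94, 0.33)),
    "hand_dip": AreaCondition(53 / 744, GroupMoments(1.63, 0.97), GroupMoments(0.84, 0.32)),
}

# Whole-cohort (pooled) moments, used when a single uniform condition is wanted.
TOTAL_AFFECTED = GroupMoments(1.79, 0.95)
TOTAL_NONAFFECTED = GroupMoments(1.06, 0.64)
TOTAL_PREVALENCE = 0.123


@dataclass(frozen=True)
class CohortSpec:
    """Study-level simulation conditions."""

    n_patients: int = 93
    areas: Mapping[str, AreaCondition] = field(
        default_factory=lambda: dict(TABLE_CONDITIONS)
    )
    reader: ReaderModel = field(default_factory=ReaderModel)
    erosion: ErosionModel = field(default_factory=ErosionModel)
    exclusion_rate: float = 11 / 5952
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise PhantomError("n_patients must be >= 1")
        missing = {a.name for a in AREAS} - set(self.areas)
        if missing:
            raise PhantomError(f"areas mapping is missing conditions for: {sorted(missing)}")
        if not 0.0 <= self.exclusion_rate < 1.0:
            raise PhantomError("exclusion_rate must lie in [0, 1)")

    @classmethod
    def uniform(
        cls,
        prevalence: float = TOTAL_PREVALENCE,
        affected: GroupMoments = TOTAL_AFFECTED,
        nonaffected: GroupMoments = TOTAL_NONAFFECTED,
        **kwargs,
    ) -> "CohortSpec":
        """One condition applied to every area (the pooled-cohort setting)."""
        cond = AreaCondition(prevalence, affected, nonaffected)
        return cls(areas={a.name: cond for a in AREAS}, **kwargs)


COHORT_COLUMNS = [
    "patient_id",
    "joint_id",
    "area",
    "side",
    "digit_index",
    "excluded",
    "affected",
    "true_ratio",
    "ratio_reader1",
    "ratio_reader2",
    "grade_reader1",
    "grade_reader2",
    "has_xray",
    "erosion",
]


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a labelled per-joint cohort table (one row per patient x joint).

    Excluded joints carry NaN ratios/grades/labels throughout, mirroring how
    arthroplasty joints drop out of every downstream statistic.
    """
    rng = np.random.default_rng(spec.seed)
    joints = list_joints()
    n_j = len(joints)
    n = spec.n_patients

    prev = np.array([spec.areas[j.area.name].prevalence for j in joints])
    mu_a, sg_a = np.array(
        [spec.areas[j.area.name].affected.lognormal_params() for j in joints]
    ).T
    mu_n, sg_n = np.array(
        [spec.areas[j.area.name].nonaffected.lognormal_params() for j in joints]
    ).T

    rows = []
    t1, t2 = spec.reader.thresholds
    for p in range(n):
        pid = f"sim{p + 1:03d}"
        excluded = rng.random(n_j) < spec.exclusion_rate
        affected = rng.random(n_j) < prev
        z = rng.standard_normal(n_j)
        true_ratio = np.where(
            affected, np.exp(mu_a + sg_a * z), np.exp(mu_n + sg_n * z)
        )
        grades = []
        ratios = []
        for r in range(2):
            latent = (
                true_ratio
                + spec.reader.grade_bias[r]
                + spec.reader.grade_noise_sd[r] * rng.standard_normal(n_j)
            )
            grades.append(1 + (latent > t1).astype(int) + (latent > t2).astype(int))
            ratios.append(
                np.maximum(
                    true_ratio + spec.reader.ratio_noise_sd[r] * rng.standard_normal(n_j),
                    0.0,
                )
            )
        has_xray = rng.random(n_j) < spec.erosion.xray_fraction
        p_er = np.where(
            affected, spec.erosion.p_given_affected, spec.erosion.p_given_nonaffected
        )
        erosion = has_xray & (rng.random(n_j) < p_er)

        for i, j in enumerate(joints):
            if excluded[i]:
                rows.append(
                    {
                        "patient_id": pid,
                        "joint_id": j.joint_id,
                        "area": j.area.name,
                        "side": j.side,
                        "digit_index": j.digit_index,
                        "excluded": True,
                        "affected": np.nan,
                        "true_ratio": np.nan,
                        "ratio_reader1": np.nan,
                        "ratio_reader2": np.nan,
                        "grade_reader1": np.nan,
                        "grade_reader2": np.nan,
                        "has_xray": False,
                        "erosion": np.nan,
                    }
                )
            else:
                rows.append(
                    {
                        "patient_id": pid,
                        "joint_id": j.joint_id,
                        "area": j.area.name,
                        "side": j.side,
                        "digit_index": j.digit_index,
                        "excluded": False,
                        "affected": bool(affected[i]),
                        "true_ratio": float(true_ratio[i]),
                        "ratio_reader1": float(ratios[0][i]),
                        "ratio_reader2": float(ratios[1][i]),
                        "grade_reader1": int(grades[0][i]),
                        "grade_reader2": int(grades[1][i]),
                        "has_xray": bool(has_xray[i]),
                        "erosion": bool(erosion[i]) if has_xray[i] else np.nan,
                    }
                )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
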