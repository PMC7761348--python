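"""Square-ROI uptake quantification: the joint-to-bone uptake ratio.

For every joint a square region of interest (ROI) is placed on the view that
images it, and one reference-bone ROI is placed per view (skull on the
anterior whole-body view, sacrum on the posterior pelvis spot, distal radius
on the hands spot, distal tibia on the feet spot).  The joint uptake ratio is

    ratio = mean counts/pixel in the joint ROI
            -------------------------------------
            mean counts/pixel in the reference ROI

a dimensionless normalisation that cancels administered activity, decay and
camera sensitivity, leaving a per-joint relative uptake score.

ROI means average ALL pixels of the closed square window — no thresholding
and no background subtraction.  Excluded joints (e.g. arthroplasty) propagate
as missing values, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .joint_schema import (
    View,
    _coerce_view,
    descriptor_for,
    joint_ids,
    list_joints,
    reference_bone_for,
)
from .scintigram_io import PlanarScintigram, StudyBundle, TableSchemaError, validate_bundle

__all__ = [
    "SquareRoi",
    "JointMeasurement",
    "QuantifyError",
    "RoiOutOfBoundsError",
    "MissingRoiError",
    "UnusableReferenceError",
    "BundleNotReadyError",
    "ROI_COLUMNS",
    "roi_mean",
    "joint_uptake_ratio",
    "quantify_study",
    "read_roi_table",
    "write_roi_table",
]


class QuantifyError(ValueError):
    pass


class RoiOutOfBoundsError(QuantifyError):
    pass


class MissingRoiError(QuantifyError):
    pass


class UnusableReferenceError(QuantifyError):
    """Reference ROI mean is not strictly positive; ratios are undefined."""


class BundleNotReadyError(QuantifyError):
    pass


@dataclass(frozen=True)
class SquareRoi:
    """A square pixel window of side ``2*half_width + 1`` centred on a pixel.

    ``kind`` is ``"joint"`` for joint ROIs (``roi_id`` is a schema joint_id)
    or ``"reference"`` for the per-view reference-bone ROI.
    """

    roi_id: str
    view: View
    center_row: int
    center_col: int
    half_width: int
    kind: str = "joint"

    def __post_init__(self) -> None:
        object.__setattr__(self, "view", _coerce_view(self.view))
        if self.half_width < 1:
            raise QuantifyError("half_width must be a positive integer")
        if self.kind not in ("joint", "reference"):
            raise QuantifyError(f"ROI kind must be 'joint' or 'reference', got {self.kind!r}")

    @property
    def side(self) -> int:
        return 2 * self.half_width + 1

    def window(self) -> tuple[slice, slice]:
        return (
            slice(self.center_row - self.half_width, self.center_row + self.half_width + 1),
            slice(self.center_col - self.half_width, self.center_col + self.half_width + 1),
        )

    def fits(self, shape: tuple[int, int]) -> bool:
        return (
            self.center_row - self.half_width >= 0
            and self.center_col - self.half_width >= 0
            and self.center_row + self.half_width < shape[0]
            and self.center_col + self.half_width < shape[1]
        )


@dataclass(frozen=True)
class JointMeasurement:
    """Per-joint measurement record; ``ratio`` is present iff status=='measured'."""

    patient_id: str
    joint_id: str
    joint_mean: Optional[float]
    reference_mean: Optional[float]
    ratio: Optional[float]
    status: str  # "measured" | "excluded"

    def __post_init__(self) -> None:
        if self.status not in ("measured", "excluded"):
            raise QuantifyError(f"status must be 'measured' or 'excluded', got {self.status!r}")
        if self.status == "measured":
            if self.ratio is None or self.joint_mean is None or self.reference_mean is None:
                raise QuantifyError("measured joints must carry means and a ratio")
            if self.ratio < 0:
                raise QuantifyError("uptake ratio must be nonnegative")
            if not self.reference_mean > 0:
                raise UnusableReferenceError("measured joints require reference_mean > 0")
        elif self.ratio is not None:
            raise QuantifyError("excluded joints must not carry a ratio")


def roi_mean(image: PlanarScintigram, roi: SquareRoi) -> float:
    """Arithmetic mean of all pixels in the closed square window.

    The ROI must lie fully inside the image; an out-of-bounds window raises
    rather than being silently clipped (clipping would change the mean).
    """
    if roi.view is not image.view:
        raise QuantifyError(
            f"ROI {roi.roi_id!r} is defined on view {roi.view.value}, "
            f"image is {image.view.value}"
        )
    if not roi.fits(image.shape):
        raise RoiOutOfBoundsError(
            f"ROI {roi.roi_id!r} ({roi.side}x{roi.side} at "
            f"({roi.center_row},{roi.center_col})) exceeds image shape {image.shape}"
        )
    return float(image.counts[roi.window()].mean())


def joint_uptake_ratio(joint_mean: float, reference_mean: float) -> float:
    """Joint-to-bone uptake ratio (dimensionless)."""
    if not reference_mean > 0:
        raise UnusableReferenceError(
            f"reference ROI mean must be > 0, got {reference_mean!r}"
        )
    if joint_mean < 0:
        raise QuantifyError("joint ROI mean must be nonnegative")
    return float(joint_mean) / float(reference_mean)


def quantify_study(bundle: StudyBundle, rois: Iterable[SquareRoi]) -> list[JointMeasurement]:
    """Measure all 64 schema joints of one analysis-ready study.

    Returns one record per schema joint in canonical order: excluded joints
    carry status='excluded' and no ratio; every measured joint's ratio uses
    the reference ROI of its own view.
    """
    problems = validate_bundle(bundle)
    if problems:
        raise BundleNotReadyError(
            f"study {bundle.patient_id!r} is not analysis-ready: " + "; ".join(problems)
        )

    roi_list = list(rois)
    references: dict[View, SquareRoi] = {}
    joints: dict[str, SquareRoi] = {}
    for roi in roi_list:
        if roi.kind == "reference":
            if roi.view in references:
                raise QuantifyError(f"duplicate reference ROI for view {roi.view.value}")
            references[roi.view] = roi
        else:
            if roi.roi_id in joints:
                raise QuantifyError(f"duplicate ROI for joint {roi.roi_id!r}")
            if roi.roi_id not in set(joint_ids()):
                raise QuantifyError(f"ROI id {roi.roi_id!r} is not a schema joint")
            joints[roi.roi_id] = roi

    ref_means: dict[View, float] = {}
    for view in View:
        if any(j.view is view and j.joint_id not in bundle.exclusions for j in list_joints()):
            if view not in references:
                raise MissingRoiError(f"missing reference ROI for view {view.value}")
            ref_means[view] = roi_mean(bundle.views[view], references[view])
            if not ref_means[view] > 0:
                raise UnusableReferenceError(
                    f"reference ROI on view {view.value} has nonpositive mean"
                )

    out: list[JointMeasurement] = []
    for joint in list_joints():
        jid = joint.joint_id
        if jid in bundle.exclusions:
            out.append(
                JointMeasurement(bundle.patient_id, jid, None, None, None, "excluded")
            )
            continue
        if jid not in joints:
            raise MissingRoiError(f"no ROI provided for non-excluded joint {jid!r}")
        jmean = roi_mean(bundle.views[joint.view], joints[jid])
        rmean = ref_means[joint.view]
        out.append(
            JointMeasurement(
                bundle.patient_id,
                jid,
                jmean,
                rmean,
                joint_uptake_ratio(jmean, rmean),
                "measured",
            )
        )
    return out


# ---------------------------------------------------------------------------
# ROI tables

ROI_COLUMNS = ["patient_id", "id", "view", "center_row", "center_col", "half_width", "kind"]


def write_roi_table(rois: Mapping[str, Sequence[SquareRoi]] | Sequence[SquareRoi], path) -> None:
    """Write ROIs to CSV; accepts one study's ROIs or a {patient_id: rois} map."""
    if isinstance(rois, Mapping):
        items = [(pid, roi) for pid, rs in rois.items() for roi in rs]
    else:
        items = [("", roi) for roi in rois]
    rows = [
        {
            "patient_id": pid,
            "id": r.roi_id,
            "view": r.view.value,
            "center_row": r.center_row,
            "center_col": r.center_col,
            "half_width": r.half_width,
            "kind": r.kind,
        }
        for pid, r in items
    ]
    pd.DataFrame(rows, columns=ROI_COLUMNS).to_csv(path, index=False)


def read_roi_table(path) -> dict[str, list[SquareRoi]]:
    """Read a ROI CSV into {patient_id: [SquareRoi, ...]}."""
    df = pd.read_csv(path, dtype={"patient_id": str, "id": str, "view": str, "kind": str})
    if list(df.columns) != ROI_COLUMNS:
        raise TableSchemaError(f"ROI table columns must be {ROI_COLUMNS}, got {list(df.columns)}")
    out: dict[str, list[SquareRoi]] = {}
    for rec in df.itertuples(index=False):
        pid = "" if pd.isna(rec.patient_id) else str(rec.patient_id)
        out.setdefault(pid, []).append(
            SquareRoi(
                roi_id=rec.id,
                view=rec.view,
                center_row=int(rec.center_row),
                center_col=int(rec.center_col),
                half_width=int(rec.half_width),
                kind=rec.kind,
            )
        )
    return out
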