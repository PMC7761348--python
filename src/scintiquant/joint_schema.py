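"""Fixed inventory of the 64 peripheral joints scored on planar bone scintigraphy.

Whole-body joint uptake is quantified on four planar views: one anterior
whole-body view and three spot views (posterior pelvis, bilateral hands,
bilateral feet).  Each view carries exactly one reference bone whose mean
uptake normalises every joint measured on that view:

========================  ===============
view                      reference bone
========================  ===============
anterior whole body       skull
posterior pelvis spot     sacrum
bilateral hands spot      distal radius
bilateral feet spot       distal tibia
========================  ===============

The inventory covers 14 joint areas and 64 joints per patient: bilateral
shoulder, sternoclavicular, elbow, knee, sacroiliac, ankle, tarsal and wrist
joints; 10 metatarso-phalangeal (MTP) and 10 toe interphalangeal (IP) joints;
10 metacarpo-phalangeal (MCP) joints; bilateral thumb IP joints; and 8 hand
proximal (PIP) and 8 hand distal (DIP) interphalangeal joints.

The ordering of descriptors (area order as listed above, right before left,
ascending digit) is a repository convention adopted so every exported table
is byte-stable; it carries no anatomical meaning.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "View",
    "ReferenceBone",
    "JointArea",
    "JointDescriptor",
    "UnknownViewError",
    "SchemaError",
    "AREAS",
    "VIEW_REFERENCE",
    "list_joints",
    "joints_for_view",
    "joint_ids",
    "descriptor_for",
    "reference_bone_for",
    "schema_table",
    "export_schema",
    "import_schema",
]


class View(str, Enum):
    """The four planar acquisitions a study must contain."""

    ANTERIOR_WHOLE_BODY = "anterior_whole_body"
    POSTERIOR_PELVIS = "posterior_pelvis"
    HANDS_SPOT = "hands_spot"
    FEET_SPOT = "feet_spot"


class ReferenceBone(str, Enum):
    SKULL = "skull"
    SACRUM = "sacrum"
    DISTAL_RADIUS = "distal_radius"
    DISTAL_TIBIA = "distal_tibia"


class UnknownViewError(KeyError):
    """Raised when a view label is not one of the four defined views."""


class SchemaError(ValueError):
    """Raised when an imported schema table disagrees with the fixed inventory."""


VIEW_REFERENCE: dict[View, ReferenceBone] = {
    View.ANTERIOR_WHOLE_BODY: ReferenceBone.SKULL,
    View.POSTERIOR_PELVIS: ReferenceBone.SACRUM,
    View.HANDS_SPOT: ReferenceBone.DISTAL_RADIUS,
    View.FEET_SPOT: ReferenceBone.DISTAL_TIBIA,
}


@dataclass(frozen=True)
class JointArea:
    """One of the 14 joint areas, with laterality/digit structure.

    ``digits`` is ``None`` for plain bilateral areas (one joint per side) and a
    tuple of digit numbers for digit areas (one joint per side per digit).
    """

    name: str
    view: View
    digits: Optional[tuple[int, ...]] = None

    @property
    def joints_per_patient(self) -> int:
        return 2 * (len(self.digits) if self.digits else 1)

    @property
    def reference_bone(self) -> ReferenceBone:
        return VIEW_REFERENCE[self.view]


# Table order used throughout: large joints head-to-foot-of-table, then the
# hand chain.  Thumb IP is its own area (digit 1); hand PIP/DIP cover digits
# 2-5; MTP, toe IP and MCP cover digits 1-5.
AREAS: tuple[JointArea, ...] = (
    JointArea("shoulder", View.ANTERIOR_WHOLE_BODY),
    JointArea("sternoclavicular", View.ANTERIOR_WHOLE_BODY),
    JointArea("elbow", View.ANTERIOR_WHOLE_BODY),
    JointArea("knee", View.ANTERIOR_WHOLE_BODY),
    JointArea("sacroiliac", View.POSTERIOR_PELVIS),
    JointArea("ankle", View.FEET_SPOT),
    JointArea("tarsal", View.FEET_SPOT),
    JointArea("mtp", View.FEET_SPOT, digits=(1, 2, 3, 4, 5)),
    JointArea("toe_ip", View.FEET_SPOT, digits=(1, 2, 3, 4, 5)),
    JointArea("wrist", View.HANDS_SPOT),
    JointArea("thumb_ip", View.HANDS_SPOT, digits=(1,)),
    JointArea("mcp", View.HANDS_SPOT, digits=(1, 2, 3, 4, 5)),
    JointArea("hand_pip", View.HANDS_SPOT, digits=(2, 3, 4, 5)),
    JointArea("hand_dip", View.HANDS_SPOT, digits=(2, 3, 4, 5)),
)

AREA_BY_NAME: dict[str, JointArea] = {a.name: a for a in AREAS}

_SIDES = ("R", "L")


@dataclass(frozen=True)
class JointDescriptor:
    """A single joint of the 64-joint inventory."""

    area: JointArea
    side: str  # "R" | "L"
    digit_index: Optional[int] = None

    @property
    def joint_id(self) -> str:
        if self.digit_index is None:
            return f"{self.area.name}_{self.side}"
        return f"{self.area.name}_{self.side}{self.digit_index}"

    @property
    def view(self) -> View:
        return self.area.view

    @property
    def reference_bone(self) -> ReferenceBone:
        return self.area.reference_bone


@lru_cache(maxsize=1)
def list_joints() -> tuple[JointDescriptor, ...]:
    """All 64 joints in canonical order (area, right before left, digit 1..5)."""
    out: list[JointDescriptor] = []
    for area in AREAS:
        for side in _SIDES:
            if area.digits is None:
                out.append(JointDescriptor(area, side))
            else:
                out.extend(JointDescriptor(area, side, d) for d in area.digits)
    return tuple(out)


def joint_ids() -> tuple[str, ...]:
    return tuple(j.joint_id for j in list_joints())


@lru_cache(maxsize=1)
def _by_id() -> dict[str, JointDescriptor]:
    return {j.joint_id: j for j in list_joints()}


def descriptor_for(joint_id: str) -> JointDescriptor:
    try:
        return _by_id()[joint_id]
    except KeyError:
        raise SchemaError(f"unknown joint_id: {joint_id!r}") from None


def joints_for_view(view: "View | str") -> tuple[JointDescriptor, ...]:
    view = _coerce_view(view)
    return tuple(j for j in list_joints() if j.view is view)


def _coerce_view(view: "View | str") -> View:
    if isinstance(view, View):
        return view
    try:
        return View(view)
    except ValueError:
        raise UnknownViewError(f"unknown view label: {view!r}") from None


def reference_bone_for(view: "View | str") -> ReferenceBone:
    """The unique reference bone normalising joints measured on ``view``."""
    return VIEW_REFERENCE[_coerce_view(view)]


# ---------------------------------------------------------------------------
# delimited import/export so downstream files can be validated


_SCHEMA_COLUMNS = ["joint_id", "area", "side", "digit_index", "view", "reference_bone"]


def schema_table() -> pd.DataFrame:
    rows = [
        {
            "joint_id": j.joint_id,
            "area": j.area.name,
            "side": j.side,
            "digit_index": j.digit_index if j.digit_index is not None else "",
            "view": j.view.value,
            "reference_bone": j.reference_bone.value,
        }
        for j in list_joints()
    ]
    return pd.DataFrame(rows, columns=_SCHEMA_COLUMNS)


def export_schema(path) -> None:
    schema_table().to_csv(path, index=False)


def import_schema(path) -> tuple[JointDescriptor, ...]:
    """Read a schema table and check it matches the fixed inventory exactly."""
    df = pd.read_csv(path, dtype=str).fillna("")
    if list(df.columns) != _SCHEMA_COLUMNS:
        raise SchemaError(f"schema columns must be {_SCHEMA_COLUMNS}, got {list(df.columns)}")
    expected = schema_table()
    if list(df["joint_id"]) != list(expected["joint_id"]):
        raise SchemaError("schema joint_id column does not match the fixed 64-joint inventory")
    for col in _SCHEMA_COLUMNS[1:]:
        if list(df[col].astype(str)) != list(expected[col].astype(str)):
            raise SchemaError(f"schema column {col!r} does not match the fixed inventory")
    return list_joints()
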