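"""Reading, validating and writing planar scintigrams and their sidecar tables.

A study is a bundle of four planar count images (anterior whole body,
posterior pelvis spot, hands spot, feet spot).  Supported rasters are 16-bit
grayscale PNG, whitespace-delimited numeric text grids, and (optionally)
planar nuclear-medicine DICOM frames; counts are kept losslessly for integer
inputs.  Tabular sidecars (ROI tables, measurement tables, grade tables) are
UTF-8 CSV with a header row and fixed column sets.

Conventions: grids are row-major with 0-based indices and pixel-centre
coordinates; row 0 is the image top.  A study missing any of the four views
is excluded from analysis rather than analysed partially.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .joint_schema import View, joint_ids, _coerce_view

__all__ = [
    "PlanarScintigram",
    "StudyBundle",
    "ScintigramError",
    "UnsupportedFormatError",
    "NegativeCountsError",
    "EmptyImageError",
    "TableSchemaError",
    "REQUIRED_VIEWS",
    "MEASUREMENT_COLUMNS",
    "read_scintigram",
    "write_scintigram",
    "validate_bundle",
    "read_bundle_dir",
    "write_measurements",
    "read_measurements",
]


class ScintigramError(ValueError):
    """Base class for image/table ingestion problems."""


class UnsupportedFormatError(ScintigramError):
    pass


class NegativeCountsError(ScintigramError):
    pass


class EmptyImageError(ScintigramError):
    pass


class TableSchemaError(ScintigramError):
    pass


REQUIRED_VIEWS: tuple[View, ...] = tuple(View)


@dataclass
class PlanarScintigram:
    """A 2-D grid of nonnegative gamma counts for one view."""

    counts: np.ndarray
    view: View
    pixel_spacing_mm: float = 2.4
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.view = _coerce_view(self.view)
        arr = np.asarray(self.counts, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise EmptyImageError("counts must be a non-empty 2-D grid")
        if not np.all(np.isfinite(arr)):
            raise ScintigramError("counts contain non-finite values")
        if (arr < 0).any():
            raise NegativeCountsError("gamma counts must be nonnegative")
        if not self.pixel_spacing_mm > 0:
            raise ScintigramError("pixel_spacing_mm must be positive")
        self.counts = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape  # type: ignore[return-value]


@dataclass
class StudyBundle:
    """All views of one patient study plus declared joint exclusions."""

    patient_id: str
    views: dict[View, PlanarScintigram] = field(default_factory=dict)
    exclusions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.views = {_coerce_view(v): img for v, img in self.views.items()}
        self.exclusions = frozenset(self.exclusions)

    @property
    def analysis_ready(self) -> bool:
        return not validate_bundle(self)


def validate_bundle(bundle: StudyBundle) -> list[str]:
    """Return a list of violations; empty means the bundle is analysis-ready.

    Violations are reported, never raised: a missing view or a stray exclusion
    is a property of the input data, not a programming error.
    """
    problems: list[str] = []
    for view in REQUIRED_VIEWS:
        if view not in bundle.views:
            problems.append(f"missing required view: {view.value}")
    valid_ids = set(joint_ids())
    for jid in sorted(bundle.exclusions):
        if jid not in valid_ids:
            problems.append(f"exclusion references unknown joint_id: {jid}")
    for view, img in bundle.views.items():
        if img.view is not view:
            problems.append(f"view key {view.value} holds an image labelled {img.view.value}")
    return problems


# ---------------------------------------------------------------------------
# raster I/O


def read_scintigram(
    path: "str | os.PathLike",
    view: "View | str",
    *,
    pixel_spacing_mm: float | None = None,
    patient_id: str = "",
) -> PlanarScintigram:
    """Read one planar view from PNG, numeric text grid, or DICOM.

    The format is chosen by file suffix (``.png``, ``.dcm``/``.dicom``,
    anything else is parsed as a whitespace-delimited grid).  Integer counts
    round-trip losslessly; negative pixels are rejected.
    """
    path = os.fspath(path)
    suffix = os.path.splitext(path)[1].lower()
    spacing = pixel_spacing_mm
    if suffix == ".png":
        arr = _read_png(path)
    elif suffix in (".dcm", ".dicom"):
        arr, dcm_spacing = _read_dicom(path)
        spacing = spacing if spacing is not None else dcm_spacing
    elif suffix in (".txt", ".dat", ".grid", ".tsv", ""):
        arr = _read_text_grid(path)
    else:
        raise UnsupportedFormatError(f"unsupported raster format: {suffix!r}")
    return PlanarScintigram(
        counts=arr,
        view=view,
        pixel_spacing_mm=spacing if spacing is not None else 2.4,
        patient_id=patient_id,
    )


def _read_png(path: str) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        if im.mode not in ("I", "I;16", "I;16B", "L"):
            raise UnsupportedFormatError(
                f"PNG must be single-channel grayscale, got mode {im.mode!r}"
            )
        return np.asarray(im, dtype=np.int64).astype(float)


def _read_text_grid(path: str) -> np.ndarray:
    try:
        arr = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise UnsupportedFormatError(f"cannot parse numeric grid {path}: {exc}") from exc
    return arr


def _read_dicom(path: str) -> tuple[np.ndarray, float | None]:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = np.asarray(ds.pixel_array, dtype=float)
    if arr.ndim == 3:  # multi-frame NM: take the first frame
        arr = arr[0]
    spacing = None
    ps = getattr(ds, "PixelSpacing", None)
    if ps:
        spacing = float(ps[0])
    return arr, spacing


def write_scintigram(image: PlanarScintigram, path: "str | os.PathLike") -> None:
    """Write a view to 16-bit PNG or a text grid, by suffix."""
    path = os.fspath(path)
    suffix = os.path.splitext(path)[1].lower()
    if suffix == ".png":
        from PIL import Image

        arr = image.counts
        rounded = np.rint(arr)
        if not np.array_equal(arr, rounded):
            raise UnsupportedFormatError("PNG export requires integer counts")
        if rounded.max(initial=0) > np.iinfo(np.uint16).max:
            raise UnsupportedFormatError("counts exceed the 16-bit PNG range")
        Image.fromarray(rounded.astype(np.uint16)).save(path)
    elif suffix in (".txt", ".dat", ".grid", ""):
        np.savetxt(path, image.counts, fmt="%.6g")
    else:
        raise UnsupportedFormatError(f"unsupported raster format: {suffix!r}")


_VIEW_FILENAMES = {v: v.value for v in View}


def read_bundle_dir(
    directory: "str | os.PathLike",
    patient_id: str | None = None,
    exclusions: Iterable[str] = (),
) -> StudyBundle:
    """Assemble a StudyBundle from ``<directory>/<view>.{png,txt,dcm}`` files."""
    directory = os.fspath(directory)
    pid = patient_id if patient_id is not None else os.path.basename(os.path.normpath(directory))
    views: dict[View, PlanarScintigram] = {}
    for view, stem in _VIEW_FILENAMES.items():
        for ext in (".png", ".txt", ".dat", ".dcm"):
            candidate = os.path.join(directory, stem + ext)
            if os.path.exists(candidate):
                views[view] = read_scintigram(candidate, view, patient_id=pid)
                break
    return StudyBundle(patient_id=pid, views=views, exclusions=frozenset(exclusions))


# ---------------------------------------------------------------------------
# measurement tables

MEASUREMENT_COLUMNS = ["patient_id", "joint_id", "joint_mean", "reference_mean", "ratio", "status"]


def write_measurements(measurements: Sequence, path) -> None:
    """Write JointMeasurement records to CSV (lossless to printed precision)."""
    rows = []
    for m in measurements:
        rows.append(
            {
                "patient_id": m.patient_id,
                "joint_id": m.joint_id,
                "joint_mean": "" if m.joint_mean is None else repr(float(m.joint_mean)),
                "reference_mean": "" if m.reference_mean is None else repr(float(m.reference_mean)),
                "ratio": "" if m.ratio is None else repr(float(m.ratio)),
                "status": m.status,
            }
        )
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(path, index=False)


def read_measurements(path) -> list:
    """Read a measurement table back into JointMeasurement records."""
    from .quantify import JointMeasurement  # local import: quantify imports this module

    df = pd.read_csv(path, dtype={"patient_id": str, "joint_id": str, "status": str})
    if list(df.columns) != MEASUREMENT_COLUMNS:
        raise TableSchemaError(
            f"measurement table columns must be {MEASUREMENT_COLUMNS}, got {list(df.columns)}"
        )
    valid_ids = set(joint_ids())
    out = []
    for rec in df.itertuples(index=False):
        if rec.joint_id not in valid_ids:
            raise TableSchemaError(f"measurement row references unknown joint_id: {rec.joint_id}")
        out.append(
            JointMeasurement(
                patient_id=rec.patient_id,
                joint_id=rec.joint_id,
                joint_mean=None if _isna(rec.joint_mean) else float(rec.joint_mean),
                reference_mean=None if _isna(rec.reference_mean) else float(rec.reference_mean),
                ratio=None if _isna(rec.ratio) else float(rec.ratio),
                status=rec.status,
            )
        )
    return out


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or x == ""
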