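"""Shape morphometry of fitted ellipsoids.

For each 3D ellipsoid with sorted semilengths l1 >= l2 >= l3 the module
computes the axis-ratio features l2/l1 and l3/l2 — which place every
shape inside the unit square, with spheres at the top-right corner,
prolate (rugby-ball) shapes on the right boundary and oblate (disc)
shapes on the top boundary — plus the aspect ratio l3/l1.  It bins the
joint ratios into 2D histograms and summarizes groups (e.g. control vs
drug-treated) by mean ratios and 1D aspect-ratio histograms.

No between-group significance test is computed; the output is counts
and means, inference is left to the user.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quadrics import EllipsoidGeometry

__all__ = [
    "ShapeRecord",
    "Histogram2D",
    "GroupSummary",
    "compute_shape_records",
    "histogram_2d",
    "summarize_groups",
    "records_to_frame",
]

DEFAULT_BINS = 20


@dataclass(frozen=True)
class ShapeRecord:
    """Axis-ratio features of one ellipsoid."""

    id: str
    semilengths: tuple[float, float, float]
    ratio_21: float     # l2/l1 in (0, 1]
    ratio_32: float     # l3/l2 in (0, 1]
    aspect_ratio: float  # l3/l1 = ratio_21 * ratio_32
    group: str = ""


@dataclass(frozen=True)
class Histogram2D:
    """Binned joint ratios over the unit square, plus the distribution mean."""

    counts: np.ndarray          # (bins, bins); [i, j] = ratio_21 bin i, ratio_32 bin j
    edges: np.ndarray           # shared bin edges on [0, 1]
    mean_ratio_21: float
    mean_ratio_32: float


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean_ratio_21: float
    mean_ratio_32: float
    mean_aspect: float
    aspect_histogram: np.ndarray
    aspect_edges: np.ndarray


def compute_shape_records(
    geoms: list[EllipsoidGeometry], group: str = "", ids: list[str] | None = None
) -> list[ShapeRecord]:
    """Axis ratios for a list of 3D geometries (semilengths re-sorted)."""
    records = []
    for k, g in enumerate(geoms):
        if g.dim != 3:
            raise ValueError("shape statistics require 3D geometries")
        l1, l2, l3 = np.sort(g.semilengths)[::-1]
        records.append(
            ShapeRecord(
                id=ids[k] if ids is not None else str(k),
                semilengths=(float(l1), float(l2), float(l3)),
                ratio_21=float(l2 / l1),
                ratio_32=float(l3 / l2),
                aspect_ratio=float(l3 / l1),
                group=group,
            )
        )
    return records


def _bin_unit_interval(x: np.ndarray, bins: int) -> np.ndarray:
    """Right-closed binning of values in [0, 1]: bin i covers (i/b, (i+1)/b],
    except bin 0 which also includes 0."""
    idx = np.ceil(np.asarray(x) * bins).astype(int) - 1
    return np.clip(idx, 0, bins - 1)


def histogram_2d(records: list[ShapeRecord], bins: int = DEFAULT_BINS) -> Histogram2D:
    """Joint histogram of (l2/l1, l3/l2) over [0,1]^2; counts sum to n."""
    if not records:
        raise ValueError("histogram_2d needs at least one record")
    r21 = np.array([r.ratio_21 for r in records])
    r32 = np.array([r.ratio_32 for r in records])
    counts = np.zeros((bins, bins), dtype=int)
    np.add.at(counts, (_bin_unit_interval(r21, bins), _bin_unit_interval(r32, bins)), 1)
    return Histogram2D(
        counts=counts,
        edges=np.linspace(0.0, 1.0, bins + 1),
        mean_ratio_21=float(r21.mean()),
        mean_ratio_32=float(r32.mean()),
    )


def summarize_groups(
    records: list[ShapeRecord], bins: int = DEFAULT_BINS
) -> tuple[dict[str, GroupSummary], str]:
    """Per-group means and 1D aspect-ratio histograms.

    Returns the summaries keyed by group label plus a one-line description
    of the shift direction when exactly two groups are present.
    """
    if not records:
        raise ValueError("no records to summarize")
    groups: dict[str, list[ShapeRecord]] = {}
    for r in records:
        groups.setdefault(r.group, []).append(r)
    edges = np.linspace(0.0, 1.0, bins + 1)
    summaries = {}
    for label, recs in groups.items():
        aspects = np.array([r.aspect_ratio for r in recs])
        hist = np.bincount(_bin_unit_interval(aspects, bins), minlength=bins)
        summaries[label] = GroupSummary(
            n=len(recs),
            mean_ratio_21=float(np.mean([r.ratio_21 for r in recs])),
            mean_ratio_32=float(np.mean([r.ratio_32 for r in recs])),
            mean_aspect=float(aspects.mean()),
            aspect_histogram=hist,
            aspect_edges=edges,
        )
    shift = ""
    if len(summaries) == 2:
        (la, sa), (lb, sb) = summaries.items()
        if sa.mean_aspect == sb.mean_aspect:
            shift = f"no aspect-ratio shift between '{la}' and '{lb}'"
        else:
            hi, lo = (la, lb) if sa.mean_aspect > sb.mean_aspect else (lb, la)
            shift = (
                f"mean aspect ratio higher in '{hi}' than in '{lo}' "
                f"(rounder shapes in '{hi}')"
            )
    return summaries, shift


def records_to_frame(records: list[ShapeRecord]) -> pd.DataFrame:
    """Tabular view of shape records for CSV export / plotting."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "group": [r.group for r in records],
            "length_1": [r.semilengths[0] for r in records],
            "length_2": [r.semilengths[1] for r in records],
            "length_3": [r.semilengths[2] for r in records],
            "ratio_21": [r.ratio_21 for r in records],
            "ratio_32": [r.ratio_32 for r in records],
            "aspect_ratio": [r.aspect_ratio for r in records],
        }
    )
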