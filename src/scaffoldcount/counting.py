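"""Object counting with unbiased stereological rules.

Two counting paths turn masks into per-column cell counts:

* ``count_projection`` -- the automated path: count labelled objects in a
  z-projection, applying the unbiased counting frame (objects touching the two
  exclusion edges are never counted; objects touching the inclusion edges
  are).  The rule makes counts additive over frames that tile a region.
* ``count_disector`` -- the manual-analog 3D path: link object cross-sections
  across adjacent optical sections, count each 3D object once in the section
  where it first appears ("tops" rule), and never count objects already
  visible in the reference (exclusion) plane supplied as the first mask.

Frame convention (documented, since any consistent choice is unbiased):
array row 0 and column 0 are the exclusion edges (the field's low-y and low-x
borders plus their extensions); the opposite edges are inclusion edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import FormatError, GeometryError
from .sampling import ColumnSpec
from .segmentation import LabeledMask


@dataclass(frozen=True)
class CountResult:
    """A per-column cell count and the geometry it refers to."""

    column_id: int
    method: str  # "projection" | "disector" | "ground_truth"
    count: int
    frame_area_mm2: float
    disector_height_mm: float | None = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.method not in ("projection", "disector", "ground_truth"):
            raise ValueError(f"unknown counting method {self.method!r}")


def _excluded_labels(labels: np.ndarray) -> set[int]:
    """Labels with any pixel on an exclusion edge (row 0 or column 0)."""
    edge = np.concatenate([labels[0, :], labels[:, 0]])
    return set(np.unique(edge[edge > 0]).tolist())


def count_projection(mask: LabeledMask, frame: ColumnSpec) -> CountResult:
    """Count objects in a projection mask under the counting-frame rule."""
    if mask.labels.ndim != 2 or mask.provenance != "projection":
        raise FormatError("count_projection expects a 2D projection mask")
    labels = mask.labels
    excluded = _excluded_labels(labels)
    present = np.unique(labels)
    present = present[present > 0]
    n = int(sum(1 for lab in present if int(lab) not in excluded))
    return CountResult(
        column_id=frame.column_id,
        method="projection",
        count=n,
        frame_area_mm2=frame.field_width * frame.field_height,
    )


def count_in_frame(
    scene: LabeledMask | np.ndarray,
    row0: int,
    col0: int,
    height: int,
    width: int,
) -> int:
    """Frame-rule count of a frame placed *inside* a labelled scene.

    Implements the exclusion edges together with their extensions, which
    requires seeing each object's full extent (unlike
    :func:`count_projection`, which works on a mask clipped to the frame).
    An object is counted iff

    1. it has at least one pixel inside the frame,
    2. no pixel below the frame (bottom exclusion edge and its horizontal
       extensions), and
    3. no pixel left of the frame at any row below the frame's top (left
       exclusion edge and its extension downward).

    For frames that tile the scene, every object is counted in exactly one
    frame -- the one holding the leftmost pixel of its bottom row -- so frame
    counts are exactly additive.
    """
    labels = scene.labels if isinstance(scene, LabeledMask) else np.asarray(scene)
    if labels.ndim != 2:
        raise FormatError("count_in_frame expects a 2D labelled scene")
    rows, cols = np.nonzero(labels)
    if rows.size == 0:
        return 0
    ids = labels[rows, cols]
    n = int(ids.max())
    min_row = np.full(n + 1, np.iinfo(np.int64).max)
    np.minimum.at(min_row, ids, rows)
    # leftmost pixel among rows below the frame's top edge
    below_top = rows < row0 + height
    min_col_below = np.full(n + 1, np.iinfo(np.int64).max)
    np.minimum.at(min_col_below, ids[below_top], cols[below_top])
    in_frame = (
        (rows >= row0)
        & (rows < row0 + height)
        & (cols >= col0)
        & (cols < col0 + width)
    )
    candidates = np.unique(ids[in_frame])
    count = 0
    for obj in candidates:
        if min_row[obj] >= row0 and min_col_below[obj] >= col0:
            count += 1
    return count


def overlap_link(
    section_masks: Sequence[LabeledMask],
    min_overlap_frac: float = 0.0,
) -> np.ndarray:
    """Link per-section 2D objects into 3D objects by pixel overlap.

    Cross-sections in adjacent sections belong to one object iff their pixel
    overlap is at least ``min_overlap_frac`` of the smaller cross-section
    (0 = any shared pixel); transitive closure defines the objects.  Returns a
    (z, y, x) int32 label volume with consecutive object ids.
    """
    if not section_masks:
        raise GeometryError("need at least one section mask")
    shape = section_masks[0].labels.shape
    for m in section_masks:
        if m.labels.shape != shape or m.labels.ndim != 2:
            raise GeometryError("all section masks must share one 2D shape")

    # give every 2D cross-section a globally unique id
    offsets = np.cumsum([0] + [m.n_objects for m in section_masks])
    n_nodes = int(offsets[-1])
    vol = np.zeros((len(section_masks),) + shape, dtype=np.int32)
    for k, m in enumerate(section_masks):
        lab = m.labels
        vol[k] = np.where(lab > 0, lab + offsets[k], 0)
    if n_nodes == 0:
        return vol

    areas = np.bincount(vol.ravel(), minlength=n_nodes + 1)
    rows, cols = [], []
    for k in range(len(section_masks) - 1):
        a, b = vol[k], vol[k + 1]
        both = (a > 0) & (b > 0)
        if not both.any():
            continue
        pairs = np.stack([a[both], b[both]])
        uniq, counts = np.unique(pairs, axis=1, return_counts=True)
        if min_overlap_frac > 0:
            smaller = np.minimum(areas[uniq[0]], areas[uniq[1]])
            keep = counts >= min_overlap_frac * smaller
            uniq = uniq[:, keep]
        rows.append(uniq[0])
        cols.append(uniq[1])
    if rows:
        r = np.concatenate(rows) - 1
        c = np.concatenate(cols) - 1
        graph = coo_matrix(
            (np.ones(r.size), (r, c)), shape=(n_nodes, n_nodes)
        )
        _, comp = connected_components(graph, directed=False)
    else:
        comp = np.arange(n_nodes)
    lut = np.zeros(n_nodes + 1, dtype=np.int32)
    lut[1:] = comp + 1
    vol = lut[vol]
    # renumber components consecutively
    ids = np.unique(vol)
    ids = ids[ids > 0]
    lut2 = np.zeros(int(vol.max()) + 1, dtype=np.int32)
    lut2[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return lut2[vol]


def count_disector(
    section_masks: Sequence[LabeledMask],
    column: ColumnSpec,
    min_overlap_frac: float = 0.0,
) -> CountResult:
    """Optical-disector count of a z-ordered stack of section masks.

    The first mask is the reference (exclusion) plane: objects visible there
    are never counted.  Every other 3D object is counted once, in the section
    where it first appears, where the 2D counting-frame edge rule is applied
    to its cross-section.  When the exclusion plane is an extra section
    acquired one spacing below the column (see
    :meth:`~scaffoldcount.sampling.ColumnSpec.with_lookup_section`), all
    ``column.n_sections`` slabs are counted and the disector height equals the
    column depth.
    """
    vol = overlap_link(section_masks, min_overlap_frac)
    nz = vol.shape[0]
    n_obj = int(vol.max())
    count = 0
    if n_obj:
        # first section of appearance for every object
        first = np.full(n_obj + 1, nz, dtype=np.int64)
        for k in range(nz - 1, -1, -1):
            present = np.unique(vol[k])
            first[present[present > 0]] = k
        for obj in range(1, n_obj + 1):
            top = int(first[obj])
            if top == 0:  # visible in the exclusion plane
                continue
            sect = vol[top] == obj
            if sect[0, :].any() or sect[:, 0].any():  # exclusion edges
                continue
            count += 1
    return CountResult(
        column_id=column.column_id,
        method="disector",
        count=count,
        frame_area_mm2=column.field_width * column.field_height,
        disector_height_mm=(len(section_masks) - 1) * column.z_spacing,
    )


def counts_to_frame(
    counts: Sequence[CountResult], scaffold_id: str | int = 0
) -> pd.DataFrame:
    """Tabulate counts as (scaffold_id, column_id, method, count)."""
    return pd.DataFrame(
        {
            "scaffold_id": scaffold_id,
            "column_id": [c.column_id for c in counts],
            "method": [c.method for c in counts],
            "count": [c.count for c in counts],
        }
    )
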