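"""Detection of endocrine islets as circles from marker transcripts.

Forming islets of Langerhans are dense aggregates of hormone transcripts
(SST, GLUC, INS).  They are detected by density-based clustering of marker
transcript positions and each cluster is summarized by its minimum
enclosing circle, so that every member transcript is guaranteed to lie
inside the reported circle.  Clusters down to ``min_points`` members are
retained, which admits single-cell exocrine regions when ``min_points`` is
small.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely import MultiPoint, minimum_bounding_circle, minimum_bounding_radius
from sklearn.cluster import DBSCAN

from .data import TranscriptTable

# float-safety inflation so the containment invariant survives round-off
_RADIUS_EPS = 1e-9


@dataclass(frozen=True)
class Islet:
    """A circular islet: center (micrometres), radius > 0, member count."""

    cx: float
    cy: float
    radius: float
    member_count: int

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("islet radius must be > 0")
        if self.member_count < 1:
            raise ValueError("islet must have at least one member")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)

    def contains(self, x: float, y: float) -> bool:
        """Boundary counts as inside."""
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.radius**2


@dataclass(frozen=True)
class IsletSet:
    islets: tuple[Islet, ...]
    marker_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.marker_genes:
            raise ValueError("marker_genes must be non-empty")

    def __len__(self) -> int:
        return len(self.islets)

    def __iter__(self):
        return iter(self.islets)

    def __getitem__(self, i: int) -> Islet:
        return self.islets[i]


def _enclosing_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Exact minimum enclosing circle (center x, center y, radius)."""
    if len(points) == 1:
        x, y = points[0]
        return float(x), float(y), 0.0
    mp = MultiPoint(points)
    radius = float(minimum_bounding_radius(mp))
    center = minimum_bounding_circle(mp).centroid
    return float(center.x), float(center.y), radius


def detect_islets(
    table: TranscriptTable,
    marker_genes: Sequence[str] = ("SST", "GLUC", "INS"),
    neighborhood_radius: float = 20.0,
    min_points: int = 3,
) -> IsletSet:
    """Cluster marker transcripts into circular islets.

    DBSCAN with ``eps = neighborhood_radius`` and ``min_samples =
    min_points`` groups marker positions into density-connected clusters;
    unclustered markers are noise.  Each cluster becomes the minimum
    enclosing circle of its points (a degenerate single-point cluster
    receives a radius of half the neighborhood radius so its circle has
    positive area).  Islets are returned sorted lexicographically by
    center, making the output deterministic.

    Parameters
    ----------
    marker_genes : labels whose transcripts demarcate endocrine cells.
    neighborhood_radius : DBSCAN eps in micrometres (default 20, twice the
        typical nuclei spacing).
    min_points : minimum cluster size; 1 admits single-cell regions.
    """
    if neighborhood_radius <= 0:
        raise ValueError("neighborhood_radius must be > 0")
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    markers = [g for g in marker_genes]
    unknown = set(markers) - set(table.panel)
    if unknown:
        raise ValueError(f"marker genes not in panel: {sorted(unknown)}")

    sub = table.records[table.records["gene"].isin(markers)]
    if sub.empty:
        return IsletSet((), tuple(markers))
    xy = sub[["x", "y"]].to_numpy(float)
    labels = DBSCAN(eps=neighborhood_radius, min_samples=min_points).fit_predict(xy)

    islets: list[Islet] = []
    for lab in sorted(set(labels) - {-1}):
        pts = xy[labels == lab]
        cx, cy, r = _enclosing_circle(pts)
        r = max(r * (1.0 + _RADIUS_EPS) + _RADIUS_EPS, neighborhood_radius / 2.0)
        islets.append(Islet(cx, cy, r, int(len(pts))))
    islets.sort(key=lambda c: (c.cx, c.cy))
    return IsletSet(tuple(islets), tuple(markers))


def assign_islet_membership(
    points: np.ndarray, islets: IsletSet
) -> np.ndarray:
    """Boolean inside/outside label per point (True = inside some islet).

    A point on an islet boundary (distance exactly equal to the radius)
    counts as inside.  With no islets, every point is outside.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    inside = np.zeros(len(pts), dtype=bool)
    for islet in islets:
        d2 = (pts[:, 0] - islet.cx) ** 2 + (pts[:, 1] - islet.cy) ** 2
        inside |= d2 <= islet.radius**2
    return inside


def islet_diameters(islets: IsletSet) -> list[float]:
    """Diameters (2r, micrometres) for size-distribution reporting."""
    return [islet.diameter for islet in islets]


def write_islets_json(islets: IsletSet, path: str | Path) -> None:
    payload = {
        "marker_genes": list(islets.marker_genes),
        "islets": [
            {"cx": c.cx, "cy": c.cy, "radius": c.radius,
             "member_count": c.member_count}
            for c in islets
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_islets_json(path: str | Path) -> IsletSet:
    payload = json.loads(Path(path).read_text())
    return IsletSet(
        tuple(
            Islet(d["cx"], d["cy"], d["radius"], d["member_count"])
            for d in payload["islets"]
        ),
        tuple(payload["marker_genes"]),
    )
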