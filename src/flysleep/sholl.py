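"""Cone-restricted Sholl analysis: the defasciculation index (DI).

The DI quantifies how spread out (defasciculated) the dorsal axonal
projections of PDF-expressing s-LNv clock neurons are.  Concentric circles
(15 rings, 10 um apart by default) are centred on the point where the dorsal
ramification opens; every transversal crossing of a traced neurite with a
ring is recorded with its polar angle.  A narrow cone (full apex angle 15
degrees by default) is oriented to capture the maximum number of crossings,
and

    DI = crossings outside the cone / total crossings

so a tightly fasciculated bundle scores near 0 and widely spread projections
score toward 1.  DI is undefined (an error, not 0) when the arbor produces
no crossings at all.

Geometry notes.  Crossings are found exactly by solving the segment/circle
quadratic; tangential touches and polyline vertices that sit exactly on a
ring are counted once, not twice (geometric tolerance 1e-9 um).  The cone
orientation search is exact: an optimal cone can always be rotated until one
edge touches a crossing angle, so only edge-anchored candidates need to be
enumerated.  Ties in the maximal in-cone count are broken toward the
smallest cone-centre angle in [0, 360); ties never affect the DI value
itself, only the reported orientation.  SWC input is projected to 2-D by
dropping z (maximum-intensity-projection tracing convention) unless the
configuration rejects 3-D input.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DIUndefinedError, ParseError, ValidationError

#: Tolerance, in micrometers, below which two crossing points are one crossing.
GEOM_TOL_UM = 1e-9

#: Angular tolerance, degrees, for deciding cone-edge membership.
ANGLE_TOL_DEG = 1e-9


@dataclass
class Skeleton:
    """Rooted 2-D polyline arbor in micrometers."""

    root: np.ndarray
    branches: list[np.ndarray]

    def __post_init__(self) -> None:
        self.root = np.asarray(self.root, dtype=float).reshape(2)
        if not np.isfinite(self.root).all():
            raise ValidationError("root coordinates must be finite")
        branches = []
        for i, b in enumerate(self.branches):
            b = np.asarray(b, dtype=float)
            if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] < 2:
                raise ValidationError(f"branch {i}: need >= 2 points of 2 coordinates")
            if not np.isfinite(b).all():
                raise ValidationError(f"branch {i}: non-finite coordinate")
            if (np.linalg.norm(np.diff(b, axis=0), axis=1) == 0).any():
                raise ValidationError(f"branch {i}: consecutive duplicate points")
            branches.append(b)
        self.branches = branches

    def transformed(self, fn) -> "Skeleton":
        """Apply a point transform (e.g. rotation about the root)."""
        return Skeleton(root=fn(self.root), branches=[fn(b) for b in self.branches])


@dataclass
class ShollConfig:
    """Ring/cone geometry; defaults are 15 rings x 10 um with a 15-degree cone."""

    n_rings: int = 15
    ring_spacing_um: float = 10.0
    cone_full_angle_deg: float = 15.0
    orientation_step_deg: float = 0.1   # resolution for the optional grid cross-check
    project_3d: bool = True             # drop SWC z; False rejects 3-D input

    def __post_init__(self) -> None:
        if self.n_rings < 1:
            raise ValidationError("n_rings must be >= 1")
        if self.ring_spacing_um <= 0:
            raise ValidationError("ring_spacing_um must be > 0")
        if not 0 < self.cone_full_angle_deg < 360:
            raise ValidationError("cone_full_angle_deg must lie in (0, 360)")

    @property
    def radii(self) -> np.ndarray:
        return self.ring_spacing_um * np.arange(1, self.n_rings + 1)


@dataclass
class Crossing:
    """One ring/neurite intersection: 1-based ring index, polar angle, point."""

    ring: int
    angle_deg: float
    point: np.ndarray


@dataclass
class IntersectionSet:
    crossings: list[Crossing]
    root: np.ndarray

    def __len__(self) -> int:
        return len(self.crossings)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([c.angle_deg for c in self.crossings], dtype=float)


@dataclass
class DIResult:
    """Crossing counts, the chosen cone orientation, and the index itself."""

    total: int
    in_cone: int
    di: float
    cone_center_deg: float


# ---------------------------------------------------------------------------
# skeleton I/O

def read_skeleton(
    path,
    dialect: str = "swc",
    root: Sequence[float] | None = None,
    project_3d: bool = True,
) -> Skeleton:
    """Read an SWC tree or a ``branch_id,x_um,y_um`` CSV into a :class:`Skeleton`.

    SWC polylines are the maximal unbranched paths of the parent-link tree;
    a branch point is shared by every polyline that meets it.  For the CSV
    dialect the root comes from ``root`` or from a ``<path>.root`` sidecar
    holding ``x,y``.
    """
    path = pathlib.Path(path)
    if dialect == "swc":
        return _read_swc(path, root, project_3d)
    if dialect == "csv_polyline":
        return _read_csv_polyline(path, root)
    raise ValidationError(f"unknown skeleton dialect {dialect!r}")


def _read_swc(path: pathlib.Path, root, project_3d: bool) -> Skeleton:
    nodes: dict[int, tuple[float, float, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 7:
                raise ParseError(f"{path}: line {lineno}: expected 7 SWC columns")
            try:
                nid = int(cols[0])
                x, y, z = float(cols[2]), float(cols[3]), float(cols[4])
                parent = int(cols[6])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if not project_3d and z != 0.0:
                raise ValidationError(f"{path}: line {lineno}: 3-D input rejected (z={z})")
            if nid in nodes:
                raise ParseError(f"{path}: line {lineno}: duplicate node id {nid}")
            nodes[nid] = (x, y, z, parent)
            order.append(nid)
    if not nodes:
        raise ParseError(f"{path}: empty SWC file")

    children: dict[int, list[int]] = {nid: [] for nid in nodes}
    roots = []
    for nid in order:
        parent = nodes[nid][3]
        if parent == -1:
            roots.append(nid)
        else:
            if parent not in nodes:
                raise ParseError(f"{path}: node {nid} references missing parent {parent}")
            children[parent].append(nid)
    if not roots:
        raise ParseError(f"{path}: no root node (parent -1)")

    def xy(nid: int) -> list[float]:
        x, y, _, _ = nodes[nid]
        return [x, y]

    # polylines start at the root or at branch points and run to the next
    # branch point or leaf
    branches: list[np.ndarray] = []
    starts = [nid for nid in order if nodes[nid][3] == -1 or len(children[nid]) > 1]
    for start in starts:
        for child in children[start]:
            pts = [xy(start), xy(child)]
            cur = child
            while len(children[cur]) == 1:
                cur = children[cur][0]
                pts.append(xy(cur))
            if len(pts) >= 2:
                branches.append(np.asarray(pts))
    if not branches:
        raise ValidationError(f"{path}: fewer than 2 points per branch")
    root_pt = np.asarray(root, dtype=float) if root is not None else np.asarray(xy(roots[0]))
    return Skeleton(root=root_pt, branches=branches)


def _read_csv_polyline(path: pathlib.Path, root) -> Skeleton:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: {exc}") from exc
    if list(df.columns) != ["branch_id", "x_um", "y_um"]:
        raise ParseError(f"{path}: header must be branch_id,x_um,y_um")
    if root is None:
        sidecar = path.with_suffix(path.suffix + ".root")
        if not sidecar.exists():
            raise ValidationError(
                f"{path}: csv_polyline needs a root point (argument or {sidecar.name} sidecar)"
            )
        root = [float(v) for v in sidecar.read_text().strip().split(",")]
    branches = []
    for _, grp in df.groupby("branch_id", sort=False):
        branches.append(grp[["x_um", "y_um"]].to_numpy(dtype=float))
    return Skeleton(root=np.asarray(root, dtype=float), branches=branches)


def write_skeleton(skel: Skeleton, path, dialect: str = "swc") -> None:
    """Write a skeleton; ``read_skeleton`` inverts it on the same dialect.

    The CSV dialect round-trips any skeleton exactly (full-precision floats,
    root in a sidecar).  The SWC dialect writes a tree rooted at the root
    point, which is exact for arbors whose branches all start at the root.
    """
    path = pathlib.Path(path)
    if dialect == "csv_polyline":
        rows = []
        for i, b in enumerate(skel.branches):
            for x, y in b:
                rows.append((i, repr(float(x)), repr(float(y))))
        pd.DataFrame(rows, columns=["branch_id", "x_um", "y_um"]).to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".root")
        sidecar.write_text(f"{float(skel.root[0])!r},{float(skel.root[1])!r}\n")
        return
    if dialect != "swc":
        raise ValidationError(f"unknown skeleton dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        fmt = lambda v: repr(float(v))
        fh.write(f"1 1 {fmt(skel.root[0])} {fmt(skel.root[1])} 0 1.0 -1\n")
        nid = 1
        for b in skel.branches:
            if not np.array_equal(b[0], skel.root):
                raise ValidationError(
                    "SWC output requires every branch to start at the root; "
                    "use the csv_polyline dialect for general skeletons"
                )
            parent = 1
            for x, y in b[1:]:
                nid += 1
                fh.write(f"{nid} 3 {fmt(x)} {fmt(y)} 0 1.0 {parent}\n")
                parent = nid


# ---------------------------------------------------------------------------
# geometry

def ring_intersections(skel: Skeleton, config: ShollConfig | None = None) -> IntersectionSet:
    """Exact transversal crossings of every branch with every ring.

    Each segment/circle intersection is found by solving the quadratic
    ``|p0 + t d - root|^2 = r^2`` for t in [0, 1].  Within a branch, a point
    already recorded for the same ring (endpoint shared by two segments, or
    a tangential double root) is not recorded twice.
    """
    config = config or ShollConfig()
    radii = config.radii
    crossings: list[Crossing] = []
    for b in skel.branches:
        rel = b - skel.root
        seen: dict[int, list[np.ndarray]] = {}
        for i in range(len(rel) - 1):
            p0, p1 = rel[i], rel[i + 1]
            d = p1 - p0
            a = float(d @ d)
            bq = 2.0 * float(p0 @ d)
            r0, r1 = np.linalg.norm(p0), np.linalg.norm(p1)
            lo = min(r0, r1)
            hi = max(r0, r1)
            # segments can bow inward toward the root; the closest approach
            # bounds which rings are reachable
            t_min = np.clip(-bq / (2.0 * a), 0.0, 1.0)
            lo = min(lo, float(np.linalg.norm(p0 + t_min * d)))
            for k, r in enumerate(radii, start=1):
                if r < lo - GEOM_TOL_UM or r > hi + GEOM_TOL_UM:
                    continue
                c = float(p0 @ p0) - r * r
                disc = bq * bq - 4.0 * a * c
                if disc < 0:
                    continue
                sq = float(np.sqrt(disc))
                for t in ((-bq - sq) / (2 * a), (-bq + sq) / (2 * a)):
                    if not -GEOM_TOL_UM <= t <= 1.0 + GEOM_TOL_UM:
                        continue
                    pt = p0 + np.clip(t, 0.0, 1.0) * d
                    prev = seen.setdefault(k, [])
                    if any(np.linalg.norm(pt - q) <= GEOM_TOL_UM for q in prev):
                        continue
                    prev.append(pt)
                    ang = float(np.degrees(np.arctan2(pt[1], pt[0]))) % 360.0
                    crossings.append(Crossing(ring=k, angle_deg=ang, point=pt + skel.root))
    return IntersectionSet(crossings=crossings, root=skel.root.copy())


def _circular_diff(angles: np.ndarray, center: float) -> np.ndarray:
    d = np.abs((angles - center) % 360.0)
    return np.minimum(d, 360.0 - d)


def best_cone(
    crossings: IntersectionSet | np.ndarray, config: ShollConfig | None = None
) -> tuple[float, int]:
    """Cone orientation capturing the maximum number of crossing angles.

    Exact via the anchor argument: some optimal cone has an edge touching a
    crossing angle, so centres offset by +-w/2 from each angle (plus the
    angles themselves) exhaust the optima.  Returns ``(center_deg, count)``;
    ties go to the smallest candidate centre in [0, 360).
    """
    config = config or ShollConfig()
    angles = crossings.angles_deg if isinstance(crossings, IntersectionSet) else (
        np.asarray(crossings, dtype=float) % 360.0
    )
    if angles.size == 0:
        raise DIUndefinedError("DI undefined: no intersections")
    half = config.cone_full_angle_deg / 2.0
    if config.cone_full_angle_deg >= 360.0 - ANGLE_TOL_DEG:
        return 0.0, int(angles.size)
    cands = np.unique(np.concatenate([
        (angles + half) % 360.0, (angles - half) % 360.0, angles,
    ]))
    counts = np.array([
        int((_circular_diff(angles, c) <= half + ANGLE_TOL_DEG).sum()) for c in cands
    ])
    best = counts.max()
    center = float(cands[counts == best].min())
    return center, int(best)


def defasciculation_index(skel: Skeleton, config: ShollConfig | None = None) -> DIResult:
    """DI = crossings outside the best-oriented cone / total crossings."""
    config = config or ShollConfig()
    inter = ring_intersections(skel, config)
    if len(inter) == 0:
        raise DIUndefinedError("DI undefined: no intersections")
    center, in_cone = best_cone(inter, config)
    total = len(inter)
    return DIResult(total=total, in_cone=in_cone,
                    di=(total - in_cone) / total, cone_center_deg=center)


def di_batch(
    skeletons: Iterable[tuple[str, Skeleton]] | dict,
    config: ShollConfig | None = None,
    groups: dict | None = None,
) -> "DIBatchResult":
    """Map :func:`defasciculation_index` over labelled skeletons.

    Per-skeleton failures (e.g. no crossings) are flagged rows, not batch
    failures.  ``groups`` optionally maps labels to group names for the
    mean +- SEM summary; otherwise all rows form one group.
    """
    config = config or ShollConfig()
    items = skeletons.items() if isinstance(skeletons, dict) else skeletons
    rows = []
    for label, skel in items:
        group = (groups or {}).get(label, "all")
        try:
            r = defasciculation_index(skel, config)
            rows.append({"label": label, "group": group, "total": r.total,
                         "in_cone": r.in_cone, "di": r.di,
                         "cone_center_deg": r.cone_center_deg, "error": ""})
        except DIUndefinedError as exc:
            rows.append({"label": label, "group": group, "total": 0, "in_cone": 0,
                         "di": np.nan, "cone_center_deg": np.nan, "error": str(exc)})
    per = pd.DataFrame(rows)
    ok = per[per["error"] == ""]
    summary = (
        ok.groupby("group")["di"]
        .agg(n="count", di_mean="mean", di_sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    return DIBatchResult(per_skeleton=per, summary=summary)


@dataclass
class DIBatchResult:
    per_skeleton: pd.DataFrame
    summary: pd.DataFrame
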