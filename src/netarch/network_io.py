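"""Network representations and I/O.

A filament network extracted from a fluorescence image is represented as a
set of *snakes* — ordered, intensity-bearing point sequences tracing cables
(single filaments or unresolvable bundles) — plus a set of *junctions*,
the crossover points where cables intersect.  This module parses the text
output of the SOAX active-contour tracer, reads/writes an internal JSON
schema, and applies the editing rules used on real data: fusing junction
pairs closer than ``1.2 c`` (with ``c`` the snake sampling distance,
0.625 um by default) and pruning spurious snakes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .field import DEFAULT_SAMPLING_DISTANCE, FieldSpec

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1
DEFAULT_FUSE_FACTOR = 1.2


class SoaxParseError(ValueError):
    """Raised when a SOAX result file contains a malformed record."""


@dataclass
class Snake:
    """An open active contour: ordered (x, y, intensity) samples in um.

    ``points`` is an (N, 3) float array with columns x (um), y (um),
    intensity (detector counts/pixel).  At least two points; consecutive
    points must be distinct.
    """

    snake_id: str
    points: np.ndarray
    is_open: bool = True
    ground_truth: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] == 2:  # tolerate intensity-less input
            self.points = np.column_stack([self.points, np.zeros(len(self.points))])
        if self.points.shape[0] < 2:
            raise ValueError(f"snake {self.snake_id!r} needs >= 2 points")
        if self.points.shape[1] != 3:
            raise ValueError("snake points must be (N, 3): x, y, intensity")
        steps = np.diff(self.points[:, :2], axis=0)
        if np.any(np.all(steps == 0.0, axis=1)):
            raise ValueError(f"snake {self.snake_id!r} has coincident consecutive points")
        if np.any(self.points[:, 2] < 0):
            raise ValueError(f"snake {self.snake_id!r} has negative intensities")

    @property
    def xy(self) -> np.ndarray:
        return self.points[:, :2]

    @property
    def intensities(self) -> np.ndarray:
        return self.points[:, 2]

    @property
    def length(self) -> float:
        """Contour length in um."""
        return float(np.sum(np.hypot(*np.diff(self.xy, axis=0).T)))

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensities))


@dataclass
class Junction:
    """A filament crossover point."""

    junction_id: str
    centroid: tuple[float, float]
    incident_snakes: list[str] = dc_field(default_factory=list)


@dataclass
class NetworkModel:
    """Snakes + junctions for one field of view.

    ``c`` is the snake sampling distance in um (default 0.625 um = 8 pixels);
    it sets the length scale of the junction-fusion rule and the default
    curvature sampling distance.
    """

    snakes: list[Snake]
    junctions: list[Junction]
    field: FieldSpec
    c: float = DEFAULT_SAMPLING_DISTANCE

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("sampling distance c must be positive")
        ids = [j.junction_id for j in self.junctions]
        if len(ids) != len(set(ids)):
            raise ValueError("junction ids must be unique")

    def junction_coords(self) -> np.ndarray:
        """(M, 2) array of junction centroids in um."""
        if not self.junctions:
            return np.empty((0, 2))
        return np.array([j.centroid for j in self.junctions], dtype=float)


# ---------------------------------------------------------------------------
# SOAX-dialect text parsing
# ---------------------------------------------------------------------------

def parse_soax(
    path: str | Path,
    pixel_size: float,
    field: FieldSpec | None = None,
    c: float = DEFAULT_SAMPLING_DISTANCE,
) -> NetworkModel:
    """Parse a SOAX-style result text file into a :class:`NetworkModel`.

    The dialect is: header lines prefixed with ``#`` (parameter dumps from
    the tracer, ignored except for warnings), per-point records with at
    least six fields ``snake_index point_index x y z intensity`` (comma or
    whitespace delimited; coordinates in pixels), and a trailing junction
    block introduced by a line containing ``junction`` followed by ``x y
    [z]`` coordinate rows.  Pixel coordinates are converted to um via
    ``pixel_size``.  A nonzero z anywhere triggers a single warning (the
    analysis is a 2-D projection).
    """
    path = Path(path)
    snake_points: dict[int, list[tuple[int, float, float, float]]] = {}
    junction_xy: list[tuple[float, float]] = []
    in_junctions = False
    saw_junction_marker = False
    saw_nonzero_z = False

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#") or line.startswith("["):
            if "junction" in line.lower():
                in_junctions = True
                saw_junction_marker = True
            continue
        if "junction" in line.lower():
            in_junctions = True
            saw_junction_marker = True
            continue
        fields = line.replace(",", " ").split()
        try:
            values = [float(v) for v in fields]
        except ValueError as exc:
            raise SoaxParseError(f"{path.name}:{lineno}: malformed record {line!r}") from exc
        if in_junctions:
            if len(values) < 2:
                raise SoaxParseError(f"{path.name}:{lineno}: junction record needs x y")
            x, y = values[0], values[1]
            if len(values) >= 3 and values[2] != 0.0:
                saw_nonzero_z = True
            junction_xy.append((x * pixel_size, y * pixel_size))
        else:
            if len(values) < 6:
                raise SoaxParseError(
                    f"{path.name}:{lineno}: point record needs >= 6 fields "
                    "(snake, point, x, y, z, intensity)"
                )
            s_idx, p_idx, x, y, z, inten = values[:6]
            if z != 0.0:
                saw_nonzero_z = True
            snake_points.setdefault(int(s_idx), []).append(
                (int(p_idx), x * pixel_size, y * pixel_size, inten)
            )

    if saw_nonzero_z:
        warnings.warn("nonzero z coordinates ignored (2-D projection analysis)", stacklevel=2)
    if not saw_junction_marker and snake_points:
        warnings.warn(f"{path.name}: no junction block found; junction list empty", stacklevel=2)
    if not snake_points and not junction_xy:
        warnings.warn(f"{path.name}: no records parsed; empty model", stacklevel=2)

    snakes = []
    for s_idx in sorted(snake_points):
        rows = sorted(snake_points[s_idx])
        pts = np.array([(x, y, i) for _, x, y, i in rows])
        if len(pts) >= 2:
            snakes.append(Snake(snake_id=f"s{s_idx}", points=pts))
        else:
            log.warning("snake %d has < 2 points; dropped", s_idx)

    junctions = [
        Junction(junction_id=f"j{i}", centroid=(x, y)) for i, (x, y) in enumerate(junction_xy)
    ]

    if field is None:
        all_xy = [s.xy for s in snakes]
        if junction_xy:
            all_xy.append(np.array(junction_xy))
        if all_xy:
            coords = np.vstack(all_xy)
            width = max(float(coords[:, 0].max()) + pixel_size, pixel_size)
            height = max(float(coords[:, 1].max()) + pixel_size, pixel_size)
        else:
            width = height = pixel_size
        field = FieldSpec(width=width, height=height, pixel_size=pixel_size)

    model = NetworkModel(snakes=snakes, junctions=junctions, field=field, c=c)
    _assign_incidence(model)
    return model


def _assign_incidence(net: NetworkModel) -> None:
    """Recompute junction-snake incidence geometrically.

    A snake is incident on a junction when any of its sampled points lies
    within ``c/2`` of the junction centroid.
    """
    if not net.junctions or not net.snakes:
        return
    jc = net.junction_coords()
    tree = cKDTree(jc)
    for snake in net.snakes:
        hit = tree.query_ball_point(snake.xy, r=net.c / 2.0)
        incident = sorted({j for sub in hit for j in sub})
        for j in incident:
            if snake.snake_id not in net.junctions[j].incident_snakes:
                net.junctions[j].incident_snakes.append(snake.snake_id)


# ---------------------------------------------------------------------------
# Internal JSON schema
# ---------------------------------------------------------------------------

def write_network_json(net: NetworkModel, path: str | Path) -> None:
    """Serialize a network to the versioned internal JSON schema."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "field": net.field.to_dict(),
        "c": net.c,
        "snakes": [
            {
                "snake_id": s.snake_id,
                "is_open": s.is_open,
                "points": [[float(x), float(y), float(i)] for x, y, i in s.points],
            }
            for s in net.snakes
        ],
        "junctions": [
            {
                "junction_id": j.junction_id,
                "centroid": [float(j.centroid[0]), float(j.centroid[1])],
                "incident_snakes": list(j.incident_snakes),
            }
            for j in net.junctions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_network_json(path: str | Path) -> NetworkModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported network schema version {doc.get('schema_version')!r}")
    snakes = [
        Snake(snake_id=s["snake_id"], points=np.array(s["points"]), is_open=s.get("is_open", True))
        for s in doc["snakes"]
    ]
    junctions = [
        Junction(
            junction_id=j["junction_id"],
            centroid=(j["centroid"][0], j["centroid"][1]),
            incident_snakes=list(j.get("incident_snakes", [])),
        )
        for j in doc["junctions"]
    ]
    return NetworkModel(
        snakes=snakes,
        junctions=junctions,
        field=FieldSpec.from_dict(doc["field"]),
        c=doc.get("c", DEFAULT_SAMPLING_DISTANCE),
    )


# ---------------------------------------------------------------------------
# Editing rules
# ---------------------------------------------------------------------------

def fuse_junctions(net: NetworkModel, factor: float = DEFAULT_FUSE_FACTOR) -> NetworkModel:
    """Fuse neighbouring junctions closer than ``factor * c``.

    Fusion is transitive (single-link): junctions connected by a chain of
    sub-threshold gaps collapse into one, placed at the unweighted centroid
    of the original member junctions, with incident snake lists unioned.
    The merge is iterated to a fixed point so the operation is idempotent,
    and it is independent of junction input order up to id relabelling.
    """
    if factor <= 0:
        raise ValueError("fusion factor must be positive")
    threshold = factor * net.c
    coords = net.junction_coords()
    if len(coords) < 2:
        return net

    # Each working junction carries the count of original members so that
    # repeated merges still yield the unweighted centroid of the originals.
    weights = np.ones(len(coords))
    members: list[list[str]] = [list(j.incident_snakes) for j in net.junctions]

    while True:
        tree = cKDTree(coords)
        pairs = tree.query_pairs(r=threshold)
        # strict inequality: the rule is separation < factor*c
        pairs = [(i, j) for i, j in pairs if np.hypot(*(coords[i] - coords[j])) < threshold]
        if not pairs:
            break
        parent = list(range(len(coords)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in pairs:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
        groups: dict[int, list[int]] = {}
        for i in range(len(coords)):
            groups.setdefault(find(i), []).append(i)
        new_coords, new_weights, new_members = [], [], []
        for idx in sorted(groups):
            g = groups[idx]
            w = weights[g]
            new_coords.append(np.average(coords[g], axis=0, weights=w))
            new_weights.append(w.sum())
            merged: list[str] = []
            for gi in g:
                for sid in members[gi]:
                    if sid not in merged:
                        merged.append(sid)
            new_members.append(merged)
        coords = np.array(new_coords)
        weights = np.array(new_weights)
        members = new_members

    order = np.lexsort((coords[:, 1], coords[:, 0]))
    junctions = [
        Junction(junction_id=f"j{k}", centroid=tuple(coords[i]), incident_snakes=sorted(members[i]))
        for k, i in enumerate(order)
    ]
    log.info("fuse_junctions: %d -> %d junctions", len(net.junctions), len(junctions))
    return NetworkModel(snakes=net.snakes, junctions=junctions, field=net.field, c=net.c)


def prune_snakes(
    net: NetworkModel, min_length: float = 0.0, min_mean_intensity: float = 0.0
) -> NetworkModel:
    """Remove spurious snakes below a length or mean-intensity threshold.

    Junctions are never touched here; removals are logged so that the
    effect of the editing step stays auditable.
    """
    if min_length < 0 or min_mean_intensity < 0:
        raise ValueError("pruning thresholds must be >= 0")
    kept, removed = [], []
    for s in net.snakes:
        if s.length < min_length or s.mean_intensity < min_mean_intensity:
            removed.append(s.snake_id)
        else:
            kept.append(s)
    if removed:
        log.info("prune_snakes removed %d snakes: %s", len(removed), removed)
    return NetworkModel(snakes=kept, junctions=net.junctions, field=net.field, c=net.c)


__all__ = [
    "Snake",
    "Junction",
    "NetworkModel",
    "SoaxParseError",
    "parse_soax",
    "write_network_json",
    "read_network_json",
    "fuse_junctions",
    "prune_snakes",
    "DEFAULT_FUSE_FACTOR",
]
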