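"""Branching-morphogenesis simulation and time-lapse morphometrics for the
developing renal collecting duct.

The mouse collecting-duct system arises by repeated bifurcation of an
initially unbranched epithelial tube, the ureteric bud.  Early growth
produces an almost fractal tree with branch points (nodes) spread through
the organ; the mature medulla instead shows long, nearly parallel ducts
converging on the renal pelvis.  ``budmorph`` implements a 2-D model of
this transformation: exponential branch elongation, timed synchronous tip
bifurcation at a fixed divergence angle (93 degrees by default, the value
measured in cultured kidneys), and *node retraction* -- centripetal
movement of internal branch points that shortens their stalks, spares the
central "pelvis" segment and the terminal tips, and remodels a spread tree
into a radially organised one.

The module is organised in the order a study runs:

1.  configuration and logging;
2.  the tree model (node records, derived 2-D geometry, SWC and tabular
    serialisation, time-lapse container);
3.  the simulation engine (growth, bifurcation, retraction, thickness law,
    the main ``run`` loop);
4.  morphometrics on time-lapse data (internode length series, radial
    growth, divergence angles, retraction detection and incidence, radial
    alignment, frame registration, exponential-rate recovery);
5.  synthetic time-lapse fixtures with measurement noise, stage drift and
    ground-truth labels;
6.  rendering (SVG/PNG panels with an age-dependent thickness law).

Lengths are in arbitrary units (nominally micrometres), angles in degrees,
time in arbitrary simulation units.
"""

from __future__ import annotations

import io
import logging
import math
import os
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BudmorphError",
    "ConfigError",
    "StructureError",
    "SWCParseError",
    "MeasurementError",
    "NodeRecord",
    "Tree",
    "TimeLapse",
    "SimulationConfig",
    "load_config",
    "write_manifest",
    "derive_positions",
    "tip_count",
    "write_swc",
    "read_swc",
    "write_timelapse",
    "read_timelapse",
    "tree_to_table",
    "tree_from_table",
    "apply_growth",
    "bifurcate_tips",
    "apply_retraction",
    "thickness",
    "descendant_count",
    "retraction_eligible",
    "run",
    "LengthSeries",
    "RetractionCall",
    "FractionResult",
    "internode_length_series",
    "radial_growth_series",
    "path_length_series",
    "divergence_angle",
    "detect_retraction",
    "fraction_retracting",
    "restrict_timelapse",
    "radial_alignment",
    "register_frames",
    "fit_exponential_rate",
    "FixtureSpec",
    "make_fixture",
    "default_fixture",
    "evaluate_detection",
    "RenderSpec",
    "render",
    "render_svg",
    "render_png",
]

# --------------------------------------------------------------------------
# configuration & logging
# --------------------------------------------------------------------------

logger = logging.getLogger("budmorph")

_EPS = 1e-12


class BudmorphError(Exception):
    """Base class for all budmorph errors."""


class ConfigError(BudmorphError, ValueError):
    """Invalid parameter or configuration value (names the offending field)."""


class StructureError(BudmorphError):
    """Tree violates structural invariants (cycle, missing parent, ...)."""


class SWCParseError(BudmorphError):
    """Malformed SWC input; message carries the 1-based line number."""


class MeasurementError(BudmorphError):
    """A morphometric operation cannot apply to the given node/series."""


@dataclass
class SimulationConfig:
    """All parameters of the growth + bifurcation + retraction model.

    Rates are per unit time and act multiplicatively per unit length
    (exponential laws), so trajectories are independent of the step size
    ``dt``.  Defaults describe the reference run used throughout the test
    suite: five synchronous bifurcation rounds (32 tips) during a growth
    era of 5.5 time units, then a pure retraction era until t = 8.

    Attributes
    ----------
    growth_rate : float
        Exponential elongation rate of every segment during the growth era.
    retraction_rate : float
        Exponential shortening rate of eligible internal stalks.
    bifurcation_interval : float
        Time between synchronous bifurcation rounds; rounds fire at
        t = k * interval for t strictly inside the growth era.
    divergence_angle : float
        Inter-daughter angle at a fresh bifurcation, degrees.  93 by
        default (measured in cultured kidneys); 90 is the classical
        literature value.
    daughter_initial_length : float
        Length of a freshly created daughter segment.
    growth_end_time : float
        Growth and branching stop at this time.
    retraction_start_time : float or None
        Retraction era start; ``None`` resolves to ``growth_end_time``
        (the reference behaviour).  May be set earlier to overlap growth,
        as seen in live cultures where some branches still elongate while
        neighbours retract.
    run_end_time : float
        End of the run; retraction may continue after growth stops until
        this time.
    retraction_enabled : bool
        Master switch for node retraction.
    retraction_mode : {'length_based', 'tip_anchored'}
        'length_based': eligible stalk lengths decay, relative angles
        fixed (the classical formulation).  'tip_anchored': the node is
        pulled toward its parent while its daughters' distal endpoints
        stay fixed, so daughters lengthen and their divergence angle
        narrows (the behaviour seen in time-lapse movies).
    dt : float
        Step size of the main loop.  ``frame_interval`` must be an
        integer multiple of it.
    frame_interval : float
        Time between recorded frames (mirrors movie acquisition).
    thickness_base, thickness_slope : float
        Rendering thickness law: base + slope * (descendants of the
        segment's distal node), so older branches draw thicker.
    seed : int
        Seed for the angle-jitter generator (the only stochastic element).
    angle_jitter_sigma : float
        Gaussian jitter (degrees) added independently to each daughter's
        relative angle; 0 gives a fully deterministic, self-similar tree.
    root_heading : float
        Absolute direction of the root segment, degrees (90 = 'outward').
    """

    growth_rate: float = 0.35
    retraction_rate: float = 1.0
    bifurcation_interval: float = 1.0
    divergence_angle: float = 93.0
    daughter_initial_length: float = 0.05
    growth_end_time: float = 5.5
    retraction_start_time: float | None = None
    run_end_time: float = 8.0
    retraction_enabled: bool = True
    retraction_mode: str = "length_based"
    dt: float = 0.05
    frame_interval: float = 0.25
    thickness_base: float = 1.0
    thickness_slope: float = 0.25
    seed: int = 0
    angle_jitter_sigma: float = 0.0
    root_heading: float = 90.0

    def resolved_retraction_start(self) -> float:
        return (
            self.growth_end_time
            if self.retraction_start_time is None
            else self.retraction_start_time
        )

    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the first invalid field."""
        numeric = [f.name for f in fields(self) if f.name not in ("retraction_enabled", "retraction_mode", "seed")]
        for name in numeric:
            value = getattr(self, name)
            if value is None and name == "retraction_start_time":
                continue
            if not isinstance(value, (int, float)) or not math.isfinite(value):
                raise ConfigError(f"{name}: must be a finite number, got {value!r}")
        for name in ("growth_rate", "retraction_rate", "dt", "daughter_initial_length", "bifurcation_interval", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be > 0, got {getattr(self, name)}")
        if self.growth_end_time < 0:
            raise ConfigError(f"growth_end_time: must be >= 0, got {self.growth_end_time}")
        if self.run_end_time < self.growth_end_time:
            raise ConfigError(
                f"run_end_time: must be >= growth_end_time "
                f"({self.run_end_time} < {self.growth_end_time})"
            )
        if not 0.0 < self.divergence_angle < 180.0:
            raise ConfigError(
                f"divergence_angle: must lie in (0, 180) degrees, got {self.divergence_angle}"
            )
        if self.retraction_mode not in ("length_based", "tip_anchored"):
            raise ConfigError(
                f"retraction_mode: unknown mode {self.retraction_mode!r} "
                "(expected 'length_based' or 'tip_anchored')"
            )
        if self.angle_jitter_sigma < 0:
            raise ConfigError(f"angle_jitter_sigma: must be >= 0, got {self.angle_jitter_sigma}")
        ratio = self.frame_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError(
                f"frame_interval: must be an integer multiple of dt "
                f"({self.frame_interval} / {self.dt})"
            )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
        cfg = cls(**dict(data))
        cfg.validate()
        return cfg


def load_config(path: str | os.PathLike) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from YAML or flat ``key = value`` text.

    Field names mirror the dataclass exactly; unknown keys raise
    :class:`ConfigError`.
    """
    text = Path(path).read_text()
    data = None
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = None
    if not isinstance(data, Mapping):
        data = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}: line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            data[key.strip()] = yaml.safe_load(value.strip())
    return SimulationConfig.from_dict(data)


def write_manifest(path: str | os.PathLike, entries: Mapping) -> None:
    """Write a plain-text ``key=value`` manifest enabling exact re-runs."""
    with open(path, "w") as fh:
        for key in sorted(entries):
            fh.write(f"{key}={entries[key]}\n")


def read_manifest(path: str | os.PathLike) -> dict:
    out: dict = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        key, _, value = raw.partition("=")
        out[key.strip()] = yaml.safe_load(value.strip())
    return out


# --------------------------------------------------------------------------
# tree model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeRecord:
    """One node (branch point or tip) of the tree.

    Geometry is intrinsic: each node stores the length of the segment from
    its mother and the signed angle of that segment relative to the
    mother's direction; absolute x,y positions are derived on demand.
    The root stores an absolute heading on the tree instead.

    ``kind`` is 'root' for the unique parentless node, otherwise 'tip'
    (no children) or 'internal'.  The simulator only ever bifurcates, so
    its internal nodes have exactly two children; unary chain nodes are
    tolerated when reading external skeletons.
    """

    node_id: int
    parent_id: int | None
    branch_length: float
    relative_angle: float
    birth_time: float = 0.0
    kind: str = "tip"


class Tree:
    """A rooted, strictly bifurcating 2-D tree at one instant.

    Positions are a pure function of (branch lengths, relative angles,
    ``root_heading``); the proximal end of the root segment sits at the
    origin.  Trees are treated as immutable: simulator operations return
    new trees.
    """

    def __init__(
        self,
        nodes: Iterable[NodeRecord],
        root_heading: float = 90.0,
        time: float = 0.0,
        validate: bool = True,
    ) -> None:
        self.nodes: dict[int, NodeRecord] = {}
        for rec in nodes:
            if rec.node_id in self.nodes:
                raise StructureError(f"duplicate node_id {rec.node_id}")
            self.nodes[rec.node_id] = rec
        self.root_heading = float(root_heading)
        self.time = float(time)
        self._children: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        roots = []
        for rec in self.nodes.values():
            if rec.parent_id is None:
                roots.append(rec.node_id)
            else:
                if rec.parent_id not in self.nodes:
                    raise StructureError(
                        f"node {rec.node_id}: parent {rec.parent_id} not in tree"
                    )
                self._children[rec.parent_id].append(rec.node_id)
        if len(roots) != 1:
            raise StructureError(f"tree must have exactly one root, found {len(roots)}")
        self._root_id = roots[0]
        for kids in self._children.values():
            kids.sort()
        if validate:
            self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def root_id(self) -> int:
        return self._root_id

    def children(self, node_id: int) -> list[int]:
        return self._children[node_id]

    def parent(self, node_id: int) -> int | None:
        return self.nodes[node_id].parent_id

    def preorder(self) -> list[int]:
        """Node ids root-first; children visited in ascending id order."""
        order: list[int] = []
        stack = [self._root_id]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(reversed(self._children[nid]))
        return order

    def validate(self) -> None:
        """Check connectivity, bifurcation and kind invariants."""
        order = self.preorder()
        if len(order) != len(self.nodes):
            seen = set(order)
            orphan = next(n for n in self.nodes if n not in seen)
            raise StructureError(
                f"node {orphan}: unreachable from root (cycle or broken lineage)"
            )
        for nid, rec in self.nodes.items():
            if rec.branch_length < 0:
                raise StructureError(f"node {nid}: negative branch_length")
            n_kids = len(self._children[nid])
            if n_kids > 2:
                raise StructureError(
                    f"node {nid}: has {n_kids} children; the tree is at most bifurcating"
                )
            expected = _kind_for(rec.parent_id, n_kids)
            if rec.kind != expected:
                raise StructureError(
                    f"node {nid}: kind {rec.kind!r} inconsistent with structure "
                    f"(expected {expected!r})"
                )

    def leaves(self) -> list[int]:
        return [nid for nid in self.nodes if not self._children[nid]]

    def bifurcation_nodes(self) -> list[int]:
        return [nid for nid in self.nodes if len(self._children[nid]) == 2]

    def with_time(self, time: float) -> "Tree":
        clone = Tree(self.nodes.values(), self.root_heading, time, validate=False)
        return clone

    # -- geometry ----------------------------------------------------------

    def derive_positions(self) -> dict[int, np.ndarray]:
        """Absolute 2-D position of every node, root base at the origin.

        position(root) = branch_length * unit(root_heading); every other
        node extends its parent's position along direction(parent) +
        relative_angle.  Deterministic preorder construction.
        """
        pos: dict[int, np.ndarray] = {}
        heading: dict[int, float] = {}
        for nid in self.preorder():
            rec = self.nodes[nid]
            if rec.parent_id is None:
                theta = self.root_heading
                base = np.zeros(2)
            else:
                theta = heading[rec.parent_id] + rec.relative_angle
                base = pos[rec.parent_id]
            heading[nid] = theta
            rad = math.radians(theta)
            pos[nid] = base + rec.branch_length * np.array(
                [math.cos(rad), math.sin(rad)]
            )
        return pos

    def headings(self) -> dict[int, float]:
        """Absolute direction (degrees) of every segment."""
        heading: dict[int, float] = {}
        for nid in self.preorder():
            rec = self.nodes[nid]
            if rec.parent_id is None:
                heading[nid] = self.root_heading
            else:
                heading[nid] = heading[rec.parent_id] + rec.relative_angle
        return heading

    def depths(self) -> dict[int, int]:
        depth: dict[int, int] = {}
        for nid in self.preorder():
            pid = self.nodes[nid].parent_id
            depth[nid] = 0 if pid is None else depth[pid] + 1
        return depth


def _kind_for(parent_id: int | None, n_children: int) -> str:
    if parent_id is None:
        return "root"
    return "tip" if n_children == 0 else "internal"


def _wrap_angle(a: float) -> float:
    """Wrap to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def derive_positions(tree: Tree) -> dict[int, np.ndarray]:
    """Module-level alias for :meth:`Tree.derive_positions`."""
    return tree.derive_positions()


def tip_count(tree: Tree) -> int:
    """Number of leaf nodes (an unbranched bud counts as one tip)."""
    return len(tree.leaves())


def _tree_from_positions(template: Tree, pos: Mapping[int, np.ndarray], time: float | None = None) -> Tree:
    """Rebuild intrinsic geometry (lengths, relative angles, heading) from
    an absolute position map, keeping topology, kinds and birth times."""
    heading: dict[int, float] = {}
    records: list[NodeRecord] = []
    root_heading = template.root_heading
    for nid in template.preorder():
        rec = template.nodes[nid]
        p = np.asarray(pos[nid], dtype=float)
        if rec.parent_id is None:
            vec = p  # root base at origin
        else:
            vec = p - np.asarray(pos[rec.parent_id], dtype=float)
        length = float(np.hypot(vec[0], vec[1]))
        if length > 0:
            theta = math.degrees(math.atan2(vec[1], vec[0]))
        else:  # degenerate zero-length segment keeps its old direction
            theta = (
                template.root_heading
                if rec.parent_id is None
                else heading[rec.parent_id] + rec.relative_angle
            )
        heading[nid] = theta
        if rec.parent_id is None:
            root_heading = theta
            rel = rec.relative_angle
        else:
            rel = _wrap_angle(theta - heading[rec.parent_id])
        records.append(replace(rec, branch_length=length, relative_angle=rel))
    return Tree(records, root_heading, template.time if time is None else time, validate=False)


# -- serialisation ---------------------------------------------------------

_SWC_COLUMNS = ["node_id", "type", "x", "y", "z", "radius", "parent_id"]


def write_swc(
    tree: Tree,
    path: str | os.PathLike,
    coords: Mapping[int, np.ndarray] | None = None,
    thickness_base: float = 1.0,
    thickness_slope: float = 0.25,
) -> None:
    """Write the tree as standard 7-column SWC (id type x y z radius parent).

    The z column is 0; type is 0 for every segment; the radius column
    carries the rendering thickness law value for the segment.  ``coords``
    may override the derived positions (used for noisy fixture frames).
    Floats are written with 9 decimals so identical trees produce
    byte-identical files.
    """
    pos = tree.derive_positions() if coords is None else coords
    counts = _descendant_counts(tree)
    lines = [
        "# SWC tree skeleton (id type x y z radius parent)",
        f"# time {tree.time:.9f}",
    ]
    for nid in tree.preorder():
        rec = tree.nodes[nid]
        p = pos[nid]
        radius = thickness_base + thickness_slope * counts[nid]
        parent = -1 if rec.parent_id is None else rec.parent_id
        lines.append(
            f"{nid} 0 {p[0]:.9f} {p[1]:.9f} 0 {radius:.9f} {parent}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path: str | os.PathLike) -> Tree:
    """Read an SWC file back into a :class:`Tree`.

    Intrinsic geometry (lengths, relative angles, root heading) is
    recovered from the coordinates, with the root segment taken to start
    at the origin (the writer's convention).  Raises
    :class:`SWCParseError` with a line number on malformed lines,
    duplicate ids, forward references to unseen parents, or a second root.
    """
    pos: dict[int, np.ndarray] = {}
    parents: dict[int, int | None] = {}
    time = 0.0
    root_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*time\s+([-+0-9.eE]+)", line)
            if m:
                time = float(m.group(1))
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCParseError(f"{path}: line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid = int(parts[0])
            x, y = float(parts[2]), float(parts[3])
            parent = int(parts[6])
        except ValueError as exc:
            raise SWCParseError(f"{path}: line {lineno}: {exc}") from None
        if nid in pos:
            raise SWCParseError(f"{path}: line {lineno}: duplicate node id {nid}")
        if parent == -1:
            if root_seen:
                raise SWCParseError(
                    f"{path}: line {lineno}: second root (parent -1) at node {nid}"
                )
            root_seen = True
            parents[nid] = None
        else:
            if parent not in pos:
                raise SWCParseError(
                    f"{path}: line {lineno}: node {nid} references unseen parent {parent}"
                )
            parents[nid] = parent
        pos[nid] = np.array([x, y])
    if not pos:
        raise SWCParseError(f"{path}: no nodes found")
    n_children: dict[int, int] = {nid: 0 for nid in pos}
    for nid, pid in parents.items():
        if pid is not None:
            n_children[pid] += 1
    records = [
        NodeRecord(nid, parents[nid], 0.0, 0.0, 0.0, _kind_for(parents[nid], n_children[nid]))
        for nid in pos
    ]
    skeleton = Tree(records, 90.0, time, validate=False)
    return _tree_from_positions(skeleton, pos, time=time)


def tree_to_table(tree: Tree) -> pd.DataFrame:
    """Flat node table: node_id,parent_id,branch_length,relative_angle,birth_time,kind."""
    rows = [
        {
            "node_id": rec.node_id,
            "parent_id": rec.parent_id,
            "branch_length": rec.branch_length,
            "relative_angle": rec.relative_angle,
            "birth_time": rec.birth_time,
            "kind": rec.kind,
        }
        for rec in (tree.nodes[n] for n in tree.preorder())
    ]
    return pd.DataFrame(rows, columns=["node_id", "parent_id", "branch_length", "relative_angle", "birth_time", "kind"])


def tree_from_table(table: pd.DataFrame, root_heading: float = 90.0, time: float = 0.0) -> Tree:
    records = []
    for row in table.itertuples(index=False):
        pid = None if pd.isna(row.parent_id) else int(row.parent_id)
        records.append(
            NodeRecord(
                int(row.node_id), pid, float(row.branch_length),
                float(row.relative_angle), float(row.birth_time), str(row.kind),
            )
        )
    return Tree(records, root_heading, time)


# -- time-lapse container --------------------------------------------------


@dataclass
class TimeLapse:
    """An ordered sequence of tree snapshots at a fixed frame interval.

    ``coords`` optionally carries *observed* per-frame coordinates (noisy
    and/or drifted); measurements use them when present and fall back to
    the derived (clean) positions otherwise.  ``drift`` records the global
    translation applied to each frame, if any.
    """

    frames: list[Tree]
    frame_interval: float
    noise_sigma: float = 0.0
    drift: np.ndarray | None = None
    coords: list[dict[int, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.frames)

    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def coordinates(self, k: int) -> dict[int, np.ndarray]:
        if self.coords is not None:
            return self.coords[k]
        return self.frames[k].derive_positions()

    def validate(self) -> None:
        times = self.times()
        if len(times) > 1:
            steps = np.diff(times)
            if not np.allclose(steps, self.frame_interval, atol=1e-6):
                raise StructureError("frame times must increase by frame_interval")
        present = [set(f.nodes) for f in self.frames]
        for k in range(len(present) - 2):
            ghosts = (present[k] & present[k + 2]) - present[k + 1]
            if ghosts:
                raise StructureError(
                    f"node {min(ghosts)} present in frames {k} and {k + 2} "
                    f"but missing from frame {k + 1}"
                )


def write_timelapse(
    timelapse: TimeLapse,
    out_dir: str | os.PathLike,
    thickness_base: float = 1.0,
    thickness_slope: float = 0.25,
    frame_indices: Sequence[int] | None = None,
) -> list[Path]:
    """Write one ``frame_%05d.swc`` per frame plus a small manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    indices = list(range(len(timelapse))) if frame_indices is None else list(frame_indices)
    paths = []
    for j, k in enumerate(indices):
        path = out / f"frame_{j:05d}.swc"
        coords = timelapse.coords[k] if timelapse.coords is not None else None
        write_swc(timelapse.frames[k], path, coords=coords,
                  thickness_base=thickness_base, thickness_slope=thickness_slope)
        paths.append(path)
    return paths


def read_timelapse(frames_dir: str | os.PathLike) -> TimeLapse:
    """Load a directory of ``frame_*.swc`` files into a :class:`TimeLapse`.

    Observed coordinates are taken verbatim from the files (so noise and
    drift survive the round trip); the frame interval is inferred from the
    recorded frame times.
    """
    files = sorted(Path(frames_dir).glob("frame_*.swc"))
    if not files:
        raise MeasurementError(f"no frame_*.swc files found in {frames_dir}")
    frames, coords = [], []
    for path in files:
        tree = read_swc(path)
        frames.append(tree)
        coords.append(tree.derive_positions())
    times = np.array([f.time for f in frames])
    interval = float(np.median(np.diff(times))) if len(frames) > 1 else 1.0
    tl = TimeLapse(frames, interval, coords=coords)
    tl.validate()
    return tl


# --------------------------------------------------------------------------
# simulation engine
# --------------------------------------------------------------------------


def _descendant_counts(tree: Tree) -> dict[int, int]:
    counts = {nid: 0 for nid in tree.nodes}
    for nid in reversed(tree.preorder()):
        pid = tree.nodes[nid].parent_id
        if pid is not None:
            counts[pid] += counts[nid] + 1
    return counts


def descendant_count(tree: Tree, node_id: int) -> int:
    """Number of descendants of ``node_id`` (children, grandchildren, ...)."""
    if node_id not in tree.nodes:
        raise StructureError(f"node {node_id} not in tree")
    return _descendant_counts(tree)[node_id]


def thickness(
    tree: Tree, node_id: int, thickness_base: float = 1.0, thickness_slope: float = 0.25
) -> float:
    """Rendering thickness of the segment ending at ``node_id``.

    base + slope * descendant count of the distal node, so thickness is a
    strictly increasing proxy for segment age: tips get the base value,
    the trunk draws thickest.
    """
    return thickness_base + thickness_slope * descendant_count(tree, node_id)


def retraction_eligible(tree: Tree) -> list[int]:
    """Distal node ids of segments subject to retraction.

    Retraction spares the terminal branches and the central 'pelvis'
    (root) segment: eligible segments end at nodes that have a parent and
    exactly two children.
    """
    return [
        nid
        for nid in tree.preorder()
        if tree.nodes[nid].parent_id is not None and len(tree.children(nid)) == 2
    ]


def _scale_lengths(tree: Tree, factor: float, node_ids: Iterable[int]) -> Tree:
    ids = set(node_ids)
    records = [
        replace(rec, branch_length=rec.branch_length * factor) if rec.node_id in ids else rec
        for rec in tree.nodes.values()
    ]
    return Tree(records, tree.root_heading, tree.time, validate=False)


def apply_growth(tree: Tree, rate: float, dt: float) -> Tree:
    """Elongate every segment by the exact factor exp(rate * dt).

    Growth is a constant rate per unit length, i.e. exponential; per-step
    exact factors make n small steps identical to one big one.
    """
    if rate < 0 or dt < 0:
        raise ConfigError(f"growth rate and dt must be >= 0 (rate={rate}, dt={dt})")
    if rate * dt == 0:
        return tree
    return _scale_lengths(tree, math.exp(rate * dt), tree.nodes)


def bifurcate_tips(
    tree: Tree,
    divergence_angle: float = 93.0,
    daughter_initial_length: float = 0.05,
    jitter_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    time: float | None = None,
) -> Tree:
    """Synchronously bifurcate every tip into two daughters.

    Each former tip becomes an internal node; its daughters start at
    ``daughter_initial_length`` with relative angles -/+ divergence/2
    (left daughter first), plus independent Gaussian jitter when
    ``jitter_sigma`` > 0 (consumed in ascending tip-id order, left before
    right, so runs are reproducible).  Pre-existing geometry is untouched.
    """
    if not 0.0 < divergence_angle < 180.0:
        raise ConfigError(
            f"divergence_angle: must lie in (0, 180) degrees, got {divergence_angle}"
        )
    if daughter_initial_length <= 0:
        raise ConfigError(
            f"daughter_initial_length: must be > 0, got {daughter_initial_length}"
        )
    birth = tree.time if time is None else time
    half = divergence_angle / 2.0
    records = {nid: rec for nid, rec in tree.nodes.items()}
    next_id = max(records) + 1
    for tip in sorted(tree.leaves()):
        rec = records[tip]
        records[tip] = replace(rec, kind=_kind_for(rec.parent_id, 2))
        for sign in (-1.0, +1.0):
            angle = sign * half
            if jitter_sigma > 0:
                if rng is None:
                    raise ConfigError("jitter_sigma > 0 requires an rng")
                angle += float(rng.normal(0.0, jitter_sigma))
            records[next_id] = NodeRecord(
                next_id, tip, daughter_initial_length, angle, birth, "tip"
            )
            next_id += 1
    return Tree(records.values(), tree.root_heading, tree.time, validate=False)


def apply_retraction(
    tree: Tree, rate: float, dt: float, mode: str = "length_based"
) -> Tree:
    """Retract eligible internal nodes toward the tree base.

    Terminal branches and the central 'pelvis' (root) segment are exempt.

    mode 'length_based'
        Every eligible stalk length is multiplied by exp(-rate * dt);
        relative angles and topology are unchanged (daughter subtrees ride
        inward rigidly).
    mode 'tip_anchored'
        Each eligible node is pulled along its stalk toward its parent by
        the same exponential factor while the current positions of all
        other nodes -- in particular its daughters' distal endpoints --
        stay fixed.  Daughter lengths and relative angles are recomputed
        from the fixed endpoints, so daughters lengthen and their
        divergence angle narrows (a 'Y' closing toward a 'V').  Nodes are
        processed deepest-first.
    """
    if rate < 0 or dt < 0:
        raise ConfigError(f"retraction rate and dt must be >= 0 (rate={rate}, dt={dt})")
    if mode not in ("length_based", "tip_anchored"):
        raise ConfigError(f"retraction_mode: unknown mode {mode!r}")
    if rate * dt == 0:
        return tree
    factor = math.exp(-rate * dt)
    eligible = retraction_eligible(tree)
    if not eligible:
        return tree
    if mode == "length_based":
        return _scale_lengths(tree, factor, eligible)
    pos = tree.derive_positions()
    depth = tree.depths()
    for nid in sorted(eligible, key=lambda n: (-depth[n], n)):
        pid = tree.nodes[nid].parent_id
        pos[nid] = pos[pid] + factor * (pos[nid] - pos[pid])
    return _tree_from_positions(tree, pos)


def run(config: SimulationConfig) -> TimeLapse:
    """Run the full growth + bifurcation + retraction model.

    Starts from an unbranched bud (a single root segment of
    ``daughter_initial_length``), advances in steps of ``dt`` applying, in
    order, growth (while t < growth_end_time), synchronous tip bifurcation
    (at multiples of bifurcation_interval inside the growth era) and
    retraction (when enabled, from retraction_start_time to run_end_time),
    recording a frame every ``frame_interval``.  Each dt step is split at
    event and era boundaries and exact exponential factors are applied
    over each sub-span, so trajectories are independent of ``dt``.
    Deterministic whenever ``angle_jitter_sigma`` is 0.
    """
    config.validate()
    g = config.growth_rate
    rho = config.retraction_rate
    g_end = config.growth_end_time
    r_start = config.resolved_retraction_start()
    t_end = config.run_end_time
    dt = config.dt
    rng = np.random.default_rng(config.seed)

    bud = NodeRecord(1, None, config.daughter_initial_length, 0.0, 0.0, "root")
    tree = Tree([bud], config.root_heading, 0.0)
    frames = [tree]

    n_steps = int(math.ceil(t_end / dt - 1e-9))
    frame_every = int(round(config.frame_interval / dt))
    next_event = 1  # index k of the next bifurcation round at k * interval
    counters = {"growth_steps": 0, "retraction_steps": 0, "bifurcations": 0}

    for i in range(1, n_steps + 1):
        t0 = (i - 1) * dt
        t1 = min(i * dt, t_end)
        t = t0
        while t < t1 - _EPS:
            t_ev = next_event * config.bifurcation_interval
            has_event = t_ev < g_end - 1e-9 and t < t_ev <= t1 + 1e-9
            t_next = min(t_ev, t1) if has_event else t1
            span_g = min(t_next, g_end) - t
            if span_g > _EPS:
                tree = apply_growth(tree, g, span_g)
            span_r = min(t_next, t_end) - max(t, r_start)
            if config.retraction_enabled and span_r > _EPS:
                tree = apply_retraction(tree, rho, span_r, config.retraction_mode)
            if has_event and t_next >= t_ev - 1e-9:
                tree = bifurcate_tips(
                    tree,
                    config.divergence_angle,
                    config.daughter_initial_length,
                    config.angle_jitter_sigma,
                    rng,
                    time=t_ev,
                )
                counters["bifurcations"] += 1
                next_event += 1
            t = t_next
        if t1 < g_end - 1e-9 or t0 < g_end - 1e-9:
            counters["growth_steps"] += 1
        if config.retraction_enabled and t1 > r_start + 1e-9:
            counters["retraction_steps"] += 1
        tree = tree.with_time(t1)
        if i % frame_every == 0:
            frames.append(tree)

    logger.info(
        "run complete: %d steps (%d growth-era, %d retraction-era), "
        "%d bifurcation rounds, %d tips, %d frames",
        n_steps,
        counters["growth_steps"],
        counters["retraction_steps"],
        counters["bifurcations"],
        tip_count(tree),
        len(frames),
    )
    timelapse = TimeLapse(frames, config.frame_interval)
    timelapse.validate()
    return timelapse


# --------------------------------------------------------------------------
# morphometrics
# --------------------------------------------------------------------------


@dataclass
class LengthSeries:
    """Per-frame measured length of one branch (the segment ending at
    ``branch_id``).

    Lengths are Euclidean distances on observed coordinates -- the
    time-lapse equivalent of measuring printed movie frames with a ruler
    -- so coordinate noise and drift propagate into them.  ``fold_changes``
    normalise to the first frame.
    """

    branch_id: int
    times: np.ndarray
    absolute_lengths: np.ndarray
    fold_changes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absolute_lengths = np.asarray(self.absolute_lengths, dtype=float)
        first = self.absolute_lengths[0] if len(self.absolute_lengths) else np.nan
        self.fold_changes = (
            self.absolute_lengths / first if first and first > 0 else np.full_like(self.absolute_lengths, np.nan)
        )


@dataclass
class RetractionCall:
    """Classification of one branch as retracting or not."""

    branch_id: int
    is_retracting: bool
    onset_time: float | None
    net_change: float


class FractionResult(NamedTuple):
    n_retracting: int
    n_total: int
    proportion: float


def _frame_point(tl: TimeLapse, k: int, node_id: int | None) -> np.ndarray:
    """Observed position of a node, or of the root base when node_id is None.

    The root base is not itself an observable node; under observed
    coordinates it is placed by carrying the derived base along with the
    root node's observed displacement.
    """
    coords = tl.coordinates(k)
    if node_id is not None:
        if node_id not in coords:
            raise MeasurementError(
                f"node {node_id} missing from frame {k}: identity does not persist"
            )
        return np.asarray(coords[node_id], dtype=float)
    root = tl.frames[k].root_id
    if root not in coords:
        raise MeasurementError(f"root {root} missing from frame {k}")
    offset = np.asarray(coords[root], dtype=float) - tl.frames[k].derive_positions()[root]
    return offset  # derived base is the origin


def internode_length_series(tl: TimeLapse, branch_id: int) -> LengthSeries:
    """Measured length of one internode across every frame.

    The internode is the segment between ``branch_id`` and its mother
    node; its length is the per-frame Euclidean distance between the two
    endpoints on observed coordinates (translation-invariant, so global
    drift cancels; isotropic noise does not).
    """
    lengths = []
    for k in range(len(tl)):
        frame = tl.frames[k]
        if branch_id not in frame.nodes:
            raise MeasurementError(
                f"branch {branch_id} missing from frame {k}: identity does not persist"
            )
        a = _frame_point(tl, k, branch_id)
        b = _frame_point(tl, k, frame.nodes[branch_id].parent_id)
        lengths.append(float(np.hypot(*(a - b))))
    return LengthSeries(branch_id, tl.times(), np.array(lengths))


def radial_growth_series(tl: TimeLapse, from_node: int, to_tip: int) -> LengthSeries:
    """Straight-line distance from a named node to a named tip per frame.

    This is the point-to-point 'pelvis-to-periphery' measure of radial
    tree growth (a dotted line from a deep branch node out to the same
    tip in every frame).
    """
    lengths = []
    for k in range(len(tl)):
        a = _frame_point(tl, k, from_node)
        b = _frame_point(tl, k, to_tip)
        lengths.append(float(np.hypot(*(a - b))))
    return LengthSeries(to_tip, tl.times(), np.array(lengths))


def path_length_series(tl: TimeLapse, to_tip: int) -> LengthSeries:
    """Pelvis-to-tip distance summed along the line of the branches.

    Complements :func:`radial_growth_series`: the path length from the
    root base to ``to_tip`` through every intervening node, per frame.
    """
    lengths = []
    for k in range(len(tl)):
        frame = tl.frames[k]
        if to_tip not in frame.nodes:
            raise MeasurementError(
                f"node {to_tip} missing from frame {k}: identity does not persist"
            )
        total, nid = 0.0, to_tip
        while nid is not None:
            pid = frame.nodes[nid].parent_id
            a = _frame_point(tl, k, nid)
            b = _frame_point(tl, k, pid)
            total += float(np.hypot(*(a - b)))
            nid = pid
        lengths.append(total)
    return LengthSeries(to_tip, tl.times(), np.array(lengths))


def divergence_angle(
    tree: Tree, node_id: int, coords: Mapping[int, np.ndarray] | None = None
) -> float:
    """Unsigned planar angle (degrees) between the two daughter segments
    at a node.

    Defined for bifurcation nodes only; collinear daughters return the
    degenerate values 0 or 180 rather than erroring.
    """
    if node_id not in tree.nodes:
        raise MeasurementError(f"node {node_id} not in tree")
    kids = tree.children(node_id)
    if len(kids) != 2:
        raise MeasurementError(
            f"node {node_id} ({tree.nodes[node_id].kind}) has no divergence angle: "
            "two daughters required"
        )
    pos = tree.derive_positions() if coords is None else coords
    origin = np.asarray(pos[node_id], dtype=float)
    v1 = np.asarray(pos[kids[0]], dtype=float) - origin
    v2 = np.asarray(pos[kids[1]], dtype=float) - origin
    n1, n2 = np.hypot(*v1), np.hypot(*v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    cosang = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def detect_retraction(
    series: LengthSeries,
    min_relative_drop: float = 0.05,
    smoothing_window: int = 3,
) -> RetractionCall:
    """Classify a branch as retracting from its measured length series.

    The series is smoothed with a centred moving mean of width
    ``smoothing_window``; only positions where the full window fits carry
    a smoothed value (partial edge windows would be noisier than the
    stated width).  The branch is called retracting as soon as the
    smoothed length falls more than ``min_relative_drop`` below its
    running maximum.  A drop-from-running-max criterion (rather than net
    first-to-last change) catches nodes whose retraction rate varies over
    time or that pause and resume.
    """
    n = len(series.absolute_lengths)
    if n < 3:
        raise MeasurementError(f"branch {series.branch_id}: need >= 3 time points, got {n}")
    if not 1 <= smoothing_window <= n:
        raise ConfigError(
            f"smoothing_window: must lie in [1, {n}], got {smoothing_window}"
        )
    if not 0 < min_relative_drop < 1:
        raise ConfigError(f"min_relative_drop: must lie in (0, 1), got {min_relative_drop}")
    smoothed = (
        pd.Series(series.absolute_lengths)
        .rolling(smoothing_window, center=True, min_periods=smoothing_window)
        .mean()
        .to_numpy()
    )
    valid = ~np.isnan(smoothed)
    values = smoothed[valid]
    valid_times = series.times[valid]
    running_max = np.maximum.accumulate(values)
    below = values < (1.0 - min_relative_drop) * running_max
    is_retracting = bool(below.any())
    onset = float(valid_times[int(np.argmax(below))]) if is_retracting else None
    net = float(series.absolute_lengths[-1] - series.absolute_lengths[0])
    return RetractionCall(series.branch_id, is_retracting, onset, net)


def restrict_timelapse(tl: TimeLapse, interval: tuple[float, float]) -> TimeLapse:
    """Frames of ``tl`` whose times fall inside ``interval`` (>= 3 required)."""
    t0, t1 = interval
    if not t1 > t0:
        raise ConfigError(f"interval: must be non-empty, got ({t0}, {t1})")
    times = tl.times()
    keep = [k for k, t in enumerate(times) if t0 - 1e-9 <= t <= t1 + 1e-9]
    if len(keep) < 3:
        raise ConfigError(
            f"interval ({t0}, {t1}) covers only {len(keep)} frames; >= 3 required"
        )
    frames = [tl.frames[k] for k in keep]
    coords = [tl.coords[k] for k in keep] if tl.coords is not None else None
    drift = tl.drift[keep] if tl.drift is not None else None
    return TimeLapse(frames, tl.frame_interval, tl.noise_sigma, drift, coords)


def fraction_retracting(
    tl: TimeLapse,
    interval: tuple[float, float] | None = None,
    min_relative_drop: float = 0.05,
    smoothing_window: int = 3,
) -> FractionResult:
    """Proportion of visible nodes showing any retraction in an interval.

    Every segment whose distal node is a branch point in the last frame of
    the interval is assessed with :func:`detect_retraction`; the result is
    (number retracting, number assessed, proportion) -- the simulated
    counterpart of counting visible nodes and the fraction retracting in
    a movie interval.
    """
    window = tl if interval is None else restrict_timelapse(tl, interval)
    last = window.frames[-1]
    candidates = [nid for nid in last.preorder() if len(last.children(nid)) == 2]
    n_ret = total = 0
    min_frames = max(3, smoothing_window)
    for nid in candidates:
        # a node is assessable over the frames in which it is visible
        first = next(k for k in range(len(window)) if nid in window.frames[k].nodes)
        if len(window) - first < min_frames:
            continue
        sub = TimeLapse(
            window.frames[first:],
            window.frame_interval,
            window.noise_sigma,
            None,
            window.coords[first:] if window.coords is not None else None,
        )
        series = internode_length_series(sub, nid)
        call = detect_retraction(series, min_relative_drop, smoothing_window)
        total += 1
        n_ret += int(call.is_retracting)
    return FractionResult(n_ret, total, n_ret / total if total else 0.0)


def radial_alignment(tree: Tree, coords: Mapping[int, np.ndarray] | None = None) -> float:
    """Mean mis-alignment (degrees) of terminal segments with the radial
    direction; 0 means every terminal branch points straight away from
    the tree base.

    For each terminal segment the unsigned angle is taken between the
    segment's direction and the outward radius from the root base to the
    segment's midpoint, then averaged.  Lower scores quantify the 'long
    radial medullary rays' appearance of a retracted tree versus the
    spread fractal form of a growth-only tree.
    """
    pos = tree.derive_positions() if coords is None else coords
    root = tree.root_id
    base = np.asarray(pos[root], dtype=float) - tree.derive_positions()[root] if coords is not None else np.zeros(2)
    angles = []
    for tip in tree.leaves():
        pid = tree.nodes[tip].parent_id
        p_tip = np.asarray(pos[tip], dtype=float)
        p_par = base if pid is None else np.asarray(pos[pid], dtype=float)
        seg = p_tip - p_par
        mid = 0.5 * (p_tip + p_par)
        radial = mid - base
        ns, nr = np.hypot(*seg), np.hypot(*radial)
        if ns == 0 or nr == 0:
            continue
        cosang = float(np.clip(np.dot(seg, radial) / (ns * nr), -1.0, 1.0))
        angles.append(math.degrees(math.acos(cosang)))
    if not angles:
        raise MeasurementError("tree has no measurable terminal segment")
    return float(np.mean(angles))


def register_frames(tl: TimeLapse, anchor_node: int) -> TimeLapse:
    """Translate every frame so the anchor node sits at the origin.

    Removes any global stage drift exactly (per-frame translation cannot
    survive anchoring); measurement noise on the anchor itself is shared
    across the frame's registered coordinates.
    """
    new_coords = []
    for k in range(len(tl)):
        coords = tl.coordinates(k)
        if anchor_node not in coords:
            raise MeasurementError(f"anchor node {anchor_node} missing from frame {k}")
        shift = np.asarray(coords[anchor_node], dtype=float)
        new_coords.append({nid: np.asarray(p, dtype=float) - shift for nid, p in coords.items()})
    return TimeLapse(list(tl.frames), tl.frame_interval, tl.noise_sigma, None, new_coords)


def fit_exponential_rate(series: LengthSeries) -> float:
    """Recover the exponential rate of a length trajectory.

    Least-squares slope of log(length) against time; positive for growth,
    negative for retraction.  Exact (to numerical precision) on noiseless
    exponential series.
    """
    mask = series.absolute_lengths > 0
    if mask.sum() < 2:
        raise MeasurementError(
            f"branch {series.branch_id}: need >= 2 positive lengths to fit a rate"
        )
    slope = np.polyfit(series.times[mask], np.log(series.absolute_lengths[mask]), 1)[0]
    return float(slope)


# --------------------------------------------------------------------------
# synthetic time-lapse fixtures
# --------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    """Recipe for a labelled synthetic time-lapse.

    Wraps a simulator run and adds the two nuisance processes of real
    movie acquisition: isotropic per-frame coordinate noise of scale
    ``coord_noise_sigma`` (temporally independent) and cumulative linear
    stage drift ``drift_per_frame``.  Ground-truth labels record which
    branches actually retract and when, so detection can be scored with
    no external data.
    """

    base_config: SimulationConfig = field(default_factory=SimulationConfig)
    coord_noise_sigma: float = 0.0
    drift_per_frame: tuple[float, float] | None = None
    seed: int = 0


def _ground_truth_labels(tl: TimeLapse, config: SimulationConfig) -> pd.DataFrame:
    """Per-branch truth: does the segment retract, and from when.

    A segment retracts iff retraction is enabled, the retraction era is
    non-empty, and its distal node is an eligible branch point (has a
    parent and two daughters).  Onset is the later of the era start and
    the moment the node became a branch point (its daughters' birth).
    """
    final = tl.frames[-1]
    r_start = config.resolved_retraction_start()
    era = config.retraction_enabled and config.run_end_time > r_start
    rows = []
    for nid in final.preorder():
        rec = final.nodes[nid]
        kids = final.children(nid)
        eligible = rec.parent_id is not None and len(kids) == 2
        retracting = bool(era and eligible)
        onset = (
            max(r_start, max(final.nodes[c].birth_time for c in kids))
            if retracting
            else np.nan
        )
        rows.append(
            {
                "branch_id": nid,
                "parent_id": -1 if rec.parent_id is None else rec.parent_id,
                "kind": rec.kind,
                "eligible": eligible,
                "retracting": retracting,
                "onset_time": onset,
            }
        )
    return pd.DataFrame(rows)


def make_fixture(
    spec: FixtureSpec, out_dir: str | os.PathLike | None = None
) -> tuple[TimeLapse, pd.DataFrame]:
    """Build a labelled synthetic time-lapse (and optionally write it out).

    Runs the simulator, perturbs every node coordinate in every frame
    with isotropic Gaussian noise of scale ``coord_noise_sigma``, adds
    cumulative drift, and derives ground-truth labels.  With a directory,
    writes ``frame_%05d.swc`` files, ``labels.csv`` and a ``manifest.txt``;
    output is byte-identical for equal seeds.
    """
    if spec.coord_noise_sigma < 0:
        raise ConfigError(f"coord_noise_sigma: must be >= 0, got {spec.coord_noise_sigma}")
    tl = run(spec.base_config)
    rng = np.random.default_rng(spec.seed)
    drift = (
        np.zeros(2)
        if spec.drift_per_frame is None
        else np.asarray(spec.drift_per_frame, dtype=float)
    )
    coords: list[dict[int, np.ndarray]] = []
    drift_table = np.zeros((len(tl), 2))
    for k, frame in enumerate(tl.frames):
        clean = frame.derive_positions()
        offset = k * drift
        drift_table[k] = offset
        frame_coords = {}
        for nid in sorted(clean):  # fixed order keeps noise reproducible
            noise = (
                rng.normal(0.0, spec.coord_noise_sigma, size=2)
                if spec.coord_noise_sigma > 0
                else np.zeros(2)
            )
            frame_coords[nid] = clean[nid] + noise + offset
        coords.append(frame_coords)
    noisy = TimeLapse(
        list(tl.frames),
        tl.frame_interval,
        noise_sigma=spec.coord_noise_sigma,
        drift=drift_table if spec.drift_per_frame is not None else None,
        coords=coords,
    )
    labels = _ground_truth_labels(tl, spec.base_config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_timelapse(
            noisy,
            out,
            thickness_base=spec.base_config.thickness_base,
            thickness_slope=spec.base_config.thickness_slope,
        )
        labels.to_csv(out / "labels.csv", index=False, float_format="%.9f")
        manifest = dict(spec.base_config.to_dict())
        manifest.update(
            {
                "coord_noise_sigma": f"{spec.coord_noise_sigma:.9f}",
                "drift_per_frame": (
                    "none"
                    if spec.drift_per_frame is None
                    else f"{drift[0]:.9f},{drift[1]:.9f}"
                ),
                "fixture_seed": spec.seed,
                "n_frames": len(noisy),
            }
        )
        write_manifest(out / "manifest.txt", manifest)
    return noisy, labels


def mean_internode_length(tl: TimeLapse) -> float:
    """Mean segment length over all segments and frames (clean geometry)."""
    lengths = [
        rec.branch_length for frame in tl.frames for rec in frame.nodes.values()
    ]
    return float(np.mean(lengths))


def default_fixture(
    seed: int = 0,
    noise_level: float = 0.02,
    config: SimulationConfig | None = None,
    drift_per_frame: tuple[float, float] | None = None,
) -> tuple[TimeLapse, pd.DataFrame, float]:
    """Reference fixture: default run with noise scaled to the tree.

    The coordinate noise scale is ``noise_level`` times the mean internode
    length of the clean run (2 % by default).  Returns (timelapse, labels,
    sigma).
    """
    cfg = config if config is not None else SimulationConfig()
    sigma = noise_level * mean_internode_length(run(cfg)) if noise_level > 0 else 0.0
    spec = FixtureSpec(cfg, coord_noise_sigma=sigma, drift_per_frame=drift_per_frame, seed=seed)
    tl, labels = make_fixture(spec)
    return tl, labels, sigma


def evaluate_detection(
    tl: TimeLapse,
    labels: pd.DataFrame,
    interval: tuple[float, float],
    min_relative_drop: float = 0.05,
    smoothing_window: int = 3,
) -> dict:
    """Score detect_retraction against fixture ground truth.

    Assesses every labelled segment (branch points and tips alike, the
    root segment included) over ``interval`` and returns the confusion
    counts plus balanced accuracy (mean of sensitivity and specificity).
    """
    window = restrict_timelapse(tl, interval)
    tp = fp = tn = fn = 0
    for row in labels.itertuples(index=False):
        series = internode_length_series(window, int(row.branch_id))
        call = detect_retraction(series, min_relative_drop, smoothing_window)
        if row.retracting and call.is_retracting:
            tp += 1
        elif row.retracting:
            fn += 1
        elif call.is_retracting:
            fp += 1
        else:
            tn += 1
    sens = tp / (tp + fn) if (tp + fn) else 1.0
    spec_ = tn / (tn + fp) if (tn + fp) else 1.0
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "sensitivity": sens,
        "specificity": spec_,
        "balanced_accuracy": 0.5 * (sens + spec_),
    }


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


@dataclass
class RenderSpec:
    """How to draw a tree: canvas, scale and the thickness law.

    With ``scale`` None the drawing auto-fits the tree's bounding box into
    the canvas minus the margin, so no stroke is clipped.  Stroke width is
    thickness(node) * ``thickness_px``: older (more descendant-rich)
    segments draw thicker, tips thinnest.
    """

    width: int = 800
    height: int = 800
    margin: float = 40.0
    background: str = "white"
    stroke: str = "black"
    thickness_base: float = 1.0
    thickness_slope: float = 0.25
    thickness_px: float = 1.0
    scale: float | None = None

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigError(f"canvas: width/height must be > 0 ({self.width}x{self.height})")
        if self.scale is not None and self.scale <= 0:
            raise ConfigError(f"scale: must be > 0, got {self.scale}")


def _segments_px(tree: Tree, spec: RenderSpec) -> list[tuple[int, np.ndarray, np.ndarray, float]]:
    pos = tree.derive_positions()
    counts = _descendant_counts(tree)
    points = np.vstack([np.zeros(2)] + [pos[n] for n in tree.preorder()])
    lo, hi = points.min(axis=0), points.max(axis=0)
    extent = np.maximum(hi - lo, 1e-9)
    if spec.scale is None:
        scale = min(
            (spec.width - 2 * spec.margin) / extent[0],
            (spec.height - 2 * spec.margin) / extent[1],
        )
    else:
        scale = spec.scale
    centre = 0.5 * (lo + hi)
    cx, cy = spec.width / 2.0, spec.height / 2.0

    def to_px(p: np.ndarray) -> np.ndarray:
        return np.array(
            [cx + (p[0] - centre[0]) * scale, cy - (p[1] - centre[1]) * scale]
        )

    segs = []
    for nid in tree.preorder():  # oldest first, tips drawn on top
        rec = tree.nodes[nid]
        a = np.zeros(2) if rec.parent_id is None else pos[rec.parent_id]
        width = (spec.thickness_base + spec.thickness_slope * counts[nid]) * spec.thickness_px
        segs.append((nid, to_px(a), to_px(pos[nid]), width))
    return segs


def render_svg(tree: Tree, spec: RenderSpec, path: str | os.PathLike) -> None:
    """Draw the tree as an SVG 1.1 file, one straight stroke per segment.

    Deterministic: equal trees and specs yield byte-identical files.
    """
    spec.validate()
    buf = io.StringIO()
    buf.write('<?xml version="1.0" encoding="UTF-8"?>\n')
    buf.write(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{spec.width}" height="{spec.height}" '
        f'viewBox="0 0 {spec.width} {spec.height}">\n'
    )
    buf.write(
        f'  <rect x="0" y="0" width="{spec.width}" height="{spec.height}" '
        f'fill="{spec.background}"/>\n'
    )
    for nid, a, b, width in _segments_px(tree, spec):
        buf.write(
            f'  <line x1="{a[0]:.3f}" y1="{a[1]:.3f}" x2="{b[0]:.3f}" y2="{b[1]:.3f}" '
            f'stroke="{spec.stroke}" stroke-width="{width:.3f}" stroke-linecap="round"/>\n'
        )
    buf.write("</svg>\n")
    Path(path).write_text(buf.getvalue())


def render_png(tree: Tree, spec: RenderSpec, path: str | os.PathLike) -> None:
    """Draw the tree as an anti-aliased PNG via matplotlib."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    spec.validate()
    dpi = 100.0
    fig, ax = plt.subplots(figsize=(spec.width / dpi, spec.height / dpi), dpi=dpi)
    fig.patch.set_facecolor(spec.background)
    segs, widths = [], []
    for _, a, b, width in _segments_px(tree, spec):
        segs.append([(a[0], a[1]), (b[0], b[1])])
        widths.append(width)
    ax.add_collection(
        LineCollection(segs, linewidths=widths, colors=spec.stroke, capstyle="round")
    )
    ax.set_xlim(0, spec.width)
    ax.set_ylim(spec.height, 0)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.subplots_adjust(0, 0, 1, 1)
    fig.savefig(path, dpi=dpi, facecolor=spec.background)
    plt.close(fig)


def render(tree: Tree, spec: RenderSpec, path: str | os.PathLike) -> None:
    """Render to SVG or PNG depending on the file suffix (SVG default)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".png":
        render_png(tree, spec, path)
    else:
        render_svg(tree, spec, path)
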