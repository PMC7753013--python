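"""Constrained vascular-tree geometry.

A tree is a set of typed nodes (root / bifurcation / inter / leaf) joined
by directed, radius-bearing edges. Every generated bifurcation satisfies
the radius power law ``r_p**g = r_l**g + r_r**g`` (the bifurcation
exponent ``g`` defaults to the classical value 3) and the optimal
branching-angle constraints

    cos(phi_l) = (r_p**4 + r_l**4 - r_r**4) / (2 r_p**2 r_l**2)
    cos(phi_r) = (r_p**4 + r_r**4 - r_l**4) / (2 r_p**2 r_r**2)

which place the branch point at the minimum-volume optimum.

The full biophysical growth model (oxygen demand / growth-factor fields)
is intentionally not simulated; growth here is a geometric surrogate that
enforces exactly the printed constraints: direction inherited from the
parent and rotated by the constraint angles about a random azimuth,
daughter radii from the closed-form radius split, and segment length
proportional to radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NODE_TYPES",
    "VesselNode",
    "VesselSegment",
    "VesselTree",
    "TreeViolation",
    "ValidationReport",
    "GeometryError",
    "DegenerateTreeError",
    "murray_split",
    "bifurcation_angles",
    "sample_tree",
    "validate_tree",
]

NODE_TYPES = ("root", "bifurcation", "inter", "leaf")


class GeometryError(ValueError):
    """Raised for radius triples with no valid bifurcation geometry."""


class DegenerateTreeError(ValueError):
    """Raised when a growth configuration cannot produce any segment."""


@dataclass
class VesselNode:
    id: int
    position: np.ndarray  # (3,) float, voxel units, 0-based
    node_type: str

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64)
        if self.position.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got {self.position.shape}")
        if self.node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {self.node_type!r}")


@dataclass
class VesselSegment:
    parent: int
    child: int
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"segment radius must be positive, got {self.radius}")


@dataclass
class VesselTree:
    """Directed tree of vessel nodes and radius-bearing segments."""

    nodes: dict[int, VesselNode] = field(default_factory=dict)
    segments: list[VesselSegment] = field(default_factory=list)

    def add_node(self, position, node_type: str) -> int:
        nid = len(self.nodes)
        while nid in self.nodes:  # pragma: no cover - defensive
            nid += 1
        self.nodes[nid] = VesselNode(nid, position, node_type)
        return nid

    def add_segment(self, parent: int, child: int, radius: float) -> None:
        self.segments.append(VesselSegment(parent, child, radius))

    def children(self, nid: int) -> list[VesselSegment]:
        return [s for s in self.segments if s.parent == nid]

    def parent_segment(self, nid: int) -> VesselSegment | None:
        for s in self.segments:
            if s.child == nid:
                return s
        return None

    @property
    def root_ids(self) -> list[int]:
        return [n.id for n in self.nodes.values() if n.node_type == "root"]

    def segment_length(self, seg: VesselSegment) -> float:
        a = self.nodes[seg.parent].position
        b = self.nodes[seg.child].position
        return float(np.linalg.norm(b - a))

    def bifurcation_nodes(self) -> list[VesselNode]:
        return [n for n in self.nodes.values() if n.node_type == "bifurcation"]

    def __len__(self) -> int:
        return len(self.nodes)


def murray_split(r_p: float, asymmetry: float, gamma: float = 3.0) -> tuple[float, float]:
    """Split a parent radius into daughter radii under the radius power law.

    ``asymmetry`` is the ratio r_r / r_l in (0, 1]; the closed form
    ``r_l = r_p / (1 + asymmetry**gamma)**(1/gamma)`` makes the law hold
    exactly by construction.
    """
    if r_p <= 0:
        raise ValueError(f"parent radius must be positive, got {r_p}")
    if not 0.0 < asymmetry <= 1.0:
        raise ValueError(f"asymmetry must lie in (0, 1], got {asymmetry}")
    if gamma <= 0:
        raise ValueError(f"bifurcation exponent must be positive, got {gamma}")
    r_l = r_p / (1.0 + asymmetry**gamma) ** (1.0 / gamma)
    r_r = asymmetry * r_l
    return r_l, r_r


def bifurcation_angles(r_p: float, r_l: float, r_r: float) -> tuple[float, float]:
    """Optimal branching angles (radians) for a parent/daughter radius triple."""
    if min(r_p, r_l, r_r) <= 0:
        raise ValueError("radii must be positive")
    cos_l = (r_p**4 + r_l**4 - r_r**4) / (2.0 * r_p**2 * r_l**2)
    cos_r = (r_p**4 + r_r**4 - r_l**4) / (2.0 * r_p**2 * r_r**2)
    tol = 1e-12
    if not (-1.0 - tol <= cos_l <= 1.0 + tol) or not (-1.0 - tol <= cos_r <= 1.0 + tol):
        raise GeometryError(
            f"radius triple (r_p={r_p}, r_l={r_l}, r_r={r_r}) admits no bifurcation: "
            f"cosines ({cos_l:.6g}, {cos_r:.6g}) outside [-1, 1]"
        )
    return math.acos(np.clip(cos_l, -1.0, 1.0)), math.acos(np.clip(cos_r, -1.0, 1.0))


def _perpendicular(d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random unit vector perpendicular to unit vector d (uniform azimuth)."""
    while True:
        v = rng.normal(size=3)
        v -= np.dot(v, d) * d
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            return v / norm


def _clip_to_bounds(p0, p1, shape, margin):
    """Shorten p0->p1 so the endpoint stays ``margin`` inside the volume.

    Returns the clipped endpoint, or None when no forward motion remains.
    """
    lo = np.full(3, float(margin))
    hi = np.asarray(shape, dtype=np.float64) - 1.0 - margin
    d = p1 - p0
    t = 1.0
    for ax in range(3):
        if d[ax] > 0 and p1[ax] > hi[ax]:
            t = min(t, (hi[ax] - p0[ax]) / d[ax])
        elif d[ax] < 0 and p1[ax] < lo[ax]:
            t = min(t, (lo[ax] - p0[ax]) / d[ax])
    if t <= 1e-3:
        return None
    return p0 + t * d


def sample_tree(config, seed: int | None = None) -> VesselTree:
    """Grow a random constrained tree inside ``config.volume_shape``.

    The root sits on a volume face and grows inward; branching recurses
    until the daughter radius falls below ``config.min_terminal_radius``,
    the boundary is reached, or ``config.max_nodes`` is hit. Deterministic
    for a fixed (config, seed).
    """
    rng = np.random.default_rng(seed)
    shape = np.asarray(config.volume_shape, dtype=np.float64)
    gamma = config.gamma
    r_lo, r_hi = config.root_radius
    if r_hi <= 0:
        raise DegenerateTreeError(f"root radius range {config.root_radius} is non-positive")
    root_radius = float(rng.uniform(r_lo, r_hi)) * config.radius_scale

    # root on a random face, pointing inward with a random tilt
    axis = int(rng.integers(3))
    side = int(rng.integers(2))
    pos = rng.uniform(0.15, 0.85, size=3) * (shape - 1)
    pos[axis] = 0.0 if side == 0 else shape[axis] - 1.0
    direction = np.zeros(3)
    direction[axis] = 1.0 if side == 0 else -1.0
    tilt = _perpendicular(direction, rng)
    ang = rng.uniform(0.0, 0.35)
    direction = math.cos(ang) * direction + math.sin(ang) * tilt

    tree = VesselTree()
    root_id = tree.add_node(pos, "root")

    # (parent node id, start, unit direction, radius)
    stack = [(root_id, pos, direction, root_radius)]
    while stack and len(tree) < config.max_nodes:
        parent_id, p0, d, radius = stack.pop()
        length = config.length_ratio * radius * float(
            rng.uniform(1.0 - config.length_jitter, 1.0 + config.length_jitter)
        )
        p1 = p0 + length * d
        clipped = _clip_to_bounds(p0, p1, shape, margin=0.0)
        if clipped is None:
            continue  # no room to extend; parent retyped in the final fixup
        hit_boundary = not np.allclose(clipped, p1)
        p1 = clipped

        terminal = radius <= config.min_terminal_radius or hit_boundary
        if terminal:
            nid = tree.add_node(p1, "leaf")
            tree.add_segment(parent_id, nid, radius)
            continue

        asymmetry = float(rng.uniform(*config.asymmetry_range))
        r_l, r_r = murray_split(radius, asymmetry, gamma)
        phi_l, phi_r = bifurcation_angles(radius, r_l, r_r)
        u = _perpendicular(d, rng)
        d_l = math.cos(phi_l) * d + math.sin(phi_l) * u
        d_r = math.cos(phi_r) * d - math.sin(phi_r) * u

        nid = tree.add_node(p1, "bifurcation")
        tree.add_segment(parent_id, nid, radius)
        # right daughter pushed first so the left (larger) pops first
        stack.append((nid, p1, d_r / np.linalg.norm(d_r), r_r))
        stack.append((nid, p1, d_l / np.linalg.norm(d_l), r_l))

    # nodes whose daughters were never placed (max_nodes cut-off or clipping)
    for node in tree.nodes.values():
        n_children = len(tree.children(node.id))
        if node.node_type == "bifurcation":
            if n_children == 0:
                node.node_type = "leaf"
            elif n_children == 1:
                node.node_type = "inter"
    return tree


@dataclass
class TreeViolation:
    kind: str  # murray | angle | bounds | topology
    node_id: int | None
    detail: str
    residual: float = 0.0


@dataclass
class ValidationReport:
    violations: list[TreeViolation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def of_kind(self, kind: str) -> list[TreeViolation]:
        return [v for v in self.violations if v.kind == kind]


def validate_tree(
    tree: VesselTree,
    gamma: float = 3.0,
    volume_shape=None,
    tol: float = 1e-9,
) -> ValidationReport:
    """Check radius-law residuals, angle residuals, bounds, and topology."""
    report = ValidationReport()
    add = report.violations.append

    # topology -------------------------------------------------------------
    ids = set(tree.nodes)
    parents: dict[int, int] = {}
    for seg in tree.segments:
        if seg.parent not in ids or seg.child not in ids:
            add(TreeViolation("topology", None, f"edge {seg.parent}->{seg.child} references missing node"))
            continue
        if seg.child in parents:
            add(TreeViolation("topology", seg.child, f"node {seg.child} has multiple parents"))
        parents[seg.child] = seg.parent
    roots = tree.root_ids
    if len(roots) != 1:
        add(TreeViolation("topology", None, f"expected exactly one root, found {len(roots)}"))
    # cycle check by walking to the root from every node
    for nid in ids:
        seen = set()
        cur = nid
        while cur in parents:
            if cur in seen:
                add(TreeViolation("topology", nid, f"cycle reachable from node {nid}"))
                break
            seen.add(cur)
            cur = parents[cur]
    expected_degree = {"root": (1,), "inter": (1,), "bifurcation": (2,), "leaf": (0,)}
    for node in tree.nodes.values():
        deg = len(tree.children(node.id))
        if deg not in expected_degree[node.node_type]:
            add(
                TreeViolation(
                    "topology",
                    node.id,
                    f"{node.node_type} node {node.id} has out-degree {deg}",
                )
            )

    # bounds ---------------------------------------------------------------
    if volume_shape is not None:
        hi = np.asarray(volume_shape, dtype=np.float64) - 1.0
        for node in tree.nodes.values():
            if np.any(node.position < -1e-9) or np.any(node.position > hi + 1e-9):
                add(TreeViolation("bounds", node.id, f"node {node.id} at {node.position} outside volume"))

    # geometry -------------------------------------------------------------
    for node in tree.bifurcation_nodes():
        parent_seg = tree.parent_segment(node.id)
        child_segs = tree.children(node.id)
        if parent_seg is None or len(child_segs) != 2:
            continue  # already flagged as topology
        r_p = parent_seg.radius
        c0, c1 = child_segs
        r_a, r_b = c0.radius, c1.radius
        # left = larger daughter by convention
        if r_a >= r_b:
            left, right = c0, c1
        else:
            left, right = c1, c0
        r_l, r_r = left.radius, right.radius
        residual = abs(r_p**gamma - r_l**gamma - r_r**gamma) / r_p**gamma
        if residual > tol:
            add(TreeViolation("murray", node.id, f"radius-law residual at node {node.id}", residual))
        try:
            phi_l, phi_r = bifurcation_angles(r_p, r_l, r_r)
        except GeometryError as exc:
            add(TreeViolation("angle", node.id, str(exc), residual=float("inf")))
            continue
        d_parent = node.position - tree.nodes[parent_seg.parent].position
        d_parent = d_parent / np.linalg.norm(d_parent)
        for seg, phi in ((left, phi_l), (right, phi_r)):
            d_child = tree.nodes[seg.child].position - node.position
            d_child = d_child / np.linalg.norm(d_child)
            actual = math.acos(float(np.clip(np.dot(d_parent, d_child), -1.0, 1.0)))
            ang_res = abs(math.cos(actual) - math.cos(phi))
            if ang_res > tol:
                add(TreeViolation("angle", node.id, f"branch-angle residual at node {node.id}", ang_res))
    return report
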