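"""File formats: NIfTI volumes, JSON tree documents, YAML configs, manifests.

Volumes are stored as NIfTI-1 with the voxel spacing on the affine
diagonal; array axis order (i, j, k) maps to NIfTI voxel axes directly and
no reorientation is performed. Masks should be written as unsigned 8-bit,
images as 32- or 64-bit float.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .models import NetworkSpec, default_fcn_spec
from .pipeline import TrainConfig
from .synth import SynthConfig, VesselTree
from .volume import Volume3D

__all__ = [
    "FormatError",
    "SchemaError",
    "read_volume",
    "write_volume",
    "read_tree",
    "write_tree",
    "load_config",
    "Config",
    "config_hash",
    "Manifest",
    "TOOL_VERSION",
]

TOOL_VERSION = "0.1.0"


class FormatError(ValueError):
    """Unreadable or malformed data file."""


class SchemaError(ValueError):
    """Structurally invalid document (bad keys, dangling references)."""


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------


def read_volume(path) -> Volume3D:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of types
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(data, spacing)


def write_volume(volume: Volume3D, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data), affine)
    img.header.set_zooms(volume.spacing)
    img.set_data_dtype(volume.data.dtype)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def write_tree(tree: VesselTree, path, metadata: dict | None = None) -> None:
    doc = {
        "nodes": [
            {
                "id": n.id,
                "x": float(n.position[0]),
                "y": float(n.position[1]),
                "z": float(n.position[2]),
                "type": n.node_type,
            }
            for n in tree.nodes.values()
        ],
        "edges": [
            {"parent": s.parent, "child": s.child, "radius": s.radius}
            for s in tree.segments
        ],
        "metadata": metadata or {},
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(doc, indent=1))


def read_tree(path) -> VesselTree:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such tree file: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse tree document {path}: {exc}") from exc
    from .synth.tree import NODE_TYPES, VesselNode, VesselSegment

    tree = VesselTree()
    for nd in doc.get("nodes", []):
        try:
            nid = int(nd["id"])
            pos = (nd["x"], nd["y"], nd["z"])
            ntype = nd["type"]
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"{path}: malformed node entry {nd}") from exc
        if ntype not in NODE_TYPES:
            raise SchemaError(f"{path}: unknown node type {ntype!r}")
        if nid in tree.nodes:
            raise SchemaError(f"{path}: duplicate node id {nid}")
        tree.nodes[nid] = VesselNode(nid, pos, ntype)
    for ed in doc.get("edges", []):
        try:
            parent, child, radius = int(ed["parent"]), int(ed["child"]), float(ed["radius"])
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"{path}: malformed edge entry {ed}") from exc
        if parent not in tree.nodes or child not in tree.nodes:
            raise SchemaError(f"{path}: edge {parent}->{child} references a missing node")
        tree.segments.append(VesselSegment(parent, child, radius))
    return tree


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Config:
    """Validated umbrella config: synthesis, training, and model sections."""

    synth: SynthConfig
    train: TrainConfig
    model: NetworkSpec

    def as_dict(self) -> dict:
        return {
            "synth": self.synth.as_dict(),
            "train": dataclasses.asdict(self.train),
            "model": self.model.as_dict(),
        }


_MODEL_KEYS = {"mode", "in_channels", "hidden"}


def _build_section(cls, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise SchemaError(f"unknown {name} config keys: {sorted(unknown)}")
    coerced = {}
    for key, value in section.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except ValueError as exc:
        raise SchemaError(f"invalid {name} config: {exc}") from exc


def _build_model(section: dict) -> NetworkSpec:
    unknown = set(section) - _MODEL_KEYS
    if unknown:
        raise SchemaError(f"unknown model config keys: {sorted(unknown)}")
    if "hidden" in section:
        try:
            spec = NetworkSpec.from_dict({"hidden": section["hidden"]})
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"invalid model config: {exc}") from exc
        return spec
    return default_fcn_spec(
        mode=section.get("mode", "crosshair"),
        in_channels=section.get("in_channels", 1),
    )


def load_config(path=None) -> Config:
    """Load and validate a YAML config; missing sections get full defaults."""
    raw = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FormatError(f"no such config file: {p}")
        try:
            raw = yaml.safe_load(p.read_text()) or {}
        except yaml.YAMLError as exc:
            raise FormatError(f"cannot parse YAML config {p}: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - {"synth", "train", "model"}
    if unknown:
        raise SchemaError(f"unknown top-level config keys: {sorted(unknown)}")
    synth = _build_section(SynthConfig, raw.get("synth", {}) or {}, "synth")
    train = _build_section(TrainConfig, raw.get("train", {}) or {}, "train")
    model = _build_model(raw.get("model", {}) or {})
    return Config(synth=synth, train=train, model=model)


def config_hash(config) -> str:
    d = config.as_dict() if hasattr(config, "as_dict") else config
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Manifest:
    command: str
    seed: int | None
    config_hash: str
    tool_version: str = TOOL_VERSION
    timestamp: str = ""
    extra: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def write(self, path) -> None:
        doc = dataclasses.asdict(self)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(doc, indent=1, default=str))
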