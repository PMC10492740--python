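"""Rule-based validation and inspection of OME-Zarr trees.

Every rule has a stable code with a fixed severity:

* errors — violations of the 0.4 layout (an image that a compliant
  reader may misinterpret or fail to open);
* warnings — interoperability risks (e.g. a codec this package cannot
  decode but other stacks may);
* info — benign observations (e.g. chunks left implicit and read as the
  fill value).

A report is ``ok`` iff it contains no errors. Rules short-circuit along
their dependencies: when the axes list itself is illegal, rank and
transform-length checks against it are suppressed, so one defect yields
one finding.

Validation works on the raw JSON documents, deliberately more lenient
than the strict parsers in :mod:`ngffkit.ngff_model` — a malformed tree
should produce findings, not exceptions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import chunk_store as cs
from .chunk_store import ArraySchema, KVStore, join_path
from .codecs import codec_is_known
from .ngff_model import AXIS_TYPES, NGFF_VERSION

__all__ = ["Finding", "ValidationReport", "TreeSummary", "LevelSummary",
           "CODES", "validate_image", "validate_plate", "summarize"]

#: registry of finding codes and their severities
CODES: Dict[str, str] = {
    "E_MISSING_MULTISCALES": "error",
    "E_BAD_MULTISCALES": "error",
    "E_AXES_COUNT": "error",
    "E_AXES_TYPE": "error",
    "E_AXES_ORDER": "error",
    "E_DATASET_MISSING": "error",
    "E_RANK_MISMATCH": "error",
    "E_LEVEL_ORDER": "error",
    "E_TRANSFORM_MISSING": "error",
    "E_TRANSFORM_LENGTH": "error",
    "E_SCALE_ORDER": "error",
    "E_LABEL_DTYPE": "error",
    "E_LABEL_MISSING": "error",
    "E_MISSING_PLATE": "error",
    "E_WELL_PATH": "error",
    "E_WELL_MISSING": "error",
    "W_UNKNOWN_CODEC": "warning",
    "I_IMPLICIT_FILL_CHUNK": "info",
}

_SEVERITY_RANK = {"error": 0, "warning": 1, "info": 2}


@dataclass(frozen=True)
class Finding:
    severity: str
    code: str
    path: str
    message: str

    def __post_init__(self) -> None:
        if self.code not in CODES:
            raise ValueError(f"unregistered finding code {self.code!r}")
        if self.severity != CODES[self.code]:
            raise ValueError(f"{self.code} must have severity {CODES[self.code]!r}")

    def to_doc(self) -> Dict[str, str]:
        return {"severity": self.severity, "code": self.code,
                "path": self.path, "message": self.message}


@dataclass(frozen=True)
class ValidationReport:
    findings: Tuple[Finding, ...]

    @property
    def ok(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    @property
    def errors(self) -> Tuple[Finding, ...]:
        return tuple(f for f in self.findings if f.severity == "error")

    def codes(self) -> List[str]:
        return [f.code for f in self.findings]

    def to_doc(self) -> Dict[str, object]:
        return {"ok": self.ok, "findings": [f.to_doc() for f in self.findings]}


class _Collector:
    def __init__(self) -> None:
        self.findings: List[Finding] = []

    def add(self, code: str, path: str, message: str) -> None:
        self.findings.append(Finding(CODES[code], code, path, message))

    def report(self) -> ValidationReport:
        ordered = sorted(self.findings,
                         key=lambda f: (f.path, f.code))
        return ValidationReport(findings=tuple(ordered))


def _exists(store: KVStore, path: str) -> bool:
    return (cs.is_group(store, path) or cs.is_array(store, path)
            or bool(cs.read_attrs(store, path)) or bool(store.list(path)))


def validate_image(store: KVStore, path: str) -> ValidationReport:
    """Validate one multiscale image group (and any label subtree)."""
    if not _exists(store, path):
        raise KeyError(f"no node at {path!r}")
    out = _Collector()
    _check_image(store, path, out, is_label=False)
    return out.report()


def _check_image(store: KVStore, path: str, out: _Collector,
                 is_label: bool) -> None:
    attrs = cs.read_attrs(store, path)
    entries = attrs.get("multiscales")
    if not isinstance(entries, list) or not entries:
        out.add("E_MISSING_MULTISCALES", path,
                "group has no 'multiscales' attribute block")
        return
    for i, entry in enumerate(entries):
        epath = path if len(entries) == 1 else f"{path}#multiscales[{i}]"
        _check_multiscale_entry(store, path, epath, entry, out, is_label)
    if not is_label:
        _check_labels_subtree(store, path, out)


def _check_multiscale_entry(store: KVStore, group: str, epath: str,
                            entry: object, out: _Collector,
                            is_label: bool) -> None:
    if not isinstance(entry, Mapping) or \
            not isinstance(entry.get("axes"), list) or \
            not isinstance(entry.get("datasets"), list) or not entry["datasets"]:
        out.add("E_BAD_MULTISCALES", epath,
                "multiscales entry lacks an axes list or a non-empty datasets list")
        return

    axes = entry["axes"]
    axes_ok = True
    if not 2 <= len(axes) <= 5:
        out.add("E_AXES_COUNT", epath,
                f"{len(axes)} axes; version {NGFF_VERSION} supports 2 to 5 "
                f"dimensional images")
        axes_ok = False
    else:
        types = []
        for a in axes:
            t = a.get("type") if isinstance(a, Mapping) else None
            if t not in AXIS_TYPES:
                out.add("E_AXES_TYPE", epath,
                        f"axis {a!r} has illegal type {t!r} "
                        f"(allowed: {', '.join(AXIS_TYPES)})")
                axes_ok = False
            else:
                types.append(t)
        if axes_ok:
            names = [a.get("name") for a in axes]
            rank = {"time": 0, "channel": 1, "space": 2}
            order_ok = ([rank[t] for t in types] == sorted(rank[t] for t in types)
                        and types.count("time") <= 1
                        and types.count("channel") <= 1
                        and 2 <= types.count("space") <= 3
                        and len(set(names)) == len(names))
            if not order_ok:
                out.add("E_AXES_ORDER", epath,
                        f"axes must be unique and ordered time, channel, then "
                        f"2-3 space axes; got {types}")
                axes_ok = False
    ndim = len(axes)

    # per-dataset checks
    shapes: List[Optional[Tuple[int, ...]]] = []
    scales: List[Optional[Tuple[float, ...]]] = []
    for d in entry["datasets"]:
        dpath = d.get("path") if isinstance(d, Mapping) else None
        node = join_path(group, str(dpath)) if dpath is not None else epath
        if dpath is None or not cs.is_array(store, node):
            out.add("E_DATASET_MISSING", epath,
                    f"dataset path {dpath!r} has no array in the store")
            shapes.append(None)
            scales.append(None)
            continue
        try:
            schema = cs.read_array_schema(store, node)
        except ValueError as exc:
            out.add("E_DATASET_MISSING", node, f"unreadable array metadata: {exc}")
            shapes.append(None)
            scales.append(None)
            continue
        shapes.append(schema.shape)
        if axes_ok and len(schema.shape) != ndim:
            out.add("E_RANK_MISMATCH", node,
                    f"array rank {len(schema.shape)} != {ndim} axes")
        if is_label and schema.dtype.kind not in "iu":
            out.add("E_LABEL_DTYPE", node,
                    f"label images require integer dtype, found "
                    f"{schema.dtype_code}")
        _check_chunks(store, node, schema, out)
        scales.append(_dataset_scale(d, epath, node, ndim if axes_ok else None, out))

    # cross-level ordering (only between levels whose ranks agree)
    for lvl in range(1, len(shapes)):
        a, b = shapes[lvl - 1], shapes[lvl]
        if a is not None and b is not None and len(a) == len(b):
            if any(bb > aa for aa, bb in zip(a, b)):
                out.add("E_LEVEL_ORDER", epath,
                        f"level {lvl} shape {b} exceeds level {lvl - 1} "
                        f"shape {a}; levels must be highest resolution first")
        sa, sb = scales[lvl - 1], scales[lvl]
        if sa is not None and sb is not None and len(sa) == len(sb):
            if any(y < x for x, y in zip(sa, sb)):
                out.add("E_SCALE_ORDER", epath,
                        f"level {lvl} scale {sb} decreases below level "
                        f"{lvl - 1} scale {sa}")


def _dataset_scale(d: Mapping[str, object], epath: str, node: str,
                   ndim: Optional[int], out: _Collector
                   ) -> Optional[Tuple[float, ...]]:
    transforms = d.get("coordinateTransformations")
    scale = None
    if isinstance(transforms, list):
        for t in transforms:
            if isinstance(t, Mapping) and t.get("type") == "scale" \
                    and isinstance(t.get("scale"), list):
                scale = tuple(float(s) for s in t["scale"])
                break
    if scale is None:
        out.add("E_TRANSFORM_MISSING", node,
                "dataset lacks a scale coordinate transformation")
        return None
    if ndim is not None and len(scale) != ndim:
        out.add("E_TRANSFORM_LENGTH", node,
                f"scale has {len(scale)} entries for {ndim} axes")
        return None
    return scale


def _check_chunks(store: KVStore, node: str, schema: ArraySchema,
                  out: _Collector) -> None:
    if schema.codec is not None and not codec_is_known(schema.codec.id):
        out.add("W_UNKNOWN_CODEC", node,
                f"codec {schema.codec.id!r} is not available to this reader; "
                f"chunk data cannot be verified")
    expected = 1
    for g in schema.grid:
        expected *= g
    stored = sum(1 for k in store.list(node)
                 if not k.rsplit("/", 1)[-1].startswith("."))
    if stored < expected:
        out.add("I_IMPLICIT_FILL_CHUNK", node,
                f"{expected - stored} of {expected} chunks are implicit "
                f"(read as fill value {schema.fill_value!r})")


def _check_labels_subtree(store: KVStore, path: str, out: _Collector) -> None:
    lpath = join_path(path, "labels")
    attrs = cs.read_attrs(store, lpath)
    if not attrs and not cs.is_group(store, lpath):
        return
    for name in attrs.get("labels", []) or []:
        node = join_path(lpath, str(name))
        if not _exists(store, node):
            out.add("E_LABEL_MISSING", node,
                    f"label {name!r} is listed but has no image group")
            continue
        _check_image(store, node, out, is_label=True)


def validate_plate(store: KVStore, path: str) -> ValidationReport:
    """Validate an HCS plate: grid declaration, wells, and every field."""
    if not _exists(store, path):
        raise KeyError(f"no node at {path!r}")
    out = _Collector()
    attrs = cs.read_attrs(store, path)
    plate = attrs.get("plate")
    if not isinstance(plate, Mapping):
        out.add("E_MISSING_PLATE", path, "group has no 'plate' attribute block")
        return out.report()
    rows = [r.get("name") for r in plate.get("rows", []) if isinstance(r, Mapping)]
    cols = [c.get("name") for c in plate.get("columns", []) if isinstance(c, Mapping)]
    for w in plate.get("wells", []) or []:
        if not isinstance(w, Mapping):
            out.add("E_WELL_PATH", path, f"malformed well entry {w!r}")
            continue
        wp = w.get("path")
        r, c = w.get("rowIndex"), w.get("columnIndex")
        valid = (isinstance(wp, str) and isinstance(r, int) and isinstance(c, int)
                 and 0 <= r < len(rows) and 0 <= c < len(cols)
                 and wp == f"{rows[r]}/{cols[c]}")
        if not valid:
            out.add("E_WELL_PATH", join_path(path, str(wp)),
                    f"well path {wp!r} does not match declared row/column "
                    f"names and indices")
            continue
        node = join_path(path, wp)
        wattrs = cs.read_attrs(store, node)
        if "well" not in wattrs:
            out.add("E_WELL_MISSING", node,
                    f"well {wp!r} is declared but has no well group")
            continue
        for img in (wattrs["well"] or {}).get("images", []) or []:
            if isinstance(img, Mapping) and isinstance(img.get("path"), str):
                _check_image(store, join_path(node, img["path"]), out,
                             is_label=False)
    return out.report()


# ---------------------------------------------------------------------------
# inspection

@dataclass(frozen=True)
class LevelSummary:
    path: str
    shape: Tuple[int, ...]
    chunk_shape: Tuple[int, ...]
    dtype_code: str
    n_chunks: int
    n_chunks_stored: int
    stored_bytes: int


@dataclass(frozen=True)
class TreeSummary:
    """Size/geometry overview of one multiscale image (Fig-7-style)."""

    path: str
    levels: Tuple[LevelSummary, ...]
    total_voxels: int
    raw_bytes: int
    plate_grid: Optional[Tuple[int, int]] = None

    def format(self) -> str:
        lines = [f"{self.path or '/'}: {len(self.levels)} resolution level(s), "
                 f"{self.total_voxels:,} voxels, {self.raw_bytes:,} raw bytes"]
        if self.plate_grid is not None:
            lines.append(f"  plate grid: {self.plate_grid[0]} rows x "
                         f"{self.plate_grid[1]} columns")
        for lv in self.levels:
            lines.append(
                f"  level {lv.path}: shape {lv.shape}, chunks {lv.chunk_shape} "
                f"({lv.n_chunks_stored}/{lv.n_chunks} stored, "
                f"{lv.stored_bytes:,} bytes), dtype {lv.dtype_code}")
        return "\n".join(lines)

    def to_doc(self) -> Dict[str, object]:
        return {
            "path": self.path,
            "total_voxels": self.total_voxels,
            "raw_bytes": self.raw_bytes,
            "plate_grid": list(self.plate_grid) if self.plate_grid else None,
            "levels": [{
                "path": lv.path, "shape": list(lv.shape),
                "chunk_shape": list(lv.chunk_shape), "dtype": lv.dtype_code,
                "n_chunks": lv.n_chunks,
                "n_chunks_stored": lv.n_chunks_stored,
                "stored_bytes": lv.stored_bytes,
            } for lv in self.levels],
        }


def summarize(store: KVStore, path: str) -> TreeSummary:
    """Per-level geometry, chunk statistics and byte totals of an image.

    For a plate, the first present well's first field is summarized and
    the plate grid dimensions are reported alongside.
    """
    if not _exists(store, path):
        raise KeyError(f"no node at {path!r}")
    attrs = cs.read_attrs(store, path)
    plate_grid = None
    if "plate" in attrs:
        from .collections import parse_plate, parse_well
        plate = parse_plate(attrs)
        plate_grid = (len(plate.row_names), len(plate.column_names))
        for wp, _r, _c in plate.wells:
            wattrs = cs.read_attrs(store, join_path(path, wp))
            if wattrs:
                well = parse_well(wattrs)
                path = join_path(path, wp, well.images[0][0])
                attrs = cs.read_attrs(store, path)
                break
        else:
            raise ValueError(f"plate {path!r} has no wells present")
    entries = attrs.get("multiscales")
    if not isinstance(entries, list) or not entries:
        raise ValueError(f"{path!r} is not a multiscale image")
    levels: List[LevelSummary] = []
    for d in entries[0].get("datasets", []):
        node = join_path(path, str(d.get("path")))
        schema = cs.read_array_schema(store, node)
        n_chunks = 1
        for g in schema.grid:
            n_chunks *= g
        chunk_keys = [k for k in store.list(node)
                      if not k.rsplit("/", 1)[-1].startswith(".")]
        stored_bytes = sum(len(store.get(k)) for k in chunk_keys)
        levels.append(LevelSummary(
            path=str(d.get("path")), shape=schema.shape,
            chunk_shape=schema.chunk_shape, dtype_code=schema.dtype_code,
            n_chunks=n_chunks, n_chunks_stored=len(chunk_keys),
            stored_bytes=stored_bytes))
    if not levels:
        raise ValueError(f"{path!r} lists no datasets")
    total_voxels = 1
    for s in levels[0].shape:
        total_voxels *= s
    raw = cs.raw_byte_size(levels[0].shape, levels[0].dtype_code)
    return TreeSummary(path=path, levels=tuple(levels),
                       total_voxels=total_voxels, raw_bytes=raw,
                       plate_grid=plate_grid)
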