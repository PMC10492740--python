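"""Grouped-image containers: HCS plates and label images.

A high-content-screening plate is a three-level hierarchy — plate →
well → field — in which every field is a complete multiscale image.
The plate group's attributes declare the row/column grid and the wells
present; each well group lists its fields. Concatenating one low
resolution level of every well produces a plate montage, the quick
whole-plate overview a screening viewer shows first.

Segmentations ride along as label images: integer-valued multiscale
images stored under ``labels/{name}`` beside the image they annotate,
downsampled by local mode so labels never bleed into each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import chunk_store as cs
from .chunk_store import KVStore, join_path
from .ngff_model import NGFF_VERSION, parse_multiscales
from .pyramid import write_multiscale_image

__all__ = [
    "PlateMeta", "WellMeta", "LabelMeta",
    "well_path", "write_plate", "write_well", "montage", "write_labels",
    "parse_plate", "parse_well", "parse_label_meta",
]


def well_path(row_name: str, column_name: str) -> str:
    """The group path of one well, ``"{row}/{column}"``."""
    for name in (row_name, column_name):
        if not name or not name.isalnum():
            raise ValueError(f"well row/column names must be non-empty "
                             f"alphanumerics, got {name!r}")
    return f"{row_name}/{column_name}"


@dataclass(frozen=True)
class PlateMeta:
    """Plate grid: named rows/columns plus the wells actually present."""

    row_names: Tuple[str, ...]
    column_names: Tuple[str, ...]
    wells: Tuple[Tuple[str, int, int], ...]  # (path, row_index, column_index)
    field_count: int = 1
    acquisitions: Optional[Tuple[Tuple[int, str], ...]] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "row_names", tuple(self.row_names))
        object.__setattr__(self, "column_names", tuple(self.column_names))
        object.__setattr__(self, "wells", tuple(tuple(w) for w in self.wells))
        if self.field_count < 1:
            raise ValueError("field_count must be >= 1")
        paths = [w[0] for w in self.wells]
        if len(set(paths)) != len(paths):
            raise ValueError("duplicate well paths in plate")
        for path, r, c in self.wells:
            if not 0 <= r < len(self.row_names) or not 0 <= c < len(self.column_names):
                raise ValueError(f"well {path!r}: row/column index out of range")
            expect = well_path(self.row_names[r], self.column_names[c])
            if path != expect:
                raise ValueError(f"well path {path!r} != {expect!r} implied by indices")

    @classmethod
    def from_grid(cls, n_rows: int, n_cols: int, field_count: int = 1,
                  name: Optional[str] = None) -> "PlateMeta":
        """Full plate with rows "A".. and columns "1".., every well present."""
        if n_rows < 1 or n_cols < 1:
            raise ValueError("plate grid dimensions must be >= 1")
        rows = tuple(chr(ord("A") + i) for i in range(n_rows))
        cols = tuple(str(j + 1) for j in range(n_cols))
        wells = tuple((well_path(r, c), i, j)
                      for i, r in enumerate(rows) for j, c in enumerate(cols))
        return cls(row_names=rows, column_names=cols, wells=wells,
                   field_count=field_count, name=name)

    def to_doc(self) -> Dict[str, object]:
        doc: Dict[str, object] = {
            "version": NGFF_VERSION,
            "rows": [{"name": r} for r in self.row_names],
            "columns": [{"name": c} for c in self.column_names],
            "wells": [{"path": p, "rowIndex": r, "columnIndex": c}
                      for p, r, c in self.wells],
            "field_count": self.field_count,
        }
        if self.acquisitions is not None:
            doc["acquisitions"] = [{"id": i, "name": n} for i, n in self.acquisitions]
        if self.name is not None:
            doc["name"] = self.name
        return {"plate": doc}


def parse_plate(attrs: Mapping[str, object]) -> PlateMeta:
    if "plate" not in attrs:
        raise ValueError("attribute document lacks 'plate'")
    doc = attrs["plate"]
    acq = None
    if doc.get("acquisitions") is not None:
        acq = tuple((int(a["id"]), str(a.get("name", ""))) for a in doc["acquisitions"])
    return PlateMeta(
        row_names=tuple(r["name"] for r in doc["rows"]),
        column_names=tuple(c["name"] for c in doc["columns"]),
        wells=tuple((w["path"], int(w["rowIndex"]), int(w["columnIndex"]))
                    for w in doc["wells"]),
        field_count=int(doc.get("field_count", 1)),
        acquisitions=acq,
        name=None if doc.get("name") is None else str(doc["name"]))


@dataclass(frozen=True)
class WellMeta:
    """Fields of one well: image paths plus optional acquisition ids."""

    images: Tuple[Tuple[str, Optional[int]], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "images", tuple(tuple(i) for i in self.images))
        if not self.images:
            raise ValueError("a well must contain at least one image")
        paths = [i[0] for i in self.images]
        if len(set(paths)) != len(paths):
            raise ValueError("duplicate field paths in well")

    def to_doc(self) -> Dict[str, object]:
        return {"well": {
            "version": NGFF_VERSION,
            "images": [
                {"path": p, **({"acquisition": a} if a is not None else {})}
                for p, a in self.images],
        }}


def parse_well(attrs: Mapping[str, object]) -> WellMeta:
    if "well" not in attrs:
        raise ValueError("attribute document lacks 'well'")
    doc = attrs["well"]
    return WellMeta(images=tuple(
        (str(i["path"]), None if i.get("acquisition") is None else int(i["acquisition"]))
        for i in doc["images"]))


def write_well(store: KVStore, plate_path: str, plate: PlateMeta, well: str,
               images: Sequence[np.ndarray], **image_options) -> str:
    """Write one well (all its field images) under an existing plate group."""
    if well not in {w[0] for w in plate.wells}:
        raise ValueError(f"well {well!r} is not declared by the plate")
    if len(images) > plate.field_count:
        raise ValueError(f"{len(images)} fields exceed plate field_count "
                         f"{plate.field_count}")
    if not images:
        raise ValueError("a well needs at least one field image")
    wpath = join_path(plate_path, well)
    if cs.read_attrs(store, wpath):
        raise ValueError(f"well {well!r} already written")
    # row group ("A/") then well group ("A/1/")
    cs.init_group(store, join_path(plate_path, well.split("/")[0]))
    cs.init_group(store, wpath)
    for i, img in enumerate(images):
        write_multiscale_image(store, join_path(wpath, str(i)), img,
                               **image_options)
    cs.write_attrs(store, wpath,
                   WellMeta(images=tuple((str(i), None)
                                         for i in range(len(images)))).to_doc())
    return wpath


def write_plate(store: KVStore, path: str, plate: PlateMeta,
                fields: Mapping[str, Sequence[np.ndarray]],
                **image_options) -> str:
    """Write a whole plate: plate attributes plus one group per well.

    ``fields`` maps declared well paths to that well's field images; wells
    missing from the mapping are declared but absent on disk (sparse
    plates are legal).
    """
    declared = {w[0] for w in plate.wells}
    undeclared = set(fields) - declared
    if undeclared:
        raise ValueError(f"wells not declared by the plate: {sorted(undeclared)}")
    cs.init_group(store, path)
    cs.write_attrs(store, path, plate.to_doc())
    for well in sorted(fields):
        write_well(store, path, plate, well, fields[well], **image_options)
    return path


def montage(store: KVStore, plate_path: str, level: int = -1,
            field: int = 0) -> np.ndarray:
    """Tile one resolution level of one field of every well into a 2D mosaic.

    Wells are laid out row-major on the declared plate grid; the first
    t/c/z hyperplane of the chosen level is used as the cell. Missing
    wells appear as the array fill value. ``level`` may be negative to
    count from the coarsest level.
    """
    plate = parse_plate(cs.read_attrs(store, plate_path))
    if not 0 <= field < plate.field_count:
        raise ValueError(f"field {field} out of range (field_count "
                         f"{plate.field_count})")
    cells: Dict[Tuple[int, int], np.ndarray] = {}
    fill = 0
    for wpath, r, c in plate.wells:
        attrs = cs.read_attrs(store, join_path(plate_path, wpath))
        if not attrs:
            continue  # well declared but absent
        well = parse_well(attrs)
        if field >= len(well.images):
            continue
        img_path = join_path(plate_path, wpath, well.images[field][0])
        meta = parse_multiscales(cs.read_attrs(store, img_path))[0]
        n_levels = len(meta.datasets)
        lvl = level if level >= 0 else n_levels + level
        if not 0 <= lvl < n_levels:
            raise ValueError(f"level {level} absent from well {wpath!r} "
                             f"({n_levels} levels)")
        apath = join_path(img_path, meta.datasets[lvl].path)
        schema = cs.read_array_schema(store, apath)
        fill = schema.fill_value
        arr = cs.read_full(store, apath)
        cells[(r, c)] = arr[(0,) * (arr.ndim - 2)]  # first t/c/z hyperplane
    if not cells:
        raise ValueError(f"plate {plate_path!r} has no wells present")
    cell0 = next(iter(cells.values()))
    h, w = cell0.shape
    out = np.full((len(plate.row_names) * h, len(plate.column_names) * w),
                  fill, dtype=cell0.dtype)
    for (r, c), cell in cells.items():
        out[r * h:r * h + cell.shape[0], c * w:c * w + cell.shape[1]] = cell
    return out


@dataclass(frozen=True)
class LabelMeta:
    """Display/provenance metadata of one label image."""

    colors: Optional[Tuple[Tuple[int, Tuple[int, int, int, int]], ...]] = None
    source: Optional[str] = None
    properties: Optional[Tuple[Mapping[str, object], ...]] = None

    def __post_init__(self) -> None:
        if self.colors is not None:
            object.__setattr__(self, "colors",
                               tuple((int(v), tuple(rgba)) for v, rgba in self.colors))
            values = [v for v, _ in self.colors]
            if len(set(values)) != len(values):
                raise ValueError("duplicate label values in colors")
            for v, rgba in self.colors:
                if len(rgba) != 4 or any(not 0 <= ch <= 255 for ch in rgba):
                    raise ValueError(f"label {v}: RGBA components must be in [0, 255]")

    def to_doc(self) -> Dict[str, object]:
        doc: Dict[str, object] = {"version": NGFF_VERSION}
        if self.colors is not None:
            doc["colors"] = [{"label-value": v, "rgba": list(rgba)}
                             for v, rgba in self.colors]
        if self.source is not None:
            doc["source"] = {"image": self.source}
        if self.properties is not None:
            doc["properties"] = [dict(p) for p in self.properties]
        return doc


def parse_label_meta(doc: Mapping[str, object]) -> LabelMeta:
    colors = None
    if doc.get("colors") is not None:
        colors = tuple((int(c["label-value"]), tuple(c["rgba"]))
                       for c in doc["colors"])
    source = None
    if isinstance(doc.get("source"), Mapping):
        source = doc["source"].get("image")
    props = None
    if doc.get("properties") is not None:
        props = tuple(dict(p) for p in doc["properties"])
    return LabelMeta(colors=colors, source=source, properties=props)


def write_labels(store: KVStore, image_path: str, name: str,
                 labels: np.ndarray, meta: Optional[LabelMeta] = None,
                 **image_options) -> str:
    """Store a segmentation as ``labels/{name}`` beside its source image."""
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("label images require integer dtype")
    if not name or "/" in name:
        raise ValueError(f"illegal label name {name!r}")
    labels_group = join_path(image_path, "labels")
    attrs = cs.read_attrs(store, labels_group)
    listed = list(attrs.get("labels", []))
    if name in listed:
        raise ValueError(f"label {name!r} already exists under {image_path!r}")
    if meta is None:
        meta = LabelMeta(source="../../")
    elif meta.source is None:
        meta = LabelMeta(colors=meta.colors, source="../../",
                         properties=meta.properties)
    cs.init_group(store, labels_group)
    cs.write_attrs(store, labels_group, {"labels": listed + [name]})
    target = join_path(labels_group, name)
    image_options.setdefault("kind", "label")
    write_multiscale_image(store, target, labels,
                           extra_attrs={"image-label": meta.to_doc()},
                           **image_options)
    return target
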