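"""The OME-NGFF 0.4 image metadata model.

An image is described by an ordered list of named axes (time, channel and
2–3 spatial axes, in that order — version 0.4 caps images at five
dimensions) and an ordered list of resolution levels ("datasets"),
highest resolution first. Each level carries one scale transform mapping
array indices to physical coordinates, optionally followed by one
translation. An optional channel-rendering block ("omero") records
per-channel color and contrast-window hints.

This module is pure data-in/data-out: dataclasses on one side, the JSON
attribute documents stored in a group's ``.zattrs`` on the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

NGFF_VERSION = "0.4"

AXIS_TYPES = ("time", "channel", "space")

#: canonical default axis names, outermost first
DEFAULT_AXIS_NAMES = ("t", "c", "z", "y", "x")
_DEFAULT_AXIS_TYPES = ("time", "channel", "space", "space", "space")


class MetadataError(ValueError):
    """Raised when an attribute document cannot be parsed as 0.4 metadata."""


@dataclass(frozen=True)
class Axis:
    name: str
    type: str
    unit: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("axis name must be non-empty")
        if self.type not in AXIS_TYPES:
            raise ValueError(f"axis type {self.type!r} not in {AXIS_TYPES}")

    def to_doc(self) -> Dict[str, object]:
        doc: Dict[str, object] = {"name": self.name, "type": self.type}
        if self.unit is not None:
            doc["unit"] = self.unit
        return doc

    @classmethod
    def from_doc(cls, doc: Mapping[str, object]) -> "Axis":
        if "name" not in doc or "type" not in doc:
            raise MetadataError(f"axis document lacks name/type: {dict(doc)!r}")
        try:
            return cls(name=str(doc["name"]), type=str(doc["type"]),
                       unit=None if doc.get("unit") is None else str(doc["unit"]))
        except ValueError as exc:
            raise MetadataError(str(exc)) from None


@dataclass(frozen=True)
class DatasetEntry:
    """One resolution level: the array path plus its physical transforms."""

    path: str
    scale: Tuple[float, ...]
    translation: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scale", tuple(float(s) for s in self.scale))
        if self.translation is not None:
            object.__setattr__(self, "translation",
                               tuple(float(t) for t in self.translation))
        if not self.path:
            raise ValueError("dataset path must be non-empty")
        if any(s <= 0 for s in self.scale):
            raise ValueError("scale entries must be positive")
        if self.translation is not None and len(self.translation) != len(self.scale):
            raise ValueError("translation length must match scale length")

    def to_doc(self) -> Dict[str, object]:
        transforms: List[Dict[str, object]] = [
            {"type": "scale", "scale": list(self.scale)}]
        if self.translation is not None:
            transforms.append({"type": "translation",
                               "translation": list(self.translation)})
        return {"path": self.path, "coordinateTransformations": transforms}

    @classmethod
    def from_doc(cls, doc: Mapping[str, object]) -> "DatasetEntry":
        if "path" not in doc:
            raise MetadataError("dataset document lacks 'path'")
        transforms = doc.get("coordinateTransformations")
        if not isinstance(transforms, list) or not transforms:
            raise MetadataError(f"dataset {doc['path']!r} lacks coordinateTransformations")
        first = transforms[0]
        if not isinstance(first, Mapping) or first.get("type") != "scale":
            raise MetadataError(
                f"dataset {doc['path']!r}: first transform must be a scale")
        scale = tuple(first["scale"])
        translation = None
        if len(transforms) > 1:
            second = transforms[1]
            if not isinstance(second, Mapping) or second.get("type") != "translation":
                raise MetadataError(
                    f"dataset {doc['path']!r}: second transform must be a translation")
            translation = tuple(second["translation"])
        if len(transforms) > 2:
            raise MetadataError(
                f"dataset {doc['path']!r}: at most scale + translation supported")
        try:
            return cls(path=str(doc["path"]), scale=scale, translation=translation)
        except ValueError as exc:
            raise MetadataError(str(exc)) from None


@dataclass(frozen=True)
class MultiscaleMeta:
    """Axes plus the ordered resolution levels of one multiscale image."""

    axes: Tuple[Axis, ...]
    datasets: Tuple[DatasetEntry, ...]
    version: str = NGFF_VERSION
    name: Optional[str] = None
    downsampling_method: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "axes", tuple(self.axes))
        object.__setattr__(self, "datasets", tuple(self.datasets))
        check_axes(self.axes)
        if not self.datasets:
            raise ValueError("at least one dataset (resolution level) is required")
        for ds in self.datasets:
            if len(ds.scale) != len(self.axes):
                raise ValueError(
                    f"dataset {ds.path!r}: scale has {len(ds.scale)} entries "
                    f"for {len(self.axes)} axes")

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def to_doc(self) -> Dict[str, object]:
        entry: Dict[str, object] = {
            "version": self.version,
            "axes": [a.to_doc() for a in self.axes],
            "datasets": [d.to_doc() for d in self.datasets],
        }
        if self.name is not None:
            entry["name"] = self.name
        if self.downsampling_method is not None:
            entry["metadata"] = {"method": self.downsampling_method}
        return entry


def check_axes(axes: Sequence[Axis]) -> None:
    """Enforce the 0.4 axis rules: 2–5 axes, unique names, at most one time
    and one channel axis, 2–3 space axes, ordered time → channel → space."""
    if not 2 <= len(axes) <= 5:
        raise ValueError(
            f"{len(axes)} axes unsupported in version {NGFF_VERSION}: "
            f"images must have 2 to 5 dimensions")
    names = [a.name for a in axes]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate axis names in {names}")
    types = [a.type for a in axes]
    if types.count("time") > 1 or types.count("channel") > 1:
        raise ValueError("at most one time axis and one channel axis allowed")
    n_space = types.count("space")
    if not 2 <= n_space <= 3:
        raise ValueError(f"{n_space} space axes; 2 or 3 required")
    # time, then channel, then space — checked as monotone type ranks
    rank = {"time": 0, "channel": 1, "space": 2}
    ranks = [rank[t] for t in types]
    if ranks != sorted(ranks):
        raise ValueError(f"axis order must be time, channel, then space; got {types}")


def default_axes(ndim: int, *, space_unit: Optional[str] = None,
                 time_unit: Optional[str] = None) -> Tuple[Axis, ...]:
    """The canonical trailing subset of (t, c, z, y, x) for a given rank."""
    if not 2 <= ndim <= 5:
        raise ValueError(
            f"{ndim} dimensions unsupported: version {NGFF_VERSION} supports "
            f"2 to 5 dimensional images")
    names = DEFAULT_AXIS_NAMES[5 - ndim:]
    types = _DEFAULT_AXIS_TYPES[5 - ndim:]
    units = {"space": space_unit, "time": time_unit, "channel": None}
    return tuple(Axis(name=n, type=t, unit=units[t]) for n, t in zip(names, types))


def multiscales_to_doc(meta: MultiscaleMeta) -> Dict[str, object]:
    """Serialize one multiscale description to a ``.zattrs`` fragment."""
    return {"multiscales": [meta.to_doc()]}


def parse_multiscales(doc: Mapping[str, object]) -> List[MultiscaleMeta]:
    """Parse every multiscale entry from an attribute document (strict)."""
    if "multiscales" not in doc:
        raise MetadataError("attribute document lacks 'multiscales'")
    entries = doc["multiscales"]
    if not isinstance(entries, list) or not entries:
        raise MetadataError("'multiscales' must be a non-empty list")
    out: List[MultiscaleMeta] = []
    for i, entry in enumerate(entries):
        if not isinstance(entry, Mapping):
            raise MetadataError(f"multiscales[{i}] is not an object")
        version = str(entry.get("version", ""))
        if version != NGFF_VERSION:
            raise MetadataError(
                f"multiscales[{i}]: unknown version {version!r} "
                f"(only {NGFF_VERSION} supported)")
        if "axes" not in entry:
            raise MetadataError(f"multiscales[{i}] lacks 'axes'")
        if "datasets" not in entry:
            raise MetadataError(f"multiscales[{i}] lacks 'datasets'")
        axes = tuple(Axis.from_doc(a) for a in entry["axes"])
        datasets = tuple(DatasetEntry.from_doc(d) for d in entry["datasets"])
        method = None
        md = entry.get("metadata")
        if isinstance(md, Mapping) and md.get("method") is not None:
            method = str(md["method"])
        try:
            out.append(MultiscaleMeta(
                axes=axes, datasets=datasets, version=version,
                name=None if entry.get("name") is None else str(entry["name"]),
                downsampling_method=method))
        except ValueError as exc:
            raise MetadataError(f"multiscales[{i}]: {exc}") from None
    return out


def level_scale(base_scale: Sequence[float], level: int, spatial_factor: int,
                downsampled_axes: Sequence[int]) -> Tuple[float, ...]:
    """Physical scale of pyramid level ``level``.

    Axis positions in ``downsampled_axes`` are coarsened by
    ``spatial_factor ** level``; all other axes keep the base scale.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    if spatial_factor < 2:
        raise ValueError("spatial_factor must be >= 2")
    ds = set(downsampled_axes)
    factor = float(spatial_factor) ** level
    return tuple(s * factor if i in ds else float(s)
                 for i, s in enumerate(base_scale))


# ---------------------------------------------------------------------------
# channel rendering ("omero" block)

@dataclass(frozen=True)
class ChannelWindow:
    min: float
    max: float
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.min <= self.start <= self.end <= self.max:
            raise ValueError(
                f"window must satisfy min <= start <= end <= max, got "
                f"({self.min}, {self.start}, {self.end}, {self.max})")


@dataclass(frozen=True)
class Channel:
    color: str  # 6-hex-digit RGB
    window: ChannelWindow
    label: Optional[str] = None
    active: bool = True

    def __post_init__(self) -> None:
        if len(self.color) != 6 or any(c not in "0123456789abcdefABCDEF"
                                       for c in self.color):
            raise ValueError(f"color must be 6 hex digits, got {self.color!r}")


@dataclass(frozen=True)
class ChannelRendering:
    channels: Tuple[Channel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))

    def to_doc(self) -> Dict[str, object]:
        return {"channels": [
            {
                "color": ch.color,
                "window": {"min": ch.window.min, "max": ch.window.max,
                           "start": ch.window.start, "end": ch.window.end},
                **({"label": ch.label} if ch.label is not None else {}),
                "active": ch.active,
            }
            for ch in self.channels
        ]}

    @classmethod
    def from_doc(cls, doc: Mapping[str, object]) -> "ChannelRendering":
        # lenient on read: skip malformed channels rather than fail
        channels: List[Channel] = []
        for ch in doc.get("channels", []) or []:
            if not isinstance(ch, Mapping):
                continue
            try:
                w = ch.get("window") or {}
                channels.append(Channel(
                    color=str(ch.get("color", "FFFFFF")),
                    window=ChannelWindow(
                        min=float(w.get("min", 0)), max=float(w.get("max", 1)),
                        start=float(w.get("start", w.get("min", 0))),
                        end=float(w.get("end", w.get("max", 1)))),
                    label=None if ch.get("label") is None else str(ch["label"]),
                    active=bool(ch.get("active", True))))
            except (ValueError, TypeError):
                continue
        return cls(channels=tuple(channels))
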