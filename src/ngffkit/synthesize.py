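"""Deterministic synthetic fixtures: images, labelled blobs, whole plates.

Everything the other modules need for testing is generated here, with no
downloads and bit-level reproducibility across platforms. Randomness
comes from an explicitly specified counter-based SplitMix64 stream, not
from ambient global state, so a fixture spec maps to exactly one byte
sequence forever.

The module also hosts the *mutation helpers*: minimal, targeted edits
that each break exactly one validation rule of :mod:`ngffkit.validator`.
They exist so the validator's error codes can be exercised one at a
time against otherwise-clean trees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import chunk_store as cs
from .chunk_store import KVStore, join_path
from .collections import LabelMeta, PlateMeta, write_labels, write_plate
from .ngff_model import Channel, ChannelRendering, ChannelWindow, default_axes
from .pyramid import write_multiscale_image

__all__ = ["SplitMix64", "FixtureSpec", "make_image", "write_image_fixture",
           "make_plate_fixture", "MUTATIONS", "apply_mutation"]

_MASK = (1 << 64) - 1
_GOLDEN = 0x9E3779B97F4A7C15


def _mix(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer on an array of uint64 counters."""
    z = x.astype(np.uint64, copy=True)
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z


class SplitMix64:
    """Counter-based SplitMix64 stream.

    State advances by the 64-bit golden-gamma constant per draw; outputs
    are the standard SplitMix64 finalizer of the state. Vector draws use
    the same sequence as repeated scalar draws.
    """

    def __init__(self, seed: int) -> None:
        self._counter = int(seed) & _MASK

    def _take(self, n: int) -> np.ndarray:
        start = self._counter
        idx = (np.uint64(start) +
               (np.arange(1, n + 1, dtype=np.uint64) * np.uint64(_GOLDEN)))
        self._counter = (start + n * _GOLDEN) & _MASK
        return _mix(idx)

    def next_u64(self) -> int:
        return int(self._take(1)[0])

    def floats(self, n: int) -> np.ndarray:
        """n doubles uniform in [0, 1) with 53-bit resolution."""
        return (self._take(n) >> np.uint64(11)) * (1.0 / (1 << 53))

    def integers(self, n: int, low: int, high: int) -> np.ndarray:
        """n integers uniform in [low, high) (via floating rejection-free map)."""
        if high <= low:
            raise ValueError("high must exceed low")
        return low + np.floor(self.floats(n) * (high - low)).astype(np.int64)

    def spawn(self, key: int) -> "SplitMix64":
        """An independent stream derived from this seed and a key."""
        mixed = (self._counter + _GOLDEN * (key + 1)) & _MASK
        return SplitMix64(int(_mix(np.array([mixed], dtype=np.uint64))[0]))


@dataclass(frozen=True)
class FixtureSpec:
    """Everything that determines one synthetic fixture, bit for bit."""

    seed: int = 0
    shape: Tuple[int, ...] = (1, 1, 1, 64, 64)
    dtype_code: str = "u2"
    content: str = "blobs"  # gradient | blobs | noise
    blob_count: int = 4
    plate_rows: int = 2
    plate_cols: int = 3
    plate_fields: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if not 2 <= len(self.shape) <= 5:
            raise ValueError(f"fixture rank {len(self.shape)} outside 2-5")
        if self.content not in ("gradient", "blobs", "noise"):
            raise ValueError(f"unknown content {self.content!r}")
        if self.blob_count < 0:
            raise ValueError("blob_count must be >= 0")
        if min(self.plate_rows, self.plate_cols, self.plate_fields) < 1:
            raise ValueError("plate grid dimensions must be >= 1")


def _intensity_range(dtype: np.dtype) -> float:
    if dtype.kind in "iu":
        return float(min(np.iinfo(dtype).max, 10000))
    return 1.0


def make_image(spec: FixtureSpec) -> Tuple[np.ndarray, Dict[str, object]]:
    """Generate a deterministic image plus its ground truth.

    The trailing two (or three) axes are spatial; for blob content the
    ground truth records each blob's channel, center, radius and label
    id, together with a spatial label mask whose nonzero values are the
    blob ids.
    """
    dtype = cs.dtype_of(spec.dtype_code)
    shape = spec.shape
    rank = len(shape)
    hi = _intensity_range(dtype)
    rng = SplitMix64(spec.seed)
    truth: Dict[str, object] = {"content": spec.content}

    if spec.content == "gradient":
        grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                            indexing="ij", sparse=True)
        acc = np.zeros(shape, dtype=np.float64)
        for ax, g in enumerate(grids):
            denom = max(shape[ax] - 1, 1)
            acc = acc + (ax + 1) * g / denom
        data = acc / (rank * (rank + 1) / 2) * hi
    elif spec.content == "noise":
        data = rng.floats(int(np.prod(shape))).reshape(shape) * hi
    else:  # blobs
        data, blobs, mask = _make_blobs(spec, rng, hi)
        truth["blobs"] = blobs
        truth["label_mask"] = mask
    return data.astype(dtype), truth


def _make_blobs(spec: FixtureSpec, rng: SplitMix64, hi: float
                ) -> Tuple[np.ndarray, List[Dict[str, object]], np.ndarray]:
    shape = spec.shape
    rank = len(shape)
    n_space = 3 if rank >= 3 else 2
    spatial = shape[-n_space:]
    n_chan = shape[-4] if rank >= 4 else 1

    # low-amplitude noise background
    data = rng.floats(int(np.prod(shape))).reshape(shape) * (0.1 * hi)
    mask = np.zeros(spatial, dtype=np.int32)
    blobs: List[Dict[str, object]] = []

    n = spec.blob_count
    if n:
        # jittered-grid placement on y/x guarantees disjoint blobs
        gy = int(math.ceil(math.sqrt(n)))
        gx = int(math.ceil(n / gy))
        cell = (spatial[-2] // gy, spatial[-1] // gx)
        if min(cell) < 4:
            raise ValueError(f"image {spatial} too small for {n} blobs")
        radius = max(min(cell) // 4, 1)
        jitter = rng.integers(2 * n, -(min(cell) // 8) or 0,
                              (min(cell) // 8) + 1)
        channels = rng.integers(n, 0, n_chan)
        coords = np.meshgrid(*[np.arange(s) for s in spatial], indexing="ij")
        for b in range(n):
            gy_i, gx_i = divmod(b, gx)
            cy = gy_i * cell[0] + cell[0] // 2 + int(jitter[2 * b])
            cx_ = gx_i * cell[1] + cell[1] // 2 + int(jitter[2 * b + 1])
            center = ((spatial[0] // 2, cy, cx_) if n_space == 3 else (cy, cx_))
            dist2 = sum((coords[i] - center[i]) ** 2 for i in range(n_space))
            rz = min(radius, max(spatial[0] // 2, 1)) if n_space == 3 else radius
            # anisotropic z: scale z distance so the blob fits thin stacks
            if n_space == 3 and rz < radius:
                dist2 = ((coords[0] - center[0]) ** 2 *
                         (radius / max(rz, 1)) ** 2
                         + (coords[1] - center[1]) ** 2
                         + (coords[2] - center[2]) ** 2)
            inside = dist2 <= radius ** 2
            label = b + 1
            mask[inside] = label
            ch = int(channels[b])
            if rank == n_space:
                data[..., inside] = 0.9 * hi
            elif rank == n_space + 1:  # (c, spatial...)
                data[ch][inside] = 0.9 * hi
            else:  # (t, c, spatial...)
                data[:, ch][:, inside] = 0.9 * hi
            blobs.append({"label": label, "channel": ch,
                          "center": tuple(int(v) for v in center),
                          "radius": int(radius)})
    return data, blobs, mask


def _fixture_rendering(n_chan: int, dtype: np.dtype) -> ChannelRendering:
    hi = _intensity_range(dtype)
    palette = ["FF0000", "00FF00", "0000FF", "FFFF00", "FF00FF", "00FFFF"]
    return ChannelRendering(channels=tuple(
        Channel(color=palette[i % len(palette)],
                window=ChannelWindow(min=0, max=hi, start=0, end=hi),
                label=f"ch{i}")
        for i in range(n_chan)))


#: pyramid stop threshold used for fixtures — small so even 64-pixel test
#: images get several levels to exercise multiscale logic
FIXTURE_MIN_EXTENT = 16


def write_image_fixture(store: KVStore, path: str, spec: FixtureSpec,
                        min_extent: int = FIXTURE_MIN_EXTENT,
                        chunk_shape: Optional[Sequence[int]] = None,
                        with_labels: bool = True) -> Dict[str, object]:
    """Write a complete, valid multiscale image fixture; returns ground truth.

    For blob content a "blobs" label image (with per-label colors) is
    written beside it unless ``with_labels`` is false.
    """
    data, truth = make_image(spec)
    rank = data.ndim
    n_chan = data.shape[-4] if rank >= 4 else 1
    if chunk_shape is None:
        chunk_shape = (1,) * (rank - 2) + tuple(min(s, 32) for s in data.shape[-2:])
    write_multiscale_image(
        store, path, data, axes=default_axes(rank),
        chunk_shape=chunk_shape, min_extent=min_extent,
        name=f"fixture-{spec.content}-{spec.seed}",
        channel_rendering=_fixture_rendering(n_chan, data.dtype))
    if with_labels and spec.content == "blobs":
        mask = truth["label_mask"]
        rng = SplitMix64(spec.seed).spawn(0xC0102)
        colors = tuple(
            (b["label"], tuple(int(v) for v in rng.integers(3, 0, 256)) + (255,))
            for b in truth["blobs"])
        write_labels(store, path, "blobs", mask,
                     LabelMeta(colors=colors or None),
                     chunk_shape=tuple(min(s, 32) for s in mask.shape),
                     min_extent=min_extent)
    return truth


def make_plate_fixture(spec: FixtureSpec, store: KVStore, path: str,
                       min_extent: int = FIXTURE_MIN_EXTENT,
                       missing_wells: Sequence[str] = ()) -> str:
    """Write a full HCS plate fixture; every well holds blob-field images.

    ``missing_wells`` names grid positions to leave out entirely: they are
    neither declared nor written (a sparse but still compliant plate)."""
    full = PlateMeta.from_grid(spec.plate_rows, spec.plate_cols,
                               field_count=spec.plate_fields,
                               name=f"fixture-plate-{spec.seed}")
    plate = PlateMeta(row_names=full.row_names, column_names=full.column_names,
                      wells=tuple(w for w in full.wells
                                  if w[0] not in missing_wells),
                      field_count=full.field_count, name=full.name)
    fields: Dict[str, List[np.ndarray]] = {}
    base = SplitMix64(spec.seed)
    for i, (wp, _r, _c) in enumerate(full.wells):
        if wp in missing_wells:
            continue
        imgs = []
        for f in range(spec.plate_fields):
            wspec = replace(spec, seed=base.spawn(i * 97 + f).next_u64() % (1 << 62))
            imgs.append(make_image(wspec)[0])
        fields[wp] = imgs
    write_plate(store, path, plate, fields, min_extent=min_extent,
                chunk_shape=(1,) * (len(spec.shape) - 2) +
                tuple(min(s, 32) for s in spec.shape[-2:]))
    return path


# ---------------------------------------------------------------------------
# mutation helpers — each breaks exactly one validation rule

def _edit_json(store: KVStore, key: str, fn: Callable[[dict], None]) -> None:
    doc = json.loads(store.get(key))
    fn(doc)
    store.put(key, json.dumps(doc, indent=2, sort_keys=True).encode())


def _edit_attrs(store: KVStore, path: str, fn: Callable[[dict], None]) -> None:
    _edit_json(store, join_path(path, cs.ATTRS_KEY), fn)


def _first_chunk_key(store: KVStore, array_path: str) -> str:
    for k in store.list(array_path):
        if not k.rsplit("/", 1)[-1].startswith("."):
            return k
    raise KeyError(f"no chunks under {array_path!r}")


def _m_missing_multiscales(store, path):
    _edit_attrs(store, path, lambda d: d.pop("multiscales"))


def _m_bad_multiscales(store, path):
    _edit_attrs(store, path, lambda d: d.__setitem__("multiscales", [{}]))


def _m_axes_count(store, path):
    def fn(d):
        d["multiscales"][0]["axes"].append({"name": "q", "type": "space"})
    _edit_attrs(store, path, fn)


def _m_axes_type(store, path):
    def fn(d):
        d["multiscales"][0]["axes"][0]["type"] = "frequency"
    _edit_attrs(store, path, fn)


def _m_axes_order(store, path):
    def fn(d):
        axes = d["multiscales"][0]["axes"]
        axes[0], axes[1] = axes[1], axes[0]
    _edit_attrs(store, path, fn)


def _m_dataset_missing(store, path):
    store.delete(join_path(path, "1", cs.ARRAY_META_KEY))


def _m_rank_mismatch(store, path):
    def fn(d):
        d["shape"] = d["shape"][1:]
        d["chunks"] = d["chunks"][1:]
    _edit_json(store, join_path(path, "0", cs.ARRAY_META_KEY), fn)


def _m_level_order(store, path):
    def fn(d):
        ds = d["multiscales"][0]["datasets"]
        ds[0]["path"], ds[1]["path"] = ds[1]["path"], ds[0]["path"]
    _edit_attrs(store, path, fn)


def _m_transform_missing(store, path):
    def fn(d):
        d["multiscales"][0]["datasets"][0]["coordinateTransformations"] = []
    _edit_attrs(store, path, fn)


def _m_transform_length(store, path):
    def fn(d):
        tr = d["multiscales"][0]["datasets"][0]["coordinateTransformations"]
        tr[0]["scale"] = tr[0]["scale"][:-1]
    _edit_attrs(store, path, fn)


def _m_scale_order(store, path):
    def fn(d):
        tr = d["multiscales"][0]["datasets"][1]["coordinateTransformations"]
        tr[0]["scale"] = [s * 0.25 for s in tr[0]["scale"]]
    _edit_attrs(store, path, fn)


def _m_label_dtype(store, path):
    def fn(d):
        d["dtype"] = "<f4"
    _edit_json(store, join_path(path, "labels", "blobs", "0",
                                cs.ARRAY_META_KEY), fn)


def _m_label_missing(store, path):
    _edit_attrs(store, join_path(path, "labels"),
                lambda d: d["labels"].append("ghost"))


def _m_unknown_codec(store, path):
    def fn(d):
        d["compressor"] = {"id": "zstd", "level": 3}
    _edit_json(store, join_path(path, "0", cs.ARRAY_META_KEY), fn)


def _m_implicit_fill(store, path):
    store.delete(_first_chunk_key(store, join_path(path, "0")))


def _m_missing_plate(store, path):
    _edit_attrs(store, path, lambda d: d.pop("plate"))


def _m_well_path(store, path):
    def fn(d):
        d["plate"]["wells"].append({"path": "Z/99", "rowIndex": 0,
                                    "columnIndex": 0})
    _edit_attrs(store, path, fn)


def _m_well_missing(store, path):
    first = json.loads(store.get(join_path(path, cs.ATTRS_KEY)))
    wp = first["plate"]["wells"][0]["path"]
    store.delete(join_path(path, wp, cs.ATTRS_KEY))


@dataclass(frozen=True)
class Mutation:
    code: str
    scope: str  # "image" or "plate"
    apply: Callable[[KVStore, str], None]


#: one mutation per registered finding code (errors, plus the
#: warning/info codes) — applied to a clean fixture, each flips its rule
MUTATIONS: Dict[str, Mutation] = {m.code: m for m in [
    Mutation("E_MISSING_MULTISCALES", "image", _m_missing_multiscales),
    Mutation("E_BAD_MULTISCALES", "image", _m_bad_multiscales),
    Mutation("E_AXES_COUNT", "image", _m_axes_count),
    Mutation("E_AXES_TYPE", "image", _m_axes_type),
    Mutation("E_AXES_ORDER", "image", _m_axes_order),
    Mutation("E_DATASET_MISSING", "image", _m_dataset_missing),
    Mutation("E_RANK_MISMATCH", "image", _m_rank_mismatch),
    Mutation("E_LEVEL_ORDER", "image", _m_level_order),
    Mutation("E_TRANSFORM_MISSING", "image", _m_transform_missing),
    Mutation("E_TRANSFORM_LENGTH", "image", _m_transform_length),
    Mutation("E_SCALE_ORDER", "image", _m_scale_order),
    Mutation("E_LABEL_DTYPE", "image", _m_label_dtype),
    Mutation("E_LABEL_MISSING", "image", _m_label_missing),
    Mutation("E_MISSING_PLATE", "plate", _m_missing_plate),
    Mutation("E_WELL_PATH", "plate", _m_well_path),
    Mutation("E_WELL_MISSING", "plate", _m_well_missing),
    Mutation("W_UNKNOWN_CODEC", "image", _m_unknown_codec),
    Mutation("I_IMPLICIT_FILL_CHUNK", "image", _m_implicit_fill),
]}


def apply_mutation(code: str, store: KVStore, path: str) -> None:
    """Apply the registered mutation for ``code`` to the tree at ``path``."""
    MUTATIONS[code].apply(store, path)
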