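"""Chunked N-dimensional array storage in the Zarr v2 on-disk dialect.

Arrays are split into a regular grid of fixed-shape chunks; each chunk is
serialized row-major, passed through an optional codec, and stored as one
object in a flat key-value store. Metadata lives beside the chunks in
small JSON documents (``.zarray`` for array geometry, ``.zgroup`` for
groups, ``.zattrs`` for attributes), so the whole tree is browsable with
ordinary file tools and each chunk is independently addressable — the
property that makes the layout cloud-friendly.

Semantics implemented here:

* zero-based indices, half-open regions, row-major ("C") layout;
* edge chunks are stored full-size, padded with the fill value, and
  readers crop;
* a grid cell with no stored object reads as the fill value
  ("implicit fill"), never as an error;
* region reads touch only the chunks that intersect the request.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .codecs import CodecSpec, codec_is_known, decode_bytes, encode_bytes

__all__ = [
    "ArraySchema",
    "CodecSpec",
    "Region",
    "KVStore",
    "MemoryStore",
    "FileStore",
    "grid_shape",
    "chunk_key",
    "encode_chunk",
    "decode_chunk",
    "write_array",
    "read_region",
    "read_full",
    "read_array_schema",
    "raw_byte_size",
    "init_group",
    "write_attrs",
    "read_attrs",
    "is_array",
    "is_group",
    "join_path",
]

ARRAY_META_KEY = ".zarray"
GROUP_META_KEY = ".zgroup"
ATTRS_KEY = ".zattrs"

# dtype registry: short code -> numpy dtype string as written to .zarray.
# Little-endian throughout; single-byte types carry the "|" byte-order flag.
DTYPES: Dict[str, str] = {
    "u1": "|u1",
    "i1": "|i1",
    "u2": "<u2",
    "i2": "<i2",
    "u4": "<u4",
    "i4": "<i4",
    "f4": "<f4",
    "f8": "<f8",
}
_DTYPE_FROM_WIRE = {v: k for k, v in DTYPES.items()}
# tolerate the explicit little-endian spelling for single-byte types
_DTYPE_FROM_WIRE.update({"<u1": "u1", "<i1": "i1"})

DEFAULT_FILL = 0


def dtype_of(dtype_code: str) -> np.dtype:
    try:
        return np.dtype(DTYPES[dtype_code])
    except KeyError:
        raise ValueError(f"unknown dtype code {dtype_code!r}; "
                         f"supported: {sorted(DTYPES)}") from None


def dtype_code_of(dtype: Union[str, np.dtype]) -> str:
    """The registry code for a numpy dtype; rejects unsupported dtypes."""
    dt = np.dtype(dtype)
    if dt.itemsize > 1:
        dt = dt.newbyteorder("<")
    for code, wire in DTYPES.items():
        if dt == np.dtype(wire):
            return code
    raise ValueError(f"unsupported dtype {dtype!r}; supported codes: {sorted(DTYPES)}")


def join_path(*parts: str) -> str:
    """Join "/"-separated key segments, dropping empty parts."""
    return "/".join(p.strip("/") for p in parts if p.strip("/"))


@dataclass(frozen=True)
class ArraySchema:
    """Shape, chunking, dtype, codec and fill value of one stored array."""

    shape: Tuple[int, ...]
    chunk_shape: Tuple[int, ...]
    dtype_code: str
    codec: Optional[CodecSpec] = None
    fill_value: Union[int, float] = DEFAULT_FILL
    dimension_separator: str = "/"

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "chunk_shape", tuple(int(c) for c in self.chunk_shape))
        if len(self.shape) != len(self.chunk_shape):
            raise ValueError(
                f"rank mismatch: shape has {len(self.shape)} axes, "
                f"chunk_shape has {len(self.chunk_shape)}")
        if any(s < 1 for s in self.shape) or any(c < 1 for c in self.chunk_shape):
            raise ValueError("shape and chunk_shape entries must be >= 1")
        dt = dtype_of(self.dtype_code)  # validates the code
        if self.dimension_separator not in ("/", "."):
            raise ValueError("dimension_separator must be '/' or '.'")
        # fill value must be representable in the dtype (exactly, for integers)
        try:
            cast = np.asarray(self.fill_value, dtype=dt)
            ok = dt.kind == "f" or bool(cast == self.fill_value)
        except (OverflowError, ValueError, TypeError):
            ok = False
        if not ok:
            raise ValueError(f"fill_value {self.fill_value!r} not representable as {self.dtype_code}")

    @property
    def dtype(self) -> np.dtype:
        return dtype_of(self.dtype_code)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def grid(self) -> Tuple[int, ...]:
        return grid_shape(self.shape, self.chunk_shape)

    def to_doc(self) -> Dict[str, object]:
        return {
            "zarr_format": 2,
            "shape": list(self.shape),
            "chunks": list(self.chunk_shape),
            "dtype": DTYPES[self.dtype_code],
            "compressor": self.codec.to_doc() if self.codec is not None else None,
            "fill_value": self.fill_value,
            "order": "C",
            "filters": None,
            "dimension_separator": self.dimension_separator,
        }

    @classmethod
    def from_doc(cls, doc: Mapping[str, object]) -> "ArraySchema":
        if doc.get("zarr_format") != 2:
            raise ValueError(f"unsupported zarr_format {doc.get('zarr_format')!r}")
        wire = str(doc["dtype"])
        if wire not in _DTYPE_FROM_WIRE:
            raise ValueError(f"unsupported dtype {wire!r}")
        if doc.get("order", "C") != "C":
            raise ValueError("only row-major ('C') layout is supported")
        if doc.get("filters") not in (None, []):
            raise ValueError("filters are not supported")
        comp = doc.get("compressor")
        codec = CodecSpec.from_doc(comp) if comp is not None else None
        return cls(
            shape=tuple(doc["shape"]),  # type: ignore[arg-type]
            chunk_shape=tuple(doc["chunks"]),  # type: ignore[arg-type]
            dtype_code=_DTYPE_FROM_WIRE[wire],
            codec=codec,
            fill_value=doc.get("fill_value", DEFAULT_FILL) or 0,
            dimension_separator=str(doc.get("dimension_separator", ".")),
        )


@dataclass(frozen=True)
class Region:
    """A half-open, zero-based axis-aligned box inside an array."""

    origin: Tuple[int, ...]
    extent: Tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(int(o) for o in self.origin))
        object.__setattr__(self, "extent", tuple(int(e) for e in self.extent))
        if len(self.origin) != len(self.extent):
            raise ValueError("origin and extent must have equal rank")
        if any(o < 0 for o in self.origin):
            raise ValueError("origin entries must be non-negative")
        if any(e < 1 for e in self.extent):
            raise ValueError("extent entries must be positive")

    def check_within(self, shape: Sequence[int]) -> None:
        if len(self.origin) != len(shape):
            raise ValueError(f"region rank {len(self.origin)} != array rank {len(shape)}")
        for i, (o, e, s) in enumerate(zip(self.origin, self.extent, shape)):
            if o + e > s:
                raise ValueError(
                    f"region [{o}, {o + e}) exceeds axis {i} of extent {s}")

    @classmethod
    def full(cls, shape: Sequence[int]) -> "Region":
        return cls(origin=(0,) * len(shape), extent=tuple(shape))


# ---------------------------------------------------------------------------
# stores

class KVStore:
    """Flat key-value store contract; keys are "/"-joined path segments."""

    def get(self, key: str) -> bytes:
        raise NotImplementedError

    def put(self, key: str, value: bytes) -> None:
        raise NotImplementedError

    def list(self, prefix: str = "") -> List[str]:
        raise NotImplementedError

    def delete(self, key: str) -> None:
        raise NotImplementedError

    def contains(self, key: str) -> bool:
        try:
            self.get(key)
            return True
        except KeyError:
            return False


class MemoryStore(KVStore):
    """Dictionary-backed store, mainly for tests and scratch work."""

    def __init__(self) -> None:
        self._data: Dict[str, bytes] = {}

    def get(self, key: str) -> bytes:
        try:
            return self._data[key]
        except KeyError:
            raise KeyError(key) from None

    def put(self, key: str, value: bytes) -> None:
        self._data[key] = bytes(value)

    def list(self, prefix: str = "") -> List[str]:
        if prefix and not prefix.endswith("/"):
            prefix = prefix + "/"
        return sorted(k for k in self._data if k.startswith(prefix))

    def delete(self, key: str) -> None:
        try:
            del self._data[key]
        except KeyError:
            raise KeyError(key) from None


class FileStore(KVStore):
    """Store rooted at a directory; keys map to relative file paths.

    This yields exactly the nested-directory layout that generic Zarr v2
    readers understand.
    """

    def __init__(self, root: Union[str, os.PathLike]) -> None:
        self.root = os.fspath(root)
        os.makedirs(self.root, exist_ok=True)

    def _path(self, key: str) -> str:
        if key.startswith("/") or ".." in key.split("/"):
            raise ValueError(f"illegal key {key!r}")
        return os.path.join(self.root, *key.split("/"))

    def get(self, key: str) -> bytes:
        try:
            with open(self._path(key), "rb") as fh:
                return fh.read()
        except (FileNotFoundError, IsADirectoryError):
            raise KeyError(key) from None

    def put(self, key: str, value: bytes) -> None:
        path = self._path(key)
        os.makedirs(os.path.dirname(path), exist_ok=True)
        with open(path, "wb") as fh:
            fh.write(value)

    def list(self, prefix: str = "") -> List[str]:
        base = self._path(prefix) if prefix else self.root
        keys: List[str] = []
        for dirpath, _dirnames, filenames in os.walk(base):
            rel = os.path.relpath(dirpath, self.root)
            for name in filenames:
                key = name if rel == "." else f"{rel.replace(os.sep, '/')}/{name}"
                keys.append(key)
        return sorted(keys)

    def delete(self, key: str) -> None:
        try:
            os.remove(self._path(key))
        except FileNotFoundError:
            raise KeyError(key) from None


# ---------------------------------------------------------------------------
# chunk-grid arithmetic

def grid_shape(shape: Sequence[int], chunk_shape: Sequence[int]) -> Tuple[int, ...]:
    """Number of chunks per axis: the per-axis ceiling of shape / chunk."""
    if len(shape) != len(chunk_shape):
        raise ValueError(f"rank mismatch: {len(shape)} vs {len(chunk_shape)}")
    if any(s < 1 for s in shape) or any(c < 1 for c in chunk_shape):
        raise ValueError("extents must be positive")
    return tuple(-(-int(s) // int(c)) for s, c in zip(shape, chunk_shape))


def chunk_key(array_path: str, grid_index: Sequence[int], separator: str = "/",
              grid: Optional[Sequence[int]] = None) -> str:
    """Store key of one chunk object.

    When ``grid`` is supplied the index is bounds-checked against it.
    """
    if separator not in ("/", "."):
        raise ValueError("separator must be '/' or '.'")
    if any(i < 0 for i in grid_index):
        raise IndexError(f"negative grid index {tuple(grid_index)}")
    if grid is not None:
        if len(grid_index) != len(grid):
            raise IndexError("grid index rank mismatch")
        if any(i >= g for i, g in zip(grid_index, grid)):
            raise IndexError(f"grid index {tuple(grid_index)} outside grid {tuple(grid)}")
    name = separator.join(str(int(i)) for i in grid_index)
    return join_path(array_path, name) if separator == "/" else (
        f"{array_path}/{name}" if array_path else name)


def raw_byte_size(shape: Sequence[int], dtype_code: str) -> int:
    """Uncompressed size in bytes of an array of the given shape and dtype."""
    itemsize = dtype_of(dtype_code).itemsize
    n = 1
    for s in shape:
        n *= int(s)
    return n * itemsize


# ---------------------------------------------------------------------------
# chunk encoding

def encode_chunk(block: np.ndarray, schema: ArraySchema) -> bytes:
    """Serialize one full-size chunk row-major and run it through the codec."""
    if tuple(block.shape) != schema.chunk_shape:
        raise ValueError(f"block shape {block.shape} != chunk shape {schema.chunk_shape}")
    raw = np.ascontiguousarray(block, dtype=schema.dtype).tobytes(order="C")
    return encode_bytes(raw, schema.codec)


def decode_chunk(payload: bytes, schema: ArraySchema) -> np.ndarray:
    """Inverse of :func:`encode_chunk`."""
    raw = decode_bytes(payload, schema.codec)
    expected = raw_byte_size(schema.chunk_shape, schema.dtype_code)
    if len(raw) != expected:
        raise ValueError(f"decoded chunk has {len(raw)} bytes, expected {expected}")
    return np.frombuffer(raw, dtype=schema.dtype).reshape(schema.chunk_shape).copy()


# ---------------------------------------------------------------------------
# array read / write

def _chunk_slices(schema: ArraySchema, idx: Tuple[int, ...]) -> Tuple[slice, ...]:
    return tuple(slice(i * c, min((i + 1) * c, s))
                 for i, c, s in zip(idx, schema.chunk_shape, schema.shape))


def write_array(store: KVStore, path: str, data: np.ndarray,
                schema: ArraySchema) -> ArraySchema:
    """Write a dense array as metadata plus one encoded object per grid cell.

    Edge chunks are padded to the full chunk shape with the fill value.
    """
    data = np.asarray(data)
    if tuple(data.shape) != schema.shape:
        raise ValueError(f"data shape {data.shape} does not match schema shape {schema.shape}")
    if not np.can_cast(data.dtype, schema.dtype, casting="same_kind"):
        raise ValueError(f"cannot store {data.dtype} data as {schema.dtype_code}")
    data = data.astype(schema.dtype, copy=False)
    store.put(join_path(path, ARRAY_META_KEY),
              json.dumps(schema.to_doc(), indent=2, sort_keys=True).encode())
    grid = schema.grid
    for idx in np.ndindex(*grid):
        sel = _chunk_slices(schema, idx)
        src = data[sel]
        if tuple(src.shape) != schema.chunk_shape:
            block = np.full(schema.chunk_shape, schema.fill_value, dtype=schema.dtype)
            block[tuple(slice(0, e) for e in src.shape)] = src
        else:
            block = src
        key = chunk_key(path, idx, schema.dimension_separator, grid)
        store.put(key, encode_chunk(block, schema))
    return schema


def read_array_schema(store: KVStore, path: str) -> ArraySchema:
    try:
        doc = json.loads(store.get(join_path(path, ARRAY_META_KEY)))
    except KeyError:
        raise KeyError(f"no array at {path!r}") from None
    return ArraySchema.from_doc(doc)


def read_region(store: KVStore, path: str, region: Region) -> np.ndarray:
    """Read exactly the requested voxels.

    Only the chunks intersecting the region are fetched; grid cells with no
    stored object contribute the fill value.
    """
    schema = read_array_schema(store, path)
    region.check_within(schema.shape)
    out = np.full(region.extent, schema.fill_value, dtype=schema.dtype)
    grid = schema.grid
    first = tuple(o // c for o, c in zip(region.origin, schema.chunk_shape))
    last = tuple((o + e - 1) // c
                 for o, e, c in zip(region.origin, region.extent, schema.chunk_shape))
    for idx in np.ndindex(*[hi - lo + 1 for lo, hi in zip(first, last)]):
        cell = tuple(lo + i for lo, i in zip(first, idx))
        key = chunk_key(path, cell, schema.dimension_separator, grid)
        try:
            payload = store.get(key)
        except KeyError:
            continue  # implicit fill
        block = decode_chunk(payload, schema)
        # overlap of this chunk with the region, in both coordinate frames
        out_sel, blk_sel = [], []
        for ax, (g, c, o, e) in enumerate(zip(cell, schema.chunk_shape,
                                              region.origin, region.extent)):
            c0 = g * c
            lo = max(c0, o)
            hi = min(c0 + c, o + e, schema.shape[ax])
            out_sel.append(slice(lo - o, hi - o))
            blk_sel.append(slice(lo - c0, hi - c0))
        out[tuple(out_sel)] = block[tuple(blk_sel)]
    return out


def read_full(store: KVStore, path: str) -> np.ndarray:
    """Convenience: read the whole array."""
    schema = read_array_schema(store, path)
    return read_region(store, path, Region.full(schema.shape))


# ---------------------------------------------------------------------------
# groups and attributes

def init_group(store: KVStore, path: str) -> None:
    store.put(join_path(path, GROUP_META_KEY),
              json.dumps({"zarr_format": 2}, indent=2).encode())


def write_attrs(store: KVStore, path: str, attrs: Mapping[str, object]) -> None:
    store.put(join_path(path, ATTRS_KEY),
              json.dumps(attrs, indent=2, sort_keys=True).encode())


def read_attrs(store: KVStore, path: str) -> Dict[str, object]:
    try:
        return json.loads(store.get(join_path(path, ATTRS_KEY)))
    except KeyError:
        return {}


def is_array(store: KVStore, path: str) -> bool:
    return store.contains(join_path(path, ARRAY_META_KEY))


def is_group(store: KVStore, path: str) -> bool:
    return store.contains(join_path(path, GROUP_META_KEY))
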