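"""Conversion of plane-based image sources into multiscale OME-Zarr.

The converter consumes any *plane source*: an object that declares sizes
(T, C, Z, Y, X) and hands out 2D (Y, X) planes indexed by (t, c, z).
This decouples conversion from input formats — a TIFF adapter is
provided, and in-memory arrays satisfy the same contract — in the way
converter tools decouple themselves from the reading library.

Level 0 is written chunk by chunk directly from the source, so the full
image is never resident in memory; pyramid levels are then derived from
a read-back of the previous level (each a factor ``spatial_factor**2``
smaller). Outputs are deterministic: identical source and options yield
byte-identical trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import tifffile

from . import chunk_store as cs
from .chunk_store import ArraySchema, CodecSpec, KVStore, join_path
from .ngff_model import (Axis, Channel, ChannelRendering, ChannelWindow,
                         DatasetEntry, MultiscaleMeta, default_axes,
                         level_scale, multiscales_to_doc)
from .pyramid import (DEFAULT_FACTOR, DEFAULT_MIN_EXTENT, VOLUMETRIC_CHUNKS,
                      downsample_mean, plan_levels, spatial_axis_indices)

__all__ = ["PlaneSource", "ArrayPlaneSource", "TiffPlaneSource",
           "tiff_plane_source", "ConvertOptions", "convert_stack",
           "VOLUMETRIC_CHUNKS"]


class PlaneSource:
    """Contract for ordered suppliers of 2D planes.

    Implementations must set ``sizes`` (T, C, Z, Y, X), ``dtype_code``,
    and implement :meth:`get_plane`. ``physical_pixel_sizes`` optionally
    maps axis names ("t", "z", "y", "x") to (value, unit) pairs;
    ``channel_names`` optionally names each channel.
    """

    sizes: Tuple[int, int, int, int, int]
    dtype_code: str
    physical_pixel_sizes: Optional[Mapping[str, Tuple[float, str]]] = None
    channel_names: Optional[Sequence[str]] = None

    def get_plane(self, t: int, c: int, z: int) -> np.ndarray:
        raise NotImplementedError

    def _check_index(self, t: int, c: int, z: int) -> None:
        T, C, Z, _, _ = self.sizes
        if not (0 <= t < T and 0 <= c < C and 0 <= z < Z):
            raise IndexError(f"plane index {(t, c, z)} outside sizes {(T, C, Z)}")


class ArrayPlaneSource(PlaneSource):
    """Wrap an in-memory array (rank 2–5) as a plane source."""

    def __init__(self, data: np.ndarray,
                 physical_pixel_sizes: Optional[Mapping[str, Tuple[float, str]]] = None,
                 channel_names: Optional[Sequence[str]] = None) -> None:
        data = np.asarray(data)
        if not 2 <= data.ndim <= 5:
            raise ValueError(f"rank {data.ndim} unsupported; need 2-5")
        self._data = data.reshape((1,) * (5 - data.ndim) + data.shape)
        self.sizes = self._data.shape  # type: ignore[assignment]
        self.dtype_code = cs.dtype_code_of(data.dtype)
        self.physical_pixel_sizes = physical_pixel_sizes
        self.channel_names = channel_names

    def get_plane(self, t: int, c: int, z: int) -> np.ndarray:
        self._check_index(t, c, z)
        return self._data[t, c, z]


class TiffPlaneSource(PlaneSource):
    """Plane source over the pages of a (multi-page, grayscale) TIFF.

    ``order`` names the non-spatial dimensions from slowest- to
    fastest-varying across pages (a permutation of a subset of "TCZ");
    dimensions not named have size 1. Sizes for named dimensions come
    from ``sizes``; at most one may be omitted and is inferred from the
    page count.
    """

    def __init__(self, path: str, order: str = "Z",
                 sizes: Optional[Mapping[str, int]] = None) -> None:
        order = order.upper()
        if len(set(order)) != len(order) or any(ch not in "TCZ" for ch in order):
            raise ValueError(f"order must be a permutation of a subset of "
                             f"'TCZ', got {order!r}")
        self._tiff = tifffile.TiffFile(path)
        pages = self._tiff.pages
        n_pages = len(pages)
        shapes = {tuple(p.shape) for p in pages}
        dtypes = {np.dtype(p.dtype) for p in pages}
        if len(shapes) != 1 or any(len(s) != 2 for s in shapes):
            raise ValueError(f"pages must all be 2D of one shape, got {shapes}")
        if len(dtypes) != 1:
            raise ValueError(f"pages must share one dtype, got {dtypes}")
        sizes = dict(sizes or {})
        known = 1
        unknown = [ch for ch in order if ch not in sizes]
        for ch in order:
            if ch in sizes:
                known *= int(sizes[ch])
        if len(unknown) > 1:
            raise ValueError(f"sizes must be given for all but one of {order!r}")
        if unknown:
            if n_pages % known:
                raise ValueError(f"{n_pages} pages not divisible by declared "
                                 f"sizes (product {known})")
            sizes[unknown[0]] = n_pages // known
        total = 1
        for ch in order:
            total *= int(sizes[ch])
        if total != n_pages:
            raise ValueError(f"declared sizes imply {total} pages, file has "
                             f"{n_pages}")
        self._order = order
        self._dim_sizes = {ch: int(sizes.get(ch, 1)) for ch in "TCZ"}
        (y, x) = next(iter(shapes))
        self.sizes = (self._dim_sizes["T"], self._dim_sizes["C"],
                      self._dim_sizes["Z"], y, x)
        self.dtype_code = cs.dtype_code_of(next(iter(dtypes)))
        self.physical_pixel_sizes = None
        self.channel_names = None

    def page_index(self, t: int, c: int, z: int) -> int:
        value = {"T": t, "C": c, "Z": z}
        idx = 0
        for ch in self._order:
            idx = idx * self._dim_sizes[ch] + value[ch]
        return idx

    def get_plane(self, t: int, c: int, z: int) -> np.ndarray:
        self._check_index(t, c, z)
        return np.asarray(self._tiff.pages[self.page_index(t, c, z)].asarray())

    def close(self) -> None:
        self._tiff.close()


def tiff_plane_source(path: str, order: str = "Z",
                      sizes: Optional[Mapping[str, int]] = None
                      ) -> TiffPlaneSource:
    """Open a TIFF file as a :class:`PlaneSource`."""
    return TiffPlaneSource(path, order=order, sizes=sizes)


@dataclass(frozen=True)
class ConvertOptions:
    """Conversion knobs: chunking, pyramid depth, compression."""

    chunk_shape: Union[str, Tuple[int, ...]] = "auto"
    resolution_levels: Union[str, int] = "auto"
    codec: Optional[CodecSpec] = CodecSpec("zlib", {"level": 1})
    min_extent: int = DEFAULT_MIN_EXTENT
    spatial_factor: int = DEFAULT_FACTOR
    dimension_separator: str = "/"
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.chunk_shape != "auto":
            shape = tuple(int(c) for c in self.chunk_shape)
            if len(shape) != 5 or any(c < 1 for c in shape):
                raise ValueError("chunk_shape must be 5 positive extents or 'auto'")
            object.__setattr__(self, "chunk_shape", shape)
        if self.resolution_levels != "auto" and int(self.resolution_levels) < 1:
            raise ValueError("resolution_levels must be >= 1 or 'auto'")


def _auto_chunks(sizes: Tuple[int, int, int, int, int]) -> Tuple[int, ...]:
    _, _, _, y, x = sizes
    return (1, 1, 1, min(y, 1024), min(x, 1024))


def convert_stack(source: PlaneSource, store: KVStore, path: str,
                  options: Optional[ConvertOptions] = None) -> str:
    """Convert a plane source into a validated 5D multiscale image.

    Level 0 reproduces the source planes exactly; further levels are
    local-mean downsampled on y/x per the options.
    """
    options = options or ConvertOptions()
    sizes = tuple(int(s) for s in source.sizes)
    if len(sizes) != 5 or any(s < 1 for s in sizes):
        raise ValueError(f"source sizes must be 5 positive extents, got {sizes}")
    T, C, Z, Y, X = sizes
    dtype = cs.dtype_of(source.dtype_code)
    chunk = _auto_chunks(sizes) if options.chunk_shape == "auto" else options.chunk_shape

    axes = _axes_for(source)
    base_scale = _base_scale_for(source)
    max_levels = (None if options.resolution_levels == "auto"
                  else int(options.resolution_levels))
    plan = plan_levels(sizes, axes, min_extent=options.min_extent,
                       max_levels=max_levels,
                       spatial_factor=options.spatial_factor)

    cs.init_group(store, path)

    # ---- level 0, streamed one chunk at a time from the source
    schema0 = ArraySchema(
        shape=sizes,
        chunk_shape=tuple(min(c, s) for c, s in zip(chunk, sizes)),
        dtype_code=source.dtype_code,
        codec=options.codec,
        dimension_separator=options.dimension_separator)
    apath0 = join_path(path, "0")
    store.put(join_path(apath0, cs.ARRAY_META_KEY),
              _schema_doc_bytes(schema0))
    grid = schema0.grid
    ct, cc, cz, cy, cx = schema0.chunk_shape
    for idx in np.ndindex(*grid):
        block = np.full(schema0.chunk_shape, schema0.fill_value, dtype=dtype)
        t0, c0, z0 = idx[0] * ct, idx[1] * cc, idx[2] * cz
        ys = slice(idx[3] * cy, min((idx[3] + 1) * cy, Y))
        xs = slice(idx[4] * cx, min((idx[4] + 1) * cx, X))
        for dt_ in range(min(ct, T - t0)):
            for dc in range(min(cc, C - c0)):
                for dz in range(min(cz, Z - z0)):
                    plane = np.asarray(
                        source.get_plane(t0 + dt_, c0 + dc, z0 + dz))
                    if plane.shape != (Y, X) or plane.dtype != dtype:
                        raise ValueError(
                            f"plane {(t0 + dt_, c0 + dc, z0 + dz)} has shape "
                            f"{plane.shape} dtype {plane.dtype}; declared "
                            f"({Y}, {X}) {dtype}")
                    tile = plane[ys, xs]
                    block[dt_, dc, dz, :tile.shape[0], :tile.shape[1]] = tile
        store.put(cs.chunk_key(apath0, idx, schema0.dimension_separator, grid),
                  cs.encode_chunk(block, schema0))

    # ---- pyramid levels from read-back of the previous level
    for lvl in range(1, plan.n_levels):
        prev = cs.read_full(store, join_path(path, str(lvl - 1)))
        block = downsample_mean(prev, plan.level_factors(lvl))
        schema = ArraySchema(
            shape=block.shape,
            chunk_shape=tuple(min(c, s) for c, s in zip(chunk, block.shape)),
            dtype_code=source.dtype_code,
            codec=options.codec,
            dimension_separator=options.dimension_separator)
        cs.write_array(store, join_path(path, str(lvl)), block, schema)

    # ---- metadata
    ds_axes = plan.downsampled_axes
    meta = MultiscaleMeta(
        axes=axes,
        datasets=tuple(
            DatasetEntry(path=str(lvl),
                         scale=level_scale(base_scale, lvl,
                                           options.spatial_factor, ds_axes))
            for lvl in range(plan.n_levels)),
        name=options.name,
        downsampling_method=(
            f"local mean, factor {options.spatial_factor} on "
            + ",".join(axes[i].name for i in ds_axes)))
    attrs = multiscales_to_doc(meta)
    rendering = _channel_rendering_for(source)
    if rendering is not None:
        attrs["omero"] = rendering.to_doc()
    cs.write_attrs(store, path, attrs)
    return path


def _schema_doc_bytes(schema: ArraySchema) -> bytes:
    import json
    return json.dumps(schema.to_doc(), indent=2, sort_keys=True).encode()


def _axes_for(source: PlaneSource) -> Tuple[Axis, ...]:
    pps = source.physical_pixel_sizes or {}
    axes = []
    for axis in default_axes(5):
        entry = pps.get(axis.name)
        unit = entry[1] if entry is not None else None
        axes.append(Axis(name=axis.name, type=axis.type, unit=unit))
    return tuple(axes)


def _base_scale_for(source: PlaneSource) -> Tuple[float, ...]:
    pps = source.physical_pixel_sizes or {}
    return tuple(float(pps[name][0]) if name in pps else 1.0
                 for name in ("t", "c", "z", "y", "x"))


def _channel_rendering_for(source: PlaneSource) -> Optional[ChannelRendering]:
    names = source.channel_names
    if not names:
        return None
    lo, hi = _dtype_display_range(cs.dtype_of(source.dtype_code))
    palette = ["FF0000", "00FF00", "0000FF", "FFFF00", "FF00FF", "00FFFF",
               "FFFFFF"]
    return ChannelRendering(channels=tuple(
        Channel(color=palette[i % len(palette)],
                window=ChannelWindow(min=lo, max=hi, start=lo, end=hi),
                label=str(name))
        for i, name in enumerate(names)))


def _dtype_display_range(dtype: np.dtype) -> Tuple[float, float]:
    if dtype.kind in "iu":
        info = np.iinfo(dtype)
        return float(info.min), float(info.max)
    return 0.0, 1.0
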