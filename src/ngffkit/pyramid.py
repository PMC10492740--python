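"""Multiscale pyramid construction.

A pyramid is a series of progressively coarser copies of an image so that
viewers can load a resolution appropriate to the zoom level. Planning
decides the level shapes (repeated ceiling-halving of the downsampled
axes until the largest one fits a typical display tile); building applies
a kind-appropriate reducer per level:

* intensity images — the local arithmetic mean, accumulated in 64-bit
  float and cast back with round-half-to-even;
* label images — the local mode, ties broken toward the smallest label,
  so no level ever contains a label absent from the full resolution.

By default only the two trailing space axes (y, x) are downsampled by a
factor of 2, mirroring the common converter behaviour for planar
acquisitions; isotropic volumes can opt z in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import chunk_store as cs
from .chunk_store import ArraySchema, CodecSpec, KVStore, join_path
from .ngff_model import (Axis, ChannelRendering, DatasetEntry, MultiscaleMeta,
                         default_axes, level_scale, multiscales_to_doc)

DEFAULT_MIN_EXTENT = 256
DEFAULT_FACTOR = 2


@dataclass(frozen=True)
class PyramidPlan:
    """Planned level geometry of one pyramid (level 0 first)."""

    level_shapes: Tuple[Tuple[int, ...], ...]
    spatial_factor: int = DEFAULT_FACTOR
    downsampled_axes: Tuple[int, ...] = ()
    min_extent: int = DEFAULT_MIN_EXTENT
    max_levels: Optional[int] = None

    @property
    def n_levels(self) -> int:
        return len(self.level_shapes)

    def level_factors(self, level: int) -> Tuple[int, ...]:
        """Per-axis reduction factors applied between level-1 and level."""
        ndim = len(self.level_shapes[0])
        return tuple(self.spatial_factor if i in self.downsampled_axes else 1
                     for i in range(ndim))


def spatial_axis_indices(axes: Sequence[Axis], include_z: bool = False) -> Tuple[int, ...]:
    """Positions of the axes to downsample: the trailing two space axes,
    plus any further space axes (e.g. z) when ``include_z`` is set."""
    space = [i for i, a in enumerate(axes) if a.type == "space"]
    if include_z:
        return tuple(space)
    return tuple(space[-2:])


def plan_levels(shape: Sequence[int], axes: Sequence[Axis], *,
                min_extent: int = DEFAULT_MIN_EXTENT,
                max_levels: Optional[int] = None,
                spatial_factor: int = DEFAULT_FACTOR,
                include_z: bool = False) -> PyramidPlan:
    """Plan level shapes by repeated ceiling division of the spatial axes.

    Planning stops once the largest downsampled extent is at most
    ``min_extent`` (or after ``max_levels`` levels); there is always at
    least one level.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != len(axes):
        raise ValueError(f"shape rank {len(shape)} != number of axes {len(axes)}")
    if min_extent < 1:
        raise ValueError("min_extent must be >= 1")
    if spatial_factor < 2:
        raise ValueError("spatial_factor must be >= 2")
    ds = spatial_axis_indices(axes, include_z=include_z)
    shapes: List[Tuple[int, ...]] = [shape]
    while max_levels is None or len(shapes) < max_levels:
        cur = shapes[-1]
        if max(cur[i] for i in ds) <= min_extent:
            break
        nxt = tuple(-(-s // spatial_factor) if i in ds else s
                    for i, s in enumerate(cur))
        shapes.append(nxt)
    return PyramidPlan(level_shapes=tuple(shapes), spatial_factor=spatial_factor,
                       downsampled_axes=ds, min_extent=min_extent,
                       max_levels=max_levels)


def downsample_mean(block: np.ndarray, factors: Sequence[int]) -> np.ndarray:
    """Reduce by the local arithmetic mean with window shape ``factors``.

    Edge windows may be partial; their mean is taken over the elements
    present. Accumulation is in float64; integer outputs are produced by
    round-half-to-even.
    """
    block = np.asarray(block)
    factors = tuple(int(f) for f in factors)
    if len(factors) != block.ndim:
        raise ValueError(f"{len(factors)} factors for rank-{block.ndim} block")
    if any(f < 1 for f in factors):
        raise ValueError("factors must be positive")
    sums = block.astype(np.float64, copy=False)
    counts = np.ones(block.shape, dtype=np.float64)
    for ax, f in enumerate(factors):
        if f == 1:
            continue
        idx = np.arange(0, sums.shape[ax], f)
        sums = np.add.reduceat(sums, idx, axis=ax)
        counts = np.add.reduceat(counts, idx, axis=ax)
    means = sums / counts
    if np.issubdtype(block.dtype, np.integer):
        return np.rint(means).astype(block.dtype)
    return means.astype(block.dtype)


def downsample_mode(block: np.ndarray, factors: Sequence[int]) -> np.ndarray:
    """Reduce an integer (label) block by the local mode.

    The most frequent value in each (possibly partial) window wins; ties
    go to the smallest value, so segmentations stay deterministic.
    """
    block = np.asarray(block)
    if not np.issubdtype(block.dtype, np.integer):
        raise ValueError("label images require integer dtype")
    factors = tuple(int(f) for f in factors)
    if len(factors) != block.ndim:
        raise ValueError(f"{len(factors)} factors for rank-{block.ndim} block")
    if any(f < 1 for f in factors):
        raise ValueError("factors must be positive")
    out_shape = tuple(-(-s // f) for s, f in zip(block.shape, factors))
    out = np.empty(out_shape, dtype=block.dtype)
    for idx in np.ndindex(*out_shape):
        window = block[tuple(slice(i * f, (i + 1) * f)
                             for i, f in zip(idx, factors))]
        vals, counts = np.unique(window, return_counts=True)
        out[idx] = vals[np.argmax(counts)]  # vals sorted -> first max is smallest
    return out


def build_pyramid(data: np.ndarray, axes: Optional[Sequence[Axis]] = None, *,
                  kind: str = "intensity",
                  min_extent: int = DEFAULT_MIN_EXTENT,
                  max_levels: Optional[int] = None,
                  spatial_factor: int = DEFAULT_FACTOR,
                  include_z: bool = False,
                  base_scale: Optional[Sequence[float]] = None,
                  name: Optional[str] = None,
                  ) -> Tuple[List[np.ndarray], MultiscaleMeta]:
    """Compute all pyramid levels plus their multiscale metadata.

    Level 0 is the input unmodified; each further level applies the
    reducer selected by ``kind`` ("intensity" → mean, "label" → mode).
    """
    data = np.asarray(data)
    if axes is None:
        axes = default_axes(data.ndim)
    if len(axes) != data.ndim:
        raise ValueError(f"data rank {data.ndim} != number of axes {len(axes)}")
    if kind not in ("intensity", "label"):
        raise ValueError(f"unknown pyramid kind {kind!r}")
    if kind == "label" and not np.issubdtype(data.dtype, np.integer):
        raise ValueError("label images require integer dtype")
    plan = plan_levels(data.shape, axes, min_extent=min_extent,
                       max_levels=max_levels, spatial_factor=spatial_factor,
                       include_z=include_z)
    reduce = downsample_mean if kind == "intensity" else downsample_mode
    levels = [data]
    for lvl in range(1, plan.n_levels):
        levels.append(reduce(levels[-1], plan.level_factors(lvl)))
    if base_scale is None:
        base_scale = (1.0,) * data.ndim
    ds_names = ",".join(axes[i].name for i in plan.downsampled_axes)
    method = ("local mean" if kind == "intensity" else
              "local mode (smallest-label tie-break)")
    meta = MultiscaleMeta(
        axes=tuple(axes),
        datasets=tuple(
            DatasetEntry(path=str(lvl),
                         scale=level_scale(base_scale, lvl, spatial_factor,
                                           plan.downsampled_axes))
            for lvl in range(plan.n_levels)),
        name=name,
        downsampling_method=f"{method}, factor {spatial_factor} on {ds_names}")
    return levels, meta


def default_chunk_shape(shape: Sequence[int]) -> Tuple[int, ...]:
    """Planar default: one (t, c, z) hyperplane per chunk, y/x tiled at
    up to 1024 pixels."""
    shape = tuple(int(s) for s in shape)
    lead = (1,) * (len(shape) - 2)
    return lead + tuple(min(s, 1024) for s in shape[-2:])


#: chunking recommended for isotropic volumetric data
VOLUMETRIC_CHUNKS = (1, 1, 128, 128, 128)


def write_multiscale_image(store: KVStore, path: str, data: np.ndarray, *,
                           axes: Optional[Sequence[Axis]] = None,
                           kind: str = "intensity",
                           chunk_shape: Optional[Sequence[int]] = None,
                           codec: Optional[CodecSpec] = None,
                           fill_value: float = 0,
                           dimension_separator: str = "/",
                           min_extent: int = DEFAULT_MIN_EXTENT,
                           max_levels: Optional[int] = None,
                           spatial_factor: int = DEFAULT_FACTOR,
                           include_z: bool = False,
                           base_scale: Optional[Sequence[float]] = None,
                           name: Optional[str] = None,
                           channel_rendering: Optional[ChannelRendering] = None,
                           extra_attrs: Optional[dict] = None,
                           ) -> MultiscaleMeta:
    """Write ``data`` as a complete multiscale image group.

    Creates the group, one array per pyramid level (named "0", "1", ...)
    and the "multiscales" attribute block; per-level chunk shapes are the
    requested shape clipped to the level extents.
    """
    data = np.asarray(data)
    dtype_code = cs.dtype_code_of(data.dtype)
    levels, meta = build_pyramid(data, axes, kind=kind, min_extent=min_extent,
                                 max_levels=max_levels,
                                 spatial_factor=spatial_factor,
                                 include_z=include_z, base_scale=base_scale,
                                 name=name)
    if chunk_shape is None:
        chunk_shape = default_chunk_shape(data.shape)
    cs.init_group(store, path)
    for lvl, block in enumerate(levels):
        schema = ArraySchema(
            shape=block.shape,
            chunk_shape=tuple(min(c, s) for c, s in zip(chunk_shape, block.shape)),
            dtype_code=dtype_code,
            codec=codec,
            fill_value=fill_value,
            dimension_separator=dimension_separator)
        cs.write_array(store, join_path(path, str(lvl)), block, schema)
    attrs = multiscales_to_doc(meta)
    if channel_rendering is not None:
        attrs["omero"] = channel_rendering.to_doc()
    if extra_attrs:
        attrs.update(extra_attrs)
    cs.write_attrs(store, path, attrs)
    return meta
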