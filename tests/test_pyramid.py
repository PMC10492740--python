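"""Pyramid planning and the mean/mode downsampling operators."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ngffkit.chunk_store import MemoryStore, read_full
from ngffkit.ngff_model import default_axes
from ngffkit.pyramid import (build_pyramid, downsample_mean, downsample_mode,
                             plan_levels, write_multiscale_image)


# ---------------------------------------------------------------------------
# independent oracles

def naive_mean(block, factors):
    out_shape = tuple(-(-s // f) for s, f in zip(block.shape, factors))
    out = np.empty(out_shape, dtype=np.float64)
    for idx in np.ndindex(*out_shape):
        window = block[tuple(slice(i * f, (i + 1) * f)
                             for i, f in zip(idx, factors))]
        out[idx] = np.mean(window.astype(np.float64))
    if np.issubdtype(block.dtype, np.integer):
        return np.rint(out).astype(block.dtype)
    return out.astype(block.dtype)


def naive_mode(block, factors):
    out_shape = tuple(-(-s // f) for s, f in zip(block.shape, factors))
    out = np.empty(out_shape, dtype=block.dtype)
    for idx in np.ndindex(*out_shape):
        window = block[tuple(slice(i * f, (i + 1) * f)
                             for i, f in zip(idx, factors))].ravel()
        best, best_count = None, -1
        for v in sorted(set(window.tolist())):
            count = int((window == v).sum())
            if count > best_count:
                best, best_count = v, count
        out[idx] = best
    return out


# ---------------------------------------------------------------------------
# planning

def test_plan_halves_until_min_extent():
    plan = plan_levels((1, 1, 1, 2048, 2048), default_axes(5), min_extent=256)
    assert [s[-1] for s in plan.level_shapes] == [2048, 1024, 512, 256]
    assert all(s[:3] == (1, 1, 1) for s in plan.level_shapes)


def test_plan_single_level_when_already_small():
    plan = plan_levels((1, 1, 1, 200, 200), default_axes(5), min_extent=256)
    assert plan.n_levels == 1


def test_plan_ceiling_division():
    plan = plan_levels((1, 1, 1, 5, 5), default_axes(5), min_extent=2)
    assert [s[-1] for s in plan.level_shapes] == [5, 3, 2]


def test_plan_max_levels_cap_and_z_option():
    plan = plan_levels((1, 1, 64, 512, 512), default_axes(5), min_extent=16,
                       max_levels=2)
    assert plan.n_levels == 2
    plan_z = plan_levels((1, 1, 64, 64, 64), default_axes(5), min_extent=16,
                         include_z=True)
    assert plan_z.level_shapes[1][2] == 32  # z halved when opted in
    plan_noz = plan_levels((1, 1, 64, 64, 64), default_axes(5), min_extent=16)
    assert plan_noz.level_shapes[1][2] == 64


def test_plan_rejects_rank_mismatch():
    with pytest.raises(ValueError):
        plan_levels((64, 64), default_axes(3))


def test_extents_never_increase_with_level():
    plan = plan_levels((2, 3, 7, 100, 311), default_axes(5), min_extent=4)
    for prev, cur in itertools.pairwise(plan.level_shapes):
        assert all(c <= p for p, c in zip(prev, cur))


# ---------------------------------------------------------------------------
# mean

def test_mean_of_full_window():
    out = downsample_mean(np.array([[1, 3], [5, 7]], dtype="u2"), (2, 2))
    assert out.tolist() == [[4]]


def test_mean_partial_window_averages_present_elements():
    out = downsample_mean(np.array([1, 2, 3], dtype="u2"), (2,))
    assert out.tolist() == [2, 3]  # mean(1,2)=1.5 -> 2 (half to even), mean(3)=3


def test_mean_rounds_half_to_even():
    out = downsample_mean(np.array([[0, 1], [1, 0]], dtype="u2"), (2, 2))
    assert out.tolist() == [[0]]  # 0.5 rounds to 0, not 1


def test_mean_preserves_constant_blocks():
    block = np.full((4, 6), 9, dtype="i2")
    assert np.array_equal(downsample_mean(block, (2, 3)),
                          np.full((2, 2), 9, dtype="i2"))


def test_mean_rejects_bad_factors():
    with pytest.raises(ValueError):
        downsample_mean(np.zeros((2, 2)), (0, 2))
    with pytest.raises(ValueError):
        downsample_mean(np.zeros((2, 2)), (2,))


# ---------------------------------------------------------------------------
# mode

def test_mode_majority_and_tie_break():
    assert downsample_mode(np.array([[1, 1], [2, 3]]), (2, 2)).tolist() == [[1]]
    assert downsample_mode(np.array([[1, 2], [2, 1]]), (2, 2)).tolist() == [[1]]
    block = np.full((3, 3), 5, dtype="i4")
    assert np.array_equal(downsample_mode(block, (2, 2)),
                          np.full((2, 2), 5, dtype="i4"))


def test_mode_rejects_float_blocks():
    with pytest.raises(ValueError, match="integer"):
        downsample_mode(np.zeros((2, 2), dtype="f4"), (2, 2))


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(0, 2 ** 32 - 1), st.integers(1, 3))
def test_operators_match_naive_oracles(seed, rank):
    rng = np.random.default_rng(seed)
    shape = tuple(int(v) for v in rng.integers(1, 10, rank))
    factors = tuple(int(v) for v in rng.integers(1, 4, rank))
    ints = rng.integers(0, 5, shape).astype("i4")
    floats = rng.random(shape)
    assert np.array_equal(downsample_mean(ints, factors),
                          naive_mean(ints, factors))
    assert np.allclose(downsample_mean(floats, factors),
                       naive_mean(floats, factors))
    assert np.array_equal(downsample_mode(ints, factors),
                          naive_mode(ints, factors))


# ---------------------------------------------------------------------------
# whole pyramids

def test_level_zero_is_input_bit_for_bit():
    rng = np.random.default_rng(1)
    data = rng.integers(0, 1000, (1, 1, 1, 64, 64)).astype("u2")
    levels, meta = build_pyramid(data, min_extent=16)
    assert levels[0] is data or np.array_equal(levels[0], data)
    assert len(levels) == len(meta.datasets) == 3


def test_global_mean_conserved_on_even_extents():
    rng = np.random.default_rng(2)
    data = rng.integers(0, 4096, (1, 1, 1, 64, 128)).astype("f8")
    levels, _ = build_pyramid(data, min_extent=32)
    assert float(levels[1].mean()) == float(levels[0].mean())


def test_label_pyramid_introduces_no_new_values():
    rng = np.random.default_rng(3)
    data = rng.integers(0, 6, (1, 1, 1, 80, 80)).astype("i4")
    levels, meta = build_pyramid(data, kind="label", min_extent=10)
    base = set(np.unique(levels[0]).tolist())
    for lvl in levels[1:]:
        assert set(np.unique(lvl).tolist()) <= base
    assert "mode" in meta.downsampling_method


def test_label_kind_requires_integer_dtype():
    with pytest.raises(ValueError, match="integer"):
        build_pyramid(np.zeros((1, 1, 1, 8, 8), dtype="f4"), kind="label")


def test_metadata_scales_double_per_level():
    data = np.zeros((1, 1, 1, 128, 128), dtype="u1")
    _, meta = build_pyramid(data, min_extent=32, base_scale=(1, 1, 1, 0.5, 0.5))
    assert [d.scale[-1] for d in meta.datasets] == [0.5, 1.0, 2.0]


def test_physical_extent_conserved_across_levels():
    """shape[i] * scale[i] stays within one voxel of the level-0 extent."""
    data = np.zeros((1, 1, 1, 100, 311), dtype="u1")
    levels, meta = build_pyramid(data, min_extent=16)
    for block, ds in zip(levels, meta.datasets):
        for ax in (3, 4):
            phys = block.shape[ax] * ds.scale[ax]
            assert abs(phys - data.shape[ax]) < ds.scale[ax]


def test_write_multiscale_image_reads_back(store):
    rng = np.random.default_rng(4)
    data = rng.integers(0, 255, (2, 48, 48)).astype("u1")
    meta = write_multiscale_image(store, "img", data, min_extent=16)
    assert len(meta.datasets) >= 2
    assert np.array_equal(read_full(store, "img/0"), data)
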