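"""Chunk-grid arithmetic, codecs, and lazy region I/O."""

import json
import zlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ngffkit.chunk_store import (ARRAY_META_KEY, ArraySchema, CodecSpec,
                                 FileStore, MemoryStore, Region, chunk_key,
                                 decode_chunk, dtype_code_of, encode_chunk,
                                 grid_shape, raw_byte_size, read_full,
                                 read_region, write_array, DTYPES)
from ngffkit.codecs import UnknownCodecError


# ---------------------------------------------------------------------------
# grid arithmetic

@pytest.mark.parametrize("shape,chunks,expected", [
    ((10,), (3,), (4,)),
    ((2048, 2048), (1024, 1024), (2, 2)),
    ((24576, 10656, 2048), (128, 128, 128), (192, 84, 16)),
    ((5,), (5,), (1,)),
    ((5,), (7,), (1,)),
])
def test_grid_shape_is_per_axis_ceiling(shape, chunks, expected):
    assert grid_shape(shape, chunks) == expected


@pytest.mark.parametrize("shape,chunks", [
    ((4, 4), (2,)),          # rank mismatch
    ((0,), (1,)),            # non-positive extent
    ((4,), (0,)),            # non-positive chunk
])
def test_grid_shape_rejects_bad_input(shape, chunks):
    with pytest.raises(ValueError):
        grid_shape(shape, chunks)


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.tuples(st.integers(1, 10), st.integers(1, 10)),
                min_size=1, max_size=4))
def test_grid_shape_matches_chunk_origin_enumeration(axes):
    """Brute force: chunks per axis == number of chunk origins 0, c, 2c, ..."""
    shape = tuple(a for a, _ in axes)
    chunks = tuple(c for _, c in axes)
    expected = tuple(len(range(0, s, c)) for s, c in zip(shape, chunks))
    assert grid_shape(shape, chunks) == expected


@pytest.mark.parametrize("path,idx,sep,expected", [
    ("0", (0, 0, 0, 0, 0), ".", "0/0.0.0.0.0"),
    ("labels/nuclei/0", (1, 2), ".", "labels/nuclei/0/1.2"),
    ("0", (3,), "/", "0/3"),
])
def test_chunk_key_layout(path, idx, sep, expected):
    assert chunk_key(path, idx, sep) == expected


def test_chunk_key_bounds_checked_against_grid():
    with pytest.raises(IndexError):
        chunk_key("0", (2, 0), "/", grid=(2, 2))
    with pytest.raises(IndexError):
        chunk_key("0", (-1,), "/")


def test_raw_byte_size_terabyte_tile():
    # one lightsheet tile of 24576 x 10656 x 2048 16-bit voxels is ~1 TB
    assert raw_byte_size((24576, 10656, 2048), "u2") == 1_072_668_082_176
    assert raw_byte_size((1, 1, 128, 128, 128), "u2") == 4_194_304
    assert raw_byte_size((1,), "u1") == 1
    with pytest.raises(ValueError):
        raw_byte_size((4,), "u8")


# ---------------------------------------------------------------------------
# schema and codecs

def test_schema_round_trips_through_zarray_doc():
    schema = ArraySchema(shape=(6, 7), chunk_shape=(4, 4), dtype_code="f4",
                         codec=CodecSpec("zlib", {"level": 3}), fill_value=0,
                         dimension_separator="/")
    doc = schema.to_doc()
    assert doc["zarr_format"] == 2 and doc["dtype"] == "<f4"
    assert ArraySchema.from_doc(doc) == schema


def test_schema_rejects_bad_input():
    with pytest.raises(ValueError):
        ArraySchema(shape=(4, 4), chunk_shape=(2,), dtype_code="u1")
    with pytest.raises(ValueError):
        ArraySchema(shape=(4,), chunk_shape=(2,), dtype_code="u8")
    with pytest.raises(ValueError):
        ArraySchema(shape=(4,), chunk_shape=(2,), dtype_code="u1",
                    fill_value=300)
    with pytest.raises(ValueError):
        ArraySchema(shape=(4,), chunk_shape=(2,), dtype_code="u1",
                    dimension_separator=",")
    with pytest.raises(ValueError):
        ArraySchema.from_doc({"zarr_format": 3, "shape": [4], "chunks": [2],
                              "dtype": "|u1"})


def test_encode_chunk_raw_is_row_major_bytes():
    schema = ArraySchema(shape=(2, 2), chunk_shape=(2, 2), dtype_code="u1")
    block = np.array([[0, 1], [2, 3]], dtype="u1")
    assert encode_chunk(block, schema) == bytes([0, 1, 2, 3])


def test_encode_decode_zlib_round_trip():
    rng = np.random.default_rng(7)
    schema = ArraySchema(shape=(5, 6), chunk_shape=(5, 6), dtype_code="f4",
                         codec=CodecSpec("zlib", {"level": 5}))
    block = rng.random((5, 6), dtype=np.float32)
    assert np.array_equal(decode_chunk(encode_chunk(block, schema), schema),
                          block)


def test_unknown_codec_is_rejected():
    schema = ArraySchema(shape=(2,), chunk_shape=(2,), dtype_code="u1",
                         codec=CodecSpec("lz99"))
    with pytest.raises(UnknownCodecError, match="unknown codec"):
        encode_chunk(np.zeros(2, dtype="u1"), schema)


def test_corrupted_payload_raises():
    schema = ArraySchema(shape=(4,), chunk_shape=(4,), dtype_code="u2",
                         codec=CodecSpec("zlib"))
    with pytest.raises(ValueError, match="decode"):
        decode_chunk(b"not zlib data", schema)


def test_dtype_code_of_native_dtypes():
    assert dtype_code_of(np.dtype("uint16")) == "u2"
    assert dtype_code_of("float64") == "f8"
    with pytest.raises(ValueError):
        dtype_code_of("int64")


# ---------------------------------------------------------------------------
# write / read

@pytest.mark.parametrize("dtype_code", sorted(DTYPES))
def test_write_then_read_is_bit_identical(store, dtype_code):
    rng = np.random.default_rng(11)
    for shape, chunks in [((7,), (3,)), ((5, 6), (2, 4)),
                          ((3, 4, 5), (2, 2, 2)), ((2, 1, 3, 4, 5), (1, 1, 2, 3, 3))]:
        data = (rng.random(shape) * 100).astype(DTYPES[dtype_code])
        schema = ArraySchema(shape=shape, chunk_shape=chunks,
                             dtype_code=dtype_code,
                             codec=CodecSpec("zlib", {"level": 1}))
        path = f"a{len(shape)}"
        write_array(store, path, data, schema)
        assert np.array_equal(read_full(store, path), data)


def test_edge_chunks_padded_with_fill(store):
    schema = ArraySchema(shape=(5,), chunk_shape=(2,), dtype_code="u1",
                         fill_value=9)
    write_array(store, "a", np.arange(5, dtype="u1"), schema)
    keys = [k for k in store.list("a") if not k.endswith(ARRAY_META_KEY)]
    assert len(keys) == 3
    # last chunk is stored full-size; the padding byte is the fill value
    assert store.get("a/2") == bytes([4, 9])


def test_region_read_extracts_exact_voxels(store):
    data = np.array([10, 20, 30, 40], dtype="u2")
    schema = ArraySchema(shape=(4,), chunk_shape=(3,), dtype_code="u2")
    write_array(store, "a", data, schema)
    assert read_region(store, "a", Region((1,), (2,))).tolist() == [20, 30]
    with pytest.raises(ValueError):
        read_region(store, "a", Region((3,), (5,)))


def test_read_unknown_array_raises(store):
    with pytest.raises(KeyError):
        read_region(store, "nope", Region((0,), (1,)))


def test_region_reads_touch_only_intersecting_chunks(counting_store):
    data = np.arange(100, dtype="u2").reshape(10, 10)
    schema = ArraySchema(shape=(10, 10), chunk_shape=(5, 5), dtype_code="u2")
    write_array(counting_store, "a", data, schema)
    counting_store.get_log.clear()
    out = read_region(counting_store, "a", Region((6, 6), (2, 2)))
    assert np.array_equal(out, data[6:8, 6:8])
    chunk_gets = [k for k in counting_store.get_log
                  if not k.endswith(ARRAY_META_KEY)]
    assert chunk_gets == ["a/1/1"]  # exactly the one intersecting chunk


def test_deleted_chunk_reads_as_fill_value(store):
    data = np.ones((4, 4), dtype="u2")
    schema = ArraySchema(shape=(4, 4), chunk_shape=(2, 2), dtype_code="u2",
                         fill_value=7)
    write_array(store, "a", data, schema)
    store.delete("a/0/1")
    out = read_full(store, "a")
    assert np.array_equal(out[:2, 2:], np.full((2, 2), 7, dtype="u2"))
    assert np.array_equal(out[2:, :], np.ones((2, 4), dtype="u2"))


def test_write_array_rejects_rank_and_shape_mismatch(store):
    schema = ArraySchema(shape=(2, 2, 2), chunk_shape=(2, 2, 2), dtype_code="u1")
    with pytest.raises(ValueError):
        write_array(store, "a", np.zeros((2, 2), dtype="u1"), schema)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 2 ** 32 - 1), st.integers(1, 5))
def test_round_trip_random_shapes(seed, rank):
    rng = np.random.default_rng(seed)
    shape = tuple(int(v) for v in rng.integers(1, 9, rank))
    chunks = tuple(int(v) for v in rng.integers(1, 9, rank))
    data = rng.integers(0, 2 ** 15, shape).astype("<i2")
    store = MemoryStore()
    schema = ArraySchema(shape=shape, chunk_shape=chunks, dtype_code="i2",
                         codec=CodecSpec("zlib", {"level": 1}))
    write_array(store, "a", data, schema)
    assert np.array_equal(read_full(store, "a"), data)


# ---------------------------------------------------------------------------
# interop: an independent Zarr v2 reader understands what we write

def test_zarr_python_reads_our_trees(tmp_path):
    zarr = pytest.importorskip("zarr")
    rng = np.random.default_rng(5)
    data = rng.integers(0, 60000, (3, 50, 40)).astype("<u2")
    store = FileStore(tmp_path / "i.zarr")
    for sep, name in [("/", "nested"), (".", "flat")]:
        schema = ArraySchema(shape=data.shape, chunk_shape=(2, 32, 32),
                             dtype_code="u2",
                             codec=CodecSpec("zlib", {"level": 1}),
                             dimension_separator=sep)
        write_array(store, name, data, schema)
        z = zarr.open_array(str(tmp_path / "i.zarr" / name), mode="r")
        assert np.array_equal(np.asarray(z), data)


def test_file_store_round_trip(tmp_path):
    fs = FileStore(tmp_path / "s")
    fs.put("a/b/c", b"payload")
    assert fs.get("a/b/c") == b"payload"
    assert fs.list("a") == ["a/b/c"]
    fs.delete("a/b/c")
    with pytest.raises(KeyError):
        fs.get("a/b/c")
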