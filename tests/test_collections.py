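"""HCS plate layout, montage arithmetic, and label-image storage."""

import numpy as np
import pytest

from ngffkit.chunk_store import MemoryStore, read_attrs, read_full
from ngffkit.collections import (LabelMeta, PlateMeta, montage,
                                 parse_label_meta, parse_plate, parse_well,
                                 well_path, write_labels, write_plate,
                                 write_well)
from ngffkit.synthesize import SplitMix64
from ngffkit.validator import validate_image, validate_plate


def _well_image(seed, shape=(1, 1, 1, 64, 64)):
    rng = np.random.default_rng(seed)
    return rng.integers(0, 4096, shape).astype("u2")


@pytest.mark.parametrize("row,col,expected", [
    ("A", "1", "A/1"),
    ("H", "12", "H/12"),
])
def test_well_path_joins_names(row, col, expected):
    assert well_path(row, col) == expected


@pytest.mark.parametrize("row,col", [("", "1"), ("A", ""), ("A/B", "1")])
def test_well_path_rejects_bad_names(row, col):
    with pytest.raises(ValueError):
        well_path(row, col)


def test_plate_meta_rejects_inconsistencies():
    with pytest.raises(ValueError, match="duplicate"):
        PlateMeta(row_names=("A",), column_names=("1",),
                  wells=(("A/1", 0, 0), ("A/1", 0, 0)))
    with pytest.raises(ValueError, match="out of range"):
        PlateMeta(row_names=("A",), column_names=("1",), wells=(("A/1", 0, 3),))
    with pytest.raises(ValueError, match="implied"):
        PlateMeta(row_names=("A", "B"), column_names=("1",),
                  wells=(("A/1", 1, 0),))


def test_write_plate_layout(store):
    plate = PlateMeta.from_grid(2, 3)
    fields = {w: [_well_image(i)] for i, (w, _, _) in enumerate(plate.wells)}
    write_plate(store, "p", plate, fields, min_extent=16)
    doc = parse_plate(read_attrs(store, "p"))
    assert len(doc.wells) == 6
    for wp, r, c in doc.wells:
        assert wp == well_path(doc.row_names[r], doc.column_names[c])
        well = parse_well(read_attrs(store, f"p/{wp}"))
        assert [i[0] for i in well.images] == ["0"]
    assert validate_plate(store, "p").ok


def test_writing_same_well_twice_errors(store):
    plate = PlateMeta.from_grid(1, 1)
    write_plate(store, "p", plate, {"A/1": [_well_image(0)]}, min_extent=16)
    with pytest.raises(ValueError, match="already"):
        write_well(store, "p", plate, "A/1", [_well_image(1)], min_extent=16)


def test_undeclared_well_rejected(store):
    plate = PlateMeta.from_grid(1, 1)
    with pytest.raises(ValueError, match="not declared"):
        write_plate(store, "p", plate, {"B/9": [_well_image(0)]})


def test_too_many_fields_rejected(store):
    plate = PlateMeta.from_grid(1, 1, field_count=1)
    with pytest.raises(ValueError, match="field_count"):
        write_plate(store, "p", plate,
                    {"A/1": [_well_image(0), _well_image(1)]})


def test_montage_extents_for_full_plate(store):
    plate = PlateMeta.from_grid(2, 3)
    fields = {w: [_well_image(i)] for i, (w, _, _) in enumerate(plate.wells)}
    write_plate(store, "p", plate, fields, min_extent=256)  # single level
    mosaic = montage(store, "p", level=0)
    assert mosaic.shape == (2 * 64, 3 * 64)


def test_montage_missing_well_is_fill(store):
    plate = PlateMeta.from_grid(2, 2)
    fields = {w: [_well_image(i)] for i, (w, _, _) in enumerate(plate.wells)
              if w != "B/2"}
    write_plate(store, "p", plate, fields, min_extent=256)
    mosaic = montage(store, "p", level=0)
    assert mosaic.shape == (128, 128)
    assert not mosaic[64:, 64:].any()  # absent well renders as fill value 0


def test_montage_rejects_absent_level_and_field(store):
    plate = PlateMeta.from_grid(1, 1)
    write_plate(store, "p", plate, {"A/1": [_well_image(0)]}, min_extent=16)
    with pytest.raises(ValueError, match="level"):
        montage(store, "p", level=9)
    with pytest.raises(ValueError, match="field"):
        montage(store, "p", field=5)


def test_montage_randomized_grids_with_missing_wells():
    rng = SplitMix64(2024)
    for _ in range(6):
        rows = int(rng.integers(1, 1, 9)[0])
        cols = int(rng.integers(1, 1, 13)[0])
        store = MemoryStore()
        plate = PlateMeta.from_grid(rows, cols)
        names = [w for w, _, _ in plate.wells]
        keep = [w for w in names
                if rng.floats(1)[0] < 0.7] or [names[0]]
        fields = {w: [_well_image(1, (1, 1, 1, 16, 16))] for w in keep}
        write_plate(store, "p", plate, fields, min_extent=256)
        mosaic = montage(store, "p", level=0)
        assert mosaic.shape == (rows * 16, cols * 16)


def test_labels_written_beside_image(image_fixture):
    store, truth = image_fixture
    attrs = read_attrs(store, "img/labels")
    assert attrs["labels"] == ["blobs"]
    label_attrs = read_attrs(store, "img/labels/blobs")
    assert "image-label" in label_attrs
    meta = parse_label_meta(label_attrs["image-label"])
    assert meta.source == "../../"
    assert len(meta.colors) == len(truth["blobs"])
    mask = read_full(store, "img/labels/blobs/0")
    assert np.array_equal(mask, truth["label_mask"])
    assert validate_image(store, "img").ok


def test_label_colors_round_trip(store):
    labels = np.array([[0, 1], [2, 2]], dtype="i4")
    colors = ((1, (255, 0, 0, 255)), (2, (0, 255, 0, 128)))
    write_labels(store, "img", "nuclei", labels, LabelMeta(colors=colors),
                 min_extent=256)
    back = parse_label_meta(read_attrs(store, "img/labels/nuclei")["image-label"])
    assert back.colors == colors


def test_float_labels_rejected(store):
    with pytest.raises(ValueError, match="integer dtype"):
        write_labels(store, "img", "bad", np.zeros((4, 4), dtype="f4"))


def test_duplicate_label_name_rejected(store):
    labels = np.zeros((4, 4), dtype="i4")
    write_labels(store, "img", "nuclei", labels, min_extent=256)
    with pytest.raises(ValueError, match="already exists"):
        write_labels(store, "img", "nuclei", labels, min_extent=256)


def test_label_meta_invariants():
    with pytest.raises(ValueError, match="duplicate"):
        LabelMeta(colors=((1, (0, 0, 0, 0)), (1, (1, 1, 1, 1))))
    with pytest.raises(ValueError, match="255"):
        LabelMeta(colors=((1, (300, 0, 0, 0)),))
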