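# ngffkit

Read, write, validate and convert **OME-Zarr** (OME-NGFF 0.4) bioimaging
containers — the cloud-optimized, chunked format that stores an imaging
experiment as a browsable directory tree instead of an opaque binary blob.

`ngffkit` is aimed at bioimage-analysis developers and facility engineers
who need to produce or check NGFF trees programmatically: converting plane
stacks, writing segmentations beside their source images, assembling
high-content-screening plates, and verifying that data written by one tool
will be understood by another.

## The data model

An OME-Zarr image is a Zarr v2 group hierarchy:

* **Chunked arrays.** Each image is split into a regular grid of
  N-dimensional chunks; each chunk is serialized row-major, optionally
  compressed (zlib/gzip here, pluggable registry for others) and stored as
  one object. A region read of extent *e* touches only the
  `∏ᵢ ⌈eᵢ/cᵢ⌉`-ish chunks that intersect it; a grid cell with no stored
  object reads as the *fill value*. Chunk counts follow
  `grid = ⌈shape/chunks⌉` per axis — e.g. one 24,576 × 10,656 × 2,048 voxel
  16-bit lightsheet tile (≈ 1 TB raw) decomposes into 192 × 84 × 16 chunks
  of 128³.
* **Axes and pyramids.** Version 0.4 images have 2–5 named axes, ordered
  time → channel → space `(t, c, z, y, x)`. A multiscale image lists
  resolution levels `0, 1, …` (highest first), each with a physical
  `scale` transform; level *l* downsamples y/x by `2ˡ` (local mean for
  intensities, local mode with smallest-label tie-break for label images).
* **Collections.** An HCS plate is a plate → well → field hierarchy in
  which every field is itself a multiscale image; concatenating a low
  resolution level of every well yields the plate montage. Segmentations
  are stored as integer *label images* under `labels/{name}` beside the
  image they annotate.
* **Validation.** A rule engine walks a tree and emits ordered findings
  `(severity, code, path, message)` — errors for layout violations
  (`E_AXES_COUNT`, `E_LEVEL_ORDER`, …), warnings for interoperability
  risks (`W_UNKNOWN_CODEC`), info for benign states
  (`I_IMPLICIT_FILL_CHUNK`). A tree is compliant iff there are no errors.

## Worked example

```python
from ngffkit import (FixtureSpec, MemoryStore, grid_shape, raw_byte_size,
                     summarize, validate_image, write_image_fixture)

store = MemoryStore()
truth = write_image_fixture(store, "img",
                            FixtureSpec(seed=42, shape=(1, 2, 2, 64, 64)))
print("blobs in ground truth:", len(truth["blobs"]))
report = validate_image(store, "img")
print("valid:", report.ok, "| findings:", len(report.findings))
print(summarize(store, "img").format())
print("chunks per axis for one exaSPIM tile:",
      grid_shape((24576, 10656, 2048), (128, 128, 128)))
print("raw bytes:", f"{raw_byte_size((24576, 10656, 2048), 'u2'):,}")
```

prints

```
blobs in ground truth: 4
valid: True | findings: 0
img: 3 resolution level(s), 16,384 voxels, 32,768 raw bytes
  level 0: shape (1, 2, 2, 64, 64), chunks (1, 1, 1, 32, 32) (16/16 stored, 32,768 bytes), dtype u2
  level 1: shape (1, 2, 2, 32, 32), chunks (1, 1, 1, 32, 32) (4/4 stored, 8,192 bytes), dtype u2
  level 2: shape (1, 2, 2, 16, 16), chunks (1, 1, 1, 16, 16) (4/4 stored, 2,048 bytes), dtype u2
chunks per axis for one exaSPIM tile: (192, 84, 16)
raw bytes: 1,072,668,082,176
```

The fixture generator wrote a 5-D, two-channel multiscale image with four
labelled blobs (the segmentation lives at `img/labels/blobs`); the
validator found nothing to complain about; the summary lists the pyramid
geometry and stored chunk statistics. The final two lines show the chunk
and byte arithmetic for a real-world-scale tile — storage is metadata plus
per-chunk objects, so declaring such an array costs only a JSON document.

## Command line

```sh
ngffkit synth image fx.zarr --seed 5          # deterministic test image
ngffkit synth plate plate.zarr --rows 2 --cols 3
ngffkit convert stack.tif out.zarr --order CZ --size C=2
ngffkit validate out.zarr [--json]            # exit 0 iff compliant
ngffkit info out.zarr                         # level-by-level summary
ngffkit montage plate.zarr montage.tif        # whole-plate mosaic
```

Exit codes: 0 success, 1 validation failure, 2 usage error, 3 I/O error.

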