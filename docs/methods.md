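# Methods

This note records how `ngffkit` implements the OME-NGFF 0.4 container
model, the numerical choices involved, what the synthetic fixtures do and
do not emulate, and the design decisions taken where the format leaves
room.

## Storage model

Arrays are stored in the Zarr v2 on-disk dialect: a `.zarray` JSON
document (shape, chunks, dtype, compressor, fill value, row-major order,
dimension separator) plus one object per chunk-grid cell, named by the
joined grid indices. Groups carry `.zgroup`, attributes `.zattrs`. All
JSON is written with sorted keys and no timestamps, so identical inputs
produce byte-identical trees — determinism is treated as a correctness
property, not an accident.

Semantics:

* **Indices** are zero-based; regions are half-open boxes; layout is
  row-major throughout.
* **Edge chunks** are stored full-size, padded with the fill value;
  readers crop. This keeps every chunk object the same decoded byte
  length at the cost of a little storage on the ragged edge.
* **Implicit fill**: a grid cell with no stored object reads as the fill
  value. This makes sparse and metadata-only arrays legal, and deleting a
  chunk is equivalent to resetting it.
* **Laziness**: `read_region` computes the first/last grid cell per axis
  from the region bounds and fetches only that sub-grid. The test suite
  asserts this with an instrumented store that logs every `get`.
* **Dimension separator**: written as `/` (nested directories) by
  default; `.` is accepted on read and on write. The choice is recorded
  in the array metadata, so readers never guess.

Supported dtypes are little-endian `u1 i1 u2 i2 u4 i4 f4 f8`; unknown
codes are rejected when metadata is parsed. Codecs are a pluggable
registry shipping `raw`, `zlib` and `gzip` (stdlib implementations).
Metadata naming other codecs (blosc, zstd, …) still parses; decoding
without a registered implementation fails with a clear error, and the
validator reports it as a warning rather than an error, since other
readers may well support it.

Interoperability is verified in the tests by reading `ngffkit`-written
trees with zarr-python (both separator dialects) and comparing bit for
bit.

## Metadata model

Version 0.4 is implemented and pinned: 2–5 axes, at most one time and one
channel axis, 2–3 space axes, ordered time → channel → space. The rank
ceiling is enforced both in the object model (`default_axes(6)` raises)
and in the validator (`E_AXES_COUNT`); later format revisions relax this,
so the version string matters and unknown versions are rejected on parse.
Each resolution level carries exactly one `scale` transform, optionally
followed by one `translation`; other transform types are rejected. The
optional `omero` channel-rendering block is written when channel
information is available and parsed leniently (malformed channels are
skipped, never fatal).

## Pyramids

Planning halves (ceiling division) the two trailing space axes per level
until the largest downsampled extent is ≤ `min_extent` (default 256,
roughly one display tile) or an explicit level cap is reached; there is
always at least one level. z can be opted in for isotropic volumes;
time and channel axes are never downsampled.

* **Intensity reducer** — window mean accumulated in float64
  (`np.add.reduceat` per axis over sums and counts, so partial edge
  windows average only the elements present), cast back to the input
  dtype by round-half-to-even. With even extents every window is full and
  the global mean is conserved exactly in float arithmetic; the
  acceptance suite asserts exact equality.
* **Label reducer** — window mode with ties broken toward the smallest
  label. This guarantees every level's value set is a subset of level 0.
  The implementation loops over output cells (`np.unique` per window);
  that is O(output × window) and entirely adequate at fixture scale, but
  it is the first thing to vectorize if this package were pointed at
  gigapixel label images.

Both reducers are checked against naive nested-loop oracles on random
blocks. The reducer used is recorded in the multiscale metadata
(`metadata.method`) as provenance, since the format itself does not
prescribe a downsampling operator.

Per-level chunk shapes are the requested chunk shape clipped to the level
extents. The planar default is `(1, 1, 1, min(Y,1024), min(X,1024))`; a
`(1, 1, 128, 128, 128)` volumetric preset is provided, matching the
chunking commonly recommended for lightsheet volumes.

## Conversion

The converter consumes a *plane source* — sizes `(T, C, Z, Y, X)`, a
dtype, and `get_plane(t, c, z) → (Y, X)` — which decouples it from input
formats. A TIFF adapter maps pages to planes via a declared
slowest-to-fastest dimension order (page index
`i = ((t·C_or_1 …)` per the order string), inferring at most one missing
size from the page count and rejecting mixed page shapes. Level 0 is
written chunk by chunk straight from the source, so the full image is
never held in memory; each pyramid level is then computed from a full
read-back of the previous level, which is at most a quarter the size of
its predecessor. Physical pixel sizes become axis units and base scales;
channel names become the rendering block. Plane shape and dtype are
checked against the declared sizes on every read, so a source that lies
fails loudly mid-conversion rather than silently corrupting the output.

## Validation

Validation operates on the raw JSON documents with a deliberately
lenient structural walk — malformed trees produce findings, not
exceptions — while the strict parsers in the object model serve writers.
Severity policy: layout violations are errors; interoperability risks
(unknown codec) are warnings; implicit-fill chunks are info. Rules
short-circuit along their dependencies (an illegal axes list suppresses
rank and transform-length checks against it) so one defect yields one
finding; the tests enforce this with a mutation matrix: for every
registered error code there is a minimal fixture mutation that triggers
exactly that code and nothing else, and everything the package's own
writers produce validates with zero findings. Findings are sorted by
(path, code), making reports deterministic. Plate validation checks the
grid declaration, each well path against the declared row/column names,
well existence, and recursively validates every field image, prefixing
finding paths with their node.

The scale-ordering rule requires per-axis scales to be non-decreasing
with level and flags decreases as errors; the format text is ambiguous
here, and non-decreasing is the reading consistent with levels being
ordered highest-resolution first.

## Synthetic fixtures

Randomness comes from a counter-based SplitMix64 stream specified in
`synthesize.py` (state advances by the 64-bit golden gamma; outputs are
the standard finalizer, checked in the tests against the well-known
reference values for seed 0). No ambient or library RNG is used, so
fixtures are bit-reproducible across platforms and numpy versions.

Three contents are generated: a normalized coordinate gradient
(deterministic, no RNG), uniform noise, and *blobs* — bright spheres on a
dim noisy background, placed on a jittered grid so they never overlap,
each assigned a channel, with a ground-truth record (center, radius,
channel, label id) and a matching integer label mask written as a label
image with per-label colors. Plate fixtures fill an A…/1… grid with
per-well blob images seeded from per-well spawned streams; wells can be
left out to model sparse plates (left out of both the declaration and
the tree, which is the compliant sparse form). Fixture pyramids use
`min_extent=16` so even 64-pixel test images exercise multiple levels,
and default extents stay ≤ 96 pixels and plates ≤ 2×3 so the whole suite
runs in seconds.

What the fixtures deliberately do **not** emulate: optics (no PSF, no
realistic noise model, no illumination gradients), acquisition metadata
beyond the container's needs, or real-data scale. Passing tests therefore
demonstrate container correctness — layout, arithmetic, round-trips,
validation — not fitness of any image-analysis algorithm run on the
pixels.

The mutation helpers live beside the generator because they are fixture
machinery: each applies the minimal edit that flips one validation rule
(drop the multiscale block, append a sixth axis, shorten a scale vector,
re-point a well path, …), and the registry is asserted to cover every
validator code.

## Problem sizes

Tests and the acceptance script run at desk scale by design: arrays up to
rank 5 with extents ≤ a few hundred, plates up to 8×12 wells of 16-pixel
cells for montage arithmetic, and brute-force oracle comparisons on
blocks with extents ≤ 9. Large-scale figures (terabyte tiles) enter only
through size *arithmetic* on declared shapes — which the implicit-fill
semantics make representable without storing a voxel.

## Known limitations

* Zarr v2 only; no v3, sharding, or consolidated metadata.
* Filesystem and in-memory stores only; the `KVStore` contract admits
  remote backends but none is shipped.
* Single-writer; no concurrency control.
* `downsample_mode`'s per-window loop does not scale to very large label
  images.
* Only grayscale TIFF pages are handled by the adapter; proprietary
  microscopy formats are out of scope.
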