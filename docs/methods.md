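# Methods

This note records what each stage of the toolkit actually computes, the
parameters that matter, the assumptions behind the synthetic phantoms, and
the design choices made where several reasonable options existed.

## Data model and grouping

The unit of input is the classic single-frame DICOM file. Files are grouped
by Patient ID (0010,0020) into subjects, by Study Instance UID (0020,000D)
into sessions, and by Series Instance UID (0020,000E) into scans; a file
missing Patient ID or Study Instance UID is excluded with a warning rather
than failing the batch. Grouping output is ordered lexicographically by
identifier, so it is a pure function of the file *set* — shuffling the scan
order cannot change the result.

Volume assembly sorts slices by the projection of Image Position (Patient)
onto the slice normal (the cross product of the row/column direction
cosines), ascending, with Instance Number and then file path as tie-breaks.
Projections are rounded to 1e-4 mm before comparison so float jitter in
vendor headers cannot split a slice position. 4D series are recognized by
repeating slice positions: if every position occurs T times, the series has
T timepoints, ordered by Instance Number within a position. Anything else —
uneven multiplicities, mismatched shapes or pixel spacing, duplicated
positions within a single timepoint — raises a spatial-inconsistency error,
which the diffusion QA path converts into a failed `spatial` check rather
than a crash. The NIfTI affine is built from the direction cosines, pixel
spacing, and the mean slice step; voxel data round-trips bit-identically
for integer pixel types.

## De-identification

The default profile removes 20 header attributes that carry direct
identifiers. Removal means deletion of the attribute: audits can then
assert absence, which is a stronger and more testable property than
emptiness. A `blank` action exists for toolchains that require the
attributes to be structurally present, but it is off by default, and the
conformance audit deliberately counts a present-but-empty protected
attribute as a violation. Patient ID itself is not in the profile — the
archive replaces subject identity with the user-chosen subject label, and
the original ID never reaches the archived copy's hierarchy.

The sharing annotation is serialized into Study Comments (0032,4000) as
`incf:user=<u>;project=<p>;subject=<s>;session=<e>`. The identifier rule
(`[A-Za-z0-9_-]`, length ≤ 64) excludes `;` and `=`, so the format needs no
escaping and parse∘serialize is the identity on valid annotations.
Identifiers are validated before anything is written.

## Archive semantics

Ingest receives one session's files and runs every check — annotation
present, parseable and consistent; user known (or registrable); protected
fields absent; labels valid, non-colliding, and permitted — before writing
a single byte. File placement then goes through a staging directory that is
moved into the hierarchy in one step, and the JSON index is saved last, so
a rejected or crashed ingest leaves the archive exactly as it was, except
for a rejection report in `reports/` naming each offending file and field
(the stand-in for a notification e-mail). Permissions follow a project
ownership model: the creator of a project owns it, and sharing changes or
removal apply to the whole project at once.

QA dispatch gates on scan metadata: structural QA runs only when the Series
Description equals `MPRAGE` (case-insensitive) — a deliberate, documented
string-equality gate rather than a scan-type lexicon, which would chase
real-world naming forever; time-series QA runs for every scan and returns
not-applicable for a single timepoint; diffusion QA returns not-applicable
when no volume carries gradient encoding. An exception inside a QA
procedure marks the record `failed` with a logged traceback and never
corrupts the archive.

## Structural QA

The segmenter is intentionally simple — triage quality on phantoms and
cooperative data, not anatomical fidelity:

1. **Head**: Otsu threshold, two iterations of binary closing, largest
   connected component, hole fill. Morphology runs on an edge-replicated
   pad so a head truncated by the field of view is treated as continuing
   beyond it instead of being eroded away at the boundary.
2. **Brain**: head eroded by `erosion_margin` voxels (default 2).
3. **Tissues**: 3-class 1-D k-means over brain intensities; ascending
   centers map to CSF, gray matter, white matter. Centers initialize evenly
   across the robust (2nd–98th percentile) intensity range. Quantile-based
   initialization was rejected: when one tissue dominates the volume (the
   CSF shell is ~58% of the default phantom's brain), two initial centers
   land in the same class and the fit converges to a split of that class.
4. **Exterior**: complement of the head dilated by `exterior_gap` voxels
   (default 3), leaving a buffer ring that belongs to neither head nor
   exterior so partial-volume rim voxels contaminate neither statistics.

Externally produced masks can be substituted: the statistics functions
accept any mapping of region name to boolean mask.

Region statistics use the population SD (divide by N) and a nearest-rank
definition of the robust 2nd/98th percentiles, both chosen to match the
conventions of the common command-line image-statistics tools; an empty
region yields undefined statistics, not an error. SNR is mean(brain) /
SD(exterior); a zero exterior SD (noiseless phantom) flags SNR undefined
(NaN) rather than raising.

## Time-series QA

The mean-intensity trace is the grand mean per timepoint; the center of
mass is the intensity-weighted centroid in voxel coordinates (mm via the
affine if needed) — voxel units keep step artifacts readable at a glance.
tSNR is temporal mean over raw temporal SD per voxel; SFNR is temporal mean
over the SD of residuals after a 2nd-order polynomial detrend on a time
axis normalized to [−1, 1]. Both use population SDs; since the detrend
basis includes the constant, the residual SD can never exceed the raw SD,
so SFNR ≥ tSNR voxelwise by construction. Voxels with zero raw temporal SD
carry no noise information and are excluded, with the count reported. The
automatic mask takes voxels above 20% of the robust maximum of the
temporal-mean image — deterministic and adequate for phantoms; real brain
data would normally get an explicit mask. Scalars are plain means over the
mask. The detrend order, mask fraction, and minimum timepoint count (5) are
keyword-configurable.

## Diffusion QA

Gradient tables are read per volume from (0018,9087)/(0018,9089); FSL
bval/bvec text import/export is provided. The rule set and defaults:

| check | status on finding | default threshold |
|---|---|---|
| spatial consistency (volumes vs table) | fail | — |
| incomplete gradient table | fail | — |
| non-unit or zero direction at b > 0 | fail | norm tol 0.01 |
| duplicate direction (antipodal folded) | warn | dot tol 1e-6 |
| < 6 unique directions | warn | 6 |
| b outside [100, 10000] s/mm² | warn | — |
| no b=0 volume | warn | — |

Antipodal directions count as duplicates because the diffusion tensor is
symmetric under sign flip. Slice-wise/interlace intensity-artifact
detection is out of scope: only the reportable header/geometry categories
above are checked. Overall verdict is pass exactly when no check failed;
warnings inform but do not fail.

## Synthetic phantoms

The generator is the test bed's ground-truth authority. All randomness
comes from one seeded NumPy generator; UIDs come from a fixed root plus the
seed and a counter; dates are constants — a fixed seed reproduces the tree
byte for byte. Pixels are 16-bit unsigned, explicit VR little endian.

* **Structural** (defaults): 64×64×48 at 1 mm; brain ellipsoid with
  semi-axes (20, 20, 16) voxels holding concentric shells at 0.5/0.75 of
  the brain axes — white 900 innermost, gray 600, CSF 300 — inside a scalp
  shell (450) 2 voxels thicker than the brain; background mean 50 with
  Gaussian noise SD 10 everywhere. The background mean sits 5 SD above
  zero so that clipping to the unsigned pixel range does not bias the
  exterior noise estimate; the 2-voxel head margin matches the segmenter's
  default erosion. True SNR is the noiseless brain mean (≈464, the
  volume-weighted tissue mixture) over the noise SD.
* **Time series**: a signal ellipsoid (mean 1000) over dark background,
  with optional additive linear drift across the series, multiplicative
  whole-volume spikes at scheduled timepoints, and cumulative integer-voxel
  shifts from their scheduled timepoint onward (applied by array roll, so
  shifts are exact in voxel units).
* **Diffusion**: a sphere whose intensity decays mono-exponentially with b
  (D = 1e-3 mm²/s), one volume per gradient-table row; rows may be left
  untagged to fabricate incomplete tables.

What the phantoms do **not** emulate: anatomy, bias fields, partial-volume
mixtures, physiological noise, k-space artifacts, vendor private tags,
compressed or enhanced multiframe DICOM. Passing tests therefore
demonstrate correctness of the statistics and the workflow on data that
satisfies each procedure's stated assumptions — not segmentation or QA
robustness on clinical data.

## Problem sizes and numerics

Tests and the acceptance script run phantoms from 8×8×4 (grouping-only
fixtures) up to 48×48×36 (segmentation and SNR recovery, ~10⁴ exterior
voxels, which puts the sampling error of the noise-SD estimate near 0.7%)
and time series of 24×24×12×200 (~1700 mask voxels). At these sizes the 5%
recovery tolerances sit an order of magnitude above sampling noise, and the
whole suite runs in seconds. Slice-position keys are rounded to 1e-4 mm;
k-means runs at most 100 iterations from its deterministic start;
histograms default to 10 bins over the reference range.

## Known limitations

Only classic single-frame uncompressed DICOM is read. The structural
segmenter assumes a single bright head on a dark background and unimodal
tissue classes. The MPRAGE string gate misses structural scans under other
names (by design, see above). tSNR is implemented as the temporal-SNR
variant; odd–even difference-image SNR is not computed. No pixel-level
de-identification (face removal, burned-in text) is attempted.
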