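# Methods

This note records the conventions, parameters and design choices behind
`tmakit`, in the spirit of a model/methods appendix: what the toolkit
assumes, which knobs matter, what the synthetic data does and does not
emulate, and where the design was genuinely open.

## Data model

A scoring study is organised as study → marker → scorer → slide. A
*slidemap* describes one slide's array: recipient-block geometry (grid
dimensions, core diameter and centre-to-centre spacing in mm, serial
slice number) plus one `CorePosition` per grid cell. Positions are
1-based, x = column, y = row, origin top-left with y increasing downward
(the first core a scorer sees is the top-left one). A position is
`tissue` (carries a donor-block identifier; donor ids may repeat —
replicate cores), `marker` (an orientation core, excluded from scoring)
or `empty` (a gap; `used=false` if and only if empty). Patient identity
is never stored: the donor-block identifier is the only outward link.

Every recorded field is bound to a Common Data Element. A CDE carries a
name, definition, a value domain (enumerated codes, integer or real
range, or free text with an optional pattern), units, and alternative
names. The default registry holds 16 elements: the layout vocabulary
(block/slide/core identifiers, core diameter and spacing, slice number,
x/y coordinates, position-used) and the scoring vocabulary (Allred
intensity/proportion/total, percentage staining, HER2 IHC, binary
staining). Where the TMA DES exchange vocabulary defines an equivalent
tag (`block_identifier`, `block_core_size`, `block_core_spacing`,
`slide_identifier`, `core_histo-repository_donor-block`,
`core_results_percent-tissue-staining`), the tag is recorded as an
alternative name, so lookups by either vocabulary resolve to the same
element. Name lookups are case-sensitive and exact: determinism beats
leniency in a registry that other systems validate against.

Value domains not fixed by the exchange vocabulary follow the standard
published scoring conventions: Allred intensity integer 0–3, proportion
0–5, total 0–8; percentage staining real 0–100; HER2 IHC enumerated
{0, 1+, 2+, 3+}; binary {positive, negative}.

## Scoring

Scoring systems are ordered field lists bound to CDEs, plus optional
derivation rules. Validation is three-layered: field presence (no
unknown, no missing fields), per-field domain membership, then
derivation rules. The Allred rule enforces total = intensity +
proportion together with the coupling constraint (components zero
together or non-zero together), which makes a total of 1 unreachable;
ER classification is negative for totals ≤ 2 and positive for ≥ 3.

Scores are immutable, versioned records. Re-scoring a core appends a
record with the next `record_version` for that (core, scorer, marker);
readers take the maximum version. This keeps a full audit trail while
"latest value" views stay simple. A core with no scorable tumour is
recorded as a `no_tumour` status record carrying no field values, not as
a numeric score. Timestamps are supplied by an injected clock
(`FixedClock` in simulations and tests, `SystemClock` otherwise), so
fixture trees are byte-reproducible.

## Imaging

**Export convention.** Cores export as
`{slide_id}_{x}_{y}_{version}.JPEG`. Parsing is right-anchored — the
last three underscore-separated numeric tokens are version, y, x — so
slide identifiers may contain underscores. "70% resolution" is
interpreted as linear scaling of each axis by 0.70 (round-half-up,
floor 1 px); JPEG quality is an independent knob (default 85). Both are
exposed in config, since dimension scaling and compression quality are
the two plausible readings of an export-resolution setting.

**Deep Zoom.** Pyramids follow the published DZI convention: level
`max_level = ceil(log2(max(w, h)))` is the source image and each lower
level is a ceiling-halved downsample, ending at a 1×1 level 0. Tiles
default to 254 px with 1 px overlap, named `{level}/{col}_{row}.{ext}`
under `{name}_files/`, beside a descriptor XML recording Size, TileSize,
Overlap and Format — bit-compatible with standard Deep Zoom viewers.
Downsampling is a 2×2 box mean with ceiling dimensions; odd edges
average only the pixels present (implemented as edge replication, which
is arithmetically identical), so a flat field stays exactly flat through
every level and the whole chain is checkable against a brute-force
oracle. All pixel work is done on lossless arrays; JPEG encoding happens
only at file boundaries, and equality tests use PNG tiles to avoid
codec noise.

**Synthetic cores.** The generator emulates the geometry of a scanned
core: a centred circular tissue disc (default radius 0.45 of the frame)
in an unstained counterstain tone on a uniform grey background
(default 235), with a controllable fraction of in-disc pixels covered by
stain clusters. Clusters come from thresholding a sum of random Gaussian
blobs at the quantile matching the requested stained fraction, so
staining is spatially clumped like real DAB deposition; stain colour
interpolates from the unstained tone to a DAB brown in proportion to the
0–3 intensity grade. Everything derives from one integer seed. The
generator does **not** emulate nuclei, texture, focus gradients,
scanner colour profiles or segmentation artefacts — passing tests show
the pipeline's bookkeeping, geometry and determinism are right on
realistic *shapes and sizes* of data, not that any staining
quantification would work on real tissue (the toolkit performs none;
scoring is manual by design).

## Store and exchange

The study store is a plain directory tree of XML documents —
`{study}/{marker}/{scorer}/{slide_id}.xml`, with canonical slidemaps
under `{study}/{marker}/_slidemaps/` — rather than an embedded XML
database: the collection semantics survive, and every state change is a
diffable file write with no hidden state (close/reopen is byte-exact).
A scorer's slide document stores a *reference* to the canonical slidemap
plus its SHA-256 checksum, so a layout edited after scoring began is
detectable. Permissions are advisory (scorer, study, marker) grants
enforced by the API; authentication and transport security are
deployment concerns, out of scope.

TMA DES export writes fields with an exchange equivalent under the DES
tag and everything else (coordinates, position-used, slice number,
grid dimensions, Allred components, HER2, binary, score metadata) as
extension elements under the project namespace (prefix `cg`). Per-core
x/y extension elements are emitted rather than any packed array-hash
representation: explicit coordinates are self-describing and
independently parseable. The generic 0–3 intensity field maps to
`core_results_tissue-intensity` (the exchange vocabulary's general
staining-intensity value); Allred components are deliberately *not*
collapsed onto it, since they are a specific scoring system, and travel
as extensions instead. The header is minimal — origin, ISO-8601 date,
generator string with the toolkit version. On import, unrecognised
vendor elements are preserved as opaque annotations and logged, and a
core without coordinates is kept as an unplaced donor reference rather
than rejected; only a missing slide identifier is fatal.

## Heatmaps

One cell per grid position, `cell_px` square (default 24, minimum 4).
The discrete 0–3 legend is pale yellow (255,255,204), intense yellow
(255,215,0), pale blue (173,216,230), intense blue (0,0,205); marker
cores grey (128,128,128), no-tumour pink (255,192,203), unscored white;
the current position is outlined in black. The deployed system's exact
hues are not recoverable, so these are this project's concrete choices
for the colour-class names, overridable via config. Systems outside the
discrete map (Allred total 0–8, percentage 0–100) interpolate linearly
between the pale-yellow and intense-blue endpoints. Scorer comparison
uses the intersection rule — a cell is compared only when both scorers
scored it — on latest-version values, with a no-tumour call treated as
a comparable value.

## Simulation defaults and problem sizes

The simulator's defaults describe a small but structurally complete
study: a 3×3 grid, two markers (ER, PR) sharing one layout (as serial
sections of one block would), one scorer, no gaps or marker cores unless
requested, 64 px cores, every tissue core scored under the 0–3 intensity
system. The test suite and the acceptance script deliberately run at
compact sizes — grids up to 5×5, images up to ~60 px for pixel-exact
pyramid oracles, 300×300 for the geometry sweep, 200 randomized cases
per round-trip family — chosen so the full suite re-runs in seconds
while still exercising every code path and edge case (1×1 images, tile
size 1, odd dimensions, underscored identifiers, replicate donors).

## Known limitations

- No whole-slide de-arraying, automated staining quantification, or
  viewer UI; the toolkit prepares, stores and exchanges data for manual
  scoring.
- Inter-rater agreement is reported as discrepancy counts only; no
  chance-corrected statistics.
- The registry XML dialect is a minimal ISO/IEC 11179-flavoured format
  defined by this project, not the full metamodel; the slidemap XML
  dialect is likewise project-defined (vendor slidemap schemas are
  proprietary), annotated with CDE/DES names for interoperability.
- TMA DES documents are not validated against the official DTD; the
  writer guarantees only that every element is either a known DES tag or
  namespaced as an extension.
- The store is single-process; concurrent multi-user semantics are out
  of scope.
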