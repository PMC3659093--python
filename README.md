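# tmakit

A metadata-aware toolkit for tissue-microarray (TMA) scoring pipelines.

Tissue microarrays pack hundreds of cylindrical tissue cores, punched from
donor blocks, into a single recipient block; slides sectioned from it are
stained by immunohistochemistry (IHC) and each core is scored for a
biomarker. Running such studies across laboratories raises three recurring
engineering problems that `tmakit` addresses for pathology informatics
groups:

1. **Tracking** — every score at grid position (x, y) must trace back to a
   donor tissue block (and hence a patient, whose identity is *not* stored
   here). Array layouts arrive as spreadsheets; `tmakit` turns them into
   slidemap XML and keeps the linkage through to export.
2. **Standardised capture** — every recorded field is governed by a
   Common Data Element (CDE): a registered definition with a value domain
   that constrains input. The built-in registry ships 16 TMA CDEs covering
   layout geometry and the common IHC scoring systems, with the
   TMA Data Exchange Specification (TMA DES) tag names recorded as
   alternative names for interoperability.
3. **Review at scale** — per-core JPEGs are renamed
   `slideID_x_y_version.JPEG`, exported at 70% resolution, and converted
   into Deep Zoom (DZI) pyramids for smooth zoom/pan viewing; score
   heatmaps, virtual-slide montages and inter-scorer discrepancy reports
   support navigation, training and quality assurance.

The scoring model includes the Allred system for oestrogen-receptor (ER)
status: an intensity component *I* ∈ {0..3} and a proportion component
*P* ∈ {0..5}, coupled so that *I* = 0 ⇔ *P* = 0, with total
*T* = *I* + *P* ∈ {0} ∪ [2, 8] and ER-positive defined as *T* ≥ 3
(totals 2 and 3 are the borderline grades).

## Worked example

```bash
# a deterministic synthetic study: 3x3 grid, two markers, one scorer
tmakit simulate --store store --images images --seed 42
# -> simulated 2 slides, 18 images, 18 scores

tmakit build-pyramids images pyramids --tile-size 64 --manifest manifest.json
# -> converted 18 images

tmakit heatmap --store store --study SIM --marker ER \
    --scorer path1 --slide-id SIM-ER-1 -o heatmap.png --current 2 2
# -> wrote heatmap.png

tmakit export --store store --study SIM --marker ER -o scores.csv
# -> exported 9 rows
```

The exported table starts:

```
study,marker,scorer,slide_id,x,y,donor_block_id,status,intensity,timestamp
SIM,ER,path1,SIM-ER-1,1,1,DB001,scored,2,2013-05-01T09:00:00+00:00
SIM,ER,path1,SIM-ER-1,2,1,DB002,scored,0,2013-05-01T09:01:00+00:00
```

Each row is one core's latest score: position (x, y) on slide `SIM-ER-1`,
the donor block (`DB001`) it was punched from — the identifier that links
the score back to the source tissue — and the recorded 0–3 staining
intensity. `tmakit export --format tmades` writes the same collection as a
TMA DES XML document, and `tmakit query-donor DB001 --store store` lists
every core from that donor block across markers.

The same operations are available as a library (`tmakit.registry`,
`tmakit.slidemap`, `tmakit.imaging`, `tmakit.scoring`, `tmakit.heatmap`,
`tmakit.store`, `tmakit.tmades`, `tmakit.simulate`); see `docs/methods.md`
for the underlying conventions and design choices.

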