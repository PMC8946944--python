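# pimoquant

Spatial quantification of tumor hypoxia from immunofluorescence sections.

Solid tumors contain pockets of hypoxia that drive therapy resistance and
metastasis. The extrinsic probe pimonidazole (PIMO) marks acutely hypoxic
tissue, and endogenous proteins — the glucose transporters GLUT1 and GLUT3
and carbonic anhydrase IX (CA9) — are candidate stand-in biomarkers.
`pimoquant` implements the image-analysis side of evaluating such markers:

* **Xenograft mode (zonal colocalization).** PIMO-positive regions are
  segmented with a fixed per-tumor threshold, then expanded into concentric
  distance bands ("donuts", >0–15 µm and >15–30 µm by default). For a marker
  channel *M* and zone *z* the statistic is the fold change

  *F(z) = mean(M | z) / mean(M | background)*,

  where the background is tumor tissue >30 µm from any PIMO signal. *F* = 1
  means no enrichment; a decaying *F* across seed → rings reveals the radial
  gradient hypoxia markers form around hypoxic pockets.

* **PDX mode (percent-positive area).** For serially sectioned
  patient-derived xenografts stained with different antibodies (e.g. GLUT3
  vs. a GLUT1/GLUT3/CA9 triple cocktail), the tumor mask comes from
  E-cadherin, the stain threshold is fixed on a designated anchor section
  and reused on the others, and each stain is scored as
  100 · |stain ∩ tumor| / |tumor| with pairwise anchor/single ratios.

* **DE summaries.** Per-timepoint hypoxia-vs-normoxia differential
  expression tables are collapsed into averaged volcano coordinates
  (mean log2FC, mean −log10 Padj), a strict all-contrasts heatmap gene
  selection within a hypoxia gene set, a signed average-rank metric for
  pre-ranked enrichment analysis, and row mean-centered expression matrices.

Everything shares a calibrated mask toolkit (empirical-but-recorded
threshold policies, 8-connected components, a >30 µm minimum-size filter,
exact micron-valued dilation via distance transforms, red-blood-cell
autofluorescence exclusion) and a seeded synthetic-data generator that
provides ground truth for every stage.

## Worked example

Generate a synthetic section (512×512 px at 1 µm/px, three irregular
hypoxic pockets, 10% additive noise) and run the full xenograft recipe:

```python
from pimoquant import synth, masking, zonal
from pimoquant.types import ThresholdPolicy

spec = synth.SectionSpec(seed=0)
channels, truth = synth.generate_section(spec)

tissue = masking.tissue_mask(channels["nuclear"], ThresholdPolicy("fixed", 50), erosion_px=10)
rbc    = masking.rbc_mask(channels["nuclear"], ThresholdPolicy("fixed", 600), tissue)
seed   = masking.pimo_seed_mask(channels["pimo"], 400, tissue, rbc)
zones  = zonal.build_zones(seed, tissue, rbc)
stats  = zonal.zone_stats(channels["marker"], zones)

for zone in ("seed", "ring1", "ring2", "background"):
    print(f"{zone:10s} pixels {stats.pixel_counts[zone]:6d}   "
          f"fold {stats.fold_change[zone]:.3f}   true {truth.true_zone_fold[zone]:.3f}")
```

prints

```
seed       pixels   9847   fold 3.000   true 3.000
ring1      pixels  11113   fold 2.122   true 2.126
ring2      pixels  15326   fold 1.409   true 1.416
background pixels 185837   fold 1.000   true 1.000
```

The marker is 3-fold enriched inside PIMO-positive tissue, decaying through
the two annuli to the background level, and the estimates track the
generator's recorded truth to well under a percent despite the noise.
The same analysis is available from the shell:

```sh
pimoquant simulate section --seed 0 --out run/sim
pimoquant xenograft --config xenograft.yaml --images run/sim --out run/zones
pimoquant volume 10 20        # caliper tumor volume (width² × length / 2)
```

Each run writes CSV/TSV tables plus a JSON provenance record containing
every threshold actually applied, so results re-run bit-identically.

## Layout

| Module | Contents |
| --- | --- |
| `pimoquant.synth` | seeded section / serial-section / DE-table generators with ground truth |
| `pimoquant.masking` | threshold policies, tissue / RBC / marker / PIMO-seed masks, size filter |
| `pimoquant.zonal` | tiling, distance-band zones, fold-change statistics, field summaries |
| `pimoquant.area` | E-cadherin tumor masks, anchored thresholds, percent-positive area, panel ratios |
| `pimoquant.desummary` | BH adjustment, averaged volcano, heatmap selection, signed rank metric |
| `pimoquant.io` | multipage TIFF + YAML sidecars, PNG masks, provenance JSON |
| `pimoquant.cli` | `simulate`, `xenograft`, `pdx`, `desummary`, `volume` subcommands |

See `docs/methods.md` for the model details, parameter defaults, and known
limitations.
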