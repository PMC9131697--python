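# issmap

Probabilistic cell typing and spatial statistics for targeted **in situ
sequencing (ISS)** maps of the oligodendrocyte lineage — with a
synthetic-tissue generator so the whole pipeline can be validated against
known ground truth without any imaging data.

ISS decodes barcoded padlock-probe amplicons in tissue sections, yielding a
table of transcripts (gene symbol + x/y in μm) for a targeted panel — here
124 marker genes covering 13 reference populations of the oligodendrocyte
lineage (OPC, COP, NFOL1/2, MFOL1/2, MOL1–6, VLMC). `issmap` takes decoded
spots, segmented cells, reference expression profiles and region polygons,
and produces everything a spatial mapping study reports: per-cell type
posteriors and winner-takes-all calls, abundances and densities per region,
kernel-density tissue maps, cortical depth profiles, and nearest-neighbor /
neighborhood-enrichment statistics. It is aimed at analysts working with
pciSeq-style targeted spatial transcriptomics who want the downstream
statistics as a reusable, tested library.

## The model in brief

Spots are assigned to the nearest segmented cell within a radius (default
15 μm, else background). For cell *c* with gene counts *n<sub>cg</sub>*
(total *N<sub>c</sub>*), the posterior over types *k* is

> P(k | n<sub>c</sub>) ∝ π(k) · ∏<sub>g</sub> Poisson(n<sub>cg</sub> ;
> N<sub>c</sub> · q<sub>gk</sub>)

with q<sub>gk</sub> the pseudocounted, per-type-normalized reference
profile, so cells are typed by transcript *composition*. Cells are called
winner-takes-all and gated on a pan-lineage marker (*Plp1*). Abundance
changes between conditions use `ratio = 100 − 100/(X/Y)` with *X* the
larger condition (30 vs 10 → 66.66%), compared across samples by one-way
ANOVA with Tukey's HSD. Neighborhoods come from the Delaunay triangulation
(dual of the Voronoi tessellation), which contains every cell's true
nearest neighbor; enrichment of type pairs is tested by permuting labels
over fixed positions. See `docs/methods.md` for the full account.

## Worked example

```python
import issmap as im

# a simulated adult coronal section: cortex (GM) over corpus callosum (WM)
tissue, profiles = im.preset_tissue("p60", seed=1, scale=1000.0)
assignment, counts = im.assign_spots_to_cells(
    tissue.spots, tissue.cells, max_radius=15.0, gene_ids=profiles.gene_ids)
posterior = im.compute_type_posteriors(counts, profiles)
typing = im.TypingResult(counts, posterior, assignment)
called = im.call_cells(typing, tissue.cells, pan_marker="Plp1")
print(f"cells: {len(tissue.cells)}  spots: {len(tissue.spots)}  "
      f"retained (Plp1+): {len(called)}")

merged = called.merge(tissue.cells[["cell_id", "true_type"]], on="cell_id")
acc = (merged.called_type == merged.true_type).mean()
print(f"typing accuracy vs ground truth: {100 * acc:.1f}%")

table = im.abundance_table({"sec1": called}, tissue.layout)
print(table[table.region == "CC"].nlargest(3, "fraction")
      [["type", "count", "density", "fraction"]].to_string(index=False))

graph = im.build_graph(called[called.region == "CC"])
print(f"CC mean nearest-neighbor distance: {graph.nn_dist.mean():.1f} um")
print("change_ratio(30, 10) =", f"{im.change_ratio(30, 10):.2f}%")
```

prints

```
cells: 715  spots: 12934  retained (Plp1+): 708
typing accuracy vs ground truth: 99.3%
type  count    density  fraction
MOL5    106 176.666667 28.804348
MOL6     47  78.333333 12.771739
 OPC     43  71.666667 11.684783
CC mean nearest-neighbor distance: 21.0 um
change_ratio(30, 10) = 66.67%
```

The section carries ~17 transcripts per cell; 708 of 715 cells pass the
*Plp1* gate and 99.3% of them are called as their simulated ground-truth
type. In the white-matter band the recovered density (~590 cells/mm²
summed over types; 176.7 for MOL5 alone, the dominant adult population)
and the ~21 μm nearest-neighbor spacing land in the regime reported for
the adult corpus callosum, and the change-ratio arithmetic reproduces the
standard worked example. The same analysis runs from the shell:

```sh
issmap run-all --preset p60 --seed 1 --outdir out/
```

writing spots/cells/profiles/regions, typing tables, `abundance.csv` +
`changes.csv`, density rasters with PNG heatmaps, neighborhood tables, and
a `manifest.json` with per-stage timings and row counts.

## Layout

```
src/issmap/
  profiles.py          reference panels (genes x types, pan marker)
  regions.py           region polygons, compartments, depth axes, GeoJSON
  simulate.py          synthetic tissue generator and age presets
  celltyping.py        spot assignment, posteriors, calls, pie charts
  abundance.py         counts, densities, fractions, change ratios, ANOVA+Tukey
  density_profiles.py  KDE maps, depth profiles, area occurrences
  neighborhood.py      Delaunay/Voronoi graphs, NN stats, enrichment test
  cli.py               `issmap` command-line interface
docs/methods.md        model, assumptions, parameter choices, limitations
```
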