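# immunogradient

Spatial analytics for the tumor–stroma interface in segmented tissue
images, and the survival statistics built on top of them.

In digital pathology, whole-slide images of immunohistochemically stained
tumor sections are segmented into tissue classes (tumor, stroma, lymphoid
follicles, background) and immune cells (CD8+ cytotoxic T cells, CD20+
B cells, CD68+ macrophages) are detected as point coordinates. How those
immune cells distribute *across the tumor–stroma boundary* — whether their
density rises toward the tumor or stalls in the stroma — carries prognostic
information that plain cell counts miss. This package implements the
hexagonal-grid interface-zone methodology that quantifies this gradient,
and the cohort statistics that turn it into prognostic scores.

## Method

1. **Hexagonal tiling.** The tissue-class raster is subsampled by a
   hexagonal lattice (default side 65 µm). Each hexagon gets per-class
   tissue areas (by pixel counting) and per-marker cell counts.
2. **Tumor edge and ranks.** Hexagons are classified tumor / stroma /
   background by area fractions; the tumor edge (TE) is the set of
   mixed-content hexagons plus tumor hexagons touching stroma. Every tissue
   hexagon receives a signed rank: the hexagon-lattice distance to the
   nearest TE hexagon, positive on the tumor side, negative on the stromal
   side, 0 on the TE. An interface zone of width *w* is the band with
   |rank| ≤ (w−1)/2; width 3 (IZ₃, ranks −1/0/+1 = stroma aspect S, TE,
   tumor aspect T) is the default.
3. **Immunogradient indicators.** With q(r) the mean cell density
   (cells/mm² of analyzed tissue) over hexagons of rank r, the Center of
   Mass

       CM = Σᵣ r·q(r) / Σᵣ q(r)

   locates which side the density gravitates towards (CM > 0: toward the
   tumor). Per case and marker the package reports CM, the aspect
   densities d_S, d_TE, d_T, and the pooled intratumoral density INT —
   15 indicators per case.
4. **Cohort statistics and scores.** Optimal log-rank cutoffs dichotomize
   CM for CD8 and CD20; the two binary strata sum to the CD8–CD20
   Immunogradient score (0–2), and adding the binary tumor growth pattern
   (pushing = favorable) yields the immuno-interface score, IIS (0–3).
   Fisher's exact association tests, log-transformed ANOVA/Welch
   comparisons, Kaplan–Meier / log-rank stratification, Cox proportional
   hazards with stepwise likelihood-ratio selection, and leave-one-out
   cross-validation are provided for the downstream analysis.

A synthetic-data module generates label rasters (tumor blobs with smooth or
fingered margins), inhomogeneous-Poisson cell patterns with configurable
density gradients λ(d) = a·exp(b·d) across the boundary, and survival
cohorts under proportional hazards tied to the true strata — so the whole
pipeline is testable end to end without patient data.

## Worked example

```python
from immunogradient import (SimConfig, PipelineConfig, simulate_tissue_map,
                            simulate_cells, compute_indicator_set)

cfg = SimConfig(seed=1)                      # 3.2 x 3.2 mm slide, 4 um/px
tissue, boundary = simulate_tissue_map(cfg)  # pushing-margin tumor blob
cells = simulate_cells(tissue, cfg)          # inhomogeneous Poisson cells
print(f"tumor area: {tissue.class_area_mm2(1):.2f} mm2, cells: {len(cells)}")

result = compute_indicator_set(tissue, cells, PipelineConfig())
print(f"QC: {result.qc_pass} ({result.qc_reason})")
for marker in ("CD8", "CD20", "CD68"):
    cm = result.indicators[f"{marker}_CM"]
    d_s = result.indicators[f"{marker}_d_S"]
    d_t = result.indicators[f"{marker}_d_T"]
    intd = result.indicators[f"INT_{marker}"]
    print(f"{marker:5s} CM={cm:+.3f}  d_S={d_s:6.1f}  d_T={d_t:6.1f}  INT={intd:6.1f} cells/mm2")
```

prints

```
tumor area: 5.31 mm2, cells: 4213
QC: True (tumor area 5.310 mm2 >= 4.5 mm2)
CD8   CM=-0.254  d_S= 238.1  d_T= 114.4  INT=  65.9 cells/mm2
CD20  CM=-0.541  d_S=  67.7  d_T=   8.6  INT=   9.6 cells/mm2
CD68  CM=-0.254  d_S= 236.1  d_T= 111.8  INT=  71.0 cells/mm2
```

The slide passes the 4.5 mm² tumor-area QC. All three markers have CM < 0:
their densities are highest in the stroma aspect (d_S) and fall toward the
tumor aspect (d_T), with CD20 showing the steepest drop — exactly the
configured simulation gradients. INT is each marker's pooled density over
all tumor tissue.

There is also a CLI (`immunogradient simulate / case / cohort`) that writes
per-case hexagon tables, ranked grids, indicator rows, QC reports and
cohort-level statistics to CSV/JSON.

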