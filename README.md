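# metquant

Quantification pipeline for fluorescence-microscopy studies of **macrophage
extracellular traps (METs)** — webs of DNA, histones and granule proteins
(MPO) that macrophages can release while remaining alive ("vital METosis")
or during pyroptotic death.

The package re-implements, as tested reusable code, the image-analysis chain
such studies rely on:

* **Nuclear counting** — watershed particle analysis of the Hoechst 33342
  channel; the count is the per-cell denominator for every percentage.
* **Condensation gating** — apoptotic nuclei gated as high-MFI / low-area
  outliers on the (area, mean fluorescence intensity) plane.
* **MET scoring** — CitH3 signal with nuclear regions blacked out,
  thresholded, particle-counted, and merged by repeated binary dilation
  (3 × radius-1 disk by default) so a fragmented trap counts once:
  `percent = 100 · n_MET / n_nuclei`, fold change against a control percent.
* **Cytoplasmic DNA puncta** — per-cell detection on a DNA channel with the
  nuclear mask excluded, cell boundaries from MPO staining, and staining
  classification into the nested combination classes
  H → H+S → H+S+M → H+S+M+C (Hoechst, SYTOX, MPO, CitH3).
* **Cytoplasm-restricted Manders colocalization** —
  `M1 = Σ DNA_i [DNA_i > t_d ∧ prot_i > t_p] / Σ DNA_i [DNA_i > t_d]`
  over non-nuclear pixels only (single direction: control cells have no
  cytoplasmic DNA, so the reverse coefficient is undefined there).
* **Quadrant polarity** — puncta counted per 90° sector of a circle on the
  nucleus, sector 1 oriented toward the MET release site; paired t-tests of
  sector 1 versus the others.
* **Death kinetics** — per-frame SYTOX-positive counts normalized to the
  frame-0 Hoechst nucleus count, with plateau level and onset estimation.
* **Statistics** — Student t / one-way ANOVA + Tukey HSD, star notation,
  and normal QQ diagnostics.

Because raw microscope data for such experiments are rarely deposited, the
package ships a **synthetic-field generator** (`metquant.synthcell`) that
renders 4-channel fields and time-lapse series with complete ground truth —
cell fates, MET blobs anchored on cell edges, staged puncta with
von-Mises-polarized placement, logistic death times — so every measurement
can be validated against a known answer.

## Worked example

```python
from metquant import (PipelineConfig, SimConfig, simulate_field,
                      count_nuclei, quantify_mets)

pc = PipelineConfig()
cfg = SimConfig(n_cells=500, field_size_px=(1536, 1536), frac_met_positive=0.16)
stack, truth = simulate_field(cfg, seed=1001)

n, table, nuclei_labels = count_nuclei(stack.plane("hoechst"), pc.nuclei)
res = quantify_mets(stack.plane("cith3"), nuclei_labels, n, pc.mets)
print(n, truth.n_met_positive, res.n_met_segments_raw, res.n_met_merged, res.percent)
```

prints

```
500 67 67 67 13.4
```

— all 500 nuclei are counted, and the 67 MET-positive cells drawn by the
simulator (a binomial realization of the configured 16%) are recovered
exactly: 67 raw CitH3 segments merge to 67 components, 13.4% of cells.

The same pipeline is scriptable from a shell:

```bash
metquant simulate --seed 4 --n-cells 60 --out sim
metquant mets --image sim/field.ome.tif --out mets_out
metquant gate --image sim/field.ome.tif --out gate_out
```

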