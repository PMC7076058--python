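# ttfplan

Voxel-based planning analysis for **Tumor Treating Fields (TTFields)**
transducer-array layouts, with emphasis on posterior-fossa (cerebellar)
tumors.

TTFields therapy delivers alternating electric fields (~200 kHz) to the
head through two orthogonal channels, each a pair of 3×3 disc transducer
arrays on the scalp. The standard montage is designed for supratentorial
tumors; for a tumor in the posterior fossa the question is whether moving
the posteroanterior (PA) array down to the lower occiput/upper neck and
shifting the lateral arrays backward improves field coverage of the gross
tumor volume (GTV). `ttfplan` answers this class of question on synthetic
voxelized head phantoms (or real NIfTI label volumes):

1. **phantom** — nested-ellipsoid head (scalp/skull/CSF/brain shells), a
   posterior-inferior cerebellar compartment holding a dorsal midline GTV
   sphere with optional necrotic core, brainstem, and a neck cylinder;
   label → conductivity maps; NIfTI I/O.
2. **layout** — the seven named montage configurations
   (`SUPRATENTORIAL`, `PA_HORIZONTAL`, `PA_HORIZONTAL_RIGHT/LEFT`,
   `PA_VERTICAL_SUPERIOR/CENTER`, `AP_PA_HORIZONTAL`), realized by ray
   casting disc arrays onto the scalp and rasterizing each disc into a
   gel layer capped by electrode voxels.
3. **solver** — the 200 kHz quasi-static volume-conductor problem
   ∇·(σ∇φ) = 0 per channel, discretized by cell-centered finite volumes
   with harmonic-mean face conductivities and solved by preconditioned
   conjugate gradients; solutions are normalized to a target channel
   current (default 0.9 A); E = −∇φ, J = σE.
4. **metrics** — electric-field and current-density volume histograms
   (EVH/CDVH, the DVH analogue: `fraction(t) = |{v ∈ ROI : f(v) ≥ t}| / |ROI|`)
   and the derived plan-quality metrics: `E_AUC` (= ROI mean |E| by the
   layer-cake identity), `E_x%` (intensity of the hottest x% of the ROI;
   `E_50%` median, `E_5%` hotspot), `V_Et` (% volume at or above t), and
   their current-density analogues.
5. **report** — percent changes versus a baseline configuration,
   averages over the alternative configurations, rankings by GTV
   coverage, and calibrated field-over-anatomy overlay images.
6. **cli** — `ttfp phantom|layout|solve|metrics|report|run`.

## Worked example

The report module's aggregation arithmetic on a published per-montage
PQM table (bundled in `ttfplan.published`; a single-patient posterior-fossa
modelling study):

```python
from ttfplan.published import published_records
from ttfplan.report import aggregate_alternatives, percent_change

records = published_records()
print(aggregate_alternatives(records, "E_AUC", roi="CEREBELLUM"))  # 60.8
print(aggregate_alternatives(records, "CD_AUC", roi="CEREBELLUM")) # 10.0
print(aggregate_alternatives(records, "E_5%", roi="GTV"))          # 86.2
print(percent_change(41.0, 26.4))                                  # 55.3
```

The cerebellum receives a mean `E_AUC` of 60.8 V/m averaged over the six
posterior-fossa montages (versus 20.5 V/m supratentorial), mean `CD_AUC`
10.0 A/m², and the GTV hotspot `E_5%` averages 86.2 V/m; the best single
montage (`PA_HORIZONTAL`) increases GTV `E_AUC` by 55.3% over the
supratentorial baseline (recomputed from the rounded table entries).

A full simulation on the synthetic phantom:

```bash
ttfp run --spacing 4 --out runs/demo
```

```
baseline: SUPRATENTORIAL
GTV: best=PA_VERTICAL_CENTER ranking=PA_VERTICAL_CENTER > PA_VERTICAL_SUPERIOR > AP_PA_HORIZONTAL > PA_HORIZONTAL > PA_HORIZONTAL_LEFT > PA_HORIZONTAL_RIGHT > SUPRATENTORIAL
CEREBELLUM: best=PA_VERTICAL_CENTER ranking=PA_VERTICAL_CENTER > AP_PA_HORIZONTAL > PA_HORIZONTAL > PA_HORIZONTAL_LEFT > PA_HORIZONTAL_RIGHT > PA_VERTICAL_SUPERIOR > SUPRATENTORIAL
artifacts in runs/demo
```

On the default phantom the supratentorial montage yields a GTV mean |E|
of 76.4 V/m (0.9 A per channel, channel-averaged) and every posterior-fossa
montage beats it (e.g. `PA_HORIZONTAL` 94.6 V/m, a 24% gain); the ±2 cm
left/right PA shifts agree to ~1e-5 by mirror symmetry. Absolute
magnitudes depend on the phantom and drive settings — the package claims
comparative quantities, not patient-specific field values (see
`docs/methods.md`).

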