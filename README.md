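# spotmap

Flexible single-cell-to-spot mapping between scRNA-seq and spatial
transcriptomics (ST) data.

Multi-cell ST spots (e.g. 10x Visium) blur single-cell structure, while
scRNA-seq loses positions. `spotmap` learns an m × w row-stochastic
mapping matrix **M** between m cells and w spots by minimizing

    L = Σᵢⱼ KL(Cᵢ‖Sⱼ) Mᵢⱼ + Σᵢⱼ Dᵢⱼ Mᵢⱼ + λ·(1/w)·Σⱼ |Nⱼ − Σᵢ Mᵢⱼ|

where KL compares expression profiles, Dᵢⱼ = 1 − PCC(Zᵢˢᶜ, Zⱼˢᵗ) compares
graph-attention-autoencoder embeddings, and Nⱼ is the expected number of
cells in spot j (estimated from UMI totals or H&E nucleus counts;
λ = 0.1). From the fitted M it extracts either

* **regular** assignments — each spot is filled with its Nⱼ
  highest-scoring cells (spot composition at single-cell resolution), or
* **greedy** assignments — every cell is placed at its highest-scoring
  spot (a location for the whole atlas).

The package also ships a ground-truthed simulator (typed tissues binned
into multi-cell spots, with a 2^N(0,1) gene-perturbation noise model) and
the standard evaluation metrics (per-type mapping precision Pmap/Ploc,
per-spot cell-type error rate, proportion PCC, K-distance proximity).
See `docs/methods.md` for the model details.

## Worked example

```python
import spotmap as sm

# simulate a ground-truthed section: 4 cell types, ~5 cells per spot
tissue = sm.generate_synthetic_tissue(n_types=4, cells_per_type=50,
                                      n_genes=120, n_markers_per_type=8, seed=0)
st = sm.bin_cells_to_spots(tissue, target_mean_cells=5.0)
sc = sm.perturb_expression(tissue.cells, 0.05, seed=1)   # 5% platform noise

cfg = sm.MapperConfig(gate=sm.GateConfig(dims=(64, 16), epochs=50, lr=1e-3),
                      mapping=sm.MappingConfig(epochs=300))
model = sm.CellToSpotModel(sc, st.spots, st.geometry,
                           annotation=tissue.annotation, config=cfg)
res = model.fit(seed=0)
print(res.summary())
report = res.evaluate(st.truth)
print("median Pmap:", round(report.per_type_pmap.median(), 3))
```

prints

```
Cell-to-spot mapping results
============================================
cells (m):                 200
spots (w):                 40
genes after preprocessing: 120
embedding dimension:       16
expected cells (sum N_j):  185
lambda (quantity weight):  0.1
initial mapping loss:      34.8945
final mapping loss:        13.7128
mean |N_j - column mass|:  1.4548
sc GATE loss (init->final): 2597179.2 -> 947322.8
st GATE loss (init->final): 542803.6 -> 205176.0
median Pmap: 0.528
```

Reading the summary: 200 cells were mapped onto 40 spots over the 120
shared genes; the UMI rule expects 185 cells across the section; the
three-term loss fell from 34.9 to 13.7 and the average gap between each
spot's column mass in M and its expected cell count is ≈1.5 cells. With
this deliberately tiny configuration roughly half of each type's cells
land on their exact true spot (`median Pmap` 0.53); the full-size
benchmark below reaches ~65%. `res.regular()` / `res.greedy()` return the
assignment tables, `res.proportions()` the per-spot cell-type mix, and
`res.plot_assignments()` a spatial scatter.

The same workflow is available from the shell:

```bash
spotmap simulate --n-types 4 --cells-per-type 50 --genes 120 --seed 0 --out-dir data/
spotmap map --sc data/sc_counts.csv --st data/st_counts.csv \
            --coords data/st_coords.csv --annotations data/cell_types.csv \
            --mode regular --seed 0 --out-dir run/
spotmap evaluate --assignments run/assignments_regular.csv \
                 --truth data/truth.csv --annotations data/cell_types.csv \
                 --mode regular --out run/report.json
```

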