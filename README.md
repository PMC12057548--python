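# crumbscan

Quantifies the pore structure of baked-goods crumb (cakes, bread) from
photographs, and computes the companion nutritional and physical quality
indices used when benchmarking alternative starches in gluten-free baking.

The crumb of a cake slice photographed against even lighting shows dark
pores ("cells") in a brighter matrix. `crumbscan` reduces an 8-bit
grayscale photograph to its 256-bin intensity histogram, picks a single
global threshold `T` with any of five classical criteria, and measures the
resulting binary pore mask:

* **Otsu** — maximize the between-class variance
  `P(T)(1−P(T))(μ_f(T) − μ_b(T))²`;
* **IsoData** (Ridler–Calvard) — fixed point of
  `T ← round((μ_below(T) + μ_above(T)) / 2)`;
* **MaxEntropy** (Kapur) — maximize the sum of Shannon entropies of the two
  normalized class distributions;
* **Huang** (Huang–Wang) — minimize the histogram-weighted fuzzy entropy
  `Σ_g S(μ(g,T))·n_g` with membership `μ = 1/(1 + |g − μ_class|/C)`;
* **Intermodes** (Prewitt–Mendelsohn) — smooth the histogram with a 3-point
  running mean until exactly two modes `j < k` remain; `T = ⌊(j+k)/2⌋`.

Pixels at or below `T` are pores (the dark class). After one pass of a 3×3
binary median despeckle, 8-connected particle analysis reports the crumb
grain table: cell count, total area (mm²), average cell size, % area,
min/max cell area, mean cell periphery, the per-cell perimeter–area fractal
dimension `DFp = 2·log(P/4)/log(A)` (P in mm, A in mm²), and the texture
fractal dimension `DFt`, the log–log slope of cell counts across size
scales (cell-size distribution or box counting).

Companion calculators:

* **Englyst starch fractions** from in-vitro glucose release (g/100 g):
  `TS = (TG − FG)·0.9`, `RAG = G20`, `RDS = (G20 − FG)·0.9`,
  `SDS = (G120 − G20)·0.9`, `SHI = RDS/TS·100`;
* **hydrolysis / predicted glycemic index**: `HI` is the trapezoidal AUC of
  the digestion curve relative to a reference food, and
  `pGI = 39.71 + 0.549·HI`;
* **CIELAB color**: total color difference
  `ΔE = √(ΔL² + Δa² + Δb²)` and browning index
  `BI = 100·(x − 0.31)/0.17`, `x = (a + 1.79L)/(5.645L + a − 3.012b)`;
* **physical quality**: specific volume (mL/g), baking weight loss (%), and
  hardness-increase rate over storage (N/day).

Because crumb photographs are rarely published alongside papers, the
package ships a synthetic-data module that draws crumb-like images (dark
lognormal-radius disks in a bright matrix, Gaussian gray noise, optional
blur and speckle) with an exact ground-truth pore mask, plus first-order
digestion profiles with known fractions — so the whole chain is testable
end to end with no downloads.

## Worked example

```python
import crumbscan as cs

params = cs.CrumbSynthParams(seed=11, gray_sd=5.0)   # 30 mm x 30 mm field
image, truth = cs.generate_crumb_image(params)
print(f"ground truth: {truth.true_count} pores, {truth.true_total_area_mm2:.2f} mm^2")

hist = cs.build_histogram(image)
for method in cs.THRESHOLD_METHODS:
    r = cs.compute_threshold(hist, method)
    mask = cs.remove_noise(cs.binarize(image, r.T))
    parts = cs.measure_particles(cs.label_particles(mask), image.scale_mm_per_px)
    cs.attach_dfp(parts)
    dft = cs.texture_fractal_dimension(parts).dft
    s = cs.summarize_pores(parts, image.field_area_mm2, dft=dft)
    print(f"{method:>10}: T={r.T:3d}  count={s.cell_count}  "
          f"area={s.total_area_mm2:.2f} mm^2  %area={s.pct_area:.1f}")
```

prints

```
ground truth: 244 pores, 260.25 mm^2
     huang: T=101  count=244  area=260.26 mm^2  %area=28.9
maxentropy: T=161  count=251  area=262.07 mm^2  %area=29.1
intermodes: T=125  count=244  area=260.26 mm^2  %area=28.9
   isodata: T=125  count=244  area=260.26 mm^2  %area=28.9
      otsu: T=101  count=244  area=260.26 mm^2  %area=28.9
```

Huang, IsoData, Otsu and Intermodes place the cutoff in the gap between the
pore and matrix gray modes and recover the ground truth exactly; MaxEntropy
cuts into the matrix mode and picks up a handful of spurious sub-resolution
specks — the same relative behavior reported for real crumb images.

The quality calculators work off plain numbers or the bundled published
measurement tables:

```python
tables = cs.load_reference_tables()
ref = cs.ColorTriplet(*tables["crumb_color"]["rice"])
maize = cs.ColorTriplet(*tables["crumb_color"]["maize"])
print(f"{cs.delta_e(maize, ref):.2f}")        # 6.01

profile, _ = cs.generate_digestion_profile(cs.DigestionSynthParams(noise_sd=0.0))
f = cs.starch_fractions(profile)
print(f"RDS={f.RDS:.2f} SDS={f.SDS:.2f} SHI={f.SHI:.2f}")
# RDS=37.29 SDS=12.20 SHI=75.34
```

A `crumbscan` console command wraps the same stages
(`analyze`, `threshold`, `synth-image`, `synth-digestion`, `nutrition`,
`color`); run `crumbscan --help`.

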