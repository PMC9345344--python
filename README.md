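# motion3c

Three-component analysis of single-cell migration trajectories.

Cells tracked in time-lapse microscopy rarely move by pure diffusion: most
adherent lines show *superdiffusive* paths produced by some mix of
directional **persistence** (a tendency to keep the previous direction,
e.g. from cytoskeletal inertia) and **directional bias** (a shared
stimulus, e.g. the empty space left by a wound in a scratch assay).  The
classical descriptors confound the two: the persistence time P of the
Fürth model is grossly inflated when a bias is present, and the naive
bias estimate (the mean displacement vector) overshoots when persistence
is present.

`motion3c` separates them by modelling each displacement **d** over one
analysis interval Δt as the vector sum of three components,

```
d = b·û(β) + p·û(prev d) + r
```

a constant bias of module *b* along direction β shared by all cells, a
persistence vector of module *p* aligned with the cell's previous
displacement, and a random residual **r**.  Projecting d on the bias
direction gives the linear regression at the heart of the method,

```
d_b = b + p·cos(α)
```

where α is the angle between the previous displacement and the bias
direction.  Fitting it over all steps of a population yields *b* and *p*
separately; subtracting both from each displacement recovers the random
vectors and their mean module *r*, the natural normaliser for *b* and *p*.

The package is aimed at anyone quantifying 2D cell motility from tracking
output (wound-healing/scratch assays, chemotaxis, free migration):

* `motion3c.tracks` — tabular track I/O, resampling to the analysis
  interval, displacement steps;
* `motion3c.simulate` — seeded generator of synthetic populations with
  prescribed random MSD, persistence and bias;
* `motion3c.msd` — MSD curves, count-weighted power-law (`MSD = k·t^α`)
  and Fürth (`MSD = 2S²P[t − P(1 − e^(−t/P))]`) fits;
* `motion3c.decompose` — the three-component decomposition;
* `motion3c.windows` — overlapping-window time courses and the quadratic
  relation `P/Δt ≈ 2·(p/r)²` linking time- and vector-persistence;
* `motion3c` CLI — `simulate`, `msd`, `decompose`, `timecourse`,
  `relation`.

## Worked example

Simulate a wound-like population (30 cells, 24 h at 40-min intervals,
random MSD 100 μm²/interval, persistence 8 μm, bias 8 μm pointing along
+x) and decompose it:

```sh
motion3c simulate --cells 30 --steps 36 --persistence 8 --bias-module 8 \
    --bias-angle-deg 0 --seed 1 -o wound_like.tsv
motion3c decompose wound_like.tsv --expected-angle-deg 0 -o -
```

```json
{
  "b_um": 7.397870605751746,
  "b_se": 0.569828978221816,
  "p_um": 8.633382650823576,
  "p_se": 0.6517583140098824,
  "r_mean_um": 8.684521248139337,
  "raw_bias_um": 14.173968242472803,
  "beta_deg": -0.9555558681629596,
  "delta_deg": 0.9555558681629596,
  "n_steps_used": 1050
}
```

(abridged to the scientific fields; the full JSON also records parameters,
input hashes and the package version)

Reading: the naive bias estimate (`raw_bias_um` ≈ 14.2 μm) nearly doubles
the true 8 μm input because persistence aligns steps with the bias, while
the decomposition recovers both inputs within their standard errors
(b = 7.4 ± 0.6 μm, p = 8.6 ± 0.7 μm) and a mean random module of 8.7 μm
(the Rayleigh mean of an MSD-100 μm² random walk is 8.9 μm).  The bias
points within 1° of the expected direction (`delta_deg`).  The classical
fits on the same data (`motion3c msd wound_like.tsv --model both`) give
α = 1.92 — strongly superdiffusive — and a Fürth persistence time of
338 min, more than five times the ~65 min a bias-free population with the
same persistence module shows: time-persistence absorbs the bias, the
vector decomposition does not.

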