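# forestdiv

Which facet of biodiversity best predicts forest aboveground biomass (AGB)
— the trait values of the dominant species (functional identity), the
spread of traits (functional diversity), or the evolutionary relatedness
of the species present (phylogenetic diversity)? `forestdiv` is a tested
Python implementation of the full plot-based workflow ecologists use to
ask that question separately for the overstory (DBH ≥ 9 cm) and
understory (1–9 cm) tree strata:

1. **Allometric AGB** per stem, W = a(D²H)^b (kg), summed to plot totals
   in Mg/ha per stratum.
2. **Diversity metrics** per plot × stratum from a species × trait table
   and a phylogeny:
   - CWM_t = Σ wᵢ·traitᵢ (community-weighted means of SLA and leaf
     N/P/K/C),
   - FDis = Σ wᵢ‖xᵢ − c‖ (dispersion around the weighted centroid in
     standardized trait space),
   - FRic (convex-hull volume relative to the species pool),
   - FDiv (arctan-transformed weighted log-variance of traits),
   - MPD = [2/(n(n−1))] Σ_{i<j} d(sᵢ,sⱼ), MNTD = (1/n) Σᵢ min_{j≠i}
     d(sᵢ,sⱼ) (patristic distances),
   - PSV = 1 − mean phylogenetic correlation, PSR = n·PSV.
3. **Environmental axes**: separate correlation-matrix PCAs of
   topographic and edaphic variables → Topo_PC1/2, Soil_PC1/2.
4. **PLS regression** of stratum AGB on the 15 candidate predictors, with
   VIP scoring (Σ VIP² = p), backward "shaving" guided by cross-validated
   RMSEP, VIP banding (> 1 major, 0.8–1 medium, ≤ 0.8 negligible) and
   bivariate OLS fits for the predictors that survive.

A first-class synthetic-data module generates phylogenies (Yule), traits
(Brownian motion with tunable phylogenetic signal λ), stratified stem
inventories and environment tables with *planted* predictor→AGB effects,
so the whole pipeline is validated against known ground truth — no field
data required. See `docs/methods.md` for the models, defaults and their
rationale.

## Worked example

Simulate a 30-plot study with the default planted effects (overstory AGB
driven by CWM-SLA and MPD) and run the full analysis:

```python
import forestdiv as fd

res = fd.run_pipeline(fd.SimulationConfig(seed=11))
over = res.strata[fd.OVERSTORY]
print("overstory mean AGB: %.2f Mg/ha (sd %.2f)"
      % (over.agb["agb"].mean(), over.agb["agb"].std()))
print(over.vip_table.to_string(index=False))
print(over.bivariate[["predictor", "slope", "r2", "p_value"]]
      .round(4).to_string(index=False))
```

prints

```
overstory mean AGB: 412.74 Mg/ha (sd 159.46)
  stratum predictor      VIP   band  boundary
overstory   CWM_SLA 1.142486  major     False
overstory       MPD 0.833502 medium     False
predictor    slope     r2  p_value
  CWM_SLA 137.4722 0.5881   0.0000
      MPD 244.5369 0.3130   0.0013
```

Reading it: plot AGB averages ≈ 413 Mg/ha across the 30 simulated
overstories; backward shaving kept exactly the two planted drivers out of
the 15 candidates; CWM-SLA is a major contributor (VIP > 1) and MPD a
medium one in the refit model; and each driver shows the expected positive
bivariate relationship with AGB (e.g. R² = 0.59, p < 10⁻⁴ for CWM-SLA —
plots dominated by acquisitive, high-SLA species hold more biomass, as
planted).

The same analysis runs on real data by passing an inventory, trait table,
Newick phylogeny, environment table and allometric-coefficient table to
`run_pipeline(...)` (see `forestdiv.io` for the file formats).

## Command line

```bash
forestdiv simulate --seed 4 --out-dir sim/      # write a synthetic dataset
forestdiv all --seed 4 --out-dir results/       # simulate + analyze + report
forestdiv pls --config config.yaml              # just the VIP tables
```

Every table (AGB, diversity profiles, env scores, VIP bands, bivariate
fits, run manifest with seed and config hash) is written as CSV/JSON and
is byte-identical across reruns with the same seed.

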