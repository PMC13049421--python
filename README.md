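# acidflux

Analysis pipeline for time-resolved bacterial acid-stress
transcriptomics, modelled on experiments in which *Corynebacterium
glutamicum* is exposed to an **acute** low-pH shock (pH 4.0 vs a pH 7.0
control, sampled at 1 and 4 h) or **sustained** low-pH stress (pH-stat
pH 5.5 vs pH 7.0, sampled at 1, 8 and 18 h). It is aimed at microbial
physiologists and systems biologists who have gene-level count
matrices, a transcriptional regulatory network, and growth curves — and
want a reproducible route from those inputs to growth kinetics,
differentially expressed genes, their temporal set algebra, and the
transcription factors driving the response.

The pipeline has four analytical cores:

- **Growth kinetics** — OD600 is ln-transformed and a sliding 7-point
  OLS regression is run along the series; the exponential phase is the
  first contiguous run of windows with R² ≥ 0.90, and
  μ_max (h⁻¹) is the steepest eligible slope. A GCV-smoothed spline
  derivative gives the continuous μ(t), and helpers compute percent
  reductions, log₁₀ CFU changes, and titration counter-ion loads (mM).
- **Differential expression** — per contrast (stress vs same-timepoint
  control), a moderated t-test on log₂(CPM + 0.5) with empirical-Bayes
  variance shrinkage (posterior s̃² = (d₀s₀² + d·s²)/(d₀+d)), BH-adjusted
  p-values, and the DEG rule |log₂FC| > 1 and FDR < 0.05. External DE
  tables can be imported instead.
- **Trajectory set algebra** — signed per-timepoint calls classified
  into persistent/switching trajectories, exclusive UpSet-style
  intersection counts, and cross-regime overlaps (co-induced,
  co-repressed, opposite) at shared timepoints.
- **Reporter transcription factors** — on a cleaned TF→target network,
  each TF is scored **Z = (μ_target − μ_bg)/σ_bg** over gene
  significances s = −log₁₀(adjusted p), with low-abundance genes
  (mean CPM < 1) excluded, a size-matched sampling null for
  significance, and per-TF target-direction profiles.

A synthetic-data module generates negative-binomial count matrices,
regulatory networks with planted-active and decoy TFs, and growth
curves with known ground truth, so the whole pipeline is benchmarkable
without any sequencing data.

## Worked example

```python
from acidflux.synthetic_data import SimConfig, simulate_counts, simulate_network, simulate_growth
from acidflux.de_stats import Contrast, fit_contrast, call_degs
from acidflux.reporter_tf import reporter_analysis
from acidflux.growth_kinetics import summarize_growth

cfg = SimConfig(n_genes=1000, de_fraction=0.1, lfc_range=(2.0, 4.0), seed=1)
counts, design, truth = simulate_counts(cfg)
network, truth = simulate_network(cfg, truth)

contrast = Contrast.from_design(design, "acute", 1.0)
table = fit_contrast(counts, design, contrast)
calls = call_degs(table)
print(sum(c.direction == "up" for c in calls), "up,",
      sum(c.direction == "down" for c in calls), "down")

results = reporter_analysis(network, table, counts, seed=1)
top = max((r for r in results if r.z is not None), key=lambda r: r.z)
print(f"top reporter TF: {top.tf_id}  Z={top.z:.2f}  p_adj={top.p_adj:.4f}")

curve = simulate_growth("logistic", mu=0.4, noise_sd=0.02, seed=1, with_ph=True)
gs = summarize_growth(curve)
print(f"mu_max={gs.mu_max:.3f} h^-1  OD_max={gs.od_max:.1f}  dpH_max={gs.delta_ph_max:.2f}")
```

prints

```
48 up, 52 down
top reporter TF: TF_planted_1  Z=2.22  p_adj=0.0021
mu_max=0.446 h^-1  OD_max=29.0  dpH_max=3.10
```

The 100 DEG calls (48 up, 52 down) recover 97 of the 100 planted
effects at the 1 h acute contrast, with 3 false positives; the planted
TF — 80% of whose regulon was wired to truly responsive genes — tops
the reporter ranking with a BH-adjusted sampling p of 0.002; and the
noisy logistic growth curve (true μ = 0.4 h⁻¹) yields a μ_max estimate
of 0.446 h⁻¹, with the pH trace peaking 3.10 units above its acidic
start.

The same pipeline runs from the shell:

```bash
acidflux simulate --seed 1 --out run/          # synthetic dataset
acidflux de --counts run/counts.tsv --design run/design.tsv --out run/
acidflux growth run/growth_acute.csv --out run/
acidflux run --config config.yaml --out run/   # everything from YAML
```

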