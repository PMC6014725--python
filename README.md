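# stedspine

An in-silico implementation of the quantitative analysis behind chronic
super-resolution (two-photon STED) imaging of dendritic spines on
hippocampal CA1 basal dendrites. Dendritic spines sit at densities of
2–4 per µm and have ~150 nm necks, so diffraction-limited two-photon
(2P) microscopy systematically undercounts them; STED microscopy improves
the *lateral* resolution about six-fold while leaving the axial
resolution unchanged, which detects ~32 % more spines but still misses
those that protrude along the optical axis. This package reproduces that
whole analysis chain on synthetic data, so every stage is testable
without microscope or animal:

- **scene** — a generative model of dendrites (cylinders, radius *R*)
  bearing spines with lognormal morphologies and azimuthally uniform
  placement, evolved across imaging sessions with size-dependent loss
  (survival `s(V) = 1/(1+exp(−(a + b·log₁₀V)))`) balanced by gain.
- **imaging** — an anisotropic Gaussian-PSF forward model rendering
  scenes and 40 nm calibration beads into 3-D TIFF stacks.
- **observer** — the manual counting rules as a deterministic geometric
  observer: a spine counts only if it protrudes laterally more than
  `d_min` = 200 nm beyond the shaft silhouette, and same-side spines
  closer than the lateral resolution merge into one.
- **blindzone** — the geometric blind-zone model: with uniform azimuths a
  fraction `f = (2/π)·arcsin((R + d_min)/(R + L))` of spines is
  undetectable, and dividing a measured density by `1 − f` extrapolates
  the true 3-D density (2.13 µm⁻¹ → 2.91 µm⁻¹ with the default anatomy,
  where `f ≈ 0.267` — about a quarter).
- **turnover** — identity matching across sessions (≥ 500 nm shift = new
  spine) and the survival / lost / new fractions
  `F_s(t) = N_r(t)/N(1)·100`, `F_lost(t) = N_L(t)/N(t−1)·100`,
  `F_new(t) = N_n(t)/N(t)·100`, aggregated per dendrite as mean ± sem.
- **morpho** — two-pixel line profiles fitted with Lorentzians
  (FWHM = 2γ) for resolution and neck widths; persistence classes
  (">2 days" = seen in all three sessions); Ward hierarchical clustering
  of standardized morphologies (head/neck ratio, max head diameter,
  length) into three classes; Mann–Whitney two-group comparison.
- **pipeline / cli** — YAML-configured end-to-end studies with seeded,
  byte-reproducible CSV/JSON/TIFF output bundles.

## Worked example

```python
import stedspine as ss

# the blind-zone correction with the default anatomy
f = ss.hidden_fraction(R=0.35, L=1.0, d_min=0.2)
print(f"hidden fraction {f:.3f}, corrected "
      f"{ss.corrected_density(2.13, f):.2f} spines/um")
# hidden fraction 0.267, corrected 2.91 spines/um

# a full in-silico study: 14 dendrites, 3 sessions (days 0/2/4)
res = ss.run_study(ss.StudyConfig(seed=5), "out/")
print(res["summary"]["turnover_2P-STED"]["F_s_day4"])
# {'mean_pct': 64.9087..., 'sem_pct': 1.2750...}
```

The study summary also reports the measured STED density (2.15 µm⁻¹ at
seed 5), its blind-zone-corrected value (2.94 µm⁻¹), the per-interval
lost/new fractions (~21 %/~20 %), and the morphology section (persistent
spines' median head volume 0.039 µm³ vs 0.010 µm³ for transient ones,
rank-sum p ≈ 6e-56, with the mushroom cluster holding 42 % of persistent
but only 15 % of transient spines). The same pipeline is scriptable from
the shell:

```sh
stedspine simulate --seed 5 --out series.csv
stedspine turnover --scene-csv series.csv --ground-truth-ids --out turnover.csv
stedspine blindzone --measured-density 2.13
stedspine paper-arithmetic
```

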