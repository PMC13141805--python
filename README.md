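# steatoquant

Feature-based quantification of **macrovesicular steatosis (MaS)** on
H&E-stained liver histology images, for pathologists and surgical teams who
need an objective, inspectable fat-fraction readout during donor-liver
evaluation — plus the rater-agreement statistics used to validate such a
readout against human grading, and a seeded synthetic-slide generator so
everything is testable without clinical data.

On H&E, lipid vacuoles are bright unstained holes in eosin-pink tissue. The
pipeline is classical and transparent:

1. **Tissue mask** — grayscale, 5×5 mean filter, Otsu threshold; debris
   < 2000 µm² removed; a 100-px border band excluded.
2. **Artifact suppression** — closing bridges narrow tears; interior holes
   are filled back as tissue unless larger than 1.5×10⁶ µm² or ragged
   (solidity < 0.85); low-saturation, maximal-brightness glare is removed.
3. **Candidate detection** — dynamic threshold: gray ≥ local mean (31 px
   window) + 5 gray levels, inside tissue.
4. **Shape classification** — each candidate region is accepted iff
   area ∈ [50, 12 000] µm², roundness = 1 − σ_d/d̄ ≥ 0.55,
   circularity = A/(π·max dᵢ²) ≥ 0.45, compactness = L²/(4πA) ≤ 2.0,
   convexity ≥ 0.80 and anisometry (axis ratio) ≤ 2.5 — separating round
   vacuoles from vessels, tears and debris.
5. **Quantification** — MaS % = 100 × Σ accepted vacuole area / tissue
   area, with an ordinal grade over the bins 0%, 1–5%, 6–10%, 11–15%,
   16–20%, 21–30%, >30%.

Agreement statistics: Pearson r (Fisher-z CI, R² = r²), Spearman ρ, RMSE,
Bland–Altman limits of agreement, ±5-point tolerance rate, range
classification, and quadratically weighted Cohen's κ with Landis–Koch
bands. See `docs/methods.md` for definitions and design rationale.

## Worked example

```python
import steatoquant as sq

# a synthetic slide with known 10% vacuole fraction plus artifacts
spec = sq.SyntheticSpec(target_fraction=0.10, n_vessels=3, n_tears=1,
                        n_glare=1, rng_seed=42)
slide, truth = sq.generate_slide(spec)
result = sq.run_pipeline(slide)
print(f"true {100 * truth.true_fraction:.2f}%  "
      f"estimated {result.steatosis_pct:.2f}%  grade {result.category}  "
      f"accepted {result.n_accepted}")
```

prints

```
true 10.15%  estimated 10.10%  grade 11-15%  accepted 22
```

i.e. the pipeline recovered the ground-truth fat fraction within 0.05
percentage points; 22 vacuoles were accepted while the vessels, the tear
and the glare patch were rejected by the shape filters or excluded from the
tissue mask.

The same workflow from the shell:

```bash
steatoquant simulate --n 3 --seed 11 --fraction 0.08 --out sim/
steatoquant quantify sim/slide_000.png --out out/       # report + overlay
steatoquant batch sim/ --out out/                       # cohort summary CSV
steatoquant agree ratings.csv --ai-rater AI             # agreement report
```

`quantify` writes a JSON report (steatosis %, grade, areas, effective
config, run manifest), a green/yellow overlay PNG (accepted vacuoles green,
rejected candidates yellow) and a per-region CSV of shape features. Exit
codes: 0 success, 2 no tissue, 1 I/O error.

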