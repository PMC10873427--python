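# retinaggr

Quantitative analysis pipeline for studies of misfolding rhodopsin mutants
in autosomal dominant retinitis pigmentosa (adRP): receptor aggregation
measured in vitro by detergent-decomposition FRET and colocalization, and
retinal degeneration measured in vivo by outer-nuclear-layer (ONL) decay
kinetics, electroretinogram (ERG) dose-response curves, stained-field
particle counts, and expression quantification. Every analysis stage is
paired with a seeded synthetic-data generator with known ground truth, so
the whole pipeline runs and is testable without any raw microscopy or
physiology data.

Intended users: vision researchers and image/physiology analysts who want
the statistical machinery of these assays as reusable, tested Python
instead of one-off spreadsheet or Prism workflows.

## The models

**FRET decomposition.** With donor intensities at 476 nm measured
untreated (F0), after mild detergent DM (FDM), and after SDS (FSDS, the
zero-FRET reference, since SDS dissolves all complexes):

    E_total          = (FSDS − F0)  / FSDS     (all complexes)
    E_DM-insensitive = (FSDS − FDM) / FSDS     (aggregates survive DM)
    E_DM-sensitive   = (FDM  − F0)  / FSDS     (oligomers dissolved by DM)

Each component's saturation with the acceptor:donor expression ratio x is
fit to the rectangular hyperbola E = E_max·x / (EC50 + x), and E_max is
compared against a non-specific FRET ceiling with an extra sum-of-squares
F test (null model: E_max pinned at the ceiling; F(1, n−2)).

**ONL decay kinetics.** Windowed nuclei counts (mean of 600/800/1000 µm
from the optic nerve, per region) over age x follow one-phase decay

    y = (y0 − plateau)·e^(−k·x) + plateau,   plateau ≡ 1

with y0 shared across series fit together and one rate constant k
(month⁻¹) per series. Exponential loss is the signature of one-hit
(stochastic, constant-risk) photoreceptor death; the cumulative-damage
alternative predicts sigmoidal kinetics, and the two are discriminated by
small-sample AIC against a logistic alternative.

**ERG dose-response.** Wave amplitude R (µV) over flash intensity I
(cd·s/m²) follows the standard model R = Rmax / (1 + 10^(logKA − logI)) or
its biphasic extension with two half-max intensities KA < KB mixed by a
fraction f; the models are nested (f = 1) and compared by an extra
sum-of-squares F test with 2 numerator degrees of freedom.

**Particle counting.** TUNEL/PROTEOSTAT/DAPI-positive objects in
317 × 317 µm retinal fields: deterministic Otsu threshold with a
bimodality gate, connected components (8-connectivity), physical
minimum-area filter.

**Expression.** Western densitometry (summed rhodopsin bands / GAPDH,
relative to control mean) and comparative-CT qPCR
(fold = 2^(−ΔΔCT), replicates averaged on the CT scale).

## Worked example

```python
import retinaggr as ra

# 1. Synthesize a FRET saturation experiment and analyze it back.
series, truth = ra.make_fret_dataset(noise_sigma=0.01, seed=1)
table = ra.fret.efficiencies_table(series)          # columns: A:D, E_tot, E_sens, E_ins
result = ra.test_specificity(
    list(zip(table[:, 0], table[:, 2])),            # DM-sensitive component
    e_max_nonspecific=0.05,
)
print(f"Emax = {result.fit.e_max:.3f} ± {result.fit.se_e_max:.3f}, "
      f"F = {result.f_statistic:.1f}, p = {result.p_value:.2e}, "
      f"specific: {result.is_specific}")

# 2. Joint decay fit at the study design (ages 0.5/1/3/6 months, n = 6 mice).
data, _ = ra.make_onl_series({"het": 0.24, "homo": 1.84}, noise_sigma=1.0, seed=1)
fit = ra.fit_one_phase_decay({k: v["mean_points"] for k, v in data.items()})
for label, sf in fit.per_series.items():
    print(f"{label}: k = {sf.k:.2f} ± {sf.se_k:.2f} /month")
print("fold:", ra.rate_ratio(fit.per_series["homo"].k, fit.per_series["het"].k).rounded_ratio)
```

Output:

```
Emax = 0.196 ± 0.007, F = 1091.8, p = 5.00e-06, specific: True
het: k = 0.24 ± 0.02 /month
homo: k = 1.90 ± 0.12 /month
fold: 8
```

The fitted Emax of 0.20 sits well above the 0.05 non-specific ceiling
(the generator's true value is 0.20), and the two decay rates recover the
generating constants 0.24 and 1.84 month⁻¹; their ~8-fold ratio is the
kind of homozygote-vs-heterozygote comparison the kinetics table is built
for.

The same stages run from the shell:

```sh
retinaggr run --seed 1 --out out/          # all stages, one CSV+JSON table each
retinaggr kinetics --seed 1 --out out/     # a single stage
```

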