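# entrostress

Early detection of plant drought stress from hyperspectral (HSI) and thermal
infrared (TIR) imagery, using Shannon entropy of plant-pixel histograms as an
explainable high-level feature and a small single-layer perceptron (SLP) as
the classifier.

The package is aimed at plant-phenotyping and smart-agriculture researchers
who want an interpretable alternative to deep models: every input to the
classifier is a named histogram statistic of a named vegetation index, every
output is a labeled stress state, and the whole network has ~10³ weights.

## The method

A monitored canopy is imaged on a fixed set of *key days* (1, 3, 6, 8, 12,
19, 25) spanning the transition from no stress to deep stress. From each
hyperspectral cube, ten single-channel *index images* are computed: the
thermal image TIR, the vegetation indices

- NDVI  = (ρ₈₀₀ − ρ₆₈₀)/(ρ₈₀₀ + ρ₆₈₀)
- GNDVI = (ρ₈₀₀ − ρ₅₅₀)/(ρ₈₀₀ + ρ₅₅₀)
- GCL   = ρ₈₀₀/ρ₅₅₀ − 1
- SIPI  = (ρ₈₀₀ − ρ₄₅₀)/(ρ₈₀₀ − ρ₆₈₀)
- GI    = ρ₅₅₀/ρ₆₃₀

the three visible channels R₆₃₀, G₅₅₀, B₄₈₀, and the masking index

- NDblue = (G₅₅₀ − B₄₅₀) / (max(G₅₅₀ − B₄₅₀) − min(G₅₅₀ − B₄₅₀)),

whose image-wide range normalization makes a single constant threshold
(value > 0.1) separate plant from background on every day. Masked pixel
values are denoised by percentile trimming (TIR: 1% bottom / 5% top;
HSI-based: 1%/1%) and summarized by six statistics: **min, max, mean, std,
max−min, and the Shannon entropy** of the 64-bin histogram,

  H = −Σᵢ pᵢ log₂ pᵢ.

Entropy and the histogram width max−min track the *diversity* of plant
states — homogeneous canopy → homogenization during growth → diversification
as stress enters unevenly → heterogeneous drying → uniform withering — which
is what makes them early, index-agnostic stress features.

The classifier is an SLP with M = m × I inputs (m features per index,
I indices), one ReLU hidden layer of N = I + 5 neurons, and K = number of
key days outputs; for the full feature vector M = 10 × 6 = 60, N = 15, K = 7
and the weight count is Nw = M·N + N·K = 1005. Weights are drawn from the
Kaiming-He normal distribution (variance 2/fan-in); reported accuracy is the
mean over 50–100 trials, each with a fresh stratified 70/30 split and fresh
weights. The ablation study trains the SLP on every single feature, every
feature pair within each index, each index with all six features, and
combinations of 2–5 indices, for a short (12-day) and long (25-day)
monitoring period.

Because the original 25-day wheat dataset is not public, the package ships a
first-class synthetic-data module: per-day Gaussian-mixture canopies
(mixture components = plant sub-populations entering stress unevenly) with a
co-registered thermal channel that reproduces the canonical signals — a
+0.2 °C canopy warming by day 6, monotone warming to day 19 with a trend
break at day 25, and the per-day entropy pattern above.

## Worked example

```python
from entrostress import (SceneConfig, default_state_specs, generate_experiment,
                         subsample_feature_dataset, trial_average, compute_index,
                         build_plant_mask, apply_mask, trim_percentiles,
                         shannon_entropy, IndexName)
from entrostress.features import HSI_TRIM

config = SceneConfig()                                   # 64x64, 8 bands
scenes = generate_experiment(config, default_state_specs("long"), seed=1)

for scene in scenes:
    green = compute_index(scene.cube, IndexName.GREEN)
    mask = build_plant_mask(compute_index(scene.cube, IndexName.NDBLUE), 0.1)
    h = shannon_entropy(trim_percentiles(apply_mask(green, mask), HSI_TRIM), 64)
    print(f"day {scene.day:2d}: mask {mask.area:4d} px   H(G550) = {h:.3f} bits")

table = subsample_feature_dataset(scenes, samples_per_day=100, seed=1)
result = trial_average(table, [("TIR", "mean"), ("TIR", "std")], n_trials=50, seed=1)
print(f"TIR (mean, std): accuracy {result.mean_accuracy:.3f} over {result.n_trials} trials "
      f"(M={result.config.n_inputs}, N={result.config.n_hidden}, K={result.config.n_outputs})")
```

prints

```
day  1: mask 1234 px   H(G550) = 5.768 bits
day  3: mask 1229 px   H(G550) = 5.340 bits
day  6: mask 1229 px   H(G550) = 5.842 bits
day  8: mask 1230 px   H(G550) = 5.849 bits
day 12: mask 1230 px   H(G550) = 5.905 bits
day 19: mask 1229 px   H(G550) = 5.870 bits
day 25: mask 1229 px   H(G550) = 5.618 bits
TIR (mean, std): accuracy 0.997 over 50 trials (M=2, N=6, K=7)
```

The entropy column is the stress trajectory: day 3 below day 1
(homogenization while plants still grow), rising diversity from day 6
through the drying phase, and a drop on day 25 once most plants have
withered. A single feature pair classifies all seven key days essentially
perfectly, at chance level (1/7 ≈ 0.14) when labels are shuffled.

The same workflow is available from the shell:

```
entrostress synth --out scenes/ --period long --seed 1
entrostress features --scenes scenes/ --samples 100 --seed 1 --out features.csv
entrostress train --features features.csv --subset "TIR:mean,TIR:std" \
    --trials 50 --seed 1 --out result.json
entrostress study --features features.csv --level pairs --trials 100 --seed 1 --out study/
```

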