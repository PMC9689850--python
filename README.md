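# sodpeeg

Seizure detection from scalp EEG via **second-order difference plot (SODP)
geometry** and **hybrid swarm/genetic feature selection**.

Epileptic seizures show up in scalp EEG as a drastic increase in amplitude
with spike–wave and sharp-wave complexes. The SODP of a signal `s` — the
scatter of successive first differences

```
x(i) = s(i+1) − s(i),    y(i) = s(i+2) − s(i+1)
```

— spreads over a much larger, differently shaped region during seizures
than during seizure-free background. `sodpeeg` implements the full
detection pipeline around this observation:

1. **`eeg_io`** — EDF reading/writing, 23-channel bipolar montage
   selection, sliding-window segmentation (20 s windows, 15 s overlap) and
   zero-phase FIR decomposition into the clinical δ (0–4 Hz), θ (4–8 Hz),
   α (8–15 Hz) and β (15–30 Hz) bands.
2. **`sodp_features`** — ten geometric descriptors of each band-filtered
   segment's SODP: the fitted-ellipse dispersion STD (π·STD1·STD2), the
   sum of inter-vector angle cosines SAV, radial distances SDC, triangle
   areas STA, diagonal distances SSHD, centroid drift SCC, trajectory
   length SSVL, and the central tendency measure CTM at disk radii of
   30/40/50 % of the plot's radial extent (plus eight classical
   time-domain features for comparison).
3. **`optimizers`** — GA, PSO, AsyLnCPSO (asynchronously scheduled
   learning factors, c1 2.5→0.5, c2 0.5→2.5) and the hybrid
   **AsyLnCPSO-GA** (each iteration: swarm update, then GA
   selection/crossover/mutation with elitism), validated on the
   Rastrigin, Sphere, Rosenbrock and Schwefel benchmark functions.
4. **`selection`** — feature subsets encoded as real-valued particles
   thresholded at 0; fitness = stratified 10-fold cross-validated accuracy
   of a Gaussian naive-Bayes classifier on the selected columns; band
   crossing concatenates 10-feature blocks over any of the 15 band
   combinations.
5. **`synth_eeg`** — a labeled synthetic EEG generator (1/f background +
   band oscillations; seizures add gated 2.5 Hz spike–wave trains at 4×
   background RMS) so the whole pipeline is testable without clinical
   data.
6. **`reporting`** — one-way ANOVA group comparisons, [0,1] display
   normalization, key-feature occurrence frequencies and per-band
   contribution shares across optimization trials.

## Worked example

```python
from sodpeeg.eeg_io import band_decompose
from sodpeeg.selection import select_features
from sodpeeg.sodp_features import extract_features
from sodpeeg.synth_eeg import SynthConfig, gen_dataset

config = SynthConfig(n_seizure=100, n_free=100, seed=7)
segments, manifest = gen_dataset(config)

delta = [band_decompose(s, "delta") for s in segments]
table = extract_features(delta)

result = select_features(table, ("delta",), mode="AsyLnCPSO-GA", trials=20, seed=7)
print(f"accuracy min/max/mean: {result.min:.4f} / {result.max:.4f} / {result.mean:.4f}")
print(f"best subset ({result.best_mask.n_selected} features):",
      ", ".join(result.best_mask.selected_names()))

from sodpeeg.reporting import key_feature_frequency
print(key_feature_frequency(result).top_k(4))
```

prints

```
accuracy min/max/mean: 0.9950 / 0.9950 / 0.9950
best subset (3 features): delta:SAV, delta:SCC, delta:CTM04
    band feature  fraction
0  delta   CTM04      0.90
1  delta     STD      0.85
2  delta   CTM05      0.80
3  delta     STA      0.70
```

All 20 trials of the hybrid search converge to 99.5 % cross-validated
accuracy on this synthetic δ-band benchmark — above the best single
feature (96.5 % here) — and CTM-0.4 enters the best mask in 90 % of
trials, i.e. the central tendency measure acts as a key feature, with the
scale-free SAV/CTM descriptors complementing the amplitude-driven ones.

The same pipeline runs from the shell:

```sh
sodpeeg synth --n-seizure 100 --n-free 100 --seed 7 --out data/
sodpeeg features --segments data/ --bands delta --out features.csv
sodpeeg select --features features.csv --bands delta --mode AsyLnCPSO-GA \
    --trials 20 --seed 7 --out result.json
sodpeeg benchmark --function rastrigin --mode AsyLnCPSO-GA --dim 10 --seed 1
```

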