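# emgforce

Force-invariant feature extraction for multichannel surface-EMG gesture
recognition, with a full evaluation framework and a built-in synthetic EMG
generator.

## The problem

Myoelectric prosthetic hands decode the wearer's intended gesture from
surface electromyogram (EMG) signals on the residual forearm. Muscle force
is a confound: contracting harder changes both the amplitude and the
frequency content of the EMG, so a classifier trained at one force level
degrades badly when the user contracts at another. `emgforce` implements a
feature set designed to be *force-invariant* — to describe which muscles are
active and how, independently of how hard they contract — together with
everything needed to evaluate it: six classical baseline feature sets,
dimensionality reduction, classifiers, force-level train/test protocols, a
cluster-separability index, and a statistically structured synthetic
multichannel EMG generator so the entire pipeline is testable without any
external recordings.

## The feature set

For a window `x[0..N-1]` of each channel, seven time-domain scalars are
computed:

- mean absolute value `MV = (1/N) Σ |x[i]|`;
- even power-spectral moments `P0 = Σ x[i]²`, `P2 = Σ (Δx[i])²`,
  `P4 = Σ (Δ²x[i])²`, `P6 = Σ (Δ³x[i])²`, where `Δ` is the first
  difference — by Parseval's theorem these equal frequency-weighted sums
  `Σ k^n P[k]` of the power spectral density, computed without an FFT;
- average amplitude changes `AC1 = (1/(N-1)) Σ |Δx|`,
  `AC2 = (1/(N-2)) Σ |Δ²x|` (indirect frequency information).

Each is passed through the natural logarithm, giving `f1..f7` per channel.
A force gain `g` multiplies the signal, so it shifts `f1..f7` *additively*
(by `ln g` or `2 ln g`) instead of rescaling them, and compresses the
dynamic range so low-force windows separate as well as high-force ones.
The Pearson correlation coefficient `ρ(x, y)` of every unordered channel
pair is appended; correlation is exactly invariant to per-channel gain, so
this block encodes only the spatial co-activation pattern of the gesture.
For 8 channels the vector has dimension `7·8 + C(8,2) = 84`.

Evaluation reduces features to `c − 1` dimensions (c = number of gestures)
with spectral regression discriminant analysis (SRDA), classifies with a
quadratic discriminant, an RBF-kernel SVM, or 3-nearest-neighbours under
trial-wise 5-fold cross-validation, and scores macro-averaged one-vs-rest
accuracy, sensitivity, specificity, precision and F1. Four *cases* vary the
training forces (same / one / two / all three force levels). Cluster quality
of 2-D reduced features is quantified by the RES index — mean Euclidean
distance between gesture-cluster means over mean within-cluster standard
deviation.

## Worked example

Train only at medium force, test at all three forces (the hardest realistic
protocol), on one synthetic subject:

```python
from emgforce.synth import SynthConfig, generate_dataset
from emgforce.features import feature_table
from emgforce.evaluate import CaseScheme, crossvalidate
from emgforce.res_index import reduced_scatter, res
from emgforce.signal_io import FORCES

trials = generate_dataset(SynthConfig(n_subjects=1, duration_s=4.0, seed=7))
feats = feature_table(trials, "proposed")          # 150 ms windows, 50 ms overlap
report = crossvalidate(feats, CaseScheme(2, ("medium",), FORCES), classifier="SVM")
print(report[["fold", "accuracy", "f1"]].round(2).to_string(index=False))
print(f"mean macro-F1 across folds: {report.f1.mean():.2f}%")

pts, gestures, _ = reduced_scatter(trials, seed=7)
print(f"RES index (log features, 150 ms): {res(pts, gestures):.1f}")
```

prints

```
 fold  accuracy    f1
    1     100.0 100.0
    2     100.0 100.0
    3     100.0 100.0
    4     100.0 100.0
    5     100.0 100.0
mean macro-F1 across folds: 100.00%
RES index (log features, 150 ms): 51.1
```

Every fold holds out one of the five trials entirely; 100% macro-F1 across
all test forces from medium-force training shows the features carrying
gesture identity across the force gains, while the same split with the
Hudgins time-domain baseline (`feature_table(trials, "TD")`) loses tens of
F1 points. The RES index of ~51 means gesture-cluster means sit ~51
within-cluster standard deviations apart in the normalised 2-D SRDA space.

A command-line interface wraps the same pipeline:

```sh
emgforce synth --out data/ --subjects 1 --duration 4 --seed 7
emgforce extract --data data/ --method proposed --out features.csv
emgforce evaluate --case 2 --classifier SVM --out results/
emgforce res --lengths 50,150,400 --seed 7 --out sweep.csv
```

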