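# hrv2d — two-dimensional LF-HF analysis of heart rate variability

`hrv2d` analyzes stress states from heart rate variability (HRV). The raw
signal is the sequence of normal-to-normal intervals (NNIs) — the times, in
milliseconds, between consecutive normal heartbeats. Autonomic activity
modulates the NNI series in two conventional frequency bands: the low
frequency band LF = 0.04–0.15 Hz (linked to sympathetic activity) and the
high frequency band HF = 0.15–0.4 Hz (parasympathetic, respiratory).

The classical univariate index of "sympathovagal balance" is the ratio of
band powers, LFp/HFp. That ratio — like any single number of the form

    P1 = LFp/HFp          P2 = b1·LFp²/HFp + b2       P3 = c1·LFp − c2·HFp + c3
    P4 = d1·LFp² − d2·HFp + d3                        P5 = e1·LFp/HFp² + e2

that increases with LFp and decreases with HFp — discards one degree of
freedom: along any fixed-ratio locus (e.g. HFp = 0.8·LFp, where P1 ≡ 1.25)
the other members of the family disagree even on the *direction* of change.
`hrv2d` therefore treats the LF and HF features jointly as a point in the
2-D LF-HF plane, fits a polynomial-kernel SVM to the labeled scatter, and
scores scenarios by categorization accuracy (CA, the percentage of analysis
windows assigned to their true scenario).

For robustness to short large-amplitude artifacts (deep breaths, ectopic
beats, transient bradycardia) the package computes instantaneous-amplitude
features: bandpass the uniformly resampled tachogram into LF and HF,
take the Hilbert-transform envelope of each band, and within each sliding
window average the envelope after discarding its 20% largest and smallest
samples. The resulting LFiA and HFiA (in ms) track oscillation amplitude
while a disturbance covering a small fraction of a window lands entirely
in the trimmed tails.

A seeded synthetic NNI simulator with known band content (tones of known
amplitude plus white noise, scenario presets, injectable artifacts)
provides ground truth for every stage.

## Worked example

Simulate a five-scenario protocol (15 min each of Rest 1, Math, Rest 2,
Exercise, Rest 3), extract per-window features (300 s windows, 10 s step,
120 s buffers at scenario boundaries), and categorize:

```sh
$ hrv2d simulate --preset part1 --seed 0 --out demo
wrote 5095 beats over 4499 s to demo

$ hrv2d features --in demo/rr.txt --labels demo/labels.csv --out demo/features.csv
wrote 180 feature rows to demo/features.csv

$ hrv2d categorize --features demo/features.csv --pair iA --mode 2d
CA = 80.0% over 180 windows, classes: Exercise, Math, Rest 1, Rest 2, Rest 3
```

Each feature row holds the window's band powers (LFp, HFp, their sum TP),
normalized powers (LFn, HFn — note LFn + HFn = 1 by construction, so they
carry one degree of freedom), the power ratio, and the envelope features
LFiA/HFiA with their ratio. The 80% five-class accuracy is expected: the
three rest segments share identical generating parameters, so they are
mutually indistinguishable by design.

Restricting to the three distinct states, as in a Python session:

```python
import hrv2d as h
feats = h.read_features("demo/features.csv")
fset = h.LabeledFeatureSet(feats).restrict(["Rest 1", "Math", "Exercise"])
model = h.fit_categorizer_2d(fset)
h.categorization_accuracy(model, fset)            # 100.0
h.categorization_accuracy(h.fit_categorizer_1d(fset, "LFiA_ms"), fset)  # 79.6
h.categorization_accuracy(h.fit_categorizer_1d(fset, "HFiA_ms"), fset)  # 88.9
```

The preset amplitudes place the three states in an XOR-like layout — rest
and exercise coincide on the LF axis, math and exercise on the HF axis —
so each 1-D categorizer confuses one pair of states (best 88.9%) while the
joint 2-D view separates all three (100%). `hrv2d plot --scatter`-style
output is available via `hrv2d plot`, which draws the scatter over the
fitted SVM decision regions.

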