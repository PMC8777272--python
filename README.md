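# fouriermotion

Tools for studying how the larval zebrafish visual system processes
**Fourier motion energy** — the luminance-defined (first-order) component of
a moving stimulus — as opposed to second-order features such as edges and
contrast.

The central stimulus is the **missing-fundamental grating**: a square wave
whose fundamental Fourier component has been removed.  A square wave of
spatial period λ decomposes into odd harmonics with amplitudes ∝ 1/k:

```
s(x) = (4/π) Σ_{k odd} (1/k) sin(2πkx/λ)
```

Deleting the k = 1 term leaves the 3rd harmonic as the strongest component.
When the pattern is animated in jumps of λ/4, the 3rd harmonic advances by
three quarters of *its own* wavelength — indistinguishable from moving
**backwards** by one quarter.  The Fourier energy therefore moves opposite
to the pattern's edges, and an animal that tracks Fourier energy turns its
eyes the "wrong" way.  The package covers the full analysis chain of such an
experiment:

| module       | contents |
|--------------|----------|
| `stimulus`   | square / missing-fundamental / 3rd-harmonic grating synthesis, quarter-cycle animation, apparent-direction measurement, cylindrical-screen warp, presentation protocols |
| `okr`        | optokinetic-response analysis: saccade detection, pursuit/spontaneous sorting, group ANOVA |
| `imaging`    | two-photon movie hygiene (XY registration, movement-artifact z-scores), watershed nuclear segmentation, trace extraction, cross-animal affine mapping, quadrant labels |
| `events`     | ΔF/F against an 8th-percentile running baseline, robust noise model, Bayesian odds-ratio detection of significant calcium events constrained by the H2B-GCaMP6f decay constant (2.88 s) |
| `census`     | per-neuron response scores and z-scores, the responsiveness rule (≥ 4 significant frames in ≥ half of the repetitions), the 2⁶-pattern response census with a 0.1 % floor, Wilcoxon + Benjamini–Hochberg region comparison, spatial lateralization reports |
| `synthetic`  | ground-truthed generators for every stage: epoch-locked calcium traces, renderable nuclear movies, sawtooth OKR eye traces |

`pipeline.analyze_traces` chains the trace stages end to end, and the
`fouriermotion` command line exposes the common operations
(`stim`, `okr`, `img`, `events`, `synth` groups).

## Worked example

Simulate a reduced session (200 neurons, 5 repetitions of each of the six
moving stimuli, transient amplitude 5× the noise sigma) with two planted
"behavioral output" populations — neurons that respond to every stimulus
whose Fourier energy moves one particular way (SqL + MFR + 3hR and its
mirror) — biased 80 % toward the caudal half of the plane, then recover
everything from the raw traces:

```python
import fouriermotion as fm
from fouriermotion.pipeline import analyze_traces

protocol = fm.build_protocol(reps_per_direction=5, seed=1)
config = fm.SynthConfig(
    n_neurons=200, seed=1, snr=5.0,
    planted_patterns={1: 0.05, 2: 0.05, 8: 0.05, 41: 0.10, 22: 0.10, 12: 0.05},
    caudal_bias={41: 0.8, 22: 0.8},
)
raw, truth = fm.simulate_traces(config, protocol)
result = analyze_traces(raw, protocol)

profiles = result["profiles"]
print(f"responders: {profiles['responder'].sum()}")
print(profiles[profiles["responder"]]["label"].value_counts().head(4))

frame = fm.RegionFrame(midline=(0, 1, -128), region="pretectum",
                       rostrocaudal_divide=(1, 0, -128))
quadrants = fm.assign_quadrants(truth.positions[result["kept"]], frame)
report = fm.spatial_report(profiles, quadrants, patterns=[41, 22])
```

Output:

```
neurons kept by sanity filter: 200 / 200
responders: 81
most common response types:
  SqR+MFL+3hL   20 neurons
  SqL+MFR+3hR   20 neurons
  SqR           11 neurons
  SqL           10 neurons
SqL+MFR+3hR: 90.0% caudal (60.0% right hemisphere, n=20)
SqR+MFL+3hL: 75.0% caudal (30.0% right hemisphere, n=20)
```

All 80 planted responders (plus one borderline spontaneous neuron) are
recovered; the two composite populations come back with their exact 6-bit
patterns, and their planted 80 % caudal bias is recovered within binomial
error.  Pattern ids encode the six moving conditions as bits in the order
SqL, SqR, MFL, MFR, 3hL, 3hR (so 41 = SqL + MFR + 3hR).

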