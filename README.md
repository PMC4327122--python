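# imurehab

Activity recognition for frozen-shoulder rehabilitation exercises from
wireless inertial-sensor packets.

Streams of six-channel sensor packets (tri-axial acceleration + tri-axial
angular velocity, 8 packets/s per node, 128 ADC counts per channel) are
parsed, validated and calibrated into physical-unit samples.  Four feature
streams — the three acceleration components plus the *included angle*
between consecutive acceleration vectors — are cut into overlapping 25-s
windows (200 ticks, stride 150) and flattened into 800-long entries.  A
from-scratch back-propagation network (800 inputs, 5 log-sigmoid hidden
neurons, 6 linear outputs) is trained with a performance-goal target and
validation-based early stopping; recognition decodes each window to one of
six exercises.  Two feature-engineering analyses are included: a
characteristic-space module (per-window max/mean acceleration points,
cluster polygons, and a segment-intersection region-overlap test) and a
spectral module (one-sided FFT spectra, primary/secondary peak grouping,
20-tap FIR low-pass with 1-in-5 downsampling, spectrum enveloping, and
squared-magnitude-difference-driven selection of the envelope grid
parameters).

No public recordings exist for the original experiments, so a synthetic
simulator (`imurehab.synth`) stands in for the hardware: each exercise
template pins a waveform family (gentle / nodal / impulse), a peak included
angle, and per-axis tone frequencies, and the generator emits calibrated
sample streams and ADC packet logs (with an optional corruption model and
ground-truth manifest).

## Command line

```sh
# six packet logs (CSV), 3 windows each, plus ground-truth JSON
imurehab simulate --out-dir data/ --seed 1 --windows 3

# train (optionally sweeping PG values and data-set sizes) and score
imurehab train --data-dir data/ --out model.json --rates-out rates.csv \
    --pg 1e-5 --sizes 18,36,72 --seed 1

# decode windows from a packet log
imurehab recognize --model model.json --input data/ex3.csv --label 3 \
    --out-prefix out/ex3

# frequency-domain and characteristic-space analyses
imurehab export-samples --input data/ex3.csv --out ex3.samples.csv
imurehab spectrum --input ex3.samples.csv --channel az --out spec.csv \
    --envelope 0.115 0.1
imurehab charspace --data-dir data/ --axis z --out points.csv
```

Every output file embeds the seed and a hash of the effective
configuration.  `imurehab simulate --blind N` additionally emits N
synthetic blind-test subjects, each performing a random subset of the
exercises.

## Layout

| module | role |
| --- | --- |
| `packet_io` | packet log parsing (CSV/binary), validation/filtering, ADC-to-physical conversion, calibration config |
| `features` | included angle, window assembly, motion/target matrices, input scaling |
| `bpnn` | logistic sigmoid, forward pass, batch back-propagation with adaptive rate, early stopping, JSON model persistence |
| `recognition` | result-matrix computation, index clamping, argmax decoding, per-exercise rates |
| `charspace` | per-window (a_max, a_avg) points, convex cluster regions, segment-intersection overlap test |
| `spectral` | FFT spectra, peak grouping, FIR low-pass + downsampling, envelope, parameter selection |
| `synth` | exercise templates, signal generator, ADC packet encoder with corruption model |
| `pipeline` | end-to-end experiment orchestration |
| `cli` | `imurehab` command group |
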