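# aefpipe

Single-trial recognition of auditory evoked magnetic fields (AEFs) in MEG.

Event-related fields are usually recovered by averaging hundreds of trials,
which destroys trial-to-trial information. `aefpipe` implements a
single-trial alternative for researchers working with whole-head MEG: it
enhances each 0.3 s post-stimulus window using the spatial correlation
structure of neighboring sensors, renders the per-sensor signal energy as a
scalp topography image, and trains a convolutional network to recognize the
evoked activation pattern (energy concentrated over auditory cortex in the
temporal lobes) against empty-room noise topographies. A seeded synthetic
session generator provides physically grounded MEG data — dipole sources,
realistic noise and artifacts, and ground truth for every stage — so the
whole pipeline runs and is tested without any data download.

## Method

For each MEG sensor *i* a neighborhood is defined as all sensors within a
fixed radius (default 0.022 × 1.7 m, i.e. 1.7 × the mean inter-sensor
spacing of a 274-channel whole-head array). On each single trial, the
Pearson correlation between the selected signal X<sub>i</sub> and each
neighborhood signal X<sub>j</sub> is

c<sub>ij</sub> = (E[X<sub>i</sub>X<sub>j</sub>] − E[X<sub>i</sub>]E[X<sub>j</sub>]) / √(Var X<sub>i</sub> · Var X<sub>j</sub>)

Neighbors with |c<sub>ij</sub>| ≥ 0.8 qualify; with Q the qualifying set and
n = |Q|, the enhanced signal is

- n = 0:  X′<sub>i</sub> = X<sub>i</sub> (noise-dominated channels are left alone)
- n = 1:  X′<sub>i</sub> = X<sub>i</sub> + c<sub>ij</sub> X<sub>j</sub>
- n ≥ 2:  X′<sub>i</sub> = X<sub>i</sub> + (Σ<sub>j∈Q</sub> c<sub>ij</sub> X<sub>j</sub>) / (n − 1)

A genuine evoked field is coherent across adjacent sensors and gets
amplified; uncorrelated sensor noise does not. The per-channel energy
Σ<sub>t</sub> X′<sub>i</sub>(t)², normalized to max 1, is interpolated over
the projected scalp disc into a 224 × 224 RGB image and classified
(aef vs noise) by a compact CNN trained with dropout 0.6, learning rate
1e-4, 10 epochs, and a stratified 80/20 train/validation split.

Upstream of the enhancement, each session is cleaned exactly as an MEG
practitioner would: stimulus onsets are marked from the audio channel
(the sound reaches the subject ~0.13 s after the electrical trigger), blink
and cardiac artifacts are marked from the bipolar EOG/ECG and removed by
signal-space projection, alpha/beta rhythms at 10/11/20/21 Hz are notched
out (2nd-order IIR, 2 Hz −3 dB bandwidth each), and an even-order
linear-phase FIR low-pass at 40 Hz with ≥ 60 dB stopband attenuation removes
high-frequency noise including the 60/120/180 Hz line harmonics. Trials
whose maximum channel power exceeds median + 10 × MAD across trials are
screened out.

## Worked example

A desk-scale experiment — two simulated 80 s sessions of 40 stimuli plus an
empty-room noise session, full pipeline, default classifier:

```python
import json
from aefpipe import PipelineConfig, SynthScenario, ClassifierSpec, run_pipeline

cfg = PipelineConfig(
    scenario=SynthScenario(n_stimuli=40, session_length=80.0,
                           noise_session_length=30.0, seed=0),
    classifier=ClassifierSpec(seed=0),
    test_n_stimuli=40, n_noise_train=40, n_noise_test=40, seed=0,
)
metrics = run_pipeline(cfg)
print(json.dumps(metrics["stages"]["train_session"], indent=1))
print(metrics["training_source_accuracy"], metrics["testing_source_accuracy"])
```

prints

```
{
 "stimuli_detected": 40,
 "stimuli_truth": 40,
 "artifacts_detected": 91,
 "trials_segmented": 40,
 "trials_kept": 40,
 "trials_rejected": []
}
1.0 1.0
```

All 40 stimulus onsets in the training session were recovered from the audio
channel, no trial was screened out as a power outlier, and the trained
classifier separates the held-out session's evoked-field images from unseen
noise images with accuracy 1.0 (100%). The same run is available from the
shell:

```bash
aefpipe run-all --seed 0 --out out/   # full-size default experiment
aefpipe simulate --seed 0 --out sim/  # just write the sessions + ground truth
```

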