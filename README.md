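# ssvepsr

Untrained SSVEP decoding with CCA spatial filtering and underdamped
second-order stochastic resonance.

Steady-state visual evoked potentials (SSVEPs) let a brain-computer
interface tell which of many flickering or moving targets a subject is
gazing at, from a few seconds of occipital EEG.  Ring-shaped motion
checkerboards are comfortable to watch but evoke a response with almost
no harmonics and tightly concentrated spectral energy, where the standard
untrained recognizers — canonical correlation analysis (CCA) and
filter-bank CCA (FBCCA) — lose accuracy.  This package implements a
decoding pipeline that enhances the weak target-frequency response with a
nonlinear bistable filter before recognition:

1. **Band-pass** the raw epoch (Butterworth 3–40 Hz, zero-phase).
2. **Reduce** the 8 channels to one signal — CAR, PCA, MDS, LLE, or a CCA
   projection `w_xᵀX` fitted against sinusoidal reference templates.
3. **Enhance** with the underdamped second-order stochastic-resonance
   (USSR) system `x'' = a x − b x³ − β x' + s(t) + n(t)`, integrated by
   fixed-step RK4 (`[a, b, β, h] = [0.1, 1, 0.35, 0.1]`), which converts
   broadband noise energy into response at the drive frequency.
4. **Recognize** the frequency by CCA correlation or exact
   single-frequency spectral power (PSDA) against templates
   `Y_f = [cos 2πft; sin 2πft; cos 4πft; sin 4πft]`.
5. **Classify** as the stimulus frequency with the maximal score, and
   report accuracy and the information transfer rate
   `ITR = (60/T)[log₂M + σlog₂σ + (1−σ)log₂((1−σ)/(M−1))]` bits/min.

Because matched multichannel recordings are not redistributable, the
package includes a seeded synthetic generator emulating the recording
setup (8 occipital channels, 1 kHz, 3 s trials, 35 targets at 3–20 Hz in
0.5 Hz steps, weak first harmonic, 1/f + white background), plus a
42-subject reference benchmark table used to validate the ITR
arithmetic.  See `docs/methods.md` for the full model description.

## Worked example

```python
import ssvepsr as s

freqs = s.stimulus_grid()                      # 3-20 Hz, 0.5 Hz: 35 targets
base = s.SyntheticConfig(f_target=3.0, duration=2.0, snr_db=-16.0)
epochs = s.generate_dataset(freqs, 2, base, seed=123)   # 70 labelled trials

for method in ("cca", "fbcca", "cca_ussr"):
    rep = s.evaluate_method(epochs, method, freqs)
    print(f"{method:9s} accuracy {rep.accuracy_pct:5.1f}%   "
          f"ITR {rep.itr_bits_per_min:6.2f} bits/min")
```

```
cca       accuracy  60.0%   ITR  63.70 bits/min
fbcca     accuracy  72.9%   ITR  87.15 bits/min
cca_ussr  accuracy  67.1%   ITR  76.33 bits/min
```

Seventy simulated 2 s trials at the default −16 dB SSVEP-to-background
ratio: plain CCA sits at its calibrated ~60% operating point, and
routing each candidate's CCA projection through the stochastic-resonance
filter (`cca_ussr`) recovers a further ~7 points of accuracy and
~13 bits/min.  An accuracy of 60% over 35 classes every 2 s corresponds
to 63.7 bits/min through the ITR formula above.

The same pipeline is scriptable from the shell:

```bash
ssvepsr fixtures  --out fx --seed 1                  # canonical synthetic sets
ssvepsr decode    --input fx/noiseless --out out --method cca_ussr
ssvepsr spectrum  --input fx/noiseless/epoch_000_f3.npz --out spec.csv
ssvepsr benchmark --config my.yaml --out bench --seed 1
```

`decode` writes a per-epoch prediction table, `spectrum` the 1–40 Hz
coefficient spectrum (79 points), and `benchmark` a Table-style CSV/JSON
of accuracy and ITR for each configured method × data length.  All
commands are deterministic given a config and seed, and every constant of
the pipeline lives in a validated YAML/JSON config.

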