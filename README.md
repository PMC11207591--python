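# semgrip

Grip-force monitoring from wireless surface electromyography (sEMG), end to
end: decode the acquisition terminals' binary packet protocol, preprocess
two-channel forearm sEMG, extract sliding-window features, and predict grip
force as a percentage of maximum voluntary contraction (%MVC) with a Random
Forest whose hyperparameters are tuned by the bald eagle search (BES)
metaheuristic. The package also implements the agreement metrics used to
validate a wearable acquisition system against a commercial reference, and a
synthetic-session generator so every stage runs and is testable without
recorded subject data.

## Who this is for

Researchers and engineers building sEMG-based muscle-status monitors
(rehabilitation, training, prosthetics) who need a reproducible software
reference for the acquisition-to-prediction chain: a bit-exact packet codec,
a standard EMG preprocessing pipeline, the classic time/frequency feature
set, and metaheuristic hyperparameter tuning of a regression forest.

## The method

**Acquisition protocol.** Each wireless terminal samples one muscle at
1000 Hz with a 12-bit ADC (3.3 V reference, signal offset to a 1.65 V
baseline) and transmits one 116-byte packet every 50 ms: 2-byte header,
4-byte frame sequence, 6-byte MAC, fifty 16-bit samples, 2-byte end-of-data
flag, 2-byte trailer. Streams are reconstructed per MAC in frame order;
lost frames are reported as gaps, never interpolated.

**Preprocessing.** Segments (manually annotated contractions) are band-pass
filtered 20–490 Hz with a zero-phase 4th-order Butterworth filter, full-wave
rectified, and normalized by the subject's MVC amplitude:

    sEMG_nor = sEMG_task / sEMG_MVC × 100  [%MVC]

**Features.** Windows of 256 ms with a 56 ms step; per window and channel:
integrated EMG `iEMG = (1/N) Σ|x_i|`, root mean square
`RMS = √((1/N) Σ x_i²)`, waveform length `WL = Σ|x_{i+1} − x_i|`, Shannon
entropy of the amplitude histogram (bits), and the median (MF) and mean
power frequency (MPF) of the Hann-tapered periodogram.

**Model.** A Random Forest regressor maps feature vectors to %MVC. BES
minimizes the fitness `MSE_train + MSE_test` over
`(n_estimators, min_samples_leaf)` through its three phases (select space,
search prey, swoop) with greedy acceptance; evaluation reports
`MAE`, `MSE`, and `R² = 1 − Σ(p_i − f_i)² / Σ(f_i − f̄)²`.

**System agreement.** Processed waveforms of two systems are envelope
smoothed, lag-aligned, and compared with the cross-correlation coefficient
(CCC ∈ [−1, 1]) and the relative agreement of RMS amplitudes
`1 − RE = (1 − |x − y|/y) × 100 %` against the reference system `y`.

## Worked example

The whole chain on one synthetic session (two channels; one MVC trial plus
contractions at 80/60/40 %MVC):

```sh
semgrip simulate --seed 1 --out sim
semgrip decode --stream sim/packets.bin --out dec
semgrip preprocess --streams dec/streams.csv \
    --annotations sim/annotations.csv \
    --channel-map sim/channel_map.csv --out pre
semgrip features --segments pre/segments.csv --out feat/features.csv
semgrip tune --features feat/features.csv --out tun --seed 1 \
    --pop-size 5 --max-iter 5 --max-trees 200
semgrip train --features feat/features.csv \
    --params tun/best_params.json --out model.joblib --seed 1
semgrip evaluate --features feat/features.csv --model model.joblib \
    --out report.json --seed 1
```

prints

```
wrote 680 packets for 2 channels to sim
decoded 680 packets -> dec/streams.csv
wrote segments for 2 channels to pre
wrote 200 feature rows -> feat/features.csv
best params: n_estimators=18 min_samples_leaf=1 fitness=8.4480
model -> model.joblib
R2=0.9897 MAE=0.7593 MSE=5.9877
```

Reading the numbers: the 17 s session becomes 680 packets (2 channels ×
20 packets/s), 4 annotated contractions give 4 × 50 = 200 feature windows,
BES picks a small forest whose summed train+test MSE is 8.45 (%MVC)², and
on the held-out 30 % of windows the model explains 99 % of the force-label
variance with a mean absolute error of 0.76 %MVC. Synthetic sessions are
cleaner than real recordings, so these scores are an upper bound on what
the same pipeline achieves on real muscle data.

The same workflow is available as a library:

```python
from semgrip import SynthConfig, SplitConfig, generate_feature_dataset, tune_train_evaluate

ds = generate_feature_dataset(2, SynthConfig(seed=1))
tuned, report, _ = tune_train_evaluate(ds, SplitConfig(seed=1))
print(report.r2, report.mae, report.mse)
```

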