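# tastechip

Signal analysis for a taste organoids-on-a-chip bioelectronic tongue,
plus a ground-truthed simulator of the chip itself.

The system this package models couples taste organoids — self-organising
cultures containing type II (sweet/bitter-sensing), type III
(sour-sensing) and salt-sensing taste receptor cells — to a 64-electrode
microelectrode array (MEA). Each electrode records the extracellular
potential of the cells above it; tastant identity and concentration are
read out computationally:

1. **Spectral features** — a Hamming short-time Fourier spectrogram per
   channel; mean power spectral density (µV²/Hz) in the five bands
   δ (0–4 Hz), θ (4–8), α (8–12), β (12–30), γ (30–40).
2. **Spike features** — events where |signal| exceeds 3× the trace SD;
   fire rate, maximum and average peak-to-peak amplitude.
3. **Electrode specificity** — channels whose total band PSD rises ≥2-fold
   over baseline for exactly one tastant are kept.
4. **Recognition** — the 8-parameter vectors (5 band PSDs + 3 spike
   features), averaged per replicate chip, are standardised, projected on
   3 principal components and clustered (Ward linkage on condition
   centroids, cluster count chosen by silhouette). The lowest tested
   concentration that does not share the control's cluster is the
   chip's detection threshold for that tastant. Group statistics use
   ordinary one-way ANOVA with uncorrected Fisher's LSD.

Because no recordings from such a chip are public, `tastechip.simulate`
generates synthetic 64-electrode recordings whose spike rates, lognormal
spike amplitudes and band powers vary with tastant and concentration
according to the reported dose-response behaviour of the preparation
(acetic acid, sucrose, phenylthiocarbamide, NaCl), with per-channel
ground truth. `docs/methods.md` describes the generative model, its
calibration and its limits.

## Worked example

Simulate and analyse a sucrose dose-response experiment (control plus
1, 0.75, 0.5, 0.25, 0.125 g/mL; three replicate chips; 48 electrodes,
60 s per stimulus):

```
$ tastechip report --tastant sweet_sucrose --seed 7 \
      --duration 60 --electrodes 48 --out report/
k=5 clusters, detection threshold=0.25; manifest at report/manifest.json
```

The six conditions cluster into **5 types**, the lowest concentration
(0.125 g/mL) sharing a cluster with the control — so the chip's sucrose
detection threshold is **0.25 g/mL**. `report/summary.csv` holds the
per-condition feature means; for this run the recovered fire rate /
average amplitude were:

| sucrose (g/mL) | fire rate (spikes/s) | mean amplitude (µV) |
|---------------:|---------------------:|--------------------:|
| 0 (control)    | 0.060                | 0.7                 |
| 0.125          | 0.058                | 0.2                 |
| 0.25           | 0.101                | 18.9                |
| 0.5            | 0.193                | 51.4                |
| 0.75           | 0.240                | 49.2                |
| 1.0            | 0.191                | 37.4                |

reproducing the non-monotone response profile (peak near 0.75 g/mL) the
simulator plants. The report directory also contains the per-channel
feature matrix, radar-normalised table, ANOVA/LSD statistics, PCA scores
with cluster labels, the specificity mask and a JSON manifest; identical
config + seed reproduces every file byte-for-byte. Add `--figures` for
trace/spectrogram/radar/PCA plots, or use the `simulate`, `analyze` and
`classify` subcommands for the individual stages.

The same flow in Python:

```python
from tastechip import PipelineConfig, Tastant, run_full_pipeline

report = run_full_pipeline(
    PipelineConfig(seed=7, duration_s=60, n_electrodes=48),
    Tastant.SWEET_SUCROSE,
)
print(report.clusters.k, report.threshold)   # 5, 0.25
```

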