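# eyeflow

Quantitative analysis of periodic epithelial cell flows at the
morphogenetic furrow (MF) of the developing *Drosophila* eye, with a
synthetic ground-truth movie generator for end-to-end validation.

## The problem

The eye imaginal disc patterns a precise triangular lattice of
photoreceptor clusters (ommatidia). Live imaging shows that as the MF — a
stripe of apically constricted cells — sweeps anteriorly at ~1.44 µm/hr,
cells inside it flow anteriorly in alternating clusters: groups moving
with the furrow (1.2–1.5 µm/hr) interleaved along the dorsoventral (DV)
axis with groups slowing to 0.35–0.55 µm/hr, at a fixed DV period of
14.17 µm (the lattice spacing of R8 founder cells) and a temporal phase
that flips every ~2 h (a ~4 h period, the time to form two ommatidial
columns). The flow is generated by a narrow stripe of cell dilation ~10 µm
posterior to the MF (the source) and of contraction ~10 µm anterior (the
sink), and is focused into a periodic profile by the immobile ommatidia of
the three youngest columns. Loss of the secreted glycoprotein Scabrous
reduces the maximal dilation rate by ~75% and collapses the periodic flow.

`eyeflow` implements the measurement chain behind those numbers, for
anyone analysing junction-labelled epithelial time-lapse movies of this
kind:

* `eyeflow.synth` — ground-truth movie generator: prescribes the flow
  field (source/sink lobes, DV-periodic stripe, immobile columns),
  advects cells, and renders intensity / boundary-probability / label
  stacks with full per-cell ground truth;
* `eyeflow.segment` — watershed cell detection on boundary-probability
  maps (h-minima seeds, ridge reassignment so labels partition the frame)
  and per-cell geometry;
* `eyeflow.track` — Hungarian frame-to-frame linking with a distance
  gate, lineage-aware tracks, birth/death/border endpoint classes;
* `eyeflow.furrow` — MF localization: the most anterior prominent peak of
  the DV-summed, Gaussian-diffused intensity image, smoothed over time;
* `eyeflow.kinematics` — per-cell velocity and area-change rate
  (12-frame central differences), MF-relative offsets, shape index;
* `eyeflow.periodicity` — velocity interpolation to a 1 µm grid, per-row
  DV magnitude spectra by MF-relative bin, dominant-period estimation,
  odd/even parity profiles and window-averaged autocorrelation;
* `eyeflow.profiles` — MF-aligned sliding profiles, the six fixed AP
  bins (+15…−20 µm; the posterior transition zone is −7.5…−12.5 µm),
  division histograms, bootstrap CIs, Mann-Whitney −log10(p);
* `eyeflow.cellstate` — backward fate propagation along lineages,
  reporter-intensity trajectories aligned on rosette closure, R8 lattice
  spacing, pixel-contact tests;
* `eyeflow.pipeline` / `eyeflow.cli` — orchestration, TIFF/CSV/YAML I/O,
  rigid-translation registration fallback, and the `eyeflow` command.

See `docs/methods.md` for the model, parameter defaults, and the design
choices (and their limitations).

## Worked example

Generate a wildtype synthetic movie with the study presets (10 h at 5 min
frames, 60 × 56.68 µm field), run the full chain, and print the summary:

```
$ eyeflow run-all --seed 1 --out runs/wt
wrote runs/wt/summary.json
  autocorr_max_lag_hr: 4.0202
  autocorr_min_lag_hr: 2.0038
  census: {'full_span': 0.654321, 'border': 0.143659, 'birth': 0.121212, 'death': 0.080808}
  dilation_peak_position_um: -9.75
  dilation_peak_um2_per_hr: 0.7609
  dominant_period_confident: True
  dominant_period_um: 14.2262
  mean_r8_spacing_um: 14.4035
  mf_speed_um_per_hr: 1.4501
  n_kinematic_records: 72364
  n_tracks: 891
  parity_anticorrelation_r: -0.9481
```

Reading the headline numbers: the furrow trace recovers the generating MF
speed (1.45 vs 1.44 µm/hr); the row-wise Fourier analysis of the gridded
anterior-velocity field finds the DV flow period (14.23 vs 14.17 µm),
matching the measured R8 spacing (14.40 µm); the window-averaged
autocorrelation of cluster velocities is maximally anti-correlated at a 2 h
lag and correlated again at 4 h, with odd and even rows oscillating in
anti-phase (r = −0.95); and the rate-of-area-change profile peaks at
−9.75 µm, the dilation source posterior to the MF. The output directory
also holds the per-stage CSVs (tracks, kinematic records, furrow trace,
profiles, spectra, autocorrelation, fates) with units declared in their
header lines.

The `synth`, `segment`, `track`, `furrow` and `analyze` subcommands run
individual stages; `--preset scabrous` generates the mutant condition
(dilation lobe and flow-modulation depth scaled by 0.25, contraction
untouched).

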