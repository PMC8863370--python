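# Methods

## The system and the measurement problem

During *Drosophila* eye development a dorsoventral indentation of apically
constricted cells — the morphogenetic furrow (MF) — sweeps anteriorly across
the eye epithelium at ~1.4 µm/hr, leaving behind a triangular lattice of
5-cell photoreceptor rosettes (ommatidia: R2, R3, R4, R5 around the R8
founder). Live imaging of this process shows that cells inside the MF are
not stationary: they flow anteriorly in coherent clusters of 15–25 cells,
alternating along the DV axis between high flow (~1.2–1.5 µm/hr, matching
the MF itself) and low flow (~0.35–0.55 µm/hr), with a DV spatial period of
14.17 µm — the spacing of neighbouring R8 cells within a column — and a
temporal phase that flips every ~2 hr, giving a ~4 hr period, the time to
form two ommatidial columns. The flow is fed by a narrow stripe of cell
dilation ~10 µm posterior to the MF (the source; coinciding with the
"posterior transition zone", PTZ) and drained by a stripe of contraction
~10 µm anterior (the sink). Newly formed ommatidia in the three youngest
columns are immobile and act as obstacles; in *scabrous* mutants the
maximal dilation rate drops by ~75%, the periodic component of MF flow
collapses, and the lattice becomes disordered, while contraction anterior
to the MF is unchanged.

This package implements the measurement chain that quantifies those
statements from segmented/tracked movies, together with a synthetic movie
generator that encodes them as ground truth, so every stage of the chain
can be validated end to end without microscopy data.

## The synthetic generator

**Kinematic, not mechanical.** The generator prescribes a deterministic
velocity field rather than solving a pressure/force model. The analysis
modules consume kinematics only, and a prescribed field gives exact
oracles: the spatial period, temporal period, MF speed and dilation
contrast of a generated movie are known by construction.

**Baseline AP profile.** The anterior-positive AP velocity along the MF
offset axis `s` (anterior positive, MF at 0) is the sum of a dilation
(source) lobe and a contraction (sink) lobe. Each lobe is zero at its own
offset (±10 µm), rises sinusoidally over 2.5 µm toward the MF to a plateau,
and carries a recirculation tail of opposite sign on its far side (half
amplitude, 2.5 µm long, slope-matched at the zero crossing so the
strain-rate profile has no kink at the source). The lobes crossfade
smoothly (smoothstep over ±2 µm) at the MF, so when their amplitudes are
equal the baseline is exactly flat — at (high+low)/2 = 0.9 µm/hr — across
the stripe −7.5…+7.5 µm. Cells are advected by forward Euler at the frame
interval plus Gaussian centroid jitter (default SD 0.05 µm/frame, a
sub-pixel tracking-noise scale).

Because the source and sink ride with the MF, every cell drifts through
the pattern in the co-moving frame, and apical-area dynamics emerge from
continuity rather than being scripted: cells compress ~2.7× crossing the
contraction zone into the MF (apical constriction), stay compressed through
the stripe, and dilate back crossing the source. The dilation-rate peak
therefore sits at the source, where cell area equals the far-field area in
every genotype — which is what makes the wildtype/mutant peak ratio equal
the programmed dilation factor.

**Periodic stripe.** Within the stripe (−7.5…+2.5 µm, 1 µm cosine edge
ramps) the AP velocity alternates along DV between the high-flow and
low-flow values as a clipped cosine (gain 8, so the plateaus span ~92% of
each half period — coherent clusters of ~15–21 cells; a pure sinusoid is
available via `waveform="sine"`). The phase flips instantaneously every
half temporal period. Odd-parity rows sit at (k+¼)·14.17 µm, even rows half
a period away.

**Ommatidial columns.** One column is deposited per 2.0 hr — exactly half
the temporal period, because a column forms at every phase flip and the
4 hr period is the time to form two columns. Parity alternates between
consecutive columns structurally. At deposition (at the posterior edge of
the MF, s = −2.5 µm, where multicellular arcs form), the up-to-5 unfated
cells within 1.2 cell diameters of each lattice site become the R8 (the
nearest) and R2/R3/R4/R5 of a new ommatidium and freeze; the flow field is
zeroed over cell-sized discs (0.7 µm) at the positions the frozen cells
occupy. A column is released — rejoins the ambient flow abruptly — once
three younger columns exist, which places the release at the PTZ.

**Births, deaths, reporter.** Divisions occur only in the anterior
proliferation stripe (+10…+20 µm) and the narrow posterior stripe
(−7…−12 µm, non-ommatidial cells only), at 0.006 /cell/hr; delaminations
are uniform at 0.004 /cell/hr (instantaneous removal — the progressive
apical constriction of a delaminating cell is not emulated because cell
area is Voronoi-emergent). At a division the parent id continues as one
daughter; only the second daughter receives a new id, which is how a
tracker follows a division and what makes the census arithmetic (births ≈
6%, deaths ≈ 4% of cells) well defined. The junctional-reporter level per
cell relaxes (1/hr) toward a target that is uniform and elevated in the MF
and bifurcates at MF exit: R-fated cells rise above the MF level, non-R
cells fall below the progenitor level.

**Burn-in and seeding.** The movie opens mid-development: a 4 hr lead-in
is simulated before frame 0 so the density lanes and reporter field are in
their quasi-steady oscillation, as in a real recording. Initial centroids
are variable-radius Poisson-disc samples; anterior of the deposition line
the spacing follows the advective steady state (area ∝ MF-frame drift),
posterior of it the tissue is seeded relaxed, because column deposition
continually extracts most of the mobile flux there.

**Rendering.** The label stack is the Voronoi partition of the centroids
(nearest-centroid rasterization); the boundary-probability channel is the
blurred (σ = 1 px) edge skeleton plus Gaussian noise (SD 0.02), standing in
for a pixel classifier's output; the intensity channel paints each cell's
edges with its reporter level. Default sampling is 0.15 µm/px, ≥6 px
across the smallest (furrow-constricted) cells, matching the sampling the
imaging study required for segmentation.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: 3D surface curvature (the ~1.5% AP distance
error of projecting a curved epithelium), the DV equator-to-margin
maturation gradient (which in real spectra adds near-zero-frequency peaks),
photobleaching (available as a linear-decay flag, default off), ommatidial
rotation, mechanical feedback of crowding on velocity, T1-driven
intercalation dynamics, and the progressive constriction of dying cells.
The tissue is DV-periodic, which real fields of view are not.

## Analysis parameters (defaults)

| parameter | value | why |
|---|---|---|
| watershed smoothing σ | 1 px | noise suppression before h-minima seeding |
| h-minimum depth | 0.05 × dynamic range | rejects shallow spurious basins |
| minimum region | 4 px² | merges slivers into the largest neighbour |
| linking gate | 2.0 µm/frame | ~15× the per-frame displacement at MF speeds; lets births/deaths emerge from the assignment |
| division area drop | 30% | flags daughter/parent pairs for review |
| MF profile σ | 10 px | diffuse before DV-summing the intensity image |
| MF peak prominence | 0.1 × profile range | guards against the MF peak merging with column 1 |
| trace smoothing | 3-frame centred mean | adjacent-time-point averaging |
| kinematic window | 12 frames (1 hr) | the timescale at which deterministic motion emerges from positional noise |
| interpolation grid | 1 µm | spectral sampling of the velocity field |
| low-frequency cutoff | periods > H/2 excluded | removes long-wavelength (maturation-gradient-like) structure |
| search windows | 2.5 × 2.5 µm at the odd/even rows, riding the MF | cluster-velocity time series |
| sliding window | 0.5 µm, half-open [p, p+0.5) | 1D MF-aligned profiles |
| AP bins | +15, +7.5, +2.5, −2.5, −7.5, −12.5, −20 µm | six fixed MF-relative zones (PTZ = −7.5…−12.5) |
| stationary interval | frames 7–60 | profiles/spectra/distributions |
| bootstrap | 1000 percentile replicates, seeded | 95% CIs of means |

Mann-Whitney U tests are two-sided, exact for untied samples with n ≤ 20
and normal-approximated with tie correction otherwise, reported as
−log10(p) with an `inf` sentinel on underflow and no multiple-testing
correction. Kernel densities use Silverman bandwidth.

## Numerical and design choices

* **Axis conventions.** Anterior is decreasing image x (a config flag);
  every reported velocity and MF offset is anterior-positive. DV-positive
  = increasing row index; the choice is arbitrary and only consistency
  matters.
* **Watershed ridges** are assigned to the adjacent basin whose mean
  boundary value is lowest, so labels partition the frame (the area
  analyses need a partition, not a skeleton). A constant map yields one
  label covering the frame.
* **Segmentation accuracy** is one-to-one IoU > 0.5 per true cell; a
  merged prediction fails both participants.
* **Linking** minimizes total centroid distance with a per-cell dummy cost
  equal to the gate; matches beyond the gate are forbidden outright, and
  ties are broken lexicographically via an infinitesimal index-dependent
  cost offset.
* **Spectra** average DFT magnitudes (not complex values, whose phases
  would cancel across rows and frames; not power) after removing each
  row's mean; rows with >20% masked nodes are skipped, remaining masked
  nodes are filled with the row mean. Peak frequencies are refined by
  3-point parabolic interpolation.
* **Autocorrelation** is the per-window Pearson correlation of the series
  with its lagged self, missing frames excluded pairwise; curves are
  averaged across windows and the extremum lags are refined by a
  least-squares parabola over ±0.5 hr. On a 10 hr movie (2.3 periods) the
  finite-series scatter of the extremum lags is ~±0.1 hr, so temporal-
  period recovery uses the 16 hr `wildtype_extended` preset (4 periods).
* **Profile peaks** are read off a 1.5 µm moving-line average of the
  sliding profile: the maximum of a noisy curve is biased upward by the
  point noise, and the bias — additive and genotype-independent — would
  otherwise compress the wildtype/mutant peak ratio. The dilation-peak
  contrast additionally pools every valid frame (the 7–60 restriction
  guards against late-movie culture degradation, which the generator does
  not emulate) and uses a 10% trimmed window mean as a stand-in for the
  manual track curation of the published datasets.
* **Cluster bimodality** (wildtype high/low flow, lost in the mutant) is
  assessed on the per-search-window mean velocities: single-cell
  histograms at the default jitter are washed out because half of all
  1 hr central-difference windows straddle a phase flip.
* **Fate propagation** walks parent links backward; conflicting fates
  reaching one ancestor raise an error (the pipeline then falls back to
  unpropagated terminal annotations and logs it). On synthetic runs the
  terminal annotations come from matching ground-truth R cells to tracked
  cells by majority vote along their fated lifetime.
* **R8 spacing** uses DV-sorted adjacent pairs within each annotated
  column, restricted to frames at which the column exists; before its
  deposition a future R cell is an ordinary flowing cell and carries no
  lattice information in this generator (unlike the real tissue, where
  the periodic flow pre-positions them).
* **Degenerate inputs**: flat boundary maps segment to a single region;
  empty assignment inputs yield empty assignments; single-element
  bootstrap samples give degenerate CIs; a mutant movie without a
  periodic flow component has no autocorrelation extrema and the summary
  omits those keys.

## Problem sizes

The default study fixture is a 60 × 56.68 µm field (the DV extent is
exactly four flow periods, so spectral fixtures are leakage-free) imaged
for 10 hr at 5 min intervals, ~850–900 cells per frame at 0.15 µm/px; the
temporal fixture is 72 µm wide, 16 hr, at 0.2 µm/px. The acceptance script
analyses two wildtype replicates, each paired with a scabrous movie from
the same seed, plus one extended movie; a full run takes a few minutes on
one CPU. Bootstrap CIs in the scripted runs use 200 replicates.
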