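# Methods

## The measurement being modelled

A gold nanohole-array substrate supports an extraordinary-optical-transmission
(EOT) resonance (λ₀ = 860.7 nm in water, FWHM Γ = 22.6 nm). A PDMS micromesh
on top of it forms open microwells (200 μm diameter, 50 μm height, ≈1.5 nl),
each holding at most one cell, with empty wells kept as references. The chip
is illuminated by a narrowband near-infrared LED that overlaps one flank of
the resonance, and an sCMOS camera records the transmitted intensity. When a
cell secretes — e.g. IgG captured by protein A/G on the gold — the local
refractive index rises and the resonance redshifts, so the transmitted
intensity at each affected camera pixel changes. A time-lapse of such images
therefore encodes a spatially resolved binding sensorgram around each cell.

`secretomap` turns those time-lapses into 4D secretion maps
(x, y, intensity-change, time), total-intensity-change (TIC) and
secretion-area curves, kinetic rates, and a per-cell secretion-type label.

## Processing chain

1. **Cropping and pairing** (`io`). Each sensing well is cropped to a square
   window (350 px in the published configuration) and paired with a reference
   well of identical frame count and timing. The effective pixel size is
   `pitch × binning / magnification` and is deliberately a configurable
   scalar: with the published 4.25 μm pitch and ×20 objective it is
   0.2125 μm/px, which cannot place a 200 μm well inside a 350 px crop, so
   the true acquisition must involve binning or downsampling that the source
   does not state. Nothing downstream assumes a fixed scale.

2. **Cell tracking** (`features`, `tracking`). Pixels are described by a
   37-channel multi-scale filter bank: Gaussian at σ ∈ {0.3, 0.7, 1.0, 1.6,
   3.5, 5.0, 10.0} px, and at the six scales ≥ 0.7 px one channel each for
   Laplacian of Gaussian, Gaussian gradient magnitude, difference of
   Gaussians (σ vs 0.66σ), the larger structure-tensor eigenvalue and the
   larger Hessian-of-Gaussian eigenvalue. The eigenvalue families contribute
   one channel per scale — that is the only reading under which the channel
   arithmetic (7 + 5×6 = 37) closes. A 100-tree random forest trained on
   sparse cell/background labels yields a background-probability map
   (0 = cell), which is mean-filtered (3×3 default), Otsu-thresholded, and
   accumulated over time into the cumulative mask of every pixel the cell
   ever occupied. Track metrics (centroid, area, boundary, MSD relative to
   the first frame) come from the largest connected component per frame.

3. **Secretion mapping** (`mapping`). Difference images ΔI(t) = |I(t) − I(0)|
   are Gaussian-smoothed (σ = 1.5 px), then gated by the per-frame level
   μ + 3σ of a small ROI (default 50×50 px, centred) in the paired
   reference well's difference image; values below the level clamp to zero,
   making it a one-sided noise gate. The microwell border is found by a
   circular Hough transform on an Otsu-thresholded Sobel edge map; pixels
   outside the circle are zeroed. Analysis is restricted to an automatic
   annulus between the dilated final cumulative mask (4 px — wide enough
   that the σ = 1.5 smoothing tail of the high-contrast cell edge cannot
   leak through) and the circle eroded by a 10 px margin (edge artefacts).
   Optional iterative K-means pruning removes difference clusters that are
   both small (< 20 px) and far from the cell (> half the well radius).
   Finally the maps are multiplied by the complement of the cumulative mask,
   so nothing the cell ever touched contributes.

4. **Kinetics** (`kinetics`). TIC is the per-frame sum of non-zero map
   pixels; area is the non-zero count times the physical pixel area. Onset
   is the first sustained TIC above the noise floor (see below). A plateau
   begins when, after at least one rising step, three successive steps each
   increase by ≤ ε·max(TIC), and ends when three successive steps each
   increase by more; ε defaults to 0.5% of the maximum (ε = 0 reproduces the
   literal no-increase rule). Types: no plateau → I; plateau to the curve
   end → II; plateau followed by a fittable second rise → III. Fits are
   least-squares lines, slopes per hour: onset → 80% of maximum for I/II;
   for III, onset → 80% of the plateau mean and plateau end → 80% of
   maximum. Duration is the fitted-interval length (sum of both for III);
   the plateau never counts. Population summaries use sample (n−1) standard
   deviations and percentages to one decimal.

## Noise gating: the choices that needed making

- **ε = 0.005, not 0.01.** For a 73-frame full-range linear curve the mean
  per-frame increment is ≈1.4% of the maximum, so a 1% tolerance classifies
  most early ramp steps as "not increasing" and fabricates plateaus on
  type I curves. 0.5% sits between the plateau fluctuation scale (< 0.2% of
  max under the default noise model) and the minimum ramp step (≈0.7%).
- **Noise floor.** The reference well, processed exactly like a sensing
  well against its own μ + 3σ level, still shows a small positive residual
  TIC: the clamp keeps the ~0.1% of pixels above the one-sided 3σ gate. The
  NS floor is the mean plus 5× the standard deviation of that residual
  series. A floor built from the standard deviation alone would sit below
  the residual's own mean and flag every empty well as secreting.
- **Onset uses the floor and 3-frame persistence.** Literal "first TIC > 0"
  fires at frame 1 on any data with noise, for the same residual reason.
  Classification therefore takes onset as the first TIC above the noise
  floor sustained for three successive frames (the same three-frame motif
  as the plateau rules); `detect_onset` itself defaults to the literal
  rule. On simulated scenes this recovers the true onset within 2 frames.
- **A "further rise" that cannot support a 3-sample fit is not a rise**:
  such curves fall back to type II instead of failing.

## The scene simulator

`simulate` renders a sensing/reference pair with known truth:

- **Release**: profiles `none`, `constant` (rate r, default 2 mass/min from
  30 min), `saturating` (stops at 300 min), `two_phase` (pause 300–480 min,
  then resumes), `burst` (400 mass units inside a ≤10 min window) and
  `burst_plus_gradual`. Each step's mass lands as an angularly weighted
  Gaussian puff of width σ(age) = √(σ₀² + 4D·age) (σ₀ = 5 μm,
  D = 0.5 μm²/min), so the halo both brightens and spreads, as the real
  maps do. Capture is an irreversible Langmuir law — deposition scales with
  (1 − b/b_max), capped at the capacity b_max = 3 — which produces the
  saturating map behaviour without a desorption term (protein A/G–IgG
  capture is effectively irreversible over hours).
- **Optics**: Δλ(x) = Δλ_max·b(x)/b_max (Δλ_max = 10 nm); transmitted
  intensity is a Gaussian LED band (850 nm centre, 30 nm FWHM) integrated
  against a Lorentzian line at λ₀ + Δλ, normalized to 1000 counts at zero
  binding; a first-order linear mode is selectable. The nonlinearity factor
  peaks at ≈11% for shifts near half the linewidth.
- **Scene**: bright uniform substrate (the 200 nm nanoholes are far below
  the simulated resolution), a dark ring at the well wall so the Hough
  detector has a real edge, a dark cell disc (30% contrast, 8 μm radius) on
  a seeded random walk scaled to ≈1.2 μm² run-MSD, optional 2-frame
  elongation-then-split mitosis. Noise: additive Gaussian read noise
  (σ = 2 counts), optional Poisson shot noise, and a multiplicative drift
  shared by both wells — amplitude 0.2% with a period of 4 runs, i.e. a
  slow near-monotone thermal drift as in an equilibrated incubator
  microscope. The μ + 3σ level rides on the drift, and its effect on the
  TIC is amplified by the large near-gate halo-tail area, so a full drift
  oscillation inside one run would fabricate type III second rises; the
  slow-drift default keeps the correction exercised without that artefact.
- **Default geometry for testing**: 0.65 μm/px puts the 200 μm well inside
  the 350 px crop; the test suite mostly runs 128 px crops at 1.8 μm/px
  (identical physics, seconds per scene). These sizes are the package's
  choice of desk-scale study conditions.

What the simulator does **not** emulate: real nanohole texture and speckle,
focus drift, cell debris and multi-cell wells, spectral (wavelength-resolved)
structure beyond the single Lorentzian line, hydrodynamic flow in the well,
and analyte-specific binding kinetics with measurable dissociation. Passing
recovery tests on these scenes therefore demonstrates the correctness and
statistical calibration of the processing chain, not instrument-level
validation.

## Known limitations

- The μ + 3σ clamp biases TIC downward by roughly L·(1 + ln(P/L)) per unit
  halo area (P = local signal, L = level), so TIC-slope ratios across cells
  track release-rate ratios only when signals are well above the gate; at
  default noise the 2× rate-doubling ratio is recovered within 15% only in
  the low-noise linear-transduction configuration. Absolute rates in a.u.
  are not comparable across optical configurations at all — there is no
  intensity-to-mass calibration.
- Apoptosis onset annotation is accepted as an external input column; no
  algorithm is provided for it.
- The pixel classifier is trained per dataset; the packaged training
  protocol on simulator labels is a stand-in for human annotation.
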