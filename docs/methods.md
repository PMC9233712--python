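# Methods

## Model

The tissue is a planar polygonal tessellation with disk topology: cells
are simple polygons sharing vertices and edges, and only the apical
surface is represented. The dimensionless mechanical energy is

    E = Σ_α ½ (A_α/A_α⁽⁰⁾ − 1)²  +  Σ_(i,j) Λ̃_ij l_ij  +  Σ_α (Γ̃_α/2) L_α²

(area elasticity K = 1 by the choice of units: lengths in √A⁽⁰⁾). The
model assumes mechanical quasi-equilibrium sampling rather than
force-balance integration: dynamics are Metropolis vertex moves, so time
is measured in move attempts, not physical seconds, and temperature-like
fluctuations enter only through the uphill acceptance probability.

Parameters (dimensionless, defaults):

| parameter | default | meaning |
|---|---|---|
| Λ̃ | 0.06 | junctional line tension |
| Γ̃ | 0.02 | perimeter contractility |
| boundary factor | 1.6 | stiffening of tissue-boundary edges (prevents boundary buckling) |
| P_accept | 0.05 | acceptance probability of energy-raising moves |
| δd | 0.005 | max trial displacement per coordinate |
| d_min | 0.2 | junction length below which a T1 is considered |
| iterations/sts | 130,000 | bookkeeping unit ("simulation time step") |
| a0_min | 1e-3 | resting-area floor for the elastic-term form switch |

The two extrusion protocols multiply, once per iteration from sts 20 on
and only for the ten tracked cells, either Γ̃ by (1+c) (contractility,
purse-string-like) or A⁽⁰⁾ by (1−r) (resting-area-driven). With the
published r values the resting area reaches ~0 within a fraction of an
sts; the gradual constriction that follows is relaxation-limited, which
is deliberate and is left untouched.

## Initial tissue

Cell centres are drawn uniformly in a disk and tessellated with a
Voronoi diagram; two rings of ghost points outside the disk keep every
real region finite and give a consistent polygonal boundary (each
boundary cell ends in chords, and neighbouring cells share vertex
indices exactly). Three Lloyd relaxation steps regularise the
tessellation; the mean tracked-cell circularity of the result is ~0.82,
inside the published 0.81 ± 0.088 band. Rings are stored
counter-clockwise with positive shoelace area.

The tissue is then rescaled so the mean cell area is
`initial_area_ratio` × A⁽⁰⁾, **default 3.7**. The default is the value
implied by the published initial tracked-cell perimeter of 7.58 ± 0.05
(for a near-regular tessellation, A ≈ C·P²/4π ≈ 3.7): the experimentally
matched tissue starts pre-stretched relative to the single-cell resting
area. Because the tessellation conserves bulk area, a pre-stretched
tissue cannot relax by shrinking individual cells — only the free
boundary creeps inward — so the control condition is quasi-stable
(tracked perimeter drifts <2% per 20 sts) even though every cell is far
from A⁽⁰⁾. At ratio 1.0 (also available) the tissue sits near its true
equilibrium, but d_min = 0.2 is then a third of a typical edge length
and T1 side-loss dominates the shape response, suppressing the
contractility rounding signature; ratio 3.7 reproduces both the control
stability and the two regime signatures.

## Dynamics details

* **Proposal.** Δx and Δy are drawn independently and uniformly from
  [−δd, +δd]. A literal one-shared-scalar variant (δd ∈ [0, δd_max]
  added to both coordinates) is available as `proposal_mode="literal"`,
  but it biases drift along +x+y and is not the default.
* **Geometry guard.** A proposal is rejected outright when any incident
  face would invert (signed area ≤ 1e-12) or self-intersect; the
  intersection test checks the two moved edges against the face's other
  edges.
* **T1 operationalisation.** Every 100 iterations (configurable), each
  internal junction shorter than d_min whose length has decreased since
  the previous sts snapshot is a candidate. Eligible candidates (both
  endpoints interior and 3-valent, four distinct surrounding faces, the
  two side faces keeping ≥3 vertices) are rewired, the junction
  reopening orthogonally at 1.05·d_min; the rewiring is kept when it
  lowers the energy and otherwise with probability P_accept, and is
  rolled back when rejected or geometrically invalid. Face count and the
  Euler relation V − E + F = 1 are invariant.
* **Degenerate resting area.** Below a0_min the elastic term switches
  from ½(A/A⁽⁰⁾−1)² (which diverges as A⁽⁰⁾→0) to the dimensional
  ½K(A−A⁽⁰⁾)², preserving the drive toward zero area with finite
  energies.
* **Energy ledger.** The running sum of accepted ΔE (moves and T1s)
  reproduces the end-to-end energy difference of a control run to 1e-6;
  face area/perimeter caches are rewritten from coordinates on every
  acceptance, so no incremental drift accumulates.
* **Reproducibility.** Each run derives every stream (move proposals,
  T1 decisions, tissue construction, tracked-cell choice) from its seed;
  identical seeds give bitwise-identical trajectories. Paired design:
  for a given seed all conditions share the initial mesh, tracked set
  and proposal stream, so trajectories are identical until the ramp
  starts and a rate-0 run equals the control.
* **Performance path.** The hot loop runs as a numba-compiled kernel
  over flat arrays; the readable `tissue_energy` /
  `local_energy_delta` / `metropolis_step` functions are the reference
  implementations the kernel is tested against (ΔE agreement to 1e-9 on
  10⁴ random moves).

## Problem sizes

The `paper` preset is the full-size setup (1141 cells, 130,000
iterations/sts, 50 sts = 6.5×10⁶ iterations). The `small` preset
(300 cells, 13,000 iterations/sts) is the package's desk-scale working
point for sweeps and CI; per-iteration ramp rates are rescaled so the
per-sts ramp factor matches the full-scale one exactly
((1+c′)^13000 = (1+c)^130000). Note the small preset performs ~2.7×
fewer move attempts per vertex per sts, so constriction is shallower at
a given sts than at full scale; regime signatures are direction-correct
but smaller in magnitude. With ten tracked cells the resting-area
circularity drop (≈ −0.01…−0.03 by sts 40) is consistently negative but
only ~1.4 cell-level SEMs per run, so the significance-gated classifier
(`regime_signature`, default 2·SEM on per-cell paired changes with
±2-sts endpoint averaging) is conservative there and may return
`"none"`; the sign of the cohort mean is the sensitive desk-scale
readout.

## Trace pipeline choices

* **Smoothing.** "Moving average" is a centered boxcar whose window
  shrinks symmetrically at the trace ends (so linear ramps are fixed
  points everywhere); "loess" is statsmodels' locally weighted *linear*
  regression with span given as a fraction of the trace (default 0.07,
  floored at 3 points). The classical loess is locally quadratic; at
  these spans the difference is immaterial.
* **Onset detection** smooths with a 5-point moving average, then scores
  every breakpoint b (≥5 points per side) by the summed SSE of separate
  line fits to samples [0, b) and [b, n); the minimiser is the
  inflection point. When the slope drop across the break is smaller
  than `slope_min` (0.01 units/min) the trace is flagged
  "no constriction" — this catches flat *and* uniformly sloped traces,
  which have no inflection. The search is exhaustive, so the detector
  coincides with the brute-force oracle by construction; recovery on
  noisy synthetic traces (5% noise) has median error ≤3 frames.
* **Cross-correlation** is the zero-normalised form
  Σa′(t)b′(t+L)/√(Σa′²Σb′²) (unit peak for identical inputs); lags are
  reported in minutes, the default lag range is a third of the trace.
  `coupling_lag` smooths both channels first, mirroring the rest of the
  pipeline, and correlates myosin with −dP/dt.
* **Pulses.** Amplitude is the topographic prominence (height above the
  higher flanking minimum) — the same convention the detection
  threshold (default 7, raw intensity units) already uses; width is
  measured at half that amplitude. Both are invariant to intensity
  offsets and time translation.
* **Contraction yield** divides the constriction rate at each
  contraction-rate peak by the (smoothed) myosin intensity there, and
  bins peaks into floor-aligned 5-min windows relative to the onset;
  cohort tables average cell-level bin means so each cell counts once.
  The myosin channel is selectable (junctional by default when region
  intensities are available).
* **Regions.** Medial = mask eroded 3 px, total = dilated 3 px,
  junctional = the 6-px band straddling the contour; offsets are taken
  literally in pixels, background is the mean of a caller-supplied
  outside-tissue ROI. Pixel discretisation means an eroded mask can
  graze a ring signal's innermost pixels; "medial ≈ 0" holds relative to
  the ring intensity.
* **Fisher exact test** enumerates same-margin tables in exact integer
  arithmetic and sums probabilities ≤ the observed one (two-sided);
  binomial CIs are Clopper–Pearson by default (Wilson available).
* **Test dispatch** runs Shapiro–Wilk on both samples (α = 0.05): both
  normal → t test (paired/unpaired), otherwise Mann–Whitney / Wilcoxon.
  Constant samples are flagged and sent down the rank path.
* **Missing frames** are linearly interpolated up to 2 consecutive
  frames; longer gaps exclude the cell from ensembles.

## Synthetic data: what it does and does not emulate

The generators produce plateau→linear-constriction perimeter traces
(the measurement stops, at exactly 0, when the apical surface is gone),
Poisson- or renewal-timed Gaussian myosin pulses driving constriction
through a gain with an integer frame lag and a post-onset yield
multiplier, shrinking-ring image stacks with a medial pool, and cohorts
with jittered onsets. Every output carries a truth record sufficient to
score the corresponding pipeline stage, and every generator is
deterministic per seed.

Pulse timing is pure Poisson by default; because ~20% of Poisson
arrivals fall within a pulse width of their predecessor and merge into a
single local maximum, pulse-*count* recovery is only tested with the
`pulse_min_gap_min` refractory-gap option (a renewal process with exact
mean rate), which matches the quasi-periodic character of actomyosin
oscillations.

Not emulated: segmentation errors, photobleaching, focal drift, cell
shape anisotropy, or spatially structured noise. Passing the recovery
tests therefore shows the pipeline is correct and well-calibrated on
clean statistical structure, not that it is robust to microscopy
artefacts.

## Known limitations

* No cell divisions or removal of fully constricted cells from the
  mesh: the model covers the early extrusion phase only, and fully
  collapsed cells persist as tiny polygons.
* T1s are restricted to interior 3-valent junction pairs; boundary
  rearrangements are skipped (rare, and irrelevant to the tracked
  interior cells).
* Metropolis time has no physical unit, so only shape trajectories, not
  rates, are comparable to imaging.
* The full-size initial perimeter (7.58) is matched through the
  `initial_area_ratio` scale; the absolute value depends on that single
  scale choice, which is why the scale-free circularity is the
  quantitative anchor.
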