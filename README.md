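# epiextrude

Vertex-model simulation of epithelial cell extrusion, plus the
quantification pipeline for the live-imaging traces such simulations are
compared against.

Cell extrusion — the coordinated expulsion of a (dying) cell from an
epithelium — begins with constriction of the cell's apical perimeter. Two
mechanically distinct drives can produce the same perimeter decrease but
leave different shape signatures: a purse-string-like increase of
junctional tension/contractility rounds the cell up (circularity rises),
while a shrinking target ("resting") apical area crumples it (circularity
falls). This package lets you simulate both regimes in a 2D vertex model
and quantify them — in simulations or in segmented-microscopy time series
— with the same statistics.

## The model

Cells are simple polygons sharing vertices and edges. The dimensionless
tissue energy is

    E = Σ_α ½ (A_α/A_α⁽⁰⁾ − 1)² + Σ_(i,j) Λ̃_ij l_ij + Σ_α (Γ̃_α/2) L_α²

with A the apical area, A⁽⁰⁾ the resting area, l_ij junction lengths,
L the cell perimeter, Λ̃ the line tension (0.06; ×1.6 on the tissue
boundary) and Γ̃ the perimeter contractility (0.02). Dynamics are
Metropolis vertex moves (trial displacement ≤ 0.005 √A⁽⁰⁾ per
coordinate; downhill moves always accepted, uphill with probability
0.05) with T1 neighbour exchanges for shrinking junctions below
d_min = 0.2. One simulation time step (sts) is 130,000 vertex
iterations. From sts 20, ten tracked interior cells are forced to
constrict either by `Γ̃ ← Γ̃(1+c)` per iteration (contractility, rates
c = [0…7.5]×10⁻⁷) or by `A⁽⁰⁾ ← A⁽⁰⁾(1−r)` (resting area,
r = [0…3.5]×10⁻⁴).

The analysis half implements: loess/moving-average smoothing; onset
(inflection) detection by an exhaustive two-segment linear fit;
end/onset-aligned normalised ensembles; derivatives and normalised
cross-correlation; pulse metrics (time, prominence amplitude, width at
half maximum, frequency); the contraction yield (constriction rate per
unit myosin at contraction peaks, in 5-min bins around the onset);
radial averaged kymographs on 3-px rings; medial/junctional/total region
intensities (−3 px / 6-px band / +3 px); apicobasal profiles;
perimeter fold changes; extrusion durations; elimination proportions
with Clopper–Pearson CIs and an exact-enumeration two-sided Fisher test;
and a Shapiro–Wilk-gated t/rank test dispatch.

A synthetic-data module generates traces, trace pairs, image stacks and
cohorts with machine-readable ground truth for every pipeline stage.

## Worked example

```python
from epiextrude import build_initial_tissue, select_tracked_cells, ModelParams
from epiextrude.mc_dynamics import RateSchedule, run_simulation
from epiextrude.experiments import PRESETS, regime_signature

preset = PRESETS["small"]                      # 300 cells, 13,000 iters/sts
mesh = build_initial_tissue(300, seed=0)
tracked = select_tracked_cells(mesh, 10, seed=10_000)
params = ModelParams(iterations_per_sts=13_000)
sch = RateSchedule("contractility", preset.scaled_rate(7.5e-7), 20, 50, tuple(tracked))
res = run_simulation(mesh, params, sch, seed=0)
print(res.summary.set_index("sts").loc[[0, 20, 40], ["mean_P", "mean_C"]].round(3))
print("signature:", regime_signature(res.trajectory))
```

prints

```
     mean_P  mean_C
sts
0     7.218   0.823
20    7.405   0.815
40    6.743   0.831
signature: tension-like
```

i.e. the tracked cells' mean perimeter is stable until the ramp starts at
sts 20 and then constricts by ~9% by sts 40 while mean circularity
*rises* — the purse-string signature ("tension-like"). A
`"resting_area"` schedule instead lowers circularity while constriction
proceeds ("resting-area-like").

On the analysis side, a planted myosin→constriction delay is recovered
exactly from a noisy synthetic pair:

```python
from epiextrude.synthetic_data import SynthCohortSpec, gen_pulsatile_pair
from epiextrude.trace_analysis import coupling_lag

spec = SynthCohortSpec(noise_sd=2.0, coupling_lag_frames=3, onset_min=80.0, seed=7)
myosin, perimeter, truth = gen_pulsatile_pair(spec)
print("planted lag (min):", truth["lag_min"], " recovered:", coupling_lag(myosin, perimeter))
# planted lag (min): 3.0  recovered: 3.0
```

A CLI wraps the same operations: `epiextrude simulate|sweep|analyze|synth
--help`.

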