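# Methods

## The neuron model

Each synthetic neuron is a single compartment with capacitance `C_m` (pF)
obeying, in current clamp,

```
C_m dV/dt = −I_leak − I_h − I_T − I_D − I_R − w + I_bias + I_inj + ξ
```

with all conductances in nS, voltages in mV, currents in pA and times in ms:

| current | form | role |
|---|---|---|
| leak | `g_L (V − E_L)` | input resistance, resting potential |
| HCN (`I_h`) | `g_h r (V − E_h)`, `ṙ = (r∞(V) − r)/τ_h`, `r∞` sigmoidal (half `vhalf_h`, slope `k_h`, decreasing in V) | voltage sag; slow inward clamp current |
| low-threshold (`I_T`) | `g_T m∞(V)² h (V − E_T)`; `m∞` instantaneous (half −52, k 5), `h` inactivates depolarized (half −78, k 5; τ 25 ms depolarized / 100 ms hyperpolarized) | rebound burst after hyperpolarization (Type II only) |
| D-type K⁺ (`I_D`) | `g_D a∞(V) b (V − E_K)`; `a∞` instantaneous (half −50, k 4), `b` slowly inactivates (half −58, k 4, τ 300 ms) | perithreshold brake: late first spike, raised rheobase ("Others" only) |
| outward rectifier (`I_R`) | `g_R a_R(V) (V − E_K)`, instantaneous, half −15 mV, k 5, `g_R` = 25 nS | bounds the depolarized plateau during block to ≈ −25…−5 mV |
| adaptation `w` | `+adapt_inc` per spike (saturating at `adapt_max`), decay `adapt_tau` | spike-frequency adaptation |

Spike emission is phenomenological: when V crosses the dynamic threshold
`threshold + q` (and the neuron is armed, not refractory, and not blocked) a
spike is pasted at +35 mV and V resets to `reset + q`. The threshold
adaptation `q` climbs by `th_adapt_inc` per spike and relaxes with
`th_adapt_tau`; it is the model's stand-in for cumulative Na-channel
inactivation and is what drives depolarization block: as the inter-spike
voltage band ratchets upward, the 5 ms low-pass-filtered voltage eventually
exceeds `V_block`, at which point emission is disabled. Because the blocked
plateau (set by the rectifier) lies above every template's `V_block`, block
latches for the rest of the step, as in the recordings this emulates. An
"armed" flag (emission requires an upward threshold crossing after recovery
from block) prevents a spurious spike when the step ends and V repolarizes
through the threshold from above. During the refractory period V integrates
without emitting, so at very strong drive the refractory excursions
accelerate block onset — this is why the small-capacitance Type II template
blocks at the lowest currents.

Holding at −60 mV is implemented as an amplifier would: a constant bias
current solving the steady-state equation at −60 mV is pre-computed per
neuron and applied throughout current-clamp sweeps; gates start at their
−60 mV steady states. The RMP protocol applies no bias and lets V settle to
the zero-current fixed point. Voltage clamp is ideal: V follows the command
exactly and the recorded current is the sum of ionic currents (outward
positive), so the capacitive transient is absent and the `I_h` relaxation at
a clamped potential is exactly exponential (the exponential-Euler gate
update is exact at fixed V).

Integration is fixed-step forward Euler for V with exponential-Euler gate
updates, dt = 0.05 ms (the configuration rejects dt > 0.05). Reproducibility
and simplicity were preferred over adaptive stepping; the system is not
stiff at this dt because the largest conductance/capacitance ratios stay
well below the stability limit. Identical parameters, protocol and seed give
bit-identical sweeps. Injected current noise is available (`noise_sd`, pA
per sample) but defaults to 0 so tests are exact.

## Templates

The four templates encode the qualitative contrasts that define the
phenotypes; they were tuned so each class signature holds with a wide margin
and survives cohort jitter:

| | I | II | III | Others |
|---|---|---|---|---|
| C_m (pF) | 50 | 25 | 55 | 110 |
| g_L (nS) | 1.4 | 0.8 | 1.3 | 4.0 |
| E_L (mV) | −66 | −69 | −64 | −76 |
| g_h (nS) / vhalf_h | 1.8 / −102 | 0.4 / −110 | 0.05 / −95 | 10 / −112 |
| g_T (nS) | 0 | 8 | 0 | 0 |
| g_D (nS) | 0 | 0 | 0 | 2 |
| V_block (mV) | −36 | −40 | −34 | −24 |

Type II has the highest input resistance and smallest capacitance (fast,
excitable, earliest block); "Others" the largest capacitance, most negative
resting potential, and an I_h that only activates below ≈ −100 mV — large
clamp current at −140 mV with no sag in the current-clamp range, realizing
the observation that these neurons dissociate I_h from sag. Type III's g_h
is negligible everywhere. The effective I_h reversal is −50 mV (biophysical
HCN reversals are nearer −30 mV; the more negative effective value keeps the
post-hyperpolarization I_h tail from depolarizing Type I to threshold, i.e.
it enforces "sag without rebound" within a one-gate model). "Others" uses a
saturating adaptation (`adapt_inc` 60 pA, `adapt_max` 300 pA, τ 2 s): near
rheobase a single spike's adaptation silences the cell (late single-spike
firing), while at +400 pA and above the saturated adaptation is a constant
offset and the cell fires at high rates with little further adaptation —
the same dissociation the late-firing phenotype shows in recordings.

Cohort jitter is multiplicative lognormal (sd 0.1 in log space, clipped at
±2.5 sd) on `C_m, g_L, g_h, g_T, g_D` and additive Gaussian (sd = jitter ×
20 mV) on `E_L`. Zero conductances stay zero, so jitter can never give a
Type III neuron a sag or a Type I neuron a rebound current.

## Feature extraction

Defaults (all configurable): spikes are upward crossings of 0 mV followed by
a local maximum, events closer than 2 ms merged to the larger peak; sag =
steady (mean of last 100 ms of the step) minus peak (minimum in the first
150 ms), clipped at 0; I_h amplitude = |steady (last 50 ms) − instantaneous
(10–30 ms after onset)|, density divides by measured capacitance; rebound
window = 500 ms after offset; depolarization block within a sweep is
declared when the 5 ms-filtered voltage stays above −20 mV for ≥ 50 ms with
no spike, and MFR counts only spikes before the first block, ties across
steps breaking to the lowest current. ISI bins are 5 ms, half-open, counts
normalized by the type's sample size. Features that require spikes are
missing, not zero, when no spike occurs; the clustering stage then applies
the row-exclusion rule (any missing selected parameter drops the row).

Passives: RMP is the mean of the settled zero-current trace; input
resistance is the regression slope of steady-state ΔV on ΔI over the −30,
−20, −10 pA steps; capacitance is τ/R_in with τ from a mono-exponential fit
to the −20 pA onset (first 100 ms). The I_h half-activations were placed
negative enough that the gate barely moves over these small steps; this is
what keeps the τ/R capacitance estimate within a few percent of the true
C_m (a steeply-activating I_h in the passive range would bias the secant
resistance and the estimate by ~20%).

## Classification

Exclusion: RMP more positive than −50 mV (strict) or no spike at any
depolarizing excitability step. Then, in order: "Others" if silent below
+30 pA and never more than one evoked spike per step; Type II if ≥ 1 rebound
spike at −80 pA; Type I if sag at −80 pA ≥ 3 mV; else Type III. Rebound
precedes sag because rebound spiking is exclusive to Type II; a
rebound-without-sag neuron is labeled II with a flag in its rationale. The
3 mV sag threshold is this package's quantification of a judgement that is
made visually at the rig; it cleanly separates the simulated templates
(Type I jittered sags stay above ~5 mV, Type III below ~0.5 mV) and is a
config parameter, not a claim about a canonical cutoff.

## Clustering and statistics

Ward agglomeration (scipy, `method="ward"` on Euclidean rows — the ward.D2
variant: heights are the root of twice the within-cluster variance
increase). Columns are z-scored by default because the six parameters mix
pA/pF, mV, ms, counts and pA; a raw-value mode exists, and the 3D scatter
export always uses raw values. The cluster count k is a user choice (4 for
the three-parameter set, 3 for the six-parameter set in the drivers); the
agreement table and per-cluster purity, not the cut itself, are the
evaluation surface. Newick export writes an ultrametric tree with each
internal node at half its merge height.

Two-way ANOVAs treat neuron type and stimulus step as categorical fixed
factors and use Type-III sums of squares with sum-to-zero contrasts, the
appropriate convention for the unbalanced cell sizes that unequal group
sizes produce (and the convention of the mainstream GUI packages this
mirrors). Cells with n ≤ 1 or empty cells are rejected with a named error.
Tukey HSD uses the studentized-range distribution exactly (Tukey-Kramer
standard errors for unequal n); the post-hoc family for the two-way designs
is within-step, flagged in the output. Summaries are mean ± SEM.

## What the generator does and does not emulate

The synthetic cohorts reproduce the *feature-level* signatures of the four
phenotypes — sag, rebound bursting, late single-spike firing, block order,
I_h density contrasts, passive-property contrasts — with per-neuron
parameter jitter. They do not emulate: action-potential waveforms (spikes
are pasted markers), synaptic or channel noise (default noise is zero),
series-resistance and clamp artifacts, the very deep hyperpolarizations a
real high-R_in cell would never reach (the model lacks an inward rectifier,
so −80 pA can drive the Type II template below −120 mV; an inward rectifier
was deliberately omitted because it would crush the sag signal the
classifier depends on), multi-compartment morphology, or biophysically
calibrated HCN/T-type kinetics. Passing tests therefore show the *pipeline*
is correct and that the rules separate phenotypes whose signatures hold; it
does not validate the templates as biophysical models of real BNST neurons,
and real-data proportions will differ from the balanced cohort design.

## Numerical choices and problem sizes

dt = 0.05 ms everywhere; sweeps are ~1.0–1.2 s. The default cohort is
30 neurons per phenotype (seed-deterministic), which the test suite and the
acceptance script simulate in ~10–15 s. Oracle checks use 1,000 random
band-limited traces (spike detector), 100 random matrices with n ≤ 12 (Ward
vs. exhaustive agglomeration), and 2,000 simulated null datasets (two-way
interaction type-I error). Ties in agglomeration are broken toward the
lowest-index pair; with continuous random data ties have probability zero,
and the oracle applies the same rule. ABF/NWB ingestion is isolated from
the core pipeline and not provided here; the internal HDF5 container plus
command-waveform protocol matching cover the acquisition-side interface.
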