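# Methods

## Model

The dendrite-and-soma (DS) model couples a conductance-based point soma to a
passive equivalent cylinder. The soma carries a leak current and a set of
voltage-activated currents `G_j (E_j − v) Π a_i^{p_i}`; each gating variable
relaxes to its steady-state curve with a voltage-dependent time constant, or
is instantaneous (algebraically eliminated). The default soma is the
Morris–Lecar model in its class-I excitability regime, scaled to whole-cell
units:

| parameter | value | units |
|---|---|---|
| C_σ | 20 | pF |
| G_σ (leak) | 2 | nS |
| E_L | −60 | mV |
| G_Ca, E_Ca | 4, 120 | nS, mV |
| G_K, E_K | 8, −80 | nS, mV |
| V1, V2 (m∞) | −1.2, 18 | mV |
| V3, V4 (w∞) | 12, 17.4 | mV |
| φ (1/τ_w scale) | 1/15 | 1/ms |

Ca²⁺ activation `m` is instantaneous; `w` is the single dynamic gate with
`τ_w = 1/(φ cosh((v−V3)/(2V4)))`. With this set the cusp, zero-τ_δ BT and
BTC points land at `G_in = 5.53 nS`, `4.77 nS` and `τ_δ = 12.9 ms`
respectively, which pins the whole-cell scaling. Note the potassium reversal
of −80 mV: the variant with −84 mV (also common in the literature) moves the
cusp to 5.32 nS and is not the regime studied here.

The cable is parametrised by its passive time constant `τ_δ = c_δ/g_δ`,
electrotonic length constant `λ = √(d/(4 r_a g_δ))`, dominance factor
`ρ = π d λ g_δ / G_σ` and electrotonic length `ℓ = L/λ`. All electrical
properties at the soma depend only on `(G_in, τ_δ, ℓ)`. Semi-infinite cables
are exact in every analytic formula; simulations truncate them at `ℓ = 5`,
where the sealed end changes `G_in` by less than 10⁻⁴ relative.

Units are mV, ms, nS, pF, pA throughout (1 nS·mV = 1 pA, 1 pA/pF = 1 mV/ms).

## Discretisation

The cable is discretised cell-centred: M compartments of electrotonic length
`h = ℓ/M` at centres `(i−1/2)h`, second-order interior stencil, natural
no-flux (sealed) boundary at the distal end, and a half-segment axial
conductance `2ρG_σ/h` joining the soma to the first compartment. The scheme's
DC input conductance differs from the analytic `G_in` at O(h²); protocols
that compare simulated behaviour against saddle-node *currents* with
sub-0.1 pA resolution therefore evaluate those currents at the discrete
conductance (`DSSystem.G_in_discrete`). `τ_δ = 0` is taken as the exact
instantaneous-cable limit: the cable states are dropped and the model
reduces to a point neuron with lumped leak `G_in`.

Time stepping is fixed-step classical RK4 (compiled), with
`dt = 0.8·2.78·τ_δ/(4/h² + 1)` capped at 25 µs — the linear-stability bound
of the cable stencil with a 20 % margin. Spike times are upward crossings of
0 mV, linearly interpolated within the step; a voltage jump (perturbation or
synaptic impulse) that itself crosses threshold is counted as a spike at the
jump time, and in networks such jump-induced firings propagate within the
step (each neuron fires at most once per step).

## Bifurcation analysis

Equilibria are roots of `I_∞(v) + I_ext = 0` with
`I_∞(v) = I_active(v) + G_in(E_L − v)`; the dendritic flux at rest collapses
into `G_in`, so the saddle-node condition `dI_∞/dv = 0` and the cusp
condition `d²I_∞/dv² = 0` are independent of `τ_δ` and of the cable
geometry. Both are solved by bracketing + Brent on a physiological window
(−80 to 20 mV, tolerance 10⁻¹⁰ mV).

Stability-dependent bifurcations come from the characteristic function

```
χ(s; v) = s − ∂f_S/∂v − Σ_i (∂f_S/∂a_i) a_i′(v)/(1 + s τ_i) + (ρG_σ/C_σ) γ_fac(s)
```

with `γ_fac = γ` (semi-infinite) or `γ tanh(ℓγ)` (finite), `γ = √(1+sτ_δ)`
on the principal branch. `χ(0) = 0` is algebraically the saddle-node
condition; a Hopf point is a root pair `s = ±iω`; a BT point is a double
root at 0, i.e. `χ(0) = χ′(0) = 0`. Substituting the saddle-node condition
into `χ′(0)` yields a closed-form scalar BT equation with the cable entering
through `α₀ = γ_fac′(0)/(τ_δ γ_fac(0))` (= 1/2 for the semi-infinite cable);
the BTC point then follows by solving the same equation — linear in `τ_δ` —
at the cusp voltage.

Hopf points are continued from the BT point in `G_in`, solving
`[Re χ(iω), Im χ(iω)/ω] = 0` by a damped Newton (hybrid) method in
`(v, log ω)`. Dividing the odd imaginary part by ω removes the spurious
ω = 0 saddle-node root, and the log parameterisation keeps the Jacobian
non-degenerate where ω ~ √(G − G_BT); steps are quadratically refined toward
the BT end. Criticality is the first Lyapunov coefficient of the discretised
system (M = 50) by the standard projection method, with the bilinear and
trilinear forms evaluated by central differences of the right-hand side
(step 0.05 along unit eigenvector directions); `l₁ > 0` is subcritical.

The saddle-node-loop point is global and found by bisection in `G_in` on a
bistability probe: burn in above the upper saddle-node current (where
spiking is the only attractor), drop to `I_SN,high − δI` (δI = 0.05–0.1 pA
against the *discrete* SN current) and test whether spiking survives.
Survival marks the homoclinic regime. Because the probe detects a bistable
window of width ≥ δI rather than the exact SNL, the estimate carries a
positive bias of order the window growth rate (~0.1 pA/nS) times δI; the
orderings and monotonicities reported are insensitive to this.

## Onset currents and PRCs

The onset current is the smallest `I_ext` giving sustained regular spiking
at or above a target rate (1 Hz by default), found by a geometric scan
(factor 1.2 — the spiking band is bounded above by depolarisation block, so
coarser scans can skip it) followed by bisection with downward continuation
from a spiking state. In the homoclinic regime the spiking branch is thereby
followed below the upper saddle-node current. The f–I curve near homoclinic
onset is logarithmically steep, so the lowest achievable rate there can
exceed the 1 Hz target (e.g. ~1.4 Hz at `G_in = 4.53`, `τ_δ = 2.5 ms`); the
measured PRC shape is extremely sensitive to the current margin above onset,
which is why onset bisection tolerances of 10⁻³–10⁻⁴ pA are used before PRC
measurement in the homoclinic regime.

PRCs use the direct method: from a phase-zero snapshot of the steady cycle,
a single somatic voltage step Δv is applied at phase `θ_k = k/100 − 0.005`
and the shift of the next spike is expressed in cycle fractions (advance
positive; phase zero at the threshold crossing). Δv is auto-tuned so the
peak advance lies in [0.05, 0.1] (verified linear: halving Δv halves the
curve within 10 %). Classification: a negative lobe exceeding 5 % of total
|area| → Hopf-like; otherwise peak phase before 0.45 → HOM; else SNIC. At
onset these thresholds separate the three classes with wide margins (SNIC
peaks at 0.47–0.51, HOM at 0.22–0.40, Hopf-like curves carry 9 %+ negative
area).

## Networks

Synapses are excitatory, instantaneous and current-based: a presynaptic
spike adds a fixed voltage `ΔV_syn` to every other soma with zero delay.
`ΔV_syn` is calibrated from the measured PRC so that the maximum phase
advance per input is ~0.1 for pair studies. All neurons are identical and
driven at their common onset current. Phases are extracted per reference
cycle (neuron 0's spikes): each neuron's phase is the elapsed fraction of
the cycle since its own last spike; sorted cyclic gaps ψ_i (Σψ_i = 1) feed
the synchrony measure `R = √(N/(N−1)(Σψ_i² − 1/N))`.

Study conditions. Pair studies run at `G_in = 3.45 nS` (SNIC) and
`4.53 nS` (HOM) with `τ_δ = 2.5 ms` and initial phase difference 0.3: the
SNIC pair creeps to a weakly stable near-in-phase lock; the HOM pair locks
robustly in anti-phase (its coupling function's anti-phase basin spans
0.09–0.91 versus 0.26–0.74 for SNIC). Five-neuron all-to-all studies use
`τ_δ = 3.5 ms`, starting from splay-perturbed phases (`i/5` ± uniform 0.02,
seeded). The HOM network runs at `G_in = 4.6 nS`, where the 1 Hz onset is
attainable and the PRC peak falls before 1/N = 0.2 — the known condition for
splay stability in pulse-coupled rings — and with the synaptic advance
reduced to ~0.02 per input: at ~0.1 the total input per cycle (four
impulses) leaves the weak-coupling regime, and near-coincident neurons are
absorbed into clusters through the small stable near-in-phase lock that the
measured HOM coupling function carries. In that weak-coupling regime the
HOM network converges to the exact splay state (gaps 0.2, R → 0) while the
SNIC network (`G_in = 3.45`) abandons splay and drifts non-monotonically
toward synchrony (R from ~0.06 to ~0.96 over 250 cycles).

## Morphologies

The synthetic arbour generator emulates staged reconstructions: `n_stems`
stems leave the soma and bifurcate symmetrically for `depth` levels, with
exact 3/2-power diameters and segment lengths ∝ √d (equal electrotonic
segment lengths for any membrane), so an exact Rall equivalent cylinder
exists; a non-exact mode jitters the branch-power sum to emulate real
arbours. The reduction collapses tips-inward, summing `d^{3/2}` across
siblings and averaging electrotonic lengths weighted by `d^{3/2}`; all rule
violations are absorbed into ρ and the largest relative spread is reported
as a mismatch metric. Branched trees are also simulated directly
(compartments of ≤ 0.2 electrotonic length for PRC comparisons; the
tree-vs-cylinder normalised PRCs agree within 0.04 for the default test
arbour, and within 0.3 pA in onset current).

What the generator does not emulate: tapering diameters, spines, dendritic
nonuniform membrane, and the sheer compartment count of real Purkinje
reconstructions; agreement between a tree and its reduction here shows the
reduction machinery is consistent, and the achievable margin on real
morphologies is bounded below by their rule violations (reported via the
mismatch metric), not by the code path.

## Problem sizes and numerical defaults

Default resolution is M = 50 compartments on ℓ = 5 (the simulation standard
throughout); the eigenvalue cross-check uses M = 200. Onset probes integrate
2–18 s of biological time depending on the stage; bistability probes for the
SNL search use 2.5 s transient + 5 s window probes during bisection.
Network runs span 60–250 cycles at ~1 Hz. These sizes are the package's
defaults chosen to keep every protocol's discriminating quantity an order of
magnitude above its noise floor; all are arguments, not constants.

## Known limitations

- Fast integration paths require the Morris–Lecar soma pattern (one dynamic
  gate, tanh curves); generic somas are supported by the analytic layer and
  the (slow) scipy path only.
- The SNL locator inherits the bistability probe's δI bias (see above).
- Onset-current and PRC protocols assume a bounded tonic-spiking band with
  regular firing; bursting dynamics (absent in this model class) would
  confound the spike-based phase definition.
- The fold of limit cycles adjacent to homoclinic onset is not computed
  separately; onset classification treats the whole bistable window as
  homoclinic, consistent with the spike-timing behaviour there.
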