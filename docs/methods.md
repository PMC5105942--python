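# Methods

## Model

The membrane is a Morris–Lecar-type conductance-based neuron in density
units (mV, ms, μA/cm², mS/cm², μF/cm²).  Sodium activation m is
instantaneous (m = m∞(V)); the recovery variable w aggregates the
delayed-rectifier and low-threshold potassium currents that oppose spike
initiation; an optional inactivation gate h, with the same functional form
as w but its own midpoint/slope/rate (β_h = −28 mV, γ_h = −14 mV,
φ_h = 0.005), applies to a fraction p of the sodium conductance.  With
p = 0 the h terms cancel exactly and the inactivation-free model is
recovered bit-for-bit (tested).

Baseline parameters: C = 2 μF/cm², ḡ_Na = 20, ḡ_K = 20, g_leak = 2 mS/cm²,
E_Na = 50, E_K = −100, E_leak = −70 mV, β_m = −1.2, γ_m = 18, γ_w = 10 mV,
φ_w = 0.15, β_w = −20 mV.  β_w is the excitability parameter: less negative
values lower the recruitment threshold of w less steeply than V rises,
which converts onset-only (transient) firing into sustained (repetitive)
firing.  A "revised" preset (g_leak = 0.7, ḡ_K = 30 mS/cm²) reproduces the
much higher GABA sensitivity seen in dissociated DRG somata; the axon
preset raises ḡ_Na = ḡ_K = 30 mS/cm².

Dynamic-clamp-style quantities are per-capacitance densities:
g[mS/cm²] = g[nS/pF] × C[μF/cm²] (1 nS/pF ≡ 1 mS/μF), and currents
pA/pF × C → μA/cm².  With C = 2, a 2 nS/pF conductance is 4 mS/cm².

Resting state is the root of the steady-state current with w = w∞(V),
h = h∞(V), found by bracketed bisection on [−100, 0] mV plus one Newton
polish (residual < 10⁻⁹); for the baseline parameters V_rest = −69.4 mV.
Every protocol starts from this fixed point, so no burn-in is needed and
cells never inherit state from previous stimuli.

## Stimuli

GABA_A conductance inputs are steps, linear-onset ramps (default 500 ms
rise), or peak-normalized double exponentials
g(t) = ḡ·x·(e^(−t/τ_decay) − e^(−t/τ_rise)); fast kinetics (2/20 ms)
emulate phasic intrasynaptic receptors, slow kinetics (20/200 ms)
asynchronous extrasynaptic activation.  The classification window for a
synaptic waveform runs from onset to the time the waveform decays below 5%
of peak; steps and ramps use their hold window (default 1000 ms — long
enough that "sustained to stimulus end" is unambiguous).

## Numerics

Single compartment: classical RK4 on a fixed 0.01 ms grid with stimuli
pre-sampled at half steps, output subsampled to 0.05 ms (numba-compiled).
A fixed-step high-order explicit scheme was chosen over an adaptive stiff
solver for throughput: the parameter sweeps run ~10⁴ one-second
simulations, and the model is only mildly stiff near spike onset.  Halving
the step changes no sample of a 1000 ms repetitively spiking trace by more
than 0.2 mV and no response label anywhere in the acceptance grids
(tested); an independent LSODA path (scipy) agrees on spike counts and
voltages to < 1 mV and serves as the cross-check in the test suite.

Spike detection: upward crossing of 0 mV with a 2 ms refractory period and
a prominence criterion (peak ≥ 20 mV above the mean of the preceding
10 ms), which rejects the shunt-clamped plateau near E_GABA that otherwise
drifts across threshold; all thresholds configurable.  Responses are
classified none / transient / repetitive: repetitive requires ≥ 3 spikes
with the last in the final quarter of the stimulus window, so an onset
burst is never "repetitive".  These detection rules are declared package
choices, not measured quantities.

Cable: three 1 mm compartments of 1 μm diameter, R_a = 150 Ω·cm,
discretized by the d_lambda rule (segment ≤ 0.01·λ at 100 Hz;
λ₁₀₀ ≈ 163 μm, giving 615 segments per compartment).  At that resolution
explicit integration is diffusion-limited to unusably small steps, so the
cable uses Rush–Larsen exponential gating updates plus a θ-method
(Crank–Nicolson, θ = 0.5) voltage step with a Thomas tridiagonal solve —
unconditionally stable in the axial part, 0.01 ms default step (0.005 ms in
refinement checks).  Conduction latency changes < 5% under either spatial
(d_lambda/2) or temporal (dt/2) refinement, and with axial coupling zeroed
each compartment reproduces the single-compartment trajectories (both
tested).  Current pulses are injected uniformly over the leftmost 100 μm
(a point source would be diluted into a 1.6 μm segment); the evoked
stimulus is a 1 ms pulse at twice the bisected threshold.  Propagation
scoring uses a paired-simulation attribution: a GABA-only run identifies
PAD-evoked spikes, and midpoint spikes in the combined run matching those
times (±1.5 ms) are credited to PAD; remaining spikes are claimed greedily
by evoked pulses within a 30 ms window (longer than the ~19 ms end-to-end
latency).  Near-coincidences are flagged ambiguous rather than classified.

## Protocols

* **Titration** — bisection of ḡ_GABA to the minimum eliciting the target
  response (default resolution 0.01 nS/pF, bounds [0, 10]); the bracketing
  invariant (spiking at min, none at min − resolution) is verified, and an
  optional coarse pre-scan brackets the first onset when spiking is
  non-monotone in ḡ_GABA (the region maps show it need not be monotone).
* **4-AP analog** — Δβ_w toward 0 mV, default +10 mV; the true
  pharmacological shift is unknown, so results are reported across Δβ_w.
* **Virtual sodium conductance** — a non-inactivating channel added at a
  per-capacitance density.  By default it inherits the model's own
  activation curve; its midpoint/slope can be overridden, and the
  hyperexcitability demonstrations use midpoint −55 mV (slope 10 mV),
  because a channel activating only above −20 mV cannot destabilize a
  −69 mV rest at realistic densities.  "Switching on" the conductance means
  starting from the rest of the cell without it, as in the experiment.
* **Rheobase** — minimum I_stim step (pA/pF, bisected to 0.1) evoking ≥ 1
  spike while a g_GABA step is active (g 100–700 ms, I 300–600 ms).  At
  depolarized E_GABA the smallest conductances are net excitatory in this
  model (consistent with the spiking maps), so the shunting-dominated
  behaviour is evaluated for ḡ_GABA ≥ 0.5 nS/pF, where rheobase rises
  strictly with ḡ_GABA at both E_GABA values.
* **Inhibition assays and maps** — an I_stim step (30 pA/pF default, which
  drives repetitive firing across p at β_w = 0) with a 400 ms g_GABA step
  interposed 300 ms after current onset (or, in the g-before-I ordering,
  leading and overlapping the first 100 ms of the current).  "Stopped"
  means zero spikes in the last 50% of the overlap window; a weaker
  "reduced" criterion (≥ 50% rate drop versus the I-alone run) is computed
  alongside.  Region boundaries come from grid sweeps with optional 1-D
  bisection refinement (0.25 mV), not numerical continuation; refinement
  invariance stands in for continuation accuracy.

## Synthetic populations

A virtual population draws β_w from a normal distribution (mean −20 mV,
SD 4 mV) truncated to [−30, −5] mV — centred on the normal excitability and
wide enough to straddle the region boundaries — optionally with lognormal
jitter on g_leak and ḡ_K.  Sampling is rejection-based, deterministic given
the seed, and errors out (rather than looping) if more than 10·n draws are
rejected.  The default condition matrix crosses E_GABA ∈ {−35, −20} mV with
Δβ_w ∈ {0, +10} mV, and each cell is titrated per condition.

What the generator does *not* emulate: the real DRG excitability
distribution is unknown (the published spiking proportions cannot identify
it), and real cells add channel noise, chloride dynamics and
soma-vs-terminal differences.  Passing population tests therefore
demonstrate the model's orderings — depolarized E_GABA and raised
excitability each recruit more cells, and their combination recruits the
most, cell-by-cell (dominance, a stronger property than the proportion
ordering) — not quantitative proportions.

## Design choices and limitations

* In repetitive-regime cells the fast and slow waveform thresholds agree
  closely but not exactly (slow is a few hundredths of a nS/pF *lower*,
  since a longer input integrates further); rate-insensitivity is asserted
  as "slow requires no more than fast, within 10%", versus the ~2× gap in
  transient-regime cells.
* Problem sizes: acceptance tests use 2.5 mV grids (5 mV × 0.25 for the
  inhibition maps); the acceptance script runs the full 1 × 0.5 mV sweep
  (2346 cells) with 0.01 nS/pF titration.
* No chloride-concentration dynamics (activity-dependent E_GABA shifts are
  discussed qualitatively only), no channel noise, no temperature
  dependence, no myelin/branch geometry, no stability/bifurcation-type
  labelling of the region borders.
* Spike-height attenuation under shunting means strongly attenuated spikes
  falling below the 0 mV detection threshold are counted as non-spiking;
  the prominence criterion and configurable threshold make this rule
  explicit rather than hidden.
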