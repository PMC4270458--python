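# Methods

This note documents the model, the analytic machinery, the numerical
choices and the package's default parameters, together with their
rationale and known limitations.

## 1. Model

### Geometry and state

A two-compartment passive neuron: a lumped isopotential soma of membrane
area `S` attached at `x = 0` to an unbranched cylindrical dendrite of
length `L` and diameter `d`, sealed at `x = L`. The state is the membrane
potential `v(x, t)` relative to rest, in mV; internal units are
ms, cm, µF/cm², mS/cm² and kΩ·cm throughout, so no hidden conversion
factors appear in the equations.

### Cable equation

On the dendrite,

```
c_m ∂v/∂t = a ∂²v/∂x² − g_L v − Σ_q f_q g_q(t) δ(x − x_q) (v − ε_q),
a = d / (4 r_a),
```

where `c_m` is the specific capacitance, `g_L` the leak conductance
density, `r_a` the axial resistivity, and each synaptic input `q` is a
point conductance of strength `f_q` (the weight of the spatial delta,
mS/cm²·cm), unit-peak waveform `g_q(t)`, and reversal potential `ε_q`
relative to rest (`ε_E > 0 > ε_I`).

Boundary conditions: a sealed end `∂v/∂x(L, t) = 0`, and conservation at
the soma,

```
S c_m dv_s/dt = −S g_L v_s + β ∂v/∂x(0, t),      β = π d² / (4 r_a),
```

with continuity `v_s(t) = v(0, t)`. Writing `γ = S / (π d)` (the soma as
an equivalent cable length) makes the somatic condition
`γ c_m v_t(0) = γ (a/γ·…)` reduce, in the Laplace domain, to a Robin
condition at `x = 0`.

### Synaptic waveform

The conductance time course is the peak-normalized double exponential

```
g(t) = N · [exp(−(t−t₀)/σ_d) − exp(−(t−t₀)/σ_r)] · H(t−t₀),
t* = σ_r σ_d/(σ_d−σ_r) · ln(σ_d/σ_r),     N = 1 / (e^{−t*/σ_d} − e^{−t*/σ_r}),
```

so that `max_t g = 1` exactly (for `σ_r = 1, σ_d = 2` ms, `N = 4` in
closed form — used as a unit test oracle).

## 2. Finite-difference oracle (`fd`)

The full nonlinear model is discretized by control volumes: node 0 carries
the somatic area plus half a cell of dendrite, interior nodes carry
`π d Δx`, the sealed end half a cell. Time stepping is Crank–Nicolson with
the synaptic conductances evaluated at the half step, which keeps each
step linear in the unknowns (the synaptic term is
`g(t_{n+1/2}) (v − ε)` with `v` averaged between levels) while retaining
second-order accuracy; each step solves one tridiagonal system
(`scipy.linalg.solve_banded`).

Properties used as tests:

- **Charge conservation**: for the linear solver, total membrane charge
  after an impulse decays exactly as `exp(−g_L t / c_m)` (the axial terms
  telescope); the FD solution reproduces this to ~1e−6 relative.
- **Convergence**: ~2nd order in `Δt` by Richardson ratios; `Δx`
  refinement changes the EPSP peak by <1%.
- Crank–Nicolson applied to a *delta initial condition* produces a brief
  oscillatory startup transient (non-smooth data); comparisons against the
  analytic Green's function therefore start at `t = 1 ms`, after which the
  two agree to ~1e−5 of peak.

`calibrate_strength` bisects (Brent) on the input strength until the FD
somatic peak matches a target amplitude; because the conductance response
is sublinear in `f`, the initial bracket is expanded upward as needed.

## 3. Green's function (`green`)

Laplace transforming the linear (subthreshold, source-free) cable with the
Robin soma condition gives the characteristic equation for the spatial
wavenumbers:

```
sin(kL) + γ k cos(kL) = 0        (equivalently tan(kL) = −γk),
```

with exactly one root in each interval `((n−½)π/L, nπ/L)` (found by
`brentq`), plus the uniform mode `k₀ = 0`. The poles are
`s_n = −(g_L + a k_n²)/c_m` — all real and negative. The Green's function
(somatic impulse normalization `q δ(x−y) δ(t)` on the per-area equation)
is the mode sum

```
G(x, y, t) = Σ_n A_n(x, y) exp(s_n t),
A_0 = 1 / (c_m (L + γ)),
A_n = 2 [cos(k_n x<) − γ k_n sin(k_n x<)] cos(k_n (L − x>)) /
      { c_m cos(k_n L) [ (L + γ) + γ² k_n² L ] },
```

with `x< = min(x,y)`, `x> = max(x,y)`; `A_n` is symmetric in `(x, y)`.
`A_0` has a physical check: a unit impulse spread uniformly over the total
capacitance `c_m (π d L + S)` per circumference `π d`. The default
truncation is 80 modes; doubling it changes somatic responses by <1e−4 of
peak (fast modes decay within microseconds and only matter inside the
FD startup window excluded above).

### Source convolution

Time-dependent sources are convolved mode by mode. Rather than sampling
`exp(s_n t)` and applying the trapezoid rule — which degrades for stiff
modes with `|s_n| Δt ≳ 1` — the package integrates each mode *exactly* for
the piecewise-linear interpolant of the source:

```
y_{m+1} = e^{s Δt} y_m + Δt [ q_m φ₁(sΔt) + (q_{m+1} − q_m) φ₂(sΔt) ],
φ₁(z) = (e^z − 1)/z,   φ₂(z) = (e^z − 1 − z)/z²,
```

an A-stable exponential-integrator recurrence of the same `O(Δt²)` class
as the trapezoid rule but with no step-size restriction. A plain
trapezoid convolution (`convolve_green_source`) is also provided and
tested for its convergence order.

## 4. Perturbative hierarchy (`asymptotic`)

Expanding `v = Σ f_a^j f_b^k v^{(j,k)}` in the input strengths and
collecting powers yields linear cable problems, each driven by a source
*localized at an input site*, so the spatial integrals collapse to point
evaluations:

- order `f`: source `+δ(x−y) g(t) ε` → first-order PSP `v¹`;
- order `f²`: source `−δ(x−y) g(t) v¹(y, t)` → sublinear self-correction;
- order `f_a f_b`: sources `−δ(x−y_a) g_a(t) v_b¹(y_a, t)` and
  `−δ(x−y_b) g_b(t) v_a¹(y_b, t)` → the cross term `v¹¹`, whose somatic
  trace is the shunting component per unit `f_a f_b`.

For E–I pairs a *simplified* cross term keeps only the
`−g_I v_E¹` source; it stays within 15% of the full term because
`|ε_E| ≈ 7 |ε_I|`.

Measured orders against the FD oracle (halving `f`): first-order max error
shrinks ≈4×, second-order ≈8×, confirming `O(f²)` and `O(f³)` remainders.
At a threshold-scale 10 mV EPSP the composed second-order EPSP peak is
within 3.3% of FD (the headline `t1` figure).

**Limitation.** The hierarchy is perturbative in the *conductance*
strengths. An IPSP of −2 mV against the small inhibitory driving force
(`|ε_I| = 10 mV`) requires a strong conductance, so the truncated SSP for
a 5/−2 mV E–I pair deviates up to ~11% of peak from FD. This does not
limit the practical rule: the bilinear prediction composes *measured*
PSPs, and its error is ~1% (below).

## 5. Bilinear rule (`bilinear`)

The shunting coefficient is the strength-free quotient of somatic
components

```
k(t) = v¹¹(0, t) / (v_a¹(0, t) · v_b¹(0, t)),
```

evaluated where both first-order PSPs exceed 10% of their peaks (the
validity window; outside it the denominator is small and the correction
negligible). `k` is signed: positive for E–I (SC < 0, one factor < 0),
negative for E–E.

Prediction uses `SSP ≈ PSP₁ + PSP₂ + k·PSP₁·PSP₂` with `k` *continued
outside the window by its nearest valid value*: the window floor protects
the estimation of `k`, not its application, and `k(t)` itself is smooth.
(Zeroing the correction outside the window instead leaves a ~6%-of-peak
discontinuity artifact at the window edge; with the continuation the
maximum pair-prediction error at the 5/−2 mV condition is 1.1% of the SSP
peak.) Notably the product of *measured* PSPs partially resummates
higher-order terms, which is why the rule outperforms the raw truncated
hierarchy.

Multi-input integration sums all PSPs plus all pairwise bilinear terms.
At unitary amplitudes (15 E sites of 0.2–1 mV, 5 I sites of 0.1–0.5 mV,
onsets spread over 25 ms) the prediction's RMS error is ~19% of the linear
sum's, with predicted-vs-simulated regression slope 1.04. At several-mV
per-input amplitudes (linear sum ≳ 15 mV, far above threshold scale) the
pairwise rule degrades — expected for a perturbative expansion — so the
multi-input rule should be read as a statement about physiological
unitary-input regimes.

The dendritic graph maps input sites to nodes and pairwise SC time series
to edge weights; `active_edges` thresholds it at a time point, and
`expected_active_pairs` gives the functional-sparsity estimate
`m(m−1)/2` with `m = n·rate·window` expected concurrently active inputs
(≪ all `C(n,2)` pairs at cortical rates).

## 6. Estimation (`estimate`)

Mirrors the experimental protocol: simulate each input of a pair alone and
together over a 3×3 strength grid, optionally add seeded Gaussian
recording noise (default SD 0.05 mV), measure SC and PSP amplitudes at a
chosen time (or the PSP₁ peak), scatter SC against the PSP product, bin
(10 equal-width bins when ≥ 8 points per bin, else raw points) and fit by
OLS with intercept. The slope estimates `k` with a 95% CI and R²; the
intercept near zero is a model check.

Choices worth noting:

- The **fit uses raw trial amplitudes**. Smoothing first (2 ms centered
  moving average, provided for trace display) shrinks the noise CI below
  the small deterministic higher-order bias (~5%) between FD-derived and
  analytic `k`, making "analytic k within the CI" ill-posed; on raw
  amplitudes the CI reflects the noise and covers the analytic value
  across seeds and across the `k(t)` window (coverage ≈ 0.91–0.94).
- `k(t)` time courses are fit where the reference PSP exceeds 20% of its
  peak; R² stays > 0.98 throughout, showing the rule holds at every time,
  not only at the peak.
- Noiseless trials recover the FD-derived slope to machine precision and
  the fit is stable to the bin count (6–16 bins: <5% slope variation).

## 7. Default parameters

Chosen as representative passive-membrane values for a hippocampal/
cortical pyramidal cell; all are plain package defaults and every public
function takes them as arguments.

| Quantity | Value | Rationale |
| --- | --- | --- |
| Dendrite length `L` | 600 µm | typical apical trunk scale |
| Dendrite diameter `d` | 1 µm | thin distal trunk |
| Soma area `S` | π·(25 µm)² ≈ 1963.5 µm² | 25 µm sphere |
| `c_m` | 1 µF/cm² | standard membrane value |
| `g_L` | 0.05 mS/cm² | `τ_m = c_m/g_L = 20 ms` |
| `r_a` | 0.1 kΩ·cm | standard axoplasm value |
| `ε_E` | +70 mV | rest −70 mV, E reversal 0 mV |
| `ε_I` | −10 mV | I reversal −80 mV; `ε_E ≫ |ε_I|` underlies the simplified cross term |
| E kinetics | σ_r = 5 ms, σ_d = 7.8 ms | tens-of-ms PSP time course |
| I kinetics | σ_r = 6 ms, σ_d = 18 ms | slower GABA-A-like decay |
| Grid | Δx = 2 µm, Δt = 0.05 ms | production; acceptance uses 1 µm / 0.02 ms |
| Sites | E at 200 µm, I at 100 µm | inhibition proximal to excitation |
| Modes | 80 | tail < 1e−4 of peak |

## 8. Problem sizes and runtimes (one CPU)

- One FD solve on the production grid (2000 steps × 301 nodes): ~0.3 s.
- Amplitude calibration (bisection): ~10 FD solves.
- Full 20-input multi-input study (20 calibrations, 21 FD solves, 190
  pairwise cross terms): ~35 s.
- Whole test suite: ~1 min; acceptance script: ~5 s plus calibration on
  the fine grid (~30 s total).

## 9. Known limitations

- Passive membrane only: no active channels, no branching; the rule's
  form is expected (from the literature) to survive both, but this
  package does not model them.
- The truncated hierarchy degrades for strong conductances (see §4); use
  the measured-PSP composition for quantitative work.
- E–E sublinearity is amplitude-dependent: `|SC|/SSP ≈ 0.04` at equal
  3 mV EPSPs but grows to ~0.07–0.09 toward 5–6 mV; the "<5%" figure
  refers to mid-physiological amplitudes.
- Recording noise is modeled as additive white Gaussian only.
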