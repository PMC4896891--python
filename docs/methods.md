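# Methods

## Model

Four electron-conformational states of the reaction center; occupancies
`x = (x1, x2, x3, x4)` evolve under the master equation

```
dx/dt = Q x,      Q_ij = k_ji (i != j),   Q_jj = -sum_i k_ji
```

Columns of `Q` sum to zero, so `x1+x2+x3+x4` is conserved; all
trajectories here start on the simplex with total 1.  State 1 is the
dark-adapted state and the normalized 865 nm absorbance is identified
with `x1(t)`.  Under illumination all 12 off-diagonal rates may be
nonzero; in darkness the light-driven rates `k12, k13, k14` are zero
(9 free rates).  Rates scale with excitation intensity only through the
packaged tables; the generator does not extrapolate between table
columns beyond the stored presets.

Because `Q` has a zero eigenvalue (conservation) on a 4-state network,
every observable is a constant plus at most **three** decaying
exponentials with decrements `d_i = -lambda_i(Q)`.  This identity — the
decrements are eigenvalues, the amplitudes are projections of the
initial condition onto left/right eigenvectors — is what ties the
decomposition layer to the inverse layer.

### Integration

`solve_occupancies` uses the analytic eigendecomposition
`x(t) = V exp(Lambda t) V^{-1} x0`.  If `cond(V) > 1e10` the matrix is
treated as (numerically) defective and we fall back to `scipy`'s LSODA
with `rtol=1e-10, atol=1e-12`.  Genuinely defective cases exist (e.g. a
pure chain `k12=k23` with equal rates); the fallback reproduces the
`t e^{-t}` secular behaviour to ~1e-8.  A property test checks the
analytic path against the ODE path to 1e-8 sup-norm over random rate
sets.

### Initial conditions

The dark-adapted state `x0 = (1,0,0,0)` is the canonical start for the
oxidation phase.  The reduction phase *requires* an explicit initial
condition: its trace alone does not determine where the occupancy left
by the light phase sits, so `fit_reduction` takes `ic` as a mandatory
argument.  The analysis drivers compute it by propagating the *fitted*
oxidation rates to light-off, so the pipeline never peeks at the true
generator state.

## Multi-exponential decomposition

`fit_multiexp` builds `f(t) = A0 + sum a_j exp(-b_j t)` by greedy term
addition: fit the residual with a single term (log-linear start refined
by bounded scalar search), then alternate sweeps re-optimizing each
decrement with the amplitudes re-solved by linear least squares
(`optimal_amplitudes`, QR-based).  A new term is accepted while it
improves RMSE by at least 1% *and* the fit is above the precision floor
`1e-8 × RMS(signal)`; the floor prevents fitting numerical noise with
spurious terms.  Two refinements matter in practice.  First, the
single-term prefilter inside the greedy step is only advisory: on a
strongly correlated residual a genuine extra mode can look flat in
isolation, so every candidate decrement is handed to the joint sweep and
the post-sweep improvement makes the model-order decision.  Second, when
the per-coordinate sweeps stall above the floor (decrements strongly
correlated over a short observation window), a joint Nelder-Mead polish
over all log-decrements finishes the descent.  On noiseless model traces
three terms reach RMSE below 1e-8 and a fourth is always rejected — the
model-order result the decomposition layer is designed to expose.

## Inverse solver

`fit_oxidation` / `fit_reduction` minimize the dispersion
`mean((x1_model - trace)^2)` over the admissible rate vector by staged
pairwise coordinate descent: rates are organized into forward/backward
pairs per edge (`(k12,k21), (k23,k32), ...`); each cycle visits pairs in
a schedule, optimizing each pair with Nelder-Mead in log-rate space
while all other rates are held fixed.  Pinned rates (the light-driven
set during reduction) are excluded from the schedule and held at zero.
Descent is monotone by construction — a pair update is accepted only if
it lowers the dispersion — and the recorded history is asserted
non-increasing in the tests.

Convergence: a cycle stops early when no pair moved its rates by more
than `rate_rel_tol`, or when the *cycle-level* dispersion improvement
falls below `disp_rel_tol × dispersion` (stall detection; this matters
on noisy traces where the noise floor is reached long before the rate
stability criterion fires).

### Constructive mode-matched starts

Coordinate descent from generic starts stalls in shallow basins, so the
default first start is constructed from the fitted exponential model
itself:

* **Oxidation from the dark-adapted state (star topology).**  With
  `x0 = e1`, a star network (state 1 exchanging with each of 2,3,4)
  reproducing given decrements and amplitudes can be written in closed
  form by partial fractions of the Laplace transform: the branch return
  rates are the roots of
  `N(s) = A0 * prod(s + d_i) + sum_i C_i s prod_{k != i}(s + d_k)`
  and the outgoing rates follow from the residues.  Under noise the
  construction can land marginally outside the admissible cone
  (slightly complex roots, slightly negative residues); such cases are
  *clipped* onto the boundary rather than rejected, because a projected
  start in the right basin beats an uninformed one.  Grossly
  inadmissible solutions (violations above 10% of scale) are rejected.
* **Reduction in darkness (relaxation cascade).**  With `k12=k13=k14=0`
  the network restricted to {2,3,4} is a transient system draining into
  state 1.  Any acyclic ordering `(s1, s2, s3)` of {2,3,4} with flows
  `s1->s2, s1->s3, s2->s3` plus drains to state 1 is solvable
  sequentially, giving closed-form mode weights in the three decrements.
  Matching those weights to the fitted amplitudes leaves one free flow
  (`f12`), which is scanned over `[0, d_fast]`; all 6 orderings × 6
  mode-to-decrement assignments are tried and the admissible candidate
  with the lowest dispersion seeds the descent.  Decompositions with
  fewer than three resolved terms are padded with a zero-weight dummy
  mode (at some intensities the third mode carries no measurable
  amplitude — see limitations).

With these starts a single multi-start (`n_starts=1`) suffices for every
packaged preset; random log-uniform restarts remain available.

## Problem sizes and runtime

Traces are 5k–30k samples; one noiseless inversion takes 2–9 s, one
noisy inversion 3–20 s (single CPU).  The full recovery grid
(6 noiseless + 10 noisy) runs in a few minutes.

## Validation and known limits

* **Round trips.**  Noiseless: trace RMSE ≤ 4.1e-9 and decrement errors
  ≤ 2.3e-5 at all six packaged intensities (oxidation), and RMSE
  1.4e-7 / decrement error 1e-5 for the reduction example.
* **Noisy recovery and identifiability.**  With Gaussian noise
  sd 5e-4, recovery of the decrements is only meaningful for modes that
  carry amplitude above the noise.  At 0.2 mW/cm^2 the middle mode's
  amplitude is ~0.007 — the 3-term *decomposition itself* misplaces that
  decrement by ~8% on some noise draws, so no inverse method can do
  better from that trace.  At 2 mW/cm^2 the amplitudes are
  ~(0.78, 0.06, 0.15): all three modes are resolvable and the full
  pipeline recovers every decrement within 1.1% across 10 seeds.  The
  noisy validation is therefore stated for the well-separated-mode
  condition; the low-intensity case is an information limit of the
  measurement, not of the solver.
* **Rates vs decrements.**  Individual rate constants are generally not
  identifiable from a single `x1` trace (many rate sets share one
  marginal).  Validation therefore scores the trace residual and the
  decrement spectrum, which are identifiable.
* **Degenerate spectra.**  Near-coincident decrements reduce the
  effective model order; the decomposition reports fewer terms and the
  cascade start pads accordingly.
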