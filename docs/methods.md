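# Methods

## The model

`trajlm` treats a spatially discretized 1-D order-parameter trajectory as a
sentence in an N-character alphabet and fits a character-level LSTM language
model to it.  At each time step the current character `s(t)` (one-hot,
length N) is embedded as a dense M-vector `x(t) = Λ s(t)`; an LSTM cell with
L units updates its hidden and cell state

    f = σ(W_f x + U_f h + b_f)        (forget gate)
    i = σ(W_i x + U_i h + b_i)        (input gate)
    o = σ(W_o x + U_o h + b_o)        (output gate)
    c~ = tanh(W_c x + U_c h + b_c)    (candidate cell value)
    c(t) = f ∘ c(t-1) + i ∘ c~
    h(t) = o ∘ tanh(c(t))

and a dense head predicts the next-character distribution
`ŷ(t) = softmax(D_d h(t) + b_d)`.  Training minimizes the teacher-forced
cross-entropy `J = −Σ_t ln ŷ(t)[s(t+1)]`.

Because per-symbol cross-entropy of a stationary ergodic source is bounded
below by the source's entropy rate, and the gap is the Kullback–Leibler
divergence between the true and the learned path measures, a per-symbol
loss that converges onto the analytic entropy rate certifies that the model
has learned the path distribution — this is the package's central testable
property, checked against Markov chains whose entropy rate is known in
closed form.

The learned object supports three analyses:

1. **Boltzmann statistics.**  Autoregressive sampling at temperature 1
   produces synthetic label trajectories; metastable-state occupancies of
   generated and input trajectories are compared with standard errors over
   contiguous segments.
2. **Commit-time kinetics.**  A trajectory is *committed* to a state once
   it has spent `commit_time` consecutive samples there.  Transition counts
   between consecutive committed visits, as a function of commit time,
   characterize kinetics across timescales; generated trajectories should
   reproduce the input's curves.
3. **Embedding kinetic distance.**  The dot-product geometry of the learned
   embedding columns defines a transition-probability ansatz
   `Q_lm = exp(x_m·x_l)/Σ_k exp(x_k·x_l)`; combined with the model's
   state probabilities `Q_l` this gives an interconversion time
   `t_lm = 1/(Q_l Q_lm + Q_m Q_ml)`, compared (after min-max rescaling)
   against the counted commute time `τ_lm = T/⟨N_lm⟩`, where `⟨N_lm⟩`
   averages both-direction transition counts over the commit-time grid.

## Built-in study systems

Three 2-D model potentials (polynomial confinement `W(x^d + y^d)` with
`W = 10⁻⁴` plus signed Gaussians of width σ = 0.8) are sampled by
overdamped Euler–Maruyama Langevin dynamics, `dt = 0.01`, at β = 9.5
(linear 3-state, 4-state) and β = 9.0 (triangular 3-state); only the
x-coordinate is given to the model.

* **linear3** — wells at (−2,0), (0,0), (2,0), sextic confinement.  The
  x-projection is kinetically truthful: A↔C requires passing through B.
* **triangular3** — an equilateral triangle of side 2.2: wells at
  (−1.1,0), (1.1,0), (0, 1.1√3), sextic confinement.  All pairs are
  kinetically equidistant, but the x-projection (−1.1, +1.1, 0) makes the
  apex state look like an intermediate.  The side length was chosen so
  barrier heights are comparable to the linear system's well spacing of 2
  and transitions are abundant in desk-scale runs; placing the outer wells
  at x = ±2 (side 4) makes barrier crossing ~10³ times rarer at these
  temperatures and would require trajectories of ≥10⁸ steps for usable
  transition statistics.  Centers are configurable.
* **four_state** — quartic confinement, repulsive bump at the origin and
  wells at (2,−1), (0.5,2), (−0.5,−2), (−2,1), exactly the printed
  geometry.  The x-projection overlaps the two middle wells, and the
  highest-barrier pairs show very few direct transitions at desk scale —
  an intrinsic sampling limitation of this system, visible as larger error
  bars and forward/backward count asymmetry.

The integrator is overdamped with unit friction and mass: it has the exact
Boltzmann stationary law (up to O(dt) discretization bias) and no free
parameter beyond dt and β.  Trajectories are saved every 10 steps; one
"sample" in all kinetics below is therefore 0.1 time units.

## Discretization and state assignment

Bins are N = 32 equal-width intervals spanning the observed range of the
training series; representative values are bin midpoints; the last bin is
closed and out-of-range values clamp, so encoding is total.  Metastable
states are the labels whose representative value lies within 0.5 (the
well Gaussian σ being 0.8) of a well center's x-projection, nearest-well,
ties to the lower state id; barrier bins stay unassigned and are skipped in
kinetics.  In any 1-D projection of a 2-D landscape some barrier crossings
pass through another state's window (e.g., the triangular A↔B saddle lies
at x ≈ 0, inside the apex state's window); commit-time counting suppresses
these single-sample apparitions at commit times above 1–2 samples, which is
exactly the artifact the commit formalism exists to handle.

## Training protocol

Windows of 100 symbols (+1 target) are cut without overlap, shuffled each
epoch (run-seeded), batched at 64; the hidden state resets to zero at every
window start, which makes training order-independent.  The final 10% of
the series (contiguous, unshuffled) is the validation split.  Softmax is
max-subtracted and the loss uses log-sum-exp; gradients are clipped at
global norm 5.  Default dimensions for the model potentials are M = 8,
L = 64; 20 epochs.

Both plain SGD (the historically used method) and Adam are implemented.

## Sampling protocol

Generation feeds a random training subsequence of 100 symbols through the
model, then draws each next character from the learned categorical law at
temperature 1 and feeds it back; the first 1000 generated symbols are
discarded as burn-in.  Temperature is fixed at 1 because the Boltzmann and
kinetics claims require unbiased samples of the learned conditional.
Periodically re-warming the state from the trailing context (to mimic the
zero-state training regime exactly) was evaluated and produced statistics
indistinguishable from free-running generation, so the simpler protocol is
used.

## Error bars and comparison protocol

Standard errors are population SD over contiguous segments divided by
√n_segments.  For generated-side statistics the pipeline trains several
independent trials (fresh initialization, shuffling and sampling streams)
and pools each trial's segments, so the quoted SE includes trial-to-trial
training variability; each trial generates an equal share of a trajectory
as long as the training series.  Agreement between input and generated
statistics is quantified as z = |difference| / √(SE_md² + SE_lm²); grid
points where both sides have zero counts and zero spread agree exactly
(z = 0).

## Numerical and degenerate-input choices

* Encoding requires a non-degenerate range; constant series are rejected.
* `free_energy` maps zero probability to +inf rather than raising.
* Min–max rescaling maps an all-equal vector to 0.5 and infinite commute
  times (pairs with no observed transitions) to 1.
* The stationary distribution of a fixture chain is the leading left
  eigenvector; irreducibility is checked by strongly connected components.
* Commit counting: runs shorter than the commit time are skipped and equal
  committed neighbours merged — under this rule per-pair commit curves are
  *not* necessarily monotone in commit time when a pair is bridged by an
  intermediate state (via-B paths become direct A→C counts once B's visits
  fall below the commit time); only the total committed-transition count is
  monotone.  The package reports curves as measured.
* Interconversion-time aggregation: `Q_l` and `Q_lm` are collapsed from
  labels to states by occupancy-weighted averaging over in-state labels
  ("weighted", the default — per-trial measurements showed that
  representing a state by a single modal label leaves the distance
  dominated by the noise of one embedding column) or by the most occupied
  label ("modal").
* Markov-chain fixture evaluations score the trained model on a long fresh
  realization of the chain rather than on the short in-sample validation
  split, whose own finite-sample entropy fluctuates by several percent.

## Problem sizes

Model-potential studies in the test suite and the acceptance script use
trajectories of 1.5–5 × 10⁶ integrator steps (1.5–5 × 10⁵ samples at
stride 10), 2–4 training trials per system, and commit-time grids of 1–200
samples.  These lengths give hundreds to thousands of well-to-well
transitions for the 3-state systems; the 4-state system's slowest pairs
remain sparsely sampled, as they are in the original study design.

## Known limitations

* The synthetic Langevin data are exactly Markovian in 2-D and nearly so
  after projection and striding; real molecular or experimental series have
  memory, measurement noise and drift that these tests do not probe.
* Generated long-horizon statistics (occupancies, slow-pair commit counts)
  carry a finite-training bias of a few percent per trial that is not
  eliminated by driving the per-symbol loss to the entropy floor; it is
  partially averaged out across trials, and it is visible once trajectory
  standard errors fall below ~2%.
* The embedding-based kinetic distance is the least stable readout: at
  desk-scale training (10⁵–10⁶ symbols, 20 epochs) the induced geometry
  varies qualitatively between training trials — roughly half of individual
  trials reproduce the expected linear-system pattern — so distance
  contrasts should be read from many-trial ensembles, which the original
  protocol (50 trials) used and desk-scale runs cannot afford.
* The 4-state system's corner wells equilibrate only on ≥10⁷-step
  trajectories (symmetry-equivalent wells can differ 30-fold in measured
  occupancy below that), and the commit-grid-averaged commute time of the
  x-adjacent well pair is dominated by single-sample projection flickers;
  rank comparisons of kinetic distances on this system are accordingly
  unreliable at desk scale.
* Single-layer LSTM only; the biomolecular-scale configuration (M = 128,
  L = 1024) runs but is far too slow for routine testing in NumPy.
* Multi-dimensional order parameters are out of scope; only scalar series
  are encoded.
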