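# Methods

## The model

`srsmotor` simulates SpoIIIE motors on linear DNA as a discrete-time,
discrete-space stochastic process.  A DNA molecule is a 1D lattice of `n`
sites, one site per base pair; a site is either SRS (inside an SRS
interval) or non-specific (NS).  Motors are in one of four states:
unbound, bound (diffusing), translocating (ATP-active), or retired
together with their DNA molecule once its triplex has been displaced.
All rates are probabilities per Monte Carlo step (MCS).

One MCS updates every motor from the common pre-step state:

1. **Binding.**  An unbound motor draws one candidate site uniformly on
   its DNA molecule and binds with probability `p_on(site type)` if the
   site is free.  With `p_on^SRS = p_on^NS` (the default) this is uniform
   binding, matching the observation that association rates are
   sequence-independent.
2. **Unbinding / activation / sliding.**  A bound motor unbinds with
   `p_off(site)`.  A survivor, when ATP is present, activates with
   `p_atp(site)`; on activation it draws its translocation direction —
   on an SRS site the SRS-dictated direction (toward the end the motif
   points at) with probability `p_dir`, otherwise the opposite; on an NS
   site ±1 equiprobably — and the direction then stays fixed until the
   motor dissociates.  A bound motor that did not activate takes one
   sliding step: magnitude drawn from the discretised non-negative normal
   |N(sld_mean, sld_sd)| of its current site type, sign ±1 equiprobably,
   reflecting off the lattice ends.  **A sliding motor scans the DNA it
   traverses and is captured by the first SRS site crossed.**  Sliding is
   thereby the target-search mechanism: with the default kernels
   (145 ± 36 bp on NS, 1.0 ± 0.25 bp on SRS) a motor explores hundreds of
   base pairs per step on non-specific DNA but is nearly immobile once on
   SRS.
3. **Translocation.**  A translocating motor unbinds with `p_off^NS`
   (dissociation during translocation is sequence-independent); otherwise
   it advances `v_step = round(v_trans · dt)` sites in its fixed
   direction.  Translocation does not stop at SRS.  Reaching the
   triplex-bearing end displaces the triplex with probability `p_triplex`
   and retires the molecule.  Reaching a plain end arrests the motor at
   the terminal site, still in its active state; it leaves only by
   dissociation.  This arrest is what accumulates motors at the DNA ends
   in the ATP steady state (~40% of attached motors at the defaults).
4. **Collisions.**  If two motors propose the same site, a translocating
   motor displaces a bound/diffusing one; ties within a class are broken
   uniformly at random and the loser unbinds.  With the default
   stoichiometry of one motor per DNA molecule this phase is inert.

Updates are synchronous (all motors propose from the pre-step state, then
conflicts are resolved).  With one motor per molecule this is exactly
equivalent to sequential per-motor scheduling, because motors on different
molecules never interact; for multi-motor studies the collision rule above
is the normative semantics.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `p_on_srs`, `p_on_ns` | 0.022 | /MCS | association (identical on both site types) |
| `p_off_srs` | 0.006 | /MCS | dissociation from SRS (~2.3× slower than NS) |
| `p_off_ns` | 0.014 | /MCS | dissociation from NS sites and during translocation |
| `sld_ns` | 145 ± 36 | bp | sliding-step length on non-specific DNA |
| `sld_srs` | 1.0 ± 0.25 | bp | sliding-step length on SRS |
| `p_atp_ns` | 0.012 | /MCS | activation on non-specific DNA |
| `p_atp_srs` | 0.012 | /MCS | activation on SRS; ≥ 0.4 reproduces the measured kinetic asymmetry regime |
| `p_dir` | 0.5 | — | probability an SRS-triggered activation heads toward the SRS-proximal end |
| `p_triplex` | 1.0 | — | triplex displacement on end arrival by translocation |
| `v_trans` | 5000 | bp/s | translocation velocity |
| `dt` | 0.07 | s/MCS | time calibration (below) |
| `equilibration_mcs`, `sampling_mcs` | 2000, 1000 | MCS | occupancy averaging window |

Substrate geometry defaults: a 3000-bp lattice (the experimental substrate
is a ~3-kb plasmid derivative), one 22-bp SRS triple repeat with its
proximal edge 300 bp from the left (5′, triplex) end, oriented toward that
end.  The non-specific control replaces the SRS by plain sites and keeps a
`control_window` marking the equivalent region.  The exact SRS offset on
the experimental substrate is not published; it is fully configurable, and
θ is insensitive to it (varying the offset 25–300 bp moves θ by < 0.02).

**Time calibration.**  Probabilities are defined per MCS, so every
frequency-ratio observable (occupancies, θ) is independent of `dt`; `dt`
only converts MCS to seconds and sets `v_step`.  The default
`dt = 0.07 s` makes the mean active lifetime 1/`p_off_ns` ≈ 71 MCS ≈ 5 s,
consistent with the measured seconds-scale single-round translocation
times, and gives `v_step = 350 bp/MCS` at 5 kb/s.

## Observables

- **SRS occupancy** (no ATP): temporal average, over the sampling window,
  of (#bound motors in the SRS window)/(#bound motors); snapshots with no
  bound motor are skipped.  The window defaults to the SRS interval.
- **End occupancy** (ATP): temporal average of (#attached motors at the
  DNA ends)/(#attached motors).  The default window is the terminal
  lattice site at each end — the population that has arrived by
  translocation — because with end-arrest the model's "reached the end"
  motors sit exactly there; `AFM_BIN_BP` (147 bp = one 50-nm bin at
  0.34 nm/bp) is available for the AFM-style readout, which adds motors
  diffusing through the terminal region (~3 percentage points at the
  defaults).
- **Localization histogram / F ± δF:** positions are binned at 50 nm; the
  first-bin relative frequency is F = f(x₁)/Σf(xᵢ), with
  δF = sqrt(((S−f₁)/S²)² + (n_bins−1)(f₁/S²)²), S = Σfᵢ, from first-order
  propagation with an uncertainty of ±1 protein per bin.
- **Kinetic trace / θ:** a triplex run records the cumulative released
  fraction from t = 0; the anisotropy proxy is 1 − released fraction
  (the signal is assumed linear in the number of intact triplexes).
  θ = AUC(signal_SRS)/AUC(signal_NS) by the trapezoid rule over a common
  window — by default from t = 0 to the first MCS at which the *slower*
  substrate reaches 95% release (capped at 50 000 MCS).  θ is invariant
  under relabelling the time axis with a different `dt`.  Because both
  signals decay to zero, θ is monotone in the window length and converges
  to the mean-release-time ratio; the 95% rule sits close to that limit.
- **First-passage statistics:** search time = MCS from binding to first
  SRS arrival within one continuous bound episode (episodes that detach
  first are excluded); translocation duration = activation to
  dissociation or end arrival.  At the defaults the mean search time is
  ≈ 40 MCS ≈ 2.8 s and the off-rate-limited translocation duration is
  ≈ 71 MCS ≈ 5 s, both on the experimentally observed scales.

## The simulator as data source

The package generates all of its own data.  Simulated position snapshots
emulate what AFM sees — an instantaneous localization of protein on DNA —
but not deposition artefacts, surface-equilibration bias, imaging
resolution, or the image-analysis step (position tables are taken as
given, and `fixtures.generate_afm_positions` produces synthetic tables
from a known bin distribution for round-trip tests).  Kinetic traces
emulate the anisotropy decay only through the linearity assumption above:
photophysics, dead time and instrument noise are outside the model.
Passing tests therefore validate the model logic and its statistics, not
those experimental layers.

## Numerical choices

- The sliding magnitude PMF discretises the normal by rounding to the
  nearest non-negative integer after resampling negative draws
  (mass at k is Φ(k+½)−Φ(k−½) on k ≥ 1, Φ(½)−Φ(0) at 0, renormalised);
  the engine samples it by inverse CDF, and the oracle consumes the same
  PMF, so both share one discretisation.
- Boundary reflection folds positions with the triangle map of period
  2(n−1).  SRS capture scans at most one reflection per step; the engine
  therefore requires the kernel reach to be below n−1 on SRS-bearing
  substrates (always true at the defaults).
- The no-ATP oracle builds the exact (n+1)×(n+1) one-MCS transition
  matrix (guarded to n ≤ 200) and solves πP = π by least squares with a
  normalisation row; the residual must be below 1e−10.  Oracle/simulation
  agreement within 3 Monte Carlo standard errors is the primary
  correctness gate for the Markov rules.
- Stationary occupancy of the homogeneous chain is uniform only in the
  interior: reflecting jumps distort a boundary layer of about one kernel
  reach.  Tests assert interior uniformity.
- Zero-denominator guards: occupancy ratios skip zero-bound snapshots;
  θ raises on a zero NS area; empty event sets return `None` rather than
  raising.
- Replicate seeds derive from a base seed via `SeedSequence` and stay
  below 2³¹; identical inputs give bit-identical outputs.
- Scales: occupancy scenarios use 1000 molecules × 3000 MCS; triplex runs
  1000 molecules until full release (typically 2000–5000 MCS); the
  activation sweep uses 3 replicates per grid point with the non-specific
  control traces shared across grid values (they do not depend on
  SRS-side parameters).  Each scenario takes on the order of a second on
  one CPU.

## Design choices where the rules were open

- **Per-MCS action order** bind → unbind → activate → slide →
  translocate → collisions; each motor takes at most one stochastic
  action class per MCS.
- **Slide capture.**  Whether a sliding step lands blindly or scans the
  intervening DNA is a genuine openness of "slide a distance sld".
  Scanning-with-capture is adopted: it is the facilitated-diffusion
  reading (recognition happens while sliding over the motif), and it is
  what quantitatively produces the observed ~38% SRS occupancy at the
  published rates (blind landing yields ~25%).
- **End arrest.**  A motor whose translocation reaches a plain DNA end
  stays arrested there, active, until it dissociates — the reading on
  which translocation direction is "constant until dissociation".  The
  alternatives (reverting to diffusion, or re-activating in place with a
  fresh direction) were evaluated and rejected: resumed diffusion empties
  the ends (~14% instead of ~40% end occupancy), and in-place
  re-activation suppresses the end accumulation that instant activation
  (p_ATP = 1) must produce.
- **Direction across episodes.**  A motor that dissociates and rebinds,
  or re-activates later, draws a fresh direction; persistence applies to
  one continuous translocation run.
- **Binding-site choice** is uniform with acceptance by site-type
  p_on — equivalent to uniform binding at the default equal p_on values.

## Known limitations

- The catalytic-regulation sweep (raising `p_atp_srs` at fixed
  `p_atp_ns`) reproduces the qualitative saturation: θ falls steeply and
  plateaus for `p_atp_srs` ≥ 0.4, where release on the SRS substrate
  becomes limited by the ATP-independent steps.  Quantitatively the
  plateau computed by `scripts/acceptance.py` sits at θ ≈ 0.71–0.75,
  above the experimentally measured 0.62 ± 0.06 band.  The plateau value
  equals the mean-release-time ratio, and on the SRS side that time is
  dominated by repeated bind/search cycles whose efficiency is fixed by
  the published binding and sliding rates (the same rates reproduce the
  measured ~2.8-s search time), so within this model the gap cannot be
  closed by any window, geometry or calibration choice; it is reported as
  is rather than absorbed into a redefined statistic.
- The model has no ATP-concentration dependence, no mechanochemical
  stepping substructure, no hexamer assembly, and no 3D
  hopping/intersegmental transfer; "1 site = 1 bp" ties the lattice to
  the sliding-length calibration.
- Multi-motor crowding is supported (collision rule above) but the
  defaults follow the experimental ~1 hexamer per DNA stoichiometry, and
  the collision rule has not been confronted with crowding data.
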