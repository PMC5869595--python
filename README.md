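# srsmotor

Stochastic lattice model of the *Bacillus subtilis* DNA translocase
SpoIIIE interacting with linear DNA: non-specific binding, anomalous 1D
sliding, sequence-regulated ATP activation, directional translocation, and
single-round triplex-displacement kinetics.

SpoIIIE pumps chromosomal DNA across the sporulation septum.  Its
directionality is set by octameric SpoIIIE Recognition Sequences (SRS,
`GAGAAGGG`) read in an orientation-specific way.  This package implements a
kinetic Monte Carlo model for distinguishing two candidate mechanisms:
*recruit-and-orient* (SRS concentrates and points the motor) versus
*catalytic regulation* (SRS raises the probability that a bound motor
starts translocating).  It is aimed at single-molecule biophysicists who
want to confront AFM localization data and fluorescence-anisotropy triplex
assays with an explicit motor-DNA model.

## Model

Each of *m* DNA molecules is an array of *n* sites (1 site = 1 bp); *r*
motors (default one hexamer per molecule) evolve in discrete Monte Carlo
steps (MCS).  Per MCS a motor can

- **bind** a uniformly drawn site with probability *p*<sub>on</sub>
  (0.022, identical on SRS and non-specific DNA),
- **unbind** with *p*<sub>off</sub> (0.006 on SRS, 0.014 elsewhere —
  SRS dissociation is ~2.3-fold slower),
- **slide** a distance drawn from |N(*sld*<sub>m</sub>, *sld*<sub>s</sub>)|
  in a random direction: 145 ± 36 bp on non-specific DNA but 1.0 ± 0.25 bp
  on SRS (anomalous sliding), reflecting at the DNA ends and stopping at
  the first SRS site scanned,
- **activate** (with ATP) with *p*<sub>ATP</sub> per MCS
  (0.012 on non-specific DNA; the SRS value is the central free
  parameter), then translocate deterministically at *v*<sub>trans</sub> =
  5 kb/s with a direction fixed until dissociation
  (*p*<sub>dir</sub> toward the SRS-proximal end when activated on SRS,
  50/50 on non-specific DNA),
- **displace the triplex** when translocation reaches the triplex-bearing
  DNA end (probability *p*<sub>triplex</sub> = 1), retiring that molecule.

Observables mirror the experiments: the fraction of bound motors in the
SRS window (no ATP), the fraction at the DNA ends (with ATP), the 50-nm
AFM localization histogram with its first-bin statistic
F = f(x₁)/Σf(xᵢ) ± δF, and the triplex kinetic trace with the area-under-
curve ratio θ<sub>SRS/NS</sub> between SRS and non-specific substrates.
An exact transition-matrix oracle of the no-ATP Markov chain doubles as an
independent correctness check of the simulator.

## Worked example

```python
import srsmotor as sm

res = sm.run_preset("noATP_SRS", seed=1, n_dna=1000)
occ = sm.srs_occupancy(res)
print(f"SRS occupancy (no ATP): {occ.mean:.3f} +/- {occ.sd:.3f}")

res_atp = sm.run_preset("ATP_SRS", seed=1, n_dna=1000)
end = sm.end_occupancy(res_atp)
print(f"End occupancy (ATP):    {end.mean:.3f} +/- {end.sd:.3f}")

theta, _, _ = sm.run_theta_pair(seed=1, n_dna=1000)
print(f"theta_SRS/NS (equal activation): {theta:.3f}")
```

prints

```
SRS occupancy (no ATP): 0.357 +/- 0.018
End occupancy (ATP):    0.435 +/- 0.019
theta_SRS/NS (equal activation): 0.975
```

Without ATP roughly 36% of DNA-bound motors sit on the 22-bp SRS (a
~50-fold enrichment over its length fraction, produced by anomalous
sliding plus slow SRS dissociation); with ATP ~43% of attached motors have
translocated to a DNA end; and with equal activation probabilities the two
substrates displace the triplex at nearly the same rate (θ ≈ 1), showing
that affinity alone does not create directionality.  Raising the SRS
activation probability is what accelerates the SRS substrate:

```sh
$ srsmotor triplex --p-atp-srs 0.8 --seed 1 --n-dna 1000
theta_SRS/NS = 0.707 +/- 0.028 (3 replicates; AUC window to 95% completion
of the slower trace, NS 95% at MCS [1482, 1365, 1287])
```

The same CLI exposes `simulate`, `sweep`, `afm-quant` (Eq.-style F ± δF
from a position table), `scan` (FASTA → BED of SRS motifs on both strands)
and `fixtures`.

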