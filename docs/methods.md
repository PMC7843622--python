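# Methods

## Decaying-source dosimetry

The dose model treats a well-stirred medium of mass *m* (kg) as both
source and target for the β⁺ emissions of a dissolved radionuclide.
With initial activity *A₀* (Bq), decay constant λ = ln 2 / t½ (s⁻¹),
β⁺ branching ratio κ and mean β⁺ energy Ē (J), the absorbed dose over
an irradiation time *T* is D = Ã Ē κ / m with cumulated activity
Ã = A₀ (1 − e^(−λT)) / λ. Assumptions:

* **Absorbed fraction 1 for β⁺.** Mean/maximum ¹⁸F β⁺ ranges in water
  (0.6 / 2.4 mm) are small against the dimensions of a ≥2 mL medium
  volume, so essentially all β⁺ kinetic energy is absorbed locally.
  This slightly overestimates dose near the free surface.
* **Annihilation photons excluded.** The two 0.511 MeV photons have
  centimetre-scale interaction lengths and mostly escape a small flask;
  their contribution is omitted from the analytic dose. This is the
  main reason a full transport calculation over an enclosing phantom
  would report a few percent more dose.
* **Water-equivalent medium.** Mass defaults to volume × 1 g/mL; an
  explicit mass inconsistent with that by more than 1% requires an
  override flag.

Units: seconds, Bq, Gy; nuclide record energies in keV, converted to
joules only inside the dose kernel. The inverse planner is the exact
algebraic inverse, so plan → dose → plan round-trips to ~10⁻¹⁰
relative. Evaluating the model for the three measured activities
(52.4 / 104.9 / 157.3 MBq, 18 h, 2 mL) gives 9.63 / 19.27 / 28.90 Gy,
about 0.7% below the rounded values usually quoted for these plans;
the difference is within the stated measurement uncertainties and is
not adjusted for.

## Clonogenic survival and RBE

Plating efficiency (PE) is the mean colonies/seeded ratio of the 0 Gy
controls; SF(D) is the mean treated ratio divided by PE. The standard
error of SF combines replicate scatter with a Poisson counting floor
(√N counting error of the pooled colony counts): with a handful of
replicates, the sample SEM alone is an unreliable weight and the
counting floor stabilizes both the weighted fit and its covariance.
Doses where no colonies formed are flagged below-detection and
excluded from log-domain fitting.

The LQ model ln SF = −(αD + βD²) is fitted through the origin by
weighted least squares with weights 1/se², se = sf_err/SF, and α, β
constrained non-negative (physical branch; an unconstrained fit is
available). The covariance is (XᵀWX)⁻¹ treating the supplied errors as
absolute; when no errors are available the residual variance scales it.

Because α̂/β̂ is a ratio of correlated noisy estimates it carries an
upward Jensen bias of order var(β̂)/β². `LQFit.alpha_beta_ratio` is the
plain ratio; `alpha_beta_ratio_debiased` subtracts the second-order
delta-method term and is the right choice when averaging recovered
ratios across many datasets (the parameter-recovery checks use it).

RBE(sf) = D_ref(sf) / D_test(sf) from the two fitted curves; the
positive root of βD² + αD + ln sf = 0 gives D(sf). For a test arm
whose curve is nearly exponential and sparsely sampled, a piecewise
log-linear interpolation route (`method="interp"`) is provided;
results outside the measured range carry an extrapolation flag. RBE
confidence intervals propagate both fit covariances by the delta
method with numeric gradients.

## Linear DNA geometry

A straight 100-bp double-helix abstraction: 34 nm long, 2.37 nm outer
diameter, 1 nm base-core diameter, 0.34 nm rise per base. Per base
pair, the cross-section holds two half-cylinder base sectors (inner
core, one per strand) and two quarter-cylinder backbone sectors in the
annulus, centred at azimuth 0° and 180°. The remaining half of the
annulus is not a scoring volume. Choices where the published geometry
is silent, exposed as parameters:

* **No helical twist by default** (twist per base 0°, 36° available):
  the scoring statistics of an isotropically irradiated cylinder are
  insensitive to twist, and the untwisted sectors admit an exact
  brute-force oracle.
* **Sector placement**: backbone quarters at 0°/180°; base halves
  split at ±90°. All intervals half-open, lower bound inclusive, so
  classification is a total deterministic function.
* **Source volume**: coaxial cylinder, radius twice the DNA outer
  radius, extending one outer radius past each end. It encloses and
  overlaps the DNA; emission from inside scoring volumes is allowed.
  Recorded in all campaign output.

## Surrogate track-structure model

The transport model is deliberately parameterized rather than derived
from interaction cross sections: published sub-keV positron/electron
cross-section sets are not reproduced here, and every default below is
configuration recorded alongside output. The defaults encode three
qualitative facts about sub-keV lepton tracks in water: energy is lost
in discrete spur-scale quanta (tens of eV, up to ~100 eV), inelastic
mean free paths are nanometre-scale, and stopping power falls with
energy over 250–1500 eV.

* Inelastic mean free path: log-log interpolated, 2 nm at 250 eV to
  6 nm at 1500 eV.
* Per-collision loss: exponential, mean 40 eV, truncated at 100 eV
  (and at the remaining energy).
* Elastic channel: mean free path 0.5× inelastic; Gaussian polar
  deflection, σ = 30°.
* Transport cutoff 100 eV: transport below this energy is not followed
  event by event; the residual is deposited as a terminal blob.
* Positron terminus: the blob is smeared over a Gaussian of σ = 2 nm
  (the blob is a diffuse multi-species cluster, not a point), and the
  terminal annihilation appends 2 extra ionizations of 20 eV each
  within the same radius, flagged `annihilation`. Annihilation photons
  are not transported (negligible interaction probability over nm) and
  a core-electron annihilation probability exists only as a
  qualitative flag. Secondaries are not transported independently —
  sub-100 eV electrons are below the cutoff by construction.

Energy bookkeeping is exact: non-annihilation event energies sum to
the initial kinetic energy; annihilation-channel energy is extra and
separately flagged, included in damage scoring and LET but never in
the conservation identity. LET is total deposited energy over path
length (eV/nm ≡ keV/μm); it is undefined (NaN) for zero-path tracks.

Each primary draws its RNG stream from (seed, species, energy, primary
index), so campaigns are bit-reproducible and order-independent, and
per-seed results are kept separate to report mean ± spread (max−min).

## Strand-break scoring

Energy is accumulated per backbone volume per primary history; a
volume reaching the 17.5 eV threshold (inclusive) records one SSB.
Base-core depositions never produce breaks. A per-event accumulation
mode exists for sensitivity analysis. DSBs pair SSBs on opposite
strands within 10 bases (inclusive) by a greedy ascending sweep taking
the nearest eligible partner, each SSB used once. For breaks indexed
on a line with a maximum-separation rule, matching the leftmost
unpaired break to its nearest (equivalently leftmost) compatible
partner is optimal, so the greedy count equals the maximum-cardinality
matching; the test suite verifies this against exhaustive search.
Same-strand pairing and a zero-separation rule are available behind
flags. Raising the threshold can only remove breaks (monotonicity).

## Synthetic data

* **Clonogenic assays**: colonies ~ Poisson(seeded · PE · SF(D)),
  truncated at the seeded count (binomial optional). Defaults: PE 0.5,
  3 replicates, the 0–7.5 Gy (2.5 Gy step) reference grid, and
  per-dose seeding aiming at ~100 expected colonies — the standard
  practice of seeding more cells at higher doses. Two-arm studies
  rescale the reference curve (α → rα, β → r²β) so the dose ratio at
  every survival level equals the constructed RBE truth r.
* **Event streams**: Poisson event counts per primary, uniform 5–25 eV
  energies, positions either uniform in the source or clustered within
  1.2× the DNA outer radius; each stream ships with ground-truth
  SSB/DSB counts from an independent scalar naive scorer.

What the generators do *not* emulate: real assays have inter-experiment
PE drift, counting subjectivity and dose-delivery uncertainty; real
event streams have spatially correlated spur structure along tracks.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated noise model, not performance on real
laboratory data.

## What the surrogate campaign can and cannot show

The simulator reproduces *structural* properties: exact energy
conservation; the positron-as-electron limit (annihilation and
smearing disabled, transport distributions coincide); the annihilation
channel can only add damage (with a common transport stream the
with-channel event set is a superset per primary, so SSB/DSB counts
are pointwise ≥ the electron-limit baseline); and ensemble LET
decreasing with initial energy, with positron LET exceeding electron
LET at 250 eV. Absolute SSB/DSB frequencies per 10⁶ primaries, and
therefore the exact percentage SSB/DSB excess of positrons over
electrons at a given energy, depend on the underlying cross sections
and on the blob/annihilation parameterization; the campaign reports
them as properties of this surrogate model only. In particular the
cross-species DSB difference at mid energies is the small net of an
annihilation gain and a blob-smearing loss and is statistically
indistinguishable from zero at desk-scale primary counts.

Problem sizes used by the default test and reproduction runs: 500
synthetic assays for LQ recovery, 40 two-arm studies for RBE, 10⁴ (2 ×
10³ in the reproduction script) random event sets for the scoring
oracle, 10⁵ primaries for the electron-limit equivalence test, and
4–12 × 10³ primaries per (species, energy) cell for campaign trends.

## Known limitations

* No photon or secondary-electron transport; no radical chemistry or
  indirect damage; no repair modeling; direct-damage SSB/DSB only.
* Dose model has no geometry beyond a mass; no dose-rate (G-factor)
  correction in the LQ analysis — the two irradiation modalities the
  package compares differ enormously in dose rate, and that biology is
  out of scope.
* The DSB pairing convention (greedy/maximum matching) is one of
  several defensible readings of a proximity rule; counts for dense
  break clusters depend on it, which is why it is pinned down exactly
  and oracle-tested.
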