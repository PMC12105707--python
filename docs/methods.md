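# Methods

## System and scope

`cptube` analyzes the stability of nanotubes formed by stacked cyclic
D,L-peptide–polymer conjugates ("unimers").  A cyclic peptide of
alternating D- and L-residues is flat, with its backbone amides
perpendicular to the ring plane; stacked rings hydrogen-bond like an
antiparallel beta-sheet.  For an 8-residue ring, each inter-ring interface
supports up to 8 backbone N–H···O=C bonds, so an octamer (7 interfaces)
supports at most 56, of which 16 belong to the two cap interfaces
(terminal unimers) and 40 to the core.

The package does not run molecular dynamics.  It supplies (i) idealized
nanotube geometry, (ii) synthetic trajectories and bond-occupancy kinetics
with known ground truth, (iii) geometric hydrogen-bond detection and
break-rate statistics, and (iv) a core–shell cylinder scattering model with
a recovery-validated fitter.  Everything downstream of geometry is
therefore testable against closed-form or brute-force oracles.

## Idealized geometry

Each residue carries four backbone sites: amide N and H, carbonyl C and O.
Residue *i* of an *n*-residue ring sits at angle 2πi/n on a circle of
radius 4.0 Å in the ring plane; its amide face alternates (+z, −z, ...)
around the ring, the geometric signature of alternating chirality.  N and C
are displaced ±0.6 Å (the *amide offset*) off the plane, H and O a further
bond length (1.0 and 1.23 Å) along the same axes.  All parameters are
overridable.

Stacking places ring *i* at z = i·d with d = 4.85 Å, the measured mean
inter-unimer spacing of assembled nanotubes.  Antiparallel registry mirrors
every odd ring through its own plane and rotates it by 360°/n about the
axis (45° for n = 8).  This choice makes every donor column of one face sit
exactly over an acceptor column of the neighboring face, giving axial,
nearly linear (≈180°) hydrogen bonds as in real beta-sheet stacking, and
realizes exactly n bonds per interface.  A smaller registry angle also
yields n bonds per interface but with bent (≈132°) bonds that sit close to
the angular cutoff, so detection under thermal jitter would be dominated by
criterion noise rather than actual geometry changes; the aligned registry
avoids that artifact.

## Hydrogen-bond detection

A bond is accepted when N···O ≤ 3.5 Å and the N–H···O angle at the
hydrogen is ≥ 120°, the common geometric defaults of MD analysis suites;
both cutoffs are configurable because reported break-rate numbers are
criterion-dependent.  Only adjacent-ring (intermolecular) pairs count as
nanotube backbone bonds; each donor hydrogen bonds at most once, to its
closest passing acceptor, with exact-distance ties resolved by the lower
acceptor residue index so detection is deterministic.  The optimized
detector is tested bond-for-bond against a brute-force all-pairs scan with
no adjacency shortcut.

## Synthetic data

The generators define the study conditions:

- **Thermal jitter** — i.i.d. Gaussian displacement of every site per
  frame, default σ = 0.2 Å, frame interval 0.1 ns.  Frame 0 is
  unperturbed.  This emulates frame-to-frame positional fluctuation of a
  stable stack; it has no correlated motion, no drift, and no actual
  bond-breaking dynamics, so jittered-trajectory tests validate the
  detector and distance metrics, not kinetics.
- **Scripted cap unbinding** — from a chosen frame the terminal ring is
  tilted 15° and lifted 10 Å along the axis, deleting the terminal
  interface's 8 bonds.  In solution the mechanism is a water-attack
  process; only its geometric signature is modelled.
- **Two-state Markov bond kinetics** — each bond independently flips
  formed ↔ broken with per-frame probabilities from exact exponential
  discretization, p = 1 − exp(−k·Δt), at distinct cap vs core break rates
  (defaults 0.05 and 0.005 ns⁻¹ against a 5 ns⁻¹ reform rate, a
  stable-tube regime with caps an order of magnitude more dynamic than the
  core).  Bond populations default to the octamer's 16 cap + 40 core.
  Real bond dynamics are correlated (one broken bond destabilizes its
  neighbors — this is what makes caps cooperative); independence is a
  deliberate simplification that makes the estimator exactly checkable.

All randomness flows through per-call `numpy.random.Generator(PCG64)`
instances with explicit integer seeds; outputs are bit-reproducible.

## Break-rate statistic

BHB ns⁻¹ counts present→absent transitions of the per-bond presence
matrix divided by covered time (n_frames − 1)·Δt, reported total, per
class, and per bond within class (the cap and core populations differ,
16 vs 40, so raw and per-bond rates order differently in general).  An
optional *flicker window* requires an absence to persist ≥ w frames before
it counts as a break; the default w = 0 counts raw transitions, and the
estimate is non-increasing in w.  Absence runs truncated by the end of the
series shorter than w are not counted, since their persistence cannot be
confirmed.

For the Markov generator the expected raw rate is n·k_break·π_formed with
π_formed = k_reform/(k_break + k_reform).  Recovery tests run at
Δt = 0.01 ns: the raw transition-count estimator targets
π_disc·(1 − e^(−kΔt))/Δt, which differs from the continuous closed form by
O(kΔt); at the default 0.1 ns interval and k = 0.5 ns⁻¹ that bias (~2.5%)
would exceed the statistical resolution of a 10⁴-frame run, while at
0.01 ns it is negligible against 3 standard errors.  Standard errors are
binomial in the transition counts.

## Dissociation events and distances

The total-count series is median-filtered (11 frames) to suppress
single-frame flicker; an event fires when the filtered count sits at least
6 bonds below the running pre-event median and stays there ≥ 50 frames.
The thresholds are set so a full cap loss (8 bonds) triggers while Markov
flicker at default rates does not.  Event magnitude is the baseline minus
the post-event median — exactly 8 for a clean cap unbinding.

Inter-unimer distance is the centroid–centroid distance of adjacent rings
(centroids over backbone sites), averaged over frames and interfaces.
Averaging over 32 sites suppresses atomic jitter; the residual inflation
is O(σ²/d), well under 0.02 Å at σ = 0.2 Å.

TEM-style length lists are summarized by mean/sd/histogram, and converted
to unimer counts by rounding length/0.485 nm (minimum 1 unimer).

## Scattering model

The core–shell cylinder intensity is the standard orientation-averaged
form factor (core radius R_c, shell thickness t, length L, three SLDs,
scale, flat background), with I in cm⁻¹ for SLDs in 10⁻⁶ Å⁻² and lengths
in Å.  Defaults describe a polymer-coated peptide nanotube in D₂O:
R_c = 10 Å, t = 40 Å (total diameter 100 Å, consistent with sub-20 nm
tube widths), L = 1000 Å (a ~100 nm tube), SLDs 2.0 / 0.8 / 6.36.

The orientation integral uses fixed 256-point Gauss–Legendre quadrature,
which resolves the axial Bessel oscillations of cylinders up to
~1500 Å over q ≤ 0.5 Å⁻¹ (doubling the order changes I by < 10⁻⁴
relative); the order is configurable.  Instrument resolution smearing and
size polydispersity are not modelled.

Fitting is bounded weighted least squares on (I_model − I_obs)/dI, falling
back to relative weighting |I_obs| when no uncertainties are given.  The
χ² landscape of cylinder models is rugged (Bessel minima), so the
optimizer restarts from a small deterministic grid — factors
{0.5, 1, 2} on each free geometry parameter — and keeps the lowest-cost
solution.  SLDs are typically known from chemistry and held fixed; the
default frees R_c, t, scale and background.  Validation is by parameter
recovery: exact to < 1% on noiseless synthetic curves, < 10% median error
over seeds at 5% multiplicative noise.  L is only identifiable when
q_min·L ≲ π; at the default grid (q_min = 3×10⁻³ Å⁻¹, L = 1000 Å,
q_min·L = 3) it sits at the edge of identifiability and is fixed by
default.

## Problem sizes

Default analyses run on an 8-unimer, 8-residue system: 1000-frame
trajectories for event detection, 10⁴–2×10⁴-frame Markov simulations for
rate recovery, 100-point scattering curves.  These sizes give the
statistical resolution quoted above while keeping a full pipeline run in
seconds.

## Known limitations

- The geometry is a construction, not a reproduction of any published
  octamer coordinates; registry angle and ring radius are package choices.
- Bond kinetics are independent two-state chains; cooperative unbinding
  enters only as the scripted event.
- Absolute break-rate values depend on the detection criteria; comparisons
  across systems at fixed criteria are the meaningful use.
- No polymer-chain coordinates: polymer effects enter only through the
  kinetic rate parameters and the scattering shell.
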