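# Methods

This note documents the models implemented in `phosphobind`, the synthetic
data used to exercise them, the numerical choices, and the limits of what
the tests demonstrate.

## Conventions and units

All concentrations are molar inside the library; conversions happen only
at I/O. Protein concentrations follow the 14-3-3 *monomer* convention:
each protomer of the dimer carries one amphipathic binding groove, so for
a fully dimeric protein the monomer concentration equals the binding-site
concentration. Temperature defaults to 298.15 K (assays at 25 °C) and the
gas constant is 8.314 J/(mol·K); free energies are reported in kJ/mol.

## Fluorescence anisotropy

### Signal model

Each well provides parallel (S) and perpendicular (P) intensities. Total
intensity and anisotropy are

    I = 2·P·G + S,        r = (S − P·G) / I,

with G the instrument grating factor. Replicates are aggregated to
mean ± SD per concentration. The measured anisotropy of a free/bound
tracer mixture is the intensity-weighted average

    r = (r_min·(1−fb) + λ·fb·r_max) / ((1−fb) + λ·fb),

where λ = I_bound/I_unbound is the intensity-change ratio (default 1, in
which case r is linear in fraction bound and the conversion

    Lb = (r − r_min) / (λ·(r_max − r) + r − r_min)

reduces to linear rescaling). The published logistic window form is
garbled in print; it is implemented as an increasing sigmoid in
x = log10(concentration), r(x) = r_min + (r_max − r_min)/(1 + 10^(logx0 − x)),
because a titration of protein into a fixed tracer must increase r.

### Tight-binding fit

Because the tracer (50 nM) is comparable to the tightest Kd values,
binding depletes the free species and the bound-tracer concentration is
the exact smaller root of the 1:1 quadratic,

    y = ((K + X + FL) − sqrt((K + X + FL)² − 4·X·FL)) / 2,

evaluated in the cancellation-free form 2·X·FL/(b + sqrt(b² − 4·X·FL)).
The fit chain is: logistic window → fraction bound → quadratic fit of
bound tracer vs total protein with log10(Kd) free. A sigmoid is not the
exact tight-binding shape, so the logistic plateaus only seed a refinement
in which r_min, r_max and Kd are fitted jointly against the anisotropy;
on noiseless synthetic data this recovers the generating parameters to
machine precision. One design consequence worth knowing: at X_total = K
with a 50 nM tracer the exact occupancy is 0.438, *below* the dilute-limit
0.5, because the titrated partner is itself depleted — a naive hyperbola
fit in this regime is biased high (demonstrated in the test suite).

Titrations that never approach the upper plateau (span below 3× the median
replicate SD, or fitted midpoint at/beyond the top concentration) raise a
saturation error carrying a Kd lower bound — mirroring affinities
reportable only as "> limiting value".

### Biphasic decomposition

Doubly phosphorylated tracers give two-transition curves. Detection
compares a single sigmoid against a sum of two sigmoids on the log axis;
two events are accepted when both amplitudes clear the noise floor (3× the
median replicate SD and ≥3% of the total span) with midpoints ≥1 decade
apart. The split is placed at the flattest point of the two-sigmoid model
between the midpoints (a manual `split_conc` overrides detection). Each
event is then fitted separately to its own 1:1 model with event-local
plateaus — event 1 on concentrations ≤ split, event 2 on ≥ split — with
the overlap handled by alternately correcting each segment for the other
event's modelled contribution. Finally the additive two-event model
(five parameters: three plateaus, Kd1, Kd2) is refitted on the whole curve
from the stepwise starting point. The polish exists because the stepwise
stage alone carries a few-percent boundary bias from event overlap even at
zero noise; with it the zero-noise round trip is exact while the stepwise
structure (and its per-event diagnostics) is retained. If only one
transition is detected the routine falls back to a single-site fit with a
warning.

## ITC

The one-set-of-sites forward model titrates peptide into protein. Each
injection of volume dV into working volume V0 dilutes cell contents by
(1 − dV/V0) and adds syringe material; bound complex then follows the
tight-binding quadratic with site concentration n·[protein]. The measured
heat uses the standard displaced-volume correction

    q_i = Q_i − Q_{i−1} + (dV_i/V0)·(Q_i + Q_{i−1})/2,   Q_i = ΔH·V0·[bound]_i,

assigning expelled material the mean of the pre- and post-injection
composition. Note that "cumulative heat = n·ΔH·V0·[protein]₀" holds only
when saturation precedes significant displacement; protein expelled
unbound never releases heat, so slowly saturating schedules fall a few
percent short of that identity.

Fitted parameters are {Kd, ΔH, n} (Kd log-parameterized); ΔG = RT·ln Kd
and −TΔS = ΔG − ΔH follow by construction. A c-value (n·[cell]/Kd) outside
[1, 1000] triggers a reliability warning — at c ≈ 1400 (the tandem-peptide
conditions) Kd recovery under 2% heat noise scatters by ~25%, consistent
with the large uncertainty reported for that measurement. Heats are
accepted in µJ, µcal, J or cal with an explicit unit tag (joules
internally). An optional `discard_first` drops the customary first-
injection anomaly.

The bivalent generator variant models one peptide occupying both protomers
of a dimer by halving the binding-site concentration; fitting such an
isotherm with the monovalent model returns apparent n = 0.5, the classic
stoichiometry signature distinguishing groove-bridging from one-peptide-
per-protomer binding.

## SPR

Association follows R(t) = Req·(1 − e^{−(kon·C + koff)·t}) with
Req = Rmax·C/(C + koff/kon); dissociation decays as R0·e^{−koff·t}. The
kinetic fit is global across all cycles of the multicycle series (one
immobilized surface → shared kon, koff, Rmax). End-of-injection response
is the mean over the final 5% of the association phase (configurable), and
the steady-state route fits those responses to the binding hyperbola.
When every cycle reaches ~equilibrium within one sample interval the
kinetic fit refuses with a "kinetics too fast" error (only steady-state
affinity is then determinable). A steady-state series whose top
concentration is below the fitted Kd is flagged lower-bound-only.
Complete regeneration between cycles is assumed (no decaying-surface
correction).

## Coupled mass-action solver

The solver treats monomer M (one groove), dimer D (two grooves) and a
peptide of valency 1 or 2 with species M, D, L, ML, DL (one peptide, one
groove), DL2 (one peptide per groove) and — for bivalent peptides — the
bridged complex DLb in which one peptide spans both grooves. Parameters:
dimerization constant Kdim = [M]²/[D] (0 = fully dimeric, ∞ = fully
monomeric), intrinsic per-groove/per-site constant Kd_site, and an
effective molarity α_bridge giving the intramolecular bridging step a
dimensionless equilibrium α_bridge/Kd_site. Statistical factors count the
microstates (e.g. DL carries a factor 2·valency).

Numerically: monomer conservation is closed-form (a quadratic in free M
given free L), so only ligand conservation needs a root find — Brent's
method on free L with near-machine tolerances; conservation residuals are
verified to 1e-10× the totals. In the fully-dimeric, valency-1 limit the
solver reproduces the tight-binding quadratic to better than 1e-9
relative, which is how it serves as the independent oracle in the tests.
The model deliberately exposes only one bridging knob (α_bridge): whether
the second FA binding event reflects dimerization-linked or non-specific
binding is left open, and both can be emulated.

## Synthetic-data designs

The generators emulate the study conditions: FA uses a 50 nM tracer,
half-fold serial dilution (24 points from 500 µM monomer), triplicate
wells and additive Gaussian fractional noise per channel; ITC defaults to
a 200 µL cell at 20 µM protein, 200 µM syringe, 20 × 2 µL injections
(printed concentrations of "0.02/0.1 m" and "0.2–1 m" are read as mM —
molar values are physically implausible for this system); SPR uses an
11-point half-fold dilution from 10× Kd, 1 min association, 4 min
dissociation, 2.5 Hz sampling (unstated by the source; chosen to resolve
the fastest tabulated kinetics comfortably), and absolute Gaussian RU
noise. Noise is independent per channel/injection/timepoint — the simplest
model consistent with replicate-SD error bars. All generators are seeded
and replay byte-identically.

The FA anisotropy plateaus default to r_free = 0.06, first-event plateau
0.24, second-event plateau 0.34 — a typical FAM-phosphopeptide/14-3-3
window. This choice matters more than it looks: the attainable relative
precision of Kd recovery scales inversely with the plateau span (the
Cramér–Rao bound for the two-event design is ~6%/12% for Kd1/Kd2 at 1%
channel noise with these spans), so markedly narrower windows make
few-percent recovery impossible regardless of estimator. Isoform-dependent
maximum anisotropy is emulated by these plateau knobs, not mechanistically.

What the generators do *not* model: instrument drift and baselines,
photobleaching, read-time dependence, mass-transport-limited SPR kinetics,
vendor raw-file formats. Passing recovery tests therefore demonstrate
estimator correctness and precision under idealized instrument noise, not
robustness to systematic artefacts.

## Motif classification

Phosphopeptides are written as uppercase sequences with `pS`/`pT` tokens,
optional `Ac-`/`FAM-Ahx-` prefix and `-NH2`/`-OH` suffix. For each
phosphosite the scanner tests mode II (Arg −5, Tyr/Phe −3, Pro +2), then
mode I (Arg −3, Pro +2), then mode III (phosphosite penultimate *and*
free-acid C-terminus) — II before I because its anchor set is more
specific, and a single deterministic label is reported per site. Amidated
peptides can never be mode III (the definition is anchored on the protein
C-terminus). Individually satisfied anchors are reported even when no full
mode matches, so weak sites (e.g. Arg −3 without Pro +2) can be described
per-anchor. Offsets into full-protein numbering are reporting-only and
never affect classification. The scanner is strict by design: it does not
re-score sites with the ensemble predictors used for candidate selection,
nor soften mode definitions for near-matches.

## Thermodynamic summaries

ΔG tables apply RT·ln(Kd) at one decimal place, propagating lower-bound
flags. Cooperativity classifies ΔΔG = ΔG_tandem − (ΔG_A + ΔG_B) against a
tolerance of 1.0 kJ/mol (about the fit-error scale of the tabulated
energies; configurable): below −tol positively cooperative, above +tol
negatively cooperative (less than additive), else additive. Fold
enhancements are Kd ratios, optionally rounded to significant figures.
Cross-technique concordance rows collect FA/ITC/SPR constants, render
lower bounds as "> value", and report the maximum pairwise fold-difference
without judging it. Known inconsistencies in the source tables — an
FA-derived ΔG column at odds with the FA Kd table by a factor-of-ten in
Kd, one unsigned tandem ΔG, and a kinetic koff/kon ratio (310 nM) that
disagrees with the printed steady-state Kd (189 nM) for the same peptide —
are deliberately not reproduced or reconciled; the package reports each
technique's constants separately.

## Known limitations

* Single- and two-phosphosite peptides only; no heterodimeric 14-3-3
  species, no more-than-two-event decompositions.
* Unweighted least squares on replicate means (replicate SDs are reported,
  not used as weights); whether the source fitted means or pooled wells is
  unknowable.
* No van 't Hoff analysis (ΔH is temperature-independent within a fit).
* ITC inputs are integrated heats; raw power traces and baseline
  integration are out of scope.
* The second FA binding event is fitted phenomenologically; its mechanism
  (dimerization-linked vs non-specific) is not decided by the package.
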