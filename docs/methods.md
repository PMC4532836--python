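# Methods

`cuproforce` models and analyses single-molecule AFM pulling experiments on
cupredoxin polyproteins — blue-copper proteins such as azurin and
plastocyanin flanked by titin I27 fingerprint domains — in which the protein
can unfold through two competing terminal mechanical clamps and become
transiently arrested at its Cu centre. This note documents the models, the
calibrations, the numerical choices, and what the synthetic data do and do
not establish.

## Polymer elasticity

Unfolded polypeptide is modelled as a worm-like chain with the Marko–Siggia
interpolation

F(x) = (kT/p) · [ 1/(4(1 − x/Lc)²) − 1/4 + x/Lc ],

the standard choice for AFM sawtooth fits. Units are fixed package-wide
(nm, pN, s, K); kT = 4.114 pN·nm at 298 K. The persistence length defaults
to p = 0.4 nm and is **held fixed** during fitting: co-fitting p and Lc on
single rising edges is ill-conditioned, and 0.4 nm is the conventional value
for polypeptide. Published contour-length increments may embed a slightly
different p; fitted increments shift by roughly 2–4 % per 0.1 nm of p.
Inversion is by bracketed root finding on x/Lc ∈ [0, 1 − 1e−12] (absolute
tolerance 1e−12 in x/Lc); contour-length fitting minimises squared force
residuals by bounded scalar search on Lc ∈ (max x, 100·max x], xatol 1e−9.

## Unfolding scheme and kinetics

Each protein module is a small state graph. A metal-bearing (holo)
cupredoxin is decomposed into three additive contour segments:

* C segment (C terminus → Cu–S(Cys) bond), ~6.2 nm for azurin;
* N segment (N terminus → Cu–N(His) bond), ~9.4 nm for wild-type azurin
  (19.0 nm without the C3–C26 disulfide shortcut);
* core (everything still anchored to Cu), total − C − N.

From `folded`, the two terminal clamps compete; rupture of one releases its
segment and arrests the chain at the Cu bond; the Cu anchor then ruptures
(releasing the rest) or — rarely — the second clamp breaks first, giving the
four-state cascade in which both segments are released sequentially. Apo
modules unfold in a single all-or-none step of the full length. Total
released contour is path-independent by construction and validated at
scheme construction. Holo fractions default to 0.8 (azurin constructs) and
0.6 (plastocyanin), matching the observed shares of intermediate-bearing
trajectories.

All transitions follow the Bell–Evans law k(F) = k0·exp(F·Δx/kT). The
experiments report forces, not rates, so k0/Δx are calibration constants,
set by simulating the full (protein–I27)₄ construct at 400 nm/s and a
20 pN/nm cantilever until the mean rupture forces approximated the reported
ones (azurin main ~53 pN vs reported 54.1 ± 11.3; Cu ruptures ~42 vs
42.3 ± 12.3; plastocyanin ~76 vs 75.8 ± 12; I27 ~214 vs ~210 pN). Because
the first ruptures in a polyprotein are order statistics over all folded
modules, these k0 are several-fold smaller than a naive single-molecule
Evans–Ritchie inversion would give. Δx = 0.45 nm for the terminal clamps
reproduces the ~12 pN reported spread of unfolding forces and is consistent
with an unzipping geometry; the I27 Δx is the conventional 0.25 nm.

Known limitation: with memoryless Bell kinetics and the reported force
separation (~75 pN clamps vs ~46–52 pN Cu bonds), the plastocyanin
four-state branch is vanishingly rare in simulation (<2 %), whereas ~10 %
has been reported. Reproducing that share would require history-dependent
or heterogeneous kinetics, which are out of scope. For azurin the simulated
four-state share (~3–6 % of modules) brackets the reported 5 %.

## Trace synthesis

Constant velocity: the cantilever base retracts at v; each time step solves
the force balance k_s(z − x) = F_WLC(x; Lc) by safeguarded Newton iteration,
and every active transition fires with probability 1 − exp(−k(F)Δt). The
simulator uses discrete time with a rate-bounded adaptive sub-step
(k_max·Δt ≤ 0.05, at most 400 sub-steps per sample) rather than an
event-driven scheme because the force — and hence every rate — changes
continuously during the ramp. Competing clamps are sampled jointly with
independent Bernoulli draws; double fires are resolved rate-proportionally
and logged as simultaneous. White Gaussian noise (default sd 5 pN) is added
to the recorded force channel only; the event log stores noise-free ground
truth. Instrument defaults sit inside the reported ranges: 400 nm/s,
20 pN/nm, 10 kHz sampling, initial tether contour 20 nm (handles plus
folded-domain spans; this choice reproduces both the reported force
statistics and clearly resolvable sawtooth peaks).

Force clamp: rates are constant at the set force, so dwell times are drawn
exactly (Gillespie); each transition adds ΔLc·(x/Lc at the clamp force) of
extension, producing a staircase.

## Event detection and fitting

Rupture detection scores every sample with a matched step estimator (the
difference between mean force over w = 6 samples before and after; noise
sd·√(2/w) ≈ 2.9 pN at default settings) and extracts events by greedy
matching pursuit: the largest remaining triangular step signature is
recorded and subtracted, which separates ruptures in quick succession whose
signatures overlap. A candidate must drop by ≥ 15 pN (default) and the drop
must persist within 5 nm of extension. The rupture force is reported as the
pre-drop window mean — unlike a raw argmax it is not biased upward by noise
excursions.

Each rising edge is WLC-fitted (p fixed) on lightly smoothed force samples
above max(10 pN, half the rupture force); the upper part of the edge pins
Lc most strongly and is least affected by small undetected releases earlier
in the segment. ΔLc is the difference of consecutive fits; the intermediate
position is by definition this contour-length difference, not a raw
extension difference. Recordings are accepted only when at least two I27
fingerprint events (ΔLc 28 ± 3 nm at 210 ± 60 pN) are present.

Pathway classification groups cupredoxin events: an event whose ΔLc falls
in a construct's intermediate windows continues the preceding main event's
cascade; otherwise it starts a new one. Windows sit at the midpoints
between the reported mode positions (wild-type azurin: C [3.5, 7.8) nm,
N [7.8, 12] nm; C26A: C [3.5, 7.5), N [15, 23]; plastocyanin: C [3.5, 9),
N [11, 18]). No intermediate → two-state; one → C-first or N-first by
window; two → four-state.

Force-clamp staircases are segmented by binary-segmentation changepoints
with a noise-scaled BIC penalty (3·σ²·log n, σ from the median absolute
first difference); plateaus closer than the minimum step are merged.

**Resolution limits.** Under the calibrated kinetics roughly 20 % of
ground-truth transitions are physically unresolvable: cascades in which the
Cu bond ruptures within the detector's resolution window of the main
rupture, or releases whose instantaneous force step is below the detection
threshold (a 6.2 nm release at 45 pN drops the force by only ~12–20 pN
depending on compliance). Such events are indistinguishable from a single
rupture in *any* analysis, which is also why a share of experimentally
two-state-looking trajectories may hide fast intermediates. Detection and
label-recovery benchmarks are therefore evaluated on resolvable events —
steps clearing the threshold by twice the estimator noise and separated by
at least the resolution window (18 samples); on that set the detector
achieves ≥ 0.95 recall/precision and the end-to-end pipeline recovers
≥ 90 % of generating pathway labels. Unconditioned recall is ~0.8, and
detected pathway fractions under-count intermediates accordingly.

## Structure-derived contour predictions

A released stretch of n residues contributes 0.38 nm per residue. The
measurable increment additionally reflects folded geometry:

ΔL = 0.38·n + S_crosslink + d(anchor, far terminus) − d(N, C termini),

where the folded domain initially spans its termini distance and, after
partial unfolding to an anchor, the remainder spans the anchor-to-far-
terminus distance. A disulfide (i, j) wholly inside the released stretch
traps residues i..j inclusive; the bridge is traversed and contributes its
Cα–Cα span (S_crosslink). This sign convention is required by the data:
the 19.0 nm increment reported for the disulfide-free N-terminal pathway
exceeds the bare backbone contour of residues 1–45 (17.1 nm), which a
purely subtractive span could never produce.

Because the real crystal structures cannot be redistributed with the
package, the bundled reference models are **synthetic**: residue counts and
numbering, the C3–C26 crosslink, Cu-ligand identities and the published
Cu–ligand bond lengths are encoded exactly, key Cα positions are pinned at
geometrically plausible β-barrel distances chosen so the ΔL bookkeeping is
consistent with the reported increments, and the remaining residues follow
a deterministic coiled path. Tests against these models validate the
*calculus* (parsing, loop bookkeeping, geometry measurement), not the
crystallography; running `cuproforce predict` on the real PDB entries will
reproduce the same bookkeeping with true native spans.

## Partition statistics

Hartigan's dip statistic is computed exactly via the band formulation: for
each candidate mode position (every gap between data values and every
possible atom), a unimodal CDF within sup-distance t of the empirical CDF
exists iff the greatest convex minorant of the upper CDF limits stays
within 2t of the lower limits on the convex side (symmetrically on the
concave side); the minimum over mode positions is found by binary search
(both side-deviations are monotone in the mode index). The implementation
agrees to 1e−10 with a brute-force linear-programming oracle on all tested
small samples, including ties. P-values are Monte-Carlo against the
Uniform(0,1) null at matching n (Hartigan's choice; conservative for other
unimodal nulls) with the (k+1)/(N+1) estimator, so p is never exactly zero.

Pathway fractions carry Wilson 95 % intervals; intermediate positions are
summarised per fixed mode window ("mean ± sd, n" style). Window binning is
deterministic; a two-component Gaussian mixture (initialised at the window
midpoints, tolerance 1e−8) is available as a cross-check.

A caution established by this package's own simulations: an equal mixture
of Normal(6.2, 1.0²) and Normal(9.4, 1.5²) — the two intermediate modes at
their reported means and spreads — is *not* detectably bimodal at n = 323.
Its population dip is ~0.0019 against a uniform-null median of ~0.018, and
the density valley is only ~8 % below the lower mode, so the dip test's
median certainty over seeds is far below 99.9 %. High dip-test certainty on
real intermediate-position samples therefore implies the underlying modes
are substantially sharper, or less balanced, than those summary parameters
suggest.

## What the synthetic data do not show

The generator emulates kinetic partitioning, WLC elasticity, white force
noise and instrument stiffness. It does not model baseline drift,
hydrodynamic cantilever response, refolding, multiple tethers, surface
adhesion peaks, or heterogeneity in k0/Δx between molecules. Passing
round-trip tests shows the analysis is correct for data generated by this
model family; performance on real recordings with those artefacts may be
lower, particularly for event detection near the drop threshold.
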