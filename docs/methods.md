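# Methods

This note documents the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer should know about.

## Chemical-shift perturbation

For each backbone amide the combined perturbation between two states is

    Δδ_av = sqrt(Δδ_H² + (w_N · Δδ_N)²)

with Δδ_H, Δδ_N the 1H and 15N shift differences (free − bound) and
w_N = 1/5 by default. The 1/5 scaling compensates the larger 15N shift
dispersion and is the most common convention in the CSP literature; 0.14 and
0.10 are also in circulation, so `weight_N` is an argument everywhere it
matters (CSP computation, titration matching, the noise split in the
generator). Δδ_av is nonnegative, symmetric under exchanging which state is
called free, and monotone in |Δδ_H| and |Δδ_N| separately — these are tested
invariants.

Perturbed-residue classification uses a strict inequality (Δδ_av > 0.10 ppm
by default): a residue sitting exactly at the cutoff is not selected.

Titration alignment matches peaks by assignment label only. Residues missing
at a point (exchange-broadened or unassigned) are recorded as gaps and never
interpolated; a weighted shift step > 0.15 ppm between consecutive points
raises a warning (likely mis-assignment) but never triggers automatic
reassignment. How broadened/ambiguous peaks should be interpreted is left to
the user — the pipeline only refuses to guess.

## Fast-exchange 1:1 isotherm

Observed CSPs in fast exchange follow Δδ_obs = Δδ_max · f_b, with f_b the
bound fraction of the labelled protein from exact 1:1 mass balance (the
quadratic root, computed in the cancellation-free form
2PL/(s + √(s² − 4PL)), s = P + L + K_d, which agrees with a brute-force
root-finder to 1e-10 across the tested grid).

The fit is over log10(K_d) — scale-free, bounds 1e-3 to 1e5 μM — with the
per-residue amplitudes Δδ_max profiled out in closed form (they enter the
least-squares problem linearly for fixed K_d, clamped at zero). Global mode
(one shared K_d, the default) treats all perturbed residues as reporting on
a single binding event; per-residue mode exists for diagnostics. Five
log-spaced multi-starts guard against local minima and a final bounded
high-precision polish (xatol 1e-12) makes refits of identical data
bit-reproducible. A fit whose optimum sits on the K_d bounds is reported
with `converged = False`, never silently.

**Uncertainty.** Global-mode uncertainty is a residue-level case bootstrap
(residues resampled with replacement, each draw refitted with warm starts
around the full-data optimum plus dispersed starts ±2 decades); per-residue
mode resamples residuals. The 90% interval is constructed on the log scale
as the 5–95 percentile half-width of the bootstrap distribution centred on
the full-data estimate. Two properties motivated this construction over the
plain percentile interval: (i) the estimator has a small downward bias
(fitting folded magnitudes Δδ_av inflates small shifts more than large ones,
mimicking earlier saturation), and a percentile interval inherits that bias
twice; (ii) rare degenerate resamples that happen to contain few informative
residues produce outlying K_d values that should widen a robust width
estimate only in genuinely unidentifiable fits. A fit is labelled *poorly
determined* when the interval spans more than one order of magnitude or the
optimum is pinned at the bounds.

**Identifiability.** A titration sampled only past one equivalent of ligand
in the tight-binding regime (P ≫ K_d) carries almost no K_d information:
every point is saturated and the isotherm is flat. The pipeline flags such
fits as poorly determined. Note that a single well-measured point *at* the
1:1 corner restores identifiability even at P/K_d ≳ 100, because the bound
fraction there is depressed by ≈ √(K_d/P) — a ~10% effect, large compared
with typical shift precision. Saturation failure is therefore a property of
the sampled ratio grid, not of the concentration ratio alone.

## Heteronuclear NOE

noe = I_sat/I_ref per residue; the ratio is scale-invariant and residues
present in only one table are reported unmatched rather than dropped
silently. Error propagation from spectral noise estimates is performed only
when those estimates are supplied; otherwise `noe_err` is omitted, not
fabricated. Classification: noe < 0 "highly flexible" (sub-nanosecond
motions), 0 ≤ noe < 0.65 "partially ordered", noe ≥ 0.65 "rigid"; the
thresholds are arguments and the classes partition the residue set.

## PRE proximity profiling

Ratios I_para/I_dia per residue, with residues vanished from the
paramagnetic spectrum assigned ratio 0 and flagged proximal (logged).
Negative paramagnetic intensities are clamped to zero with a log entry.
Proximity calling is either an absolute ratio threshold (default 0.7) or a
profile-relative mode (below mean − 1 SD). The structural consistency check
measures the distance from each flagged residue's amide nitrogen to the
label site's representative atom — the side-chain heavy atom farthest from
CA (the nitroxide extends from the mutated side chain), falling back to CB
then CA — and reports the fraction within the interpretation cutoff
(default 20 Å) plus explicit violations.

No quantitative Γ₂ → distance inversion is attempted; the PRE stage reports
ratios and proximity flags only.

## One-site ITC

The forward model is the perfusion-cell convention of titration
microcalorimeters: each injection of volume dv displaces an equal volume,
diluting cell contents by (1 − dv/V₀), and

    q_i = ΔH · ( V₀ (ΔPL_i) + dv (PL_i + PL_{i−1})/2 ) + q_dil

where PL is the bound-complex concentration from 1:1 mass balance between
n·[cell analyte] and the titrant, and the dv term credits complex carried
out with the displaced volume at the mean of pre/post concentrations. Heats
are in μcal, ΔH and ΔG in kcal/mol, ΔS in cal/(mol K), matching instrument
output. The cumulative heat approaches n·ΔH·[P]₀·V₀ at saturation with a
deficit of order V_sat/(2V₀) — the unbound protein displaced before the
titrant reaches it; under the standard protocol (V_sat = 10 μL, V₀ = 200 μL)
this is ≈ 2.5%, and the conservation tests drive the limit with a more
concentrated titrant where the deficit falls below 1%.

Fitting: lmfit least squares over (log10 K_d, ΔH, constant dilution offset)
with n fixed to 1 by default (one-site assumption) or free; multi-start over
log-spaced K_d; the first injection is discarded by default (universal
practice — the first aliquot is corrupted by syringe diffusion). Flat
thermograms and bound-pinned optima return `converged = False` with no
parameter values. The dilution correction is a fitted constant offset;
blank-titration subtraction can be applied upstream instead.

Thermodynamic relations use ΔG = −RT ln K_b and ΔG = ΔH − TΔS with
R = 1.9872e-3 kcal/(mol K) and T = 298 K (not 298.15: consistency with the
stated experimental convention; T is an argument). `derive_thermo` completes
any two of {K_d, ΔH, ΔS} into a fully consistent parameter set whose
internal identities hold to 1e-9 relative and are enforced at construction.

## Solvent accessibility and docking restraints

SASA is Shrake–Rupley with a deterministic Fibonacci-spiral point set
(default 960 points, probe 1.4 Å, Bondi element radii). The point set is
made antipodally symmetric so mirror-image configurations receive exactly
equal areas; accuracy is verified against the closed-form sphere area (an
isolated atom), a Monte-Carlo random-direction oracle, and an independent
open-source implementation. Relative accessibility divides residue SASA by
the theoretical Gly-X-Gly maxima of Tien et al. (2013); values over 100%
(termini) are logged and never clipped. The accessibility variant is
whole-residue, side-chain-inclusive; the reference table is an argument for
users who need a different convention.

Active residues = CSP-perturbed ∩ relative accessibility > 45%; passive =
other accessible residues with any heavy atom within 6.5 Å (the standard
protocol's adjacency radius) of an active residue. Selection is monotone in
both thresholds. Restraints are emitted as CNS `assign` statements — one
ambiguous block per active residue against the partner's active+passive
set, bounds 2.0 Å (−2.0/+0.0) — and the writer round-trips exactly through
the bundled parser. Docking itself (minimization, refinement, clustering)
is out of scope: this package produces the restraint input.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of a seed (byte-identical reruns). The
defaults encode the study conditions:

* **Titrations** — K_d = 3.27 μM, labelled protein 10 μM, twelve ratios
  0–8 (0, 0.2, 0.5, 0.7, 1, 1.5, 2, 3, 4, 5, 6, 8), Gaussian shift noise
  0.004 ppm per axis (1H-equivalent). Only residues 404–407 shift
  (Δδ_max 0.10–0.25 ppm, each along a fixed random direction in the
  (1H, 15N) plane — straight fast-exchange trajectories); residues 382–403
  are negative controls.
* **hetNOE** — a rigid core (NOE ≈ 0.75) with a C-terminal tail whose
  403–407 window averages exactly −0.71 (free) / 0.48 (bound) by
  construction; 2% fractional intensity noise by default.
* **PRE** — a reduced forward model, Γ₂(r) = Γ₂_ref (r_ref/r)⁶ and
  ratio = R₂/(R₂+Γ₂)·exp(−Γ₂ t), with R₂ = 15 s⁻¹, r_ref = 15 Å,
  t = 10 ms, and Γ₂_ref = 30 s⁻¹ — calibrated so the noise-free ratio at
  20 Å equals the 0.7 broadening threshold, keeping the generated data
  internally consistent with the 20 Å proximity interpretation. This is
  deliberately not a full Solomon–Bloembergen treatment: the analysis side
  consumes only ratios and a distance cutoff, so the generator needs only
  the correct monotone r⁻⁶ structure.
* **ITC** — the one-site perfusion model under the standard protocol
  (1 mM titrant, 20 × 2 μL into 50 μM, V₀ = 200 μL, 298 K) plus 0.05 μcal
  Gaussian heat noise.
* **Toy structures** — ideal poly-alanine backbones (N, CA, C, O, CB)
  built from standard internal coordinates by sequential frame placement;
  helix torsions −57/−47 (1.5 Å rise per residue), β-strand torsions for
  the extended form.

The generators do **not** simulate raw spectra, peak overlap, differential
line broadening, exchange-regime crossover, baseline drift in thermograms,
or real side-chain packing. Passing tests therefore demonstrate that the
*analysis* is correct under the stated statistical model, not that every
complication of real data is handled; in particular, real intermediate-
exchange titrations and ITC baselines need upstream care the pipeline
assumes done.

## Problem sizes

The stochastic checks use 100 titration replicates for CSP K_d recovery,
50 simulate-then-fit ITC replicates, 40 bootstrap-coverage trials with 60
resamples each, and 30-residue toy structures for PRE/SASA geometry —
sizes at which the medians and fractions under test are stable across
seeds while the whole suite runs in a few minutes on one core.

## Known limitations

* The CSP amplitude fit uses folded magnitudes Δδ_av, which carries a small
  (≈ 5% at the default noise) downward K_d bias; fitting signed projections
  along per-residue trajectories would remove it but requires trajectory
  directions to be well defined, which broadened sparse data often deny.
* The ITC dilution correction is a constant offset; strongly concentration-
  dependent dilution heats need a blank titration subtracted upstream.
* Relative-accessibility conventions differ between tools by a few percent;
  selections near the 45% cutoff can differ accordingly (the table and
  variant are explicit arguments for this reason).
* PRE proximity is interpreted through a single cutoff; no attempt is made
  to model label-linker flexibility or multiple label rotamers.
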