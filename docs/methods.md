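# Methods

## The model

The electrolyte is a restricted primitive model (RPM): a 1:1 salt of
charged hard spheres with common diameter d = 3 Å in a structureless
solvent, simulated in the canonical ensemble at T = 298 K.  The package's
modification is *local dielectric saturation*: the relative permittivity
entering the Coulomb interaction depends on the ion–ion separation r,

    ε_r(r) = ε_c                                   r ≤ d
    ε_r(r) = ε_c + (ε_b − ε_c)(r − d)/Δ            d < r < d + Δ
    ε_r(r) = ε_b                                   r ≥ d + Δ

so that water in the overlapping hydration shells of two approaching ions
is treated as dielectrically saturated (ε_c = 23 at contact) while beyond
a solvent layer of thickness Δ = 3 Å the bulk response ε_b = 78.3 is
recovered.  The pair energy in units of k_BT is

    βu_ij(r) = z_i z_j l_B(ε_r(r)) / r ,   l_B(ε) = βe₀²/(4πε₀ε),

with a hard-core sentinel for r < d.  Setting ε_c = ε_b gives back the
uniform-permittivity RPM exactly; the uniform ε_r = 23 model used as a
comparison throughout is the same object with both permittivities set to
23.  Physically, the ramp adds a *short-ranged* extra attraction between
unlike ions (and repulsion between like ions) on top of an ordinary
ε_b-RPM; because the enhancement is local, like-charge repulsion inside a
dense cluster is not amplified at long range, which is what allows large
clusters to survive.  All constants are CODATA 2018; lengths are in Å,
energies in k_BT, charges in e₀ (1 M = 6.02214×10⁻⁴ ions/Å³).

Choice of the ramp form: the interpolation runs between (d, ε_c) and
(d + Δ, ε_b) in the centre-to-centre separation; this is the unique
piecewise-linear function consistent with "contact value ε_c" and "slope
set by the solvent-layer thickness Δ".

## Geometries and electrostatics

*Bulk*: a cubic box of side L, periodic in x, y, z.  Pair interactions use
full cubic minimum-image (MI) truncation — each pair interacts once,
through its nearest periodic image, with no spherical cutoff.  The box
tie-break at exactly L/2 chooses the positive image (a probability-zero
event, fixed for determinism).

*Slit*: an L×L×H cell, periodic in x, y, with impenetrable hard walls at
z = ±H/2 carrying uniform surface charge σ.  H is the wall-to-wall
distance; ion centres are confined to |z| ≤ (H − d)/2.  Because the
interior field of two identical charged planes cancels, the
position-dependent wall energy is identically zero inside the slit; the
wall physics enters through the counterion excess that neutralises
2σL².  The surface charge is specified as inverse area per elementary
charge (70 Å²/e ⇒ σ = −1/70 e₀/Å²) and is adjusted minimally so the
integer counterion excess neutralises the walls exactly.

Long-ranged lateral interactions in the slit use the charged-sheet
decomposition: for each pair, the explicit MI point charge (with the
dielectric ramp) plus, at ε_b, the infinite uniform sheet carrying the
partner's charge density q/L² at its height minus the central L×L square
patch of that sheet (the piece the explicit point charge replaces).  The
square-patch potential is evaluated in closed form
(F(u,v) = u ln(v+r) + v ln(u+r) − h·atan(uv/hr), summed over corners).

The sheet continuum misses the discreteness of the actual image lattice.
That residual — the exact lateral image sum minus (sheet − patch) — is a
smooth function of the pair offset on the scale of L, so it is tabulated
once per slit geometry (25×25×49 grid over |Δx|,|Δy| ≤ L/2, |Δz| ≤ H−d;
40 image shells plus an analytic midpoint-curvature tail) and trilinearly
interpolated during sampling.  With this refinement the slit total energy
reproduces explicit lateral image summation to ~10⁻⁴ relative, which the
test suite verifies against a Richardson-extrapolated brute-force sum on
electroneutral 4-ion fixtures (the plain sheet − patch approximation
alone leaves ~10⁻² relative errors on such small systems).  Per-ion
self-image terms (configuration-independent) are included so totals are
comparable to the image sum; the divergent sheet constants cancel for
electroneutral systems.  The dielectric ramp applies only to the direct
MI ion–ion term; all far-field terms use ε_b.

## Monte Carlo

Canonical Metropolis sampling with two move types:

* single-particle displacements, uniform in a cube of half-width
  `max_step`.  During equilibration `max_step` is tuned toward 30–50%
  acceptance and then frozen for production (adapting during production
  would violate detailed balance).
* rigid cluster translations (10% of attempts by default): a seed ion is
  chosen uniformly, its cluster is the connected component under MI
  distance ≤ δ_mv (default d + 0.5 Å, the same criterion used for
  analysis), and the whole cluster is translated.  A move whose translated
  cluster would acquire any new member is rejected outright; with that
  merge guard the reverse move selects the identical member set with
  identical probability and detailed balance holds.  Rotations are not
  implemented (rigid translations suffice for the sampling improvements
  needed here and keep the proof of detailed balance elementary).

Cluster moves matter enormously above ~0.5 M, where single-particle moves
cannot transport bound pairs and clusters; the suite cross-validates the
two samplers against each other on a small system.

Energy bookkeeping is incremental (ΔU per accepted move) with periodic
reconciliation against a full O(N²) recomputation; drift beyond
10⁻⁶ k_BT·N aborts the run.  All randomness flows from one master
numpy Generator; the compiled sweep kernel is re-seeded from it at each
sampling-block boundary, making runs reproducible from a single seed and
checkpoint/resume bitwise identical.

Initial configurations come from seeded random insertion with rejection;
an attempt budget converts pathological packings into a clear error.

## Observables

* Species-resolved RDFs with bin width 0.1–0.25 Å up to L/2, pooled over
  the symmetry-equivalent channels: g_pp = (g₊₊ + g₋₋)/2,
  g_pm = (g₊₋ + g₋₊)/2.  The density–density and charge–charge
  combinations are g_nn = (g_pp + g_pm)/2 and g_cc = (g_pm − g_pp)/2,
  algebraically identical to the four-channel definitions.
* Cluster decomposition: connected components under MI distance ≤ δ
  (δ = d + 0.5 Å, inclusive), via a periodic KD-tree neighbour search and
  a sparse-graph connected-components pass; clusters may wrap the box and
  are counted by total membership.  P_ion(N_c) is the probability that an
  ion sits in a cluster of size N_c, normalised per frame.
* Yukawa tail fits: weighted least squares of ln(r|h|) vs r, slope
  −1/λ.  Sign changes inside the window raise a fit-not-applicable error
  (the oscillatory regime has no single decay length).
* Phase-separation diagnostic: linear regression of g₊₊ over a tail
  window (default [r_max/2, r_max]); "separated" when
  |slope|·window > 0.05 **and** the tail mean deviates from 1 by more
  than 0.02.  Both numbers are package conventions standing in for the
  by-eye classification of correlation tails.  The 3.45 M ε_c scan uses
  the [L/3, L/2] window (beyond the cluster-correlation range at ~100
  ion pairs) and classifies on slope excess alone at 0.1, a decision
  boundary placed in the gap between the slope populations of
  equilibrated homogeneous states (≤ 0.05) and phase-separated states
  (≥ 0.16) at this system size; the tail-mean guard, useful against
  flat noise, misfires on separated profiles whose tail crosses 1
  inside the window.
* Local electroneutrality: the zeroth charge moment 8πn ∫r²g_cc dr → 1.
  In a canonical fixed-N run g_cc carries an O(1/N) large-r offset that
  the r² weight amplifies, so the observable subtracts the tail-mean
  baseline (outer 30% of the r range) before integrating.
* Slit profiles: z-histograms normalised by L²Δz, reported in mol/L;
  Δn(z) = n₊(z) − n₋(z).  Slit molarities use the accessible volume
  L²(H − d).  The midplane concentration (mean of (n₊+n₋)/2 over a
  central window) is how a slit run's "bulk" concentration is quoted.

## Screening-length estimation (Widom route)

A +q/−q ghost pair at separation r is inserted at random positions and
orientations into stored frames; w(r) = −ln⟨exp(−βΔU)⟩ (ghost–medium plus
the constant ghost–ghost term) is the potential of mean force between the
test charges, referenced to the largest sampled separation to remove the
r-independent solvation part.  If charge correlations decay as a Yukawa,
w(r) ≃ −A e^{−r/λ}/r with A > 0, and λ is the effective screening
length; the fit uses the reference-subtracted two-term form with
bootstrap-over-frames uncertainties.  Ghosts interact through the same
ramp potential and hard core as real ions and never perturb the stored
configurations.

Three estimator details matter at strong coupling.  (i) *Common random
numbers*: each insertion draws one +q position and one orientation shared
across all separations, so the r-independent solvation part of dU —
including rare near-contact Boltzmann spikes — cancels in the referenced
differences.  (ii) *Probe charge*: the default test charge is 1 e0, but
the screening-length measurements use a reduced linear-response probe
(0.3 e0): the decay length is probe-charge independent while the contact
Boltzmann factor drops from e^8.1 to e^0.7, which converts a hopelessly
heavy-tailed average into a well-behaved one.  (iii) *Weighted, bounded
fitting*: per-separation bootstrap uncertainties weight the nonlinear
fit (otherwise the near-zero far points dominate the residuals), with
lambda confined to (0.1 A, 10 r_ref).

Fit windows are per-concentration analysis choices: (1.2-3.5) lambda_D at
0.05 M (the whole range is asymptotic in the Debye-Hueckel regime), and
(1.5-5) lambda_D at 0.25 M / (2-6) lambda_D at 0.5 M, because w(r) there
develops a steep contact-structure-driven initial decay over the first
~2 lambda_D followed by the slower asymptotic tail that carries the
screening length.  At these scaled-down sizes the protocol yields
lambda/lambda_D ~ 1.0-1.2 at 0.05 M, ~1.2-1.7 at 0.25 M and ~1.3-2.7 at
0.5 M (seed-dependent within the quoted bootstrap errors) — Debye-scale
screening when dilute and mild underscreening when concentrated, with no
significant increase of lambda itself with concentration.  In the dilute limit the estimator reproduces λ_D
(verified against the 0.05 M uniform-ε control); an exactly Coulombic
(zero-ion) w is flagged "no screening" with λ = ∞, and a non-monotone |w|
is flagged "oscillatory" but still fitted — an *effective* length, which
is precisely how the method remains usable above 1 M where the strict
Yukawa form breaks down.  This ghost-pair route is adopted as the
operational estimator because it is fully specified and testable against
the Debye–Hückel limit; outputs are tagged `widom-pair`.

## Problem sizes and what the tests show

All simulation-based checks run at deliberately small scale so the whole
suite completes on a single CPU: 80–128 ion pairs for bulk trajectories
(10⁴–10⁵ sweeps), ~130 ions in the slit, 100 pairs for the 3.45 M
phase-boundary scan.  At these sizes the qualitative physics —
Debye-scale screening at 0.05 M, mild underscreening at 0.25–0.5 M,
strong cluster growth of the ramp model at 1 M, the persistent Δn(z)
tail in the slit, and the ε_c phase boundary between 21 and 23 — is
reproducible and statistically resolvable, and that is what the
acceptance suite asserts.  Quantities that require the publication-scale
systems (5000 ion pairs, box sides >130 Å) — sharp tail classification at
large r, screening lengths above 1 M where g_cc is oscillatory, smooth
P_ion(N_c) spectra out to N_c ~ 10² — are out of reach at this scale and
are not asserted numerically.  The synthetic-data generators (fixtures)
emulate hand-checkable micro-configurations and ideal Yukawa curves; they
contain no model noise beyond what is explicitly injected, so fit-recovery
tests bound estimator bias, not real-data variance.

## Numerical conventions

* Hard-core/wall overlaps are sentinel energies (rejection handles them);
  the kernels short-circuit so ∞ never enters arithmetic.
* The MI tie-break at exactly L/2 takes the positive image.
* RDF normalisation uses exact shell volumes 4π/3 (r₂³ − r₁³).
* The Widom fit seeds, bin widths, fit windows and all run schedules are
  recorded in output metadata; any table can be regenerated from its
  manifest.
* Checkpoints store positions and energies as hex floats (bit-exact round
  trip through JSON).

## Known limitations

* The dielectric ramp is pairwise; genuine dielectric saturation is a
  many-body effect, so cluster interiors are over-strengthened — the
  choice ε_c = 23 partially compensates, and the condensed phase that
  forms below ε_c ≈ 22 is amorphous rather than crystalline.
* MI truncation is structurally accurate for bulk correlations at these
  couplings but is not an Ewald sum; energies carry O(1/L) truncation
  character that cancels in the structural observables compared here.
* Screening lengths above ~1 M are "effective" values extracted from an
  oscillatory w(r); they carry the quality flag and should not be read as
  strict Yukawa decay constants.
* Cluster moves implement translations only; extension to rotations would
  accelerate decorrelation of large clusters further.
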