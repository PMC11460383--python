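# Methods

This note documents the models, numerical conventions and design choices
behind solscat, and what its synthetic test systems do and do not establish
about real data.

## Scattering model

The solute is a set of N scattering sites in implicit solvent.  A site is a
non-hydrogen atom together with its implicit hydrogens (CH, CH₂, NH₃, …);
hydrogens present in an input file are merged into their parent heavy atom
and never scatter on their own.  Each site type carries

* a vacuum form factor f(q) = Σ₅ aᵢ·exp(−bᵢq²) (five Gaussians, electrons;
  b in Å² multiplying q²),
* a displaced solvent volume V (Å³) whose dummy-atom factor is the Gaussian
  g(q) = ρ_s·V·exp(−q²·V^(2/3)/4π),

giving the contrast factor A(q) = f(q) − g(q) with A(0) = ΔZ = Z − ρ_s·V.
The solvent electron density ρ_s defaults to 0.334 e/Å³ (pure water) and is
user-settable; hydration layers are supported only through user-supplied
explicit water coordinates (type `H2O`), not constructed automatically.

Momentum transfer is q = 4π·sinθ/λ in Å⁻¹, distances in Å.  Default output
grids: 300 q points on [0, 3] Å⁻¹; PDDF output spacing 0.5 Å; histogram bin
width 0.2 Å.

### Form-factor table

`src/solscat/data/atom_groups.json` is generated by
`scripts/make_formfactor_table.py`.  Targets are the International Tables
(1992) four-Gaussian-plus-constant atomic form factors as evaluated by
gemmi, with group targets f_heavy + n_H·f_H; each is refit to five *pure*
Gaussians on q ∈ [0, 25] Å⁻¹ (the tabulation's validity range) so that
every term of a form-factor product is itself a Gaussian and the analytic
PDDF needs no delta-function bookkeeping.  Two deliberate constraints:

* **Positive amplitudes, exact f(0).**  Amplitudes are parameterized by a
  softmax scaled to the integer electron count, so f(0) = Z exactly and all
  aᵢ > 0.  Free-sign fits achieve marginally lower residuals but are badly
  conditioned (cancelling ±hundreds-of-electrons amplitude pairs), and that
  conditioning directly amplifies histogram-aliasing noise in the analytic
  PDDF; positive Z-bounded amplitudes keep it at the sub-percent level.
* **Exponent floor b ≥ 0.0025 Å²** (real-space σ ≥ 0.07 Å), so every PDDF
  kernel is resolvable on a 0.1 Å grid and the trapezoid/rectangle area
  identity holds to better than 0.5%.  The constant term of the source
  parameterization (a few percent of Z) is absorbed by a floor-width
  Gaussian.  Cost: deviations up to ~1 e from the tabulation at
  q ≳ 15 Å⁻¹, far beyond the solution-scattering range; fits agree with the
  tabulation to <0.1% for q ≤ 3 Å⁻¹.

Displaced volumes follow the published dummy-atom convention (H 5.15,
C 16.44, N 2.49, O 9.13, S 19.86, P 5.73 Å³, groups additive in hydrogens).
An explicit water site uses the bulk volume per water molecule (29.9 Å³), so
user-added water shells are near contrast-neutral at ρ_s = 0.334 unless a
different solvent density is chosen.  Ion entries use neutral-atom form
factors and Shannon ionic-radius volumes; they matter only for ΔZ of rare
sites.

## Engines

**Point charge.**  P(r) accumulates ΔZ_j·ΔZ_k into bins of width Δr with
the rule bin = round(r/Δr) (bins centred on m·Δr); self pairs (j = k) are a
separate mass at r = 0, never divided by a bin width, so the identity
total weight = (ΣΔZ)² is exact in floating point.  The transform
I(q) = Σ p(r_m)·sinc(q·r_m)·Δr + self_mass converges for Δr ≲ 0.1 Å;
coarser curves are internally rebinned mass-conservingly (bin 0's mass is
spread over [0, Δr/2] at doubled density).

**Direct Debye.**  I(q) is the exact double sum with sinc kernels, grouped
by type pair so Gaussian products are formed N_T² times, never per atom
pair.  The analytic PDDF uses, per product term c·e^(−dq²) of a pair at
distance a, the closed-form inverse sine transform

K(r; a, d) = c·r/(2a√(πd))·[e^(−(r−a)²/4d) − e^(−(r+a)²/4d)],

whose a→0 limit c·r²/(2d√(πd))·e^(−r²/4d) handles self pairs analytically;
both integrate to c, pinning the normalization to the forward-scattering
identity.  Inner loops generate consecutive Gaussian/sine values by
two-multiply recurrences (numba-compiled), with terms truncated where the
relative tail is below e⁻⁴⁰.  The independent quadrature route
(`xs_to_pddf_numeric`, P(r) = (2r/π)∫ q·I(q)·sin(qr) dq) is kept as a
validation oracle only.

**Distance histogram.**  Typed ordered-pair counts H[t,u,m] (symmetric;
per-type self counts stored separately so the Debye diagonal stays exact),
then the same sinc/Gaussian kernels weighted by counts at the bin-centre
abscissae m·Δr.  Binning error in I(q) is O(Δr²) at fixed q on average; the
narrowest kernel components additionally alias the Δr comb, which is why
fit conditioning (above) matters.  At the production width Δr = 0.2 Å the
engine tracks the direct sum to <0.3% for q ≤ 0.3 Å⁻¹ and ~1% out to
3 Å⁻¹ on a 4000-site protein-like globule, and the PDDFs agree to <1% of
the peak over the central distance range — consistent with the behaviour
the method is known for on real proteins.  Histograms are cacheable as
versioned TSV.

**Partials.**  All three engines are linear in the set of atom pairs, so
the subunit decomposition (per-subunit curves plus ordered cross-pair
correlation terms, a factor 2 relative to unordered pairs) is exact by
construction; the implementation validates that subunit selections are
disjoint and exhaustive and reports the additivity residual
(≲1e−12 relative for PC/DH, ≲1e−9 for DD).

**Dmax analysis.**  The true Dmax is the exact maximum pair distance
(convex-hull reduction for large sets, blocked O(N²) otherwise — both
exact).  The apparent Dmax is the largest grid point with
P(r) ≥ threshold·max P (default 0.1%), located on the stored grid without
interpolation — the result carries the grid's Δr precision, matching how
such markers are read off plotted curves at 0.5 Å resolution.  The analytic
PDDF's Gaussian tails extend a kernel width beyond the true Dmax, so the
apparent value is clamped to the true one.  Normalization: per-particle is
the native scaling of coordinate-based PDDFs (molar-concentration scaling
experimentally); per-mass (division by MW, computed from the atomic
composition with implicit hydrogens) reproduces the mass-concentration
scaling whose misuse the analysis utilities are designed to demonstrate.

## Synthetic study systems

The fixture generator produces geometries with ground truth known by
construction (exact distances, Dmax bounds, subunit partitions), each
emulating a class of real systems: a two-site pair (closed forms), a
layered ladder/chain (nucleic-acid-like PDDF oscillation at the rise), a
double helix, a uniform ball (compact globule), a hollow shell (capsid-like
PDDF), and a ring of rigid subunit clusters (cyclodextrin-like, for
decomposition).  Coordinates are rounded to 0.001 Å so fixtures round-trip
exactly through PDB files (the group label is carried in the atom-name
field); one seeded generator per call makes every fixture bit-reproducible.

The "protein-like globule" used for accuracy measurements is 4000 sites in
a prolate ellipsoid (a = 23 Å, c/a = 1.5) cycling the 12 biomolecular group
types — BSA-sized at protein atom density.  The ellipsoidal envelope is
deliberate: a perfect uniform sphere has interference minima far deeper
than any real protein, and relative engine-difference measures blow up in
those minima.  What these fixtures do **not** emulate: bonded local
structure (the sharp 1.5 Å bond peaks of real PDDFs), sequence-correlated
type placement, hydration shells, and conformational ensembles.  Passing
tests therefore establish the engines' mutual consistency, conservation
laws and limit behaviour — not agreement with experimental scattering of
any particular protein.  The checks against the published structural
constants of deposited PDB entries live in the test suite but require the
user to download those entries (`data/reference_structures/`).

## Numerical choices and limitations

* Bin rule round(r/Δr) everywhere; bin-centre abscissae in all kernels; one
  convention shared by PC and DH so decompositions are bin-compatible.
* Kernel windows cut at |r−a| = √(160·d) (tail < e⁻⁴⁰); recurrence drift
  over a window is ≲1e−13 relative.
* Areas use the rectangle rule with the separate self mass added; for
  smooth analytic curves on Δr ≤ 0.1 Å grids this is spectrally accurate
  (the integrand is a sum of Gaussians vanishing at both ends).
* Alternate locations resolve to the highest occupancy (ties: first in
  file); blank-altloc duplicate names are kept as distinct sites.
* Unknown residues fall back to bare-element typing (zero implicit H) with
  a logged warning, after attempting distance-based merging of any explicit
  hydrogens present and, for generated site lists, interpreting the atom
  name as a group label when the element matches.
* NMR ensembles default to model 1; biological assemblies are expanded only
  on request from the deposited transforms.
* Wall-clock scaling: histogram build and point-charge accumulation are
  O(N²) with small constants (~10⁸ pairs/s); the direct Debye engines are
  O(N²·N_Q) and O(N²·N_R·N_G²) and become impractical beyond ~10⁴ atoms,
  which is exactly the regime the histogram engine exists for.
* No instrument smearing, no fitting to experimental data, no automatic
  hydration layer, no anomalous corrections, no high-angle empirical
  intensity adjustment for the point-charge profile.
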