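# solscat

Coordinate-based simulation of solution X-ray scattering (SAXS/WAXS)
profiles **I(q)** and pair distance distribution functions **P(r)** for
atomic models in implicit solvent — from single ligands to megadalton
assemblies.

Solution scattering is routinely interpreted by comparing experimental
curves against profiles computed from structural models, but the
corresponding *real-space* function, the PDDF, is usually only obtained from
experiment by regularized indirect Fourier inversion, which can introduce
artefacts (false oscillations, over-smoothed peaks, ambiguous maximum
dimension D<sub>max</sub>). Computing the PDDF *directly from coordinates*
gives an artefact-free reference: it lets you tell structural features from
inversion artefacts, dissect which subunits or subunit–subunit correlations
produce each PDDF peak, and study how the apparent D<sub>max</sub> read off
a PDDF relates to the true largest dimension of the model.  solscat is for
structural biologists and scattering beamline users who want that
real-space companion view alongside the usual reciprocal-space simulation.

## Methods

Every non-hydrogen atom (with its implicit hydrogens merged in, e.g. CH₂) is
a scattering site with a contrast form factor

> A_j(q) = f_j(q) − g_j(q),  A_j(0) = ΔZ_j = Z_j − ρ_s·V_j,

where f_j is the atomic/group form factor (five-Gaussian fit), g_j the
Gaussian dummy-atom factor of the displaced solvent volume V_j in solvent of
electron density ρ_s (default 0.334 e/Å³), and ΔZ_j the effective (contrast)
electron number.  Three engines produce matched I(q)/P(r) pairs:

* **Point charge (PC)** — all contrast electrons at the atom centre:
  P(r) = Σ_j Σ_k ΔZ_j ΔZ_k δ(r − r_jk), a weighted distance histogram;
  I(q) follows by the sine transform I(q) = ∫ P(r)·sin(qr)/(qr) dr.
  Fast and accurate at small angles.
* **Direct Debye (DD)** — the exact orientational average
  I(q) = Σ_j Σ_k A_j(q) A_k(q)·sin(q r_jk)/(q r_jk).  Because every product
  A_j·A_k is again a short Gaussian sum, the inverse transform has a closed
  form and P(r) becomes a sum of distance-weighted Gaussians — the
  high-fidelity analytic reference, at O(N²) cost per output point.
* **Distance histogram (DH)** — the Debye sums rewritten over typed
  pair-distance histograms H_jk(r_m) for the 10–15 atom-group types of a
  biomolecule: one O(N²) histogram build, then I(q) and P(r) cost
  O(N_T²·N_R) per point, independent of atom count.  This is the production
  path for large assemblies.

Invariants maintained throughout: the PDDF area equals the forward
scattering, ∫P(r)dr = I(0) = (Σ_j ΔZ_j)²; DH converges to DD as the bin
width shrinks; and a PDDF decomposes exactly into per-subunit curves plus
inter-subunit correlation terms,
P(r) = Σ_j P_j(r) + Σ_{j<k} P^corr_jk(r).

## Worked example

Simulate a BSA-sized protein-like globule (4000 sites, 12 group types) and
compare the production histogram engine against the direct Debye reference:

```python
import numpy as np
import solscat as ss

protein_like = ["C","CH","CH2","CH3","N","NH","NH2","NH3","O","OH","S","SH"]
model, _ = ss.make_fixture("sphere", n=4000, radius=23, aspect=1.5,
                           seed=7, labels=protein_like)
q = np.linspace(0.0, 3.0, 300)

hist = ss.build_histograms(model, dr=0.2)      # the one O(N²) step
xs = ss.dh_xs(hist, q)
pddf = ss.dh_pddf(hist, dr_out=0.5)

sum_dz = model.delta_z.sum()
print(f"I(0) = {xs.i[0]:.4e}  (sum dZ)^2 = {sum_dz**2:.4e}")
rep = ss.apparent_dmax(pddf, ss.max_pair_distance(model), threshold=0.001)
print(f"true Dmax = {rep.true_dmax:.1f} A, apparent (0.1%) = "
      f"{rep.apparent_dmax:.1f} A, gap = {rep.gap:.1f} A")
rel = np.abs(xs.i / ss.dd_xs(model, q).i - 1) * 100
print(f"DH vs direct-Debye intensity: {rel[q<=0.3].max():.3f}% (q<=0.3), "
      f"{rel.max():.2f}% (q<=3.0)")
```

prints

```
I(0) = 2.3261e+08  (sum dZ)^2 = 2.3261e+08
true Dmax = 68.2 A, apparent (0.1%) = 64.0 A, gap = 4.2 A
DH vs direct-Debye intensity: 0.155% (q<=0.3), 1.11% (q<=3.0)
```

The forward scattering reproduces the squared contrast electron count
exactly; the 0.1%-threshold apparent D<sub>max</sub> sits ~4 Å below the
true largest dimension (the long shallow PDDF tail carried by a few surface
atom pairs); and the accelerated engine tracks the exact Debye sum to a
fraction of a percent in the small-angle range.

The same workflows are available from the shell for PDB/mmCIF inputs:

```
solscat compute model.pdb --method dh -o run          # run.xs.dat, run.pddf.dat, manifest
solscat dmax model.pdb --method dh                    # true/apparent Dmax JSON
solscat decompose model.pdb --subunit "A=chain A" --subunit "B=chain B" -o parts
solscat fixture shell --param radius=80 --param n=5000 -o capsid.pdb
solscat histogram big_assembly.cif --assembly 1 -o cache.tsv
```

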