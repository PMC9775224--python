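# phlink

**pH-linkage analysis of constant-pH molecular dynamics output.**

Constant-pH MD (CpHMD) simulations of a protein in its monomeric and
dimeric forms yield, frame by frame, the binary protonation state of every
titratable site (Asp, Glu, His, termini, …) at a handful of pH values.
`phlink` turns those occupancy series into the thermodynamics and kinetics
of pH-dependent association:

* **Titration statistics** — per-pH mean protonations n̄ and n̄_i, Hill
  fits (pKa, h), the mean-charge curve and isoionic point, with two-level
  (replicate + block) bootstrap errors.
* **Wyman–Tanford linkage free energies** — the relative dimerization free
  energy

  ```
  ΔΔG°(pH) = RT ln10 ∫_{pH_ref}^{pH} ( n̄^D − 2 n̄^M ) dpH′
  ```

  integrated in closed form from cubic Hermite splines whose slopes are
  not fitted but *thermodynamic*, supplied by the fluctuation relations

  ```
  dn̄/dpH = −ln10 · var(n),     dn̄_i/dpH = −ln10 · cov(n_i, n),
  ```

  so the integrand is anchored to both the sampled means and their exact
  derivatives at every sampled pH. The total splits exactly into per-site
  contributions ΔΔG_i°, a Hill-integral route is provided for comparison,
  and the relative curve can be vertically least-squares anchored to
  experimental ΔG° points.
* **Proton-occupancy correlations** — pairwise Pearson matrices
  (intrachain and interchain), thresholded correlation networks,
  occupancy autocorrelation functions, and correlation times (first lag
  with ACF < 0.1).
* **Ionic density fingerprints** — Gaussian-KDE ion concentration grids
  (mM, 1 Å mesh, 2 Å bandwidth) from trajectory ion tracks after rigid
  fitting onto a central structure, and Boltzmann-relation maps
  c(r) = c_bulk·exp(−zFφ/RT) from external Poisson–Boltzmann potential
  grids (OpenDX I/O).
* **Structural stage** — COM-distance / RMSD dissociation filtering
  (defaults 3.3 nm / 1.2 nm), central structures, a built-in deterministic
  Shrake–Rupley SASA and interface contact areas, interface torsions,
  decoupled-fit PCA (fit atoms and analysed atoms disjoint) and
  free-energy landscapes F = −k_B T ln(P/P_max).

Everything is validated against an **exactly solvable synthetic titration
model**: a coupled-site Hamiltonian whose binding polynomial, moments, and
monomer/dimer free-energy difference are computed by microstate
enumeration, plus a Metropolis sampler that produces occupancy
trajectories with that exact stationary distribution. No external data is
needed to exercise the full pipeline.

## Worked example

Build the shipped 4-site monomer and its dimer (a repulsive interchain
coupling on the interface glutamate makes association pH-sensitive),
enumerate the exact titration moments at pH 3–8, and run the
spline-linkage pipeline:

```python
import numpy as np
from phlink import (demo_study_specs, enumerate_exact,
                    titration_curve_from_exact, ddG_profile, exact_ddG)

m, d = demo_study_specs()
phs = np.arange(3.0, 8.01, 1.0)
cm = titration_curve_from_exact(enumerate_exact(m, phs))
cd = titration_curve_from_exact(enumerate_exact(d, phs))
prof = ddG_profile(cm, cd, pH_ref=3.0)

for ph in phs:
    print(f"{ph:.1f}  {prof.at(ph):10.3f}  {exact_ddG(m, d, ph, 3.0):10.3f}")
```

prints the spline-integrated profile next to the exact binding-polynomial
value (kJ/mol, relative to pH 3):

```
3.0       0.000       0.000
4.0      -3.375      -3.365
5.0      -5.682      -5.709
6.0      -6.096      -6.108
7.0      -6.102      -6.118
8.0      -6.103      -6.118
```

The maximum deviation over the whole dense grid is 0.027 kJ/mol, and the
per-site decomposition (`prof.per_site`) attributes essentially all of it
to the coupled interface site: GLU45 carries |ΔΔG_i| up to 6.34 kJ/mol.
Negative ΔΔG° at high pH means dimerization is *more* favourable there
than at pH 3 — the dimer holds its interface acids protonated less
reluctantly once the monomers have released their protons.

## Command line

The same pipeline runs from a shell on occupancy tables (a plain
tab-separated dialect: header `time_ps<TAB><site>…`, one row per frame,
`#` comments, a `label<TAB>acid|base` sidecar):

```bash
phlink simulate --out study/ --seed 7            # synthetic study + config.yaml
phlink titrate  --config study/config.yaml --out out/titrate
phlink energy   --config study/config.yaml --out out/energy --units kj
phlink correlate --config study/config.yaml --out out/correlate
phlink ions     --config study/config.yaml --out out/ions
phlink conform  --config study/config.yaml --out out/conform
phlink run-all  --config study/config.yaml --out out/
```

`simulate` also writes a multi-model PDB rigid-motion dimer sweep (with
two deliberately dissociated frames) and Na⁺/Cl⁻ ion tracks, so `conform`
and `ions` run end-to-end on synthetic data. Each stage writes TSV/OpenDX
outputs plus a JSON manifest and is bit-reproducible under a fixed seed.

## Layout

```
src/phlink/occupancy.py     data model + table I/O + frame masking
src/phlink/titration.py     moments, fluctuation slopes, Hill fits, bootstrap
src/phlink/linkage.py       Hermite splines, ΔΔG°(pH), decomposition, anchoring
src/phlink/correlations.py  Pearson matrices, networks, ACFs, correlation times
src/phlink/ions.py          KDE + Boltzmann concentration grids, OpenDX I/O
src/phlink/conformation.py  RMSD, SASA, dissociation filter, PCA, landscapes
src/phlink/synthetic.py     enumeration oracle, Metropolis sampler, generators
src/phlink/cli.py           the `phlink` command
```

See `docs/methods.md` for the model conventions, parameter defaults and
known limitations.
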