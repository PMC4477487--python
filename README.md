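# fibrilscatter

Fibre-diffraction analysis of cellulose microfibrils from 1D scattering
profiles: equatorial WAXS peak fitting with size/disorder separation,
monoclinic hk0 cell inversion, SANS interfibril spacing and contrast
matching, WANS H/D difference analysis, and microfibril chain-count
geometry — plus a seeded synthetic-pattern generator with known ground
truth for every stage.

## The problem

Plant cellulose is organised into microfibrils a few nanometres across,
each containing tens of parallel glucan chains packed on the monoclinic
cellulose I-beta lattice.  For grass and cereal cell walls (bamboo being
the best-oriented example) three scattering experiments probe
complementary aspects of this organisation:

* **WAXS** (equatorial): the 1-10, 110, 200 and 400 reflections of the hk0
  lattice.  Peak positions give the lattice spacings d = 2 pi / q0 and the
  monoclinic angle gamma; peak breadths mix crystallite size with
  paracrystalline disorder.
* **WANS with H/D exchange**: soaking in D2O deuterates only *accessible*
  hydroxyls.  The D - H difference pattern isolates the exchanged
  (surface/disordered) chains, locates the 1-10 reflection that overlaps
  110 hopelessly in any single pattern, and reveals meridional 00l peaks
  from irregular chain stagger at the surfaces.
* **SANS with contrast variation**: regularly aggregated microfibrils give
  a broad Bragg peak near q = 2 nm^-1 whose position tracks the
  centre-to-centre spacing d = 2 pi / q_peak; its amplitude scales with
  (delta-rho)^2 and vanishes at the D2O:H2O composition whose scattering
  length density matches cellulose.

The package is for structural-bioscience users who have reduced instrument
data to radial/azimuthal profiles (plain text) and want the full inference
chain, and for methodologists who want a generative test-bed for it.

## Core models

Size/disorder separation on the 200 reflection family: the integral
breadth delta-q (area/height of the symmetric part of the peak) obeys

    delta-q = delta-q0 + (pi/2) g^2 q^2 d

so a line fitted to delta-q vs q^2 d separates the Scherrer dimension
(mean column length) **L = 2 pi / delta-q0** from the disorder parameter
**g = sqrt(2 slope / pi)**.  The 200 peak itself is asymmetric:
F(q) = F0(q) for q >= q0 and F0(q) (1 + 0.1 (q - q0)^2) below, with F0
Gaussian and the constant fixed at 0.1 nm^2.

Monoclinic hk0 lattice: 1/d^2 = [h^2/a^2 + k^2/b^2 - 2hk cos(gamma)/(ab)]
/ sin^2(gamma); `invert_cell` recovers (a, b, gamma) from a spacing triple
on the gamma >= 90 convention.

Contrast matching: sld = (sum n_i b_i) rho N_A / M from tabulated coherent
scattering lengths; the match fraction solves
f sld_D2O + (1-f) sld_H2O = sld_cellulose.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

```python
from fibrilscatter.simulate import GroundTruth, generate_equatorial_waxs
from fibrilscatter.waxs import analyze_equatorial

truth = GroundTruth.bamboo(seed=1)          # gamma=92, L=3.84 nm, g=0.036
profile = generate_equatorial_waxs(truth)   # 1% noise, Cu K-alpha labels
result = analyze_equatorial(profile)
print(result.broadening.L, result.broadening.g, result.cell.gamma)
```

Running `python examples/waxs_size_disorder.py` (which does the above and
prints the full table) produces:

```
  (2, 0, 0): q0 = 15.590 nm^-1, d = 0.4030 nm, integral breadth = 1.836 nm^-1
  (4, 0, 0): q0 = 31.182 nm^-1, d = 0.2015 nm, integral breadth = 2.434 nm^-1

Size/disorder separation on the 200 family:
  delta_q0 (size-only intercept) = 1.636 nm^-1
  Scherrer dimension L = 2 pi / delta_q0 = 3.84 nm (truth 3.84)
  disorder parameter g = 0.0360 (truth 0.036)
  monoclinic angle gamma = 93.1 deg (truth 92.0)
```

The 200 and 400 breadths (1.836 and 2.434 nm^-1 at the same lattice
spacing) differ only through the q^2 disorder term; the regression's
intercept converts to a 3.84 nm mean crystallite dimension perpendicular
to the chain sheets, and the 0.036 disorder parameter is typical of
celluloses.  The other examples cover SANS contrast matching
(`sans_contrast_match.py`), the H/D difference analysis
(`wans_deuteration_difference.py`) and chain counting
(`chain_counting.py`).

A thin CLI wraps the config-driven pipeline:

```bash
fibrilscatter all --seed 1 --out run1/      # simulate + analyse + report.json
fibrilscatter simulate --seed 1 --out sim/  # write synthetic profiles only
```

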