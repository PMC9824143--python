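# bilayerlab

Analysis toolkit for the biophysical characterisation of phospholipid
bilayers, built around the experiments used to probe how small amphiphilic
solutes (e.g. semisynthetic catechins) perturb anionic
phosphatidylglycerol membranes: small- and wide-angle X-ray diffraction
(SAXD/WAXD), differential scanning calorimetry (DSC), infrared carbonyl-band
spectroscopy (FTIR), and geometric statistics on molecular-dynamics
trajectories. A seeded synthetic-data generator stands in for the
instruments and the MD engine, so every stage is testable end to end with no
external data.

## What it computes

**SAXD (`bilayerlab.saxd`).** The transverse electron density of a symmetric
bilayer is modelled as three Gaussians — headgroup peaks of width σ_H at
±Z_H (unit amplitude) and a chain trough of width σ_C and negative relative
amplitude ρ_r at z = 0. For positionally uncorrelated vesicles the diffuse
intensity is

    I(q) = s·|F(q)|²/q² + b,
    F(q) = √(2π)·[2σ_H cos(qZ_H) e^(−q²σ_H²/2) + σ_C ρ_r e^(−q²σ_C²/2)],

and a full-q-range weighted least-squares fit (σ_H conventionally fixed at
3 Å, multi-start against the cosine's local minima) yields the steric
bilayer thickness **d_B = 2(Z_H + 2σ_H)**.

**WAXD (`bilayerlab.waxd`).** Gaussian deconvolution of the 1.32–1.95 Å⁻¹
chain-packing window, d-spacings d = 2π/q₀, and phase assignment:
sharp + broad asymmetric pattern → tilted gel (Lβ′), single symmetric
reflection → rippled gel (Pβ′), diffuse scattering → fluid (Lα).

**DSC (`bilayerlab.dsc`).** Linear baseline subtraction, peak detection,
tangent-construction onset/completion temperatures (for a Gaussian peak:
centre ∓ 2σ), trapezoidal enthalpies, and partial phase diagrams
(solidus = onsets, fluidus = completions vs. solute mole fraction) with
automatic flagging of immiscible (composition-independent) boundary runs.

**FTIR (`bilayerlab.ftir`).** Sub-grid carbonyl band maxima in the
1670–1780 cm⁻¹ window, two-component (≈1742/1728 cm⁻¹,
non-H-bonded/H-bonded) decomposition with the bonded area fraction
`f_hbond`, and sigmoid tracking of the band maximum across temperature to
locate the melting midpoint.

**Trajectories (`bilayerlab.traj`).** Area per lipid (lateral box area per
leaflet lipid), P–P bilayer thickness, geometric hydrogen bonds
(d(D···A) ≤ 0.35 nm, ∠(D→H, D→A) ≤ 30°), non-symmetrised mass density
profiles recentred on the lipid centroid, and single-linkage solute
cluster-size distributions with a 0.25 nm atom-contact cutoff — all under
the minimum-image convention in orthorhombic boxes.

## Worked example

```sh
bilayerlab synth saxd --seed 7 --noise 0.02 --out saxd.tsv
bilayerlab saxd-fit --in saxd.tsv --out fit.json
# d_B = 50.16 A (reduced chi2 0.858)

bilayerlab synth dsc --seed 7 --out thermo.tsv
bilayerlab dsc --in thermo.tsv --out dsc.json
# pretransition: onset 9.00 C, peak 10.00 C, completion 11.00 C, dH 2.0 kJ/mol
# main: onset 22.30 C, peak 23.10 C, completion 23.90 C, dH 27.2 kJ/mol

echo "jitter_sd: 0.0" > spec.yaml
bilayerlab synth bilayer --seed 7 --frames 3 --config spec.yaml --out bilayer.gro
bilayerlab traj --in bilayer.gro --out traj.json
# area_per_lipid_nm2: 0.630 ± 0.000
# pp_thickness_nm: 3.370 ± 0.000
```

The synthetic scattering curve is generated from a gel-phase profile
(Z_H = 19.08 Å, σ_H = 3 Å) with 2% counting noise; the fit recovers the
thickness of a gel-phase phosphatidylglycerol bilayer, d_B = 50.16 Å. The
default thermogram plants a weak pretransition (onset 9 °C) and the main
gel→fluid transition of pure DMPG (onset 22.3 °C, ΔH 27.2 kJ/mol), both of
which the tangent/integration pipeline recovers. The default pseudo-bilayer
emulates 128 lipids in a 6.35 nm box (area per lipid 0.63 nm²) with
phosphorus planes ±1.685 nm apart (P–P thickness 3.37 nm).

## Layout

```
src/bilayerlab/   curves, structures (IO) · saxd · waxd · dsc · ftir ·
                  traj · synth · cli
docs/methods.md   model assumptions, parameter defaults, limitations
tests/            pytest suite with brute-force oracles and property tests
```
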