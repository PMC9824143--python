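# Methods

This note records the models behind each analysis stage, the defaults that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Diffuse small-angle scattering and bilayer thickness

The bilayer's transverse electron-density contrast is a sum of three
Gaussians: headgroup peaks of width σ_H (Å) at ±Z_H and a hydrocarbon-chain
trough of width σ_C and negative amplitude ρ_r (relative to the headgroup
amplitude, which is fixed at 1 — the model is only determined up to overall
scale, and fixing the amplitude removes that degeneracy). The form factor is
the closed-form cosine transform of this profile; for charged vesicles with
no positional correlations the measured intensity is the pure diffuse term
s·|F(q)|²/q² plus a constant background. Scale and background are fitted
even though the idealised model omits them: any real full-q-range fit needs
both, and the fit report states they were included.

Model assumptions: a symmetric, laterally infinite bilayer; no lamellar
structure factor (positionally uncorrelated vesicles); no instrumental
smearing. A slit-smearing correction for Kratky-type cameras is a known
limitation — no smearing geometry is modelled, so fits to strongly smeared
data will bias σ values.

Fitting: weighted least squares (1/σ² weights when uncertainties are
present), bounds Z_H ∈ [5, 40] Å, σ_H ∈ [1, 6] Å, σ_C ∈ [2, 15] Å,
ρ_r ∈ [−2, 0). The cosine term makes the residual surface multimodal in
Z_H, so the optimiser restarts from 5 seeded perturbations of the initial
point and keeps the best reduced χ². σ_H is held at 3 Å by default — the
conventional constraint for this profile family; the headgroup width is
poorly determined by diffuse data alone. The steric thickness is
d_B = 2(Z_H + 2σ_H); its 1-σ uncertainty comes from the local quadratic
approximation (covariance) at the optimum.

## Wide-angle chain packing

Reflections in the 1.32–1.95 Å⁻¹ window are modelled as Gaussians on a flat
baseline; no peak shape is canonical here, and Gaussian keeps the
deconvolution linear in log-likelihood terms. When the component count is
not forced, 1- vs 2-component fits are compared by corrected Akaike
criterion (AICc) — an explicit, testable stand-in for by-eye pattern
classification. Phase assignment is a deliberate simplification of the
field's qualitative taxonomy with two tunables:

* two components with FWHM ratio ≥ 2 → Lβ′ (sharp reflection riding on a
  broad one: tilted chains, pseudo-orthorhombic packing);
* a single component narrower than the diffuse threshold (default
  0.15 Å⁻¹ FWHM) → Pβ′ (symmetric reflection, hexagonal packing);
* a single component at/above the threshold → Lα (diffuse, fluid chains).

Width ratios in [1.5, 2) are labelled Pβ′ with an "ambiguous" flag; ratios
below 1.5 are treated as one effectively symmetric reflection and
classified by mean width ("similar-widths" flag). These thresholds are
artifact decisions, not measured constants. Unit-cell indexing and
chain-tilt estimation are out of scope.

## Calorimetry

Thermograms are processed as excess heat capacity (kJ·mol⁻¹·K⁻¹) vs.
temperature; the ordinate is assumed already molar, so no lipid-mass
bookkeeping is done (instrument-export conventions vary too much to guess).

* **Baseline**: the straight line through the mean points of two user-chosen
  peak-free windows; subtraction is idempotent, and a window overlapping a
  detected peak is an error.
* **Peak regions**: prominence-based maxima; each region extends outward to
  where the signal falls below 0.1% of the peak height. This edge keeps
  ≥ 99.97% of a Gaussian peak's area inside the region so integrated
  enthalpies match planted areas to better than 0.2%; a looser 1% edge
  would silently discard ~0.24% of the area. Overlapping regions are merged
  and flagged.
* **Onset/completion**: the tangent at the steepest point of the leading
  (trailing) edge, located on a Savitzky–Golay-smoothed derivative
  (window 5–11 points, default 7, polynomial order 3), intersected with the
  zero baseline. For a Gaussian of centre c and width σ this gives exactly
  c − 2σ and c + 2σ, which anchors the tests. The completion construction
  mirrors the onset construction onto the trailing edge; only the
  leading-edge procedure is classical, so the mirrored trailing-edge
  tangent is this package's own interpretation.
* **Enthalpy**: trapezoidal integration over the region. Overlapping
  domains are not deconvolved into component enthalpies.
* **Phase diagram**: onsets form the solidus, completions the fluidus,
  indexed by solute mole fraction; the fluidus−solidus gap is the
  coexistence width. A maximal run of ≥ 3 consecutive boundary points with
  temperature spread ≤ 0.3 °C (the order of peak-position reproducibility;
  configurable) is flagged immiscible: an additive whose increasing
  concentration stops shifting the transition leaves pure phospholipid
  melting at a fixed temperature.

## Carbonyl-band infrared analysis

The ester carbonyl stretching band (1670–1780 cm⁻¹) is treated as the sum
of a non-hydrogen-bonded component near 1742 cm⁻¹ and a hydrogen-bonded
component near 1728 cm⁻¹. Components are Gaussian (the band shape at this
resolution does not discriminate; pseudo-Voigt would add a shape parameter
the synthetic data cannot constrain). The bonded fraction is
f_hbond = area_low/(area_low + area_high); component centres are bounded to
±6 cm⁻¹ of their initial guesses to keep the two-component fit identified.
Band maxima are refined below grid resolution by a quadratic through the 5
points around the discrete maximum. Across a temperature series a falling
logistic sigmoid is fitted to the maxima; if it does not beat a constant by
AICc the midpoint is reported absent. Spectra are assumed pre-corrected for
solvent background (measurements in deuterated buffer leave this window
clear); no solvent subtraction is implemented.

## Trajectory statistics

All pair distances use the minimum-image convention in orthorhombic boxes;
triclinic boxes are rejected at the IO layer. Neighbour searches use a
periodic k-d tree whose candidate pairs are re-checked with the same
minimum-image arithmetic the brute-force test oracles use, so the two
routes agree exactly.

* **Area per lipid**: box_x·box_y/(N/2) per frame, mean ± sd over frames.
* **Leaflets / P–P thickness**: lipids are assigned to leaflets by
  phosphorus z relative to the mass-weighted lipid centroid (phosphorus
  within 0.1 nm of the midplane is flagged ambiguous, assigned by sign);
  thickness is the distance between the mean phosphorus planes.
* **Hydrogen bonds**: donor–acceptor distance ≤ 0.35 nm and the angle at
  the donor between D→H and D→A ≤ 30°, inclusive; intra-molecular pairs
  are excluded. The donor-centred angle convention is used; the
  acceptor-centred alternative is deliberately rejected as it measures a
  different geometry. Hydrogens attach to the nearest donor of their own
  molecule (the containers carry no bond table).
* **Density profiles**: per frame the lipid mass centroid defines z = 0
  (the bilayer's natural frame), selected masses are binned along z
  (default 0.1 nm), and frames are averaged with no leaflet
  symmetrisation, so leaflet asymmetries survive.
* **Clusters**: two solute molecules are linked when the minimum over all
  atom pairs of the minimum-image distance is ≤ 0.25 nm; clusters are
  connected components (single linkage). The atom-pair minimum is the
  default because a 0.25 nm cutoff describes atomic contact; a centroid
  metric is available (`method="centroid"`) but would miss contacts
  between large molecules. All solute atoms participate, hydrogens
  included. Histograms are accumulated per frame then averaged (not
  pooled), so a replicate-style spread is recoverable; the monomer
  fraction is the time-averaged fraction of molecules in size-1 clusters.
  A `--discard` fraction drops initial frames, mirroring the common
  practice of analysing only the equilibrated tail of a run.

## Synthetic data: what it emulates, what it does not

Generators exist so every stage can be validated against planted truth with
no instrument or MD engine. Defaults encode the study conditions: SAXD on
q ∈ [0.05, 0.6] Å⁻¹ with 2% relative counting noise from a gel-phase
profile (Z_H 19.08 Å, σ_H 3 Å); thermograms on a 0.01 °C grid with a weak
pretransition (centre 10 °C, σ 0.5, 2 kJ/mol → onset 9 °C) and the main
transition (centre 23.1 °C, σ 0.4, 27.2 kJ/mol → onset 22.3 °C); carbonyl
bands at 1742/1728 cm⁻¹ (σ 8 cm⁻¹) whose bonded weight follows a logistic
in temperature; and a pseudo-bilayer of 128 three-site lipids (P planes
±1.685 nm, lateral box 6.3499 nm → area per lipid 0.63 nm²) with 14
single-atom solutes planted as the partition {3, 3, 4, 1, 1, 1, 1}
(monomer fraction 4/14).

Deliberate simplifications, chosen for testability:

* DSC peaks are symmetric Gaussians although real endotherms are skewed;
  the tangent construction does not require skewness and the symmetric
  shape gives closed-form onsets.
* Planted solute clusters keep a 2× separation margin (≥ 0.55 nm between
  clusters vs. 0.2 nm chain spacing inside one), making single-linkage
  recovery tie-free; planted hydrogen-bond triplets sit at 0.30 nm/0°
  while every decoy violates the criterion by ≥ 0.10 nm or ≥ 60°. Two
  decoy units (one distance, one angle violation) are always planted so a
  zero bond count is still informative.
* Positional jitter applies to lipid sites only; solute and probe
  positions are frame-constant so the planted combinatorics hold in every
  frame.
* Equal FTIR component widths and a weight range symmetric about ½ make
  the band-maximum series antisymmetric about the planted midpoint, so the
  sigmoid fit recovers it exactly.

None of this produces physically realistic lipid conformations, force-field
energetics, skewed endotherms, smeared scattering, or correlated noise.
Passing tests therefore demonstrate that the estimators recover known
ground truth under the stated statistical structure — not that they are
robust to every artefact of real instruments.

## Problem sizes and reproducibility

Test and acceptance runs use desk-scale problems: 20-replicate noise
ensembles for the SAXD/WAXD/FTIR recovery checks, 50 random periodic
configurations (~90 atoms each) for the exact oracle comparisons,
≤ 100-frame synthetic trajectories, and 0.002 Å⁻¹ / 0.01 °C / 0.25 cm⁻¹
grids. Every stochastic step takes an explicit integer seed
(`numpy.random.default_rng`); identical seeds give bit-identical curves,
configurations and CLI output files.

## Known limitations

* No multilamellar structure factor (Caillé theory) and no absolute-scale
  electron densities; the SAXD fit applies only to uncorrelated bilayers.
* No instrumental smearing model for slit-collimated cameras.
* No scan-rate correction or van't Hoff cooperativity analysis in DSC.
* GRO/PDB only (no XTC/TRR or mmCIF); orthorhombic boxes only.
* Hydrogen-bond donors are paired to hydrogens by same-molecule proximity,
  which assumes each hydroxyl-like group is its own labelled molecule or
  unambiguous within one.
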