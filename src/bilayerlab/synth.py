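"""Synthetic instrument- and simulation-style inputs with known ground truth.

No public data accompany the measurements this pipeline targets, so every
analysis stage is exercised on generated inputs that carry the statistical
structure the stage assumes:

* smeared-free diffuse bilayer scattering with relative Gaussian counting
  noise (small-angle stage);
* Gaussian chain-packing reflections on a flat baseline (wide-angle stage);
* calorimetric endotherms as unit-area-normalised Gaussian peaks on a linear
  baseline, so planted peak areas are exactly the recoverable enthalpies and
  the tangent onset of a planted Gaussian is centre − 2σ in closed form;
* carbonyl bands as two overlapping Gaussian components whose
  hydrogen-bonded weight follows a logistic sigmoid in temperature;
* two-leaflet pseudo-bilayer configurations with labelled phosphorus /
  carbonyl / terminal-methyl sites, solute molecules with a planted cluster
  partition (2× separation margin between clusters so single-linkage
  recovery is unambiguous), and donor–H–acceptor triplets planted inside —
  or violating by a safe margin — the geometric hydrogen-bond criterion.

Every generator takes an explicit seed and is reproducible bit-for-bit.
Positional jitter applies to lipid sites only; solute and probe positions
are deterministic up to their seeded draws and keep the separation
guarantees exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import Curve
from .saxd import ElectronDensityProfile, model_intensity
from .structures import Configuration, Trajectory

__all__ = [
    "SaxdTruth",
    "ThermogramTruth",
    "BilayerSpec",
    "DEFAULT_ROLE_MAP",
    "DEFAULT_KIND_MAP",
    "generate_saxd_curve",
    "generate_waxd_curve",
    "generate_thermogram",
    "generate_ftir_series",
    "generate_bilayer",
]

#: atom-name → site-role map matching the generator's naming
DEFAULT_ROLE_MAP = {
    "P": "phosphorus", "CO": "carbonyl", "CM": "terminal_methyl",
    "OD": "donor", "HD": "hydrogen", "OA": "acceptor",
}
#: residue-name → molecule-kind map matching the generator's naming
DEFAULT_KIND_MAP = {
    "DMP": "lipid", "TMB": "solute", "SOL": "water",
    "DOH": "water", "ACC": "water",
}

_MASS = {"P": 30.974, "CO": 28.010, "CM": 15.035, "S": 466.5,
         "OD": 15.999, "HD": 1.008, "OA": 15.999, "OW": 18.015}


# ---------------------------------------------------------------------------
# scattering

@dataclass
class SaxdTruth:
    """Ground truth for a diffuse small-angle scattering curve."""

    edp: ElectronDensityProfile
    scale: float = 1.0
    background: float = 0.0
    q_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.05, 0.6001, 0.002))
    noise_fraction: float = 0.02

    def __post_init__(self) -> None:
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        if np.any(self.q_grid <= 0) or np.any(self.q_grid > 2.0):
            raise ValueError("q_grid must lie within (0, 2] Å⁻¹")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")


def generate_saxd_curve(truth: SaxdTruth, seed: int = 0) -> Curve:
    """Diffuse bilayer scattering with relative Gaussian counting noise.

    y = scale·|F(q)|²/q² + background, perturbed point-wise by Gaussian noise
    of sd = noise_fraction·y; the per-point sd becomes ``y_err``.
    """
    rng = np.random.default_rng(seed)
    q = truth.q_grid
    y_clean = model_intensity(q, truth.edp, truth.scale, truth.background)
    meta = {
        "x_unit": "1/angstrom", "generator": "saxd",
        "Z_H": f"{truth.edp.Z_H:g}", "sigma_H": f"{truth.edp.sigma_H:g}",
        "sigma_C": f"{truth.edp.sigma_C:g}", "rho_r": f"{truth.edp.rho_r:g}",
        "scale": f"{truth.scale:g}", "background": f"{truth.background:g}",
        "noise_fraction": f"{truth.noise_fraction:g}", "seed": str(seed),
    }
    if truth.noise_fraction == 0:
        return Curve(q.copy(), y_clean, None, meta)
    sd = truth.noise_fraction * np.abs(y_clean)
    y = y_clean + rng.standard_normal(q.size) * sd
    sd = np.where(sd > 0, sd, np.finfo(float).tiny)
    return Curve(q.copy(), y, sd, meta)


def generate_waxd_curve(peaks, baseline: float = 0.0,
                        q_grid=None, noise_sd: float = 0.0,
                        seed: int = 0) -> Curve:
    """Wide-angle pattern: Gaussian reflections on a flat baseline.

    ``peaks`` is an iterable of (center Å⁻¹, fwhm Å⁻¹, amplitude).
    """
    rng = np.random.default_rng(seed)
    q = (np.asarray(q_grid, dtype=float) if q_grid is not None
         else np.arange(1.32, 1.9501, 0.002))
    y = np.full_like(q, float(baseline))
    fwhm_to_sigma = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    for center, fwhm, amp in peaks:
        sigma = fwhm * fwhm_to_sigma
        y = y + amp * np.exp(-((q - center) ** 2) / (2.0 * sigma**2))
    if noise_sd > 0:
        y = y + rng.standard_normal(q.size) * noise_sd
    return Curve(q, y, None, {"x_unit": "1/angstrom", "generator": "waxd",
                              "seed": str(seed)})


# ---------------------------------------------------------------------------
# calorimetry

@dataclass
class ThermogramTruth:
    """Ground truth for a synthetic heating endotherm.

    Each peak is (center °C, width °C, area kJ/mol) with a unit-area Gaussian
    shape, so the integral above the baseline equals the sum of areas and the
    tangent onset/completion are centre ∓ 2·width in closed form.  Real
    endotherms are skewed; the symmetric shape is a deliberate testability
    choice — the tangent construction does not require skewness.
    """

    peaks: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(10.0, 0.5, 2.0), (23.1, 0.4, 27.2)])
    baseline: tuple[float, float] = (0.0, 0.0)  # intercept, slope
    T_grid: np.ndarray = field(
        default_factory=lambda: np.arange(2.0, 35.0001, 0.01))
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        for c, w, a in self.peaks:
            if w <= 0:
                raise ValueError("peak widths must be positive")
            if a < 0:
                raise ValueError("peak areas must be non-negative")


def generate_thermogram(truth: ThermogramTruth, seed: int = 0) -> Curve:
    """Excess heat capacity vs. temperature with planted peak areas.

    Raises "peak truncated" when the grid does not cover every peak ± 5
    widths, so planted areas remain recoverable by integration.
    """
    rng = np.random.default_rng(seed)
    T = truth.T_grid
    for c, w, _ in truth.peaks:
        if c - 5 * w < T[0] or c + 5 * w > T[-1]:
            raise ValueError(
                f"peak truncated: grid does not cover {c:g} ± 5·{w:g} °C")
    a0, a1 = truth.baseline
    y = a0 + a1 * T
    for c, w, area in truth.peaks:
        y = y + area * np.exp(-((T - c) ** 2) / (2.0 * w**2)) / (
            w * np.sqrt(2.0 * np.pi))
    if truth.noise_sd > 0:
        y = y + rng.standard_normal(T.size) * truth.noise_sd
    return Curve(T.copy(), y, None,
                 {"x_unit": "degC", "generator": "dsc", "seed": str(seed)})


# ---------------------------------------------------------------------------
# infrared

def generate_ftir_series(T_m: float, temps, *, centers=(1742.0, 1728.0),
                         widths=(8.0, 8.0), weight_range=(0.15, 0.85),
                         transition_width: float = 1.0,
                         noise_sd: float = 0.0, seed: int = 0,
                         grid=None) -> list[tuple[float, Curve]]:
    """Carbonyl-band spectra across temperature with a planted midpoint.

    Each spectrum is the sum of two Gaussian component bands; the relative
    weight of the low-wavenumber (hydrogen-bonded) component rises with a
    logistic sigmoid centred at ``T_m``, emulating interfacial hydration in
    the fluid phase.  With equal component widths and a weight range
    symmetric about ½ the wavenumber-maximum series is antisymmetric about
    ``T_m``, so the planted midpoint is exactly recoverable.

    Returns a list of (temperature, Curve) pairs.
    """
    temps = list(temps)
    if not temps:
        raise ValueError("temps must not be empty")
    for c in centers:
        if not (1670.0 <= c <= 1780.0):
            raise ValueError("component centres must lie in 1670–1780 cm⁻¹")
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    x = (np.asarray(grid, dtype=float) if grid is not None
         else np.arange(1670.0, 1780.0 + 0.125, 0.25))
    c_hi, c_lo = max(centers), min(centers)
    s_hi, s_lo = (widths[0], widths[1]) if centers[0] >= centers[1] else (
        widths[1], widths[0])
    w0, w1 = weight_range
    out = []
    for T in temps:
        w_low = w0 + (w1 - w0) * expit((T - T_m) / transition_width)
        y = ((1.0 - w_low) * np.exp(-((x - c_hi) ** 2) / (2 * s_hi**2))
             + w_low * np.exp(-((x - c_lo) ** 2) / (2 * s_lo**2)))
        if noise_sd > 0:
            y = y + rng.standard_normal(x.size) * noise_sd
        out.append((float(T), Curve(
            x.copy(), y, None,
            {"x_unit": "1/cm", "generator": "ftir",
             "temperature_C": f"{T:g}", "seed": str(seed)})))
    return out


# ---------------------------------------------------------------------------
# pseudo-bilayer configurations

#: intra-cluster chain spacing (nm); the contact cutoff of the cluster stage
_CHAIN_SPACING = 0.20
#: required clear gap between distinct clusters (2 × the 0.25 nm cutoff + margin)
_CLUSTER_GAP = 0.55
#: grid spacing between planted hydrogen-bond probe units (nm)
_HB_SPACING = 1.0


@dataclass
class BilayerSpec:
    """Geometry of a generated two-leaflet pseudo-bilayer.

    Defaults emulate the study system: 128 lipids split over two leaflets
    with phosphorus planes at ±1.685 nm (P–P thickness 3.37 nm), a lateral
    box of 6.3499 nm (area per lipid 0.63 nm²), and 14 solute molecules
    whose planted partition {3, 3, 4, 1, 1, 1, 1} gives a monomer fraction
    of 4/14 ≈ 28.6%.
    """

    n_lipids: int = 128
    leaflet_z: float = 1.685           # nm, ± position of the P planes
    carbonyl_offset: float = 0.45      # nm toward the bilayer centre
    methyl_offset: float = 1.65        # nm toward the bilayer centre
    n_solute: int = 14
    solute_z_band: tuple[float, float] = (0.5, 1.1)  # nm above the centre
    planted_clusters: tuple[int, ...] = (3, 3, 4, 1, 1, 1, 1)  # sizes
    planted_hbonds: int = 6
    n_water: int = 0
    box: tuple[float, float, float] = (6.3499, 6.3499, 9.0)
    jitter_sd: float = 0.05            # nm, lipid-site positional noise

    def __post_init__(self) -> None:
        if self.n_lipids % 2:
            raise ValueError("n_lipids must be even")
        if sum(self.planted_clusters) != self.n_solute:
            raise ValueError("planted_clusters must partition the solutes")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.leaflet_z >= self.box[2] / 2:
            raise ValueError("leaflet_z must lie inside the box")
        if self.planted_hbonds < 0:
            raise ValueError("planted_hbonds must be >= 0")

    def cluster_partition(self) -> list[tuple[int, ...]]:
        """Planted partition as explicit solute ids (consecutive blocks)."""
        out, start = [], 0
        for size in self.planted_clusters:
            out.append(tuple(range(start, start + size)))
            start += size
        return out


def _place_clusters(spec: BilayerSpec, rng) -> np.ndarray:
    """Solute positions honouring intra-/inter-cluster distance guarantees."""
    Lx, Ly, _ = spec.box
    margin = 0.3  # keeps min-image gaps across the boundary ≥ _CLUSTER_GAP
    usable_x = Lx - 2 * margin
    usable_y = Ly - 2 * margin
    if usable_x <= 0 or usable_y <= 0:
        raise ValueError("box too small for the planted cluster layout")
    zc = spec.box[2] / 2.0
    positions = []
    x_cur, row = margin, 0
    for size in spec.planted_clusters:
        width = _CHAIN_SPACING * (size - 1)
        if x_cur + width > margin + usable_x:
            row += 1
            x_cur = margin
            if x_cur + width > margin + usable_x:
                raise ValueError("box too small for the planted cluster layout")
        y = margin + row * _CLUSTER_GAP
        if y > margin + usable_y:
            raise ValueError("box too small for the planted cluster layout")
        z = zc + rng.uniform(*spec.solute_z_band)
        for k in range(size):
            positions.append([x_cur + k * _CHAIN_SPACING, y, z])
        x_cur += width + _CLUSTER_GAP
    return np.asarray(positions)


def _place_hbond_units(spec: BilayerSpec, rng):
    """Planted bond units plus one distance decoy and one angle decoy.

    Each unit is one donor–hydrogen molecule and one acceptor molecule.
    Planted units: d(D,A) = 0.30 nm, collinear (angle 0).  Distance decoy:
    d(D,A) = 0.45 nm (violates 0.35 by 0.10 ≥ the 0.05 margin).  Angle
    decoy: d(D,A) = 0.30 nm but the hydrogen perpendicular to D→A (90°,
    violating 30° by 60 ≥ the 10° margin).  Units sit on a 1 nm grid in the
    water slab so no cross-unit pair comes near the distance cutoff.
    """
    Lx, Ly, Lz = spec.box
    z_slab = Lz / 2.0 + spec.leaflet_z + 1.2
    if z_slab > Lz - 0.5:
        raise ValueError("box too small for the hydrogen-bond probe slab")
    n_units = spec.planted_hbonds + 2
    margin = 0.5
    nx = int((Lx - 2 * margin) // _HB_SPACING) + 1
    ny = int((Ly - 2 * margin) // _HB_SPACING) + 1
    if nx * ny < n_units:
        raise ValueError("box too small for the planted hydrogen bonds")
    units = []
    for u in range(n_units):
        gx = margin + (u % nx) * _HB_SPACING
        gy = margin + (u // nx) * _HB_SPACING
        d = np.array([gx, gy, z_slab])
        if u < spec.planted_hbonds:          # genuine bond
            a = d + [0.30, 0.0, 0.0]
            h = d + [0.10, 0.0, 0.0]
        elif u == spec.planted_hbonds:       # distance decoy
            a = d + [0.45, 0.0, 0.0]
            h = d + [0.10, 0.0, 0.0]
        else:                                 # angle decoy
            a = d + [0.30, 0.0, 0.0]
            h = d + [0.0, 0.10, 0.0]
        units.append((d, h, a))
    return units


def generate_bilayer(spec: BilayerSpec, n_frames: int = 1,
                     seed: int = 0) -> Trajectory:
    """Generate a labelled pseudo-bilayer trajectory with planted truth.

    Each lipid contributes a phosphorus, a carbonyl and a terminal-methyl
    site; lipids are laid out on a per-leaflet lattice and jittered
    independently per frame with sd ``spec.jitter_sd``.  Solute and
    hydrogen-bond probe positions are fixed across frames so the planted
    cluster partition and bond count hold in every frame.
    """
    rng = np.random.default_rng(seed)
    Lx, Ly, Lz = spec.box
    zc = Lz / 2.0

    solute_xyz = _place_clusters(spec, rng)
    hb_units = _place_hbond_units(spec, rng)
    water_xyz = rng.uniform([0, 0, 0], [Lx, Ly, Lz], size=(spec.n_water, 3))

    per_leaflet = spec.n_lipids // 2
    side = int(np.ceil(np.sqrt(per_leaflet)))
    lattice = [(Lx * (i + 0.5) / side, Ly * (j + 0.5) / side)
               for i in range(side) for j in range(side)][:per_leaflet]

    # static labelling shared by all frames
    names, resnames, mol_ids, roles, kinds, masses = [], [], [], [], [], []

    def add(name, resname, mol, role, kind):
        names.append(name)
        resnames.append(resname)
        mol_ids.append(mol)
        roles.append(role)
        kinds.append(kind)
        masses.append(_MASS.get(name, 12.011))

    mol = 0
    for sign in (+1, -1):
        for _ in lattice:
            mol += 1
            for name, role in (("P", "phosphorus"), ("CO", "carbonyl"),
                               ("CM", "terminal_methyl")):
                add(name, "DMP", mol, role, "lipid")
    for _ in range(spec.n_solute):
        mol += 1
        add("S", "TMB", mol, "other", "solute")
    for _ in hb_units:
        mol += 1
        add("OD", "DOH", mol, "donor", "water")
        add("HD", "DOH", mol, "hydrogen", "water")
        mol += 1
        add("OA", "ACC", mol, "acceptor", "water")
    for _ in range(spec.n_water):
        mol += 1
        add("OW", "SOL", mol, "other", "water")

    static = np.zeros((len(names), 3))
    i = spec.n_lipids * 3
    static[i:i + spec.n_solute] = solute_xyz
    i += spec.n_solute
    for d, h, a in hb_units:
        static[i], static[i + 1], static[i + 2] = d, h, a
        i += 3
    static[i:i + spec.n_water] = water_xyz

    frames = []
    for _ in range(n_frames):
        pos = static.copy()
        k = 0
        for sign in (+1, -1):
            for (x, y) in lattice:
                base_z = zc + sign * spec.leaflet_z
                for offset in (0.0, spec.carbonyl_offset, spec.methyl_offset):
                    p = np.array([x, y, base_z - sign * offset])
                    if spec.jitter_sd > 0:
                        p = p + rng.normal(0.0, spec.jitter_sd, 3)
                    pos[k] = p
                    k += 1
        frames.append(Configuration(
            positions=pos, box=np.array(spec.box),
            mol_ids=np.array(mol_ids), mol_kinds=np.array(kinds, dtype=object),
            roles=np.array(roles, dtype=object), masses=np.array(masses),
            names=np.array(names, dtype=object),
            resnames=np.array(resnames, dtype=object),
        ))
    return Trajectory(frames, np.arange(n_frames) * 0.1)
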