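"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's neighbour-search code paths: all-pairs
loops with explicit minimum-image arithmetic, plain quadrature, and
union-find connected components.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad


def mi_dist(a, b, box):
    """Minimum-image distance between two points in an orthorhombic box."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d -= box * np.round(d / box)
    return float(np.sqrt((d * d).sum()))


def quad_form_factor(q, Z_H, sigma_H, sigma_C, rho_r, z_max=80.0):
    """Numerical cosine transform of the three-Gaussian density profile."""

    def rho(z):
        return (np.exp(-((z - Z_H) ** 2) / (2 * sigma_H**2))
                + np.exp(-((z + Z_H) ** 2) / (2 * sigma_H**2))
                + rho_r * np.exp(-(z**2) / (2 * sigma_C**2)))

    val, _ = quad(lambda z: rho(z) * np.cos(q * z), -z_max, z_max, limit=400)
    return val


def brute_hbond_count(conf, r_max=0.35, theta_max=30.0):
    """All-pairs geometric hydrogen-bond count.

    Assumes each donor molecule carries exactly one donor and one hydrogen
    (the configurations built for oracle tests guarantee this), so the
    donor–hydrogen pairing is unambiguous.
    """
    donors = np.flatnonzero(conf.roles == "donor")
    acceptors = np.flatnonzero(conf.roles == "acceptor")
    hydros = np.flatnonzero(conf.roles == "hydrogen")
    h_of = {}
    for d in donors:
        hs = [h for h in hydros if conf.mol_ids[h] == conf.mol_ids[d]]
        assert len(hs) == 1, "oracle requires one hydrogen per donor molecule"
        h_of[d] = hs[0]
    box = conf.box
    cos_max = np.cos(np.deg2rad(theta_max))
    count = 0
    for d in donors:
        h = h_of[d]
        v_dh = conf.positions[h] - conf.positions[d]
        v_dh -= box * np.round(v_dh / box)
        for a in acceptors:
            if conf.mol_ids[a] == conf.mol_ids[d]:
                continue
            v_da = conf.positions[a] - conf.positions[d]
            v_da -= box * np.round(v_da / box)
            r = np.sqrt((v_da * v_da).sum())
            if r > r_max or r == 0:
                continue
            cos = float(v_da @ v_dh) / (r * np.sqrt((v_dh * v_dh).sum()))
            if cos >= cos_max:
                count += 1
    return count


def brute_cluster_sizes(conf, cutoff=0.25):
    """Single-linkage solute cluster sizes by all-pairs union-find."""
    mols = sorted(set(int(m) for m, k in zip(conf.mol_ids, conf.mol_kinds)
                      if k == "solute"))
    atoms = {m: np.flatnonzero((conf.mol_ids == m)
                               & (conf.mol_kinds == "solute")) for m in mols}
    parent = {m: m for m in mols}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, m1 in enumerate(mols):
        for m2 in mols[i + 1:]:
            linked = any(
                mi_dist(conf.positions[a], conf.positions[b], conf.box)
                <= cutoff
                for a in atoms[m1] for b in atoms[m2])
            if linked:
                parent[find(m1)] = find(m2)
    sizes: dict[int, int] = {}
    for m in mols:
        r = find(m)
        sizes[r] = sizes.get(r, 0) + 1
    return sorted(sizes.values())
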