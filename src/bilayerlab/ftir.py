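"""Ester carbonyl stretching band analysis (ν(C=O), 1670–1780 cm⁻¹).

The carbonyl band of a phosphoglyceride is a superposition of two component
bands: a high-wavenumber component near 1742 cm⁻¹ from non-hydrogen-bonded
carbonyls and a low-wavenumber component near 1728 cm⁻¹ from hydrogen-bonded
carbonyls.  Melting of the acyl chains hydrates the interfacial region, the
hydrogen-bonded fraction grows, and the band maximum shifts to lower
wavenumber — so tracking the maximum across temperature traces the phase
transition, and a two-component decomposition quantifies the bonded
fraction ``f_hbond = area_low / (area_low + area_high)``.

Components are modelled as Gaussians (the band shape is not sharply
determined at this resolution); spectra are assumed already corrected for
solvent background (measurements in deuterated buffer leave this window
clear).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
from scipy.special import expit

from .curves import Curve

__all__ = [
    "CARBONYL_WINDOW",
    "CarbonylDecomposition",
    "band_maximum",
    "decompose_carbonyl",
    "maximum_vs_temperature",
]

#: spectral window of the ester carbonyl band (cm⁻¹)
CARBONYL_WINDOW = (1670.0, 1780.0)


@dataclass
class CarbonylDecomposition:
    """Two-component decomposition of the carbonyl band."""

    center_high: float   # non-H-bonded component, cm⁻¹
    center_low: float    # H-bonded component, cm⁻¹
    width_high: float    # Gaussian sigma, cm⁻¹
    width_low: float
    amp_high: float
    amp_low: float
    f_hbond: float       # relative area of the low component, in [0, 1]

    def __post_init__(self) -> None:
        if not self.center_low < self.center_high:
            raise ValueError("require center_low < center_high")
        if not (0.0 <= self.f_hbond <= 1.0):
            raise ValueError("f_hbond must be in [0, 1]")

    @property
    def area_low(self) -> float:
        return self.amp_low * self.width_low * np.sqrt(2.0 * np.pi)

    @property
    def area_high(self) -> float:
        return self.amp_high * self.width_high * np.sqrt(2.0 * np.pi)


def band_maximum(spectrum: Curve, window=CARBONYL_WINDOW) -> float:
    """Sub-grid position (cm⁻¹) of the band maximum inside ``window``.

    A quadratic is fitted through the 5 points around the discrete maximum
    and its vertex returned; a maximum at the window edge cannot be refined
    and triggers a "truncated band" warning.
    """
    lo, hi = window
    if lo < spectrum.x[0] - 1e-9 or hi > spectrum.x[-1] + 1e-9:
        raise ValueError("window extends beyond the spectrum")
    sub = spectrum.crop(lo, hi)
    if len(sub) < 5:
        raise ValueError("window contains fewer than 5 points")
    i = int(np.argmax(sub.y))
    if i < 2 or i > len(sub) - 3:
        warnings.warn("truncated band: maximum at the window edge",
                      stacklevel=2)
        return float(sub.x[i])
    xs = sub.x[i - 2:i + 3]
    ys = sub.y[i - 2:i + 3]
    a, b, _ = np.polyfit(xs - xs[2], ys, 2)
    if a >= 0:  # degenerate curvature; fall back to the grid maximum
        return float(xs[2])
    return float(xs[2] - b / (2.0 * a))


def decompose_carbonyl(spectrum: Curve, init_centers=(1742.0, 1728.0),
                       center_bound: float = 6.0) -> CarbonylDecomposition:
    """Two-Gaussian least-squares fit of the carbonyl band.

    Component centres are bounded to ±``center_bound`` cm⁻¹ of the initial
    guesses; the result is ordered so that ``center_low < center_high``.
    """
    sub = spectrum.crop(*CARBONYL_WINDOW)
    x, y = sub.x, sub.y
    if x.size < 10:
        raise ValueError("too few points for a two-component fit")
    c_hi, c_lo = max(init_centers), min(init_centers)

    params = lmfit.Parameters()
    amp0 = max(float(y.max()), 1e-12)
    for tag, c0 in (("high", c_hi), ("low", c_lo)):
        params.add(f"c_{tag}", value=c0, min=c0 - center_bound,
                   max=c0 + center_bound)
        params.add(f"s_{tag}", value=7.0, min=1.0, max=25.0)
        params.add(f"a_{tag}", value=0.6 * amp0, min=0.0)

    def model(p):
        out = np.zeros_like(x)
        for tag in ("high", "low"):
            out = out + p[f"a_{tag}"].value * np.exp(
                -((x - p[f"c_{tag}"].value) ** 2)
                / (2.0 * p[f"s_{tag}"].value ** 2))
        return out

    res = lmfit.minimize(lambda p: y - model(p), params,
                         method="least_squares")
    if not res.success:
        raise RuntimeError("carbonyl band decomposition did not converge")
    p = res.params
    comps = sorted(
        ((p[f"c_{t}"].value, p[f"s_{t}"].value, p[f"a_{t}"].value)
         for t in ("high", "low")),
        key=lambda c: c[0])
    (cl, sl, al), (ch, sh, ah) = comps
    area_l, area_h = al * sl, ah * sh  # common √(2π) cancels in the ratio
    total = area_l + area_h
    f = float(area_l / total) if total > 0 else 0.0
    return CarbonylDecomposition(
        center_high=float(ch), center_low=float(cl),
        width_high=float(sh), width_low=float(sl),
        amp_high=float(ah), amp_low=float(al), f_hbond=f)


def _aicc(rss, n, k):
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:  # small-sample correction when defined
        return aic + 2.0 * k * (k + 1) / (n - k - 1)
    return aic


def maximum_vs_temperature(series):
    """Track the carbonyl band maximum across a temperature series.

    Parameters
    ----------
    series
        Iterable of ``(temperature, spectrum)`` pairs (≥ 5 temperatures
        spanning the transition).

    Returns
    -------
    (curve, midpoint, amplitude)
        ``curve`` is the band maximum vs. temperature; a falling logistic
        sigmoid ``ν(T) = ν₀ − Δ·expit((T − T_m)/w)`` is fitted and its
        midpoint ``T_m`` (°C) and drop amplitude Δ (cm⁻¹) returned.  When the
        sigmoid is not supported over a constant by corrected Akaike
        comparison (e.g. a flat series) the midpoint is ``None``.
    """
    pairs = sorted(series, key=lambda ts: ts[0])
    if len(pairs) < 5:
        raise ValueError("need at least 5 temperatures spanning the transition")
    T = np.array([t for t, _ in pairs], dtype=float)
    nu = np.array([band_maximum(s) for _, s in pairs])
    curve = Curve(T, nu, None, {"x_unit": "degC", "y_unit": "1/cm"})

    rss_const = float(np.sum((nu - nu.mean()) ** 2))
    n = nu.size

    grad = np.gradient(nu, T)
    params = lmfit.Parameters()
    params.add("nu0", value=float(nu.max()))
    params.add("drop", value=max(float(np.ptp(nu)), 1e-6), min=0.0)
    params.add("T_m", value=float(T[int(np.argmin(grad))]),
               min=float(T[0] - 5.0), max=float(T[-1] + 5.0))
    params.add("w", value=1.0, min=0.05, max=20.0)

    def resid(p):
        return nu - (p["nu0"].value - p["drop"].value
                     * expit((T - p["T_m"].value) / p["w"].value))

    try:
        res = lmfit.minimize(resid, params, method="least_squares")
        rss_sig = float(np.sum(res.residual**2))
        ok = res.success
    except Exception:  # noqa: BLE001
        ok = False
        rss_sig = np.inf
    if not ok or _aicc(rss_sig, n, 4) >= _aicc(rss_const, n, 1):
        return curve, None, None
    p = res.params
    return curve, float(p["T_m"].value), float(p["drop"].value)
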