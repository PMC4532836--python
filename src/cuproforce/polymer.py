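"""Worm-like chain (WLC) polymer elasticity.

Force-extension curves of unfolded polypeptide are modelled with the
Marko-Siggia interpolation formula

    F(x) = (kT/p) * [ 1/(4 (1 - x/Lc)^2) - 1/4 + x/Lc ],

the standard choice for AFM force-spectroscopy fits, where ``p`` is the
persistence length, ``Lc`` the contour length and ``kT`` the thermal energy.
Units are fixed package-wide: nm, pN, s, K (kT ~ 4.114 pN nm at 298 K).

The contour length is the only free parameter when fitting rising edges of
sawtooth traces; the persistence length is held fixed (default 0.4 nm)
because co-fitting p and Lc on single peaks is ill-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "BOLTZMANN_PN_NM",
    "PolymerModel",
    "wlc_force",
    "wlc_extension",
    "fit_contour_length",
]

#: Boltzmann constant in pN nm / K (1.380649e-23 J/K).
BOLTZMANN_PN_NM = 1.380649e-2

#: Contour length contributed per amino-acid residue, nm.
LENGTH_PER_RESIDUE_NM = 0.38


def thermal_energy(temperature: float) -> float:
    """kT in pN nm for a temperature in kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return BOLTZMANN_PN_NM * temperature


@dataclass(frozen=True)
class PolymerModel:
    """WLC parameter set: contour length, persistence length, temperature.

    Parameters
    ----------
    contour_length : float
        Total contour length Lc of the stretched segment, nm. Must be > 0.
    persistence_length : float, default 0.4
        Persistence length p, nm. Must be > 0. 0.4 nm is the conventional
        value for unfolded polypeptide in AFM work.
    temperature : float, default 298.0
        Absolute temperature, K.
    """

    contour_length: float
    persistence_length: float = 0.4
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.contour_length <= 0:
            raise ValueError(f"contour_length must be > 0, got {self.contour_length}")
        if self.persistence_length <= 0:
            raise ValueError(
                f"persistence_length must be > 0, got {self.persistence_length}"
            )
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")

    @property
    def kT(self) -> float:
        """Thermal energy, pN nm."""
        return thermal_energy(self.temperature)


def wlc_force(extension, model: PolymerModel):
    """WLC restoring force at a given end-to-end extension.

    Parameters
    ----------
    extension : float or array_like
        End-to-end extension x, nm; must satisfy 0 <= x < Lc.
    model : PolymerModel

    Returns
    -------
    float or ndarray
        Force in pN. Zero at zero extension, strictly increasing,
        diverging as x -> Lc.
    """
    x = np.asarray(extension, dtype=float)
    if np.any(x < 0) or np.any(x >= model.contour_length):
        raise ValueError(
            "extension must lie in [0, contour_length); "
            f"got range [{x.min() if x.size else np.nan}, "
            f"{x.max() if x.size else np.nan}] for Lc={model.contour_length}"
        )
    u = x / model.contour_length
    f = (model.kT / model.persistence_length) * (0.25 / (1.0 - u) ** 2 - 0.25 + u)
    if np.isscalar(extension):
        return float(f)
    return f


def _reduced_force(u: float, model: PolymerModel) -> float:
    return (model.kT / model.persistence_length) * (0.25 / (1.0 - u) ** 2 - 0.25 + u)


def wlc_extension(force, model: PolymerModel):
    """Invert the WLC force law: extension at which the chain bears ``force``.

    Bracketed root finding on x/Lc in [0, 1 - 1e-12], absolute tolerance
    1e-12 in x/Lc, so the forward/inverse round trip holds to ~1e-9 relative.

    Parameters
    ----------
    force : float or array_like
        Tension in pN, must be >= 0.
    model : PolymerModel

    Returns
    -------
    float or ndarray
        Extension in nm, in [0, contour_length).
    """
    f_arr = np.atleast_1d(np.asarray(force, dtype=float))
    if np.any(f_arr < 0):
        raise ValueError("force must be >= 0")
    hi = 1.0 - 1e-12
    out = np.empty_like(f_arr)
    f_hi = _reduced_force(hi, model)
    for i, f in enumerate(f_arr):
        if f == 0.0:
            out[i] = 0.0
        elif f >= f_hi:
            out[i] = hi * model.contour_length
        else:
            u = brentq(
                lambda u_: _reduced_force(u_, model) - f,
                0.0,
                hi,
                xtol=1e-12,
                rtol=8.9e-16,
            )
            out[i] = u * model.contour_length
    if np.isscalar(force):
        return float(out[0])
    return out


def fit_contour_length(
    points,
    persistence_length: float = 0.4,
    temperature: float = 298.0,
    max_contour_factor: float = 100.0,
) -> tuple[float, float]:
    """Least-squares estimate of the contour length from (extension, force) points.

    The persistence length is held fixed; only Lc is optimised, by bounded
    scalar minimisation of the sum of squared force residuals on
    Lc in (max(x), max_contour_factor * max(x)).

    Parameters
    ----------
    points : array_like, shape (n, 2)
        Columns (extension nm, force pN); n >= 3, all forces > 0.
    persistence_length, temperature : float
        Fixed WLC parameters.
    max_contour_factor : float
        Upper search bound for Lc as a multiple of the largest extension.

    Returns
    -------
    (contour_length_estimate, residual)
        Lc in nm and the root-mean-square force residual in pN.

    Raises
    ------
    ValueError
        Fewer than 3 points, or non-positive forces/extensions.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (extension, force) points")
    x, f = pts[:, 0], pts[:, 1]
    if np.any(f <= 0):
        raise ValueError("all forces must be positive")
    if np.any(x <= 0):
        raise ValueError("all extensions must be positive")
    x_max = float(x.max())
    lo = x_max * (1.0 + 1e-10)
    hi = x_max * max_contour_factor

    def sse(lc: float) -> float:
        model = PolymerModel(lc, persistence_length, temperature)
        return float(np.sum((wlc_force(x, model) - f) ** 2))

    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-9})
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise ValueError(f"contour-length fit failed: {res.message}")
    lc_hat = float(res.x)
    rms = float(np.sqrt(sse(lc_hat) / len(f)))
    return lc_hat, rms
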