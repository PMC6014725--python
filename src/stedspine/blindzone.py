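"""Geometric blind-zone model: hidden spine fraction and density correction.

A microscope whose resolution improves only laterally leaves spines that
point along the optical axis undetected: their projection does not clear
the dendritic shaft silhouette by the counting threshold d_min. For a
spine of length L on a shaft of radius R at azimuth phi (0 = optical
axis), the projected protrusion is e = (R + L)|sin phi| - R, so the spine
is hidden whenever |sin phi| < (R + d_min) / (R + L). With azimuths
uniform on [0, 2*pi), the hidden fraction is

    f = (2 / pi) * arcsin(min(1, (R + d_min) / (R + L)))

and the measured linear density underestimates the true 3-D density by the
factor (1 - f); dividing by it extrapolates the full density. With the
default anatomy (R = 0.35 um, L = 1.0 um, d_min = 0.2 um) about a quarter
of spines (f ~ 0.267) fall in the blind zone, lifting a measured
2.13 spines/um to ~2.91 spines/um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._rng import as_rng
from .observer import lateral_protrusion


def critical_azimuth(R: float, L: float, d_min: float,
                     lateral_fwhm: float = 0.0) -> float:
    """Azimuth (rad, measured from the optical axis) below which a spine
    of length L is hidden. ``lateral_fwhm`` > 0 enables the model variant
    that adds half the PSF width to the shaft silhouette."""
    if R <= 0 or L <= 0:
        raise ValueError("R and L must be positive")
    if d_min < 0:
        raise ValueError("d_min must be non-negative")
    arg = (R + d_min + lateral_fwhm / 2.0) / (R + L)
    return float(np.arcsin(min(1.0, arg)))


def hidden_fraction(R: float, L: float, d_min: float,
                    lateral_fwhm: float = 0.0) -> float:
    """Fraction of azimuthally uniform spines inside the blind zone."""
    return float(np.clip(2.0 / np.pi * critical_azimuth(R, L, d_min,
                                                        lateral_fwhm), 0.0, 1.0))


def hidden_fraction_lognormal(
    R: float,
    d_min: float,
    length_median: float,
    length_sigma: float,
    n_nodes: int = 512,
    lateral_fwhm: float = 0.0,
) -> float:
    """Hidden fraction averaged over a lognormal spine-length distribution.

    Midpoint quadrature on the probability scale: lengths at the quantile
    nodes of LogNormal(ln median, sigma), f averaged across nodes.
    """
    q = (np.arange(n_nodes) + 0.5) / n_nodes
    lengths = length_median * np.exp(length_sigma * stats.norm.ppf(q))
    fs = [hidden_fraction(R, float(L), d_min, lateral_fwhm) for L in lengths]
    return float(np.mean(fs))


def monte_carlo_hidden_fraction(
    R: float,
    L: float,
    d_min: float,
    n_samples: int = 1_000_000,
    seed=None,
) -> float:
    """Monte-Carlo oracle for :func:`hidden_fraction`.

    Samples azimuths uniformly and applies the observer's protrusion
    criterion directly; standard error ~ sqrt(f (1-f) / n).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if R <= 0 or L <= 0:
        raise ValueError("R and L must be positive")
    rng = as_rng(seed, "blindzone-mc")
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_samples)
    hidden = lateral_protrusion(R, L, phi) < d_min
    return float(hidden.mean())


def corrected_density(measured_density: float, f: float) -> float:
    """Extrapolate a measured linear spine density to 3-D.

    Divides by the visible fraction (1 - f); undefined at f = 1 where
    nothing is visible.
    """
    if measured_density < 0:
        raise ValueError("measured_density must be non-negative")
    if not 0.0 <= f < 1.0:
        raise ValueError("hidden fraction must lie in [0, 1)")
    return measured_density / (1.0 - f)


@dataclass
class BlindZoneModel:
    """Bundled model parameters with derived quantities.

    Defaults reproduce the in vivo correction: f ~ 0.267, 2.13 -> 2.91
    spines/um.
    """

    R: float = 0.35
    L: float = 1.0
    d_min: float = 0.2
    lateral_fwhm: float = 0.0

    @property
    def phi_c(self) -> float:
        return critical_azimuth(self.R, self.L, self.d_min, self.lateral_fwhm)

    @property
    def f(self) -> float:
        return hidden_fraction(self.R, self.L, self.d_min, self.lateral_fwhm)

    def correct(self, measured_density: float) -> float:
        return corrected_density(measured_density, self.f)

    def to_dict(self) -> dict:
        return {
            "R_um": self.R,
            "L_um": self.L,
            "d_min_um": self.d_min,
            "lateral_fwhm_um": self.lateral_fwhm,
            "phi_c_rad": self.phi_c,
            "hidden_fraction": self.f,
        }


def parameter_sweep(R_values, L_values, d_min_values):
    """Hidden fraction over a parameter grid; rows of (R, L, d_min, f)."""
    import pandas as pd

    rows = [
        {"R_um": R, "L_um": L, "d_min_um": d, "hidden_fraction": hidden_fraction(R, L, d)}
        for R in R_values
        for L in L_values
        for d in d_min_values
    ]
    return pd.DataFrame(rows)
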