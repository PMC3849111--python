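"""Power functions, preferred frequency Omega0 and gap-junction-location
sweeps.

The power function of a response is P(Omega) = |Ghat(Omega)|^2 with the
Laplace variable evaluated on the positive real axis (Omega in rad/ms);
its maximiser Omega0 is the preferred (resonant) frequency of the
response at the chosen observation/stimulus pair.

Why the real axis: for resonant membrane the admittance of the inductive
pathway, 1/(r + Omega*L), decays with Omega while the capacitive term
grows, so gamma(Omega) -- and with it every factor of the response --
has an interior extremum at Omega* = sqrt(1/(L*C)) - r/L (per-area
constants). Because each segment's transform is a function of
gamma(Omega) alone on the infinite-cable network, Omega0 is *exactly* the
same on every segment and independent of the coupling resistance there;
once lumped somata enter (whose admittance has its own frequency
dependence) Omega0 becomes location- and coupling-dependent, which is
what the gap-junction-location sweeps map out. Passive membrane gives a
monotone (low-pass) P with its maximum at the lower search bound. All
kernel poles lie on the negative real axis, so Omega >= 0 is always safe
to evaluate on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from dendrogap.closed_forms import TwoSomaConfig, word_series_ghat

__all__ = [
    "PowerSpectrum",
    "BoundaryMaximumWarning",
    "power_function",
    "find_omega0",
    "sweep_gj_location",
]

DEFAULT_INTERVAL = (1e-3, 5.0)
COARSE_STEP = 0.005
REFINE_XTOL = 1e-5


class BoundaryMaximumWarning(UserWarning):
    """The power maximum sits at the search-interval boundary (e.g. the
    low-pass Omega0 = 0 of purely passive membrane)."""


@dataclass(frozen=True)
class PowerSpectrum:
    omega: np.ndarray  # rad/ms
    P: np.ndarray
    normalised: bool

    def normalise(self) -> "PowerSpectrum":
        return PowerSpectrum(self.omega, self.P / np.max(self.P), True)


def power_function(ghat, omega_grid, normalised: bool = False) -> PowerSpectrum:
    """Evaluate P(Omega) = |ghat(Omega)|^2 on a real frequency grid."""
    omega_grid = np.asarray(omega_grid, dtype=float)
    P = np.abs(ghat(omega_grid + 0.0j)) ** 2
    spec = PowerSpectrum(omega_grid, P, False)
    return spec.normalise() if normalised else spec


def find_omega0(
    ghat,
    interval: tuple[float, float] = DEFAULT_INTERVAL,
    coarse_step: float = COARSE_STEP,
    xtol: float = REFINE_XTOL,
) -> float:
    """Preferred frequency Omega0 = argmax_Omega |ghat(Omega)|^2 over
    real Omega.

    Coarse grid scan (step ``coarse_step`` rad/ms) followed by bounded
    golden-section refinement to ``xtol``. Ties break toward the smallest
    maximiser; a maximum at the interval boundary issues
    :class:`BoundaryMaximumWarning` and returns the boundary value.
    """
    lo, hi = interval
    grid = np.arange(lo, hi + coarse_step / 2, coarse_step)
    P = np.abs(ghat(grid + 0.0j)) ** 2
    i = int(np.argmax(P))  # argmax returns the first (smallest) maximiser
    if i == 0 or i == grid.size - 1:
        warnings.warn(
            f"power maximum at the search boundary Omega = {grid[i]:g} rad/ms "
            "(no interior resonance peak)",
            BoundaryMaximumWarning,
            stacklevel=2,
        )
        return float(grid[i])
    res = minimize_scalar(
        lambda om: -abs(ghat(complex(om))) ** 2,
        bracket=(grid[i - 1], grid[i], grid[i + 1]),
        method="golden",
        options={"xtol": xtol},
    )
    return float(res.x)


def sweep_gj_location(
    base: TwoSomaConfig,
    L_GJ_values,
    R_GJ_values,
    y0_offset: float = 10.0,
    n_max: int = 20,
    interval: tuple[float, float] = DEFAULT_INTERVAL,
) -> pd.DataFrame:
    """Somatic Omega0 of each cell as the gap junction moves along the
    dendrite.

    For every (L_GJ, R_GJ) combination the two-cell configuration is
    rebuilt with the stimulus at y0 = L_GJ + y0_offset um, the somatic
    word-series response functions are formed (series truncated at
    ``n_max``), and Omega0 is located for each cell. Returns a tidy frame
    with columns cell, L_GJ_um, R_GJ_MOhm, omega0_rad_per_ms.
    """
    rows = []
    for R in R_GJ_values:
        for L in L_GJ_values:
            cfg = TwoSomaConfig(
                params=base.params,
                soma=base.soma,
                N=base.N,
                L_GJ=float(L),
                R_GJ=float(R),
                y0=float(L) + y0_offset,
            )
            for cell in (1, 2):
                ghat = lambda w, c=cell: word_series_ghat(cfg, c, 0.0, w, n_max=n_max)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", BoundaryMaximumWarning)
                    om0 = find_omega0(ghat, interval=interval)
                rows.append(
                    {
                        "cell": cell,
                        "L_GJ_um": float(L),
                        "R_GJ_MOhm": float(R),
                        "omega0_rad_per_ms": om0,
                    }
                )
    return pd.DataFrame(rows)
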