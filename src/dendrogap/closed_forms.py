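"""Closed-form response functions for the two-cell configurations.

Covers, in the Laplace domain, the two infinite-cable cells coupled by one
gap junction (identical and heterogeneous parameter sets) and the
word-series (geometrically resummed trip classes) for two soma-and-N-
dendrites cells coupled at distance L_GJ from each soma; and, in the time
domain, the fully analytic passive-membrane solutions (impulse responses
and rectangular-pulse responses) that serve as oracles for the numerical
inverse Laplace transform.

Conventions: every Ghat carries the prefactor 1/(c_j * D_j * gamma_j) of
the stimulated branch (c_j = capacitance per unit length, nF/um), matching
the trips engine, so frequency- and time-domain functions are mV per
nA*ms impulse and mV per nA drive respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfcx

from dendrogap import _backend

from dendrogap.kernels import char_admittance, gamma, gamma_soma, p_gj_identical
from dendrogap.network_model import MembraneParams, NetworkError, SomaParams

__all__ = [
    "TwoCellInfiniteConfig",
    "TwoSomaConfig",
    "two_cell_ghat",
    "word_series_ghat",
    "passive_F",
    "passive_infinite_G",
    "passive_two_cell_G",
    "passive_rect_response",
    "SEGMENTS",
]

SEGMENTS = ("m-", "m+", "n-", "n+")


@dataclass(frozen=True)
class TwoCellInfiniteConfig:
    """Two infinite dendritic cables coupled by one gap junction at x=0,
    which splits them into four semi-infinite segments m-, m+, n-, n+.
    The stimulus sits on segment m- at distance y from the junction."""

    params_m: MembraneParams
    params_n: MembraneParams
    R_GJ: float

    @property
    def identical(self) -> bool:
        return self.params_m == self.params_n

    def p_gj_mn(self, omega) -> tuple[np.ndarray, np.ndarray]:
        zm = char_admittance(self.params_m, omega)
        zn = char_admittance(self.params_n, omega)
        den = zm + zn + 2.0 * self.R_GJ * zm * zn
        return zm / den, zn / den


def two_cell_ghat(config: TwoCellInfiniteConfig, segment: str, x, y, omega) -> np.ndarray:
    """Laplace-domain Green's function on one of the four segments, for a
    stimulus at y >= 0 on segment m- and observation at x >= 0 on
    ``segment`` (both measured from the gap junction).

    Identical cells:
        Ghat_m- = (1/c)[Ghat_inf(x-y) - p_GJ * Ghat_inf(x+y)]
        Ghat_m+ = (1/c)(1 - p_GJ) Ghat_inf(x+y)
        Ghat_n+- = (1/c) p_GJ Ghat_inf(x+y)
    Heterogeneous cells use p_GJ,m / p_GJ,n and the mixed exponent
    gamma_n*x + gamma_m*y on the far cell.
    """
    if segment not in SEGMENTS:
        raise NetworkError(f"segment must be one of {SEGMENTS}, got {segment!r}")
    pm = config.params_m
    gm = gamma(pm, omega)
    pref = 1.0 / (pm.c_len * 2.0 * pm.D * gm)
    p_gj_m, p_gj_n = config.p_gj_mn(omega)
    exp = _backend.exp
    if segment == "m-":
        return pref * (exp(-gm * abs(x - y)) - p_gj_n * exp(-gm * (x + y)))
    if segment == "m+":
        return pref * (1.0 - p_gj_n) * exp(-gm * (x + y))
    gn = gamma(config.params_n, omega)
    return pref * p_gj_m * exp(-(gn * x + gm * y))


@dataclass(frozen=True)
class TwoSomaConfig:
    """Two identical cells, each a lumped soma with N semi-infinite
    dendrites, coupled by a gap junction at distance L_GJ from each soma
    along one dendrite; the stimulus sits at y0 >= L_GJ (from the soma of
    cell 1) on the gap-junction-bearing dendrite of cell 1."""

    params: MembraneParams
    soma: SomaParams
    N: int
    L_GJ: float
    R_GJ: float
    y0: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise NetworkError("N must be >= 1")
        if not (self.L_GJ > 0):
            raise NetworkError("L_GJ must be > 0")
        if self.y0 < self.L_GJ:
            raise NetworkError("y0 must lie at or beyond the gap junction (y0 >= L_GJ)")

    def p_s(self, omega) -> np.ndarray:
        """Somatic coefficient for N identical dendrites:
        p_s = z / (N z + gamma_s)."""
        z = char_admittance(self.params, omega)
        return z / (self.N * z + gamma_soma(self.soma, omega))

    def p_gj(self, omega) -> np.ndarray:
        return p_gj_identical(self.params, self.R_GJ, omega)


def word_series_ghat(
    config: TwoSomaConfig,
    cell: int,
    x0: float,
    omega,
    n_max: int = 20,
    y0: float | None = None,
) -> np.ndarray:
    """Word-series Green's function Ghat_cell(x0, y0, omega), truncated at
    series index n_max.

    x0 is the observation point on the soma-to-gap-junction path of
    ``cell`` (0 <= x0 <= L_GJ; x0 = 0 is the soma). cell=1 is the
    stimulated cell (hosting y0), cell=2 the other one:

        Ghat_2 = p_GJ [Ginf(y0-x0) + (2ps-1) Ginf(y0+x0)]
                 + sum_n 2^n (-p_GJ (2ps-1))^{n+1} (2 p_GJ - 1)
                   [Ginf(y0-x0+2(n+1)L) + (2ps-1) Ginf(y0+x0+2(n+1)L)]

    and Ghat_1 likewise with leading factor (1 - p_GJ) and series factor
    (1 - 2 p_GJ). At x0 = 0 both brackets merge with weight 2 p_s, giving
    the somatic response functions.
    """
    if cell not in (1, 2):
        raise NetworkError("cell must be 1 or 2")
    if y0 is None:
        y0 = config.y0
    if not (0.0 <= x0 <= config.L_GJ):
        raise NetworkError(f"x0 must lie in [0, L_GJ], got {x0}")
    p = config.params
    w = _backend.as_omega(omega)
    g = gamma(p, w)
    pgj = config.p_gj(w)
    ps = config.p_s(w)
    rs = 2.0 * ps - 1.0

    def ginf(ell):
        return _backend.exp(-g * ell) / (2.0 * p.D * g)

    bracket0 = ginf(y0 - x0) + rs * ginf(y0 + x0)
    lead = pgj if cell == 2 else (1.0 - pgj)
    sgn = (2.0 * pgj - 1.0) if cell == 2 else (1.0 - 2.0 * pgj)
    total = lead * bracket0
    base = -pgj * rs  # per-shell ratio (times 2 and the geometric lengths)
    term_pref = sgn * base  # n = 0 prefactor (2^0 * base^{0+1})
    for n in range(n_max + 1):
        ell = 2.0 * (n + 1) * config.L_GJ
        total = total + term_pref * (ginf(y0 - x0 + ell) + rs * ginf(y0 + x0 + ell))
        term_pref = term_pref * 2.0 * base
    return total / (p.c_len * 1.0)


# --------------------------------------------------------------------------
# passive-membrane analytic time-domain forms
# --------------------------------------------------------------------------

def _theta(t: np.ndarray) -> np.ndarray:
    return (t > 0).astype(float)


def passive_F(x, t, q: float, params: MembraneParams) -> np.ndarray:
    """Inverse Laplace transform of Fhat(x, omega, q) =
    e^(-gamma|x|) / ((gamma + q) * 2 * D * gamma) for a passive cable:

        F(x, t, q) = 1/2 e^{|x|q} e^{(q^2 D - 1/tau) t}
                     erfc(q sqrt(D t) + |x|/(2 sqrt(D t))) Theta(t)

    computed through the scaled complement erfcx to avoid overflow of the
    exp * erfc product.
    """
    if params.resonant:
        raise NetworkError("passive_F requires passive membrane parameters")
    t = np.asarray(t, dtype=float)
    x = np.abs(x)
    D, tau = params.D, params.tau
    with np.errstate(divide="ignore", invalid="ignore"):
        sq = np.sqrt(D * np.maximum(t, 0.0))
        z = q * sq + np.where(t > 0, x / (2.0 * sq), np.inf)
        damp = np.exp(np.where(t > 0, -t / tau - x**2 / (4.0 * D * t), -np.inf))
        safe = z > -25.0
        out = np.where(
            safe,
            0.5 * damp * erfcx(np.where(safe, z, 0.0)),
            # erfc(z) = 2 - erfc(-z) for very negative z
            np.exp(x * q + (q**2 * D - 1.0 / tau) * np.where(t > 0, t, 0.0))
            - 0.5 * damp * erfcx(np.where(safe, 0.0, -z)),
        )
    return np.where(t > 0, out, 0.0)


def passive_infinite_G(x, t, params: MembraneParams) -> np.ndarray:
    """Impulse response of the passive infinite cable (before the 1/c
    prefactor): G_inf(x,t) = e^{-t/tau} e^{-x^2/(4 D t)} / sqrt(4 pi D t)."""
    t = np.asarray(t, dtype=float)
    D, tau = params.D, params.tau
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.exp(np.where(t > 0, -t / tau - x**2 / (4.0 * D * t), -np.inf)) / np.sqrt(
            4.0 * math.pi * D * np.maximum(t, np.finfo(float).tiny)
        )
    return np.where(t > 0, val, 0.0)


def passive_two_cell_G(
    segment: str, x, y, t, params: MembraneParams, R_GJ: float
) -> np.ndarray:
    """Time-domain Green's function of the identical passive two-cell
    model (stimulus on m-), in mV per nA*ms impulse:

        G_m- = [G_inf(x-y,t) - ra/(2 R_GJ) F(x+y, t, ra/R_GJ)] / c
        G_m+ = [G_inf(x+y,t) - ra/(2 R_GJ) F(x+y, t, ra/R_GJ)] / c
        G_n+- = [ra/(2 R_GJ) F(x+y, t, ra/R_GJ)] / c
    """
    if segment not in SEGMENTS:
        raise NetworkError(f"segment must be one of {SEGMENTS}, got {segment!r}")
    q = params.ra / R_GJ
    coupling = (params.ra / (2.0 * R_GJ)) * passive_F(x + y, t, q, params)
    if segment == "m-":
        val = passive_infinite_G(x - y, t, params) - coupling
    elif segment == "m+":
        val = passive_infinite_G(x + y, t, params) - coupling
    else:
        val = coupling
    return val / params.c_len


def _rect_B(x, t, eta0: float, params: MembraneParams) -> np.ndarray:
    """Step-onset response of the infinite passive cable:
    B(x,t) = eta0/(4 sqrt(D/tau)) [e^{-|x|eps} erfc(|x|/(2 sqrt(Dt)) - sqrt(t/tau))
             - e^{+|x|eps} erfc(|x|/(2 sqrt(Dt)) + sqrt(t/tau))] Theta(t),
    eps = 1/sqrt(D tau)."""
    t = np.asarray(t, dtype=float)
    x = np.abs(x)
    D, tau = params.D, params.tau
    eps = 1.0 / math.sqrt(D * tau)
    with np.errstate(divide="ignore", invalid="ignore"):
        sq = np.sqrt(D * np.maximum(t, 0.0))
        u = np.where(t > 0, x / (2.0 * sq), np.inf)
        v = np.sqrt(np.maximum(t, 0.0) / tau)
        damp = np.exp(np.where(t > 0, -t / tau - x**2 / (4.0 * D * t), -np.inf))
        z1, z2 = u - v, u + v
        safe = z1 > -25.0
        term = np.where(
            safe,
            damp * (erfcx(np.where(safe, z1, 0.0)) - erfcx(z2)),
            2.0 * np.exp(-x * eps)
            - damp * (erfcx(np.where(safe, 0.0, -z1)) + erfcx(z2)),
        )
    return np.where(t > 0, (eta0 / (4.0 * math.sqrt(D / tau))) * term, 0.0)


def _rect_P(x, t, eta0: float, params: MembraneParams, R_GJ: float) -> np.ndarray:
    """Gap-junction term of the rectangular-pulse response (onset part):
    P(x,t) = eta0 ra/(2 D R_GJ) [a F(x,t,q) + b F(x,t,eps) + c F(x,t,-eps)]
    with q = ra/R_GJ, eps = 1/sqrt(D tau) and partial-fraction weights
    a = 1/(q^2 - eps^2), b = 1/(2 eps (eps - q)), c = 1/(2 eps (eps + q)).
    """
    D, tau = params.D, params.tau
    q = params.ra / R_GJ
    eps = 1.0 / math.sqrt(D * tau)
    if math.isclose(q, eps, rel_tol=1e-9):
        raise NetworkError(
            "degenerate coupling ra/R_GJ == 1/sqrt(D*tau): the partial-fraction "
            "coefficients are singular; perturb R_GJ slightly"
        )
    a = 1.0 / (q**2 - eps**2)
    b = 1.0 / (2.0 * eps * (eps - q))
    c = 1.0 / (2.0 * eps * (eps + q))
    pref = eta0 * params.ra / (2.0 * D * R_GJ)
    return pref * (
        a * passive_F(x, t, q, params)
        + b * passive_F(x, t, eps, params)
        + c * passive_F(x, t, -eps, params)
    )


def _B_transient(x, t, eta0: float, params: MembraneParams) -> np.ndarray:
    """beta(x,t) = B_infinity(x) - B(x,t), the decaying remainder of the
    step response:
    beta = eta0/(4 sqrt(D/tau)) e^{-t/tau - x^2/(4Dt)} [erfcx(v-u) + erfcx(v+u)]
    with u = |x|/(2 sqrt(Dt)), v = sqrt(t/tau). Stable for all t > 0."""
    t = np.asarray(t, dtype=float)
    x = np.abs(x)
    D, tau = params.D, params.tau
    eps = 1.0 / math.sqrt(D * tau)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(t > 0, x / (2.0 * np.sqrt(D * np.abs(t))), np.inf)
        v = np.sqrt(np.maximum(t, 0.0) / tau)
        damp = np.exp(np.where(t > 0, -t / tau - x**2 / (4.0 * D * t), -np.inf))
        z = v - u
        safe = z > -25.0
        term = np.where(
            safe,
            damp * (erfcx(np.where(safe, z, 0.0)) + erfcx(v + u)),
            2.0 * np.exp(-x * eps)
            - damp * (erfcx(np.where(safe, 0.0, -z)) - erfcx(v + u)),
        )
    return np.where(t > 0, (eta0 / (4.0 * math.sqrt(D / tau))) * term, 0.0)


def _F_transient_neg_eps(x, t, params: MembraneParams) -> np.ndarray:
    """F(x,t,-eps) - e^{-|x| eps} Theta(t), the decaying remainder of the
    only non-vanishing F term: -1/2 e^{-t/tau - x^2/(4Dt)} erfcx(v - u)."""
    t = np.asarray(t, dtype=float)
    x = np.abs(x)
    D, tau = params.D, params.tau
    eps = 1.0 / math.sqrt(D * tau)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(t > 0, x / (2.0 * np.sqrt(D * np.abs(t))), np.inf)
        v = np.sqrt(np.maximum(t, 0.0) / tau)
        damp = np.exp(np.where(t > 0, -t / tau - x**2 / (4.0 * D * t), -np.inf))
        z = v - u
        safe = z > -25.0
        term = np.where(
            safe,
            -0.5 * damp * erfcx(np.where(safe, z, 0.0)),
            -np.exp(-x * eps) + 0.5 * damp * erfcx(np.where(safe, 0.0, -z)),
        )
    return np.where(t > 0, term, 0.0)


def _rect_B_diff(x, t, eta0: float, tau_R: float, params: MembraneParams) -> np.ndarray:
    """B(x,t) - B(x,t-tau_R) without loss of accuracy: for t > tau_R the
    steady parts cancel exactly and only the transients are subtracted."""
    t = np.asarray(t, dtype=float)
    onset = _rect_B(x, t, eta0, params)
    tail = _B_transient(x, t - tau_R, eta0, params) - _B_transient(x, t, eta0, params)
    return np.where(t <= tau_R, onset, tail)


def _rect_P_diff(
    x, t, eta0: float, tau_R: float, params: MembraneParams, R_GJ: float
) -> np.ndarray:
    """P(x,t) - P(x,t-tau_R), cancelling the steady part of the
    F(x,t,-eps) term analytically for t > tau_R."""
    D, tau = params.D, params.tau
    q = params.ra / R_GJ
    eps = 1.0 / math.sqrt(D * tau)
    if math.isclose(q, eps, rel_tol=1e-9):
        raise NetworkError(
            "degenerate coupling ra/R_GJ == 1/sqrt(D*tau): the partial-fraction "
            "coefficients are singular; perturb R_GJ slightly"
        )
    a = 1.0 / (q**2 - eps**2)
    b = 1.0 / (2.0 * eps * (eps - q))
    c = 1.0 / (2.0 * eps * (eps + q))
    pref = eta0 * params.ra / (2.0 * D * R_GJ)
    t = np.asarray(t, dtype=float)
    onset = _rect_P(x, t, eta0, params, R_GJ)
    tail = pref * (
        a * (passive_F(x, t, q, params) - passive_F(x, t - tau_R, q, params))
        + b * (passive_F(x, t, eps, params) - passive_F(x, t - tau_R, eps, params))
        + c * (_F_transient_neg_eps(x, t, params) - _F_transient_neg_eps(x, t - tau_R, params))
    )
    return np.where(t <= tau_R, onset, tail)


def passive_rect_response(
    segment: str,
    x,
    y,
    t,
    params: MembraneParams,
    R_GJ: float,
    eta0: float,
    tau_R: float,
) -> np.ndarray:
    """Voltage response (mV) of the identical passive two-cell model to a
    rectangular current pulse of strength eta0 (nA) and duration tau_R (ms)
    applied at y on segment m-."""
    if segment not in SEGMENTS:
        raise NetworkError(f"segment must be one of {SEGMENTS}, got {segment!r}")
    if not (tau_R > 0):
        raise NetworkError("tau_R must be > 0")
    t = np.asarray(t, dtype=float)
    P = _rect_P_diff(x + y, t, eta0, tau_R, params, R_GJ)
    if segment == "m-":
        val = _rect_B_diff(x - y, t, eta0, tau_R, params) - P
    elif segment == "m+":
        val = _rect_B_diff(x + y, t, eta0, tau_R, params) - P
    else:
        val = P
    return val / params.c_len
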