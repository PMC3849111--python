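"""Frequency-domain scalar kernels.

Everything here is a pure function of membrane/soma parameters and the
complex Laplace variable omega (units 1/ms). The central objects are

* ``gamma(params, omega)`` -- the spatial decay rate of a cable,
  gamma^2 = (1/tau + omega + (1/C)/(r + omega*L)) / D for resonant
  membrane and (1/tau + omega)/D in the passive limit r -> infinity;
* ``z = gamma/ra`` -- the characteristic (input) admittance of a
  semi-infinite cable, MOhm^-1;
* the node coefficients p (branch point), p_s (lumped soma) and
  p_GJ,m / p_GJ,n (gap junction) from which every trip coefficient is
  built.

All functions broadcast over numpy arrays of omega. The square root branch
is the principal one, flipped where necessary so that Re gamma >= 0
(decaying solutions); kernel poles (the inductive pathways' poles on the
negative real axis) raise :class:`PoleError` when hit exactly.
"""

from __future__ import annotations

import numpy as np

from dendrogap import _backend
from dendrogap.network_model import (
    GAP_JUNCTION,
    SOMA,
    BRANCH_POINT,
    MembraneParams,
    Network,
    Node,
    SomaParams,
)

__all__ = [
    "PoleError",
    "gamma",
    "gamma_squared",
    "ghat_infinite",
    "char_admittance",
    "gamma_soma",
    "p_branch",
    "p_soma",
    "p_gj_pair",
    "FrequencyKernelSet",
]


class PoleError(ArithmeticError):
    """Kernel evaluated exactly at a pole of an inductive pathway."""


def _asarray(omega):
    return _backend.as_omega(omega)


def gamma_squared(params: MembraneParams, omega) -> np.ndarray:
    w = _asarray(omega)
    g2 = 1.0 / params.tau + w
    if params.resonant:
        den = params.r_area + w * params.L_area
        if np.any(den == 0):
            raise PoleError(
                f"gamma evaluated at the inductive pole omega = {params.pole:g} 1/ms"
            )
        g2 = g2 + 1.0 / (params.C_area * den)
    return g2 * (1.0 / params.D)


def gamma(params: MembraneParams, omega) -> np.ndarray:
    """Cable decay rate gamma(omega) in 1/um, with Re gamma >= 0."""
    return _backend.positive_real_sqrt(gamma_squared(params, omega))


def ghat_infinite(params: MembraneParams, x, omega) -> np.ndarray:
    """Laplace-domain Green's function of the infinite cable,
    e^(-gamma|x|) / (2*D*gamma). Even in x. Units: ms/um per unit of the
    injected delta (the 1/c capacitance prefactor is applied by callers)."""
    g = gamma(params, omega)
    return _backend.exp(-g * abs(x)) / (2.0 * params.D * g)


def char_admittance(params: MembraneParams, omega) -> np.ndarray:
    """z(omega) = gamma/ra, the input admittance of a semi-infinite cable
    (MOhm^-1)."""
    return gamma(params, omega) / params.ra


def gamma_soma(soma: SomaParams, omega) -> np.ndarray:
    """Absolute somatic admittance (MOhm^-1):
    gamma_s = Cs*omega + 1/Rs + 1/(rs + Ls*omega), with the specific
    constants scaled by the soma membrane area pi*a_s^2. The inductive term
    is dropped for a passive soma."""
    w = _asarray(omega)
    g = soma.Cs_abs * w + 1.0 / soma.Rs_abs
    if soma.resonant:
        den = soma.rs_abs + soma.Ls_abs * w
        if np.any(den == 0):
            raise PoleError(
                f"soma admittance evaluated at its inductive pole omega = {soma.pole:g} 1/ms"
            )
        g = g + 1.0 / den
    return g


def _incident_params(network: Network, node_id: str) -> list[tuple[str, MembraneParams]]:
    return [(b, network.branches[b].params) for b, _ in network.incident_ends(node_id)]


def p_branch(network: Network, node_id: str, k: str, omega) -> np.ndarray:
    """Branch-point coefficient p_k = z_k / sum_n z_n over the branches
    incident to the node."""
    node = network.nodes[node_id]
    if node.kind != BRANCH_POINT:
        raise ValueError(f"node {node_id!r} is not a branch point")
    incident = _incident_params(network, node_id)
    if k not in {b for b, _ in incident}:
        raise ValueError(f"branch {k!r} is not incident to node {node_id!r}")
    total = sum(char_admittance(p, omega) for _, p in incident)
    return char_admittance(network.branches[k].params, omega) / total


def p_soma(network: Network, node_id: str, k: str, omega) -> np.ndarray:
    """Somatic coefficient p_s,k = z_k / (sum_n z_n + gamma_s)."""
    node = network.nodes[node_id]
    if node.kind != SOMA:
        raise ValueError(f"node {node_id!r} is not a soma")
    incident = _incident_params(network, node_id)
    if k not in {b for b, _ in incident}:
        raise ValueError(f"branch {k!r} is not incident to node {node_id!r}")
    total = sum(char_admittance(p, omega) for _, p in incident)
    return char_admittance(network.branches[k].params, omega) / (
        total + gamma_soma(node.soma, omega)
    )


def p_gj_pair(network: Network, node_id: str, omega) -> tuple[np.ndarray, np.ndarray]:
    """Gap-junction coefficients (p_GJ,m, p_GJ,n) for the node's two host
    dendrites (in pairing order):

        p_GJ,m = z_m / (z_m + z_n + 2*R_GJ*z_m*z_n)

    and symmetrically for n. For identical cables both reduce to
    1/(2*(z*R_GJ + 1)).
    """
    node = network.nodes[node_id]
    if node.kind != GAP_JUNCTION:
        raise ValueError(f"node {node_id!r} is not a gap junction")
    zm = char_admittance(network.branches[node.pairing[0][0][0]].params, omega)
    zn = char_admittance(network.branches[node.pairing[1][0][0]].params, omega)
    den = zm + zn + 2.0 * node.R_GJ * zm * zn
    return zm / den, zn / den


def p_gj_identical(params: MembraneParams, R_GJ: float, omega) -> np.ndarray:
    """p_GJ = 1/(2*(z*R_GJ + 1)) for two identical cables."""
    return 1.0 / (2.0 * (char_admittance(params, omega) * R_GJ + 1.0))


class FrequencyKernelSet:
    """Per-network cache of kernel evaluations at one omega (scalar or
    array).

    Exposes ``gamma_of(branch_id)``, ``z_of(branch_id)`` and the node
    coefficient lookups used by the trips engine; values are computed once
    per distinct parameter set per omega batch.
    """

    def __init__(self, network: Network, omega):
        self.network = network
        self.omega = _asarray(omega)
        self._gamma: dict[MembraneParams, np.ndarray] = {}
        self._z: dict[MembraneParams, np.ndarray] = {}
        self._soma: dict[str, np.ndarray] = {}
        self._gj: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def gamma_params(self, params: MembraneParams) -> np.ndarray:
        if params not in self._gamma:
            self._gamma[params] = gamma(params, self.omega)
        return self._gamma[params]

    def gamma_of(self, branch_id: str) -> np.ndarray:
        return self.gamma_params(self.network.branches[branch_id].params)

    def z_of(self, branch_id: str) -> np.ndarray:
        params = self.network.branches[branch_id].params
        if params not in self._z:
            self._z[params] = self.gamma_params(params) / params.ra
        return self._z[params]

    def soma_admittance(self, node: Node) -> np.ndarray:
        if node.id not in self._soma:
            self._soma[node.id] = gamma_soma(node.soma, self.omega)
        return self._soma[node.id]

    def gj_pair(self, node: Node) -> tuple[np.ndarray, np.ndarray]:
        if node.id not in self._gj:
            self._gj[node.id] = p_gj_pair(self.network, node.id, self.omega)
        return self._gj[node.id]
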