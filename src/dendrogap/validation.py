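"""Boundary-condition residual operators and random-network generation.

The sum-over-trips Green's function must satisfy, in the Laplace domain,
value continuity and current balance at every node: Kirchhoff sums
weighted by 1/ra at branch points, the somatic admittance condition
gamma_s * Ghat_s = sum_j (1/ra_j) dGhat_j/dx at somata, sealed/zero
conditions at terminals, and at gap junctions continuity along each host
dendrite plus the junction-current balance

    (1/ra_m)(dG_m-/dx + dG_m+/dx)|_0 = g_GJ (G_m(0) - G_n(0)),   g_GJ = 1/R_GJ

(x measured outward from the node on each segment). These operators
evaluate the truncated trips-engine solution near a node with one-sided
finite-difference derivatives (3-point, Richardson-extrapolated once) and
report the residuals relative to the local solution scale: an independent
numerical check that the engine's node factors implement the cable
boundary conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from dendrogap.kernels import FrequencyKernelSet
from dendrogap.network_model import (
    BRANCH_POINT,
    GAP_JUNCTION,
    SOMA,
    TERMINAL_CLOSED,
    TERMINAL_OPEN,
    Network,
    NetworkError,
    PointLocation,
    build_network,
)
from dendrogap.trips_engine import GreensEvaluator

__all__ = [
    "ResidualReport",
    "gj_boundary_residual",
    "soma_branch_residuals",
    "network_residual_suite",
    "random_network",
    "random_network_config",
]


@dataclass(frozen=True)
class ResidualReport:
    node_id: str
    residual_type: str  # "value_continuity" | "current_balance" | "terminal"
    residual: float  # relative magnitude
    omega: complex


def _outward_profile(
    network: Network,
    branch_id: str,
    end: str,
    y: PointLocation,
    omega,
    offsets: np.ndarray,
    tol: float,
):
    """Ghat at distances ``offsets`` (um) from the (branch, end) node,
    measured outward into the branch. Returns array (len(offsets), n_omega).
    """
    b = network.branches[branch_id]
    # enumerate from the innermost sample: at the node itself the value can
    # vanish identically (open terminal), which would starve the relative
    # truncation test; from inside, the node value follows by offset shift
    ref = float(offsets[-1])
    if end == "prox":
        x0 = ref
        rel = offsets - ref
    else:
        x0 = b.length - ref
        rel = ref - offsets
    ev = GreensEvaluator(network, PointLocation(branch_id, x0), y)
    return ev.evaluate(np.asarray(omega, dtype=complex), tol=tol, x_offsets=rel)


_H = 1e-2  # base finite-difference step, um


def _value_and_derivative(profile: np.ndarray, h: float):
    """Node value and outward one-sided derivative from samples at
    [0, h, 2h, 4h]: 3-point one-sided differences at steps h and 2h,
    Richardson-combined once (O(h^3))."""
    g0, g1, g2, g4 = profile
    d_h = (-3.0 * g0 + 4.0 * g1 - g2) / (2.0 * h)
    d_2h = (-3.0 * g0 + 4.0 * g2 - g4) / (4.0 * h)
    return g0, (4.0 * d_h - d_2h) / 3.0


def gj_boundary_residual(
    network: Network,
    gj_node_id: str,
    y: PointLocation,
    omega,
    step: float = _H,
    tol: float = 3e-6,
) -> list[ResidualReport]:
    """Continuity and current-balance residuals of the trips-engine
    Green's function at one gap-junction node, for a stimulus at y (which
    must not sit on the node)."""
    node = network.nodes[gj_node_id]
    if node.kind != GAP_JUNCTION:
        raise NetworkError(f"node {gj_node_id!r} is not a gap junction")
    w = np.atleast_1d(np.asarray(omega, dtype=complex))
    offsets = np.array([0.0, step, 2 * step, 4 * step])
    vals, ders, ra = [], [], []
    for pair in node.pairing:
        pv, pd = [], []
        for branch_id, end in pair:
            prof = _outward_profile(network, branch_id, end, y, w, offsets, tol)
            g0, d = _value_and_derivative(prof, step)
            pv.append(g0)
            pd.append(d)
        vals.append(pv)
        ders.append(pd)
        ra.append(network.branches[pair[0][0]].params.ra)
    g_gj = 1.0 / node.R_GJ
    out: list[ResidualReport] = []
    scale_v = max(np.max(np.abs(v)) for pv in vals for v in pv)
    scale_v = max(scale_v, np.finfo(float).tiny)
    for d_idx, pv in enumerate(vals):
        cont = np.abs(pv[0] - pv[1]) / scale_v
        for wi, om in enumerate(w):
            out.append(
                ResidualReport(gj_node_id, "value_continuity", float(cont[wi]), complex(om))
            )
        other = vals[1 - d_idx]
        lhs = (ders[d_idx][0] + ders[d_idx][1]) / ra[d_idx]
        rhs = g_gj * (pv[0] - other[0])
        scale = (
            (np.abs(ders[d_idx][0]) + np.abs(ders[d_idx][1])) / ra[d_idx]
            + g_gj * (np.abs(pv[0]) + np.abs(other[0]))
            + np.finfo(float).tiny
        )
        resid = np.abs(lhs - rhs) / scale
        for wi, om in enumerate(w):
            out.append(
                ResidualReport(gj_node_id, "current_balance", float(resid[wi]), complex(om))
            )
    return out


def soma_branch_residuals(
    network: Network,
    node_id: str,
    y: PointLocation,
    omega,
    step: float = _H,
    tol: float = 3e-6,
) -> list[ResidualReport]:
    """Continuity/Kirchhoff (branch point), somatic-admittance (soma) or
    terminal residuals at a non-GJ node."""
    node = network.nodes[node_id]
    w = np.atleast_1d(np.asarray(omega, dtype=complex))
    offsets = np.array([0.0, step, 2 * step, 4 * step])
    ends = network.incident_ends(node_id)
    vals, ders, ras = [], [], []
    for branch_id, end in ends:
        prof = _outward_profile(network, branch_id, end, y, w, offsets, tol)
        g0, d = _value_and_derivative(prof, step)
        vals.append(g0)
        ders.append(d)
        ras.append(network.branches[branch_id].params.ra)
    out: list[ResidualReport] = []
    if node.kind in (TERMINAL_CLOSED, TERMINAL_OPEN):
        interior = np.abs(vals[0]) + np.abs(ders[0]) * step + np.finfo(float).tiny
        if node.kind == TERMINAL_CLOSED:
            resid = np.abs(ders[0]) / (np.abs(vals[0]) / step + np.finfo(float).tiny)
        else:
            resid = np.abs(vals[0]) / interior
        for wi, om in enumerate(w):
            out.append(ResidualReport(node_id, "terminal", float(resid[wi]), complex(om)))
        return out
    scale_v = max(np.max(np.abs(v)) for v in vals) + np.finfo(float).tiny
    for v in vals[1:]:
        cont = np.abs(v - vals[0]) / scale_v
        for wi, om in enumerate(w):
            out.append(
                ResidualReport(node_id, "value_continuity", float(cont[wi]), complex(om))
            )
    kirchhoff = sum(d / r for d, r in zip(ders, ras))
    scale_k = sum(np.abs(d) / r for d, r in zip(ders, ras)) + np.finfo(float).tiny
    if node.kind == SOMA:
        gs = FrequencyKernelSet(network, w).soma_admittance(node)
        kirchhoff = kirchhoff - gs * vals[0]
        scale_k = scale_k + np.abs(gs * vals[0])
    elif node.kind != BRANCH_POINT:  # pragma: no cover
        raise NetworkError(f"node {node_id!r}: use gj_boundary_residual for gap junctions")
    resid = np.abs(kirchhoff) / scale_k
    for wi, om in enumerate(w):
        out.append(ResidualReport(node_id, "current_balance", float(resid[wi]), complex(om)))
    return out


def network_residual_suite(
    network: Network,
    y: PointLocation,
    omega,
    step: float = _H,
    tol: float = 3e-6,
) -> list[ResidualReport]:
    """Residuals at every node of the network that the stimulus does not
    sit on (the delta source introduces its own derivative jump)."""
    yseg, yloc = None, None
    from dendrogap.network_model import locate

    yseg, yloc = locate(network, y)
    out: list[ResidualReport] = []
    for node in network.nodes.values():
        # skip nodes that coincide with the stimulus point
        skip = False
        for branch_id, end in network.incident_ends(node.id):
            b = network.branches[branch_id]
            at = 0.0 if end == "prox" else b.length
            if branch_id == yseg and abs(yloc - at) < 8 * step:
                skip = True
        if skip:
            continue
        if node.kind == GAP_JUNCTION:
            out.extend(gj_boundary_residual(network, node.id, y, omega, step, tol))
        else:
            out.extend(soma_branch_residuals(network, node.id, y, omega, step, tol))
    return out


# --------------------------------------------------------------------------
# random networks
# --------------------------------------------------------------------------

def _log_uniform(rng: np.random.Generator, centre: float, decades: float) -> float:
    return float(centre * 10.0 ** rng.uniform(-decades, decades))


def random_network_config(seed: int, max_extra_branches: int = 2) -> dict:
    """A reproducible random two-cell network joined by one gap junction.

    Each cell: a soma (randomly passive or resonant), one finite primary
    dendrite that hosts the gap junction at a random interior point, a
    random subtree (up to ``max_extra_branches`` finite child branches
    with random sealed/open terminals) beyond it, and a further
    semi-infinite dendrite at the soma. Electrical parameters are
    log-uniform within half a decade of the reference resonant-dendrite
    values; R_GJ is log-uniform in [1, 1000] MOhm.
    """
    rng = np.random.default_rng(seed)

    def membrane() -> dict:
        resonant = rng.random() < 0.7
        out = {
            "diameter_um": _log_uniform(rng, 2.0, 0.2),
            "C_uF_cm2": 1.0,
            "R_Ohm_cm2": _log_uniform(rng, 2000.0, 0.5),
            "Ra_Ohm_cm": _log_uniform(rng, 100.0, 0.3),
        }
        if resonant:
            out["r_Ohm_cm2"] = _log_uniform(rng, 100.0, 0.5)
            out["L_H_cm2"] = _log_uniform(rng, 5.0, 0.5)
        return out

    def soma() -> dict:
        out = {
            "diameter_um": _log_uniform(rng, 25.0, 0.2),
            "Cs_uF_cm2": 1.0,
            "Rs_Ohm_cm2": _log_uniform(rng, 2000.0, 0.5),
        }
        if rng.random() < 0.5:
            out["rs_Ohm_cm2"] = _log_uniform(rng, 1.0, 0.5)
            out["Ls_H_cm2"] = _log_uniform(rng, 0.1, 0.5)
        return out

    cells = []
    gj_sites = []
    for ci in range(2):
        cid = f"cell{ci}"
        branches = []
        terminals = {}
        primary_len = float(rng.uniform(250.0, 500.0))
        branches.append(
            {"id": "primary", "length_um": primary_len, "parent_node": "soma", **membrane()}
        )
        n_extra = int(rng.integers(0, max_extra_branches + 1))
        for k in range(n_extra):
            bid = f"child{k}"
            if rng.random() < 0.4:
                branches.append(
                    {"id": bid, "length_um": "inf", "parent_node": "primary", **membrane()}
                )
            else:
                branches.append(
                    {
                        "id": bid,
                        "length_um": float(rng.uniform(200.0, 400.0)),
                        "parent_node": "primary",
                        **membrane(),
                    }
                )
                terminals[bid] = "closed" if rng.random() < 0.7 else "open"
        if n_extra == 0:
            terminals["primary"] = "closed" if rng.random() < 0.7 else "open"
        branches.append(
            {"id": "aux", "length_um": "inf", "parent_node": "soma", **membrane()}
        )
        cells.append(
            {"id": cid, "soma": soma(), "branches": branches, "terminals": terminals}
        )
        gj_sites.append(
            {
                "cell": cid,
                "branch": "primary",
                "x_um": float(rng.uniform(0.3, 0.7) * primary_len),
            }
        )
    return {
        "cells": cells,
        "gap_junctions": [
            {
                "R_MOhm": _log_uniform(rng, math.sqrt(1000.0), 1.5),
                "site_1": gj_sites[0],
                "site_2": gj_sites[1],
            }
        ],
    }


def random_network(seed: int, max_extra_branches: int = 2) -> Network:
    """Build the validated network for :func:`random_network_config`."""
    return build_network(random_network_config(seed, max_extra_branches))
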