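"""Named reference configurations.

These encode the worked parameter sets used throughout the package's
examples and tests: a resonant dendrite with a = 2 um, D = 50000 um^2/ms,
tau = 2 ms, C = 1 uF/cm^2, Ra = 100 Ohm cm and an inductive pathway
r = 100 Ohm cm^2, L = 5 H cm^2 (preferred frequency near 0.43 rad/ms);
a 25 um soma with Cs = 1 uF/cm^2, Rs = 2000 Ohm cm^2, optionally resonant
with rs = 1 Ohm cm^2, Ls = 0.1 H cm^2; and gap-junction resistances in
the physiological 1-1000 MOhm range.
"""

from __future__ import annotations

import math

from dendrogap.closed_forms import TwoCellInfiniteConfig, TwoSomaConfig
from dendrogap.network_model import MembraneParams, SomaParams, build_network

__all__ = [
    "resonant_dendrite",
    "passive_dendrite",
    "passive_soma",
    "resonant_soma",
    "two_cell_identical_config",
    "two_cell_hetero_config",
    "two_soma_network_config",
    "two_cell_network_config",
    "two_soma_config",
    "NAMED_CONFIGS",
]

_DEND = dict(a=2.0, D=5.0e4, tau=2.0, C=1.0)
_RES = dict(r=100.0, L=5.0)


def resonant_dendrite(**overrides) -> MembraneParams:
    """Reference resonant ('LRC') dendritic membrane."""
    kw = {**_DEND, **_RES, **overrides}
    return MembraneParams.from_cable_constants(**kw)


def passive_dendrite(**overrides) -> MembraneParams:
    """Reference passive ('RC') dendritic membrane (r, L absent)."""
    kw = {**_DEND, **overrides}
    return MembraneParams.from_cable_constants(**kw)


def passive_soma() -> SomaParams:
    return SomaParams(a_s=25.0, Cs=1.0, Rs=2000.0)


def resonant_soma() -> SomaParams:
    return SomaParams(a_s=25.0, Cs=1.0, Rs=2000.0, rs=1.0, Ls=0.1)


def two_cell_identical_config(R_GJ: float = 100.0, resonant: bool = True) -> TwoCellInfiniteConfig:
    p = resonant_dendrite() if resonant else passive_dendrite()
    return TwoCellInfiniteConfig(params_m=p, params_n=p, R_GJ=R_GJ)


def two_cell_hetero_config(
    R_GJ: float = 100.0,
    m_overrides: dict | None = None,
    n_overrides: dict | None = None,
) -> TwoCellInfiniteConfig:
    """Heterogeneous two-cell configuration; by default cell n carries a
    five-fold larger dendritic inductance (L_n = 25 H cm^2)."""
    if m_overrides is None and n_overrides is None:
        n_overrides = {"L": 25.0}
    return TwoCellInfiniteConfig(
        params_m=resonant_dendrite(**(m_overrides or {})),
        params_n=resonant_dendrite(**(n_overrides or {})),
        R_GJ=R_GJ,
    )


def _branch_cfg(bid: str, length, params: MembraneParams, parent: str) -> dict:
    return {
        "id": bid,
        "length_um": "inf" if math.isinf(length) else length,
        "diameter_um": params.a,
        "C_uF_cm2": params.C,
        "R_Ohm_cm2": params.R,
        "Ra_Ohm_cm": params.Ra,
        "r_Ohm_cm2": params.r,
        "L_H_cm2": params.L,
        "parent_node": parent,
    }


def two_cell_network_config(config: TwoCellInfiniteConfig) -> dict:
    """Network schema for the two infinite-cable cells coupled at x = 0.

    Each cell is a doubly-infinite cable, written as two semi-infinite
    branches ("minus" hosting the stimulus side, "plus") joined at a plain
    junction that the gap junction absorbs.
    """
    cells = []
    for cid, p in (("cell_m", config.params_m), ("cell_n", config.params_n)):
        cells.append(
            {
                "id": cid,
                "soma": None,
                "branches": [
                    _branch_cfg("minus", math.inf, p, "mid"),
                    _branch_cfg("plus", math.inf, p, "mid"),
                ],
            }
        )
    return {
        "cells": cells,
        "gap_junctions": [
            {
                "R_MOhm": config.R_GJ,
                "site_1": {"cell": "cell_m", "branch": "minus", "x_um": 0.0},
                "site_2": {"cell": "cell_n", "branch": "minus", "x_um": 0.0},
            }
        ],
    }


def _soma_cfg(s: SomaParams) -> dict:
    out = {"diameter_um": s.a_s, "Cs_uF_cm2": s.Cs, "Rs_Ohm_cm2": s.Rs}
    if s.resonant:
        out["rs_Ohm_cm2"] = s.rs
        out["Ls_H_cm2"] = s.Ls
    return out


def two_soma_config(
    L_GJ: float = 200.0,
    R_GJ: float = 100.0,
    N: int = 4,
    soma_resonant: bool = False,
    dendrites_resonant: bool = True,
    y0: float | None = None,
) -> TwoSomaConfig:
    """Two identical soma-plus-N-semi-infinite-dendrite cells, coupled
    L_GJ um from each soma; the stimulus defaults to 10 um beyond the gap
    junction."""
    return TwoSomaConfig(
        params=resonant_dendrite() if dendrites_resonant else passive_dendrite(),
        soma=resonant_soma() if soma_resonant else passive_soma(),
        N=N,
        L_GJ=L_GJ,
        R_GJ=R_GJ,
        y0=L_GJ + 10.0 if y0 is None else y0,
    )


def two_soma_network_config(cfg: TwoSomaConfig) -> dict:
    """Network schema for the two-soma configuration: per cell, one
    semi-infinite dendrite hosting the gap junction at L_GJ plus N-1 plain
    semi-infinite dendrites, all rooted at the soma."""
    cells = []
    for cid in ("cell1", "cell2"):
        branches = [_branch_cfg("gjdend", math.inf, cfg.params, "soma")]
        branches += [
            _branch_cfg(f"dend{i}", math.inf, cfg.params, "soma") for i in range(1, cfg.N)
        ]
        cells.append({"id": cid, "soma": _soma_cfg(cfg.soma), "branches": branches})
    return {
        "cells": cells,
        "gap_junctions": [
            {
                "R_MOhm": cfg.R_GJ,
                "site_1": {"cell": "cell1", "branch": "gjdend", "x_um": cfg.L_GJ},
                "site_2": {"cell": "cell2", "branch": "gjdend", "x_um": cfg.L_GJ},
            }
        ],
    }


def _named() -> dict:
    return {
        "two_cell_identical": two_cell_network_config(two_cell_identical_config()),
        "two_cell_hetero_Ln25": two_cell_network_config(two_cell_hetero_config()),
        "two_cell_passive": two_cell_network_config(
            two_cell_identical_config(resonant=False)
        ),
        "two_soma_N4": two_soma_network_config(two_soma_config()),
        "sweep_passive_soma_resonant_dendrites": two_soma_network_config(
            two_soma_config(soma_resonant=False, dendrites_resonant=True)
        ),
        "sweep_resonant_soma_passive_dendrites": two_soma_network_config(
            two_soma_config(soma_resonant=True, dendrites_resonant=False)
        ),
        "sweep_all_resonant": two_soma_network_config(
            two_soma_config(soma_resonant=True, dendrites_resonant=True)
        ),
    }


#: name -> network schema dict for all reference configurations
NAMED_CONFIGS = _named()


def named_network(name: str):
    return build_network(NAMED_CONFIGS[name])
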