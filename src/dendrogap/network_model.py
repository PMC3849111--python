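"""Data model for gap-junction coupled dendritic networks.

A network is an extended tree: branches (cable segments with uniform
electrical parameters) glued at typed nodes (sealed/open terminals, regular
branch points, lumped somata, gap junctions). Gap junctions are nodes with
exactly four incident branch ends, partitioned into two pairs -- each pair
being the two halves of one host dendrite.

Unit conventions
----------------
User-facing electrical constants use the customary mixed units of cable
theory (uF/cm^2, Ohm cm^2, H cm^2, Ohm cm, um, MOhm). Internally everything
is converted to {um, ms, mV, nA, MOhm}:

* capacitance per area   1 uF/cm^2 = 1e-5 nF/um^2
* resistance times area  1 Ohm cm^2 = 100  MOhm um^2
* inductance times area  1 H cm^2   = 1e5  MOhm ms um^2
* axial resistivity      1 Ohm cm   = 1e-2 MOhm um

With these, tau = C*R is in ms, D = a/(4*Ra*C) in um^2/ms and
ra = 4*Ra/(pi*a^2) in MOhm/um without further factors.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "MembraneParams",
    "SomaParams",
    "Branch",
    "Node",
    "BranchEnd",
    "PointLocation",
    "Network",
    "NetworkError",
    "build_network",
    "derive_cable_constants",
    "locate",
    "load_network",
    "normalize_config",
    "swc_to_cell_config",
]

# unit conversion factors: user units -> internal {um, ms, mV, nA, MOhm}
_C_AREA = 1e-5   # uF/cm^2   -> nF/um^2
_R_AREA = 100.0  # Ohm cm^2  -> MOhm um^2
_L_AREA = 1e5    # H cm^2    -> MOhm ms um^2
_RA_LIN = 1e-2   # Ohm cm    -> MOhm um


class NetworkError(ValueError):
    """Raised for invalid parameters, malformed configs or bad queries."""


def _require_positive(name: str, value: float) -> None:
    if not (value > 0) or math.isnan(value):
        raise NetworkError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class MembraneParams:
    """Specific electrical constants of one cable branch.

    Parameters
    ----------
    C : float
        Specific membrane capacitance, uF/cm^2.
    R : float
        Specific leak resistance, Ohm cm^2.
    Ra : float
        Cytoplasmic (axial) resistivity, Ohm cm.
    a : float
        Branch diameter, um.
    r, L : float, optional
        Resistance (Ohm cm^2) and inductance (H cm^2) of the inductive
        membrane pathway. Present together for resonant ('LRC') membrane;
        both absent for passive ('RC') membrane.
    """

    C: float
    R: float
    Ra: float
    a: float
    r: float | None = None
    L: float | None = None

    def __post_init__(self) -> None:
        for name in ("C", "R", "Ra", "a"):
            _require_positive(name, getattr(self, name))
        if (self.r is None) != (self.L is None):
            raise NetworkError("r and L must be both present (resonant) or both absent (passive)")
        if self.r is not None:
            _require_positive("r", self.r)
            _require_positive("L", self.L)

    # -- internal-unit views -------------------------------------------------
    @property
    def resonant(self) -> bool:
        return self.r is not None

    @property
    def C_area(self) -> float:
        """Capacitance per area, nF/um^2."""
        return self.C * _C_AREA

    @property
    def R_area(self) -> float:
        """Leak resistance times area, MOhm um^2."""
        return self.R * _R_AREA

    @property
    def r_area(self) -> float:
        return self.r * _R_AREA

    @property
    def L_area(self) -> float:
        return self.L * _L_AREA

    @property
    def Ra_lin(self) -> float:
        """Axial resistivity, MOhm um."""
        return self.Ra * _RA_LIN

    @property
    def D(self) -> float:
        """Diffusion coefficient a/(4*Ra*C), um^2/ms."""
        return self.a / (4.0 * self.Ra_lin * self.C_area)

    @property
    def tau(self) -> float:
        """Membrane time constant C*R, ms."""
        return self.C_area * self.R_area

    @property
    def ra(self) -> float:
        """Axial resistance per unit length 4*Ra/(pi*a^2), MOhm/um."""
        return 4.0 * self.Ra_lin / (math.pi * self.a**2)

    @property
    def c_len(self) -> float:
        """Membrane capacitance per unit length C*pi*a, nF/um."""
        return self.C_area * math.pi * self.a

    @property
    def pole(self) -> float | None:
        """Laplace-domain pole -r/(L) of the inductive pathway (1/ms), or None."""
        if not self.resonant:
            return None
        return -self.r_area / self.L_area

    @classmethod
    def from_cable_constants(
        cls,
        a: float,
        D: float,
        tau: float,
        C: float = 1.0,
        r: float | None = None,
        L: float | None = None,
    ) -> "MembraneParams":
        """Construct from (a, D, tau) as usually quoted, instead of (Ra, R).

        Inverts D = a/(4*Ra*C) and tau = C*R.
        """
        _require_positive("D", D)
        _require_positive("tau", tau)
        Ra_lin = a / (4.0 * D * C * _C_AREA)
        R_area = tau / (C * _C_AREA)
        return cls(C=C, R=R_area / _R_AREA, Ra=Ra_lin / _RA_LIN, a=a, r=r, L=L)


@dataclass(frozen=True)
class SomaParams:
    """Lumped-soma constants: diameter a_s (um) and specific C_s, R_s
    (uF/cm^2, Ohm cm^2), with optional resonant pathway (r_s, L_s).

    The soma is iso-potential; its absolute admittance is the specific
    admittance times the membrane area pi*a_s^2 (sphere of diameter a_s).
    """

    a_s: float
    Cs: float
    Rs: float
    rs: float | None = None
    Ls: float | None = None

    def __post_init__(self) -> None:
        for name in ("a_s", "Cs", "Rs"):
            _require_positive(name, getattr(self, name))
        if (self.rs is None) != (self.Ls is None):
            raise NetworkError("rs and Ls must be both present (resonant soma) or both absent")
        if self.rs is not None:
            _require_positive("rs", self.rs)
            _require_positive("Ls", self.Ls)

    @property
    def resonant(self) -> bool:
        return self.rs is not None

    @property
    def area(self) -> float:
        """Membrane area pi*a_s^2, um^2."""
        return math.pi * self.a_s**2

    @property
    def Cs_abs(self) -> float:
        """Absolute capacitance, nF."""
        return self.Cs * _C_AREA * self.area

    @property
    def Rs_abs(self) -> float:
        """Absolute leak resistance, MOhm."""
        return self.Rs * _R_AREA / self.area

    @property
    def rs_abs(self) -> float:
        return self.rs * _R_AREA / self.area

    @property
    def Ls_abs(self) -> float:
        return self.Ls * _L_AREA / self.area

    @property
    def pole(self) -> float | None:
        if not self.resonant:
            return None
        return -self.rs_abs / self.Ls_abs


def derive_cable_constants(params: MembraneParams) -> tuple[float, float, float]:
    """Return (D, tau, ra) in internal units (um^2/ms, ms, MOhm/um)."""
    return params.D, params.tau, params.ra


# --------------------------------------------------------------------------
# graph structure
# --------------------------------------------------------------------------

#: A branch end: (branch id, "prox" | "dist").
BranchEnd = tuple[str, str]

TERMINAL_CLOSED = "terminal_closed"
TERMINAL_OPEN = "terminal_open"
BRANCH_POINT = "branch_point"
SOMA = "soma"
GAP_JUNCTION = "gap_junction"

_NODE_KINDS = {TERMINAL_CLOSED, TERMINAL_OPEN, BRANCH_POINT, SOMA, GAP_JUNCTION}


@dataclass(frozen=True)
class Branch:
    """One uniform cable segment. ``length`` may be ``math.inf`` for a
    semi-infinite branch, in which case there is no distal node."""

    id: str
    length: float
    params: MembraneParams
    proximal: str
    distal: str | None

    def __post_init__(self) -> None:
        if not (self.length > 0):
            raise NetworkError(f"branch {self.id!r}: length must be > 0, got {self.length}")
        if math.isinf(self.length) and self.distal is not None:
            raise NetworkError(f"branch {self.id!r}: a semi-infinite branch has no distal node")
        if not math.isinf(self.length) and self.distal is None:
            raise NetworkError(f"branch {self.id!r}: a finite branch needs a distal node")

    @property
    def semi_infinite(self) -> bool:
        return math.isinf(self.length)


@dataclass(frozen=True)
class Node:
    """A typed node of the extended tree.

    For ``gap_junction`` nodes, ``pairing`` holds two ordered pairs of
    incident branch ends ``((m_minus, m_plus), (n_minus, n_plus))``: each
    pair is the two halves of one host dendrite. ``R_GJ`` is the junction
    resistance in MOhm.
    """

    id: str
    kind: str
    soma: SomaParams | None = None
    R_GJ: float | None = None
    pairing: tuple[tuple[BranchEnd, BranchEnd], tuple[BranchEnd, BranchEnd]] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _NODE_KINDS:
            raise NetworkError(f"node {self.id!r}: unknown kind {self.kind!r}")
        if (self.kind == SOMA) != (self.soma is not None):
            raise NetworkError(f"node {self.id!r}: soma parameters iff kind='soma'")
        if self.kind == GAP_JUNCTION:
            if self.R_GJ is None or not (self.R_GJ > 0):
                raise NetworkError(f"node {self.id!r}: gap junction needs R_GJ > 0")
            if self.pairing is None:
                raise NetworkError(f"node {self.id!r}: gap junction needs a dendrite pairing")


@dataclass(frozen=True)
class PointLocation:
    """A point on the network: branch id plus distance x (um) from the
    branch's proximal end. Branch ids may refer to original (pre-split)
    config branches; :func:`locate` resolves them to live segments."""

    branch_id: str
    x: float


@dataclass
class Network:
    """A validated extended-tree network.

    Attributes
    ----------
    branches, nodes : dict
        Live branches/nodes by id (gap-junction host branches appear as
        their split segments).
    cell_of : dict
        Branch id -> cell id.
    segment_map : dict
        Original config branch id -> ascending list of (segment_id, x0, x1)
        covering [0, length]; identity entries for unsplit branches.
    """

    branches: dict[str, Branch]
    nodes: dict[str, Node]
    cell_of: dict[str, str]
    segment_map: dict[str, list[tuple[str, float, float]]]
    terminals_cfg: dict[str, str] = field(default_factory=dict)
    cell_order: list[str] = field(default_factory=list)

    # -- incidence ----------------------------------------------------------
    def incident_ends(self, node_id: str) -> list[BranchEnd]:
        out: list[BranchEnd] = []
        for b in self.branches.values():
            if b.proximal == node_id:
                out.append((b.id, "prox"))
            if b.distal == node_id:
                out.append((b.id, "dist"))
        return out

    def node_at(self, branch_id: str, end: str) -> str | None:
        b = self.branches[branch_id]
        return b.proximal if end == "prox" else b.distal

    def cells(self) -> dict[str, set[str]]:
        """Cell id -> set of live branch ids."""
        out: dict[str, set[str]] = {c: set() for c in self.cell_order}
        for bid, cid in self.cell_of.items():
            out.setdefault(cid, set()).add(bid)
        return out

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for b in self.branches.values():
            for nid in (b.proximal, b.distal):
                if nid is not None and nid not in self.nodes:
                    raise NetworkError(f"branch {b.id!r}: dangling end at unknown node {nid!r}")
        degree = {nid: len(self.incident_ends(nid)) for nid in self.nodes}
        for node in self.nodes.values():
            d = degree[node.id]
            if node.kind in (TERMINAL_CLOSED, TERMINAL_OPEN) and d != 1:
                raise NetworkError(f"terminal node {node.id!r} has {d} incident ends (want 1)")
            if node.kind == BRANCH_POINT and d < 2:
                raise NetworkError(f"branch point {node.id!r} has {d} incident ends (want >=2)")
            if node.kind == SOMA and d < 1:
                raise NetworkError(f"soma node {node.id!r} has no incident branches")
            if node.kind == GAP_JUNCTION:
                if d != 4:
                    raise NetworkError(
                        f"gap junction {node.id!r} has {d} incident ends (want exactly 4)"
                    )
                listed = [e for pair in node.pairing for e in pair]
                if sorted(listed) != sorted(self.incident_ends(node.id)):
                    raise NetworkError(
                        f"gap junction {node.id!r}: pairing does not partition its incident ends"
                    )
                for pair in node.pairing:
                    cells = {self.cell_of[b] for b, _ in pair}
                    if len(cells) != 1:
                        raise NetworkError(
                            f"gap junction {node.id!r}: a dendrite pair spans two cells"
                        )
        # connectivity of the full extended tree
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for b in self.branches.values():
            if b.distal is not None:
                g.add_edge(b.proximal, b.distal, branch=b.id)
            else:
                g.add_node(b.proximal)
        if g.number_of_nodes() and not nx.is_connected(g):
            raise NetworkError("network graph is not connected")
        # removing GJ nodes must decompose into the declared cells
        g2 = nx.Graph()
        for b in self.branches.values():
            g2.add_node(("b", b.id))
            for nid in (b.proximal, b.distal):
                if nid is not None and self.nodes[nid].kind != GAP_JUNCTION:
                    g2.add_edge(("b", b.id), ("n", nid))
        comps = [
            {name for tag, name in comp if tag == "b"} for comp in nx.connected_components(g2)
        ]
        comps = [c for c in comps if c]
        # each component must lie within exactly one declared cell (gap
        # junctions are the only inter-cell links; a cell may itself split
        # into several pieces when a junction sits mid-dendrite)
        for comp in comps:
            owners = {self.cell_of[b] for b in comp}
            if len(owners) != 1:
                raise NetworkError(
                    "cell decomposition mismatch: a gap-junction-free component "
                    f"spans cells {sorted(owners)}"
                )


# --------------------------------------------------------------------------
# config schema -> Network
# --------------------------------------------------------------------------

_BRANCH_KEYS = {
    "id",
    "length_um",
    "diameter_um",
    "C_uF_cm2",
    "R_Ohm_cm2",
    "r_Ohm_cm2",
    "L_H_cm2",
    "Ra_Ohm_cm",
    "parent_node",
}


def _params_from_branch_cfg(b: Mapping, where: str) -> MembraneParams:
    try:
        return MembraneParams(
            C=b["C_uF_cm2"],
            R=b["R_Ohm_cm2"],
            Ra=b["Ra_Ohm_cm"],
            a=b["diameter_um"],
            r=b.get("r_Ohm_cm2"),
            L=b.get("L_H_cm2"),
        )
    except KeyError as exc:
        raise NetworkError(f"{where}: missing key {exc}") from None


def _soma_from_cfg(s: Mapping, where: str) -> SomaParams:
    try:
        return SomaParams(
            a_s=s["diameter_um"],
            Cs=s["Cs_uF_cm2"],
            Rs=s["Rs_Ohm_cm2"],
            rs=s.get("rs_Ohm_cm2"),
            Ls=s.get("Ls_H_cm2"),
        )
    except KeyError as exc:
        raise NetworkError(f"{where}: missing key {exc}") from None


def normalize_config(config: Mapping) -> dict:
    """Deep-copy ``config`` with defaults filled in (explicit null r/L keys,
    terminal map entries, cell ids), for stable round-tripping."""
    cfg = copy.deepcopy(dict(config))
    cells = []
    for i, cell in enumerate(cfg.get("cells", [])):
        cell = dict(cell)
        cell.setdefault("id", f"cell{i}")
        cell.setdefault("soma", None)
        branches = []
        terminals = dict(cell.get("terminals") or {})
        for b in cell.get("branches", []):
            b = dict(b)
            b.setdefault("r_Ohm_cm2", None)
            b.setdefault("L_H_cm2", None)
            b.setdefault("parent_node", "root")
            if b.get("length_um") != "inf" and b["id"] not in terminals:
                terminals[b["id"]] = "closed"
            branches.append(b)
        has_child = {b["parent_node"] for b in branches}
        terminals = {
            k: v
            for k, v in terminals.items()
            if k not in has_child  # ends with children are junctions, not terminals
        }
        cell["branches"] = branches
        cell["terminals"] = terminals
        cells.append(cell)
    cfg["cells"] = cells
    cfg.setdefault("gap_junctions", [])
    return cfg


def build_network(config: Mapping) -> Network:
    """Build and validate a :class:`Network` from a config mapping.

    Schema (YAML/JSON friendly)::

        cells:
          - id: cell_m                # optional, defaults to cell<i>
            soma: {diameter_um, Cs_uF_cm2, Rs_Ohm_cm2, [rs_Ohm_cm2, Ls_H_cm2]} | null
            branches:
              - id: dend
                length_um: 500       # or "inf" for a semi-infinite branch
                diameter_um: 2
                C_uF_cm2: 1
                R_Ohm_cm2: 2000
                Ra_Ohm_cm: 100
                r_Ohm_cm2: 100       # optional (resonant membrane)
                L_H_cm2: 5           # optional
                parent_node: soma    # "soma" | another branch id (attach to
                                     # its distal end) | any other label (a
                                     # named junction within the cell)
            terminals: {dend: closed}   # "closed" (sealed) | "open"
        gap_junctions:
          - R_MOhm: 100
            site_1: {cell: cell_m, branch: dend, x_um: 50}
            site_2: {cell: cell_n, branch: dend, x_um: 50}

    A gap junction at ``x_um`` strictly inside a branch splits it into
    segments ``<id>.prox`` / ``<id>.dist``. ``x_um == 0`` is allowed when
    the branch's proximal node is a plain two-way junction: the junction is
    absorbed into the gap-junction node (this encodes a doubly-infinite
    cable split at the junction).
    """
    cfg = normalize_config(config)
    branches: dict[str, Branch] = {}
    nodes: dict[str, Node] = {}
    cell_of: dict[str, str] = {}
    terminals_cfg: dict[str, str] = {}
    cell_order: list[str] = []

    for cell in cfg["cells"]:
        cid = cell["id"]
        if cid in cell_order:
            raise NetworkError(f"duplicate cell id {cid!r}")
        cell_order.append(cid)
        soma_node = None
        if cell["soma"] is not None:
            soma_node = f"{cid}:soma"
            nodes[soma_node] = Node(
                id=soma_node, kind=SOMA, soma=_soma_from_cfg(cell["soma"], f"cell {cid!r} soma")
            )
        ids = [b["id"] for b in cell["branches"]]
        if len(set(ids)) != len(ids):
            raise NetworkError(f"cell {cid!r}: duplicate branch ids")
        qual = {bid: f"{cid}:{bid}" for bid in ids}
        # resolve proximal attachment of every branch
        children_of: dict[str, list[str]] = {}
        for b in cell["branches"]:
            bid = b["id"]
            parent = b["parent_node"]
            if parent == "soma":
                if soma_node is None:
                    raise NetworkError(f"cell {cid!r}, branch {bid!r}: parent 'soma' but no soma")
                prox = soma_node
            elif parent in qual:
                if parent == bid:
                    raise NetworkError(f"cell {cid!r}, branch {bid!r}: cannot attach to itself")
                prox = f"{qual[parent]}:dist"
                children_of.setdefault(parent, []).append(bid)
            else:
                prox = f"{cid}:junction:{parent}"
                if prox not in nodes:
                    nodes[prox] = Node(id=prox, kind=BRANCH_POINT)
            b["_prox_node"] = prox
        for b in cell["branches"]:
            bid = b["id"]
            length = math.inf if b["length_um"] == "inf" else float(b["length_um"])
            if not math.isinf(length) and not (length > 0):
                raise NetworkError(f"cell {cid!r}, branch {bid!r}: length must be > 0")
            params = _params_from_branch_cfg(b, f"cell {cid!r}, branch {bid!r}")
            distal: str | None
            if math.isinf(length):
                if bid in children_of:
                    raise NetworkError(
                        f"cell {cid!r}, branch {bid!r}: semi-infinite branch cannot have children"
                    )
                distal = None
            elif bid in children_of:
                distal = f"{qual[bid]}:dist"
                nodes[distal] = Node(id=distal, kind=BRANCH_POINT)
            else:
                cond = cell["terminals"].get(bid, "closed")
                if cond not in ("closed", "open"):
                    raise NetworkError(f"cell {cid!r}: terminal condition {cond!r} invalid")
                distal = f"{qual[bid]}:end"
                nodes[distal] = Node(
                    id=distal, kind=TERMINAL_CLOSED if cond == "closed" else TERMINAL_OPEN
                )
                terminals_cfg[qual[bid]] = cond
            qb = qual[bid]
            branches[qb] = Branch(
                id=qb, length=length, params=params, proximal=b["_prox_node"], distal=distal
            )
            cell_of[qb] = cid

    net = Network(
        branches=branches,
        nodes=nodes,
        cell_of=cell_of,
        segment_map={bid: [(bid, 0.0, b.length)] for bid, b in branches.items()},
        terminals_cfg=terminals_cfg,
        cell_order=cell_order,
    )

    for gi, gj in enumerate(cfg["gap_junctions"]):
        gj_id = f"gj{gi}"
        try:
            r_gj = gj["R_MOhm"]
            sites = (gj["site_1"], gj["site_2"])
        except KeyError as exc:
            raise NetworkError(f"gap junction {gi}: missing key {exc}") from None
        pairs = []
        for site in sites:
            pairs.append(_attach_gj_site(net, gj_id, site, gi))
        net.nodes[gj_id] = Node(
            id=gj_id, kind=GAP_JUNCTION, R_GJ=r_gj, pairing=(pairs[0], pairs[1])
        )

    net.validate()
    net._config = cfg  # normalized source config, for serialisation
    return net


def _attach_gj_site(net: Network, gj_id: str, site: Mapping, gi: int) -> tuple[BranchEnd, BranchEnd]:
    """Split (or absorb into) the host branch at one gap-junction site and
    return the ordered pair of same-dendrite branch ends (minus, plus)."""
    try:
        cid, bid, x = site["cell"], site["branch"], float(site["x_um"])
    except KeyError as exc:
        raise NetworkError(f"gap junction {gi}: site missing key {exc}") from None
    qb = f"{cid}:{bid}"
    if qb not in net.segment_map:
        raise NetworkError(f"gap junction {gi}: unknown branch {bid!r} in cell {cid!r}")
    seg_id, x0, x1 = _segment_containing(net, qb, x, gi)
    seg = net.branches[seg_id]
    x_local = x - x0
    if x_local == 0.0:
        # place at the proximal node: must be a plain 2-way junction to absorb
        node = net.nodes[seg.proximal]
        ends = net.incident_ends(node.id)
        if node.kind != BRANCH_POINT or len(ends) != 2:
            raise NetworkError(
                f"gap junction {gi}: site at x_um={x} coincides with node {node.id!r} "
                f"(kind {node.kind!r}); only a plain two-way junction can host a gap junction"
            )
        del net.nodes[node.id]
        new_branches = {}
        for e_bid, e_end in ends:
            b = net.branches[e_bid]
            if e_end == "prox":
                new_branches[e_bid] = Branch(b.id, b.length, b.params, gj_id, b.distal)
            else:
                new_branches[e_bid] = Branch(b.id, b.length, b.params, b.proximal, gj_id)
        net.branches.update(new_branches)
        return (ends[0], ends[1])
    if seg.length <= x_local:
        raise NetworkError(
            f"gap junction {gi}: x_um={x} is outside branch {bid!r} or on an existing node"
        )
    # split the segment at x_local
    lo_id, hi_id = f"{seg_id}.prox", f"{seg_id}.dist"
    hi_len = seg.length - x_local
    net.branches[lo_id] = Branch(lo_id, x_local, seg.params, seg.proximal, gj_id)
    net.branches[hi_id] = Branch(
        hi_id, hi_len, seg.params, gj_id, seg.distal if not math.isinf(hi_len) else None
    )
    del net.branches[seg_id]
    net.cell_of[lo_id] = net.cell_of[hi_id] = net.cell_of.pop(seg_id)
    # update the segment map of the original branch
    for orig, segs in net.segment_map.items():
        for i, (sid, s0, s1) in enumerate(segs):
            if sid == seg_id:
                segs[i : i + 1] = [(lo_id, s0, s0 + x_local), (hi_id, s0 + x_local, s1)]
                break
    return ((lo_id, "dist"), (hi_id, "prox"))


def _segment_containing(net: Network, qb: str, x: float, gi: int) -> tuple[str, float, float]:
    segs = net.segment_map[qb]
    total = segs[-1][2]
    if x < 0 or x > total:
        raise NetworkError(f"gap junction {gi}: x_um={x} outside [0, {total}] on {qb!r}")
    for sid, s0, s1 in segs:
        if s0 <= x < s1 or (x == s1 and math.isinf(s1)):
            return sid, s0, s1
    raise NetworkError(f"gap junction {gi}: x_um={x} coincides with an existing node on {qb!r}")


def locate(network: Network, loc: PointLocation) -> tuple[str, float]:
    """Resolve a :class:`PointLocation` to a live ``(segment_id, x_local)``.

    ``loc.branch_id`` may be ``"cell:branch"`` qualified or a bare config
    branch id if unambiguous. A point falling exactly on a gap-junction
    split is assigned to the proximal-side segment (its distal end), which
    by value continuity across the junction is equivalent to the other
    convention.
    """
    bid = loc.branch_id
    if bid in network.branches and bid not in network.segment_map:
        # a live split segment referenced directly
        b = network.branches[bid]
        if loc.x < 0 or loc.x > b.length:
            raise NetworkError(f"x={loc.x} outside [0, {b.length}] on segment {bid!r}")
        return bid, loc.x
    if bid not in network.segment_map:
        matches = [k for k in network.segment_map if k.split(":", 1)[-1] == bid]
        if len(matches) == 1:
            bid = matches[0]
        elif len(matches) > 1:
            raise NetworkError(f"branch id {loc.branch_id!r} is ambiguous: {sorted(matches)}")
        else:
            raise NetworkError(f"unknown branch {loc.branch_id!r}")
    segs = network.segment_map[bid]
    total = segs[-1][2]
    if loc.x < 0 or loc.x > total:
        raise NetworkError(f"x={loc.x} outside [0, {total}] on branch {bid!r}")
    for sid, s0, s1 in segs:
        if s0 <= loc.x <= s1:
            return sid, loc.x - s0
    raise NetworkError(f"x={loc.x} not locatable on branch {bid!r}")  # pragma: no cover


def serialise(network: Network) -> dict:
    """Return the normalized config the network was built from."""
    cfg = getattr(network, "_config", None)
    if cfg is None:
        raise NetworkError("network was not built from a config")
    out = copy.deepcopy(cfg)
    for cell in out["cells"]:
        for b in cell["branches"]:
            b.pop("_prox_node", None)
    return out


def load_network(path) -> Network:
    """Load a network config from a YAML (or JSON; JSON is a YAML subset)
    file and build it."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise NetworkError(f"config file {path!r} does not contain a mapping")
    return build_network(cfg)


# --------------------------------------------------------------------------
# SWC import (single-cell morphology)
# --------------------------------------------------------------------------

def swc_to_cell_config(
    swc_text: str | Iterable[str],
    membrane: Mapping,
    soma: Mapping | None = None,
    cell_id: str = "cell0",
) -> dict:
    """Convert a standard 7-column SWC morphology into one cell config.

    Samples of type 1 (soma) are collapsed into a single lumped soma node;
    dendritic samples (type 3, others treated alike) are chained into
    unbranched cable sections between topological branch points, with
    section length the summed Euclidean sample distances and diameter the
    length-weighted mean of 2*radius. Electrical constants (``membrane``:
    C_uF_cm2, R_Ohm_cm2, Ra_Ohm_cm, optional r_Ohm_cm2/L_H_cm2) are
    supplied separately and shared by all sections; ``soma`` (same keys as
    the config schema) overrides the lumped soma parameters, defaulting the
    diameter to the SWC soma extent.
    """
    lines = swc_text.splitlines() if isinstance(swc_text, str) else list(swc_text)
    samples: dict[int, tuple[int, float, float, float, float, int]] = {}
    for ln in lines:
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) != 7:
            raise NetworkError(f"malformed SWC line: {ln!r}")
        sid, styp = int(parts[0]), int(parts[1])
        x, y, z, rad = map(float, parts[2:6])
        parent = int(parts[6])
        samples[sid] = (styp, x, y, z, rad, parent)
    if not samples:
        raise NetworkError("empty SWC morphology")

    soma_ids = {sid for sid, s in samples.items() if s[0] == 1}
    children: dict[int, list[int]] = {}
    for sid, s in samples.items():
        children.setdefault(s[5], []).append(sid)

    def dist(i: int, j: int) -> float:
        _, xi, yi, zi, _, _ = samples[i]
        _, xj, yj, zj, _, _ = samples[j]
        return math.dist((xi, yi, zi), (xj, yj, zj))

    # soma diameter: max pairwise extent of soma samples, else 2*radius
    if soma_ids:
        pts = sorted(soma_ids)
        extent = max(
            (dist(i, j) for i in pts for j in pts if i < j),
            default=0.0,
        )
        soma_diam = extent if extent > 0 else 2.0 * samples[pts[0]][4]
    else:
        soma_diam = None

    # section roots: non-soma samples whose parent is soma (or -1), plus
    # children of branch points
    def is_branchpoint(sid: int) -> bool:
        kids = [k for k in children.get(sid, []) if k not in soma_ids]
        return len(kids) >= 2

    branch_cfgs = []
    sec_of_sample: dict[int, str] = {}
    counter = [0]

    def walk_section(root: int, parent_label: str) -> None:
        sec = f"swc{counter[0]}"
        counter[0] += 1
        length = 0.0
        wdiam = 0.0
        cur = root
        prev = samples[root][5]
        while True:
            if prev in samples and prev not in soma_ids:
                d = dist(prev, cur)
            elif prev in soma_ids:
                d = 0.0  # soma is lumped; the section starts at the soma node
            else:
                d = 0.0
            length += d
            wdiam += d * 2.0 * samples[cur][4]
            sec_of_sample[cur] = sec
            kids = [k for k in children.get(cur, []) if k not in soma_ids]
            if len(kids) == 1 and not is_branchpoint(cur):
                prev, cur = cur, kids[0]
                continue
            break
        if length <= 0:
            length = max(2.0 * samples[root][4], 1.0)
            wdiam = length * 2.0 * samples[root][4]
        branch_cfgs.append(
            {
                "id": sec,
                "length_um": length,
                "diameter_um": (wdiam / length) if length > 0 else 2.0 * samples[root][4],
                "C_uF_cm2": membrane["C_uF_cm2"],
                "R_Ohm_cm2": membrane["R_Ohm_cm2"],
                "Ra_Ohm_cm": membrane["Ra_Ohm_cm"],
                "r_Ohm_cm2": membrane.get("r_Ohm_cm2"),
                "L_H_cm2": membrane.get("L_H_cm2"),
                "parent_node": parent_label,
            }
        )
        for k in [k for k in children.get(cur, []) if k not in soma_ids]:
            walk_section(k, sec)

    roots = [
        sid
        for sid, s in samples.items()
        if sid not in soma_ids and (s[5] == -1 or s[5] in soma_ids)
    ]
    for root in sorted(roots):
        walk_section(root, "soma" if soma_ids else "root")

    soma_cfg = None
    if soma_ids or soma is not None:
        soma_cfg = {
            "diameter_um": soma_diam if soma_diam else 20.0,
            "Cs_uF_cm2": membrane["C_uF_cm2"],
            "Rs_Ohm_cm2": membrane["R_Ohm_cm2"],
        }
        if soma:
            soma_cfg.update(soma)
    return {"id": cell_id, "soma": soma_cfg, "branches": branch_cfgs, "terminals": {}}
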