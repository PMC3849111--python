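"""The sum-over-trips engine for arbitrary network geometries.

The Laplace-domain Green's function between two point locations x (on
branch i) and y (on branch j) is the series

    Ghat_ij(x, y, w) = 1/(c_j * D_j * gamma_j(w)) * sum_trips A_trip(w)
                       * exp(-L_trip(w)) / 2

where L_trip is the trip's length with every branch piece scaled by that
branch's gamma_k(w), A_trip is a product of node factors picked up along
the way, and c_j = C_j*pi*a_j is the capacitance per unit length of the
stimulated branch (so responses are mV per nA*ms impulse).

Node factor rules (action names in parentheses):

* branch point -- pass onto branch k (``pass_to``): 2*p_k;
  reflect back along k (``reflect``): 2*p_k - 1
* terminal (``terminal_reflect``): +1 sealed, -1 open
* soma -- pass onto k (``pass_to``): 2*p_s,k; reflect (``reflect``):
  2*p_s,k - 1
* gap junction, arriving on a segment of host dendrite m --
  reflect back (``gj_reflect``): -p_GJ,n;
  pass onto the other segment of m (``gj_pass_same_dendrite``): 1 - p_GJ,n;
  cross into either segment of dendrite n (``gj_cross``): p_GJ,n
  (and with m, n swapped).

Trips are enumerated exhaustively in ascending *physical* length by
uniform-cost search, so one enumeration serves every omega; truncation is
by length shells whose contribution is monitored at evaluation time.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field

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
    locate,
)

__all__ = [
    "Trip",
    "TripExpansion",
    "ConvergenceError",
    "enumerate_trips",
    "trip_coefficient",
    "scaled_trip_length",
    "greens_laplace",
    "GreensEvaluator",
]


class ConvergenceError(RuntimeError):
    """The trip series did not converge within the shell cap."""


@dataclass(frozen=True)
class Trip:
    """One walk from x to y.

    ``events`` is the ordered list of (node_id, action) pairs; ``factors``
    the corresponding factor keys consumed by the kernel cache;
    ``seg_lengths`` the traversed physical length per branch (aggregated);
    ``x_slope`` is d(total length)/dx for the trip's first leg (+1 toward
    the proximal node of x's branch, -1 toward the distal one), used to
    re-evaluate the same trip set at nearby x.
    """

    events: tuple[tuple[str, str], ...]
    factors: tuple[tuple, ...]
    seg_lengths: tuple[tuple[str, float], ...]
    total_length: float
    x_slope: int
    x_branch: str

    def length_on(self, branch_id: str) -> float:
        return sum(l for b, l in self.seg_lengths if b == branch_id)


@dataclass
class TripExpansion:
    """All trips of physical length <= cutoff between x and y, ascending."""

    trips: list[Trip]
    cutoff: float
    x: tuple[str, float]
    y: tuple[str, float]
    exhausted: bool = False


_ACTION_OF = {
    "branch_pass": "pass_to",
    "branch_reflect": "reflect",
    "soma_pass": "pass_to",
    "soma_reflect": "reflect",
    "term": "terminal_reflect",
    "gj_cross": "gj_cross",
    "gj_pass": "gj_pass_same_dendrite",
    "gj_reflect": "gj_reflect",
}


def factor_value(kernels: FrequencyKernelSet, key: tuple) -> np.ndarray:
    """Evaluate one node-factor key at the kernel cache's omega."""
    net = kernels.network
    kind = key[0]
    if kind == "term":
        node = net.nodes[key[1]]
        sign = 1.0 if node.kind == TERMINAL_CLOSED else -1.0
        return np.broadcast_to(np.asarray(sign, dtype=complex), kernels.omega.shape)
    if kind in ("branch_pass", "branch_reflect"):
        _, node_id, branch_id = key
        total = sum(kernels.z_of(b) for b, _ in net.incident_ends(node_id))
        p = kernels.z_of(branch_id) / total
        return 2.0 * p if kind == "branch_pass" else 2.0 * p - 1.0
    if kind in ("soma_pass", "soma_reflect"):
        _, node_id, branch_id = key
        node = net.nodes[node_id]
        total = sum(kernels.z_of(b) for b, _ in net.incident_ends(node_id))
        p = kernels.z_of(branch_id) / (total + kernels.soma_admittance(node))
        return 2.0 * p if kind == "soma_pass" else 2.0 * p - 1.0
    if kind in ("gj_cross", "gj_pass", "gj_reflect"):
        _, node_id, dendrite = key
        pm, pn = kernels.gj_pair(net.nodes[node_id])
        p_of = (pm, pn)
        if kind == "gj_cross":
            return p_of[dendrite]  # dendrite = the one being entered
        other = p_of[1 - dendrite]  # dendrite = the one being travelled
        return 1.0 - other if kind == "gj_pass" else -other
    raise NetworkError(f"unknown factor key {key!r}")  # pragma: no cover


def trip_coefficient(trip: Trip, kernels: FrequencyKernelSet) -> np.ndarray:
    """A_trip(omega): the product of the trip's node factors (1 for the
    event-free direct trip)."""
    out = np.ones_like(kernels.omega)
    for key in trip.factors:
        out = out * factor_value(kernels, key)
    return out


def scaled_trip_length(trip: Trip, kernels: FrequencyKernelSet) -> np.ndarray:
    """Sum of gamma_k(omega) * (physical length traversed on branch k)."""
    out = np.zeros_like(kernels.omega)
    for branch_id, length in trip.seg_lengths:
        out = out + kernels.gamma_of(branch_id) * length
    return out


# --------------------------------------------------------------------------
# enumeration
# --------------------------------------------------------------------------

def _gj_dendrite_of(node, end) -> int:
    for d, pair in enumerate(node.pairing):
        if end in pair:
            return d
    raise NetworkError(f"end {end!r} not in gap junction {node.id!r} pairing")


def _trip_from_path(path, x_branch, x_slope, total) -> Trip:
    factors = []
    events = []
    lengths: dict[str, float] = {}
    node_of_key = lambda key: key[1]
    while path is not None:
        key, branch, leg, path = path
        if key is not None:
            factors.append(key)
            events.append((node_of_key(key), _ACTION_OF[key[0]]))
        if leg:
            lengths[branch] = lengths.get(branch, 0.0) + leg
    factors.reverse()
    events.reverse()
    return Trip(
        events=tuple(events),
        factors=tuple(factors),
        seg_lengths=tuple(sorted(lengths.items())),
        total_length=total,
        x_slope=x_slope,
        x_branch=x_branch,
    )


def _iter_trips(network: Network, xseg: str, xloc: float, yseg: str, yloc: float):
    """Yield trips from (xseg, xloc) to (yseg, yloc) in ascending physical
    length (ties broken deterministically by insertion order)."""
    branches = network.branches
    nodes = network.nodes
    incident = {nid: network.incident_ends(nid) for nid in nodes}
    heap: list = []
    seq = itertools.count()
    bx = branches[xseg]

    def push_done(total, path, slope):
        heapq.heappush(heap, (total, next(seq), "done", path, slope))

    def push_arrive(total, node_id, via, path, slope):
        heapq.heappush(heap, (total, next(seq), "arrive", (node_id, via, path), slope))

    if xseg == yseg:
        # direct leg along the shared branch, no node events
        slope = 1 if xloc >= yloc else -1
        path = (None, xseg, abs(xloc - yloc), None)
        push_done(abs(xloc - yloc), path, slope)
    # initial legs toward each end of x's branch
    if bx.proximal is not None:
        push_arrive(xloc, bx.proximal, (xseg, "prox"), (None, xseg, xloc, None), 1)
    if bx.distal is not None:
        leg = bx.length - xloc
        push_arrive(leg, bx.distal, (xseg, "dist"), (None, xseg, leg, None), -1)

    while heap:
        total, _, kind, payload, slope = heapq.heappop(heap)
        if kind == "done":
            yield total, payload, slope
            continue
        node_id, via, path = payload
        node = nodes[node_id]
        ends = incident[node_id]
        for end in ends:
            b2, e2 = end
            br2 = branches[b2]
            # factor picked up for choosing this outgoing end
            if node.kind in (TERMINAL_CLOSED, TERMINAL_OPEN):
                key = ("term", node_id)
            elif node.kind == BRANCH_POINT:
                key = (
                    ("branch_reflect", node_id, b2)
                    if end == via
                    else ("branch_pass", node_id, b2)
                )
            elif node.kind == SOMA:
                key = (
                    ("soma_reflect", node_id, b2) if end == via else ("soma_pass", node_id, b2)
                )
            elif node.kind == GAP_JUNCTION:
                d_in = _gj_dendrite_of(node, via)
                d_out = _gj_dendrite_of(node, end)
                if end == via:
                    key = ("gj_reflect", node_id, d_in)
                elif d_out == d_in:
                    key = ("gj_pass", node_id, d_in)
                else:
                    key = ("gj_cross", node_id, d_out)
            else:  # pragma: no cover
                raise NetworkError(f"node {node_id!r}: unhandled kind {node.kind!r}")
            # finish into y?
            if b2 == yseg:
                leg = yloc if e2 == "prox" else br2.length - yloc
                push_done(total + leg, (key, b2, leg, path), slope)
            # continue to the far end of the entered branch
            far_end = "dist" if e2 == "prox" else "prox"
            far_node = network.node_at(b2, far_end)
            if far_node is not None:
                leg = br2.length
                push_arrive(total + leg, far_node, (b2, far_end), (key, b2, leg, path), slope)
            # a semi-infinite branch not hosting y is a dead end: nothing pushed


def enumerate_trips(
    network: Network,
    x: PointLocation,
    y: PointLocation,
    cutoff: float,
    max_trips: int | None = None,
) -> TripExpansion:
    """Exhaustively enumerate all trips of physical length <= cutoff.

    Raises :class:`NetworkError` if the cutoff excludes even the shortest
    trip (empty expansion).
    """
    xseg, xloc = locate(network, x)
    yseg, yloc = locate(network, y)
    trips: list[Trip] = []
    exhausted = True
    for total, path, slope in _iter_trips(network, xseg, xloc, yseg, yloc):
        if total > cutoff:
            exhausted = False
            break
        trips.append(_trip_from_path(path, xseg, slope, total))
        if max_trips is not None and len(trips) >= max_trips:
            exhausted = False
            break
    if not trips:
        raise NetworkError(
            f"cutoff {cutoff} um excludes every trip from {x} to {y} (empty expansion)"
        )
    return TripExpansion(trips=trips, cutoff=cutoff, x=(xseg, xloc), y=(yseg, yloc), exhausted=exhausted)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

class GreensEvaluator:
    """Adaptive evaluation of Ghat(x, y, omega) on one network.

    Enumerates trips lazily (ascending physical length) and, per omega
    batch, sums shell by shell until the last shell's modulus contribution
    drops below ``tol`` times the running sum for two consecutive shells.
    The enumeration is shared across omega batches and across nearby x
    offsets (``profile``), since trip lengths depend on x only through
    +/- dx on the first leg.
    """

    def __init__(self, network: Network, x: PointLocation, y: PointLocation):
        self.network = network
        self.xseg, self.xloc = locate(network, x)
        self.yseg, self.yloc = locate(network, y)
        self._gen = _iter_trips(network, self.xseg, self.xloc, self.yseg, self.yloc)
        self._trips: list[Trip] = []
        self._exhausted = False

    #: hard cap on enumerated trips; beyond this the series is declared
    #: non-convergent (the geometry decays too slowly for length-ordered
    #: truncation at the requested tolerance)
    max_trips: int = 300_000

    def _extend_to(self, cutoff: float) -> None:
        while not self._exhausted and (
            not self._trips or self._trips[-1].total_length <= cutoff
        ):
            if len(self._trips) >= self.max_trips:
                raise ConvergenceError(
                    f"trip enumeration exceeded {self.max_trips} trips before "
                    f"reaching cutoff {cutoff:.0f} um; the trip series decays too "
                    "slowly at this frequency (try larger |omega| or a looser "
                    "tolerance)"
                )
            try:
                total, path, slope = next(self._gen)
            except StopIteration:
                self._exhausted = True
                return
            self._trips.append(_trip_from_path(path, self.xseg, slope, total))

    def _shell_width(self, kernels: FrequencyKernelSet) -> float:
        gmin = min(
            float(np.min(kernels.gamma_params(b.params).real))
            for b in self.network.branches.values()
        )
        gmin = max(gmin, 1e-6)
        return 2.0 / gmin

    def _bulk_shell(self, trips: list[Trip], kernels: FrequencyKernelSet):
        """Sum a shell of trips in bulk: returns (s_plus, s_minus), the
        per-omega totals of the trips whose length grows (+) or shrinks (-)
        with the x coordinate. Coefficients are assembled as
        exp(C @ log F - L @ Gamma)/2 with integer factor multiplicities C
        (exact for any log branch)."""
        n_omega = kernels.omega.size
        if not trips:
            z = np.zeros(n_omega, dtype=complex)
            return z, z.copy()
        fcols: dict[tuple, int] = {}
        bcols: dict[str, int] = {}
        for t in trips:
            for key in t.factors:
                fcols.setdefault(key, len(fcols))
            for b, _ in t.seg_lengths:
                bcols.setdefault(b, len(bcols))
        C = np.zeros((len(trips), len(fcols)))
        L = np.zeros((len(trips), len(bcols)))
        slope = np.empty(len(trips))
        for i, t in enumerate(trips):
            slope[i] = t.x_slope
            for key in t.factors:
                C[i, fcols[key]] += 1.0
            for b, ell in t.seg_lengths:
                L[i, bcols[b]] += ell
        F = np.empty((len(fcols), n_omega), dtype=complex)
        for key, col in fcols.items():
            F[col] = factor_value(kernels, key)
        G = np.empty((len(bcols), n_omega), dtype=complex)
        for b, col in bcols.items():
            G[col] = kernels.gamma_of(b)
        with np.errstate(divide="ignore", invalid="ignore"):
            logF = np.log(F)
        # an exactly-zero factor gives log = -inf, which would poison the
        # matmul through 0*inf = nan; a huge finite negative works the same
        bad = ~np.isfinite(logF.real)
        if np.any(bad):
            logF[bad] = -1e300
        expo = C @ logF - L @ G
        with np.errstate(over="ignore", under="ignore"):
            contrib = 0.5 * np.exp(expo)
        pos = slope >= 0
        return contrib[pos].sum(axis=0), contrib[~pos].sum(axis=0)

    def evaluate(
        self,
        omega,
        tol: float = 1e-10,
        max_shells: int = 60,
        x_offsets=None,
    ) -> np.ndarray:
        """Ghat at omega (scalar or array). With ``x_offsets`` (array of
        shifts dx, um, all small enough that no node or y lies between),
        returns shape (len(x_offsets),) + omega.shape evaluated at
        x + dx on x's segment."""
        omega_arr = np.asarray(omega, dtype=complex)
        kernels = FrequencyKernelSet(self.network, omega_arr.ravel())
        yparams = self.network.branches[self.yseg].params
        pref = 1.0 / (
            yparams.c_len * yparams.D * kernels.gamma_params(yparams)
        )
        gx = kernels.gamma_params(self.network.branches[self.xseg].params)

        offsets = None if x_offsets is None else np.asarray(x_offsets, dtype=float)
        width = self._shell_width(kernels)
        nflat = kernels.omega.shape
        acc_plus = np.zeros(nflat, dtype=complex)
        acc_minus = np.zeros(nflat, dtype=complex)
        shell_edge = width
        calm = 0
        idx = 0
        shells_done = 0
        self._extend_to(shell_edge)
        while True:
            hi = idx
            while hi < len(self._trips) and self._trips[hi].total_length <= shell_edge:
                hi += 1
            s_plus, s_minus = self._bulk_shell(self._trips[idx:hi], kernels)
            idx = hi
            acc_plus += s_plus
            acc_minus += s_minus
            if self._exhausted and idx >= len(self._trips):
                break
            shells_done += 1
            acc_abs = np.abs(acc_plus + acc_minus)
            scale = np.max(acc_abs)
            # per-omega relative shell contribution (frequencies in one
            # batch can decay at very different rates), with a floor so a
            # single near-zero component cannot stall convergence; use the
            # *cancelled* shell sum: near a node trips arrive in nearly
            # cancelling pairs (e.g. +/-1 terminal reflections) and the
            # truncated tail cancels to the same degree
            shell_abs = np.abs(s_plus + s_minus)
            denom = np.maximum(acc_abs, 1e-6 * scale) if scale > 0 else acc_abs
            shell_mag = float(np.max(shell_abs))
            if scale > 0 and np.all(shell_abs <= tol * denom):
                calm += 1
                if calm >= 2:
                    break
            else:
                calm = 0
            if shells_done >= max_shells:
                raise ConvergenceError(
                    f"trip series not converged after {max_shells} shells "
                    f"(last shell contribution {shell_mag:.3e} vs "
                    f"sum {scale:.3e}, {len(self._trips)} trips)"
                )
            shell_edge += width
            self._extend_to(shell_edge)
        if offsets is None:
            out = (acc_plus + acc_minus) * pref
            return out.reshape(np.shape(omega)) if np.shape(omega) else out[0]
        shift = np.exp(-np.multiply.outer(offsets, gx))
        out = (acc_plus[None, :] * shift + acc_minus[None, :] / shift) * pref[None, :]
        return out.reshape((len(offsets),) + np.shape(omega)) if np.shape(omega) else out[:, 0]

    @property
    def n_trips(self) -> int:
        return len(self._trips)


def greens_laplace(
    network: Network,
    x: PointLocation,
    y: PointLocation,
    omega,
    tol: float = 1e-10,
    max_shells: int = 60,
):
    """Ghat_ij(x, y, omega) by adaptively truncated sum-over-trips.

    omega may be a complex scalar or array; the result matches its shape.
    Raises :class:`ConvergenceError` if the length-shell contributions have
    not fallen below ``tol`` (relative) within ``max_shells`` shells.
    """
    return GreensEvaluator(network, x, y).evaluate(omega, tol=tol, max_shells=max_shells)
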