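# Methods

## Model

Each branch of each cell is a uniform cable with transmembrane dynamics
given by the linearised ('quasi-active') membrane: a leak pathway (R), a
capacitive pathway (C) and an inductive pathway (resistance r in series
with inductance L). The voltage on branch i obeys

    ∂V/∂t = D ∂²V/∂x² − V/τ − (I_L − I_inj)/C,
    L ∂I_L/∂t = −r I_L + V,

with D = a/(4 R_a C) and τ = C R. Passive ('RC') membrane is the limit
r → ∞ (the inductive pathway carries no current); the code represents it
by omitting r and L rather than by a large finite r, which keeps the
kernel free of a spurious pole. In the Laplace domain the branch is
characterised by the decay rate

    γ²(ω) = [1/τ + ω + 1/(C(r + ωL))] / D,

with the principal square root flipped onto Re γ ≥ 0 so that e^(−γx)
decays. All poles and branch points of the kernels lie on the negative
real ω axis (the inductive pole at −r/L, the soma's at −r_s/L_s, the
γ² = 0 roots), so the closed right half plane and the positive real axis
are always safe evaluation regions.

Cells are joined into one extended tree by typed nodes: sealed or open
terminals, branch points (continuity + Kirchhoff with weights 1/r_a,
r_a = 4R_a/(πa²)), lumped somata (an iso-potential sphere of diameter a_s
whose admittance γ_s(ω) = C_s ω + 1/R_s + 1/(r_s + L_s ω), a specific
admittance scaled by the membrane area πa_s², enters the somatic current
balance), and gap junctions: a node with four incident branch ends, two
per host dendrite, imposing voltage continuity along each dendrite and a
junction current g_GJ ΔV, g_GJ = 1/R_GJ, between them.

### Units

Internally {μm, ms, mV, nA, MΩ}: then mV/nA = MΩ and MΩ·nF = ms, so the
Ohmic and RC relations are coefficient-free. Specific constants are
converted at ingest (1 μF/cm² = 10⁻⁵ nF/μm², 1 Ω cm² = 100 MΩ μm²,
1 H cm² = 10⁵ MΩ ms μm², 1 Ω cm = 10⁻² MΩ μm). The soma's admittance is
made absolute with its total membrane area πa_s²; for the reference soma
(a_s = 25 μm, R_s = 2000 Ω cm²) this gives γ_s(0) = 9.82·10⁻³ MΩ⁻¹,
commensurate with the N·z ≈ 0.18 MΩ⁻¹ input admittance of four reference
dendrites — the soma genuinely loads the tree.

### Response normalisation

Every Green's function carries the prefactor 1/(c_j D_j γ_j) with
c_j = C_j π a_j the capacitance per unit length of the *stimulated*
branch, making G(x, y, t) a voltage in mV per nA·ms of injected impulse
and V(t) = (G ⊛ I)(t) a voltage in mV for currents in nA. One uniform
convention is used across the trip engine, the two-cell closed forms and
the word series, so the oracle-equivalence tests compare like with like.
The preferred frequency and all normalised power functions are invariant
to this choice.

## Sum-over-trips engine

Trips from x to y are enumerated exhaustively in ascending *physical*
length by uniform-cost search over (branch-end, direction) states, so one
enumeration serves every frequency. Trip identity is the event sequence;
the degenerate x = y zero-length trip counts once; a semi-infinite branch
not hosting y is never entered (no trip can return from infinity). A
gap-junction traversal that stays on one dendrite is a single
"pass" event (factor 1 − p_GJ of the other dendrite), never decomposed
into reflect + cross.

Evaluation sums trips in length shells of width 2/min_k Re γ_k and stops
when the shell contribution falls below the requested relative tolerance
for two consecutive shells, *per frequency* (a batch may mix fast- and
slow-decaying ω) and with a floor of 10⁻⁶ of the batch scale so a single
near-zero component (e.g. an observation point at an open terminal,
where trips cancel in ±1 pairs) cannot stall truncation. Shell sums are
assembled in bulk as exp(C·log F − L·Γ)/2 with integer factor
multiplicities C — exact for any log branch — which keeps the cost of a
10⁵-trip expansion at a few matrix products. A hard cap (3·10⁵ trips,
60 shells) converts pathologically slow geometries into an informative
`ConvergenceError` instead of unbounded work; slow decay arises when
γ·(typical segment length) is small compared to the log of the local
branching factor, and evaluating at larger |ω| restores fast convergence.

An observation point lying exactly on a node is assigned to a designated
incident segment (the query's segment); value continuity makes the two
conventions agree, which is asserted in tests.

## Closed forms

For two identical infinite cables coupled at x = 0 the trip set is
finite: the same-cell response is the free kernel minus a p_GJ-weighted
image term, the cross-cell response is p_GJ times the image kernel, with
p_GJ = 1/(2(zR_GJ + 1)). The heterogeneous pair replaces p_GJ by
p_GJ,m/p_GJ,n and scales x and y by their own cells' γ. For two
soma-plus-N-dendrite cells the trips organise into four families that
resum geometrically (the "word series"): the somatic responses are

    Ĝ₁(0, y₀, ω) = 2p_s(1 − p_GJ)Ĝ∞(y₀) +
        Σ_n 2ⁿ(−p_GJ(2p_s−1))^{n+1}(1 − 2p_GJ)·2p_s·Ĝ∞(y₀ + 2(n+1)L_GJ),

and likewise for the stimulated cell's partner with p_GJ and
(2p_GJ − 1) leading factors. The per-term ratio is
2|p_GJ(2p_s − 1)|e^(−2γL_GJ); at the reference parameters it is ≤ 0.4
even at L_GJ = 50 μm, and for L_GJ ≥ 100 μm truncation at n = 10 vs
n = 20 already agrees to better than 10⁻⁶. Terms are summed ascending;
no resummation is needed.

For passive membrane the two-cell solutions invert analytically. The
implementation evaluates every exp·erfc product through the scaled
complement erfcx so nothing overflows, and computes pulse responses
V(t) = S(t) − S(t − τ_R) with the steady-state parts of the two step
responses cancelled *analytically* — the naive difference of two
near-steady values loses up to five digits in the response tail. The
partial-fraction weights of the junction term are a = 1/(q² − ε²),
b = 1/(2ε(ε − q)), c = 1/(2ε(ε + q)) with q = r_a/R_GJ and ε = 1/√(Dτ)
(derived from 1/ω = 1/(D(γ−ε)(γ+ε)); the derivation is re-verified
against numerical inversion in the tests). The degenerate case q = ε has
singular weights and raises with guidance to perturb R_GJ.

## Inverse Laplace transform

The primary scheme is the Euler-accelerated Fourier-series (Bromwich
line) method: samples at ω_k = (M ln10/3 + iπk)/t, binomially weighted
alternating summation, M = 24 by default. All samples lie in the right
half plane; left-plane contour deformations (Talbot-style) are *invalid*
here because the kernels' poles and the γ branch cuts sit on the
negative real axis, where such contours wrap. Discretisation error
scales like 10^(−M/3) and round-off like 10^(+M/3)·eps on the transform
scale, so double precision certifies roughly 10⁻⁸ relative to the peak.
Responses decay exponentially, so pointwise relative accuracy deep in
the tail (the impulse response at t = 50 ms spans e^(−25) of dynamic
range) is unreachable at any fixed double-precision scheme; where the
per-point error estimate exceeds the target, those points are
re-inverted in arbitrary precision (mpmath, de Hoog rational
acceleration), doubling the working precision until two rounds agree.
The analytic kernels accept mpmath scalars natively for this purpose;
transforms that cannot (the truncated trip expansion) fall back to an
`AccuracyWarning` carrying the achieved-error estimate.

Rectangular pulses are handled as exact time shifts of the step response
(the e^(−ωτ_R) delay factor oscillates along the Bromwich line and
defeats Euler acceleration if inverted directly); tail points whose
shift difference cancels are re-inverted from the product transform in
arbitrary precision. Chirp stimuli, whose transform involves Fresnel
integrals, are convolved in the time domain on a uniform grid with step
at most a twentieth of the shortest instantaneous period reached.

## Resonance

The power function is P(Ω) = |Ĝ(Ω)|² with the Laplace variable on the
positive real axis. For resonant membrane the inductive admittance
1/(r + ΩL) falls while the capacitive term Ω rises, so γ(Ω) has an
interior minimum at Ω* = √(1/(LC)) − r/L — 0.42721 rad/ms for the
reference dendrite — and every quantity that is a function of γ alone
peaks exactly there: on the infinite-cable pair the preferred frequency
is therefore *identical on all four segments* and *independent of
R_GJ*. Once a lumped soma enters, γ_s(ω) has its own frequency
dependence and the somatic Ω₀ becomes location- and coupling-dependent:
the gap-junction-location sweeps (y₀ = L_GJ + 10 μm, word series at
n = 20, Ω₀ by 0.005 rad/ms grid scan plus golden-section refinement to
10⁻⁵ on [10⁻³, 5]) show Ω₀ increasing with L_GJ for a passive soma with
resonant dendrites and decreasing whenever the soma is resonant.
Passive membrane is low-pass: P is monotone and the search reports a
boundary maximum with a warning.

A distinct frequency is the Fourier-magnitude peak, argmax_Ω |Ĝ(iΩ)|
(≈ 0.46 rad/ms at the reference parameters). A chirp's envelope peaks
where its instantaneous frequency 2ω_c t crosses *that* value (verified
within 10% in the tests); the real-axis Ω₀ sits a few percent below it.

Responses of resonant membrane also carry a slow rebound tail governed
by the inductive pole −r/L (−0.02 ms⁻¹ here): a pulse response is small
but not negligible at 100 ms (≈ 10⁻⁵ of peak), unlike passive membrane
whose e^(−t/τ) tail is gone. The long-time decay tests distinguish the
two cases accordingly.

Electrical coupling strength between the cells is quantified, as is
standard for electrically coupled neurons, by the steady-state coupling
coefficient — the DC voltage transfer ratio between the observation
points — which at R_GJ = 10⁹ MΩ is below 10⁻¹¹ (decoupled); at finite
frequencies the frequency-resolved ratio p_GJ(ω)e^(−2γ(ω)(y−x)) is
larger wherever γ dips, as the closed form makes explicit.

## Validation surface and synthetic networks

The residual operators re-derive the node boundary conditions from the
*assembled* solution: Ĝ is evaluated at 0, h, 2h, 4h (h = 0.01 μm) from
each node along each incident segment in one trip enumeration (lengths
shift by ±dx on the first leg only), one-sided 3-point derivatives at
steps h and 2h are Richardson-combined once, and continuity, Kirchhoff,
somatic-admittance, terminal and junction-current residuals are reported
relative to the local solution scale. The profile's reference point sits
at 4h inside the segment, not on the node, because an open terminal's
value vanishes identically there and would starve a relative truncation
test. The trip-series tolerance for residual work is 3·10⁻⁶, keeping the
truncation contribution several orders below the 10⁻⁵ acceptance scale
at modest cost; measured residuals on the random ensemble are 10⁻¹²–10⁻⁸.

The random-network generator emulates small dendro-dendritically coupled
pairs: per cell a soma (passive or resonant), one finite primary
dendrite (250–500 μm) hosting the junction at a random interior point, up
to two further finite or semi-infinite children with random sealed/open
terminals, one semi-infinite dendrite at the soma, membrane constants
log-uniform within half a decade of the reference values (diameters
within 0.2 decades, axial resistivity within 0.3 — wider spreads push
γ·length low enough that length-ordered truncation becomes combinatorial),
and R_GJ log-uniform over 1–1000 MΩ. Residual identities hold at any ω;
they are checked at Re ω ∈ [5, 15], |Im ω| ≤ 5, where trips decay within
a few segment lengths. What these synthetic networks do *not* emulate:
realistic morphometry (taper, branch-order statistics), dendritic spines,
nonlinear conductances, or more than one junction per pair — so passing
residuals demonstrate correctness of the boundary algebra, not
biological realism.

## Problem sizes

The test suite runs the full residual ensemble (50 networks × 10
frequencies), the three sweep configurations at ten junction locations ×
two resistances, oracle equivalences at 20–50 random complex
frequencies, and inversion checks on ~8-point time grids spanning
0.5–50 ms; the complete suite takes a few minutes on one core, with the
residual ensemble the largest item.

## Known limitations

* Length-ordered truncation is exhaustive in trip count; geometries whose
  γ·segment-length is small against the branching entropy converge
  slowly and may hit the trip cap at low |ω| (the error message says so).
* A gap junction exactly at a sealed branch tip is not representable
  (a junction at x = 0 requires a plain two-way junction to absorb);
  place it an arbitrarily small distance inside instead.
* Zero initial data is assumed throughout; initial-value terms of the
  superposition formula are out of scope.
* The word series covers observation points between soma and junction
  only; other placements go through the trip engine.
* Chirp responses use fixed-grid convolution; very fast chirps
  (ω_c t² sweeping beyond ~5 rad/ms within the window) need a finer grid
  than the default heuristic.
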