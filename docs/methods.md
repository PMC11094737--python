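# Methods

`gqpull` quantifies the mechanical unfolding of tetramolecular
parallel-stranded G-quadruplexes (GQs) from pulling trajectories. This
note records the models and operational definitions the package
implements, the choices made where several definitions were defensible,
and what the synthetic test substrate does and does not demonstrate.

## The system and its frame of reference

A tetramolecular parallel GQ consists of four strands, all oriented
5'→3' the same way, each contributing one *anti* guanine to every
G-quartet. Within a quartet each G donates two hydrogen bonds from its
Watson–Crick (WC) edge (N1–H···O6 and N2–H···N7) to the next strand
around the channel and accepts two on its Hoogsteen edge from the
previous strand — eight bonds per quartet. Monovalent cations (K⁺ here)
occupy the channel between adjacent quartets.

All analyses are phrased relative to a `StemTopology`: the four strands
in fixed cyclic order (strand *s* donates to strand *s+1* mod 4), the
quartet membership per stacking level (level 0 = 5'-most), the flanking
thymines whose C2/C4/C6 geometric centers act as pulling anchors, and an
indexing of the eight strand ends, termini 1–4 for the 5' ends of
strands 1–4 and 5–8 for their 3' ends. A pulling setup is then named by
its anchor pair, e.g. `3Q^1-8` for a three-quartet stem pulled between
terminus 1 and terminus 8.

## Quartet-plane geometry

Each quartet is summarised by the best-fit plane through the heavy atoms
of its four guanine bases (ring atoms plus exocyclic O6 and N2; sugars
and phosphates are excluded because they would corrupt the base-plane
fit). The fit is the SVD of the centred coordinates; the singular vector
of smallest variance is the plane normal, and the planarity is

  P = σ₃ / √N,

identically the RMSD of the signed atom–plane distances. Planarity,
tilt, rise and |twist| are invariant under rigid motion of the frame;
this is property-tested.

Per quartet–quartet step the package reports:

- **tilt** — angle between the two plane normals after co-orienting all
  normals with the 5'→3' stem axis (SVD normal signs are arbitrary);
- **rise** — a single plane is fitted to the pooled base atoms of both
  quartets, and the rise is the sum of the two quartet centroids'
  unsigned distances from it. The alternative reading (plane normal =
  bisector of the two individual co-oriented normals through the
  mid-centroid) is exposed as `rise(..., method="bisector")` but is not
  the default: the pooled fit stays well-defined for strongly tilted
  quartets. For parallel quartets the two definitions agree exactly.
- **step twist** — signed rotation about the stem axis, positive for a
  right-handed advance 5'→3', in (−180°, 180°].

The **stem axis** is the principal direction through the quartet
centroids, oriented 5'→3'; for two quartets it degenerates to the
normalised centroid difference. The **total twist** is the sum of step
twists and its sign is the handedness of the helix.

Two twist estimators are provided. The default (`twist_method="matched"`)
projects all strand-matched base-atom pairs of the two quartets onto the
plane orthogonal to the axis and takes the angle of the summed
cross/dot products; it is exact for a rigid helical step and averages
isotropic coordinate noise over ~44 atom pairs (≈0.15–0.4° error at
σ = 0.2 Å noise). The single-reference variant
(`twist_method="reference_atom"`, centroid→N9 of one strand's G) is
simpler to interpret but carries the full noise of one atom at ~8 Å
radius (≈1.3° at the same noise level), which is why it is not the
default. For ideal geometry the two differ only through noise.

Degenerate inputs (fewer than 3 points, collinear clouds, reference
vectors parallel to the axis, coincident centroids) raise
`DegenerateGeometryError` naming the quartet; arccos arguments are
clamped to [−1, 1]; angles are degrees, distances Å.

## Pulling forces

The pull is a moving harmonic distance restraint between the C2/C4/C6
centers of two terminal thymines: center c(t) = d₀ + v·t with force
constant k = 180 kJ mol⁻¹ nm⁻² and speed v = 5.4 nm μs⁻¹ by default.
The spring force on the distance coordinate is F = k·(c − d), converted
with the fixed constant

  1 kJ mol⁻¹ nm⁻¹ = 1.660539 pN  (10²¹/N_A),

stated here so outputs are bit-reproducible. Positive force stretches
the anchors apart; compressive episodes are negative and |F| enters all
averages.

The force's **out-of-plane angle** β is measured against the average
quartet plane (mean of the co-oriented per-quartet normals,
renormalised), computed per frame from the instantaneous planes — not
the starting structure — so that elastic deformation is reflected in the
decomposition. β = 0 for an in-plane force; the sign follows the 5'→3'
normal. F_h = F·cos β, F_v = F·sin β, and the vertical-to-horizontal
ratio equals tan β, keeping β's sign (anchor pairs placed "upside down"
relative to the reference plane legitimately produce negative ratios).
A vanishing force returns NaN for β rather than raising: the spring
force crosses zero in real traces.

The **force–edge overlap** of a designated guanine is

  feo = (|F·u_wc| − |F·u_h|) / |F| ∈ [−1, 1],

where u_wc is the normalised mean of its two WC-edge H-bond unit vectors
and u_h of its two Hoogsteen-edge ones; positive feo means the pull
aligns better with the WC edge. Edge-vector signs cancel in the absolute
values.

The **rupture force** is the maximum of the running average of |F| over
a 2 ns window, taken over all window positions lying wholly before the
first stem-altering unfolding event. A window spans the m samples with
(m−1)·Δt ≤ 2 ns. Because the maximum ranges over every admissible
window position, centered and trailing labelings select the same window
set; the **transition force** of each subsequent event is the average of
|F| over the trailing 2 ns window ending at the event time (window
truncated with a warning at the trajectory start). The window length is
a parameter everywhere.

## H-bond state and register

A bond is present iff donor–acceptor distance ≤ 3.5 Å and, when the
donor hydrogens exist in the topology, donor–H–acceptor angle ≥ 135°;
for hydrogen-free topologies a distance-only criterion at 3.4 Å applies
(both cutoffs inclusive). Bonds are evaluated for all level combinations
of adjacent strand pairs, which makes register shifts observable: a
strand's **register offset** is the modal partner-level shift of its
bonds versus the native assignment (per-residue detail preserved;
modal ties break toward 0, then toward the negative shift; a strand with
no inter-strand bonds has an undefined offset and is a detachment
candidate).

## Event classification

The classifier is deliberately rule-based with every threshold in
`ClassifierParams`; the taxonomy covers unzipping, strand slippage,
opening, detachment, spiral formation/resolution, cross-like strand
rotation, refolding and anchor-T unstacking. Operational definitions:

- **unzip** — a G loses all four quartet bonds while its quartet's other
  members remain mutually bonded; the G must have been solidly bonded
  within the preceding 30 frames (a long-free G whose neighbours merely
  flicker is not a new transition).
- **strand_slippage** — the register offset steps by ±1 and holds, with
  bonds re-formed at the new level.
- **opening** — a strand loses every bond to exactly one neighbour
  across ≥2 levels while keeping ≥2 levels with the other neighbour. The
  event is attributed to the strand that moved (larger displacement than
  the lost neighbour), and a neighbour that lost all of its own bonds
  (it detached or flipped) cannot charge this strand with an opening.
- **detachment** — zero inter-strand bonds *and* minimum base-atom
  distance to the rest above 8 Å; terminal for the strand (permanence is
  asserted on all outputs).
- **spiral_form** — per-residue fractional level offsets monotone with
  spread ≥ 0.7 level, cumulative extra backbone winding about the axis
  ≥ 45° per slipped level, strand still roughly axis-aligned (< 60°)
  and attached; the winding sign gives the handedness. **spiral_resolve**
  fires when that state ends, with the outcome (back to native, or
  slippage completed) judged once the transition settles.
- **rotation_crosslike** — the strand's end-to-end vector makes > 120°
  with the stem axis while contacts persist.
- **refold** — the complete native bond set returns after an unresolved
  perturbation (a native-restoring spiral resolution leaves nothing to
  refold).
- **anchorT_unstack** — a flanking T separates from its own terminal G
  by > 6 Å *and* is the moving party; it alters no stem H-bond and never
  counts as the first stem event.

Geometric strand features (fractional level offsets, winding, axis
angle) are measured in a reference frame obtained by rigidly superposing
the native (first-frame) structure onto the currently still-bonded Gs of
the *other three* strands. This keeps the reference frame from being
dragged by the strand under evaluation or by previously displaced Gs,
and makes the features invariant under rigid motion of the whole system.

Commitment requires a predicate to hold for the persistence window
(default 10 frames); ties break by frame, then by a fixed precedence
(detachment > rotation > spiral > slippage > opening > unzip > refold).
Single-G unzip signatures that appear within 30 frames of a committed
strand-level event of the same strand are absorbed by it: a slipping,
spiralling, rotating or detaching strand necessarily strips bonds from
individual Gs on the way.

The **first unzip edge** compares, for the first unzipped G, the frames
at which its WC-side and Hoogsteen-side bonds last vanished before the
event; simultaneous loss within one frame reports "both". If the first
stem event is not an unzip, the record says "n/a".

**Channel occupancy**: a site between adjacent quartets is occupied in a
frame iff an ion's projection on the stem axis lies strictly between the
two quartet centroids' projections and its distance from the axis is
≤ 2.5 Å (the channel-radius scale); reported as the percentage of
frames per site.

## Synthetic substrate

The generator builds an idealised stem and choreographs labelled events;
it is the ground truth for every recovery test. Key choices:

- **Quartet assembly.** The guanine and thymine bases use standard
  planar reference-frame heavy-atom coordinates; the backbone is
  represented minimally (C1′ and the glycosidic nitrogen), which is all
  the analyses need. The quartet is assembled by solving for the rigid
  in-plane placement of the guanine template that realises the cyclic
  N1···O6 / N2···N7 bonding at 2.90 Å under exact C4 symmetry. These two
  constraints pin the quartet geometry rigidly: only two solution
  branches exist, one physical (O6 carbonyls lining the channel) and one
  with overlapping bases. The blueprint's `c1_radius` therefore acts as
  a branch selector rather than a free parameter; the physical branch
  has a C1′ radius of ≈ 8.2 Å.
- **Defaults** — 3–5 quartets, 3.4 Å rise and +30° right-handed twist
  per step (the helical parameters of the crystallographic tetramolecular
  parallel stem the package is aimed at), one channel K⁺ per
  inter-quartet site, flanking Ts at both termini continuing the helix.
- **Deformations** — per-frame twist/rise schedules (scalar or
  per-step) and single-base buckling about the in-plane tangential axis,
  plus seeded Gaussian coordinate noise. Injected values are recovered
  exactly without noise; with σ = 0.2 Å noise, trajectory-mean recovery
  is within 1° / 0.1 Å.
- **Event choreography** is linear interpolation of rigid sub-group
  motions ramped over the frames preceding each event's scripted frame,
  so the event's defining geometric condition first holds at the
  scripted frame and persists. No physics is claimed; the contract is
  label fidelity. Unzips slide the base along the breaking edge's bond
  direction (a hinge cannot break the Hoogsteen edge first because O6 is
  nearly collinear with the N1–N2 line), then extract it radially;
  openings move each residue along its own level's bond direction
  (orientations rotate with the helical twist, so a space-fixed
  translation would break levels unevenly); spirals combine a monotone
  partial level shift with 60° of extra winding; detachment is a ≥15 Å
  rigid radial separation.
- **Force traces** rise to a scripted plateau held for 4 ns before each
  rupture, then drop; the distance column is derived from the (noisy)
  force so that spring-force reconstruction from (time, distance,
  center) matches the stored bias to < 10⁻⁶ pN.
- **Determinism** — identical inputs and seed give bit-identical
  trajectories and traces.

What the synthetic substrate does *not* emulate: thermal fluctuation
structure beyond isotropic Gaussian noise, solvent and realistic ion
dynamics, backbone sterics, force-field-dependent kinetics, and the
co-occurrence statistics of real unfolding pathways. Passing recovery
tests therefore demonstrates the correctness of the *definitions and
estimators*, not that the classifier thresholds are optimal for any
particular simulation ensemble; on real trajectories the thresholds in
`ClassifierParams` are the knobs to revisit.

Ensemble-shape statistics (fraction of runs whose first stem event is
3'-initiated, spiral handedness split, refolding fraction) are computed
by classifying scripted ensembles; they exercise the whole
pipeline-and-statistics path, with the scripted composition — not the
physics — setting the expected values.

## Classification-threshold defaults

| parameter | default | unit | role |
|---|---|---|---|
| `d_cut` / `d_cut_no_h` | 3.5 / 3.4 | Å | H-bond distance cutoffs |
| `angle_cut` | 135 | ° | donor–H–acceptor angle |
| `persistence` | 10 | frames | commitment window |
| `detach_min_dist` | 8.0 | Å | strand separation for detachment |
| `rotation_angle` | 120 | ° | end-to-end vs axis |
| `spiral_offset_range` | 0.7 | levels | partial-slippage spread |
| `spiral_wind_per_level` | 45 | ° | extra winding per slipped level |
| `spiral_align_max` | 60 | ° | spiral must stay axis-aligned |
| `t_unstack_dist` | 6.0 | Å | anchor-T separation |
| `suppress_window` | 30 | frames | strand-event absorption of unzips |
| `strand_move_min` | 1.0 | Å | minimum motion for spiral calls |

## Known limitations

- The classifier assumes the trajectory starts in (or near) the native
  state; frame 0 defines the register, winding and orientation
  references.
- Multiple simultaneous strand-scale events inside one persistence
  window resolve by precedence, not joint inference.
- Geometric strand features degrade when fewer than two bonded reference
  Gs remain on the other strands (late-stage unfolding); H-bond-derived
  calls (unzip, slippage, opening, detachment) are unaffected.
- Interlocked/multimeric species and G-triplex-specific descriptors are
  out of scope; the stem is analysed as a single tetramolecular unit.
- Problem sizes in the test-suite and in `scripts/acceptance.py`
  (hundreds of frames per scripted run, ensembles of tens of runs) are
  the package's chosen demonstration scale; all estimators are O(frames)
  and run unchanged on longer inputs.
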