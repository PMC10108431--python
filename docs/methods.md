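# Methods

## The problem

A mathematical knot is a property of a *closed* curve; a protein
backbone is open. The standard way to assign a knot type to an open
chain is stochastic closure: connect both termini to a random point far
outside the structure, compute the knot type of the resulting closed
curve with a polynomial invariant, and repeat. The resulting frequency
distribution over knot types is robust to the arbitrariness of any
single closure, and its mode (the *dominant knot*) is the chain's type.
`knotscan` applies this machinery to predicted protein models, locates
the minimal knotted subchain, and judges whether a predicted knot is
credible from the model's own confidence estimates and from the
conservation of the topology among homologous proteins.

## Stochastic closure

The closure point is sampled uniformly on a sphere centred at the
chain's Cα centroid with radius `closure_radius_factor` (default 10)
times the maximal centroid-to-Cα distance; the closed curve is
C-terminus → sphere point → N-terminus. Ten structure radii keep the
two closure segments essentially radial, so the closure rarely threads
the structure itself; the residual ambiguity is exactly what the
frequency spectrum quantifies. The default of 200 closures for a
headline call gives a standard error below 0.04 on any closure
fraction; subchain matrix cells use 50 closures (standard error ~0.07)
as a cost/precision compromise. Each closure draws from an RNG stream
seeded by (seed, closure index), so spectra are bit-reproducible and
independent of evaluation order.

A per-chain optimisation: the open chain is KMT-reduced once with fixed
ends before the closure loop, and each closed curve is reduced again in
closed mode. The closure arcs attach to the original (fixed) termini,
and the validity of the shortcut is covered by the planted-knot
recovery tests, which exercise exactly this path.

## KMT reduction

The Koniaris–Muthukumar–Taylor scheme deletes vertex *i* whenever the
triangle (*i*−1, *i*, *i*+1) is pierced by no other segment of the
curve — an isotopy, so the knot type is preserved — iterated to a fixed
point. Two implementation details matter:

* **Removals are committed one at a time.** Deleting a vertex replaces
  two segments by a new chord; a second vertex whose triangle was empty
  with respect to the *old* segments may be pierced by that chord.
  Each candidate in a sweep is therefore re-validated against the
  chords created earlier in the same sweep, and skipped when a
  neighbour has already been removed. (Batch removal without this check
  demonstrably unties tight curves.)
* **Borderline hits count as pierced.** All triangle tests use
  conservative tolerances — a segment touching a triangle's boundary
  blocks the removal. Flat (planar) neighbourhoods get an exact 2-D
  overlap test instead of the degenerate 3-D one.

## HOMFLY-PT engine

Diagrams are stored as signed Gauss codes (per-component cyclic visit
sequences with over/under flags and crossing signs). A closed polygonal
curve becomes a diagram by projection along a direction: crossings are
segment-pair intersections in the projection plane, over/under from
depth, sign from the orientation of the projected tangents. Non-generic
projections (tangencies, endpoint hits, overlapping collinear spans,
near-equal depths) raise and the caller retries a perturbed direction;
disjoint collinear segments — ubiquitous after resampling straight
runs — are accepted.

The polynomial uses the skein convention
`l·P(L+) + l⁻¹·P(L−) + m·P(L0) = 0` with `P(unknot) = 1` and split
unions multiplying by `δ = −(l + l⁻¹)/m`. The recursion switches the
first crossing (in traversal order) whose first encounter is an
underpass; the switched diagram is strictly closer to a descending
(unlink) diagram and the smoothed one has one crossing fewer, so the
recursion terminates. Diagrams are simplified between steps
(Reidemeister I kinks and adjacent-bigon Reidemeister II pairs on the
Gauss code, split-component factoring) and memoised under a canonical
renumbering minimised over traversal starts; the memo is shared across
calls, which matters when 200 closures of the same chain produce nearly
identical reduced diagrams. Diagrams still above `crossing_cap`
(default 24) crossings after simplification raise; the typing layer
retries alternative projections and finally counts the closure under
the label `other`.

Knot labels are exact polynomial matches against a reference table
generated at run time from braid-word closures of the supported types
(3_1 … 7_2, the granny and square forms of 3_1#3_1), with both mirror
images inserted so chirality is collapsed. No polynomial constant is
transcribed from literature: the braid words themselves are gated, at
table-build time, by an independent Alexander-polynomial oracle (the
classical crossing-matrix determinant, evaluated symbolically) whose
values *are* classical table data. A wrong braid word fails loudly
instead of silently poisoning every downstream label.

## Knot fingerprint and core

The matrix model types every subchain (start, end) on a coarse grid
(default step 10, subchains shorter than 10 residues skipped), then
refines the boundaries of the minimal cell carrying the full-chain
label at single-residue steps. Each cell's closure seed derives
deterministically from (seed, start, end), so a cell evaluates
identically whether reached by the coarse pass, the refinement, or an
exhaustive sweep — the refined result provably matches the exhaustive
matrix wherever the same cells are visited (tested against a full
step-1 sweep on an 81-residue chain). Cells are labelled by plurality
of their closure spectrum, with ties resolved toward the unknot first
and lexicographically after.

The knot core is the shortest cell whose label equals the full-chain
label (ties → smaller start); its mean pLDDT is averaged over the core
residues; a knot whose shorter tail is below 5 residues is *shallow*.
Slipknot motifs are maximal regions of nontrivial cells that either
differ from the full-chain label or match it without containing the
core, reported as `K<full> <internal>`.

## Credibility rules

With the dominant knot nontrivial, five rules are evaluated:
nontrivial-majority (dominant frequency exceeds the unknot frequency),
core confidence (mean core pLDDT > 50), clash-freedom, homolog
conservation (> 80% of homologs share the type; *close* homologs are
those at ≥ 60% sequence identity and are reported separately), and
second-model agreement. *Knotted* requires all five to pass and always
raises a needs-visual-inspection flag — the manual step made explicit
rather than silently skipped. *Artifact* is reserved for structures
whose closures favour the unknot or whose core confidence is below the
pLDDT floor; everything else — including structures whose homolog table
or second model is simply unavailable — is *potentially knotted*:
missing evidence can never promote. Improving any single rule input
never demotes the verdict (property-tested over the full input grid).

The clash check is a Cα-geometry heuristic: any core pair at sequence
separation ≥ 3 closer than 3.0 Å fails. It replaces an external
all-atom contact analysis; on Cα-only traces it is the natural
equivalent and its threshold is configurable.

Homolog tables are inputs (TSV: id, knot label, identity in [0, 1]);
sequence searching is out of scope. For family-level summaries a
CD-hit-style greedy clustering is provided: sequences in descending
length order, each joining the first cluster whose founder it matches
at ≥ 60% identity, else founding a new one.

## Synthetic data

The generator emulates the *topology and confidence structure* of
predicted models, not their physics: idealised Cα traces with 3.8 Å
virtual bonds, a 4.0 Å minimum separation between residues at sequence
distance ≥ 3, Gaussian coordinate noise (default sd 0.2 Å), and pLDDT
profiles that are either uniform or low-over-the-core — the two shapes
needed to exercise every classification rule.

Planted cores start from verified closed curves: torus-knot
parametrizations for 3_1/5_1/7_1, the classical figure-eight curve for
4_1, braid-closure embeddings for the rest. Every curve is relaxed into
a near-ideal tube by a clearance-guarded equilibration (Laplacian
smoothing plus segment-segment repulsion, per-vertex displacement
capped at 0.3× the current minimal segment clearance so strand passage
within a step is geometrically impossible), and its knot type is
re-verified by the invariant engine before use. Tightness serves two
purposes: it maximises the clearance available at protein-like bond
density, and it minimises slack, so the planted window localises the
knot well. The 7_2 embedding does not stabilise under this scheme and
is rejected with an explicit error (its closed-curve geometry and its
label remain fully supported).

The closed curve is resampled to the requested core length (recommended
windows: 61 residues for 3_1, 91 for 4_1 through 6_3 and the composite,
131 for 7_1 — smaller windows cannot hold the tube at 4 Å
self-avoidance) and opened at a *screened* cut: every candidate cut is
probe-typed with a short closure run and the first whose open chain
retains the planted type in ≥ 90% of probes is kept. Tails are
escape-biased self-avoiding walks (a fixed jittered ray pointing away
from the core, per-step noise); because a tail can thread back through
a tight knot — either untying it or becoming an essential part of it —
each tail, and the noisy core itself, is validated by quick closure
probes (planted type preserved, and removable-tail subchains still
typed as planted) with rejection and re-draw. Generation is
deterministic per (spec, seed).

A cut-open tight knot always keeps a few residues of slack near the
termini (the closure re-completes a short arc), so the minimal knotted
subchain sits a little inside the planted window. The reference
("planted") core span is therefore *measured once* on the clean opened
core — no noise, no tails, fixed probe seed — and shared across seeds;
recovery tests then quantify the stability of core localization under
noise, tails and closure stochasticity.

What passing tests on synthetic data do **not** show: real predicted
models have secondary structure, variable local density, genuinely
ambiguous low-confidence regions and chain breaks; synthetic backbones
have none of these, so the tests validate the topology machinery and
the rule logic, not AlphaFold-specific failure modes.

## Pipeline and problem sizes

The batch scanner processes each model independently (failures recorded
per row), short-circuits unknotted chains, and echoes its full
configuration into the report header so a scan is reproducible from the
artifact alone. Chains above 3000 residues are processed but flagged:
models of that size are stitched from overlapping prediction fragments
and are disproportionately artifact-prone.

Test and acceptance workloads use chains of 80–150 residues, 200
closures for headline calls, 50 per matrix cell, and 3–5 seeds per
planted type — sizes at which the full suite completes in minutes on a
single CPU while every statistic is still comfortably resolved at the
thresholds tested.

## Known limitations

* Labels cover the knot types reported for proteins plus "other"; no
  general tabulation beyond 7 crossings, no link invariants.
* The one-point closure is the only closure scheme; a deterministic
  direct closure exists only as an internal path, not a headline mode.
* No backbone embedding for 7_2 (see above).
* The clash heuristic sees only Cα atoms.
* Homolog search, structure prediction and fragment stitching of very
  large proteins are out of scope; their outputs are consumed as files.
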