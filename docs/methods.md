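# Methods

This note documents the models and procedures implemented in `ssefold`,
their assumptions, the parameters that matter, and the design decisions
taken where the method left room.

## Secondary structure and base-pair annotation

A secondary structure is a sequence over {A, C, G, U} plus a set of base
pairs with 1-based indices, serialized as dot-bracket text.  Crossing
(pseudoknot) pairs use additional bracket alphabets `()[]{}<>`, each layer
matched independently by a stack; four layers are supported, and deeper
mutual crossings are a serialization error (never reached at the scales
handled here).

Pairs are derived from 3D coordinates by a geometric annotator.  Every
base gets a frame: ring-atom centroid, best-fit plane normal (SVD, sign
fixed by the right-hand rule over the ring atom order), and the glycosidic
nitrogen.  A candidate pair (i, j) with i+1 < j must pass all of:

| criterion | default | meaning |
|---|---|---|
| `origin_cutoff` | 15 Å | centroid distance prefilter |
| `c1_cutoff` | 10.5 Å | C1'–C1' pairing window |
| `plane_angle_deg` | 65° | angle between base normals (or ≥ 115°, anti-parallel) |
| `vertical_cutoff` | 2.5 Å | rise between the bases along the mean normal |
| `hbond_cutoff` | 3.5 Å | at least one polar edge-atom contact |

These constants are declared stand-ins in the standard ranges used by
structure annotators, not fitted values; they live in
`config.AnnotationParams` and are overridable.  Adjacent residues are
never paired.  Non-standard base combinations are retained deliberately —
only AU, GC and GU count as *standard*, a flag used by the conflict
filter.  Externally computed pair lists can be imported verbatim in place
of detection (two-column text, 1-based indices).

When a residue is claimed by several candidates the keeper maximizes a
ranked criterion tuple, compared lexicographically: sequence interval
|j−i| > 4, then standard pair, then neighbour support (a candidate
(i−1, j+1) or (i+1, j−1) exists), then — as deterministic tie-breaks —
higher geometry score, smaller span, smaller i.  The criteria were stated
as a list without precedence; ranking them in the order listed is a design
decision, and the greedy algorithm provably equals the brute-force search
over all conflict-free subsets under that objective (the keys are static,
so the exchange argument applies; the equivalence is also tested against
an independent enumerator).  The geometry score is an equal-weight sum of
normalized criterion margins and matters only in ties.

Crossing pairs are then removed by exact interval dynamic programming that
keeps a maximum-cardinality nested subset (ties prefer the pair opening at
the smaller index).  Removed pairs are retained as chain metadata; SSE
decomposition operates on trees, and pseudoknots are excluded from the
library statistics by construction.

## Chain ingestion

Structure files are read natively (PDB and mmCIF through gemmi); the first
model is used, and the highest-occupancy conformer is kept per atom.  A
chain enters the pipeline when it contains at least one residue that maps
to a parent base: standard codes map to themselves and modified
nucleotides map through a curated parent-base table (~90 common
components); unknown codes are treated as non-RNA and dropped with a log
entry.  Sanitation then (1) drops non-RNA residues, (2) renames modified
residues keeping the atoms the parent shares, (3) drops residues with
fewer than 9 observed heavy atoms, (4) completes remaining missing atoms
by least-squares grafting of an idealized residue template onto the
observed atoms, (5) reindexes 1..n, and (6) rejects chains below 6 nt,
which cannot form an SSE.  The eliminate-vs-complete threshold at 9 atoms
resolves an ambiguity in the underlying recipe: badly observed residues
are removed, partially observed ones are completed.  Completion by rigid
template grafting (instead of a force-field rebuild) is deterministic,
dependency-free and sufficient for fragment assembly, where only anchor
geometry matters.  Sanitation is idempotent, every action is reported as
tab-separated text, and rejection is an outcome, not an error.

Chains with identical sequence *and* identical derived secondary structure
are deduplicated (first encountered wins); chains whose derived structure
has no pairs are flagged library-ineligible.

## SSE decomposition

Stems are maximal runs of stacked pairs (i, j), (i+1, j−1), …  Loops are
classified from the stem tree: hairpin (one closing stem), bulge (two
stems, exactly one non-empty unpaired gap), internal (two stems, both gaps
non-empty), junction (≥ 3 incident stems), and one open loop for the
exterior — 5'/3' tails plus the gaps between top-level stems — emitted
whenever the exterior holds unpaired residues or more than one stem.  Each
loop record annexes the two terminal pairs of every adjoining stem (all
pairs of a one-pair stem); stems shorter than two contribute what they
have.  Two stems stacked with a gap on exactly one strand are a bulge with
an empty segment — the record preserves the coaxial geometry.  Records
store segments (merged index runs), sequence and dot-bracket with `&`
separating discontinuous strands, and every residue of the chain is
covered by at least one record; residues shared between a stem and a loop
are exactly the annexed flanking residues.

`lib1` applies single-pair opening before identification, iterated to a
fixed point (opening one pair can strand a neighbouring pair; iteration
makes the result order-independent — a deliberate strengthening of the
single-pass description).  For chains without single-pair stems the two
schemes produce identical records, which is asserted as a property; when
single pairs are present the schemes legitimately differ in both loop
shapes and counts.

## Template library

Records are grouped by a topology key — SSE type plus the
sequence-agnostic dot-bracket pattern — and matching is exact on topology:
no loop-length tolerance is implemented, keeping search semantics simple
and faithful; inexact matching would be a separate extension.  Ranking is
by full-sequence identity over all segments and flanking pairs, with
source id as the deterministic tie-break.  Self-exclusion removes whole
source structures (accession level), not individual chains.  Exact
duplicates (same type, sequence, pattern, coordinates) are folded at
insertion keeping the lexicographically smallest source, which makes the
stored set independent of insertion order and lets incremental updates
equal a rebuild from the union; `filter_unique` additionally keeps one
record per identical sequence-plus-pattern, the quantity reported in the
"filter" column of the statistics (junctions bucketed as 3wj/4wj/5wj and
nwj for ≥ 6 incident helices).

On disk a library is a directory: `meta.txt` (scheme and provenance),
`index.txt` (line-oriented key-value blocks) and one PDB fragment per
record keeping original residue numbering.  The layout is diff-able and
append-friendly; a save/load cycle is the identity at format precision
(coordinates are written at the PDB's 10⁻³ Å).  Provenance stores
insertion batches rather than wall-clock timestamps so that identical runs
produce byte-identical indexes; timestamps appear only in logs.

## Assembly

The target is decomposed under the library's scheme; the rank-1 template
is chosen per SSE (a missing topology aborts with an error naming the
pattern — the realistic failure mode, typically open loops and high-order
junctions).  Fragments are placed breadth-first from the exterior record:
each new fragment is superposed onto the already-placed structure over the
shared flanking-pair residues, using anchor atoms P, C4', C1' and the
glycosidic N of each shared residue (≥ 3 non-collinear points spanning
backbone and base).  First placement wins for overlapping residues.
Template sequences are imposed chimerically: where the template base
differs from the target base, an idealized residue of the target base is
superposed onto the template's sugar and contributes the base atoms, so
every residue ends with the full heavy-atom set of its target base.  Arm
orientation at junctions is taken from the junction template itself; no
re-orientation heuristic is applied (mis-oriented junction templates are a
known, accepted failure source).  Assembly is deterministic; with
self-inclusion and a single-stem-path target the chain is reproduced to
numerical precision (superposition chaining is exact on exact matches).

## Energy model, relaxation, refinement and ranking

The built-in scorer is deliberately simple and pluggable (any
`coordinates → float` callable):

* soft-sphere repulsion `k_clash (d₀ − d)²` for heavy-atom pairs closer
  than `d₀ = 2.8 Å` (same and sequence-adjacent residues excluded),
  `k_clash = 100`;
* harmonic O3'(i)–P(i+1) links toward 1.6 Å; links longer than 4 Å at
  setup are held at their current length instead of pulled closed (chain
  breaks and exploded fixtures must not be dragged together);
* harmonic distance restraints (`k = 10`/Ų) among the anchor atoms of
  every flanking base pair, holding each stem–loop interface as
  assembled.  Distance (not positional) restraints keep the model free to
  move rigidly, so clashes can relax to exactly zero.

`minimize_clashes` runs L-BFGS with the analytic gradient (neighbor pairs
from a k-d tree per evaluation); descent-only line search keeps the final
energy at or below the initial one, and termination is by gradient norm
(10⁻⁴) or 500 iterations.

SAMC refinement applies rigid-body moves to moveable elements derived from
the stem tree: each helical arm together with its distal subtree (pivot at
the arm's outer pair, axis along the helix), and each unpaired loop
segment (pivot at its upstream anchor).  The element set is an
interpretation — the method names the move types but not the groups.  A
move translates (≤ 2 Å), rotates about a random axis through the pivot, or
rotates about the element's own axis (≤ 10°), accepted by the Metropolis
rule; the temperature cools geometrically (5.0 → 0.1 score units, factor
0.98 every 100 steps; all configurable — the original procedure states no
schedule).  Snapshots are taken every `sample_every` accepted moves and
the best-energy structure is always kept in the ensemble.  A fixed seed
gives a bit-reproducible trajectory; with a zero scorer the sampler
reduces to a pure random walk with acceptance rate 1, which is tested as
schedule plumbing.

The ensemble is clustered on its pairwise-RMSD matrix (all heavy atoms,
optimal superposition per pair).  "k-means on RMSD values" is realized as
k-medoids, the natural reading when only a distance matrix exists: for
small problems (≤ 20,000 medoid subsets) the optimal medoid set is found
exactly by enumeration; larger ensembles use PAM iteration from a
deterministic greedy seed.  Representatives (medoids) are ranked by scorer
energy ascending.  RMSD to a reference superposes all shared heavy atoms
by default, with an optional atom-name selection.

## Synthetic fixtures

The generator exists to make every stage testable without external data,
and its design goal is *unambiguous annotation*: every written pair must
be recovered and no spurious pair may appear, at zero noise, for random
nested structures up to 60 nt.  Stems are ideal duplexes built from
idealized nucleotide templates — planar standard-geometry bases, a shared
C3'-endo-like ribose, and backbone atoms solved at import time so the
O3'–P link closes to 1.6 Å at the default twist (32.7°) and rise (2.81 Å);
G·U pairs get a 1.2 Å in-plane wobble shear.  Each stem sits on its own
grid slot (40 Å apart, axis vertical); hairpin loops coil around their
closing stem just above it (radius 12 Å, pitch 11 Å, ~5.9 Å between
residues, bases pointing radially outward); all other unpaired segments
are laid out as straight rows in a separated strand region.  The spacings
guarantee that for any non-paired residue pair at least one detection
criterion fails by a margin — e.g. successive stacked residues exceed the
2.5 Å rise cutoff, next-nearest residues exceed the C1' window, and
inter-element atoms stay beyond hydrogen-bond range.

What the fixtures do *not* emulate: loop closure between elements
(connector segments are not covalently continuous with their stems),
compact tertiary packing, realistic loop conformations, sugar-pucker
variation, non-canonical pairs, and experimental noise artifacts.
Passing tests therefore demonstrate the correctness of the pipeline's
logic and geometry handling, not predictive accuracy on real deposited
structures, which would require the full structure corpus.  The
free-standing duplex fixture orders its complementary strand 3'→5' so
paired residues sit at a constant index offset, keeping every pair
non-adjacent and visible to the annotator; it is a detection fixture, not
a folded chain.

## Determinism and problem sizes

One top-level seed fans out to per-stage seeds through a seed sequence;
identical configuration and inputs give byte-identical coordinate and
index files (logs may differ in timestamps).  The default test suite and
the acceptance script run on synthetic problems sized for a single CPU:
exhaustive classification up to length 14 (~180k structures), 1,000-set
brute-force comparisons for the combinatorial kernels, 200 annotation
round trips at lengths 8–60, and 5,000-step SAMC runs on two-arm
fixtures; these sizes exercise every code path while keeping the whole
suite under a minute apiece.

## Known limitations

* Exact-topology template matching only; targets with loop lengths absent
  from the library fail with a clear error instead of matching loosely.
* The built-in energy is a clash/connectivity score, not a statistical
  potential; ranking quality on real targets depends on plugging in a
  proper scorer.
* Junction arm orientation is inherited from the template with no
  re-orientation search.
* Single chains only; no multi-chain SSEs, pseudoknotted SSE types,
  ligands or ions.
* The annotator is a geometric stand-in, not a re-implementation of any
  published annotation tool; on deposited structures its pair lists will
  differ in edge cases, and external annotations can be imported instead.
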