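# Methods

## The model of a sketch

A sketch is a molecular connection table with 2D depiction coordinates:
atoms carry an element symbol (or an abbreviation, or the `*` guide
placeholder), an integer charge, an unpaired-electron count, an isotope mass
(0 = natural abundance), an explicit-hydrogen count (None = automatic), and
x, y in Ångstroms. Bonds carry an order in {0,1,2,3,4} and a stereo style in
{none, inclined, declined, unknown}; the (from, to) direction is significant
for wedges, whose narrow end sits at the *from* atom. Editing state adds a
*subject*: a selection set, or a current atom, or a current bond (never
both). A primitive resolves its subject as: all selected atoms (ascending
index) — else the current atom — else the two atoms of the current bond in
[from, to] order — else nothing. Atom identifiers are 0-based list indices;
deleting atoms renumbers the tail, which replay scripts must account for.

Units and global constants:

| constant | value | role |
|---|---|---|
| default bond length | 1.5 Å | every new bond; Connect Atoms target |
| overlap threshold | 0.2 Å | merging, equivalence mapping, multi-atom overlay |
| match tolerance | 2° | template matching, vacancy degeneracy, ring-bond immobility |
| nudges | 0.1 / 0.5 Å | small / large Move Atoms |
| scale factors | 1.25 / 0.8 | grow / shrink |
| congestion softening | 0.001 Å² | additive constant in 1/(d²+c) |
| connect slack | ±0.3 Å | "approximately a bond length" in Connect Atoms |
| merge tolerance | 0.5 Å | Merge Atoms proximity (well under a bond) |

The connect slack and merge tolerance are this package's own calibration of
qualitative statements ("approximately", "significantly shorter than the
default bond distance"); both are module constants.

## Geometry perception

Seven templates cover the bond-direction patterns of 2D depiction. Their
exact angle sets are a design choice of this package, isolated in one table
(`GEOMETRY_TEMPLATES`) so they can be swapped without touching algorithms:
linear (0,180); trigonal (0,120,240); tetra1 (0,120,180,240 — cyclic gaps
120/60/60/120); tetra2 (0,60,180,240); square planar (0,90,180,270); octa1
(0,60,…,300 — the "regular" hexagonal drawing of an octahedral centre);
octa2 (0,45,90,180,225,270 — a superset of square planar).

Plausible templates for adding a bond of order k at an atom follow a
decision list on (element, existing orders, k): terminal C/N heading for an
alkyne- or allene-like pattern ({3,1} or {2,2} order multiset) → linear;
terminal atoms outside the s/p blocks → both octahedrals; terminal C/N/O →
trigonal; other terminal → trigonal, linear. A divalent atom whose two
bonds are collinear (within 2°) → square planar (s/p block) or octahedrals.
Otherwise a periodic-block table applies; notably carbon with all-single
bonds (the new bond included — adding a double bond classifies trigonal)
offers trigonal, square planar and both tetrahedral variants. The p-block
cutoff "first rows" is read as periods 2–4 (B→Kr). The rules are exhaustive.

Matching existing bearings onto a template tries a rotation seeded at every
(bearing, slot) pair — and the template's mirror image — greedily assigns
bearings to distinct nearest slots, then refines the rotation to the mean
signed offset and re-checks at the 2° tolerance; the refinement matters when
two bearings err in opposite directions (a pair spread of up to 124° still
matches a 120° pair). Vacancies from all distinct superpositions are pooled
and collapsed at the same 2°. New-bond proposal: isolated atom → the four
axis directions; else the first enumerated template with a non-empty vacancy
set wins; else median-cut (circular midpoints of consecutive bearings, one
per neighbour). Candidate positions 1.5 Å out are scored by point
congestion; ties break to the smallest angle.

Refitting an atom to a requested geometry (Set Geometry) leaves it alone if
any superposition already matches. Otherwise every (existing bond, slot)
seed rotation of the template and its mirror is tried; remaining bonds snap
to nearest distinct slots, any assignment that would move a ring bond (a
non-bridge edge) by more than 2° is discarded, and the smallest total
angular displacement wins (ties: unmirrored template, then lowest seed slot
index; displacements are rounded to 1e-6 degrees so floating-point noise
cannot flip the tie-break). A moved neighbour carries its whole acyclic
branch rigidly. Switch Geometry estimates the non-terminal end's geometry
with the switched bond removed, takes the first matching template's
vacancies, drops those within 2° of the current bearing, and rotates the
terminal atom (preserving bond length) to the nearest anti-clockwise viable
position, so repetition cycles through all of them.

## Grafting and scoring

All graft modes assemble base + transformed fragment, then merge overlapping
atoms pairwise across the two partitions (most exotic atom survives; the
input-structure atom on a draw; duplicate bonds collapse keeping the more
exotic, first on a draw). Mirroring (x → −x, inclined↔declined) is applied
in every mode. Direct atom connection rotates the fragment by
θ₁ − θ₂ + 180° (counter-clockwise) about the overlaid atom, where θ₁ and θ₂
are candidate new-bond angles on either side; bridge connection places the
fragment atom 1.5 Å out along θ₁ and joins with a single bond. Bond
connection aligns bond centroids parallel and anti-parallel and force-merges
the matched atom pairs with the input structure's coordinates retained.
Multi-atom overlay anchors one fragment atom on the first subject atom,
rotates to align with the second, and demands every further subject atom
overlap a fragment atom within 0.2 Å — no rescaling is ever attempted.

Guide modes: a single one-neighbour guide maps onto the subject atom, the
fragment is rotated so the guide→neighbour direction matches a projected
bond angle, the guide's bond is rewired to the subject and the guide
deleted — the guide→neighbour *distance* (not the default length) becomes
the bond length, which is the point of guides. A multi-neighbour guide uses
the circular median of its neighbour directions; this median is aligned
*with* the projection angle so the ligand occupies the vacancy (reading the
source description's "anti-parallel substrate vector" as the vector pointing
from the projected position back to the subject — the literal opposite
reading would fold the ligand onto the existing substituents). A guide bond
mapped onto a subject bond has 4 base permutations and, when the lengths
differ, a bifurcation keeping either length. k guides map onto k subjects
exactly as multi-atom overlay.

Score (lower better) = total congestion + 1·(atoms merged by overlap) +
50·(C/N/O/P/S atoms, neutral and non-radical, clearly sp/sp²/sp³, whose new
bond lies off 180°/120°/120° from some pre-existing neighbour by more than
5°) + 1000·(C or N atoms with total bond order ≥ 5) − 1·(guide atoms used).
"New" bonds are those absent from the pre-graft structure; fragment-internal
atoms have no pre-existing neighbours and are never penalised, so the term
compares only the junctions the graft created. Hybridisation is read from
bond orders alone: a triple or two doubles → sp; exactly one double → sp²;
all single → sp³. Results are deduplicated by the coordinate-level
equivalence test (centre-translated unique nearest-atom mapping within
0.2 Å, field equality, bond correspondence with direction-sensitive wedges),
sorted stably by score, and candidates at or above 1000 are dropped whenever
any candidate scores below 1000.

## Worked-example scripts

The three example scripts are transcriptions of interactive drawing
sessions; their reference connection tables are hand-encoded and the replay
test checks labelled graph isomorphism (element, charge, order, stereo) plus
the 1.5 Å bond-length invariant. Where the engine offers several ranked
results the scripts record the picked index, as a user browsing the result
list would. Two transcription choices are worth noting. The bridged
bicyclo[4.4.1] core of the ingenol skeleton is built by overlaying a second
seven-ring on two *non-bonded* 1,3 ring atoms (two regular heptagons sharing
a contiguous arc of 3+ atoms can only coincide, so the overlay admits
exactly the flipped-arc tricycle, whose spare bridge atom is then deleted).
In the organometallic example the one deliberately non-default distance is
the metal–carbene bond, grown ×1.25 by Scale Bond; every other bond stays at
1.5 Å.

## What the tests do and do not show

All inputs are generated in-repo: idealized ring templates, hand-written
molfile blocks, and seeded random connection tables whose atoms are kept
0.5 Å apart. They exercise the engine's contracts — determinism, rigid
transforms, merge/equivalence semantics, brute-force agreement of the
congestion sums (≤ 20 atoms, 1e-12), oracle agreement of template matching
(exhaustive rotation scan at 0.05° steps) — on desk-scale structures (≤ 36
atoms). They do not establish aesthetic quality of layouts for large
congested molecules, nor coverage of real-world template libraries beyond
the minimal built-in set (C3–C8 rings, benzene, cyclopentadiene,
naphthalene, acetyl, carboxyl).

## Known limitations

- Flip Atoms does not exchange inclined/declined wedges; mirroring a
  stereocentre therefore changes depicted chirality. (Template mirroring
  *does* exchange them.) Isolated in one function if the other convention is
  wanted.
- Direct atom-connection, taken literally, aligns the two candidate vectors
  anti-parallel; some junction candidates are tilted relative to the
  textbook depiction and rely on the angle-penalty term to rank below the
  regular ones.
- Equivalence compares the hydrogen-count *mode* strictly (automatic vs
  explicit), even when the implied counts would agree.
- V2000 only (≤ 999 atoms); z is written as 0. Bond order 4 is a literal
  quadruple bond, not aromatic. Guide atoms serialize as the `*` symbol;
  `A` and `R#` are accepted on input.
- Scripts address atoms by index into the evolving molecule; deletions and
  merges renumber, so scripts are position-sensitive by design.
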