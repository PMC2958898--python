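# molsketch

A headless engine for sketching publication-quality 2D molecular structure
diagrams with **no pointing device**: every edit is a discrete *primitive*
(select a subject, pick an action, optionally pick one of a ranked list of
results), so a whole drawing session is a short replayable text script. The
engine targets the situation of mobile or remote interfaces — and scripted
structure generation — where dragging bond vectors with a mouse is not an
option, so the algorithms must infer where new atoms and bonds belong.

It is aimed at cheminformatics developers who need a scriptable way to build
MDL connection tables with good 2D coordinates: the molecule model is a
plain connection table (atoms with x,y in Å; bonds with order 0–4 and
wedge/hash/unknown stereo), read and written as molfile V2000 / SD files.

## The core ideas

**Geometry perception.** Seven idealized bond-direction templates cover
almost all drawn atom environments: linear (0°, 180°), trigonal (0°, 120°,
240°), two tetrahedral drawing variants, square planar, and two octahedral
drawing variants. Given an atom's element, existing bond orders and the
order of the bond about to be drawn, the engine enumerates the plausible
templates, superimposes the existing bond bearings onto template slots
(any rotation, the mirror image too, 2° tolerance) and proposes the vacant
directions; when nothing matches it falls back to the circular midpoints
between consecutive bearings.

**Congestion.** Degenerate choices are resolved by crowding. The congestion
at a point is

    C(x, y) = Σ_i 1 / ((x_i − x)² + (y_i − y)² + 0.001)

summed over atoms, and the total congestion of a sketch is the same sum over
unique atom pairs. New atoms go to the least congested candidate position.

**Template grafting.** Predrawn fragments (rings, acyl groups, a clipboard
copy of part of the sketch) are fused onto the structure by atom overlay,
bond alignment, a bridging bond, or by mapping *guide atoms* — `*`
placeholders that encode the intended attachment direction and distance.
Overlapping atoms merge (the more *exotic* atom survives: one point each for
non-carbon element, charge, radicals, isotope, explicit H count). Candidates
are deduplicated with a coordinate-level equivalence test, scored
(total congestion, +1 per merge, +50 per irregular new-bond angle on a
clearly sp/sp²/sp³ C,N,O,P,S atom, +1000 per pentavalent C/N, −1 per guide)
and returned ranked, best first.

## Worked example

Aspirin in nine primitives, from an empty sketch (this is
`molsketch.examples.ASPIRIN_SCRIPT`): graft benzene; two *New Bond with
Order* calls and a *Switch Geometry* to grow the carboxyl arm; *Set Element
Label: O* on the two carboxyl oxygens; another new bond relabelled to the
ester oxygen; finally *Graft with Atom Connection: acetyl*, picking ranked
result 6 (the bridge that acetylates the ester oxygen).

```python
from molsketch.examples import draw_example
from molsketch import write_molfile

mol = draw_example("aspirin")
print(len(mol.atoms), len(mol.bonds))   # 13 13
print(write_molfile(mol, name="aspirin"))
```

prints the 13-atom, 13-bond acetylsalicylic acid connection table:

```
aspirin
  molsketch 2D

 13 13  0  0  0  0  0  0  0  0999 V2000
   -1.2990    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    1.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    ...
```

Every bond in the result is exactly 1.5 Å — the default bond length — and
the same script always yields the bit-identical molfile (the engine is fully
deterministic). The ingenol-skeleton and organometallic examples
(`INGENOL_SCRIPT`, `GOLD_SCRIPT`) exercise the bridged-ring, clipboard and
guide-atom machinery the same way.

The same runs from a shell:

```
sketch apply --script steps.json --out out.mol
sketch templates list
sketch graft --in in.mol --template acetyl --subject 0 --show-ranked
sketch equiv a.mol b.mol
```

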