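"""MDL molfile (V2000) and SD file reading and writing.

Only the fields the sketch data model carries are round-tripped: 2D
coordinates (z is written as 0.0 and ignored on input), element symbols,
charge (``M  CHG``), isotope (``M  ISO``), unpaired electrons (``M  RAD``),
explicit hydrogen counts (atom-block hhh field, stored as count+1), bond
orders 0-4 and wedge/stereo flags (1 = inclined, 6 = declined, 4 = unknown).

Guide-atom placeholders are written with the literal ``*`` symbol; the
reader also accepts ``A`` and ``R#`` as placeholder spellings.
"""

from __future__ import annotations

from .structures import Atom, Bond, Molecule

__all__ = [
    "MolfileError",
    "read_molfile",
    "write_molfile",
    "read_sdfile",
    "write_sdfile",
]

V2000_ATOM_LIMIT = 999

_STEREO_TO_CODE = {"none": 0, "inclined": 1, "declined": 6, "unknown": 4}
_CODE_TO_STEREO = {v: k for k, v in _STEREO_TO_CODE.items()}

_PLACEHOLDER_SYMBOLS = {"A", "R#"}

# Radical codes in M  RAD lines: 1=singlet(carbene-ish), 2=doublet, 3=triplet.
# The sketch model stores a plain unpaired-electron count; doublet -> 1,
# triplet -> 2, anything else maps through unchanged.
_RAD_TO_UNPAIRED = {0: 0, 1: 2, 2: 1, 3: 2}
_UNPAIRED_TO_RAD = {0: 0, 1: 2, 2: 3}


class MolfileError(ValueError):
    """Raised for malformed molfile input, naming the offending line."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


def read_molfile(text: str) -> Molecule:
    """Parse a V2000 molfile string into a :class:`Molecule`."""
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileError("molfile too short: missing counts line", len(lines))
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise MolfileError(f"malformed counts line: {counts!r}", 4) from None
    if "V3000" in counts:
        raise MolfileError("V3000 molfiles are not supported", 4)

    atoms: list[Atom] = []
    for i in range(n_atoms):
        ln = 4 + i
        try:
            raw = lines[ln]
            x = float(raw[0:10])
            y = float(raw[10:20])
            symbol = raw[31:34].strip() or raw[30:33].strip()
        except (ValueError, IndexError):
            raise MolfileError("malformed atom line", ln + 1) from None
        if symbol in _PLACEHOLDER_SYMBOLS:
            symbol = "*"
        hydrogens = None
        hhh = raw[42:45].strip()
        if hhh and hhh.isdigit() and int(hhh) > 0:
            hydrogens = int(hhh) - 1
        charge = _legacy_charge(raw[36:39])
        atoms.append(Atom(element=symbol, x=x, y=y, charge=charge, hydrogens=hydrogens))

    bonds: list[Bond] = []
    for i in range(n_bonds):
        ln = 4 + n_atoms + i
        try:
            raw = lines[ln]
            a = int(raw[0:3])
            b = int(raw[3:6])
            order = int(raw[6:9])
            code = int(raw[9:12]) if raw[9:12].strip() else 0
        except (ValueError, IndexError):
            raise MolfileError("malformed bond line", ln + 1) from None
        if order not in (0, 1, 2, 3, 4):
            raise MolfileError(f"unknown bond order code {order}", ln + 1)
        if code not in _CODE_TO_STEREO:
            raise MolfileError(f"unknown bond stereo code {code}", ln + 1)
        if not (1 <= a <= n_atoms and 1 <= b <= n_atoms):
            raise MolfileError("bond references an atom outside the atom block", ln + 1)
        bonds.append(Bond(frm=a - 1, to=b - 1, order=order, stereo=_CODE_TO_STEREO[code]))

    for ln in range(4 + n_atoms + n_bonds, len(lines)):
        raw = lines[ln]
        if raw.startswith("M  END"):
            break
        if raw.startswith("M  CHG"):
            for idx, val in _property_pairs(raw, ln):
                atoms[idx].charge = val
        elif raw.startswith("M  ISO"):
            for idx, val in _property_pairs(raw, ln):
                atoms[idx].isotope = val
        elif raw.startswith("M  RAD"):
            for idx, val in _property_pairs(raw, ln):
                atoms[idx].unpaired = _RAD_TO_UNPAIRED.get(val, val)
    return Molecule(atoms, bonds)


def _legacy_charge(fld: str) -> int:
    # atom-block charge column: 0 none, 1=+3, 2=+2, 3=+1, 4=radical, 5=-1,
    # 6=-2, 7=-3. M  CHG lines override when present.
    table = {0: 0, 1: 3, 2: 2, 3: 1, 4: 0, 5: -1, 6: -2, 7: -3}
    try:
        return table.get(int(fld), 0)
    except ValueError:
        return 0


def _property_pairs(raw: str, ln: int) -> list[tuple[int, int]]:
    try:
        count = int(raw[6:9])
        out = []
        for k in range(count):
            base = 9 + 8 * k
            idx = int(raw[base : base + 4]) - 1
            val = int(raw[base + 4 : base + 8])
            out.append((idx, val))
        return out
    except (ValueError, IndexError):
        raise MolfileError("malformed property line", ln + 1) from None


def write_molfile(mol: Molecule, name: str = "") -> str:
    """Serialize a :class:`Molecule` to a V2000 molfile string."""
    if len(mol.atoms) > V2000_ATOM_LIMIT:
        raise ValueError(f"V2000 supports at most {V2000_ATOM_LIMIT} atoms")
    lines = [name, "  molsketch 2D", ""]
    lines.append(f"{len(mol.atoms):3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for a in mol.atoms:
        hhh = 0 if a.hydrogens is None else a.hydrogens + 1
        lines.append(f"{a.x:10.4f}{a.y:10.4f}{0.0:10.4f} {a.element:<3s} 0  0  0{hhh:3d}  0  0  0  0  0  0  0  0")
    for b in mol.bonds:
        code = _STEREO_TO_CODE[b.stereo]
        lines.append(f"{b.frm + 1:3d}{b.to + 1:3d}{b.order:3d}{code:3d}  0  0  0")
    for tag, values in (
        ("CHG", [(i, a.charge) for i, a in enumerate(mol.atoms) if a.charge != 0]),
        ("ISO", [(i, a.isotope) for i, a in enumerate(mol.atoms) if a.isotope != 0]),
        ("RAD", [(i, _UNPAIRED_TO_RAD.get(a.unpaired, a.unpaired)) for i, a in enumerate(mol.atoms) if a.unpaired > 0]),
    ):
        for start in range(0, len(values), 8):
            chunk = values[start : start + 8]
            body = "".join(f"{i + 1:4d}{v:4d}" for i, v in chunk)
            lines.append(f"M  {tag}{len(chunk):3d}{body}")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def read_sdfile(text: str) -> list[Molecule]:
    """Parse a multi-record SD file into a list of molecules.

    Data fields between ``M  END`` and the ``$$$$`` delimiter are ignored.
    """
    records = []
    current: list[str] = []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            if any(s.strip() for s in current):
                records.append("\n".join(current))
            current = []
        else:
            current.append(line)
    if any(s.strip() for s in current):
        records.append("\n".join(current))
    out = []
    for rec in records:
        # trim trailing data fields: everything after M  END
        body = rec.split("M  END")[0] + "M  END"
        out.append(read_molfile(body))
    return out


def write_sdfile(mols: list[Molecule], names: list[str] | None = None) -> str:
    parts = []
    for i, mol in enumerate(mols):
        name = names[i] if names else ""
        parts.append(write_molfile(mol, name=name) + "$$$$\n")
    return "".join(parts)
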