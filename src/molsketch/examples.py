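"""Worked drawing examples: aspirin, the ingenol skeleton, and a
carbene-gold carboxylation intermediate.

Each example is a plain list of script-step dictionaries (the same format
:func:`molsketch.script.load_script` reads from JSON), so they double as
documentation of the scripting format and as end-to-end regression inputs.
Grafting steps carry explicit ``result`` indices: the engine presents a
ranked list of candidate fusions and the script records which one the
"user" picked, exactly as an interactive session would.
"""

from __future__ import annotations

from .script import ScriptStep, run_script
from .structures import Molecule

__all__ = ["ASPIRIN_SCRIPT", "INGENOL_SCRIPT", "GOLD_SCRIPT", "draw_example"]

#: Aspirin in nine steps: benzene, the carboxyl arm grown bond by bond
#: (with one Switch Geometry to swing the carbonyl into place), the ester
#: oxygen, and an acetyl template grafted onto it.
ASPIRIN_SCRIPT: list[dict] = [
    dict(action="graft", params={"template": "benzene"}, result=0),
    dict(action="new_bond_with_order", current_atom=0, params={"order": 1}),
    dict(action="new_bond_with_order", current_atom=6, params={"order": 2}),
    dict(action="switch_geometry", current_bond=[6, 7]),
    dict(action="new_bond_with_order", current_atom=6, params={"order": 1}),
    dict(action="set_element", select=[7, 8], params={"value": "O"}),
    dict(action="new_bond_with_order", current_atom=1, params={"order": 1}),
    dict(action="set_element", current_atom=9, params={"value": "O"}),
    dict(action="graft", current_atom=9, params={"template": "acetyl"}, result=6),
]

#: Ingenol skeleton: the bridged bicyclo[4.4.1]undecane core is built by
#: overlaying a second cycloheptane on two 1,3-related ring atoms and
#: deleting the duplicated inner atom; cyclopentane and cyclopropane rings
#: are fused on, then the ketone, alkene, methyls and wedged substituents.
INGENOL_SCRIPT: list[dict] = [
    dict(action="graft", params={"template": "cycloheptane"}, result=0),
    dict(action="graft", select=[0, 2], params={"template": "cycloheptane"}, result=1),
    dict(action="delete_atoms", select=[11]),
    dict(action="graft", current_bond=[4, 5], params={"template": "cyclopentane"}, result=0),
    dict(action="graft", current_bond=[8, 9], params={"template": "cyclopropane"}, result=0),
    dict(action="new_bond_with_order", current_atom=1, params={"order": 2}),
    dict(action="flip_atoms", select=[1, 15], current_atom=1, params={"axis": "vertical"}),
    dict(action="set_stereo_style", current_bond=[0, 7], params={"style": "inclined"}),
    dict(action="set_stereo_style", current_bond=[0, 7], params={"style": "inclined"}),
    dict(action="set_bond_order", current_bond=[12, 13], params={"order": 2}),
    dict(action="new_bond_with_order", current_atom=12, params={"order": 1}),
    dict(action="new_bond_with_style", current_atom=3, params={"style": "inclined"}),
    dict(action="new_bond_with_style", current_atom=2, params={"style": "declined"}),
    dict(action="new_bond_with_geometry", current_atom=14, params={"geometry": "tetra1"}),
    dict(action="new_bond_with_geometry", current_atom=14, params={"geometry": "tetra1"}),
    dict(action="new_bond_with_order", current_atom=16, params={"order": 1}),
    dict(action="set_element", select=[15, 17, 21], params={"value": "O"}),
    dict(action="set_element", select=[18], params={"value": "H"}),
]

#: Carbene-gold carboxylation intermediate: a three-membered N,N-carbene is
#: assembled on gold, one bulky N-aryl wing is drawn by hand, copied to the
#: clipboard (the boundary nitrogen becomes a guide atom) and pasted onto
#: the second nitrogen, then the Au=C bond is grown and the trans
#: carboxylate arm (Au-O-C(=O)-azolyl) is built with linear geometry,
#: an acetyl graft and a heteroring graft.
GOLD_SCRIPT: list[dict] = [
    dict(action="add_atom", params={"element": "Au"}),
    dict(action="graft", current_atom=0, params={"template": "cyclopropane"}, result=0),
    dict(action="set_bond_order", current_bond=[0, 1], params={"order": 2}),
    dict(action="set_element", select=[2, 3], params={"value": "N"}),
    dict(action="new_bond_with_order", current_atom=2, params={"order": 1}),
    dict(action="graft", current_atom=4, params={"template": "benzene"}, result=6),
    dict(action="new_bond_with_style", current_atom=6, params={"style": "declined"}),
    dict(action="new_bond_with_style", current_atom=8, params={"style": "inclined"}),
    dict(action="new_bond_with_order", select=[10, 11], params={"order": 1}),
    dict(action="new_bond_with_order", select=[10, 11], params={"order": 1}),
    dict(action="create_template", select=[4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]),
    dict(action="graft", current_atom=3, params={"clipboard": True}, result=0),
    dict(action="scale_bond", current_bond=[0, 1], params={"mode": "grow"}),
    dict(action="new_bond_with_geometry", current_atom=0, params={"geometry": "linear"}),
    dict(action="set_element", current_atom=28, params={"value": "O"}),
    dict(action="new_bond_with_geometry", current_atom=28, params={"geometry": "linear"}),
    dict(action="graft", current_bond=[28, 29], params={"template": "acetyl"}, result=1),
    dict(action="graft", current_atom=29, params={"template": "cyclopentadiene"}, result=1),
    dict(action="set_element", select=[33], params={"value": "N"}),
    dict(action="set_element", select=[31], params={"value": "O"}),
]

_EXAMPLES = {
    "aspirin": ASPIRIN_SCRIPT,
    "ingenol": INGENOL_SCRIPT,
    "gold_intermediate": GOLD_SCRIPT,
}


def draw_example(name: str) -> Molecule:
    """Replay one of the worked examples from an empty sketch."""
    if name not in _EXAMPLES:
        raise KeyError(f"unknown example {name!r}; available: {sorted(_EXAMPLES)}")
    steps = [ScriptStep.from_dict(d) for d in _EXAMPLES[name]]
    return run_script(steps)
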