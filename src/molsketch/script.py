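"""Script-driven replay of primitive sequences.

A script is a list of steps, each naming a subject (selection indices, a
current atom, or a current bond), an action, parameters, and -- for actions
that produce a ranked list of results, i.e. grafts -- the index of the
result to keep. Scripts are plain JSON or YAML lists, so a whole drawing
session is a short, replayable text file.

Subject indices refer to atom order in the evolving molecule. Deleting or
merging atoms renumbers subsequent indices; scripts must account for this.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Any, Callable

from . import edit, sketch
from .fixtures import builtin_templates
from .grafting import Template, create_template, graft
from .structures import Molecule, SketchState

__all__ = ["ScriptStep", "ScriptError", "SketchEngine", "run_script", "load_script"]

log = logging.getLogger(__name__)


class ScriptError(RuntimeError):
    """A step failed; carries the 1-based step number."""

    def __init__(self, step: int, message: str):
        super().__init__(f"step {step}: {message}")
        self.step = step


@dataclass
class ScriptStep:
    """One primitive invocation: subject -> action -> result index."""

    action: str
    subject: dict[str, Any] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)
    result: int = 0

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "ScriptStep":
        if "action" not in raw:
            raise ValueError("script step missing 'action'")
        subject = {}
        for key in ("select", "current_atom", "current_bond"):
            if key in raw:
                subject[key] = raw[key]
        params = dict(raw.get("params", {}))
        return cls(
            action=raw["action"],
            subject=subject,
            params=params,
            result=int(raw.get("result", 0)),
        )


def _simple(fn: Callable, **defaults) -> Callable:
    def runner(engine: "SketchEngine", state: SketchState, params: dict) -> SketchState:
        return fn(state, **{**defaults, **params})

    return runner


def _graft_action(engine: "SketchEngine", state: SketchState, params: dict):
    if params.get("clipboard"):
        template = engine.clipboard
        if template is None:
            raise ValueError("clipboard is empty")
    else:
        name = params["template"]
        template = engine.templates[name]
    return graft(state, template)


def _create_template_action(engine: "SketchEngine", state: SketchState, params: dict) -> SketchState:
    template = create_template(state)
    if params.get("name"):
        engine.templates[params["name"]] = template
    engine.clipboard = template
    return state


_ACTIONS: dict[str, Callable] = {
    "add_atom": lambda e, s, p: edit.add_atom(s, p["element"]),
    "set_element": lambda e, s, p: edit.set_atom_property(s, "element", p["value"]),
    "set_charge": lambda e, s, p: edit.set_atom_property(s, "charge", p["value"]),
    "set_unpaired": lambda e, s, p: edit.set_atom_property(s, "unpaired", p["value"]),
    "set_hydrogens": lambda e, s, p: edit.set_atom_property(s, "hydrogens", p["value"]),
    "set_isotope": lambda e, s, p: edit.set_atom_property(s, "isotope", p["value"]),
    "set_bond_order": lambda e, s, p: edit.set_bond_order(s, p["order"]),
    "set_stereo_style": lambda e, s, p: edit.set_stereo_style(s, p["style"]),
    "connect_atoms": lambda e, s, p: edit.connect_atoms(s),
    "disconnect_atoms": lambda e, s, p: edit.disconnect_atoms(s),
    "delete_atoms": lambda e, s, p: edit.delete(s, "atoms"),
    "delete_bonds": lambda e, s, p: edit.delete(s, "bonds"),
    "delete_all": lambda e, s, p: edit.delete(s, "all"),
    "merge_atoms": lambda e, s, p: edit.merge_atoms(s),
    "move_atoms": lambda e, s, p: edit.move_atoms(s, p["direction"], p["extent"]),
    "scale_atoms": lambda e, s, p: edit.scale_atoms(s, p["mode"]),
    "scale_bond": lambda e, s, p: edit.scale_bond(s, p["mode"]),
    "flip_atoms": lambda e, s, p: edit.flip_atoms(s, p["axis"]),
    "rotate_atoms": lambda e, s, p: edit.rotate_atoms(s, p["increment"]),
    "new_bond_with_order": lambda e, s, p: sketch.new_bond_with_order(s, p.get("order", 1)),
    "new_bond_with_style": lambda e, s, p: sketch.new_bond_with_style(s, p["style"]),
    "new_bond_with_geometry": lambda e, s, p: sketch.new_bond_with_geometry(s, p["geometry"]),
    "set_geometry": lambda e, s, p: sketch.set_geometry(s, p["geometry"]),
    "switch_geometry": lambda e, s, p: sketch.switch_geometry(s),
    "graft": _graft_action,
    "create_template": _create_template_action,
}


class SketchEngine:
    """Replays primitive scripts against an evolving sketch state."""

    def __init__(self, initial: Molecule | None = None,
                 templates: dict[str, Template] | None = None):
        self.state = SketchState(molecule=initial.copy() if initial else Molecule())
        self.templates = dict(templates) if templates is not None else builtin_templates()
        self.clipboard: Template | None = None

    def apply(self, step: ScriptStep, number: int = 0) -> None:
        if step.action not in _ACTIONS:
            raise ScriptError(number, f"unknown action {step.action!r}")
        state = self._with_subject(step, number)
        log.info(
            "step %d: %s subject=%s params=%s", number, step.action,
            step.subject or "(empty)", step.params,
        )
        try:
            outcome = _ACTIONS[step.action](self, state, step.params)
        except ScriptError:
            raise
        except Exception as exc:
            raise ScriptError(number, f"{step.action} failed: {exc}") from exc
        if isinstance(outcome, list):  # ranked graft results
            log.info("step %d: %d ranked results", number, len(outcome))
            if not outcome:
                raise ScriptError(number, "graft produced no results")
            if not 0 <= step.result < len(outcome):
                raise ScriptError(
                    number,
                    f"result index {step.result} out of range (have {len(outcome)})",
                )
            self.state = SketchState(molecule=outcome[step.result].molecule)
        else:
            self.state = outcome

    def _with_subject(self, step: ScriptStep, number: int) -> SketchState:
        mol = self.state.molecule
        state = SketchState(molecule=mol)
        sub = step.subject
        try:
            if "select" in sub:
                state.selection = set(int(i) for i in sub["select"])
            if "current_atom" in sub and sub["current_atom"] is not None:
                state = SketchState(
                    molecule=mol, selection=state.selection,
                    current_atom=int(sub["current_atom"]),
                )
            if "current_bond" in sub and sub["current_bond"] is not None:
                a, b = sub["current_bond"]
                bidx = mol.find_bond(int(a), int(b))
                if bidx is None:
                    raise ValueError(f"no bond between atoms {a} and {b}")
                state = SketchState(
                    molecule=mol, selection=state.selection, current_bond=bidx,
                )
            if not sub:
                state = SketchState(molecule=mol)
        except (ValueError, KeyError) as exc:
            raise ScriptError(number, f"bad subject: {exc}") from exc
        if any(not 0 <= i < len(mol.atoms) for i in state.selection):
            raise ScriptError(number, "selection index out of range")
        return state


def load_script(text: str) -> list[ScriptStep]:
    """Parse a JSON (or YAML, when available) script into steps."""
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        raw = yaml.safe_load(text)
    if not isinstance(raw, list):
        raise ValueError("a script must be a list of steps")
    return [ScriptStep.from_dict(d) for d in raw]


def run_script(steps: list[ScriptStep], initial: Molecule | None = None,
               templates: dict[str, Template] | None = None) -> Molecule:
    """Apply the steps in order and return the final molecule."""
    engine = SketchEngine(initial, templates)
    for i, step in enumerate(steps, start=1):
        engine.apply(step, i)
    return engine.state.molecule
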