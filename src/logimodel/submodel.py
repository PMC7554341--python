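"""Sub-model extraction around a selected component set.

Given a selection C, the sub-model keeps C plus the regulators of every
selected component (one regulator layer, no recursion).  A kept component
whose regulators all lie in the sub-model keeps its original rule; any
other kept component becomes an external input (self-copy rule), so the
verification harness can explore every valuation of the boundary.
"""

from __future__ import annotations

from typing import Dict, Iterable, Set

from .model_core import (
    Component,
    LogicalFunction,
    LogicalModel,
    ModelError,
    identity_function,
)

__all__ = ["extract_submodel"]


def extract_submodel(model: LogicalModel, selection: Iterable[str]) -> LogicalModel:
    """Extract the sub-model M' = (S, f') around ``selection``.

    S is the selection plus the regulators of each selected component.
    For c in S, f'_c is f_c when R(c) is contained in S, otherwise c
    becomes an input.  Component order and max_levels are preserved.
    """
    selected: Set[str] = set(selection)
    if not selected:
        raise ModelError("selection must be non-empty")
    for name in selected:
        model.component(name)

    kept: Set[str] = set(selected)
    for name in selected:
        kept |= model.functions[name].regulators()

    components = []
    functions: Dict[str, LogicalFunction] = {}
    for comp in model.components:
        if comp.name not in kept:
            continue
        if model.functions[comp.name].regulators() <= kept:
            components.append(Component(comp.name, comp.max_level, comp.input))
            functions[comp.name] = model.functions[comp.name]
        else:
            components.append(Component(comp.name, comp.max_level, input=True))
            functions[comp.name] = identity_function(comp.name, comp.max_level)
    return LogicalModel(tuple(components), functions)
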