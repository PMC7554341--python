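"""Built-in toy models and a seeded random-model generator.

The toy models cover a six-node percolation example (four inputs feeding
two core nodes) and a pair of small calcium-handling models: the ER calcium
reservoir (Calcium_ER) is emptied through the IP3R1 channel and refilled by
the SERCA pump.  The *default* rule ``SERCA & !IP3R1`` forces SERCA active
in any stable state with a full reservoir; the *corrected* rule adds the
reservoir's own persistence, ``(SERCA | Calcium_ER) & !IP3R1``, so a full
reservoir can be stable with the pump off as long as the channel stays
closed.  The two fixtures form a matched fail/pass pair for the
verification harness.

The random generator builds human-readable expression-tree rules (not raw
truth tables) and is deterministic for a given seed, providing the test
surface for the brute-force oracles.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Optional

from .model_core import (
    Atom,
    Component,
    Expr,
    LogicalFunction,
    LogicalModel,
    ModelError,
    Not,
    PartialAssignment,
    identity_function,
    make_and,
    make_or,
    parse_model,
)

__all__ = [
    "toy_model",
    "TOY_MODELS",
    "GeneratorConfig",
    "random_model",
    "apply_perturbation",
]

_FIGURE3 = """\
# Six-node percolation example: four inputs (A, B, C, F) and two core
# nodes.  D integrates three activators; E needs D and is blocked by F.
A, A
B, B
C, C
F, F
D, A | B | C
E, D & !F
"""

_CALCIUM_COMMON = """\
IP3R_stim, IP3R_stim
SERCA_stim, SERCA_stim
IP3R1, IP3R_stim
SERCA, SERCA_stim
"""

_CALCIUM_DEFAULT = _CALCIUM_COMMON + "Calcium_ER, SERCA & !IP3R1\n"
_CALCIUM_CORRECTED = _CALCIUM_COMMON + "Calcium_ER, (SERCA | Calcium_ER) & !IP3R1\n"

TOY_MODELS = ("figure3", "calcium_default", "calcium_corrected")


def toy_model(name: str) -> LogicalModel:
    """A named built-in toy model (see module docstring)."""
    if name == "figure3":
        return parse_model(_FIGURE3)
    if name == "calcium_default":
        return parse_model(_CALCIUM_DEFAULT)
    if name == "calcium_corrected":
        return parse_model(_CALCIUM_CORRECTED)
    raise ModelError(f"unknown toy model {name!r}; available: {', '.join(TOY_MODELS)}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random-model generator.

    ``expression_bias`` is the probability of AND (vs OR) at each internal
    node of a generated rule; ``negation_prob`` the probability that a leaf
    literal is negated.  ``max_level`` > 1 lets each non-input component
    draw a maximum level in ``1..max_level`` and carry per-level cases.
    """

    n_components: int
    n_inputs: int = 0
    max_in_degree: int = 2
    max_level: int = 1
    expression_bias: float = 0.5
    negation_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_components < 1:
            raise ModelError("n_components must be >= 1")
        if not 0 <= self.n_inputs <= self.n_components:
            raise ModelError("n_inputs must be in 0..n_components")
        if self.max_in_degree < 1:
            raise ModelError("max_in_degree must be >= 1")
        if self.max_level < 1:
            raise ModelError("max_level must be >= 1")
        for p in (self.expression_bias, self.negation_prob):
            if not 0.0 <= p <= 1.0:
                raise ModelError("probabilities must be in [0, 1]")


def _random_expression(
    rng: random.Random,
    regulators: List[str],
    max_levels: Dict[str, int],
    bias: float,
    neg_prob: float,
) -> Expr:
    """Random expression tree using each regulator exactly once as a leaf."""
    if len(regulators) == 1:
        name = regulators[0]
        leaf: Expr = Atom(name, rng.randint(1, max_levels[name]))
        return Not(leaf) if rng.random() < neg_prob else leaf
    cut = rng.randint(1, len(regulators) - 1)
    left = _random_expression(rng, regulators[:cut], max_levels, bias, neg_prob)
    right = _random_expression(rng, regulators[cut:], max_levels, bias, neg_prob)
    if rng.random() < bias:
        return make_and(left, right)
    return make_or(left, right)


def _reachable_cases(model_max: Dict[str, int], cases):
    """Drop cases whose condition is subsumed by earlier cases."""
    from itertools import product as _product

    kept = []
    for condition, level in cases:
        regs = sorted(
            {a.component for c, _ in kept for a in c.atoms()}
            | {a.component for a in condition.atoms()}
        )
        ranges = [range(model_max[r] + 1) for r in regs]
        reachable = False
        for combo in _product(*ranges):
            local = dict(zip(regs, combo))
            if condition.evaluate(local) and not any(
                c.evaluate(local) for c, _ in kept
            ):
                reachable = True
                break
        if reachable:
            kept.append((condition, level))
    return tuple(kept)


def random_model(config: GeneratorConfig) -> LogicalModel:
    """Generate a seeded random model satisfying ``validate_model``."""
    rng = random.Random(config.seed)
    n_core = config.n_components - config.n_inputs
    input_names = [f"i{k + 1}" for k in range(config.n_inputs)]
    core_names = [f"v{k + 1}" for k in range(n_core)]
    all_names = input_names + core_names

    max_levels: Dict[str, int] = {}
    for name in all_names:
        max_levels[name] = (
            1 if config.max_level == 1 else rng.randint(1, config.max_level)
        )

    components = []
    functions: Dict[str, LogicalFunction] = {}
    for name in input_names:
        components.append(Component(name, max_levels[name], input=True))
        functions[name] = identity_function(name, max_levels[name])
    for name in core_names:
        k = rng.randint(1, min(config.max_in_degree, len(all_names)))
        regs = rng.sample(all_names, k)
        own_max = max_levels[name]
        if own_max == 1:
            expr = _random_expression(
                rng, regs, max_levels, config.expression_bias, config.negation_prob
            )
            cases = ((expr, 1),)
        else:
            n_cases = rng.randint(1, own_max)
            targets = rng.sample(range(1, own_max + 1), n_cases)
            raw = tuple(
                (
                    _random_expression(
                        rng,
                        regs,
                        max_levels,
                        config.expression_bias,
                        config.negation_prob,
                    ),
                    target,
                )
                for target in targets
            )
            cases = _reachable_cases(max_levels, raw)
        fn = LogicalFunction(cases)
        # a rule that came out as the bare identity makes the component an
        # input by convention; flag it so serialisation round-trips
        components.append(
            Component(name, own_max, input=(fn == identity_function(name, own_max)))
        )
        functions[name] = fn
    return LogicalModel(tuple(components), functions)


def apply_perturbation(
    model: LogicalModel,
    component: str,
    kind: str,
    level: Optional[int] = None,
) -> PartialAssignment:
    """Clamp set for a knockout (level 0) or ectopic expression.

    Ectopic level defaults to the component's maximal level.  The returned
    clamp composes with other clamps and feeds propagate/verify directly.
    """
    comp = model.component(component)
    if kind == "knockout":
        if level not in (None, 0):
            raise ModelError("knockout fixes level 0; do not pass a level")
        return {component: 0}
    if kind == "ectopic":
        if level is None:
            level = comp.max_level
        if not 1 <= level <= comp.max_level:
            raise ModelError(
                f"ectopic level {level} out of range 1..{comp.max_level} "
                f"for {component}"
            )
        return {component: level}
    raise ModelError(f"unknown perturbation kind {kind!r}")
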