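"""Decision layer: expected utility of mating alternatives.

A mating decision is scored by attaching utilities to the offspring
genotype (e.g. 100/100/0 to value any non-affected pup, or 100/50/0 to
penalize carriers) and averaging them over the genotype posterior under
the evidence describing that alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import inference
from . import network as net_mod
from .exceptions import ValidationError
from .network import CounselingNetwork
from .pedigree import GENOTYPES

__all__ = ["UtilitySpec", "Alternative", "DecisionReport", "expected_utility", "compare_alternatives"]


@dataclass(frozen=True)
class UtilitySpec:
    """Utility of each offspring genotype (uAA, uAB, uBB)."""

    uAA: float
    uAB: float
    uBB: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(u) for u in (self.uAA, self.uAB, self.uBB)):
            raise ValidationError("utilities must be finite")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.uAA, self.uAB, self.uBB)


@dataclass(frozen=True)
class Alternative:
    """One decision alternative: a label plus its evidence assignment."""

    label: str
    evidence: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class DecisionReport:
    """Expected utility per alternative and the argmax recommendation."""

    expected_utilities: Mapping[str, float]
    recommended: str
    tie: bool

    def as_dict(self) -> dict:
        return {
            "expected_utilities": dict(self.expected_utilities),
            "recommended": self.recommended,
            "tie": self.tie,
        }


def expected_utility(
    net: CounselingNetwork,
    evidence: Mapping[str, str],
    utilities: UtilitySpec,
    offspring_id: str = "offspring",
) -> float:
    """Expected utility over the offspring genotype posterior."""
    node = net_mod.genotype_node(offspring_id)
    if node not in net.nodes:
        raise ValidationError(f"no genotype node for individual {offspring_id!r}")
    if node in evidence:
        raise ValidationError(f"offspring genotype {node!r} must not be evidence")
    report = inference.posterior(net, node, evidence)
    return sum(report[g] * u for g, u in zip(GENOTYPES, utilities.as_tuple()))


def compare_alternatives(
    net: CounselingNetwork,
    alternatives: Sequence[Alternative],
    utilities: UtilitySpec,
    offspring_id: str = "offspring",
) -> DecisionReport:
    """Score alternatives and recommend the expected-utility maximizer.

    Exact ties are broken lexicographically by label and flagged.
    """
    if not alternatives:
        raise ValidationError("at least one alternative is required")
    labels = [a.label for a in alternatives]
    if len(set(labels)) != len(labels):
        raise ValidationError("alternative labels must be unique")
    scores = {
        a.label: expected_utility(net, a.evidence, utilities, offspring_id)
        for a in alternatives
    }
    best = max(scores.values())
    winners = sorted(label for label, s in scores.items() if s == best)
    return DecisionReport(scores, winners[0], tie=len(winners) > 1)
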