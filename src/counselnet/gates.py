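"""Leaky noisy-OR gates: risk evaluation and CPT construction.

A noisy-OR gate models an effect (here: clinical signs) with several
independent causal mechanisms. Each modeled cause, when present, fires
its mechanism with its link probability p_i; unmodeled causes fire with
the leak probability p_0; the effect occurs iff at least one mechanism
fires. For the set of active causes the risk is therefore

    P(effect | active) = 1 - (1 - p_0) * prod_{i active} (1 - p_i)

The leak multiplies into every row (Diez convention), so the all-absent
row equals (p_0, 1 - p_0). The CPT over n causes takes n + 1 numbers
instead of 2^n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Tuple

from .exceptions import ValidationError

__all__ = ["NoisyOrSpec", "risk", "build_cpt", "MAX_CAUSES"]

#: Hard cap on explicit CPT materialization (2^16 rows).
MAX_CAUSES = 16

#: One CPT row key: ((cause, present?), ...) in the spec's cause order.
Assignment = Tuple[Tuple[str, bool], ...]


def _check_prob(p: float, what: str) -> float:
    p = float(p)
    if not (math.isfinite(p) and 0.0 <= p <= 1.0):
        raise ValidationError(f"{what} must be a probability in [0, 1], got {p}")
    return p


@dataclass(frozen=True)
class NoisyOrSpec:
    """Leak probability plus ordered per-cause link probabilities."""

    leak: float
    links: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_prob(self.leak, "leak")
        links = dict(self.links)
        if len(links) != len(self.links):
            raise ValidationError("cause identifiers must be unique")
        for cause, p in links.items():
            _check_prob(p, f"link probability of {cause!r}")
        object.__setattr__(self, "links", links)

    @property
    def causes(self) -> tuple[str, ...]:
        return tuple(self.links)


def risk(spec: NoisyOrSpec, active: Iterable[str]) -> float:
    """Probability of the effect given the set of active causes.

    ``active`` is any iterable of cause identifiers; causes outside the
    spec raise a :class:`ValidationError`.
    """
    active = set(active)
    unknown = active - set(spec.links)
    if unknown:
        raise ValidationError(f"unknown cause identifier(s): {sorted(unknown)}")
    if not active:  # empty product: the leak, exactly
        return spec.leak
    survive = 1.0 - spec.leak
    for cause in active:
        survive *= 1.0 - spec.links[cause]
    return 1.0 - survive


def build_cpt(spec: NoisyOrSpec) -> dict[Assignment, tuple[float, float]]:
    """Materialize the full CPT of a noisy-OR gate.

    Returns a mapping from each of the 2^n cause-state assignments
    (explicit ``(cause, present)`` pairs, in the spec's cause order — a
    row is addressed by what it asserts, never by position) to the pair
    ``(P(effect), 1 - P(effect))``.
    """
    causes = spec.causes
    if len(causes) > MAX_CAUSES:
        raise ValidationError(
            f"CPT over {len(causes)} causes would have {2 ** len(causes)} rows; "
            f"the limit is {MAX_CAUSES} causes"
        )
    cpt: dict[Assignment, tuple[float, float]] = {}
    for states in product((False, True), repeat=len(causes)):
        key: Assignment = tuple(zip(causes, states))
        p = risk(spec, (c for c, on in key if on))
        cpt[key] = (p, 1.0 - p)
    return cpt
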