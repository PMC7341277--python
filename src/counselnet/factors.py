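"""Discrete factor algebra for exact inference.

A Factor is a nonnegative table over a tuple of named variables, each
with named states. Factors multiply by broadcasting over the union of
their scopes, marginalize by summing an axis out, and reduce by slicing
an observed state. These three operations are all that enumeration and
variable elimination need.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = ["Factor"]


class Factor:
    __slots__ = ("variables", "states", "values")

    def __init__(
        self,
        variables: Sequence[str],
        states: Mapping[str, Sequence[str]],
        values: np.ndarray,
    ):
        self.variables = tuple(variables)
        self.states = {v: tuple(states[v]) for v in self.variables}
        self.values = np.asarray(values, dtype=float)
        expected = tuple(len(self.states[v]) for v in self.variables)
        if self.values.shape != expected:
            raise ValidationError(
                f"factor over {self.variables} expects shape {expected}, "
                f"got {self.values.shape}"
            )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Factor({self.variables}, total={self.values.sum():.6g})"

    def multiply(self, other: "Factor") -> "Factor":
        union = list(self.variables) + [
            v for v in other.variables if v not in self.variables
        ]
        states = {**other.states, **self.states}
        a = self._aligned(union, states)
        b = other._aligned(union, states)
        return Factor(union, states, a * b)

    def _aligned(self, union: list[str], states: Mapping[str, Sequence[str]]) -> np.ndarray:
        """View of values broadcastable over the union scope."""
        present = [v for v in union if v in self.variables]
        perm = [self.variables.index(v) for v in present]
        arr = np.transpose(self.values, perm)
        shape = tuple(len(states[v]) if v in self.variables else 1 for v in union)
        return arr.reshape(shape)

    def marginalize(self, variable: str) -> "Factor":
        axis = self.variables.index(variable)
        rest = tuple(v for v in self.variables if v != variable)
        return Factor(rest, self.states, self.values.sum(axis=axis))

    def reduce(self, variable: str, state: str) -> "Factor":
        axis = self.variables.index(variable)
        try:
            idx = self.states[variable].index(state)
        except ValueError:
            raise ValidationError(
                f"state {state!r} not valid for {variable!r}; "
                f"expected one of {self.states[variable]}"
            ) from None
        rest = tuple(v for v in self.variables if v != variable)
        return Factor(rest, self.states, np.take(self.values, idx, axis=axis))

    def total(self) -> float:
        return float(self.values.sum())
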