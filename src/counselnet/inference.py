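"""Exact inference: enumeration oracle, variable elimination, counseling queries.

Two independent routes compute every posterior. ``joint_enumeration``
multiplies all CPT factors into the full joint table (exponential, only
viable on small networks) and is the correctness oracle.
``posterior`` runs variable elimination with a min-degree ordering and
is the production path; the two agree to 1e-10 by construction and by
test.

Evidence whose joint probability is zero raises
:class:`~counselnet.exceptions.InconsistentEvidenceError` — a Mendelian
impossibility should fail loudly, not normalize garbage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from . import network as net_mod
from . import priors as priors_mod
from .exceptions import InconsistentEvidenceError, ValidationError
from .factors import Factor
from .network import CounselingNetwork

__all__ = [
    "PosteriorReport",
    "joint_enumeration",
    "posterior",
    "enumeration_posterior",
    "counsel_risk",
    "posterior_over_draws",
]

#: Node-count cap for full-joint enumeration.
MAX_ENUMERATION_NODES = 24

_ZERO_MASS = 1e-300


@dataclass(frozen=True)
class PosteriorReport:
    """Posterior distribution of one node, with the query context echoed."""

    query: str
    states: tuple[str, ...]
    probabilities: tuple[float, ...]
    evidence: Mapping[str, str] = field(default_factory=dict)
    meta: Mapping[str, object] = field(default_factory=dict)

    def __getitem__(self, state: str) -> float:
        return self.probabilities[self.states.index(state)]

    def as_dict(self) -> dict:
        return {
            "query": self.query,
            "posterior": dict(zip(self.states, self.probabilities)),
            "evidence": dict(self.evidence),
            "meta": dict(self.meta),
        }


def _reduced_factors(net: CounselingNetwork, evidence: Mapping[str, str]) -> list[Factor]:
    evidence = net.check_evidence(evidence)
    factors = []
    for f in net.to_factors():
        for node, state in evidence.items():
            if node in f.variables:
                f = f.reduce(node, state)
        factors.append(f)
    return factors


def joint_enumeration(net: CounselingNetwork, evidence: Mapping[str, str]) -> Factor:
    """Unnormalized joint over all non-evidence nodes, by brute force.

    Multiplies every CPT factor (evidence sliced out) into one table
    with no elimination order and no intermediate marginalization; the
    total mass equals P(evidence). Raises on zero-probability evidence.
    """
    if len(net.nodes) > MAX_ENUMERATION_NODES:
        raise ValidationError(
            f"enumeration limited to {MAX_ENUMERATION_NODES} nodes, "
            f"network has {len(net.nodes)}"
        )
    factors = _reduced_factors(net, evidence)
    joint = factors[0]
    for f in factors[1:]:
        joint = joint.multiply(f)
    if joint.total() <= _ZERO_MASS:
        raise InconsistentEvidenceError(
            f"evidence {dict(evidence)} has zero probability under the model"
        )
    return joint


def enumeration_posterior(
    net: CounselingNetwork, query: str, evidence: Mapping[str, str]
) -> PosteriorReport:
    """Posterior via the enumeration oracle (for cross-checks)."""
    if query in evidence:
        raise ValidationError(f"query node {query!r} is already evidence")
    if query not in net.nodes:
        raise ValidationError(f"unknown query node {query!r}")
    joint = joint_enumeration(net, evidence)
    for v in sorted(joint.variables):
        if v != query:
            joint = joint.marginalize(v)
    probs = joint.values / joint.total()
    return PosteriorReport(
        query, net.nodes[query].states, tuple(float(p) for p in probs), dict(evidence),
        {"method": "enumeration"},
    )


def _min_degree_order(factors: list[Factor], keep: set[str]) -> list[str]:
    """Min-degree elimination order; ties broken lexicographically."""
    neighbors: dict[str, set[str]] = {}
    for f in factors:
        for v in f.variables:
            neighbors.setdefault(v, set()).update(f.variables)
    for v, ns in neighbors.items():
        ns.discard(v)
    order = []
    remaining = {v for v in neighbors if v not in keep}
    while remaining:
        v = min(remaining, key=lambda x: (len(neighbors[x] & remaining), x))
        order.append(v)
        # connect v's remaining neighbors (fill-in), then drop v
        around = neighbors[v] & remaining
        for a in around:
            neighbors[a].update(around - {a})
            neighbors[a].discard(v)
        remaining.remove(v)
    return order


def posterior(
    net: CounselingNetwork,
    query: str,
    evidence: Mapping[str, str] | None = None,
    meta: Mapping[str, object] | None = None,
) -> PosteriorReport:
    """Posterior of one node by variable elimination."""
    evidence = dict(evidence or {})
    if query in evidence:
        raise ValidationError(f"query node {query!r} is already evidence")
    if query not in net.nodes:
        raise ValidationError(f"unknown query node {query!r}")
    factors = _reduced_factors(net, evidence)
    for var in _min_degree_order(factors, keep={query}):
        touching = [f for f in factors if var in f.variables]
        rest = [f for f in factors if var not in f.variables]
        prod = touching[0]
        for f in touching[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.marginalize(var)]
    result = factors[0]
    for f in factors[1:]:
        result = result.multiply(f)
    total = result.total()
    if total <= _ZERO_MASS:
        raise InconsistentEvidenceError(
            f"evidence {evidence} has zero probability under the model"
        )
    if result.variables != (query,):
        result = Factor(
            (query,), {query: result.states[query]}, result._aligned([query], result.states).reshape(-1)
        )
    probs = result.values / total
    return PosteriorReport(
        query,
        net.nodes[query].states,
        tuple(float(p) for p in probs),
        evidence,
        dict(meta or {"method": "variable_elimination"}),
    )


def counsel_risk(
    net: CounselingNetwork,
    individual_id: str,
    evidence: Mapping[str, str] | None = None,
    ng_states: Mapping[str, str] | None = None,
) -> float:
    """Probability that an individual shows clinical signs.

    ``ng_states`` optionally instantiates the individual's own diet /
    exercise / age nodes ('T' or 'F') on top of ``evidence`` (which may
    carry genotype or test results).
    """
    if individual_id not in net.individuals:
        raise ValidationError(f"unknown individual {individual_id!r}")
    ev = dict(evidence or {})
    if ng_states:
        rf_by_cause = dict(
            zip(("diet", "exercise", "age"), net_mod.risk_factor_nodes(individual_id))
        )
        for cause, state in ng_states.items():
            if cause not in rf_by_cause:
                raise ValidationError(f"unknown non-genetic factor {cause!r}")
            ev[rf_by_cause[cause]] = state
    report = posterior(net, net_mod.phenotype_node(individual_id), ev)
    return report["signs"]


def posterior_over_draws(
    group: priors_mod.PriorGroup,
    evidence: Mapping[str, str],
    query: str,
    n_draws: int,
    seed=0,
    build: Callable[[Mapping[str, float]], CounselingNetwork] | None = None,
) -> PosteriorReport:
    """Average a posterior over gate-parameter draws (experimental).

    For each draw, sample point values (leak, genetic link, one link per
    non-genetic factor) from the prior group, rebuild the network with
    ``build`` (default: the trio builder) and recompute the posterior;
    report the across-draw mean per state, with the across-draw sd in
    ``meta['sd']``. Deterministic given the seed.
    """
    if n_draws < 2:
        raise ValidationError(f"n_draws must be >= 2, got {n_draws}")
    rngs = priors_mod._spawn(seed, 5)
    leak = priors_mod.sample(group.leak, n_draws, rngs[0])
    link_g = priors_mod.sample(group.link_g, n_draws, rngs[1])
    ng = [priors_mod.sample(group.link_ng, n_draws, rngs[2 + i]) for i in range(3)]

    if build is None:
        def build(params: Mapping[str, float]) -> CounselingNetwork:
            from . import gates

            return net_mod.build_trio(
                gate=gates.NoisyOrSpec(
                    leak=params["leak"],
                    links={
                        "genetic": params["genetic"],
                        "diet": params["diet"],
                        "exercise": params["exercise"],
                        "age": params["age"],
                    },
                )
            )

    rows = []
    states = None
    for k in range(n_draws):
        net = build(
            {
                "leak": float(leak[k]),
                "genetic": float(link_g[k]),
                "diet": float(ng[0][k]),
                "exercise": float(ng[1][k]),
                "age": float(ng[2][k]),
            }
        )
        rep = posterior(net, query, evidence)
        states = rep.states
        rows.append(rep.probabilities)
    arr = np.array(rows)
    return PosteriorReport(
        query,
        states,
        tuple(float(p) for p in arr.mean(axis=0)),
        dict(evidence),
        {
            "method": "per_draw_posterior",
            "draws": n_draws,
            "seed": seed,
            "sd": tuple(float(s) for s in arr.std(axis=0, ddof=1)),
        },
    )
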