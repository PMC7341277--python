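"""Assembly of the counseling Bayesian network.

The network mirrors a pedigree: one genotype node per individual
(founders carry a prior, children a Mendelian transmission CPT keyed on
their parents' genotypes), and per individual a phenotype node driven by
a leaky noisy-OR gate over four causes — the genetic cause (active for
the at-risk genotypes) and three binary non-genetic risk factors (diet,
exercise, age). Optional test nodes attach to genotype nodes with a
sensitivity/specificity CPT.

Node naming follows the pedigree: ``G_<id>`` genotype, ``P_<id>``
phenotype, ``D_<id>``/``E_<id>``/``A_<id>`` diet/exercise/age,
``T_<id>`` test result.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from . import gates, pedigree, priors
from .exceptions import ConfigError, StructureError, ValidationError
from .factors import Factor

__all__ = [
    "CounselingNetwork",
    "DiscreteNode",
    "Individual",
    "build_trio",
    "add_relative",
    "add_test_node",
    "deterministic_limit_gate",
    "from_config",
    "to_config",
    "parse_probability",
    "genotype_node",
    "phenotype_node",
    "risk_factor_nodes",
    "test_node",
    "BINARY_STATES",
    "PHENOTYPE_STATES",
    "TEST_STATES",
]

#: Binary risk-factor states: present / absent.
BINARY_STATES = ("T", "F")
#: Phenotype states: clinical signs present / absent.
PHENOTYPE_STATES = ("signs", "healthy")
#: Genetic-test result states.
TEST_STATES = ("positive", "negative")

#: Cause identifiers of the phenotype gate, in fixed order.
GATE_CAUSES = ("genetic", "diet", "exercise", "age")
#: Risk-factor node prefixes paired with their gate cause.
_RF_PREFIXES = (("D", "diet"), ("E", "exercise"), ("A", "age"))


def genotype_node(individual_id: str) -> str:
    return f"G_{individual_id}"


def phenotype_node(individual_id: str) -> str:
    return f"P_{individual_id}"


def risk_factor_nodes(individual_id: str) -> tuple[str, str, str]:
    """(diet, exercise, age) node names for one individual."""
    return tuple(f"{p}_{individual_id}" for p, _ in _RF_PREFIXES)


def test_node(individual_id: str) -> str:
    return f"T_{individual_id}"


@dataclass(frozen=True)
class DiscreteNode:
    """One discrete node: named states and a CPT indexed by parent states.

    ``cpt`` has shape ``(card(parent_1), ..., card(parent_k), card(self))``;
    root nodes hold a bare prior of shape ``(card(self),)``.
    """

    name: str
    states: tuple[str, ...]
    parents: tuple[str, ...]
    cpt: np.ndarray


@dataclass(frozen=True)
class Individual:
    """Pedigree member: founder (prior) or child of a sire and a dam."""

    id: str
    sire: str | None = None
    dam: str | None = None
    genotype_prior: pedigree.GenotypeDist | None = None

    def __post_init__(self) -> None:
        has_parents = self.sire is not None or self.dam is not None
        if has_parents:
            if self.sire is None or self.dam is None:
                raise StructureError(
                    f"individual {self.id!r} must have both parents or neither"
                )
            if self.sire == self.dam:
                raise StructureError(
                    f"individual {self.id!r} has identical sire and dam {self.sire!r}"
                )
            if self.id in (self.sire, self.dam):
                raise StructureError(f"individual {self.id!r} cannot be its own parent")
        elif self.genotype_prior is None:
            raise StructureError(f"founder {self.id!r} needs a genotype prior")

    @property
    def is_founder(self) -> bool:
        return self.sire is None


def deterministic_limit_gate(link_ng: float = 0.0) -> gates.NoisyOrSpec:
    """Gate in the deterministic limit: leak 0, genetic link 1.

    Under it an at-risk genotype always produces signs and, with no
    active non-genetic factor, any other genotype never does.
    """
    return gates.NoisyOrSpec(
        leak=0.0,
        links={"genetic": 1.0, "diet": link_ng, "exercise": link_ng, "age": link_ng},
    )


def _genetic_active(genotype: str, genetic_model: str) -> bool:
    if genetic_model == "recessive":
        return genotype == "BB"
    if genetic_model == "dominant":
        return genotype in ("AB", "BB")
    raise ValidationError(f"unknown genetic model {genetic_model!r}")


def _phenotype_cpt_point(gate: gates.NoisyOrSpec, genetic_model: str) -> np.ndarray:
    """Phenotype CPT from point-valued gate parameters.

    Parent order: genotype, diet, exercise, age. Shape (3, 2, 2, 2, 2).
    """
    cpt = np.empty((3, 2, 2, 2, 2))
    for gi, genotype in enumerate(pedigree.GENOTYPES):
        for di, d in enumerate(BINARY_STATES):
            for ei, e in enumerate(BINARY_STATES):
                for ai, a in enumerate(BINARY_STATES):
                    active = [
                        c
                        for c, on in zip(
                            GATE_CAUSES,
                            (
                                _genetic_active(genotype, genetic_model),
                                d == "T",
                                e == "T",
                                a == "T",
                            ),
                        )
                        if on
                    ]
                    p = gates.risk(gate, active)
                    cpt[gi, di, ei, ai] = (p, 1.0 - p)
    return cpt


def _phenotype_cpt_mc(
    group: priors.PriorGroup, genetic_model: str, draws: int, seed
) -> np.ndarray:
    """Phenotype CPT as the Monte-Carlo average over gate-parameter draws."""
    if draws < 2:
        raise ValidationError(f"mc_mean needs draws >= 2, got {draws}")
    rngs = priors._spawn(seed, 5)  # leak, genetic, diet, exercise, age
    leak = priors.sample(group.leak, draws, rngs[0])
    link_g = priors.sample(group.link_g, draws, rngs[1])
    ng = [priors.sample(group.link_ng, draws, rngs[2 + i]) for i in range(3)]
    acc = np.zeros((3, 2, 2, 2, 2))
    links_by_cause = dict(zip(GATE_CAUSES, [link_g] + ng))
    for gi, genotype in enumerate(pedigree.GENOTYPES):
        for di, d in enumerate(BINARY_STATES):
            for ei, e in enumerate(BINARY_STATES):
                for ai, a in enumerate(BINARY_STATES):
                    survive = 1.0 - leak
                    flags = (
                        _genetic_active(genotype, genetic_model),
                        d == "T",
                        e == "T",
                        a == "T",
                    )
                    for cause, on in zip(GATE_CAUSES, flags):
                        if on:
                            survive = survive * (1.0 - links_by_cause[cause])
                    p = float(np.mean(1.0 - survive))
                    acc[gi, di, ei, ai] = (p, 1.0 - p)
    return acc


class CounselingNetwork:
    """Pedigree-structured discrete Bayesian network with noisy-OR phenotypes.

    Nodes are inserted parents-first, so the stored order is topological
    and the graph is acyclic by construction; :meth:`validate` re-checks
    both properties defensively.
    """

    def __init__(
        self,
        genetic_model: str = "recessive",
        rf_prior: float = 0.5,
        phenotype_cpt: np.ndarray | None = None,
        gate_prior: priors.PriorGroup | None = None,
        config: dict | None = None,
    ):
        if genetic_model not in ("recessive", "dominant"):
            raise ValidationError(f"unknown genetic model {genetic_model!r}")
        if not 0.0 <= rf_prior <= 1.0:
            raise ValidationError(f"risk-factor prior must be in [0,1], got {rf_prior}")
        self.genetic_model = genetic_model
        self.rf_prior = rf_prior
        self.phenotype_cpt = phenotype_cpt  # shared by all individuals
        self.gate_prior = gate_prior  # Beta priors behind the gate, if any
        self.nodes: dict[str, DiscreteNode] = {}
        self.individuals: dict[str, Individual] = {}
        self.config = config

    # -- construction -------------------------------------------------

    def _add_node(
        self,
        name: str,
        states: Sequence[str],
        parents: Sequence[str],
        cpt: np.ndarray,
    ) -> None:
        if name in self.nodes:
            raise StructureError(f"duplicate node id {name!r}")
        for p in parents:
            if p not in self.nodes:
                raise StructureError(f"node {name!r} references unknown parent {p!r}")
        cpt = np.asarray(cpt, dtype=float)
        expected = tuple(len(self.nodes[p].states) for p in parents) + (len(states),)
        if cpt.shape != expected:
            raise StructureError(
                f"CPT of {name!r} has shape {cpt.shape}, expected {expected}"
            )
        if np.any(cpt < -1e-12) or np.any(np.abs(cpt.sum(axis=-1) - 1.0) > 1e-9):
            raise StructureError(f"CPT rows of {name!r} must be probabilities summing to 1")
        self.nodes[name] = DiscreteNode(name, tuple(states), tuple(parents), cpt)

    def add_individual(self, individual: Individual) -> None:
        """Add an individual's genotype, risk-factor and phenotype nodes."""
        if self.phenotype_cpt is None:
            raise StructureError("network has no phenotype gate configured")
        if individual.id in self.individuals:
            raise StructureError(f"duplicate individual id {individual.id!r}")
        g = genotype_node(individual.id)
        if individual.is_founder:
            self._add_node(g, pedigree.GENOTYPES, (), individual.genotype_prior.as_tuple())
        else:
            for parent in (individual.sire, individual.dam):
                if parent not in self.individuals:
                    raise StructureError(
                        f"individual {individual.id!r} references unknown parent {parent!r}"
                    )
            trans = np.empty((3, 3, 3))
            for si, gs in enumerate(pedigree.GENOTYPES):
                for di, gd in enumerate(pedigree.GENOTYPES):
                    trans[si, di] = pedigree.transmission(gs, gd).as_tuple()
            self._add_node(
                g,
                pedigree.GENOTYPES,
                (genotype_node(individual.sire), genotype_node(individual.dam)),
                trans,
            )
        for rf in risk_factor_nodes(individual.id):
            self._add_node(rf, BINARY_STATES, (), (self.rf_prior, 1.0 - self.rf_prior))
        self._add_node(
            phenotype_node(individual.id),
            PHENOTYPE_STATES,
            (g, *risk_factor_nodes(individual.id)),
            self.phenotype_cpt,
        )
        self.individuals[individual.id] = individual

    def add_test(
        self,
        individual_id: str,
        sensitivity: float,
        specificity: float,
        semantics: str = "genotype_bb",
    ) -> None:
        """Attach a genetic-test node to an individual's genotype.

        ``semantics`` fixes the heterozygote: under ``genotype_bb`` the
        assay targets the BB genotype and AB behaves like a negative
        animal (positive with rate 1 - specificity); under ``allele`` it
        detects carriage of B, so AB is a true positive (rate =
        sensitivity).
        """
        if individual_id not in self.individuals:
            raise StructureError(f"unknown individual {individual_id!r}")
        for name, p in (("sensitivity", sensitivity), ("specificity", specificity)):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        if semantics not in ("genotype_bb", "allele"):
            raise ValidationError(f"unknown test semantics {semantics!r}")
        p_pos = {
            "AA": 1.0 - specificity,
            "AB": sensitivity if semantics == "allele" else 1.0 - specificity,
            "BB": sensitivity,
        }
        cpt = np.array([(p_pos[g], 1.0 - p_pos[g]) for g in pedigree.GENOTYPES])
        self._add_node(test_node(individual_id), TEST_STATES, (genotype_node(individual_id),), cpt)

    # -- queries over structure ---------------------------------------

    def to_factors(self) -> list[Factor]:
        states = {n.name: n.states for n in self.nodes.values()}
        return [
            Factor((*n.parents, n.name), states, n.cpt) for n in self.nodes.values()
        ]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for n in self.nodes.values():
            g.add_edges_from((p, n.name) for p in n.parents)
        return g

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise StructureError("network graph contains a directed cycle")
        for n in self.nodes.values():
            if np.any(np.abs(n.cpt.sum(axis=-1) - 1.0) > 1e-12):
                raise StructureError(f"CPT rows of {n.name!r} do not sum to 1")

    def check_evidence(self, evidence: Mapping[str, str]) -> dict[str, str]:
        out = {}
        for node, state in evidence.items():
            if node not in self.nodes:
                raise ValidationError(f"evidence names unknown node {node!r}")
            if state not in self.nodes[node].states:
                raise ValidationError(
                    f"state {state!r} invalid for node {node!r}; "
                    f"expected one of {self.nodes[node].states}"
                )
            out[node] = state
        return out

    def copy(self) -> "CounselingNetwork":
        return _copy.deepcopy(self)


# -- builders ---------------------------------------------------------


def _gate_from_spec(gate) -> gates.NoisyOrSpec:
    if isinstance(gate, gates.NoisyOrSpec):
        missing = set(GATE_CAUSES) - set(gate.links)
        if missing:
            raise ValidationError(f"phenotype gate missing causes {sorted(missing)}")
        return gate
    if isinstance(gate, Mapping):
        leak = gate.get("leak", priors.DEFAULT_LEAK_MEAN)
        ng = gate["link_ng"]
        return gates.NoisyOrSpec(
            leak=leak,
            links={
                "genetic": gate["link_g"],
                "diet": ng,
                "exercise": ng,
                "age": ng,
            },
        )
    raise ValidationError(f"cannot interpret gate specification {gate!r}")


def build_trio(
    group: priors.PriorGroup | None = None,
    cpt_mode: str = "point_mean",
    draws: int = 1000,
    seed=0,
    genetic_model: str = "recessive",
    *,
    gate: gates.NoisyOrSpec | Mapping | None = None,
    sire_prior: pedigree.GenotypeDist | None = None,
    dam_prior: pedigree.GenotypeDist | None = None,
    rf_prior: float = 0.5,
) -> CounselingNetwork:
    """Build the sire-dam-offspring network.

    Exactly one of ``group`` (Beta priors on the gate parameters) or
    ``gate`` (point-valued noisy-OR parameters) must be given. With a
    prior group, ``cpt_mode='point_mean'`` plugs the prior means into
    the gate; ``'mc_mean'`` averages the CPT over ``draws`` parameter
    draws. Founder genotype priors default to uniform (1/3 each).
    """
    if (group is None) == (gate is None):
        raise ValidationError("provide exactly one of a prior group or a point gate")
    if cpt_mode not in ("point_mean", "mc_mean"):
        raise ValidationError(f"unknown cpt_mode {cpt_mode!r}")
    if gate is not None:
        pheno = _phenotype_cpt_point(_gate_from_spec(gate), genetic_model)
    elif cpt_mode == "point_mean":
        leak, ng, g = group.means()
        pheno = _phenotype_cpt_point(
            _gate_from_spec({"leak": leak, "link_ng": ng, "link_g": g}), genetic_model
        )
    else:
        pheno = _phenotype_cpt_mc(group, genetic_model, draws, seed)
    net = CounselingNetwork(
        genetic_model=genetic_model,
        rf_prior=rf_prior,
        phenotype_cpt=pheno,
        gate_prior=group,
    )
    net.add_individual(
        Individual("sire", genotype_prior=sire_prior or pedigree.uniform_prior())
    )
    net.add_individual(
        Individual("dam", genotype_prior=dam_prior or pedigree.uniform_prior())
    )
    net.add_individual(Individual("offspring", sire="sire", dam="dam"))
    return net


def add_relative(net: CounselingNetwork, individual: Individual) -> CounselingNetwork:
    """Extend a network with one more relative (in place).

    Existing CPTs are untouched; the new individual reuses the network's
    phenotype gate. Parents, if any, must already be present.
    """
    net.add_individual(individual)
    return net


def with_gate(net: CounselingNetwork, gate: gates.NoisyOrSpec | Mapping) -> CounselingNetwork:
    """Copy of a network with every phenotype CPT rebuilt from point gate values.

    Used to re-evaluate the same pedigree under different gate-parameter
    draws without touching the original network.
    """
    new = net.copy()
    cpt = _phenotype_cpt_point(_gate_from_spec(gate), net.genetic_model)
    new.phenotype_cpt = cpt
    for ind_id in new.individuals:
        name = phenotype_node(ind_id)
        node = new.nodes[name]
        new.nodes[name] = DiscreteNode(node.name, node.states, node.parents, cpt)
    return new


def add_test_node(
    net: CounselingNetwork,
    individual_id: str,
    sensitivity: float,
    specificity: float,
    semantics: str = "genotype_bb",
) -> CounselingNetwork:
    """Attach a genetic-test node (see :meth:`CounselingNetwork.add_test`)."""
    net.add_test(individual_id, sensitivity, specificity, semantics)
    return net


# -- structured-text configuration ------------------------------------


def parse_probability(value, path: str = "probability") -> float:
    """Parse a probability from a float or a percent string like ``'1%'``."""
    if isinstance(value, str):
        text = value.strip()
        try:
            p = float(text[:-1]) / 100.0 if text.endswith("%") else float(text)
        except ValueError:
            raise ConfigError(f"cannot parse probability from {value!r}", path) from None
    elif isinstance(value, (int, float)) and not isinstance(value, bool):
        p = float(value)
    else:
        raise ConfigError(f"cannot parse probability from {value!r}", path)
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"probability {p} outside [0, 1]", path)
    return p


def _check_keys(d: Mapping, allowed: set[str], required: set[str], path: str) -> None:
    if not isinstance(d, Mapping):
        raise ConfigError(f"expected a mapping, got {type(d).__name__}", path)
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)}", path)
    missing = required - set(d)
    if missing:
        raise ConfigError(f"missing required key(s) {sorted(missing)}", path)


def _parse_prior_entry(value, path: str):
    """One gate-parameter entry: point probability or a Beta prior spec."""
    if isinstance(value, Mapping):
        keys = set(value)
        if keys == {"alpha", "beta"}:
            return priors.BetaSpec(float(value["alpha"]), float(value["beta"]))
        if keys == {"mean", "sd"}:
            return priors.beta_from_moments(
                parse_probability(value["mean"], f"{path}.mean"),
                parse_probability(value["sd"], f"{path}.sd"),
            )
        if keys == {"mean", "nu"}:
            return priors.beta_from_mean_concentration(
                parse_probability(value["mean"], f"{path}.mean"), float(value["nu"])
            )
        raise ConfigError(
            "prior must be {mean, sd}, {mean, nu}, {alpha, beta} or a probability",
            path,
        )
    return parse_probability(value, path)


def _parse_genotype_prior(value, path: str) -> pedigree.GenotypeDist:
    if not isinstance(value, str):
        raise ConfigError("genotype_prior must be a string", path)
    text = value.strip()
    if text == "uniform":
        return pedigree.uniform_prior()
    if text.startswith("hwe(") and text.endswith(")"):
        return pedigree.hwe_prior(parse_probability(text[4:-1], path))
    if text.startswith("fixed(") and text.endswith(")"):
        return pedigree.fixed_prior(text[6:-1].strip())
    raise ConfigError(
        f"genotype_prior {value!r} not understood; use uniform, hwe(q) or fixed(STATE)",
        path,
    )


_NETWORK_KEYS = {
    "individuals",
    "gate",
    "cpt_mode",
    "genetic_model",
    "rf_prior",
    "draws",
    "seed",
    "test_nodes",
}


def from_config(cfg: Mapping) -> CounselingNetwork:
    """Build a network from a structured-text (dict) configuration.

    The canonicalized configuration is stored on the returned network,
    so ``to_config(from_config(cfg))`` is a stable round trip.
    """
    _check_keys(cfg, _NETWORK_KEYS, {"individuals", "gate"}, "network")
    cpt_mode = cfg.get("cpt_mode", "point_mean")
    genetic_model = cfg.get("genetic_model", "recessive")
    rf_prior = parse_probability(cfg.get("rf_prior", 0.5), "network.rf_prior")
    draws = int(cfg.get("draws", 1000))
    seed = int(cfg.get("seed", 0))

    gate_cfg = cfg["gate"]
    _check_keys(gate_cfg, {"leak", "link_ng", "link_g"}, {"link_ng", "link_g"}, "network.gate")
    leak = _parse_prior_entry(gate_cfg.get("leak", priors.DEFAULT_LEAK_MEAN), "network.gate.leak")
    link_ng = _parse_prior_entry(gate_cfg["link_ng"], "network.gate.link_ng")
    link_g = _parse_prior_entry(gate_cfg["link_g"], "network.gate.link_g")
    group = priors.PriorGroup("config", leak=leak, link_ng=link_ng, link_g=link_g)

    if cpt_mode == "mc_mean":
        pheno = _phenotype_cpt_mc(group, genetic_model, draws, seed)
    else:
        m_leak, m_ng, m_g = group.means()
        pheno = _phenotype_cpt_point(
            _gate_from_spec({"leak": m_leak, "link_ng": m_ng, "link_g": m_g}),
            genetic_model,
        )
    net = CounselingNetwork(
        genetic_model=genetic_model,
        rf_prior=rf_prior,
        phenotype_cpt=pheno,
        gate_prior=group,
    )

    if not isinstance(cfg["individuals"], Sequence) or isinstance(cfg["individuals"], str):
        raise ConfigError("individuals must be a list", "network.individuals")
    canon_individuals = []
    pending = []
    for i, ind_cfg in enumerate(cfg["individuals"]):
        path = f"network.individuals[{i}]"
        _check_keys(ind_cfg, {"id", "sire", "dam", "genotype_prior"}, {"id"}, path)
        ind_id = str(ind_cfg["id"])
        if "sire" in ind_cfg or "dam" in ind_cfg:
            if "genotype_prior" in ind_cfg:
                raise ConfigError("children cannot carry a genotype_prior", path)
            ind = Individual(ind_id, sire=str(ind_cfg["sire"]), dam=str(ind_cfg["dam"]))
            canon_individuals.append({"id": ind_id, "sire": ind.sire, "dam": ind.dam})
        else:
            prior_str = ind_cfg.get("genotype_prior", "uniform")
            ind = Individual(
                ind_id,
                genotype_prior=_parse_genotype_prior(prior_str, f"{path}.genotype_prior"),
            )
            canon_individuals.append({"id": ind_id, "genotype_prior": str(prior_str).strip()})
        pending.append(ind)

    # insert in dependency order; anything left over is a cycle or a
    # reference to a missing parent
    while pending:
        progressed = False
        for ind in list(pending):
            ready = ind.is_founder or (
                ind.sire in net.individuals and ind.dam in net.individuals
            )
            if ready:
                net.add_individual(ind)
                pending.remove(ind)
                progressed = True
        if not progressed:
            stuck = sorted(ind.id for ind in pending)
            raise StructureError(
                f"individuals {stuck} form a pedigree cycle or reference missing parents"
            )

    canon_tests = []
    for i, t_cfg in enumerate(cfg.get("test_nodes", [])):
        path = f"network.test_nodes[{i}]"
        _check_keys(
            t_cfg,
            {"individual", "sensitivity", "specificity", "semantics"},
            {"individual", "sensitivity", "specificity"},
            path,
        )
        se = parse_probability(t_cfg["sensitivity"], f"{path}.sensitivity")
        sp = parse_probability(t_cfg["specificity"], f"{path}.specificity")
        semantics = t_cfg.get("semantics", "genotype_bb")
        net.add_test(str(t_cfg["individual"]), se, sp, semantics)
        canon_tests.append(
            {
                "individual": str(t_cfg["individual"]),
                "sensitivity": se,
                "specificity": sp,
                "semantics": semantics,
            }
        )

    def canon_prior(p):
        if isinstance(p, priors.BetaSpec):
            return {"alpha": p.alpha, "beta": p.beta}
        return p

    net.config = {
        "individuals": canon_individuals,
        "gate": {
            "leak": canon_prior(leak),
            "link_ng": canon_prior(link_ng),
            "link_g": canon_prior(link_g),
        },
        "cpt_mode": cpt_mode,
        "genetic_model": genetic_model,
        "rf_prior": rf_prior,
        "draws": draws,
        "seed": seed,
        "test_nodes": canon_tests,
    }
    return net


def to_config(net: CounselingNetwork) -> dict:
    """Canonical configuration dict of a config-built network."""
    if net.config is None:
        raise ValidationError("network was not built from a configuration")
    return _copy.deepcopy(net.config)
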