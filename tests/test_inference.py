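"""Exact inference: enumeration oracle, variable elimination, counseling queries."""

import itertools

import numpy as np
import pytest

import counselnet as cn
from counselnet import (
    InconsistentEvidenceError,
    ValidationError,
    counsel_risk,
    enumeration_posterior,
    joint_enumeration,
    posterior,
    posterior_over_draws,
)
from counselnet import network as net_mod
from counselnet import scenarios as sc

from conftest import dam_signs_evidence, healthy_parents_evidence


class TestEnumeration:
    def test_empty_evidence_normalizes(self, det_net):
        assert joint_enumeration(det_net, {}).total() == pytest.approx(1.0, abs=1e-10)

    def test_offspring_bb_mass_is_quarter(self, det_net):
        """Sum of Mendelian BB probabilities over 9 equiprobable parent pairs."""
        joint = joint_enumeration(det_net, {"G_offspring": "BB"})
        assert joint.total() == pytest.approx(0.25, abs=1e-12)

    def test_mendelian_impossibility_raises(self, det_net):
        with pytest.raises(InconsistentEvidenceError):
            joint_enumeration(det_net, {"G_sire": "AA", "G_offspring": "BB"})

    def test_brute_force_assignment_sum_matches(self, det_net):
        """Pure-Python per-assignment enumeration agrees with the factor joint."""
        nodes = list(det_net.nodes.values())
        evidence = {"G_offspring": "BB", "P_dam": "signs"}
        total = 0.0
        free = [n for n in nodes if n.name not in evidence]
        for combo in itertools.product(*(range(len(n.states)) for n in free)):
            assign = dict(zip((n.name for n in free), combo))
            assign.update(
                {k: det_net.nodes[k].states.index(v) for k, v in evidence.items()}
            )
            p = 1.0
            for n in nodes:
                idx = tuple(assign[par] for par in n.parents) + (assign[n.name],)
                p *= n.cpt[idx]
            total += p
        assert joint_enumeration(det_net, evidence).total() == pytest.approx(
            total, rel=1e-10
        )


class TestNamedQueries:
    def test_backward_parent_given_offspring_bb(self, group5_net):
        rep = posterior(group5_net, "G_sire", {"G_offspring": "BB"})
        assert rep.probabilities == pytest.approx((0.0, 1 / 3, 2 / 3), abs=1e-12)

    def test_healthy_parents_deterministic_limit(self, det_net):
        rep = posterior(det_net, "G_offspring", healthy_parents_evidence())
        assert rep.probabilities == pytest.approx((0.5625, 0.375, 0.0625), abs=1e-12)

    def test_dam_signs_unknown_father(self, det_net):
        rep = posterior(det_net, "G_offspring", dam_signs_evidence())
        assert rep.probabilities == pytest.approx((0.0, 0.5, 0.5), abs=1e-12)

    @pytest.mark.parametrize("q", [0.5, 0.1])
    def test_offspring_bb_equals_allele_frequency(self, q):
        """With the dam certainly affected, offspring BB risk equals the
        father's population allele frequency under Hardy-Weinberg."""
        net = cn.build_trio(
            gate=cn.deterministic_limit_gate(0.1), sire_prior=cn.hwe_prior(q)
        )
        rep = posterior(net, "G_offspring", dam_signs_evidence())
        assert rep["BB"] == pytest.approx(q, abs=1e-12)
        net2 = cn.build_trio(
            gate=cn.deterministic_limit_gate(0.1), sire_prior=cn.hwe_prior(q)
        )
        rep2 = posterior(net2, "G_offspring", {"G_dam": "BB"})
        assert rep2["BB"] == pytest.approx(q, abs=1e-12)

    def test_query_errors(self, det_net):
        with pytest.raises(ValidationError):
            posterior(det_net, "G_sire", {"G_sire": "AA"})
        with pytest.raises(ValidationError):
            posterior(det_net, "G_nobody", {})
        with pytest.raises(InconsistentEvidenceError):
            posterior(det_net, "G_dam", {"G_sire": "AA", "G_offspring": "BB"})


class TestOracleEquivalence:
    def test_random_generic_networks(self):
        for seed in range(300):
            net, evidence, query = sc.random_network(seed)
            ve = posterior(net, query, evidence)
            oracle = enumeration_posterior(net, query, evidence)
            assert ve.probabilities == pytest.approx(
                oracle.probabilities, abs=1e-10
            ), f"seed {seed}"

    def test_random_pedigree_scenarios(self):
        for seed in range(60):
            s = sc.random_scenario(seed, 3 + seed % 2)
            net = s.build()
            ve = posterior(net, s.query, s.evidence)
            oracle = enumeration_posterior(net, s.query, s.evidence)
            assert ve.probabilities == pytest.approx(
                oracle.probabilities, abs=1e-10
            ), f"seed {seed}"


class TestCounselRisk:
    def test_tested_bb_no_ng_factors(self, group5_net):
        ev = {net_mod.genotype_node("offspring"): "BB"}
        risk = counsel_risk(
            group5_net, "offspring", ev, ng_states={"diet": "F", "exercise": "F", "age": "F"}
        )
        assert risk == pytest.approx(0.901, abs=1e-12)

    def test_tested_aa_reduces_to_leak(self, group5_net):
        ev = {net_mod.genotype_node("offspring"): "AA"}
        risk = counsel_risk(
            group5_net, "offspring", ev, ng_states={"diet": "F", "exercise": "F", "age": "F"}
        )
        assert risk == pytest.approx(0.01, abs=1e-12)

    @pytest.mark.parametrize("k", range(1, 8))
    def test_monotone_in_active_factors_every_group(self, k):
        net = cn.build_trio(cn.table1_groups()[k])
        causes = ("diet", "exercise", "age")
        ev = {net_mod.genotype_node("offspring"): "BB"}
        risks = []
        for n_active in range(4):
            ng = {c: ("T" if i < n_active else "F") for i, c in enumerate(causes)}
            risks.append(counsel_risk(net, "offspring", ev, ng_states=ng))
        assert risks == sorted(risks)
        assert risks[0] < risks[-1]

    def test_unknown_individual_or_factor(self, group5_net):
        with pytest.raises(ValidationError):
            counsel_risk(group5_net, "nobody")
        with pytest.raises(ValidationError):
            counsel_risk(group5_net, "offspring", ng_states={"weather": "T"})


class TestPosteriorOverDraws:
    def test_degenerate_priors_equal_point_posterior(self, group5_net):
        group = cn.PriorGroup("point", leak=0.01, link_ng=0.1, link_g=0.9)
        ev = dam_signs_evidence()
        avg = posterior_over_draws(group, ev, "G_offspring", n_draws=5, seed=1)
        point = posterior(group5_net, "G_offspring", ev)
        assert avg.probabilities == pytest.approx(point.probabilities, abs=1e-12)
        assert avg.meta["sd"] == pytest.approx((0, 0, 0), abs=1e-12)

    def test_active_ng_factors_lower_offspring_bb(self, group5):
        """With the dam affected, active non-genetic factors explain away
        the genetic cause, lowering the offspring carrier risk."""
        ev_false = dam_signs_evidence()
        ev_true = {"P_dam": "signs"}
        ev_true.update({rf: "T" for rf in net_mod.risk_factor_nodes("dam")})
        lo = posterior_over_draws(group5, ev_true, "G_offspring", 400, seed=2)
        hi = posterior_over_draws(group5, ev_false, "G_offspring", 400, seed=2)
        assert lo["BB"] < hi["BB"]

    def test_seed_determinism(self, group5):
        ev = dam_signs_evidence()
        a = posterior_over_draws(group5, ev, "G_offspring", 50, seed=9)
        b = posterior_over_draws(group5, ev, "G_offspring", 50, seed=9)
        assert a.probabilities == b.probabilities
        assert a.meta["sd"] == b.meta["sd"]


def test_uninformative_leaf_evidence_is_barren(group5_net):
    """Evidence on a test node with sensitivity = 1 - specificity carries no
    information and must leave every other posterior unchanged."""
    before = posterior(group5_net, "G_sire", {"G_offspring": "BB"}).probabilities
    cn.add_test_node(group5_net, "dam", sensitivity=0.3, specificity=0.7)
    after = posterior(
        group5_net, "G_sire", {"G_offspring": "BB", "T_dam": "positive"}
    ).probabilities
    assert after == pytest.approx(before, abs=1e-12)
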