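"""Network assembly: structure, CPT construction, relatives, test nodes, config."""

import numpy as np
import pytest

import counselnet as cn
from counselnet import (
    ConfigError,
    Individual,
    StructureError,
    add_relative,
    add_test_node,
    build_trio,
    from_config,
    to_config,
)
from counselnet import network as net_mod
from counselnet.inference import joint_enumeration, posterior
from counselnet.pedigree import GENOTYPES

from conftest import healthy_parents_evidence


def trio_config(**overrides):
    cfg = {
        "individuals": [
            {"id": "sire", "genotype_prior": "uniform"},
            {"id": "dam", "genotype_prior": "uniform"},
            {"id": "offspring", "sire": "sire", "dam": "dam"},
        ],
        "gate": {"leak": "1%", "link_ng": "10%", "link_g": "90%"},
    }
    cfg.update(overrides)
    return cfg


class TestStructure:
    def test_trio_node_audit(self, group5_net):
        net = group5_net
        assert len(net.individuals) == 3
        assert len(net.nodes) == 15  # 5 nodes per individual
        for ind in ("sire", "dam", "offspring"):
            assert net_mod.genotype_node(ind) in net.nodes
            assert net_mod.phenotype_node(ind) in net.nodes
            for rf in net_mod.risk_factor_nodes(ind):
                assert rf in net.nodes
        net.validate()

    def test_all_cpt_rows_normalized(self, group5_net):
        for node in group5_net.nodes.values():
            assert np.allclose(node.cpt.sum(axis=-1), 1.0, atol=1e-12)

    def test_offspring_genotype_is_mendelian(self, group5_net):
        node = group5_net.nodes["G_offspring"]
        assert node.parents == ("G_sire", "G_dam")
        ab_ab = node.cpt[GENOTYPES.index("AB"), GENOTYPES.index("AB")]
        assert ab_ab == pytest.approx((0.25, 0.5, 0.25))

    def test_requires_exactly_one_parameter_source(self, group5):
        with pytest.raises(cn.ValidationError):
            build_trio()
        with pytest.raises(cn.ValidationError):
            build_trio(group5, gate=cn.deterministic_limit_gate())


class TestPhenotypeCpt:
    def test_point_mean_group5_bb_row(self, group5_net):
        """P(signs | BB, no active NG factor) = 1 - 0.99 * 0.1."""
        cpt = group5_net.nodes["P_offspring"].cpt
        bb_row = cpt[GENOTYPES.index("BB"), 1, 1, 1]  # F = index 1
        assert bb_row[0] == pytest.approx(0.901, abs=1e-12)

    def test_recessive_model_treats_aa_and_ab_alike(self, group5_net):
        cpt = group5_net.nodes["P_sire"].cpt
        assert np.array_equal(cpt[GENOTYPES.index("AA")], cpt[GENOTYPES.index("AB")])

    def test_dominant_model_activates_heterozygote(self, group5):
        net = build_trio(group5, genetic_model="dominant")
        cpt = net.nodes["P_sire"].cpt
        assert np.array_equal(cpt[GENOTYPES.index("AB")], cpt[GENOTYPES.index("BB")])
        assert not np.array_equal(cpt[GENOTYPES.index("AA")], cpt[GENOTYPES.index("AB")])

    def test_mc_mean_with_degenerate_priors_equals_point_mean(self):
        group = cn.PriorGroup("point", leak=0.01, link_ng=0.1, link_g=0.9)
        a = build_trio(group, cpt_mode="point_mean")
        b = build_trio(group, cpt_mode="mc_mean", draws=10, seed=0)
        assert np.allclose(
            a.nodes["P_offspring"].cpt, b.nodes["P_offspring"].cpt, atol=1e-12
        )

    def test_mc_mean_is_seed_deterministic(self, group5):
        a = build_trio(group5, cpt_mode="mc_mean", draws=200, seed=5)
        b = build_trio(group5, cpt_mode="mc_mean", draws=200, seed=5)
        assert np.array_equal(a.nodes["P_dam"].cpt, b.nodes["P_dam"].cpt)

    def test_with_gate_rebuilds_all_phenotypes(self, group5_net):
        new = net_mod.with_gate(group5_net, cn.deterministic_limit_gate())
        for ind in new.individuals:
            cpt = new.nodes[net_mod.phenotype_node(ind)].cpt
            assert cpt[GENOTYPES.index("BB"), 1, 1, 1, 0] == 1.0
        # original untouched
        old = group5_net.nodes["P_sire"].cpt
        assert old[GENOTYPES.index("BB"), 1, 1, 1, 0] == pytest.approx(0.901)


class TestRelatives:
    def test_second_offspring_is_barren_for_trio_queries(self, det_net):
        evidence = healthy_parents_evidence()
        before = posterior(det_net, "G_offspring", evidence).probabilities
        add_relative(det_net, Individual("offspring2", sire="sire", dam="dam"))
        assert len(det_net.individuals) == 4
        det_net.validate()
        after = posterior(det_net, "G_offspring", evidence).probabilities
        assert after == pytest.approx(before, abs=1e-12)

    def test_self_parent_rejected(self, det_net):
        with pytest.raises(StructureError):
            add_relative(det_net, Individual("x", sire="x", dam="dam"))

    def test_unknown_parent_and_duplicate_rejected(self, det_net):
        with pytest.raises(StructureError, match="unknown parent"):
            add_relative(det_net, Individual("pup", sire="ghost", dam="dam"))
        with pytest.raises(StructureError, match="duplicate"):
            add_relative(
                det_net,
                Individual("sire", genotype_prior=cn.uniform_prior()),
            )

    def test_three_generation_chain_normalizes(self, det_net):
        add_relative(det_net, Individual("mate", genotype_prior=cn.uniform_prior()))
        add_relative(det_net, Individual("grandpup", sire="offspring", dam="mate"))
        det_net.validate()
        rep = posterior(det_net, "G_grandpup", {})
        assert sum(rep.probabilities) == pytest.approx(1.0, abs=1e-10)
        # grandchild of uniform founders keeps the Mendelian marginal shape
        assert rep.probabilities == pytest.approx((0.25, 0.5, 0.25), abs=1e-10)


class TestTestNodes:
    def test_perfect_test_pins_genotype(self, group5_net):
        add_test_node(group5_net, "offspring", sensitivity=1.0, specificity=1.0)
        rep = posterior(group5_net, "G_offspring", {"T_offspring": "positive"})
        assert rep["BB"] == pytest.approx(1.0, abs=1e-12)

    def test_uninformative_test_leaves_prior(self, group5_net):
        prior = posterior(group5_net, "G_offspring", {}).probabilities
        add_test_node(group5_net, "offspring", sensitivity=0.5, specificity=0.5)
        post = posterior(
            group5_net, "G_offspring", {"T_offspring": "positive"}
        ).probabilities
        assert post == pytest.approx(prior, abs=1e-12)

    def test_perfect_allele_test_excludes_aa_by_aa_parents(self, group5_net):
        add_test_node(group5_net, "offspring", 1.0, 1.0, semantics="allele")
        joint = joint_enumeration(group5_net, {"T_offspring": "positive"})
        for v in [v for v in joint.variables if v not in ("G_sire", "G_dam")]:
            joint = joint.marginalize(v)
        both_aa = joint.reduce("G_sire", "AA").reduce("G_dam", "AA").total()
        assert both_aa == pytest.approx(0.0, abs=1e-15)

    def test_bad_probabilities_rejected(self, group5_net):
        with pytest.raises(cn.ValidationError):
            add_test_node(group5_net, "offspring", 1.5, 1.0)


def test_sire_dam_exchangeable(det_net):
    ev = {"P_dam": "signs"}
    ev.update({rf: "F" for rf in net_mod.risk_factor_nodes("dam")})
    swapped = {"P_sire": "signs"}
    swapped.update({rf: "F" for rf in net_mod.risk_factor_nodes("sire")})
    a = posterior(det_net, "G_offspring", ev).probabilities
    b = posterior(det_net, "G_offspring", swapped).probabilities
    assert a == pytest.approx(b, abs=1e-12)


class TestConfig:
    def test_round_trip_is_stable(self):
        net = from_config(trio_config())
        cfg1 = to_config(net)
        cfg2 = to_config(from_config(cfg1))
        assert cfg1 == cfg2
        assert cfg1["gate"]["leak"] == 0.01  # percent strings canonicalized

    def test_unknown_key_rejected_with_location(self):
        with pytest.raises(ConfigError, match="network.gate"):
            from_config(trio_config(gate={"leak": 0.1, "link_ng": 0.1, "link_g": 0.5, "oops": 1}))
        with pytest.raises(ConfigError, match=r"individuals\[0\]"):
            cfg = trio_config()
            cfg["individuals"][0]["color"] = "brown"
            from_config(cfg)

    def test_child_with_prior_rejected(self):
        cfg = trio_config()
        cfg["individuals"][2]["genotype_prior"] = "uniform"
        with pytest.raises(ConfigError, match="children"):
            from_config(cfg)

    def test_pedigree_cycle_rejected(self):
        cfg = trio_config()
        cfg["individuals"] = [
            {"id": "a", "sire": "b", "dam": "c"},
            {"id": "b", "sire": "a", "dam": "c"},
            {"id": "c", "genotype_prior": "uniform"},
        ]
        with pytest.raises(StructureError, match="cycle|missing"):
            from_config(cfg)

    def test_prior_spellings(self):
        cfg = trio_config(
            gate={
                "leak": {"mean": "1%", "nu": 9},
                "link_ng": {"mean": 0.1, "sd": 0.0948683},
                "link_g": {"alpha": 8.1, "beta": 0.9},
            }
        )
        net = from_config(cfg)
        leak, ng, g = net.gate_prior.means()
        assert leak == pytest.approx(0.01, abs=1e-12)
        assert ng == pytest.approx(0.1, abs=1e-12)
        assert g == pytest.approx(0.9, abs=1e-12)

    def test_hwe_and_fixed_founder_priors(self):
        cfg = trio_config()
        cfg["individuals"][0]["genotype_prior"] = "hwe(0.1)"
        cfg["individuals"][1]["genotype_prior"] = "fixed(BB)"
        net = from_config(cfg)
        assert net.nodes["G_sire"].cpt == pytest.approx((0.81, 0.18, 0.01))
        assert net.nodes["G_dam"].cpt == pytest.approx((0.0, 0.0, 1.0))
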