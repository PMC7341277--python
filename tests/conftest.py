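import pytest

import counselnet as cn
from counselnet import network as net_mod


@pytest.fixture
def det_net():
    """Trio in the deterministic gate limit (leak 0, genetic link 1)."""
    return cn.build_trio(gate=cn.deterministic_limit_gate(0.1))


@pytest.fixture
def group5():
    """Prior group with NG link mean 10% and genetic link mean 90%."""
    return cn.table1_groups()[5]


@pytest.fixture
def group5_net(group5):
    return cn.build_trio(group5, cpt_mode="point_mean")


def healthy_parents_evidence():
    ev = {"P_sire": "healthy", "P_dam": "healthy"}
    for ind in ("sire", "dam"):
        ev.update({rf: "F" for rf in net_mod.risk_factor_nodes(ind)})
    return ev


def dam_signs_evidence():
    ev = {"P_dam": "signs"}
    ev.update({rf: "F" for rf in net_mod.risk_factor_nodes("dam")})
    return ev
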