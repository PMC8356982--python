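import numpy as np
import pytest

from spesnet.synthetic import GroundTruthNetwork, SimConfig, simulate_session
from spesnet.types import EffectiveNetwork, ElectrodeContact, StimBlock


@pytest.fixture
def small_session():
    """A compact single-block session with two known connections."""
    n = 6
    ids = [f"c{i}" for i in range(n)]
    truth = np.zeros((n, n))
    truth[0, 2] = truth[1, 2] = 12.0
    truth[0, 4] = truth[1, 4] = 8.0
    cfg = SimConfig(n_channels=n, n_mtr_channels=0, rng_seed=7)
    gt = GroundTruthNetwork(true_weights=truth, group_profile="focal_mtr", node_ids=ids)
    onsets = 1000 + np.arange(50) * 1000
    block = StimBlock("c0", "c1", onsets, 4.0, 1.0)
    rec, events = simulate_session(cfg, gt, [block])
    return {"rec": rec, "block": block, "truth": gt, "config": cfg, "events": events}


def make_contact(cid, structure="other", hemisphere="left", in_soz=False,
                 stimulated=True, patient="p", index=0, shank="s"):
    return ElectrodeContact(
        contact_id=cid, patient_id=patient, hemisphere=hemisphere,
        structure=structure, in_soz=in_soz, stimulated=stimulated,
        channel_index=index, shank=shank,
    )


@pytest.fixture
def toy_network():
    """Six-node network with hand-assembled weights for density arithmetic.

    Nodes: a, b (left hippocampus/amygdala, stimulated), c (left entorhinal),
    d, e (left lateral 'other'), f (left 'other', SOZ outside the MTR).
    """
    contacts = [
        make_contact("a", "hippocampus", index=0),
        make_contact("b", "amygdala", index=1),
        make_contact("c", "entorhinal", index=2, stimulated=False),
        make_contact("d", index=3),
        make_contact("e", index=4, stimulated=False),
        make_contact("f", index=5, in_soz=True, stimulated=False),
    ]
    ids = [c.contact_id for c in contacts]
    n = len(ids)
    w = np.zeros((n, n))
    poss = np.zeros((n, n), dtype=bool)
    # stimulated pair {a, b}; d also stimulated with partner a in another block
    for s in (0, 1):
        for t in range(n):
            if t not in (0, 1):
                poss[s, t] = True
    for t in range(n):
        if t != 3 and t not in (0,):
            poss[3, t] = True
    poss[3, 0] = False
    w[0, 2] = w[1, 2] = 8.0   # within-MTR response
    w[0, 3] = w[1, 3] = 10.0  # out response
    w[3, 2] = 7.0             # in response
    w[3, 4] = 9.0             # outside response
    stim = np.array([True, True, False, True, False, False])
    return EffectiveNetwork(w, poss, ids, contacts, stim)
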