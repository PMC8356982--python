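"""Node centralities of the weighted directed effective network.

Six measures per node: normalized in/outdegree, HITS authority/hub, and
Katz receive/broadcast. Degrees are normalized by the number of possible
connections the node could have received or projected; HITS and Katz vectors
are normalized to unit Euclidean norm over the patient's node set. Outgoing
measures are meaningful only for stimulated nodes and are masked to them at
reporting time.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import EffectiveNetwork, ElectrodeContact


def degree_centrality(net: EffectiveNetwork) -> pd.DataFrame:
    """Possible-connection-normalized weighted in/outdegree per node.

    Nodes with zero possible incoming (outgoing) connections get NaN —
    "never observable" is distinct from "observed nothing".
    """
    w, poss = net.weights, net.possible_mask
    out_poss = poss.sum(axis=1)
    in_poss = poss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        outdeg = np.where(out_poss > 0, w.sum(axis=1) / out_poss, np.nan)
        indeg = np.where(in_poss > 0, w.sum(axis=0) / in_poss, np.nan)
    return pd.DataFrame(
        {"node_id": net.node_ids, "indegree": indeg, "outdegree": outdeg}
    )


def hits_centrality(
    net: EffectiveNetwork, tol: float = 1e-12, max_iter: int = 5000
) -> pd.DataFrame:
    """Hub/authority scores by power iteration with Euclidean renormalization.

    Authorities receive projections from important hubs and vice versa:
    a ← Wᵀh, h ← Wa, renormalized each step, from a uniform nonnegative
    start. An empty graph yields all-zero scores with a warning.
    """
    w = net.weights
    n = net.n_nodes
    if not np.any(w > 0):
        warnings.warn("empty effective network: HITS scores undefined, returning zeros",
                      stacklevel=2)
        zeros = np.zeros(n)
        return pd.DataFrame({"node_id": net.node_ids, "authority": zeros, "hub": zeros})
    h = np.ones(n) / np.sqrt(n)
    a = np.ones(n) / np.sqrt(n)
    for _ in range(max_iter):
        a_new = w.T @ h
        a_new /= np.linalg.norm(a_new) or 1.0
        h_new = w @ a_new
        h_new /= np.linalg.norm(h_new) or 1.0
        if max(np.abs(a_new - a).max(), np.abs(h_new - h).max()) < tol:
            a, h = a_new, h_new
            break
        a, h = a_new, h_new
    return pd.DataFrame({"node_id": net.node_ids, "authority": a, "hub": h})


def katz_centrality(
    net: EffectiveNetwork, alpha_frac: float = 0.9, beta: float = 1.0
) -> pd.DataFrame:
    """Attenuated-walk centrality, receive (incoming) and broadcast (outgoing).

    The attenuation is set relative to the spectral radius λ of the weight
    matrix, α = alpha_frac/λ, which keeps the Katz series convergent for any
    alpha_frac < 1 and makes the scores invariant to global weight rescaling.
    Solved directly: x = (I − αWᵀ)⁻¹ β·1 for receive (W for broadcast), then
    unit-normalized. A graph with zero spectral radius (no cycles of any
    length — nilpotent W) has a terminating Katz series; the attenuation is
    then scaled by the largest singular value instead.
    """
    if not (0 < alpha_frac < 1):
        raise ValueError("alpha_frac must lie in (0, 1) for a convergent Katz series")
    w = net.weights
    n = net.n_nodes
    lam = float(np.max(np.abs(np.linalg.eigvals(w)))) if n else 0.0
    ones = beta * np.ones(n)
    if lam <= 1e-12:
        scale = float(np.linalg.norm(w, 2))
        if scale <= 1e-12:
            receive = ones.copy()
            broadcast = ones.copy()
            scale = None
        else:
            alpha = alpha_frac / scale
            receive = np.linalg.solve(np.eye(n) - alpha * w.T, ones)
            broadcast = np.linalg.solve(np.eye(n) - alpha * w, ones)
    else:
        alpha = alpha_frac / lam
        receive = np.linalg.solve(np.eye(n) - alpha * w.T, ones)
        broadcast = np.linalg.solve(np.eye(n) - alpha * w, ones)
    receive = receive / (np.linalg.norm(receive) or 1.0)
    broadcast = broadcast / (np.linalg.norm(broadcast) or 1.0)
    return pd.DataFrame(
        {"node_id": net.node_ids, "katz_receive": receive, "katz_broadcast": broadcast}
    )


OUTGOING_MEASURES = ("outdegree", "hub", "katz_broadcast")
INCOMING_MEASURES = ("indegree", "authority", "katz_receive")
ALL_MEASURES = INCOMING_MEASURES + OUTGOING_MEASURES


def centrality_table(
    net: EffectiveNetwork, alpha_frac: float = 0.9, beta: float = 1.0
) -> pd.DataFrame:
    """All six measures per node, with outgoing measures masked to
    stimulated nodes (non-stimulated nodes have no observable outgoing
    edges, so their outgoing centrality is undefined rather than zero)."""
    df = degree_centrality(net)
    df = df.merge(hits_centrality(net), on="node_id")
    df = df.merge(katz_centrality(net, alpha_frac=alpha_frac, beta=beta), on="node_id")
    df["stimulated"] = net.stimulated_mask
    for m in OUTGOING_MEASURES:
        df.loc[~df["stimulated"], m] = np.nan
    return df


def node_location(contact: ElectrodeContact, soz_side: str) -> str | None:
    """Location group for centrality comparisons; None for excluded nodes
    (seizure-onset tissue outside the MTR)."""
    if contact.in_mtr:
        return "ipsi_mtr" if contact.hemisphere == soz_side else "contra_mtr"
    return None if contact.in_soz else "outside_nonepi"


def group_centralities(
    table: pd.DataFrame,
    contacts: list[ElectrodeContact],
    soz_side: str,
    patient_id: str | None = None,
    group: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tag node rows by location and emit pooled and per-patient-mean views.

    Returns (pooled, means): pooled has one row per node with its location
    tag; means averages each measure per location (a location with a single
    node keeps that node's value). Outgoing measures remain restricted to
    stimulated nodes through the NaN masking upstream.
    """
    by_id = {c.contact_id: c for c in contacts}
    locs = []
    for cid in table["node_id"]:
        c = by_id[cid]
        locs.append(node_location(c, soz_side))
    pooled = table.copy()
    pooled["location"] = locs
    pooled = pooled[pooled["location"].notna()].reset_index(drop=True)
    if patient_id is not None:
        pooled["patient_id"] = patient_id
    if group is not None:
        pooled["group"] = group
    means = (
        pooled.groupby("location", sort=False)[list(ALL_MEASURES)]
        .mean()
        .reset_index()
    )
    if patient_id is not None:
        means["patient_id"] = patient_id
    if group is not None:
        means["group"] = group
    return pooled, means
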