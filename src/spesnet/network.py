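"""Effective-network assembly, connection classification relative to the
mesial temporal region, weighted densities, and response distributions.

Each stimulation block contributes one row of significant Z-scores to the
weighted, directed adjacency. Because stimulation is bipolar, the row is
attributed to both member electrodes of the stimulated pair; an electrode
stimulated in several pairs keeps the maximum Z per target.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import EffectiveNetwork, ElectrodeContact

CONNECTION_CLASSES = ("within", "out", "in", "outside")


def build_network(
    evoked_tables: dict[tuple[str, str], pd.DataFrame],
    contacts: list[ElectrodeContact],
    threshold: float = 6.0,
    pair_mapping: str = "duplicate",
) -> EffectiveNetwork:
    """Assemble the weighted directed adjacency from per-block evoked tables.

    ``evoked_tables`` maps each stimulated pair to its evoked table
    (columns channel_id, zscore, significant, usable). ``pair_mapping``:
    "duplicate" attributes the block row to both pair members (default),
    "split" to the anode only.
    """
    if not evoked_tables:
        raise ValueError("need at least one stimulation block")
    if pair_mapping not in ("duplicate", "split"):
        raise ValueError("pair_mapping must be 'duplicate' or 'split'")
    node_ids = [c.contact_id for c in contacts]
    index = {cid: i for i, cid in enumerate(node_ids)}
    n = len(node_ids)
    weights = np.zeros((n, n))
    possible = np.zeros((n, n), dtype=bool)
    stimulated = np.zeros(n, dtype=bool)
    for (anode, cathode), table in evoked_tables.items():
        sources = (anode, cathode) if pair_mapping == "duplicate" else (anode,)
        for s in (anode, cathode):
            if s in index:
                stimulated[index[s]] = True
        src_idx = [index[s] for s in sources if s in index]
        for _, row in table.iterrows():
            cid = row["channel_id"]
            if cid not in index:
                raise ValueError(f"evoked table references unknown channel {cid!r}")
            if cid in (anode, cathode):
                continue  # self-edges undefined
            t = index[cid]
            if not bool(row.get("usable", 1)):
                continue
            z = float(row["zscore"])
            for s in src_idx:
                possible[s, t] = True
                if bool(row["significant"]) and z > threshold:
                    weights[s, t] = max(weights[s, t], z)
    np.fill_diagonal(weights, 0.0)
    np.fill_diagonal(possible, False)
    return EffectiveNetwork(
        weights=weights,
        possible_mask=possible,
        node_ids=node_ids,
        contacts=list(contacts),
        stimulated_mask=stimulated,
        threshold=threshold,
    )


def classify_connection(
    source: ElectrodeContact, target: ElectrodeContact, side: str
) -> str:
    """Classify an ordered pair relative to the chosen side's MTR.

    within: both inside that side's MTR; out: stimulation inside, response
    outside; in: stimulation outside, response inside; outside: both outside.
    Pairs touching seizure-onset tissue outside the MTR are "excluded", so
    the only epileptogenicity variance left is within the MTR.
    """
    for c in (source, target):
        if c.in_soz and not c.in_mtr:
            return "excluded"
    src_in = source.in_mtr and source.hemisphere == side
    tgt_in = target.in_mtr and target.hemisphere == side
    if src_in and tgt_in:
        return "within"
    if src_in:
        return "out"
    if tgt_in:
        return "in"
    return "outside"


def _class_masks(net: EffectiveNetwork, side: str) -> dict[str, np.ndarray]:
    n = net.n_nodes
    labels = np.empty((n, n), dtype=object)
    for i, s in enumerate(net.contacts):
        for j, t in enumerate(net.contacts):
            labels[i, j] = classify_connection(s, t, side)
    return {lab: (labels == lab) & net.possible_mask for lab in CONNECTION_CLASSES}


def weighted_density(net: EffectiveNetwork, class_label: str, side: str) -> float | None:
    """Sum of significant Z-scores over a connection class divided by the
    class's possible-connection count (the subnetwork's average Z when
    insignificant weights count as zero). ``None`` when the class has no
    possible connection."""
    if class_label not in CONNECTION_CLASSES:
        raise ValueError(f"unknown connection class {class_label!r}")
    mask = _class_masks(net, side)[class_label]
    count = int(mask.sum())
    if count == 0:
        return None
    return float(net.weights[mask].sum() / count)


def class_density_table(net: EffectiveNetwork, side: str) -> pd.DataFrame:
    """Per-class weighted density and possible-count for one side's MTR."""
    masks = _class_masks(net, side)
    rows = []
    for lab in CONNECTION_CLASSES:
        count = int(masks[lab].sum())
        rows.append(
            {
                "conn_type": lab,
                "side": side,
                "n_possible": count,
                "n_significant": int((net.weights[masks[lab]] > 0).sum()),
                "weighted_density": (
                    float(net.weights[masks[lab]].sum() / count) if count else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def class_zscores(net: EffectiveNetwork, side: str) -> pd.DataFrame:
    """Z-scores of every significant connection, tagged by class."""
    masks = _class_masks(net, side)
    rows = []
    for lab in CONNECTION_CLASSES:
        zs = net.weights[masks[lab]]
        for z in zs[zs > 0]:
            rows.append({"conn_type": lab, "side": side, "zscore": float(z)})
    return pd.DataFrame(rows, columns=["conn_type", "side", "zscore"])


def response_distribution(net: EffectiveNetwork, stim_side: str) -> dict:
    """Distribution of significant responses from stimulating one MTR.

    Counts significant and possible responses inside vs outside that side's
    MTR, over sources that are stimulated MTR contacts of the side. The
    counts feed Fisher's exact / chi-squared comparisons of ipsilateral vs
    contralateral stimulation.
    """
    src = [
        i
        for i, c in enumerate(net.contacts)
        if c.in_mtr and c.hemisphere == stim_side and net.stimulated_mask[i]
    ]
    if not src:
        raise ValueError(f"no stimulated MTR contacts on side {stim_side!r}")
    inside = np.array(
        [c.in_mtr and c.hemisphere == stim_side for c in net.contacts], dtype=bool
    )
    excluded = np.array([c.in_soz and not c.in_mtr for c in net.contacts], dtype=bool)
    sig_in = sig_out = poss_in = poss_out = 0
    for s in src:
        for t in range(net.n_nodes):
            if not net.possible_mask[s, t] or excluded[t]:
                continue
            if inside[t]:
                poss_in += 1
                sig_in += net.weights[s, t] > 0
            else:
                poss_out += 1
                sig_out += net.weights[s, t] > 0
    return {
        "side": stim_side,
        "significant_inside": int(sig_in),
        "significant_outside": int(sig_out),
        "possible_inside": int(poss_in),
        "possible_outside": int(poss_out),
        "proportion_inside": sig_in / poss_in if poss_in else np.nan,
        "proportion_outside": sig_out / poss_out if poss_out else np.nan,
    }


def adjacency_frame(net: EffectiveNetwork) -> pd.DataFrame:
    """Adjacency as a labelled DataFrame (CSV-ready)."""
    return pd.DataFrame(net.weights, index=net.node_ids, columns=net.node_ids)


def possible_frame(net: EffectiveNetwork) -> pd.DataFrame:
    return pd.DataFrame(
        net.possible_mask.astype(int), index=net.node_ids, columns=net.node_ids
    )
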