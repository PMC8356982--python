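"""Cohort I/O: electrode tables, patient grouping, and cohort summaries.

The reference cohort (18 mesial-temporal-lobe-epilepsy patients) ships as a
per-patient TSV fixture; :func:`load_reference_cohort` expands it into
:class:`~spesnet.types.PatientRecord` objects whose contact-level counts
reproduce the published per-patient electrode tallies.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    GROUPS,
    STRUCTURES,
    ElectrodeContact,
    PatientRecord,
    StimBlock,
)

ELECTRODE_COLUMNS = [
    "contact_id",
    "patient",
    "hemisphere",
    "structure",
    "in_soz",
    "stimulated",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def read_electrode_table(path: str | Path) -> list[ElectrodeContact]:
    """Read a TSV of electrode contacts.

    Required columns: contact_id, patient, hemisphere, structure, in_soz,
    stimulated (booleans as 0/1). Optional: shank, channel_index.
    ``in_mtr`` is derived from the structure label.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contact_id": str, "patient": str})
    for col in ELECTRODE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"electrode table is missing required column {col!r}")
    bad = set(df["structure"]) - STRUCTURES
    if bad:
        raise ValueError(
            f"unknown structure labels {sorted(bad)}; allowed: {sorted(STRUCTURES)}"
        )
    contacts = []
    for i, row in df.iterrows():
        contacts.append(
            ElectrodeContact(
                contact_id=str(row["contact_id"]),
                patient_id=str(row["patient"]),
                hemisphere=str(row["hemisphere"]),
                structure=str(row["structure"]),
                in_soz=bool(int(row["in_soz"])),
                stimulated=bool(int(row["stimulated"])),
                channel_index=int(row.get("channel_index", i) if "channel_index" in df.columns else i),
                shank=str(row["shank"]) if "shank" in df.columns else None,
            )
        )
    seen: dict[tuple[str, str], int] = {}
    for c in contacts:
        key = (c.patient_id, c.contact_id)
        if key in seen:
            raise ValueError(f"duplicate contact_id {c.contact_id!r} in patient {c.patient_id}")
        seen[key] = 1
    return contacts


def write_electrode_table(contacts: list[ElectrodeContact], path: str | Path) -> None:
    """Write contacts back to TSV (round-trips with :func:`read_electrode_table`)."""
    df = pd.DataFrame(
        {
            "contact_id": [c.contact_id for c in contacts],
            "patient": [c.patient_id for c in contacts],
            "hemisphere": [c.hemisphere for c in contacts],
            "structure": [c.structure for c in contacts],
            "in_soz": [int(c.in_soz) for c in contacts],
            "stimulated": [int(c.stimulated) for c in contacts],
            "channel_index": [c.channel_index for c in contacts],
            "shank": [c.shank if c.shank is not None else "" for c in contacts],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_stim_events(path: str | Path) -> pd.DataFrame:
    """Read a stimulation-event TSV (anode_id, cathode_id, onset_sample, current_mA, isi_s)."""
    df = pd.read_csv(path, sep="\t", dtype={"anode_id": str, "cathode_id": str})
    required = ["anode_id", "cathode_id", "onset_sample", "current_mA", "isi_s"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"stim event table is missing required column {col!r}")
    return df


def events_to_blocks(events: pd.DataFrame) -> list[StimBlock]:
    """Group an event table into one StimBlock per stimulated pair."""
    blocks = []
    for (a, c), grp in events.groupby(["anode_id", "cathode_id"], sort=False):
        grp = grp.sort_values("onset_sample")
        blocks.append(
            StimBlock(
                anode_id=str(a),
                cathode_id=str(c),
                onset_samples=grp["onset_sample"].to_numpy(),
                current_mA=float(grp["current_mA"].iloc[0]),
                isi_s=float(grp["isi_s"].iloc[0]),
            )
        )
    return blocks


def blocks_to_events(blocks: list[StimBlock]) -> pd.DataFrame:
    rows = []
    for b in blocks:
        for onset in b.onset_samples:
            rows.append(
                {
                    "anode_id": b.anode_id,
                    "cathode_id": b.cathode_id,
                    "onset_sample": int(onset),
                    "current_mA": b.current_mA,
                    "isi_s": b.isi_s,
                }
            )
    return pd.DataFrame(rows)


def classify_patient_group(
    contacts: list[ElectrodeContact],
    soz_extends_beyond_unilateral_mtr: bool | None = None,
) -> str:
    """Assign a patient group from seizure-onset-zone (SOZ) contact labels.

    focal_mtr: SOZ isolated to one hemisphere's mesial temporal region;
    multifocal_mtr: SOZ involves the MTR but extends beyond it (other
    structures or both hemispheres); non_epileptogenic_mtr: no MTR contact in
    the SOZ. The optional flag overrides the contact-derived extent when the
    clinical SOZ is known to exceed electrode coverage.
    """
    soz = [c for c in contacts if c.in_soz]
    if not soz:
        raise ValueError("no SOZ contacts: patient group undefined")
    soz_mtr = [c for c in soz if c.in_mtr]
    if not soz_mtr:
        return "non_epileptogenic_mtr"
    extends = any(not c.in_mtr for c in soz) or len({c.hemisphere for c in soz_mtr}) > 1
    if soz_extends_beyond_unilateral_mtr is not None:
        extends = extends or soz_extends_beyond_unilateral_mtr
    return "multifocal_mtr" if extends else "focal_mtr"


def _expand_patient(row: pd.Series, sampling_rate: float = 1000.0) -> PatientRecord:
    """Materialize one fixture row as contact-level PatientRecord.

    Only counts are published per patient, so contacts are synthesized:
    per-side MTR contacts cycle through the implanted structures, stimulated
    flags fill from the front, and the remainder are non-MTR ('other')
    contacts. SOZ flags follow the group definition.
    """
    contacts: list[ElectrodeContact] = []
    group = row["group"]
    mtr_stim = {
        "left": int(row["mtr_left_stimulated"]),
        "right": int(row["mtr_right_stimulated"]),
    }
    mtr_impl = {
        "left": int(row["mtr_left_implanted"]),
        "right": int(row["mtr_right_implanted"]),
    }
    # Seizure-onset side: the side with more stimulated MTR contacts (left on ties).
    soz_side = "right" if mtr_stim["right"] > mtr_stim["left"] else "left"
    idx = 0
    for side in ("left", "right"):
        structures = [
            s
            for s in str(row[f"{side}_structures"]).split(",")
            if s and s != "none"
        ]
        n, n_stim = mtr_impl[side], mtr_stim[side]
        for k in range(n):
            structure = structures[k % len(structures)] if structures else "hippocampus"
            in_soz = (
                side == soz_side
                and group in ("focal_mtr", "multifocal_mtr")
            )
            contacts.append(
                ElectrodeContact(
                    contact_id=f"{row['patient_id']}-{side[0].upper()}M{k}",
                    patient_id=row["patient_id"],
                    hemisphere=side,
                    structure=structure,
                    in_soz=in_soz,
                    stimulated=k < n_stim,
                    channel_index=idx,
                    shank=f"{side[0]}mtr",
                )
            )
            idx += 1
    n_other = int(row["n_implanted"]) - mtr_impl["left"] - mtr_impl["right"]
    n_other_stim = int(row["n_stimulated"]) - mtr_stim["left"] - mtr_stim["right"]
    for k in range(n_other):
        # non-MTR SOZ contacts realise the 'extends beyond MTR' part of
        # multifocal patients and the whole SOZ of non-epileptogenic ones
        in_soz = k < 2 and group in ("multifocal_mtr", "non_epileptogenic_mtr")
        contacts.append(
            ElectrodeContact(
                contact_id=f"{row['patient_id']}-O{k}",
                patient_id=row["patient_id"],
                hemisphere=soz_side,
                structure="other",
                in_soz=in_soz,
                stimulated=k < n_other_stim,
                channel_index=idx,
                shank="lat",
            )
        )
        idx += 1
    return PatientRecord(
        patient_id=row["patient_id"],
        group=group,
        soz_side=soz_side,
        bilateral_stim=mtr_stim["left"] > 0 and mtr_stim["right"] > 0,
        sampling_rate=sampling_rate,
        contacts=contacts,
        age=float(row["age"]),
        sex=row["sex"],
    )


def load_reference_cohort() -> tuple[pd.DataFrame, list[PatientRecord]]:
    """Load the packaged 18-patient reference cohort table and expand it."""
    with resources.as_file(
        resources.files("spesnet") / "data" / "table1_cohort.tsv"
    ) as p:
        df = pd.read_csv(p, sep="\t")
    patients = [_expand_patient(row) for _, row in df.iterrows()]
    return df, patients


def _median_range(values: list[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    return {
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def cohort_summary(patients: list[PatientRecord]) -> dict:
    """Cohort aggregates: electrode counts, per-side MTR counts, groups.

    Mesial-temporal medians are counted per implanted hemisphere side (a
    bilateral patient contributes two values), and stimulated-side medians
    only over sides with at least one stimulated MTR contact.
    """
    if not patients:
        raise ValueError("empty cohort")
    implanted = [len(p.contacts) for p in patients]
    stimulated = [sum(c.stimulated for c in p.contacts) for p in patients]
    mtr_impl_sides: list[int] = []
    mtr_stim_sides: list[int] = []
    n_bilateral = 0
    for p in patients:
        stim_sides = 0
        for side in ("left", "right"):
            side_mtr = [c for c in p.contacts if c.in_mtr and c.hemisphere == side]
            if side_mtr:
                mtr_impl_sides.append(len(side_mtr))
            n_stim = sum(c.stimulated for c in side_mtr)
            if n_stim:
                mtr_stim_sides.append(n_stim)
                stim_sides += 1
        if stim_sides == 2:
            n_bilateral += 1
    ages = [p.age for p in patients if p.age is not None]
    group_counts = {g: sum(p.group == g for p in patients) for g in GROUPS}
    out = {
        "n_patients": len(patients),
        "electrodes_implanted": _median_range(implanted),
        "electrodes_stimulated": _median_range(stimulated),
        "mtr_implanted_per_side": _median_range(mtr_impl_sides),
        "mtr_stimulated_per_side": _median_range(mtr_stim_sides),
        "group_counts": group_counts,
        "n_bilateral_stim": n_bilateral,
        "n_unilateral_stim": len(patients) - n_bilateral,
    }
    if ages:
        out["age"] = _median_range(ages)
    return out


def cohort_summary_table(summary: dict) -> pd.DataFrame:
    """Flatten a cohort summary dict to a tidy two-column table."""
    rows = []
    for key, val in summary.items():
        if isinstance(val, dict):
            for sub, v in val.items():
                rows.append({"metric": f"{key}.{sub}", "value": v})
        else:
            rows.append({"metric": key, "value": val})
    return pd.DataFrame(rows)
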