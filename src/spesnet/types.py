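"""Core data model for SPES effective-connectivity analysis.

The objects here mirror the stages of the pipeline: electrode contacts and
patients (cohort metadata), stimulation blocks and voltage recordings (raw
data), epoch sets (preprocessed trials), evoked responses (normalized
averages with N1/N2 peaks), and the weighted directed effective network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

#: Structures that constitute the mesial temporal region (MTR).
MTR_STRUCTURES = frozenset({"amygdala", "hippocampus", "entorhinal", "parahippocampal"})

#: All recognised anatomical structure labels.
STRUCTURES = MTR_STRUCTURES | {"other"}

HEMISPHERES = ("left", "right")

GROUPS = ("focal_mtr", "multifocal_mtr", "non_epileptogenic_mtr")


@dataclass(frozen=True)
class ElectrodeContact:
    """A recording/stimulation site; the node of the effective network.

    ``in_mtr`` is derived: a contact is mesial temporal iff its structure is
    amygdala, hippocampus, entorhinal cortex, or parahippocampal gyrus.
    """

    contact_id: str
    patient_id: str
    hemisphere: str
    structure: str
    in_soz: bool
    stimulated: bool
    channel_index: int = 0
    shank: str | None = None
    boundary: bool = False  # bipolar pair straddles the MTR boundary

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"unknown hemisphere {self.hemisphere!r}; allowed: {HEMISPHERES}"
            )
        if self.structure not in STRUCTURES:
            raise ValueError(
                f"unknown structure {self.structure!r}; allowed: {sorted(STRUCTURES)}"
            )
        if self.channel_index < 0:
            raise ValueError("channel_index must be >= 0")

    @property
    def in_mtr(self) -> bool:
        return self.structure in MTR_STRUCTURES


@dataclass
class PatientRecord:
    """One patient: group label, seizure-onset side, and implanted contacts."""

    patient_id: str
    group: str
    soz_side: str
    bilateral_stim: bool
    sampling_rate: float
    contacts: list[ElectrodeContact]
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; allowed: {GROUPS}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        ids = [c.contact_id for c in self.contacts]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate contact_id within patient {self.patient_id}")


@dataclass
class StimBlock:
    """One bipolar stimulation condition: 50 biphasic pulses at fixed ISI."""

    anode_id: str
    cathode_id: str
    onset_samples: np.ndarray
    current_mA: float
    isi_s: float
    pulse_width_ms: float = 0.3

    def __post_init__(self) -> None:
        if self.anode_id == self.cathode_id:
            raise ValueError("anode and cathode must differ")
        self.onset_samples = np.asarray(self.onset_samples, dtype=np.int64)
        if self.onset_samples.size and np.any(np.diff(self.onset_samples) <= 0):
            raise ValueError("stimulation onsets must be strictly increasing")
        if self.isi_s not in (1, 2, 1.0, 2.0):
            raise ValueError("isi_s must be 1 or 2 seconds")
        if self.current_mA > 10:
            raise ValueError("current_mA exceeds the 10 mA safety limit")

    @property
    def n_trials(self) -> int:
        return int(self.onset_samples.size)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.anode_id, self.cathode_id)

    def validate_spacing(self, sampling_rate: float) -> None:
        min_gap = self.isi_s * sampling_rate
        if self.onset_samples.size > 1 and np.any(
            np.diff(self.onset_samples) < min_gap - 0.5
        ):
            raise ValueError("onset spacing below the interstimulus interval")


@dataclass
class Recording:
    """Multichannel voltage data (µV), channels x time.

    ``montage`` records whether channels are raw contacts ("referential")
    or already correspond to analysis nodes ("bipolar").
    """

    samples: np.ndarray
    sampling_rate: float
    channel_ids: list[str]
    montage: str = "referential"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.samples.shape[0] != len(self.channel_ids):
            raise ValueError(
                f"{self.samples.shape[0]} channel rows but "
                f"{len(self.channel_ids)} channel_ids"
            )
        if np.isnan(self.samples).any():
            raise ValueError("recording contains NaN samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def index_of(self, channel_id: str) -> int:
        return self.channel_ids.index(channel_id)

    def pick(self, channel_ids: Sequence[str]) -> "Recording":
        idx = [self.index_of(c) for c in channel_ids]
        return replace(
            self, samples=self.samples[idx], channel_ids=list(channel_ids)
        )

    def save(self, path: str | Path) -> None:
        """Write float32 little-endian flat binary plus a JSON sidecar."""
        path = Path(path)
        self.samples.astype("<f4").tofile(path)
        sidecar = {
            "sampling_rate": self.sampling_rate,
            "channel_ids": list(self.channel_ids),
            "n_channels": self.n_channels,
            "n_samples": self.n_samples,
            "montage": self.montage,
            "dtype": "<f4",
            "order": "C",
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def load(cls, path: str | Path) -> "Recording":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        data = np.fromfile(path, dtype="<f4").reshape(
            sidecar["n_channels"], sidecar["n_samples"]
        )
        return cls(
            samples=data.astype(np.float64),
            sampling_rate=sidecar["sampling_rate"],
            channel_ids=list(sidecar["channel_ids"]),
            montage=sidecar.get("montage", "referential"),
        )


# Analysis windows by interstimulus interval (ms relative to stimulus).
EPOCH_WINDOWS_MS = {2: (-500.0, 1500.0), 1: (-250.0, 750.0)}
BASELINE_WINDOWS_MS = {2: (-500.0, -10.0), 1: (-250.0, -10.0)}


@dataclass
class EpochSet:
    """Per-block trial cube: channels x trials x time."""

    data: np.ndarray
    time_ms: np.ndarray
    window_ms: tuple[float, float]
    baseline_ms: tuple[float, float]
    channel_ids: list[str]
    stim_block: StimBlock
    n_dropped_trials: int = 0

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    def baseline_indices(self) -> np.ndarray:
        lo, hi = self.baseline_ms
        return np.flatnonzero((self.time_ms >= lo) & (self.time_ms <= hi))


@dataclass(frozen=True)
class Peak:
    latency_ms: float
    amplitude_z: float
    polarity: int  # +1 or -1


@dataclass
class EvokedResponse:
    """Normalized average response of one channel to one stimulation block."""

    channel_id: str
    waveform_z: np.ndarray
    time_ms: np.ndarray
    n1: Peak | None
    n2: Peak | None
    zscore: float
    significant: bool
    usable: bool = True


@dataclass
class EffectiveNetwork:
    """Weighted directed adjacency over electrode nodes.

    ``weights[s, t]`` is the Z-score of the significant evoked response at
    node ``t`` when stimulating node ``s`` (0 where absent or below
    threshold). ``possible_mask[s, t]`` marks pairs where a connection could
    have been observed given the stimulation protocol.
    """

    weights: np.ndarray
    possible_mask: np.ndarray
    node_ids: list[str]
    contacts: list[ElectrodeContact]
    stimulated_mask: np.ndarray
    threshold: float = 6.0

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if self.weights.shape != (n, n) or self.possible_mask.shape != (n, n):
            raise ValueError("adjacency/possible mask shape mismatch with nodes")
        if np.any(self.weights[~self.possible_mask] != 0):
            raise ValueError("weights present outside the possible mask")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("self-edges are undefined")
        nz = self.weights[self.weights > 0]
        if nz.size and nz.min() <= self.threshold:
            raise ValueError("nonzero weights must exceed the significance threshold")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: str) -> int:
        return self.node_ids.index(node_id)


@dataclass
class StatResult:
    """A single hypothesis-test outcome with its FDR family."""

    test: str
    statistic: float
    df: float | tuple
    p_raw: float
    comparison: str
    family_id: str
    p_fdr: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.p_raw <= 1 or np.isnan(self.p_raw)):
            raise ValueError("p_raw outside [0, 1]")
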