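"""Synthetic SPES sessions and cohorts with known ground-truth connectivity.

The generator emulates the study protocol — 50-trial biphasic stimulation
blocks at 1 or 2 s interstimulus interval, a broadband artifact confined to
−5..+10 ms, early (N1, 10–50 ms) and late (N2, 70–300 ms) evoked
deflections, and coloured (1/f² + white) baseline noise — on top of a
ground-truth directed connectivity matrix whose entries are target Z-scores.

Amplitude calibration
---------------------
Ground-truth weights are expressed in units of the averaged response's
baseline standard deviation (the pipeline's Z-score). A per-trial deflection
of amplitude ``w·sd·r/(g·sqrt(n_trials))`` µV is injected, where ``sd`` is
the single-trial noise SD, ``r`` is the expected measured baseline SD after
the pipeline's 50 Hz low-pass and baseline-mean removal as a fraction of
``sd`` (:func:`baseline_sd_retention`), and ``g`` is the peak retention of
the (jitter-smeared, filtered) N1 template. Both correction factors are
computed from the generator's own noise spectrum and template, so the
averaged, normalized response targets Z ≈ w.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .types import (
    ElectrodeContact,
    GROUPS,
    PatientRecord,
    Recording,
    StimBlock,
)


@dataclass(frozen=True)
class SimConfig:
    """Session-generation parameters.

    Latencies are (mean_ms, jitter_sd_ms) pairs; noise is a 1/(f²+f0²)
    coloured process plus a small white floor, scaled to ``noise_sd_uV``.
    """

    n_channels: int = 22
    n_mtr_channels: int = 10
    isi_s: float = 1.0
    n_trials: int = 50
    noise_sd_uV: float = 15.0
    n1_latency_ms: tuple[float, float] = (25.0, 3.0)
    n2_latency_ms: tuple[float, float] = (150.0, 15.0)
    n2_relative_amplitude: float = 0.5
    artifact_amplitude_uV: float = 500.0
    noise_knee_hz: float = 12.0
    noise_white_fraction: float = 0.1  # fraction of total noise power
    lowpass_hz: float = 50.0  # nominal analysis filter the weights target
    current_mA: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mtr_channels > self.n_channels:
            raise ValueError("n_mtr_channels exceeds n_channels")
        for sd in (self.n1_latency_ms[1], self.n2_latency_ms[1], self.noise_sd_uV):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")


@dataclass
class GroundTruthNetwork:
    """Known directed connectivity: N1 amplitudes in baseline-SD units."""

    true_weights: np.ndarray
    group_profile: str
    node_ids: list[str]

    def __post_init__(self) -> None:
        w = np.asarray(self.true_weights, dtype=float)
        if w.shape[0] != w.shape[1] or w.shape[0] != len(self.node_ids):
            raise ValueError("true_weights must be square and match node_ids")
        if np.any(np.diag(w) != 0):
            raise ValueError("ground-truth diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("ground-truth weights must be non-negative")
        self.true_weights = w


def gamma_bump(t_ms: np.ndarray, peak_ms: float, shape: float) -> np.ndarray:
    """Unit-peak gamma-shaped bump: (t/tp)^k exp(k(1−t/tp)) for t > 0."""
    out = np.zeros_like(t_ms, dtype=float)
    pos = t_ms > 0
    x = t_ms[pos] / peak_ms
    out[pos] = x**shape * np.exp(shape * (1.0 - x))
    return out


def _noise_amplitude_spectrum(freqs: np.ndarray, config: SimConfig) -> np.ndarray:
    """Relative amplitude shaping of the baseline noise at FFT frequencies."""
    colored = 1.0 / (freqs**2 + config.noise_knee_hz**2)
    colored[0] = colored[1] if colored.size > 1 else 0.0
    colored /= colored.sum()
    white = np.ones_like(freqs) / freqs.size
    power = (1.0 - config.noise_white_fraction) * colored + config.noise_white_fraction * white
    return np.sqrt(power)


def _lowpass_sos(fs: float, cutoff_hz: float):
    return signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")


def baseline_sd_retention(config: SimConfig, fs: float, n_ref: int = 2**16) -> float:
    """Expected measured baseline SD as a fraction of the raw noise SD.

    The pipeline estimates the normalizing scale as the sample SD over the
    pre-stimulus baseline segment of the (low-pass filtered, baseline-mean-
    centered) average. For coloured noise that estimate is systematically
    below the marginal filtered SD, because segment-mean removal absorbs the
    slow components. This computes the exact expectation for the generator's
    noise spectrum from the filtered autocovariance:
    E[s²] = C(0) − (1/(L(L−1))) Σ_{i≠j} C(τ_ij) over the L baseline samples.
    """
    from scipy.linalg import toeplitz
    from scipy.special import gammaln

    freqs = np.fft.rfftfreq(n_ref, d=1.0 / fs)
    power = _noise_amplitude_spectrum(freqs, config) ** 2
    _, h = signal.sosfreqz(_lowpass_sos(fs, config.lowpass_hz), worN=freqs, fs=fs)
    psd_filt = power * np.abs(h) ** 4  # forward-backward: power response |H|^4
    autocov = np.fft.irfft(psd_filt, n=n_ref)
    raw_var = np.fft.irfft(power, n=n_ref)[0]
    pre_ms = 500.0 if int(config.isi_s) == 2 else 250.0
    n_base = int(round((pre_ms - 10.0) * fs / 1000.0)) + 1
    # sample variance of the mean-removed baseline is the quadratic form
    # x'Ax with A = (I − J/L)/(L−1); for Gaussian x: E = tr(AC),
    # Var = 2 tr((AC)²), matched to a scaled chi² with ν effective dof
    cov = toeplitz(autocov[:n_base])
    a_mat = (np.eye(n_base) - np.ones((n_base, n_base)) / n_base) / (n_base - 1)
    ac = a_mat @ cov
    expected_var = float(np.trace(ac))
    nu = expected_var**2 / float(np.trace(ac @ ac))
    # E[1/s] for s² ~ (E[s²]/ν)·χ²_ν; the generator calibrates against the
    # reciprocal moment so the normalized response is unbiased for Z = w
    log_corr = 0.5 * np.log(nu / 2.0) + gammaln((nu - 1) / 2.0) - gammaln(nu / 2.0)
    inv_mean = np.exp(log_corr) / np.sqrt(expected_var)
    return float(1.0 / (inv_mean * np.sqrt(raw_var)))


def n1_peak_retention(config: SimConfig, fs: float) -> float:
    """Peak retention of the N1 template after jitter smearing and filtering."""
    t = np.arange(0, int(0.4 * fs)) * 1000.0 / fs
    mean, jitter = config.n1_latency_ms
    if jitter > 0:
        qs = np.linspace(0.01, 0.99, 41)
        from scipy.stats import norm

        lats = np.clip(norm.ppf(qs, loc=mean, scale=jitter), 11.0, 49.0)
        smeared = np.mean([gamma_bump(t - (lat - mean), mean, _N1_SHAPE) for lat in lats], axis=0)
    else:
        smeared = gamma_bump(t, mean, _N1_SHAPE)
    pad = np.zeros(int(0.3 * fs))
    padded = np.concatenate([pad, smeared, pad])
    filtered = signal.sosfiltfilt(_lowpass_sos(fs, config.lowpass_hz), padded)
    return float(np.abs(filtered).max())


_N1_SHAPE = 8.0  # gamma shape of the fast N1 deflection (FWHM ~ 21 ms at 25 ms)
_N2_SHAPE = 6.0  # slower N2 deflection


def _colored_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                   fs: float, config: SimConfig) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = _noise_amplitude_spectrum(freqs, config)
    spec = amp * (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    )
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x * config.noise_sd_uV


def _artifact_waveform(fs: float, amplitude_uV: float) -> tuple[np.ndarray, int]:
    """Broadband burst strictly confined to −5..+10 ms around the stimulus."""
    lo, hi = int(round(-5e-3 * fs)), int(round(10e-3 * fs))
    t = np.arange(lo, hi + 1) / fs
    burst = np.cos(2 * np.pi * 250.0 * t) * np.exp(-np.abs(t) / 3e-3)
    burst *= np.hanning(t.size)
    return amplitude_uV * burst, lo


def simulate_session(
    config: SimConfig,
    truth: GroundTruthNetwork,
    blocks: list[StimBlock],
    sampling_rate: float = 1000.0,
) -> tuple[Recording, pd.DataFrame]:
    """Render one SPES session: noise + evoked deflections + artifacts.

    Channels map one-to-one to ground-truth nodes (an analysis-node,
    bipolar-equivalent montage). Deterministic under ``config.rng_seed``.
    """
    fs = sampling_rate
    node_ids = truth.node_ids
    n_ch = len(node_ids)
    if n_ch != config.n_channels:
        raise ValueError("truth dimensions do not match configured channel count")
    node_index = {cid: i for i, cid in enumerate(node_ids)}
    all_onsets = np.sort(np.concatenate([b.onset_samples for b in blocks]))
    if np.any(np.diff(all_onsets) < min(b.isi_s for b in blocks) * fs - 0.5):
        raise ValueError("trial windows overlap across blocks")
    n_samples = int(all_onsets.max() + (max(b.isi_s for b in blocks) + 1.0) * fs)
    if all_onsets.min() < 0.5 * fs:
        raise ValueError("first onset leaves no pre-stimulus padding")

    rng = np.random.default_rng(config.rng_seed)
    data = _colored_noise(rng, n_ch, n_samples, fs, config)

    # deterministic per-weight amplitude calibration (see module docstring)
    r_noise = baseline_sd_retention(config, fs)
    g_n1 = n1_peak_retention(config, fs)
    amp_per_w = config.noise_sd_uV * r_noise / (g_n1 * np.sqrt(config.n_trials))

    t_resp = np.arange(0, int(0.45 * fs)) * 1000.0 / fs  # 0..450 ms template span
    artifact, art_lo = _artifact_waveform(fs, config.artifact_amplitude_uV)
    art_gain = rng.uniform(0.5, 1.5, size=n_ch)

    for block in blocks:
        ia, ic = node_index[block.anode_id], node_index[block.cathode_id]
        w_eff = np.maximum(truth.true_weights[ia], truth.true_weights[ic])
        w_eff[[ia, ic]] = 0.0
        targets = np.flatnonzero(w_eff > 0)
        for onset in block.onset_samples:
            if config.artifact_amplitude_uV > 0:
                a = onset + art_lo
                data[:, a : a + artifact.size] += art_gain[:, None] * artifact
            for tgt in targets:
                lat1 = float(
                    np.clip(
                        rng.normal(config.n1_latency_ms[0], config.n1_latency_ms[1]),
                        11.0,
                        49.0,
                    )
                )
                lat2 = float(
                    np.clip(
                        rng.normal(config.n2_latency_ms[0], config.n2_latency_ms[1]),
                        75.0,
                        295.0,
                    )
                )
                amp = w_eff[tgt] * amp_per_w
                ep = -amp * (
                    gamma_bump(t_resp - (lat1 - config.n1_latency_ms[0]),
                               config.n1_latency_ms[0], _N1_SHAPE)
                    + config.n2_relative_amplitude
                    * gamma_bump(t_resp - (lat2 - config.n2_latency_ms[0]),
                                 config.n2_latency_ms[0], _N2_SHAPE)
                )
                end = min(onset + ep.size, n_samples)
                data[tgt, onset:end] += ep[: end - onset]

    rec = Recording(
        samples=data.astype(np.float32).astype(np.float64),
        sampling_rate=fs,
        channel_ids=list(node_ids),
        montage="bipolar",
    )
    from .cohort_io import blocks_to_events

    return rec, blocks_to_events(blocks)


# --- cohort generation -----------------------------------------------------

#: Connection-class profiles: (connection probability, gamma scale of the
#: weight above the 8-Z floor). Weights are 8 + Gamma(shape=2, scale), so the
#: class mean weight is 8 + 2*scale.
DEFAULT_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "focal_mtr": {"within": (0.65, 4.0), "out": (0.40, 3.0), "in": (0.40, 3.0)},
    "multifocal_mtr": {"within": (0.65, 4.0), "out": (0.22, 1.5), "in": (0.22, 1.5)},
    "non_epileptogenic_mtr": {
        "within": (0.65, 4.0),
        "out": (0.20, 1.25),
        "in": (0.20, 1.25),
    },
}

#: Profiles shared across groups: the contralateral non-epileptogenic MTR and
#: the background outside-outside connectivity.
SHARED_PROFILES: dict[str, tuple[float, float]] = {
    "contra_within": (0.65, 4.0),
    "contra_out": (0.20, 1.25),
    "contra_in": (0.20, 1.25),
    "cross_mtr": (0.20, 1.25),
    "outside": (0.12, 1.0),
}

_WEIGHT_FLOOR = 8.0
_WEIGHT_SHAPE = 2.0


@dataclass
class SyntheticPatient:
    """One synthetic patient: metadata, protocol, and ground truth.

    The voltage recording is rendered on demand (:meth:`render`) to keep
    cohort-scale memory bounded.
    """

    patient: PatientRecord
    contacts: list[ElectrodeContact]
    blocks: list[StimBlock]
    truth: GroundTruthNetwork
    config: SimConfig

    def render(self) -> tuple[Recording, pd.DataFrame]:
        return simulate_session(self.config, self.truth, self.blocks,
                                sampling_rate=self.patient.sampling_rate)


def _make_contacts(patient_id: str, soz_side: str, group: str) -> list[ElectrodeContact]:
    """Default layout: 6 ipsilateral MTR, 4 contralateral MTR, 12 lateral.

    The last two lateral contacts carry the extra-mesial part of the seizure
    onset zone for multifocal and non-epileptogenic patients.
    """
    contra = "right" if soz_side == "left" else "left"
    structures = ["amygdala", "hippocampus", "entorhinal", "parahippocampal"]
    contacts = []
    idx = 0
    for k in range(6):
        contacts.append(
            ElectrodeContact(
                contact_id=f"{patient_id}-iM{k}",
                patient_id=patient_id,
                hemisphere=soz_side,
                structure=structures[k % 4],
                in_soz=group in ("focal_mtr", "multifocal_mtr"),
                stimulated=True,
                channel_index=idx,
                shank="imtr",
            )
        )
        idx += 1
    for k in range(4):
        contacts.append(
            ElectrodeContact(
                contact_id=f"{patient_id}-cM{k}",
                patient_id=patient_id,
                hemisphere=contra,
                structure=structures[k % 4],
                in_soz=False,
                stimulated=True,
                channel_index=idx,
                shank="cmtr",
            )
        )
        idx += 1
    for k in range(12):
        soz_here = k >= 10 and group in ("multifocal_mtr", "non_epileptogenic_mtr")
        contacts.append(
            ElectrodeContact(
                contact_id=f"{patient_id}-O{k}",
                patient_id=patient_id,
                hemisphere=soz_side,
                structure="other",
                in_soz=soz_here,
                stimulated=k < 8,
                channel_index=idx,
                shank="lat",
            )
        )
        idx += 1
    return contacts


def _contact_zone(c: ElectrodeContact, soz_side: str) -> str:
    if c.in_mtr:
        return "ipsi_mtr" if c.hemisphere == soz_side else "contra_mtr"
    return "outside"


def _pair_class(src_zone: str, tgt_zone: str) -> str:
    """Ground-truth profile key for a source-zone → target-zone connection."""
    if src_zone == "ipsi_mtr":
        return {"ipsi_mtr": "within", "contra_mtr": "cross_mtr", "outside": "out"}[tgt_zone]
    if src_zone == "contra_mtr":
        return {
            "ipsi_mtr": "cross_mtr",
            "contra_mtr": "contra_within",
            "outside": "contra_out",
        }[tgt_zone]
    return {"ipsi_mtr": "in", "contra_mtr": "contra_in", "outside": "outside"}[tgt_zone]


def _sample_truth(
    rng: np.random.Generator,
    contacts: list[ElectrodeContact],
    blocks: list[StimBlock],
    group: str,
    soz_side: str,
    profiles: dict[str, dict[str, tuple[float, float]]],
) -> GroundTruthNetwork:
    node_ids = [c.contact_id for c in contacts]
    idx = {cid: i for i, cid in enumerate(node_ids)}
    zones = {c.contact_id: _contact_zone(c, soz_side) for c in contacts}
    w = np.zeros((len(contacts), len(contacts)))
    group_prof = profiles[group]
    for block in blocks:
        src_zone = zones[block.anode_id]
        for c in contacts:
            if c.contact_id in block.pair:
                continue
            key = _pair_class(src_zone, zones[c.contact_id])
            p, scale = group_prof.get(key, SHARED_PROFILES.get(key, SHARED_PROFILES["outside"]))
            if rng.random() < p:
                weight = _WEIGHT_FLOOR + rng.gamma(_WEIGHT_SHAPE, scale)
                # the stimulated pair shares one row of the adjacency, so
                # both members carry the same outgoing ground truth
                for src in block.pair:
                    w[idx[src], idx[c.contact_id]] = weight
    return GroundTruthNetwork(true_weights=w, group_profile=group, node_ids=node_ids)


def _make_blocks(
    contacts: list[ElectrodeContact], config: SimConfig, fs: float
) -> list[StimBlock]:
    """Sequential 50-trial blocks over the stimulated pairs, 1 s gaps."""
    pairs = []
    by_shank: dict[str, list[ElectrodeContact]] = {}
    for c in contacts:
        if c.stimulated:
            by_shank.setdefault(c.shank or "x", []).append(c)
    for members in by_shank.values():
        members = sorted(members, key=lambda c: c.channel_index)
        for k in range(0, len(members) - 1, 2):
            pairs.append((members[k].contact_id, members[k + 1].contact_id))
    blocks = []
    isi = config.isi_s
    start = int(1.0 * fs)
    for anode, cathode in pairs:
        onsets = start + (np.arange(config.n_trials) * isi * fs).astype(np.int64)
        blocks.append(
            StimBlock(
                anode_id=anode,
                cathode_id=cathode,
                onset_samples=onsets,
                current_mA=config.current_mA,
                isi_s=isi,
            )
        )
        start = int(onsets[-1] + (isi + 1.0) * fs)
    return blocks


def simulate_cohort(
    n_per_group: int = 2,
    profiles: dict[str, dict[str, tuple[float, float]]] | None = None,
    rng_seed: int = 0,
    config: SimConfig | None = None,
    sampling_rate: float = 1000.0,
) -> list[SyntheticPatient]:
    """Generate a synthetic cohort with ``n_per_group`` patients per group.

    All patients are bilaterally stimulated; the seizure-onset side
    alternates across patients. The contralateral MTR shares one profile
    across groups, while the epileptogenic-MTR in/out profiles differ by
    group (focal elevated).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    profiles = profiles if profiles is not None else DEFAULT_PROFILES
    base = config if config is not None else SimConfig()
    seeds = np.random.SeedSequence(rng_seed).spawn(3 * n_per_group)
    out = []
    i = 0
    for group in GROUPS:
        for _ in range(n_per_group):
            pid = f"S{i + 1:02d}"
            soz_side = "left" if i % 2 == 0 else "right"
            contacts = _make_contacts(pid, soz_side, group)
            cfg = SimConfig(
                **{
                    **base.__dict__,
                    "n_channels": len(contacts),
                    "n_mtr_channels": sum(c.in_mtr for c in contacts),
                    "rng_seed": int(seeds[i].generate_state(1)[0] % (2**31)),
                }
            )
            rng = np.random.default_rng(seeds[i])
            blocks = _make_blocks(contacts, cfg, sampling_rate)
            truth = _sample_truth(rng, contacts, blocks, group, soz_side, profiles)
            patient = PatientRecord(
                patient_id=pid,
                group=group,
                soz_side=soz_side,
                bilateral_stim=True,
                sampling_rate=sampling_rate,
                contacts=contacts,
            )
            out.append(
                SyntheticPatient(
                    patient=patient,
                    contacts=contacts,
                    blocks=blocks,
                    truth=truth,
                    config=cfg,
                )
            )
            i += 1
    return out
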