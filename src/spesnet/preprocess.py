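"""SPES preprocessing: channel rejection, bipolar montage, artifact
replacement, 50 Hz low-pass filtering, and epoching.

The pipeline order is fixed — reject noisy channels, re-reference to a
bipolar montage, replace the stimulation artifact (−5 to +10 ms around each
pulse), low-pass filter at 50 Hz, then cut trials into analysis windows —
because artifact replacement must precede filtering to avoid smearing the
broadband artifact into the evoked window.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy import signal

from .types import (
    BASELINE_WINDOWS_MS,
    EPOCH_WINDOWS_MS,
    ElectrodeContact,
    EpochSet,
    Recording,
    StimBlock,
)


def robust_sd(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Median-absolute-deviation estimate of the standard deviation."""
    med = np.median(x, axis=axis, keepdims=True)
    return 1.4826 * np.median(np.abs(x - med), axis=axis)


def reject_noisy_channels(
    rec: Recording, sd_multiplier: float = 5.0
) -> tuple[list[str], list[dict]]:
    """Flag flat channels and channels whose robust SD exceeds
    ``sd_multiplier`` times the median robust SD across channels.

    Returns the kept channel ids and a per-rejection report.
    """
    if rec.n_channels < 2:
        raise ValueError("need at least two channels for rejection statistics")
    sds = robust_sd(rec.samples, axis=1)
    median_sd = np.median(sds[sds > 0]) if np.any(sds > 0) else 0.0
    kept, report = [], []
    for cid, sd in zip(rec.channel_ids, sds):
        if sd == 0:
            report.append({"channel_id": cid, "reason": "flat", "robust_sd": 0.0})
        elif median_sd > 0 and sd > sd_multiplier * median_sd:
            report.append(
                {"channel_id": cid, "reason": "excessive_noise", "robust_sd": float(sd)}
            )
        else:
            kept.append(cid)
    if not kept:
        raise ValueError("all channels rejected")
    return kept, report


def bipolar_rereference(
    rec: Recording, contacts: list[ElectrodeContact]
) -> tuple[Recording, list[ElectrodeContact]]:
    """Derive a bipolar montage: adjacent contact pairs on the same shank.

    Derived channel i is contact[i] − contact[i+1] within a shank (contacts
    ordered by ``channel_index``). The derived channel inherits the label and
    anatomical attributes of its first (deeper) contact; if the pair
    straddles the MTR boundary it is flagged ``boundary=True``. Shanks with a
    single surviving contact are dropped with a warning.
    """
    by_id = {c.contact_id: c for c in contacts}
    missing = [cid for cid in rec.channel_ids if cid not in by_id]
    if missing:
        raise ValueError(f"recording channels without contact metadata: {missing}")
    shanks: dict[str, list[ElectrodeContact]] = {}
    for cid in rec.channel_ids:
        c = by_id[cid]
        if c.shank is None:
            raise ValueError(f"contact {cid} lacks shank grouping")
        shanks.setdefault(c.shank, []).append(c)
    out_rows, out_contacts = [], []
    for shank, members in shanks.items():
        members = sorted(members, key=lambda c: c.channel_index)
        if len(members) < 2:
            warnings.warn(
                f"shank {shank!r} has a single surviving contact; dropped",
                stacklevel=2,
            )
            continue
        for first, second in zip(members[:-1], members[1:]):
            i = rec.index_of(first.contact_id)
            j = rec.index_of(second.contact_id)
            out_rows.append(rec.samples[i] - rec.samples[j])
            out_contacts.append(
                replace(
                    first,
                    contact_id=f"{first.contact_id}-{second.contact_id}",
                    stimulated=first.stimulated or second.stimulated,
                    boundary=first.in_mtr != second.in_mtr,
                )
            )
    if not out_rows:
        raise ValueError("no bipolar pairs could be formed")
    derived = Recording(
        samples=np.asarray(out_rows),
        sampling_rate=rec.sampling_rate,
        channel_ids=[c.contact_id for c in out_contacts],
        montage="bipolar",
    )
    return derived, out_contacts


def remove_stim_artifact(
    rec: Recording,
    onsets: np.ndarray,
    window_ms: tuple[float, float] = (-5.0, 10.0),
    taper_ms: float | None = None,
) -> Recording:
    """Replace the stimulation artifact with reversed, tapered flank copies.

    Samples in ``[onset + window_ms[0], onset + window_ms[1]]`` are replaced
    by the combination of the time-reversed pre-window flank and the
    time-reversed post-window flank, each weighted by complementary linear
    ramps so the splice is continuous at both boundaries and the local
    time-frequency content is preserved. Samples outside the window are
    untouched. ``taper_ms`` limits the cross-fade region to the final
    ``taper_ms`` of the window (default: cross-fade across the full window).
    Onsets too close to a recording edge are skipped with a warning.
    """
    fs = rec.sampling_rate
    lo = int(round(window_ms[0] * fs / 1000.0))
    hi = int(round(window_ms[1] * fs / 1000.0))
    L = hi - lo + 1  # inclusive window
    out = rec.samples.copy()
    n = rec.n_samples
    # complementary ramps: pre-flank weight 1 at left edge, 0 at right edge
    if taper_ms is None or taper_ms * fs / 1000.0 >= L - 1:
        w_pre = np.linspace(1.0, 0.0, L)
    else:
        t = max(int(round(taper_ms * fs / 1000.0)), 1)
        w_pre = np.ones(L)
        w_pre[L - t - 1 :] = np.linspace(1.0, 0.0, t + 1)
    w_post = 1.0 - w_pre
    for onset in np.asarray(onsets, dtype=np.int64):
        a = onset + lo
        b = a + L  # exclusive
        if a - L < 0 or b + L > n:
            warnings.warn(
                f"onset {onset} too close to recording edge; artifact left in place",
                stacklevel=2,
            )
            continue
        rev_pre = out[:, a - L : a][:, ::-1]
        rev_post = out[:, b : b + L][:, ::-1]
        out[:, a:b] = rev_pre * w_pre + rev_post * w_post
    return replace(rec, samples=out)


def lowpass_filter(rec: Recording, cutoff_hz: float = 50.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth low-pass (forward-backward, so the effective
    order is doubled and group delay cancels)."""
    nyq = rec.sampling_rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz at or above Nyquist ({nyq} Hz)")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=filtered)


def epoch(rec: Recording, block: StimBlock) -> EpochSet:
    """Cut trials into the ISI-dependent analysis window.

    2 s ISI: −500..+1500 ms window, −500..−10 ms baseline; 1 s ISI:
    −250..+750 ms window, −250..−10 ms baseline. Trials whose window exceeds
    the recording edges are dropped and counted.
    """
    isi = int(block.isi_s)
    window_ms = EPOCH_WINDOWS_MS[isi]
    baseline_ms = BASELINE_WINDOWS_MS[isi]
    fs = rec.sampling_rate
    lo = int(round(window_ms[0] * fs / 1000.0))
    hi = int(round(window_ms[1] * fs / 1000.0))
    block.validate_spacing(fs)
    trials, dropped = [], 0
    for onset in block.onset_samples:
        a, b = onset + lo, onset + hi + 1
        if a < 0 or b > rec.n_samples:
            dropped += 1
            continue
        trials.append(rec.samples[:, a:b])
    if not trials:
        raise ValueError("no usable trials: all windows exceed the recording edges")
    data = np.stack(trials, axis=1)  # channels x trials x time
    time_ms = np.arange(lo, hi + 1) * 1000.0 / fs
    return EpochSet(
        data=data,
        time_ms=time_ms,
        window_ms=window_ms,
        baseline_ms=baseline_ms,
        channel_ids=list(rec.channel_ids),
        stim_block=block,
        n_dropped_trials=dropped,
    )


def preprocess_session(
    rec: Recording,
    contacts: list[ElectrodeContact],
    blocks: list[StimBlock],
    sd_multiplier: float = 5.0,
    artifact_window_ms: tuple[float, float] = (-5.0, 10.0),
    taper_ms: float | None = None,
    lowpass_hz: float = 50.0,
) -> tuple[dict[tuple[str, str], EpochSet], list[ElectrodeContact], list[dict]]:
    """Run the full preprocessing chain and epoch every stimulation block.

    Recordings already in an analysis-node (bipolar) montage skip the
    re-referencing step. Returns epoch sets keyed by stimulated pair, the
    surviving analysis contacts, and the channel-rejection report.
    """
    kept, report = reject_noisy_channels(rec, sd_multiplier=sd_multiplier)
    rec = rec.pick(kept)
    by_id = {c.contact_id: c for c in contacts}
    if rec.montage == "referential":
        rec, analysis_contacts = bipolar_rereference(
            rec, [by_id[cid] for cid in rec.channel_ids]
        )
    else:
        analysis_contacts = [by_id[cid] for cid in rec.channel_ids]
    all_onsets = np.sort(np.concatenate([b.onset_samples for b in blocks]))
    rec = remove_stim_artifact(rec, all_onsets, window_ms=artifact_window_ms, taper_ms=taper_ms)
    rec = lowpass_filter(rec, cutoff_hz=lowpass_hz)
    epochs = {b.pair: epoch(rec, b) for b in blocks}
    return epochs, analysis_contacts, report
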