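"""Evoked-potential quantification: normalized averages, N1/N2 peaks, and
significance calls.

Each channel's trials are baseline-mean-centered, averaged, and divided by
the standard deviation of the averaged waveform's pre-stimulus baseline, so
the resulting waveform is in baseline-SD units. The channel Z-score is the
absolute N1 peak amplitude (10–50 ms); responses with Z > 6 are significant
effective connections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import EpochSet, EvokedResponse, Peak

N1_WINDOW_MS = (10.0, 50.0)
N2_WINDOW_MS = (70.0, 300.0)
DEFAULT_THRESHOLD = 6.0


def normalize_average(
    epochs: EpochSet, baseline_sd_mode: str = "average"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Baseline-center each trial, average, and normalize per channel.

    ``baseline_sd_mode`` selects the normalizing scale: "average" (default)
    uses the SD of the averaged waveform's baseline segment, so the output
    is in units of the average's own noise; "pooled" uses the SD pooled over
    all single-trial baseline samples.

    Returns (waveforms_z, baseline_sds, usable) with one row per channel;
    channels with zero baseline SD are marked unusable.
    """
    if baseline_sd_mode not in ("average", "pooled"):
        raise ValueError("baseline_sd_mode must be 'average' or 'pooled'")
    bidx = epochs.baseline_indices()
    if bidx.size == 0:
        raise ValueError("empty baseline window")
    data = epochs.data  # channels x trials x time
    centered = data - data[:, :, bidx].mean(axis=2, keepdims=True)
    avg = centered.mean(axis=1)  # channels x time
    if baseline_sd_mode == "average":
        sds = avg[:, bidx].std(axis=1, ddof=1)
    else:
        sds = centered[:, :, bidx].std(axis=(1, 2), ddof=1)
    usable = sds > 0
    safe = np.where(usable, sds, 1.0)
    return avg / safe[:, None], sds, usable


def detect_peaks(
    waveform_z: np.ndarray,
    time_ms: np.ndarray,
    n1_window_ms: tuple[float, float] = N1_WINDOW_MS,
    n2_window_ms: tuple[float, float] = N2_WINDOW_MS,
) -> tuple[Peak, Peak | None]:
    """Locate the N1 and N2 extrema of a normalized waveform.

    Each peak is the sample of largest absolute amplitude within its window
    (endpoints inclusive, either polarity; ties resolve to the earlier
    latency). Bipolar derivation makes the deflection sign montage-dependent,
    so polarity is recorded rather than assumed negative.
    """

    def _extremum(window: tuple[float, float]) -> Peak | None:
        mask = (time_ms >= window[0]) & (time_ms <= window[1])
        if not mask.any():
            return None
        idx = np.flatnonzero(mask)
        k = idx[np.argmax(np.abs(waveform_z[idx]))]  # argmax: first on ties
        amp = waveform_z[k]
        return Peak(
            latency_ms=float(time_ms[k]),
            amplitude_z=float(abs(amp)),
            polarity=-1 if amp < 0 else 1,
        )

    n1 = _extremum(n1_window_ms)
    if n1 is None:
        raise ValueError("waveform does not cover the N1 window")
    return n1, _extremum(n2_window_ms)


def call_significance(zscore: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Strict threshold: a response is significant iff Z > threshold."""
    return bool(zscore > threshold)


def evoked_responses(
    epochs: EpochSet,
    threshold: float = DEFAULT_THRESHOLD,
    baseline_sd_mode: str = "average",
) -> list[EvokedResponse]:
    """Quantify every response channel of one stimulation block.

    The two channels of the stimulated pair are excluded (self-edges are
    undefined).
    """
    pair = set(epochs.stim_block.pair)
    waveforms, _, usable = normalize_average(epochs, baseline_sd_mode=baseline_sd_mode)
    out = []
    for i, cid in enumerate(epochs.channel_ids):
        if cid in pair:
            continue
        if not usable[i]:
            out.append(
                EvokedResponse(
                    channel_id=cid,
                    waveform_z=waveforms[i],
                    time_ms=epochs.time_ms,
                    n1=None,
                    n2=None,
                    zscore=float("nan"),
                    significant=False,
                    usable=False,
                )
            )
            continue
        n1, n2 = detect_peaks(waveforms[i], epochs.time_ms)
        z = n1.amplitude_z
        out.append(
            EvokedResponse(
                channel_id=cid,
                waveform_z=waveforms[i],
                time_ms=epochs.time_ms,
                n1=n1,
                n2=n2,
                zscore=z,
                significant=call_significance(z, threshold),
            )
        )
    return out


def evoked_table(responses: list[EvokedResponse]) -> pd.DataFrame:
    """Tidy per-channel table for one stimulation block."""
    rows = []
    for r in responses:
        rows.append(
            {
                "channel_id": r.channel_id,
                "n1_latency_ms": r.n1.latency_ms if r.n1 else np.nan,
                "n1_amp_z": r.n1.amplitude_z if r.n1 else np.nan,
                "n1_polarity": r.n1.polarity if r.n1 else 0,
                "n2_latency_ms": r.n2.latency_ms if r.n2 else np.nan,
                "n2_amp_z": r.n2.amplitude_z if r.n2 else np.nan,
                "zscore": r.zscore,
                "significant": int(r.significant),
                "usable": int(r.usable),
            }
        )
    return pd.DataFrame(rows)
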