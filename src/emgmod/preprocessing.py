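"""Envelope extraction and stride normalization.

Raw EMG is high-pass filtered at 60 Hz, full-wave rectified and low-pass
filtered at 5 Hz (all zero-lag 4th-order Butterworth, applied
forward-backward).  Each stride is then linearly interpolated onto a
200-point time base, the per-cycle minimum is subtracted, and every
muscle is scaled by its maximum over all retained cycles.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .containers import CYCLE_SAMPLES, EmgEnvelopeSet

HIGHPASS_HZ = 60.0
LOWPASS_HZ = 5.0


def filter_rectify(raw: np.ndarray, sampling_rate: float) -> np.ndarray:
    """High-pass 60 Hz -> full-wave rectify -> low-pass 5 Hz, clip at 0.

    ``raw`` is (n_channels, n_samples).  The zero-lag filters are
    forward-backward (filtfilt) applications of the 4th-order design.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if sampling_rate <= 2 * HIGHPASS_HZ:
        raise ValueError(
            f"sampling_rate must exceed {2 * HIGHPASS_HZ} Hz, got {sampling_rate}"
        )
    bh, ah = butter(4, HIGHPASS_HZ / (sampling_rate / 2), "high")
    bl, al = butter(4, LOWPASS_HZ / (sampling_rate / 2), "low")
    x = filtfilt(bh, ah, raw, axis=1)
    x = np.abs(x)
    x = filtfilt(bl, al, x, axis=1)
    return np.clip(x, 0.0, None)


def normalize_strides(
    envelope: np.ndarray,
    stride_events: np.ndarray,
    sampling_rate: float,
    muscle_labels=None,
    source: str = "experimental",
) -> EmgEnvelopeSet:
    """Cut strides at touch-down events, time-normalize and amplitude-normalize.

    Each stride (interval between consecutive ``stride_events``, given in
    seconds) is interpolated to 200 points; the per-muscle minimum over
    each cycle is subtracted; each muscle is divided by its maximum over
    all cycles of the recording.
    """
    envelope = np.atleast_2d(np.asarray(envelope, dtype=float))
    ev = np.asarray(stride_events, dtype=float)
    if ev.size < 2:
        raise ValueError("need at least two stride events (one complete stride)")
    idx = np.round(ev * sampling_rate).astype(int)
    if np.any(np.diff(idx) <= 0):
        raise ValueError("stride of zero (or negative) duration")
    n_strides = ev.size - 1
    M = envelope.shape[0]
    out = np.empty((M, n_strides * CYCLE_SAMPLES))
    for s in range(n_strides):
        seg = envelope[:, idx[s]: idx[s + 1] + 1]
        src = np.linspace(0, 1, seg.shape[1])
        dst = np.linspace(0, 1, CYCLE_SAMPLES, endpoint=False)
        for m in range(M):
            out[m, s * CYCLE_SAMPLES:(s + 1) * CYCLE_SAMPLES] = np.interp(
                dst, src, seg[m]
            )
        blk = out[:, s * CYCLE_SAMPLES:(s + 1) * CYCLE_SAMPLES]
        blk -= blk.min(axis=1, keepdims=True)
    gmax = out.max(axis=1, keepdims=True)
    gmax[gmax == 0] = 1.0
    out /= gmax
    labels = muscle_labels or tuple(f"m{i}" for i in range(M))
    T = float(np.mean(np.diff(ev)))
    return EmgEnvelopeSet(
        out, muscle_labels=labels, stride_duration=T, source=source, normalized=True
    )


def renormalize(emg: EmgEnvelopeSet) -> EmgEnvelopeSet:
    """Apply per-cycle min subtraction and global-max scaling to an existing set."""
    X = emg.data.copy()
    for s in range(emg.n_strides):
        blk = X[:, s * CYCLE_SAMPLES:(s + 1) * CYCLE_SAMPLES]
        blk -= blk.min(axis=1, keepdims=True)
    gmax = X.max(axis=1, keepdims=True)
    gmax[gmax == 0] = 1.0
    X /= gmax
    return emg.copy_with(X, normalized=True)


def select_strides(
    emg: EmgEnvelopeSet,
    n: int = 7,
    consecutive_fraction: float = 0.2,
    seed: int | None = None,
) -> EmgEnvelopeSet:
    """Randomly sample ``n`` strides, constrained to include a consecutive run.

    To mirror the reference sampling conditions (~20% of selected strides
    in one consecutive run), a run of ``round(consecutive_fraction * n)``
    consecutive strides (at least 1) is placed first when the recording
    allows it, and the remaining strides are sampled without replacement
    from the rest.
    """
    S = emg.n_strides
    if S < n:
        raise ValueError(f"insufficient data: {S} strides available, {n} requested")
    rng = np.random.default_rng(seed)
    if S == n:
        chosen = np.arange(S)
    else:
        run = max(1, int(round(consecutive_fraction * n)))
        start = rng.integers(0, S - run + 1)
        base = list(range(start, start + run))
        rest = [i for i in range(S) if i not in base]
        extra = rng.choice(rest, size=n - run, replace=False)
        chosen = np.sort(np.concatenate([base, extra]))
    stk = emg.strides()[chosen]  # (n, M, 200)
    data = np.concatenate(list(stk.transpose(0, 1, 2)), axis=1)
    return emg.copy_with(data)


# ---------------------------------------------------------------------------
# delimited-text I/O: TSV (samples x channels) + JSON sidecar


def write_envelope_tsv(emg: EmgEnvelopeSet, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(emg.data.T, columns=list(emg.muscle_labels)).to_csv(
        path, sep="\t", index=False
    )
    meta = {
        "muscle_labels": list(emg.muscle_labels),
        "stride_duration": emg.stride_duration,
        "n_strides": emg.n_strides,
        "source": emg.source,
        "normalized": emg.normalized,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_envelope_tsv(path: str | Path) -> EmgEnvelopeSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    return EmgEnvelopeSet(
        df.to_numpy().T,
        muscle_labels=tuple(meta["muscle_labels"]),
        stride_duration=meta["stride_duration"],
        source=meta.get("source", "experimental"),
        normalized=meta.get("normalized", False),
    )
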