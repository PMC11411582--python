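"""EEG preprocessing: filtering, ocular-component removal, epoching,
peak-to-peak artifact rejection, Morlet spectral power, and feature z-scoring.

The chain mirrors a standard scalp-EEG pipeline for event-locked spectral
analyses: band-pass 0.5-200 Hz plus 60 Hz notch (and harmonics); ICA
decomposition with removal of components whose correlation with any EOG
channel is an outlier (|z| > 3) of the per-EOG correlation distribution;
epoching -100..1000 ms around stimulus onsets with baseline correction;
rejection of epochs with sliding-window peak-to-peak excursions beyond
±250 µV; Morlet wavelet power (4 cycles) at 30 log-spaced frequencies from
4 to 100 Hz on mirror-padded epochs; base-10 log transform; and z-scoring of
epoch-averaged power across epochs, separately per channel and frequency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import mne
import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA

logger = logging.getLogger(__name__)

DEFAULT_FREQS = np.logspace(np.log10(4.0), np.log10(100.0), 30)


@dataclass
class EpochArray:
    """Trials x channels x samples voltage container with metadata.

    ``times`` runs from tmin to tmax inclusive. ``metadata`` carries one row
    per epoch (aligned with axis 0 of ``data``); ``rejected`` is a boolean
    mask over epochs maintained by :func:`reject_artifacts`.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    ch_names: list[str]
    metadata: pd.DataFrame
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.rejected is None:
            self.rejected = np.zeros(len(self.data), dtype=bool)

    @property
    def n_epochs(self) -> int:
        return len(self.data)

    def retained(self) -> "EpochArray":
        keep = ~self.rejected
        return replace(
            self,
            data=self.data[keep],
            metadata=self.metadata.loc[keep].reset_index(drop=True),
            rejected=np.zeros(int(keep.sum()), dtype=bool),
        )

    def time_window(self, lo: float, hi: float) -> np.ndarray:
        """Sample mask for the window [lo, hi) in seconds."""
        return (self.times >= lo - 1e-9) & (self.times < hi - 1e-9)

    def pick(self, ch: str) -> int:
        try:
            return self.ch_names.index(ch)
        except ValueError:
            raise ValueError(
                f"channel {ch!r} not found; available: {self.ch_names}"
            ) from None

    def save(self, outdir, stem: str = "epochs") -> None:
        """Write voltages as an .npz container with a JSON metadata sidecar
        and the rejection mask as CSV."""
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(out / f"{stem}.npz", data=self.data, times=self.times)
        meta = {"sfreq": self.sfreq, "ch_names": self.ch_names,
                "units": "microvolts", "n_epochs": int(self.n_epochs)}
        (out / f"{stem}.json").write_text(json.dumps(meta, indent=1))
        self.metadata.assign(rejected=self.rejected).to_csv(
            out / f"{stem}_rejection.csv", index=False
        )


@dataclass
class SpectralPower:
    """Log10 Morlet power: trials x channels x frequencies (x samples)."""

    power: np.ndarray            # (n_ep, n_ch, n_freq) or (..., n_times)
    freqs: np.ndarray
    ch_names: list[str]
    metadata: pd.DataFrame
    times: np.ndarray | None = None
    sfreq: float | None = None

    @property
    def time_resolved(self) -> bool:
        return self.power.ndim == 4

    def save(self, outdir, stem: str = "power") -> None:
        """Write power as an .npz container with a JSON metadata sidecar."""
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        arrays = {"power": self.power, "freqs": self.freqs}
        if self.times is not None:
            arrays["times"] = self.times
        np.savez_compressed(out / f"{stem}.npz", **arrays)
        meta = {"ch_names": self.ch_names, "sfreq": self.sfreq,
                "units": "log10(power)", "time_resolved": self.time_resolved}
        (out / f"{stem}.json").write_text(json.dumps(meta, indent=1))


def filter_continuous(
    data: np.ndarray,
    sfreq: float,
    l_freq: float = 0.5,
    h_freq: float = 200.0,
    notch: float | None = 60.0,
    n_harmonics: int | None = None,
) -> np.ndarray:
    """Band-pass and notch filter a (channels x samples) recording.

    The high cutoff is clipped below Nyquist with a warning when the sampling
    rate cannot support it. Notch filtering covers ``notch`` and its
    harmonics up to the effective high cutoff (FIR notch, mne defaults).
    """
    nyq = sfreq / 2.0
    if h_freq is not None and h_freq >= nyq:
        h_eff = 0.9 * nyq
        warnings.warn(
            f"high cutoff {h_freq} Hz >= Nyquist ({nyq} Hz); clipping to {h_eff:.1f} Hz"
        )
        h_freq = h_eff
    out = mne.filter.filter_data(
        data.astype(np.float64), sfreq, l_freq, h_freq, verbose="error"
    )
    if notch:
        top = h_freq if h_freq is not None else nyq
        if n_harmonics is None:
            freqs = np.arange(notch, min(top, nyq * 0.95), notch)
        else:
            freqs = notch * np.arange(1, n_harmonics + 1)
            freqs = freqs[freqs < nyq * 0.95]
        if len(freqs):
            out = mne.filter.notch_filter(out, sfreq, freqs, verbose="error")
    return out


def remove_ocular_components(
    data: np.ndarray,
    ch_names: list[str],
    eog_channels: list[str],
    n_components: int | None = None,
    z_thresh: float = 3.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """ICA-based removal of EOG-coupled components.

    The scalp channels are decomposed with FastICA; each component's Pearson
    correlation with each EOG channel is computed, the correlation
    distribution is z-scored per EOG channel across components, and any
    component with |z| > ``z_thresh`` for any EOG channel is zeroed before
    reconstruction. EOG channels pass through untouched.

    Returns the cleaned array and a diagnostics dict (excluded component
    indices, correlation matrix, z matrix).
    """
    eog_ix = [ch_names.index(ch) for ch in eog_channels]
    if len(eog_ix) < 2:
        raise ValueError("need at least 2 EOG channels")
    scalp_ix = [i for i in range(len(ch_names)) if i not in eog_ix]
    X = data[scalp_ix].T  # samples x channels
    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        random_state=seed,
        max_iter=1000,
        tol=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # FastICA convergence warnings
        S = ica.fit_transform(X)  # samples x components
    eog = data[eog_ix]
    n_comp = S.shape[1]
    r = np.empty((n_comp, len(eog_ix)))
    for j, e in enumerate(eog):
        e0 = e - e.mean()
        es = e0.std()
        for k in range(n_comp):
            s0 = S[:, k] - S[:, k].mean()
            denom = s0.std() * es
            r[k, j] = (s0 @ e0) / (len(e0) * denom) if denom > 0 else 0.0
    mu = r.mean(axis=0, keepdims=True)
    sd = r.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (r - mu) / sd
    bad = np.flatnonzero((np.abs(z) > z_thresh).any(axis=1))
    S_clean = S.copy()
    S_clean[:, bad] = 0.0
    X_clean = ica.inverse_transform(S_clean).T
    out = data.copy()
    out[scalp_ix] = X_clean
    info = {"excluded": bad, "correlations": r, "z": z, "n_components": n_comp}
    logger.info("ocular removal: excluded %d of %d components", len(bad), n_comp)
    return out, info


def epoch_and_baseline(
    data: np.ndarray,
    sfreq: float,
    onsets: np.ndarray,
    ch_names: list[str],
    metadata: pd.DataFrame | None = None,
    tmin: float = -0.1,
    tmax: float = 1.0,
    baseline: tuple[float, float] = (-0.1, 0.0),
) -> EpochArray:
    """Cut epochs around onsets and subtract the baseline mean per channel.

    Onsets whose window falls outside the recording are dropped (logged).
    The time axis is tmin..tmax inclusive.
    """
    n_samples = data.shape[1]
    i0 = int(round(tmin * sfreq))
    i1 = int(round(tmax * sfreq))
    times = np.arange(i0, i1 + 1) / sfreq
    keep, dropped = [], []
    for k, o in enumerate(np.asarray(onsets, dtype=int)):
        if o + i0 < 0 or o + i1 + 1 > n_samples:
            dropped.append(k)
        else:
            keep.append(k)
    if dropped:
        logger.info("epoching: dropped %d onsets at recording edge", len(dropped))
    onsets = np.asarray(onsets, dtype=int)[keep]
    ep = np.stack([data[:, o + i0 : o + i1 + 1] for o in onsets]) if len(onsets) \
        else np.empty((0, data.shape[0], len(times)))
    # windows are closed on the left, open on the right: baseline [-100, 0) ms
    bmask = (times >= baseline[0] - 1e-9) & (times < baseline[1] - 1e-9)
    if len(onsets):
        ep = ep - ep[:, :, bmask].mean(axis=2, keepdims=True)
    if metadata is None:
        metadata = pd.DataFrame({"epoch": np.arange(len(onsets))})
    else:
        metadata = metadata.iloc[keep].reset_index(drop=True)
    return EpochArray(
        data=ep, times=times, sfreq=sfreq, ch_names=list(ch_names),
        metadata=metadata,
    )


def reject_artifacts(
    epochs: EpochArray,
    threshold: float = 250.0,
    win_s: float = 0.2,
    step_s: float = 0.05,
    channels: list[str] | None = None,
) -> np.ndarray:
    """Sliding-window peak-to-peak rejection mask (True = rejected).

    An epoch is rejected iff any channel's max-min within any window exceeds
    ``threshold``. Windows start every ``step_s`` from the epoch start; a
    final partial window is evaluated if at least half of ``win_s`` remains.
    The mask is also stored on ``epochs.rejected``.
    """
    n_t = epochs.data.shape[2]
    win = int(round(win_s * epochs.sfreq))
    step = max(int(round(step_s * epochs.sfreq)), 1)
    if win > n_t:
        raise ValueError("window longer than epoch")
    ch_ix = (
        slice(None)
        if channels is None
        else [epochs.pick(c) for c in channels]
    )
    x = epochs.data[:, ch_ix, :]
    starts = [s for s in range(0, n_t, step) if n_t - s >= win or 2 * (n_t - s) >= win]
    mask = np.zeros(epochs.n_epochs, dtype=bool)
    for s in starts:
        seg = x[:, :, s : s + win]
        ptp = seg.max(axis=2) - seg.min(axis=2)
        mask |= (ptp > threshold).any(axis=1)
    epochs.rejected = mask
    return mask


def spectral_power(
    epochs: EpochArray,
    freqs: np.ndarray = DEFAULT_FREQS,
    n_cycles: float = 4.0,
    time_bandwidth: float = 4.0,
    average_time: bool = False,
    decim: int = 1,
    channel_chunk: int | None = None,
) -> SpectralPower:
    """Morlet wavelet log10 power with mirrored pre/post buffers.

    Each epoch is reflected in time and concatenated before and after itself
    so edge effects fall in the discarded buffers. Wavelets use ``n_cycles``
    cycles per frequency (Morlet family; ``time_bandwidth`` is accepted for
    interface compatibility with multitaper parameterizations and is inert
    here). The base-10 log is applied to the power samples; with
    ``average_time`` the log-power is then averaged across the epoch's
    samples, giving the trials x channels x frequencies matrix that feeds
    :func:`zscore_features`.
    """
    freqs = np.asarray(freqs, float)
    nyq = epochs.sfreq / 2.0
    if freqs.max() >= nyq:
        raise ValueError(
            f"max frequency {freqs.max():.1f} Hz >= Nyquist {nyq:.1f} Hz"
        )
    n_ep, n_ch, n_t = epochs.data.shape
    if channel_chunk is None:
        # bound the transform's float64 workspace (epochs x chunk x freqs x
        # mirrored samples) to ~300 MB
        per_channel = n_ep * len(freqs) * 3 * n_t * 8
        channel_chunk = int(np.clip(300e6 // max(per_channel, 1), 1, n_ch))
    out_times = epochs.times[::decim]
    n_out = len(out_times)
    # time-averaged features keep float64 (z-score invariants to 1e-10);
    # time-resolved arrays are float32 to bound memory
    if average_time:
        power = np.empty((n_ep, n_ch, len(freqs)), dtype=np.float64)
    else:
        power = np.empty((n_ep, n_ch, len(freqs), n_out), dtype=np.float32)
    for c0 in range(0, n_ch, channel_chunk):
        c1 = min(c0 + channel_chunk, n_ch)
        x = epochs.data[:, c0:c1, :]
        mirrored = np.concatenate([x[:, :, ::-1], x, x[:, :, ::-1]], axis=2)
        tfr = mne.time_frequency.tfr_array_morlet(
            mirrored,
            sfreq=epochs.sfreq,
            freqs=freqs,
            n_cycles=n_cycles,
            output="power",
            verbose="error",
        )
        core = tfr[:, :, :, n_t : 2 * n_t : decim]
        core = np.log10(np.maximum(core, np.finfo(float).tiny))
        if average_time:
            power[:, c0:c1] = core.mean(axis=3)
        else:
            power[:, c0:c1] = core
    return SpectralPower(
        power=power,
        freqs=freqs,
        ch_names=list(epochs.ch_names),
        metadata=epochs.metadata.copy(),
        times=None if average_time else out_times,
        sfreq=epochs.sfreq / decim,
    )


def zscore_features(power: SpectralPower) -> SpectralPower:
    """Z-score log-power across epochs, separately per channel x frequency.

    Power is first averaged across samples within each epoch (when
    time-resolved); the across-epoch mean and SD of these epoch-level values
    define the standardization, which for time-resolved output is applied to
    every sample (epoch-level statistics, so evoked within-epoch dynamics are
    preserved).
    """
    if power.power.shape[0] < 2:
        raise ValueError("need at least 2 epochs to z-score")
    x = power.power
    # statistics in float64; large time-resolved arrays stay in their own
    # dtype to avoid doubling memory
    epoch_level = (
        x.mean(axis=3, dtype=np.float64)
        if power.time_resolved
        else x.astype(np.float64, copy=False)
    )
    mu = epoch_level.mean(axis=0)
    sd = epoch_level.std(axis=0, ddof=0)
    zero = np.argwhere(sd == 0)
    if len(zero):
        ch, fr = zero[0]
        raise ValueError(
            f"zero variance across epochs at channel {power.ch_names[ch]!r}, "
            f"frequency {power.freqs[fr]:.2f} Hz"
        )
    if power.time_resolved:
        mu_c = mu.astype(x.dtype)[None, :, :, None]
        sd_c = sd.astype(x.dtype)[None, :, :, None]
        z = (x - mu_c) / sd_c
    else:
        z = (x - mu[None]) / sd[None]
    return SpectralPower(
        power=z,
        freqs=power.freqs,
        ch_names=power.ch_names,
        metadata=power.metadata.copy(),
        times=power.times,
        sfreq=power.sfreq,
    )


def features_matrix(power: SpectralPower) -> tuple[np.ndarray, list[tuple[str, float]]]:
    """Flatten (epochs, channels, freqs) power to (epochs, channel x freq).

    Returns the matrix and the feature index [(channel, freq), ...].
    """
    if power.time_resolved:
        raise ValueError("flatten expects time-averaged power")
    n_ep, n_ch, n_f = power.power.shape
    index = [(ch, float(f)) for ch in power.ch_names for f in power.freqs]
    return power.power.reshape(n_ep, n_ch * n_f).astype(np.float64), index
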