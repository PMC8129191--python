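"""Signal preprocessing: from continuous recordings to epoched band power.

The fixed stage order is: line-noise contact screen -> comb notch ->
shaft-Laplacian reference -> 6th-order Butterworth band-pass + Hilbert
power -> epoching -> per-trial baseline z-scoring -> 80-ms Gaussian
smoothing -> artifact-contact rejection.  Each stage appends to the
provenance log carried on the epoched output.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .datatypes import (
    BandDefinition,
    BANDS,
    ContactInfo,
    EpochedPower,
    RecordingSession,
)


@dataclass
class PreprocConfig:
    """Tunable preprocessing parameters (defaults follow the analysis
    protocol: MAD multiplier 10, 200 ms baseline, 80 ms smoothing)."""

    line_freq: float = 50.0
    line_bandwidth_hz: float = 1.0  # half-width of the band used to measure line power
    mad_multiplier: float = 10.0
    notch_bandwidth_hz: float = 2.0
    baseline_ms: float = 200.0
    epoch_ms: float = 1000.0
    smooth_ms: float = 80.0
    artifact_floor_z: float = 0.1
    artifact_se_floor_mult: float = 3.0
    artifact_mode: str = "pointwise"  # or "se_time_average"
    apply_notch: bool = True


def screen_line_noise_contacts(
    session: RecordingSession,
    line_freq: float = 50.0,
    bandwidth_hz: float = 1.0,
    mad_multiplier: float = 10.0,
):
    """Partition contacts by line-noise power.

    Line power is the mean Welch periodogram power within
    ``line_freq +- bandwidth_hz``.  A contact is removed when its line
    power strictly exceeds the median across contacts plus
    ``mad_multiplier`` times their median absolute deviation.

    Returns ``(kept_indices, removed_indices, line_power)``; removal
    reasons are recorded on the session's ContactInfo entries.
    """
    if session.n_contacts < 3:
        raise ValueError("line-noise screening needs >= 3 contacts (MAD degenerate)")
    fs = session.fs
    nperseg = min(session.n_samples, int(4 * fs))  # 0.25 Hz resolution at fs=1 kHz
    freqs, psd = sps.welch(session.signals, fs=fs, nperseg=nperseg, axis=1)
    band = (freqs >= line_freq - bandwidth_hz) & (freqs <= line_freq + bandwidth_hz)
    line_power = psd[:, band].mean(axis=1)
    med = np.median(line_power)
    mad = np.median(np.abs(line_power - med))
    threshold = med + mad_multiplier * mad
    removed = np.flatnonzero(line_power > threshold)
    kept = np.flatnonzero(line_power <= threshold)
    for i in removed:
        session.contacts[i].excluded = True
        session.contacts[i].exclusion_reason = "line_noise"
    return kept, removed, line_power


def _comb_notch_sos(fs: float, base: float, bandwidth_hz: float) -> np.ndarray:
    nyq = fs / 2.0
    harmonics = np.arange(base, nyq * 0.98, base)
    if len(harmonics) == 0:
        raise ValueError(f"no notch harmonics below Nyquist for base {base} Hz")
    sections = []
    for f0 in harmonics:
        b, a = sps.iirnotch(f0, Q=f0 / bandwidth_hz, fs=fs)
        sections.append(sps.tf2sos(b, a))
    return np.vstack(sections)


def comb_notch(
    session: RecordingSession, base: float = 50.0, bandwidth_hz: float = 2.0
) -> RecordingSession:
    """Zero-phase comb notch at ``base`` Hz and its harmonics.

    Realized as cascaded 2nd-order IIR notches applied forward-backward,
    so the attenuation at each harmonic is doubled and the phase is zero.
    """
    sos = _comb_notch_sos(session.fs, base, bandwidth_hz)
    filtered = sps.sosfiltfilt(sos, session.signals, axis=1)
    out = copy.copy(session)
    out.signals = filtered
    return out


def laplacian_reference(session: RecordingSession) -> RecordingSession:
    """Shaft-Laplacian re-reference.

    Each non-excluded contact's trace minus the mean of its nearest
    non-excluded neighbors (the adjacent lower- and higher-index kept
    contacts on the same shaft).  A contact with zero available neighbors
    is excluded with reason ``no_neighbor``.
    """
    out = copy.copy(session)
    out.contacts = [c.copy() for c in session.contacts]
    referenced = session.signals.copy()

    by_shaft: dict[str, list[int]] = {}
    for i, c in enumerate(out.contacts):
        if not c.excluded:
            by_shaft.setdefault(c.shaft_id, []).append(i)
    for shaft, idx in by_shaft.items():
        idx = sorted(idx, key=lambda i: out.contacts[i].index_on_shaft)
        if len(idx) == 1:
            c = out.contacts[idx[0]]
            c.excluded = True
            c.exclusion_reason = "no_neighbor"
            warnings.warn(
                f"contact {c.contact_id}: single kept contact on shaft {shaft}; "
                "excluded (no Laplacian neighbor)"
            )
            continue
        for pos, i in enumerate(idx):
            neighbors = []
            if pos > 0:
                neighbors.append(idx[pos - 1])
            if pos < len(idx) - 1:
                neighbors.append(idx[pos + 1])
            referenced[i] = session.signals[i] - session.signals[neighbors].mean(axis=0)
    out.signals = referenced
    return out


def common_average_reference(session: RecordingSession) -> RecordingSession:
    """Common-average re-reference (test utility, not part of the pipeline)."""
    out = copy.copy(session)
    out.signals = session.signals - session.signals.mean(axis=0, keepdims=True)
    return out


def band_power(session: RecordingSession, band: BandDefinition) -> np.ndarray:
    """Instantaneous band power per contact.

    Zero-phase 6th-order Butterworth band-pass, then the squared
    magnitude of the analytic (Hilbert-transformed) signal.
    """
    nyq = session.fs / 2.0
    if not (0.0 < band.low < band.high < nyq):
        raise ValueError(
            f"band {band.name} ({band.low}-{band.high} Hz) outside (0, {nyq}) Hz"
        )
    sos = sps.butter(
        6, [band.low, band.high], btype="bandpass", fs=session.fs, output="sos"
    )
    filtered = sps.sosfiltfilt(sos, session.signals, axis=1)
    analytic = sps.hilbert(filtered, axis=1)
    return np.abs(analytic) ** 2


def epoch_and_zscore(
    power: np.ndarray,
    session: RecordingSession,
    contacts: list[ContactInfo],
    baseline_ms: float = 200.0,
    epoch_ms: float = 1000.0,
) -> EpochedPower:
    """Epoch power traces and z-score each trial against its own baseline.

    z(t) = (power(t) - mean(baseline)) / sd(baseline), with the baseline
    the ``baseline_ms`` immediately preceding stimulus onset.  Raw power
    (post-onset and baseline) is retained for latency tests.
    """
    fs = session.fs
    base_n = int(round(baseline_ms * fs / 1000.0))
    post_n = int(round(epoch_ms * fs / 1000.0))
    onsets = session.events.onsets
    labels = session.events.labels
    if np.any(onsets - base_n < 0) or np.any(onsets + post_n > power.shape[1]):
        bad = int(
            np.flatnonzero((onsets - base_n < 0) | (onsets + post_n > power.shape[1]))[0]
        )
        raise ValueError(
            f"event row {bad}: needs {baseline_ms} ms pre-onset and {epoch_ms} ms "
            "post-onset samples"
        )
    n_trials = len(onsets)
    n_contacts = power.shape[0]
    raw = np.empty((n_trials, n_contacts, post_n))
    base = np.empty((n_trials, n_contacts, base_n))
    for t, onset in enumerate(onsets):
        raw[t] = power[:, onset : onset + post_n]
        base[t] = power[:, onset - base_n : onset]
    mu = base.mean(axis=2, keepdims=True)
    sd = base.std(axis=2, keepdims=True)
    zero = np.isclose(sd[..., 0], 0.0)
    if np.any(zero):
        t, c = np.argwhere(zero)[0]
        raise ValueError(
            f"constant baseline (sd=0) for trial {t}, contact "
            f"{contacts[c].contact_id}"
        )
    z = (raw - mu) / sd
    return EpochedPower(
        z_power=z,
        baseline_power=base,
        raw_power=raw,
        labels=labels,
        fs=fs,
        contacts=[c.copy() for c in contacts],
        log=["epoch_and_zscore"],
    )


def smooth_gaussian(ep: EpochedPower, window_ms: float = 80.0) -> EpochedPower:
    """Convolve each z-power trace with a unit-area Gaussian kernel.

    The ``window_ms`` total support corresponds to +-3 sigma, i.e.
    sigma = window_ms / 6; boundaries are handled by reflection, so a
    constant trace passes through unchanged.
    """
    n_epoch = ep.z_power.shape[2]
    if window_ms * ep.fs / 1000.0 >= n_epoch:
        raise ValueError("smoothing window must be shorter than the epoch")
    sigma_samples = (window_ms / 6.0) * ep.fs / 1000.0
    smoothed = gaussian_filter1d(
        ep.z_power, sigma=sigma_samples, axis=2, mode="reflect", truncate=3.0
    )
    return EpochedPower(
        z_power=smoothed,
        baseline_power=ep.baseline_power,
        raw_power=ep.raw_power,
        labels=ep.labels,
        fs=ep.fs,
        contacts=[c.copy() for c in ep.contacts],
        log=list(ep.log) + [f"smooth_gaussian:{window_ms}ms"],
    )


def reject_artifact_contacts(
    ep: EpochedPower,
    floor_z: float = 0.1,
    se_floor_mult: float = 3.0,
    mode: str = "pointwise",
):
    """Partition contacts by across-trial variability.

    A contact is removed when the across-trial standard error SE(t) of
    its smoothed z-power exceeds the magnitude of the across-trial mean
    M(t) at any post-onset time point where |M(t)| clears a
    minimal-magnitude floor (``mode='pointwise'``).  The floor is
    ``max(floor_z, se_floor_mult * median_t SE(t))``: the absolute part
    avoids removing contacts wherever the mean crosses zero, the
    relative part keeps the rule calibrated across trial counts (SE
    shrinks as 1/sqrt(trials), so a fixed floor alone would mass-remove
    contacts in small sessions).  ``mode='se_time_average'`` instead
    compares SE(t) against the time-averaged SE (alternative reading of
    the rule).

    Returns ``(kept_epochs, removed_contact_ids)``.
    """
    if ep.n_trials < 2:
        raise ValueError("artifact rejection needs >= 2 trials")
    if mode not in ("pointwise", "se_time_average"):
        raise ValueError(f"unknown artifact mode {mode!r}")
    mean = ep.z_power.mean(axis=0)  # contacts x time
    se = ep.z_power.std(axis=0, ddof=1) / np.sqrt(ep.n_trials)
    floor = np.maximum(floor_z, se_floor_mult * np.median(se, axis=1, keepdims=True))
    if mode == "pointwise":
        bad_t = (se > np.abs(mean)) & (np.abs(mean) >= floor)
    else:
        bad_t = se > se.mean(axis=1, keepdims=True) + np.abs(mean)
    bad = bad_t.any(axis=1)
    removed_ids = [ep.contacts[i].contact_id for i in np.flatnonzero(bad)]
    kept_idx = np.flatnonzero(~bad)
    kept = ep.subset_contacts(kept_idx)
    for c in ep.contacts:
        if c.contact_id in removed_ids:
            c.excluded = True
            c.exclusion_reason = "artifact"
    kept.log[-1] = f"reject_artifact_contacts:removed={len(removed_ids)}"
    return kept, removed_ids


def preprocess_session(
    session: RecordingSession,
    band: BandDefinition | str = "high_gamma",
    config: PreprocConfig | None = None,
) -> EpochedPower:
    """Run the full preprocessing chain on one session.

    Stage order: screen -> notch -> Laplacian -> band-pass/Hilbert ->
    epoch -> z-score -> smooth -> artifact-reject.
    """
    if isinstance(band, str):
        band = BANDS[band]
    cfg = config or PreprocConfig()
    log = []

    work = copy.copy(session)
    work.contacts = [c.copy() for c in session.contacts]
    _, removed, _ = screen_line_noise_contacts(
        work, cfg.line_freq, cfg.line_bandwidth_hz, cfg.mad_multiplier
    )
    log.append(f"screen_line_noise:removed={len(removed)}")

    if cfg.apply_notch:
        work = comb_notch(work, base=cfg.line_freq, bandwidth_hz=cfg.notch_bandwidth_hz)
        log.append(f"comb_notch:{cfg.line_freq}Hz")

    work = laplacian_reference(work)
    log.append("laplacian_reference")

    kept_idx = [i for i, c in enumerate(work.contacts) if not c.excluded]
    kept_contacts = [work.contacts[i] for i in kept_idx]
    sub = copy.copy(work)
    sub.signals = work.signals[kept_idx]
    sub.contacts = kept_contacts

    power = band_power(sub, band)
    log.append(f"band_power:{band.name}")

    ep = epoch_and_zscore(
        power, sub, kept_contacts, baseline_ms=cfg.baseline_ms, epoch_ms=cfg.epoch_ms
    )
    ep = smooth_gaussian(ep, window_ms=cfg.smooth_ms)
    ep, removed_ids = reject_artifact_contacts(
        ep,
        floor_z=cfg.artifact_floor_z,
        se_floor_mult=cfg.artifact_se_floor_mult,
        mode=cfg.artifact_mode,
    )
    ep.log = log + ep.log
    return ep
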