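"""Synthetic SEEG session generator.

Emulates the statistical structure the downstream analysis assumes:
1/f-like background on every contact, optional 50 Hz line contamination,
and class-dependent band-limited power increases at chosen contacts with
chosen onset latencies.  Trials of two stimulus classes (own / other
name) are scheduled with a fixed stimulus duration and an inter-trial
interval, optionally with uniform jitter.

The generator also builds synthetic stimulus pairs (amplitude-modulated
tones, binary raster images) with a controlled physical similarity, for
testing the similarity-vs-accuracy regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datatypes import ContactInfo, EventTable, RecordingSession

#: ramp applied when gating effect envelopes on/off, to avoid spectral
#: clicks leaking into other bands
RAMP_MS = 20.0


@dataclass
class EffectSpec:
    """A class-dependent band-limited power increase at one contact.

    The contact carries a continuous band-limited noise component of RMS
    ``base_amplitude_uv``; during ``[onset_ms, onset_ms + duration_ms]``
    of trials of ``class_label`` its amplitude is multiplied by
    ``effect_size`` (>= 1; 1 means null effect).
    """

    contact_id: str
    band: tuple = (60.0, 145.0)
    class_label: str = "own"
    onset_ms: float = 300.0
    duration_ms: float = 400.0
    effect_size: float = 3.0
    base_amplitude_uv: float = 0.5

    def validate(self, stimulus_ms: float) -> None:
        if self.effect_size < 1.0:
            raise ValueError("effect_size must be >= 1")
        if self.onset_ms < 0 or self.duration_ms <= 0:
            raise ValueError("onset/duration must be non-negative/positive")
        if self.onset_ms + self.duration_ms > stimulus_ms:
            raise ValueError(
                f"effect window {self.onset_ms}+{self.duration_ms} ms overruns "
                f"the {stimulus_ms} ms stimulus"
            )


@dataclass
class SimConfig:
    """Parameters of one simulated session.

    Defaults mirror a typical recording: fs 1000 Hz, 2 shafts of 8
    contacts, 60 trials per class, 1000 ms stimuli and 1000 ms ITI
    (optionally jittered by up to ``jitter_ms`` extra, drawn uniformly).
    Background is 1/f-like with power-spectral exponent
    ``background_exponent`` and broadband RMS ``background_rms_uv``.
    """

    n_shafts: int = 2
    contacts_per_shaft: int = 8
    fs: float = 1000.0
    n_trials_per_class: int = 60
    stimulus_ms: float = 1000.0
    iti_ms: float = 1000.0
    jitter_ms: float = 0.0
    background_exponent: float = 2.0
    background_rms_uv: float = 20.0
    noise_floor_uv: float = 2.0  # broadband (white) noise floor
    line_noise_amp_uv: float = 0.0
    line_freq: float = 50.0
    effects: list = field(default_factory=list)
    modality: str = "auditory"
    subject: str = "sim"
    seed: int = 0
    pre_roll_ms: float = 2400.0  # head room before the first onset
    post_roll_ms: float = 1400.0

    def validate(self) -> None:
        if self.n_trials_per_class < 2:
            raise ValueError("n_trials_per_class must be >= 2")
        for name in ("stimulus_ms", "iti_ms", "fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.jitter_ms < 0:
            raise ValueError("jitter_ms must be >= 0")
        for eff in self.effects:
            eff.validate(self.stimulus_ms)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["effects"] = [
            e if isinstance(e, EffectSpec) else EffectSpec(**{**e, "band": tuple(e["band"])})
            for e in d.get("effects", [])
        ]
        return cls(**d)


def _one_over_f_noise(rng, n_samples: int, fs: float, exponent: float) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit RMS."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    # amplitude scales as f^(-exponent/2) so power goes as f^(-exponent);
    # pin DC to zero
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=n_samples)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms


def _band_limited_noise(rng, n_samples: int, fs: float, band) -> np.ndarray:
    """White noise restricted to ``band`` (FFT brick wall), unit RMS.

    The sharp spectral cut keeps the effect component from leaking power
    into the line-noise screen's 50 Hz measurement band.
    """
    low, high = band
    spec = np.fft.rfft(rng.standard_normal(n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    spec[(freqs < low) | (freqs > high)] = 0.0
    x = np.fft.irfft(spec, n=n_samples)
    return x / np.sqrt(np.mean(x**2))


def _effect_envelope(
    n_samples: int,
    fs: float,
    onsets: np.ndarray,
    labels: np.ndarray,
    spec: EffectSpec,
) -> np.ndarray:
    """Amplitude envelope: 1 everywhere, ``effect_size`` inside matching
    trial windows, with cosine on/off ramps of RAMP_MS."""
    env = np.ones(n_samples)
    gain = spec.effect_size
    if gain == 1.0:
        return env
    ramp_n = max(1, int(round(RAMP_MS * fs / 1000.0)))
    up = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, ramp_n)))
    start_off = int(round(spec.onset_ms * fs / 1000.0))
    dur_n = int(round(spec.duration_ms * fs / 1000.0))
    for onset, lab in zip(onsets, labels):
        if lab != spec.class_label:
            continue
        a = onset + start_off
        b = a + dur_n
        env[a : a + ramp_n] += (gain - 1.0) * up[: max(0, min(ramp_n, n_samples - a))]
        env[a + ramp_n : b - ramp_n] = gain
        env[b - ramp_n : b] = 1.0 + (gain - 1.0) * up[::-1][: max(0, b - (b - ramp_n))]
    return env


def generate_session(config: SimConfig):
    """Generate a RecordingSession plus a ground-truth record.

    Returns ``(session, ground_truth)`` where the ground truth is a
    DataFrame listing the discriminative (contact, time-window) pairs.
    Identical config and seed give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs

    contacts = []
    for s in range(config.n_shafts):
        shaft = f"S{s + 1}"
        for k in range(1, config.contacts_per_shaft + 1):
            contacts.append(
                ContactInfo(
                    contact_id=f"{shaft}-{k}",
                    shaft_id=shaft,
                    index_on_shaft=k,
                    region_label=f"region {s + 1}",
                    hemisphere="left",
                )
            )
    known_ids = {c.contact_id for c in contacts}
    for eff in config.effects:
        if eff.contact_id not in known_ids:
            raise ValueError(f"EffectSpec references unknown contact {eff.contact_id!r}")

    # schedule events: balanced pseudo-random class sequence
    n_trials = 2 * config.n_trials_per_class
    labels = np.array(
        ["own"] * config.n_trials_per_class + ["other"] * config.n_trials_per_class,
        dtype=object,
    )
    rng.shuffle(labels)
    stim_n = int(round(config.stimulus_ms * fs / 1000.0))
    iti_n = int(round(config.iti_ms * fs / 1000.0))
    jitters = (
        rng.integers(0, int(round(config.jitter_ms * fs / 1000.0)) + 1, size=n_trials)
        if config.jitter_ms > 0
        else np.zeros(n_trials, dtype=np.int64)
    )
    onsets = np.empty(n_trials, dtype=np.int64)
    cursor = int(round(config.pre_roll_ms * fs / 1000.0))
    for i in range(n_trials):
        onsets[i] = cursor
        cursor += stim_n + iti_n + int(jitters[i])
    n_samples = cursor + int(round(config.post_roll_ms * fs / 1000.0))

    signals = np.empty((len(contacts), n_samples))
    for i in range(len(contacts)):
        signals[i] = config.background_rms_uv * _one_over_f_noise(
            rng, n_samples, fs, config.background_exponent
        )
        if config.noise_floor_uv > 0:
            signals[i] += config.noise_floor_uv * rng.standard_normal(n_samples)
    if config.line_noise_amp_uv > 0:
        t = np.arange(n_samples) / fs
        line = np.sin(2 * np.pi * config.line_freq * t)
        for i in range(len(contacts)):
            signals[i] += config.line_noise_amp_uv * line

    gt_rows = []
    for eff in config.effects:
        idx = next(i for i, c in enumerate(contacts) if c.contact_id == eff.contact_id)
        comp = _band_limited_noise(rng, n_samples, fs, eff.band)
        env = _effect_envelope(n_samples, fs, onsets, labels, eff)
        signals[idx] += eff.base_amplitude_uv * env * comp
        gt_rows.append(
            {
                "contact_id": eff.contact_id,
                "class_label": eff.class_label,
                "onset_ms": eff.onset_ms,
                "duration_ms": eff.duration_ms,
                "band_low": eff.band[0],
                "band_high": eff.band[1],
                "effect_size": eff.effect_size,
            }
        )
    ground_truth = pd.DataFrame(
        gt_rows,
        columns=[
            "contact_id",
            "class_label",
            "onset_ms",
            "duration_ms",
            "band_low",
            "band_high",
            "effect_size",
        ],
    )

    events = EventTable.from_arrays(onsets, labels, config.modality)
    session = RecordingSession(
        signals=signals,
        fs=fs,
        contacts=contacts,
        events=events,
        session_meta={
            "subject": config.subject,
            "modality": config.modality,
            "stimulus_ms": config.stimulus_ms,
            "iti_ms": config.iti_ms,
            "jitter_ms": config.jitter_ms,
            "seed": int(config.seed),
        },
    )
    session.validate()
    return session, ground_truth


# ---------------------------------------------------------------------------
# Synthetic stimulus pairs with controlled physical similarity


def _correlated_pair(rng, n: int, rho: float):
    """Two unit-variance vectors with *sample* correlation exactly rho."""
    u = rng.standard_normal(n)
    v = rng.standard_normal(n)
    u = (u - u.mean()) / u.std()
    # orthogonalize v against u empirically, then standardize
    v = v - (v @ u) / (u @ u) * u
    v = (v - v.mean()) / v.std()
    w = rho * u + np.sqrt(max(0.0, 1.0 - rho**2)) * v
    return u, (w - w.mean()) / w.std()


def make_stimulus_pair(kind: str, similarity: float, seed: int = 0):
    """Build two synthetic stimuli with the requested zero-lag similarity.

    ``kind='auditory'``: two 1-s amplitude-modulated tones (fs 8000 Hz,
    1 kHz carrier) whose Hilbert amplitude envelopes correlate at the
    requested level.  ``kind='visual'``: two binary raster images whose
    mean-centered zero-shift cross-correlation matches the request.
    """
    if not 0.0 <= similarity <= 1.0:
        raise ValueError("similarity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if kind == "auditory":
        fs = 8000.0
        n = int(fs)
        # slowly varying (<= 50 Hz) modulators with exact sample correlation
        u, w = _correlated_pair(rng, n, similarity)
        sos = sps.butter(4, 50.0, btype="lowpass", fs=fs, output="sos")
        lu = sps.sosfiltfilt(sos, u)
        lw = sps.sosfiltfilt(sos, w)
        lu = (lu - lu.mean()) / lu.std()
        lw = (lw - lw.mean()) / lw.std()
        # re-impose the exact correlation after filtering
        lw = lw - (lw @ lu) / (lu @ lu) * lu
        if lw.std() > 0:
            lw = (lw - lw.mean()) / lw.std()
        lw = similarity * lu + np.sqrt(max(0.0, 1.0 - similarity**2)) * lw
        env_u = np.clip(1.0 + 0.2 * lu, 0.01, None)
        env_w = np.clip(1.0 + 0.2 * lw, 0.01, None)
        if similarity == 1.0:
            env_w = env_u
        t = np.arange(n) / fs
        carrier = np.sin(2 * np.pi * 1000.0 * t)
        return env_u * carrier, env_w * carrier
    if kind == "visual":
        shape = (64, 128)
        img_a = (rng.random(shape) < 0.5).astype(float)
        if similarity == 1.0:
            return img_a, img_a.copy()
        # flipping a fraction phi of balanced binary pixels lowers the
        # correlation to ~ 1 - 2*phi
        n_pix = img_a.size
        n_flip = int(round((1.0 - similarity) / 2.0 * n_pix))
        flip_idx = rng.choice(n_pix, size=n_flip, replace=False)
        img_b = img_a.copy().ravel()
        img_b[flip_idx] = 1.0 - img_b[flip_idx]
        return img_a, img_b.reshape(shape)
    raise ValueError(f"unknown stimulus kind {kind!r}")
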