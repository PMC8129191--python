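"""Shared data model for the SEEG name-decoding pipeline.

The pipeline operates on one recording session at a time: a continuous
multichannel intracranial recording with stimulus-event markers and
per-contact metadata (shaft membership, anatomical region, optional MNI
coordinates).  Depth-electrode shafts carry 8-16 contacts each; contacts
are identified by ``(shaft_id, index_on_shaft)`` with 1-based contiguous
indices along the shaft.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

VALID_CLASS_LABELS = ("own", "other", "rest")
VALID_MODALITIES = ("auditory", "visual")
VALID_EXCLUSION_REASONS = ("none", "line_noise", "artifact", "no_neighbor")


class SessionValidationError(ValueError):
    """Raised when a session violates a structural invariant.

    The message names the offending row or contact.
    """


@dataclass
class ContactInfo:
    """Identity and metadata for one recording contact."""

    contact_id: str
    shaft_id: str
    index_on_shaft: int  # 1-based along the shaft
    region_label: str = "unknown"
    hemisphere: str = "left"
    mni_xyz: Optional[np.ndarray] = None  # millimetres, shape (3,)
    excluded: bool = False
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if self.mni_xyz is not None:
            self.mni_xyz = np.asarray(self.mni_xyz, dtype=float)
            if self.mni_xyz.shape != (3,):
                raise SessionValidationError(
                    f"contact {self.contact_id}: mni_xyz must be a 3-vector"
                )
        if self.exclusion_reason not in VALID_EXCLUSION_REASONS:
            raise SessionValidationError(
                f"contact {self.contact_id}: unknown exclusion reason "
                f"{self.exclusion_reason!r}"
            )

    def copy(self) -> "ContactInfo":
        return dataclasses.replace(
            self,
            mni_xyz=None if self.mni_xyz is None else self.mni_xyz.copy(),
        )


def normalize_region_label(label: str) -> str:
    """Case-insensitive, whitespace-normalized region key.

    Region labels are free strings (e.g. Freesurfer parcel names such as
    "Left supramarginal"); no fixed atlas is assumed.
    """
    return " ".join(str(label).split()).lower()


class EventTable:
    """Stimulus events of one session.

    Wraps a DataFrame with columns ``onset_sample`` (integer, 0-based),
    ``class_label`` (own|other|rest) and ``modality`` (auditory|visual).
    """

    COLUMNS = ("onset_sample", "class_label", "modality")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise SessionValidationError(f"event table missing columns: {missing}")
        self.df = df.reset_index(drop=True).copy()
        self.df["onset_sample"] = self.df["onset_sample"].astype(np.int64)

    @classmethod
    def from_arrays(
        cls,
        onset_sample: Sequence[int],
        class_label: Sequence[str],
        modality: str | Sequence[str],
    ) -> "EventTable":
        n = len(onset_sample)
        if isinstance(modality, str):
            modality = [modality] * n
        return cls(
            pd.DataFrame(
                {
                    "onset_sample": np.asarray(onset_sample, dtype=np.int64),
                    "class_label": list(class_label),
                    "modality": list(modality),
                }
            )
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def onsets(self) -> np.ndarray:
        return self.df["onset_sample"].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.df["class_label"].to_numpy(dtype=object)

    def validate(
        self,
        n_samples: int,
        fs: float,
        stimulus_ms: float,
        min_iti_ms: float = 0.0,
    ) -> None:
        onsets = self.onsets
        labels = self.labels
        for i, lab in enumerate(labels):
            if lab not in VALID_CLASS_LABELS:
                raise SessionValidationError(f"event row {i}: unknown class {lab!r}")
        for i, mod in enumerate(self.df["modality"]):
            if mod not in VALID_MODALITIES:
                raise SessionValidationError(f"event row {i}: unknown modality {mod!r}")
        if np.any(np.diff(onsets) <= 0):
            i = int(np.flatnonzero(np.diff(onsets) <= 0)[0]) + 1
            raise SessionValidationError(
                f"event row {i}: onsets must be strictly increasing"
            )
        min_gap = int(round((stimulus_ms + min_iti_ms) * fs / 1000.0))
        gaps = np.diff(onsets)
        if np.any(gaps < min_gap):
            i = int(np.flatnonzero(gaps < min_gap)[0]) + 1
            raise SessionValidationError(
                f"event row {i}: inter-onset gap {gaps[i - 1]} samples is below "
                f"stimulus + minimum ITI ({min_gap} samples)"
            )
        horizon = int(round(stimulus_ms * fs / 1000.0))
        late = onsets + horizon > n_samples
        if np.any(late):
            i = int(np.flatnonzero(late)[0])
            raise SessionValidationError(
                f"event row {i}: onset {onsets[i]} + stimulus window exceeds "
                f"recording length {n_samples}"
            )
        n_own = int(np.sum(labels == "own"))
        n_other = int(np.sum(labels == "other"))
        if n_own != n_other:
            raise SessionValidationError(
                f"unbalanced design: {n_own} own vs {n_other} other trials"
            )


@dataclass
class RecordingSession:
    """One subject/modality recording: signals, events, contact metadata.

    ``signals`` is contacts x samples in microvolts; ``fs`` in Hz.
    """

    signals: np.ndarray
    fs: float
    contacts: list[ContactInfo]
    events: EventTable
    session_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)

    @property
    def n_contacts(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def stimulus_ms(self) -> float:
        return float(self.session_meta.get("stimulus_ms", 1000.0))

    def contact_index(self, contact_id: str) -> int:
        for i, c in enumerate(self.contacts):
            if c.contact_id == contact_id:
                return i
        raise KeyError(f"unknown contact {contact_id!r}")

    def validate(self) -> None:
        if self.signals.ndim != 2:
            raise SessionValidationError("signals must be a 2-D contacts x samples array")
        if self.signals.shape[0] != len(self.contacts):
            raise SessionValidationError(
                f"signals have {self.signals.shape[0]} rows but "
                f"{len(self.contacts)} contacts are listed"
            )
        ids = [c.contact_id for c in self.contacts]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SessionValidationError(f"duplicate contact ids: {dup}")
        pairs = [(c.shaft_id, c.index_on_shaft) for c in self.contacts]
        if len(set(pairs)) != len(pairs):
            dup = sorted({p for p in pairs if pairs.count(p) > 1})
            raise SessionValidationError(f"duplicate (shaft, index) pairs: {dup}")
        # index_on_shaft must form a contiguous 1..k run per shaft
        by_shaft: dict[str, list[int]] = {}
        for c in self.contacts:
            by_shaft.setdefault(c.shaft_id, []).append(c.index_on_shaft)
        for shaft, idx in by_shaft.items():
            if sorted(idx) != list(range(1, len(idx) + 1)):
                raise SessionValidationError(
                    f"shaft {shaft}: index_on_shaft not a contiguous 1..k run: "
                    f"{sorted(idx)}"
                )
        self.events.validate(
            n_samples=self.n_samples,
            fs=self.fs,
            stimulus_ms=self.stimulus_ms,
            min_iti_ms=float(self.session_meta.get("min_iti_ms", 0.0)),
        )

    def kept_contacts(self) -> list[ContactInfo]:
        return [c for c in self.contacts if not c.excluded]


@dataclass
class BandDefinition:
    """A named frequency band in Hz."""

    name: str
    low: float
    high: float


#: Canonical analysis bands.  High gamma (60-145 Hz) reflects local
#: population firing and is the best-performing feature band.
BANDS = {
    "high_gamma": BandDefinition("high_gamma", 60.0, 145.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
}


@dataclass
class EpochedPower:
    """Per-trial, per-contact normalized band-power traces.

    ``z_power``: trials x contacts x time, z-units, 0-1000 ms post-onset.
    ``raw_power``: same shape, raw power (kept for latency tests).
    ``baseline_power``: trials x contacts x baseline samples, raw power
    over the 200 ms immediately preceding stimulus onset.
    """

    z_power: np.ndarray
    baseline_power: np.ndarray
    raw_power: np.ndarray
    labels: np.ndarray  # per-trial class labels
    fs: float
    contacts: list[ContactInfo]
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        n_trials = self.z_power.shape[0]
        if len(self.labels) != n_trials:
            raise ValueError("labels length must equal trial count")
        if self.baseline_power.shape[:2] != self.z_power.shape[:2]:
            raise ValueError("baseline and post-onset trial/contact axes differ")

    @property
    def n_trials(self) -> int:
        return self.z_power.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.z_power.shape[1]

    @property
    def n_times(self) -> int:
        return self.z_power.shape[2]

    def contact_index(self, contact_id: str) -> int:
        for i, c in enumerate(self.contacts):
            if c.contact_id == contact_id:
                return i
        raise KeyError(f"unknown contact {contact_id!r}")

    def subset_contacts(self, indices: Sequence[int]) -> "EpochedPower":
        idx = list(indices)
        return EpochedPower(
            z_power=self.z_power[:, idx, :],
            baseline_power=self.baseline_power[:, idx, :],
            raw_power=self.raw_power[:, idx, :],
            labels=self.labels.copy(),
            fs=self.fs,
            contacts=[self.contacts[i].copy() for i in idx],
            log=list(self.log) + [f"subset_contacts:{len(idx)}"],
        )


@dataclass
class FeatureSet:
    """Trial x feature matrix with per-feature provenance.

    Houses the full spatiotemporal feature vector V (100 ten-ms bins per
    contact, contact-major order) and, after selection, V20 (or the
    three-class 30-feature union).  ``contact_ids`` / ``bin_index`` give
    each column's origin; ``bin_start_ms`` is ``10 * bin_index``.
    """

    matrix: np.ndarray  # trials x features, z-power units
    contact_ids: np.ndarray  # per feature
    bin_index: np.ndarray  # per feature, 0..99
    labels: np.ndarray  # per trial
    r_values: Optional[np.ndarray] = None
    p_values: Optional[np.ndarray] = None
    selected: Optional[np.ndarray] = None
    n_significant: Optional[int] = None
    bonferroni_alpha: Optional[float] = None
    pair_origin: Optional[np.ndarray] = None  # three-class: which pair chose it
    bin_ms: float = 10.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.contact_ids = np.asarray(self.contact_ids, dtype=object)
        self.bin_index = np.asarray(self.bin_index, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.matrix.shape[1] != len(self.contact_ids):
            raise ValueError("provenance length must equal feature count")
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("labels length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def bin_start_ms(self) -> np.ndarray:
        return self.bin_index * self.bin_ms

    def subset_features(self, col_idx: np.ndarray, **extra) -> "FeatureSet":
        col_idx = np.asarray(col_idx, dtype=np.int64)
        return FeatureSet(
            matrix=self.matrix[:, col_idx],
            contact_ids=self.contact_ids[col_idx],
            bin_index=self.bin_index[col_idx],
            labels=self.labels.copy(),
            bin_ms=self.bin_ms,
            **extra,
        )

    def subset_trials(self, row_idx: np.ndarray) -> "FeatureSet":
        row_idx = np.asarray(row_idx)
        return FeatureSet(
            matrix=self.matrix[row_idx],
            contact_ids=self.contact_ids.copy(),
            bin_index=self.bin_index.copy(),
            labels=self.labels[row_idx],
            bin_ms=self.bin_ms,
        )


@dataclass
class DecodingResult:
    """Outcome of leave-one-out decoding for one session/band/classifier."""

    y_true: np.ndarray
    y_pred: np.ndarray
    classes: list[str]
    scores: np.ndarray  # trials x classes, class posteriors / vote fractions
    accuracy: float  # percent
    classifier: str  # lda | random_forest
    n_components_used: Optional[list[int]] = None  # per fold (LDA path)
    significance_threshold: Optional[float] = None  # percent
    permutation_p: Optional[float] = None

    @property
    def n_trials(self) -> int:
        return len(self.y_true)


@dataclass
class MultiClassReport:
    """Three-class evaluation: confusion matrix, sensitivity, precision, ROC.

    sensitivity = 100 * TP / (TP + FN); precision = 100 * TP / (TP + FP).
    Per-class accuracy equals the sensitivity (confusion diagonal over row
    sum).
    """

    classes: list[str]
    confusion_matrix: np.ndarray  # rows: true, columns: predicted
    sensitivity: dict
    precision: dict
    roc: dict  # class -> {"fpr": ..., "tpr": ..., "auc": float}


@dataclass
class RegionReport:
    """Per-region contribution and decoding summary."""

    region_label: str
    n_contacts: int
    n_features_contributed: int
    single_region_accuracy: Optional[float] = None  # percent
    significance_threshold: Optional[float] = None  # percent
    is_max_contributor: bool = False
    is_cross_modal: Optional[bool] = None
    cross_modal_contacts: Optional[list[str]] = None


@dataclass
class SimilarityRecord:
    """Physical stimulus similarity paired with region accuracies."""

    modality: str
    cross_correlation: float  # normalized, in [-1, 1]
    region_accuracies: dict = field(default_factory=dict)


@dataclass
class LatencyReport:
    """First-significant-bin latencies for one contact (ms, bin starts)."""

    contact_id: str
    own_vs_rest_ms: Optional[float] = None
    other_vs_rest_ms: Optional[float] = None
    own_vs_other_ms: Optional[float] = None
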