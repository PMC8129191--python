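"""Per-session analysis orchestration: two-class and three-class runs.

``run_two_class`` executes preprocess -> bin -> per-fold select+decode
-> one-shot reporting selection -> region contributions -> latencies,
and returns a JSON-serializable report with a provenance log.
``run_three_class`` adds rest-state epochs cut from the 1,000 ms
pre-onset interval of every trial and evaluates the three-class
(rest / own / other) problem with 10 features per pairwise test.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .datatypes import EpochedPower, RecordingSession
from .preprocess import PreprocConfig, preprocess_session
from .features import bin_features, select_threeclass_features, select_top_features
from .classify import evaluate_threeclass, loo_decode
from .latency import contact_latency_report
from .regions import region_contribution


@dataclass
class AnalysisConfig:
    """All pipeline parameters with their protocol defaults."""

    band: str = "high_gamma"
    classifier: str = "lda"
    k: int = 20  # two-class selected dimension
    k_per_pair: int = 10  # three-class: features per pairwise test
    alpha: float = 0.05
    n_perm_select: int = 1000
    n_perm_acc: int = 1000
    n_perm_latency: int = 1000
    selection_mode: str = "per_fold"  # anti-leakage default
    var_threshold: float = 0.90
    n_trees: int = 200
    rest_ms: float = 1000.0  # pre-onset rest window (three-class control)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "preproc" in d and isinstance(d["preproc"], dict):
            d["preproc"] = PreprocConfig(**d["preproc"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _decode_report(result) -> dict:
    rep = {
        "accuracy_pct": result.accuracy,
        "significance_threshold_pct": result.significance_threshold,
        "permutation_p": result.permutation_p,
        "classifier": result.classifier,
        "classes": list(result.classes),
        "per_trial": [
            {"true": str(t), "predicted": str(p)}
            for t, p in zip(result.y_true, result.y_pred)
        ],
    }
    if result.n_components_used:
        rep["n_components_used"] = {
            "min": int(min(result.n_components_used)),
            "max": int(max(result.n_components_used)),
        }
    return rep


def run_two_class(
    session: RecordingSession, config: AnalysisConfig | None = None, seed: int = 0
) -> dict:
    """Full two-class analysis of one session; returns the report bundle."""
    cfg = config or AnalysisConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)]

    ep = preprocess_session(session, band=cfg.band, config=cfg.preproc)
    fset = bin_features(ep)
    result = loo_decode(
        fset,
        classifier=cfg.classifier,
        k=min(cfg.k, fset.n_features),
        selection_mode=cfg.selection_mode,
        n_perm_select=cfg.n_perm_select,
        n_perm_acc=cfg.n_perm_acc,
        alpha=cfg.alpha,
        var_threshold=cfg.var_threshold,
        n_trees=cfg.n_trees,
        seed=seeds[0],
    )

    # one-shot selection on the whole session, for region reporting only
    report_sel = select_top_features(
        fset,
        k=min(cfg.k, fset.n_features),
        alpha=cfg.alpha,
        n_perm=cfg.n_perm_select,
        seed=seeds[1],
    )
    region_reports = region_contribution(report_sel, ep.contacts)

    lat_rng = np.random.default_rng(seeds[2])
    latencies = {}
    for cid in sorted(set(map(str, report_sel.contact_ids))):
        rep = contact_latency_report(
            ep, cid, alpha=cfg.alpha, n_perm=cfg.n_perm_latency, rng=lat_rng
        )
        latencies[cid] = {
            "own_vs_rest_ms": rep.own_vs_rest_ms,
            "other_vs_rest_ms": rep.other_vs_rest_ms,
            "own_vs_other_ms": rep.own_vs_other_ms,
        }

    removed = [
        {"contact_id": c.contact_id, "reason": c.exclusion_reason}
        for c in session.contacts
        if c.excluded
    ]
    report = {
        "kind": "two_class",
        "seed": int(seed),
        "band": cfg.band,
        "config": cfg.to_dict(),
        "decoding": _decode_report(result),
        "reporting_selection": {
            "n_features": int(report_sel.n_features),
            "n_significant": int(report_sel.n_significant),
            "bonferroni_alpha": float(report_sel.bonferroni_alpha),
            "features": [
                {"contact_id": str(c), "bin_start_ms": float(t), "p": float(p)}
                for c, t, p in zip(
                    report_sel.contact_ids,
                    report_sel.bin_start_ms,
                    report_sel.p_values,
                )
            ],
        },
        "regions": [
            {
                "region": r.region_label,
                "n_contacts": r.n_contacts,
                "n_features": r.n_features_contributed,
                "max_contributor": r.is_max_contributor,
            }
            for r in region_reports
        ],
        "latencies_ms": latencies,
        "provenance": {
            "stages": list(ep.log),
            "seeds": {"decode": seeds[0], "report_selection": seeds[1],
                      "latency": seeds[2]},
            "removed_contacts": removed,
            "n_kept_contacts": ep.n_contacts,
        },
    }
    return report


def build_rest_epochs(
    session: RecordingSession,
    band: str = "high_gamma",
    config: PreprocConfig | None = None,
    rest_ms: float = 1000.0,
) -> EpochedPower:
    """Three-class epochs: stimulus epochs plus pre-onset rest epochs.

    For every trial the ``rest_ms`` interval preceding stimulus onset is
    cut as a rest-state sample and z-scored against its own first 200 ms
    (symmetric with the stimulus epochs).  A rest window that would
    overlap the previous stimulus, or run off the start of the
    recording, is an error.
    """
    cfg = config or PreprocConfig()
    fs = session.fs
    rest_n = int(round(rest_ms * fs / 1000.0))
    base_n = int(round(cfg.baseline_ms * fs / 1000.0))
    onsets = session.events.onsets
    stim_n = int(round(session.stimulus_ms * fs / 1000.0))
    starts = onsets - rest_n
    if np.any(starts < 0):
        i = int(np.flatnonzero(starts < 0)[0])
        raise ValueError(f"event row {i}: insufficient pre-onset interval for rest epoch")
    prev_end = onsets[:-1] + stim_n
    if np.any(starts[1:] < prev_end):
        i = int(np.flatnonzero(starts[1:] < prev_end)[0]) + 1
        raise ValueError(
            f"event row {i}: rest epoch would overlap the previous stimulus"
        )

    stim_ep = preprocess_session(session, band=band, config=cfg)
    kept_ids = {c.contact_id for c in stim_ep.contacts}

    # recompute power on the same kept contacts for the rest windows
    import copy as _copy

    from .preprocess import band_power, comb_notch, laplacian_reference, smooth_gaussian
    from .datatypes import BANDS, EventTable

    work = _copy.copy(session)
    work.contacts = [c.copy() for c in session.contacts]
    for c in work.contacts:
        if c.contact_id not in kept_ids:
            c.excluded = True
    if cfg.apply_notch:
        work = comb_notch(work, base=cfg.line_freq, bandwidth_hz=cfg.notch_bandwidth_hz)
    work = laplacian_reference(work)
    kept_idx = [i for i, c in enumerate(work.contacts) if c.contact_id in kept_ids]
    sub = _copy.copy(work)
    sub.signals = work.signals[kept_idx]
    sub.contacts = [work.contacts[i] for i in kept_idx]
    band_def = BANDS[band] if isinstance(band, str) else band
    power = band_power(sub, band_def)

    n_trials = len(onsets)
    n_contacts = len(kept_idx)
    raw = np.empty((n_trials, n_contacts, rest_n))
    base = np.empty((n_trials, n_contacts, base_n))
    for t, s0 in enumerate(starts):
        raw[t] = power[:, s0 : s0 + rest_n]
        base[t] = power[:, s0 : s0 + base_n]
    mu = base.mean(axis=2, keepdims=True)
    sd = base.std(axis=2, keepdims=True)
    if np.any(np.isclose(sd[..., 0], 0.0)):
        t, c = np.argwhere(np.isclose(sd[..., 0], 0.0))[0]
        raise ValueError(
            f"constant rest baseline for trial {t}, contact "
            f"{sub.contacts[c].contact_id}"
        )
    z = (raw - mu) / sd
    rest_ep = EpochedPower(
        z_power=z,
        baseline_power=base,
        raw_power=raw,
        labels=np.asarray(["rest"] * n_trials, dtype=object),
        fs=fs,
        contacts=[c.copy() for c in sub.contacts],
        log=["rest_epochs"],
    )
    rest_ep = smooth_gaussian(rest_ep, window_ms=cfg.smooth_ms)

    combined = EpochedPower(
        z_power=np.concatenate([stim_ep.z_power, rest_ep.z_power], axis=0),
        baseline_power=np.concatenate(
            [stim_ep.baseline_power, rest_ep.baseline_power], axis=0
        ),
        raw_power=np.concatenate([stim_ep.raw_power, rest_ep.raw_power], axis=0),
        labels=np.concatenate([stim_ep.labels, rest_ep.labels]),
        fs=fs,
        contacts=[c.copy() for c in stim_ep.contacts],
        log=list(stim_ep.log) + ["rest_epochs_appended"],
    )
    return combined


def run_three_class(
    session: RecordingSession, config: AnalysisConfig | None = None, seed: int = 0
) -> dict:
    """Three-class (rest / own / other) control analysis."""
    cfg = config or AnalysisConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2)]

    ep = build_rest_epochs(
        session, band=cfg.band, config=cfg.preproc, rest_ms=cfg.rest_ms
    )
    fset = bin_features(ep)
    result = loo_decode(
        fset,
        classifier=cfg.classifier,
        k=cfg.k_per_pair,
        selection_mode=cfg.selection_mode,
        n_perm_select=cfg.n_perm_select,
        n_perm_acc=cfg.n_perm_acc,
        alpha=cfg.alpha,
        var_threshold=cfg.var_threshold,
        n_trees=cfg.n_trees,
        seed=seeds[0],
    )
    mc = evaluate_threeclass(result)

    report_sel = select_threeclass_features(
        fset,
        k_per_pair=cfg.k_per_pair,
        alpha=cfg.alpha,
        n_perm=cfg.n_perm_select,
        seed=seeds[1],
    )
    report = {
        "kind": "three_class",
        "seed": int(seed),
        "band": cfg.band,
        "decoding": _decode_report(result),
        "selected_dimension": int(report_sel.n_features),
        "n_significant": int(report_sel.n_significant),
        "confusion_matrix": mc.confusion_matrix.tolist(),
        "classes": mc.classes,
        "sensitivity_pct": {k: float(v) for k, v in mc.sensitivity.items()},
        "precision_pct": {k: float(v) for k, v in mc.precision.items()},
        "auc": {k: float(v["auc"]) for k, v in mc.roc.items()},
        "provenance": {"stages": list(ep.log), "seeds": {"decode": seeds[0]}},
    }
    return report


def save_report(report: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return path
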