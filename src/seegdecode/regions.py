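"""Per-region contribution, cross-modal regions, and stimulus similarity.

Contacts are clustered by their anatomical region labels (free strings,
matched case-insensitively after whitespace normalization).  A region's
contribution is the number of selected features whose provenance traces
to its contacts; single-region decoding re-runs the full selection +
leave-one-out pipeline restricted to the region's contacts.  A region is
cross-modal when its decoding accuracy strictly exceeds the significance
threshold in both the auditory and the visual session.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps
from scipy import stats

from .datatypes import (
    ContactInfo,
    DecodingResult,
    EpochedPower,
    FeatureSet,
    RegionReport,
    normalize_region_label,
)
from .classify import loo_decode
from .features import bin_features


def region_contribution(
    selected: FeatureSet, contacts: list[ContactInfo]
) -> list[RegionReport]:
    """Count selected-feature provenance per region.

    The maximal contributor(s) are flagged; ties are reported jointly.
    Every contact must carry a region label.
    """
    region_of = {}
    region_contacts: dict[str, set] = {}
    display: dict[str, str] = {}
    for c in contacts:
        if not str(c.region_label).strip() or str(c.region_label) == "nan":
            raise ValueError(f"contact {c.contact_id} has no region label")
        key = normalize_region_label(c.region_label)
        region_of[c.contact_id] = key
        display.setdefault(key, " ".join(str(c.region_label).split()))
        region_contacts.setdefault(key, set()).add(c.contact_id)

    counts = {key: 0 for key in region_contacts}
    for cid in selected.contact_ids:
        key = region_of.get(str(cid))
        if key is None:
            raise ValueError(f"selected feature references unlabeled contact {cid!r}")
        counts[key] += 1
    max_count = max(counts.values()) if counts else 0
    reports = [
        RegionReport(
            region_label=display[key],
            n_contacts=len(region_contacts[key]),
            n_features_contributed=counts[key],
            is_max_contributor=(counts[key] == max_count and max_count > 0),
        )
        for key in sorted(counts)
    ]
    return reports


def single_region_accuracy(
    ep: EpochedPower,
    region_label: str,
    classifier: str = "lda",
    k: int = 20,
    selection_mode: str = "per_fold",
    n_perm_select: int = 1000,
    n_perm_acc: int = 1000,
    seed: int = 0,
    **decode_kwargs,
) -> DecodingResult:
    """Decode using only the contacts of one region.

    The same feature extraction and selection procedure is re-run on the
    region's contacts (``k`` capped at the region's feature count).
    """
    key = normalize_region_label(region_label)
    idx = [
        i
        for i, c in enumerate(ep.contacts)
        if normalize_region_label(c.region_label) == key
    ]
    if not idx:
        raise ValueError(f"region {region_label!r} has no kept contacts")
    sub = ep.subset_contacts(idx)
    fset = bin_features(sub)
    return loo_decode(
        fset,
        classifier=classifier,
        k=min(k, fset.n_features),
        selection_mode=selection_mode,
        n_perm_select=n_perm_select,
        n_perm_acc=n_perm_acc,
        seed=seed,
        **decode_kwargs,
    )


def find_cross_modal_regions(
    auditory: dict,
    visual: dict,
    auditory_threshold: float,
    visual_threshold: float,
) -> list[str]:
    """Regions whose accuracy strictly exceeds the threshold in BOTH
    modalities.

    ``auditory`` / ``visual`` map region label -> accuracy (percent).
    The thresholds are the multi-region significance levels of the two
    sessions, applied uniformly to all single regions.  Regions present
    in only one modality are skipped with a warning.
    """
    aud = {normalize_region_label(k): (k, v) for k, v in auditory.items()}
    vis = {normalize_region_label(k): (k, v) for k, v in visual.items()}
    only = set(aud) ^ set(vis)
    for key in sorted(only):
        label = (aud.get(key) or vis.get(key))[0]
        warnings.warn(f"region {label!r} present in only one modality; skipped")
    out = []
    for key in sorted(set(aud) & set(vis)):
        label, acc_a = aud[key]
        _, acc_v = vis[key]
        if acc_a > auditory_threshold and acc_v > visual_threshold:
            out.append(label)
    return out


def cross_modal_contacts(
    region_label: str,
    auditory_selected: FeatureSet,
    visual_selected: FeatureSet,
    contacts: list[ContactInfo],
) -> list[str]:
    """Contacts of a region contributing selected features in BOTH
    modalities."""
    key = normalize_region_label(region_label)
    region_ids = {
        c.contact_id
        for c in contacts
        if normalize_region_label(c.region_label) == key
    }
    aud = set(map(str, auditory_selected.contact_ids)) & region_ids
    vis = set(map(str, visual_selected.contact_ids)) & region_ids
    return sorted(aud & vis)


def cross_modal_contact_proportions(region_to_contacts: dict) -> dict:
    """Proportion of pooled cross-modal contacts per region (percent).

    ``region_to_contacts`` maps region -> list of contact identifiers
    pooled over subjects; each region's count is divided by the pooled
    total.
    """
    totals = {k: len(v) for k, v in region_to_contacts.items()}
    grand = sum(totals.values())
    if grand == 0:
        return {k: 0.0 for k in totals}
    return {k: 100.0 * v / grand for k, v in totals.items()}


def stimulus_similarity(stim_a, stim_b, kind: str) -> float:
    """Normalized zero-lag (zero-shift) cross-correlation of two stimuli.

    Auditory: the Hilbert amplitude envelopes of the two waveforms are
    compared at zero lag.  Visual: the two equal-size images are compared
    at zero shift (2-D cross-correlation central value).  Both inputs are
    mean-centered and the product is divided by the geometric mean of
    their energies, so self-similarity is exactly 1 and the value is
    bounded in [-1, 1].
    """
    a = np.asarray(stim_a, dtype=float)
    b = np.asarray(stim_b, dtype=float)
    if kind == "auditory":
        if a.ndim != 1 or b.ndim != 1:
            raise ValueError("auditory stimuli must be 1-D waveforms")
        n = min(len(a), len(b))
        ea = np.abs(sps.hilbert(a[:n]))
        eb = np.abs(sps.hilbert(b[:n]))
    elif kind == "visual":
        if a.shape != b.shape:
            # zero-pad to a common canvas
            shape = tuple(max(sa, sb) for sa, sb in zip(a.shape, b.shape))
            pa = np.zeros(shape)
            pb = np.zeros(shape)
            pa[tuple(slice(0, s) for s in a.shape)] = a
            pb[tuple(slice(0, s) for s in b.shape)] = b
            a, b = pa, pb
        ea, eb = a.ravel(), b.ravel()
    else:
        raise ValueError(f"unknown stimulus kind {kind!r}")
    ea = ea - ea.mean()
    eb = eb - eb.mean()
    denom = np.sqrt(np.sum(ea**2) * np.sum(eb**2))
    if denom == 0:
        raise ValueError("zero-energy stimulus")
    return float(np.sum(ea * eb) / denom)


def regress_similarity_vs_accuracy(similarities, accuracies):
    """Ordinary least-squares regression of accuracy on similarity.

    Returns ``(slope, r_squared, p_value)``.  Duplicated similarity
    values across regions of one session are permitted (regions of the
    same subject share the same physical stimulus difference); a constant
    similarity vector is an error.
    """
    x = np.asarray(similarities, dtype=float)
    y = np.asarray(accuracies, dtype=float)
    if len(x) != len(y):
        raise ValueError("similarities and accuracies must have the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in similarity values")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)
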