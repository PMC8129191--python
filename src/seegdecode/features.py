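"""Spatiotemporal feature extraction and permutation-test selection.

Each contact's 1,000 ms post-onset z-power trace is averaged within 100
non-overlapping 10-ms bins, giving a per-contact vector v; concatenating
v over contacts (contact-major, bin-minor) yields the trial feature
vector V.  Dimensional reduction correlates each feature with the binary
class labels (Spearman r), builds a surrogate r distribution from label
shuffles, and keeps the k features with the smallest p-values; the
Bonferroni significance level is alpha divided by dim(V).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .datatypes import EpochedPower, FeatureSet

logger = logging.getLogger(__name__)


def bin_features(ep: EpochedPower, bin_ms: float = 10.0) -> FeatureSet:
    """Average z-power in non-overlapping bins; build the V matrix.

    Requires the epoch length to be an exact multiple of the bin length
    (10 ms bins need fs * 0.010 to be an integer sample count).
    """
    samples_per_bin = bin_ms * ep.fs / 1000.0
    if abs(samples_per_bin - round(samples_per_bin)) > 1e-9:
        raise ValueError(f"bin length {bin_ms} ms is not an integer sample count")
    spb = int(round(samples_per_bin))
    n_times = ep.z_power.shape[2]
    if n_times % spb != 0:
        raise ValueError(
            f"epoch length {n_times} samples is not a multiple of the "
            f"{bin_ms} ms bin ({spb} samples)"
        )
    n_bins = n_times // spb
    n_trials, n_contacts = ep.n_trials, ep.n_contacts
    binned = ep.z_power.reshape(n_trials, n_contacts, n_bins, spb).mean(axis=3)
    matrix = binned.reshape(n_trials, n_contacts * n_bins)
    contact_ids = np.repeat([c.contact_id for c in ep.contacts], n_bins)
    bin_index = np.tile(np.arange(n_bins), n_contacts)
    return FeatureSet(
        matrix=matrix,
        contact_ids=contact_ids,
        bin_index=bin_index,
        labels=ep.labels,
        bin_ms=bin_ms,
    )


def _binary_label_vector(labels: np.ndarray) -> np.ndarray:
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    return (labels == classes[1]).astype(float)


def permutation_feature_pvalues(
    matrix: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    method: str = "gaussian",
):
    """Spearman-r label-permutation p-values for every feature column.

    r is the Spearman correlation between a feature's values and the
    binary labels; the null distribution comes from ``n_perm`` label
    shuffles.  ``method='gaussian'`` fits a normal to the surrogate
    r-values and returns the two-sided tail of |r| (this is what allows
    p below 1/n_perm, as the Bonferroni threshold requires);
    ``method='empirical'`` returns the surrogate fraction with
    |r_perm| >= |r|.  Constant features get r = 0, p = 1 by convention.

    Returns ``(r, p)`` arrays, one entry per column.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if method not in ("gaussian", "empirical"):
        raise ValueError(f"unknown p-value method {method!r}")
    rng = rng or np.random.default_rng()
    y = _binary_label_vector(np.asarray(labels, dtype=object))
    n = len(y)

    ranks = stats.rankdata(matrix, axis=0)
    mu = ranks.mean(axis=0)
    sd = ranks.std(axis=0)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    rz = (ranks - mu) / sd_safe  # standardized ranks, columns unit variance

    yr = stats.rankdata(y)
    yz = (yr - yr.mean()) / yr.std()

    r = (yz @ rz) / n
    r[constant] = 0.0
    if np.any(constant):
        logger.info("%d constant feature(s): p set to 1", int(constant.sum()))

    perms = np.empty((n_perm, n))
    for i in range(n_perm):
        perms[i] = yz[rng.permutation(n)]
    surrogate = (perms @ rz) / n  # n_perm x features

    if method == "gaussian":
        smu = surrogate.mean(axis=0)
        ssd = surrogate.std(axis=0)
        ssd = np.where(ssd == 0, np.inf, ssd)
        p = 2.0 * stats.norm.sf(np.abs(r - smu) / ssd)
    else:
        p = np.mean(np.abs(surrogate) >= np.abs(r)[None, :], axis=0)
    p = np.where(constant, 1.0, np.clip(p, 0.0, 1.0))
    return r, p


def spearman_perm_pvalue(
    feature_values,
    labels,
    n_perm: int = 1000,
    seed: int | None = None,
    method: str = "gaussian",
):
    """Single-feature convenience wrapper; returns ``(r, p)``."""
    values = np.asarray(feature_values, dtype=float).reshape(-1, 1)
    rng = np.random.default_rng(seed)
    r, p = permutation_feature_pvalues(values, labels, n_perm=n_perm, rng=rng,
                                       method=method)
    return float(r[0]), float(p[0])


def _rank_order(p: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Order features by p ascending; ties by larger |r|, then by column."""
    return np.lexsort((np.arange(len(p)), -np.abs(r), p))


def select_top_features(
    fset: FeatureSet,
    k: int = 20,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    method: str = "gaussian",
) -> FeatureSet:
    """Keep the k features with the smallest permutation p-values (V20).

    The Bonferroni significance level is ``alpha / dim(V)``;
    ``n_significant`` on the result counts selected features clearing it.
    Always returns exactly k features.
    """
    if k > fset.n_features:
        raise ValueError(f"k={k} exceeds feature count {fset.n_features}")
    rng = rng or np.random.default_rng(seed)
    r, p = permutation_feature_pvalues(
        fset.matrix, fset.labels, n_perm=n_perm, rng=rng, method=method
    )
    order = _rank_order(p, r)
    chosen = order[:k]
    bonf = alpha / fset.n_features
    out = fset.subset_features(
        chosen,
        r_values=r[chosen],
        p_values=p[chosen],
        selected=np.ones(k, dtype=bool),
        n_significant=int(np.sum(p[chosen] < bonf)),
        bonferroni_alpha=bonf,
    )
    return out


THREECLASS_PAIRS = (("rest", "own"), ("rest", "other"), ("own", "other"))


def select_threeclass_features(
    fset: FeatureSet,
    k_per_pair: int = 10,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    method: str = "gaussian",
) -> FeatureSet:
    """Pairwise selection over (rest, own), (rest, other), (own, other).

    Each pairwise permutation test selects ``k_per_pair`` features from
    the trials of those two classes only; the union (duplicates retained
    as distinct slots) gives ``3 * k_per_pair`` features.  Bonferroni
    correction is applied per execution.
    """
    labels = fset.labels
    present = set(labels)
    for pair in THREECLASS_PAIRS:
        for cls in pair:
            if cls not in present:
                raise ValueError(f"class {cls!r} missing from labels")
    rng = rng or np.random.default_rng(seed)
    cols, rs, ps, origins = [], [], [], []
    bonf = alpha / fset.n_features
    n_sig = 0
    for pair in THREECLASS_PAIRS:
        mask = np.isin(labels.astype(str), pair)
        r, p = permutation_feature_pvalues(
            fset.matrix[mask], labels[mask], n_perm=n_perm, rng=rng, method=method
        )
        order = _rank_order(p, r)[:k_per_pair]
        cols.extend(order.tolist())
        rs.extend(r[order].tolist())
        ps.extend(p[order].tolist())
        origins.extend([f"{pair[0]}|{pair[1]}"] * k_per_pair)
        n_sig += int(np.sum(p[order] < bonf))
    cols = np.asarray(cols, dtype=np.int64)
    out = fset.subset_features(
        cols,
        r_values=np.asarray(rs),
        p_values=np.asarray(ps),
        selected=np.ones(len(cols), dtype=bool),
        n_significant=n_sig,
        bonferroni_alpha=bonf,
        pair_origin=np.asarray(origins, dtype=object),
    )
    return out
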