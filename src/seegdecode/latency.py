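"""Response-latency estimation by per-bin permutation tests.

The activation latency of a class at a contact is the start time of the
first 10-ms post-onset bin whose mean power differs significantly from
the per-trial baseline means (a two-sided permutation test on the mean
difference).  The difference latency is the first bin at which the own-
and other-name responses differ.  No multiple-comparison correction is
applied across bins by default (the latency is a first crossing of a
per-bin test); an optional persistence criterion requires several
consecutive significant bins to curb false onsets.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import EpochedPower, FeatureSet, LatencyReport


def _bin_means(traces: np.ndarray, fs: float, bin_ms: float = 10.0) -> np.ndarray:
    """trials x time -> trials x bins (mean within non-overlapping bins)."""
    spb = int(round(bin_ms * fs / 1000.0))
    n_bins = traces.shape[1] // spb
    return traces[:, : n_bins * spb].reshape(traces.shape[0], n_bins, spb).mean(axis=2)


def _welch_stat(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """|Welch t| per column: studentizing keeps the permutation test
    calibrated when the two groups have unequal variances (a 200-ms
    baseline average is far less variable than a 10-ms bin mean)."""
    na, nb = A.shape[0], B.shape[0]
    va = A.var(axis=0, ddof=1) / na
    vb = B.var(axis=0, ddof=1) / nb
    denom = np.sqrt(va + vb)
    denom = np.where(denom == 0, np.inf, denom)
    return np.abs(A.mean(axis=0) - B.mean(axis=0)) / denom


def _perm_twosample_pvalues(
    A: np.ndarray, B: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Two-sided permutation p-values per column for group A vs group B.

    Shuffles group membership with a single permutation set shared
    across columns; the test statistic is the studentized (Welch) mean
    difference.
    """
    na = A.shape[0]
    pooled = np.concatenate([A, B], axis=0)
    n = pooled.shape[0]
    observed = _welch_stat(A, B)
    count = np.zeros(A.shape[1], dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        count += _welch_stat(pooled[perm[:na]], pooled[perm[na:]]) >= observed
    return (count + 1.0) / (n_perm + 1.0)


def _perm_mean_diff_pvalues(
    x: np.ndarray, Y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Permutation p-value of baseline means x vs each bin column of Y."""
    X = np.broadcast_to(x[:, None], (len(x), Y.shape[1]))
    return _perm_twosample_pvalues(X, Y, n_perm, rng)


def _first_significant_bin(
    p: np.ndarray, alpha: float, min_consecutive: int, bin_ms: float
):
    sig = p < alpha
    if min_consecutive <= 1:
        hits = np.flatnonzero(sig)
        return float(hits[0] * bin_ms) if len(hits) else None
    run = 0
    for i, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= min_consecutive:
            return float((i - min_consecutive + 1) * bin_ms)
    return None


def activation_latency(
    ep: EpochedPower,
    class_label: str,
    contact_id: str,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    min_consecutive: int = 1,
    bin_ms: float = 10.0,
):
    """First post-onset bin whose power differs from baseline, in ms.

    x = per-trial mean raw baseline power for trials of ``class_label``;
    for each 10-ms bin, y = per-trial mean raw post-onset power in the
    bin.  Returns the first significant bin's start time, or None when
    no bin is significant.
    """
    mask = ep.labels == class_label
    if not np.any(mask):
        raise ValueError(f"no trials of class {class_label!r}")
    if int(mask.sum()) < 5:
        raise ValueError(f"need >= 5 trials of class {class_label!r}")
    c = ep.contact_index(contact_id)
    rng = rng or np.random.default_rng(seed)
    x = ep.baseline_power[mask, c, :].mean(axis=1)
    Y = _bin_means(ep.raw_power[mask, c, :], ep.fs, bin_ms)
    p = _perm_mean_diff_pvalues(x, Y, n_perm, rng)
    return _first_significant_bin(p, alpha, min_consecutive, bin_ms)


def difference_latency(
    ep: EpochedPower,
    contact_id: str,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    min_consecutive: int = 1,
    bin_ms: float = 10.0,
):
    """First bin at which own- and other-name responses differ, in ms."""
    own = ep.labels == "own"
    other = ep.labels == "other"
    if not np.any(own) or not np.any(other):
        raise ValueError("both own and other trials are required")
    c = ep.contact_index(contact_id)
    rng = rng or np.random.default_rng(seed)
    # z computed from unsmoothed power: smoothing correlates adjacent
    # bins and would blur the onset backwards
    mu = ep.baseline_power[:, c, :].mean(axis=1, keepdims=True)
    sd = ep.baseline_power[:, c, :].std(axis=1, keepdims=True)
    z = (ep.raw_power[:, c, :] - mu) / sd
    A = _bin_means(z[own], ep.fs, bin_ms)
    B = _bin_means(z[other], ep.fs, bin_ms)
    p = _perm_twosample_pvalues(A, B, n_perm, rng)
    return _first_significant_bin(p, alpha, min_consecutive, bin_ms)


def contact_latency_report(
    ep: EpochedPower, contact_id: str, **kwargs
) -> LatencyReport:
    """All three latency types for one contact."""
    return LatencyReport(
        contact_id=contact_id,
        own_vs_rest_ms=activation_latency(ep, "own", contact_id, **kwargs),
        other_vs_rest_ms=activation_latency(ep, "other", contact_id, **kwargs),
        own_vs_other_ms=difference_latency(ep, contact_id, **kwargs),
    )


LATENCY_TYPES = ("own_vs_rest_ms", "other_vs_rest_ms", "own_vs_other_ms")


def region_latency_summary(
    reports: list[LatencyReport],
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict:
    """Mean +- standard error per latency type across contacts, plus
    pairwise permutation tests between latency types.

    Contacts whose latency of a given type is undefined are dropped from
    that type's summary.  With a single defined contact the SE is NaN
    and flagged.
    """
    if not reports:
        raise ValueError("empty region")
    rng = np.random.default_rng(seed)
    out: dict = {"n_contacts": len(reports), "types": {}, "comparisons": {}}
    values = {}
    for t in LATENCY_TYPES:
        vals = np.asarray(
            [getattr(r, t) for r in reports if getattr(r, t) is not None], dtype=float
        )
        values[t] = vals
        entry = {"n": int(len(vals))}
        if len(vals) == 0:
            entry.update({"mean_ms": None, "se_ms": None})
        else:
            entry["mean_ms"] = float(vals.mean())
            entry["se_ms"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else None
            )
            entry["single_contact"] = len(vals) == 1
        out["types"][t] = entry
    for i in range(len(LATENCY_TYPES)):
        for j in range(i + 1, len(LATENCY_TYPES)):
            a, b = values[LATENCY_TYPES[i]], values[LATENCY_TYPES[j]]
            key = f"{LATENCY_TYPES[i]}__vs__{LATENCY_TYPES[j]}"
            if len(a) < 2 or len(b) < 2:
                out["comparisons"][key] = {"p": None}
                continue
            pooled = np.concatenate([a, b])
            obs = abs(a.mean() - b.mean())
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(len(pooled))
                count += (
                    abs(pooled[perm[: len(a)]].mean() - pooled[perm[len(a):]].mean())
                    >= obs
                )
            p = (count + 1.0) / (n_perm + 1.0)
            out["comparisons"][key] = {"p": float(p), "significant": p < alpha}
    return out


def feature_time_distribution(
    selected: FeatureSet, grid_ms: float = 1.0, t_max_ms: float = 1000.0
) -> dict:
    """Probability density of selected-feature generation times.

    Gaussian kernel density (Silverman bandwidth) over the bin-start
    times, truncated to [0, t_max_ms] and renormalized to integrate to
    1.  With fewer than 5 feature times a histogram fallback is used and
    flagged.  Returns grid, density, and the mode location.
    """
    times = np.asarray(selected.bin_start_ms, dtype=float)
    grid = np.arange(0.0, t_max_ms + grid_ms, grid_ms)
    if len(times) < 5 or np.allclose(times, times[0]):
        # degenerate KDE: histogram fallback
        edges = np.arange(0.0, t_max_ms + 10.0, 10.0)
        hist, _ = np.histogram(times, bins=edges, density=True)
        density = hist[np.clip((grid // 10).astype(int), 0, len(hist) - 1)]
        area = np.trapezoid(density, grid)
        if area > 0:
            density = density / area
        mode = float(edges[np.argmax(hist)])
        return {"grid_ms": grid, "density": density, "mode_ms": mode,
                "method": "histogram"}
    kde = stats.gaussian_kde(times, bw_method="silverman")
    density = kde(grid)
    density = density / np.trapezoid(density, grid)
    mode = float(grid[np.argmax(density)])
    return {"grid_ms": grid, "density": density, "mode_ms": mode, "method": "kde"}
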