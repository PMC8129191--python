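"""Leave-one-out decoding and its permutation significance.

Two classifiers are supported: PCA (components covering >90% explained
variance) followed by linear discriminant analysis, and a 200-tree
random forest with sqrt-subsetting of the selected features.  Validation
is leave-one-out: each trial is predicted by a model fitted on all
others; when per-fold selection is enabled the feature selection itself
is re-run on every training fold so the held-out trial never influences
the selected set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc, confusion_matrix, roc_curve

from .datatypes import DecodingResult, FeatureSet, MultiClassReport
from .features import select_threeclass_features, select_top_features


def _n_components_over_90(X: np.ndarray, threshold: float = 0.90) -> int:
    """Smallest component count with cumulative explained variance > threshold."""
    pca = PCA()
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    return int(np.searchsorted(cum, threshold, side="right")) + 1


def _fit_predict_lda(Xtr, ytr, Xte, classes, threshold=0.90):
    n_comp = min(_n_components_over_90(Xtr, threshold), Xtr.shape[0] - 1, Xtr.shape[1])
    pca = PCA(n_components=n_comp)
    Ztr = pca.fit_transform(Xtr)
    Zte = pca.transform(Xte)
    lda = LinearDiscriminantAnalysis(solver="svd")
    lda.fit(Ztr, ytr)
    proba = lda.predict_proba(Zte)
    # align score columns to the global class order
    scores = np.zeros((Xte.shape[0], len(classes)))
    for j, cls in enumerate(lda.classes_):
        scores[:, classes.index(cls)] = proba[:, j]
    pred = lda.predict(Zte)
    return pred, scores, n_comp


def _fit_predict_rf(Xtr, ytr, Xte, classes, n_trees, seed):
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed
    )
    rf.fit(Xtr, ytr)
    proba = rf.predict_proba(Xte)  # vote fractions
    scores = np.zeros((Xte.shape[0], len(classes)))
    for j, cls in enumerate(rf.classes_):
        scores[:, classes.index(cls)] = proba[:, j]
    pred = rf.predict(Xte)
    return pred, scores, None


def loo_decode(
    fset: FeatureSet,
    classifier: str = "lda",
    k: int = 20,
    selection_mode: str = "per_fold",
    n_perm_select: int = 1000,
    n_perm_acc: int = 1000,
    alpha: float = 0.05,
    var_threshold: float = 0.90,
    n_trees: int = 200,
    seed: int = 0,
) -> DecodingResult:
    """Leave-one-out decoding of an (unselected) feature set.

    ``selection_mode='per_fold'`` re-runs the permutation-test selection
    on each training fold (no test-set leakage); ``'one_shot'`` selects
    once on all trials before the loop (reporting mode only);
    ``'none'`` uses the columns as given (the set is assumed already
    selected).  With two classes the selector keeps ``k`` features; with
    three classes it keeps ``k`` per pairwise test (3k total).
    """
    if classifier not in ("lda", "random_forest"):
        raise ValueError(f"unknown classifier {classifier!r}")
    if selection_mode not in ("per_fold", "one_shot", "none"):
        raise ValueError(f"unknown selection mode {selection_mode!r}")
    labels = np.asarray(fset.labels, dtype=object)
    classes = sorted(set(labels))
    counts = {c: int(np.sum(labels == c)) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"need >= 2 trials per class, got {counts}")
    n = fset.n_trials
    three_class = len(classes) > 2

    ss = np.random.SeedSequence(seed)
    sel_rng = np.random.default_rng(ss.spawn(1)[0])
    rf_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(0, 2**31 - 1))

    def _select(sub: FeatureSet) -> np.ndarray:
        if three_class:
            sel = select_threeclass_features(
                sub, k_per_pair=k, alpha=alpha, n_perm=n_perm_select, rng=sel_rng
            )
        else:
            sel = select_top_features(
                sub, k=k, alpha=alpha, n_perm=n_perm_select, rng=sel_rng
            )
        return sel

    if selection_mode == "one_shot":
        fset = _select(fset)

    y_pred = np.empty(n, dtype=object)
    scores = np.zeros((n, len(classes)))
    n_components_used: list[int] = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        tr_labels = labels[train]
        if any(np.sum(tr_labels == c) == 0 for c in classes):
            raise ValueError(f"class absent from the training fold of trial {i}")
        if selection_mode == "per_fold":
            sub = fset.subset_trials(np.flatnonzero(train))
            sel = _select(sub)
            Xtr = sel.matrix
            cols = _match_columns(fset, sel)
            Xte = fset.matrix[i : i + 1, cols]
        else:
            Xtr = fset.matrix[train]
            Xte = fset.matrix[i : i + 1]
        if classifier == "lda":
            pred, sc, n_comp = _fit_predict_lda(
                Xtr, tr_labels, Xte, classes, var_threshold
            )
            n_components_used.append(n_comp)
        else:
            pred, sc, _ = _fit_predict_rf(Xtr, tr_labels, Xte, classes, n_trees, rf_seed)
        y_pred[i] = pred[0]
        scores[i] = sc[0]

    accuracy = 100.0 * float(np.mean(y_pred == labels))
    result = DecodingResult(
        y_true=labels,
        y_pred=y_pred,
        classes=classes,
        scores=scores,
        accuracy=accuracy,
        classifier=classifier,
        n_components_used=n_components_used or None,
    )
    thr_rng = np.random.default_rng(ss.spawn(1)[0])
    threshold, p = accuracy_significance(y_pred, labels, n_perm=n_perm_acc, rng=thr_rng)
    result.significance_threshold = threshold
    result.permutation_p = p
    return result


def _match_columns(full: FeatureSet, sel: FeatureSet) -> np.ndarray:
    """Column indices in ``full`` matching the provenance of ``sel``."""
    key = {
        (cid, int(b)): i
        for i, (cid, b) in enumerate(zip(full.contact_ids, full.bin_index))
    }
    return np.asarray(
        [key[(cid, int(b))] for cid, b in zip(sel.contact_ids, sel.bin_index)],
        dtype=np.int64,
    )


def accuracy_significance(
    y_pred,
    y_true,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Permutation significance of a decoding accuracy.

    The classifier's output labels are kept fixed while the actual
    labels are shuffled (label permutation, so class counts are
    preserved); the threshold is the 95th percentile of the resulting
    accuracy distribution (in percent) and p is the fraction of permuted
    accuracies >= the observed accuracy.
    """
    y_pred = np.asarray(y_pred, dtype=object)
    y_true = np.asarray(y_true, dtype=object)
    if len(y_pred) != len(y_true):
        raise ValueError("label vectors must have the same length")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = rng or np.random.default_rng(seed)
    n = len(y_true)
    observed = float(np.mean(y_pred == y_true))
    perm_acc = np.empty(n_perm)
    for i in range(n_perm):
        perm_acc[i] = np.mean(y_pred == y_true[rng.permutation(n)])
    threshold = 100.0 * float(np.percentile(perm_acc, 95))
    p = float(np.mean(perm_acc >= observed))
    return threshold, p


def evaluate_threeclass(result: DecodingResult) -> MultiClassReport:
    """Confusion matrix, per-class sensitivity/precision, and ROC.

    sensitivity = 100 * TP / (TP + FN); precision = 100 * TP / (TP + FP);
    the per-class accuracy equals the sensitivity.  ROC is one-vs-rest
    from the per-class scores, with AUC by the trapezoid rule.
    """
    if result.scores is None:
        raise ValueError("per-class scores are required for the three-class report")
    classes = result.classes
    cm = confusion_matrix(result.y_true, result.y_pred, labels=classes)
    sens, prec, roc = {}, {}, {}
    for j, cls in enumerate(classes):
        tp = cm[j, j]
        fn = cm[j].sum() - tp
        fp = cm[:, j].sum() - tp
        sens[cls] = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
        prec[cls] = 100.0 * tp / (tp + fp) if (tp + fp) else float("nan")
        fpr, tpr, _ = roc_curve(result.y_true == cls, result.scores[:, j])
        roc[cls] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}
    return MultiClassReport(
        classes=list(classes),
        confusion_matrix=cm,
        sensitivity=sens,
        precision=prec,
        roc=roc,
    )


def compare_bands(table: pd.DataFrame) -> pd.DataFrame:
    """Two-factor fixed-effects ANOVA of accuracy over band x classifier.

    ``table`` needs columns ``band``, ``classifier``, ``accuracy`` with a
    balanced design (equal cell counts).  Convenience reporting only.
    Returns a DataFrame with sum-of-squares, df, F and p per factor.
    """
    for col in ("band", "classifier", "accuracy"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    cell_sizes = table.groupby(["band", "classifier"]).size()
    if cell_sizes.nunique() != 1:
        raise ValueError("unbalanced design: equal cell counts are assumed")

    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    y = table["accuracy"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        rows = []
        for factor in ("band", "classifier"):
            df_f = table[factor].nunique() - 1
            rows.append({"factor": factor, "sum_sq": 0.0, "df": df_f, "F": 0.0, "p": 1.0})
        return pd.DataFrame(rows)

    import warnings

    with warnings.catch_warnings():
        # degenerate (zero-residual) designs trip divide-by-zero inside
        # the F computation; they are rejected explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", sm.tools.sm_exceptions.ValueWarning)
        model = ols("accuracy ~ C(band) + C(classifier)", data=table).fit()
        anova = sm.stats.anova_lm(model, typ=2)
    resid_ss = float(anova.loc["Residual", "sum_sq"])
    resid_df = float(anova.loc["Residual", "df"])
    if resid_df <= 0 or resid_ss < 1e-10 * float(np.var(y) * len(y) + 1e-300):
        raise ValueError(
            "degenerate design: (near-)zero residual variance / residual df; "
            "F ratios are undefined"
        )
    rows = []
    for name, factor in (("C(band)", "band"), ("C(classifier)", "classifier")):
        rows.append(
            {
                "factor": factor,
                "sum_sq": float(anova.loc[name, "sum_sq"]),
                "df": float(anova.loc[name, "df"]),
                "F": float(anova.loc[name, "F"]),
                "p": float(anova.loc[name, "PR(>F)"]),
            }
        )
    return pd.DataFrame(rows)
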