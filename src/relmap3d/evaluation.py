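"""Classification metrics, Youden-threshold selection, and validity checks.

Covers the evaluation protocol around the CNN: ROC/AUC and balanced accuracy,
the Youden-index operating point, the hippocampus-volume baseline classifier
(Youden threshold fitted on training residuals, lower residual volume meaning
higher disease risk), and the Pearson correlation between region relevance
sums and residualized hippocampus volume that validates the relevance maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import balanced_accuracy_score as _sk_balanced_accuracy
from sklearn.metrics import roc_auc_score

from .analysis import region_relevance_sum
from .lrp import compute_relevance_map


@dataclass
class ROCResult:
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    n_pos: int
    n_neg: int

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _check_two_class(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney: P(score_pos > score_neg), ties 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _check_two_class(labels)
    return float(roc_auc_score(labels, scores))


def balanced_accuracy(predictions, labels) -> float:
    """(sensitivity + specificity) / 2 for binary predictions."""
    predictions = np.asarray(predictions, int)
    labels = np.asarray(labels, int)
    _check_two_class(labels)
    return float(_sk_balanced_accuracy(labels, predictions))


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y)[0])


def youden_threshold(scores, labels) -> ROCResult:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints of adjacent sorted unique scores; a
    subject is classified positive when score >= threshold; ties on J resolve
    to the lowest threshold.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _check_two_class(labels)
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("need at least two distinct scores to place a threshold")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    pos, neg = labels == 1, labels == 0
    best = None
    for t in candidates:  # ascending, so the first maximizer is the lowest threshold
        pred = scores >= t
        sens = float(pred[pos].mean())
        spec = float((~pred[neg]).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    j, t, sens, spec = best
    return ROCResult(
        auc=roc_auc(scores, labels),
        threshold=float(t),
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        n_pos=int(pos.sum()),
        n_neg=int(neg.sum()),
    )


def volumetric_baseline(
    train_volumes_ml,
    train_labels,
    test_volumes_ml,
    test_labels,
) -> ROCResult:
    """Hippocampus-volume classifier: train-derived Youden threshold on test data.

    Inputs are *residualized* volumes (covariate-corrected, via
    ``io_preproc.residualize_scalar``). Lower residual volume means more
    atrophy, so scores are sign-flipped volumes. The threshold is fitted on
    the training residuals and applied unchanged to the test set.
    """
    train_scores = -np.asarray(train_volumes_ml, float)
    test_scores = -np.asarray(test_volumes_ml, float)
    test_labels = np.asarray(test_labels, int)
    fit = youden_threshold(train_scores, train_labels)
    pred = test_scores >= fit.threshold
    pos, neg = test_labels == 1, test_labels == 0
    _check_two_class(test_labels)
    sens = float(pred[pos].mean())
    spec = float((~pred[neg]).mean())
    return ROCResult(
        auc=roc_auc(test_scores, test_labels),
        threshold=fit.threshold,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        n_pos=int(pos.sum()),
        n_neg=int(neg.sum()),
    )


def relevance_volume_report(
    models,
    volumes,
    records,
    atlas,
    hippocampus_residuals,
    target_class: int = 1,
    lrp_config=None,
) -> pd.DataFrame:
    """Correlate per-region relevance sums with residualized hippocampus volume.

    ``volumes`` are the (residualized) inputs fed to the models. For every
    model and every atlas region (plus the whole brain), the Pearson r between
    the subjects' region relevance totals and their residualized hippocampus
    volumes is reported, along with the median across models.
    """
    if not models:
        raise ValueError("need at least one trained model")
    hippo = np.asarray(hippocampus_residuals, float)
    regions = list(atlas.region_names.values())
    rows = []
    for m, model in enumerate(models):
        sums = {name: [] for name in regions}
        sums["whole_brain"] = []
        for vol in volumes:
            rmap = compute_relevance_map(model, vol, target_class, lrp_config)
            for name in regions:
                sums[name].append(region_relevance_sum(rmap, atlas.mask(name)))
            sums["whole_brain"].append(float(rmap.values.sum()))
        for name, values in sums.items():
            rows.append(
                {
                    "model": m,
                    "region": name,
                    "r": pearson_r(values, hippo),
                    "n": len(values),
                }
            )
    df = pd.DataFrame(rows)
    median = (
        df.groupby("region")["r"].median().rename("r").reset_index().assign(model="median")
    )
    return pd.concat([df, median[["model", "region", "r"]]], ignore_index=True)
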