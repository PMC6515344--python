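"""Circular-to-linear score, ROC discrimination and clinical correlations.

The score compresses the significantly modulated circular fractions of
a sample into one number: the mean, over those features, of the
sample's log2 fold change relative to the control-group mean of the
feature. Controls therefore average to a score of zero, and higher
scores indicate stronger circRNA dysregulation. Discrimination between
cases and controls is summarized by the ROC curve and its area (the
Mann-Whitney pair-ordering probability); clinical relevance by Pearson
correlation with muscle strength (MRC megascore), splicing covariates,
and a comparison across disease stages (MIRS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from circlin.stats import group_test

logger = logging.getLogger(__name__)


@dataclass
class ScoreVector:
    """Per-sample circular-to-linear score over a fixed feature set."""

    scores: pd.Series
    feature_set: list[str]
    reference_group_stats: pd.Series  # per-feature control-group mean (log2)
    n_features_used: pd.Series = field(default=None)


@dataclass
class RocCurve:
    """ROC curve of a score against the case/control labels.

    ``thresholds`` ascend; a sample is called positive when its score
    is >= the threshold, so sensitivity is non-increasing along the
    list (starting from (sens, spec) = (1, 0) at -inf). ``auc`` is the
    probability that a random case outscores a random control, ties
    counting half.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    positive_label: str = "case"
    n_pos: int = 0
    n_neg: int = 0


def circ_lin_score(
    log2_matrix: pd.DataFrame,
    significant_features: list[str],
    metadata: pd.DataFrame,
) -> ScoreVector:
    """Average per-sample log2 fold changes over the significant features.

    ``log2_matrix`` holds log2-scale values (log2 circular fractions or
    log2 relative expression), features x samples. Each feature is
    centered on its control-group mean; a sample's score is the mean of
    its available centered values over ``significant_features``.
    Missing features are skipped per sample, with the number actually
    used recorded. An empty significant set admits no score.
    """
    feats = [f for f in significant_features if f in log2_matrix.index]
    if not significant_features:
        raise ValueError("no score definable: empty significant feature set")
    if not feats:
        raise ValueError("no score definable: no significant feature present in the matrix")
    groups = metadata.set_index("sample_id")["group"]
    ctrl_cols = [s for s in log2_matrix.columns if groups.get(s) == "control"]
    if not ctrl_cols:
        raise ValueError("no control samples to define the fold-change reference")
    sub = log2_matrix.loc[feats]
    ctrl_means = sub[ctrl_cols].mean(axis=1)
    centered = sub.sub(ctrl_means, axis=0)
    scores = centered.mean(axis=0, skipna=True)
    n_used = centered.notna().sum(axis=0)
    scores = scores[n_used > 0]
    return ScoreVector(
        scores=scores,
        feature_set=feats,
        reference_group_stats=ctrl_means,
        n_features_used=n_used,
    )


def roc_auc(
    scores: pd.Series,
    metadata: pd.DataFrame,
    positive_label: str = "case",
) -> RocCurve:
    """ROC curve and AUC of a per-sample score.

    The AUC is computed as the Mann-Whitney statistic
    ``(#{case > control} + 0.5 * #ties) / (n_case * n_control)`` via
    rank sums; curve points are generated at every distinct score.
    """
    groups = metadata.set_index("sample_id")["group"]
    labels = scores.index.map(lambda s: groups.get(s))
    pos = scores[labels == positive_label].to_numpy(dtype=float)
    neg = scores[(labels != positive_label) & pd.notna(labels)].to_numpy(dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC needs both classes present")

    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    auc = float(u / (len(pos) * len(neg)))

    thresholds = np.concatenate([[-np.inf], np.unique(np.concatenate([pos, neg]))])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        positive_label=positive_label,
        n_pos=len(pos),
        n_neg=len(neg),
    )


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the conventional two-sided t test.

    p comes from t = r * sqrt((n-2)/(1-r**2)) on n-2 degrees of
    freedom; |r| = 1 gives p = 0 by convention. Zero variance in
    either vector leaves r undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("pearson_with_p needs n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    p = 0.0 if abs(r) >= 1.0 - 1e-12 else float(res.pvalue)
    return r, p


def mirs_group_compare(scores: pd.Series, metadata: pd.DataFrame) -> dict:
    """Compare scores of mildly vs severely staged cases.

    Cases are split by MIRS stage into a low stratum (stages 1-3) and
    a high stratum (stages 4-5); controls and cases without a stage are
    excluded (logged). A two-tailed two-sample t-test compares the two
    strata, identical degenerate strata giving p = 1.
    """
    meta = metadata.set_index("sample_id")
    cases = [s for s in scores.index if meta["group"].get(s) == "case"]
    stages = pd.to_numeric(meta["mirs_stage"].reindex(cases), errors="coerce")
    n_missing = int(stages.isna().sum())
    if n_missing:
        logger.info("mirs_group_compare: excluded %d case(s) with missing MIRS stage", n_missing)
    low = scores[[s for s in cases if stages.get(s) in (1, 2, 3)]]
    high = scores[[s for s in cases if stages.get(s) in (4, 5)]]
    if len(low) < 2 or len(high) < 2:
        raise ValueError("each MIRS stratum needs >= 2 staged cases")
    res = group_test(high, low, test_policy="t")
    return {
        "p_value": res.p_value,
        "mean_low": float(low.mean()),
        "mean_high": float(high.mean()),
        "n_low": len(low),
        "n_high": len(high),
    }


def exon_exclusion_percent(splicing: pd.DataFrame) -> pd.DataFrame:
    """Percentage of exon exclusion from gel band intensity pairs.

    ``100 * excl / (incl + excl)`` per record; both-zero intensity
    pairs yield a missing percentage. Events assayed as inclusion
    events (direction "inclusion") still report percent *exclusion*,
    so every splicing covariate shares one axis; the direction label
    is preserved. Records carrying a percentage but no intensities
    keep their stated value.
    """
    out = splicing.copy()
    incl = out["incl_intensity"].astype(float)
    excl = out["excl_intensity"].astype(float)
    total = incl + excl
    have_bands = incl.notna() & excl.notna()
    computable = have_bands & (total > 0)
    pct = pd.Series(np.nan, index=out.index)
    pct[computable] = 100.0 * excl[computable] / total[computable]
    keep_stated = ~have_bands & out["percent"].notna()
    pct[keep_stated] = out.loc[keep_stated, "percent"]
    out["percent"] = pct
    return out


def correlate_with_covariates(
    values: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation of each feature against each covariate.

    ``values`` is features x samples (a score occupies one row);
    ``covariates`` is samples x covariates. Pairs with a missing value
    are dropped per (feature, covariate) cell; cells with fewer than 3
    complete pairs or a constant vector are flagged rather than
    computed.
    """
    rows = []
    for fid, frow in values.iterrows():
        for cov in covariates.columns:
            joined = pd.concat([frow, covariates[cov]], axis=1, join="inner").dropna()
            n = len(joined)
            if n < 3:
                rows.append({"feature_id": fid, "covariate": cov, "r": np.nan,
                             "p_value": np.nan, "n": n, "flag": "insufficient"})
                continue
            x = joined.iloc[:, 0].to_numpy(float)
            y = joined.iloc[:, 1].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                rows.append({"feature_id": fid, "covariate": cov, "r": np.nan,
                             "p_value": np.nan, "n": n, "flag": "undefined"})
                continue
            r, p = pearson_with_p(x, y)
            rows.append({"feature_id": fid, "covariate": cov, "r": r,
                         "p_value": p, "n": n, "flag": "ok"})
    return pd.DataFrame(rows, columns=["feature_id", "covariate", "r", "p_value", "n", "flag"])
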