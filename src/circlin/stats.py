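"""qPCR quantification and two-group differential testing.

Implements the comparative-Ct machinery (primer efficiency from
dilution series, 2**-ddCt relative expression against averaged
reference genes, and the Ct-difference circular fraction), the
normality-gated two-group test, and the adaptive two-stage
Benjamini-Krieger-Yekutieli (BKY) false-discovery-rate procedure.

All fold changes are computed on the log2 scale as differences of
group means, since dCt data are natively log2: one qPCR cycle is one
doubling of template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny

#: minimum group size for the D'Agostino-Pearson omnibus test; the
#: kurtosis component is undefined below this, so smaller groups fall
#: back to the rank test.
NORMALITY_MIN_N = 8


@dataclass
class TestResult:
    """Outcome of one feature's two-group comparison."""

    feature_id: str
    test_used: str  # "t" or "mann_whitney"
    p_value: float
    log2_fc_group: float
    normality_p_case: float = np.nan
    normality_p_control: float = np.nan
    q_flag: bool = False
    n_case: int = 0
    n_control: int = 0


# ---------------------------------------------------------------------------
# primer efficiency
# ---------------------------------------------------------------------------

def primer_efficiency(dilution_log10: list[float], ct: list[float]) -> dict:
    """Amplification efficiency from a qPCR dilution series.

    Fits Ct against log10(relative template amount) by least squares;
    the amplification factor per cycle is ``10**(-1/slope)``, so a
    slope of -3.3219 (= -1/log10(2)) means perfect doubling
    (efficiency 2.0). Returns the efficiency, slope, R**2 and a
    validity flag; a non-negative slope (Ct not decreasing with more
    template) is flagged invalid.
    """
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("primer_efficiency needs >= 3 paired dilution points")
    res = sps.linregress(x, y)
    slope = res.slope
    if slope >= 0:
        return {"efficiency": np.nan, "slope": slope, "r_squared": res.rvalue**2,
                "valid": False}
    return {
        "efficiency": 10.0 ** (-1.0 / slope),
        "slope": slope,
        "r_squared": res.rvalue**2,
        "valid": True,
    }


# ---------------------------------------------------------------------------
# comparative Ct
# ---------------------------------------------------------------------------

def _mean_ct(ct: pd.DataFrame) -> pd.DataFrame:
    """Average replicate Cts -> one row per (target, isoform, sample)."""
    return (
        ct.groupby(["target_id", "isoform", "sample_id"], as_index=False)["ct"].mean()
    )


def relative_expression(
    ct: pd.DataFrame,
    targets: list[str],
    reference_ids: list[str],
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """2**-ddCt relative expression against averaged reference genes.

    Per sample, dCt = Ct_target - mean(reference Cts); ddCt subtracts
    the control-group mean dCt of that target, so the control group
    averages to relative expression 1. Replicates are averaged
    (arithmetically, on the Ct scale) first. A sample missing any
    reference gene is excluded for all targets, with a log line.

    Returns long records ``target_id, sample_id, delta_ct, rel_expr,
    log2_fc``.
    """
    if not reference_ids:
        raise ValueError("at least one reference gene required")
    flat = _mean_ct(ct)
    refs = flat[flat["target_id"].isin(reference_ids) & (flat["isoform"] == "reference")]
    ref_mean = refs.groupby("sample_id")["ct"].agg(["mean", "size"])
    complete = ref_mean[ref_mean["size"] == len(reference_ids)]["mean"]
    dropped = sorted(set(flat["sample_id"]) - set(complete.index))
    if dropped:
        logger.info("relative_expression: excluded %d sample(s) with missing reference Cts: %s",
                    len(dropped), dropped)

    groups = metadata.set_index("sample_id")["group"]
    out = []
    tgt = flat[flat["target_id"].isin(targets) & (flat["isoform"] != "reference")]
    for (target, isoform), sub in tgt.groupby(["target_id", "isoform"]):
        sub = sub[sub["sample_id"].isin(complete.index)]
        if sub.empty:
            continue
        dct = sub.set_index("sample_id")["ct"] - complete
        ctrl = dct[[s for s in dct.index if groups.get(s) == "control"]]
        if ctrl.empty:
            raise ValueError(f"no control samples with Ct for target {target!r}")
        ddct = dct - ctrl.mean()
        for sid, value in ddct.items():
            out.append(
                {
                    "target_id": target,
                    "isoform": isoform,
                    "sample_id": sid,
                    "delta_ct": dct[sid],
                    "rel_expr": 2.0 ** (-value),
                    "log2_fc": -value,
                }
            )
    return pd.DataFrame(out, columns=["target_id", "isoform", "sample_id",
                                      "delta_ct", "rel_expr", "log2_fc"])


def circ_fraction(ct: pd.DataFrame, circ_linear_pairs: list[str] | None = None) -> pd.DataFrame:
    """Circular fraction of a gene from raw Cts of its two isoforms.

    dCt = Ct_circular - Ct_linear; the circular-to-linear ratio on the
    log2 scale is ``-dCt`` (one cycle of difference = a factor of two,
    assuming efficiency 2 for both primer pairs). No reference-gene
    normalization is involved: the linear isoform is the internal
    reference. Samples missing either isoform yield no record.

    Returns long records ``target_id, sample_id, dct, log2_fraction``.
    """
    flat = _mean_ct(ct)
    wide = flat.pivot_table(index=["target_id", "sample_id"], columns="isoform", values="ct")
    if "circular" not in wide.columns or "linear" not in wide.columns:
        wide = wide.reindex(columns=["circular", "linear"])
    wide = wide.dropna(subset=["circular", "linear"]).reset_index()
    if circ_linear_pairs is not None:
        wide = wide[wide["target_id"].isin(circ_linear_pairs)]
    dct = wide["circular"] - wide["linear"]
    return pd.DataFrame(
        {
            "target_id": wide["target_id"],
            "sample_id": wide["sample_id"],
            "dct": dct,
            "log2_fraction": -dct,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# two-group testing
# ---------------------------------------------------------------------------

def _mannwhitney_p(case: np.ndarray, control: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact for small tie-free samples,
    otherwise the tie-corrected normal approximation (no continuity
    correction, so identical samples give p = 1 exactly)."""
    pooled = np.concatenate([case, control])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and max(len(case), len(control)) <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(case, control, alternative="two-sided",
                           method=method, use_continuity=False)
    return float(res.pvalue)


def group_test(
    values_case,
    values_control,
    normality_alpha: float = 0.05,
    test_policy: str = "auto",
    equal_var: bool = True,
    feature_id: str = "",
) -> TestResult:
    """Two-group comparison with a normality-gated choice of test.

    ``auto`` policy: when both groups have at least 8 observations and
    both pass the D'Agostino-Pearson omnibus normality test
    (p > ``normality_alpha``), a two-tailed two-sample Student t-test
    is used (Welch via ``equal_var=False``); otherwise a two-tailed
    Mann-Whitney test. Groups too small for the normality test fall
    back to Mann-Whitney. The group fold change is the difference of
    group means, which is a log2 fold change when inputs are log2
    scale (dCt-derived values are).
    """
    case = np.asarray(values_case, dtype=float)
    control = np.asarray(values_control, dtype=float)
    if len(case) < 2 or len(control) < 2:
        raise ValueError("each group needs >= 2 values")
    if test_policy not in ("auto", "t", "mann_whitney"):
        raise ValueError(f"unknown test policy {test_policy!r}")

    log2_fc = float(case.mean() - control.mean())
    norm_p_case = norm_p_ctrl = np.nan

    degenerate = case.std() == 0 and control.std() == 0 and case.mean() == control.mean()

    if test_policy == "auto":
        if min(len(case), len(control)) >= NORMALITY_MIN_N:
            norm_p_case = float(sps.normaltest(case).pvalue) if case.std() > 0 else 0.0
            norm_p_ctrl = float(sps.normaltest(control).pvalue) if control.std() > 0 else 0.0
            use_t = norm_p_case > normality_alpha and norm_p_ctrl > normality_alpha
        else:
            use_t = False
        test_used = "t" if use_t else "mann_whitney"
    else:
        test_used = test_policy

    if degenerate:
        p = 1.0
    elif test_used == "t":
        p = float(sps.ttest_ind(case, control, equal_var=equal_var).pvalue)
    else:
        p = _mannwhitney_p(case, control)
    p = float(np.clip(p, _TINY, 1.0))

    return TestResult(
        feature_id=feature_id,
        test_used=test_used,
        p_value=p,
        log2_fc_group=log2_fc,
        normality_p_case=norm_p_case,
        normality_p_control=norm_p_ctrl,
        n_case=len(case),
        n_control=len(control),
    )


# ---------------------------------------------------------------------------
# two-stage FDR
# ---------------------------------------------------------------------------

def _bh_reject(p: np.ndarray, level: float) -> np.ndarray:
    """Benjamini-Hochberg linear step-up rejection flags at ``level``."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    crit = level * np.arange(1, m + 1) / m
    below = sorted_p <= crit
    flags = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        flags[order[: k + 1]] = True
    return flags


def tsbky_fdr(p_values, q: float = 0.01) -> tuple[np.ndarray, float]:
    """Two-stage Benjamini-Krieger-Yekutieli adaptive FDR procedure.

    Stage 1 runs Benjamini-Hochberg at q' = q/(1+q); its rejection
    count r1 estimates the number of true nulls as m0 = m - r1. With
    r1 = 0 nothing is rejected; with m0 = 0 everything is. Otherwise
    stage 2 reruns the linear step-up at level q' * m/m0. Returns the
    boolean rejection flags and the largest rejected p-value (NaN when
    none).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.nan
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    q_prime = q / (1.0 + q)
    stage1 = _bh_reject(p, q_prime)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool), np.nan
    if r1 == m:
        return np.ones(m, dtype=bool), float(p.max())
    m0 = m - r1
    flags = _bh_reject(p, q_prime * m / m0)
    thresh = float(p[flags].max()) if flags.any() else np.nan
    return flags, thresh


# ---------------------------------------------------------------------------
# per-feature differential analysis
# ---------------------------------------------------------------------------

def differential_analysis(
    feature_matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    q: float = 0.01,
    test_policy: str = "auto",
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group test per feature followed by two-stage FDR across features.

    ``feature_matrix`` holds log2-scale values (features x samples);
    group labels come from the metadata. Features are each tested with
    `group_test`, the family of p-values is corrected with
    `tsbky_fdr` at FDR level ``q``, and the table is returned sorted
    by p-value.
    """
    groups = metadata.set_index("sample_id")["group"]
    case_cols = [s for s in feature_matrix.columns if groups.get(s) == "case"]
    ctrl_cols = [s for s in feature_matrix.columns if groups.get(s) == "control"]

    results: list[TestResult] = []
    for fid, row in feature_matrix.iterrows():
        case = row[case_cols].dropna()
        ctrl = row[ctrl_cols].dropna()
        results.append(
            group_test(case, ctrl, normality_alpha=normality_alpha,
                       test_policy=test_policy, feature_id=str(fid))
        )

    df = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "test_used": [r.test_used for r in results],
            "p_value": [r.p_value for r in results],
            "log2_fc": [r.log2_fc_group for r in results],
            "normality_p_case": [r.normality_p_case for r in results],
            "normality_p_control": [r.normality_p_control for r in results],
            "n_case": [r.n_case for r in results],
            "n_control": [r.n_control for r in results],
        }
    )
    flags, _ = tsbky_fdr(df["p_value"].to_numpy(), q=q)
    df["q_flag"] = flags
    return df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
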