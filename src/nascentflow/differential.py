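"""Differential-labeling calls between two conditions on RPMu values.

Significance follows the fixed thresholds p < alpha and |log2FC| >= lfc
(defaults 0.05 and 1).  The default test is Welch's t on log2(rpmu +
pseudocount) per replicate; "student" forces equal variances; "nb" fits a
negative-binomial GLM on raw tcReadCount with non-TC library sums as
exposure, as a documented alternative reading of the upstream pipeline.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from nascentflow.errors import ConfigurationError, DegenerateDataError

ALPHA_DEFAULT = 0.05
LFC_DEFAULT = 1.0


def _condition_samples(design: pd.DataFrame, condition: str) -> list[str]:
    samples = design.loc[design["condition"] == condition, "sample"].tolist()
    if len(samples) < 2:
        raise ConfigurationError(
            f"condition {condition!r} has {len(samples)} replicates; >= 2 required"
        )
    return samples


def _pivot(counts: pd.DataFrame, value: str) -> pd.DataFrame:
    return counts.pivot_table(index="gene_id", columns="sample", values=value, sort=True)


def differential_labeling(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    control: str,
    treated: str,
    pseudocount: float = 1.0,
    test_method: str = "welch",
    alpha: float = ALPHA_DEFAULT,
    lfc: float = LFC_DEFAULT,
    bh: bool = False,
) -> pd.DataFrame:
    """Call differentially labeled transcripts.

    `counts` is the long-format count table with an `rpmu` column; `design`
    maps sample -> condition.  Returns a frame indexed by transcript with
    log2FC, p_value, significant, direction.
    """
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be >= 0")
    if test_method not in {"welch", "student", "nb"}:
        raise ConfigurationError(f"unknown test_method {test_method!r}")
    ctrl_samples = _condition_samples(design, control)
    trt_samples = _condition_samples(design, treated)

    rpmu = _pivot(counts, "rpmu")
    missing = [s for s in ctrl_samples + trt_samples if s not in rpmu.columns]
    if missing:
        raise ConfigurationError(f"design samples absent from counts: {missing}")
    ctrl = rpmu[ctrl_samples].to_numpy(float)
    trt = rpmu[trt_samples].to_numpy(float)

    log2fc = np.log2(trt.mean(axis=1) + pseudocount) - np.log2(ctrl.mean(axis=1) + pseudocount)

    if test_method == "nb":
        p = _nb_pvalues(counts, ctrl_samples, trt_samples, rpmu.index)
    else:
        if pseudocount <= 0 and ((ctrl <= 0).any() or (trt <= 0).any()):
            raise ConfigurationError("pseudocount must be > 0 when zero rpmu values are present")
        lc = np.log2(ctrl + pseudocount)
        lt = np.log2(trt + pseudocount)
        equal_var = test_method == "student"
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance rows -> p=1
            _, p = stats.ttest_ind(lt, lc, axis=1, equal_var=equal_var)
        p = np.asarray(p)

    # transcripts all-zero under both conditions: defined null result, not an error
    all_zero = (ctrl == 0).all(axis=1) & (trt == 0).all(axis=1)
    log2fc[all_zero] = 0.0
    p[all_zero] = 1.0
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    if bh:
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]

    significant = (p < alpha) & (np.abs(log2fc) >= lfc)
    direction = np.where(~significant, "none", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "transcript_id": rpmu.index,
            "log2FC": log2fc,
            "p_value": p,
            "significant": significant,
            "direction": direction,
        }
    ).reset_index(drop=True)


def _nb_pvalues(
    counts: pd.DataFrame,
    ctrl_samples: list[str],
    trt_samples: list[str],
    gene_order: pd.Index,
) -> np.ndarray:
    """Negative-binomial Wald p-values on raw tcReadCount with per-sample
    non-TC library sums as exposure."""
    import statsmodels.api as sm

    tc = _pivot(counts, "tcReadCount")
    totals = counts.groupby("sample").apply(
        lambda g: (g["readCount"] - g["tcReadCount"]).sum(), include_groups=False
    )
    if (totals[ctrl_samples + trt_samples] <= 0).any():
        raise DegenerateDataError("non-TC library sum is zero for some sample")
    samples = ctrl_samples + trt_samples
    y_all = tc.loc[gene_order, samples].to_numpy(float)
    exposure = totals[samples].to_numpy(float)
    x = np.column_stack(
        [np.ones(len(samples)), [0] * len(ctrl_samples) + [1] * len(trt_samples)]
    )
    p = np.empty(len(gene_order))
    for i, y in enumerate(y_all):
        if y.sum() == 0:
            p[i] = 1.0
            continue
        try:
            fit = sm.GLM(
                y, x, family=sm.families.NegativeBinomial(alpha=0.1), exposure=exposure
            ).fit()
            p[i] = fit.pvalues[1]
        except Exception:
            p[i] = 1.0
    return p


def volcano_summary(table: pd.DataFrame) -> tuple[int, int, int]:
    """(n_up, n_down, n_tested) from a differential table."""
    if len(table) == 0:
        return (0, 0, 0)
    sig = table["significant"].astype(bool)
    n_up = int((sig & (table["direction"] == "up")).sum())
    n_down = int((sig & (table["direction"] == "down")).sum())
    return (n_up, n_down, int(len(table)))
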