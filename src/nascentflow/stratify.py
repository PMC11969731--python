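"""Gene-length trichotomization, exon-count stratification, per-stratum
shift tests, and the labeling-time linearity check.

Default length boundaries: short = [0, 250), medium = [250, 10001),
long = [10001, inf) nucleotides — i.e. 249 is short, 250-10000 medium,
above 10000 long.  Cutoffs are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from nascentflow.errors import ConfigurationError, DegenerateDataError

LENGTH_CUTOFFS_DEFAULT = (250, 10001)
EXON_CUTOFF_DEFAULT = 30
LENGTH_LABELS = ("short", "medium", "long")


@dataclass(frozen=True)
class StratumResult:
    stratum: str
    n_genes: int
    mean_log2FC: float
    p_value: float | None
    testable: bool = True


def trichotomize(
    lengths: Mapping[str, int], cutoffs: tuple[int, int] = LENGTH_CUTOFFS_DEFAULT
) -> dict[str, str]:
    """Map gene_id -> {short, medium, long} by genomic span length."""
    lo, hi = cutoffs
    if not (0 < lo < hi):
        raise ConfigurationError(f"cutoffs must be strictly increasing positives, got {cutoffs}")
    out = {}
    for gid, length in lengths.items():
        if length < 0:
            raise ConfigurationError(f"{gid}: negative length")
        if length < lo:
            out[gid] = "short"
        elif length < hi:
            out[gid] = "medium"
        else:
            out[gid] = "long"
    return out


def _one_sample(values: np.ndarray) -> float:
    if np.allclose(values, values[0]):
        # zero variance: p=1 when centered on 0, else extreme
        return 1.0 if np.isclose(values[0], 0.0) else 0.0
    return float(stats.ttest_1samp(values, 0.0).pvalue)


def stratified_shift(
    table: pd.DataFrame,
    class_map: Mapping[str, str],
    mode: str = "vs_zero",
    equal_var: bool = True,
) -> list[StratumResult]:
    """Test each stratum's log2FC distribution.

    mode "vs_zero": one-sample t-test of each stratum against 0.
    mode "pairwise": two-sample t-tests between every pair of strata, with
    the stratum field set to "A_vs_B".
    Strata with < 2 genes are returned untestable with p unset.
    """
    if mode not in {"vs_zero", "pairwise"}:
        raise ConfigurationError(f"unknown mode {mode!r}")
    missing = [g for g in table["transcript_id"] if g not in class_map]
    if missing:
        raise ConfigurationError(f"class map does not cover genes: {missing[:5]}...")
    labels = table["transcript_id"].map(class_map)
    groups: dict[str, np.ndarray] = {
        str(lab): table.loc[labels == lab, "log2FC"].to_numpy(float)
        for lab in pd.unique(labels)
    }
    order = [lab for lab in LENGTH_LABELS if lab in groups] + sorted(
        set(groups) - set(LENGTH_LABELS)
    )

    results = []
    if mode == "vs_zero":
        for lab in order:
            vals = groups[lab]
            if len(vals) < 2:
                results.append(
                    StratumResult(lab, len(vals), float(vals.mean()) if len(vals) else float("nan"),
                                  None, testable=False)
                )
                continue
            results.append(StratumResult(lab, len(vals), float(vals.mean()), _one_sample(vals)))
    else:
        for a, b in combinations(order, 2):
            va, vb = groups[a], groups[b]
            if len(va) < 2 or len(vb) < 2:
                results.append(
                    StratumResult(f"{a}_vs_{b}", len(va) + len(vb), float("nan"), None,
                                  testable=False)
                )
                continue
            p = float(stats.ttest_ind(va, vb, equal_var=equal_var).pvalue)
            results.append(
                StratumResult(f"{a}_vs_{b}", len(va) + len(vb),
                              float(va.mean() - vb.mean()), p)
            )
    return results


def target_set_shift(
    table: pd.DataFrame, gene_set: Iterable[str], equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sample t-test of log2FC inside a gene set vs outside it.

    Returns (mean_in_set, mean_out_of_set, p_value).
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ConfigurationError("gene_set is empty")
    in_mask = table["transcript_id"].isin(gene_set).to_numpy()
    if not in_mask.any():
        raise ConfigurationError("gene_set does not intersect the differential table")
    if in_mask.all():
        raise ConfigurationError("gene_set covers every tested gene; no out-group to compare")
    vin = table.loc[in_mask, "log2FC"].to_numpy(float)
    vout = table.loc[~in_mask, "log2FC"].to_numpy(float)
    if len(vin) < 2 or len(vout) < 2:
        raise DegenerateDataError("need >= 2 genes on each side of the comparison")
    p = float(stats.ttest_ind(vin, vout, equal_var=equal_var).pvalue)
    return (float(vin.mean()), float(vout.mean()), p)


def exon_stratify(
    table: pd.DataFrame,
    exon_counts: Mapping[str, int],
    exon_cutoff: int = EXON_CUTOFF_DEFAULT,
    equal_var: bool = True,
) -> list[StratumResult]:
    """Split genes at `exon_cutoff` exons (strictly above vs at-or-below) and
    run the vs-zero shift test on each stratum."""
    if exon_cutoff < 0:
        raise ConfigurationError("exon_cutoff must be >= 0")
    class_map = {
        gid: (f"over_{exon_cutoff}_exons" if n > exon_cutoff else f"upto_{exon_cutoff}_exons")
        for gid, n in exon_counts.items()
    }
    # ensure both strata are reported even when one is empty
    results = {r.stratum: r for r in stratified_shift(table, class_map, mode="vs_zero",
                                                      equal_var=equal_var)}
    out = []
    for lab in (f"over_{exon_cutoff}_exons", f"upto_{exon_cutoff}_exons"):
        out.append(results.get(lab, StratumResult(lab, 0, float("nan"), None, testable=False)))
    return out


def label_time_ratio(
    counts_t1: pd.DataFrame,
    counts_t2: pd.DataFrame,
    baseline: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Ratio of summed label intensity between two labeling times (t2 / t1).

    Reported both on raw tcReadCount sums and on rpmu sums (when present).
    An optional `baseline` count table from an unlabeled control is
    subtracted from both numerator and denominator, yielding the
    background-corrected label-intensity ratio.
    """
    u1 = set(counts_t1["gene_id"])
    u2 = set(counts_t2["gene_id"])
    if u1 != u2:
        raise ConfigurationError("count tables cover different transcript universes")

    def _sums(df: pd.DataFrame) -> tuple[float, float | None]:
        raw = float(df["tcReadCount"].sum())
        rpmu = float(df["rpmu"].sum()) if "rpmu" in df.columns else None
        return raw, rpmu

    raw1, rpmu1 = _sums(counts_t1)
    raw2, rpmu2 = _sums(counts_t2)
    if baseline is not None:
        raw0, rpmu0 = _sums(baseline)
        raw1, raw2 = raw1 - raw0, raw2 - raw0
        if rpmu0 is not None and rpmu1 is not None and rpmu2 is not None:
            rpmu1, rpmu2 = rpmu1 - rpmu0, rpmu2 - rpmu0
    if raw1 <= 0:
        raise DegenerateDataError("zero label intensity at t1; ratio undefined")
    out = {"raw_ratio": raw2 / raw1}
    if rpmu1 is not None and rpmu2 is not None:
        if rpmu1 <= 0:
            raise DegenerateDataError("zero rpmu intensity at t1; ratio undefined")
        out["rpmu_ratio"] = rpmu2 / rpmu1
    return out


def strata_to_frame(results: list[StratumResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stratum": [r.stratum for r in results],
            "n_genes": [r.n_genes for r in results],
            "mean_log2FC": [r.mean_log2FC for r in results],
            "p_value": [r.p_value if r.p_value is not None else np.nan for r in results],
            "testable": [r.testable for r in results],
        }
    )
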