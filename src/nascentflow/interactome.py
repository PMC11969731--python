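"""Bait-normalized AP-MS differential interactome analysis.

Processing order is fixed: missing intensities (exact zeros) are floored to
1 first, then every sample column is divided by the bait's intensity in
that same sample.  Replicate means per condition give the fold change
relative to control; a two-sample Student's t-test gives the p-value; the
gained/lost call combines p < alpha with the sign of the log2 fold change.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from nascentflow.errors import ConfigurationError, InputFormatError

PSEUDO_FLOOR = 1.0
ALPHA_DEFAULT = 0.05


def pseudo_floor(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace exact-zero intensities with 1; idempotent, other values untouched."""
    values = matrix.to_numpy(float)
    if (values < 0).any():
        raise InputFormatError("negative intensities in matrix")
    out = matrix.copy()
    out[out == 0] = PSEUDO_FLOOR
    return out


def bait_normalize(matrix: pd.DataFrame, bait_id: str) -> pd.DataFrame:
    """Divide every sample column by the bait's intensity in that sample.

    The bait row becomes exactly 1 everywhere; per-sample multiplicative
    factors (loading, IP efficiency) cancel.
    """
    if bait_id not in matrix.index:
        raise InputFormatError(f"bait {bait_id!r} not present in intensity matrix")
    bait = matrix.loc[bait_id]
    if (bait <= 0).any():
        raise InputFormatError(
            f"bait {bait_id!r} has non-positive intensity in some sample; "
            "apply pseudo_floor first"
        )
    return matrix.div(bait, axis=1)


def imputed_floor_flags(raw_matrix: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    """Proteins undetected (all zero) in at least one whole condition, which
    the floor makes testable; flagged for transparency."""
    flags = pd.Series(False, index=raw_matrix.index)
    for cond, group in design.groupby("condition"):
        cols = group["sample"].tolist()
        flags |= (raw_matrix[cols] == 0).all(axis=1)
    return flags.rename("imputed_floor")


def differential_interactome(
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    control: str,
    treated: str,
    alpha: float = ALPHA_DEFAULT,
    log_scale: bool = False,
    imputed: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-protein fold change (treated/control on replicate means of
    bait-normalized intensities), Student's t p-value, and class.

    With `log_scale` the t-test runs on log2 of normalized values (the
    statistically safer option); the fold change is unchanged.
    """
    ctrl_cols = design.loc[design["condition"] == control, "sample"].tolist()
    trt_cols = design.loc[design["condition"] == treated, "sample"].tolist()
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise ConfigurationError("each condition needs >= 2 replicates")
    missing = [c for c in ctrl_cols + trt_cols if c not in normalized.columns]
    if missing:
        raise ConfigurationError(f"design samples absent from matrix: {missing}")

    ctrl = normalized[ctrl_cols].to_numpy(float)
    trt = normalized[trt_cols].to_numpy(float)
    if (ctrl <= 0).any() or (trt <= 0).any():
        raise InputFormatError("non-positive normalized intensities; apply pseudo_floor first")

    mean_ctrl = ctrl.mean(axis=1)
    mean_trt = trt.mean(axis=1)
    fold_change = mean_trt / mean_ctrl
    log2fc = np.log2(fold_change)

    a, b = (np.log2(trt), np.log2(ctrl)) if log_scale else (trt, ctrl)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance rows (e.g. bait) -> p=1
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.where(np.isnan(p), 1.0, np.asarray(p))

    cls = np.where(
        (p < alpha) & (log2fc > 0), "gained", np.where((p < alpha) & (log2fc < 0), "lost", "unchanged")
    )
    table = pd.DataFrame(
        {
            "protein_id": normalized.index,
            "mean_norm_control": mean_ctrl,
            "mean_norm_treated": mean_trt,
            "fold_change": fold_change,
            "log2FC": log2fc,
            "p_value": p,
            "class": cls,
        }
    ).reset_index(drop=True)
    if imputed is not None:
        table["imputed_floor"] = imputed.reindex(normalized.index).fillna(False).to_numpy()
    return table


def analyze(
    raw_matrix: pd.DataFrame,
    design: pd.DataFrame,
    bait_id: str,
    control: str,
    treated: str,
    alpha: float = ALPHA_DEFAULT,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Full contrast in the fixed order: floor -> bait-normalize -> test."""
    floored = pseudo_floor(raw_matrix)
    normalized = bait_normalize(floored, bait_id)
    flags = imputed_floor_flags(raw_matrix, design)
    return differential_interactome(
        normalized, design, control, treated, alpha=alpha, log_scale=log_scale, imputed=flags
    )


def dual_response_filter(
    table_a: pd.DataFrame, table_b: pd.DataFrame, lfc_cutoff: float = 2.0
) -> pd.DataFrame:
    """Proteins significant in both contrasts with |log2FC| >= cutoff in both.

    Returns a frame with per-table log2FCs and a concordance column
    (concordant-gained / concordant-lost / discordant).
    """
    ua, ub = set(table_a["protein_id"]), set(table_b["protein_id"])
    if not (ua & ub):
        raise ConfigurationError("protein universes of the two tables are disjoint")
    a = table_a.set_index("protein_id")
    b = table_b.set_index("protein_id")
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    sig = (
        (a["class"] != "unchanged")
        & (b["class"] != "unchanged")
        & (a["log2FC"].abs() >= lfc_cutoff)
        & (b["log2FC"].abs() >= lfc_cutoff)
    )
    hits = pd.DataFrame(
        {
            "protein_id": shared[sig],
            "log2FC_a": a.loc[sig, "log2FC"].to_numpy(),
            "log2FC_b": b.loc[sig, "log2FC"].to_numpy(),
        }
    )
    same_sign = np.sign(hits["log2FC_a"]) == np.sign(hits["log2FC_b"])
    hits["concordance"] = np.where(
        ~same_sign, "discordant", np.where(hits["log2FC_a"] > 0, "concordant-gained", "concordant-lost")
    )
    return hits.reset_index(drop=True)


def selective_sets(
    tables: Mapping[str, pd.DataFrame], direction: str
) -> tuple[dict[str, set[str]], dict[frozenset, set[str]]]:
    """Membership analysis of significant proteins across conditions.

    `direction` is "lost" or "gained".  Returns (exclusive, patterns):
    `exclusive[cond]` holds proteins significant in exactly that condition;
    `patterns` maps every non-empty condition subset to the proteins
    significant in exactly those conditions (the UpSet decomposition).
    """
    if direction not in {"lost", "gained"}:
        raise ConfigurationError(f"direction must be 'lost' or 'gained', got {direction!r}")
    if len(tables) < 1:
        raise ConfigurationError("at least one table required")
    members = {
        cond: set(t.loc[t["class"] == direction, "protein_id"]) for cond, t in tables.items()
    }
    universe = set().union(*members.values())
    patterns: dict[frozenset, set[str]] = {}
    for protein in universe:
        key = frozenset(c for c, s in members.items() if protein in s)
        patterns.setdefault(key, set()).add(protein)
    exclusive = {
        cond: patterns.get(frozenset({cond}), set()) for cond in tables
    }
    return exclusive, patterns


def intersection_sizes(patterns: dict[frozenset, set[str]]) -> pd.DataFrame:
    """Flatten an UpSet pattern map into a sorted size table."""
    rows = [
        ("+".join(sorted(key)), len(val)) for key, val in patterns.items()
    ]
    return pd.DataFrame(rows, columns=["pattern", "size"]).sort_values(
        ["size", "pattern"], ascending=[False, True]
    ).reset_index(drop=True)


def complex_summary(
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    control: str,
    treated: str,
    member_list: Iterable[str],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Relative binding of a protein complex's members.

    Per member: mean normalized treated / mean normalized control.  Returns
    the per-member table plus complex-level stats (mean relative binding,
    fraction below/above 1, members missing from the matrix).
    """
    member_list = list(dict.fromkeys(member_list))
    present = [m for m in member_list if m in normalized.index]
    absent = [m for m in member_list if m not in normalized.index]
    if not present:
        raise InputFormatError(f"no complex member detected; absent: {absent}")
    ctrl_cols = design.loc[design["condition"] == control, "sample"].tolist()
    trt_cols = design.loc[design["condition"] == treated, "sample"].tolist()
    rel = (
        normalized.loc[present, trt_cols].mean(axis=1)
        / normalized.loc[present, ctrl_cols].mean(axis=1)
    )
    table = pd.DataFrame({"protein_id": present, "relative_binding": rel.to_numpy()})
    summary = {
        "complex_mean_relative_binding": float(rel.mean()),
        "fraction_below_1": float((rel < 1).mean()),
        "fraction_above_1": float((rel > 1).mean()),
        "n_members_detected": float(len(present)),
        "n_members_missing": float(len(absent)),
    }
    return table, summary
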