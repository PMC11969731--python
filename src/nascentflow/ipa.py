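"""Intronic-polyadenylation detection from per-intron coverage.

A deliberately simple change-point scorer: for a candidate position k the
score is (mean_up - mean_down) / mean_up, with the means taken over the
full segments on each side of k.  The called site maximizes the score over
positions with at least `min_flank` bases on each side (leftmost on ties);
an event is emitted iff mean_up >= min_depth and score >= min_score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from nascentflow.errors import ConfigurationError
from nascentflow.synthetic import CoverageProfile

MIN_FLANK_DEFAULT = 100
MIN_DEPTH_DEFAULT = 10.0
MIN_SCORE_DEFAULT = 0.25


@dataclass(frozen=True)
class IPAEvent:
    gene_id: str
    intron_interval: tuple[int, int]
    site: int
    ipa_score: float
    mean_up: float
    mean_down: float
    passed: bool
    sample_id: str = "sample"


def score_ipa(
    profile: CoverageProfile,
    min_flank: int = MIN_FLANK_DEFAULT,
    min_depth: float = MIN_DEPTH_DEFAULT,
    min_score: float = MIN_SCORE_DEFAULT,
) -> IPAEvent | None:
    """Score one intron's coverage profile for a premature-termination step.

    Returns the maximal-score event if it passes both the depth and score
    thresholds, otherwise None.  Profiles shorter than 2*min_flank are
    skipped with a warning.
    """
    if min_flank < 1:
        raise ConfigurationError("min_flank must be >= 1")
    depth = np.asarray(profile.depth, dtype=float)
    n = len(depth)
    if n < 2 * min_flank:
        warnings.warn(
            f"{profile.gene_id} intron {profile.intron_interval}: profile of length {n} "
            f"shorter than 2*min_flank={2 * min_flank}; skipped",
            stacklevel=2,
        )
        return None

    # candidate split k: upstream = depth[:k], downstream = depth[k:]
    cumsum = np.concatenate([[0.0], np.cumsum(depth)])
    ks = np.arange(min_flank, n - min_flank + 1)
    mean_up = cumsum[ks] / ks
    mean_down = (cumsum[n] - cumsum[ks]) / (n - ks)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(mean_up > 0, (mean_up - mean_down) / mean_up, -np.inf)
    best = int(np.argmax(scores))  # argmax returns first (leftmost) maximum
    k = int(ks[best])
    score = float(scores[best])
    up, down = float(mean_up[best]), float(mean_down[best])

    if not np.isfinite(score) or down > up:
        return None
    passed = up >= min_depth and score >= min_score
    if not passed:
        return None
    start = profile.intron_interval[0]
    return IPAEvent(
        gene_id=profile.gene_id,
        intron_interval=profile.intron_interval,
        site=start + k,
        ipa_score=score,
        mean_up=up,
        mean_down=down,
        passed=True,
        sample_id=profile.sample_id,
    )


def scan_profiles(
    profiles: Iterable[CoverageProfile],
    min_flank: int = MIN_FLANK_DEFAULT,
    min_depth: float = MIN_DEPTH_DEFAULT,
    min_score: float = MIN_SCORE_DEFAULT,
) -> list[IPAEvent]:
    """Apply :func:`score_ipa` to a profile collection, keeping events."""
    events = []
    for profile in profiles:
        ev = score_ipa(profile, min_flank=min_flank, min_depth=min_depth, min_score=min_score)
        if ev is not None:
            events.append(ev)
    return events


def count_ipa(events: Iterable[IPAEvent], pass_only: bool = True) -> pd.Series:
    """Number of (passed) IPA events per sample."""
    counts: dict[str, int] = {}
    for ev in events:
        if pass_only and not ev.passed:
            continue
        counts[ev.sample_id] = counts.get(ev.sample_id, 0) + 1
    return pd.Series(counts, dtype=int).sort_index().rename("n_ipa_events")


def events_to_frame(events: Iterable[IPAEvent]) -> pd.DataFrame:
    """One line per event with its features, mirroring a tab-delimited
    event report."""
    rows = [
        (
            ev.gene_id,
            ev.intron_interval[0],
            ev.intron_interval[1],
            ev.site,
            ev.ipa_score,
            ev.mean_up,
            ev.mean_down,
            ev.passed,
            ev.sample_id,
        )
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "intron_start",
            "intron_end",
            "site",
            "ipa_score",
            "mean_up",
            "mean_down",
            "passed",
            "sample",
        ],
    )
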