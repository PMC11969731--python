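"""T>C conversion counting, labeled-read classification, aggregation, and
RPMu normalization.

RPMu for a transcript is its TC-read count divided by the sample-wide sum of
non-TC reads, times 1e7; the denominator is a library-size proxy computed
over all transcripts in the sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from nascentflow.errors import DegenerateDataError, InputFormatError

RPMU_SCALE = 10_000_000


@dataclass(frozen=True)
class ReadConversionSummary:
    """Per-read tally of reference-T positions covered and T>C mismatches."""

    read_id: str
    transcript_id: str
    n_ref_T: int
    n_TC: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_TC <= self.n_ref_T):
            raise InputFormatError(
                f"read {self.read_id}: n_TC={self.n_TC} outside [0, n_ref_T={self.n_ref_T}]"
            )


def count_conversions(aligned_read, snp_mask: frozenset | set | None = None) -> ReadConversionSummary:
    """Tally reference-T positions and T>C mismatches for one aligned read.

    `aligned_read` is a pysam AlignedSegment whose MD tag allows the
    reference base to be recovered at every aligned position.  Positions in
    `snp_mask` (0-based reference coordinates) are excluded entirely.
    Minus-strand alignments are evaluated as A>G in genome space, which is
    T>C in transcript space.
    """
    snp_mask = snp_mask or frozenset()
    try:
        pairs = aligned_read.get_aligned_pairs(with_seq=True)
    except ValueError as exc:
        raise InputFormatError(
            f"read {aligned_read.query_name}: cannot recover reference bases ({exc}); "
            "MD tag required"
        ) from exc
    query = aligned_read.query_sequence
    if query is None:
        raise InputFormatError(f"read {aligned_read.query_name}: no query sequence")

    if aligned_read.is_reverse:
        ref_base_wanted, conv_base = "a", "G"  # A>G on the genome strand
    else:
        ref_base_wanted, conv_base = "t", "C"

    n_ref = 0
    n_tc = 0
    for qpos, rpos, ref_base in pairs:
        if qpos is None or rpos is None or ref_base is None:
            continue  # indels / clips carry no mismatch information
        if rpos in snp_mask:
            continue
        if ref_base.lower() != ref_base_wanted:
            continue
        n_ref += 1
        if query[qpos].upper() == conv_base:
            n_tc += 1
    return ReadConversionSummary(
        read_id=aligned_read.query_name,
        transcript_id=aligned_read.reference_name or "",
        n_ref_T=n_ref,
        n_TC=n_tc,
    )


def count_conversions_sam(
    path: str, snp_mask: frozenset | set | None = None
) -> list[ReadConversionSummary]:
    """Run :func:`count_conversions` over every mapped read in a SAM/BAM file."""
    import pysam

    out = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            out.append(count_conversions(read, snp_mask))
    return out


def classify_labeled(summary: ReadConversionSummary, threshold: int = 1) -> bool:
    """A read is labeled iff it carries at least `threshold` T>C conversions."""
    if threshold < 1:
        raise InputFormatError("conversion threshold must be >= 1")
    return summary.n_TC >= threshold


def aggregate_counts(
    summaries: Iterable[ReadConversionSummary],
    transcript_ids: Iterable[str],
    threshold: int = 1,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Aggregate read summaries into per-transcript (readCount, tcReadCount).

    Every id in `transcript_ids` appears in the output, with zeros when it
    received no reads.  Reads referencing unknown transcripts are an error.
    """
    known = list(dict.fromkeys(transcript_ids))
    read_count = {tid: 0 for tid in known}
    tc_count = {tid: 0 for tid in known}
    unknown = set()
    for s in summaries:
        if s.transcript_id not in read_count:
            unknown.add(s.transcript_id)
            continue
        read_count[s.transcript_id] += 1
        if classify_labeled(s, threshold):
            tc_count[s.transcript_id] += 1
    if unknown:
        raise InputFormatError(f"reads reference unknown transcripts: {sorted(unknown)}")
    return pd.DataFrame(
        {
            "gene_id": known,
            "sample": sample_id,
            "readCount": [read_count[t] for t in known],
            "tcReadCount": [tc_count[t] for t in known],
        }
    )


def rpmu_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Attach the `rpmu` column: tcReadCount / (sample-wide non-TC sum) * 1e7.

    Normalization is per sample (per value of the `sample` column when
    present).  A sample whose non-TC sum is zero is degenerate.
    """
    counts = counts.copy()
    if (counts["tcReadCount"] > counts["readCount"]).any():
        raise InputFormatError("tcReadCount exceeds readCount")

    def _one(group: pd.DataFrame) -> pd.Series:
        non_tc = (group["readCount"] - group["tcReadCount"]).sum()
        if non_tc <= 0:
            name = group["sample"].iloc[0] if "sample" in group else "<sample>"
            raise DegenerateDataError(f"sample {name}: non-TC read sum is zero")
        return group["tcReadCount"] / non_tc * RPMU_SCALE

    if "sample" in counts.columns:
        parts = []
        for _, group in counts.groupby("sample", sort=False):
            parts.append(_one(group))
        counts["rpmu"] = pd.concat(parts).reindex(counts.index)
    else:
        counts["rpmu"] = _one(counts)
    counts["rpmu"] = counts["rpmu"].astype(float)
    return counts


def total_tc(counts: pd.DataFrame) -> int:
    """Library-wide TC-read count (label intensity on the raw count scale)."""
    return int(np.asarray(counts["tcReadCount"]).sum())
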