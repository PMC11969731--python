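"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Counts-level simulation is canonical; :func:`emit_sam` exists only so the
SAM/MD ingestion path can be exercised without real alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nascentflow.errors import ConfigurationError
from nascentflow.seeding import (
    STREAM_INTERACTOME,
    STREAM_IPA,
    STREAM_SAM,
    STREAM_SLAM,
    STREAM_TRANSCRIPTOME,
    substream,
)

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One gene/transcript: genomic span length (exons + introns), exon count,
    intron intervals (0-based half-open, gene-local coordinates), and the
    number of reference uridine (T) positions covered by a read window."""

    gene_id: str
    length_nt: int
    exon_count: int
    introns: tuple[tuple[int, int], ...] = ()
    n_uridines: int = 30

    def __post_init__(self) -> None:
        if self.length_nt < 1:
            raise ConfigurationError(f"{self.gene_id}: length_nt must be >= 1")
        if self.exon_count < 1:
            raise ConfigurationError(f"{self.gene_id}: exon_count must be >= 1")
        if self.n_uridines < 1:
            raise ConfigurationError(f"{self.gene_id}: n_uridines must be >= 1")
        last = 0
        for start, end in self.introns:
            if not (0 <= start < end <= self.length_nt):
                raise ConfigurationError(
                    f"{self.gene_id}: intron [{start},{end}) outside gene span"
                )
            if start < last:
                raise ConfigurationError(f"{self.gene_id}: introns overlap or are unsorted")
            last = end


@dataclass(frozen=True)
class LabelingModel:
    """Metabolic-labeling model: per-uridine conversion probability grows
    linearly with labeling time on top of a uniform background error rate."""

    labeling_time_min: float
    conversion_rate_per_min: float
    background_error_rate: float = 0.0
    labeled_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.labeling_time_min > 0 and np.isfinite(self.labeling_time_min)):
            raise ConfigurationError("labeling_time_min must be positive and finite")
        if not (0 < self.conversion_rate_per_min < 1):
            raise ConfigurationError("conversion_rate_per_min must be in (0, 1)")
        if not (0 <= self.background_error_rate < 1):
            raise ConfigurationError("background_error_rate must be in [0, 1)")
        if not (0 <= self.labeled_fraction <= 1):
            raise ConfigurationError("labeled_fraction must be in [0, 1]")
        if self.conversion_probability >= 1:
            raise ConfigurationError(
                "labeling_time_min * conversion_rate_per_min + background >= 1: "
                "not a valid per-uridine probability"
            )

    @property
    def conversion_probability(self) -> float:
        """Per-uridine T>C probability for a labeled read."""
        return self.labeling_time_min * self.conversion_rate_per_min + self.background_error_rate


@dataclass(frozen=True)
class InteractomeSpikeDesign:
    """Design of a synthetic AP-MS experiment: a lognormal intensity baseline,
    a bait protein, replicate structure, and spiked log2 effects applied in
    the treated condition only."""

    n_proteins: int
    bait_id: str = "BAIT"
    n_replicates_per_condition: int = 3
    lognormal_sigma: float = 0.2
    spiked: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    missing_fraction: float = 0.0
    sample_scale_sigma: float = 0.3
    bait_sigma: float | None = None
    conditions: tuple[str, str] = ("control", "treated")

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if self.n_replicates_per_condition < 2:
            raise ConfigurationError(
                "n_replicates_per_condition must be >= 2 (t-test undefined otherwise)"
            )
        if self.lognormal_sigma <= 0:
            raise ConfigurationError("lognormal_sigma must be positive")
        if not (0 <= self.missing_fraction < 1):
            raise ConfigurationError("missing_fraction must be in [0, 1)")
        universe = set(self.protein_ids)
        unknown = set(self.spiked) - universe
        if unknown:
            raise ConfigurationError(f"spiked proteins outside universe: {sorted(unknown)}")

    @property
    def protein_ids(self) -> list[str]:
        width = len(str(self.n_proteins))
        ids = [f"P{i:0{width}d}" for i in range(1, self.n_proteins)]
        return [self.bait_id, *ids]


@dataclass(frozen=True)
class CoverageProfile:
    """Per-base read depth across one intron, with the simulated truth
    (change-point position and usage fraction) attached when present."""

    gene_id: str
    intron_interval: tuple[int, int]
    depth: np.ndarray
    true_ipa_site: int | None = None
    true_usage_fraction: float = 0.0
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        start, end = self.intron_interval
        if len(self.depth) != end - start:
            raise ConfigurationError(
                f"{self.gene_id}: depth length {len(self.depth)} != interval length {end - start}"
            )
        if np.any(np.asarray(self.depth) < 0):
            raise ConfigurationError(f"{self.gene_id}: negative depth")
        if self.true_ipa_site is not None and not (start < self.true_ipa_site < end):
            raise ConfigurationError(f"{self.gene_id}: true_ipa_site outside intron")


# ---------------------------------------------------------------------------
# generators


def _make_introns(length: int, exon_count: int) -> tuple[tuple[int, int], ...]:
    """Deterministic intron layout: split the span into 2*exon_count - 1
    equal segments, alternating exon/intron."""
    n_seg = 2 * exon_count - 1
    if n_seg > length:  # gene too short to host the introns; collapse
        return ()
    bounds = np.linspace(0, length, n_seg + 1).astype(int)
    return tuple(
        (int(bounds[i]), int(bounds[i + 1])) for i in range(1, n_seg, 2)
    )


def simulate_transcriptome(
    n_genes: int,
    length_distribution_params: dict,
    exon_distribution_params: dict | None = None,
    seed: int = 0,
    n_uridines_per_read: int = 30,
) -> list[TranscriptAnnotation]:
    """Draw `n_genes` annotations.

    `length_distribution_params` is one of
    ``{"kind": "fixed", "values": [...]}`` or
    ``{"kind": "lognormal", "mean_log": m, "sigma_log": s}`` (natural-log
    parameters of gene length in nt).  `exon_distribution_params` defaults to
    ``{"kind": "poisson", "lam": 8}`` (shifted by 1 so exon_count >= 1) and
    also accepts ``{"kind": "fixed", "values": [...]}``.

    n_uridines reflects the read window, not the gene length.
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    exon_distribution_params = exon_distribution_params or {"kind": "poisson", "lam": 8}
    rng = substream(seed, STREAM_TRANSCRIPTOME)

    kind = length_distribution_params.get("kind")
    if kind == "fixed":
        values = list(length_distribution_params["values"])
        if len(values) != n_genes:
            raise ConfigurationError("fixed length values must have length n_genes")
        lengths = np.asarray(values, dtype=int)
    elif kind == "lognormal":
        mean_log = float(length_distribution_params["mean_log"])
        sigma_log = float(length_distribution_params["sigma_log"])
        if sigma_log <= 0:
            raise ConfigurationError("sigma_log must be positive")
        lengths = np.maximum(1, np.round(rng.lognormal(mean_log, sigma_log, n_genes))).astype(int)
    else:
        raise ConfigurationError(f"unknown length distribution kind: {kind!r}")

    ekind = exon_distribution_params.get("kind")
    if ekind == "fixed":
        evalues = list(exon_distribution_params["values"])
        if len(evalues) != n_genes:
            raise ConfigurationError("fixed exon values must have length n_genes")
        exons = np.asarray(evalues, dtype=int)
        if np.any(exons < 1):
            raise ConfigurationError("exon_count must be >= 1")
    elif ekind == "poisson":
        lam = float(exon_distribution_params["lam"])
        if lam < 0:
            raise ConfigurationError("poisson lam must be >= 0")
        exons = 1 + rng.poisson(lam, n_genes)
    else:
        raise ConfigurationError(f"unknown exon distribution kind: {ekind!r}")

    width = len(str(n_genes))
    return [
        TranscriptAnnotation(
            gene_id=f"G{i:0{width}d}",
            length_nt=int(lengths[i]),
            exon_count=int(exons[i]),
            introns=_make_introns(int(lengths[i]), int(exons[i])),
            n_uridines=n_uridines_per_read,
        )
        for i in range(n_genes)
    ]


def simulate_slam_counts(
    annotation: list[TranscriptAnnotation],
    labeling_model: LabelingModel,
    n_reads_per_transcript: int,
    conversion_call_threshold: int = 1,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Simulate per-transcript SLAM counts for one sample.

    Each read is labeled with probability `labeled_fraction`; labeled reads
    draw Binomial(n_uridines, time*rate + background) conversions, unlabeled
    reads Binomial(n_uridines, background).  Reads at or above the
    conversion-call threshold are counted as TC reads.

    Returns a frame with columns gene_id, sample, readCount, tcReadCount.
    """
    if n_reads_per_transcript < 0:
        raise ConfigurationError("n_reads_per_transcript must be >= 0")
    if conversion_call_threshold < 1:
        raise ConfigurationError("conversion_call_threshold must be >= 1")
    rng = substream(labeling_model.seed, STREAM_SLAM)
    p_lab = labeling_model.conversion_probability
    p_bg = labeling_model.background_error_rate
    frac = labeling_model.labeled_fraction

    rows = []
    for ann in annotation:
        n = n_reads_per_transcript
        labeled = rng.random(n) < frac
        conv = np.empty(n, dtype=np.int64)
        n_lab = int(labeled.sum())
        conv[labeled] = rng.binomial(ann.n_uridines, p_lab, n_lab)
        conv[~labeled] = rng.binomial(ann.n_uridines, p_bg, n - n_lab)
        tc = int((conv >= conversion_call_threshold).sum())
        rows.append((ann.gene_id, sample_id, n, tc))
    return pd.DataFrame(rows, columns=["gene_id", "sample", "readCount", "tcReadCount"])


def simulate_interactome(design: InteractomeSpikeDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an AP-MS intensity matrix from a spike design.

    Returns ``(intensity, design_table)``: `intensity` is proteins x samples
    (raw intensities, exact zeros marking missing detections); `design_table`
    has columns sample, condition, replicate.

    Per-sample multiplicative scale factors model IP-efficiency differences;
    the bait participates in them, so bait normalization is genuinely
    exercised.  Spiked effects multiply the treated condition by 2**effect.
    """
    rng = substream(design.seed, STREAM_INTERACTOME)
    proteins = design.protein_ids
    n_p = len(proteins)
    conds = design.conditions
    n_rep = design.n_replicates_per_condition
    samples = [f"{cond}_r{r + 1}" for cond in conds for r in range(n_rep)]
    condition = [cond for cond in conds for _ in range(n_rep)]
    n_s = len(samples)

    base = rng.lognormal(mean=np.log(1e6), sigma=1.0, size=n_p)
    sample_scale = rng.lognormal(mean=0.0, sigma=design.sample_scale_sigma, size=n_s)
    sigma = np.full(n_p, design.lognormal_sigma)
    if design.bait_sigma is not None:
        sigma[proteins.index(design.bait_id)] = design.bait_sigma
    noise = np.exp(rng.normal(0.0, 1.0, size=(n_p, n_s)) * sigma[:, None])

    effect = np.zeros((n_p, n_s))
    treated_cols = np.asarray([c == conds[1] for c in condition])
    for pid, log2_eff in design.spiked.items():
        effect[proteins.index(pid), treated_cols] = log2_eff

    intensity = base[:, None] * sample_scale[None, :] * noise * np.exp2(effect)

    if design.missing_fraction > 0:
        miss = rng.random((n_p, n_s)) < design.missing_fraction
        miss[proteins.index(design.bait_id), :] = False  # bait always detected
        intensity[miss] = 0.0

    matrix = pd.DataFrame(intensity, index=pd.Index(proteins, name="protein_id"), columns=samples)
    design_table = pd.DataFrame(
        {
            "sample": samples,
            "condition": condition,
            "replicate": [r + 1 for _ in conds for r in range(n_rep)],
        }
    )
    return matrix, design_table


def simulate_ipa_coverage(
    annotation: list[TranscriptAnnotation],
    usage_fraction: float,
    depth: float,
    seed: int = 0,
    sample_id: str = "sample",
    site_margin: float = 0.25,
) -> list[CoverageProfile]:
    """Simulate one coverage profile per annotated intron.

    Depth is Poisson(depth) upstream of the IPA site and
    Poisson(depth * (1 - usage_fraction)) downstream.  `usage_fraction` = 0
    yields a flat-mean profile with no true site.  The site is drawn
    uniformly within the central (1 - 2*site_margin) of the intron.
    """
    if not (0 <= usage_fraction <= 1):
        raise ConfigurationError("usage_fraction must be in [0, 1]")
    if depth < 1:
        raise ConfigurationError("depth must be >= 1")
    rng = substream(seed, STREAM_IPA)
    profiles = []
    for ann in annotation:
        for start, end in ann.introns:
            n = end - start
            if usage_fraction == 0 or n < 4:
                prof_depth = rng.poisson(depth, n)
                site = None
            else:
                lo = start + max(1, int(n * site_margin))
                hi = end - max(1, int(n * site_margin))
                site = int(rng.integers(lo, max(lo + 1, hi)))
                up = rng.poisson(depth, site - start)
                down = rng.poisson(depth * (1 - usage_fraction), end - site)
                prof_depth = np.concatenate([up, down])
            profiles.append(
                CoverageProfile(
                    gene_id=ann.gene_id,
                    intron_interval=(start, end),
                    depth=prof_depth,
                    true_ipa_site=site,
                    true_usage_fraction=usage_fraction if site is not None else 0.0,
                    sample_id=sample_id,
                )
            )
    return profiles


# ---------------------------------------------------------------------------
# optional SAM emitter (I/O testing only)

_READ_LEN_PAD = 2  # spacer bases between uridine positions in the reference


def emit_sam(
    path: str,
    annotation: list[TranscriptAnnotation],
    labeling_model: LabelingModel,
    n_reads_per_transcript: int,
) -> None:
    """Write a SAM file of fully-aligned reads whose MD tags encode T>C
    mismatches drawn from `labeling_model`.

    The per-transcript reference is an alternating C/T pattern so every read
    covers exactly `n_uridines` reference-T positions.  Intended only for
    exercising the MD-tag ingestion path.
    """
    import pysam

    rng = substream(labeling_model.seed, STREAM_SAM)
    p_lab = labeling_model.conversion_probability
    p_bg = labeling_model.background_error_rate

    refs = {}
    for ann in annotation:
        # reference: n_uridines 'T's each preceded by _READ_LEN_PAD 'A's
        refs[ann.gene_id] = ("A" * _READ_LEN_PAD + "T") * ann.n_uridines
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": gid, "LN": len(seq)} for gid, seq in refs.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for tid, ann in enumerate(annotation):
            ref_seq = refs[ann.gene_id]
            t_positions = [i for i, b in enumerate(ref_seq) if b == "T"]
            for ridx in range(n_reads_per_transcript):
                labeled = rng.random() < labeling_model.labeled_fraction
                p = p_lab if labeled else p_bg
                converted = rng.random(len(t_positions)) < p
                read_seq = list(ref_seq)
                for pos, conv in zip(t_positions, converted):
                    if conv:
                        read_seq[pos] = "C"
                read_seq = "".join(read_seq)
                a = pysam.AlignedSegment()
                a.query_name = f"{ann.gene_id}_read{ridx}"
                a.query_sequence = read_seq
                a.flag = 0
                a.reference_id = tid
                a.reference_start = 0
                a.mapping_quality = 60
                a.cigarstring = f"{len(read_seq)}M"
                a.set_tag("MD", _md_tag(ref_seq, read_seq))
                a.set_tag("NM", sum(r != q for r, q in zip(ref_seq, read_seq)))
                out.write(a)


def _md_tag(ref: str, query: str) -> str:
    parts = []
    run = 0
    for r, q in zip(ref, query):
        if r == q:
            run += 1
        else:
            parts.append(str(run))
            parts.append(r)
            run = 0
    parts.append(str(run))
    return "".join(parts)
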