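"""End-to-end pipeline driver: simulate -> quantify -> diff -> stratify,
plus the interactome and IPA branches, with a reproducibility manifest.

All stage outputs are TSVs sorted by id and stamped with the config hash in
a leading comment line, so two runs with the same config and seed produce
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from nascentflow import __version__, differential, interactome, io, ipa, slam, stratify
from nascentflow.errors import ConfigurationError
from nascentflow.synthetic import (
    InteractomeSpikeDesign,
    LabelingModel,
    simulate_interactome,
    simulate_ipa_coverage,
    simulate_slam_counts,
    simulate_transcriptome,
)


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on besides its inputs."""

    seed: int = 0
    alpha: float = 0.05
    lfc: float = 1.0
    conversion_threshold: int = 1
    length_cutoffs: tuple[int, int] = stratify.LENGTH_CUTOFFS_DEFAULT
    exon_cutoff: int = stratify.EXON_CUTOFF_DEFAULT
    pseudocount: float = 1.0
    test_method: str = "welch"
    # simulation block
    n_genes: int = 200
    n_reads_per_transcript: int = 200
    length_mean_log: float = 8.0
    length_sigma_log: float = 1.5
    labeling_time_min: float = 10.0
    conversion_rate_per_min: float = 1e-4
    background_error_rate: float = 1e-4
    labeled_fraction: float = 1.0
    treated_label_effect: float = 0.0  # multiplier on labeled_fraction in treated
    n_replicates: int = 3
    # interactome block
    n_proteins: int = 100
    bait_id: str = "BAIT"
    lognormal_sigma: float = 0.2
    spiked: dict[str, float] = field(default_factory=dict)
    # ipa block
    ipa_usage_fraction: float = 0.5
    ipa_depth: float = 100.0
    ipa_min_flank: int = 100
    ipa_min_depth: float = 10.0
    ipa_min_score: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.lfc < 0:
            raise ConfigurationError("lfc must be >= 0")
        if self.conversion_threshold < 1:
            raise ConfigurationError("conversion_threshold must be >= 1")
        lo, hi = self.length_cutoffs
        if not (0 < lo < hi):
            raise ConfigurationError("length_cutoffs must be strictly increasing")
        self.length_cutoffs = (int(lo), int(hi))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["length_cutoffs"] = list(d["length_cutoffs"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "length_cutoffs" in d:
            d["length_cutoffs"] = tuple(d["length_cutoffs"])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        elif path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(text)
        else:
            data = json.loads(text)
        try:
            return cls.from_dict(data)
        except TypeError as exc:
            raise ConfigurationError(f"bad config {path}: {exc}") from exc

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    row_counts: dict[str, int]
    started: str
    finished: str

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path, verbose: bool = False) -> RunManifest:
    """Simulated end-to-end run writing every stage output under `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    row_counts: dict[str, int] = {}

    def log(msg: str) -> None:
        if verbose:
            print(f"[nascentflow] {msg}", file=sys.stderr)

    def emit(name: str, df: pd.DataFrame) -> None:
        io.write_table(df, outdir / name, comment=f"nascentflow config_hash={chash}")
        row_counts[name] = len(df)
        log(f"{name}: {len(df)} rows")

    # --- simulate annotation
    annotation = simulate_transcriptome(
        config.n_genes,
        {"kind": "lognormal", "mean_log": config.length_mean_log, "sigma_log": config.length_sigma_log},
        seed=config.seed,
    )
    io.write_annotation_tsv(annotation, outdir / "annotation.tsv", comment=f"nascentflow config_hash={chash}")
    row_counts["annotation.tsv"] = len(annotation)
    log(f"annotation.tsv: {len(annotation)} rows")

    # --- simulate counts per condition/replicate and quantify
    frames = []
    design_rows = []
    for cond_idx, cond in enumerate(("control", "treated")):
        frac = config.labeled_fraction
        if cond == "treated":
            frac = min(1.0, frac * 2.0**config.treated_label_effect)
        for rep in range(1, config.n_replicates + 1):
            sample = f"{cond}_r{rep}"
            model = LabelingModel(
                labeling_time_min=config.labeling_time_min,
                conversion_rate_per_min=config.conversion_rate_per_min,
                background_error_rate=config.background_error_rate,
                labeled_fraction=frac,
                seed=config.seed * 1000 + cond_idx * 100 + rep,
            )
            frames.append(
                simulate_slam_counts(
                    annotation, model, config.n_reads_per_transcript,
                    conversion_call_threshold=config.conversion_threshold, sample_id=sample,
                )
            )
            design_rows.append((sample, cond, rep))
    counts = pd.concat(frames, ignore_index=True)
    counts = slam.rpmu_normalize(counts).sort_values(["sample", "gene_id"]).reset_index(drop=True)
    design = pd.DataFrame(design_rows, columns=["sample", "condition", "replicate"])
    emit("counts.tsv", counts)
    emit("design.tsv", design)

    # --- differential labeling
    table = differential.differential_labeling(
        counts, design, "control", "treated",
        pseudocount=config.pseudocount, test_method=config.test_method,
        alpha=config.alpha, lfc=config.lfc,
    ).sort_values("transcript_id").reset_index(drop=True)
    emit("differential.tsv", table)

    # --- stratification
    lengths, exons = io.annotation_maps(annotation)
    class_map = stratify.trichotomize(lengths, config.length_cutoffs)
    strata = stratify.strata_to_frame(stratify.stratified_shift(table, class_map))
    emit("strata_length.tsv", strata)
    estrata = stratify.strata_to_frame(stratify.exon_stratify(table, exons, config.exon_cutoff))
    emit("strata_exon.tsv", estrata)

    # --- interactome branch
    design_ms = InteractomeSpikeDesign(
        n_proteins=config.n_proteins,
        bait_id=config.bait_id,
        n_replicates_per_condition=config.n_replicates,
        lognormal_sigma=config.lognormal_sigma,
        spiked=dict(config.spiked),
        seed=config.seed,
    )
    matrix, ms_design = simulate_interactome(design_ms)
    io.write_intensity_matrix(matrix, outdir / "intensities.tsv", comment=f"nascentflow config_hash={chash}")
    row_counts["intensities.tsv"] = len(matrix)
    itable = interactome.analyze(matrix, ms_design, config.bait_id, "control", "treated",
                                 alpha=config.alpha)
    itable = itable.sort_values("protein_id").reset_index(drop=True)
    emit("interactome.tsv", itable)

    # --- IPA branch
    profiles = []
    for cond_idx, cond in enumerate(("control", "treated")):
        usage = config.ipa_usage_fraction if cond == "treated" else 0.0
        profiles.extend(
            simulate_ipa_coverage(annotation, usage, config.ipa_depth,
                                  seed=config.seed * 10 + cond_idx, sample_id=cond)
        )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short introns are skipped silently in batch runs
        events = ipa.scan_profiles(profiles, min_flank=config.ipa_min_flank,
                                   min_depth=config.ipa_min_depth, min_score=config.ipa_min_score)
    eframe = ipa.events_to_frame(events).sort_values(["sample", "gene_id", "site"]).reset_index(drop=True)
    emit("ipa_events.tsv", eframe)
    icounts = ipa.count_ipa(events).rename_axis("sample").reset_index()
    emit("ipa_counts.tsv", icounts)

    manifest = RunManifest(
        version=__version__,
        config_hash=chash,
        row_counts=row_counts,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(outdir / "manifest.json")
    return manifest
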