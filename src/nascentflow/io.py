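"""Readers and writers for the pipeline's interchange formats.

TSV is canonical for counts, intensities, and results; GTF/BED/SAM are
accepted at ingestion only.  All coordinates are 0-based half-open
internally; GTF's 1-based closed intervals are converted at the boundary.
Tabular outputs are written sorted by id and may carry `#`-prefixed header
comments (e.g. the run's config hash), which every reader skips.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import pandas as pd

from nascentflow.errors import InputFormatError
from nascentflow.synthetic import CoverageProfile, TranscriptAnnotation

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_annotation(path: str | Path, format: str | None = None) -> list[TranscriptAnnotation]:
    """Read a transcript annotation from GTF or the simplified TSV.

    Format is inferred from the extension when not given.  Gene length is
    the genomic span (exons + introns); exon_count comes from exon records.
    """
    path = Path(path)
    if format is None:
        format = "gtf" if path.suffix.lower() in {".gtf", ".gff"} else "tsv"
    if format == "gtf":
        return _read_gtf(path)
    if format == "tsv":
        return _read_annotation_tsv(path)
    raise InputFormatError(f"unknown annotation format {format!r}")


def _read_gtf(path: Path) -> list[TranscriptAnnotation]:
    span: dict[str, list[int]] = {}
    exon_count: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise InputFormatError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            _, _, feature, start, end, _, _, _, attributes = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise InputFormatError(f"{path}:{lineno}: non-integer coordinates") from None
            attrs = dict(_GTF_ATTR_RE.findall(attributes))
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise InputFormatError(f"{path}:{lineno}: missing gene_id attribute")
            # GTF is 1-based closed; convert to 0-based half-open
            lo, hi = start_i - 1, end_i
            if gene_id in span:
                span[gene_id][0] = min(span[gene_id][0], lo)
                span[gene_id][1] = max(span[gene_id][1], hi)
            else:
                span[gene_id] = [lo, hi]
            if feature == "exon":
                exon_count[gene_id] = exon_count.get(gene_id, 0) + 1
    return [
        TranscriptAnnotation(
            gene_id=gid,
            length_nt=hi - lo,
            exon_count=max(1, exon_count.get(gid, 0)),
        )
        for gid, (lo, hi) in sorted(span.items())
    ]


def _parse_introns(text: str) -> tuple[tuple[int, int], ...]:
    text = text.strip()
    if not text or text == ".":
        return ()
    introns = []
    for token in text.split(";"):
        m = re.fullmatch(r"[^:]*:(\d+)-(\d+)", token.strip())
        if not m:
            raise InputFormatError(f"bad intron interval {token!r}; expected chrom:start-end")
        introns.append((int(m.group(1)), int(m.group(2))))
    return tuple(introns)


def _read_annotation_tsv(path: Path) -> list[TranscriptAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "length_nt", "exon_count"}
    if not required <= set(df.columns):
        raise InputFormatError(f"{path}: annotation TSV needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            TranscriptAnnotation(
                gene_id=str(row["gene_id"]),
                length_nt=int(row["length_nt"]),
                exon_count=int(row["exon_count"]),
                introns=_parse_introns(str(row["introns"])) if "introns" in df.columns else (),
                n_uridines=int(row["n_uridines"]) if "n_uridines" in df.columns else 30,
            )
        )
    return out


def write_annotation_tsv(
    annotation: Iterable[TranscriptAnnotation], path: str | Path, comment: str | None = None
) -> None:
    rows = [
        {
            "gene_id": a.gene_id,
            "length_nt": a.length_nt,
            "exon_count": a.exon_count,
            "introns": ";".join(f"{a.gene_id}:{s}-{e}" for s, e in a.introns) or ".",
            "n_uridines": a.n_uridines,
        }
        for a in sorted(annotation, key=lambda a: a.gene_id)
    ]
    write_table(pd.DataFrame(rows), path, comment=comment)


def write_table(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    """Write a TSV with an optional leading `#` comment line."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_design(path: str | Path) -> pd.DataFrame:
    """Design TSV: sample, condition, replicate."""
    df = read_table(path)
    required = {"sample", "condition"}
    if not required <= set(df.columns):
        raise InputFormatError(f"{path}: design TSV needs columns {sorted(required)}")
    return df


def read_intensity_matrix(path: str | Path) -> pd.DataFrame:
    """Intensity TSV: protein rows, sample columns; first column protein_id."""
    df = read_table(path)
    if df.columns[0] != "protein_id":
        raise InputFormatError(f"{path}: first column must be protein_id")
    return df.set_index("protein_id")


def write_intensity_matrix(matrix: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    out = matrix.sort_index().reset_index()
    out = out.rename(columns={out.columns[0]: "protein_id"})
    write_table(out, path, comment=comment)


def read_snp_mask_bed(path: str | Path) -> frozenset[int]:
    """BED (0-based half-open) of masked positions; chrom column ignored
    because positions are transcript-local."""
    positions: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputFormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise InputFormatError(f"{path}:{lineno}: non-integer BED coordinates") from None
            positions.update(range(start, end))
    return frozenset(positions)


def read_gene_set(path: str | Path) -> set[str]:
    """One gene id per line; blank lines and `#` comments ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def write_coverage_tsv(
    profiles: Iterable[CoverageProfile], path: str | Path, comment: str | None = None
) -> None:
    """BED-like per-base depth: gene_id, pos (0-based), depth, sample."""
    rows = []
    for p in sorted(profiles, key=lambda p: (p.sample_id, p.gene_id, p.intron_interval)):
        start = p.intron_interval[0]
        for offset, d in enumerate(p.depth):
            rows.append((p.gene_id, start + offset, int(d), p.sample_id))
    write_table(pd.DataFrame(rows, columns=["gene_id", "pos", "depth", "sample"]), path, comment)


def read_coverage_tsv(path: str | Path) -> list[CoverageProfile]:
    df = read_table(path)
    required = {"gene_id", "pos", "depth"}
    if not required <= set(df.columns):
        raise InputFormatError(f"{path}: coverage TSV needs columns {sorted(required)}")
    if "sample" not in df.columns:
        df["sample"] = "sample"
    profiles = []
    for (sample, gid), group in df.groupby(["sample", "gene_id"], sort=True):
        group = group.sort_values("pos")
        pos = group["pos"].to_numpy()
        # split into contiguous runs (one profile per intron)
        breaks = [0, *((pos[1:] != pos[:-1] + 1).nonzero()[0] + 1), len(pos)]
        for i in range(len(breaks) - 1):
            chunk = group.iloc[breaks[i] : breaks[i + 1]]
            start, end = int(chunk["pos"].iloc[0]), int(chunk["pos"].iloc[-1]) + 1
            profiles.append(
                CoverageProfile(
                    gene_id=str(gid),
                    intron_interval=(start, end),
                    depth=chunk["depth"].to_numpy(),
                    sample_id=str(sample),
                )
            )
    return profiles


def annotation_maps(
    annotation: Iterable[TranscriptAnnotation],
) -> tuple[dict[str, int], dict[str, int]]:
    """(gene -> length, gene -> exon_count) convenience maps."""
    lengths, exons = {}, {}
    for a in annotation:
        lengths[a.gene_id] = a.length_nt
        exons[a.gene_id] = a.exon_count
    return lengths, exons
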