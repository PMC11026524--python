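"""Readers and writers for the pipeline's plain-text interchange formats.

Formats: BED6+ for target-site annotations and aggregated sites, TSV for
read-level calls and minimal alignment records, JSON for model bundles,
run configuration and manifests, FASTA for oligo references (via
Bio.SeqIO) with a sidecar oligo table, and optional SAM via pysam. All
writers round-trip losslessly through their readers; coordinates are
0-based half-open as in BED.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .motifs import SUPPORTED_MOTIFS, normalize_motif
from .synthetic import Oligo

logger = logging.getLogger("m6aread")

__all__ = [
    "TargetSiteAnnotation",
    "read_target_bed",
    "write_target_bed",
    "write_sites_table",
    "read_sites_table",
    "write_calls",
    "read_calls",
    "write_alignments",
    "read_alignments",
    "read_peaks_bed",
    "write_oligo_fasta",
    "read_oligo_fasta",
    "write_reads_fasta",
    "write_sam",
    "RunConfig",
    "write_manifest",
]

CALL_COLUMNS = ["read_id", "contig", "position", "strand", "motif", "prob"]
ALIGNMENT_COLUMNS = ["read_id", "contig", "pos", "strand", "mapq", "group_id"]
_FLOAT_FORMAT = "%.6g"


@dataclass(frozen=True)
class TargetSiteAnnotation:
    """One annotated target A in a DRACH context (0-based position)."""

    contig: str
    position: int
    strand: str
    motif: str


def read_target_bed(path) -> list[TargetSiteAnnotation]:
    """Read target-site annotations from a BED6 file.

    Columns: contig, start, end, motif, score, strand. Motifs are
    normalized to the DNA alphabet; lines whose motif is not one of the six
    targets are skipped (count logged). Malformed lines raise ``ValueError``
    naming the line number.
    """
    out: list[TargetSiteAnnotation] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected at least 6 BED columns")
            contig, start, end, name, _score, strand = fields[:6]
            try:
                position = int(start)
                int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: strand must be + or -")
            try:
                motif = normalize_motif(name)
            except ValueError:
                skipped += 1
                continue
            if motif not in SUPPORTED_MOTIFS:
                skipped += 1
                continue
            out.append(TargetSiteAnnotation(contig, position, strand, motif))
    if skipped:
        logger.info("read_target_bed: skipped %d non-target annotations", skipped)
    return out


def write_target_bed(annotations: Iterable[TargetSiteAnnotation], path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.contig}\t{a.position}\t{a.position + 1}\t{a.motif}\t0\t{a.strand}\n")


def write_sites_table(sites: pd.DataFrame, path) -> None:
    """BED-like site table: contig, start, end, motif, stoichiometry, coverage, strand."""
    df = sites.copy()
    df["start"] = df["position"].astype(int)
    df["end"] = df["start"] + 1
    cols = ["contig", "start", "end", "motif", "stoichiometry", "coverage", "strand"]
    df[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_sites_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["position"] = df["start"].astype(int)
    return df[["contig", "position", "strand", "motif", "coverage", "stoichiometry"]]


def write_calls(calls: pd.DataFrame, path) -> None:
    """Read-level calls as TSV (read_id, contig, position, strand, motif, prob)."""
    calls[CALL_COLUMNS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_alignments(alignments: pd.DataFrame, path) -> None:
    alignments[ALIGNMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_alignments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_peaks_bed(path) -> pd.DataFrame:
    """Peak list (e.g. antibody crosslinking peaks) from BED6."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    df["position"] = df["start"].astype(int)
    return df[["contig", "position", "strand", "name"]]


def write_oligo_fasta(oligos: Sequence[Oligo], fasta_path, sidecar_path=None) -> None:
    """Write oligo sequences as FASTA plus a sidecar bookkeeping table."""
    records = [
        SeqRecord(Seq(o.sequence), id=o.oligo_id, description="")
        for o in oligos
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if sidecar_path is not None:
        pd.DataFrame(
            [
                {
                    "oligo_id": o.oligo_id,
                    "central_offset": o.central_offset,
                    "motif": o.motif,
                    "modified": int(o.modified),
                }
                for o in oligos
            ]
        ).to_csv(sidecar_path, sep="\t", index=False)


def read_oligo_fasta(fasta_path, sidecar_path) -> list[Oligo]:
    meta = pd.read_csv(sidecar_path, sep="\t").set_index("oligo_id")
    oligos = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = meta.loc[rec.id]
        oligos.append(
            Oligo(
                oligo_id=rec.id,
                sequence=str(rec.seq),
                motif=row["motif"],
                central_offset=int(row["central_offset"]),
                modified=bool(row["modified"]),
            )
        )
    return oligos


def write_reads_fasta(reads, path) -> None:
    """Write simulated concatemer reads as FASTA."""
    records = [
        SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        for r in reads
    ]
    SeqIO.write(records, str(path), "fasta")


def write_sam(alignments: pd.DataFrame, contig_lengths: dict, path) -> None:
    """Minimal SAM export of alignment records for interoperability.

    Records are written as 1-nt anchors at the site position with mapq
    carried through; sequence and cigar are left undefined.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in contig_lengths.items()],
        "PG": [{"ID": "m6aread", "PN": "m6aread", "VN": __version__}],
    }
    refs = {c: i for i, c in enumerate(contig_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in alignments.itertuples(index=False):
            a = pysam.AlignedSegment(out.header)
            a.query_name = row.read_id
            a.reference_id = refs[row.contig]
            a.reference_start = int(row.pos)
            a.mapping_quality = int(row.mapq)
            a.flag = 0 if row.strand == "+" else 16
            a.cigarstring = "1M"
            a.query_sequence = "N"
            out.write(a)


@dataclass
class RunConfig:
    """Pipeline thresholds and bookkeeping; round-trips through JSON."""

    p_threshold: float = 0.5
    min_coverage: int = 50
    min_mapq: int = 50
    min_identity: float = 0.8
    n_features: int = 768
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_threshold <= 1.0:
            raise ValueError("p_threshold must lie in [0, 1]")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must lie in [0, 1]")
        if self.min_coverage < 0 or self.min_mapq < 0:
            raise ValueError("min_coverage and min_mapq must be non-negative")
        if self.n_features < 2:
            raise ValueError("n_features must be at least 2")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def write_manifest(path, command: str, params: dict) -> None:
    """Machine-readable run manifest: tool version plus the full parameter set."""
    manifest = {
        "tool": "m6aread",
        "version": __version__,
        "command": command,
        "params": {k: params[k] for k in sorted(params)},
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
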