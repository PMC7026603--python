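"""FASTA/BED/TSV readers and writers plus flat config serialisation.

All file coordinates are 0-based half-open (BED dialect).  Every output
file written by the CLI embeds the package version and a hash of the
grammar configuration in comment headers for provenance.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import ConsensusModel, InvalidSequenceError
from .scanner import CompositeSite, MotifMatch, SiteCluster, bed_score

__all__ = [
    "read_fasta",
    "write_fasta",
    "BedRecord",
    "read_bed",
    "write_bed",
    "matches_to_bed",
    "sites_to_frame",
    "clusters_to_frame",
    "write_tsv",
    "write_config",
    "read_config",
    "config_hash",
]

_FASTA_ALPHABET = set("ACGTRYSWKMBDHVN")


def read_fasta(path) -> list[tuple[str, str]]:
    """Ordered (id, sequence) records; sequences uppercased and IUPAC-validated."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for i, base in enumerate(seq):
            if base not in _FASTA_ALPHABET:
                raise InvalidSequenceError(
                    f"invalid character {base!r} at position {i + 1} of record "
                    f"{rec.id!r} in {path}"
                )
        records.append((rec.id, seq))
    return records


def write_fasta(records, path, header_lines: list[str] | None = None) -> None:
    """Write (id, sequence) pairs as FASTA (comment headers prepended)."""
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines or []:
            fh.write(f";{line}\n")
        SeqIO.write(
            (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
            fh,
            "fasta",
        )


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"BED interval must satisfy start < end, got [{self.start}, {self.end})"
            )


def write_bed(records, path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}\n")


def read_bed(path) -> list[BedRecord]:
    records = []
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {ln} of {path}: expected >= 3 BED columns")
            records.append(
                BedRecord(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    name=parts[3] if len(parts) > 3 else ".",
                    score=int(parts[4]) if len(parts) > 4 else 0,
                    strand=parts[5] if len(parts) > 5 else ".",
                )
            )
    return records


def matches_to_bed(matches: list[MotifMatch], model: ConsensusModel) -> list[BedRecord]:
    """BED6 for heptamer matches: name = mismatch signature, score = scaled penalty."""
    return [
        BedRecord(
            chrom=m.sequence_id,
            start=m.start,
            end=m.end,
            name=m.signature,
            score=bed_score(m.penalty, model),
            strand=m.strand,
        )
        for m in matches
    ]


_SITE_COLUMNS = [
    "seq_id", "start", "end", "spacer", "spacing_class", "orientation_class",
    "total_mismatches", "total_penalty", "affinity_class", "flags",
]


def sites_to_frame(sites: list[CompositeSite]) -> pd.DataFrame:
    rows = [
        {
            "seq_id": s.sequence_id,
            "start": s.start,
            "end": s.end,
            "spacer": s.spacer,
            "spacing_class": s.spacing_class,
            "orientation_class": s.orientation_class,
            "total_mismatches": s.total_mismatches,
            "total_penalty": s.total_penalty,
            "affinity_class": s.affinity_class,
            "flags": ";".join(s.flags) or ".",
        }
        for s in sites
    ]
    return pd.DataFrame(rows, columns=_SITE_COLUMNS)


def clusters_to_frame(clusters: list[SiteCluster]) -> pd.DataFrame:
    rows = [
        {
            "seq_id": c.sequence_id,
            "start": c.start,
            "end": c.end,
            "n_sites": len(c.sites),
            "score": c.score,
            "affinity_class": c.affinity_class,
            "flags": ";".join(c.flags) or ".",
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=["seq_id", "start", "end", "n_sites", "score", "affinity_class", "flags"],
    )


def write_tsv(frame: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_config(model: ConsensusModel, path) -> None:
    """Serialise grammar parameters as a flat key = value (TOML) file."""
    with Path(path).open("w") as fh:
        for key, value in model.to_config().items():
            fh.write(f'{key} = "{value}"\n')


def read_config(path) -> ConsensusModel:
    """Read a flat config file back into a :class:`ConsensusModel`.

    Unknown keys are rejected; the round trip through
    :func:`write_config` is lossless.
    """
    raw = tomllib.loads(Path(path).read_text())
    return ConsensusModel.from_config({k: str(v) for k, v in raw.items()})


def config_hash(model: ConsensusModel) -> str:
    canonical = ";".join(f"{k}={v}" for k, v in sorted(model.to_config().items()))
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
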