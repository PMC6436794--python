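"""Shared file I/O and run configuration.

FASTA/FASTQ goes through Biopython (gzip-aware); tables are TSV with a
header and stable column order; calibration and summaries are JSON.
Fractions are reported to 4 decimals everywhere.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "RunConfig",
    "FastqRead",
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "write_fastq",
    "write_tsv",
    "read_tsv",
    "write_json",
    "read_manifest",
]


@dataclass
class RunConfig:
    """All tunable pipeline parameters, serialisable to/from YAML.

    Defaults reflect the assay's fixed-length 135 nt insert and
    conservative error handling; see docs/methods.md for rationale.
    """

    primer_mismatch: int = 2          # IUPAC-aware mismatches allowed when trimming read primers
    length_tolerance: int = 10        # nt slack around the expected insert length
    min_overlap: int = 20             # minimum mate overlap for merging
    max_overlap_mismatch: float = 0.1  # max mismatch fraction inside the overlap
    denoise_error_rate: float = 0.001  # per-base substitution rate e
    denoise_alpha: float = 1e-6       # Poisson tail threshold for absorbing minors
    chimera_fold: float = 2.0         # parent abundance multiple required to call a chimera
    novel_max: int = 2                # max nt distance for a "novel" haplotype call
    divergence_floor_fraction: float = 0.10  # below-cutoff flagging needs > this fraction of insert length
    ntc_max_reads: int = 0            # verified reads tolerated in a no-template control
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.denoise_error_rate < 0.1):
            raise ValueError("denoise_error_rate must be in (0, 0.1)")
        if not (0 < self.denoise_alpha < 1):
            raise ValueError("denoise_alpha must be in (0, 1)")
        if self.primer_mismatch < 0 or self.length_tolerance < 0 or self.ntc_max_reads < 0:
            raise ValueError("counts must be non-negative")
        if not (0 <= self.max_overlap_mismatch < 1):
            raise ValueError("max_overlap_mismatch must be in [0, 1)")
        if self.chimera_fold < 1:
            raise ValueError("chimera_fold must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass(frozen=True)
class FastqRead:
    id: str
    sequence: str
    quality: str  # phred+33

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.id!r}: sequence/quality length mismatch")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA as an ordered id -> uppercase sequence mapping.

    The whole header line (minus ``>``) is the id: panel records use
    ``species|label|segment`` ids whose species names contain spaces.
    """
    with _open_text(path) as fh:
        return {rec.description: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


def _read_fastq(path: str | Path) -> Iterator[FastqRead]:
    with _open_text(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
            quals = rec.letter_annotations["phred_quality"]
            yield FastqRead(rec.id, str(rec.seq).upper(), "".join(chr(q + 33) for q in quals))


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple[FastqRead, FastqRead]]:
    """Iterate synchronised mate pairs from two (optionally gzipped) FASTQs."""
    it1, it2 = _read_fastq(r1_path), _read_fastq(r2_path)
    for r1 in it1:
        try:
            r2 = next(it2)
        except StopIteration:
            raise ValueError(f"{r2_path} has fewer records than {r1_path}") from None
        yield r1, r2
    if next(it2, None) is not None:
        raise ValueError(f"{r2_path} has more records than {r1_path}")


def write_fastq(path: str | Path, reads: list[FastqRead]) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def write_tsv(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


MANIFEST_COLUMNS = ["sample_id", "role", "fastq_r1", "fastq_r2", "spacer_f", "spacer_r"]
MANIFEST_ROLES = {"sample", "positive_control", "ntc"}


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Sample manifest TSV; validates required columns and roles."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing column(s): {', '.join(missing)}")
    bad = set(df["role"]) - MANIFEST_ROLES
    if bad:
        raise ValueError(f"manifest has invalid role(s): {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"manifest has duplicate sample_id(s): {dupes}")
    return df
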