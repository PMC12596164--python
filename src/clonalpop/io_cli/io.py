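"""FASTA and tabular readers/writers plus the packaged sampling-table fixture."""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingRecord",
    "read_fasta",
    "write_fasta",
    "parse_sampling_table",
    "packaged_sampling_table",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, upper-cased sequence) tuples.

    Duplicate ids and empty files are errors; mixed-case input is
    upper-cased with a logged notice.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    mixed_case = False
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        if seq != seq.upper():
            mixed_case = True
        records.append((rec.id, seq.upper()))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if mixed_case:
        logger.info("%s: lower-case residues upper-cased", path)
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) tuples as 60-column-wrapped FASTA."""
    if not records:
        raise ValueError("no records to write")
    seqs = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


# ---------------------------------------------------------------------------
# sampling-table fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingRecord:
    """One sampling event: label, physico-chemical readings, isolate counts.

    Missing values ("ND" in the source table) are ``None``.  DNA/RNA-only
    samplings have missing isolate counts and contribute 0 to totals.
    """

    label: str
    temperature_c: float | None
    salinity_ppt: float | None
    ph: float | None
    oxygen_mg_l: float | None
    isolates_obtained: int | None
    isolates_sequenced: int | None

    def __post_init__(self) -> None:
        if (
            self.isolates_obtained is not None
            and self.isolates_sequenced is not None
            and self.isolates_sequenced > self.isolates_obtained
        ):
            raise ValueError(
                f"{self.label}: sequenced count {self.isolates_sequenced} exceeds "
                f"obtained count {self.isolates_obtained}"
            )


_EXPECTED_HEADER = [
    "label",
    "temperature_c",
    "salinity_ppt",
    "ph",
    "oxygen_mg_l",
    "obtained",
    "sequenced",
]


def packaged_sampling_table() -> Path:
    """Path to the packaged sampling-table fixture."""
    return Path(str(resources.files("clonalpop.io_cli") / "data" / "sampling_table.csv"))


def _parse_cell(raw: str, label: str, column: str, kind):
    raw = raw.strip()
    if raw in ("", "ND", "NA"):
        return None
    try:
        return kind(raw)
    except ValueError as exc:
        raise ValueError(f"row {label!r}: malformed {column} value {raw!r}") from exc


def parse_sampling_table(
    path: str | Path | None = None,
) -> tuple[list[SamplingRecord], tuple[int, int]]:
    """Parse a sampling table CSV; defaults to the packaged fixture.

    Returns the records plus (total obtained, total sequenced); rows with
    missing counts contribute 0 to the totals.
    """
    path = packaged_sampling_table() if path is None else Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _EXPECTED_HEADER:
            raise ValueError(
                f"{path}: header {reader.fieldnames} does not match {_EXPECTED_HEADER}"
            )
        records: list[SamplingRecord] = []
        for row in reader:
            label = row["label"].strip()
            if not label:
                raise ValueError(f"{path}: row with empty label")
            records.append(
                SamplingRecord(
                    label=label,
                    temperature_c=_parse_cell(row["temperature_c"], label, "temperature_c", float),
                    salinity_ppt=_parse_cell(row["salinity_ppt"], label, "salinity_ppt", float),
                    ph=_parse_cell(row["ph"], label, "ph", float),
                    oxygen_mg_l=_parse_cell(row["oxygen_mg_l"], label, "oxygen_mg_l", float),
                    isolates_obtained=_parse_cell(row["obtained"], label, "obtained", int),
                    isolates_sequenced=_parse_cell(row["sequenced"], label, "sequenced", int),
                )
            )
    if not records:
        raise ValueError(f"{path}: empty sampling table")
    total_obtained = sum(r.isolates_obtained or 0 for r in records)
    total_sequenced = sum(r.isolates_sequenced or 0 for r in records)
    return records, (total_obtained, total_sequenced)
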