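"""Reference, read and table IO for small-RNA 3'-end analysis.

All sequences are stored in the RNA alphabet (ACGU); DNA input (T) is
normalized on load. 3'-end coordinates are expressed as *offsets* relative
to the canonical 3' end of the mature small RNA: offset 0 is the last base
of the mature sequence, offset +k is the k-th base of the downstream
genomic context, and negative offsets denote trimmed (shortened) ends.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

TAIL_CLASSES = ("none", "monoA", "oligoA", "monoU", "oligoU", "U_then_A", "other")
CALL_STATUSES = ("called", "no_adapter", "unmatched", "ambiguous_ref")

TAIL_CALL_COLUMNS = [
    "read_id", "ref_id", "end_offset", "tail_seq", "tail_class", "n_mismatch", "status",
]
PROFILE_COLUMNS = [
    "ref_id", "sample_id", "end_offset", "tail_class", "tail_len", "count", "fraction",
]


class ReferenceError(ValueError):
    """A reference record violates a stated invariant."""


def normalize_rna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase and convert T->U; reject characters outside ACGUT."""
    s = str(seq).upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ReferenceError(
            f"{context}: invalid characters {sorted(bad)} (alphabet is ACGU/ACGT)"
        )
    return s


@dataclasses.dataclass(frozen=True)
class ReferenceRecord:
    """One annotated small RNA.

    Parameters
    ----------
    ref_id : str
        Unique identifier.
    ref_class : {"miRNA", "snRNA"}
    mature_seq : str
        Mature sequence, 5'->3', RNA alphabet, length >= 15.
    downstream_seq : str
        Genomic bases immediately 3' of the canonical end (>= 8 nt
        recommended); the templated context that creates genomic/tail
        ambiguity at the 3' boundary.
    boundary_offset : int or None
        For snRNA: offset (canonical-end convention) of the uridine
        labelled "+1U", adjacent to the Lsm2-8 site.
    partner_id : str or None
        The paired arm for guide/passenger analysis.
    arm_role : {"guide", "passenger", "none"}
    """

    ref_id: str
    ref_class: str
    mature_seq: str
    downstream_seq: str
    boundary_offset: int | None = None
    partner_id: str | None = None
    arm_role: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mature_seq", normalize_rna(self.mature_seq, context=f"{self.ref_id} mature_seq")
        )
        object.__setattr__(
            self,
            "downstream_seq",
            normalize_rna(self.downstream_seq, context=f"{self.ref_id} downstream_seq"),
        )
        if self.ref_class not in ("miRNA", "snRNA"):
            raise ReferenceError(f"{self.ref_id}: unknown ref_class {self.ref_class!r}")
        if len(self.mature_seq) < 15:
            raise ReferenceError(
                f"{self.ref_id}: mature_seq length {len(self.mature_seq)} < 15"
            )
        if self.arm_role not in ("guide", "passenger", "none"):
            raise ReferenceError(f"{self.ref_id}: unknown arm_role {self.arm_role!r}")

    @property
    def template(self) -> str:
        """Mature sequence plus downstream genomic context (the templated space)."""
        return self.mature_seq + self.downstream_seq

    def end_label(self, end_offset: int) -> str:
        """Human-readable end label; snRNA ends at/past the Lsm boundary get '+nU' labels."""
        if self.boundary_offset is not None:
            n = end_offset - self.boundary_offset + 1
            if n >= 1:
                return f"+{n}U"
        return str(end_offset)


@dataclasses.dataclass(frozen=True)
class ReadRecord:
    read_id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


# ---------------------------------------------------------------------------
# reference sets

ANNOTATION_COLUMNS = [
    "ref_id", "ref_class", "downstream_seq", "boundary_offset", "partner_id", "arm_role",
]


def load_reference_set(fasta_path, annotation_tsv_path) -> dict[str, ReferenceRecord]:
    """Load mature sequences (FASTA) joined with their annotation (TSV).

    The TSV columns are: ref_id, ref_class, downstream_seq, boundary_offset
    (empty allowed), partner_id (empty allowed), arm_role. Every FASTA record
    must have an annotation row; partner links must be symmetric.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    annot = pd.read_csv(annotation_tsv_path, sep="\t", dtype=str).fillna("")
    missing_cols = set(ANNOTATION_COLUMNS) - set(annot.columns)
    if missing_cols:
        raise ReferenceError(f"annotation TSV lacks columns {sorted(missing_cols)}")
    annot = annot.set_index("ref_id", drop=False)
    if annot.index.has_duplicates:
        dup = annot.index[annot.index.duplicated()].tolist()
        raise ReferenceError(f"duplicate annotation rows for {dup}")

    records: dict[str, ReferenceRecord] = {}
    for ref_id, seq in seqs.items():
        if ref_id not in annot.index:
            raise ReferenceError(f"FASTA record {ref_id!r} has no annotation row")
        row = annot.loc[ref_id]
        boundary = row["boundary_offset"]
        records[ref_id] = ReferenceRecord(
            ref_id=ref_id,
            ref_class=row["ref_class"],
            mature_seq=seq,
            downstream_seq=row["downstream_seq"],
            boundary_offset=int(boundary) if boundary != "" else None,
            partner_id=row["partner_id"] or None,
            arm_role=row["arm_role"] or "none",
        )
    validate_reference_set(records)
    return records


def validate_reference_set(records: Mapping[str, ReferenceRecord]) -> None:
    """Check partner symmetry across a loaded reference set."""
    for rec in records.values():
        if rec.partner_id is None:
            continue
        partner = records.get(rec.partner_id)
        if partner is None:
            raise ReferenceError(
                f"{rec.ref_id}: partner_id {rec.partner_id!r} not in reference set"
            )
        if partner.partner_id != rec.ref_id:
            raise ReferenceError(
                f"{rec.ref_id}: partner {rec.partner_id!r} does not point back"
            )


def write_reference_set(records: Mapping[str, ReferenceRecord], fasta_path, annotation_tsv_path) -> None:
    with open(fasta_path, "w") as fh:
        for rec in records.values():
            fh.write(f">{rec.ref_id}\n{rec.mature_seq}\n")
    rows = []
    for rec in records.values():
        rows.append({
            "ref_id": rec.ref_id,
            "ref_class": rec.ref_class,
            "downstream_seq": rec.downstream_seq,
            "boundary_offset": "" if rec.boundary_offset is None else rec.boundary_offset,
            "partner_id": rec.partner_id or "",
            "arm_role": rec.arm_role,
        })
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        annotation_tsv_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# reads

def load_reads(fastq_path) -> Iterator[ReadRecord]:
    """Lazily yield reads from a FASTQ file, normalized to the RNA alphabet.

    Raises on truncated records (FASTQ must be 4-line records) and on
    quality strings shorter than the sequence.
    """
    with open(fastq_path) as fh:
        index = 0
        while True:
            header = fh.readline()
            if not header:
                return
            if not header.startswith("@"):
                raise ValueError(f"FASTQ record {index}: malformed header {header!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+") or not seq:
                raise ValueError(f"FASTQ record {index}: truncated record")
            if len(qual) != len(seq):
                raise ValueError(
                    f"FASTQ record {index}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            yield ReadRecord(
                read_id=header[1:].split()[0],
                seq=seq.upper().replace("T", "U"),
                qual=qual,
            )
            index += 1


def write_reads(reads: Iterable[ReadRecord], fastq_path) -> None:
    with open(fastq_path, "w") as fh:
        for read in reads:
            qual = read.qual if read.qual is not None else "I" * len(read.seq)
            fh.write(f"@{read.read_id}\n{read.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# tail-call and profile tables

def write_tail_calls(calls, tsv_path) -> None:
    """Write tail calls (DataFrame or iterable of TailCall-likes) as TSV."""
    df = calls if isinstance(calls, pd.DataFrame) else pd.DataFrame(
        [dataclasses.asdict(c) if dataclasses.is_dataclass(c) else c._asdict() for c in calls]
    )
    if df.empty:
        df = pd.DataFrame(columns=TAIL_CALL_COLUMNS)
    df = df[TAIL_CALL_COLUMNS]
    df.to_csv(tsv_path, sep="\t", index=False)


def load_tail_calls(tsv_path) -> pd.DataFrame:
    df = pd.read_csv(
        tsv_path, sep="\t",
        dtype={"read_id": str, "ref_id": str, "tail_seq": str,
               "tail_class": str, "status": str},
        keep_default_na=False,
    )
    df["end_offset"] = df["end_offset"].astype(int)
    df["n_mismatch"] = df["n_mismatch"].astype(int)
    return df[TAIL_CALL_COLUMNS]


def write_profile(profile, tsv_path) -> None:
    """Write an EndProfile as a TSV; fractions formatted to 6 decimal places."""
    df = profile.to_frame()
    df = df.copy()
    df["fraction"] = df["fraction"].map(lambda x: f"{x:.6f}")
    df.to_csv(tsv_path, sep="\t", index=False)


def load_profile(tsv_path):
    from .profiles import EndProfile  # local import: avoid cycle

    df = pd.read_csv(tsv_path, sep="\t", dtype={"ref_id": str, "sample_id": str,
                                                "tail_class": str}, keep_default_na=False)
    for col in ("end_offset", "tail_len", "count"):
        df[col] = df[col].astype(int)
    df["fraction"] = df["fraction"].astype(float)
    return EndProfile.from_frame(df)


# ---------------------------------------------------------------------------
# count tables

def load_count_table(tsv_path) -> pd.DataFrame:
    """Counts with ref_id rows and sample columns; validates nonnegativity."""
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    validate_count_table(df)
    return df


def validate_count_table(df: pd.DataFrame) -> None:
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("count table has duplicate row or column labels")
    if (df.to_numpy() < 0).any():
        raise ValueError("count table has negative cells")


def write_count_table(df: pd.DataFrame, tsv_path) -> None:
    validate_count_table(df)
    df.to_csv(tsv_path, sep="\t")
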