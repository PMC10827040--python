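"""Decompose small-RNA reads into templated body and non-templated 3' tail.

A read is modelled as ``insert + adapter``; the insert is a 5'-anchored copy
of a mature small RNA that may extend into the downstream genomic context
(templated extension) and may carry post-transcriptionally added 3'
nucleotides (the tail). The decomposition is *templated-maximal*: a
3'-terminal base that could equally be genomic or added is counted genomic.
Under this convention a miR-125a-5p read ending ...GUGA is a genomic end
(the A is encoded downstream), while ...GUGAA carries a one-base A tail;
the end-offset histogram retains the information needed to treat the
templated single-A end as functionally adenylated (see
``profiles.summarize_profile`` mode ``"adenylated-inclusive"``).

Tail classes: none, monoA (exactly "A"), oligoA (>=2 A's), monoU, oligoU,
U_then_A (>=1 U then >=1 A, the oligoU+A substrate shape), other.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Mapping

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .refio import ReadRecord, ReferenceRecord, TAIL_CALL_COLUMNS

# no mismatch tolerated this close to the templated 3' terminus: the
# boundary decides the call, so it must be exact
_TERMINAL_EXACT = 4
# trimmed species window: ends shortened by up to 3 nt are still called
_MAX_TRIM = 3
_MIN_INSERT = 15


@dataclasses.dataclass(frozen=True)
class TailCall:
    """Per-read decomposition into templated end offset + non-templated tail."""

    read_id: str
    ref_id: str
    end_offset: int
    tail_seq: str
    tail_class: str
    n_mismatch: int
    status: str

    def _asdict(self) -> dict:
        return dataclasses.asdict(self)


def classify_tail(tail_seq: str) -> str:
    """Map any tail string to exactly one tail class."""
    if not tail_seq:
        return "none"
    n = len(tail_seq)
    n_a_suffix = 0
    while n_a_suffix < n and tail_seq[n - 1 - n_a_suffix] == "A":
        n_a_suffix += 1
    n_u_prefix = 0
    while n_u_prefix < n and tail_seq[n_u_prefix] == "U":
        n_u_prefix += 1
    if n_a_suffix == n:
        return "monoA" if n == 1 else "oligoA"
    if n_u_prefix == n:
        return "monoU" if n == 1 else "oligoU"
    if n_u_prefix >= 1 and n_u_prefix + n_a_suffix == n:
        return "U_then_A"
    return "other"


def trim_adapter(
    read_seq: str, adapter_seq: str, *, min_overlap: int = 6, max_mismatch: int = 1
) -> tuple[str, str]:
    """Remove the 3' adapter from a read sequence.

    Scans 5'->3' from position 15 for the earliest occurrence of an adapter
    prefix of length >= ``min_overlap`` with <= ``max_mismatch``
    substitutions. Returns ``(insert, status)`` where status is ``"called"``
    on success and ``"no_adapter"`` when the read ends without one (the full
    read is returned as the insert, still eligible for calling).
    """
    if len(adapter_seq) < min_overlap:
        raise ValueError("adapter_seq shorter than min_overlap")
    for i in range(_MIN_INSERT, len(read_seq) - min_overlap + 1):
        overlap = min(len(adapter_seq), len(read_seq) - i)
        mm = 0
        for a, b in zip(read_seq[i : i + overlap], adapter_seq[:overlap]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return read_seq[:i], "called"
    return read_seq, "no_adapter"


def _max_templated(insert: str, template: str, mature_len: int, max_mismatch: int) -> tuple[int, int]:
    """Greedy maximal templated match length and mismatch count.

    Mismatches are allowed only within the mature body (never in the
    downstream extension), up to ``max_mismatch`` total and never within the
    final ``_TERMINAL_EXACT`` bases of the final match (backtracked if the
    match ends too soon after a consumed mismatch).
    """
    n = min(len(insert), len(template))
    length = 0
    mm_positions: list[int] = []
    while length < n:
        if insert[length] == template[length]:
            length += 1
        elif length < mature_len and len(mm_positions) < max_mismatch:
            mm_positions.append(length)
            length += 1
        else:
            break
    while mm_positions and mm_positions[-1] >= length - _TERMINAL_EXACT:
        length = mm_positions.pop()
    return length, len(mm_positions)


def call_tail(
    insert: str,
    reference: ReferenceRecord,
    *,
    max_mismatch: int = 1,
    read_id: str = "",
) -> TailCall:
    """Call the templated end offset and non-templated tail of one insert.

    The insert's 5' end must match the mature sequence (<= ``max_mismatch``
    substitutions in the mature body, none in the final matched bases or the
    downstream extension); the match is extended 3'-ward as far as bases
    agree, and the remaining suffix is the tail. Inserts ending up to 3 nt
    short of the canonical end with no tail are called with negative offsets
    (trimmed species); anything shorter, or a truncated match with leftover
    sequence, is ``unmatched``.
    """
    ref_id = reference.ref_id
    if len(insert) < _MIN_INSERT:
        return TailCall(read_id, ref_id, 0, "", "none", 0, "unmatched")
    mature_len = len(reference.mature_seq)
    length, n_mismatch = _max_templated(insert, reference.template, mature_len, max_mismatch)
    tail = insert[length:]
    if length >= mature_len:
        return TailCall(
            read_id, ref_id, length - mature_len, tail, classify_tail(tail),
            n_mismatch, "called",
        )
    if length >= mature_len - _MAX_TRIM and not tail:
        return TailCall(read_id, ref_id, length - mature_len, "", "none", n_mismatch, "called")
    return TailCall(read_id, ref_id, 0, "", "none", 0, "unmatched")


def _prefix_match_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def assign_reference(
    insert: str, references: Mapping[str, ReferenceRecord], *, min_anchor: int = 12
) -> tuple[str | None, str]:
    """Assign an insert to the reference with the longest exact 5'-anchored match.

    Returns ``(ref_id, "called")``; ``(None, "ambiguous_ref")`` on a tie;
    ``(None, "unmatched")`` when no reference matches >= ``min_anchor`` bases.
    """
    best_len = -1
    best_id: str | None = None
    tie = False
    for ref in references.values():
        m = _prefix_match_len(insert, ref.mature_seq)
        if m > best_len:
            best_len, best_id, tie = m, ref.ref_id, False
        elif m == best_len:
            tie = True
    if best_len < min_anchor:
        return None, "unmatched"
    if tie:
        return None, "ambiguous_ref"
    return best_id, "called"


def call_sample(
    reads: Iterable[ReadRecord],
    references: Mapping[str, ReferenceRecord],
    *,
    adapter_seq: str | None = None,
    max_mismatch: int = 1,
    min_overlap: int = 6,
    min_anchor: int = 12,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Trim, assign and tail-call a whole sample.

    Returns the tail-call table (one row per read) and a status summary.
    Reads without a recognizable adapter keep their call fields when callable
    but are flagged ``no_adapter``; ties between references are
    ``ambiguous_ref`` and excluded from downstream profiles.
    """
    if not references:
        raise ValueError("empty reference set")
    rows: list[tuple] = []
    status_counts: Counter[str] = Counter()
    for read in reads:
        if adapter_seq is not None:
            insert, trim_status = trim_adapter(
                read.seq, adapter_seq, min_overlap=min_overlap, max_mismatch=max_mismatch
            )
        else:
            insert, trim_status = read.seq, "called"
        ref_id, assign_status = assign_reference(insert, references, min_anchor=min_anchor)
        if ref_id is None:
            rows.append((read.read_id, "", 0, "", "none", 0, assign_status))
            status_counts[assign_status] += 1
            continue
        call = call_tail(
            insert, references[ref_id], max_mismatch=max_mismatch, read_id=read.read_id
        )
        status = call.status
        if status == "called" and trim_status == "no_adapter":
            status = "no_adapter"
        rows.append((
            read.read_id, call.ref_id, call.end_offset, call.tail_seq,
            call.tail_class, call.n_mismatch, status,
        ))
        status_counts[status] += 1
    calls = pd.DataFrame(rows, columns=TAIL_CALL_COLUMNS)
    return calls, dict(status_counts)


class TailCaller(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping reads to a tail-call table.

    Parameters mirror :func:`call_sample`; ``transform`` accepts an iterable
    of :class:`~srnatail.refio.ReadRecord` and returns the call DataFrame.
    Composes with sklearn pipelines; ``fit`` is a no-op.
    """

    def __init__(
        self,
        references: Mapping[str, ReferenceRecord] | None = None,
        adapter_seq: str | None = None,
        max_mismatch: int = 1,
        min_overlap: int = 6,
        min_anchor: int = 12,
    ):
        self.references = references
        self.adapter_seq = adapter_seq
        self.max_mismatch = max_mismatch
        self.min_overlap = min_overlap
        self.min_anchor = min_anchor

    def fit(self, X=None, y=None):
        if not self.references:
            raise ValueError("empty reference set")
        self.n_references_ = len(self.references)
        return self

    def transform(self, X: Iterable[ReadRecord]) -> pd.DataFrame:
        calls, counts = call_sample(
            X,
            self.references,
            adapter_seq=self.adapter_seq,
            max_mismatch=self.max_mismatch,
            min_overlap=self.min_overlap,
            min_anchor=self.min_anchor,
        )
        self.status_counts_ = counts
        return calls
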