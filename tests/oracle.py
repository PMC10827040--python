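"""Independent brute-force oracle for the tail decomposition.

Enumerates every split of an insert into (templated prefix along
mature+downstream, suffix), keeps the splits satisfying the mismatch policy
by direct position-wise comparison, and selects the longest templated
prefix. Classification goes through regexes. Deliberately quadratic and
declarative — shares no code path with srnatail.calling.
"""

import re

_CLASS_PATTERNS = [
    ("monoA", re.compile(r"\AA\Z")),
    ("oligoA", re.compile(r"\AA{2,}\Z")),
    ("monoU", re.compile(r"\AU\Z")),
    ("oligoU", re.compile(r"\AU{2,}\Z")),
    ("U_then_A", re.compile(r"\AU+A+\Z")),
]


def classify_regex(tail: str) -> str:
    if tail == "":
        return "none"
    for name, pat in _CLASS_PATTERNS:
        if pat.match(tail):
            return name
    return "other"


def random_insert(rng, ref, max_len: int = 40) -> str:
    """Random insert biased toward realistic reads: reference prefix + tail, with noise."""
    kind = rng.integers(0, 4)
    template = ref.mature_seq + ref.downstream_seq
    if kind == 0:  # pure random
        length = int(rng.integers(15, max_len + 1))
        return "".join(rng.choice(list("ACGU"), size=length))
    end = int(rng.integers(len(ref.mature_seq) - 4, len(template) + 1))
    insert = template[:end]
    if kind >= 2:  # add a tail
        tail_len = int(rng.integers(1, 7))
        insert += "".join(rng.choice(list("AUAUCG"), size=tail_len))
    if kind == 3:  # sprinkle 1-2 substitutions
        chars = list(insert)
        for pos in rng.choice(len(chars), size=int(rng.integers(1, 3)), replace=False):
            chars[pos] = str(rng.choice([b for b in "ACGU" if b != chars[pos]]))
        insert = "".join(chars)
    return insert[:max_len]


def oracle_call(insert: str, ref, max_mismatch: int = 1):
    """Return (status, end_offset, tail_seq, tail_class, n_mismatch)."""
    mature_len = len(ref.mature_seq)
    template = ref.mature_seq + ref.downstream_seq
    if len(insert) < 15:
        return ("unmatched", 0, "", "none", 0)
    best = (0, 0)
    for length in range(0, min(len(insert), len(template)) + 1):
        mism = [i for i in range(length) if insert[i] != template[i]]
        if len(mism) > max_mismatch:
            continue
        if any(i >= mature_len for i in mism):
            continue
        if any(i >= length - 4 for i in mism):
            continue
        if length >= best[0]:
            best = (length, len(mism))
    length, n_mismatch = best
    tail = insert[length:]
    if length >= mature_len:
        return ("called", length - mature_len, tail, classify_regex(tail), n_mismatch)
    if length >= mature_len - 3 and tail == "":
        return ("called", length - mature_len, "", "none", n_mismatch)
    return ("unmatched", 0, "", "none", 0)
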