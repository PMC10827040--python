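"""Aggregate tail calls into 3'-end profiles and condition-level summaries.

An :class:`EndProfile` is the per-reference joint distribution over
(end offset, tail class, tail length) observed in one sample. Summaries
expose the three views used in the field: tail-class fractions with an
A-tail length histogram, the end-position distribution (snRNA ends labelled
"+nU" relative to the Lsm boundary), and the "adenylated-inclusive" view in
which a templated single-A end (the GUG -> GUGA situation, where the extra A
is genomically encoded) is pooled with non-templated A tails into one
A-ended category.

Condition comparisons follow the common reporting convention for replicated
end profiles: per-replicate fractions summarized as mean +/- SD, compared by
Welch's t-test (this package's choice; degenerate zero-variance cases return
p=1 with a warning). Guide/passenger asymmetry is a per-pair difference of
log2 fold changes tested with a Wilcoxon signed-rank test.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .refio import PROFILE_COLUMNS, ReferenceRecord

TAIL_LEN_CAP = 10  # longer tails are binned as "10+" in histograms


@dataclasses.dataclass
class EndProfile:
    """Per-reference joint (end_offset, tail_class, tail_len) -> count distribution."""

    ref_id: str
    sample_id: str
    counts: pd.Series  # MultiIndex (end_offset, tail_class, tail_len) -> int

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def empty(self) -> bool:
        return self.total == 0

    @property
    def fractions(self) -> pd.Series:
        if self.empty:
            raise ValueError(f"profile {self.ref_id}/{self.sample_id} is empty")
        return self.counts / self.total

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.rename("count").reset_index()
        df.insert(0, "sample_id", self.sample_id)
        df.insert(0, "ref_id", self.ref_id)
        df["fraction"] = 0.0 if self.empty else df["count"] / self.total
        return df[PROFILE_COLUMNS]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EndProfile":
        ref_id = df["ref_id"].iloc[0] if len(df) else ""
        sample_id = df["sample_id"].iloc[0] if len(df) else ""
        counts = df.set_index(["end_offset", "tail_class", "tail_len"])["count"]
        return cls(ref_id=ref_id, sample_id=sample_id, counts=counts)


def build_profile(tail_calls: pd.DataFrame, ref: ReferenceRecord, sample_id: str) -> EndProfile:
    """Aggregate called reads for one reference into an end profile.

    Input is filtered to ``status == "called"`` and ``ref_id == ref.ref_id``;
    counts are exact, fractions are count/total.
    """
    if tail_calls.empty:
        sub = tail_calls
    else:
        sub = tail_calls[
            (tail_calls["status"] == "called") & (tail_calls["ref_id"] == ref.ref_id)
        ]
    if sub.empty:
        counts = pd.Series(
            [], dtype=int,
            index=pd.MultiIndex.from_arrays([[], [], []],
                                            names=["end_offset", "tail_class", "tail_len"]),
        )
        return EndProfile(ref_id=ref.ref_id, sample_id=sample_id, counts=counts)
    tail_len = sub["tail_seq"].str.len().fillna(0).astype(int)
    grouped = (
        sub.assign(tail_len=tail_len)
        .groupby(["end_offset", "tail_class", "tail_len"])
        .size()
        .sort_index()
    )
    return EndProfile(ref_id=ref.ref_id, sample_id=sample_id, counts=grouped)


def summarize_profile(
    profile: EndProfile,
    mode: str = "tail",
    *,
    ref: ReferenceRecord | None = None,
):
    """Summary fractions for one profile.

    mode="tail"
        fractions over {genomic, monoA, oligoA, U_containing, other} plus an
        A-tail length histogram over pure-A tails (capped at 10, binned "10+").
    mode="endpos"
        distribution over end offsets; labelled "+nU" when ``ref`` carries a
        Lsm boundary offset.
    mode="adenylated-inclusive"
        pools the templated single-A end (offset +1 whose templated base is
        A, no tail) with monoA/oligoA tails into "A_ended"; requires ``ref``.
    """
    if profile.empty:
        raise ValueError("cannot summarize an empty profile")
    frac = profile.fractions

    if mode == "tail":
        by_class = frac.groupby(level="tail_class").sum()
        get = lambda c: float(by_class.get(c, 0.0))
        fractions = pd.Series({
            "genomic": get("none"),
            "monoA": get("monoA"),
            "oligoA": get("oligoA"),
            "U_containing": get("monoU") + get("oligoU") + get("U_then_A"),
            "other": get("other"),
        })
        a_counts = profile.counts[
            profile.counts.index.get_level_values("tail_class").isin(["monoA", "oligoA"])
        ]
        lengths = a_counts.index.get_level_values("tail_len")
        binned = pd.Series(a_counts.values, index=[
            str(l) if l < TAIL_LEN_CAP else f"{TAIL_LEN_CAP}+" for l in lengths
        ]).groupby(level=0).sum()
        return {"fractions": fractions, "a_tail_length_hist": binned}

    if mode == "endpos":
        by_end = frac.groupby(level="end_offset").sum().sort_index()
        if ref is not None:
            by_end.index = [ref.end_label(o) for o in by_end.index]
        return by_end

    if mode == "adenylated-inclusive":
        if ref is None:
            raise ValueError("adenylated-inclusive mode needs the reference record")
        templated_a = 0.0
        genomic = 0.0
        a_tailed = 0.0
        rest = 0.0
        for (offset, tclass, _tlen), f in frac.items():
            if tclass == "none":
                if offset == 1 and len(ref.downstream_seq) >= 1 and ref.downstream_seq[0] == "A":
                    templated_a += f
                else:
                    genomic += f
            elif tclass in ("monoA", "oligoA"):
                a_tailed += f
            else:
                rest += f
        return pd.Series({
            "A_ended": templated_a + a_tailed,
            "genomic": genomic,
            "other": rest,
        })

    raise ValueError(f"unknown summarize mode {mode!r}")


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if np.mean(a) == np.mean(b):
            warnings.warn("zero variance in both conditions; p set to 1")
            return 1.0
        warnings.warn("zero variance in both conditions with unequal means; p set to 0")
        return 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def compare_conditions(
    profiles_a: Sequence[EndProfile],
    profiles_b: Sequence[EndProfile],
    categories: Sequence[str] | None = None,
    *,
    mode: str = "tail",
    ref: ReferenceRecord | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Replicate-level comparison of profile summary fractions.

    Each replicate profile is reduced to its summary fractions; per category
    the table reports mean/SD per condition, the difference of means and a
    Welch two-sided p-value (NaN with a single replicate per condition).
    Benjamini-Hochberg across categories is available but off by default.
    """
    def replicate_fractions(profiles):
        rows = []
        for p in profiles:
            s = summarize_profile(p, mode=mode, ref=ref)
            rows.append(s["fractions"] if isinstance(s, dict) else s)
        return pd.DataFrame(rows).fillna(0.0)

    fa = replicate_fractions(profiles_a)
    fb = replicate_fractions(profiles_b)
    if categories is None:
        categories = sorted(set(fa.columns) | set(fb.columns))
    rows = []
    for cat in categories:
        a = fa.get(cat, pd.Series(np.zeros(len(fa)))).to_numpy(dtype=float)
        b = fb.get(cat, pd.Series(np.zeros(len(fb)))).to_numpy(dtype=float)
        single = len(a) < 2 or len(b) < 2
        rows.append({
            "category": cat,
            "mean_A": a.mean(),
            "sd_A": a.std(ddof=1) if len(a) > 1 else np.nan,
            "mean_B": b.mean(),
            "sd_B": b.std(ddof=1) if len(b) > 1 else np.nan,
            "difference": b.mean() - a.mean(),
            "p_value": np.nan if single else _welch_p(a, b),
        })
    out = pd.DataFrame(rows).set_index("category")
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        mask = out["p_value"].notna()
        adj = out["p_value"].copy()
        if mask.any():
            adj.loc[mask] = multipletests(out.loc[mask, "p_value"], method="fdr_bh")[1]
        out["p_adj"] = adj
    return out


# ---------------------------------------------------------------------------
# count normalization and strand asymmetry

def cpm_normalize(count_table: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: count / column_total * 1e6 per sample column."""
    totals = count_table.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"column totals must be > 0 (offending: {bad})")
    return count_table / totals * 1e6


def log2fc(
    norm_table: pd.DataFrame,
    cond_a_cols: Sequence[str],
    cond_b_cols: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-reference log2((mean_B + pc) / (mean_A + pc)) on the normalized scale."""
    mean_a = norm_table[list(cond_a_cols)].mean(axis=1)
    mean_b = norm_table[list(cond_b_cols)].mean(axis=1)
    return np.log2((mean_b + pseudocount) / (mean_a + pseudocount)).rename("log2fc")


def strand_asymmetry(
    norm_table: pd.DataFrame,
    pairs: Iterable[tuple[str, str]],
    cond_a_cols: Sequence[str],
    cond_b_cols: Sequence[str],
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, float]:
    """Guide-vs-passenger fold-change asymmetry across miRNA duplexes.

    ``pairs`` is an iterable of (guide_id, passenger_id). Per pair the table
    holds both arms' log2 fold changes and delta = guide - passenger; across
    pairs, deltas are tested against 0 with a two-sided Wilcoxon signed-rank
    test (p=1 by convention when every delta is zero).
    """
    lfc = log2fc(norm_table, cond_a_cols, cond_b_cols, pseudocount=pseudocount)
    rows = []
    for guide_id, passenger_id in pairs:
        if guide_id not in lfc.index or passenger_id not in lfc.index:
            raise ValueError(f"pair ({guide_id}, {passenger_id}) not fully in table")
        g, p = float(lfc[guide_id]), float(lfc[passenger_id])
        rows.append({
            "pair_id": f"{guide_id}|{passenger_id}",
            "guide_log2fc": g,
            "passenger_log2fc": p,
            "delta": g - p,
        })
    table = pd.DataFrame(rows).set_index("pair_id")
    deltas = table["delta"].to_numpy()
    if len(deltas) == 0 or np.allclose(deltas, 0.0):
        pval = 1.0
    else:
        pval = float(stats.wilcoxon(deltas, alternative="two-sided").pvalue)
    return table, pval
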