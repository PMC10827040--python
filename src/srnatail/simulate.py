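"""Synthetic small-RNA reads, count tables and decay time courses.

The generator emits reads of the form ``mature[:end] + tail + adapter`` with
known per-read ground truth, emulating the structure of 3'-end sequencing
libraries from a wild-type-like state (ends at the Lsm-adjacent +1U, tails
mostly absent or monoadenylated) and an exonuclease-deficient mutant-like
state (U-tract ends shifted outward, tails mostly oligoadenylated). It also
simulates transcription-shutoff decay time courses (first-order decay with
lognormal noise) and two-condition guide/passenger count tables (Poisson).

Preset fractions are illustrative package defaults shaped like the reported
phenotypes, not fitted to any measured library.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .refio import ReadRecord, ReferenceRecord

TRUTH_COLUMNS = ["read_id", "ref_id", "true_end_offset", "true_tail_seq", "true_tail_class"]

DEFAULT_ADAPTER = "UGGAAUUCUCGGGUGCCAAGG"  # standard small-RNA 3' adapter (RNA alphabet)


@dataclasses.dataclass
class TailModel:
    """Per-reference distribution over (templated end, tail class, tail length).

    ``end_offset_dist`` and ``tail_class_probs`` are categorical
    (value -> probability). Oligo tail lengths are truncated geometric:
    P(L) proportional to (1-p)^(L-2) for L in [2, max]; mono classes have
    length exactly 1.
    """

    end_offset_dist: Mapping[int, float]
    tail_class_probs: Mapping[str, float]
    p_a: float = 0.5
    max_a: int = 8
    p_u: float = 0.5
    max_u: int = 10

    def __post_init__(self) -> None:
        for name, dist in (("end_offset_dist", self.end_offset_dist),
                           ("tail_class_probs", self.tail_class_probs)):
            total = float(sum(dist.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, not 1")
        unknown = set(self.tail_class_probs) - {
            "none", "monoA", "oligoA", "monoU", "oligoU", "U_then_A", "other"}
        if unknown:
            raise ValueError(f"unknown tail classes {sorted(unknown)}")


@dataclasses.dataclass
class SampleConfig:
    """One simulated library: abundances, tail models, error model, depth."""

    abundances: Mapping[str, float]
    tail_models: Mapping[str, TailModel]
    n_reads: int = 10_000
    seq_error_rate: float = 0.0
    adapter_seq: str = DEFAULT_ADAPTER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if not (0.0 <= self.seq_error_rate < 0.25):
            raise ValueError("seq_error_rate must be in [0, 0.25)")


def _sample_categorical(rng: np.random.Generator, dist: Mapping, size: int) -> np.ndarray:
    keys = list(dist.keys())
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=size, p=probs)
    return np.asarray(keys, dtype=object)[idx]


def _trunc_geometric(rng: np.random.Generator, p: float, lo: int, hi: int, size: int) -> np.ndarray:
    lengths = np.arange(lo, hi + 1)
    w = (1.0 - p) ** (lengths - lo)
    w = w / w.sum()
    return rng.choice(lengths, size=size, p=w)


_ERROR_SUBS = {b: np.array([c for c in "ACGU" if c != b]) for b in "ACGU"}


def _draw_tail(rng: np.random.Generator, tail_class: str, model: TailModel) -> str:
    if tail_class == "none":
        return ""
    if tail_class == "monoA":
        return "A"
    if tail_class == "monoU":
        return "U"
    if tail_class == "oligoA":
        return "A" * int(_trunc_geometric(rng, model.p_a, 2, model.max_a, 1)[0])
    if tail_class == "oligoU":
        return "U" * int(_trunc_geometric(rng, model.p_u, 2, model.max_u, 1)[0])
    if tail_class == "U_then_A":
        n_u = int(_trunc_geometric(rng, model.p_u, 1, model.max_u, 1)[0])
        n_a = int(_trunc_geometric(rng, model.p_a, 1, model.max_a, 1)[0])
        return "U" * n_u + "A" * n_a
    if tail_class == "other":
        # short tail guaranteed non-A/U-classifiable: one C or G somewhere
        length = int(rng.integers(1, 4))
        bases = rng.choice(np.array(list("ACGU")), size=length)
        bases[rng.integers(0, length)] = rng.choice(np.array(["C", "G"]))
        return "".join(bases)
    raise ValueError(f"unknown tail class {tail_class!r}")


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0 or not seq:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for pos in positions:
        chars[pos] = str(rng.choice(_ERROR_SUBS[chars[pos]]))
    return "".join(chars)


def simulate_sample(
    references: Mapping[str, ReferenceRecord],
    config: SampleConfig,
    *,
    read_prefix: str = "read",
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate one library; returns (reads, truth table).

    Each read is ``mature[:canonical_end + offset] + tail + adapter`` with
    iid substitution errors applied to the insert (never the adapter). The
    truth table records the pre-error structure, one row per read. Identical
    (config, seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    ref_ids = sorted(config.abundances)
    for rid in ref_ids:
        if rid not in references:
            raise ValueError(f"abundance given for unknown reference {rid!r}")
        model = config.tail_models[rid]
        max_off = max(model.end_offset_dist)
        if max_off > len(references[rid].downstream_seq):
            raise ValueError(
                f"{rid}: end offset {max_off} beyond downstream context "
                f"({len(references[rid].downstream_seq)} nt)"
            )
    weights = np.asarray([config.abundances[r] for r in ref_ids], dtype=float)
    n = config.n_reads
    chosen = rng.choice(len(ref_ids), size=n, p=weights / weights.sum())

    # draws are vectorized per reference/class; read order stays by index
    offsets = np.zeros(n, dtype=int)
    classes = np.empty(n, dtype=object)
    tails = np.empty(n, dtype=object)
    for ref_idx, rid in enumerate(ref_ids):
        idx = np.nonzero(chosen == ref_idx)[0]
        if len(idx) == 0:
            continue
        model = config.tail_models[rid]
        offsets[idx] = _sample_categorical(rng, model.end_offset_dist, len(idx)).astype(int)
        cls = _sample_categorical(rng, model.tail_class_probs, len(idx))
        classes[idx] = cls
        for tail_class in ("none", "monoA", "monoU", "oligoA", "oligoU", "U_then_A", "other"):
            sub = idx[cls == tail_class]
            if len(sub) == 0:
                continue
            if tail_class == "none":
                tails[sub] = ""
            elif tail_class == "monoA":
                tails[sub] = "A"
            elif tail_class == "monoU":
                tails[sub] = "U"
            elif tail_class == "oligoA":
                lens = _trunc_geometric(rng, model.p_a, 2, model.max_a, len(sub))
                tails[sub] = ["A" * int(l) for l in lens]
            elif tail_class == "oligoU":
                lens = _trunc_geometric(rng, model.p_u, 2, model.max_u, len(sub))
                tails[sub] = ["U" * int(l) for l in lens]
            elif tail_class == "U_then_A":
                n_u = _trunc_geometric(rng, model.p_u, 1, model.max_u, len(sub))
                n_a = _trunc_geometric(rng, model.p_a, 1, model.max_a, len(sub))
                tails[sub] = ["U" * int(u) + "A" * int(a) for u, a in zip(n_u, n_a)]
            else:
                tails[sub] = [_draw_tail(rng, "other", model) for _ in sub]

    reads: list[ReadRecord] = []
    truth_rows: list[tuple] = []
    adapter = config.adapter_seq
    rate = config.seq_error_rate
    for i in range(n):
        rid = ref_ids[int(chosen[i])]
        ref = references[rid]
        offset = int(offsets[i])
        tail = tails[i]
        body = ref.template[: len(ref.mature_seq) + offset]
        insert = _apply_errors(rng, body + tail, rate)
        read_id = f"{read_prefix}{i:06d}"
        reads.append(ReadRecord(read_id=read_id, seq=insert + adapter))
        truth_rows.append((read_id, rid, offset, tail, classes[i]))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth


def wt_mut_presets(
    references: Mapping[str, ReferenceRecord],
    *,
    n_reads: int = 10_000,
    seq_error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[SampleConfig, SampleConfig]:
    """Editable WT-like and mutant-like sample configurations.

    WT-like snRNA: ends concentrated at the Lsm-adjacent +1U, tailed ends
    dominated by monoadenylation. Mutant-like snRNA: ends shifted outward
    along the U tract (+3U/+4U), tails mostly oligoadenylated. miRNA refs
    get a genomic-vs-adenylated shift. Fractions are illustrative defaults.
    """
    classes = {r.ref_class for r in references.values()}
    if classes != {"miRNA", "snRNA"}:
        raise ValueError("presets need at least one miRNA and one snRNA reference")

    wt_models: dict[str, TailModel] = {}
    mut_models: dict[str, TailModel] = {}
    for rid, ref in references.items():
        if ref.ref_class == "snRNA":
            b = ref.boundary_offset if ref.boundary_offset is not None else 0
            wt_models[rid] = TailModel(
                end_offset_dist={b: 0.40, b + 1: 0.25, b + 2: 0.20, b + 3: 0.10, b + 4: 0.05},
                tail_class_probs={"none": 0.30, "monoA": 0.62, "oligoA": 0.05,
                                  "monoU": 0.02, "oligoU": 0.01},
            )
            mut_models[rid] = TailModel(
                end_offset_dist={b: 0.05, b + 1: 0.10, b + 2: 0.30, b + 3: 0.35, b + 4: 0.20},
                tail_class_probs={"none": 0.08, "monoA": 0.10, "oligoA": 0.72,
                                  "monoU": 0.02, "oligoU": 0.03, "U_then_A": 0.05},
            )
        else:
            wt_models[rid] = TailModel(
                end_offset_dist={0: 1.0},
                tail_class_probs={"none": 0.55, "monoA": 0.32, "oligoA": 0.08,
                                  "monoU": 0.02, "oligoU": 0.01, "U_then_A": 0.01,
                                  "other": 0.01},
            )
            mut_models[rid] = TailModel(
                end_offset_dist={0: 1.0},
                tail_class_probs={"none": 0.28, "monoA": 0.24, "oligoA": 0.42,
                                  "monoU": 0.02, "oligoU": 0.01, "U_then_A": 0.02,
                                  "other": 0.01},
            )
    abundances = {rid: 1.0 for rid in references}
    wt = SampleConfig(abundances=abundances, tail_models=wt_models, n_reads=n_reads,
                      seq_error_rate=seq_error_rate, seed=seed)
    mut = SampleConfig(abundances=dict(abundances), tail_models=mut_models, n_reads=n_reads,
                       seq_error_rate=seq_error_rate, seed=seed + 1)
    return wt, mut


def simulate_decay(
    k_per_ref: Mapping[str, float],
    timepoints: Sequence[float],
    n0_per_ref: Mapping[str, float],
    *,
    noise_cv: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transcription-shutoff time course: counts ~ n0*exp(-k*t) with lognormal noise.

    Returns a long-format count table (ref_id, replicate, time, count) and a
    truth table (ref_id, k, half_life). Noise is multiplicative lognormal
    with coefficient of variation ``noise_cv``; counts are rounded to ints.
    """
    timepoints = np.asarray(sorted(timepoints), dtype=float)
    if 0.0 not in timepoints:
        raise ValueError("timepoints must include 0")
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    for rid in sorted(k_per_ref):
        k = float(k_per_ref[rid])
        n0 = float(n0_per_ref[rid])
        if k < 0:
            raise ValueError(f"{rid}: negative decay rate")
        if n0 < 0:
            raise ValueError(f"{rid}: negative initial abundance")
        truth_rows.append((rid, k, np.inf if k == 0 else np.log(2) / k))
        for rep in range(1, n_replicates + 1):
            expected = n0 * np.exp(-k * timepoints)
            if sigma > 0:
                noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=len(timepoints))
                expected = expected * noise
            for t, c in zip(timepoints, np.rint(expected).astype(int)):
                rows.append((rid, rep, float(t), int(c)))
    counts = pd.DataFrame(rows, columns=["ref_id", "replicate", "time", "count"])
    truth = pd.DataFrame(truth_rows, columns=["ref_id", "k", "half_life"])
    return counts, truth


def simulate_strand_pairs(
    references: Mapping[str, ReferenceRecord],
    base_counts: Mapping[str, float],
    *,
    guide_logfc: float = -1.0,
    passenger_logfc: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    poisson: bool = True,
) -> pd.DataFrame:
    """Two-condition guide/passenger count table with arm-specific fold change.

    Condition-2 expected counts are scaled by ``2**logfc`` per arm role, then
    Poisson-sampled (or kept exact with ``poisson=False``). Columns are
    ``condA_rep{i}`` / ``condB_rep{i}``.
    """
    rng = np.random.default_rng(seed)
    for rid in base_counts:
        ref = references[rid]
        if ref.partner_id is None or ref.arm_role == "none":
            raise ValueError(f"{rid}: unpaired reference passed to simulate_strand_pairs")
    ref_ids = sorted(base_counts)
    data = {}
    for rep in range(1, n_replicates + 1):
        col_a, col_b = [], []
        for rid in ref_ids:
            mu = float(base_counts[rid])
            logfc = guide_logfc if references[rid].arm_role == "guide" else passenger_logfc
            mu_b = mu * 2.0**logfc
            if poisson:
                col_a.append(int(rng.poisson(mu)))
                col_b.append(int(rng.poisson(mu_b)))
            else:
                col_a.append(mu)
                col_b.append(mu_b)
        data[f"condA_rep{rep}"] = col_a
        data[f"condB_rep{rep}"] = col_b
    return pd.DataFrame(data, index=pd.Index(ref_ids, name="ref_id"))
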