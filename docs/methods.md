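# Methods

## The decomposition problem

A 3′-end sequencing read of a small RNA is `insert + adapter`, where the
insert is a 5′-anchored copy of the mature RNA that may (a) stop short of
the canonical end (exonucleolytic trimming), (b) run into the downstream
genomic context (templated extension, e.g. unprocessed snRNA U-tract ends),
and (c) carry post-transcriptionally added nucleotides (the tail). (b) and
(c) are not separable wherever the first tail base equals the next genomic
base. `srnatail` resolves the ambiguity with a single explicit convention
and keeps enough information in its output to recompute the alternative
view.

### Templated-maximal convention

The matched length *L* is the longest prefix of the insert aligning to
`mature + downstream` subject to the mismatch policy below; everything after
*L* is the tail. A terminal base that could be either genomic or added is
therefore always counted genomic. Consequence: on a reference with a
genomic A downstream (the miR-125a-5p `GUG`/`GUGA` situation), one extra A
is a *genomic* end at offset +1, and k ≥ 2 extra As yield a tail of k−1 As.
Studies that treat the single-A extension as the adenylation phenotype are
served by the profiler's `adenylated-inclusive` summary, which pools the
templated single-A end (offset +1, templated base A, no tail) with
non-templated pure-A tails into one `A_ended` category. U_then_A tails are
reported separately in that view: they are operationally a different
(oligoU-derived) substrate even though they end in A.

### Mismatch policy

Defaults: at most 1 substitution, allowed only within the mature body, never
within the final 4 bases of the match and never in the downstream
extension; the greedy matcher backtracks past a consumed mismatch that ends
up inside the terminal window. Rationale: the templated/non-templated
boundary decides the biology, so it must be exact — a sequencing error near
the 3′ terminus would otherwise masquerade as a tail (it instead makes the
read `unmatched`). Equivalence of the greedy matcher with exhaustive
enumeration of all (templated prefix, suffix) splits is property-tested
against an independent brute-force oracle.

Other calling rules: inserts must be ≥ 15 nt and start at mature base 1 (no
5′ heterogeneity; an isomiR-tolerant mode was considered and rejected
because 5′ variants change the anchor and are out of scope); untailed
inserts up to 3 nt short of the canonical end are called as trimmed species
(offsets −1..−3), chosen to capture exonuclease trimming intermediates
without admitting spurious short matches; reference assignment takes the
longest exact 5′ prefix match, requires ≥ 12 nt (chance match probability
4⁻¹² per reference), and declares ties `ambiguous_ref`. Adapter trimming
scans 5′→3′ from position 15 for ≥ 6 adapter bases with ≤ 1 substitution;
reads without an adapter are flagged `no_adapter` but still called, and are
excluded from profiles. Quality strings are carried but unused.

## End profiles and statistics

A profile is the exact joint count over (end offset, tail class, tail
length) for one reference in one sample; fractions are counts/total, and
empty profiles are flagged rather than divided. Offsets are relative to the
canonical 3′ end; snRNA offsets are additionally labelled `+nU` via the
annotated Lsm-boundary offset, so the boundary-adjacent uridine is `+1U`.
A-tail length histograms cover pure-A tails only (the A-run length of a
`U_then_A` tail is not recoverable from the profile key) and are capped at
10 nt, longer tails binned `10+`.

Replicated profiles are compared on per-replicate summary fractions as mean
± SD with a Welch two-sided t-test; this test choice is this package's
(field reports for such panels typically state only mean ± SD over n=2–3
biological replicates). Degenerate zero-variance cases return p = 1 (equal
means) or p = 0 with a warning instead of erroring. Benjamini–Hochberg
across categories is available and off by default. Count tables are
CPM-normalized (columns sum to 10⁶); fold changes use
log₂((mean_B + 0.5)/(mean_A + 0.5)) on the CPM scale, the pseudocount
guarding dropout miRNAs. Guide/passenger asymmetry is the per-duplex delta
of arm log₂ fold changes, tested across duplexes with a two-sided Wilcoxon
signed-rank test (p = 1 by convention when all deltas are zero).

## Decay kinetics

Time courses are normalized to the shutoff start within each replicate, so
ln A(t) = −k·t with a structurally zero intercept; the per-replicate fit is
least squares through the origin (free-intercept variant behind a flag),
k is clipped at 0 (upward drift is reported via r² and a warning), zeros are
floored at ε = 10⁻⁶ of the t=0 abundance before the log, and the pooled rate
is the replicate mean with SE = SD/√n. Half-life is ln2/k, flagged infinite
at k ≤ 10⁻¹². Default timepoints in simulations are 0, 4, 8 h, the standard
actinomycin-D design. The endpoint-ratio alternative (comparing only t=8
abundances) was rejected as noisier and rate-free.

## Synthetic data: what it emulates and what it does not

`simulate_sample` draws, per read: a reference (abundance-weighted), a
templated end offset, a tail class, and a tail (oligo lengths truncated
geometric — the simplest monotone family, parameters p_A = p_U = 0.5, max
8 A / 10 U), then emits `body + tail + adapter` with iid substitutions at
the configured rate on the insert only. It emulates heterogeneous templated
ends, mono- vs oligo-tails, U-then-A tails, sequencing error and replicate
structure. It does **not** emulate ligation bias, UMIs, PCR duplication,
indels, 5′ heterogeneity, or quality-score structure — so green round-trip
tests establish correctness of the decomposition logic under the stated
read model, not robustness to real library artefacts. Decay counts are
n₀·e^(−kt) with multiplicative lognormal noise (mean-1 parametrization from
the target CV); strand-pair tables are Poisson around 2^logfc-scaled means.

The WT-like/mutant-like presets place snRNA ends at {+1U: 0.40 … +5U: 0.05}
vs {+3U/+4U-dominant}, and tail classes mostly none/monoA vs mostly oligoA,
with analogous genomic→adenylated shifts for miRNAs. These shapes follow the
qualitative phenotype (wild-type: boundary-trimmed, ~monoadenylated;
exonuclease-deficient: extended, oligoadenylated) but the exact fractions
are illustrative package defaults — deliberately *not* set to any
published measurement, so that pipeline tests cannot be circular.

Determinism: one integer seed per sample feeds a single `numpy` Generator;
identical (config, seed) gives byte-identical FASTQ. Draws are vectorized
per reference and class, so outputs are stable for a fixed package version
but not guaranteed across numpy versions; regression tests freeze truth
tables rather than re-generating streams.

A deliberate interaction to be aware of: a generated tail whose first base
equals the next genomic base is, by the templated-maximal convention,
correctly re-assigned to the templated side by the caller (e.g. U tails on
the snRNA U tract). Truth tables record the as-generated structure, so
round-trip concordance checks use reference fixtures whose downstream
context cannot collide with the sampled tails; the colliding case is
exercised explicitly by the genomic-A ambiguity tests.

## Numerical choices

- Probability vectors validated to 1 ± 10⁻⁹; profile fractions sum to 1
  exactly by construction and are written to 6 decimal places (round trips
  are integer-exact for counts, 10⁻⁶ for fractions).
- Welch t via `scipy.stats.ttest_ind(equal_var=False)`; Wilcoxon via
  `scipy.stats.wilcoxon` (exact method at these n).
- Error rate bounded to [0, 0.25): above that, substitution "errors"
  approach random sequence and the decomposition oracle is meaningless.

## Known limitations

- No genome-wide mapping: reads are assigned to an annotated reference set
  by exact 5′ anchoring; novel or 5′-variant species are `unmatched`.
- Single-substitution tolerance means doubly-errored reads (~(ℓp)² of
  reads) drop out rather than risk miscalls; at 0.5%/base this loses ~1% of
  reads and concordance among called reads stays ≥ 97%.
- The decay model is single-exponential; biphasic decay would bias k toward
  the early phase.
- `compare_conditions` treats replicate fractions as approximately normal;
  with n = 2 replicates the Welch test is underpowered and mean ± SD is the
  meaningful output, matching how such panels are usually reported.
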