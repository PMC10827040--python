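# srnatail

Non-templated 3′-tail calling, end profiling and decay kinetics for small
RNAs.

Small RNAs such as miRNAs and the U6/U6atac snRNAs are regulated at their 3′
ends: non-canonical poly(A) polymerases (PAPD5/7) add destabilizing oligo(A)
tails, and 3′→5′ exonucleases (USB1, PARN) remove them. Reads from 3′-end
sequencing therefore mix *templated* ends (genomically encoded bases
downstream of the canonical end) with *non-templated* tails, and the two are
ambiguous wherever a tail base equals the next genomic base — e.g. a
miR-125a-5p read ending `...GUGA` may be a genomic end or an adenylated
`...GUG`. `srnatail` resolves each read under an explicit
**templated-maximal** convention, profiles the resulting end/tail
distributions, and provides the downstream quantifications used in tailing
studies: condition comparisons of adenylation fractions, Lsm-boundary-
relative snRNA end positions, guide/passenger strand asymmetry, and
first-order decay fits after transcription shutoff. A synthetic-read
generator with per-read ground truth replaces sequencing data for testing
and power analysis.

## Core model

For a reference with mature sequence *M* and downstream genomic context *D*,
an insert *s* is decomposed by choosing the **longest** prefix of *s* that
aligns to *M·D* with at most one substitution in the mature body (none in
the final 4 matched bases, none in the downstream extension). With matched
length *L*:

- `end_offset = L − |M|` (0 = canonical end, +k = k bases into *D*,
  negative = trimmed species, floor −3),
- `tail_seq = s[L:]`, classified as one of
  `none | monoA | oligoA | monoU | oligoU | U_then_A | other`
  (`U_then_A` matches `U+A+`, the oligoU-then-A substrate shape).

Decay is modelled as first-order: abundances are normalized to the shutoff
start, ln *A* is regressed on *t* through the origin per replicate, the rate
*k* is the replicate mean (half-life ln2/*k*), and genotypes are compared by
the rate ratio with a Welch test on replicate-level rates. Strand asymmetry
is Δ = log₂FC(guide) − log₂FC(passenger) per duplex, tested across duplexes
with a Wilcoxon signed-rank test.

## Worked example

```python
import numpy as np
from srnatail import (ReferenceRecord, wt_mut_presets, simulate_sample,
                      call_sample, build_profile, summarize_profile)
from srnatail.simulate import DEFAULT_ADAPTER

refs = {
    "mir-guga": ReferenceRecord("mir-guga", "miRNA",
                                "UCCCUGAGACCCUUUAACCUGUG", "AUUUCGGC"),
    "u6-like": ReferenceRecord("u6-like", "snRNA",
                               "GAUUAGCAUGGCCCCUGCGCAAGGAUU", "UUUUCGCA",
                               boundary_offset=0),
}
wt, mut = wt_mut_presets(refs, n_reads=10_000, seed=1)
reads, truth = simulate_sample(refs, wt)
calls, status = call_sample(reads, refs, adapter_seq=DEFAULT_ADAPTER)
prof = build_profile(calls, refs["u6-like"], "WT-rep1")
print(summarize_profile(prof, "endpos", ref=refs["u6-like"]).round(3))
print(summarize_profile(prof, "tail")["fractions"].round(3))
```

prints (seed 1)

```
+1U    0.387
+2U    0.254
+3U    0.206
+4U    0.103
+5U    0.050
dtype: float64
genomic         0.323
monoA           0.620
oligoA          0.051
U_containing    0.006
other           0.000
dtype: float64
```

i.e. in the wild-type-like library ~39% of snRNA reads end at the
Lsm-adjacent +1U and tailed ends are predominantly monoadenylated; the
mutant-like preset shifts the mode to +3U/+4U and the tails to oligo(A).
(The `genomic` fraction slightly exceeds the configured untailed rate
because U tails landing on the genomic U tract are, correctly, absorbed as
templated ends.)

The same objects drive the CLI: `srnatail simulate | call | profile |
compare | strands | decay` (see `--help` on each subcommand).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch at the given seed — simulated
WT-like vs mutant-like libraries through tail calling and profile
comparison, decay fitting on a simulated shutoff time course with a 2× rate
difference, and guide/passenger asymmetry over 20 simulated duplexes —
printing each stage's summary tables and writing the results JSON to
`--out`.
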