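# Methods

This note documents the models, parameter choices and numerical
decisions behind `iskit`, and what its synthetic-data tests do and do
not demonstrate about real genomes.

## Element model and TIR search

An IS element is a transposase ORF bounded by a terminal inverted
repeat: a left arm whose reverse complement appears at the element's
other end. The search enumerates every (left-arm start, right-arm end,
arm length) triple with arm length in `[min_arm, max_arm]` = [6, 40]
and at most `max_mismatch` = 2 substitutions, scoring
`arm_length − mismatches`; ties prefer fewer mismatches, then a smaller
enclosed span, then the leftmost placement. The left arm must start in
the upstream flank or the first 60 nt of the ORF (and mirrored on the
right), because in some families — IS*701* notably — the TIR genuinely
overlaps the transposase ORF. The implementation accumulates
complementary-match counts along anti-diagonals of the base-pairing
matrix with numpy; a cubic brute-force enumeration with identical
tie-breaks serves as the test oracle, and the two agree exactly on
every window up to ~300 nt.

**Noise floor (`min_score` = 16).** In a 2-kb flanking window of a 67%
GC genome there are ~10⁶ candidate arm placements, so chance pairs
scoring 13–15 are expected by combinatorics alone. Arm pairs below the
floor are therefore reported as "no TIR" (the element is flagged
*partial*) rather than as spurious arms. A genuine 6-nt TIR (the
shortest the package models) is below any usable floor for kb-scale
windows; it can still be found by lowering `min_score` and searching a
small window with `max_mismatch=0`. This is an honest resolution limit
of best-score inverted-repeat detection, not a defect: 16–20-nt arms
are detected reliably, 6-nt arms require corroborating evidence.

**DR corroboration.** Among the top five arm-pair candidates the
catalog prefers the first whose flanks carry an exact target-site
duplication of ≥3 nt (`dr_corroboration_min`). A chance arm pair
rarely arrives with a flanking duplication, while a real integration
boundary usually does; this makes planted-element recovery exact in
simulation where a raw best-score rule occasionally (≈1–2% of windows)
loses to a chance higher-scoring pair. The plain best-score answer is
still available via `find_tir`.

**Direct repeats** are exact-match only, length 2–12 (observed DRs in
the emulated system span 3–9 nt), taken as the longest `k` such that
the `k` nt immediately 5' of the left arm equal the `k` nt immediately
3' of the right arm.

## Subtypes and families

Pairwise transposase identity = identical aligned positions ÷ length of
the *shorter* sequence, after a global alignment with match 1,
mismatch 0 and affine gaps (open −2, extend −0.5). The
shorter-sequence denominator is deliberate: it reproduces the
integer-ratio identities that manual IS characterisations report for
transposases of unequal length, where alignment-length denominators do
not land on round fractions. Subtypes are single-linkage clusters at
90% identity — chosen to separate the reported same-subtype identity
range (≥92.8%) from reported between-subtype ranges (≤89.1%). Family
assignment is best identity against one exemplar transposase per
family at a permissive 30% floor, "unclassified" below it.

The packaged exemplar file
(`src/iskit/data/family_exemplars_synthetic.faa`) is a **synthetic**
stand-in set — one deterministic pseudo-protein per family at a
family-typical length — sufficient for the simulator's mutation-derived
transposases and for exercising the classification machinery. For real
genomes it should be replaced (`exemplar_path`) with curated reference
transposases; family calls against the synthetic set carry no
biological meaning.

## Insertion calling

Position convention: the reported position is the 1-based wild-type
coordinate of the last base before the junction, computed as the
longest common prefix of wild type and mutant, with the target-site
duplication reported at the 3' end of the inserted segment. A DR of
length k makes k+1 junction placements sequence-identical; this
canonical form makes calls comparable and matches how integration loci
are conventionally reported ("integrated at the 275th nucleotide"
means 275 wild-type bases, including the original DR copy, precede the
element). Orientation cannot come from the element boundaries — an
element reads TIR … rc(TIR) in either orientation — so it is carried by
the transposase ORF direction (longest-ORF rule) relative to the
disrupted gene's coding strand. Every returned call satisfies the
reconstruction identity `wt[:pos] + element + dr + wt[pos:] == mutant`
exactly; a call that fails it raises instead of returning.

In-silico PCR uses exact, IUPAC-aware primer matching (≥15-nt primers,
mismatch tolerance configurable, 0 by default since screening primers
are designed to match) and measures products 5' end to 5' end
inclusive. Transposition mode is classified from explicit donor-locus
evidence (presence booleans, as a PCR screen would establish):
replicative if all donor copies of the matched subtype remain and a new
copy exists, conservative if exactly one donor locus is empty,
indeterminate otherwise (including any donor without evidence).

## Statistics

Selection frequency is the plain ratio mutants/CFU with a Wilson score
95% interval (statsmodels); Monte-Carlo checks confirm ~95% coverage at
frequencies near 5×10⁻⁴. Relative expression follows the Livak
2^−ΔΔCt method with the reference gene paired to targets by replicate;
the test is a two-sided two-sample t-test on replicate ΔCt values,
Welch by default (`equal_var=False`) since equal variances are not
guaranteed — the choice is configurable. No multiple-testing
correction is applied; results are per-comparison, and both SD and SEM
of the replicate ΔCt are exported since error-bar conventions vary.
The reference gene appears in the output as a self-test (fold exactly
1.0).

## The simulator, and what passing tests show

Genomes are seeded i.i.d. base draws at a target GC (default 0.674,
matching the GC-rich Deinococcus-type genomes the package emulates)
organised into start/stop-valid CDS features with intergenic spacers;
realised GC stays within ±2% of target beyond ~50 kb. Planted elements
follow family blueprints (two IS4-like subtypes with 17/20-nt TIRs and
9-nt DRs, IS5-like with 3-nt DRs, IS66-like 8 nt, IS630-like 3 nt,
IS701-like 4 nt); planted transposases are seeded point-mutants of the
family exemplar at a per-subtype identity, so subtypes of one family
cluster apart while remaining family-assignable. Every generator is a
pure function of its seed.

**Unambiguous planting.** A duplication of length k makes k+1 junction
placements identical, and a chance match between an element boundary
and the adjacent host base extends the apparent duplication or the
apparent arm length. Exact ground-truth recovery is therefore only
well-defined at sites where no such chance extension exists, and the
simulator guarantees it: insertions slide by the minimal offset (and
plantings additionally break boundary-adjacent complementarity) until
the junction, the duplication and the arm pair are all maximal exactly
as planted. The realised coordinates are recorded in the truth
records. Simulated positions are consequently "requested ± a few nt".

What the passing round-trip suites show: the catalog and caller recover
planted anatomy (spans, arms, duplications, subtype, orientation,
mode) with zero errors across 100 seeded scenarios covering DR lengths
0–12, both orientations and both modes. What they do not show: i.i.d.
base draws have no repeat structure, codon bias, or degraded element
fossils; real flanks are messier, real TIRs drift, and real annotation
mislabels transposases. The accession-gated checks (genome length, GC,
transposase length and the 67.19% between-subtype identity of the
reference organism) are the bridge to real data and require a one-time
download (`scripts/fetch_genome.py`).

## Problem sizes and degenerate inputs

Default test and acceptance runs use 4–12-gene genomes (5–15 kb) for
round trips and a 100-gene (~100 kb) genome with 8 planted elements
and 6 events for the end-to-end check; the full pipeline at that scale
completes in seconds, so these sizes are generous for the properties
being tested. Degenerate inputs are explicit errors: windows shorter
than two arms, empty sequences, non-IUPAC primers, counts exceeding
CFU, a reference gene missing from a qPCR condition. TIR arms at a
window edge with under-length DR context return a result flagged
`truncated_context`. Windows that would wrap a linear genome edge are
clamped and flagged truncated; circular genomes wrap contiguously.
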