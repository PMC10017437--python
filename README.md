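# iskit

Insertion-sequence (IS) analysis for bacterial genomes: catalog the IS
elements of an annotated genome, characterise IS integrations in
disrupted genes, and compute the accompanying selection-frequency and
qPCR statistics — with a built-in transposition simulator that makes
every stage testable against known ground truth.

`iskit` is aimed at microbiologists studying stress-induced genome
plasticity: the workflow it automates is the classic one of selecting a
visible mutant phenotype (e.g. loss of carotenoid pigmentation after
oxidative stress), spotting an enlarged PCR product across a candidate
gene, and characterising the integrated element — its boundaries,
family, orientation, target-site duplication and transposition mode.

## What it computes

**IS catalog.** An IS element is modelled as a transposase ORF bounded
by a terminal inverted repeat (TIR): an arm of 6–40 nt at the 5' end
whose reverse complement closes the 3' end. Integration typically
duplicates 3–9 nt of the target site, leaving identical direct repeats
(DR) immediately outside both arms. For each annotated transposase the
package scans a flanking window (1 kb each side by default) for the
best arm pair, scoring `arm_length − mismatches` with ≤2 mismatches,
preferring candidates corroborated by an exact flanking DR; transposases
are then clustered into subtypes by global amino-acid identity
(single linkage at 90%; identity = identical aligned positions ÷ length
of the shorter sequence) and each subtype is assigned to an IS family
(IS*1*, IS*4*, IS*5*, IS*66*, IS*630*, IS*701*) by best identity
against a replaceable exemplar set.

**Insertion calls.** Given wild-type and mutant gene sequences, the
caller locates the junction from the longest common prefix/suffix,
reports the 1-based coordinate of the last wild-type base before the
junction, strips the largest exact target-site duplication from the
3' end of the inserted segment, matches the element to the catalog by
its terminal arms, and orients it by its transposase ORF direction.
Every call must reconstruct the mutant exactly: wild type +
element + one DR copy = mutant, or the call is refused. In-silico PCR
predicts the amplicon enlargement (element + DR length), and
donor-locus evidence classifies the event as replicative
(copy-and-paste: all donor copies retained) or conservative
(cut-and-paste: one donor locus emptied).

**Statistics.** Mutant-selection frequency = colonies / CFU with a
Wilson score 95% CI; qPCR relative expression by the Livak method,
fold = 2^−ΔΔCt with per-replicate ΔCt = Ct(target) − Ct(reference),
Welch two-sided t-tests on replicate ΔCt, and significance stars at
0.05/0.01/0.001.

**Simulator.** Seeded generators produce GC-rich annotated genomes
(67.4% GC by default), plant IS elements with family-specific TIR/DR
anatomy, simulate transposition events in either mode and orientation
with full ground truth, and sample selection counts (binomial at
frequencies ~10⁻⁴) and replicate Ct tables with condition effects.

## Worked example

Simulate a genome with two IS4-subtype elements and one replicative
transposition into gene `SYN_00006`, then call the insertion:

```sh
iskit simulate --n-genes 12 --seed 7 --n-elements 2 \
      --event-gene SYN_00006 --event-position 250 --out-dir sim_out
iskit call sim_out/wt_gene.fasta sim_out/mut_gene.fasta --out calls.tsv
```

`calls.tsv` then reads:

```
gene       status     position  orientation  dr         dr_len  element_len  matched_element  tir_match
SYN_00006  insertion  249       forward      CTTTGTTGC  9       1060         novel            none
```

i.e. a 1060-nt element integrated after the 249th nucleotide of the
wild-type gene in the forward direction, duplicating the 9-nt target
site `CTTTGTTGC` — matching the simulator's ground truth in
`sim_out/truth.json` exactly (the requested position 250 is slid
minimally so the junction is unambiguous; the truth file records the
realised coordinate). Passing `--catalog-genome` to `iskit call`
additionally matches the element to a catalog subtype instead of
`novel`. `iskit catalog`, `pcr`, `freq` and `qpcr` cover the remaining
stages; `--help` lists every threshold and default.

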