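"""Synthetic-data generator with full ground truth.

Generates GC-rich annotated genomes, plants IS elements with
family-specific TIR/DR anatomy, simulates transposition events
(replicative copy-and-paste or conservative cut-and-paste) into target
genes, and produces selection-count tables and qPCR Ct tables — so the
whole pipeline is testable without any downloads.  Every generator is a
pure function of its seed.

Unambiguous planting
--------------------
A target-site duplication of length k makes k+1 junction placements of
an insertion sequence-identical, and a chance match between the element
boundary and the flanking host base can extend the apparent duplication
beyond the planted one.  Because the ground truth must be recoverable
*exactly* from sequence, the simulator plants at the nearest site (by
minimal slide from the requested position) where the junction is
unambiguous: the host base after the junction differs from the
element's first base, the host base 5' of the duplicated target differs
from the element's last base, and no longer exact duplication arises by
chance.  The realised position is recorded in the truth record.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome_io import CdsFeature, GenomeRecord, TpaseCandidate
from .is_catalog import (
    FAMILY_DR_LEN,
    DirectRepeat,
    ISElement,
    TIRPair,
    load_family_exemplars,
    revcomp,
)

__all__ = [
    "ISSpec",
    "TranspositionEvent",
    "CountData",
    "DEFAULT_IS_SPECS",
    "random_dna",
    "synth_genome",
    "plant_element",
    "simulate_transposition",
    "simulate_selection_counts",
    "simulate_ct_table",
    "gene_sequence",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_AA_CODONS: dict[str, list[str]] = {}
for codon, aa in _TABLE11.forward_table.items():
    _AA_CODONS.setdefault(aa, []).append(codon)
_AA20 = sorted(_AA_CODONS)


@dataclass(frozen=True)
class ISSpec:
    """Blueprint of a planted IS element.

    ``tpase_identity`` is the amino-acid identity of the planted
    transposase to its packaged family exemplar (subtypes of one family
    are planted at different identities so that they cluster apart).
    """

    family: str
    tir: str
    dr_len: int
    tpase_len: int
    subtype: str
    tpase_identity: float = 0.7
    spacer_up: int = 54
    spacer_down: int = 9

    def __post_init__(self) -> None:
        if not (6 <= len(self.tir) <= 40):
            raise ValueError("tir length must be in [6, 40]")
        if not (0 <= self.dr_len <= 12):
            raise ValueError("dr_len must be in [0, 12]")
        if self.tpase_len < 50:
            raise ValueError("tpase_len must be >= 50 aa")


#: Default element blueprints mirroring the family anatomy of a GC-rich
#: Deinococcus-type mobilome: two IS4 subtypes (17/20-nt TIRs, 9-nt DR),
#: two IS5 subtypes (6/16-nt TIRs, 3-nt "TAG"-style DR), IS66 (8-nt DR),
#: IS630 (3-nt DR) and IS701 (4-nt "nTAG" DR, long TIR).
DEFAULT_IS_SPECS: tuple[ISSpec, ...] = (
    ISSpec("IS4", "CTCTGTACCGGACAACT", 9, 320, "ISDrpg2-like", 0.75),
    ISSpec("IS4", "CTCGGTAGCTGACAACTTCA", 9, 327, "ISDrpg3-like", 0.65),
    ISSpec("IS5", "AGGCTG", 3, 265, "ISDrpg4-like", 0.75),
    ISSpec("IS5", "ACCTCCTGCGAAAGTC", 3, 277, "ISDrpg5-like", 0.60),
    ISSpec("IS66", "GTCTGTGATTAGCGGTCG", 8, 472, "ISDrpg6-like", 0.70),
    ISSpec("IS630", "TACGGACTCCGATTAA", 3, 187, "ISDrpg7-like", 0.70),
    ISSpec("IS701", "CTGTACTTTGGGGATATTCA", 4, 432, "ISDrpg9-like", 0.70),
)


@dataclass(frozen=True)
class TranspositionEvent:
    """Ground truth for one simulated transposition."""

    element_ref: str  # subtype name of the moved element
    target_gene: str
    position: int  # 1-based within the target gene CDS, as realised
    orientation: str  # forward|reverse vs the gene's coding strand
    dr_len: int
    mode: str  # replicative|conservative
    seed: int
    requested_position: int = 0
    genome_junction: int = 0  # 1-based genome coordinate of last base before junction
    inserted_length: int = 0  # element + DR copy


@dataclass(frozen=True)
class CountData:
    """One selection experiment: mutant colonies out of total CFU."""

    n_selected: int
    cfu: int
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.cfu <= 0:
            raise ValueError("cfu must be > 0")
        if not (0 <= self.n_selected <= self.cfu):
            raise ValueError("require 0 <= n_selected <= cfu")


# ---------------------------------------------------------------------------
# sequence generation


def random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    """Random DNA of length ``n`` with expected GC fraction ``gc``."""
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _random_coding(n_codons: int, gc: float, rng: np.random.Generator) -> str:
    """Random stop-free codons at roughly the requested GC."""
    out = []
    while len(out) < n_codons:
        chunk = random_dna(3 * (n_codons - len(out)), gc, rng)
        for i in range(0, len(chunk), 3):
            codon = chunk[i : i + 3]
            if codon not in _STOPS:
                out.append(codon)
            if len(out) == n_codons:
                break
    return "".join(out)


def _random_protein(n_aa: int, rng: np.random.Generator) -> str:
    body = rng.choice(np.array(list("ACDEFGHIKLMNPQRSTVWY")), size=n_aa - 1)
    return "M" + "".join(body.tolist())


def _mutate_protein(protein: str, identity: float, rng: np.random.Generator) -> str:
    """Seeded point mutation to approximately the requested identity."""
    out = list(protein)
    n_mut = int(round((1.0 - identity) * len(out)))
    if n_mut == 0:
        return protein
    idx = rng.choice(len(out), size=min(n_mut, len(out) - 1) , replace=False)
    for i in idx:
        if i == 0:
            continue  # keep the start Met
        choices = [a for a in _AA20 if a != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _backtranslate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        opts = _AA_CODONS[aa]
        codons.append(opts[int(rng.integers(len(opts)))])
    return "".join(codons)


def _fit_length(protein: str, n_aa: int, rng: np.random.Generator) -> str:
    if len(protein) >= n_aa:
        return protein[:n_aa]
    extra = _random_protein(n_aa - len(protein) + 1, rng)[1:]
    return protein + extra


# ---------------------------------------------------------------------------
# genome synthesis


def synth_genome(
    n_genes: int,
    mean_gene_len: int = 900,
    gc: float = 0.674,
    seed: int = 0,
    genome_id: str = "synthetic",
    intergenic_len: int = 200,
    topology: str = "linear",
) -> GenomeRecord:
    """Seeded annotated genome with ``n_genes`` plus-strand CDS features.

    Genes have start/stop codons, a ``hypothetical protein`` product,
    and computed translations; intergenic spacers average
    ``intergenic_len`` nt.  Realised GC tracks the target to within a
    couple of percent for sequences of ~50 kb and longer.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    feats: list[CdsFeature] = []
    pos = 0
    for gi in range(n_genes):
        spacer = random_dna(int(rng.integers(intergenic_len // 2, intergenic_len * 3 // 2 + 1)), gc, rng)
        parts.append(spacer)
        pos += len(spacer)
        n_codons = max(30, int(rng.normal(mean_gene_len / 3, mean_gene_len / 15)))
        body = _random_coding(n_codons - 2, gc, rng)
        stop = _STOPS[int(rng.integers(3))]
        cds = "ATG" + body + stop
        start = pos + 1
        end = pos + len(cds)
        translation = str(Seq(cds).translate(table=11, to_stop=True))
        feats.append(
            CdsFeature(
                locus_tag=f"SYN_{gi + 1:05d}",
                start=start,
                end=end,
                strand="+",
                product="hypothetical protein",
                translation=translation,
            )
        )
        parts.append(cds)
        pos = end
    tail = random_dna(int(rng.integers(intergenic_len // 2, intergenic_len * 3 // 2 + 1)), gc, rng)
    parts.append(tail)
    seq = "".join(parts)
    if not seq:
        seq = random_dna(max(intergenic_len, 1), gc, rng)
    return GenomeRecord(
        id=genome_id, sequence=seq, topology=topology, features=tuple(feats)
    )


def gene_sequence(genome: GenomeRecord, locus_tag: str) -> str:
    """Coding-strand sequence of a feature."""
    f = genome.feature_by_locus_tag(locus_tag)
    s = genome.subseq(f.start, f.end)
    return revcomp(s) if f.strand == "-" else s


# ---------------------------------------------------------------------------
# element construction and planting


def element_sequence(
    spec: ISSpec,
    element_seed: int | None = None,
    exemplars: dict[str, str] | None = None,
) -> tuple[str, tuple[int, int], str]:
    """Build the canonical element: TIR + spacer + Tpase ORF + spacer + rc(TIR).

    Returns ``(sequence, tpase_span_within_element (1-based), translation)``.
    The default ``element_seed`` is derived from the subtype tag, so two
    plantings of the same spec yield byte-identical elements.
    """
    if element_seed is None:
        element_seed = zlib.crc32(spec.subtype.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(element_seed)
    if exemplars is None:
        exemplars = load_family_exemplars()
    if spec.family in exemplars:
        protein = _fit_length(
            _mutate_protein(exemplars[spec.family], spec.tpase_identity, rng),
            spec.tpase_len,
            rng,
        )
    else:
        protein = _random_protein(spec.tpase_len, rng)
    cds = _backtranslate(protein, rng) + _STOPS[int(rng.integers(3))]
    up = _random_coding(max(spec.spacer_up // 3, 1), 0.6, rng)[: spec.spacer_up]
    down = _random_coding(max(spec.spacer_down // 3, 1), 0.6, rng)[: spec.spacer_down]
    # keep the planted TIR maximal: a competing longer arm pair needs more
    # matched than mismatched extension steps within the 2-mismatch budget,
    # which three consecutive non-complementary inward pairs rule out
    down = list(down)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i in range(min(3, len(up), len(down))):
        while down[len(down) - 1 - i] == comp[up[i]]:
            down[len(down) - 1 - i] = "ACGT"[int(rng.integers(4))]
    down = "".join(down)
    seq = spec.tir + up + cds + down + revcomp(spec.tir)
    t0 = len(spec.tir) + len(up) + 1
    return seq, (t0, t0 + len(cds) - 1), protein


def _site_is_clean(g: str, p: int, ins: str, k: int, max_dr: int = 12) -> bool:
    """True when planting ``ins`` after ``g[:p]`` with a k-nt TSD leaves the
    junction unambiguous and the duplication maximal (see module docstring)."""
    if p - max(k, 1) - 1 < 0 or p >= len(g):
        return False
    if ins[0] == g[p]:
        return False
    if ins[-1] == g[p - k - 1]:
        return False
    dup = g[p - k : p]
    # block outward TIR-arm extension: the three host bases 5' of the element
    # must not complement the three bases that follow it (DR copy then host)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    after = dup + g[p:]
    for i in range(3):
        if p - 1 - i < 0 or i >= len(after):
            break
        if after[i] == comp.get(g[p - 1 - i], "N"):
            return False
    for k2 in range(k + 1, max_dr + 1):
        if p - k2 < 0:
            break
        left = g[p - k2 : p]
        # guards catalog-side DR search (context vs context)
        if left == (dup + g[p : p + k2 - k])[:k2]:
            return False
        # guards caller-side DR resolution (wt context vs inserted 3' end)
        if left == (ins + dup)[-(k2):]:
            return False
    return True


def _find_clean_site(
    g: str, p_req: int, ins: str, k: int, lo: int, hi: int, max_slide: int = 200
) -> int:
    """Nearest p to ``p_req`` in [lo, hi] where the site is clean."""
    for delta in range(max_slide + 1):
        for p in ({p_req + delta, p_req - delta}):
            if lo <= p <= hi and _site_is_clean(g, p, ins, k):
                return p
    raise RuntimeError(
        f"no unambiguous insertion site within {max_slide} nt of {p_req}"
    )


def _shift_features(
    feats: tuple[CdsFeature, ...], p: int, ins_len: int, disrupted_tag: str | None
) -> tuple[CdsFeature, ...]:
    """Shift annotation downstream of an insertion after base ``p`` (0-based
    slice point); the disrupted feature, if any, is extended over the insert."""
    out = []
    for f in feats:
        if f.start > p:  # wholly downstream (1-based start > p)
            out.append(replace(f, start=f.start + ins_len, end=f.end + ins_len))
        elif f.end > p:  # spans the junction
            if f.locus_tag == disrupted_tag:
                out.append(replace(f, end=f.end + ins_len, translation=None,
                                   product=f.product + " (IS-disrupted)"))
            else:
                out.append(replace(f, end=f.end + ins_len))
        else:
            out.append(f)
    return tuple(sorted(out, key=lambda f: f.start))


_PLANT_COUNTER = "ISTP_{:05d}"


def plant_element(
    genome: GenomeRecord,
    spec: ISSpec,
    locus: int,
    orientation: str = "+",
    seed: int = 0,
    disruptive: bool = False,
    element_seed: int | None = None,
    exemplars: dict[str, str] | None = None,
    locus_tag: str | None = None,
) -> tuple[GenomeRecord, ISElement]:
    """Insert a full IS element after genome position ``locus`` (1-based),
    duplicating ``spec.dr_len`` target bases; returns the new genome and
    the truth element (coordinates in the *new* genome).

    The site is slid minimally to keep the planting unambiguous.  Unless
    ``disruptive``, the locus must be intergenic.
    """
    g = genome.sequence
    if not (1 <= locus <= len(g) - 1):
        raise ValueError(f"locus {locus} out of range for genome of {len(g)} nt")
    elem, (t0, t1), protein = element_sequence(spec, element_seed, exemplars)
    ins = elem if orientation == "+" else revcomp(elem)
    k = spec.dr_len
    p = _find_clean_site(g, locus, ins, k, lo=max(k, 1) + 1, hi=len(g) - 1)
    if not disruptive:
        for f in genome.features:
            if f.start <= p < f.end:  # junction inside a CDS
                raise ValueError(
                    f"locus {p} lies inside {f.locus_tag}; pass disruptive=True"
                )
    dup = g[p - k : p] if k else ""
    new_seq = g[:p] + ins + dup + g[p:]
    ins_len = len(ins) + k
    disrupted = None
    if disruptive:
        for f in genome.features:
            if f.start <= p < f.end:
                disrupted = f.locus_tag
    feats = list(_shift_features(genome.features, p, ins_len, disrupted))
    # transposase CDS of the new copy, genome coordinates
    if orientation == "+":
        t_start, t_end = p + t0, p + t1
        t_strand = "+"
    else:
        t_start = p + (len(elem) - t1) + 1
        t_end = p + (len(elem) - t0) + 1
        t_strand = "-"
    tag = locus_tag or _PLANT_COUNTER.format(p % 100000)
    tpase_feat = CdsFeature(
        locus_tag=tag,
        start=t_start,
        end=t_end,
        strand=t_strand,
        product=f"{spec.family} family transposase" if spec.family != "unclassified"
        else "transposase",
        translation=protein,
    )
    feats.append(tpase_feat)
    feats.sort(key=lambda f: f.start)
    new_genome = replace(genome, sequence=new_seq, features=tuple(feats))
    el_start, el_end = p + 1, p + len(ins)
    n_tir = len(spec.tir)
    tir = TIRPair(
        left_span=(el_start, el_start + n_tir - 1),
        left_seq=ins[:n_tir],
        right_span=(el_end - n_tir + 1, el_end),
        right_seq=ins[-n_tir:],
        mismatches=0,
    )
    dr = (
        DirectRepeat(
            sequence=dup,
            left_span=(p - k + 1, p),
            right_span=(el_end + 1, el_end + k),
        )
        if k >= 2
        else None
    )
    truth = ISElement(
        name=spec.subtype,
        family=spec.family,
        subtype=spec.subtype,
        tpase=TpaseCandidate(feature=tpase_feat, match_reason="planted"),
        element_span=(el_start, el_end),
        tir=tir,
        dr=dr,
        completeness="full",
    )
    return new_genome, truth


# ---------------------------------------------------------------------------
# transposition events


def simulate_transposition(
    genome: GenomeRecord,
    donor: ISElement,
    target_gene: str,
    position: int,
    orientation: str = "forward",
    mode: str = "replicative",
    seed: int = 0,
    dr_len: int | None = None,
) -> tuple[GenomeRecord, TranspositionEvent]:
    """Move/copy a donor element into a target gene.

    ``position`` is 1-based within the target gene CDS (coding strand);
    the realised position after the unambiguous-site slide is recorded
    in the returned :class:`TranspositionEvent`.  ``dr_len`` defaults to
    the donor family's characteristic target-site-duplication length.
    Replicative mode retains the donor copy; conservative mode excises
    it, restoring the pre-element donor locus.
    """
    if mode not in ("replicative", "conservative"):
        raise ValueError("mode must be replicative|conservative")
    if orientation not in ("forward", "reverse"):
        raise ValueError("orientation must be forward|reverse")
    gene = genome.feature_by_locus_tag(target_gene)  # KeyError if unknown
    if not (1 <= position <= len(gene)):
        raise ValueError(f"position {position} outside CDS of {target_gene}")
    if dr_len is None:
        dr_len = FAMILY_DR_LEN.get(donor.family, donor.dr.length if donor.dr else 0)
    g = genome.sequence
    d0, d1 = donor.element_span
    donor_seq = g[d0 - 1 : d1]
    donor_strand = donor.tpase.feature.strand
    if gene.strand == "+":
        want = "+" if orientation == "forward" else "-"
        p_req = gene.start - 1 + position
        lo, hi = gene.start, gene.end - 1
    else:
        want = "-" if orientation == "forward" else "+"
        p_req = gene.end - position
        lo, hi = gene.start, gene.end - 1
    ins = donor_seq if donor_strand == want else revcomp(donor_seq)
    p = _find_clean_site(g, p_req, ins, dr_len, lo=lo, hi=hi)
    dup = g[p - dr_len : p] if dr_len else ""
    new_seq = g[:p] + ins + dup + g[p:]
    ins_len = len(ins) + dr_len
    feats = list(_shift_features(genome.features, p, ins_len, gene.locus_tag))
    # annotate the new transposase copy
    tf = donor.tpase.feature
    off_in_donor = (tf.start - d0, tf.end - d0)  # 0-based offsets on donor '+'
    if donor_strand == want:
        n_start = p + 1 + off_in_donor[0]
        n_end = p + 1 + off_in_donor[1]
        n_strand = tf.strand
    else:
        n_start = p + 1 + (len(donor_seq) - 1 - off_in_donor[1])
        n_end = p + 1 + (len(donor_seq) - 1 - off_in_donor[0])
        n_strand = "-" if tf.strand == "+" else "+"
    feats.append(
        CdsFeature(
            locus_tag=f"{tf.locus_tag}_copy",
            start=n_start,
            end=n_end,
            strand=n_strand,
            product=tf.product,
            translation=tf.translation,
        )
    )
    feats.sort(key=lambda f: f.start)
    mutant = replace(genome, sequence=new_seq, features=tuple(feats))
    if mode == "conservative":
        mutant = _excise_donor(mutant, donor, ins_offset=p, ins_len=ins_len)
    if gene.strand == "+":
        realised = p - (gene.start - 1)
    else:
        realised = gene.end - p
    event = TranspositionEvent(
        element_ref=donor.name,
        target_gene=target_gene,
        position=realised,
        orientation=orientation,
        dr_len=dr_len,
        mode=mode,
        seed=seed,
        requested_position=position,
        genome_junction=p,
        inserted_length=ins_len,
    )
    return mutant, event


def _excise_donor(genome: GenomeRecord, donor: ISElement, ins_offset: int, ins_len: int) -> GenomeRecord:
    """Remove the donor element plus one DR copy, restoring the donor locus."""
    d0, d1 = donor.element_span
    # donor coordinates were computed on the pre-insertion genome; shift if
    # the new insertion lies upstream of the donor
    if d0 - 1 >= ins_offset:
        d0 += ins_len
        d1 += ins_len
    cut0, cut1 = d0 - 1, d1  # 0-based half-open element span
    if donor.dr is not None:
        cut1 += donor.dr.length  # drop the 3' DR copy as well
    removed = cut1 - cut0
    g = genome.sequence
    new_seq = g[:cut0] + g[cut1:]
    feats = []
    for f in genome.features:
        if f.locus_tag == donor.tpase.feature.locus_tag:
            continue  # the transposase left with the element
        if f.start > cut1:
            feats.append(replace(f, start=f.start - removed, end=f.end - removed))
        elif f.end <= cut0:
            feats.append(f)
        else:  # overlapped the donor span (should not happen for planted donors)
            continue
    return replace(genome, sequence=new_seq, features=tuple(sorted(feats, key=lambda f: f.start)))


# ---------------------------------------------------------------------------
# counts and Ct tables


def simulate_selection_counts(
    true_freq: float,
    cfu: int,
    n_experiments: int = 1,
    seed: int = 0,
) -> list[CountData]:
    """Binomially sampled mutant-selection counts at a true frequency."""
    if not (0.0 <= true_freq <= 1.0):
        raise ValueError("true_freq must be in [0, 1]")
    rng = np.random.default_rng(seed)
    draws = rng.binomial(cfu, true_freq, size=n_experiments)
    return [CountData(n_selected=int(d), cfu=cfu) for d in draws]


def simulate_ct_table(
    genes: list[str],
    conditions: list[str],
    log2_effects: dict[tuple[str, str], float] | None = None,
    reference_gene: str = "GAPDH",
    sd_ct: float = 0.3,
    n_reps: int = 3,
    seed: int = 0,
    baseline_ct: float = 20.0,
) -> pd.DataFrame:
    """Replicate Ct table with per-(gene, condition) expression effects.

    ``log2_effects[(gene, condition)]`` is the log2 fold change of the
    gene under that condition relative to the first condition; an
    up-regulation of ``e`` log2 units lowers Ct by ``e`` cycles.  The
    reference gene's effect is fixed at 0 (an explicit nonzero effect
    raises).  Columns: gene, condition, replicate, ct.
    """
    effects = dict(log2_effects or {})
    for (gene, cond), e in effects.items():
        if gene == reference_gene and e != 0.0:
            raise ValueError("reference gene effect must be 0")
    rng = np.random.default_rng(seed)
    all_genes = list(genes)
    if reference_gene not in all_genes:
        all_genes.append(reference_gene)
    rows = []
    for gene in all_genes:
        for cond in conditions:
            eff = effects.get((gene, cond), 0.0)
            for rep in range(1, n_reps + 1):
                noise = rng.normal(0.0, sd_ct) if sd_ct > 0 else 0.0
                rows.append({
                    "gene": gene,
                    "condition": cond,
                    "replicate": rep,
                    "ct": baseline_ct - eff + noise,
                })
    return pd.DataFrame(rows)
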