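"""Call IS integrations from wild-type vs mutant gene sequences.

Given the wild-type sequence of a disrupted gene and the mutant
(IS-carrying) sequence, this module locates the integration junction,
resolves the target-site duplication (direct repeat, DR), matches the
inserted element to a genome IS catalog by its terminal inverted
repeats and internal transposase, predicts the PCR amplicon enlargement
a screening assay would see, and classifies the transposition mode
(replicative vs conservative) from donor-locus evidence.

Position convention: the reported position is the 1-based wild-type
coordinate of the last base before the insertion junction, with the
direct repeat reported at the 3' end of the inserted segment (so "an
element integrated at the 275th nt" means the wild-type prefix of 275
bases, including the original copy of the DR, precedes the element in
the mutant).  A DR of length k makes k+1 junction placements
sequence-identical; this canonical form makes calls comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GenomeRecord
from .is_catalog import DirectRepeat, ISCatalog, ISElement, pairwise_identity, revcomp

__all__ = [
    "RawInsertion",
    "InsertionCall",
    "AmpliconPrediction",
    "ReconstructionError",
    "locate_insertion",
    "resolve_direct_repeat",
    "identify_element",
    "call_insertion",
    "in_silico_pcr",
    "classify_transposition_mode",
]

_IUPAC = set("ACGTRYSWKMBDHVN")

_AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class ReconstructionError(RuntimeError):
    """Internal-consistency failure: a call does not reconstruct the mutant."""


@dataclass(frozen=True)
class RawInsertion:
    """Junction and inserted segment before DR resolution.

    ``position`` is the canonical junction (see module docstring);
    ``status`` is ``insertion`` or, when the mutant is not longer than
    the wild type, a diagnosis (``identical`` | ``not_insertion``).
    """

    position: int
    inserted: str
    status: str = "insertion"


@dataclass(frozen=True)
class InsertionCall:
    """A fully characterised integration event in one gene."""

    gene_id: str
    position: int
    orientation: str  # forward|reverse (Tpase direction vs gene coding strand)
    dr: DirectRepeat | None
    element_seq: str  # DR-free inserted element
    inserted_span: tuple[int, int]  # 1-based span of element (incl. DR copy) in mutant
    matched_element: str  # catalog subtype name or "novel"
    tir_match: str  # exact|partial|none
    status: str = "insertion"

    @property
    def dr_length(self) -> int:
        return self.dr.length if self.dr else 0


@dataclass(frozen=True)
class AmpliconPrediction:
    """Predicted PCR products for one primer pair on one template."""

    template_id: str
    primer_fwd: str
    primer_rev: str
    products: tuple[int, ...]  # lengths, 5'-to-5' inclusive
    positions: tuple[tuple[int, int], ...] = ()  # 1-based (fwd 5', rev 5') coords


# ---------------------------------------------------------------------------


def locate_insertion(wt: str, mut: str) -> RawInsertion | None:
    """Locate a single contiguous insertion of ``mut`` relative to ``wt``.

    Returns ``None`` when the sequences are identical; a diagnostic
    ``RawInsertion`` with status ``not_insertion`` when the mutant is
    not longer or the difference is not a clean insertion (substitution
    or deletion); otherwise the canonical junction and inserted segment.
    """
    if not wt or not mut:
        raise ValueError("sequences must be non-empty")
    wt, mut = wt.upper(), mut.upper()
    if wt == mut:
        return None
    if len(mut) <= len(wt):
        return RawInsertion(position=0, inserted="", status="not_insertion")
    # longest common prefix / suffix
    p = 0
    lim = len(wt)
    while p < lim and wt[p] == mut[p]:
        p += 1
    s = 0
    while s < lim and wt[len(wt) - 1 - s] == mut[len(mut) - 1 - s]:
        s += 1
    if p + s < len(wt):
        # substitutions besides the length change: not a clean insertion
        return RawInsertion(position=0, inserted="", status="not_insertion")
    d = len(mut) - len(wt)
    # consistent junctions span [len(wt)-s, p]; canonical = rightmost, which
    # keeps the duplicated target bases at the 3' end of the inserted segment
    pos = min(p, len(wt))
    return RawInsertion(position=pos, inserted=mut[pos : pos + d])


def resolve_direct_repeat(
    wt: str,
    mut: str,
    raw: RawInsertion,
    min_dr: int = 2,
    max_dr: int = 12,
) -> tuple[int, str, DirectRepeat | None]:
    """Strip the target-site duplication from a raw insertion.

    Finds the largest ``k <= max_dr`` such that the ``k`` wild-type
    bases ending at the junction reappear at the 3' end of the inserted
    segment, i.e. flank the element on both sides in the mutant.
    Returns ``(position, element_seq, dr)`` with the element DR-free;
    ``dr`` is ``None`` when ``k < min_dr``.
    """
    if raw.status != "insertion":
        raise ValueError("raw input is not a genuine insertion")
    wt, mut = wt.upper(), mut.upper()
    pos, ins = raw.position, raw.inserted
    k_hi = min(max_dr, pos, len(ins))
    best_k = 0
    for k in range(k_hi, 0, -1):
        if wt[pos - k : pos] == ins[len(ins) - k :]:
            best_k = k
            break
    if best_k < min_dr:
        return pos, ins, None
    k = best_k
    dr = DirectRepeat(
        sequence=wt[pos - k : pos],
        left_span=(pos - k + 1, pos),
        right_span=(pos + len(ins) - k + 1, pos + len(ins)),
    )
    return pos, ins[: len(ins) - k], dr


def _arm_mismatches(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def _longest_orf(seq: str, min_aa: int = 50) -> str | None:
    """Longest Met-to-stop ORF translation in the three plus-strand frames."""
    from Bio.Seq import Seq

    best = None
    for frame in range(3):
        sub = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
        if len(sub) < 3 * min_aa:
            continue
        prot = str(Seq(sub).translate(table=11))
        for chunk in prot.split("*"):
            idx = chunk.find("M")
            if idx >= 0:
                orf = chunk[idx:]
                if len(orf) >= min_aa and (best is None or len(orf) > len(best)):
                    best = orf
    return best


def _tpase_strand(seq: str) -> tuple[str, str | None]:
    """Strand carrying the element's transposase, by the longest-ORF rule.

    An IS element reads identically at both boundaries in either
    orientation (TIR + body + rc(TIR)), so orientation is carried by the
    transposase ORF direction alone.
    """
    plus = _longest_orf(seq)
    minus = _longest_orf(revcomp(seq))
    if plus is None and minus is None:
        return "+", None
    if minus is None or (plus is not None and len(plus) >= len(minus)):
        return "+", plus
    return "-", minus


def identify_element(
    element_seq: str,
    catalog: ISCatalog,
    genome: GenomeRecord | None = None,
    gene_strand: str = "+",
    max_arm_mismatch: int = 2,
    tpase_threshold: float = 0.5,
) -> tuple[str, str, str]:
    """Match an inserted element to the catalog and orient it.

    Terminal arms are compared against every catalog element's TIR in
    both orientations (exact match -> ``exact``; ``<= max_arm_mismatch``
    substitutions -> ``partial``); if no arm matches, the best internal
    ORF is compared against cluster-representative transposases
    (``genome`` supplies the catalog translations' source; optional).
    Returns ``(matched_element, orientation, tir_match)``, orientation
    being ``forward`` when the element's transposase runs with the
    disrupted gene's coding strand.
    """
    if not catalog.elements:
        raise ValueError("catalog is empty")
    seq = element_seq.upper()
    # the element's transposase strand within the inserted segment fixes the
    # orientation: forward = Tpase runs with the disrupted gene's coding strand
    ins_strand, orf = _tpase_strand(seq)
    orientation = "forward" if ins_strand == gene_strand else "reverse"

    best: tuple[int, int, str] | None = None  # (rank, -armlen, name)
    for el in catalog.elements:
        if el.tir is None:
            continue
        arm = el.tir.left_seq
        n = len(arm)
        if len(seq) < 2 * n:
            continue
        mm = max(
            _arm_mismatches(seq[:n], arm),
            _arm_mismatches(seq[-n:], revcomp(arm)),
        )
        if mm == 0:
            rank = 0
        elif mm <= max_arm_mismatch:
            rank = 1
        else:
            continue
        # prefer exact over partial, then the longest arm, then name order
        key = (rank, -n, el.name)
        if best is None or key < best:
            best = key
    if best is not None:
        return best[2], orientation, "exact" if best[0] == 0 else "partial"
    # no arm match: fall back on transposase identity of the best internal ORF
    if orf and genome is not None:
        best_name, best_id = None, 0.0
        for cl in catalog.clusters:
            try:
                feat = genome.feature_by_locus_tag(cl.representative)
            except KeyError:
                continue
            if not feat.translation:
                continue
            ident = pairwise_identity(orf, feat.translation)
            if ident > best_id:
                best_name, best_id = cl.subtype_label, ident
        if best_name is not None and best_id >= tpase_threshold:
            return best_name, orientation, "none"
    return "novel", orientation, "none"


def call_insertion(
    wt: str,
    mut: str,
    gene_id: str,
    catalog: ISCatalog | None = None,
    genome: GenomeRecord | None = None,
    gene_strand: str = "+",
    min_dr: int = 2,
    max_dr: int = 12,
) -> InsertionCall | None:
    """Full characterisation of one integration event.

    Orchestrates junction location, DR resolution and element
    identification, then enforces the reconstruction invariant: the
    wild type with (element + one DR copy) re-inserted must equal the
    mutant exactly.  Returns ``None`` for identical sequences and a
    status-only call for non-insertion differences.
    """
    raw = locate_insertion(wt, mut)
    if raw is None:
        return None
    if raw.status != "insertion":
        return InsertionCall(
            gene_id=gene_id, position=0, orientation="forward", dr=None,
            element_seq="", inserted_span=(0, 0), matched_element="novel",
            tir_match="none", status=raw.status,
        )
    pos, element, dr = resolve_direct_repeat(wt, mut, raw, min_dr=min_dr, max_dr=max_dr)
    if catalog is not None and catalog.elements:
        matched, orientation, tir_match = identify_element(
            element, catalog, genome=genome, gene_strand=gene_strand
        )
    else:
        matched, orientation, tir_match = "novel", "forward", "none"
    wt_u, mut_u = wt.upper(), mut.upper()
    dr_seq = dr.sequence if dr else ""
    rebuilt = wt_u[:pos] + element + dr_seq + wt_u[pos:]
    if rebuilt != mut_u:
        raise ReconstructionError(
            f"{gene_id}: call at position {pos} does not reconstruct the mutant"
        )
    call = InsertionCall(
        gene_id=gene_id,
        position=pos,
        orientation=orientation,
        dr=dr,
        element_seq=element,
        inserted_span=(pos + 1, pos + len(raw.inserted)),
        matched_element=matched,
        tir_match=tir_match,
    )
    return call


# ---------------------------------------------------------------------------
# in-silico PCR


def _match_with_ambiguity(template: str, primer: str, max_mismatch: int) -> list[int]:
    """0-based start positions where the primer anneals (IUPAC-aware)."""
    hits = []
    n = len(primer)
    for start in range(len(template) - n + 1):
        mm = 0
        for t, p in zip(template[start : start + n], primer):
            if t not in _AMBIG[p]:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            hits.append(start)
    return hits


def in_silico_pcr(
    template: str,
    fwd: str,
    rev: str,
    template_id: str = "template",
    max_mismatch: int = 0,
    max_product: int = 20000,
) -> AmpliconPrediction:
    """Predict PCR products from convergent primer placements.

    The forward primer anneals to the plus strand, the reverse primer to
    the minus strand 3'-ward of it; product length is measured 5' end to
    5' end, inclusive.  Primers must be >= 15 nt of IUPAC DNA;
    ``max_mismatch`` defaults to exact matching.
    """
    for name, primer in (("fwd", fwd), ("rev", rev)):
        if len(primer) < 15:
            raise ValueError(f"{name} primer shorter than 15 nt")
        bad = set(primer.upper()) - _IUPAC
        if bad:
            raise ValueError(f"{name} primer has non-IUPAC characters: {sorted(bad)}")
    template = template.upper()
    fwd_u, rev_u = fwd.upper(), rev.upper()
    fwd_hits = _match_with_ambiguity(template, fwd_u, max_mismatch)
    # the reverse primer matches the plus strand as its reverse complement
    rev_site = revcomp(rev_u)
    rev_hits = _match_with_ambiguity(template, rev_site, max_mismatch)
    products = []
    positions = []
    for f0 in fwd_hits:
        for r0 in rev_hits:
            five_rev = r0 + len(rev_site) - 1  # 0-based 5' end of reverse primer
            length = five_rev - f0 + 1
            if length >= len(fwd_u) + len(rev_u) and length <= max_product:
                products.append(length)
                positions.append((f0 + 1, five_rev + 1))
    order = sorted(range(len(products)), key=lambda idx: positions[idx])
    return AmpliconPrediction(
        template_id=template_id,
        primer_fwd=fwd_u,
        primer_rev=rev_u,
        products=tuple(products[idx] for idx in order),
        positions=tuple(positions[idx] for idx in order),
    )


# ---------------------------------------------------------------------------
# transposition mode


def classify_transposition_mode(
    catalog_before: ISCatalog,
    call: InsertionCall,
    donor_present: dict[str, bool],
) -> str:
    """Replicative vs conservative transposition from donor evidence.

    ``donor_present`` maps each donor-copy locus tag of the matched
    subtype to whether that copy is still present after the event (as
    established e.g. by locus-specific PCR).  All donors retained plus
    the new copy -> ``replicative``; exactly one donor lost ->
    ``conservative``; anything else -> ``indeterminate``.
    """
    if call.matched_element == "novel":
        raise ValueError("mode classification requires a catalog-matched call")
    donors = catalog_before.elements_of_subtype(call.matched_element)
    if not donors:
        raise ValueError(f"subtype {call.matched_element} not in catalog")
    missing = [el.locus_tag for el in donors if not donor_present.get(el.locus_tag, False)]
    unknown = [el.locus_tag for el in donors if el.locus_tag not in donor_present]
    if unknown:
        return "indeterminate"
    if not missing:
        return "replicative"
    if len(missing) == 1:
        return "conservative"
    return "indeterminate"
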