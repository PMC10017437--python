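"""IS-element discovery: TIR/DR detection, subtype clustering, family calls.

An insertion sequence (IS) is modelled as a transposase ORF bounded by a
terminal inverted repeat (TIR): a short arm at the element's 5' end
whose reverse complement closes the 3' end.  Integration usually
duplicates a few bases of the target site, leaving identical direct
repeats (DR, the target-site duplication) immediately outside both arms.
This module finds the best TIR arm pair in the flanking window around
each transposase candidate, reads off the DR, clusters transposases into
subtypes by global amino-acid identity (single linkage), assigns each
subtype to a known IS family by best identity against a reference
exemplar set, and assembles the genome-wide catalog.

TIR search
----------
The search enumerates every (left-arm start, right-arm end, arm length)
triple with the arm length in ``[min_arm, max_arm]`` and at most
``max_mismatch`` substitutions between the left arm and the reverse
complement of the right arm, scoring ``arm_length - mismatches``.  The
left arm must *start* in the upstream flank or within the first
``orf_overlap`` nt of the ORF, and the right arm must *end* in the
downstream flank or last ``orf_overlap`` nt of the ORF — some families'
TIRs genuinely overlap the transposase ORF.  The implementation walks
anti-diagonals of the base-complementarity matrix with numpy, which is
algebraically identical to (and tested against) the cubic brute-force
enumeration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq

from .genome_io import (
    CdsFeature,
    FlankWindow,
    GenomeRecord,
    TpaseCandidate,
    extract_flank_window,
    find_transposase_candidates,
    DEFAULT_TPASE_KEYWORDS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TIRPair",
    "DirectRepeat",
    "ISElement",
    "TpaseCluster",
    "ISCatalog",
    "CatalogConfig",
    "find_tir",
    "find_tir_candidates",
    "find_dr",
    "pairwise_identity",
    "cluster_subtypes",
    "assign_family",
    "build_catalog",
    "load_family_exemplars",
    "FAMILY_DR_LEN",
    "IS_FAMILIES",
]

IS_FAMILIES = ("IS1", "IS4", "IS5", "IS66", "IS630", "IS701")

#: Characteristic target-site-duplication length (nt) per IS family.
#: These are catalog-level defaults used by the transposition simulator;
#: observed DRs are always measured from sequence, never from this table.
FAMILY_DR_LEN: dict[str, int] = {
    "IS1": 9,
    "IS4": 9,
    "IS5": 3,
    "IS66": 8,
    "IS630": 3,
    "IS701": 4,
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class DegenerateInputError(ValueError):
    """Input too short/empty for the requested analysis."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TIRPair:
    """A terminal-inverted-repeat arm pair, spans 1-based within a window."""

    left_span: tuple[int, int]
    left_seq: str
    right_span: tuple[int, int]
    right_seq: str
    mismatches: int

    def __post_init__(self) -> None:
        if self.left_span[1] >= self.right_span[0]:
            raise ValueError("left arm must end before the right arm begins")
        if len(self.left_seq) != len(self.right_seq):
            raise ValueError("TIR arms must have equal length")
        diff = sum(a != b for a, b in zip(self.left_seq, revcomp(self.right_seq)))
        if diff != self.mismatches:
            raise ValueError(
                f"recorded mismatches ({self.mismatches}) disagree with arms ({diff})"
            )

    @property
    def arm_length(self) -> int:
        return len(self.left_seq)

    @property
    def score(self) -> int:
        return self.arm_length - self.mismatches


@dataclass(frozen=True)
class DirectRepeat:
    """Target-site duplication flanking a TIR pair (exact match)."""

    sequence: str
    left_span: tuple[int, int]
    right_span: tuple[int, int]
    truncated_context: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ISElement:
    """One full or partial IS copy anchored at a transposase locus."""

    name: str
    family: str
    subtype: str
    tpase: TpaseCandidate
    element_span: tuple[int, int]
    tir: TIRPair | None = None
    dr: DirectRepeat | None = None
    completeness: str = "full"

    def __post_init__(self) -> None:
        if (self.tir is None) != (self.completeness == "partial"):
            raise ValueError("completeness must be 'partial' iff tir is absent")

    @property
    def locus_tag(self) -> str:
        return self.tpase.feature.locus_tag

    def element_sequence(self, genome: GenomeRecord) -> str:
        """Element sequence on the plus strand of the genome."""
        return genome.subseq(*self.element_span)


@dataclass
class TpaseCluster:
    """Subtype cluster of transposases under single-linkage identity."""

    subtype_label: str
    member_locus_tags: list[str]
    representative: str
    identity_matrix: np.ndarray  # over members, symmetric, unit diagonal
    family: str = "unclassified"

    def __post_init__(self) -> None:
        m = np.asarray(self.identity_matrix, dtype=float)
        if m.shape != (len(self.member_locus_tags),) * 2:
            raise ValueError("identity matrix shape must match member count")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 1.0):
            raise ValueError("identity matrix must be symmetric with unit diagonal")
        self.identity_matrix = m


@dataclass
class ISCatalog:
    """All IS elements of one genome plus their subtype clusters."""

    genome_id: str
    elements: list[ISElement]
    clusters: list[TpaseCluster]
    unclustered_locus_tags: list[str] = field(default_factory=list)

    @property
    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for el in self.elements:
            counts[el.family] = counts.get(el.family, 0) + 1
        return counts

    @property
    def n_full(self) -> int:
        return sum(1 for el in self.elements if el.completeness == "full")

    @property
    def n_partial(self) -> int:
        return sum(1 for el in self.elements if el.completeness == "partial")

    def elements_of_subtype(self, subtype: str) -> list[ISElement]:
        return [el for el in self.elements if el.subtype == subtype]

    # -- exports -----------------------------------------------------------
    TSV_COLUMNS = (
        "name", "family", "subtype", "locus_tag", "start", "end", "strand",
        "tir_seq", "tir_len", "tir_mismatches", "dr_seq", "dr_len", "completeness",
    )

    def to_rows(self) -> list[dict]:
        rows = []
        for el in self.elements:
            rows.append({
                "name": el.name,
                "family": el.family,
                "subtype": el.subtype,
                "locus_tag": el.locus_tag,
                "start": el.element_span[0],
                "end": el.element_span[1],
                "strand": el.tpase.feature.strand,
                "tir_seq": el.tir.left_seq if el.tir else "",
                "tir_len": el.tir.arm_length if el.tir else 0,
                "tir_mismatches": el.tir.mismatches if el.tir else "",
                "dr_seq": el.dr.sequence if el.dr else "",
                "dr_len": el.dr.length if el.dr else 0,
                "completeness": el.completeness,
            })
        return rows

    def write_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("\t".join(self.TSV_COLUMNS) + "\n")
            for row in self.to_rows():
                fh.write("\t".join(str(row[c]) for c in self.TSV_COLUMNS) + "\n")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for el in self.elements:
                attrs = (
                    f"ID={el.name}_{el.locus_tag};Name={el.name};"
                    f"mobile_element_type=insertion sequence:{el.family};"
                    f"subtype={el.subtype};completeness={el.completeness}"
                )
                fh.write(
                    "\t".join([
                        self.genome_id, "iskit", "mobile_genetic_element",
                        str(el.element_span[0]), str(el.element_span[1]),
                        ".", el.tpase.feature.strand, ".", attrs,
                    ]) + "\n"
                )

    def cluster_report(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "clusters": [
                {
                    "subtype": c.subtype_label,
                    "family": c.family,
                    "members": list(c.member_locus_tags),
                    "representative": c.representative,
                    "identity_matrix": [
                        [round(float(v), 4) for v in row] for row in c.identity_matrix
                    ],
                }
                for c in self.clusters
            ],
            "unclustered": list(self.unclustered_locus_tags),
            "family_counts": self.family_counts,
            "n_full": self.n_full,
            "n_partial": self.n_partial,
        }

    def write_cluster_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.cluster_report(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# TIR search


def find_tir_candidates(
    window: FlankWindow,
    min_arm: int = 6,
    max_arm: int = 40,
    max_mismatch: int = 2,
    orf_overlap: int = 60,
    min_score: int = 16,
    top_n: int = 5,
) -> list[TIRPair]:
    """Top-``top_n`` TIR arm-pair candidates, best first.

    Candidates closer than 8 nt to an already-reported pair (on both
    arms) are folded into it, so the list holds genuinely distinct
    placements.

    Score is ``arm_length - mismatches``; ties prefer fewer mismatches,
    then a smaller enclosed span, then the leftmost left arm.  The left
    arm must start upstream of (or within the first ``orf_overlap`` nt
    of) the transposase ORF; mirrored for the right arm.

    ``min_score`` sets the noise floor: in kb-scale GC-rich flanks,
    chance arm pairs scoring 13-15 are expected by combinatorics alone,
    so anything weaker than the floor is reported as "no TIR" rather
    than as a spurious arm pair.  Lower it (with a smaller window and
    ``max_mismatch=0``) to hunt genuinely short arms such as 6-nt TIRs.
    """
    seq = window.sequence.upper()
    L = len(seq)
    if L < 2 * min_arm:
        raise DegenerateInputError(
            f"window of {L} nt cannot hold two {min_arm}-nt arms"
        )
    ts, te = window.tpase_offset  # 1-based
    ts0, te0 = ts - 1, te - 1  # 0-based
    i_max = min(ts0 + orf_overlap, L - 1)  # last allowed left-arm start (0-based)
    u_min = max(te0 - orf_overlap, 0)      # first allowed right-arm end (0-based)

    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)[::-1].copy()
    # C[p, q] = 1 iff base p is complementary to base q
    Np = min(i_max + max_arm, L)        # left arm may extend past its start bound
    q_lo = max(u_min - max_arm + 1, 0)  # right arm may begin before its end bound
    left = arr[:Np]
    right = comp[q_lo:]
    Nq = right.size
    C = (left[:, None] == right[None, :]).astype(np.int16)

    # candidates ranked by key (-(score), mism, enclosed span, leftmost i),
    # i.e. maximise score = a - mism, then fewer mismatches, then smaller
    # enclosed span, then the leftmost left arm
    hits: list[np.ndarray] = []  # columns: a, mism, i, u
    M = np.zeros_like(C)
    # after step t, M[x, t + y] holds the complementary-match count of the
    # arm pair with left start x, right end (q_lo + t + y), arm length t+1;
    # fixing (left start, right end) makes the count incremental in length.
    for t in range(max_arm):
        if t >= Np or t >= Nq:
            break
        Mv = M[: Np - t, t:]
        Mv += C[t:, : Nq - t]
        a = t + 1
        if a < min_arm:
            continue
        hit = Mv >= max(a - max_mismatch, min_score)
        if not hit.any():
            continue
        xs, ys = np.nonzero(hit)
        i = xs
        u = q_lo + ys + t
        j = u - a + 1
        ok = (i <= i_max) & (u >= u_min) & (j > i + a - 1)
        if not ok.any():
            continue
        i, u = i[ok], u[ok]
        mism = (a - Mv[xs[ok], ys[ok]]).astype(np.int64)
        hits.append(np.stack([np.full(i.shape, a), mism, i, u], axis=1))
    if not hits:
        return []
    allh = np.concatenate(hits, axis=0)
    a_c, mism_c, i_c, u_c = allh[:, 0], allh[:, 1], allh[:, 2], allh[:, 3]
    order = np.lexsort((i_c, u_c - i_c + 1, mism_c, -(a_c - mism_c)))
    out: list[TIRPair] = []
    placed: list[tuple[int, int]] = []
    for idx in order.tolist():
        a, mism, i, u = (int(allh[idx, 0]), int(allh[idx, 1]),
                         int(allh[idx, 2]), int(allh[idx, 3]))
        if any(abs(i - pi) < 8 and abs(u - pu) < 8 for pi, pu in placed):
            continue  # same placement, shorter/noisier variant
        j = u - a + 1
        out.append(
            TIRPair(
                left_span=(i + 1, i + a),
                left_seq=seq[i : i + a],
                right_span=(j + 1, u + 1),
                right_seq=seq[j : u + 1],
                mismatches=mism,
            )
        )
        placed.append((i, u))
        if len(out) == top_n:
            break
    return out


def find_tir(
    window: FlankWindow,
    min_arm: int = 6,
    max_arm: int = 40,
    max_mismatch: int = 2,
    orf_overlap: int = 60,
    min_score: int = 16,
) -> TIRPair | None:
    """Best-scoring TIR arm pair in a flank window, or ``None``.

    Scoring, tie-breaks and constraints as in :func:`find_tir_candidates`.
    """
    cands = find_tir_candidates(
        window,
        min_arm=min_arm,
        max_arm=max_arm,
        max_mismatch=max_mismatch,
        orf_overlap=orf_overlap,
        min_score=min_score,
        top_n=1,
    )
    return cands[0] if cands else None


def find_dr(
    window: FlankWindow,
    tir: TIRPair,
    min_dr: int = 2,
    max_dr: int = 12,
) -> DirectRepeat | None:
    """Longest exact duplication immediately outside the TIR arms.

    Compares the ``k`` nt 5' of the left arm with the ``k`` nt 3' of the
    right arm for ``k`` from ``max_dr`` down to ``min_dr``; returns the
    longest exact match, or ``None``.  When the window edge leaves fewer
    than ``max_dr`` nt of context the available shorter range is
    searched and any result is flagged ``truncated_context``.
    """
    seq = window.sequence.upper()
    ls = tir.left_span[0] - 1   # 0-based left-arm start
    re_ = tir.right_span[1]     # 0-based index just past right arm
    avail_left = ls
    avail_right = len(seq) - re_
    k_hi = min(max_dr, avail_left, avail_right)
    truncated = min(avail_left, avail_right) < max_dr
    for k in range(k_hi, min_dr - 1, -1):
        left = seq[ls - k : ls]
        right = seq[re_ : re_ + k]
        if left == right:
            return DirectRepeat(
                sequence=left,
                left_span=(ls - k + 1, ls),
                right_span=(re_ + 1, re_ + k),
                truncated_context=truncated,
            )
    return None


# ---------------------------------------------------------------------------
# identity, clustering, families


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity with the *shorter-sequence* denominator.

    Identity = identical aligned positions / length of the shorter
    sequence, after a global alignment with affine gaps (match 1,
    mismatch 0).  Symmetric; identity(a, a) == 1.
    """
    if not a or not b:
        raise DegenerateInputError("pairwise_identity requires non-empty sequences")
    a, b = a.upper(), b.upper()
    if a == b:
        return 1.0
    aln = _ALIGNER.align(a, b)[0]
    ident = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        sa, sb = a[a0:a1], b[b0:b1]
        ident += sum(x == y for x, y in zip(sa, sb))
    return ident / min(len(a), len(b))


def identity_matrix(translations: Sequence[str]) -> np.ndarray:
    n = len(translations)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_identity(translations[i], translations[j])
    return m


def cluster_subtypes(
    candidates: Sequence[TpaseCandidate],
    subtype_threshold: float = 0.90,
) -> tuple[list[TpaseCluster], list[TpaseCandidate]]:
    """Single-linkage clusters of transposases at an identity threshold.

    Returns ``(clusters, excluded)`` where ``excluded`` holds candidates
    lacking a translation.  Cluster labels are deterministic: clusters
    are ordered by the genome coordinate of their leftmost member and
    labelled ``subtype_1``, ``subtype_2``, ...  (renamed during catalog
    assembly).  The result is invariant to input order.
    """
    withtr = [c for c in candidates if c.feature.translation]
    excluded = [c for c in candidates if not c.feature.translation]
    for c in excluded:
        logger.warning(
            "candidate %s lacks a translation; excluded from clustering",
            c.feature.locus_tag,
        )
    if not withtr:
        return [], excluded
    withtr = sorted(withtr, key=lambda c: c.feature.start)
    trans = [c.feature.translation for c in withtr]
    full = identity_matrix(trans)
    n = len(withtr)
    if n == 1:
        labels = np.array([1])
    else:
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        dist = np.clip(1.0 - full, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="single")
        labels = fcluster(Z, t=1.0 - subtype_threshold, criterion="distance")
    clusters = []
    for lab in sorted(set(labels), key=lambda l: min(
        withtr[i].feature.start for i in range(n) if labels[i] == l
    )):
        idx = [i for i in range(n) if labels[i] == lab]
        sub = full[np.ix_(idx, idx)]
        # medoid representative: max summed identity, tie -> leftmost
        rep_local = max(range(len(idx)), key=lambda r: (sub[r].sum(), -idx[r]))
        clusters.append(
            TpaseCluster(
                subtype_label=f"subtype_{len(clusters) + 1}",
                member_locus_tags=[withtr[i].feature.locus_tag for i in idx],
                representative=withtr[idx[rep_local]].feature.locus_tag,
                identity_matrix=sub,
            )
        )
    return clusters, excluded


def load_family_exemplars(path: str | Path | None = None) -> dict[str, str]:
    """Family -> exemplar transposase protein. Default: packaged set.

    The packaged exemplar file is a synthetic stand-in set (one
    deterministic pseudo-protein per DDE family at a family-typical
    length); replace with curated reference transposases via ``path``
    for real-genome work.
    """
    if path is None:
        ref = resources.files("iskit.data").joinpath("family_exemplars_synthetic.faa")
        with resources.as_file(ref) as p:
            records = list(SeqIO.parse(str(p), "fasta"))
    else:
        records = list(SeqIO.parse(str(path), "fasta"))
    out = {}
    for rec in records:
        fam = rec.id.split("|")[0]
        out[fam] = str(rec.seq)
    if not out:
        raise ValueError("exemplar set is empty")
    return out


def assign_family(
    cluster: TpaseCluster,
    exemplars: Mapping[str, str],
    representative_translation: str,
    family_threshold: float = 0.30,
) -> str:
    """Family of the best-identity exemplar, or ``unclassified``."""
    if not exemplars:
        raise ValueError("exemplar set must be non-empty")
    best_fam, best_id = "unclassified", -1.0
    for fam in sorted(exemplars):
        ident = pairwise_identity(representative_translation, exemplars[fam])
        if ident > best_id:
            best_fam, best_id = fam, ident
    return best_fam if best_id >= family_threshold else "unclassified"


# ---------------------------------------------------------------------------
# catalog assembly


@dataclass
class CatalogConfig:
    """Tunable parameters of catalog construction."""

    keywords: tuple[str, ...] = DEFAULT_TPASE_KEYWORDS
    flank_len: int = 1000
    min_arm: int = 6
    max_arm: int = 40
    max_mismatch: int = 2
    min_score: int = 16
    orf_overlap: int = 60
    min_dr: int = 2
    max_dr: int = 12
    tir_top_n: int = 5
    dr_corroboration_min: int = 3
    subtype_threshold: float = 0.90
    family_threshold: float = 0.30
    strain_tag: str = "Drpg"
    exemplar_path: str | None = None

    def validate(self) -> None:
        if not (1 <= self.min_arm <= self.max_arm):
            raise ValueError("require 1 <= min_arm <= max_arm")
        if self.min_score < 1:
            raise ValueError("min_score must be >= 1")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if not (0 <= self.min_dr <= self.max_dr):
            raise ValueError("require 0 <= min_dr <= max_dr")
        for name in ("subtype_threshold", "family_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.flank_len < 0:
            raise ValueError("flank_len must be >= 0")


def build_catalog(genome: GenomeRecord, config: CatalogConfig | None = None) -> ISCatalog:
    """End-to-end IS catalog of one genome.

    Pipeline: keyword candidate detection -> flank-window extraction ->
    TIR search -> DR search -> element definition (no TIR = partial) ->
    subtype clustering -> family assignment -> deterministic naming
    (``IS<tag><n>`` per subtype, numbered by family then genome order).
    A failure at any single candidate is logged and skipped, never
    aborting the whole catalog.
    """
    cfg = config or CatalogConfig()
    cfg.validate()
    candidates = find_transposase_candidates(genome, cfg.keywords)
    # ensure translations (annotation may omit them)
    fixed: list[TpaseCandidate] = []
    for c in candidates:
        f = c.feature
        if not f.translation:
            try:
                cds = genome.subseq(f.start, f.end)
                if f.strand == "-":
                    cds = revcomp(cds)
                tr = str(Seq(cds).translate(table=11, to_stop=True))
                if tr:
                    f = CdsFeature(f.locus_tag, f.start, f.end, f.strand, f.product, tr)
            except Exception:  # malformed CDS: keep without translation
                logger.warning("could not translate %s", f.locus_tag)
            c = TpaseCandidate(feature=f, match_reason=c.match_reason)
        fixed.append(c)
    candidates = fixed

    per_candidate: dict[str, tuple[TIRPair | None, DirectRepeat | None, tuple[int, int]]] = {}
    for cand in candidates:
        feat = cand.feature
        try:
            window = extract_flank_window(genome, cand, flank_len=cfg.flank_len)
            tir_cands = find_tir_candidates(
                window,
                min_arm=cfg.min_arm,
                max_arm=cfg.max_arm,
                max_mismatch=cfg.max_mismatch,
                orf_overlap=cfg.orf_overlap,
                min_score=cfg.min_score,
                top_n=cfg.tir_top_n,
            )
        except DegenerateInputError as exc:
            logger.warning("skipping TIR search at %s: %s", feat.locus_tag, exc)
            tir_cands = []
            window = None
        # among the top-scoring arm pairs, prefer the first corroborated by
        # an exact target-site duplication: a chance arm pair rarely comes
        # with a flanking DR, a real integration boundary usually does
        tir = None
        dr = None
        if tir_cands:
            tir, dr = tir_cands[0], None
            for tc in tir_cands:
                d = find_dr(window, tc, min_dr=cfg.min_dr, max_dr=cfg.max_dr)
                if d is not None and d.length >= cfg.dr_corroboration_min:
                    tir, dr = tc, d
                    break
            else:
                dr = find_dr(window, tir, min_dr=cfg.min_dr, max_dr=cfg.max_dr)
        span = feat.span
        if tir is not None and window is not None:
            off = window.window_span[0] - 1
            span = (off + tir.left_span[0], off + tir.right_span[1])
        per_candidate[feat.locus_tag] = (tir, dr, span)

    clusters, excluded = cluster_subtypes(candidates, cfg.subtype_threshold)
    exemplars = load_family_exemplars(cfg.exemplar_path)
    by_tag = {c.feature.locus_tag: c for c in candidates}
    for cl in clusters:
        rep_tr = by_tag[cl.representative].feature.translation
        cl.family = assign_family(cl, exemplars, rep_tr, cfg.family_threshold)
    # untranslatable candidates form singleton unclassified clusters so that
    # every element belongs to exactly one cluster
    for c in excluded:
        clusters.append(
            TpaseCluster(
                subtype_label="subtype_x",
                member_locus_tags=[c.feature.locus_tag],
                representative=c.feature.locus_tag,
                identity_matrix=np.eye(1),
                family="unclassified",
            )
        )

    # naming: number subtypes by family (ordered by first genome appearance
    # of the family), then by genome order within the family
    def cluster_leftmost(cl: TpaseCluster) -> int:
        return min(by_tag[t].feature.start for t in cl.member_locus_tags)

    fam_first: dict[str, int] = {}
    for cl in clusters:
        pos = cluster_leftmost(cl)
        fam_first[cl.family] = min(fam_first.get(cl.family, pos), pos)
    ordered = sorted(clusters, key=lambda cl: (fam_first[cl.family], cluster_leftmost(cl)))
    for n, cl in enumerate(ordered, start=1):
        cl.subtype_label = f"IS{cfg.strain_tag}{n}"

    elements = []
    for cand in candidates:
        tag = cand.feature.locus_tag
        tir, dr, span = per_candidate[tag]
        cl = next(c for c in clusters if tag in c.member_locus_tags)
        elements.append(
            ISElement(
                name=cl.subtype_label,
                family=cl.family,
                subtype=cl.subtype_label,
                tpase=cand,
                element_span=span,
                tir=tir,
                dr=dr,
                completeness="full" if tir is not None else "partial",
            )
        )
    return ISCatalog(
        genome_id=genome.id,
        elements=elements,
        clusters=ordered,
        unclustered_locus_tags=[c.feature.locus_tag for c in excluded],
    )
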