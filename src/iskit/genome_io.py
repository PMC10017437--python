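"""Annotated-genome I/O and transposase-candidate discovery.

This module reads annotated bacterial genomes (GenBank flat files, or
FASTA + GFF3), represents them as light-weight records with 1-based
inclusive CDS coordinates (the GenBank convention), finds candidate
transposase ORFs by annotation keyword, and extracts the flanking
analysis window around each candidate (by default 1 kb on each side of
the ORF, so a typical window is ~3 kb) in which terminal inverted
repeats and target-site duplications are subsequently searched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRecord",
    "CdsFeature",
    "TpaseCandidate",
    "FlankWindow",
    "GenomeFormatError",
    "MissingAnnotationError",
    "read_genome",
    "read_genomes",
    "write_genbank",
    "find_transposase_candidates",
    "extract_flank_window",
    "DEFAULT_TPASE_KEYWORDS",
]

#: Annotation keywords that mark a CDS as a transposase candidate.
DEFAULT_TPASE_KEYWORDS = ("transposase", "insertion sequence", "IS family")

_DNA_RE = re.compile(r"^[ACGTRYSWKMBDHVN]+$", re.IGNORECASE)


class GenomeFormatError(ValueError):
    """Raised when an input file cannot be parsed under the named format."""


class MissingAnnotationError(ValueError):
    """Raised when annotation (GFF3) is required but absent."""


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature with 1-based inclusive coordinates."""

    locus_tag: str
    start: int
    end: int
    strand: str  # "+" or "-"
    product: str = ""
    translation: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeRecord:
    """One replicon: sequence plus CDS annotation.

    Coordinates throughout are 1-based inclusive.  ``topology`` is
    ``"linear"`` or ``"circular"``; feature spans may wrap the origin
    only on circular records.
    """

    id: str
    sequence: str
    topology: str = "linear"
    features: tuple[CdsFeature, ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("genome sequence must be non-empty")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear|circular, got {self.topology!r}")
        if not _DNA_RE.match(self.sequence):
            raise ValueError("sequence contains non-IUPAC characters")
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "features", tuple(self.features))
        L = len(self.sequence)
        for f in self.features:
            if f.end > L and self.topology != "circular":
                raise ValueError(
                    f"feature {f.locus_tag} span {f.span} exceeds length {L}"
                )
            if f.start > f.end and self.topology != "circular":
                raise ValueError(
                    f"feature {f.locus_tag} has start > end on a linear record"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        """GC fraction of the sequence."""
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice; wraps the origin on circular records."""
        L = len(self.sequence)
        if start >= 1 and end <= L:
            return self.sequence[start - 1 : end]
        if self.topology != "circular":
            raise IndexError(f"span ({start}, {end}) outside linear genome of length {L}")
        # unroll the circle: normalise start into [1, L]
        s0 = (start - 1) % L
        n = end - start + 1
        doubled = self.sequence + self.sequence
        return doubled[s0 : s0 + n]

    def feature_by_locus_tag(self, locus_tag: str) -> CdsFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)

    def reverse_complement(self) -> "GenomeRecord":
        """Record on the opposite strand with remapped feature coordinates."""
        L = len(self.sequence)
        rc = str(Seq(self.sequence).reverse_complement())
        feats = []
        for f in self.features:
            feats.append(
                replace(
                    f,
                    start=L - f.end + 1,
                    end=L - f.start + 1,
                    strand="-" if f.strand == "+" else "+",
                )
            )
        feats.sort(key=lambda f: f.start)
        return replace(self, sequence=rc, features=tuple(feats))


@dataclass(frozen=True)
class TpaseCandidate:
    """A CDS whose annotation matched a transposase keyword."""

    feature: CdsFeature
    match_reason: str

    def __post_init__(self) -> None:
        if not self.match_reason:
            raise ValueError("match_reason must be non-empty")


@dataclass(frozen=True)
class FlankWindow:
    """Plus-strand window around a transposase candidate.

    ``window_span`` is the 1-based inclusive genome span; on circular
    genomes a window that wraps the origin keeps ``end`` > genome length
    (coordinates on the unrolled circle).  ``tpase_offset`` locates the
    candidate ORF within the window (1-based inclusive), and
    ``truncated`` flags windows clamped at a linear genome edge.
    """

    genome_id: str
    tpase: TpaseCandidate
    window_span: tuple[int, int]
    sequence: str
    tpase_offset: tuple[int, int]
    truncated: bool = False

    def __post_init__(self) -> None:
        s, e = self.tpase_offset
        if not (1 <= s <= e <= len(self.sequence)):
            raise ValueError("tpase_offset must lie inside the window")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# reading / writing


def _cds_from_seqfeature(feat: SeqFeature, index: int) -> CdsFeature:
    q = feat.qualifiers
    locus = q.get("locus_tag", [f"CDS_{index:05d}"])[0]
    product = q.get("product", [""])[0]
    translation = q.get("translation", [None])[0]
    start = int(feat.location.start) + 1  # Biopython is 0-based half-open
    end = int(feat.location.end)
    strand = "-" if feat.location.strand == -1 else "+"
    return CdsFeature(
        locus_tag=locus,
        start=start,
        end=end,
        strand=strand,
        product=product,
        translation=translation,
    )


def _record_from_seqrecord(rec: SeqRecord) -> GenomeRecord:
    topology = rec.annotations.get("topology", "linear")
    if topology not in ("linear", "circular"):
        topology = "linear"
    feats = [
        _cds_from_seqfeature(f, i)
        for i, f in enumerate(rec.features)
        if f.type == "CDS"
    ]
    feats.sort(key=lambda f: f.start)
    return GenomeRecord(
        id=rec.id,
        sequence=str(rec.seq),
        topology=topology,
        features=tuple(feats),
        description=rec.description or "",
    )


def read_genomes(path: str | Path, format: str = "genbank", gff: str | Path | None = None) -> list[GenomeRecord]:
    """Read every sequence record from ``path``.

    ``format`` is ``"genbank"`` or ``"fasta_gff"``.  For ``fasta_gff``
    the companion GFF3 file is ``gff`` (default: ``path`` with a
    ``.gff``/``.gff3`` sibling).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genbank":
        try:
            recs = list(SeqIO.parse(str(path), "genbank"))
        except Exception as exc:  # Biopython raises assorted ValueError subclasses
            raise GenomeFormatError(f"{path}: not parseable as GenBank: {exc}") from exc
        if not recs:
            raise GenomeFormatError(f"{path}: no GenBank records found")
        out = []
        for rec in recs:
            if len(rec.seq) == 0:
                raise GenomeFormatError(f"{path}: record {rec.id} has no sequence")
            out.append(_record_from_seqrecord(rec))
        return out
    if format == "fasta_gff":
        if gff is None:
            for ext in (".gff", ".gff3"):
                cand = path.with_suffix(ext)
                if cand.exists():
                    gff = cand
                    break
        if gff is None or not Path(gff).exists():
            raise MissingAnnotationError(
                f"{path}: format=fasta_gff requires a companion GFF3 file"
            )
        try:
            recs = list(SeqIO.parse(str(path), "fasta"))
        except Exception as exc:
            raise GenomeFormatError(f"{path}: not parseable as FASTA: {exc}") from exc
        if not recs:
            raise GenomeFormatError(f"{path}: no FASTA records found")
        by_id = {rec.id: rec for rec in recs}
        feats_by_seq: dict[str, list[CdsFeature]] = {rid: [] for rid in by_id}
        import gffutils

        db = gffutils.create_db(
            str(gff), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        for i, f in enumerate(db.features_of_type("CDS")):
            if f.seqid not in by_id:
                raise GenomeFormatError(
                    f"{gff}: CDS on unknown sequence {f.seqid!r}"
                )
            locus = (f.attributes.get("locus_tag") or f.attributes.get("ID") or [f"CDS_{i:05d}"])[0]
            product = (f.attributes.get("product") or [""])[0]
            strand = "-" if f.strand == "-" else "+"
            seq = by_id[f.seqid].seq[f.start - 1 : f.end]
            if strand == "-":
                seq = seq.reverse_complement()
            translation = str(seq.translate(table=11, to_stop=True)) if len(seq) >= 6 else None
            feats_by_seq[f.seqid].append(
                CdsFeature(locus, f.start, f.end, strand, product, translation)
            )
        return [
            GenomeRecord(
                id=rid,
                sequence=str(rec.seq),
                topology="linear",
                features=tuple(sorted(feats_by_seq[rid], key=lambda c: c.start)),
                description=rec.description,
            )
            for rid, rec in by_id.items()
        ]
    raise ValueError(f"unknown format {format!r} (expected genbank|fasta_gff)")


def read_genome(path: str | Path, format: str = "genbank", gff: str | Path | None = None) -> GenomeRecord:
    """Read a single-replicon genome (first record of the file)."""
    return read_genomes(path, format=format, gff=gff)[0]


def _to_seqrecord(genome: GenomeRecord) -> SeqRecord:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description=genome.description)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = genome.topology
    for f in genome.features:
        quals = {"locus_tag": [f.locus_tag]}
        if f.product:
            quals["product"] = [f.product]
        if f.translation:
            quals["translation"] = [f.translation]
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start - 1, f.end, strand=1 if f.strand == "+" else -1),
                type="CDS",
                qualifiers=quals,
            )
        )
    return rec


def write_genbank(genome: GenomeRecord, path: str | Path) -> None:
    """Write a GenomeRecord as a GenBank flat file (round-trip safe)."""
    SeqIO.write([_to_seqrecord(genome)], str(path), "genbank")


# ---------------------------------------------------------------------------
# transposase candidates and flank windows


def find_transposase_candidates(
    genome: GenomeRecord,
    keywords: Sequence[str] = DEFAULT_TPASE_KEYWORDS,
) -> list[TpaseCandidate]:
    """CDS features whose product matches any keyword (case-insensitive regex).

    Returned in genome order; an empty list is a valid result.
    """
    pats = [re.compile(k, re.IGNORECASE) for k in keywords]
    out = []
    for f in genome.features:
        for k, pat in zip(keywords, pats):
            if pat.search(f.product or ""):
                out.append(TpaseCandidate(feature=f, match_reason=k))
                break
    out.sort(key=lambda c: c.feature.start)
    return out


def extract_flank_window(
    genome: GenomeRecord,
    candidate: TpaseCandidate,
    flank_len: int = 1000,
) -> FlankWindow:
    """Plus-strand window covering the candidate ORF plus up to ``flank_len``
    nt on each side.

    Linear genomes clamp at the ends (the window is flagged truncated);
    circular genomes wrap across the origin, yielding a contiguous
    sequence on the unrolled circle.
    """
    feat = candidate.feature
    try:
        genome.feature_by_locus_tag(feat.locus_tag)
    except KeyError:
        raise KeyError(
            f"candidate {feat.locus_tag} not found in genome {genome.id}"
        ) from None
    L = len(genome)
    if genome.topology == "circular":
        start = feat.start - flank_len
        end = feat.end + flank_len
        if end - start + 1 >= L:  # window would cover the whole genome
            start, end = 1, L
        seq = genome.subseq(start, end)
        truncated = False
    else:
        start = max(1, feat.start - flank_len)
        end = min(L, feat.end + flank_len)
        seq = genome.subseq(start, end)
        truncated = start > feat.start - flank_len or end < feat.end + flank_len
    return FlankWindow(
        genome_id=genome.id,
        tpase=candidate,
        window_span=(start, end),
        sequence=seq,
        tpase_offset=(feat.start - start + 1, feat.end - start + 1),
        truncated=truncated,
    )


def iter_flank_windows(
    genome: GenomeRecord,
    candidates: Iterable[TpaseCandidate],
    flank_len: int = 1000,
) -> Iterable[FlankWindow]:
    for c in candidates:
        yield extract_flank_window(genome, c, flank_len=flank_len)
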