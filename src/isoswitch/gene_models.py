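"""Gene/transcript/exon models, exon classification and k-mer feature indices.

Alternative-promoter isoforms (the motivating case is the thyroid hormone
receptor beta gene, whose TRβ1- and TRβ2-like transcripts differ only in their
5' exons) cannot be separated by whole-gene read counting.  This module
provides the substrate for isoform-resolved counting: parse a gene annotation,
decide which exons are specific to one isoform and which are shared, pull out
the corresponding sequences, and build a k-mer index mapping sequence words to
feature classes.

Coordinates are 0-based half-open internally; GTF (1-based inclusive) is
converted at the parsing/writing boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# 2-bit base codes for the vectorized k-mer path; anything else (N) maps to 4.
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lower case


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent gene annotations."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Exon:
    interval: GenomicInterval
    exon_id: str
    coding: bool = True


@dataclass
class Transcript:
    transcript_id: str
    isoform_label: str
    exons: list[Exon]

    def __post_init__(self) -> None:
        ids = [e.exon_id for e in self.exons]
        if len(set(ids)) != len(ids):
            raise AnnotationError(
                f"duplicate exon ids in transcript {self.transcript_id}"
            )
        ivs = sorted((e.interval.start, e.interval.end) for e in self.exons)
        for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"overlapping exons within transcript {self.transcript_id}"
                )

    @property
    def length(self) -> int:
        return sum(len(e.interval) for e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")

    @property
    def span(self) -> GenomicInterval:
        exons = [e.interval for t in self.transcripts for e in t.exons]
        return GenomicInterval(
            exons[0].chrom,
            min(e.start for e in exons),
            max(e.end for e in exons),
            exons[0].strand,
        )

    @property
    def isoform_labels(self) -> list[str]:
        seen: list[str] = []
        for t in self.transcripts:
            if t.isoform_label not in seen:
                seen.append(t.isoform_label)
        return seen


@dataclass
class ExonClassification:
    """Per-interval labels: an isoform label, or ``'common'``."""

    labels: dict[tuple[str, int, int], str]
    specific_counts: dict[str, int]

    COMMON = "common"


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id}")
        if re.search("[^ACGTNacgtn]", self.sequence):
            raise ValueError(f"record {self.id} contains non-ACGTN characters")

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_gene_annotation(annotation_text: str) -> list[GeneModel]:
    """Parse GTF text into :class:`GeneModel` objects.

    Only ``exon`` features are used.  Required attributes are ``gene_id`` and
    ``transcript_id``; an optional ``isoform`` attribute labels the isoform
    (defaulting to the transcript id).  An optional ``coding`` attribute
    ("true"/"false") marks non-coding exons.  GTF 1-based inclusive
    coordinates become 0-based half-open.
    """
    genes: dict[str, dict[str, dict]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(annotation_text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationError(
                f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        if feature != "exon":
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise AnnotationError(f"line {lineno}: non-integer coordinates") from None
        if strand not in ("+", "-"):
            raise AnnotationError(f"line {lineno}: bad strand {strand!r}")
        attr = dict(_ATTR_RE.findall(attrs))
        if "gene_id" not in attr:
            raise AnnotationError(f"line {lineno}: missing gene_id attribute")
        if "transcript_id" not in attr:
            raise AnnotationError(f"line {lineno}: missing transcript_id attribute")
        gid, tid = attr["gene_id"], attr["transcript_id"]
        if gid not in genes:
            genes[gid] = {}
            order.append(gid)
        tdict = genes[gid].setdefault(
            tid, {"isoform": attr.get("isoform", tid), "exons": []}
        )
        try:
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: {exc}") from None
        tdict["exons"].append(
            Exon(
                iv,
                attr.get("exon_id", f"{tid}.e{len(tdict['exons']) + 1}"),
                coding=attr.get("coding", "true").lower() != "false",
            )
        )

    models = []
    for gid in order:
        transcripts = []
        for tid, tdict in genes[gid].items():
            exons = tdict["exons"]
            if not exons:
                raise AnnotationError(f"transcript {tid} has no exons")
            # 5'->3': ascending genomic order on +, descending on -
            rev = exons[0].interval.strand == "-"
            exons = sorted(exons, key=lambda e: e.interval.start, reverse=rev)
            transcripts.append(Transcript(tid, tdict["isoform"], exons))
        models.append(GeneModel(gid, transcripts))
    return models


def classify_exons(gene: GeneModel) -> ExonClassification:
    """Label each distinct exon interval isoform-specific or common.

    An interval is specific to isoform *i* iff it intersects exons belonging
    to transcripts of exactly one isoform label; it is common iff it
    intersects exons of two or more isoform labels.  Intersection, not exact
    identity, is used so that near-identical exon variants share a label.
    """
    intervals: dict[tuple[str, int, int], GenomicInterval] = {}
    touching: dict[tuple[str, int, int], set[str]] = {}
    all_exons = [
        (t.isoform_label, e.interval) for t in gene.transcripts for e in t.exons
    ]
    for _label, iv in all_exons:
        key = (iv.chrom, iv.start, iv.end)
        intervals.setdefault(key, iv)
        touching.setdefault(key, set())
    for key, iv in intervals.items():
        for label, other in all_exons:
            if iv.overlaps(other):
                touching[key].add(label)

    labels: dict[tuple[str, int, int], str] = {}
    counts = {label: 0 for label in gene.isoform_labels}
    for key, isoforms in touching.items():
        if len(isoforms) == 1:
            (label,) = isoforms
            labels[key] = label
            counts[label] += 1
        else:
            labels[key] = ExonClassification.COMMON
    return ExonClassification(labels, counts)


def extract_feature_sequences(
    genome: Mapping[str, str] | Iterable[SequenceRecord],
    features: Sequence[tuple[str, Sequence[GenomicInterval]]],
) -> list[SequenceRecord]:
    """Extract feature sequences, one record per feature.

    Multi-interval features are concatenated in the given (transcript) order;
    minus-strand features are reverse-complemented so records are in sense
    orientation.
    """
    if not isinstance(genome, Mapping):
        genome = {rec.id: rec.sequence for rec in genome}
    out = []
    for feature_id, intervals in features:
        parts = []
        for iv in intervals:
            if iv.chrom not in genome:
                raise KeyError(f"feature {feature_id}: unknown chromosome {iv.chrom}")
            chrom_seq = genome[iv.chrom]
            if iv.end > len(chrom_seq):
                raise IndexError(
                    f"feature {feature_id}: interval {iv.chrom}:{iv.start}-{iv.end} "
                    f"exceeds sequence length {len(chrom_seq)}"
                )
            piece = chrom_seq[iv.start : iv.end]
            parts.append(reverse_complement(piece) if iv.strand == "-" else piece)
        out.append(SequenceRecord(feature_id, "".join(parts)))
    return out


class FeatureIndex:
    """k-mer map from sequence words to feature classes.

    Built from class-grouped sequence records.  Words containing N are
    skipped.  ``common_classes`` names classes whose reads are
    isoform-uninformative (shared downstream exons); read assignment uses
    this to prefer isoform-specific evidence on junction reads.
    """

    def __init__(
        self,
        k: int,
        classes: Sequence[str],
        kmer_map: dict[str, frozenset[str]],
        feature_lengths: dict[str, int],
        common_classes: frozenset[str] = frozenset(),
    ) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.classes = list(classes)
        self.kmer_map = kmer_map
        self.feature_lengths = dict(feature_lengths)
        self.common_classes = frozenset(common_classes)
        unknown = self.common_classes - set(self.classes)
        if unknown:
            raise ValueError(f"common_classes not declared: {sorted(unknown)}")
        self._codes: np.ndarray | None = None
        self._masks: np.ndarray | None = None

    def __contains__(self, word: str) -> bool:
        return word in self.kmer_map

    def lookup(self, word: str) -> frozenset[str]:
        return self.kmer_map.get(word, frozenset())

    # --- packed representation for the vectorized assignment path ---

    def _ensure_packed(self) -> tuple[np.ndarray, np.ndarray]:
        if self._codes is None:
            if self.k > 31:
                raise ValueError("vectorized path supports k <= 31")
            bit = {c: 1 << i for i, c in enumerate(self.classes)}
            codes = np.empty(len(self.kmer_map), dtype=np.int64)
            masks = np.empty(len(self.kmer_map), dtype=np.int64)
            for i, (word, cls) in enumerate(self.kmer_map.items()):
                codes[i] = encode_kmer(word)
                masks[i] = sum(bit[c] for c in cls)
            order = np.argsort(codes)
            self._codes = codes[order]
            self._masks = masks[order]
        return self._codes, self._masks


def encode_kmer(word: str) -> int:
    """2-bit encode an ACGT word (A=0 C=1 G=2 T=3, big-endian)."""
    code = 0
    for ch in word:
        b = _BASE_CODE[ord(ch)]
        if b > 3:
            raise ValueError(f"cannot encode word containing {ch!r}")
        code = (code << 2) | int(b)
    return code


def build_feature_index(
    class_records: Mapping[str, Sequence[SequenceRecord]],
    k: int,
    common_classes: Iterable[str] = (),
) -> FeatureIndex:
    """Index every length-k word of every record under its class.

    A word shared between classes maps to the set of all of them.  A class's
    feature length is the total bases of its records.  Raises if no record in
    any class is long enough to contribute a word.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    kmer_map: dict[str, set[str]] = {}
    lengths: dict[str, int] = {}
    n_words = 0
    for class_id, records in class_records.items():
        lengths[class_id] = sum(len(r) for r in records)
        for rec in records:
            seq = rec.sequence.upper()
            for i in range(len(seq) - k + 1):
                word = seq[i : i + k]
                if "N" in word:
                    continue
                kmer_map.setdefault(word, set()).add(class_id)
                n_words += 1
    if n_words == 0:
        raise ValueError(f"k={k} exceeds every record length; index would be empty")
    return FeatureIndex(
        k,
        list(class_records),
        {w: frozenset(c) for w, c in kmer_map.items()},
        lengths,
        frozenset(common_classes),
    )


_STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE: dict[str, str] | None = None


def _codon_table() -> dict[str, str]:
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE = dict(standard_dna_table.forward_table)
    return _CODON_TABLE


def translate_longest_orf(cdna: SequenceRecord) -> str | None:
    """Translate the longest ATG-initiated, stop-terminated forward-strand ORF.

    Returns the protein (stop excluded), or ``None`` if no complete ORF
    exists.  Ties go to the leftmost start.  Used to check that a cDNA
    encodes the expected receptor protein length.
    """
    seq = cdna.sequence.upper()
    table = _codon_table()
    best: tuple[int, int] | None = None  # (length_nt, start)
    start = seq.find("ATG")
    while start != -1:
        for pos in range(start, len(seq) - 2, 3):
            if seq[pos : pos + 3] in _STOP_CODONS:
                length = pos - start
                if best is None or length > best[0]:
                    best = (length, start)
                break
        start = seq.find("ATG", start + 1)
    if best is None:
        return None
    length, start = best
    protein = []
    for pos in range(start, start + length, 3):
        protein.append(table.get(seq[pos : pos + 3], "X"))
    return "".join(protein)
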