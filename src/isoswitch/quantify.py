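"""Read-to-feature assignment by k-mer class membership, and CPM/TPM.

A read is assigned to a feature class (e.g. an isoform-specific exon set, the
shared-exon set, or a whole-gene exon union) when its k-mers give unambiguous
evidence for that class.  This replaces aligner-based counting with an
explicit, testable rule:

* a k-mer "hits" if it is present in the index; a hit is *unique* to class c
  if its class set is exactly {c};
* if all hits lie in a single class and at least ``min_hits`` of them are
  unique to it, the read is assigned to that class;
* if hits span several classes, the read is assigned to the single class with
  >= ``min_hits`` unique hits if there is exactly one such class — or, when
  several qualify, to the single qualifying isoform-specific (non-common)
  class, so a junction read spanning a specific/common boundary counts as
  isoform evidence; otherwise it is ambiguous;
* no hits (or fewer than ``min_hits`` in a single class): unassigned.

CPM uses the total read count of the sample (library size) as denominator.
TPM divides counts by effective length (length - read_length + 1, floored at
1) and rescales rates to sum to 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_models import (
    _BASE_CODE,
    FeatureIndex,
    GeneModel,
    SequenceRecord,
    build_feature_index,
    extract_feature_sequences,
)

ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"

DEFAULT_MIN_HITS = 2


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    outcome: str  # assigned | ambiguous | unassigned
    feature_class: str | None
    hit_kmers: int


def _decide(
    unique_counts: Mapping[str, int],
    classes_hit: frozenset[str] | set[str],
    common_classes: frozenset[str],
    min_hits: int,
) -> tuple[str, str | None]:
    """Shared decision rule for the scalar and vectorized paths."""
    if not classes_hit:
        return UNASSIGNED, None
    qualifying = [c for c in classes_hit if unique_counts.get(c, 0) >= min_hits]
    if len(classes_hit) == 1:
        (c,) = classes_hit
        return (ASSIGNED, c) if qualifying else (UNASSIGNED, None)
    if len(qualifying) == 1:
        return ASSIGNED, qualifying[0]
    specific = [c for c in qualifying if c not in common_classes]
    if len(qualifying) > 1 and len(specific) == 1:
        return ASSIGNED, specific[0]
    return AMBIGUOUS, None


def assign_read(
    read: SequenceRecord | str,
    index: FeatureIndex,
    min_hits: int = DEFAULT_MIN_HITS,
) -> ReadAssignment:
    """Assign one read.  Reads shorter than k are unassigned."""
    if isinstance(read, SequenceRecord):
        read_id, seq = read.id, read.sequence
    else:
        read_id, seq = "", read
    seq = seq.upper()
    k = index.k
    if len(seq) < k:
        return ReadAssignment(read_id, UNASSIGNED, None, 0)
    unique: dict[str, int] = {}
    classes_hit: set[str] = set()
    n_hits = 0
    for i in range(len(seq) - k + 1):
        cls = index.lookup(seq[i : i + k])
        if not cls:
            continue
        n_hits += 1
        classes_hit |= cls
        if len(cls) == 1:
            (c,) = cls
            unique[c] = unique.get(c, 0) + 1
    outcome, chosen = _decide(unique, classes_hit, index.common_classes, min_hits)
    return ReadAssignment(read_id, outcome, chosen, n_hits)


def assign_batch(
    reads: np.ndarray,
    index: FeatureIndex,
    min_hits: int = DEFAULT_MIN_HITS,
) -> np.ndarray:
    """Vectorized assignment of a (n_reads, read_length) uint8 ASCII array.

    Returns an int array: class position in ``index.classes`` if assigned,
    -1 ambiguous, -2 unassigned.  Equivalent to :func:`assign_read` per row.
    """
    codes_sorted, masks_sorted = index._ensure_packed()
    n, read_len = reads.shape
    k = index.k
    out = np.full(n, -2, dtype=np.int64)
    if n == 0 or read_len < k:
        return out
    base = _BASE_CODE[reads]  # (n, L), 4 = non-ACGT
    nw = read_len - k + 1
    # rolling 2-bit encoding of each window
    kcodes = np.zeros((n, nw), dtype=np.int64)
    for j in range(k):
        kcodes <<= 2
        kcodes |= base[:, j : j + nw]
    # windows containing non-ACGT bases are invalid
    bad = (base > 3).astype(np.int32)
    cs = np.concatenate([np.zeros((n, 1), np.int32), np.cumsum(bad, axis=1)], axis=1)
    valid = (cs[:, k:] - cs[:, :-k]) == 0

    pos = np.searchsorted(codes_sorted, kcodes)
    pos_c = np.minimum(pos, len(codes_sorted) - 1)
    hit = valid & (pos < len(codes_sorted)) & (codes_sorted[pos_c] == kcodes)
    masks = np.where(hit, masks_sorted[pos_c], 0)

    orred = np.bitwise_or.reduce(masks, axis=1)
    n_classes = len(index.classes)
    uniq = np.empty((n, n_classes), dtype=np.int64)
    for c in range(n_classes):
        uniq[:, c] = (masks == (1 << c)).sum(axis=1)
    qual = uniq >= min_hits
    class_bits = (orred[:, None] >> np.arange(n_classes)[None, :]) & 1
    qual &= class_bits.astype(bool)
    nq = qual.sum(axis=1)
    common_mask = np.array(
        [c in index.common_classes for c in index.classes], dtype=bool
    )
    nq_specific = (qual & ~common_mask[None, :]).sum(axis=1)

    popcount = np.bitwise_count(orred.astype(np.uint64)).astype(np.int64)
    single = popcount == 1
    multi = popcount >= 2

    # single class: assigned iff it qualifies, else unassigned
    out[single & (nq == 1)] = np.argmax(qual[single & (nq == 1)], axis=1)
    # multi class: unique qualifier wins; else lone specific qualifier wins
    lone = multi & (nq == 1)
    out[lone] = np.argmax(qual[lone], axis=1)
    pref = multi & (nq >= 2) & (nq_specific == 1)
    out[pref] = np.argmax(qual[pref] & ~common_mask[None, :], axis=1)
    ambiguous = multi & ~lone & ~pref
    out[ambiguous] = -1
    return out


@dataclass
class CountTable:
    """Per-sample feature-class counts plus library sizes.

    ``counts`` is samples x classes (plus ``ambiguous``/``unassigned``
    columns); ``library_size`` indexes by sample.
    """

    counts: pd.DataFrame
    library_size: pd.Series

    def cpm_matrix(self, feature_classes: Sequence[str] | None = None) -> pd.DataFrame:
        """Features x samples CPM matrix for the given classes."""
        cols = list(feature_classes) if feature_classes is not None else [
            c for c in self.counts.columns if c not in (AMBIGUOUS, UNASSIGNED)
        ]
        lib = self.library_size.reindex(self.counts.index)
        if (lib <= 0).any():
            raise ValueError("library size must be positive for CPM")
        return (self.counts[cols].div(lib, axis=0) * 1e6).T


def reads_to_batch(reads: Iterable[tuple[str, str]], read_length: int) -> np.ndarray:
    """Pack (id, sequence) reads of uniform length into a uint8 array."""
    seqs = [seq for _rid, seq in reads]
    if not seqs:
        return np.empty((0, read_length), dtype=np.uint8)
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(seqs), read_length).copy()


def quantify_sample(
    reads: np.ndarray | Iterable[tuple[str, str]],
    index: FeatureIndex,
    min_hits: int = DEFAULT_MIN_HITS,
) -> dict[str, int]:
    """Count assigned reads per class; tally ambiguous/unassigned separately.

    ``reads`` is either a packed uint8 batch or an iterable of (id, seq).
    Returns class counts plus ``ambiguous``, ``unassigned`` and
    ``library_size`` entries.  An empty input yields a zero row.
    """
    if not isinstance(reads, np.ndarray):
        reads = list(reads)
        if reads and len({len(s) for _r, s in reads}) == 1:
            reads = reads_to_batch(reads, len(reads[0][1]))
    row = {c: 0 for c in index.classes}
    row[AMBIGUOUS] = 0
    row[UNASSIGNED] = 0
    if isinstance(reads, np.ndarray):
        codes = assign_batch(reads, index, min_hits)
        row["library_size"] = int(reads.shape[0])
        for c_pos, cls in enumerate(index.classes):
            row[cls] = int((codes == c_pos).sum())
        row[AMBIGUOUS] = int((codes == -1).sum())
        row[UNASSIGNED] = int((codes == -2).sum())
    else:  # ragged read lengths: scalar path
        total = 0
        for rid, seq in reads:
            total += 1
            a = assign_read(SequenceRecord(rid or "r", seq), index, min_hits)
            if a.outcome == ASSIGNED:
                row[a.feature_class] += 1
            else:
                row[a.outcome] += 1
        row["library_size"] = total
    return row


def cpm(count: float, library_size: int) -> float:
    """Counts per million: count / library_size * 1e6."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / library_size * 1e6


def effective_length(length: int, read_length: int) -> int:
    return max(length - read_length + 1, 1)


def tpm(
    counts: Mapping[str, float], effective_lengths: Mapping[str, float]
) -> dict[str, float]:
    """Transcripts per million over the quantified feature set.

    rate_f = count_f / effective_length_f; TPM_f = rate_f / sum(rates) * 1e6.
    All-zero counts return all-zero TPM.
    """
    rates = {}
    for f, c in counts.items():
        el = effective_lengths[f]
        if el <= 0:
            raise ValueError(f"effective length of {f} must be positive")
        rates[f] = c / el
    total = sum(rates.values())
    if total == 0:
        return {f: 0.0 for f in counts}
    return {f: r / total * 1e6 for f, r in rates.items()}


def build_isoform_indices(
    gene: GeneModel,
    genome: Mapping[str, str],
    k: int,
    concatenate: bool = False,
) -> FeatureIndex:
    """Build the isoform-resolved index for a two-or-more-isoform gene.

    One class per isoform (its specific exons, by default as separate
    co-classed records; ``concatenate`` joins them into one record) plus a
    separate ``common`` class for the shared exons.
    """
    from .gene_models import ExonClassification, classify_exons

    cls = classify_exons(gene)
    by_class: dict[str, list[tuple[str, list]]] = {}
    seen: set[tuple[str, int, int]] = set()
    for t in gene.transcripts:
        for e in t.exons:
            key = (e.interval.chrom, e.interval.start, e.interval.end)
            if key in seen:
                continue
            seen.add(key)
            label = cls.labels[key]
            by_class.setdefault(label, []).append((e.exon_id, [e.interval]))
    class_records: dict[str, list[SequenceRecord]] = {}
    for label, feats in by_class.items():
        if concatenate:
            merged = (f"{label}", [iv for _eid, ivs in feats for iv in ivs])
            recs = extract_feature_sequences(genome, [merged])
        else:
            recs = extract_feature_sequences(genome, feats)
        class_records[label] = recs
    common = (
        [ExonClassification.COMMON]
        if ExonClassification.COMMON in class_records
        else []
    )
    return build_feature_index(class_records, k, common_classes=common)


def build_whole_gene_index(
    gene: GeneModel, genome: Mapping[str, str], k: int
) -> FeatureIndex:
    """Single-class index over the union of all exons of all isoforms.

    This is the standard whole-gene reference that cannot separate promoter
    isoforms; it exists to demonstrate how it masks an isoform switch.
    """
    seen: set[tuple[str, int, int]] = set()
    feats = []
    for t in gene.transcripts:
        for e in t.exons:
            key = (e.interval.chrom, e.interval.start, e.interval.end)
            if key not in seen:
                seen.add(key)
                feats.append((e.exon_id, [e.interval]))
    records = extract_feature_sequences(genome, feats)
    return build_feature_index({gene.gene_id: records}, k)
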