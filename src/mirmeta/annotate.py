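"""Removal of reads matching non-miRNA annotation classes.

Before miRNA discovery, reads matching mRNA fragments, structural ncRNAs
(rRNA, tRNA, snRNA, snoRNA) or repeat elements are removed. External
alignment (BLAST against Rfam/Repbase/mRNA sets in the original analysis)
is replaced by deterministic full-length ungapped substring matching:
reads of 15-26 nt gain nothing from local alignment at that length, and
the mismatch tolerance is an explicit parameter (default 0).

A read hitting several classes is assigned by fixed precedence
rRNA > tRNA > snoRNA > snRNA > repeat > mRNA (structural ncRNAs are
higher-confidence annotations than mRNA fragments).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .preprocess import UniqueRead, canonicalize
from .simulate import revcomp

ANNOTATION_CLASSES = ("rRNA", "tRNA", "snoRNA", "snRNA", "repeat", "mRNA")
_PRECEDENCE = {cls: rank for rank, cls in enumerate(ANNOTATION_CLASSES)}


@dataclass(frozen=True)
class ReferenceRecord:
    id: str
    annotation_class: str
    sequence: str

    def __post_init__(self) -> None:
        if self.annotation_class not in ANNOTATION_CLASSES:
            raise ValueError(f"unknown annotation class {self.annotation_class!r}")
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")


@dataclass(frozen=True)
class AnnotationCall:
    sequence: str
    reference_id: str
    annotation_class: str
    offset: int          # 0-based offset of the read in the reference
    mismatches: int
    strand: str = "+"


def _mismatch_at(read: str, ref: str, off: int, budget: int) -> int | None:
    mm = 0
    for a, b in zip(read, ref[off: off + len(read)]):
        if a != b:
            mm += 1
            if mm > budget:
                return None
    return mm


class ReferenceIndex:
    """Ungapped substring index over an annotation reference catalog.

    Supports exact and <=k-mismatch full-length queries. The reverse
    strand is searched for classes in ``both_strand_classes`` (repeats by
    default, since repeat consensus orientation is arbitrary).
    """

    def __init__(self, references: Sequence[ReferenceRecord], *,
                 both_strand_classes: tuple[str, ...] = ("repeat",)) -> None:
        if not references:
            raise ValueError("reference catalog is empty")
        ids = [r.id for r in references]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reference ids")
        self.references = [
            ReferenceRecord(r.id, r.annotation_class, canonicalize(r.sequence))
            for r in references
        ]
        self.both_strand_classes = both_strand_classes

    def query(self, sequence: str, max_mismatch: int = 0) -> list[AnnotationCall]:
        """All (best-per-reference) hits of a read, sorted by class precedence."""
        read = canonicalize(sequence)
        hits = []
        for ref in self.references:
            strands = [("+", ref.sequence)]
            if ref.annotation_class in self.both_strand_classes:
                strands.append(("-", revcomp(ref.sequence)))
            best = None
            for strand, ref_seq in strands:
                if len(read) > len(ref_seq):
                    continue
                if max_mismatch == 0:
                    off = ref_seq.find(read)
                    if off >= 0:
                        cand = (0, off, strand)
                    else:
                        continue
                else:
                    cand = None
                    for off in range(len(ref_seq) - len(read) + 1):
                        mm = _mismatch_at(read, ref_seq, off, max_mismatch)
                        if mm is not None and (cand is None or mm < cand[0]):
                            cand = (mm, off, strand)
                            if mm == 0:
                                break
                if cand and (best is None or cand < best):
                    best = cand
            if best is not None:
                hits.append(AnnotationCall(
                    sequence=read, reference_id=ref.id,
                    annotation_class=ref.annotation_class,
                    offset=best[1], mismatches=best[0], strand=best[2]))
        hits.sort(key=lambda h: (_PRECEDENCE[h.annotation_class],
                                 h.mismatches, h.reference_id))
        return hits


def build_reference_index(references: Sequence[ReferenceRecord],
                          **kwargs) -> ReferenceIndex:
    return ReferenceIndex(references, **kwargs)


def annotate_and_remove(
    reads: Iterable[UniqueRead], index: ReferenceIndex, *,
    max_mismatch: int = 0,
) -> tuple[list[AnnotationCall], list[UniqueRead]]:
    """Split reads into (removed annotation calls, retained reads).

    Removed + retained partition the input exactly; each removed read
    carries the single call chosen by class precedence.
    """
    removed: list[AnnotationCall] = []
    kept: list[UniqueRead] = []
    for r in reads:
        hits = index.query(r.sequence, max_mismatch=max_mismatch)
        if hits:
            removed.append(hits[0])
        else:
            kept.append(r)
    return removed, kept


def parse_reference_fasta(text: str) -> list[ReferenceRecord]:
    """Parse a reference FASTA whose descriptions carry ``class=<name>``."""
    import io as _io

    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        cls = None
        for token in rec.description.split():
            if token.startswith("class="):
                cls = token.split("=", 1)[1]
        if cls is None:
            raise ValueError(f"reference {rec.id} lacks a class= tag")
        records.append(ReferenceRecord(rec.id, cls, str(rec.seq)))
    return records
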