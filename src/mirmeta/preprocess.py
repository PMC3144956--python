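"""Read collapsing, the small-RNA filter cascade, and length distributions.

Raw libraries are collapsed to unique sequences with copy counts (T/U
canonicalized to RNA), then passed through the retention cascade used for
the flounder library: keep reads of 15-26 nt observed at >= 3 copies that
are not low-complexity. Discard reasons are assigned in a fixed order
(length, then copies, then complexity) so each discarded read carries a
deterministic first failing reason.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

RETAINED = "retained"
REASONS = ("length", "low-copy", "low-complexity")


@dataclass(frozen=True)
class UniqueRead:
    """A collapsed read: one distinct (canonical RNA) sequence + copy count."""

    sequence: str
    count: int
    status: str = RETAINED       # "retained" or "discarded"
    reason: str | None = None    # first failing filter, when discarded

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if self.count < 1:
            raise ValueError("count must be >= 1")


def canonicalize(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


def collapse_reads(source) -> list[UniqueRead]:
    """Collapse a FASTQ/FASTA file (path, handle or text) to unique reads.

    Counts sum to the number of input reads; first-seen order is kept.
    An empty file yields an empty list with a warning.
    """
    handle, fmt = _open_reads(source)
    counts: dict[str, int] = {}
    try:
        for rec in SeqIO.parse(handle, fmt):
            seq = canonicalize(str(rec.seq))
            counts[seq] = counts.get(seq, 0) + 1
    except ValueError as exc:
        raise ValueError(f"malformed {fmt} record: {exc}") from exc
    finally:
        if hasattr(handle, "close") and not isinstance(source, io.IOBase):
            handle.close()
    if not counts:
        log.warning("no reads found in input")
    return [UniqueRead(sequence=s, count=c) for s, c in counts.items()]


def _open_reads(source):
    """Return (handle, format) for a path or raw FASTQ/FASTA text."""
    looks_like_path = (isinstance(source, (str, Path))
                       and "\n" not in str(source)
                       and str(source).strip() != ""
                       and not str(source).lstrip().startswith((">", "@")))
    if looks_like_path:
        path = Path(source)
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
        return open(path), fmt
    text = source if isinstance(source, str) else source.read()
    stripped = text.lstrip()
    fmt = "fastq" if stripped.startswith("@") else "fasta"
    return io.StringIO(text), fmt


def is_low_complexity(seq: str, *, max_distinct: int = 2,
                      max_single_base_frac: float = 0.80) -> bool:
    """Simple-sequence mask: <= 2 distinct bases, or one base > 80%."""
    if len(set(seq)) <= max_distinct:
        return True
    top = max(seq.count(b) for b in set(seq))
    return top / len(seq) > max_single_base_frac


def apply_filters(reads: Iterable[UniqueRead], *, min_len: int = 15,
                  max_len: int = 26, min_copies: int = 3) -> list[UniqueRead]:
    """Partition unique reads into retained and discarded-with-reason.

    Evaluation order is fixed: length window, then copy count, then the
    low-complexity mask; a read failing several filters reports only the
    first. Already-retained reads pass through unchanged (idempotence).
    """
    if min_len <= 0 or min_copies <= 0 or min_len > max_len:
        raise ValueError("thresholds must be positive with min_len <= max_len")
    out = []
    for r in reads:
        if not (min_len <= len(r.sequence) <= max_len):
            out.append(replace(r, status="discarded", reason="length"))
        elif r.count < min_copies:
            out.append(replace(r, status="discarded", reason="low-copy"))
        elif is_low_complexity(r.sequence):
            out.append(replace(r, status="discarded", reason="low-complexity"))
        else:
            out.append(replace(r, status=RETAINED, reason=None))
    return out


def retained(reads: Iterable[UniqueRead]) -> list[UniqueRead]:
    return [r for r in reads if r.status == RETAINED]


@dataclass(frozen=True)
class LengthDistribution:
    """Redundant (all reads) and unique counts per length bin.

    Bins cover ``window``; reads outside it land in the ``under``/``over``
    overflow bins.
    """

    window: tuple[int, int]
    redundant: dict[int, int]
    unique: dict[int, int]
    under: tuple[int, int]      # (redundant, unique) below the window
    over: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.window
        rows = [{"length": n, "redundant": self.redundant[n],
                 "unique": self.unique[n]} for n in range(lo, hi + 1)]
        rows.append({"length": f"<{lo}", "redundant": self.under[0],
                     "unique": self.under[1]})
        rows.append({"length": f">{hi}", "redundant": self.over[0],
                     "unique": self.over[1]})
        return pd.DataFrame(rows)


def length_distribution(reads: Iterable[UniqueRead],
                        window: tuple[int, int] = (14, 28)) -> LengthDistribution:
    """Per-length totals of all reads (redundant) and unique sequences."""
    lo, hi = window
    red = {n: 0 for n in range(lo, hi + 1)}
    uni = {n: 0 for n in range(lo, hi + 1)}
    under = [0, 0]
    over = [0, 0]
    for r in reads:
        n = len(r.sequence)
        if n < lo:
            under[0] += r.count
            under[1] += 1
        elif n > hi:
            over[0] += r.count
            over[1] += 1
        else:
            red[n] += r.count
            uni[n] += 1
    return LengthDistribution(window=window, redundant=red, unique=uni,
                              under=tuple(under), over=tuple(over))


def to_frame(reads: Iterable[UniqueRead]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sequence": r.sequence, "count": r.count, "status": r.status,
          "reason": r.reason or ""} for r in reads])
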