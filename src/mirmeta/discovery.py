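"""Conserved miRNA and miRNA* identification.

Reads surviving the filter cascade and annotation removal are compared to
a catalog of known metazoan mature miRNAs: a read is called conserved if
its best ungapped alignment to some catalog mature has at most one
substitution and an exactly matching seed (mature positions 2-8, the
region that drives target recognition). Read ends may differ from the
catalog mature by up to 2 nt (isomiR ends are ubiquitous); overhanging
bases are not counted as mismatches but lower a reported overlap score.

Conserved calls are aggregated into per-miRNA expression counts, grouped
into miRBase-style families, and paired with passenger-strand (miRNA*)
reads found on the opposite arm of a folded precursor hairpin. Star
sequences are themselves classified against a known-star catalog,
conserved when within three mismatches.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

from .fold import HairpinStructure, fold
from .preprocess import UniqueRead, canonicalize

log = logging.getLogger(__name__)

SEED_SPAN = (2, 8)               # 1-based inclusive positions of the seed
DEFAULT_SPECIES_PRIORITY = ("dre", "fru", "tni", "ola", "omy", "pol")

_NAME_RE = re.compile(
    r"^(?:(?P<species>[a-z]{3,4})-)?"
    r"(?P<prefix>let|miR|mir|lin)-"
    r"(?P<number>\d+)"
    r"(?P<paralog>[a-z]*)"
    r"(?:-(?P<copy>\d+))?"
    r"(?:-(?P<arm>[35]p|star))?$"
)


@dataclass(frozen=True)
class MatureMiRNA:
    """A known mature miRNA with its seed and parsed family."""

    name: str
    sequence: str
    species: str | None = None
    family: str | None = None

    @property
    def seed(self) -> str:
        lo, hi = SEED_SPAN
        return self.sequence[lo - 1: hi]

    @staticmethod
    def from_name(name: str, sequence: str) -> "MatureMiRNA":
        species, family = parse_mirna_name(name)
        return MatureMiRNA(name=name, sequence=canonicalize(sequence),
                           species=species, family=family)


def parse_mirna_name(name: str) -> tuple[str | None, str | None]:
    """Split a miRBase-style name into (species, family).

    The family strips the species prefix, arm suffix (-5p/-3p/-star),
    trailing paralog letters and locus copy numbers: let-7a..let-7j all
    map to let-7; pol-mir-199-1 and -199-2 to mir-199. miR/mir are
    normalized to "mir". Unparseable names yield (None, None).
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        return None, None
    prefix = m.group("prefix")
    prefix = "mir" if prefix in ("miR", "mir") else prefix
    return m.group("species"), f"{prefix}-{m.group('number')}"


@dataclass(frozen=True)
class ConservedHit:
    """A read assigned to a known mature miRNA (<=1 mismatch, exact seed)."""

    sequence: str
    count: int
    mature_name: str
    offset: int          # read start relative to mature start (0-based, may be <0)
    mismatches: int
    overlap_score: float
    seed_exact: bool = True


def _align_to_mature(read: str, mature: str, *, max_mismatch: int,
                     max_length_diff: int, require_seed: bool):
    """Best ungapped alignment of ``read`` against ``mature``.

    Returns (mismatches, overlap_score, offset) or None. Offsets shift the
    read by up to ``max_length_diff`` nt past either mature end; only the
    overlapping region is scored. With ``require_seed``, mature positions
    2-8 must be inside the overlap and match exactly.
    """
    if abs(len(read) - len(mature)) > max_length_diff:
        return None
    lo, hi = SEED_SPAN
    best = None
    for off in range(-max_length_diff,
                     len(mature) - len(read) + max_length_diff + 1):
        o_start = max(0, off)                       # overlap, mature coords
        o_end = min(len(mature), off + len(read))
        if o_end <= o_start:
            continue
        if require_seed and not (o_start <= lo - 1 and hi <= o_end):
            continue
        mm = 0
        ok = True
        for m_pos in range(o_start, o_end):
            if mature[m_pos] != read[m_pos - off]:
                if require_seed and lo - 1 <= m_pos <= hi - 1:
                    ok = False
                    break
                mm += 1
                if mm > max_mismatch:
                    ok = False
                    break
        if not ok:
            continue
        overlap = (o_end - o_start) / len(read)
        cand = (mm, -overlap, off)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    return best[0], -best[1], best[2]


def match_conserved(
    reads: Iterable[UniqueRead],
    catalog: Sequence[MatureMiRNA],
    *,
    max_mismatch: int = 1,
    max_length_diff: int = 2,
    min_len: int = 16,
    max_len: int = 26,
    species_priority: Sequence[str] = DEFAULT_SPECIES_PRIORITY,
) -> list[ConservedHit]:
    """Assign reads in the discovery window to known matures.

    Each read gets at most one mature: the best alignment over all catalog
    entries with <= ``max_mismatch`` substitutions and an exact seed, ties
    broken by fewest mismatches, then largest overlap, then species
    priority (nearest model fish first), then lexicographic name.
    """
    if not catalog:
        raise ValueError("mature miRNA catalog is empty")
    rank = {sp: i for i, sp in enumerate(species_priority)}
    hits = []
    for read in reads:
        seq = canonicalize(read.sequence)
        if not (min_len <= len(seq) <= max_len):
            continue
        best = None
        for mat in catalog:
            res = _align_to_mature(seq, mat.sequence,
                                   max_mismatch=max_mismatch,
                                   max_length_diff=max_length_diff,
                                   require_seed=True)
            if res is None:
                continue
            mm, overlap, off = res
            key = (mm, -overlap, rank.get(mat.species, len(rank)), mat.name)
            if best is None or key < best[0]:
                best = (key, mat, mm, overlap, off)
        if best is not None:
            _, mat, mm, overlap, off = best
            hits.append(ConservedHit(sequence=seq, count=read.count,
                                     mature_name=mat.name, offset=off,
                                     mismatches=mm, overlap_score=overlap))
    return hits


def aggregate_expression(hits: Iterable[ConservedHit],
                         *, high_threshold: int = 10_000) -> pd.DataFrame:
    """Per-miRNA total read counts with a high-expression flag.

    The flag marks miRNAs whose summed count strictly exceeds
    ``high_threshold`` reads.
    """
    rows: dict[str, int] = {}
    for h in hits:
        rows[h.mature_name] = rows.get(h.mature_name, 0) + h.count
    df = pd.DataFrame(
        [{"mirna": k, "reads": v, "high_expression": v > high_threshold}
         for k, v in sorted(rows.items())])
    return df


def assign_families(names: Iterable[str]) -> pd.DataFrame:
    """Group miRNA names into families; unparseable names get family 'none'."""
    rows = []
    for name in names:
        _, family = parse_mirna_name(name)
        rows.append({"mirna": name, "family": family or "none",
                     "parsed": family is not None})
    df = pd.DataFrame(rows)
    if not df.empty:
        sizes = df.groupby("family")["mirna"].transform("size")
        df["family_size"] = sizes.where(df["parsed"], 1)
    return df


@dataclass(frozen=True)
class StarCall:
    """A passenger-strand read on the arm opposite an annotated mature."""

    precursor: str
    sequence: str
    count: int
    arm: str                     # "5p" | "3p"
    start: int                   # 1-based position on the precursor
    paired_with_mature: int      # base pairs formed with the mature region
    mismatches_to_known: int | None = None
    status: str = "unclassified"  # conserved | needs-validation


def detect_star_pairs(
    reads: Iterable[UniqueRead],
    precursors,
    *,
    fold_fn: Callable[[str], HairpinStructure] = fold,
    min_duplex_pairs: int = 10,
) -> list[StarCall]:
    """Find miRNA:miRNA* duplex pairs on folded precursors.

    For each precursor the folded hairpin's terminal loop delimits the
    arms; a star call is the most abundant read (ties: 5'-most) that maps
    exactly within the arm opposite the annotated mature and base-pairs
    with the mature region over at least ``min_duplex_pairs`` positions.
    Precursors that do not fold into a hairpin are skipped with a warning.
    """
    read_list = [(canonicalize(r.sequence), r.count) for r in reads]
    calls = []
    for pre in precursors:
        structure = fold_fn(pre.sequence)
        if not structure.pairs:
            log.warning("precursor %s does not fold into a hairpin; skipped",
                        pre.name)
            continue
        loop_start, loop_end, _ = structure.terminal_loop
        m0, m1 = pre.mature
        n = len(pre.sequence)
        if m1 < loop_start:                  # mature on 5' arm
            arm_iv, arm = (loop_end + 1, n), "3p"
        elif m0 > loop_end:
            arm_iv, arm = (1, loop_start - 1), "5p"
        else:
            log.warning("precursor %s: mature overlaps the terminal loop; "
                        "skipped", pre.name)
            continue
        mature_set = set(range(m0, m1 + 1))
        best = None
        for seq, count in read_list:
            start = pre.sequence.find(seq)
            while start >= 0:
                s1, e1 = start + 1, start + len(seq)
                if arm_iv[0] <= s1 and e1 <= arm_iv[1]:
                    span = set(range(s1, e1 + 1))
                    paired = sum(1 for i, j in structure.pairs
                                 if (i in span and j in mature_set)
                                 or (j in span and i in mature_set))
                    if paired >= min_duplex_pairs:
                        key = (-count, s1)
                        if best is None or key < best[0]:
                            best = (key, seq, count, s1, paired)
                start = pre.sequence.find(seq, start + 1)
        if best is not None:
            _, seq, count, s1, paired = best
            calls.append(StarCall(precursor=pre.name, sequence=seq,
                                  count=count, arm=arm, start=s1,
                                  paired_with_mature=paired))
    return calls


def classify_star_conservation(
    calls: Iterable[StarCall],
    known_stars: Sequence[MatureMiRNA],
    *,
    max_mismatch: int = 3,
    max_length_diff: int = 2,
) -> list[StarCall]:
    """Label star calls conserved (<= ``max_mismatch`` to a known star).

    Alignment is the same ungapped best-offset scan used for conserved
    matures, without the seed requirement. Calls beyond the threshold are
    labelled needs-validation, as is everything when the known-star
    catalog is empty.
    """
    from dataclasses import replace

    known = list(known_stars)
    if not known:
        log.warning("known-star catalog empty; all calls need validation")
        return [replace(c, mismatches_to_known=None, status="needs-validation")
                for c in calls]
    out = []
    for call in calls:
        best_mm = None
        for star in known:
            res = _align_to_mature(call.sequence, star.sequence,
                                   max_mismatch=max(max_mismatch,
                                                    len(call.sequence)),
                                   max_length_diff=max_length_diff,
                                   require_seed=False)
            if res is None:
                continue
            if best_mm is None or res[0] < best_mm:
                best_mm = res[0]
        status = ("conserved" if best_mm is not None and best_mm <= max_mismatch
                  else "needs-validation")
        out.append(replace(call, mismatches_to_known=best_mm, status=status))
    return out
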