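"""Phylogenetic distribution of miRNA families and clade-specific substitutions.

Conserved miRNA families are classified by which animal lineages carry
them (mammals, birds, amphibians, fish, insects, nematodes), yielding
five named distribution groups, from pan-bilaterian families such as
let-7 down to fish-restricted miRNAs. Within a family's aligned mature
sequences, positions where clades are internally monomorphic but differ
from each other mark clade-specific substitutions (e.g. fish vs the other
vertebrates in miR-21), and a single focal species can be separated from
an otherwise-monomorphic set (a flounder-specific position in miR-29a).

Inputs are pre-aligned, equal-length mature sequences; matures within a
family are length-matched in practice, so no alignment algorithm is
provided. '-' is tolerated as a fifth symbol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

LINEAGES = ("mammals", "birds", "amphibians", "fish", "insects", "nematodes")
_VERTEBRATE = ("mammals", "birds", "amphibians", "fish")

GROUP_ALL_SIX = "all-six"
GROUP_NO_NEMATODE = "five-no-nematode"
GROUP_TETRAPOD_FISH = "vertebrate-tetrapod-fish"
GROUP_VERTEBRATE = "vertebrate-specific"
GROUP_FISH = "fish-restricted"
GROUP_OTHER = "other"

SEED_SPAN = (2, 8)


def classify_distribution(matrix: pd.DataFrame) -> pd.DataFrame:
    """Map each family's lineage-presence pattern to a distribution group.

    ``matrix``: boolean (or 0/1 or '+'/'-') DataFrame, rows = families,
    columns = the six lineages. Patterns outside the five named templates
    are labelled "other" with the raw pattern reported. The output
    partitions the input rows.
    """
    unknown = set(matrix.columns) - set(LINEAGES)
    if unknown:
        raise ValueError(f"unknown lineage columns: {sorted(unknown)}")
    missing = set(LINEAGES) - set(matrix.columns)
    if missing:
        raise ValueError(f"missing lineage columns: {sorted(missing)}")
    present = matrix[list(LINEAGES)].apply(
        lambda col: col.map(lambda v: {"+": True, "-": False}.get(v, v))
    ).astype(bool)
    rows = []
    for family, row in present.iterrows():
        on = frozenset(c for c in LINEAGES if row[c])
        if not on:
            raise ValueError(f"family {family} present in no lineage")
        if on == frozenset(LINEAGES):
            group = GROUP_ALL_SIX
        elif on == frozenset(LINEAGES) - {"nematodes"}:
            group = GROUP_NO_NEMATODE
        elif on == frozenset(_VERTEBRATE):
            group = GROUP_TETRAPOD_FISH
        elif on == frozenset({"fish"}):
            group = GROUP_FISH
        elif on < frozenset(_VERTEBRATE):
            group = GROUP_VERTEBRATE
        else:
            group = GROUP_OTHER
        rows.append({"family": family, "group": group,
                     "pattern": "".join("+" if row[c] else "-" for c in LINEAGES)})
    return pd.DataFrame(rows).set_index("family")


def group_members(classified: pd.DataFrame) -> dict[str, list[str]]:
    return {g: sorted(sub.index) for g, sub in classified.groupby("group")}


@dataclass(frozen=True)
class CladeSubstitution:
    """A position separating two internally-monomorphic clades."""

    position: int                # 1-based alignment position
    consensus: Mapping[str, str]  # clade -> base
    in_seed: bool


def find_clade_specific_positions(
    sequences: Mapping[str, str],
    clades: Mapping[str, str],
) -> list[CladeSubstitution]:
    """Positions where every clade is monomorphic and consensuses differ.

    ``sequences`` maps sequence name -> aligned (equal-length) mature
    sequence; ``clades`` maps sequence name -> clade label. Clades with
    fewer than 2 members are skipped with a warning; at least two clades
    must remain. The result is invariant to sequence order and clade
    relabeling.
    """
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise ValueError("sequences must be pre-aligned to equal length")
    by_clade: dict[str, list[str]] = {}
    for name, seq in sequences.items():
        by_clade.setdefault(clades[name], []).append(seq.upper())
    usable = {}
    for clade, seqs in by_clade.items():
        if len(seqs) < 2:
            log.warning("clade %s has <2 members; skipped", clade)
        else:
            usable[clade] = seqs
    if len(usable) < 2:
        return []
    (length,) = lengths
    lo, hi = SEED_SPAN
    out = []
    for pos in range(length):
        consensus = {}
        ok = True
        for clade, seqs in usable.items():
            bases = {s[pos] for s in seqs}
            if len(bases) != 1:
                ok = False
                break
            consensus[clade] = next(iter(bases))
        if ok and len(set(consensus.values())) > 1:
            out.append(CladeSubstitution(
                position=pos + 1, consensus=dict(sorted(consensus.items())),
                in_seed=lo <= pos + 1 <= hi))
    return out


def singleton_divergence(
    sequences: Mapping[str, str],
    focal: str,
) -> list[int]:
    """1-based positions where the focal sequence differs from an
    otherwise-monomorphic background.

    Positions where the non-focal sequences disagree among themselves are
    excluded. Requires >= 3 sequences.
    """
    if focal not in sequences:
        raise KeyError(f"focal sequence {focal!r} not present")
    if len(sequences) < 3:
        raise ValueError("need >= 3 sequences")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise ValueError("sequences must be pre-aligned to equal length")
    others = [s.upper() for k, s in sequences.items() if k != focal]
    f = sequences[focal].upper()
    out = []
    for pos in range(len(f)):
        bases = {s[pos] for s in others}
        if len(bases) == 1 and f[pos] not in bases:
            out.append(pos + 1)
    return out


# ---------------------------------------------------------------------------
# packaged fixture


def flounder_presence_fixture() -> pd.DataFrame:
    """Lineage-presence matrix for the 84 conserved flounder miRNA families
    plus 7 family-less miRNAs.

    Named members come from the published distribution statements: the 5
    pan-bilaterian families (mir-1, -34, -9, -124, let-7), the 7
    fish-restricted miRNAs (mir-459, -462, -722, -724, -726, -727, -731),
    and the sizes of the remaining groups (13 families shared by all
    lineages except nematodes; 6 shared by mammals, birds, amphibians and
    fish; the other 60 vertebrate-specific). The per-family identities of
    the unnamed groups are not recoverable from text, so those rows carry
    clearly synthetic placeholder ids (``nn-*``, ``tf-*``, ``vs-*``).
    """
    rows: dict[str, tuple[int, ...]] = {}

    def add(name: str, pattern: Sequence[int]) -> None:
        rows[name] = tuple(pattern)

    for fam in ("mir-1", "mir-34", "mir-9", "mir-124", "let-7"):
        add(fam, (1, 1, 1, 1, 1, 1))
    for k in range(13):
        add(f"nn-family-{k + 1:02d}", (1, 1, 1, 1, 1, 0))
    for k in range(6):
        add(f"tf-family-{k + 1:02d}", (1, 1, 1, 1, 0, 0))
    for fam in ("mir-459", "mir-462", "mir-722", "mir-724", "mir-726",
                "mir-727", "mir-731"):
        add(fam, (0, 0, 0, 1, 0, 0))
    # remaining 60 vertebrate-specific families: subsets of the four
    # vertebrate lineages other than the full set or fish alone
    patterns = ((1, 1, 0, 1, 0, 0), (1, 0, 1, 1, 0, 0), (0, 1, 1, 1, 0, 0),
                (1, 0, 0, 1, 0, 0), (0, 0, 1, 1, 0, 0))
    for k in range(60):
        add(f"vs-family-{k + 1:02d}", patterns[k % len(patterns)])

    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(LINEAGES)).astype(bool)
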