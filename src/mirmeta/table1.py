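"""Packaged transcription of the 20 cloned flounder miRNA precursors.

Twenty miRNA:miRNA* duplexes from the Japanese flounder small-RNA library
were PCR-amplified from genomic DNA and sequenced; each precursor below is
stored exactly as published, with the mature arm wrapped in ``**...**``
and the star (passenger) arm in ``*...*``. :func:`load_table1` strips the
markup and converts the arms to 1-based inclusive intervals.

These records serve as a regression fixture for the folding module: each
one is expected to fold into a single-terminal-loop hairpin.
"""

from __future__ import annotations

from dataclasses import dataclass

_TABLE1_ROWS: tuple[tuple[str, str], ...] = (
    ("pol-mir-1", "*ACAUACUUCUUUAUAUGCCCAUA*UGAACAAGAGCAACUA**UGGAAUGUAAAGAAGUAUGUAU**"),
    ("pol-let-7b", "**UGAGGUAGUAGGUUGUGUGGUU**UCAGGGUUGUGAUUUUACCCCAUCAGGAGCUAA*CUAUACAACCUACUGCCUUCC*"),
    ("pol-let-7c", "**UGAGGUAGUAGGUUGUAUGGUU**UGUGGGAUGGAGUAAAUCCUACUCAGGGGAUAA*CUAUACAACCUACUGCCUUCC*"),
    ("pol-let-7d", "**UGAGGUAGUUGGUUGUAUGGUU**UCGCAUAAUAAACAGCACGGAGAUAA*CUGUACAACCUUCUAGCUUUCC*"),
    ("pol-mir-9", "**UCUUUGGUUAUCUAGCUGUAUGA**GUUUUAAUUUCA*UAAAGCUAGAGAACCGAAAGUA*"),
    ("pol-mir-10d", "**UACCCUGUAGAACCGAAUGUGU**GUGAUGCAACCACAGUCAC*AGAUUCGAUUCUAGGGGAGUAU*"),
    ("pol-mir-21", "**UAGCUUAUCAGACUGGUGUUGG**CUGUUUAGAUUGCAAGG*CGACAACAGUCUGAAGGCUGUC*"),
    ("pol-mir-22a", "CAGC*AGUUCUUCACUGGCAAGCUUUA*UGUCCUCAUGUAUCAACUA**AAGCUGCCAGCUGAAGAACU**GU"),
    ("pol-mir-122", "CUG**UGGAGUGUGACAAUGGUGUUUG**UGUCCUGUCUAUCA*AACGCCAUUAUCACACUAUAUA*GC"),
    ("pol-mir-124", "*CGUGUUCACAGCGGACCUUGAU*UUAAUGUCCAUACAAU**UAAGGCACGCGGUGAAUGCCAA**"),
    ("pol-mir-133b", "*GCUGGUCAAACGGAACCAAGU*CAGGUGUUUCUGUGAGG**UUUGGUCCCCUUCAACCAGCU**A"),
    ("pol-mir-140", "**CAGUGGUUUUACCCUAUGGUAG**GUGACAUCAUGCUGUUCU*ACCACAGGGUAGAACCACGGAC*"),
    ("pol-mir-144", "GCGG*GGAUAUCAUCUUAUACUGUAAGU*UUAUUAUAGAGACAC**UACAGUAUAGAUGAUGUACUAU**CCCG"),
    ("pol-mir-182", "**UUUGGCAAUGGUAGAACUCACA**CUGGUGAGGUAGAUGGAUCCGG*UGGUUCUAGACUUGCCAACUA*"),
    ("pol-mir-199-1", "**CCCAGUGUUCAGACUACCUGUU**CAUUGUCAUACUGGUGU*ACAGUAGUCUGCACAUUGGUUA*"),
    ("pol-mir-199-2", "**CCCAGUGUUCAGACUACCUGUU**CAGGAAGUAGUGGUUGU*ACAGUAGUCUGCACAUUGGUUA*"),
    ("pol-mir-203", "*AGUGGUUCUCAACAGUUCAACAG*UUCUUAGAGAAAAUU**GUGAAAUGUUUAGGACCACUUG**"),
    ("pol-mir-206a", "*ACAUGCUUCCUUAUAUCCCCAU*AUUCAUACAGCACUUA**UGGAAUGUAAGGAAGUGUGUGG**"),
    ("pol-mir-219", "**UGAUUGUCCAAACGCAAUUCUU**GUAUCACUUGUCUGUAUCUA*GGAGUUGUGGAUGGACAUCACG*"),
    ("pol-mir-221", "UGA*ACCUGGCAUACAAUGUAGAUUU*CUGUGUGUCAGUCUAC**AGCUACAUUGUCUGCUGGGUUU**CA"),
)


@dataclass(frozen=True)
class Precursor:
    """A pre-miRNA hairpin with annotated mature and star arm intervals.

    Intervals are 1-based inclusive and non-overlapping; ``source`` records
    where the annotation came from (``table1-fixture``, ``synthetic`` or
    ``catalog``). ``star`` may be None for catalog entries without a
    documented passenger arm.
    """

    name: str
    sequence: str
    mature: tuple[int, int]
    star: tuple[int, int] | None = None
    source: str = "catalog"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for label, iv in (("mature", self.mature), ("star", self.star)):
            if iv is None:
                continue
            lo, hi = iv
            if not (1 <= lo <= hi <= n):
                raise ValueError(f"{self.name}: {label} interval {iv} outside 1..{n}")
        if self.star is not None:
            a, b = sorted([self.mature, self.star])
            if a[1] >= b[0]:
                raise ValueError(f"{self.name}: mature and star intervals overlap")

    @property
    def mature_seq(self) -> str:
        return self.sequence[self.mature[0] - 1: self.mature[1]]

    @property
    def star_seq(self) -> str | None:
        if self.star is None:
            return None
        return self.sequence[self.star[0] - 1: self.star[1]]


def parse_annotated(name: str, annotated: str, source: str = "table1-fixture") -> Precursor:
    """Parse a ``**mature**`` / ``*star*`` annotated precursor string."""
    mature = star = None
    seq_chars: list[str] = []
    i = 0
    while i < len(annotated):
        if annotated.startswith("**", i):
            end = annotated.index("**", i + 2)
            seg = annotated[i + 2: end]
            mature = (len(seq_chars) + 1, len(seq_chars) + len(seg))
            seq_chars.extend(seg)
            i = end + 2
        elif annotated[i] == "*":
            end = annotated.index("*", i + 1)
            seg = annotated[i + 1: end]
            star = (len(seq_chars) + 1, len(seq_chars) + len(seg))
            seq_chars.extend(seg)
            i = end + 1
        else:
            seq_chars.append(annotated[i])
            i += 1
    if mature is None or star is None:
        raise ValueError(f"{name}: annotation must mark both mature and star arms")
    return Precursor(name=name, sequence="".join(seq_chars),
                     mature=mature, star=star, source=source)


def load_table1() -> list[Precursor]:
    """The 20 cloned precursors, parsed to :class:`Precursor` records."""
    return [parse_annotated(name, row) for name, row in _TABLE1_ROWS]
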