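"""Hairpin-restricted minimum-free-energy folding of pre-miRNA candidates.

Pre-miRNAs are short (~55-90 nt) RNAs whose functional structure is a
single stem-loop: one helix, interrupted by bulges and internal loops,
closed by one terminal loop. This module folds candidate sequences under
a nearest-neighbor energy model restricted to exactly that shape — no
multibranch loops, no pseudoknots — which keeps the search space small
enough that an exhaustive enumeration oracle (:func:`enumerate_structures`)
can certify the dynamic program on short sequences.

Energies combine published base-pair stacking terms with size-dependent
destabilization for hairpin, bulge and internal loops; the constants live
in ``data/nn_energies.yaml`` so an alternative parameter set can be swapped
in without code changes. All arithmetic is done in integer centi-kcal/mol
to make ties exact and the tie-break (more pairs, then first traceback
option in a fixed scan order) deterministic.

Six structural acceptance criteria for calling a sequence a credible
miRNA precursor are evaluated by :func:`evaluate_criteria`:

1. stem contains >= 18 base pairs;
2. no single bulge/internal loop holds > 18 unpaired nucleotides
   (summed over both sides);
3. folding free energy dG <= -15 kcal/mol;
4. >= 80% of the mature miRNA lies on the stem;
5. hairpin span (both stem arms + terminal loop) >= 53 nt;
6. terminal loop <= 22 nt.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Sequence

import yaml

PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_LOOP = 3          # minimum hairpin loop length, nt
MAX_INTERIOR = 30     # cap on unpaired nt in one internal loop/bulge (both sides)
MIN_FOLD_LEN = 30
MAX_FOLD_LEN = 200

_INF = 10 ** 9


class FoldInputError(ValueError):
    """Raised for sequences outside the folder's domain."""


def _load_params() -> dict:
    text = resources.files("mirmeta").joinpath("data/nn_energies.yaml").read_text()
    return yaml.safe_load(text)


@functools.lru_cache(maxsize=1)
def energy_params() -> dict:
    """Load and expand the nearest-neighbor parameter tables.

    Returns a dict with integer centi-kcal tables: ``stack[(x, y, z, w)]``
    for the motif 5'-xy-3'/3'-zw-5', and closures ``hairpin(n)``,
    ``bulge(n)``, ``internal(n1, n2)``.
    """
    raw = _load_params()
    stack: dict[tuple[str, str, str, str], int] = {}
    for motif, dg in raw["stacking"].items():
        top, bottom = motif.split("/")
        x, y = top[0], top[1]
        z, w = bottom[0], bottom[1]
        e = round(dg * 100)
        stack[(x, y, z, w)] = e
        # 180-degree rotation of the duplex gives the same physical motif
        stack[(w, z, y, x)] = e

    coeff = raw["loop_extrapolation_coeff"]

    def _table(name: str) -> dict[int, float]:
        return {int(k): float(v) for k, v in raw[name].items()}

    hp, bl, il = _table("hairpin_loop"), _table("bulge_loop"), _table("internal_loop")

    def _extrapolate(table: dict[int, float], n: int) -> int:
        nmax = max(table)
        if n <= nmax:
            return round(table[n] * 100)
        return round((table[nmax] + coeff * math.log(n / nmax)) * 100)

    asym = raw["internal_asymmetry_per_nt"]
    asym_max = raw["internal_asymmetry_max"]

    def hairpin(n: int) -> int:
        if n < MIN_LOOP:
            return _INF
        return _extrapolate(hp, n)

    def bulge(n: int) -> int:
        return _extrapolate(bl, n)

    def internal(n1: int, n2: int) -> int:
        base = _extrapolate(il, n1 + n2)
        penalty = min(asym * abs(n1 - n2), asym_max)
        return base + round(penalty * 100)

    return {"stack": stack, "hairpin": hairpin, "bulge": bulge, "internal": internal}


@dataclass(frozen=True)
class HairpinStructure:
    """A single-stem-loop secondary structure for one sequence.

    Coordinates are 1-based; ``pairs`` are (i, j) with i < j, sorted
    outermost first. An empty pair list is the open (unfolded) structure
    with zero free energy.
    """

    sequence: str
    pairs: tuple[tuple[int, int], ...]
    energy: float  # kcal/mol

    @property
    def dot_bracket(self) -> str:
        chars = ["."] * len(self.sequence)
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def terminal_loop(self) -> tuple[int, int, int] | None:
        """(start, end, length) of the loop enclosed by the innermost pair."""
        if not self.pairs:
            return None
        p, q = self.pairs[-1]
        return (p + 1, q - 1, q - p - 1)

    @property
    def n_terminal_loops(self) -> int:
        """Number of terminal loops (0 for the open structure, else 1).

        The fold search space admits only chains of nested pairs, so any
        non-empty structure from :func:`fold` has exactly one; counted
        from the pair set for use as an explicit check.
        """
        if not self.pairs:
            return 0
        loops = 0
        enclosed = {p: [] for p in self.pairs}
        ordered = sorted(self.pairs)
        for k, inner in enumerate(ordered):
            for outer in ordered[:k]:
                if outer[0] < inner[0] and inner[1] < outer[1]:
                    enclosed[outer].append(inner)
        for p in ordered:
            if not enclosed[p]:
                loops += 1
        return loops

    @property
    def interior_loops(self) -> list[tuple[int, int]]:
        """Per interior loop: (unpaired on 5' side, unpaired on 3' side)."""
        out = []
        for (i, j), (k, l) in zip(self.pairs, self.pairs[1:]):
            a, b = k - i - 1, j - l - 1
            if a or b:
                out.append((a, b))
        return out

    @property
    def stem_span(self) -> tuple[int, int] | None:
        """1-based (start, end) of the full hairpin: outermost pair span."""
        if not self.pairs:
            return None
        return self.pairs[0]

    def vienna(self) -> str:
        """Sequence + dot-bracket + energy, RNAfold-style."""
        return f"{self.sequence}\n{self.dot_bracket} ({self.energy:6.2f})"


def _canonical_rna(sequence: str) -> str:
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise FoldInputError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def _pair_matrix(seq: str) -> list[list[bool]]:
    n = len(seq)
    return [[(seq[i], seq[j]) in PAIRABLE for j in range(n)] for i in range(n)]


def energy_of_structure(sequence: str, pairs: Sequence[tuple[int, int]]) -> float:
    """Free energy (kcal/mol) of a given nested-chain structure.

    Shared by the DP and the enumeration oracle so that both score a
    candidate identically. ``pairs`` must form a chain of nested pairs
    (each pair enclosing the next); 1-based coordinates.
    """
    if not pairs:
        return 0.0
    seq = _canonical_rna(sequence)
    params = energy_params()
    ordered = sorted(pairs)
    total = 0
    for (i, j), (k, l) in zip(ordered, ordered[1:]):
        if not (i < k < l < j):
            raise ValueError("pairs do not form a nested chain")
        a, b = k - i - 1, j - l - 1
        if a == 0 and b == 0:
            motif = (seq[i - 1], seq[k - 1], seq[j - 1], seq[l - 1])
            total += params["stack"].get(motif, 0)
        elif a == 0 or b == 0:
            total += params["bulge"](a + b)
        else:
            total += params["internal"](a, b)
    p, q = ordered[-1]
    total += params["hairpin"](q - p - 1)
    return total / 100.0


def fold(sequence: str, *, min_len: int = MIN_FOLD_LEN,
         max_len: int = MAX_FOLD_LEN) -> HairpinStructure:
    """Fold a sequence to its minimum-energy single-stem-loop structure.

    The dynamic program minimizes over chains of nested pairs: ``V(i, j)``
    is the best energy with (i, j) paired and the interior a continuing
    chain; the answer is the best ``V`` over all outer pairs, or the open
    structure (energy 0) if no pairing is stabilizing. Ties prefer more
    pairs, then the first option in the fixed traceback scan order, so
    output is deterministic.

    Raises :class:`FoldInputError` for out-of-range lengths or non-ACGU(T)
    characters.
    """
    seq = _canonical_rna(sequence)
    n = len(seq)
    if not (min_len <= n <= max_len):
        raise FoldInputError(
            f"sequence length {n} outside folding range [{min_len}, {max_len}]")
    return _fold_canonical(seq)


def _fold_canonical(seq: str) -> HairpinStructure:
    n = len(seq)
    params = energy_params()
    stack = params["stack"]
    hairpin_e = params["hairpin"]
    bulge_e = params["bulge"]
    internal_e = params["internal"]
    can_pair = _pair_matrix(seq)

    # V[i][j]: (energy, -npairs) with (i, j) paired (0-based), or None
    V: list[list[tuple[int, int] | None]] = [[None] * n for _ in range(n)]

    for span in range(MIN_LOOP + 1, n):          # span = j - i
        for i in range(0, n - span):
            j = i + span
            if not can_pair[i][j]:
                continue
            best = (hairpin_e(j - i - 1), -1)
            # interior transition to the next pair (k, l)
            amax = min(MAX_INTERIOR, j - i - MIN_LOOP - 2)
            for a in range(0, amax + 1):
                k = i + 1 + a
                bmax = min(MAX_INTERIOR - a, j - k - MIN_LOOP - 1)
                for b in range(0, bmax + 1):
                    l = j - 1 - b
                    inner = V[k][l]
                    if inner is None:
                        continue
                    if a == 0 and b == 0:
                        loop = stack.get((seq[i], seq[k], seq[j], seq[l]), 0)
                    elif a == 0 or b == 0:
                        loop = bulge_e(a + b)
                    else:
                        loop = internal_e(a, b)
                    cand = (inner[0] + loop, inner[1] - 1)
                    if cand < best:
                        best = cand
            if best[0] < _INF:
                V[i][j] = best

    # choose the best outer pair vs the open structure
    best_outer: tuple[int, int] | None = None
    best_val = (0, 0)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            v = V[i][j]
            if v is not None and v < best_val:
                best_val = v
                best_outer = (i, j)

    if best_outer is None:
        return HairpinStructure(sequence=seq, pairs=(), energy=0.0)

    # traceback, re-scanning options in the DP's order
    pairs: list[tuple[int, int]] = []
    i, j = best_outer
    while True:
        pairs.append((i + 1, j + 1))
        target = V[i][j]
        assert target is not None
        found = None
        amax = min(MAX_INTERIOR, j - i - MIN_LOOP - 2)
        for a in range(0, amax + 1):
            k = i + 1 + a
            bmax = min(MAX_INTERIOR - a, j - k - MIN_LOOP - 1)
            for b in range(0, bmax + 1):
                l = j - 1 - b
                inner = V[k][l]
                if inner is None:
                    continue
                if a == 0 and b == 0:
                    loop = stack.get((seq[i], seq[k], seq[j], seq[l]), 0)
                elif a == 0 or b == 0:
                    loop = bulge_e(a + b)
                else:
                    loop = internal_e(a, b)
                if (inner[0] + loop, inner[1] - 1) == target:
                    found = (k, l)
                    break
            if found:
                break
        if found is None:       # hairpin closes here
            break
        i, j = found

    return HairpinStructure(sequence=seq, pairs=tuple(pairs),
                            energy=best_val[0] / 100.0)


MAX_ENUM_LEN = 18


def enumerate_structures(sequence: str) -> Iterator[HairpinStructure]:
    """Exhaustively enumerate every nested-chain structure with its energy.

    Test oracle for :func:`fold`: on sequences of length <= 18 nt it yields
    the open structure and every chain of nested pairs respecting the
    minimum loop length and the interior-loop size cap, scored by the same
    :func:`energy_of_structure`. Refuses longer sequences (combinatorial
    safety bound).
    """
    seq = _canonical_rna(sequence)
    n = len(seq)
    if n > MAX_ENUM_LEN:
        raise FoldInputError(
            f"enumeration limited to {MAX_ENUM_LEN} nt (got {n})")
    can_pair = _pair_matrix(seq)

    yield HairpinStructure(sequence=seq, pairs=(), energy=0.0)

    def chains(i: int, j: int) -> Iterator[tuple[tuple[int, int], ...]]:
        """All chains starting with outer pair (i, j), 0-based."""
        yield ((i + 1, j + 1),)
        for k in range(i + 1, j - MIN_LOOP):
            for l in range(k + MIN_LOOP + 1, j):
                a, b = k - i - 1, j - l - 1
                if a + b > MAX_INTERIOR or not can_pair[k][l]:
                    continue
                for rest in chains(k, l):
                    yield ((i + 1, j + 1),) + rest

    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            if not can_pair[i][j]:
                continue
            for chain in chains(i, j):
                yield HairpinStructure(
                    sequence=seq, pairs=chain,
                    energy=energy_of_structure(seq, chain))


# ---------------------------------------------------------------------------
# precursor acceptance criteria


@dataclass(frozen=True)
class Criterion:
    name: str
    measured: float
    threshold: float
    passed: bool


@dataclass(frozen=True)
class CriteriaReport:
    """Pass/fail plus measured value for each of the six hairpin criteria."""

    criteria: tuple[Criterion, ...] = field(default_factory=tuple)

    @property
    def overall(self) -> bool:
        return all(c.passed for c in self.criteria)

    def __getitem__(self, name: str) -> Criterion:
        for c in self.criteria:
            if c.name == name:
                return c
        raise KeyError(name)


def evaluate_criteria(
    structure: HairpinStructure,
    mature_interval: tuple[int, int],
    *,
    min_stem_pairs: int = 18,
    max_bulge_errors: int = 18,
    max_energy: float = -15.0,
    min_mature_in_stem: float = 0.80,
    min_hairpin_len: int = 53,
    max_loop_len: int = 22,
) -> CriteriaReport:
    """Score a folded candidate against the six precursor criteria.

    ``mature_interval`` is 1-based inclusive and must lie within the
    sequence. The stem is every position between the outermost pair and
    the terminal loop, on either arm; mature positions inside the terminal
    loop or outside the outermost pair count against criterion 4. A
    structure with zero pairs fails every structural criterion but still
    yields a full report.
    """
    m0, m1 = mature_interval
    n = len(structure.sequence)
    if not (1 <= m0 <= m1 <= n):
        raise ValueError(f"mature interval ({m0}, {m1}) outside sequence of length {n}")

    stem_pairs = structure.n_pairs
    worst_bulge = max((a + b for a, b in structure.interior_loops), default=0)
    energy = structure.energy

    if structure.pairs:
        (s0, s1) = structure.stem_span       # outermost pair
        loop_start, loop_end, loop_len = structure.terminal_loop
        stem_positions = set(range(s0, loop_start)) | set(range(loop_end + 1, s1 + 1))
        mature_positions = set(range(m0, m1 + 1))
        in_stem = len(mature_positions & stem_positions) / len(mature_positions)
        hairpin_len = s1 - s0 + 1
    else:
        in_stem = 0.0
        hairpin_len = 0
        loop_len = 0

    criteria = (
        Criterion("stem_pairs", stem_pairs, min_stem_pairs,
                  stem_pairs >= min_stem_pairs),
        Criterion("max_bulge", worst_bulge, max_bulge_errors,
                  worst_bulge <= max_bulge_errors),
        Criterion("free_energy", energy, max_energy,
                  structure.pairs != () and energy <= max_energy),
        Criterion("mature_in_stem", in_stem, min_mature_in_stem,
                  in_stem >= min_mature_in_stem),
        Criterion("hairpin_length", hairpin_len, min_hairpin_len,
                  hairpin_len >= min_hairpin_len),
        Criterion("loop_length", loop_len, max_loop_len,
                  structure.pairs != () and loop_len <= max_loop_len),
    )
    return CriteriaReport(criteria=criteria)
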