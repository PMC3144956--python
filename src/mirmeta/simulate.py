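"""Synthetic small-RNA libraries, microarrays and qPCR plates with planted truth.

Every input the discovery and expression pipeline consumes can be generated
here under a single seeded configuration, with a truth table recording the
origin of every emitted unique read, the planted arm coordinates of every
precursor, and the true differential-expression status of every array probe.
The generator emulates the structure of a metamorphic-stage small-RNA
library: hairpin precursors carrying a mature/star duplex, reads drawn from
precursor arms plus contaminant ncRNA fragments, low-complexity junk and
random background, long-tailed copy-count distributions, and two-stage
microarray / qPCR measurements with replicate noise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

COMPLEMENT = str.maketrans("ACGU", "UGCA")
BASES = np.array(list("ACGU"))

ARRAY_STAGES = ("17dph", "29dph")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions at desk scale: ~22-nt matures on
    53-90 nt hairpins, a 14-28 nt read-length window spanning both sides
    of the 15/26 retention filter, a power-law copy-count tail so the
    >=3-copy filter bites, a two-stage (17 vs 29 dph) array with three
    replicates per stage, and multiplicative replicate noise.
    """

    seed: int = 0
    n_precursors: int = 20
    n_reads: int = 10_000
    mature_fraction: float = 0.35
    star_fraction: float = 0.05
    contaminant_fraction: float = 0.20
    junk_fraction: float = 0.10
    error_rate: float = 0.0
    length_range: tuple[int, int] = (14, 28)
    mature_length: int = 22
    loop_length: int | None = None       # None: drawn uniformly from 9-15 nt
    precursor_length_range: tuple[int, int] = (53, 90)
    copy_exponent: float = 1.5           # zeta exponent of the copy-count tail
    array_n_mirnas: int = 100
    array_n_de: int = 10
    array_effect_log2: float = 3.0
    array_low_fraction: float = 0.10     # probes forced below detection
    replicate_cv: float = 0.10
    ct_noise_sd: float = 0.10

    def __post_init__(self) -> None:
        fracs = {
            "mature_fraction": self.mature_fraction,
            "star_fraction": self.star_fraction,
            "contaminant_fraction": self.contaminant_fraction,
            "junk_fraction": self.junk_fraction,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if sum(fracs.values()) > 1.0 + 1e-12:
            raise ConfigError("origin fractions must sum to <= 1")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ConfigError(f"error_rate must be in [0, 1], got {self.error_rate}")
        for name in ("length_range", "precursor_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ConfigError(f"{name} must satisfy 0 < min <= max, got {(lo, hi)}")
        if self.n_precursors < 1:
            raise ConfigError("n_precursors must be >= 1")
        if self.array_n_de > self.array_n_mirnas:
            raise ConfigError("array_n_de must be <= array_n_mirnas")
        if self.copy_exponent <= 1.0:
            raise ConfigError("copy_exponent must be > 1")
        if self.replicate_cv < 0 or self.ct_noise_sd < 0:
            raise ConfigError("noise parameters must be non-negative")

    @property
    def background_fraction(self) -> float:
        return 1.0 - (self.mature_fraction + self.star_fraction
                      + self.contaminant_fraction + self.junk_fraction)


@dataclass
class TruthTable:
    """Planted ground truth for one simulated study.

    ``reads``: one row per emitted unique sequence draw (label, source,
    copies). ``precursors``: planted arm coordinates. ``probes``: per
    array probe, DE status and true log2 effect. ``ct``: planted qPCR
    fold changes.
    """

    reads: pd.DataFrame = field(default_factory=pd.DataFrame)
    precursors: pd.DataFrame = field(default_factory=pd.DataFrame)
    probes: pd.DataFrame = field(default_factory=pd.DataFrame)
    ct: pd.DataFrame = field(default_factory=pd.DataFrame)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _perturb(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq
    chars = list(seq)
    for i, c in enumerate(chars):
        if rng.random() < rate:
            chars[i] = rng.choice([b for b in "ACGU" if b != c])
    return "".join(chars)


def simulate_precursors(config: SimConfig):
    """Build hairpin precursors with planted mature/star duplexes.

    Each precursor is mature arm + loop + noisy reverse complement of the
    mature arm (the star), so a foldable stem is guaranteed; the mature
    arm is placed 5' or 3' of the loop at random. Returns
    ``(precursors, truth, fasta_text)``.
    """
    from .table1 import Precursor  # local import to avoid cycle at module load

    rng = np.random.default_rng(config.seed)
    lo, hi = config.precursor_length_range
    records: list[Precursor] = []
    rows = []
    for idx in range(config.n_precursors):
        while True:
            m_len = int(rng.integers(max(20, config.mature_length - 2),
                                     config.mature_length + 3))
            loop_len = (config.loop_length if config.loop_length is not None
                        else int(rng.integers(9, 16)))
            total = 2 * m_len + loop_len
            if lo <= total <= hi:
                break
        mature = _random_seq(rng, m_len)
        loop = _random_seq(rng, loop_len)
        star = _perturb(rng, revcomp(mature), config.error_rate)
        mature_on_5p = bool(rng.random() < 0.5)
        if mature_on_5p:
            seq = mature + loop + star
            m_iv = (1, m_len)
            s_iv = (m_len + loop_len + 1, total)
        else:
            seq = star + loop + mature
            s_iv = (1, m_len)
            m_iv = (m_len + loop_len + 1, total)
        name = f"syn-mir-{idx + 1:03d}"
        records.append(Precursor(name=name, sequence=seq, mature=m_iv,
                                 star=s_iv, source="synthetic"))
        rows.append({"name": name, "length": total,
                     "mature_start": m_iv[0], "mature_end": m_iv[1],
                     "star_start": s_iv[0], "star_end": s_iv[1],
                     "mature_arm": "5p" if mature_on_5p else "3p"})
    truth = pd.DataFrame(rows)
    fasta = "".join(f">{p.name}\n{p.sequence}\n" for p in records)
    return records, truth, fasta


def simulate_contaminants(config: SimConfig, *, n_per_class: int = 3,
                          length: int = 200) -> list[tuple[str, str, str]]:
    """Reference ncRNA/repeat/mRNA catalog: (id, class, sequence) triples."""
    rng = np.random.default_rng(config.seed + 101)
    classes = ("rRNA", "tRNA", "snoRNA", "snRNA", "repeat", "mRNA")
    out = []
    for cls in classes:
        for k in range(n_per_class):
            out.append((f"{cls}-{k + 1}", cls, _random_seq(rng, length)))
    return out


_ORIGINS = ("mature", "star", "contaminant", "junk", "background")


def simulate_reads(config: SimConfig, precursors, contaminants):
    """Emit a FASTQ library of error-perturbed reads with a truth table.

    Unique sequence draws get origins from the configured fractions and
    zeta-distributed copy counts (so part of the library sits below the
    3-copy filter); mature/star draws copy an annotated precursor arm,
    contaminant draws are substrings of catalog references, junk draws are
    low-complexity (<= 2 distinct bases), background draws are uniform
    random. Returns ``(fastq_text, truth_df)``; emission stops once
    ``config.n_reads`` total reads (copies) are written.
    """
    if not precursors:
        raise ValueError("precursor catalog is empty")
    if not contaminants:
        raise ValueError("contaminant catalog is empty")
    rng = np.random.default_rng(config.seed + 7)
    probs = np.array([
        config.mature_fraction, config.star_fraction,
        config.contaminant_fraction, config.junk_fraction,
        config.background_fraction,
    ])
    lo, hi = config.length_range
    rows = []
    buf = io.StringIO()
    emitted = 0
    draw = 0
    while emitted < config.n_reads:
        origin = _ORIGINS[rng.choice(len(_ORIGINS), p=probs)]
        source = ""
        if origin in ("mature", "star"):
            p = precursors[rng.integers(len(precursors))]
            iv = p.mature if origin == "mature" else p.star
            arm = p.sequence[iv[0] - 1: iv[1]]
            seq = _perturb(rng, arm, config.error_rate)
            source = p.name
        elif origin == "contaminant":
            ref_id, cls, ref_seq = contaminants[rng.integers(len(contaminants))]
            rd_len = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, len(ref_seq) - rd_len + 1))
            seq = _perturb(rng, ref_seq[start: start + rd_len], config.error_rate)
            source = f"{cls}:{ref_id}"
        elif origin == "junk":
            rd_len = int(rng.integers(lo, hi + 1))
            alphabet = rng.choice(BASES, size=rng.integers(1, 3), replace=False)
            seq = "".join(rng.choice(alphabet, size=rd_len))
        else:
            rd_len = int(rng.integers(lo, hi + 1))
            seq = _random_seq(rng, rd_len)
        copies = int(min(rng.zipf(config.copy_exponent), 5000))
        copies = min(copies, config.n_reads - emitted)
        if copies == 0:
            break
        draw += 1
        rows.append({"draw": draw, "sequence": seq, "origin": origin,
                     "source": source, "copies": copies})
        qual = "I" * len(seq)
        for c in range(copies):
            buf.write(f"@read_{draw}_{c + 1} origin={origin}\n"
                      f"{seq}\n+\n{qual}\n")
        emitted += copies
    return buf.getvalue(), pd.DataFrame(rows)


def simulate_array(config: SimConfig):
    """Two-stage microarray signals (3 replicates per stage) + probe truth.

    Non-DE probes share one per-probe mean across stages; DE probes differ
    by ``array_effect_log2`` (random direction). Replicate noise is
    multiplicative log-normal with coefficient of variation
    ``replicate_cv``; a configurable fraction of probes is forced below
    the detection threshold regime. Returns ``(signals_df, truth_df)``
    with columns ``{stage}_r{1..3}`` indexed by probe name.
    """
    rng = np.random.default_rng(config.seed + 23)
    n = config.array_n_mirnas
    names = [f"probe-mir-{i + 1:03d}" for i in range(n)]
    base = 2.0 ** rng.uniform(6.0, 12.0, size=n)          # ~64..4096
    n_low = int(round(config.array_low_fraction * n))
    low_idx = rng.choice(n, size=n_low, replace=False)
    base[low_idx] = 2.0 ** rng.uniform(1.0, 4.0, size=n_low)   # 2..16, sub-threshold
    de_idx = rng.choice(np.setdiff1d(np.arange(n), low_idx),
                        size=config.array_n_de, replace=False)
    direction = rng.choice([-1.0, 1.0], size=n)
    effect = np.zeros(n)
    effect[de_idx] = config.array_effect_log2 * direction[de_idx]

    sigma = float(np.sqrt(np.log1p(config.replicate_cv ** 2)))
    cols = {}
    for stage_i, stage in enumerate(ARRAY_STAGES):
        mean = base * (2.0 ** (effect if stage_i == 1 else 0.0))
        for r in range(3):
            noise = (np.exp(rng.normal(-sigma ** 2 / 2, sigma, size=n))
                     if sigma > 0 else np.ones(n))
            cols[f"{stage}_r{r + 1}"] = mean * noise
    signals = pd.DataFrame(cols, index=pd.Index(names, name="probe"))
    truth = pd.DataFrame({
        "probe": names,
        "is_de": np.isin(np.arange(n), de_idx),
        "true_log2_effect": effect,
        "sub_threshold": np.isin(np.arange(n), low_idx),
    }).set_index("probe")
    return signals, truth


def simulate_ct(config: SimConfig, fold_changes: dict[str, float] | None = None):
    """Two-stage qPCR Ct triplicates for target miRNAs + a 5S rRNA control.

    The planted fold change of each target between test and calibrator
    stage is converted to a Ct shift (delta-Ct = -log2(fold)); the
    reference gene keeps a constant mean across stages. Gaussian cycle
    noise with sd ``ct_noise_sd`` is added to every well. Returns
    ``(ct_df, truth_df)`` in long form (gene, stage, replicate, ct).
    """
    if fold_changes is None:
        fold_changes = {"mir-1": 4.0, "mir-22a": 0.25, "mir-10d": 1.0}
    rng = np.random.default_rng(config.seed + 47)
    rows = []
    truth_rows = []
    ref_ct = 15.0
    for gene, fold in fold_changes.items():
        base_ct = float(rng.uniform(20.0, 28.0))
        for stage_i, stage in enumerate(ARRAY_STAGES):
            shift = -np.log2(fold) if stage_i == 1 else 0.0
            for rep in range(3):
                rows.append({
                    "gene": gene, "stage": stage, "replicate": rep + 1,
                    "ct": base_ct + shift + rng.normal(0, config.ct_noise_sd),
                })
        truth_rows.append({"gene": gene, "true_fold": fold})
    for stage in ARRAY_STAGES:
        for rep in range(3):
            rows.append({
                "gene": "5S_rRNA", "stage": stage, "replicate": rep + 1,
                "ct": ref_ct + rng.normal(0, config.ct_noise_sd),
            })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_study(config: SimConfig):
    """Run every generator under one config; returns a dict of artifacts."""
    precursors, pre_truth, fasta = simulate_precursors(config)
    contaminants = simulate_contaminants(config)
    fastq, read_truth = simulate_reads(config, precursors, contaminants)
    signals, probe_truth = simulate_array(config)
    ct, ct_truth = simulate_ct(config)
    truth = TruthTable(reads=read_truth, precursors=pre_truth,
                       probes=probe_truth, ct=ct_truth)
    return {
        "config": asdict(config),
        "precursors": precursors,
        "precursor_fasta": fasta,
        "contaminants": contaminants,
        "fastq": fastq,
        "array_signals": signals,
        "ct": ct,
        "truth": truth,
    }
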