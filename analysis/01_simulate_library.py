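#!/usr/bin/env python
"""Generate the synthetic study every later step consumes.

Writes a seeded small-RNA library (FASTQ), hairpin precursors and
contaminant references (FASTA), two-stage microarray signals and qPCR Ct
plates (TSV), plus the planted truth tables, under scratch/simulated/
(raw simulated inputs are bulky and regenerable, so they stay out of the
versioned results).
"""

from pathlib import Path

from mirmeta.simulate import SimConfig, simulate_study

OUT = Path(__file__).resolve().parents[1] / "scratch" / "simulated"

config = SimConfig(seed=20110727, n_reads=50_000, error_rate=0.01,
                   mature_fraction=0.35, star_fraction=0.10,
                   contaminant_fraction=0.20, junk_fraction=0.10)

study = simulate_study(config)
OUT.mkdir(parents=True, exist_ok=True)
(OUT / "precursors.fasta").write_text(study["precursor_fasta"])
(OUT / "reads.fastq").write_text(study["fastq"])
with open(OUT / "contaminants.fasta", "w") as fh:
    for rid, cls, seq in study["contaminants"]:
        fh.write(f">{rid} class={cls}\n{seq}\n")
study["array_signals"].to_csv(OUT / "array_signals.tsv", sep="\t")
study["ct"].to_csv(OUT / "ct.tsv", sep="\t", index=False)
truth = study["truth"]
truth.reads.to_csv(OUT / "truth_reads.tsv", sep="\t", index=False)
truth.precursors.to_csv(OUT / "truth_precursors.tsv", sep="\t", index=False)
truth.probes.to_csv(OUT / "truth_probes.tsv", sep="\t")
truth.ct.to_csv(OUT / "truth_ct.tsv", sep="\t", index=False)

n_unique = truth.reads.shape[0]
print(f"simulated {config.n_reads} reads ({n_unique} unique draws), "
      f"{config.n_precursors} precursors, "
      f"{config.array_n_mirnas}-probe array with {config.array_n_de} planted "
      f"DE miRNAs -> {OUT}/")
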