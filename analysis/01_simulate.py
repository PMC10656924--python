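#!/usr/bin/env python
"""Generate the default synthetic recolonization experiment.

Writes the study's input surface — counts, metadata, per-genome pathway
presence, subsystem map, ASV and genome 16S FASTA, and the planted truth —
under results/synthetic/.  The design mirrors the recolonization study:
3 inocula (bL, bJ, bA) x 4 timepoints (2, 7, 14, 28 dpr) x 5 replicates on
2 substrates (polyp, tube) plus one sample per inoculum.
"""

from pathlib import Path

from microsucc.simulate import default_truth, generate_experiment, write_experiment

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 1


def main() -> None:
    spec = default_truth(seed=SEED, n_taxa=80, n_pathways=100)
    exp = generate_experiment(spec, n_replicates=5, depth=20_000)
    paths = write_experiment(exp, OUT)
    n_early = sum(1 for c in spec.class_of.values() if c == "early")
    n_late = sum(1 for c in spec.class_of.values() if c == "late")
    print(f"wrote {len(paths)} files under {OUT}")
    print(f"  {exp.table.counts.shape[0]} samples x {exp.table.counts.shape[1]} ASVs")
    print(f"  planted classes: {n_early} early, {n_late} late, "
          f"{spec.n_taxa - n_early - n_late} inoculum-specific")
    print(f"  planted pathways: 10 early-associated, 10 late-associated, 80 neutral")


if __name__ == "__main__":
    main()
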