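#!/usr/bin/env python
"""Generate the synthetic hybrid transcriptome used by the downstream steps.

Builds a catalogue of 800 A:B homeolog pairs at 7% nucleotide divergence,
8 two-member 100%-identity gene groups and 40 singletons, then simulates
negative-binomial counts for a 2-condition x 2-time-point x 3-replicate
design (one control replicate dropped, mirroring a discarded low-depth
library).  Control ratios are drawn at beta concentration 60, stress at 12,
so homeolog expression divergence widens under stress by construction.

Writes catalogue, design, counts and the truth table to results/analysis/.
"""

from pathlib import Path

import homeologdiv as hd

OUT = Path("results/analysis")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cat = hd.build_catalogue(
        n_pairs=800, n_identity_groups=8, group_size=2, n_singletons=40,
        divergence=0.07, length_sampler=(600, 2400), seed=SEED)
    design = hd.SimulationDesign(
        library_size=2e6, nb_dispersion=0.05, seed=SEED,
        drop_control_replicate=True, frac_condition_specific=0.01)
    counts, truth = hd.simulate_counts(cat, design)

    cat.to_annotation_tsv(OUT / "catalogue.tsv")
    design.samples().to_csv(OUT / "design.tsv", sep="\t")
    counts.rename_axis("gene_id").to_csv(OUT / "counts_full.tsv", sep="\t")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)

    print(f"catalogue: {len(cat.genes)} genes "
          f"({len(cat.pairs)} pairs, {len(cat.identity_groups)} identity "
          f"groups, 40 singletons)")
    print(f"design: {len(design.samples())} samples "
          f"(one control_t18 replicate dropped)")
    print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples, "
          f"median library {int(counts.sum().median()):,} fragments")
    print(f"wrote catalogue/design/counts/truth under {OUT}/")


if __name__ == "__main__":
    main()
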