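#!/usr/bin/env python
"""Demonstrate stringent exact-match counting on simulated reads.

On a small hybrid catalogue (60 pairs, 4 identity groups), simulates 100-nt
fragments with 0.5% per-base error, assigns them by zero-mismatch
full-length matching, and tallies the four-way read partition: uniquely
assigned reads feed the per-gene "full" counts, multimappers confined to a
100%-identity group feed the pooled "duplicated" counts, boundary-crossing
multimappers are discarded, and reads broken by sequencing error go
unaligned.  At 7% homeolog divergence nearly every error-free 100-mer is
diagnostic for its gene, so unique assignment dominates; identity-group
members by construction yield no unique reads at all.

Writes the per-sample partition audit and both count flavors.
"""

from pathlib import Path

import pandas as pd

import homeologdiv as hd
from homeologdiv.simulate import substream

OUT = Path("results/analysis")
SEED = 2


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cat = hd.build_catalogue(n_pairs=60, n_identity_groups=4, group_size=2,
                             n_singletons=6, divergence=0.07,
                             length_sampler=900, seed=SEED)
    design = hd.SimulationDesign(
        timepoints=("t18",), library_size=30_000, nb_dispersion=0.05,
        seed=SEED)
    expected, _ = hd.simulate_counts(cat, design)

    index = hd.index_transcripts(cat, read_length=100)
    gids = [cat.group_id(i) for i in range(len(cat.identity_groups))]
    rng_reads = substream(SEED, "reads")
    rng_assign = substream(SEED, "assignment")
    full, dup, audit = {}, {}, []
    for sample in expected.columns:
        reads = hd.simulate_reads(cat, expected[sample], 100,
                                  error_rate=0.005,
                                  seed=int(rng_reads.integers(0, 2**31)))
        hitsets = hd.assign_reads(reads, index,
                                  seed=int(rng_assign.integers(0, 2**31)))
        full[sample] = hd.count_full(hitsets, cat)
        dup[sample] = hd.count_duplicated(hitsets, cat.identity_groups, gids)
        audit.append({"sample_id": sample,
                      **hd.partition_reads(hitsets, cat.identity_groups)})
    audit = pd.DataFrame(audit).set_index("sample_id")
    full = pd.DataFrame(full)
    dup = pd.DataFrame(dup)

    audit.to_csv(OUT / "read_partition_audit.tsv", sep="\t")
    full.rename_axis("gene_id").to_csv(OUT / "reads_counts_full.tsv", sep="\t")
    dup.rename_axis("group_id").to_csv(OUT / "reads_counts_duplicated.tsv",
                                       sep="\t")

    tot = audit.sum()
    n = tot.sum()
    print(f"{n:,} reads across {len(audit)} samples:")
    for k in ("unique", "within_group", "discarded", "unaligned"):
        print(f"  {k:>13}: {tot[k]:>7,} ({100 * tot[k] / n:.1f}%)")
    members = [m for grp in cat.identity_groups for m in grp]
    assert (full.loc[members] == 0).all().all()
    print("identity-group members received 0 unique ('full') counts, "
          "as forced by exact duplication")
    print(f"wrote audit and counts under {OUT}/")


if __name__ == "__main__":
    main()
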