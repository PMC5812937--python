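"""Hybrid gene catalogue: the gene universe of an allopolyploid transcriptome.

An interspecies hybrid carries two parental subgenomes (tagged ``A`` and
``B``); most genes exist as an A:B homeolog pair diverged in nucleotide
sequence (about 7% for the hybrid yeast this package models).  Loss of
heterozygosity after hybridization additionally produces groups of genes
with 100% sequence identity (A:A or B:B pairs), which no exact-match read
assignment can tell apart, plus unpaired singletons (tag ``N``).

:class:`HybridCatalogue` holds this structure; :func:`build_catalogue`
generates a synthetic one with controlled pair divergence so that the
whole counting-and-ratio analysis is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = np.array(list("ACGT"))

__all__ = ["GeneModel", "HybridCatalogue", "build_catalogue"]


@dataclass
class GeneModel:
    """One gene: id, parental subgenome tag, length and (optional) sequence."""

    gene_id: str
    subgenome: str  # one of A, B, N
    length_bp: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.subgenome not in ("A", "B", "N"):
            raise ValueError(f"subgenome must be A, B or N, got {self.subgenome!r}")
        if self.length_bp <= 0:
            raise ValueError(f"gene {self.gene_id}: length_bp must be positive")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise ValueError(
                f"gene {self.gene_id}: length_bp={self.length_bp} != "
                f"len(sequence)={len(self.sequence)}"
            )


@dataclass
class HybridCatalogue:
    """Gene universe with homeolog pairing and 100%-identity group structure.

    Attributes
    ----------
    genes
        All gene models, unique ids.
    pairs
        ``(gene_id_A, gene_id_B)`` homeolog pairs; first member is the A copy.
    identity_groups
        Lists of gene ids with byte-identical sequences (composite signal
        under exact-match counting).  Disjoint from each other and from pairs.
    """

    genes: list[GeneModel] = field(default_factory=list)
    pairs: list[tuple[str, str]] = field(default_factory=list)
    identity_groups: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- access helpers -------------------------------------------------
    @property
    def gene_map(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def lengths(self) -> pd.Series:
        return pd.Series({g.gene_id: g.length_bp for g in self.genes}, name="length_bp")

    def group_id(self, index: int) -> str:
        return f"IDG{index + 1:04d}"

    def group_map(self) -> dict[str, str]:
        """gene_id -> identity group label."""
        out: dict[str, str] = {}
        for i, members in enumerate(self.identity_groups):
            for gid in members:
                out[gid] = self.group_id(i)
        return out

    def has_sequences(self) -> bool:
        return all(g.sequence is not None for g in self.genes)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        known = set(ids)
        seen_in_pair: set[str] = set()
        gmap = {g.gene_id: g for g in self.genes}
        for a, b in self.pairs:
            for gid in (a, b):
                if gid not in known:
                    raise ValueError(f"pair references unknown gene {gid!r}")
                if gid in seen_in_pair:
                    raise ValueError(f"gene {gid!r} appears in more than one pair")
                seen_in_pair.add(gid)
            if (gmap[a].subgenome, gmap[b].subgenome) != ("A", "B"):
                raise ValueError(f"pair ({a}, {b}) must have subgenomes (A, B)")
        seen_in_group: set[str] = set()
        for members in self.identity_groups:
            if len(members) < 2:
                raise ValueError("identity groups need at least 2 members")
            for gid in members:
                if gid not in known:
                    raise ValueError(f"identity group references unknown gene {gid!r}")
                if gid in seen_in_group:
                    raise ValueError(f"gene {gid!r} in more than one identity group")
                seen_in_group.add(gid)
            seqs = {gmap[gid].sequence for gid in members}
            if len(seqs) > 1:
                raise ValueError(
                    f"identity group {members} members are not byte-identical"
                )

    # -- IO ---------------------------------------------------------------
    def to_fasta(self, path: str | Path) -> None:
        if not self.has_sequences():
            raise ValueError("catalogue has sequence-free genes; cannot write FASTA")
        records = [
            SeqRecord(Seq(g.sequence), id=g.gene_id, description="")
            for g in self.genes
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_annotation_tsv(self, path: str | Path) -> None:
        pair_of: dict[str, str] = {}
        for i, (a, b) in enumerate(self.pairs):
            pair_of[a] = pair_of[b] = f"PAIR{i + 1:05d}"
        grp = self.group_map()
        rows = [
            {
                "gene_id": g.gene_id,
                "subgenome": g.subgenome,
                "length_bp": g.length_bp,
                "pair_id": pair_of.get(g.gene_id, ""),
                "identity_group_id": grp.get(g.gene_id, ""),
            }
            for g in self.genes
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_files(
        cls, annotation_tsv: str | Path, fasta: str | Path | None = None
    ) -> "HybridCatalogue":
        """Rebuild a catalogue from its annotation TSV (and optional FASTA)."""
        ann = pd.read_csv(annotation_tsv, sep="\t", dtype={"gene_id": str})
        seqs: dict[str, str] = {}
        if fasta is not None:
            seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta), "fasta")}
        genes = [
            GeneModel(
                gene_id=row.gene_id,
                subgenome=row.subgenome,
                length_bp=int(row.length_bp),
                sequence=seqs.get(row.gene_id),
            )
            for row in ann.itertuples()
        ]
        pairs = []
        if "pair_id" in ann.columns:
            by_pair = ann[ann.pair_id.notna() & (ann.pair_id != "")].groupby("pair_id")
            for _, sub in sorted(by_pair, key=lambda kv: kv[0]):
                sub = sub.sort_values("subgenome")
                if len(sub) != 2:
                    raise ValueError(
                        f"pair {sub.pair_id.iloc[0]!r} has {len(sub)} members"
                    )
                pairs.append((sub.gene_id.iloc[0], sub.gene_id.iloc[1]))
        groups: list[list[str]] = []
        if "identity_group_id" in ann.columns:
            mask = ann.identity_group_id.notna() & (ann.identity_group_id != "")
            for _, sub in sorted(ann[mask].groupby("identity_group_id"),
                                 key=lambda kv: kv[0]):
                groups.append(list(sub.gene_id))
        return cls(genes=genes, pairs=pairs, identity_groups=groups)


def _sample_lengths(
    length_sampler: int | tuple[int, int] | Callable[[np.random.Generator, int], np.ndarray],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Resolve a length specifier: constant, uniform (lo, hi) range, or callable."""
    if isinstance(length_sampler, int):
        return np.full(n, length_sampler, dtype=int)
    if isinstance(length_sampler, tuple):
        lo, hi = length_sampler
        return rng.integers(lo, hi + 1, size=n)
    return np.asarray(length_sampler(rng, n), dtype=int)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-site substitution at `rate`, always to a different base.

    No indels and no back-mutation, so the observed mismatch fraction
    between original and mutant equals the realized substitution fraction.
    """
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        idx = np.flatnonzero(hit)
        # offset 1..3 in base order guarantees a different base
        cur = np.searchsorted(BASES, arr[idx])
        arr[idx] = BASES[(cur + rng.integers(1, 4, size=idx.size)) % 4]
    return "".join(arr)


def build_catalogue(
    n_pairs: int,
    n_identity_groups: int = 0,
    group_size: int = 2,
    n_singletons: int = 0,
    divergence: float = 0.07,
    length_sampler: int | tuple[int, int] | Callable = 1500,
    seed: int = 0,
) -> HybridCatalogue:
    """Generate a synthetic hybrid gene catalogue.

    Each homeolog pair is built by drawing the A sequence uniformly over
    ACGT and deriving the B copy by per-site substitution at rate
    ``divergence``.  Identity-group members share one byte-identical
    sequence; singletons are unpaired ``_N`` genes.

    Parameters
    ----------
    n_pairs
        Number of A:B homeolog pairs.
    n_identity_groups, group_size
        Number and size of 100%-identity gene groups.
    n_singletons
        Unpaired genes outside any group.
    divergence
        Expected per-site A-vs-B substitution fraction in [0, 1].
    length_sampler
        Gene length in bp: a constant, a ``(lo, hi)`` uniform range, or a
        callable ``(rng, n) -> lengths``.
    seed
        Seeds all sequence generation; fixed seed gives a byte-identical
        catalogue.
    """
    if n_pairs < 0 or n_identity_groups < 0 or n_singletons < 0:
        raise ValueError("gene counts must be nonnegative")
    if group_size < 2 and n_identity_groups > 0:
        raise ValueError("group_size must be >= 2")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence must be in [0, 1], got {divergence}")

    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    pairs: list[tuple[str, str]] = []
    groups: list[list[str]] = []

    pair_lengths = _sample_lengths(length_sampler, n_pairs, rng)
    for i in range(n_pairs):
        length = int(pair_lengths[i])
        seq_a = _random_sequence(rng, length)
        seq_b = _mutate(rng, seq_a, divergence)
        ida, idb = f"P{i + 1:05d}_A", f"P{i + 1:05d}_B"
        genes.append(GeneModel(ida, "A", length, seq_a))
        genes.append(GeneModel(idb, "B", length, seq_b))
        pairs.append((ida, idb))

    group_lengths = _sample_lengths(length_sampler, n_identity_groups, rng)
    for i in range(n_identity_groups):
        length = int(group_lengths[i])
        seq = _random_sequence(rng, length)
        members = []
        for m in range(group_size):
            gid = f"G{i + 1:04d}M{m + 1}_A"
            genes.append(GeneModel(gid, "A", length, seq))
            members.append(gid)
        groups.append(members)

    single_lengths = _sample_lengths(length_sampler, n_singletons, rng)
    for i in range(n_singletons):
        length = int(single_lengths[i])
        genes.append(GeneModel(f"S{i + 1:05d}_N", "N", length,
                               _random_sequence(rng, length)))

    return HybridCatalogue(genes=genes, pairs=pairs, identity_groups=groups)


def observed_pair_divergence(catalogue: HybridCatalogue) -> float:
    """Mean mismatch fraction over all homeolog pairs (equal-length pairs)."""
    gmap = catalogue.gene_map
    mism = total = 0
    for a, b in catalogue.pairs:
        sa, sb = gmap[a].sequence, gmap[b].sequence
        if sa is None or sb is None:
            raise ValueError("sequences required to measure divergence")
        mism += sum(x != y for x, y in zip(sa, sb))
        total += len(sa)
    if total == 0:
        raise ValueError("catalogue has no pairs")
    return mism / total
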