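"""Stringent read-to-gene assignment and dual-flavor counting.

Emulates a zero-mismatch alignment policy at the transcript level: a read is
assigned to every gene that contains it as an exact, full-length substring.
Reads with exactly one hit feed the "full" per-gene counts; reads whose whole
hit set falls inside one 100%-identity gene group feed the pooled
"duplicated" per-group counts; multimappers that straddle a group boundary
are discarded; reads matching nothing are unaligned.  Every read lands in
exactly one of those four classes.

A random best hit (``chosen``) is recorded per multimapper to mirror the
single-reported-alignment convention of short-read aligners, but counting
never uses it, so counts are seed-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalogue import HybridCatalogue
from .simulate import ReadRecord

__all__ = [
    "HitSet",
    "ExactMatchIndex",
    "index_transcripts",
    "assign_reads",
    "count_full",
    "count_duplicated",
    "partition_reads",
    "write_sam_like",
]

PARTITIONS = ("unique", "within_group", "discarded", "unaligned")


@dataclass
class HitSet:
    """Exact-match hits of one read; ``chosen`` is the reported alignment."""

    read_id: str
    hits: frozenset[str]
    chosen: str | None
    multimapped: bool


class ExactMatchIndex:
    """Seed-and-verify exact substring index over gene sequences.

    A prefix k-mer (k = min(read_length, 31)) narrows the candidate genes;
    each candidate is then verified by full-length substring containment,
    so results equal a brute-force scan over all genes.
    """

    def __init__(self, catalogue: HybridCatalogue, read_length: int):
        if read_length < 1:
            raise ValueError("read_length must be >= 1")
        missing = [g.gene_id for g in catalogue.genes if g.sequence is None]
        if missing:
            raise ValueError(f"genes without sequences: {missing[:5]}")
        self.read_length = read_length
        self.k = min(read_length, 31)
        self.sequences = {g.gene_id: g.sequence for g in catalogue.genes}
        self._seeds: dict[str, set[str]] = {}
        for gid, seq in self.sequences.items():
            for i in range(len(seq) - self.k + 1):
                self._seeds.setdefault(seq[i:i + self.k], set()).add(gid)

    def query(self, read: str) -> frozenset[str]:
        """Genes containing ``read`` as an exact full-length substring."""
        if len(read) != self.read_length:
            raise ValueError(
                f"query length {len(read)} != index read_length {self.read_length}"
            )
        candidates = self._seeds.get(read[: self.k])
        if not candidates:
            return frozenset()
        return frozenset(g for g in candidates if read in self.sequences[g])


def index_transcripts(catalogue: HybridCatalogue, read_length: int) -> ExactMatchIndex:
    return ExactMatchIndex(catalogue, read_length)


def assign_reads(
    reads: Sequence[ReadRecord], index: ExactMatchIndex, seed: int = 0
) -> list[HitSet]:
    """Assign each read to its exact-match hit set.

    A read with two or more hits is multimapped and gets one hit ``chosen``
    uniformly at random (seeded); a read with no exact match is unaligned
    (empty hit set, no chosen gene).
    """
    rng = np.random.default_rng(seed)
    out = []
    for r in reads:
        hits = index.query(r.sequence)
        if not hits:
            out.append(HitSet(r.read_id, hits, None, False))
        elif len(hits) == 1:
            (only,) = hits
            out.append(HitSet(r.read_id, hits, only, False))
        else:
            ordered = sorted(hits)
            chosen = ordered[rng.integers(0, len(ordered))]
            out.append(HitSet(r.read_id, hits, chosen, True))
    return out


def count_full(
    hitsets: Iterable[HitSet], catalogue: HybridCatalogue
) -> pd.Series:
    """Per-gene counts from uniquely assigned reads only (one sample)."""
    counts = dict.fromkeys(catalogue.gene_ids, 0)
    for h in hitsets:
        if len(h.hits) == 1:
            (g,) = h.hits
            counts[g] += 1
    return pd.Series(counts, name="count", dtype=np.int64)


def count_duplicated(
    hitsets: Iterable[HitSet],
    identity_groups: Sequence[Sequence[str]],
    group_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Pooled per-group counts of multimappers confined to one identity group.

    A multimapped read counts toward group G iff its entire hit set is a
    subset of G; multimappers touching genes outside any single group are
    discarded.  Unique reads never contribute (they belong to full counts).
    """
    seen: set[str] = set()
    for grp in identity_groups:
        for gid in grp:
            if gid in seen:
                raise ValueError(f"identity groups overlap at gene {gid!r}")
            seen.add(gid)
    if group_ids is None:
        group_ids = [f"IDG{i + 1:04d}" for i in range(len(identity_groups))]
    member_sets = [set(g) for g in identity_groups]
    counts = dict.fromkeys(group_ids, 0)
    for h in hitsets:
        if not h.multimapped:
            continue
        for gid_label, members in zip(group_ids, member_sets):
            if h.hits <= members:
                counts[gid_label] += 1
                break
    return pd.Series(counts, name="count", dtype=np.int64)


def partition_reads(
    hitsets: Iterable[HitSet], identity_groups: Sequence[Sequence[str]]
) -> pd.Series:
    """Classify every read as unique / within_group / discarded / unaligned."""
    member_sets = [set(g) for g in identity_groups]
    tally = dict.fromkeys(PARTITIONS, 0)
    for h in hitsets:
        if not h.hits:
            tally["unaligned"] += 1
        elif len(h.hits) == 1:
            tally["unique"] += 1
        elif any(h.hits <= m for m in member_sets):
            tally["within_group"] += 1
        else:
            tally["discarded"] += 1
    return pd.Series(tally, dtype=np.int64)


def write_sam_like(hitsets: Iterable[HitSet], path: str | Path) -> None:
    """TSV dump mirroring the aligner's reporting convention: the chosen
    gene, MAPQ 0 with an ``XM:i:2`` tag for multimappers, MAPQ 255 for
    unique hits, ``*`` for unaligned reads."""
    rows = []
    for h in hitsets:
        rows.append({
            "read_id": h.read_id,
            "gene": h.chosen if h.chosen is not None else "*",
            "mapq": 0 if h.multimapped else (255 if h.hits else 0),
            "tags": "XM:i:2" if h.multimapped else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def brute_force_hits(read: str, catalogue: HybridCatalogue) -> frozenset[str]:
    """Reference substring scan over every gene (oracle for the index)."""
    return frozenset(
        g.gene_id for g in catalogue.genes
        if g.sequence is not None and read in g.sequence
    )
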