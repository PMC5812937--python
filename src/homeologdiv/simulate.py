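"""Simulation of hybrid RNA-seq data: homeolog expression ratios, negative-
binomial count matrices, and (optionally) raw reads.

The generative model mirrors the structure of a two-condition, two-time-point
bulk RNA-seq experiment on a hybrid yeast.  Each homeolog pair p receives a
total abundance and, per sample group g = (condition, timepoint), an A-share
ratio r_pg ~ Beta(c_g * m, c_g * (1 - m)) where c_g is the condition's
concentration and m the mean bias (0.5 = no subgenome preference).  A smaller
concentration gives a wider ratio distribution — the signature of expression
divergence under stress.  Gene-level expected counts are proportional to
abundance x share x gene length, scaled to the target library size, and drawn
negative-binomially with variance mu + dispersion * mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalogue import BASES, HybridCatalogue

__all__ = [
    "RatioModel",
    "SimulationDesign",
    "ReadRecord",
    "draw_pair_ratios",
    "simulate_counts",
    "simulate_reads",
    "write_reads",
]

# substream tags so each stochastic stage draws from an independent stream
# derived from the one root seed
_STREAMS = {"catalogue": 1, "ratios": 2, "abundance": 3, "counts": 4,
            "reads": 5, "assignment": 6}


def substream(seed: int, name: str, extra: Sequence[int] = ()) -> np.random.Generator:
    """Independent generator for a named stage under one root seed."""
    return np.random.default_rng([int(seed), _STREAMS[name], *map(int, extra)])


@dataclass
class RatioModel:
    """Beta model for the per-pair A/(A+B) expression share.

    ``balanced_concentration`` applies under the control condition,
    ``stress_concentration`` under stress; smaller concentration = wider
    spread of ratios.  ``mean_bias`` shifts the distribution mean away
    from 0.5 (towards the A subgenome when > 0.5).
    """

    balanced_concentration: float = 60.0
    stress_concentration: float = 12.0
    mean_bias: float = 0.5

    def __post_init__(self) -> None:
        if self.balanced_concentration <= 0 or self.stress_concentration <= 0:
            raise ValueError("beta concentrations must be > 0")
        if not 0.0 < self.mean_bias < 1.0:
            raise ValueError("mean_bias must be in (0, 1)")

    def concentration(self, condition: str) -> float:
        return (self.stress_concentration if condition == "stress"
                else self.balanced_concentration)


@dataclass
class SimulationDesign:
    """Experimental layout and count-model parameters for one simulation."""

    conditions: tuple[str, ...] = ("control", "stress")
    timepoints: tuple[str, ...] = ("t18", "t42")
    replicates_per_group: int = 3
    library_size: float = 2e6
    nb_dispersion: float = 0.05
    ratio_model: RatioModel = field(default_factory=RatioModel)
    seed: int = 0
    drop_control_replicate: bool = False  # mirrors a discarded low-depth library
    frac_condition_specific: float = 0.0  # per condition, zero abundance elsewhere

    def __post_init__(self) -> None:
        if not self.conditions or not self.timepoints:
            raise ValueError("conditions and timepoints must be nonempty")
        if self.replicates_per_group < 1:
            raise ValueError("replicates_per_group must be >= 1")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be nonnegative")
        if not 0.0 <= self.frac_condition_specific < 0.5:
            raise ValueError("frac_condition_specific must be in [0, 0.5)")

    def samples(self) -> pd.DataFrame:
        """Sample sheet: sample_id -> (condition, timepoint, replicate)."""
        rows = []
        for cond in self.conditions:
            for tp in self.timepoints:
                for rep in range(1, self.replicates_per_group + 1):
                    rows.append({
                        "sample_id": f"{cond}_{tp}_r{rep}",
                        "condition": cond,
                        "timepoint": tp,
                        "replicate": rep,
                    })
        design = pd.DataFrame(rows).set_index("sample_id")
        if self.drop_control_replicate:
            victim = (f"{self.conditions[0]}_{self.timepoints[0]}_"
                      f"r{self.replicates_per_group}")
            design = design.drop(index=victim)
        return design

    def groups(self) -> list[tuple[str, str]]:
        return [(c, t) for c in self.conditions for t in self.timepoints]


@dataclass
class ReadRecord:
    """One simulated fragment with its truth label."""

    read_id: str
    sequence: str
    origin_gene: str


def draw_pair_ratios(
    n_pairs: int, condition: str, model: RatioModel, seed: int
) -> np.ndarray:
    """Draw i.i.d. Beta(c*m, c*(1-m)) A-share ratios for one condition."""
    if n_pairs < 0:
        raise ValueError("n_pairs must be nonnegative")
    c = model.concentration(condition)
    m = model.mean_bias
    rng = np.random.default_rng(seed)
    return rng.beta(c * m, c * (1.0 - m), size=n_pairs)


def _draw_counts(rng: np.random.Generator, mu: np.ndarray,
                 dispersion: float) -> np.ndarray:
    """NB counts with var = mu + dispersion*mu^2; dispersion 0 is the
    deterministic limit (rounded expectations)."""
    if dispersion == 0:
        return np.rint(mu).astype(np.int64)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + np.maximum(mu, 1e-300))
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(size_param, p[pos])
    return out


def simulate_counts(
    catalogue: HybridCatalogue, design: SimulationDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x samples count matrix plus its truth table.

    Returns
    -------
    counts
        Integer DataFrame, rows = gene ids, columns = sample ids.
    truth
        One row per (pair, condition, timepoint) with the drawn A-share
        ratio, plus per-gene condition-specificity labels recorded in the
        ``specific_to`` column of the attached attrs (see ``truth.attrs``).
    """
    if not catalogue.genes:
        raise ValueError("catalogue is empty")
    design_df = design.samples()
    gene_ids = catalogue.gene_ids
    gmap = catalogue.gene_map
    lengths = np.array([gmap[g].length_bp for g in gene_ids], dtype=float)
    gpos = {g: i for i, g in enumerate(gene_ids)}

    n_pairs = len(catalogue.pairs)
    # per-pair / per-unpaired-gene abundance: lognormal, fixed across samples
    rng_ab = substream(design.seed, "abundance")
    pair_abund = rng_ab.lognormal(mean=0.0, sigma=1.0, size=n_pairs)
    unpaired = [g for g in gene_ids
                if g not in {x for p in catalogue.pairs for x in p}]
    unpaired_abund = dict(zip(unpaired,
                              rng_ab.lognormal(0.0, 1.0, size=len(unpaired))))

    # condition-specific genes: zero abundance outside their condition
    specific_to: dict[str, str] = {}
    if design.frac_condition_specific > 0:
        flat = list(gene_ids)
        n_spec = int(round(design.frac_condition_specific * len(flat)))
        chosen = rng_ab.choice(len(flat), size=min(2 * n_spec, len(flat)),
                               replace=False)
        for j, gi in enumerate(chosen):
            specific_to[flat[gi]] = design.conditions[j % len(design.conditions)]

    # per-group ratios
    truth_rows = []
    ratios_by_group: dict[tuple[str, str], np.ndarray] = {}
    for cond, tp in design.groups():
        rg = substream(design.seed, "ratios",
                       (design.conditions.index(cond),
                        design.timepoints.index(tp)))
        r = draw_pair_ratios(n_pairs, cond, design.ratio_model,
                             seed=rg.integers(0, 2**31))
        ratios_by_group[(cond, tp)] = r
        for i, (a, b) in enumerate(catalogue.pairs):
            truth_rows.append({
                "pair_id": f"PAIR{i + 1:05d}", "gene_id_A": a, "gene_id_B": b,
                "condition": cond, "timepoint": tp, "true_ratio": r[i],
                "pair_abundance": pair_abund[i],
            })
    truth = pd.DataFrame(truth_rows)
    truth.attrs["specific_to"] = specific_to

    counts = np.zeros((len(gene_ids), len(design_df)), dtype=np.int64)
    rng_counts = substream(design.seed, "counts")
    for s, (sample_id, row) in enumerate(design_df.iterrows()):
        cond, tp = row["condition"], row["timepoint"]
        r = ratios_by_group[(cond, tp)]
        weight = np.zeros(len(gene_ids))
        for i, (a, b) in enumerate(catalogue.pairs):
            weight[gpos[a]] = pair_abund[i] * r[i] * lengths[gpos[a]]
            weight[gpos[b]] = pair_abund[i] * (1.0 - r[i]) * lengths[gpos[b]]
        for g in unpaired:
            weight[gpos[g]] = unpaired_abund[g] * lengths[gpos[g]]
        for g, only in specific_to.items():
            if only != cond:
                weight[gpos[g]] = 0.0
        total = weight.sum()
        if total <= 0:
            raise ValueError("all expected abundances are zero")
        mu = weight / total * design.library_size
        counts[:, s] = _draw_counts(rng_counts, mu, design.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=design_df.index)
    counts_df.attrs["flavor"] = "full"
    return counts_df, truth


def simulate_reads(
    catalogue: HybridCatalogue,
    expression: Mapping[str, int] | pd.Series,
    read_length: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[ReadRecord]:
    """Draw single-fragment reads: uniform start positions, substitution
    errors at ``error_rate`` per base, truth label retained.

    ``expression`` maps gene id -> number of fragments to draw.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    gmap = catalogue.gene_map
    if isinstance(expression, pd.Series):
        expression = expression.to_dict()
    for gid, n in expression.items():
        if n > 0:
            gene = gmap.get(gid)
            if gene is None:
                raise ValueError(f"unknown gene {gid!r} in expression table")
            if gene.sequence is None:
                raise ValueError(f"gene {gid!r} has no sequence")
            if read_length > gene.length_bp:
                raise ValueError(
                    f"read_length {read_length} exceeds length of gene {gid!r} "
                    f"({gene.length_bp} bp)"
                )
    rng = np.random.default_rng(seed)
    reads: list[ReadRecord] = []
    counter = 0
    for gid in sorted(expression):  # deterministic order
        n = int(expression[gid])
        if n <= 0:
            continue
        seq = gmap[gid].sequence
        starts = rng.integers(0, len(seq) - read_length + 1, size=n)
        for st in starts:
            frag = seq[st:st + read_length]
            if error_rate > 0:
                hit = rng.random(read_length) < error_rate
                if hit.any():
                    arr = np.array(list(frag))
                    idx = np.flatnonzero(hit)
                    cur = np.searchsorted(BASES, arr[idx])
                    arr[idx] = BASES[(cur + rng.integers(1, 4, size=idx.size)) % 4]
                    frag = "".join(arr)
            counter += 1
            reads.append(ReadRecord(f"read{counter:07d}:{gid}", frag, gid))
    return reads


def write_reads(reads: Sequence[ReadRecord], path: str | Path,
                fmt: str = "fastq") -> None:
    """Write reads as FASTA or FASTQ (constant Phred-40 qualities)."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), fmt)


def read_reads(path: str | Path, fmt: str | None = None) -> list[ReadRecord]:
    """Load reads from FASTA/FASTQ; the truth label (if any) follows the
    colon in the read id and is otherwise empty."""
    p = Path(path)
    if fmt is None:
        fmt = "fastq" if p.suffix.lower() in (".fastq", ".fq") else "fasta"
    out = []
    for rec in SeqIO.parse(str(p), fmt):
        origin = rec.id.split(":", 1)[1] if ":" in rec.id else ""
        out.append(ReadRecord(rec.id, str(rec.seq), origin))
    return out
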