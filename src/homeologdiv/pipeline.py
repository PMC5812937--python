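"""End-to-end pipeline: simulate -> count -> normalize -> ratios -> report.

One root seed drives named substreams for every stochastic stage, so an
identical config + seed reproduces every intermediate byte for byte.  All
intermediates (catalogue, design, counts, truth, factors, CPM/RPKM, ratio
table, group summaries) are persisted as TSV/JSON under the configured
output directory, and the machine-readable run report contains only numbers
recomputable from those files.

Two entry modes exist: ``counts`` (the count-level shortcut: negative-
binomial matrices straight from the generator, so the statistical stages run
in milliseconds) and ``reads`` (fragment simulation, exact-match assignment
and dual-flavor counting before normalization).  User-supplied count
matrices enter at the normalize stage via :func:`load_user_counts`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assign import (assign_reads, count_duplicated, count_full,
                     index_transcripts, partition_reads)
from .catalogue import HybridCatalogue, build_catalogue
from .normalize import category_counts, flag_expression, normalize_counts
from .ratios import (build_ratio_table, summarize_ratio_table,
                     variance_divergence_test)
from .simulate import (RatioModel, SimulationDesign, simulate_counts,
                       simulate_reads, substream, write_reads)

__all__ = ["RunConfig", "run_pipeline", "load_user_counts", "load_config"]


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``load_config`` for YAML)."""

    seed: int = 0
    output_dir: str = "results/run"
    mode: str = "counts"  # counts | reads
    simulate: dict = field(default_factory=dict)
    normalize: dict = field(default_factory=dict)
    ratios: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "reads"):
            raise ValueError(f"mode must be 'counts' or 'reads', got {self.mode!r}")

    def design(self) -> SimulationDesign:
        s = self.simulate
        model = RatioModel(
            balanced_concentration=s.get("balanced_concentration", 60.0),
            stress_concentration=s.get("stress_concentration", 12.0),
            mean_bias=s.get("mean_bias", 0.5),
        )
        return SimulationDesign(
            conditions=tuple(s.get("conditions", ("control", "stress"))),
            timepoints=tuple(s.get("timepoints", ("t18", "t42"))),
            replicates_per_group=s.get("replicates_per_group", 3),
            library_size=s.get("library_size", 2e6),
            nb_dispersion=s.get("nb_dispersion", 0.05),
            ratio_model=model,
            seed=self.seed,
            drop_control_replicate=s.get("drop_control_replicate", False),
            frac_condition_specific=s.get("frac_condition_specific", 0.0),
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(
        seed=raw.get("seed", 0),
        output_dir=raw.get("output_dir", "results/run"),
        mode=raw.get("mode", "counts"),
        simulate=raw.get("simulate", {}) or {},
        normalize=raw.get("normalize", {}) or {},
        ratios=raw.get("ratios", {}) or {},
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None):
    df.to_csv(path, sep="\t", index=index_label is not None,
              index_label=index_label, float_format="%.10g")


def _simulate_stage(cfg: RunConfig, out: Path):
    s = cfg.simulate
    length = s.get("gene_length", 1500)
    if isinstance(length, list):
        length = tuple(length)
    cat = build_catalogue(
        n_pairs=s.get("n_pairs", 2000),
        n_identity_groups=s.get("n_identity_groups", 0),
        group_size=s.get("group_size", 2),
        n_singletons=s.get("n_singletons", 0),
        divergence=s.get("divergence", 0.07),
        length_sampler=length,
        seed=int(substream(cfg.seed, "catalogue").integers(0, 2**31)),
    )
    design = cfg.design()
    counts, truth = simulate_counts(cat, design)
    cat.to_annotation_tsv(out / "catalogue.tsv")
    if cfg.mode == "reads":
        cat.to_fasta(out / "catalogue.fasta")
    _write_tsv(design.samples(), out / "design.tsv", index_label="sample_id")
    _write_tsv(truth.drop(columns=[], errors="ignore"), out / "truth.tsv")
    return cat, design, counts, truth


def _count_stage(cfg: RunConfig, cat: HybridCatalogue, design: SimulationDesign,
                 expected_counts: pd.DataFrame, out: Path):
    """Reads mode: simulate fragments per sample, assign, count both flavors."""
    read_length = cfg.simulate.get("read_length", 100)
    error_rate = cfg.simulate.get("error_rate", 0.0)
    index = index_transcripts(cat, read_length)
    group_map = cat.group_map()
    group_ids = [cat.group_id(i) for i in range(len(cat.identity_groups))]
    full_cols, dup_cols, audit_rows = {}, {}, []
    rng_reads = substream(cfg.seed, "reads")
    rng_assign = substream(cfg.seed, "assignment")
    for sample_id in expected_counts.columns:
        reads = simulate_reads(
            cat, expected_counts[sample_id], read_length=read_length,
            error_rate=error_rate,
            seed=int(rng_reads.integers(0, 2**31)),
        )
        write_reads(reads, out / f"reads_{sample_id}.fastq", "fastq")
        hitsets = assign_reads(reads, index,
                               seed=int(rng_assign.integers(0, 2**31)))
        full_cols[sample_id] = count_full(hitsets, cat)
        dup_cols[sample_id] = count_duplicated(hitsets, cat.identity_groups,
                                               group_ids)
        part = partition_reads(hitsets, cat.identity_groups)
        audit_rows.append({"sample_id": sample_id, **part.to_dict(),
                           "total_reads": len(reads)})
    full = pd.DataFrame(full_cols)
    full.attrs["flavor"] = "full"
    dup = pd.DataFrame(dup_cols)
    dup.attrs["flavor"] = "duplicated"
    audit = pd.DataFrame(audit_rows)
    return full, dup, audit


def _pool_identity_groups(counts: pd.DataFrame, cat: HybridCatalogue) -> pd.DataFrame:
    """Counts-mode stand-in for duplicated counting: pool member counts."""
    rows = {}
    for i, members in enumerate(cat.identity_groups):
        rows[cat.group_id(i)] = counts.loc[members].sum(axis=0)
    dup = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=counts.columns)
    dup.attrs["flavor"] = "duplicated"
    return dup


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config": {
            "seed": cfg.seed, "mode": cfg.mode, "simulate": cfg.simulate,
            "normalize": cfg.normalize, "ratios": cfg.ratios,
        },
        "stages": {},
    }

    # -- simulate -------------------------------------------------------
    try:
        cat, design, sim_counts, truth = _simulate_stage(cfg, out)
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    report["stages"]["simulate"] = {
        "n_genes": len(cat.genes), "n_pairs": len(cat.pairs),
        "n_identity_groups": len(cat.identity_groups),
        "n_samples": int(sim_counts.shape[1]),
    }

    # -- count ----------------------------------------------------------
    if cfg.mode == "reads":
        # expected fragment counts per gene feed the read simulator
        full, dup, audit = _count_stage(cfg, cat, design, sim_counts, out)
        _write_tsv(audit, out / "read_partition_audit.tsv")
        report["stages"]["count"] = {
            "partition_totals": audit[list(audit.columns.drop("sample_id"))]
            .sum().astype(int).to_dict(),
        }
    else:
        full, dup = sim_counts, _pool_identity_groups(sim_counts, cat)
        report["stages"]["count"] = {"mode": "count-level shortcut"}
    _write_tsv(full, out / "counts_full.tsv", index_label="gene_id")
    (out / "counts_full.meta.json").write_text(
        json.dumps({"flavor": "full", "stage": "counts"}))
    if len(dup):
        _write_tsv(dup, out / "counts_duplicated.tsv", index_label="group_id")
        (out / "counts_duplicated.meta.json").write_text(
            json.dumps({"flavor": "duplicated", "stage": "counts"}))

    # -- normalize ------------------------------------------------------
    ncfg = cfg.normalize
    lengths = cat.lengths()
    try:
        norm = normalize_counts(
            full, lengths,
            use_effective_sizes=ncfg.get("use_effective_sizes", True))
    except Exception as exc:
        raise RuntimeError(f"stage 'normalize' failed: {exc}") from exc
    design_df = design.samples()
    evidence = flag_expression(
        norm.cpm, design_df,
        min_cpm=ncfg.get("min_cpm", 1.0),
        min_samples=ncfg.get("min_samples", 3),
        pool_timepoints=ncfg.get("pool_timepoints", True),
    )
    _write_tsv(norm.cpm, out / "cpm_full.tsv", index_label="gene_id")
    _write_tsv(norm.rpkm, out / "rpkm_full.tsv", index_label="gene_id")
    _write_tsv(evidence, out / "expression_evidence.tsv", index_label="gene_id")
    (out / "normalization.json").write_text(json.dumps({
        "flavor": "full",
        "tmm_factors": norm.tmm_factors.round(10).to_dict(),
        "effective_library_sizes":
            norm.effective_library_sizes.round(4).to_dict(),
    }, indent=1, sort_keys=True))
    report["stages"]["normalize"] = {
        "tmm_factors": norm.tmm_factors.round(6).to_dict(),
        "category_counts": category_counts(evidence).astype(int).to_dict(),
    }
    if len(dup):
        glens = pd.Series({cat.group_id(i): cat.gene_map[m[0]].length_bp
                           for i, m in enumerate(cat.identity_groups)})
        if (dup.sum(axis=0) > 0).all() and dup.shape[0] >= 2:
            norm_dup = normalize_counts(dup, glens)
            _write_tsv(norm_dup.rpkm, out / "rpkm_duplicated.tsv",
                       index_label="group_id")

    # -- ratios ---------------------------------------------------------
    rcfg = cfg.ratios
    thresholds = tuple(rcfg.get("thresholds", (0.4, 0.6)))
    try:
        rt = build_ratio_table(norm.rpkm, design_df, cat.pairs,
                               evidence=evidence, thresholds=thresholds)
    except Exception as exc:
        raise RuntimeError(f"stage 'ratios' failed: {exc}") from exc
    _write_tsv(rt.table, out / "ratio_table.tsv")
    summaries = summarize_ratio_table(
        rt.table, family_size=rcfg.get("family_size", 4),
        thresholds=thresholds)
    variance_tests = {}
    conds = list(design.conditions)
    if len(conds) == 2:
        for tp in design.timepoints:
            sub = rt.table[rt.table.timepoint == tp]
            x = sub[sub.condition == conds[0]]["ratio"].values
            y = sub[sub.condition == conds[1]]["ratio"].values
            stat, p = variance_divergence_test(x, y)
            variance_tests[tp] = {"statistic": stat, "p_value": p}
    hist = {}
    for s_ in summaries:
        sub = rt.table[(rt.table.condition + "_" + rt.table.timepoint) == s_.group]
        vals = sub["ratio"].dropna().values
        edges = np.linspace(0, 1, 21)
        hist[s_.group] = np.histogram(vals, bins=edges)[0].astype(int).tolist()
    report["stages"]["ratios"] = {
        "n_pairs_input": rt.n_pairs_input,
        "n_pairs_excluded_no_evidence": rt.n_pairs_excluded_no_evidence,
        "n_pairs_single_expressed": rt.n_pairs_single_expressed,
        "group_summaries": [s_.to_dict() for s_ in summaries],
        "variance_tests": variance_tests,
        "ratio_histograms_20bins": hist,
    }
    pd.DataFrame([s_.to_dict() for s_ in summaries]).to_csv(
        out / "group_summaries.tsv", sep="\t", index=False)

    # -- report ---------------------------------------------------------
    report["file_digests"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.suffix in (".tsv", ".json", ".fasta", ".fastq")
        and p.name != "report.json"
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=float))
    (out / "report.txt").write_text(_render_text_report(report))
    return report


def _render_text_report(report: dict) -> str:
    lines = [f"homeologdiv v{report['version']} run report", ""]
    sim = report["stages"]["simulate"]
    lines.append(f"catalogue: {sim['n_genes']} genes, {sim['n_pairs']} homeolog "
                 f"pairs, {sim['n_identity_groups']} identity groups")
    cats = report["stages"]["normalize"]["category_counts"]
    lines.append("expression categories: "
                 + ", ".join(f"{k}={v}" for k, v in cats.items()))
    lines.append("")
    lines.append("group\tn\tmean\tmedian\tsd\tskew\tAb\taB\tP(adj)\t%unbal")
    for s in report["stages"]["ratios"]["group_summaries"]:
        lines.append(
            f"{s['group']}\t{s['n_pairs']}\t{s['mean']:.3f}\t{s['median']:.3f}"
            f"\t{s['sd']:.3f}\t{s['skew']:.3f}\t{s['n_Ab']}\t{s['n_aB']}"
            f"\t{s['binom_p_adjusted']:.3g}\t{s['pct_unbalanced']:.1f}")
    lines.append("")
    for tp, t in report["stages"]["ratios"]["variance_tests"].items():
        lines.append(f"variance divergence {tp}: FK chi2={t['statistic']:.2f} "
                     f"P={t['p_value']:.3g}")
    return "\n".join(lines) + "\n"


def load_user_counts(
    counts_tsv: str | Path,
    annotation_tsv: str | Path,
    design_tsv: str | Path,
) -> tuple[pd.DataFrame, HybridCatalogue, pd.DataFrame]:
    """Validate and load a user count matrix for entry at the normalize stage.

    counts: genes x samples TSV with a ``gene_id`` first column; annotation:
    gene_id / subgenome / length_bp / pair_id / identity_group_id; design:
    sample_id / condition / timepoint / replicate.
    """
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    if counts.index.has_duplicates:
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in counts: {dupes[:5]}")
    if counts.columns.has_duplicates:
        dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in counts: {dupes}")
    bad_cols = [c for c in counts.columns
                if not np.issubdtype(counts[c].dtype, np.integer)]
    if bad_cols:
        raise ValueError(f"non-integer counts in samples: {bad_cols}")
    if (counts.values < 0).any():
        raise ValueError("negative values in count matrix")

    cat = HybridCatalogue.from_files(annotation_tsv)
    known = set(cat.gene_ids)
    missing = [g for g in counts.index if g not in known]
    if missing:
        raise ValueError(f"count genes missing from annotation: {missing[:5]}")

    design = pd.read_csv(design_tsv, sep="\t", index_col=0)
    for col in ("condition", "timepoint"):
        if col not in design.columns:
            raise ValueError(f"design table lacks column {col!r}")
    unknown_samples = [s for s in design.index if s not in counts.columns]
    if unknown_samples:
        raise ValueError(f"design samples missing from counts: {unknown_samples}")
    counts.attrs["flavor"] = "full"
    return counts, cat, design
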