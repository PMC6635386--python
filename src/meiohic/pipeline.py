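"""Configuration-driven orchestration: simulate -> normalize -> analyse.

A :class:`PipelineConfig` (usually loaded from YAML) names the stages to
run and their parameters; :func:`run_pipeline` executes them in dependency
order, writes TSV/BED artifacts to the output directory, and returns a
machine-readable report with per-stage summaries and a checksummed output
manifest.  Identical configs and seeds give bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import assoc, core, domains, metrics, sim
from .matrix import write_contacts

logger = logging.getLogger("meiohic")

STAGES = ("simulate", "filter", "normalize", "compartments", "tads", "metrics",
          "peaks")

# implicit prerequisites; simulate is the only data source in this pipeline
_REQUIRES = {
    "filter": ("simulate",),
    "normalize": ("filter",),
    "compartments": ("filter",),
    "tads": ("normalize",),
    "metrics": ("filter",),
    "peaks": ("simulate", "compartments", "normalize"),
}


@dataclass
class PipelineConfig:
    stages: list[str]
    out_dir: Path
    seed: int = 0
    n_reads: int = 1_000_000
    genome: dict = field(default_factory=dict)  # GenomeSpec overrides
    architecture: dict = field(default_factory=dict)  # ArchitectureSpec overrides
    effects: dict = field(default_factory=dict)  # EffectSpec overrides
    min_count: float = 10.0
    ice_tol: float = 1e-5
    ice_max_iter: int = 200
    n_perm: int = 1_000
    force: bool = False

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}; valid: {list(STAGES)}")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the report dict.

    The report carries a per-stage summary (compartment fractions and
    recovery vs the planted truth, ratio tables, border counts, association
    Z-scores) and an output manifest with sha256 checksums.  Missing
    prerequisites raise before any computation.
    """
    for s in config.stages:
        for req in _REQUIRES.get(s, ()):
            if req not in config.stages:
                raise ValueError(f"stage {s!r} requires stage {req!r}")
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": config.seed}
    artifacts: list[Path] = []
    state: dict = {}

    def emit(name: str, writer) -> None:
        path = out / name
        if path.exists() and not config.force:
            raise FileExistsError(f"{path} exists; use force to overwrite")
        writer(path)
        artifacts.append(path)

    for stage in config.stages:
        logger.info("stage %s", stage)
        summary: dict = {}
        if stage == "simulate":
            gspec = sim.GenomeSpec(**config.genome)
            arch = sim.ArchitectureSpec(seed=config.seed, **config.architecture)
            layout, genes = sim.build_genome_layout(
                gspec, compartment_block_bins=arch.compartment_block_bins,
                seed=config.seed,
            )
            labels = sim.planted_compartment_labels(
                layout, arch.compartment_block_bins
            )
            expected = sim.simulate_expected_matrix(
                layout, arch, labels, telomere_window=gspec.telomere_window
            )
            reads, raw = sim.sample_contact_reads(
                expected, config.n_reads, seed=config.seed
            )
            effect = sim.EffectSpec(seed=config.seed, **config.effects)
            peaks = sim.simulate_peak_tracks(layout, genes, effect)
            gene_bins = np.array(
                [layout.bin_index(c, int(t))
                 for c, t in zip(genes["chrom"], genes["tss"])]
            )
            expr = sim.simulate_expression_table(
                genes, labels[gene_bins],
                genes["gene_id"].isin(peaks.loc[peaks["promoter"], "gene_id"]),
                effect,
            )
            state.update(layout=layout, genes=genes, labels=labels, raw=raw,
                         peaks=peaks, expr=expr, arch=arch, gspec=gspec)
            emit("contacts.tsv", lambda p: write_contacts(raw, p))
            emit("genes.tsv", lambda p: genes.to_csv(p, sep="\t", index=False))
            emit("peaks.bed", lambda p: assoc.write_bed(peaks, p))
            emit("expression.tsv", lambda p: expr.to_csv(p, sep="\t", index=False))
            summary = {"n_bins": layout.n_bins, "n_reads": config.n_reads,
                       "n_genes": len(genes), "n_peaks": len(peaks)}
        elif stage == "filter":
            state["filtered"] = core.filter_low_count_bins(
                state["raw"], min_count=config.min_count
            )
            summary = {
                "masked_bins": int(state["filtered"].mask.sum()),
                "threshold": state["filtered"].meta["low_count_threshold"],
            }
        elif stage == "normalize":
            bal = core.ice_normalize(
                state["filtered"], max_iter=config.ice_max_iter, tol=config.ice_tol
            )
            state["balanced"] = bal
            state["scaled"] = core.scale_matrix(bal, 2e8)
            emit("balanced.tsv", lambda p: write_contacts(bal, p))
            summary = {"converged": bal.meta["ice_converged"],
                       "iterations": bal.meta["ice_iterations"]}
        elif stage == "compartments":
            layout, genes = state["layout"], state["genes"]
            gd = np.zeros(layout.n_bins)
            for c, t in zip(genes["chrom"], genes["tss"]):
                gd[layout.bin_index(c, int(t))] += 1
            prof = domains.call_compartments(state["filtered"], gd)
            state["profile"] = prof
            emit("compartments.bed", prof.to_bed)
            assigned = prof.labels != "NA"
            recovery = float(
                (prof.labels[assigned] == state["labels"][assigned]).mean()
            ) if assigned.any() else np.nan
            summary = dict(prof.summary(), planted_label_recovery=recovery)
        elif stage == "tads":
            track = domains.insulation_score(state["scaled"])
            borders = domains.call_tad_borders(track)
            state["track"], state["borders"] = track, borders
            emit("tad_borders.bed", borders.to_bed)
            truth = sim.planted_tad_borders(
                state["layout"], state["arch"].tad_segment_bins
            )
            called = borders.borders
            tp = sum(1 for b in called if np.abs(truth - b).min() <= 1)
            summary = {
                "n_borders": int(called.size),
                "border_precision": tp / called.size if called.size else np.nan,
                "border_recall": float(
                    np.mean([np.abs(called - t).min() <= 1 for t in truth])
                ) if called.size else 0.0,
                "mean_robustness": float(borders.robustness.mean())
                if called.size else np.nan,
            }
        elif stage == "metrics":
            rt = metrics.inter_intra_ratio(state["raw"])
            curve = metrics.contact_probability_curve(
                core.scale_matrix(state["raw"], 1.0)
            )
            slope, _ = curve.fit_slope()
            emit("ratio_table.tsv",
                 lambda p: rt.table.to_csv(p, sep="\t", index=False))
            emit("decay_curve.tsv",
                 lambda p: curve.to_frame().to_csv(p, sep="\t", index=False))
            summary = {"ratios": rt.table["ratio"].round(6).tolist(),
                       "decay_slope": slope}
        elif stage == "peaks":
            layout = state["layout"]
            cats, _ = assoc.annotate_peaks_to_features(state["peaks"],
                                                       state["genes"])
            track = domains.insulation_score(state["scaled"]).aggregate
            pr = assoc.permutation_mean_zscore(
                track, state["peaks"], layout, n_perm=config.n_perm,
                seed=config.seed, mask=state["filtered"].mask,
            )
            frac_a, p_a = assoc.compartment_occupancy_enrichment(
                state["peaks"], state["profile"], n_perm=config.n_perm,
                seed=config.seed,
            )
            peak_genes = state["peaks"].loc[state["peaks"]["promoter"], "gene_id"]
            stat, p_expr, direction = assoc.expression_group_comparison(
                state["expr"], list(peak_genes),
                [g for g in state["expr"]["gene_id"] if g not in set(peak_genes)],
            )
            summary = {
                "categories": cats.value_counts().to_dict(),
                "insulation_z": pr.z,
                "fraction_in_A": frac_a,
                "occupancy_p": p_a,
                "expression_p": p_expr,
                "expression_direction": direction,
            }
        report["stages"][stage] = summary

    report["manifest"] = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(artifacts)
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
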