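"""End-to-end orchestration: run every analysis stage from one config and
emit per-stage CSVs plus a deterministic summary JSON.

Stage order is structure -> indels -> photopath -> codonevol -> climate.
When diurnal Pn traces are provided, the photopath calls override the
configured category map for the downstream grouping (species whose trace is
undetermined keep their configured label).  A stage whose inputs are absent
is recorded as "skipped"; a failing stage stops the run with its name in
the error, retaining the outputs written so far.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import climate as climate_mod
from . import codonevol, indels, photopath, structure, synthetic_data
from .formats_io import (
    PlastevolError,
    PlastomeRecord,
    read_annotations,
    read_dated_tree,
    read_fasta,
    write_annotations_tsv,
    write_fasta,
)

logger = logging.getLogger("plastevol")

SUMMARY_SCHEMA_VERSION = 1


class PipelineStageError(PlastevolError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs and parameters of one full pipeline run."""

    outdir: str
    fasta: str | None = None
    annotations: str | None = None
    alignment: str | None = None
    tree: str | None = None
    pn_csv: str | None = None
    climate_csv: str | None = None
    genes_dir: str | None = None
    reference_id: str = "REF"
    categories: dict[str, str] = field(default_factory=dict)
    min_ir_len: int = 1000
    n_remove_high_ds: int = 35
    pca_axes: int = 2
    n_permutations: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as handle:
            raw = yaml.safe_load(handle)
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p):
            if p is None:
                return None
            return p if os.path.isabs(p) else os.path.join(base, p)

        kwargs = dict(raw)
        for key in ("outdir", "fasta", "annotations", "alignment", "tree",
                    "pn_csv", "climate_csv", "genes_dir"):
            if key in kwargs:
                kwargs[key] = resolve(kwargs[key])
        return cls(**kwargs)


def _require(config: RunConfig, stage: str, **paths: str | None) -> None:
    missing = [name for name, p in paths.items() if p is None or not os.path.exists(p)]
    if missing:
        raise PlastevolError(
            f"stage {stage!r}: missing required input(s): {', '.join(missing)}"
        )


def run_structure(config: RunConfig) -> dict:
    _require(config, "structure", fasta=config.fasta, annotations=config.annotations)
    sequences = dict(read_fasta(config.fasta))
    annotations = read_annotations(config.annotations)
    rows = []
    for seq_id, seq in sequences.items():
        record = PlastomeRecord(
            id=seq_id, sequence=seq, genes=annotations.get(seq_id, {})
        )
        part = structure.detect_inverted_repeat(seq, min_ir_len=config.min_ir_len)
        gc = structure.gc_by_region(record, part)
        prof = structure.profile_junctions(record, part)
        rows.append(
            {
                "id": seq_id,
                "genome_length": part.genome_length,
                "lsc_length": part.lsc.length,
                "ssc_length": part.ssc.length,
                "ir_length": part.ir_length,
                "gc_total": gc.total,
                "gc_lsc": gc.lsc,
                "gc_ssc": gc.ssc,
                "gc_ir": gc.ir,
                "j_lb": prof.j_lb,
                "j_sb": prof.j_sb,
                "j_sa": prof.j_sa,
                "j_la": prof.j_la,
                "psi_rpl22_len": prof.psi_rpl22_len,
                "psi_ycf1_len": prof.psi_ycf1_len,
                "ndhf_jsb_offset": prof.ndhf_jsb_offset,
                "jsb_type": prof.jsb_type,
            }
        )
    report = pd.DataFrame(rows)
    report.to_csv(os.path.join(config.outdir, "structure.csv"), index=False)
    return {"n_genomes": len(rows)}


def run_indels(config: RunConfig) -> dict:
    _require(
        config, "indels",
        alignment=config.alignment, tree=config.tree, fasta=config.fasta,
    )
    alignment = read_fasta(config.alignment)
    tree = read_dated_tree(config.tree)
    sequences = dict(read_fasta(config.fasta))
    if config.reference_id not in sequences:
        raise PlastevolError(
            f"reference {config.reference_id!r} not found in {config.fasta}"
        )
    ref_partition = structure.detect_inverted_repeat(
        sequences[config.reference_id].replace("-", ""),
        min_ir_len=config.min_ir_len,
    )
    events = indels.call_indels(alignment, config.reference_id)
    events = indels.assign_regions(events, ref_partition)
    frame = indels.events_to_frame(events)
    frame.to_csv(os.path.join(config.outdir, "indel_events.tsv"), sep="\t", index=False)
    summary = indels.summarize_indels(events)
    density = indels.indel_density(summary, ref_partition)
    density.to_csv(os.path.join(config.outdir, "indel_summary.csv"), index=False)
    by_sample: dict[str, list[indels.IndelEvent]] = {}
    for ev in events:
        by_sample.setdefault(ev.sample_id, []).append(ev)
    rates = indels.branch_rates(by_sample, tree)
    pd.DataFrame(
        [
            {
                "branch_id": r.branch_id,
                "duration_myr": r.duration_myr,
                "insertion_bp": r.insertion_bp,
                "deletion_bp": r.deletion_bp,
                "insertion_rate_bp_per_myr": r.insertion_rate,
                "deletion_rate_bp_per_myr": r.deletion_rate,
            }
            for r in sorted(rates, key=lambda r: r.branch_id)
        ]
    ).to_csv(os.path.join(config.outdir, "indel_rates.csv"), index=False)
    return {"n_events": len(events), "n_samples": len(by_sample)}


def run_photopath(config: RunConfig) -> tuple[dict, dict[str, str]]:
    _require(config, "photopath", pn_csv=config.pn_csv)
    traces = pd.read_csv(config.pn_csv)
    calls = photopath.classify_table(traces)
    calls.to_csv(os.path.join(config.outdir, "pathway_calls.csv"), index=False)
    called = {
        row.species: row.call
        for row in calls.itertuples()
        if row.call != "undetermined"
    }
    return {"n_species": len(calls), "n_determined": len(called)}, called


def run_codonevol(config: RunConfig, categories: dict[str, str]) -> dict:
    _require(config, "codonevol", genes_dir=config.genes_dir)
    rates: list[codonevol.GeneRates] = []
    gene_files = sorted(
        f for f in os.listdir(config.genes_dir) if f.endswith((".fa", ".fasta"))
    )
    if not gene_files:
        raise PlastevolError(f"no per-gene FASTA files in {config.genes_dir}")
    for fname in gene_files:
        gene = os.path.splitext(fname)[0]
        records = dict(read_fasta(os.path.join(config.genes_dir, fname)))
        if config.reference_id not in records:
            raise PlastevolError(f"{fname}: reference {config.reference_id!r} missing")
        ref_seq = records[config.reference_id]
        for taxon, seq in records.items():
            if taxon == config.reference_id:
                continue
            rates.append(codonevol.ng86_pair(ref_seq, seq, gene=gene, taxon=taxon))
    table = codonevol.rates_to_frame(rates)
    table.to_csv(os.path.join(config.outdir, "gene_rates.csv"), index=False)
    filtered = codonevol.filter_high_ds(table, n_remove=config.n_remove_high_ds)
    per_gene, pooled = codonevol.category_rate_comparison(filtered, categories)
    per_gene.to_csv(os.path.join(config.outdir, "category_comparison.csv"), index=False)
    pooled.to_csv(os.path.join(config.outdir, "category_pooled.csv"), index=False)
    return {
        "n_genes": int(table["gene"].nunique()),
        "n_genes_retained": int(filtered["gene"].nunique()),
    }


def run_climate(config: RunConfig, categories: dict[str, str]) -> dict:
    _require(config, "climate", climate_csv=config.climate_csv)
    table = pd.read_csv(config.climate_csv)
    matrix = climate_mod.load_climate_matrix(table)
    result = climate_mod.pca_fit(matrix, k=config.pca_axes)
    result.loadings.to_csv(os.path.join(config.outdir, "pca_loadings.csv"))
    scores = result.scores.copy()
    scores.insert(0, "species", table["species"].to_numpy())
    scores.to_csv(os.path.join(config.outdir, "pca_scores.csv"), index=False)
    labels = table["species"].map(categories)
    if labels.isna().any():
        missing = sorted(table.loc[labels.isna(), "species"].unique())
        raise PlastevolError(f"climate: species without category: {missing}")
    sep = climate_mod.group_separation(
        result.scores, labels.to_numpy(), axis="PC1",
        n_permutations=config.n_permutations, seed=config.seed,
    )
    attribution = climate_mod.axis_attribution(result, top_m=6)
    with open(os.path.join(config.outdir, "pca_attribution.json"), "w") as fh:
        json.dump(
            {
                "explained_variance_ratio": [
                    round(float(v), 6) for v in result.explained_variance_ratio
                ],
                "top_variables": attribution,
                "pc1_separation_f": round(sep.f_ratio, 4),
                "pc1_separation_p": sep.p_value,
            },
            fh, indent=2, sort_keys=True,
        )
    return {
        "n_localities": int(len(table)),
        "pc1_separation_p": sep.p_value,
    }


def run_all(config: RunConfig) -> dict:
    """Execute every stage whose inputs are present; write summary.json.

    Returns the summary dict.  Determinism: identical config and seed give
    byte-identical summary JSON (no timestamps in the output)."""
    os.makedirs(config.outdir, exist_ok=True)
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "stages": {},
    }
    categories = dict(config.categories)

    def run_stage(name: str, fn, *args):
        try:
            info = fn(config, *args)
        except Exception as exc:
            summary["stages"][name] = {"status": "error", "error": str(exc)}
            _write_summary(config, summary)
            logger.error("stage %s failed: %s", name, exc)
            raise PipelineStageError(name, exc) from exc
        logger.info("stage %s ok: %s", name, info)
        return info

    def record(name: str, info: dict) -> None:
        summary["stages"][name] = {"status": "ok", **info}

    if config.fasta and config.annotations:
        record("structure", run_stage("structure", run_structure))
    else:
        summary["stages"]["structure"] = {"status": "skipped"}

    if config.alignment:
        record("indels", run_stage("indels", run_indels))
    else:
        summary["stages"]["indels"] = {"status": "skipped"}

    if config.pn_csv:
        info, called = run_stage("photopath", run_photopath)
        record("photopath", info)
        categories.update(called)  # Pn calls override the configured map
    else:
        summary["stages"]["photopath"] = {"status": "skipped"}

    if config.genes_dir:
        record("codonevol", run_stage("codonevol", run_codonevol, categories))
    else:
        summary["stages"]["codonevol"] = {"status": "skipped"}

    if config.climate_csv:
        record("climate", run_stage("climate", run_climate, categories))
    else:
        summary["stages"]["climate"] = {"status": "skipped"}

    _write_summary(config, summary)
    return summary


def _write_summary(config: RunConfig, summary: dict) -> None:
    with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Writing a simulated bundle to disk (inputs for a full run)


def write_bundle(bundle: synthetic_data.Bundle, outdir: str) -> str:
    """Write every simulated input as plain-text files plus a ready-to-run
    config.yaml; returns the config path."""
    import yaml

    os.makedirs(outdir, exist_ok=True)
    sim = bundle.simulation
    config = sim.config
    write_fasta(
        os.path.join(outdir, "reference.fasta"),
        [(sim.ancestor.id, sim.ancestor.sequence)],
    )
    write_annotations_tsv(
        os.path.join(outdir, "reference_genes.tsv"),
        {sim.ancestor.id: sim.ancestor.genes},
    )
    write_fasta(os.path.join(outdir, "alignment.fasta"), sim.alignment)
    write_fasta(
        os.path.join(outdir, "tips.fasta"),
        [(tip, rec.sequence) for tip, rec in sim.tip_records.items()],
    )
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(sim.tree.as_newick() + "\n")
    indels.events_to_frame(
        [e for events in sim.events_by_tip.values() for e in events]
    ).to_csv(os.path.join(outdir, "events_true.tsv"), sep="\t", index=False)
    bundle.pn_traces.to_csv(os.path.join(outdir, "pn.csv"), index=False)
    bundle.climate.to_csv(os.path.join(outdir, "climate.csv"), index=False)
    genes_dir = os.path.join(outdir, "genes")
    os.makedirs(genes_dir, exist_ok=True)
    for gene, pairs in bundle.codon_alignments.items():
        write_fasta(os.path.join(genes_dir, f"{gene}.fasta"), pairs)
    run_config = {
        "outdir": "results",
        "fasta": "reference.fasta",
        "annotations": "reference_genes.tsv",
        "alignment": "alignment.fasta",
        "tree": "tree.nwk",
        "pn_csv": "pn.csv",
        "climate_csv": "climate.csv",
        "genes_dir": "genes",
        "reference_id": config.reference_id,
        "categories": dict(config.categories),
        "seed": config.seed,
        "n_remove_high_ds": config.n_high_ds_genes,
    }
    config_path = os.path.join(outdir, "config.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=True)
    return config_path
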