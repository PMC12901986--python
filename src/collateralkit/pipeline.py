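"""End-to-end pipeline: simulate, then run the analysis stages on the
simulated artifacts, producing a checksummed manifest.

Identical configuration + seed yields byte-identical outputs (and hence
identical manifest checksums). All stage randomness derives from named
substreams of the single global seed; nothing reads the wall clock.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import assays, dipcall, integrity, simkit, spikenorm
from ._rng import stage_rng
from .config import RunConfig
from .errors import CollateralKitError
from .io import (
    parse_paf,
    read_counts_tsv,
    read_cq_csv,
    read_electropherogram_tsv,
    read_fasta,
    read_sample_sheet,
    write_counts_tsv,
    write_cq_csv,
    write_electropherogram_tsv,
    write_fasta,
    write_fold_change_tsv,
    write_paf,
    write_pfm_tsv,
    write_sample_sheet,
    write_sites_bed,
    write_sites_tsv,
    write_truth_bed,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_stage"]


class StageError(CollateralKitError):
    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage {stage!r} failed: {error}")
        self.stage = stage
        self.error = error


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _build_model(sim: dict) -> simkit.CleavageModel:
    return simkit.CleavageModel(
        loop_mask_fraction=sim["loop_mask_fraction"],
        abundance_slope=sim["abundance_slope"],
        class_multipliers={
            "protein_coding": sim["class_multiplier_pc"],
            "mito_mRNA": 0.0,
            "nuclear_ncRNA": 0.0,
            "spike_in": 0.0,
        },
    )


def simulate_stage(config: RunConfig, outdir: Path) -> list[Path]:
    """Generate all four data modalities with planted ground truth."""
    sim = config["simulate"]
    seed = config.seed
    outputs: list[Path] = []

    tx = simkit.build_transcriptome(
        n_transcripts=sim["n_transcripts"],
        biotype_fractions=dict(sim["biotype_fractions"]),
        abundance_lognormal_params=(sim["abundance_mu"], sim["abundance_sigma"]),
        seq_length_range=tuple(sim["seq_length_range"]),
        n_spikeins=sim["n_spikeins"],
        seed=int(stage_rng(seed, "transcriptome").integers(2**31)),
    )
    fasta_path = outdir / "transcriptome.fasta"
    write_fasta(tx, fasta_path)
    outputs.append(fasta_path)

    model = _build_model(sim)
    sites = simkit.plant_cleavage_sites(
        tx,
        model,
        density=sim["site_density_per_kb"],
        seed=int(stage_rng(seed, "sites").integers(2**31)),
    )
    truth_path = outdir / "truth_sites.bed"
    write_truth_bed(sites, truth_path)
    outputs.append(truth_path)

    timepoints = list(sim["timepoints"])
    for t in timepoints:
        pool = simkit.simulate_fragment_pool(
            tx,
            sites,
            model,
            timepoint=t,
            n_molecules_scale=sim["n_molecules_scale"],
            seed=int(stage_rng(seed, f"pool_t{t}").integers(2**31)),
        )
        aln = simkit.simulate_read_alignments(
            pool,
            depth=sim["read_depth"],
            full_length_prob=sim["full_length_prob"],
            seed=int(stage_rng(seed, f"reads_t{t}").integers(2**31)),
        )
        paf_path = outdir / f"alignments_t{t}.paf"
        write_paf(aln, paf_path)
        outputs.append(paf_path)

        trace = simkit.simulate_electropherogram(pool, sample_id=f"t{t}")
        trace_path = outdir / f"electropherogram_t{t}.tsv"
        write_electropherogram_tsv(trace, trace_path)
        outputs.append(trace_path)

    # count matrix: replicated targeting-vs-control design at one timepoint
    n_rep = int(sim["n_replicates"])
    design = {}
    for i in range(1, n_rep + 1):
        design[f"ctrl_{i}"] = "non_targeting"
        design[f"trt_{i}"] = "targeting"
    spec = simkit.DepletionSpec(intercept=sim["depletion_log2fc"])
    cm = simkit.simulate_count_matrix(
        tx,
        spec,
        design,
        dispersion=sim["nb_dispersion"],
        seed=int(stage_rng(seed, "counts").integers(2**31)),
        timepoint=timepoints[-1],
    )
    counts_path = outdir / "counts.tsv"
    write_counts_tsv(cm, counts_path)
    outputs.append(counts_path)
    sheet = cm.samples.reset_index(names="sample")
    sheet_path = outdir / "count_samples.csv"
    write_sample_sheet(sheet, sheet_path)
    outputs.append(sheet_path)

    # Cq tables: an empty-control condition plus a targeting condition at
    # each timepoint, templates derived from the fragment pools
    pc = tx.by_biotype("protein_coding")
    if pc:
        target = max(pc, key=lambda t: t.abundance)
        length = target.length
        assay = simkit.QpcrAssay(
            target_id=target.id,
            amplicon_5p=(min(20, length // 10), min(120, length // 5)),
            amplicon_3p=(max(length - 120, length // 2), length - 5),
        )
        cq_frames = []
        sheet_rows = []
        n_mol = max(200, int(target.abundance * sim["n_molecules_scale"]))
        for i in range(1, n_rep + 1):
            sample = f"empty_{i}"
            cq_frames.append(
                simkit.simulate_cq_table(
                    simkit.templates_from_cut_fraction(n_mol, 0.0),
                    sample=sample,
                    target=target.id,
                    efficiency=sim["qpcr_efficiency"],
                    noise_sd=sim["cq_noise_sd"],
                    seed=int(stage_rng(seed, f"cq_{sample}").integers(2**31)),
                )
            )
            sheet_rows.append(
                {"sample": sample, "condition": "empty", "is_empty_control": True}
            )
        for t in timepoints:
            pool = simkit.simulate_fragment_pool(
                tx,
                sites,
                model,
                timepoint=t,
                n_molecules_scale=sim["n_molecules_scale"],
                seed=int(stage_rng(seed, f"cq_pool_t{t}").integers(2**31)),
            )
            for i in range(1, n_rep + 1):
                sample = f"targeting_t{t}_{i}"
                cq_frames.append(
                    simkit.simulate_cq_table(
                        pool,
                        assay=assay,
                        sample=sample,
                        target=target.id,
                        efficiency=sim["qpcr_efficiency"],
                        noise_sd=sim["cq_noise_sd"],
                        seed=int(stage_rng(seed, f"cq_{sample}").integers(2**31)),
                    )
                )
                sheet_rows.append(
                    {
                        "sample": sample,
                        "condition": f"targeting_t{t}",
                        "is_empty_control": False,
                    }
                )
        cq_path = outdir / "cq.csv"
        write_cq_csv(pd.concat(cq_frames, ignore_index=True), cq_path)
        outputs.append(cq_path)
        cq_sheet_path = outdir / "cq_samples.csv"
        write_sample_sheet(pd.DataFrame(sheet_rows), cq_sheet_path)
        outputs.append(cq_sheet_path)

    return outputs


def auc_stage(config: RunConfig, outdir: Path) -> list[Path]:
    params = config["auc"]
    traces = []
    for path in sorted(outdir.glob("electropherogram_*.tsv")):
        traces.append(read_electropherogram_tsv(path))
    if not traces:
        raise CollateralKitError("no electropherogram traces found")
    if params["normalize"]:
        traces = assays.normalize_traces(traces)
    region = tuple(params["region"])
    rows = []
    for trace in traces:
        total = assays.trace_total_auc(trace)
        area, fraction = assays.region_auc(trace, region)
        rows.append(
            {
                "sample": trace.sample_id,
                "total_auc": total,
                "region_auc": area,
                "region_fraction": fraction,
            }
        )
    out = outdir / "auc.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False, float_format="%.6g")
    return [out]


def integrity_stage(config: RunConfig, outdir: Path) -> list[Path]:
    cq = read_cq_csv(outdir / "cq.csv")
    sheet = read_sample_sheet(outdir / "cq_samples.csv")
    per_sample, per_condition = integrity.integrity_analysis(cq, sheet)
    p1 = outdir / "integrity_per_sample.tsv"
    p2 = outdir / "integrity_per_condition.tsv"
    per_sample.to_csv(p1, sep="\t", index=False, float_format="%.6g")
    per_condition.to_csv(p2, sep="\t", index=False, float_format="%.6g")
    return [p1, p2]


def spikenorm_stage(config: RunConfig, outdir: Path) -> list[Path]:
    params = config["spikenorm"]
    sheet = read_sample_sheet(outdir / "count_samples.csv")
    cm = read_counts_tsv(outdir / "counts.tsv", sample_sheet=sheet)
    factors = spikenorm.spikein_size_factors(cm)
    normalized = spikenorm.normalize_counts(cm, factors)
    targeting = cm.samples.index[cm.samples["condition"] == "targeting"].tolist()
    control = cm.samples.index[
        cm.samples["condition"] == params["control_condition"]
    ].tolist()
    table = spikenorm.fold_change_table(
        normalized,
        cm.spike_in,
        targeting,
        control,
        pseudocount=params["pseudocount"],
        min_count=params["min_count"],
        biotypes=cm.biotypes,
    )
    fit = spikenorm.abundance_depletion_fit(table, biotype_filter=["protein_coding"])
    threshold = params["threshold"]
    if threshold is None:
        threshold = spikenorm.DEFAULT_SELECTION_THRESHOLDS.get(
            params["timepoint"], 2.0
        )
    out_table = spikenorm.selection_table(fit, threshold)
    path = outdir / "fold_changes.tsv"
    write_fold_change_tsv(
        out_table,
        path,
        header={
            "slope": f"{fit.slope:.6g}",
            "intercept": f"{fit.intercept:.6g}",
            "threshold": threshold,
            "size_factors": ",".join(
                f"{s}={factors[s]:.6g}" for s in sorted(factors.index)
            ),
        },
    )
    return [path]


def dipcall_stage(config: RunConfig, outdir: Path) -> list[Path]:
    params = config["dipcall"]
    sequences = read_fasta(outdir / "transcriptome.fasta")
    paf_paths = sorted(outdir.glob("alignments_t*.paf"))
    if not paf_paths:
        raise CollateralKitError("no alignment files found")
    # the last timepoint carries the strongest signal
    aln = parse_paf(paf_paths[-1])
    calls = dipcall.call_transcriptome_dips(
        aln,
        sequences,
        upstream_search=params["upstream_search"],
        context_flank=params["flank"],
        smooth_window=params["smooth_window"],
        baseline_window=params["baseline_window"],
        depth_ratio_threshold=params["depth_ratio_threshold"],
        width_range=(params["width_min"], params["width_max"]),
        edge_exclusion=params["edge_exclusion"],
        min_mean_depth=params["min_mean_depth"],
    )
    outputs = []
    bed_path = outdir / "dips.bed"
    write_sites_bed(calls, bed_path)
    outputs.append(bed_path)
    sites_path = outdir / "sites.tsv"
    write_sites_tsv(calls, sites_path)
    outputs.append(sites_path)
    assigned = [c for c in calls if c.position is not None]
    if assigned:
        summary = dipcall.cleavage_context_pfm(
            assigned, sequences, flank=params["flank"]
        )
        pfm_path = outdir / "context_pfm.tsv"
        write_pfm_tsv(summary, pfm_path)
        outputs.append(pfm_path)
    per_read, summary_stats = dipcall.mapped_length_stats(aln)
    lengths_path = outdir / "read_lengths.tsv"
    per_read.to_csv(lengths_path, sep="\t", index=False, float_format="%.6g")
    outputs.append(lengths_path)
    stats_path = outdir / "read_length_summary.json"
    with open(stats_path, "w") as fh:
        json.dump(summary_stats, fh, indent=2, sort_keys=True, allow_nan=True)
    outputs.append(stats_path)
    return outputs


_STAGES = {
    "simulate": simulate_stage,
    "auc": auc_stage,
    "integrity": integrity_stage,
    "spikenorm": spikenorm_stage,
    "dipcall": dipcall_stage,
}


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the configured stages and return the output manifest
    (relative path -> sha256)."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    config.dump(outdir / "config.yaml")
    produced: list[Path] = []
    for stage_name, stage_fn in _STAGES.items():
        if not config.stage_enabled(stage_name):
            logger.info("stage %s disabled", stage_name)
            continue
        logger.info("running stage %s", stage_name)
        try:
            produced.extend(stage_fn(config, outdir))
        except Exception as exc:  # abort with the stage name attached
            raise StageError(stage_name, exc) from exc
    manifest = {str(p.relative_to(outdir)): _sha256(p) for p in produced}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
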