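"""Canonical simulation experiments for validating the analysis stages.

Each function builds a synthetic dataset with planted ground truth, runs
the corresponding analysis stage on it, and returns the recovery metrics.
They are the package's self-checks: the test suite asserts tolerance
bands on their outputs and the acceptance report re-runs them from
scratch for a given seed.
"""

from __future__ import annotations

import math

import numpy as np

from . import dipcall, integrity, spikenorm
from ._rng import stage_rng
from .errors import LowCoverageError
from .simkit import (
    CleavageModel,
    DepletionSpec,
    build_transcriptome,
    plant_cleavage_sites,
    plant_spaced_sites,
    simulate_cq_table,
    simulate_count_matrix,
    simulate_fragment_pool,
    simulate_read_alignments,
    templates_from_cut_fraction,
)

__all__ = [
    "spike_normalization_experiment",
    "selection_recovery_experiment",
    "dip_recovery_experiment",
    "dip_null_experiment",
    "context_logo_experiment",
    "qpcr_oracle_experiment",
    "temporal_shape_experiment",
]

_SIX_SAMPLE_DESIGN = {
    "ctrl_1": "non_targeting",
    "ctrl_2": "non_targeting",
    "ctrl_3": "non_targeting",
    "trt_1": "targeting",
    "trt_2": "targeting",
    "trt_3": "targeting",
}

_T_SAMPLES = ["trt_1", "trt_2", "trt_3"]
_C_SAMPLES = ["ctrl_1", "ctrl_2", "ctrl_3"]


def _depletion_matrix(
    seed: int,
    n_genes: int,
    n_spikes: int,
    global_log2fc: float,
    dispersion: float,
    gene_offsets: dict[str, float] | None = None,
):
    tx = build_transcriptome(
        n_genes + n_spikes,
        {"protein_coding": 1.0, "spike_in": 0.0},
        abundance_lognormal_params=(math.log(100.0), 1.0),
        seq_length_range=(500, 2000),
        n_spikeins=n_spikes,
        seed=int(stage_rng(seed, "bench_tx").integers(2**31)),
    )
    spec = DepletionSpec(intercept=global_log2fc, gene_offsets=gene_offsets or {})
    cm = simulate_count_matrix(
        tx,
        spec,
        _SIX_SAMPLE_DESIGN,
        dispersion=dispersion,
        seed=int(stage_rng(seed, "bench_counts").integers(2**31)),
        spike_scale=2e-2,
    )
    return tx, cm


def spike_normalization_experiment(
    seed: int,
    n_genes: int = 2000,
    n_spikes: int = 92,
    global_log2fc: float = -1.0,
    dispersion: float = 0.05,
) -> dict:
    """Global depletion visible under spike anchoring, hidden without it.

    3 control + 3 targeting samples; every gene carries the same true
    log2FC while spike-ins are untouched. Returns the median estimated
    log2FC under spike-restricted and under total-count normalization.
    """
    _, cm = _depletion_matrix(seed, n_genes, n_spikes, global_log2fc, dispersion)
    out = {}
    for label, factors in (
        ("spike_normalized_median_log2fc", spikenorm.spikein_size_factors(cm)),
        ("total_count_median_log2fc", spikenorm.total_count_size_factors(cm)),
    ):
        norm = spikenorm.normalize_counts(cm, factors)
        table = spikenorm.fold_change_table(
            norm, cm.spike_in, _T_SAMPLES, _C_SAMPLES
        )
        out[label] = float(table["log2fc"].median())
    out["n_genes"] = n_genes
    return out


def selection_recovery_experiment(
    seed: int,
    n_genes: int = 2000,
    n_spikes: int = 92,
    n_offset_genes: int = 50,
    offset: float = 3.0,
    threshold: float = 2.0,
    dispersion: float = 0.05,
) -> dict:
    """Recovery of transcripts planted above the abundance regression.

    ``n_offset_genes`` genes receive a +``offset`` log2FC on top of the
    global depletion; selection at the given residual threshold is scored
    as sensitivity and false-selection rate (fraction of selected genes
    that were not planted).
    """
    rng = stage_rng(seed, "bench_offsets")
    tx_probe = build_transcriptome(
        n_genes + n_spikes,
        {"protein_coding": 1.0, "spike_in": 0.0},
        n_spikeins=n_spikes,
        seed=int(stage_rng(seed, "bench_tx").integers(2**31)),
    )
    gene_ids = [t.id for t in tx_probe.by_biotype("protein_coding")]
    planted = set(
        np.array(gene_ids)[rng.choice(len(gene_ids), n_offset_genes, replace=False)]
    )
    _, cm = _depletion_matrix(
        seed, n_genes, n_spikes, -1.0, dispersion,
        gene_offsets={g: offset for g in planted},
    )
    factors = spikenorm.spikein_size_factors(cm)
    norm = spikenorm.normalize_counts(cm, factors)
    table = spikenorm.fold_change_table(
        norm, cm.spike_in, _T_SAMPLES, _C_SAMPLES, biotypes=cm.biotypes
    )
    fit = spikenorm.abundance_depletion_fit(table)
    selected = set(spikenorm.select_outlier_transcripts(fit, threshold=threshold))
    planted_present = planted & set(table.index)
    tp = len(selected & planted_present)
    sensitivity = tp / len(planted_present) if planted_present else float("nan")
    false_rate = (len(selected) - tp) / len(selected) if selected else 0.0
    return {
        "sensitivity": sensitivity,
        "false_selection_rate": false_rate,
        "n_selected": len(selected),
        "n_planted": len(planted_present),
    }


def _recovery_model() -> CleavageModel:
    return CleavageModel(
        activation_curve={200: 1.0},
        abundance_slope=0.0,
        class_multipliers={
            "protein_coding": 1.0,
            "mito_mRNA": 0.0,
            "nuclear_ncRNA": 0.0,
            "spike_in": 0.0,
        },
    )


def _dip_sim(
    seed: int,
    n_transcripts: int,
    truth_fn,
    mean_molecules: float = 400.0,
    depth: float = 0.6,
    full_length_prob: float = 0.1,
):
    tx = build_transcriptome(
        n_transcripts,
        {"protein_coding": 1.0},
        abundance_lognormal_params=(math.log(mean_molecules), 0.0),
        seq_length_range=(1200, 1800),
        n_spikeins=0,
        seed=int(stage_rng(seed, "dip_tx").integers(2**31)),
    )
    model = _recovery_model()
    truth = truth_fn(tx, model)
    pool = simulate_fragment_pool(
        tx, truth, model, 200, 1.0,
        seed=int(stage_rng(seed, "dip_pool").integers(2**31)),
    )
    aln = simulate_read_alignments(
        pool, depth=depth, full_length_prob=full_length_prob,
        seed=int(stage_rng(seed, "dip_reads").integers(2**31)),
    )
    return tx, truth, aln


def score_site_calls(tx, truth, calls, tolerance: int = 10) -> dict:
    """Recall/precision/positional error of dip calls against planted sites.

    A call matches a true site when its assigned position lies within
    ``tolerance`` nt; each true site can be matched once.
    """
    tp = fp = fn = 0
    errors: list[int] = []
    by_tx: dict[str, list] = {}
    for c in calls:
        by_tx.setdefault(c.transcript_id, []).append(c)
    for t in tx.transcripts:
        true_pos = [p for p, _ in truth.get(t.id, [])]
        matched: set[int] = set()
        for c in by_tx.get(t.id, []):
            if c.position is None:
                fp += 1
                continue
            dists = [abs(c.position - p) for p in true_pos]
            if dists and min(dists) <= tolerance:
                matched.add(int(np.argmin(dists)))
                errors.append(min(dists))
                tp += 1
            else:
                fp += 1
        fn += len(true_pos) - len(matched)
    return {
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "median_positional_error": float(np.median(errors)) if errors else float("nan"),
        "n_true_sites": tp + fn,
        "n_calls": tp + fp,
    }


def dip_recovery_experiment(seed: int, n_transcripts: int = 100) -> dict:
    """Planted-site recovery: 1-3 well-separated sites per transcript,
    ~200x mean coverage, default dip-caller knobs."""

    def truth_fn(tx, model):
        return plant_spaced_sites(
            tx, model, n_sites_range=(1, 3), constant_weight=2.5,
            seed=int(stage_rng(seed, "dip_sites").integers(2**31)),
        )

    tx, truth, aln = _dip_sim(seed, n_transcripts, truth_fn)
    calls = dipcall.call_transcriptome_dips(aln, tx.sequences)
    result = score_site_calls(tx, truth, calls)
    depths = [
        dipcall.transcript_coverage(aln, t.id).mean_depth for t in tx.transcripts
    ]
    result["mean_depth"] = float(np.mean(depths))
    result["n_transcripts"] = n_transcripts
    return result


def dip_null_experiment(seed: int, n_transcripts: int = 100) -> dict:
    """False-positive rate of the dip caller on cleavage-free data."""
    tx, _, aln = _dip_sim(
        seed, n_transcripts, lambda tx, model: {t.id: [] for t in tx.transcripts}
    )
    n_dips = 0
    for t in tx.transcripts:
        try:
            n_dips += len(dipcall.detect_dips(dipcall.transcript_coverage(aln, t.id)))
        except LowCoverageError:
            continue
    return {
        "dips_per_transcript": n_dips / n_transcripts,
        "n_transcripts": n_transcripts,
    }


def context_logo_experiment(seed: int, n_transcripts: int = 60) -> dict:
    """Dinucleotide preference of called sites under hot US weights.

    Sites are planted proportionally to the model's dinucleotide weights
    (UG/UC ten times hotter than UA/UU) and cut with their dinucleotide
    hazard; the called-site summary reports the US fraction and the
    information content at position 0.
    """

    def truth_fn(tx, model):
        return plant_spaced_sites(
            tx, model, n_sites_range=(2, 3), weights="dinucleotide",
            seed=int(stage_rng(seed, "ctx_sites").integers(2**31)),
        )

    tx = build_transcriptome(
        n_transcripts,
        {"protein_coding": 1.0},
        abundance_lognormal_params=(math.log(400.0), 0.0),
        seq_length_range=(1200, 1800),
        n_spikeins=0,
        seed=int(stage_rng(seed, "ctx_tx").integers(2**31)),
    )
    model = CleavageModel(
        site_weights={"UG": 10.0, "UC": 10.0, "UA": 1.0, "UU": 1.0},
        activation_curve={200: 1.0},
        abundance_slope=0.0,
        class_multipliers={
            "protein_coding": 0.25,
            "mito_mRNA": 0.0,
            "nuclear_ncRNA": 0.0,
            "spike_in": 0.0,
        },
    )
    truth = truth_fn(tx, model)
    pool = simulate_fragment_pool(
        tx, truth, model, 200, 1.0,
        seed=int(stage_rng(seed, "ctx_pool").integers(2**31)),
    )
    aln = simulate_read_alignments(
        pool, depth=0.6, full_length_prob=0.1,
        seed=int(stage_rng(seed, "ctx_reads").integers(2**31)),
    )
    calls = [
        c
        for c in dipcall.call_transcriptome_dips(aln, tx.sequences)
        if c.position is not None
    ]
    summary = dipcall.cleavage_context_pfm(calls, tx.sequences, flank=5)
    return {
        "us_fraction": summary.us_fraction(),
        "information_bits_at_0": float(summary.information_content.loc[0]),
        "n_sites": summary.n_sites,
    }


def qpcr_oracle_experiment(
    seed: int,
    fractions: tuple[float, ...] = (0.25, 0.5, 0.75),
    efficiencies: tuple[float, ...] = (0.9, 1.0),
    noise_sd: float = 0.15,
    n_replicates: int = 6,
    n_molecules: float = 10_000.0,
) -> dict:
    """ddCq recovery against the closed form -log2(1-f)/log2(1+E).

    Returns the worst absolute deviation over the (f, E) grid for the
    noiseless tables and for noisy tables with the given replicate count.
    """

    def ddcq(fraction, efficiency, sd, sub_seed):
        control = simulate_cq_table(
            templates_from_cut_fraction(n_molecules, 0.0),
            sample="ctrl", target="G", efficiency=efficiency,
            noise_sd=sd, n_replicates=n_replicates,
            seed=int(stage_rng(seed, f"cq_c_{sub_seed}").integers(2**31)),
        )
        treated = simulate_cq_table(
            templates_from_cut_fraction(n_molecules, fraction),
            sample="trt", target="G", efficiency=efficiency,
            noise_sd=sd, n_replicates=n_replicates,
            seed=int(stage_rng(seed, f"cq_t_{sub_seed}").integers(2**31)),
        )

        def dcq(table):
            collapsed = integrity.collapse_replicates(table)
            return integrity.compute_dcq(collapsed).loc[0, "dcq_53"]

        res = integrity.five_three_ddcq([dcq(treated)], [dcq(control)])
        return float(res["ddcq"][0])

    worst_exact = 0.0
    worst_noisy = 0.0
    for fraction in fractions:
        for efficiency in efficiencies:
            expected = -math.log2(1 - fraction) / math.log2(1 + efficiency)
            tag = f"{fraction}_{efficiency}"
            worst_exact = max(
                worst_exact, abs(ddcq(fraction, efficiency, 0.0, tag) - expected)
            )
            worst_noisy = max(
                worst_noisy,
                abs(ddcq(fraction, efficiency, noise_sd, "n" + tag) - expected),
            )
    return {
        "max_abs_error_noiseless": worst_exact,
        "max_abs_error_noisy": worst_noisy,
        "n_conditions": len(fractions) * len(efficiencies),
    }


def temporal_shape_experiment(
    seed: int,
    n_transcripts: int = 120,
    timepoints: tuple[float, ...] = (0, 100, 200, 1440),
) -> dict:
    """Full-length read fraction over time, by transcript class.

    Default cleavage model and activation curve; reads are full length
    unless cut (full_length_prob 1), so the statistic isolates cleavage.
    """
    tx = build_transcriptome(
        n_transcripts,
        {"protein_coding": 0.8, "mito_mRNA": 0.1, "nuclear_ncRNA": 0.05,
         "spike_in": 0.05},
        abundance_lognormal_params=(math.log(60.0), 0.7),
        seq_length_range=(800, 2000),
        n_spikeins=10,
        seed=int(stage_rng(seed, "temp_tx").integers(2**31)),
    )
    model = CleavageModel(abundance_slope=0.0)
    sites = plant_cleavage_sites(
        tx, model, density=3.0,
        seed=int(stage_rng(seed, "temp_sites").integers(2**31)),
    )
    pc = {t.id for t in tx.by_biotype("protein_coding")}
    mito = {t.id for t in tx.by_biotype("mito_mRNA")}
    out: dict = {"timepoints": list(timepoints)}
    pc_frac, mito_frac = {}, {}
    for t in timepoints:
        pool = simulate_fragment_pool(
            tx, sites, model, t, 0.5,
            seed=int(stage_rng(seed, f"temp_pool_{t}").integers(2**31)),
        )
        aln = simulate_read_alignments(
            pool, depth=1.0, full_length_prob=1.0,
            seed=int(stage_rng(seed, f"temp_reads_{t}").integers(2**31)),
        )
        _, s_pc = dipcall.mapped_length_stats(aln, transcript_ids=pc)
        _, s_mito = dipcall.mapped_length_stats(aln, transcript_ids=mito)
        pc_frac[t] = s_pc["full_length_fraction"]
        mito_frac[t] = s_mito["full_length_fraction"]
    out["protein_coding_full_length"] = pc_frac
    out["mito_full_length"] = mito_frac
    return out
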