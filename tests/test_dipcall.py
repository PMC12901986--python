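import numpy as np
import pytest

from collateralkit.alignments import AlignmentRecord, AlignmentSet
from collateralkit.dipcall import (
    DipCall,
    assign_cleavage_sites,
    call_transcriptome_dips,
    cleavage_context_pfm,
    detect_dips,
    mapped_length_stats,
    transcript_coverage,
)
from collateralkit.dipcall.coverage import CoverageProfile
from collateralkit.errors import LowCoverageError, ValidationError
from collateralkit.simkit import (
    CleavageModel,
    build_transcriptome,
    plant_spaced_sites,
    simulate_fragment_pool,
    simulate_read_alignments,
)
from tests.conftest import interval_jaccard


def aln_set(intervals, length=30, transcript="TX1"):
    records = [
        AlignmentRecord(f"r{i}", transcript, s, e) for i, (s, e) in enumerate(intervals)
    ]
    return AlignmentSet(records, {transcript: length})


def synthetic_profile(depth_array, transcript_id="TX1"):
    return CoverageProfile(
        transcript_id=transcript_id,
        depth=np.asarray(depth_array, dtype=np.int64),
        n_reads=100,
    )


class TestTranscriptCoverage:
    def test_single_read(self):
        profile = transcript_coverage(aln_set([(10, 20)]), "TX1")
        expected = np.zeros(30)
        expected[10:20] = 1
        assert np.array_equal(profile.depth, expected)

    def test_two_overlapping_reads(self):
        profile = transcript_coverage(aln_set([(0, 30), (10, 20)]), "TX1")
        expected = np.ones(30)
        expected[10:20] = 2
        assert np.array_equal(profile.depth, expected)

    def test_uniform_full_length_relative_depth_one(self):
        profile = transcript_coverage(aln_set([(0, 30)] * 7), "TX1")
        assert np.allclose(profile.relative_depth, 1.0)

    def test_coverage_conservation(self):
        rng = np.random.default_rng(3)
        intervals = []
        for _ in range(200):
            s = int(rng.integers(0, 29))
            e = int(rng.integers(s + 1, 31))
            intervals.append((s, e))
        profile = transcript_coverage(aln_set(intervals), "TX1")
        assert profile.depth.sum() == sum(e - s for s, e in intervals)

    def test_secondary_records_ignored(self):
        records = [
            AlignmentRecord("r0", "TX1", 0, 30, is_primary=True),
            AlignmentRecord("r1", "TX1", 0, 30, is_primary=False),
        ]
        profile = transcript_coverage(
            AlignmentSet(records, {"TX1": 30}), "TX1"
        )
        assert profile.depth.max() == 1
        assert profile.n_reads == 1

    def test_unknown_transcript(self):
        with pytest.raises(ValidationError, match="unknown"):
            transcript_coverage(aln_set([(0, 10)]), "NOPE")

    def test_min_reads_flag(self):
        profile = transcript_coverage(aln_set([(0, 30)]), "TX1", min_reads=5)
        assert not profile.covered


class TestDetectDips:
    def test_constructed_dip_found(self):
        depth = np.full(600, 100)
        depth[200:215] = 40
        dips = detect_dips(synthetic_profile(depth))
        assert len(dips) == 1
        dip = dips[0]
        # smoothing can move each boundary by at most half the window
        assert abs(dip.start - 200) <= 2
        assert abs(dip.end - 215) <= 2
        assert dip.depth_ratio == pytest.approx(0.4, abs=0.02)

    def test_flat_profile_no_dips(self):
        assert detect_dips(synthetic_profile(np.full(500, 80))) == []

    def test_narrow_dip_rejected(self):
        depth = np.full(600, 100)
        depth[300:305] = 10
        assert detect_dips(synthetic_profile(depth), width_range=(8, 30)) == []

    def test_wide_depression_rejected(self):
        depth = np.full(800, 100)
        depth[300:360] = 10  # wider than width_range max
        assert detect_dips(synthetic_profile(depth)) == []

    def test_edge_dips_excluded(self):
        depth = np.full(400, 100)
        depth[5:20] = 10
        depth[385:398] = 10
        assert detect_dips(synthetic_profile(depth), edge_exclusion=25) == []

    def test_low_coverage_raises(self):
        with pytest.raises(LowCoverageError):
            detect_dips(synthetic_profile(np.full(300, 3)), min_mean_depth=20)

    def test_nearby_runs_merged(self):
        depth = np.full(600, 100)
        depth[200:206] = 30
        depth[207:213] = 30  # gap of 1 position; merged run width 13
        dips = detect_dips(synthetic_profile(depth))
        assert len(dips) == 1
        assert dips[0].end - dips[0].start >= 10


class TestAssignSites:
    def test_forced_example(self):
        seq = "AAUGCCGG"
        dips = [DipCall("TX1", 3, 6, 0.3)]
        (call,) = assign_cleavage_sites(dips, seq)
        assert call.position == 2
        assert call.dinucleotide == "UG"

    def test_no_u_in_window(self):
        seq = "AAGGCCGGGGCCGGGG"
        dips = [DipCall("TX1", 8, 12, 0.3)]
        (call,) = assign_cleavage_sites(dips, seq, upstream_search=3)
        assert call.position is None

    def test_u_at_dip_start_beats_upstream(self):
        #          0123456789
        seq = "AAUAUGCCCCCC"
        dips = [DipCall("TX1", 4, 9, 0.3)]  # U at 4 (distance 0), U at 2 (distance 2)
        (call,) = assign_cleavage_sites(dips, seq)
        assert call.position == 4

    def test_tie_prefers_upstream(self):
        #      position: 0123456
        seq = "AAUAUCCCCCC"
        # dip start 3: U at 2 (distance 1) and U at 4 (distance 1) -> upstream
        dips = [DipCall("TX1", 3, 8, 0.3)]
        (call,) = assign_cleavage_sites(dips, seq)
        assert call.position == 2


class TestContextPfm:
    def test_all_ug_context(self):
        seqs = {"TX1": "ACGUAUGCCAA" * 4}
        # positions of 'U' followed by 'G': index 5 in each 11-mer
        calls = [
            DipCall("TX1", 6 + 11 * k, 16 + 11 * k, 0.3, position=5 + 11 * k)
            for k in range(3)
        ]
        summary = cleavage_context_pfm(calls, seqs, flank=1)
        assert summary.pfm.loc[0, "U"] == 1.0
        assert summary.pfm.loc[1, "G"] == 1.0
        assert summary.information_content.loc[0] == pytest.approx(2.0)
        assert summary.information_content.loc[1] == pytest.approx(2.0)
        assert summary.dinucleotide_counts.to_dict() == {"UG": 3}

    def test_uniform_position_zero_ic(self):
        # +1 composition exactly (1/4, 1/4, 1/4, 1/4) -> IC 0 at +1
        seqs = {
            "A": "GGGGUAGGGG",
            "C": "GGGGUCGGGG",
            "G": "GGGGUGGGGG",
            "U": "GGGGUUGGGG",
        }
        calls = [DipCall(t, 5, 9, 0.3, position=4) for t in "ACGU"]
        summary = cleavage_context_pfm(calls, seqs, flank=2)
        assert summary.information_content.loc[1] == pytest.approx(0.0, abs=1e-12)
        assert summary.information_content.loc[0] == pytest.approx(2.0)

    def test_truncated_windows_excluded(self):
        seqs = {"TX1": "UAAA"}  # U at 0: window would start below 0
        calls = [DipCall("TX1", 1, 3, 0.3, position=0)]
        with pytest.raises(ValidationError, match="complete context"):
            cleavage_context_pfm(calls, seqs, flank=2)

    def test_zero_sites_rejected(self):
        with pytest.raises(ValidationError):
            cleavage_context_pfm([DipCall("TX1", 1, 3, 0.3)], {"TX1": "AAAA"})

    def test_small_sample_correction_lowers_ic(self):
        seqs = {"TX1": "ACGUAUGCCAA"}
        calls = [DipCall("TX1", 6, 9, 0.3, position=5)]
        a = cleavage_context_pfm(calls, seqs, flank=1)
        b = cleavage_context_pfm(calls, seqs, flank=1, small_sample_correction=True)
        assert b.information_content.loc[0] < a.information_content.loc[0]


class TestMappedLengthStats:
    def test_all_full_length(self):
        per_read, summary = mapped_length_stats(aln_set([(0, 30)] * 5))
        assert summary["full_length_fraction"] == 1.0
        assert summary["median_ratio"] == 1.0

    def test_median_of_mixed_ratios(self):
        per_read, summary = mapped_length_stats(aln_set([(0, 30), (0, 15)]))
        assert summary["median_ratio"] == pytest.approx(0.75)

    def test_exclusions_filtered(self):
        records = [
            AlignmentRecord("r0", "TX1", 0, 30),
            AlignmentRecord("r1", "HIST1", 0, 10),
        ]
        aln = AlignmentSet(records, {"TX1": 30, "HIST1": 30})
        per_read, summary = mapped_length_stats(aln, exclusions=("HIST1",))
        assert summary["n_reads"] == 1
        assert set(per_read["transcript_id"]) == {"TX1"}

    def test_empty(self):
        per_read, summary = mapped_length_stats(aln_set([]))
        assert summary["n_reads"] == 0
        assert np.isnan(summary["median_ratio"])


def _recovery_sim(seed, n_tx=25, site_weight=2.5):
    tx = build_transcriptome(
        n_tx,
        {"protein_coding": 1.0},
        abundance_lognormal_params=(np.log(400.0), 0.0),
        seq_length_range=(1200, 1800),
        n_spikeins=0,
        seed=seed,
    )
    model = CleavageModel(
        activation_curve={200: 1.0},
        abundance_slope=0.0,
        class_multipliers={
            "protein_coding": 1.0,
            "mito_mRNA": 0.0,
            "nuclear_ncRNA": 0.0,
            "spike_in": 0.0,
        },
    )
    truth = plant_spaced_sites(
        tx, model, n_sites_range=(1, 3), constant_weight=site_weight, seed=seed + 1
    )
    pool = simulate_fragment_pool(tx, truth, model, 200, 1.0, seed=seed + 2)
    aln = simulate_read_alignments(
        pool, depth=0.6, full_length_prob=0.1, seed=seed + 3
    )
    return tx, truth, aln


def _score_calls(tx, truth, calls, tolerance=10):
    tp = fp = fn = 0
    errors = []
    by_tx: dict[str, list] = {}
    for c in calls:
        by_tx.setdefault(c.transcript_id, []).append(c)
    for t in tx.transcripts:
        true_pos = [p for p, _ in truth[t.id]]
        matched = set()
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
    recall = tp / (tp + fn) if tp + fn else np.nan
    precision = tp / (tp + fp) if tp + fp else np.nan
    return recall, precision, errors


class TestPlantedSiteRecovery:
    def test_recall_precision_positional_error(self, small_transcriptome):
        tx, truth, aln = _recovery_sim(seed=31)
        calls = call_transcriptome_dips(aln, tx.sequences)
        recall, precision, errors = _score_calls(tx, truth, calls)
        assert recall >= 0.9
        assert precision >= 0.9
        assert np.median(errors) <= 3

    def test_null_calibration(self):
        tx = build_transcriptome(
            40,
            {"protein_coding": 1.0},
            abundance_lognormal_params=(np.log(400.0), 0.0),
            seq_length_range=(1200, 1800),
            n_spikeins=0,
            seed=41,
        )
        model = CleavageModel(activation_curve={200: 0.0}, abundance_slope=0.0)
        truth = {t.id: [] for t in tx.transcripts}
        pool = simulate_fragment_pool(tx, truth, model, 200, 1.0, seed=42)
        aln = simulate_read_alignments(pool, 0.6, full_length_prob=0.1, seed=43)
        calls = call_transcriptome_dips(aln, tx.sequences)
        assert len(calls) / len(tx.transcripts) <= 0.05

    def test_replicate_reproducibility(self):
        # same planted ground truth, independent molecule/read noise:
        # dip intervals overlap with Jaccard >= 0.7
        tx, truth, _ = _recovery_sim(seed=51)
        model = CleavageModel(
            activation_curve={200: 1.0},
            abundance_slope=0.0,
            class_multipliers={
                "protein_coding": 1.0,
                "mito_mRNA": 0.0,
                "nuclear_ncRNA": 0.0,
                "spike_in": 0.0,
            },
        )
        jaccards = []
        calls = []
        for rep_seed in (100, 200):
            pool = simulate_fragment_pool(tx, truth, model, 200, 1.0, seed=rep_seed)
            aln = simulate_read_alignments(
                pool, depth=0.6, full_length_prob=0.1, seed=rep_seed + 1
            )
            calls.append(call_transcriptome_dips(aln, tx.sequences))
        for t in tx.transcripts:
            a = [(c.start, c.end) for c in calls[0] if c.transcript_id == t.id]
            b = [(c.start, c.end) for c in calls[1] if c.transcript_id == t.id]
            if not a and not b:
                continue
            jaccards.append(interval_jaccard(a, b, t.length))
        assert np.mean(jaccards) >= 0.7
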