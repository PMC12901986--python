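import numpy as np
import pytest
from scipy import stats

from collateralkit.errors import ValidationError
from collateralkit.simkit import (
    CleavageModel,
    Transcriptome,
    TranscriptRecord,
    plant_cleavage_sites,
    plant_spaced_sites,
    simulate_fragment_pool,
)


def single_transcript(sequence: str, abundance: float = 100.0) -> Transcriptome:
    return Transcriptome(
        [TranscriptRecord("TX1", sequence, "protein_coding", abundance)]
    )


class TestCleavageModelValidation:
    def test_non_u_weight_key_rejected(self):
        with pytest.raises(ValidationError, match="starting with U"):
            CleavageModel(site_weights={"AG": 1.0})

    def test_spike_multiplier_must_be_zero(self):
        with pytest.raises(ValidationError, match="spike_in"):
            CleavageModel(
                class_multipliers={"protein_coding": 1.0, "spike_in": 0.5}
            )

    def test_activation_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError, match="activation"):
            CleavageModel(activation_curve={0: 1.5})

    def test_unknown_timepoint_lists_available(self):
        model = CleavageModel(activation_curve={0: 0.1, 200: 1.0})
        with pytest.raises(ValidationError, match=r"\[0, 200\]"):
            model.activation_at(77)


class TestPlantCleavageSites:
    def test_no_uracil_no_sites(self):
        tx = single_transcript("GGGCCC")
        sites = plant_cleavage_sites(tx, CleavageModel(), density=10.0, seed=1)
        assert sites["TX1"] == []

    def test_forced_site_position(self):
        # 'AUGAUA': U at 1 (UG, weight 1) and U at 4 (UA, weight 0)
        tx = single_transcript("AUGAUA")
        model = CleavageModel(
            site_weights={"UG": 1.0, "UC": 1.0}, loop_mask_fraction=1.0
        )
        # density high enough to force inclusion probability 1
        sites = plant_cleavage_sites(tx, model, density=10000.0, seed=1)
        assert [p for p, _ in sites["TX1"]] == [1]
        assert sites["TX1"][0][1] == 1.0

    def test_sites_only_at_uracils(self, small_transcriptome, default_model):
        sites = plant_cleavage_sites(
            small_transcriptome, default_model, density=5.0, seed=3
        )
        for t in small_transcriptome.transcripts:
            for p, w in sites[t.id]:
                assert t.sequence[p] == "U"
                assert w == default_model.site_weights[t.sequence[p : p + 2]]

    def test_spikeins_never_get_sites(self, small_transcriptome, default_model):
        sites = plant_cleavage_sites(
            small_transcriptome, default_model, density=50.0, seed=3
        )
        for t in small_transcriptome.transcripts:
            if t.biotype == "spike_in":
                assert sites[t.id] == []

    def test_mean_site_count_poisson_band(self):
        # Oracle: with density 2/kb on a 10 kb transcript the site count is
        # a sum of independent Bernoullis with total mean 20; over 1000
        # seeds the observed mean lies in the 99% band for the mean of
        # 1000 iid Poisson-binomial(mean 20, variance <= 20) draws:
        # 20 +/- 2.576 * sqrt(20 / 1000) = [19.64, 20.36]; the spec's wider
        # [18.9, 21.1] single-draw band is implied.
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGU"), size=10_000))
        tx = single_transcript(seq)
        model = CleavageModel()
        counts = [
            len(plant_cleavage_sites(tx, model, density=2.0, seed=s)["TX1"])
            for s in range(1000)
        ]
        assert 18.9 <= np.mean(counts) <= 21.1
        assert 19.64 - 0.5 <= np.mean(counts) <= 20.36 + 0.5  # slack for mask variance

    def test_negative_density_rejected(self, small_transcriptome, default_model):
        with pytest.raises(ValidationError):
            plant_cleavage_sites(small_transcriptome, default_model, -1.0)


class TestSimulateFragmentPool:
    def test_zero_activation_full_spans(self):
        tx = single_transcript("AUGC" * 100, abundance=50.0)
        model = CleavageModel(activation_curve={0: 0.0}, target_hazard=0.0)
        sites = {"TX1": [(1, 5.0), (101, 5.0)]}
        pool = simulate_fragment_pool(tx, sites, model, 0, 1.0, seed=1)
        assert len(pool) > 0
        assert all(f.start == 0 and f.end == 400 for f in pool.fragments)

    def test_certain_cut_two_fragments(self):
        tx = single_transcript("AUGC" * 100, abundance=50.0)
        # hazard 1e9 -> cut probability 1
        model = CleavageModel(
            activation_curve={200: 1.0},
            class_multipliers={"protein_coding": 1e9, "spike_in": 0.0},
            abundance_slope=0.0,
        )
        sites = {"TX1": [(99, 1.0)]}
        pool = simulate_fragment_pool(tx, sites, model, 200, 1.0, seed=1)
        by_mol = {}
        for f in pool.fragments:
            by_mol.setdefault(f.molecule_id, []).append(f)
        for frags in by_mol.values():
            frags.sort(key=lambda f: f.start)
            assert [(f.start, f.end) for f in frags] == [(0, 100), (100, 400)]

    def test_cut_fraction_binomial_interval(self):
        # Oracle: one site with realized cut probability 0.5 over ~1e4
        # molecules; the cut fraction lies in the exact binomial 99%
        # interval [0.487, 0.513].
        tx = single_transcript("AUGC" * 250, abundance=10_000.0)
        p_target = 0.5
        weight = -np.log(1.0 - p_target)
        model = CleavageModel(
            activation_curve={200: 1.0},
            class_multipliers={"protein_coding": 1.0, "spike_in": 0.0},
            abundance_slope=0.0,
        )
        sites = {"TX1": [(501, weight)]}
        pool = simulate_fragment_pool(tx, sites, model, 200, 1.0, seed=11)
        lo, hi = stats.binom.interval(0.99, pool.n_molecules(), p_target)
        assert lo / pool.n_molecules() <= pool.cut_fraction() <= hi / pool.n_molecules()

    def test_fragment_conservation(self, small_transcriptome, default_model):
        sites = plant_cleavage_sites(
            small_transcriptome, default_model, density=5.0, seed=5
        )
        pool = simulate_fragment_pool(
            small_transcriptome, sites, default_model, 100, 0.3, seed=6
        )
        by_mol: dict[int, list] = {}
        for f in pool.fragments:
            by_mol.setdefault(f.molecule_id, []).append(f)
        for frags in by_mol.values():
            length = pool.transcript_lengths[frags[0].transcript_id]
            assert sum(f.length for f in frags) == length
            frags.sort(key=lambda f: f.start)
            assert frags[0].start == 0 and frags[-1].end == length
            for a, b in zip(frags, frags[1:]):
                assert a.end == b.start  # tiling, no overlap

    def test_native_polya_iff_reaches_end(self, small_transcriptome, default_model):
        sites = plant_cleavage_sites(
            small_transcriptome, default_model, density=5.0, seed=5
        )
        pool = simulate_fragment_pool(
            small_transcriptome, sites, default_model, 100, 0.2, seed=6
        )
        for f in pool.fragments:
            expected = f.end == pool.transcript_lengths[f.transcript_id]
            assert pool.has_native_polyA(f) == expected

    def test_spike_in_immunity(self, small_transcriptome):
        # even with absurd weights and density, spikes take zero cuts
        model = CleavageModel(
            site_weights={"UG": 1e6, "UC": 1e6, "UA": 1e6, "UU": 1e6},
            loop_mask_fraction=1.0,
        )
        sites = plant_cleavage_sites(small_transcriptome, model, 100.0, seed=1)
        pool = simulate_fragment_pool(small_transcriptome, sites, model, 100, 0.5, seed=2)
        spike_ids = {
            t.id for t in small_transcriptome.transcripts if t.biotype == "spike_in"
        }
        for f in pool.fragments:
            if f.transcript_id in spike_ids:
                assert f.start == 0
                assert f.end == pool.transcript_lengths[f.transcript_id]

    def test_seed_determinism(self, small_transcriptome, default_model):
        sites = plant_cleavage_sites(
            small_transcriptome, default_model, density=3.0, seed=9
        )
        a = simulate_fragment_pool(
            small_transcriptome, sites, default_model, 200, 0.3, seed=10
        )
        b = simulate_fragment_pool(
            small_transcriptome, sites, default_model, 200, 0.3, seed=10
        )
        assert a.fragments == b.fragments

    def test_unknown_timepoint_rejected(self, small_transcriptome, default_model):
        with pytest.raises(ValidationError, match="timepoint"):
            simulate_fragment_pool(
                small_transcriptome, {}, default_model, 123.4, 1.0, seed=1
            )

    def test_temporal_shape(self, small_transcriptome, default_model):
        sites = plant_cleavage_sites(
            small_transcriptome, default_model, density=3.0, seed=20
        )
        fractions = {
            t: simulate_fragment_pool(
                small_transcriptome, sites, default_model, t, 0.5, seed=21
            ).cut_fraction()
            for t in (0, 100, 200, 1440)
        }
        assert fractions[100] > fractions[0]
        assert fractions[200] > fractions[0]
        assert fractions[100] > fractions[1440]
        assert fractions[200] > fractions[1440]

    def test_target_cleavage_from_t0(self):
        tx = single_transcript("ACGU" * 200, abundance=200.0)
        model = CleavageModel(
            activation_curve={0: 0.0},
            target_id="TX1",
            target_position=399,
            target_hazard=1.0,
        )
        pool = simulate_fragment_pool(tx, {"TX1": []}, model, 0, 1.0, seed=3)
        # collateral machinery inactive (A=0) but the guide-directed cut fires
        boundaries = {(f.start, f.end) for f in pool.fragments}
        assert boundaries == {(0, 400), (400, 800)}


class TestContextFidelity:
    def test_us_enrichment_vs_equal_weight_oracle(self):
        # Exact oracle: expected US fraction among realized cuts is
        # sum_US p_i / sum_all p_i. Under hot US weights that exceeds the
        # equal-weight expectation (the fraction of US sites).
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGU"), size=4000))
        tx = single_transcript(seq, abundance=3000.0)
        model = CleavageModel(
            site_weights={"UG": 10.0, "UC": 10.0, "UA": 1.0, "UU": 1.0},
            loop_mask_fraction=1.0,
            activation_curve={100: 1.0},
            class_multipliers={"protein_coding": 0.05, "spike_in": 0.0},
            abundance_slope=0.0,
        )
        sites = plant_cleavage_sites(tx, model, density=5.0, seed=6)
        positions = np.array([p for p, _ in sites["TX1"]])
        weights = np.array([w for _, w in sites["TX1"]])
        is_us = np.array([seq[p + 1] in "GC" for p in positions])
        p_cut = 1.0 - np.exp(-0.05 * weights)
        expected_us = p_cut[is_us].sum() / p_cut.sum()
        equal_weight_expectation = is_us.mean()
        assert expected_us > equal_weight_expectation  # oracle-level check

        pool = simulate_fragment_pool(tx, sites, model, 100, 1.0, seed=7)
        cut_points = [
            f.start - 1 for f in pool.fragments if f.start > 0
        ]  # boundary is 3' of the cleaved U
        observed_us = np.mean([seq[c + 1] in "GC" for c in cut_points])
        assert observed_us > equal_weight_expectation
        # and close to the exact expectation
        assert observed_us == pytest.approx(expected_us, abs=0.05)


class TestPlantSpacedSites:
    def test_separation_and_margins(self, small_transcriptome, default_model):
        sites = plant_spaced_sites(
            small_transcriptome,
            default_model,
            n_sites_range=(1, 3),
            min_separation=50,
            edge_margin=40,
            seed=4,
        )
        for t in small_transcriptome.transcripts:
            positions = [p for p, _ in sites[t.id]]
            for p in positions:
                assert t.sequence[p] == "U"
                assert 40 <= p < t.length - 40
            for a, b in zip(positions, positions[1:]):
                assert b - a >= 50

    def test_only_cleavable_classes(self, small_transcriptome, default_model):
        sites = plant_spaced_sites(small_transcriptome, default_model, seed=4)
        for t in small_transcriptome.transcripts:
            if t.biotype != "protein_coding":
                assert sites[t.id] == []
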