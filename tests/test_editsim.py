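import numpy as np
import pandas as pd
import pytest

from dualcut import (
    DropletNoise,
    OutcomeModel,
    ReadSimConfig,
    amplicon_reference,
    emit_amplicon_reads,
    emit_droplet_panel,
    emit_long_reads,
    revcomp,
    simulate_sample,
    truth_from_counts,
)
from dualcut.editsim import LongReadUnsupportedError

NOERR = dict(substitution_error_rate=0.0, indel_error_rate=0.0)


class TestSimulateSample:
    def test_counts_partition_allele_population(self, locus_1kb, default_model):
        truth = simulate_sample(locus_1kb, default_model, n_cells=5000, seed=1)
        assert sum(truth.counts.values()) == 2 * 5000
        assert all(v >= 0 for v in truth.counts.values())

    def test_deterministic_given_seed(self, locus_1kb, default_model):
        a = simulate_sample(locus_1kb, default_model, n_cells=3000, seed=42)
        b = simulate_sample(locus_1kb, default_model, n_cells=3000, seed=42)
        assert a.counts == b.counts
        pd.testing.assert_frame_equal(a.edited, b.edited)

    @pytest.mark.parametrize("seed", range(5))
    def test_rearrangements_require_both_active_guides(self, locus_1kb, seed):
        model = OutcomeModel(p_cut_var=0.0, p_inv=0.3, p_del=0.3, p_perfect=0.1)
        truth = simulate_sample(locus_1kb, model, n_cells=2000, seed=seed)
        assert truth.counts["inversion"] == 0
        assert truth.counts["deletion"] == 0

    def test_no_transfection_means_all_wild_type(self, locus_1kb):
        model = OutcomeModel(p_transfect=0.0)
        truth = simulate_sample(locus_1kb, model, n_cells=1000, seed=3)
        assert truth.counts["wild_type"] == 2000

    def test_inversion_fraction_matches_generative_product(self, locus_1kb):
        # closed form: p_transfect * p_cut_fixed * p_cut_var * p_inv
        model = OutcomeModel(
            p_transfect=0.5, p_cut_fixed=0.5, p_cut_var=0.5, p_inv=0.05,
            p_del=0.1, p_perfect=0.3,
        )
        expected = 0.5 * 0.25 * 0.05  # 6.25e-3
        fracs = [
            simulate_sample(locus_1kb, model, n_cells=100_000, seed=s).fraction("inversion")
            for s in range(10)
        ]
        n_total = 10 * 200_000
        se = np.sqrt(expected * (1 - expected) / n_total)
        assert abs(np.mean(fracs) - expected) < 3 * se

    @pytest.mark.parametrize("seeds", [range(10)])
    def test_halving_transfection_halves_edited_fraction(self, locus_1kb, default_model, seeds):
        def mean_edited(p_t):
            model = OutcomeModel(p_transfect=p_t)
            fr = []
            for s in seeds:
                t = simulate_sample(locus_1kb, model, n_cells=20_000, seed=s)
                fr.append(1 - t.fraction("wild_type") + 0)
            return np.mean(fr)

        hi, lo = mean_edited(0.6), mean_edited(0.3)
        assert hi / lo == pytest.approx(2.0, rel=0.05)

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError):
            OutcomeModel(p_inv=0.6, p_del=0.5, p_perfect=0.2)
        with pytest.raises(ValueError):
            OutcomeModel(p_transfect=1.2)

    def test_truth_from_counts_exact(self, default_model):
        counts = {"wild_type": 1900, "inversion": 50, "deletion": 50}
        truth = truth_from_counts(counts, default_model, seed=5)
        assert truth.counts["inversion"] == 50
        assert truth.n_alleles == 2000
        assert truth.junction_carrier_fraction == 0.025


class TestDropletPanel:
    def test_no_inversions_no_double_positives(self, default_model):
        truth = truth_from_counts({"wild_type": 20_000}, default_model, seed=1)
        panel, _ = emit_droplet_panel(truth, dna_mass_g=1e-8, n_droplets=5000, seed=2)
        dp = (panel["ch1"] > 2500) & (panel["ch2"] > 2500)
        assert dp.sum() == 0

    def test_single_genome_single_droplet_double_positive(self, default_model):
        # exact-count partitioning puts the lone inversion genome in the lone droplet
        truth = truth_from_counts({"inversion": 2}, default_model, seed=1)
        mass = 1.0 / (6.022e23 / (1.179e9 * 659.928))  # exactly one genome copy
        panel, _ = emit_droplet_panel(
            truth,
            dna_mass_g=mass,
            loaded_vol_ul=0.59e-3,
            droplet_vol_nl=0.59,
            n_droplets=1,
            noise=DropletNoise(bg_sd=0.0, pos_sd=0.0, invalid_fraction=0.0),
            seed=3,
            occupancy="multinomial",
        )
        assert len(panel) == 1
        assert panel.loc[0, "ch1"] > 2500 and panel.loc[0, "ch2"] > 2500

    def test_double_positive_rate_matches_poisson_formula(self, default_model):
        # per-droplet P(positive) = 1 - exp(-lambda * f)
        f = 0.01
        truth = truth_from_counts(
            {"wild_type": 99_000, "inversion": 1000}, default_model, seed=0
        )
        copies = 4.7e5
        mass = copies / (6.022e23 / (1.179e9 * 659.928))
        lam = copies * 0.59 / 25_000.0
        rates = []
        for s in range(10):
            panel, _ = emit_droplet_panel(
                truth, dna_mass_g=mass, n_droplets=25_000,
                noise=DropletNoise(invalid_fraction=0.0), seed=s,
            )
            dp = (panel["ch1"] > 2500) & (panel["ch2"] > 2500)
            rates.append(dp.mean())
        p = 1 - np.exp(-lam * f)
        se = np.sqrt(p * (1 - p) / (25_000 * 10))
        assert abs(np.mean(rates) - p) < 3 * se

    def test_volume_budget_enforced(self, default_model):
        truth = truth_from_counts({"wild_type": 100}, default_model, seed=1)
        with pytest.raises(ValueError, match="exceeds loaded volume"):
            emit_droplet_panel(
                truth, dna_mass_g=1e-9, loaded_vol_ul=0.01, n_droplets=1000, seed=0
            )
        with pytest.raises(ValueError):
            emit_droplet_panel(truth, dna_mass_g=-1e-9, seed=0)

    def test_panel_deterministic_and_flags_invalid(self, default_model):
        truth = truth_from_counts({"wild_type": 1000, "inversion": 10}, default_model, seed=1)
        a, ta = emit_droplet_panel(truth, dna_mass_g=1e-8, n_droplets=2000, seed=9)
        b, tb = emit_droplet_panel(truth, dna_mass_g=1e-8, n_droplets=2000, seed=9)
        pd.testing.assert_frame_equal(a, b)
        assert ta == tb
        assert 0 < (~a["valid"]).sum() < len(a)


class TestAmpliconReads:
    def test_all_wild_type_zero_error_reads_equal_reference(self, locus_1kb, default_model):
        truth = truth_from_counts({"wild_type": 2000}, default_model, seed=1)
        cfg = ReadSimConfig(coverage=200, seed=2, **NOERR)
        ref, _ = amplicon_reference(locus_1kb, "fixed", cfg)
        reads = emit_amplicon_reads(truth, locus_1kb, "fixed", cfg)
        assert all(r.seq == ref for r in reads)

    def test_deletion_allele_read_is_shorter_by_its_size(self, locus_1kb):
        model = OutcomeModel(indel_size_dist={-3: 1.0})
        truth = truth_from_counts({"indel_fixed_only": 2000}, model, seed=1)
        cfg = ReadSimConfig(coverage=100, seed=2, **NOERR)
        ref, _ = amplicon_reference(locus_1kb, "fixed", cfg)
        reads = emit_amplicon_reads(truth, locus_1kb, "fixed", cfg)
        assert all(len(r.seq) == len(ref) - 3 for r in reads)

    def test_indel_read_fraction_tracks_allele_fraction(self, locus_1kb, default_model):
        truth = truth_from_counts(
            {"wild_type": 7000, "indel_fixed_only": 3000}, default_model, seed=1
        )
        cfg = ReadSimConfig(coverage=10_000, seed=3, **NOERR)
        reads = emit_amplicon_reads(truth, locus_1kb, "fixed", cfg)
        frac = np.mean([r.label == "indel_fixed_only" for r in reads])
        se = np.sqrt(0.3 * 0.7 / 10_000)
        assert abs(frac - 0.3) < 4 * se

    def test_rearranged_alleles_drop_out_by_default(self, locus_1kb, default_model):
        truth = truth_from_counts(
            {"wild_type": 1000, "inversion": 500, "deletion": 500}, default_model, seed=1
        )
        cfg = ReadSimConfig(coverage=500, seed=4, **NOERR)
        reads = emit_amplicon_reads(truth, locus_1kb, "fixed", cfg)
        assert all(r.label == "wild_type" for r in reads)

    def test_dropout_off_emits_junction_products(self, locus_1kb, default_model):
        truth = truth_from_counts({"inversion": 2000}, default_model, seed=1)
        cfg = ReadSimConfig(coverage=50, seed=4, rearranged_dropout=False, **NOERR)
        ref, _ = amplicon_reference(locus_1kb, "fixed", cfg)
        reads = emit_amplicon_reads(truth, locus_1kb, "fixed", cfg)
        assert all(r.label == "inversion" for r in reads)
        assert all(r.seq != ref for r in reads)


class TestLongReads:
    def test_inversion_read_carries_only_inverted_junctions(self, locus_1kb, default_model):
        truth = truth_from_counts({"inversion": 2000}, default_model, seed=1)
        cfg = ReadSimConfig(coverage=50, seed=5, **NOERR)
        seg = locus_1kb.ref_segment
        a, b = locus_1kb.left_cut, locus_1kb.right_cut
        wt_left = seg[a - 20 : a + 20]
        wt_right = seg[b - 20 : b + 20]
        upstream = seg[a - 20 : a]
        for r in emit_long_reads(truth, locus_1kb, cfg):
            both = r.seq + "|" + revcomp(r.seq)
            # wild-type junctions destroyed; the upstream flank is still there
            assert wt_left not in both and wt_right not in both
            assert upstream in both

    def test_deletion_read_length(self, locus_1kb):
        model = OutcomeModel(junction_insert_dist={0: 1.0})
        truth = truth_from_counts({"deletion": 2000}, model, seed=1)
        cfg = ReadSimConfig(coverage=20, seed=6, **NOERR)
        reads = emit_long_reads(truth, locus_1kb, cfg)
        expect = len(locus_1kb.ref_segment) - locus_1kb.interval_bp
        assert all(len(r.seq) == expect for r in reads)

    def test_interval_above_ceiling_rejected(self, default_model):
        from dualcut import make_locus

        big = make_locus(interval_bp=6000, margin=200, seed=1)
        truth = truth_from_counts({"wild_type": 200}, default_model, seed=1)
        with pytest.raises(LongReadUnsupportedError, match="unsupported for this interval"):
            emit_long_reads(truth, big, ReadSimConfig(coverage=10, seed=1))

    def test_byte_identical_given_seed(self, locus_1kb, default_model):
        truth = simulate_sample(locus_1kb, default_model, n_cells=1000, seed=2)
        cfg = ReadSimConfig(coverage=300, seed=8)
        r1 = emit_long_reads(truth, locus_1kb, cfg)
        r2 = emit_long_reads(truth, locus_1kb, cfg)
        assert [(a.read_id, a.seq, a.label) for a in r1] == [
            (b.read_id, b.seq, b.label) for b in r2
        ]
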