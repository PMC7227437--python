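"""Ground-truth generator: clone sizes, two-stage sampling, spiking."""

import numpy as np
import pytest
from scipy import optimize, stats

from clonodiff import (
    DepthError,
    ValidationError,
    clonality,
    expected_overlap,
    generate_base_repertoire,
    generate_experimental_sections,
    make_pair,
    pairwise_correlation,
    singleton_preset,
    split_control_replicates,
    tcell_paper_preset,
)
from clonodiff.repertoire_io import translate_nt
from clonodiff.synthetic import SUBSET_EXPRESSION, depth_mismatch_scenario


class TestBaseRepertoire:
    def test_singleton_preset_matches_toy_repertoire(self):
        gt = singleton_preset(100)
        assert gt.n_clones == 100
        assert gt.total_cells == 100
        assert np.all(gt.cell_counts == 1)

    def test_all_plasma_rates(self):
        gt = generate_base_repertoire(
            50, 2.0, 500, {"plasma": 1.0}, seed=0, chain="IGH", base_expression=0.5
        )
        assert np.all(gt.expression_rate == 0.5 * SUBSET_EXPRESSION["plasma"])
        assert set(gt.subset) == {"plasma"}

    def test_total_cells_exact_and_counts_nonnegative(self):
        gt = generate_base_repertoire(300, 2.2, 7_919, {"effector": 1.0}, seed=3)
        assert gt.total_cells == 7_919
        assert np.all(gt.cell_counts >= 0)

    def test_cdr3s_in_frame_and_unique(self):
        gt = generate_base_repertoire(200, 2.0, 2_000, {"effector": 1.0}, seed=1)
        assert len(set(gt.cdr3_nt)) == 200
        for nt, aa in zip(gt.cdr3_nt[:20], gt.cdr3_aa[:20]):
            assert translate_nt(nt) == aa
            assert aa.startswith("C") and aa[-1] in "FW"

    def test_powerlaw_exponent_recovered(self):
        # tail-conditional discrete MLE (sizes >= xmin): renormalizing
        # to a fixed cell total reshuffles the singleton head but leaves
        # the tail index intact
        exponent = 2.5
        gt = generate_base_repertoire(10_000, exponent, 25_000, {"effector": 1.0}, seed=5)
        xmin = 5
        sizes = gt.cell_counts[gt.cell_counts >= xmin]

        def nll(a):
            return -np.sum(
                stats.zipf.logpmf(sizes, a) - np.log(stats.zipf.sf(xmin - 1, a))
            )

        fit = optimize.minimize_scalar(nll, bounds=(1.2, 6.0), method="bounded")
        assert abs(fit.x - exponent) < 0.2

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValidationError):
            generate_base_repertoire(10, 0.9, 100, {"effector": 1.0}, seed=0)
        with pytest.raises(ValidationError):
            generate_base_repertoire(10, 2.0, 100, {"effector": 0.5}, seed=0)
        with pytest.raises(ValidationError):
            generate_base_repertoire(10, 2.0, 100, {"stem": 1.0}, seed=0)


class TestControlSplit:
    def test_cell_partition_conserves_pool(self):
        gt = generate_base_repertoire(100, 2.0, 5_000, {"effector": 1.0}, seed=2)
        reps = split_control_replicates(gt, 3, 1_500, None, seed=4, sigma=0.0, poisson=False)
        # with deterministic unit expression, UMI counts equal cell draws;
        # replicate sums cannot exceed the tissue pool clone by clone
        total = np.zeros(gt.n_clones)
        for rep in reps:
            joined = {k: c for k, c in zip(rep.table["cdr3_nt"], rep.table["umi_count"])}
            for i, nt in enumerate(gt.cdr3_nt):
                total[i] += joined.get(nt, 0)
        assert total.sum() == 3 * 1_500
        assert np.all(total <= gt.cell_counts)

    def test_no_noise_limit_reproduces_ground_truth_frequencies(self):
        gt = generate_base_repertoire(80, 2.0, 4_000, {"effector": 1.0}, seed=6)
        (rep,) = split_control_replicates(
            gt, 1, gt.total_cells, None, seed=1, sigma=0.0, poisson=False
        )
        observed = {k: c for k, c in zip(rep.table["cdr3_nt"], rep.table["umi_count"])}
        for i, nt in enumerate(gt.cdr3_nt):
            assert observed.get(nt, 0) == gt.cell_counts[i]

    def test_frequency_unbiasedness_without_expression_noise(self):
        gt = generate_base_repertoire(50, 1.8, 10_000, {"effector": 1.0}, seed=8,
                                      size_model="rank")
        top = int(np.argmax(gt.cell_counts))
        f_true = gt.cell_counts[top] / gt.total_cells
        freqs = []
        for seed in range(60):
            reps = split_control_replicates(gt, 1, 2_000, 1_500, seed=seed, sigma=0.0)
            rep = reps[0]
            row = rep.table[rep.table["cdr3_nt"] == gt.cdr3_nt[top]]
            freqs.append(float(row["umi_count"].iloc[0]) / rep.total_umi)
        se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - f_true) < 3.5 * se

    def test_expression_dispersion_increases_replicate_variance(self):
        gt = generate_base_repertoire(200, 1.8, 40_000, {"effector": 1.0}, seed=9,
                                      size_model="rank")
        spreads = []
        for sigma in (0.0, 0.5, 1.0, 2.0):
            sq = []
            for seed in range(8):
                reps = split_control_replicates(gt, 2, 10_000, 8_000,
                                                seed=seed, sigma=sigma)
                pair = make_pair(reps[0], reps[1], role="control")
                a, b = pair.counts()
                f_a, f_b = a / pair.depth_a, b / pair.depth_b
                sq.append(np.mean((f_a - f_b) ** 2))
            spreads.append(np.mean(sq))
        assert spreads[0] < spreads[1] < spreads[2] < spreads[3]

    def test_overdrawn_cells_rejected(self):
        gt = singleton_preset(100)
        with pytest.raises(DepthError):
            split_control_replicates(gt, 2, 60, 10, seed=0)

    def test_bit_reproducible(self):
        gt1 = tcell_paper_preset(5, total_cells=6_000)
        gt2 = tcell_paper_preset(5, total_cells=6_000)
        assert np.array_equal(gt1.cell_counts, gt2.cell_counts)
        assert list(gt1.cdr3_nt) == list(gt2.cdr3_nt)
        r1 = split_control_replicates(gt1, 2, 1_500, 1_200, seed=3)
        r2 = split_control_replicates(gt2, 2, 1_500, 1_200, seed=3)
        for a, b in zip(r1, r2):
            assert a.table.equals(b.table)

    def test_singleton_overlap_matches_closed_form(self):
        # two *independent* 10-cell draws from the 100-singleton tissue
        # (two sections of identical composition) share ~1 clone, the
        # textbook expected-overlap case.  Suspension-SPLIT replicates
        # instead partition cells, so their singleton overlap is 0 —
        # independent section sampling is the right design here.
        gt = singleton_preset(100)
        shared = []
        for seed in range(2_000):
            secs = generate_experimental_sections(
                gt, 2, 0, (1.0, 1.0), seed=seed,
                cells_per_section=10, umis_per_section=None, sigma=0.0,
                poisson=False,
            )
            shared.append(
                len(set(secs[0].table["cdr3_nt"]) & set(secs[1].table["cdr3_nt"]))
            )
        se = np.std(shared, ddof=1) / np.sqrt(len(shared))
        assert abs(np.mean(shared) - expected_overlap(10, 10, 100)) < 3 * se

    def test_split_replicates_partition_cells_exclusively(self):
        # the suspension-split design: a singleton cell lands in exactly
        # one replicate, so split replicates never share singleton clones
        gt = singleton_preset(100)
        reps = split_control_replicates(gt, 2, 10, None, seed=7,
                                        sigma=0.0, poisson=False)
        assert not set(reps[0].table["cdr3_nt"]) & set(reps[1].table["cdr3_nt"])


class TestExperimentalSections:
    def test_null_sections_carry_no_spikes(self):
        gt = tcell_paper_preset(3, total_cells=30_000)
        secs = generate_experimental_sections(gt, 2, 0, (8.0, 8.0), seed=1,
                                              cells_per_section=5_000,
                                              umis_per_section=4_000)
        assert gt.section_spikes == {"sec1": {}, "sec2": {}}
        assert len(secs) == 2

    def test_spiked_identities_recorded_with_folds(self):
        gt = tcell_paper_preset(4, total_cells=30_000)
        generate_experimental_sections(gt, 2, 5, (4.0, 16.0), seed=2,
                                       cells_per_section=5_000,
                                       umis_per_section=4_000)
        for sec in ("sec1", "sec2"):
            spikes = gt.section_spikes[sec]
            assert len(spikes) == 5
            assert all(4.0 <= f <= 16.0 for f in spikes.values())
            freqs = gt.frequencies()
            assert all(5e-4 <= freqs[i] <= 5e-3 for i in spikes)

    def test_invalid_fold_rejected(self):
        gt = singleton_preset(100)
        with pytest.raises(ValidationError):
            generate_experimental_sections(gt, 1, 1, (0.0, 2.0), seed=0,
                                           cells_per_section=10,
                                           umis_per_section=None)


class TestDepthMismatchScenario:
    def test_returns_two_null_pairs_at_10x_cell_ratio(self):
        gt = generate_base_repertoire(500, 1.8, 50_000, {"effector": 1.0},
                                      seed=11, size_model="rank")
        deep, shallow = depth_mismatch_scenario(gt, 20_000, 2_000, seed=1,
                                                umis_per_replicate=1_500)
        assert [r.n_cells for r in deep] == [20_000, 20_000]
        assert [r.n_cells for r in shallow] == [2_000, 2_000]
        assert all(r.total_umi == 1_500 for r in deep + shallow)

    def test_shallower_pair_correlates_worse(self):
        gt = generate_base_repertoire(500, 1.8, 50_000, {"effector": 1.0},
                                      seed=12, size_model="rank")
        r_deep, r_shallow = [], []
        for seed in range(6):
            deep, shallow = depth_mismatch_scenario(gt, 20_000, 2_000, seed=seed,
                                                    umis_per_replicate=1_500)
            r_deep.append(pairwise_correlation(make_pair(*deep, role="control")))
            r_shallow.append(pairwise_correlation(make_pair(*shallow, role="control")))
        assert np.median(r_shallow) < np.median(r_deep)

    def test_depth_order_enforced(self):
        gt = singleton_preset(100)
        with pytest.raises(ValidationError):
            depth_mismatch_scenario(gt, 10, 20, seed=0)


class TestStudyScalePresets:
    def test_tcell_preset_hits_cd8_like_clonality(self):
        gt = tcell_paper_preset(0)
        reps = split_control_replicates(gt, 2, 15_000, 13_000, seed=1)
        c = clonality(reps[0], target_umi=500, n_iterations=30, seed=2)
        assert 0.15 <= c.clonality_mean <= 0.35

    def test_control_replicates_correlate_better_than_spiked_sections(self):
        r_ctrl, r_expt = [], []
        for seed in range(8):
            gt = tcell_paper_preset(seed, total_cells=60_000)
            reps = split_control_replicates(gt, 2, 15_000, 13_000, seed=seed + 50)
            r_ctrl.append(pairwise_correlation(make_pair(reps[0], reps[1], role="control")))
            secs = generate_experimental_sections(
                gt, 2, 10, (4.0, 16.0), seed=seed + 90,
                cells_per_section=15_000, umis_per_section=13_000,
            )
            r_expt.append(pairwise_correlation(make_pair(secs[0], secs[1], role="experimental")))
        assert np.median(r_expt) < np.median(r_ctrl)
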