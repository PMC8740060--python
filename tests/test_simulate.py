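"""Generator contracts: determinism, planted truth, moment structure."""

import numpy as np
import pandas as pd
import pytest

import cistrans as ct
from cistrans.simulate import (
    GENERATIVE_CATEGORIES,
    INHERITANCE_MODES,
    ConfigurationError,
    SimulationConfig,
)


def _config(**overrides):
    base = dict(
        n_genes=100,
        category_proportions={"conserved": 1.0},
        base_mean_range=(500.0, 500.0),
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            _config(category_proportions={"conserved": 0.5, "cis_only": 0.4})

    def test_ambiguous_cannot_be_planted(self):
        with pytest.raises(ConfigurationError):
            _config(category_proportions={"conserved": 0.5, "ambiguous": 0.5})

    def test_ranges_and_dispersion_checked(self):
        with pytest.raises(ConfigurationError):
            _config(cis_fold_range=(8.0, 2.0))
        with pytest.raises(ConfigurationError):
            _config(dispersion=0.0)
        with pytest.raises(ConfigurationError):
            _config(base_mean_range=(-5.0, 10.0))

    def test_depth_factor_layout_checked(self):
        with pytest.raises(ConfigurationError):
            _config(n_replicates=3, library_depth_factors=(1.0, 1.0))


class TestRegulatoryCounts:
    def test_same_seed_is_byte_identical(self):
        c1, t1 = ct.simulate_regulatory_counts(_config())
        c2, t2 = ct.simulate_regulatory_counts(_config())
        assert c1.to_csv() == c2.to_csv()
        assert t1 == t2

    def test_one_record_per_gene(self):
        counts, truth = ct.simulate_regulatory_counts(_config(n_genes=50))
        assert len(counts) == 50 and len(truth) == 50
        assert counts["gene_id"].is_unique

    def test_truth_invariants_per_category(self):
        config = _config(
            n_genes=250,
            category_proportions={k: 0.2 for k in GENERATIVE_CATEGORIES},
        )
        _, truth = ct.simulate_regulatory_counts(config)
        for t in truth:
            if t.true_category == "conserved":
                assert t.c == 1.0 and t.t == 1.0
            elif t.true_category == "cis_only":
                assert t.c != 1.0 and t.t == 1.0
            elif t.true_category == "trans_only":
                assert t.c == 1.0 and t.t != 1.0
            elif t.true_category == "compensatory":
                assert t.c != 1.0 and t.t == pytest.approx(1.0 / t.c)
            else:
                assert t.c != 1.0 and t.t != 1.0
                assert not np.isclose(t.t, 1.0 / t.c)

    def test_conserved_null_is_symmetric(self):
        counts, _ = ct.simulate_regulatory_counts(_config(n_genes=600))
        frac = counts["P_pse"] / (counts["P_pse"] + counts["P_bog"])
        se = frac.std(ddof=1) / np.sqrt(len(frac))
        assert abs(frac.mean() - 0.5) < 3 * se

    def test_hybrid_fraction_tracks_cis_effect(self):
        # cis-only genes, |log2 c| = 2, mu = 500: the hybrid allelic
        # fraction estimates c/(1+c) per gene
        config = _config(
            n_genes=600,
            category_proportions={"cis_only": 1.0},
            cis_fold_range=(4.0, 4.0),
            seed=42,
        )
        counts, truth = ct.simulate_regulatory_counts(config)
        c = np.array([t.c for t in truth])
        frac = (counts["H_pse"] / (counts["H_pse"] + counts["H_bog"])).to_numpy()
        resid = frac - c / (1 + c)
        se = resid.std(ddof=1) / np.sqrt(len(resid))
        assert abs(resid.mean()) < 3 * se
        # and the parental fraction estimates c*t/(1+c*t) with t = 1
        pfrac = (counts["P_pse"] / (counts["P_pse"] + counts["P_bog"])).to_numpy()
        presid = pfrac - c / (1 + c)
        pse = presid.std(ddof=1) / np.sqrt(len(presid))
        assert abs(presid.mean()) < 3 * pse

    def test_compensatory_parents_balanced_hybrid_skewed(self):
        config = _config(
            n_genes=500,
            category_proportions={"compensatory": 1.0},
            cis_fold_range=(4.0, 4.0),
            seed=9,
        )
        counts, truth = ct.simulate_regulatory_counts(config)
        pfrac = counts["P_pse"] / (counts["P_pse"] + counts["P_bog"])
        se = pfrac.std(ddof=1) / np.sqrt(len(pfrac))
        assert abs(pfrac.mean() - 0.5) < 3 * se  # c*t = 1 forces symmetry
        c = np.array([t.c for t in truth])
        hfrac = (counts["H_pse"] / (counts["H_pse"] + counts["H_bog"])).to_numpy()
        resid = hfrac - c / (1 + c)
        hse = resid.std(ddof=1) / np.sqrt(len(resid))
        assert abs(resid.mean()) < 3 * hse


class TestGeneAnnotation:
    LENGTHS = {"X": 20_000_000, "2": 12_000_000}

    def test_empty_request(self):
        assert ct.simulate_gene_annotation(0, self.LENGTHS) == []

    def test_deterministic(self):
        a = ct.simulate_gene_annotation(100, self.LENGTHS, seed=5)
        b = ct.simulate_gene_annotation(100, self.LENGTHS, seed=5)
        assert a == b

    def test_loci_do_not_overlap(self):
        loci = ct.simulate_gene_annotation(200, self.LENGTHS, seed=5)
        by_chrom = {}
        for l in loci:
            by_chrom.setdefault(l.chromosome, []).append(l)
        for genes in by_chrom.values():
            genes.sort(key=lambda l: l.start)
            for prev, cur in zip(genes, genes[1:]):
                assert cur.start > prev.end

    def test_planted_cluster_round_trip(self):
        loci = ct.simulate_gene_annotation(
            40, self.LENGTHS, planted_clusters=[("X", 1251)], seed=3
        )
        clusters = ct.detect_clusters(loci, max_gap=5500)
        assert len(clusters) == 1
        assert clusters[0].gaps == (1251,)
        assert set(clusters[0].gene_ids) == {"clu0_a", "clu0_b"}

    def test_capacity_error(self):
        with pytest.raises(ValueError):
            ct.simulate_gene_annotation(500, {"X": 100_000}, seed=0)


class TestAlignmentPanel:
    def test_planted_fixed_round_trip(self):
        panel, truth = ct.simulate_alignment_panel(31, 5, 1000, 7, 3, 2, seed=8)
        n, positions = ct.count_fixed_differences(panel)
        assert n == 7 and positions == truth["fixed"]
        assert ct.count_polymorphisms(panel, "pse") == 3
        assert ct.count_polymorphisms(panel, "bog") == 2

    def test_no_fixed_sites(self):
        panel, _ = ct.simulate_alignment_panel(5, 4, 300, 0, 3, 0, seed=1)
        assert ct.count_fixed_differences(panel)[0] == 0
        assert ct.count_polymorphisms(panel, "bog") == 0

    def test_site_budget_error(self):
        with pytest.raises(ValueError):
            ct.simulate_alignment_panel(3, 3, 10, 8, 2, 2, seed=0)

    def test_protein_alphabet(self):
        panel, truth = ct.simulate_alignment_panel(
            6, 3, 150, 4, alphabet="protein", seed=2
        )
        assert panel.alphabet == "protein"
        assert ct.count_fixed_differences(panel)[0] == 4

    def test_deterministic(self):
        p1, _ = ct.simulate_alignment_panel(4, 4, 200, 3, 1, 1, seed=6)
        p2, _ = ct.simulate_alignment_panel(4, 4, 200, 3, 1, 1, seed=6)
        assert p1.sequences == p2.sequences


class TestInheritanceCounts:
    def test_deterministic(self):
        a1 = ct.simulate_inheritance_counts(50, {"additive": 1.0}, seed=4)
        a2 = ct.simulate_inheritance_counts(50, {"additive": 1.0}, seed=4)
        for m1, m2 in zip(a1[:3], a2[:3]):
            pd.testing.assert_frame_equal(m1, m2)
        assert a1[3] == a2[3]

    def test_mode_means_are_ordered_as_planted(self):
        pa, pb, hy, modes = ct.simulate_inheritance_counts(
            400,
            {m: 0.25 for m in INHERITANCE_MODES},
            fold=4.0,
            depth=500.0,
            seed=12,
        )
        modes = np.array(modes)
        up = modes == "transgressive_up"
        down = modes == "transgressive_down"
        add = modes == "additive"
        # hybrid mean = fold * parents for up, parents / fold for down,
        # parental midpoint for additive (group-level, 10% tolerance)
        assert hy.values[up].mean() == pytest.approx(
            4.0 * pa.values[up].mean(), rel=0.1
        )
        assert hy.values[down].mean() == pytest.approx(
            pa.values[down].mean() / 4.0, rel=0.1
        )
        mid = (pa.values[add].mean() + pb.values[add].mean()) / 2
        assert hy.values[add].mean() == pytest.approx(mid, rel=0.1)

    def test_null_genes_recovered_as_non_differential(self):
        pa, pb, hy, _ = ct.simulate_inheritance_counts(
            200, {"non_differential": 1.0}, fold=1.0, depth=500.0, seed=42
        )
        calls = ct.classify_inheritance_table(hy, pa, pb, alpha=0.05, lfc_threshold=1.0)
        assert (calls["mode"] == "non_differential").mean() >= 0.90

    def test_proportions_validated(self):
        with pytest.raises(ConfigurationError):
            ct.simulate_inheritance_counts(10, {"additive": 0.7}, seed=0)
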