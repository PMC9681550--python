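"""Generator contracts: determinism, ground-truth bookkeeping, calibration."""

import numpy as np
import pandas as pd
import pytest

from tsrnakit import catalog as cat
from tsrnakit import cohort as coh
from tsrnakit import simulate as sim


class TestGenes:
    def test_fixed_seed_is_byte_identical(self, tmp_path):
        out = []
        for i in range(2):
            genes, genome, _ = sim.simulate_trna_genes(5, seed=123)
            p = tmp_path / f"g{i}.fa"
            sim.write_genome_fasta(genome, p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_family_copies_share_sequence_under_distinct_ids(self):
        genes, _, truth = sim.simulate_trna_genes(8, seed=4, family_copies=3)
        fam = [g for g in genes if truth["genes"][g.gene_id]["family"]]
        assert len(fam) == 3
        bodies = {truth["genes"][g.gene_id]["mature_body"] for g in fam}
        assert len(bodies) == 1
        assert len({g.gene_id for g in fam}) == 3

    def test_intron_genes_emitted_and_spliceable(self):
        for seed in range(8):
            genes, genome, truth = sim.simulate_trna_genes(
                12, seed=seed, intron_prob=0.5)
            two_exon = [g for g in genes if len(g.exon_spans) > 1]
            if two_exon:
                models = cat.build_reference_models(genes, genome)
                for g in two_exon:
                    assert models.matures[g.gene_id].sequence == \
                        truth["genes"][g.gene_id]["mature"]
                return
        pytest.fail("no intron gene emitted over 8 seeds at p=0.5")

    def test_annotation_bed_round_trips_through_loader(self, tmp_path):
        from tsrnakit.reference import load_trna_annotation

        genes, genome, truth = sim.simulate_trna_genes(10, seed=7, intron_prob=0.3)
        sim.write_genome_fasta(genome, tmp_path / "g.fa")
        sim.write_annotation_bed(genes, tmp_path / "g.bed")
        loaded = load_trna_annotation(tmp_path / "g.bed", tmp_path / "g.fa")
        assert len(loaded) == len(genes)
        for orig, back in zip(genes, loaded):
            assert back.gene_id == orig.gene_id
            assert back.genomic_sequence == orig.genomic_sequence
            assert back.spliced_sequence == orig.spliced_sequence


class TestCatalog:
    def test_mixture_recovered_within_binomial_tolerance(self):
        genes, genome, _ = sim.simulate_trna_genes(40, seed=15)
        models = cat.build_reference_models(genes, genome)
        mixture = {"tRF-5": 0.26, "tRF-3": 0.33, "i-tRF": 0.21,
                   "tRF-1": 0.12, "5'U-tRF": 0.08}
        _, truth = sim.simulate_catalog(models, mixture, n_fragments=300, seed=5)
        props = truth["true_type"].value_counts(normalize=True)
        for t, p in mixture.items():
            assert abs(props.get(t, 0.0) - p) < 0.05

    def test_all_trf3_mixture_ends_in_cca(self, small_reference):
        records, _ = sim.simulate_catalog(
            small_reference["models"], {"tRF-3": 1.0}, n_fragments=40, seed=6)
        assert all(r.sequence.endswith("CCA") for r in records)

    def test_truth_round_trips_through_classifier(self, classified_catalog):
        truth = classified_catalog["truth"]
        got = pd.Series({r.fragment_id: r.type for r in classified_catalog["records"]})
        assert (got.loc[truth.index] == truth["true_type"]).all()


class TestReads:
    def test_zero_decoys_means_zero_unmapped(self, classified_catalog):
        records = classified_catalog["records"][:20]
        reads, truth = sim.simulate_reads(
            records, {r.fragment_id: 1.0 for r in records},
            reads_per_sample=500, seed=1, decoy_fraction=0.0)
        assert truth["n_unmapped"] == 0
        assert len(reads) == 500

    def test_doubling_abundance_roughly_doubles_count(self, classified_catalog):
        records = classified_catalog["records"][:10]
        base = {r.fragment_id: 1.0 for r in records}
        fid = records[0].fragment_id
        hi = dict(base)
        hi[fid] = 2.0
        _, t1 = sim.simulate_reads(records, base, reads_per_sample=40000, seed=2,
                                   decoy_fraction=0.0)
        _, t2 = sim.simulate_reads(records, hi, reads_per_sample=40000, seed=2,
                                   decoy_fraction=0.0)
        r = t2["unique_counts"][fid] / t1["unique_counts"][fid]
        assert r == pytest.approx(2.0 * 40000 / 44000 / (40000 / 40000), rel=0.1)


class TestCohort:
    def test_null_hazard_gives_uniform_logrank_p(self):
        # hazard_ratio=1: rejection at alpha=.05 stays near nominal
        rng = np.random.default_rng(50)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            cfg = sim.SimulationConfig(
                seed=int(rng.integers(2**31)), n_tumor=20, n_nontumor=20,
                survival_hazard_ratio=1.0, n_planted=0)
            out = sim.simulate_cohort([f"f{i}" for i in range(10)], cfg)
            ann = out["annotation"].dropna(subset=["survival_time"])
            _, p = coh.logrank_test(ann["survival_time"], ann["event"],
                                    ann["expr_group_truth"])
            if not np.isnan(p) and p < 0.05:
                rejections += 1
        assert 0.01 <= rejections / n_rep <= 0.09

    def test_strong_hazard_is_detected(self):
        rng = np.random.default_rng(60)
        hits = 0
        for _ in range(20):
            # 120 tumor patients: the median split yields 60 per arm
            cfg = sim.SimulationConfig(
                seed=int(rng.integers(2**31)), n_tumor=120, n_nontumor=10,
                survival_hazard_ratio=3.0)
            out = sim.simulate_cohort([f"f{i}" for i in range(10)], cfg)
            ann = out["annotation"].dropna(subset=["survival_time"])
            _, p = coh.logrank_test(ann["survival_time"], ann["event"],
                                    ann["expr_group_truth"])
            if p < 0.05:
                hits += 1
        assert hits >= 18

    def test_low_group_has_higher_hazard_direction(self):
        cfg = sim.SimulationConfig(seed=77, n_tumor=100, n_nontumor=100,
                                   survival_hazard_ratio=4.0,
                                   censoring_fraction=0.0)
        out = sim.simulate_cohort([f"f{i}" for i in range(5)], cfg)
        ann = out["annotation"].dropna(subset=["survival_time"])
        low = ann["expr_group_truth"] == "low"
        assert ann.loc[low, "survival_time"].median() < \
            ann.loc[~low, "survival_time"].median()

    def test_censoring_fraction_calibrated(self):
        cfg = sim.SimulationConfig(seed=13, n_tumor=300, n_nontumor=300,
                                   censoring_fraction=0.3,
                                   survival_hazard_ratio=1.0)
        out = sim.simulate_cohort(["f0"], cfg)
        censored = 1 - out["annotation"]["event"].dropna().mean()
        assert censored == pytest.approx(0.3, abs=0.06)

    def test_feature_association_has_configured_direction(self):
        cfg = sim.SimulationConfig(seed=5, n_tumor=200, n_nontumor=200,
                                   feature_odds=6.0)
        out = sim.simulate_cohort([f"f{i}" for i in range(5)], cfg)
        ann = out["annotation"][out["annotation"]["group"] == "tumor"]
        tab = pd.crosstab(ann["expr_group_truth"], ann["IDH_status"])
        odds = (tab.loc["high", "mutant"] * tab.loc["low", "wildtype"]) / (
            tab.loc["high", "wildtype"] * tab.loc["low", "mutant"])
        assert odds > 3

    def test_planted_mrna_correlation_top_ranked(self):
        cfg = sim.SimulationConfig(seed=101, n_tumor=50, n_nontumor=50)
        fids = [f"f{i}" for i in range(10)]
        out = sim.simulate_cohort(
            fids, cfg, n_mrna=100,
            planted_correlations={"GENE0001": ("f0", 0.6)})
        counts = out["counts"]
        rpm = counts.div(counts.sum(axis=0), axis=1) * 1e6
        res = coh.correlate_with_mrna(np.log2(rpm.loc["f0"] + 1), out["mrna"],
                                      "spearman")
        top5 = res.sort_values("effect", ascending=False).head(5).index
        assert "GENE0001" in top5
        assert res.loc["GENE0001", "effect"] == pytest.approx(0.6, abs=0.2)


class TestUTRs:
    def test_truth_offsets_are_exact(self):
        frag = "GATCGCGATATACCGTAA"
        utrs, truth = sim.simulate_utrs({"fx": frag}, n_targets=15,
                                        planted_sites=8, seed=3)
        from tsrnakit.targets import find_seed_sites

        for row in truth.itertuples():
            assert row.seed_site in find_seed_sites(frag, utrs[row.target_id])

    def test_lengths_in_configured_range(self):
        utrs, _ = sim.simulate_utrs({"fx": "GATCGCGATATACCGTAA"}, n_targets=30,
                                    planted_sites=0, seed=4,
                                    length_range=(300, 2000))
        assert all(300 <= len(s) <= 2000 for s in utrs.values())

    def test_determinism(self):
        u1, t1 = sim.simulate_utrs({"fx": "GATCGCGATATACCGTAA"}, 10, 5, seed=9)
        u2, t2 = sim.simulate_utrs({"fx": "GATCGCGATATACCGTAA"}, 10, 5, seed=9)
        assert u1 == u2
        assert t1.equals(t2)


def test_config_validates_mixture():
    with pytest.raises(ValueError, match="mixture"):
        sim.SimulationConfig(type_mixture={"tRF-5": 0.5})
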