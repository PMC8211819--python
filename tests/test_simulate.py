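"""Synthetic-data generator: determinism, planted structure, truth tables."""

import numpy as np
import pandas as pd
import pytest

from oracles import naive_plus_hits
from rloopkit import io, metrics, rlfs, simulate
from rloopkit.simulate import SimulationConfig


class TestConfigValidation:
    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="cohort_rho"):
            SimulationConfig(cohort_rho=1.5)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0)

    def test_effect_below_one_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(rlfs_enrichment_effect=0.5)

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig.from_dict({"seed": 1, "n_loci": 5})


class TestGenome:
    def test_zero_rate_gives_background_only(self):
        config = SimulationConfig(seed=1, n_chromosomes=1, chrom_length_bp=20_000,
                                  planted_rlfs_rate=0.0)
        seqs, truth = simulate.simulate_genome(config)
        assert len(truth.planted_rlfs) == 0
        assert len(seqs["chr1"]) == 20_000
        assert set(seqs["chr1"]) <= set("ACGT")

    def test_identical_config_and_seed_give_identical_fasta_bytes(self, tmp_path):
        config = SimulationConfig(seed=4, n_chromosomes=1, chrom_length_bp=50_000,
                                  planted_rlfs_rate=5.0)
        for sub in ("a", "b"):
            seqs, _ = simulate.simulate_genome(config)
            io.write_fasta(seqs, tmp_path / f"{sub}.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_planted_spans_match_the_cassette_pattern(self):
        config = SimulationConfig(seed=1, n_chromosomes=1, chrom_length_bp=100_000,
                                  planted_rlfs_rate=5.0)
        seqs, truth = simulate.simulate_genome(config)
        assert len(truth.planted_rlfs) > 0
        for _, row in truth.planted_rlfs.iterrows():
            span = seqs[row["chrom"]][row["start"] : row["end"]]
            if row["strand"] == "-":
                span = rlfs.revcomp(span)
            # the naive scanner finds an initiation zone at the cassette start
            assert any(start == 0 for start, _ in naive_plus_hits(span))

    def test_planted_loci_within_bounds_and_disjoint(self):
        config = SimulationConfig(seed=2, n_chromosomes=2, chrom_length_bp=80_000,
                                  planted_rlfs_rate=15.0)
        seqs, truth = simulate.simulate_genome(config)
        for chrom, grp in truth.planted_rlfs.groupby("chrom"):
            assert grp["start"].min() >= 0
            assert grp["end"].max() <= len(seqs[chrom])
            sorted_grp = grp.sort_values("start")
            assert (sorted_grp["start"].values[1:] >= sorted_grp["end"].values[:-1]).all()

    def test_chromosome_too_short_raises(self):
        config = SimulationConfig(seed=3, n_chromosomes=1, chrom_length_bp=100,
                                  planted_rlfs_rate=5000.0, n_genes=1)
        with pytest.raises(ValueError, match="short"):
            simulate.simulate_genome(config)


class TestAnnotation:
    def test_genes_non_overlapping_stranded_with_exons(self, default_sim):
        genes = default_sim["genes"]
        assert (genes["exon_count"] >= 1).all()
        assert set(genes["strand"]) <= {"+", "-"}
        for _, grp in genes.groupby("chrom"):
            g = grp.sort_values("start")
            assert (g["start"].values[1:] >= g["end"].values[:-1]).all()

    def test_impossible_gene_count_raises_naming_constraint(self):
        config = SimulationConfig(seed=5, n_chromosomes=1, chrom_length_bp=10_000,
                                  n_genes=200, mean_gene_length_bp=400)
        seqs, truth = simulate.simulate_genome(config)
        with pytest.raises(ValueError, match="cannot place"):
            simulate.simulate_annotation(config, seqs, truth)

    def test_gene_table_round_trips_through_bed6(self, default_sim, tmp_path):
        genes = default_sim["genes"]
        path = tmp_path / "genes.bed"
        io.write_bed6(io.genes_to_bed6(genes), path)
        back = io.bed6_to_genes(io.read_bed6(path))
        for col in ("gene_id", "chrom", "start", "end", "strand", "exon_count"):
            assert list(back[col]) == list(genes[col])

    def test_no_effect_gives_similar_responder_overlap_rates(self):
        config = SimulationConfig(seed=6, rlfs_enrichment_effect=1.0)
        art = simulate.simulate_all(config)
        genes, truth = art["genes"], art["truth"]
        planted = truth.planted_rlfs

        def overlaps(row):
            sel = (
                (planted["chrom"] == row["chrom"])
                & (planted["strand"] == row["strand"])
                & (planted["start"] < row["end"] + 2000)
                & (planted["end"] > row["start"] - 2000)
            )
            return sel.any()

        genes = genes[genes["biotype"] == "protein_coding"].copy()
        genes["hit"] = genes.apply(overlaps, axis=1)
        is_resp = genes["gene_id"].isin(truth.responder_genes)
        p_resp = genes.loc[is_resp, "hit"].mean()
        p_other = genes.loc[~is_resp, "hit"].mean()
        assert abs(p_resp - p_other) < 0.2  # binomial noise only

    def test_strong_effect_raises_responder_rlfs_density(self, default_sim):
        art = default_sim
        hits = rlfs.scan_genome(art["sequences"])
        merged = rlfs.merge_hits(hits)
        table = metrics.compute_gene_metrics(art["genes"], merged, art["sequences"])
        table = table.set_index(art["genes"]["gene_id"].values)
        resp = list(art["truth"].responder_genes)
        others = [g for g in table.index if g not in art["truth"].responder_genes]
        assert table.loc[resp, "rlfs_per_kb"].mean() > table.loc[others, "rlfs_per_kb"].mean()


class TestExpression:
    def test_shape_groups_and_determinism(self, default_sim):
        counts, design = default_sim["counts"], default_sim["design"]
        config = SimulationConfig(seed=3)
        assert counts.shape == (config.n_genes, 4 * config.n_samples_per_group)
        assert set(design["group"]) == set(simulate.GROUPS)
        again = simulate.simulate_all(config)
        pd.testing.assert_frame_equal(counts, again["counts"])

    def test_library_sizes_within_three_fold(self, default_sim):
        totals = default_sim["counts"].sum(axis=0)
        assert totals.max() / totals.min() < 3.0

    def test_responders_shift_only_in_knockdown_hypoxia(self, default_sim):
        counts, design = default_sim["counts"], default_sim["design"]
        truth = default_sim["truth"].responder_genes
        groups = design.set_index("sample")["group"]
        up = [g for g, d in truth.items() if d == 1]
        kd = counts.loc[up, groups[groups == "siSETX_hyp"].index].mean(axis=1)
        ctrl = counts.loc[up, groups[groups == "siCTRL_hyp"].index].mean(axis=1)
        norm_kd = counts.loc[up, groups[groups == "siSETX_norm"].index].mean(axis=1)
        norm_ctrl = counts.loc[up, groups[groups == "siCTRL_norm"].index].mean(axis=1)
        # ~4-fold in knockdown-hypoxia, none in normoxia (geometric means)
        assert np.log2((kd + 0.5) / (ctrl + 0.5)).mean() > 1.5
        assert abs(np.log2((norm_kd + 0.5) / (norm_ctrl + 0.5)).mean()) < 0.5


class TestWriteSimulation:
    def test_manifest_checksums_reproducible(self, tmp_path):
        config = SimulationConfig(seed=13, n_chromosomes=1, chrom_length_bp=60_000,
                                  n_genes=60, cohort_n=40)
        m1 = simulate.write_simulation(config, tmp_path / "run1")
        m2 = simulate.write_simulation(config, tmp_path / "run2")
        assert m1["checksums"] == m2["checksums"]
        assert (tmp_path / "run1" / "genome.fa").exists()

    def test_different_seed_changes_outputs(self, tmp_path):
        a = simulate.write_simulation(
            SimulationConfig(seed=1, n_chromosomes=1, chrom_length_bp=60_000,
                             n_genes=60, cohort_n=40), tmp_path / "a")
        b = simulate.write_simulation(
            SimulationConfig(seed=2, n_chromosomes=1, chrom_length_bp=60_000,
                             n_genes=60, cohort_n=40), tmp_path / "b")
        assert a["checksums"]["genome.fa"] != b["checksums"]["genome.fa"]
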