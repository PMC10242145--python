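"""Synthetic-data generator: determinism, placement, planted structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from neutronet.expression import call_enriched_genes, compute_tpm
from neutronet.motifs import scan_pwm
from neutronet.simulate import (CapacityError, SimulationDesign, default_design,
                                decode_genome, generate_atac, generate_expression,
                                generate_genome, generate_methylation,
                                generate_motifs_and_ppi, simulate_dataset)


class TestGenerateGenome:
    def test_empty_design(self):
        d = SimulationDesign(n_genes=0, n_chromosomes=1, chromosome_length=200_000)
        seqs, ann = generate_genome(d)
        assert ann.n_genes == 0
        assert len(seqs["chr1"]) == 200_000

    def test_determinism(self):
        d = SimulationDesign(n_genes=50, n_chromosomes=1,
                             chromosome_length=1_000_000, seed=7)
        s1, a1 = generate_genome(d)
        s2, a2 = generate_genome(d)
        assert all(np.array_equal(s1[c], s2[c]) for c in s1)
        pd.testing.assert_frame_equal(a1.genes, a2.genes)

    def test_min_tss_spacing(self):
        d = SimulationDesign(n_genes=50, n_chromosomes=1,
                             chromosome_length=1_000_000, seed=7)
        _, ann = generate_genome(d)
        for _, sub in ann.genes.groupby("chrom"):
            tss = np.sort(sub["tss"].to_numpy())
            assert np.diff(tss).min() >= 8000

    def test_capacity_error(self):
        d = SimulationDesign(n_genes=500, n_chromosomes=1, chromosome_length=200_000)
        with pytest.raises(CapacityError):
            generate_genome(d)

    def test_strands_and_gene_lengths(self):
        d = SimulationDesign(n_genes=100, n_chromosomes=2,
                             chromosome_length=1_000_000, seed=3)
        _, ann = generate_genome(d)
        assert set(ann.genes["strand"]) == {"+", "-"}
        assert ann.genes["length"].between(1000, 20_000).all()


class TestGenerateExpression:
    def test_determinism(self):
        d = default_design(seed=5, n_genes=150)
        _, ann = generate_genome(d)
        m1, _ = generate_expression(d, ann)
        m2, _ = generate_expression(d, ann)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_planted_fold_change_recovered(self):
        # FC = 10 at base_mean 500 -> empirical cross-cell-type ratio in [5, 20]
        ids = [f"G{i:04d}" for i in range(1, 101)]
        d = SimulationDesign(n_genes=100, n_chromosomes=1,
                             chromosome_length=1_000_000, base_mean=500,
                             nb_dispersion=0.05, seed=9,
                             enriched_gene_plan={"neutrophil": {ids[0]: 10.0}})
        _, ann = generate_genome(d)
        m, truth = generate_expression(d, ann)
        means = m.cell_type_means()
        own = means.loc[ids[0], "neutrophil"]
        rest = means.loc[ids[0]].drop("neutrophil").mean()
        assert 5 <= own / rest <= 20
        assert truth.true_enriched["neutrophil"] == [ids[0]]

    def test_null_design_rarely_calls_segs(self):
        d = SimulationDesign(n_genes=400, n_chromosomes=1,
                             chromosome_length=4_000_000, base_mean=500,
                             nb_dispersion=0.05, seed=13)
        _, ann = generate_genome(d)
        m, _ = generate_expression(d, ann)
        e = call_enriched_genes(compute_tpm(m))
        frac = e.table["seg"].mean()
        assert frac <= 0.05

    def test_module_genes_coexpressed(self):
        d = default_design(seed=2, n_genes=150)
        _, ann = generate_genome(d)
        m, _ = generate_expression(d, ann)
        tf, _, targets = d.tf_module_plan[0]
        sub = np.log2(m.values.loc[targets[:6]].to_numpy() + 1.0)
        r = np.corrcoef(sub)
        iu = np.triu_indices(len(sub), 1)
        assert np.median(r[iu]) >= 0.95


class TestGenerateAtac:
    def test_no_accessible_genes_no_promoter_overlap(self):
        d = SimulationDesign(n_genes=50, n_chromosomes=1,
                             chromosome_length=1_000_000, seed=3)
        _, ann = generate_genome(d)
        peaks = generate_atac(d, ann)
        prom = ann.promoters(3000)
        for _, pr in prom.iterrows():
            sub = peaks.peaks[peaks.peaks["chrom"] == pr["chrom"]]
            assert not ((sub["start"] < pr["end"]) & (sub["end"] > pr["start"])).any()

    def test_width_mean_near_one_kb(self):
        d = SimulationDesign(n_genes=0, n_chromosomes=1,
                             chromosome_length=2_000_000,
                             n_background_peaks=1000, seed=4)
        _, ann = generate_genome(d)
        peaks = generate_atac(d, ann)
        assert 800 <= peaks.widths.mean() <= 1200

    def test_replicate_concordance(self):
        d = default_design(seed=8, n_genes=150)
        _, ann = generate_genome(d)
        m, truth = generate_expression(d, ann)
        peaks = generate_atac(d, ann, gene_means=truth.expected_mean)
        r = np.corrcoef(np.log2(peaks.counts["atac_r1"] + 1),
                        np.log2(peaks.counts["atac_r2"] + 1))[0, 1]
        assert r > 0.9

    def test_promoter_counts_elevated(self):
        d = default_design(seed=8, n_genes=150)
        _, ann = generate_genome(d)
        m, truth = generate_expression(d, ann)
        peaks = generate_atac(d, ann, gene_means=truth.expected_mean)
        is_prom = peaks.counts.index.str.startswith("peak_")
        assert peaks.counts[is_prom].mean().mean() >= 4 * peaks.counts[~is_prom].mean().mean()


class TestGenerateMethylation:
    def test_background_mean_without_planting(self):
        d = SimulationDesign(n_genes=30, n_chromosomes=1,
                             chromosome_length=500_000, seed=5)
        _, ann = generate_genome(d)
        track, planted = generate_methylation(d, ann)
        assert planted == []
        assert 0.75 <= track.mean_rate() <= 0.85

    def test_planted_promoters_hypomethylated(self):
        d = default_design(seed=5, n_genes=150)
        _, ann = generate_genome(d)
        track, planted = generate_methylation(d, ann)
        data = track.data
        rates = []
        for chrom, lo, hi in planted:
            sel = data[(data.chrom == chrom) & (data.start >= lo) & (data.start < hi)]
            rates.append(sel["rate"].mean())
        assert np.mean(rates) < 0.3
        assert data["rate"].between(0, 1).all()


class TestGenerateMotifsAndPpi:
    def make(self, seed=3, both_strands=False):
        d = default_design(seed=seed, n_genes=150)
        d = dataclasses.replace(d, motif_both_strands=both_strands)
        genome, ann = generate_genome(d)
        pwms, ppi, placements = generate_motifs_and_ppi(d, genome, ann)
        return d, genome, ann, pwms, ppi, placements

    def test_consensus_planted_at_recorded_offset(self):
        d, genome, ann, pwms, _, placements = self.make()
        seqs = decode_genome(genome)
        by_id = {p.motif_id: p for p in pwms}
        for gene, (chrom, pos, strand, pwm_id) in placements.items():
            pwm = by_id[pwm_id]
            window = seqs[chrom][pos:pos + pwm.length]
            assert window == pwm.consensus
            hits = scan_pwm(window, pwm)
            assert hits and hits[0][2] == pytest.approx(pwm.max_score)

    def test_non_target_promoters_lack_consensus(self):
        d, genome, ann, pwms, _, placements = self.make()
        seqs = decode_genome(genome)
        non_targets = [g for g in ann.genes.index if g not in placements][:60]
        false_hits = 0
        for g in non_targets:
            info = ann.genes.loc[g]
            lo = max(int(info["tss"]) - 3000, 0)
            hi = int(info["tss"]) + 3000
            seq = seqs[info["chrom"]][lo:hi]
            for p in pwms:
                false_hits += p.consensus in seq
        # expected occurrences per promoter: ~12 kb windows * (1/4)^12 << 1
        assert false_hits <= 1

    def test_determinism_and_both_strand_flag(self):
        _, _, _, p1, ppi1, pl1 = self.make(seed=4)
        _, _, _, p2, ppi2, pl2 = self.make(seed=4)
        assert pl1 == pl2
        assert all(np.array_equal(a.matrix, b.matrix) for a, b in zip(p1, p2))
        pd.testing.assert_frame_equal(ppi1, ppi2)
        _, _, _, _, _, pl_both = self.make(seed=4, both_strands=True)
        assert {s for _, _, s, _ in pl_both.values()} == {"+", "-"}

    def test_empty_module_plan_rejected(self):
        d = SimulationDesign(n_genes=10, n_chromosomes=1, chromosome_length=200_000)
        genome, ann = generate_genome(d)
        with pytest.raises(ValueError):
            generate_motifs_and_ppi(d, genome, ann)


class TestSimulateDataset:
    def test_byte_identical_outputs(self, tmp_path):
        d = default_design(seed=21, n_genes=150)
        p1 = simulate_dataset(d, tmp_path / "a")
        p2 = simulate_dataset(d, tmp_path / "b")
        for key in p1:
            b1 = open(p1[key], "rb").read()
            b2 = open(p2[key], "rb").read()
            assert b1 == b2, f"{key} differs between identical runs"

    def test_different_seed_different_data(self, tmp_path):
        pa = simulate_dataset(default_design(seed=1, n_genes=150), tmp_path / "a")
        pb = simulate_dataset(default_design(seed=2, n_genes=150), tmp_path / "b")
        assert open(pa["expression"]).read() != open(pb["expression"]).read()
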