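import numpy as np
import pytest

from ltrcall import detection as D
from ltrcall import synthetic_data as S


class TestTEConsensus:
    def test_ltr_identity_invariant(self):
        te = S.build_te_consensus(np.random.default_rng(1), 5000, 400)
        assert te.sequence[0:400] == te.sequence[4600:5000]

    def test_degenerate_single_bp_ltr(self):
        te = S.build_te_consensus(np.random.default_rng(1), 100, 1)
        assert te.ltr_len == 1 and te.ltr5_seq == te.ltr3_seq

    @pytest.mark.parametrize("seed", range(5))
    def test_seeds_differ_but_keep_ltr_identity(self, seed):
        a = S.build_te_consensus(np.random.default_rng(seed), 2000, 200)
        b = S.build_te_consensus(np.random.default_rng(seed + 100), 2000, 200)
        assert a.ltr5_seq == a.ltr3_seq and b.ltr5_seq == b.ltr3_seq
        assert a.sequence != b.sequence

    def test_ltr_too_long_rejected(self):
        with pytest.raises(ValueError):
            S.build_te_consensus(np.random.default_rng(0), 100, 50)


class TestToyGenome:
    def test_zero_het_fraction(self):
        cfg = S.SimulationConfig(het_fraction=0.0, n_te_copies=3,
                                 chrom_length=60_000, n_chromosomes=1)
        toy = S.build_toy_genome(cfg, np.random.default_rng(2))
        assert toy.heterochromatin == []

    def test_fixed_seed_determinism(self):
        cfg = S.SimulationConfig(chrom_length=50_000, n_chromosomes=2, n_te_copies=2)
        a = S.build_toy_genome(cfg, np.random.default_rng(9))
        b = S.build_toy_genome(cfg, np.random.default_rng(9))
        assert all(a.assembly[c] == b.assembly[c] for c in a.assembly)
        assert len(a.annotation.genes) == len(b.annotation.genes)

    def test_heterochromatin_total_matches_config(self):
        cfg = S.SimulationConfig(n_chromosomes=5, chrom_length=400_000,
                                 het_fraction=0.15, n_te_copies=5)
        toy = S.build_toy_genome(cfg, np.random.default_rng(4))
        total = sum(len(iv) for iv in toy.heterochromatin)
        assert total == 5 * round(400_000 * 0.15)

    def test_majority_of_copies_in_heterochromatin(self):
        cfg = S.SimulationConfig()
        toy = S.build_toy_genome(cfg, np.random.default_rng(0))
        in_het = sum(
            any(h.chrom == t.interval.chrom and h.start <= t.interval.start < h.end
                for h in toy.heterochromatin)
            for t in toy.annotation.te_features)
        assert in_het > len(toy.annotation.te_features) / 2


class TestPlanting:
    def test_length_arithmetic(self):
        for tsd in (0, 5):
            cfg = S.SimulationConfig(n_chromosomes=1, chrom_length=100_000,
                                     n_insertions=3, n_te_copies=0, tsd_len=tsd)
            rng = np.random.default_rng(6)
            toy = S.build_toy_genome(cfg, rng)
            mut = S.plant_insertions(toy, cfg, rng)
            expected = toy.assembly.total_length + 3 * (cfg.element_len + tsd)
            assert mut.assembly.total_length == expected

    def test_tsd_duplicated_around_element(self):
        cfg = S.SimulationConfig(n_chromosomes=1, chrom_length=80_000,
                                 n_insertions=1, n_te_copies=0, tsd_len=5)
        rng = np.random.default_rng(8)
        toy = S.build_toy_genome(cfg, rng)
        mut = S.plant_insertions(toy, cfg, rng)
        ins = mut.truth[0]
        ref = toy.assembly[ins.chrom]
        tsd = ref[ins.pos : ins.pos + 5]
        mutseq = mut.assembly[ins.chrom]
        elem_start = ins.pos + 5
        assert mutseq[elem_start - 5 : elem_start] == tsd
        assert mutseq[elem_start + cfg.element_len : elem_start + cfg.element_len + 5] == tsd

    def test_genic_bias_fraction(self):
        cfg = S.SimulationConfig(n_insertions=100, genic_bias=0.9)
        rng = np.random.default_rng(10)
        toy = S.build_toy_genome(cfg, rng)
        mut = S.plant_insertions(toy, cfg, rng)
        frac = np.mean([t.genic for t in mut.truth])
        assert abs(frac - 0.9) < 3 * np.sqrt(0.9 * 0.1 / 100)

    def test_impossible_spacing_errors(self):
        cfg = S.SimulationConfig(n_chromosomes=1, chrom_length=20_000,
                                 n_insertions=50, n_te_copies=0)
        rng = np.random.default_rng(0)
        toy = S.build_toy_genome(cfg, rng)
        with pytest.raises(ValueError, match="spacing"):
            S.plant_insertions(toy, cfg, rng)


class TestAlignmentSimulation:
    def test_no_insertions_no_errors_all_mapped(self):
        cfg = S.SimulationConfig(n_chromosomes=1, chrom_length=50_000,
                                 n_insertions=0, n_te_copies=0, error_rate=0.0,
                                 coverage=5.0)
        rng = np.random.default_rng(12)
        toy = S.build_toy_genome(cfg, rng)
        mut = S.plant_insertions(toy, cfg, rng)
        reads = S.simulate_alignments(mut, [], cfg, rng)
        assert reads and all(r.mapped for r in reads)

    def test_zero_coverage_empty(self):
        cfg = S.SimulationConfig(n_chromosomes=1, chrom_length=50_000,
                                 n_insertions=0, n_te_copies=0, coverage=0.0)
        rng = np.random.default_rng(12)
        toy = S.build_toy_genome(cfg, rng)
        mut = S.plant_insertions(toy, cfg, rng)
        assert S.simulate_alignments(mut, [], cfg, rng) == []

    def test_fixed_seed_determinism(self):
        cfg = S.SimulationConfig(n_chromosomes=1, chrom_length=40_000,
                                 n_insertions=2, n_te_copies=0, coverage=5.0)

        def one(seed):
            rng = np.random.default_rng(seed)
            toy = S.build_toy_genome(cfg, rng)
            mut = S.plant_insertions(toy, cfg, rng)
            return S.simulate_alignments(mut, [], cfg, rng)

        a, b = one(3), one(3)
        assert len(a) == len(b)
        assert all(x.seq == y.seq and x.pos == y.pos and x.mapped == y.mapped
                   for x, y in zip(a, b))

    def test_evidence_classes_near_single_insertion(self, tiny_te):
        cfg = S.SimulationConfig(n_chromosomes=1, chrom_length=60_000,
                                 n_insertions=1, n_te_copies=0, coverage=30.0)
        rng = np.random.default_rng(21)
        toy = S.build_toy_genome(cfg, rng)
        mut = S.plant_insertions(toy, cfg, rng)
        reads = S.simulate_alignments(mut, [], cfg, rng)
        params = D.DetectionParams()
        disc = D.find_discordant_candidates(reads, toy.te, params)
        frags = D.find_junction_fragments([r for r in reads if not r.mapped],
                                          toy.te, params)
        junc, _ = D.remap_fragments(frags, toy.assembly, params)
        pos = mut.truth[0].pos
        assert sum(abs(e.position - pos) < 600 for e in disc) >= 2
        assert sum(abs(e.junction_point - pos) <= 20 for e in junc) >= 1

    def test_evidence_guarantee_over_seeds(self):
        """At >= 20x coverage and error <= 0.005, every planted insertion has
        >= 2 discordant pairs and >= 1 junction read (20 seeds)."""
        cfg = S.SimulationConfig(n_chromosomes=1, chrom_length=60_000,
                                 n_insertions=3, n_te_copies=0, coverage=20.0,
                                 error_rate=0.005)
        params = D.DetectionParams()
        for seed in range(20):
            rng = np.random.default_rng(seed)
            toy = S.build_toy_genome(cfg, rng)
            mut = S.plant_insertions(toy, cfg, rng)
            reads = S.simulate_alignments(mut, [], cfg, rng)
            disc = D.find_discordant_candidates(reads, toy.te, params)
            frags = D.find_junction_fragments([r for r in reads if not r.mapped],
                                              toy.te, params)
            junc, _ = D.remap_fragments(frags, toy.assembly, params)
            for t in mut.truth:
                nd = sum(abs(e.position - t.pos) < 600 for e in disc)
                nj = sum(abs(e.junction_point - t.pos) <= 20 for e in junc)
                assert nd >= 2 and nj >= 1, (seed, t)


class TestChromatinTrack:
    def test_noiseless_two_level_step(self):
        cfg = S.SimulationConfig(n_chromosomes=1, chrom_length=60_000, n_te_copies=0)
        rng = np.random.default_rng(14)
        toy = S.build_toy_genome(cfg, rng)
        track = S.simulate_h3k9me2_track(toy.heterochromatin, toy.assembly, rng,
                                         noise_sd=0.0)
        assert set(np.unique(track.values["chr1"])) == {0.5, 3.0}

    def test_flat_signal_has_no_partition(self):
        from ltrcall.chromatin import partition_from_raw
        cfg = S.SimulationConfig(n_chromosomes=1, chrom_length=60_000, n_te_copies=0)
        rng = np.random.default_rng(15)
        toy = S.build_toy_genome(cfg, rng)
        track = S.simulate_h3k9me2_track(toy.heterochromatin, toy.assembly, rng,
                                         signal_high=1.0, signal_low=1.0, noise_sd=0.0)
        part = partition_from_raw(track, 100, threshold=1.5, round_to=1000)
        assert part.heterochromatin == []


class TestCountTable:
    def test_determinism_and_planted_fold(self, default_sim):
        _, toy, _, _ = default_sim
        targets = {g.gene_id for g in toy.annotation.genes[:10]}
        a, ea = S.simulate_count_table(toy.annotation, targets, np.random.default_rng(5))
        b, _ = S.simulate_count_table(toy.annotation, targets, np.random.default_rng(5))
        assert a.equals(b)
        assert set(ea.index[ea["activated"]]) == targets

    def test_rejects_fold_below_one(self, default_sim):
        _, toy, _, _ = default_sim
        with pytest.raises(ValueError):
            S.simulate_count_table(toy.annotation, set(), np.random.default_rng(0),
                                   fold_change=0.5)
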