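"""Generator properties: determinism, construction identities, bookkeeping."""

from __future__ import annotations

import numpy as np
import pytest

from cdip import (
    GenomeInterval,
    Scar,
    ScanConfig,
    classify_pattern,
    dot_matrix,
    emulate_sd_annotation,
    generate_genome,
    plant_csdp,
    plant_decoy,
    scan_pairs,
    simulate_dataset,
)
from cdip.synthetic import JUNCTIONS, SimulationConfig


class TestGenomeGeneration:
    def test_seed_determinism(self):
        a = generate_genome({"chr1": 100_000}, gc=0.41, seed=7)
        b = generate_genome({"chr1": 100_000}, gc=0.41, seed=7)
        assert a.sequences == b.sequences

    def test_gc_fraction_within_binomial_bound(self):
        g = generate_genome({"chr1": 1_000_000}, gc=0.41, seed=7)
        seq = g.sequences["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.41) < 0.01

    def test_different_seeds_differ(self):
        a = generate_genome({"chr1": 100_000}, seed=1).sequences["chr1"]
        b = generate_genome({"chr1": 100_000}, seed=2).sequences["chr1"]
        assert sum(x != y for x, y in zip(a, b)) > 10_000

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_genome({"chr1": 100_000}, gc=1.5)
        with pytest.raises(ValueError):
            generate_genome({"chr1": 100})

    def test_fasta_round_trip(self, tmp_path):
        g = generate_genome({"chr1": 50_000, "chr2": 30_000}, seed=3)
        path = tmp_path / "g.fa"
        g.write_fasta(path)
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        assert str(fa["chr1"][:]) == g.sequences["chr1"]
        assert str(fa["chr2"][:]) == g.sequences["chr2"]


class TestPlantCsdp:
    def test_blunt_construction_identity(self):
        # blunt scars, zero divergence: derivative = donor[open:] + donor[:open]
        g = generate_genome({"chr1": 1_000_000}, seed=5)
        donor_seq = g.sequences["chr1"][100_000:200_000]
        truth = plant_csdp(g, GenomeInterval("chr1", 100_000, 200_000), 150_000,
                           ("chr1", 600_000), "parallel", None, 0.0, seed=1)
        deriv = g.get("chr1", truth.derivative_span.start, truth.derivative_span.end)
        assert len(deriv) == 100_000
        assert deriv[:50_000] == donor_seq[50_000:]
        assert deriv[50_000:] == donor_seq[:50_000]

    def test_microhomology_length_bookkeeping(self):
        g = generate_genome({"chr1": 1_000_000}, seed=5)
        truth = plant_csdp(g, GenomeInterval("chr1", 100_000, 200_000), 150_000,
                           ("chr1", 600_000), "parallel", {"AD": Scar(mh=2)}, 0.0, seed=1)
        assert len(truth.derivative_span) == 100_000 - 2

    @pytest.mark.parametrize("seed", range(6))
    def test_general_length_bookkeeping(self, seed):
        # derivative length = donor - sum(mh + del) + sum(ins), exactly
        from cdip import ScarModel

        rng = np.random.default_rng(seed)
        model = ScarModel()
        scars = model.draw_junctions(rng)
        g = generate_genome({"chr1": 1_000_000}, seed=seed)
        truth = plant_csdp(g, GenomeInterval("chr1", 100_000, 160_000), 125_000,
                           ("chr1", 700_000), "inverted" if seed % 2 else "parallel",
                           scars, 0.03, seed=seed)
        # derivative length = donor - sum(mh + donor-side del) + sum(ins);
        # acceptor-side deletions remove acceptor bases, not copy bases
        expected = 60_000
        for j in JUNCTIONS:
            s = scars[j]
            expected += len(s.ins) - s.mh
        expected -= (scars["AD"].del_left + scars["AD"].del_right
                     + scars["betaC"].del_right + scars["Balpha"].del_left)
        assert len(truth.derivative_span) == expected

    def test_divergence_rate_within_binomial_bound(self):
        g = generate_genome({"chr1": 1_000_000}, seed=5)
        donor_seq = g.sequences["chr1"][100_000:200_000]
        truth = plant_csdp(g, GenomeInterval("chr1", 100_000, 200_000), 150_000,
                           ("chr1", 600_000), "parallel", None, 0.05, seed=1)
        deriv = g.get("chr1", truth.derivative_span.start, truth.derivative_span.end)
        expect = donor_seq[50_000:] + donor_seq[:50_000]
        frac = sum(a != b for a, b in zip(deriv, expect)) / len(expect)
        assert abs(frac - 0.05) < 0.005

    def test_diverged_copy_shows_flip_signature(self):
        g = generate_genome({"chr1": 1_000_000}, seed=5)
        truth = plant_csdp(g, GenomeInterval("chr1", 100_000, 150_000), 120_000,
                           ("chr1", 600_000), "parallel", None, 0.05, seed=1)
        x = g.get("chr1", *truth.donor_span.as_tuple()[1:])
        y = g.get("chr1", *truth.derivative_span.as_tuple()[1:])
        assert classify_pattern(dot_matrix(x, y, k=12)).label == "flip_parallel"

    def test_precondition_violations(self):
        g = generate_genome({"chr1": 1_000_000}, seed=5)
        donor = GenomeInterval("chr1", 100_000, 200_000)
        with pytest.raises(ValueError):
            plant_csdp(g, donor, 100_000, ("chr1", 600_000))  # opening on boundary
        with pytest.raises(ValueError):
            plant_csdp(g, donor, 150_000, ("chr1", 150_000))  # acceptor inside donor


class TestEmulatedAnnotation:
    def test_clean_event_yields_two_flip_records(self):
        g = generate_genome({"chr1": 1_000_000, "chr2": 1_000_000}, seed=5)
        truth = plant_csdp(g, GenomeInterval("chr1", 100_000, 160_000), 130_000,
                           ("chr2", 500_000), "parallel", None, 0.0, seed=1)
        table = emulate_sd_annotation(g, [truth], noise=0)
        assert len(table) == 2
        cands = scan_pairs(table)
        assert len(cands) == 1
        assert cands[0].donor_gap_bp == 0
        assert cands[0].derivative_gap_bp == 0

    def test_jittered_records_still_detected(self):
        g = generate_genome({"chr1": 1_000_000, "chr2": 1_000_000}, seed=5)
        truth = plant_csdp(g, GenomeInterval("chr1", 100_000, 160_000), 130_000,
                           ("chr2", 500_000), "parallel", None, 0.0, seed=1)
        table = emulate_sd_annotation(g, [truth], noise=50, seed=2)
        assert len(scan_pairs(table, ScanConfig(gap_tol_bp=10_000))) == 1

    def test_tandem_dup_yields_one_adjacent_record(self):
        g = generate_genome({"chr1": 1_000_000}, seed=5)
        truth = plant_decoy(g, "tandem_dup", GenomeInterval("chr1", 100_000, 150_000), seed=1)
        table = emulate_sd_annotation(g, [truth])
        assert len(table) == 1
        rec = table[0]
        assert rec.side_b.start == rec.side_a.end
        assert scan_pairs(table) == []


class TestDecoys:
    def test_transposition_inversion_dotplot_signature(self):
        g = generate_genome({"chr1": 1_000_000, "chr2": 1_000_000}, seed=5)
        truth = plant_decoy(g, "transposition_inversion",
                            GenomeInterval("chr1", 100_000, 140_000),
                            acceptor=("chr2", 500_000), internal_point=120_000, seed=1)
        x = g.get("chr1", *truth.donor_span.as_tuple()[1:])
        y = g.get("chr2", *truth.derivative_span.as_tuple()[1:])
        m = dot_matrix(x, y, k=16)
        fwd = [r for r in m.merged_runs if r.slope == 1 and r.length >= 1000]
        rev = [r for r in m.merged_runs if r.slope == -1 and r.length >= 1000]
        assert len(fwd) == 1 and len(rev) == 1
        # never two parallel forward runs at offsets of opposite sign
        offsets = [r.y_start - r.x_start for r in fwd]
        assert not (any(o > 0 for o in offsets) and any(o < 0 for o in offsets))
        assert classify_pattern(m).label != "flip_parallel"

    def test_decoys_produce_no_flip_candidates(self):
        g = generate_genome({"chr1": 1_000_000, "chr2": 1_000_000}, seed=5)
        t1 = plant_decoy(g, "transposition_inversion",
                         GenomeInterval("chr1", 100_000, 140_000),
                         acceptor=("chr2", 500_000), internal_point=120_000, seed=1)
        t2 = plant_decoy(g, "tandem_dup", GenomeInterval("chr1", 400_000, 450_000), seed=2)
        table = emulate_sd_annotation(g, [t1, t2])
        assert scan_pairs(table) == []


class TestDatasetOrchestration:
    def test_simulation_is_seed_deterministic(self):
        cfg = SimulationConfig(n_csdp=3, n_decoys=3, n_chromosomes=2,
                               chrom_length=4_000_000, size_range=(20_000, 50_000),
                               decoy_size_range=(20_000, 30_000))
        a = simulate_dataset(cfg, seed=9)
        b = simulate_dataset(cfg, seed=9)
        assert a.genome.sequences == b.genome.sequences
        assert [(r.side_a, r.side_b, r.strand, r.frac_match) for r in a.sd_table] == [
            (r.side_a, r.side_b, r.strand, r.frac_match) for r in b.sd_table
        ]

    def test_truth_coordinates_point_at_real_sequence(self, small_dataset):
        # every csdp truth's derivative blocks match its donor blocks at the
        # recorded divergence (substitutions only, so equal lengths)
        from cdip._seq import revcomp

        g = small_dataset.genome
        for truth in small_dataset.truths:
            if truth.event_type != "csdp":
                continue
            da = g.get(*truth.donor_block_ab.as_tuple())
            va = g.get(*truth.derivative_block_ab.as_tuple())
            if truth.orientation == "inverted":
                va = revcomp(va)
            assert len(da) == len(va)
            mismatch = sum(a != b for a, b in zip(da, va)) / max(len(da), 1)
            assert mismatch <= truth.divergence + 0.01
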