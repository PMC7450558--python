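"""Junction scar resolution: constructed cases, brute-force oracle, screens."""

from __future__ import annotations

import numpy as np
import pytest

from cdip import (
    GenomeInterval,
    JunctionInput,
    Scar,
    ScarModel,
    flank_homology_screen,
    generate_genome,
    plant_csdp,
    resolve_cluster_junctions,
    resolve_junction,
    simulate_junction,
)
from cdip.junctions import AnchorError, find_inverted_repeats

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(seq):
    return "".join(_RC[b] for b in reversed(seq))


class TestConstructedScars:
    """The four canonical junction configurations, built by hand."""

    @pytest.mark.parametrize(
        "scar,expect",
        [
            (Scar(), ("blunt", 0, "", 0, 0)),
            (Scar(mh=2), ("microhomology", 2, "", 0, 0)),
            (Scar(ins="G"), ("insertion", 0, "G", 0, 0)),
            (Scar(del_left=13), ("deletion", 0, "", 13, 0)),
            (Scar(del_right=27), ("deletion", 0, "", 0, 27)),
            (Scar(ins="GATTACAGATTACAGATTACAGATTACA"[:27]), ("insertion", 0, None, 0, 0)),
        ],
    )
    def test_scar_recovered_exactly(self, scar, expect):
        inp, truth = simulate_junction(scar, flank=120, seed=17)
        s = resolve_junction(inp)
        cls, mh, ins, dl, dr = expect
        assert s.scar_class == cls
        assert s.mh_len == mh
        if ins is not None:
            assert s.ins_seq == ins
        else:
            assert s.ins_seq == truth.ins
        assert (s.del_left_bp, s.del_right_bp) == (dl, dr)
        assert s.alignment_mismatches == 0

    def test_microhomology_and_insertion_mutually_exclusive(self):
        with pytest.raises(ValueError):
            Scar(mh=1, ins="A")
        rng = np.random.default_rng(0)
        model = ScarModel()
        for i in range(100):
            inp, _ = simulate_junction(model.draw(rng), flank=100, seed=i)
            s = resolve_junction(inp)
            assert not (s.mh_len > 0 and s.ins_seq)

    def test_unalignable_anchors_rejected(self):
        rng = np.random.default_rng(1)
        bases = np.frombuffer(b"ACGT", dtype="S1")

        def rand(n):
            return rng.choice(bases, size=n).tobytes().decode()

        # a junction read from a completely different locus
        inp = JunctionInput(rand(200), rand(200), rand(200), 100, 100)
        with pytest.raises(AnchorError):
            resolve_junction(inp)


def _oracle_resolve(inp, max_ins=8, max_del=12):
    """Exhaustive search over all split/deletion assignments (quarter units)."""
    L, R, read = inp.left_reference, inp.right_reference, inp.junction_read
    lb, rb, n = inp.left_break, inp.right_break, len(read)
    mm_l = {}
    for s_l in range(n + 1):
        for dl in range(max_del + 1):
            e = lb - dl
            if e >= s_l:
                mm_l[s_l, dl] = sum(1 for t in range(s_l) if read[t] != L[e - s_l + t])
    mm_r = {}
    for s_r in range(n + 1):
        for dr in range(max_del + 1):
            b = rb + dr
            if b + (n - s_r) <= len(R):
                mm_r[s_r, dr] = sum(1 for t in range(n - s_r) if read[s_r + t] != R[b + t])
    best = None
    for s_l in range(n + 1):
        for s_r in range(s_l, min(n, s_l + max_ins) + 1):
            for dl in range(max_del + 1):
                if (s_l, dl) not in mm_l:
                    continue
                for dr in range(max_del + 1):
                    if (s_r, dr) not in mm_r:
                        continue
                    cost = 4 * (mm_l[s_l, dl] + mm_r[s_r, dr]) + 3 * (dl + dr + (s_r - s_l))
                    cand = (cost, s_l, s_r, dl, dr)
                    if best is None or cand < best:
                        best = cand
    cost, s_l, s_r, dl, dr = best
    ins = read[s_l:s_r]
    mh = 0
    if not ins:
        e = lb - dl
        b = rb + dr
        if dl > 0:
            m = 0
            while m < dl and s_l + m < n and read[s_l + m] == L[e + m]:
                m += 1
            if m == dl:
                mh += dl
                dl = 0
        if dr > 0:
            m = 0
            while m < dr and s_l - 1 - m >= 0 and read[s_l - 1 - m] == R[b - 1 - m]:
                m += 1
            if m == dr:
                mh += dr
                dr = 0
    return (s_l, s_r, mh, ins, dl, dr)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(40))
    def test_resolver_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        model = ScarModel(ins_lengths=tuple(range(1, 8)), del_lengths=tuple(range(1, 12)))
        scar = model.draw(rng)
        div = float(rng.uniform(0, 0.03))
        inp, _ = simulate_junction(scar, flank=45, divergence=div, seed=seed + 1000)
        s = resolve_junction(inp, min_anchor=10, max_ins=8, max_del=12)
        assert (
            s.split_left, s.split_right, s.mh_len, s.ins_seq,
            s.del_left_bp, s.del_right_bp,
        ) == _oracle_resolve(inp)


class TestStrandInvariance:
    @pytest.mark.parametrize(
        "scar", [Scar(), Scar(mh=2), Scar(ins="GAT"), Scar(del_left=7), Scar(del_right=4)]
    )
    def test_mirrored_input_gives_mirrored_scar(self, scar):
        inp, _ = simulate_junction(scar, flank=120, seed=23)
        fwd = resolve_junction(inp)
        rev = resolve_junction(inp.mirrored())
        assert rev.scar_class == fwd.scar_class
        assert rev.mh_len == fwd.mh_len
        assert rev.ins_seq == _rc(fwd.ins_seq)
        assert (rev.del_left_bp, rev.del_right_bp) == (fwd.del_right_bp, fwd.del_left_bp)


class TestClusterJunctions:
    @pytest.mark.parametrize("orientation", ["parallel", "inverted"])
    def test_planted_scars_recovered_exactly(self, orientation):
        genome = generate_genome({"chr1": 1_000_000, "chr2": 1_000_000}, seed=7)
        scars = {"AD": Scar(mh=2), "betaC": Scar(ins="GATC"), "Balpha": Scar()}
        truth = plant_csdp(
            genome, GenomeInterval("chr1", 100_000, 160_000), 130_000,
            ("chr2", 500_000), orientation, scars, divergence=0.02, seed=3,
        )
        res = resolve_cluster_junctions(truth.junction_geometry(), genome)
        assert res["AD"].scar_class == "microhomology" and res["AD"].mh_len == 2
        assert res["betaC"].scar_class == "insertion" and res["betaC"].ins_seq == "GATC"
        assert res["Balpha"].scar_class == "blunt"

    def test_zero_divergence_blunt_everywhere(self):
        genome = generate_genome({"chr1": 1_000_000}, seed=9)
        truth = plant_csdp(genome, GenomeInterval("chr1", 100_000, 140_000), 120_000,
                           ("chr1", 700_000), "parallel", None, divergence=0.0, seed=4)
        res = resolve_cluster_junctions(truth.junction_geometry(), genome)
        for scar in res.values():
            assert scar.scar_class == "blunt"
            assert scar.alignment_mismatches == 0

    def test_n_gap_junction_marked_unresolvable(self):
        genome = generate_genome({"chr1": 1_000_000}, seed=11)
        truth = plant_csdp(genome, GenomeInterval("chr1", 100_000, 140_000), 120_000,
                           ("chr1", 700_000), "parallel", None, seed=4)
        # bury the donor A-start flank (used by the A/D junction) in Ns
        seq = genome.sequences["chr1"]
        genome.sequences["chr1"] = seq[:99_900] + "N" * 200 + seq[100_100:]
        res = resolve_cluster_junctions(truth.junction_geometry(), genome)
        assert res["AD"] is None
        assert res["betaC"] is not None
        assert res["Balpha"] is not None


class TestFlankScreen:
    def test_random_flanks_not_flagged(self):
        genome = generate_genome({"chr1": 1_000_000}, seed=13)
        res = flank_homology_screen(genome, [("chr1", 200_000), ("chr1", 600_000)])
        assert not res.homology_positive

    def test_shared_diverged_element_flagged(self):
        genome = generate_genome({"chr1": 1_000_000}, seed=14)
        rng = np.random.default_rng(15)
        seq = genome.sequences["chr1"]
        element = seq[200_100:200_400]  # 300 bp
        copy = list(element)
        for i in np.flatnonzero(rng.random(len(copy)) < 0.05):  # ~95% identity
            copy[i] = _RC[copy[i]]
        genome.sequences["chr1"] = seq[:600_100] + "".join(copy) + seq[600_400:]
        res = flank_homology_screen(genome, [("chr1", 200_000), ("chr1", 600_000)])
        assert res.homology_positive
        # oracle on the construction: >= 270 matching positions in a 300 bp
        # window dominate the local alignment score threshold
        matches = sum(a == b for a, b in zip(element, copy))
        assert matches - (len(element) - matches) >= 50

    def test_planted_inverted_repeat_flagged(self):
        genome = generate_genome({"chr1": 1_000_000}, seed=16)
        seq = genome.sequences["chr1"]
        arm = seq[300_200:300_225]  # 25 bp arm
        spacer = seq[300_225:300_235]  # 10 bp spacer
        genome.sequences["chr1"] = (
            seq[:300_200] + arm + spacer + _rc(arm) + seq[300_260:]
        )
        res = flank_homology_screen(genome, [("chr1", 300_000)])
        assert res.inverted_repeat_positive

    def test_inverted_repeat_finder_by_construction(self):
        rng = np.random.default_rng(17)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        flank = rng.choice(bases, size=400).tobytes().decode()
        arm = "GATTACAGATTAC"  # 13 bp
        planted = flank[:200] + arm + "TTTTT" + _rc(arm) + flank[200:]
        hits = find_inverted_repeats(planted, arm=10, max_spacer=100)
        assert any(a <= 203 and ln >= 10 for a, _, ln in hits)
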