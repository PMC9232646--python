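"""Chunking, assembly planning, junction primers and in-silico assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neochrom import assembly as asm
from neochrom import design as dsg
from neochrom.seqtools import revcomp, rotations_equal

from conftest import build_edited_design


def random_circle(n, seed, gc=0.4):
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=n, p=p))
    return dsg.NeoChromosomeDesign(
        name=f"circle{n}", topology="circular", sequence=seq, initial_sequence=seq
    )


class TestChunking:
    def test_30kb_default_three_chunks_sharing_200bp(self):
        d = random_circle(30_000, seed=1)
        chunks = asm.chunk_design(d)
        assert len(chunks) == 3
        for i, c in enumerate(chunks):
            nxt = chunks[(i + 1) % 3]
            assert c.right_overhang == nxt.left_overhang
            assert len(c.right_overhang) == 200
        assert "".join(c.body for c in chunks) == d.sequence

    def test_boundaries_near_even_spacing(self):
        d = random_circle(50_000, seed=2)
        chunks = asm.chunk_design(d, target_size=10_000)
        starts = [c.start for c in chunks]
        for k, s in enumerate(starts):
            assert abs(s - k * 10_000) <= 1_000

    def test_overlap_windows_unique_in_design(self):
        d = random_circle(40_000, seed=3)
        for c in asm.chunk_design(d):
            if c.right_overhang:
                assert (d.sequence + d.sequence).count(c.right_overhang) <= 2

    def test_design_shorter_than_target_rejected(self):
        d = random_circle(5_000, seed=4)
        with pytest.raises(asm.AssemblyError, match="not longer"):
            asm.chunk_design(d, target_size=10_000)

    def test_roundtrip_random_circles(self):
        for seed, n in [(5, 52_000), (6, 147_000), (7, 250_000)]:
            d = random_circle(n, seed)
            chunks = asm.chunk_design(d)
            assert asm.verify_chunk_roundtrip(d, chunks)

    def test_roundtrip_on_edited_design(self, small_design):
        chunks = asm.chunk_design(small_design)
        assembled = asm.simulate_hr_assembly([c.sequence for c in chunks])
        assert rotations_equal(assembled, small_design.sequence)


class TestHrAssembly:
    def test_two_pieces_share_200bp_terminus(self):
        rng = np.random.default_rng(8)
        a = "".join(rng.choice(list("ACGT"), size=1000))
        b = a[-200:] + "".join(rng.choice(list("ACGT"), size=700))
        joined = asm.simulate_hr_assembly([a, b], circularize=False)
        assert len(joined) == 1000 + 900 - 200
        assert joined == a + b[200:]

    def test_single_mismatch_breaks_the_join(self):
        rng = np.random.default_rng(9)
        a = "".join(rng.choice(list("ACGT"), size=1000))
        tail = list(a[-200:])
        tail[100] = "A" if tail[100] != "A" else "C"
        b = "".join(tail) + "".join(rng.choice(list("ACGT"), size=500))
        with pytest.raises(asm.AssemblyError, match="unjoined|end"):
            asm.simulate_hr_assembly([a, b], circularize=False)

    def test_ambiguous_join_detected(self):
        rng = np.random.default_rng(10)
        a = "".join(rng.choice(list("ACGT"), size=600))
        b = a[-200:] + "".join(rng.choice(list("ACGT"), size=300))
        c = a[-200:] + "".join(rng.choice(list("ACGT"), size=400))
        with pytest.raises(asm.AssemblyError, match="ambiguous"):
            asm.simulate_hr_assembly([a, b, c], circularize=False)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1_000), k=st.integers(2, 6))
    def test_length_conservation_formula(self, seed, k):
        """Joined length equals the sum of pieces minus overlap per join."""
        d = random_circle(k * 3_000, seed)
        chunks = asm.chunk_design(d, target_size=3_000, overlap=150)
        pieces = [c.sequence for c in chunks]
        joined = asm.simulate_hr_assembly(pieces, circularize=True, overlap=150)
        assert len(joined) == sum(len(p) for p in pieces) - 150 * len(pieces)


class TestAssemblyPlan:
    def test_default_schedule_opens_like_the_build(self):
        plan = asm.plan_assembly(21)
        assert plan.rounds[0] == (1, (1, 2), "URA3")
        assert plan.rounds[1] == (2, (3, 4, 5), "LEU2")
        assert plan.final_swap == (plan.rounds[-1][2], "BFP")

    @pytest.mark.parametrize("n", range(1, 31))
    def test_all_chunk_counts_yield_valid_plans(self, n):
        """Brute-force validity: alternation, exactly-once coverage, 1-4/round."""
        plan = asm.plan_assembly(n)
        covered = []
        markers = []
        for rnd, chunks, marker in plan.rounds:
            assert 1 <= len(chunks) <= 4
            covered.extend(chunks)
            markers.append(marker)
        assert covered == list(range(1, n + 1))
        assert all(a != b for a, b in zip(markers, markers[1:]))
        assert plan.final_swap[0] == markers[-1]

    def test_per_round_max_bounds(self):
        for bad in (0, 5):
            with pytest.raises(asm.AssemblyError, match="per_round_max"):
                asm.plan_assembly(10, per_round_max=bad)


# --- independent nearest-neighbor Tm oracle --------------------------------
# Unified duplex parameters (kcal/mol, cal/mol/K), standard published set.

NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}


def brute_force_tm(seq, Na=50.0, dnac1=500.0):
    dh, ds = 0.0, 0.0
    for base in (seq[0], seq[-1]):
        dh += INIT[base][0]
        ds += INIT[base][1]
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        dh += NN[pair][0]
        ds += NN[pair][1]
    ds += 0.368 * (len(seq) - 1) * math.log(Na / 1e3)  # monovalent-salt entropy
    k = dnac1 * 1e-9  # excess-primer approximation
    return 1000 * dh / (ds + 1.987 * math.log(k)) - 273.15


class TestJunctionPrimers:
    def test_one_pair_per_junction_spanning_each_boundary(self, small_design):
        chunks = asm.chunk_design(small_design)
        pairs = asm.design_junction_primers(small_design, chunks)
        assert len(pairs) == len(chunks)  # circular: one junction per boundary
        n = len(small_design.sequence)
        boundaries = [chunks[0].start] + [c.start for c in chunks[1:]]
        for p, b in zip(pairs, boundaries):
            span = (p.reverse_start + len(p.reverse) - p.forward_start) % n
            offset = (b - p.forward_start) % n
            assert 0 < offset < span  # amplicon covers the junction
            assert 400 <= p.product_length <= 1000
            assert 58 <= p.tm_forward <= 62
            assert 58 <= p.tm_reverse <= 62

    def test_primers_unique_in_design(self, small_design):
        chunks = asm.chunk_design(small_design)
        seq2 = small_design.sequence + small_design.sequence
        for p in asm.design_junction_primers(small_design, chunks):
            for primer in (p.forward, p.reverse):
                hits = seq2.count(primer) + seq2.count(revcomp(primer))
                assert hits == 2  # once per circle copy

    def test_melting_temperature_matches_brute_force_summation(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(18, 26))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert asm.primer_tm(seq) == pytest.approx(brute_force_tm(seq), abs=0.01)


class TestReplaceRegion:
    def _design(self):
        seq = "A" * 30 + "ATGAAATAA" + "T" * 30 + "ATGCCCTAA" + "G" * 30
        d = dsg.NeoChromosomeDesign(
            name="toy", topology="circular", sequence=seq,
            features=[
                dsg.Feature("o1", "ORF", 30, 39, "+", {}),
                dsg.Feature("leu2", "marker", 48, 69, "+", {}),
                dsg.Feature("o2", "ORF", 69, 78, "+", {}),
            ],
            initial_sequence=seq,
        )
        return d

    def test_marker_swap_changes_length_keeps_flanks(self):
        d = self._design()
        old_len = len(d.sequence)
        payload = "C" * 10
        asm.replace_region(d, "leu2", payload, payload_name="BFP")
        assert len(d.sequence) == old_len + 10 - 21
        assert d.sequence[:48] == ("A" * 30 + "ATGAAATAA" + "T" * 9)
        assert d.feature_by_id("o2").start == 48 + 10  # shifted downstream

    def test_insertion_between_orfs_preserves_both(self):
        d = self._design()
        before = [d.orf_cds(d.feature_by_id(o)) for o in ("o1", "o2")]
        asm.replace_region(d, (40, 40), "ACGT" * 25, payload_name="ARS305",
                           payload_type="ARS")
        after = [d.orf_cds(d.feature_by_id(o)) for o in ("o1", "o2")]
        assert before == after

    def test_pure_deletion_and_orf_protection(self):
        d = self._design()
        old_len = len(d.sequence)
        asm.replace_region(d, (10, 20), "")
        assert len(d.sequence) == old_len - 10
        with pytest.raises(dsg.DesignError, match="overlaps ORF"):
            asm.replace_region(d, (25, 35), "AAA")
        asm.replace_region(d, (25, 35), "AAA", override=True)  # explicit override
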