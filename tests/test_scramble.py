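"""SCRaMbLE simulation, segment maps, SV calling, copy-number estimation."""

import numpy as np
import pandas as pd
import pytest

from neochrom import design as dsg
from neochrom import scramble as scr
from neochrom.seqtools import LOXPSYM, revcomp


def lox_circle(segment_lengths, seed=0):
    """A circular molecule whose segments are random and site-delimited."""
    rng = np.random.default_rng(seed)
    parts = []
    for n in segment_lengths:
        parts.append("".join(rng.choice(list("ACGT"), size=n)))
        parts.append(LOXPSYM)
    seq = "".join(parts)
    return dsg.NeoChromosomeDesign(
        name="toy", topology="circular", sequence=seq, initial_sequence=seq
    )


class TestSegmentMap:
    def test_no_sites_single_segment(self):
        d = dsg.NeoChromosomeDesign(
            name="t", topology="circular", sequence="ACGT" * 100,
            initial_sequence="ACGT" * 100,
        )
        m = scr.build_segment_map(d)
        assert len(m.order) == 1 and m.segments[0] == d.sequence

    @pytest.mark.parametrize("k", [1, 2, 5, 9])
    def test_circular_design_site_count_equals_segment_count(self, k):
        d = lox_circle([120 + 10 * i for i in range(k)], seed=k)
        m = scr.build_segment_map(d)
        assert len(m.order) == k == m.n_sites

    def test_reconstruction_over_random_designs(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(1, 8))
            d = lox_circle(list(rng.integers(60, 400, size=k)), seed=seed)
            m = scr.build_segment_map(d)
            assert m.reconstruct() == d.sequence

    def test_segment_containing(self, pgnc_design, pgnc_segmap):
        backbone = pgnc_design.feature_by_id("backbone")
        sid = scr.segment_containing(pgnc_design, backbone.start)
        seg = pgnc_segmap.segments[sid]
        assert pgnc_design.sequence[backbone.start : backbone.start + 50] in seg


class TestSimulate:
    def test_zero_events_identity(self, pgnc_segmap):
        seq, events, out = scr.simulate_scramble(pgnc_segmap, n_events=0, seed=1)
        assert events == []
        assert out.order == pgnc_segmap.order
        assert seq == pgnc_segmap.realize()

    def test_single_inversion_semantics(self, pgnc_segmap):
        rng = np.random.default_rng(0)
        for seed in rng.integers(0, 10_000, size=10):
            seq, events, out = scr.simulate_scramble(
                pgnc_segmap, n_events=1, seed=int(seed),
                type_probs={"INV": 1.0},
            )
            assert len(seq) == len(pgnc_segmap.realize())
            assert sorted(s for s, _ in out.order) == sorted(
                s for s, _ in pgnc_segmap.order
            )
            flipped = [s for s, sign in out.order if sign < 0]
            assert set(flipped) == set(events[0].segment_ids)

    def test_conservation_per_event_type(self, pgnc_segmap):
        base_len = len(pgnc_segmap.realize())
        for seed in range(30):
            for etype, cmp in [("DEL", -1), ("INV", 0), ("DUP", 1)]:
                seq, events, out = scr.simulate_scramble(
                    pgnc_segmap, n_events=1, seed=seed, type_probs={etype: 1.0}
                )
                n_sites = len(out.order)
                if cmp == 0:
                    assert len(seq) == base_len and n_sites == 63
                elif cmp < 0:
                    assert len(seq) < base_len and n_sites < 63
                else:
                    assert len(seq) > base_len and n_sites > 63

    def test_essential_segment_never_deleted(self, pgnc_segmap, pgnc_essential):
        for seed in range(50):
            _, _, out = scr.simulate_scramble(
                pgnc_segmap, n_events=3, seed=seed,
                type_probs={"DEL": 1.0}, essential_segments=pgnc_essential,
            )
            assert pgnc_essential[0] in {s for s, _ in out.order}

    def test_replay_reproduces_sequence(self, pgnc_segmap, pgnc_essential):
        for seed in range(30):
            seq, events, _ = scr.simulate_scramble(
                pgnc_segmap, n_events=2, seed=seed,
                essential_segments=pgnc_essential,
            )
            assert scr.replay_events(pgnc_segmap, events) == seq

    def test_event_on_too_few_sites_errors(self):
        d = lox_circle([200], seed=1)
        m = scr.build_segment_map(d)
        with pytest.raises(scr.ScrambleError, match="site"):
            scr.simulate_scramble(m, n_events=1, seed=0)

    def test_seeded_determinism(self, pgnc_segmap):
        a = scr.simulate_scramble(pgnc_segmap, n_events=3, seed=99)
        b = scr.simulate_scramble(pgnc_segmap, n_events=3, seed=99)
        assert a[0] == b[0]
        assert [e.segment_ids for e in a[1]] == [e.segment_ids for e in b[1]]


class TestCaller:
    def test_unscrambled_molecule_yields_empty_report(self, pgnc_segmap):
        rep = scr.call_structural_variants(pgnc_segmap, pgnc_segmap.realize())
        assert rep.events == [] and not rep.unexplained
        assert all(c == 1 for c in rep.copy_number.values())
        assert all(signs == [1] for signs in rep.orientation.values())

    def test_single_event_classification_matches_simulated_type(
        self, pgnc_segmap, pgnc_essential
    ):
        """300 seeded single-event genomes: called type equals simulated."""
        agree = 0
        for seed in range(300):
            rng = np.random.default_rng(seed)
            etype = ["DEL", "INV", "DUP"][int(rng.integers(3))]
            seq, events, _ = scr.simulate_scramble(
                pgnc_segmap, n_events=1, seed=seed + 1,
                type_probs={etype: 1.0}, essential_segments=pgnc_essential,
            )
            rep = scr.call_structural_variants(pgnc_segmap, seq)
            if (
                len(rep.events) == 1
                and rep.events[0].type == etype
                and set(rep.events[0].segment_ids) == set(events[0].segment_ids)
            ):
                agree += 1
        assert agree == 300

    def test_intergenic_inversion_and_deletion_distinguished(self):
        """Two clones altered at the same span: one inverted, one deleted."""
        d = lox_circle([300, 80, 250, 400], seed=7)
        m = scr.build_segment_map(d)
        intergenic = 1  # the short span between two sites
        inv_order = list(m.order)
        inv_order[intergenic] = (intergenic, -1)
        clone_inv = m.realize(inv_order)
        del_order = [x for x in m.order if x[0] != intergenic]
        clone_del = m.realize(del_order)

        rep_inv = scr.call_structural_variants(m, clone_inv)
        assert [e.type for e in rep_inv.events] == ["INV"]
        assert set(rep_inv.events[0].segment_ids) == {intergenic}

        rep_del = scr.call_structural_variants(m, clone_del)
        assert [e.type for e in rep_del.events] == ["DEL"]
        assert rep_del.copy_number[intergenic] == 0

    def test_duplication_copy_number(self, pgnc_segmap, pgnc_essential):
        seq, events, _ = scr.simulate_scramble(
            pgnc_segmap, n_events=1, seed=11, type_probs={"DUP": 1.0},
            essential_segments=pgnc_essential,
        )
        rep = scr.call_structural_variants(pgnc_segmap, seq)
        for sid in events[0].segment_ids:
            assert rep.copy_number[sid] == 2

    def test_foreign_sequence_flagged_not_raised(self, pgnc_segmap):
        rng = np.random.default_rng(5)
        foreign = "".join(rng.choice(list("ACGT"), size=500))
        chimera = pgnc_segmap.realize() + LOXPSYM + foreign
        rep = scr.call_structural_variants(pgnc_segmap, chimera)
        assert rep.unexplained and rep.notes


class TestCopyNumber:
    def _table(self, element_depth, genome_depth=30.0):
        return pd.DataFrame(
            {
                "contig": ["c1", "c2", "small", "PGNC"],
                "length": [1_000_000, 500_000, 50_000, 211_000],
                "mean_depth": [genome_depth, genome_depth, 999.0, element_depth],
            }
        )

    def test_equal_depths_give_one(self):
        assert scr.estimate_copy_number(self._table(30.0), "PGNC") == 1.0

    def test_doubled_element_gives_two(self):
        assert scr.estimate_copy_number(self._table(60.0), "PGNC") == 2.0

    def test_small_contigs_excluded_from_reference(self):
        # the 999x small contig must not perturb the genome reference level
        assert scr.estimate_copy_number(self._table(45.0), "PGNC") == 1.5

    def test_missing_element_and_no_large_contig_errors(self):
        with pytest.raises(scr.ScrambleError, match="not in coverage"):
            scr.estimate_copy_number(self._table(30.0), "nope")
        with pytest.raises(scr.ScrambleError, match="longer than"):
            scr.estimate_copy_number(self._table(30.0), "PGNC", min_contig=10**7)
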