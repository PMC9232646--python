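"""Design construction and Sc2.0-style editing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neochrom import design as dsg
from neochrom import simulate as sim
from neochrom.seqtools import (
    LOXPSYM,
    alternate_codon,
    find_all,
    revcomp,
    translate,
)

from conftest import build_edited_design


def frag(id_, seq, orfs=()):
    return dsg.Fragment(id=id_, sequence=seq, orfs=list(orfs))


def plain_design(sequence, orfs=(), topology="circular", recoded=True):
    """A bare design for coordinate-level examples."""
    d = dsg.NeoChromosomeDesign(
        name="toy",
        topology=topology,
        sequence=sequence,
        features=[
            dsg.Feature(o.id, "ORF", o.start, o.end, o.strand,
                        {"confidence": o.confidence})
            for o in orfs
        ],
        initial_sequence=sequence,
    )
    if recoded:
        d.metadata["stops_recoded"] = True
    for orf in d.orf_features():
        orf.attributes["original_translation"] = translate(d.orf_cds(orf))
    return d


BACKBONE = sim.make_backbone(length=1000, seed=9)


class TestConcatenation:
    def test_descending_size_order_with_backbone_last(self):
        rng = np.random.default_rng(0)
        seqs = {
            k: "".join(rng.choice(list("ACGT"), size=n))
            for k, n in [("a", 3000), ("b", 10000), ("c", 5000)]
        }
        d = dsg.concatenate_fragments(
            [frag("a", seqs["a"]), frag("b", seqs["b"]), frag("c", seqs["c"])],
            BACKBONE,
        )
        assert d.sequence == seqs["b"] + seqs["c"] + seqs["a"] + BACKBONE.sequence
        assert len(d.sequence) == 18000 + len(BACKBONE)
        assert d.topology == "circular"
        assert d.metadata["fragment_order"][:3] == ["b", "c", "a"]

    def test_equal_lengths_tie_break_by_id(self):
        d = dsg.concatenate_fragments(
            [frag("z", "ACGT" * 100), frag("a", "TGCA" * 100)], BACKBONE
        )
        assert d.metadata["fragment_order"][:2] == ["a", "z"]

    def test_single_fragment(self):
        d = dsg.concatenate_fragments([frag("only", "ACGT" * 50)], BACKBONE)
        assert d.sequence == "ACGT" * 50 + BACKBONE.sequence

    def test_orf_features_lifted_to_design_coordinates(self):
        f1 = frag("big", "T" * 30, [dsg.OrfAnnotation("o1", 3, 12, "+")])
        f2 = frag("small", "A" * 12, [dsg.OrfAnnotation("o2", 0, 9, "-")])
        d = dsg.concatenate_fragments([f2, f1], BACKBONE)
        assert d.feature_by_id("o1").start == 3
        assert d.feature_by_id("o2").start == 30

    @pytest.mark.parametrize(
        "fragments, match",
        [([], "at least one"), ([frag("x", "ACGT"), frag("x", "TTTT")], "duplicate")],
    )
    def test_errors(self, fragments, match):
        with pytest.raises(dsg.DesignError, match=match):
            dsg.concatenate_fragments(fragments, BACKBONE)

    def test_backbone_without_features_rejected(self):
        with pytest.raises(dsg.DesignError, match="backbone"):
            dsg.concatenate_fragments([frag("a", "ACGT" * 10)], frag("bb", "A" * 50))


class TestStopRecoding:
    @pytest.mark.parametrize(
        "cds, expected",
        [("ATGAAATAG", "ATGAAATAA"), ("ATGAAATAA", "ATGAAATAA"),
         ("ATGAAATGA", "ATGAAATGA")],
    )
    def test_plus_strand_terminal_codon(self, cds, expected):
        seq = "CCC" + cds + "GGG"
        d = plain_design(seq, [dsg.OrfAnnotation("o", 3, 12, "+")], recoded=False)
        dsg.recode_stop_codons(d)
        assert d.sequence == "CCC" + expected + "GGG"

    def test_minus_strand_tag_recoded_in_forward_coordinates(self):
        # ORF-strand ATGAAATAG lies at forward positions [2, 11) as CTATTTCAT
        seq = "GG" + revcomp("ATGAAATAG") + "CC"
        d = plain_design(seq, [dsg.OrfAnnotation("o", 2, 11, "-")], recoded=False)
        dsg.recode_stop_codons(d)
        assert d.orf_cds(d.feature_by_id("o")) == "ATGAAATAA"
        assert len(d.sequence) == len(seq)

    def test_non_stop_terminal_reported_not_silently_accepted(self):
        d = plain_design(
            "ATGAAACCC" + "G", [dsg.OrfAnnotation("o", 0, 9, "+")], recoded=False
        )
        dsg.recode_stop_codons(d)
        assert any("not a stop" in v for v in d.metadata["orf_stop_violations"])
        assert d.sequence.startswith("ATGAAACCC")  # untouched


class TestLoxpsymInsertion:
    def test_site_is_its_own_reverse_complement(self):
        assert revcomp(LOXPSYM) == LOXPSYM
        assert len(LOXPSYM) == 34

    def test_plus_strand_site_three_bp_after_stop(self):
        # ORF occupies [0, 9); insertion lands at 9 + 3 = 12, site [12, 46)
        seq = "ATGAAATAA" + "C" * 51
        d = plain_design(seq, [dsg.OrfAnnotation("o", 0, 9, "+")])
        dsg.insert_loxpsym(d)
        assert len(d.sequence) == 94
        site = d.loxpsym_features()[0]
        assert (site.start, site.end) == (12, 46)
        assert d.sequence[12:46] == LOXPSYM

    def test_minus_strand_site_ends_three_bp_left_of_orf_start(self):
        seq = "G" * 40 + revcomp("ATGAAATAA") + "G" * 11
        d = plain_design(seq, [dsg.OrfAnnotation("o", 40, 49, "-")])
        dsg.insert_loxpsym(d)
        assert len(d.sequence) == 94
        site = d.loxpsym_features()[0]
        orf = d.feature_by_id("o")
        assert site.end == orf.start - 3  # 3-bp spacer downstream of the stop
        assert d.sequence[site.start : site.end] == LOXPSYM

    def test_requires_recoding_first(self):
        d = plain_design("ATGAAATAA" + "C" * 51,
                         [dsg.OrfAnnotation("o", 0, 9, "+")], recoded=False)
        with pytest.raises(dsg.DesignError, match="recode_stop_codons"):
            dsg.insert_loxpsym(d)

    def test_collision_skipped_and_reported(self):
        # second ORF starts 2 bp after the first stop: insertion point inside it
        seq = "ATGAAATAA" + "CC" + "ATGCCCTAA" + "G" * 40
        d = plain_design(
            seq,
            [dsg.OrfAnnotation("o1", 0, 9, "+"), dsg.OrfAnnotation("o2", 11, 20, "+")],
        )
        dsg.insert_loxpsym(d, selection=["o1", "o2"])
        skipped = d.metadata["loxpsym_skipped"]
        assert len(d.loxpsym_features()) == 1
        assert any("o1" in s for s in skipped)
        with pytest.raises(dsg.DesignError, match="inside feature"):
            d2 = plain_design(
                seq,
                [dsg.OrfAnnotation("o1", 0, 9, "+"),
                 dsg.OrfAnnotation("o2", 11, 20, "+")],
            )
            dsg.insert_loxpsym(d2, selection=["o1", "o2"], on_collision="error")

    def test_default_selection_targets_high_confidence_orfs(self):
        design = build_edited_design(
            seed=5, n_fragments=4, size_range=(2000, 6000), n_loxpsym=None
        )
        n_high = sum(
            1 for o in design.orf_features() if o.attributes["confidence"] == "high"
        )
        n_skipped = len(design.metadata["loxpsym_skipped"])
        assert len(design.loxpsym_features()) == n_high - n_skipped

    def test_length_accounting(self):
        design = build_edited_design(
            seed=6, n_fragments=4, size_range=(2000, 6000), n_loxpsym=None
        )
        n_sites = len(design.loxpsym_features())
        assert len(design.sequence) == len(design.initial_sequence) + 34 * n_sites


class TestWatermarks:
    def _watermarked(self, payloads, seed=3):
        frags = sim.generate_pan_fragments(
            sim.FragmentSpec(n_fragments=2, size_range=(2000, 5000), seed=seed)
        )
        d = dsg.concatenate_fragments(frags, BACKBONE)
        dsg.recode_stop_codons(d)
        orf_ids = [o.id for o in d.orf_features()][: len(payloads)]
        dsg.embed_watermarks(d, orf_ids, payloads)
        return d, orf_ids

    def test_translation_unchanged_and_roundtrip(self):
        rng = np.random.default_rng(0)
        payloads = [
            "".join(str(b) for b in rng.integers(0, 2, size=int(rng.integers(1, 9))))
            for _ in range(3)
        ]
        d, orf_ids = self._watermarked(payloads)
        for orf in d.orf_features():
            assert translate(d.orf_cds(orf)) == orf.attributes["original_translation"]
        for orf_id, payload in zip(orf_ids, payloads):
            assert dsg.decode_watermark(d, orf_id) == payload

    def test_hundred_random_payloads_roundtrip(self):
        rng = np.random.default_rng(42)
        for trial in range(10):
            payloads = [
                "".join(str(b) for b in rng.integers(0, 2, size=8))
                for _ in range(10)
            ]
            frags = sim.generate_pan_fragments(
                sim.FragmentSpec(n_fragments=3, size_range=(3000, 8000),
                                 orf_density=0.6, seed=100 + trial)
            )
            d = dsg.concatenate_fragments(frags, BACKBONE)
            dsg.recode_stop_codons(d)
            orf_ids = [o.id for o in d.orf_features()][: len(payloads)]
            dsg.embed_watermarks(d, orf_ids, payloads[: len(orf_ids)])
            for orf_id, payload in zip(orf_ids, payloads):
                assert dsg.decode_watermark(d, orf_id) == payload

    def test_window_without_degeneracy_errors(self):
        # Met/Trp codons only: no synonymous alternatives anywhere
        cds = "ATG" + "TGG" * 30 + "TAA"
        d = plain_design(cds + "C" * 7, [dsg.OrfAnnotation("o", 0, len(cds), "+")])
        with pytest.raises(dsg.DesignError, match="no degenerate codons"):
            dsg.embed_watermarks(d, ["o"], ["1"])

    def test_watermarking_never_changes_length(self):
        d, _ = self._watermarked(["10101010"])
        assert len(d.sequence) == len(d.initial_sequence)

    def test_unwatermarked_orf_decodes_empty(self):
        d, _ = self._watermarked(["11"])
        other = [o.id for o in d.orf_features()][-1]
        assert dsg.decode_watermark(d, other) == ""

    def test_alternate_codon_maximal_distance_deterministic_tie(self):
        # Leu CTG: TTA is the unique synonym at Hamming distance 2
        assert alternate_codon("CTG") == "TTA"
        # Gly GGG: GGA/GGC/GGT all at distance 1 -> lexicographic tie-break
        assert alternate_codon("GGG") == "GGA"
        assert alternate_codon("ATG") is None  # Met has no synonym


class TestValidation:
    def test_fresh_design_passes_with_zero_loxpsym(self):
        frags = sim.generate_pan_fragments(
            sim.FragmentSpec(n_fragments=3, size_range=(2000, 4000), seed=8)
        )
        d = dsg.concatenate_fragments(frags, BACKBONE)
        report = dsg.validate_design(d)
        assert report.passed, report.failures()
        assert report["loxpsym_count"] == (True, "0")

    def test_planted_restriction_site_flagged(self):
        frags = sim.generate_pan_fragments(
            sim.FragmentSpec(n_fragments=2, size_range=(2000, 3000), seed=9)
        )
        d = dsg.concatenate_fragments(frags, BACKBONE)
        pos = next(
            p for p in range(len(d.sequence))
            if not any(f.start < p + 8 and f.end > p for f in d.features)
        )
        d.sequence = d.sequence[:pos] + "GTTTAAAC" + d.sequence[pos + 8 :]
        d.initial_sequence = d.sequence
        report = dsg.validate_design(d)
        ok, detail = report["restriction_sites_absent"]
        assert not ok and "PmeI" in detail
        # independent oracle: plain substring search finds it too
        assert pos in find_all(d.sequence, "GTTTAAAC")

    def test_edit_log_replay_detects_tampering(self):
        design = build_edited_design(
            seed=10, n_fragments=3, size_range=(2000, 4000), n_loxpsym=None
        )
        assert dsg.validate_design(design).passed
        flipped = "A" if design.sequence[0] != "A" else "C"
        design.sequence = flipped + design.sequence[1:]
        ok, _ = dsg.validate_design(design)["edit_log_replay"]
        assert not ok

    def test_full_edit_chain_validates(self):
        design = build_edited_design(
            seed=12, n_fragments=4, size_range=(2000, 6000), n_loxpsym=None
        )
        report = dsg.validate_design(design)
        assert report.passed, report.failures()


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_proteome_preserved_property(seed):
    """Random fragment sets: the edit chain never changes any translation."""
    design = build_edited_design(
        seed=seed, n_fragments=2, size_range=(1_500, 3_000), n_loxpsym=None
    )
    for orf in design.orf_features():
        assert translate(design.orf_cds(orf)) == orf.attributes["original_translation"]
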