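"""Shared fixtures: synthetic designs at the scales the checks need."""

from __future__ import annotations

import pytest

from neochrom import design as dsg
from neochrom import scramble as scr
from neochrom import simulate as sim


def build_edited_design(
    seed: int = 1,
    n_fragments: int = 17,
    size_range: tuple[int, int] = (1_100, 60_300),
    n_loxpsym: int | None = 63,
):
    """Fragments -> concatenate -> recode -> loxPsym, ready for downstream."""
    frags = sim.generate_pan_fragments(
        sim.FragmentSpec(n_fragments=n_fragments, size_range=size_range, seed=seed)
    )
    backbone = sim.make_backbone(seed=seed + 1)
    design = dsg.concatenate_fragments(frags, backbone)
    dsg.recode_stop_codons(design)
    if n_loxpsym is None:
        dsg.insert_loxpsym(design)
    else:
        high = [
            o.id
            for o in design.orf_features()
            if o.attributes["confidence"] == "high"
        ][:n_loxpsym]
        dsg.insert_loxpsym(design, selection=high)
    return design


@pytest.fixture(scope="session")
def pgnc_design():
    """A full-scale edited design with 63 loxPsym sites."""
    return build_edited_design()


@pytest.fixture(scope="session")
def pgnc_segmap(pgnc_design):
    return scr.build_segment_map(pgnc_design)


@pytest.fixture(scope="session")
def pgnc_essential(pgnc_design):
    backbone = pgnc_design.feature_by_id("backbone")
    return [scr.segment_containing(pgnc_design, backbone.start)]


@pytest.fixture(scope="session")
def small_design():
    """A quick ~40 kb edited design for chunking/primer/IO tests."""
    return build_edited_design(
        seed=11, n_fragments=6, size_range=(2_000, 12_000), n_loxpsym=None
    )
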