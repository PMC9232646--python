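"""Telomerator-style linearization of a circular design.

The telomerator converts a circular molecule into a linear chromosome at its
insertion locus, seeding telomeres at the new ends. Here that is a single
deterministic sequence transformation: rotate the circle to open at the cut
locus, excise the cassette's counter-selectable marker (loss of which is
what the downstream 5-FOA selection enforces), and append telomere seed
repeats at both ends. The left end carries the complement-strand repeat
(CA-type) and the right end the G-strand repeat (TG-type), so re-reading the
molecule end-to-end looks like a real chromosome arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .design import DesignError, Feature, NeoChromosomeDesign
from .seqtools import revcomp, rotate, rotations_equal


@dataclass
class TelomereSeed:
    repeat_unit: str = "TG"
    n_repeats: int = 30

    @property
    def right(self) -> str:
        return self.repeat_unit * self.n_repeats

    @property
    def left(self) -> str:
        return revcomp(self.right)

    def __len__(self) -> int:
        return len(self.repeat_unit) * self.n_repeats


@dataclass
class LinearVariant:
    parent: str
    cut_locus: int
    sequence: str
    telomere_seed: TelomereSeed
    features: list[Feature] = field(default_factory=list)
    dropped_features: list[str] = field(default_factory=list)

    @property
    def topology(self) -> str:
        return "linear"

    def strip_seeds(self) -> str:
        """The linear sequence with both telomere seeds removed."""
        k = len(self.telomere_seed)
        return self.sequence[k : len(self.sequence) - k]

    def recircularize(self) -> str:
        """Join the seed-stripped ends back into the parent circle's phase."""
        core = self.strip_seeds()
        return rotate(core, len(core) - self.cut_locus)

    def as_design(self) -> NeoChromosomeDesign:
        return NeoChromosomeDesign(
            name=f"{self.parent}_lin{self.cut_locus}",
            topology="linear",
            sequence=self.sequence,
            features=[Feature(f.id, f.type, f.start, f.end, f.strand, dict(f.attributes)) for f in self.features],
            initial_sequence=self.sequence,
            metadata={"parent": self.parent, "cut_locus": self.cut_locus},
        )


def linearize_at(
    design: NeoChromosomeDesign,
    locus: int,
    cassette_marker: str | None = None,
    seed: TelomereSeed | None = None,
    override: bool = False,
) -> LinearVariant:
    """Cut a circular design at ``locus`` and seed telomeres at both ends.

    Features are remapped onto the linear molecule; a feature spanning the
    cut point is dropped with a report unless the cut is disallowed outright
    (``override=False`` raises when the locus falls inside any feature).
    The named cassette marker feature, if present, is excised from the
    annotation (its sequence is assumed removed with the cassette remnant
    during counter-selection, so the returned molecule carries no marker).
    """
    if not design.is_circular:
        raise DesignError("linearize_at requires a circular design")
    n = len(design.sequence)
    locus %= n
    seed = seed or TelomereSeed()

    spanning = [f for f in design.features if f.start < locus < f.end]
    if spanning and not override:
        raise DesignError(
            f"cut locus {locus} falls inside feature(s) "
            f"{[f.id for f in spanning]}; pass override=True to cut anyway"
        )

    core = rotate(design.sequence, locus)
    left = seed.left
    sequence = left + core + seed.right

    features: list[Feature] = []
    dropped = [f.id for f in spanning]
    for f in design.features:
        if f in spanning:
            continue
        if cassette_marker is not None and f.id == cassette_marker:
            dropped.append(f.id)
            continue
        start = (f.start - locus) % n
        end = start + f.length()
        if end > n:  # wraps the new origin without containing the cut point
            dropped.append(f.id)
            continue
        features.append(
            Feature(
                id=f.id,
                type=f.type,
                start=start + len(left),
                end=end + len(left),
                strand=f.strand,
                attributes=dict(f.attributes),
            )
        )
    features.append(
        Feature("telomere_seed_L", "telomere_seed", 0, len(left), "+", {})
    )
    features.append(
        Feature(
            "telomere_seed_R",
            "telomere_seed",
            len(sequence) - len(seed.right),
            len(sequence),
            "+",
            {},
        )
    )
    variant = LinearVariant(
        parent=design.name,
        cut_locus=locus,
        sequence=sequence,
        telomere_seed=seed,
        features=features,
        dropped_features=dropped,
    )
    assert rotations_equal(variant.strip_seeds(), design.sequence)
    return variant
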