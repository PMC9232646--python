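"""Neo-chromosome design: concatenation and Sc2.0-style sequence edits.

A design is built by concatenating pan-genome fragments in descending size
order onto a centromeric backbone, then edited in a fixed order:

1. :func:`recode_stop_codons` — terminal TAG stop codons become TAA;
2. :func:`embed_watermarks` — synonymous-codon watermarks inside chosen ORFs;
3. :func:`insert_loxpsym` — a 34-bp symmetric Cre site 3 bp downstream of the
   stop codon of selected high-confidence ORFs.

Every edit is appended to an ordered edit log; replaying the log on the
concatenated input reproduces the design byte-identically, which
:func:`validate_design` checks along with alphabet, bounds, stop-codon,
translation-preservation and restriction-site constraints.

Coordinates are 0-based half-open on the stored forward strand; circular
designs keep their origin at index 0 and insertion points wrap modulo length.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .seqtools import (
    LOXPSYM,
    NOTI_SITE,
    PMEI_SITE,
    STOP_CODONS,
    alternate_codon,
    find_all,
    revcomp,
    translate,
    validate_dna,
)

#: Edits must not create new copies of these motifs.
FORBIDDEN_MOTIFS = (LOXPSYM, PMEI_SITE, NOTI_SITE)


class DesignError(ValueError):
    """Raised when a design operation's preconditions are violated."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class OrfAnnotation:
    """An open reading frame on a fragment (0-based, half-open)."""

    id: str
    start: int
    end: int
    strand: str
    confidence: str = "high"
    product: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise DesignError(f"ORF {self.id}: strand must be '+' or '-'")
        if self.end <= self.start:
            raise DesignError(f"ORF {self.id}: empty or inverted interval")

    def violations(self, fragment_seq: str) -> list[str]:
        """Structural problems, reported rather than silently accepted."""
        out = []
        length = self.end - self.start
        if length % 3 != 0 or length < 6:
            out.append(f"ORF {self.id}: length {length} not a multiple of 3 >= 6")
            return out
        if self.end > len(fragment_seq):
            out.append(f"ORF {self.id}: extends past fragment end")
            return out
        cds = fragment_seq[self.start : self.end]
        if self.strand == "-":
            cds = revcomp(cds)
        if not cds.startswith("ATG"):
            out.append(f"ORF {self.id}: first codon {cds[:3]} is not ATG")
        if cds[-3:] not in STOP_CODONS:
            out.append(f"ORF {self.id}: last codon {cds[-3:]} is not a stop codon")
        return out


@dataclass
class Fragment:
    """A pan-genome DNA fragment with its ORF annotations.

    ``features`` carries non-ORF annotations (centromere, marker, ...) which
    matters for the assembly backbone.
    """

    id: str
    sequence: str
    source_label: str = ""
    orfs: list[OrfAnnotation] = field(default_factory=list)
    features: list["Feature"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DesignError(f"fragment {self.id}: empty sequence")
        validate_dna(self.sequence, context=f"fragment {self.id}")
        for orf in self.orfs:
            if orf.end > len(self.sequence):
                raise DesignError(f"ORF {orf.id} out of bounds on fragment {self.id}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Feature:
    """A typed annotation interval on a design (forward-strand coordinates)."""

    id: str
    type: str  # ORF | loxPsym | watermark | marker | backbone | ARS | telomere_seed | cassette | centromere
    start: int
    end: int
    strand: str = "+"
    attributes: dict = field(default_factory=dict)

    def length(self) -> int:
        return self.end - self.start


@dataclass
class Watermark:
    """Synonymous-codon payload embedded in one ORF."""

    orf_id: str
    codon_window: tuple[int, int]  # (first codon index, n codons)
    payload: str  # bit string
    bit_codon_indices: list[int]  # codon indices actually carrying bits
    original_codons: list[str]
    recoded_codons: list[str]
    skipped_codon_indices: list[int] = field(default_factory=list)


@dataclass
class ValidationReport:
    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, name: str, ok: bool, detail: str = "") -> None:
        self.checks.append((name, bool(ok), detail))

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failures(self) -> list[tuple[str, str]]:
        return [(name, detail) for name, ok, detail in self.checks if not ok]

    def __getitem__(self, name: str) -> tuple[bool, str]:
        for n, ok, detail in self.checks:
            if n == name:
                return ok, detail
        raise KeyError(name)


@dataclass
class NeoChromosomeDesign:
    name: str
    topology: str  # "circular" | "linear"
    sequence: str
    features: list[Feature] = field(default_factory=list)
    edit_log: list[dict] = field(default_factory=list)
    initial_sequence: str = ""
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def orf_features(self) -> list[Feature]:
        return [f for f in self.features if f.type == "ORF"]

    def loxpsym_features(self) -> list[Feature]:
        return sorted(
            (f for f in self.features if f.type == "loxPsym"), key=lambda f: f.start
        )

    def feature_by_id(self, fid: str) -> Feature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(f"no feature with id {fid!r}")

    def copy(self) -> "NeoChromosomeDesign":
        return _copy.deepcopy(self)

    def orf_cds(self, orf: Feature) -> str:
        cds = self.sequence[orf.start : orf.end]
        return revcomp(cds) if orf.strand == "-" else cds


# ---------------------------------------------------------------------------
# Edit-log plumbing
# ---------------------------------------------------------------------------


def _apply_edit(
    design: NeoChromosomeDesign,
    op: str,
    pos: int,
    removed: str,
    inserted: str,
    detail: str = "",
) -> None:
    """Splice ``inserted`` over ``removed`` at ``pos``, shifting features.

    Length-changing edits shift every feature lying entirely at or beyond
    the edited region; callers are responsible for not editing inside
    features they do not own.
    """
    seq = design.sequence
    if seq[pos : pos + len(removed)] != removed:
        raise DesignError(
            f"edit {op!r} at {pos}: expected {removed!r}, "
            f"found {seq[pos : pos + len(removed)]!r}"
        )
    design.sequence = seq[:pos] + inserted + seq[pos + len(removed) :]
    delta = len(inserted) - len(removed)
    if delta:
        cut = pos + len(removed)
        for f in design.features:
            if f.start >= cut or (not removed and f.start >= pos):
                f.start += delta
                f.end += delta
            elif f.end > pos and f.start < pos and f.end >= cut:
                # edit strictly inside the feature: it grows/shrinks
                f.end += delta
    design.edit_log.append(
        {
            "op": op,
            "pos": pos,
            "removed": removed,
            "inserted": inserted,
            "detail": detail,
            "length_before": len(seq),
            "length_after": len(design.sequence),
        }
    )


def replay_edit_log(initial_sequence: str, edit_log: Iterable[dict]) -> str:
    """Re-apply an edit log to the concatenated input sequence."""
    seq = initial_sequence
    for e in edit_log:
        pos, removed, inserted = e["pos"], e["removed"], e["inserted"]
        if seq[pos : pos + len(removed)] != removed:
            raise DesignError(f"edit log replay mismatch at {pos} ({e['op']})")
        seq = seq[:pos] + inserted + seq[pos + len(removed) :]
    return seq


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def concatenate_fragments(
    fragments: Sequence[Fragment],
    backbone: Fragment,
    name: str = "neochromosome",
) -> NeoChromosomeDesign:
    """Concatenate fragments in descending size order onto a backbone.

    Fragments are ordered largest first (ties broken by id), the backbone is
    appended last and the resulting molecule is circular. ORF annotations are
    lifted to design coordinates and each ORF's translation is recorded so
    later edits can prove they preserved the proteome.
    """
    if not fragments:
        raise DesignError("at least one fragment is required")
    ids = [f.id for f in fragments]
    if len(set(ids)) != len(ids):
        raise DesignError("duplicate fragment ids")
    if not (backbone.features or backbone.orfs):
        raise DesignError("backbone must carry centromere/selection features")

    ordered = sorted(fragments, key=lambda f: (-len(f), f.id))
    pieces = []
    features: list[Feature] = []
    offset = 0
    for frag in ordered:
        pieces.append(frag.sequence)
        for orf in frag.orfs:
            features.append(
                Feature(
                    id=orf.id,
                    type="ORF",
                    start=offset + orf.start,
                    end=offset + orf.end,
                    strand=orf.strand,
                    attributes={
                        "confidence": orf.confidence,
                        "source_fragment": frag.id,
                        **({"product": orf.product} if orf.product else {}),
                    },
                )
            )
        offset += len(frag)

    backbone_start = offset
    pieces.append(backbone.sequence)
    for orf in backbone.orfs:
        features.append(
            Feature(
                id=orf.id,
                type="ORF",
                start=backbone_start + orf.start,
                end=backbone_start + orf.end,
                strand=orf.strand,
                attributes={"confidence": orf.confidence, "source_fragment": backbone.id},
            )
        )
    for f in backbone.features:
        features.append(
            Feature(
                id=f.id,
                type=f.type,
                start=backbone_start + f.start,
                end=backbone_start + f.end,
                strand=f.strand,
                attributes=dict(f.attributes),
            )
        )
    features.append(
        Feature(
            id="backbone",
            type="backbone",
            start=backbone_start,
            end=backbone_start + len(backbone),
            strand="+",
            attributes={"source_fragment": backbone.id},
        )
    )

    sequence = "".join(pieces)
    design = NeoChromosomeDesign(
        name=name,
        topology="circular",
        sequence=sequence,
        features=features,
        initial_sequence=sequence,
        metadata={
            "fragment_order": [f.id for f in ordered] + [backbone.id],
            "loxpsym_site": LOXPSYM,
        },
    )
    for orf in design.orf_features():
        orf.attributes["original_translation"] = translate(design.orf_cds(orf))
    return design


def _terminal_stop(design: NeoChromosomeDesign, orf: Feature) -> tuple[int, str]:
    """Forward-strand interval start and ORF-strand codon of the stop."""
    if orf.strand == "+":
        pos = orf.end - 3
        codon = design.sequence[pos : pos + 3]
    else:
        pos = orf.start
        codon = revcomp(design.sequence[pos : pos + 3])
    return pos, codon


def recode_stop_codons(design: NeoChromosomeDesign) -> NeoChromosomeDesign:
    """Replace every terminal TAG stop codon with TAA (TAA/TGA untouched)."""
    violations: list[str] = []
    for orf in design.orf_features():
        pos, codon = _terminal_stop(design, orf)
        if codon not in STOP_CODONS:
            violations.append(f"ORF {orf.id}: terminal codon {codon} is not a stop")
            continue
        if codon == "TAG":
            new = "TAA" if orf.strand == "+" else revcomp("TAA")
            old = design.sequence[pos : pos + 3]
            _apply_edit(
                design, "recode_stop", pos, old, new, detail=f"ORF {orf.id} TAG->TAA"
            )
    design.metadata["stops_recoded"] = True
    design.metadata.setdefault("orf_stop_violations", []).extend(violations)
    return design


def loxpsym_insertion_point(orf: Feature, spacer: int = 3) -> int:
    """Insertion index placing the site ``spacer`` bp past the stop codon.

    On '+' ORFs the site goes downstream of ``end``; on '-' ORFs downstream
    in ORF orientation means leftward of ``start`` in forward coordinates.
    """
    return orf.end + spacer if orf.strand == "+" else orf.start - spacer


def insert_loxpsym(
    design: NeoChromosomeDesign,
    selection: Sequence[str] | Callable[[Feature], bool] | None = None,
    site: str = LOXPSYM,
    spacer: int = 3,
    on_collision: str = "skip",
) -> NeoChromosomeDesign:
    """Insert the symmetric Cre site 3 bp after selected ORFs' stop codons.

    ``selection`` is ``None`` (all high-confidence ORFs), a list of ORF ids,
    or a predicate over ORF features. Insertions are applied in descending
    coordinate order so earlier coordinates stay valid; an insertion point
    falling strictly inside another feature is skipped and reported (or
    raises with ``on_collision='error'``).
    """
    if not design.metadata.get("stops_recoded"):
        raise DesignError("recode_stop_codons must run before insert_loxpsym")
    if revcomp(site) != site:
        raise DesignError("loxPsym site must be self-reverse-complementary")
    if on_collision not in ("skip", "error"):
        raise DesignError("on_collision must be 'skip' or 'error'")

    orfs = design.orf_features()
    if selection is None:
        chosen = [o for o in orfs if o.attributes.get("confidence") == "high"]
    elif callable(selection):
        chosen = [o for o in orfs if selection(o)]
    else:
        wanted = set(selection)
        chosen = [o for o in orfs if o.id in wanted]
        missing = wanted - {o.id for o in chosen}
        if missing:
            raise DesignError(f"selected ORFs not found: {sorted(missing)}")

    n = len(design.sequence)
    planned = []
    for orf in chosen:
        p = loxpsym_insertion_point(orf, spacer)
        if design.is_circular:
            p %= n
        elif not 0 <= p <= n:
            p = None
        planned.append((orf, p))

    skipped: list[str] = []
    inserted = 0
    for orf, p in sorted(planned, key=lambda t: -(t[1] if t[1] is not None else -1)):
        if p is None:
            skipped.append(f"{orf.id}: insertion point outside linear design")
            continue
        hit = next(
            (f for f in design.features if f.start < p < f.end and f.id != orf.id),
            None,
        )
        if hit is not None:
            msg = f"{orf.id}: insertion point {p} inside feature {hit.id}"
            if on_collision == "error":
                raise DesignError(msg)
            skipped.append(msg)
            continue
        _apply_edit(
            design, "insert_loxpsym", p, "", site, detail=f"after ORF {orf.id}"
        )
        design.features.append(
            Feature(
                id=f"loxPsym_{orf.id}",
                type="loxPsym",
                start=p,
                end=p + len(site),
                strand="+",
                attributes={"after_orf": orf.id},
            )
        )
        inserted += 1

    design.metadata["loxpsym_site"] = site
    design.metadata.setdefault("loxpsym_skipped", []).extend(skipped)
    design.metadata["loxpsym_count"] = len(design.loxpsym_features())
    return design


def _codon_interval(orf: Feature, codon_index: int) -> tuple[int, int]:
    """Forward-strand interval of codon ``codon_index`` (0-based from ATG)."""
    if orf.strand == "+":
        s = orf.start + 3 * codon_index
    else:
        s = orf.end - 3 * (codon_index + 1)
    return s, s + 3


def _read_codon(design: NeoChromosomeDesign, orf: Feature, codon_index: int) -> str:
    s, e = _codon_interval(orf, codon_index)
    codon = design.sequence[s:e]
    return revcomp(codon) if orf.strand == "-" else codon


def _motif_counts(seq: str, lo: int, hi: int) -> dict[str, int]:
    window = seq[max(0, lo) : min(len(seq), hi)]
    return {m: window.count(m) for m in FORBIDDEN_MOTIFS}


def embed_watermarks(
    design: NeoChromosomeDesign,
    orf_ids: Sequence[str],
    payloads: Sequence[str],
    window_start: int = 10,
    window_len: int = 12,
) -> NeoChromosomeDesign:
    """Embed bit-string payloads as synonymous codon swaps inside ORFs.

    Within a window of ``window_len`` codons starting at codon
    ``window_start``, each codon with at least one synonym carries one bit:
    bit 0 keeps the original codon, bit 1 swaps to the synonym at maximal
    nucleotide Hamming distance (ties to the lexicographically smallest).
    Swaps that would create a loxPsym/PmeI/NotI occurrence are skipped and
    the bit moves to the next degenerate codon. Translations are unchanged
    by construction.
    """
    if len(orf_ids) != len(payloads):
        raise DesignError("orf_ids and payloads must have equal length")
    for orf_id, payload in zip(orf_ids, payloads):
        if set(payload) - {"0", "1"}:
            raise DesignError(f"payload for {orf_id} is not a bit string")
        orf = design.feature_by_id(orf_id)
        if orf.type != "ORF":
            raise DesignError(f"{orf_id} is not an ORF feature")
        n_codons = orf.length() // 3
        if window_start + window_len > n_codons - 1:
            raise DesignError(
                f"ORF {orf_id}: window [{window_start}, {window_start + window_len}) "
                f"does not fit in {n_codons} codons (stop excluded)"
            )
        window = list(range(window_start, window_start + window_len))
        degenerate = [i for i in window if alternate_codon(_read_codon(design, orf, i))]
        if not degenerate:
            raise DesignError(f"ORF {orf_id}: no degenerate codons in window")
        if len(payload) > len(degenerate):
            raise DesignError(
                f"ORF {orf_id}: payload of {len(payload)} bits exceeds "
                f"{len(degenerate)} degenerate codons in window"
            )

        used: list[int] = []
        originals: list[str] = []
        recoded: list[str] = []
        skipped: list[int] = []
        queue = list(degenerate)
        for bit in payload:
            placed = False
            while queue and not placed:
                ci = queue.pop(0)
                original = _read_codon(design, orf, ci)
                if bit == "0":
                    used.append(ci)
                    originals.append(original)
                    recoded.append(original)
                    placed = True
                    continue
                new = alternate_codon(original)
                s, e = _codon_interval(orf, ci)
                fwd_new = revcomp(new) if orf.strand == "-" else new
                lo, hi = s - 40, e + 40
                before = _motif_counts(design.sequence, lo, hi)
                trial = design.sequence[:s] + fwd_new + design.sequence[e:]
                after = _motif_counts(trial, lo, hi)
                if any(after[m] > before[m] for m in FORBIDDEN_MOTIFS):
                    skipped.append(ci)
                    continue
                _apply_edit(
                    design,
                    "watermark_codon",
                    s,
                    design.sequence[s:e],
                    fwd_new,
                    detail=f"ORF {orf_id} codon {ci} {original}->{new}",
                )
                used.append(ci)
                originals.append(original)
                recoded.append(new)
                placed = True
            if not placed:
                raise DesignError(
                    f"ORF {orf_id}: payload does not fit after skipping "
                    f"codons that would create restriction/loxPsym sites"
                )

        ws, we = _codon_interval(orf, window[0])
        ws2, we2 = _codon_interval(orf, window[-1])
        design.features.append(
            Feature(
                id=f"watermark_{orf_id}",
                type="watermark",
                start=min(ws, ws2),
                end=max(we, we2),
                strand=orf.strand,
                attributes={
                    "orf_id": orf_id,
                    "codon_window": (window_start, window_len),
                    "bit_codon_indices": used,
                    "original_codons": originals,
                    "recoded_codons": recoded,
                    "skipped_codon_indices": skipped,
                },
            )
        )
    return design


def decode_watermark(design: NeoChromosomeDesign, orf_id: str) -> str:
    """Recover a watermark payload by comparing codons with their originals.

    Returns the empty string when the ORF carries no watermark feature.
    """
    wm = next(
        (
            f
            for f in design.features
            if f.type == "watermark" and f.attributes.get("orf_id") == orf_id
        ),
        None,
    )
    if wm is None:
        return ""
    orf = design.feature_by_id(orf_id)
    bits = []
    for ci, original in zip(
        wm.attributes["bit_codon_indices"], wm.attributes["original_codons"]
    ):
        current = _read_codon(design, orf, ci)
        if current == original:
            bits.append("0")
        elif current == alternate_codon(original):
            bits.append("1")
        else:
            raise DesignError(
                f"watermark on {orf_id}: codon {ci} is {current}, neither the "
                f"original {original} nor its encoding alternate"
            )
    return "".join(bits)


def validate_design(
    design: NeoChromosomeDesign,
    allowed_site_positions: dict[str, set[int]] | None = None,
) -> ValidationReport:
    """Run the full battery of structural checks on a design."""
    report = ValidationReport()
    seq, n = design.sequence, len(design.sequence)

    bad = set(seq) - set("ACGT")
    report.add("alphabet", not bad, f"illegal characters: {sorted(bad)}" if bad else "")

    oob = [f.id for f in design.features if not (0 <= f.start < f.end <= n)]
    report.add("feature_bounds", not oob, f"out of bounds: {oob[:5]}" if oob else "")

    bad_stops = []
    expected = {"TAA", "TGA"} if design.metadata.get("stops_recoded") else STOP_CODONS
    for orf in design.orf_features():
        _, codon = _terminal_stop(design, orf)
        if codon not in expected:
            bad_stops.append(f"{orf.id}:{codon}")
    report.add(
        "orf_terminal_stops", not bad_stops, ", ".join(bad_stops[:5]) if bad_stops else ""
    )

    site = design.metadata.get("loxpsym_site", LOXPSYM)
    lox = design.loxpsym_features()
    wrong = [
        f.id
        for f in lox
        if seq[f.start : f.end] != site or f.length() != len(site)
    ]
    report.add(
        "loxpsym_sequences",
        not wrong and revcomp(site) == site,
        f"bad sites: {wrong[:5]}" if wrong else "",
    )
    overlaps = [
        (a.id, b.id) for a, b in zip(lox, lox[1:]) if b.start < a.end
    ]
    report.add("loxpsym_nonoverlapping", not overlaps, str(overlaps[:3]))
    report.add("loxpsym_count", True, str(len(lox)))

    changed = []
    for orf in design.orf_features():
        orig = orf.attributes.get("original_translation")
        if orig is not None and translate(design.orf_cds(orf)) != orig:
            changed.append(orf.id)
    report.add(
        "translations_preserved", not changed, f"changed: {changed[:5]}" if changed else ""
    )

    allowed = allowed_site_positions or {}
    offending = []
    for motif_name, motif in (("PmeI", PMEI_SITE), ("NotI", NOTI_SITE)):
        hits = find_all(seq, motif, circular=design.is_circular)
        extra = [h for h in hits if h not in allowed.get(motif_name, set())]
        offending.extend((motif_name, h) for h in extra)
    report.add(
        "restriction_sites_absent",
        not offending,
        f"unexpected sites: {offending[:5]}" if offending else "",
    )

    try:
        replayed = replay_edit_log(design.initial_sequence, design.edit_log)
        report.add("edit_log_replay", replayed == seq, "")
    except DesignError as err:
        report.add("edit_log_replay", False, str(err))

    report.add("total_length", True, str(n))
    counts: dict[str, int] = {}
    for f in design.features:
        counts[f.type] = counts.get(f.type, 0) + 1
    report.add("feature_counts", True, str(sorted(counts.items())))
    return report
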