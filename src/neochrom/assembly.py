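"""Synthesis chunking, iterative assembly planning and in-silico assembly.

A design is divided into ~10 kb chunks. Chunk *i*'s sequence is its body
(one arc of the design) plus a 200-bp right overhang copying the start of
chunk *i+1*'s body, so adjacent synthesized fragments share exactly one
200-bp homology window and concatenating the bodies alone reproduces the
design. Chunk boundaries are placed by greedy even spacing with a local
search for an overlap window that is unique in the design and free of
PmeI/NotI sites.

:func:`simulate_hr_assembly` models yeast homologous recombination as exact
joining of terminal windows; :func:`plan_assembly` produces the alternating
URA3/LEU2 marker schedule with a terminal marker-to-BFP swap;
:func:`design_junction_primers` finds junction-spanning confirmation primer
pairs using nearest-neighbor melting temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .design import DesignError, Feature, NeoChromosomeDesign, _apply_edit
from .seqtools import (
    NOTI_SITE,
    PMEI_SITE,
    count_occurrences,
    revcomp,
    rotations_equal,
)

MARKERS = ("URA3", "LEU2")


class AssemblyError(ValueError):
    pass


@dataclass
class Chunk:
    index: int
    body: str
    left_overhang: str
    right_overhang: str
    flank_sites: tuple[str, ...] = ("PmeI", "NotI")
    start: int = 0  # body start on the design
    internal_sites: list[tuple[str, int]] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        """The synthesized insert: body plus right homology overhang."""
        return self.body + self.right_overhang

    def as_synthesized(self) -> str:
        """Insert flanked by the release restriction sites."""
        left = PMEI_SITE if "PmeI" in self.flank_sites else ""
        right = NOTI_SITE if "NotI" in self.flank_sites else ""
        return left + self.sequence + right

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblyPlan:
    rounds: list[tuple[int, tuple[int, ...], str]]  # (round, chunk indices, marker)
    final_swap: tuple[str, str]  # (marker removed, cassette installed)

    def validate(self) -> None:
        seen: list[int] = []
        for k, (rnd, chunks, marker) in enumerate(self.rounds, start=1):
            if rnd != k:
                raise AssemblyError(f"round numbers must be 1..n, got {rnd}")
            if not 1 <= len(chunks) <= 4:
                raise AssemblyError(f"round {rnd} has {len(chunks)} chunks (1-4 allowed)")
            if marker not in MARKERS:
                raise AssemblyError(f"unknown marker {marker}")
            seen.extend(chunks)
        if seen != sorted(seen) or len(set(seen)) != len(seen):
            raise AssemblyError("chunks must appear exactly once, in order")
        markers = [m for _, _, m in self.rounds]
        for a, b in zip(markers, markers[1:]):
            if a == b:
                raise AssemblyError("markers must strictly alternate")
        if self.final_swap[0] != markers[-1]:
            raise AssemblyError("final swap must remove the last marker used")


@dataclass
class PrimerPair:
    junction_index: int
    forward: str
    reverse: str
    forward_start: int
    reverse_start: int  # start of the reverse primer's binding site (fwd coords)
    tm_forward: float
    tm_reverse: float
    product_length: int


# ---------------------------------------------------------------------------


def _circular_slice(seq: str, start: int, end: int) -> str:
    """seq[start:end] on a circle (end may exceed len(seq))."""
    n = len(seq)
    length = end - start
    if length > n:
        raise AssemblyError("slice longer than the molecule")
    start %= n
    stop = start + length
    if stop <= n:
        return seq[start:stop]
    return seq[start:] + seq[: stop - n]


def _window_admissible(design_seq: str, pos: int, overlap: int, circular: bool) -> bool:
    n = len(design_seq)
    if not circular and (pos < 0 or pos + overlap > n):
        return False
    window = _circular_slice(design_seq, pos, pos + overlap) if circular else design_seq[pos : pos + overlap]
    if PMEI_SITE in window or NOTI_SITE in window:
        return False
    return count_occurrences(design_seq, window, circular=circular) == 1


def chunk_design(
    design: NeoChromosomeDesign,
    target_size: int = 10_000,
    overlap: int = 200,
    max_shift: int = 1_000,
) -> list[Chunk]:
    """Divide a design into chunks of roughly ``target_size`` bp.

    Boundaries start at even spacing and are shifted locally (up to
    ``max_shift`` bp, capped at 10% of the target spacing) until each
    boundary's ``overlap``-bp window is unique in the design and free of
    PmeI/NotI sites. Concatenating chunk bodies reproduces the design.
    """
    seq = design.sequence
    n = len(seq)
    if n <= target_size:
        raise AssemblyError("design is not longer than the target chunk size")
    if overlap >= target_size:
        raise AssemblyError("overlap must be smaller than the chunk size")
    circular = design.is_circular
    n_chunks = max(2, round(n / target_size))
    spacing = n / n_chunks
    shift_cap = min(max_shift, int(0.1 * spacing))

    n_bounds = n_chunks if circular else n_chunks - 1
    first = 0 if circular else 1
    boundaries = []
    for k in range(first, first + n_bounds):
        ideal = round(k * spacing) % n if circular else round(k * spacing)
        placed = None
        for off in range(0, shift_cap + 1):
            for cand in ([ideal] if off == 0 else [ideal + off, ideal - off]):
                pos = cand % n if circular else cand
                if _window_admissible(seq, pos, overlap, circular):
                    placed = pos
                    break
            if placed is not None:
                break
        if placed is None:
            raise AssemblyError(
                f"no admissible boundary within {shift_cap} bp of position {ideal}"
            )
        boundaries.append(placed)
    if len(set(boundaries)) != len(boundaries):
        raise AssemblyError("boundary placement collapsed two boundaries")
    boundaries.sort()

    chunks: list[Chunk] = []
    if circular:
        starts = boundaries
        ends = boundaries[1:] + [boundaries[0] + n]
    else:
        starts = [0] + boundaries
        ends = boundaries + [n]
    for i, (s, e) in enumerate(zip(starts, ends)):
        body = _circular_slice(seq, s, e) if circular else seq[s:e]
        if circular or i < len(starts) - 1:
            right = _circular_slice(seq, e % n, e % n + overlap) if circular else seq[e : e + overlap]
        else:
            right = ""
        left = body[:overlap] if (circular or i > 0) else ""
        internal = [
            (name, body.find(site))
            for name, site in (("PmeI", PMEI_SITE), ("NotI", NOTI_SITE))
            if site in body
        ]
        chunks.append(
            Chunk(
                index=i,
                body=body,
                left_overhang=left,
                right_overhang=right,
                start=s % n if circular else s,
                internal_sites=internal,
            )
        )
    return chunks


def plan_assembly(
    chunks: Sequence[Chunk] | int,
    per_round_max: int = 4,
    first_marker: str = "URA3",
    opening_rounds: tuple[int, ...] = (2, 3),
    final_cassette: str = "BFP",
) -> AssemblyPlan:
    """Group chunks into assembly rounds with alternating markers.

    The default grouping opens with rounds of 2 and 3 chunks (matching the
    historical build schedule) and then packs ``per_round_max`` chunks per
    round; markers alternate strictly and the final step swaps the last
    marker for the ``final_cassette``.
    """
    n = chunks if isinstance(chunks, int) else len(chunks)
    if n < 1:
        raise AssemblyError("at least one chunk required")
    if not 1 <= per_round_max <= 4:
        raise AssemblyError("per_round_max must be between 1 and 4")
    if first_marker not in MARKERS:
        raise AssemblyError(f"first_marker must be one of {MARKERS}")

    sizes: list[int] = []
    remaining = n
    for size in opening_rounds:
        if remaining <= 0:
            break
        take = min(size, remaining, per_round_max)
        sizes.append(take)
        remaining -= take
    while remaining > 0:
        take = min(per_round_max, remaining)
        sizes.append(take)
        remaining -= take

    order = [first_marker, MARKERS[1 - MARKERS.index(first_marker)]]
    rounds = []
    idx = 1
    for r, size in enumerate(sizes, start=1):
        rounds.append((r, tuple(range(idx, idx + size)), order[(r - 1) % 2]))
        idx += size
    plan = AssemblyPlan(rounds=rounds, final_swap=(rounds[-1][2], final_cassette))
    plan.validate()
    return plan


def simulate_hr_assembly(
    pieces: Sequence[str],
    circularize: bool = True,
    overlap: int = 200,
) -> str:
    """Join linear pieces wherever terminal windows match exactly.

    Each piece's last ``overlap`` bp must equal exactly one other piece's
    first ``overlap`` bp; ambiguous or missing overlaps are errors. With
    ``circularize`` the chain must close into a single circle and the
    returned string starts at piece 0's body.
    """
    if len(pieces) < 2:
        raise AssemblyError("at least two pieces required")
    for i, p in enumerate(pieces):
        if len(p) < overlap + 1:
            raise AssemblyError(f"piece {i} shorter than the overlap window")

    heads = {}
    for j, p in enumerate(pieces):
        heads.setdefault(p[:overlap], []).append(j)
    successor: dict[int, int] = {}
    dangling: list[int] = []
    for i, p in enumerate(pieces):
        tail = p[-overlap:]
        partners = [j for j in heads.get(tail, []) if j != i]
        if len(partners) > 1:
            raise AssemblyError(
                f"ambiguous join: piece {i} tail matches heads of pieces {partners}"
            )
        if partners:
            successor[i] = partners[0]
        else:
            dangling.append(i)

    if circularize:
        if dangling or len(set(successor.values())) != len(pieces):
            raise AssemblyError(
                f"cannot circularize: unjoined termini on pieces {dangling}"
            )
        order = [0]
        while True:
            nxt = successor[order[-1]]
            if nxt == 0:
                break
            if nxt in order:
                raise AssemblyError("pieces form more than one circle")
            order.append(nxt)
        if len(order) != len(pieces):
            raise AssemblyError("pieces form more than one circle")
        return "".join(pieces[i][:-overlap] for i in order)

    if len(dangling) != 1:
        raise AssemblyError(f"linear assembly needs exactly one end; got {dangling}")
    preds = set(successor.values())
    starts = [i for i in range(len(pieces)) if i not in preds]
    if len(starts) != 1:
        raise AssemblyError(f"linear assembly needs exactly one start; got {starts}")
    order = [starts[0]]
    while order[-1] in successor:
        order.append(successor[order[-1]])
    if len(order) != len(pieces):
        raise AssemblyError("disconnected pieces remain unjoined")
    out = pieces[order[0]]
    for i in order[1:]:
        out += pieces[i][overlap:]
    return out


# ---------------------------------------------------------------------------
# Junction confirmation primers
# ---------------------------------------------------------------------------


def primer_tm(seq: str, Na: float = 50.0, dnac1: float = 500.0) -> float:
    """Nearest-neighbor melting temperature (SantaLucia unified parameters).

    50 mM monovalent salt and 500 nM primer by default.
    """
    return float(_mt.Tm_NN(seq, Na=Na, dnac1=dnac1, dnac2=0, nn_table=_mt.DNA_NN3))


def _primer_unique(design_seq: str, primer: str, circular: bool) -> bool:
    hits = count_occurrences(design_seq, primer, circular=circular)
    rc = revcomp(primer)
    if rc != primer:
        hits += count_occurrences(design_seq, rc, circular=circular)
    return hits == 1


def design_junction_primers(
    design: NeoChromosomeDesign,
    chunks: Sequence[Chunk],
    primer_len: tuple[int, int] = (18, 25),
    tm_range: tuple[float, float] = (58.0, 62.0),
    product_range: tuple[int, int] = (400, 1000),
) -> list[PrimerPair]:
    """One junction-spanning confirmation primer pair per chunk junction.

    The amplicon covers the boundary between adjacent chunks (including the
    wrap-around junction on circular designs). Primers are unique in the
    design by exact search on both strands.
    """
    seq = design.sequence
    n = len(seq)
    circular = design.is_circular
    boundaries = [c.start for c in chunks[1:]]
    if circular:
        boundaries = [chunks[0].start] + boundaries

    def candidates(center: int, side: str, max_hits: int = 25):
        """Unique in-range primers at increasing distance off the junction."""
        hits = []
        for dist in range(150, 481, 3):
            for length in range(primer_len[0], primer_len[1] + 1):
                if side == "fwd":
                    start = center - dist
                    if not circular and start < 0:
                        continue
                    cand = _circular_slice(seq, start % n, start % n + length)
                else:
                    end = center + dist
                    start = end - length
                    if not circular and end > n:
                        continue
                    cand = revcomp(_circular_slice(seq, start % n, start % n + length))
                tm = primer_tm(cand)
                if tm_range[0] <= tm <= tm_range[1] and _primer_unique(
                    seq, cand, circular
                ):
                    hits.append((dist, cand, start % n if circular else start))
                    if len(hits) >= max_hits:
                        return hits
                    break  # one length per distance is enough
        return hits

    pairs = []
    for j, b in enumerate(boundaries):
        fwds = candidates(b, "fwd")
        revs = candidates(b, "rev")
        best = None
        for df, fwd_seq, fwd_start in fwds:
            for dr, rev_seq, rev_start in revs:
                product = df + dr
                if product_range[0] <= product <= product_range[1]:
                    score = abs(product - 600)
                    if best is None or score < best[0]:
                        best = (score, fwd_seq, fwd_start, rev_seq, rev_start, product)
        if best is None:
            raise AssemblyError(
                f"no unique primer pair satisfying constraints near junction {j} "
                f"(boundary {b})"
            )
        _, fwd_seq, fwd_start, rev_seq, rev_start, product = best
        pairs.append(
            PrimerPair(
                junction_index=j,
                forward=fwd_seq,
                reverse=rev_seq,
                forward_start=fwd_start,
                reverse_start=rev_start,
                tm_forward=primer_tm(fwd_seq),
                tm_reverse=primer_tm(rev_seq),
                product_length=product,
            )
        )
    return pairs


# ---------------------------------------------------------------------------


def replace_region(
    design: NeoChromosomeDesign,
    target: tuple[int, int] | str,
    payload: str,
    payload_name: str | None = None,
    payload_type: str = "cassette",
    override: bool = False,
) -> NeoChromosomeDesign:
    """Replace a target interval (or named feature) with a payload sequence.

    An empty payload deletes; a zero-length target inserts. Downstream
    feature coordinates shift; replacing across an ORF requires ``override``.
    The replaced feature (if named) is dropped and a payload feature added.
    """
    if payload:
        from .seqtools import validate_dna

        validate_dna(payload, context="payload")
    dropped: Feature | None = None
    if isinstance(target, str):
        dropped = design.feature_by_id(target)
        start, end = dropped.start, dropped.end
    else:
        start, end = target
    n = len(design.sequence)
    if not (0 <= start <= end <= n):
        raise DesignError(f"target interval ({start}, {end}) out of bounds")

    overlapping = [
        f
        for f in design.features
        if f.start < end and f.end > start and f is not dropped
    ]
    orf_hits = [f.id for f in overlapping if f.type == "ORF"]
    if orf_hits and not override:
        raise DesignError(
            f"target overlaps ORF(s) {orf_hits}; pass override=True to proceed"
        )
    if dropped is not None:
        design.features.remove(dropped)
    for f in overlapping:
        f.attributes["disrupted_by"] = payload_name or "replace_region"
    removed = design.sequence[start:end]
    _apply_edit(
        design,
        "replace_region",
        start,
        removed,
        payload,
        detail=payload_name or "",
    )
    if payload:
        design.features.append(
            Feature(
                id=payload_name or f"insert_{start}",
                type=payload_type,
                start=start,
                end=start + len(payload),
                strand="+",
                attributes={"replaced": dropped.id if dropped else None},
            )
        )
    return design


def verify_chunk_roundtrip(design: NeoChromosomeDesign, chunks: Sequence[Chunk]) -> bool:
    """True when reassembling the chunks reproduces the design (up to rotation)."""
    overlap = len(chunks[0].right_overhang) or len(chunks[0].left_overhang)
    if design.is_circular:
        assembled = simulate_hr_assembly(
            [c.sequence for c in chunks], circularize=True, overlap=overlap
        )
        return rotations_equal(assembled, design.sequence)
    assembled = simulate_hr_assembly(
        [c.sequence if c.right_overhang else c.body for c in chunks],
        circularize=False,
        overlap=overlap,
    )
    return assembled == design.sequence
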