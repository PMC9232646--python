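"""Cre/loxPsym recombination (SCRaMbLE) simulation and SV calling.

A design with *n* symmetric Cre sites on a circle is represented as a signed
circular sequence of the *n* loxPsym-delimited segments. Recombination
between two sites produces, depending on the relative capture of the excised
circle, a deletion (DEL), an inversion (INV) or a tandem duplication (DUP)
of the spanned segments; because loxPsym is its own reverse complement every
event leaves intact sites behind, so events compose.

The caller works backwards from an observed sequence: it re-locates the
sites, matches the intervening segments to the original segment vocabulary
by exact sequence (in either orientation), and searches for a minimal event
history (bounded, breakpoint-guided depth-first search over interleaved
deletions and inversions, plus tandem-run detection for duplications) that
transforms the original segment order into the observed one.

Copy number of the whole element is estimated from sequencing depth as the
ratio of the element's mean coverage to the mean coverage of large
(>200 kb) genomic contigs, so a gained element reads as a ratio above 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design import NeoChromosomeDesign
from .seqtools import LOXPSYM, find_all, revcomp, rotations_equal


class ScrambleError(ValueError):
    pass


SignedSeg = tuple[int, int]  # (segment id, +1 | -1)


@dataclass
class SegmentMap:
    """loxPsym-delimited segment structure of a molecule."""

    segments: dict[int, str]  # id -> forward sequence (design orientation)
    order: list[SignedSeg]
    topology: str = "circular"
    site: str = LOXPSYM
    origin_offset: int = 0  # design position of order[0]'s first base

    @property
    def n_sites(self) -> int:
        if self.topology == "circular":
            return len(self.order)
        return max(0, len(self.order) - 1)

    def realize(self, order: Sequence[SignedSeg] | None = None) -> str:
        """Sequence for a segment order: segments interleaved with sites."""
        order = self.order if order is None else list(order)
        parts = []
        for sid, sign in order:
            seq = self.segments[sid]
            parts.append(seq if sign > 0 else revcomp(seq))
            parts.append(self.site)
        if self.topology != "circular":
            parts = parts[:-1]
        return "".join(parts)

    def reconstruct(self) -> str:
        """The source molecule, byte-identical (undoes the site rotation)."""
        joined = self.realize()
        if self.topology != "circular" or not self.order:
            return joined
        n = len(joined)
        return joined[n - self.origin_offset :] + joined[: n - self.origin_offset]


@dataclass
class ScrambleEvent:
    index: int
    type: str  # DEL | INV | DUP
    site_pair: tuple[int, int]  # site indices at event time
    segment_ids: tuple[int, ...]  # original segment ids affected

    def key(self) -> tuple[str, frozenset[int]]:
        return (self.type, frozenset(self.segment_ids))


@dataclass
class SVReport:
    copy_number: dict[int, int]
    orientation: dict[int, list[int]]  # id -> signs of each copy in observed order
    events: list[ScrambleEvent]
    unexplained: bool = False
    notes: list[str] = field(default_factory=list)

    def event_keys(self) -> set[tuple[str, frozenset[int]]]:
        return {e.key() for e in self.events}


# ---------------------------------------------------------------------------
# Segment map construction
# ---------------------------------------------------------------------------


def _site_positions(sequence: str, site: str, circular: bool) -> list[int]:
    return sorted(find_all(sequence, site, circular=circular))


def build_segment_map(
    design: NeoChromosomeDesign | str,
    site: str = LOXPSYM,
    topology: str | None = None,
) -> SegmentMap:
    """Segment a molecule at its loxPsym sites.

    Segments are the maximal site-free intervals between consecutive sites;
    a molecule with no site yields a single segment. On a circle the segment
    count equals the site count.
    """
    if isinstance(design, NeoChromosomeDesign):
        sequence = design.sequence
        circular = design.is_circular
        site = design.metadata.get("loxpsym_site", site)
    else:
        sequence = design
        circular = (topology or "circular") == "circular"
    positions = _site_positions(sequence, site, circular)
    k = len(site)
    n = len(sequence)

    if not positions:
        return SegmentMap(
            segments={0: sequence},
            order=[(0, 1)],
            topology="circular" if circular else "linear",
            site=site,
            origin_offset=0,
        )

    segments: dict[int, str] = {}
    order: list[SignedSeg] = []
    if circular:
        for i, p in enumerate(positions):
            seg_start = (p + k) % n
            seg_end = positions[(i + 1) % len(positions)]
            seg = (
                sequence[seg_start:seg_end]
                if seg_start <= seg_end
                else sequence[seg_start:] + sequence[:seg_end]
            )
            segments[i] = seg
            order.append((i, 1))
        origin = (positions[0] + k) % n
        return SegmentMap(segments, order, "circular", site, origin_offset=origin)

    bounds = [0] + [p for p in positions for _ in (0,)] + [n]
    segs = []
    prev = 0
    for p in positions:
        segs.append(sequence[prev:p])
        prev = p + k
    segs.append(sequence[prev:])
    for i, seg in enumerate(segs):
        segments[i] = seg
        order.append((i, 1))
    return SegmentMap(segments, order, "linear", site, origin_offset=0)


def segment_containing(
    design: NeoChromosomeDesign, position: int, site: str | None = None
) -> int:
    """Id of the segment (per :func:`build_segment_map`) covering a position."""
    site = site or design.metadata.get("loxpsym_site", LOXPSYM)
    positions = _site_positions(design.sequence, site, design.is_circular)
    if not positions:
        return 0
    n = len(design.sequence)
    k = len(site)
    for i, p in enumerate(positions):
        start = (p + k) % n
        end = positions[(i + 1) % len(positions)]
        if start <= end:
            if start <= position < end:
                return i
        elif position >= start or position < end:
            return i
    raise ScrambleError(f"position {position} falls inside a loxPsym site")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _apply_inv(order: list[SignedSeg], i: int, j: int) -> list[SignedSeg]:
    """Reverse-complement segments i..j-1 (site indices i < j)."""
    span = [(sid, -sign) for sid, sign in reversed(order[i:j])]
    return order[:i] + span + order[j:]


def _apply_del(order: list[SignedSeg], i: int, j: int) -> list[SignedSeg]:
    return order[:i] + order[j:]


def _apply_dup(order: list[SignedSeg], i: int, j: int) -> list[SignedSeg]:
    return order[:i] + order[i:j] + order[i:j] + order[j:]


def simulate_scramble(
    design: NeoChromosomeDesign | SegmentMap,
    n_events: int | None = None,
    rate: float = 2.0,
    type_probs: dict[str, float] | None = None,
    essential_segments: Sequence[int] | None = None,
    seed: int | None = None,
    max_retries: int = 100,
) -> tuple[str, list[ScrambleEvent], SegmentMap]:
    """Apply random Cre recombination events between loxPsym site pairs.

    The event count is ``n_events`` if given, else Poisson(``rate``). Event
    types default to DEL 0.45 / INV 0.45 / DUP 0.10. Site pairs are sampled
    uniformly; a deletion removes the arc that spares every essential
    segment (resampled, then an error, if both arcs hit one). Returns the
    scrambled sequence, the replayable truth log, and the segment map whose
    current ``order`` is the scrambled state.
    """
    segmap = design if isinstance(design, SegmentMap) else build_segment_map(design)
    if segmap.topology != "circular":
        raise ScrambleError("SCRaMbLE simulation expects a circular molecule")
    rng = np.random.default_rng(seed)
    probs = type_probs or {"DEL": 0.45, "INV": 0.45, "DUP": 0.10}
    types = sorted(probs)
    p = np.array([probs[t] for t in types], dtype=float)
    p /= p.sum()
    essential = set(essential_segments or [])

    k = int(n_events) if n_events is not None else int(rng.poisson(rate))
    order = list(segmap.order)
    events: list[ScrambleEvent] = []
    for e_idx in range(k):
        n_sites = len(order)
        if n_sites < 2:
            raise ScrambleError(
                f"event {e_idx}: only {n_sites} loxPsym site(s) remain"
            )
        etype = types[int(rng.choice(len(types), p=p))]
        for attempt in range(max_retries):
            i, j = sorted(rng.choice(n_sites, size=2, replace=False).tolist())
            span_ids = [sid for sid, _ in order[i:j]]
            if etype == "DEL":
                if essential & set(span_ids):
                    outside = [sid for sid, _ in order[:i] + order[j:]]
                    if essential & set(outside):
                        continue  # both arcs essential: resample the pair
                    # delete the complementary arc instead
                    order = order[i:j]
                    deleted = tuple(outside)
                    events.append(ScrambleEvent(e_idx, "DEL", (i, j), deleted))
                else:
                    order = _apply_del(order, i, j)
                    events.append(ScrambleEvent(e_idx, "DEL", (i, j), tuple(span_ids)))
                break
            if etype == "INV":
                order = _apply_inv(order, i, j)
                events.append(ScrambleEvent(e_idx, "INV", (i, j), tuple(span_ids)))
                break
            order = _apply_dup(order, i, j)
            events.append(ScrambleEvent(e_idx, "DUP", (i, j), tuple(span_ids)))
            break
        else:
            raise ScrambleError(
                f"event {e_idx}: no admissible {etype} found in {max_retries} draws"
            )

    scrambled = segmap.realize(order)
    out_map = SegmentMap(
        segments=dict(segmap.segments),
        order=order,
        topology="circular",
        site=segmap.site,
        origin_offset=0,
    )
    return scrambled, events, out_map


def replay_events(segmap: SegmentMap, events: Sequence[ScrambleEvent]) -> str:
    """Re-apply a truth log to the original segment map."""
    order = list(segmap.order)
    for e in events:
        i, j = e.site_pair
        if e.type == "INV":
            order = _apply_inv(order, i, j)
        elif e.type == "DUP":
            order = _apply_dup(order, i, j)
        elif e.type == "DEL":
            span_ids = tuple(sid for sid, _ in order[i:j])
            if span_ids == e.segment_ids:
                order = _apply_del(order, i, j)
            else:  # the complementary arc was deleted
                order = order[i:j]
        else:
            raise ScrambleError(f"unknown event type {e.type}")
    return segmap.realize(order)


# ---------------------------------------------------------------------------
# Structural-variant calling
# ---------------------------------------------------------------------------


def _match_segments(
    original: SegmentMap, observed_sequence: str
) -> tuple[list[SignedSeg], list[str]]:
    """Signed segment calls for an observed circular sequence."""
    by_seq: dict[str, SignedSeg] = {}
    for sid, seq in original.segments.items():
        by_seq[seq] = (sid, 1)
        rc = revcomp(seq)
        if rc != seq:
            by_seq[rc] = (sid, -1)
    obs_map = build_segment_map(observed_sequence, site=original.site)
    calls: list[SignedSeg] = []
    unmatched: list[str] = []
    for sid, _ in obs_map.order:
        seq = obs_map.segments[sid]
        hit = by_seq.get(seq)
        if hit is None:
            unmatched.append(seq)
        else:
            calls.append(hit)
    return calls, unmatched


def _canonical(order: tuple[SignedSeg, ...]) -> tuple[SignedSeg, ...]:
    """Lexicographically smallest rotation of a circular signed sequence."""
    if not order:
        return order
    best = min(tuple(order[i:] + order[:i]) for i in range(len(order)))
    return best


def _adjacencies(order: Sequence[SignedSeg]) -> set[tuple[SignedSeg, SignedSeg]]:
    adj = set()
    n = len(order)
    for i in range(n):
        a, b = order[i], order[(i + 1) % n]
        adj.add((a, b))
        adj.add(((b[0], -b[1]), (a[0], -a[1])))
    return adj


def _missing_runs(order: list[SignedSeg], missing: set[int]) -> list[tuple[int, int]]:
    """Maximal circular runs of missing segments as (start, end) positions."""
    n = len(order)
    flags = [sid in missing for sid, _ in order]
    if all(flags) or not any(flags):
        return []
    runs = []
    pos = 0
    while pos < n:
        if flags[pos] and not flags[pos - 1]:
            end = pos
            while flags[end % n]:
                end += 1
            runs.append((pos, end))
            pos = end
        else:
            pos += 1
    return runs


def _breakpoint_positions(
    order: list[SignedSeg], target_adj: set[tuple[SignedSeg, SignedSeg]]
) -> list[int]:
    n = len(order)
    return [
        pos for pos in range(n) if (order[pos - 1], order[pos]) not in target_adj
    ]


def _inversion_moves(
    order: list[SignedSeg], cuts: list[int]
) -> list[tuple[tuple[int, ...], list[SignedSeg]]]:
    """All inversions bounded by cut positions, both arcs of the circle."""
    moves = []
    for x in range(len(cuts)):
        for y in range(x + 1, len(cuts)):
            i, j = cuts[x], cuts[y]
            moves.append(
                (tuple(sid for sid, _ in order[i:j]), _apply_inv(order, i, j))
            )
            rotated = order[j:] + order[:j]
            span = len(order) - (j - i)
            moves.append(
                (
                    tuple(sid for sid, _ in rotated[:span]),
                    _apply_inv(rotated, 0, span),
                )
            )
    return moves


def _search_inversions(
    start: list[SignedSeg],
    target_canon: tuple[SignedSeg, ...],
    target_adj: set[tuple[SignedSeg, SignedSeg]],
    max_depth: int,
    budget: list[int],
) -> list[tuple[str, tuple[int, ...]]] | None:
    """Iterative-deepening DFS over breakpoint-bounded inversions.

    A reversal removes at most two breakpoints, which prunes the tree;
    candidate moves are ordered by resulting breakpoint count so the
    straightforward explanation is found first, deterministically.
    """

    def dfs(order: list[SignedSeg], depth: int, history: list):
        budget[0] -= 1
        if budget[0] < 0:
            return None
        bp = _breakpoint_positions(order, target_adj)
        if not bp:
            if _canonical(tuple(order)) == target_canon:
                return list(history)
            return None
        if len(bp) > 2 * depth:
            return None
        moves = _inversion_moves(order, bp)
        scored = sorted(
            (len(_breakpoint_positions(new, target_adj)), k, ids, new)
            for k, (ids, new) in enumerate(moves)
        )
        for _, _, ids, new in scored:
            history.append(("INV", ids))
            hit = dfs(new, depth - 1, history)
            if hit is not None:
                return hit
            history.pop()
        return None

    for depth in range(max_depth + 1):
        hit = dfs(list(start), depth, [])
        if hit is not None:
            return hit
        if budget[0] < 0:
            return None
    return None


def _search_interleaved(
    start: list[SignedSeg],
    target_canon: tuple[SignedSeg, ...],
    target_adj: set[tuple[SignedSeg, SignedSeg]],
    missing: set[int],
    max_events: int,
    budget: list[int],
    max_cuts: int = 24,
) -> list[tuple[str, tuple[int, ...]]] | None:
    """Bounded DFS interleaving deletions and inversions (interacting events)."""

    def cuts_of(order: list[SignedSeg]) -> list[int]:
        # true breakpoints between surviving segments, plus the boundary
        # junctions of each missing run (an inversion endpoint strictly
        # inside a run that is later deleted leaves no trace, so minimal
        # histories never need one)
        n = len(order)
        out = set()
        for pos in range(n):
            a, b = order[pos - 1], order[pos]
            if a[0] in missing or b[0] in missing:
                continue
            if (a, b) not in target_adj:
                out.add(pos)
        for s, e in _missing_runs(order, missing):
            out.add(s % n)
            out.add(e % n)
        return sorted(out)

    def dfs(order: list[SignedSeg], depth: int, history: list):
        budget[0] -= 1
        if budget[0] < 0:
            return None
        runs = _missing_runs(order, missing)
        has_missing = any(sid in missing for sid, _ in order)
        if not has_missing:
            bp = _breakpoint_positions(order, target_adj)
            if not bp and _canonical(tuple(order)) == target_canon:
                return list(history)
            if len(bp) > 2 * depth:
                return None
        if depth == 0 or len(runs) > depth:
            return None
        for s, e in runs:
            ids = tuple(order[k % len(order)][0] for k in range(s, e))
            new_order = order[:s] + order[e:] if e <= len(order) else order[e % len(order) : s]
            history.append(("DEL", ids))
            hit = dfs(new_order, depth - 1, history)
            if hit is not None:
                return hit
            history.pop()
        cuts = cuts_of(order)
        if len(cuts) <= max_cuts:
            for ids, new in _inversion_moves(order, cuts):
                history.append(("INV", ids))
                hit = dfs(new, depth - 1, history)
                if hit is not None:
                    return hit
                history.pop()
        return None

    for depth in range(max_events + 1):
        hit = dfs(list(start), depth, [])
        if hit is not None:
            return hit
        if budget[0] < 0:
            return None
    return None


def _search_history(
    start: list[SignedSeg],
    target: tuple[SignedSeg, ...],
    missing: set[int],
    max_events: int,
    node_budget: int = 50_000,
) -> list[tuple[str, tuple[int, ...]]] | None:
    """Minimal DEL/INV event history turning ``start`` into ``target``.

    Deletions and inversions commute whenever their arcs do not interact, so
    the search first deletes every maximal run of missing segments and then
    looks for inversions alone; only if that fails does it fall back to a
    budgeted search over interleaved histories (events whose arcs crossed).
    """
    target_canon = _canonical(target)
    target_adj = _adjacencies(target)

    # base history: delete every maximal missing run, then inversions only
    order = list(start)
    del_events: list[tuple[str, tuple[int, ...]]] = []
    runs = _missing_runs(order, missing)
    while runs:
        s, e = runs[0]
        ids = tuple(order[k % len(order)][0] for k in range(s, e))
        order = order[:s] + order[e:] if e <= len(order) else order[e % len(order) : s]
        del_events.append(("DEL", ids))
        runs = _missing_runs(order, missing)

    base: list[tuple[str, tuple[int, ...]]] | None = None
    if len(del_events) <= max_events:
        budget = [node_budget]
        hist = _search_inversions(
            order, target_canon, target_adj, max_events - len(del_events), budget
        )
        if hist is not None:
            base = del_events + hist

    # parsimony: an interleaved history (inversion crossing a later deletion)
    # can be strictly shorter than the dels-first one; prefer the shortest
    cap = (len(base) - 1) if base is not None else max_events
    if missing and cap >= 1:
        budget = [node_budget]
        shorter = _search_interleaved(
            list(start), target_canon, target_adj, missing, cap, budget
        )
        if shorter is not None:
            return shorter
    if base is not None:
        return base
    budget = [node_budget]
    return _search_interleaved(
        list(start), target_canon, target_adj, missing, max_events, budget
    )


def _find_tandem_dups(
    observed: list[SignedSeg],
) -> tuple[list[SignedSeg], list[tuple[str, tuple[int, ...]]]]:
    """Collapse tandem duplicated runs, returning reduced order and events."""
    events = []
    order = list(observed)
    changed = True
    while changed:
        changed = False
        n = len(order)
        counts: dict[int, int] = {}
        for sid, _ in order:
            counts[sid] = counts.get(sid, 0) + 1
        dup_ids = {sid for sid, c in counts.items() if c > 1}
        if not dup_ids:
            break
        for span in range(n // 2, 0, -1):
            for s in range(n):
                a = [order[(s + k) % n] for k in range(span)]
                b = [order[(s + span + k) % n] for k in range(span)]
                if a == b and any(sid in dup_ids for sid, _ in a):
                    keep = [order[(s + span + span + k) % n] for k in range(n - 2 * span)]
                    order = a + keep
                    events.append(("DUP", tuple(sid for sid, _ in a)))
                    changed = True
                    break
            if changed:
                break
    return order, events


def call_structural_variants(
    original: SegmentMap,
    observed_sequence: str,
    max_events: int = 6,
) -> SVReport:
    """Infer SCRaMbLE events by comparing observed structure to the design.

    Deletions are runs of absent segments, inversions are found by a
    bounded event-history search, and tandem duplications are collapsed
    first. An observed structure no bounded history explains is returned
    with ``unexplained=True`` rather than raising.
    """
    calls, unmatched = _match_segments(original, observed_sequence)
    notes = []
    if unmatched:
        notes.append(
            f"{len(unmatched)} observed segment(s) match no original segment"
        )

    copy_number = {sid: 0 for sid in original.segments}
    orientation: dict[int, list[int]] = {sid: [] for sid in original.segments}
    for sid, sign in calls:
        copy_number[sid] += 1
        orientation[sid].append(sign)

    reduced, dup_events = _find_tandem_dups(calls)
    missing = {sid for sid, c in copy_number.items() if c == 0}
    counts_after: dict[int, int] = {}
    for sid, _ in reduced:
        counts_after[sid] = counts_after.get(sid, 0) + 1
    still_dup = {sid for sid, c in counts_after.items() if c > 1}

    events: list[ScrambleEvent] = [
        ScrambleEvent(-1, t, (0, 0), ids) for t, ids in dup_events
    ]
    unexplained = bool(unmatched) or bool(still_dup)

    if not unexplained:
        start = list(original.order)
        target = tuple(reduced)
        history = _search_history(start, target, missing, max_events)
        if history is None:
            unexplained = True
            notes.append("no bounded DEL/INV history explains the observation")
        else:
            for t, ids in history:
                events.append(ScrambleEvent(-1, t, (0, 0), ids))
    for idx, e in enumerate(events):
        e.index = idx
    return SVReport(
        copy_number=copy_number,
        orientation=orientation,
        events=events,
        unexplained=unexplained,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Copy number from coverage
# ---------------------------------------------------------------------------


def estimate_copy_number(
    coverage: pd.DataFrame,
    element_name: str,
    min_contig: int = 200_000,
) -> float:
    """Element:genome depth ratio; gain of the element gives a ratio > 1.

    ``coverage`` needs columns ``contig``, ``length`` and ``mean_depth``.
    The genome reference level is the mean of the per-contig mean depths of
    contigs longer than ``min_contig`` (the element itself excluded).
    """
    required = {"contig", "length", "mean_depth"}
    if not required <= set(coverage.columns):
        raise ScrambleError(f"coverage table needs columns {sorted(required)}")
    if element_name not in set(coverage["contig"]):
        raise ScrambleError(f"element {element_name!r} not in coverage table")
    element_depth = float(
        coverage.loc[coverage["contig"] == element_name, "mean_depth"].iloc[0]
    )
    genome = coverage[
        (coverage["contig"] != element_name) & (coverage["length"] > min_contig)
    ]
    if genome.empty:
        raise ScrambleError(f"no genomic contig longer than {min_contig} bp")
    return element_depth / float(genome["mean_depth"].mean())
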