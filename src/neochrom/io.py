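"""Readers and writers for the package's interchange formats.

Designs travel as FASTA (sequence, via biopython) plus GFF3 (features).
GFF3 uses 1-based inclusive coordinates on disk; the in-memory convention
is 0-based half-open and the conversion happens only at this boundary.
Topology is carried by a GFF3 ``region`` feature with the standard
``Is_circular`` attribute. The edit log and generation metadata live in a
JSON sidecar (``<features>.edits.json``) written and read automatically.
Structured attribute values (lists, tuples) are JSON-encoded and
percent-escaped inside the GFF3 attribute column.

Tabular artifacts (plates, stability counts, coverage, plans, primers,
event logs) are tidy TSV via pandas.
"""

from __future__ import annotations

import json
import urllib.parse
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assembly import AssemblyPlan, Chunk, PrimerPair
from .design import DesignError, Feature, NeoChromosomeDesign
from .phenotype import PlateKinetics, StabilityExperiment
from .seqtools import DNA_ALPHABET


class IOError_(ValueError):
    """Named load/save errors (coordinate, alphabet, topology problems)."""


# ---------------------------------------------------------------------------
# Designs: FASTA + GFF3 (+ JSON edit sidecar)
# ---------------------------------------------------------------------------


def _encode_attr(value) -> str:
    if isinstance(value, str):
        return urllib.parse.quote(value, safe="")
    return urllib.parse.quote(json.dumps(value), safe="")


def _decode_attr(text: str):
    raw = urllib.parse.unquote(text)
    try:
        return json.loads(raw)
    except (json.JSONDecodeError, ValueError):
        return raw


def write_design(
    design: NeoChromosomeDesign,
    fasta_path: str | Path,
    features_path: str | Path,
    edits_path: str | Path | None = None,
) -> None:
    fasta_path, features_path = Path(fasta_path), Path(features_path)
    record = SeqRecord(
        Seq(design.sequence),
        id=design.name,
        description=f"topology={design.topology} length={len(design.sequence)}",
    )
    SeqIO.write([record], str(fasta_path), "fasta")

    n = len(design.sequence)
    lines = ["##gff-version 3", f"##sequence-region {design.name} 1 {n}"]
    circ = "true" if design.is_circular else "false"
    lines.append(
        "\t".join(
            [
                design.name,
                "neochrom",
                "region",
                "1",
                str(n),
                ".",
                "+",
                ".",
                f"ID={design.name};Is_circular={circ}",
            ]
        )
    )
    for f in sorted(design.features, key=lambda f: (f.start, f.end, f.id)):
        attrs = [f"ID={_encode_attr(f.id)}"]
        for key, value in f.attributes.items():
            attrs.append(f"{key}={_encode_attr(value)}")
        lines.append(
            "\t".join(
                [
                    design.name,
                    "neochrom",
                    f.type,
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    features_path.write_text("\n".join(lines) + "\n")

    edits_path = Path(edits_path) if edits_path else _default_edits_path(features_path)
    edits_path.write_text(
        json.dumps(
            {
                "initial_sequence": design.initial_sequence,
                "edit_log": design.edit_log,
                "metadata": design.metadata,
            }
        )
    )


def _default_edits_path(features_path: Path) -> Path:
    return features_path.with_suffix(features_path.suffix + ".edits.json")


def read_design(
    fasta_path: str | Path,
    features_path: str | Path,
    edits_path: str | Path | None = None,
) -> NeoChromosomeDesign:
    """Load and validate a design written by :func:`write_design`.

    Lowercase sequence is normalized to uppercase; illegal characters,
    out-of-bounds feature coordinates and a missing topology attribute each
    raise a distinct named error.
    """
    fasta_path, features_path = Path(fasta_path), Path(features_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise IOError_(f"no FASTA record in {fasta_path}")
    record = records[0]
    sequence = str(record.seq).upper()
    bad = set(sequence) - DNA_ALPHABET
    if bad:
        raise IOError_(f"illegal sequence characters in {fasta_path}: {sorted(bad)}")

    topology: str | None = None
    features: list[Feature] = []
    for line in features_path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise IOError_(f"malformed GFF3 line: {line[:60]!r}")
        _, _, ftype, start, end, _, strand, _, attr_text = cols
        attrs = {}
        for item in attr_text.split(";"):
            if "=" in item:
                key, value = item.split("=", 1)
                attrs[key] = _decode_attr(value)
        if ftype == "region":
            circ = attrs.get("Is_circular")
            if circ is None:
                raise IOError_("region feature lacks the Is_circular attribute")
            topology = "circular" if str(circ).lower() == "true" else "linear"
            continue
        start0, end0 = int(start) - 1, int(end)
        fid = str(attrs.pop("ID", f"{ftype}_{start0}"))
        if not (0 <= start0 < end0 <= len(sequence)):
            raise IOError_(
                f"feature {fid} coordinates ({start0}, {end0}) out of bounds "
                f"for sequence of length {len(sequence)}"
            )
        features.append(Feature(fid, ftype, start0, end0, strand, attrs))
    if topology is None:
        raise IOError_(f"{features_path} carries no region/Is_circular topology")

    edits_path = Path(edits_path) if edits_path else _default_edits_path(features_path)
    initial, edit_log, metadata = sequence, [], {}
    if edits_path.exists():
        payload = json.loads(edits_path.read_text())
        initial = payload.get("initial_sequence", sequence)
        edit_log = payload.get("edit_log", [])
        metadata = payload.get("metadata", {})
    return NeoChromosomeDesign(
        name=record.id,
        topology=topology,
        sequence=sequence,
        features=features,
        edit_log=edit_log,
        initial_sequence=initial,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------


def write_fragments(fragments, fasta_path: str | Path, gff_path: str | Path) -> None:
    """Multi-record FASTA plus a GFF3 of ORF features with confidence."""
    records = [
        SeqRecord(Seq(f.sequence), id=f.id, description=f.source_label)
        for f in fragments
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    lines = ["##gff-version 3"]
    for f in fragments:
        lines.append(f"##sequence-region {f.id} 1 {len(f.sequence)}")
        for orf in f.orfs:
            lines.append(
                "\t".join(
                    [
                        f.id,
                        "neochrom",
                        "ORF",
                        str(orf.start + 1),
                        str(orf.end),
                        ".",
                        orf.strand,
                        "0",
                        f"ID={orf.id};confidence={orf.confidence}",
                    ]
                )
            )
    Path(gff_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Chunks / plans / primers
# ---------------------------------------------------------------------------


def write_chunks(
    chunks: Sequence[Chunk],
    design_name: str,
    fasta_path: str | Path,
    bed_path: str | Path,
) -> None:
    records = []
    bed_lines = []
    for c in chunks:
        records.append(
            SeqRecord(
                Seq(c.sequence),
                id=f"chunk_{c.index + 1:02d}",
                description=(
                    f"overhang={len(c.right_overhang)} flanks={','.join(c.flank_sites)}"
                ),
            )
        )
        bed_lines.append(
            f"{design_name}\t{c.start}\t{c.start + len(c.body)}\tchunk_{c.index + 1:02d}"
        )
    SeqIO.write(records, str(fasta_path), "fasta")
    Path(bed_path).write_text("\n".join(bed_lines) + "\n")


def plan_to_frame(plan: AssemblyPlan) -> pd.DataFrame:
    rows = [
        {
            "round": rnd,
            "chunks": ",".join(str(c) for c in chunks),
            "marker": marker,
        }
        for rnd, chunks, marker in plan.rounds
    ]
    rows.append(
        {
            "round": len(plan.rounds) + 1,
            "chunks": "",
            "marker": f"{plan.final_swap[0]}->{plan.final_swap[1]}",
        }
    )
    return pd.DataFrame(rows)


def primers_to_frame(pairs: Sequence[PrimerPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "junction": p.junction_index,
                "forward": p.forward,
                "reverse": p.reverse,
                "tm_forward": round(p.tm_forward, 2),
                "tm_reverse": round(p.tm_reverse, 2),
                "product_length": p.product_length,
            }
            for p in pairs
        ]
    )


# ---------------------------------------------------------------------------
# Tabular data
# ---------------------------------------------------------------------------


def write_plate_tsv(plate: PlateKinetics, path: str | Path) -> None:
    df = plate.data.copy()
    df["role"] = df["well"].map(plate.roles)
    df["compound"] = df["well"].map(plate.compounds).fillna("")
    df.to_csv(path, sep="\t", index=False)


def read_plate_tsv(path: str | Path) -> PlateKinetics:
    df = pd.read_csv(path, sep="\t", dtype={"well": str})
    roles = dict(zip(df["well"], df["role"]))
    compounds = {
        w: c
        for w, c in zip(df["well"], df.get("compound", pd.Series(dtype=str)).fillna(""))
        if c
    }
    return PlateKinetics(
        data=df[["well", "time", "value"]].copy(), roles=roles, compounds=compounds
    )


def write_stability_tsv(exp: StabilityExperiment, path: str | Path) -> None:
    exp.counts.to_csv(path, sep="\t", index=False)


def read_stability_tsv(path: str | Path) -> StabilityExperiment:
    return StabilityExperiment(counts=pd.read_csv(path, sep="\t"))


def write_coverage_tsv(coverage: pd.DataFrame, path: str | Path) -> None:
    coverage.to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
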