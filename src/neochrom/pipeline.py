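"""Run configuration and the end-to-end design-build-test pipeline.

The pipeline exercises every stage on synthetic inputs: generate pan-genome
fragments, build and edit the design (stop recoding, watermarks, loxPsym),
validate it, divide it into synthesis chunks, plan the alternating-marker
assembly, design junction primers, re-assemble in silico and confirm
identity, optionally linearize and SCRaMbLE, and compute the phenotype
statistics on generated plate/passaging/coverage data. All randomness flows
from the single config seed through documented substreams; rerunning with
the same config reproduces every artifact checksum.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import assembly as asm
from . import design as dsg
from . import linearize as lin
from . import phenotype as phn
from . import scramble as scr
from . import simulate as sim
from .seqtools import LOXPSYM, rotations_equal


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
        self.message = message


@dataclass
class RunConfig:
    seed: int = 0
    # design
    n_fragments: int = 17
    fragment_size_range: tuple[int, int] = (1_100, 60_300)
    orf_density: float = 0.35
    gc_target: float = 0.38
    loxpsym_site: str = LOXPSYM
    n_watermarks: int = 36
    watermark_window_start: int = 10
    watermark_window_len: int = 12
    # chunking
    chunk_size: int = 10_000
    chunk_overlap: int = 200
    design_primers: bool = True
    # optional stages
    run_linearize: bool = True
    run_scramble: bool = True
    scramble_events: int = 2
    # phenotype
    biolog_noise_cv: float = 0.05
    p_loss: float = 0.019
    min_over_negative: float = 50.0
    min_positive: float = 100.0

    def __post_init__(self) -> None:
        if self.chunk_overlap >= self.chunk_size:
            raise ValueError("chunk overlap must be smaller than the chunk size")
        self.fragment_size_range = tuple(self.fragment_size_range)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["fragment_size_range"] = list(self.fragment_size_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _checksum(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _gap_position(design: dsg.NeoChromosomeDesign, min_gap: int = 10) -> int:
    """Midpoint of the first inter-feature gap (a safe cut/insert locus)."""
    intervals = sorted((f.start, f.end) for f in design.features)
    prev_end = 0
    for start, end in intervals:
        if start - prev_end >= min_gap:
            return (prev_end + start) // 2
        prev_end = max(prev_end, end)
    if len(design.sequence) - prev_end >= min_gap:
        return (prev_end + len(design.sequence)) // 2
    raise PipelineError("linearize", "no inter-feature gap available for the cut")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns artifacts plus checksums."""
    seeds = sim.derive_seeds(config.seed, 8)
    artifacts: dict = {"config": config}
    checksums: dict[str, str] = {}

    def stage(name: str):
        def wrap(fn):
            try:
                return fn()
            except Exception as err:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineError(name, str(err)) from err

        return wrap

    # --- synthetic fragments -> design -------------------------------------
    fragments = stage("fragments")(
        lambda: sim.generate_pan_fragments(
            sim.FragmentSpec(
                n_fragments=config.n_fragments,
                size_range=config.fragment_size_range,
                orf_density=config.orf_density,
                gc_target=config.gc_target,
                seed=seeds[0],
            )
        )
    )
    backbone = stage("fragments")(lambda: sim.make_backbone(seed=seeds[1]))
    artifacts["fragments"] = fragments

    def build_design():
        design = dsg.concatenate_fragments(fragments, backbone)
        dsg.recode_stop_codons(design)
        import numpy as np

        rng = np.random.default_rng(seeds[2])
        eligible = [
            o.id
            for o in design.orf_features()
            if o.length() // 3
            > config.watermark_window_start + config.watermark_window_len
        ]
        chosen = eligible[: config.n_watermarks]
        payloads = [
            "".join(str(b) for b in rng.integers(0, 2, size=8)) for _ in chosen
        ]
        dsg.embed_watermarks(
            design,
            chosen,
            payloads,
            window_start=config.watermark_window_start,
            window_len=config.watermark_window_len,
        )
        dsg.insert_loxpsym(design, site=config.loxpsym_site)
        report = dsg.validate_design(design)
        if not report.passed:
            raise dsg.DesignError(f"validation failed: {report.failures()}")
        return design, report, payloads

    design, report, payloads = stage("design")(build_design)
    artifacts["design"] = design
    artifacts["validation"] = report
    artifacts["watermark_payloads"] = payloads
    checksums["design_sequence"] = _checksum(design.sequence)

    # --- chunking, planning, primers, reassembly ---------------------------
    chunks = stage("chunk")(
        lambda: asm.chunk_design(design, config.chunk_size, config.chunk_overlap)
    )
    artifacts["chunks"] = chunks
    plan = stage("plan")(lambda: asm.plan_assembly(chunks))
    artifacts["plan"] = plan
    if config.design_primers:
        artifacts["primers"] = stage("primers")(
            lambda: asm.design_junction_primers(design, chunks)
        )

    def reassemble():
        assembled = asm.simulate_hr_assembly(
            [c.sequence for c in chunks], circularize=True, overlap=config.chunk_overlap
        )
        if not rotations_equal(assembled, design.sequence):
            raise asm.AssemblyError("reassembled sequence differs from the design")
        return assembled

    assembled = stage("assemble")(reassemble)
    checksums["assembled_sequence"] = _checksum(assembled)

    # --- linearization ------------------------------------------------------
    if config.run_linearize:
        locus = _gap_position(design)
        variant = stage("linearize")(lambda: lin.linearize_at(design, locus))
        artifacts["linear_variant"] = variant
        checksums["linear_sequence"] = _checksum(variant.sequence)

    # --- SCRaMbLE -----------------------------------------------------------
    if config.run_scramble:

        def scramble():
            segmap = scr.build_segment_map(design)
            backbone_feature = design.feature_by_id("backbone")
            essential = [scr.segment_containing(design, backbone_feature.start)]
            scrambled, events, _ = scr.simulate_scramble(
                segmap,
                n_events=config.scramble_events,
                essential_segments=essential,
                seed=seeds[3],
            )
            report = scr.call_structural_variants(segmap, scrambled)
            return scrambled, events, report

        scrambled, events, sv_report = stage("scramble")(scramble)
        artifacts["scrambled_sequence"] = scrambled
        artifacts["scramble_truth"] = events
        artifacts["sv_report"] = sv_report
        checksums["scrambled_sequence"] = _checksum(scrambled)

    # --- phenotype statistics ----------------------------------------------
    def phenotypes():
        experiment = sim.generate_biolog_experiment(
            sim.PlateSpec(
                n_wells=24,
                effect_map={"W03": 2.5, "W04": 0.4},
                noise_cv=config.biolog_noise_cv,
                seed=seeds[4],
            )
        )
        classification = phn.biolog_classify(
            experiment.test,
            experiment.reference,
            min_over_negative=config.min_over_negative,
            min_positive=config.min_positive,
        )
        passaging = sim.generate_passaging_counts(
            sim.PassagingSpec(p_loss=config.p_loss, seed=seeds[5])
        )
        retention = phn.retention_stats(passaging)
        r25 = retention.loc[retention["generation"] == 25, "mean_pct"].iloc[0] / 100
        loss = phn.estimate_loss_rate(r25, 25)
        coverage = sim.generate_coverage_profile(
            sim.CoverageSpec(true_ratio=1.5, seed=seeds[6])
        )
        ratio = scr.estimate_copy_number(coverage, "PGNC")
        return classification, retention, loss, coverage, ratio

    classification, retention, loss, coverage, ratio = stage("phenotype")(phenotypes)
    artifacts["biolog"] = classification
    artifacts["retention"] = retention
    artifacts["loss_rate"] = loss
    artifacts["coverage"] = coverage
    artifacts["copy_number_ratio"] = ratio
    checksums["biolog_table"] = _checksum(classification.table.to_csv())
    checksums["retention_table"] = _checksum(retention.to_csv())

    artifacts["checksums"] = checksums
    return artifacts
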