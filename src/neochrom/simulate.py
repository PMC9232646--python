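"""Synthetic-data generators for every input the pipeline consumes.

Each generator takes a spec dataclass with an explicit seed and returns data
together with its ground truth, so downstream estimators can be scored
against known parameters. The defaults emulate the study conditions the
pipeline was built for: seventeen pan-genome fragments of 1.1-60.3 kb,
paired 96-well kinetic plates with planted fold-change effects, triplicate
96-colony serial-passaging counts under per-generation geometric loss, and
per-contig sequencing depth with a configurable element:genome copy ratio.

One top-level seed can be fanned out to per-generator substreams with
:func:`derive_seeds` (numpy ``SeedSequence`` spawning, values kept below
2^31).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Fragment, OrfAnnotation
from .phenotype import PlateKinetics, StabilityExperiment
from .seqtools import LOXPSYM, NOTI_SITE, PMEI_SITE, STOP_CODONS, revcomp

_BASES = np.array(list("ACGT"))
_FORBIDDEN = (PMEI_SITE, NOTI_SITE, LOXPSYM)


class SimulationError(ValueError):
    pass


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2^31) from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


# ---------------------------------------------------------------------------
# Pan-genome fragments
# ---------------------------------------------------------------------------


@dataclass
class FragmentSpec:
    n_fragments: int = 17
    size_range: tuple[int, int] = (1_100, 60_300)
    orf_density: float = 0.35  # ORFs per kb
    gc_target: float = 0.38
    orf_length_range: tuple[int, int] = (300, 1_500)
    high_confidence_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if lo < 300:
            raise SimulationError("size_range minimum must be >= 300 bp")
        if hi < lo:
            raise SimulationError("size_range must be (min, max) with min <= max")
        if self.orf_density <= 0:
            raise SimulationError("orf_density must be positive")
        if not 0 < self.gc_target < 1:
            raise SimulationError("gc_target must lie in (0, 1)")
        if hi < self.orf_length_range[0]:
            raise SimulationError(
                f"size_range too small to host one ORF of "
                f">= {self.orf_length_range[0]} bp"
            )


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + stop-free internal codons + a random stop codon."""
    internal = []
    while len(internal) < n_codons - 2:
        cand = "".join(_random_bases(rng, 3, gc))
        if cand not in STOP_CODONS:
            internal.append(cand)
    stop = sorted(STOP_CODONS)[rng.integers(3)]
    return "ATG" + "".join(internal) + stop


def _scrub_motifs(
    seq: list[str], orfs: list[OrfAnnotation], rng: np.random.Generator
) -> None:
    """Remove forbidden motifs in place, preserving ORF translations."""
    from .seqtools import alternate_codon

    for _ in range(100):
        text = "".join(seq)
        hit = None
        for motif in _FORBIDDEN:
            pos = text.find(motif)
            if pos != -1:
                hit = (pos, motif)
                break
        if hit is None:
            return
        pos, motif = hit
        inside = next(
            (o for o in orfs if o.start < pos + len(motif) and o.end > pos), None
        )
        if inside is None:
            i = pos + int(rng.integers(len(motif)))
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[int(rng.integers(3))]
            continue
        # recode one codon overlapping the motif synonymously
        fixed = False
        for ci in range((inside.end - inside.start) // 3):
            if inside.strand == "+":
                s = inside.start + 3 * ci
                codon = "".join(seq[s : s + 3])
            else:
                s = inside.end - 3 * (ci + 1)
                codon = revcomp("".join(seq[s : s + 3]))
            if s + 3 <= pos or s >= pos + len(motif):
                continue  # codon does not overlap the motif
            alt = alternate_codon(codon)
            if alt is None:
                continue
            fwd = revcomp(alt) if inside.strand == "-" else alt
            seq[s : s + 3] = list(fwd)
            fixed = True
            break
        if not fixed:  # motif spans only non-degenerate codons: mutate the spacer
            i = pos + int(rng.integers(len(motif)))
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[int(rng.integers(3))]
    raise SimulationError("could not scrub forbidden motifs from a fragment")


def _fix_recode_contexts(seq: list[str], orfs) -> None:
    """Avoid stop contexts whose TAG->TAA recoded image forms a motif.

    Downstream design editing replaces terminal TAG stops with TAA; in a
    GTT·TAG·AC-like context that substitution would mint a PmeI site. A
    synthesis-aware fragment swaps such stops to TGA (untouched by the
    recoding rule) at generation time.
    """
    for orf in orfs:
        if orf.strand == "+":
            s = orf.end - 3
            stop = "".join(seq[s : s + 3])
        else:
            s = orf.start
            stop = revcomp("".join(seq[s : s + 3]))
        if stop != "TAG":
            continue
        recoded = "TAA" if orf.strand == "+" else revcomp("TAA")
        lo, hi = max(0, s - 40), min(len(seq), s + 43)
        trial = "".join(seq[lo:s]) + recoded + "".join(seq[s + 3 : hi])
        if any(m in trial for m in _FORBIDDEN):
            alt = "TGA" if orf.strand == "+" else revcomp("TGA")
            seq[s : s + 3] = list(alt)
            check = "".join(seq[lo:hi])
            if any(m in check for m in _FORBIDDEN):
                raise SimulationError("could not neutralize a stop-codon context")


def generate_pan_fragments(spec: FragmentSpec) -> list[Fragment]:
    """Random pan-genome fragments carrying well-formed, non-overlapping ORFs.

    Fragment lengths are log-uniform over ``size_range``; ORFs start with
    ATG, end with a stop codon, have length divisible by 3, sit on random
    strands at roughly ``orf_density`` per kb, and carry a high/low
    confidence flag. PmeI/NotI/loxPsym motifs are scrubbed (synthesis-aware
    sequence design). Identical specs produce identical output.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.size_range
    fragments = []
    for idx in range(spec.n_fragments):
        length = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        length = min(max(length, lo), hi)
        seq = list(_random_bases(rng, length, spec.gc_target))

        target_orfs = max(1, int(rng.poisson(spec.orf_density * length / 1000)))
        orfs: list[OrfAnnotation] = []
        occupied: list[tuple[int, int]] = []
        attempts = 0
        while len(orfs) < target_orfs and attempts < 50 * target_orfs:
            attempts += 1
            olo, ohi = spec.orf_length_range
            max_len = min(ohi, length - 6)
            if max_len < olo:
                break
            l = int(rng.integers(olo // 3, max_len // 3 + 1)) * 3
            start = int(rng.integers(0, length - l + 1))
            end = start + l
            if any(s < end and e > start for s, e in occupied):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            cds = _random_cds(rng, l // 3, spec.gc_target)
            seq[start:end] = list(cds if strand == "+" else revcomp(cds))
            confidence = (
                "high" if rng.random() < spec.high_confidence_fraction else "low"
            )
            orfs.append(
                OrfAnnotation(
                    id=f"frag{idx:02d}_orf{len(orfs):02d}",
                    start=start,
                    end=end,
                    strand=strand,
                    confidence=confidence,
                )
            )
            occupied.append((start, end))
        if not orfs:
            raise SimulationError(
                f"fragment {idx}: size_range too small to host one ORF of "
                f">= {spec.orf_length_range[0]} bp"
            )
        _scrub_motifs(seq, orfs, rng)
        _fix_recode_contexts(seq, orfs)
        orfs.sort(key=lambda o: o.start)
        fragments.append(
            Fragment(
                id=f"Frag_{idx + 1:02d}",
                sequence="".join(seq),
                source_label=f"synthetic pan-genome isolate {idx + 1}",
                orfs=orfs,
            )
        )
    return fragments


def make_backbone(
    length: int = 5_000, gc: float = 0.40, seed: int = 0
) -> Fragment:
    """A synthetic centromeric backbone fragment (CEN/ARS + marker features)."""
    from .design import Feature

    rng = np.random.default_rng(seed)
    seq = list(_random_bases(rng, length, gc))
    _scrub_motifs(seq, [], rng)
    features = [
        Feature("CEN_ARS", "centromere", length // 2 - 200, length // 2 + 200, "+", {}),
        Feature("natR", "marker", 100, 900, "+", {"resistance": "clonNAT"}),
    ]
    return Fragment(
        id="backbone_p416",
        sequence="".join(seq),
        source_label="synthetic centromeric vector",
        features=features,
    )


# ---------------------------------------------------------------------------
# BioLog plates
# ---------------------------------------------------------------------------


@dataclass
class PlateSpec:
    n_wells: int = 96
    effect_map: dict[str, float] = field(default_factory=dict)  # well -> fold change
    noise_cv: float = 0.05
    negative_control: str = "W01"
    positive_control: str = "W02"
    blank_wells: tuple[str, ...] = ()
    timepoints: int = 97  # 24 h sampled every 15 min
    reference_height_range: tuple[float, float] = (150.0, 300.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise SimulationError("noise_cv must be >= 0")
        if not self.negative_control or not self.positive_control:
            raise SimulationError("plates need designated control wells")
        controls = {self.negative_control, self.positive_control}
        if controls & set(self.blank_wells) or controls & set(self.effect_map):
            raise SimulationError("control wells cannot also be compound/blank wells")
        if set(self.effect_map) & set(self.blank_wells):
            raise SimulationError("a well cannot be both compound and blank")

    def wells(self) -> list[str]:
        return [f"W{i + 1:02d}" for i in range(self.n_wells)]

    def roles(self) -> dict[str, str]:
        out = {}
        for w in self.wells():
            if w == self.negative_control:
                out[w] = "negative_control"
            elif w == self.positive_control:
                out[w] = "positive_control"
            elif w in self.blank_wells:
                out[w] = "blank"
            else:
                out[w] = "compound"
        return out


@dataclass
class BiologExperiment:
    test: PlateKinetics
    reference: PlateKinetics
    effects: dict[str, float]  # ground truth per compound well


def _logistic_curve(
    times: np.ndarray,
    plateau: float,
    rng: np.random.Generator,
    noise_cv: float,
    midpoint: float,
    steepness: float,
    baseline: float = 2.0,
) -> np.ndarray:
    mean = baseline + (plateau - baseline) / (1 + np.exp(-steepness * (times - midpoint)))
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        mean = mean * rng.lognormal(-(sigma**2) / 2, sigma, size=times.size)
    return mean


def generate_biolog_experiment(spec: PlateSpec) -> BiologExperiment:
    """Paired test/reference kinetic plates with planted fold-change effects.

    Every well holds a logistic mean curve with multiplicative lognormal
    noise; a compound well with effect f has a test-strain plateau f times
    the reference plateau. Blank wells plateau below the negative control
    + 50 units on both strains; truth effects are returned.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.linspace(0, 24, spec.timepoints)
    roles = spec.roles()
    lo, hi = spec.reference_height_range

    plateaus_ref: dict[str, float] = {}
    plateaus_test: dict[str, float] = {}
    effects: dict[str, float] = {}
    for w in spec.wells():
        role = roles[w]
        if role == "negative_control":
            plateaus_ref[w] = plateaus_test[w] = float(rng.uniform(10, 30))
        elif role == "positive_control":
            plateaus_ref[w] = plateaus_test[w] = float(rng.uniform(240, 280))
        elif role == "blank":
            plateaus_ref[w] = plateaus_test[w] = float(rng.uniform(5, 20))
        else:
            f = float(spec.effect_map.get(w, 1.0))
            ref = float(rng.uniform(lo, hi))
            plateaus_ref[w] = ref
            plateaus_test[w] = f * ref
            effects[w] = f

    frames = {"test": [], "reference": []}
    for w in spec.wells():
        midpoint = float(rng.uniform(6, 10))
        steepness = float(rng.uniform(0.6, 1.2))
        for strain, plateau in (
            ("test", plateaus_test[w]),
            ("reference", plateaus_ref[w]),
        ):
            values = _logistic_curve(
                times, plateau, rng, spec.noise_cv, midpoint, steepness
            )
            frames[strain].append(
                pd.DataFrame({"well": w, "time": times, "value": values})
            )

    compounds = {w: f"compound_{w}" for w, r in roles.items() if r == "compound"}
    test = PlateKinetics(
        data=pd.concat(frames["test"], ignore_index=True),
        roles=roles,
        compounds=compounds,
    )
    reference = PlateKinetics(
        data=pd.concat(frames["reference"], ignore_index=True),
        roles=roles,
        compounds=compounds,
    )
    return BiologExperiment(test=test, reference=reference, effects=effects)


# ---------------------------------------------------------------------------
# Microplate growth curves
# ---------------------------------------------------------------------------


@dataclass
class GrowthCurveSpec:
    """A logistic growth curve with a planted maximum specific growth rate.

    The defaults mimic a plate-reader run: a small post-blank inoculum
    (od0/plateau ~ 0.007 keeps the finite-inoculum bias of windowed
    log-linear rate estimates well below 0.01 h^-1), a 24 h run sampled
    every 20 min, and optional multiplicative lognormal noise.
    """

    rate: float = 0.53  # h^-1
    od0: float = 0.01
    plateau: float = 1.4
    hours: float = 24.0
    dt: float = 1.0 / 3.0  # h between readings
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.od0 <= 0 or self.plateau <= self.od0:
            raise SimulationError("need rate > 0 and 0 < od0 < plateau")
        if self.noise_cv < 0:
            raise SimulationError("noise_cv must be >= 0")


def generate_growth_curve(spec: GrowthCurveSpec):
    """Logistic OD(t) = K*N0*e^(rt) / (K + N0*(e^(rt)-1)), noisy if asked."""
    from .phenotype import GrowthCurve

    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.hours + spec.dt / 2, spec.dt)
    growth = np.exp(spec.rate * times)
    od = (
        spec.plateau
        * spec.od0
        * growth
        / (spec.plateau + spec.od0 * (growth - 1.0))
    )
    if spec.noise_cv > 0:
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        od = od * rng.lognormal(-(sigma**2) / 2, sigma, size=od.size)
    return GrowthCurve(times=times, od=od)


# ---------------------------------------------------------------------------
# Serial passaging
# ---------------------------------------------------------------------------


@dataclass
class PassagingSpec:
    p_loss: float = 0.019
    generations: tuple[int, ...] = (25, 50)
    n_colonies: int = 96
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_loss <= 1:
            raise SimulationError("p_loss must lie in [0, 1]")
        if list(self.generations) != sorted(set(self.generations)):
            raise SimulationError("generations must be strictly increasing")
        if self.n_colonies < 1 or self.replicates < 1:
            raise SimulationError("n_colonies and replicates must be >= 1")


def generate_passaging_counts(spec: PassagingSpec) -> StabilityExperiment:
    """Binomial colony counts under per-generation geometric element loss.

    At generation g each of ``n_colonies`` colonies is resistant (still
    carries the element) with probability (1 - p_loss)^g.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(1, spec.replicates + 1):
        for g in spec.generations:
            p_keep = (1.0 - spec.p_loss) ** g
            k = int(rng.binomial(spec.n_colonies, p_keep))
            rows.append(
                {
                    "replicate": rep,
                    "generation": g,
                    "resistant": k,
                    "total": spec.n_colonies,
                }
            )
    return StabilityExperiment(counts=pd.DataFrame(rows), p_loss=spec.p_loss)


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


@dataclass
class CoverageSpec:
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "chr_large_1": 1_000_000,
            "chr_large_2": 800_000,
            "chr_large_3": 500_000,
            "chr_small": 150_000,
            "PGNC": 211_000,
        }
    )
    element_name: str = "PGNC"
    true_ratio: float = 1.0
    mean_depth: float = 30.0
    noise: str | None = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.element_name not in self.contig_lengths:
            raise SimulationError("element_name must be present in contig_lengths")
        if self.mean_depth <= 0 or self.true_ratio <= 0:
            raise SimulationError("depths and true_ratio must be positive")
        if any(l <= 0 for l in self.contig_lengths.values()):
            raise SimulationError("contig lengths must be positive")
        if self.noise not in (None, "poisson"):
            raise SimulationError("noise must be None or 'poisson'")


def generate_coverage_profile(spec: CoverageSpec) -> pd.DataFrame:
    """Per-contig mean sequencing depth with the element scaled by the ratio.

    With Poisson noise the observed mean depth of a contig of length L is a
    Poisson(L * depth) total base count divided by L; noiseless profiles
    return the exact expectations.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for contig, length in spec.contig_lengths.items():
        depth = spec.mean_depth * (
            spec.true_ratio if contig == spec.element_name else 1.0
        )
        if spec.noise == "poisson":
            depth = float(rng.poisson(depth * length)) / length
        rows.append({"contig": contig, "length": length, "mean_depth": depth})
    df = pd.DataFrame(rows)
    df.attrs["true_ratio"] = spec.true_ratio
    return df
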