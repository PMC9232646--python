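"""Phenotype statistics: growth kinetics, phenotype-microarray (BioLog)
classification and mitotic (segregational) stability.

The specific growth rate between two optical-density readings is
U = ln(x/x0)/t; the maximum specific growth rate of a curve is the maximum
over sliding windows of the least-squares slope of ln(OD) against time.
BioLog wells are summarised by their maximum curve height A (peak of a
5-point rolling-median-smoothed series) and compared between strains as
log2(A_test/A_reference), with wells excluded when either strain fails to
exceed the negative control by 50 units or the plate's positive control
stays under 100 units. Episome retention over non-selective passaging
follows a per-generation geometric loss model, R(g) = (1 - p)^g, which
:func:`estimate_loss_rate` inverts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class PhenotypeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Growth kinetics
# ---------------------------------------------------------------------------


@dataclass
class GrowthCurve:
    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray  # optical density, >= 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.size < 2:
            raise PhenotypeError("times and od must be equal-length with >= 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise PhenotypeError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise PhenotypeError("od values must be non-negative")


def specific_growth_rate(x0: float, x: float, t: float) -> float:
    """U = ln(x/x0)/t in h^-1 between two OD readings ``t`` hours apart."""
    if x0 <= 0 or x <= 0 or t <= 0:
        raise PhenotypeError("x0, x and t must all be positive")
    return math.log(x / x0) / t


def max_specific_growth_rate(curve: GrowthCurve, window: int = 5) -> float:
    """Maximum windowed log-linear slope of a growth curve (h^-1)."""
    if window < 2:
        raise PhenotypeError("window must span at least 2 points")
    n = curve.times.size
    if n < window:
        raise PhenotypeError(f"need at least {window} points, got {n}")
    if np.any(curve.od[: n] <= 0):
        raise PhenotypeError("od must be positive to take logarithms")
    log_od = np.log(curve.od)
    best = -np.inf
    for i in range(n - window + 1):
        t = curve.times[i : i + window]
        y = log_od[i : i + window]
        tc = t - t.mean()
        slope = float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))
        best = max(best, slope)
    return best


def max_curve_height(values: np.ndarray, smooth_window: int = 5) -> float:
    """Maximum of the rolling-median-smoothed series (curve height A)."""
    values = np.asarray(values, dtype=float)
    if values.size < smooth_window:
        raise PhenotypeError(f"need at least {smooth_window} points")
    smoothed = (
        pd.Series(values)
        .rolling(smooth_window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return float(smoothed.max())


# ---------------------------------------------------------------------------
# BioLog plates
# ---------------------------------------------------------------------------


@dataclass
class PlateKinetics:
    """Per-well respiration/growth kinetics for one strain on one plate.

    ``data`` is tidy: columns well, time, value. ``roles`` maps each well to
    'compound', 'negative_control', 'positive_control' or 'blank';
    ``compounds`` labels the compound wells.
    """

    data: pd.DataFrame
    roles: dict[str, str]
    compounds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"well", "time", "value"}
        if not required <= set(self.data.columns):
            raise PhenotypeError(f"plate data needs columns {sorted(required)}")
        wells = set(self.data["well"])
        if wells - set(self.roles):
            raise PhenotypeError("every well needs a role")
        for role in ("negative_control", "positive_control"):
            if sum(r == role for r in self.roles.values()) < 1:
                raise PhenotypeError(f"plate lacks a {role} well")

    def heights(self, smooth_window: int = 5) -> pd.Series:
        out = {}
        for well, grp in self.data.sort_values("time").groupby("well"):
            out[well] = max_curve_height(grp["value"].to_numpy(), smooth_window)
        return pd.Series(out, name="A")

    def control_heights(self, smooth_window: int = 5) -> tuple[float, float]:
        """(negative, positive) control curve heights (max over such wells)."""
        h = self.heights(smooth_window)
        neg = max(h[w] for w, r in self.roles.items() if r == "negative_control")
        pos = max(h[w] for w, r in self.roles.items() if r == "positive_control")
        return float(neg), float(pos)


@dataclass
class BiologClassification:
    table: pd.DataFrame  # well, compound, A_test, A_reference, log2_ratio, status

    def counts(self) -> dict[str, int]:
        return self.table["status"].value_counts().to_dict()

    def wells(self, status: str) -> list[str]:
        return self.table.loc[self.table["status"] == status, "well"].tolist()


def classify_heights(
    a_test: dict[str, float],
    a_ref: dict[str, float],
    neg_test: float,
    neg_ref: float,
    pos_test: float,
    pos_ref: float,
    min_over_negative: float = 50.0,
    min_positive: float = 100.0,
    log2_threshold: float = 1.0,
) -> pd.DataFrame:
    """Rule-based classification on precomputed curve heights.

    A well is excluded when either strain's height fails to exceed that
    strain's negative control by ``min_over_negative`` units (inclusive:
    A >= neg + 50 passes) or either plate's positive control is below
    ``min_positive``. Otherwise the status follows log2(A_test/A_ref) with
    the symmetric +/-``log2_threshold`` rule.
    """
    plate_failed = pos_test < min_positive or pos_ref < min_positive
    rows = []
    for well in sorted(a_test):
        at, ar = a_test[well], a_ref[well]
        if (
            plate_failed
            or at < neg_test + min_over_negative
            or ar < neg_ref + min_over_negative
        ):
            rows.append((well, at, ar, np.nan, "excluded"))
            continue
        ratio = math.log2(at / ar)
        if ratio >= log2_threshold:
            status = "increased"
        elif ratio <= -log2_threshold:
            status = "decreased"
        else:
            status = "unchanged"
        rows.append((well, at, ar, ratio, status))
    return pd.DataFrame(
        rows, columns=["well", "A_test", "A_reference", "log2_ratio", "status"]
    )


def biolog_classify(
    test: PlateKinetics,
    reference: PlateKinetics,
    min_over_negative: float = 50.0,
    min_positive: float = 100.0,
    log2_threshold: float = 1.0,
    smooth_window: int = 5,
) -> BiologClassification:
    """Classify each compound well of a paired test/reference plate run."""
    test_wells = {w for w, r in test.roles.items() if r == "compound"}
    ref_wells = {w for w, r in reference.roles.items() if r == "compound"}
    if test_wells != ref_wells or test.compounds != reference.compounds:
        raise PhenotypeError("test and reference plate layouts do not match")

    ht = test.heights(smooth_window)
    hr = reference.heights(smooth_window)
    neg_t, pos_t = test.control_heights(smooth_window)
    neg_r, pos_r = reference.control_heights(smooth_window)
    table = classify_heights(
        {w: float(ht[w]) for w in sorted(test_wells)},
        {w: float(hr[w]) for w in sorted(test_wells)},
        neg_t,
        neg_r,
        pos_t,
        pos_r,
        min_over_negative,
        min_positive,
        log2_threshold,
    )
    table["compound"] = table["well"].map(test.compounds)
    return BiologClassification(table=table)


# ---------------------------------------------------------------------------
# Mitotic stability
# ---------------------------------------------------------------------------


@dataclass
class StabilityExperiment:
    """Colony counts from differential plating: replicate x generation."""

    counts: pd.DataFrame  # columns: replicate, generation, resistant, total
    p_loss: float | None = None  # ground truth when simulated

    def __post_init__(self) -> None:
        required = {"replicate", "generation", "resistant", "total"}
        if not required <= set(self.counts.columns):
            raise PhenotypeError(f"counts need columns {sorted(required)}")
        bad = self.counts[
            (self.counts["resistant"] < 0)
            | (self.counts["resistant"] > self.counts["total"])
        ]
        if len(bad):
            raise PhenotypeError("resistant counts must lie in [0, total]")


def retention_stats(exp: StabilityExperiment, ci_level: float = 0.95) -> pd.DataFrame:
    """Mean +/- sample SD of percent retention per generation.

    Also reports exact Clopper-Pearson confidence bounds per replicate,
    aggregated here as their min/max across replicates for display.
    """
    if (exp.counts["total"] <= 0).any():
        raise PhenotypeError("every replicate needs total > 0")
    alpha = 1 - ci_level
    rows = []
    for gen, grp in exp.counts.groupby("generation"):
        props = (grp["resistant"] / grp["total"]).to_numpy()
        lo_bounds, hi_bounds = [], []
        for _, r in grp.iterrows():
            k, n = int(r["resistant"]), int(r["total"])
            lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
            hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
            lo_bounds.append(lo)
            hi_bounds.append(hi)
        sd = float(np.std(props, ddof=1)) if props.size > 1 else 0.0
        rows.append(
            {
                "generation": gen,
                "n_replicates": props.size,
                "mean_pct": float(props.mean()) * 100,
                "sd_pct": sd * 100,
                "ci_low_pct": min(lo_bounds) * 100,
                "ci_high_pct": max(hi_bounds) * 100,
            }
        )
    return pd.DataFrame(rows).sort_values("generation").reset_index(drop=True)


def estimate_loss_rate(retention: float, generations: float) -> float:
    """Per-generation loss probability from R(g) = (1 - p)^g.

    p = 1 - R^(1/g). R = 0 leaves the rate unidentifiable (only a lower
    bound exists) and raises.
    """
    if generations <= 0:
        raise PhenotypeError("generations must be positive")
    if retention <= 0:
        raise PhenotypeError(
            "retention of 0 leaves the loss rate unidentifiable "
            "(only a lower bound can be reported)"
        )
    if retention > 1:
        raise PhenotypeError("retention must be a fraction in (0, 1]")
    return 1.0 - retention ** (1.0 / generations)
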