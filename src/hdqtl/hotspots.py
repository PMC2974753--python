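"""Hotspot calling, cis/trans classification, and tail-overlap summaries.

Prioritized traits are each assigned to the marker with their smallest
genome-wide corrected p-value.  A marker whose assigned-trait count
exceeds the 95th-percentile frequency of a simulated null (traits thrown
uniformly at markers) is called a regulatory hotspot.

Two null summaries are available.  ``iteration-max`` (the default used
by the pipeline) takes the per-iteration maximum count over markers and
thresholds at its 95th percentile — a family-wise bound over the marker
set, so a fully null dataset yields a hotspot in only ~5% of runs.
``pooled`` pools the per-marker counts of all iterations before taking
the percentile; it reproduces the per-marker count distribution
(Poisson(1) when as many traits as markers are assigned) but flags
~5% of *markers* under the null, which is rarely what a hotspot scan
wants.  Both use a strict ">" at the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import CorrectedPValueMatrix, MarkerMap, ValidationError

DEFAULT_PERCENTILE = 95.0
DEFAULT_NULL_MODE = "iteration-max"
NULL_MODES = ("iteration-max", "pooled")


def assign_traits(
    traits, pvals: CorrectedPValueMatrix, drop_flat: bool = False, report=None
) -> pd.Series:
    """Map each trait to its argmin-p marker (ties -> lowest marker index).

    The tie rule matches HDResult.best_marker, so hotspot assignment and
    the per-trait statistic always agree on the best locus.

    With ``drop_flat`` (used by the hotspot pipeline), traits whose
    p-values are identical across every observed marker are excluded:
    a flat profile has no "most strongly associated" locus, and the
    lowest-index tie-break would otherwise pile all such traits onto the
    first marker of the map, fabricating a hotspot there.  The number
    dropped is reported.
    """
    trait_index = {t: i for i, t in enumerate(pvals.traits)}
    assignment = {}
    n_flat = 0
    for trait in traits:
        if trait not in trait_index:
            raise ValidationError(f"trait {trait!r} has no p-value row")
        row = pvals.values[trait_index[trait]]
        finite = row[np.isfinite(row)]
        if finite.size == 0:
            raise ValidationError(f"trait {trait!r}: no defined p-values")
        if drop_flat and finite.min() == finite.max():
            n_flat += 1
            continue
        best = int(np.nanargmin(row))
        assignment[trait] = pvals.markers[best]
    if n_flat and report is not None:
        report(f"excluded {n_flat} trait(s) with flat p-value profiles")
    return pd.Series(assignment, dtype=object, name="marker").sort_index()


def hotspot_null(
    n_traits: int,
    n_markers: int,
    n_iter: int = 1000,
    seed: int | None = None,
    percentile: float = DEFAULT_PERCENTILE,
    mode: str = DEFAULT_NULL_MODE,
) -> float:
    """Null count threshold from uniform random assignment of traits to markers."""
    if mode not in NULL_MODES:
        raise ValidationError(f"unknown null mode {mode!r}")
    if n_traits < 0 or n_markers < 1 or n_iter < 1:
        raise ValidationError("n_traits >= 0, n_markers >= 1, n_iter >= 1 required")
    if n_iter < 100:
        warnings.warn("fewer than 100 null iterations; threshold will be noisy", stacklevel=2)
    if n_traits == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_traits, np.full(n_markers, 1.0 / n_markers), size=n_iter)
    if mode == "pooled":
        return float(np.percentile(counts.ravel(), percentile))
    return float(np.percentile(counts.max(axis=1), percentile))


def call_hotspots(
    assignment: pd.Series,
    markers: MarkerMap,
    null_threshold: float,
    method: str = "",
) -> pd.DataFrame:
    """Per-marker assigned-trait counts, flagged where count > threshold (strict)."""
    counts = assignment.value_counts()
    table = markers.to_frame()
    table["count"] = [int(counts.get(m, 0)) for m in markers.marker_id]
    table["is_hotspot"] = table["count"] > null_threshold
    table["null_threshold"] = null_threshold
    table["method"] = method
    unknown = set(assignment) - set(markers.marker_id)
    if unknown:
        raise ValidationError(f"assigned markers missing from the map: {sorted(unknown)}")
    return table


def aggregate_regions(hotspot_table: pd.DataFrame, max_gap: int = 1) -> pd.DataFrame:
    """Merge flagged markers within *max_gap* map positions into regions.

    Produces chromosome-level hotspot regions (one row per run of
    adjacent flagged markers), with the summed trait count.
    """
    flagged = hotspot_table[hotspot_table["is_hotspot"]]
    regions = []
    for chrom, group in flagged.groupby("chrom", sort=False):
        # row order within a chromosome is map order
        positions = hotspot_table.index[hotspot_table["chrom"] == chrom]
        rank = {i: r for r, i in enumerate(positions)}
        current = None
        for i, row in group.iterrows():
            if current is not None and rank[i] - current["last_rank"] <= max_gap:
                current["end"] = row["marker"]
                current["n_markers"] += 1
                current["n_traits"] += int(row["count"])
                current["last_rank"] = rank[i]
            else:
                if current is not None:
                    regions.append(current)
                current = {
                    "chrom": chrom,
                    "start": row["marker"],
                    "end": row["marker"],
                    "n_markers": 1,
                    "n_traits": int(row["count"]),
                    "last_rank": rank[i],
                }
        if current is not None:
            regions.append(current)
    frame = pd.DataFrame(
        regions, columns=["chrom", "start", "end", "n_markers", "n_traits", "last_rank"]
    )
    return frame.drop(columns="last_rank")


def classify_cis_trans(
    assignment: pd.Series,
    trait_chromosome: dict | None,
    markers: MarkerMap,
) -> pd.Series:
    """cis when a trait's best marker shares its annotated chromosome.

    A trait without chromosome annotation is 'unknown' rather than
    silently trans.
    """
    marker_chrom = dict(zip(markers.marker_id, markers.chromosome))
    trait_chromosome = trait_chromosome or {}
    labels = {}
    for trait, marker in assignment.items():
        trait_chrom = trait_chromosome.get(trait)
        if trait_chrom is None:
            labels[trait] = "unknown"
        elif str(trait_chrom) == marker_chrom[marker]:
            labels[trait] = "cis"
        else:
            labels[trait] = "trans"
    return pd.Series(labels, dtype=object, name="cis_trans").sort_index()


@dataclass(frozen=True)
class TailOverlap:
    """Overlap of an HD tail with the genome-wide eQTL trait set."""

    count: int
    fraction: float  # NaN when the tail is empty
    tail_size: int


def tail_overlap(tail, eqtl_traits) -> TailOverlap:
    tail = set(tail)
    overlap = len(tail & set(eqtl_traits))
    if not tail:
        warnings.warn("empty tail: overlap fraction undefined", stacklevel=2)
        return TailOverlap(0, float("nan"), 0)
    return TailOverlap(overlap, overlap / len(tail), len(tail))
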