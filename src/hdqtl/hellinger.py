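"""Per-trait Hellinger distance between a p-value profile and an x^3 reference.

A trait whose expression is controlled by a single locus shows one
exceptional genome-wide corrected p-value and a bulk of unremarkable
ones.  We histogram the trait's profile and compare it, bin by bin, to
the histogram of the reference multiset {x^3 : x = 1..L}, which models
exactly that expectation: most mass in the small bins, tapering off
towards the single largest value.  The smaller the distance, the more
the trait looks like "one exceptional association".

Two formula variants are provided.  The default is the true Hellinger
distance

    HD(P, Q) = sqrt( sum_a ( sqrt(P_a/|P|) - sqrt(Q_a/|Q|) )^2 )

with range [0, sqrt(2)].  The ``printed`` variant drops the radicals,

    HD(P, Q) = sum_a ( P_a/|P| - Q_a/|Q| )^2

with range [0, 2]; it is kept because the literature around this method
prints the formula both ways.  Both compare bin proportions, so the
statistic is invariant to the total count ("shape but not scale").

Each distribution is binned over its own range with
binwidth = (max - min) / n_bins; bins are half-open with the last bin
closed, and a zero-width range puts all mass in bin 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import CorrectedPValueMatrix, ValidationError

DEFAULT_N_BINS = 30
FORMULAS = ("hellinger", "printed")
TRANSFORMS = ("one-minus-p", "neglog10")


@dataclass(frozen=True, eq=False)
class Histogram:
    """Bin counts over [range_min, range_max] with equal-width bins."""

    counts: np.ndarray
    range_min: float
    range_max: float

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1 or counts.size < 1:
            raise ValidationError("histogram needs a 1-d, non-empty count vector")
        if (counts < 0).any():
            raise ValidationError("histogram counts must be non-negative")
        if self.range_max < self.range_min:
            raise ValidationError("histogram range is inverted")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def binwidth(self) -> float:
        return (self.range_max - self.range_min) / self.n_bins

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise ValidationError("histogram with zero total has no proportions")
        return self.counts / self.total


def significance_scores(p_row, transform: str = "one-minus-p") -> np.ndarray:
    """Orient corrected p-values so the uninteresting bulk sits near zero.

    With scores = 1 - p, non-significant associations (p ~ 1) fall in the
    small bins and the exceptional association approaches the top of the
    range, matching the orientation of the x^3 reference.  The
    ``neglog10`` alternative uses -log10(p); the add-one correction of
    the p-values bounds it at log10(N + 1).
    """
    p = np.asarray(p_row, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value row")
    if not np.all(np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("corrected p-values must lie in (0, 1]")
    if transform == "one-minus-p":
        return 1.0 - p
    if transform == "neglog10":
        return -np.log10(p)
    raise ValidationError(f"unknown transform {transform!r}")


def make_histogram(values, n_bins: int = DEFAULT_N_BINS) -> Histogram:
    """Equal-width histogram over the data's own range.

    Bins are [edge_i, edge_{i+1}) except the last, which is closed so the
    maximum is counted.  Constant input degenerates to all mass in bin 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("cannot histogram an empty value set")
    if not np.all(np.isfinite(v)):
        raise ValidationError("histogram input must be finite")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        counts = np.zeros(n_bins, dtype=np.int64)
        counts[0] = v.size
    else:
        counts, _ = np.histogram(v, bins=n_bins, range=(vmin, vmax))
    return Histogram(counts, vmin, vmax)


def hellinger_distance(P: Histogram, Q: Histogram, formula: str = "hellinger") -> float:
    """Distance between two histograms' bin-proportion vectors.

    Bins are compared positionally (bin a of P against bin a of Q), so
    both histograms must use the same number of bins; their value ranges
    may differ since each was binned over its own range.
    """
    if P.n_bins != Q.n_bins:
        raise ValidationError(
            f"bin-count mismatch: {P.n_bins} vs {Q.n_bins}"
        )
    p = P.proportions()
    q = Q.proportions()
    if formula == "hellinger":
        return float(math.sqrt(np.sum((np.sqrt(p) - np.sqrt(q)) ** 2)))
    if formula == "printed":
        return float(np.sum((p - q) ** 2))
    raise ValidationError(f"unknown formula {formula!r}")


def reference_values(n_loci: int) -> np.ndarray:
    """The reference multiset {x^3 : x = 1..L} for L loci."""
    if n_loci < 1:
        raise ValidationError("need at least one locus")
    x = np.arange(1, n_loci + 1, dtype=float)
    return x**3


def reference_histogram(n_loci: int, n_bins: int = DEFAULT_N_BINS) -> Histogram:
    """Histogram of the x^3 reference over [1, L^3].

    As L grows the first-bin proportion tends to (1/n_bins)^(1/3) and
    the counts taper monotonically, modelling a profile dominated by a
    single exceptional association.
    """
    if n_loci < 1:
        raise ValidationError("need at least one locus")
    if n_loci < n_bins:
        warnings.warn(
            f"reference over {n_loci} loci with {n_bins} bins is sparse",
            stacklevel=2,
        )
    return make_histogram(reference_values(n_loci), n_bins)


@dataclass(frozen=True)
class HDResult:
    """Per-trait Hellinger distance and the trait's best-associated marker."""

    trait_id: str
    hd: float
    best_marker: str
    best_p: float
    n_bins: int
    n_ties: int


def trait_hd(
    p_row,
    n_bins: int = DEFAULT_N_BINS,
    trait_id: str = "",
    marker_ids=None,
    formula: str = "hellinger",
    transform: str = "one-minus-p",
) -> HDResult:
    """Hellinger distance of one trait's corrected-p profile to the reference.

    Markers with missing (NaN) p-values are excluded; the reference is
    built over the number of observed loci.  The best marker is the
    argmin of p with ties broken towards the lowest marker index; the
    tie count is recorded because hotspot assignment depends on it.
    """
    p = np.asarray(p_row, dtype=float)
    valid = np.isfinite(p)
    if not valid.any():
        raise ValidationError(f"trait {trait_id!r}: no defined p-values")
    idx = np.flatnonzero(valid)
    pv = p[idx]
    scores = significance_scores(pv, transform=transform)
    hist = make_histogram(scores, n_bins)
    ref = reference_histogram(pv.size, n_bins)
    hd = hellinger_distance(hist, ref, formula=formula)
    best_local = int(np.argmin(pv))  # argmin takes the first = lowest index
    n_ties = int(np.sum(pv == pv[best_local]))
    best_idx = int(idx[best_local])
    best = marker_ids[best_idx] if marker_ids is not None else str(best_idx)
    return HDResult(str(trait_id), hd, str(best), float(pv[best_local]), n_bins, n_ties)


def hd_table(
    pvals: CorrectedPValueMatrix,
    n_bins: int = DEFAULT_N_BINS,
    formula: str = "hellinger",
    transform: str = "one-minus-p",
) -> pd.DataFrame:
    """trait_hd applied to every trait; columns trait, hd, best_marker, best_p, n_ties."""
    rows = []
    for i, trait in enumerate(pvals.traits):
        res = trait_hd(
            pvals.values[i],
            n_bins=n_bins,
            trait_id=trait,
            marker_ids=pvals.markers,
            formula=formula,
            transform=transform,
        )
        rows.append(
            (res.trait_id, res.hd, res.best_marker, res.best_p, res.n_ties)
        )
    return pd.DataFrame(rows, columns=["trait", "hd", "best_marker", "best_p", "n_ties"])


def hd_tails(
    hd: pd.DataFrame,
    tail_fraction: float = 0.05,
    count: int | None = None,
):
    """Small- and large-HD trait sets.

    Quantile mode (default): small tail = traits with hd <= the
    tail_fraction quantile (inclusive, type-7 interpolation), large tail
    = traits with hd >= the (1 - tail_fraction) quantile.  With heavy
    ties the inclusive rule can sweep in every tied trait; a warning is
    issued when the two tails overlap.

    Count mode (count=n): exactly n smallest and n largest traits, ties
    broken by trait id.  This mirrors comparisons against "an equal
    number" of genome-wide eQTL traits.
    """
    if count is None and not 0 < tail_fraction < 0.5:
        raise ValidationError("tail_fraction must be in (0, 0.5)")
    series = hd.set_index("trait")["hd"]
    if count is not None:
        order = series.reset_index().sort_values(["hd", "trait"])
        small = set(order.head(count)["trait"])
        order_desc = series.reset_index().sort_values(
            ["hd", "trait"], ascending=[False, True]
        )
        large = set(order_desc.head(count)["trait"])
    else:
        lo = float(np.quantile(series.to_numpy(), tail_fraction))
        hi = float(np.quantile(series.to_numpy(), 1.0 - tail_fraction))
        small = set(series.index[series.to_numpy() <= lo])
        large = set(series.index[series.to_numpy() >= hi])
    if small & large:
        warnings.warn(
            f"HD tails overlap on {len(small & large)} trait(s); "
            "tied statistics dominate the distribution",
            stacklevel=2,
        )
    return small, large


def bin_sweep(pvals: CorrectedPValueMatrix, bins=range(10, 101, 10), **kwargs):
    """HD per trait for each bin count, plus pairwise Spearman rank correlations.

    Returns (hd_frame, rho_frame): hd_frame is traits x bin counts;
    rho_frame holds the Spearman rho between every pair of bin counts
    (NaN, with a warning, when fewer than two traits make a rank
    correlation undefined).
    """
    bins = list(dict.fromkeys(bins))  # preserve order, drop repeats
    if not bins:
        raise ValidationError("bin list must be non-empty")
    columns = {}
    for b in bins:
        table = hd_table(pvals, n_bins=b, **kwargs)
        columns[b] = table.set_index("trait")["hd"]
    hd_frame = pd.DataFrame(columns)
    rho = pd.DataFrame(np.nan, index=bins, columns=bins, dtype=float)
    if len(hd_frame) < 2:
        warnings.warn("rank correlations undefined for fewer than two traits", stacklevel=2)
        return hd_frame, rho
    for i, a in enumerate(bins):
        for b in bins[i:]:
            if a == b:
                rho.loc[a, b] = 1.0
                continue
            r = stats.spearmanr(hd_frame[a], hd_frame[b]).statistic
            rho.loc[a, b] = rho.loc[b, a] = float(r)
    return hd_frame, rho
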