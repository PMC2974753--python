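"""Shared data model and tab-separated I/O for haploid-cross eQTL data.

The containers here describe a biparental haploid cross (e.g. segregants
of a yeast cross or progeny of a *P. falciparum* cross): genotypes are
parental-allele codes 0/1 per marker and strain, expression is a real
value per trait and strain.  Marker positions are 1-based and only their
ordering matters downstream, so the unit (bp or cM) is pass-through
metadata.

All files are TSV with a header row; floats are written with six
significant digits.  Heterozygote or otherwise unexpected genotype codes
are a hard error rather than being silently recoded, because the method
is defined for haploid panels only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

GENOTYPE_META_COLUMNS = ("marker", "chrom", "pos")
FLOAT_FORMAT = "%.6g"


class ValidationError(ValueError):
    """An input file or matrix violates the data contract."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dups}")


@dataclass(frozen=True, eq=False)
class MarkerMap:
    """Ordered marker index: id, chromosome, and position per marker.

    Positions must be strictly increasing within each chromosome, in the
    order the markers appear; this ordering defines the loci index
    1..L used throughout.
    """

    marker_id: tuple
    chromosome: tuple
    position: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "marker_id", tuple(str(m) for m in self.marker_id))
        object.__setattr__(self, "chromosome", tuple(str(c) for c in self.chromosome))
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if not (len(self.marker_id) == len(self.chromosome) == len(pos)):
            raise ValidationError("marker map fields have unequal lengths")
        _check_unique(self.marker_id, "marker")
        if len(pos) and (not np.all(np.isfinite(pos)) or np.any(pos < 0)):
            raise ValidationError("marker positions must be finite and non-negative")
        chrom = np.asarray(self.chromosome)
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValidationError(
                    f"positions not strictly increasing on chromosome {c!r}"
                )

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def index_of(self, marker: str) -> int:
        try:
            return self.marker_id.index(marker)
        except ValueError:
            raise KeyError(f"unknown marker {marker!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": list(self.marker_id),
                "chrom": list(self.chromosome),
                "pos": self.position,
            }
        )

    def subset(self, idx) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(
            tuple(np.asarray(self.marker_id, dtype=object)[idx]),
            tuple(np.asarray(self.chromosome, dtype=object)[idx]),
            self.position[idx],
        )


@dataclass(eq=False)
class GenotypeMatrix:
    """Markers x strains biallelic calls: 0/1 parental codes, NaN missing."""

    markers: MarkerMap
    strains: tuple
    calls: np.ndarray

    def __post_init__(self):
        self.strains = tuple(str(s) for s in self.strains)
        _check_unique(self.strains, "strain")
        calls = np.asarray(self.calls, dtype=float)
        if calls.shape != (len(self.markers), len(self.strains)):
            raise ValidationError(
                f"genotype calls shape {calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.strains)} strains"
            )
        observed = calls[np.isfinite(calls)]
        if observed.size and not np.isin(observed, (0.0, 1.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0))][0]
            raise ValidationError(f"genotype call {bad!r} is not in {{0, 1, NA}}")
        self.calls = calls

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def uninformative(self) -> np.ndarray:
        """Boolean mask of markers lacking both alleles among observed calls."""
        with np.errstate(invalid="ignore"):
            has0 = np.nansum(self.calls == 0, axis=1) > 0
            has1 = np.nansum(self.calls == 1, axis=1) > 0
        return ~(has0 & has1)

    def drop_uninformative(self) -> "GenotypeMatrix":
        keep = ~self.uninformative()
        return GenotypeMatrix(self.markers.subset(keep), self.strains, self.calls[keep])

    def subset_strains(self, strain_order) -> "GenotypeMatrix":
        idx = [self.strains.index(s) for s in strain_order]
        return GenotypeMatrix(self.markers, tuple(strain_order), self.calls[:, idx])


@dataclass(eq=False)
class ExpressionMatrix:
    """Traits x strains real-valued expression, with optional trait chromosome."""

    traits: tuple
    strains: tuple
    values: np.ndarray
    trait_chromosome: dict | None = None

    def __post_init__(self):
        self.traits = tuple(str(t) for t in self.traits)
        self.strains = tuple(str(s) for s in self.strains)
        _check_unique(self.traits, "trait")
        _check_unique(self.strains, "strain")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.traits), len(self.strains)):
            raise ValidationError(
                f"expression shape {values.shape} does not match "
                f"{len(self.traits)} traits x {len(self.strains)} strains"
            )
        if not np.all(np.isfinite(values)):
            t, s = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value for trait {self.traits[t]!r}, "
                f"strain {self.strains[s]!r}"
            )
        self.values = values
        if self.trait_chromosome is not None:
            self.trait_chromosome = {
                str(k): str(v) for k, v in dict(self.trait_chromosome).items()
            }

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def subset_strains(self, strain_order) -> "ExpressionMatrix":
        idx = [self.strains.index(s) for s in strain_order]
        return ExpressionMatrix(
            self.traits, tuple(strain_order), self.values[:, idx], self.trait_chromosome
        )


@dataclass(eq=False)
class TraitMarkerMatrix:
    """Base container for traits x markers score matrices."""

    traits: tuple
    markers: tuple
    values: np.ndarray

    def __post_init__(self):
        self.traits = tuple(str(t) for t in self.traits)
        self.markers = tuple(str(m) for m in self.markers)
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.traits), len(self.markers)):
            raise ValidationError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.traits)} traits x {len(self.markers)} markers"
            )
        self.values = values
        self._check_values()

    def _check_values(self):  # pragma: no cover - overridden
        pass

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.traits), columns=list(self.markers))


class AssociationMatrix(TraitMarkerMatrix):
    """Traits x markers LOD scores; NaN marks an undefined association."""

    def _check_values(self):
        observed = self.values[np.isfinite(self.values)]
        if observed.size and observed.min() < 0:
            raise ValidationError("LOD scores must be non-negative")


class CorrectedPValueMatrix(TraitMarkerMatrix):
    """Traits x markers genome-wide corrected p-values in (0, 1]."""

    def _check_values(self):
        observed = self.values[np.isfinite(self.values)]
        if observed.size and (observed.min() <= 0 or observed.max() > 1):
            raise ValidationError("corrected p-values must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path, drop_uninformative: bool = False, report=None) -> GenotypeMatrix:
    """Read a genotype TSV: columns marker, chrom, pos, then one per strain.

    Calls must be 0, 1 or NA.  Any other code is a hard error naming the
    offending marker and strain.  Markers where only one allele is
    observed are reported (and dropped when *drop_uninformative*).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENOTYPE_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    strain_cols = [c for c in df.columns if c not in GENOTYPE_META_COLUMNS]
    if not strain_cols:
        raise ValidationError(f"{path}: no strain columns found")
    markers = MarkerMap(
        tuple(df["marker"]), tuple(df["chrom"]), df["pos"].astype(float).to_numpy()
    )
    raw = df[strain_cols].to_numpy(dtype=object)
    calls = np.full(raw.shape, np.nan)
    for code, value in (("0", 0.0), ("1", 1.0)):
        calls[raw == code] = value
    bad = (raw != "0") & (raw != "1") & ~pd.isna(raw) & (raw != "NA")
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: invalid genotype call {raw[i, j]!r} at marker "
            f"{markers.marker_id[i]!r}, strain {strain_cols[j]!r}"
        )
    geno = GenotypeMatrix(markers, tuple(strain_cols), calls)
    n_uninf = int(geno.uninformative().sum())
    if n_uninf and report is not None:
        report(f"{n_uninf} uninformative marker(s) (single observed allele)")
    if drop_uninformative and n_uninf:
        geno = geno.drop_uninformative()
    return geno


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = geno.markers.to_frame()
    calls = pd.DataFrame(geno.calls, columns=list(geno.strains))
    calls = calls.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    pd.concat([df, calls], axis=1).to_csv(path, sep="\t", index=False)


def read_expression(path) -> ExpressionMatrix:
    """Read an expression TSV: columns trait, optional trait_chrom, then strains."""
    df = pd.read_csv(path, sep="\t")
    if "trait" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'trait'")
    trait_chrom = None
    if "trait_chrom" in df.columns:
        annotated = df["trait_chrom"].notna()
        trait_chrom = dict(
            zip(df.loc[annotated, "trait"].astype(str), df.loc[annotated, "trait_chrom"])
        )
    strain_cols = [c for c in df.columns if c not in ("trait", "trait_chrom")]
    if not strain_cols:
        raise ValidationError(f"{path}: no strain columns found")
    values = df[strain_cols].to_numpy(dtype=float)
    return ExpressionMatrix(tuple(df["trait"]), tuple(strain_cols), values, trait_chrom)


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame({"trait": list(expr.traits)})
    if expr.trait_chromosome is not None:
        df["trait_chrom"] = [expr.trait_chromosome.get(t, "NA") for t in expr.traits]
    values = pd.DataFrame(expr.values, columns=list(expr.strains))
    pd.concat([df, values], axis=1).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def write_matrix(matrix: TraitMarkerMatrix, path) -> None:
    matrix.to_frame().to_csv(
        path, sep="\t", index_label="trait", float_format=FLOAT_FORMAT
    )


def read_pvalue_matrix(path) -> CorrectedPValueMatrix:
    df = pd.read_csv(path, sep="\t", index_col="trait")
    return CorrectedPValueMatrix(tuple(df.index), tuple(df.columns), df.to_numpy(float))


def write_metadata(path, entries: dict) -> None:
    """Run-metadata sidecar: one key<TAB>value pair per line."""
    with open(path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key}\t{value}\n")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_strains(geno: GenotypeMatrix, expr: ExpressionMatrix, report=None):
    """Restrict both matrices to shared strains, in genotype-file order.

    Requires at least three shared strains (fewer would leave no degrees
    of freedom for a single-marker association).  Idempotent.
    """
    shared = [s for s in geno.strains if s in set(expr.strains)]
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} shared strain(s) between genotype and expression"
        )
    if report is not None:
        report(
            f"aligned on {len(shared)} shared strains "
            f"({len(geno.strains) - len(shared)} genotype-only, "
            f"{len(expr.strains) - len(shared)} expression-only dropped)"
        )
    if shared == list(geno.strains) == list(expr.strains):
        return geno, expr
    return geno.subset_strains(shared), expr.subset_strains(shared)
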