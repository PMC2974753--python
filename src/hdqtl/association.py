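"""Single-marker LOD mapping and permutation-based genome-wide correction.

For a haploid panel the single-marker regression LOD has the closed form

    LOD = -(n / 2) * log10(1 - r^2)

with ``r`` the Pearson correlation between the 0/1 genotype codes and the
expression values over the n pairwise-complete strains.  This is the
standard Haley-Knott / backcross-coded LOD used by linkage packages.

Genome-wide significance follows the Churchill-Doerge family-wise
construction: in each permutation the strain labels are shuffled by one
shared permutation (preserving linkage among markers and correlation
among traits), all trait x marker LODs are recomputed, and the single
genome-wide maximum is kept.  The corrected p-value of an observed LOD
is its add-one rank among those maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import (
    AssociationMatrix,
    CorrectedPValueMatrix,
    ExpressionMatrix,
    GenotypeMatrix,
    ValidationError,
)

DEFAULT_LOD_CAP = 300.0
DEFAULT_N_ITERATIONS = 1000
_MIN_COMPLETE = 3
_VAR_TOL = 1e-9  # on unit-scaled rows; real variation is O(n)


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and unit-scale rows over observed entries; NaN -> 0.

    Pearson correlation is affine-invariant per row, so this changes no
    LOD, but it makes 'constant on the complete subset' detectable with
    an absolute tolerance.  Returns (scaled matrix, all-constant-row mask).
    """
    mask = np.isfinite(X)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(mask, X, np.nan), axis=1, keepdims=True)
        sd = np.nanstd(np.where(mask, X, np.nan), axis=1, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd = np.where(sd > 0, sd, 1.0)
    Z = np.where(mask, (X - mean) / sd, 0.0)
    return Z, constant


def lod_matrix(
    geno_calls: np.ndarray, expr_values: np.ndarray, cap: float = DEFAULT_LOD_CAP
) -> np.ndarray:
    """All pairwise LODs between expression rows (T x n) and genotype rows (L x n).

    Uses pairwise-complete strains per (trait, marker) cell.  Cells with
    fewer than three complete strains, or where either variable is
    constant on the complete subset, are NaN ("undefined", never 0).
    Finite results are capped at *cap* so perfect separation cannot
    produce infinities.
    """
    G = np.atleast_2d(np.asarray(geno_calls, dtype=float))
    E = np.atleast_2d(np.asarray(expr_values, dtype=float))
    Gz, g_const = _standardize_rows(G)
    Ez, e_const = _standardize_rows(E)
    Mg = np.isfinite(G).astype(float)
    Me = np.isfinite(E).astype(float)

    n = Me @ Mg.T
    sx = Ez @ Mg.T
    sy = Me @ Gz.T
    sxy = Ez @ Gz.T
    sxx = (Ez * Ez) @ Mg.T
    syy = Me @ (Gz * Gz).T

    cov = n * sxy - sx * sy
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.clip((cov * cov) / (vx * vy), 0.0, 1.0)
        lod = np.minimum(-(n / 2.0) * np.log10(1.0 - r2), cap)
    undefined = (
        (n < _MIN_COMPLETE)
        | (vx <= _VAR_TOL * np.maximum(n, 1))
        | (vy <= _VAR_TOL * np.maximum(n, 1))
        | e_const[:, None]
        | g_const[None, :]
    )
    lod[undefined] = np.nan
    return lod


def lod_score(genotype_row, expression_row, cap: float = DEFAULT_LOD_CAP) -> float:
    """LOD for a single marker/trait pair; NaN when undefined."""
    return float(lod_matrix(genotype_row, expression_row, cap=cap)[0, 0])


def map_all(
    geno: GenotypeMatrix, expr: ExpressionMatrix, cap: float = DEFAULT_LOD_CAP
) -> AssociationMatrix:
    """LOD for every (trait, marker) pair of aligned matrices."""
    if geno.strains != expr.strains:
        raise ValidationError("genotype and expression strains are not aligned")
    lod = lod_matrix(geno.calls, expr.values, cap=cap)
    return AssociationMatrix(expr.traits, geno.markers.marker_id, lod)


@dataclass(frozen=True)
class NullMaxDistribution:
    """Per-iteration genome-wide maximum LODs under permuted strain labels."""

    maxima: np.ndarray
    n_iterations: int
    seed: int | None

    def __post_init__(self):
        maxima = np.asarray(self.maxima, dtype=float)
        object.__setattr__(self, "maxima", maxima)
        if maxima.size < 1:
            raise ValidationError("null distribution must hold at least one maximum")
        if np.any(maxima < 0) or not np.all(np.isfinite(maxima)):
            raise ValidationError("null maxima must be finite and non-negative")


def permutation_null(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    seed: int | None = None,
    mode: str = "shared",
    cap: float = DEFAULT_LOD_CAP,
    _permutations=None,
) -> NullMaxDistribution:
    """Null distribution of the genome-wide maximum LOD.

    mode="shared" applies one strain-label permutation per iteration to
    the whole genotype matrix, preserving marker linkage and the
    correlation structure among traits that the genome-wide maximum
    depends on.  mode="per-trait" permutes each trait independently.
    ``_permutations`` is a test hook: an iterable of explicit index
    arrays overriding the random draws.
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    if mode not in ("shared", "per-trait"):
        raise ValidationError(f"unknown permutation mode {mode!r}")
    if geno.strains != expr.strains:
        raise ValidationError("genotype and expression strains are not aligned")
    rng = np.random.default_rng(seed)
    n = geno.n_strains
    T = expr.n_traits
    maxima = np.empty(n_iterations)
    explicit = list(_permutations) if _permutations is not None else None
    if explicit is not None and len(explicit) != n_iterations:
        raise ValidationError("need one explicit permutation per iteration")
    for i in range(n_iterations):
        if mode == "shared":
            perm = explicit[i] if explicit is not None else rng.permutation(n)
            lod = lod_matrix(geno.calls[:, perm], expr.values, cap=cap)
        else:
            if explicit is not None:
                perms = np.asarray(explicit[i])
            else:
                perms = np.argsort(rng.random((T, n)), axis=1)
            lod = lod_matrix(geno.calls, expr.values[np.arange(T)[:, None], perms], cap=cap)
        finite = lod[np.isfinite(lod)]
        if finite.size == 0:
            raise ValidationError("all associations undefined in a permutation")
        maxima[i] = finite.max()
    return NullMaxDistribution(maxima, n_iterations, seed)


def corrected_pvalues(
    assoc: AssociationMatrix, null: NullMaxDistribution
) -> CorrectedPValueMatrix:
    """Genome-wide corrected p-values: p = (1 + #{maxima >= LOD}) / (N + 1).

    The add-one correction keeps p in [1/(N+1), 1], so no association is
    ever assigned p = 0.  Within a trait row, p is non-increasing in LOD.
    """
    maxima = np.sort(null.maxima)
    N = maxima.size
    lod = assoc.values
    flat = lod.ravel()
    count = N - np.searchsorted(maxima, flat, side="left")
    p = (1.0 + count) / (N + 1.0)
    p = p.reshape(lod.shape)
    p[~np.isfinite(lod)] = np.nan
    return CorrectedPValueMatrix(assoc.traits, assoc.markers, p)


@dataclass(frozen=True)
class EqtlCalls:
    """Significant (trait, marker) pairs and the traits holding at least one."""

    pairs: frozenset
    traits: frozenset
    alpha: float


def call_eqtls(pvals: CorrectedPValueMatrix, alpha: float = 0.05) -> EqtlCalls:
    """Threshold corrected p-values at *alpha* (p <= alpha is significant)."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    with np.errstate(invalid="ignore"):
        hits = pvals.values <= alpha
    pairs = frozenset(
        (pvals.traits[i], pvals.markers[j]) for i, j in np.argwhere(hits)
    )
    traits = frozenset(t for t, _ in pairs)
    return EqtlCalls(pairs, traits, alpha)
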