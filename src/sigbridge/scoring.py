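"""Rank engine and undirected single-sample signature scores.

A sample's genes are ranked by count from 0 upward; tied counts share the
lowest rank of their block (competition / "min" ranking).  An undirected
gene-set score is the mean absolute deviation of the set's ranks from the
sample's median rank, normalised by the smallest and largest deviation means
achievable on an ideal tie-free rank grid, so that every score lies in
[0, 1]: 0 when the set sits at the centre of the ranking, 1 when it occupies
the extremes.  Because the score depends only on within-sample ranks it is
invariant to any per-sample monotone transform of the counts, which is what
makes it usable on a single sample and robust to normalisation choices.

Three ranking calibrations are provided for bridging a targeted panel to a
whole transcriptome:

``no_stable``
    plain within-sample ranks mapped to [0, 1] (on the whole transcriptome
    this is the ``all`` method; applied after subsetting to the
    panel/transcriptome overlap it is the ``part`` method);
``hk_genes`` / stable genes
    ranks stratified into levels by a set of designated stable genes
    (typically the panel's housekeeping probes);
``skewed``
    plain ranks remapped through a linear transform fitted between the
    panel's uniform rank scale and the rank positions the overlap genes
    occupy in the whole-transcriptome profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountMatrix, ScoreTable, SignatureCollection
from .io import restrict_signatures

__all__ = [
    "rank_genes",
    "relative_ranks",
    "rank_matrix",
    "singscore_undirected",
    "stable_gene_ranks",
    "SkewTransform",
    "fit_skew_transform",
    "apply_skew",
    "score_table",
]


def rank_genes(counts) -> np.ndarray:
    """Integer within-sample ranks, ascending from 0, ties sharing the
    lowest rank of their block.

    >>> rank_genes([5, 7, 7, 10])
    array([0, 1, 1, 3])
    """
    counts = np.asarray(counts)
    if counts.size < 2:
        raise ValueError("need at least 2 genes to rank")
    return rankdata(counts, method="min").astype(int) - 1


def relative_ranks(counts) -> np.ndarray:
    """Ranks mapped to [0, 1] by dividing by the maximum assigned rank.

    A fully tied sample has no usable ordering; every gene is put at 0.5
    with a warning.
    """
    r = rank_genes(counts)
    top = r.max()
    if top == 0:
        warnings.warn("all counts equal; relative ranks set to 0.5")
        return np.full(r.shape, 0.5)
    return r / top


def rank_matrix(matrix: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative ranks for every column of a count matrix.

    Returns a genes x samples frame of relative ranks with
    ``.attrs["method"] = "no_stable"``.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    vals = counts.to_numpy()
    ranks = rankdata(vals, method="min", axis=0).astype(float) - 1.0
    top = ranks.max(axis=0)
    flat = top == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} sample(s) fully tied; ranks set to 0.5")
        top = np.where(flat, 1.0, top)
    rel = ranks / top
    rel[:, flat] = 0.5
    out = pd.DataFrame(rel, index=counts.index, columns=counts.columns)
    out.attrs["method"] = "no_stable"
    return out


def _deviation_bounds(n_universe: int, set_size: int) -> tuple[float, float]:
    """Smallest and largest achievable mean |rank - centre| for ``set_size``
    distinct positions on the ideal tie-free grid 0..n-1, on the relative
    rank scale (divided by n - 1).

    The bounds are deliberately data independent: ties in an observed sample
    do not move them, which keeps scores comparable across samples.
    """
    n, m = n_universe, set_size
    if not 1 <= m <= n:
        raise ValueError("set size must be between 1 and the universe size")
    dev = np.abs(np.arange(n) - (n - 1) / 2.0)
    dev.sort()
    return dev[:m].mean() / (n - 1), dev[-m:].mean() / (n - 1)


def _normalise_raw(raw, lo: float, hi: float):
    """Normalised score; when the bounds coincide (set = universe, or a
    2-gene universe) every placement is equivalent and the score is 0.5."""
    if hi - lo <= 0:
        return np.full_like(np.asarray(raw, dtype=float), 0.5) \
            if np.ndim(raw) else 0.5
    return np.clip((np.asarray(raw, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def singscore_undirected(relranks: pd.Series, gene_set,
                         center: float | None = None) -> float:
    """Undirected score of ``gene_set`` within one sample's relative ranks.

    ``relranks`` indexes the whole ranked universe.  The raw statistic is
    the mean absolute deviation of the set's relative ranks from the
    sample's median relative rank (or ``center`` if supplied, as when ranks
    were produced by a calibration that defines its own centre); it is then
    normalised by the grid bounds of :func:`_deviation_bounds` and clipped
    to [0, 1].
    """
    gene_set = list(gene_set)
    missing = [g for g in gene_set if g not in relranks.index]
    if missing:
        raise KeyError(f"genes absent from ranked universe: {missing}")
    n = len(relranks)
    c = float(np.median(relranks.to_numpy())) if center is None else center
    raw = float(np.abs(relranks.loc[gene_set].to_numpy() - c).mean())
    lo, hi = _deviation_bounds(n, len(gene_set))
    return float(_normalise_raw(raw, lo, hi))


def stable_gene_ranks(counts: pd.Series, stable_genes) -> pd.Series:
    """Relative ranks stratified by a set of stable genes.

    With k stable genes the rank scale is cut into k + 1 levels.  A gene
    with count x sits at level ``L = #{stable genes with count < x}``; within
    its level it receives the fractional position
    ``f = (competition rank among level members + 0.5) / level size`` and
    the relative rank ``(L + f) / (k + 1)``, which always lies strictly
    inside (0, 1).  The stable genes themselves are level boundaries, not
    ranked members: they are excluded from the returned universe.
    """
    stable_genes = list(stable_genes)
    missing = [g for g in stable_genes if g not in counts.index]
    if missing:
        raise KeyError(f"stable genes absent from sample: {missing}")
    k = len(stable_genes)
    if k < 1:
        raise ValueError("need at least one stable gene")
    svals = np.sort(counts.loc[stable_genes].to_numpy())
    counts = counts.drop(index=stable_genes)
    x = counts.to_numpy()
    level = np.searchsorted(svals, x, side="left")  # strict '<' count
    rel = np.empty(len(x), dtype=float)
    for lev in np.unique(level):
        idx = np.flatnonzero(level == lev)
        within = rankdata(x[idx], method="min") - 1
        rel[idx] = (lev + (within + 0.5) / len(idx)) / (k + 1)
    out = pd.Series(rel, index=counts.index)
    return out


def stable_rank_matrix(matrix: CountMatrix | pd.DataFrame, stable_genes) -> pd.DataFrame:
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    cols = {s: stable_gene_ranks(counts[s], stable_genes) for s in counts.columns}
    out = pd.DataFrame(cols)
    out.attrs["method"] = "stable_genes"
    return out


@dataclass
class SkewTransform:
    """Orientation-preserving linear remap of relative ranks, r -> a + b*r.

    Fitted between uniform quantiles and the sorted median relative ranks a
    reference platform assigns to the shared genes; ``b > 0`` is required so
    gene order is preserved.
    """

    intercept: float
    slope: float
    r_squared: float = float("nan")
    n_genes: int = 0
    excluded_bottom: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("skew transform slope must be positive")


def fit_skew_transform(median_relranks, exclude_bottom: float = 0.0,
                       quantiles_as_response: bool = False) -> SkewTransform:
    """Fit the linear rank remap from a reference platform's median ranks.

    The m median relative ranks of the shared genes are sorted ascending and
    paired with uniform plotting positions ``x_i = (i - 0.5) / m``; ordinary
    least squares of the median ranks on the quantiles gives the transform.
    ``exclude_bottom`` drops that fraction of the lowest-expressed genes from
    the fit (the low tail is often the only non-linear region).
    ``quantiles_as_response`` flips the regression orientation.
    """
    y = np.sort(np.asarray(median_relranks, dtype=float))
    m = len(y)
    if m < 10:
        raise ValueError("need at least 10 genes to fit the skew transform")
    if np.ptp(y) == 0:
        raise ValueError("degenerate reference: all median ranks equal")
    x = (np.arange(1, m + 1) - 0.5) / m
    if exclude_bottom > 0:
        keep = int(np.ceil(m * exclude_bottom))
        x, y = x[keep:], y[keep:]
    if quantiles_as_response:
        x, y = y, x
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SkewTransform(float(intercept), float(slope), r2, len(y),
                         exclude_bottom)


def apply_skew(relranks: pd.DataFrame | pd.Series, t: SkewTransform):
    """Remap relative ranks through ``t``, clipping into [0, 1].

    The map is monotone, so gene order within every sample is unchanged;
    only the scale the scores are computed on moves.
    """
    out = (t.intercept + t.slope * relranks).clip(0.0, 1.0)
    if isinstance(out, pd.DataFrame):
        out.attrs["method"] = "skewed"
    return out


_METHODS = ("no_stable", "all", "part", "hk_genes", "skewed")


def score_table(matrix: CountMatrix | pd.DataFrame,
                signatures: SignatureCollection,
                method: str = "no_stable",
                stable_genes=None,
                skew: SkewTransform | None = None,
                overlap=None,
                platform: str = "") -> ScoreTable:
    """Score every signature in every sample under one ranking calibration.

    Parameters
    ----------
    matrix
        Count matrix (only endogenous probes are ranked when probe classes
        are annotated, except that the stable genes of ``hk_genes`` are kept).
    method
        ``no_stable``/``all`` rank the full universe; ``part`` first subsets
        the matrix to ``overlap``; ``hk_genes`` stratifies ranks by
        ``stable_genes``; ``skewed`` applies the fitted ``skew`` transform to
        plain ranks.
    Signatures not fully contained in the ranked universe are dropped and
    reported in the returned table's ``excluded`` mapping.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {_METHODS}")
    if isinstance(matrix, CountMatrix):
        counts = matrix.endogenous
        platform = platform or matrix.platform
        if method == "hk_genes" and matrix.code_class is not None:
            hk = matrix.genes_of_class("Housekeeping")
            keep = counts.index.union(pd.Index(hk), sort=False)
            counts = matrix.counts.loc[[g for g in matrix.genes if g in set(keep)]]
    else:
        counts = matrix

    if method == "part":
        if overlap is None:
            raise ValueError("method 'part' requires the overlap universe")
        overlap = [g for g in overlap if g in counts.index]
        counts = counts.loc[overlap]

    if method == "hk_genes":
        if stable_genes is None:
            raise ValueError("method 'hk_genes' requires stable_genes")
        rel = stable_rank_matrix(counts, stable_genes)
    else:
        rel = rank_matrix(counts)
        if method == "skewed":
            if skew is None:
                raise ValueError("method 'skewed' requires a fitted SkewTransform")
            rel = apply_skew(rel, skew)

    kept, excluded = restrict_signatures(signatures, rel.index)
    if len(kept) == 0:
        raise ValueError("no signature is fully contained in the ranked universe")

    vals = rel.to_numpy()
    if method == "skewed":
        # skewed ranks live on the whole-transcriptome relative-rank scale,
        # whose median over ~all genes is 0.5 by construction; the panel's
        # own median is displaced from it and that displacement is exactly
        # the signal the remap is meant to restore
        centers = np.full(vals.shape[1], 0.5)
    else:
        centers = np.median(vals, axis=0)
    n = vals.shape[0]
    pos = {g: i for i, g in enumerate(rel.index)}
    rows = {}
    for name, members in kept.items():
        idx = [pos[g] for g in members]
        raw = np.abs(vals[idx, :] - centers).mean(axis=0)
        lo, hi = _deviation_bounds(n, len(idx))
        rows[name] = _normalise_raw(raw, lo, hi)
    scores = pd.DataFrame(rows, index=rel.columns).T
    return ScoreTable(scores, platform=platform, method=method,
                      sizes=kept.sizes(), excluded=excluded)
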