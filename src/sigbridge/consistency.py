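"""Cross-platform gene-rank consistency and stable-gene screening.

For a pair of genes, the consistency score is the fraction of panel samples
whose within-sample rank order of the pair preserves a reference order; the
reference is each gene's median relative rank across the whole-transcriptome
samples.  A gene's consistency is the average of its pairwise scores over
all partners.  Genes with high average consistency and low rank dispersion
(MAD of relative ranks) are candidate stable genes for cross-platform rank
calibration.

Conventions: a within-sample rank tie between the two genes does NOT
preserve a strict reference order; a tie in the reference order makes the
pair unusable and it is skipped for both genes (recorded in the report).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

log = logging.getLogger(__name__)


@dataclass
class ConsistencyReport:
    """Per-gene cross-platform rank-consistency summary."""

    per_gene: pd.DataFrame  # avg_consistency, ns_median_rr, ns_mad, wts_median_rr, wts_mad
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)
    pairwise: pd.DataFrame | None = None

    def to_tsv(self, path) -> None:
        self.per_gene.rename_axis("gene").to_csv(path, sep="\t")


def reference_order(wts_relranks: pd.DataFrame, genes=None) -> pd.Series:
    """Per-gene median relative rank across the whole-transcriptome samples."""
    if genes is None:
        genes = list(wts_relranks.index)
    else:
        genes = list(genes)
        missing = [g for g in genes if g not in wts_relranks.index]
        if missing:
            raise KeyError(f"genes absent from rank matrix: {missing}")
    return wts_relranks.loc[genes].median(axis=1)


def pairwise_consistency(g: str, h: str, ns_relranks: pd.DataFrame,
                         reference: pd.Series) -> float:
    """Fraction of panel samples preserving the reference order of (g, h).

    Returns NaN when the reference order of the pair is tied (the pair
    carries no usable order information).  Symmetric in (g, h).
    """
    ref_sign = np.sign(reference[g] - reference[h])
    if ref_sign == 0:
        log.warning("reference order tied for pair (%s, %s); skipped", g, h)
        return float("nan")
    diff = ns_relranks.loc[g].to_numpy() - ns_relranks.loc[h].to_numpy()
    return float((np.sign(diff) == ref_sign).mean())


def genewise_consistency(genes, ns_relranks: pd.DataFrame,
                         reference: pd.Series,
                         wts_relranks: pd.DataFrame | None = None,
                         keep_pairwise: bool = False) -> ConsistencyReport:
    """Average pairwise order-preservation score per gene.

    All pairs (g, h) with an untied reference order contribute; a gene's
    score is the mean over its partners.  Relative-rank medians and MADs per
    platform are attached for the stable-candidate screen.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    R = ns_relranks.loc[genes].to_numpy(dtype=float)          # G x S
    ref = reference.loc[genes].to_numpy(dtype=float)
    ref_sign = np.sign(ref[:, None] - ref[None, :])            # G x G
    samp_sign = np.sign(R[:, None, :] - R[None, :, :])         # G x G x S
    preserved = (samp_sign == ref_sign[:, :, None]).mean(axis=2)
    usable = ref_sign != 0
    np.fill_diagonal(usable, False)
    pair = np.where(usable, preserved, np.nan)
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(pair, axis=1)
    skipped = [(genes[i], genes[j])
               for i, j in zip(*np.nonzero(~usable)) if i < j and i != j
               and ref_sign[i, j] == 0]
    per_gene = pd.DataFrame({
        "avg_consistency": avg,
        "ns_median_rr": np.median(R, axis=1),
        "ns_mad": median_abs_deviation(R, axis=1, scale=1.0),
    }, index=pd.Index(genes, name="gene"))
    per_gene["wts_median_rr"] = ref
    if wts_relranks is not None:
        W = wts_relranks.loc[genes].to_numpy(dtype=float)
        per_gene["wts_median_rr"] = np.median(W, axis=1)
        per_gene["wts_mad"] = median_abs_deviation(W, axis=1, scale=1.0)
    return ConsistencyReport(per_gene, skipped,
                             pd.DataFrame(pair, index=genes, columns=genes)
                             if keep_pairwise else None)


def stable_candidates(report: ConsistencyReport,
                      consistency_min: float = 0.7,
                      top_k_mad: int | None = 50) -> list[str]:
    """Genes usable as cross-platform rank anchors.

    Keeps genes whose average consistency exceeds ``consistency_min``
    (strictly); when ``top_k_mad`` is given, of those only the
    ``top_k_mad`` with the smallest panel-platform rank MAD are kept.
    """
    df = report.per_gene
    consistent = df.index[df["avg_consistency"] > consistency_min]
    if top_k_mad is not None:
        consistent = df.loc[consistent, "ns_mad"].nsmallest(top_k_mad).index
    out = sorted(consistent)
    if not out:
        log.warning("no stable candidates at consistency > %s", consistency_min)
    return out
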