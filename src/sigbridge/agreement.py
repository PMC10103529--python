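"""Agreement between platform score tables, per sample and per signature.

Four comparison pairs bridge a targeted panel ("NS") to the whole
transcriptome ("WTS"):

1. ``NS_to_WTS_HK``     — housekeeping-stratified ranks on both platforms;
2. ``NS_to_WTS_all``    — plain panel ranks vs full-transcriptome ranks;
3. ``NS_to_WTS_part``   — plain panel ranks vs ranks on the overlap genes;
4. ``NSskew_to_WTS_all``— skew-remapped panel ranks vs full-transcriptome.

Per-sample agreement regresses the panel scores on the transcriptome scores
across shared signatures (Spearman r plus an OLS fit); per-signature
agreement correlates the two platforms' scores across shared samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, ScoreTable, SignatureCollection
from .scoring import fit_skew_transform, rank_matrix, score_table

COMPARISON_PAIRS = ("NS_to_WTS_HK", "NS_to_WTS_all", "NS_to_WTS_part",
                    "NSskew_to_WTS_all")

_COLUMNS = ["spearman_r", "r_squared", "slope", "intercept", "n", "pair"]


def _scores(table) -> pd.DataFrame:
    return table.scores if isinstance(table, ScoreTable) else table


def _fit(y: np.ndarray, x: np.ndarray):
    """Spearman r plus an OLS fit of y on x."""
    r = stats.spearmanr(x, y).statistic
    if np.ptp(x) == 0:
        return r, np.nan, np.nan, np.nan
    res = stats.linregress(x, y)
    return r, res.rvalue ** 2, res.slope, res.intercept


def per_sample_agreement(ns_scores, wts_scores, pair: str = "",
                         wts_as_predictor: bool = True) -> pd.DataFrame:
    """Agreement of the two platforms' scores within each shared sample.

    For every sample present in both tables, fits panel score (response) on
    transcriptome score (predictor) across the shared signatures; set
    ``wts_as_predictor=False`` to flip the regression orientation.  Requires
    at least 3 shared signatures.
    """
    ns, wts = _scores(ns_scores), _scores(wts_scores)
    sigs = ns.index.intersection(wts.index)
    if len(sigs) < 3:
        raise ValueError(f"need >= 3 shared signatures, found {len(sigs)}")
    samples = ns.columns.intersection(wts.columns)
    if len(samples) == 0:
        raise ValueError("no shared samples")
    rows = []
    for s in samples:
        y, x = ns.loc[sigs, s].to_numpy(), wts.loc[sigs, s].to_numpy()
        if not wts_as_predictor:
            x, y = y, x
        r, r2, slope, intercept = _fit(y, x)
        rows.append((r, r2, slope, intercept, len(sigs), pair))
    return pd.DataFrame(rows, index=pd.Index(samples, name="sample"),
                        columns=_COLUMNS)


def per_signature_correlation(ns_scores, wts_scores, r_min: float = 0.8,
                              pair: str = ""):
    """Spearman r of each shared signature's scores across shared samples.

    Returns ``(records, high)`` where ``high`` lists the signatures with
    r >= ``r_min``.  A constant score vector has no defined correlation and
    is recorded as missing with a warning.
    """
    ns, wts = _scores(ns_scores), _scores(wts_scores)
    samples = ns.columns.intersection(wts.columns)
    if len(samples) < 3:
        raise ValueError(f"need >= 3 shared samples, found {len(samples)}")
    sigs = ns.index.intersection(wts.index)
    rows = []
    for sig in sigs:
        a = ns.loc[sig, samples].to_numpy()
        b = wts.loc[sig, samples].to_numpy()
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            warnings.warn(f"signature {sig!r}: constant scores, r undefined")
            rows.append((np.nan, np.nan, np.nan, np.nan, len(samples), pair))
            continue
        r, r2, slope, intercept = _fit(a, b)
        rows.append((r, r2, slope, intercept, len(samples), pair))
    records = pd.DataFrame(rows, index=pd.Index(sigs, name="signature"),
                           columns=_COLUMNS)
    high = list(records.index[records["spearman_r"] >= r_min])
    return records, high


def comparison_suite(panel_counts: CountMatrix, wts_counts: CountMatrix,
                     signatures: SignatureCollection, stable_genes,
                     overlap, r_min: float = 0.8,
                     skew_exclude_bottom: float = 0.0) -> dict:
    """Run all four comparison pairs end to end from count matrices.

    Scores the panel under its three calibrations and the transcriptome
    under ``all``/``part``/housekeeping ranks, then computes per-sample and
    per-signature agreement for each pair.  The skew transform is fitted
    from the transcriptome's median relative ranks of the overlap genes.
    Returns a dict with per-pair results and r/r-squared summary quartiles.
    """
    overlap = list(overlap)
    wts_rel = rank_matrix(wts_counts)
    skew = fit_skew_transform(wts_rel.loc[overlap].median(axis=1),
                              exclude_bottom=skew_exclude_bottom)

    ns_tables = {
        "hk": score_table(panel_counts, signatures, "hk_genes",
                          stable_genes=stable_genes),
        "no_stable": score_table(panel_counts, signatures, "no_stable"),
        "skewed": score_table(panel_counts, signatures, "skewed", skew=skew),
    }
    wts_tables = {
        "hk": score_table(wts_counts, signatures, "hk_genes",
                          stable_genes=stable_genes),
        "all": score_table(wts_counts, signatures, "all"),
        "part": score_table(wts_counts, signatures, "part", overlap=overlap),
    }
    pairing = {
        "NS_to_WTS_HK": ("hk", "hk"),
        "NS_to_WTS_all": ("no_stable", "all"),
        "NS_to_WTS_part": ("no_stable", "part"),
        "NSskew_to_WTS_all": ("skewed", "all"),
    }
    results: dict = {"pairs": {}, "skew": skew}
    summary = []
    for pair, (ns_key, wts_key) in pairing.items():
        psamp = per_sample_agreement(ns_tables[ns_key], wts_tables[wts_key],
                                     pair=pair)
        psig, high = per_signature_correlation(ns_tables[ns_key],
                                               wts_tables[wts_key],
                                               r_min=r_min, pair=pair)
        results["pairs"][pair] = {"per_sample": psamp, "per_signature": psig,
                                  "high_correlation": high}
        q = psamp[["spearman_r", "r_squared"]].quantile([0.25, 0.5, 0.75])
        summary.append(pd.Series(
            {"r_q1": q.loc[0.25, "spearman_r"], "r_median": q.loc[0.5, "spearman_r"],
             "r_q3": q.loc[0.75, "spearman_r"], "r2_q1": q.loc[0.25, "r_squared"],
             "r2_median": q.loc[0.5, "r_squared"], "r2_q3": q.loc[0.75, "r_squared"]},
            name=pair))
    results["summary"] = pd.DataFrame(summary)
    results["score_tables"] = {"ns": ns_tables, "wts": wts_tables}
    return results
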