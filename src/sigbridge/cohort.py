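"""Response-group differential testing and cohort contingency statistics.

Signature scores are compared between responders and non-responders (or
between biopsy-site groups) with the two-sided Mann-Whitney rank-sum test,
adjusted across signatures by Benjamini-Hochberg.  Responder status follows
the RECIST-derived rule: complete or partial response, or stable disease
lasting more than 6 months without progression, counts as responder;
progressive disease or stable disease of at most 6 months does not.

The module also ships the published clinical-characteristics contingency
tables of the melanoma checkpoint-inhibitor cohort whose structure the
synthetic generator emulates, so the cohort-level association tests can be
reproduced without access to the restricted patient-level data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ScoreTable

log = logging.getLogger(__name__)

#: Treatment x response counts (rows: anti-PD-1 + anti-CTLA-4 combination,
#: anti-PD-1 monotherapy; columns: responder, non-responder) from the
#: reference cohort's clinical characteristics table.
REFERENCE_TREATMENT_TABLE = np.array([[47, 27], [43, 41]])

#: Biopsy-site x response counts from the same table (rows in the order
#: brain, liver, lung, lymph node, mucosa, primary, small bowel,
#: subcutaneous, other).
REFERENCE_BIOPSY_TABLE = np.array([
    [9, 6], [2, 0], [4, 3], [21, 23], [0, 2],
    [5, 1], [2, 1], [41, 32], [6, 0],
])

RESPONDER_CATEGORIES = ("CR", "PR")
SD_RESPONDER_MONTHS = 6.0  # SD must exceed this to count as response

TOP_TIER_ADJ_P = 2e-4
TOP_TIER_DELTA = 0.1


def derive_response(recist: pd.Series, sd_duration_months: pd.Series | None = None
                    ) -> pd.Series:
    """Binary response labels from RECIST categories.

    CR/PR are responders; SD is a responder only when its duration exceeds
    6 months (an SD of exactly 6 months is a non-responder); PD is a
    non-responder.  SD rows must carry a duration.
    """
    out = {}
    for idx, cat in recist.items():
        if cat in RESPONDER_CATEGORIES:
            out[idx] = "R"
        elif cat == "PD":
            out[idx] = "NR"
        elif cat == "SD":
            if sd_duration_months is None or pd.isna(sd_duration_months.get(idx)):
                raise ValueError(f"SD without duration for {idx!r}")
            out[idx] = "R" if sd_duration_months[idx] > SD_RESPONDER_MONTHS else "NR"
        else:
            raise ValueError(f"unknown RECIST category {cat!r} for {idx!r}")
    return pd.Series(out, name="response")


def _mwu(x: np.ndarray, y: np.ndarray):
    """Two-sided Mann-Whitney test; exact when combined n <= 25 without
    ties, tie-corrected normal approximation otherwise."""
    pooled = np.concatenate([x, y])
    exact = len(pooled) <= 25 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def dedupe_patients(samples: pd.Index, patient_ids: pd.Series) -> list[str]:
    """One sample per patient: the first sample id in sorted order."""
    chosen: dict[str, str] = {}
    for s in sorted(samples):
        p = patient_ids[s]
        chosen.setdefault(p, s)
    return [s for s in samples if s in set(chosen.values())]


def mannwhitney_bh(scores, groups: pd.Series, fdr: float = 0.05,
                   patient_ids: pd.Series | None = None,
                   positive_group: str | None = None) -> pd.DataFrame:
    """Per-signature two-group rank-sum test with BH adjustment.

    ``groups`` maps sample id to one of exactly two labels (e.g. R/NR or
    lymph-node vs other biopsy site).  When ``patient_ids`` is given,
    repeated samples are reduced to one per patient first.  The returned
    frame carries group medians, the median difference (first group minus
    second), U, raw and adjusted p, and a significance tier: ``top`` when
    adj p <= 2e-4 and \\|delta median\\| >= 0.1, else ``fdr05`` when
    adj p <= ``fdr``, else ``ns``.
    """
    table = scores.scores if isinstance(scores, ScoreTable) else scores
    samples = table.columns.intersection(groups.index)
    if patient_ids is not None:
        samples = pd.Index(dedupe_patients(samples, patient_ids))
    g = groups.loc[samples]
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, found {levels}")
    if positive_group is not None:
        if positive_group not in levels:
            raise ValueError(f"{positive_group!r} not among groups {levels}")
        levels = [positive_group] + [l for l in levels if l != positive_group]
    a_samples = samples[(g == levels[0]).to_numpy()]
    b_samples = samples[(g == levels[1]).to_numpy()]
    if len(a_samples) == 0 or len(b_samples) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for sig in table.index:
        x = table.loc[sig, a_samples].to_numpy(dtype=float)
        y = table.loc[sig, b_samples].to_numpy(dtype=float)
        u, p = _mwu(x, y)
        med_a, med_b = float(np.median(x)), float(np.median(y))
        rows.append((sig, med_a, med_b, med_a - med_b, u, p))
    out = pd.DataFrame(rows, columns=["signature", f"median_{levels[0]}",
                                      f"median_{levels[1]}", "delta_median",
                                      "U", "p"]).set_index("signature")
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    tier = np.where(
        (out["p_adj"] <= TOP_TIER_ADJ_P)
        & (out["delta_median"].abs() >= TOP_TIER_DELTA), "top",
        np.where(out["p_adj"] <= fdr, "fdr05", "ns"))
    out["tier"] = tier
    return out


def contingency_test(table, correction: str = "yates"):
    """Pearson chi-squared test of an r x c contingency table.

    ``correction="yates"`` applies the continuity correction (2x2 tables
    only); ``"none"`` is the plain Pearson statistic.  Expected counts below
    5 produce a logged warning, not an error.  Returns (chi2, df, p).
    """
    table = np.asarray(table, dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("table must hold non-negative integer counts")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("zero row/column margin")
    if correction == "yates" and table.shape != (2, 2):
        raise ValueError("Yates correction applies to 2x2 tables only")
    if correction not in ("yates", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    chi2, p, df, expected = stats.chi2_contingency(
        table, correction=(correction == "yates"))
    if (expected < 5).any():
        log.warning("%d cell(s) with expected count < 5",
                    int((expected < 5).sum()))
    return float(chi2), int(df), float(p)


def reference_cohort_statistics() -> dict[str, float]:
    """Association tests and response rates on the shipped reference
    clinical-characteristics tables."""
    _, _, p_treat = contingency_test(REFERENCE_TREATMENT_TABLE, "yates")
    _, _, p_site = contingency_test(REFERENCE_BIOPSY_TABLE, "none")
    combo_r, combo_nr = REFERENCE_TREATMENT_TABLE[0]
    mono_r, mono_nr = REFERENCE_TREATMENT_TABLE[1]
    return {
        "treatment_response_p": p_treat,
        "biopsy_site_response_p": p_site,
        "combination_response_rate_pct": 100.0 * combo_r / (combo_r + combo_nr),
        "monotherapy_response_rate_pct": 100.0 * mono_r / (mono_r + mono_nr),
    }
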