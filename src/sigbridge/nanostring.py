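"""Emulation of the documented nCounter QC / normalisation chain.

The chain, in order: background thresholding, positive-control scaling,
housekeeping-gene (%CV) screening, content normalisation against the
retained housekeeping genes, and per-gene panel-standard calibration across
cartridges.  Scaling factors are geometric-mean based; the two sample flags
(`mRNA_positive_norm_flag`, `mRNA_content_norm_flag`) mark samples whose
factors fall outside the configured bounds.

This is an emulation of the vendor's proprietary pipeline, not a
reproduction.  For the rank-based scores downstream it matters little:
every step here is a per-sample positive rescaling, which leaves
within-sample gene ranks untouched except for the ties created by
background flooring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix

log = logging.getLogger(__name__)

POSITIVE_FLAG = "mRNA_positive_norm_flag"
CONTENT_FLAG = "mRNA_content_norm_flag"

DEFAULT_BACKGROUND = 20
DEFAULT_FLAG_RATIO = 10.0
POSITIVE_FACTOR_BOUNDS = (0.3, 3.0)  # vendor-style default band


@dataclass
class NormalisationResult:
    """Normalised counts plus the per-sample factors and flags produced."""

    normalised: pd.DataFrame
    positive_factors: pd.Series | None = None
    content_factors: pd.Series | None = None
    flags: dict[str, set[str]] = field(default_factory=dict)
    excluded_hkgs: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def flagged_samples(self) -> list[str]:
        return sorted(s for s, f in self.flags.items() if f)

    def drop_flagged(self) -> pd.DataFrame:
        keep = [s for s in self.normalised.columns
                if not self.flags.get(s)]
        return self.normalised[keep]


def _geomean(values: np.ndarray, axis=0) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if (values <= 0).any():
        raise ValueError("geometric mean undefined for non-positive counts")
    return np.exp(np.log(values).mean(axis=axis))


def background_threshold(counts: pd.DataFrame, floor: float = DEFAULT_BACKGROUND
                         ) -> pd.DataFrame:
    """Raise every count below ``floor`` to ``floor`` (creating ties there)."""
    if floor < 0:
        raise ValueError("background floor must be non-negative")
    return counts.clip(lower=floor)


def positive_control_scale(counts: pd.DataFrame, positive_probes
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each sample so its positive-control geometric mean matches the
    cohort's arithmetic mean of those geometric means.

    Returns the scaled counts and the per-sample factors.
    """
    positive_probes = list(positive_probes)
    missing = [p for p in positive_probes if p not in counts.index]
    if missing:
        raise KeyError(f"positive probes absent: {missing}")
    sub = counts.loc[positive_probes].to_numpy(dtype=float)
    if (sub <= 0).any(axis=0).any():
        bad = counts.columns[(sub <= 0).any(axis=0)]
        raise ValueError(f"zero positive-control geometric mean in sample(s) "
                         f"{list(bad)}")
    geo = _geomean(sub, axis=0)
    factors = pd.Series(geo.mean() / geo, index=counts.columns)
    return counts.mul(factors, axis=1), factors


def hkg_screen(counts: pd.DataFrame, hkgs, drop=None,
               cv_sd_limit: float = 2.0) -> tuple[list[str], pd.Series]:
    """Screen housekeeping genes by percent coefficient of variation.

    An HKG is excluded when its %CV across samples exceeds
    ``mean + cv_sd_limit * SD`` of the HKG %CVs, or when it is on the
    explicit ``drop`` list.  Returns the retained genes and all %CV values.
    """
    hkgs = list(hkgs)
    if len(hkgs) < 2:
        raise ValueError("need at least 2 housekeeping genes to screen")
    missing = [g for g in hkgs if g not in counts.index]
    if missing:
        raise KeyError(f"housekeeping genes absent: {missing}")
    sub = counts.loc[hkgs].to_numpy(dtype=float)
    cv = pd.Series(100.0 * sub.std(axis=1, ddof=1) / sub.mean(axis=1), index=hkgs)
    cutoff = cv.mean() + cv_sd_limit * cv.std(ddof=1)
    drop = set(drop or [])
    retained = [g for g in hkgs
                if g not in drop and not (cv.std(ddof=1) > 0 and cv[g] > cutoff)]
    if not retained:
        raise ValueError("all housekeeping genes excluded by the %CV screen")
    for g in hkgs:
        if g not in retained:
            log.info("housekeeping gene %s excluded (%%CV %.2f)", g, cv[g])
    return retained, cv


def content_normalise(counts: pd.DataFrame, retained_hkgs,
                      flag_ratio: float = DEFAULT_FLAG_RATIO
                      ) -> tuple[pd.DataFrame, pd.Series, set[str]]:
    """Content normalisation against the retained housekeeping genes.

    The per-sample factor is (cohort mean of HKG geometric means) / (sample
    HKG geometric mean).  Samples with factor >= ``flag_ratio`` (overall low
    expression) are flagged.  Returns scaled counts, factors and the flagged
    sample set.
    """
    retained_hkgs = list(retained_hkgs)
    if not retained_hkgs:
        raise ValueError("no housekeeping genes retained")
    sub = counts.loc[retained_hkgs].to_numpy(dtype=float)
    if (sub <= 0).any(axis=0).any():
        bad = counts.columns[(sub <= 0).any(axis=0)]
        raise ValueError(f"sample(s) with non-positive housekeeping counts: "
                         f"{list(bad)}")
    geo = _geomean(sub, axis=0)
    factors = pd.Series(geo.mean() / geo, index=counts.columns)
    flagged = set(factors.index[factors >= flag_ratio])
    return counts.mul(factors, axis=1), factors, flagged


def panel_standard_calibrate(matrices_by_cartridge: dict[str, pd.DataFrame],
                             standard_sample_id: str,
                             reference_cartridge: str | None = None,
                             background: float = DEFAULT_BACKGROUND
                             ) -> pd.DataFrame:
    """Per-gene cross-cartridge calibration against a shared standard sample.

    For gene g in cartridge c the factor is
    ``reference standard count(g) / max(cartridge standard count(g),
    background)``; all counts in cartridge c are multiplied by it.  The
    standard samples themselves are removed from the output.  Applying the
    calibration twice is a no-op because calibrated standards match the
    reference exactly.
    """
    if reference_cartridge is None:
        reference_cartridge = next(iter(matrices_by_cartridge))
    for cart, mat in matrices_by_cartridge.items():
        if standard_sample_id not in mat.columns:
            raise ValueError(f"cartridge {cart!r} is missing the panel "
                             f"standard {standard_sample_id!r}")
    ref_std = matrices_by_cartridge[reference_cartridge][standard_sample_id]
    ref_std = ref_std.clip(lower=background)
    pieces = []
    for cart, mat in matrices_by_cartridge.items():
        std = mat[standard_sample_id]
        floored = std.clip(lower=background)
        if (std < background).any():
            log.warning("cartridge %s: %d standard counts at/below background; "
                        "factors use the floor", cart, int((std < background).sum()))
        factors = ref_std / floored
        out = mat.drop(columns=[standard_sample_id]).mul(factors, axis=0)
        pieces.append(out)
    return pd.concat(pieces, axis=1)


def normalise(matrix: CountMatrix,
              background: float = DEFAULT_BACKGROUND,
              flag_ratio: float = DEFAULT_FLAG_RATIO,
              hkg_drop=None,
              positive_bounds=POSITIVE_FACTOR_BOUNDS) -> NormalisationResult:
    """Run the full chain on an annotated panel matrix.

    Requires Positive and Housekeeping probe classes on the matrix.  The
    result keeps the per-sample factors and the two normalisation flags;
    cartridge calibration is separate (:func:`panel_standard_calibrate`)
    because it needs per-cartridge matrices.
    """
    pos = matrix.genes_of_class("Positive")
    hkg = matrix.genes_of_class("Housekeeping")
    if not pos or not hkg:
        raise ValueError("matrix must annotate Positive and Housekeeping probes")
    counts = background_threshold(matrix.counts.astype(float), background)
    counts, pos_factors = positive_control_scale(counts, pos)
    retained, cv = hkg_screen(counts, hkg, drop=hkg_drop)
    counts, content_factors, low_expr = content_normalise(counts, retained,
                                                          flag_ratio)
    flags: dict[str, set[str]] = {s: set() for s in counts.columns}
    lo, hi = positive_bounds
    for s in counts.columns:
        if not lo <= pos_factors[s] <= hi:
            flags[s].add(POSITIVE_FLAG)
        if s in low_expr:
            flags[s].add(CONTENT_FLAG)
    excluded = cv[[g for g in cv.index if g not in retained]]
    return NormalisationResult(counts, pos_factors, content_factors, flags,
                               excluded)
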