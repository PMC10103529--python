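"""Synthetic paired-platform cohort with known ground truth.

Every sample has one latent log-expression profile that both platforms
observe: a whole transcriptome, and a targeted panel whose endogenous
probes are drawn preferentially from the mid/high end of the baseline
expression distribution (so panel genes concentrate at median-and-above
whole-transcriptome ranks, the skew a linear rank remap has to correct).
Responder samples carry up- or down-shifts on designated signature gene
sets.  Each platform adds its own library-size factor, per-batch gene
offsets, per-gene probe-efficiency offsets and overdispersed (negative
binomial) counting noise.  The panel's housekeeping probes have high
baseline and low biological variance, but their probe-efficiency offsets
are large and their sequencing-side quantification carries extra
per-sample noise, so their cross-platform rank order is deliberately
imperfect — the realistic failure mode of housekeeping-based rank
calibration.  Samples additionally differ in immune content (tumour
purity), which shifts every panel-targeted gene jointly: invisible inside
the panel's own rank universe, but moving the panel genes against the
background genes of the whole transcriptome sample by sample.

The generator is fully deterministic given its seed, and the injected
truth (signature genes, effect sizes, realized panel rank bias) is
returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, SignatureCollection

BIOPSY_SITES = {"subcutaneous": 0.46, "lymph_node": 0.28, "brain": 0.10,
                "lung": 0.04, "primary": 0.04, "liver": 0.01, "mucosa": 0.01,
                "small_bowel": 0.02, "other": 0.04}
TREATMENTS = {"IPI+PD1": 0.47, "PD1": 0.53}

# positive-control geometric ladder (counts at full library size) and the
# flat negative-control mean, loosely modelled on panel spike-in design
POSITIVE_LADDER = (12800.0, 3200.0, 800.0, 200.0, 50.0, 12.5)
NEGATIVE_MEAN = 2.0


class ConfigurationError(ValueError):
    """Cohort configuration violates its own invariants."""


@dataclass(frozen=True)
class SignatureSpec:
    """One injected signature: name, size, responder effect (latent
    log-units), direction of the shift in responders, and the expression
    band its genes are drawn around (baseline percentile of the
    transcriptome; None draws a band at random per signature)."""

    name: str
    n_genes: int
    effect: float = 0.0
    direction: str = "up"
    pct_center: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ConfigurationError(f"direction must be up/down, got "
                                     f"{self.direction!r}")
        if self.n_genes < 1:
            raise ConfigurationError("signature needs at least 1 gene")


def default_signature_specs() -> list[SignatureSpec]:
    """An 18-gene and a 3-gene responder-up signature (the sizes of the
    classic tumour-inflammation and checkpoint-axis sets), a 10-gene
    responder-down set, and a 10-gene null set."""
    return [
        SignatureSpec("inflammation_18", 18, 0.25, "up", 0.45),
        SignatureSpec("checkpoint_3", 3, 0.25, "up", 0.45),
        SignatureSpec("stromal_10", 10, 0.25, "down", 0.45),
        SignatureSpec("null_10", 10, 0.0, "up"),
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the stated synthetic world.

    Effects are in latent log-units; ``biological_sd`` is the per-gene
    latent standard deviation, so the default 0.25 effect is a 0.5-SD
    shift.  ``panel_rank_bias`` is the logistic weight pulling panel
    membership toward high-baseline genes (0 = unbiased).
    """

    n_patients: int = 120
    responder_fraction: float = 0.55
    n_wts_genes: int = 2000
    n_panel_genes: int = 150
    n_hkg: int = 20
    n_pos_controls: int = 6
    n_neg_controls: int = 8
    panel_rank_bias: float = 6.0
    signature_specs: tuple[SignatureSpec, ...] = field(
        default_factory=lambda: tuple(default_signature_specs()))
    batch_count: int = 4
    batch_sd: float = 0.05
    repeat_patients: int = 0
    dispersion: float = 100.0
    signature_pct_sd: float = 0.08
    biological_sd: float = 0.5
    hkg_biological_sd: float = 0.05
    program_sd: float = 0.15
    global_program_sd: float = 0.25
    immune_axis_sd: float = 0.3
    platform_effect_sd: float = 0.1
    hkg_platform_sd: float = 2.5
    hkg_technical_sd: float = 0.4
    library_sd: float = 0.2
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.responder_fraction < 1:
            raise ConfigurationError("responder_fraction must lie in (0, 1)")
        if self.n_panel_genes + self.n_hkg > self.n_wts_genes:
            raise ConfigurationError("panel plus housekeeping genes exceed "
                                     "the transcriptome size")
        need = sum(s.n_genes for s in self.signature_specs)
        if need > self.n_panel_genes:
            raise ConfigurationError(
                f"signatures need {need} distinct genes but the endogenous "
                f"panel holds only {self.n_panel_genes}")
        for name, val in [("panel_rank_bias", self.panel_rank_bias),
                          ("batch_sd", self.batch_sd),
                          ("dispersion", self.dispersion)]:
            if val < 0 or (name == "dispersion" and val == 0):
                raise ConfigurationError(f"{name} must be positive")
        if self.repeat_patients > self.n_patients:
            raise ConfigurationError("more repeat patients than patients")


@dataclass
class PairedCohort:
    """Paired panel / whole-transcriptome observation of one cohort."""

    wts_counts: CountMatrix
    panel_counts: CountMatrix
    metadata: pd.DataFrame
    signatures: SignatureCollection
    truth: dict
    latent: pd.DataFrame  # genes x samples ground-truth log expression
    config: CohortConfig | None = None


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_cohort(config: CohortConfig) -> PairedCohort:
    """Generate one paired cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, S = config.n_wts_genes, config.n_patients

    genes = pd.Index([f"G{i:05d}" for i in range(G)])
    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, G)
    pct = (np.argsort(np.argsort(baseline)) + 0.5) / G  # baseline percentile

    # housekeeping probes: drawn from the top quartile of baseline
    top = np.flatnonzero(pct > 0.75)
    hkg_idx = rng.choice(top, size=config.n_hkg, replace=False)
    # endogenous panel membership: logistic weighting on baseline percentile
    rest = np.setdiff1d(np.arange(G), hkg_idx)
    w = 1.0 / (1.0 + np.exp(-config.panel_rank_bias * (pct[rest] - 0.5)))
    panel_idx = rng.choice(rest, size=config.n_panel_genes, replace=False,
                           p=w / w.sum())
    hkg_genes = list(genes[np.sort(hkg_idx)])
    panel_genes = list(genes[np.sort(panel_idx)])

    # signatures drawn disjointly from the endogenous panel (both platforms
    # can therefore score them).  Each signature's genes cluster in one
    # expression band of the transcriptome, the way curated gene programs
    # do; bands vary between signatures.  Band placement matters for an
    # undirected score, which folds deviations around the rank centre: a
    # set straddling a platform's centre carries no coherent signal on that
    # platform.  Response-linked sets default to the mid band, where the
    # rank-biased panel universe sees them clearly (below its centre).
    panel_pct = pd.Series(pct[np.sort(panel_idx)], index=panel_genes)
    signatures = SignatureCollection()
    truth_sigs = {}
    available = pd.Series(True, index=panel_genes)
    for spec in config.signature_specs:
        center = spec.pct_center
        if center is None:
            center = rng.uniform(0.65, 0.9)
        w = np.exp(-0.5 * ((panel_pct[available].to_numpy() - center)
                           / config.signature_pct_sd) ** 2) + 1e-9
        pool = available.index[available.to_numpy()]
        members = list(rng.choice(pool, size=spec.n_genes, replace=False,
                                  p=w / w.sum()))
        available[members] = False
        signatures.add(spec.name, members,
                       f"synthetic {spec.direction}-in-responders, "
                       f"effect {spec.effect}, band {center:.2f}")
        truth_sigs[spec.name] = {"genes": members, "effect": spec.effect,
                                 "direction": spec.direction,
                                 "pct_center": float(center)}

    # sample metadata
    sample_ids = [f"S{i:03d}" for i in range(S)]
    patient_ids = [f"P{i:03d}" for i in range(S)]
    n_resp = int(round(S * config.responder_fraction))
    response = np.array(["R"] * n_resp + ["NR"] * (S - n_resp))
    rng.shuffle(response)
    treatment = rng.choice(list(TREATMENTS), size=S,
                           p=list(TREATMENTS.values()))
    site = rng.choice(list(BIOPSY_SITES), size=S,
                      p=list(BIOPSY_SITES.values()))
    batch = rng.integers(0, config.batch_count, size=S)
    metadata = pd.DataFrame({
        "sample_id": sample_ids, "patient_id": patient_ids,
        "response": response, "treatment": treatment, "biopsy_site": site,
        "batch": [f"B{b}" for b in batch], "is_repeat": False,
    }).set_index("sample_id", drop=False)

    # latent log expression shared by both platforms
    bio_sd = np.full(G, config.biological_sd)
    bio_sd[hkg_idx] = config.hkg_biological_sd
    latent = baseline[:, None] + rng.normal(0.0, 1.0, (G, S)) * bio_sd[:, None]
    is_resp = response == "R"
    gene_pos = {g: i for i, g in enumerate(genes)}
    # tumour purity / immune content: every endogenous panel gene (the
    # immune compartment the panel targets) shifts jointly per sample.
    # Inside the panel universe a joint shift is rank-invariant, but in the
    # whole transcriptome it moves the panel genes against the background
    # genes sample by sample — the distortion a single global rank remap
    # cannot follow.
    immune_axis = rng.normal(0.0, config.immune_axis_sd, S)
    latent[np.sort(panel_idx), :] += immune_axis[None, :]

    # a shared per-sample activity axis (think overall immune infiltration)
    # loads on every signature with a signature-specific weight: it is what
    # makes signature scores co-vary within a cohort, on any platform
    global_activity = rng.normal(0.0, config.global_program_sd, S)
    for spec in config.signature_specs:
        rows = [gene_pos[g] for g in truth_sigs[spec.name]["genes"]]
        # each signature is a transcriptional program: its genes share a
        # per-sample activity level on top of the independent gene noise
        loading = rng.uniform(0.3, 1.0)
        activity = rng.normal(0.0, config.program_sd, S) \
            + loading * global_activity
        latent[rows, :] += activity[None, :]
        truth_sigs[spec.name]["global_loading"] = float(loading)
        if spec.effect:
            shift = spec.effect if spec.direction == "up" else -spec.effect
            latent[np.ix_(rows, np.flatnonzero(is_resp))] += shift
    latent_df = pd.DataFrame(latent, index=genes, columns=sample_ids)

    def observe(latent_mat: np.ndarray, row_genes: pd.Index,
                platform_rng: np.random.Generator) -> np.ndarray:
        lib = platform_rng.normal(0.0, config.library_sd, S)
        batch_fx = platform_rng.normal(0.0, config.batch_sd,
                                       (len(row_genes), config.batch_count))
        mu = np.exp(latent_mat + batch_fx[:, batch] + lib[None, :])
        return _nb_counts(platform_rng, mu, config.dispersion)

    wts_rng = np.random.default_rng(rng.integers(2 ** 31))
    panel_rng = np.random.default_rng(rng.integers(2 ** 31))

    # housekeeping quantification on the sequencing side carries extra
    # per-sample noise (their rank among neighbours is not stable from
    # sample to sample), so rank calibration anchored on them inherits a
    # jittering level grid
    wts_latent = latent.copy()
    wts_latent[hkg_idx, :] += wts_rng.normal(0.0, config.hkg_technical_sd,
                                             (config.n_hkg, S))
    wts_counts = observe(wts_latent, genes, wts_rng)
    wts = CountMatrix(pd.DataFrame(wts_counts, index=genes,
                                   columns=sample_ids).astype(int),
                      pd.Series("Endogenous", index=genes), "wts")

    # panel platform: per-gene probe-efficiency offsets shift each gene's
    # level relative to the transcriptome.  Housekeeping probes get larger
    # offsets, which scrambles their cross-platform rank order relative to
    # the endogenous genes and degrades housekeeping-based rank calibration
    # (the realistic failure mode of that strategy).
    panel_rows = panel_genes + hkg_genes
    efficiency = np.concatenate([
        rng.normal(0.0, config.platform_effect_sd, len(panel_genes)),
        rng.normal(0.0, config.hkg_platform_sd, len(hkg_genes)),
    ])
    panel_latent = latent_df.loc[panel_rows].to_numpy() + efficiency[:, None]
    panel_obs = observe(panel_latent, pd.Index(panel_rows), panel_rng)

    pos_names = [f"POS_{chr(65 + i)}" for i in range(config.n_pos_controls)]
    neg_names = [f"NEG_{chr(65 + i)}" for i in range(config.n_neg_controls)]
    lib = np.exp(panel_rng.normal(0.0, config.library_sd, S))
    pos_means = np.array(POSITIVE_LADDER * ((config.n_pos_controls //
                                             len(POSITIVE_LADDER)) + 1))
    pos_counts = panel_rng.poisson(pos_means[:config.n_pos_controls, None]
                                   * lib[None, :])
    neg_counts = panel_rng.poisson(np.full((config.n_neg_controls, S),
                                           NEGATIVE_MEAN) * lib[None, :])
    all_rows = panel_rows + pos_names + neg_names
    panel_full = np.vstack([panel_obs, pos_counts, neg_counts])
    classes = pd.Series(["Endogenous"] * len(panel_genes)
                        + ["Housekeeping"] * len(hkg_genes)
                        + ["Positive"] * len(pos_names)
                        + ["Negative"] * len(neg_names), index=all_rows)
    panel = CountMatrix(pd.DataFrame(panel_full, index=all_rows,
                                     columns=sample_ids).astype(int),
                        classes, "panel")

    truth = {
        "signatures": truth_sigs,
        "panel_rank_bias": config.panel_rank_bias,
        "panel_median_baseline_pct": float(np.median(pct[panel_idx])),
        "panel_efficiency_offsets": dict(zip(panel_rows, efficiency.tolist())),
        "hkg_genes": hkg_genes,
        "overlap_genes": panel_genes + hkg_genes,
    }
    cohort = PairedCohort(wts, panel, metadata, signatures, truth,
                          latent_df, config)
    if config.repeat_patients:
        cohort = make_repeats(cohort, config.repeat_patients, noise_sd=0.1,
                              seed=int(rng.integers(2 ** 31)))
    return cohort


def make_repeats(cohort: PairedCohort, n_repeats: int, noise_sd: float,
                 seed: int = 0, reassign_batch: bool = False) -> PairedCohort:
    """Append re-observed samples for the first ``n_repeats`` patients.

    A repeat reuses the patient's observed counts with fresh multiplicative
    technical noise (log-normal, sd ``noise_sd``); with ``noise_sd = 0`` and
    the original batch a repeat is byte-identical to its source.  Repeats
    are flagged in the metadata.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    originals = cohort.metadata[~cohort.metadata["is_repeat"]]
    if n_repeats > originals["patient_id"].nunique():
        raise ValueError("more repeats requested than patients available")
    if n_repeats == 0:
        return cohort
    rng = np.random.default_rng(seed)
    chosen = sorted(originals["patient_id"].unique())[:n_repeats]
    wts = cohort.wts_counts.counts.copy()
    panel = cohort.panel_counts.counts.copy()
    meta = cohort.metadata.copy()
    latent = cohort.latent.copy()
    batches = sorted(meta["batch"].unique())
    for pid in chosen:
        src = originals[originals["patient_id"] == pid].index[0]
        rep_id = f"{src}_rep"
        for mat in (wts, panel):
            noise = np.exp(rng.normal(0.0, noise_sd, mat.shape[0])) \
                if noise_sd > 0 else np.ones(mat.shape[0])
            mat[rep_id] = np.rint(mat[src].to_numpy() * noise).astype(int)
        row = meta.loc[src].copy()
        row["sample_id"] = rep_id
        row["is_repeat"] = True
        if reassign_batch:
            row["batch"] = batches[int(rng.integers(len(batches)))]
        meta.loc[rep_id] = row
        latent[rep_id] = latent[src]
    wts_m = CountMatrix(wts, cohort.wts_counts.code_class.reindex(wts.index)
                        if cohort.wts_counts.code_class is not None else None,
                        "wts")
    panel_m = CountMatrix(panel, cohort.panel_counts.code_class, "panel")
    return PairedCohort(wts_m, panel_m, meta, cohort.signatures,
                        dict(cohort.truth), latent, cohort.config)


def null_config(n_signatures: int = 200, genes_per_signature: int = 3,
                **overrides) -> CohortConfig:
    """A zero-effect configuration with many disjoint signatures, used for
    type-I-error calibration of the downstream differential test."""
    specs = tuple(SignatureSpec(f"null_{i:03d}", genes_per_signature, 0.0)
                  for i in range(n_signatures))
    base = dict(n_panel_genes=max(700, n_signatures * genes_per_signature),
                signature_specs=specs)
    base.update(overrides)
    return CohortConfig(**base)
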