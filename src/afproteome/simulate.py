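"""Synthetic cohort generator with planted ground truth.

Emulates the design of the cross-sectional amniotic-fluid study: two
gestational-age groups (15 midtrimester samples at 16.4-24.0 weeks, 13 term
samples at 37.0-41.0 weeks), ~1310 aptamer analytes plus hybridization
controls, a fraction of analytes with true group effects on the log2 scale,
per-analyte variances with a scaled-inverse-chi-square spread, correlated
latent-factor modules, tissue-signature group shifts, per-sample
hybridization scale factors, dilution bins, and plate batches.

Every planted quantity is recorded in a :class:`SimTruth` so each analysis
stage can be tested for recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    GROUP_MIDTRIMESTER,
    GROUP_TERM,
    AbundanceMatrix,
    AnalyteAnnotation,
    SampleMetadata,
    ValidationError,
)

#: The fold-change calling threshold the generator guarantees planted
#: effects to exceed: |log2 FC| >= log2(1.5) for every differential analyte.
MIN_CALL_LOG2FC = float(np.log2(1.5))


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the study conditions."""

    n_mid: int = 15
    n_term: int = 13
    n_analytes: int = 1310
    n_controls: int = 12

    # true group effects: |log2FC| = effect_min_log2fc + Exponential(tail)
    de_fraction: float = 0.25
    effect_min_log2fc: float = MIN_CALL_LOG2FC
    effect_tail_scale: float = 0.7

    # per-analyte noise variance s^2 ~ s0^2 * d0 / chi2(d0)
    variance_d0: float = 4.0
    variance_s0_sq: float = 0.09

    # correlated modules via latent factors with sign-coherent loadings
    n_modules: int = 3
    module_sizes: tuple[int, ...] | None = None
    module_loading_range: tuple[float, float] = (0.4, 0.9)
    # weight in [0, 1] tying module factors to standardized gestational age
    module_ga_weight: float = 0.0

    # tissue signatures: genes per tissue and term-group shift in noise-SD units
    n_tissues: int = 6
    signature_size: int = 10
    tissue_shifts: tuple[float, ...] | None = None

    # covariate effects
    sex_effect_sd: float = 0.2
    sex_effect_fraction: float = 0.1
    age_slope_sd: float = 0.02
    age_slope_fraction: float = 0.1
    bmi_slope_sd: float = 0.0
    bmi_slope_fraction: float = 0.1

    # technical scale factors (log-normal, natural-log sd)
    hyb_log_sd: float = 0.1
    plate_log_sd: float = 0.05
    n_plates: int = 2

    baseline_mean: float = 10.0
    baseline_sd: float = 1.5
    ga_mid_range: tuple[float, float] = (16.4, 24.0)
    ga_term_range: tuple[float, float] = (37.0, 41.0)

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mid", "n_term", "n_analytes", "n_plates"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValidationError("de_fraction must be in [0, 1]")
        if self.variance_d0 <= 0 or self.variance_s0_sq <= 0:
            raise ValidationError("variance prior (d0, s0^2) must be positive")
        if self.de_fraction > 0 and self.effect_min_log2fc < MIN_CALL_LOG2FC - 1e-12:
            raise ValidationError(
                "effect_min_log2fc below log2(1.5): planted effects would not "
                "exceed the fold-change calling threshold"
            )
        if not 0.0 <= self.module_ga_weight <= 1.0:
            raise ValidationError("module_ga_weight must be in [0, 1]")
        sizes = self.resolved_module_sizes()
        n_tissue_analytes = self.n_tissues * self.signature_size
        if sum(sizes) + n_tissue_analytes + self.n_de > self.n_analytes:
            raise ValidationError(
                "module sizes + tissue signatures + differential analytes "
                "exceed n_analytes"
            )

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_analytes))

    def resolved_module_sizes(self) -> tuple[int, ...]:
        """Module sizes; the default scales the study's 131/121/154 split."""
        if self.n_modules == 0:
            return ()
        if self.module_sizes is None:
            base = (131, 121, 154)
            scale = self.n_analytes / 1310
            if self.n_modules <= len(base):
                return tuple(max(10, round(b * scale)) for b in base[: self.n_modules])
            return tuple(
                max(10, round(0.1 * self.n_analytes)) for _ in range(self.n_modules)
            )
        if len(self.module_sizes) != self.n_modules:
            raise ValidationError("module_sizes length must equal n_modules")
        return tuple(self.module_sizes)

    def resolved_tissue_shifts(self) -> tuple[float, ...]:
        """Per-tissue term-group shift; default plants +1 and -1 SD shifts."""
        if self.n_tissues == 0:
            return ()
        if self.tissue_shifts is not None:
            if len(self.tissue_shifts) != self.n_tissues:
                raise ValidationError("tissue_shifts length must equal n_tissues")
            return tuple(self.tissue_shifts)
        shifts = [0.0] * self.n_tissues
        shifts[0] = 1.0
        if self.n_tissues > 1:
            shifts[1] = -1.0
        return tuple(shifts)

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SimTruth:
    """Planted ground truth for one simulated cohort.

    ``analytes`` records, per analyte, the true group effect (term minus
    midtrimester, log2), the differential flag, module membership and
    loading, tissue membership, noise SD, and covariate effects.
    ``log2_signal`` is the complete biological log2 signal (baseline +
    effects + factors + noise) before any technical scaling, so that
    inverting the hybridization/plate factors recovers it exactly.
    """

    analytes: pd.DataFrame
    samples: pd.DataFrame
    plate_factors: pd.DataFrame
    reference: pd.Series
    log2_signal: pd.DataFrame
    module_factors: pd.DataFrame
    tissue_shifts: dict[str, float]
    tissue_genes: dict[str, list[str]]
    calibrators: pd.DataFrame
    config: SimConfig

    @property
    def de_analytes(self) -> list[str]:
        return list(self.analytes.index[self.analytes["is_de"]])


def _sample_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_mid + cfg.n_term
    ids = [f"S{i + 1:03d}" for i in range(n)]
    group = [GROUP_MIDTRIMESTER] * cfg.n_mid + [GROUP_TERM] * cfg.n_term
    ga = np.concatenate(
        [
            rng.uniform(*cfg.ga_mid_range, size=cfg.n_mid),
            rng.uniform(*cfg.ga_term_range, size=cfg.n_term),
        ]
    ).round(1)
    sex = rng.choice(["F", "M"], size=n)
    age = np.clip(rng.normal(27.0, 6.0, size=n), 16, 45).round(1)
    bmi = np.clip(rng.normal(30.0, 5.0, size=n), 18, 50).round(1)
    plates = [f"P{(i % cfg.n_plates) + 1}" for i in range(n)]
    hyb = np.exp(rng.normal(0.0, cfg.hyb_log_sd, size=n))
    return pd.DataFrame(
        {
            "group": group,
            "gestational_age_weeks": ga,
            "fetal_sex": sex,
            "maternal_age_years": age,
            "bmi_kg_m2": bmi,
            "plate_id": plates,
            "hyb_factor": hyb,
        },
        index=pd.Index(ids, name="sample_id"),
    )


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[AbundanceMatrix, SampleMetadata, AnalyteAnnotation, SimTruth]:
    """Generate a raw abundance matrix, metadata, annotation, and truth.

    The biological log2 signal for sample *s* and analyte *a* is::

        baseline_a + effect_a * I(term) + tissue_shift + covariate effects
                   + loading_a * factor_{module(a), s} + noise(0, sd_a)

    with ``sd_a^2`` drawn from ``s0^2 * d0 / chi2(d0)``.  Raw RFU values are
    ``2 ** signal`` scaled by the per-sample hybridization factor and the
    per-plate x analyte calibration factor.  Hybridization control analytes
    carry no group effect, no noise, and no plate factor, so their planted
    factors are exactly estimable.  Differential, module, and tissue analyte
    sets are disjoint so each recovery test has an unambiguous truth.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = _sample_table(cfg, rng)
    n_samples = len(samples)

    assay_ids = [f"A{i + 1:05d}" for i in range(cfg.n_analytes)]
    control_ids = [f"CTRL{i + 1:02d}" for i in range(cfg.n_controls)]
    analyte_ids = assay_ids + control_ids
    genes = {aid: f"G{i + 1:05d}" for i, aid in enumerate(assay_ids)}

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_analytes)
    noise_sd = np.sqrt(
        cfg.variance_s0_sq
        * cfg.variance_d0
        / rng.chisquare(cfg.variance_d0, size=cfg.n_analytes)
    )

    # disjoint allocation: tissues, then modules, then differential analytes
    order = rng.permutation(cfg.n_analytes)
    cursor = 0
    tissue_id = np.array([""] * cfg.n_analytes, dtype=object)
    tissue_genes: dict[str, list[str]] = {}
    shifts = cfg.resolved_tissue_shifts()
    for t in range(cfg.n_tissues):
        name = f"tissue_{t + 1}"
        members = order[cursor : cursor + cfg.signature_size]
        cursor += cfg.signature_size
        tissue_id[members] = name
        tissue_genes[name] = sorted(genes[assay_ids[i]] for i in members)
    tissue_shifts = {f"tissue_{t + 1}": shifts[t] for t in range(cfg.n_tissues)}

    module_id = np.zeros(cfg.n_analytes, dtype=int)
    loading = np.zeros(cfg.n_analytes)
    sizes = cfg.resolved_module_sizes()
    lo, hi = cfg.module_loading_range
    for m, size in enumerate(sizes, start=1):
        members = order[cursor : cursor + size]
        cursor += size
        module_id[members] = m
        loading[members] = rng.uniform(lo, hi, size=size)

    is_de = np.zeros(cfg.n_analytes, dtype=bool)
    de_members = order[cursor : cursor + cfg.n_de]
    cursor += cfg.n_de
    is_de[de_members] = True
    true_lfc = np.zeros(cfg.n_analytes)
    magnitudes = cfg.effect_min_log2fc + rng.exponential(
        cfg.effect_tail_scale, size=cfg.n_de
    )
    signs = rng.choice([-1.0, 1.0], size=cfg.n_de)
    true_lfc[de_members] = signs * magnitudes

    sex_eff = np.zeros(cfg.n_analytes)
    age_slope = np.zeros(cfg.n_analytes)
    bmi_slope = np.zeros(cfg.n_analytes)
    eligible = np.where(tissue_id == "")[0]
    for arr, sd, frac in (
        (sex_eff, cfg.sex_effect_sd, cfg.sex_effect_fraction),
        (age_slope, cfg.age_slope_sd, cfg.age_slope_fraction),
        (bmi_slope, cfg.bmi_slope_sd, cfg.bmi_slope_fraction),
    ):
        if sd > 0 and frac > 0:
            k = int(round(frac * cfg.n_analytes))
            chosen = rng.choice(eligible, size=min(k, len(eligible)), replace=False)
            arr[chosen] = rng.normal(0.0, sd, size=len(chosen))

    # latent module factors, optionally tied to standardized gestational age
    ga = samples["gestational_age_weeks"].to_numpy(float)
    ga_z = (ga - ga.mean()) / ga.std(ddof=0)
    factors = np.empty((n_samples, len(sizes)))
    w = cfg.module_ga_weight
    for m in range(len(sizes)):
        noise = rng.normal(0.0, 1.0, size=n_samples)
        orient = -1.0 if m % 2 else 1.0
        factors[:, m] = orient * (w * ga_z + np.sqrt(1.0 - w**2) * noise)

    is_term = (samples["group"] == GROUP_TERM).to_numpy(float)
    is_male = (samples["fetal_sex"] == "M").to_numpy(float)
    age_c = samples["maternal_age_years"].to_numpy(float) - 28.0
    bmi_c = samples["bmi_kg_m2"].to_numpy(float) - 30.0

    shift_per_analyte = np.array(
        [tissue_shifts[t] if t else 0.0 for t in tissue_id], dtype=float
    )
    group_effect = true_lfc + shift_per_analyte * noise_sd

    signal = (
        baseline[None, :]
        + np.outer(is_term, group_effect)
        + np.outer(is_male, sex_eff)
        + np.outer(age_c, age_slope)
        + np.outer(bmi_c, bmi_slope)
    )
    for m in range(len(sizes)):
        members = module_id == m + 1
        signal[:, members] += np.outer(factors[:, m], loading[members])
    noise = rng.normal(0.0, 1.0, size=signal.shape) * noise_sd[None, :]
    signal = signal + noise

    plate_names = sorted(samples["plate_id"].unique())
    plate_factors = pd.DataFrame(
        np.exp(
            rng.normal(0.0, cfg.plate_log_sd, size=(len(plate_names), cfg.n_analytes))
        ),
        index=pd.Index(plate_names, name="plate_id"),
        columns=assay_ids,
    )
    for cid in control_ids:
        plate_factors[cid] = 1.0

    control_ref = 2.0 ** rng.uniform(8.0, 12.0, size=cfg.n_controls)
    control_signal = np.tile(np.log2(control_ref), (n_samples, 1))
    full_signal = np.concatenate([signal, control_signal], axis=1)

    hyb = samples["hyb_factor"].to_numpy(float)
    plate_of_sample = plate_factors.loc[
        samples["plate_id"].to_numpy(), analyte_ids
    ].to_numpy(float)
    raw = (2.0**full_signal) * hyb[:, None] * plate_of_sample

    matrix = AbundanceMatrix(
        pd.DataFrame(raw, index=samples.index, columns=analyte_ids), scale="raw"
    )

    annotation = AnalyteAnnotation(
        pd.DataFrame(
            {
                "gene_symbols": [
                    (genes[a],) if a in genes else () for a in analyte_ids
                ],
                "protein_name": [f"Protein {a}" for a in analyte_ids],
                "dilution_bin": pd.array(
                    list(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2], size=cfg.n_analytes))
                    + [pd.NA] * cfg.n_controls,
                    dtype="Int64",
                ),
                "is_control": [False] * cfg.n_analytes + [True] * cfg.n_controls,
            },
            index=pd.Index(analyte_ids, name="analyte_id"),
        )
    )

    reference = pd.Series(
        np.concatenate([2.0**baseline, control_ref]),
        index=analyte_ids,
        name="reference",
    )
    # calibrator wells: plate-scaled readings of the reference profile
    calibrators = plate_factors.mul(reference, axis=1)

    truth = SimTruth(
        analytes=pd.DataFrame(
            {
                "gene": [genes.get(a, "") for a in analyte_ids],
                "true_log2fc": np.concatenate([true_lfc, np.zeros(cfg.n_controls)]),
                "group_effect_total": np.concatenate(
                    [group_effect, np.zeros(cfg.n_controls)]
                ),
                "is_de": np.concatenate(
                    [is_de, np.zeros(cfg.n_controls, dtype=bool)]
                ),
                "module_id": np.concatenate(
                    [module_id, np.zeros(cfg.n_controls, dtype=int)]
                ),
                "module_loading": np.concatenate(
                    [loading, np.zeros(cfg.n_controls)]
                ),
                "tissue_id": list(tissue_id) + [""] * cfg.n_controls,
                "noise_sd": np.concatenate([noise_sd, np.zeros(cfg.n_controls)]),
                "sex_effect": np.concatenate([sex_eff, np.zeros(cfg.n_controls)]),
                "age_slope": np.concatenate([age_slope, np.zeros(cfg.n_controls)]),
                "bmi_slope": np.concatenate([bmi_slope, np.zeros(cfg.n_controls)]),
                "is_control": [False] * cfg.n_analytes + [True] * cfg.n_controls,
            },
            index=pd.Index(analyte_ids, name="analyte_id"),
        ),
        samples=samples,
        plate_factors=plate_factors,
        reference=reference,
        log2_signal=pd.DataFrame(
            full_signal, index=samples.index, columns=analyte_ids
        ),
        module_factors=pd.DataFrame(
            factors,
            index=samples.index,
            columns=[f"module_{m + 1}" for m in range(len(sizes))],
        ),
        tissue_shifts=tissue_shifts,
        tissue_genes=tissue_genes,
        calibrators=calibrators,
        config=cfg,
    )

    metadata = SampleMetadata(
        samples[
            [
                "group",
                "gestational_age_weeks",
                "fetal_sex",
                "maternal_age_years",
                "bmi_kg_m2",
                "plate_id",
            ]
        ].copy(),
        strict=True,
    )
    return matrix, metadata, annotation, truth


def simulate_tissue_atlas(
    cfg: SimConfig, truth: SimTruth, seed: int | None = None
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Build a gene x tissue median-expression atlas with planted signatures.

    Planted signature genes get an expression in their tissue at least the
    30x specificity ratio above the median of the other tissues; all other
    genes stay well below it.  Fifty off-panel genes are included so that
    panel intersection is exercised.  Returns the atlas and the planted
    gene lists per tissue.
    """
    if cfg.n_tissues < 2:
        raise ValidationError("need at least 2 tissues to define specificity")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    panel_genes = [g for g in truth.analytes["gene"] if g]
    extra = [f"X{i + 1:04d}" for i in range(50)]
    genes = panel_genes + extra
    tissues = list(truth.tissue_genes)
    atlas = pd.DataFrame(
        rng.uniform(5.0, 15.0, size=(len(genes), len(tissues))),
        index=pd.Index(genes, name="gene"),
        columns=tissues,
    )
    planted: dict[str, list[str]] = {}
    for tissue, members in truth.tissue_genes.items():
        if len(members) > len(genes):
            raise ValidationError("signature size exceeds available genes")
        for g in members:
            others = [t for t in tissues if t != tissue]
            atlas.loc[g, others] = rng.uniform(2.0, 8.0, size=len(others))
            med = float(np.median(atlas.loc[g, others]))
            atlas.loc[g, tissue] = med * 30.0 * rng.uniform(1.5, 4.0)
        planted[tissue] = sorted(members)
    return atlas, planted


def simulate_prior_study(
    truth: SimTruth,
    corr_target: float,
    sig_fraction: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Construct an external differential table with controlled concordance.

    The prior study's log2 fold change for each differential analyte's gene
    is a ``corr_target``-weighted mixture of the planted effect (scaled to
    unit variance, not centred, so signs are preserved) and independent
    standard-normal noise.  Significance flags are Bernoulli(sig_fraction).
    """
    if not -1.0 <= corr_target <= 1.0:
        raise ValidationError("corr_target must be in [-1, 1]")
    de = truth.analytes[truth.analytes["is_de"]]
    if de.empty:
        raise ValidationError("truth contains no differential analytes")
    rng = np.random.default_rng(seed)
    x = de["true_log2fc"].to_numpy(float)
    scaled = x / x.std(ddof=0)
    noise = rng.normal(0.0, 1.0, size=len(x))
    prior = corr_target * scaled + np.sqrt(1.0 - corr_target**2) * noise
    return pd.DataFrame(
        {
            "log2_fc": prior,
            "significant": rng.random(len(x)) < sig_fraction,
            "study": "synthetic_prior",
        },
        index=pd.Index(de["gene"].to_numpy(), name="gene"),
    )


def simulate_gene_sets(
    truth: SimTruth,
    seed: int | None = None,
    n_random: int = 20,
    n_enriched: int = 3,
    set_size: tuple[int, int] = (15, 60),
) -> dict[str, dict]:
    """Build a GMT-style gene-set collection over the panel genes.

    ``n_enriched`` sets draw 80% of their members from differential
    analytes' genes (so over-representation among called genes is real),
    ``n_random`` sets draw uniformly from the panel, and each planted
    tissue signature contributes one set.
    """
    rng = np.random.default_rng(truth.config.seed + 2 if seed is None else seed)
    genes = np.array([g for g in truth.analytes["gene"] if g])
    de_genes = np.array(
        [g for g, d in zip(truth.analytes["gene"], truth.analytes["is_de"]) if d and g]
    )
    sets: dict[str, dict] = {}
    for i in range(n_enriched):
        size = int(rng.integers(*set_size))
        n_de = min(int(round(0.8 * size)), len(de_genes))
        members = np.concatenate(
            [
                rng.choice(de_genes, size=n_de, replace=False),
                rng.choice(genes, size=size - n_de, replace=False),
            ]
        )
        sets[f"SET:DE{i + 1:02d}"] = {
            "term_name": f"planted differential set {i + 1}",
            "genes": sorted(set(members)),
        }
    for i in range(n_random):
        size = int(rng.integers(*set_size))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"SET:RND{i + 1:02d}"] = {
            "term_name": f"random set {i + 1}",
            "genes": sorted(set(members)),
        }
    for tissue, members in truth.tissue_genes.items():
        sets[f"SET:{tissue.upper()}"] = {
            "term_name": f"planted {tissue} signature",
            "genes": sorted(members),
        }
    return sets


def write_fixture_dir(outdir, cfg: SimConfig, prior_corr: float = 0.6) -> "SimTruth":
    """Write a complete synthetic fixture directory (all TSV/GMT inputs).

    Emits the raw abundance matrix, metadata, annotation, normalization
    references (control reference, calibrator reference, calibrator
    wells), tissue atlas, gene sets, a synthetic prior-study table, and
    the planted truth tables.  Returns the truth object.
    """
    from . import io as _io

    _io.ensure_dir(outdir)
    matrix, metadata, annotation, truth = simulate_cohort(cfg)
    atlas, _ = simulate_tissue_atlas(cfg, truth)
    prior = simulate_prior_study(truth, corr_target=prior_corr, seed=cfg.seed + 3)
    gene_sets = simulate_gene_sets(truth)
    _io.write_abundance_matrix(matrix, f"{outdir}/abundance_raw.tsv")
    _io.write_sample_metadata(metadata, f"{outdir}/metadata.tsv")
    _io.write_analyte_annotation(annotation, f"{outdir}/annotation.tsv")
    _io.write_table(atlas, f"{outdir}/tissue_atlas.tsv", index_label="gene")
    _io.write_gene_sets(gene_sets, f"{outdir}/gene_sets.gmt")
    _io.write_table(prior, f"{outdir}/prior_study.tsv", index_label="gene")
    _io.write_table(
        truth.reference.to_frame(), f"{outdir}/reference.tsv", index_label="analyte_id"
    )
    _io.write_table(
        truth.calibrators, f"{outdir}/calibrators.tsv", index_label="plate_id"
    )
    _io.write_table(
        truth.analytes, f"{outdir}/truth_analytes.tsv", index_label="analyte_id"
    )
    _io.write_table(
        truth.samples, f"{outdir}/truth_samples.tsv", index_label="sample_id"
    )
    return truth
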