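"""Shared domain containers for the amniotic-fluid proteome pipeline.

All stages exchange three lightweight objects built on pandas: an
:class:`AbundanceMatrix` (samples x analytes, raw RFU or log2 RFU), a
:class:`SampleMetadata` table of clinical covariates, and an
:class:`AnalyteAnnotation` table mapping aptamer reagents to gene symbols,
dilution bins, and control status.  The internal orientation convention is
samples in rows throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RAW = "raw"
LOG2 = "log2"

GROUP_MIDTRIMESTER = "midtrimester"
GROUP_TERM = "term"

#: Printed gestational-age ranges (weeks) used by strict metadata validation.
GA_RANGES = {GROUP_MIDTRIMESTER: (16.0, 24.0), GROUP_TERM: (37.0, 42.0)}


class ValidationError(ValueError):
    """Raised when an input object violates a container invariant."""


def _check_unique(ids: Sequence, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dupes}")


@dataclass
class AbundanceMatrix:
    """Sample x analyte abundance matrix with a raw/log2 scale flag.

    Parameters
    ----------
    data
        DataFrame with samples in rows and analytes in columns.  Values are
        relative fluorescence units (``scale='raw'``) or log2 RFU
        (``scale='log2'``).
    scale
        Either ``'raw'`` or ``'log2'``.  Raw values must be strictly
        positive; all values must be finite.
    """

    data: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG2):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "analyte ids")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("abundance matrix contains non-numeric cells")
        if values.size and not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                "non-finite value at sample "
                f"{self.data.index[bad[0]]!r}, analyte {self.data.columns[bad[1]]!r}"
            )
        if self.scale == RAW and values.size and values.min() <= 0:
            bad = np.argwhere(values <= 0)[0]
            raise ValidationError(
                "nonpositive raw value at sample "
                f"{self.data.index[bad[0]]!r}, analyte {self.data.columns[bad[1]]!r}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def analyte_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.data.shape[1]

    def with_values(self, values, scale: str | None = None) -> "AbundanceMatrix":
        """Return a new matrix with the same ids and new values/scale."""
        df = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=self.data.index,
            columns=self.data.columns,
        )
        return AbundanceMatrix(df, scale=self.scale if scale is None else scale)

    def subset(self, samples=None, analytes=None) -> "AbundanceMatrix":
        df = self.data
        if samples is not None:
            df = df.loc[list(samples)]
        if analytes is not None:
            df = df.loc[:, list(analytes)]
        return AbundanceMatrix(df.copy(), scale=self.scale)


REQUIRED_METADATA_COLUMNS = (
    "group",
    "gestational_age_weeks",
    "fetal_sex",
    "maternal_age_years",
)
OPTIONAL_METADATA_COLUMNS = ("bmi_kg_m2", "plate_id")


@dataclass
class SampleMetadata:
    """Per-sample clinical covariates.

    ``table`` is indexed by sample id and carries at least the columns in
    :data:`REQUIRED_METADATA_COLUMNS`.  ``strict`` validation additionally
    enforces the study's gestational-age windows (16-24 weeks for the
    midtrimester group, 37-42 weeks at term).
    """

    table: pd.DataFrame
    strict: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        groups = set(self.table["group"].unique())
        unknown = groups - {GROUP_MIDTRIMESTER, GROUP_TERM}
        if unknown:
            raise ValidationError(f"unknown group labels: {sorted(unknown)}")
        sexes = set(self.table["fetal_sex"].dropna().unique())
        if not sexes <= {"F", "M"}:
            raise ValidationError(f"fetal_sex must be F/M, got {sorted(sexes)}")
        if self.strict:
            for grp, (lo, hi) in GA_RANGES.items():
                ga = self.table.loc[self.table["group"] == grp, "gestational_age_weeks"]
                bad = ga[(ga < lo) | (ga > hi)]
                if len(bad):
                    raise ValidationError(
                        f"{grp} gestational ages outside [{lo}, {hi}]: "
                        f"{bad.to_dict()}"
                    )

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    def group_samples(self, group: str) -> list:
        return list(self.table.index[self.table["group"] == group])

    def subset(self, samples: Iterable) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(samples)].copy(), strict=False)


@dataclass
class AnalyteAnnotation:
    """Analyte id -> gene symbols, protein name, dilution bin, control flag.

    One aptamer may target a multi-subunit protein and therefore map to
    several gene symbols ("CGA LHB"); the ordered symbol list is preserved.
    Symbols are upper-cased so downstream matching is case-insensitive.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "analyte ids")
        missing = [
            c
            for c in ("gene_symbols", "protein_name", "dilution_bin", "is_control")
            if c not in self.table.columns
        ]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        self.table = self.table.copy()
        self.table["gene_symbols"] = self.table["gene_symbols"].apply(
            _normalise_symbols
        )
        noncontrol = self.table.loc[~self.table["is_control"].astype(bool)]
        if noncontrol["dilution_bin"].isna().any():
            bad = noncontrol.index[noncontrol["dilution_bin"].isna()].tolist()[:5]
            raise ValidationError(
                f"dilution_bin missing for non-control analytes: {bad}"
            )

    @property
    def analyte_ids(self) -> list:
        return list(self.table.index)

    @property
    def control_ids(self) -> list:
        return list(self.table.index[self.table["is_control"].astype(bool)])

    @property
    def assay_ids(self) -> list:
        """Analytes that are not hybridization controls."""
        return list(self.table.index[~self.table["is_control"].astype(bool)])

    def dilution_bins(self) -> pd.Series:
        """Dilution-bin label per non-control analyte."""
        return self.table.loc[self.assay_ids, "dilution_bin"]

    def genes_for(self, analyte_ids: Iterable) -> set[str]:
        """Union of gene symbols mapped by the given analytes."""
        genes: set[str] = set()
        for aid in analyte_ids:
            genes.update(self.table.at[aid, "gene_symbols"])
        return genes


def _normalise_symbols(symbols) -> tuple[str, ...]:
    if symbols is None or (isinstance(symbols, float) and np.isnan(symbols)):
        return ()
    if isinstance(symbols, str):
        symbols = symbols.split()
    out, seen = [], set()
    for s in symbols:
        s = str(s).upper()
        if s and s not in seen:
            seen.add(s)
            out.append(s)
    return tuple(out)


@dataclass
class Config:
    """Fixed analysis constants.

    Defaults mirror the study's stated choices: a 1.5-fold minimum change
    with q < 0.1 for differential abundance, a signed network at soft power
    beta = 22, hypergeometric enrichment at q < 0.05 with at least three
    hits per term, a 30x tissue-specificity ratio with top-20 signatures,
    and q < 0.05 for tissue-score comparisons.
    """

    fc_min: float = 1.5
    q_de: float = 0.1
    q_enrich: float = 0.05
    q_tissue: float = 0.05
    network_power: float = 22.0
    specificity_ratio: float = 30.0
    signature_top_n: int = 20
    min_term_hits: int = 3
    min_module_size: int = 20
    module_merge_corr: float = 0.85
    cut_height: float = 0.995
    loess_span: float = 0.75
    rng_seed: int = 0
    strict_metadata: bool = False
    covariates: tuple[str, ...] = ("fetal_sex", "maternal_age_years")
    midtrimester_boundary: float = 21.05

    def __post_init__(self) -> None:
        positive = (
            "fc_min",
            "q_de",
            "q_enrich",
            "q_tissue",
            "specificity_ratio",
            "loess_span",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.network_power < 1:
            raise ValidationError("network_power must be >= 1")
        if self.signature_top_n < 1:
            raise ValidationError("signature_top_n must be >= 1")

    def replace(self, **kwargs) -> "Config":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        kwargs = dict(d)
        if "covariates" in kwargs and kwargs["covariates"] is not None:
            kwargs["covariates"] = tuple(kwargs["covariates"])
        return cls(**kwargs)
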