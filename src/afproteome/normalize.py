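"""Median-ratio emulation of the SOMAscan three-step standardization.

The platform standardizes raw fluorescence in three steps — hybridization
normalization per sample against spiked control reagents, median
normalization across samples within dilution bins, and plate calibration
against calibrator wells — followed by a log2 transform.  The vendor
chain is proprietary; this module implements a transparent median-ratio
version of each step with the same intent.  Factors always multiply
observed values toward the reference (factor = reference / observed).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import LOG2, RAW, AbundanceMatrix, ValidationError

logger = logging.getLogger(__name__)


def _require_raw(matrix: AbundanceMatrix, op: str) -> None:
    if matrix.scale != RAW:
        raise ValidationError(f"{op} requires a raw-scale matrix")


def hybridization_normalize(
    matrix: AbundanceMatrix,
    control_ids,
    reference: pd.Series,
) -> tuple[AbundanceMatrix, pd.Series]:
    """Correct per-sample hybridization variation using control analytes.

    For each sample the factor is the median over controls of
    (reference level / observed level); every analyte in the sample is
    multiplied by it.  Afterwards each sample's median control ratio is 1.
    """
    _require_raw(matrix, "hybridization normalization")
    control_ids = list(control_ids)
    if not control_ids:
        raise ValidationError("hybridization normalization needs >= 1 control")
    missing = [c for c in control_ids if c not in matrix.data.columns]
    if missing:
        raise ValidationError(f"control analytes absent from matrix: {missing[:5]}")
    ref = reference.reindex(control_ids)
    if ref.isna().any() or (ref <= 0).any():
        raise ValidationError("control reference levels must be positive")
    observed = matrix.data[control_ids]
    if (observed.to_numpy() <= 0).any():
        raise ValidationError("zero/negative control value")
    factors = (ref / observed).median(axis=1)
    factors.name = "hyb_factor"
    out = matrix.with_values(matrix.values * factors.to_numpy()[:, None])
    return out, factors


def median_normalize(
    matrix: AbundanceMatrix,
    dilution_bins: pd.Series,
    within_bins: bool = True,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Remove residual per-sample biases by median-ratio scaling.

    Within each dilution bin (or globally with ``within_bins=False``) the
    factor for a sample is the median over the bin's analytes of
    (analyte's across-sample median / analyte's value in this sample).
    Returns the scaled matrix and a sample x bin factor table.
    """
    _require_raw(matrix, "median normalization")
    analytes = [a for a in matrix.data.columns if a in dilution_bins.index]
    missing = [a for a in matrix.data.columns if a not in dilution_bins.index]
    if missing:
        logger.warning(
            "median normalization: %d analytes without a dilution bin left "
            "unscaled (e.g. %s)",
            len(missing),
            missing[:3],
        )
    bins = dilution_bins.loc[analytes]
    if not within_bins:
        bins = pd.Series("all", index=bins.index)
    values = matrix.data.copy()
    factor_cols = {}
    for bin_label, members in bins.groupby(bins).groups.items():
        members = list(members)
        if not members:
            raise ValidationError(f"dilution bin {bin_label!r} has no analytes")
        block = values[members]
        ratios = block.median(axis=0) / block
        factors = ratios.median(axis=1)
        values[members] = block.mul(factors, axis=0)
        factor_cols[bin_label] = factors
    factor_table = pd.DataFrame(factor_cols)
    factor_table.columns.name = "dilution_bin"
    return AbundanceMatrix(values, scale=RAW), factor_table


def plate_calibrate(
    matrix: AbundanceMatrix,
    plate_ids: pd.Series,
    reference: pd.Series,
    calibrators: pd.DataFrame | None = None,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Adjust plate-to-plate variation against a per-analyte reference.

    The factor for (plate, analyte) is reference / calibrator level, where
    the calibrator level is the plate's calibrator-well reading when
    ``calibrators`` (plate x analyte) is supplied, and otherwise the median
    of the analyte over the plate's own samples.  The factor is applied to
    every sample on the plate.
    """
    _require_raw(matrix, "plate calibration")
    plate_ids = plate_ids.reindex(matrix.data.index)
    if plate_ids.isna().any():
        bad = plate_ids.index[plate_ids.isna()].tolist()[:5]
        raise ValidationError(f"samples without a plate assignment: {bad}")
    ref = reference.reindex(matrix.data.columns)
    if ref.isna().any() or (ref <= 0).any():
        raise ValidationError("calibration reference must be positive for every analyte")
    rows = {}
    for plate, samples in plate_ids.groupby(plate_ids).groups.items():
        samples = list(samples)
        if not samples:
            raise ValidationError(f"plate {plate!r} has no samples")
        if calibrators is not None and plate in calibrators.index:
            level = calibrators.loc[plate].reindex(matrix.data.columns)
        else:
            level = matrix.data.loc[samples].median(axis=0)
        if (level <= 0).any() or level.isna().any():
            raise ValidationError(f"nonpositive calibrator level on plate {plate!r}")
        rows[plate] = ref / level
    factors = pd.DataFrame(rows).T
    factors.index.name = "plate_id"
    scaled = matrix.data * factors.loc[plate_ids.to_numpy()].to_numpy()
    return AbundanceMatrix(scaled, scale=RAW), factors


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log2; flips the scale flag."""
    if matrix.scale == LOG2:
        raise ValidationError("matrix is already log2-scaled")
    values = matrix.values
    if (values <= 0).any():
        raise ValidationError("log2 transform requires strictly positive values")
    return matrix.with_values(np.log2(values), scale=LOG2)


def normalize_chain(
    matrix: AbundanceMatrix,
    annotation,
    control_reference: pd.Series | None = None,
    calibrator_reference: pd.Series | None = None,
    plate_ids: pd.Series | None = None,
    calibrators: pd.DataFrame | None = None,
    steps: tuple[str, ...] = ("hyb", "median", "plate"),
    log2: bool = True,
    within_bins: bool = True,
):
    """Run the standardization steps in order and collect the factors.

    Steps are any subset of ``{"hyb", "median", "plate"}``, applied in that
    fixed order.  Returns ``(matrix, factors)`` where ``factors`` maps each
    applied step to its audit table.
    """
    factors: dict[str, object] = {}
    out = matrix
    if "hyb" in steps:
        if control_reference is None:
            raise ValidationError("hybridization step needs control reference levels")
        out, f = hybridization_normalize(out, annotation.control_ids, control_reference)
        factors["hyb"] = f
    if "median" in steps:
        out, f = median_normalize(out, annotation.dilution_bins(), within_bins=within_bins)
        factors["median"] = f
    if "plate" in steps:
        if plate_ids is None or calibrator_reference is None:
            raise ValidationError("plate step needs plate ids and a reference")
        out, f = plate_calibrate(out, plate_ids, calibrator_reference, calibrators)
        factors["plate"] = f
    if log2:
        out = log2_transform(out)
    return out, factors
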