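"""Reproducibility and response statistics for a profiled screen.

Three per-feature summaries, all computed on mock (negative-control)
well profiles unless stated otherwise:

* plate-to-plate CV — |sample SD / mean| of the per-plate mock means,
  across plates; quantifies batch drift over the experiment;
* well-to-well CV — |sample SD / mean| across the mock wells of one
  plate, summarized over plates by the median; quantifies within-plate
  (largely positional) variability;
* response magnitude — for each feature, the maximum |z| over all wells
  of the active compounds, where z standardizes a well value against the
  same-plate mock mean and sample SD; quantifies how far compounds move
  each feature relative to control variability.

Sample (n-1) standard deviations are used throughout.  A statistic is
undefined (recorded with a reason, never silently dropped) when its
reference mean is zero (CV) or the mock SD is zero (response).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .profiling import WellProfiles

logger = logging.getLogger(__name__)

QC_COLUMNS = ["feature", "statistic", "scope", "undefined_reason"]


class QCError(ValueError):
    pass


def _cv(values: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """|sd/mean| per column with (n-1) sd; NaN + reason where mean == 0."""
    mean = values.mean()
    sd = values.std(ddof=1)
    zero = mean == 0
    cv = (sd / mean.mask(zero)).abs()
    reason = pd.Series("", index=values.columns)
    reason[zero] = "zero mean"
    return cv, reason


def plate_cv(wells: WellProfiles) -> pd.DataFrame:
    """Plate-to-plate CV: per feature, across the per-plate mock-well means."""
    mocks = wells.data.loc[wells.mock_mask]
    per_plate = mocks.groupby("plate_id")[wells.feature_names].mean()
    if len(per_plate) < 2:
        raise QCError(
            f"plate-to-plate CV needs >=2 plates with mock wells, got {len(per_plate)}"
        )
    cv, reason = _cv(per_plate)
    return pd.DataFrame(
        {
            "feature": wells.feature_names,
            "statistic": cv.to_numpy(),
            "scope": "plate_to_plate",
            "undefined_reason": reason.to_numpy(),
        }
    )


def well_position_cv(wells: WellProfiles) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Well-to-well CV across each plate's mock wells.

    Returns (summary, per_plate): the summary takes the median over
    plates per feature; per-plate values are emitted alongside.  Plates
    with fewer than two mock wells are skipped with a warning.
    """
    mocks = wells.data.loc[wells.mock_mask]
    feats = wells.feature_names
    per_plate_rows = []
    for plate, block in mocks.groupby("plate_id"):
        if len(block) < 2:
            logger.warning("plate %s has %d mock well(s); skipped", plate, len(block))
            continue
        cv, reason = _cv(block[feats])
        per_plate_rows.append(
            pd.DataFrame(
                {
                    "plate_id": plate,
                    "feature": feats,
                    "statistic": cv.to_numpy(),
                    "scope": "well_to_well",
                    "undefined_reason": reason.to_numpy(),
                }
            )
        )
    if not per_plate_rows:
        raise QCError("no plate has >=2 mock wells; well-to-well CV undefined")
    per_plate = pd.concat(per_plate_rows, ignore_index=True)
    summary_stat = per_plate.groupby("feature")["statistic"].median()
    all_nan = per_plate.groupby("feature")["statistic"].apply(lambda s: s.isna().all())
    summary = pd.DataFrame(
        {
            "feature": feats,
            "statistic": summary_stat.reindex(feats).to_numpy(),
            "scope": "well_to_well",
            "undefined_reason": np.where(all_nan.reindex(feats), "zero mean", ""),
        }
    )
    return summary, per_plate


def response_magnitude(
    wells: WellProfiles,
    actives: list[str],
    per_cell: bool = False,
    cells: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Maximal mock-standardized response per feature over active compounds.

    For each well of an active compound, z = (well value - same-plate
    mock mean) / same-plate mock sample SD; the statistic is the maximum
    |z| per feature over all such wells.  (feature, plate) pairs with
    zero mock SD are skipped; a feature undefined everywhere is recorded
    with a reason.

    With ``per_cell=True`` the mock mean/SD are taken over the individual
    mock-treated cells of the plate (requires the cell table), reading
    the control population at the cell rather than the well level.
    """
    if not actives:
        raise QCError("active set is empty")
    feats = wells.feature_names
    active_set = set(actives)
    zmax = pd.Series(np.nan, index=feats)
    any_defined = pd.Series(False, index=feats)
    for plate, block in wells.data.groupby("plate_id"):
        mocks = block.loc[block["treatment"] == wells.mock_label, feats]
        if per_cell:
            if cells is None:
                raise QCError("per_cell standardization requires the cell table")
            mock_wells = block.loc[block["treatment"] == wells.mock_label, "well"]
            sel = (cells["plate_id"] == plate) & cells["well"].isin(set(mock_wells))
            mocks = cells.loc[sel, feats]
        if len(mocks) < 2:
            logger.warning("plate %s has <2 mock observations; skipped", plate)
            continue
        mu = mocks.mean()
        sd = mocks.std(ddof=1)
        ok = sd > 0
        hits = block.loc[block["treatment"].isin(active_set), feats]
        if hits.empty:
            continue
        z = (hits - mu).abs() / sd.mask(~ok)
        plate_max = z.max()
        any_defined |= ok & plate_max.notna()
        zmax = np.fmax(zmax, plate_max)
    return pd.DataFrame(
        {
            "feature": feats,
            "statistic": zmax.to_numpy(),
            "scope": "response",
            "undefined_reason": np.where(any_defined, "", "zero mock SD on every plate"),
        }
    )
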