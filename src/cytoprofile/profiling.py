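"""Aggregation of per-cell features into well and compound profiles.

Two deliberately simple steps: the profile of a well is the mean of each
feature over the cells in that well, and the profile of a compound is
the element-wise median over its replicate well profiles.  The median
over all mock (DMSO) wells — the median mock profile — is carried in the
same table and serves as the reference point for activity calling.  No
feature transformation or reduction is applied by default; an optional
per-plate mock standardization is available but off by default, keeping
the profiles as close to the raw measurements as possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import KEY_COLUMNS
from .synthetic import DEFAULT_MOCK_LABEL

logger = logging.getLogger(__name__)

WELL_META_COLUMNS = ["plate_id", "well", "treatment", "replicate", "cell_count"]


class ProfilingError(ValueError):
    """Raised when aggregation preconditions fail."""


@dataclass
class WellProfiles:
    """One profile per occupied well.

    ``data`` holds plate_id, well, treatment, replicate, cell_count and
    one column per feature (the mean over that well's cells, missing
    cells ignored per feature).
    """

    data: pd.DataFrame
    mock_label: str = DEFAULT_MOCK_LABEL

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in WELL_META_COLUMNS]

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    @property
    def mock_mask(self) -> pd.Series:
        return self.data["treatment"] == self.mock_label

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CompoundProfiles:
    """One profile per compound plus the median mock profile.

    ``data`` holds compound_id, n_wells and the feature columns; the mock
    row (labelled with ``mock_label``) is the element-wise median over
    *all* mock wells and counts toward ``len``, so a 1600-compound screen
    yields 1601 profiles.
    """

    data: pd.DataFrame
    mock_label: str = DEFAULT_MOCK_LABEL

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("compound_id", "n_wells")]

    @property
    def median_mock(self) -> pd.Series:
        row = self.data.loc[self.data["compound_id"] == self.mock_label]
        if row.empty:
            raise ProfilingError(f"no mock profile ({self.mock_label!r}) present")
        return row.iloc[0][self.feature_names].astype(float)

    @property
    def compound_data(self) -> pd.DataFrame:
        """The non-mock rows."""
        return self.data.loc[self.data["compound_id"] != self.mock_label]

    def profile(self, compound_id: str) -> pd.Series:
        row = self.data.loc[self.data["compound_id"] == compound_id]
        if row.empty:
            raise KeyError(compound_id)
        return row.iloc[0][self.feature_names].astype(float)

    def __len__(self) -> int:
        return len(self.data)


def aggregate_wells(
    cells: pd.DataFrame,
    platemap: pd.DataFrame,
    mock_label: str = DEFAULT_MOCK_LABEL,
) -> WellProfiles:
    """Average each feature over the cells of each well.

    Every cell's (plate_id, well) must appear in the plate map.  A
    feature value is missing in a well only if it is missing for every
    cell there; features missing in *all* wells are dropped with a logged
    list.  Plate-map wells with no cells are excluded with a warning.
    """
    features = [c for c in cells.columns if c not in KEY_COLUMNS]
    if not features:
        raise ProfilingError("cell table has no feature columns")
    if cells.empty:
        raise ProfilingError("cell table is empty: zero occupied wells")

    pm = platemap.set_index(["plate_id", "well"])
    if not pm.index.is_unique:
        raise ProfilingError("plate map assigns some well more than once")
    cell_keys = pd.MultiIndex.from_frame(cells[["plate_id", "well"]])
    unknown = cell_keys.difference(pm.index)
    if len(unknown):
        raise ProfilingError(
            f"{len(unknown)} well(s) in the cell table are absent from the plate map, "
            f"e.g. {tuple(unknown[0])}"
        )

    grouped = cells.groupby(["plate_id", "well"], sort=True)
    prof = grouped[features].mean()
    counts = grouped.size().rename("cell_count")

    dead = [c for c in features if prof[c].isna().all()]
    if dead:
        logger.warning("dropping %d feature(s) missing in every well: %s", len(dead), dead)
        prof = prof.drop(columns=dead)

    empty = pm.index.difference(prof.index)
    if len(empty):
        logger.warning("%d plate-map well(s) contain no cells and are excluded", len(empty))

    out = prof.join(counts).join(pm[["treatment", "replicate"]]).reset_index()
    feat_kept = [c for c in features if c not in dead]
    out = out[["plate_id", "well", "treatment", "replicate", "cell_count"] + feat_kept]
    out = out.sort_values(["plate_id", "well"], kind="mergesort").reset_index(drop=True)
    return WellProfiles(out, mock_label=mock_label)


def aggregate_compounds(wells: WellProfiles) -> CompoundProfiles:
    """Element-wise median over each compound's replicate wells.

    The mock row is the median over all mock wells in the experiment.
    Even replicate counts use the midpoint of the two central order
    statistics; a feature missing in some wells is the median of the
    wells where it is present.
    """
    if not wells.mock_mask.any():
        raise ProfilingError(
            f"no mock wells ({wells.mock_label!r}): cannot form the median mock profile"
        )
    feats = wells.feature_names
    grouped = wells.data.groupby("treatment", sort=True)
    med = grouped[feats].median()
    n_wells = grouped.size().rename("n_wells")
    out = med.join(n_wells).reset_index().rename(columns={"treatment": "compound_id"})
    out = out[["compound_id", "n_wells"] + feats]
    out = out.sort_values("compound_id", kind="mergesort").reset_index(drop=True)
    return CompoundProfiles(out, mock_label=wells.mock_label)


def standardize_wells(wells: WellProfiles) -> WellProfiles:
    """Optional per-plate mock standardization (z-scores against same-plate mocks).

    Off by default throughout the pipeline; provided for screens where
    plate batch effects must be removed before distances are taken.
    Features whose mock standard deviation is zero on a plate become
    missing on that plate (logged).
    """
    feats = wells.feature_names
    df = wells.data.copy()
    n_degenerate = 0
    for plate, idx in df.groupby("plate_id").groups.items():
        block = df.loc[idx]
        mocks = block.loc[block["treatment"] == wells.mock_label, feats]
        if len(mocks) < 2:
            raise ProfilingError(
                f"plate {plate} has {len(mocks)} mock well(s); >=2 required to standardize"
            )
        mu = mocks.mean()
        sd = mocks.std(ddof=1)
        zero = sd == 0
        n_degenerate += int(zero.sum())
        sd = sd.replace(0, np.nan)
        df.loc[idx, feats] = ((block[feats] - mu) / sd).to_numpy()
    if n_degenerate:
        logger.warning(
            "standardization produced %d (plate, feature) block(s) with zero mock SD",
            n_degenerate,
        )
    return WellProfiles(df, mock_label=wells.mock_label)
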