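"""Activity calling by distance to the median mock profile.

A compound is deemed active when the Euclidean distance from its profile
to the median mock profile exceeds a cutoff, where the cutoff is an
empirical percentile (default the 95th) of the distances from the
individual mock wells to the median mock profile.  The asymmetry is
deliberate and preserved: the null distances come from single wells
while compounds are replicate medians, so under the null the replicate
median shrinks toward the mock centre and fewer than (1 - percentile)
of inert compounds are called active.

Distances are computed on untransformed aggregated features; the
quantile uses linear interpolation between order statistics (quantile q
of sorted x1..xn sits at rank 1 + (n-1)q), and ties at the cutoff are
inactive (strictly greater than the cutoff is required).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiling import CompoundProfiles, WellProfiles

logger = logging.getLogger(__name__)


class ActivityError(ValueError):
    pass


def _distances(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Row-wise Euclidean distance to ``reference`` over the features
    defined (non-missing) in both the row and the reference."""
    ref = np.asarray(reference, dtype=float)
    vals = np.asarray(values, dtype=float)
    diff = vals - ref
    mask = np.isnan(diff)
    diff[mask] = 0.0
    return np.sqrt((diff * diff).sum(axis=1))


@dataclass
class ActivityResult:
    """Per-compound distances and active calls.

    ``table`` has compound_id, distance, active; the mock profile itself
    is never listed (and hence never flagged).  ``mock_distances`` are
    the per-mock-well null distances the cutoff was taken from.
    """

    table: pd.DataFrame
    cutoff: float
    percentile: float
    mock_distances: np.ndarray

    @property
    def active_compounds(self) -> list[str]:
        return self.table.loc[self.table["active"], "compound_id"].tolist()

    @property
    def n_active(self) -> int:
        return int(self.table["active"].sum())


def mock_null_distances(wells: WellProfiles, median_mock: pd.Series) -> np.ndarray:
    """Euclidean distance of every mock well profile to the median mock."""
    mocks = wells.data.loc[wells.mock_mask]
    if mocks.empty:
        raise ActivityError(f"no mock wells ({wells.mock_label!r}) in the well profiles")
    if len(mocks) < 20:
        logger.warning(
            "only %d mock wells: the percentile cutoff will be unstable", len(mocks)
        )
    feats = [f for f in wells.feature_names if f in median_mock.index]
    ref = median_mock[feats].to_numpy(dtype=float)
    return _distances(mocks[feats].to_numpy(dtype=float), ref)


def activity_cutoff(mock_distances: np.ndarray, percentile: float = 0.95) -> float:
    """Empirical quantile of the mock null distances (linear interpolation)."""
    d = np.asarray(mock_distances, dtype=float)
    if d.size == 0:
        raise ActivityError("empty null distance set")
    if not (0 < percentile <= 1):
        raise ActivityError(f"percentile must lie in (0, 1], got {percentile}")
    return float(np.quantile(d, percentile, method="linear"))


def call_actives(compounds: CompoundProfiles, cutoff: float) -> pd.DataFrame:
    """Per-compound distance to the median mock and strict-> cutoff calls."""
    median_mock = compounds.median_mock
    comp = compounds.compound_data
    feats = compounds.feature_names
    dist = _distances(
        comp[feats].to_numpy(dtype=float), median_mock.to_numpy(dtype=float)
    )
    return pd.DataFrame(
        {
            "compound_id": comp["compound_id"].to_numpy(),
            "distance": dist,
            "active": dist > cutoff,
        }
    ).reset_index(drop=True)


def compute_activity(
    wells: WellProfiles,
    compounds: CompoundProfiles,
    percentile: float = 0.95,
) -> ActivityResult:
    """Full activity stage: null distances -> cutoff -> calls."""
    null = mock_null_distances(wells, compounds.median_mock)
    cutoff = activity_cutoff(null, percentile)
    table = call_actives(compounds, cutoff)
    return ActivityResult(
        table=table, cutoff=cutoff, percentile=percentile, mock_distances=null
    )
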