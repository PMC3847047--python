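"""Synthetic high-content screen generator.

Emulates the tabular output of an imaging screen without any images:
plate maps (compounds plated in replicate layouts plus a fixed block of
mock/DMSO wells per plate), per-cell feature tables with heterogeneous
feature magnitudes, plate-level shifts, edge-gradient well-position
artifacts and per-cell noise, and compound annotation tables.  Mechanism
groups shift a subset of features in a shared direction, so the
downstream clustering and enrichment stages have planted structure to
recover, recorded as :class:`GroundTruth`.

All randomness flows from a single master seed through named substreams
(baseline, platemap, effects, cells, annotations); per-plate cell tables
additionally key their stream on the plate identifier, so any plate can
be regenerated independently and in any order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MOCK_LABEL = "DMSO"

_STREAMS = {
    "baseline": 0,
    "platemap": 1,
    "effects": 2,
    "cells": 3,
    "annotations": 4,
}


class DesignError(ValueError):
    """Raised when a screen design cannot be laid out on the plates."""


def substream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Named, order-independent child RNG of one master seed."""
    if name not in _STREAMS:
        raise KeyError(f"unknown random substream {name!r}")
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS[name], *map(int, extra)])
    )


# ---------------------------------------------------------------------------
# plate geometry

_PLATE_SHAPES = {
    6: (2, 3),
    12: (3, 4),
    24: (4, 6),
    48: (6, 8),
    96: (8, 12),
    384: (16, 24),
    1536: (32, 48),
}


def plate_shape(wells_per_plate: int) -> tuple[int, int]:
    """(n_rows, n_cols) for a plate; standard SBS shapes, else the divisor
    pair closest to the 2:3 row:column aspect ratio."""
    if wells_per_plate in _PLATE_SHAPES:
        return _PLATE_SHAPES[wells_per_plate]
    best = None
    for r in range(1, int(math.isqrt(wells_per_plate)) + 1):
        if wells_per_plate % r:
            continue
        c = wells_per_plate // r
        score = abs(c / r - 1.5)
        if best is None or score < best[0]:
            best = (score, r, c)
    assert best is not None
    return best[1], best[2]


def _row_letters(i: int) -> str:
    """0 -> 'A', 25 -> 'Z', 26 -> 'AA', ... (spreadsheet convention)."""
    s = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        s = chr(65 + r) + s
    return s


def well_labels(wells_per_plate: int) -> list[str]:
    """Canonical well labels in row-major order, e.g. 'A01'...'P24'."""
    n_rows, n_cols = plate_shape(wells_per_plate)
    width = max(2, len(str(n_cols)))
    return [
        f"{_row_letters(r)}{c + 1:0{width}d}"
        for r in range(n_rows)
        for c in range(n_cols)
    ]


def _edge_factor(wells_per_plate: int) -> np.ndarray:
    """Per-well multiplier in [0, 1]: 0 at the plate centre, 1 on the rim.

    Models the gradient (evaporation, temperature) that makes edge wells
    systematically different in real plates.
    """
    n_rows, n_cols = plate_shape(wells_per_plate)
    r = np.arange(n_rows)[:, None]
    c = np.arange(n_cols)[None, :]
    fr = np.abs(r - (n_rows - 1) / 2) / max((n_rows - 1) / 2, 1)
    fc = np.abs(c - (n_cols - 1) / 2) / max((n_cols - 1) / 2, 1)
    return np.maximum(fr, fc).ravel()


# ---------------------------------------------------------------------------
# configuration dataclasses


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a screen: plates, wells, compounds, replicates, mocks.

    The layout must balance exactly:
    ``n_compounds * n_replicates + mock_wells_per_plate * n_plates ==
    n_plates * wells_per_plate``.  The default instance is a 20-plate,
    384-well screen of 1600 compounds in quadruplicate with 64 mock wells
    per plate (hence 7680 wells in total).  ``cells_per_well_range`` is
    inclusive on both ends and may be scaled far below the plated density
    of a real screen for fast simulation.
    """

    n_plates: int = 20
    wells_per_plate: int = 384
    n_compounds: int = 1600
    n_replicates: int = 4
    mock_wells_per_plate: int = 64
    n_features: int = 824
    cells_per_well_range: tuple[int, int] = (1500, 2000)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_plates", "wells_per_plate", "n_compounds",
                     "n_replicates", "n_features"):
            if getattr(self, name) < 1:
                raise DesignError(f"{name} must be positive, got {getattr(self, name)}")
        if self.mock_wells_per_plate < 0:
            raise DesignError("mock_wells_per_plate must be non-negative")
        lo, hi = self.cells_per_well_range
        if not (1 <= lo <= hi):
            raise DesignError(
                f"cells_per_well_range must satisfy 1 <= lo <= hi, got ({lo}, {hi})"
            )
        compound_wells = self.n_compounds * self.n_replicates
        mock_wells = self.mock_wells_per_plate * self.n_plates
        total = self.n_plates * self.wells_per_plate
        if compound_wells + mock_wells != total:
            raise DesignError(
                "unbalanced layout: "
                f"{self.n_compounds} compounds x {self.n_replicates} replicates "
                f"({compound_wells} wells) + {self.mock_wells_per_plate} mock wells "
                f"x {self.n_plates} plates ({mock_wells} wells) = "
                f"{compound_wells + mock_wells}, but the plates hold {total}"
            )
        if self.n_plates % self.n_replicates:
            raise DesignError(
                f"n_plates ({self.n_plates}) must be a multiple of n_replicates "
                f"({self.n_replicates}) so each layout can be plated in replicate"
            )
        n_layouts = self.n_plates // self.n_replicates
        if self.n_compounds % n_layouts:
            raise DesignError(
                f"n_compounds ({self.n_compounds}) must divide evenly across "
                f"{n_layouts} plate layouts"
            )

    @property
    def n_layouts(self) -> int:
        return self.n_plates // self.n_replicates

    @property
    def compounds_per_layout(self) -> int:
        return self.n_compounds // self.n_layouts

    @property
    def n_mock_wells(self) -> int:
        return self.mock_wells_per_plate * self.n_plates


@dataclass(frozen=True)
class EffectModel:
    """Planted compound effects.

    ``n_mechanism_groups`` groups of ``compounds_per_group`` compounds
    each share one signed effect direction over a random
    ``affected_feature_fraction`` of the features, with amplitude
    ``effect_magnitude`` in units of the per-cell mock standard deviation
    of each affected feature.  ``within_group_jitter`` scales a
    per-compound multiplicative perturbation of the shared direction.
    Compounds outside every group have a zero effect vector.
    """

    n_mechanism_groups: int = 0
    compounds_per_group: int = 0
    affected_feature_fraction: float = 0.2
    effect_magnitude: float = 0.0
    within_group_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.n_mechanism_groups < 0 or self.compounds_per_group < 0:
            raise ValueError("group counts must be non-negative")
        if not (0 < self.affected_feature_fraction <= 1):
            raise ValueError("affected_feature_fraction must lie in (0, 1]")
        if self.within_group_jitter < 0:
            raise ValueError("within_group_jitter must be non-negative")

    @property
    def n_grouped(self) -> int:
        return self.n_mechanism_groups * self.compounds_per_group


@dataclass(frozen=True)
class NoiseModel:
    """Nuisance variation, all scales relative to the per-feature baseline.

    ``plate_shift_sd``: SD of an additive per-plate, per-feature shift
    (batch effect).  ``well_position_sd``: amplitude of an additive
    edge-gradient offset, largest on the plate rim.  ``cell_noise_sd``:
    per-cell coefficient of variation.  Zero scales give deterministic
    feature means.
    """

    plate_shift_sd: float = 0.0
    well_position_sd: float = 0.0
    cell_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("plate_shift_sd", "well_position_sd", "cell_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: Default nuisance levels used for the simulated study conditions: a 2%
#: plate batch effect, a 3% edge gradient and 10% per-cell variability,
#: consistent with the small plate-to-plate CVs (well under 0.2) that a
#: well-behaved screen exhibits while still showing positional artifacts.
DEFAULT_NOISE = NoiseModel(plate_shift_sd=0.02, well_position_sd=0.03, cell_noise_sd=0.1)


@dataclass
class GroundTruth:
    """What was planted: compound->group, group->term, and the true actives."""

    compounds: list[str]
    compound_groups: dict[str, int]
    group_terms: dict[int, str]
    active_true: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "compounds": list(self.compounds),
            "compound_groups": dict(self.compound_groups),
            "group_terms": {str(g): t for g, t in self.group_terms.items()},
            "active_true": list(self.active_true),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            compounds=list(d["compounds"]),
            compound_groups={str(k): int(v) for k, v in d["compound_groups"].items()},
            group_terms={int(k): str(v) for k, v in d["group_terms"].items()},
            active_true=list(d.get("active_true", [])),
        )


def feature_names(n_features: int) -> list[str]:
    width = max(3, len(str(max(n_features - 1, 0))))
    return [f"f_{i:0{width}d}" for i in range(n_features)]


# ---------------------------------------------------------------------------
# the realized generative model


class ScreenModel:
    """A realized synthetic screen: one baseline, one set of planted effects.

    The per-feature baseline is drawn once per experiment with log-normal
    scales, mimicking the orders-of-magnitude spread between e.g. area
    and intensity features; all noise scales and effect amplitudes are
    relative to it, so untransformed Euclidean/cosine distances behave as
    they do on real feature tables.
    """

    def __init__(
        self,
        design: ExperimentDesign,
        effects: EffectModel | None = None,
        noise: NoiseModel | None = None,
        mock_label: str = DEFAULT_MOCK_LABEL,
    ) -> None:
        self.design = design
        self.effects = effects if effects is not None else EffectModel()
        self.noise = noise if noise is not None else NoiseModel()
        self.mock_label = mock_label
        if self.effects.n_grouped > design.n_compounds:
            raise DesignError(
                f"{self.effects.n_grouped} grouped compounds exceed the "
                f"{design.n_compounds} compounds in the design"
            )

        F = design.n_features
        rng = substream(design.seed, "baseline")
        # log-normal scales spanning roughly an order of magnitude around 100
        self.baseline = np.exp(rng.normal(np.log(100.0), 0.5, F))
        self.cell_sd = self.noise.cell_noise_sd * self.baseline
        # fixed per-feature direction of the positional artifact, shared by
        # all plates (edge effects hit the same features everywhere)
        self.position_direction = rng.choice([-1.0, 1.0], F)

        width = max(4, len(str(design.n_compounds)))
        self.compound_ids = [f"C{i + 1:0{width}d}" for i in range(design.n_compounds)]

        rng_e = substream(design.seed, "effects")
        cpg = self.effects.compounds_per_group
        grouped = rng_e.choice(design.n_compounds, self.effects.n_grouped, replace=False)
        n_aff = max(1, round(self.effects.affected_feature_fraction * F))
        compound_groups: dict[str, int] = {}
        group_effects: dict[int, np.ndarray] = {}
        compound_effects: dict[str, np.ndarray] = {}
        for g in range(self.effects.n_mechanism_groups):
            members = [self.compound_ids[i] for i in sorted(grouped[g * cpg:(g + 1) * cpg])]
            affected = rng_e.choice(F, n_aff, replace=False)
            signs = rng_e.choice([-1.0, 1.0], n_aff)
            vec = np.zeros(F)
            vec[affected] = self.effects.effect_magnitude * signs * self.cell_sd[affected]
            group_effects[g] = vec
            for cid in members:
                compound_groups[cid] = g
                jitter = 1.0
                if self.effects.within_group_jitter > 0:
                    jitter = 1.0 + self.effects.within_group_jitter * rng_e.standard_normal(F)
                compound_effects[cid] = vec * jitter
        self.group_effects = group_effects
        self.compound_effects = compound_effects
        self.truth = GroundTruth(
            compounds=list(self.compound_ids),
            compound_groups=compound_groups,
            group_terms={g: f"term_g{g + 1:02d}" for g in group_effects},
            active_true=sorted(compound_groups) if self.effects.effect_magnitude else [],
        )
        self.feature_names = feature_names(F)

    # -- plate maps ---------------------------------------------------------

    def platemaps(self) -> list[pd.DataFrame]:
        """One plate map per plate (columns plate_id, well, treatment, replicate).

        The experiment is laid out as ``n_layouts`` distinct plate layouts,
        each plated ``n_replicates`` times; a replicate of a compound always
        sits in the same well position, as it does when one source plate is
        pinned onto several assay plates.  Mock wells occupy positions
        chosen once per layout from the seed.
        """
        d = self.design
        rng = substream(d.seed, "platemap")
        labels = well_labels(d.wells_per_plate)
        width = max(2, len(str(d.n_plates)))
        maps: list[pd.DataFrame] = []
        for layout in range(d.n_layouts):
            mock_pos = set(
                rng.choice(d.wells_per_plate, d.mock_wells_per_plate, replace=False).tolist()
            )
            start = layout * d.compounds_per_layout
            cpds = iter(self.compound_ids[start:start + d.compounds_per_layout])
            treatment = [
                self.mock_label if i in mock_pos else next(cpds)
                for i in range(d.wells_per_plate)
            ]
            for rep in range(d.n_replicates):
                plate = layout * d.n_replicates + rep
                maps.append(
                    pd.DataFrame(
                        {
                            "plate_id": f"P{plate + 1:0{width}d}",
                            "well": labels,
                            "treatment": treatment,
                            "replicate": rep + 1,
                        }
                    )
                )
        return maps

    def null_platemaps(self, n_wells: int, prefix: str = "H") -> list[pd.DataFrame]:
        """Extra all-mock plates holding at least ``n_wells`` wells.

        Used to draw held-out wells from the mock distribution, e.g. to
        check the calibration of the activity cutoff on data that did not
        enter its construction.
        """
        d = self.design
        n_extra = math.ceil(n_wells / d.wells_per_plate)
        labels = well_labels(d.wells_per_plate)
        width = max(2, len(str(n_extra)))
        return [
            pd.DataFrame(
                {
                    "plate_id": f"{prefix}{p + 1:0{width}d}",
                    "well": labels,
                    "treatment": self.mock_label,
                    "replicate": 0,
                }
            )
            for p in range(n_extra)
        ]

    # -- cell tables --------------------------------------------------------

    def _well_means(self, platemap: pd.DataFrame, plate_rng: np.random.Generator) -> np.ndarray:
        d, F = self.design, self.design.n_features
        plate_shift = (
            plate_rng.standard_normal(F) * self.noise.plate_shift_sd * self.baseline
        )
        edge = _edge_factor(d.wells_per_plate)
        label_to_pos = {lab: i for i, lab in enumerate(well_labels(d.wells_per_plate))}
        means = np.empty((len(platemap), F))
        for i, (well, treatment) in enumerate(
            zip(platemap["well"].to_numpy(), platemap["treatment"].to_numpy())
        ):
            mu = self.baseline + plate_shift
            mu = mu + (
                self.noise.well_position_sd
                * edge[label_to_pos[well]]
                * self.position_direction
                * self.baseline
            )
            eff = self.compound_effects.get(treatment)
            if eff is not None:
                mu = mu + eff
            means[i] = mu
        return means

    def cell_table(self, platemap: pd.DataFrame) -> pd.DataFrame:
        """Per-cell feature table for one plate, reproducible from the seed.

        Each well receives a cell count drawn uniformly from the design's
        ``cells_per_well_range``; each cell's feature vector is the well
        mean (baseline + compound effect + plate shift + position offset)
        plus independent Gaussian cell noise.  The plate's random stream
        is keyed on the plate identifier, so regeneration is independent
        of call order.
        """
        plates = platemap["plate_id"].unique()
        if len(plates) != 1:
            raise ValueError(f"cell_table expects a single-plate map, got {list(plates)}")
        plate_id = str(plates[0])
        d = self.design
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [int(d.seed), _STREAMS["cells"], zlib.crc32(plate_id.encode())]
            )
        )
        lo, hi = d.cells_per_well_range
        counts = rng.integers(lo, hi + 1, size=len(platemap))
        means = self._well_means(platemap, rng)
        total = int(counts.sum())
        cell_well = np.repeat(np.arange(len(platemap)), counts)
        values = means[cell_well]
        if self.noise.cell_noise_sd > 0:
            values = values + rng.standard_normal((total, d.n_features)) * self.cell_sd
        cell_index = np.concatenate([np.arange(c) for c in counts])
        out = pd.DataFrame(values, columns=self.feature_names)
        out.insert(0, "cell_index", cell_index)
        out.insert(0, "well", platemap["well"].to_numpy()[cell_well])
        out.insert(0, "plate_id", plate_id)
        return out

    def cell_tables(self, platemaps: list[pd.DataFrame] | None = None):
        """Yield one cell table per plate map (memory-friendly)."""
        for pm in platemaps if platemaps is not None else self.platemaps():
            yield self.cell_table(pm)

    # -- annotations --------------------------------------------------------

    def annotations(
        self,
        coverage: float = 1.0,
        n_decoy_terms: int = 0,
        decoy_rate: float = 0.02,
    ) -> pd.DataFrame:
        return generate_annotations(
            self.truth,
            coverage=coverage,
            n_decoy_terms=n_decoy_terms,
            seed=self.design.seed,
            decoy_rate=decoy_rate,
        )


# ---------------------------------------------------------------------------
# module-level convenience operations


def generate_platemaps(
    design: ExperimentDesign, mock_label: str = DEFAULT_MOCK_LABEL
) -> list[pd.DataFrame]:
    """Plate maps for a design (see :meth:`ScreenModel.platemaps`)."""
    return ScreenModel(design, mock_label=mock_label).platemaps()


def generate_annotations(
    truth: GroundTruth,
    coverage: float,
    n_decoy_terms: int,
    seed: int,
    decoy_rate: float = 0.02,
) -> pd.DataFrame:
    """Annotation table (compound_id, term) from planted ground truth.

    Each grouped compound carries its group's term with probability
    ``coverage`` (annotation databases never cover a library fully);
    each of ``n_decoy_terms`` unrelated terms is scattered uniformly over
    all compounds at ``decoy_rate``, with at least one carrier so every
    term in the universe maps to some compound.  Compounds may therefore
    carry several terms.
    """
    if not (0 < coverage <= 1):
        raise ValueError(f"coverage must lie in (0, 1], got {coverage}")
    if n_decoy_terms < 0:
        raise ValueError("n_decoy_terms must be non-negative")
    rng = substream(seed, "annotations")
    rows: list[tuple[str, str]] = []
    for cid in sorted(truth.compound_groups):
        if rng.random() < coverage:
            rows.append((cid, truth.group_terms[truth.compound_groups[cid]]))
    compounds = np.asarray(truth.compounds)
    for di in range(n_decoy_terms):
        term = f"decoy_{di + 1:02d}"
        mask = rng.random(len(compounds)) < decoy_rate
        if not mask.any():
            mask[rng.integers(len(compounds))] = True
        rows.extend((cid, term) for cid in compounds[mask])
    out = pd.DataFrame(rows, columns=["compound_id", "term"])
    return (
        out.drop_duplicates()
        .sort_values(["compound_id", "term"], kind="mergesort")
        .reset_index(drop=True)
    )
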