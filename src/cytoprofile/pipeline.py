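"""End-to-end orchestration: simulate -> profile -> qc -> activity -> enrich.

A run is fully described by a :class:`PipelineConfig` (serializable to
YAML); identical config and seed give byte-identical outputs.  Inputs
are either a synthetic-screen description (design/effects/noise) or
paths to cell-feature, plate-map and annotation CSVs.  Every stage's
output is written as a deterministic CSV (plus Newick for the dendrogram
and JSON for the manifest), so any downstream stage can be re-run alone
from the intermediate files and reproduce the full-run output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .activity import compute_activity
from .enrichment import (
    ENRICHMENT_COLUMNS,
    cluster_profiles,
    cosine_distance_matrix,
    enumerate_clusters,
    rank_clusters,
    score_enrichment,
)
from .profiling import (
    WellProfiles,
    aggregate_compounds,
    aggregate_wells,
    standardize_wells,
)
from .qc import plate_cv, response_magnitude, well_position_cv
from .synthetic import (
    DEFAULT_MOCK_LABEL,
    EffectModel,
    ExperimentDesign,
    NoiseModel,
    ScreenModel,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@contextmanager
def _stage(name: str):
    logger.info("stage %s", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc


@dataclass
class PipelineConfig:
    """One config drives one reproducible run.

    Exactly one of ``synthetic`` (keys design/effects/noise/annotations)
    or ``inputs`` (keys cells/platemap/annotations, values paths or
    globs) must be set.  ``seed`` governs every stochastic stage — the
    synthetic generator through named substreams and the permutation
    test directly.
    """

    out_dir: str
    seed: int = 0
    mock_label: str = DEFAULT_MOCK_LABEL
    percentile: float = 0.95
    n_permutations: int = 10_000
    standardize: bool = False
    synthetic: dict | None = None
    inputs: dict | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' or 'inputs' must be given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _build_model(cfg: PipelineConfig) -> ScreenModel:
    syn = dict(cfg.synthetic or {})
    design_kw = dict(syn.get("design", {}))
    design_kw["seed"] = cfg.seed
    if "cells_per_well_range" in design_kw:
        design_kw["cells_per_well_range"] = tuple(design_kw["cells_per_well_range"])
    design = ExperimentDesign(**design_kw)
    effects = EffectModel(**syn.get("effects", {})) if "effects" in syn else None
    noise = NoiseModel(**syn.get("noise", {})) if "noise" in syn else None
    return ScreenModel(design, effects=effects, noise=noise, mock_label=cfg.mock_label)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; write result tables under ``config.out_dir`` and
    return the run manifest (also written as manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "mock_label": config.mock_label,
        "percentile": config.percentile,
        "n_permutations": config.n_permutations,
        "counts": {},
    }

    # ---- inputs / simulation
    annotations: pd.DataFrame
    if config.synthetic is not None:
        with _stage("simulate"):
            model = _build_model(config)
            platemaps = model.platemaps()
            ann_kw = dict(config.synthetic.get("annotations", {}))
            annotations = model.annotations(**ann_kw)
            io.write_table(pd.concat(platemaps, ignore_index=True), out / "platemap.csv", meta)
            io.write_table(annotations, out / "annotations.csv", meta)
            with open(out / "ground_truth.json", "w") as fh:
                json.dump(model.truth.to_dict(), fh, indent=2, sort_keys=True)
        with _stage("profile"):
            per_plate = []
            for pm in platemaps:
                cells = model.cell_table(pm)
                per_plate.append(aggregate_wells(cells, pm, model.mock_label).data)
            wells = WellProfiles(
                pd.concat(per_plate, ignore_index=True), mock_label=model.mock_label
            )
    else:
        with _stage("read"):
            inputs = config.inputs or {}
            cells = io.read_cell_features(inputs["cells"])
            platemap = io.read_platemap(inputs["platemap"])
            annotations = io.read_annotations(inputs["annotations"])
        with _stage("profile"):
            wells = aggregate_wells(cells, platemap, config.mock_label)

    with _stage("profile"):
        if config.standardize:
            wells = standardize_wells(wells)
        io.write_table(wells.data, out / "well_profiles.csv", meta)
        compounds = aggregate_compounds(wells)
        io.write_table(compounds.data, out / "compound_profiles.csv", meta)
        manifest["counts"]["wells"] = len(wells)
        manifest["counts"]["compound_profiles"] = len(compounds)

    with _stage("qc"):
        qc_plate = plate_cv(wells)
        qc_well, qc_well_per_plate = well_position_cv(wells)
        io.write_table(qc_plate, out / "qc_plate_cv.csv", meta)
        io.write_table(qc_well, out / "qc_well_cv.csv", meta)
        io.write_table(qc_well_per_plate, out / "qc_well_cv_per_plate.csv", meta)

    with _stage("activity"):
        act = compute_activity(wells, compounds, config.percentile)
        act_meta = {**meta, "cutoff": repr(act.cutoff), "percentile": config.percentile}
        io.write_table(act.table, out / "activity.csv", act_meta)
        io.write_table(
            pd.DataFrame({"distance": act.mock_distances}),
            out / "mock_null_distances.csv",
            meta,
        )
        manifest["counts"]["active"] = act.n_active
        manifest["cutoff"] = act.cutoff

    with _stage("qc"):
        if act.n_active:
            io.write_table(
                response_magnitude(wells, act.active_compounds),
                out / "qc_response.csv",
                meta,
            )

    with _stage("enrich"):
        annotated = set(annotations["compound_id"])
        universe = sorted(set(act.active_compounds) & annotated)
        manifest["counts"]["annotated"] = len(
            annotated & set(compounds.compound_data["compound_id"])
        )
        manifest["counts"]["active_annotated"] = len(universe)
        records = pd.DataFrame(columns=ENRICHMENT_COLUMNS + ["rank"])
        if len(universe) >= 2:
            profiles = (
                compounds.compound_data.set_index("compound_id")
                .loc[universe, compounds.feature_names]
            )
            tree = cluster_profiles(cosine_distance_matrix(profiles))
            (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
            candidates = enumerate_clusters(tree)
            manifest["counts"]["candidate_clusters"] = len(candidates)
            records = score_enrichment(
                candidates,
                annotations,
                universe,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            if not records.empty:
                records = rank_clusters(records)
        else:
            logger.warning(
                "only %d active+annotated compound(s); clustering skipped", len(universe)
            )
            manifest["counts"]["candidate_clusters"] = 0
        io.write_table(records, out / "enrichment.csv", meta)
        manifest["counts"]["enrichment_records"] = len(records)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
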