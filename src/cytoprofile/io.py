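"""Reading, validation and writing of the pipeline's table formats.

Three input kinds are supported, all plain CSV (RFC 4180, UTF-8, gzip
accepted): per-cell feature tables keyed by (plate_id, well, cell_index),
plate maps (plate_id, well, treatment, replicate) and compound annotation
tables (compound_id, term).  Well labels are canonicalized on read to
letter-row + zero-padded 1-based column ("A01"); result writers emit a
header comment line carrying the pipeline version, are deterministic in
row and column order, and round-trip through :func:`read_table`.
"""

from __future__ import annotations

import glob as _glob
import logging
import re
from pathlib import Path

import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

KEY_COLUMNS = ("plate_id", "well", "cell_index")
PLATEMAP_COLUMNS = ("plate_id", "well", "treatment", "replicate")
ANNOTATION_COLUMNS = ("compound_id", "term")

_WELL_RE = re.compile(r"^([A-Za-z]+)\s*0*([1-9][0-9]*)$")


class FormatError(ValueError):
    """Raised when an input table violates its schema."""


def canonical_well(label: str) -> str:
    """Normalize a well label to 'A01' form; raise FormatError otherwise."""
    m = _WELL_RE.match(str(label).strip())
    if not m:
        raise FormatError(f"unrecognized well label {label!r} (expected e.g. 'A01')")
    row, col = m.group(1).upper(), int(m.group(2))
    return f"{row}{col:02d}"


def parse_well(label: str) -> tuple[int, int]:
    """(row index, column index), both 0-based, from a well label."""
    m = _WELL_RE.match(str(label).strip())
    if not m:
        raise FormatError(f"unrecognized well label {label!r}")
    row = 0
    for ch in m.group(1).upper():
        row = row * 26 + (ord(ch) - 64)
    return row - 1, int(m.group(2)) - 1


def _expand_paths(paths) -> list[Path]:
    if isinstance(paths, (str, Path)):
        paths = [paths]
    out: list[Path] = []
    for p in paths:
        p = str(p)
        if any(ch in p for ch in "*?["):
            matches = sorted(_glob.glob(p))
            if not matches:
                raise FileNotFoundError(f"glob {p!r} matched no files")
            out.extend(Path(m) for m in matches)
        else:
            out.append(Path(p))
    return out


def read_cell_features(paths) -> pd.DataFrame:
    """Load one or more per-cell feature CSVs into a single validated table.

    Feature columns are every column outside the key triplet; non-numeric
    feature cells become missing values (counted and logged).  Files with
    differing feature sets or duplicate (plate_id, well, cell_index) keys
    are rejected.
    """
    frames = []
    feature_sets: dict[Path, set[str]] = {}
    for path in _expand_paths(paths):
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        missing = [c for c in KEY_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing key column(s) {missing}")
        feats = [c for c in df.columns if c not in KEY_COLUMNS]
        feature_sets[path] = set(feats)
        df["well"] = df["well"].map(canonical_well)
        n_bad = 0
        for c in feats:
            col = pd.to_numeric(df[c], errors="coerce")
            n_bad += int(col.isna().sum() - df[c].isna().sum())
            df[c] = col
        if n_bad:
            logger.warning("%s: %d non-numeric feature cell(s) set to missing", path, n_bad)
        frames.append(df)
    ref_path, ref = next(iter(feature_sets.items()))
    for path, feats in feature_sets.items():
        if feats != ref:
            diff = sorted(feats ^ ref)
            raise FormatError(
                f"inconsistent feature columns between {ref_path} and {path}: "
                f"symmetric difference {diff}"
            )
    cells = pd.concat(frames, ignore_index=True)
    dup = cells.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        first = cells.loc[dup, list(KEY_COLUMNS)].iloc[0].tolist()
        raise FormatError(
            f"duplicate (plate_id, well, cell_index) keys: {int(dup.sum())} rows, "
            f"first duplicate {tuple(first)}"
        )
    return cells


def read_platemap(paths) -> pd.DataFrame:
    """Load plate map CSV(s) with canonicalized well labels."""
    frames = []
    for path in _expand_paths(paths):
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        missing = [c for c in PLATEMAP_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing plate-map column(s) {missing}")
        df = df.loc[:, list(PLATEMAP_COLUMNS)].copy()
        df["well"] = df["well"].map(canonical_well)
        df["replicate"] = df["replicate"].astype(int)
        frames.append(df)
    pm = pd.concat(frames, ignore_index=True)
    dup = pm.duplicated(subset=["plate_id", "well"])
    if dup.any():
        first = pm.loc[dup, ["plate_id", "well"]].iloc[0].tolist()
        raise FormatError(f"plate map assigns well {tuple(first)} more than once")
    return pm


def read_annotations(path) -> pd.DataFrame:
    """Load a compound annotation table; duplicate pairs are dropped."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation column(s) {missing}")
    df = df.loc[:, list(ANNOTATION_COLUMNS)].astype(str)
    n0 = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    if len(df) < n0:
        logger.warning("%s: dropped %d duplicate annotation pair(s)", path, n0 - len(df))
    return df


def write_table(
    df: pd.DataFrame,
    path,
    meta: dict | None = None,
    sort_by: list[str] | None = None,
) -> None:
    """Write a result table as CSV with a '# cytoprofile ...' header line.

    Output is deterministic: optional stable sort by ``sort_by``, fixed
    column order as given, and the shortest round-tripping float
    representation pandas emits by default.
    """
    path = Path(path)
    if sort_by:
        df = df.sort_values(sort_by, kind="mergesort")
    parts = [f"cytoprofile v{__version__}"]
    for k, v in (meta or {}).items():
        parts.append(f"{k}={v}")
    header = "# " + " ".join(parts) + "\n"
    import gzip

    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a table written by :func:`write_table` (comments skipped)."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def read_table_meta(path) -> dict:
    """Parse the key=value pairs from a result table's header comment."""
    path = Path(path)
    import gzip

    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        line = fh.readline().strip()
    meta: dict[str, str] = {}
    if line.startswith("#"):
        for tok in line[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    return meta
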