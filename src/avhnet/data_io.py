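"""On-disk artifacts: node atlas, ROI time series, clinical table, matrices.

The pipeline consumes preprocessed regional time series (plain-text T x N
matrices, one file per subject-session) together with a node table giving
each region's anatomical label, abbreviation, and MNI coordinate, and a
clinical CSV with per-subject demographics, motion (mean frame-wise
displacement), AHRS and PANSS scores. A spherical-ROI extractor is provided
for users starting from a 4D NIfTI volume in MNI space.

The packaged 35-region AVH atlas is shipped verbatim, including its printed
anomalies (two coordinate-duplicated region pairs and two left/right
abbreviation mismatches); ``load_node_table`` flags these in a validation
report, and ``dedupe=True`` collapses exact-coordinate duplicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError, PairingError

#: Default radius (mm) of the sphere averaged around each node coordinate.
DEFAULT_ROI_RADIUS_MM = 6.0

#: Time series shorter than this many volumes trigger a warning (correlation
#: estimates become unstable, but no hard minimum is imposed).
MIN_RECOMMENDED_TIMEPOINTS = 30

NODE_TABLE_COLUMNS = ["index", "label", "abbrev", "x", "y", "z"]
CLINICAL_COLUMNS = [
    "subject_id", "group", "session", "age", "sex", "fd",
    "ahrs", "panss_pos", "panss_neg", "panss_gen", "panss_total",
]

GROUPS = ("HC", "SZ")
SESSIONS = ("baseline", "post")


@dataclass
class ValidationReport:
    """Anomalies found while loading an artifact (non-fatal)."""

    duplicate_coordinates: list[tuple[int, int]] = field(default_factory=list)
    duplicate_abbreviations: list[tuple[int, int]] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.duplicate_coordinates or
                    self.duplicate_abbreviations or self.messages)


@dataclass
class NodeTable:
    """Ordered region atlas: 1-based index, label, abbreviation, MNI (mm)."""

    frame: pd.DataFrame
    validation: ValidationReport = field(default_factory=ValidationReport)

    def __post_init__(self):
        idx = self.frame["index"].to_numpy()
        if len(idx) == 0:
            raise FormatError("node table has no rows")
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise FormatError("node indices must be consecutive from 1")
        if (self.frame["abbrev"].astype(str).str.len() == 0).any():
            raise FormatError("empty abbreviation in node table")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def abbrevs(self) -> list[str]:
        return self.frame["abbrev"].tolist()

    @property
    def coords(self) -> np.ndarray:
        """N x 3 array of MNI coordinates in mm."""
        return self.frame[["x", "y", "z"]].to_numpy(dtype=float)

    def edge_name(self, i: int, j: int) -> str:
        """Human-readable name of the edge between 0-based nodes i and j."""
        a = self.frame["abbrev"].iloc[i]
        b = self.frame["abbrev"].iloc[j]
        return f"{a}-{b}"

    def find(self, abbrev: str) -> int:
        """0-based index of the first node with this abbreviation."""
        hits = np.flatnonzero(self.frame["abbrev"].to_numpy() == abbrev)
        if len(hits) == 0:
            raise KeyError(f"abbreviation {abbrev!r} not in node table")
        return int(hits[0])


@dataclass
class SubjectRecord:
    """One subject-session: imaging matrix plus clinical covariates."""

    subject_id: str
    group: str
    session: str
    age: float
    sex: str
    fd: float
    ahrs: float = np.nan
    panss_pos: float = np.nan
    panss_neg: float = np.nan
    panss_gen: float = np.nan
    panss_total: float = np.nan
    timeseries: Optional[np.ndarray] = None
    corr: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise FormatError(f"unknown group {self.group!r}")
        if self.session not in SESSIONS:
            raise FormatError(f"unknown session {self.session!r}")
        if self.group == "HC" and self.session != "baseline":
            raise FormatError(
                f"HC record {self.subject_id} carries session "
                f"{self.session!r}; controls are scanned at baseline only")
        if self.corr is not None:
            c = np.asarray(self.corr, dtype=float)
            if c.ndim != 2 or c.shape[0] != c.shape[1]:
                raise DimensionError("correlation matrix must be square")
            if not np.allclose(c, c.T, atol=1e-10):
                raise FormatError("correlation matrix is not symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-10):
                raise FormatError("correlation matrix diagonal must be 1")

    @property
    def sex_code(self) -> int:
        """Covariate coding: male=1, female=0."""
        return 1 if self.sex == "male" else 0


@dataclass
class Cohort:
    """A node table plus the subject-session records analyzed against it."""

    node_table: NodeTable
    records: list[SubjectRecord]

    def __post_init__(self):
        n = self.node_table.n
        for rec in self.records:
            if rec.timeseries is not None and rec.timeseries.shape[1] != n:
                raise DimensionError(
                    f"{rec.subject_id}/{rec.session}: time series has "
                    f"{rec.timeseries.shape[1]} columns, expected {n}")
            if rec.corr is not None and rec.corr.shape[0] != n:
                raise DimensionError(
                    f"{rec.subject_id}/{rec.session}: matrix is "
                    f"{rec.corr.shape[0]}x{rec.corr.shape[0]}, expected {n}")

    def select(self, group: str | None = None,
               session: str | None = None) -> list[SubjectRecord]:
        out = self.records
        if group is not None:
            out = [r for r in out if r.group == group]
        if session is not None:
            out = [r for r in out if r.session == session]
        return out

    def paired_patients(self) -> list[tuple[SubjectRecord, SubjectRecord]]:
        """(baseline, post) record pairs for patients with both sessions."""
        base = {r.subject_id: r for r in self.select("SZ", "baseline")}
        post = {r.subject_id: r for r in self.select("SZ", "post")}
        return [(base[s], post[s]) for s in base if s in post]


def packaged_node_table_path() -> Path:
    """Path of the packaged 35-region AVH atlas."""
    return Path(resources.files("avhnet").joinpath("data/avh_node_table.tsv"))


def packaged_clinical_path() -> Path:
    """Path of the packaged synthetic 40-patient pre/post clinical table.

    A generator-produced (synthetic) cohort mirroring the analyzed study
    sample's marginals: 40 patients, baseline and post sessions, and a
    27/13 responder/non-responder split under the 50%-AHRS-reduction rule.
    """
    return Path(resources.files("avhnet").joinpath(
        "data/synthetic_clinical_40.csv"))


def _sniff_sep(path: Path) -> str:
    head = Path(path).read_text().splitlines()[0]
    return "," if "," in head else "\t"


def load_node_table(path: str | Path, dedupe: bool = False) -> NodeTable:
    """Read a node table (TSV/CSV, header index,label,abbrev,x,y,z).

    Coordinate- and abbreviation-duplicated rows are flagged in the returned
    table's ``validation`` report; with ``dedupe=True`` exact-coordinate
    duplicates are collapsed (first occurrence wins) and indices renumbered.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    missing = [c for c in NODE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"node table {path} missing column(s): {missing}")
    df = df[NODE_TABLE_COLUMNS].copy()
    for col in ("x", "y", "z", "index"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 1
            raise FormatError(
                f"node table {path}: non-numeric {col!r} at data row {row}")
        df[col] = coerced
    df["index"] = df["index"].astype(int)

    report = ValidationReport()
    coords = list(map(tuple, df[["x", "y", "z"]].to_numpy()))
    seen: dict[tuple, int] = {}
    for pos, key in enumerate(coords):
        if key in seen:
            pair = (int(df["index"].iloc[seen[key]]), int(df["index"].iloc[pos]))
            report.duplicate_coordinates.append(pair)
            report.messages.append(
                f"rows {pair[0]} and {pair[1]} share coordinates {key}")
        else:
            seen[key] = pos
    seen_ab: dict[str, int] = {}
    for pos, ab in enumerate(df["abbrev"].astype(str)):
        if ab in seen_ab:
            pair = (int(df["index"].iloc[seen_ab[ab]]), int(df["index"].iloc[pos]))
            report.duplicate_abbreviations.append(pair)
            report.messages.append(
                f"rows {pair[0]} and {pair[1]} share abbreviation {ab!r}")
        else:
            seen_ab[ab] = pos

    if dedupe:
        drop = {int(df["index"].iloc[pos]) for key, first in seen.items()
                for pos in range(len(coords))
                if coords[pos] == key and pos != seen[key]}
        df = df[~df["index"].isin(drop)].reset_index(drop=True)
        df["index"] = np.arange(1, len(df) + 1)
        report.messages.append(
            f"dedupe: collapsed {len(drop)} coordinate-duplicate row(s)")
    return NodeTable(frame=df, validation=report)


def load_packaged_node_table(dedupe: bool = False) -> NodeTable:
    return load_node_table(packaged_node_table_path(), dedupe=dedupe)


def write_node_table(table: NodeTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def load_timeseries(path: str | Path, node_table: NodeTable) -> np.ndarray:
    """Read a plain-text T x N regional time-series matrix."""
    path = Path(path)
    sep = _sniff_sep(path)
    try:
        mat = np.loadtxt(path, delimiter="," if sep == "," else None, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"cannot parse time series {path}: {exc}") from exc
    if mat.shape[1] != node_table.n:
        raise DimensionError(
            f"{path}: {mat.shape[1]} columns, expected {node_table.n} "
            f"(node table size)")
    if mat.shape[0] < MIN_RECOMMENDED_TIMEPOINTS:
        warnings.warn(
            f"{path}: only {mat.shape[0]} timepoints "
            f"(< {MIN_RECOMMENDED_TIMEPOINTS}); correlations will be noisy",
            stacklevel=2)
    constant = np.flatnonzero(np.ptp(mat, axis=0) == 0)
    if constant.size:
        warnings.warn(
            f"{path}: zero-variance column(s) {constant.tolist()}",
            stacklevel=2)
    return mat


def write_matrix(mat: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(mat, dtype=float), delimiter="\t", fmt="%.17g")


def load_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, ndmin=2)


def extract_roi_timeseries(
    volume: str | Path,
    node_table: NodeTable,
    radius: float = DEFAULT_ROI_RADIUS_MM,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean time series within a sphere of ``radius`` mm around each node.

    The 4D NIfTI volume must carry an affine mapping voxel indices to MNI mm.
    Returns ``(T x N matrix, voxel count per node)``; nodes whose sphere
    contains no voxel produce an all-zero column and a warning.
    """
    import nibabel as nib

    if radius <= 0:
        raise ValueError("radius must be positive (mm)")
    img = nib.load(str(volume))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{volume}: expected a 4D volume, got {data.ndim}D")
    nx, ny, nz, t_len = data.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel(),
                           np.ones(ii.size)])
    mni = vox @ img.affine.T  # voxel centers in mm
    flat = data.reshape(-1, t_len)

    out = np.zeros((t_len, node_table.n))
    counts = np.zeros(node_table.n, dtype=int)
    for j, center in enumerate(node_table.coords):
        d2 = np.sum((mni[:, :3] - center) ** 2, axis=1)
        mask = d2 <= radius ** 2
        counts[j] = int(mask.sum())
        if counts[j] == 0:
            warnings.warn(
                f"node {j + 1} ({node_table.abbrevs[j]}): no voxel within "
                f"{radius} mm of {tuple(center)}; column set to zero",
                stacklevel=2)
            continue
        out[:, j] = flat[mask].mean(axis=0)
    return out, counts


def load_clinical(path: str | Path) -> list[SubjectRecord]:
    """Read the clinical CSV into SubjectRecord stubs (no imaging attached).

    Patients' baseline/post rows are paired by ``subject_id``; a post row
    without a baseline row raises, as does a duplicated (subject_id, session).
    """
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table {path} missing column(s): {missing}")
    dup = df.duplicated(subset=["subject_id", "session"])
    if dup.any():
        key = df.loc[dup, ["subject_id", "session"]].iloc[0].tolist()
        raise FormatError(f"duplicate (subject_id, session) row: {key}")
    records = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in CLINICAL_COLUMNS if c in df.columns}
        kwargs["subject_id"] = str(kwargs["subject_id"])
        records.append(SubjectRecord(**kwargs))
    have_base = {r.subject_id for r in records if r.session == "baseline"}
    orphans = [r.subject_id for r in records
               if r.session == "post" and r.subject_id not in have_base]
    if orphans:
        raise PairingError(
            f"post session without baseline for subject(s): {sorted(orphans)}")
    return records


def attach_timeseries(records: list[SubjectRecord], directory: str | Path,
                      node_table: NodeTable) -> None:
    """Attach ``<subject_id>_<session>.tsv`` matrices from a directory."""
    directory = Path(directory)
    for rec in records:
        f = directory / f"{rec.subject_id}_{rec.session}.tsv"
        if not f.exists():
            raise FormatError(f"missing time-series file {f}")
        rec.timeseries = load_timeseries(f, node_table)
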