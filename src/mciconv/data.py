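"""Cohort data model and tab-separated feature-table / label-file I/O.

A *subject record* carries the 204 FreeSurfer-derived morphometric scalars of
one subject — cortical thickness (CT, mm), cortical volume (CV, mm3) and
cortical surface area (CS, mm2) for each of the 68 Desikan–Killiany ROIs —
plus a diagnostic label: MCI converter (MCIc, coded +1) or non-converter
(MCInc, coded -1).

Feature-table dialect: UTF-8, tab-separated, one header row, one row per
subject, first column ``subject_id``, remaining columns named
``{CATEGORY}:{ROI}_{HEMI}`` (e.g. ``CT:IPC_L``).  Labels live in a separate
two- or three-column TSV (``subject_id``, ``label``, optional ``pair_tag``)
so that one feature table can serve several diagnostic pairs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rois import ALL_ROI_NAMES, N_ROIS, ROIName

__all__ = [
    "MRI_CATEGORIES",
    "NETWORK_CATEGORIES",
    "ALL_CATEGORIES",
    "LABEL_CODES",
    "PAIR_TAGS",
    "SubjectRecord",
    "Cohort",
    "FeatureMatrix",
    "parse_column_name",
    "column_names_for",
    "load_feature_table",
    "write_feature_table",
    "write_labels",
    "assemble_features",
]

#: Measure categories in canonical order: three MRI, two network.
MRI_CATEGORIES: tuple[str, ...] = ("CT", "CV", "CS")
NETWORK_CATEGORIES: tuple[str, ...] = ("NL", "ND")
ALL_CATEGORIES: tuple[str, ...] = MRI_CATEGORIES + NETWORK_CATEGORIES

#: Diagnostic labels: converters are the positive class.
LABEL_CODES: dict[str, int] = {"MCIc": 1, "MCInc": -1}
LABEL_NAMES: dict[int, str] = {v: k for k, v in LABEL_CODES.items()}

#: Conversion-horizon tags: baseline/mixed, or 6/12/18 months before AD diagnosis.
PAIR_TAGS: tuple[str, ...] = ("mixed", "m6", "m12", "m18")


class SchemaError(ValueError):
    """Feature table or label file does not match the expected layout."""


def parse_column_name(name: str) -> tuple[str, ROIName]:
    """Split ``'CT:IPC_L'`` into ``('CT', ROIName('IPC', 'L'))``."""
    cat, sep, roi = name.partition(":")
    if not sep or cat not in ALL_CATEGORIES:
        raise SchemaError(
            f"malformed feature column {name!r}; expected '{{CAT}}:{{ROI}}_{{HEMI}}' "
            f"with CAT in {ALL_CATEGORIES}"
        )
    return cat, ROIName.parse(roi)


def column_names_for(categories: Sequence[str]) -> list[str]:
    """Column names for the given categories, category-major in canonical order."""
    cats = [c for c in ALL_CATEGORIES if c in set(categories)]
    return [f"{cat}:{roi}" for cat in cats for roi in ALL_ROI_NAMES]


@dataclass
class SubjectRecord:
    """One subject: 204 morphometric scalars, diagnostic label, horizon tag."""

    subject_id: str
    label: int  # +1 MCIc, -1 MCInc
    ct: np.ndarray  # (68,) cortical thickness, mm
    cv: np.ndarray  # (68,) cortical volume, mm3
    cs: np.ndarray  # (68,) cortical surface area, mm2
    pair_tag: str = "mixed"

    def __post_init__(self) -> None:
        if self.label not in (-1, 1):
            raise ValueError(f"label must be +1 (MCIc) or -1 (MCInc), got {self.label}")
        if self.pair_tag not in PAIR_TAGS:
            raise ValueError(f"pair_tag must be one of {PAIR_TAGS}, got {self.pair_tag!r}")
        for attr in ("ct", "cv", "cs"):
            vec = np.asarray(getattr(self, attr), dtype=float)
            if vec.shape != (N_ROIS,):
                raise ValueError(
                    f"{attr} must have one value per ROI ({N_ROIS}), got shape {vec.shape}"
                )
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"{attr} of subject {self.subject_id!r} has non-finite entries")
            if np.any(vec <= 0):
                raise ValueError(
                    f"{attr} of subject {self.subject_id!r} must be strictly positive"
                )
            setattr(self, attr, vec)

    @property
    def label_name(self) -> str:
        return LABEL_NAMES[self.label]

    def mri_features(self) -> np.ndarray:
        """The 204 MRI scalars in canonical column order (CT, CV, CS blocks)."""
        return np.concatenate([self.ct, self.cv, self.cs])


@dataclass
class Cohort:
    """Ordered collection of subjects forming one diagnostic pair."""

    subjects: list[SubjectRecord]
    pair_tag: str = "mixed"

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects], dtype=int)

    def counts(self) -> dict[str, int]:
        y = self.labels
        return {"MCIc": int(np.sum(y == 1)), "MCInc": int(np.sum(y == -1))}

    def validate_two_groups(self) -> None:
        c = self.counts()
        if c["MCIc"] == 0 or c["MCInc"] == 0:
            raise ValueError(f"cohort must contain both MCIc and MCInc subjects, got {c}")

    def measure_matrix(self, category: str) -> np.ndarray:
        """n x 68 matrix of one MRI measure (CT, CV or CS)."""
        attr = {"CT": "ct", "CV": "cv", "CS": "cs"}[category]
        return np.stack([getattr(s, attr) for s in self.subjects])


@dataclass
class FeatureMatrix:
    """n-subjects x m-features design with named, categorised columns."""

    values: np.ndarray
    columns: list[str]
    labels: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, m = self.values.shape
        if len(self.columns) != m:
            raise ValueError(f"{len(self.columns)} column names for {m} columns")
        if self.labels.shape != (n,):
            raise ValueError("labels length must match number of rows")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be coded +1/-1")
        if not self.subject_ids:
            self.subject_ids = [f"s{i:04d}" for i in range(n)]
        for name in self.columns:
            parse_column_name(name)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def categories(self) -> list[str]:
        present = {parse_column_name(c)[0] for c in self.columns}
        return [c for c in ALL_CATEGORIES if c in present]

    def column_category(self, j: int) -> str:
        return parse_column_name(self.columns[j])[0]

    def select_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.columns.index(n) for n in names]
        return FeatureMatrix(
            self.values[:, idx], [self.columns[i] for i in idx],
            self.labels, list(self.subject_ids),
        )

    def category_columns(self, categories: Iterable[str]) -> list[int]:
        cats = set(categories)
        return [j for j, c in enumerate(self.columns) if parse_column_name(c)[0] in cats]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "subject_id", self.subject_ids)
        return df


# ---------------------------------------------------------------------------
# I/O


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str)


def load_feature_table(path: str | Path, labels_path: str | Path) -> Cohort:
    """Read a feature TSV plus its label TSV into a validated :class:`Cohort`.

    Row order of the feature table is preserved.  Raises :class:`SchemaError`
    when a required ``{CAT}:{ROI}_{HEMI}`` column is missing, a cell fails to
    parse as a number, or a label is not MCIc/MCInc.
    """
    df = _read_tsv(path)
    if "subject_id" not in df.columns:
        raise SchemaError(f"{path}: first column must be 'subject_id'")
    required = column_names_for(MRI_CATEGORIES)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing feature column(s) {missing[:5]}")

    values = np.empty((len(df), len(required)), dtype=float)
    for j, col in enumerate(required):
        try:
            # python-float parsing round-trips repr() output exactly
            values[:, j] = df[col].astype(float).to_numpy()
        except (TypeError, ValueError):
            parsed = pd.to_numeric(df[col], errors="coerce")
            row = int(np.where(parsed.isna())[0][0])
            raise SchemaError(
                f"{path}: non-numeric or missing value in column {col!r}, row {row}"
            ) from None
        if np.isnan(values[:, j]).any():
            row = int(np.where(np.isnan(values[:, j]))[0][0])
            raise SchemaError(
                f"{path}: non-numeric or missing value in column {col!r}, row {row}"
            )

    lab = _read_tsv(labels_path)
    for col in ("subject_id", "label"):
        if col not in lab.columns:
            raise SchemaError(f"{labels_path}: missing column {col!r}")
    bad_labels = sorted(set(lab["label"]) - set(LABEL_CODES))
    if bad_labels:
        raise SchemaError(
            f"{labels_path}: unknown label(s) {bad_labels}; expected MCIc or MCInc"
        )
    label_map = dict(zip(lab["subject_id"], lab["label"]))
    tag_map: Mapping[str, str] = (
        dict(zip(lab["subject_id"], lab["pair_tag"])) if "pair_tag" in lab.columns else {}
    )

    subjects = []
    tags = set()
    for i, sid in enumerate(df["subject_id"]):
        if sid not in label_map:
            raise SchemaError(f"{labels_path}: no label for subject {sid!r}")
        tag = tag_map.get(sid, "mixed")
        tags.add(tag)
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                label=LABEL_CODES[label_map[sid]],
                ct=values[i, :N_ROIS],
                cv=values[i, N_ROIS : 2 * N_ROIS],
                cs=values[i, 2 * N_ROIS :],
                pair_tag=tag,
            )
        )
    pair_tag = tags.pop() if len(tags) == 1 else "mixed"
    return Cohort(subjects, pair_tag=pair_tag)


def write_feature_table(cohort: Cohort, path: str | Path) -> None:
    """Write the 204 MRI features as the canonical TSV (full float precision)."""
    cols = column_names_for(MRI_CATEGORIES)
    rows = np.stack([s.mri_features() for s in cohort.subjects])
    buf = io.StringIO()
    buf.write("subject_id\t" + "\t".join(cols) + "\n")
    for sid, row in zip(cohort.subject_ids, rows):
        buf.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_labels(cohort: Cohort, path: str | Path) -> None:
    lines = ["subject_id\tlabel\tpair_tag"]
    for s in cohort.subjects:
        lines.append(f"{s.subject_id}\t{s.label_name}\t{s.pair_tag}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Feature assembly


def assemble_features(
    cohort: Cohort,
    network_features: FeatureMatrix | None = None,
    categories: Iterable[str] = ALL_CATEGORIES,
) -> FeatureMatrix:
    """Stack the requested feature categories into one design matrix.

    Columns are grouped category-major (CT, CV, CS, NL, ND order) with ROIs in
    canonical order inside each block: 68 columns per category, hence 340 when
    all five are requested, 204 for the MRI triple, 136 for the network pair.
    Network categories require ``network_features`` (see
    :func:`mciconv.network.network_features`).
    """
    cats = set(categories)
    if not cats:
        raise ValueError("categories must be a non-empty subset of " f"{ALL_CATEGORIES}")
    unknown = cats - set(ALL_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    ordered = [c for c in ALL_CATEGORIES if c in cats]

    blocks, names = [], []
    for cat in ordered:
        if cat in MRI_CATEGORIES:
            blocks.append(cohort.measure_matrix(cat))
        else:
            if network_features is None:
                raise ValueError(
                    f"category {cat!r} requested but network_features not provided"
                )
            if network_features.subject_ids != cohort.subject_ids:
                raise ValueError("network_features subjects do not match cohort")
            want = [f"{cat}:{roi}" for roi in ALL_ROI_NAMES]
            sub = network_features.select_columns(want)
            blocks.append(sub.values)
        names.extend(f"{cat}:{roi}" for roi in ALL_ROI_NAMES)

    return FeatureMatrix(
        np.hstack(blocks), names, cohort.labels, list(cohort.subject_ids)
    )
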