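"""Curation of differentially expressed miRNA reports from postmortem brain studies.

The upstream evidence is a set of per-study reports, each naming a miRNA, the
brain region it was profiled in, and the direction of dysregulation in
Parkinson's disease versus control tissue.  This module loads the study
metadata and report tables, consolidates the per-study reports into the four
analysis sets used downstream (upregulated, downregulated, substantia nigra,
putamen), flags direction conflicts and multi-study miRNAs, and computes
cohort summary statistics (medians with type-7 quartiles).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: region labels accepted in DE reports; cortical sub-areas share the
#: ``cortex_`` family prefix (e.g. ``cortex_frontal``, ``cortex_prefrontal``).
CORE_REGIONS = frozenset(
    {"substantia_nigra", "putamen", "amygdala", "cerebellum", "other"}
)

VALID_DIRECTIONS = frozenset({"up", "down"})

SUMMARY_VARIABLES = (
    "sample_size",
    "age_at_death",
    "disease_duration",
    "pmi",
    "mirnas_per_study",
)

_STAR_RE = re.compile(r"\s+\*")


def normalize_mirna_id(raw: str) -> str:
    """Normalize a miRNA identifier to the canonical form used throughout.

    Lower-case, surrounding whitespace stripped, and the star notation
    ``"miR-21 *"`` collapsed to ``"mir-21*"``.  The species prefix (``hsa-``)
    and arm suffixes (``-3p``/``-5p``) are preserved verbatim: arm variants
    are distinct mature miRNAs and are never merged.
    """
    s = str(raw).strip()
    if not s:
        raise ValueError("empty miRNA identifier")
    return _STAR_RE.sub("*", s).lower()


def _valid_region(label: str) -> bool:
    return label in CORE_REGIONS or label.startswith("cortex_")


@dataclass(frozen=True)
class StudyRecord:
    """One row of the study-characteristics table; ``None`` marks a value the
    source printed as NA."""

    study_id: str
    country: str
    brain_regions: tuple[str, ...]
    sample_size_pd: int
    age_at_death_years: float | None
    disease_duration_years: float | None
    postmortem_interval_hours: float | None
    braak_stage: float | None
    n_mirnas_reported: int
    n_up: int
    n_down: int


@dataclass(frozen=True)
class DEReport:
    """One per-study differential-expression report for a single miRNA."""

    study_id: str
    mirna_id: str
    region: str
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in VALID_DIRECTIONS:
            raise ValueError(f"invalid direction {self.direction!r}")


@dataclass(frozen=True)
class ConsolidatedDESets:
    """The four analysis sets plus conflict/provenance flags.

    ``conflicts`` is exactly ``up & down``; ``sn`` and ``putamen`` are the
    region projections of ``up | down``; ``multi_study`` holds miRNAs reported
    by more than one distinct study.
    """

    up: frozenset[str]
    down: frozenset[str]
    sn: frozenset[str]
    putamen: frozenset[str]
    conflicts: frozenset[str]
    multi_study: frozenset[str]

    @property
    def union(self) -> frozenset[str]:
        return self.up | self.down

    def by_name(self, name: str) -> frozenset[str]:
        if name not in ("up", "down", "sn", "putamen"):
            raise KeyError(name)
        return getattr(self, name)

    def expand_reports(self) -> list[DEReport]:
        """A minimal report list whose consolidation reproduces this object.

        Used for the idempotence property: members of ``multi_study`` are
        attributed to two synthetic studies, conflict miRNAs to two studies
        with opposite directions, and region members get one row per region.
        """
        rows: list[DEReport] = []
        for m in sorted(self.union):
            directions = []
            if m in self.up:
                directions.append("up")
            if m in self.down:
                directions.append("down")
            regions = []
            if m in self.sn:
                regions.append("substantia_nigra")
            if m in self.putamen:
                regions.append("putamen")
            if not regions:
                regions = ["other"]
            studies = ["x1", "x2"] if m in self.multi_study else ["x1"]
            for d in directions:
                for sid in studies:
                    for r in regions:
                        rows.append(DEReport(sid, m, r, d))
        return rows


@dataclass(frozen=True)
class CohortSummary:
    variable: str
    median: float
    q1: float
    q3: float
    n_nonmissing: int


def _parse_number(cell: str, *, row: int, column: str) -> float | None:
    """Parse a numeric cell, accepting both '.' and ',' decimal separators;
    'NA' (any case) or empty means missing."""
    s = str(cell).strip()
    if s == "" or s.upper() == "NA" or s.lower() == "nan":
        return None
    try:
        return float(s.replace(",", "."))
    except ValueError:
        raise ValueError(
            f"malformed numeric cell {cell!r} in row {row}, column {column!r}"
        ) from None


_STUDY_COLUMNS = [
    "study_id",
    "country",
    "brain_regions",
    "sample_size_pd",
    "age_at_death_years",
    "disease_duration_years",
    "postmortem_interval_hours",
    "braak_stage",
    "n_mirnas_reported",
    "n_up",
    "n_down",
]


def load_study_table(path: str | Path) -> list[StudyRecord]:
    """Load the study-characteristics TSV into :class:`StudyRecord` rows.

    ``NA`` denotes missing; decimal commas are accepted (the source table
    prints e.g. "4,25" for 4.25).  Raises on malformed numerics (naming row
    and column) and on duplicate study ids.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in _STUDY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"study table missing columns: {missing_cols}")

    records: list[StudyRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        sid = row["study_id"].strip()
        if sid in seen:
            raise ValueError(f"duplicate study_id {sid!r}")
        seen.add(sid)

        def num(col: str) -> float | None:
            return _parse_number(row[col], row=int(i) + 2, column=col)

        def count(col: str) -> int:
            v = num(col)
            if v is None or v < 0 or v != int(v):
                raise ValueError(
                    f"expected non-negative integer in row {int(i) + 2}, "
                    f"column {col!r}, got {row[col]!r}"
                )
            return int(v)

        n = count("sample_size_pd")
        if n < 1:
            raise ValueError(f"sample_size_pd must be >= 1 (study {sid!r})")
        records.append(
            StudyRecord(
                study_id=sid,
                country=row["country"].strip(),
                brain_regions=tuple(
                    r.strip() for r in row["brain_regions"].split(";") if r.strip()
                ),
                sample_size_pd=n,
                age_at_death_years=num("age_at_death_years"),
                disease_duration_years=num("disease_duration_years"),
                postmortem_interval_hours=num("postmortem_interval_hours"),
                braak_stage=num("braak_stage"),
                n_mirnas_reported=count("n_mirnas_reported"),
                n_up=count("n_up"),
                n_down=count("n_down"),
            )
        )
    return records


def load_de_reports(path: str | Path) -> list[DEReport]:
    """Load a DE-report TSV (study_id, mirna_id, region, direction) and
    normalize miRNA identifiers."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["study_id", "mirna_id", "region", "direction"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"DE report table missing columns: {missing}")
    reports = []
    for i, row in df.iterrows():
        direction = row["direction"].strip().lower()
        if direction not in VALID_DIRECTIONS:
            raise ValueError(
                f"invalid direction {row['direction']!r} in row {int(i) + 2}"
            )
        reports.append(
            DEReport(
                study_id=row["study_id"].strip(),
                mirna_id=normalize_mirna_id(row["mirna_id"]),
                region=row["region"].strip().lower(),
                direction=direction,
            )
        )
    return reports


def consolidate_de_sets(reports: Iterable[DEReport]) -> ConsolidatedDESets:
    """Consolidate per-study reports into the four deduplicated analysis sets.

    Direction sets pool all regions; the substantia nigra and putamen sets are
    the region projections of the pooled union.  A miRNA reported up by one
    study and down by another lands in ``conflicts``; one reported by more
    than one distinct study lands in ``multi_study``.
    """
    reports = list(reports)
    bad = [(i, r.region) for i, r in enumerate(reports) if not _valid_region(r.region)]
    if bad:
        raise ValueError(f"unknown region labels in rows {bad}")

    up: set[str] = set()
    down: set[str] = set()
    sn: set[str] = set()
    putamen: set[str] = set()
    studies: dict[str, set[str]] = {}
    for r in reports:
        m = normalize_mirna_id(r.mirna_id)
        (up if r.direction == "up" else down).add(m)
        if r.region == "substantia_nigra":
            sn.add(m)
        elif r.region == "putamen":
            putamen.add(m)
        studies.setdefault(m, set()).add(r.study_id)

    return ConsolidatedDESets(
        up=frozenset(up),
        down=frozenset(down),
        sn=frozenset(sn),
        putamen=frozenset(putamen),
        conflicts=frozenset(up & down),
        multi_study=frozenset(m for m, s in studies.items() if len(s) > 1),
    )


_VARIABLE_FIELD = {
    "sample_size": "sample_size_pd",
    "age_at_death": "age_at_death_years",
    "disease_duration": "disease_duration_years",
    "pmi": "postmortem_interval_hours",
    "mirnas_per_study": "n_mirnas_reported",
}


def cohort_summary(records: Sequence[StudyRecord], variable: str) -> CohortSummary:
    """Median and quartiles (linear interpolation, "type 7") of one cohort
    variable over the non-missing studies.

    Raises if ``variable`` is unknown or every study is missing the value.
    """
    if variable not in _VARIABLE_FIELD:
        raise ValueError(
            f"unknown variable {variable!r}; expected one of {SUMMARY_VARIABLES}"
        )
    values = [
        float(v)
        for r in records
        if (v := getattr(r, _VARIABLE_FIELD[variable])) is not None
    ]
    if not values:
        raise ValueError(f"no non-missing observations for {variable!r}")
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return CohortSummary(
        variable=variable,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        n_nonmissing=len(values),
    )
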