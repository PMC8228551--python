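"""Packaged in-study fixtures: study metadata, DE-miRNA reports, and the four
published target-gene lists (shipped so the set-algebra results do not depend
on reconstructing an external interaction-database snapshot)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .curation import DEReport, StudyRecord, load_de_reports, load_study_table
from .targets import TargetSets


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    ref = resources.files("mirnet_pd.data") / name
    with resources.as_file(ref) as p:
        return Path(p)


def load_packaged_studies() -> list[StudyRecord]:
    """The 19-study characteristics table."""
    return load_study_table(fixture_path("studies.tsv"))


def load_packaged_de_reports() -> list[DEReport]:
    """Per-study DE-miRNA reports transcribed from the published table."""
    return load_de_reports(fixture_path("de_reports.tsv"))


def load_packaged_target_sets() -> TargetSets:
    """The four published target-gene lists (already evidence- and
    expression-filtered upstream of this package)."""
    df = pd.read_csv(fixture_path("target_gene_sets.tsv"), sep="\t", dtype=str)
    by_name = {
        name: frozenset(df.loc[df["set_name"] == name, "gene"])
        for name in ("up", "down", "sn", "putamen")
    }
    return TargetSets(
        up_targets=by_name["up"],
        down_targets=by_name["down"],
        sn_targets=by_name["sn"],
        putamen_targets=by_name["putamen"],
    )
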