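"""Core data containers: cohorts, assay manifests, and outcome codings.

A cohort is a wide log2 abundance matrix (samples x proteins) plus a
per-sample metadata table (outcome group, age, cohort label).  Outcome
groups come from a closed vocabulary covering surgically diagnosed
adnexal-mass patients: benign tumors, borderline (low malignant
potential) tumors, and ovarian cancer stages I-II and III-IV.
Borderline samples are carried through preprocessing but excluded from
every training comparison; they are only ever scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("benign", "borderline", "stageI_II", "stageIII_IV")

#: comparison name -> (negative groups, positive groups).  The positive
#: class (coded 1) is always the cancer, or the later stage.
COMPARISONS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "benign_vs_I_II": (("benign",), ("stageI_II",)),
    "benign_vs_III_IV": (("benign",), ("stageIII_IV",)),
    "benign_vs_I_IV": (("benign",), ("stageI_II", "stageIII_IV")),
    "I_II_vs_III_IV": (("stageI_II",), ("stageIII_IV",)),
}

META_COLUMNS = ("group", "age", "cohort")
MANIFEST_COLUMNS = ("panel", "lod", "dilution_factor", "hemolysate_tolerance")


@dataclass
class CohortData:
    """Sample x protein log2 abundance matrix with aligned metadata.

    Parameters
    ----------
    matrix
        DataFrame indexed by sample id, one column per protein id,
        holding log2 abundances (NPX or log2 pg/ml).
    metadata
        DataFrame indexed by sample id with columns ``group`` (one of
        :data:`GROUPS`), ``age`` (years) and ``cohort`` (free label).
    """

    matrix: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.matrix.index.equals(self.metadata.index):
            raise ValueError("matrix and metadata sample ids differ")
        if self.matrix.columns.has_duplicates:
            raise ValueError("duplicate protein ids in matrix")
        missing = set(META_COLUMNS) - set(self.metadata.columns)
        if missing:
            raise ValueError(f"metadata lacks columns: {sorted(missing)}")
        bad = set(self.metadata["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown outcome groups: {sorted(bad)}")
        if self.matrix.isna().any().any():
            raise ValueError("matrix contains missing values")

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.matrix.columns)

    def subset_samples(self, sample_ids) -> "CohortData":
        ids = list(sample_ids)
        return CohortData(self.matrix.loc[ids], self.metadata.loc[ids])

    def subset_proteins(self, protein_ids) -> "CohortData":
        return CohortData(self.matrix[list(protein_ids)], self.metadata)

    # -- plain-text round trip ------------------------------------------------

    def write(self, matrix_path, meta_path) -> None:
        """Write matrix and metadata as TSV (sample_id as first column)."""
        self.matrix.rename_axis("sample_id").to_csv(matrix_path, sep="\t")
        self.metadata.rename_axis("sample_id").to_csv(meta_path, sep="\t")

    @classmethod
    def read(cls, matrix_path, meta_path) -> "CohortData":
        matrix = pd.read_csv(matrix_path, sep="\t", index_col="sample_id")
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        return cls(matrix, meta.loc[matrix.index])


@dataclass
class AssayManifest:
    """Per-protein measurement metadata.

    ``table`` is indexed by protein id with columns ``panel``, ``lod``
    (log2 abundance at the lower limit of detection), ``dilution_factor``
    (1:N predilution, >= 1) and ``hemolysate_tolerance`` (mg/ml of
    hemolysate below which the assay shows interference -- larger is
    more robust).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate protein ids in manifest")
        missing = set(MANIFEST_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest lacks columns: {sorted(missing)}")
        if not np.isfinite(self.table["lod"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite LOD in manifest")
        if (self.table["dilution_factor"].to_numpy(dtype=float) < 1).any():
            raise ValueError("dilution_factor must be >= 1")

    @property
    def proteins(self) -> list[str]:
        return list(self.table.index)

    def lod(self, protein_id: str) -> float:
        return float(self.table.at[protein_id, "lod"])

    def write(self, path) -> None:
        self.table.rename_axis("protein_id").to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "AssayManifest":
        return cls(pd.read_csv(path, sep="\t", index_col="protein_id"))


@dataclass
class OutcomeCoding:
    """A binary case/control coding of a cohort ("the decision").

    ``y`` is a 0/1 Series over the included samples; benign (or the
    earlier stage) codes 0, cancer (or the later stage) codes 1.
    Borderline samples never enter a coding.
    """

    comparison: str
    negative_groups: tuple[str, ...]
    positive_groups: tuple[str, ...]
    y: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.y.index)


def code_outcome(cohort: CohortData, comparison: str) -> OutcomeCoding:
    """Build the 0/1 outcome vector for a named comparison.

    Samples outside the two group sets (including all borderline
    samples) are dropped.
    """
    if comparison not in COMPARISONS:
        raise ValueError(
            f"unknown comparison {comparison!r}; one of {sorted(COMPARISONS)}"
        )
    neg, pos = COMPARISONS[comparison]
    groups = cohort.metadata["group"]
    mask = groups.isin(neg + pos)
    if not mask.any():
        raise ValueError(f"no samples in comparison {comparison!r}")
    y = groups[mask].isin(pos).astype(int)
    if y.nunique() < 2:
        raise ValueError(f"comparison {comparison!r} has a single class")
    return OutcomeCoding(comparison, neg, pos, y)


def design_matrix(
    cohort: CohortData,
    coding: OutcomeCoding,
    proteins,
    include_age: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble (X, y, feature names) for the samples of a coding."""
    proteins = list(proteins)
    missing = set(proteins) - set(cohort.proteins)
    if missing:
        raise KeyError(f"proteins absent from cohort: {sorted(missing)}")
    ids = coding.sample_ids
    X = cohort.matrix.loc[ids, proteins].to_numpy(dtype=float)
    names = list(proteins)
    if include_age:
        X = np.column_stack([X, cohort.metadata.loc[ids, "age"].to_numpy(float)])
        names.append("age")
    return X, coding.y.loc[ids].to_numpy(dtype=int), names
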