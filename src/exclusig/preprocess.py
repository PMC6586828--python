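"""Preprocessing of PEA-style abundance data.

Covers the standard steps between raw assay output and an
analysis-ready cohort: left-censoring at the per-assay lower limit of
detection (LOD), merging of multiplex panels into one matrix,
replicate averaging with detection-limit handling, and calibration of
raw custom-assay responses to absolute concentrations via standard
curves.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import AssayManifest, CohortData

IN_RANGE, BELOW_LIMIT, ABOVE_LIMIT = "in_range", "below", "above"


def replace_below_lod(matrix: pd.DataFrame, manifest: AssayManifest) -> pd.DataFrame:
    """Replace every value below its assay's LOD with the LOD itself.

    Idempotent and never decreases a value; shape is preserved.
    """
    missing = set(matrix.columns) - set(manifest.proteins)
    if missing:
        raise KeyError(f"proteins missing from manifest: {sorted(missing)}")
    lods = manifest.table["lod"].reindex(matrix.columns)
    return matrix.clip(lower=lods, axis=1)


def merge_panels(panel_cohorts: list[CohortData]) -> CohortData:
    """Merge per-panel cohorts into one matrix over the common samples.

    Proteins are the union across panels; a protein id appearing in
    several panels is kept from the first panel that provides it (the
    later duplicate assay is dropped with a warning).  Samples are
    intersected: the analysis needs every protein characterized in all
    samples.
    """
    if not panel_cohorts:
        raise ValueError("no panels to merge")
    common = panel_cohorts[0].matrix.index
    for c in panel_cohorts[1:]:
        common = common.intersection(c.matrix.index)
    if len(common) == 0:
        raise ValueError("no samples shared by all panels")
    # preserve first panel's sample order
    order = [s for s in panel_cohorts[0].samples if s in set(common)]

    pieces, seen = [], set()
    for c in panel_cohorts:
        dup = [p for p in c.proteins if p in seen]
        if dup:
            warnings.warn(
                f"dropping {len(dup)} duplicate assay(s) (keep-first): {dup[:5]}...",
                stacklevel=2,
            )
        keep = [p for p in c.proteins if p not in seen]
        seen.update(keep)
        pieces.append(c.matrix.loc[order, keep])
    matrix = pd.concat(pieces, axis=1)
    return CohortData(matrix, panel_cohorts[0].metadata.loc[order])


def average_replicates(
    replicate_table: pd.DataFrame,
    limits: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame | CohortData:
    """Average replicate concentrations and transform to log2.

    Per sample x protein, the mean of the in-range replicates is taken
    on the linear (pg/ml) scale and then log2-transformed.  If *all*
    replicates fall below (above) the detection limits no mean is
    formed; the lower (upper) limit value is used instead.

    Parameters
    ----------
    replicate_table
        Long table with columns sample_id, protein_id, replicate,
        concentration and (optionally) flag in {in_range, below, above};
        without a flag column, flags are derived from ``limits``.
    limits
        DataFrame indexed by protein id with columns ``lower`` and
        ``upper`` (linear scale).
    metadata
        If given, the result is wrapped into a :class:`CohortData`.
    """
    if len(replicate_table) == 0:
        raise ValueError("empty replicate table")
    tab = replicate_table.copy()
    lower = limits["lower"].reindex(tab["protein_id"]).to_numpy(dtype=float)
    upper = limits["upper"].reindex(tab["protein_id"]).to_numpy(dtype=float)
    if "flag" not in tab.columns:
        conc = tab["concentration"].to_numpy(dtype=float)
        tab["flag"] = np.select(
            [conc < lower, conc > upper], [BELOW_LIMIT, ABOVE_LIMIT], IN_RANGE
        )

    values: dict[tuple, float] = {}
    for (sid, pid), g in tab.groupby(["sample_id", "protein_id"], sort=False):
        in_range = g.loc[g["flag"] == IN_RANGE, "concentration"]
        if len(in_range):
            v = in_range.mean()
        elif (g["flag"] == BELOW_LIMIT).all():
            v = limits.at[pid, "lower"]
        elif (g["flag"] == ABOVE_LIMIT).all():
            v = limits.at[pid, "upper"]
        else:  # pathological mixed out-of-range: clip to limits and average
            v = g["concentration"].clip(
                limits.at[pid, "lower"], limits.at[pid, "upper"]
            ).mean()
        values[(sid, pid)] = float(v)
    means = pd.Series(values).unstack()
    # preserve first-appearance order
    means = means.reindex(
        index=tab["sample_id"].unique(), columns=tab["protein_id"].unique()
    )
    means.index.name = None
    means.columns.name = None
    matrix = np.log2(means)
    if metadata is not None:
        return CohortData(matrix, metadata.loc[matrix.index])
    return matrix


def calibrate_concentrations(
    plate: pd.DataFrame, calibrator_block: pd.DataFrame
) -> pd.DataFrame:
    """Back-calculate concentrations through per-protein standard curves.

    A piecewise log-log linear curve is drawn through the mean response
    at each non-blank calibrator level; sample responses are inverted
    through it.  Responses outside the calibrated [low, high] range are
    clamped to the range boundary concentration and flagged ``below`` /
    ``above`` so that replicate averaging can apply its limit rules.

    Raises on non-monotone calibrator means (a corrupt plate).
    """
    out_rows = []
    for pid, cal in calibrator_block.groupby("protein_id", sort=False):
        nb = cal[cal["concentration"] > 0]
        if nb["concentration"].nunique() < 2:
            raise ValueError(f"{pid}: need >= 2 non-blank calibrator levels")
        means = nb.groupby("concentration")["response"].mean().sort_index()
        if not means.is_monotonic_increasing or means.diff().dropna().le(0).any():
            raise ValueError(f"{pid}: non-monotone calibrator means")
        log_conc = np.log2(means.index.to_numpy(dtype=float))
        log_resp = np.log2(means.to_numpy(dtype=float))

        sub = plate[plate["protein_id"] == pid]
        resp = sub["response"].to_numpy(dtype=float)
        flag = np.select(
            [resp < means.iloc[0], resp > means.iloc[-1]],
            [BELOW_LIMIT, ABOVE_LIMIT],
            IN_RANGE,
        )
        with np.errstate(divide="ignore"):
            lr = np.log2(np.clip(resp, means.iloc[0], means.iloc[-1]))
        conc = 2.0 ** np.interp(lr, log_resp, log_conc)
        for (_, row), f, c in zip(sub.iterrows(), flag, conc):
            out_rows.append((row["sample_id"], pid, row["replicate"], c, f))
    return pd.DataFrame(
        out_rows, columns=["sample_id", "protein_id", "replicate", "concentration", "flag"]
    )


def calibration_limits(calibrator_block: pd.DataFrame) -> pd.DataFrame:
    """Per-protein calibrated range (low/high level concentrations)."""
    nb = calibrator_block[calibrator_block["concentration"] > 0]
    lo = nb.groupby("protein_id")["concentration"].min()
    hi = nb.groupby("protein_id")["concentration"].max()
    return pd.DataFrame({"lower": lo, "upper": hi})
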