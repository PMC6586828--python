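"""Synthetic proximity-extension-assay cohorts and custom-assay plates.

The generator emulates the statistical structure a plasma-proteome
biomarker search assumes: correlated blocks of log2-scale protein
abundances, planted stage-dependent case/control mean shifts, per-assay
lower-limit-of-detection (LOD) left-censoring, and calibrator-based
custom plates with replicate measurements.

All abundances live on a log2 scale (the PEA convention: NPX for the
multiplex panels, log2 pg/ml for calibrated custom assays) and all
planted effects are additive on that scale.  Within-block correlation
is equicorrelated; planted signal proteins occupy the leading block
positions so that correlated null "proxy" proteins arise naturally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import GROUPS, AssayManifest, CohortData

#: Group sizes and age distributions default to a discovery-style
#: adnexal-mass cohort (benign-heavy, ages around 60 +/- 15 years).
DEFAULT_N_PER_GROUP = {"benign": 90, "stageI_II": 42, "stageIII_IV": 37}
DEFAULT_AGE_MEANS_SDS = {
    "benign": (60.0, 16.8),
    "borderline": (49.4, 19.6),
    "stageI_II": (60.7, 12.4),
    "stageIII_IV": (63.8, 14.1),
}
#: Planted per-protein shifts, in within-group SD units.  Benign is the
#: reference (0 by definition); late-stage disease separates more than
#: early-stage, borderline sits between benign and stage I-II.
DEFAULT_EFFECT_SIZES = {
    "benign": 0.0,
    "borderline": 0.5,
    "stageI_II": 1.0,
    "stageIII_IV": 1.5,
}

AGE_BOUNDS = (18.0, 100.0)


@dataclass
class CohortConfig:
    """Configuration of one synthetic case/control cohort.

    Attributes
    ----------
    n_per_group
        Samples per outcome group; groups absent from the mapping are
        not generated.
    n_proteins, n_signal
        Total assayed proteins and how many carry a planted effect.
        Signal proteins are the first ``n_signal`` protein ids.
    effect_sizes
        Per-group mean shift of every signal protein, in within-group
        SD units.  Benign must be 0.
    block_size, block_rho
        Proteins are partitioned into consecutive correlation blocks of
        ``block_size`` with equicorrelation ``block_rho`` in [0, 1).
    lod_quantile
        Per-protein LOD is placed at this quantile of the benign-group
        distribution; values below it are left-censored at the LOD.
    age_means_sds
        Per-group (mean, SD) of age in years, truncated to [18, 100].
    seed
        Master seed; fixed seed gives bit-identical output.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP)
    )
    n_proteins: int = 100
    n_signal: int = 3
    effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    block_size: int = 5
    block_rho: float = 0.5
    lod_quantile: float = 0.05
    age_means_sds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_MEANS_SDS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.n_per_group) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups: {sorted(bad)}")
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be positive")
        if not 0 < self.n_signal <= self.n_proteins:
            if self.n_signal > self.n_proteins:
                raise ValueError("n_signal > n_proteins")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("lod_quantile must be in [0, 1)")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0, 1)")
        if self.effect_sizes.get("benign", 0.0) != 0.0:
            raise ValueError("benign effect size must be 0")
        if "benign" in self.n_per_group and self.n_per_group["benign"] < 2:
            raise ValueError("need >= 2 benign samples to place LODs")

    @property
    def groups(self) -> list[str]:
        return [g for g in GROUPS if g in self.n_per_group]


def _protein_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(n)]


def _block_of(j: int, block_size: int) -> int:
    return j // block_size


def _truncated_normal(rng, mean, sd, size, bounds=AGE_BOUNDS):
    lo, hi = bounds
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    config: CohortConfig,
) -> tuple[CohortData, AssayManifest, dict]:
    """Draw one synthetic cohort plus its manifest and truth record.

    Returns
    -------
    cohort
        :class:`~exclusig.data.CohortData` of LOD-censored log2
        abundances (unit within-group SD before censoring).
    manifest
        :class:`~exclusig.data.AssayManifest` with the realised LODs and
        practicality annotations (dilution, hemolysate tolerance).
    truth
        Dict with the planted signal protein ids, per-group effect
        sizes, block assignment and correlation, for oracle checks.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_proteins
    proteins = _protein_ids(p)
    signal = proteins[: config.n_signal]

    groups = config.groups
    sizes = [int(config.n_per_group[g]) for g in groups]
    n_total = sum(sizes)
    group_col = np.repeat(groups, sizes)

    # baseline per-protein means, NPX-like
    mu = rng.normal(5.0, 2.0, size=p)

    # block-equicorrelated unit-variance noise:
    # x_j = sqrt(rho) * u_block(j) + sqrt(1 - rho) * eps_j
    n_blocks = _block_of(p - 1, config.block_size) + 1
    u = rng.standard_normal((n_total, n_blocks))
    eps = rng.standard_normal((n_total, p))
    block_idx = np.array([_block_of(j, config.block_size) for j in range(p)])
    rho = config.block_rho
    X = np.sqrt(rho) * u[:, block_idx] + np.sqrt(1.0 - rho) * eps
    X += mu

    # planted shifts on signal proteins, per outcome group
    shift = np.array([float(config.effect_sizes.get(g, 0.0)) for g in group_col])
    X[:, : config.n_signal] += shift[:, None]

    # ages
    age = np.empty(n_total)
    start = 0
    for g, n_g in zip(groups, sizes):
        mean, sd = config.age_means_sds.get(g, (60.0, 15.0))
        age[start : start + n_g] = _truncated_normal(rng, mean, sd, n_g)
        start += n_g

    sample_ids = [f"S{i:04d}" for i in range(n_total)]
    matrix = pd.DataFrame(X, index=sample_ids, columns=proteins)

    # per-protein LOD at a quantile of the benign-group distribution
    benign_mask = group_col == "benign"
    ref = matrix.loc[benign_mask] if benign_mask.any() else matrix
    if config.lod_quantile > 0:
        lod = ref.quantile(config.lod_quantile)
    else:
        lod = ref.min() - 6.0  # effectively uncensored
    matrix = matrix.clip(lower=lod, axis=1)

    metadata = pd.DataFrame(
        {"group": group_col, "age": age, "cohort": "synthetic"},
        index=sample_ids,
    )
    cohort = CohortData(matrix, metadata)

    # manifest: panels of ~92 assays, practicality annotations drawn once
    panel = [f"panel_{_block_of(j, 92) + 1}" for j in range(p)]
    dilution = rng.choice([1.0, 45.0, 2025.0], size=p, p=[0.85, 0.10, 0.05])
    hemolysate = rng.choice([2.5, 7.5, 20.0, 50.0], size=p, p=[0.05, 0.05, 0.30, 0.60])
    manifest = AssayManifest(
        pd.DataFrame(
            {
                "panel": panel,
                "lod": lod.to_numpy(),
                "dilution_factor": dilution,
                "hemolysate_tolerance": hemolysate,
            },
            index=pd.Index(proteins, name="protein_id"),
        )
    )

    truth = {
        "signal_proteins": signal,
        "effect_sizes": {g: float(config.effect_sizes.get(g, 0.0)) for g in groups},
        "block_size": config.block_size,
        "block_rho": config.block_rho,
        "blocks": {pid: int(_block_of(j, config.block_size)) for j, pid in enumerate(proteins)},
        "n_proteins": p,
        "seed": config.seed,
    }
    return cohort, manifest, truth


def same_block_proxies(truth: dict) -> set[str]:
    """Signal proteins plus the null proteins sharing their blocks."""
    blocks = truth["blocks"]
    signal_blocks = {blocks[pid] for pid in truth["signal_proteins"]}
    return {pid for pid, b in blocks.items() if b in signal_blocks}


def optimal_auc(config: CohortConfig, case_group: str, include_age: bool = False) -> float:
    """Analytic optimal AUC of benign vs one case group.

    Under the generator the two classes are homoscedastic Gaussians on
    the log2 scale (before censoring), so the best achievable AUC is
    Phi(d / sqrt(2)) with d^2 the Mahalanobis distance between the
    class means.  Age, independent of the proteins, adds its own
    squared standardized shift (using the benign SD; exact when the
    case group shares it, and ignoring the mild [18, 100] truncation).
    """
    p = config.n_proteins
    delta = np.zeros(p)
    delta[: config.n_signal] = float(config.effect_sizes[case_group])
    block_idx = np.array([_block_of(j, config.block_size) for j in range(p)])
    rho = config.block_rho
    d2 = 0.0
    for b in np.unique(block_idx):
        db = delta[block_idx == b]
        if not db.any():
            continue
        k = len(db)
        sigma = np.full((k, k), rho) + (1 - rho) * np.eye(k)
        d2 += float(db @ np.linalg.solve(sigma, db))
    if include_age:
        mu_b, sd_b = config.age_means_sds["benign"]
        mu_c, _ = config.age_means_sds[case_group]
        d2 += ((mu_c - mu_b) / sd_b) ** 2
    return float(stats.norm.cdf(np.sqrt(d2) / np.sqrt(2.0)))


# ---------------------------------------------------------------------------
# custom-assay plates


def generate_custom_assay(
    proteins: Sequence[str],
    true_concentrations: pd.DataFrame,
    calibrator_levels: Sequence[float],
    n_replicates: int = 2,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a custom multiplex plate with calibrator standards.

    The raw response of each assay is a monotone log-linear function of
    the true concentration: log2 response = a_j + b_j * log2(conc), with
    b_j > 0, plus Gaussian noise of ``noise_sd`` log2 units.  A blank
    calibrator (concentration 0) responds at the assay background,
    placed below the lowest non-blank level.  Calibrators are always
    measured in triplicate; samples in ``n_replicates`` replicates.

    Parameters
    ----------
    true_concentrations
        DataFrame (samples x proteins) of true pg/ml values.
    calibrator_levels
        Strictly increasing concentrations; the first must be 0 (blank)
        and at least two non-blank levels are required.

    Returns
    -------
    plate
        Long table: sample_id, protein_id, replicate, response (linear).
    calibrators
        Long table: level, concentration, protein_id, replicate, response.
    """
    levels = [float(v) for v in calibrator_levels]
    if levels[0] != 0.0:
        raise ValueError("first calibrator level must be blank (0)")
    nonblank = levels[1:]
    if len(nonblank) < 2:
        raise ValueError("need at least 2 non-blank calibrator levels")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("calibrator levels must be strictly increasing")
    if n_replicates not in (2, 3):
        raise ValueError("n_replicates must be 2 or 3")
    proteins = list(proteins)
    missing = set(proteins) - set(true_concentrations.columns)
    if missing:
        raise KeyError(f"concentrations missing for: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    slope = rng.uniform(0.8, 1.2, size=len(proteins))
    intercept = rng.uniform(-1.0, 1.0, size=len(proteins))
    # blank responds as if at a floor concentration well below the low level
    floor = nonblank[0] / 8.0

    def response(conc: np.ndarray, j: int, size) -> np.ndarray:
        c = np.maximum(np.asarray(conc, dtype=float), floor)
        log2_resp = intercept[j] + slope[j] * np.log2(c)
        log2_resp = log2_resp + rng.normal(0.0, noise_sd, size=size)
        return 2.0**log2_resp

    level_names = ["blank", "low", "mid", "high"][: len(levels)]
    cal_rows = []
    for name, conc in zip(level_names, levels):
        for j, pid in enumerate(proteins):
            resp = response(np.full(3, conc), j, 3)
            for r in range(3):
                cal_rows.append((name, conc, pid, r + 1, resp[r]))
    calibrators = pd.DataFrame(
        cal_rows, columns=["level", "concentration", "protein_id", "replicate", "response"]
    )

    rows = []
    for j, pid in enumerate(proteins):
        conc = true_concentrations[pid].to_numpy(dtype=float)
        for r in range(n_replicates):
            resp = response(conc, j, len(conc))
            rows.extend(
                zip(true_concentrations.index, [pid] * len(conc), [r + 1] * len(conc), resp)
            )
    plate = pd.DataFrame(rows, columns=["sample_id", "protein_id", "replicate", "response"])
    return plate, calibrators


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
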