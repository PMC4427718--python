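"""Seeded synthetic datasets with planted ground truth.

Two generators emulate the study's two platforms:

* :func:`generate_mrna_dataset` — a summarized log2 gene-expression
  matrix over the gene-expression design (parenchyma 2/2/5/5, tumor
  8/8/6/9 across sham/L/M/H), with interaction effects planted on
  chosen features.
* :func:`generate_mirna_dataset` — a miRNA-like dataset over the miRNA
  design (parenchyma 10 per dose group, tumor 8/7/6/9), optionally at
  raw probe level with replicate spots, planted always-absent features,
  and extra low-correlation outlier arrays, so the full preprocessing
  chain (background correction, normalization, summarization, detection
  filtering, array QC) can be exercised end to end.

Every feature's expectation is ``baseline + x' beta`` through the
eight-term indicator design of :mod:`ajlung.interaction`; residuals are
i.i.d. Gaussian on the log2 scale.  The returned truth table records
each feature's planted class and coefficient vector for recovery
scoring.  Identical configurations (including the seed) give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .interaction import DOSES, TERMS, TISSUES, build_design_matrix

#: Tissue-by-dose sample counts of the gene-expression design.
TABLE1_GROUPS: dict[tuple[str, str], int] = {
    ("P", "sham"): 2,
    ("P", "L"): 2,
    ("P", "M"): 5,
    ("P", "H"): 5,
    ("T", "sham"): 8,
    ("T", "L"): 8,
    ("T", "M"): 6,
    ("T", "H"): 9,
}

#: Tissue-by-dose sample counts of the miRNA design.
TABLE2_GROUPS: dict[tuple[str, str], int] = {
    ("P", "sham"): 10,
    ("P", "L"): 10,
    ("P", "M"): 10,
    ("P", "H"): 10,
    ("T", "sham"): 8,
    ("T", "L"): 7,
    ("T", "M"): 6,
    ("T", "H"): 9,
}

# Unit coefficient patterns per terminal category of the miRNA subset
# tree.  Scaled by the effect size; all nonzero planted contrasts have
# magnitude >= 1 unit so every category is identifiable at raw alpha
# when the effect is large against the residual SD.  The four contrasts
# that drive classification are ms_in_parenchyma = doH,
# ms_in_tumor = doH + CeT:doH, tissue_in_sham = CeT and
# tissue_in_ms = CeT + CeT:doH.
FIGURE8_CATEGORIES: dict[str, dict[str, float]] = {
    # smoke alters the feature in parenchyma but not in tumors
    "parenchyma-only/exposure-only": {"doH": 1, "CeT:doH": -1},
    "parenchyma-only/tissue-effect-vanishes": {"CeT": 1, "doH": 1, "CeT:doH": -1},
    "parenchyma-only/tissue-both/mixed": {"CeT": 1, "doH": 2, "CeT:doH": -2},
    "parenchyma-only/tissue-both/tumor-high": {"CeT": 2, "doH": 1, "CeT:doH": -1},
    "parenchyma-only/tissue-both/tumor-low": {"CeT": -2, "doH": -1, "CeT:doH": 1},
    # smoke alters the feature in tumors only
    "tumor-only": {"CeT:doH": 1},
    # smoke alters the feature in both tissues, in opposite directions
    "both/discordant": {"doH": -1, "CeT:doH": 2},
    # ... or in the same direction
    "both/concordant": {"doH": 1, "CeT:doH": 1},
}

#: Reported subgroup sizes of the miRNA subset tree (70 total).
FIGURE8_MEMBERSHIP: dict[str, int] = {
    "parenchyma-only/exposure-only": 3,
    "parenchyma-only/tissue-effect-vanishes": 35,
    "parenchyma-only/tissue-both/mixed": 2,
    "parenchyma-only/tissue-both/tumor-high": 5,
    "parenchyma-only/tissue-both/tumor-low": 17,
    "tumor-only": 3,
    "both/discordant": 4,
    "both/concordant": 1,
}

#: A pure difference-in-differences effect with no marginal smoke effect.
INTERACTION_ONLY = "interaction-only"

_CLASS_BETAS = dict(FIGURE8_CATEGORIES)
_CLASS_BETAS[INTERACTION_ONLY] = {"CeT:doH": 1}

#: Raw intensity written for planted always-absent miRNA features.  A
#: shared constant, so the per-array 5th-percentile detection threshold
#: ties with them and the "ties are absent" rule removes them exactly.
ABSENT_RAW_INTENSITY = 1.0


@dataclass(frozen=True)
class EffectClass:
    """``count`` features planted with the unit pattern of ``label``
    scaled by ``effect_size`` (log2 units)."""

    label: str
    count: int
    effect_size: float = 1.0

    def betas(self) -> dict[str, float]:
        if self.label not in _CLASS_BETAS:
            raise ValueError(
                f"unknown effect class {self.label!r}; known: {sorted(_CLASS_BETAS)}"
            )
        return {t: w * self.effect_size for t, w in _CLASS_BETAS[self.label].items()}


def figure8_effect_classes(effect_size: float = 1.0) -> list[EffectClass]:
    """The eight terminal subgroups at their reported sizes."""
    return [
        EffectClass(label, count, effect_size)
        for label, count in FIGURE8_MEMBERSHIP.items()
    ]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic dataset.

    Parameters
    ----------
    n_features : int
        Total features, planted plus null.
    group_sizes : mapping (tissue, dose) -> count
        Samples per design cell; all eight cells must be non-empty.
    effect_classes : sequence of EffectClass
        Planted effects; remaining features are null.
    baseline_mean_range : (low, high)
        Per-feature baseline drawn uniformly, log2 units.
    residual_sd : float
        SD of the i.i.d. Gaussian noise, log2 units.
    probe_per_feature : int
        Replicate spots per feature in probe-level output.
    outlier_arrays : int
        Extra arrays appended with within-array permuted values
        (destroying between-array correlation).
    absent_fraction : float
        Fraction of features written at a constant sub-threshold raw
        intensity (miRNA probe-level output only).
    seed : int
        Seed for all randomness.
    """

    n_features: int
    group_sizes: Mapping[tuple[str, str], int]
    effect_classes: Sequence[EffectClass] = field(default_factory=tuple)
    baseline_mean_range: tuple[float, float] = (6.0, 12.0)
    residual_sd: float = 0.25
    probe_per_feature: int = 1
    outlier_arrays: int = 0
    absent_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        if not 0.0 <= self.absent_fraction <= 1.0:
            raise ValueError("absent_fraction must lie in [0, 1]")
        if self.probe_per_feature < 1 or self.outlier_arrays < 0:
            raise ValueError("counts must be non-negative")
        for tis in TISSUES:
            for dose in DOSES:
                if self.group_sizes.get((tis, dose), 0) <= 0:
                    raise ValueError(f"empty design cell {tis}/{dose}")
        planted = sum(ec.count for ec in self.effect_classes)
        if planted > self.n_features:
            raise ValueError(
                f"{planted} planted features exceed n_features={self.n_features}"
            )


def default_mrna_config(**overrides) -> SimConfig:
    """Gene-expression-like defaults: Table-1 cells, no planted effects."""
    base = dict(n_features=2000, group_sizes=TABLE1_GROUPS)
    base.update(overrides)
    return SimConfig(**base)


def default_mirna_config(**overrides) -> SimConfig:
    """miRNA-like defaults reproducing the published pipeline geometry.

    289 features with a tenth planted absent (29) leave 260 after the
    detection filter; the 70 design arrays plus one planted outlier give
    70 columns after QC exclusion — the published 260x70 matrix shape.
    """
    base = dict(
        n_features=289,
        group_sizes=TABLE2_GROUPS,
        effect_classes=tuple(figure8_effect_classes(1.0)),
        probe_per_feature=4,
        outlier_arrays=1,
        absent_fraction=0.1,
    )
    base.update(overrides)
    return SimConfig(**base)


def build_sample_sheet(group_sizes: Mapping[tuple[str, str], int]) -> pd.DataFrame:
    """Sample sheet with one row per sample, ids ``{tissue}_{dose}_{i}``."""
    rows = []
    for (tis, dose), n in group_sizes.items():
        for i in range(1, n + 1):
            rows.append(
                {
                    "sample_id": f"{tis}_{dose}_{i:02d}",
                    "tissue": tis,
                    "dose": dose,
                    "animal_id": f"{tis}_{dose}_a{i:02d}",
                    "is_replicate": False,
                }
            )
    return pd.DataFrame(rows)


def _planted_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Truth table: feature id, class label, and the 8 planted betas."""
    feature_ids = [f"feat_{i:05d}" for i in range(1, config.n_features + 1)]
    truth = pd.DataFrame(
        0.0,
        index=pd.Index(feature_ids, name="feature_id"),
        columns=[f"beta_{t}" for t in TERMS],
    )
    truth.insert(0, "true_class", "null")
    pos = 0
    for ec in config.effect_classes:
        betas = ec.betas()
        for _ in range(ec.count):
            fid = feature_ids[pos]
            truth.loc[fid, "true_class"] = ec.label
            for term, val in betas.items():
                truth.loc[fid, f"beta_{term}"] = val
            pos += 1
    truth["beta_intercept"] = rng.uniform(*config.baseline_mean_range, config.n_features)
    return truth


def _expression_from_truth(
    truth: pd.DataFrame, design: pd.DataFrame, residual_sd: float, rng: np.random.Generator
) -> pd.DataFrame:
    B = truth[[f"beta_{t}" for t in TERMS]].to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    mean = B @ X.T
    noise = rng.normal(0.0, residual_sd, mean.shape) if residual_sd > 0 else 0.0
    return pd.DataFrame(mean + noise, index=truth.index, columns=design.index)


def generate_mrna_dataset(
    config: SimConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Summarized log2 gene-expression matrix with planted effects.

    Returns ``(matrix, sample_sheet, truth_table)``; matrix rows are
    features, columns samples.
    """
    config = config or default_mrna_config()
    rng = np.random.default_rng(config.seed)
    sheet = build_sample_sheet(config.group_sizes)
    design = build_design_matrix(sheet)
    truth = _planted_truth(config, rng)
    matrix = _expression_from_truth(truth, design, config.residual_sd, rng)
    return matrix, sheet, truth


def generate_mirna_dataset(
    config: SimConfig | None = None, level: str = "probe"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """miRNA-like dataset over the miRNA design.

    With ``level="probe"`` (default) the matrix holds raw-scale
    intensities with ``probe_per_feature`` replicate rows per feature
    (probe ids ``{feature}|p{k}``), planted-absent features at a
    constant sub-threshold intensity, and ``outlier_arrays`` extra
    permuted arrays flagged as replicates in the sample sheet.  With
    ``level="summary"`` the matrix is the summarized log2
    feature-by-sample matrix (no probes, no absent plumbing, no
    outliers) ready for model fitting.
    """
    config = config or default_mirna_config()
    if level not in ("probe", "summary"):
        raise ValueError("level must be 'probe' or 'summary'")
    rng = np.random.default_rng(config.seed)
    sheet = build_sample_sheet(config.group_sizes)
    design = build_design_matrix(sheet)
    truth = _planted_truth(config, rng)

    if level == "summary":
        matrix = _expression_from_truth(truth, design, config.residual_sd, rng)
        return matrix, sheet, truth

    n_absent = int(round(config.absent_fraction * config.n_features))
    # absent status lands on the tail (null) features, never on planted ones
    planted = sum(ec.count for ec in config.effect_classes)
    if planted + n_absent > config.n_features:
        raise ValueError("absent_fraction leaves no room for planted features")
    absent_ids = list(truth.index[config.n_features - n_absent :])
    truth["is_absent"] = truth.index.isin(absent_ids)

    expect = truth[[f"beta_{t}" for t in TERMS]].to_numpy() @ design.to_numpy().T
    reps = []
    for _ in range(config.probe_per_feature):
        noise = (
            rng.normal(0.0, config.residual_sd, expect.shape)
            if config.residual_sd > 0
            else 0.0
        )
        reps.append(expect + noise)
    # (n_features, probes, n_samples) -> feature-major probe rows
    log2 = np.stack(reps, axis=1).reshape(-1, expect.shape[1])
    probe_ids = [
        f"{fid}|p{k + 1}"
        for fid in truth.index
        for k in range(config.probe_per_feature)
    ]
    raw = pd.DataFrame(
        np.power(2.0, log2),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=design.index,
    )
    absent_probe = raw.index.str.split("|").str[0].isin(absent_ids)
    raw.loc[absent_probe, :] = ABSENT_RAW_INTENSITY

    for j in range(config.outlier_arrays):
        sid = f"P_sham_x{j + 1:02d}"
        donor = raw.iloc[:, 0].to_numpy()
        raw[sid] = rng.permutation(donor)
        sheet = pd.concat(
            [
                sheet,
                pd.DataFrame(
                    [
                        {
                            "sample_id": sid,
                            "tissue": "P",
                            "dose": "sham",
                            "animal_id": "P_sham_a01",
                            "is_replicate": True,
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
    return raw, sheet, truth


# ---------------------------------------------------------------------------
# plain-text IO (TSV: first column feature id, header row sample ids)

def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6f")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", float_format="%.6f")


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
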