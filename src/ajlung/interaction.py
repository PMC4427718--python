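"""Per-feature tissue-by-dose interaction model.

The study design crosses two tissue types (tumor ``T`` and surrounding
non-tumorous parenchyma ``P``) with four smoke-exposure groups (``sham``
plus three mainstream-smoke concentrations ``L``/``M``/``H``).  Each
feature (gene or miRNA, log2 intensity) is modelled by ordinary least
squares on an eight-column indicator design::

    y = b0 + b1*CeT + b2*doL + b3*doM + b4*doH
           + b5*CeT:doL + b6*CeT:doM + b7*CeT:doH + e

``CeT`` indicates tumor tissue and ``doL``/``doM``/``doH`` the dose
groups; the interaction columns are their products.  With all eight
tissue-by-dose cells occupied the model is saturated in the cell means,
so ``CeT:doH`` estimates the difference-in-differences
``(T_H - P_H) - (T_sham - P_sham)``: how the tumor-vs-parenchyma
difference under the highest dose departs from the same difference in
sham animals.  Samples are treated as independent.

The entry point is :class:`InteractionModel`, whose :meth:`fit` returns
an :class:`InteractionResults` carrying estimates, standard errors,
per-term t tests, Benjamini-Hochberg q-values across features, and
arbitrary linear contrasts of the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TERMS: tuple[str, ...] = (
    "intercept",
    "CeT",
    "doL",
    "doM",
    "doH",
    "CeT:doL",
    "CeT:doM",
    "CeT:doH",
)
TISSUES: tuple[str, ...] = ("T", "P")
DOSES: tuple[str, ...] = ("sham", "L", "M", "H")


def build_design_matrix(sheet: pd.DataFrame) -> pd.DataFrame:
    """Build the 8-column 0/1 interaction design from a sample sheet.

    Parameters
    ----------
    sheet : DataFrame
        Must contain columns ``sample_id``, ``tissue`` (``T``/``P``) and
        ``dose`` (``sham``/``L``/``M``/``H``).

    Returns
    -------
    DataFrame indexed by sample id with columns :data:`TERMS`.  A sham
    parenchyma sample codes to ``(1, 0, 0, 0, 0, 0, 0, 0)``.
    """
    for col in ("sample_id", "tissue", "dose"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet lacks required column {col!r}")
    X = pd.DataFrame(
        0.0, index=pd.Index(sheet["sample_id"], name="sample_id"), columns=list(TERMS)
    )
    X["intercept"] = 1.0
    for sid, tissue, dose in zip(sheet["sample_id"], sheet["tissue"], sheet["dose"]):
        if tissue not in TISSUES:
            raise ValueError(f"sample {sid!r}: unknown tissue level {tissue!r}")
        if dose not in DOSES:
            raise ValueError(f"sample {sid!r}: unknown dose level {dose!r}")
        tum = tissue == "T"
        if tum:
            X.loc[sid, "CeT"] = 1.0
        if dose != "sham":
            X.loc[sid, f"do{dose}"] = 1.0
            if tum:
                X.loc[sid, f"CeT:do{dose}"] = 1.0
    return X


@dataclass(frozen=True)
class Contrast:
    """A named linear combination of the eight model coefficients."""

    name: str
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.weights) != len(TERMS):
            raise ValueError(f"contrast {self.name!r}: expected {len(TERMS)} weights")
        if not any(w != 0 for w in self.weights):
            raise ValueError(f"contrast {self.name!r}: all weights are zero")

    @classmethod
    def from_terms(cls, name: str, weights: Mapping[str, float]) -> "Contrast":
        unknown = set(weights) - set(TERMS)
        if unknown:
            raise ValueError(f"unknown terms in contrast: {sorted(unknown)}")
        return cls(name, tuple(float(weights.get(t, 0.0)) for t in TERMS))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


#: Mainstream-smoke effect within tumors at the highest dose: T_H - T_sham.
MS_IN_TUMOR = Contrast.from_terms("ms_in_tumor", {"doH": 1, "CeT:doH": 1})
#: Mainstream-smoke effect within parenchyma at the highest dose: P_H - P_sham.
MS_IN_PARENCHYMA = Contrast.from_terms("ms_in_parenchyma", {"doH": 1})
#: Tumor-vs-parenchyma difference in sham animals.
TISSUE_IN_SHAM = Contrast.from_terms("tissue_in_sham", {"CeT": 1})
#: Tumor-vs-parenchyma difference in the high-dose animals.
TISSUE_IN_MS = Contrast.from_terms("tissue_in_ms", {"CeT": 1, "CeT:doH": 1})


def bh_adjust(pvalues: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Thresholding the returned q-values at ``alpha`` selects exactly the
    BH rejection set at level ``alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=0.05, method="fdr_bh")[1]


class InteractionModel:
    """Per-feature OLS of a log2 expression matrix on the interaction design.

    Parameters
    ----------
    matrix : DataFrame
        Features x samples, log2 scale.
    design : DataFrame
        Samples x 8 design, e.g. from :func:`build_design_matrix`.  Its
        index must cover the matrix columns.
    """

    def __init__(self, matrix: pd.DataFrame, design: pd.DataFrame) -> None:
        missing = [c for c in matrix.columns if c not in design.index]
        if missing:
            raise ValueError(f"design lacks rows for samples: {missing[:5]}")
        self.matrix = matrix
        self.design = design.loc[matrix.columns, list(TERMS)]
        if matrix.shape[1] <= len(TERMS):
            raise ValueError("need more samples than model terms")
        X = self.design.to_numpy(dtype=float)
        if np.linalg.matrix_rank(X) < len(TERMS):
            raise ValueError(
                "design matrix is rank deficient; empty tissue-by-dose cells: "
                f"{self._empty_cells()}"
            )

    @classmethod
    def from_dataframes(cls, matrix: pd.DataFrame, sheet: pd.DataFrame) -> "InteractionModel":
        """Construct from an expression matrix and a sample sheet."""
        return cls(matrix, build_design_matrix(sheet))

    def _empty_cells(self) -> list[str]:
        X = self.design
        cells = []
        for tis in TISSUES:
            for dose in DOSES:
                tum = (X["CeT"] == (1.0 if tis == "T" else 0.0))
                if dose == "sham":
                    dos = (X[["doL", "doM", "doH"]].sum(axis=1) == 0)
                else:
                    dos = X[f"do{dose}"] == 1.0
                if not (tum & dos).any():
                    cells.append(f"{tis}/{dose}")
        return cells

    def fit(self) -> "InteractionResults":
        X = self.design.to_numpy(dtype=float)
        Y = self.matrix.to_numpy(dtype=float)
        n, k = X.shape
        xtx = X.T @ X
        xtx_inv = np.linalg.inv(xtx)
        beta = Y @ X @ xtx_inv.T  # features x 8
        resid = Y - beta @ X.T
        df_resid = n - k
        scale = (resid**2).sum(axis=1) / df_resid
        bse = np.sqrt(np.outer(scale, np.diag(xtx_inv)))
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(bse > 0, beta / bse, 0.0)
        pval = 2.0 * stats.t.sf(np.abs(tval), df_resid)
        idx = self.matrix.index
        return InteractionResults(
            params=pd.DataFrame(beta, index=idx, columns=list(TERMS)),
            bse=pd.DataFrame(bse, index=idx, columns=list(TERMS)),
            tvalues=pd.DataFrame(tval, index=idx, columns=list(TERMS)),
            pvalues=pd.DataFrame(pval, index=idx, columns=list(TERMS)),
            scale=pd.Series(scale, index=idx, name="scale"),
            df_resid=df_resid,
            cov_unscaled=xtx_inv,
            model=self,
        )


@dataclass
class InteractionResults:
    """Fitted per-feature interaction model.

    Coefficients are on the log2 scale; ``df_resid = n_samples - 8``.
    """

    params: pd.DataFrame
    bse: pd.DataFrame
    tvalues: pd.DataFrame
    pvalues: pd.DataFrame
    scale: pd.Series
    df_resid: int
    cov_unscaled: np.ndarray
    model: InteractionModel | None = None
    _qcache: dict = field(default_factory=dict, repr=False)

    def test_term(self, term: str) -> pd.Series:
        """Two-sided t-test p-values for a single model term."""
        if term not in TERMS:
            raise ValueError(f"unknown term {term!r}; expected one of {TERMS}")
        return self.pvalues[term]

    def qvalues(self, term: str) -> pd.Series:
        """BH q-values for a term, adjusted across features within the term."""
        if term not in self._qcache:
            self._qcache[term] = pd.Series(
                bh_adjust(self.test_term(term).to_numpy()),
                index=self.params.index,
                name=f"q[{term}]",
            )
        return self._qcache[term]

    def test_contrast(self, contrast: Contrast) -> pd.DataFrame:
        """t-test of ``w . beta`` per feature using the coefficient covariance.

        Returns a DataFrame with columns ``estimate``, ``se``, ``tvalue``,
        ``pvalue``.
        """
        w = contrast.as_array()
        est = self.params.to_numpy() @ w
        var_factor = float(w @ self.cov_unscaled @ w)
        se = np.sqrt(self.scale.to_numpy() * var_factor)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), self.df_resid)
        return pd.DataFrame(
            {"estimate": est, "se": se, "tvalue": t, "pvalue": p},
            index=self.params.index,
        )

    def summary(self, term: str = "CeT:doH", fdr: float | None = None) -> pd.DataFrame:
        """Per-feature table for one term, sorted by p-value.

        Columns: estimate, se, t, p, q.  With ``fdr`` given, restrict to
        features passing that q-value cutoff.
        """
        tab = pd.DataFrame(
            {
                "estimate": self.params[term],
                "se": self.bse[term],
                "tvalue": self.tvalues[term],
                "pvalue": self.pvalues[term],
                "qvalue": self.qvalues(term),
            }
        ).sort_values("pvalue", kind="mergesort")
        if fdr is not None:
            tab = tab[tab["qvalue"] < fdr]
        return tab

    def significant(self, term: str = "CeT:doH", fdr: float = 0.05) -> pd.Index:
        """Feature ids whose BH q-value for ``term`` is below ``fdr``."""
        q = self.qvalues(term)
        return self.params.index[q.to_numpy() < fdr]
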