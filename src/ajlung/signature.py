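"""Resampling-based discriminative gene-signature extraction.

The procedure distinguishes spontaneously arising tumors (sham-exposed
animals) from smoke-related tumors (high-dose animals) with a fixed
signature size ``N`` and resampling count ``R``:

1. stratified random split into a training set (20% of samples per
   class) and a test set (the remainder);
2. rank genes on the training set by the SAM d-statistic
   ``d = (mean_1 - mean_2) / (s + s0)`` and keep the top ``N``;
3. train a linear support-vector machine on those ``N`` genes;
4. record the test-set misclassification fraction ``P(N, iter)``.

After ``R`` repetitions the consensus signature is the ``N`` genes most
frequently selected across iterations, and the overall error estimate
is ``Per(N)``, the mean of the recorded ``P(N, iter)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC


@dataclass(frozen=True)
class SignatureConfig:
    """Knobs of the resampling signature extraction.

    ``n_genes`` is the signature size N, ``n_resamples`` the number of
    resampling iterations R, ``train_fraction`` the per-class fraction
    placed in the training set, ``s0_quantile`` the quantile of the
    per-gene standard errors used as the SAM fudge constant, ``svm_c``
    the SVM regularization constant, and ``seed`` the master seed from
    which per-iteration streams are spawned.
    """

    n_genes: int = 50
    n_resamples: int = 50
    train_fraction: float = 0.20
    s0_quantile: float = 0.90
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_genes < 1 or self.n_resamples < 1:
            raise ValueError("n_genes and n_resamples must be positive")


@dataclass
class SignatureResult:
    """Consensus signature with selection frequencies and error curve."""

    consensus: list
    frequencies: pd.Series
    per_error: float
    iteration_errors: np.ndarray
    config: SignatureConfig
    degenerate_iterations: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Consensus genes with their selection frequencies."""
        return pd.DataFrame(
            {
                "gene": self.consensus,
                "selection_frequency": self.frequencies.reindex(self.consensus).to_numpy(),
            }
        )


def sam_statistic(
    m: pd.DataFrame,
    labels: pd.Series,
    s0: float | None = None,
    s0_quantile: float = 0.90,
) -> pd.Series:
    """SAM d-statistic per feature for a two-class comparison.

    ``d_i = (mean_1i - mean_2i) / (s_i + s0)`` where ``s_i`` is the
    pooled-variance standard error of the mean difference and ``s0``
    defaults to the ``s0_quantile`` quantile of the ``s_i`` distribution
    (the fudge constant stabilizing low-variance features).  ``s0 = 0``
    recovers the ordinary pooled two-sample t statistic.
    """
    labels = labels.loc[m.columns]
    classes = sorted(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {classes}")
    g1 = m.loc[:, labels == classes[0]].to_numpy(dtype=float)
    g2 = m.loc[:, labels == classes[1]].to_numpy(dtype=float)
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each class needs at least 2 samples")
    diff = g1.mean(axis=1) - g2.mean(axis=1)
    pooled = (
        ((g1 - g1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        + ((g2 - g2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ) / (n1 + n2 - 2)
    s = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    if s0 is None:
        s0 = float(np.quantile(s, s0_quantile))
    denom = s + s0
    if np.any(denom == 0):
        raise ValueError("zero denominator; use a positive s0 for constant features")
    return pd.Series(diff / denom, index=m.index, name="d")


def split_train_test(
    labels: pd.Series, train_fraction: float, rng: np.random.Generator
) -> tuple[list, list]:
    """Class-stratified random partition into train and test sample ids.

    Each class contributes ``ceil(train_fraction * n_class)`` training
    samples; train and test are disjoint and jointly exhaustive.
    """
    train: list = []
    test: list = []
    for cls in sorted(pd.unique(labels)):
        ids = list(labels.index[labels == cls])
        n_train = math.ceil(train_fraction * len(ids))
        if n_train >= len(ids):
            raise ValueError(f"class {cls!r} too small to leave a test sample")
        perm = rng.permutation(len(ids))
        train += [ids[i] for i in perm[:n_train]]
        test += [ids[i] for i in perm[n_train:]]
    return train, test


def train_classifier(m: pd.DataFrame, labels: pd.Series, c: float = 1.0) -> SVC:
    """Linear-kernel SVM on a genes-by-samples block (deterministic)."""
    y = labels.loc[m.columns]
    if len(pd.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    clf = SVC(kernel="linear", C=c)
    clf.fit(m.to_numpy(dtype=float).T, y.to_numpy())
    return clf


def evaluate_classifier(clf: SVC, m: pd.DataFrame, labels: pd.Series) -> float:
    """Misclassification fraction of a fitted classifier on a test block."""
    if m.shape[1] == 0:
        raise ValueError("empty test set")
    pred = clf.predict(m.to_numpy(dtype=float).T)
    truth = labels.loc[m.columns].to_numpy()
    return float(np.mean(pred != truth))


def gensigpred(
    m: pd.DataFrame, labels: pd.Series, config: SignatureConfig | None = None
) -> SignatureResult:
    """Run the full resampling signature extraction.

    ``m`` is the candidate gene pool (features x samples, log2) and
    ``labels`` the two-class phenotype per sample (e.g. sham-tumor vs
    high-dose-tumor).  Returns the consensus top-``n_genes`` signature,
    per-gene selection frequencies, and the error curve.
    """
    config = config or SignatureConfig()
    if config.n_genes > m.shape[0]:
        raise ValueError("signature size exceeds the feature pool")
    labels = labels.loc[m.columns]
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_resamples)
    counts = pd.Series(0.0, index=m.index)
    abs_d_sum = pd.Series(0.0, index=m.index)
    errors = np.full(config.n_resamples, np.nan)
    degenerate: list[int] = []
    for it in range(config.n_resamples):
        rng = np.random.default_rng(seeds[it])
        try:
            train_ids, test_ids = split_train_test(labels, config.train_fraction, rng)
            d = sam_statistic(m[train_ids], labels, s0_quantile=config.s0_quantile)
            ranked = d.abs().sort_values(ascending=False, kind="mergesort")
            top = list(ranked.index[: config.n_genes])
            clf = train_classifier(m.loc[top, train_ids], labels, c=config.svm_c)
            errors[it] = evaluate_classifier(clf, m.loc[top, test_ids], labels)
            counts.loc[top] += 1.0
            abs_d_sum += d.abs()
        except ValueError:
            degenerate.append(it)
    valid = ~np.isnan(errors)
    if not valid.any():
        raise ValueError("every resampling iteration was degenerate")
    freq = counts / valid.sum()
    order = pd.DataFrame(
        {"freq": -freq, "mean_abs_d": -abs_d_sum / valid.sum()}, index=m.index
    )
    # stable sort over a lexicographically pre-sorted index: ties at the
    # consensus boundary break by mean |d|, then by gene id
    order = order.loc[sorted(order.index, key=str)]
    ranked_genes = order.sort_values(["freq", "mean_abs_d"], kind="mergesort").index
    consensus = list(ranked_genes[: config.n_genes])
    return SignatureResult(
        consensus=consensus,
        frequencies=freq[freq > 0].sort_values(ascending=False, kind="mergesort"),
        per_error=float(np.nanmean(errors)),
        iteration_errors=errors,
        config=config,
        degenerate_iterations=degenerate,
    )


def select_signature_size(
    m: pd.DataFrame,
    labels: pd.Series,
    candidate_ns: Sequence[int],
    config: SignatureConfig | None = None,
) -> tuple[int, pd.Series]:
    """Choose the signature size minimizing ``Per(N)`` over candidates.

    Ties go to the smallest N.  Returns the chosen N and the full
    ``Per(N)`` curve.
    """
    if not candidate_ns:
        raise ValueError("need at least one candidate signature size")
    config = config or SignatureConfig()
    curve = {}
    for n in sorted(candidate_ns):
        res = gensigpred(m, labels, config=SignatureConfig(
            n_genes=n,
            n_resamples=config.n_resamples,
            train_fraction=config.train_fraction,
            s0_quantile=config.s0_quantile,
            svm_c=config.svm_c,
            seed=config.seed,
        ))
        curve[n] = res.per_error
    per = pd.Series(curve, name="Per(N)")
    best = int(per.index[np.argmin(per.to_numpy())])
    return best, per
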