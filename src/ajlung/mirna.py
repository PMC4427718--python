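"""Subset classification of interaction-significant miRNAs.

miRNAs whose tissue-by-dose interaction (``CeT:doH``) is significant at
FDR < 0.05 are sorted into a three-level taxonomy by four model
contrasts, all tested at raw p < 0.05:

* Level 1, where the smoke effect acts — ``parenchyma-only`` (smoke
  effect in parenchyma but not in tumors), ``tumor-only`` (the
  reverse), or ``both`` (split into ``discordant``/``concordant`` by
  the signs of the two smoke effects).
* Level 2, within parenchyma-only — no tumor-vs-parenchyma difference
  in sham animals (``exposure-only``), a sham tissue difference that
  disappears under smoke (``tissue-effect-vanishes``), or a tissue
  difference in both conditions (``tissue-both``).
* Level 3, within tissue-both — the sign pattern of the sham and
  high-dose tissue differences: ``tumor-high`` (+,+), ``tumor-low``
  (-,-), or ``mixed`` otherwise.

Terminal labels match :data:`ajlung.datasets.FIGURE8_CATEGORIES` so
planted-truth recovery can be scored directly.
"""

from __future__ import annotations

import pandas as pd

from .interaction import (
    MS_IN_PARENCHYMA,
    MS_IN_TUMOR,
    TISSUE_IN_MS,
    TISSUE_IN_SHAM,
    InteractionResults,
)

TERMINAL_LABELS: tuple[str, ...] = (
    "parenchyma-only/exposure-only",
    "parenchyma-only/tissue-effect-vanishes",
    "parenchyma-only/tissue-both/mixed",
    "parenchyma-only/tissue-both/tumor-high",
    "parenchyma-only/tissue-both/tumor-low",
    "tumor-only",
    "both/discordant",
    "both/concordant",
    "unclassified",
)


def classify_interaction_mirnas(
    fit: InteractionResults, alpha: float = 0.05, interaction_fdr: float = 0.05
) -> pd.DataFrame:
    """Assign each interaction-significant miRNA a terminal category.

    Returns one row per feature with ``CeT:doH`` q-value below
    ``interaction_fdr``: the interaction q-value, the four contrast
    estimates and raw p-values, the per-level labels, and the terminal
    ``category``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    q = fit.qvalues("CeT:doH")
    sig = q.index[q.to_numpy() < interaction_fdr]
    ms_t = fit.test_contrast(MS_IN_TUMOR).loc[sig]
    ms_p = fit.test_contrast(MS_IN_PARENCHYMA).loc[sig]
    tis_sham = fit.test_contrast(TISSUE_IN_SHAM).loc[sig]
    tis_ms = fit.test_contrast(TISSUE_IN_MS).loc[sig]

    table = pd.DataFrame(
        {
            "q_interaction": q.loc[sig],
            "est_ms_tumor": ms_t["estimate"],
            "p_ms_tumor": ms_t["pvalue"],
            "est_ms_parenchyma": ms_p["estimate"],
            "p_ms_parenchyma": ms_p["pvalue"],
            "est_tissue_sham": tis_sham["estimate"],
            "p_tissue_sham": tis_sham["pvalue"],
            "est_tissue_ms": tis_ms["estimate"],
            "p_tissue_ms": tis_ms["pvalue"],
        },
        index=sig,
    )

    level1, level2, level3, terminal = [], [], [], []
    for fid in sig:
        row = table.loc[fid]
        in_p = row["p_ms_parenchyma"] < alpha
        in_t = row["p_ms_tumor"] < alpha
        if in_p and not in_t:
            l1 = "parenchyma-only"
        elif in_t and not in_p:
            l1 = "tumor-only"
        elif in_t and in_p:
            l1 = "both"
        else:
            l1 = "unclassified"
        l2 = l3 = ""
        if l1 == "parenchyma-only":
            if row["p_tissue_sham"] >= alpha:
                l2 = "exposure-only"
            elif row["p_tissue_ms"] >= alpha:
                l2 = "tissue-effect-vanishes"
            else:
                l2 = "tissue-both"
                same_sign = row["est_tissue_sham"] * row["est_tissue_ms"] > 0
                if same_sign and row["est_tissue_sham"] > 0:
                    l3 = "tumor-high"
                elif same_sign:
                    l3 = "tumor-low"
                else:
                    l3 = "mixed"
            cat = "/".join(filter(None, (l1, l2, l3)))
        elif l1 == "both":
            concord = row["est_ms_tumor"] * row["est_ms_parenchyma"] > 0
            l2 = "concordant" if concord else "discordant"
            cat = f"both/{l2}"
        else:
            cat = l1
        level1.append(l1)
        level2.append(l2)
        level3.append(l3)
        terminal.append(cat)
    table["level1"] = level1
    table["level2"] = level2
    table["level3"] = level3
    table["category"] = terminal
    return table


def category_counts(table: pd.DataFrame) -> pd.Series:
    """Feature counts per terminal category (zeros for absent labels)."""
    if len(table) == 0:
        return pd.Series(0, index=list(TERMINAL_LABELS), name="count")
    counts = table["category"].value_counts()
    return counts.reindex(list(TERMINAL_LABELS), fill_value=0).rename("count")
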