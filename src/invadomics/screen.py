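"""Pooled CRISPR knockout screen scoring: counts -> guide fitness -> gene calls.

The scoring path follows the pooled core/invasive selection design used in
3D hydrogel invasion devices:

1. replicate counts per fraction are summed and scaled to counts-per-million
   (each fraction is analysed as a single pooled condition);
2. guide fitness is the log2 ratio of normalized invasive over core
   abundance, centred so the median fitness of nontargeting guides is 0
   (negative fitness = depleted among invading cells, i.e. the knockout
   disrupted invasion);
3. the gene score is the median of its guides' fitness, with a two-sided
   one-sample t-test asking whether the guides deviate from 0;
4. hits are called by symmetric score and p-value thresholds, direction
   ``core_enriched`` (invasion-essential candidate) for negative scores.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pool_and_normalize",
    "guide_fitness",
    "gene_score",
    "call_hits",
    "screen_pca",
]

log = logging.getLogger(__name__)

META_COLS = ("guide_id", "gene", "is_nontargeting")


def _split_fraction_columns(counts: pd.DataFrame) -> tuple[list[str], list[str]]:
    core = [c for c in counts.columns if c.startswith("core")]
    invasive = [c for c in counts.columns if c.startswith("invasive")]
    if not core or not invasive:
        raise ValueError("need at least one core_* and one invasive_* sample column")
    return core, invasive


def pool_and_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum replicate counts per fraction and scale to counts-per-million.

    Parameters
    ----------
    counts : DataFrame with ``guide_id, gene, is_nontargeting`` plus one
        integer column per sample, named ``core_*`` / ``invasive_*``.

    Returns
    -------
    DataFrame with the metadata columns plus ``cpm_core`` and
    ``cpm_invasive``; each CPM column sums to 1e6.
    """
    core_cols, inv_cols = _split_fraction_columns(counts)
    out = counts.loc[:, list(META_COLS)].copy()
    for name, cols in (("cpm_core", core_cols), ("cpm_invasive", inv_cols)):
        pooled = counts[cols].to_numpy(dtype=float).sum(axis=1)
        total = pooled.sum()
        if total <= 0:
            raise ValueError(f"all-zero counts in fraction {name.removeprefix('cpm_')!r}")
        out[name] = pooled / total * 1e6
    return out


def guide_fitness(norm: pd.DataFrame, pseudocount: float = 0.5,
                  center_on_nontargeting: bool = True) -> pd.DataFrame:
    """Per-guide fitness: log2((CPM_invasive + pc) / (CPM_core + pc)).

    When ``center_on_nontargeting`` (default) the median raw fitness of the
    nontargeting guides is subtracted from every guide, so the nontargeting
    median is exactly 0 and targeted-guide fitness reads as deviation from
    neutral.  If the library has no nontargeting guides a warning is logged
    and centering is skipped.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    fitness = np.log2((norm["cpm_invasive"] + pseudocount) /
                      (norm["cpm_core"] + pseudocount))
    if not np.isfinite(fitness).all():
        raise ValueError("non-finite fitness; use a positive pseudocount with zero counts")
    out = norm.loc[:, list(META_COLS)].copy()
    out["fitness"] = fitness
    if center_on_nontargeting:
        ntc = out.loc[out["is_nontargeting"].astype(bool), "fitness"]
        if len(ntc) == 0:
            log.warning("no nontargeting guides; skipping centering")
        else:
            out["fitness"] = out["fitness"] - ntc.median()
    return out


def gene_score(fitness: pd.DataFrame) -> pd.DataFrame:
    """Aggregate guide fitness to gene level.

    score = median of the gene's guide fitnesses; p_value from a two-sided
    one-sample t-test of those fitnesses against 0 (NaN for genes with a
    single guide).  Nontargeting guides are excluded.  Degenerate groups
    whose guides are all identical get p = 1 when that value is 0 (no
    deviation) and p = 0 otherwise.
    """
    targeted = fitness.loc[~fitness["is_nontargeting"].astype(bool)]
    if targeted.empty:
        raise ValueError("no targeted guides to score")
    rows = []
    for gene, grp in targeted.groupby("gene", sort=True):
        f = grp["fitness"].to_numpy()
        n = len(f)
        score = float(np.median(f))
        if n < 2:
            p = np.nan
        elif np.ptp(f) == 0.0:
            p = 1.0 if f[0] == 0.0 else 0.0
        else:
            p = float(stats.ttest_1samp(f, 0.0).pvalue)
        rows.append({"gene": gene, "score": score, "p_value": p, "n_guides": n})
    out = pd.DataFrame(rows)
    out["direction"] = np.select(
        [out["score"] < 0, out["score"] > 0],
        ["core_enriched", "invasive_enriched"], default="neutral")
    return out


def call_hits(scores: pd.DataFrame, score_threshold: float = 1.0,
              p_threshold: float = 0.05) -> pd.DataFrame:
    """Call hits symmetrically: |score| >= score_threshold and p <= p_threshold.

    ``core_enriched`` hits (score <= -threshold) are the invasion-essential
    candidates — guides depleted among invading cells.  Returns the hit rows
    sorted by p-value then by |score| descending.
    """
    if score_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    s, p = scores["score"], scores["p_value"]
    keep = (p <= p_threshold) & (s.abs() >= score_threshold) & p.notna()
    hits = scores.loc[keep].copy()
    hits["direction"] = np.where(hits["score"] <= 0, "core_enriched", "invasive_enriched")
    hits = hits.sort_values(["p_value", "score"],
                            key=lambda c: c.abs() if c.name == "score" else c,
                            ascending=[True, False])
    return hits.reset_index(drop=True)


def screen_pca(counts: pd.DataFrame, n_components: int | None = None
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of per-sample normalized counts (log2 CPM, feature-centred).

    Returns (scores, explained_variance_ratio): one row of component scores
    per sample column of ``counts``.
    """
    from sklearn.decomposition import PCA

    sample_cols = [c for c in counts.columns if c not in META_COLS]
    if len(sample_cols) < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = counts[sample_cols].to_numpy(dtype=float)
    cpm = x / np.maximum(x.sum(axis=0, keepdims=True), 1.0) * 1e6
    logged = np.log2(cpm + 1.0)
    centered = logged - logged.mean(axis=1, keepdims=True)  # centre each guide
    k = n_components or min(len(sample_cols), 10)
    pca = PCA(n_components=min(k, len(sample_cols)))
    coords = pca.fit_transform(centered.T)
    scores = pd.DataFrame(coords, index=sample_cols,
                          columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    return scores, pca.explained_variance_ratio_
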