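"""Paired core-vs-invasive differential abundance, concordance and enrichment.

Works on positive feature-abundance matrices (metabolites, lipids or gene
counts) over paired samples: every experimental unit (hydrogel device,
biopsy site pair) contributes one core and one invasive sample.  Provides:

* :func:`paired_differential` — fold change (invasive/core) and paired
  t-test p-values on log abundances, BH-adjusted;
* :func:`rank_top` — top-k enriched features with documented tie-breaks;
* :func:`bh_adjust` — Benjamini–Hochberg step-up FDR adjustment;
* :func:`geomean_normalize` — median-of-ratios depth normalization (the
  geometric-mean reference construction used for count data);
* :func:`ora_enrichment` — hypergeometric over-representation of a hit list
  against gene-set collections (GMT);
* :func:`concordance` — Pearson correlation and sign-discordance rate of
  two per-feature fold-change profiles;
* :func:`subset_metabolic` — intersection of a DEG list with a metabolic
  gene catalogue;
* :func:`pca_scores` — sample ordination of the log matrix.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "split_pairs",
    "paired_differential",
    "rank_top",
    "bh_adjust",
    "geomean_normalize",
    "read_gmt",
    "ora_enrichment",
    "concordance",
    "subset_metabolic",
    "pca_scores",
]


def split_pairs(mat: pd.DataFrame, pairing: pd.DataFrame
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a features x samples matrix into aligned core/invasive halves.

    ``pairing`` has columns ``sample, unit, fraction``; every unit must have
    exactly one core and one invasive sample present in ``mat``.  Returns
    (core, invasive) DataFrames whose columns are the unit ids, in the same
    order.
    """
    req = {"sample", "unit", "fraction"}
    if not req <= set(pairing.columns):
        raise ValueError(f"pairing table needs columns {sorted(req)}")
    halves = {}
    for frac in ("core", "invasive"):
        sub = pairing.loc[pairing["fraction"] == frac].set_index("unit")["sample"]
        if sub.index.duplicated().any():
            raise ValueError(f"unit with more than one {frac} sample")
        halves[frac] = sub
    units = sorted(set(halves["core"].index) & set(halves["invasive"].index))
    if set(halves["core"].index) != set(halves["invasive"].index):
        raise ValueError("every unit needs exactly one core and one invasive sample")
    core = mat[[halves["core"][u] for u in units]].set_axis(units, axis=1)
    inv = mat[[halves["invasive"][u] for u in units]].set_axis(units, axis=1)
    return core, inv


def paired_differential(core: pd.DataFrame, invasive: pd.DataFrame,
                        pseudo: float | None = None, paired: bool = True,
                        fc_mode: str = "mean_ratio") -> pd.DataFrame:
    """Differential abundance of invasive versus core, feature by feature.

    fold_change is the ratio of group means of pair members (``mean_ratio``,
    default) or the mean of per-pair ratios (``ratio_mean``); the test is a
    two-sided t-test on log-transformed abundances, paired across units by
    default.  ``pseudo`` guards zeros and defaults to 1e-6 times the matrix
    median.  Returns a table with fold_change, log2_fc, p_value, p_adjusted
    (Benjamini–Hochberg) and direction.
    """
    if core.shape != invasive.shape or not core.index.equals(invasive.index):
        raise ValueError("core and invasive must share features and pairing")
    n_pairs = core.shape[1]
    if n_pairs < 2:
        raise ValueError("need at least 2 complete pairs")
    if fc_mode not in ("mean_ratio", "ratio_mean"):
        raise ValueError("fc_mode must be 'mean_ratio' or 'ratio_mean'")
    c = core.to_numpy(dtype=float)
    i = invasive.to_numpy(dtype=float)
    if pseudo is None:
        med = float(np.median(np.r_[c.ravel(), i.ravel()]))
        pseudo = 1e-6 * med if med > 0 else 1e-6
    c_p, i_p = c + pseudo, i + pseudo
    if fc_mode == "mean_ratio":
        fc = i_p.mean(axis=1) / c_p.mean(axis=1)
    else:
        fc = (i_p / c_p).mean(axis=1)
    log_c, log_i = np.log(c_p), np.log(i_p)
    if paired:
        res = stats.ttest_rel(log_i, log_c, axis=1)
    else:
        res = stats.ttest_ind(log_i, log_c, axis=1)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)  # zero-variance pairs: no evidence
    out = pd.DataFrame({
        "feature": core.index,
        "fold_change": fc,
        "log2_fc": np.log2(fc),
        "p_value": p,
        "p_adjusted": bh_adjust(p),
    })
    out["direction"] = np.select([out["log2_fc"] > 0, out["log2_fc"] < 0],
                                 ["up", "down"], default="unchanged")
    return out


def rank_top(diff: pd.DataFrame, k: int = 10, p_cap: float | None = None) -> pd.DataFrame:
    """Top-k features by fold change (ties: smaller p, then lexical id)."""
    if k <= 0:
        raise ValueError("k must be > 0")
    d = diff if p_cap is None else diff.loc[diff["p_value"] <= p_cap]
    d = d.sort_values(["fold_change", "p_value", "feature"],
                      ascending=[False, True, True], kind="mergesort")
    return d.head(k).reset_index(drop=True)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def geomean_normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios depth normalization with a geometric-mean reference.

    A per-feature geometric mean across samples is the reference (features
    containing zeros are excluded from factor estimation); each sample's
    size factor is the median over features of count/reference, rescaled so
    the factors have geometric mean 1 (so normalization is idempotent and
    the overall count scale is preserved); the normalized matrix is counts
    divided by its sample's factor.  Returns (normalized counts, size
    factors).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature is positive in all samples; cannot form reference")
    ref = np.exp(np.log(x[positive]).mean(axis=1))
    factors = np.median(x[positive] / ref[:, None], axis=0)
    factors = factors / np.exp(np.log(factors).mean())
    normalized = counts / factors
    return normalized, pd.Series(factors, index=counts.columns, name="size_factor")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3 and parts[0]:
            sets[parts[0]] = [m for m in parts[2:] if m]
    return sets


def ora_enrichment(hits: list[str], sets: dict[str, list[str]],
                   universe: list[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` against each set.

    For a universe of M identifiers with n set members and N hits, the
    enrichment p-value is the upper hypergeometric tail
    P[X >= overlap].  Set members outside the universe are dropped (the
    harmonized set is what is tested).  Returns per-set overlap, p_value,
    BH-adjusted q_value and fold_enrichment, sorted by p.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    hit_set = set(hits) & uni
    if set(hits) - uni:
        raise ValueError("hits must be a subset of the universe")
    M, N = len(uni), len(hit_set)
    rows = []
    for name, members in sets.items():
        mem = set(members) & uni
        n = len(mem)
        k = len(mem & hit_set)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        expected = N * n / M if M else 0.0
        rows.append({"set": name, "overlap": k, "set_size": n,
                     "n_hits": N, "universe_size": M, "p_value": p,
                     "fold_enrichment": (k / expected) if expected > 0 else np.nan})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values(["p_value", "set"]).reset_index(drop=True)


def concordance(fc_a: pd.Series, fc_b: pd.Series) -> dict:
    """Agreement of two per-feature log2 fold-change profiles.

    Pearson r over shared features plus the sign-discordance rate: a feature
    is discordant when one profile calls it up (log2FC > 0) and the other
    down (log2FC < 0), strictly.  ``pct_discordant`` is reported to one
    decimal, e.g. 20 discordant of 322 -> 6.2.
    """
    shared = fc_a.index.intersection(fc_b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared features")
    a = fc_a.loc[shared].to_numpy(dtype=float)
    b = fc_b.loc[shared].to_numpy(dtype=float)
    r = float(stats.pearsonr(a, b).statistic)
    disc = int(np.sum(((a > 0) & (b < 0)) | ((a < 0) & (b > 0))))
    n = len(shared)
    return {"pearson_r": r, "n_total": n, "n_discordant": disc,
            "pct_discordant": round(100.0 * disc / n, 1)}


def subset_metabolic(deg_ids: list[str], catalog: set[str] | list[str]) -> dict:
    """Intersect a DEG list with a metabolic-gene catalogue.

    Returns the subset, counts, and the percentage of DEGs that are
    metabolic, rounded to the nearest integer for reporting (e.g. 344 of
    2,172 -> 16).
    """
    if len(deg_ids) == 0:
        raise ValueError("empty DEG list")
    cat = set(catalog)
    subset = sorted(set(deg_ids) & cat)
    n_deg = len(set(deg_ids))
    pct = int(round(100.0 * len(subset) / n_deg))
    return {"subset": subset, "n_deg": n_deg, "n_metabolic": len(subset), "pct": pct}


def pca_scores(mat: pd.DataFrame, n_components: int | None = None
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the log-transformed, feature-centred matrix."""
    from sklearn.decomposition import PCA

    if mat.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    x = np.log(mat.to_numpy(dtype=float) + 1.0)
    centered = x - x.mean(axis=1, keepdims=True)
    k = min(n_components or mat.shape[1], mat.shape[1], mat.shape[0])
    pca = PCA(n_components=k)
    coords = pca.fit_transform(centered.T)
    scores = pd.DataFrame(coords, index=mat.columns,
                          columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    return scores, pca.explained_variance_ratio_
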