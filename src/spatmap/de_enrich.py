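"""Differential expression, term enrichment, and colocalization ranking.

Differential expression on whole-cell lysates uses a moderated t
statistic whose variance prior depends on peptide counts: proteins
quantified from few peptides are noisier, so a trend of residual
variance versus peptide count is fitted across all proteins and each
protein's variance is shrunk toward the trend by empirical Bayes
(posterior variance with estimated prior degrees of freedom), in the
spirit of count-aware moderated tests for MS proteomics.

Term enrichment is a two-sided Fisher exact test per annotation term
with Benjamini-Hochberg control; colocalization ranking orders the
members of one compartment cluster by their mean Pearson correlation
with a set of anchor proteins' fractionation profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .classify import ClassifiedMap
from .io_preprocess import LysateMatrix


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is decreasing)."""
    if y <= 0:
        return np.inf
    lo, hi = 1e-8, 1e8
    if special.polygamma(1, hi) > y:
        return hi
    return float(optimize.brentq(lambda x: special.polygamma(1, x) - y, lo, hi))


def _variance_trend(
    log_s2: np.ndarray, counts: np.ndarray, df: int, n_bins: int = 10
) -> np.ndarray:
    """Fitted prior log-variance per protein from the peptide-count trend.

    Binned medians of log variance over log peptide count, smoothed by
    a decreasing isotonic fit and interpolated; debiased by the mean of
    log of a scaled chi-square so the result estimates the underlying
    variance, not the median of its noisy estimate.
    """
    log_c = np.log(counts.astype(float))
    uniq = np.unique(log_c)
    if len(uniq) == 1:
        trend = np.full_like(log_s2, np.median(log_s2))
    else:
        edges = np.quantile(log_c, np.linspace(0, 1, min(n_bins, len(uniq)) + 1))
        edges = np.unique(edges)
        idx = np.clip(np.searchsorted(edges, log_c, side="right") - 1, 0, len(edges) - 2)
        centers, medians = [], []
        for b in range(len(edges) - 1):
            mask = idx == b
            if mask.sum() >= 3:
                centers.append(log_c[mask].mean())
                medians.append(np.median(log_s2[mask]))
        if len(centers) < 2:
            trend = np.full_like(log_s2, np.median(log_s2))
        else:
            iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
            smoothed = iso.fit_transform(centers, medians)
            trend = np.interp(log_c, centers, smoothed)
    bias = special.digamma(df / 2.0) - np.log(df / 2.0)
    return trend - bias


def moderated_de(
    lysate: LysateMatrix,
    condition_a: str,
    condition_b: str,
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated differential expression with count-aware prior.

    Requires imputed (complete) log2 intensities and >= 2 replicates
    per group. Positive log2 fold changes mean higher in
    ``condition_a``. ``prior_df`` overrides the estimated prior
    degrees of freedom (0 recovers the ordinary t test, large values
    approach the pure trend-variance test).
    """
    cols_a = lysate.columns_for(condition_a)
    cols_b = lysate.columns_for(condition_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    X = lysate.log2_intensities
    if X[cols_a + cols_b].isna().any().any():
        raise ValueError("missing values present; impute the lysate matrix first")
    a = X[cols_a].to_numpy()
    b = X[cols_b].to_numpy()
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    logfc = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = np.maximum(ss / df, 1e-12)
    counts = lysate.peptide_counts.reindex(X.index).to_numpy()

    log_prior = _variance_trend(np.log(s2), counts, df)
    s2_prior = np.exp(log_prior)
    if prior_df is None:
        z = np.log(s2) - log_prior
        var_z = float(np.var(z, ddof=1))
        excess = var_z - special.polygamma(1, df / 2.0)
        d0 = 2.0 * _trigamma_inverse(excess) if excess > 1e-8 else np.inf
    else:
        d0 = float(prior_df)

    if np.isinf(d0):
        s2_post = s2_prior
        df_total = 1e6
    else:
        s2_post = (d0 * s2_prior + df * s2) / (d0 + df)
        df_total = df + d0
    if d0 == 0:
        s2_post = s2
        df_total = df
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t = logfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2fc": logfc,
            "t": t,
            "p": p,
            "q": q,
            "peptide_count": counts,
            "significant": q <= alpha,
        },
        index=X.index,
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_variance"] = s2_prior
    out.attrs["residual_df"] = df
    return out


def fisher_enrichment(
    foreground: list[str] | pd.Index,
    background: list[str] | pd.Index,
    annotations: dict[str, set[str]],
    alpha: float = 0.02,
) -> pd.DataFrame:
    """Two-sided Fisher exact enrichment of annotation terms.

    ``annotations`` maps accession to its set of terms. The 2x2 table
    per term counts foreground/non-foreground proteins of the
    background with/without the term. Returns a table with p, BH q,
    the enrichment ratio (foreground term frequency over background
    term frequency), and counts.
    """
    fg = pd.Index(pd.unique(pd.Index(foreground)))
    bg = pd.Index(pd.unique(pd.Index(background)))
    if not fg.isin(bg).all():
        raise ValueError("foreground must be a subset of the background")
    if not annotations:
        raise ValueError("no annotations supplied")
    term_members: dict[str, set[str]] = {}
    for acc in bg:
        for term in annotations.get(acc, ()):
            term_members.setdefault(term, set()).add(acc)
    fg_set = set(fg)
    rows = []
    for term, members in sorted(term_members.items()):
        a = len(members & fg_set)
        b = len(fg) - a
        c = len(members) - a
        d = len(bg) - len(fg) - c
        p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        fg_freq = a / len(fg)
        bg_freq = len(members) / len(bg)
        ratio = fg_freq / bg_freq if bg_freq > 0 else np.nan
        rows.append((term, a, len(members), ratio, p))
    out = pd.DataFrame(
        rows, columns=["term", "n_foreground", "n_background", "ratio", "p"]
    ).set_index("term")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["q"] <= alpha
    return out.sort_values(["q", "p"])


def colocalization_ranking(
    cmap: ClassifiedMap,
    cluster: str,
    anchors: list[str],
    k: int = 20,
) -> pd.DataFrame:
    """Rank a cluster's proteins by profile correlation with anchors.

    For every non-anchor protein classified to ``cluster``, the mean
    Pearson correlation of its combined-map profile with the anchor
    proteins' profiles; the top-k most correlated proteins are the
    best colocalization candidates (e.g. chaperones retained with
    immunoglobulin chains in the ER).
    """
    members = cmap.members(cluster)
    for anchor in anchors:
        if anchor not in members:
            raise ValueError(f"anchor {anchor!r} is not classified to {cluster!r}")
    candidates = members.difference(anchors)
    if len(candidates) == 0:
        raise ValueError(f"cluster {cluster!r} has no non-anchor members")
    profiles = cmap.profiles.data
    anchor_mat = profiles.loc[anchors].to_numpy()
    cand_mat = profiles.loc[candidates].to_numpy()

    def centered(m: np.ndarray) -> np.ndarray:
        c = m - m.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(c, axis=1, keepdims=True)
        return c / np.where(norms > 0, norms, 1.0)

    corr = centered(cand_mat) @ centered(anchor_mat).T  # candidates x anchors
    mean_r = corr.mean(axis=1)
    out = pd.DataFrame({"mean_r": mean_r}, index=candidates)
    return out.sort_values("mean_r", ascending=False).head(k)
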