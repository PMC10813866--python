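"""Normalization, redundancy filtering, cross-modal correlation, FDR, KS.

The association analysis between the two imaging modalities and the
clinical endpoints (OS months, PFS months, CD8 %):

* z-score normalization (per column, sample SD);
* redundancy filtering: among feature pairs with |Spearman| above 0.9,
  iteratively drop the member with the higher mean absolute correlation;
* cross-modal Spearman matrix with per-scale sign bookkeeping and a
  top-pair table (|rho| > 0.5 by default);
* per-endpoint Spearman with Benjamini–Hochberg FDR;
* two-sample Kolmogorov–Smirnov comparison of correlation-coefficient
  distributions.

Endpoint correlations use observed survival months and ignore
censoring — a deliberate statistical caveat of this descriptive
analysis, not a survival model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "zscore",
    "spearman",
    "spearman_matrix",
    "correlation_filter",
    "cross_correlation",
    "endpoint_correlation",
    "ks_compare",
    "CrossCorrelationResult",
    "EndpointCorrelationResult",
    "KSResult",
]


def zscore(table: pd.DataFrame) -> pd.DataFrame:
    """Center to mean 0 and scale to sample SD 1 (ddof=1) per column.

    Zero-variance columns carry no rank information and are dropped with
    a warning.
    """
    if len(table) < 2:
        raise ValueError("z-scoring requires at least 2 rows")
    sd = table.std(ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index.tolist()
    if constant:
        warnings.warn(f"dropping {len(constant)} zero-variance column(s): {constant[:5]}")
        table = table.drop(columns=constant)
        sd = sd.drop(constant)
    return (table - table.mean()) / sd


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman requires two equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input vector: Spearman rho undefined")
        return (np.nan, np.nan)
    rho, p = sstats.spearmanr(x, y)
    return float(rho), float(p)


def spearman_matrix(X: pd.DataFrame, Y: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pairwise Spearman rho between columns of X (and Y), via ranked Pearson."""
    rx = X.rank().to_numpy(dtype=float)
    rx = (rx - rx.mean(0)) / rx.std(0, ddof=0)
    if Y is None:
        m = (rx.T @ rx) / len(X)
        return pd.DataFrame(m, index=X.columns, columns=X.columns)
    ry = Y.rank().to_numpy(dtype=float)
    ry = (ry - ry.mean(0)) / ry.std(0, ddof=0)
    m = (rx.T @ ry) / len(X)
    return pd.DataFrame(m, index=X.columns, columns=Y.columns)


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation with n-2 degrees of freedom."""
    rho = np.clip(np.asarray(rho, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sstats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return p


def correlation_filter(table: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Redundancy filter on |Spearman| with a deterministic elimination order.

    Repeatedly: take the currently-largest |rho| pair above ``threshold``
    (ties broken by lexicographic pair order); of the two, eliminate the
    member with the higher mean absolute correlation against all
    currently retained columns (tie: eliminate the lexicographically
    later name); recompute means over survivors; stop when no retained
    pair exceeds the threshold.  Returns retained names in original
    column order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if table.shape[1] < 2:
        return list(table.columns)
    corr = spearman_matrix(table).abs()
    return _filter_from_corr(corr, threshold)


def _filter_from_corr(abs_corr: pd.DataFrame, threshold: float) -> list[str]:
    """Core elimination loop, operating on a precomputed |rho| matrix."""
    cols = list(abs_corr.columns)
    retained = set(cols)
    C = abs_corr.copy()
    np.fill_diagonal(C.values, 0.0)
    while True:
        sub = C.loc[sorted(retained), sorted(retained)]
        arr = sub.to_numpy()
        mx = np.nanmax(arr) if arr.size else 0.0
        if not (mx > threshold):
            break
        # among maximal pairs pick the lexicographically first (a, b), a < b
        idx = np.argwhere(np.isclose(arr, mx))
        pairs = sorted(
            {tuple(sorted((sub.index[i], sub.columns[j]))) for i, j in idx})
        a, b = pairs[0]
        others_a = sorted(retained - {a})
        others_b = sorted(retained - {b})
        mean_a = float(C.loc[a, others_a].mean()) if others_a else 0.0
        mean_b = float(C.loc[b, others_b].mean()) if others_b else 0.0
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)  # tie: lexicographically later name
        retained.discard(drop)
        if len(retained) < 2:
            break
    return [c for c in cols if c in retained]


@dataclass
class CrossCorrelationResult:
    """Pathomics x radiomics Spearman matrices and their summaries, per scale."""

    matrices: dict[str, pd.DataFrame]          # scale -> pathomics x radiomics rho
    sign_counts: pd.DataFrame                  # per scale: positive/negative/zero + pct
    top_pairs: pd.DataFrame                    # radiomics, pathomics, correlation, scale
    n_patients: int = 0


def cross_correlation(
    pathomics: dict[str, pd.DataFrame],
    radiomics: pd.DataFrame,
    report_threshold: float = 0.5,
) -> CrossCorrelationResult:
    """Spearman rho for every (pathomics, radiomics) feature pair, per scale.

    Tables are inner-joined on patient_id; mismatching patients are
    logged.  The top-pair table lists |rho| > ``report_threshold`` sorted
    by |rho| within scale, in the reporting style of the association
    tables (radiomics name, pathomics name, correlation, scale).
    """
    matrices: dict[str, pd.DataFrame] = {}
    counts_rows = []
    top_rows = []
    n_shared = None
    for scale, ptab in pathomics.items():
        shared = ptab.index.intersection(radiomics.index)
        dropped = len(ptab.index.union(radiomics.index)) - len(shared)
        if dropped:
            warnings.warn(f"scale {scale}: {dropped} patient(s) not shared between tables")
        if len(shared) < 3:
            raise ValueError("fewer than 3 shared patients between modalities")
        n_shared = len(shared)
        m = spearman_matrix(ptab.loc[shared], radiomics.loc[shared])
        matrices[scale] = m
        vals = m.to_numpy().ravel()
        vals = vals[~np.isnan(vals)]
        pos, neg, zero = int((vals > 0).sum()), int((vals < 0).sum()), int((vals == 0).sum())
        total = pos + neg + zero
        counts_rows.append({
            "scale": scale, "positive": pos, "negative": neg, "zero": zero,
            "positive_pct": 100.0 * pos / total if total else np.nan,
            "negative_pct": 100.0 * neg / total if total else np.nan,
            "rho_min": float(vals.min()) if len(vals) else np.nan,
            "rho_max": float(vals.max()) if len(vals) else np.nan,
        })
        hits = np.argwhere(np.abs(m.to_numpy()) > report_threshold)
        for i, j in hits:
            top_rows.append({
                "radiomics_feature": m.columns[j],
                "pathomics_feature": m.index[i],
                "correlation": float(m.iat[i, j]),
                "scale": scale,
            })
    top = pd.DataFrame(top_rows, columns=["radiomics_feature", "pathomics_feature",
                                          "correlation", "scale"])
    if len(top):
        top = top.reindex(top.correlation.abs().sort_values(ascending=False).index)
        top = top.sort_values("scale", kind="stable").reset_index(drop=True)
    return CrossCorrelationResult(
        matrices=matrices,
        sign_counts=pd.DataFrame(counts_rows),
        top_pairs=top,
        n_patients=n_shared or 0,
    )


@dataclass
class EndpointCorrelationResult:
    endpoint: str
    table: pd.DataFrame          # feature, rho, p, q, n
    n_positive: int
    n_negative: int


def endpoint_correlation(
    features: pd.DataFrame,
    endpoint: pd.Series,
    fdr_level: float = 0.05,
) -> EndpointCorrelationResult:
    """Per-feature Spearman against one clinical endpoint, with BH FDR.

    Missing endpoint values are handled pairwise-complete; the per-feature
    n is recorded.  q-values are Benjamini–Hochberg.
    """
    endpoint = endpoint.reindex(features.index)
    if endpoint.isna().all():
        raise ValueError("endpoint has no observed values")
    rows = []
    for col in features.columns:
        pair = pd.concat([features[col], endpoint], axis=1).dropna()
        n = len(pair)
        if n < 3 or pair.iloc[:, 0].nunique() < 2 or pair.iloc[:, 1].nunique() < 2:
            rows.append((col, np.nan, np.nan, n))
            continue
        rho, p = sstats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append((col, float(rho), float(p), n))
    tab = pd.DataFrame(rows, columns=["feature", "rho", "p", "n"])
    q = np.full(len(tab), np.nan)
    ok = tab["p"].notna().to_numpy()
    if ok.any():
        q[ok] = multipletests(tab.loc[ok, "p"], alpha=fdr_level, method="fdr_bh")[1]
    tab["q"] = q
    return EndpointCorrelationResult(
        endpoint=str(endpoint.name),
        table=tab,
        n_positive=int((tab["rho"] > 0).sum()),
        n_negative=int((tab["rho"] < 0).sum()),
    )


@dataclass
class KSResult:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int


def ks_compare(rhos_a, rhos_b) -> KSResult:
    """Two-sample two-sided KS test between two correlation samples.

    D is the supremum ECDF gap; the p-value uses the asymptotic
    Kolmogorov distribution with the standard two-sample effective size.
    """
    a = np.asarray(rhos_a, dtype=float)
    b = np.asarray(rhos_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("ks_compare requires at least 2 observations per sample")
    res = sstats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return KSResult(statistic=float(res.statistic), pvalue=float(min(res.pvalue, 1.0)),
                    n_a=len(a), n_b=len(b))
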