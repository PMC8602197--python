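"""Co-expression of circRNAs with parent genes and with gene modules, plus
generic hypergeometric term enrichment.

circRNA-parent correlations are Pearson r over shared samples (the usual
3-tissue x 3-replicate layout gives n = 9) with the two-sided t-based
p-value; significance calls use r >= 0.5 and p < 0.05 by default.  Module
co-expression summarizes each supplied gene module by its eigengene — the
first principal component of the module's standardized expression, sign-
oriented to agree with the module mean profile — and correlates every
circRNA against each eigengene (default thresholds r >= 0.9, p < 0.05).
Module *detection* is not performed here; modules come from any external
tool or from simulation truth.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ExpressionMatrix, benjamini_hochberg


def _as_df(m: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    return m.values if isinstance(m, ExpressionMatrix) else m


def _classify(r: float, p: float, r_min: float, p_max: float) -> str:
    if np.isnan(r):
        return "ns"
    if r >= r_min and p < p_max:
        return "sig_pos"
    if r <= -r_min and p < p_max:
        return "sig_neg"
    return "ns"


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p-value (t distribution, n-2 df).

    Returns (nan, nan) when either profile has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def pair_correlation(
    circ_rpm: ExpressionMatrix | pd.DataFrame,
    gene_fpkm: ExpressionMatrix | pd.DataFrame,
    pairs: Mapping[str, str],
    r_min: float = 0.5,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Correlate each circRNA with its parent gene over shared samples.

    ``pairs`` maps circ_id -> gene_id.  Pairs where either profile is
    constant get r = NaN, class 'ns' and a zero_variance flag.
    """
    circ = _as_df(circ_rpm)
    gene = _as_df(gene_fpkm)
    shared = [s for s in circ.columns if s in set(gene.columns)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, have {len(shared)}")
    rows = []
    for cid, gid in pairs.items():
        if cid not in circ.index:
            raise KeyError(f"circRNA {cid} missing from the RPM matrix")
        if gid not in gene.index:
            raise KeyError(f"gene {gid} missing from the FPKM matrix")
        r, p = pearson_with_p(circ.loc[cid, shared], gene.loc[gid, shared])
        rows.append(
            {
                "circ_id": cid,
                "partner_id": gid,
                "n": len(shared),
                "r": r,
                "p": p,
                "class": _classify(r, p, r_min, p_max),
                "zero_variance": bool(np.isnan(r)),
            }
        )
    return pd.DataFrame(rows)


def module_eigengenes(
    gene_expr: ExpressionMatrix | pd.DataFrame,
    modules: Mapping[str, str],
) -> pd.DataFrame:
    """First-PC eigengene of each module, modules x samples.

    Gene profiles are standardized before the decomposition; each
    eigengene is scaled to unit variance and sign-oriented so it
    correlates positively with the module's mean standardized profile.
    Modules whose genes are all constant are skipped with a warning.
    """
    expr = _as_df(gene_expr)
    by_module: dict[str, list[str]] = {}
    for gid, mod in modules.items():
        if gid in expr.index:
            by_module.setdefault(mod, []).append(gid)
    out = {}
    for mod, gids in sorted(by_module.items()):
        if len(gids) < 2:
            raise ValueError(f"module {mod} has fewer than 2 genes")
        arr = expr.loc[gids].to_numpy(dtype=float)
        sd = arr.std(axis=1, keepdims=True)
        keep = sd[:, 0] > 0
        if not keep.any():
            warnings.warn(f"module {mod}: all genes constant, skipped")
            continue
        z = (arr[keep] - arr[keep].mean(axis=1, keepdims=True)) / sd[keep]
        # right singular vector of the genes x samples standardized matrix
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(eig, mean_profile) < 0:
            eig = -eig
        if eig.std() > 0:
            eig = (eig - eig.mean()) / eig.std()
        out[mod] = eig
    return pd.DataFrame(out, index=expr.columns).T


def module_correlation(
    circ_rpm: ExpressionMatrix | pd.DataFrame,
    gene_expr: ExpressionMatrix | pd.DataFrame,
    modules: Mapping[str, str],
    r_min: float = 0.9,
    p_max: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate every circRNA against every module eigengene.

    Returns (eigengenes, records); records carry r, p and the significance
    class at the supplied thresholds.
    """
    circ = _as_df(circ_rpm)
    expr = _as_df(gene_expr)
    shared = [s for s in circ.columns if s in set(expr.columns)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, have {len(shared)}")
    eigen = module_eigengenes(expr[shared], modules)
    rows = []
    for cid in circ.index:
        for mod in eigen.index:
            r, p = pearson_with_p(circ.loc[cid, shared], eigen.loc[mod, shared])
            rows.append(
                {
                    "circ_id": cid,
                    "partner_id": mod,
                    "n": len(shared),
                    "r": r,
                    "p": p,
                    "class": _classify(r, p, r_min, p_max),
                }
            )
    return eigen, pd.DataFrame(rows)


def hypergeom_enrichment(
    query_genes: set[str],
    background_genes: set[str],
    term_map: Mapping[str, set[str]],
    q_max: float = 0.05,
    min_count: int = 3,
) -> pd.DataFrame:
    """Hypergeometric (upper tail, P(X >= k)) term enrichment.

    Term gene sets are intersected with the background; q-values are
    Benjamini-Hochberg over the tested terms.  A term is significant when
    q < ``q_max`` and the query/term overlap has at least ``min_count``
    genes.
    """
    if not background_genes:
        raise ValueError("empty background gene set")
    extra = query_genes - background_genes
    if extra:
        raise ValueError(f"query genes outside the background: {sorted(extra)[:5]}")
    N = len(background_genes)
    n = len(query_genes)
    rows = []
    for term, genes in sorted(term_map.items()):
        term_genes = genes & background_genes
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        fold = (k / n) / (K / N) if n > 0 else float("nan")
        rows.append(
            {
                "term_id": term,
                "genes_in_query": k,
                "genes_in_term": K,
                "background": N,
                "fold_enrichment": fold,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(q=pd.Series(dtype=float), significant=pd.Series(dtype=bool))
    df["q"] = benjamini_hochberg(df["p"].to_numpy())
    df["significant"] = (df["q"] < q_max) & (df["genes_in_query"] >= min_count)
    return df
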