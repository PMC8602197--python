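"""Expression quantification, differential expression and profile
clustering.

circRNA expression is junction reads per million total sequencing reads
(RPM); linear parent-gene expression is fragments per kilobase of exonic
length per million mapped fragments (FPKM).  Tissue-pair differential
expression uses the replicate-mean fold change with a conditional binomial
test on pooled junction counts and Benjamini-Hochberg adjustment; calls
require |log2 fold change| >= 1 and q <= 0.05 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .models import GeneModel


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with their unit and the
    per-sample library sizes used for normalization."""

    values: pd.DataFrame
    unit: str  # RPM | FPKM | raw_count
    library_sizes: dict[str, float]

    def __post_init__(self) -> None:
        if self.unit not in ("RPM", "FPKM", "raw_count"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("expression values must be >= 0")
        for s in self.values.columns:
            if self.library_sizes.get(s, 0) <= 0:
                raise ValueError(f"library size for sample {s} must be > 0")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def compute_rpm(
    junction_counts: pd.DataFrame, library_sizes: Mapping[str, float]
) -> ExpressionMatrix:
    """RPM[f, s] = counts[f, s] / library_size[s] * 1e6."""
    scale = pd.Series(
        {s: library_sizes[s] for s in junction_counts.columns}, dtype=float
    )
    if (scale <= 0).any():
        bad = list(scale.index[scale <= 0])
        raise ValueError(f"zero/negative library size for samples {bad}")
    rpm = junction_counts.astype(float).div(scale, axis=1) * 1e6
    return ExpressionMatrix(values=rpm, unit="RPM", library_sizes=dict(scale))


def compute_fpkm(
    fragment_counts: pd.DataFrame,
    gene_models: Sequence[GeneModel],
    library_sizes: Mapping[str, float],
) -> ExpressionMatrix:
    """FPKM[g, s] = counts[g, s] / (exonic_kb[g] * mapped_millions[s]).

    Exonic length is the merged exon span of the gene model.
    """
    lengths = {g.gene_id: g.exonic_length() for g in gene_models}
    missing = [g for g in fragment_counts.index if g not in lengths]
    if missing:
        raise KeyError(f"genes absent from models: {missing[:5]}")
    kb = pd.Series({g: lengths[g] / 1e3 for g in fragment_counts.index})
    if (kb <= 0).any():
        raise ValueError("gene exonic length must be > 0")
    millions = pd.Series(
        {s: library_sizes[s] / 1e6 for s in fragment_counts.columns}, dtype=float
    )
    if (millions <= 0).any():
        raise ValueError("library sizes must be > 0")
    fpkm = fragment_counts.astype(float).div(kb, axis=0).div(millions, axis=1)
    return ExpressionMatrix(values=fpkm, unit="FPKM", library_sizes={s: m * 1e6 for s, m in millions.items()})


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (step-up), preserving input order."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    counts: pd.DataFrame,
    library_sizes: Mapping[str, float],
    design: Mapping[str, str],
    pair: tuple[str, str],
    lfc_min: float = 1.0,
    q_max: float = 0.05,
    pseudo: float = 0.01,
) -> pd.DataFrame:
    """Tissue-pair differential expression of junction-read counts.

    The fold change is the ratio of replicate-mean RPM (plus ``pseudo``
    RPM on both sides so zero-count features stay finite).  The p-value is
    a two-sided conditional binomial test on the pooled counts:
    x_A ~ Binomial(x_A + x_B, pi0) with pi0 the pooled library-size share
    of tissue A.  q-values are Benjamini-Hochberg over all features of the
    pair; status is up/down iff |log2fc| >= lfc_min and q <= q_max.
    """
    tissue_a, tissue_b = pair
    samples_a = [s for s in counts.columns if design.get(s) == tissue_a]
    samples_b = [s for s in counts.columns if design.get(s) == tissue_b]
    if not samples_a or not samples_b:
        raise ValueError(f"each tissue in {pair} needs at least one sample")

    rpm = compute_rpm(counts, library_sizes).values
    mean_a = rpm[samples_a].mean(axis=1)
    mean_b = rpm[samples_b].mean(axis=1)
    log2fc = np.log2((mean_a + pseudo) / (mean_b + pseudo))

    lib_a = sum(library_sizes[s] for s in samples_a)
    lib_b = sum(library_sizes[s] for s in samples_b)
    pi0 = lib_a / (lib_a + lib_b)
    x_a = counts[samples_a].sum(axis=1).to_numpy()
    x_b = counts[samples_b].sum(axis=1).to_numpy()

    pvals = np.ones(len(counts))
    for i, (xa, xb) in enumerate(zip(x_a, x_b)):
        n = int(xa + xb)
        if n > 0:
            pvals[i] = binomtest(int(xa), n, pi0).pvalue
    qvals = benjamini_hochberg(pvals)

    status = np.where(
        (np.abs(log2fc) >= lfc_min) & (qvals <= q_max),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {
            "feature_id": counts.index,
            "tissue_a": tissue_a,
            "tissue_b": tissue_b,
            "mean_rpm_a": mean_a.to_numpy(),
            "mean_rpm_b": mean_b.to_numpy(),
            "log2fc": log2fc.to_numpy(),
            "p": pvals,
            "q": qvals,
            "status": status,
        }
    ).set_index("feature_id")


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    feature_linkage: np.ndarray
    sample_linkage: np.ndarray | None
    zscores: pd.DataFrame
    dropped: list[str]


def zscore_cluster(
    matrix: ExpressionMatrix | pd.DataFrame,
    k: int = 5,
    design: Mapping[str, str] | None = None,
) -> ClusterAssignment:
    """Z-score expression profiles and cluster them hierarchically.

    With ``design``, replicate columns are first averaged per tissue (the
    usual heatmap layout).  Rows are Z-scored (mean 0, unit population
    variance); constant rows are dropped with a warning.  Features and
    columns are clustered with Euclidean distance and average linkage; the
    feature tree is cut into ``k`` clusters (labels 1..k).
    """
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    df = df.astype(float)
    if design is not None:
        tissues = {}
        for s in df.columns:
            tissues.setdefault(design[s], []).append(s)
        df = pd.DataFrame({t: df[cols].mean(axis=1) for t, cols in tissues.items()})

    arr = df.to_numpy()
    sd = arr.std(axis=1)
    constant = sd == 0
    dropped = list(df.index[constant])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant feature(s) before clustering")
    df = df.loc[~constant]
    arr = arr[~constant]
    if k > len(df):
        raise ValueError(f"k={k} exceeds the {len(df)} clusterable features")
    z = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(axis=1, keepdims=True)
    zdf = pd.DataFrame(z, index=df.index, columns=df.columns)

    if len(df) == 1:
        feat_link = np.empty((0, 4))
        labels_arr = np.array([1])
    else:
        feat_link = hierarchy.linkage(pdist(z, metric="euclidean"), method="average")
        labels_arr = hierarchy.fcluster(feat_link, t=k, criterion="maxclust")
    sample_link = None
    if z.shape[1] >= 2:
        sample_link = hierarchy.linkage(pdist(z.T, metric="euclidean"), method="average")
    return ClusterAssignment(
        labels=dict(zip(df.index, (int(x) for x in labels_arr))),
        feature_linkage=feat_link,
        sample_linkage=sample_link,
        zscores=zdf,
        dropped=dropped,
    )
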