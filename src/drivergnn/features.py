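"""The 36-feature gene engine.

Each gene receives 26 genomic features (mutation frequency, variant allele
fraction, 11 mutational-heterogeneity covariates, 12 base-conversion counts,
copy-number variation rate), 3 transcriptomic features (log2 expression fold
change, Wilcoxon differential-expression flag, Grubbs outlier count), 1
epigenomic feature (methylation fold change) and 6 network-derived features
(4 from the mutation-outlier bipartite graph plus degree and betweenness
centrality). Features are min-max scaled per feature across genes before the
matrix is assembled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from drivergnn.io import (
    COVARIATE_COLUMNS,
    CNVMatrix,
    CovariateTable,
    ExpressionMatrix,
    MethylationMatrix,
    MutationTable,
    OmicsBundle,
    PPIGraph,
)

logger = logging.getLogger(__name__)

EPS = 1e-6

#: ordered base-conversion classes (12 genomic features)
CONVERSION_CLASSES = [
    "C>A", "C>T", "C>G", "A>T", "A>C", "A>G",
    "G>C", "G>A", "G>T", "T>A", "T>G", "T>C",
]

NETWORK_COLUMNS = [
    "bipartite_E",
    "bipartite_LCPRG",
    "bipartite_CPRG",
    "NSC",
    "degree",
    "betweenness",
]

#: the full, fixed 36-column schema: (feature name, block)
FEATURE_SCHEMA: list[tuple[str, str]] = (
    [("mutation_frequency", "genomic"), ("vaf", "genomic")]
    + [(c, "genomic") for c in COVARIATE_COLUMNS]
    + [(f"conv_{c.replace('>', '_')}", "genomic") for c in CONVERSION_CLASSES]
    + [("cnv_rate", "genomic")]
    + [
        ("expression_fold_change", "transcriptomic"),
        ("de_flag", "transcriptomic"),
        ("outlier_count", "transcriptomic"),
    ]
    + [("methylation_fold_change", "epigenomic")]
    + [(c, "network") for c in NETWORK_COLUMNS]
)

BLOCK_SIZES = {"genomic": 26, "transcriptomic": 3, "epigenomic": 1, "network": 6}


@dataclass
class GeneFeatureMatrix:
    """Genes x 36 feature table with the fixed named column schema."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        expected = [name for name, _ in FEATURE_SCHEMA]
        if list(self.values.columns) != expected:
            raise ValueError("feature matrix columns do not match the 36-feature schema")
        counts: dict[str, int] = {}
        for _, block in FEATURE_SCHEMA:
            counts[block] = counts.get(block, 0) + 1
        assert counts == BLOCK_SIZES

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def block(self, name: str) -> pd.DataFrame:
        cols = [c for c, b in FEATURE_SCHEMA if b == name]
        return self.values[cols]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    def schema_manifest(self) -> pd.DataFrame:
        return pd.DataFrame(FEATURE_SCHEMA, columns=["feature", "block"])


@dataclass
class OutlierMatrix:
    """Binary genes x tumor-samples matrix of Grubbs outlier calls."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.isin(v, (0, 1)).all():
            raise ValueError("outlier matrix entries must be 0/1")


# ---------------------------------------------------------------------------
# epigenomic / transcriptomic
# ---------------------------------------------------------------------------


def methylation_fold_change(meth: MethylationMatrix) -> pd.Series:
    """Ratio of mean tumor beta to mean normal beta, epsilon-protected.

    Genes with all-missing values in either group map to 0.
    """
    t = meth.tumor_values().mean(axis=1, skipna=True)
    n = meth.normal_values().mean(axis=1, skipna=True)
    out = (t + EPS) / (n + EPS)
    out[t.isna() | n.isna()] = 0.0
    return out.rename("methylation_fold_change")


def expression_fold_change(expr: ExpressionMatrix, log2: bool = True) -> pd.Series:
    """log2 of the epsilon-protected tumor/normal mean-expression ratio.

    ``log2=False`` returns the plain ratio instead.
    """
    t = expr.tumor_values().mean(axis=1, skipna=True)
    n = expr.normal_values().mean(axis=1, skipna=True)
    ratio = (t + EPS) / (n + EPS)
    out = np.log2(ratio) if log2 else ratio
    out[t.isna() | n.isna()] = 0.0
    return out.rename("expression_fold_change")


def de_significance_flag(expr: ExpressionMatrix, alpha: float = 0.05) -> pd.Series:
    """Wilcoxon rank-sum differential-expression flag in {-1, 0, 1}.

    1 if tumor significantly above normal, -1 if significantly below,
    0 otherwise; two-sided test at ``alpha``.
    """
    tv = expr.tumor_values()
    nv = expr.normal_values()
    genes = expr.gene_ids
    flags = pd.Series(0, index=genes, dtype=int, name="de_flag")
    if tv.shape[1] < 2 or nv.shape[1] < 2:
        logger.warning("fewer than 2 samples in a group; DE flags set to 0")
        return flags
    t_arr = tv.to_numpy(dtype=float)
    n_arr = nv.to_numpy(dtype=float)
    if not (np.isnan(t_arr).any() or np.isnan(n_arr).any()):
        stat, p = stats.ranksums(t_arr, n_arr, axis=1)
        tmean = t_arr.mean(axis=1)
        nmean = n_arr.mean(axis=1)
        sig = p < alpha
        flags[:] = np.where(sig, np.where(nmean < tmean, 1, -1), 0)
        return flags
    for i, g in enumerate(genes):
        x = t_arr[i][~np.isnan(t_arr[i])]
        y = n_arr[i][~np.isnan(n_arr[i])]
        if len(x) < 2 or len(y) < 2:
            logger.warning("gene %s has <2 values in a group; DE flag 0", g)
            continue
        _, p = stats.ranksums(x, y)
        if p < alpha:
            flags[g] = 1 if y.mean() < x.mean() else -1
    return flags


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Grubbs critical value G_p(N).

    G_p(N) = ((N-1)/sqrt(N)) * sqrt(t^2 / (N-2+t^2)) with t the upper
    alpha/(2N) quantile of Student's t with N-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs critical value requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def outlier_matrix(expr: ExpressionMatrix, alpha: float = 0.05) -> OutlierMatrix:
    """Grubbs outlier calls per gene over tumor samples.

    G_ij = (x_ij - mean_i) / S_i over tumor samples (upper tail, signed: a
    sample far below the mean is not an outlier); entry 1 iff G_ij > G_p(N).
    Constant genes (S_i = 0) yield all-zero rows.
    """
    tv = expr.tumor_values()
    n = tv.shape[1]
    if n < 3:
        raise ValueError("outlier matrix requires >= 3 tumor samples")
    x = tv.to_numpy(dtype=float)
    mean = np.nanmean(x, axis=1, keepdims=True)
    sd = np.nanstd(x, axis=1, ddof=1, keepdims=True)
    gp = grubbs_critical_value(n, alpha)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = (x - mean) / sd
    out = (g > gp).astype(int)
    out[np.broadcast_to(sd == 0, out.shape)] = 0
    out[np.isnan(x)] = 0
    return OutlierMatrix(values=pd.DataFrame(out, index=tv.index, columns=tv.columns))


def gene_outlier_count(om: OutlierMatrix) -> pd.Series:
    """Row sums of the patient-outlier matrix."""
    return om.values.sum(axis=1).rename("outlier_count")


# ---------------------------------------------------------------------------
# genomic
# ---------------------------------------------------------------------------


def mutation_frequency(
    muts: MutationTable, tumor_samples: list[str], gene_ids: list[str] | None = None
) -> pd.Series:
    """Fraction of tumor samples carrying >= 1 mutation record per gene."""
    if not tumor_samples:
        raise ValueError("tumor_samples must be non-empty")
    sample_set = set(tumor_samples)
    rec = muts.records
    rec = rec[rec["sample"].isin(sample_set)]
    counts = rec.groupby("gene")["sample"].nunique()
    idx = gene_ids if gene_ids is not None else sorted(counts.index)
    return (
        counts.reindex(idx).fillna(0).astype(float) / len(tumor_samples)
    ).rename("mutation_frequency")


def gene_vaf(muts: MutationTable, gene_ids: list[str] | None = None) -> pd.Series:
    """Mean variant allele fraction (alt_depth / total_depth) per gene."""
    rec = muts.records
    vaf = rec["alt_depth"] / rec["total_depth"]
    mean = vaf.groupby(rec["gene"]).mean()
    idx = gene_ids if gene_ids is not None else sorted(mean.index)
    return mean.reindex(idx).fillna(0.0).rename("vaf")


def base_conversion_counts(
    muts: MutationTable, gene_ids: list[str] | None = None
) -> pd.DataFrame:
    """Total SNV record count per gene in each of the 12 conversion classes."""
    rec = muts.records[muts.records["is_snv"]]
    conv = rec["ref"] + ">" + rec["alt"]
    table = pd.crosstab(rec["gene"], conv)
    idx = gene_ids if gene_ids is not None else sorted(table.index)
    table = table.reindex(index=idx, columns=CONVERSION_CLASSES).fillna(0).astype(int)
    table.columns = [f"conv_{c.replace('>', '_')}" for c in CONVERSION_CLASSES]
    return table


def cnv_rate(cnv: CNVMatrix) -> pd.Series:
    """Copy-number variation rate: tumor event sum x n over normal event sum x m.

    The per-sample event count is the absolute GISTIC call. m = tumor sample
    count, n = normal sample count. A zero normal denominator is replaced by a
    single pseudo-event.
    """
    t = cnv.tumor_values().abs().sum(axis=1, skipna=True)
    nvals = cnv.normal_values().abs().sum(axis=1, skipna=True)
    m = len(cnv.tumor_samples)
    n = len(cnv.normal_samples)
    if m == 0 or n == 0:
        raise ValueError("CNV rate requires >= 1 tumor and >= 1 normal sample")
    zero = nvals == 0
    if zero.any():
        logger.info("CNV pseudo-event applied to %d genes with all-zero normals", int(zero.sum()))
        nvals = nvals.where(~zero, 1.0)
    return ((t * n) / (nvals * m)).rename("cnv_rate")


def attach_covariates(cov: CovariateTable, gene_ids: list[str]) -> pd.DataFrame:
    """Align the 11 covariates to gene_ids; absent genes get column medians."""
    aligned = cov.values.reindex(gene_ids)
    medians = cov.values.median(axis=0)
    return aligned.fillna(medians)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def normalize_features(raw: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each feature across genes; constant features map to 0."""
    arr = raw.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        bad = raw.columns[~np.isfinite(arr).all(axis=0)].tolist()
        raise ValueError(f"non-finite values in features: {bad}")
    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    span = hi - lo
    span[span == 0] = 1.0
    scaled = (arr - lo) / span
    scaled[:, (hi - lo) == 0] = 0.0
    return pd.DataFrame(scaled, index=raw.index, columns=raw.columns)


def assemble_feature_matrix(
    mut_freq: pd.Series,
    vaf: pd.Series,
    covariates: pd.DataFrame,
    conversions: pd.DataFrame,
    cnv: pd.Series,
    expr_fc: pd.Series,
    de_flag: pd.Series,
    outlier_count: pd.Series,
    meth_fc: pd.Series,
    network: pd.DataFrame,
) -> GeneFeatureMatrix:
    """Concatenate all feature blocks in schema order and min-max normalize."""
    blocks = {
        "mutation_frequency": mut_freq,
        "vaf": vaf,
        "covariates": covariates,
        "conversions": conversions,
        "cnv_rate": cnv,
        "expression_fold_change": expr_fc,
        "de_flag": de_flag,
        "outlier_count": outlier_count,
        "methylation_fold_change": meth_fc,
        "network": network,
    }
    for name, b in blocks.items():
        if b is None:
            raise ValueError(f"missing feature block: {name}")
    gene_ids = list(mut_freq.index)
    for name, b in blocks.items():
        if list(b.index) != gene_ids:
            raise ValueError(f"feature block {name!r} gene ids do not match")
    if list(network.columns) != NETWORK_COLUMNS:
        raise ValueError("network block must have columns " + ", ".join(NETWORK_COLUMNS))
    raw = pd.concat(
        [
            mut_freq.rename("mutation_frequency"),
            vaf.rename("vaf"),
            covariates,
            conversions,
            cnv.rename("cnv_rate"),
            expr_fc.rename("expression_fold_change"),
            de_flag.rename("de_flag"),
            outlier_count.rename("outlier_count"),
            meth_fc.rename("methylation_fold_change"),
            network,
        ],
        axis=1,
    )
    return GeneFeatureMatrix(values=normalize_features(raw))


def compute_feature_matrix(
    bundle: OmicsBundle,
    ppi: PPIGraph,
    cprg: list[str],
    centrality_network: PPIGraph | None = None,
    de_alpha: float = 0.05,
    grubbs_alpha: float = 0.05,
) -> GeneFeatureMatrix:
    """End-to-end feature computation for every gene in the bundle.

    ``centrality_network`` (e.g. a BioGRID-style unscored network) defaults to
    the score-filtered PPI used for message passing.
    """
    from drivergnn.network_features import (
        bipartite_features,
        build_bipartite,
        centrality_features,
    )

    gene_ids = bundle.gene_ids
    om = outlier_matrix(bundle.expression, alpha=grubbs_alpha)
    bg = build_bipartite(bundle.mutations, om, ppi)
    bip = bipartite_features(bg, cprg, bundle.tumor_samples, gene_ids)
    cent = centrality_features(centrality_network or ppi, gene_ids)
    network = pd.concat([bip, cent], axis=1)

    return assemble_feature_matrix(
        mut_freq=mutation_frequency(bundle.mutations, bundle.tumor_samples, gene_ids),
        vaf=gene_vaf(bundle.mutations, gene_ids),
        covariates=attach_covariates(bundle.covariates, gene_ids),
        conversions=base_conversion_counts(bundle.mutations, gene_ids),
        cnv=cnv_rate(bundle.cnv).reindex(gene_ids).fillna(0.0),
        expr_fc=expression_fold_change(bundle.expression).reindex(gene_ids).fillna(0.0),
        de_flag=de_significance_flag(bundle.expression, alpha=de_alpha).reindex(gene_ids).fillna(0),
        outlier_count=gene_outlier_count(om).reindex(gene_ids).fillna(0),
        meth_fc=methylation_fold_change(bundle.methylation).reindex(gene_ids).fillna(0.0),
        network=network,
    )
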