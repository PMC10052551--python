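"""Readers, writers and domain containers for every external format the
pipeline touches.

All tabular formats are plain TSV (UTF-8, header row, gene column first).
Mutations arrive as a MAF-dialect TSV, gene sets as GMT, the PPI network as
a 2- or 3-column edge list (STRING combined scores on either the 0-1 or the
0-1000 scale are accepted).

Gene identity is the bare symbol string, case-sensitive, stripped of
surrounding whitespace. Cross-table alignment is by intersection of symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"

BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class OmicsMatrix:
    """A genes x samples matrix with a tumor/normal group for each sample.

    ``values`` is a DataFrame indexed by gene symbol with sample barcodes as
    columns; missing entries are NaN and every group mean downstream is taken
    over present values only.
    """

    values: pd.DataFrame
    group: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            raise ValueError("duplicate gene symbols in matrix index")
        if cols.has_duplicates:
            raise ValueError("duplicate sample barcodes in matrix columns")
        missing = [s for s in cols if s not in self.group]
        if missing:
            raise ValueError(f"samples without a tumor/normal group: {missing[:5]}")
        bad = {g for g in self.group.values()} - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown sample groups: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.group[s] == TUMOR]

    @property
    def normal_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.group[s] == NORMAL]

    def tumor_values(self) -> pd.DataFrame:
        return self.values[self.tumor_samples]

    def normal_values(self) -> pd.DataFrame:
        return self.values[self.normal_samples]


class ExpressionMatrix(OmicsMatrix):
    """Gene expression (non-negative, units as provided, e.g. FPKM)."""


class MethylationMatrix(OmicsMatrix):
    """Gene-level methylation beta values in [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        v = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                raise ValueError("methylation beta values must lie in [0, 1]")


class CNVMatrix(OmicsMatrix):
    """GISTIC-style integer copy-number calls (negative = deletion)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        v = self.values.to_numpy(dtype=float)
        ok = np.isnan(v) | (v == np.round(v))
        if not ok.all():
            raise ValueError("CNV matrix must be integer-valued")


#: fixed order of the 11 MutSigCV-style mutational-heterogeneity covariates
COVARIATE_COLUMNS = [
    "replication_time",
    "noncoding_mutation_rate",
    "local_gc_content",
    "hic_compartment",
    "local_gene_density",
    "wgs_mean_depth",
    "wgs_percent_20x",
    "capture_on_target_rate",
    "capture_mean_depth",
    "capture_pct200",
    "capture_mean_percentgc",
]


@dataclass
class CovariateTable:
    """Gene-level table of the 11 mutational-heterogeneity covariates."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] != 11:
            raise ValueError(
                f"covariate table must have exactly 11 columns, got {self.values.shape[1]}"
            )
        self.values = self.values.copy()
        self.values.columns = COVARIATE_COLUMNS

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class MutationTable:
    """Somatic mutation records (MAF-like).

    ``records`` has columns gene, sample, ref, alt, alt_depth, total_depth and
    an ``is_snv`` flag. Non-SNV rows (indels, multi-base alleles) are retained
    for mutation-frequency and VAF purposes but excluded from base-conversion
    counting. Records with alt_depth > total_depth or total_depth <= 0 are
    rejected at read time.
    """

    records: pd.DataFrame
    n_rejected: int = 0

    COLUMNS = ["gene", "sample", "ref", "alt", "alt_depth", "total_depth", "is_snv"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"mutation table missing columns: {missing}")
        self.records = self.records[self.COLUMNS].reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())

    def records_for(self, gene: str) -> pd.DataFrame:
        return self.records[self.records["gene"] == gene]


@dataclass
class PPIGraph:
    """Undirected simple gene graph; the message-passing substrate."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            self.graph.remove_edges_from(loops)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene))


@dataclass
class OmicsBundle:
    """The five aligned input tables plus sample group labels."""

    expression: ExpressionMatrix
    methylation: MethylationMatrix
    mutations: MutationTable
    cnv: CNVMatrix
    covariates: CovariateTable

    @property
    def gene_ids(self) -> list[str]:
        return self.expression.gene_ids

    @property
    def tumor_samples(self) -> list[str]:
        return self.expression.tumor_samples


@dataclass
class RunConfig:
    """Per-tumor-type run configuration.

    Layer widths default to the 36/64 -> 64/128 -> 128/2 configuration; the
    softmax head is always 2-wide (driver vs passenger).
    """

    tumor_type: str = "SYNTH"
    gat_out: int = 64
    sage1_out: int = 128
    sage2_out: int = 2
    train_fraction: float = 0.7
    seed: int = 7
    learning_rate: float = 0.01
    weight_decay: float = 5e-4
    epochs: int = 200
    leaky_slope: float = 0.2
    dropout: float = 0.5
    string_score_threshold: float = 0.9
    de_alpha: float = 0.05
    grubbs_alpha: float = 0.05
    label_corr_threshold: float = 0.8
    spearman_threshold: float = 0.4
    correlation_p_cutoff: float = 1e-3
    n_core_genes: int = 20
    n_candidates: int = 20
    pseudolabel_mode: bool = False

    def __post_init__(self) -> None:
        if self.sage2_out != 2:
            raise ValueError("output layer width must be 2 (binary softmax head)")
        for name in ("gat_out", "sage1_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        kwargs: dict = {}
        casts = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in casts:
                logger.warning("unknown config key %r ignored", key)
                continue
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(raw)
            elif isinstance(current, float):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        kwargs.update(overrides)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_group_map(path: str | Path) -> dict[str, str]:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"group map line with fewer than 2 columns: {line!r}")
        rows.append((parts[0].strip(), parts[1].strip()))
    # tolerate a header row
    if rows and rows[0][1] not in (TUMOR, NORMAL):
        rows = rows[1:]
    group = {}
    for sample, grp in rows:
        if grp not in (TUMOR, NORMAL):
            raise ValueError(f"sample {sample!r} has unknown group {grp!r}")
        group[sample] = grp
    return group


def _read_gene_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric cell at gene {bad.index[0]!r}, sample {col!r}: {bad.iloc[0]!r}"
                )
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        logger.warning("duplicate gene rows collapsed by mean: %s", dups[:10])
        df = df.groupby(level=0, sort=False).mean()
    return df


def _make_matrix(cls, path, group_map):
    df = _read_gene_matrix(path)
    group = _read_group_map(group_map)
    missing = [s for s in df.columns if s not in group]
    if missing:
        raise ValueError(f"sample {missing[0]!r} has no tumor/normal group assignment")
    return cls(values=df, group={s: group[s] for s in df.columns})


def read_expression_matrix(path: str | Path, group_map: str | Path) -> ExpressionMatrix:
    """Read a genes x samples expression TSV plus a sample->group TSV."""
    return _make_matrix(ExpressionMatrix, path, group_map)


def read_methylation_matrix(path: str | Path, group_map: str | Path) -> MethylationMatrix:
    return _make_matrix(MethylationMatrix, path, group_map)


def read_cnv_matrix(path: str | Path, group_map: str | Path) -> CNVMatrix:
    return _make_matrix(CNVMatrix, path, group_map)


def read_covariate_table(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    return CovariateTable(values=df)


_MAF_ALIASES = {
    "gene": ("gene", "Hugo_Symbol"),
    "sample": ("sample", "Tumor_Sample_Barcode"),
    "ref": ("ref", "Reference_Allele"),
    "alt": ("alt", "Tumor_Seq_Allele2"),
    "alt_depth": ("alt_depth", "t_alt_count"),
    "total_depth": ("total_depth", "t_depth"),
}


def read_mutation_table(path: str | Path) -> MutationTable:
    """Read a MAF-dialect somatic mutation TSV.

    Both bare column names (gene, sample, ref, alt, alt_depth, total_depth)
    and the MAF dialect (Hugo_Symbol, Tumor_Sample_Barcode, Reference_Allele,
    Tumor_Seq_Allele2, t_alt_count, t_depth) are accepted.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = {}
    for canon, aliases in _MAF_ALIASES.items():
        found = [a for a in aliases if a in raw.columns]
        if not found:
            raise ValueError(f"mutation table missing a column for {canon!r} (tried {aliases})")
        cols[canon] = found[0]
    df = pd.DataFrame(
        {
            "gene": raw[cols["gene"]].astype(str).str.strip(),
            "sample": raw[cols["sample"]].astype(str).str.strip(),
            "ref": raw[cols["ref"]].astype(str).str.strip().str.upper(),
            "alt": raw[cols["alt"]].astype(str).str.strip().str.upper(),
            "alt_depth": pd.to_numeric(raw[cols["alt_depth"]], errors="coerce"),
            "total_depth": pd.to_numeric(raw[cols["total_depth"]], errors="coerce"),
        }
    )
    bad_depth = (
        df["alt_depth"].isna()
        | df["total_depth"].isna()
        | (df["total_depth"] <= 0)
        | (df["alt_depth"] > df["total_depth"])
        | (df["alt_depth"] < 0)
    )
    n_rejected = int(bad_depth.sum())
    if n_rejected:
        logger.warning("rejected %d mutation records with invalid depths", n_rejected)
    df = df[~bad_depth].copy()
    df["alt_depth"] = df["alt_depth"].astype(int)
    df["total_depth"] = df["total_depth"].astype(int)
    df["is_snv"] = (
        df["ref"].isin(BASES) & df["alt"].isin(BASES) & (df["ref"] != df["alt"])
    )
    return MutationTable(records=df, n_rejected=n_rejected)


def read_ppi_edges(path: str | Path, threshold: float = 0.9) -> PPIGraph:
    """Read a 2/3-column edge list and keep edges with score > threshold.

    Scores on the STRING 0-1000 scale are auto-detected (any score > 1) and
    the threshold is scaled by 1000. Self-loops are dropped; duplicate pairs
    keep the maximum score. A file with no surviving edges is a hard error.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 2:
            continue
        score = None
        if len(parts) >= 3 and parts[2] != "":
            try:
                score = float(parts[2])
            except ValueError:
                continue  # header row
        rows.append((parts[0], parts[1], score))
    scored = [r for r in rows if r[2] is not None]
    scale = 1.0
    if scored and max(r[2] for r in scored) > 1.0:
        scale = 1000.0
    g = nx.Graph()
    for a, b, score in rows:
        if a == b:
            continue
        if score is not None and score <= threshold * scale:
            continue
        if g.has_edge(a, b):
            prev = g[a][b].get("score")
            if score is not None and (prev is None or score > prev):
                g[a][b]["score"] = score
        else:
            g.add_edge(a, b, score=score)
    if g.number_of_edges() == 0:
        raise ValueError(f"no PPI edges survive score threshold {threshold}")
    return PPIGraph(graph=g)


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into {set name: de-duplicated, order-preserving genes}."""
    sets: dict[str, list[str]] = {}
    lines = Path(path).read_text().splitlines()
    if not any(line.strip() for line in lines):
        logger.warning("empty gene-set file: %s", path)
        return sets
    for line in lines:
        if not line.strip():
            continue
        parts = [p.strip() for p in line.rstrip("\n").split("\t")]
        if len(parts) < 3:
            logger.warning("skipping GMT line with fewer than 3 fields: %r", line[:60])
            continue
        name, _desc, *genes = parts
        seen: dict[str, None] = {}
        for gene in genes:
            if gene and gene not in seen:
                seen[gene] = None
        sets[name] = list(seen)
    return sets


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_gene_matrix(m: OmicsMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def write_group_map(group: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, grp in group.items():
            fh.write(f"{sample}\t{grp}\n")


def write_mutation_table(muts: MutationTable, path: str | Path) -> None:
    muts.records.drop(columns="is_snv").to_csv(path, sep="\t", index=False)


def write_ppi_edges(ppi: PPIGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\tscore\n")
        for a, b, data in ppi.graph.edges(data=True):
            score = data.get("score")
            fh.write(f"{a}\t{b}\t{'' if score is None else score}\n")


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")
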