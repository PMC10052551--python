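"""Synthetic multiomics bundle generator with planted driver genes.

Emulates the shapes of the real inputs (tumor + normal expression,
methylation beta values, MAF-like SNV records, GISTIC-style CNV calls, 11
mutational covariates, a scored PPI edge list, CPRG and driver gene sets)
so the whole pipeline runs with no download. Drivers carry an elevated
mutation rate, a log2 expression shift in tumors, a methylation shift, CNV
enrichment and preferential placement on network hubs. Not a biological
simulator: no linkage, clonal structure or mutational signatures.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from drivergnn.io import (
    BASES,
    CNVMatrix,
    CovariateTable,
    ExpressionMatrix,
    MethylationMatrix,
    MutationTable,
    OmicsBundle,
    PPIGraph,
    write_gene_matrix,
    write_gene_sets,
    write_group_map,
    write_mutation_table,
    write_ppi_edges,
)
from drivergnn.labeling import NEGATIVE, POSITIVE, UNLABELED, LabelSet


@dataclass
class SimulationSpec:
    """Study conditions of the synthetic instance.

    Defaults give a recoverable planted-driver problem: 2000 genes, 200
    tumor + 30 normal samples, 50 drivers mutated at 0.25 vs a 0.02
    passenger rate, a 1.5 log2-unit tumor expression shift, a 0.15
    beta-unit methylation shift, and drivers wired toward network hubs.
    """

    n_genes: int = 2000
    n_tumor: int = 200
    n_normal: int = 30
    n_drivers: int = 50
    driver_mutation_rate: float = 0.25
    passenger_mutation_rate: float = 0.02
    driver_expression_shift: float = 1.5  # log2 units
    driver_methylation_shift: float = 0.15  # beta units
    driver_cnv_event_rate: float = 0.5  # per driver x tumor sample
    passenger_cnv_event_rate: float = 0.08
    n_cprg: int = 60
    hub_attachment: int = 3
    hub_bias: bool = True
    negative_fraction: float = 0.7
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_drivers >= self.n_genes:
            raise ValueError("n_drivers must be smaller than n_genes")
        for name in ("driver_mutation_rate", "passenger_mutation_rate"):
            r = getattr(self, name)
            if not 0 < r < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_cprg + self.n_drivers > self.n_genes:
            raise ValueError("n_cprg + n_drivers must not exceed n_genes")


@dataclass
class SimulationResult:
    bundle: OmicsBundle
    ppi: PPIGraph
    labels: LabelSet
    cprg: list[str]
    drivers: list[str]


def simulate_bundle(spec: SimulationSpec) -> SimulationResult:
    """Generate a complete, internally consistent synthetic instance."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    tumor = [f"T{i:04d}" for i in range(spec.n_tumor)]
    normal = [f"N{i:04d}" for i in range(spec.n_normal)]
    samples = tumor + normal
    group = {s: "tumor" for s in tumor} | {s: "normal" for s in normal}

    # --- network: preferential attachment; drivers wired toward hubs -----
    g_idx = nx.barabasi_albert_graph(
        spec.n_genes, spec.hub_attachment, seed=int(rng.integers(2**31))
    )
    degree_order = sorted(g_idx.nodes, key=lambda v: (-g_idx.degree[v], v))
    if spec.hub_bias:
        # drivers occupy nodes drawn from the top-degree quintile
        pool = degree_order[: max(2 * spec.n_drivers, spec.n_genes // 5)]
        driver_nodes = rng.choice(pool, size=spec.n_drivers, replace=False)
    else:
        driver_nodes = rng.choice(spec.n_genes, size=spec.n_drivers, replace=False)
    driver_nodes = set(int(v) for v in driver_nodes)
    drivers = sorted(f"G{v:05d}" for v in driver_nodes)
    relabel = {v: f"G{v:05d}" for v in g_idx.nodes}
    ppi_graph = nx.relabel_nodes(g_idx, relabel)
    for a, b in ppi_graph.edges:
        ppi_graph[a][b]["score"] = float(np.round(0.901 + 0.098 * rng.random(), 4))
    ppi = PPIGraph(graph=ppi_graph)

    driver_mask = np.array([g in set(drivers) for g in genes])
    non_drivers = [g for g in genes if g not in set(drivers)]
    cprg = sorted(rng.choice(non_drivers, size=spec.n_cprg, replace=False).tolist())
    cprg_mask = np.array([g in set(cprg) for g in genes])

    # --- expression: lognormal baseline, CPRG latent factor, driver shift
    base = rng.lognormal(mean=3.0, sigma=1.0, size=spec.n_genes)
    noise = rng.lognormal(mean=0.0, sigma=0.4, size=(spec.n_genes, len(samples)))
    expr = base[:, None] * noise
    factor = rng.lognormal(mean=0.0, sigma=0.5, size=len(samples))
    loading = rng.uniform(0.6, 1.0, size=int(cprg_mask.sum()))
    expr[cprg_mask] *= factor[None, :] ** loading[:, None]
    expr[np.ix_(driver_mask, np.arange(spec.n_tumor))] *= 2.0**spec.driver_expression_shift
    expression = ExpressionMatrix(
        values=pd.DataFrame(expr, index=genes, columns=samples), group=dict(group)
    )

    # --- methylation: Beta(5,5) background with a driver shift in tumors -
    meth = rng.beta(5.0, 5.0, size=(spec.n_genes, len(samples)))
    meth[np.ix_(driver_mask, np.arange(spec.n_tumor))] = np.clip(
        meth[np.ix_(driver_mask, np.arange(spec.n_tumor))] + spec.driver_methylation_shift,
        0.0,
        1.0,
    )
    methylation = MethylationMatrix(
        values=pd.DataFrame(meth, index=genes, columns=samples), group=dict(group)
    )

    # --- mutations: Bernoulli per gene x tumor sample, SNV records -------
    rates = np.where(driver_mask, spec.driver_mutation_rate, spec.passenger_mutation_rate)
    events = rng.random((spec.n_genes, spec.n_tumor)) < rates[:, None]
    gi, si = np.nonzero(events)
    n_events = len(gi)
    ref_idx = rng.integers(0, 4, size=n_events)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_events)) % 4
    total = np.maximum(rng.poisson(100, size=n_events), 1)
    alt = np.minimum(rng.binomial(total, 0.3), total)
    records = pd.DataFrame(
        {
            "gene": [genes[i] for i in gi],
            "sample": [tumor[j] for j in si],
            "ref": [BASES[i] for i in ref_idx],
            "alt": [BASES[i] for i in alt_idx],
            "alt_depth": alt,
            "total_depth": total,
            "is_snv": True,
        }
    )
    mutations = MutationTable(records=records)

    # --- CNV: event w.p. rate, then a +-1/+-2 GISTIC call; drivers get an
    # elevated event rate in tumors, normals half the passenger rate -------
    event_rate = np.full((spec.n_genes, len(samples)), spec.passenger_cnv_event_rate)
    event_rate[:, spec.n_tumor:] = spec.passenger_cnv_event_rate / 2.0
    event_rate[np.ix_(driver_mask, np.arange(spec.n_tumor))] = spec.driver_cnv_event_rate
    has_event = rng.random((spec.n_genes, len(samples))) < event_rate
    magnitudes = rng.choice(
        [-2, -1, 1, 2], size=(spec.n_genes, len(samples)), p=[0.1, 0.4, 0.4, 0.1]
    )
    cnv = np.where(has_event, magnitudes, 0)
    cnv_matrix = CNVMatrix(
        values=pd.DataFrame(cnv, index=genes, columns=samples), group=dict(group)
    )

    # --- covariates: standard normal -------------------------------------
    covariates = CovariateTable(
        values=pd.DataFrame(
            rng.normal(size=(spec.n_genes, 11)),
            index=genes,
            columns=range(11),
        )
    )

    # --- labels: drivers positive; a seeded 70% of the rest negative -----
    perm = rng.permutation(len(non_drivers))
    n_neg = int(round(spec.negative_fraction * len(non_drivers)))
    negatives = {non_drivers[i] for i in perm[:n_neg]}
    lab = pd.Series(
        [
            POSITIVE if g in set(drivers) else NEGATIVE if g in negatives else UNLABELED
            for g in genes
        ],
        index=genes,
        dtype=object,
    )
    labels = LabelSet(
        labels=lab, provenance={g: "planted_driver" for g in drivers}
    )

    bundle = OmicsBundle(
        expression=expression,
        methylation=methylation,
        mutations=mutations,
        cnv=cnv_matrix,
        covariates=covariates,
    )
    return SimulationResult(bundle=bundle, ppi=ppi, labels=labels, cprg=cprg, drivers=drivers)


FIXTURE_FILES = [
    "expression.tsv",
    "groups.tsv",
    "methylation.tsv",
    "cnv.tsv",
    "covariates.tsv",
    "mutations.tsv",
    "ppi.tsv",
    "gene_sets.gmt",
    "labels.tsv",
]


def write_fixture(result: SimulationResult, directory: str | Path, overwrite: bool = False) -> list[Path]:
    """Write the bundle as the standard-format file set the CLI expects.

    Emits 9 files plus a manifest TSV listing each file with its row count.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty; pass overwrite=True")
    directory.mkdir(parents=True, exist_ok=True)
    b = result.bundle
    write_gene_matrix(b.expression, directory / "expression.tsv")
    write_group_map(b.expression.group, directory / "groups.tsv")
    write_gene_matrix(b.methylation, directory / "methylation.tsv")
    write_gene_matrix(b.cnv, directory / "cnv.tsv")
    b.covariates.values.to_csv(directory / "covariates.tsv", sep="\t", index_label="gene")
    write_mutation_table(b.mutations, directory / "mutations.tsv")
    write_ppi_edges(result.ppi, directory / "ppi.tsv")
    write_gene_sets(
        {"drivers": result.drivers, "CPRG": result.cprg}, directory / "gene_sets.gmt"
    )
    result.labels.to_tsv(directory / "labels.tsv")

    rows = []
    for name in FIXTURE_FILES:
        path = directory / name
        n_rows = sum(1 for _ in open(path))
        rows.append({"file": name, "rows": n_rows, "sha256": _digest(path)})
    pd.DataFrame(rows).to_csv(directory / "manifest.tsv", sep="\t", index=False)
    return [directory / name for name in FIXTURE_FILES]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def read_fixture(directory: str | Path) -> SimulationResult:
    """Re-read a written fixture into the in-memory bundle."""
    from drivergnn.io import (
        read_cnv_matrix,
        read_covariate_table,
        read_expression_matrix,
        read_gene_sets,
        read_methylation_matrix,
        read_mutation_table,
        read_ppi_edges,
    )

    directory = Path(directory)
    groups = directory / "groups.tsv"
    bundle = OmicsBundle(
        expression=read_expression_matrix(directory / "expression.tsv", groups),
        methylation=read_methylation_matrix(directory / "methylation.tsv", groups),
        mutations=read_mutation_table(directory / "mutations.tsv"),
        cnv=read_cnv_matrix(directory / "cnv.tsv", groups),
        covariates=read_covariate_table(directory / "covariates.tsv"),
    )
    ppi = read_ppi_edges(directory / "ppi.tsv", threshold=0.9)
    sets = read_gene_sets(directory / "gene_sets.gmt")
    lab_df = pd.read_csv(directory / "labels.tsv", sep="\t", index_col=0)
    labels = LabelSet(
        labels=lab_df["label"].astype(object),
        provenance={
            g: p for g, p in lab_df["provenance"].dropna().items() if p
        },
    )
    return SimulationResult(
        bundle=bundle,
        ppi=ppi,
        labels=labels,
        cprg=sets.get("CPRG", []),
        drivers=sets.get("drivers", []),
    )
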