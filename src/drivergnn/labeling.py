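"""Positive / negative / unlabeled gene labels for semisupervised training.

Positives are the supplied high-confidence driver list. Non-positive genes
are excluded from the negative class (and left unlabeled) if they either
(rule 1) correlate in expression with any positive gene, or (rules 2-5)
appear in any of the supplied exclusion gene sets (cancer pathway members,
OMIM cancer genes, DriverDBV3 drivers, NCG drivers — consumed as lists).
Everything else is negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from drivergnn.io import ExpressionMatrix

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"


@dataclass
class LabelSet:
    """Per-gene label with provenance of the rule that fired."""

    labels: pd.Series
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {POSITIVE, NEGATIVE, UNLABELED}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @property
    def positives(self) -> list[str]:
        return list(self.labels.index[self.labels == POSITIVE])

    @property
    def negatives(self) -> list[str]:
        return list(self.labels.index[self.labels == NEGATIVE])

    @property
    def unlabeled(self) -> list[str]:
        return list(self.labels.index[self.labels == UNLABELED])

    @property
    def labeled(self) -> list[str]:
        return list(self.labels.index[self.labels != UNLABELED])

    def binary(self, genes: list[str]) -> np.ndarray:
        """1 for positive, 0 for negative; genes must be labeled."""
        sub = self.labels.reindex(genes)
        if (sub == UNLABELED).any() or sub.isna().any():
            raise ValueError("binary() called with unlabeled genes")
        return (sub == POSITIVE).to_numpy().astype(int)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "label": self.labels,
                "provenance": [self.provenance.get(g, "") for g in self.labels.index],
            }
        )
        df.to_csv(path, sep="\t", index_label="gene")


def _correlated_with_positives(
    expr: ExpressionMatrix, positives: list[str], threshold: float
) -> set[str]:
    """Genes whose tumor expression has |Spearman rho| >= threshold with any positive."""
    samples = expr.tumor_samples or expr.sample_ids
    sub = expr.values[samples]
    pos_in = [g for g in positives if g in sub.index]
    if not pos_in:
        return set()
    x = sub.to_numpy(dtype=float)
    # rank-transform rows, then Pearson of ranks == Spearman
    ranks = stats.rankdata(x, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    safe = norms.copy()
    safe[safe == 0] = 1.0
    unit = ranks / safe[:, None]
    pos_idx = [sub.index.get_loc(g) for g in pos_in]
    rho = unit @ unit[pos_idx].T  # genes x positives
    rho[norms == 0, :] = 0.0
    hit = (np.abs(rho) >= threshold).any(axis=1)
    correlated = set(np.asarray(sub.index)[hit])
    return correlated - set(pos_in)


def assign_labels(
    universe: list[str],
    positives: list[str],
    exclusion_sets: dict[str, list[str]],
    expr: ExpressionMatrix | None = None,
    corr_threshold: float = 0.8,
) -> LabelSet:
    """Assign {positive, negative, unlabeled} to every gene in the universe."""
    if not positives:
        raise ValueError("positive gene list is empty")
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    pos = [g for g in positives if g in uni_set]
    dropped = [g for g in positives if g not in uni_set]
    if dropped:
        logger.warning("positives absent from universe dropped: %s", dropped[:10])
    pos_set = set(pos)

    provenance: dict[str, str] = {g: "positive_list" for g in pos}
    excluded: set[str] = set()
    if expr is not None and corr_threshold <= 1.0:
        corr = _correlated_with_positives(expr, pos, corr_threshold) & uni_set
        for g in corr - pos_set:
            provenance.setdefault(g, "driver_expression_correlation")
        excluded |= corr
    for name, genes in exclusion_sets.items():
        hits = set(genes) & uni_set
        for g in hits - pos_set:
            provenance.setdefault(g, f"exclusion_set:{name}")
        excluded |= hits

    labels = pd.Series(NEGATIVE, index=uni, dtype=object)
    labels[labels.index.isin(excluded - pos_set)] = UNLABELED
    labels[labels.index.isin(pos_set)] = POSITIVE
    return LabelSet(labels=labels, provenance=provenance)


def pseudolabel(unlabeled: list[str], seed: int) -> dict[str, int]:
    """Independent fair-coin 0/1 labels for unlabeled genes, seeded.

    Only consulted when the optional pseudolabel training mode is enabled.
    """
    rng = np.random.default_rng(seed)
    if not unlabeled:
        return {}
    draws = rng.integers(0, 2, size=len(unlabeled))
    return {g: int(v) for g, v in zip(unlabeled, draws)}
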