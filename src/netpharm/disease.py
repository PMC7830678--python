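"""Disease-target calling from tumor/normal expression cohorts.

Per cohort, each gene is tested tumor vs normal with a Welch two-sample
t-test on log2 expression; p-values are Benjamini–Hochberg adjusted across
all genes of the cohort, and a gene is called differentially expressed
when ``q < alpha`` and ``|log2FC| >= lfc_min``.  The disease-related
target set is the intersection of the per-cohort call sets — the standard
multi-cohort Venn overlap used when several GEO series profile the same
tumor/normal contrast.

Degenerate genes are kept rather than dropped: when both group variances
are zero the test statistic is undefined, so p is set to 1 when the group
means are equal and to 0 when they differ (forced separation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionDataset",
    "differential_targets",
    "intersect_sets",
    "intersect_cohorts",
    "read_expression",
    "write_expression",
]

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class ExpressionDataset:
    """Genes x samples log2-expression matrix with tumor/normal labels."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)
    labels: list[str]  # per-sample, "tumor" or "normal"
    name: str = ""

    def validate(self) -> None:
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.labels) != len(self.samples):
            raise ValueError("one label per sample required")
        bad = set(self.labels) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown sample labels: {sorted(bad)}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        for group in (TUMOR, NORMAL):
            if self.labels.count(group) < 2:
                raise ValueError(f"group {group!r} has fewer than 2 samples")


def differential_targets(
    dataset: ExpressionDataset,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> tuple[set[str], pd.DataFrame]:
    """Welch-test every gene tumor vs normal and call DE genes.

    Returns the set of called genes and the full per-gene table with
    columns ``gene, log2fc, p, q, called`` where ``log2fc`` is
    mean(tumor) − mean(normal) and ``q`` the BH-adjusted p-value.
    """
    dataset.validate()
    lab = np.asarray(dataset.labels)
    tumor = dataset.values[:, lab == TUMOR]
    normal = dataset.values[:, lab == NORMAL]
    log2fc = tumor.mean(axis=1) - normal.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    # zero within-group variance in both groups -> statistic undefined
    degenerate = np.isnan(p)
    if degenerate.any():
        p[degenerate] = np.where(np.isclose(log2fc[degenerate], 0.0), 1.0, 0.0)

    _, q, _, _ = multipletests(p, method="fdr_bh")
    called = (q < alpha) & (np.abs(log2fc) >= lfc_min)
    table = pd.DataFrame(
        {"gene": dataset.genes, "log2fc": log2fc, "p": p, "q": q, "called": called}
    )
    return set(table.loc[table["called"], "gene"]), table


def intersect_sets(sets: Sequence[Iterable[str]]) -> set[str]:
    """Intersection of gene sets across cohorts (order-insensitive)."""
    if len(sets) == 0:
        raise ValueError("need at least one gene set to intersect")
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return out


def intersect_cohorts(
    tables: Sequence[pd.DataFrame], require_concordant_sign: bool = False
) -> set[str]:
    """Intersect per-cohort DE calls, optionally requiring a shared direction.

    By default a gene called in every cohort intersects regardless of the
    sign of its fold-change; with ``require_concordant_sign`` the gene must
    additionally be shifted in the same direction in all cohorts.
    """
    call_sets = [set(t.loc[t["called"], "gene"]) for t in tables]
    common = intersect_sets(call_sets)
    if not require_concordant_sign:
        return common
    out = set()
    for gene in common:
        signs = {np.sign(float(t.loc[t["gene"] == gene, "log2fc"].iloc[0])) for t in tables}
        if len(signs) == 1:
            out.add(gene)
    return out


# ---------------------------------------------------------------------------
# I/O: matrix TSV with sample-ID header + companion sample->label TSV

def write_expression(dataset: ExpressionDataset, matrix_path: str | Path, labels_path: str | Path) -> None:
    df = pd.DataFrame(dataset.values, index=dataset.genes, columns=dataset.samples)
    df.index.name = "gene"
    df.to_csv(matrix_path, sep="\t")
    pd.DataFrame({"sample": dataset.samples, "label": dataset.labels}).to_csv(
        labels_path, sep="\t", index=False
    )


def read_expression(matrix_path: str | Path, labels_path: str | Path, name: str = "") -> ExpressionDataset:
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    lab = pd.read_csv(labels_path, sep="\t")
    labels = dict(zip(lab["sample"].astype(str), lab["label"].astype(str)))
    missing = [s for s in df.columns if s not in labels]
    if missing:
        raise ValueError(f"samples without labels: {missing[:5]}")
    ds = ExpressionDataset(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        labels=[labels[str(s)] for s in df.columns],
        name=name,
    )
    ds.validate()
    return ds
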