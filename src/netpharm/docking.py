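"""Ranking of precomputed molecular-docking binding energies.

Consumes a complete ligand x receptor matrix of AutoDock-style binding
energies (kcal/mol; more negative = stronger binding) and produces the
best pair, a full ascending ranking, and the total energy sum.  Pose
prediction and the docking engine itself are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "DockingEnergyTable",
    "DockingSummary",
    "rank_pairs",
    "read_docking_table",
    "load_dsd_docking",
]

_DATA_DIR = Path(__file__).parent / "data"


@dataclass
class DockingEnergyTable:
    """Complete ligand x receptor binding-energy matrix, kcal/mol."""

    ligands: list[str]
    receptors: list[str]
    energies: list[list[float]]  # row-major, energies[i][j] = (ligands[i], receptors[j])

    def validate(self) -> None:
        if len(self.energies) != len(self.ligands):
            raise ValueError("energy matrix row count does not match ligand count")
        for lig, row in zip(self.ligands, self.energies):
            if len(row) != len(self.receptors):
                raise ValueError(f"ligand {lig!r}: row length does not match receptor count")
            for rec, e in zip(self.receptors, row):
                if e is None or not math.isfinite(e):
                    raise ValueError(f"missing or non-finite energy for cell ({lig!r}, {rec!r})")


@dataclass
class DockingSummary:
    """Best pair, full ascending ranking, and total energy of a docking table."""

    best_pair: tuple[str, str, float]
    ranking: list[tuple[str, str, float]]
    total: float


def rank_pairs(table: DockingEnergyTable) -> DockingSummary:
    """Rank all ligand-receptor pairs by binding energy.

    Pairs are sorted ascending by energy (most negative, i.e. strongest
    binder, first); ties are broken by (ligand, receptor) lexicographic
    order.  ``total`` is the plain sum over all cells.
    """
    table.validate()
    pairs = [
        (lig, rec, float(table.energies[i][j]))
        for i, lig in enumerate(table.ligands)
        for j, rec in enumerate(table.receptors)
    ]
    ranking = sorted(pairs, key=lambda t: (t[2], t[0], t[1]))
    if not ranking:
        raise ValueError("empty docking table")
    total = float(sum(p[2] for p in pairs))
    return DockingSummary(best_pair=ranking[0], ranking=ranking, total=total)


def read_docking_table(path: str | Path) -> DockingEnergyTable:
    """Read a TSV matrix: ligand rows, receptor columns, first column names the ligand."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DockingEnergyTable(
        ligands=[str(x) for x in df.index],
        receptors=[str(x) for x in df.columns],
        energies=df.to_numpy(dtype=float).tolist(),
    )


def load_dsd_docking() -> DockingEnergyTable:
    """Bundled 7x6 docking-energy matrix (kcal/mol).

    Seven key ingredients of the formula's two monarch herbs docked against
    the six hub targets EGFR, CUL3, APP, MCM2, CDK2, FN1.  The matrix
    follows the published table; note the published narrative swaps the
    two strongest MCM2 binders relative to the table, and the table is
    taken as authoritative here.
    """
    return read_docking_table(_DATA_DIR / "dsd_docking.tsv")
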