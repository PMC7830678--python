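"""ADME-based screening of herbal formula ingredients.

Candidate active ingredients of a multi-herb formula are selected by two
pharmacokinetic thresholds — oral bioavailability (OB, percent) and
drug-likeness (DL, dimensionless) — plus a literature-mined whitelist of
compounds that fail the thresholds but are retained on pharmacological
evidence.  The default cut-offs (OB >= 30 %, DL >= 0.18) are the standard
TCMSP screening convention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CompoundRecord",
    "CandidateSet",
    "screen_ingredients",
    "count_by_herb",
    "read_compound_table",
    "write_compound_table",
    "load_dsd_candidates",
]

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class CompoundRecord:
    """One herb ingredient with its ADME scores.

    Parameters
    ----------
    herb : str
        Herb identifier (e.g. the pinyin abbreviation used in the formula).
    compound : str
        Compound name, unique within a herb.  The same compound may occur
        in several herbs.
    ob : float
        Oral bioavailability in percent (>= 0).
    dl : float
        Drug-likeness in [0, 1].
    whitelisted : bool
        Literature-mined keep flag: retain regardless of thresholds.
    """

    herb: str
    compound: str
    ob: float
    dl: float
    whitelisted: bool = False

    def __post_init__(self) -> None:
        if self.ob < 0:
            raise ValueError(
                f"compound {self.herb}/{self.compound}: ob must be >= 0, got {self.ob}"
            )
        if not 0.0 <= self.dl <= 1.0:
            raise ValueError(
                f"compound {self.herb}/{self.compound}: dl must be in [0, 1], got {self.dl}"
            )


@dataclass
class CandidateSet:
    """Retained ingredients with per-record provenance.

    ``provenance[i]`` is ``"threshold"`` when ``records[i]`` passes both
    ADME cut-offs, otherwise ``"whitelist"``.
    """

    records: list[CompoundRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def compounds(self) -> list[str]:
        return [r.compound for r in self.records]


def _check_unique(table: Iterable[CompoundRecord]) -> None:
    seen: set[tuple[str, str]] = set()
    for rec in table:
        key = (rec.herb, rec.compound)
        if key in seen:
            raise ValueError(f"duplicate (herb, compound) pair: {key}")
        seen.add(key)


def screen_ingredients(
    table: Iterable[CompoundRecord],
    ob_min: float = 30.0,
    dl_min: float = 0.18,
) -> CandidateSet:
    """Select candidate ingredients by inclusive ADME thresholds plus whitelist.

    A record is retained iff ``(ob >= ob_min and dl >= dl_min)`` or it is
    whitelisted.  Input order is preserved.  A whitelisted record that also
    passes both thresholds is tagged ``"threshold"``.

    Returns
    -------
    CandidateSet
    """
    table = list(table)
    _check_unique(table)
    out = CandidateSet()
    for rec in table:
        passes = rec.ob >= ob_min and rec.dl >= dl_min
        if passes:
            out.records.append(rec)
            out.provenance.append("threshold")
        elif rec.whitelisted:
            out.records.append(rec)
            out.provenance.append("whitelist")
    return out


def count_by_herb(candidates: CandidateSet) -> tuple[dict[str, int], int]:
    """Per-herb candidate counts and the total.

    The counts partition the candidate set: the total always equals the sum
    of the per-herb counts.
    """
    counts = Counter(rec.herb for rec in candidates.records)
    return dict(counts), sum(counts.values())


# ---------------------------------------------------------------------------
# I/O

_COLUMNS = ["herb", "compound", "ob", "dl", "whitelisted"]


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound table from TSV (columns herb, compound, ob, dl, whitelisted)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"compound table {path} missing columns: {missing}")
    return [
        CompoundRecord(
            herb=str(r.herb),
            compound=str(r.compound),
            ob=float(r.ob),
            dl=float(r.dl),
            whitelisted=bool(r.whitelisted),
        )
        for r in df.itertuples(index=False)
    ]


def write_compound_table(table: Iterable[CompoundRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.herb, r.compound, r.ob, r.dl, r.whitelisted) for r in table],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def load_dsd_candidates() -> CandidateSet:
    """Bundled transcription of the Danggui Sini Decoction candidate table.

    The 66 candidate ingredients of the seven-herb formula (herbs DG, GZ,
    SY, XX, GC, TC, DZ).  The published table lists names only, without
    per-compound OB/DL values, so the set is loaded as already screened:
    every record is marked whitelisted and provenance is not meaningful.
    """
    df = pd.read_csv(_DATA_DIR / "dsd_ingredients.tsv", sep="\t")
    out = CandidateSet()
    for r in df.itertuples(index=False):
        out.records.append(
            CompoundRecord(herb=str(r.herb), compound=str(r.compound), ob=0.0, dl=0.0, whitelisted=True)
        )
        out.provenance.append("whitelist")
    return out
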