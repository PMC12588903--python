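"""Batch × compound concentration tables: I/O, class summaries and the
pharmacopoeial THSG qualification filter.

Concentrations are in mg per g dry weight.  Each compound carries exactly one
class label (anthraquinone, stilbene_glycoside, flavonoid or phenol).  The
qualification rule mirrors the pharmacopoeial limit for the dominant stilbene
glycoside THSG: at least 1.0% w/w, i.e. 10 mg/g.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPOUND_CLASSES",
    "THSG",
    "CompoundTable",
    "QualificationResult",
    "read_compound_table",
    "class_totals",
    "qualify_batches",
    "write_qualification_report",
]

COMPOUND_CLASSES = ("anthraquinone", "stilbene_glycoside", "flavonoid", "phenol")

#: column name of the pharmacopoeial marker compound
THSG = "THSG"


class CompoundTableError(ValueError):
    """Malformed concentration table or metadata."""


@dataclass
class CompoundTable:
    batch_ids: list[str]
    compound_ids: list[str]
    concentrations: np.ndarray  # batches x compounds, mg/g
    compound_class: dict[str, str]
    origin: dict[str, str] | None = None
    group: dict[str, str] | None = None  # optional known/assigned group labels

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.shape != (len(self.batch_ids), len(self.compound_ids)):
            raise CompoundTableError("concentration matrix shape does not match ids")
        if len(set(self.batch_ids)) != len(self.batch_ids):
            dupes = sorted({b for b in self.batch_ids if self.batch_ids.count(b) > 1})
            raise CompoundTableError(f"duplicated batch ids: {dupes}")
        missing = [c for c in self.compound_ids if c not in self.compound_class]
        if missing:
            raise CompoundTableError(f"compounds missing a class label: {missing}")
        bad = {c: k for c, k in self.compound_class.items() if k not in COMPOUND_CLASSES}
        if bad:
            raise CompoundTableError(f"unknown class labels: {bad}")
        if np.any(~np.isfinite(self.concentrations)):
            rows, cols = np.where(~np.isfinite(self.concentrations))
            cells = [(self.batch_ids[r], self.compound_ids[c]) for r, c in zip(rows, cols)]
            raise CompoundTableError(f"missing/non-finite concentrations at {cells[:5]}")
        if np.any(self.concentrations < 0):
            r, c = np.argwhere(self.concentrations < 0)[0]
            raise CompoundTableError(
                f"negative concentration for batch {self.batch_ids[r]!r}, "
                f"compound {self.compound_ids[c]!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.concentrations, index=self.batch_ids, columns=self.compound_ids)

    def column(self, compound_id: str) -> np.ndarray:
        if compound_id not in self.compound_ids:
            raise CompoundTableError(f"compound {compound_id!r} not in table")
        return self.concentrations[:, self.compound_ids.index(compound_id)]

    def subset(self, batch_ids: Sequence[str]) -> "CompoundTable":
        idx = [self.batch_ids.index(b) for b in batch_ids]
        return CompoundTable(
            batch_ids=list(batch_ids),
            compound_ids=list(self.compound_ids),
            concentrations=self.concentrations[idx],
            compound_class=dict(self.compound_class),
            origin={b: self.origin[b] for b in batch_ids} if self.origin else None,
            group={b: self.group[b] for b in batch_ids} if self.group else None,
        )

    def write_csv(self, path, metadata_path=None) -> None:
        self.to_frame().rename_axis("batch").to_csv(path)
        if metadata_path is not None:
            pd.DataFrame(
                {"compound": self.compound_ids,
                 "class": [self.compound_class[c] for c in self.compound_ids]}
            ).to_csv(metadata_path, index=False)


@dataclass(frozen=True)
class QualificationResult:
    batch_id: str
    thsg_mg_per_g: float
    qualified: bool
    threshold_mg_per_g: float = 10.0


def read_compound_table(path, metadata_path) -> CompoundTable:
    """Read a concentration CSV (rows=batches) plus a compound/class metadata CSV."""
    df = pd.read_csv(path, index_col=0)
    meta = pd.read_csv(metadata_path)
    if not {"compound", "class"} <= set(meta.columns):
        raise CompoundTableError("metadata CSV needs 'compound' and 'class' columns")
    class_map = dict(zip(meta["compound"].astype(str), meta["class"].astype(str)))
    missing = [c for c in df.columns if c not in class_map]
    if missing:
        raise CompoundTableError(f"metadata missing compounds: {missing}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        rows, cols = np.where(np.isnan(values))
        cells = [(str(df.index[r]), str(df.columns[c])) for r, c in zip(rows, cols)]
        raise CompoundTableError(f"rows with missing values rejected: {cells}")
    return CompoundTable(
        batch_ids=[str(b) for b in df.index],
        compound_ids=[str(c) for c in df.columns],
        concentrations=values,
        compound_class={c: class_map[str(c)] for c in df.columns},
    )


def class_totals(table: CompoundTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-batch class totals plus within-class compositional shares.

    Returns ``(totals, shares)``: totals is batches × classes (mg/g); shares
    gives each compound's average share of its class total across batches
    (share of a batch with zero class total is excluded from the average).
    """
    frame = table.to_frame()
    by_class = {k: [c for c in table.compound_ids if table.compound_class[c] == k]
                for k in COMPOUND_CLASSES}
    totals = pd.DataFrame(
        {k: frame[cols].sum(axis=1) if cols else 0.0 for k, cols in by_class.items()}
    )
    share_rows = []
    for k, cols in by_class.items():
        if not cols:
            continue
        tot = totals[k]
        nonzero = tot > 0
        for c in cols:
            share = (frame.loc[nonzero, c] / tot[nonzero]).mean() if nonzero.any() else np.nan
            share_rows.append({"compound": c, "class": k, "mean_share": float(share)})
    return totals, pd.DataFrame(share_rows)


def qualify_batches(table: CompoundTable, threshold_mg_per_g: float = 10.0,
                    thsg_column: str = THSG) -> list[QualificationResult]:
    """Pharmacopoeial qualification: THSG ≥ 1.0% w/w (10 mg/g), boundary inclusive."""
    thsg = table.column(thsg_column)
    return [
        QualificationResult(
            batch_id=b,
            thsg_mg_per_g=float(v),
            qualified=bool(v >= threshold_mg_per_g),
            threshold_mg_per_g=threshold_mg_per_g,
        )
        for b, v in zip(table.batch_ids, thsg)
    ]


def write_qualification_report(results: Sequence[QualificationResult], path) -> None:
    payload = [
        {"batch": r.batch_id, "thsg_mg_per_g": r.thsg_mg_per_g,
         "qualified": r.qualified, "threshold_mg_per_g": r.threshold_mg_per_g}
        for r in results
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
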