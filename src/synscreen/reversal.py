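"""Disease-signature reversal scoring of differential-expression tables.

A directional signature lists genes that are up (+1) or down (-1) in the
disease state.  Given a treatment-vs-control differential-expression table
(log2 fold-change + adjusted p-value per gene), a signature gene is

  detected  — present in the table with padj below the significance cut;
  reversed  — detected and significantly changed in the direction
              *opposite* its disease direction (sign(log2fc) == -direction
              with |log2fc| at or above the fold-change gate).

The headline statistic is the fraction of detected signature genes the
treatment reverses; "reversed up" counts disease-down genes now induced,
"reversed down" counts disease-up genes now suppressed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignatureGene",
    "DifferentialExpressionRecord",
    "ReversalSummary",
    "score_reversal",
    "compare_treatments",
    "read_de_table",
    "read_signature",
]

DEFAULT_PADJ_MAX = 0.05
DEFAULT_LFC_MIN = 2.0


@dataclasses.dataclass(frozen=True)
class SignatureGene:
    gene_id: str
    direction: int  # +1 up in disease, -1 down in disease

    def __post_init__(self):
        if self.direction not in (+1, -1):
            raise ValueError(
                f"{self.gene_id}: direction must be +1 or -1, got {self.direction}"
            )


@dataclasses.dataclass(frozen=True)
class DifferentialExpressionRecord:
    gene_id: str
    log2fc: float  # case (treated) over control; NaN if missing
    padj: float  # adjusted p in [0,1]; NaN if missing


@dataclasses.dataclass(frozen=True)
class ReversalSummary:
    name: str
    n_signature: int
    n_detected: int
    n_reversed: int
    n_reversed_up: int
    n_reversed_down: int

    @property
    def fraction_reversed(self) -> float:
        """Fraction of detected signature genes reversed; NaN when no
        signature gene is detected."""
        if self.n_detected == 0:
            return float("nan")
        return self.n_reversed / self.n_detected


def score_reversal(
    de: Sequence[DifferentialExpressionRecord] | pd.DataFrame,
    sig: Sequence[SignatureGene],
    padj_max: float = DEFAULT_PADJ_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
    name: str = "",
    flip_contrast: bool = False,
) -> ReversalSummary:
    """Count detected and direction-reversed signature genes in a DE table.

    Parameters
    ----------
    de : records or DataFrame with columns gene_id, log2fc (or
        log2FoldChange), padj
    sig : the directional signature
    padj_max : significance cut for "detected" (no fold-change gate)
    lfc_min : |log2fc| gate applied to "reversed" only
    flip_contrast : set True when the table's fold-changes are
        control-over-case; flips the sign convention
    """
    if not 0 < padj_max < 1:
        raise ValueError(f"padj_max must be in (0, 1), got {padj_max}")
    if lfc_min < 0:
        raise ValueError(f"lfc_min must be >= 0, got {lfc_min}")
    if len(sig) == 0:
        raise ValueError("empty signature")
    directions = {}
    for g in sig:
        key = g.gene_id.upper()
        if key in directions:
            raise ValueError(f"duplicate gene {g.gene_id} in signature")
        directions[key] = g.direction

    if isinstance(de, pd.DataFrame):
        df = de.rename(columns={"log2FoldChange": "log2fc"})
    else:
        df = pd.DataFrame(
            {"gene_id": [r.gene_id for r in de],
             "log2fc": [r.log2fc for r in de],
             "padj": [r.padj for r in de]}
        )
    genes = df["gene_id"].astype(str).str.upper()
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValueError(f"duplicate gene_id in DE table: {dup}")

    lfc = pd.to_numeric(df["log2fc"], errors="coerce").to_numpy(float)
    padj = pd.to_numeric(df["padj"], errors="coerce").to_numpy(float)
    if flip_contrast:
        lfc = -lfc

    in_sig = genes.map(directions).to_numpy()
    mask_sig = ~pd.isna(in_sig)
    # missing padj (independent-filtering artifacts) counts as not detected
    detected = mask_sig & np.isfinite(padj) & (padj < padj_max)
    dirs = np.where(mask_sig, in_sig, 0).astype(float)
    reversed_ = (
        detected
        & np.isfinite(lfc)
        & (np.sign(lfc) == -dirs)
        & (np.abs(lfc) >= lfc_min)
    )
    rev_up = reversed_ & (dirs == -1)  # disease-down genes now up
    rev_down = reversed_ & (dirs == +1)

    return ReversalSummary(
        name=name,
        n_signature=len(sig),
        n_detected=int(detected.sum()),
        n_reversed=int(reversed_.sum()),
        n_reversed_up=int(rev_up.sum()),
        n_reversed_down=int(rev_down.sum()),
    )


def compare_treatments(summaries: Sequence[ReversalSummary]) -> pd.DataFrame:
    """Side-by-side reversal table, best-reversing treatment first
    (stable for ties)."""
    if len(summaries) == 0:
        raise ValueError("no summaries to compare")
    rows = [
        {
            "name": s.name,
            "n_signature": s.n_signature,
            "n_detected": s.n_detected,
            "n_reversed": s.n_reversed,
            "n_reversed_up": s.n_reversed_up,
            "n_reversed_down": s.n_reversed_down,
            "fraction_reversed": s.fraction_reversed,
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows)
    order = df["fraction_reversed"].fillna(-1.0)
    df = df.iloc[np.argsort(-order.to_numpy(), kind="stable")]
    return df.reset_index(drop=True)


def read_de_table(path) -> pd.DataFrame:
    """Read a TSV differential-expression table with header gene_id,
    log2FoldChange, padj (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for want in ("gene_id", "padj"):
        if want not in cols:
            raise ValueError(f"DE table {path} missing column {want}")
    lfc_col = cols.get("log2foldchange", cols.get("log2fc"))
    if lfc_col is None:
        raise ValueError(f"DE table {path} missing column log2FoldChange")
    out = df[[cols["gene_id"], lfc_col, cols["padj"]]].copy()
    out.columns = ["gene_id", "log2fc", "padj"]
    return out


def read_signature(path) -> list[SignatureGene]:
    """Read a TSV signature with header gene_id, direction (up/down or
    +1/-1)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "gene_id" not in cols or "direction" not in cols:
        raise ValueError(f"signature {path} needs columns gene_id, direction")
    mapping = {"up": 1, "down": -1, "+1": 1, "-1": -1, "1": 1}
    out = []
    for _, row in df.iterrows():
        raw = str(row[cols["direction"]]).strip().lower()
        if raw not in mapping:
            raise ValueError(f"unrecognized direction {raw!r} for {row[cols['gene_id']]}")
        out.append(SignatureGene(str(row[cols["gene_id"]]), mapping[raw]))
    return out
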