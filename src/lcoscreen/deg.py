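"""Differential-expression table filtering and qPCR fold-changes.

This stage consumes per-gene statistics (signed fold-change + adjusted
p-value) produced upstream by a DE estimator; it does not refit models.
The filter keeps genes with |signed fold-change| >= 2.5 (inclusive) and
FDR-adjusted p <= 0.05, classifies them by replicon, and provides the
2^-ddCt fold-change used for qPCR validation.

Fold-change convention: a ratio r >= 1 is reported as r, a ratio r < 1 as
-1/r, so down-regulation is negative and |FC| >= 1 always.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEGRecord",
    "RepliconMap",
    "CIAT899_REPLICONS",
    "bh_adjust",
    "signed_fold_change",
    "filter_deg",
    "replicon_summary",
    "ddct_fold_change",
    "read_deg_table",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression statistics."""

    gene_id: str
    replicon: str
    fold_change: float        # signed convention, |FC| >= 1
    padj: Optional[float]     # None when the estimator reported NA

    def __post_init__(self) -> None:
        if self.padj is not None and not 0.0 <= self.padj <= 1.0:
            raise ValueError(f"adjusted p-value out of [0,1]: {self.padj}")
        if abs(self.fold_change) < 1.0 and self.fold_change != 0.0:
            raise ValueError(
                f"fold-change {self.fold_change} violates the signed convention "
                "(|FC| >= 1); convert ratios with signed_fold_change first"
            )

    @property
    def up(self) -> bool:
        return self.fold_change > 0


@dataclass(frozen=True)
class RepliconMap:
    """Accession -> replicon name lookup."""

    accessions: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.accessions)) != len(list(self.accessions)):
            raise ValueError("replicon accessions must be unique")

    def name(self, accession: str) -> str:
        return self.accessions.get(accession, "unknown")


# Replicon layout of Rhizobium tropici CIAT 899: one chromosome and three
# plasmids (pB is the symbiotic plasmid).
CIAT899_REPLICONS = RepliconMap({
    "CP004015.1": "chromosome",
    "CP004016.1": "pRtrCIAT899a",
    "CP004017.1": "pRtrCIAT899b",
    "CP004018.1": "pRtrCIAT899c",
})


def bh_adjust(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adj]


def signed_fold_change(ratio: float) -> float:
    """Expression ratio -> signed fold-change (r if r >= 1 else -1/r)."""
    if not ratio > 0:
        raise ValueError(f"expression ratio must be positive, got {ratio}")
    return ratio if ratio >= 1.0 else -1.0 / ratio


def log2_to_signed(log2fc: float) -> float:
    """log2 fold-change -> signed fold-change."""
    return signed_fold_change(2.0 ** log2fc)


def filter_deg(records: Sequence[DEGRecord], fc_threshold: float = 2.5,
               alpha: float = 0.05) -> List[DEGRecord]:
    """Keep records with |FC| >= threshold (inclusive) and padj <= alpha.

    Records with a missing adjusted p-value are excluded (conservative,
    matching DE-estimator output conventions); the count is logged.
    """
    na = sum(1 for r in records if r.padj is None)
    if na:
        log.info("filter_deg: excluding %d records with missing adjusted p", na)
    return [
        r for r in records
        if r.padj is not None and abs(r.fold_change) >= fc_threshold and r.padj <= alpha
    ]


def replicon_summary(records: Sequence[DEGRecord],
                     replicons: RepliconMap = CIAT899_REPLICONS) -> pd.DataFrame:
    """Cross-tab of replicon x regulation direction.

    ``records`` may carry either raw accessions or already-resolved replicon
    names; unresolvable entries are counted under "unknown" with a warning.
    """
    known_names = set(replicons.accessions.values())
    rows = []
    for r in records:
        name = r.replicon if r.replicon in known_names else replicons.name(r.replicon)
        if name == "unknown":
            log.warning("replicon_summary: unmapped replicon %r for gene %s",
                        r.replicon, r.gene_id)
        rows.append((name, "up" if r.up else "down"))
    df = pd.DataFrame(rows, columns=["replicon", "direction"])
    out = df.groupby(["replicon", "direction"]).size().unstack(fill_value=0)
    for col in ("up", "down"):
        if col not in out.columns:
            out[col] = 0
    out = out[["up", "down"]]
    out["total"] = out["up"] + out["down"]
    return out


def ddct_fold_change(ct_target_cond: float, ct_ref_cond: float,
                     ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """qPCR relative quantification: 2^-ddCt against a reference gene.

    ddCt = (Ct_target - Ct_reference) under the condition minus the same
    difference under control.
    """
    for ct in (ct_target_cond, ct_ref_cond, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_cond - ct_ref_cond) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


_FC_CANDIDATES = ("fold_change", "foldchange", "fc", "log2foldchange", "log2fc")
_P_CANDIDATES = ("padj", "adjusted_p", "p_adj", "fdr", "qvalue")
_ID_CANDIDATES = ("gene_id", "gene", "id", "accession", "protein_id")
_REP_CANDIDATES = ("replicon", "chromosome", "molecule")


def _pick(columns: Sequence[str], candidates: Sequence[str], what: str) -> str:
    lower = {c.lower().strip(): c for c in columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    raise ValueError(f"could not locate a {what} column among {list(columns)}")


def read_deg_table(path: str | Path, replicons: RepliconMap = CIAT899_REPLICONS,
                   fc_scale: str = "auto") -> List[DEGRecord]:
    """Read a DE table (TSV/CSV or spreadsheet) into DEGRecords.

    Fold-change dialect detection (``fc_scale="auto"``): published tables
    ship either log2 fold-changes or signed ratios.  Values strictly inside
    (-1, 1) and nonzero are impossible under the signed convention, so their
    presence flags a log2 table; the choice is logged.  Pass "log2" or
    "signed" to override.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep)
    fc_col = _pick(df.columns, _FC_CANDIDATES, "fold-change")
    p_col = _pick(df.columns, _P_CANDIDATES, "adjusted p-value")
    id_col = _pick(df.columns, _ID_CANDIDATES, "gene id")
    rep_col = _pick(df.columns, _REP_CANDIDATES, "replicon")

    fc = pd.to_numeric(df[fc_col], errors="coerce")
    if fc_scale == "auto":
        is_log2 = bool(((fc.abs() < 1) & (fc != 0)).any()) or "log2" in fc_col.lower()
        fc_scale = "log2" if is_log2 else "signed"
        log.info("read_deg_table: detected %s fold-change dialect in %s", fc_scale, path.name)
    records: List[DEGRecord] = []
    for gene, rep, f, p in zip(df[id_col], df[rep_col], fc,
                               pd.to_numeric(df[p_col], errors="coerce")):
        if pd.isna(f):
            continue
        value = log2_to_signed(float(f)) if fc_scale == "log2" else float(f)
        records.append(DEGRecord(
            gene_id=str(gene),
            replicon=str(rep),
            fold_change=value,
            padj=None if pd.isna(p) else float(p),
        ))
    return records
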