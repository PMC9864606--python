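"""Pathway gene sets, case-to-normal ratios and pathway activation levels.

The pathway activation level (PAL) of a pathway is the activator/repressor
weighted mean of per-gene log2 case-to-normal ratios (CNR), scaled by 100:

    PAL = 100 * sum_g ARR[g] * log2(CNR[g]) / sum_g |ARR[g]|

where the sums run over pathway genes present in the CNR vector, CNR[g] is
the ratio of the geometric-mean pseudobulk profiles (case / control) and
ARR[g] in {-1, 0, +1} marks a gene as repressor / neutral / activator.
A positive PAL means the pathway is activated in cases.  With all weights
+1 this reduces to 100 x the mean log2 CNR over the pathway's genes.

GMT files are read in the standard dialect plus an extension where a gene
token ``SYM^+1`` / ``SYM^-1`` carries its ARR weight (plain tokens default
to +1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AxisMismatchError, GmtParseError
from .qc import ExpressionProfile


@dataclass(frozen=True)
class Pathway:
    genes: tuple[str, ...]
    arr: dict[str, int] = field(hash=False)  # gene -> weight in {-1, 0, +1}
    category: str = ""


class PathwayDB(dict):
    """Mapping pathway ID -> :class:`Pathway` (insertion-ordered)."""

    def gene_universe(self) -> set[str]:
        return {g for p in self.values() for g in p.genes}


def _parse_gene_token(token: str) -> tuple[str, int]:
    if "^" in token:
        sym, w = token.rsplit("^", 1)
        try:
            weight = int(w)
        except ValueError as e:
            raise GmtParseError(f"bad weight token {token!r}") from e
        if weight not in (-1, 0, 1):
            raise GmtParseError(f"weight must be -1, 0 or +1, got {token!r}")
        return sym.upper(), weight
    return token.upper(), 1


def read_gmt(path: str) -> PathwayDB:
    """Parse a GMT file (standard or ``gene^weight`` extended dialect).

    Duplicate genes within a line are deduplicated keeping the first
    weight; a duplicate pathway ID or a line with fewer than three fields
    is an error.
    """
    db = PathwayDB()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            pid, category = fields[0], fields[1]
            if pid in db:
                raise GmtParseError(f"{path}:{lineno}: duplicate pathway ID {pid!r}")
            genes: list[str] = []
            arr: dict[str, int] = {}
            for token in fields[2:]:
                if not token:
                    continue
                sym, weight = _parse_gene_token(token)
                if sym not in arr:
                    genes.append(sym)
                    arr[sym] = weight
            db[pid] = Pathway(tuple(genes), arr, category)
    return db


def write_gmt(db: PathwayDB, path: str) -> None:
    """Serialize a PathwayDB; weights are written only when not all +1."""
    with open(path, "w") as fh:
        for pid, p in db.items():
            plain = all(p.arr[g] == 1 for g in p.genes)
            if plain:
                tokens = list(p.genes)
            else:
                tokens = [f"{g}^{p.arr[g]:+d}" for g in p.genes]
            fh.write("\t".join([pid, p.category, *tokens]) + "\n")


def compute_cnr(case: ExpressionProfile, control: ExpressionProfile) -> pd.Series:
    """Per-gene case-to-normal ratio of geometric-mean profiles.

    Both profiles have gm >= 1, so the ratio is finite and positive; genes
    silent in both conditions give CNR = 1.
    """
    if not case.gm.index.equals(control.gm.index):
        raise AxisMismatchError(
            f"profiles for {case.cell_type!r} do not share a gene axis"
        )
    cnr = case.gm / control.gm
    cnr.name = "cnr"
    return cnr


def compute_pal(cnr: pd.Series, pathway: Pathway) -> tuple[float | None, int]:
    """ARR-weighted mean log2 CNR over the pathway, scaled by 100.

    Returns ``(PAL, n_genes_used)``; PAL is None when no pathway gene with
    nonzero weight is present in the CNR vector (the pathway is then not
    evaluable and excluded from ranking, not an error).
    """
    idx = cnr.index
    genes = [g for g in pathway.genes if g in idx and pathway.arr[g] != 0]
    if not genes:
        return None, 0
    weights = np.array([pathway.arr[g] for g in genes], dtype=float)
    logs = np.log2(cnr.loc[genes].to_numpy(dtype=float))
    pal = 100.0 * float(weights @ logs) / float(np.abs(weights).sum())
    return pal, len(genes)


def pal_table(
    profiles: dict[tuple[str, str], ExpressionProfile], db: PathwayDB
) -> pd.DataFrame:
    """PAL of every evaluable pathway for every cell type with both
    conditions present.  Columns: cell_type, pathway, pal, n_genes_used.
    """
    rows = []
    cell_types = sorted({ct for ct, _ in profiles})
    for ct in cell_types:
        case = profiles.get((ct, "case"))
        control = profiles.get((ct, "control"))
        if case is None or control is None:
            continue
        cnr = compute_cnr(case, control)
        for pid in db:
            pal, n_used = compute_pal(cnr, db[pid])
            if pal is not None:
                rows.append((ct, pid, pal, n_used))
    return pd.DataFrame(rows, columns=["cell_type", "pathway", "pal", "n_genes_used"])


def top_pathways(
    pal: pd.DataFrame, cell_type: str, k: int = 10
) -> tuple[list[str], list[str]]:
    """Top-k activated (PAL > 0, descending) and inhibited (PAL < 0,
    ascending) pathway IDs for a cell type; ties break by pathway ID."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = pal[pal["cell_type"] == cell_type]
    pos = sub[sub["pal"] > 0].sort_values(
        ["pal", "pathway"], ascending=[False, True]
    )
    neg = sub[sub["pal"] < 0].sort_values(
        ["pal", "pathway"], ascending=[True, True]
    )
    return pos["pathway"].head(k).tolist(), neg["pathway"].head(k).tolist()
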