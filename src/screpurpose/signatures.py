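"""Query signatures: the up/down gene lists submitted to the drug bank.

The up side is the union of the genes of the top activated pathways, the
down side the union of the top inhibited pathways.  A gene landing in both
unions is assigned to the side matching the sign of its own log2 CNR and
dropped when that ratio is exactly 1 (no measured direction).  Each side
is ordered by descending |log2 CNR| (gene ID breaks ties) and truncated
to ``max_per_side``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptySignatureError
from .pathways import PathwayDB


@dataclass(frozen=True)
class QuerySignature:
    cell_type: str
    up: tuple[str, ...]
    down: tuple[str, ...]
    provenance: dict[str, tuple[str, ...]]  # gene -> contributing pathway IDs

    def __post_init__(self):
        if set(self.up) & set(self.down):
            raise ValueError("query up and down sides overlap")


def build_query(
    cell_type: str,
    activated: list[str],
    inhibited: list[str],
    db: PathwayDB,
    cnr: pd.Series,
    max_per_side: int = 2000,
) -> QuerySignature:
    """Build the up/down query from top activated/inhibited pathways.

    Pathway genes absent from the CNR vector (filtered out of the matrix)
    are dropped: they carry no measured direction and no ordering key.
    """
    if not activated and not inhibited:
        raise EmptySignatureError(
            f"cell type {cell_type!r}: no activated or inhibited pathways"
        )
    provenance: dict[str, list[str]] = {}
    up_union: set[str] = set()
    dn_union: set[str] = set()
    for pid in activated:
        for g in db[pid].genes:
            up_union.add(g)
            provenance.setdefault(g, []).append(pid)
    for pid in inhibited:
        for g in db[pid].genes:
            dn_union.add(g)
            provenance.setdefault(g, []).append(pid)

    idx = cnr.index
    up_union = {g for g in up_union if g in idx}
    dn_union = {g for g in dn_union if g in idx}

    both = up_union & dn_union
    for g in both:
        ratio = cnr[g]
        up_union.discard(g)
        dn_union.discard(g)
        if ratio > 1:
            up_union.add(g)
        elif ratio < 1:
            dn_union.add(g)
        # ratio == 1: no direction, dropped entirely

    def _order(genes: set[str]) -> tuple[str, ...]:
        mag = {g: abs(float(np.log2(cnr[g]))) for g in genes}
        ordered = sorted(genes, key=lambda g: (-mag[g], g))
        return tuple(ordered[:max_per_side])

    up = _order(up_union)
    down = _order(dn_union)
    kept = set(up) | set(down)
    return QuerySignature(
        cell_type,
        up,
        down,
        {g: tuple(provenance[g]) for g in sorted(kept)},
    )


def write_query_gmt(q: QuerySignature, path: str) -> None:
    """Two-line GMT: ``<celltype>-UP`` and ``<celltype>-DN``."""
    with open(path, "w") as fh:
        fh.write("\t".join([f"{q.cell_type}-UP", "query up", *q.up]) + "\n")
        fh.write("\t".join([f"{q.cell_type}-DN", "query down", *q.down]) + "\n")


def write_query_json(q: QuerySignature, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "cell_type": q.cell_type,
                "up": list(q.up),
                "down": list(q.down),
                "provenance": {g: list(p) for g, p in q.provenance.items()},
            },
            fh,
            indent=1,
            sort_keys=True,
        )


def read_query_json(path: str) -> QuerySignature:
    with open(path) as fh:
        d = json.load(fh)
    return QuerySignature(
        d["cell_type"],
        tuple(d["up"]),
        tuple(d["down"]),
        {g: tuple(p) for g, p in d["provenance"].items()},
    )
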