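"""Connectivity mapping: scoring drug signatures against a query.

Two engines are provided:

* **overlap** — the interception score: in reverse mode the fraction of
  query genes matched by the *opposing* drug sides,
  ``(|q.up ∩ d.down| + |q.down ∩ d.up|) / (|q.up| + |q.down|)``; mimic
  mode matches same-direction sides.  This is the ranking statistic of
  L1000CDS2-style reverse searches ("aggravate" = False).
* **ks** — the classic weighted Kolmogorov–Smirnov connectivity score of
  the original Connectivity Map: enrichment score of each query side in a
  drug-induced ranked gene list, combined as
  ``(ES(up) − ES(down)) / 2``; strong reversers are the most negative.

Drug banks hold per-experiment UP/DN gene sets with molecule name and
experiment metadata (cell-line and dose tags), so one molecule may own
several experiments.  Serialization is paired-GMT (lines suffixed
``-UP`` / ``-DN``, description field ``molecule|cell_line|dose``) or JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import GmtParseError
from .signatures import QuerySignature

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Experiment:
    exp_id: str
    molecule: str
    up: frozenset[str]
    down: frozenset[str]
    cell_line: str = ""
    dose: str = ""

    def __post_init__(self):
        if self.up & self.down:
            raise ValueError(f"experiment {self.exp_id}: up/down sets overlap")
        if not self.molecule:
            raise ValueError(f"experiment {self.exp_id}: empty molecule name")


@dataclass
class DrugBank:
    experiments: list[Experiment]
    universe: frozenset[str] = frozenset()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [e.exp_id for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise ValueError("experiment IDs are not unique")
        if not self.universe:
            self.universe = frozenset(
                g for e in self.experiments for g in e.up | e.down
            )

    def molecules(self) -> set[str]:
        return {e.molecule for e in self.experiments}


@dataclass(frozen=True)
class RankedHits:
    """Top-scoring experiments for one cell type, ties broken by ID."""

    cell_type: str
    table: pd.DataFrame  # rank, experiment, molecule, score, 4 overlap counts


def overlap_score(q: QuerySignature, d: Experiment, mode: str = "reverse") -> float:
    """Interception score in [0, 1]; see module docstring."""
    n = len(q.up) + len(q.down)
    if n == 0:
        raise ValueError("empty query signature")
    qup, qdn = set(q.up), set(q.down)
    if mode == "reverse":
        matched = len(qup & d.down) + len(qdn & d.up)
    elif mode == "mimic":
        matched = len(qup & d.up) + len(qdn & d.down)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return matched / n


def es_score(gene_set, ranked_list) -> float:
    """Weighted-KS enrichment score of a gene set in a ranked list.

    Running sum: +1/s at a hit, −1/(N−s) at a miss; ES is the extremum of
    largest magnitude (positive preferred on an exact magnitude tie).  A
    set with no gene in the list scores 0 with a warning.
    """
    members = set(gene_set)
    positions = [i for i, g in enumerate(ranked_list) if g in members]
    s, n_total = len(positions), len(ranked_list)
    if s == 0:
        logger.warning("gene set fully absent from ranked list; ES = 0")
        return 0.0
    if s == n_total:
        return 1.0
    # Extrema tracked as exact integer numerators over s * (N - s), so the
    # result is the correctly rounded float of the exact rational value.
    m = n_total - s
    best_max, best_min = 0, 0
    for i, pos in enumerate(positions):  # pos is 0-based
        before = i * m - (pos - i) * s  # just before hit i+1
        after = (i + 1) * m - (pos - i) * s  # just after it
        best_min = min(best_min, before)
        best_max = max(best_max, after)
    if best_max >= -best_min:  # positive preferred on exact tie
        return best_max / (s * m)
    return best_min / (s * m)


def ks_connectivity(q: QuerySignature, ranked_list) -> float:
    """Connectivity = (ES(q.up) − ES(q.down)) / 2, in [−1, 1]."""
    return (es_score(q.up, ranked_list) - es_score(q.down, ranked_list)) / 2.0


def ranked_list_for_experiment(d: Experiment, universe) -> list[str]:
    """Deterministic ranked gene list implied by an UP/DN experiment:
    up genes first, unaffected genes in the middle, down genes last,
    alphabetical within each block."""
    middle = sorted(set(universe) - d.up - d.down)
    return sorted(d.up) + middle + sorted(d.down)


def _overlap_detail(q: QuerySignature, d: Experiment) -> tuple[int, int, int, int]:
    qup, qdn = set(q.up), set(q.down)
    return (
        len(qup & d.down),
        len(qdn & d.up),
        len(qup & d.up),
        len(qdn & d.down),
    )


def rank_drugs(
    q: QuerySignature,
    bank: DrugBank,
    scorer: str = "overlap",
    mode: str = "reverse",
    top_n: int = 50,
    unique_molecules: bool = False,
) -> RankedHits:
    """Score every bank experiment against the query and keep the top.

    ``scorer='overlap'`` sorts by descending interception score;
    ``scorer='ks'`` sorts by ascending connectivity in reverse mode
    (most negative = strongest reversal) and descending in mimic mode.
    Ties break by experiment ID.  ``unique_molecules=True`` truncates to
    the first occurrence of each molecule instead of raw experiments.
    """
    if not bank.experiments:
        raise ValueError("drug bank is empty")
    rows = []
    for d in bank.experiments:
        if scorer == "overlap":
            score = overlap_score(q, d, mode=mode)
        elif scorer == "ks":
            score = ks_connectivity(q, ranked_list_for_experiment(d, bank.universe))
        else:
            raise ValueError(f"unknown scorer {scorer!r}")
        rows.append((d.exp_id, d.molecule, score, *_overlap_detail(q, d)))
    table = pd.DataFrame(
        rows,
        columns=[
            "experiment",
            "molecule",
            "score",
            "q_up_d_dn",
            "q_dn_d_up",
            "q_up_d_up",
            "q_dn_d_dn",
        ],
    )
    ascending_score = scorer == "ks" and mode == "reverse"
    table = table.sort_values(
        ["score", "experiment"], ascending=[ascending_score, True]
    ).reset_index(drop=True)
    if unique_molecules:
        table = table.drop_duplicates("molecule", keep="first").reset_index(drop=True)
    table = table.head(top_n).copy()
    table.insert(0, "rank", range(1, len(table) + 1))
    return RankedHits(q.cell_type, table)


# ---------------------------------------------------------------------------
# serialization

def write_bank_gmt(bank: DrugBank, path: str) -> None:
    with open(path, "w") as fh:
        for e in bank.experiments:
            desc = f"{e.molecule}|{e.cell_line}|{e.dose}"
            fh.write("\t".join([f"{e.exp_id}-UP", desc, *sorted(e.up)]) + "\n")
            fh.write("\t".join([f"{e.exp_id}-DN", desc, *sorted(e.down)]) + "\n")


def read_bank_gmt(path: str) -> DrugBank:
    """Read a paired-GMT drug bank (``-UP`` / ``-DN`` suffixed lines)."""
    sides: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise GmtParseError(f"{path}:{lineno}: expected >= 2 fields")
            name, desc = fields[0], fields[1]
            if name.endswith("-UP"):
                exp_id, side = name[:-3], "up"
            elif name.endswith("-DN"):
                exp_id, side = name[:-3], "down"
            else:
                raise GmtParseError(
                    f"{path}:{lineno}: bank line must end in -UP or -DN"
                )
            rec = sides.setdefault(exp_id, {"desc": desc})
            rec[side] = frozenset(g.upper() for g in fields[2:] if g)
    experiments = []
    for exp_id, rec in sides.items():
        parts = (rec["desc"].split("|") + ["", ""])[:3]
        experiments.append(
            Experiment(
                exp_id,
                parts[0],
                rec.get("up", frozenset()),
                rec.get("down", frozenset()),
                cell_line=parts[1],
                dose=parts[2],
            )
        )
    return DrugBank(experiments)


def write_bank_json(bank: DrugBank, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "universe": sorted(bank.universe),
                "metadata": bank.metadata,
                "experiments": [
                    {
                        "exp_id": e.exp_id,
                        "molecule": e.molecule,
                        "cell_line": e.cell_line,
                        "dose": e.dose,
                        "up": sorted(e.up),
                        "down": sorted(e.down),
                    }
                    for e in bank.experiments
                ],
            },
            fh,
            indent=1,
            sort_keys=True,
        )


def read_bank_json(path: str) -> DrugBank:
    with open(path) as fh:
        d = json.load(fh)
    experiments = [
        Experiment(
            e["exp_id"],
            e["molecule"],
            frozenset(g.upper() for g in e["up"]),
            frozenset(g.upper() for g in e["down"]),
            cell_line=e.get("cell_line", ""),
            dose=e.get("dose", ""),
        )
        for e in d["experiments"]
    ]
    return DrugBank(
        experiments,
        universe=frozenset(g.upper() for g in d.get("universe", [])),
        metadata=d.get("metadata", {}),
    )


def read_bank(path: str) -> DrugBank:
    return read_bank_json(path) if path.endswith(".json") else read_bank_gmt(path)
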