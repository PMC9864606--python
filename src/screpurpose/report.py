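"""Pipeline orchestration and cross-cell-type aggregation of drug hits.

``run_analysis`` executes the full chain in memory —
QC -> cell-type annotation -> pseudobulk profiles -> pathway activation ->
query signatures -> connectivity ranking — once per detected cell type,
then aggregates: occurrence counts of molecules across all per-cell-type
top lists, exact-membership (UpSet-style) intersections of the
per-cell-type molecule sets, unique and common-to-all molecule sets, and
(when ground truth is available) planted-reverser recovery.

``run_pipeline`` is the file-based wrapper: it reads a YAML config naming
the inputs, runs the analysis and writes a deterministic report bundle
(manifest JSON + TSV tables).
"""

from __future__ import annotations

import json
import os
from importlib.metadata import version as _pkg_version

import anndata as ad
import pandas as pd
import yaml

from . import celltyping, cmap, pathways, qc, signatures
from .errors import PipelineStageError
from .io import read_marker_sets, read_matrix_dir, write_tsv
from .syndata import SynTruth

DEFAULT_PARAMS: dict = {
    "qc": {
        "min_features": 200,
        "max_features": 2500,
        "min_cells": 3,
        "max_mito_pct": 10.0,
        "max_hb_pct": 10.0,
        "scale": 1e4,
    },
    "annotate": {"min_margin": 0.1},
    "pal": {"top_k": 10},
    "signature": {"max_per_side": 2000},
    "rank": {"scorer": "overlap", "mode": "reverse", "top_n": 50},
    "report": {"display_min": 6},
}


def _merge_params(overrides: dict | None) -> dict:
    params = {k: dict(v) for k, v in DEFAULT_PARAMS.items()}
    for section, vals in (overrides or {}).items():
        if section in params and isinstance(vals, dict):
            params[section].update(vals)
    return params


def run_analysis(
    adata: ad.AnnData,
    markers: dict[str, list[str]],
    db: pathways.PathwayDB,
    bank: cmap.DrugBank,
    params: dict | None = None,
) -> dict:
    """Run the full per-cell-type analysis in memory; returns the bundle.

    The bundle maps stage names to their products: ``annotation``,
    ``profiles``, ``pal`` (table), ``queries`` and ``hits`` (per cell
    type), the aggregation tables, and a ``manifest`` of parameters and
    substitution notes.
    """
    p = _merge_params(params)

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as e:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError(name, str(e)) from e

    n_cells_raw, n_genes_raw = adata.shape
    filt = _stage(
        "qc",
        lambda: qc.filter_genes(
            qc.filter_cells(
                adata,
                p["qc"]["min_features"],
                p["qc"]["max_features"],
                p["qc"]["max_mito_pct"],
                p["qc"]["max_hb_pct"],
            ),
            p["qc"]["min_cells"],
        ),
    )
    norm = _stage("qc", qc.normalize, filt, p["qc"]["scale"])
    annotation = _stage(
        "annotate", celltyping.score_cell_types, norm, markers,
        p["annotate"]["min_margin"],
    )
    profiles = _stage("profiles", qc.profiles_by_group, norm, annotation)
    pal = _stage("pal", pathways.pal_table, profiles, db)

    cell_types = sorted(
        {ct for ct, _ in profiles
         if (ct, "case") in profiles and (ct, "control") in profiles}
    )
    queries: dict[str, signatures.QuerySignature] = {}
    hits: dict[str, cmap.RankedHits] = {}
    unmatched: dict[str, int] = {}
    for ct in cell_types:
        activated, inhibited = _stage(
            "signature", pathways.top_pathways, pal, ct, p["pal"]["top_k"]
        )
        cnr = pathways.compute_cnr(profiles[(ct, "case")], profiles[(ct, "control")])
        q = _stage(
            "signature", signatures.build_query, ct, activated, inhibited,
            db, cnr, p["signature"]["max_per_side"],
        )
        queries[ct] = q
        unmatched[ct] = sum(
            1 for g in (*q.up, *q.down) if g not in bank.universe
        )
        hits[ct] = _stage(
            "rank", cmap.rank_drugs, q, bank,
            p["rank"]["scorer"], p["rank"]["mode"], p["rank"]["top_n"],
        )

    occurrence = occurrence_counts(hits, p["report"]["display_min"])
    intersections = intersect_celltypes(hits)
    unique_count, common = unique_and_common(hits)
    assert int(intersections["size"].sum()) == unique_count  # partition property

    manifest = {
        "package_version": _pkg_version("screpurpose"),
        "params": p,
        "n_cells_raw": int(n_cells_raw),
        "n_genes_raw": int(n_genes_raw),
        "n_cells_qc": int(norm.n_obs),
        "n_genes_qc": int(norm.n_vars),
        "cell_types": cell_types,
        "bank_experiments": len(bank.experiments),
        "bank_molecules": len(bank.molecules()),
        "query_genes_unmatched_in_bank": unmatched,
        "substitutions": [
            "normalization: library-size scaling + log1p "
            "(stand-in for regularized NB regression)",
            "cell typing: direct marker-score assignment "
            "(stand-in for graph clustering + cluster annotation)",
        ],
    }
    return {
        "annotation": annotation,
        "profiles": profiles,
        "pal": pal,
        "queries": queries,
        "hits": hits,
        "occurrence": occurrence,
        "intersections": intersections,
        "unique_count": unique_count,
        "common": common,
        "bank_molecules": bank.molecules(),
        "manifest": manifest,
    }


def occurrence_counts(
    hits: dict[str, cmap.RankedHits],
    display_min: int = 6,
    molecule_level: bool = False,
) -> pd.DataFrame:
    """Occurrence of each molecule across all cell types' top lists.

    Experiment-level by default (a molecule hit by two experiments within
    one cell type counts twice); ``molecule_level=True`` counts each
    molecule at most once per cell type.  The full table is returned;
    ``display_min`` is the display-layer threshold ("more than five
    times" -> count >= 6) applied by writers/plots, never here.
    """
    if not hits:
        raise ValueError("no cell types")
    counts: dict[str, int] = {}
    for rh in hits.values():
        mols = rh.table["molecule"]
        if molecule_level:
            mols = mols.drop_duplicates()
        for m in mols:
            counts[m] = counts.get(m, 0) + 1
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["molecule", "count"],
    )
    table.attrs["display_min"] = display_min
    return table


def intersect_celltypes(hits: dict[str, cmap.RankedHits]) -> pd.DataFrame:
    """Exact-membership (UpSet-style) partition of the molecule union.

    Each molecule belongs to exactly one group: the precise subset of
    cell types whose top lists contain it.  Rows sorted by subset size
    descending, then group size descending, then subset label.
    """
    if not hits:
        raise ValueError("no cell types")
    sets = {ct: set(rh.table["molecule"]) for ct, rh in hits.items()}
    membership: dict[frozenset, list[str]] = {}
    for m in sorted(set().union(*sets.values())):
        subset = frozenset(ct for ct, s in sets.items() if m in s)
        membership.setdefault(subset, []).append(m)
    rows = [
        ("|".join(sorted(subset)), ",".join(sorted(mols)), len(mols))
        for subset, mols in membership.items()
    ]
    rows.sort(key=lambda r: (-len(r[0].split("|")), -r[2], r[0]))
    return pd.DataFrame(rows, columns=["cell_types", "molecules", "size"])


def unique_and_common(hits: dict[str, cmap.RankedHits]) -> tuple[int, set[str]]:
    """Size of the molecule union and the molecules common to all cell
    types."""
    if not hits:
        raise ValueError("no cell types")
    sets = [set(rh.table["molecule"]) for rh in hits.values()]
    union = set().union(*sets)
    common = set.intersection(*sets)
    return len(union), common


def evaluate_recovery(bundle: dict, truth: SynTruth, top_n: int = 50) -> dict:
    """Per planted reverser: best rank in its targeted cell type's hits
    and whether it lies within ``top_n``; plus the summary fraction."""
    hits = bundle["hits"]
    known = bundle["bank_molecules"]
    records = []
    for molecule, ct in truth.planted_reversers:
        if molecule not in known:
            raise KeyError(f"planted reverser {molecule!r} not in the bank")
        if ct not in hits:
            raise KeyError(f"targeted cell type {ct!r} not in the bundle")
        table = hits[ct].table
        mine = table[table["molecule"] == molecule]
        best = int(mine["rank"].min()) if len(mine) else None
        records.append(
            {
                "molecule": molecule,
                "cell_type": ct,
                "best_rank": best,
                "in_top_n": best is not None and best <= top_n,
            }
        )
    frac = (
        sum(r["in_top_n"] for r in records) / len(records) if records else 0.0
    )
    return {"reversers": records, "top_n": top_n, "fraction_recovered": frac}


# ---------------------------------------------------------------------------
# file-based entry point

REQUIRED_INPUTS = {  # input key -> stage that needs it
    "matrix": "qc",
    "markers": "annotate",
    "pathways": "pal",
    "bank": "rank",
}


def run_pipeline(config, out_dir: str) -> dict:
    """Execute the pipeline from a YAML config (path or dict) and write
    the report bundle to ``out_dir``.  Fully deterministic: identical
    inputs produce byte-identical outputs."""
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    inputs = config.get("inputs", {})
    for key, stage in REQUIRED_INPUTS.items():
        if key not in inputs:
            raise PipelineStageError(stage, f"config missing inputs.{key}")

    adata = read_matrix_dir(inputs["matrix"])
    markers = read_marker_sets(inputs["markers"])
    db = pathways.read_gmt(inputs["pathways"])
    bank = cmap.read_bank(inputs["bank"])
    bundle = run_analysis(adata, markers, db, bank, params=config.get("params"))

    if "truth" in inputs:
        truth = SynTruth.from_json(inputs["truth"])
        bundle["recovery"] = evaluate_recovery(
            bundle, truth, top_n=bundle["manifest"]["params"]["rank"]["top_n"]
        )
    write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: dict, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(bundle["manifest"], fh, indent=1, sort_keys=True)

    write_tsv(bundle["pal"], os.path.join(out_dir, "pal.tsv"))
    ann = bundle["annotation"].reset_index()
    ann.columns = ["barcode", "label", "margin"]
    write_tsv(ann, os.path.join(out_dir, "annotation.tsv"))

    for ct, q in bundle["queries"].items():
        signatures.write_query_gmt(q, os.path.join(out_dir, f"query_{ct}.gmt"))
        signatures.write_query_json(q, os.path.join(out_dir, f"query_{ct}.json"))
    for ct, rh in bundle["hits"].items():
        table = rh.table.copy()
        table.insert(0, "cell_type", ct)
        write_tsv(table, os.path.join(out_dir, f"hits_{ct}.tsv"))

    write_tsv(bundle["occurrence"], os.path.join(out_dir, "occurrence.tsv"))
    write_tsv(bundle["intersections"], os.path.join(out_dir, "intersections.tsv"))
    summary = pd.DataFrame(
        [
            ("unique_molecules", bundle["unique_count"]),
            ("common_to_all", len(bundle["common"])),
            ("common_molecules", ",".join(sorted(bundle["common"]))),
        ],
        columns=["quantity", "value"],
    )
    write_tsv(summary, os.path.join(out_dir, "summary.tsv"))
    if "recovery" in bundle:
        with open(os.path.join(out_dir, "recovery.json"), "w") as fh:
            json.dump(bundle["recovery"], fh, indent=1, sort_keys=True)
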