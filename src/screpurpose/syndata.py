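"""Synthetic case/control cohorts with planted, recoverable signal.

The generator emulates a multi-donor case/control single-cell study:
counts are negative-binomial with a single global dispersion, each cell
type elevates its marker genes by a fold factor, and "planted" effects
multiply the mean of a chosen pathway's genes in case cells of a chosen
cell type by ``2**log2_fold``.  A paired drug bank can then be generated
containing experiments that exactly reverse the planted shifts (DN set
drawn from up-planted genes, UP set from down-planted genes) among
uniformly sampled decoys — so every downstream stage (QC, annotation,
pathway scoring, signature construction, connectivity ranking) has ground
truth to recover.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError
from .pathways import Pathway, PathwayDB


@dataclass(frozen=True)
class PlantedEffect:
    """A condition-specific expression shift: case cells of ``cell_type``
    get the genes of ``pathway_id`` scaled by ``2**log2_fold``."""

    pathway_id: str
    cell_type: str
    log2_fold: float

    def __post_init__(self):
        if self.log2_fold == 0:
            raise ConfigurationError("log2_fold must be nonzero")


@dataclass
class SynConfig:
    """Cohort geometry and noise model.

    Defaults are the package's standard study conditions: a 6 + 6 donor
    case/control cohort, five immune cell types with 100 cells per type
    per donor (600 cells per (type, condition)), ~1000 genes with
    negative-binomial counts (mean 0.5, dispersion 2.0 — scRNA-seq-like
    sparsity with overdispersion) and an 8-fold marker elevation.
    """

    n_genes: int = 1000
    n_cell_types: int = 5
    cells_per_type_per_donor: int = 100
    n_donors_case: int = 6
    n_donors_control: int = 6
    nb_mean: float = 0.5
    nb_dispersion: float = 2.0
    marker_fold: float = 8.0
    planted: list[PlantedEffect] = field(default_factory=list)
    seed: int = 0
    # QC emulation: genes named with MT-/HB prefixes, and a fraction of
    # cells whose mitochondrial means are boosted to fail the mito filter.
    n_mito_genes: int = 10
    n_hb_genes: int = 5
    frac_low_quality: float = 0.0
    low_quality_mito_boost: float = 50.0

    def __post_init__(self):
        for name in (
            "n_genes", "n_cell_types", "cells_per_type_per_donor",
            "n_donors_case", "n_donors_control",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ConfigurationError("nb_mean and nb_dispersion must be positive")
        if self.marker_fold <= 1:
            raise ConfigurationError("marker_fold must exceed 1")
        if self.n_mito_genes + self.n_hb_genes > self.n_genes:
            raise ConfigurationError("more MT-/HB genes than genes")


@dataclass
class SynTruth:
    """Ground truth of a generated study."""

    planted_effects: list[PlantedEffect]
    planted_reversers: list[tuple[str, str]]  # (molecule, targeted cell type)
    cell_type_of_cell: dict[str, str]
    low_quality_cells: tuple[str, ...] = ()

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_effects": [asdict(e) for e in self.planted_effects],
                    "planted_reversers": [list(r) for r in self.planted_reversers],
                    "cell_type_of_cell": self.cell_type_of_cell,
                    "low_quality_cells": list(self.low_quality_cells),
                },
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str) -> "SynTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            [PlantedEffect(**e) for e in d["planted_effects"]],
            [tuple(r) for r in d["planted_reversers"]],
            d["cell_type_of_cell"],
            tuple(d.get("low_quality_cells", ())),
        )


DEFAULT_CELL_TYPES = ("B_CELL", "GRANULOCYTE", "MONOCYTE", "NK_CELL", "T_CELL")


def make_gene_universe(config: SynConfig) -> list[str]:
    """Gene IDs: MT-/HB-prefixed QC genes first, then plain symbols."""
    genes = [f"MT-SYN{i + 1}" for i in range(config.n_mito_genes)]
    genes += [f"HBA{i + 1}" for i in range(config.n_hb_genes)]
    n_plain = config.n_genes - len(genes)
    genes += [f"GENE{i + 1:04d}" for i in range(n_plain)]
    return genes


def generate_pathway_db(
    n_pathways: int,
    genes_per_pathway: int,
    gene_universe: list[str],
    overlap_fraction: float = 0.0,
    seed: int = 0,
    repressor_fraction: float = 0.0,
) -> PathwayDB:
    """Sample ``n_pathways`` gene sets from the universe.

    Adjacent pathways share ``round(overlap_fraction * genes_per_pathway)``
    genes; the remainder is drawn without replacement from the still-unused
    pool, so with overlap 0 all sets are pairwise disjoint.
    ``repressor_fraction`` of each pathway's genes get ARR weight −1
    (default: all +1).
    """
    if genes_per_pathway > len(gene_universe):
        raise ConfigurationError("genes_per_pathway exceeds gene universe size")
    if not 0 <= overlap_fraction < 1:
        raise ConfigurationError("overlap_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_shared = int(round(overlap_fraction * genes_per_pathway))
    pool = list(gene_universe)
    rng.shuffle(pool)
    db = PathwayDB()
    prev: list[str] = []
    for i in range(n_pathways):
        shared = prev[:n_shared] if prev else []
        n_fresh = genes_per_pathway - len(shared)
        if n_fresh > len(pool):
            raise ConfigurationError(
                "gene universe too small for the requested pathways"
            )
        fresh, pool = pool[:n_fresh], pool[n_fresh:]
        genes = shared + fresh
        n_rep = int(round(repressor_fraction * len(genes)))
        rep_idx = set(
            rng.choice(len(genes), size=n_rep, replace=False) if n_rep else []
        )
        arr = {g: (-1 if j in rep_idx else 1) for j, g in enumerate(genes)}
        db[f"PW{i + 1:03d}"] = Pathway(tuple(genes), arr, "synthetic")
        prev = genes
    return db


def generate_marker_sets(
    cell_types,
    gene_universe: list[str],
    genes_per_type: int = 10,
    seed: int = 0,
    exclude=(),
) -> dict[str, list[str]]:
    """Pairwise-disjoint marker sets sampled from the universe (minus
    ``exclude``, e.g. planted pathway genes)."""
    rng = np.random.default_rng(seed)
    pool = [g for g in gene_universe if g not in set(exclude)
            and not g.startswith("MT-") and not g.startswith("HB")]
    need = genes_per_type * len(cell_types)
    if need > len(pool):
        raise ConfigurationError("gene universe too small for marker sets")
    chosen = rng.choice(len(pool), size=need, replace=False)
    markers = {}
    for k, ct in enumerate(sorted(cell_types)):
        idx = chosen[k * genes_per_type: (k + 1) * genes_per_type]
        markers[ct] = sorted(pool[i] for i in idx)
    return markers


def generate_cohort(
    config: SynConfig,
    pathway_db: PathwayDB,
    marker_sets: dict[str, list[str]],
) -> tuple[ad.AnnData, SynTruth]:
    """Draw the count matrix and ground truth for one cohort.

    Counts are NB(mean, dispersion) per gene/cell; markers of a cell's
    type multiply the mean by ``marker_fold``; planted pathway genes in
    case cells of the targeted type multiply it by ``2**log2_fold``.
    """
    seen: set[str] = set()
    for ct, genes in marker_sets.items():
        overlap = seen & set(genes)
        if overlap:
            raise ConfigurationError(
                f"marker sets overlap at {sorted(overlap)[:5]}"
            )
        seen |= set(genes)
    for eff in config.planted:
        if eff.pathway_id not in pathway_db:
            raise KeyError(f"planted pathway {eff.pathway_id!r} not in database")

    cell_types = sorted(marker_sets)
    if len(cell_types) != config.n_cell_types:
        raise ConfigurationError(
            f"marker_sets has {len(cell_types)} types, config expects "
            f"{config.n_cell_types}"
        )
    for eff in config.planted:
        if eff.cell_type not in cell_types:
            raise KeyError(f"planted cell type {eff.cell_type!r} unknown")

    genes = make_gene_universe(config)
    gene_idx = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(config.seed)

    donors = [f"case{d + 1}" for d in range(config.n_donors_case)] + [
        f"ctrl{d + 1}" for d in range(config.n_donors_control)
    ]
    conditions = ["case"] * config.n_donors_case + [
        "control"
    ] * config.n_donors_control

    barcodes, obs_donor, obs_cond, truth_type = [], [], [], {}
    mean_rows = []
    base = np.full(len(genes), config.nb_mean)
    cell_counter = 0
    for donor, cond in zip(donors, conditions):
        for ct in cell_types:
            mean_ct = base.copy()
            mean_ct[[gene_idx[g] for g in marker_sets[ct]]] *= config.marker_fold
            if cond == "case":
                for eff in config.planted:
                    if eff.cell_type == ct:
                        idx = [
                            gene_idx[g]
                            for g in pathway_db[eff.pathway_id].genes
                            if g in gene_idx
                        ]
                        mean_ct[idx] = mean_ct[idx] * (2.0 ** eff.log2_fold)
            for _ in range(config.cells_per_type_per_donor):
                bc = f"CELL{cell_counter + 1:06d}"
                cell_counter += 1
                barcodes.append(bc)
                obs_donor.append(donor)
                obs_cond.append(cond)
                truth_type[bc] = ct
                mean_rows.append(mean_ct)

    means = np.vstack(mean_rows)

    low_quality: list[str] = []
    if config.frac_low_quality > 0:
        n_low = int(round(config.frac_low_quality * len(barcodes)))
        low_idx = rng.choice(len(barcodes), size=n_low, replace=False)
        mito_cols = [i for i, g in enumerate(genes) if g.startswith("MT-")]
        means = means.copy()
        means[np.ix_(low_idx, mito_cols)] *= config.low_quality_mito_boost
        low_quality = [barcodes[i] for i in sorted(low_idx)]

    theta = config.nb_dispersion
    p = theta / (theta + means)
    counts = rng.negative_binomial(theta, p)

    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=pd.DataFrame(
            {"donor": obs_donor, "condition": obs_cond},
            index=pd.Index(barcodes, name="barcode"),
        ),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    truth = SynTruth(
        list(config.planted), [], truth_type, tuple(low_quality)
    )
    return adata, truth


def generate_drug_bank(
    pathway_db: PathwayDB,
    truth: SynTruth,
    n_decoys: int,
    sig_size: int,
    seed: int = 0,
    n_reversers_per_type: int = 1,
    corruption_fraction: float = 0.0,
    gene_universe=None,
    experiments_per_molecule: int = 1,
):
    """Build a drug bank of exact planted reversers plus uniform decoys.

    For every cell type with planted effects, ``n_reversers_per_type``
    reverser molecules are emitted whose DN set is drawn from the
    up-planted pathway genes of that type and whose UP set from its
    down-planted pathway genes; a side short of ``sig_size`` is padded
    with random non-planted genes and the pad fraction is recorded in the
    bank metadata.  Decoy UP/DN sets are sampled uniformly from
    non-planted genes.  ``corruption_fraction`` replaces that fraction of
    the planted genes in each reverser with random non-planted genes
    (harder positives).  The created reversers are appended to
    ``truth.planted_reversers``.
    """
    from .cmap import DrugBank, Experiment

    rng = np.random.default_rng(seed)
    universe = sorted(gene_universe) if gene_universe else sorted(
        pathway_db.gene_universe()
    )
    if sig_size > len(universe):
        raise ConfigurationError("sig_size exceeds gene universe size")

    planted_genes: set[str] = set()
    up_genes_of: dict[str, list[str]] = {}
    dn_genes_of: dict[str, list[str]] = {}
    for eff in truth.planted_effects:
        genes = list(pathway_db[eff.pathway_id].genes)
        planted_genes |= set(genes)
        side = up_genes_of if eff.log2_fold > 0 else dn_genes_of
        side.setdefault(eff.cell_type, []).extend(genes)
    non_planted = [g for g in universe if g not in planted_genes]

    def _pick(pool: list[str], k: int) -> list[str]:
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in idx]

    def _pad_side(source: list[str], taken: set[str]) -> tuple[frozenset, float]:
        src = sorted(set(source))
        kept = src if len(src) <= sig_size else _pick(src, sig_size)
        n_corrupt = int(round(corruption_fraction * len(kept)))
        if n_corrupt:
            drop = set(_pick(kept, n_corrupt))
            kept = [g for g in kept if g not in drop]
        pad_pool = [g for g in non_planted if g not in taken and g not in set(kept)]
        n_pad = sig_size - len(kept)
        padded = kept + (_pick(pad_pool, n_pad) if n_pad > 0 else [])
        return frozenset(padded), n_pad / sig_size if sig_size else 0.0

    experiments, metadata = [], {"pad_fraction": {}}
    targeted = sorted(set(up_genes_of) | set(dn_genes_of))
    for ct in targeted:
        for i in range(n_reversers_per_type):
            molecule = f"reverser-{ct.lower()}-{i + 1}"
            for j in range(experiments_per_molecule):
                exp_id = f"REV-{ct}-{i + 1:02d}-{j + 1}"
                dn, pad_dn = _pad_side(up_genes_of.get(ct, []), set())
                up, pad_up = _pad_side(dn_genes_of.get(ct, []), set(dn))
                metadata["pad_fraction"][exp_id] = round((pad_dn + pad_up) / 2, 4)
                experiments.append(
                    Experiment(exp_id, molecule, up, dn, cell_line="SYN",
                               dose=f"{10 * (j + 1)}uM")
                )
            truth.planted_reversers.append((molecule, ct))

    for i in range(n_decoys):
        pool = non_planted if len(non_planted) >= 2 * sig_size else universe
        both = _pick(pool, 2 * sig_size)
        experiments.append(
            Experiment(
                f"DEC-{i + 1:04d}",
                f"decoy-{i + 1}",
                frozenset(both[:sig_size]),
                frozenset(both[sig_size:]),
                cell_line="SYN",
                dose="10uM",
            )
        )
    return DrugBank(experiments, universe=frozenset(universe), metadata=metadata)


@dataclass
class SimulatedStudy:
    adata: ad.AnnData
    truth: SynTruth
    pathway_db: PathwayDB
    marker_sets: dict[str, list[str]]
    bank: "object"  # DrugBank
    config: SynConfig


def simulate_study(
    seed: int,
    n_pathways: int = 40,
    genes_per_pathway: int = 20,
    n_reversers: int = 5,
    n_decoys: int = 200,
    sig_size: int = 50,
    planted: list[PlantedEffect] | None = None,
    **config_overrides,
) -> SimulatedStudy:
    """One full synthetic study under the default conditions.

    Default planted signal: pathways PW001 and PW002 up (+2) and PW003
    down (−2) in T cells, with 5 exact reverser molecules and 200 decoys
    in the drug bank.
    """
    if planted is None:
        planted = [
            PlantedEffect("PW001", "T_CELL", 2.0),
            PlantedEffect("PW002", "T_CELL", 2.0),
            PlantedEffect("PW003", "T_CELL", -2.0),
        ]
    ss = np.random.SeedSequence(seed)
    sub = [int(s) % (2**31) for s in ss.generate_state(4)]
    config = SynConfig(planted=list(planted), seed=sub[0], **config_overrides)
    universe = make_gene_universe(config)
    db = generate_pathway_db(
        n_pathways, genes_per_pathway, universe, overlap_fraction=0.0, seed=sub[1]
    )
    planted_genes = {
        g for eff in planted for g in db[eff.pathway_id].genes
    }
    markers = generate_marker_sets(
        DEFAULT_CELL_TYPES[: config.n_cell_types],
        universe,
        seed=sub[2],
        exclude=planted_genes,
    )
    adata, truth = generate_cohort(config, db, markers)
    bank = generate_drug_bank(
        db,
        truth,
        n_decoys=n_decoys,
        sig_size=sig_size,
        seed=sub[3],
        n_reversers_per_type=n_reversers,
        gene_universe=universe,
    )
    return SimulatedStudy(adata, truth, db, markers, bank, config)
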