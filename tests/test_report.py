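"""Pipeline orchestration, aggregation tables and recovery evaluation."""

import os

import numpy as np
import pandas as pd
import pytest
import yaml

from screpurpose import (
    PlantedEffect,
    RankedHits,
    SynTruth,
    evaluate_recovery,
    intersect_celltypes,
    occurrence_counts,
    run_analysis,
    run_pipeline,
    simulate_study,
    unique_and_common,
)
from screpurpose.cli import main as cli_main
from screpurpose.cmap import write_bank_gmt
from screpurpose.errors import PipelineStageError
from screpurpose.io import write_marker_sets, write_matrix_dir
from screpurpose.pathways import write_gmt


def _hits(molecules_by_ct: dict) -> dict:
    out = {}
    for ct, mols in molecules_by_ct.items():
        table = pd.DataFrame(
            {
                "rank": range(1, len(mols) + 1),
                "experiment": [f"{ct}-E{i}" for i in range(len(mols))],
                "molecule": list(mols),
                "score": np.linspace(1, 0.5, len(mols)),
            }
        )
        out[ct] = RankedHits(ct, table)
    return out


class TestOccurrenceCounts:
    def test_two_experiments_of_one_molecule_count_twice(self):
        table = occurrence_counts(_hits({"T": ["M", "M"]}))
        assert table.set_index("molecule").loc["M", "count"] == 2

    def test_molecule_in_every_list_counts_per_cell_type(self):
        hits = _hits({f"ct{i}": ["M"] for i in range(8)})
        table = occurrence_counts(hits)
        assert table.set_index("molecule").loc["M", "count"] == 8

    def test_hand_tallied_fixture(self):
        hits = _hits({"a": ["M1", "M2"], "b": ["M2", "M3"], "c": ["M2"]})
        counts = occurrence_counts(hits).set_index("molecule")["count"]
        assert counts.to_dict() == {"M1": 1, "M2": 3, "M3": 1}

    def test_molecule_level_mode_counts_once_per_cell_type(self):
        hits = _hits({"a": ["M", "M"], "b": ["M"]})
        table = occurrence_counts(hits, molecule_level=True)
        assert table.set_index("molecule").loc["M", "count"] == 2


class TestIntersectCelltypes:
    def test_identical_sets_form_one_group(self):
        table = intersect_celltypes(_hits({"a": ["M1", "M2"], "b": ["M2", "M1"]}))
        assert len(table) == 1
        assert table.iloc[0]["cell_types"] == "a|b"
        assert table.iloc[0]["size"] == 2

    def test_disjoint_sets_form_singleton_groups(self):
        table = intersect_celltypes(_hits({"a": ["M1"], "b": ["M2"]}))
        assert len(table) == 2
        assert set(table["cell_types"]) == {"a", "b"}

    def test_hand_partition(self):
        """{A,B}, {B,C}, {B} -> groups {all}:{B}, {1}:{A}, {2}:{C}."""
        table = intersect_celltypes(
            _hits({"c1": ["A", "B"], "c2": ["B", "C"], "c3": ["B"]})
        )
        groups = dict(zip(table["cell_types"], table["molecules"]))
        assert groups == {"c1|c2|c3": "B", "c1": "A", "c2": "C"}
        assert list(table["size"]) == [1, 1, 1]


class TestUniqueAndCommon:
    def test_single_cell_type(self):
        unique, common = unique_and_common(_hits({"a": ["M1", "M2"]}))
        assert unique == 2 and common == {"M1", "M2"}

    def test_empty_list_makes_common_empty(self):
        unique, common = unique_and_common(_hits({"a": ["M1"], "b": []}))
        assert common == set()

    def test_hand_set_arithmetic(self):
        unique, common = unique_and_common(
            _hits({"a": ["A", "B", "C"], "b": ["B", "C"], "c": ["B", "C", "D"]})
        )
        assert unique == 4 and common == {"B", "C"}


class TestAggregationConservation:
    def test_partition_and_occurrence_sums(self):
        rng = np.random.default_rng(0)
        pool = [f"M{i:02d}" for i in range(30)]
        for _ in range(200):
            hits = {
                f"ct{j}": list(
                    rng.choice(pool, rng.integers(1, 15), replace=False)
                )
                for j in range(rng.integers(1, 5))
            }
            h = _hits(hits)
            unique, _ = unique_and_common(h)
            table = intersect_celltypes(h)
            assert int(table["size"].sum()) == unique
            occ = occurrence_counts(h)
            assert occ["count"].sum() == sum(len(m) for m in hits.values())


class TestEvaluateRecovery:
    def _bundle(self, hits, molecules):
        return {"hits": hits, "bank_molecules": set(molecules)}

    def test_rank_one_is_recovered_at_any_top_n(self):
        bundle = self._bundle(_hits({"T": ["M1", "M2"]}), ["M1", "M2"])
        truth = SynTruth([], [("M1", "T")], {})
        rec = evaluate_recovery(bundle, truth, top_n=1)
        assert rec["reversers"][0]["best_rank"] == 1
        assert rec["fraction_recovered"] == 1.0

    def test_unknown_drug_is_a_reference_error(self):
        bundle = self._bundle(_hits({"T": ["M1"]}), ["M1"])
        truth = SynTruth([], [("GHOST", "T")], {})
        with pytest.raises(KeyError, match="GHOST"):
            evaluate_recovery(bundle, truth)

    def test_fraction_is_hits_over_planted(self):
        hits = _hits({"T": ["M1", "M2", "M3", "M4", "X"]})
        molecules = ["M1", "M2", "M3", "M4", "M5", "X"]
        truth = SynTruth([], [(f"M{i}", "T") for i in range(1, 6)], {})
        rec = evaluate_recovery(self._bundle(hits, molecules), truth, top_n=50)
        assert rec["fraction_recovered"] == pytest.approx(0.8)


def _write_study(study, root):
    matrix_dir = os.path.join(root, "matrix")
    write_matrix_dir(study.adata, matrix_dir)
    paths = {
        "matrix": matrix_dir,
        "markers": os.path.join(root, "markers.tsv"),
        "pathways": os.path.join(root, "pathways.gmt"),
        "bank": os.path.join(root, "bank.gmt"),
        "truth": os.path.join(root, "truth.json"),
    }
    write_marker_sets(study.marker_sets, paths["markers"])
    write_gmt(study.pathway_db, paths["pathways"])
    write_bank_gmt(study.bank, paths["bank"])
    study.truth.to_json(paths["truth"])
    return paths


@pytest.fixture(scope="module")
def tiny_single_type_study():
    return simulate_study(
        5,
        n_pathways=10,
        genes_per_pathway=15,
        n_reversers=2,
        n_decoys=20,
        sig_size=15,
        planted=[PlantedEffect("PW001", "B_CELL", 2.0)],
        n_genes=500,
        n_cell_types=1,
        cells_per_type_per_donor=30,
        n_donors_case=2,
        n_donors_control=2,
        nb_mean=0.8,
    )


class TestRunPipeline:
    def test_single_cell_type_yields_one_hits_table(self, tiny_single_type_study):
        s = tiny_single_type_study
        bundle = run_analysis(s.adata, s.marker_sets, s.pathway_db, s.bank)
        assert list(bundle["hits"]) == ["B_CELL"]

    def test_missing_bank_input_names_the_rank_stage(self, tmp_path):
        config = {"inputs": {"matrix": "x", "markers": "y", "pathways": "z"}}
        with pytest.raises(PipelineStageError, match="rank"):
            run_pipeline(config, str(tmp_path / "out"))

    def test_reruns_are_byte_identical(self, tiny_single_type_study, tmp_path):
        paths = _write_study(tiny_single_type_study, str(tmp_path))
        config = {"inputs": paths}
        out1, out2 = str(tmp_path / "o1"), str(tmp_path / "o2")
        run_pipeline(config, out1)
        run_pipeline(config, out2)
        files = sorted(os.listdir(out1))
        assert files == sorted(os.listdir(out2))
        for name in files:
            with open(os.path.join(out1, name), "rb") as f1, open(
                os.path.join(out2, name), "rb"
            ) as f2:
                assert f1.read() == f2.read(), name

    def test_bundle_written_with_recovery(self, tiny_single_type_study, tmp_path):
        paths = _write_study(tiny_single_type_study, str(tmp_path))
        out = str(tmp_path / "out")
        bundle = run_pipeline({"inputs": paths}, out)
        for name in ("manifest.json", "pal.tsv", "occurrence.tsv",
                     "intersections.tsv", "summary.tsv", "recovery.json",
                     "hits_B_CELL.tsv", "query_B_CELL.gmt"):
            assert os.path.exists(os.path.join(out, name)), name
        assert bundle["recovery"]["fraction_recovered"] == 1.0

    def test_param_overrides_flow_through(self, tiny_single_type_study):
        s = tiny_single_type_study
        bundle = run_analysis(
            s.adata, s.marker_sets, s.pathway_db, s.bank,
            params={"rank": {"top_n": 5}},
        )
        assert len(bundle["hits"]["B_CELL"].table) == 5


class TestCli:
    def test_simulate_run_evaluate_round_trip(self, tmp_path):
        from click.testing import CliRunner

        runner = CliRunner()
        sim_dir = str(tmp_path / "sim")
        overrides = {
            "n_pathways": 10,
            "genes_per_pathway": 15,
            "n_reversers": 2,
            "n_decoys": 10,
            "sig_size": 15,
            "n_genes": 500,
            "cells_per_type_per_donor": 10,
            "n_donors_case": 2,
            "n_donors_control": 2,
            "nb_mean": 0.8,
        }
        cfg = tmp_path / "sim.yaml"
        cfg.write_text(yaml.safe_dump(overrides))
        res = runner.invoke(
            cli_main,
            ["simulate", "--config", str(cfg), "--out", sim_dir, "--seed", "3"],
        )
        assert res.exit_code == 0, res.output
        out_dir = str(tmp_path / "run")
        res = runner.invoke(
            cli_main,
            ["run", "--config", os.path.join(sim_dir, "config.yaml"),
             "--out", out_dir],
        )
        assert res.exit_code == 0, res.output
        assert "unique molecules" in res.output
        res = runner.invoke(
            cli_main,
            ["evaluate", "--bundle", out_dir, "--truth",
             os.path.join(sim_dir, "truth.json"), "--top-n", "10"],
        )
        assert res.exit_code == 0, res.output
        assert '"fraction_recovered": 1.0' in res.output


def test_plotting_smoke(tmp_path):
    import matplotlib.pyplot as plt

    from screpurpose.plotting import plot_intersections, plot_occurrence

    hits = _hits({"a": ["M1", "M2"], "b": ["M2"]})
    occ = occurrence_counts(hits)
    ax = plot_occurrence(occ, display_min=1)
    ax.figure.savefig(tmp_path / "occ.png")
    table = intersect_celltypes(hits)
    ax = plot_intersections(table)
    ax.figure.savefig(tmp_path / "ints.png")
    plt.close("all")
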