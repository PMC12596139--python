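import json

import pytest
from click.testing import CliRunner

from treecohort.annotations import bundled_interactions_path, load_interactions
from treecohort.cli import main
from treecohort.distances import distance_matrix, mds_embed
from treecohort.render import (
    export_pdf,
    label_colors,
    render_cohort_grid,
    render_embedding,
    render_heatmap,
    render_tree,
)
from treecohort.simulate import SimulationConfig, simulate_cohort
from treecohort.treecore import write_cohort

from .conftest import build_tree


@pytest.fixture(scope="module")
def cohort():
    c, _ = simulate_cohort(SimulationConfig(seed=12))
    return c


class TestRenderTree:
    def test_single_node_tree(self):
        svg = render_tree(build_tree("solo", [("r", None, {})]))
        assert svg.count("<circle") == 1
        assert "<line" not in svg

    def test_many_event_edge_label(self):
        t = build_tree("s", [
            ("r", None, {}),
            ("a", "r", {"snv": {"A": "", "B": "", "C": ""},
                        "amp": {"D": 1, "E": 1},
                        "del": {"F": 1, "G": 1, "H": 1, "I": 1}}),
        ])
        assert "3snv, 2amp, 4del" in render_tree(t)

    def test_deterministic_bytes(self, cohort):
        t = cohort.trees["c1_t1"]
        assert render_tree(t).encode() == render_tree(t).encode()

    def test_gene_highlight_colors(self):
        t = build_tree("s", [
            ("r", None, {}),
            ("a", "r", {"amp": {"MYC": 2}}),
            ("b", "a", {"snv": {"TP53": "x"}}),
        ])
        svg = render_tree(t, highlight_gene="MYC")
        assert '#d62728' in svg  # amplification red
        svg2 = render_tree(t, highlight_gene="TP53")
        assert '#9467bd' in svg2  # other-event violet

    def test_drug_marker_square(self):
        t = build_tree("s", [
            ("r", None, {}),
            ("a", "r", {"snv": {"BRAF": "p.V600E"}}),
        ])
        table = load_interactions(bundled_interactions_path())
        svg = render_tree(t, drug="Vemurafenib", interactions=table)
        assert "<rect" in svg


class TestRenderGrid:
    def test_cluster_tints_distinct(self, cohort):
        svg = render_cohort_grid(cohort)
        tints = {
            line.split('fill="')[1].split('"')[0]
            for line in svg.splitlines()
            if 'fill-opacity="0.15"' in line
        }
        assert len(tints) == len(cohort.clusters)

    def test_shared_label_shares_fill(self, cohort):
        from treecohort.cohort import matching_groups

        groups = matching_groups(cohort)
        fills = label_colors([g.label for g in groups])
        svg = render_cohort_grid(cohort)
        for g in groups[:3]:
            assert fills[g.label] in svg

    def test_no_clusters_uniform_background(self, cohort):
        from treecohort.treecore import TreeCohort

        bare = TreeCohort(cohort.trees)
        svg = render_cohort_grid(bare)
        assert 'fill-opacity="0.15"' not in svg

    def test_color_map_pure_function_of_label_set(self):
        a = label_colors(["b", "a", "c"])
        b = label_colors(["c", "a", "b", "a"])
        assert a == b


class TestRenderHeatmapEmbedding:
    def test_all_zero_matrix_single_color(self, cohort):
        import numpy as np

        from treecohort.treecore import DistanceMatrix

        dm = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        svg = render_heatmap(dm)
        cells = [ln for ln in svg.splitlines() if 'stroke="#eeeeee"' in ln]
        colors = {c.split('fill="')[1].split('"')[0] for c in cells}
        assert colors == {"#ffffff"}

    def test_axis_labels_and_separators(self, cohort):
        dm = distance_matrix(cohort)
        svg = render_heatmap(dm, cohort.clusters)
        for sid in dm.sample_ids:
            assert sid in svg

    def test_embedding_colors_by_cluster(self, cohort):
        dm = distance_matrix(cohort)
        coords = mds_embed(dm)
        svg = render_embedding(coords, cohort.clusters)
        assert svg == render_embedding(coords, cohort.clusters)
        assert svg.count("<circle") == len(coords)


class TestExportPdf:
    def test_writes_file_or_svg_fallback(self, tmp_path, cohort):
        svg = render_tree(cohort.trees["c1_t1"])
        out = export_pdf(svg, tmp_path / "fig.pdf")
        assert out.exists() and out.stat().st_size > 0
        assert out.suffix in (".pdf", ".svg")


class TestCli:
    @pytest.fixture
    def cohort_file(self, tmp_path, cohort):
        p = tmp_path / "cohort.json"
        write_cohort(cohort, p)
        return p

    def test_validate_ok(self, cohort_file):
        res = CliRunner().invoke(main, ["validate", str(cohort_file)])
        assert res.exit_code == 0

    def test_validate_reports_violations(self, tmp_path):
        p = tmp_path / "bad.json"
        doc = {"trees": {"s1": {"nodes": [
            {"node_id": "r", "events": {"snv": {"X": ""}}},
        ]}}}
        p.write_text(json.dumps(doc))
        out = CliRunner().invoke(main, ["validate", str(p)])
        assert out.exit_code == 1

    def test_simulate_distances_embed_pipeline(self, tmp_path):
        runner = CliRunner()
        cj = tmp_path / "c.json"
        r1 = runner.invoke(main, ["--seed", "3", "simulate", "-o", str(cj)])
        assert r1.exit_code == 0, r1.output
        assert cj.exists() and cj.with_suffix(".truth.json").exists()
        dt = tmp_path / "d.tsv"
        r2 = runner.invoke(main, ["distances", str(cj), "-o", str(dt)])
        assert r2.exit_code == 0, r2.output
        ct = tmp_path / "coords.tsv"
        r3 = runner.invoke(main, ["embed", str(dt), "-o", str(ct)])
        assert r3.exit_code == 0, r3.output
        assert ct.read_text().startswith("sample_id\tx\ty")

    def test_knn_trajectories_summary(self, cohort_file):
        runner = CliRunner()
        r = runner.invoke(main, ["knn", "--target", "c1_t1", "-k", "3",
                                 str(cohort_file)])
        assert r.exit_code == 0 and len(r.output.strip().splitlines()) == 3
        r = runner.invoke(main, ["trajectories", "--cluster", "0",
                                 "--min-support", "1.0", str(cohort_file)])
        assert r.exit_code == 0 and "->" in r.output
        r = runner.invoke(main, ["summary", "--cluster", "0", str(cohort_file)])
        assert r.exit_code == 0
        assert r.output.startswith("section\tkey\tvalue\tcount")

    def test_convert_command(self, tmp_path):
        (tmp_path / "p.tsv").write_text("node_id\tparent_id\nr\t\na\tr\n")
        (tmp_path / "e.tsv").write_text(
            "node_id\tevent_type\tgene\tdetail\na\tsnv\tTP53\tp.R175H\n"
        )
        out = tmp_path / "c.json"
        r = CliRunner().invoke(main, [
            "convert", "--dialect", "parent_vector", "--sample", "s1",
            str(tmp_path / "p.tsv"), str(tmp_path / "e.tsv"), "-o", str(out),
        ])
        assert r.exit_code == 0, r.output
        assert "TP53" in out.read_text()

    @pytest.mark.parametrize("view", ["tree", "grid", "heatmap", "embedding"])
    def test_render_views_byte_stable(self, tmp_path, cohort_file, view):
        runner = CliRunner()
        outs = []
        for name in ("a.svg", "b.svg"):
            out = tmp_path / name
            r = runner.invoke(main, ["render", view, str(cohort_file),
                                     "-o", str(out)])
            assert r.exit_code == 0, r.output
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]
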