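import numpy as np
import pytest

from gastruquant.boundary_metrics import (
    BoundaryError,
    BoundaryTrace,
    classify_junctions,
    classify_rows,
    extract_boundary,
    straightness,
    straightness_series,
)
from gastruquant.synthetic_data import TissueParams, generate_tissue, generate_timelapse
from gastruquant.tissue_model import LabelImage, build_mesh


def three_column_mesh():
    img = np.zeros((12, 9), dtype=int)
    img[:, :3], img[:, 3:6], img[:, 6:] = 1, 2, 3
    return build_mesh(
        LabelImage(img), {1: "paraxial", 2: "axial", 3: "paraxial"}
    )


class TestStraightness:
    def test_collinear_polyline(self):
        line = np.column_stack([np.zeros(20), np.linspace(0, 7, 20)])
        assert straightness(line) == pytest.approx(1.0)

    def test_semicircle(self):
        th = np.linspace(-np.pi / 2, np.pi / 2, 1000)
        arc = np.column_stack([np.cos(th), np.sin(th)])
        assert straightness(arc) == pytest.approx(np.pi / 2, abs=1e-3)

    def test_right_angle_path(self):
        path = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        assert straightness(path) == pytest.approx(np.sqrt(2.0))

    def test_coincident_endpoints_rejected(self):
        loop = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(BoundaryError, match="coincident"):
            straightness(loop)

    def test_refinement_invariance(self):
        path = np.array([[0.0, 0.0], [2.0, 1.0], [3.0, 4.0]])
        refined = [path[0]]
        for a, b in zip(path[:-1], path[1:]):
            for t in np.linspace(0, 1, 17)[1:]:
                refined.append(a + t * (b - a))
        assert straightness(np.array(refined)) == pytest.approx(
            straightness(path)
        )

    def test_rigid_motion_and_scale_invariance(self):
        path = np.array([[0.0, 0.0], [1.0, 2.0], [0.5, 4.0]])
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = 3.0 * (path @ rot.T) + np.array([5.0, -2.0])
        assert straightness(moved) == pytest.approx(straightness(path))


class TestExtractBoundary:
    def test_three_column_tissue_two_traces(self):
        left, right = extract_boundary(three_column_mesh())
        assert {left.side, right.side} == {"left", "right"}
        assert straightness(left) == pytest.approx(1.0)

    def test_all_axial_rejected(self):
        img = np.zeros((6, 6), dtype=int)
        img[:, :3], img[:, 3:] = 1, 2
        mesh = build_mesh(LabelImage(img), {1: "axial", 2: "axial"})
        with pytest.raises(BoundaryError, match="no axial"):
            extract_boundary(mesh)

    def test_trace_matches_planted_sinusoid_within_one_pixel(self, compact_params):
        p = compact_params(seed=2, boundary_amp_um=4.0)
        img, comp, truth = generate_tissue(p)
        mesh = build_mesh(img, comp)
        left, right = extract_boundary(mesh)
        for trace, planted in (
            (left, truth.boundary_left),
            (right, truth.boundary_right),
        ):
            devs = []
            for x, y in trace.vertices:
                i = np.argmin(np.abs(planted[:, 1] - y))
                devs.append(abs(planted[i, 0] - x))
            assert max(devs) <= 1.0 + 1e-9

    def test_anterior_posterior_ordering(self):
        left, right = extract_boundary(three_column_mesh())
        assert left.vertices[0, 1] < left.vertices[-1, 1]

    def test_straight_boundary_amplitude_zero(self, compact_params):
        img, comp, _ = generate_tissue(compact_params(seed=4, boundary_amp_um=0.0))
        mesh = build_mesh(img, comp)
        left, right = extract_boundary(mesh)
        assert straightness(left) == pytest.approx(1.0, abs=1e-6)
        assert straightness(right) == pytest.approx(1.0, abs=1e-6)

    def test_rasterized_ratio_matches_quadrature_of_planted_sinusoid(
        self, compact_params
    ):
        # a pixel-edge trace measures city-block length, so the oracle is
        # the L1 arc length of the planted curve sampled at pixel rows
        p = compact_params(seed=6, boundary_amp_um=5.0)
        img, comp, truth = generate_tissue(p)
        mesh = build_mesh(img, comp)
        left, _ = extract_boundary(mesh)
        planted = truth.boundary_left
        y0, y1 = left.vertices[0, 1], left.vertices[-1, 1]
        sel = (planted[:, 1] >= y0) & (planted[:, 1] <= y1)
        pl = planted[sel]
        l1 = np.abs(np.diff(pl[:, 0])).sum() + (pl[-1, 1] - pl[0, 1])
        chord = np.linalg.norm(pl[-1] - pl[0])
        assert straightness(left) == pytest.approx(l1 / chord, rel=0.03)

    def test_amplitude_monotonicity(self, compact_params):
        ratios = []
        for amp in (0.0, 3.0, 6.0):
            img, comp, _ = generate_tissue(
                compact_params(seed=11, boundary_amp_um=amp)
            )
            mesh = build_mesh(img, comp)
            left, right = extract_boundary(mesh)
            ratios.append(0.5 * (straightness(left) + straightness(right)))
        assert ratios[0] < ratios[1] < ratios[2]


class TestStraightnessSeries:
    def test_static_movie_constant_series(self, compact_params):
        tl, _ = generate_timelapse(compact_params(seed=1), t1_script=[], n_frames=3)
        series = straightness_series(tl)
        for side in ("left", "right"):
            vals = series[series["side"] == side]["straightness"]
            assert vals.nunique() == 1


class TestClassifyRows:
    def _strip(self, n_axial_cols, col_px=3):
        n = n_axial_cols + 2
        img = np.zeros((12, col_px * n), dtype=int)
        for i in range(n):
            img[:, i * col_px : (i + 1) * col_px] = i + 1
        comp = {1: "paraxial", n: "paraxial"}
        comp.update({i: "axial" for i in range(2, n)})
        return build_mesh(LabelImage(img), comp)

    def test_five_column_strip(self):
        rows = classify_rows(self._strip(5)).set_index("cell_id")
        assert list(rows.loc[[2, 3, 4, 5, 6], "row_label"]) == [
            "edge",
            "-1",
            "-2",
            "-1",
            "edge",
        ]

    def test_three_column_strip(self):
        rows = classify_rows(self._strip(3)).set_index("cell_id")
        assert list(rows.loc[[2, 3, 4], "row_label"]) == ["edge", "-1", "edge"]

    def test_two_column_strip_all_edge(self):
        rows = classify_rows(self._strip(2))
        assert (rows["row_label"] == "edge").all()

    def test_bfs_oracle_on_random_tissues(self, compact_params):
        import networkx as nx

        for seed in range(5):
            img, comp, _ = generate_tissue(compact_params(seed=seed))
            mesh = build_mesh(img, comp)
            rows = classify_rows(mesh).set_index("cell_id")
            g = nx.Graph()
            axial = {c for c, k in comp.items() if k == "axial"}
            g.add_nodes_from(axial)
            edge_cells = set()
            for iface in mesh.interfaces:
                if not iface.adjacent:
                    continue
                a, b = iface.cell_a, iface.cell_b
                if a in axial and b in axial:
                    g.add_edge(a, b)
                elif {comp[a], comp[b]} == {"axial", "paraxial"}:
                    edge_cells.add(a if a in axial else b)
            for cid in axial:
                best = min(
                    (
                        nx.shortest_path_length(g, cid, e)
                        for e in edge_cells
                        if nx.has_path(g, cid, e)
                    ),
                    default=None,
                )
                if best is None:
                    assert rows.loc[cid, "disconnected"]
                else:
                    assert rows.loc[cid, "row"] == best


class TestClassifyJunctions:
    def test_axial_paraxial_is_edge(self):
        j = classify_junctions(three_column_mesh())
        edges = j[j["junction_class"] == "Edge"]
        assert set(map(tuple, edges[["cell_a", "cell_b"]].to_numpy())) == {
            (1, 2),
            (2, 3),
        }

    def test_angle_thresholds(self):
        # vertical stripes -> axial-axial interface runs along AP (90°): T
        img = np.zeros((10, 6), dtype=int)
        img[:, :3], img[:, 3:] = 1, 2
        mesh = build_mesh(LabelImage(img), {1: "axial", 2: "axial"})
        j = classify_junctions(mesh, v_half_angle=30)
        assert list(j["junction_class"]) == ["T"]
        assert j.loc[0, "interface_angle_deg"] == pytest.approx(90.0)
        # horizontal stripes -> interface along ML (0°): V
        mesh2 = build_mesh(LabelImage(img.T.copy()), {1: "axial", 2: "axial"})
        j2 = classify_junctions(mesh2, v_half_angle=30)
        assert list(j2["junction_class"]) == ["V"]

    def test_oblique_class_exists(self, compact_params):
        img, comp, _ = generate_tissue(compact_params(seed=1, kappa=0.5))
        mesh = build_mesh(img, comp)
        j = classify_junctions(mesh)
        assert set(j["junction_class"]) <= {
            "Edge",
            "V",
            "T",
            "oblique",
            "other",
            "point",
        }

    def test_invalid_half_angle_rejected(self):
        with pytest.raises(ValueError):
            classify_junctions(three_column_mesh(), v_half_angle=50)
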