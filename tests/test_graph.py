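"""Architecture graph: construction, shape inference, parameter accounting."""

import pytest

from hierbanet import (
    ArchitectureGraph,
    LayerSpec,
    TensorShape,
    build_hierbanet,
    conv_bn_act,
    count_parameters,
    infer_shapes,
    summarize,
)
from hierbanet.golden import diff_against_golden, load_golden_summary
from hierbanet.graph import graph_from_text, graph_to_text, summary_to_csv


@pytest.fixture(scope="module")
def default_graph():
    return build_hierbanet()


def small_graph(channels=3):
    g = ArchitectureGraph(input_shape=TensorShape(8, 8, channels), num_classes=2)
    g.add(LayerSpec(name="Input", kind="input"))
    return g


class TestConvBnAct:
    def test_appends_three_layers_and_returns_activation(self):
        g = small_graph()
        out = conv_bn_act(g, "Input", "C1", 32, 3, 3)
        assert out == "C1_Act"
        assert [l.kind for l in g.layers[1:]] == ["conv", "batchnorm", "activation"]

    def test_stem_conv_param_count(self, default_graph):
        # 32 filters of 3x3x3 kernels plus one bias each
        acct = count_parameters(default_graph)
        assert acct.per_layer["Base_Conv1"] == (896, 0)

    def test_smallest_conv_has_weight_plus_bias(self):
        g = small_graph(channels=1)
        conv_bn_act(g, "Input", "C1", 1, 1, 1)
        assert count_parameters(g).per_layer["C1"] == (2, 0)

    def test_batchnorm_splits_trainable_and_running_stats(self):
        g = small_graph()
        conv_bn_act(g, "Input", "C1", 32, 3, 3)
        assert count_parameters(g).per_layer["C1_BN"] == (64, 64)

    def test_unknown_input_raises(self):
        g = small_graph()
        with pytest.raises(KeyError):
            conv_bn_act(g, "nope", "C1", 8, 3, 3)

    @pytest.mark.parametrize("filters,kh,kw", [(0, 3, 3), (8, 0, 3), (8, 3, -1)])
    def test_nonpositive_sizes_raise(self, filters, kh, kw):
        g = small_graph()
        with pytest.raises(ValueError):
            conv_bn_act(g, "Input", "C1", filters, kh, kw)


class TestBlockModules:
    """Per-block structure: diversified branches, low-level side branch."""

    @pytest.mark.parametrize(
        "layer,params",
        [
            ("B1_HL_Conv1", 2112),
            ("B1_HL_Conv2", 18496),
            ("B1_HL_Conv3", 51264),
            ("B1_HL_Conv4", 100416),
            ("B2_HL_Conv4", 1806400),
            ("B1_LL_Conv1", 18496),
            ("B2_LL_Conv1", 331840),
        ],
    )
    def test_branch_param_counts(self, default_graph, layer, params):
        assert count_parameters(default_graph).per_layer[layer][0] == params

    def test_high_level_module_emits_1280_channels_per_block(self, default_graph):
        for block in ("B1", "B2"):
            hl_convs = [
                l for l in default_graph.conv_layers() if l.name.startswith(f"{block}_HL_Conv")
            ]
            assert len(hl_convs) == 7
            assert sum(l.filters for l in hl_convs) == 1280

    def test_low_level_output_width_fixed_at_64(self, default_graph):
        shapes = infer_shapes(default_graph)
        assert shapes["B1_LL_Conv1"].channels == 64
        assert shapes["B2_LL_Conv1"].channels == 64

    def test_block_concat_shapes(self, default_graph):
        shapes = infer_shapes(default_graph)
        assert shapes["B1_Concat"].as_tuple() == (56, 56, 576)
        assert shapes["B2_Concat"].as_tuple() == (14, 14, 576)

    def test_concat_channel_conservation(self, default_graph):
        shapes = infer_shapes(default_graph)
        for l in default_graph.layers:
            if l.kind == "concat":
                assert shapes[l.name].channels == sum(shapes[i].channels for i in l.inputs)


class TestBuild:
    def test_default_layer_census(self, default_graph):
        census = default_graph.census()
        assert census == {
            "input": 1,
            "conv": 19,
            "batchnorm": 19,
            "activation": 19,
            "pool": 7,
            "concat": 4,
            "global_pool": 1,
            "dropout": 1,
            "dense": 1,
        }
        assert len(default_graph.layers) == 72

    def test_binary_head_param_count(self):
        g = build_hierbanet(num_classes=2)
        assert count_parameters(g).per_layer["Dense"][0] == 576 * 2 + 2

    @pytest.mark.parametrize("bad_classes", [0, 1, -3])
    def test_degenerate_class_count_rejected(self, bad_classes):
        with pytest.raises(ValueError):
            build_hierbanet(num_classes=bad_classes)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            build_hierbanet(input_shape=TensorShape(100, 100, 3))

    def test_invalid_block_count_rejected(self):
        with pytest.raises(ValueError):
            build_hierbanet(num_blocks=4)

    @pytest.mark.parametrize("blocks,n_conv", [(1, 10), (2, 19), (3, 28)])
    def test_ablation_variants_build(self, blocks, n_conv):
        # one trunk conv follows every block, so variants carry
        # (blocks + 1) trunk convs + 8 convs per block + no others
        g = build_hierbanet(num_blocks=blocks)
        assert len(g.conv_layers()) == n_conv
        assert f"Base_Conv{blocks + 1}" in g

    def test_param_counts_invariant_to_spatial_size(self):
        a = count_parameters(build_hierbanet(input_shape=TensorShape(224, 224, 3)))
        b = count_parameters(build_hierbanet(input_shape=TensorShape(64, 64, 3)))
        assert a.per_layer == b.per_layer
        assert a.total == b.total


class TestShapesAndAccounting:
    def test_key_output_shapes(self, default_graph):
        shapes = infer_shapes(default_graph)
        assert shapes["Base_Conv1"].as_tuple() == (224, 224, 32)
        assert shapes["Base_Conv3"].as_tuple() == (14, 14, 576)
        assert shapes["GAP"].as_tuple() == (1, 1, 576)
        assert shapes["Dense"].as_tuple() == (1, 1, 3)

    def test_pool_ceil_division_on_odd_dims(self):
        g = ArchitectureGraph(input_shape=TensorShape(5, 5, 2), num_classes=2)
        g.add(LayerSpec(name="Input", kind="input"))
        g.add(LayerSpec(name="P", kind="pool", inputs=("Input",), kernel_h=2, kernel_w=2, stride=2))
        assert infer_shapes(g)["P"].as_tuple() == (3, 3, 2)

    def test_totals(self, default_graph):
        acct = count_parameters(default_graph)
        assert (acct.total, acct.trainable, acct.non_trainable) == (14331331, 14323587, 7744)
        assert acct.total == acct.trainable + acct.non_trainable

    def test_non_trainable_is_twice_total_feature_maps(self, default_graph):
        total_maps = sum(l.filters for l in default_graph.conv_layers())
        assert count_parameters(default_graph).non_trainable == 2 * total_maps
        assert total_maps == 3872

    def test_trunk_conv_param_count(self, default_graph):
        assert count_parameters(default_graph).per_layer["Base_Conv2"][0] == 2986560


class TestSummary:
    def test_matches_embedded_golden_table(self, default_graph):
        assert diff_against_golden(summarize(default_graph)) == []

    def test_first_and_last_rows(self, default_graph):
        rows = summarize(default_graph)
        assert rows[0].name == "Base_Conv1"
        assert rows[0].param_count == 896
        assert rows[0].growth_rate == 32
        assert rows[-1].name == "Base_Conv3"
        assert rows[-1].growth_rate == 3872

    def test_growth_rate_is_cumulative_filter_sum(self, default_graph):
        rows = summarize(default_graph)
        assert [r.growth_rate for r in rows] == [
            sum(x.filters for x in rows[: i + 1]) for i in range(len(rows))
        ]
        assert all(a.growth_rate < b.growth_rate for a, b in zip(rows, rows[1:]))

    def test_branch_ordering_within_block(self, default_graph):
        names = [r.name for r in summarize(default_graph)]
        b1 = [n for n in names if n.startswith("B1_")]
        assert b1 == [f"B1_HL_Conv{i}" for i in range(1, 8)] + ["B1_LL_Conv1"]

    def test_csv_round_trip_columns(self, default_graph):
        text = summary_to_csv(summarize(default_graph))
        lines = text.strip().splitlines()
        assert lines[0] == "name,out_h,out_w,out_c,params,kernel,filters,growth"
        assert len(lines) == 20
        assert lines[1].startswith("Base_Conv1,224,224,32,896,3x3,32,32")

    def test_golden_loader_totals(self):
        golden = load_golden_summary()
        assert golden.total_params == 14331331
        assert sum(r.filters for r in golden.rows) == golden.total_feature_maps


class TestTextSerialization:
    def test_round_trip_preserves_structure(self, default_graph):
        text = graph_to_text(default_graph)
        g2 = graph_from_text(text)
        assert [l.name for l in g2.layers] == [l.name for l in default_graph.layers]
        assert g2.layers == default_graph.layers
        assert count_parameters(g2).total == count_parameters(default_graph).total
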