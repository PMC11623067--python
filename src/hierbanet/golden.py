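"""Embedded golden model summary of the published default architecture.

Used by ``summary --check`` (and the tests) to verify that the graph builder
reproduces the published per-layer shapes, parameter counts and feature-map
growth exactly, with no network access.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .graph import LayerSummary, TensorShape

_GOLDEN_FILE = "table3_golden.csv"


@dataclass(frozen=True)
class GoldenSummary:
    rows: tuple[LayerSummary, ...]
    total_params: int
    trainable_params: int
    non_trainable_params: int
    total_feature_maps: int


def load_golden_summary() -> GoldenSummary:
    text = resources.files(__package__).joinpath(_GOLDEN_FILE).read_text()
    rows: list[LayerSummary] = []
    totals: dict[str, int] = {}
    reader = csv.reader(text.splitlines())
    header = next(reader)
    assert header[0] == "name"
    for rec in reader:
        if not rec:
            continue
        if rec[0].startswith("#"):
            totals[rec[0].lstrip("# ")] = int(rec[1])
            continue
        name, h, w, c, params, kernel, filters, growth = rec
        rows.append(
            LayerSummary(
                name=name,
                output_shape=TensorShape(int(h), int(w), int(c)),
                param_count=int(params),
                kernel=kernel,
                filters=int(filters),
                growth_rate=int(growth),
            )
        )
    return GoldenSummary(
        rows=tuple(rows),
        total_params=totals["total_params"],
        trainable_params=totals["trainable_params"],
        non_trainable_params=totals["non_trainable_params"],
        total_feature_maps=totals["total_feature_maps"],
    )


def diff_against_golden(rows: list[LayerSummary]) -> list[str]:
    """Per-row differences between a computed summary and the golden table.

    Returns an empty list when the summary matches exactly.
    """
    golden = load_golden_summary()
    diffs: list[str] = []
    if len(rows) != len(golden.rows):
        diffs.append(f"row count: computed {len(rows)} vs golden {len(golden.rows)}")
    for got, want in zip(rows, golden.rows):
        if got != want:
            diffs.append(f"{want.name}: computed {got} vs golden {want}")
    return diffs
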