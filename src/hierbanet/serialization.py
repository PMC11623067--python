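"""HDF5 checkpoint format: one group per layer, one dataset per array.

Root attributes record the architecture hyper-parameters so a checkpoint is
self-describing and the matching graph can be rebuilt on load.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .graph import ArchitectureGraph, TensorShape, build_hierbanet
from .nn import Params, check_params


def save_weights(path: str | Path, graph: ArchitectureGraph, params: Params) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["input_height"] = graph.input_shape.height
        f.attrs["input_width"] = graph.input_shape.width
        f.attrs["input_channels"] = graph.input_shape.channels
        f.attrs["num_classes"] = graph.num_classes
        f.attrs["num_blocks"] = graph.num_blocks
        f.attrs["base_width"] = graph.base_width
        for lname, arrays in params.items():
            grp = f.create_group(lname)
            for aname, arr in arrays.items():
                grp.create_dataset(aname, data=np.asarray(arr, dtype=np.float64))


def load_weights(path: str | Path) -> tuple[ArchitectureGraph, Params]:
    """Rebuild the graph recorded in the checkpoint and load its parameters.

    Raises ValueError naming the first shape-incompatible layer.
    """
    with h5py.File(path, "r") as f:
        graph = build_hierbanet(
            input_shape=TensorShape(
                int(f.attrs["input_height"]),
                int(f.attrs["input_width"]),
                int(f.attrs["input_channels"]),
            ),
            num_classes=int(f.attrs["num_classes"]),
            num_blocks=int(f.attrs["num_blocks"]),
            base_width=int(f.attrs["base_width"]),
        )
        params: Params = {}
        for lname, grp in f.items():
            params[lname] = {aname: np.asarray(ds[()], dtype=np.float64) for aname, ds in grp.items()}
    check_params(graph, params)
    return graph, params
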