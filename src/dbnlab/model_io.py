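"""HDF5 persistence for trained stacks.

Layout (flat, deterministic): root attributes ``format_version``,
``n_layers``, ``architecture`` and an optional ``config`` JSON string;
per layer, datasets ``layer_{i}_W``, ``layer_{i}_b_vis``,
``layer_{i}_b_hid`` and an attribute ``layer_{i}_use_biases``. Datasets
are written with time-tracking disabled so that saving the same model
twice produces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np

from .dbn import DBN
from .rbm import RBMParams

__all__ = ["save_model", "load_model", "FORMAT_VERSION"]

FORMAT_VERSION = 1


def save_model(
    dbn: DBN, path: Union[str, Path], config: Optional[dict] = None
) -> None:
    """Write a DBN to an HDF5 file, lossless at stored precision."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "dbnlab-model"
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["n_layers"] = dbn.n_layers
        f.attrs["architecture"] = np.asarray(dbn.architecture, dtype=np.int64)
        if config is not None:
            f.attrs["config"] = json.dumps(config, sort_keys=True)
        for i, layer in enumerate(dbn.layers):
            for name, arr in (
                ("W", layer.W),
                ("b_vis", layer.b_vis),
                ("b_hid", layer.b_hid),
            ):
                f.create_dataset(f"layer_{i}_{name}", data=arr, track_times=False)
            f.attrs[f"layer_{i}_use_biases"] = bool(layer.use_biases)


def load_model(path: Union[str, Path]) -> tuple[DBN, Optional[dict]]:
    """Read a DBN back; returns (model, config dict or None).

    A file that is not a dbnlab model, has an unsupported format version,
    or is truncated raises a ValueError rather than crashing.
    """
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "dbnlab-model":
                raise ValueError(f"{path}: not a dbnlab model file")
            version = int(f.attrs.get("format_version", -1))
            if version != FORMAT_VERSION:
                raise ValueError(
                    f"{path}: unsupported model format version {version} "
                    f"(this build reads version {FORMAT_VERSION})"
                )
            n_layers = int(f.attrs["n_layers"])
            layers = []
            for i in range(n_layers):
                layers.append(
                    RBMParams(
                        W=f[f"layer_{i}_W"][...],
                        b_vis=f[f"layer_{i}_b_vis"][...],
                        b_hid=f[f"layer_{i}_b_hid"][...],
                        use_biases=bool(f.attrs[f"layer_{i}_use_biases"]),
                    )
                )
            config = None
            if "config" in f.attrs:
                config = json.loads(f.attrs["config"])
    except (OSError, KeyError) as exc:
        raise ValueError(f"{path}: unreadable or truncated model file ({exc})") from exc
    return DBN(layers), config
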