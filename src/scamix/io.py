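"""Plain-text output of extracted component sets and run manifests.

Each of the four labelled component sets is written as one TSV (rows =
samples, columns = features, with sample_id and label columns), accompanied
by a ``manifest.json`` recording dimensions and the extraction parameters
(M, delta_theta, lambda multiplier, reference policy) so a directory of
outputs is self-describing.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, read_expression_matrix
from .decompose import ComponentFeatureSets
from .errors import DimensionError, ScamixError

__all__ = ["write_component_sets", "read_component_set"]


def write_component_sets(feature_sets: ComponentFeatureSets, out_dir,
                         feature_ids=None) -> dict:
    """Write one TSV per component set plus a JSON manifest; returns the manifest."""
    if not feature_sets.sets:
        raise ScamixError("no components extracted")
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"params": feature_sets.params, "sets": {}}
    n = len(feature_sets.labels)
    for name, mat in feature_sets.sets.items():
        mat = np.asarray(mat)
        if mat.size == 0:
            raise ScamixError(f"no components extracted for set {name!r}")
        if mat.ndim != 2 or mat.shape[0] != n:
            raise DimensionError(
                f"set {name!r}: expected {n} rows, got shape {mat.shape}")
        cols = feature_ids if feature_ids is not None else \
            [f"f{j}" for j in range(mat.shape[1])]
        if len(cols) != mat.shape[1]:
            raise DimensionError(
                f"set {name!r}: {len(cols)} feature ids for {mat.shape[1]} columns")
        frame = pd.DataFrame(mat, columns=cols,
                             index=pd.Index(feature_sets.sample_ids,
                                            name="sample_id"))
        frame.insert(0, "label", feature_sets.labels)
        path = os.path.join(out_dir, f"{name}.tsv")
        frame.to_csv(path, sep="\t")
        manifest["sets"][name] = {"file": f"{name}.tsv",
                                  "n_samples": int(mat.shape[0]),
                                  "n_features": int(mat.shape[1])}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def read_component_set(path) -> ExpressionDataset:
    """Read one component-set TSV back as a labelled dataset (round-trip)."""
    return read_expression_matrix(path, label_column_or_file="label")
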