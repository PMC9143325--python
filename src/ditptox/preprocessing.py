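"""Descriptor streamlining and min-max normalization, fit on training data.

Continuous descriptor blocks are filtered in a fixed order — (1) features
with non-finite or extreme entries, (2) zero-variance features, (3) the
later member of every feature pair with |Pearson r| above the threshold —
and the survivors' training minima/maxima are recorded so that every block
(training, CV folds, external) is mapped through

    x* = (x - min) / (max - min)

with the *training* extremes. External values outside the training range
are clipped to [0, 1] and counted. Binary fingerprint bits pass through
untouched by default; the streamlining exists to simplify descriptor data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .featurization import FeatureBlock

__all__ = ["PreprocessState", "PreprocessError", "fit_preprocessor", "apply_preprocessor"]


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessState:
    """Kept features and their training min/max, per source block."""

    source_block: str
    kept_features: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    passthrough_features: list[str] = field(default_factory=list)
    dropped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if not (self.mins < self.maxs).all():
            raise PreprocessError("every kept feature needs min < max")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "source_block": self.source_block,
                    "kept_features": self.kept_features,
                    "mins": self.mins.tolist(),
                    "maxs": self.maxs.tolist(),
                    "passthrough_features": self.passthrough_features,
                    "dropped": self.dropped,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "PreprocessState":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["source_block"],
            d["kept_features"],
            np.array(d["mins"]),
            np.array(d["maxs"]),
            d.get("passthrough_features", []),
            d.get("dropped", {}),
        )


def fit_preprocessor(
    block: FeatureBlock,
    corr_threshold: float = 0.95,
    extreme_limit: float = 1e8,
    drop_constant_bits: bool = False,
) -> PreprocessState:
    """Fit the streamlining filters and normalization on training rows only.

    Only continuous columns are filtered and normalized; binary columns are
    recorded as pass-through (optionally dropped when zero-variance, via
    ``drop_constant_bits``). Correlated pairs are resolved greedily in
    column order: a column is dropped iff it correlates above the threshold
    with an *earlier* surviving column, which makes runs reproducible.
    """
    cont = [i for i, k in enumerate(block.column_kinds) if k == "continuous"]
    binary = [i for i, k in enumerate(block.column_kinds) if k != "continuous"]
    names = block.feature_names
    matrix = block.matrix

    dropped: dict[str, list[str]] = {"extreme": [], "constant": [], "correlated": []}

    passthrough = []
    for i in binary:
        if drop_constant_bits and matrix[:, i].std() == 0:
            dropped["constant"].append(names[i])
        else:
            passthrough.append(names[i])

    # (1) non-finite / extreme values
    stage1 = []
    for i in cont:
        col = matrix[:, i]
        if (~np.isfinite(col)).any() or (np.abs(col) > extreme_limit).any():
            dropped["extreme"].append(names[i])
        else:
            stage1.append(i)

    # (2) zero variance
    stage2 = []
    for i in stage1:
        if np.ptp(matrix[:, i]) == 0:
            dropped["constant"].append(names[i])
        else:
            stage2.append(i)

    # (3) greedy pairwise correlation scan in column order
    kept: list[int] = []
    if stage2:
        sub = matrix[:, stage2]
        corr = np.corrcoef(sub, rowvar=False)
        corr = np.atleast_2d(corr)
        kept_pos: list[int] = []
        for j in range(len(stage2)):
            if any(abs(corr[j, k]) > corr_threshold for k in kept_pos):
                dropped["correlated"].append(names[stage2[j]])
            else:
                kept_pos.append(j)
        kept = [stage2[j] for j in kept_pos]

    if cont and not kept:
        raise PreprocessError("all continuous features were removed by filtering")

    kept_names = [names[i] for i in kept]
    mins = matrix[:, kept].min(axis=0) if kept else np.empty(0)
    maxs = matrix[:, kept].max(axis=0) if kept else np.empty(0)
    return PreprocessState(
        source_block=block.name,
        kept_features=kept_names,
        mins=mins,
        maxs=maxs,
        passthrough_features=passthrough,
        dropped=dropped,
    )


def apply_preprocessor(state: PreprocessState, block: FeatureBlock) -> FeatureBlock:
    """Normalize a block with the fitted training extremes.

    Kept continuous features map through (x - min)/(max - min) and clip to
    [0, 1]; the number of clipped cells is reported in
    ``result.meta['n_clipped']``. Pass-through (binary) columns are copied
    unchanged. Raises if the block lacks any kept feature.
    """
    index = {f: i for i, f in enumerate(block.feature_names)}
    missing = [f for f in state.kept_features + state.passthrough_features
               if f not in index]
    if missing:
        raise PreprocessError(
            f"block {block.name!r} is missing preprocessed feature(s) "
            f"{missing[:5]}"
        )

    out_names = state.passthrough_features + state.kept_features
    cols = []
    kinds = []
    for f in state.passthrough_features:
        cols.append(block.matrix[:, index[f]])
        kinds.append("binary")
    n_clipped = 0
    for j, f in enumerate(state.kept_features):
        x = block.matrix[:, index[f]]
        z = (x - state.mins[j]) / (state.maxs[j] - state.mins[j])
        n_clipped += int(((z < 0) | (z > 1)).sum())
        cols.append(np.clip(z, 0.0, 1.0))
        kinds.append("continuous")
    matrix = np.column_stack(cols) if cols else np.empty((block.n_molecules, 0))
    kind = "binary" if all(k == "binary" for k in kinds) else (
        "continuous" if all(k == "continuous" for k in kinds) else "mixed"
    )
    result = FeatureBlock(
        block.name, kind, matrix, out_names, list(block.row_ids),
        column_kinds=kinds,
    )
    result.meta["n_clipped"] = n_clipped
    return result
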