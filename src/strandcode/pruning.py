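"""Magnitude-based pruning mathematics over named weight arrays.

Implements the mask/threshold arithmetic of one-shot global pruning,
iterative global unstructured pruning, and per-layer structured column
pruning, on abstract 2-D weight arrays (stand-ins for LSTM/linear weight
matrices).  Fine-tuning between pruning rounds is a callback contract:
the callback receives the masked layers and may update surviving weight
values but must not touch masks; the package ships an identity callback
and a toy least-squares refit as examples.

Iterating at a per-round fraction p yields overall sparsity
``1 - (1 - p)**n`` after n rounds; at the default p = 0.5 this is
(1 - 0.5**n) x 100%, i.e. 99.6% at n = 8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LayerWeights",
    "ScheduleStep",
    "global_threshold",
    "one_shot_prune",
    "iterative_prune",
    "structured_prune_columns",
    "sparsity",
    "layer_param_counts",
    "recurrent_block_shapes",
    "identity_finetune",
    "save_layers",
    "load_layers",
]


@dataclass
class LayerWeights:
    """One named weight matrix with its pruning mask (True = pruned)."""

    name: str
    values: np.ndarray
    prunable: bool = True
    mask: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"layer {self.name!r}: values must be 2-D")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError(f"layer {self.name!r}: mask shape mismatch")

    def effective(self) -> np.ndarray:
        """Weight matrix with pruned entries zeroed."""
        return np.where(self.mask, 0.0, self.values)


def identity_finetune(layers) -> None:
    """No-op fine-tuning callback (weights left as they are)."""


def _pooled_magnitudes(layers):
    mags = [
        np.abs(l.values[~l.mask]).ravel() for l in layers if l.prunable
    ]
    if not mags or sum(m.size for m in mags) == 0:
        raise ValueError("no prunable unmasked weights")
    return np.concatenate(mags)


def global_threshold(layers, x: float) -> float:
    """Magnitude threshold lambda such that fraction ``x`` of the pooled,
    currently-unmasked prunable weights lie below it.

    Computed as the k-th smallest pooled magnitude with ``k = round(x * N)``
    (the x-quantile of the discrete magnitude distribution); masking all
    ``|w| < lambda`` plus ties up to k removes as close to x of the weights
    as the discrete distribution allows.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"target fraction x={x} outside [0, 1]")
    mags = np.sort(_pooled_magnitudes(layers))
    k = int(round(x * mags.size))
    if k <= 0:
        return 0.0
    if k >= mags.size:
        return float(mags[-1]) + 1.0  # above the maximum: everything prunes
    return float(mags[k - 1])


def _apply_global_mask(layers, x: float) -> float:
    """Mask the ``round(x * N)`` smallest-magnitude unmasked weights globally.

    Strictly-below-lambda weights prune first; ties at lambda are broken by
    lowest flat index (layer order, then row-major position) until the
    target count is reached.  Returns lambda.
    """
    lam = global_threshold(layers, x)
    N = _pooled_magnitudes(layers).size
    k = int(round(x * N))
    remaining = k
    # pass 1: strict inequality
    for layer in layers:
        if not layer.prunable:
            continue
        strict = (~layer.mask) & (np.abs(layer.values) < lam)
        layer.mask |= strict
        remaining -= int(strict.sum())
    # pass 2: ties at lambda, lowest flat index first
    for layer in layers:
        if remaining <= 0:
            break
        if not layer.prunable:
            continue
        tied = np.flatnonzero((~layer.mask.ravel()) & (np.abs(layer.values.ravel()) == lam))
        take = tied[:remaining]
        flat = layer.mask.ravel()
        flat[take] = True
        layer.mask = flat.reshape(layer.values.shape)
        remaining -= take.size
    return lam


def one_shot_prune(layers, x: float, finetune=identity_finetune) -> float:
    """Single global pruning round to target sparsity ``x``, then fine-tune.

    Returns the threshold lambda used.  Non-prunable layers are untouched.
    """
    lam = _apply_global_mask(layers, x)
    finetune(layers)
    return lam


@dataclass(frozen=True)
class ScheduleStep:
    iteration: int
    threshold: float
    overall_sparsity: float
    per_layer_sparsity: dict = field(default_factory=dict)


def iterative_prune(layers, n: int, p: float = 0.5, finetune=identity_finetune):
    """``n`` rounds of global pruning, each removing fraction ``p`` of the
    weights still unmasked, with fine-tuning after every round.

    After round i the overall sparsity of prunable weights is
    ``1 - (1 - p)**i`` up to discreteness.  Returns the schedule trace.
    """
    if n < 1:
        raise ValueError("need at least one iteration")
    if not 0.0 < p < 1.0:
        raise ValueError("per-round fraction p must lie in (0, 1)")
    trace = []
    for i in range(1, n + 1):
        lam = _apply_global_mask(layers, p)
        finetune(layers)
        overall, per_layer = sparsity(layers)
        trace.append(ScheduleStep(i, lam, overall, per_layer))
    return trace


def structured_prune_columns(layer: LayerWeights, x: float) -> np.ndarray:
    """Mask the ``floor(x * cols)`` columns of lowest L1 norm (per layer).

    Column L1 norm is the sum of absolute entries; ties are broken by the
    lowest column index.  Returns the updated mask.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"target fraction x={x} outside [0, 1]")
    if layer.values.ndim != 2:
        raise ValueError("structured pruning needs a 2-D layer")
    cols = layer.values.shape[1]
    n_prune = int(np.floor(x * cols))
    if n_prune == 0:
        return layer.mask
    norms = np.abs(layer.values).sum(axis=0)
    order = np.argsort(norms, kind="stable")  # stable: ties -> lowest index
    layer.mask[:, order[:n_prune]] = True
    return layer.mask


def sparsity(layers):
    """Fraction of prunable weights masked, pooled and per layer."""
    total = 0
    masked = 0
    per_layer = {}
    for layer in layers:
        if not layer.prunable:
            continue
        t = layer.values.size
        m = int(layer.mask.sum())
        per_layer[layer.name] = m / t if t else 0.0
        total += t
        masked += m
    overall = masked / total if total else 0.0
    return overall, per_layer


def layer_param_counts(kind: str, **dims) -> int:
    """Parameter count for one layer of a basecaller-style network.

    ``recurrent`` (LSTM): input size I, hidden size H, four gate blocks
    each with an input-weight block (H x I), a recurrent block (H x H) and
    two bias vectors, so ``4 * (I*H + H*H + 2*H)`` -- e.g. I = H = 768
    gives 4,724,736, with a stacked input-weight block of shape
    (4*768 x 768) = (3072 x 768).  ``affine``: ``I*O + O``.
    """
    if kind == "recurrent":
        I, H = int(dims["input_size"]), int(dims["hidden_size"])
        return 4 * (I * H + H * H + 2 * H)
    if kind == "affine":
        I, O = int(dims["input_size"]), int(dims["output_size"])
        return I * O + O
    raise ValueError(f"unknown layer kind {kind!r}; expected 'recurrent' or 'affine'")


def recurrent_block_shapes(input_size: int, hidden_size: int):
    """Stacked weight-block shapes of a recurrent (LSTM) layer.

    The four gate blocks stack into an input-weight matrix of shape
    ``(4*H, I)`` and a recurrent matrix of shape ``(4*H, H)``; for
    I = H = 768 the input block is (3072, 768).
    """
    return {
        "input": (4 * hidden_size, input_size),
        "recurrent": (4 * hidden_size, hidden_size),
    }


def save_layers(layers, directory) -> None:
    """Write layers as whitespace-delimited text matrices plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for layer in layers:
        np.savetxt(directory / f"{layer.name}.values.txt", layer.values)
        np.savetxt(directory / f"{layer.name}.mask.txt", layer.mask.astype(int), fmt="%d")
        manifest.append({"name": layer.name, "prunable": layer.prunable,
                         "shape": list(layer.values.shape)})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_layers(directory):
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    layers = []
    for entry in manifest:
        values = np.loadtxt(directory / f"{entry['name']}.values.txt").reshape(entry["shape"])
        mask = np.loadtxt(directory / f"{entry['name']}.mask.txt").reshape(entry["shape"])
        layers.append(LayerWeights(entry["name"], values, entry["prunable"], mask.astype(bool)))
    return layers
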