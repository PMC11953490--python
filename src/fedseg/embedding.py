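"""Parameter-free site embedding F(.) of the bridge representation R(x).

The embedding concatenates a channel-wise spatial average pool with a
channel-wise spatial max pool (in that fixed order), giving a vector of
length 2C for a C-channel representation. An element-wise ``sum`` fusion
(length C) is available as an option; both add no learned parameters.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, concat, spatial_max

__all__ = ["site_embedding", "site_embedding_graph"]


def site_embedding(representation: np.ndarray, fusion: str = "concat") -> np.ndarray:
    """Pool a representation to the site-embedding vector xi.

    ``representation`` is (C, H, W) for a single sample (returns a vector) or
    (N, C, H, W) for a batch (returns one row per sample).
    """
    r = np.asarray(representation)
    if r.ndim == 3:
        return site_embedding(r[None], fusion=fusion)[0]
    if r.ndim != 4:
        raise ValueError("representation must be (C, H, W) or (N, C, H, W)")
    if r.shape[2] < 1 or r.shape[3] < 1:
        raise ValueError("empty spatial extent")
    # Spatial positions form an unordered set: summing in sorted order makes
    # the average pool exactly independent of any spatial permutation.
    flat = np.ascontiguousarray(
        np.sort(r.reshape(r.shape[0], r.shape[1], -1), axis=-1)
    )
    avg = flat.sum(axis=-1) / flat.shape[-1]
    mx = flat[..., -1]
    if fusion == "concat":
        return np.concatenate([avg, mx], axis=1)
    if fusion == "sum":
        return avg + mx
    raise ValueError("fusion must be 'concat' or 'sum'")


def site_embedding_graph(representation: Tensor, fusion: str = "concat") -> Tensor:
    """Differentiable site embedding of a batched (N, C, H, W) tensor."""
    avg = representation.mean(axis=(2, 3))
    mx = spatial_max(representation)
    if fusion == "concat":
        return concat([avg, mx], axis=1)
    if fusion == "sum":
        return avg + mx
    raise ValueError("fusion must be 'concat' or 'sum'")
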