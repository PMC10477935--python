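"""Closed-form random-walk similarity matrix (NetMF).

DeepWalk-style random-walk embeddings implicitly factorize a dense pointwise
mutual information matrix. Its closed-form estimate for a window of size T is

    R = (vol(G) / T) * (sum_{i=1..T} (D^-1 A)^i) * D^-1
    M = truncated elementwise log(R / b)

where D is the degree matrix, vol(G) the sum of degrees and b the negative
sampling parameter. M[i, j] weights the paths of length <= T joining i and j,
so using its rows as autoencoder inputs exposes longer-range topology than
adjacency rows do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph_io import Network

__all__ = ["NetMFMatrix", "netmf_matrix"]


@dataclass
class NetMFMatrix:
    """Dense truncated-log random-walk matrix with its parameters.

    ``values[i, j] == 0`` either structurally (no path of length <= window)
    or because the raw entry fell below the negative-sampling threshold b.
    """

    values: np.ndarray
    window: int
    negative: float
    vertex_ids: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def scaled01(self) -> np.ndarray:
        """Min-max scaled copy in [0, 1], used as cross-entropy targets."""
        mx = self.values.max()
        if mx <= 0:
            return np.zeros_like(self.values)
        return self.values / mx


def netmf_matrix(net: Network, window: int = 10, negative: float = 1.0) -> NetMFMatrix:
    """Compute the truncated-log NetMF matrix of a preprocessed network.

    Parameters
    ----------
    net : Network
        Preprocessed network; every vertex must have degree >= 1.
    window : int
        Context window T >= 1 (number of random-walk powers summed).
    negative : float
        Negative sampling parameter b > 0.

    Notes
    -----
    The elementwise log is undefined at 0 and negative for small entries;
    entries are mapped with ``max(log(r / b), 0)``, keeping structural zeros
    at exactly 0 so the sparsity pattern of reachability-within-T survives.
    """
    if window < 1:
        raise ValueError("window T must be >= 1")
    if negative <= 0:
        raise ValueError("negative sampling parameter b must be > 0")
    deg = net.degrees.astype(np.float64)
    if (deg == 0).any():
        raise ValueError("netmf_matrix requires all degrees >= 1 (preprocess first)")

    inv_d = 1.0 / deg
    A = net.adjacency.tocsr()
    P = sp.diags(inv_d) @ A  # row-stochastic transition matrix

    power = np.eye(net.n)
    acc = np.zeros((net.n, net.n))
    Pd = P.toarray()
    for _ in range(window):
        power = power @ Pd
        acc += power

    R = (net.volume / window) * acc * inv_d[np.newaxis, :]
    M = np.zeros_like(R)
    pos = R > 0
    M[pos] = np.maximum(np.log(R[pos] / negative), 0.0)
    return NetMFMatrix(values=M, window=int(window), negative=float(negative),
                       vertex_ids=list(net.vertex_ids))


def save_cache(m: NetMFMatrix, net: Network, path: str) -> None:
    """Persist M keyed by (network hash, T, b) for reuse across runs."""
    np.savez_compressed(
        path,
        values=m.values,
        window=m.window,
        negative=m.negative,
        key=np.array([net.content_hash()]),
        vertex_ids=np.array(m.vertex_ids),
    )


def load_cache(path: str, net: Network, window: int, negative: float):
    """Load a cached M if it matches the network and parameters, else None."""
    import os

    if not os.path.exists(path):
        return None
    with np.load(path, allow_pickle=False) as z:
        if (
            str(z["key"][0]) != net.content_hash()
            or int(z["window"]) != int(window)
            or float(z["negative"]) != float(negative)
        ):
            return None
        return NetMFMatrix(
            values=z["values"],
            window=int(z["window"]),
            negative=float(z["negative"]),
            vertex_ids=[str(v) for v in z["vertex_ids"]],
        )
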