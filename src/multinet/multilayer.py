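"""Multilayer network assembly and modularity maximization.

The quality function being maximized is the multislice modularity

    Q = (1/2mu) * sum_{ijlr} [ (A_ijl - gamma_l * M_ijl) * delta_lr
                               + delta_ij * omega_jlr ] * delta(g_il, g_jr)

where ``A_ijl`` is the similarity between subjects i and j in layer l,
``M_ijl = k_il * k_jl / (2 m_l)`` the per-layer configuration (Newman-Girvan)
null, ``gamma_l`` the per-layer resolution, ``omega_jlr`` the interlayer
coupling tying subject j's copies together, and ``2 mu`` the total edge
weight (intra-layer strengths plus interlayer couplings).  Optimization is a
generalized Louvain: greedy node moves on the supra-modularity matrix B,
community aggregation, and an outer iteration restarting from the flattened
partition until Q stops improving.

Weights may be signed: the move gains are computed on B directly, so no
separate signed null model is introduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort_io import CohortError
from .similarity import SimilarityLayer

__all__ = [
    "MultilayerNetwork",
    "Partition",
    "newman_girvan_null",
    "signed_configuration_null",
    "assemble_multilayer",
    "supra_modularity",
    "modularity_q",
    "louvain_sweep",
    "genlouvain",
    "consensus_node_labels",
]


@dataclass
class MultilayerNetwork:
    """Ordered layers with adjacency, null model, resolutions and coupling.

    Node-layers are indexed ``s = l * n + i`` (layer-major) throughout.
    """

    layer_ids: list[str]
    subject_ids: list[str]
    A: list[np.ndarray]
    M: list[np.ndarray]
    gamma: list[float]
    omega: float
    coupling: str
    two_mu: float

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_layers(self) -> int:
        return len(self.layer_ids)


@dataclass
class Partition:
    """Community assignment ``g[i, l]`` for every (subject, layer) node."""

    subject_ids: list[str]
    layer_ids: list[str]
    g: np.ndarray  # (n_subjects, n_layers) int
    q: float

    @property
    def n_communities(self) -> int:
        return int(self.g.max()) + 1


def newman_girvan_null(layer: SimilarityLayer | np.ndarray) -> np.ndarray:
    """Configuration-model expected weights ``M_ij = k_i k_j / 2m`` for one layer."""
    W = layer.weights if isinstance(layer, SimilarityLayer) else np.asarray(layer, float)
    k = W.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise CohortError("layer total weight is zero; null model undefined")
    return np.outer(k, k) / two_m


def signed_configuration_null(layer: SimilarityLayer | np.ndarray) -> np.ndarray:
    """Configuration null for signed layers: positive and negative parts get
    separate strength-preserving nulls,

        M = k+ k+^T / 2m+  -  k- k-^T / 2m-.

    For a nonnegative layer this is exactly the Newman-Girvan null.  It
    stays bounded when positive and negative weights nearly cancel, where
    ``k k^T / 2m`` blows up (a real hazard for correlation layers built from
    very few features).  Row sums still equal the signed node strengths.
    """
    W = layer.weights if isinstance(layer, SimilarityLayer) else np.asarray(layer, float)
    Wp = np.clip(W, 0.0, None)
    Wn = np.clip(-W, 0.0, None)
    M = np.zeros_like(W)
    two_mp = Wp.sum()
    two_mn = Wn.sum()
    if two_mp == 0 and two_mn == 0:
        raise CohortError("layer total weight is zero; null model undefined")
    if two_mp > 0:
        kp = Wp.sum(axis=1)
        M += np.outer(kp, kp) / two_mp
    if two_mn > 0:
        kn = Wn.sum(axis=1)
        M -= np.outer(kn, kn) / two_mn
    return M


def assemble_multilayer(
    layers: list[SimilarityLayer],
    gamma: list[float] | float = 1.0,
    omega: float = 1.0,
    coupling: str = "categorical",
    null_model: str = "signed_configuration",
) -> MultilayerNetwork:
    """Stack similarity layers into one multilayer network.

    ``categorical`` coupling links each subject to its own copy in every
    other layer with uniform weight omega (modalities are unordered);
    ``ordinal`` links consecutive layers only.  ``2 mu`` accumulates all
    intra-layer strengths plus every coupling counted from both endpoints.

    The per-layer null is the configuration model; the default
    ``signed_configuration`` handles positive and negative weights
    separately and coincides with ``newman_girvan`` on nonnegative layers.
    """
    if not layers:
        raise CohortError("need at least one layer")
    sids = layers[0].subject_ids
    for l in layers[1:]:
        if l.subject_ids != sids:
            raise CohortError(
                f"layer {l.modality_id} has mismatched subjects vs {layers[0].modality_id}"
            )
    L = len(layers)
    if isinstance(gamma, (int, float)):
        gamma = [float(gamma)] * L
    if len(gamma) != L:
        raise CohortError("need one gamma per layer")
    if omega < 0:
        raise CohortError("omega must be non-negative")
    if coupling not in ("categorical", "ordinal"):
        raise CohortError(f"unknown coupling topology {coupling!r}")

    if null_model == "signed_configuration":
        null_fn = signed_configuration_null
    elif null_model == "newman_girvan":
        null_fn = newman_girvan_null
    else:
        raise CohortError(f"unknown null model {null_model!r}")
    A = [l.weights.copy() for l in layers]
    M = [null_fn(l) for l in layers]
    n = len(sids)
    # total intra-layer strength; absolute values so signed layers cannot
    # drive 2*mu to zero (reduces to the plain sum for nonnegative layers)
    intra = float(sum(np.abs(a).sum() for a in A))
    if coupling == "categorical":
        n_couplings_directed = n * L * (L - 1)
    else:
        n_couplings_directed = n * 2 * (L - 1)
    two_mu = intra + omega * n_couplings_directed
    if two_mu <= 0:
        raise CohortError("total edge weight 2*mu must be positive")
    return MultilayerNetwork(
        layer_ids=[l.modality_id for l in layers],
        subject_ids=list(sids),
        A=A,
        M=M,
        gamma=[float(g) for g in gamma],
        omega=float(omega),
        coupling=coupling,
        two_mu=two_mu,
    )


def supra_modularity(net: MultilayerNetwork) -> np.ndarray:
    """Dense supra-modularity matrix B over node-layers (layer-major order).

    Diagonal blocks are ``A_l - gamma_l * M_l`` (including the null's
    diagonal); off-diagonal blocks are ``omega * I`` on coupled layer pairs.
    """
    n, L = net.n_subjects, net.n_layers
    B = np.zeros((n * L, n * L))
    for l in range(L):
        sl = slice(l * n, (l + 1) * n)
        B[sl, sl] = net.A[l] - net.gamma[l] * net.M[l]
    if net.omega != 0:
        eye = net.omega * np.eye(n)
        for l in range(L):
            for r in range(L):
                if l == r:
                    continue
                if net.coupling == "ordinal" and abs(l - r) != 1:
                    continue
                B[l * n : (l + 1) * n, r * n : (r + 1) * n] += eye
    return B


def _flat(g: np.ndarray) -> np.ndarray:
    """(n, L) assignment -> layer-major flat vector matching supra order."""
    return np.asarray(g, dtype=int).T.reshape(-1)


def _unflat(comm: np.ndarray, n: int, L: int) -> np.ndarray:
    return comm.reshape(L, n).T


def modularity_q(net: MultilayerNetwork, part: Partition | np.ndarray) -> float:
    """Evaluate Q for a partition via the supra-matrix quadratic form.

    Equivalent to the explicit quadruple sum over (i, j, l, r); the
    equivalence is exercised against a brute-force oracle in the test suite.
    """
    g = part.g if isinstance(part, Partition) else np.asarray(part, int)
    if g.shape != (net.n_subjects, net.n_layers):
        raise CohortError("partition shape does not match network")
    B = supra_modularity(net)
    return _q_from_supra(B, _flat(g), net.two_mu)


def _q_from_supra(B: np.ndarray, comm: np.ndarray, two_mu: float) -> float:
    total = 0.0
    for c in np.unique(comm):
        idx = np.where(comm == c)[0]
        total += B[np.ix_(idx, idx)].sum()
    return float(total / two_mu)


def _compact(comm: np.ndarray) -> np.ndarray:
    """Relabel communities to 0..K-1 by order of first appearance."""
    _, first, inv = np.unique(comm, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(first))
    return order[inv]


def _sweep_inplace(B: np.ndarray, comm: np.ndarray, rng, move_tol: float) -> bool:
    """Greedy phase-1 passes: move each node to the community with maximal
    positive gain until a full pass makes no move.  Returns whether any move
    happened.  Ties keep the current community; otherwise the lowest
    community id wins (argmax on exact floats picks the lowest index).
    """
    n = B.shape[0]
    any_move = False
    while True:
        moved = False
        ncomm = int(comm.max()) + 1
        for s in rng.permutation(n):
            row = B[s]
            cs = comm[s]
            gains = np.bincount(comm, weights=row, minlength=ncomm)
            gains[cs] -= row[s]  # exclude the self term from "staying" gain
            best = int(np.argmax(gains))
            if best != cs and gains[best] > gains[cs] + move_tol:
                comm[s] = best
                moved = True
                any_move = True
            elif gains[cs] < -move_tol and gains[best] <= move_tol:
                # with signed weights a node may be net-repelled by every
                # community: isolate it (gain 0 beats staying)
                comm[s] = ncomm
                ncomm += 1
                moved = True
                any_move = True
        if not moved:
            return any_move


def _aggregate(B: np.ndarray, comm: np.ndarray) -> np.ndarray:
    K = int(comm.max()) + 1
    Z = np.zeros((B.shape[0], K))
    Z[np.arange(B.shape[0]), comm] = 1.0
    return Z.T @ B @ Z


def _louvain_once(B: np.ndarray, init: np.ndarray, rng, move_tol: float) -> np.ndarray:
    """One full Louvain run (sweep + aggregate levels) from a given partition."""
    node_map = np.arange(B.shape[0])
    commk = _compact(init)
    Bk = B
    singleton_level = int(commk.max()) + 1 == Bk.shape[0]
    while True:
        moved = _sweep_inplace(Bk, commk, rng, move_tol)
        commk = _compact(commk)
        K = int(commk.max()) + 1
        if not moved and singleton_level:
            break
        node_map = commk[node_map]
        Bk = _aggregate(Bk, commk)
        commk = np.arange(K)
        singleton_level = True
        if K == 1:
            break
    return _compact(commk[node_map])


def louvain_sweep(net: MultilayerNetwork, part: Partition, rng) -> Partition:
    """Single phase-1 sweep on the supra-modularity structure.

    Returned Q never decreases relative to the input partition.
    """
    B = supra_modularity(net)
    move_tol = 1e-12 * max(1.0, float(np.abs(B).max()))
    comm = _flat(part.g).copy()
    _sweep_inplace(B, comm, rng, move_tol)
    comm = _compact(comm)
    q = _q_from_supra(B, comm, net.two_mu)
    return Partition(
        subject_ids=list(net.subject_ids),
        layer_ids=list(net.layer_ids),
        g=_unflat(comm, net.n_subjects, net.n_layers),
        q=q,
    )


def genlouvain(
    net: MultilayerNetwork,
    restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-10,
) -> Partition:
    """Iterated generalized Louvain with random restarts.

    The first restart runs Louvain from all-singletons; later restarts start
    from a random partition, which lets the greedy maximal-gain moves enter
    basins the singleton start never reaches on frustrated signed
    instances.  Each restart then re-seeds a fresh run from its flattened
    result until Q improves by less than ``tol``; the best-Q partition over
    restarts is returned.  Deterministic given ``seed``.
    """
    if restarts < 1:
        raise CohortError("restarts must be >= 1")
    B = supra_modularity(net)
    N = B.shape[0]
    move_tol = 1e-12 * max(1.0, float(np.abs(B).max()))
    best_comm: np.ndarray | None = None
    best_q = -np.inf
    for idx, ss in enumerate(np.random.SeedSequence(seed).spawn(restarts)):
        rng = np.random.default_rng(ss)
        comm = np.arange(N) if idx == 0 else rng.integers(0, N, size=N)
        q_prev = -np.inf
        while True:
            comm = _louvain_once(B, comm, rng, move_tol)
            q = _q_from_supra(B, comm, net.two_mu)
            if q - q_prev < tol:
                break
            q_prev = q
        if q > best_q:
            best_q = q
            best_comm = comm
    assert best_comm is not None
    return Partition(
        subject_ids=list(net.subject_ids),
        layer_ids=list(net.layer_ids),
        g=_unflat(_compact(best_comm), net.n_subjects, net.n_layers),
        q=float(best_q),
    )


def consensus_node_labels(part: Partition) -> tuple[np.ndarray, np.ndarray]:
    """Collapse per-layer assignments to one label per subject.

    The label is the majority community across the subject's layers; ties go
    to the community seen earliest in layer order.  The boolean vector flags
    subjects whose assignment differs across layers.
    """
    n, L = part.g.shape
    labels = np.empty(n, dtype=int)
    split = np.empty(n, dtype=bool)
    for i in range(n):
        row = part.g[i]
        vals, counts = np.unique(row, return_counts=True)
        top = vals[counts == counts.max()]
        if len(top) == 1:
            labels[i] = top[0]
        else:
            # earliest layer whose community is among the tied maxima
            for l in range(L):
                if row[l] in top:
                    labels[i] = row[l]
                    break
        split[i] = len(vals) > 1
    return labels, split
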