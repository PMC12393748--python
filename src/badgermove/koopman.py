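"""Koopman operator approximation and metastability analysis.

The slow component of telemetry dynamics is extracted by approximating
the Koopman operator K_tau — the linear operator advancing observables
one lag tau forward in expectation — from snapshot pairs (x_k, y_k),
where y_k is the fix one step after x_k within the same uniformly sampled
track.  The dictionary is the set of indicator functions of the occupied
cells of a ~100 m box grid, in which case the EDMD least-squares solution

    K^T = Psi_Y' Psi_Y^+

coincides with Ulam's method: K is the row-normalised matrix of box-to-box
transition counts, i.e. a Markov state model.  Eigenvalues near 1 encode
metastable (rarely-left) regions; the number of metastable states is read
off at the first spectral gap, and k-means on the corresponding leading
eigenfunctions partitions the boxes into metastable clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.cluster import KMeans

from .preprocessing import RegularTrack


@dataclass
class BoxGrid:
    """Axis-aligned box discretisation of the fix domain.

    Box counts are the spans rounded to the nearest integer number of
    ``target_edge`` boxes (clamped to >= 1), so edges are approximately —
    not exactly — ``target_edge``.  Boxes are half-open [lo, hi) except
    the final box along each axis, which is closed.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    nx: int
    ny: int
    occupied: np.ndarray = dc_field(default=None)  # sorted flat indices

    @property
    def edge_x(self) -> float:
        return (self.x_max - self.x_min) / self.nx

    @property
    def edge_y(self) -> float:
        return (self.y_max - self.y_min) / self.ny

    @property
    def n_boxes(self) -> int:
        return self.nx * self.ny

    def box_index(self, points) -> np.ndarray:
        """Flat box index of each point; points must lie in the bounding box."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if (np.any(pts[:, 0] < self.x_min - 1e-9) or np.any(pts[:, 0] > self.x_max + 1e-9)
                or np.any(pts[:, 1] < self.y_min - 1e-9) or np.any(pts[:, 1] > self.y_max + 1e-9)):
            raise ValueError("point outside the grid bounding box")
        ix = np.clip(((pts[:, 0] - self.x_min) / self.edge_x).astype(int), 0, self.nx - 1)
        iy = np.clip(((pts[:, 1] - self.y_min) / self.edge_y).astype(int), 0, self.ny - 1)
        return iy * self.nx + ix

    def box_centres(self, flat_indices) -> np.ndarray:
        flat = np.asarray(flat_indices)
        ix = flat % self.nx
        iy = flat // self.nx
        return np.column_stack([
            self.x_min + (ix + 0.5) * self.edge_x,
            self.y_min + (iy + 0.5) * self.edge_y,
        ])


def build_grid(points, target_edge: float = 100.0) -> BoxGrid:
    """Superimpose a ~``target_edge``-metre box grid over a point cloud.

    The box count along each axis is the span divided by the target edge,
    rounded to the nearest integer (at least 1); a zero-span axis yields a
    single box with a warning.  Boxes containing at least one input point
    are recorded as occupied.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("need at least one point to build a grid")
    x_min, y_min = pts.min(axis=0)
    x_max, y_max = pts.max(axis=0)
    spans = (x_max - x_min, y_max - y_min)
    if spans[0] == 0 or spans[1] == 0:
        warnings.warn("degenerate (zero-span) point cloud; using a single box "
                      "along the flat axis")
    nx = max(int(round(spans[0] / target_edge)), 1)
    ny = max(int(round(spans[1] / target_edge)), 1)
    # give zero-span axes a token extent so box membership is well defined
    if spans[0] == 0:
        x_max = x_min + 1.0
    if spans[1] == 0:
        y_max = y_min + 1.0
    grid = BoxGrid(x_min, x_max, y_min, y_max, nx, ny)
    grid.occupied = np.unique(grid.box_index(pts))
    return grid


@dataclass
class SnapshotPairs:
    """Concatenated EDMD snapshot pairs.

    ``sources[k]`` and ``destinations[k]`` are positions exactly one lag
    tau apart within one track; pairs never bridge two tracks or an
    overnight gap.  A track of m fixes contributes m - 1 pairs.
    """

    sources: np.ndarray       # (K, 2)
    destinations: np.ndarray  # (K, 2)
    tau: float                # minutes

    def __post_init__(self):
        self.sources = np.atleast_2d(np.asarray(self.sources, dtype=float))
        self.destinations = np.atleast_2d(np.asarray(self.destinations, dtype=float))
        if self.sources.shape != self.destinations.shape:
            raise ValueError("sources and destinations must match in shape")

    def __len__(self):
        return len(self.sources)

    @property
    def all_points(self) -> np.ndarray:
        return np.vstack([self.sources, self.destinations])


def build_pairs(tracks: list[RegularTrack]) -> SnapshotPairs:
    """Assemble snapshot pairs from uniformly resampled night segments.

    All tracks must share the same step dt (= the lag tau); each track of
    m fixes contributes its m - 1 consecutive pairs and nothing across
    track boundaries.
    """
    dts = {round(t.dt, 6) for t in tracks if len(t.fixes) >= 2}
    if len(dts) > 1:
        raise ValueError(f"tracks mix different sampling steps: {sorted(dts)}")
    src, dst = [], []
    for t in tracks:
        pos = t.positions
        if len(pos) < 2:
            continue
        src.append(pos[:-1])
        dst.append(pos[1:])
    if not src:
        raise ValueError("no snapshot pairs: all tracks have fewer than 2 fixes")
    return SnapshotPairs(np.vstack(src), np.vstack(dst), tau=dts.pop())


@dataclass
class KoopmanMatrix:
    """Finite-dimensional Koopman approximation over occupied boxes.

    Row j holds the one-lag transition distribution out of box
    ``box_indices[j]``; rows of boxes never seen as a pair source are
    zero (they occur only as destinations).
    """

    K: np.ndarray             # (N, N)
    grid: BoxGrid
    box_indices: np.ndarray   # flat grid indices of the N states
    source_counts: np.ndarray  # pairs starting in each state

    @property
    def n_states(self) -> int:
        return len(self.box_indices)


def transition_count_oracle(pairs: SnapshotPairs, grid: BoxGrid) -> KoopmanMatrix:
    """Ulam's method by direct counting — the module's independent oracle.

    C[j, i] = number of pairs from box j to box i; each row with any
    outgoing pair is divided by its sum.
    """
    states = np.unique(grid.box_index(pairs.all_points))
    lookup = {b: i for i, b in enumerate(states)}
    s = np.array([lookup[b] for b in grid.box_index(pairs.sources)])
    d = np.array([lookup[b] for b in grid.box_index(pairs.destinations)])
    n = len(states)
    counts = np.zeros((n, n))
    np.add.at(counts, (s, d), 1.0)
    row_sums = counts.sum(axis=1)
    K = np.divide(counts, row_sums[:, None], where=row_sums[:, None] > 0,
                  out=np.zeros_like(counts))
    return KoopmanMatrix(K, grid, states, row_sums.astype(int))


def estimate_koopman(pairs: SnapshotPairs, grid: BoxGrid) -> KoopmanMatrix:
    """EDMD with an indicator dictionary via the pseudoinverse solution
    K^T = Psi_Y' Psi_Y^+.

    The dictionary spans the boxes occupied by any pair endpoint; with
    indicator basis functions this least-squares solution equals the
    row-normalised transition-count matrix (Ulam / Markov state model),
    which :func:`transition_count_oracle` verifies independently.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one snapshot pair")
    states = np.unique(grid.box_index(pairs.all_points))
    lookup = {b: i for i, b in enumerate(states)}
    s = np.array([lookup[b] for b in grid.box_index(pairs.sources)])
    d = np.array([lookup[b] for b in grid.box_index(pairs.destinations)])
    n = len(states)
    m = len(pairs)
    # K^T = Psi_Y' Psi_Y^+ = A G^+ with the Gram matrix G = Psi_Y Psi_Y^T
    # and stiffness matrix A = Psi_Y' Psi_Y^T, accumulated in chunks so the
    # (N_K x K) dictionary matrices are never materialised in full
    G = np.zeros((n, n))
    A = np.zeros((n, n))
    counts = np.zeros(n)
    chunk = 20000
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        mc = hi - lo
        psi_y = np.zeros((n, mc))
        psi_y[s[lo:hi], np.arange(mc)] = 1.0
        psi_yp = np.zeros((n, mc))
        psi_yp[d[lo:hi], np.arange(mc)] = 1.0
        G += psi_y @ psi_y.T
        A += psi_yp @ psi_y.T
        counts += psi_y.sum(axis=1)
    K_T = A @ np.linalg.pinv(G)
    return KoopmanMatrix(K_T.T, grid, states, counts.astype(int))


def filter_sparse_pairs(pairs: SnapshotPairs, grid: BoxGrid,
                        min_count: int = 5) -> SnapshotPairs:
    """Drop pairs touching boxes with too little data to support a
    transition-probability estimate.

    A box visited only a handful of times (a brief excursion, a surviving
    GPS outlier) contributes rows of the transition matrix estimated from
    one or two samples; such states are statistical noise and distort the
    dominant spectrum.  Boxes with fewer than ``min_count`` total endpoint
    visits are removed together with the pairs touching them, iterating
    until stable.  ``min_count=1`` keeps everything.
    """
    src = grid.box_index(pairs.sources)
    dst = grid.box_index(pairs.destinations)
    keep = np.ones(len(pairs), dtype=bool)
    while True:
        flat = np.concatenate([src[keep], dst[keep]])
        boxes, counts = np.unique(flat, return_counts=True)
        ok = set(boxes[counts >= min_count])
        new_keep = keep & np.array([s in ok and d in ok
                                    for s, d in zip(src, dst)])
        if new_keep.sum() == keep.sum():
            break
        keep = new_keep
        if not keep.any():
            break
    if not keep.any():
        raise ValueError(f"no pairs survive the min_count={min_count} filter")
    return SnapshotPairs(pairs.sources[keep], pairs.destinations[keep],
                         pairs.tau)


def prune_spurious_absorbing(km: KoopmanMatrix,
                             min_class_size: int = 2) -> KoopmanMatrix:
    """Drop tiny terminal communication classes — a finite-sampling artifact.

    A box whose only observed outgoing pairs are self-loops (its genuine
    exits fell across night boundaries, so no pair records them) becomes
    a spurious absorbing state with eigenvalue exactly 1, inflating the
    apparent number of metastable sets.  Genuine metastable regions are
    terminal strongly connected classes of many boxes; terminal classes
    with fewer than ``min_class_size`` boxes are removed here and the
    remaining rows renormalised.  Transient states (zero rows from
    destination-only boxes) are kept.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = km.n_states
    adj = csr_matrix(km.K > 0)
    n_comp, comp = connected_components(adj, directed=True, connection="strong")
    # terminal = no edge leaving the class
    terminal = np.ones(n_comp, dtype=bool)
    jj, ii = np.nonzero(km.K)
    for j, i in zip(jj, ii):
        if comp[j] != comp[i]:
            terminal[comp[j]] = False
    sizes = np.bincount(comp, minlength=n_comp)
    drop_class = terminal & (sizes < min_class_size)
    keep = ~drop_class[comp]
    # rows with no outgoing data are transient bookkeeping, not classes
    keep |= km.source_counts == 0
    if keep.all():
        return km
    K = km.K[np.ix_(keep, keep)]
    sums = K.sum(axis=1)
    rows = sums > 0
    K[rows] = K[rows] / sums[rows, None]
    return KoopmanMatrix(K, km.grid, km.box_indices[keep],
                         km.source_counts[keep])


@dataclass
class SpectralResult:
    """Eigendecomposition of a Koopman matrix.

    Eigenvalues are sorted by descending real part; complex pairs arise
    only from slight non-reversibility and their imaginary magnitudes are
    recorded.  ``eigenfunction(j, x)`` evaluates phi_j at arbitrary
    points via phi_j(x) = xi_j[box(x)].
    """

    eigenvalues: np.ndarray   # (N,), complex, sorted by Re desc
    eigenvectors: np.ndarray  # (N, N); column j belongs to eigenvalues[j]
    matrix: KoopmanMatrix

    def eigenfunction(self, j: int, points) -> np.ndarray:
        flat = self.matrix.grid.box_index(points)
        lookup = {b: i for i, b in enumerate(self.matrix.box_indices)}
        rows = np.array([lookup[b] for b in flat])
        return self.eigenvectors[rows, j]

    @property
    def max_imag(self) -> float:
        return float(np.max(np.abs(self.eigenvalues.imag))) if len(self.eigenvalues) else 0.0


def spectral_decompose(km: KoopmanMatrix) -> SpectralResult:
    """Full eigendecomposition, sorted by descending real part."""
    if not np.all(np.isfinite(km.K)):
        raise ValueError("Koopman matrix contains non-finite entries")
    vals, vecs = np.linalg.eig(km.K)
    order = np.argsort(-vals.real, kind="stable")
    return SpectralResult(vals[order], vecs[:, order], km)


def spectral_gap(eigenvalues, delta: float = 0.05, n_max: int = 20) -> int:
    """Number of dominant (metastable) eigenvalues.

    With eigenvalues sorted by descending real part, returns the smallest
    i <= n_max such that Re(lambda_i) - Re(lambda_{i+1}) > delta.  If no
    successive difference exceeds delta, falls back to the largest
    successive difference among the first n_max (logged via a warning),
    which is the more robust selection when the gap is shallow.
    """
    lam = np.real(np.asarray(eigenvalues))
    if len(lam) < 2:
        raise ValueError("need at least two eigenvalues")
    lam = np.sort(lam)[::-1]
    diffs = -np.diff(lam)
    limit = min(n_max, len(diffs))
    for i in range(limit):
        if diffs[i] > delta:
            return i + 1
    warnings.warn(f"no successive eigenvalue difference exceeds delta={delta}; "
                  "falling back to the largest successive difference")
    best = diffs[:limit]
    # ties (within floating noise) break toward the earliest index
    return int(np.argmax(best >= best.max() - 1e-9)) + 1


@dataclass
class MetastablePartition:
    """Assignment of occupied boxes (and member fixes) to metastable clusters."""

    n_clusters: int
    box_labels: np.ndarray    # label 1..N per state, aligned with box_indices
    box_indices: np.ndarray
    grid: BoxGrid

    def label_points(self, points) -> np.ndarray:
        """Cluster label of each point via its box; unassigned boxes -> 0."""
        flat = self.grid.box_index(points)
        lookup = {b: l for b, l in zip(self.box_indices, self.box_labels)}
        return np.array([lookup.get(b, 0) for b in flat])


def cluster_metastable(spectral: SpectralResult, n: int, seed: int = 0,
                       n_init: int = 10,
                       include_trivial: bool = True) -> MetastablePartition:
    """Partition occupied boxes by k-means on the leading eigenfunctions.

    Each box's feature vector is the real part of the first ``n``
    eigenfunctions evaluated there (the trivial constant eigenfunction is
    included by default, mirroring clustering on the 'first N'
    eigenfunctions; it carries no contrast, so excluding it gives the
    same partition).  k = n, seeded with ``n_init`` restarts.  Boxes are
    weighted by their visit counts — the eigenfunctions are piecewise
    constant on boxes, so this is exactly k-means over the individual
    fixes, and it keeps a handful of rarely-visited boxes from
    dominating a centroid.
    """
    km = spectral.matrix
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > km.n_states:
        raise ValueError(f"n={n} exceeds the {km.n_states} occupied boxes")
    first = 0 if include_trivial else 1
    feats = np.real(spectral.eigenvectors[:, first:first + n])
    # scale-normalise each eigenfunction so k-means weights them equally
    norms = np.linalg.norm(feats, axis=0)
    feats = feats / np.where(norms > 0, norms, 1.0)
    weights = np.maximum(km.source_counts, 1).astype(float)
    labels = KMeans(n_clusters=n, n_init=n_init,
                    random_state=seed).fit_predict(feats, sample_weight=weights)
    return MetastablePartition(n, labels + 1, km.box_indices, km.grid)
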