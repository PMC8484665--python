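"""Coancestry and population-substructure statistics.

Identity-by-state distances between diploid genotypes, classical
(Torgerson) multidimensional scaling, a symmetric Procrustes permutation
test against geography, Li-Stephens haplotype painting into a coancestry
matrix, and a deterministic agglomerative surrogate for coancestry-based
clustering (average linkage with silhouette-based model choice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from ._painting import paint_all
from .exceptions import PhasingError, ValidationError
from .simdata import HaplotypePanel

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a zero diagonal."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValidationError("distances must be nonnegative")
        self.values = v


@dataclass
class CoancestryMatrix:
    """Expected copied genome length, donors in rows, recipients in columns.

    Entry (j, i) is the expected length (bp) of recipient i's genome copied
    from donor j under the painting model; the diagonal is zero by
    construction (individuals never copy from themselves).
    """

    lengths: np.ndarray
    sample_ids: list[str]
    region_labels: list[str] | None = None
    painted_length: float | None = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths < 0):
            raise ValidationError("coancestry lengths must be nonnegative")

    def normalized(self) -> np.ndarray:
        """Symmetrized matrix divided by its off-diagonal grand mean."""
        s = (self.lengths + self.lengths.T) / 2.0
        n = s.shape[0]
        off = ~np.eye(n, dtype=bool)
        gm = s[off].mean()
        if gm <= 0:
            raise ValidationError("degenerate coancestry matrix (zero mass)")
        return s / gm


@dataclass
class MdsResult:
    """Classical MDS coordinates and the (descending) eigenvalues."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray


@dataclass
class ClusterResult:
    """Agglomerative clustering of a coancestry matrix."""

    linkage: np.ndarray
    labels_by_k: dict[int, np.ndarray]
    silhouettes: dict[int, float]
    best_k: int
    labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.labels = self.labels_by_k[self.best_k]


def ibs_distance(genotypes: np.ndarray, sample_ids: list[str] | None = None) -> DistanceMatrix:
    """1 - IBS allele-sharing distance from diploid dosages.

    ``genotypes`` is (N, L) with entries in {0, 1, 2} and -1 for missing.
    d(i, j) is the mean of |g_i - g_j| / 2 over sites where both samples are
    called (pairwise-complete).
    """
    g = np.asarray(genotypes)
    if g.ndim != 2 or g.shape[0] < 2 or g.shape[1] < 1:
        raise ValidationError("need >=2 samples and >=1 site")
    n = g.shape[0]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    called = g >= 0
    gf = g.astype(float)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            m = both.sum()
            if m == 0:
                raise ValidationError(
                    f"samples {sample_ids[i]} and {sample_ids[j]} share no "
                    "non-missing sites"
                )
            d[i, j] = d[j, i] = np.abs(gf[i, both] - gf[j, both]).mean() / 2.0
    return DistanceMatrix(d, list(sample_ids))


def classical_mds(dist: DistanceMatrix, k: int = 2) -> MdsResult:
    """Torgerson scaling: eigendecomposition of the double-centred squared
    distance matrix; axes with non-positive eigenvalues are dropped."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    d = dist.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-9 * max(abs(evals[0]), 1.0))
    n_pos = int(np.sum(evals > tol))
    if k > n_pos:
        logger.warning(
            "classical_mds: requested %d axes but only %d positive "
            "eigenvalues; truncating", k, n_pos,
        )
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    return MdsResult(coordinates=coords, eigenvalues=evals)


def procrustes_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Procrustes correlation sqrt(1 - residual SS)."""
    _, _, disparity = scipy.spatial.procrustes(x, y)
    return float(np.sqrt(max(0.0, 1.0 - disparity)))


def procrustes_test(
    x: np.ndarray, y: np.ndarray, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Permutation test of the symmetric Procrustes correlation.

    Rows of ``y`` are permuted; p = (1 + #{perm corr >= observed}) /
    (n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if x.shape[0] != y.shape[0]:
        raise ValidationError("configurations must have equal row counts")
    if x.shape[0] < 3:
        raise ValidationError("need at least 3 rows")
    obs = procrustes_correlation(x, y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(y.shape[0])
        if procrustes_correlation(x, y[perm]) >= obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return obs, p


def paint_panel(
    panel: HaplotypePanel,
    switch_rate: float = 1e-6,
    miscopy_rate: float = 1e-3,
) -> CoancestryMatrix:
    """Chromosome painting of every individual against all others.

    Each recipient haplotype is painted by forward-backward under the
    Li-Stephens copying model with the haplotypes of all *other*
    individuals as donors; expected copied length per donor is accumulated
    as posterior mass times the inter-site span, donor haplotypes are
    collapsed to individuals and the recipient's two haplotypes summed.
    The painted length per recipient is twice the first-to-last-site span
    (two haplotypes), so each column of the result sums to that length.
    """
    if not isinstance(panel, HaplotypePanel):
        raise PhasingError(
            "painting requires phased haplotypes; run dosage-based "
            "analyses (IBS/MDS) on unphased data instead"
        )
    if panel.n_samples < 3:
        raise ValidationError("painting needs at least 3 individuals")
    if panel.n_sites < 2:
        raise ValidationError("painting needs at least 2 sites")
    pos = panel.positions.astype(np.float64)
    spans = np.empty(len(pos))
    spans[1:-1] = (pos[2:] - pos[:-2]) / 2.0
    spans[0] = (pos[1] - pos[0]) / 2.0
    spans[-1] = (pos[-1] - pos[-2]) / 2.0
    sample_of_hap = np.repeat(np.arange(panel.n_samples), 2)
    lengths, _, _ = paint_all(
        np.ascontiguousarray(panel.haplotypes),
        sample_of_hap,
        pos,
        spans,
        float(switch_rate),
        float(miscopy_rate),
    )
    return CoancestryMatrix(
        lengths=lengths,
        sample_ids=list(panel.sample_ids),
        region_labels=list(panel.region_labels),
        painted_length=float(2.0 * (pos[-1] - pos[0])),
    )


@dataclass
class SwitchRateFit:
    """EM estimate of the per-bp switch rate and its likelihood trace."""

    switch_rate: float
    loglik_trace: list[float]


def estimate_switch_rate(
    panel: HaplotypePanel,
    n_em_iters: int = 5,
    init_rate: float = 1e-6,
    miscopy_rate: float = 1e-3,
    min_rate: float = 1e-12,
) -> SwitchRateFit:
    """EM fit of the painting switch rate.

    Each iteration sets the rate to expected switches per painted bp
    (guarded below by ``min_rate``); if an update would decrease the total
    log-likelihood the previous rate is kept and iteration stops, so the
    recorded trace is non-decreasing.
    """
    if n_em_iters < 1:
        raise ValidationError("n_em_iters must be >= 1")
    if panel.n_sites < 2:
        raise ValidationError("switch-rate EM needs at least 2 sites")
    pos = panel.positions.astype(np.float64)
    spans = np.empty(len(pos))
    spans[1:-1] = (pos[2:] - pos[:-2]) / 2.0
    spans[0] = (pos[1] - pos[0]) / 2.0
    spans[-1] = (pos[-1] - pos[-2]) / 2.0
    sample_of_hap = np.repeat(np.arange(panel.n_samples), 2)
    haps = np.ascontiguousarray(panel.haplotypes)
    total_bp = (pos[-1] - pos[0]) * haps.shape[0]
    rate = float(init_rate)
    trace: list[float] = []
    for _ in range(n_em_iters):
        _, ll, e_switches = paint_all(
            haps, sample_of_hap, pos, spans, rate, float(miscopy_rate)
        )
        if trace and ll < trace[-1]:
            break
        trace.append(ll)
        rate_new = max(min_rate, e_switches / total_bp)
        if abs(rate_new - rate) / max(rate, min_rate) < 1e-6:
            rate = rate_new
            break
        rate = rate_new
    return SwitchRateFit(switch_rate=rate, loglik_trace=trace)


def cluster_coancestry(coancestry: CoancestryMatrix, k_max: int = 6) -> ClusterResult:
    """Average-linkage clustering of row-normalized symmetrized coancestry.

    Each individual's profile is its row of the symmetrized matrix scaled
    to sum 1 (self column set to the row mean so it carries no signal);
    profiles are clustered on Pearson correlation distance, which reads the
    copying pattern rather than its magnitude, and the flat clustering with
    the highest mean silhouette over k = 2..k_max is chosen.
    """
    n = coancestry.lengths.shape[0]
    if k_max >= n:
        raise ValidationError("k_max must be < number of individuals")
    if k_max < 2:
        raise ValidationError("k_max must be >= 2")
    s = (coancestry.lengths + coancestry.lengths.T) / 2.0
    off = ~np.eye(n, dtype=bool)
    profiles = s.copy()
    np.fill_diagonal(profiles, s[off].reshape(n, n - 1).mean(axis=1))
    rowsums = profiles.sum(axis=1, keepdims=True)
    rowsums[rowsums == 0] = 1.0
    profiles = profiles / rowsums
    d = scipy.spatial.distance.pdist(profiles, metric="correlation")
    link = sch.linkage(d, method="average")
    dsq = squareform(d)
    labels_by_k: dict[int, np.ndarray] = {}
    silhouettes: dict[int, float] = {}
    for k in range(2, k_max + 1):
        labels = sch.fcluster(link, t=k, criterion="maxclust")
        labels_by_k[k] = labels
        if len(np.unique(labels)) < 2:
            silhouettes[k] = -1.0
        else:
            silhouettes[k] = float(
                silhouette_score(dsq, labels, metric="precomputed")
            )
    best_k = max(silhouettes, key=lambda k: (silhouettes[k], -k))
    return ClusterResult(
        linkage=link,
        labels_by_k=labels_by_k,
        silhouettes=silhouettes,
        best_k=best_k,
    )


def write_matrix_tsv(matrix: np.ndarray, sample_ids: list[str], path) -> None:
    """Matrix as TSV with a header row and a leading ID column."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(sample_ids) + "\n")
        for sid, row in zip(sample_ids, matrix):
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        ids = fh.readline().rstrip("\n").split("\t")[1:]
        rows = [
            [float(v) for v in line.rstrip("\n").split("\t")[1:]]
            for line in fh
            if line.strip()
        ]
    return np.asarray(rows), ids
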