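"""Linkage disequilibrium and autozygosity statistics.

The HR statistic is a phase-free composite LD measure implemented as the
squared Pearson correlation of diploid dosage vectors. LD decay averages HR
over pairs of SNVs with similar minor allele frequencies (|dMAF| < 0.05 by
default), which limits the frequency dependence of LD comparisons between
cohorts. Runs of homozygosity are called with a sliding-window scan, and
per-individual heterozygosity ratios (HetR) can be normalized across
cohorts of different size by repeated fixed-size subsampling (nHetR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError


@dataclass
class LDConfig:
    """Pair selection and binning for LD decay."""

    maf_tolerance: float = 0.05
    min_maf: float = 0.05
    bin_edges: np.ndarray = field(
        default_factory=lambda: np.arange(0, 500_001, 10_000)
    )
    max_sites: int | None = None  # deterministic thinning of the site set

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.maf_tolerance <= 0:
            raise ValidationError("maf_tolerance must be > 0")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("bin edges must be increasing")

    @property
    def max_distance(self) -> float:
        return float(self.bin_edges[-1])


@dataclass
class LDDecayCurve:
    """Mean HR per distance bin; empty bins have NaN mean and count 0."""

    bin_mid: np.ndarray
    mean_hr: np.ndarray
    pair_counts: np.ndarray


@dataclass
class RoHSegment:
    """A run of homozygosity, 0-based half-open bp interval."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_snvs: int
    n_het: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("RoH segment must have end > start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RoHParams:
    """Sliding-window RoH caller parameters."""

    window_snvs: int = 50
    max_het_per_window: int = 1
    min_length_bp: float = 1e6
    min_snvs: int = 50
    max_gap_bp: float = 1e5


@dataclass
class HetRatioResult:
    """Heterozygote / homozygote-alternate count ratio for one sample."""

    sample_id: str
    n_het: int
    n_hom_alt: int
    het_ratio: float | None
    defined: bool


def _complete_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = (a >= 0) & (b >= 0)
    return a[ok], b[ok]


def hr_statistic(dosages_a: np.ndarray, dosages_b: np.ndarray, signed: bool = False) -> float:
    """Composite LD between two sites from diploid dosages.

    Squared Pearson correlation of the dosage vectors over individuals with
    both sites called (the signed correlation with ``signed=True``).
    """
    a, b = _complete_pair(dosages_a, dosages_b)
    if len(a) < 5:
        raise ValidationError("need >=5 individuals with complete dosages")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError(
            "undefined LD: monomorphic site in the sample "
            f"(site a var={np.ptp(a)}, site b var={np.ptp(b)})"
        )
    r = np.corrcoef(a, b)[0, 1]
    return float(r) if signed else float(r * r)


def minor_allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Per-site MAF from an (N, L) dosage matrix with -1 for missing."""
    d = np.asarray(dosages, dtype=float)
    called = d >= 0
    n = 2.0 * called.sum(axis=0)
    alt = np.where(called, d, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / n, np.nan)
    return np.minimum(p, 1.0 - p)


def ld_decay(
    dosages: np.ndarray,
    positions: np.ndarray,
    config: LDConfig | None = None,
    return_pairs: bool = False,
):
    """Mean HR by physical distance, restricted to MAF-matched pairs.

    Pairs must lie within the last bin edge, both sites must pass
    ``min_maf`` and their MAFs must differ by less than ``maf_tolerance``.
    Returns an :class:`LDDecayCurve`, optionally with the per-pair records.
    """
    config = config or LDConfig()
    d = np.asarray(dosages, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if d.shape[0] < 5:
        raise ValidationError("LD decay needs >=5 individuals")
    maf = minor_allele_frequencies(d)
    keep = np.flatnonzero((maf >= config.min_maf) & ~np.isnan(maf))
    # Drop sites monomorphic in this sample (zero dosage variance).
    keep = keep[np.ptp(d[:, keep], axis=0) > 0]
    if config.max_sites is not None and len(keep) > config.max_sites:
        sel = np.linspace(0, len(keep) - 1, config.max_sites).astype(int)
        keep = keep[sel]
    pos_k = pos[keep]
    maf_k = maf[keep]
    dk = d[:, keep]
    # Standardize site columns once; r = z_a . z_b / N (complete data).
    if np.any(dk < 0):
        raise ValidationError("ld_decay requires complete dosages")
    z = (dk - dk.mean(axis=0)) / dk.std(axis=0)
    n_ind = dk.shape[0]
    ia: list[np.ndarray] = []
    ib: list[np.ndarray] = []
    upper = np.searchsorted(pos_k, pos_k + config.max_distance, side="right")
    for i in range(len(keep)):
        j = np.arange(i + 1, upper[i])
        if len(j) == 0:
            continue
        j = j[np.abs(maf_k[j] - maf_k[i]) < config.maf_tolerance]
        if len(j):
            ia.append(np.full(len(j), i))
            ib.append(j)
    if ia:
        ia_arr = np.concatenate(ia)
        ib_arr = np.concatenate(ib)
        r = np.einsum("ij,ij->j", z[:, ia_arr], z[:, ib_arr]) / n_ind
        hr = r * r
        dist = pos_k[ib_arr] - pos_k[ia_arr]
    else:
        hr = np.zeros(0)
        dist = np.zeros(0)
    nbins = len(config.bin_edges) - 1
    which = np.digitize(dist, config.bin_edges) - 1
    ok = (which >= 0) & (which < nbins)
    counts = np.bincount(which[ok], minlength=nbins)
    sums = np.bincount(which[ok], weights=hr[ok], minlength=nbins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    curve = LDDecayCurve(
        bin_mid=(config.bin_edges[:-1] + config.bin_edges[1:]) / 2.0,
        mean_hr=means,
        pair_counts=counts,
    )
    if return_pairs:
        pairs = pd.DataFrame(
            {"site_a": ia_arr if ia else [], "site_b": ib_arr if ia else [],
             "distance": dist, "hr": hr, "bin": which}
        )
        return curve, pairs
    return curve


def detect_roh(
    dosages: np.ndarray,
    positions: np.ndarray,
    sample_id: str = "sample",
    chrom: str = "1",
    params: RoHParams | None = None,
) -> list[RoHSegment]:
    """Sliding-window RoH caller for one sample.

    Windows of ``window_snvs`` consecutive called sites with at most
    ``max_het_per_window`` heterozygotes flag their member sites; maximal
    runs of flagged sites are split at inter-site gaps above ``max_gap_bp``
    and kept if they span ``min_length_bp`` and contain ``min_snvs`` sites.
    """
    params = params or RoHParams()
    pos = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(pos) < 0):
        raise ValidationError("positions must be sorted")
    d = np.asarray(dosages)
    called = d >= 0
    pos = pos[called]
    d = d[called]
    L = len(pos)
    w = params.window_snvs
    if L < max(w, params.min_snvs):
        return []
    het = (d == 1).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    window_het = chet[w:] - chet[:-w]  # het count of window starting at i
    good_start = window_het <= params.max_het_per_window  # length L-w+1
    # A site is flagged if any window covering it is good.
    cgood = np.concatenate([[0], np.cumsum(good_start.astype(np.int64))])
    flagged = np.zeros(L, dtype=bool)
    for i in range(L):
        lo = max(0, i - w + 1)
        hi = min(i, L - w)
        if hi >= lo and cgood[hi + 1] - cgood[lo] > 0:
            flagged[i] = True
    segments: list[RoHSegment] = []
    i = 0
    while i < L:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < L
            and flagged[j + 1]
            and pos[j + 1] - pos[j] <= params.max_gap_bp
        ):
            j += 1
        start, end = int(pos[i]), int(pos[j]) + 1
        n_snvs = j - i + 1
        if end - start >= params.min_length_bp and n_snvs >= params.min_snvs:
            segments.append(
                RoHSegment(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_snvs=n_snvs,
                    n_het=int(het[i : j + 1].sum()),
                )
            )
        i = j + 1
    return segments


def roh_totals(
    dosages: np.ndarray,
    positions: np.ndarray,
    sample_ids: list[str],
    params: RoHParams | None = None,
) -> pd.Series:
    """Total RoH length (bp) per sample from an (N, L) dosage matrix."""
    totals = {}
    for i, sid in enumerate(sample_ids):
        segs = detect_roh(dosages[i], positions, sample_id=sid, params=params)
        totals[sid] = float(sum(s.length for s in segs))
    return pd.Series(totals, name="roh_total_bp")


def roh_region_test(
    totals: np.ndarray, region_labels: np.ndarray
) -> tuple[float, float]:
    """Kruskal-Wallis rank test of per-individual RoH totals across regions."""
    totals = np.asarray(totals, dtype=float)
    labels = np.asarray(region_labels)
    regions = np.unique(labels)
    if len(regions) < 2:
        raise ValidationError("need >=2 regions")
    groups = []
    for r in regions:
        vals = totals[labels == r]
        if len(vals) < 2:
            raise ValidationError(f"region {r} has fewer than 2 samples")
        groups.append(vals)
    if np.ptp(totals) == 0:
        # All observations tied: no evidence of differences.
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def het_ratio(dosages: np.ndarray, sample_id: str = "sample") -> HetRatioResult:
    """HetR = #heterozygous / #homozygous-alternate sites (missing excluded).

    A zero denominator yields a flagged, undefined result rather than an
    exception or a silent zero.
    """
    d = np.asarray(dosages)
    n_het = int(np.sum(d == 1))
    n_hom_alt = int(np.sum(d == 2))
    if n_hom_alt == 0:
        return HetRatioResult(sample_id, n_het, 0, None, defined=False)
    return HetRatioResult(
        sample_id, n_het, n_hom_alt, n_het / n_hom_alt, defined=True
    )


def normalized_het_ratio(
    dosages: np.ndarray,
    region_labels: list[str],
    sample_ids: list[str],
    subsample_size: int = 5,
    n_reps: int = 5000,
    seed: int = 0,
) -> pd.Series:
    """Resampling-normalized HetR (nHetR) per sample.

    Each replicate draws ``subsample_size`` samples without replacement
    from every region, restricts to sites polymorphic within the pooled
    drawn set, and computes each drawn sample's HetR on those sites; a
    sample's nHetR is the mean over the replicates in which it was drawn
    (undefined replicate values are excluded).
    """
    d = np.asarray(dosages)
    labels = np.asarray(region_labels)
    ids = list(sample_ids)
    rng = np.random.default_rng(seed)
    region_index = {}
    for r in np.unique(labels):
        idx = np.flatnonzero(labels == r)
        if len(idx) < subsample_size:
            raise ValidationError(
                f"region {r} has {len(idx)} samples, fewer than the "
                f"subsample size {subsample_size}"
            )
        region_index[r] = idx
    sums = np.zeros(len(ids))
    counts = np.zeros(len(ids))
    for _ in range(n_reps):
        drawn = np.concatenate(
            [rng.choice(idx, size=subsample_size, replace=False)
             for r, idx in sorted(region_index.items())]
        )
        sub = d[drawn]
        called = sub >= 0
        alt = np.where(called, sub, 0).sum(axis=0)
        n_alleles = 2 * called.sum(axis=0)
        poly = (alt > 0) & (alt < n_alleles)
        if not poly.any():
            continue
        sub_poly = sub[:, poly]
        n_het = (sub_poly == 1).sum(axis=1)
        n_hom = (sub_poly == 2).sum(axis=1)
        for k, si in enumerate(drawn):
            if n_hom[k] > 0:
                sums[si] += n_het[k] / n_hom[k]
                counts[si] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        nhetr = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(nhetr, index=ids, name="nHetR")
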