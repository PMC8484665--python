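"""Synthetic genotype data under a five-valley demographic model.

This module provides the data-generating side of the package:

* uniform (and log-uniform) priors over the parameters of a
  five-population split model with migration, including symbolic upper
  bounds (split times of subgroups are bounded by the root split time);
* coalescent simulation of phased diploid haplotype panels with msprime;
* plain-text VCF round-trip and a sample->region/coordinate map;
* deterministic fixtures (planted runs of homozygosity, two-cluster
  coancestry matrices, anisotropic lattices) used to validate the
  downstream statistics against known ground truth.

The demographic model has five terminal populations labelled G, R, U, P
and B sampled along a ~140 km west-to-east axis. G and R merge (backwards
in time) into an ancestral population GR, while U, P and B merge
simultaneously into UPB; GR and UPB merge into the root population GRUBP.
Effective sizes are expressed in chromosomes (haploid counts) and split
times in years before present, converted to generations assuming 29 years
per generation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import msprime
import numpy as np

from .exceptions import ConfigurationError, PhasingError, ValidationError

logger = logging.getLogger(__name__)

#: Terminal populations, west-to-east sampling order is P, U, B, R, G but the
#: canonical parameter order below follows the model topology.
REGIONS: tuple[str, ...] = ("G", "R", "U", "P", "B")

#: Planar sampling coordinates (km). The five valleys span ~140 km on a
#: west-east axis with small north-south offsets; plumbing constants with no
#: claim of cartographic accuracy, configurable through a sample map TSV.
DEFAULT_REGION_COORDS: dict[str, tuple[float, float]] = {
    "P": (0.0, 0.0),
    "U": (38.0, 6.0),
    "B": (72.0, -4.0),
    "R": (106.0, 5.0),
    "G": (140.0, 0.0),
}

PARAMETER_NAMES: tuple[str, ...] = (
    "Ne_GRUBP",
    "Ne_GR",
    "Ne_UPB",
    "Ne_G",
    "Ne_R",
    "Ne_U",
    "Ne_P",
    "Ne_B",
    "t_GRUBP",
    "t_GR",
    "t_UPB",
    "m",
)


@dataclass(frozen=True)
class PriorSpec:
    """A univariate prior for one demographic parameter.

    ``low``/``high`` are numeric bounds; ``high`` may instead name another
    parameter, in which case the bound is resolved to that parameter's drawn
    value (e.g. subgroup split times are bounded above by the root split
    time). ``dist`` is ``"uniform"`` or ``"loguniform"``.
    """

    name: str
    low: float
    high: float | str
    dist: str = "uniform"

    def __post_init__(self) -> None:
        if self.dist not in ("uniform", "loguniform"):
            raise ConfigurationError(f"unknown distribution {self.dist!r}")
        if self.dist == "loguniform" and self.low <= 0:
            raise ConfigurationError(
                f"log-uniform prior {self.name} requires low > 0"
            )
        if not isinstance(self.high, str) and not self.low <= float(self.high):
            raise ConfigurationError(
                f"prior {self.name}: low {self.low} must be <= high {self.high}"
            )


#: Default priors: uniform effective sizes (chromosomes) and split times
#: (years); subgroup split times are bounded above by the drawn root split
#: time. Migration is log-uniform per generation between terminal
#: populations (the model includes migration but no canonical rate exists,
#: so a broad log-uniform prior is used).
DEFAULT_PRIORS: tuple[PriorSpec, ...] = (
    PriorSpec("Ne_GRUBP", 15000, 40000),
    PriorSpec("Ne_GR", 1000, 5000),
    PriorSpec("Ne_UPB", 1000, 5000),
    PriorSpec("Ne_G", 500, 2500),
    PriorSpec("Ne_R", 500, 2500),
    PriorSpec("Ne_U", 200, 2000),
    PriorSpec("Ne_P", 500, 2500),
    PriorSpec("Ne_B", 500, 10000),
    PriorSpec("t_GRUBP", 2320, 14500),
    PriorSpec("t_GR", 870, "t_GRUBP"),
    PriorSpec("t_UPB", 870, "t_GRUBP"),
    PriorSpec("m", 1e-5, 1e-2, dist="loguniform"),
)


@dataclass(frozen=True)
class ParameterVector:
    """One point of the demographic model's parameter space.

    Effective sizes are haploid chromosome counts; split times are years
    before present; ``m`` is the symmetric per-generation migration rate
    between each pair of terminal populations.
    """

    Ne_GRUBP: float
    Ne_GR: float
    Ne_UPB: float
    Ne_G: float
    Ne_R: float
    Ne_U: float
    Ne_P: float
    Ne_B: float
    t_GRUBP: float
    t_GR: float
    t_UPB: float
    m: float = 0.0

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES[:8]:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 < self.t_GR <= self.t_GRUBP:
            raise ValidationError("need 0 < t_GR <= t_GRUBP")
        if not 0 < self.t_UPB <= self.t_GRUBP:
            raise ValidationError("need 0 < t_UPB <= t_GRUBP")
        if self.m < 0:
            raise ValidationError("migration rate must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_NAMES])

    @classmethod
    def from_mapping(cls, values: Mapping[str, float]) -> "ParameterVector":
        return cls(**{n: float(values[n]) for n in PARAMETER_NAMES if n in values})


@dataclass(frozen=True)
class ModelConfig:
    """Simulation configuration independent of the demographic parameters."""

    generation_time: float = 29.0
    mutation_rate: float = 1.25e-8
    recombination_rate: float = 1e-8
    sequence_length: float = 5e6
    samples_per_region: Mapping[str, int] = field(
        default_factory=lambda: {"G": 6, "R": 6, "U": 6, "P": 6, "B": 5}
    )
    seed: int = 1

    def __post_init__(self) -> None:
        if self.generation_time <= 0:
            raise ConfigurationError("generation_time must be > 0")
        if set(self.samples_per_region) != set(REGIONS):
            raise ConfigurationError(
                f"samples_per_region keys must be {set(REGIONS)}"
            )


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes with sample metadata.

    ``haplotypes`` is a (2N, L) matrix of 0/1 alleles with the two
    haplotypes of sample ``i`` in rows ``2i`` and ``2i+1``; ``positions``
    are strictly increasing 0-based bp coordinates; ``coords`` are planar
    km per sample.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    sample_ids: list[str]
    region_labels: list[str]
    coords: np.ndarray
    sequence_length: float | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n = len(self.sample_ids)
        if self.haplotypes.shape[0] != 2 * n:
            raise ValidationError("expected exactly 2 haplotypes per sample")
        if len(self.region_labels) != n or len(self.coords) != n:
            raise ValidationError("metadata length mismatch")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValidationError("haplotype/position length mismatch")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValidationError("positions must be strictly increasing")
        if self.haplotypes.size and (
            self.haplotypes.min() < 0 or self.haplotypes.max() > 1
        ):
            raise ValidationError("alleles must be in {0, 1}")
        self.coords = np.asarray(self.coords, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def dosages(self) -> np.ndarray:
        """(N, L) diploid alternate-allele dosages in {0, 1, 2}."""
        h = self.haplotypes.astype(np.int16)
        return (h[0::2] + h[1::2]).astype(np.int8)

    def region_index(self, region: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.region_labels) == region)

    def subset_samples(self, idx: Sequence[int]) -> "HaplotypePanel":
        idx = np.asarray(idx, dtype=int)
        hap_rows = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
        hap = self.haplotypes[hap_rows]
        keep = hap.sum(axis=0) > 0
        keep &= hap.sum(axis=0) < hap.shape[0]
        return HaplotypePanel(
            haplotypes=hap[:, keep],
            positions=self.positions[keep],
            sample_ids=[self.sample_ids[i] for i in idx],
            region_labels=[self.region_labels[i] for i in idx],
            coords=self.coords[idx],
            sequence_length=self.sequence_length,
        )


@dataclass
class DosagePanel:
    """Unphased diploid dosages in {0, 1, 2}, -1 for missing."""

    dosages: np.ndarray
    positions: np.ndarray
    sample_ids: list[str]
    region_labels: list[str] | None = None
    coords: np.ndarray | None = None


def sample_priors(
    priors: Iterable[PriorSpec] = DEFAULT_PRIORS,
    seed: int | np.random.Generator = 0,
) -> ParameterVector:
    """Draw one parameter vector from the prior.

    Symbolic upper bounds are resolved against values already drawn in this
    call; priors must therefore be resolvable in some order (no cycles).
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    pending = list(priors)
    drawn: dict[str, float] = {}
    while pending:
        progressed = False
        deferred = []
        for spec in pending:
            if isinstance(spec.high, str):
                if spec.high not in drawn:
                    deferred.append(spec)
                    continue
                high = drawn[spec.high]
                if not spec.low <= high:
                    raise ConfigurationError(
                        f"prior {spec.name}: resolved bound {spec.high}="
                        f"{high} is not above low {spec.low}"
                    )
            else:
                high = float(spec.high)
            if spec.dist == "loguniform":
                drawn[spec.name] = math.exp(
                    rng.uniform(math.log(spec.low), math.log(high))
                )
            else:
                drawn[spec.name] = rng.uniform(spec.low, high)
            progressed = True
        if not progressed and deferred:
            names = ", ".join(s.name for s in deferred)
            raise ConfigurationError(
                f"unresolvable symbolic prior bounds (cycle or missing "
                f"parameter): {names}"
            )
        pending = deferred
    missing = [n for n in PARAMETER_NAMES[:-1] if n not in drawn]
    if missing:
        raise ConfigurationError(f"priors missing parameters: {missing}")
    return ParameterVector.from_mapping(drawn)


def sample_priors_batch(
    n: int,
    priors: Iterable[PriorSpec] = DEFAULT_PRIORS,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, list[str]]:
    """Vectorized prior sampling: (n, n_params) matrix plus column names.

    Symbolic upper bounds are resolved row-wise against the referenced
    parameter's draws; draw order follows dependency resolution exactly as
    in :func:`sample_priors`.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    pending = list(priors)
    drawn: dict[str, np.ndarray] = {}
    order: list[str] = []
    while pending:
        deferred = []
        progressed = False
        for spec in pending:
            if isinstance(spec.high, str):
                if spec.high not in drawn:
                    deferred.append(spec)
                    continue
                high = drawn[spec.high]
                if np.any(high < spec.low):
                    raise ConfigurationError(
                        f"prior {spec.name}: resolved bound below low"
                    )
            else:
                high = float(spec.high)
            if spec.dist == "loguniform":
                drawn[spec.name] = np.exp(
                    rng.uniform(math.log(spec.low), np.log(high), size=n)
                )
            else:
                drawn[spec.name] = rng.uniform(spec.low, high, size=n)
            order.append(spec.name)
            progressed = True
        if not progressed and deferred:
            names = ", ".join(s.name for s in deferred)
            raise ConfigurationError(
                f"unresolvable symbolic prior bounds: {names}"
            )
        pending = deferred
    names = [n_ for n_ in PARAMETER_NAMES if n_ in drawn]
    return np.column_stack([drawn[n_] for n_ in names]), names


def years_to_generations(years: float, generation_time: float = 29.0) -> int:
    """Convert years before present to the nearest whole generation."""
    if years < 0:
        raise ValidationError("times must be non-negative")
    return int(round(years / generation_time))


def build_demography(
    params: ParameterVector, generation_time: float = 29.0
) -> msprime.Demography:
    """msprime demography for the (((G,R)GR,((U,P,B)UPB)GRUBP model.

    Sizes are haploid chromosome counts, so msprime's diploid population
    sizes are Ne/2. Migration is symmetric between all pairs of terminal
    populations while they exist.
    """
    dem = msprime.Demography()
    for r in REGIONS:
        dem.add_population(
            name=r, initial_size=getattr(params, f"Ne_{r}") / 2.0
        )
    dem.add_population(name="GR", initial_size=params.Ne_GR / 2.0)
    dem.add_population(name="UPB", initial_size=params.Ne_UPB / 2.0)
    dem.add_population(name="GRUBP", initial_size=params.Ne_GRUBP / 2.0)
    if params.m > 0:
        for i, a in enumerate(REGIONS):
            for b in REGIONS[i + 1 :]:
                dem.set_symmetric_migration_rate([a, b], params.m)
    t_gr = years_to_generations(params.t_GR, generation_time)
    t_upb = years_to_generations(params.t_UPB, generation_time)
    t_root = years_to_generations(params.t_GRUBP, generation_time)
    if t_gr > t_root or t_upb > t_root:
        raise ValidationError("split-time ordering violated after rounding")
    dem.add_population_split(time=t_gr, derived=["G", "R"], ancestral="GR")
    dem.add_population_split(
        time=t_upb, derived=["U", "P", "B"], ancestral="UPB"
    )
    dem.add_population_split(
        time=t_root, derived=["GR", "UPB"], ancestral="GRUBP"
    )
    dem.sort_events()
    return dem


def _panel_from_ts(
    ts, sample_ids: list[str], region_labels: list[str], coords: np.ndarray
) -> HaplotypePanel:
    """Extract segregating biallelic 0/1 sites from a tree sequence."""
    haps = []
    positions = []
    for var in ts.variants():
        g = var.genotypes
        if len(var.alleles) > 2:
            continue
        if g.max() == g.min():  # not segregating after recurrent mutation
            continue
        haps.append(g.astype(np.int8))
        positions.append(int(var.site.position))
    if haps:
        hap_matrix = np.stack(haps, axis=1)
        pos = np.array(positions, dtype=np.int64)
        keep = np.ones(len(pos), dtype=bool)
        keep[1:] = np.diff(pos) > 0
        hap_matrix = hap_matrix[:, keep]
        pos = pos[keep]
    else:
        hap_matrix = np.zeros((2 * len(sample_ids), 0), dtype=np.int8)
        pos = np.zeros(0, dtype=np.int64)
    return HaplotypePanel(
        haplotypes=hap_matrix,
        positions=pos,
        sample_ids=sample_ids,
        region_labels=region_labels,
        coords=coords,
        sequence_length=ts.sequence_length,
    )


def simulate_dataset(
    params: ParameterVector, config: ModelConfig
) -> HaplotypePanel:
    """Simulate one phased diploid panel under the demographic model.

    Returns only segregating biallelic sites. Bit-reproducible for a fixed
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)
    dem = build_demography(params, config.generation_time)
    samples = [
        msprime.SampleSet(config.samples_per_region[r], population=r)
        for r in REGIONS
    ]
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=config.sequence_length,
        recombination_rate=config.recombination_rate,
        ploidy=2,
        random_seed=int(anc_seed),
    )
    if config.mutation_rate > 0:
        ts = msprime.sim_mutations(
            ts,
            rate=config.mutation_rate,
            model=msprime.BinaryMutationModel(),
            random_seed=int(mut_seed),
        )
    sample_ids: list[str] = []
    region_labels: list[str] = []
    coords = []
    for r in REGIONS:
        for i in range(config.samples_per_region[r]):
            sample_ids.append(f"{r}{i + 1}")
            region_labels.append(r)
            coords.append(DEFAULT_REGION_COORDS[r])
    return _panel_from_ts(ts, sample_ids, region_labels, np.array(coords))


def panmictic_params(ne: float, m: float = 0.0) -> ParameterVector:
    """Parameters that collapse the model to a single population of size ne.

    All splits are placed one generation in the past and every deme has the
    same size, so the sample behaves as a panmictic population of ``ne``
    chromosomes (used for closed-form checks and null datasets).
    """
    return ParameterVector(
        Ne_GRUBP=ne, Ne_GR=ne, Ne_UPB=ne, Ne_G=ne, Ne_R=ne, Ne_U=ne,
        Ne_P=ne, Ne_B=ne, t_GRUBP=29.0, t_GR=29.0, t_UPB=29.0, m=m,
    )


# ---------------------------------------------------------------------------
# VCF and sample-map I/O


def write_vcf(panel: HaplotypePanel, path) -> None:
    """Write the panel as an uncompressed VCFv4.2 with phased GT fields.

    Internal coordinates are 0-based; VCF POS is 1-based.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=finescale\n")
        length = int(panel.sequence_length or (panel.positions[-1] + 1 if panel.n_sites else 1))
        fh.write(f"##contig=<ID=1,length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        hap = panel.haplotypes
        for j, pos in enumerate(panel.positions):
            gts = "\t".join(
                f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}"
                for i in range(panel.n_samples)
            )
            fh.write(f"1\t{pos + 1}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_sample_map(panel: HaplotypePanel, path) -> None:
    """TSV with columns sample_id, region, x_km, y_km."""
    with open(path, "w") as fh:
        fh.write("sample_id\tregion\tx_km\ty_km\n")
        for i, sid in enumerate(panel.sample_ids):
            fh.write(
                f"{sid}\t{panel.region_labels[i]}\t"
                f"{panel.coords[i, 0]}\t{panel.coords[i, 1]}\n"
            )


def read_sample_map(path) -> dict[str, tuple[str, float, float]]:
    out: dict[str, tuple[str, float, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: k for k, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            out[parts[idx["sample_id"]]] = (
                parts[idx["region"]],
                float(parts[idx["x_km"]]),
                float(parts[idx["y_km"]]),
            )
    return out


def read_vcf(
    path,
    region_map: Mapping[str, tuple[str, float, float]] | str | None = None,
    unphased_ok: bool = False,
) -> HaplotypePanel | DosagePanel:
    """Read biallelic SNVs from a VCF into a panel.

    Non-biallelic records are skipped (the count is logged). With
    ``unphased_ok=False`` all genotypes must be phased and complete and a
    :class:`HaplotypePanel` is returned; otherwise a :class:`DosagePanel`
    of dosages is returned, with half-calls and missing genotypes coded -1.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    haps: list[np.ndarray] = []
    doses: list[np.ndarray] = []
    positions: list[int] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.REF or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = var.genotypes  # rows [allele0, allele1, phased]
        row_h = np.empty(2 * n, dtype=np.int8)
        row_d = np.empty(n, dtype=np.int8)
        ok_phased = True
        for i, gt in enumerate(gts):
            a, b = int(gt[0]), int(gt[1])
            phased = bool(gt[2])
            if a < 0 or b < 0:
                row_d[i] = -1
                ok_phased = False
            else:
                row_d[i] = a + b
                row_h[2 * i], row_h[2 * i + 1] = a, b
                if not phased and a != b:
                    ok_phased = False
        if not ok_phased and not unphased_ok:
            raise PhasingError(
                f"unphased or incomplete genotype at position {var.POS}; "
                "pass unphased_ok=True for dosage-only analyses"
            )
        positions.append(var.POS - 1)
        haps.append(row_h)
        doses.append(row_d)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic records", n_skipped)
    regions: list[str] | None = None
    coords = None
    if region_map is not None:
        if isinstance(region_map, str):
            region_map = read_sample_map(region_map)
        regions = [region_map[s][0] for s in sample_ids]
        coords = np.array([[region_map[s][1], region_map[s][2]] for s in sample_ids])
    pos = np.array(positions, dtype=np.int64)
    if unphased_ok:
        panel = DosagePanel(
            dosages=np.stack(doses, axis=1) if doses else np.zeros((n, 0), np.int8),
            positions=pos,
            sample_ids=sample_ids,
            region_labels=regions,
            coords=coords,
        )
        panel.n_skipped = n_skipped  # type: ignore[attr-defined]
        return panel
    panel = HaplotypePanel(
        haplotypes=np.stack(haps, axis=1) if haps else np.zeros((2 * n, 0), np.int8),
        positions=pos,
        sample_ids=sample_ids,
        region_labels=regions if regions is not None else [""] * n,
        coords=coords if coords is not None else np.zeros((n, 2)),
    )
    panel.n_skipped = n_skipped  # type: ignore[attr-defined]
    return panel


# ---------------------------------------------------------------------------
# Fixtures with known ground truth


@dataclass
class PlantedRohFixture:
    """Diploid dosages with homozygous tracts planted at known coordinates."""

    dosages: np.ndarray  # (n_samples, L)
    positions: np.ndarray
    tracts: list[tuple[int, int]]  # 0-based half-open bp intervals
    sequence_length: int


@dataclass
class CoancestryFixture:
    """Symmetric coancestry-like matrix with known cluster labels."""

    matrix: np.ndarray
    sample_ids: list[str]
    true_labels: np.ndarray


@dataclass
class LatticeFixture:
    """Coordinates and a coancestry matrix from the barrier model itself."""

    coords: np.ndarray
    region_labels: list[str]
    sample_ids: list[str]
    matrix: np.ndarray
    partition: dict[str, int]
    params: dict


def _make_planted_roh(params: Mapping, rng: np.random.Generator) -> PlantedRohFixture:
    length = int(params.get("sequence_length", 5_000_000))
    n_sites = int(params.get("n_sites", 5000))
    n_samples = int(params.get("n_samples", 1))
    het_rate = float(params.get("het_rate", 0.35))
    tracts = [tuple(map(int, t)) for t in params.get("tracts", [(1_000_000, 3_000_000)])]
    for start, end in tracts:
        if end <= start:
            raise ValidationError(f"non-positive tract length: ({start}, {end})")
    positions = np.sort(rng.choice(length, size=n_sites, replace=False)).astype(np.int64)
    dosages = np.empty((n_samples, n_sites), dtype=np.int8)
    for s in range(n_samples):
        draws = rng.random(n_sites)
        geno = np.where(draws < het_rate, 1, np.where(rng.random(n_sites) < 0.5, 0, 2))
        in_tract = np.zeros(n_sites, dtype=bool)
        for start, end in tracts:
            in_tract |= (positions >= start) & (positions < end)
        hom = np.where(rng.random(n_sites) < 0.5, 0, 2).astype(np.int8)
        geno = np.where(in_tract, hom, geno)
        dosages[s] = geno
    return PlantedRohFixture(dosages, positions, tracts, length)


def _make_two_cluster(params: Mapping, rng: np.random.Generator) -> CoancestryFixture:
    n_per = int(params.get("n_per_cluster", 10))
    within = float(params.get("within_mean", 2.0))
    between = float(params.get("between_mean", 1.0))
    noise = float(params.get("noise_sd", 0.05))
    n = 2 * n_per
    labels = np.repeat([0, 1], n_per)
    mean = np.where(labels[:, None] == labels[None, :], within, between)
    mat = mean + rng.normal(0.0, noise, size=(n, n))
    mat = (mat + mat.T) / 2.0
    mat = np.abs(mat)
    np.fill_diagonal(mat, 0.0)
    ids = [f"c{labels[i]}_{i}" for i in range(n)]
    return CoancestryFixture(mat, ids, labels)


def _make_anisotropic_lattice(params: Mapping, rng: np.random.Generator) -> LatticeFixture:
    # The matrix is produced by the barrier model's own forward predictor so
    # that a noise-free fixture is exactly representable by the fit.
    from . import barriers

    nx = int(params.get("nx", 6))
    ny = int(params.get("ny", 4))
    spacing = float(params.get("spacing", 10.0))
    theta = params.get("theta", (0.3, 1.2))
    rho = params.get("rho", (2.0, 1.5))
    scale = params.get("scale", (0.05, 0.05))
    barrier = float(params.get("barrier", 1.0))
    beta0 = float(params.get("beta0", 1.0))
    beta1 = float(params.get("beta1", 1.0))
    noise = float(params.get("noise_sd", 0.0))
    if barrier < 0:
        raise ValidationError("barrier must be >= 0")
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing)
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    # Two pseudo-regions split across the lattice's x midpoint.
    cut = coords[:, 0].mean()
    groups = (coords[:, 0] > cut).astype(int)
    region_labels = [("W", "E")[g] for g in groups]
    partition = {"W": 0, "E": 1}
    fit = barriers.BarrierModelFit(
        partition=partition,
        groups=[
            barriers.SpatialGroup({"W"}, float(theta[0]), float(rho[0]), float(scale[0])),
            barriers.SpatialGroup({"E"}, float(theta[1]), float(rho[1]), float(scale[1])),
        ],
        barrier={(0, 1): barrier},
        beta0=beta0,
        beta1=beta1,
        lam=1.0,
        fit_score=0.0,
        p_value=None,
    )
    mat = barriers.predict_coancestry(fit, coords, np.array(region_labels))
    if noise > 0:
        pert = rng.normal(0.0, noise, size=mat.shape)
        pert = (pert + pert.T) / 2.0
        mat = mat + pert
    np.fill_diagonal(mat, 0.0)
    ids = [f"s{i}" for i in range(len(coords))]
    return LatticeFixture(
        coords=coords,
        region_labels=region_labels,
        sample_ids=ids,
        matrix=mat,
        partition=partition,
        params={
            "theta": tuple(theta), "rho": tuple(rho), "scale": tuple(scale),
            "barrier": barrier, "beta0": beta0, "beta1": beta1,
        },
    )


_FIXTURE_MAKERS = {
    "planted_roh": _make_planted_roh,
    "two_cluster_coancestry": _make_two_cluster,
    "anisotropic_lattice": _make_anisotropic_lattice,
}


def make_fixture(kind: str, params: Mapping | None = None, seed: int = 0):
    """Build a ground-truth fixture of the requested ``kind``.

    Kinds: ``planted_roh`` (dosages with known homozygous tracts),
    ``two_cluster_coancestry`` (block-structured symmetric matrix),
    ``anisotropic_lattice`` (coordinates plus a coancestry matrix generated
    by the barrier model's own predictor).
    """
    if kind not in _FIXTURE_MAKERS:
        raise ConfigurationError(
            f"unknown fixture kind {kind!r}; expected one of {sorted(_FIXTURE_MAKERS)}"
        )
    return _FIXTURE_MAKERS[kind](params or {}, np.random.default_rng(seed))
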