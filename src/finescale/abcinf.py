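"""Approximate Bayesian computation for the five-population model.

Simulations drawn from the prior are reduced to a fixed vector of classical
summaries (per-region folded SFS, heterozygosity, pairwise Hudson F_ST,
short-range LD and RoH totals). A small feed-forward regressor maps
summaries to parameter predictions and rejection sampling is carried out in
that learned-summary space (with a raw-summary path available); posteriors
are reported as mean, median, half-range mode, 95% equal-tailed credible
interval and 89% highest-density interval, with split times in years before
present (29 years per generation by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import diversity
from .exceptions import ValidationError
from .simdata import (
    DEFAULT_PRIORS,
    PARAMETER_NAMES,
    REGIONS,
    HaplotypePanel,
    ModelConfig,
    ParameterVector,
    PriorSpec,
    sample_priors,
    simulate_dataset,
)

logger = logging.getLogger(__name__)


@dataclass
class SummaryConfig:
    """Which summaries are computed and at what resolution."""

    hr_bin_edges: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 5e4, 2e5, 1e6])
    )
    hr_max_sites: int = 150
    min_maf: float = 0.05
    maf_tolerance: float = 0.05
    roh_params: diversity.RoHParams = field(
        default_factory=lambda: diversity.RoHParams(
            window_snvs=30, max_het_per_window=1, min_length_bp=5e5,
            min_snvs=30, max_gap_bp=1e5,
        )
    )


@dataclass
class SummaryVector:
    """Fixed-order summary vector with component names."""

    values: np.ndarray
    names: list[str]
    monomorphic: bool = False


def hudson_fst(
    dosages_a: np.ndarray, dosages_b: np.ndarray
) -> float:
    """Hudson's F_ST (ratio-of-sums over sites) from two dosage blocks.

    Returns 0.0 when no site is informative (flagged by the caller).
    """
    da = np.asarray(dosages_a, dtype=float)
    db = np.asarray(dosages_b, dtype=float)
    n1 = 2.0 * da.shape[0]
    n2 = 2.0 * db.shape[0]
    p1 = da.sum(axis=0) / n1
    p2 = db.sum(axis=0) / n2
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    informative = den > 0
    if not informative.any():
        return 0.0
    return float(num[informative].sum() / den[informative].sum())


def _folded_sfs(dosages: np.ndarray) -> np.ndarray:
    """Normalized folded SFS over minor-allele counts 1..n_hap//2."""
    n_hap = 2 * dosages.shape[0]
    alt = dosages.sum(axis=0)
    seg = (alt > 0) & (alt < n_hap)
    minor = np.minimum(alt[seg], n_hap - alt[seg]).astype(int)
    counts = np.bincount(minor, minlength=n_hap // 2 + 1)[1 : n_hap // 2 + 1]
    total = counts.sum()
    if total == 0:
        return np.zeros(n_hap // 2)
    return counts / total


def summarize_panel(
    panel: HaplotypePanel, config: SummaryConfig | None = None
) -> SummaryVector:
    """Deterministic summary vector of a five-region panel.

    Monomorphic panels yield an all-zero vector with the ``monomorphic``
    flag set (undefined F_ST entries are encoded as 0).
    """
    config = config or SummaryConfig()
    present = set(panel.region_labels)
    missing = [r for r in REGIONS if r not in present]
    if missing:
        raise ValidationError(f"panel is missing regions: {missing}")
    dos = panel.dosages().astype(float)
    values: list[float] = []
    names: list[str] = []
    region_dos = {r: dos[panel.region_index(r)] for r in REGIONS}
    monomorphic = panel.n_sites == 0
    for r in REGIONS:
        sfs = (
            _folded_sfs(region_dos[r])
            if panel.n_sites
            else np.zeros(region_dos[r].shape[0])
        )
        values.extend(sfs.tolist())
        names.extend(f"sfs_{r}_{i + 1}" for i in range(len(sfs)))
    for r in REGIONS:
        d = region_dos[r]
        if panel.n_sites:
            n_hap = 2 * d.shape[0]
            alt = d.sum(axis=0)
            seg = (alt > 0) & (alt < n_hap)
            het = float((d[:, seg] == 1).mean()) if seg.any() else 0.0
        else:
            het = 0.0
        values.append(het)
        names.append(f"het_{r}")
    for i, a in enumerate(REGIONS):
        for b in REGIONS[i + 1 :]:
            fst = (
                hudson_fst(region_dos[a], region_dos[b])
                if panel.n_sites
                else 0.0
            )
            values.append(fst)
            names.append(f"fst_{a}_{b}")
    ld_conf = diversity.LDConfig(
        maf_tolerance=config.maf_tolerance,
        min_maf=config.min_maf,
        bin_edges=config.hr_bin_edges,
        max_sites=config.hr_max_sites,
    )
    for r in REGIONS:
        if panel.n_sites:
            curve = diversity.ld_decay(region_dos[r], panel.positions, ld_conf)
            hr = np.nan_to_num(curve.mean_hr, nan=0.0)
        else:
            hr = np.zeros(len(config.hr_bin_edges) - 1)
        values.extend(hr.tolist())
        names.extend(
            f"hr_{r}_bin{i + 1}" for i in range(len(config.hr_bin_edges) - 1)
        )
    for r in REGIONS:
        idx = panel.region_index(r)
        if panel.n_sites:
            totals = diversity.roh_totals(
                dos[idx], panel.positions,
                [panel.sample_ids[i] for i in idx],
                params=config.roh_params,
            )
            values.append(float(totals.mean()))
        else:
            values.append(0.0)
        names.append(f"roh_{r}")
    vec = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(vec)):
        raise ValidationError("non-finite summary entries")
    return SummaryVector(values=vec, names=names, monomorphic=monomorphic)


# ---------------------------------------------------------------------------
# Learned summaries ("ABC-DL-lite")


@dataclass
class SummaryRegressor:
    """Feed-forward mapping from summaries to parameter predictions."""

    net: object
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    kept_columns: np.ndarray
    loss_trace: list[float]

    def predict(self, summaries: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(summaries, dtype=float))
        x = (x[:, self.kept_columns] - self.x_mean) / self.x_sd
        y = self.net.predict(x)
        return np.atleast_2d(y) * self.y_sd + self.y_mean


def train_summary_regressor(
    params: np.ndarray,
    summaries: np.ndarray,
    hidden: tuple[int, ...] = (64, 64),
    epochs: int = 300,
    seed: int = 0,
) -> SummaryRegressor:
    """Train the summaries -> parameters regressor on standardized data.

    Constant summary columns are dropped with a warning. Training is
    seed-reproducible (single-threaded L-BFGS-free adam via scikit-learn).
    """
    from sklearn.neural_network import MLPRegressor

    x = np.asarray(summaries, dtype=float)
    y = np.asarray(params, dtype=float)
    if x.shape[0] < 200:
        raise ValidationError("need >=200 training simulations")
    sd = x.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    if len(kept) < x.shape[1]:
        logger.warning(
            "train_summary_regressor: dropping %d constant summary columns",
            x.shape[1] - len(kept),
        )
    if len(kept) == 0:
        raise ValidationError("all summary columns are constant")
    x_mean, x_sd = x[:, kept].mean(axis=0), x[:, kept].std(axis=0)
    y_mean, y_sd = y.mean(axis=0), y.std(axis=0)
    y_sd = np.where(y_sd > 0, y_sd, 1.0)
    xs = (x[:, kept] - x_mean) / x_sd
    ys = (y - y_mean) / y_sd
    net = MLPRegressor(
        hidden_layer_sizes=hidden,
        max_iter=epochs,
        random_state=seed,
        early_stopping=False,
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(xs, ys)
    return SummaryRegressor(
        net=net,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        kept_columns=kept,
        loss_trace=list(net.loss_curve_),
    )


# ---------------------------------------------------------------------------
# Rejection sampling and posterior summaries


@dataclass
class PosteriorSample:
    """Accepted parameter draws with their summary-space distances."""

    params: np.ndarray  # (n_accept, n_params) in PARAMETER_NAMES order
    distances: np.ndarray
    tolerance: float
    accepted_indices: np.ndarray

    def column(self, name: str) -> np.ndarray:
        return self.params[:, PARAMETER_NAMES.index(name)]


def abc_reject(
    observed: np.ndarray,
    sim_params: np.ndarray,
    sim_summaries: np.ndarray,
    regressor: SummaryRegressor | None = None,
    accept_fraction: float = 0.05,
) -> PosteriorSample:
    """Rejection ABC in (optionally learned) summary space.

    Each retained dimension is standardized by its SD over the simulations;
    distance is Euclidean and the lowest ``accept_fraction`` quantile of
    simulations is accepted.
    """
    if not 0 < accept_fraction <= 1:
        raise ValidationError("accept_fraction must be in (0, 1]")
    sim_params = np.asarray(sim_params, dtype=float)
    sim_summaries = np.asarray(sim_summaries, dtype=float)
    observed = np.asarray(observed, dtype=float)
    n = sim_summaries.shape[0]
    if n == 0:
        raise ValidationError("no simulations supplied")
    if regressor is not None:
        space_sims = regressor.predict(sim_summaries)
        space_obs = regressor.predict(observed[None, :])[0]
    else:
        space_sims = sim_summaries
        space_obs = observed
    sd = space_sims.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "abc_reject: dropping %d zero-variance dimensions",
            int((~keep).sum()),
        )
    if not keep.any():
        raise ValidationError("all summary dimensions are constant")
    z_sims = (space_sims[:, keep] - space_obs[keep]) / sd[keep]
    dist = np.sqrt((z_sims**2).sum(axis=1))
    n_accept = int(math.floor(accept_fraction * n))
    if n_accept < 1:
        raise ValidationError(
            f"accept_fraction {accept_fraction} accepts zero of {n} sims"
        )
    order = np.argsort(dist, kind="stable")[:n_accept]
    return PosteriorSample(
        params=sim_params[order],
        distances=dist[order],
        tolerance=float(dist[order][-1]),
        accepted_indices=order,
    )


@dataclass
class PosteriorSummary:
    """Location and interval summaries of one parameter's posterior."""

    mean: float
    median: float
    half_range_mode: float
    ci_low: float
    ci_high: float
    hdi_low: float
    hdi_high: float


def half_range_mode(values: Sequence[float]) -> float:
    """Iterative modal-interval halving mode estimator.

    Repeatedly keep the half-range window (anchored at an observed value)
    containing the most points, preferring the leftmost window on ties,
    until at most two values remain; return their mean.
    """
    x = np.sort(np.asarray(values, dtype=float))
    while len(x) > 2:
        rng = x[-1] - x[0]
        if rng == 0:
            return float(x[0])
        w = rng / 2.0
        hi = np.searchsorted(x, x + w, side="right")
        counts = hi - np.arange(len(x))
        best = int(np.argmax(counts))  # leftmost maximal window
        x = x[best : hi[best]]
    return float(x.mean())


def highest_density_interval(
    values: Sequence[float], mass: float = 0.89
) -> tuple[float, float]:
    """Shortest contiguous interval of sorted values holding ``mass``."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    m = int(math.ceil(mass * n))
    m = min(max(m, 1), n)
    widths = x[m - 1 :] - x[: n - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])


def posterior_summaries(values: Sequence[float]) -> PosteriorSummary:
    """Mean, median, half-range mode, 95% CI and 89% HDI of a sample."""
    x = np.asarray(values, dtype=float)
    if len(x) < 10:
        raise ValidationError("need >=10 posterior values")
    lo, hi = np.quantile(x, [0.025, 0.975])
    hdi_lo, hdi_hi = highest_density_interval(x, 0.89)
    return PosteriorSummary(
        mean=float(x.mean()),
        median=float(np.median(x)),
        half_range_mode=half_range_mode(x),
        ci_low=float(lo),
        ci_high=float(hi),
        hdi_low=hdi_lo,
        hdi_high=hdi_hi,
    )


def convert_times(
    values: Sequence[float],
    generation_time: float = 29.0,
    direction: str = "years_to_generations",
) -> np.ndarray:
    """Convert split times between years and generations (rounded)."""
    if generation_time <= 0:
        raise ValidationError("generation_time must be > 0")
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValidationError("times must be non-negative")
    if direction == "years_to_generations":
        return np.round(x / generation_time).astype(int)
    if direction == "generations_to_years":
        return x * generation_time
    raise ValidationError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass
class ABCConfig:
    """Scale and reproducibility knobs of the ABC pipeline."""

    n_train: int = 2000
    n_abc: int = 1000
    accept_fraction: float = 0.05
    seed: int = 1
    model: ModelConfig = field(default_factory=ModelConfig)
    priors: tuple[PriorSpec, ...] = DEFAULT_PRIORS
    summaries: SummaryConfig = field(default_factory=SummaryConfig)
    use_net: bool = True
    hidden: tuple[int, ...] = (64, 64)
    epochs: int = 300


def _param_targets(params: np.ndarray) -> np.ndarray:
    """Regression targets: raw sizes/times, log10 migration rate."""
    out = params.copy()
    m_col = PARAMETER_NAMES.index("m")
    out[:, m_col] = np.log10(np.maximum(out[:, m_col], 1e-12))
    return out


def simulate_reference_table(
    n: int,
    priors: Sequence[PriorSpec],
    model: ModelConfig,
    summaries: SummaryConfig,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` prior simulations; returns (params, summaries) matrices."""
    rng = np.random.default_rng(seed)
    params_rows = []
    summary_rows = []
    for _ in range(n):
        theta = sample_priors(priors, rng)
        sim_seed = int(rng.integers(1, 2**31 - 1))
        panel = simulate_dataset(
            theta,
            ModelConfig(
                generation_time=model.generation_time,
                mutation_rate=model.mutation_rate,
                recombination_rate=model.recombination_rate,
                sequence_length=model.sequence_length,
                samples_per_region=model.samples_per_region,
                seed=sim_seed,
            ),
        )
        params_rows.append(theta.as_array())
        summary_rows.append(summarize_panel(panel, summaries).values)
    return np.asarray(params_rows), np.asarray(summary_rows)


def _prior_label(spec: PriorSpec) -> str:
    high = spec.high if isinstance(spec.high, str) else f"{spec.high:g}"
    tag = "logU" if spec.dist == "loguniform" else "U"
    return f"{tag} ({spec.low:g}, {high})"


def run_abc_pipeline(
    observed: HaplotypePanel, config: ABCConfig | None = None
) -> tuple[pd.DataFrame, PosteriorSample]:
    """Full inference: priors -> simulate -> summarize -> learn -> reject.

    Returns the posterior-summary report (one row per demographic
    parameter, times in years) and the accepted posterior sample.
    """
    config = config or ABCConfig()
    rng = np.random.default_rng(config.seed)
    try:
        obs_summary = summarize_panel(observed, config.summaries).values
    except Exception as e:  # pragma: no cover - context labelling
        raise RuntimeError("ABC stage 'summarize observed' failed") from e
    try:
        train_params, train_summaries = simulate_reference_table(
            config.n_train, config.priors, config.model, config.summaries,
            int(rng.integers(1, 2**31 - 1)),
        )
    except Exception as e:
        raise RuntimeError("ABC stage 'training simulations' failed") from e
    regressor = None
    if config.use_net:
        try:
            regressor = train_summary_regressor(
                _param_targets(train_params),
                train_summaries,
                hidden=config.hidden,
                epochs=config.epochs,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        except Exception as e:
            raise RuntimeError("ABC stage 'regressor training' failed") from e
    try:
        abc_params, abc_summaries = simulate_reference_table(
            config.n_abc, config.priors, config.model, config.summaries,
            int(rng.integers(1, 2**31 - 1)),
        )
    except Exception as e:
        raise RuntimeError("ABC stage 'ABC simulations' failed") from e
    posterior = abc_reject(
        obs_summary,
        abc_params,
        abc_summaries,
        regressor=regressor,
        accept_fraction=config.accept_fraction,
    )
    prior_by_name = {p.name: p for p in config.priors}
    rows = []
    for name in PARAMETER_NAMES[:11]:
        s = posterior_summaries(posterior.column(name))
        rows.append(
            {
                "parameter": name,
                "prior": _prior_label(prior_by_name[name]),
                "mean": s.mean,
                "median": s.median,
                "half_range_mode": s.half_range_mode,
                "ci_2.5": s.ci_low,
                "ci_97.5": s.ci_high,
                "hdi_low": s.hdi_low,
                "hdi_high": s.hdi_high,
            }
        )
    report = pd.DataFrame(rows)
    return report, posterior
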