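"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a genome-wide single-gene-knockout screen on a
circular bacterial chromosome: a gene annotation with essential flags and
flat functional-category codes; wild-type expression (log10 RPKM) carrying a
sinusoidal positional component plus gene-specific effects; per-gene true
knockout growth rates negatively coupled to expression, with a phase-locked
sign-reversed positional component; and logistic plate-reader OD600 curves
with a well-location bias on the carrying capacity only.

Every stage is deterministic given the config seed, and the coupling
strength between expression and knockout growth is calibrated numerically so
the realized Spearman correlation matches the configured target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigError, PlacementError
from .growth import GrowthCurve, serpentine_index
from .periodicity import gene_midpoints_kb

__all__ = [
    "MediumSpec",
    "SyntheticConfig",
    "generate_annotation",
    "generate_expression",
    "generate_growth_truth",
    "generate_plate_curves",
    "default_layout",
]

# flat functional-category codes in the Riley style: e = enzyme,
# t = transporter, r = regulator, f = factor, s = structural component,
# cp = cell process, c = carrier, m = membrane, l = leader, d = dna-related,
# o = unknown orf, p* = putative variants
_DEFAULT_CATEGORIES = (
    ("e", 0.20), ("t", 0.08), ("r", 0.05), ("f", 0.04), ("s", 0.03),
    ("cp", 0.04), ("c", 0.02), ("m", 0.02), ("l", 0.01), ("d", 0.02),
    ("o", 0.12), ("pc", 0.03), ("pe", 0.06), ("pf", 0.04), ("ph", 0.02),
    ("pl", 0.02), ("pm", 0.05), ("pr", 0.05), ("pt", 0.10),
)


@dataclass(frozen=True)
class MediumSpec:
    """Growth medium with its wild-type kinetics and expression baseline."""

    name: str
    mu_wt: float                 # wild-type exponential rate, h^-1
    carrying_capacity: float     # saturation OD600
    expr_baseline: float = 2.0   # log10 RPKM center


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic knockout screen.

    Defaults mirror a genome-scale E. coli knockout library: a 4,632-kb
    circular genome, ~4,200 genes of which ~7% are essential (leaving ~3,900
    knockout strains), a six-period positional harmonic, and a target
    expression-growth Spearman correlation of -0.37.
    """

    genome_length_kb: int = 4632
    n_genes: int = 4200
    essential_fraction: float = 0.072
    categories: tuple[tuple[str, float], ...] = _DEFAULT_CATEGORIES
    n_periods: int = 6
    positional_phase: float = 0.0                 # radians
    positional_amplitude_expr: float = 0.15       # log10 RPKM
    positional_amplitude_growth: float = 0.02     # h^-1
    target_rho: float = -0.37
    media: tuple[MediumSpec, ...] = (
        MediumSpec("LB", mu_wt=1.30, carrying_capacity=1.00),
        MediumSpec("M63", mu_wt=0.50, carrying_capacity=0.60),
    )
    n_replicates: int = 3
    sampling_interval_h: float = 0.5
    duration_h: float = 24.0
    initial_od: float = 0.01
    blank_od: float = 0.05
    well_bias_slope: float = 0.0                  # OD per serpentine well index
    expr_gene_sd: float = 0.40                    # gene-specific effect, log10 RPKM
    expr_noise_sd: float = 0.10                   # replicate noise, log10 RPKM
    growth_noise_sd: float = 0.03                 # residual on true mu, h^-1
    rate_replicate_sd: float = 0.02               # replicate jitter on mu, h^-1
    od_noise_sd: float = 0.003                    # OD600 measurement noise
    diff_fraction: float = 0.0                    # genes shifted in media[1]
    diff_shift: float = 0.0                       # log10 RPKM shift for those genes
    planted_slow_category: str | None = None      # category given depressed mu
    planted_slow_delta: float = 0.0               # h^-1 depression
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length_kb <= 0:
            raise ConfigError("genome_length_kb must be positive")
        if not 0 <= self.essential_fraction < 1:
            raise ConfigError("essential_fraction must be in [0, 1)")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not -1 <= self.target_rho <= 0:
            raise ConfigError("target_rho must be in [-1, 0]")
        for sd in (self.expr_gene_sd, self.expr_noise_sd, self.growth_noise_sd,
                   self.rate_replicate_sd, self.od_noise_sd):
            if sd < 0:
                raise ConfigError("noise standard deviations must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not self.media:
            raise ConfigError("at least one medium required")
        if self.initial_od <= 0:
            raise ConfigError("initial_od must be positive")

    def medium(self, name: str) -> MediumSpec:
        for m in self.media:
            if m.name == name:
                return m
        raise ConfigError(f"unknown medium {name!r}")

    def medium_index(self, name: str) -> int:
        return [m.name for m in self.media].index(self.medium(name).name)


def _rng(config: SyntheticConfig, *stream: int) -> np.random.Generator:
    """Independent deterministic stream per generation stage."""
    return np.random.default_rng([config.seed, *stream])


_MIN_GENE_KB = 0.1


def generate_annotation(config: SyntheticConfig) -> pd.DataFrame:
    """Gene annotation with uniformly scattered midpoints on the circle.

    Returns a frame with columns ``gene, start_bp, end_bp, strand, essential,
    category`` (1-based inclusive bp coordinates) and ``genome_length_kb`` in
    ``attrs``.
    """
    L = config.genome_length_kb
    if config.n_genes * _MIN_GENE_KB > L:
        raise PlacementError(
            f"{config.n_genes} genes of >= {_MIN_GENE_KB} kb cannot be placed "
            f"on a {L}-kb genome"
        )
    rng = _rng(config, 0)
    mids_kb = rng.uniform(0.0, L, size=config.n_genes)
    mids_kb.sort()
    lengths_kb = np.clip(rng.normal(0.95, 0.25, size=config.n_genes), _MIN_GENE_KB, 3.0)
    start_bp = (np.round((mids_kb - lengths_kb / 2) * 1000).astype(int)) % (L * 1000) + 1
    end_bp = (start_bp - 1 + np.round(lengths_kb * 1000).astype(int) - 1) % (L * 1000) + 1
    strand = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    essential = rng.random(config.n_genes) < config.essential_fraction
    labels = [c for c, _ in config.categories]
    weights = np.array([w for _, w in config.categories], dtype=float)
    weights = weights / weights.sum()
    category = rng.choice(labels, size=config.n_genes, p=weights)
    ann = pd.DataFrame(
        {
            "gene": [f"g{i:04d}" for i in range(config.n_genes)],
            "start_bp": start_bp,
            "end_bp": end_bp,
            "strand": strand,
            "essential": essential,
            "category": category,
        }
    )
    ann.attrs["genome_length_kb"] = L
    return ann


def _positional_cosine(config: SyntheticConfig, mids_kb: np.ndarray) -> np.ndarray:
    theta = 2.0 * np.pi * config.n_periods * mids_kb / config.genome_length_kb
    return np.cos(theta + config.positional_phase)


def generate_expression(
    annotation: pd.DataFrame, config: SyntheticConfig, medium: str
) -> pd.DataFrame:
    """Wild-type expression table (log10 RPKM) for one medium.

    Per gene at circular midpoint x:
    ``baseline + A_e*cos(2*pi*k*x/L + phi) + gene effect + replicate noise``.
    Gene effects are medium-independent; a configurable fraction of genes
    additionally receives a ``diff_shift`` in media beyond the first, to
    plant differential expression with known labels.
    """
    spec = config.medium(medium)
    m_idx = config.medium_index(medium)
    mids = gene_midpoints_kb(annotation, config.genome_length_kb)
    positional = config.positional_amplitude_expr * _positional_cosine(config, mids)

    n = len(annotation)
    gene_effects = _rng(config, 1).normal(0.0, config.expr_gene_sd, size=n)
    base = spec.expr_baseline + positional + gene_effects

    if m_idx > 0 and config.diff_fraction > 0 and config.diff_shift != 0:
        n_diff = int(round(config.diff_fraction * n))
        which = _rng(config, 2).choice(n, size=n_diff, replace=False)
        signs = np.where(_rng(config, 3).random(n_diff) < 0.5, 1.0, -1.0)
        base = base.copy()
        base[which] = base[which] + signs * config.diff_shift

    noise_rng = _rng(config, 4, m_idx)
    reps = {
        f"rep{r + 1}": base + noise_rng.normal(0.0, config.expr_noise_sd, size=n)
        for r in range(config.n_replicates)
    }
    table = pd.DataFrame({"gene": annotation["gene"].to_numpy(), "medium": medium, **reps})
    rep_cols = [c for c in table.columns if c.startswith("rep")]
    table["mean"] = table[rep_cols].mean(axis=1)
    table.attrs["genome_length_kb"] = config.genome_length_kb
    return table


_BETA_MAX = 2.0        # h^-1 per log10 RPKM; far beyond any realistic coupling
_RHO_TOL = 0.01        # bisection convergence on the realized correlation


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ra = pd.Series(a).rank().to_numpy()
    rb = pd.Series(b).rank().to_numpy()
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra**2).sum() * (rb**2).sum())
    if denom == 0:
        return 0.0
    return float((ra * rb).sum() / denom)


def generate_growth_truth(
    annotation: pd.DataFrame,
    expression: pd.DataFrame,
    config: SyntheticConfig,
    medium: str,
) -> pd.DataFrame:
    """Per-gene true knockout growth rates coupled to expression.

    ``mu_g = mu_wt - A_g*cos(2*pi*k*x/L + phi) - beta*(E_g - baseline) + eps``
    where ``E_g`` is the gene's mean expression.  ``beta`` is calibrated by
    bisection so the realized Spearman correlation between mean expression
    and ``mu`` over the non-essential genes lands within the configured
    target; Spearman under mixed signal and noise has no closed form, so the
    calibration is numeric on the generated sample.  Essential genes carry a
    true ``mu`` but stay flagged for downstream exclusion or zeroing.
    """
    spec = config.medium(medium)
    m_idx = config.medium_index(medium)
    if not np.array_equal(annotation["gene"].to_numpy(), expression["gene"].to_numpy()):
        raise ConfigError("expression table does not match the annotation")

    mids = gene_midpoints_kb(annotation, config.genome_length_kb)
    positional = config.positional_amplitude_growth * _positional_cosine(config, mids)
    expr_dev = expression["mean"].to_numpy() - spec.expr_baseline
    eps = _rng(config, 5, m_idx).normal(0.0, config.growth_noise_sd, size=len(annotation))
    nonessential = ~annotation["essential"].to_numpy(dtype=bool)

    planted = np.zeros(len(annotation))
    if config.planted_slow_category is not None:
        in_cat = annotation["category"].to_numpy() == config.planted_slow_category
        planted = np.where(in_cat, config.planted_slow_delta, 0.0)

    def mu_of(beta: float) -> np.ndarray:
        return spec.mu_wt - positional - beta * expr_dev + eps - planted

    def rho_of(beta: float) -> float:
        mu = mu_of(beta)
        return _spearman(expr_dev[nonessential], mu[nonessential])

    lo, hi = -_BETA_MAX, _BETA_MAX
    rho_lo, rho_hi = rho_of(lo), rho_of(hi)  # rho decreasing in beta
    target = config.target_rho
    if not (rho_hi - _RHO_TOL <= target <= rho_lo + _RHO_TOL):
        raise CalibrationError(
            f"target_rho={target} unreachable; feasible range is "
            f"[{rho_hi:.3f}, {rho_lo:.3f}] for |beta| <= {_BETA_MAX}"
        )
    beta = 0.0
    for _ in range(80):
        beta = 0.5 * (lo + hi)
        rho = rho_of(beta)
        if abs(rho - target) <= _RHO_TOL:
            break
        if rho > target:
            lo = beta
        else:
            hi = beta

    truth = pd.DataFrame(
        {
            "gene": annotation["gene"].to_numpy(),
            "medium": medium,
            "true_mu": mu_of(beta),
            "essential": annotation["essential"].to_numpy(),
            "category": annotation["category"].to_numpy(),
        }
    )
    truth.attrs["beta"] = float(beta)
    truth.attrs["realized_rho"] = rho_of(beta)
    truth.attrs["mu_wt"] = spec.mu_wt
    return truth


def default_layout(
    strains: list[str], medium: str, n_replicates: int, wells_per_plate: int = 96
) -> pd.DataFrame:
    """Assign strain replicates to plate wells, replicates in different wells.

    Wells fill row-major (A1..A12, B1..B12, ...); the last well of every
    plate is reserved for a medium blank.  Each replicate series starts from
    a rotated strain order so a strain never sits in the same well twice.
    """
    rows = "ABCDEFGH"
    n_cols = 12
    if wells_per_plate > len(rows) * n_cols:
        raise ConfigError("wells_per_plate exceeds an 8x12 plate")
    usable = wells_per_plate - 1  # last well is the blank
    well_names = [f"{rows[i // n_cols]}{i % n_cols + 1}" for i in range(wells_per_plate)]
    records = []
    n = len(strains)
    for rep in range(1, n_replicates + 1):
        # rotate so replicate r of a strain lands in a different well
        order = strains[(rep - 1) % max(n, 1):] + strains[: (rep - 1) % max(n, 1)]
        for i, strain in enumerate(order):
            plate = f"{medium}-rep{rep}-p{i // usable + 1}"
            records.append(
                {
                    "plate": plate,
                    "well": well_names[i % usable],
                    "strain": strain,
                    "medium": medium,
                    "replicate": rep,
                }
            )
        n_plates = (n + usable - 1) // usable
        for p in range(1, n_plates + 1):
            records.append(
                {
                    "plate": f"{medium}-rep{rep}-p{p}",
                    "well": well_names[-1],
                    "strain": "BLANK",
                    "medium": medium,
                    "replicate": rep,
                }
            )
    return pd.DataFrame.from_records(records)


def generate_plate_curves(
    truth: pd.DataFrame, config: SyntheticConfig, layout: pd.DataFrame
) -> list[GrowthCurve]:
    """Logistic OD600 curves for every mapped strain well.

    ``OD(t) = K_w / (1 + ((K_w - OD0)/OD0) * exp(-mu t)) + blank + noise``
    with ``K_w = K + well_bias_slope * serpentine_index(well)`` — the
    well-location bias acts on the carrying capacity only, never on ``mu``.
    Measurement noise is additive Gaussian truncated at the blank floor
    (plate readers bottom out at the blank).  Strains with ``mu <= 0`` stay
    flat at the inoculum.  Wells mapped to strain ``BLANK`` are emitted as
    flat blank-level series so written plate CSVs carry them for the
    reader's per-plate blank estimate.
    """
    medium_names = {m.name for m in config.media}
    dup = layout[layout["strain"] != "BLANK"].duplicated(subset=["plate", "well"])
    if dup.any():
        raise ConfigError("layout assigns multiple strains to one well")
    mu_by_gene = dict(zip(truth["gene"], truth["true_mu"]))
    times = np.arange(0.0, config.duration_h + 1e-9, config.sampling_interval_h)
    curves: list[GrowthCurve] = []
    for i, row in enumerate(layout.itertuples(index=False)):
        if row.strain == "BLANK":
            od = np.full_like(times, config.blank_od)
            if config.od_noise_sd > 0:
                od = od + _rng(config, 7, i).normal(0.0, config.od_noise_sd, times.size)
            curves.append(
                GrowthCurve(
                    strain="BLANK", medium=row.medium, replicate=int(row.replicate),
                    plate=row.plate, well=row.well, times=times.copy(),
                    od=np.maximum(od, 0.0), blank=config.blank_od,
                )
            )
            continue
        if row.medium not in medium_names:
            raise ConfigError(f"layout references unknown medium {row.medium!r}")
        spec = config.medium(row.medium)
        m_idx = config.medium_index(row.medium)
        gene_idx = int(row.strain[1:]) if row.strain.startswith("g") else 0
        rng = _rng(config, 6, m_idx, gene_idx, int(row.replicate))
        mu = mu_by_gene[row.strain] + rng.normal(0.0, config.rate_replicate_sd)
        k_w = spec.carrying_capacity + config.well_bias_slope * serpentine_index(row.well)
        od0 = config.initial_od
        if mu > 0:
            growth = k_w / (1.0 + ((k_w - od0) / od0) * np.exp(-mu * times))
        else:
            growth = np.full_like(times, od0)
        od = growth + config.blank_od
        if config.od_noise_sd > 0:
            od = od + rng.normal(0.0, config.od_noise_sd, size=times.size)
        od = np.maximum(od, config.blank_od)
        curves.append(
            GrowthCurve(
                strain=row.strain,
                medium=row.medium,
                replicate=int(row.replicate),
                plate=row.plate,
                well=row.well,
                times=times.copy(),
                od=od,
                blank=config.blank_od,
            )
        )
    return curves
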