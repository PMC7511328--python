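"""Circular-genome positional signals, Fourier periodogram and Fisher's g test.

Per-gene values (knockout growth rates, wild-type expression levels, or gene
counts) are summarised as a sliding-window mean over a circular chromosome:
one anchor per kilobase, each window covering the 100 kb downstream of its
anchor.  The smoothed series is mean-subtracted and Fourier transformed;
spectral power at harmonic ``k`` corresponds to a wavelength of ``L/k`` kb
(``L`` = genome length).  Significance of the dominant harmonic is assessed
with Fisher's exact g test, and the dominant sinusoid is recovered in closed
form from the corresponding Fourier coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import UndefinedStatisticError

__all__ = [
    "PositionalSignal",
    "PeriodogramResult",
    "sliding_window_mean",
    "positional_signal",
    "periodogram",
    "fisher_g_test",
    "fit_sinusoid",
    "dominant_period",
    "essential_density_correlation",
    "gene_midpoints_kb",
]


@dataclass
class PositionalSignal:
    """Per-1-kb circular series of window means of a per-gene quantity.

    ``values[a]`` is the mean over genes whose midpoint falls in the circular
    half-open window ``[a, a + window_kb)`` kb; ``n_contributing[a]`` counts
    those genes.  Empty windows are filled according to ``fill_policy``.
    """

    values: np.ndarray
    genome_length_kb: int
    bin_step_kb: int = 1
    window_kb: int = 100
    n_contributing: np.ndarray | None = None
    fill_policy: str = "global_mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.genome_length_kb % self.bin_step_kb != 0:
            raise UndefinedStatisticError(
                "genome_length_kb must be a multiple of bin_step_kb"
            )
        n_anchors = self.genome_length_kb // self.bin_step_kb
        if self.values.shape != (n_anchors,):
            raise UndefinedStatisticError(
                f"expected {n_anchors} anchors, got {self.values.shape}"
            )

    @property
    def n_anchors(self) -> int:
        return self.values.size


@dataclass
class PeriodogramResult:
    """One-sided periodogram plus (optionally) the dominant-harmonic summary."""

    k: np.ndarray                    # harmonic index 1..N//2
    wavelength_kb: np.ndarray        # genome_length / k
    power: np.ndarray                # |F_k|^2 / N
    genome_length_kb: int
    dominant_k: int | None = None
    g: float | None = None
    g_pvalue: float | None = None
    amplitude: float | None = None
    phase: float | None = None
    offset: float | None = None
    k1_excluded: bool = False
    residual_ss: float | None = None

    @property
    def dominant_wavelength_kb(self) -> float:
        if self.dominant_k is None:
            raise UndefinedStatisticError("dominant harmonic not determined")
        return self.genome_length_kb / self.dominant_k

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k, "wavelength_kb": self.wavelength_kb, "power": self.power}
        )


def gene_midpoints_kb(annotation: pd.DataFrame, genome_length_kb: int) -> np.ndarray:
    """Circular midpoint of each gene in kb on ``[0, L)``.

    Coordinates are 1-based inclusive bp.  Genes wrapping the origin
    (``end_bp < start_bp``) get their midpoint computed modulo the genome
    length.
    """
    length_bp = genome_length_kb * 1000
    start = annotation["start_bp"].to_numpy(dtype=float) - 1.0  # 0-based
    end = annotation["end_bp"].to_numpy(dtype=float)            # exclusive
    span = np.mod(end - start, length_bp)
    span = np.where(span == 0, length_bp, span)
    mid_bp = np.mod(start + span / 2.0, length_bp)
    return mid_bp / 1000.0


def _window_sums(per_bin: np.ndarray, window_bins: int) -> np.ndarray:
    """Circular forward-looking window sum: out[a] = sum(x[a : a+W]) mod N."""
    n = per_bin.size
    padded = np.concatenate([per_bin, per_bin[: window_bins - 1]])
    csum = np.concatenate([[0.0], np.cumsum(padded)])
    return csum[window_bins : window_bins + n] - csum[:n]


def sliding_window_mean(
    values: np.ndarray, window_bins: int
) -> np.ndarray:
    """Circular moving average over the half-open window ``[a, a+W)``."""
    values = np.asarray(values, dtype=float)
    if not 1 <= window_bins <= values.size:
        raise UndefinedStatisticError("window must be in [1, len(values)]")
    return _window_sums(values, window_bins) / window_bins


def positional_signal(
    annotation: pd.DataFrame,
    values: pd.Series | dict | None,
    mode: str = "essential_zero",
    *,
    genome_length_kb: int,
    window_kb: int = 100,
    bin_step_kb: int = 1,
    fill_policy: str = "global_mean",
) -> PositionalSignal:
    """Window-mean positional signal of a per-gene quantity.

    Parameters
    ----------
    annotation
        Gene table with ``gene``, ``start_bp``, ``end_bp`` and ``essential``
        columns.
    values
        Per-gene values indexed (or keyed) by gene id.  Ignored when
        ``mode='density'``.
    mode
        ``'essential_zero'`` — essential genes enter with value 0 (their
        knockout is lethal, i.e. zero growth), non-essential genes with their
        recorded value; ``'nonessential_only'`` — essential genes are dropped;
        ``'density'`` — count genes per window instead of averaging (used for
        the essential-gene density track when the annotation passed in is
        pre-filtered to essential genes).
    """
    if len(annotation) == 0:
        raise UndefinedStatisticError("empty annotation")
    if bin_step_kb != 1:
        # anchors are laid every bin_step kb; window arithmetic below assumes
        # integer bins, so the window must be a multiple of the step
        if window_kb % bin_step_kb != 0:
            raise UndefinedStatisticError("window_kb must be a multiple of bin_step_kb")
    n_anchors = genome_length_kb // bin_step_kb
    window_bins = window_kb // bin_step_kb

    ann = annotation
    essential = ann["essential"].to_numpy(dtype=bool)
    mids = gene_midpoints_kb(ann, genome_length_kb)

    if mode == "density":
        gene_vals = np.ones(len(ann))
        keep = np.ones(len(ann), dtype=bool)
    else:
        if values is None:
            raise UndefinedStatisticError(f"mode {mode!r} requires per-gene values")
        series = pd.Series(values)
        aligned = series.reindex(ann["gene"])
        gene_vals = aligned.to_numpy(dtype=float)
        if mode == "essential_zero":
            gene_vals = np.where(essential, 0.0, gene_vals)
            keep = np.ones(len(ann), dtype=bool)
        elif mode == "nonessential_only":
            keep = ~essential
        else:
            raise UndefinedStatisticError(f"unknown mode {mode!r}")
        keep = keep & np.isfinite(gene_vals)

    mids = mids[keep]
    gene_vals = gene_vals[keep]
    bins = np.floor(mids / bin_step_kb).astype(int) % n_anchors

    count_per_bin = np.bincount(bins, minlength=n_anchors).astype(float)
    sum_per_bin = np.bincount(bins, weights=gene_vals, minlength=n_anchors)
    n_window = _window_sums(count_per_bin, window_bins)
    sum_window = _window_sums(sum_per_bin, window_bins)

    if mode == "density":
        sig = n_window.copy()
    else:
        with np.errstate(invalid="ignore"):
            sig = np.where(n_window > 0, sum_window / np.maximum(n_window, 1), np.nan)
        empty = n_window == 0
        if empty.any():
            if fill_policy == "global_mean":
                sig[empty] = np.nanmean(sig[~empty])
            elif fill_policy == "zero":
                sig[empty] = 0.0
            else:
                raise UndefinedStatisticError(f"unknown fill policy {fill_policy!r}")
    return PositionalSignal(
        values=sig,
        genome_length_kb=genome_length_kb,
        bin_step_kb=bin_step_kb,
        window_kb=window_kb,
        n_contributing=n_window,
        fill_policy=fill_policy,
    )


def periodogram(signal: PositionalSignal) -> PeriodogramResult:
    """One-sided periodogram of the mean-subtracted signal.

    Power at harmonic ``k`` is ``|F_k|^2 / N`` with ``F`` the unnormalised
    discrete Fourier transform.  With this scaling Parseval's identity reads
    ``2*sum(power[k<N/2]) + power[N/2]*(N even) = sum((x - mean(x))^2)``.
    """
    x = signal.values - signal.values.mean()
    n = x.size
    coeffs = np.fft.rfft(x)
    k = np.arange(1, n // 2 + 1)
    power = np.abs(coeffs[1 : n // 2 + 1]) ** 2 / n
    return PeriodogramResult(
        k=k,
        wavelength_kb=signal.genome_length_kb / k.astype(float),
        power=power,
        genome_length_kb=signal.genome_length_kb,
    )


# terms larger than this cannot be summed safely in float64; they only occur
# deep in the null bulk where the exact tail probability is ~1
_FISHER_G_LOG_TERM_MAX = 30.0


def fisher_g_test(powers: np.ndarray) -> tuple[float, float]:
    """Fisher's exact test for a hidden periodicity.

    ``g`` is the largest periodogram ordinate divided by the sum of ordinates.
    The exact null tail probability is

        p = sum_{j=1}^{floor(1/g)} (-1)^(j-1) C(n, j) (1 - j*g)^(n-1)

    with ``n`` the number of positive-frequency ordinates, clipped to [0, 1].
    """
    powers = np.asarray(powers, dtype=float)
    n = powers.size
    if n < 2:
        raise UndefinedStatisticError("Fisher's g needs >= 2 ordinates")
    total = powers.sum()
    if total <= 0 or not np.isfinite(total):
        raise UndefinedStatisticError("all-zero or non-finite spectrum")
    g = float(powers.max() / total)
    jmax = min(n, int(np.floor(1.0 / g + 1e-12)))
    j = np.arange(1, jmax + 1)
    base = 1.0 - j * g
    valid = base > 0
    log_terms = np.full(j.shape, -np.inf)
    log_terms[valid] = (
        gammaln(n + 1)
        - gammaln(j[valid] + 1)
        - gammaln(n - j[valid] + 1)
        + (n - 1) * np.log(base[valid])
    )
    if log_terms.max() > _FISHER_G_LOG_TERM_MAX:
        return g, 1.0
    terms = np.exp(log_terms) * (-1.0) ** (j - 1)
    p = float(np.clip(terms.sum(), 0.0, 1.0))
    return g, p


def fit_sinusoid(signal: PositionalSignal, k: int) -> tuple[float, float, float]:
    """Least-squares fit of ``m + A*cos(2*pi*k*x/L + phi)`` to the signal.

    Because the harmonics are orthogonal on the regular circular grid, the
    least-squares solution is closed-form from the k-th Fourier coefficient:
    ``A = 2|c_k|/N``, ``phi = arg(c_k)``, ``m = mean``.
    """
    if k < 1:
        raise UndefinedStatisticError("harmonic index must be >= 1")
    x = signal.values
    n = x.size
    c_k = np.fft.rfft(x - x.mean())[k] if k <= n // 2 else 0.0
    amplitude = 2.0 * np.abs(c_k) / n
    phase = float(np.angle(c_k))
    offset = float(x.mean())
    return float(amplitude), phase, offset


def dominant_period(
    signal: PositionalSignal, exclude_k1: bool = True
) -> PeriodogramResult:
    """Dominant harmonic of the signal with Fisher's g and the fitted sinusoid.

    The full-genome harmonic (k = 1, wavelength = L) is excluded by default:
    a peak there reflects the genome's full length rather than a repeating
    chromosomal period.  Ties go to the smaller ``k``.
    """
    pg = periodogram(signal)
    if not np.any(pg.power > 0):
        raise UndefinedStatisticError("flat spectrum: dominant harmonic undefined")
    power = pg.power.copy()
    if exclude_k1:
        if power.size < 2:
            raise UndefinedStatisticError("cannot exclude k=1 from a 1-ordinate spectrum")
        power[0] = -np.inf
    dominant_k = int(pg.k[np.argmax(power)])  # argmax returns first max -> smaller k
    g, p = fisher_g_test(pg.power)
    amplitude, phase, offset = fit_sinusoid(signal, dominant_k)

    theta = 2.0 * np.pi * dominant_k * np.arange(signal.n_anchors) / signal.n_anchors
    fitted = offset + amplitude * np.cos(theta + phase)
    residual_ss = float(np.sum((signal.values - fitted) ** 2))
    pg.dominant_k = dominant_k
    pg.g = g
    pg.g_pvalue = p
    pg.amplitude = amplitude
    pg.phase = phase
    pg.offset = offset
    pg.k1_excluded = exclude_k1
    pg.residual_ss = residual_ss
    return pg


def essential_density_correlation(
    value_signal: PositionalSignal, density_signal: PositionalSignal
) -> tuple[float, float]:
    """Pearson correlation between two positional signals over the anchors.

    Typically the window-mean knockout growth rates against the window count
    of essential genes.
    """
    a = value_signal.values
    b = density_signal.values
    if a.size != b.size:
        raise UndefinedStatisticError("signals have mismatched lengths")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatisticError("constant signal: correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
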