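"""Periodicity analysis of valve-angle series.

The dominant period of a multi-day valve-gape record is identified from the
discrete Fourier periodogram of time-binned means, and its significance is
assessed with Fisher's exact g-test: g is the largest periodogram ordinate
divided by the sum of all tested ordinates, whose null distribution under
Gaussian white noise is known in closed form.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import fsum

import numpy as np
from scipy.special import gammaln

from .tag import ValveAngleSeries

__all__ = ["PeriodogramResult", "periodogram", "fisher_g_test"]


@dataclass
class PeriodogramResult:
    """Periodogram ordinates and the Fisher g-test of the largest one.

    Frequencies are in cycles per hour; ordinates use the one-sided
    normalization in which their sum equals n times the variance of the
    binned series (Parseval).
    """

    frequencies: np.ndarray
    ordinates: np.ndarray
    m: int
    dominant_period_h: float
    g: float
    p_value: float

    @property
    def periods_h(self) -> np.ndarray:
        return 1.0 / self.frequencies


def fisher_g_test(ordinates: np.ndarray) -> tuple[float, float]:
    """Fisher's exact test for a hidden periodicity.

    ``g = max(I) / sum(I)`` over m periodogram ordinates; under the Gaussian
    white-noise null the exact tail probability is

        p = sum_{j=1}^{floor(1/g)} (-1)^(j-1) C(m, j) (1 - j g)^(m-1),

    evaluated with log-binomial terms.  When the alternating series is
    numerically unusable (it only is when g is within a hair of its minimum
    1/m, where negative association of the normalized ordinates bounds p
    above 1 - 1e-13), p = 1 is returned.
    """
    I = np.asarray(ordinates, dtype=float)
    m = len(I)
    if m < 2:
        raise ValueError("need at least 2 ordinates")
    total = I.sum()
    if total <= 0:
        raise ValueError("ordinates are all zero")
    if I.min() < 0:
        raise ValueError("ordinates must be nonnegative")
    g = float(I.max() / total)

    # Dirichlet components are negatively associated, so
    # P(all < g) <= prod P(W_i < g) = (1 - q)^m with q = (1-g)^(m-1);
    # when that bound pins p to 1 at double precision, skip the series.
    q = np.exp((m - 1) * np.log1p(-g)) if g < 1.0 else 0.0
    if q > 0 and m * np.log1p(-min(q, 1 - 1e-300)) < -30:
        return g, 1.0

    jmax = min(m, int(np.floor(1.0 / g)))
    terms = []
    for j in range(1, jmax + 1):
        base = 1.0 - j * g
        if base <= 0.0:
            break
        log_t = (gammaln(m + 1) - gammaln(j + 1) - gammaln(m - j + 1)
                 + (m - 1) * np.log(base))
        terms.append((-1.0) ** (j - 1) * np.exp(log_t))
    p = fsum(terms) if terms else 0.0
    return g, float(min(1.0, max(0.0, p)))


def periodogram(angles: ValveAngleSeries, bin_minutes: float = 10.0) -> PeriodogramResult:
    """Fourier periodogram of a binned valve-angle series.

    The series is trimmed to whole days (so the Fourier grid contains the
    24 h period exactly), averaged into ``bin_minutes`` bins, mean-removed,
    and transformed at the Fourier frequencies.  Ordinates are restricted to
    periods between twice the bin width and half the record length; the
    dominant period is the reciprocal of the frequency of the largest
    ordinate, and its significance comes from :func:`fisher_g_test`.

    Missing samples (NaN) are tolerated up to 5% of bins and mean-imputed.
    """
    fs = angles.fs
    n_day = int(round(86400 * fs))
    n_whole = (angles.n // n_day) * n_day
    if n_whole < 3 * n_day:
        raise ValueError("record must span at least 3 whole days")
    x = angles.angle[:n_whole]

    bin_n = int(round(bin_minutes * 60 * fs))
    if bin_n < 1:
        raise ValueError("bin shorter than one sample")
    nbins = n_whole // bin_n
    binned = x[: nbins * bin_n].reshape(nbins, bin_n)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        xb = np.nanmean(binned, axis=1)
    nan_bins = ~np.isfinite(xb)
    if nan_bins.any():
        if nan_bins.mean() > 0.05:
            raise ValueError("more than 5% of bins are empty")
        xb[nan_bins] = np.nanmean(xb)
    if np.var(xb) == 0:
        raise ValueError("constant series has no periodicity")

    xb = xb - xb.mean()
    n = len(xb)
    bin_h = bin_minutes / 60.0
    X = np.fft.rfft(xb)
    k = np.arange(1, n // 2 + 1)
    # one-sided ordinates normalized so their sum ~= n * variance
    I = 2.0 * np.abs(X[1: n // 2 + 1]) ** 2 / n
    if n % 2 == 0:
        I[-1] /= 2.0  # Nyquist appears once
    freqs_cph = k / (n * bin_h)  # cycles per hour
    T_h = n * bin_h

    keep = (1.0 / freqs_cph >= 2.0 * bin_h) & (1.0 / freqs_cph <= T_h / 2.0)
    freqs_cph = freqs_cph[keep]
    I = I[keep]
    m = len(I)
    if m < 2:
        raise ValueError("too few ordinates in the tested period range")
    g, p = fisher_g_test(I)
    dominant = float(1.0 / freqs_cph[int(np.argmax(I))])
    return PeriodogramResult(frequencies=freqs_cph, ordinates=I, m=m,
                             dominant_period_h=dominant, g=g, p_value=p)
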