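"""Cohort-level statistics on assigned spike signatures.

Covers the population-level tests used to compare mouse groups: enrichment of
a signature within its origin group (2x2 chi-square), pairwise comparison of
signature proportions between groups (pooled two-proportion z-test, no
continuity correction), one-way ANOVA with Tukey-Kramer post hoc tests on
per-cell skewness, and accelerometer tremor peak power from a Hann-windowed
periodogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .core_io import SIGNATURES

__all__ = [
    "CohortSummary",
    "AccelTrace",
    "two_proportion_z",
    "enrichment_chi_square",
    "anova_tukey",
    "tremor_peak_power",
    "proportion_table",
]


@dataclass
class CohortSummary:
    """Origin-group x assigned-signature contingency table."""

    counts: pd.DataFrame  # rows: origin groups, columns: signatures

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def from_assignments(cls, origins, signatures) -> "CohortSummary":
        df = pd.crosstab(pd.Series(origins, name="origin"),
                         pd.Series(signatures, name="signature"))
        # Fixed column order; keep any extra origin groups as given.
        cols = [s for s in SIGNATURES if s in df.columns] + [
            c for c in df.columns if c not in SIGNATURES]
        return cls(df[cols])

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class AccelTrace:
    """Accelerometer samples from the tremor monitor (arbitrary units)."""

    samples: np.ndarray
    sampling_rate: float  # Hz; must exceed 60 Hz to resolve the 0-30 Hz band

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 60.0:
            raise ValueError("sampling_rate must exceed 60 Hz")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test without continuity correction.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion;
    returns (z, two-sided normal p-value).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not (0 <= x <= n):
            raise ValueError("need 0 <= x <= n and n > 0")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("pooled proportion is degenerate (0 or 1); z set to 0")
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def enrichment_chi_square(summary: CohortSummary, origin_group: str,
                          signature: str) -> tuple[float, float]:
    """2x2 chi-square (df=1, no continuity correction) for enrichment of one
    signature in one origin group versus the rest of the population."""
    c = summary.counts
    if origin_group not in c.index:
        raise KeyError(f"unknown origin group {origin_group!r}")
    if signature not in c.columns:
        raise KeyError(f"unknown signature {signature!r}")
    in_g = c.loc[origin_group]
    out_g = c.sum(axis=0) - in_g
    table = np.array([
        [in_g[signature], in_g.sum() - in_g[signature]],
        [out_g[signature], out_g.sum() - out_g[signature]],
    ], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("a margin of the 2x2 table is zero; expected counts undefined")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


@dataclass
class AnovaTukeyResult:
    F: float
    p: float
    tukey: pd.DataFrame  # columns: group1, group2, diff, p_adj


def anova_tukey(groups: dict[str, np.ndarray]) -> AnovaTukeyResult:
    """One-way ANOVA followed by Tukey-Kramer HSD for unequal group sizes.

    Degenerate all-identical data yields F = 0 and all adjusted p = 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")

    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0:  # all observations identical
        pairs = [(names[i], names[j], 0.0, 1.0)
                 for i in range(len(names)) for j in range(i + 1, len(names))]
        return AnovaTukeyResult(0.0, 1.0, pd.DataFrame(
            pairs, columns=["group1", "group2", "diff", "p_adj"]))

    F, p = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append((names[i], names[j],
                         float(arrays[i].mean() - arrays[j].mean()),
                         float(res.pvalue[i, j])))
    return AnovaTukeyResult(float(F), float(p),
                            pd.DataFrame(rows, columns=["group1", "group2",
                                                        "diff", "p_adj"]))


def tremor_peak_power(trace: AccelTrace, band_hz: tuple[float, float] = (0.0, 30.0)
                      ) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Peak of the Hann-windowed periodogram on the tremor band.

    The signal is mean-removed and a single full-segment periodogram is taken
    (power spectral density scaling, so total power integrates to the signal
    variance). The peak is the maximum on (0, 30] Hz - the zero-frequency bin
    is excluded. Returns (peak_power, peak_frequency_hz, (freqs, psd)).
    """
    if trace.duration < 2.0:
        raise ValueError("trace shorter than 2 s")
    freqs, psd = signal.periodogram(trace.samples, fs=trace.sampling_rate,
                                    window="hann", detrend="constant",
                                    scaling="density")
    in_band = (freqs > band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        raise ValueError("no frequency bins inside the search band")
    k = np.flatnonzero(in_band)[np.argmax(psd[in_band])]
    return float(psd[k]), float(freqs[k]), (freqs, psd)


def proportion_table(summary: CohortSummary) -> pd.DataFrame:
    """Row-normalized signature proportions; all-zero rows stay zero."""
    c = summary.counts.astype(float)
    totals = c.sum(axis=1)
    out = c.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    zero_rows = totals[totals == 0].index.tolist()
    if zero_rows:
        warnings.warn(f"zero-count origin group(s): {zero_rows}")
    return out
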