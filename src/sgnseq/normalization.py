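"""Within- and between-sample normalization: CPM, TPM and TMM factors.

CPM (counts per million) divides each count by its library size; TPM
(transcripts per million) first divides by gene length so that values are
comparable across genes. TMM (trimmed mean of M-values) estimates a
between-sample scaling factor from precision-weighted log-ratios after
trimming the most extreme genes, so that a handful of highly differential
genes does not distort the library-size normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .design import StudyDesign
from .io import CountMatrix


@dataclass
class NormFactors:
    """Per-sample TMM factors and library sizes.

    Factors are dimensionless, positive, and rescaled so their geometric
    mean is 1; the effective library size is ``lib_size * factor``.
    """

    factors: pd.Series
    lib_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        if (self.lib_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


def compute_cpm(m: CountMatrix, eff_lib: pd.Series | NormFactors | None = None) -> pd.DataFrame:
    """Counts per million per sample.

    With ``eff_lib`` omitted, raw column sums are used and every column
    sums to exactly 1e6. A :class:`NormFactors` gives TMM-effective sizes.
    """
    if eff_lib is None:
        lib = m.lib_sizes.astype(float)
    elif isinstance(eff_lib, NormFactors):
        lib = eff_lib.effective_lib_sizes.astype(float)
    else:
        lib = eff_lib.astype(float)
    lib = lib.reindex(m.sample_ids)
    if (lib <= 0).any() or lib.isna().any():
        raise ValueError("library sizes must be positive for all samples")
    return m.counts.div(lib, axis=1) * 1e6


def compute_tpm(m: CountMatrix, lengths: pd.Series | None = None) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates rescaled per sample."""
    if lengths is None:
        lengths = m.lengths
    if lengths is None:
        raise ValueError("gene lengths are required for TPM")
    lengths = lengths.reindex(m.counts.index)
    missing = lengths.index[lengths.isna()].tolist()
    if missing:
        raise ValueError(f"missing length for counted gene(s): {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = m.counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    denom = denom.where(denom > 0, 1.0)  # all-zero sample stays all-zero
    return rate.div(denom, axis=1) * 1e6


def group_means(x: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Arithmetic per-group mean of a per-sample matrix, per gene."""
    cols = {}
    for grp in design.groups:
        members = design.samples_in(grp)
        if not members:
            raise ValueError(f"group {grp!r} has no samples")
        cols[grp] = x[members].mean(axis=1)
    return pd.DataFrame(cols)


@dataclass
class ExpressionSummary:
    """Per-sample and per-group CPM/TPM used by gates, filters and QC."""

    cpm: pd.DataFrame
    tpm: pd.DataFrame
    cpm_group_means: pd.DataFrame
    tpm_group_means: pd.DataFrame

    @classmethod
    def from_counts(cls, m: CountMatrix, lengths: pd.Series | None = None) -> "ExpressionSummary":
        cpm = compute_cpm(m)
        tpm = compute_tpm(m, lengths)
        return cls(
            cpm=cpm,
            tpm=tpm,
            cpm_group_means=group_means(cpm, m.design),
            tpm_group_means=group_means(tpm, m.design),
        )


def _choose_reference(counts: np.ndarray, lib: np.ndarray) -> int:
    """Sample whose upper-quartile count fraction is closest to the mean."""
    with np.errstate(invalid="ignore"):
        uq = np.quantile(counts / lib, 0.75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference.

    Genes zero in either sample are dropped; M (log2 ratio of count
    proportions) is trimmed two-sided by 30% and A (average log2
    proportion) by 5%; the factor is 2 to the weighted mean of the
    surviving M with inverse-asymptotic-variance weights.
    """
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        warnings.warn("no genes survive zero-filtering in TMM; factor set to 1")
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # inverse asymptotic variance of M under binomial sampling
    w = 1.0 / (1.0 / obs - 1.0 / n_obs + 1.0 / ref - 1.0 / n_ref)

    if np.max(np.abs(m)) < 1e-6:  # technical replicate: no adjustment
        return 1.0

    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        warnings.warn("no genes survive TMM trimming; factor set to 1")
        return 1.0
    f = np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(m: CountMatrix, ref_sample: str | None = None) -> NormFactors:
    """TMM scaling factors for every sample, geometric-mean-1 rescaled.

    The reference defaults to the sample whose upper-quartile count
    proportion is closest to the across-sample mean; pass ``ref_sample``
    to override.
    """
    counts = m.counts.to_numpy(dtype=float)
    lib = m.lib_sizes.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if (lib <= 0).any():
        raise ValueError("every sample needs a nonzero library")
    if ref_sample is None:
        ref_idx = _choose_reference(counts, lib)
    else:
        if ref_sample not in m.sample_ids:
            raise ValueError(f"unknown reference sample {ref_sample!r}")
        ref_idx = m.sample_ids.index(ref_sample)
    fac = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        fac[j] = _tmm_pair(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx])
    fac = fac / np.exp(np.mean(np.log(fac)))
    return NormFactors(
        factors=pd.Series(fac, index=m.sample_ids),
        lib_sizes=m.lib_sizes.astype(float),
    )
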