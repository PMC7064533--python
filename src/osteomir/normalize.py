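"""Expression-space transforms used before any survival modelling.

Covers median-of-ratios size-factor normalization of read counts (the
classical DESeq-style estimator), the 2^-dCt transform for qRT-PCR panels,
beta -> M logit conversion for methylation arrays, and the variance and
transcript-length feature filters.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, MatrixError


def size_factor_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios normalization followed by log2(x + 1).

    Size factor of sample j is the median over reference features i of
    count_ij / geomean_i, where the reference set is the features with
    strictly positive counts in every sample.  Output values are
    log2(count_ij / s_j + 1).
    """
    if counts.space != "counts":
        raise MatrixError(f"size_factor_normalize expects counts, got {counts.space!r}")
    values = counts.data.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise MatrixError(
            "no feature has strictly positive counts in every sample; "
            "median-of-ratios has no reference set (pseudo-reference fallback is disabled)"
        )
    ref = values[positive]
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geomean)
    size_factors = np.median(ratios, axis=0)
    normalized = np.log2(values / size_factors + 1.0)
    frame = pd.DataFrame(normalized, index=counts.data.index, columns=counts.data.columns)
    out = ExpressionMatrix(frame, "log2norm")
    out.size_factors = pd.Series(size_factors, index=counts.data.columns)
    return out


def delta_ct_transform(ct: ExpressionMatrix, reference_feature: str) -> ExpressionMatrix:
    """Relative expression 2^-(Ct_target - Ct_reference), per sample.

    Lower Ct means more template, so the transform maps the reference feature
    to 1.0 in every sample and expresses everything else relative to it.
    Output is linear-scale and tagged ``counts``.
    """
    if ct.space != "Ct":
        raise MatrixError(f"delta_ct_transform expects Ct values, got {ct.space!r}")
    if reference_feature not in ct.data.index:
        raise MatrixError(f"reference feature {reference_feature!r} not present")
    ref_row = ct.data.loc[reference_feature]
    if ref_row.isna().any():
        bad = ct.data.columns[ref_row.isna()].tolist()
        raise MatrixError(f"reference feature {reference_feature!r} missing in sample(s): {bad}")
    delta = ct.data.sub(ref_row, axis=1)
    return ExpressionMatrix(np.power(2.0, -delta), "counts")


def beta_to_m(beta: ExpressionMatrix, epsilon: float = 1e-6) -> ExpressionMatrix:
    """Logit2 conversion M = log2(beta / (1 - beta)), clamping to [eps, 1-eps].

    M-values are the standard scale for differential methylation testing
    because beta fractions are heteroskedastic near 0 and 1.
    """
    if beta.space != "beta":
        raise MatrixError(f"beta_to_m expects beta values, got {beta.space!r}")
    if epsilon <= 0:
        raise MatrixError("epsilon must be > 0")
    clamped = beta.data.clip(lower=epsilon, upper=1.0 - epsilon)
    m = np.log2(clamped / (1.0 - clamped))
    return ExpressionMatrix(m, "M")


def m_to_beta(m: ExpressionMatrix) -> ExpressionMatrix:
    """Inverse logit2: beta = 1 / (1 + 2^-M)."""
    if m.space != "M":
        raise MatrixError(f"m_to_beta expects M values, got {m.space!r}")
    beta = 1.0 / (1.0 + np.power(2.0, -m.data))
    return ExpressionMatrix(beta, "beta")


def variance_filter(matrix: ExpressionMatrix, drop_fraction: float) -> ExpressionMatrix:
    """Retain the ceil((1 - drop_fraction) * F) highest-variance features.

    Variance is the unbiased sample variance across samples; ties are broken
    in favour of the lexicographically smaller feature id.  Original feature
    order is preserved among the survivors.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise MatrixError("drop_fraction must lie in [0, 1)")
    n_features = matrix.shape[0]
    n_keep = int(np.ceil((1.0 - drop_fraction) * n_features))
    variances = matrix.data.var(axis=1, ddof=1)
    order = sorted(matrix.feature_ids, key=lambda f: (-variances[f], f))
    keep = set(order[:n_keep])
    retained = [f for f in matrix.feature_ids if f in keep]
    return ExpressionMatrix(matrix.data.loc[retained].copy(), matrix.space)


def length_filter(
    matrix: ExpressionMatrix,
    lengths: dict[str, int] | pd.Series,
    min_length: int = 200,
) -> ExpressionMatrix:
    """Drop transcripts shorter than ``min_length`` bases (strictly less-than).

    Every feature must be annotated with a length; features exactly at the
    threshold are retained.
    """
    lengths = pd.Series(lengths)
    missing = [f for f in matrix.feature_ids if f not in lengths.index]
    if missing:
        raise MatrixError(f"unannotated feature(s): {missing}")
    retained = [f for f in matrix.feature_ids if lengths[f] >= min_length]
    if not retained:
        warnings.warn("length_filter removed every feature", stacklevel=2)
    return ExpressionMatrix(matrix.data.loc[retained].copy(), matrix.space)
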