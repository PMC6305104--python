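"""Normalization of RNA-Seq counts and miRNA array signals.

RNA-Seq counts become RPMPCG values (reads per million protein-coding genes):
each count is divided by the sample's total count over the protein-coding gene
universe and multiplied by 1e6. The denominator is always the full
protein-coding table, even when only a pathway subset is reported, so pathway
values are comparable across samples and studies.

miRNA array signals are rescaled so every sample shares a common 75th
percentile: each sample is multiplied by (median of all samples' 75th
percentiles) / (its own 75th percentile). This removes per-sample
multiplicative distortions from labeling, hybridization and scanning.

Prevalence filters drop features detected (value strictly greater than zero)
in too few samples; the miRNA default keeps features expressed in more than
20% of normal-mucosa samples, the mRNA default in more than half of all
samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import NormalizedSet, PairedExpressionSet, NORMAL


class RPMPCGNormalizer(BaseEstimator, TransformerMixin):
    """Scale counts to reads per million protein-coding genes.

    Parameters
    ----------
    protein_coding_ids : sequence of str, optional
        Gene universe for the per-sample denominator. ``None`` means every
        feature in the table is treated as protein coding (the synthetic
        generator's convention).
    keep : sequence of str, optional
        Restrict the output to these features (e.g. a pathway gene list). The
        denominator is still computed over the full protein-coding universe.
    """

    def __init__(self, protein_coding_ids=None, keep=None):
        self.protein_coding_ids = protein_coding_ids
        self.keep = keep

    def fit(self, X: PairedExpressionSet, y=None):
        pc = list(self.protein_coding_ids) if self.protein_coding_ids is not None else list(X.feature_ids)
        missing = set(pc) - set(X.feature_ids)
        if missing:
            raise KeyError(
                f"protein-coding IDs absent from the count table: {sorted(missing)[:5]}"
            )
        totals = X.values.loc[pc].sum(axis=0).astype(float)
        zero = totals.index[totals <= 0]
        if len(zero):
            raise ValueError(f"zero protein-coding total in sample(s) {list(zero)[:5]}")
        self.protein_coding_ids_ = pc
        self.totals_ = totals
        return self

    def transform(self, X: PairedExpressionSet) -> NormalizedSet:
        totals = self.totals_.loc[X.sample_ids]
        values = X.values.div(totals, axis=1) * 1e6
        out = NormalizedSet(
            values=values,
            subject_of=X.subject_of.loc[X.sample_ids],
            tissue_of=X.tissue_of.loc[X.sample_ids],
            normalization="RPMPCG",
            scale_factors=totals / 1e6,
        )
        if self.keep is not None:
            out = out.subset_features(list(self.keep))
        return out


class SeventyFifthPercentileScaler(BaseEstimator, TransformerMixin):
    """Median-of-75th-percentiles scaling for microarray total gene signals.

    ``percentile_method`` is forwarded to :func:`numpy.percentile` (the array
    vendor's exact interpolation convention is not published; linear is the
    common default). With ``detected_only=True`` the percentile is computed
    over strictly positive signals only.
    """

    def __init__(self, percentile_method: str = "linear", detected_only: bool = False):
        self.percentile_method = percentile_method
        self.detected_only = detected_only

    def _p75(self, col: pd.Series) -> float:
        x = col.to_numpy(dtype=float)
        if self.detected_only:
            x = x[x > 0]
        if x.size == 0:
            return 0.0
        return float(np.percentile(x, 75, method=self.percentile_method))

    def fit(self, X: PairedExpressionSet, y=None):
        p75 = X.values.apply(self._p75, axis=0)
        zero = p75.index[p75 <= 0]
        if len(zero):
            raise ValueError(f"75th percentile is zero in sample(s) {list(zero)[:5]}")
        self.p75_ = p75
        self.scale_factors_ = float(np.median(p75)) / p75
        return self

    def transform(self, X: PairedExpressionSet) -> NormalizedSet:
        factors = self.scale_factors_.loc[X.sample_ids]
        return NormalizedSet(
            values=X.values.mul(factors, axis=1),
            subject_of=X.subject_of.loc[X.sample_ids],
            tissue_of=X.tissue_of.loc[X.sample_ids],
            normalization="Q75",
            scale_factors=factors,
        )


class PrevalenceFilter(BaseEstimator, TransformerMixin):
    """Drop features expressed in too few samples.

    A feature is retained when its value is strictly greater than zero in
    strictly more than ``min_fraction`` of the reference samples
    (``reference="normal_only"`` counts normal-mucosa samples only,
    ``"all"`` counts every sample). Feature order is preserved.
    """

    def __init__(self, min_fraction: float = 0.20, reference: str = "normal_only"):
        self.min_fraction = min_fraction
        self.reference = reference

    def fit(self, X: PairedExpressionSet, y=None):
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.reference == "normal_only":
            cols = X.samples_of(NORMAL)
        elif self.reference == "all":
            cols = list(X.sample_ids)
        else:
            raise ValueError("reference must be 'normal_only' or 'all'")
        frac = (X.values[cols] > 0).sum(axis=1) / len(cols)
        mask = frac > self.min_fraction
        self.retained_features_ = X.feature_ids[mask]
        if len(self.retained_features_) == 0:
            warnings.warn("prevalence filter retained no features", stacklevel=2)
        return self

    def transform(self, X: PairedExpressionSet) -> PairedExpressionSet:
        return X.subset_features(list(self.retained_features_))


# -- thin functional wrappers ------------------------------------------------


def rpmpcg_normalize(counts: PairedExpressionSet, protein_coding_ids=None, keep=None) -> NormalizedSet:
    """RPMPCG-normalize ``counts``; see :class:`RPMPCGNormalizer`."""
    return RPMPCGNormalizer(protein_coding_ids, keep=keep).fit(counts).transform(counts)


def q75_scale(signals: PairedExpressionSet, percentile_method="linear", detected_only=False) -> NormalizedSet:
    """75th-percentile scale ``signals``; see :class:`SeventyFifthPercentileScaler`."""
    scaler = SeventyFifthPercentileScaler(percentile_method, detected_only)
    return scaler.fit(signals).transform(signals)


def prevalence_filter(data: PairedExpressionSet, min_fraction: float, reference: str = "all"):
    """Apply the expression-prevalence filter; see :class:`PrevalenceFilter`."""
    return PrevalenceFilter(min_fraction, reference).fit(data).transform(data)
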