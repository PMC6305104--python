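"""Containers for paired carcinoma/normal expression data.

Every pipeline stage consumes a :class:`PairedExpressionSet`: a feature-by-sample
matrix (RNA-Seq counts or microarray signals) together with the subject pairing
(each subject contributes exactly one carcinoma and one normal-mucosa sample).
Normalized data carry their per-sample scale factors in :class:`NormalizedSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CARCINOMA = "carcinoma"
NORMAL = "normal"
TISSUES = (CARCINOMA, NORMAL)


class PairingError(ValueError):
    """The sample-to-subject map does not describe a complete paired design."""


@dataclass
class PairedExpressionSet:
    """Feature x sample expression matrix with a paired tumor/normal design.

    Parameters
    ----------
    values
        Non-negative matrix with feature IDs (gene symbols or miRNA names) as
        the index and sample IDs as columns.
    subject_of
        Maps each sample ID to its subject ID.
    tissue_of
        Maps each sample ID to ``"carcinoma"`` or ``"normal"``.

    Each subject must contribute exactly one sample of each tissue; feature IDs
    must be unique; values must be finite and non-negative.
    """

    values: pd.DataFrame
    subject_of: pd.Series
    tissue_of: pd.Series

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.subject_of = pd.Series(self.subject_of)
        self.tissue_of = pd.Series(self.tissue_of)

        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and (not np.isfinite(arr.astype(float)).all() or (arr < 0).any()):
            raise ValueError("expression values must be finite and non-negative")

        samples = list(self.values.columns)
        for name, mapping in (("subject_of", self.subject_of), ("tissue_of", self.tissue_of)):
            missing = set(samples) - set(mapping.index)
            if missing:
                raise PairingError(f"{name} lacks entries for samples {sorted(missing)[:5]}")
        bad = set(self.tissue_of.loc[samples]) - set(TISSUES)
        if bad:
            raise PairingError(f"unknown tissue labels: {sorted(bad)}")

        pairs: dict[str, dict[str, str]] = {}
        for s in samples:
            subj = self.subject_of.loc[s]
            tis = self.tissue_of.loc[s]
            slot = pairs.setdefault(subj, {})
            if tis in slot:
                raise PairingError(f"subject {subj!r} has more than one {tis} sample")
            slot[tis] = s
        for subj, slot in pairs.items():
            if set(slot) != set(TISSUES):
                raise PairingError(f"subject {subj!r} lacks a {set(TISSUES) - set(slot)} sample")
        # subjects in order of first appearance among the columns
        seen: list[str] = []
        for s in samples:
            subj = self.subject_of.loc[s]
            if subj not in seen:
                seen.append(subj)
        self._pairs = pd.DataFrame(
            {t: [pairs[subj][t] for subj in seen] for t in TISSUES}, index=pd.Index(seen, name="subject")
        )

    # -- accessors ---------------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def subjects(self) -> pd.Index:
        return self._pairs.index

    @property
    def n_subjects(self) -> int:
        return len(self._pairs)

    def samples_of(self, tissue: str) -> list[str]:
        """Sample IDs of one tissue, in subject order."""
        if tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}")
        return self._pairs[tissue].tolist()

    def sample_of(self, subject: str, tissue: str) -> str:
        return self._pairs.loc[subject, tissue]

    def tissue_values(self, tissue: str) -> pd.DataFrame:
        """Feature x subject matrix for one tissue (columns relabeled to subjects)."""
        block = self.values[self.samples_of(tissue)]
        block = block.set_axis(self.subjects, axis=1)
        return block

    def subset_features(self, features) -> "PairedExpressionSet":
        missing = set(features) - set(self.feature_ids)
        if missing:
            raise KeyError(f"unknown features: {sorted(missing)[:5]}")
        return self._replace(values=self.values.loc[list(features)])

    def subset_subjects(self, subjects) -> "PairedExpressionSet":
        keep = [s for s in self.sample_ids if self.subject_of.loc[s] in set(subjects)]
        return self._replace(values=self.values[keep])

    def _replace(self, values: pd.DataFrame) -> "PairedExpressionSet":
        cols = values.columns
        return type(self)(
            values=values,
            subject_of=self.subject_of.loc[cols],
            tissue_of=self.tissue_of.loc[cols],
            **self._extra_fields(),
        )

    def _extra_fields(self) -> dict:
        return {}


@dataclass
class NormalizedSet(PairedExpressionSet):
    """A :class:`PairedExpressionSet` after normalization.

    ``normalization`` is ``"RPMPCG"`` (reads per million protein-coding genes)
    or ``"Q75"`` (median-of-75th-percentiles microarray scaling);
    ``scale_factors`` holds the per-sample divisor/multiplier applied.
    """

    normalization: str = ""
    scale_factors: pd.Series | None = field(default=None)

    def _extra_fields(self) -> dict:
        sf = self.scale_factors
        return {
            "normalization": self.normalization,
            "scale_factors": None if sf is None else sf.loc[[c for c in self.sample_ids if c in sf.index]],
        }

    def _replace(self, values: pd.DataFrame) -> "NormalizedSet":
        cols = values.columns
        sf = self.scale_factors
        return NormalizedSet(
            values=values,
            subject_of=self.subject_of.loc[cols],
            tissue_of=self.tissue_of.loc[cols],
            normalization=self.normalization,
            scale_factors=None if sf is None else sf.loc[cols],
        )
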