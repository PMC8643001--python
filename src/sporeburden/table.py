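"""Core in-memory containers: feature tables and sample metadata.

The feature table is held in a fixed orientation — features as rows,
samples as columns — so that every downstream operation (QC, contaminant
flagging, rarefaction, log-ratios) can index it the same way. Readers
transpose on the way in if asked to; nothing downstream ever does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_TYPES = ("floor", "field_control", "negative_control", "extraction_control")
CONTROL_TYPES = ("field_control", "negative_control", "extraction_control")
#: controls with no sample material at all (reagent/extraction blanks)
NO_TEMPLATE_TYPES = ("negative_control", "extraction_control")


class FormatError(ValueError):
    """Raised when an input file or in-memory table violates the format contract."""


@dataclass
class FeatureTable:
    """Counts of sOTUs (or genera) across samples.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, features as rows and samples as
        columns. Row/column labels are the feature and sample ids.
    taxonomy : pandas.Series, optional
        Per-feature lineage string (semicolon-separated ranks,
        Greengenes-style ``g__Genus`` prefixes accepted). When present it
        must cover every feature.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dupes}")
        if c.columns.has_duplicates:
            dupes = c.columns[c.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # allow float input only if it is exactly integral
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere(arr != np.floor(arr))
                if bad.size:
                    i, j = bad[0]
                    raise FormatError(
                        f"non-integer count {arr[i, j]!r} at feature "
                        f"{c.index[i]!r}, sample {c.columns[j]!r}"
                    )
                raise FormatError("counts must be finite integers")
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at feature {c.index[i]!r}, sample {c.columns[j]!r}"
            )
        if self.taxonomy is not None:
            missing = c.index.difference(self.taxonomy.index)
            if len(missing):
                raise FormatError(
                    f"taxonomy missing for features: {missing.tolist()[:5]}"
                )
            self.taxonomy = self.taxonomy.reindex(c.index)

    # -- accessors --------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        """Per-sample read totals (column sums)."""
        return self.counts.sum(axis=0)

    def feature_totals(self) -> pd.Series:
        """Per-feature read totals across all samples (row sums)."""
        return self.counts.sum(axis=1)

    # -- subsetting -------------------------------------------------------
    def select_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.counts.loc[:, list(sample_ids)], self.taxonomy)

    def drop_features(self, feature_ids) -> "FeatureTable":
        keep = self.counts.index.difference(pd.Index(feature_ids), sort=False)
        tax = self.taxonomy.loc[keep] if self.taxonomy is not None else None
        return FeatureTable(self.counts.loc[keep], tax)

    def select_features(self, feature_ids) -> "FeatureTable":
        ids = list(feature_ids)
        tax = self.taxonomy.loc[ids] if self.taxonomy is not None else None
        return FeatureTable(self.counts.loc[ids], tax)


@dataclass
class SampleMetadata:
    """Per-sample study annotations.

    Wraps a DataFrame indexed by sample id with the required columns
    ``sample_type``, ``pma_treated``, ``location_id``, ``radius``,
    ``session_index`` and ``session_date``; unknown columns are carried
    along untouched.
    """

    data: pd.DataFrame

    REQUIRED = (
        "sample_type",
        "pma_treated",
        "location_id",
        "radius",
        "session_index",
        "session_date",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing required columns: {missing}")
        bad_types = set(df["sample_type"]) - set(SAMPLE_TYPES)
        if bad_types:
            raise FormatError(
                f"unknown sample_type values {sorted(bad_types)}; "
                f"expected one of {SAMPLE_TYPES}"
            )
        floors = df[df["sample_type"] == "floor"]
        if floors["radius"].isna().any():
            bad = floors.index[floors["radius"].isna()].tolist()
            raise FormatError(f"floor samples missing radius: {bad[:5]}")
        if floors["location_id"].isna().any():
            bad = floors.index[floors["location_id"].isna()].tolist()
            raise FormatError(f"floor samples missing location_id: {bad[:5]}")
        if (df["radius"].dropna() < 0).any():
            raise FormatError("radius must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def require_samples(self, sample_ids) -> None:
        """Check that every id resolves to exactly one metadata row."""
        missing = pd.Index(sample_ids).difference(self.data.index)
        if len(missing):
            raise FormatError(
                f"samples without metadata: {missing.tolist()[:5]}"
            )

    def sample_type(self) -> pd.Series:
        return self.data["sample_type"]

    def is_control(self) -> pd.Series:
        return self.data["sample_type"].isin(CONTROL_TYPES)

    def samples_of_type(self, *types: str) -> list[str]:
        mask = self.data["sample_type"].isin(types)
        return list(self.data.index[mask])

    def select(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)].copy())


def genus_of(lineage: str | float | None) -> str | None:
    """Extract the genus from a lineage string.

    Accepts Greengenes-style ``k__...; g__Bacillus; s__`` prefixes or a
    plain semicolon-separated rank list (genus taken as the 6th rank).
    Returns None when no genus is resolvable.
    """
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        return None
    parts = [p.strip() for p in str(lineage).split(";")]
    for part in parts:
        if part.lower().startswith("g__"):
            name = part[3:].strip()
            return name or None
    if len(parts) >= 6 and parts[5] and "__" not in parts[5]:
        return parts[5]
    return None
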