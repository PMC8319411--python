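"""Core tabular containers shared across the pipeline.

The pipeline moves three tables around: an OTU count table (samples x OTUs),
a sample-metadata table describing the erosion-gradient design, and a soil
property table.  Validation happens on construction so downstream stages can
assume the invariants (non-negative integer counts, unique identifiers,
erosion labels from the declared ordered set).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Ordered erosion-intensity classes: non-eroded, lightly, moderately and
#: heavily eroded (erosion modulus <500, 500-2500, 2500-5000 and
#: 5000-8000 t km^-2 a^-1 respectively).
EROSION_LEVELS: tuple[str, ...] = ("E0", "EL", "EM", "EH")

#: The 13 measured soil variables.  pH is measured but excluded from the
#: multifunctionality index by default because it is on a log scale.
SOIL_VARIABLES: tuple[str, ...] = (
    "moisture", "pH", "OC", "TN", "TP", "NH4", "NO3",
    "AP", "AK", "MBC", "MBN", "Cm", "Nm",
)


class FormatError(ValueError):
    """Malformed on-disk table (duplicates, bad header, wrong shape)."""


class ValidationError(ValueError):
    """Well-formed table violating a domain invariant."""


@dataclass(frozen=True)
class OtuTable:
    """OTU count table, samples as rows and OTUs as columns.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix; index = sample ids, columns = OTU ids.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate OTU ids: {dups}")
        values = c.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if values.size:
            if np.any(values < 0):
                raise ValidationError("negative counts are not allowed")
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integers")
            c = c.astype(np.int64)
        c.index = c.index.rename("sample_id")
        c.columns = c.columns.rename("otu_id")
        object.__setattr__(self, "counts", c)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise ValidationError(f"all-zero samples: {bad}")
        return self.counts.div(totals, axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return OtuTable(self.counts.loc[list(sample_ids)])

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        missing = [o for o in otu_ids if o not in self.counts.columns]
        if missing:
            raise ValidationError(f"unknown OTU ids: {missing}")
        return OtuTable(self.counts.loc[:, list(otu_ids)])


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata frame and return a normalized copy.

    Expects columns ``sample_id, site, erosion, transect, plot``; erosion
    becomes an ordered categorical over :data:`EROSION_LEVELS`.
    """
    required = ["sample_id", "site", "erosion", "transect", "plot"]
    missing = [c for c in required if c not in metadata.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    md = metadata.copy()
    if md["sample_id"].duplicated().any():
        dups = md.loc[md["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids in metadata: {dups}")
    bad = sorted(set(md["erosion"].astype(str)) - set(EROSION_LEVELS))
    if bad:
        raise ValidationError(
            f"unknown erosion labels {bad}; expected one of {list(EROSION_LEVELS)}"
        )
    md["erosion"] = pd.Categorical(
        md["erosion"], categories=EROSION_LEVELS, ordered=True
    )
    design = md[["site", "erosion", "transect", "plot"]].astype(str)
    if design.duplicated().any():
        raise ValidationError("(site, erosion, transect, plot) must be jointly unique")
    return md.set_index("sample_id", drop=False)


def validate_soil(soil: pd.DataFrame) -> pd.DataFrame:
    """Validate a soil table (one row per plot/sample, 13 variables)."""
    if "sample_id" not in soil.columns:
        raise FormatError("soil table missing 'sample_id' column")
    missing = [v for v in SOIL_VARIABLES if v not in soil.columns]
    if missing:
        raise FormatError(f"soil table missing variables: {missing}")
    st = soil.copy()
    if st["sample_id"].duplicated().any():
        dups = st.loc[st["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids in soil table: {dups}")
    # Nm (net N mineralization) may legitimately be negative; pH bounded.
    nonneg = [v for v in SOIL_VARIABLES if v not in ("Nm",)]
    for v in nonneg:
        if (st[v] < 0).any():
            raise ValidationError(f"soil variable {v} has negative values")
    if ((st["pH"] <= 0) | (st["pH"] >= 14)).any():
        raise ValidationError("pH out of (0, 14)")
    return st.set_index("sample_id", drop=False)


def align_tables(
    otu: OtuTable, metadata: pd.DataFrame, soil: pd.DataFrame | None = None
) -> None:
    """Check the three tables describe the same samples; raise otherwise."""
    otu_ids = set(otu.sample_ids)
    md_ids = set(metadata["sample_id"])
    if otu_ids != md_ids:
        raise ValidationError(
            "sample ids differ between OTU table and metadata: "
            f"only in OTU table {sorted(otu_ids - md_ids)[:5]}, "
            f"only in metadata {sorted(md_ids - otu_ids)[:5]}"
        )
    if soil is not None:
        soil_ids = set(soil["sample_id"])
        if soil_ids != otu_ids:
            raise ValidationError(
                "sample ids differ between OTU table and soil table: "
                f"only in OTU table {sorted(otu_ids - soil_ids)[:5]}, "
                f"only in soil table {sorted(soil_ids - otu_ids)[:5]}"
            )
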