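"""Core data containers for the iTreg time-course multi-omics pipeline.

The experiment layout follows a fixed vocabulary: treatment groups
``G01``–``G07`` (unstimulated naive cells, Mock-stimulated control, four
Treg-inducing protocols, and natural Tregs) and time points ``T01``–``T06``
mapping to 0, 2, 6, 24, 48 and 144 hours of culture.  All expression
containers are thin wrappers around pandas DataFrames with genes in rows
and samples in columns, validated on construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical hour assignment of the time-point codes
TIME_HOURS: dict[str, float] = {
    "T01": 0.0,
    "T02": 2.0,
    "T03": 6.0,
    "T04": 24.0,
    "T05": 48.0,
    "T06": 144.0,
}

#: treatment-group codes; G02 is the Mock-stimulated reference,
#: G03–G06 are the four Treg-inducing protocols
GROUP_CODES: tuple[str, ...] = ("G01", "G02", "G03", "G04", "G05", "G06", "G07")

#: the four iTreg conditions (cytokine cocktails on top of activation)
ITREG_GROUPS: tuple[str, ...] = ("G03", "G04", "G05", "G06")


class ValidationError(ValueError):
    """Raised when a container or design table violates its contract."""


@dataclass
class SampleDesign:
    """Sample annotation table.

    ``table`` is indexed by sample id and carries at least ``donor``,
    ``group`` and ``time`` columns; ``batch``, ``tmt_set`` and
    ``technical_replicate`` are optional.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in ("donor", "group", "time"):
            if col not in t.columns:
                raise ValidationError(f"design table lacks required column {col!r}")
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in design: {dups}")
        bad_groups = set(t["group"]) - set(GROUP_CODES)
        if bad_groups:
            raise ValidationError(f"unknown group codes: {sorted(bad_groups)}")
        bad_times = set(t["time"]) - set(TIME_HOURS)
        if bad_times:
            raise ValidationError(f"unknown time codes: {sorted(bad_times)}")
        if "technical_replicate" not in t.columns:
            t["technical_replicate"] = 0
        key = t[["donor", "group", "time", "technical_replicate"]]
        if key.duplicated().any():
            raise ValidationError(
                "duplicated (donor, group, time, technical_replicate) combinations"
            )
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def hours(self) -> pd.Series:
        """Hours of culture per sample, from the time-point code."""
        return self.table["time"].map(TIME_HOURS).astype(float)

    def subset(self, samples) -> "SampleDesign":
        return SampleDesign(self.table.loc[list(samples)])

    def samples_in(self, groups=None, times=None) -> list[str]:
        """Sample ids restricted to the given group and/or time codes."""
        mask = pd.Series(True, index=self.table.index)
        if groups is not None:
            mask &= self.table["group"].isin(list(groups))
        if times is not None:
            mask &= self.table["time"].isin(list(times))
        return list(self.table.index[mask])


def _check_axes(values: pd.DataFrame) -> None:
    if values.index.has_duplicates:
        raise ValidationError("duplicated gene ids")
    if values.columns.has_duplicates:
        raise ValidationError("duplicated sample ids")


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    ``gene_meta`` (optional) is indexed like ``values`` and may carry
    ``length_bp``, ``biotype``, ``symbol`` and ``is_tf`` columns.
    """

    values: pd.DataFrame
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_axes(self.values)
        arr = self.values.to_numpy()
        if np.any(arr < 0):
            raise ValidationError("negative counts")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integral")
        self.values = self.values.astype(np.int64)
        if self.gene_meta is not None and not self.gene_meta.index.equals(
            self.values.index
        ):
            self.gene_meta = self.gene_meta.reindex(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class AbundanceMatrix:
    """Gene x sample matrix of transformed real-valued abundances.

    ``transform`` records provenance: one of ``fpkm``, ``log2fpkm``,
    ``modlog``, ``zscore``, ``protein_log2r``.
    """

    values: pd.DataFrame
    transform: str = "modlog"

    _KNOWN = ("fpkm", "log2fpkm", "modlog", "zscore", "protein_log2r")

    def __post_init__(self) -> None:
        _check_axes(self.values)
        if self.transform not in self._KNOWN:
            raise ValidationError(
                f"unknown transform tag {self.transform!r}; expected one of {self._KNOWN}"
            )
        self.values = self.values.astype(float)
        if self.transform == "zscore":
            arr = self.values.to_numpy()
            mu = np.nanmean(arr, axis=1)
            sd = np.nanstd(arr, axis=1)
            ok = np.isfinite(mu) & (sd > 0)
            if ok.any() and (
                np.abs(mu[ok]).max() > 1e-8 or np.abs(sd[ok] - 1.0).max() > 1e-6
            ):
                raise ValidationError("zscore rows must have mean 0 and SD 1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProteinQuant:
    """Protein-level relative quantification (log2 ratio vs internal standard).

    Only proteins quantified in every sample (``quantified_in_all``) enter
    downstream statistics; others are retained for bookkeeping.
    """

    log2r: pd.DataFrame
    quantified_in_all: pd.Series = field(default=None)  # type: ignore[assignment]
    gene_map: pd.Series | None = None  # protein id -> gene id

    def __post_init__(self) -> None:
        _check_axes(self.log2r)
        self.log2r = self.log2r.astype(float)
        if self.quantified_in_all is None:
            self.quantified_in_all = self.log2r.notna().all(axis=1)
        self.quantified_in_all = self.quantified_in_all.reindex(
            self.log2r.index
        ).fillna(False)

    def complete(self) -> pd.DataFrame:
        """Matrix restricted to proteins quantified in all samples."""
        return self.log2r.loc[self.quantified_in_all]


def zscore_rows(values: pd.DataFrame, ddof: int = 0) -> AbundanceMatrix:
    """Per-gene z-scores across columns; constant rows become all-zero."""
    arr = values.to_numpy(dtype=float)
    mu = np.nanmean(arr, axis=1, keepdims=True)
    sd = np.nanstd(arr, axis=1, ddof=ddof, keepdims=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = (arr - mu) / sd
    z[~np.isfinite(z)] = 0.0
    return AbundanceMatrix(
        pd.DataFrame(z, index=values.index, columns=values.columns),
        transform="zscore",
    )
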