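"""Omics data blocks: the basic sample-by-feature container used throughout.

A block holds one internal-phenotype dataset (e.g. ileal transcriptomics,
ileal microbiota, serum cytokines, serum or urine metabolomics) as a
features x samples matrix together with feature/sample identifiers, a
data-type label and the diet-group assignment of every sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OmicsBlock", "read_block", "read_group_map", "write_group_map"]


@dataclass
class OmicsBlock:
    """One omics dataset: ``values[i, j]`` is feature ``i`` in sample ``j``.

    Parameters
    ----------
    values
        Numeric matrix, shape ``(n_features, n_samples)``. Units are
        data-type specific (expression intensity, relative abundance,
        pg/ml, uM, ...).
    feature_ids, sample_ids
        Unique identifiers matching the matrix dimensions.
    data_type
        Label such as ``"transcriptomics"`` or ``"microbiota"``; free-form.
    groups
        Mapping sample_id -> experimental group label (here: diet).
    reference_group
        The group used as the baseline in differential contrasts
        (the soy-bean-meal diet in the motivating study). ``None`` when
        the block is not destined for screening.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    data_type: str
    groups: dict[str, str] = field(default_factory=dict)
    reference_group: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (features x samples)")
        nf, ns = self.values.shape
        if len(self.feature_ids) != nf:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {nf} matrix rows"
            )
        if len(self.sample_ids) != ns:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {ns} matrix columns"
            )
        if len(set(self.feature_ids)) != nf:
            raise ValueError("feature_ids are not unique")
        if len(set(self.sample_ids)) != ns:
            raise ValueError("sample_ids are not unique")
        if self.groups:
            missing = [s for s in self.sample_ids if s not in self.groups]
            if missing:
                raise ValueError(f"samples without a group label: {missing[:5]}")

    # -- basic geometry -------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_labels(self) -> list[str]:
        """Distinct group labels in first-appearance order over samples."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            g = self.groups[s]
            if g not in seen:
                seen[g] = None
        return list(seen)

    # -- subsetting -----------------------------------------------------

    def subset_features(self, keep: list[str]) -> "OmicsBlock":
        """Restrict to the given features, preserving this block's order."""
        keep_set = set(keep)
        unknown = keep_set - set(self.feature_ids)
        if unknown:
            raise KeyError(f"unknown feature ids: {sorted(unknown)[:5]}")
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep_set]
        return replace(
            self,
            values=self.values[idx, :],
            feature_ids=[self.feature_ids[i] for i in idx],
        )

    def subset_samples(self, keep: list[str]) -> "OmicsBlock":
        keep_set = set(keep)
        unknown = keep_set - set(self.sample_ids)
        if unknown:
            raise KeyError(f"unknown sample ids: {sorted(unknown)[:5]}")
        idx = [j for j, s in enumerate(self.sample_ids) if s in keep_set]
        return replace(
            self,
            values=self.values[:, idx],
            sample_ids=[self.sample_ids[j] for j in idx],
            groups={s: self.groups[s] for s in self.sample_ids if s in keep_set}
            if self.groups
            else {},
        )

    # -- I/O --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def write_tsv(self, path: str | Path) -> None:
        """Write the feature table: rows = features, first column = feature id."""
        df = self.to_frame()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OmicsBlock):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and self.data_type == other.data_type
            and self.groups == other.groups
            and self.reference_group == other.reference_group
            and np.array_equal(self.values, other.values)
        )


def read_block(
    path: str | Path,
    data_type: str,
    groups_path: str | Path | None = None,
    reference_group: str | None = None,
) -> OmicsBlock:
    """Read a feature-table TSV (written by :meth:`OmicsBlock.write_tsv`)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in feature table: {exc}")
    groups: dict[str, str] = {}
    if groups_path is not None:
        groups_all = read_group_map(groups_path)
        groups = {s: groups_all[s] for s in df.columns if s in groups_all}
        missing = [s for s in df.columns if s not in groups_all]
        if missing:
            raise ValueError(
                f"{groups_path}: no group label for samples {missing[:5]}"
            )
    return OmicsBlock(
        values=values,
        feature_ids=[str(f) for f in df.index],
        sample_ids=[str(s) for s in df.columns],
        data_type=data_type,
        groups=groups,
        reference_group=reference_group,
    )


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> group TSV (header ``sample_id\\tgroup``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, group)")
    sample_col, group_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        dup = df[sample_col][df[sample_col].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return dict(zip(df[sample_col], df[group_col]))


def write_group_map(groups: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)
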