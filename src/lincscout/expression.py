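"""Count matrices and library-size / length normalization (CPM, RPKM)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


class ExpressionMatrix:
    """Features x samples count matrix with group labels.

    Wraps a pandas DataFrame of non-negative integer counts (rows =
    features, columns = samples) plus a sample -> group mapping. Library
    sizes are the column sums of the retained matrix.
    """

    def __init__(self, counts: pd.DataFrame, sample_group: Mapping[str, str]):
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        self.sample_group = dict(sample_group)
        missing = set(counts.columns) - set(self.sample_group)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        lib = self.counts.sum(axis=0)
        zero = lib[lib == 0]
        if len(zero):
            raise ValueError(f"zero library size for sample(s): {list(zero.index)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_group[s] == group]

    # -- normalizations ----------------------------------------------------

    def cpm(self) -> pd.DataFrame:
        """Counts per million; every column sums to 1e6."""
        return self.counts / self.library_sizes * 1e6

    def log2cpm1(self) -> pd.DataFrame:
        """log2(CPM + 1); zero counts map to 0."""
        return np.log2(self.cpm() + 1.0)

    def rpkm(self, lengths: Mapping[str, int]) -> pd.DataFrame:
        """Reads per kilobase per million: CPM / (feature length in kb)."""
        return self._per_kb(self.cpm(), lengths)

    def length_norm_cpm(self, lengths: Mapping[str, int]) -> pd.DataFrame:
        """CPM divided by feature length in kb (identical formula to RPKM;
        kept as a separate name because downstream reports use it for
        exon-level isoform comparisons rather than expression filtering)."""
        return self._per_kb(self.cpm(), lengths)

    def _per_kb(self, mat: pd.DataFrame, lengths: Mapping[str, int]) -> pd.DataFrame:
        kb = pd.Series(
            {f: lengths[f] / 1e3 for f in mat.index}, dtype=float
        )
        if (kb <= 0).any():
            raise ValueError("feature lengths must be positive")
        return mat.div(kb, axis=0)

    def normalize(
        self, kind: str, lengths: Mapping[str, int] | None = None
    ) -> pd.DataFrame:
        """Dispatch by name: CPM, RPKM, log2CPM1 or length_norm_CPM."""
        if kind == "CPM":
            return self.cpm()
        if kind == "log2CPM1":
            return self.log2cpm1()
        if kind in ("RPKM", "length_norm_CPM"):
            if lengths is None:
                raise ValueError(f"{kind} requires feature lengths")
            return self._per_kb(self.cpm(), lengths)
        raise ValueError(f"unknown normalization {kind!r}")

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        """Row subset; library sizes are recomputed over the subset."""
        return ExpressionMatrix(self.counts.loc[list(feature_ids)], self.sample_group)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, counts_path: str | Path, groups_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature_id")
        pd.Series(self.sample_group, name="group").rename_axis("sample_id").to_csv(
            groups_path, sep="\t"
        )

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, groups_path: str | Path
    ) -> "ExpressionMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
        return cls(counts, groups.to_dict())
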