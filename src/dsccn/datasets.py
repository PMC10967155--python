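"""Paired multi-omics dataset container and delimited-text I/O.

The on-disk format is plain tab-separated text: one matrix file per omics
(rows = samples, first column ``sample_id``, header = feature IDs) and one
labels table with columns ``sample_id``, ``subtype``, ``group``.  Either label
column may be empty for a given sample: healthy samples used only by the
differential-expression stage carry a group but no subtype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OmicsDataset", "load_dataset"]


@dataclass
class OmicsDataset:
    """Sample-aligned expression matrices for two omics plus per-sample labels.

    Attributes
    ----------
    X, Y : pandas.DataFrame
        Expression matrices (samples x features) for the two omics, indexed by
        sample ID with identical row order.
    subtype : pandas.Series
        Subtype label per sample (NaN where unknown, e.g. healthy samples).
    group : pandas.Series
        Cohort membership per sample, ``"healthy"`` or ``"disease"``.
    truth : dict or None
        Ground-truth bookkeeping for synthetic data (planted supports, weights,
        graph edges); absent for real data.
    """

    X: pd.DataFrame
    Y: pd.DataFrame
    subtype: pd.Series
    group: pd.Series
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.Y.index):
            raise ValueError("X and Y must share an identical sample index")
        for s in (self.subtype, self.group):
            if not s.index.equals(self.X.index):
                raise ValueError("label series must be aligned with the sample index")

    @property
    def sample_ids(self) -> pd.Index:
        return self.X.index

    @property
    def n_samples(self) -> int:
        return len(self.X.index)

    def disease_view(self) -> "OmicsDataset":
        """Restrict to samples with a subtype label (the classification cohort)."""
        keep = self.subtype.notna()
        return OmicsDataset(
            X=self.X.loc[keep],
            Y=self.Y.loc[keep],
            subtype=self.subtype.loc[keep],
            group=self.group.loc[keep],
            truth=self.truth,
        )

    def de_groups(self, omics: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (disease, healthy) row blocks of one omics matrix."""
        mat = {"x": self.X, "y": self.Y}[omics.lower()]
        case = mat.loc[self.group == "disease"]
        ctrl = mat.loc[self.group == "healthy"]
        return case, ctrl

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subtype": self.subtype, "group": self.group},
            index=self.sample_ids,
        ).rename_axis("sample_id")

    def to_dir(self, path: str | Path) -> None:
        """Write matrices, labels and (if present) a JSON truth sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.X.rename_axis("sample_id").to_csv(path / "X.tsv", sep="\t")
        self.Y.rename_axis("sample_id").to_csv(path / "Y.tsv", sep="\t")
        self.labels_frame().to_csv(path / "labels.tsv", sep="\t")
        if self.truth is not None:
            with open(path / "truth.json", "w") as fh:
                json.dump(_jsonable(self.truth), fh, indent=1)

    @classmethod
    def from_dir(cls, path: str | Path) -> "OmicsDataset":
        path = Path(path)
        ds = load_dataset(path / "X.tsv", path / "Y.tsv", path / "labels.tsv")
        truth_file = path / "truth.json"
        if truth_file.exists():
            with open(truth_file) as fh:
                ds.truth = json.load(fh)
        return ds


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in {path}: {dups}")
    return df


def load_dataset(
    x_path: str | Path, y_path: str | Path, labels_path: str | Path
) -> OmicsDataset:
    """Load two matrix files and a labels table, aligning on common samples.

    Samples are intersected across the two omics (mirroring the reduction of a
    multi-omics cohort to its common sample set) and ordered by their order of
    appearance in the first matrix.  Every retained sample must appear in the
    labels table.
    """
    X = _read_matrix(x_path)
    Y = _read_matrix(y_path)
    common = X.index.intersection(Y.index)  # keeps X's order
    if len(common) == 0:
        raise ValueError("the two omics matrices share no sample IDs")
    labels = pd.read_csv(labels_path, sep="\t", dtype={"sample_id": str})
    labels = labels.set_index("sample_id")
    if labels.index.has_duplicates:
        raise ValueError("duplicate sample IDs in the labels table")
    missing = common.difference(labels.index)
    if len(missing) > 0:
        raise ValueError(f"samples missing from the labels table: {list(missing[:5])}")
    subtype = labels.reindex(common).get("subtype", pd.Series(np.nan, index=common))
    group = labels.reindex(common).get("group", pd.Series(np.nan, index=common))
    return OmicsDataset(
        X=X.loc[common],
        Y=Y.loc[common],
        subtype=pd.Series(subtype, index=common, name="subtype"),
        group=pd.Series(group, index=common, name="group"),
    )
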