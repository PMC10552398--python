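"""Subject-level trial data container and CSV round-trip.

One row per subject: K binary outcome columns, a cluster identifier, a 0/1
treatment indicator, and optional continuous/discrete covariates.  Internally
the design matrix always carries a leading constant column, cluster labels
are mapped to contiguous indices 0..J-1, and outcomes are validated as 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrialDataset", "read_dataset_csv", "write_dataset_csv"]


@dataclass
class TrialDataset:
    """Rectangular trial data in the form the samplers consume.

    Attributes
    ----------
    y : ndarray (n, K)
        Binary outcomes per subject.
    x : ndarray (n, P)
        Design matrix; column 0 is the constant 1.
    cluster : ndarray (n,)
        Contiguous cluster indices in ``0..J-1``.
    treatment_col : int
        Column of ``x`` holding the 0/1 treatment indicator.
    outcome_names, covariate_names, cluster_labels
        Optional metadata preserved through CSV round-trips.
    """

    y: np.ndarray
    x: np.ndarray
    cluster: np.ndarray
    treatment_col: int = 1
    outcome_names: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)
    cluster_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.cluster = np.asarray(self.cluster, dtype=np.int64)
        if self.y.ndim != 2:
            raise ValueError("y must be a 2-d (n, K) array")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("outcomes must be 0/1")
        self.y = self.y.astype(np.int8)
        n = self.y.shape[0]
        if self.x.shape[0] != n or self.cluster.shape[0] != n:
            raise ValueError("y, x and cluster must have the same number of rows")
        if not np.allclose(self.x[:, 0], 1.0):
            raise ValueError("first design column must be the constant 1")
        if not (0 <= self.treatment_col < self.x.shape[1]):
            raise ValueError("treatment_col out of range")
        if not np.isin(self.x[:, self.treatment_col], (0.0, 1.0)).all():
            raise ValueError("treatment indicator must be 0/1")
        # remap cluster labels to contiguous 0..J-1
        labels, idx = np.unique(self.cluster, return_inverse=True)
        if self.cluster_labels is None:
            self.cluster_labels = labels
        self.cluster = idx
        if not self.outcome_names:
            self.outcome_names = [f"y{k + 1}" for k in range(self.K)]
        if not self.covariate_names:
            self.covariate_names = ["const"] + [f"x{p}" for p in range(1, self.P)]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def K(self) -> int:
        return self.y.shape[1]

    @property
    def P(self) -> int:
        return self.x.shape[1]

    @property
    def J(self) -> int:
        return int(self.cluster.max()) + 1 if self.n else 0

    @property
    def n_j(self) -> np.ndarray:
        """Per-cluster subject counts."""
        return np.bincount(self.cluster, minlength=self.J)

    @property
    def treatment(self) -> np.ndarray:
        return self.x[:, self.treatment_col].astype(np.int64)

    def subset(self, mask: np.ndarray) -> "TrialDataset":
        """Row subset (used for subgroup analyses); keeps cluster labels."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty subset")
        return TrialDataset(
            y=self.y[mask],
            x=self.x[mask],
            cluster=np.asarray(self.cluster_labels)[self.cluster[mask]],
            treatment_col=self.treatment_col,
            outcome_names=list(self.outcome_names),
            covariate_names=list(self.covariate_names),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=self.outcome_names)
        df["cluster"] = np.asarray(self.cluster_labels)[self.cluster]
        for p in range(1, self.P):  # drop the constant column
            df[self.covariate_names[p]] = self.x[:, p]
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome_cols: list[str],
        cluster_col: str,
        treatment_col: str,
        covariate_cols: list[str] | None = None,
    ) -> "TrialDataset":
        for col in [*outcome_cols, cluster_col, treatment_col, *(covariate_cols or [])]:
            if col not in df.columns:
                raise KeyError(f"column '{col}' not found in data")
        covariate_cols = covariate_cols or []
        x = np.column_stack(
            [np.ones(len(df)), df[treatment_col].to_numpy(float)]
            + [df[c].to_numpy(float) for c in covariate_cols]
        )
        return cls(
            y=df[outcome_cols].to_numpy(),
            x=x,
            cluster=df[cluster_col].to_numpy(),
            treatment_col=1,
            outcome_names=list(outcome_cols),
            covariate_names=["const", treatment_col, *covariate_cols],
        )


def read_dataset_csv(
    path,
    outcome_cols: list[str],
    cluster_col: str = "cluster",
    treatment_col: str = "treatment",
    covariate_cols: list[str] | None = None,
) -> TrialDataset:
    """Read a subject-level CSV (comma-separated, header row, '.' decimal)."""
    return TrialDataset.from_dataframe(
        pd.read_csv(path), outcome_cols, cluster_col, treatment_col, covariate_cols
    )


def write_dataset_csv(data: TrialDataset, path) -> None:
    data.to_dataframe().to_csv(path, index=False)
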