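"""Tabular categorical datasets: the unit of exchange between all pipeline stages.

A record is a vector of ``d`` integer category codes plus a binary outcome
(a positive/negative test result). Datasets optionally carry a center id per
record and, internally, provenance tags (owning party and synthetic-replicate
index) used to assert that a party never trains on its own synthetic data.
Provenance is stripped on CSV export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["TabularDataset", "concat_datasets", "split_by_center"]


@dataclass(frozen=True)
class TabularDataset:
    """Immutable table of ``n`` records with ``d`` categorical features.

    Parameters
    ----------
    features
        ``(n, d)`` integer array; column ``j`` holds codes in ``[0, level_counts[j])``.
    outcome
        ``(n,)`` integer array with values in ``{0, 1}``.
    level_counts
        Declared number of levels per feature (the schema, independent of which
        levels happen to be observed).
    center_id
        Optional ``(n,)`` integer center label per record.
    provenance
        Optional ``(n, 2)`` integer array of (party id, replicate id); real
        records carry ``(-1, -1)``.
    """

    features: np.ndarray
    outcome: np.ndarray
    level_counts: tuple[int, ...]
    center_id: np.ndarray | None = None
    provenance: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=np.int64).reshape(-1, len(self.level_counts))
        out = np.asarray(self.outcome, dtype=np.int64).ravel()
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "outcome", out)
        object.__setattr__(self, "level_counts", tuple(int(l) for l in self.level_counts))
        if feats.shape[0] != out.shape[0]:
            raise ValueError("features and outcome disagree on record count")
        if out.size and not np.isin(out, (0, 1)).all():
            raise ValueError("outcome values must lie in {0, 1}")
        for j, lj in enumerate(self.level_counts):
            if lj < 1:
                raise ValueError(f"feature {j} declares {lj} levels")
            col = feats[:, j]
            if col.size and (col.min() < 0 or col.max() >= lj):
                raise ValueError(f"feature {j} has codes outside [0, {lj})")
        if self.center_id is not None:
            cid = np.asarray(self.center_id, dtype=np.int64).ravel()
            if cid.shape[0] != out.shape[0]:
                raise ValueError("center_id length mismatch")
            object.__setattr__(self, "center_id", cid)
        if self.provenance is not None:
            prov = np.asarray(self.provenance, dtype=np.int64).reshape(-1, 2)
            if prov.shape[0] != out.shape[0]:
                raise ValueError("provenance length mismatch")
            object.__setattr__(self, "provenance", prov)

    @property
    def n(self) -> int:
        return int(self.outcome.shape[0])

    @property
    def d(self) -> int:
        return len(self.level_counts)

    def take(self, idx: np.ndarray) -> "TabularDataset":
        """Row subset by integer index array (order preserved)."""
        idx = np.asarray(idx, dtype=np.int64)
        return TabularDataset(
            features=self.features[idx],
            outcome=self.outcome[idx],
            level_counts=self.level_counts,
            center_id=None if self.center_id is None else self.center_id[idx],
            provenance=None if self.provenance is None else self.provenance[idx],
        )

    def with_center(self, center: int) -> "TabularDataset":
        return TabularDataset(
            features=self.features,
            outcome=self.outcome,
            level_counts=self.level_counts,
            center_id=np.full(self.n, int(center), dtype=np.int64),
            provenance=self.provenance,
        )

    def with_provenance(self, party: int, replicate: int) -> "TabularDataset":
        prov = np.column_stack(
            [np.full(self.n, int(party)), np.full(self.n, int(replicate))]
        ).astype(np.int64)
        return TabularDataset(self.features, self.outcome, self.level_counts,
                              self.center_id, prov)

    def feature_marginal(self, j: int) -> np.ndarray:
        """Empirical distribution of feature ``j`` over its declared levels."""
        counts = np.bincount(self.features[:, j], minlength=self.level_counts[j])
        total = counts.sum()
        return counts / total if total else counts.astype(float)

    # -- CSV interchange: header x1..xd, y, optional center; provenance never
    #    leaves the process.
    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.features, columns=[f"x{j + 1}" for j in range(self.d)]
        )
        df["y"] = self.outcome
        if self.center_id is not None:
            df["center"] = self.center_id
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, level_counts: Sequence[int] | None = None
                 ) -> "TabularDataset":
        df = pd.read_csv(path)
        xcols = sorted((c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
                       key=lambda c: int(c[1:]))
        if not xcols or "y" not in df.columns:
            raise ValueError("CSV must provide columns x1..xd and y")
        feats = df[xcols].to_numpy(dtype=np.int64)
        if level_counts is None:
            level_counts = tuple(int(feats[:, j].max()) + 1 for j in range(feats.shape[1]))
        center = df["center"].to_numpy(np.int64) if "center" in df.columns else None
        return cls(feats, df["y"].to_numpy(np.int64), tuple(level_counts), center)


def split_by_center(ds: TabularDataset) -> list[TabularDataset]:
    """Split a multi-center table (e.g. an ingested CSV with a ``center``
    column) into per-center datasets, ordered by center label."""
    if ds.center_id is None:
        raise ValueError("dataset carries no center labels")
    return [ds.take(np.flatnonzero(ds.center_id == m))
            for m in np.unique(ds.center_id)]


def concat_datasets(parts: Sequence[TabularDataset]) -> TabularDataset:
    """Stack datasets sharing a schema; provenance defaults to (-1,-1) for parts
    that carry none if any part carries tags."""
    if not parts:
        raise ValueError("nothing to concatenate")
    lc = parts[0].level_counts
    for p in parts[1:]:
        if p.level_counts != lc:
            raise ValueError("level_counts mismatch between parts")
    any_prov = any(p.provenance is not None for p in parts)
    provs = []
    for p in parts:
        if any_prov:
            provs.append(p.provenance if p.provenance is not None
                         else np.full((p.n, 2), -1, dtype=np.int64))
    any_center = any(p.center_id is not None for p in parts)
    centers = []
    for p in parts:
        if any_center:
            centers.append(p.center_id if p.center_id is not None
                           else np.full(p.n, -1, dtype=np.int64))
    return TabularDataset(
        features=np.concatenate([p.features for p in parts], axis=0),
        outcome=np.concatenate([p.outcome for p in parts]),
        level_counts=lc,
        center_id=np.concatenate(centers) if any_center else None,
        provenance=np.concatenate(provs, axis=0) if any_prov else None,
    )
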