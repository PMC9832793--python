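"""Core containers for right-censored tabular survival data.

A :class:`SurvivalDataset` holds one row per subject: follow-up time in
years, an event indicator, and a mixed continuous/binary feature table in
which missing cells are ``NaN``.  Feature types are carried explicitly so
that downstream stages (imputation models, categorical embeddings) never
have to guess a column's nature from its values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

FeatureKind = Literal["continuous", "binary"]


@dataclass(frozen=True)
class FeatureMeta:
    """Name and kind of a single feature column."""

    name: str
    kind: FeatureKind

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name!r}")


@dataclass
class SurvivalDataset:
    """Subjects x features table with follow-up time and event indicator.

    Parameters
    ----------
    time:
        Strictly positive follow-up time per subject (years).
    event:
        Event indicator per subject, 0 (censored) or 1 (event).
    features:
        Numeric table, one column per feature; missing cells are ``NaN``.
    feature_meta:
        One :class:`FeatureMeta` per feature column, in column order.
    """

    time: np.ndarray
    event: np.ndarray
    features: pd.DataFrame
    feature_meta: list[FeatureMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.ndim != 1 or self.event.shape != self.time.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if len(self.features) != len(self.time):
            raise ValueError("features row count does not match time/event")
        if np.any(self.time <= 0):
            raise ValueError("follow-up times must be strictly positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        names = [m.name for m in self.feature_meta]
        if names != list(self.features.columns):
            raise ValueError("feature_meta must cover every feature column exactly once, in order")
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in feature_meta")
        obs = self.features.to_numpy(dtype=float)
        if np.isinf(obs[~np.isnan(obs)]).any():
            raise ValueError("observed feature cells must be finite")

    # -- basic views ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean observed-cell indicator (True = observed)."""
        return self.features.notna()

    @property
    def is_complete(self) -> bool:
        return bool(self.features.notna().all().all())

    def kinds(self) -> dict[str, FeatureKind]:
        return {m.name: m.kind for m in self.feature_meta}

    def continuous_names(self) -> list[str]:
        return [m.name for m in self.feature_meta if m.kind == "continuous"]

    def binary_names(self) -> list[str]:
        return [m.name for m in self.feature_meta if m.kind == "binary"]

    def subset(self, idx: Sequence[int] | np.ndarray) -> "SurvivalDataset":
        idx = np.asarray(idx)
        return SurvivalDataset(
            time=self.time[idx],
            event=self.event[idx],
            features=self.features.iloc[idx].reset_index(drop=True),
            feature_meta=list(self.feature_meta),
        )

    def select_features(self, names: Iterable[str]) -> "SurvivalDataset":
        names = list(names)
        meta = {m.name: m for m in self.feature_meta}
        return SurvivalDataset(
            time=self.time.copy(),
            event=self.event.copy(),
            features=self.features[names].copy(),
            feature_meta=[meta[n] for n in names],
        )

    def copy(self) -> "SurvivalDataset":
        return SurvivalDataset(
            time=self.time.copy(),
            event=self.event.copy(),
            features=self.features.copy(),
            feature_meta=list(self.feature_meta),
        )

    # -- IO ------------------------------------------------------------

    def to_csv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        """Write ``id,time,event,<features...>`` CSV plus a side-car meta JSON.

        Missing cells are written as empty fields.
        """
        path = Path(path)
        out = pd.DataFrame({"id": np.arange(self.n), "time": self.time, "event": self.event})
        out = pd.concat([out, self.features.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False)
        meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
        meta = [{"name": m.name, "kind": m.kind} for m in self.feature_meta]
        meta_path.write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path, meta_path: str | Path | None = None) -> "SurvivalDataset":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
        meta = [FeatureMeta(**m) for m in json.loads(meta_path.read_text())]
        cols = [m.name for m in meta]
        return cls(
            time=df["time"].to_numpy(),
            event=df["event"].to_numpy(),
            features=df[cols].astype(float),
            feature_meta=meta,
        )


def child_seed(master: int, *tags: object) -> int:
    """Derive a reproducible child seed (< 2**31) from a master seed and tags.

    Every source of randomness in the package draws its seed through this
    single fan-out so that any stage of a run can be replayed in isolation.
    """
    import hashlib

    key = hashlib.sha256(("|".join(str(t) for t in (master, *tags))).encode()).digest()
    return int.from_bytes(key[:4], "big") % (2**31 - 1)


def child_rng(master: int, *tags: object) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, *tags))
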