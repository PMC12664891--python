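"""TMT channel design: which channel is which sample, and the impurity matrix.

A plex is an ordered list of channels.  Each channel is either an
experimental sample (a condition label plus a replicate index) or the
carrier — a channel loaded with an excess of fully heavy-IAA-labeled
proteome whose only purpose is to boost precursor signal of oxidized
peptides.  At most one carrier is allowed and it is excluded from every
quantitative statistic downstream.

The isotope impurity matrix is the vendor lot-sheet cross-contamination
matrix: row = true channel, column = observed channel, rows sum to 1.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

CARRIER = "carrier"

_ROW_SUM_TOL = 1e-9


class DesignError(ValueError):
    """Invalid channel design (bad roles, carrier count, or impurity matrix)."""


@dataclasses.dataclass(frozen=True)
class Channel:
    name: str
    condition: str | None = None
    replicate: int | None = None
    is_carrier: bool = False

    def __post_init__(self) -> None:
        if self.is_carrier:
            if self.condition is not None or self.replicate is not None:
                raise DesignError(
                    f"carrier channel {self.name!r} cannot carry a condition/replicate"
                )
        else:
            if self.condition is None or self.replicate is None:
                raise DesignError(
                    f"sample channel {self.name!r} needs condition and replicate"
                )


@dataclasses.dataclass(frozen=True)
class ChannelDesign:
    """Ordered TMT channels with roles and an optional impurity matrix."""

    channels: tuple[Channel, ...]
    impurity_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise DesignError("channel names must be unique")
        n_carrier = sum(c.is_carrier for c in self.channels)
        if n_carrier > 1:
            raise DesignError(f"at most one carrier channel allowed, got {n_carrier}")
        if self.impurity_matrix is not None:
            m = np.asarray(self.impurity_matrix, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise DesignError("impurity matrix must be square")
            if m.shape[0] != len(self.channels):
                raise DesignError(
                    f"impurity matrix is {m.shape[0]}x{m.shape[0]} but design has "
                    f"{len(self.channels)} channels"
                )
            if (m < 0).any():
                raise DesignError("impurity matrix entries must be non-negative")
            if not np.allclose(m.sum(axis=1), 1.0, atol=_ROW_SUM_TOL, rtol=0):
                raise DesignError("impurity matrix rows must sum to 1")
            object.__setattr__(self, "impurity_matrix", m)

    # -- convenience views -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def carrier_index(self) -> int | None:
        for i, c in enumerate(self.channels):
            if c.is_carrier:
                return i
        return None

    @property
    def sample_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.channels) if not c.is_carrier]

    @property
    def sample_names(self) -> list[str]:
        return [self.channels[i].name for i in self.sample_indices]

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels in channel order."""
        seen: list[str] = []
        for c in self.channels:
            if not c.is_carrier and c.condition not in seen:
                seen.append(c.condition)
        return seen

    def condition_of(self, channel_name: str) -> str | None:
        for c in self.channels:
            if c.name == channel_name:
                return None if c.is_carrier else c.condition
        raise KeyError(channel_name)

    def sample_groups(self) -> pd.Series:
        """Condition label per sample channel, indexed by channel name."""
        return pd.Series(
            {c.name: c.condition for c in self.channels if not c.is_carrier},
            name="condition",
        )

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        entries = []
        for c in self.channels:
            if c.is_carrier:
                entries.append({"name": c.name, "role": CARRIER})
            else:
                entries.append(
                    {"name": c.name, "condition": c.condition, "replicate": c.replicate}
                )
        doc: dict = {"channels": entries}
        path = Path(path)
        if self.impurity_matrix is not None:
            mat_path = path.with_suffix(".impurities.tsv")
            write_impurity_matrix(self.impurity_matrix, self.names, mat_path)
            doc["impurity_matrix"] = mat_path.name
        path.write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChannelDesign":
        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        if not isinstance(doc, dict) or "channels" not in doc:
            raise DesignError(f"{path}: expected a mapping with a 'channels' list")
        channels = []
        for e in doc["channels"]:
            if e.get("role") == CARRIER:
                channels.append(Channel(name=str(e["name"]), is_carrier=True))
            else:
                channels.append(
                    Channel(
                        name=str(e["name"]),
                        condition=str(e["condition"]),
                        replicate=int(e["replicate"]),
                    )
                )
        matrix = None
        if "impurity_matrix" in doc:
            mat_path = Path(doc["impurity_matrix"])
            if not mat_path.is_absolute():
                mat_path = path.parent / mat_path
            matrix, _ = read_impurity_matrix(mat_path)
        return cls(channels=tuple(channels), impurity_matrix=matrix)


def simple_design(
    conditions: Sequence[str],
    n_replicates: int,
    carrier: bool = True,
    impurity_matrix: np.ndarray | None = None,
) -> ChannelDesign:
    """Build a one-plex design: replicates nested in conditions, carrier last.

    Channel names follow TMT convention loosely ("126", "127", ...).
    """
    channels = []
    k = 126
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            channels.append(Channel(name=str(k), condition=cond, replicate=rep))
            k += 1
    if carrier:
        channels.append(Channel(name=str(k), is_carrier=True))
    return ChannelDesign(channels=tuple(channels), impurity_matrix=impurity_matrix)


def tmt_like_impurity_matrix(n_channels: int, leak: float = 0.05) -> np.ndarray:
    """Diagonally dominant row-stochastic matrix mimicking a TMT lot sheet.

    Each channel leaks `leak` of its signal into each adjacent channel
    (one-sided at the plex edges); the diagonal absorbs the remainder so
    rows sum to 1 exactly.
    """
    if not 0 <= leak < 0.5:
        raise ValueError("leak must be in [0, 0.5)")
    m = np.zeros((n_channels, n_channels))
    for i in range(n_channels):
        if i > 0:
            m[i, i - 1] = leak
        if i < n_channels - 1:
            m[i, i + 1] = leak
        m[i, i] = 1.0 - m[i].sum()
    return m


def write_impurity_matrix(
    matrix: np.ndarray, channel_names: Sequence[str], path: str | Path
) -> None:
    df = pd.DataFrame(matrix, index=list(channel_names), columns=list(channel_names))
    df.to_csv(path, sep="\t", index_label="channel")


def read_impurity_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a channels x channels TSV (lot-sheet layout, row = true channel)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise DesignError(f"{path}: impurity matrix must be square, got {df.shape}")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]
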