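"""Core data containers shared by every pipeline stage.

A :class:`MetaboliteTable` is a samples x variables concentration matrix with
a binary group label per sample and a biofluid block tag per variable; it is
the unit every stage of the workflow consumes and produces.  Variables are
named ``"<block>__<metabolite>"`` so that names stay unique after multiblock
fusion.  :class:`ScalingParams` holds per-variable autoscaling statistics and
:class:`SpectrumSet` holds spectrum-like intensity vectors on a shared
chemical-shift (ppm) axis for the normalization/binning stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MetaboliteTable",
    "ScalingParams",
    "SpectrumSet",
    "ConfigurationError",
]

BLOCK_SEP = "__"


class ConfigurationError(ValueError):
    """Raised when a configuration references names or values that do not fit."""


@dataclass
class MetaboliteTable:
    """Samples x variables matrix with group labels and block-tagged names.

    Parameters
    ----------
    sample_ids
        Unique identifier per row.
    group_labels
        One label per sample; exactly two distinct labels are required.
    values
        ``(n_samples, n_variables)`` float matrix, no missing values.
    variable_names
        Unique names of the form ``"<block>__<metabolite>"``.
    block_of_variable
        Map variable name -> block name.  Derived from the names when omitted.
    """

    sample_ids: list[str]
    group_labels: np.ndarray
    values: np.ndarray
    variable_names: list[str]
    block_of_variable: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group_labels = np.asarray(self.group_labels, dtype=object)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_names = [str(v) for v in self.variable_names]
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.group_labels) != n:
            raise ValueError("sample ids / labels do not match the value matrix")
        if len(self.variable_names) != p:
            raise ValueError("variable names do not match the value matrix")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if len(set(self.variable_names)) != p:
            raise ValueError("variable names must be unique across blocks")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("value matrix contains missing or non-finite entries")
        # two labels for a full cohort; single-group row subsets are permitted
        if not 1 <= len(set(self.group_labels)) <= 2:
            raise ValueError("at most two distinct group labels are supported")
        if not self.block_of_variable:
            self.block_of_variable = {
                v: v.split(BLOCK_SEP, 1)[0] if BLOCK_SEP in v else "block"
                for v in self.variable_names
            }

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.group_labels))

    @property
    def blocks(self) -> list[str]:
        seen: list[str] = []
        for v in self.variable_names:
            b = self.block_of_variable[v]
            if b not in seen:
                seen.append(b)
        return seen

    def group_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.group_labels == label)

    # -- subsetting --------------------------------------------------------
    def select_samples(self, ids_or_idx) -> "MetaboliteTable":
        """Row subset, by sample id (strings) or positional index (ints)."""
        if len(ids_or_idx) and isinstance(next(iter(ids_or_idx)), str):
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = [pos[s] for s in ids_or_idx]
        else:
            idx = list(ids_or_idx)
        return MetaboliteTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            group_labels=self.group_labels[idx],
            values=self.values[idx],
            variable_names=list(self.variable_names),
            block_of_variable=dict(self.block_of_variable),
        )

    def select_variables(self, names) -> "MetaboliteTable":
        names = list(names)
        pos = {v: j for j, v in enumerate(self.variable_names)}
        missing = [v for v in names if v not in pos]
        if missing:
            raise KeyError(f"unknown variables: {missing}")
        cols = [pos[v] for v in names]
        return MetaboliteTable(
            sample_ids=list(self.sample_ids),
            group_labels=self.group_labels.copy(),
            values=self.values[:, cols],
            variable_names=names,
            block_of_variable={v: self.block_of_variable[v] for v in names},
        )

    def select_blocks(self, blocks) -> "MetaboliteTable":
        blocks = set(blocks)
        keep = [v for v in self.variable_names if self.block_of_variable[v] in blocks]
        if not keep:
            raise KeyError(f"no variables found for blocks {sorted(blocks)}")
        return self.select_variables(keep)

    # -- I/O ----------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, "group", self.group_labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MetaboliteTable":
        if list(df.columns[:2]) != ["sample_id", "group"]:
            raise ValueError("expected columns: sample_id, group, <block>__<metabolite>...")
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            group_labels=df["group"].to_numpy(dtype=object),
            values=df.iloc[:, 2:].to_numpy(dtype=float),
            variable_names=[str(c) for c in df.columns[2:]],
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "MetaboliteTable":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass
class ScalingParams:
    """Per-variable autoscaling statistics, estimated on the model set only."""

    variable_names: list[str]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.variable_names) == self.mean.size == self.sd.size):
            raise ValueError("mean/sd length must match variable names")

    def subset(self, names) -> "ScalingParams":
        pos = {v: j for j, v in enumerate(self.variable_names)}
        idx = [pos[v] for v in names]
        return ScalingParams(list(names), self.mean[idx], self.sd[idx])

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "variable_names": self.variable_names,
                    "mean": self.mean.tolist(),
                    "sd": self.sd.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "ScalingParams":
        d = json.loads(Path(path).read_text())
        return cls(d["variable_names"], np.array(d["mean"]), np.array(d["sd"]))


@dataclass
class SpectrumSet:
    """Spectrum-like intensity vectors on a shared, strictly decreasing ppm axis."""

    ppm: np.ndarray
    intensities: np.ndarray
    true_dilutions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.ppm.ndim != 1 or self.intensities.shape[1] != self.ppm.size:
            raise ValueError("intensity matrix must be samples x len(ppm)")
        d = np.diff(self.ppm)
        if not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.true_dilutions is not None:
            self.true_dilutions = np.asarray(self.true_dilutions, dtype=float)
            if self.true_dilutions.size != self.intensities.shape[0]:
                raise ValueError("one dilution factor per spectrum required")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]
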