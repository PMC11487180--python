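"""Protein-microarray hit calling.

Turns an array results table (probe id, gene symbol, signal and/or Z-score)
into a gene-level candidate-interactor list: signals are standardized to
Z-scores and probes whose Z strictly exceeds a threshold (default 2.5) are
nominated, collapsing duplicate probes per gene to their maximum Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateInputError",
    "ArrayDataset",
    "HitList",
    "read_array_table",
    "compute_zscores",
    "call_hits",
    "write_hits",
    "write_audit",
]

DEFAULT_Z_THRESHOLD = 2.5

#: 1 / Phi^{-1}(3/4): scales the median absolute deviation to a Gaussian SD
MAD_SCALE = 1.4826


class DegenerateInputError(ValueError):
    """Raised when the signal distribution has no spread to standardize by."""


def _harmonize(symbols: pd.Series) -> pd.Series:
    return symbols.astype(str).str.strip().str.upper()


@dataclass
class ArrayDataset:
    """Per-probe microarray records.

    ``frame`` columns: ``probe_id`` (unique), ``symbol`` (harmonized gene
    symbol), ``signal`` (fluorescence, a.u.), optional ``z``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "symbol", "signal"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"array table lacks columns: {sorted(missing)}")
        frame = self.frame.copy()
        frame["symbol"] = _harmonize(frame["symbol"])
        if frame["probe_id"].duplicated().any():
            raise ValueError("probe ids must be unique")
        if not np.isfinite(frame["signal"].to_numpy(dtype=float)).all():
            raise ValueError("signals must be finite")
        if "z" in frame.columns:
            z = frame["z"].to_numpy(dtype=float)
            if np.isnan(z).all():
                frame = frame.drop(columns="z")
            elif not np.isfinite(z).all():
                raise ValueError("z values, when present, must be finite")
        self.frame = frame

    @property
    def has_z(self) -> bool:
        return "z" in self.frame.columns

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class HitList:
    """Gene-level hits: unique symbols ordered by decreasing Z, with the
    per-gene maximum Z and the threshold used."""

    symbols: list[str]
    max_z: dict[str, float]
    threshold: float = DEFAULT_Z_THRESHOLD

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.max_z


def read_array_table(
    path,
    *,
    probe_col: str = "probe_id",
    symbol_col: str = "symbol",
    signal_col: str = "signal",
    z_col: str | None = "z",
) -> ArrayDataset:
    """Read a delimited text table or a spreadsheet workbook (first sheet).

    Column names are remapped to the canonical schema.  A Z column is used
    when present; otherwise it is left absent for :func:`compute_zscores`.
    If the table carries no probe-id column, row numbers are used.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm", ".xls"}:
        raw = pd.read_excel(path, sheet_name=0)
    else:
        raw = pd.read_csv(path, sep=None, engine="python")
    rename = {symbol_col: "symbol", signal_col: "signal", probe_col: "probe_id"}
    if z_col:
        rename[z_col] = "z"
    raw = raw.rename(columns={k: v for k, v in rename.items()
                              if k in raw.columns})
    if "probe_id" not in raw.columns:
        raw["probe_id"] = [f"ROW{i:06d}" for i in range(len(raw))]
    if "signal" not in raw.columns and "z" in raw.columns:
        # some deposited tables carry only precomputed Z
        raw["signal"] = raw["z"]
    keep = [c for c in ("probe_id", "symbol", "signal", "z") if c in raw.columns]
    return ArrayDataset(raw[keep])


def compute_zscores(dataset: ArrayDataset, method: str = "mean_sd") -> ArrayDataset:
    """Standardize signals to Z-scores.

    ``mean_sd``: z = (x - mean) / sd with the sample SD (ddof=1).
    ``median_mad``: z = (x - median) / (1.4826 * MAD), robust to the heavy
    upper tail true binders put on the signal distribution.

    Z is invariant under affine transforms of the signal.  A distribution
    with zero spread cannot be standardized and raises
    :class:`DegenerateInputError`.
    """
    x = dataset.frame["signal"].to_numpy(dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateInputError("need at least two distinct signal values")
    if method == "mean_sd":
        scale = x.std(ddof=1)
        center = x.mean()
    elif method == "median_mad":
        center = np.median(x)
        scale = MAD_SCALE * np.median(np.abs(x - center))
    else:
        raise ValueError(f"unknown method {method!r}")
    if scale == 0:
        raise DegenerateInputError(f"zero spread under method {method!r}")
    frame = dataset.frame.copy()
    frame["z"] = (x - center) / scale
    return ArrayDataset(frame)


def call_hits(dataset: ArrayDataset,
              threshold: float = DEFAULT_Z_THRESHOLD) -> HitList:
    """Nominate genes whose Z strictly exceeds ``threshold``.

    Probes are collapsed to genes by the maximum Z per symbol before
    filtering; the boundary value Z == threshold is not a hit.
    """
    if not dataset.has_z:
        raise ValueError("dataset has no z column; run compute_zscores first")
    per_gene = dataset.frame.groupby("symbol", sort=False)["z"].max()
    hits = per_gene[per_gene > threshold].sort_values(ascending=False)
    return HitList(symbols=list(hits.index),
                   max_z=hits.to_dict(),
                   threshold=threshold)


def write_hits(hits: HitList, path) -> None:
    with open(path, "w") as fh:
        for sym in hits.symbols:
            fh.write(sym + "\n")


def write_audit(hits: HitList, path) -> None:
    pd.DataFrame({
        "symbol": hits.symbols,
        "max_z": [hits.max_z[s] for s in hits.symbols],
        "threshold": hits.threshold,
    }).to_csv(path, sep="\t", index=False)
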