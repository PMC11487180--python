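"""Cilium and centrosome morphometry from per-cell records.

Two readouts of ciliogenesis and centrosomal cohesion:

* ciliation — the percentage of cells per imaging field bearing a primary
  cilium, with the mean cilium length over ciliated cells;
* centrosome cohesion — duplicated centrosomes are scored "split" when the
  Euclidean distance between their centers, measured on a maximum-intensity
  projection (hence in 2D), strictly exceeds 2.5 um.  Mitotic cells are
  excluded from scoring.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "SPLIT_THRESHOLD_UM",
    "MitoticRecordError",
    "read_morphometry",
    "centrosome_distance",
    "centrosome_distances",
    "classify_split",
    "split_fraction",
    "ciliation_summary",
    "permutation_group_test",
]

SPLIT_THRESHOLD_UM = 2.5


class MitoticRecordError(ValueError):
    """Raised when a mitotic record reaches a scorer that must exclude it."""


def read_morphometry(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def centrosome_distance(c1, c2, mitotic: bool = False) -> float:
    """Euclidean inter-centrosome distance (um) in the projection plane."""
    if mitotic:
        raise MitoticRecordError("mitotic cells are excluded from scoring")
    (x1, y1), (x2, y2) = c1, c2
    return float(np.hypot(x2 - x1, y2 - y1))


def centrosome_distances(pairs: pd.DataFrame) -> pd.Series:
    """Distances for all non-mitotic records of a centrosome table
    (columns cx1, cy1, cx2, cy2 and optional mitotic flag)."""
    df = pairs
    if "mitotic" in df.columns:
        df = df[~df["mitotic"].astype(bool)]
    d = np.hypot(df["cx2"] - df["cx1"], df["cy2"] - df["cy1"])
    if not np.isfinite(d).all():
        raise ValueError("centrosome coordinates must be finite")
    return pd.Series(d, index=df.index, name="distance_um")


def classify_split(distance, threshold: float = SPLIT_THRESHOLD_UM):
    """Split iff distance strictly exceeds the threshold (boundary value at
    exactly the threshold scores not-split)."""
    return np.asarray(distance) > threshold


def split_fraction(pairs: pd.DataFrame, per: str = "group",
                   threshold: float = SPLIT_THRESHOLD_UM) -> pd.DataFrame:
    """Fraction of non-mitotic cells with split centrosomes, per group.

    ``per='group'``: binomial SEM sqrt(p(1-p)/n) over cells.
    ``per='field'``: per-field fractions first, then mean +/- SEM across
    fields (requires a ``field`` column).
    """
    df = pairs
    if "mitotic" in df.columns:
        df = df[~df["mitotic"].astype(bool)]
    if df.empty:
        raise ValueError("no scorable (non-mitotic) records")
    df = df.assign(split=classify_split(centrosome_distances(df), threshold))
    group_key = df["group"] if "group" in df.columns else "all"
    rows = []
    for name, sub in df.groupby(group_key):
        if per == "field":
            if "field" not in sub.columns:
                raise ValueError("per='field' requires a field column")
            per_field = sub.groupby("field")["split"].mean()
            frac = per_field.mean()
            sem = per_field.std(ddof=1) / np.sqrt(len(per_field)) \
                if len(per_field) > 1 else np.nan
        else:
            frac = sub["split"].mean()
            sem = np.sqrt(frac * (1 - frac) / len(sub))
        rows.append({"group": name, "n": len(sub),
                     "split_fraction": float(frac), "sem": float(sem)})
    return pd.DataFrame(rows)


def ciliation_summary(cells: pd.DataFrame, per: str = "field") -> pd.DataFrame:
    """Percentage of ciliated cells and mean cilium length per group.

    Percentages are formed per imaging field and averaged (mean +/- SEM
    across fields) when ``per='field'``; ``per='group'`` pools cells with a
    binomial SEM.  Lengths are summarized over ciliated cells only; a group
    with no ciliated cells reports a 0% fraction and no length summary.
    """
    if cells.empty:
        raise ValueError("no cell records")
    group_key = cells["group"] if "group" in cells.columns else "all"
    rows = []
    for name, sub in cells.groupby(group_key):
        cil = sub["ciliated"].astype(bool)
        if per == "field":
            if "field" not in sub.columns:
                raise ValueError("per='field' requires a field column")
            per_field = sub.groupby("field")["ciliated"].mean() * 100.0
            pct = per_field.mean()
            pct_sem = per_field.std(ddof=1) / np.sqrt(len(per_field)) \
                if len(per_field) > 1 else np.nan
        else:
            pct = cil.mean() * 100.0
            pct_sem = 100.0 * np.sqrt(cil.mean() * (1 - cil.mean()) / len(sub))
        lengths = sub.loc[cil, "length_um"].dropna() \
            if "length_um" in sub.columns else pd.Series(dtype=float)
        row = {"group": name, "n_cells": len(sub),
               "percent_ciliated": float(pct),
               "percent_sem": float(pct_sem)}
        if len(lengths):
            row["length_mean_um"] = float(lengths.mean())
            row["length_sem_um"] = float(
                lengths.std(ddof=1) / np.sqrt(len(lengths))
            ) if len(lengths) > 1 else np.nan
        else:
            row["length_mean_um"] = np.nan
            row["length_sem_um"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def permutation_group_test(values_a, values_b, stat: str = "mean_diff",
                           n_perm: int = 10000, seed=None) -> float:
    """Two-sided label-permutation p-value for a two-group comparison.

    ``mean_diff`` compares group means; ``fraction_diff`` treats values as
    booleans and compares fractions (the statistic is the same mean
    difference on 0/1 data).  Ties count toward the p-value, and the
    observed labelling is included: p = (1 + #{|T*| >= |T|}) / (1 + n_perm).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if stat not in {"mean_diff", "fraction_diff"}:
        raise ValueError(f"unknown statistic {stat!r}")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value")
    pooled = np.concatenate([a, b])
    n_a = a.size
    t_obs = abs(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    exceed = 0
    # permute in blocks to bound memory at large n_perm
    block = 1000
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        keys = rng.random((m, pooled.size))
        order = np.argsort(keys, axis=1)
        perm = pooled[order]
        t = np.abs(perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1))
        exceed += int((t >= t_obs - 1e-12).sum())
        done += m
    return (1 + exceed) / (1 + n_perm)
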