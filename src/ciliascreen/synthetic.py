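"""Synthetic data generation for every pipeline input class.

Each generator emulates one experimental readout with known ground truth:

* protein-microarray signal vectors (null background plus spiked binders),
* gene universe / annotation set / query list with a planted overlap,
* microscale-thermophoresis (MST) dose-response series from the 1:1
  ligand-depletion isotherm with Gaussian noise,
* per-cell morphometry records (ciliation, cilium length, centrosome pairs).

Array signals are simulated directly on the Z scale: the downstream screen
filters on standardized signals, so a standard-Gaussian background with
mean-shifted true binders captures everything the hit caller sees.  True
interactors are a mean shift of ``hit_effect`` standard deviations.

Determinism: every generator derives its own independent RNG stream from
``(STREAM_ID, config.seed)`` via :func:`numpy.random.default_rng`, so the same
config reproduces each output bit-for-bit regardless of which generators are
called or in which order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_hits import ArrayDataset
from .binding import DoseResponse, binding_isotherm
from .enrichment import GeneCollections

__all__ = [
    "ParameterError",
    "SimulationConfig",
    "gen_array_dataset",
    "gen_annotation",
    "gen_mst_experiment",
    "gen_cell_population",
    "gen_centrosome_population",
    "write_array_table",
    "write_gene_collections",
    "write_dose_response",
    "write_cells",
    "write_centrosomes",
]


class ParameterError(ValueError):
    """Raised when a simulation parameter is out of its valid range."""


# stream ids for per-generator RNG derivation (documented in the docstring)
_STREAM_ARRAY = 1
_STREAM_GENES = 2
_STREAM_MST = 3
_STREAM_CILIA = 4
_STREAM_CENTROSOME = 5


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for all synthetic generators.

    Defaults mirror the study conditions of the screen this package models:
    a ~20k-protein array filtered at Z > 2.5, a gene universe of 24609
    symbols with a 640-gene ciliary set and a 147-gene query sharing 6
    members, a 16-point two-fold MST titration from 110 uM against a 100 nM
    labelled target with a 10.2 uM dissociation constant, and neuronal cell
    populations with ~13.7% ciliation and 1.9 um mean cilium length.
    """

    seed: int = 0

    # protein microarray (Z-scale simulation)
    n_probes: int = 20000
    n_true_hits: int = 50
    hit_effect: float = 6.0        # Z-shift of true binders
    array_noise_sd: float = 1.0    # null spread on the Z scale

    # gene collections
    universe_size: int = 24609
    set_size: int = 640
    list_size: int = 147
    planted_overlap: int = 6

    # MST titration
    kd_true: float = 10.2e-6       # M
    target_conc: float = 100e-9    # M, labelled target
    titration_top: float = 110e-6  # M, highest ligand concentration
    dilution_factor: float = 2.0
    n_dilutions: int = 16
    n_replicates: int = 3
    fnorm_baseline: float = 900.0  # per-mille units
    fnorm_amplitude: float = 40.0  # per-mille units (sign free)
    noise_sd: float = 2.0          # Fnorm units; 2.0 = 5% of the amplitude

    # cell morphometry
    n_cells: int = 1000
    cells_per_field: int = 35
    ciliation_prob: float = 0.137
    length_mean: float = 1.9       # um
    length_sd: float = 0.24        # um
    split_fraction: float = 0.2
    mitotic_fraction: float = 0.05
    cohesive_distance: tuple[float, float] = (0.2, 2.4)   # um, uniform range
    split_distance: tuple[float, float] = (3.0, 8.0)      # um, uniform range

    def validate(self) -> None:
        c = self
        if min(c.n_probes, c.n_true_hits, c.universe_size, c.set_size,
               c.list_size, c.planted_overlap, c.n_dilutions, c.n_replicates,
               c.n_cells, c.cells_per_field) < 0:
            raise ParameterError("counts must be non-negative")
        if c.n_true_hits > c.n_probes:
            raise ParameterError("n_true_hits exceeds n_probes")
        if c.set_size > c.universe_size or c.list_size > c.universe_size:
            raise ParameterError("gene set / list larger than the universe")
        if c.planted_overlap > min(c.set_size, c.list_size):
            raise ParameterError("planted_overlap exceeds min(set, list) size")
        if c.list_size - c.planted_overlap > c.universe_size - c.set_size:
            raise ParameterError("not enough off-set symbols for the query")
        for p in (c.ciliation_prob, c.split_fraction, c.mitotic_fraction):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("probabilities must lie in [0, 1]")
        if c.dilution_factor <= 1.0:
            raise ParameterError("dilution_factor must exceed 1")
        if c.kd_true <= 0 or c.target_conc <= 0 or c.titration_top <= 0:
            raise ParameterError("concentrations must be positive")
        if c.noise_sd < 0 or c.array_noise_sd < 0 or c.length_sd < 0:
            raise ParameterError("noise levels must be non-negative")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, int(config.seed)])


def _symbol(i: int) -> str:
    return f"G{i:06d}"


# ---------------------------------------------------------------------------
# protein microarray


def gen_array_dataset(config: SimulationConfig) -> tuple[ArrayDataset, np.ndarray]:
    """Simulate a protein-microarray result table on the Z scale.

    Returns the dataset (probe id, gene symbol, signal, z — signal and z
    coincide because the null is standard Gaussian) and a boolean truth
    vector marking the spiked true interactors.
    """
    config.validate()
    rng = _rng(config, _STREAM_ARRAY)
    z = rng.normal(0.0, config.array_noise_sd, size=config.n_probes)
    truth = np.zeros(config.n_probes, dtype=bool)
    if config.n_true_hits:
        planted = rng.choice(config.n_probes, size=config.n_true_hits,
                             replace=False)
        z[planted] += config.hit_effect
        truth[planted] = True
    frame = pd.DataFrame({
        "probe_id": [f"P{i:06d}" for i in range(config.n_probes)],
        "symbol": [_symbol(i) for i in range(config.n_probes)],
        "signal": z,
        "z": z,
    })
    return ArrayDataset(frame), truth


# ---------------------------------------------------------------------------
# gene collections


def gen_annotation(config: SimulationConfig) -> GeneCollections:
    """Build a universe, an annotation gene set and a query list sharing
    exactly ``planted_overlap`` symbols with the set."""
    config.validate()
    rng = _rng(config, _STREAM_GENES)
    universe = [_symbol(i) for i in range(config.universe_size)]
    set_idx = rng.choice(config.universe_size, size=config.set_size,
                         replace=False)
    in_set = np.zeros(config.universe_size, dtype=bool)
    in_set[set_idx] = True
    off_idx = np.flatnonzero(~in_set)

    shared = rng.choice(set_idx, size=config.planted_overlap, replace=False)
    rest = rng.choice(off_idx, size=config.list_size - config.planted_overlap,
                      replace=False)
    query_idx = rng.permutation(np.concatenate([shared, rest]))
    return GeneCollections(
        universe=frozenset(universe),
        gene_set=frozenset(_symbol(i) for i in set_idx),
        query=tuple(_symbol(i) for i in query_idx),
    )


# ---------------------------------------------------------------------------
# MST titration


def titration_ladder(config: SimulationConfig) -> np.ndarray:
    """Serial-dilution ladder, highest first: top / factor**i."""
    i = np.arange(config.n_dilutions)
    return config.titration_top / config.dilution_factor ** i


def gen_mst_experiment(config: SimulationConfig) -> DoseResponse:
    """Simulate replicated normalized-fluorescence dose-response points from
    the 1:1 ligand-depletion isotherm plus Gaussian noise."""
    config.validate()
    if config.n_dilutions < 4:
        raise ParameterError("need at least 4 dilution points")
    rng = _rng(config, _STREAM_MST)
    ladder = titration_ladder(config)
    fb = binding_isotherm(ladder, config.target_conc, config.kd_true)
    clean = config.fnorm_baseline + config.fnorm_amplitude * fb
    rows = []
    for rep in range(1, config.n_replicates + 1):
        noise = rng.normal(0.0, config.noise_sd, size=ladder.size)
        rows.append(pd.DataFrame({
            "conc_M": ladder,
            "fnorm": clean + noise,
            "replicate": rep,
        }))
    frame = pd.concat(rows, ignore_index=True)
    return DoseResponse(frame, target_conc=config.target_conc)


# ---------------------------------------------------------------------------
# cell morphometry


def gen_cell_population(config: SimulationConfig) -> pd.DataFrame:
    """Per-cell ciliation records: Bernoulli ciliation flags and positive
    truncated-Gaussian cilium lengths for the ciliated cells.

    Cells are grouped into imaging fields of ``cells_per_field`` so per-field
    summaries (the aggregation unit of the violin plots this emulates) can be
    formed downstream.
    """
    config.validate()
    rng = _rng(config, _STREAM_CILIA)
    n = config.n_cells
    ciliated = rng.random(n) < config.ciliation_prob
    length = np.full(n, np.nan)
    todo = np.flatnonzero(ciliated)
    # rejection-sample the truncation at zero; a couple of rounds suffice
    while todo.size:
        draw = rng.normal(config.length_mean, config.length_sd, size=todo.size)
        ok = draw > 0
        length[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return pd.DataFrame({
        "cell_id": [f"C{i:05d}" for i in range(n)],
        "group": "synthetic",
        "field": np.arange(n) // max(config.cells_per_field, 1),
        "transfected": True,
        "ciliated": ciliated,
        "length_um": length,
    })


def gen_centrosome_population(config: SimulationConfig) -> pd.DataFrame:
    """Paired centrosome coordinates with a planted split fraction.

    Inter-centrosome distances are drawn from two regimes: a cohesive range
    below the 2.5 um scoring threshold and a split range above it, chosen
    with probability ``split_fraction``.  A ``mitotic_fraction`` of records
    is flagged mitotic; scoring excludes them.
    """
    config.validate()
    rng = _rng(config, _STREAM_CENTROSOME)
    n = config.n_cells
    split = rng.random(n) < config.split_fraction
    d = np.where(
        split,
        rng.uniform(*config.split_distance, size=n),
        rng.uniform(*config.cohesive_distance, size=n),
    )
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    cx1 = rng.uniform(0.0, 100.0, size=n)
    cy1 = rng.uniform(0.0, 100.0, size=n)
    return pd.DataFrame({
        "cell_id": [f"C{i:05d}" for i in range(n)],
        "group": "synthetic",
        "mitotic": rng.random(n) < config.mitotic_fraction,
        "cx1": cx1,
        "cy1": cy1,
        "cx2": cx1 + d * np.cos(theta),
        "cy2": cy1 + d * np.sin(theta),
    })


# ---------------------------------------------------------------------------
# writers (all round-trip through the downstream readers)


def write_array_table(dataset: ArrayDataset, path) -> None:
    dataset.frame.to_csv(path, sep="\t", index=False)


def write_gene_collections(collections: GeneCollections, universe_path,
                           gmt_path, query_path,
                           set_name: str = "SYNTHETIC_SET") -> None:
    with open(universe_path, "w") as fh:
        for sym in sorted(collections.universe):
            fh.write(sym + "\n")
    with open(gmt_path, "w") as fh:
        members = "\t".join(sorted(collections.gene_set))
        fh.write(f"{set_name}\tsynthetic annotation set\t{members}\n")
    with open(query_path, "w") as fh:
        for sym in collections.query:
            fh.write(sym + "\n")


def write_dose_response(dr: DoseResponse, path) -> None:
    dr.frame.to_csv(path, sep="\t", index=False)


def write_cells(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, sep="\t", index=False)


def write_centrosomes(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)
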