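"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a short treated-vs-control expression time course:
per-gene log2 baselines, seven temporal response archetypes for the truly
responding genes, zero-mean Gaussian measurement noise whose SD decreases
with intensity, and a duplicate time-0 sample in both conditions (the
source of the empirical error model).  It also fabricates a small
single-root is_a ontology with ancestor-closed annotations and planted
enriched terms, and a qPCR-style cycle-threshold matrix on a denser time
grid, so that every downstream stage can be exercised without external
downloads.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Callable, Sequence
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import TimeSeriesExperiment
from .ontology import AnnotationMap, OntologyDAG

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "InvalidGridError",
    "default_noise_sd",
    "generate_patterns",
    "simulate_timeseries",
    "simulate_ontology",
    "SimulatedOntology",
    "simulate_qpcr",
    "DEFAULT_TIMES",
    "QPCR_TIMES",
    "N_PATTERNS",
]

#: Default microarray sampling grid (minutes).
DEFAULT_TIMES = (0.0, 40.0, 100.0, 200.0, 340.0, 440.0)
#: Denser grid used by the qPCR design (minutes, 10 points over 0-480).
QPCR_TIMES = (0.0, 30.0, 60.0, 120.0, 180.0, 240.0, 300.0, 360.0, 420.0, 480.0)

N_PATTERNS = 7

#: Archetype knots in normalized time u = t / t_max.  Piecewise-linear,
#: unit amplitude, all 0 at u = 0 (the stimulus starts at t = 0):
#:   1  peak near mid-course (~200 min on the default grid)
#:   2  early down-regulation then plateau
#:   3  early decrease returning to baseline
#:   4  transient rise then decrease below baseline
#:   5  rise near ~100 min then plateau
#:   6  down-regulation at intermediate times (two dips)
#:   7  sustained, monotone down-regulation
_PATTERN_KNOTS: dict[int, tuple[tuple[float, ...], tuple[float, ...]]] = {
    1: ((0.0, 0.20, 0.455, 0.70, 1.0), (0.0, 0.45, 1.0, 0.35, 0.10)),
    2: ((0.0, 0.091, 0.227, 1.0), (0.0, -0.80, -1.0, -1.0)),
    3: ((0.0, 0.091, 0.227, 0.455, 0.773, 1.0), (0.0, -0.90, -1.0, -0.45, -0.10, 0.0)),
    4: ((0.0, 0.091, 0.227, 0.455, 0.773, 1.0), (0.0, 0.80, 1.0, 0.30, -0.40, -0.70)),
    5: ((0.0, 0.091, 0.227, 1.0), (0.0, 0.50, 1.0, 1.0)),
    6: ((0.0, 0.091, 0.227, 0.455, 0.773, 1.0), (0.0, -0.40, -1.0, -0.30, -1.0, -0.20)),
    7: ((0.0, 0.091, 0.227, 0.455, 0.773, 1.0), (0.0, -0.15, -0.35, -0.55, -0.80, -1.0)),
}


class InvalidGridError(ValueError):
    """Time grid unusable for pattern generation."""


def default_noise_sd(intensity: np.ndarray | float) -> np.ndarray:
    """Default measurement-error SD (log2): 0.4 at intensity 4 falling
    linearly to 0.1 at intensity 12, clamped outside that range."""
    return np.interp(np.asarray(intensity, dtype=float), [4.0, 12.0], [0.4, 0.1])


def generate_patterns(times: Sequence[float]) -> np.ndarray:
    """Unit-amplitude archetype difference profiles on *times* (7 x T).

    Patterns are piecewise-linear in normalized time through fixed knots;
    every pattern is 0 at time 0 and pattern 7 is monotone non-increasing.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 4:
        raise InvalidGridError("need at least 4 time points")
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise InvalidGridError("times must be strictly increasing and start at 0")
    u = t / t[-1]
    return np.vstack(
        [np.interp(u, *_PATTERN_KNOTS[k]) for k in range(1, N_PATTERNS + 1)]
    )


@dataclasses.dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic time course."""

    n_genes: int = 2000
    frac_de: float = 0.1
    times: Sequence[float] = DEFAULT_TIMES
    baseline_range: tuple[float, float] = (4.0, 12.0)
    noise_sd_fn: Callable[[np.ndarray], np.ndarray] = default_noise_sd
    effect_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        t = np.asarray(self.times, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and start at 0")
        lo, hi = self.baseline_range
        if not lo < hi:
            raise ValueError("baseline_range must be a nonempty interval")
        if np.any(np.asarray(self.noise_sd_fn(t * 0 + lo)) < 0):
            raise ValueError("noise SDs must be nonnegative")


@dataclasses.dataclass
class GroundTruth:
    """Truth labels of a simulated experiment (for validation only)."""

    de_flag: np.ndarray  # bool per gene
    pattern_id: np.ndarray  # 1..7 for DE genes, 0 otherwise
    true_changes: np.ndarray  # genes x times, log2; all-zero for non-DE

    def __post_init__(self) -> None:
        if np.any((self.pattern_id > 0) != self.de_flag):
            raise ValueError("pattern_id must be set exactly for DE genes")
        if np.any(self.true_changes[~self.de_flag] != 0):
            raise ValueError("non-DE genes must have all-zero true changes")

    @property
    def n_de(self) -> int:
        return int(self.de_flag.sum())

    def to_frame(self, gene_ids: Sequence[str], times: Sequence[float]) -> pd.DataFrame:
        data: dict[str, object] = {
            "gene": list(gene_ids),
            "de": self.de_flag.astype(int),
            "pattern": self.pattern_id,
        }
        for j, t in enumerate(np.asarray(times, dtype=float)):
            data[f"true_change_{t:g}"] = self.true_changes[:, j]
        return pd.DataFrame(data)


def simulate_timeseries(
    config: SimulationConfig,
) -> tuple[TimeSeriesExperiment, GroundTruth]:
    """Simulate a paired treated/control log2 time course.

    Control = baseline + noise; treated adds ``effect_amplitude * pattern``
    for the truly responding genes.  Noise is zero-mean Gaussian with
    SD = ``noise_sd_fn(baseline)``, independent per measurement, and both
    conditions receive an independent duplicate draw at time 0.  The same
    seed yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.times, dtype=float)
    n, t = config.n_genes, len(times)

    baselines = rng.uniform(*config.baseline_range, size=n)
    n_de = round(config.frac_de * n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    de_flag = np.zeros(n, dtype=bool)
    de_flag[de_idx] = True
    pattern_id = np.zeros(n, dtype=int)
    pattern_id[de_idx] = rng.integers(1, N_PATTERNS + 1, size=n_de)

    patterns = generate_patterns(times)
    true_changes = np.zeros((n, t))
    true_changes[de_idx] = config.effect_amplitude * patterns[pattern_id[de_idx] - 1]

    sd = np.asarray(config.noise_sd_fn(baselines), dtype=float)[:, None]
    control = baselines[:, None] + rng.normal(0.0, 1.0, size=(n, t)) * sd
    treated = baselines[:, None] + true_changes + rng.normal(0.0, 1.0, size=(n, t)) * sd
    control_rep = baselines + rng.normal(0.0, 1.0, size=n) * sd[:, 0]
    treated_rep = baselines + rng.normal(0.0, 1.0, size=n) * sd[:, 0]

    width = max(5, len(str(n)))
    exp = TimeSeriesExperiment(
        gene_ids=[f"G{i:0{width}d}" for i in range(n)],
        times=times,
        treated=treated,
        control=control,
        treated_t0_rep=treated_rep,
        control_t0_rep=control_rep,
    )
    truth = GroundTruth(de_flag=de_flag, pattern_id=pattern_id, true_changes=true_changes)
    return exp, truth


# ---------------------------------------------------------------------------
# ontology simulation


class SimulatedOntology(NamedTuple):
    dag: OntologyDAG
    annotations: AnnotationMap
    planted_terms: list[str]
    selected_genes: set[str]


def simulate_ontology(
    n_terms: int = 50,
    max_depth: int = 4,
    n_genes: int = 200,
    planted_terms: int = 2,
    seed: int = 0,
    selected_frac: float = 0.2,
    genes_per_planted: int = 8,
) -> SimulatedOntology:
    """Fabricate a single-root is_a DAG with ancestor-closed annotations.

    Every non-root term points to at least one parent of strictly smaller
    depth (acyclic by construction); a fraction of genes is designated
    "selected", and each planted term is annotated exclusively to selected
    genes so that its selected percentage is 100%.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if n_terms < max_depth + 1:
        raise ValueError("need at least max_depth + 1 terms")
    if planted_terms > n_terms - 1:
        raise ValueError("planted_terms must be <= n_terms - 1")
    rng = np.random.default_rng(seed)

    term_ids = [f"T{i:03d}" for i in range(n_terms)]
    root = term_ids[0]
    depth = {root: 0}
    # guarantee every depth 1..max_depth is populated, then fill randomly
    for i, term in enumerate(term_ids[1:], start=1):
        depth[term] = i if i <= max_depth else int(rng.integers(1, max_depth + 1))
    by_depth: dict[int, list[str]] = {}
    for term, d in depth.items():
        by_depth.setdefault(d, []).append(term)
    edges: list[tuple[str, str]] = []
    for term in term_ids[1:]:
        parents = by_depth[depth[term] - 1]
        edges.append((term, parents[int(rng.integers(len(parents)))]))
        # occasional second parent anywhere strictly above
        shallower = [t for t in term_ids if depth[t] < depth[term] and t != edges[-1][1]]
        if shallower and rng.random() < 0.2:
            edges.append((term, shallower[int(rng.integers(len(shallower)))]))
    dag = OntologyDAG.from_edges(edges, extra_terms=term_ids)

    genes = [f"g{i:04d}" for i in range(n_genes)]
    n_selected = max(1, round(selected_frac * n_genes))
    selected = set(rng.choice(genes, size=n_selected, replace=False).tolist())

    deepest = by_depth[max_depth]
    if planted_terms > len(deepest):
        pool = deepest + [t for t in term_ids[1:] if t not in deepest]
        planted = pool[:planted_terms]
    else:
        planted = rng.choice(deepest, size=planted_terms, replace=False).tolist()

    pairs: list[tuple[str, str]] = []
    background = [t for t in term_ids[1:] if t not in planted]
    for g in genes:
        k = int(rng.integers(1, 4))
        for t in rng.choice(background, size=min(k, len(background)), replace=False):
            pairs.append((g, str(t)))
    selected_list = sorted(selected)
    for t in planted:
        chosen = rng.choice(selected_list, size=min(genes_per_planted, len(selected_list)),
                            replace=False)
        for g in chosen:
            pairs.append((str(g), t))
    ann = AnnotationMap.from_pairs(pairs, dag=dag, propagate=True)
    assert ann.is_ancestor_closed(dag)
    return SimulatedOntology(dag=dag, annotations=ann,
                             planted_terms=sorted(planted), selected_genes=selected)


# ---------------------------------------------------------------------------
# qPCR simulation


def simulate_qpcr(
    selected_profiles: np.ndarray,
    times: Sequence[float] = QPCR_TIMES,
    ct_noise_sd: float = 0.25,
    seed: int = 0,
    base_ct: float = 22.0,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cycle-threshold matrix for given log2 abundance-change profiles.

    CT decreases by exactly one cycle per doubling of abundance:
    ``CT = base_ct - profile + noise`` with noise ~ N(0, ct_noise_sd).
    Returns genes x times (columns labelled by minutes).
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    profiles = np.atleast_2d(np.asarray(selected_profiles, dtype=float))
    times = np.asarray(times, dtype=float)
    if profiles.shape[1] != len(times):
        raise ValueError("profile length must match the time grid")
    rng = np.random.default_rng(seed)
    ct = base_ct - profiles + rng.normal(0.0, 1.0, size=profiles.shape) * ct_noise_sd
    if gene_ids is None:
        gene_ids = [f"q{i:03d}" for i in range(profiles.shape[0])]
    return pd.DataFrame(ct, index=pd.Index(gene_ids, name="gene"),
                        columns=[f"{t:g}" for t in times])
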