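"""Relative quantification of qPCR data and cross-platform concordance.

Cycle-threshold (CT) values drop by one cycle per doubling of template, so
log2 abundance is ``-CT`` up to a constant.  Normalization uses a
median calibrator: per gene, ``ddCT = CT - median(CT over samples)`` and
the relative quantity is ``RQ = 2**-ddCT``, which makes RQ ratios between
samples invariant to any constant shift of the row.

``log2(RQ)`` profiles are fed to the same area-statistic selection used
for the array data, with the null built from an assumed CT replicate SD
(one cycle = one log2 unit).  Agreement between the platforms' selection
calls is summarised by a 2x2 contingency table.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .selection import SelectionResult, _null_areas_for_sd, _abs_areas, bh_adjust, empirical_p

__all__ = [
    "QpcrPlate",
    "ContingencyTable2x2",
    "compute_rq",
    "select_qpcr_genes",
    "concordance",
    "average_profile",
]


@dataclasses.dataclass
class QpcrPlate:
    """CT matrix with per-gene median calibrator and relative quantities."""

    ct: pd.DataFrame  # genes x samples, cycles
    calibrator: pd.Series  # per-gene median CT
    rq: pd.DataFrame  # 2**-ddCT, dimensionless

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ct.index)

    def log2_rq(self) -> pd.DataFrame:
        """log2 relative quantity = -ddCT (genes x samples)."""
        return -(self.ct.sub(self.calibrator, axis=0))


def compute_rq(ct: pd.DataFrame) -> QpcrPlate:
    """Median-calibrator relative quantification.

    Per gene, calibrator = median CT over samples, ``ddCT = CT - calibrator``
    and ``RQ = 2**-ddCT`` (so a CT one cycle below the gene median gives
    RQ = 2).
    """
    if ct.shape[1] < 2:
        raise ValueError("need at least 2 samples per gene")
    values = ct.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite CT value")
    calibrator = ct.median(axis=1)
    ddct = ct.sub(calibrator, axis=0)
    return QpcrPlate(ct=ct, calibrator=calibrator, rq=2.0 ** (-ddct))


def select_qpcr_genes(
    plate: QpcrPlate,
    times: Sequence[float],
    alpha: float = 0.05,
    ct_replicate_sd: float = 0.25,
    n_mc: int = 10000,
    seed: int = 0,
) -> SelectionResult:
    """Area-statistic selection on log2(RQ) profiles.

    The design has no separate control channel: RQ is already normalized
    to the per-gene median, so log2(RQ) plays the role of the
    treated-minus-control profile.  The null samples a single measurement
    error ~ N(0, ct_replicate_sd) per time point (CT cycles equal log2
    units).  Genes with FDR-adjusted value <= *alpha* are selected.
    """
    times = np.asarray(times, dtype=float)
    profiles = plate.log2_rq().to_numpy(dtype=float)
    if profiles.shape[1] != len(times):
        raise ValueError("time grid does not match the number of samples")
    areas = _abs_areas(profiles, times)
    rng = np.random.default_rng(seed)
    null = _null_areas_for_sd(float(ct_replicate_sd), times, n_mc, rng, n_channels=1)
    if null[-1] == 0.0:  # zero-noise null: positive area is significant
        p = np.where(areas > 0, 1.0 / (1.0 + n_mc), 1.0)
    else:
        p = empirical_p(areas, null)
    q = bh_adjust(p)
    return SelectionResult(
        gene_ids=plate.gene_ids,
        times=times,
        area=areas,
        p_value=p,
        q_value=q,
        selected=q <= alpha,
        fdr_level=alpha,
    )


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Selected/not-selected agreement between two platforms."""

    both_selected: int
    a_only: int
    b_only: int
    neither: int

    @property
    def total(self) -> int:
        return self.both_selected + self.a_only + self.b_only + self.neither

    @property
    def n_selected_a(self) -> int:
        return self.both_selected + self.a_only

    @property
    def n_selected_b(self) -> int:
        return self.both_selected + self.b_only

    @property
    def agreement(self) -> float:
        """Fraction of genes on which the two platforms agree."""
        return (self.both_selected + self.neither) / self.total

    @property
    def agreement_percent(self) -> int:
        """Agreement as a percentage, rounded to the nearest integer."""
        return round(100.0 * self.agreement)

    @property
    def a_in_b_percent(self) -> int:
        """Percent of platform-A selections also selected by B (rounded)."""
        return round(100.0 * self.both_selected / self.n_selected_a)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "both_selected": self.both_selected,
                    "a_only": self.a_only,
                    "b_only": self.b_only,
                    "neither": self.neither,
                    "agreement": self.agreement,
                }
            ]
        )


def concordance(
    calls_a: Mapping[str, bool], calls_b: Mapping[str, bool]
) -> ContingencyTable2x2:
    """2x2 contingency table of selection calls over a shared gene universe.

    Raises with the offending genes when the two universes differ.
    """
    genes_a, genes_b = set(calls_a), set(calls_b)
    if genes_a != genes_b:
        raise ValueError(
            "mismatched gene universes: "
            f"only in A: {sorted(genes_a - genes_b)}; "
            f"only in B: {sorted(genes_b - genes_a)}"
        )
    both = a_only = b_only = neither = 0
    for g in genes_a:
        a, b = bool(calls_a[g]), bool(calls_b[g])
        if a and b:
            both += 1
        elif a:
            a_only += 1
        elif b:
            b_only += 1
        else:
            neither += 1
    return ContingencyTable2x2(both, a_only, b_only, neither)


def average_profile(plate: QpcrPlate, selected: set[str]) -> pd.Series:
    """Mean log2(RQ) time series across the selected genes."""
    selected = set(selected)
    missing = selected - set(plate.gene_ids)
    if missing:
        raise ValueError(f"selected genes not on the plate: {sorted(missing)}")
    if not selected:
        raise ValueError("empty selection")
    l2 = plate.log2_rq()
    return l2.loc[sorted(selected)].mean(axis=0)
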