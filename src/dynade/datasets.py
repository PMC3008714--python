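"""Small packaged datasets used in examples and tests."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import TimeSeriesExperiment, read_expression_tsv, read_gmt

__all__ = [
    "load_etc_validation_calls",
    "load_etc_gene_set",
    "load_example_timeseries",
]


def _data_path(name: str):
    return resources.files("dynade").joinpath("data", name)


def load_etc_validation_calls() -> pd.DataFrame:
    """Published cross-platform selection calls for 32 electron-transport-chain genes.

    Columns: ``gene``, ``selected_qpcr`` and ``selected_affy`` (0/1 calls
    from the qPCR and microarray platforms), the functional-group tag(s)
    and the temporal-cluster id (empty for unselected genes).
    """
    with resources.as_file(_data_path("etc_validation_calls.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"gene": str, "go_group": str, "cluster": str})


def load_etc_gene_set() -> dict[str, set[str]]:
    """Electron-transport-chain gene set (GMT, 32 members)."""
    with resources.as_file(_data_path("electron_transport_chain.gmt")) as p:
        return read_gmt(p)


def load_example_timeseries() -> TimeSeriesExperiment:
    """Tiny synthetic expression matrix on the 0-440 min grid.

    Twelve genes simulated with the package's own generator (synthetic
    data, not measurements); handy for format examples and smoke tests.
    """
    with resources.as_file(_data_path("example_timeseries_synthetic.tsv")) as p:
        return read_expression_tsv(p)
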