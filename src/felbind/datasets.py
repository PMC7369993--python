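"""Bundled MDM2/MDMX benchmark tables.

Two published benchmark sets of p53-pathway inhibitors: five complexes
against MDMX (a comparatively rigid receptor) and fourteen against MDM2
(highly flexible), each with the experimentally derived binding free
energy, the raw alchemical estimate and — for MDM2 — the landscape
correction term.
"""

from __future__ import annotations

from importlib import resources

from .io import ComplexRecord, read_dataset

__all__ = ["load_mdmx", "load_mdm2"]


def _load(name: str) -> list[ComplexRecord]:
    ref = resources.files("felbind.data").joinpath(name)
    with resources.as_file(ref) as path:
        return read_dataset(path)


def load_mdmx() -> list[ComplexRecord]:
    """Five MDMX complexes: IC50, dG_calculated and dG_experimental."""
    return _load("mdmx_benchmark.csv")


def load_mdm2() -> list[ComplexRecord]:
    """Fourteen MDM2 complexes, including the landscape correction column."""
    return _load("mdm2_benchmark.csv")
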