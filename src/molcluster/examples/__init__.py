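"""Packaged example models.

``nephrin_nck_nwasp`` is the canonical three-species multivalent system:
Nephrin with three phosphotyrosine sites, Nck with one SH2 and three SH3
domains, NWASP with six proline-rich motifs.  Copy numbers are chosen to
balance binding-site stoichiometry (180 Nephrin x 3 pY = 540 = 540 Nck SH2;
540 Nck x 3 SH3 = 1620 = 270 NWASP x 6 PRM), 990 molecules in total.  The
strong-affinity variant (kon = koff, so K = 1 per site pair) sits deep in
the clustered regime; ``nephrin_nck_nwasp_weak`` lowers kon by five orders
of magnitude into the dispersed, monomer-dominated regime.  ``dimer`` is a
minimal A + B <-> AB model used in tests and docs.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from ..model_io import ModelSpec, load_bngl

__all__ = ["list_examples", "example_path", "load_example"]

_NAMES = ("dimer", "nephrin_nck_nwasp", "nephrin_nck_nwasp_weak")


def list_examples() -> tuple[str, ...]:
    return _NAMES


def example_path(name: str) -> Path:
    """Filesystem path of a packaged example model file."""
    if name not in _NAMES:
        raise KeyError(f"unknown example {name!r}; available: {', '.join(_NAMES)}")
    return Path(str(resources.files(__package__) / f"{name}.bngl"))


def load_example(name: str) -> ModelSpec:
    """Load a packaged example model by name."""
    return load_bngl(example_path(name))
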