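"""Model and output-file I/O for rule-based multivalent binding models.

This module defines the in-memory model description (:class:`ModelSpec`) and
reads/writes a restricted BNGL dialect sufficient for supply-limited
clustering studies: multi-site molecule types (plain binding sites, no
internal states or compartments), seed species with integer copy numbers,
reversible bimolecular site--site binding rules with stochastic on/off rate
constants, a small vocabulary of named observables, and a single
``simulate({...})`` directive carrying the three simulation parameters
(duration, number of output points, number of stochastic trials) plus a
master random seed.

It also reads NFsim-style output files: whitespace-delimited observable
time-course tables (the ``.gdat`` dialect, comment-prefixed header naming
``time`` then the observables) and final-species files (one BNGL complex
string plus an integer count per line).

Rate constants are stochastic (copy-number) rate constants; no molar/volume
conversion is performed.  ``koff = 0`` encodes irreversible binding.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import IO, Union

import numpy as np

__all__ = [
    "BnglError",
    "MoleculeType",
    "BindingRule",
    "SeedSpecies",
    "ObservableDef",
    "SimParams",
    "ModelSpec",
    "TimecourseTable",
    "OBSERVABLE_KINDS",
    "read_bngl",
    "write_bngl",
    "load_bngl",
    "save_bngl",
    "read_gdat",
    "write_gdat",
    "read_species_file",
    "write_species_file",
]

_IDENT = r"[A-Za-z_]\w*"

OBSERVABLE_KINDS = ("free_molecule", "free_site", "bond_count", "total_clusters")


class BnglError(ValueError):
    """Syntax or cross-reference error in a model or output file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MoleculeType:
    """A molecule type: a name and an ordered tuple of binding-site names.

    The number of sites is the molecule's valence, the maximum number of
    bonds a single copy can engage in.
    """

    name: str
    sites: tuple[str, ...]

    def __post_init__(self):
        if not self.name:
            raise BnglError("molecule type name must be nonempty")
        if len(self.sites) < 1:
            raise BnglError(f"molecule type {self.name!r} must declare at least one site")
        if len(set(self.sites)) != len(self.sites):
            raise BnglError(f"molecule type {self.name!r} has duplicate site names")

    @property
    def valence(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class BindingRule:
    """A reversible bimolecular site--site binding rule.

    ``site_a`` and ``site_b`` are ``(molecule name, site name)`` endpoint
    pairs.  All bonds formed by a rule share the same stochastic association
    rate constant ``kon`` (per eligible site pair per time unit) and
    dissociation rate constant ``koff`` (per bond per time unit).
    """

    name: str
    site_a: tuple[str, str]
    site_b: tuple[str, str]
    kon: float
    koff: float

    def __post_init__(self):
        if self.kon < 0 or self.koff < 0:
            raise BnglError(f"rule {self.name!r}: rate constants must be nonnegative")

    @property
    def is_symmetric(self) -> bool:
        """True when both endpoints are the same (type, site), e.g. A(a)+A(a)."""
        return self.site_a == self.site_b


@dataclass(frozen=True)
class SeedSpecies:
    """Initial free (fully unbound) copies of one molecule type."""

    molecule: str
    count: int

    def __post_init__(self):
        if self.count < 0:
            raise BnglError(f"seed species {self.molecule!r}: count must be >= 0")


@dataclass(frozen=True)
class ObservableDef:
    """A named global observable recorded along the simulated time course.

    Kinds:

    ``free_molecule``
        number of fully monomeric copies of a molecule type
        (target: molecule name);
    ``free_site``
        number of unbound copies of one named site
        (target: ``(molecule, site)``);
    ``bond_count``
        number of bonds currently formed by one rule (target: rule name);
    ``total_clusters``
        number of connected clusters, monomers included (no target).
    """

    name: str
    kind: str
    target: Union[str, tuple[str, str], None] = None

    def __post_init__(self):
        if self.kind not in OBSERVABLE_KINDS:
            raise BnglError(f"observable {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "total_clusters" and self.target is not None:
            raise BnglError(f"observable {self.name!r}: total_clusters takes no target")


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters: duration, output grid, trials, master seed."""

    t_end: float
    n_steps: int
    n_runs: int
    seed: int = 1

    def __post_init__(self):
        if not self.t_end > 0:
            raise BnglError("t_end must be > 0")
        if self.n_steps < 1:
            raise BnglError("n_steps must be >= 1")
        if self.n_runs < 1:
            raise BnglError("n_runs must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    """A complete, cross-checked model."""

    molecule_types: tuple[MoleculeType, ...]
    seeds: tuple[SeedSpecies, ...]
    rules: tuple[BindingRule, ...]
    observables: tuple[ObservableDef, ...] = ()
    sim_params: SimParams = SimParams(t_end=1.0, n_steps=1, n_runs=1)

    def __post_init__(self):
        if not self.molecule_types:
            raise BnglError("model must declare at least one molecule type")
        names = [mt.name for mt in self.molecule_types]
        if len(set(names)) != len(names):
            raise BnglError("duplicate molecule type names")
        if not self.seeds:
            raise BnglError("model must declare at least one seed species")
        by_name = {mt.name: mt for mt in self.molecule_types}
        for s in self.seeds:
            if s.molecule not in by_name:
                raise BnglError(f"seed species references undeclared molecule {s.molecule!r}")
        rule_names = [r.name for r in self.rules]
        if len(set(rule_names)) != len(rule_names):
            raise BnglError("duplicate rule names")
        for r in self.rules:
            for mol, site in (r.site_a, r.site_b):
                if mol not in by_name:
                    raise BnglError(f"rule {r.name!r} references undeclared molecule {mol!r}")
                if site not in by_name[mol].sites:
                    raise BnglError(
                        f"rule {r.name!r} references undeclared site {site!r} on {mol!r}"
                    )
        obs_names = [o.name for o in self.observables]
        if len(set(obs_names)) != len(obs_names):
            raise BnglError("duplicate observable names")
        for o in self.observables:
            if o.kind == "free_molecule":
                if o.target not in by_name:
                    raise BnglError(
                        f"observable {o.name!r} references undeclared molecule {o.target!r}"
                    )
            elif o.kind == "free_site":
                mol, site = o.target  # type: ignore[misc]
                if mol not in by_name or site not in by_name[mol].sites:
                    raise BnglError(
                        f"observable {o.name!r} references undeclared site {mol}.{site}"
                    )
            elif o.kind == "bond_count":
                if o.target not in set(rule_names):
                    raise BnglError(
                        f"observable {o.name!r} references undeclared rule {o.target!r}"
                    )

    # -- convenience -------------------------------------------------------

    def molecule(self, name: str) -> MoleculeType:
        for mt in self.molecule_types:
            if mt.name == name:
                return mt
        raise KeyError(name)

    def valence(self, name: str) -> int:
        return self.molecule(name).valence

    def total_molecules(self) -> int:
        return sum(s.count for s in self.seeds)

    def seed_count(self, name: str) -> int:
        return sum(s.count for s in self.seeds if s.molecule == name)


# ---------------------------------------------------------------------------
# time-course table
# ---------------------------------------------------------------------------


@dataclass
class TimecourseTable:
    """Observable time courses: strictly increasing times plus named columns."""

    times: np.ndarray
    columns: dict[str, np.ndarray]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.columns = {k: np.asarray(v, dtype=float) for k, v in self.columns.items()}
        if self.times.ndim != 1:
            raise BnglError("times must be one-dimensional")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise BnglError("times must be strictly increasing")
        for name, col in self.columns.items():
            if col.shape != self.times.shape:
                raise BnglError(f"column {name!r} length differs from times")
            if len(col) and (not np.all(np.isfinite(col)) or np.any(col < 0)):
                raise BnglError(f"column {name!r} has non-finite or negative values")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.columns)

    @property
    def n_points(self) -> int:
        return len(self.times)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, **self.columns})

    def __eq__(self, other):
        if not isinstance(other, TimecourseTable):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and self.names == other.names
            and all(np.array_equal(self.columns[k], other.columns[k]) for k in self.columns)
        )


# ---------------------------------------------------------------------------
# BNGL reading
# ---------------------------------------------------------------------------

_MOL_DECL_RE = re.compile(rf"^({_IDENT})\(([^()]*)\)$")
_RULE_RE = re.compile(
    rf"^(?:({_IDENT})\s*:\s*)?"
    rf"({_IDENT})\(({_IDENT})\)\s*\+\s*({_IDENT})\(({_IDENT})\)\s*"
    rf"<->\s*"
    rf"({_IDENT})\(({_IDENT})!1\)\.({_IDENT})\(({_IDENT})!1\)\s+"
    rf"(\S+)\s*,\s*(\S+)$"
)
_SIM_RE = re.compile(r"^simulate\s*\(\s*\{(.*)\}\s*\)\s*;?$")

_BLOCKS = {"parameters", "molecule types", "seed species", "reaction rules", "observables"}


def _as_text(source: Union[str, IO[str]]) -> str:
    if hasattr(source, "read"):
        return source.read()
    return str(source)


def _norm_block(name: str, line: int) -> str:
    norm = " ".join(name.replace("_", " ").split()).lower()
    if norm not in _BLOCKS:
        raise BnglError(f"unknown block {name.strip()!r}", line)
    return norm


def _resolve_num(token: str, params: dict[str, float], line: int) -> float:
    if token in params:
        return params[token]
    try:
        return float(token)
    except ValueError:
        raise BnglError(f"cannot resolve numeric value {token!r}", line) from None


def _resolve_int(token: str, params: dict[str, float], line: int) -> int:
    val = _resolve_num(token, params, line)
    if not float(val).is_integer():
        raise BnglError(f"expected an integer, got {token!r}", line)
    return int(val)


def _parse_simulate(body: str, params: dict[str, float], line: int) -> SimParams:
    kv: dict[str, str] = {}
    for item in body.split(","):
        item = item.strip()
        if not item:
            continue
        if "=>" not in item:
            raise BnglError(f"malformed simulate argument {item!r}", line)
        key, val = (p.strip() for p in item.split("=>", 1))
        kv[key] = val.strip("\"'")
    kv.pop("method", None)  # accepted and ignored; only network-free is offered
    unknown = set(kv) - {"t_end", "n_steps", "n_runs", "seed"}
    if unknown:
        raise BnglError(f"unknown simulate argument(s) {sorted(unknown)}", line)
    for req in ("t_end", "n_steps", "n_runs"):
        if req not in kv:
            raise BnglError(f"simulate(...) is missing {req!r}", line)
    try:
        return SimParams(
            t_end=_resolve_num(kv["t_end"], params, line),
            n_steps=_resolve_int(kv["n_steps"], params, line),
            n_runs=_resolve_int(kv["n_runs"], params, line),
            seed=_resolve_int(kv.get("seed", "1"), params, line),
        )
    except BnglError as e:
        raise BnglError(str(e).split(": ", 1)[-1], line) from None


def read_bngl(source: Union[str, IO[str]]) -> ModelSpec:
    """Parse the restricted BNGL dialect into a cross-checked :class:`ModelSpec`.

    ``source`` is the model text (or an open text handle).  Raises
    :class:`BnglError` (with a line number where possible) on syntax errors,
    references to undeclared molecules/sites/rules, or negative rates and
    counts.
    """
    text = _as_text(source)
    params: dict[str, float] = {}
    mol_types: list[MoleculeType] = []
    by_name: dict[str, MoleculeType] = {}
    seeds: list[SeedSpecies] = []
    rules: list[BindingRule] = []
    rule_names: set[str] = set()
    observables: list[ObservableDef] = []
    sim: SimParams | None = None
    block: str | None = None
    n_auto_rules = 0

    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        low = line.lower()
        if low in ("begin model", "end model"):
            continue
        if low.startswith("begin "):
            if block is not None:
                raise BnglError(f"'begin' encountered inside block {block!r}", ln)
            block = _norm_block(line[6:], ln)
            continue
        if low.startswith("end "):
            name = _norm_block(line[4:], ln)
            if block != name:
                raise BnglError(f"'end {name}' does not match open block {block!r}", ln)
            block = None
            continue

        if block is None:
            m = _SIM_RE.match(line)
            if m:
                sim = _parse_simulate(m.group(1), params, ln)
                continue
            raise BnglError(f"unexpected statement outside any block: {line!r}", ln)

        if block == "parameters":
            parts = line.split()
            if len(parts) != 2:
                raise BnglError(f"malformed parameter line {line!r}", ln)
            try:
                params[parts[0]] = float(parts[1])
            except ValueError:
                raise BnglError(f"parameter {parts[0]!r}: bad value {parts[1]!r}", ln) from None

        elif block == "molecule types":
            m = _MOL_DECL_RE.match(line)
            if not m:
                raise BnglError(f"malformed molecule type declaration {line!r}", ln)
            name, body = m.group(1), m.group(2)
            sites = tuple(s.strip() for s in body.split(",")) if body.strip() else ()
            if any(not re.fullmatch(_IDENT, s) for s in sites):
                raise BnglError(f"malformed site list in {line!r}", ln)
            if name in by_name:
                raise BnglError(f"duplicate molecule type {name!r}", ln)
            try:
                mt = MoleculeType(name, sites)
            except BnglError as e:
                raise BnglError(str(e), ln) from None
            mol_types.append(mt)
            by_name[name] = mt

        elif block == "seed species":
            parts = line.rsplit(None, 1)
            if len(parts) != 2:
                raise BnglError(f"malformed seed species line {line!r}", ln)
            pattern, count_tok = parts
            count = _resolve_int(count_tok, params, ln)
            if count < 0:
                raise BnglError(f"seed count must be >= 0, got {count}", ln)
            if "(" in pattern:
                m = _MOL_DECL_RE.match(pattern)
                if not m:
                    raise BnglError(f"malformed seed species pattern {pattern!r}", ln)
                name, body = m.group(1), m.group(2)
                if name not in by_name:
                    raise BnglError(f"undeclared molecule {name!r}", ln)
                listed = tuple(s.strip() for s in body.split(",")) if body.strip() else ()
                if any("!" in s for s in listed):
                    raise BnglError("seed species must be fully unbound", ln)
                if set(listed) != set(by_name[name].sites):
                    raise BnglError(
                        f"seed species sites {listed} do not match declaration of {name!r}", ln
                    )
            else:
                name = pattern
                if name not in by_name:
                    raise BnglError(f"undeclared molecule {name!r}", ln)
            seeds.append(SeedSpecies(name, count))

        elif block == "reaction rules":
            m = _RULE_RE.match(line)
            if not m:
                raise BnglError(f"malformed reaction rule {line!r}", ln)
            (rname, a, sa, b, sb, a2, sa2, b2, sb2, kon_tok, koff_tok) = m.groups()
            if (a2, sa2, b2, sb2) != (a, sa, b, sb):
                raise BnglError("product side does not match reactant side", ln)
            if rname is None:
                n_auto_rules += 1
                while f"R{n_auto_rules}" in rule_names:
                    n_auto_rules += 1
                rname = f"R{n_auto_rules}"
            if rname in rule_names:
                raise BnglError(f"duplicate rule name {rname!r}", ln)
            for mol, site in ((a, sa), (b, sb)):
                if mol not in by_name:
                    raise BnglError(f"undeclared molecule {mol!r}", ln)
                if site not in by_name[mol].sites:
                    raise BnglError(f"undeclared site {site!r} on {mol!r}", ln)
            kon = _resolve_num(kon_tok, params, ln)
            koff = _resolve_num(koff_tok, params, ln)
            try:
                rule = BindingRule(rname, (a, sa), (b, sb), kon, koff)
            except BnglError as e:
                raise BnglError(str(e), ln) from None
            rules.append(rule)
            rule_names.add(rname)

        elif block == "observables":
            toks = line.split()
            kind = toks[0]
            if kind not in OBSERVABLE_KINDS:
                raise BnglError(f"unknown observable kind {kind!r}", ln)
            if kind == "total_clusters":
                if len(toks) != 2:
                    raise BnglError("total_clusters observable takes only a name", ln)
                observables.append(ObservableDef(toks[1], kind))
            else:
                if len(toks) != 3:
                    raise BnglError(f"malformed observable line {line!r}", ln)
                name, target = toks[1], toks[2]
                if kind == "free_site":
                    if "." not in target:
                        raise BnglError("free_site target must be Molecule.site", ln)
                    mol, site = target.split(".", 1)
                    observables.append(ObservableDef(name, kind, (mol, site)))
                else:
                    observables.append(ObservableDef(name, kind, target))

    if block is not None:
        raise BnglError(f"unterminated block {block!r}")
    if sim is None:
        raise BnglError("model is missing the simulate({...}) directive")
    return ModelSpec(
        molecule_types=tuple(mol_types),
        seeds=tuple(seeds),
        rules=tuple(rules),
        observables=tuple(observables),
        sim_params=sim,
    )


# ---------------------------------------------------------------------------
# BNGL writing
# ---------------------------------------------------------------------------


def _fmt_num(x: float) -> str:
    return repr(float(x))


def write_bngl(model: ModelSpec) -> str:
    """Emit the restricted dialect; ``read_bngl(write_bngl(m)) == m``."""
    out: list[str] = ["begin model", "begin molecule types"]
    for mt in model.molecule_types:
        out.append(f"  {mt.name}({','.join(mt.sites)})")
    out.append("end molecule types")
    out.append("begin seed species")
    for s in model.seeds:
        mt = model.molecule(s.molecule)
        out.append(f"  {mt.name}({','.join(mt.sites)}) {s.count}")
    out.append("end seed species")
    out.append("begin observables")
    for o in model.observables:
        if o.kind == "total_clusters":
            out.append(f"  total_clusters {o.name}")
        elif o.kind == "free_site":
            mol, site = o.target  # type: ignore[misc]
            out.append(f"  free_site {o.name} {mol}.{site}")
        else:
            out.append(f"  {o.kind} {o.name} {o.target}")
    out.append("end observables")
    out.append("begin reaction rules")
    for r in model.rules:
        (a, sa), (b, sb) = r.site_a, r.site_b
        out.append(
            f"  {r.name}: {a}({sa}) + {b}({sb}) <-> "
            f"{a}({sa}!1).{b}({sb}!1) {_fmt_num(r.kon)}, {_fmt_num(r.koff)}"
        )
    out.append("end reaction rules")
    out.append("end model")
    p = model.sim_params
    out.append(
        f"simulate({{t_end=>{_fmt_num(p.t_end)}, n_steps=>{p.n_steps}, "
        f"n_runs=>{p.n_runs}, seed=>{p.seed}}})"
    )
    return "\n".join(out) + "\n"


def load_bngl(path: Union[str, os.PathLike]) -> ModelSpec:
    with open(path, "r", encoding="utf-8") as fh:
        return read_bngl(fh)


def save_bngl(model: ModelSpec, path: Union[str, os.PathLike]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_bngl(model))


# ---------------------------------------------------------------------------
# gdat time-course tables
# ---------------------------------------------------------------------------


def read_gdat(source: Union[str, IO[str]]) -> TimecourseTable:
    """Parse a gdat-dialect observable table.

    The first non-blank line must be a ``#``-prefixed header naming the time
    column and then one name per observable; data rows are whitespace
    separated, one value per column, scientific notation allowed.
    """
    text = _as_text(source)
    names: list[str] | None = None
    rows: list[list[float]] = []
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if names is None:
            if not line.startswith("#"):
                raise BnglError("missing '#'-prefixed header line", ln)
            names = line.lstrip("#").split()
            if len(names) < 1:
                raise BnglError("header names no columns", ln)
            continue
        if line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) != len(names):
            raise BnglError(
                f"ragged row: {len(toks)} fields under {len(names)}-column header", ln
            )
        try:
            rows.append([float(t) for t in toks])
        except ValueError:
            raise BnglError(f"non-numeric cell in row {line!r}", ln) from None
    if names is None:
        raise BnglError("empty gdat input: no header found")
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(names))
    return TimecourseTable(
        times=data[:, 0],
        columns={name: data[:, i + 1] for i, name in enumerate(names[1:])},
    )


def write_gdat(table: TimecourseTable) -> str:
    names = ["time", *table.names]
    out = ["# " + " ".join(names)]
    cols = [table.times, *(table.columns[n] for n in table.names)]
    for i in range(table.n_points):
        out.append(" ".join(f"{col[i]:.10g}" for col in cols))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# species files
# ---------------------------------------------------------------------------


def read_species_file(source: Union[str, IO[str]]) -> list[tuple[str, int]]:
    """Parse a final-species file into an ordered ``(complex string, count)`` list.

    Each nonempty, non-comment line is a BNGL complex string followed by a
    positive integer count.  No line is silently dropped.
    """
    text = _as_text(source)
    entries: list[tuple[str, int]] = []
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.rsplit(None, 1)
        if len(parts) != 2:
            raise BnglError(f"malformed species line {line!r}", ln)
        spec, count_tok = parts
        try:
            count = int(count_tok)
        except ValueError:
            raise BnglError(f"bad count {count_tok!r}", ln) from None
        if count < 1:
            raise BnglError(f"species count must be >= 1, got {count}", ln)
        entries.append((spec, count))
    return entries


def write_species_file(entries: list[tuple[str, int]]) -> str:
    for spec, count in entries:
        if count < 1:
            raise BnglError(f"species count must be >= 1, got {count}")
    return "".join(f"{spec} {count}\n" for spec, count in entries)
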