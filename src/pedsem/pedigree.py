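"""Pedigree representation, kinship computation, and relationship matrices.

A pedigree is a single family: an ordered list of individuals with parent
links, optional proband flags, and per-individual data columns (phenotypes,
covariates, SNP genotype counts).  Members are kept in topological order
(every parent precedes all of its offspring), which is what the recursive
kinship algorithm requires and what makes gene dropping a single forward
pass.  Loops through marriage (e.g. cousin matings) are permitted; the
kinship recursion handles them without special-casing.

Relationship matrices per variance component:

* polygenic   -- numerator relationship matrix ``2 * Phi`` (diagonal 1 for
  non-inbred individuals), so a polygenic variance parameter is the additive
  genetic variance of one individual;
* environment -- identity;
* household   -- block of ones over household groups (whole family when no
  household column is present);
* linkage     -- matrix of marker-specific IBD sharing proportions with
  diagonal fixed at 1, read from an IBD file or produced by the simulator.
"""

from __future__ import annotations

import heapq
import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PedigreeFormatError, PedigreeStructureError

__all__ = [
    "Individual",
    "Pedigree",
    "Diagnostic",
    "IbdStore",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "pedigrees_from_frame",
    "validate_pedigree",
    "kinship_matrix",
    "relationship_matrix",
    "read_ibd_file",
]

MISSING_PARENT_CODES = {"", "0", "0.0", "na", "nan", "none"}

_SEX_MALE = {"1", "m", "male"}
_SEX_FEMALE = {"2", "f", "female"}
_TRUTHY = {"1", "1.0", "true", "t", "yes", "y"}

_GENOTYPE_NAME_RE = re.compile(r"^(rs\d+|snp[\w.]*)$", re.IGNORECASE)


@dataclass
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` for founders (both present or
    both absent).  Phenotypes, covariates, and genotypes are name->value maps;
    missing values are ``nan``.  Genotypes are counts of the coded allele in
    {0, 1, 2}.
    """

    person_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"  # {male, female, unknown}
    proband: bool = False
    household: str | None = None
    phenotypes: dict[str, float] = field(default_factory=dict)
    covariates: dict[str, float] = field(default_factory=dict)
    genotypes: dict[str, float] = field(default_factory=dict)

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    def get(self, name: str) -> float:
        """Look up a data column by name (phenotype, covariate, or genotype)."""
        for store in (self.phenotypes, self.covariates, self.genotypes):
            if name in store:
                return store[name]
        return math.nan


class Pedigree:
    """One family: members in topological order plus index lookups."""

    def __init__(self, family_id: str, members: list[Individual]):
        self.family_id = family_id
        self.members = list(members)
        self._index = {m.person_id: i for i, m in enumerate(self.members)}
        if len(self._index) != len(self.members):
            raise PedigreeStructureError(
                f"family {family_id}: duplicate individual ids"
            )

    @property
    def size(self) -> int:
        return len(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __repr__(self) -> str:
        return f"Pedigree({self.family_id!r}, n={self.size})"

    def index_of(self, person_id: str) -> int:
        return self._index[person_id]

    def parent_indices(self) -> list[tuple[int, int] | None]:
        """Per member: (father index, mother index), or None for founders."""
        out: list[tuple[int, int] | None] = []
        for m in self.members:
            if m.is_founder:
                out.append(None)
            else:
                out.append((self._index[m.father_id], self._index[m.mother_id]))
        return out

    @property
    def proband_index(self) -> int | None:
        """Index of the first flagged proband in member order, or None."""
        for i, m in enumerate(self.members):
            if m.proband:
                return i
        return None

    def column(self, name: str) -> np.ndarray:
        """Values of a named data column across members (nan = missing)."""
        return np.array([m.get(name) for m in self.members], dtype=float)

    def data_matrix(self, names: list[str]) -> np.ndarray:
        """(size x len(names)) matrix of named columns."""
        return np.column_stack([self.column(n) for n in names]) if names else \
            np.empty((self.size, 0))


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # {"warning", "error"}
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.message}"


# ---------------------------------------------------------------------------
# reading / writing


def _parse_sex(raw) -> str:
    s = str(raw).strip().lower()
    if s in _SEX_MALE:
        return "male"
    if s in _SEX_FEMALE:
        return "female"
    return "unknown"


def _sex_code(sex: str) -> str:
    return {"male": "1", "female": "2"}.get(sex, "0")


def _parse_parent(raw) -> str | None:
    s = str(raw).strip()
    if s.lower() in MISSING_PARENT_CODES:
        return None
    return s


def _is_truthy(raw) -> bool:
    return str(raw).strip().lower() in _TRUTHY


def _to_float(raw) -> float:
    try:
        v = float(raw)
    except (TypeError, ValueError):
        return math.nan
    return v


DEFAULT_DIALECT = {
    "family": "family",
    "id": "id",
    "father": "father",
    "mother": "mother",
    "sex": "sex",
    "proband": "proband",
    "household": "household",
}


def _resolve_dialect(columns, dialect):
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update({k: v for k, v in dialect.items()
                  if k in DEFAULT_DIALECT and v is not None})
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for role, name in d.items():
        resolved[role] = lower.get(str(name).lower())
    for role in ("family", "id", "father", "mother"):
        if resolved[role] is None:
            raise PedigreeFormatError(f"missing mandatory column: {d[role]}")
    return resolved


def _classify_data_columns(columns, resolved, dialect):
    used = {c for c in resolved.values() if c is not None}
    rest = [c for c in columns if c not in used]
    geno = set((dialect or {}).get("genotype_cols") or [])
    cov = set((dialect or {}).get("covariate_cols") or [])
    genotype_cols, covariate_cols, phenotype_cols = [], [], []
    for c in rest:
        if c in geno or (not geno and _GENOTYPE_NAME_RE.match(c)):
            genotype_cols.append(c)
        elif c in cov:
            covariate_cols.append(c)
        else:
            phenotype_cols.append(c)
    return genotype_cols, covariate_cols, phenotype_cols


def _topological_order(ids, parents):
    """Kahn's algorithm with file-order tie-breaking; raises on cycles."""
    n = len(ids)
    index = {pid: i for i, pid in enumerate(ids)}
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = [0] * n
    for i, pp in enumerate(parents):
        if pp is None:
            continue
        for p in pp:
            children[index[p]].append(i)
            indeg[i] += 1
    heap = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        i = heapq.heappop(heap)
        order.append(i)
        for ch in children[i]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                heapq.heappush(heap, ch)
    if len(order) != n:
        raise PedigreeStructureError("cyclic parentage: an individual is its own ancestor")
    return order


def pedigrees_from_frame(frame: pd.DataFrame, dialect: dict | None = None,
                         strict: bool = False) -> list[Pedigree]:
    """Build pedigrees from a pedigree table (see :func:`read_pedigree_csv`)."""
    resolved = _resolve_dialect(frame.columns, dialect)
    geno_cols, cov_cols, pheno_cols = _classify_data_columns(
        frame.columns, resolved, dialect)

    peds = []
    for fam, sub in frame.groupby(resolved["family"], sort=False):
        fam = str(fam)
        rows = {}
        order_in_file = []
        for _, row in sub.iterrows():
            pid = str(row[resolved["id"]]).strip()
            father = _parse_parent(row[resolved["father"]])
            mother = _parse_parent(row[resolved["mother"]])
            if (father is None) != (mother is None):
                raise PedigreeStructureError(
                    f"family {fam}, individual {pid}: exactly one parent is "
                    "missing (founders must have both parents missing)")
            ind = Individual(
                person_id=pid,
                father_id=father,
                mother_id=mother,
                sex=_parse_sex(row[resolved["sex"]]) if resolved["sex"] else "unknown",
                proband=_is_truthy(row[resolved["proband"]]) if resolved["proband"] else False,
                household=(str(row[resolved["household"]]).strip()
                           if resolved["household"] else None),
                phenotypes={c: _to_float(row[c]) for c in pheno_cols},
                covariates={c: _to_float(row[c]) for c in cov_cols},
                genotypes={c: _validate_genotype(row[c], fam, pid, c)
                           for c in geno_cols},
            )
            rows[pid] = ind
            order_in_file.append(pid)

        # parents referenced but not listed become data-free founders
        for pid in list(order_in_file):
            ind = rows[pid]
            for role, par in (("father", ind.father_id), ("mother", ind.mother_id)):
                if par is not None and par not in rows:
                    if strict:
                        raise PedigreeStructureError(
                            f"family {fam}: {role} {par} of {pid} not found "
                            "in the family")
                    warnings.warn(
                        f"family {fam}: {role} {par} of {pid} not listed; "
                        "auto-created as a founder with all data missing",
                        stacklevel=2)
                    rows[par] = Individual(
                        person_id=par,
                        sex="male" if role == "father" else "female",
                        phenotypes={c: math.nan for c in pheno_cols},
                        covariates={c: math.nan for c in cov_cols},
                        genotypes={c: math.nan for c in geno_cols},
                    )
                    order_in_file.append(par)

        ids = order_in_file
        parents = []
        for pid in ids:
            ind = rows[pid]
            if ind.is_founder:
                parents.append(None)
            else:
                for par, role in ((ind.father_id, "father"), (ind.mother_id, "mother")):
                    if par not in rows:  # pragma: no cover - auto-created above
                        raise PedigreeStructureError(
                            f"family {fam}: {role} {par} of {pid} not found")
                parents.append((ind.father_id, ind.mother_id))
        order = _topological_order(ids, parents)
        peds.append(Pedigree(fam, [rows[ids[i]] for i in order]))
    return peds


def _validate_genotype(raw, fam, pid, col) -> float:
    v = _to_float(raw)
    if math.isnan(v):
        return v
    if v not in (0.0, 1.0, 2.0):
        raise PedigreeFormatError(
            f"family {fam}, individual {pid}: genotype {col}={raw!r} "
            "is not an allele count in {0,1,2}")
    return v


def read_pedigree_csv(path, dialect: dict | None = None,
                      strict: bool = False) -> list[Pedigree]:
    """Read a pedigree CSV into one :class:`Pedigree` per family.

    Expected header: ``family,id,father,mother[,sex][,proband][,household]``
    plus data columns.  Missing parents are coded ``0`` or empty; sex codes
    ``{1,M,male}/{2,F,female}`` are case-insensitive.  Columns matching
    ``rs<digits>``/``snp*`` are treated as genotype counts unless the
    ``dialect`` map says otherwise (keys ``genotype_cols``/``covariate_cols``
    list data columns explicitly; keys ``family``/``id``/... rename the
    structural columns).  Members come back topologically sorted.

    Individuals appearing only as parents are auto-created as data-free
    founders with a warning; ``strict=True`` raises a referential error
    instead.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return pedigrees_from_frame(frame, dialect, strict=strict)


def write_pedigree_csv(peds: list[Pedigree], path) -> None:
    """Write pedigrees in the CSV dialect read by :func:`read_pedigree_csv`."""
    pheno, cov, geno = [], [], []
    have_household = any(m.household not in (None, "")
                         for p in peds for m in p.members)
    for p in peds:
        for m in p.members:
            for c in m.phenotypes:
                if c not in pheno:
                    pheno.append(c)
            for c in m.covariates:
                if c not in cov:
                    cov.append(c)
            for c in m.genotypes:
                if c not in geno:
                    geno.append(c)
    rows = []
    for p in peds:
        for m in p.members:
            row = {
                "family": p.family_id,
                "id": m.person_id,
                "father": m.father_id or "0",
                "mother": m.mother_id or "0",
                "sex": _sex_code(m.sex),
                "proband": "1" if m.proband else "0",
            }
            if have_household:
                row["household"] = m.household or ""
            for c in pheno + cov + geno:
                v = m.get(c)
                row[c] = "" if math.isnan(v) else repr(v)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# validation


def validate_pedigree(ped: Pedigree) -> list[Diagnostic]:
    """Check individual/pedigree invariants; returns diagnostics, raises nothing.

    Errors: cycles, missing parents, half-specified parents, sex
    inconsistencies (a known-sex father who is not male, etc.).  Warnings:
    multiple probands (analysis conditions on the first one).
    """
    diags: list[Diagnostic] = []
    fam = ped.family_id
    ids = {m.person_id for m in ped.members}

    for m in ped.members:
        if (m.father_id is None) != (m.mother_id is None):
            diags.append(Diagnostic(
                "error", f"family {fam}, {m.person_id}: only one parent specified"))
            continue
        if m.is_founder:
            continue
        for role, par, want in (("father", m.father_id, "male"),
                                ("mother", m.mother_id, "female")):
            if par not in ids:
                diags.append(Diagnostic(
                    "error", f"family {fam}, {m.person_id}: {role} {par} not in family"))
                continue
            sex = ped.members[ped.index_of(par)].sex
            if sex not in ("unknown", want):
                diags.append(Diagnostic(
                    "error",
                    f"family {fam}: {role} {par} of {m.person_id} has sex {sex}"))

    ids_list = [m.person_id for m in ped.members]
    parents = [None if m.is_founder else
               tuple(p for p in (m.father_id, m.mother_id) if p in ids)
               for m in ped.members]
    try:
        order = _topological_order(ids_list, [pp or None for pp in parents])
    except PedigreeStructureError:
        diags.append(Diagnostic(
            "error", f"family {fam}: cyclic parentage detected"))
        order = None
    if order is not None:
        seen = set()
        sorted_ok = True
        pos = {pid: i for i, pid in enumerate(ids_list)}
        for m in ped.members:
            if not m.is_founder:
                for p in (m.father_id, m.mother_id):
                    if p in ids and pos[p] > pos[m.person_id]:
                        sorted_ok = False
            seen.add(m.person_id)
        if not sorted_ok:
            diags.append(Diagnostic(
                "error", f"family {fam}: members are not in topological order"))

    n_probands = sum(m.proband for m in ped.members)
    if n_probands > 1:
        diags.append(Diagnostic(
            "warning",
            f"family {fam}: {n_probands} probands flagged; analysis "
            "conditions on the first in member order"))
    return diags


# ---------------------------------------------------------------------------
# kinship and relationship matrices


def kinship_matrix(ped: Pedigree) -> np.ndarray:
    """Kinship coefficient matrix Phi via the standard recursion.

    phi(i,i) = (1 + phi(f_i, m_i)) / 2, with phi of a missing parent pair 0;
    phi(i,j) = (phi(f_i, j) + phi(m_i, j)) / 2 for j earlier in topological
    order.  Works unchanged for inbred pedigrees and loops.
    """
    n = ped.size
    K = np.zeros((n, n))
    parents = ped.parent_indices()
    for i in range(n):
        pp = parents[i]
        if pp is None:
            K[i, i] = 0.5
        else:
            f, m = pp
            if f >= i or m >= i:
                raise PedigreeStructureError(
                    f"family {ped.family_id}: members not topologically sorted")
            K[i, i] = 0.5 * (1.0 + K[f, m])
            for j in range(i):
                K[i, j] = K[j, i] = 0.5 * (K[f, j] + K[m, j])
    return K


def relationship_matrix(ped: Pedigree, component: str,
                        ibd: "IbdStore | None" = None,
                        marker: str | None = None) -> np.ndarray:
    """Relationship matrix for one variance component (see module docstring)."""
    n = ped.size
    if component in ("polygenic", "p"):
        return 2.0 * kinship_matrix(ped)
    if component in ("environment", "e"):
        return np.eye(n)
    if component in ("household", "c"):
        groups = [m.household if m.household not in (None, "") else "__whole__"
                  for m in ped.members]
        R = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if groups[i] == groups[j]:
                    R[i, j] = 1.0
        return R
    if component in ("linkage", "a"):
        if ibd is None or marker is None:
            raise ConfigurationError(
                "linkage component requires IBD data and a marker name")
        return ibd.matrix(ped, marker)
    raise ConfigurationError(f"unknown variance component: {component!r}")


# ---------------------------------------------------------------------------
# IBD sharing input


class IbdStore:
    """Marker-specific IBD sharing proportions keyed by (family, marker, pair)."""

    def __init__(self):
        self._data: dict[tuple[str, str], dict[tuple[str, str], float]] = {}

    def set(self, family: str, marker: str, id1: str, id2: str, pi: float) -> None:
        if not (0.0 <= pi <= 1.0):
            raise PedigreeFormatError(
                f"IBD proportion {pi} for ({family},{marker},{id1},{id2}) "
                "outside [0, 1]")
        key = (str(family), str(marker))
        pair = tuple(sorted((str(id1), str(id2))))
        self._data.setdefault(key, {})[pair] = float(pi)

    def get(self, family: str, marker: str, id1: str, id2: str) -> float:
        key = (str(family), str(marker))
        pair = tuple(sorted((str(id1), str(id2))))
        try:
            return self._data[key][pair]
        except KeyError:
            raise ConfigurationError(
                f"no IBD value for pair ({id1},{id2}) at marker {marker} "
                f"in family {family}") from None

    def markers(self) -> set[str]:
        return {m for (_, m) in self._data}

    def __len__(self) -> int:
        return sum(len(v) for v in self._data.values())

    def matrix(self, ped: Pedigree, marker: str) -> np.ndarray:
        """Symmetric IBD matrix for one pedigree, diagonal set to 1."""
        n = ped.size
        R = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                pi = self.get(ped.family_id, marker,
                              ped.members[i].person_id, ped.members[j].person_id)
                R[i, j] = R[j, i] = pi
        return R

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"family": fam, "marker": mk, "id1": a, "id2": b, "pi": pi}
            for (fam, mk), pairs in sorted(self._data.items())
            for (a, b), pi in sorted(pairs.items())
        ]
        return pd.DataFrame(rows, columns=["family", "marker", "id1", "id2", "pi"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_ibd_file(path) -> IbdStore:
    """Read an IBD CSV with columns family, marker, id1, id2, pi.

    ``pi`` is the expected proportion of alleles shared IBD, in [0, 1].
    Storage is symmetric in (id1, id2).  Pairs absent from the file are an
    error at lookup time (no kinship-based default is substituted).
    """
    frame = pd.read_csv(path, dtype={"family": str, "marker": str,
                                     "id1": str, "id2": str})
    required = ["family", "marker", "id1", "id2", "pi"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise PedigreeFormatError(f"IBD file missing columns: {missing}")
    store = IbdStore()
    for _, row in frame.iterrows():
        store.set(row["family"], row["marker"], row["id1"], row["id2"],
                  float(row["pi"]))
    return store
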