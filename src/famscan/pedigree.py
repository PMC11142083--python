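"""Pedigree structures and pedigree-based kinship.

A pedigree is a set of families, each an acyclic graph of parent-offspring
links. The kinship coefficient phi(i, j) is the probability that an allele
drawn at random from i is identical by descent (IBD) with an allele drawn at
random from j; it is computed here by the classical tabular recursion in which
founders are unrelated and non-inbred, and each individual's row is built from
its parents' rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PedigreeError",
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "read_pedigree",
    "kinship_matrix",
]


class PedigreeError(ValueError):
    """Structural or parse problem in a pedigree."""


_SEX_CODES = {
    "1": "male",
    "m": "male",
    "2": "female",
    "f": "female",
    "0": "unknown",
    "u": "unknown",
}
_MISSING_PARENT = {"0", "", ".", "na", "nan", "-9"}


@dataclass(frozen=True)
class Individual:
    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """A validated collection of individuals grouped into families.

    Invariants enforced on construction: individual ids are unique, every
    named parent exists in the same family (absent parents are auto-created
    as founders, with a warning), the parent graph is acyclic, fathers are
    male and mothers female whenever sex is known, and unknown sex is only
    permitted for founders.
    """

    records: list[Individual]
    _index: dict[str, Individual] = field(init=False, repr=False)
    _topo: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._validate_and_complete()

    # -- construction helpers -------------------------------------------------

    def _validate_and_complete(self) -> None:
        seen: dict[str, Individual] = {}
        for rec in self.records:
            if rec.individual_id in seen:
                raise PedigreeError(
                    f"duplicate individual id {rec.individual_id!r}"
                )
            seen[rec.individual_id] = rec

        # Auto-create referenced-but-absent parents as founders.
        created: list[Individual] = []
        for rec in list(self.records):
            for pid, sex in ((rec.father_id, "male"), (rec.mother_id, "female")):
                if pid is not None and pid not in seen:
                    warnings.warn(
                        f"parent {pid!r} of {rec.individual_id!r} not listed; "
                        "created as founder",
                        stacklevel=2,
                    )
                    founder = Individual(rec.family_id, pid, None, None, sex)
                    seen[pid] = founder
                    created.append(founder)
        self.records.extend(created)
        self._index = seen

        for rec in self.records:
            for pid, role, want in (
                (rec.father_id, "father", "male"),
                (rec.mother_id, "mother", "female"),
            ):
                if pid is None:
                    continue
                parent = seen[pid]
                if parent.family_id != rec.family_id:
                    raise PedigreeError(
                        f"{role} {pid!r} of {rec.individual_id!r} belongs to a "
                        f"different family ({parent.family_id!r})"
                    )
                if parent.sex not in (want, "unknown"):
                    raise PedigreeError(
                        f"{role} {pid!r} of {rec.individual_id!r} has sex "
                        f"{parent.sex!r}"
                    )
            if rec.sex == "unknown" and not rec.is_founder:
                raise PedigreeError(
                    f"non-founder {rec.individual_id!r} has unknown sex"
                )

        self._topo = self._toposort()

    def _toposort(self) -> list[str]:
        """Kahn's algorithm over parent->child edges; raises on cycles."""
        indeg = {r.individual_id: 0 for r in self.records}
        children: dict[str, list[str]] = {r.individual_id: [] for r in self.records}
        for rec in self.records:
            for pid in (rec.father_id, rec.mother_id):
                if pid is not None:
                    indeg[rec.individual_id] += 1
                    children[pid].append(rec.individual_id)
        queue = sorted(i for i, d in indeg.items() if d == 0)
        order: list[str] = []
        while queue:
            node = queue.pop(0)
            order.append(node)
            for child in children[node]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if len(order) != len(self.records):
            cyc = sorted(i for i, d in indeg.items() if d > 0)
            raise PedigreeError(f"cyclic parentage involving {cyc}")
        return order

    # -- queries --------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, individual_id: str) -> Individual:
        return self._index[individual_id]

    @property
    def ids(self) -> list[str]:
        """Individual ids in a parents-before-children order."""
        return list(self._topo)

    @property
    def family_ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.family_id not in out:
                out.append(rec.family_id)
        return out

    def family(self, family_id: str) -> list[Individual]:
        return [r for r in self.records if r.family_id == family_id]

    def founders(self) -> list[Individual]:
        return [r for r in self.records if r.is_founder]

    def family_of(self) -> dict[str, str]:
        return {r.individual_id: r.family_id for r in self.records}


def read_pedigree(path) -> Pedigree:
    """Read a whitespace/tab-delimited PED/FAM file.

    Expected columns: family, individual, father, mother, sex
    [, phenotype...]; ``0`` (and ``.``/``NA``) denote a missing parent.
    Sex codes 1/2/0 and M/F/U are accepted.
    """
    records: list[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise PedigreeError(
                    f"{path}:{lineno}: expected >=5 columns, got {len(parts)}"
                )
            fam, iid, fid, mid, sex = parts[:5]
            sex_norm = _SEX_CODES.get(sex.lower())
            if sex_norm is None:
                raise PedigreeError(f"{path}:{lineno}: bad sex code {sex!r}")
            if iid == fid or iid == mid:
                raise PedigreeError(
                    f"{path}:{lineno}: individual {iid!r} lists itself as parent"
                )
            records.append(
                Individual(
                    family_id=fam,
                    individual_id=iid,
                    father_id=None if fid.lower() in _MISSING_PARENT else fid,
                    mother_id=None if mid.lower() in _MISSING_PARENT else mid,
                    sex=sex_norm,
                )
            )
    if not records:
        raise PedigreeError(f"{path}: no pedigree records")
    return Pedigree(records)


@dataclass
class KinshipMatrix:
    """Pairwise kinship coefficients Phi over an ordered set of individuals.

    ``values[i, j] = phi(ids[i], ids[j])``; the additive genetic relationship
    matrix used in variance-components models is ``2 * values``.  ``families``
    labels each individual with its family id, making the block-diagonal
    structure explicit.
    """

    ids: list[str]
    values: np.ndarray
    families: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.families = np.asarray(self.families, dtype=object)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match ids")

    @property
    def kin2(self) -> np.ndarray:
        """2*Phi, the expected genotypic covariance structure."""
        return 2.0 * self.values

    def index_of(self, ids) -> np.ndarray:
        pos = {iid: k for k, iid in enumerate(self.ids)}
        try:
            return np.array([pos[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in kinship matrix") from exc

    def subset(self, ids) -> "KinshipMatrix":
        idx = self.index_of(ids)
        return KinshipMatrix(
            ids=list(ids),
            values=self.values[np.ix_(idx, idx)],
            families=self.families[idx],
        )


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Compute kinship recursively from pedigree structure.

    phi(i,i) = 0.5 * (1 + phi(father_i, mother_i)) and, for i not an ancestor
    of j, phi(i,j) = 0.5 * (phi(father_i, j) + phi(mother_i, j)); founders are
    unrelated and non-inbred. Individuals from different families have
    kinship 0 by construction.
    """
    order = ped.ids  # parents precede children, so earlier j is never a descendant of i
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    # cross-family kinship is 0, so the recursion runs family by family
    by_family: dict[str, list[str]] = {}
    for iid in order:
        by_family.setdefault(ped[iid].family_id, []).append(iid)
    for members in by_family.values():
        local = {iid: k for k, iid in enumerate(members)}
        m = len(members)
        block = np.zeros((m, m))
        for i, iid in enumerate(members):
            rec = ped[iid]
            fi = local.get(rec.father_id) if rec.father_id is not None else None
            mi = local.get(rec.mother_id) if rec.mother_id is not None else None
            if fi is not None and mi is not None:
                block[i, i] = 0.5 + 0.5 * block[fi, mi]
            else:
                block[i, i] = 0.5  # founder (a single missing parent is an unrelated founder)
            for j in range(i):
                val = 0.0
                if fi is not None:
                    val += 0.5 * block[fi, j]
                if mi is not None:
                    val += 0.5 * block[mi, j]
                block[i, j] = block[j, i] = val
        gidx = np.array([pos[iid] for iid in members])
        phi[np.ix_(gidx, gidx)] = block
    fams = np.array([ped[i].family_id for i in order], dtype=object)
    return KinshipMatrix(ids=order, values=phi, families=fams)
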