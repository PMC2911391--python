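"""Pedigree parsing, validation and kinship computation.

The kinship coefficient Phi(i, j) is the probability that one allele
drawn at random from i and one from j are identical by descent.  The
additive genetic covariance between relatives in the polygenic model is
proportional to 2*Phi, so everything downstream (association scan,
bivariate decomposition) consumes the matrix computed here.

Kinship is computed by the exact recursion on a parents-before-children
ordering, so inbreeding loops (e.g. cousin marriages in extended
pedigrees) are handled without any non-inbred shortcut:

    Phi(i, i) = 0.5 * (1 + Phi(f_i, m_i))
    Phi(i, j) = 0.5 * (Phi(f_i, j) + Phi(m_i, j))   for j already placed

with founders mutually unrelated.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MISSING_PARENT = "0"

_SEX_CODES = {
    "1": "male",
    "2": "female",
    "0": "unknown",
    "m": "male",
    "f": "female",
    "male": "male",
    "female": "female",
    "unknown": "unknown",
}


class PedigreeError(ValueError):
    """Structural or format problem in a pedigree file."""


@dataclass(frozen=True)
class Individual:
    family: str
    iid: str
    father: str | None
    mother: str | None
    sex: str  # 'male' | 'female' | 'unknown'

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass
class Pedigree:
    """A validated set of individuals with parent links.

    Invariants enforced at construction: unique ids, no half-specified
    parentage (either both parents present or both missing), all parent
    ids resolvable, and an acyclic parent graph.
    """

    individuals: list[Individual]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [ind.iid for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate individual id(s): {', '.join(dup)}")
        self._index = {iid: k for k, iid in enumerate(ids)}
        known = set(ids)
        for ind in self.individuals:
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(
                    f"individual {ind.iid}: half-specified parentage "
                    "(exactly one parent missing)"
                )
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in known:
                    raise PedigreeError(
                        f"individual {ind.iid}: unknown parent id {parent!r}"
                    )
        self._toposort()  # raises on cycles

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.iid for ind in self.individuals]

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[self._index[iid]]

    def _toposort(self) -> list[str]:
        """Kahn topological order, parents before children."""
        children: dict[str, list[str]] = {iid: [] for iid in self._index}
        indeg = {iid: 0 for iid in self._index}
        for ind in self.individuals:
            if ind.father is not None:
                for p in (ind.father, ind.mother):
                    children[p].append(ind.iid)
                    indeg[ind.iid] += 1
        queue = [iid for iid, d in indeg.items() if d == 0]
        order: list[str] = []
        while queue:
            iid = queue.pop()
            order.append(iid)
            for ch in children[iid]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if len(order) != len(self.individuals):
            stuck = sorted(iid for iid, d in indeg.items() if d > 0)
            raise PedigreeError(
                f"pedigree contains a cycle involving individual {stuck[0]}"
            )
        return order

    def topological_ids(self) -> list[str]:
        return self._toposort()

    def founders(self) -> list[str]:
        return [ind.iid for ind in self.individuals if ind.is_founder]

    def connected_components(self) -> list[list[str]]:
        """Partition ids into connected pedigree components (union-find)."""
        parent = {iid: iid for iid in self._index}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a: str, b: str) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

        for ind in self.individuals:
            if ind.father is not None:
                union(ind.iid, ind.father)
                union(ind.iid, ind.mother)
        groups: dict[str, list[str]] = {}
        for ind in self.individuals:
            groups.setdefault(find(ind.iid), []).append(ind.iid)
        # stable order: by first appearance in the file
        return sorted(groups.values(), key=lambda g: self._index[g[0]])


@dataclass
class KinshipMatrix:
    """Kinship coefficients on an ordered id list, with block structure.

    ``phi`` is symmetric, Phi(i,i) >= 0.5 (equality for non-inbred
    individuals) and zero between connected components.  ``blocks``
    holds index arrays (into ``ids``) for each component; 2*Phi
    restricted to any block is positive semi-definite.
    """

    ids: list[str]
    phi: np.ndarray
    blocks: list[np.ndarray]

    def __post_init__(self) -> None:
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    def subset(self, ids: list[str]) -> "KinshipMatrix":
        """Restrict to ``ids`` (in the given order), recomputing blocks."""
        idx = np.array([self._index[i] for i in ids])
        phi = self.phi[np.ix_(idx, idx)]
        # connected components of the nonzero pattern
        n = len(ids)
        seen = np.zeros(n, dtype=bool)
        blocks = []
        adj = phi != 0.0
        for start in range(n):
            if seen[start]:
                continue
            stack = [start]
            comp = []
            seen[start] = True
            while stack:
                k = stack.pop()
                comp.append(k)
                nxt = np.nonzero(adj[k] & ~seen)[0]
                seen[nxt] = True
                stack.extend(nxt.tolist())
            blocks.append(np.array(sorted(comp)))
        return KinshipMatrix(ids=list(ids), phi=phi, blocks=blocks)

    def to_long_frame(self):
        """Long-format (id1, id2, phi) table of the nonzero upper triangle."""
        import pandas as pd

        rows = []
        for b in self.blocks:
            for ii, i in enumerate(b):
                for j in b[ii:]:
                    rows.append((self.ids[i], self.ids[j], self.phi[i, j]))
        return pd.DataFrame(rows, columns=["id1", "id2", "phi"])


def _parse_sex(token: str) -> str:
    try:
        return _SEX_CODES[token.strip().lower()]
    except KeyError:
        raise PedigreeError(f"unrecognized sex code {token!r}") from None


def read_pedigree(path: str | Path | io.TextIOBase, strict_sex: bool = False) -> Pedigree:
    """Read a PED/FAM-style whitespace-delimited pedigree file.

    Columns: family, individual, father, mother, sex[, trailing columns
    ignored].  ``0`` or an empty field denotes a missing parent.  With
    ``strict_sex`` the father/mother columns are cross-checked against
    the recorded sex of each named parent.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    individuals: list[Individual] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.replace("\t", " ").split()
        if len(fields) < 5:
            raise PedigreeError(
                f"line {lineno}: expected >=5 columns (family, id, father, "
                f"mother, sex), got {len(fields)}"
            )
        fam, iid, fa, mo, sex = fields[:5]
        father = None if fa in (MISSING_PARENT, "") else fa
        mother = None if mo in (MISSING_PARENT, "") else mo
        individuals.append(
            Individual(family=fam, iid=iid, father=father, mother=mother,
                       sex=_parse_sex(sex))
        )
    ped = Pedigree(individuals)
    if strict_sex:
        for ind in ped.individuals:
            if ind.father is not None and ped[ind.father].sex == "female":
                raise PedigreeError(
                    f"individual {ind.iid}: father {ind.father} recorded as female"
                )
            if ind.mother is not None and ped[ind.mother].sex == "male":
                raise PedigreeError(
                    f"individual {ind.iid}: mother {ind.mother} recorded as male"
                )
    return ped


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Compute the full kinship matrix by the exact recursion.

    Individuals are processed parents-before-children; at each step the
    recursion only references already-placed individuals, so loops and
    inbreeding are handled exactly.
    """
    order = ped.topological_ids()
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for k, iid in enumerate(order):
        ind = ped[iid]
        if ind.is_founder:
            phi[k, k] = 0.5
        else:
            f, m = pos[ind.father], pos[ind.mother]
            phi[k, k] = 0.5 * (1.0 + phi[f, m])
            for j in range(k):
                val = 0.5 * (phi[f, j] + phi[m, j])
                phi[k, j] = phi[j, k] = val
    # re-order to match the file order of ids
    file_ids = ped.ids
    perm = np.array([pos[iid] for iid in file_ids])
    phi = phi[np.ix_(perm, perm)]
    comps = ped.connected_components()
    index = {iid: k for k, iid in enumerate(file_ids)}
    blocks = [np.array(sorted(index[i] for i in comp)) for comp in comps]
    return KinshipMatrix(ids=file_ids, phi=phi, blocks=blocks)


def write_kinship_tsv(kin: KinshipMatrix, path: str | Path) -> None:
    kin.to_long_frame().to_csv(path, sep="\t", index=False)


def write_block_manifest(kin: KinshipMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("block\tid\n")
        for b_idx, block in enumerate(kin.blocks):
            for i in block:
                fh.write(f"{b_idx}\t{kin.ids[i]}\n")


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    sex_out = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for ind in ped.individuals:
            fa = ind.father or MISSING_PARENT
            mo = ind.mother or MISSING_PARENT
            fh.write(f"{ind.family}\t{ind.iid}\t{fa}\t{mo}\t{sex_out[ind.sex]}\n")
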