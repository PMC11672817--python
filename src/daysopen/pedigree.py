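"""Pedigree handling and numerator relationship matrix (A) algebra.

The additive genetic covariance of an animal model is ``A * sigma_u2`` where
``A`` is the numerator relationship matrix implied by the pedigree.  This
module reads pedigree files, renumbers and topologically orders them,
computes inbreeding coefficients with the Meuwissen-Luo algorithm, builds the
dense A by the tabular method (small pedigrees, used mainly as an oracle) and
builds the sparse inverse of A directly from Henderson's rules with
inbreeding-adjusted Mendelian-sampling variances, which is what the mixed
model equations and the Gibbs samplers consume.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = 0

#: dense-A guard: above this the tabular matrix is refused
DENSE_A_LIMIT = 5000


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id, missing parent)."""


@dataclass
class Pedigree:
    """Renumbered, topologically ordered pedigree.

    Internal ids are dense ``1..n`` with 0 meaning *unknown parent*; every
    known parent precedes its progeny.  ``original_ids[i-1]`` recovers the
    external label of internal id ``i``.
    """

    sire: np.ndarray  # length n+1, index 0 unused; 0 = unknown
    dam: np.ndarray
    original_ids: list = field(repr=False)
    id_map: dict = field(repr=False)  # external label -> internal id

    @property
    def n(self) -> int:
        return len(self.sire) - 1

    @property
    def animals(self) -> np.ndarray:
        return np.arange(1, self.n + 1)

    def is_founder(self, i: int) -> bool:
        return self.sire[i] == UNKNOWN and self.dam[i] == UNKNOWN

    @property
    def founders(self) -> np.ndarray:
        a = self.animals
        return a[(self.sire[1:] == UNKNOWN) & (self.dam[1:] == UNKNOWN)]

    def to_internal(self, labels) -> np.ndarray:
        """Map external labels to internal ids, raising on unknown labels."""
        out = np.empty(len(labels), dtype=np.int64)
        missing = []
        for k, lab in enumerate(labels):
            try:
                out[k] = self.id_map[lab]
            except KeyError:
                missing.append(lab)
        if missing:
            raise PedigreeError(f"labels not in pedigree: {missing[:10]}")
        return out

    def to_external(self, ids) -> list:
        return [self.original_ids[i - 1] for i in ids]


def _toposort(parents: dict) -> list:
    """Kahn's algorithm (iterative) over the parent->child DAG.

    Raises on cycles, naming one animal involved.
    """
    children: dict = {a: [] for a in parents}
    indeg = {a: 0 for a in parents}
    for a, (s, d) in parents.items():
        for p in (s, d):
            if p is not None:
                children[p].append(a)
                indeg[a] += 1
    queue = [a for a, k in indeg.items() if k == 0]
    order = []
    while queue:
        nxt = []
        for a in queue:
            order.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    nxt.append(c)
        queue = nxt
    if len(order) != len(parents):
        bad = [a for a, k in indeg.items() if k > 0]
        raise PedigreeError(
            f"pedigree contains a cycle involving animal(s) {bad[:5]}"
        )
    return order


def from_triples(triples) -> Pedigree:
    """Build a :class:`Pedigree` from (animal, sire, dam) triples.

    Unknown parents are coded 0 (or None / empty).  Parents that appear only
    as parents are added as founders.  Animals are renumbered 1..n in a
    topological order (parents first).
    """
    def norm(v):
        if v is None:
            return None
        if isinstance(v, float) and np.isnan(v):
            return None
        if isinstance(v, str):
            v = v.strip()
            if v in ("", "0", ".", "NA"):
                return None
            return v
        if isinstance(v, (int, np.integer)) and int(v) == 0:
            return None
        return v

    parents: dict = {}
    for a, s, d in triples:
        a, s, d = norm(a), norm(s), norm(d)
        if a is None:
            raise PedigreeError("animal id missing in pedigree row")
        if a in parents:
            raise PedigreeError(f"duplicate animal id {a!r}")
        if a == s or a == d:
            raise PedigreeError(f"pedigree contains a cycle involving animal(s) [{a!r}]")
        parents[a] = (s, d)
    # parents never listed as animals become founders
    for s, d in list(parents.values()):
        for p in (s, d):
            if p is not None and p not in parents:
                parents[p] = (None, None)

    order = _toposort(parents)
    id_map = {lab: i + 1 for i, lab in enumerate(order)}
    n = len(order)
    sire = np.zeros(n + 1, dtype=np.int64)
    dam = np.zeros(n + 1, dtype=np.int64)
    for lab, i in id_map.items():
        s, d = parents[lab]
        sire[i] = id_map[s] if s is not None else UNKNOWN
        dam[i] = id_map[d] if d is not None else UNKNOWN
    return Pedigree(sire=sire, dam=dam, original_ids=order, id_map=id_map)


def read_pedigree(path) -> Pedigree:
    """Read a pedigree file: columns animal, sire, dam; '0' = unknown.

    Whitespace- or comma-delimited; an optional header row is auto-detected
    (a header is any first row whose first field is non-numeric and matches
    no later animal id pattern such as 'animal').
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "," if "," in first else r"\s+"
    header = 0 if any(
        tok.lower() in ("animal", "id", "sire", "dam")
        for tok in first.replace(",", " ").split()
    ) else None
    df = pd.read_csv(path, sep=sep, header=header, dtype=str,
                     skip_blank_lines=True)
    if df.shape[1] < 3:
        raise PedigreeError("pedigree file needs >= 3 columns (animal sire dam)")
    cols = []
    for k in range(3):
        col = df.iloc[:, k]
        # integer labels stay integers so they match phenotype-file cow ids
        if col.dropna().str.fullmatch(r"\d+").all():
            col = col.fillna("0").astype(np.int64)
        cols.append(col.tolist())
    return from_triples(list(zip(*cols)))


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F (Meuwissen-Luo algorithm).

    Returns an array of length ``n`` (index ``i-1`` for animal ``i``).
    Founders and animals with an unknown parent get F = 0; otherwise
    F_i = 0.5 * a(sire_i, dam_i).
    """
    n = ped.n
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n + 1)
    # Mendelian-sampling variance D_j; uses convention F(unknown) = -1
    def mendel_d(j):
        s, d = sire[j], dam[j]
        fs = F[s] if s != UNKNOWN else -1.0
        fd = F[d] if d != UNKNOWN else -1.0
        return 0.5 - 0.25 * (fs + fd)

    D = np.empty(n + 1)
    L = np.zeros(n + 1)
    for i in range(1, n + 1):
        D[i] = mendel_d(i)
        s, d = sire[i], dam[i]
        if s == UNKNOWN or d == UNKNOWN:
            F[i] = 0.0
            continue
        # accumulate a_ii = sum_j L_ij^2 D_j over ancestors j of i
        aii = 0.0
        L[i] = 1.0
        heap = [-i]
        inheap = {i}
        while heap:
            j = -heapq.heappop(heap)
            inheap.discard(j)
            lj = L[j]
            L[j] = 0.0
            aii += lj * lj * D[j]
            for p in (sire[j], dam[j]):
                if p != UNKNOWN:
                    L[p] += 0.5 * lj
                    if p not in inheap:
                        heapq.heappush(heap, -p)
                        inheap.add(p)
        F[i] = aii - 1.0
    return F[1:]


def build_A(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    Intended for small pedigrees (oracle / debugging path); model fitting
    uses :func:`build_A_inverse`.
    """
    n = ped.n
    if n > DENSE_A_LIMIT:
        raise PedigreeError(
            f"pedigree has {n} > {DENSE_A_LIMIT} animals; "
            "use build_A_inverse (sparse) instead of the dense tabular A"
        )
    A = np.zeros((n + 1, n + 1))
    sire, dam = ped.sire, ped.dam
    for i in range(1, n + 1):
        s, d = sire[i], dam[i]
        row = 0.5 * (A[s, 1:i] + A[d, 1:i])  # row 0 stays all-zero = unknown
        A[i, 1:i] = row
        A[1:i, i] = row
        A[i, i] = 1.0 + 0.5 * A[s, d]
    return A[1:, 1:]


def mendelian_variances(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """Within-family (Mendelian-sampling) variances d_i given parental F."""
    n = ped.n
    d = np.empty(n)
    for i in range(1, n + 1):
        s, dm = ped.sire[i], ped.dam[i]
        fs = F[s - 1] if s != UNKNOWN else -1.0
        fd = F[dm - 1] if dm != UNKNOWN else -1.0
        d[i - 1] = 0.5 - 0.25 * (fs + fd)
    return d


def build_A_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse A-inverse from Henderson's rules with inbreeding adjustment.

    For each animal the reciprocal of its Mendelian-sampling variance
    ``d_i`` (shrunk by parental inbreeding) is scattered over the
    animal/sire/dam index triple.  Returns a 0-based ``n x n`` CSR matrix.
    """
    n = ped.n
    if F is None:
        F = inbreeding(ped)
    d = mendelian_variances(ped, F)
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r - 1)
        cols.append(c - 1)
        vals.append(v)

    for i in range(1, n + 1):
        s, dm = ped.sire[i], ped.dam[i]
        alpha = 1.0 / d[i - 1]
        add(i, i, alpha)
        for p in (s, dm):
            if p != UNKNOWN:
                add(i, p, -alpha / 2.0)
                add(p, i, -alpha / 2.0)
        for p in (s, dm):
            for q in (s, dm):
                if p != UNKNOWN and q != UNKNOWN:
                    add(p, q, alpha / 4.0)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def prune_to_phenotyped(ped: Pedigree, labels) -> Pedigree:
    """Restrict a pedigree to the given animals plus all their ancestors.

    Optional: evaluations default to the full pedigree file; pruning only
    drops lines that contribute no relationship information to the kept
    animals, so inbreeding and relationships among kept animals are
    unchanged.
    """
    keep = set(int(i) for i in ped.to_internal(list(labels)))
    stack = list(keep)
    while stack:
        i = stack.pop()
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN and p not in keep:
                keep.add(int(p))
                stack.append(int(p))
    triples = []
    for i in sorted(keep):
        s, dm = ped.sire[i], ped.dam[i]
        triples.append(
            (
                ped.original_ids[i - 1],
                ped.original_ids[s - 1] if s != UNKNOWN else 0,
                ped.original_ids[dm - 1] if dm != UNKNOWN else 0,
            )
        )
    return from_triples(triples)


def mean_inbreeding(ped: Pedigree, subset, F: np.ndarray | None = None) -> float:
    """Mean inbreeding coefficient over a subset of internal animal ids."""
    ids = np.asarray(list(subset), dtype=np.int64)
    if ids.size == 0:
        raise ValueError("mean_inbreeding: empty subset")
    if ids.min() < 1 or ids.max() > ped.n:
        raise ValueError("mean_inbreeding: subset contains ids outside pedigree")
    if F is None:
        F = inbreeding(ped)
    return float(np.mean(F[ids - 1]))
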