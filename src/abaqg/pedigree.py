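"""Pedigree handling and the numerator relationship matrix.

The additive (numerator) relationship matrix A holds expected additive
genetic relationships between individuals: a_ij is twice the kinship
coefficient, the diagonal is 1 + F_i with F_i the inbreeding coefficient.
The animal model uses Var(a) = A * sigma_a^2, and Henderson's mixed-model
equations need the sparse inverse of A, which is built directly from
pedigree rules without ever forming A itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = -1
DEFAULT_UNKNOWN_CODES = frozenset({"0", "NA", ""})

SEX_LEVELS = ("F", "M", "U")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates...)."""


@dataclass
class Pedigree:
    """Topologically sorted pedigree.

    Parents always precede offspring. ``sire`` / ``dam`` hold integer
    positions into ``ids`` (or ``UNKNOWN``). ``sex`` holds 'F', 'M', 'U'
    or '' when unrecorded.
    """

    ids: np.ndarray          # dtype object/str, unique
    sire: np.ndarray         # int positions, UNKNOWN if missing
    dam: np.ndarray
    sex: np.ndarray
    founder_count: int = 0
    generation: np.ndarray = field(default=None)  # depth per individual

    def __post_init__(self):
        if self.generation is None:
            self.generation = _depths(self.sire, self.dam)
        self.founder_count = int(
            np.sum((self.sire == UNKNOWN) & (self.dam == UNKNOWN))
        )
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def position(self, individual_id) -> int:
        return self._index[individual_id]

    def positions(self, individual_ids) -> np.ndarray:
        missing = [i for i in individual_ids if i not in self._index]
        if missing:
            raise PedigreeError(
                f"{len(missing)} individuals absent from pedigree, e.g. "
                f"{missing[:5]}"
            )
        return np.fromiter(
            (self._index[i] for i in individual_ids), dtype=np.int64,
            count=len(individual_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        def name(ix):
            return np.where(ix == UNKNOWN, "0", self.ids[np.maximum(ix, 0)])

        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": name(self.sire),
                "dam": name(self.dam),
                "sex": self.sex,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _depths(sire, dam) -> np.ndarray:
    depth = np.zeros(len(sire), dtype=np.int64)
    for i in range(len(sire)):
        d = 0
        if sire[i] != UNKNOWN:
            d = depth[sire[i]] + 1
        if dam[i] != UNKNOWN:
            d = max(d, depth[dam[i]] + 1)
        depth[i] = d
    return depth


def _toposort(ids, sire_name, dam_name):
    """Kahn's algorithm with deterministic input-order tie-break.

    Returns the new ordering (positions into the input arrays); raises on
    cycles with an offending chain.
    """
    n = len(ids)
    index = {iid: k for k, iid in enumerate(ids)}
    children = [[] for _ in range(n)]
    n_parents = np.zeros(n, dtype=np.int64)
    for k in range(n):
        for pname in (sire_name[k], dam_name[k]):
            if pname is not None:
                p = index[pname]
                children[p].append(k)
                n_parents[k] += 1
    order = []
    ready = [k for k in range(n) if n_parents[k] == 0]
    head = 0
    while head < len(ready):
        k = ready[head]
        head += 1
        order.append(k)
        for c in children[k]:
            n_parents[c] -= 1
            if n_parents[c] == 0:
                ready.append(c)
    if len(order) != n:
        stuck = [ids[k] for k in range(n) if n_parents[k] > 0]
        raise PedigreeError(
            f"pedigree contains a cycle involving: {stuck[:10]}"
        )
    return order


def pedigree_from_frame(
    df: pd.DataFrame, unknown_codes=DEFAULT_UNKNOWN_CODES
) -> Pedigree:
    """Build a sorted Pedigree from an id/sire/dam(/sex) table.

    Named-but-undeclared parents are auto-created as founders (prepended
    in first-mention order). Unknown-parent codes are treated as missing.
    """
    unknown_codes = set(unknown_codes)
    df = df.copy()
    for col in ("id", "sire", "dam"):
        if col not in df.columns:
            raise PedigreeError(f"pedigree table lacks required column {col!r}")
        df[col] = df[col].astype("string").fillna("").str.strip()
    ids = df["id"].to_numpy(dtype=object)
    if len(set(ids)) != len(ids):
        dupes = df["id"][df["id"].duplicated()].tolist()
        raise PedigreeError(f"duplicate individual ids: {dupes[:5]}")

    def clean(col):
        return [
            None if v in unknown_codes else v for v in df[col].to_numpy(object)
        ]

    sire_name, dam_name = clean("sire"), clean("dam")
    for k in range(len(ids)):
        if (
            sire_name[k] is not None
            and dam_name[k] is not None
            and sire_name[k] == dam_name[k]
        ):
            raise PedigreeError(
                f"individual {ids[k]!r} lists the same sire and dam "
                f"({sire_name[k]!r})"
            )
        if sire_name[k] == ids[k] or dam_name[k] == ids[k]:
            raise PedigreeError(f"individual {ids[k]!r} is its own parent")

    declared = set(ids)
    implied = []
    seen = set()
    for names in (sire_name, dam_name):
        for v in names:
            if v is not None and v not in declared and v not in seen:
                seen.add(v)
                implied.append(v)
    if "sex" in df.columns:
        sex = (
            df["sex"].astype("string").fillna("").str.strip().str.upper()
        ).to_numpy(object)
        bad = [s for s in set(sex) if s not in {"", *SEX_LEVELS}]
        if bad:
            raise PedigreeError(f"unrecognized sex codes: {bad}")
    else:
        sex = np.full(len(ids), "", dtype=object)

    all_ids = np.concatenate([np.array(implied, dtype=object), ids])
    all_sire = [None] * len(implied) + sire_name
    all_dam = [None] * len(implied) + dam_name
    all_sex = np.concatenate([np.full(len(implied), "", dtype=object), sex])

    order = _toposort(all_ids, all_sire, all_dam)
    pos = {iid: r for r, k in enumerate(order) for iid in [all_ids[k]]}
    new_ids = all_ids[order]
    n = len(new_ids)
    sire_ix = np.full(n, UNKNOWN, dtype=np.int64)
    dam_ix = np.full(n, UNKNOWN, dtype=np.int64)
    for r, k in enumerate(order):
        if all_sire[k] is not None:
            sire_ix[r] = pos[all_sire[k]]
        if all_dam[k] is not None:
            dam_ix[r] = pos[all_dam[k]]
    return Pedigree(
        ids=new_ids, sire=sire_ix, dam=dam_ix, sex=all_sex[order]
    )


def read_pedigree(path, unknown_codes=DEFAULT_UNKNOWN_CODES) -> Pedigree:
    """Read a pedigree CSV with header columns id,sire,dam[,sex]."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return pedigree_from_frame(df, unknown_codes=unknown_codes)


# ---------------------------------------------------------------------------
# Relationship matrix


@dataclass
class RelationshipMatrix:
    order: int
    values: np.ndarray       # dense symmetric A
    inbreeding: np.ndarray   # F_i = a_ii - 1

    def write_csv(self, path, ids=None) -> None:
        pd.DataFrame(self.values, index=ids, columns=ids).to_csv(path)


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Dense A by the tabular method.

    a_jj = 1 + 0.5 a_{s(j),d(j)};  a_ij = 0.5 (a_{i,s(j)} + a_{i,d(j)}).
    Quadratic in pedigree size; intended for desk-scale pedigrees (the
    mixed-model machinery only ever needs the sparse inverse).
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for j in range(n):
        row = np.zeros(j)
        if s[j] != UNKNOWN:
            row += 0.5 * A[s[j], :j]
        if d[j] != UNKNOWN:
            row += 0.5 * A[d[j], :j]
        A[j, :j] = row
        A[:j, j] = row
        ajj = 1.0
        if s[j] != UNKNOWN and d[j] != UNKNOWN:
            ajj += 0.5 * A[s[j], d[j]]
        A[j, j] = ajj
    return RelationshipMatrix(order=n, values=A, inbreeding=np.diag(A) - 1.0)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo recursion.

    Computes each F_i from the L factor of A = L D L' row by row, without
    forming A; linear memory, suitable for the full design pedigree.
    """
    n = len(ped)
    s, d = ped.sire, ped.dam
    F = np.zeros(n)
    Dvec = np.zeros(n)
    for i in range(n):
        Fs = F[s[i]] if s[i] != UNKNOWN else -1.0
        Fd = F[d[i]] if d[i] != UNKNOWN else -1.0
        Dvec[i] = 0.5 - 0.25 * (Fs + Fd)
        if s[i] == UNKNOWN or d[i] == UNKNOWN:
            F[i] = 0.0
            continue
        # accumulate a_{s,d}/2 by walking ancestors of i
        L = {i: 1.0}
        queue = [i]
        aii = 0.0
        # traverse in decreasing position: dict keyed by position
        pending = {i: 1.0}
        while pending:
            j = max(pending)
            lj = pending.pop(j)
            # contribution of j's within-family segregation variance
            dj = Dvec[j] if j != i else Dvec[i]
            aii += lj * lj * dj
            if s[j] != UNKNOWN:
                pending[s[j]] = pending.get(s[j], 0.0) + 0.5 * lj
            if d[j] != UNKNOWN:
                pending[d[j]] = pending.get(d[j], 0.0) + 0.5 * lj
        F[i] = aii - 1.0
    return F


def mendelian_variance_scale(ped: Pedigree, F: np.ndarray = None) -> np.ndarray:
    """Within-family (Mendelian sampling) variance multipliers d_i.

    d_i = 0.5 - 0.25 (F_s + F_d) with both parents known, 0.75 - 0.25 F_p
    with one, and 1 for founders; A = (I-T)^-1 D (I-T)^-T with D = diag(d).
    """
    if F is None:
        F = inbreeding_coefficients(ped)
    n = len(ped)
    s, d = ped.sire, ped.dam
    out = np.ones(n)
    both = (s != UNKNOWN) & (d != UNKNOWN)
    out[both] = 0.5 - 0.25 * (F[s[both]] + F[d[both]])
    sire_only = (s != UNKNOWN) & (d == UNKNOWN)
    out[sire_only] = 0.75 - 0.25 * F[s[sire_only]]
    dam_only = (s == UNKNOWN) & (d != UNKNOWN)
    out[dam_only] = 0.75 - 0.25 * F[d[dam_only]]
    return out


def build_A_inverse(ped: Pedigree, return_logdet: bool = False):
    """Sparse A^-1 by Henderson's rules with Meuwissen–Luo inbreeding.

    For each individual i with parents s, d and Mendelian variance d_i,
    A^-1 gains 1/d_i at (i,i), -1/(2 d_i) at (i,parent) and 1/(4 d_i) at
    (parent,parent') entries. Optionally also returns
    log|A| = sum_i log d_i.
    """
    n = len(ped)
    F = inbreeding_coefficients(ped)
    dvec = mendelian_variance_scale(ped, F)
    rows, cols, vals = [], [], []
    s, d = ped.sire, ped.dam
    for i in range(n):
        w = 1.0 / dvec[i]
        parents = [p for p in (s[i], d[i]) if p != UNKNOWN]
        rows.append(i); cols.append(i); vals.append(w)
        for p in parents:
            rows += [i, p]; cols += [p, i]; vals += [-0.5 * w, -0.5 * w]
        for p in parents:
            for q in parents:
                rows.append(p); cols.append(q); vals.append(0.25 * w)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    if return_logdet:
        return Ainv, float(np.sum(np.log(dvec)))
    return Ainv


def relationship_factor(ped: Pedigree):
    """Sparse (I - T) and D^(1/2) such that A = (I-T)^-1 D (I-T)^-T.

    T holds 0.5 at (offspring, parent). Lets A·x be computed with two
    sparse triangular solves, used by the AI-REML derivative machinery.
    """
    n = len(ped)
    dvec = mendelian_variance_scale(ped)
    rows, cols, vals = list(range(n)), list(range(n)), [1.0] * n
    for i in range(n):
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                rows.append(i); cols.append(p); vals.append(-0.5)
    I_minus_T = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return I_minus_T, dvec


def A_matvec(I_minus_T, dvec, x: np.ndarray) -> np.ndarray:
    """Compute A @ x via triangular solves with the pedigree factor."""
    from scipy.sparse.linalg import spsolve_triangular

    z = spsolve_triangular(
        I_minus_T.T.tocsr(), np.asarray(x, dtype=float), lower=False
    )
    if z.ndim == 1:
        z = z * dvec
    else:
        z = z * dvec[:, None]
    return spsolve_triangular(I_minus_T.tocsr(), z, lower=True)


# ---------------------------------------------------------------------------
# Family structure


@dataclass
class FamilyMap:
    family_of: pd.Series     # id -> family label ("" if a parent is unknown)
    sire_of: pd.Series
    dam_of: pd.Series
    n_families: int
    n_sires: int
    n_dams: int
    family_sizes: pd.Series

    def families_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": self.family_sizes.index,
                "size": self.family_sizes.to_numpy(),
            }
        )


def family_structure(ped: Pedigree) -> FamilyMap:
    """Full-sib family map: two individuals share a family iff they share
    both (known) parents. Individuals with an unknown parent get no family.
    """
    s, d = ped.sire, ped.dam
    both = (s != UNKNOWN) & (d != UNKNOWN)
    fam = np.full(len(ped), "", dtype=object)
    sire_ids = np.full(len(ped), "", dtype=object)
    dam_ids = np.full(len(ped), "", dtype=object)
    sire_ids[both] = ped.ids[s[both]]
    dam_ids[both] = ped.ids[d[both]]
    fam[both] = [
        f"{a}x{b}" for a, b in zip(sire_ids[both], dam_ids[both])
    ]
    idx = pd.Index(ped.ids, name="id")
    fam_s = pd.Series(fam, index=idx, name="family")
    sizes = fam_s[both].value_counts().sort_index()
    return FamilyMap(
        family_of=fam_s,
        sire_of=pd.Series(sire_ids, index=idx, name="sire"),
        dam_of=pd.Series(dam_ids, index=idx, name="dam"),
        n_families=int(len(sizes)),
        n_sires=int(pd.unique(sire_ids[both]).size),
        n_dams=int(pd.unique(dam_ids[both]).size),
        family_sizes=sizes,
    )


def prune_pedigree(ped: Pedigree, keep_ids) -> Pedigree:
    """Restrict to the given individuals plus all their ancestors.

    Standard practice before building mixed-model equations: individuals
    with no phenotype and no phenotyped descendants contribute nothing.
    """
    keep = np.zeros(len(ped), dtype=bool)
    keep[ped.positions(list(keep_ids))] = True
    for i in range(len(ped) - 1, -1, -1):
        if keep[i]:
            for p in (ped.sire[i], ped.dam[i]):
                if p != UNKNOWN:
                    keep[p] = True
    old_pos = np.flatnonzero(keep)
    remap = {o: n for n, o in enumerate(old_pos)}

    def remap_parents(arr):
        out = np.full(len(old_pos), UNKNOWN, dtype=np.int64)
        for n_, o in enumerate(old_pos):
            if arr[o] != UNKNOWN:
                out[n_] = remap[arr[o]]
        return out

    return Pedigree(
        ids=ped.ids[old_pos],
        sire=remap_parents(ped.sire),
        dam=remap_parents(ped.dam),
        sex=ped.sex[old_pos],
    )


def write_A_inverse_mtx(Ainv: sp.spmatrix, path) -> None:
    """Export A^-1 in MatrixMarket coordinate format."""
    from scipy.io import mmwrite

    mmwrite(str(path), sp.coo_matrix(Ainv))
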