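"""Relationship structures for single-step evaluation.

Builds the inbreeding-aware sparse A-inverse from a (possibly truncated)
pedigree, phantom parent groups with their QP-transformed A*, the genomic
relationship matrix after quality control, the pedigree relationships among
genotyped animals (A22, by Colleau's indirect method), and the assembled
single-step H* used in the mixed-model equations.

Pedigree tables are pandas DataFrames with columns ``animal``, ``sire``,
``dam`` (0/NaN/'' mean unknown) and, where relevant, ``sex``,
``birth_date``, ``herd`` and ``breed_*`` fraction columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._kernels import a_matvec, inbreeding_ml

__all__ = [
    "PedigreeCodes",
    "PhantomGroupMap",
    "RelationshipSet",
    "order_pedigree",
    "truncate_pedigree",
    "assign_phantom_parents",
    "compute_inbreeding_and_A_inverse",
    "build_A22",
    "genotype_qc",
    "build_G",
    "build_H_star",
    "build_relationships",
]


def _unknown_mask(col: pd.Series) -> pd.Series:
    s = col.astype("object")
    return s.isna() | s.isin([0, "0", "", None])


@dataclass
class PedigreeCodes:
    """Positional encoding of a pedigree, parents before offspring."""

    ids: np.ndarray          # animal ids in topological order
    sire: np.ndarray         # int64 positional index, -1 unknown
    dam: np.ndarray
    index: dict              # id -> position

    @property
    def n(self) -> int:
        return self.ids.size

    def positions(self, ids) -> np.ndarray:
        return np.asarray([self.index[i] for i in ids], dtype=np.int64)


class PedigreeCycleError(ValueError):
    """Raised when an animal is its own ancestor; carries the chain."""

    def __init__(self, chain):
        self.chain = list(chain)
        super().__init__(f"pedigree cycle: {' -> '.join(map(str, self.chain))}")


def order_pedigree(ped: pd.DataFrame) -> PedigreeCodes:
    """Topologically sort the pedigree and encode parents positionally.

    Parents referenced but absent from the ``animal`` column are added as
    founders.  Raises :class:`PedigreeCycleError` on a cycle.
    """
    animals = list(ped["animal"])
    sire_map, dam_map = {}, {}
    for a, s, d in zip(ped["animal"], ped["sire"], ped["dam"]):
        sire_map[a] = s
        dam_map[a] = d
    known = set(animals)
    su, du = _unknown_mask(ped["sire"]), _unknown_mask(ped["dam"])
    parents = set(ped.loc[~su, "sire"]) | set(ped.loc[~du, "dam"])
    for p in parents - known:
        animals.append(p)
        sire_map[p] = None
        dam_map[p] = None
    # Kahn's algorithm, stable in input order.
    def _par(a):
        out = []
        for m in (sire_map, dam_map):
            v = m.get(a)
            if v is not None and not (isinstance(v, float) and np.isnan(v)) \
                    and v not in (0, "0", ""):
                out.append(v)
        return out

    order: list = []
    state: dict = {}  # 0 in-progress, 1 done

    for a0 in animals:
        if state.get(a0) == 1:
            continue
        stack = [(a0, iter(_par(a0)))]
        state[a0] = 0
        path = [a0]
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                st = state.get(p)
                if st == 0:
                    raise PedigreeCycleError(path + [p])
                if st is None:
                    state[p] = 0
                    stack.append((p, iter(_par(p))))
                    path.append(p)
                    advanced = True
                    break
            if not advanced:
                order.append(node)
                state[node] = 1
                stack.pop()
                path.pop()

    index = {a: i for i, a in enumerate(order)}
    n = len(order)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for a in order:
        i = index[a]
        for arr, m in ((sire, sire_map), (dam, dam_map)):
            v = m.get(a)
            if v is not None and not (isinstance(v, float) and np.isnan(v)) \
                    and v not in (0, "0", ""):
                arr[i] = index[v]
    return PedigreeCodes(ids=np.asarray(order, dtype=object), sire=sire,
                         dam=dam, index=index)


def truncate_pedigree(ped: pd.DataFrame, phenotyped, n_gen: int = 5) -> pd.DataFrame:
    """Keep phenotyped animals plus ancestors within ``n_gen`` parent hops."""
    phenotyped = set(phenotyped)
    if not phenotyped:
        raise ValueError("phenotyped set is empty")
    sire_map = dict(zip(ped["animal"], ped["sire"]))
    dam_map = dict(zip(ped["animal"], ped["dam"]))

    def _known(v):
        return v is not None and not (isinstance(v, float) and np.isnan(v)) \
            and v not in (0, "0", "")

    keep = set(phenotyped)
    frontier = set(phenotyped)
    for _ in range(n_gen):
        nxt = set()
        for a in frontier:
            for m in (sire_map, dam_map):
                v = m.get(a)
                if _known(v) and v not in keep:
                    nxt.add(v)
        keep |= nxt
        frontier = nxt
    out = ped[ped["animal"].isin(keep)].copy()
    # sever parent links pointing outside the kept set
    for col in ("sire", "dam"):
        out.loc[~out[col].isin(keep), col] = 0
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# phantom parent groups


@dataclass
class PhantomGroupMap:
    """Assignment of unknown-parent slots to phantom parent groups.

    Groups are keyed by (birth-year bin, sex of the missing parent, breed
    label of the progeny); ``slot_to_group`` maps ``(animal, 'sire'|'dam')``
    to a group position.
    """

    labels: list = field(default_factory=list)
    slot_to_group: dict = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def parent_arrays(self, codes: PedigreeCodes):
        """sire/dam arrays with unknown slots re-pointed at group columns
        (indices ``codes.n + g``)."""
        sire = codes.sire.copy()
        dam = codes.dam.copy()
        for (animal, slot), g in self.slot_to_group.items():
            i = codes.index[animal]
            if slot == "sire":
                sire[i] = codes.n + g
            else:
                dam[i] = codes.n + g
        return sire, dam

    def q_matrix(self, codes: PedigreeCodes) -> np.ndarray:
        """Expected genome fraction of each animal from each group (n x g)."""
        n, g = codes.n, self.n_groups
        Q = np.zeros((n, g))
        sire, dam = self.parent_arrays(codes)
        for i in range(n):
            for p in (sire[i], dam[i]):
                if p < 0:
                    continue
                if p >= n:
                    Q[i, p - n] += 0.5
                else:
                    Q[i] += 0.5 * Q[p]
        return Q


def dominant_breed(ped: pd.DataFrame) -> pd.Series:
    """Label each animal with its largest breed fraction (ties by column
    order); 'unknown' if no breed columns or all-zero fractions."""
    cols = [c for c in ped.columns if c.startswith("breed_")]
    if not cols:
        return pd.Series("unknown", index=ped["animal"].values)
    fr = ped[cols].fillna(0.0).to_numpy()
    lab = np.asarray([c[len("breed_"):] for c in cols], dtype=object)
    out = np.where(fr.sum(axis=1) > 0, lab[fr.argmax(axis=1)], "unknown")
    return pd.Series(out, index=ped["animal"].values)


def assign_phantom_parents(ped: pd.DataFrame, year_bin: int = 1) -> PhantomGroupMap:
    """Map every unknown-parent slot to a phantom parent group.

    Group key: (birth-year bin of the progeny, missing parent's sex,
    progeny's dominant breed).  Animals with unknown breed fall into the
    'unknown' catch-all breed label.
    """
    breed = dominant_breed(ped)
    years = pd.to_datetime(ped["birth_date"]).dt.year if "birth_date" in ped \
        else pd.Series(0, index=ped.index)
    gmap = PhantomGroupMap()
    key_to_pos: dict = {}
    su, du = _unknown_mask(ped["sire"]), _unknown_mask(ped["dam"])
    for row, a in enumerate(ped["animal"]):
        yb = int(years.iloc[row]) // year_bin * year_bin
        for slot, unknown, sex in (("sire", su.iloc[row], "M"),
                                   ("dam", du.iloc[row], "F")):
            if not unknown:
                continue
            key = (yb, sex, breed.loc[a])
            if key not in key_to_pos:
                key_to_pos[key] = len(gmap.labels)
                gmap.labels.append(key)
            gmap.slot_to_group[(a, slot)] = key_to_pos[key]
    return gmap


# ---------------------------------------------------------------------------
# A-inverse and A22


def compute_inbreeding_and_A_inverse(ped: pd.DataFrame,
                                     groups: PhantomGroupMap | None = None):
    """Meuwissen-Luo inbreeding plus Henderson's sparse A-inverse.

    With ``groups`` the unknown-parent slots point at phantom-group columns
    and the result is the QP-transformed A* of size (n + n_groups); phantom
    groups enter Henderson's rules as parents with F = -1, so they never
    reduce Mendelian-sampling variance.

    Returns ``(F, A_inv, codes)``.
    """
    codes = order_pedigree(ped)
    F, D = inbreeding_ml(codes.sire, codes.dam)
    n = codes.n
    if groups is not None:
        sire, dam = groups.parent_arrays(codes)
        size = n + groups.n_groups
    else:
        sire, dam = codes.sire, codes.dam
        size = n
    rows, cols, vals = [], [], []
    for i in range(n):
        alpha = 1.0 / D[i]
        rows.append(i); cols.append(i); vals.append(alpha)
        pars = [p for p in (sire[i], dam[i]) if p >= 0]
        for p in pars:
            rows += [i, p]; cols += [p, i]; vals += [-alpha / 2.0] * 2
        for p in pars:
            for q in pars:
                rows.append(p); cols.append(q); vals.append(alpha / 4.0)
    a_inv = sp.coo_matrix((vals, (rows, cols)), shape=(size, size)).tocsr()
    return pd.Series(F, index=codes.ids), a_inv, codes


def build_A22(codes: PedigreeCodes, genotyped_ids) -> np.ndarray:
    """Pedigree relationships among genotyped animals via Colleau matvecs."""
    _, D = inbreeding_ml(codes.sire, codes.dam)
    pos = codes.positions(genotyped_ids)
    g = pos.size
    A22 = np.empty((g, g))
    for j, pj in enumerate(pos):
        e = np.zeros(codes.n)
        e[pj] = 1.0
        col = a_matvec(codes.sire, codes.dam, D, e)
        A22[:, j] = col[pos]
    return 0.5 * (A22 + A22.T)


# ---------------------------------------------------------------------------
# genotypes


def genotype_qc(geno: pd.DataFrame, snp_map: pd.DataFrame | None = None, *,
                dup_overlap: float = 0.98, call_rate: float = 0.90,
                het_bounds: tuple = (0.20, 0.80), maf_min: float = 0.05,
                phenotype_counts: pd.Series | None = None):
    """Quality control of a 0/1/2/NaN genotype matrix (animals x SNPs).

    Rules run in order: duplicate genotypes (concordance > ``dup_overlap``,
    keeping the animal with more phenotype records then the lower id),
    animal and SNP call rate < ``call_rate``, animal heterozygosity outside
    ``het_bounds``, minor allele frequency < ``maf_min`` (strict), and SNPs
    without a mapped location.  Idempotent.  Returns (filtered, report).
    """
    report: dict = {}
    g = geno.copy()

    # 1) duplicates
    X = g.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    match = np.zeros((len(g), len(g)))
    for val in (0.0, 1.0, 2.0):
        ind = np.where(obs & (X == val), 1.0, 0.0)
        match += ind @ ind.T
    joint = obs.astype(float) @ obs.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(joint > 0, match / joint, 0.0)
    drop: set = set()
    ids = list(g.index)
    ii, jj = np.where(np.triu(conc, 1) > dup_overlap)
    for i, j in zip(ii, jj):
        a, b = ids[i], ids[j]
        if a in drop or b in drop:
            continue
        if phenotype_counts is not None:
            ca = phenotype_counts.get(a, 0)
            cb = phenotype_counts.get(b, 0)
            if ca != cb:
                drop.add(a if ca < cb else b)
                continue
        drop.add(max(a, b, key=str))
    report["duplicate_animals"] = len(drop)
    g = g.drop(index=list(drop))

    # 2) call rate
    acr = g.notna().mean(axis=1)
    bad_a = acr[acr < call_rate].index
    report["animal_call_rate"] = len(bad_a)
    g = g.drop(index=bad_a)
    scr = g.notna().mean(axis=0)
    bad_s = scr[scr < call_rate].index
    report["snp_call_rate"] = len(bad_s)
    g = g.drop(columns=bad_s)

    # 3) heterozygosity (per animal)
    het = (g == 1).sum(axis=1) / g.notna().sum(axis=1).clip(lower=1)
    bad_h = het[(het < het_bounds[0]) | (het > het_bounds[1])].index
    report["heterozygosity"] = len(bad_h)
    g = g.drop(index=bad_h)

    # 4) MAF (strict <)
    p = g.mean(axis=0, skipna=True) / 2.0
    maf = np.minimum(p, 1.0 - p)
    bad_m = maf[maf < maf_min].index
    report["maf"] = len(bad_m)
    g = g.drop(columns=bad_m)

    # 5) unmapped SNPs
    if snp_map is not None:
        chrom = snp_map.reindex(g.columns)["chrom"]
        unmapped = chrom.isna() | (chrom.astype(float) == 0)
        report["unmapped"] = int(unmapped.sum())
        g = g.drop(columns=g.columns[unmapped.to_numpy()])
    else:
        report["unmapped"] = 0

    if g.shape[1] == 0:
        raise ValueError("genotype QC removed every SNP; check thresholds")
    if len(g) == 0:
        raise ValueError("genotype QC removed every animal; check thresholds")
    report["animals_left"] = len(g)
    report["snps_left"] = g.shape[1]
    return g, report


def build_G(geno: pd.DataFrame, allele_freqs=None) -> pd.DataFrame:
    """VanRaden method-1 genomic relationship matrix.

    Residual missing calls are mean-imputed; monomorphic SNPs are dropped
    before scaling.  Allele frequencies come from the genotyped set itself
    unless ``allele_freqs`` supplies external (e.g. base-population) ones.
    """
    M = geno.to_numpy(dtype=float)
    p = np.asarray(allele_freqs, dtype=float) if allele_freqs is not None \
        else np.nanmean(M, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    M = M[:, poly]
    p = p[poly]
    if M.shape[1] == 0:
        raise ValueError("no polymorphic SNPs available for G")
    inds = np.where(np.isnan(M))
    M[inds] = (2.0 * p)[inds[1]]
    Z = M - 2.0 * p
    scale = 2.0 * np.sum(p * (1.0 - p))
    G = (Z @ Z.T) / scale
    return pd.DataFrame(G, index=geno.index, columns=geno.index)


def blend_G(G: np.ndarray, A22: np.ndarray, weight: float = 0.95) -> np.ndarray:
    """weight*G + (1-weight)*A22; guarantees an invertible genomic matrix."""
    return weight * np.asarray(G) + (1.0 - weight) * np.asarray(A22)


# ---------------------------------------------------------------------------
# H*


def build_H_star(a_star: sp.spmatrix, genotyped_pos: np.ndarray,
                 G_inv: np.ndarray, A22_inv: np.ndarray,
                 Q2: np.ndarray | None = None, n_groups: int = 0,
                 tau: float = 1.0, omega: float = 1.0) -> sp.csr_matrix:
    """Assemble the PPG-modified single-step precision structure.

    ``a_star`` is A-inverse (or the QP-transformed A* with ``n_groups``
    trailing group columns), ``genotyped_pos`` the positions of genotyped
    animals within the animal block.  The genomic correction uses the
    difference form ``tau*G_inv - omega*A22_inv``; with phantom groups the
    corrections ``-delta@Q2`` / ``Q2'@delta@Q2`` keep group solutions
    consistent with the genomic block.
    """
    size = a_star.shape[0]
    delta = tau * np.asarray(G_inv) - omega * np.asarray(A22_inv)
    g = genotyped_pos.size
    if g == 0:
        return sp.csr_matrix(a_star)
    rows = np.repeat(genotyped_pos, g)
    cols = np.tile(genotyped_pos, g)
    H = sp.csr_matrix(a_star, copy=True) + sp.coo_matrix(
        (delta.ravel(), (rows, cols)), shape=(size, size)).tocsr()
    if n_groups and Q2 is not None:
        gp = np.arange(size - n_groups, size)
        dq = delta @ Q2
        qdq = Q2.T @ dq
        r2 = np.concatenate([np.repeat(genotyped_pos, n_groups),
                             np.repeat(gp, g),
                             np.repeat(gp, n_groups)])
        c2 = np.concatenate([np.tile(gp, g),
                             np.tile(genotyped_pos, n_groups),
                             np.tile(gp, n_groups)])
        v2 = np.concatenate([-dq.ravel(), -dq.T.ravel(), qdq.ravel()])
        H = H + sp.coo_matrix((v2, (r2, c2)), shape=(size, size)).tocsr()
    return H


def save_sparse_coo(path: str, mat: sp.spmatrix, ids=None) -> None:
    """Persist a sparse matrix as text triples (row, col, value); when
    ``ids`` is given, an ``<path>.index`` file maps ids to equation
    numbers."""
    coo = sp.coo_matrix(mat)
    with open(path, "w") as fh:
        fh.write(f"# shape {coo.shape[0]} {coo.shape[1]}\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r} {c} {float(v)!r}\n")
    if ids is not None:
        with open(path + ".index", "w") as fh:
            for eq, aid in enumerate(ids):
                fh.write(f"{aid}\t{eq}\n")


def load_sparse_coo(path: str) -> sp.csr_matrix:
    with open(path) as fh:
        header = fh.readline().split()
        shape = (int(header[2]), int(header[3]))
        rows, cols, vals = [], [], []
        for line in fh:
            r, c, v = line.split()
            rows.append(int(r))
            cols.append(int(c))
            vals.append(float(v))
    return sp.coo_matrix((vals, (rows, cols)), shape=shape).tocsr()


@dataclass
class RelationshipSet:
    """All relationship pieces needed by the single-step equations."""

    codes: PedigreeCodes
    F: pd.Series
    a_star: sp.csr_matrix           # A-inverse, or QP-transformed A*
    groups: PhantomGroupMap | None
    genotyped_ids: np.ndarray
    G_inv: np.ndarray | None
    A22_inv: np.ndarray | None
    Q2: np.ndarray | None
    tau: float
    omega: float
    h_star: sp.csr_matrix

    @property
    def n_animals(self) -> int:
        return self.codes.n

    @property
    def n_groups(self) -> int:
        return self.groups.n_groups if self.groups is not None else 0


def build_relationships(ped: pd.DataFrame, geno: pd.DataFrame | None = None,
                        snp_map: pd.DataFrame | None = None, *,
                        use_groups: bool = True, year_bin: int = 1,
                        tau: float = 1.0, omega: float = 1.0,
                        blend_weight: float = 0.95,
                        qc: bool = True) -> RelationshipSet:
    """One-call assembly: A*, genotype QC, G, A22 and H*."""
    groups = assign_phantom_parents(ped, year_bin=year_bin) if use_groups else None
    if groups is not None and groups.n_groups == 0:
        groups = None
    F, a_star, codes = compute_inbreeding_and_A_inverse(ped, groups)
    if geno is None or len(geno) == 0:
        return RelationshipSet(codes, F, a_star, groups,
                               np.asarray([], dtype=object), None, None, None,
                               tau, omega, sp.csr_matrix(a_star))
    if qc:
        try:
            geno, _ = genotype_qc(geno, snp_map)
        except ValueError:
            # uninformative panel: fall back to the pedigree-only evaluation
            import warnings
            warnings.warn("genotype QC removed every SNP; "
                          "falling back to pedigree-only relationships")
            return RelationshipSet(codes, F, a_star, groups,
                                   np.asarray([], dtype=object), None, None,
                                   None, tau, omega, sp.csr_matrix(a_star))
    geno = geno.loc[[i for i in geno.index if i in codes.index]]
    gids = np.asarray(geno.index, dtype=object)
    A22 = build_A22(codes, gids)
    G = blend_G(build_G(geno).to_numpy(), A22, blend_weight)
    try:
        G_inv = np.linalg.inv(G)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "genomic matrix is singular; increase the blending weight on A22"
        ) from err
    A22_inv = np.linalg.inv(A22)
    pos = codes.positions(gids)
    Q2 = None
    if groups is not None:
        Q2 = groups.q_matrix(codes)[pos]
    h_star = build_H_star(a_star, pos, G_inv, A22_inv, Q2,
                          groups.n_groups if groups else 0, tau, omega)
    return RelationshipSet(codes, F, a_star, groups, gids, G_inv, A22_inv,
                           Q2, tau, omega, h_star)
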