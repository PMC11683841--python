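"""Single-step prediction and validation.

Solves the mixed-model equations with the H* precision structure by
preconditioned conjugate gradients (Jacobi preconditioner, rolling-average
squared-relative-residual stopping in the style of iteration-on-data
solvers), rescales EBV to the number-of-calves unit by linear regression
on opportunity cows, and runs the modified forward validation where the
evaluation is repeated on year-truncated data and compared with the final
run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import pearsonr, spearmanr

from . import phenotypes, relmat
from .bayes import _fixed_design, _hstack_csc, _level_design

__all__ = [
    "EvaluationResult",
    "ValidationReport",
    "solve_ssgblup",
    "ebv_to_calves",
    "compute_epd",
    "precorrect_phenotypes",
    "forward_validate",
    "compare_models",
    "overlap_percentage",
]

log = logging.getLogger(__name__)

MIN_SQ_TOL = 1e-24  # squared relative residual ~ (1e-12)^2


@dataclass
class EvaluationResult:
    ebv: pd.Series                      # per-animal EBV (RRM: at parity 8)
    fixed: pd.Series
    pe: pd.Series
    cg: pd.Series
    groups: pd.Series | None
    iterations: int
    converged: bool
    final_eps: float
    ebv_intercept: pd.Series | None = None
    ebv_slope: pd.Series | None = None
    fixed_names: list = field(default_factory=list)

    def ebv_at(self, parity: float) -> pd.Series:
        if self.ebv_intercept is None:
            return self.ebv
        return self.ebv_intercept + parity * self.ebv_slope


def _pcg(C: sp.csr_matrix, b: np.ndarray, tol: float, max_iter: int,
         window: int = 50):
    """Jacobi-preconditioned CG; stops when the rolling mean over
    ``window`` rounds of ||b - Cx||^2 / ||b||^2 drops below ``tol``."""
    d = C.diagonal()
    minv = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
    x = np.zeros_like(b)
    r = b.copy()
    z = minv * r
    p = z.copy()
    rz = r @ z
    b2 = b @ b
    if b2 == 0:
        return x, 0, True, 0.0
    hist: list = []
    it = 0
    for it in range(1, max_iter + 1):
        Cp = C @ p
        denom = p @ Cp
        if denom <= 0:
            break
        alpha = rz / denom
        x += alpha * p
        r -= alpha * Cp
        eps = (r @ r) / b2
        hist.append(eps)
        if len(hist) >= window and float(np.mean(hist[-window:])) < tol:
            return x, it, True, eps
        if eps < tol / window:   # early exit well below threshold
            return x, it, True, eps
        z = minv * r
        rz_new = r @ z
        p = z + (rz_new / rz) * p
        rz = rz_new
    return x, it, False, hist[-1] if hist else np.inf


def solve_ssgblup(records: pd.DataFrame, h_star: sp.spmatrix, animal_ids,
                  variances: dict, *, n_groups: int = 0, model: str = "rep",
                  response: str = "y", tol: float = 1e-18,
                  max_iter: int = 5000) -> EvaluationResult:
    """Solve the single-step mixed-model equations.

    ``h_star`` spans the animal block plus ``n_groups`` trailing phantom
    group equations.  ``variances``: for the repeatability model keys
    ``u``, ``p``, ``c``, ``e``; for ``model='rrm'`` 2x2 arrays ``G_u``,
    ``G_p``, ``G_c`` plus ``e``.  QP-transformed group equations mean the
    animal solutions already include their group means, so ``ebv`` is
    directly comparable across animals.
    """
    if tol < MIN_SQ_TOL:
        warnings.warn(f"tolerance {tol:g} below double-precision reach; "
                      f"clamped to {MIN_SQ_TOL:g}")
        tol = MIN_SQ_TOL
    if response not in records:
        response = "success"
    y = records[response].to_numpy(dtype=float)
    animal_ids = list(animal_ids)
    n_u = len(animal_ids)
    if h_star.shape[0] != n_u + n_groups:
        raise ValueError("h_star size does not match animals + groups")
    cows = sorted(records["cow"].unique(), key=str)
    cgs = sorted(records["cg"].unique(), key=str)
    Wf, fixed_names = _fixed_design(records)
    nf = Wf.shape[1]
    var_e = float(variances["e"])
    n_p, n_c = len(cows), len(cgs)

    if model == "rep":
        Wu = _level_design(records["cow"], animal_ids)
        pad = sp.coo_matrix((len(records), n_groups))
        W = _hstack_csc([Wf, Wu, pad,
                         _level_design(records["cow"], cows),
                         _level_design(records["cg"], cgs)])
        prior = sp.block_diag([
            sp.coo_matrix((nf, nf)),
            sp.csr_matrix(h_star) * (var_e / float(variances["u"])),
            sp.identity(n_p) * (var_e / float(variances["p"])),
            sp.identity(n_c) * (var_e / float(variances["c"])),
        ]).tocsr()
        u_dim = n_u + n_groups
    elif model == "rrm":
        t = records["parity"].to_numpy(dtype=float)

        def _pair(values, levels):
            base = _level_design(values, levels).tocoo()
            rows = np.repeat(base.row, 2)
            cols = np.empty(rows.size, dtype=np.int64)
            cols[0::2] = 2 * base.col
            cols[1::2] = 2 * base.col + 1
            vals = np.empty(rows.size)
            vals[0::2] = 1.0
            vals[1::2] = t[base.row]
            return sp.coo_matrix((vals, (rows, cols)),
                                 shape=(len(values), 2 * len(levels)))

        pad = sp.coo_matrix((len(records), 2 * n_groups))
        W = _hstack_csc([Wf, _pair(records["cow"], animal_ids), pad,
                         _pair(records["cow"], cows),
                         _pair(records["cg"], cgs)])
        prior = sp.block_diag([
            sp.coo_matrix((nf, nf)),
            sp.kron(sp.csr_matrix(h_star),
                    np.linalg.inv(variances["G_u"])) * var_e,
            sp.kron(sp.identity(n_p),
                    np.linalg.inv(variances["G_p"])) * var_e,
            sp.kron(sp.identity(n_c),
                    np.linalg.inv(variances["G_c"])) * var_e,
        ]).tocsr()
        u_dim = 2 * (n_u + n_groups)
    else:
        raise ValueError(f"unknown model {model!r}")

    C = (W.T @ W).tocsr() + prior
    rhs = W.T @ y
    x, its, conv, eps = _pcg(C, rhs, tol, max_iter)
    if not conv:
        warnings.warn(f"PCG did not converge in {its} iterations "
                      f"(eps={eps:g}); returning best solution")

    fixed = pd.Series(x[:nf], index=fixed_names)
    if model == "rep":
        u = pd.Series(x[nf:nf + n_u], index=animal_ids, name="ebv")
        grp = pd.Series(x[nf + n_u:nf + n_u + n_groups]) if n_groups else None
        off = nf + n_u + n_groups
        pe = pd.Series(x[off:off + n_p], index=cows)
        cg = pd.Series(x[off + n_p:off + n_p + n_c], index=cgs)
        return EvaluationResult(u, fixed, pe, cg, grp, its, conv, eps,
                                fixed_names=fixed_names)
    blk = x[nf:nf + 2 * n_u].reshape(n_u, 2)
    icpt = pd.Series(blk[:, 0], index=animal_ids)
    slope = pd.Series(blk[:, 1], index=animal_ids)
    off = nf + u_dim
    pe = pd.Series(x[off:off + 2 * n_p:2], index=cows)
    cg = pd.Series(x[off + 2 * n_p:off + 2 * n_p + 2 * n_c:2], index=cgs)
    grp = None
    if n_groups:
        gblk = x[nf + 2 * n_u:nf + u_dim].reshape(n_groups, 2)
        grp = pd.Series(gblk[:, 0])
    ebv8 = icpt + 8.0 * slope
    ebv8.name = "ebv"
    return EvaluationResult(ebv8, fixed, pe, cg, grp, its, conv, eps,
                            ebv_intercept=icpt, ebv_slope=slope,
                            fixed_names=fixed_names)


def ebv_to_calves(ebv: pd.Series, calf_counts: pd.Series):
    """OLS of observed calf count on EBV over opportunity cows.

    Returns ``(b0, b1, ebv_nc)`` with the affine map applied to every
    animal in ``ebv``.
    """
    common = ebv.index.intersection(calf_counts.index)
    if len(common) < 2:
        raise ValueError("need at least two opportunity cows")
    x = ebv.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("EBV has zero variance among opportunity cows")
    yv = calf_counts.loc[common].to_numpy(dtype=float)
    b1, b0 = np.polyfit(x, yv, 1)
    return float(b0), float(b1), b0 + b1 * ebv


def compute_epd(ebv_nc: pd.Series, base: float = 0.0) -> pd.Series:
    """Expected progeny difference: half the EBV deviation from ``base``."""
    return (ebv_nc - base) / 2.0


def precorrect_phenotypes(counts: pd.Series, fixed_contrib: pd.Series,
                          ) -> pd.Series:
    """Subtract estimated nongenetic fixed contributions from raw counts,
    re-centering to the raw mean.  Cows without a contribution are dropped
    (logged)."""
    contrib = fixed_contrib.reindex(counts.index)
    missing = contrib.isna()
    if missing.any():
        log.info("precorrect: dropping %d cows without fixed-effect "
                 "covariates", int(missing.sum()))
    kept = counts[~missing]
    adj = kept - contrib[~missing]
    return adj + (kept.mean() - adj.mean())


def fixed_contributions(records: pd.DataFrame, fixed: pd.Series) -> pd.Series:
    """Per-cow sum of fitted fixed-effect contributions over her records."""
    Wf, names = _fixed_design(records)
    b = fixed.reindex(names).fillna(0.0).to_numpy()
    per_record = np.asarray(Wf.tocsr() @ b).ravel()
    return pd.Series(per_record, index=records["cow"].values).groupby(
        level=0).sum()


def calf_counts(records: pd.DataFrame) -> pd.Series:
    """Total calves per cow: the anchoring first calf plus later successes."""
    return records.groupby("cow")["success"].sum() + 1


ValidationReport = pd.DataFrame  # rows: truncation year, bias, correlations


def run_evaluation(pedigree: pd.DataFrame, calvings: pd.DataFrame,
                   data_end, variances: dict, *, model: str = "rep",
                   geno: pd.DataFrame | None = None,
                   snp_map: pd.DataFrame | None = None,
                   use_groups: bool = False, n_gen: int = 5,
                   edit_config=None, tol: float = 1e-18,
                   max_iter: int = 5000, keep_animals=None):
    """Pipeline: edits -> PL records -> relationships -> ssGBLUP solve.

    Returns ``(EvaluationResult | None, records)``; None when no records
    survive editing (pedigree/genomic-only scenario).  ``keep_animals``
    are retained in the pruned pedigree even without records, so e.g.
    validation candidates receive parent-average EBV.
    """
    rec, _ = phenotypes.build_pl_dataset(pedigree, calvings, data_end,
                                         edit_config)
    if rec.empty:
        return None, rec
    anchor = set(rec["cow"].unique())
    if keep_animals is not None:
        anchor |= set(keep_animals) & set(pedigree["animal"])
    ped = relmat.truncate_pedigree(pedigree, anchor, n_gen)
    if geno is not None:
        geno = geno.loc[geno.index.intersection(ped["animal"])]
    rel = relmat.build_relationships(ped, geno, snp_map,
                                     use_groups=use_groups)
    res = solve_ssgblup(rec, rel.h_star, list(rel.codes.ids), variances,
                        n_groups=rel.n_groups, model=model,
                        response="success", tol=tol, max_iter=max_iter)
    return res, rec


def forward_validate(pedigree: pd.DataFrame, calvings: pd.DataFrame,
                     variances: dict, validation_birth_year: int,
                     truncation_years, final_year: int, *,
                     geno: pd.DataFrame | None = None,
                     snp_map: pd.DataFrame | None = None,
                     model: str = "rep", use_groups: bool = False,
                     edit_config=None) -> ValidationReport:
    """Modified forward validation against the final evaluation.

    For each truncation year, all information from animals born after
    December 31 of that year is removed (pedigree, phenotype, genomic),
    the evaluation re-run, EBV rescaled to calves, and the validation
    cows' predictions correlated with their final observed and
    precorrected calf counts.  Bias is the slope of final-run EBV_NC
    regressed on truncated-run EBV_NC (slope < 1 reads as inflation).
    """
    ped = pedigree.copy()
    ped["_birth"] = pd.to_datetime(ped["birth_date"])
    cal = calvings.copy()
    cal["_date"] = pd.to_datetime(cal["calf_birth_date"])

    def _truncate(year):
        cutoff = pd.Timestamp(f"{year}-12-31")
        p = ped[ped["_birth"] <= cutoff].drop(columns="_birth").copy()
        keep = set(p["animal"])
        for col in ("sire", "dam"):
            p.loc[~p[col].isin(keep), col] = 0
        c = cal[(cal["_date"] <= cutoff) & cal["dam"].isin(keep)]
        g = geno.loc[geno.index.intersection(p["animal"])] \
            if geno is not None else None
        return p, c.drop(columns="_date"), g, cutoff

    ped_f, cal_f, geno_f, end_f = _truncate(final_year)
    final_res, final_rec = run_evaluation(
        ped_f, cal_f, end_f, variances, model=model, geno=geno_f,
        snp_map=snp_map, use_groups=use_groups, edit_config=edit_config)
    if final_res is None:
        raise ValueError("final evaluation has no records")
    counts = calf_counts(final_rec)
    pre = precorrect_phenotypes(
        counts, fixed_contributions(final_rec, final_res.fixed))
    byear = ped.set_index("animal")["_birth"].dt.year
    val_cows = [c for c in counts.index
                if byear.get(c) == validation_birth_year]
    if not val_cows:
        raise ValueError(f"no validation cows born {validation_birth_year} "
                         "with final records")
    opp_year = final_year - 9
    opp_cows = [c for c in counts.index if byear.get(c) <= opp_year]
    if len(opp_cows) < 2:
        opp_cows = list(counts.index)
    _, _, nc_final = ebv_to_calves(final_res.ebv, counts.loc[opp_cows])

    rows = []
    for year in truncation_years:
        p_t, c_t, g_t, end_t = _truncate(year)
        res_t, rec_t = run_evaluation(
            p_t, c_t, end_t, variances, model=model, geno=g_t,
            snp_map=snp_map, use_groups=use_groups, edit_config=edit_config,
            keep_animals=val_cows)
        if res_t is None:
            rows.append([year, np.nan, np.nan, np.nan, 0])
            continue
        try:
            cnt_t = calf_counts(rec_t)
            opp_t = [c for c in cnt_t.index if byear.get(c) <= year - 9]
            if len(opp_t) < 2:
                opp_t = list(cnt_t.index)
            _, _, nc_t = ebv_to_calves(res_t.ebv, cnt_t.loc[opp_t])
        except ValueError:
            nc_t = res_t.ebv
        avail = [c for c in val_cows if c in nc_t.index]
        if len(avail) < 3:
            rows.append([year, np.nan, np.nan, np.nan, len(avail)])
            continue
        x = nc_t.loc[avail].to_numpy(dtype=float)
        bias = np.nan
        if np.ptp(x) > 0:
            bias = float(np.polyfit(
                x, nc_final.loc[avail].to_numpy(dtype=float), 1)[0])
            r_pre = float(pearsonr(x, pre.loc[avail]).statistic)
            r_obs = float(pearsonr(x, counts.loc[avail]).statistic)
        else:
            r_pre = r_obs = np.nan
        rows.append([year, bias, r_pre, r_obs, len(avail)])
    return pd.DataFrame(rows, columns=["truncation_year", "bias",
                                       "r_precorrected", "r_observed",
                                       "n_validation"])


def overlap_percentage(n_common: int, n_top: int) -> float:
    """Share of the top set selected in common by both models, as %."""
    if n_top <= 0:
        raise ValueError("empty top set")
    return 100.0 * n_common / n_top


def compare_models(ebv_rep: pd.Series, ebv_rrm: pd.Series,
                   top_fraction: float = 0.01):
    """Spearman correlation plus top-fraction selection overlap (%).

    Raises on mismatched animal sets, listing the orphan ids.
    """
    orphans = ebv_rep.index.symmetric_difference(ebv_rrm.index)
    if len(orphans):
        raise ValueError(f"mismatched animal sets; orphans: "
                         f"{list(orphans[:10])}")
    rho = float(spearmanr(ebv_rep, ebv_rrm.reindex(ebv_rep.index)).statistic)
    k = max(int(round(top_fraction * len(ebv_rep))), 1)
    top_rep = set(ebv_rep.nlargest(k).index)
    top_rrm = set(ebv_rrm.nlargest(k).index)
    return rho, overlap_percentage(len(top_rep & top_rrm), k)
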