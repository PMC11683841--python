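"""Gibbs samplers for the repeatability and random-regression models.

Both samplers run single-site updates over all location effects inside a
numba kernel (one sweep per iteration, residual-updating form), then draw
variance components from their scaled-inverse-chi-square or inverse-Wishart
full conditionals.  Fixed effects get flat priors; contemporary group is a
random effect in both models.  The parity covariate is centered at 5
internally and reported on the raw 2..8 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import invwishart, norm

from ._kernels import gibbs_sweep_rep, gibbs_sweep_rrm

__all__ = [
    "GibbsConfig",
    "RepVariances",
    "RRCoefCov",
    "gibbs_rep",
    "gibbs_rrm",
    "geweke_diagnostic",
    "hpd_interval",
    "rr_variance_at_parity",
    "genetic_ratios",
]

PARITY_CENTER = 5.0


@dataclass
class GibbsConfig:
    n_iter: int = 100_000
    burn_in: int = 50_000
    thin: int = 50
    seed: int = 0
    prior_df: float = 4.0
    prior_scales: dict | None = None   # keys u, p, c, e; None -> from data

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def default_prior_scales(y: np.ndarray) -> dict:
    """Weakly informative: a quarter of Var(y), split equally 4 ways."""
    s = 0.25 * float(np.var(y)) / 4.0
    return {"u": s, "p": s, "c": s, "e": s}


def _fixed_design(records: pd.DataFrame):
    """Year-season class dummies plus centered AFC, parity and RH columns."""
    ys = records["year_season"].astype(str)
    levels = sorted(ys.unique())
    lut = {l: j for j, l in enumerate(levels)}
    n = len(records)
    rows = np.arange(n)
    cols_list = [ys.map(lut).to_numpy()]
    vals_list = [np.ones(n)]
    covs = []
    for name, center in (("afc", None), ("parity", PARITY_CENTER),
                         ("rh", None)):
        src = records["parity_cov"] if name == "parity" and "parity_cov" in records \
            else records[name]
        x = src.to_numpy(dtype=float)
        x = x - (float(np.mean(x)) if center is None else center)
        if np.ptp(x) > 0:
            covs.append((name, x))
    nf = len(levels) + len(covs)
    for j, (_, x) in enumerate(covs):
        cols_list.append(np.full(n, len(levels) + j))
        vals_list.append(x)
    W = sp.coo_matrix((np.concatenate(vals_list),
                       (np.tile(rows, 1 + len(covs)),
                        np.concatenate(cols_list))), shape=(n, nf))
    names = [f"ys_{l}" for l in levels] + [c for c, _ in covs]
    return W, names


def _level_design(values: pd.Series, levels) -> sp.coo_matrix:
    lut = {l: j for j, l in enumerate(levels)}
    n = len(values)
    return sp.coo_matrix((np.ones(n),
                          (np.arange(n), values.map(lut).to_numpy())),
                         shape=(n, len(levels)))


def _hstack_csc(blocks):
    W = sp.hstack(blocks).tocsc()
    W.sort_indices()
    return W


@dataclass
class RepVariances:
    chains: dict
    means: dict
    hpd: dict
    geweke_p: dict
    ratio_chains: dict
    ratio_means: dict
    ratio_hpd: dict
    location: dict
    config: GibbsConfig

    @property
    def n_retained(self) -> int:
        return len(next(iter(self.chains.values())))

    @property
    def ratio_of_means(self) -> dict:
        """Ratios of posterior-mean components (plug-in version); the
        per-draw ``ratio_means`` are the primary summaries."""
        return genetic_ratios(self.means["var_u"], self.means["var_p"],
                              self.means["var_c"], self.means["var_e"])

    def summary(self) -> pd.DataFrame:
        rows = []
        for k in self.chains:
            lo, hi = self.hpd[k]
            rows.append([k, self.means[k], lo, hi, self.geweke_p.get(k)])
        for k in self.ratio_chains:
            lo, hi = self.ratio_hpd[k]
            rows.append([k, self.ratio_means[k], lo, hi,
                         self.geweke_p.get(k)])
        return pd.DataFrame(rows, columns=["parameter", "mean", "hpd_lo",
                                           "hpd_hi", "geweke_p"])

    def save(self, chains_csv: str, summary_json: str | None = None) -> None:
        _save_chains({**self.chains, **self.ratio_chains}, chains_csv)
        if summary_json:
            _save_summary(self.summary(), summary_json)


def gibbs_rep(records: pd.DataFrame, a_inv: sp.spmatrix | None, animal_ids,
              config: GibbsConfig, response: str = "y",
              start_variances=None, fit_pe: bool = True,
              sample_variances: bool = True) -> RepVariances:
    """Repeatability animal model y = Xb + Zu*u + Zp*p + Zc*c + e.

    ``a_inv`` is the additive precision over ``animal_ids`` (records'
    cows must appear there); Gaussian records in ``records[response]``
    (falls back to the binary ``success`` column).  ``a_inv=None`` drops
    the animal effect, ``fit_pe=False`` the permanent-environment effect,
    and a missing ``cg`` column the contemporary-group effect — useful
    for reduced oracle models.  With ``sample_variances=False`` the
    variances stay fixed at ``start_variances``.
    """
    if response not in records:
        response = "success"
    y = records[response].to_numpy(dtype=float)
    n = y.size
    if n == 0:
        raise ValueError("no records")
    animal_ids = list(animal_ids) if animal_ids is not None else []
    n_u = len(animal_ids)
    if a_inv is None:
        a_inv = sp.csr_matrix((0, 0))
    if a_inv.shape[0] != n_u:
        raise ValueError("a_inv does not match animal_ids")
    cows = sorted(records["cow"].unique(), key=str) if fit_pe else []
    cgs = sorted(records["cg"].unique(), key=str) if "cg" in records else []
    Wf, fixed_names = _fixed_design(records)
    blocks = [Wf]
    if n_u:
        missing = set(records["cow"]) - set(animal_ids)
        if missing:
            raise ValueError(f"cows missing from pedigree index: "
                             f"{sorted(missing, key=str)[:5]}")
        blocks.append(_level_design(records["cow"], animal_ids))
    if cows:
        blocks.append(_level_design(records["cow"], cows))
    if cgs:
        blocks.append(_level_design(records["cg"], cgs))
    W = _hstack_csc(blocks)
    nf = Wf.shape[1]
    u_start, p_start, c_start = nf, nf + n_u, nf + n_u + len(cows)
    n_eff = W.shape[1]
    wtw = np.asarray(W.multiply(W).sum(axis=0)).ravel()

    A = a_inv.tocsr()
    A.sort_indices()
    rng = np.random.default_rng(config.seed)
    scales = config.prior_scales or default_prior_scales(y)
    nu = config.prior_df

    if start_variances is None:
        v = float(np.var(y))
        var = {"u": 0.1 * v, "p": 0.1 * v, "c": 0.1 * v, "e": 0.7 * v}
    else:
        var = dict(zip("upce", start_variances))
    theta = np.zeros(n_eff)
    resid = y.copy()

    keep = config.n_retained
    chains = {k: np.empty(keep) for k in ("var_u", "var_p", "var_c", "var_e")}
    loc_sum = np.zeros(n_eff)
    kept = 0
    n_p, n_c = len(cows), len(cgs)
    for it in range(config.n_iter):
        z = rng.standard_normal(n_eff)
        gibbs_sweep_rep(theta, resid, W.indptr, W.indices, W.data, wtw,
                        A.indptr, A.indices, A.data, u_start, n_u,
                        p_start, n_p, c_start, n_c,
                        var["u"], var["p"], var["c"], var["e"], z)
        if sample_variances:
            u = theta[u_start:u_start + n_u]
            var["u"] = ((u @ (A @ u) + nu * scales["u"])
                        / rng.chisquare(nu + n_u))
            pvec = theta[p_start:p_start + n_p]
            var["p"] = ((pvec @ pvec + nu * scales["p"])
                        / rng.chisquare(nu + n_p))
            cvec = theta[c_start:c_start + n_c]
            var["c"] = ((cvec @ cvec + nu * scales["c"])
                        / rng.chisquare(nu + n_c))
            var["e"] = ((resid @ resid + nu * scales["e"])
                        / rng.chisquare(nu + n))
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 \
                and kept < keep:
            for key, name in zip("upce", ("var_u", "var_p", "var_c", "var_e")):
                chains[name][kept] = var[key]
            loc_sum += theta
            kept += 1

    loc_mean = loc_sum / max(kept, 1)
    location = {
        "fixed": pd.Series(loc_mean[:nf], index=fixed_names),
        "u": pd.Series(loc_mean[u_start:u_start + n_u], index=animal_ids),
        "p": pd.Series(loc_mean[p_start:p_start + n_p], index=cows),
        "c": pd.Series(loc_mean[c_start:c_start + n_c], index=cgs),
    }
    ratio_chains = genetic_ratios(chains["var_u"], chains["var_p"],
                                  chains["var_c"], chains["var_e"])
    geweke_p = {}
    for k, ch in {**chains, **ratio_chains}.items():
        geweke_p[k] = _safe_geweke(ch)
    return RepVariances(
        chains=chains,
        means={k: float(np.mean(v)) for k, v in chains.items()},
        hpd={k: hpd_interval(v) for k, v in chains.items()},
        geweke_p=geweke_p,
        ratio_chains=ratio_chains,
        ratio_means={k: float(np.mean(v)) for k, v in ratio_chains.items()},
        ratio_hpd={k: hpd_interval(v) for k, v in ratio_chains.items()},
        location=location,
        config=config,
    )


@dataclass
class RRCoefCov:
    chains: dict                 # flattened chains: gu_11, gu_12, ... var_e
    G_u: np.ndarray              # posterior-mean 2x2, raw parity scale
    G_p: np.ndarray
    G_c: np.ndarray
    var_e: float
    hpd: dict
    geweke_p: dict
    location: dict
    config: GibbsConfig

    @property
    def n_retained(self) -> int:
        return len(self.chains["var_e"])

    def save(self, chains_csv: str, summary_json: str | None = None) -> None:
        _save_chains(self.chains, chains_csv)
        if summary_json:
            rows = [[k, float(np.mean(v)), *self.hpd[k], self.geweke_p[k]]
                    for k, v in self.chains.items()]
            _save_summary(pd.DataFrame(rows, columns=[
                "parameter", "mean", "hpd_lo", "hpd_hi", "geweke_p"]),
                summary_json)


def _uncenter_G(G: np.ndarray) -> np.ndarray:
    """Translate a coefficient covariance from parity-5-centered to raw."""
    S = np.array([[1.0, -PARITY_CENTER], [0.0, 1.0]])
    return S @ G @ S.T


def gibbs_rrm(records: pd.DataFrame, a_inv: sp.spmatrix, animal_ids,
              config: GibbsConfig, response: str = "y") -> RRCoefCov:
    """Random-regression model: intercept + parity slope per random level.

    Additive coefficients have prior N(0, G_u (x) A); permanent-environment
    and contemporary-group coefficients are i.i.d. across levels with 2x2
    covariances G_p, G_c; all three get inverse-Wishart full conditionals
    and the residual a scaled-inverse-chi-square.
    """
    if response not in records:
        response = "success"
    y = records[response].to_numpy(dtype=float)
    n = y.size
    if records["cow"].nunique() < 2:
        raise ValueError("need at least two cows for the RRM")
    if records.groupby("cow")["parity"].nunique().max() < 2:
        warnings.warn("fewer than 2 distinct parities per cow: "
                      "slope variances will follow the prior")
    animal_ids = list(animal_ids)
    n_u = len(animal_ids)
    cows = sorted(records["cow"].unique(), key=str)
    cgs = sorted(records["cg"].unique(), key=str)
    t = records["parity"].to_numpy(dtype=float) - PARITY_CENTER

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

    Wf, fixed_names = _fixed_design(records)
    W = _hstack_csc([Wf, _pair(records["cow"], animal_ids),
                     _pair(records["cow"], cows),
                     _pair(records["cg"], cgs)])
    nf = Wf.shape[1]
    n_p, n_c = len(cows), len(cgs)
    u_start = nf
    p_start = nf + 2 * n_u
    c_start = p_start + 2 * n_p
    n_eff = W.shape[1]
    wtw = np.asarray(W.multiply(W).sum(axis=0)).ravel()
    A = a_inv.tocsr()
    A.sort_indices()

    rng = np.random.default_rng(config.seed)
    scales = config.prior_scales or default_prior_scales(y)
    nu = max(config.prior_df, 4.0)  # IW on 2x2 needs df > 3 for a mean
    V = {k: (nu - 3.0) * np.diag([scales[k], scales[k] / 25.0])
         for k in ("u", "p", "c")}

    v0 = float(np.var(y))
    G = {k: np.diag([0.1 * v0, 0.01 * v0]) for k in ("u", "p", "c")}
    var_e = 0.7 * v0
    theta = np.zeros(n_eff)
    resid = y.copy()

    keep = config.n_retained
    names = [f"g{k}_{ij}" for k in "upc" for ij in ("11", "12", "22")]
    names.append("var_e")
    chains = {nm: np.empty(keep) for nm in names}
    loc_sum = np.zeros(n_eff)
    kept = 0
    for it in range(config.n_iter):
        z = rng.standard_normal(n_eff)
        gibbs_sweep_rrm(theta, resid, W.indptr, W.indices, W.data, wtw,
                        A.indptr, A.indices, A.data, u_start, n_u,
                        p_start, n_p, c_start, n_c,
                        np.linalg.inv(G["u"]), np.linalg.inv(G["p"]),
                        np.linalg.inv(G["c"]), var_e, z)
        U = theta[u_start:u_start + 2 * n_u].reshape(n_u, 2)
        S_u = U.T @ (A @ U)
        G["u"] = invwishart.rvs(df=nu + n_u, scale=V["u"] + S_u,
                                random_state=rng)
        P = theta[p_start:p_start + 2 * n_p].reshape(n_p, 2)
        G["p"] = invwishart.rvs(df=nu + n_p, scale=V["p"] + P.T @ P,
                                random_state=rng)
        C = theta[c_start:c_start + 2 * n_c].reshape(n_c, 2)
        G["c"] = invwishart.rvs(df=nu + n_c, scale=V["c"] + C.T @ C,
                                random_state=rng)
        var_e = ((resid @ resid + nu * scales["e"])
                 / rng.chisquare(nu + n))
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 \
                and kept < keep:
            for k in "upc":
                raw = _uncenter_G(G[k])
                chains[f"g{k}_11"][kept] = raw[0, 0]
                chains[f"g{k}_12"][kept] = raw[0, 1]
                chains[f"g{k}_22"][kept] = raw[1, 1]
            chains["var_e"][kept] = var_e
            loc_sum += theta
            kept += 1

    loc_mean = loc_sum / max(kept, 1)
    Uc = loc_mean[u_start:u_start + 2 * n_u].reshape(n_u, 2)
    # raw-scale coefficients: a0_raw = a0 - 5*a1
    u0 = Uc[:, 0] - PARITY_CENTER * Uc[:, 1]
    location = {
        "fixed": pd.Series(loc_mean[:nf], index=fixed_names),
        "u_intercept": pd.Series(u0, index=animal_ids),
        "u_slope": pd.Series(Uc[:, 1], index=animal_ids),
    }

    def _mean_G(k):
        return np.array([[np.mean(chains[f"g{k}_11"]),
                          np.mean(chains[f"g{k}_12"])],
                         [np.mean(chains[f"g{k}_12"]),
                          np.mean(chains[f"g{k}_22"])]])

    geweke_p = {}
    for k, ch in chains.items():
        geweke_p[k] = _safe_geweke(ch)
    return RRCoefCov(
        chains=chains, G_u=_mean_G("u"), G_p=_mean_G("p"), G_c=_mean_G("c"),
        var_e=float(np.mean(chains["var_e"])),
        hpd={k: hpd_interval(v) for k, v in chains.items()},
        geweke_p=geweke_p, location=location, config=config)


# ---------------------------------------------------------------------------
# diagnostics and transformations


def _save_chains(chains: dict, path: str) -> None:
    """Long-format CSV: iteration, parameter, value."""
    frames = [pd.DataFrame({"iteration": np.arange(len(v)),
                            "parameter": k, "value": v})
              for k, v in chains.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _save_summary(summary: pd.DataFrame, path: str) -> None:
    import json
    payload = {row["parameter"]: {k: row[k] for k in summary.columns
                                  if k != "parameter"}
               for _, row in summary.iterrows()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


def _safe_geweke(chain) -> float:
    try:
        return geweke_diagnostic(chain)[1]
    except ValueError:
        return float("nan")


def hpd_interval(draws: np.ndarray, prob: float = 0.95):
    """Shortest interval containing ``prob`` of the draws."""
    x = np.sort(np.asarray(draws))
    n = x.size
    m = max(int(np.ceil(prob * n)), 2)
    widths = x[m - 1:] - x[:n - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])


def _spectral0(x: np.ndarray) -> float:
    """Spectral density at frequency zero (Bartlett lag window)."""
    n = x.size
    xc = x - x.mean()
    L = max(int(np.sqrt(n)), 1)
    s = float(xc @ xc) / n
    for k in range(1, L + 1):
        gamma = float(xc[:-k] @ xc[k:]) / n
        s += 2.0 * (1.0 - k / (L + 1.0)) * gamma
    return max(s, 0.0)


def geweke_diagnostic(chain, frac_a: float = 0.1, frac_b: float = 0.5):
    """Geweke convergence z-score and two-sided p-value.

    Compares the mean of the first ``frac_a`` of the chain with the last
    ``frac_b``, with spectral-density standard errors.  Constant chains
    yield (nan, nan).
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("chain too short for the Geweke diagnostic (< 100)")
    a = x[: int(n * frac_a)]
    b = x[n - int(n * frac_b):]
    if np.ptp(x) == 0:
        return float("nan"), float("nan")
    se2 = _spectral0(a) / a.size + _spectral0(b) / b.size
    if se2 == 0:
        return float("nan"), float("nan")
    z = (a.mean() - b.mean()) / np.sqrt(se2)
    p = 2.0 * (1.0 - norm.cdf(abs(z)))
    return float(z), float(p)


def rr_variance_at_parity(G_u, G_p, G_c, var_e, parities=None) -> dict:
    """Per-parity variances and cross-parity correlations from 2x2
    coefficient covariances: var(t) = g11 + 2 t g12 + t^2 g22 and
    cov(t, s) = g11 + (t + s) g12 + t s g22 (T = [1, t])."""
    if parities is None:
        parities = np.arange(2, 9)
    t = np.asarray(parities, dtype=float)
    out: dict = {"parity": t}
    total = np.full(t.size, float(var_e))
    for name, G in (("u", np.asarray(G_u)), ("p", np.asarray(G_p)),
                    ("c", np.asarray(G_c))):
        var = G[0, 0] + 2.0 * t * G[0, 1] + t * t * G[1, 1]
        if np.any(var < 0):
            warnings.warn(f"negative {name} variance at some parity: "
                          "input covariance may not be PSD")
        cov = (G[0, 0] + np.add.outer(t, t) * G[0, 1]
               + np.outer(t, t) * G[1, 1])
        sd = np.sqrt(np.clip(var, 0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / np.outer(sd, sd)
        out[f"var_{name}"] = var
        out[f"corr_{name}"] = corr
        total = total + var
    out["var_e"] = np.full(t.size, float(var_e))
    out["var_total"] = total
    return out


def genetic_ratios(var_u, var_p, var_c, var_e) -> dict:
    """h2, p2, c2 and repeatability r from variance components.

    Works elementwise on chains (per-draw ratios) or on scalars.
    """
    u, p, c, e = (np.asarray(v, dtype=float)
                  for v in (var_u, var_p, var_c, var_e))
    total = u + p + c + e
    if np.any(total <= 0):
        raise ValueError("zero total variance")
    out = {"h2": u / total, "p2": p / total, "c2": c / total,
           "r": (u + p) / total}
    if np.ndim(total) == 0:
        out = {k: float(v) for k, v in out.items()}
    return out
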