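"""Synthetic multibreed herds for end-to-end testing.

Generates pedigrees with breed fractions, gene-dropped SNP genotypes,
Markov calving histories over parities 2-8, and Gaussian repeatability-model
phenotypes with the true effects stored, so that every downstream stage
(editing, relationship matrices, Gibbs sampling, single-step prediction,
validation) can be exercised and checked against known truth.

Each entity class draws from its own child RNG stream of the configured
seed, so components can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import inbreeding_ml
from . import relmat

__all__ = [
    "SimConfig",
    "SyntheticHerd",
    "simulate_pedigree",
    "simulate_genotypes",
    "make_snp_map",
    "simulate_calving_histories",
    "make_cg_map",
    "simulate_rep_phenotypes",
    "generate",
]

DAYS_PER_YEAR = 365.25

# Conditional per-parity success defaults chosen so the marginal calving
# rate is ~0.68 at parity 2 decaying to ~0.08 by parity 8.
DEFAULT_PARITY_SUCCESS = (0.68, 0.70, 0.70, 0.70, 0.70, 0.70, 0.70)
DEFAULT_VARIANCES = (0.019, 0.057, 0.026, 0.081)


@dataclass
class SimConfig:
    breeds: tuple = ("AN", "SM")
    n_founders_per_breed: int = 40
    n_generations: int = 3
    n_herds: int = 4
    start_year: int = 1990
    data_end_year: int = 2020
    true_variances: tuple = DEFAULT_VARIANCES          # (u, p, c, e)
    parity_success: tuple = DEFAULT_PARITY_SUCCESS     # parities 2..8
    genotyping_fraction: float = 0.0
    n_snps: int = 200
    maf_range: tuple = (0.05, 0.5)
    seed: int = 0
    # pedigree shape
    gen_interval_years: int = 3
    offspring_per_dam: int = 2
    # cap on breeding males per generation; None uses every male.  Small
    # values create large half-sib families, which sharpens the
    # additive/permanent-environment separation in recovery studies.
    n_sires_per_gen: int | None = None
    # calving process
    afc_range: tuple = (1.5, 2.67)
    interval_jitter_days: float = 30.0
    et_rate: float = 0.01
    twin_rate: float = 0.01
    # contemporary groups
    cg_size: int = 36
    # probit shift of calving success by the cow's true (u + p) effects,
    # in residual-sd units; 0 keeps histories independent of genetics
    liability_scale: float = 0.0

    def __post_init__(self):
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if len(self.parity_success) != 7:
            raise ValueError("parity_success must have 7 entries (parities 2-8)")
        ps = np.asarray(self.parity_success, dtype=float)
        if np.any(ps < 0) or np.any(ps > 1):
            raise ValueError("parity success probabilities must lie in [0, 1]")
        if np.any(np.asarray(self.true_variances, dtype=float) < 0):
            raise ValueError("variances must be non-negative")
        if not (0 <= self.genotyping_fraction <= 1):
            raise ValueError("genotyping_fraction must lie in [0, 1]")

    def streams(self):
        kids = np.random.SeedSequence(self.seed).spawn(4)
        names = ("pedigree", "genotypes", "calvings", "effects")
        return {k: np.random.default_rng(s) for k, s in zip(names, kids)}


@dataclass
class SyntheticHerd:
    config: SimConfig
    pedigree: pd.DataFrame
    calvings: pd.DataFrame
    genotypes: pd.DataFrame | None
    snp_map: pd.DataFrame | None
    records: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.pedigree.to_csv(os.path.join(outdir, "pedigree.csv"), index=False)
        self.calvings.to_csv(os.path.join(outdir, "calvings.csv"), index=False)
        self.records.to_csv(os.path.join(outdir, "records.csv"), index=False)
        if self.genotypes is not None:
            write_plink_raw(self.genotypes, self.pedigree,
                            os.path.join(outdir, "genotypes.raw"))
            self.snp_map.to_csv(os.path.join(outdir, "snps.tsv"),
                                sep="\t", index=False)
        tru = pd.DataFrame({"animal": self.truth["u"].index,
                            "true_bv": self.truth["u"].values})
        tru["true_pe"] = tru["animal"].map(self.truth["p"]).fillna("")
        tru.to_csv(os.path.join(outdir, "truth.csv"), index=False)


def simulate_pedigree(cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Multibreed pedigree: pure founders, then random-mating generations.

    Founders are purebred, half of each sex; each later-generation female
    is mated to a random male of her generation to produce
    ``offspring_per_dam`` offspring whose breed fractions average the
    parents'.  Birth years advance by ``gen_interval_years`` per
    generation, so parents always precede offspring.
    """
    rng = rng or cfg.streams()["pedigree"]
    rows = []
    next_id = 1
    nb = len(cfg.breeds)

    def bd(year):
        month = int(rng.integers(1, 13))
        day = int(rng.integers(1, 29))
        return f"{year:04d}-{month:02d}-{day:02d}"

    prev = []
    for bi, breed in enumerate(cfg.breeds):
        for j in range(cfg.n_founders_per_breed):
            frac = [0.0] * nb
            frac[bi] = 1.0
            sex = "M" if j % 2 == 0 else "F"
            herd = int(rng.integers(1, cfg.n_herds + 1))
            rows.append([next_id, 0, 0, sex, bd(cfg.start_year), herd, 0] + frac)
            prev.append(len(rows) - 1)
            next_id += 1

    cols = ["animal", "sire", "dam", "sex", "birth_date", "herd", "generation"]
    cols += [f"breed_{b}" for b in cfg.breeds]

    for g in range(1, cfg.n_generations + 1):
        males = [r for r in prev if rows[r][3] == "M"]
        females = [r for r in prev if rows[r][3] == "F"]
        if not males or not females:
            raise ValueError("a generation ran out of one sex")
        if cfg.n_sires_per_gen and len(males) > cfg.n_sires_per_gen:
            picked = rng.choice(len(males), cfg.n_sires_per_gen,
                                replace=False)
            males = [males[i] for i in picked]
        year = cfg.start_year + g * cfg.gen_interval_years
        cur = []
        for d in females:
            s = males[int(rng.integers(len(males)))]
            for _ in range(cfg.offspring_per_dam):
                frac = [0.5 * (rows[s][7 + k] + rows[d][7 + k])
                        for k in range(nb)]
                sex = "M" if rng.random() < 0.5 else "F"
                rows.append([next_id, rows[s][0], rows[d][0], sex, bd(year),
                             rows[d][5], g] + frac)
                cur.append(len(rows) - 1)
                next_id += 1
        prev = cur
    return pd.DataFrame(rows, columns=cols)


def simulate_genotypes(pedigree: pd.DataFrame, n_snps: int,
                       maf_range: tuple = (0.05, 0.5), seed=None, *,
                       allele_freqs=None, missing_rate: float = 0.0):
    """Gene-drop 0/1/2 genotypes down the pedigree.

    Founders draw Hardy-Weinberg genotypes at allele frequencies uniform in
    ``maf_range`` (or the given ``allele_freqs``); descendants receive one
    gamete per parent, Bernoulli(g/2) per SNP.  Gametes for unknown parents
    come from the founder frequencies.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    codes = relmat.order_pedigree(pedigree)
    if allele_freqs is None:
        p = rng.uniform(lo, hi, size=n_snps)
    else:
        p = np.asarray(allele_freqs, dtype=float)
        n_snps = p.size
    geno = np.zeros((codes.n, n_snps), dtype=np.int8)

    def gamete(i):
        if i < 0:
            return (rng.random(n_snps) < p).astype(np.int8)
        g = geno[i]
        return ((g == 2) | ((g == 1) & (rng.random(n_snps) < 0.5))).astype(np.int8)

    for i in range(codes.n):
        s, d = codes.sire[i], codes.dam[i]
        if s < 0 and d < 0:
            geno[i] = rng.binomial(2, p).astype(np.int8)
        else:
            geno[i] = gamete(s) + gamete(d)
    out = pd.DataFrame(geno, index=codes.ids,
                       columns=[f"SNP{j+1}" for j in range(n_snps)],
                       dtype=float)
    if missing_rate > 0:
        mask = rng.random(out.shape) < missing_rate
        out = out.mask(mask)
    return out


def make_snp_map(snp_ids, rng=None, unmapped_fraction: float = 0.0,
                 n_chrom: int = 29) -> pd.DataFrame:
    rng = rng or np.random.default_rng(0)
    n = len(snp_ids)
    chrom = rng.integers(1, n_chrom + 1, size=n)
    pos = rng.integers(1, 10**8, size=n)
    if unmapped_fraction > 0:
        unmapped = rng.random(n) < unmapped_fraction
        chrom = np.where(unmapped, 0, chrom)
    return pd.DataFrame({"snp": list(snp_ids), "chrom": chrom, "pos": pos})


def simulate_calving_histories(pedigree: pd.DataFrame, cfg: SimConfig,
                               rng=None, liability: pd.Series | None = None
                               ) -> pd.DataFrame:
    """Markov calving process per cow, absorbing on the first failure.

    Cows calve first at a uniform age in ``afc_range``; each subsequent
    parity k in 2..8 succeeds with probability ``parity_success[k-2]``
    (probit-shifted by ``liability`` when given) and on success the
    calving lands ~365 d after the previous one, jittered by up to
    ``interval_jitter_days``.  Calvings after the data-end year are
    censored away; ET/twin flags are injected at the configured rates.
    """
    from scipy.stats import norm

    rng = rng or cfg.streams()["calvings"]
    data_end = pd.Timestamp(f"{cfg.data_end_year}-12-31")
    rows = []
    females = pedigree[pedigree["sex"] == "F"]
    for _, cow in females.iterrows():
        birth = pd.Timestamp(cow["birth_date"])
        afc = rng.uniform(*cfg.afc_range)
        date = birth + pd.Timedelta(days=round(afc * DAYS_PER_YEAR))
        dates = [date]
        for k in range(2, 9):
            pk = cfg.parity_success[k - 2]
            if liability is not None and cow["animal"] in liability.index:
                pk = float(norm.cdf(norm.ppf(np.clip(pk, 1e-9, 1 - 1e-9))
                                    + liability[cow["animal"]]))
            if rng.random() >= pk:
                break
            jit = rng.uniform(-cfg.interval_jitter_days, cfg.interval_jitter_days)
            date = date + pd.Timedelta(days=round(365 + jit))
            dates.append(date)
        et = rng.random() < cfg.et_rate
        twin = rng.random() < cfg.twin_rate
        flag_at = int(rng.integers(len(dates)))
        for j, dte in enumerate(dates):
            if dte > data_end:
                break
            rows.append([cow["animal"], f"C{cow['animal']}_{j+1}",
                         dte.date().isoformat(), cow["herd"],
                         int(et and j == flag_at), int(twin and j == flag_at)])
    return pd.DataFrame(rows, columns=["dam", "calf", "calf_birth_date",
                                       "herd", "et_flag", "twin_flag"])


def make_cg_map(pedigree: pd.DataFrame, cows, cg_size: int = 36) -> pd.Series:
    """Chunk cows into contemporary groups of ~cg_size within herd/cohort."""
    ped = pedigree.set_index("animal")
    b = pd.to_datetime(ped["birth_date"].reindex(cows))
    key = pd.DataFrame({
        "cow": list(cows),
        "herd": ped["herd"].reindex(cows).values,
        "year": b.dt.year.values,
        "season": np.where(b.dt.month.values <= 6, 1, 2),
    }).sort_values(["herd", "year", "season", "cow"], kind="stable")
    labels = []
    for (h, y, s), grp in key.groupby(["herd", "year", "season"], sort=False):
        for j, _ in enumerate(grp.index):
            labels.append(f"{h}_{y}_{s}_{j // cg_size}")
    key["cg"] = labels
    return key.set_index("cow")["cg"]


def simulate_rep_phenotypes(pedigree: pd.DataFrame, cg_map: pd.Series,
                            true_variances=DEFAULT_VARIANCES, seed=None, *,
                            n_parities: int = 7, mode: str = "gaussian",
                            betas: dict | None = None,
                            afc_range: tuple = (1.5, 2.67),
                            binary_thresholds=None):
    """Repeatability-model records with the generating truth attached.

    Breeding values follow sigma2_u * A exactly, drawn by recursive
    Mendelian sampling (parent average + sqrt(d_i * sigma2_u) * z with the
    inbreeding-adjusted d_i); permanent-environment, contemporary-group and
    residual effects are independent Gaussians.  Each cow in ``cg_map``
    gets ``n_parities`` records (parities 2..n_parities+1).  ``mode``
    'binary' additionally thresholds the latent records.
    """
    var_u, var_p, var_c, var_e = [float(v) for v in true_variances]
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    codes = relmat.order_pedigree(pedigree)
    _, D = inbreeding_ml(codes.sire, codes.dam)
    if np.any(D <= 0):
        raise ValueError("non-positive Mendelian variance: pedigree bug upstream")

    u = np.zeros(codes.n)
    z = rng.standard_normal(codes.n)
    for i in range(codes.n):
        pa = 0.0
        if codes.sire[i] >= 0:
            pa += 0.5 * u[codes.sire[i]]
        if codes.dam[i] >= 0:
            pa += 0.5 * u[codes.dam[i]]
        u[i] = pa + np.sqrt(var_u * D[i]) * z[i]
    u = pd.Series(u, index=codes.ids, name="true_bv")

    cows = list(cg_map.index)
    p = pd.Series(rng.normal(0.0, np.sqrt(var_p), len(cows)), index=cows)
    cgs = sorted(cg_map.unique())
    c = pd.Series(rng.normal(0.0, np.sqrt(var_c), len(cgs)), index=cgs)

    bt = {"afc": 0.05, "parity": -0.01, "rh": 0.05, "ys_sd": 0.05}
    if betas:
        bt.update(betas)

    from .phenotypes import compute_breed_composition, retained_heterosis_table
    try:
        comp = compute_breed_composition(pedigree)
        rh = retained_heterosis_table(pedigree, comp).reindex(cows).fillna(0.0)
    except ValueError:
        rh = pd.Series(0.0, index=cows)
    afc = pd.Series(rng.uniform(*afc_range, len(cows)), index=cows)
    byear = pd.to_datetime(
        pedigree.set_index("animal")["birth_date"]).dt.year.reindex(cows)

    parities = np.arange(2, 2 + n_parities)
    n_rec = len(cows) * n_parities
    cow_col = np.repeat(cows, n_parities)
    par_col = np.tile(parities, len(cows))
    ys_year = np.repeat(byear.to_numpy(), n_parities) + par_col - 1
    ys_levels = sorted(set(ys_year))
    ys_eff = pd.Series(rng.normal(0.0, bt["ys_sd"], len(ys_levels)),
                       index=ys_levels)
    e = rng.normal(0.0, np.sqrt(var_e), n_rec)
    y = (ys_eff.reindex(ys_year).to_numpy()
         + bt["afc"] * (afc.reindex(cow_col).to_numpy() - float(afc.mean()))
         + bt["parity"] * (par_col - 5.0)
         + bt["rh"] * rh.reindex(cow_col).to_numpy()
         + u.reindex(cow_col).to_numpy()
         + p.reindex(cow_col).to_numpy()
         + c.reindex(cg_map.reindex(cow_col)).to_numpy()
         + e)
    rec = pd.DataFrame({
        "cow": cow_col,
        "parity": par_col,
        "observation": par_col - 1,
        "year_season": [f"{int(yy)}_1" for yy in ys_year],
        "afc": afc.reindex(cow_col).to_numpy(),
        "rh": rh.reindex(cow_col).to_numpy(),
        "cg": cg_map.reindex(cow_col).to_numpy(),
        "y": y,
    })
    truth = {"u": u, "p": p, "c": c, "betas": bt, "ys": ys_eff}
    if mode == "binary":
        thr = binary_thresholds if binary_thresholds is not None \
            else np.zeros(n_parities)
        cut = np.asarray(thr)[par_col - 2]
        rec["success"] = (y > cut).astype(int)
    return rec, truth


def write_plink_raw(geno: pd.DataFrame, pedigree: pd.DataFrame, path: str):
    """PLINK .raw dialect: FID IID PAT MAT SEX PHENOTYPE SNP columns."""
    ped = pedigree.set_index("animal")
    sex_code = {"M": 1, "F": 2}
    with open(path, "w") as fh:
        fh.write("FID IID PAT MAT SEX PHENOTYPE "
                 + " ".join(geno.columns) + "\n")
        for aid, row in geno.iterrows():
            info = ped.loc[aid] if aid in ped.index else None
            pat = info["sire"] if info is not None else 0
            mat = info["dam"] if info is not None else 0
            sx = sex_code.get(info["sex"], 0) if info is not None else 0
            vals = " ".join("NA" if np.isnan(v) else str(int(v)) for v in row)
            fh.write(f"{aid} {aid} {pat} {mat} {sx} -9 {vals}\n")


def read_plink_raw(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", na_values="NA")
    df = df.set_index("IID").drop(columns=["FID", "PAT", "MAT", "SEX",
                                           "PHENOTYPE"])
    return df.astype(float)


def generate(cfg: SimConfig) -> SyntheticHerd:
    """Full synthetic herd: pedigree, genotypes, calvings and phenotypes."""
    streams = cfg.streams()
    ped = simulate_pedigree(cfg, streams["pedigree"])
    cows = ped[(ped["sex"] == "F") & (ped["generation"] > 0)]["animal"]
    cg_map = make_cg_map(ped, cows, cfg.cg_size)
    rec, truth = simulate_rep_phenotypes(ped, cg_map, cfg.true_variances,
                                         streams["effects"],
                                         afc_range=cfg.afc_range)
    liability = None
    if cfg.liability_scale:
        tot_sd = np.sqrt(sum(cfg.true_variances)) or 1.0
        liab_all = truth["u"].copy()
        liab_all.loc[truth["p"].index] += truth["p"]
        liability = cfg.liability_scale * liab_all / tot_sd
    cal = simulate_calving_histories(ped, cfg, streams["calvings"],
                                     liability=liability)
    geno = snp_map = None
    if cfg.genotyping_fraction > 0 and cfg.n_snps > 0:
        rng = streams["genotypes"]
        geno = simulate_genotypes(ped, cfg.n_snps, cfg.maf_range, rng)
        latest = ped[ped["generation"] >= ped["generation"].max() - 1]["animal"]
        take = rng.random(len(latest)) < cfg.genotyping_fraction
        geno = geno.loc[latest[take.astype(bool)].values]
        snp_map = make_snp_map(geno.columns, rng)
    return SyntheticHerd(cfg, ped, cal, geno, snp_map, rec, truth)
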