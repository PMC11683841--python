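"""Phenotype construction for productive longevity.

Takes raw pedigree and calving tables and produces the modeling dataset:
binary success records for parities 2-8 (observation k <-> parity k+1),
the record-editing rules with an audit log, contemporary groups, age at
first calving, breed composition, and retained heterosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EditConfig",
    "apply_edits",
    "derive_pl_records",
    "assign_contemporary_groups",
    "compute_breed_composition",
    "compute_retained_heterosis",
    "compute_afc",
    "build_pl_dataset",
]

DAYS_PER_YEAR = 365.25
MAX_PARITY = 8
MAX_INTERVAL_DAYS = 730.0


@dataclass
class EditConfig:
    afc_min_months: float = 18.0
    afc_max_months: float = 36.0
    max_interval_days: float = MAX_INTERVAL_DAYS
    min_birth_year: int = 1970
    min_cg_size: int = 3


def _to_dates(col: pd.Series, what: str) -> pd.Series:
    try:
        return pd.to_datetime(col, format="ISO8601")
    except (ValueError, TypeError):
        try:
            return pd.to_datetime(col)
        except (ValueError, TypeError) as err:
            raise ValueError(f"unparseable {what} dates") from err


def season_of(dates: pd.Series) -> pd.Series:
    """January-June = 1, July-December = 2."""
    return np.where(pd.to_datetime(dates).dt.month <= 6, 1, 2)


def apply_edits(pedigree: pd.DataFrame, calvings: pd.DataFrame,
                config: EditConfig | None = None):
    """Record-editing rules 1-4 and 6 on raw calving data.

    1. drop records missing dam, calf birth date, or herd;
    2. drop every record of cows with two calvings in one calendar year,
       an embryo-transfer flag, or a twin flag;
    3. drop cows whose first calving falls before ``afc_min_months`` or
       after ``afc_max_months`` of age (boundaries retained);
    4. drop cows with any interval between consecutive calvings longer
       than ``max_interval_days``;
    6. drop cows born before ``min_birth_year``.

    Rule 5 (contemporary groups) runs in :func:`assign_contemporary_groups`
    once groups exist; rule 7 (no first-parity observations) is structural
    in :func:`derive_pl_records`, which starts coding at parity 2.

    Returns ``(filtered_calvings, audit)`` where audit counts removals.
    """
    cfg = config or EditConfig()
    audit: dict = {}
    cal = calvings.copy()

    missing = (_unknownish(cal["dam"]) | cal["calf_birth_date"].isna()
               | _unknownish(cal["herd"]))
    audit["rule1_missing_fields"] = int(missing.sum())
    cal = cal[~missing].copy()
    if cal.empty:
        audit["cows_removed_total"] = 0
        return cal, audit
    cal["calf_birth_date"] = _to_dates(cal["calf_birth_date"], "calving")
    cal = cal.sort_values(["dam", "calf_birth_date"], kind="stable")

    bad_cows: set = set()

    year = cal["calf_birth_date"].dt.year
    multi = cal.groupby(["dam", year]).size()
    flagged = set(multi[multi > 1].index.get_level_values(0))
    for col in ("et_flag", "twin_flag"):
        if col in cal:
            flagged |= set(cal.loc[cal[col].fillna(0).astype(int) > 0, "dam"])
    audit["rule2_multiple_et_twin"] = len(flagged)
    bad_cows |= flagged

    birth = pd.Series(
        _to_dates(pedigree.set_index("animal")["birth_date"], "pedigree").values,
        index=pedigree["animal"].values)
    first = cal.groupby("dam")["calf_birth_date"].min()
    afc_months = (first - birth.reindex(first.index)).dt.days / DAYS_PER_YEAR * 12
    bad_afc = set(afc_months[(afc_months < cfg.afc_min_months)
                             | (afc_months > cfg.afc_max_months)].index)
    bad_afc |= set(afc_months[afc_months.isna()].index)
    audit["rule3_afc"] = len(bad_afc - bad_cows)
    bad_cows |= bad_afc

    gaps = cal.groupby("dam")["calf_birth_date"].diff().dt.days
    bad_gap = set(cal.loc[gaps > cfg.max_interval_days, "dam"])
    audit["rule4_interval"] = len(bad_gap - bad_cows)
    bad_cows |= bad_gap

    by = birth.reindex(first.index).dt.year
    bad_year = set(by[by < cfg.min_birth_year].index)
    audit["rule6_birth_year"] = len(bad_year - bad_cows)
    bad_cows |= bad_year

    audit["cows_removed_total"] = len(bad_cows)
    out = cal[~cal["dam"].isin(bad_cows)].reset_index(drop=True)
    return out, audit


def _unknownish(col: pd.Series) -> pd.Series:
    s = col.astype("object")
    return s.isna() | s.isin([0, "0", "", None])


def compute_afc(calvings: pd.DataFrame, pedigree: pd.DataFrame) -> pd.Series:
    """Age at first calving in years per cow; negative ages raise."""
    birth = pd.Series(
        pd.to_datetime(pedigree["birth_date"]).values,
        index=pedigree["animal"].values)
    first = calvings.groupby("dam")["calf_birth_date"].min()
    first = pd.to_datetime(first)
    afc = (first - birth.reindex(first.index)).dt.days / DAYS_PER_YEAR
    if (afc <= 0).any():
        bad = afc[afc <= 0].index.tolist()
        raise ValueError(f"non-positive age at first calving for cows {bad[:5]}")
    return afc


def derive_pl_records(calvings: pd.DataFrame, pedigree: pd.DataFrame,
                      data_end_date, *,
                      max_interval_days: float = MAX_INTERVAL_DAYS) -> pd.DataFrame:
    """Code binary success per opportunity parity 2-8.

    A cow has opportunity at parity k while her age at ``data_end_date``
    is at least k+1 years (parity k corresponds to dam age k+1).  Success
    at parity k requires an unbroken run of calvings in ordinal positions
    2..k, each within ``max_interval_days`` of the previous; the first
    missed parity zeroes all later opportunity records (absorbing failure).
    For failed parities the year-season covariate uses the expected calving
    date (first calving + (k-1) years).
    """
    data_end = pd.Timestamp(data_end_date)
    cal = calvings.copy()
    cal["calf_birth_date"] = pd.to_datetime(cal["calf_birth_date"])
    cal = cal.sort_values(["dam", "calf_birth_date"], kind="stable")
    birth = pd.Series(pd.to_datetime(pedigree["birth_date"]).values,
                      index=pedigree["animal"].values)
    herd_of = pd.Series(pedigree["herd"].values, index=pedigree["animal"].values) \
        if "herd" in pedigree else None

    rows = []
    for cow, grp in cal.groupby("dam", sort=False):
        dates = grp["calf_birth_date"].to_list()
        b = birth.get(cow)
        if b is None or pd.isna(b):
            continue
        afc = (dates[0] - b).days / DAYS_PER_YEAR
        # length of the consecutive-calving streak, counting parity 1
        streak = 1
        for i in range(1, len(dates)):
            if (dates[i] - dates[i - 1]).days <= max_interval_days:
                streak += 1
            else:
                break
        age_end = (data_end - b).days / DAYS_PER_YEAR
        herd = grp["herd"].iloc[0] if "herd" in grp else (
            herd_of.get(cow) if herd_of is not None else None)
        for k in range(2, MAX_PARITY + 1):
            if age_end < k + 1:
                break
            success = 1 if streak >= k else 0
            if success:
                calf_date = dates[k - 1]
            else:
                calf_date = dates[0] + pd.Timedelta(
                    days=round((k - 1) * DAYS_PER_YEAR))
            rows.append((cow, k, k - 1, success, herd,
                         calf_date.year, 1 if calf_date.month <= 6 else 2,
                         afc, k))
    return pd.DataFrame(rows, columns=[
        "cow", "parity", "observation", "success", "herd",
        "calf_year", "calf_season", "afc", "parity_cov"])


def assign_contemporary_groups(pl_records: pd.DataFrame,
                               pedigree: pd.DataFrame, *,
                               min_size: int = 3):
    """Contemporary group = cow's herd x cow's birth year-season (rule 5).

    Groups with fewer than ``min_size`` cows, or whose records show no
    variability (all successes or all failures), are removed together with
    their records.  Returns ``(filtered_records, audit)``.
    """
    ped = pedigree.set_index("animal")
    bdate = pd.to_datetime(ped["birth_date"])
    rec = pl_records.copy()
    cows = rec["cow"]
    byear = bdate.reindex(cows).dt.year.to_numpy()
    bseason = np.where(bdate.reindex(cows).dt.month.to_numpy() <= 6, 1, 2)
    herd = rec["herd"].to_numpy()
    rec["cg"] = [f"{h}_{y}_{s}" for h, y, s in zip(herd, byear, bseason)]

    audit: dict = {}
    sizes = rec.groupby("cg")["cow"].nunique()
    small = set(sizes[sizes < min_size].index)
    audit["rule5_small_cg"] = len(small)
    rec = rec[~rec["cg"].isin(small)]
    var = rec.groupby("cg")["success"].nunique()
    flat = set(var[var < 2].index)
    audit["rule5_no_variability"] = len(flat)
    rec = rec[~rec["cg"].isin(flat)].reset_index(drop=True)
    return rec, audit


def compute_breed_composition(pedigree: pd.DataFrame,
                              founder_fractions: pd.DataFrame | None = None,
                              phantom_breeds: dict | None = None,
                              tol: float = 1e-9) -> pd.DataFrame:
    """Breed fractions by averaging parental fractions down the pedigree.

    Founders must come with fractions summing to 1 (either as ``breed_*``
    columns on the pedigree or in ``founder_fractions``).  An unknown
    parent contributes the pure breed named by ``phantom_breeds[(animal,
    slot)]`` when supplied, otherwise it mirrors the known parent (or the
    animal's own founder label).
    """
    from .relmat import order_pedigree

    codes = order_pedigree(pedigree)
    if founder_fractions is None:
        cols = [c for c in pedigree.columns if c.startswith("breed_")]
        if not cols:
            raise ValueError("no breed fraction columns and no founder table")
        founder_fractions = pedigree.set_index("animal")[cols]
    breeds = [c[len("breed_"):] for c in founder_fractions.columns]
    nb = len(breeds)
    fr = np.zeros((codes.n, nb))
    given = founder_fractions.reindex(codes.ids)
    has = ~given.isna().all(axis=1).to_numpy()
    vals = given.fillna(0.0).to_numpy(dtype=float)

    for i in range(codes.n):
        s, d = codes.sire[i], codes.dam[i]
        if s < 0 and d < 0:
            if not has[i]:
                raise ValueError(
                    f"founder {codes.ids[i]} has no breed fractions")
            v = vals[i]
            if abs(v.sum() - 1.0) > tol:
                raise ValueError(
                    f"founder {codes.ids[i]} fractions sum to {v.sum()}")
            fr[i] = v
            continue
        parts = []
        for p, slot in ((s, "sire"), (d, "dam")):
            if p >= 0:
                parts.append(fr[p])
            elif phantom_breeds and (codes.ids[i], slot) in phantom_breeds:
                v = np.zeros(nb)
                v[breeds.index(phantom_breeds[(codes.ids[i], slot)])] = 1.0
                parts.append(v)
            else:
                parts.append(None)
        known = [p for p in parts if p is not None]
        filled = [p if p is not None else known[0] for p in parts]
        fr[i] = 0.5 * (filled[0] + filled[1])
    return pd.DataFrame(fr, index=codes.ids,
                        columns=[f"breed_{b}" for b in breeds])


def compute_retained_heterosis(sire_comp, dam_comp) -> float | np.ndarray:
    """RH = 1 - sum_i P_si * P_di over breed fractions of the two parents."""
    s = np.asarray(sire_comp, dtype=float)
    d = np.asarray(dam_comp, dtype=float)
    rh = 1.0 - np.sum(s * d, axis=-1)
    return float(rh) if np.ndim(rh) == 0 else rh


def retained_heterosis_table(pedigree: pd.DataFrame,
                             composition: pd.DataFrame) -> pd.Series:
    """Per-animal RH from its parents' breed compositions.

    Animals with an unknown parent get RH computed against the known
    parent's composition mirrored (RH = 0 if purebred); founders get 0.
    """
    comp = composition.to_numpy()
    idx = {a: i for i, a in enumerate(composition.index)}
    out = np.zeros(len(pedigree))
    for r, (a, s, d) in enumerate(zip(pedigree["animal"], pedigree["sire"],
                                      pedigree["dam"])):
        sc = comp[idx[s]] if s in idx else None
        dc = comp[idx[d]] if d in idx else None
        if sc is None and dc is None:
            continue
        if sc is None:
            sc = dc
        if dc is None:
            dc = sc
        out[r] = 1.0 - float(np.sum(sc * dc))
    return pd.Series(out, index=pedigree["animal"].values, name="rh")


def build_pl_dataset(pedigree: pd.DataFrame, calvings: pd.DataFrame,
                     data_end_date, config: EditConfig | None = None):
    """Full pipeline: edits -> PL coding -> contemporary groups -> covariates.

    Returns ``(records, audit)`` where records carry success, parity,
    observation, cg, calf year-season, AFC and RH per cow-parity row.
    """
    cfg = config or EditConfig()
    cal, audit = apply_edits(pedigree, calvings, cfg)
    rec = derive_pl_records(cal, pedigree, data_end_date,
                            max_interval_days=cfg.max_interval_days)
    audit["rule7_first_parity"] = rec["cow"].nunique()
    rec, cg_audit = assign_contemporary_groups(rec, pedigree,
                                               min_size=cfg.min_cg_size)
    audit.update(cg_audit)
    if len(rec):
        comp = compute_breed_composition(pedigree)
        rh = retained_heterosis_table(pedigree, comp)
        rec["rh"] = rh.reindex(rec["cow"]).fillna(0.0).to_numpy()
        rec["year_season"] = (rec["calf_year"].astype(str) + "_"
                              + rec["calf_season"].astype(str))
    return rec, audit
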