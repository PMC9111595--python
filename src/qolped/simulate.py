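"""Synthetic twin-family data generator.

Emulates a register-style sample of adult twin families: MZ and DZ twin
pairs with their parents always present in the pedigree structure
(phenotyped with some probability, as in real register data where many
parents never return a survey), optional non-twin siblings and spouses
of twins, and optional spouse-only families.  Parents of twins, and a
twin with a spouse, share a household id — the household (C) component
is what induces spousal resemblance here; there is no assortative-mating
process.

Phenotypes are drawn from exactly the model the varcomp module fits:
per family, the stacked (person x occasion) vector is multivariate
normal with covariance sum_k R_k (x) Gamma_k built from the family's
relatedness matrices, plus grand means and linear age and sex effects.
Occasion-specific missingness is MCAR, and scores can optionally be
discretized to the 1-10 ladder (discretization attenuates variance and
is off by default so parameter-recovery studies are run on the scale the
model assumes).

Default truth values are the published ACE blocks for QoL before/during
the 2020 lockdown (A: 0.3503/0.2835, cov 0.1828; C: 0.4837/0.4731,
cov 0.1936; E: 0.2983/1.0754, cov 0.0292), with grand means 7.73 and
7.02; the default family mix and role age distributions follow the
published pedigree-composition table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from qolped.pedigree import Pedigree, relatedness_matrices, write_pedigree
from qolped.varcomp import ComponentMatrix


class SimulationError(ValueError):
    pass


def table3_ace_truth() -> dict[str, ComponentMatrix]:
    """The published bivariate ACE blocks used as default truth."""
    return {
        "A": ComponentMatrix("A", 0.3503, 0.2835, 0.1828),
        "C": ComponentMatrix("C", 0.4837, 0.4731, 0.1936),
        "E": ComponentMatrix("E", 0.2983, 1.0754, 0.0292),
    }


#: default proportions of family templates (twin-pair families in the
#: approximate zygosity mix of the register sample)
DEFAULT_FAMILY_MIX = {
    "MZF": 0.36,
    "MZM": 0.14,
    "DZF": 0.19,
    "DZM": 0.10,
    "DOS": 0.21,
    "spouse_only": 0.0,
}

#: (mean, sd) of age in years per role, truncated at 16.  Parent ages
#: are not drawn independently: mother = twin age + N(28, 4) years and
#: father = mother + N(3, 3), keeping generations consistent.
DEFAULT_AGE_DISTRIBUTION = {
    "twin": (36.0, 16.0),
    "twin_spouse": (53.0, 13.0),
    "spouse_only": (50.0, 12.0),
}


@dataclass
class SimConfig:
    """Generative settings; the defaults are the study-like conditions."""

    n_families: int = 1000
    family_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FAMILY_MIX))
    truth: dict[str, ComponentMatrix] = field(default_factory=table3_ace_truth)
    mean_pre: float = 7.73
    mean_pan: float = 7.02
    beta_age: float = -0.01
    beta_sex: float = 0.1
    age_distribution: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_DISTRIBUTION)
    )
    occasion_gap_years: float = 3.0
    p_mother_phenotyped: float = 0.65
    p_father_phenotyped: float = 0.40
    p_sibling: float = 0.08
    p_twin_spouse: float = 0.02
    missing_pre: float = 0.15
    missing_pan: float = 0.35
    discretize: bool = False
    seed: int = 0

    def validate(self):
        s = sum(self.family_mix.values())
        if not np.isclose(s, 1.0):
            raise SimulationError(f"family_mix proportions sum to {s}, not 1")
        for p in (self.missing_pre, self.missing_pan):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"missingness probability {p} outside [0, 1]")
        for comp, cm in self.truth.items():
            if not cm.is_psd():
                raise SimulationError(f"truth block for {comp} is not PSD")


# template member tuple: (role, sex or None for 'draw at random')
_TEMPLATES = {
    "MZF": ("F", "F", True),
    "MZM": ("M", "M", True),
    "DZF": ("F", "F", False),
    "DZM": ("M", "M", False),
    "DOS": ("M", "F", False),
}


def _truncnorm16(rng, mean, sd, size=None):
    a = rng.normal(mean, sd, size=size)
    return np.maximum(a, 16.0)


def _build_family_rows(cfg: SimConfig, rng: np.random.Generator, fam_no: int, template: str):
    """Rows (dicts, phenotypes filled later) for one family."""
    fid = f"F{fam_no:05d}"
    rows = []

    def pid(tag):
        return f"{fid}.{tag}"

    if template == "spouse_only":
        age = _truncnorm16(rng, *cfg.age_distribution["spouse_only"])
        hh = pid("hh")
        for tag, sex, da in (("s1", "M", 0.0), ("s2", "F", -2.0)):
            rows.append(
                dict(fam_id=fid, person_id=pid(tag), father_id=None, mother_id=None,
                     sex=sex, mz_group=None, household_id=hh,
                     age=max(age + da, 16.0), role="spouse_only", phenotyped=True)
            )
        return rows

    sex1, sex2, is_mz = _TEMPLATES[template]
    twin_age = float(_truncnorm16(rng, *cfg.age_distribution["twin"]))
    mother_age = max(twin_age + rng.normal(28.0, 4.0), twin_age + 16.0)
    father_age = max(mother_age + rng.normal(3.0, 3.0), twin_age + 16.0)
    fa, mo = pid("fa"), pid("mo")
    hh_parents = pid("hhp")
    rows.append(dict(fam_id=fid, person_id=fa, father_id=None, mother_id=None,
                     sex="M", mz_group=None, household_id=hh_parents, age=father_age,
                     role="father", phenotyped=rng.random() < cfg.p_father_phenotyped))
    rows.append(dict(fam_id=fid, person_id=mo, father_id=None, mother_id=None,
                     sex="F", mz_group=None, household_id=hh_parents, age=mother_age,
                     role="mother", phenotyped=rng.random() < cfg.p_mother_phenotyped))
    mz = pid("mz") if is_mz else None
    for tag, sex in (("t1", sex1), ("t2", sex2)):
        rows.append(dict(fam_id=fid, person_id=pid(tag), father_id=fa, mother_id=mo,
                         sex=sex, mz_group=mz, household_id=None, age=twin_age,
                         role="twin", phenotyped=True))
    if rng.random() < cfg.p_sibling:
        sib_age = max(twin_age + rng.normal(2.5, 4.0), 16.0)
        rows.append(dict(fam_id=fid, person_id=pid("sib"), father_id=fa, mother_id=mo,
                         sex="M" if rng.random() < 0.5 else "F", mz_group=None,
                         household_id=None, age=sib_age, role="sibling", phenotyped=True))
    if rng.random() < cfg.p_twin_spouse:
        hh_tw = pid("hht")
        rows[2]["household_id"] = hh_tw  # first twin marries
        sp_sex = "F" if rows[2]["sex"] == "M" else "M"
        rows.append(dict(fam_id=fid, person_id=pid("sp"), father_id=None, mother_id=None,
                         sex=sp_sex, mz_group=None, household_id=hh_tw,
                         age=float(_truncnorm16(rng, *cfg.age_distribution["twin_spouse"])),
                         role="twin_spouse", phenotyped=True))
    return rows


def simulate(cfg: SimConfig, out_path=None) -> Pedigree:
    """Draw a pedigree under the configured generative model.

    Families sharing a structure reuse one Cholesky factor of the model
    covariance, so large samples are fast.  Fully reproducible from
    ``cfg.seed``.  If ``out_path`` is given the pedigree is also written
    in the standard dialect with a provenance header.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    templates = list(cfg.family_mix)
    probs = np.array([cfg.family_mix[t] for t in templates])
    choice = rng.choice(len(templates), size=cfg.n_families, p=probs)

    all_rows = []
    for fam_no in range(cfg.n_families):
        all_rows.extend(_build_family_rows(cfg, rng, fam_no, templates[choice[fam_no]]))
    df = pd.DataFrame(all_rows)
    df["age_pre"] = df["age"].round(2)
    df["age_pan"] = (df["age"] + cfg.occasion_gap_years).round(2)
    df["qol_pre"] = np.nan
    df["qol_pan"] = np.nan
    df["covid_excluded"] = 0
    ped = Pedigree(
        df[["fam_id", "person_id", "father_id", "mother_id", "sex", "mz_group",
            "household_id", "age_pre", "qol_pre", "age_pan", "qol_pan",
            "covid_excluded"]].copy(),
        validate=False,
    )

    # structural signature -> families sharing one covariance factor
    fam_rows: dict[str, np.ndarray] = {
        fid: idx.to_numpy() for fid, idx in df.groupby("fam_id", sort=False).groups.items()
    }
    by_sig: dict[tuple, list[str]] = {}
    for fid, idx in fam_rows.items():
        grp = df.iloc[idx]
        tags = tuple(p.split(".", 1)[1] for p in grp["person_id"])
        mzflag = tuple(grp["mz_group"].notna())
        hh = tuple(
            "-" if h is None else str(h).split(".", 1)[1] for h in grp["household_id"]
        )
        by_sig.setdefault((tags, mzflag, hh), []).append(fid)

    values = np.full((len(df), 2), np.nan)
    ages_all = df[["age_pre", "age_pan"]].to_numpy(dtype=float)
    female = (df["sex"] == "F").to_numpy(dtype=float)
    for sig, fids in by_sig.items():
        rel = relatedness_matrices(ped, fids[0])
        n = len(rel.member_order)
        sigma = np.zeros((2 * n, 2 * n))
        for comp, cm in cfg.truth.items():
            R = getattr(rel, {"A": "additive", "C": "household",
                              "D": "dominance", "E": "identity"}[comp])
            sigma += np.kron(R, cm.matrix)
        L = np.linalg.cholesky(sigma + 1e-10 * np.eye(2 * n))
        z = rng.standard_normal((len(fids), 2 * n))
        draws = z @ L.T
        for b, fid in enumerate(fids):
            idx = fam_rows[fid]
            vec = draws[b].reshape(n, 2)
            mean = np.column_stack([
                cfg.mean_pre + cfg.beta_age * ages_all[idx, 0] + cfg.beta_sex * female[idx],
                cfg.mean_pan + cfg.beta_age * ages_all[idx, 1] + cfg.beta_sex * female[idx],
            ])
            values[idx] = mean + vec

    # unphenotyped members (structural parents who never responded)
    phen = df["phenotyped"].to_numpy(dtype=bool)
    values[~phen] = np.nan
    # occasion-specific MCAR missingness
    if cfg.missing_pre > 0:
        values[rng.random(len(df)) < cfg.missing_pre, 0] = np.nan
    if cfg.missing_pan > 0:
        values[rng.random(len(df)) < cfg.missing_pan, 1] = np.nan
    if cfg.discretize:
        # clamp-and-round onto the 1-10 ladder; continuous mode stays on
        # the model's latent scale (no censoring, so moments are exact)
        with np.errstate(invalid="ignore"):
            values = np.clip(np.round(values), 1, 10)

    out = ped.df.copy()
    out["qol_pre"] = values[:, 0]
    out["qol_pan"] = values[:, 1]
    result = Pedigree(out, check_bounds=cfg.discretize)
    if out_path is not None:
        write_pedigree(
            result, out_path,
            header_comment=f"qolped simulate seed={cfg.seed} n_families={cfg.n_families}",
        )
    return result


_ROLE_LABELS = {
    ("twin", "MZF"): "MZ females",
    ("twin", "MZM"): "MZ males",
    ("twin", "DZF"): "DZ females from DZ female pairs",
    ("twin", "DZM"): "DZ males from DZ male pairs",
    ("twin", "DOSM"): "DZ males from DZ opposite-sex twin pairs",
    ("twin", "DOSF"): "DZ females from DZ opposite-sex twin pairs",
}


def assign_roles(ped: Pedigree) -> pd.Series:
    """Role label per person: twin categories by zygosity and sex,
    father/mother (appearing as a parent id), sibling (full sib of a
    twin), spouse of a twin, or other."""
    df = ped.df
    roles = pd.Series("other", index=df["person_id"].tolist())
    parent_ids_fa = set(df["father_id"].dropna())
    parent_ids_mo = set(df["mother_id"].dropna())
    twin_ids = set()
    for _, grp in df.groupby("fam_id", sort=False):
        kids = grp[grp["father_id"].notna() & grp["mother_id"].notna()]
        for (fa, mo), sibs in kids.groupby(["father_id", "mother_id"]):
            # co-born: same MZ group, or identical recorded age
            for i in range(len(sibs)):
                for j in range(i + 1, len(sibs)):
                    a, b = sibs.iloc[i], sibs.iloc[j]
                    mz = a["mz_group"] is not None and a["mz_group"] == b["mz_group"]
                    co = mz or any(
                        pd.notna(a[c]) and pd.notna(b[c]) and a[c] == b[c]
                        for c in ("age_pre", "age_pan")
                    )
                    if not co:
                        continue
                    sexes = "".join(sorted([a["sex"], b["sex"]]))
                    for person in (a, b):
                        if mz:
                            lab = "MZ females" if person["sex"] == "F" else "MZ males"
                        elif sexes == "FF":
                            lab = "DZ females from DZ female pairs"
                        elif sexes == "MM":
                            lab = "DZ males from DZ male pairs"
                        else:
                            lab = ("DZ males" if person["sex"] == "M" else "DZ females") \
                                + " from DZ opposite-sex twin pairs"
                        roles[person["person_id"]] = lab
                        twin_ids.add(person["person_id"])
    hh_of = dict(zip(df["person_id"], df["household_id"]))
    for _, r in df.iterrows():
        p = r["person_id"]
        if p in twin_ids:
            continue
        if p in parent_ids_fa:
            roles[p] = "Fathers"
        elif p in parent_ids_mo:
            roles[p] = "Mothers"
        elif r["father_id"] is not None and r["mother_id"] is not None:
            roles[p] = "Brothers" if r["sex"] == "M" else "Sisters"
        elif r["household_id"] is not None and any(
            q in twin_ids and hh_of[q] == r["household_id"]
            for q in df.loc[df["fam_id"] == r["fam_id"], "person_id"]
        ):
            roles[p] = "Spouses of twins"
    return roles


def summarize_sample(ped: Pedigree) -> pd.DataFrame:
    """Pedigree-composition table: per role, the number of individuals
    with data and mean (sd) age, at each occasion and in the overlap."""
    df = ped.df
    roles = assign_roles(ped)
    df = df.assign(role=roles.loc[df["person_id"]].to_numpy())
    rows = []
    cats = ["Individuals"] + sorted(r for r in df["role"].unique())
    for cat in cats:
        sub = df if cat == "Individuals" else df[df["role"] == cat]
        pre = sub[sub["qol_pre"].notna()]
        pan = sub[sub["qol_pan"].notna()]
        both = sub[sub["qol_pre"].notna() & sub["qol_pan"].notna()]
        rows.append(
            {
                "role": cat,
                "n_pre": len(pre),
                "age_pre_mean": round(float(pre["age_pre"].mean()), 2) if len(pre) else float("nan"),
                "age_pre_sd": round(float(pre["age_pre"].std()), 2) if len(pre) > 1 else float("nan"),
                "n_pan": len(pan),
                "age_pan_mean": round(float(pan["age_pan"].mean()), 2) if len(pan) else float("nan"),
                "age_pan_sd": round(float(pan["age_pan"].std()), 2) if len(pan) > 1 else float("nan"),
                "n_both": len(both),
            }
        )
    return pd.DataFrame(rows)
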