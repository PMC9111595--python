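"""Pedigree parsing, validation and relatedness algebra.

A pedigree file has one row per individual with family id, person id,
parental ids, sex, an MZ-group code shared by members of one monozygotic
multiple, a household id shared by spouse pairs, and the phenotype (QoL
on the 1-10 ladder) and age at each of two occasions ("pre" = before the
lockdown, "pan" = during it), plus a boolean infection-exclusion flag.

Relatedness between family members is derived purely from the parental
links: the recursive kinship coefficient Phi gives the expected additive
relatedness 2*Phi, and the (non-inbred) fraternity coefficient gives the
dominance relatedness.  Members of one MZ group are merged into a single
genetic identity before the recursion, so relatives *through* an MZ twin
(e.g. the child of one twin vs. the co-twin) come out right, and the
co-twins themselves get additive and dominance relatedness 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical column order of the pedigree file dialect
COLUMNS = [
    "fam_id",
    "person_id",
    "father_id",
    "mother_id",
    "sex",
    "mz_group",
    "household_id",
    "age_pre",
    "qol_pre",
    "age_pan",
    "qol_pan",
    "covid_excluded",
]

_ID_COLS = ["fam_id", "person_id", "father_id", "mother_id", "mz_group", "household_id"]
_NUM_COLS = ["age_pre", "qol_pre", "age_pan", "qol_pan"]

#: relationship-type labels produced by classify_pairs
RELATIONSHIP_TYPES = [
    "spouse",
    "MZM",
    "MZF",
    "DZM",
    "DZF",
    "DOS",
    "mother-daughter",
    "mother-son",
    "father-daughter",
    "father-son",
    "brother-brother",
    "brother-sister",
    "sister-sister",
    "other",
]

#: types whose two members are exchangeable (double-entered in correlations)
SYMMETRIC_TYPES = {
    "spouse",
    "MZM",
    "MZF",
    "DZM",
    "DZF",
    "DOS",
    "brother-brother",
    "brother-sister",
    "sister-sister",
    "other",
}


class PedigreeError(ValueError):
    """Base class for pedigree I/O and validation failures."""


class ParseError(PedigreeError):
    """A row of the pedigree file could not be parsed."""


class ValidationError(PedigreeError):
    """Structural validation failed; ``offenders`` lists the person ids."""

    def __init__(self, message: str, offenders=()):
        super().__init__(message)
        self.offenders = list(offenders)


@dataclass(frozen=True)
class Individual:
    """One pedigree member.  Missing fields are ``None``/NaN."""

    person_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # 'M' or 'F'
    mz_group: str | None
    household_id: str | None
    age_pre: float
    qol_pre: float
    age_pan: float
    qol_pan: float
    excluded_covid: bool


@dataclass
class RelatednessSet:
    """Per-family relatedness matrices in a fixed member order.

    ``additive`` holds the expected additive relatedness 2*Phi (1 for MZ
    co-twins), ``dominance`` the non-inbred fraternity coefficients,
    ``household`` a 0/1 indicator of shared household (unit diagonal) and
    ``identity`` the identity; all share ``member_order``.
    """

    additive: np.ndarray
    dominance: np.ndarray
    household: np.ndarray
    identity: np.ndarray
    member_order: list[str]

    def __post_init__(self):
        n = len(self.member_order)
        for m in (self.additive, self.dominance, self.household, self.identity):
            if m.shape != (n, n):
                raise ValueError("relatedness matrices must match member_order")


class Pedigree:
    """A validated collection of individuals partitioned into families.

    Wraps a :class:`pandas.DataFrame` in the standard column dialect; the
    frame is validated on construction (parental sexes, acyclicity,
    MZ-group consistency, phenotype range, household size).
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True, check_bounds: bool = True):
        df = _coerce(df)
        self.df = df.reset_index(drop=True)
        self._row_of = {p: i for i, p in enumerate(self.df["person_id"])}
        if len(self._row_of) != len(self.df):
            dup = self.df["person_id"][self.df["person_id"].duplicated()].tolist()
            raise ValidationError(f"duplicate person ids: {dup}", dup)
        self._kinship_cache: dict[str, "_FamilyKinship"] = {}
        self._fam_groups: dict[str, pd.DataFrame] | None = None
        if validate:
            self._validate(check_bounds)

    # -- container interface -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, person_id: str) -> bool:
        return person_id in self._row_of

    @property
    def families(self) -> dict[str, pd.DataFrame]:
        return {f: g for f, g in self.df.groupby("fam_id", sort=False)}

    @property
    def n_families(self) -> int:
        return self.df["fam_id"].nunique()

    def family_of(self, person_id: str) -> str:
        return self.df.at[self._row_of[person_id], "fam_id"]

    def individual(self, person_id: str) -> Individual:
        r = self.df.loc[self._row_of[person_id]]
        return Individual(
            person_id=r["person_id"],
            family_id=r["fam_id"],
            father_id=r["father_id"],
            mother_id=r["mother_id"],
            sex=r["sex"],
            mz_group=r["mz_group"],
            household_id=r["household_id"],
            age_pre=r["age_pre"],
            qol_pre=r["qol_pre"],
            age_pan=r["age_pan"],
            qol_pan=r["qol_pan"],
            excluded_covid=bool(r["covid_excluded"]),
        )

    def drop_excluded(self) -> "Pedigree":
        """Return a copy where individuals flagged by the infection filter
        leave the analysis sample: their phenotypes are blanked while the
        pedigree structure (parent links, households) is kept intact, as
        flagged members may still connect unflagged relatives."""
        df = self.df.copy()
        flagged = df["covid_excluded"].astype(bool)
        df.loc[flagged, ["qol_pre", "qol_pan"]] = np.nan
        return Pedigree(df, validate=False)

    @property
    def n_phenotyped(self) -> int:
        """Individuals contributing at least one phenotype."""
        return int((self.df["qol_pre"].notna() | self.df["qol_pan"].notna()).sum())

    # -- validation ----------------------------------------------------------
    def _validate(self, check_bounds: bool = True):
        df = self.df
        bad_sex = df[~df["sex"].isin(["M", "F"])]["person_id"].tolist()
        if bad_sex:
            raise ValidationError(f"sex must be M or F: {bad_sex}", bad_sex)

        if check_bounds:
            for col, lab in (("qol_pre", "pre"), ("qol_pan", "pan")):
                v = df[col]
                bad = df[(v.notna()) & ((v < 1) | (v > 10))]["person_id"].tolist()
                if bad:
                    raise ValidationError(
                        f"{lab}-occasion phenotype outside [1, 10] for: {bad}", bad
                    )

        both = df["age_pre"].notna() & df["age_pan"].notna()
        bad = df[both & (df["age_pan"] < df["age_pre"])]["person_id"].tolist()
        if bad:
            raise ValidationError(f"age_pan < age_pre for: {bad}", bad)

        sex_of = dict(zip(df["person_id"], df["sex"]))
        fam_of = dict(zip(df["person_id"], df["fam_id"]))
        offenders = []
        for _, r in df.iterrows():
            for pcol, want in (("father_id", "M"), ("mother_id", "F")):
                pid = r[pcol]
                if pid is None:
                    continue
                if pid not in sex_of:
                    raise ValidationError(
                        f"unknown {pcol[:-3]} {pid!r} for {r['person_id']!r}",
                        [r["person_id"]],
                    )
                if fam_of[pid] != r["fam_id"]:
                    offenders.append(r["person_id"])
                elif sex_of[pid] != want:
                    offenders.append(r["person_id"])
        if offenders:
            raise ValidationError(
                f"parent sex/family inconsistency for: {offenders}", offenders
            )

        self._check_acyclic()
        self._check_mz_groups()
        self._check_households()

    def _check_acyclic(self):
        parents = {
            r["person_id"]: [p for p in (r["father_id"], r["mother_id"]) if p]
            for _, r in self.df.iterrows()
        }
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(p, stack):
            if state.get(p) == 1:
                return
            if state.get(p) == 0:
                raise ValidationError(f"pedigree cycle through {p!r}", stack)
            state[p] = 0
            for q in parents.get(p, []):
                visit(q, stack + [q])
            state[p] = 1

        for p in parents:
            visit(p, [p])

    def _check_mz_groups(self):
        df = self.df[self.df["mz_group"].notna()]
        for g, grp in df.groupby("mz_group"):
            for col in ("father_id", "mother_id", "sex"):
                if grp[col].nunique(dropna=False) > 1:
                    raise ValidationError(
                        f"MZ group {g!r} members differ in {col}",
                        grp["person_id"].tolist(),
                    )

    def _check_households(self):
        df = self.df[self.df["household_id"].notna()]
        for h, grp in df.groupby("household_id"):
            if len(grp) > 2:
                raise ValidationError(
                    f"household {h!r} has {len(grp)} members (max 2: a spouse pair)",
                    grp["person_id"].tolist(),
                )

    # -- kinship -------------------------------------------------------------
    def _fam_df(self, fam_id: str) -> pd.DataFrame:
        if self._fam_groups is None:
            self._fam_groups = {f: g for f, g in self.df.groupby("fam_id", sort=False)}
        if fam_id not in self._fam_groups:
            raise PedigreeError(f"no such family: {fam_id!r}")
        return self._fam_groups[fam_id]

    def _family_kinship(self, fam_id: str) -> "_FamilyKinship":
        if fam_id not in self._kinship_cache:
            self._kinship_cache[fam_id] = _FamilyKinship(self._fam_df(fam_id))
        return self._kinship_cache[fam_id]


class _FamilyKinship:
    """Memoized kinship recursion over one family, with MZ groups merged
    to a single genetic node before recursion."""

    def __init__(self, fam_df: pd.DataFrame):
        self.members = list(fam_df["person_id"])
        # genetic node: MZ co-twins collapse onto the lexicographically
        # smallest member of their group
        rep: dict[str, str] = {}
        for g, grp in fam_df[fam_df["mz_group"].notna()].groupby("mz_group"):
            ids = sorted(grp["person_id"])
            for p in ids:
                rep[p] = ids[0]
        self.node = {p: rep.get(p, p) for p in self.members}
        self.parents: dict[str, tuple[str | None, str | None]] = {}
        for _, r in fam_df.iterrows():
            fa = self.node.get(r["father_id"], r["father_id"])
            mo = self.node.get(r["mother_id"], r["mother_id"])
            self.parents[self.node[r["person_id"]]] = (fa, mo)
        self._phi: dict[tuple[str, str], float] = {}
        self._depth: dict[str, int] = {}

    def depth(self, a: str | None) -> int:
        if a is None or a not in self.parents:
            return 0
        if a not in self._depth:
            fa, mo = self.parents[a]
            self._depth[a] = 1 + max(self.depth(fa), self.depth(mo))
        return self._depth[a]

    def phi_nodes(self, a: str | None, b: str | None) -> float:
        # missing parents are unique unrelated founders
        if a is None or b is None:
            return 0.0
        if a > b:
            a, b = b, a
        key = (a, b)
        if key in self._phi:
            return self._phi[key]
        if a == b:
            fa, mo = self.parents.get(a, (None, None))
            val = 0.5 * (1.0 + self.phi_nodes(fa, mo))
        else:
            # recurse on the deeper node; it cannot be ancestral to the other
            x, y = (a, b) if self.depth(a) >= self.depth(b) else (b, a)
            fa, mo = self.parents.get(x, (None, None))
            val = 0.5 * (self.phi_nodes(fa, y) + self.phi_nodes(mo, y))
        self._phi[key] = val
        return val

    def phi(self, i: str, j: str) -> float:
        return self.phi_nodes(self.node[i], self.node[j])


# ---------------------------------------------------------------------------
# I/O

def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"pedigree file lacks required columns: {missing}")
    df = df[COLUMNS].copy()
    for c in _ID_COLS:
        s = df[c].astype("object")
        s = s.where(pd.notna(s), None)
        s = s.map(lambda v: None if v is None or str(v).strip() in ("", "NA") else str(v))
        df[c] = s
    for c in _NUM_COLS:
        try:
            df[c] = pd.to_numeric(df[c].replace({"": None, "NA": None}))
        except (ValueError, TypeError) as e:
            raise ParseError(f"non-numeric value in column {c}: {e}") from None
    df["sex"] = df["sex"].astype(str).str.strip()
    exc = df["covid_excluded"]
    exc = pd.to_numeric(exc.replace({"": 0, "NA": 0}), errors="coerce").fillna(0)
    if not exc.isin([0, 1]).all():
        bad = df.loc[~exc.isin([0, 1]), "person_id"].tolist()
        raise ParseError(f"covid_excluded must be 0/1; bad rows: {bad}")
    df["covid_excluded"] = exc.astype(int)
    return df


def read_pedigree(path, sep: str | None = None) -> Pedigree:
    """Read a pedigree file (tab- or comma-separated, header required).

    Missing values are empty fields or ``NA``; sex is coded M/F and the
    exclusion flag 0/1.  The returned pedigree is fully validated:
    unknown parent ids, out-of-range phenotypes, inconsistent MZ groups
    or oversized households raise :class:`ValidationError`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    return _read_pedigree_text(text, sep)


def _read_pedigree_text(text: str, sep: str | None = None) -> Pedigree:
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    if not lines:
        raise ParseError("empty pedigree file")
    if sep is None:
        sep = "\t" if "\t" in lines[0] else ","
    ncol = len(lines[0].split(sep))
    for i, ln in enumerate(lines[1:], start=2):
        if ln and len(ln.split(sep)) != ncol:
            raise ParseError(f"malformed row at line {i}: expected {ncol} fields")
    df = pd.read_csv(
        io.StringIO("\n".join(lines)), sep=sep, dtype=str,
        keep_default_na=False, na_values=[],
    )
    return Pedigree(df)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        if np.isnan(v):
            return ""
        return repr(v)
    return str(v)


def write_pedigree(ped: Pedigree, path, sep: str = "\t", header_comment: str | None = None):
    """Write a pedigree in the standard dialect.

    Round-trips bit-identically: ``write(read(write(p)))`` equals
    ``write(p)`` byte for byte.  ``header_comment`` lines (if given) are
    emitted with a leading ``#`` and skipped by the reader.
    """
    df = ped.df
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for ln in header_comment.splitlines():
                fh.write(f"# {ln}\n")
        fh.write(sep.join(COLUMNS) + "\n")
        for _, r in df.iterrows():
            vals = [_fmt(r[c]) if c != "covid_excluded" else str(int(r[c])) for c in COLUMNS]
            fh.write(sep.join(vals) + "\n")


# ---------------------------------------------------------------------------
# relatedness

def kinship_coefficient(ped: Pedigree, i: str, j: str) -> float:
    """Kinship coefficient Phi(i, j) traced through the parental links.

    Founders are unrelated, Phi(i,i) = (1 + Phi(father, mother)) / 2 and
    Phi(i,j) averages over i's parents; MZ co-twins are one genetic
    identity, so their "self" kinship 1/2 applies between them and
    relatives through either twin are equally related to both.
    """
    for p in (i, j):
        if p not in ped:
            raise PedigreeError(f"unknown person id: {p!r}")
    fi, fj = ped.family_of(i), ped.family_of(j)
    if fi != fj:
        raise PedigreeError(f"{i!r} and {j!r} are in different families ({fi!r} vs {fj!r})")
    return ped._family_kinship(fi).phi(i, j)


def relatedness_matrices(ped: Pedigree, fam_id: str) -> RelatednessSet:
    """Additive (2*Phi), dominance, household and identity matrices for
    one family, in a fixed member order.

    Dominance uses the non-inbred fraternity coefficient
    ``Phi(fa_i,fa_j)*Phi(mo_i,mo_j) + Phi(fa_i,mo_j)*Phi(mo_i,fa_j)``
    with unit diagonal; MZ co-twins get additive and dominance 1.  The
    household matrix is 1 where two members share a household id, plus
    the unit diagonal.
    """
    ks = ped._family_kinship(fam_id)
    grp = ped._fam_df(fam_id)
    order = list(grp["person_id"])
    n = len(order)
    node = ks.node
    par = {p: ks.parents[node[p]] for p in order}
    hh = dict(zip(grp["person_id"], grp["household_id"]))

    A = np.empty((n, n))
    D = np.empty((n, n))
    H = np.eye(n)
    for a in range(n):
        i = order[a]
        for b in range(a, n):
            j = order[b]
            if node[i] == node[j]:
                A[a, b] = A[b, a] = 1.0
                D[a, b] = D[b, a] = 1.0
            else:
                A[a, b] = A[b, a] = 2.0 * ks.phi(i, j)
                fai, moi = par[i]
                faj, moj = par[j]
                d = (
                    ks.phi_nodes(fai, faj) * ks.phi_nodes(moi, moj)
                    + ks.phi_nodes(fai, moj) * ks.phi_nodes(moi, faj)
                )
                D[a, b] = D[b, a] = d
            if a != b and hh[i] is not None and hh[i] == hh[j]:
                H[a, b] = H[b, a] = 1.0
    return RelatednessSet(A, D, H, np.eye(n), order)


# ---------------------------------------------------------------------------
# relationship classification

def _pair_type(ped: Pedigree, ri, rj) -> str:
    sexes = "".join(sorted([ri["sex"], rj["sex"]]))
    if ri["household_id"] is not None and ri["household_id"] == rj["household_id"]:
        return "spouse"
    # parent-offspring
    for parent, child in ((ri, rj), (rj, ri)):
        if child["father_id"] == parent["person_id"] or child["mother_id"] == parent["person_id"]:
            role = "mother" if parent["sex"] == "F" else "father"
            kid = "son" if child["sex"] == "M" else "daughter"
            return f"{role}-{kid}"
    same_parents = (
        ri["father_id"] is not None
        and ri["mother_id"] is not None
        and ri["father_id"] == rj["father_id"]
        and ri["mother_id"] == rj["mother_id"]
    )
    if same_parents:
        if ri["mz_group"] is not None and ri["mz_group"] == rj["mz_group"]:
            return "MZM" if ri["sex"] == "M" else "MZF"
        # co-born DZ pairs are full sibs with identical recorded age at
        # either occasion (no separate twin code exists in the dialect)
        co_born = any(
            pd.notna(ri[c]) and pd.notna(rj[c]) and ri[c] == rj[c]
            for c in ("age_pre", "age_pan")
        )
        if co_born:
            return {"MM": "DZM", "FF": "DZF", "FM": "DOS"}[sexes]
        return {"MM": "brother-brother", "FF": "sister-sister", "FM": "brother-sister"}[sexes]
    return "other"


def classify_pairs(ped: Pedigree, require_phenotyped: bool = True) -> pd.DataFrame:
    """Assign every within-family pair to exactly one relationship type.

    Returns a frame with columns ``id1, id2, relationship_type``.  For
    symmetric types id1 < id2; parent-offspring pairs store the parent
    as id1.  Twin types apply only to co-members of one birth (same two
    parents and, for DZ, identical recorded age); twin-sibling and
    ordinary full-sib pairs map to the sibling types, everything else to
    ``other``.  With ``require_phenotyped`` only pairs whose members both
    carry at least one phenotype are returned.
    """
    rows = []
    for _, grp in ped.df.groupby("fam_id", sort=False):
        recs = grp.to_dict("records")
        if require_phenotyped:
            recs = [
                r for r in recs
                if pd.notna(r["qol_pre"]) or pd.notna(r["qol_pan"])
            ]
        for a in range(len(recs)):
            for b in range(a + 1, len(recs)):
                ri, rj = recs[a], recs[b]
                t = _pair_type(ped, ri, rj)
                i, j = ri["person_id"], rj["person_id"]
                if t.startswith(("mother-", "father-")):
                    # parent first
                    if rj["father_id"] == i or rj["mother_id"] == i:
                        pass
                    else:
                        i, j = j, i
                elif i > j:
                    i, j = j, i
                rows.append((i, j, t))
    return pd.DataFrame(rows, columns=["id1", "id2", "relationship_type"])
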