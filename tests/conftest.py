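import numpy as np
import pandas as pd
import pytest

from qolped.pedigree import COLUMNS, Pedigree


def make_ped(rows) -> Pedigree:
    """Build a pedigree from (fam, pid, fa, mo, sex, mz, hh, age_pre,
    qol_pre, age_pan, qol_pan, excl) tuples."""
    return Pedigree(pd.DataFrame(rows, columns=COLUMNS))


@pytest.fixture
def dz_family():
    """Father + mother (spouse household) + a DZ male twin pair."""
    return make_ped([
        ("f1", "fa", None, None, "M", None, "h1", 50, 8, 53, 7, 0),
        ("f1", "mo", None, None, "F", None, "h1", 48, 7, 51, 6, 0),
        ("f1", "t1", "fa", "mo", "M", None, None, 20, 6, 23, 5, 0),
        ("f1", "t2", "fa", "mo", "M", None, None, 20, 9, 23, 8, 0),
    ])


@pytest.fixture
def mz_family():
    """Father + mother + MZ female pair + a younger non-twin sister."""
    return make_ped([
        ("f1", "fa", None, None, "M", None, "h1", 55, 8, 58, 7, 0),
        ("f1", "mo", None, None, "F", None, "h1", 52, 7, 55, 8, 0),
        ("f1", "t1", "fa", "mo", "F", "mz1", None, 25, 6, 28, 6, 0),
        ("f1", "t2", "fa", "mo", "F", "mz1", None, 25, 7, 28, 5, 0),
        ("f1", "s1", "fa", "mo", "F", None, None, 22, 8, 25, 7, 0),
    ])


@pytest.fixture
def three_gen_family():
    """Three generations through an MZ pair: grandparents, MZ twin
    sisters and their brother, each twin's spouse and one child each.

    The children are genetic half sibs (their mothers are MZ), and each
    child is a 'genetic parent-offspring' relative of the aunt twin.
    """
    return make_ped([
        ("g1", "gpf", None, None, "M", None, "hg", 80, 7, 83, 6, 0),
        ("g1", "gpm", None, None, "F", None, "hg", 78, 8, 81, 7, 0),
        ("g1", "t1", "gpf", "gpm", "F", "mzA", "h1", 50, 7, 53, 7, 0),
        ("g1", "t2", "gpf", "gpm", "F", "mzA", "h2", 50, 8, 53, 6, 0),
        ("g1", "bro", "gpf", "gpm", "M", None, None, 47, 6, 50, 7, 0),
        ("g1", "sp1", None, None, "M", None, "h1", 52, 7, 55, 8, 0),
        ("g1", "sp2", None, None, "M", None, "h2", 51, 8, 54, 7, 0),
        ("g1", "c1", "sp1", "t1", "F", None, None, 25, 6, 28, 5, 0),
        ("g1", "c2", "sp2", "t2", "M", None, None, 24, 7, 27, 8, 0),
    ])


def gene_drop_phi(ped: Pedigree, fam_id: str, n_rep: int, seed: int) -> dict:
    """Monte-Carlo kinship by gene dropping: founders carry unique
    alleles, children inherit one random allele per parent, MZ co-twins
    copy the representative's genotype.  Returns {(i, j): (phi_hat, se)}
    for every ordered-by-id pair including self pairs.

    Independent of the recursive implementation: it simulates actual
    meioses and counts identity by descent.
    """
    rng = np.random.default_rng(seed)
    grp = ped.df[ped.df["fam_id"] == fam_id]
    members = list(grp["person_id"])
    fa = dict(zip(grp["person_id"], grp["father_id"]))
    mo = dict(zip(grp["person_id"], grp["mother_id"]))
    mz = dict(zip(grp["person_id"], grp["mz_group"]))

    # MZ representative shares its simulated genotype with co-twins
    rep = {}
    for g in set(v for v in mz.values() if v is not None):
        ids = sorted(p for p in members if mz[p] == g)
        for p in ids:
            rep[p] = ids[0]

    order = []
    done = set()

    def visit(p):
        if p in done or p not in members:
            return
        for q in (fa[p], mo[p]):
            if q is not None:
                visit(q)
        done.add(p)
        order.append(p)

    for p in members:
        visit(p)

    alleles = {}
    counter = 0
    for p in order:
        r = rep.get(p, p)
        if r != p:
            continue
        a = np.empty((n_rep, 2), dtype=np.int64)
        for k, parent in enumerate((fa[p], mo[p])):
            if parent is None or parent not in alleles and rep.get(parent, parent) not in alleles:
                a[:, k] = counter
                counter += 1
            else:
                pg = alleles[rep.get(parent, parent)]
                pick = rng.integers(0, 2, size=n_rep)
                a[:, k] = pg[np.arange(n_rep), pick]
        alleles[p] = a
    for p in members:
        if p not in alleles:
            alleles[p] = alleles[rep[p]]

    out = {}
    for i in range(len(members)):
        for j in range(i, len(members)):
            ai, aj = alleles[members[i]], alleles[members[j]]
            ibd = np.zeros(n_rep)
            for a in range(2):
                for b in range(2):
                    ibd += (ai[:, a] == aj[:, b])
            phat = ibd.mean() / 4.0
            se = ibd.std(ddof=1) / 4.0 / np.sqrt(n_rep)
            out[(members[i], members[j])] = (phat, se)
    return out
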