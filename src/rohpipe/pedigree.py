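"""Studbook parsing, tabular-method kinship and inbreeding, generation time.

Captive breeding programs are managed from studbook pedigrees in which
founders — individuals of unknown wild ancestry — have both parents
recorded as ``WILD``.  Founders are assumed unrelated and non-inbred; this
is the standard, and potentially dangerous, studbook assumption, made
explicit here so that pedigree-based inbreeding coefficients can be
contrasted with genomic (ROH-based) evidence that may contradict it.

Kinship is computed by the tabular method in pedigree (topological)
order: with ``f(i, j)`` the kinship coefficient,

    f(i, j) = ½ [ f(sire_i, j) + f(dam_i, j) ]     (j not a descendant of i)
    f(i, i) = ½ [ 1 + f(sire_i, dam_i) ]
    f(·, WILD) = 0

The inbreeding coefficient is the kinship of the parents,
``F(i) = f(sire_i, dam_i)``; it equals Wright's path-counting coefficient
Σ (½)^(n_s + n_d + 1) (1 + F_A) over common ancestors A.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

WILD = "WILD"
_MISSING_PARENTS = {"", "WILD", "UNK", "UNKNOWN", "NA", "NAN", "?"}


def _normalise_parent(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return WILD
    s = str(value).strip()
    return WILD if s.upper() in _MISSING_PARENTS else s


def _find_cycle(parents: dict[str, tuple[str, str]]) -> list[str] | None:
    """Return one parental cycle as a list of ids, or None."""
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {i: WHITE for i in parents}
    for start in parents:
        if colour[start] != WHITE:
            continue
        stack: list[tuple[str, int]] = [(start, 0)]
        path: list[str] = []
        while stack:
            node, pi = stack[-1]
            if pi == 0:
                colour[node] = GREY
                path.append(node)
            nxt = [p for p in parents.get(node, ()) if p != WILD and p in parents]
            if pi < len(nxt):
                stack[-1] = (node, pi + 1)
                child = nxt[pi]
                if colour[child] == GREY:
                    return path[path.index(child):] + [child]
                if colour[child] == WHITE:
                    stack.append((child, 0))
            else:
                colour[node] = BLACK
                path.pop()
                stack.pop()
    return None


def _parse_date(value) -> _dt.date | None:
    """ISO-8601 dates; bare years use a mid-year (July 1) convention."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.upper() in {"NA", "NAN", "UNKNOWN", "?"}:
        return None
    if s.isdigit() and len(s) == 4:
        return _dt.date(int(s), 7, 1)
    return _dt.date.fromisoformat(s[:10])


def validate_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Normalise parents, check unique ids and acyclicity."""
    out = ped.copy()
    out["id"] = out["id"].astype(str).str.strip()
    dup = out["id"][out["id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate individual id(s): {sorted(set(dup))}")
    for col in ("sire", "dam"):
        out[col] = out[col].map(_normalise_parent)
    parents = {r.id: (r.sire, r.dam) for r in out.itertuples(index=False)}
    cycle = _find_cycle(parents)
    if cycle:
        raise ValueError(f"pedigree contains a cycle: {' -> '.join(cycle)}")
    out["founder"] = (out["sire"] == WILD) & (out["dam"] == WILD)
    return out.reset_index(drop=True)


def read_studbook(path: str | Path) -> pd.DataFrame:
    """Read a studbook CSV (columns id, sire, dam, birth_date[, origin]).

    Unknown parents are normalised to ``WILD``; the result carries a
    ``founder`` flag and is validated acyclic.
    """
    ped = pd.read_csv(path, dtype=str)
    required = {"id", "sire", "dam", "birth_date"}
    missing = required - set(ped.columns)
    if missing:
        raise ValueError(f"studbook missing columns: {sorted(missing)}")
    return validate_pedigree(ped)


def _topological_order(ped: pd.DataFrame) -> list[str]:
    parents = {r.id: (r.sire, r.dam) for r in ped.itertuples(index=False)}
    order: list[str] = []
    seen: set[str] = set()

    def visit(i: str) -> None:
        if i in seen or i == WILD or i not in parents:
            return
        s, d = parents[i]
        visit(s)
        visit(d)
        seen.add(i)
        order.append(i)

    for i in parents:
        visit(i)
    return order


def kinship(ped: pd.DataFrame) -> pd.DataFrame:
    """Kinship-coefficient matrix f(i, j) by the tabular method.

    Founders are unrelated and non-inbred; f(i, i) = (1 + F(i)) / 2.
    """
    ped = validate_pedigree(ped)
    order = _topological_order(ped)
    idx = {i: k for k, i in enumerate(order)}
    parents = {r.id: (r.sire, r.dam) for r in ped.itertuples(index=False)}
    n = len(order)
    f = np.zeros((n, n))

    def pk(p: str, j: int) -> float:
        # kinship of a parent (possibly WILD / outside pedigree) with node j
        return f[idx[p], j] if p in idx else 0.0

    for k, i in enumerate(order):
        s, d = parents[i]
        for j in range(k):
            f[k, j] = f[j, k] = 0.5 * (pk(s, j) + pk(d, j))
        f_parents = f[idx[s], idx[d]] if (s in idx and d in idx) else 0.0
        f[k, k] = 0.5 * (1.0 + f_parents)
    return pd.DataFrame(f, index=order, columns=order)


def inbreeding(ped: pd.DataFrame) -> pd.Series:
    """Inbreeding coefficient per individual: F(i) = f(sire_i, dam_i)."""
    ped = validate_pedigree(ped)
    f = kinship(ped)
    out = {}
    for r in ped.itertuples(index=False):
        if r.sire in f.index and r.dam in f.index:
            out[r.id] = float(f.loc[r.sire, r.dam])
        else:
            out[r.id] = 0.0
    return pd.Series(out, name="F")


def generation_time(ped: pd.DataFrame) -> float:
    """Mean parental age (years) at offspring birth over datable pairs."""
    ped = validate_pedigree(ped)
    births = {r.id: _parse_date(r.birth_date) for r in ped.itertuples(index=False)}
    ages = []
    for r in ped.itertuples(index=False):
        child = births.get(r.id)
        if child is None:
            continue
        for parent in (r.sire, r.dam):
            pb = births.get(parent)
            if parent != WILD and pb is not None:
                ages.append((child - pb).days / 365.25)
    if not ages:
        raise ValueError("no parent-offspring pairs with known birth dates")
    return float(np.mean(ages))
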