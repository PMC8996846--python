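"""Pedigree handling: validation, completeness metrics, A-inverse, data editing.

The pedigree is a plain DataFrame with columns animal_id, sire_id, dam_id and
optionally sex and birth_date; missing parents are coded 0.  The numerator
relationship matrix inverse is built directly from Henderson's rules, with
inbreeding coefficients from the Meuwissen-Luo recursion when requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "EditThresholds",
    "read_pedigree",
    "validate_pedigree",
    "pedigree_completeness",
    "generations_traced",
    "a_inverse",
    "a_matrix",
    "edit_data",
]

MISSING = 0

PEDIGREE_COLUMNS = ["animal_id", "sire_id", "dam_id"]


@dataclass
class EditThresholds:
    """Data-editing thresholds.

    min_obs_per_cell applies to every level of every modelled class effect.
    Environmental groups are kept only when they contain at least
    eg_min_levels herd-environment levels and eg_min_records records; the
    defaults are the published thresholds for test-day (MT) and single-record
    (FS/LTT) datasets.
    """

    min_obs_per_cell: int = 2
    eg_min_levels_mt: int = 6
    eg_min_records_mt: int = 6000
    eg_min_levels_fs: int = 5
    eg_min_records_fs: int = 300

    def __post_init__(self):
        for f in ("min_obs_per_cell", "eg_min_levels_mt", "eg_min_records_mt",
                  "eg_min_levels_fs", "eg_min_records_fs"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")

    def eg_thresholds(self, dataset_kind: str) -> tuple[int, int]:
        if dataset_kind == "MT":
            return self.eg_min_levels_mt, self.eg_min_records_mt
        if dataset_kind in ("FS", "LTT", "FS/LTT"):
            return self.eg_min_levels_fs, self.eg_min_records_fs
        raise ValueError(f"unknown dataset_kind {dataset_kind!r}; expected 'MT' or 'FS'")


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path)
    missing = [c for c in PEDIGREE_COLUMNS if c not in ped.columns]
    if missing:
        raise ValueError(f"pedigree file lacks columns {missing}")
    for c in PEDIGREE_COLUMNS:
        try:
            ped[c] = ped[c].fillna(MISSING).astype(np.int64)
        except (ValueError, TypeError) as exc:
            bad = ped[pd.to_numeric(ped[c], errors="coerce").isna()].index
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"unparseable id in column {c} near file row {row}") from exc
    if "birth_date" in ped.columns:
        ped["birth_date"] = pd.to_datetime(ped["birth_date"], errors="raise")
    return ped


def _parent_map(ped: pd.DataFrame) -> dict[int, tuple[int, int]]:
    return {
        int(a): (int(s), int(d))
        for a, s, d in zip(ped["animal_id"], ped["sire_id"], ped["dam_id"])
    }


def validate_pedigree(ped: pd.DataFrame) -> dict:
    """Quality check: cycles, date consistency, sex conflicts, dangling parents.

    Returns a report dict with one list per issue class; a clean pedigree
    yields empty lists throughout.
    """
    parents = _parent_map(ped)
    known = set(parents)
    report: dict[str, list] = {
        "cycles": [],
        "date_conflicts": [],
        "sex_conflicts": [],
        "dangling_parents": [],
        "duplicate_animals": [],
    }

    dup = ped["animal_id"][ped["animal_id"].duplicated()].unique()
    report["duplicate_animals"] = [int(a) for a in dup]

    g = nx.DiGraph()
    for a, (s, d) in parents.items():
        for par in (s, d):
            if par != MISSING:
                g.add_edge(par, a)
                if par not in known:
                    report["dangling_parents"].append({"animal": a, "parent": par})
    try:
        cyc = nx.find_cycle(g)
        report["cycles"].append([int(u) for u, _ in cyc])
    except nx.NetworkXNoCycle:
        pass

    if "birth_date" in ped.columns:
        bdate = dict(zip(ped["animal_id"], ped["birth_date"]))
        for a, (s, d) in parents.items():
            for par in (s, d):
                if par in bdate and a in bdate:
                    if pd.notna(bdate[par]) and pd.notna(bdate[a]) and bdate[par] >= bdate[a]:
                        report["date_conflicts"].append({"animal": int(a), "parent": int(par)})

    if "sex" in ped.columns:
        sex = dict(zip(ped["animal_id"], ped["sex"]))
        for a, (s, d) in parents.items():
            if s in sex and str(sex[s]).upper().startswith("F"):
                report["sex_conflicts"].append({"parent": int(s), "role": "sire"})
            if d in sex and str(sex[d]).upper().startswith("M"):
                report["sex_conflicts"].append({"parent": int(d), "role": "dam"})
    return report


def _completeness(animal: int, parents: dict, depth: int) -> float:
    """Fraction-of-known-ancestors completeness over `depth` generations."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    total = 0.0
    gen = [animal]
    for g in range(1, depth + 1):
        nxt = []
        for a in gen:
            s, d = parents.get(a, (MISSING, MISSING))
            for par in (s, d):
                if par != MISSING:
                    nxt.append(par)
        total += len(nxt) / 2.0 ** g
        gen = nxt
        if not gen:
            break
    return total / depth


def pedigree_completeness(ped: pd.DataFrame, animal: int, depth: int = 5) -> float:
    """Index of pedigree completeness: harmonic mean of parental completeness.

    Each parent's completeness is the mean over generations 1..depth of the
    proportion of known ancestors in that generation of the parent's own
    pedigree; IPC = 2 C_s C_d / (C_s + C_d), zero when either parent is
    unknown (or has an empty pedigree).
    """
    parents = _parent_map(ped)
    if animal not in parents:
        raise KeyError(f"animal {animal} not in pedigree")
    s, d = parents[animal]
    # parent completeness includes the parent itself as generation-0 anchor:
    # C_parent = (1/depth) * sum_g known ancestors of the parent / 2^g,
    # and an unknown parent contributes 0
    cs = _parent_side_completeness(s, parents, depth)
    cd = _parent_side_completeness(d, parents, depth)
    if cs + cd == 0.0:
        return 0.0
    return 2.0 * cs * cd / (cs + cd)


def _parent_side_completeness(parent: int, parents: dict, depth: int) -> float:
    """Completeness of one parent's own pedigree over generations 1..depth."""
    if parent == MISSING:
        return 0.0
    return _completeness(parent, parents, depth)


def generations_traced(ped: pd.DataFrame, animals=None) -> dict:
    """Mean maximum pedigree depth and mean complete-generation equivalents.

    max-depth is the longest ancestor path; CGE sums (1/2)^g over every known
    ancestor occurrence g generations back (a fully known pedigree to depth D
    gives CGE = D).
    """
    parents = _parent_map(ped)
    if animals is None:
        animals = list(parents)
    depth_memo: dict[int, int] = {}
    cge_memo: dict[int, float] = {}

    def max_depth(a: int) -> int:
        if a in depth_memo:
            return depth_memo[a]
        s, d = parents.get(a, (MISSING, MISSING))
        best = 0
        for par in (s, d):
            if par != MISSING:
                best = max(best, 1 + max_depth(par))
        depth_memo[a] = best
        return best

    def cge(a: int) -> float:
        if a in cge_memo:
            return cge_memo[a]
        s, d = parents.get(a, (MISSING, MISSING))
        tot = 0.0
        for par in (s, d):
            if par != MISSING:
                tot += 0.5 * (1.0 + cge(par))
        cge_memo[a] = tot
        return tot

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, len(parents) + 100))
    try:
        depths = [max_depth(a) for a in animals]
        cges = [cge(a) for a in animals]
    finally:
        sys.setrecursionlimit(old)
    return {
        "mean_max_depth": float(np.mean(depths)) if depths else 0.0,
        "mean_cge": float(np.mean(cges)) if cges else 0.0,
    }


def _sorted_ids(ped: pd.DataFrame) -> list[int]:
    """Parents-before-offspring ordering (topological; birth dates break ties)."""
    parents = _parent_map(ped)
    g = nx.DiGraph()
    g.add_nodes_from(parents)
    for a, (s, d) in parents.items():
        for par in (s, d):
            if par != MISSING and par in parents:
                g.add_edge(par, a)
    try:
        return list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible as exc:
        raise ValueError("pedigree contains a cycle; cannot order chronologically") from exc


def inbreeding_coefficients(ped: pd.DataFrame) -> dict[int, float]:
    """Inbreeding by the Meuwissen-Luo recursion (via the tabular diagonal).

    Exact for any pedigree; implemented through the L'DL factorisation of A,
    computing each animal's diagonal element A_ii = 1 + F_i.
    """
    order = _sorted_ids(ped)
    parents = _parent_map(ped)
    idx = {a: i for i, a in enumerate(order)}
    n = len(order)
    f = np.zeros(n)          # inbreeding
    d = np.zeros(n)          # Mendelian-sampling variances
    for i, a in enumerate(order):
        s, dd = parents[a]
        si = idx.get(s, -1) if s != MISSING else -1
        di = idx.get(dd, -1) if dd != MISSING else -1
        fs = f[si] if si >= 0 else -1.0  # convention: unknown parent F = -1
        fd = f[di] if di >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (fs + fd)
        if si < 0 and di < 0:
            f[i] = 0.0
            continue
        # accumulate ancestor contributions (Meuwissen & Luo walk):
        # A_ii = sum_j L_ij^2 d_j, walking ancestors youngest-first
        import heapq

        fi = -1.0
        heap = [-i]
        coef = {i: 1.0}
        while heap:
            j = -heapq.heappop(heap)
            cj = coef.pop(j)
            fi += cj * cj * d[j]
            aj = order[j]
            sj, dj = parents[aj]
            for par in (sj, dj):
                if par == MISSING:
                    continue
                pi = idx.get(par, -1)
                if pi < 0:
                    continue
                if pi in coef:
                    coef[pi] += 0.5 * cj
                else:
                    coef[pi] = 0.5 * cj
                    heapq.heappush(heap, -pi)
        f[i] = fi
    return {order[i]: float(f[i]) for i in range(n)}


def a_inverse(ped: pd.DataFrame, use_inbreeding: bool = False):
    """Sparse inverse of the numerator relationship matrix (Henderson's rules).

    Returns (A_inverse as CSR, ids in parents-before-offspring order).  With
    use_inbreeding, Mendelian-sampling variances account for parental
    inbreeding; otherwise the classic 1 / (2, 4/3, 1) weights apply.
    Unknown parents are treated as missing (no unknown-parent groups).
    """
    order = _sorted_ids(ped)
    parents = _parent_map(ped)
    idx = {a: i for i, a in enumerate(order)}
    n = len(order)
    if use_inbreeding:
        fmap = inbreeding_coefficients(ped)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for a in order:
        i = idx[a]
        s, d = parents[a]
        si = idx.get(s, -1) if s != MISSING else -1
        di = idx.get(d, -1) if d != MISSING else -1
        if use_inbreeding:
            fs = fmap[s] if si >= 0 else -1.0
            fd = fmap[d] if di >= 0 else -1.0
            mend = 0.5 - 0.25 * (fs + fd)
        else:
            n_known = (si >= 0) + (di >= 0)
            mend = (1.0, 0.75, 0.5)[n_known]
        b = 1.0 / mend
        add(i, i, b)
        for pi in (si, di):
            if pi >= 0:
                add(i, pi, -b / 2.0)
                add(pi, i, -b / 2.0)
        for pi in (si, di):
            for pj in (si, di):
                if pi >= 0 and pj >= 0:
                    add(pi, pj, b / 4.0)
    ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    ainv.sum_duplicates()
    return ainv, np.asarray(order, dtype=np.int64)


def write_matrix_coo(matrix, ids, path) -> None:
    """Export a (sparse) symmetric matrix as coordinate CSV (row, col, value),
    using pedigree ids as labels."""
    coo = sp.coo_matrix(matrix)
    ids = np.asarray(ids)
    pd.DataFrame({
        "row": ids[coo.row], "col": ids[coo.col], "value": coo.data,
    }).to_csv(path, index=False)


def a_matrix(ped: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Dense numerator relationship matrix by the tabular method.

    Quadratic in pedigree size; intended for small pedigrees and as the
    independent cross-check of `a_inverse`.
    """
    order = _sorted_ids(ped)
    parents = _parent_map(ped)
    idx = {a: i for i, a in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for a in order:
        i = idx[a]
        s, d = parents[a]
        si = idx.get(s, -1) if s != MISSING else -1
        di = idx.get(d, -1) if d != MISSING else -1
        asd = A[si, di] if si >= 0 and di >= 0 else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        for j in range(i):
            val = 0.0
            if si >= 0:
                val += 0.5 * A[j, si]
            if di >= 0:
                val += 0.5 * A[j, di]
            A[i, j] = A[j, i] = val
    return A, np.asarray(order, dtype=np.int64)


def edit_data(
    phenotypes: pd.DataFrame,
    env_assignment: pd.DataFrame,
    thresholds: EditThresholds,
    dataset_kind: str,
    class_columns: list[str] | None = None,
    audit_path=None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the editing rules: per-cell minimum counts and EG viability.

    Drops records in any level of any modelled class effect with fewer than
    min_obs_per_cell records (iterated to a fixed point, since removing one
    cell can empty another), then drops whole environmental groups that fail
    the level-count / record-count thresholds for the dataset kind.  EG level
    counts are the number of distinct herd-environment (HEG) levels in the
    group.  Returns the filtered table and an audit log of removals per rule.
    """
    min_levels, min_records = thresholds.eg_thresholds(dataset_kind)
    df = phenotypes.copy()
    audit: list[dict] = []

    if "eg_label" not in df.columns:
        if "eg_label" not in env_assignment.columns or "herd_id" not in env_assignment.columns:
            raise ValueError("need eg_label on phenotypes or (herd_id, eg_label) assignment")
        df = df.merge(env_assignment[["herd_id", "eg_label"]], on="herd_id", how="left")
    if df["eg_label"].isna().any():
        raise ValueError("records with no environmental-group label")
    if "heg_level" not in df.columns:
        df["heg_level"] = df["herd_id"].astype(str) + ":" + df["eg_label"].astype(str)

    # EG viability first (group-level rule), then per-cell counts
    sizes = df.groupby("eg_label").agg(
        n_levels=("heg_level", "nunique"), n_records=("heg_level", "size")
    )
    bad = sizes[(sizes["n_levels"] < min_levels) | (sizes["n_records"] < min_records)]
    for eg, row in bad.iterrows():
        audit.append({
            "rule": "eg_thresholds", "eg_label": str(eg),
            "n_levels": int(row["n_levels"]), "n_records": int(row["n_records"]),
            "removed": int(row["n_records"]),
        })
    df = df[~df["eg_label"].isin(bad.index)]

    cols = class_columns or []
    changed = True
    while changed:
        changed = False
        for col in cols:
            counts = df[col].value_counts()
            small = counts[counts < thresholds.min_obs_per_cell]
            if len(small):
                audit.append({
                    "rule": "min_obs_per_cell", "column": col,
                    "levels_removed": int(len(small)),
                    "removed": int(small.sum()),
                })
                df = df[~df[col].isin(small.index)]
                changed = True

    audit.append({"rule": "summary", "records_in": int(len(phenotypes)),
                  "records_out": int(len(df))})
    if audit_path is not None:
        with open(audit_path, "w") as fh:
            for entry in audit:
                fh.write(json.dumps(entry) + "\n")
    return df.reset_index(drop=True), audit
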