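"""Social-network quantification for the troop.

Turns the three raw observation streams — proximity scans, unidirectional
conflict outcomes and grooming — into the dyadic and individual
covariates of the playback analysis: friendship scores (dyadic
association), Elo ratings (competitive success), maternal-kin coding,
eigenvector centrality with a central/peripheral split, Mantel
matrix-correlation tests (including the split-half network-stability
check) and the playback-condition dyad selector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EloState",
    "CentralityResult",
    "MantelResult",
    "parse_neighbours",
    "build_association_matrix",
    "zscore_dyadic",
    "elo_ratings",
    "eigenvector_centrality",
    "mantel_test",
    "stability_split",
    "kinship_matrix",
    "select_condition_dyads",
]


def parse_neighbours(cell) -> list[str]:
    """Split a ';'-separated neighbour cell; empty/NaN means no neighbours."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    s = str(cell).strip()
    return [t for t in s.split(";") if t] if s else []


def build_association_matrix(scans: pd.DataFrame, mode: str = "count",
                             individuals: list[str] | None = None) -> pd.DataFrame:
    """Dyadic friendship scores from proximity scans.

    Entry (i, j) counts the scans in which one of the pair was the focal
    and the other was recorded within 2 m (focal-neighbour occurrences
    pooled symmetrically).  ``mode="rate"`` divides each dyad by the
    combined scan effort of its two members.
    """
    if scans.empty:
        raise ValueError("scan table is empty")
    if mode not in ("count", "rate"):
        raise ValueError("mode must be 'count' or 'rate'")
    focals = scans["focal_id"].astype(str)
    nb_lists = scans["neighbour_ids"].map(parse_neighbours)
    if individuals is None:
        ids = sorted(set(focals) | {i for nb in nb_lists for i in nb})
    else:
        ids = list(individuals)
        unknown = sorted({i for nb in nb_lists for i in nb} - set(ids))
        if unknown:
            raise ValueError(f"neighbour ids not in the roster: {unknown}")
    pos = {i: k for k, i in enumerate(ids)}
    a = np.zeros((len(ids), len(ids)))
    for f, nbs in zip(focals, nb_lists):
        fi = pos[f]
        for nbid in nbs:
            if nbid == f:
                raise ValueError(f"focal {f!r} listed as its own neighbour")
            j = pos[nbid]
            a[fi, j] += 1
            a[j, fi] += 1
    if mode == "rate":
        effort = focals.value_counts().reindex(ids).fillna(0).to_numpy(dtype=float)
        denom = effort[:, None] + effort[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(denom > 0, a / denom, 0.0)
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=ids, columns=ids)


def zscore_dyadic(matrix: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Z-score the off-diagonal dyadic values of a symmetric matrix.

    The default convention divides by the population sd (ddof=0), so the
    two-value set {0, 2} maps to {-1, +1}.  The diagonal is left at 0.
    """
    a = matrix.to_numpy(dtype=float).copy()
    mask = ~np.eye(len(a), dtype=bool)
    vals = a[mask]
    sd = vals.std(ddof=ddof)
    if sd == 0:
        raise ValueError("dyadic values have zero variance; cannot z-score")
    a[mask] = (vals - vals.mean()) / sd
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=matrix.index, columns=matrix.columns)


@dataclass(frozen=True)
class EloState:
    """Final Elo ratings plus the full per-event trajectory."""

    ratings: dict[str, float]
    k: float
    start_value: float
    history: pd.DataFrame  # one row per event: order, winner, loser, ratings after

    def ranking(self) -> list[str]:
        """Individuals from highest to lowest final rating (ties by id)."""
        return sorted(self.ratings, key=lambda i: (-self.ratings[i], i))


def elo_ratings(conflicts: pd.DataFrame, k: float = 100.0,
                start: float = 1000.0,
                individuals: list[str] | None = None) -> EloState:
    """Sequential Elo ratings from ordered unidirectional conflicts.

    Expected winner probability is the logistic curve on the rating
    difference with scale 400; the winner gains ``k * (1 - E)`` and the
    loser loses the same, so the rating sum is conserved.
    """
    events = conflicts.sort_values("order") if "order" in conflicts else conflicts
    ids = set(individuals or [])
    ids |= set(events["winner_id"].astype(str)) | set(events["loser_id"].astype(str))
    if individuals is not None:
        unknown = (set(events["winner_id"]) | set(events["loser_id"])) - set(individuals)
        if unknown:
            raise ValueError(f"conflict ids not in the roster: {sorted(unknown)}")
    ratings = {i: float(start) for i in sorted(ids)}
    hist = []
    for _, ev in events.iterrows():
        w, l = str(ev["winner_id"]), str(ev["loser_id"])
        if w == l:
            raise ValueError(f"event has winner == loser ({w!r})")
        e_w = 1.0 / (1.0 + 10.0 ** ((ratings[l] - ratings[w]) / 400.0))
        delta = k * (1.0 - e_w)
        ratings[w] += delta
        ratings[l] -= delta
        hist.append({"order": ev.get("order", len(hist) + 1), "winner_id": w,
                     "loser_id": l, "winner_rating": ratings[w],
                     "loser_rating": ratings[l]})
    return EloState(ratings=ratings, k=k, start_value=start,
                    history=pd.DataFrame(hist))


@dataclass(frozen=True)
class CentralityResult:
    scores: dict[str, float]      # max-normalised to 1
    central_set: frozenset[str]   # top ceil(n/2)
    peripheral_set: frozenset[str]


def eigenvector_centrality(assoc: pd.DataFrame, tol: float = 1e-12,
                           max_iter: int = 10_000) -> CentralityResult:
    """Eigenvector centrality of the weighted association network.

    Scores are the dominant eigenvector of the (symmetric, non-negative)
    association matrix, computed by power iteration and max-normalised
    to 1.  The top ceil(n/2) individuals form the central set, the rest
    the peripheral set; ties broken by id.
    """
    a = assoc.to_numpy(dtype=float)
    ids = list(assoc.index)
    if a.size == 0 or not np.any(a):
        raise ValueError("association matrix is empty or all-zero")
    if a.min() < 0:
        raise ValueError("association weights must be non-negative")
    # identity shift keeps the dominant eigenvector but prevents the
    # sign-flip oscillation of power iteration on bipartite graphs
    shifted = a + a.max() * np.eye(len(ids))
    v = np.ones(len(ids)) / np.sqrt(len(ids))
    for _ in range(max_iter):
        nv = shifted @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            raise ValueError("matrix annihilates the start vector; graph too sparse")
        nv /= norm
        if np.linalg.norm(nv - v) < tol:
            v = nv
            break
        v = nv
    v = np.abs(v)
    v /= v.max()
    scores = {i: float(s) for i, s in zip(ids, v)}
    order = sorted(ids, key=lambda i: (-scores[i], i))
    n_central = int(np.ceil(len(ids) / 2))
    central = frozenset(order[:n_central])
    return CentralityResult(scores=scores, central_set=central,
                            peripheral_set=frozenset(ids) - central)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    tail: str = "greater"


def _upper(a: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(len(a), 1)
    return a[iu]


def mantel_test(m1: pd.DataFrame, m2: pd.DataFrame, n_perm: int = 5000,
                seed: int = 0) -> MantelResult:
    """One-tailed Mantel test of association between two dyadic matrices.

    r is the Pearson correlation over upper-triangle dyads; the null
    permutes individuals (rows and columns of the second matrix jointly);
    p = (#{r_perm >= r_obs} + 1) / (n_perm + 1).
    """
    if list(m1.index) != list(m2.index) or len(m1) != len(m2):
        raise ValueError("matrices must share the same individuals in order")
    a = m1.to_numpy(dtype=float)
    b = m2.to_numpy(dtype=float)
    x = _upper(a)
    if x.std() == 0 or _upper(b).std() == 0:
        raise ValueError("a matrix has zero dyadic variance")
    xc = x - x.mean()
    xs = np.sqrt((xc ** 2).sum())

    def _corr(bm: np.ndarray) -> float:
        y = _upper(bm)
        yc = y - y.mean()
        return float((xc @ yc) / (xs * np.sqrt((yc ** 2).sum())))

    r_obs = _corr(b)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(len(b))
        if _corr(b[np.ix_(p, p)]) >= r_obs:
            exceed += 1
    return MantelResult(r=r_obs, p_value=(exceed + 1.0) / (n_perm + 1.0),
                        n_perm=n_perm)


def stability_split(scans: pd.DataFrame, split: float = 0.5, n_perm: int = 5000,
                    seed: int = 0, mode: str = "count") -> MantelResult:
    """Split-half stability of the association network.

    Scans are split chronologically per focal at the given fraction; an
    association matrix is built on each block and the two compared with
    a Mantel test.  A stable network yields a strong positive r.
    """
    if not 0.0 < split < 1.0:
        raise ValueError("split must lie in (0, 1)")
    parts = {True: [], False: []}
    for focal, grp in scans.groupby("focal_id", sort=False):
        grp = grp.sort_values("scan_index")
        cut = int(round(split * len(grp)))
        parts[True].append(grp.iloc[:cut])
        parts[False].append(grp.iloc[cut:])
    first = pd.concat(parts[True], ignore_index=True)
    second = pd.concat(parts[False], ignore_index=True)
    ids = sorted(set(scans["focal_id"].astype(str))
                 | {i for nb in scans["neighbour_ids"].map(parse_neighbours) for i in nb})
    for name, block in (("first", first), ("second", second)):
        if block.empty or not any(parse_neighbours(c) for c in block["neighbour_ids"]):
            raise ValueError(
                f"the {name} block has no co-occurrences; use a less extreme split"
            )
    a1 = build_association_matrix(first, mode=mode, individuals=ids)
    a2 = build_association_matrix(second, mode=mode, individuals=ids)
    return mantel_test(a1, a2, n_perm=n_perm, seed=seed)


def kinship_matrix(matrilines: dict[str, str]) -> pd.DataFrame:
    """Binary maternal-kin matrix: 1 iff two individuals share a matriline."""
    ids = sorted(matrilines)
    missing = [i for i in ids if matrilines[i] in (None, "")]
    if missing:
        raise ValueError(f"individuals without a matriline label: {missing}")
    lab = np.array([matrilines[i] for i in ids])
    k = (lab[:, None] == lab[None, :]).astype(int)
    return pd.DataFrame(k, index=ids, columns=ids)


def _low(score: float, ref_scores: np.ndarray) -> bool:
    return score < np.median(ref_scores)


def select_condition_dyads(subject: str, assoc: pd.DataFrame, kin: pd.DataFrame,
                           sexes: dict[str, str], centrality: CentralityResult,
                           condition: int,
                           ranks: dict[str, int] | None = None
                           ) -> tuple[str, str] | None:
    """Pick the caller dyad (A, B) for one subject and condition, or
    ``None`` when the condition is infeasible for that subject.

    Conditions (callers are always female and never the subject):

    1. A = the female with the highest friendship score with the subject;
       B = A's strongest female associate among those with a low (below
       subject-median) friendship with the subject.
    2. A as in 1; B = a female with low friendship with both A and the
       subject (the weakest such associate of A).
    3. A and B are friends with each other but both have low friendship
       with the subject.  Collected only on peripheral subjects; central
       subjects return infeasible, as no qualifying dyad exists for them.
    4. As 3 but A and B are also non-friends of each other (the weakest
       qualifying pair).  Peripheral subjects only.
    5. A = a matriarch (top-ranked female of a matriline when ``ranks``
       is given, else lowest id); B = a female of the same matriline.
    6. A = a matriarch; B = a female of a different matriline.

    "Low friendship" means below the median of the reference
    individual's scores with the eligible females.  Ties break by id.
    """
    if subject not in assoc.index:
        raise ValueError(f"unknown subject {subject!r}")
    if condition not in range(1, 7):
        raise ValueError("condition must be in 1..6")
    females = sorted(i for i in assoc.index if sexes.get(i) == "F" and i != subject)
    if len(females) < 3:
        return None

    def f(i: str, j: str) -> float:
        return float(assoc.loc[i, j])

    subj_scores = np.array([f(subject, x) for x in females])

    if condition in (1, 2):
        a = min(females, key=lambda x: (-f(subject, x), x))
        cands = [x for x in females
                 if x != a and _low(f(subject, x), subj_scores)]
        if not cands:
            return None
        if condition == 1:
            b = min(cands, key=lambda x: (-f(a, x), x))
        else:
            a_scores = np.array([f(a, x) for x in females if x != a])
            cands = [x for x in cands if _low(f(a, x), a_scores)]
            if not cands:
                return None
            b = min(cands, key=lambda x: (f(a, x), x))
        return (a, b)

    if condition in (3, 4):
        if subject in centrality.central_set:
            return None
        non_friends = [x for x in females if _low(f(subject, x), subj_scores)]
        if len(non_friends) < 2:
            return None
        pairs = []
        for i, a in enumerate(non_friends):
            a_scores = np.array([f(a, x) for x in females if x != a])
            for b in non_friends[i + 1:]:
                friends_ab = not _low(f(a, b), a_scores)
                if (condition == 3) == friends_ab:
                    pairs.append((a, b))
        if not pairs:
            return None
        key = (lambda p: (-f(*p), p)) if condition == 3 else (lambda p: (f(*p), p))
        return min(pairs, key=key)

    # conditions 5-6: a matriarch in conflict with kin / non-kin
    matriline_of = {}
    for i in kin.index:
        same = tuple(sorted(j for j in kin.index if kin.loc[i, j] == 1))
        matriline_of[i] = same
    fem_set = set(females)
    matriarch_key = (lambda x: (ranks.get(x, 10 ** 9), x)) if ranks else (lambda x: x)
    for members in sorted(set(matriline_of[i] for i in kin.index)):
        fem_members = [m for m in members if m in fem_set]
        if not fem_members:
            continue
        a = min(fem_members, key=matriarch_key)
        if condition == 5:
            partners = [m for m in fem_members if m != a]
        else:
            partners = [x for x in females if x not in members]
        if partners:
            b = min(partners)
            return (a, b)
    return None
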