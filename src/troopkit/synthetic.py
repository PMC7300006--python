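"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline — caller-identity discrimination,
social-network metrics, playback-condition construction and looking-time
models — can be exercised on data produced here, where the true caller
effects, the true affinity network, the true dominance order and the true
condition effects are all planted and therefore recoverable.

All generators are pure functions of their spec (including the seed): the
same spec yields bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

FEATURE_NAMES = ["DFB1", "DFA2", "PF", "FR", "duration"]

__all__ = [
    "FEATURE_NAMES",
    "CallSimSpec",
    "TroopSimSpec",
    "TrialSimSpec",
    "TroopData",
    "gen_call_features",
    "gen_call_waveforms",
    "gen_troop_observations",
    "gen_trials",
    "matriline_affinity",
]


@dataclass(frozen=True)
class CallSimSpec:
    """Hierarchical generator spec for call-unit acoustic features.

    Units are nested in calling bouts and bouts in callers: a unit's
    feature vector is ``caller mean + bout effect + unit noise``, all
    additive Gaussian.  ``feature_means`` is the grand mean of the five
    features; per-caller means are drawn around it with spread
    ``between_caller_sd``.

    The waveform fields (``f0_range_hz``, ``n_harmonics``,
    ``duration_range_ms``) govern :func:`gen_call_waveforms` only: each
    unit is a harmonic tonal burst, emulating a tonal agonistic call with
    energy concentrated in the 2-10 kHz band.
    """

    n_callers: int = 9
    bouts_per_caller: int = 6
    units_per_bout: tuple[int, int] = (2, 12)
    feature_means: tuple[float, ...] = (3500.0, 4500.0, 5000.0, 4000.0, 250.0)
    between_caller_sd: tuple[float, ...] = (300.0, 300.0, 400.0, 400.0, 40.0)
    within_caller_sd: tuple[float, ...] = (150.0, 150.0, 200.0, 200.0, 25.0)
    bout_sd: tuple[float, ...] = (100.0, 100.0, 120.0, 120.0, 15.0)
    seed: int = 0
    # waveform-only parameters
    f0_range_hz: tuple[float, float] = (2000.0, 6000.0)
    n_harmonics: int = 3
    duration_range_ms: tuple[float, float] = (150.0, 400.0)

    def __post_init__(self) -> None:
        if self.n_callers < 2:
            raise ValueError("n_callers must be >= 2")
        if self.bouts_per_caller < 1:
            raise ValueError("bouts_per_caller must be >= 1")
        lo, hi = self.units_per_bout
        if lo < 1 or hi < lo:
            raise ValueError("units_per_bout must be a range with min >= 1")
        for name in ("feature_means", "between_caller_sd", "within_caller_sd", "bout_sd"):
            vec = getattr(self, name)
            if len(vec) != len(FEATURE_NAMES):
                raise ValueError(f"{name} must have {len(FEATURE_NAMES)} entries")
            if name != "feature_means" and any(v < 0 for v in vec):
                raise ValueError(f"{name} entries must be >= 0")


def gen_call_features(spec: CallSimSpec) -> pd.DataFrame:
    """Generate a call-unit feature table with bout-nested caller structure.

    Returns a DataFrame with columns ``unit_id, bout_id, caller_id`` and
    the five acoustic features.  Bout ids are unique across callers; all
    units of a bout share one caller.
    """
    rng = np.random.default_rng(spec.seed)
    grand = np.asarray(spec.feature_means, dtype=float)
    between = np.asarray(spec.between_caller_sd, dtype=float)
    within = np.asarray(spec.within_caller_sd, dtype=float)
    bout_s = np.asarray(spec.bout_sd, dtype=float)

    caller_means = grand + between * rng.standard_normal((spec.n_callers, len(grand)))
    lo, hi = spec.units_per_bout
    rows = []
    bout_counter = 0
    unit_counter = 0
    for c in range(spec.n_callers):
        caller = f"C{c + 1:02d}"
        for _ in range(spec.bouts_per_caller):
            bout_counter += 1
            bout = f"B{bout_counter:03d}"
            n_units = int(rng.integers(lo, hi + 1))
            bout_eff = bout_s * rng.standard_normal(len(grand))
            feats = (
                caller_means[c]
                + bout_eff
                + within * rng.standard_normal((n_units, len(grand)))
            )
            for u in range(n_units):
                unit_counter += 1
                rows.append(
                    {"unit_id": f"U{unit_counter:04d}", "bout_id": bout, "caller_id": caller}
                    | dict(zip(FEATURE_NAMES, feats[u]))
                )
    return pd.DataFrame(rows)


def _harmonic_burst(rng: np.random.Generator, f0: float, n_harm: int,
                    dur_s: float, rate: int) -> tuple[np.ndarray, float]:
    """One tonal burst: f0 plus decaying harmonics, Hann-enveloped."""
    n = int(round(dur_s * rate))
    t = np.arange(n) / rate
    sig = np.zeros(n)
    for h in range(1, n_harm + 1):
        f = f0 * h
        if f >= rate / 2:
            break
        amp = 1.0 / h  # 6 dB/harmonic roll-off
        sig += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    env = np.hanning(n) if n > 1 else np.ones(n)
    sig *= env
    peak = np.max(np.abs(sig))
    if peak > 0:
        sig = 0.9 * sig / peak
    return sig, f0


def gen_call_waveforms(spec: CallSimSpec, out_dir: str | Path,
                       rate: int = 44100) -> pd.DataFrame:
    """Write one WAV per call unit (16-bit PCM mono) plus a metadata table.

    Each file contains a harmonic tonal burst whose fundamental and
    duration are drawn from the spec ranges; the metadata table records
    the planted fundamental, harmonic count, duration and file path, and
    is also written to ``metadata.csv`` in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    lo_f, hi_f = spec.f0_range_hz
    lo_d, hi_d = spec.duration_range_ms
    lo_u, hi_u = spec.units_per_bout

    rows = []
    bout_counter = 0
    unit_counter = 0
    for c in range(spec.n_callers):
        caller = f"C{c + 1:02d}"
        # each caller has a characteristic fundamental region
        caller_f0 = rng.uniform(lo_f, hi_f)
        for _ in range(spec.bouts_per_caller):
            bout_counter += 1
            bout = f"B{bout_counter:03d}"
            n_units = int(rng.integers(lo_u, hi_u + 1))
            for _ in range(n_units):
                unit_counter += 1
                unit = f"U{unit_counter:04d}"
                f0 = float(np.clip(caller_f0 + rng.normal(0, 100.0), lo_f, hi_f))
                dur_ms = float(rng.uniform(lo_d, hi_d))
                sig, f0 = _harmonic_burst(rng, f0, spec.n_harmonics, dur_ms / 1000.0, rate)
                path = out_dir / f"{unit}.wav"
                wavfile.write(path, rate, (sig * 32767).astype(np.int16))
                rows.append({
                    "unit_id": unit, "bout_id": bout, "caller_id": caller,
                    "file": str(path), "f0_hz": f0,
                    "n_harmonics": spec.n_harmonics,
                    "duration_ms": len(sig) / rate * 1000.0,
                })
    meta = pd.DataFrame(rows)
    meta.to_csv(out_dir / "metadata.csv", index=False)
    return meta


# ---------------------------------------------------------------------------
# Troop observations


def matriline_affinity(matrilines: dict[str, str], within: float = 0.45,
                       between: float = 0.08, heterogeneity: float = 0.6,
                       seed: int | None = None) -> pd.DataFrame:
    """Planted affinity matrix with community structure along matrilines.

    Dyads in the same matriline get a baseline probability ``within`` of
    being recorded as neighbours on any scan, other dyads ``between``.
    ``heterogeneity`` adds deterministic log-normal dyad-level variation
    around those baselines (sd of the log factor), so that friendship is
    correlated with, but not reducible to, kinship — as in real groups,
    where particular cross-matriline dyads can be close associates.
    Set it to 0 for a pure block structure.
    """
    ids = sorted(matrilines)
    n = len(ids)
    a = np.full((n, n), between, dtype=float)
    for i in range(n):
        for j in range(n):
            if matrilines[ids[i]] == matrilines[ids[j]]:
                a[i, j] = within
    if heterogeneity > 0:
        rng = np.random.default_rng(0 if seed is None else seed)
        jit = np.exp(rng.normal(0.0, heterogeneity, size=(n, n)))
        jit = np.triu(jit, 1)
        jit = jit + jit.T
        a = np.clip(a * jit, 0.01, 0.9)
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=ids, columns=ids)


@dataclass(frozen=True)
class TroopSimSpec:
    """Generator spec for the three observation streams of a troop study:
    proximity scans, unidirectional conflicts and a grooming matrix.

    ``planted_affinity`` gives per-dyad neighbour probabilities per scan;
    ``true_ranks`` is the latent dominance order (1 = top) and
    ``rank_steepness`` the probability that a conflict is won by the
    higher-ranking member.  Defaults emulate a group of 19 adults in five
    matrilines observed for 160 scans per focal with 145 conflicts.
    """

    n_individuals: int = 19
    sexes: dict[str, str] | None = None
    matrilines: dict[str, str] | None = None
    true_ranks: dict[str, int] | None = None
    planted_affinity: pd.DataFrame | None = None
    n_scans_per_focal: int = 160
    n_conflicts: int = 145
    rank_steepness: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 3:
            raise ValueError("n_individuals must be >= 3")
        if not 0.5 <= self.rank_steepness <= 1.0:
            raise ValueError("rank_steepness must lie in [0.5, 1]")
        if self.planted_affinity is not None:
            a = self.planted_affinity.to_numpy(dtype=float)
            if not np.allclose(a, a.T):
                raise ValueError("planted_affinity must be symmetric")
            if not np.allclose(np.diag(a), 0.0):
                raise ValueError("planted_affinity must have zero diagonal")
            if a.min() < 0 or a.max() > 1:
                raise ValueError("planted_affinity entries must lie in [0, 1]")

    def resolve(self) -> "TroopSimSpec":
        """Fill unset fields deterministically from the seed."""
        rng = np.random.default_rng(self.seed)
        if self.planted_affinity is not None:
            ids = [str(i) for i in self.planted_affinity.index]
        elif self.matrilines is not None:
            ids = sorted(self.matrilines)
        elif self.sexes is not None:
            ids = sorted(self.sexes)
        else:
            ids = [f"I{i + 1:02d}" for i in range(self.n_individuals)]
        if len(ids) != self.n_individuals:
            raise ValueError("n_individuals does not match the supplied ids")
        sexes = self.sexes or {
            i: ("F" if k % 3 != 2 else "M") for k, i in enumerate(ids)
        }  # roughly two-thirds female, as in a matrilineal macaque group
        if self.matrilines is None:
            n_mat = min(5, self.n_individuals)
            labels = rng.integers(0, n_mat, size=self.n_individuals)
            matrilines = {i: f"M{l + 1}" for i, l in zip(ids, labels)}
        else:
            matrilines = self.matrilines
        if self.true_ranks is None:
            order = rng.permutation(self.n_individuals)
            true_ranks = {ids[k]: int(order[k]) + 1 for k in range(self.n_individuals)}
        else:
            true_ranks = self.true_ranks
        affinity = (
            self.planted_affinity
            if self.planted_affinity is not None
            else matriline_affinity(matrilines, seed=self.seed)
        )
        return dataclasses.replace(
            self, sexes=sexes, matrilines=matrilines,
            true_ranks=true_ranks, planted_affinity=affinity,
        )


@dataclass
class TroopData:
    """Bundle of generated troop observation streams plus the resolved spec."""

    scans: pd.DataFrame       # focal_id, scan_index, neighbour_ids (';'-joined)
    conflicts: pd.DataFrame   # winner_id, loser_id, order
    grooming: pd.DataFrame    # square matrix, ids as index/columns
    spec: TroopSimSpec


def gen_troop_observations(spec: TroopSimSpec) -> TroopData:
    """Generate proximity scans, conflicts and grooming for one troop.

    Scan neighbours are independent Bernoulli draws with the planted
    dyadic probability; each conflict pits a uniformly drawn dyad, won by
    the higher-ranked member with probability ``rank_steepness``; the
    grooming matrix is a Poisson transform of the planted affinity (so it
    is a monotone, noisy image of the same network).
    """
    spec = spec.resolve()
    rng = np.random.default_rng(spec.seed)
    ids = list(spec.planted_affinity.index)
    aff = spec.planted_affinity.to_numpy(dtype=float)
    n = len(ids)

    scan_rows = []
    for fi, focal in enumerate(ids):
        draws = rng.random((spec.n_scans_per_focal, n)) < aff[fi]
        draws[:, fi] = False
        for s in range(spec.n_scans_per_focal):
            nb = [ids[j] for j in np.nonzero(draws[s])[0]]
            scan_rows.append({
                "focal_id": focal, "scan_index": s + 1,
                "neighbour_ids": ";".join(nb),
            })
    scans = pd.DataFrame(scan_rows)

    ranks = np.array([spec.true_ranks[i] for i in ids])
    conflict_rows = []
    for e in range(spec.n_conflicts):
        i, j = rng.choice(n, size=2, replace=False)
        hi, lo = (i, j) if ranks[i] < ranks[j] else (j, i)  # rank 1 = top
        if rng.random() < spec.rank_steepness:
            w, l = hi, lo
        else:
            w, l = lo, hi
        conflict_rows.append({"winner_id": ids[w], "loser_id": ids[l], "order": e + 1})
    conflicts = pd.DataFrame(conflict_rows)

    lam = 20.0 * aff
    g = rng.poisson(lam).astype(float)
    g = np.triu(g, 1)
    g = g + g.T
    grooming = pd.DataFrame(g, index=ids, columns=ids)

    return TroopData(scans=scans, conflicts=conflicts, grooming=grooming, spec=spec)


# ---------------------------------------------------------------------------
# Playback trials


@dataclass(frozen=True)
class TrialSimSpec:
    """Generator spec for playback trials with planted condition effects.

    Look time (seconds, truncated to the 30-s observation window) is
    ``condition mean + subject intercept + order_slope * order + noise``
    plus optional planted covariate effects on the z-scored dyadic
    covariates (all default 0).
    """

    n_subjects: int = 16
    conditions: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    condition_means: dict[int, float] = field(
        default_factory=lambda: {1: 9.5, 2: 4.3, 3: 7.9, 4: 5.4, 5: 6.5, 6: 5.1}
    )
    subject_sd: float = 1.5
    residual_sd: float = 3.0
    order_slope: float = 0.0
    friendship_slope: float = 0.0
    relatedness_effect: float = 0.0
    elo_diff_slope: float = 0.0
    centrality_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.condition_means.values()):
            raise ValueError("condition_means must be >= 0")
        if not set(self.conditions) <= set(range(1, 7)):
            raise ValueError("conditions must be a subset of {1..6}")


def gen_trials(spec: TrialSimSpec, troop: TroopData) -> pd.DataFrame:
    """Generate one playback-trial table from troop observations.

    Dyads for each subject x condition come from
    :func:`troopkit.social.select_condition_dyads`; infeasible
    combinations (e.g. central subjects in conditions 3-4) are emitted
    with ``skipped=True`` and no look time.  Trial order is randomised
    per subject over its feasible trials.
    """
    from . import social  # deferred: social imports nothing from here

    spec_t = spec
    troop_spec = troop.spec
    rng = np.random.default_rng(spec_t.seed)

    assoc = social.build_association_matrix(troop.scans)
    kin = social.kinship_matrix(troop_spec.matrilines)
    cent = social.eigenvector_centrality(assoc)
    elo = social.elo_ratings(troop.conflicts)
    ranks = {i: troop_spec.true_ranks[i] for i in assoc.index}

    ids = list(assoc.index)
    subjects = sorted(rng.choice(ids, size=min(spec_t.n_subjects, len(ids)),
                                 replace=False).tolist())

    rows = []
    for subj in subjects:
        feasible = []
        for cond in spec_t.conditions:
            dyad = social.select_condition_dyads(
                subj, assoc, kin, troop_spec.sexes, cent, cond, ranks=ranks,
            )
            if dyad is None:
                rows.append({
                    "subject_id": subj, "condition": cond, "caller_A": None,
                    "caller_B": None, "skipped": True,
                })
            else:
                feasible.append((cond, dyad))
        order = rng.permutation(len(feasible)) + 1
        intercept = rng.normal(0.0, spec_t.subject_sd)
        for (cond, (a, b)), k in zip(feasible, order):
            rows.append({
                "subject_id": subj, "condition": cond,
                "caller_A": a, "caller_B": b, "skipped": False,
                "trial_order": int(k),
                "_intercept": intercept,
                "friendship_raw": float(assoc.loc[a, b]),
                "relatedness_between_callers": int(kin.loc[a, b]),
                "elo_raw": abs(float(elo.ratings[a] - elo.ratings[b])),
                "subject_centrality": float(cent.scores[subj]),
                "conflict_intensity": float(np.clip(rng.normal(4.0, 1.0), 1.0, 7.0)),
            })
    trials = pd.DataFrame(rows)
    done = trials[~trials["skipped"]].copy()
    if done.empty:
        raise ValueError("no feasible trials could be generated")

    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else x * 0.0

    done["friendship_between_callers"] = _z(done["friendship_raw"])
    done["elo_diff"] = _z(done["elo_raw"])
    mu = (
        done["condition"].map(spec_t.condition_means).astype(float)
        + done["_intercept"]
        + spec_t.order_slope * done["trial_order"]
        + spec_t.friendship_slope * done["friendship_between_callers"]
        + spec_t.relatedness_effect * done["relatedness_between_callers"]
        + spec_t.elo_diff_slope * done["elo_diff"]
        + spec_t.centrality_slope * done["subject_centrality"]
    )
    noise = rng.normal(0.0, spec_t.residual_sd, size=len(done))
    done["look_time"] = np.clip(mu + noise, 0.0, 30.0)
    done = done.drop(columns=["_intercept", "friendship_raw", "elo_raw"])

    skipped = trials[trials["skipped"]]
    out = pd.concat([done, skipped], ignore_index=True)
    return out.sort_values(["subject_id", "condition"]).reset_index(drop=True)
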