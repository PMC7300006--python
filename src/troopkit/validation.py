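"""Planted-truth validation experiments.

Each function here runs a standard, self-contained experiment against the
synthetic generators — calibration of permutation p-values, recovery of
planted effects, agreement with independent oracles — and returns the
measured quantity.  They are used by the test suite and by the
repository's acceptance script; all take an explicit seed and are
deterministic given it.
"""

from __future__ import annotations

import tempfile
import warnings
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import acoustics, models, pdfa, social, synthetic

__all__ = [
    "pdfa_type1_rate",
    "pdfa_power_run",
    "permutation_exactness",
    "lda_oracle_agreement",
    "elo_validation",
    "centrality_oracle_deviation",
    "mantel_validation",
    "condition_model_recovery",
    "relationship_model_recovery",
    "lrt_type1_rate",
    "vif_checks",
    "acoustic_recovery",
    "stimulus_checks",
]

# study-scale default: 9 callers x 6 bouts x 2-12 units
_NULL_CALL_KW = dict(n_callers=9, bouts_per_caller=6, units_per_bout=(2, 12))


def _null_call_spec(seed: int, effect_mult: float = 0.0) -> synthetic.CallSimSpec:
    within = (150.0, 150.0, 200.0, 200.0, 25.0)
    return synthetic.CallSimSpec(
        between_caller_sd=tuple(effect_mult * w for w in within),
        within_caller_sd=within,
        bout_sd=(50.0, 50.0, 60.0, 60.0, 8.0),
        seed=seed, **_NULL_CALL_KW)


def pdfa_type1_rate(n_rep: int = 200, n_perm: int = 999,
                    alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of null-generator datasets (no caller effect) whose pDFA
    p-value falls at or below alpha.  Should approximate alpha."""
    rej = 0
    for r in range(n_rep):
        t = synthetic.gen_call_features(_null_call_spec(seed * 100_003 + r))
        res = pdfa.pdfa_test(t, n_perm=n_perm, seed=seed + r)
        if res.p_value <= alpha:
            rej += 1
    return rej / n_rep


def pdfa_power_run(effect_mult: float = 3.0, n_perm: int = 999,
                   seed: int = 0) -> pdfa.PDFAResult:
    """One pDFA run on a dataset with a between-caller effect of
    ``effect_mult`` times the within-caller sd."""
    t = synthetic.gen_call_features(_null_call_spec(seed, effect_mult))
    return pdfa.pdfa_test(t, n_perm=n_perm, seed=seed)


def permutation_exactness(n_draws: int = 10_000, seed: int = 0) -> dict:
    """Exactness of the nested permutation engine.

    Returns the fraction of draws preserving the bouts-per-caller
    multiset (on a study-scale table) and the chi-square GOF p-value for
    uniformity over the 6 assignments of a 3-bout toy.
    """
    rng = np.random.default_rng(seed)
    t = synthetic.gen_call_features(_null_call_spec(seed))
    labels = t["caller_id"].to_numpy()
    bouts = t["bout_id"].to_numpy()
    bout_of = t.groupby("bout_id")["caller_id"].first()
    target = Counter(Counter(bout_of).values())
    ok = 0
    for _ in range(n_draws):
        perm = pdfa.permute_nested(labels, bouts, rng)
        d = pd.Series(perm).groupby(pd.Series(bouts)).first()
        if Counter(Counter(d).values()) == target:
            ok += 1
    toy_labels = np.array(["A", "A", "B", "C", "C", "C"])
    toy_bouts = np.array(["b1", "b1", "b2", "b3", "b3", "b3"])
    counts = Counter()
    for _ in range(6000):
        counts[tuple(pdfa.permute_nested(toy_labels, toy_bouts, rng))] += 1
    gof_p = float(stats.chisquare(list(counts.values())).pvalue) \
        if len(counts) == 6 else 0.0
    return {"multiset_preserved_fraction": ok / n_draws,
            "toy_assignments_observed": len(counts),
            "uniformity_gof_p": gof_p}


def _brute_force_predict(table: pd.DataFrame) -> np.ndarray:
    """Reference discriminant classifier written against the closed-form
    per-class Gaussian score, independent of the production code path."""
    feats = list(synthetic.FEATURE_NAMES)
    classes = sorted(table["caller_id"].unique())
    n = len(table)
    x_all = table[feats].to_numpy(float)
    sw = np.zeros((5, 5))
    means, priors = {}, {}
    for c in classes:
        xc = table.loc[table["caller_id"] == c, feats].to_numpy(float)
        means[c] = xc.mean(axis=0)
        d = xc - means[c]
        sw += d.T @ d
        priors[c] = len(xc) / n
    cov = sw / (n - len(classes))
    cov = (cov + cov.T) / 2 + 1e-8 * max(x_all.var(axis=0).mean(), 1.0) * np.eye(5)
    covi = np.linalg.inv(cov)
    out = []
    for x in x_all:
        best, best_s = None, -np.inf
        for c in classes:
            s = x @ covi @ means[c] - 0.5 * means[c] @ covi @ means[c] \
                + np.log(priors[c])
            if s > best_s:
                best, best_s = c, s
        out.append(best)
    return np.array(out)


def lda_oracle_agreement(n_tables: int = 50, n_units: int = 30,
                         seed: int = 0) -> float:
    """Fraction of random tables on which the LDA predictions agree
    label-for-label with the brute-force discriminant oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_tables):
        rows = []
        for u in range(n_units):
            c = u % 3
            feats = rng.standard_normal(5) + rng.uniform(0, 2) * c
            rows.append({"unit_id": u, "bout_id": f"B{u % 6}_{c}",
                         "caller_id": f"C{c}"}
                        | dict(zip(synthetic.FEATURE_NAMES, feats)))
        t = pd.DataFrame(rows)
        model = pdfa.fit_lda(t)
        pred, _, _ = pdfa.classify(model, t)
        if np.array_equal(pred, _brute_force_predict(t)):
            agree += 1
    return agree / n_tables


def elo_validation(seed: int = 0) -> dict:
    """Closed-form first update, rating-sum conservation, and Spearman
    recovery of a planted 10-individual hierarchy from 2000 conflicts at
    steepness 0.95."""
    one = pd.DataFrame([{"winner_id": "A", "loser_id": "B", "order": 1}])
    st = social.elo_ratings(one, k=100, start=1000)
    first_delta = st.ratings["A"] - 1000.0

    spec = synthetic.TroopSimSpec(n_individuals=10, rank_steepness=0.95,
                                  n_conflicts=2000, n_scans_per_focal=5,
                                  seed=seed)
    troop = synthetic.gen_troop_observations(spec)
    elo = social.elo_ratings(troop.conflicts,
                             individuals=list(spec.resolve().planted_affinity.index))
    n = len(elo.ratings)
    ratings = {i: 1000.0 for i in elo.ratings}
    max_dev = 0.0
    for _, ev in elo.history.iterrows():
        ratings[ev["winner_id"]] = ev["winner_rating"]
        ratings[ev["loser_id"]] = ev["loser_rating"]
        max_dev = max(max_dev, abs(sum(ratings.values()) - 1000.0 * n))
    ranks = troop.spec.true_ranks
    ids = list(elo.ratings)
    rho = float(stats.spearmanr([-elo.ratings[i] for i in ids],
                                [ranks[i] for i in ids]).statistic)
    return {"first_update_delta": first_delta,
            "max_rating_sum_deviation": max_dev,
            "hierarchy_spearman": rho}


def centrality_oracle_deviation(n_graphs: int = 100, n_nodes: int = 10,
                                seed: int = 0) -> dict:
    """Worst-case deviation of the power-iteration centrality from a
    dense eigensolver over random weighted graphs, plus the spread of
    scores on a complete equal-weight graph (which must vanish)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_graphs):
        w = rng.random((n_nodes, n_nodes))
        w = np.triu(w, 1)
        w = w + w.T
        ids = [f"I{i}" for i in range(n_nodes)]
        m = pd.DataFrame(w, index=ids, columns=ids)
        c = social.eigenvector_centrality(m)
        evals, evecs = np.linalg.eigh(w)
        v = np.abs(evecs[:, np.argmax(evals)])
        v /= v.max()
        got = np.array([c.scores[i] for i in ids])
        worst = max(worst, float(np.max(np.abs(got - v))))
    ids = [f"I{i}" for i in range(8)]
    comp = pd.DataFrame(1.0, index=ids, columns=ids)
    np.fill_diagonal(comp.values, 0.0)
    cc = social.eigenvector_centrality(comp)
    spread = max(cc.scores.values()) - min(cc.scores.values())
    return {"max_oracle_deviation": worst, "complete_graph_spread": spread}


def mantel_validation(n_rep: int = 200, n_perm: int = 999, n_nodes: int = 15,
                      alpha: float = 0.05, seed: int = 0) -> dict:
    """Identity case (r = 1, minimal p) and the type-I error rate of the
    Mantel test on independent random matrices."""
    rng = np.random.default_rng(seed)
    ids = [f"I{i}" for i in range(n_nodes)]

    def rand_mat():
        w = rng.random((n_nodes, n_nodes))
        w = np.triu(w, 1)
        w = w + w.T
        return pd.DataFrame(w, index=ids, columns=ids)

    m = rand_mat()
    ident = social.mantel_test(m, m, n_perm=n_perm, seed=seed)
    rej = 0
    for r in range(n_rep):
        res = social.mantel_test(rand_mat(), rand_mat(), n_perm=n_perm,
                                 seed=seed + r + 1)
        if res.p_value <= alpha:
            rej += 1
    return {"identity_r": ident.r, "identity_p": ident.p_value,
            "min_possible_p": 1.0 / (n_perm + 1),
            "type1_rate": rej / n_rep}


def _trial_replicate(seed: int, troop: synthetic.TroopData,
                     **spec_kw) -> pd.DataFrame:
    return synthetic.gen_trials(synthetic.TrialSimSpec(seed=seed, **spec_kw),
                                troop)


def condition_model_recovery(n_rep: int = 200, seed: int = 0) -> dict:
    """Coverage of the planted condition-2 contrast by estimate +/- 2 SE
    in the condition model, over replicate trial tables."""
    troop = synthetic.gen_troop_observations(synthetic.TroopSimSpec(seed=seed))
    means = {1: 9.5, 2: 4.3, 3: 7.9, 4: 5.4, 5: 6.5, 6: 5.1}
    true_contrast = means[2] - means[1]
    covered = 0
    for r in range(n_rep):
        t = _trial_replicate(seed + 7000 + r, troop, condition_means=means)
        fit, _ = models.fit_condition_model(t, which=1)
        est = fit.terms.loc["condition_2", "estimate"]
        se = fit.terms.loc["condition_2", "se"]
        if abs(est - true_contrast) <= 2 * se:
            covered += 1
    return {"true_contrast": true_contrast, "coverage": covered / n_rep}


def relationship_model_recovery(n_rep: int = 200, slope: float = 1.2,
                                seed: int = 0) -> dict:
    """Coverage of a planted friendship slope by the mixed model, with
    condition means held equal so the slope is the only signal."""
    troop = synthetic.gen_troop_observations(synthetic.TroopSimSpec(seed=seed))
    flat = {c: 8.0 for c in range(1, 7)}
    covered = 0
    positive = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_rep):
            t = _trial_replicate(seed + 11_000 + r, troop,
                                 condition_means=flat,
                                 friendship_slope=slope)
            fit, _ = models.fit_relationship_model(t)
            est = fit.terms.loc["friendship_between_callers", "estimate"]
            se = fit.terms.loc["friendship_between_callers", "se"]
            if abs(est - slope) <= 2 * se:
                covered += 1
            if est > 0:
                positive += 1
    return {"true_slope": slope, "coverage": covered / n_rep,
            "positive_sign_rate": positive / n_rep}


def lrt_type1_rate(n_rep: int = 200, alpha: float = 0.05,
                   seed: int = 0) -> float:
    """Rejection rate of the condition-model LRT when all condition
    means are equal (null true)."""
    troop = synthetic.gen_troop_observations(synthetic.TroopSimSpec(seed=seed))
    flat = {c: 8.0 for c in range(1, 7)}
    rej = 0
    for r in range(n_rep):
        t = _trial_replicate(seed + 23_000 + r, troop, condition_means=flat)
        _, lrt = models.fit_condition_model(t, which=1)
        if lrt.p_value <= alpha:
            rej += 1
    return rej / n_rep


def vif_checks(seed: int = 0) -> dict:
    """Closed-form VIF cases: orthogonal design -> 1; a pair with sample
    correlation exactly 0.6 -> 1/(1 - 0.36)."""
    rng = np.random.default_rng(seed)
    n = 400
    ortho = pd.DataFrame({"a": np.tile([1.0, -1.0], n // 2),
                          "b": np.repeat([1.0, -1.0], n // 2)})
    v_orth = float(models.vif(ortho).max())
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    a = (a - a.mean()) / a.std()
    b = b - b.mean()
    b -= a * (a @ b) / n
    b /= b.std()
    corr = pd.DataFrame({"a": a, "b": 0.6 * a + np.sqrt(1 - 0.36) * b})
    v_corr = float(models.vif(corr).max())
    return {"orthogonal_vif": v_orth, "r06_vif": v_corr}


def acoustic_recovery(n_fixtures: int = 100, seed: int = 0) -> dict:
    """Feature extraction on generated harmonic fixtures: rate of PF and
    DFB1 landing within one FFT bin of a planted harmonic, and the
    worst duration error in ms."""
    bin_hz = 44100 / 512
    per_unit = max(1, n_fixtures // 25)
    spec = synthetic.CallSimSpec(n_callers=5, bouts_per_caller=5,
                                 units_per_bout=(per_unit, per_unit),
                                 seed=seed)
    pf_hits = dfb1_hits = n = 0
    dur_err = 0.0
    with tempfile.TemporaryDirectory() as d:
        meta = synthetic.gen_call_waveforms(spec, Path(d))
        meta = meta.iloc[:n_fixtures]
        for _, r in meta.iterrows():
            f = acoustics.extract_features(acoustics.load_wav(r["file"]))
            harm = [r["f0_hz"] * h for h in range(1, int(r["n_harmonics"]) + 1)]
            n += 1
            if min(abs(f["PF"] - h) for h in harm) <= bin_hz:
                pf_hits += 1
            if min(abs(f["DFB1"] - h) for h in harm) <= bin_hz:
                dfb1_hits += 1
            dur_err = max(dur_err, abs(f["duration"] - r["duration_ms"]))
    return {"n_fixtures": n, "pf_hit_rate": pf_hits / n,
            "dfb1_hit_rate": dfb1_hits / n, "max_duration_error_ms": dur_err}


def stimulus_checks(seed: int = 0) -> dict:
    """Stimulus builder: exact 4-s output and sub-1 kHz attenuation
    measured on a 500 Hz probe mixed with a 3 kHz call."""
    rate = 44100
    t = np.arange(2 * rate) / rate
    a = acoustics.Waveform(0.5 * np.sin(2 * np.pi * 3000 * t), rate)
    b = acoustics.Waveform(0.5 * np.sin(2 * np.pi * 500 * t), rate)
    s = acoustics.build_stimulus(a, b)

    def band_peak(x, f0):
        sp = np.abs(np.fft.rfft(x))
        fr = np.fft.rfftfreq(len(x), 1 / rate)
        return sp[(fr > f0 - 50) & (fr < f0 + 50)].max()

    raw = np.pad(a.samples + b.samples, (0, 2 * rate))
    rel_in = band_peak(raw, 500) / band_peak(raw, 3000)
    rel_out = band_peak(s.samples, 500) / band_peak(s.samples, 3000)
    atten_db = float(20 * np.log10(rel_in / rel_out))
    return {"duration_s": len(s.samples) / s.rate,
            "lowcut_attenuation_db": atten_db}
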