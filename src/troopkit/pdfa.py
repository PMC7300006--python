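"""Permuted discriminant function analysis (pDFA) for caller identity.

A linear discriminant classifier assigns each call unit to a caller from
its acoustic features; the observed classification accuracy is compared
with a permutation null in which caller labels are shuffled at the level
of calling bouts, so that the non-independence of units within a bout
cannot inflate apparent accuracy.  Both a resubstitution variant and a
leave-one-out cross-validated variant are provided, plus the inclusion
rule (a caller enters the analysis only if it contributes more units
than the number of features).

The LDA here is the classic pooled-covariance Gaussian discriminant:
classify x to the class maximising

    score_c(x) = x' S⁻¹ m_c − ½ m_c' S⁻¹ m_c + log p_c

with m_c the class mean, S the pooled within-class covariance and p_c
the empirical prior.  Ties go to the lowest caller id (class labels are
processed in sorted order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import FEATURE_NAMES

__all__ = [
    "LDAModel",
    "PDFAResult",
    "check_inclusion",
    "fit_lda",
    "classify",
    "permute_nested",
    "pdfa_test",
    "pdfa_crossvalidated",
]

_RIDGE = 1e-8


@dataclass(frozen=True)
class LDAModel:
    classes: np.ndarray            # sorted caller ids
    class_means: np.ndarray        # k x p
    pooled_within_cov: np.ndarray  # p x p
    priors: np.ndarray             # k
    discriminant_axes: np.ndarray  # p x (k-1) generalised eigenvectors
    feature_names: tuple[str, ...]


@dataclass(frozen=True)
class PDFAResult:
    observed_accuracy: float
    per_class_accuracy: dict[str, float]
    per_class_p: dict[str, float]
    permuted_accuracies: np.ndarray
    p_value: float
    null_mean: float
    null_ci: tuple[float, float]
    n_perm: int
    seed: int
    mode: str  # "plain" | "cross_validated"

    def to_dict(self) -> dict:
        return {
            "observed_accuracy": self.observed_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "per_class_p": self.per_class_p,
            "p_value": self.p_value,
            "null_mean": self.null_mean,
            "null_ci": list(self.null_ci),
            "n_perm": self.n_perm,
            "seed": self.seed,
            "mode": self.mode,
        }


def check_inclusion(table: pd.DataFrame, n_params: int | None = None
                    ) -> tuple[list[str], pd.DataFrame]:
    """Apply the inclusion criterion: a caller is eligible only if its
    unit count exceeds the number of parameters in the analysis.

    Returns the eligible caller ids (sorted) and the table restricted to
    them.  Raises if fewer than two callers remain.
    """
    if n_params is None:
        n_params = len([c for c in FEATURE_NAMES if c in table.columns])
    counts = table["caller_id"].value_counts()
    eligible = sorted(counts.index[counts > n_params])
    if len(eligible) < 2:
        raise ValueError(
            f"only {len(eligible)} caller(s) have more than {n_params} units; "
            "discriminant analysis needs at least two eligible callers"
        )
    return eligible, table[table["caller_id"].isin(eligible)].reset_index(drop=True)


def _feature_matrix(table: pd.DataFrame,
                    feature_names: tuple[str, ...] | None = None
                    ) -> tuple[np.ndarray, tuple[str, ...]]:
    names = feature_names or tuple(c for c in FEATURE_NAMES if c in table.columns)
    missing = [c for c in names if c not in table.columns]
    if missing:
        raise ValueError(f"feature columns missing from table: {missing}")
    return table[list(names)].to_numpy(dtype=float), names


def _pooled_fit(x: np.ndarray, codes: np.ndarray, k: int,
                ridge: float = _RIDGE) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class means, pooled within covariance and priors from coded labels."""
    n, p = x.shape
    counts = np.bincount(codes, minlength=k).astype(float)
    if np.any(counts == 0):
        raise ValueError("every class needs at least one unit")
    onehot_sums = np.zeros((k, p))
    np.add.at(onehot_sums, codes, x)
    means = onehot_sums / counts[:, None]
    sw = x.T @ x - (means * counts[:, None]).T @ means
    cov = sw / max(n - k, 1)
    cov = (cov + cov.T) / 2
    # ridge scaled by the total variance so it dominates cancellation noise
    # even when the within-class spread is exactly zero
    scale = max(float(x.var(axis=0).mean()), 1.0)
    cov = cov + ridge * scale * np.eye(p)
    return means, cov, counts / n


def fit_lda(table: pd.DataFrame,
            feature_names: tuple[str, ...] | None = None,
            ridge: float = _RIDGE) -> LDAModel:
    """Fit the pooled-covariance linear discriminant model.

    A small ridge (default 1e-8) is added to the covariance diagonal;
    with five features and small classes the pooled covariance can
    become near-singular under permutation.
    """
    x, names = _feature_matrix(table, feature_names)
    classes, codes = np.unique(table["caller_id"].to_numpy(), return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit an LDA")
    means, cov, priors = _pooled_fit(x, codes, len(classes), ridge)
    if ridge == 0 and np.linalg.matrix_rank(cov) < cov.shape[0]:
        raise np.linalg.LinAlgError(
            "pooled within-class covariance is singular; enable a small "
            "ridge to regularise"
        )
    # Fisher axes: S_b v = λ S_w v, solved in the whitened basis
    # W' S_b W with W = S_w^{-1/2} (eigenvalues clipped for stability)
    grand = x.mean(axis=0)
    d = means - grand
    counts = priors * len(x)
    sb = (d * counts[:, None]).T @ d
    evals, evecs = np.linalg.eigh((cov + cov.T) / 2)
    evals = np.maximum(evals, max(ridge, 1e-12))
    w_half = evecs @ np.diag(evals ** -0.5) @ evecs.T
    m = w_half @ sb @ w_half
    vals, vecs = np.linalg.eigh((m + m.T) / 2)
    order = np.argsort(vals)[::-1][: len(classes) - 1]
    axes = w_half @ vecs[:, order]
    return LDAModel(classes=classes, class_means=means, pooled_within_cov=cov,
                    priors=priors, discriminant_axes=axes, feature_names=names)


def _scores(x: np.ndarray, means: np.ndarray, cov: np.ndarray,
            priors: np.ndarray) -> np.ndarray:
    w = np.linalg.solve(cov, means.T)          # p x k
    const = -0.5 * np.einsum("kp,pk->k", means, w) + np.log(priors)
    return x @ w + const


def classify(model: LDAModel, table: pd.DataFrame
             ) -> tuple[np.ndarray, float, dict[str, float]]:
    """Predict caller ids and report overall and per-class accuracy.

    Per-class accuracy is the fraction correct within each true class;
    ``np.argmax`` over classes sorted ascending makes ties go to the
    lowest caller id.
    """
    x, _ = _feature_matrix(table, model.feature_names)
    scores = _scores(x, model.class_means, model.pooled_within_cov, model.priors)
    pred = model.classes[np.argmax(scores, axis=1)]
    truth = table["caller_id"].to_numpy()
    acc = float(np.mean(pred == truth))
    per_class = {
        str(c): float(np.mean(pred[truth == c] == c))
        for c in model.classes
        if np.any(truth == c)
    }
    return pred, acc, per_class


def _bout_structure(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(bout code per unit, caller code per bout, classes).

    Raises if any bout spans two callers — a data-integrity violation.
    """
    bouts, bout_codes = np.unique(table["bout_id"].to_numpy(), return_inverse=True)
    classes, caller_codes = np.unique(table["caller_id"].to_numpy(), return_inverse=True)
    bout_caller = np.full(len(bouts), -1, dtype=int)
    for u in range(len(table)):
        b = bout_codes[u]
        if bout_caller[b] == -1:
            bout_caller[b] = caller_codes[u]
        elif bout_caller[b] != caller_codes[u]:
            raise ValueError(
                f"bout {bouts[b]!r} spans more than one caller; units of a "
                "bout must share a single caller"
            )
    return bout_codes, bout_caller, classes


def permute_nested(labels: np.ndarray, bout_ids: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """One nested permutation of caller labels.

    The bout-to-caller assignment vector is permuted uniformly at random
    and every unit inherits its bout's new caller, so units of a bout
    stay together and the multiset of bouts per caller is preserved.
    """
    df = pd.DataFrame({"bout_id": bout_ids, "caller_id": labels})
    bout_codes, bout_caller, classes = _bout_structure(df)
    permuted_bout_caller = bout_caller[rng.permutation(len(bout_caller))]
    return classes[permuted_bout_caller[bout_codes]]


def _fit_and_score(x: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, np.ndarray]:
    """Resubstitution accuracy (overall, per class) for coded labels."""
    means, cov, priors = _pooled_fit(x, codes, k)
    pred = np.argmax(_scores(x, means, cov, priors), axis=1)
    hit = pred == codes
    per = np.bincount(codes, weights=hit, minlength=k) / np.bincount(codes, minlength=k)
    return float(hit.mean()), per


def _loo_score(x: np.ndarray, codes: np.ndarray, k: int,
               holdout_groups: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Leave-one-out accuracy; with ``holdout_groups`` set, whole groups
    (bouts) are left out together."""
    n, p = x.shape
    groups = np.arange(n) if holdout_groups is None else holdout_groups
    counts_all = np.bincount(codes, minlength=k).astype(float)
    sums_all = np.zeros((k, p))
    np.add.at(sums_all, codes, x)
    xx_all = x.T @ x
    scale = max(float(x.var(axis=0).mean()), 1.0)
    hit = np.zeros(n, dtype=bool)
    for g in np.unique(groups):
        mask = groups == g
        xg, cg = x[mask], codes[mask]
        counts = counts_all - np.bincount(cg, minlength=k)
        if np.any(counts == 0):
            # a class vanishes from the training fold; score against the rest
            pass
        sums = sums_all.copy()
        np.add.at(sums, cg, -xg)
        live = counts > 0
        means = np.zeros((k, p))
        means[live] = sums[live] / counts[live, None]
        sw = (xx_all - xg.T @ xg) - (means * counts[:, None]).T @ means
        n_train = int(counts.sum())
        cov = sw / max(n_train - int(live.sum()), 1)
        cov = (cov + cov.T) / 2 + _RIDGE * scale * np.eye(p)
        priors = np.where(live, counts / n_train, 1e-300)
        w = np.linalg.solve(cov, means.T)
        const = -0.5 * np.einsum("kp,pk->k", means, w) + np.log(priors)
        sc = xg @ w + const
        sc[:, ~live] = -np.inf
        hit[mask] = np.argmax(sc, axis=1) == cg
    per = np.bincount(codes, weights=hit, minlength=k) / counts_all
    return float(hit.mean()), per


def _perm_p(null: np.ndarray, observed: float) -> float:
    return (np.sum(null >= observed) + 1.0) / (len(null) + 1.0)


def _run_pdfa(table: pd.DataFrame, n_perm: int, seed: int, mode: str,
              holdout: str, feature_names: tuple[str, ...] | None) -> PDFAResult:
    import warnings

    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse null; prefer >= 1000",
                      stacklevel=3)
    x, _ = _feature_matrix(table, feature_names)
    bout_codes, bout_caller, classes = _bout_structure(table)
    k = len(classes)
    if k < 2:
        raise ValueError("need at least 2 callers")
    counts_bouts = np.bincount(bout_caller, minlength=k)
    if np.all(counts_bouts == 1) and k == len(bout_caller):
        # each caller contributes exactly one bout: every nested permutation
        # is a pure relabelling and the null is degenerate
        raise ValueError(
            "one bout per caller: nested permutation cannot break the "
            "caller-bout link; the permutation null is undefined"
        )
    rng = np.random.default_rng(seed)

    if mode == "plain":
        score = lambda codes: _fit_and_score(x, codes, k)  # noqa: E731
    elif mode == "cross_validated":
        groups = bout_codes if holdout == "bout" else None
        score = lambda codes: _loo_score(x, codes, k, groups)  # noqa: E731
    else:
        raise ValueError(f"unknown mode {mode!r}")

    obs_acc, obs_per = score(bout_caller[bout_codes])

    null = np.empty(n_perm)
    null_per = np.empty((n_perm, k))
    for i in range(n_perm):
        perm_codes = bout_caller[rng.permutation(len(bout_caller))][bout_codes]
        null[i], null_per[i] = score(perm_codes)

    per_class_acc = {str(classes[c]): float(obs_per[c]) for c in range(k)}
    per_class_p = {
        str(classes[c]): _perm_p(null_per[:, c], obs_per[c]) for c in range(k)
    }
    lo, hi = np.quantile(null, [0.025, 0.975])
    return PDFAResult(
        observed_accuracy=obs_acc,
        per_class_accuracy=per_class_acc,
        per_class_p=per_class_p,
        permuted_accuracies=null,
        p_value=_perm_p(null, obs_acc),
        null_mean=float(null.mean()),
        null_ci=(float(lo), float(hi)),
        n_perm=n_perm,
        seed=seed,
        mode=mode,
    )


def pdfa_test(table: pd.DataFrame, n_perm: int = 5000, seed: int = 0,
              feature_names: tuple[str, ...] | None = None) -> PDFAResult:
    """Permuted discriminant function analysis, resubstitution variant.

    Observed accuracy comes from fitting and re-classifying the true
    labels; the null distribution from ``n_perm`` nested permutations,
    each refit and scored identically.  The p-value uses the add-one
    permutation formula ``(r + 1) / (m + 1)`` and is therefore never 0.
    """
    return _run_pdfa(table, n_perm, seed, "plain", "unit", feature_names)


def pdfa_crossvalidated(table: pd.DataFrame, n_perm: int = 5000, seed: int = 0,
                        holdout: str = "unit",
                        feature_names: tuple[str, ...] | None = None) -> PDFAResult:
    """pDFA with leave-one-out accuracy instead of resubstitution.

    ``holdout="unit"`` leaves out single call units (classical LOO).
    Because units of a bout resemble each other, unit-level LOO leaks
    bout information into training; ``holdout="bout"`` leaves out whole
    bouts and removes that leakage.
    """
    if holdout not in ("unit", "bout"):
        raise ValueError("holdout must be 'unit' or 'bout'")
    return _run_pdfa(table, n_perm, seed, "cross_validated", holdout, feature_names)
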