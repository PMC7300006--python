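"""Schema-validated table readers/writers and the end-to-end pipeline.

CSV schemas (headers are exact):

* ``features``: ``unit_id,bout_id,caller_id,DFB1,DFA2,PF,FR,duration``
* ``scans``: ``focal_id,scan_index,neighbour_ids`` (neighbours ';'-joined)
* ``conflicts``: ``winner_id,loser_id,order``
* ``matrilines``: ``individual_id,matriline``
* ``trials``: one row per playback trial (see ``TRIALS_COLUMNS``)
* square matrices: ids as the header row and first column

``run_pipeline`` chains the stages — simulate, pdfa, network, design,
models — writing JSON/CSV reports plus a run manifest with input
checksums, per-stage timings and the seeds used.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models as pm
from . import pdfa as pdfa_mod
from . import social, synthetic

log = logging.getLogger("troopkit")

FEATURES_COLUMNS = ["unit_id", "bout_id", "caller_id",
                    "DFB1", "DFA2", "PF", "FR", "duration"]
TRIALS_COLUMNS = ["subject_id", "condition", "caller_A", "caller_B", "look_time",
                  "trial_order", "conflict_intensity",
                  "friendship_between_callers", "relatedness_between_callers",
                  "elo_diff", "subject_centrality"]

SCHEMAS: dict[str, list[str]] = {
    "features": FEATURES_COLUMNS,
    "scans": ["focal_id", "scan_index", "neighbour_ids"],
    "conflicts": ["winner_id", "loser_id", "order"],
    "matrilines": ["individual_id", "matriline"],
    "trials": TRIALS_COLUMNS,
}

_NUMERIC = {
    "features": ["DFB1", "DFA2", "PF", "FR", "duration"],
    "scans": ["scan_index"],
    "conflicts": ["order"],
    "matrilines": [],
    "trials": ["condition", "look_time", "trial_order", "conflict_intensity",
               "friendship_between_callers", "relatedness_between_callers",
               "elo_diff", "subject_centrality"],
}


class ValidationError(ValueError):
    """Raised when an input table violates its schema."""


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against one of the named schemas.

    Raises :class:`ValidationError` naming the missing columns, the rows
    with unparsable numeric values, or duplicate unit ids.  An empty
    file with a valid header yields an empty table with a warning.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = SCHEMAS[schema_name]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if df.empty:
        import warnings
        warnings.warn(f"{path}: header only, no data rows", stacklevel=2)
        return df
    for col in _NUMERIC[schema_name]:
        if col not in df.columns:
            continue
        conv = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        src = df[col].replace("", np.nan)
        bad = df.index[conv.isna() & src.notna()].tolist()
        if bad:
            raise ValidationError(
                f"{path}: non-numeric values in {col!r} at rows "
                f"{[b + 2 for b in bad]}"  # 1-based + header line
            )
        df[col] = conv
    if schema_name == "features":
        dup = df["unit_id"][df["unit_id"].duplicated()].tolist()
        if dup:
            raise ValidationError(f"{path}: duplicate unit_id values: {dup}")
    if schema_name == "trials" and "skipped" in df.columns:
        df["skipped"] = df["skipped"].isin(("True", "true", "1"))
    return df


def write_matrix(m: pd.DataFrame, path) -> None:
    m.to_csv(path, index_label="id")


def read_matrix(path) -> pd.DataFrame:
    m = pd.read_csv(path, index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    return m


def write_edge_list(m: pd.DataFrame, path) -> None:
    """Export a symmetric matrix as a dyadic edge list for external
    network-visualisation tools."""
    rows = []
    ids = list(m.index)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            w = float(m.loc[a, b])
            if w != 0:
                rows.append({"id_a": a, "id_b": b, "weight": w})
    pd.DataFrame(rows, columns=["id_a", "id_b", "weight"]).to_csv(path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    With no input paths set, the simulate stage generates every stream
    synthetically from the seed.
    """

    out_dir: str = "troopkit_out"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "pdfa", "network", "design", "models")
    # input paths (optional; simulate fills anything unset)
    features_path: str | None = None
    scans_path: str | None = None
    conflicts_path: str | None = None
    matrilines_path: str | None = None
    trials_path: str | None = None
    # stage settings
    n_perm: int = 999
    pdfa_mode: str = "plain"      # plain | cv
    holdout: str = "unit"
    elo_k: float = 100.0
    elo_start: float = 1000.0
    assoc_mode: str = "count"
    sim: dict = field(default_factory=dict)  # overrides for the sim specs

    def validate(self) -> None:
        known = {"simulate", "features", "pdfa", "network", "design", "models"}
        bad = set(self.stages) - known
        if bad:
            raise ValidationError(f"unknown stages: {sorted(bad)}")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.pdfa_mode not in ("plain", "cv"):
            raise ValidationError("pdfa_mode must be 'plain' or 'cv'")
        if "models" in self.stages and "simulate" not in self.stages \
                and self.trials_path is None:
            raise ValidationError("models stage needs a trials file or the "
                                  "simulate stage")
        if "pdfa" in self.stages and "simulate" not in self.stages \
                and self.features_path is None:
            raise ValidationError("pdfa stage needs a features file or the "
                                  "simulate stage")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in vars(cfg).items() if k != "sim"},
                      "stages": {}, "outputs": {}, "seed": cfg.seed}
    state: dict = {}

    def stage(name):
        def deco(fn):
            if name in cfg.stages:
                t0 = time.perf_counter()
                log.info("[%s] start", name)
                try:
                    fn()
                except Exception as exc:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                manifest["stages"][name] = round(time.perf_counter() - t0, 3)
                log.info("[%s] done in %.2fs", name, manifest["stages"][name])
            return fn
        return deco

    @stage("simulate")
    def _simulate():
        call_spec = synthetic.CallSimSpec(seed=cfg.seed,
                                          **cfg.sim.get("call", {}))
        troop_spec = synthetic.TroopSimSpec(seed=cfg.seed + 1,
                                            **cfg.sim.get("troop", {}))
        trial_spec = synthetic.TrialSimSpec(seed=cfg.seed + 2,
                                            **cfg.sim.get("trial", {}))
        state["features"] = synthetic.gen_call_features(call_spec)
        state["troop"] = synthetic.gen_troop_observations(troop_spec)
        state["trials"] = synthetic.gen_trials(trial_spec, state["troop"])
        state["features"].to_csv(out / "features.csv", index=False)
        state["troop"].scans.to_csv(out / "scans.csv", index=False)
        state["troop"].conflicts.to_csv(out / "conflicts.csv", index=False)
        write_matrix(state["troop"].grooming, out / "grooming.csv")
        state["trials"].to_csv(out / "trials.csv", index=False)
        state["scans"] = state["troop"].scans
        state["conflicts"] = state["troop"].conflicts
        state["matrilines"] = state["troop"].spec.matrilines
        state["sexes"] = state["troop"].spec.sexes

    def _need(key, path, schema):
        if key not in state:
            if path is None:
                raise ValidationError(f"no {schema} input available: provide "
                                      f"a file or enable the simulate stage")
            state[key] = read_table(path, schema)
        return state[key]

    @stage("pdfa")
    def _pdfa():
        table = _need("features", cfg.features_path, "features")
        _, table = pdfa_mod.check_inclusion(table)
        run = (pdfa_mod.pdfa_test if cfg.pdfa_mode == "plain"
               else lambda t, **kw: pdfa_mod.pdfa_crossvalidated(
                   t, holdout=cfg.holdout, **kw))
        res = run(table, n_perm=cfg.n_perm, seed=cfg.seed)
        (out / "pdfa.json").write_text(json.dumps(res.to_dict(), indent=2))

    @stage("network")
    def _network():
        scans = _need("scans", cfg.scans_path, "scans")
        conflicts = _need("conflicts", cfg.conflicts_path, "conflicts")
        assoc = social.build_association_matrix(scans, mode=cfg.assoc_mode)
        elo = social.elo_ratings(conflicts, k=cfg.elo_k, start=cfg.elo_start,
                                 individuals=list(assoc.index))
        cent = social.eigenvector_centrality(assoc)
        stab = social.stability_split(scans, 0.5, n_perm=cfg.n_perm, seed=cfg.seed)
        write_matrix(assoc, out / "association.csv")
        write_edge_list(assoc, out / "network_edges.csv")
        report = {
            "elo": elo.ratings,
            "centrality": cent.scores,
            "central_set": sorted(cent.central_set),
            "stability_r": stab.r, "stability_p": stab.p_value,
        }
        if "troop" in state:
            groom = social.mantel_test(assoc, state["troop"].grooming,
                                       n_perm=cfg.n_perm, seed=cfg.seed)
            report["grooming_mantel_r"] = groom.r
            report["grooming_mantel_p"] = groom.p_value
        (out / "network.json").write_text(json.dumps(report, indent=2))
        state["assoc"], state["cent"], state["elo"] = assoc, cent, elo

    @stage("design")
    def _design():
        if "assoc" not in state:
            scans = _need("scans", cfg.scans_path, "scans")
            state["assoc"] = social.build_association_matrix(scans,
                                                             mode=cfg.assoc_mode)
            state["cent"] = social.eigenvector_centrality(state["assoc"])
        if "matrilines" not in state:
            mt = read_table(cfg.matrilines_path, "matrilines")
            state["matrilines"] = dict(zip(mt["individual_id"], mt["matriline"]))
            state["sexes"] = {i: "F" for i in state["assoc"].index}
        kin = social.kinship_matrix(state["matrilines"])
        rows = []
        for subj in state["assoc"].index:
            for cond in range(1, 7):
                dyad = social.select_condition_dyads(
                    subj, state["assoc"], kin, state["sexes"], state["cent"], cond)
                rows.append({"subject_id": subj, "condition": cond,
                             "caller_A": dyad[0] if dyad else "",
                             "caller_B": dyad[1] if dyad else "",
                             "feasible": dyad is not None})
        pd.DataFrame(rows).to_csv(out / "design.csv", index=False)

    @stage("models")
    def _models():
        trials = _need("trials", cfg.trials_path, "trials")
        report: dict = {"condition_models": {}, "tables": {}}
        for which in (1, 2, 3):
            try:
                fit, lrt = pm.fit_condition_model(trials, which)
            except ValueError as exc:
                report["condition_models"][str(which)] = {"error": str(exc)}
                continue
            report["condition_models"][str(which)] = {
                "terms": fit.terms.round(4).to_dict("index"),
                "lrt": vars(lrt), "n_obs": fit.n_obs,
            }
            fit.terms.to_csv(out / f"model_condition_{which}.csv")
        fit, lrt = pm.fit_relationship_model(trials)
        report["relationship_model"] = {
            "terms": fit.terms.round(4).to_dict("index"),
            "lrt": vars(lrt), "n_obs": fit.n_obs,
            "random_effects": fit.random_effects,
            "singular": fit.singular,
        }
        fit.terms.to_csv(out / "model_relationship.csv")
        design = _clean_design(trials)
        if design is not None:
            report["vif"] = pm.vif(design).round(4).to_dict()
        report["residuals"] = {
            k: v for k, v in pm.residual_checks(fit).items()
            if not k.startswith("qq")
        }
        (out / "models.json").write_text(json.dumps(report, indent=2, default=float))

    for p in sorted(out.iterdir()):
        if p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _clean_design(trials: pd.DataFrame) -> pd.DataFrame | None:
    cols = pm.RELATIONSHIP_PREDICTORS + ["trial_order"]
    t = trials.copy()
    if "skipped" in t.columns:
        t = t[~t["skipped"].astype(bool)]
    if not set(cols) <= set(t.columns):
        return None
    d = t[cols].astype(float).dropna()
    return d if len(d) > len(cols) else None
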