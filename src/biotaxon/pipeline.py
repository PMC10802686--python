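"""End-to-end orchestration: simulate -> preprocess -> bio-factors ->
cluster-number estimation -> biotypes -> stability -> CDA -> group stats.

Every random stage receives an explicit seed derived from the master seed
via a seed sequence, so an identical configuration reproduces the report
byte-for-byte (modulo the timestamp in the provenance block).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biotype import canonical_labels, kmeans
from .cda import fit_cda, variate_posthoc
from .clustnum import gap_statistic, solutions_for_range, validity_indices
from .cohort import SyntheticConfig, generate_cohort
from .factors import BioFactorModel
from .groupstats import compare_groups
from .preprocess import apply_adjustment, fit_adjustment, standardize
from .stability import subsample_experiment

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration; ``seed`` is mandatory."""

    seed: int | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    alpha: float = 0.05
    kappa: float = 3.0
    kmax: int = 8
    gap_B: int = 100
    clust_n_init: int = 10
    kmeans_n_init: int = 50
    force_k: int | None = 3
    stability_sizes: tuple[int, ...] = (200, 400, 600)
    stability_reps: int = 100
    run_clustnum: bool = True
    run_stability: bool = True

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("RunConfig.seed must be set explicitly")
        self.synthetic.validate()

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["synthetic"] = json.loads(self.synthetic.to_json())
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(master: int, names) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(names))
    return {
        name: int(c.generate_state(1, dtype=np.uint32)[0]) % (2**31 - 1)
        for name, c in zip(names, children)
    }


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full analysis on a synthetic cohort; returns the report."""
    config.validate()
    seeds = _stage_seeds(
        config.seed, ["simulate", "gap", "solutions", "kmeans", "stability"]
    )
    report: dict = {
        "provenance": {
            "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "config_hash": config.config_hash(),
            "seeds": seeds,
        }
    }

    # --- simulate ----------------------------------------------------------
    syn = dataclasses.replace(config.synthetic, seed=seeds["simulate"])
    subjects, panel = generate_cohort(syn)
    is_proband = (subjects["role"] == "proband").to_numpy()
    is_healthy = (subjects["role"] == "healthy").to_numpy()
    is_relative = (subjects["role"] == "relative").to_numpy()
    report["cohort"] = {
        "n_probands": int(is_proband.sum()),
        "n_relatives": int(is_relative.sum()),
        "n_healthy": int(is_healthy.sum()),
    }

    # --- preprocess --------------------------------------------------------
    adjuster = fit_adjustment(panel, subjects, alpha=config.alpha)
    adjusted = apply_adjustment(adjuster, panel, subjects)
    ref_mask = (is_proband | is_healthy)
    std_panel, scaler = standardize(adjusted, ref_mask)
    report["preprocess"] = {
        "age_adjusted": adjuster.age_flag_[adjuster.age_flag_].index.tolist(),
        "sex_adjusted": adjuster.sex_flag_[adjuster.sex_flag_].index.tolist(),
    }

    # --- bio-factors -------------------------------------------------------
    fit_panel = type(panel)(
        values=std_panel.values.loc[ref_mask], domain_of=std_panel.domain_of
    )
    model = BioFactorModel(kappa=config.kappa).fit(fit_panel)
    fit_scores = model.score_fit_sample(fit_panel)
    rel_panel = type(panel)(
        values=std_panel.values.loc[is_relative], domain_of=std_panel.domain_of
    )
    rel_scores = model.project_relatives(rel_panel)
    report["biofactor"] = {
        "n_factors": model.n_factors_,
        "factor_labels": model.factor_labels_,
        "domain_counts": model.domain_factor_counts(),
    }

    proband_ids = subjects.loc[is_proband, "subject_id"]
    proband_scores = fit_scores.loc[proband_ids]

    # --- cluster number ----------------------------------------------------
    chosen_k = config.force_k or 3
    if config.run_clustnum:
        gap = gap_statistic(
            proband_scores, kmax=config.kmax, B=config.gap_B, seed=seeds["gap"],
            n_init=config.clust_n_init,
        )
        sols = solutions_for_range(
            proband_scores.to_numpy(), range(2, config.kmax + 1),
            n_init=config.clust_n_init, seed=seeds["solutions"],
        )
        votes = validity_indices(
            proband_scores.to_numpy(), sols, gap_curve=gap
        )
        report["clustnum"] = {
            "gap_k": gap.chosen_k,
            "gap_curve": gap.to_frame().to_dict(orient="list"),
            "votes": votes.votes,
            "tally": {str(k): v for k, v in votes.tally.items()},
            "majority_k": votes.winner,
        }
        if config.force_k is None:
            chosen_k = votes.winner
    report["chosen_k"] = chosen_k

    # --- biotypes ----------------------------------------------------------
    solution = kmeans(
        proband_scores, chosen_k, n_init=config.kmeans_n_init,
        seed=seeds["kmeans"],
    )
    solution = canonical_labels(solution)
    bt_labels = pd.Series(solution.labels, index=proband_ids, name="biotype")
    report["biotype"] = {
        "k": solution.k,
        "sizes": {f"BT{b}": int((solution.labels == b).sum())
                  for b in range(1, solution.k + 1)},
        "n_iter": solution.n_iter,
        "inertia": solution.inertia,
        "centroids": pd.DataFrame(
            solution.centroids, columns=model.factor_labels_,
            index=[f"BT{b}" for b in range(1, solution.k + 1)],
        ).to_dict(orient="index"),
    }

    # --- stability ---------------------------------------------------------
    if config.run_stability:
        sizes = [m for m in config.stability_sizes if m <= len(proband_scores)]
        curve = subsample_experiment(
            proband_scores, solution, sizes, n_reps=config.stability_reps,
            seed=seeds["stability"],
        )
        report["stability"] = curve.summary.to_dict(orient="list")

    # --- CDA ---------------------------------------------------------------
    groups_ph = np.where(
        is_proband,
        [f"BT{b}" for b in bt_labels.reindex(subjects["subject_id"]).fillna(0).astype(int)],
        "HC",
    )[ref_mask]
    cda = fit_cda(fit_scores, groups_ph)
    posthoc = variate_posthoc(cda, fit_scores, groups_ph, alpha=config.alpha)
    report["cda"] = {
        "canonical_correlations": cda.canonical_correlations_.round(4).tolist(),
        "chi2": cda.chi2_.round(2).tolist(),
        "chi2_df": cda.chi2_df_.tolist(),
        "chi2_p": cda.chi2_p_.tolist(),
        "structure": cda.structure_matrix().round(4).to_dict(orient="index"),
        "posthoc": posthoc.to_dict(orient="records"),
    }

    # --- group statistics --------------------------------------------------
    comp = compare_groups(fit_scores, groups_ph, healthy_label="HC",
                          alpha=config.alpha)
    report["stats_probands"] = comp.table.round(4).to_dict(orient="records")

    # relatives grouped by their proband's assigned biotype, plus healthy
    fam_bt = subjects.loc[is_proband].assign(bt=solution.labels).set_index(
        "family_id"
    )["bt"]
    rel_subj = subjects.loc[is_relative]
    rel_groups = [f"BT{fam_bt[f]}" for f in rel_subj["family_id"]]
    healthy_ids = subjects.loc[is_healthy, "subject_id"]
    rel_stack = pd.concat([rel_scores, fit_scores.loc[healthy_ids]])
    rel_stack_groups = np.array(rel_groups + ["HC"] * len(healthy_ids))
    rel_families = np.concatenate(
        [rel_subj["family_id"].to_numpy(),
         subjects.loc[is_healthy, "family_id"].to_numpy()]
    )
    if len(rel_subj):
        comp_rel = compare_groups(
            rel_stack, rel_stack_groups, healthy_label="HC",
            family_ids=rel_families, alpha=config.alpha,
        )
        report["stats_relatives"] = comp_rel.table.round(4).to_dict(orient="records")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        subjects.to_csv(outdir / "subjects.csv", index=False)
        panel.to_csv(outdir / "panel_raw.csv")
        std_panel.to_csv(outdir / "panel_standardized.csv")
        fit_scores.to_csv(outdir / "scores_fit_sample.csv")
        rel_scores.to_csv(outdir / "scores_relatives.csv")
        bt_labels.to_csv(outdir / "biotype_labels.csv")
        (outdir / "biofactor_model.json").write_text(model.to_json())
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, default=_jsonable)
        )
    return report


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
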