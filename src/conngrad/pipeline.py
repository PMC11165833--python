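"""End-to-end orchestration of the gradient-contrast pipeline.

``contrast_pipeline`` chains consensus -> template gradients -> individual
alignment -> manifold eccentricity -> permutation contrast and is the unit
re-used by the sensitivity variants; ``run_all`` drives every stage from a
single config mapping and writes all result tables plus a manifest into an
output directory. A single root seed deterministically spawns per-stage
seeds, so one integer reproduces the whole run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as cio
from .classify import build_feature_table, cross_validated_classify
from .consensus import consensus_from_cohort
from .eccentricity import manifold_eccentricity
from .gradients import GradientSet, embed_individuals, template_gradients
from .simulate import ConnectomeCohort, SimulationConfig, simulate_cohort
from .stats import encode_covariates, permutation_test, stratify
from .subcortical import subcortical_contrast, subcortical_degree

logger = logging.getLogger(__name__)


def spawn_seeds(root_seed: int, n: int) -> list:
    """Deterministic per-stage seeds below 2**31 from one root seed."""
    rng = np.random.default_rng(int(root_seed))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


@dataclass
class ContrastOutput:
    consensus: object
    template: GradientSet
    gradients: GradientSet
    eccentricity: object
    result: object  # PermutationResult over cortical regions
    network_summary: object = None
    hierarchy_summary: object = None


def contrast_pipeline(
    cohort: ConnectomeCohort,
    n_bins: int = 10,
    n_components: int = 3,
    sparsity: float = 0.9,
    alpha: float = 0.5,
    n_perm: int = 10000,
    seed: int = 0,
    fdr_alpha: float = 0.05,
    use_covariates: bool = True,
    center: str = "template",
    template: Optional[GradientSet] = None,
    stratify_results: bool = True,
) -> ContrastOutput:
    """Cortical manifold-eccentricity group contrast for one cohort.

    If ``template`` is given it is reused as the alignment target (e.g. for
    subject-subset sensitivity variants); otherwise a distance-dependent
    consensus of this cohort defines it.
    """
    cons = None
    if template is None:
        cons = consensus_from_cohort(cohort, n_bins=n_bins)
        template = template_gradients(cons.matrix, n_components=n_components, sparsity=sparsity, alpha=alpha)
    grads = embed_individuals(cohort, template)
    kept = cohort.subjects["subject_id"].isin(grads.subject_ids).to_numpy()
    subjects = cohort.subjects.loc[kept]
    ecc = manifold_eccentricity(grads, n_components=n_components, center=center)
    cov = (
        encode_covariates(subjects["age"].to_numpy(), subjects["sex"].to_numpy())
        if use_covariates
        else None
    )
    result = permutation_test(
        ecc.values,
        subjects["group"].to_numpy(),
        covariates=cov,
        n_perm=n_perm,
        seed=seed,
        fdr_alpha=fdr_alpha,
        region_ids=cohort.atlas.cortical_ids,
    )
    net = hier = None
    if stratify_results:
        net = stratify(result, cohort.atlas, "network7")
        hier = stratify(result, cohort.atlas, "hierarchy4")
    return ContrastOutput(
        consensus=cons,
        template=template,
        gradients=grads,
        eccentricity=ecc,
        result=result,
        network_summary=net,
        hierarchy_summary=hier,
    )


DEFAULT_CONFIG = {
    "seed": 0,
    "cohort_dir": None,  # read an existing cohort instead of simulating
    "simulate": {},  # SimulationConfig overrides
    "n_bins": 10,
    "n_components": 3,
    "sparsity": 0.9,
    "alpha": 0.5,
    "n_perm": 10000,
    "fdr_alpha": 0.05,
    "use_covariates": True,
    "center": "template",
    "classify": {"n_repeats": 100, "n_folds": 5, "threshold": 0.5},
    "variants": [],
    "write_cohort": True,
}

REQUIRED_KEYS = ("seed", "n_perm", "n_components")


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **user}
    for key in REQUIRED_KEYS:
        if cfg.get(key) is None:
            raise KeyError(f"pipeline config is missing required key {key!r}")
    return cfg


def run_all(config: dict, out_dir) -> Path:
    """Run every stage from one config mapping; write results + manifest."""
    cfg = {**DEFAULT_CONFIG, **config}
    for key in REQUIRED_KEYS:
        if cfg.get(key) is None:
            raise KeyError(f"pipeline config is missing required key {key!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(cfg, indent=1, default=str))
    seeds = spawn_seeds(cfg["seed"], 4)
    manifest = {"stages": [], "root_seed": cfg["seed"], "stage_seeds": seeds}

    def stage(name):
        t0 = time.time()

        def done():
            manifest["stages"].append({"name": name, "wall_s": round(time.time() - t0, 3)})
            logger.info("stage %s finished in %.2fs", name, time.time() - t0)

        return done

    end = stage("cohort")
    if cfg.get("cohort_dir"):
        cohort = cio.read_cohort(cfg["cohort_dir"])
    else:
        sim = SimulationConfig(**{**cfg.get("simulate", {}), "seed": seeds[0]})
        cohort = simulate_cohort(sim)
        if cfg.get("write_cohort", True):
            cio.write_cohort(cohort, out / "cohort")
    end()

    end = stage("contrast")
    res = contrast_pipeline(
        cohort,
        n_bins=cfg["n_bins"],
        n_components=cfg["n_components"],
        sparsity=cfg["sparsity"],
        alpha=cfg["alpha"],
        n_perm=cfg["n_perm"],
        seed=seeds[1],
        fdr_alpha=cfg["fdr_alpha"],
        use_covariates=cfg["use_covariates"],
        center=cfg["center"],
    )
    df = res.result.to_frame()
    cio.write_results(df, out / "eccentricity_contrast.tsv")
    np.savetxt(out / "template_gradients.tsv", res.template.template, fmt="%.10g", delimiter="\t")
    (out / "eigenvalues.json").write_text(
        json.dumps(
            {
                "eigenvalues": res.template.eigenvalues.tolist(),
                "variance_explained": res.template.variance_explained.tolist(),
            },
            indent=1,
        )
    )
    np.savetxt(out / "eccentricity.tsv", res.eccentricity.values, fmt="%.10g", delimiter="\t")
    strat = {
        "network7": res.network_summary.class_means,
        "hierarchy4": res.hierarchy_summary.class_means,
    }
    (out / "stratification.json").write_text(json.dumps(strat, indent=1))
    end()

    end = stage("subcortical")
    kept = cohort.subjects["subject_id"].isin(res.gradients.subject_ids).to_numpy()
    subjects = cohort.subjects.loc[kept]
    deg = subcortical_degree(cohort.subset(kept))
    cov = (
        encode_covariates(subjects["age"].to_numpy(), subjects["sex"].to_numpy())
        if cfg["use_covariates"]
        else None
    )
    deg_res = subcortical_contrast(deg, subjects["group"].to_numpy(), covariates=cov, n_perm=cfg["n_perm"], seed=seeds[2], fdr_alpha=cfg["fdr_alpha"])
    deg_df = deg_res.to_frame()
    deg_df["region"] = deg.names
    cio.write_results(deg_df, out / "subcortical_contrast.tsv")
    end()

    end = stage("classify")
    feats = build_feature_table(res.eccentricity, deg)
    ccfg = {**DEFAULT_CONFIG["classify"], **cfg.get("classify", {})}
    report = cross_validated_classify(
        feats,
        subjects["group"].to_numpy(),
        covariates=cov,
        n_repeats=ccfg["n_repeats"],
        n_folds=ccfg["n_folds"],
        threshold=ccfg["threshold"],
        seed=seeds[3],
    )
    report.to_frame().to_csv(out / "classification_repeats.tsv", sep="\t", index=False)
    report.selection_probability.rename("selection_probability").to_csv(out / "selection_probability.tsv", sep="\t")
    (out / "classification_summary.json").write_text(json.dumps(report.summary, indent=1))
    end()

    if cfg.get("variants"):
        from .sensitivity import VariantSpec, run_variant

        end = stage("sensitivity")
        rows = []
        for v in cfg["variants"]:
            spec = VariantSpec(**v) if isinstance(v, dict) else v
            comp = run_variant(cohort, spec, res.result, template=res.template, n_perm=cfg["n_perm"], seed=seeds[1], fdr_alpha=cfg["fdr_alpha"])
            rows.append({"variant": comp.name, "r": comp.r, "p": comp.p, "n_regions": comp.n_regions})
        (out / "sensitivity.json").write_text(json.dumps(rows, indent=1))
        end()

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
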