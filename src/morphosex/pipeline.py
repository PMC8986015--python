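"""End-to-end analysis pipeline: align -> slide -> PCA -> stats -> classify.

``run_pipeline`` reproduces the full analysis graph on one dataset and
writes a report bundle: aligned coordinates (npz), slid coordinates (TPS),
a PC/regression table (shape and form space), a univariate measurement
table, a classification table with per-sex cross-validated percentages and
AUCs, ROC point CSVs, and a machine-readable JSON manifest holding
versions, seeds and parameters (re-running a config with the same seed
reproduces every number; the manifest contains no timestamps so reruns are
byte-identical).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (
    ClassifierSpec,
    boxs_m,
    lda_loo_cv,
    select_significant_pcs,
)
from .landmark_io import (
    TemplateDefinition,
    read_metadata,
    read_tps,
    subset_landmarks,
    validate_dataset,
    write_tps,
)
from .morphostats import (
    allometry_corrected_sex_effect,
    pca,
    permutation_mean_difference,
    procrustes_anova,
    ttest_and_effect,
    variance_explained_regression,
)
from .osteometrics import measurements_table, read_measurements_csv
from .semilandmarks import slide_semilandmarks
from .superimposition import gpa_align, to_form_space
from .synthetic import default_population_spec, default_template, simulate_dataset

logger = logging.getLogger("morphosex.pipeline")

MEASUREMENT_FEATURES = ("SW", "CW", "CD", "CBI", "CAI", "corpus_area")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    data: str | None = None          # TPS file; None => simulate
    metadata: str | None = None      # metadata CSV; None => simulate
    measurements: str | None = None  # measurement CSV; None => from landmarks
    template: str | None = None      # template YAML; None => default
    subset: str | None = None        # named landmark subset, optional
    simulate_n: dict | None = None   # cells override for simulation
    sliding_iterations: int = 3
    spaces: tuple[str, ...] = ("shape", "form")
    classifiers: tuple[str, ...] = ("pcs", "lncs", "pcs+lncs") + MEASUREMENT_FEATURES
    priors: str = "equal"
    n_perm: int = 999
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "morphosex_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls(**d)
        if isinstance(cfg.spaces, list):
            cfg.spaces = tuple(cfg.spaces)
        if isinstance(cfg.classifiers, list):
            cfg.classifiers = tuple(cfg.classifiers)
        return cfg

    def to_dict(self) -> dict:
        return {
            "data": self.data, "metadata": self.metadata,
            "measurements": self.measurements, "template": self.template,
            "subset": self.subset, "simulate_n": self.simulate_n,
            "sliding_iterations": self.sliding_iterations,
            "spaces": list(self.spaces), "classifiers": list(self.classifiers),
            "priors": self.priors, "n_perm": self.n_perm, "alpha": self.alpha,
            "seed": self.seed, "output_dir": self.output_dir,
        }


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline and write the report bundle to
    ``config.output_dir``. Returns the manifest dict.

    On a stage failure a :class:`StageError` naming the stage is raised and
    the partial manifest is retained as ``manifest.partial.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "morphosex",
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    try:
        return _run_stages(config, out, manifest)
    except StageError:
        with open(out / "manifest.partial.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        raise


def _run_stages(config: PipelineConfig, out: Path, manifest: dict) -> dict:

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        info = stage("load")
        if config.template:
            template = TemplateDefinition.from_yaml(config.template)
            reference = None
        else:
            template, reference = default_template()
        if config.data:
            configs = read_tps(config.data, template)
            meta = read_metadata(config.metadata)
            truth = None
        else:
            spec = default_population_spec(
                seed=config.seed, cells=config.simulate_n and {
                    tuple(k.split("|")): v for k, v in config.simulate_n.items()
                }
            )
            configs, meta, truth = simulate_dataset(spec)
            write_tps(configs, out / "simulated.tps")
            meta.to_csv(out / "simulated_meta.csv", index=False)
        info.update(n_specimens=len(configs), template=template.name,
                    simulated=config.data is None)
        del reference, truth
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", exc) from exc

    try:
        info = stage("validate")
        report = validate_dataset(configs, meta)
        info.update(n_issues=len(report.issues))
    except Exception as exc:  # noqa: BLE001
        raise StageError("validate", exc) from exc

    try:
        if config.subset:
            info = stage("subset")
            configs, template = subset_landmarks(configs, template, config.subset)
            info.update(subset=config.subset, k=template.n_landmarks)
    except Exception as exc:  # noqa: BLE001
        raise StageError("subset", exc) from exc

    # measurements come from the raw (pre-sliding, unscaled) configurations
    try:
        info = stage("measurements")
        if config.measurements:
            mtable = read_measurements_csv(config.measurements)
        elif all(m in template.measurement_registry for m in ("SW", "CW", "CD")):
            mtable = measurements_table(configs, template)
        else:
            mtable = None
        if mtable is not None:
            mtable.to_csv(out / "measurements.csv", index=False)
            info.update(n=len(mtable))
        else:
            info.update(skipped="no measurement registry in subset template")
    except Exception as exc:  # noqa: BLE001
        raise StageError("measurements", exc) from exc

    try:
        info = stage("slide")
        if template.curves and config.sliding_iterations > 0:
            slid = slide_semilandmarks(
                configs, template, outer_iterations=config.sliding_iterations
            )
            configs = slid.configs
            write_tps(configs, out / "slid.tps")
            energy = pd.DataFrame(
                {
                    "specimen_id": [c.specimen_id for c in configs],
                    "bending_energy_before": slid.bending_energy_before,
                    "bending_energy_after": slid.bending_energy_after,
                }
            )
            energy.to_csv(out / "sliding_report.csv", index=False)
            info.update(outer_iterations=slid.outer_iterations,
                        mean_energy_after=float(slid.bending_energy_after.mean()))
        else:
            info.update(skipped="no curves or sliding disabled")
    except Exception as exc:  # noqa: BLE001
        raise StageError("slide", exc) from exc

    try:
        info = stage("align")
        aligned = gpa_align(configs)
        aligned.save_npz(out / "aligned.npz")
        info.update(iterations=aligned.iterations_used, converged=aligned.converged)
    except Exception as exc:  # noqa: BLE001
        raise StageError("align", exc) from exc

    meta_idx = meta.set_index("specimen_id")
    sex = meta_idx.loc[aligned.specimen_ids, "sex"].to_numpy()
    group = meta_idx.loc[aligned.specimen_ids, "group"].to_numpy()
    known = sex != "U"

    try:
        info = stage("pca_stats")
        spaces = {}
        pc_rows = []
        for kind in config.spaces:
            mat = aligned.as_matrix() if kind == "shape" \
                else to_form_space(aligned).augmented_coordinates
            space = pca(mat, space_kind=kind)
            spaces[kind] = (mat, space)
            for j in range(min(3, space.n_components)):
                pc_rows.append(
                    {"space": kind, "component": f"PC{j + 1}",
                     "percent_variance": space.percent_variance[j]}
                )
        shape_mat = spaces.get("shape", (aligned.as_matrix(), None))[0]
        reg_rows = []
        for name, pred in (
            ("lnCS", aligned.lncs[known]),
            ("sex", (sex[known] == "M").astype(float)),
            ("origin", group[known]),
        ):
            try:
                r = variance_explained_regression(
                    shape_mat[known], pred, predictor_name=name,
                    n_perm=config.n_perm, seed=config.seed,
                )
                reg_rows.append(
                    {"space": "shape", "component": f"regression:{name}",
                     "percent_variance": r.percent_variance_explained,
                     "permutation_p": r.permutation_p}
                )
            except ValueError as exc:
                reg_rows.append(
                    {"space": "shape", "component": f"regression:{name}",
                     "percent_variance": float("nan"), "note": str(exc)}
                )
        allo = allometry_corrected_sex_effect(
            shape_mat[known], aligned.lncs[known], (sex[known] == "M").astype(float)
        )
        reg_rows.append(
            {"space": "shape", "component": "sex|lnCS (allometry-corrected)",
             "percent_variance": allo.percent_of_total}
        )
        pd.DataFrame(pc_rows + reg_rows).to_csv(out / "pc_table.csv", index=False)
        perm = permutation_mean_difference(
            shape_mat[known], sex[known], n_perm=config.n_perm, seed=config.seed
        )
        anova = procrustes_anova(
            shape_mat[known],
            {"lncs": aligned.lncs[known], "sex": (sex[known] == "M").astype(float)},
            include_interaction=True, n_perm=config.n_perm, seed=config.seed,
        )
        anova.to_frame().to_csv(out / "procrustes_anova.csv", index=False)
        info.update(
            sex_mean_distance=perm.observed_statistic,
            sex_permutation_p=perm.p_value,
            allometry_corrected_sex_percent=allo.percent_of_total,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("pca_stats", exc) from exc

    try:
        info = stage("univariate")
        if mtable is not None:
            m_idx = mtable.set_index("specimen_id")
            msex = meta_idx.loc[m_idx.index, "sex"].to_numpy()
            rows = []
            for col in MEASUREMENT_FEATURES:
                st = ttest_and_effect(
                    m_idx[col].to_numpy()[msex != "U"], msex[msex != "U"]
                )
                rows.append(
                    {
                        "measurement": col,
                        "mean_F": st.groups["F"]["mean"], "sd_F": st.groups["F"]["sd"],
                        "mean_M": st.groups["M"]["mean"], "sd_M": st.groups["M"]["sd"],
                        "average_difference": st.average_difference,
                        "t": st.t_statistic, "p": st.p_value,
                        "cohens_d_total": st.cohens_d_total,
                        "cohens_d_pooled": st.cohens_d_pooled,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "univariate_table.csv", index=False)
            info.update(n_measurements=len(rows))
        else:
            info.update(skipped="no measurements")
    except Exception as exc:  # noqa: BLE001
        raise StageError("univariate", exc) from exc

    try:
        info = stage("classification")
        shape_space = spaces.get("shape", (None, None))[1]
        feats: dict[str, np.ndarray] = {}
        if shape_space is not None:
            sel = select_significant_pcs(
                shape_space.scores[known], sex[known], alpha=config.alpha
            )
            info["significant_pcs"] = [int(i) + 1 for i in sel]
            if sel:
                feats["pcs"] = shape_space.scores[known][:, sel]
                feats["pcs+lncs"] = np.column_stack(
                    [shape_space.scores[known][:, sel], aligned.lncs[known]]
                )
        feats["lncs"] = aligned.lncs[known][:, None]
        if mtable is not None:
            m_idx = mtable.set_index("specimen_id")
            msex = meta_idx.loc[m_idx.index, "sex"].to_numpy()
            for col in MEASUREMENT_FEATURES:
                feats[col] = m_idx[col].to_numpy()[msex != "U", None]
        rows = []
        roc_frames = []
        for name in config.classifiers:
            if name not in feats:
                continue
            x = feats[name]
            labels = sex[known] if name in ("pcs", "pcs+lncs", "lncs") \
                else msex[msex != "U"]
            cspec = ClassifierSpec(feature_set=name, priors=config.priors)
            rep = lda_loo_cv(x, labels, cspec)
            box = None
            if x.shape[1] >= 1:
                try:
                    box = boxs_m(x, labels)
                except ValueError:
                    box = None
            rows.append(
                {
                    "feature_set": name,
                    "n": rep.n,
                    "percent_correct_F": rep.percent_correct["positive"],
                    "percent_correct_M": rep.percent_correct["negative"],
                    "weighted_accuracy": rep.accuracy_weighted,
                    "auc": rep.auc,
                    "priors": rep.priors,
                    "box_m_p": None if box is None else box.p_value,
                }
            )
            rf = pd.DataFrame(rep.roc_points, columns=["fpr", "tpr"])
            rf.insert(0, "feature_set", name)
            roc_frames.append(rf)
        pd.DataFrame(rows).to_csv(out / "classification_table.csv", index=False)
        if roc_frames:
            pd.concat(roc_frames).to_csv(out / "roc_points.csv", index=False)
        info.update(n_classifiers=len(rows))
        manifest["classification"] = rows
    except Exception as exc:  # noqa: BLE001
        raise StageError("classification", exc) from exc

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    logger.info("pipeline complete: %s", manifest_path)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
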