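"""End-to-end orchestration: simulate -> normalize -> tendency -> cluster ->
discriminate -> indices -> DNL -> associate, from one YAML configuration.

Every stochastic stage takes an explicit seed from the config; rerunning the
same config reproduces the report bit-identically. Stage failures are
isolated: dependent stages are skipped with a status, independent ones still
run. All artifacts are listed in a manifest with SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import AdjustmentSet, association_scan, attenuation_report
from .bhc import (
    bhc_cut,
    bhc_fit,
    cluster_composition,
    cluster_share,
    label_dnl_cluster,
    to_newick,
)
from .clinical import group_summary, homa_ir, steatosis_labels
from .containers import FeatureTable
from .dnl import cluster_dnl_regression, fsr_linear
from .opls import cv_anova, oplsda_fit, permutation_test, predict_and_roc, splot
from .preprocess import Scaler, qc_normalize, tag_percent_normalize
from .synthetic import (
    CohortSpec,
    TracerSpec,
    generate_cohort,
    generate_enrichment_timecourse,
    generate_mouse_livers,
)
from .tendency import hopkins_by_class

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "RunReport"]

DEFAULT_MARKERS = ["TAG(46:1)", "TAG(46:2)", "TAG(48:1)", "TAG(48:2)", "TAG(50:1)"]
DEFAULT_SETS = {
    "homa": ["homa_ir"],
    "adiposity": ["bmi", "waist_cm"],
    "lifestyle": ["age", "sex", "diet_satfat_pct", "diet_sugar_pct"],
    "genetic": ["snp_ppp1r3b", "snp_gckr", "snp_pnpla3"],
}


@dataclass
class PipelineConfig:
    outdir: Path
    cohort: CohortSpec
    tracer: TracerSpec
    mouse: dict = field(default_factory=lambda: {"n_per_group": 8, "diet_effect": 1.1, "seed": 0})
    bhc: dict = field(default_factory=lambda: {"alpha": 1.0, "r_threshold": 0.5})
    opls: dict = field(
        default_factory=lambda: {"n_folds": 7, "n_perm": 200, "seed": 0, "train_fraction": 0.6}
    )
    association: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.bhc.get("r_threshold", 0.5):
            raise ValueError("bhc.r_threshold must be positive")
        if self.bhc.get("alpha", 1.0) <= 0:
            raise ValueError("bhc.alpha must be positive")
        for key in ("n_folds", "n_perm"):
            if self.opls.get(key, 1) < 1:
                raise ValueError(f"opls.{key} must be >= 1")
        if "seed" not in self.opls:
            raise ValueError("opls config must specify a seed")
        if "seed" not in self.mouse:
            raise ValueError("mouse config must specify a seed")
        tf = self.opls.get("train_fraction", 0.6)
        if not 0.1 <= tf <= 0.9:
            raise ValueError("opls.train_fraction must lie in [0.1, 0.9]")

    def canonical(self) -> dict:
        return {
            "cohort": {**self.cohort.__dict__, "cluster_shares": list(self.cohort.cluster_shares)},
            "tracer": dict(self.tracer.__dict__),
            "mouse": dict(self.mouse),
            "bhc": dict(self.bhc),
            "opls": dict(self.opls),
            "association": dict(self.association),
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config before any computation."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("pipeline config must be a mapping")
    unknown = set(raw) - {"outdir", "cohort", "tracer", "mouse", "bhc", "opls", "association"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    if "outdir" not in raw:
        raise ValueError("config must set outdir")
    cfg = PipelineConfig(
        outdir=Path(raw["outdir"]),
        cohort=CohortSpec.from_dict(raw.get("cohort", {"seed": 0})),
        tracer=TracerSpec.from_dict(raw.get("tracer", {"seed": 0})),
    )
    for sect in ("mouse", "bhc", "opls", "association"):
        if sect in raw:
            getattr(cfg, sect).update(raw[sect])
    cfg.validate()
    return cfg


@dataclass
class RunReport:
    status: dict
    stats: dict
    artifacts: dict
    version: str
    config_hash: str

    def to_json(self, path=None) -> str:
        payload = {
            "version": self.version,
            "config_hash": self.config_hash,
            "status": self.status,
            "stats": self.stats,
            "artifacts": self.artifacts,
        }
        text = json.dumps(payload, indent=1, sort_keys=True, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, log=sys.stderr) -> RunReport:
    """Run all stages, writing artifacts, a manifest and a report under outdir."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict = {}
    stats: dict = {}
    artifacts: dict = {}

    def note(stage, msg):
        print(f"[tagdnl:{stage}] {msg}", file=log)

    def save(name, writer):
        path = out / name
        writer(path)
        artifacts[name] = _sha256(path)
        return path

    t0 = time.time()
    # ---- simulate --------------------------------------------------------
    table = subjects = None
    try:
        table, subjects = generate_cohort(config.cohort)
        tc = generate_enrichment_timecourse(config.tracer)
        mouse_table, mouse_dnl = generate_mouse_livers(
            n_per_group=int(config.mouse["n_per_group"]),
            diet_effect=float(config.mouse["diet_effect"]),
            seed=int(config.mouse["seed"]),
        )
        save("cohort_features.tsv", table.to_tsv)
        save("subjects.tsv", lambda p: subjects.to_csv(p, sep="\t"))
        save("timecourse.tsv", tc.to_tsv)
        save("mouse_features.tsv", mouse_table.to_tsv)
        save("mouse_dnl.tsv", lambda p: mouse_dnl.to_csv(p, sep="\t"))
        status["simulate"] = "ok"
        note("simulate", f"{table.n_samples} samples x {table.n_features} features")
    except Exception as exc:  # noqa: BLE001
        status["simulate"] = f"failed: {exc}"

    # ---- normalize -------------------------------------------------------
    normed = None
    if status.get("simulate") == "ok":
        try:
            normed, report = qc_normalize(table)
            save("normalized_features.tsv", normed.to_tsv)
            save("normalization_report.json", lambda p: report.to_json(p) and None)
            stats["mean_qc_cv_before"] = report.mean_cv_before
            stats["mean_qc_cv_after"] = report.mean_cv_after
            status["normalize"] = "ok"
            note("normalize", f"mean QC CV {report.mean_cv_before:.3f} -> {report.mean_cv_after:.3f}")
        except Exception as exc:  # noqa: BLE001
            status["normalize"] = f"failed: {exc}"
    else:
        status["normalize"] = "skipped"

    # ---- clustering tendency --------------------------------------------
    if status.get("normalize") == "ok":
        try:
            hp = hopkins_by_class(normed, seed=config.cohort.seed)
            stats["hopkins_by_class"] = {
                k: (v.to_dict() if v is not None else "not testable") for k, v in hp.items()
            }
            save(
                "hopkins.json",
                lambda p: p.write_text(
                    json.dumps(stats["hopkins_by_class"], indent=1, sort_keys=True)
                )
                and None,
            )
            status["tendency"] = "ok"
        except Exception as exc:  # noqa: BLE001
            status["tendency"] = f"failed: {exc}"
    else:
        status["tendency"] = "skipped"

    # ---- BHC of TAG profiles --------------------------------------------
    assign = None
    if status.get("normalize") == "ok":
        try:
            tagpct = tag_percent_normalize(normed.subjects())
            Z = Scaler("pareto").fit_transform(tagpct.intensities.to_numpy())
            tree = bhc_fit(
                Z.T, alpha=float(config.bhc.get("alpha", 1.0)), labels=tagpct.feature_labels
            )
            assign = bhc_cut(tree, r_threshold=float(config.bhc.get("r_threshold", 0.5)))
            shares = cluster_share(assign, normed)
            comp = cluster_composition(assign, tagpct.species)
            dnl_cluster = label_dnl_cluster(comp)
            save("bhc_tree.nwk", lambda p: p.write_text(to_newick(tree)) and None)
            save("bhc_assignment.tsv", lambda p: assign.to_frame().to_csv(p, sep="\t", index=False))
            save("cluster_composition.tsv", lambda p: comp.to_csv(p, sep="\t"))
            stats["n_tag_clusters"] = assign.n_clusters
            stats["cluster_shares"] = {int(k): float(v) for k, v in shares.items()}
            stats["dnl_cluster"] = dnl_cluster
            stats["dnl_cluster_share"] = float(shares.loc[dnl_cluster])
            status["bhc"] = "ok"
            note("bhc", f"{assign.n_clusters} clusters; DNL cluster share "
                        f"{stats['dnl_cluster_share']:.3f}")
        except Exception as exc:  # noqa: BLE001
            status["bhc"] = f"failed: {exc}"
    else:
        status["bhc"] = "skipped"

    # ---- OPLS-DA of steatosis -------------------------------------------
    if status.get("normalize") == "ok":
        try:
            subj = normed.subjects()
            X = subj.intensities
            meta = subjects.loc[X.index]
            fli_y = steatosis_labels(meta, scheme="fli60").to_numpy()
            seed = int(config.opls["seed"])
            n_folds = int(config.opls.get("n_folds", 7))
            model = oplsda_fit(X, fli_y, n_folds=n_folds, seed=seed)
            F, df1, df2, p_cv = cv_anova(model)
            perm = permutation_test(
                X.to_numpy(), fli_y,
                n_perm=int(config.opls.get("n_perm", 200)),
                seed=seed, n_folds=n_folds, n_ortho=model.n_ortho,
            )
            sp = splot(model, model.scaler.transform(X.to_numpy()))
            save("opls_splot.tsv", lambda p: sp.to_csv(p, sep="\t"))

            # train on FLI-labelled subjects, test on ultrasound-labelled ones
            n_train = int(round(config.opls.get("train_fraction", 0.6) * X.shape[0]))
            tr, te = X.index[:n_train], X.index[n_train:]
            m_tr = oplsda_fit(X.loc[tr], steatosis_labels(meta.loc[tr], "fli60").to_numpy(),
                              n_folds=n_folds, seed=seed)
            us_y = steatosis_labels(meta.loc[te], "ultrasound").to_numpy()
            _, _, roc, auc_val = predict_and_roc(m_tr, X.loc[te], us_y)
            save("roc.tsv", lambda p: roc.to_csv(p, sep="\t", index=False))
            stats["opls"] = {
                **model.summary(),
                "cv_anova": {"F": F, "df1": df1, "df2": df2, "p": p_cv},
                "permutation": perm.to_dict(),
                "test_auc": auc_val,
            }
            save("opls_summary.json", lambda p: p.write_text(
                json.dumps(stats["opls"], indent=1, sort_keys=True, default=_jsonable))
                and None)
            status["opls"] = "ok"
            note("opls", f"R2X={model.r2x:.2f} R2Y={model.r2y:.2f} Q2={model.q2:.2f} "
                         f"AUC={auc_val:.3f} perm_passed={perm.passed}")
        except Exception as exc:  # noqa: BLE001
            status["opls"] = f"failed: {exc}"
    else:
        status["opls"] = "skipped"

    # ---- clinical indices ------------------------------------------------
    if status.get("simulate") == "ok":
        try:
            labels = steatosis_labels(subjects, scheme="ultrasound")
            summary = group_summary(subjects, labels)
            save("indices_summary.tsv", lambda p: summary.to_csv(p, sep="\t"))
            stats["ultrasound_prevalence"] = float(labels.mean())
            stats["fli_prevalence"] = float(steatosis_labels(subjects, "fli60").mean())
            status["indices"] = "ok"
        except Exception as exc:  # noqa: BLE001
            status["indices"] = f"failed: {exc}"
    else:
        status["indices"] = "skipped"

    # ---- DNL kinetics ----------------------------------------------------
    if status.get("simulate") == "ok":
        try:
            est = fsr_linear(tc)
            save("dnl_estimate.json", lambda p: p.write_text(
                json.dumps(est.to_dict(), indent=1, sort_keys=True)) and None)
            stats["fsr_pct_per_h"] = est.fsr
            # regress the DNL-labelled BHC cluster signal against measured DNL
            if assign is not None and status.get("bhc") == "ok":
                members = [
                    f for f in assign.members(stats["dnl_cluster"])
                    if f in mouse_table.intensities.columns
                ]
                sig = mouse_table.intensities[members].sum(axis=1)
                reg = cluster_dnl_regression(sig, mouse_dnl["de_novo_palmitate_mg"])
                stats["cluster_dnl"] = reg.to_dict()
                save("cluster_dnl.json", lambda p: p.write_text(
                    json.dumps(reg.to_dict(), indent=1, sort_keys=True)) and None)
                note("dnl", f"FSR={est.fsr:.2f} %/h; cluster-DNL R2={reg.r2:.3f}")
            status["dnl"] = "ok"
        except Exception as exc:  # noqa: BLE001
            status["dnl"] = f"failed: {exc}"
    else:
        status["dnl"] = "skipped"

    # ---- association scan ------------------------------------------------
    if status.get("normalize") == "ok":
        try:
            meta = subjects.copy()
            meta["homa_ir"] = homa_ir(meta["glucose_mmol_l"], meta["insulin_pmol_l"])
            markers = config.association.get("markers", DEFAULT_MARKERS)
            set_map = config.association.get("sets", DEFAULT_SETS)
            sets = [AdjustmentSet(n, tuple(c)) for n, c in set_map.items()]
            res = association_scan(normed, meta, markers, "ultrasound_ordinal", sets)
            att = attenuation_report(res)
            save("association.tsv", lambda p: res.to_csv(p, sep="\t", index=False))
            save("attenuation.tsv", lambda p: att.to_csv(p, sep="\t", index=False))
            stats["association_significant_base"] = int(
                ((res["set"] == "base") & (res["p"] < 0.05)).sum()
            )
            status["associate"] = "ok"
        except Exception as exc:  # noqa: BLE001
            status["associate"] = f"failed: {exc}"
    else:
        status["associate"] = "skipped"

    note("pipeline", f"finished in {time.time() - t0:.1f}s")
    report = RunReport(
        status=status,
        stats=stats,
        artifacts=artifacts,
        version=__version__,
        config_hash=config.config_hash(),
    )
    report.to_json(out / "report.json")
    manifest = {"artifacts": artifacts, "config_hash": report.config_hash}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return report
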