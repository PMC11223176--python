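"""End-to-end orchestration: synthetic cohort (or user files) -> fitted maps
-> regional summaries -> correlation / mixed-model / delta report.

Stage order: simulate -> segment (TLCO + TEO) -> fit (R2*, ASL RBF, DCE
4 models x 4 AIF placements, CEUS TIC) -> summarize -> statistics.  A run
is fully deterministic given its configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asl import quantify_asl_rbf
from .bold import fit_r2star
from .ceus import average_roi_tics, tic_parameters
from .dce import PK_MODELS, fit_pk
from .regions import regional_summary, tlco_labels, teo_labels
from .stats import (CorrelationResult, lmm_treatment_effect, spearman_correlate,
                    summary_from_means, treatment_delta)
from .synthetic import StudyConfig, SyntheticStudy, generate_cohort
from .types import RegionalSummary

log = logging.getLogger("renalperf")

AGGREGATES = ("cortex", "medulla", "whole")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class ReportBundle:
    """All pipeline outputs plus provenance.

    Tables are tidy DataFrames; every row carries the dataset id
    (dog/treatment/side) it derives from.
    """

    regional: pd.DataFrame
    tic_params: pd.DataFrame
    pk_results: pd.DataFrame
    correlations: pd.DataFrame
    effects: pd.DataFrame
    deltas: pd.DataFrame
    provenance: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"regional": self.regional, "tic_params": self.tic_params,
                "pk_results": self.pk_results, "correlations": self.correlations,
                "effects": self.effects, "deltas": self.deltas}

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for name, df in sorted(self.tables().items()):
            h.update(name.encode())
            h.update(df.round(9).to_csv(index=False).encode())
        return h.hexdigest()

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(out / f"{name}.csv", index=False)
        from .io import save_manifest
        save_manifest(out / "manifest.json",
                      {**self.provenance, "report_hash": self.content_hash()})


def _config_hash(config: StudyConfig) -> str:
    from .io import config_to_dict
    import json
    return hashlib.sha256(
        json.dumps(config_to_dict(config), sort_keys=True).encode()).hexdigest()


def summaries_for_dataset(ds, fitted_rbf=None, fitted_r2s=None) -> list[dict]:
    """Regional summary rows (both schemes) for the fitted maps of one dataset."""
    rows = []
    for kind, pmap in (("RBF", fitted_rbf), ("R2*", fitted_r2s)):
        if pmap is None:
            continue
        for labels in (ds.truth.labels_tlco, ds.truth.labels_teo):
            summ = regional_summary(pmap, labels)
            for rid, (m, sd, n) in summ.per_region.items():
                rows.append(dict(dog=ds.subject, treatment=ds.treatment,
                                 side=ds.side, scheme=labels.scheme,
                                 region=str(rid), outcome=kind, mean=m, sd=sd,
                                 n_pixels=n))
            for name, (m, sd, n) in summ.aggregates.items():
                rows.append(dict(dog=ds.subject, treatment=ds.treatment,
                                 side=ds.side, scheme=labels.scheme,
                                 region=name, outcome=kind, mean=m, sd=sd,
                                 n_pixels=n))
    return rows


def run_pipeline(config: StudyConfig, cohort: SyntheticStudy | None = None
                 ) -> ReportBundle:
    """Run the full synthetic study and return the report bundle."""
    stage = "simulate"
    try:
        if cohort is None:
            cohort = generate_cohort(config)
        log.info("simulate: %d datasets", len(cohort))

        stage = "fit"
        regional_rows: list[dict] = []
        pk_rows: list[dict] = []
        tic_rows: list[dict] = []
        for ds in cohort:
            fitted_rbf = fitted_r2s = None
            if ds.asl is not None:
                control, label, m0 = ds.asl
                fitted_rbf = quantify_asl_rbf(control, label, m0,
                                              config.asl_params, ds.mask).rbf_map
            if ds.bold is not None:
                fitted_r2s = fit_r2star(ds.bold).r2s_map
            regional_rows.extend(summaries_for_dataset(ds, fitted_rbf, fitted_r2s))

            if ds.dce is not None:
                ct = ds.dce.tissue.data
                for placement, aif in ds.dce.placements.items():
                    for model in PK_MODELS:
                        res = fit_pk(ct, aif, model)
                        pk_rows.append(dict(
                            dog=ds.subject, treatment=ds.treatment, side=ds.side,
                            model=model, placement=placement, F_p=res.fp,
                            v_p=res.vp, F_t=res.ft, T_t=res.tt, RBF=res.rbf,
                            r_squared=res.r_squared, converged=res.converged))
            if ds.ceus is not None:
                for cls, tics in ds.ceus.items():
                    params = tic_parameters(average_roi_tics(tics, cls))
                    tic_rows.append(dict(dog=ds.subject, treatment=ds.treatment,
                                         side=ds.side, roi_class=cls,
                                         **params.as_dict(),
                                         flags=";".join(params.flags)))
        regional = pd.DataFrame(regional_rows)
        pk_results = pd.DataFrame(pk_rows)
        tic_params = pd.DataFrame(tic_rows)
        log.info("fit: %d regional rows, %d PK cells, %d TIC rows",
                 len(regional), len(pk_results), len(tic_params))

        stage = "stats"
        correlations = baseline_correlations(regional, config)
        effects = treatment_effects(regional, pk_results, tic_params, config)
        deltas = fitted_deltas(regional)
        log.info("stats: %d correlations, %d effects, %d delta rows",
                 len(correlations), len(effects), len(deltas))
    except Exception as exc:  # noqa: BLE001 - structured stage error
        raise StageError(stage, exc) from exc

    provenance = {
        "config_hash": _config_hash(config),
        "master_seed": config.master_seed,
        "version": __version__,
        "n_datasets": len(cohort),
    }
    return ReportBundle(regional=regional, tic_params=tic_params,
                        pk_results=pk_results, correlations=correlations,
                        effects=effects, deltas=deltas, provenance=provenance)


def baseline_correlations(regional: pd.DataFrame, config: StudyConfig
                          ) -> pd.DataFrame:
    """Spearman correlation between fitted RBF and fitted R2* across control
    kidneys, at the cortex and the medulla (TLCO aggregates), Bonferroni-
    corrected for the batch."""
    rows = []
    base = regional[(regional.treatment == config.treatments[0])
                    & regional.scheme.str.startswith("TLCO")]
    if base.empty or not {"RBF", "R2*"} <= set(base.outcome.unique()):
        return pd.DataFrame(columns=["level", "var_x", "var_y", "r", "p",
                                     "p_corrected", "band", "n"])
    levels = ["cortex", "medulla"]
    for level in levels:
        sel = base[base.region == level]
        piv = sel.pivot_table(index=["dog", "side"], columns="outcome",
                              values="mean")
        if len(piv) < 5:  # too few kidneys for a rank correlation
            rows.append(dict(level=level, var_x="RBF", var_y="R2*",
                             r=float("nan"), p=float("nan"),
                             p_corrected=float("nan"), band="undefined",
                             n=len(piv)))
            continue
        res = spearman_correlate(piv["RBF"], piv["R2*"], m=len(levels),
                                 pair=("RBF", "R2*"))
        rows.append(dict(level=level, var_x="RBF", var_y="R2*", r=res.r,
                         p=res.p, p_corrected=res.p_corrected, band=res.band,
                         n=res.n))
    return pd.DataFrame(rows)


def treatment_effects(regional: pd.DataFrame, pk_results: pd.DataFrame,
                      tic_params: pd.DataFrame, config: StudyConfig
                      ) -> pd.DataFrame:
    """LMM treatment effects with modality-appropriate nesting: dog/side for
    the regional MRI aggregates, dog/side for DCE, dog for CEUS.

    Designs too small for a mixed model (a single subject) are recorded as
    undefined rather than failing the run."""
    rows = []

    def _fit(sub, structure):
        from .types import InvalidInputError
        try:
            eff = lmm_treatment_effect(sub, "value", structure)
            return dict(estimate=eff.estimate, se=eff.se, lrt=eff.lrt, p=eff.p,
                        flags=";".join(eff.flags))
        except InvalidInputError as exc:
            nan = float("nan")
            return dict(estimate=nan, se=nan, lrt=nan, p=nan, flags=str(exc))
    if not regional.empty:
        tlco = regional[regional.scheme.str.startswith("TLCO")]
        for outcome in sorted(tlco.outcome.unique()):
            for level in AGGREGATES:
                sub = tlco[(tlco.outcome == outcome) & (tlco.region == level)]
                sub = sub.rename(columns={"mean": "value"})
                rows.append(dict(modality="ASL" if outcome == "RBF" else "BOLD",
                                 outcome=outcome, level=level,
                                 **_fit(sub, ("dog", "side"))))
    if not pk_results.empty:
        for (model, placement), sub in pk_results.groupby(["model", "placement"]):
            sub = sub.rename(columns={"RBF": "value"})
            rows.append(dict(modality="DCE", outcome=f"RBF[{model},{placement}]",
                             level="whole", **_fit(sub, ("dog", "side"))))
    if not tic_params.empty:
        for (cls, param) in [(c, p) for c in ("cortex", "medulla")
                             for p in ("PI", "WiR", "AUC", "TTP", "RT", "FT")]:
            sub = tic_params[tic_params.roi_class == cls].rename(
                columns={param: "value"})
            rows.append(dict(modality="CEUS", outcome=param, level=cls,
                             **_fit(sub, ("dog",))))
    return pd.DataFrame(rows)


def fitted_deltas(regional: pd.DataFrame) -> pd.DataFrame:
    """Treatment-minus-control differences of the cohort-mean fitted TLCO
    regional values, per outcome."""
    if regional.empty:
        return pd.DataFrame(columns=["outcome", "region", "treated_mean",
                                     "treated_sd", "control_mean", "control_sd",
                                     "delta"])
    out = []
    tlco = regional[regional.scheme.str.startswith("TLCO")]
    treatments = sorted(tlco.treatment.unique())
    treated_name = "dopamine" if "dopamine" in treatments else treatments[-1]
    control_name = [t for t in treatments if t != treated_name][0]
    for outcome, sub in tlco.groupby("outcome"):
        summaries = {}
        for tname in (treated_name, control_name):
            g = sub[sub.treatment == tname].groupby("region")["mean"]
            means, sds = g.mean(), g.std(ddof=1)
            entries = {}
            for region in means.index:
                key = region if region in AGGREGATES else int(region)
                entries[key] = (float(means[region]), float(sds[region]))
            summaries[tname] = summary_from_means("TLCO-12", outcome, entries)
        tab = treatment_delta(summaries[treated_name], summaries[control_name])
        tab.insert(0, "outcome", outcome)
        out.append(tab)
    return pd.concat(out, ignore_index=True)
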