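"""End-to-end orchestration: simulate -> AIMs -> ancestry -> IVs -> MR.

The flowchart implemented here:

1. simulate reference panels, admixed case-control cohort and PheWAS catalog;
2. panel allele frequencies and informativeness-based AIM preselection;
3. supervised EM ancestry estimation on the AIM union (the exposure);
4. exposure scan (controls) at the genome-wide threshold;
5. PheWAS confounder-phenotype exclusion;
6. explained-variance-ranked greedy LD pruning in the controls
   (preliminary instruments);
7. age-adjusted outcome scan (cases + controls), harmonisation and iterative
   radial outlier exclusion (final instruments);
8. IVW / MR-Egger / weighted-median estimation plus instrument-strength
   summaries;
9. stratified re-analysis on case subsets with the controls reused unchanged.

Every stage records its SNP count, producing the selection waterfall; the
whole report is a plain JSON-serialisable dict, reproducible byte for byte
from the config and seed.

Explained variances feed the cumulative R^2 on the 0-1 proportion scale of the
exposure (per-allele beta / 100), which keeps the sum of per-SNP
contributions a small absolute variance; the mean per-instrument F uses true
per-SNP variance fractions. See docs/methods.md for the scale discussion.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aims import AimPanel, allele_frequencies, preselect_aims
from .ancestry import ancestry_summary, estimate_cohort_ancestry
from .config import PipelineConfig
from .instruments import (
    InstrumentReport,
    explained_variance,
    greedy_ld_prune,
    instrument_strength,
    linear_scan_ancestry,
    logistic_scan_outcome,
    phewas_filter,
)
from .mr import MRResult, harmonize, ivw, mr_egger, radial_outlier_filter, weighted_median
from .simulate import Cohort, simulate_case_control_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "stratified_run", "stratum_mask"]


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def stratum_mask(phenotypes: pd.DataFrame, name: str) -> np.ndarray:
    """Boolean mask over individuals selecting the cases of a stratum.

    Strata are defined on case attributes only; controls are never selected.
    """
    cases = phenotypes["status"].to_numpy(int) == 1
    if name == "all":
        return cases
    if name == "diag_le_45":
        aad = phenotypes["age_at_diagnosis"].to_numpy(float)
        with np.errstate(invalid="ignore"):
            return cases & (aad <= 45.0)
    if name == "familial":
        return cases & (phenotypes["family_history"].to_numpy(int) == 1)
    er = phenotypes["er"].astype("string")
    if name == "er_pos":
        return cases & (er == "+").to_numpy(dtype=bool, na_value=False)
    if name == "er_neg":
        return cases & (er == "-").to_numpy(dtype=bool, na_value=False)
    if name == "triple_negative":
        pr = phenotypes["pr"].astype("string")
        her2 = phenotypes["her2"].astype("string")
        return (
            cases
            & (er == "-").to_numpy(dtype=bool, na_value=False)
            & (pr == "-").to_numpy(dtype=bool, na_value=False)
            & (her2 == "-").to_numpy(dtype=bool, na_value=False)
        )
    raise ValueError(f"unknown stratum {name!r}")


@dataclass
class PipelineResult:
    """Report bundle of one pipeline run."""

    config: dict
    stage_counts: dict
    ancestry_controls: dict
    instrument_report: InstrumentReport
    main: dict[str, MRResult]
    strata: dict[str, dict]
    tables: dict[str, pd.DataFrame]

    def report(self) -> dict:
        rep = {
            "config": self.config,
            "stage_counts": self.stage_counts,
            "ancestry_controls": self.ancestry_controls,
            "instruments": {
                "n_iv": self.instrument_report.k,
                "r2_cumulative": self.instrument_report.r2_cumulative,
                "explained_variance_pct": 100.0 * self.instrument_report.r2_cumulative,
                "f_stat": self.instrument_report.f_stat,
                "f_mean_per_iv": self.instrument_report.f_mean_per_iv,
            },
            "main": {k: v.to_dict() for k, v in self.main.items()},
            "strata": self.strata,
        }
        return rep

    def to_json(self) -> str:
        return json.dumps(self.report(), sort_keys=True, indent=2)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json() + "\n")
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")


def _mr_suite(inst, config: PipelineConfig, seed: int) -> dict[str, MRResult]:
    out = {"IVW": ivw(inst, random_effects=config.random_effects)}
    if inst.n_iv >= 3:
        out["Egger"] = mr_egger(inst)
        out["WM"] = weighted_median(inst, n_boot=config.n_boot_wm, seed=seed)
    return out


def _attach_strength(res: MRResult, report: InstrumentReport) -> MRResult:
    return dataclasses.replace(res, r2_cumulative=report.r2_cumulative, f_stat=report.f_stat)


def stratified_run(
    cohort: Cohort,
    exposure_stats: pd.DataFrame,
    prelim_ids: np.ndarray,
    config: PipelineConfig,
    strata: Sequence[str] | None = None,
    ev_by_snp: Mapping[str, float] | None = None,
    exposure_variance: float | None = None,
) -> dict[str, dict]:
    """Re-run the outcome arm of the analysis on case strata.

    For each stratum the outcome scan is recomputed on the stratum's cases
    plus ALL controls, the preliminary instruments are re-harmonised and
    radial-filtered (so instrument counts may differ between strata), and the
    MR estimators are refitted. Strata with fewer than
    ``config.min_stratum_cases`` cases are refused.
    """
    strata = tuple(strata if strata is not None else config.strata)
    ph = cohort.phenotypes
    controls = ph["status"].to_numpy(int) == 0
    col = {s: j for j, s in enumerate(cohort.snp_ids)}
    cols = np.array([col[s] for s in prelim_ids])
    prelim_exp = exposure_stats[exposure_stats["snp_id"].isin(set(prelim_ids))]
    out: dict[str, dict] = {}
    for name in strata:
        mask = stratum_mask(ph, name)
        n_cases = int(mask.sum())
        if n_cases < config.min_stratum_cases:
            raise ValueError(
                f"stratum {name!r} has only {n_cases} cases "
                f"(< {config.min_stratum_cases}); too unstable to analyse"
            )
        rows = mask | controls
        out_stats = logistic_scan_outcome(
            cohort.genotypes[np.ix_(rows, cols)],
            ph.loc[rows, "status"].to_numpy(int),
            ph.loc[rows, "age"].to_numpy(float),
            prelim_ids,
            None if cohort.ref is None else cohort.ref[cols],
            None if cohort.alt is None else cohort.alt[cols],
        )
        inst = harmonize(prelim_exp, out_stats)
        if inst.n_iv >= 3:
            inst, _ = radial_outlier_filter(inst, alpha=config.radial_p)
        results = _mr_suite(inst, config, seed=config.simulation.seed)
        entry = {"n_cases": n_cases, "n_iv": inst.n_iv}
        if ev_by_snp is not None:
            ev = np.array([ev_by_snp[s] for s in inst.snp_ids])
            rep = instrument_strength(
                inst.snp_ids, ev, n=int(controls.sum()), exposure_variance=exposure_variance
            )
            entry["explained_variance_pct"] = 100.0 * rep.r2_cumulative
            results = {k: _attach_strength(v, rep) for k, v in results.items()}
        entry.update({k: v.to_dict() for k, v in results.items()})
        out[name] = entry
    return out


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute the whole flowchart from a config; reproducible from the seed."""
    sim = config.simulation

    cohort, panels, _true_freqs, catalog = _stage("simulate")(simulate_case_control_study)(sim)
    ph = cohort.phenotypes
    status = ph["status"].to_numpy(int)
    age = ph["age"].to_numpy(float)
    controls = status == 0

    panel_freqs = _stage("panel_frequencies")(allele_frequencies)(panels, cohort.snp_ids)
    aim_panel: AimPanel = _stage("preselect_aims")(preselect_aims)(panel_freqs, top_k=config.top_k)
    aim_set = set(aim_panel.union)
    aim_mask = np.fromiter((s in aim_set for s in cohort.snp_ids), bool, cohort.n_snps)

    anc = _stage("estimate_ancestry")(estimate_cohort_ancestry)(
        cohort.genotypes,
        cohort.snp_ids,
        cohort.sample_ids,
        panel_freqs,
        restrict_to=aim_panel.union,
        tol=config.em_tol,
        max_iter=config.em_max_iter,
    )
    qhat_pct = anc["q_NA_percent"].to_numpy(float)
    anc_summary = ancestry_summary(qhat_pct, controls)

    exp_stats = _stage("exposure_scan")(linear_scan_ancestry)(
        cohort.genotypes[np.ix_(controls, np.flatnonzero(aim_mask))],
        qhat_pct[controls],
        age[controls],
        cohort.snp_ids[aim_mask],
        None if cohort.ref is None else cohort.ref[aim_mask],
        None if cohort.alt is None else cohort.alt[aim_mask],
    )
    sig = exp_stats[exp_stats["pval"] < config.gwas_p].reset_index(drop=True)
    if sig.empty:
        raise StageError("stage 'gwas_threshold' failed: no SNP passed the exposure threshold")

    kept_ids = _stage("phewas_filter")(phewas_filter)(
        sig["snp_id"].to_numpy(), catalog, threshold=config.phewas_p
    )
    sig = sig[sig["snp_id"].isin(set(kept_ids))].reset_index(drop=True)
    if sig.empty:
        raise StageError("stage 'phewas_filter' failed: every candidate was excluded")

    # explained variance on the 0-1 proportion scale of the exposure
    ev_all = explained_variance(sig["beta"].to_numpy() / 100.0, sig["eaf"].to_numpy())
    var_prop = float(np.var(qhat_pct[controls] / 100.0))
    col = {s: j for j, s in enumerate(cohort.snp_ids)}
    sig_cols = np.array([col[s] for s in sig["snp_id"]])
    prelim_ids = _stage("ld_prune")(greedy_ld_prune)(
        sig["snp_id"].to_numpy(),
        ev_all,
        cohort.genotypes[np.ix_(controls, sig_cols)],
        r2_threshold=config.ld_r2,
    )
    ev_by_snp = dict(zip(sig["snp_id"], ev_all))

    prelim_cols = np.array([col[s] for s in prelim_ids])
    out_stats = _stage("outcome_scan")(logistic_scan_outcome)(
        cohort.genotypes[:, prelim_cols],
        status,
        age,
        prelim_ids,
        None if cohort.ref is None else cohort.ref[prelim_cols],
        None if cohort.alt is None else cohort.alt[prelim_cols],
    )
    prelim_exp = sig[sig["snp_id"].isin(set(prelim_ids))]
    inst = _stage("harmonize")(harmonize)(prelim_exp, out_stats)
    removed = np.array([], dtype=str)
    if inst.n_iv >= 3:
        inst, removed = _stage("radial_filter")(radial_outlier_filter)(
            inst, alpha=config.radial_p
        )

    ev_final = np.array([ev_by_snp[s] for s in inst.snp_ids])
    report = _stage("instrument_strength")(instrument_strength)(
        inst.snp_ids,
        ev_final,
        n=int(controls.sum()),
        exposure_variance=var_prop,
        stage_counts={},
    )
    main = {k: _attach_strength(v, report) for k, v in _mr_suite(inst, config, sim.seed).items()}

    strata_res: dict[str, dict] = {}
    for name in config.strata:
        try:
            strata_res.update(
                stratified_run(
                    cohort,
                    exp_stats,
                    prelim_ids,
                    config,
                    strata=[name],
                    ev_by_snp=ev_by_snp,
                    exposure_variance=var_prop,
                )
            )
        except ValueError as exc:
            strata_res[name] = {"skipped": str(exc)}

    stage_counts = {
        "simulated_snps": int(cohort.n_snps),
        "preselected_aims": int(aim_panel.n_retained),
        "gwas_significant": int((exp_stats["pval"] < config.gwas_p).sum()),
        "after_phewas": int(len(sig)),
        "preliminary_ivs": int(prelim_ids.size),
        "final_ivs": int(inst.n_iv),
    }

    tables = {
        "ancestry": anc,
        "exposure_stats": exp_stats,
        "outcome_stats": out_stats,
        "instruments": inst.to_frame(),
        "aim_rankings": aim_panel.rankings,
    }
    result = PipelineResult(
        config=config.to_dict(),
        stage_counts=stage_counts,
        ancestry_controls=anc_summary,
        instrument_report=report,
        main=main,
        strata=strata_res,
        tables=tables,
    )
    if outdir is not None:
        result.write(outdir)
    return result
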