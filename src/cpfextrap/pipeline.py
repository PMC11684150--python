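"""End-to-end pipeline: cohort -> pool -> impute -> events -> KM -> fits ->
semi-Markov extrapolation -> report.

Every stage reads its inputs from and writes its outputs to a run
directory, so stages are individually re-runnable; a manifest records the
config echo, seeds, package versions and output hashes. Point estimates
average over the imputation completions; the extrapolation uses the
selected family's fit per arm.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, generate_cohort, write_cohort
from .events import OUTCOMES, apply_lead_in, derive_all_outcomes
from .families import get_family
from .harmonize import apply_exclusions, link_and_resolve
from .impute import fit_imputation_model, impute
from .nonparam import km_estimate, km_to_frame, plot_km_overlay, two_sample_test
from .paramfit import FamilySpec, compare_models, fit_mle, load_fits, predict_curve, save_fits
from .records import frames_to_records, records_to_frames
from .semimarkov import TransitionModel, bias_adjust, remission_table, simulate_cohort, solve_renewal

logger = logging.getLogger(__name__)

DEFAULT_FAMILIES = ("weibull", "gompertz", "gengamma", "loglogistic", "lognormal")
DEFAULT_LOCATION_COVARIATES = (
    "age_c",
    "male",
    "cd_duration_c",
    "luminal_active",
    "prior_biologic",
)


@dataclass
class PipelineConfig:
    """Single-config parameterization of the whole analysis.

    Defaults reproduce the analysis shape of the study the package
    emulates: four outcomes, five candidate families, a 4-week lead-in and
    a 48-month extrapolation horizon.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    m_imputations: int = 20
    outcomes: tuple = OUTCOMES
    families: tuple = DEFAULT_FAMILIES
    location_covariates: tuple = DEFAULT_LOCATION_COVARIATES
    shape_covariates: tuple = ()
    lead_in_weeks: float = 4.0
    horizon_months: float = 48.0
    engine: str = "microsim"  # or "renewal"
    n_sim: int = 20000
    report_months: tuple = (0, 8, 24, 48)
    extrapolation_family: str | None = "gompertz"  # None = best AIC per arm
    remission_outcome: str = "CPC_REMISSION"
    relapse_outcome: str = "CPC_RELAPSE_FROM_CPC"
    bias_adjust_variables: tuple = ()
    seed: int = 2024

    def validate(self) -> None:
        for fam in self.families:
            get_family(fam)
        if self.extrapolation_family is not None:
            get_family(self.extrapolation_family)
        for o in self.outcomes:
            if o not in OUTCOMES:
                raise ValueError(f"unknown outcome {o!r}")
        if self.engine not in ("microsim", "renewal"):
            raise ValueError("engine must be 'microsim' or 'renewal'")
        if self.m_imputations < 1:
            raise ValueError("m_imputations must be >= 1")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be > 0")
        if max(self.report_months) > self.horizon_months:
            raise ValueError("report month beyond horizon")
        self.cohort.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        cohort = CohortConfig(**cohort_raw)
        tuple_keys = {
            "outcomes", "families", "location_covariates", "shape_covariates",
            "report_months", "bias_adjust_variables",
        }
        kwargs = {}
        for k, v in raw.items():
            kwargs[k] = tuple(v) if k in tuple_keys and v is not None else v
        cfg = cls(cohort=cohort, **kwargs)
        cfg.validate()
        return cfg


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineRun:
    """Stage-by-stage executor bound to a run directory."""

    def __init__(self, config: PipelineConfig, outdir):
        config.validate()
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.timings: dict = {}

    # -- stages ---------------------------------------------------------
    def stage_cohort(self):
        cfg = self.config.cohort
        records = generate_cohort(cfg)
        write_cohort(records, self.outdir / "cohort", config=cfg)
        return records

    def _read_records(self, sub):
        base = pd.read_csv(self.outdir / sub / "baseline.csv")
        visits = pd.read_csv(self.outdir / sub / "visits.csv")
        return frames_to_records(base, visits)

    def stage_pool(self):
        records = self._read_records("cohort")
        trial = [r for r in records if r.study == "TRIAL"]
        rwe = [r for r in records if r.study == "RWE"]
        merged = link_and_resolve(trial, [], require_link=False) + rwe
        dvs, soc = apply_exclusions(merged)
        pooled = dvs.records + soc.records
        out = self.outdir / "pooled"
        write_cohort(pooled, out)
        retention = {
            "DVS_SET": dvs.retention,
            "SOC_SET": soc.retention,
            "n_dvs": len(dvs.records),
            "n_soc": len(soc.records),
            "n_total": len(pooled),
        }
        (out / "retention.json").write_text(json.dumps(retention, indent=2))
        return dvs, soc

    def stage_impute(self):
        records = self._read_records("pooled")
        model = fit_imputation_model(records)
        result = impute(model, records, m=self.config.m_imputations, seed=self.config.seed + 1)
        out = self.outdir / "imputed"
        out.mkdir(exist_ok=True)
        frames = []
        for i, recs in enumerate(result.completed):
            b, v = records_to_frames(recs)
            b["imputation_index"] = i
            v["imputation_index"] = i
            frames.append((b, v))
        pd.concat([f[0] for f in frames]).to_csv(out / "baseline.csv", index=False)
        pd.concat([f[1] for f in frames]).to_csv(out / "visits.csv", index=False)
        (out / "diagnostics.json").write_text(json.dumps(result.diagnostics, indent=2))
        return result

    def _read_completions(self):
        base = pd.read_csv(self.outdir / "imputed" / "baseline.csv")
        visits = pd.read_csv(self.outdir / "imputed" / "visits.csv")
        completions = []
        for i in sorted(base["imputation_index"].unique()):
            b = base[base["imputation_index"] == i].drop(columns="imputation_index")
            v = visits[visits["imputation_index"] == i].drop(columns="imputation_index")
            completions.append(frames_to_records(b, v))
        return completions

    def stage_events(self):
        completions = self._read_completions()
        out = self.outdir / "events"
        out.mkdir(exist_ok=True)
        all_frames = []
        for i, recs in enumerate(completions):
            for outcome, df in derive_all_outcomes(recs).items():
                if outcome not in self.config.outcomes:
                    continue
                df = df.copy()
                df["imputation_index"] = i
                all_frames.append(df)
        samples = pd.concat(all_frames, ignore_index=True)
        samples.to_csv(out / "samples.csv", index=False)
        return samples

    def stage_km(self):
        samples = pd.read_csv(self.outdir / "events" / "samples.csv")
        first = samples[samples["imputation_index"] == samples["imputation_index"].min()]
        out = self.outdir / "km"
        out.mkdir(exist_ok=True)
        summary = {}
        for outcome in self.config.outcomes:
            sub = first[first["outcome"] == outcome]
            per_arm = {}
            ests = {}
            for arm in sorted(sub["arm"].unique()):
                s = sub[sub["arm"] == arm]
                est = km_estimate(s["time"], s["event"])
                ests[arm] = est
                km_to_frame(est).to_csv(out / f"km_{outcome}_{arm}.csv", index=False)
                per_arm[arm] = {
                    "n": est.n,
                    "median_weeks": est.median,
                    "median_ci": list(est.median_ci),
                    "rmst": est.rmst,
                }
            tests = {}
            arms = sorted(sub["arm"].unique())
            if len(arms) == 2:
                a, b = arms
                sa, sb = sub[sub["arm"] == a], sub[sub["arm"] == b]
                for method in ("LOGRANK", "GEHAN_WILCOXON_PETO"):
                    tr = two_sample_test(sa["time"], sa["event"], sb["time"], sb["event"], method)
                    tests[method] = {"statistic": tr.statistic, "p_value": tr.p_value, "df": tr.df}
                ax = plot_km_overlay(ests, title=outcome)
                ax.figure.savefig(out / f"km_{outcome}.png", dpi=120)
                import matplotlib.pyplot as plt

                plt.close(ax.figure)
            summary[outcome] = {"arms": per_arm, "tests": tests}
        (out / "km_summary.json").write_text(json.dumps(summary, indent=2, default=float))
        return summary

    def stage_fit(self):
        samples = pd.read_csv(self.outdir / "events" / "samples.csv")
        out = self.outdir / "fits"
        out.mkdir(exist_ok=True)
        fits: dict = {}
        selection_rows = []
        for outcome in self.config.outcomes:
            for arm in sorted(samples["arm"].unique()):
                per_family_pooled = {}
                for fam in self.config.families:
                    spec = FamilySpec(fam, self.config.location_covariates, self.config.shape_covariates)
                    per_imp = []
                    for i in sorted(samples["imputation_index"].unique()):
                        sub = samples[
                            (samples["outcome"] == outcome)
                            & (samples["arm"] == arm)
                            & (samples["imputation_index"] == i)
                        ]
                        if len(sub) < 5:
                            continue
                        shifted = apply_lead_in(sub, self.config.lead_in_weeks)
                        per_imp.append(fit_mle(shifted, spec, auto_drop_shape=True))
                    if not per_imp:
                        continue
                    # average coefficients over completions; AIC/BIC averaged
                    pooled = per_imp[0]
                    for key in pooled.beta:
                        pooled.beta[key] = float(np.mean([f.beta[key] for f in per_imp]))
                    for key in pooled.gamma_shape:
                        pooled.gamma_shape[key] = float(
                            np.mean([f.gamma_shape.get(key, 0.0) for f in per_imp])
                        )
                    if pooled.q is not None:
                        pooled.q = float(np.mean([f.q for f in per_imp]))
                    pooled.aic = float(np.mean([f.aic for f in per_imp]))
                    pooled.bic = float(np.mean([f.bic for f in per_imp]))
                    pooled.loglik = float(np.mean([f.loglik for f in per_imp]))
                    per_family_pooled[fam] = pooled
                    selection_rows.append(
                        {
                            "outcome": outcome,
                            "arm": arm,
                            "family": fam,
                            "aic": pooled.aic,
                            "bic": pooled.bic,
                            "converged": all(f.converged for f in per_imp),
                        }
                    )
                for fam, f in per_family_pooled.items():
                    fits[f"{outcome}.{arm}.{fam}"] = f
        save_fits(fits, out / "fits.json")
        pd.DataFrame(selection_rows).to_csv(out / "model_selection.csv", index=False)
        return fits

    def _population_table(self, arm):
        base = pd.read_csv(self.outdir / "imputed" / "baseline.csv")
        first = base[base["imputation_index"] == base["imputation_index"].min()]
        sub = first[first["arm"] == arm]
        from .records import encode_covariates

        recs = []
        for _, row in sub.iterrows():
            recs.append(encode_covariates({k: row.get(k) for k in row.index}))
        return pd.DataFrame(recs)

    def stage_extrapolate(self):
        fits = load_fits(self.outdir / "fits" / "fits.json")
        sel = pd.read_csv(self.outdir / "fits" / "model_selection.csv")
        out = self.outdir / "extrapolation"
        out.mkdir(exist_ok=True)
        traces = {}
        for arm in sorted({k.split(".")[1] for k in fits}):
            if self.config.extrapolation_family is not None:
                fam = self.config.extrapolation_family
            else:
                sub = sel[(sel["arm"] == arm) & (sel["outcome"] == self.config.remission_outcome)]
                fam = sub.sort_values("aic").iloc[0]["family"]
            rem = fits[f"{self.config.remission_outcome}.{arm}.{fam}"]
            rel_key = f"{self.config.relapse_outcome}.{arm}.{fam}"
            rel = fits.get(rel_key)
            if rel is None:
                raise ValueError(f"missing relapse fit {rel_key}")
            table = self._population_table(arm)
            weights = None
            if self.config.bias_adjust_variables:
                ref = self._population_table("DVS")
                adj = bias_adjust(table, ref, list(self.config.bias_adjust_variables))
                weights = adj["weight"].to_numpy()
            model = TransitionModel(
                to_remission=rem,
                to_relapse=rel,
                lead_in_weeks=self.config.lead_in_weeks,
                covariate_table=table,
                arm=arm,
                weights=weights,
            )
            if self.config.engine == "microsim":
                trace = simulate_cohort(
                    model, self.config.n_sim, self.config.horizon_months,
                    seed=self.config.seed + 7,
                )
            else:
                trace = solve_renewal(model, self.config.horizon_months, max_profiles=200,
                                      seed=self.config.seed + 7)
            trace.to_frame().to_csv(out / f"trace_{arm}.csv", index=False)
            traces[arm] = trace
        return traces

    def stage_report(self):
        out = self.outdir / "report"
        out.mkdir(exist_ok=True)
        traces = {}
        for f in sorted((self.outdir / "extrapolation").glob("trace_*.csv")):
            arm = f.stem.replace("trace_", "")
            df = pd.read_csv(f)
            from .semimarkov import CohortTrace

            traces[arm] = CohortTrace(
                months=df["month"].to_numpy(),
                proportion_remission=df["proportion_remission"].to_numpy(),
                arm=arm,
            )
        table = remission_table(traces, months=self.config.report_months)
        table.to_csv(out / "remission_table.csv", index=False)
        table.to_json(out / "remission_table.json", orient="records", indent=2)

        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        for arm, trace in traces.items():
            ax.plot(trace.months, 100.0 * trace.proportion_remission, label=arm)
        ax.set_xlabel("months since treatment")
        ax.set_ylabel("% in CPC remission")
        ax.legend()
        fig.savefig(out / "occupancy.png", dpi=120)
        plt.close(fig)
        return table

    STAGES = ("cohort", "pool", "impute", "events", "km", "fit", "extrapolate", "report")

    def run_stage(self, name):
        t0 = time.perf_counter()
        result = getattr(self, f"stage_{name}")()
        self.timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.1fs", name, self.timings[name])
        return result

    def run_all(self):
        result = None
        try:
            for name in self.STAGES:
                result = self.run_stage(name)
        except Exception as e:
            self._write_manifest(failed_stage=name, error=str(e))
            raise RuntimeError(f"pipeline failed at stage {name!r}: {e}") from e
        self._write_manifest()
        return result

    def _write_manifest(self, failed_stage=None, error=None):
        cfg = asdict(self.config)
        cfg["cohort"] = {
            k: v for k, v in cfg["cohort"].items()
            if k not in ("covariate_model", "true_models", "missingness")
        }
        outputs = {
            str(p.relative_to(self.outdir)): _hash_file(p)
            for p in sorted(self.outdir.rglob("*"))
            if p.is_file() and p.suffix in (".csv", ".json") and p.name != "manifest.json"
        }
        from . import __version__ as pkg_version

        manifest = {
            "package_version": pkg_version,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "config": cfg,
            "seed": self.config.seed,
            "timings_s": self.timings,
            "outputs_sha256_16": outputs,
            "failed_stage": failed_stage,
            "error": error,
        }
        (self.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute every stage in order; returns the run directory."""
    run = PipelineRun(config, outdir)
    run.run_all()
    return run.outdir
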