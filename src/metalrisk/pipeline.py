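"""End-to-end pipeline with a reproducibility manifest.

A RunConfig captures every semantic setting; run_pipeline executes the
requested stages (risk, Monte Carlo, chemometrics) on an input table or a
simulated cohort, writes the reports, and records a manifest (package
version, config hash, seeds, input checksum) so a run can be reproduced
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import __version__
from .chemometrics import correlation_report, pearson_matrix, records_to_matrix, run_hca, run_pca
from .ingest import (
    load_study_records,
    read_concentrations,
    resolve_censored,
    write_records,
    write_report,
)
from .montecarlo import (
    FittedDistribution,
    fit_candidates,
    mc_report,
    point_mass,
    propagate,
)
from .reference import TISSUES, load_reference_bundle
from .risk import risk_table, tissue_risk
from .synthetic import default_cohort_spec, generate_cohort


class PipelineError(RuntimeError):
    """Stage failure; the message names the failed stage."""


@dataclass
class RunConfig:
    """Pipeline settings; defaults reproduce the packaged study choices
    (non-detects as zero, equal group pooling, 10,000 MC iterations,
    70-kg adult)."""

    input: Optional[str] = None      # CSV path; None = packaged study table
    simulate: bool = False           # generate a synthetic cohort instead
    output_prefix: str = "metalrisk_run"
    nd_policy: str = "zero"
    pooling: str = "equal"
    tissues: tuple = TISSUES
    exposure_overrides: dict = field(default_factory=dict)
    mc_families: tuple = ("lognormal", "weibull", "beta_scaled", "normal")
    mc_iters: int = 10_000
    seed: int = 42
    stages: tuple = ("risk",)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _atomic_write(path: str, writer) -> None:
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns {stage: output path} plus
    the manifest path."""
    outputs: dict[str, str] = {}
    tox, params, lod_table = load_reference_bundle(
        config.exposure_overrides or None
    )

    # --- ingest / simulate ------------------------------------------------
    try:
        if config.simulate:
            spec = default_cohort_spec(seed=config.seed)
            records = generate_cohort(spec, lod_table)
            cohort_path = f"{config.output_prefix}_cohort.csv"
            _atomic_write(cohort_path, lambda p: write_records(records, p))
            outputs["cohort"] = cohort_path
            input_checksum = _sha256_file(cohort_path)
        elif config.input is not None:
            records = read_concentrations(config.input, lod_table)
            input_checksum = _sha256_file(config.input)
        else:
            records = load_study_records()
            input_checksum = "packaged-study-table"
    except (OSError, ValueError) as exc:
        raise PipelineError(f"ingest stage failed: {exc}") from exc

    # --- deterministic risk ----------------------------------------------
    if "risk" in config.stages:
        try:
            trs = [
                tissue_risk(records, tox, params, tissue,
                            weights=config.pooling, nd_policy=config.nd_policy)
                for tissue in config.tissues
            ]
            table = risk_table(trs)
            risk_csv = f"{config.output_prefix}_risk.csv"
            risk_json = f"{config.output_prefix}_risk.json"
            _atomic_write(risk_csv, lambda p: write_report(table, p, "csv"))
            _atomic_write(risk_json, lambda p: write_report(table, p, "json"))
            outputs["risk_csv"] = risk_csv
            outputs["risk_json"] = risk_json
        except (ValueError, KeyError) as exc:
            raise PipelineError(f"risk stage failed: {exc}") from exc

    # --- Monte Carlo -------------------------------------------------------
    if "mc" in config.stages:
        try:
            frames = []
            for tissue in config.tissues:
                fitted = {}
                per_sample = [r for r in records
                              if r.group.tissue == tissue and r.sample_id]
                if per_sample:
                    mat = records_to_matrix(per_sample, nd_policy=config.nd_policy)
                    for el in mat.columns:
                        x = mat[el].dropna().to_numpy()
                        if x.max() == x.min():
                            fitted[el] = point_mass(float(x[0]))
                        else:
                            fitted[el] = fit_candidates(x, config.mc_families)[0]
                else:
                    # group summaries: moment-matched lognormal per pooled cell
                    import math

                    from scipy import stats

                    from .risk import pool_groups
                    from .synthetic import _lognormal_params

                    pooled = pool_groups(records, weights=config.pooling,
                                         nd_policy=config.nd_policy)
                    pooled = pooled[pooled["tissue"] == tissue]
                    res = resolve_censored(
                        [r for r in records if r.group.tissue == tissue],
                        policy=config.nd_policy)
                    sds = pd.DataFrame(
                        [{"element": r.element, "sd": r.sd} for r in res]
                    ).groupby("element")["sd"].mean()
                    for _, row in pooled.iterrows():
                        el, m = row["element"], float(row["concentration"])
                        s = float(sds.get(el) or 0.0)
                        if m <= 0 or s <= 0:
                            fitted[el] = point_mass(max(m, 0.0))
                        else:
                            mu, sigma = _lognormal_params(m, s)
                            fitted[el] = FittedDistribution(
                                family="lognormal",
                                parameters={"mu": mu, "sigma": sigma},
                                gof_statistic=float("nan"),
                                gof_pvalue=float("nan"),
                                n_fit=0,
                                _dist=stats.lognorm(s=sigma, scale=math.exp(mu)),
                            )
                summaries = propagate(fitted, params, tox, tissue,
                                      n_iter=config.mc_iters, seed=config.seed)
                frames.append(mc_report(summaries))
            mc_table = pd.concat(frames, ignore_index=True)
            mc_path = f"{config.output_prefix}_mc.csv"
            _atomic_write(mc_path, lambda p: write_report(mc_table, p, "csv"))
            outputs["mc"] = mc_path
        except (ValueError, KeyError) as exc:
            raise PipelineError(f"mc stage failed: {exc}") from exc

    # --- chemometrics -------------------------------------------------------
    if "sources" in config.stages:
        try:
            per_sample = [r for r in records if r.sample_id]
            if not per_sample:
                raise ValueError(
                    "source identification needs per-sample data "
                    "(use simulate mode or a per-sample CSV)")
            mat = records_to_matrix(per_sample, nd_policy=config.nd_policy)
            corr = pearson_matrix(mat)
            pca = run_pca(mat)
            tree = run_hca(mat)

            corr_path = f"{config.output_prefix}_pcc.csv"
            _atomic_write(corr_path,
                          lambda p: correlation_report(corr).to_csv(p, index=False))
            pca_path = f"{config.output_prefix}_pca.csv"
            loads = pca.loadings.copy()
            loads.loc["explained_variance_pct"] = pca.explained_variance_pct
            _atomic_write(pca_path, lambda p: loads.to_csv(p))
            hca_path = f"{config.output_prefix}_hca.csv"
            merge_df = pd.DataFrame(
                tree.merges, columns=["node_a", "node_b", "height", "size"])
            _atomic_write(hca_path, lambda p: merge_df.to_csv(p, index=False))
            outputs.update(pcc=corr_path, pca=pca_path, hca=hca_path)
        except (ValueError, KeyError) as exc:
            raise PipelineError(f"sources stage failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "input_checksum": input_checksum,
        "outputs": outputs,
    }
    manifest_path = f"{config.output_prefix}_manifest.json"
    _atomic_write(
        manifest_path,
        lambda p: open(p, "w").write(json.dumps(manifest, indent=2, default=str)),
    )
    outputs["manifest"] = manifest_path
    return outputs
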