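"""End-to-end orchestration: simulate -> genotype -> consensus -> spectra
-> burden -> signatures, with a reproducible JSON report.

A single master seed spawns independent per-stage streams so a rerun with
the same configuration is byte-identical.  Stage outputs are written as
TSV with a provenance header comment (seed, config digest); the report
bundles the genotype frequency table, the multiplicative-change effect
table with age equivalences, and the signature group contrasts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import burden as burden_mod
from . import consensus as consensus_mod
from . import genotype as genotype_mod
from . import hdp as hdp_mod
from . import spectrum as spectrum_mod
from . import synthetic as synthetic_mod

logger = logging.getLogger(__name__)

REPORT_SCHEMA_KEYS = {"config", "seeds", "stages"}


@dataclass
class PipelineConfig:
    scenario: str = "combined"  # tcga | yale | combined
    n_samples: Optional[int] = None  # override the scenario size
    seed: int = 0
    out_dir: Optional[str] = None
    profile: str = "demo"  # demo | desk | paper (HDP sampler settings)
    m_imputations: int = 10
    n_callers: int = 3
    fn_rate: float = 0.05
    fp_rate: float = 0.02
    run_burden: bool = True
    run_signatures: bool = True
    burden_modes: tuple[str, ...] = ("presence", "total")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    seqs = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(s.generate_state(1)[0] % (2**31)) for n, s in zip(names, seqs)}


def _hdp_config(profile: str, seed: int) -> hdp_mod.SamplerConfig:
    if profile == "paper":
        return hdp_mod.paper_profile(seed)
    if profile == "desk":
        return hdp_mod.desk_profile(seed)
    # demo: sized for smoke tests
    return hdp_mod.SamplerConfig(
        n_chains=1, burnin=100, n_posterior_per_chain=20, spacing=2, seed=seed
    )


def _write_tsv(df: pd.DataFrame, path: str, seed: int, digest: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mc1rburden provenance: seed={seed} config={digest}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the report payload."""
    scen = {
        "tcga": synthetic_mod.tcga_config,
        "yale": synthetic_mod.yale_config,
        "combined": synthetic_mod.combined_config,
    }[config.scenario.lower()]
    seeds = _stage_seeds(
        config.seed, ["simulate", "callers", "germline", "burden", "signatures"]
    )
    digest = config.digest()
    report: dict = {
        "config": {**asdict(config), "digest": digest},
        "seeds": seeds,
        "stages": {},
    }
    out_dir = config.out_dir
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)

    # --- simulate
    cc = scen(seed=seeds["simulate"])
    if config.n_samples is not None:
        cc = cc.replace(n_samples=config.n_samples)
    cohort, truth = synthetic_mod.generate_cohort(cc)
    report["stages"]["simulate"] = {
        "n_samples": int(len(cohort)),
        "scenario": config.scenario,
    }
    logger.info("simulate: %d samples (%s)", len(cohort), config.scenario)

    # --- genotype (round-trip through emitted germline variant records)
    variants = synthetic_mod.emit_germline_variants(truth, seed=seeds["germline"])
    genotypes = genotype_mod.genotype_cohort(
        variants, all_samples=list(cohort["sample_id"])
    )
    freq = genotype_mod.summarize_genotypes(genotypes)
    geno_frame = genotype_mod.genotypes_to_frame(genotypes)
    report["stages"]["genotype"] = {
        "n_samples": int(len(geno_frame)),
        "frequencies": freq.to_dict(orient="records"),
    }

    # --- consensus (noisy caller call sets from the cohort's mutations)
    true_calls = synthetic_mod.spectra_to_calls(cohort, seed=seeds["callers"])
    callsets = synthetic_mod.generate_caller_callsets(
        true_calls[["sample_id", "chrom", "pos", "ref", "alt"]],
        n_callers=config.n_callers,
        fn_rate=config.fn_rate,
        fp_rate=config.fp_rate,
        seed=seeds["callers"],
    )
    cons = consensus_mod.consensus_calls(callsets, min_callers=2)
    snvs, mnv_report = consensus_mod.decompose_mnvs(cons)
    report["stages"]["consensus"] = {
        "n_true_calls": int(len(true_calls)),
        "n_consensus": int(len(cons)),
        "mean_mnv_fraction": float(mnv_report["mnv_fraction"].mean())
        if len(mnv_report) else 0.0,
    }

    # --- spectra (contexts carried by the simulated calls)
    tri = true_calls.set_index(["sample_id", "chrom", "pos"])["trinucleotide"]
    snvs = snvs.join(tri, on=["sample_id", "chrom", "pos"])
    snvs = snvs.dropna(subset=["trinucleotide"])
    snvs = spectrum_mod.classify_table(snvs)
    spectra = spectrum_mod.build_spectra(snvs, list(cohort["sample_id"]))
    report["stages"]["spectrum"] = {
        "n_snvs": int(len(snvs)),
        "total_mutations": int(spectra.to_numpy().sum()),
    }

    # --- burden regression
    if config.run_burden:
        burden_out = {}
        for mode in config.burden_modes:
            spec = burden_mod.ModelSpec(
                response="total" if mode == "total" else "six_class",
                r_predictor="count" if mode == "count" else "presence",
                covariates=tuple(
                    c for c in cc.covariates if c in cohort.columns
                ),
            )
            analysis = burden_mod.run_burden_analysis(
                cohort, spec, m=config.m_imputations, seed=seeds["burden"]
            )
            burden_out[mode] = analysis.table().to_dict(orient="records")
            if out_dir:
                _write_tsv(
                    analysis.table(), os.path.join(out_dir, f"burden_{mode}.tsv"),
                    config.seed, digest,
                )
        report["stages"]["burden"] = burden_out

    # --- signatures
    if config.run_signatures:
        tree = hdp_mod.build_tree(
            spectra, geno_frame[["sample_id", "r_present"]]
        )
        store = hdp_mod.run_sampler(tree, _hdp_config(config.profile, seeds["signatures"]))
        sigset = hdp_mod.extract_components(store)
        contrasts = hdp_mod.compare_group_exposures(sigset)
        report["stages"]["signatures"] = {
            "n_components": int(sigset.components.shape[1]),
            "explained_fraction": sigset.explained_fraction,
            "contrasts": contrasts.to_dict(orient="records"),
        }
        if out_dir:
            comp_df = sigset.components.reset_index(names="context")
            _write_tsv(comp_df, os.path.join(out_dir, "signature_components.tsv"),
                       config.seed, digest)

    if out_dir:
        _write_tsv(cohort, os.path.join(out_dir, "cohort.tsv"), config.seed, digest)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def validate_report(report: dict) -> bool:
    """Minimal schema check on a report payload."""
    return REPORT_SCHEMA_KEYS.issubset(report) and isinstance(report["stages"], dict)


def validate_inputs(
    cohort_path: Optional[str] = None,
    spectra_path: Optional[str] = None,
    genotypes_path: Optional[str] = None,
) -> list[dict]:
    """Check input file dialects and cross-file sample agreement.

    Returns a machine-readable issue list (empty when everything is
    well-formed); never raises for content problems.
    """
    issues: list[dict] = []

    def load(path, what):
        if path is None:
            return None
        if not os.path.exists(path):
            issues.append({"file": path, "issue": f"{what} file not found"})
            return None
        try:
            return pd.read_csv(path, sep="\t", comment="#")
        except Exception as exc:
            issues.append({"file": path, "issue": f"unreadable {what}: {exc}"})
            return None

    cohort = load(cohort_path, "cohort")
    spectra = load(spectra_path, "spectra")
    genotypes = load(genotypes_path, "genotypes")

    for name, df in (("cohort", cohort), ("spectra", spectra), ("genotypes", genotypes)):
        if df is None:
            continue
        if "sample_id" not in df.columns:
            issues.append({"file": name, "issue": "missing sample_id column"})
            continue
        dup = df["sample_id"][df["sample_id"].duplicated()].unique()
        for d in dup:
            issues.append({"file": name, "issue": "duplicate sample", "sample_id": str(d)})

    if spectra is not None and "sample_id" in getattr(spectra, "columns", []):
        missing_ctx = [c for c in spectrum_mod.CONTEXTS96 if c not in spectra.columns]
        if missing_ctx:
            issues.append(
                {"file": "spectra", "issue": f"missing {len(missing_ctx)} context columns"}
            )
    ref = cohort if cohort is not None else genotypes
    if ref is not None and spectra is not None and "sample_id" in spectra.columns \
            and "sample_id" in ref.columns:
        for s in set(ref["sample_id"]) - set(spectra["sample_id"]):
            issues.append({"issue": "sample missing spectrum", "sample_id": str(s)})
    return issues
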