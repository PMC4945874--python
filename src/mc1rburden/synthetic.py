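"""Synthetic melanoma-exome cohorts with the structure the analysis assumes.

The generator emulates two whole-exome melanoma cohorts (a TCGA-like
collection of 273 tumour/germline pairs with eight clinical covariates and
~12% missing clinical data, and a Yale-like collection of 132 pairs with
three complete covariates) plus their combination.  Per sample it draws:

* an MC1R genotype (0, 1 or 2 R alleles at the cohorts' observed
  frequencies),
* clinical covariates (age truncated-normal around the reported median,
  sex, collection centre, body area, sample type, Breslow depth, Clark
  level, ulceration), with missingness injected MCAR or MAR-on-age,
* per-class somatic SNV counts from a log-linear negative-binomial model
  (NB2, variance mu + mu^2/theta, drawn as a gamma-Poisson mixture) whose
  linear predictor contains the configured R-presence and age effects,
* a 96-trinucleotide-context breakdown of each class count, multinomial
  under the R-group's mutational-signature mixture.

Scenario constructors encode the published study conditions: the C>T
rate ratio for R-allele presence is 1.24 (TCGA), 1.58 (Yale) and 1.42
(combined), with a 1.7%-per-year age effect, and these are the generative
ground truths the recovery simulations target.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .genotype import GermlineVariant
from .spectrum import CLASSES6, CONTEXTS96

REFERENCE_AGE = 57.0  # years; linear predictors are centred here

# Clinical marginals reported for the TCGA SKCM cohort (known categories,
# renormalized over non-missing samples).
TCGA_CENTRE_COUNTS = {
    "EE": 86, "D3": 55, "FS": 36, "ER": 30, "EB": 27, "D9": 11,
    "GN": 11, "FR": 6, "FW": 5, "GF": 3, "BF": 2, "IH": 1,
}
TCGA_BODY_AREA_COUNTS = {"extremities": 112, "trunk": 106, "head_neck": 21, "other": 4}
TCGA_CLARK_COUNTS = {"I": 5, "II": 13, "III": 51, "IV": 92, "V": 35}

CLINICAL_COLUMNS = [
    "age", "sex", "centre", "sample_type", "body_area", "breslow", "clark", "ulceration",
]


def _norm(counts: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


def default_signature_profiles() -> np.ndarray:
    """Three stylized signature profiles over the 96 contexts.

    Component 0 is UV-like (C>T with a 5' pyrimidine, the CPD-driven
    pattern dominating melanoma), component 1 is ageing-like (C>T at CpG,
    5-methylcytosine deamination), component 2 is a broad background with
    a mild C>A tilt.  Built programmatically; values are illustrative, not
    catalogue signatures.
    """
    profiles = np.zeros((3, 96))
    labels = list(CONTEXTS96)
    for i, lab in enumerate(labels):
        five, cls, three = lab[0], lab[2:5], lab[6]
        # UV-like
        if cls == "C>T" and five in ("C", "T"):
            profiles[0, i] = 6.0 if five == "T" else 4.0
        elif cls == "C>T":
            profiles[0, i] = 0.4
        else:
            profiles[0, i] = 0.05
        # ageing-like: C>T at NpCpG
        if cls == "C>T" and three == "G":
            profiles[1, i] = 5.0
        elif cls == "C>T":
            profiles[1, i] = 0.3
        else:
            profiles[1, i] = 0.08
        # broad background
        profiles[2, i] = 1.5 if cls == "C>A" else 0.8
    profiles /= profiles.sum(axis=1, keepdims=True)
    return profiles


@dataclass
class CohortConfig:
    """Generative configuration for one synthetic cohort."""

    n_samples: int = 405
    label: str = "combined"
    r_genotype_probs: tuple[float, float, float] = (0.521, 0.410, 0.069)
    age_distribution: tuple[float, float, tuple[float, float]] = (58.0, 14.0, (20.0, 95.0))
    sex_prob_male: float = 0.64
    centre_probs: dict[str, float] = field(
        default_factory=lambda: _norm({**TCGA_CENTRE_COUNTS, "Yale": 132})
    )
    body_area_probs: dict[str, float] = field(
        default_factory=lambda: _norm(TCGA_BODY_AREA_COUNTS)
    )
    sample_type_probs: dict[str, float] = field(
        default_factory=lambda: {"primary": 0.175, "metastasis": 0.825}
    )
    clark_probs: dict[str, float] = field(default_factory=lambda: _norm(TCGA_CLARK_COUNTS))
    ulceration_prob: float = 0.46
    breslow_lognormal: tuple[float, float] = (np.log(2.5), 1.06)
    covariates: tuple[str, ...] = ("age", "sex", "centre", "sample_type")
    effect_log_rate_ratios: dict[str, dict[str, float]] = field(default_factory=dict)
    baseline_log_means: dict[str, float] = field(
        default_factory=lambda: {
            "C>A": np.log(35.0), "C>G": np.log(25.0), "C>T": np.log(250.0),
            "T>A": np.log(15.0), "T>C": np.log(30.0), "T>G": np.log(10.0),
        }
    )
    dispersion: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in CLASSES6}
    )
    signature_profiles: np.ndarray = field(default_factory=default_signature_profiles)
    signature_exposure_by_group: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: {0: (0.55, 0.25, 0.20), 1: (0.65, 0.15, 0.20)}
    )
    missing_rate: float = 0.0
    missing_mechanism: str = "MAR-on-age"  # or "MCAR"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.effect_log_rate_ratios:
            self.effect_log_rate_ratios = {
                c: {"r_present": np.log(1.42), "age": np.log(1.017)} for c in CLASSES6
            }
        self.validate()

    def validate(self) -> None:
        for name, vec in [
            ("r_genotype_probs", list(self.r_genotype_probs)),
            ("centre_probs", list(self.centre_probs.values())),
            ("body_area_probs", list(self.body_area_probs.values())),
            ("sample_type_probs", list(self.sample_type_probs.values())),
            ("clark_probs", list(self.clark_probs.values())),
        ]:
            if abs(sum(vec) - 1.0) > 1e-9 or min(vec) < 0:
                raise ValueError(f"{name} is not a probability vector: {vec}")
        for g, w in self.signature_exposure_by_group.items():
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"exposure weights for group {g} do not sum to 1")
        for c, th in self.dispersion.items():
            if th <= 0:
                raise ValueError(f"dispersion theta for {c} must be > 0")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")
        prof = np.asarray(self.signature_profiles)
        if prof.ndim != 2 or prof.shape[1] != 96:
            raise ValueError("signature_profiles must be K x 96")
        if np.any(np.abs(prof.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each signature profile must sum to 1")

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


def tcga_config(**overrides) -> CohortConfig:
    """TCGA-like scenario: n=273, eight covariates, ~12% MAR missingness,
    C>T rate ratio 1.24 for R presence."""
    cfg = CohortConfig(
        n_samples=273,
        label="TCGA",
        r_genotype_probs=(0.505, 0.411, 0.084),
        centre_probs=_norm(TCGA_CENTRE_COUNTS),
        sample_type_probs={"primary": 0.158, "metastasis": 0.842},
        covariates=tuple(CLINICAL_COLUMNS),
        effect_log_rate_ratios={
            c: {"r_present": np.log(1.24), "age": np.log(1.017)} for c in CLASSES6
        },
        missing_rate=0.12,
    )
    return cfg.replace(**overrides) if overrides else cfg


def yale_config(**overrides) -> CohortConfig:
    """Yale-like scenario: n=132, covariates age/sex/sample-type only, no
    missingness, C>T rate ratio 1.58 for R presence."""
    cfg = CohortConfig(
        n_samples=132,
        label="Yale",
        r_genotype_probs=(0.553, 0.409, 0.038),
        centre_probs={"Yale": 1.0},
        sample_type_probs={"primary": 0.212, "metastasis": 0.788},
        covariates=("age", "sex", "sample_type"),
        effect_log_rate_ratios={
            c: {"r_present": np.log(1.58), "age": np.log(1.017)} for c in CLASSES6
        },
        missing_rate=0.0,
    )
    return cfg.replace(**overrides) if overrides else cfg


def combined_config(**overrides) -> CohortConfig:
    """Combined-cohort scenario: n=405, covariates common to both cohorts
    (age, sex, sample type, centre with Yale as one centre level), 12%
    MAR missingness on the TCGA-like fraction emulated cohort-wide, C>T
    rate ratio 1.42 for R presence."""
    cfg = CohortConfig(missing_rate=0.12)
    return cfg.replace(**overrides) if overrides else cfg


@dataclass
class SyntheticTruth:
    """Ground truth retained alongside a generated cohort."""

    genotypes: pd.DataFrame  # sample_id, r_count, r_present
    covariates: pd.DataFrame  # pre-missingness clinical values
    class_means: pd.DataFrame  # samples x 6 true NB means
    exposures: dict[int, tuple[float, ...]]
    seed: int


def _draw_categorical(rng, probs: Mapping[str, float], n: int) -> np.ndarray:
    keys = list(probs.keys())
    p = np.array([probs[k] for k in keys], dtype=float)
    return rng.choice(keys, size=n, p=p / p.sum())


def group_context_distribution(config: CohortConfig, group: int) -> np.ndarray:
    """The 96-context distribution implied by a group's signature mixture
    combined with the baseline class-mean weights (reference covariates)."""
    w = np.asarray(config.signature_exposure_by_group[group], dtype=float)
    mix = w @ np.asarray(config.signature_profiles)
    class_means = np.array([np.exp(config.baseline_log_means[c]) for c in CLASSES6])
    p = np.zeros(96)
    for ci in range(6):
        sl = slice(16 * ci, 16 * (ci + 1))
        block = mix[sl]
        p[sl] = class_means[ci] * block / block.sum()
    return p / p.sum()


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw one cohort table (with injected missingness) plus its truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"{config.label}-{i:04d}" for i in range(n)]

    empty_cols = (
        ["sample_id", "cohort", "r_count", "r_present"]
        + list(config.covariates)
        + list(CONTEXTS96)
    )
    if n == 0:
        empty = pd.DataFrame(columns=empty_cols)
        truth = SyntheticTruth(
            genotypes=pd.DataFrame(columns=["sample_id", "r_count", "r_present"]),
            covariates=pd.DataFrame(columns=["sample_id", *config.covariates]),
            class_means=pd.DataFrame(columns=["sample_id", *CLASSES6]),
            exposures=dict(config.signature_exposure_by_group),
            seed=config.seed,
        )
        return empty, truth

    r_count = rng.choice([0, 1, 2], size=n, p=np.asarray(config.r_genotype_probs))
    r_present = (r_count >= 1).astype(int)

    mean, sd, (lo, hi) = config.age_distribution
    a, b = (lo - mean) / sd, (hi - mean) / sd
    age = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)

    cov: dict[str, np.ndarray] = {"age": np.round(age, 1)}
    cov["sex"] = np.where(rng.random(n) < config.sex_prob_male, "M", "F")
    cov["centre"] = _draw_categorical(rng, config.centre_probs, n)
    cov["sample_type"] = _draw_categorical(rng, config.sample_type_probs, n)
    cov["body_area"] = _draw_categorical(rng, config.body_area_probs, n)
    cov["clark"] = _draw_categorical(rng, config.clark_probs, n)
    cov["ulceration"] = rng.random(n) < config.ulceration_prob
    logm, logs = config.breslow_lognormal
    cov["breslow"] = np.round(np.exp(rng.normal(logm, logs, size=n)), 2)

    covariate_values = {c: cov[c] for c in config.covariates}

    # per-class NB2 counts via gamma-Poisson, then multinomial context split
    profiles = np.asarray(config.signature_profiles)
    group_mix = {
        g: np.asarray(wts) @ profiles for g, wts in config.signature_exposure_by_group.items()
    }
    counts96 = np.zeros((n, 96), dtype=np.int64)
    class_means = np.zeros((n, 6))
    for ci, cls in enumerate(CLASSES6):
        effects = config.effect_log_rate_ratios.get(cls, {})
        eta = np.full(n, config.baseline_log_means[cls])
        for predictor, beta in effects.items():
            if predictor == "r_present":
                eta = eta + beta * r_present
            elif predictor == "r_count":
                eta = eta + beta * r_count
            elif predictor == "age":
                eta = eta + beta * (age - REFERENCE_AGE)
            elif ":" in predictor:
                colname, level = predictor.split(":", 1)
                values = covariate_values.get(colname, cov.get(colname))
                eta = eta + beta * (np.asarray(values).astype(str) == level)
            else:
                raise ValueError(f"unknown effect predictor {predictor!r}")
        mu = np.exp(eta)
        class_means[:, ci] = mu
        theta = config.dispersion[cls]
        lam = rng.gamma(shape=theta, scale=mu / theta)
        class_counts = rng.poisson(lam)
        sl = slice(16 * ci, 16 * (ci + 1))
        for g, mix in group_mix.items():
            block = mix[sl] / mix[sl].sum()
            members = np.flatnonzero(r_present == (1 if g else 0))
            for i in members:
                if class_counts[i] > 0:
                    counts96[i, sl] += rng.multinomial(class_counts[i], block)

    table = pd.DataFrame({"sample_id": sample_ids, "cohort": config.label})
    table["r_count"] = r_count
    table["r_present"] = r_present.astype(bool)
    for c in config.covariates:
        table[c] = covariate_values[c]
    spectra = pd.DataFrame(counts96, columns=list(CONTEXTS96))
    table = pd.concat([table, spectra], axis=1)

    truth = SyntheticTruth(
        genotypes=pd.DataFrame(
            {"sample_id": sample_ids, "r_count": r_count, "r_present": r_present.astype(bool)}
        ),
        covariates=pd.DataFrame({"sample_id": sample_ids, **covariate_values}),
        class_means=pd.DataFrame(
            {"sample_id": sample_ids, **{c: class_means[:, i] for i, c in enumerate(CLASSES6)}}
        ),
        exposures=dict(config.signature_exposure_by_group),
        seed=config.seed,
    )

    if config.missing_rate > 0:
        miss_seed = int(np.random.SeedSequence(config.seed).spawn(1)[0].generate_state(1)[0] % (2**31))
        table = inject_missingness(
            table,
            rate=config.missing_rate,
            mechanism=config.missing_mechanism,
            seed=miss_seed,
            columns=[c for c in config.covariates],
        )
    return table, truth


def inject_missingness(
    table: pd.DataFrame,
    rate: float,
    mechanism: str = "MCAR",
    seed: int = 0,
    columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Set a fraction of eligible clinical cells to missing.

    ``MCAR`` masks each eligible cell independently with probability
    ``rate``.  ``MAR-on-age`` makes the masking probability logistic in
    the sample's age (slope 0.5 per age SD), with the intercept calibrated
    so the marginal rate matches ``rate``; the age column itself, being
    the conditioning variable, is masked MCAR at the same rate.  Genotype
    and mutation-count columns are never eligible.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    if mechanism not in ("MCAR", "MAR-on-age"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    table = table.copy()
    if columns is None:
        columns = [c for c in CLINICAL_COLUMNS if c in table.columns]
    columns = [c for c in columns if c in table.columns]
    if rate == 0.0 or not columns or table.empty:
        return table
    rng = np.random.default_rng(seed)
    n = len(table)

    if mechanism == "MCAR" or "age" not in table.columns:
        p_row = np.full(n, rate)
    else:
        z = np.asarray(table["age"], dtype=float)
        z = (z - np.nanmean(z)) / (np.nanstd(z) + 1e-12)
        slope = 0.5
        # calibrate the intercept so the mean masking probability equals rate
        lo_a, hi_a = -20.0, 20.0
        for _ in range(80):
            mid = 0.5 * (lo_a + hi_a)
            if expit(mid + slope * z).mean() < rate:
                lo_a = mid
            else:
                hi_a = mid
        p_row = expit(0.5 * (lo_a + hi_a) + slope * z)

    for col in columns:
        p = np.full(n, rate) if col == "age" else p_row
        mask = rng.random(n) < p
        if mask.any():
            if table[col].dtype == bool:
                table[col] = table[col].astype(object)
            table.loc[mask, col] = np.nan if pd.api.types.is_numeric_dtype(table[col]) else None
            if not pd.api.types.is_numeric_dtype(table[col]):
                table.loc[mask, col] = np.nan
    return table


def generate_caller_callsets(
    true_calls: pd.DataFrame,
    n_callers: int,
    fn_rate: float,
    fp_rate: float,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Derive noisy per-caller call sets from a true substitution set.

    Each caller drops every true call independently with probability
    ``fn_rate`` and fabricates ``Poisson(fp_rate * n_true)`` spurious,
    caller-private calls (marked ``fabricated=True``).  All emitted calls
    carry FILTER status PASS; fabrication is flagged in its own column so
    consensus precision can be scored against truth.
    """
    if n_callers < 1:
        raise ValueError("n_callers must be >= 1")
    if not (0.0 <= fn_rate <= 1.0) or not (0.0 <= fp_rate < 1.0):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_true = len(true_calls)
    out = []
    for c in range(n_callers):
        keep = rng.random(n_true) >= fn_rate if n_true else np.array([], dtype=bool)
        kept = true_calls.loc[keep].copy()
        kept["filter_pass"] = True
        kept["fabricated"] = False
        n_fp = rng.poisson(fp_rate * n_true) if n_true else 0
        if n_fp:
            samples = (
                rng.choice(true_calls["sample_id"].unique(), size=n_fp)
                if n_true
                else np.array([])
            )
            bases = np.array(["A", "C", "G", "T"])
            ref = rng.choice(bases, size=n_fp)
            alt = np.array(
                [rng.choice([b for b in bases if b != r]) for r in ref]
            )
            fab = pd.DataFrame(
                {
                    "sample_id": samples,
                    "chrom": "chrFP",
                    # caller-private coordinate block so fabricated calls never collide
                    "pos": rng.integers(1, 10**8, size=n_fp) * 10 + c,
                    "ref": ref,
                    "alt": alt,
                    "filter_pass": True,
                    "fabricated": True,
                }
            )
            kept = pd.concat([kept, fab], ignore_index=True)
        out.append(kept.reset_index(drop=True))
    return out


def spectra_to_calls(
    cohort: pd.DataFrame,
    seed: int = 0,
    dnv_fraction: float = 0.0,
) -> pd.DataFrame:
    """Materialize a cohort's 96-context counts as substitution records.

    Every counted mutation becomes one call on a synthetic contig with its
    trinucleotide context carried in a ``trinucleotide`` column (so no
    reference FASTA is needed downstream).  Positions are spaced so calls
    are non-adjacent; with ``dnv_fraction > 0`` a fraction of each
    sample's C>T calls are paired into adjacent positions to exercise MNV
    handling (counts are conserved).
    """
    rng = np.random.default_rng(seed)
    rows = []
    ctx_cols = [c for c in CONTEXTS96 if c in cohort.columns]
    for _, row in cohort.iterrows():
        sid = row["sample_id"]
        pos_cursor = 1000
        sample_rows = []
        for lab in ctx_cols:
            k = int(row[lab])
            if k == 0:
                continue
            five, cls, three = lab[0], lab[2:5], lab[6]
            ref, alt = cls[0], cls[2]
            tri = five + ref + three
            for _ in range(k):
                pos_cursor += int(rng.integers(5, 50))
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "chrom": "chrSim",
                        "pos": pos_cursor,
                        "ref": ref,
                        "alt": alt,
                        "trinucleotide": tri,
                        "filter_pass": True,
                    }
                )
        if dnv_fraction > 0:
            ct = [i for i, r in enumerate(sample_rows) if r["ref"] == "C" and r["alt"] == "T"]
            n_pairs = int(dnv_fraction * len(ct) / 2)
            for p in range(n_pairs):
                i, j = ct[2 * p], ct[2 * p + 1]
                sample_rows[j]["pos"] = sample_rows[i]["pos"] + 1
            sample_rows.sort(key=lambda r: r["pos"])
        rows.extend(sample_rows)
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "trinucleotide", "filter_pass"],
    )


_CANONICAL_R = ["p.Arg151Cys", "p.Arg160Trp", "p.Asp294His", "p.Asp84Glu", "p.Arg142His"]
_CANONICAL_SMALL_R = ["p.Val60Leu", "p.Val92Met", "p.Arg163Gln"]


def emit_germline_variants(
    truth: SyntheticTruth, seed: int = 0, r_small_prob: float = 0.3
) -> list[GermlineVariant]:
    """Emit annotated germline MC1R variant records consistent with truth.

    Samples with two R alleles are emitted as a homozygote or a compound
    heterozygote (50/50); r alleles are added at ``r_small_prob`` where
    the two-allele cap leaves room.  Round-tripping these records through
    the genotyping module recovers the true R counts exactly.
    """
    rng = np.random.default_rng(seed)
    out = []
    for row in truth.genotypes.itertuples(index=False):
        sid, rc = row.sample_id, int(row.r_count)
        if rc == 2:
            if rng.random() < 0.5:
                pc = _CANONICAL_R[int(rng.integers(len(_CANONICAL_R)))]
                out.append(GermlineVariant(sid, pc, "missense", "hom"))
            else:
                picks = rng.choice(len(_CANONICAL_R), size=2, replace=False)
                for p in picks:
                    out.append(GermlineVariant(sid, _CANONICAL_R[p], "missense", "het"))
        elif rc == 1:
            pc = _CANONICAL_R[int(rng.integers(len(_CANONICAL_R)))]
            out.append(GermlineVariant(sid, pc, "missense", "het"))
            if rng.random() < r_small_prob:
                ps = _CANONICAL_SMALL_R[int(rng.integers(len(_CANONICAL_SMALL_R)))]
                out.append(GermlineVariant(sid, ps, "missense", "het"))
        else:
            if rng.random() < r_small_prob:
                ps = _CANONICAL_SMALL_R[int(rng.integers(len(_CANONICAL_SMALL_R)))]
                out.append(GermlineVariant(sid, ps, "missense", "het"))
    return out


def config_from_yaml(path: str) -> CohortConfig:
    """Build a :class:`CohortConfig` from a YAML file mirroring its fields.

    A ``scenario`` key (``tcga``/``yale``/``combined``) selects a base
    configuration; remaining keys override individual fields."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scenario = raw.pop("scenario", None)
    base = {"tcga": tcga_config, "yale": yale_config, "combined": combined_config}.get(
        (scenario or "").lower(), CohortConfig
    )
    cfg = base()
    tuple_fields = {"r_genotype_probs", "covariates"}
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config field {key!r}")
        if key in tuple_fields and isinstance(value, list):
            value = tuple(value)
        if key == "age_distribution" and isinstance(value, list):
            value = (value[0], value[1], tuple(value[2]))
        setattr(cfg, key, value)
    cfg.validate()
    return cfg
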