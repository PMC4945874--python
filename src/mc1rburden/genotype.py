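"""MC1R germline allele classification and per-sample genotyping.

MC1R coding variants are classified into three functional tiers: *R*
alleles (null or strongly hypomorphic receptor variants, strongly
associated with red hair and fair skin), *r* alleles (missense variants
weakly associated with that phenotype), and wild-type.  The nine canonical
missense polymorphisms carry literature-consensus assignments shipped as a
data table; protein-truncating variants (nonsense, frameshift) are R; rare
missense variants are resolved from SIFT and PolyPhen predictions; and an
explicit override table takes precedence over every rule, which is how
reclassification sensitivity analyses (e.g. p.Thr95Met -> r,
p.Arg213Trp -> R) are expressed.

Per-sample genotypes count R and r alleles: a homozygous variant
contributes two alleles, each heterozygous variant one, with the total
capped at two (two distinct heterozygous R variants are treated as a
compound heterozygote, i.e. R/R).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CONSEQUENCES = ("missense", "nonsense", "frameshift", "synonymous", "other")
CATEGORIES = ("R/R", "R/r", "R/0", "r/r", "r/0", "0/0")


@dataclass(frozen=True)
class GermlineVariant:
    """One annotated MC1R coding variant in one sample."""

    sample_id: str
    protein_change: Optional[str]
    consequence: str  # missense | nonsense | frameshift | synonymous | other
    zygosity: str  # het | hom
    sift_class: Optional[str] = None  # deleterious | tolerated | None
    sift_score: Optional[float] = None
    polyphen_class: Optional[str] = None  # probably_damaging | possibly_damaging | benign | None
    polyphen_score: Optional[float] = None
    filter_pass: bool = True

    def __post_init__(self) -> None:
        for score in (self.sift_score, self.polyphen_score):
            if score is not None and not (0.0 <= score <= 1.0):
                raise ValueError(f"predictor score {score} outside [0, 1]")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")


@dataclass(frozen=True)
class MC1RGenotype:
    """Per-sample R/r allele counts and the derived category label."""

    sample_id: str
    r_count_big: int  # number of R alleles, 0..2
    r_count_small: int  # number of r alleles, 0..2
    category: str

    @property
    def r_present(self) -> bool:
        return self.r_count_big >= 1


def load_canonical_table(path: Optional[str] = None) -> dict[str, str]:
    """Load the canonical protein-change -> {R, r} lookup table.

    Defaults to the packaged consensus assignment of the nine canonical
    MC1R missense polymorphisms.
    """
    if path is None:
        with resources.files("mc1rburden.data").joinpath("mc1r_canonical.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    return dict(zip(table["protein_change"], table["class"]))


def classify_allele(
    variant: GermlineVariant,
    canonical_table: Optional[Mapping[str, str]] = None,
    overrides: Optional[Mapping[str, str]] = None,
) -> str:
    """Classify one germline variant as ``"R"``, ``"r"``, ``"wildtype"``
    or ``"unresolved"``.

    Precedence: overrides > canonical table > consequence rules > the
    SIFT/PolyPhen decision rule for rare missense variants:

    * SIFT deleterious AND PolyPhen (probably or possibly) damaging -> R
    * exactly one of the two predictors damaging/deleterious -> r
    * both benign/tolerated -> wildtype
    * both predictors unavailable -> unresolved (excluded from counting)
    """
    if canonical_table is None:
        canonical_table = load_canonical_table()
    pc = variant.protein_change
    if overrides and pc in overrides:
        return overrides[pc]
    if pc is not None and pc in canonical_table:
        return canonical_table[pc]
    if variant.consequence in ("nonsense", "frameshift"):
        return "R"
    if variant.consequence in ("synonymous", "other"):
        return "wildtype"
    # rare missense: resolve from the predictors
    sift_damaging = variant.sift_class == "deleterious"
    poly_damaging = variant.polyphen_class in ("probably_damaging", "possibly_damaging")
    sift_known = variant.sift_class in ("deleterious", "tolerated")
    poly_known = variant.polyphen_class in ("probably_damaging", "possibly_damaging", "benign")
    if not sift_known and not poly_known:
        logger.warning(
            "variant %s in %s has no usable SIFT/PolyPhen prediction; unresolved",
            pc, variant.sample_id,
        )
        return "unresolved"
    if sift_damaging and poly_damaging:
        return "R"
    if sift_damaging or poly_damaging:
        return "r"
    return "wildtype"


def _category(r_big: int, r_small: int) -> str:
    if r_big == 2:
        return "R/R"
    if r_big == 1:
        return "R/r" if r_small >= 1 else "R/0"
    if r_small == 2:
        return "r/r"
    if r_small == 1:
        return "r/0"
    return "0/0"


def genotype_sample(
    variants: Sequence[GermlineVariant],
    canonical_table: Optional[Mapping[str, str]] = None,
    overrides: Optional[Mapping[str, str]] = None,
) -> MC1RGenotype:
    """Aggregate one sample's classified variants into an MC1R genotype.

    Homozygous variants contribute two alleles, heterozygous one.  Totals
    are capped at two alleles; when the cap binds, R alleles take
    precedence over r (disruptive alleles drive the phenotype of
    interest), and a warning is logged.
    """
    if not variants:
        raise ValueError("genotype_sample requires at least one variant record")
    sample_ids = {v.sample_id for v in variants}
    if len(sample_ids) != 1:
        raise ValueError(f"variants span multiple samples: {sorted(sample_ids)}")
    sample_id = variants[0].sample_id
    if canonical_table is None:
        canonical_table = load_canonical_table()
    r_big = 0
    r_small = 0
    for v in variants:
        if not v.filter_pass:
            continue
        cls = classify_allele(v, canonical_table, overrides)
        dose = 2 if v.zygosity == "hom" else 1
        if cls == "R":
            r_big += dose
        elif cls == "r":
            r_small += dose
    if r_big + r_small > 2:
        logger.warning(
            "sample %s carries %d classified alleles; capping at 2 (R first)",
            sample_id, r_big + r_small,
        )
    r_big = min(r_big, 2)
    r_small = min(r_small, 2 - r_big)
    return MC1RGenotype(sample_id, r_big, r_small, _category(r_big, r_small))


def genotype_cohort(
    variants: Iterable[GermlineVariant],
    all_samples: Optional[Sequence[str]] = None,
    canonical_table: Optional[Mapping[str, str]] = None,
    overrides: Optional[Mapping[str, str]] = None,
) -> list[MC1RGenotype]:
    """Genotype every sample; samples with no variant records are 0/0."""
    if canonical_table is None:
        canonical_table = load_canonical_table()
    by_sample: dict[str, list[GermlineVariant]] = {}
    for v in variants:
        by_sample.setdefault(v.sample_id, []).append(v)
    samples = list(all_samples) if all_samples is not None else sorted(by_sample)
    out = []
    for s in samples:
        if s in by_sample:
            out.append(genotype_sample(by_sample[s], canonical_table, overrides))
        else:
            out.append(MC1RGenotype(s, 0, 0, "0/0"))
    return out


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def summarize_genotypes(genotypes: Sequence[MC1RGenotype]) -> pd.DataFrame:
    """Frequency table by category and by R-allele count.

    Percentages are rounded half-up to whole numbers, matching how cohort
    genotype frequencies are conventionally reported.
    """
    if not genotypes:
        raise ValueError("cannot summarize an empty cohort")
    n = len(genotypes)
    rows = []
    for cat in CATEGORIES:
        count = sum(1 for g in genotypes if g.category == cat)
        rows.append(("category", cat, count, _round_half_up(100.0 * count / n)))
    for r in (0, 1, 2):
        count = sum(1 for g in genotypes if g.r_count_big == r)
        rows.append(("r_count", str(r), count, _round_half_up(100.0 * count / n)))
    return pd.DataFrame(rows, columns=["level_type", "level", "count", "percent"])


def genotypes_to_frame(genotypes: Sequence[MC1RGenotype]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [g.sample_id for g in genotypes],
            "r_count": [g.r_count_big for g in genotypes],
            "r_small_count": [g.r_count_small for g in genotypes],
            "category": [g.category for g in genotypes],
            "r_present": [g.r_present for g in genotypes],
        }
    )


# ---------------------------------------------------------------------------
# I/O

GERMLINE_TSV_COLUMNS = [
    "sample_id", "protein_change", "consequence", "zygosity",
    "sift_class", "sift_score", "polyphen_class", "polyphen_score", "filter_pass",
]


def read_germline_tsv(path: str) -> list[GermlineVariant]:
    """Read annotated germline variants from the TSV dialect."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(GERMLINE_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"germline TSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            GermlineVariant(
                sample_id=row.sample_id,
                protein_change=None if pd.isna(row.protein_change) else row.protein_change,
                consequence=row.consequence,
                zygosity=row.zygosity,
                sift_class=None if pd.isna(row.sift_class) else row.sift_class,
                sift_score=None if pd.isna(row.sift_score) else float(row.sift_score),
                polyphen_class=None if pd.isna(row.polyphen_class) else row.polyphen_class,
                polyphen_score=None if pd.isna(row.polyphen_score) else float(row.polyphen_score),
                filter_pass=bool(row.filter_pass),
            )
        )
    return out


def read_germline_vcf(path: str, sample_id: Optional[str] = None) -> list[GermlineVariant]:
    """Read VEP-annotated germline variants from a VCF.

    Expects a CSQ INFO field with Consequence, protein change (HGVSp or
    Amino_acids/Protein_position), SIFT and PolyPhen sub-fields, i.e. the
    standard VEP layout.  Genotype 1/1 is hom, anything with one alt
    allele is het.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    csq_fields: list[str] = []
    for rec in vcf.header_iter():
        info = rec.info()
        if info.get("ID") == "CSQ":
            desc = info.get("Description", "")
            if "Format:" in desc:
                csq_fields = desc.split("Format:")[1].strip().strip('"').split("|")
    if not csq_fields:
        raise ValueError("VCF lacks a VEP CSQ header")
    sid = sample_id or (vcf.samples[0] if vcf.samples else "sample")

    def parse_pred(text: str) -> tuple[Optional[str], Optional[float]]:
        # VEP encodes e.g. "deleterious(0.01)" / "probably_damaging(0.98)"
        if not text:
            return None, None
        if "(" in text:
            cls, score = text.rstrip(")").split("(")
            return cls, float(score)
        return text, None

    out = []
    for var in vcf:
        csq = var.INFO.get("CSQ")
        if csq is None:
            continue
        first = dict(zip(csq_fields, csq.split(",")[0].split("|")))
        raw_cons = first.get("Consequence", "")
        if "missense" in raw_cons:
            consequence = "missense"
        elif "stop_gained" in raw_cons:
            consequence = "nonsense"
        elif "frameshift" in raw_cons:
            consequence = "frameshift"
        elif "synonymous" in raw_cons:
            consequence = "synonymous"
        else:
            consequence = "other"
        hgvsp = first.get("HGVSp", "")
        protein_change = hgvsp.split(":")[-1] if hgvsp else None
        sift_class, sift_score = parse_pred(first.get("SIFT", ""))
        poly_class, poly_score = parse_pred(first.get("PolyPhen", ""))
        gts = var.genotypes
        zygosity = "het"
        if gts and len(gts[0]) >= 2 and gts[0][0] == 1 and gts[0][1] == 1:
            zygosity = "hom"
        out.append(
            GermlineVariant(
                sample_id=sid,
                protein_change=protein_change,
                consequence=consequence,
                zygosity=zygosity,
                sift_class=sift_class,
                sift_score=sift_score,
                polyphen_class=poly_class,
                polyphen_score=poly_score,
                filter_pass=(var.FILTER is None),
            )
        )
    return out
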