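"""Consensus somatic calls across callers and multi-nucleotide decomposition.

A stringent substitution set is built by keeping calls made by at least
``min_callers`` independent pipelines, each of which must have marked the
call PASS (the strictest reading: PASS is required per supporting caller,
non-PASS records do not contribute support).  Double- and triple-nucleotide
variants — either emitted as a single multi-base substitution record or as
adjacent single-base calls within one sample — are decomposed into their
component SNVs, each tagged with its MNV of origin, so that a DNV adds two
to every downstream SNV count.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .spectrum import MalformedRecordError

CALL_KEY = ["sample_id", "chrom", "pos", "ref", "alt"]


def _normalize_callset(calls: pd.DataFrame, caller: str) -> pd.DataFrame:
    df = calls.copy()
    required = set(CALL_KEY)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"callset {caller!r} missing columns: {sorted(missing)}")
    if "filter_pass" not in df.columns:
        if "filter" in df.columns:
            df["filter_pass"] = df["filter"].astype(str).str.upper().eq("PASS")
        else:
            df["filter_pass"] = True
    df["caller"] = caller
    return df[CALL_KEY + ["filter_pass", "caller"]]


def consensus_calls(
    callsets: Sequence[pd.DataFrame],
    caller_labels: Optional[Sequence[str]] = None,
    min_callers: int = 2,
    require_pass: bool = True,
) -> pd.DataFrame:
    """Intersect per-caller call sets into a consensus substitution set.

    Returns one row per retained call with a ``support`` column listing
    the supporting callers (comma-joined, sorted) and ``n_callers``.
    """
    if len(callsets) == 0:
        raise ValueError("consensus requires at least one callset")
    if caller_labels is None:
        caller_labels = [f"caller{i + 1}" for i in range(len(callsets))]
    if len(caller_labels) != len(callsets):
        raise ValueError("caller_labels length must match callsets")
    frames = [_normalize_callset(cs, lab) for cs, lab in zip(callsets, caller_labels)]
    stacked = pd.concat(frames, ignore_index=True)
    if require_pass:
        stacked = stacked.loc[stacked["filter_pass"]]
    if stacked.empty:
        return pd.DataFrame(columns=CALL_KEY + ["support", "n_callers"])
    # a caller supports a call at most once
    stacked = stacked.drop_duplicates(subset=CALL_KEY + ["caller"])
    grouped = (
        stacked.groupby(CALL_KEY, sort=True)["caller"]
        .agg(lambda c: ",".join(sorted(c)))
        .reset_index()
        .rename(columns={"caller": "support"})
    )
    grouped["n_callers"] = grouped["support"].str.count(",") + 1
    out = grouped.loc[grouped["n_callers"] >= min_callers].reset_index(drop=True)
    return out


def decompose_mnvs(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split substitution calls into component SNVs and tag MNV origins.

    Two sources of multi-nucleotide variants are handled: a single record
    with ``len(ref) == len(alt) in {2, 3}`` is split at every position
    where ref and alt differ; and runs of adjacent (1 bp apart) single-base
    calls within one sample on one contig are tagged as belonging to one
    MNV.  Returns ``(snvs, report)`` where ``snvs`` carries an ``mnv_id``
    column (empty string for isolated SNVs) and ``report`` gives, per
    sample, total SNVs, MNV-derived SNVs and their fraction.
    """
    records = []
    mnv_counter = 0
    for row in calls.itertuples(index=False):
        ref, alt = str(row.ref), str(row.alt)
        if len(ref) != len(alt):
            raise MalformedRecordError(
                f"ref/alt length mismatch at {row.chrom}:{row.pos} ({ref}>{alt})"
            )
        if len(ref) == 1:
            records.append((row.sample_id, row.chrom, int(row.pos), ref, alt, ""))
        elif len(ref) in (2, 3):
            mnv_counter += 1
            tag = f"mnv{mnv_counter}"
            for offset, (rb, ab) in enumerate(zip(ref, alt)):
                if rb != ab:
                    records.append(
                        (row.sample_id, row.chrom, int(row.pos) + offset, rb, ab, tag)
                    )
        else:
            raise MalformedRecordError(
                f"substitution longer than 3 bp at {row.chrom}:{row.pos}"
            )
    snvs = pd.DataFrame(records, columns=CALL_KEY + ["mnv_id"])
    if not snvs.empty:
        # merge adjacent single-base calls (1 bp window, same sample/contig)
        snvs = snvs.sort_values(["sample_id", "chrom", "pos"], kind="stable").reset_index(
            drop=True
        )
        untagged = snvs["mnv_id"].eq("")
        prev_adjacent = (
            snvs["sample_id"].eq(snvs["sample_id"].shift())
            & snvs["chrom"].eq(snvs["chrom"].shift())
            & (snvs["pos"] - snvs["pos"].shift()).eq(1)
            & untagged
            & untagged.shift(fill_value=False)
        )
        run_id = (~prev_adjacent).cumsum()
        run_sizes = run_id.map(run_id.value_counts())
        needs_tag = untagged & (run_sizes >= 2)
        for rid in run_id[needs_tag].unique():
            mnv_counter += 1
            snvs.loc[needs_tag & run_id.eq(rid), "mnv_id"] = f"mnv{mnv_counter}"
    report_rows = []
    for sid, grp in snvs.groupby("sample_id", sort=True):
        total = len(grp)
        derived = int(grp["mnv_id"].ne("").sum())
        report_rows.append((sid, total, derived, derived / total if total else 0.0))
    report = pd.DataFrame(
        report_rows, columns=["sample_id", "n_snvs", "n_mnv_derived", "mnv_fraction"]
    )
    return snvs, report


def read_callset_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    return df


def read_callset_vcf(path: str, sample_id: Optional[str] = None) -> pd.DataFrame:
    """Read substitution calls from a (possibly multi-sample-naive) VCF.

    Every record becomes one row attributed to ``sample_id`` (or the first
    VCF sample); indels (length-changing alleles) are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    sid = sample_id or (vcf.samples[0] if vcf.samples else "sample")
    rows = []
    for var in vcf:
        for alt in var.ALT:
            if len(var.REF) != len(alt):
                continue
            rows.append(
                {
                    "sample_id": sid,
                    "chrom": var.CHROM,
                    "pos": var.POS,
                    "ref": var.REF,
                    "alt": alt,
                    "filter_pass": var.FILTER is None,
                }
            )
    return pd.DataFrame(rows, columns=CALL_KEY + ["filter_pass"])
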