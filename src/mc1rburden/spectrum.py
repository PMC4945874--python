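"""Pyrimidine-centred SNV classification and 96-trinucleotide-context spectra.

Single-base substitutions are reduced to six classes (C>A, C>G, C>T, T>A,
T>C, T>G) by reverse-complementing purine-reference changes, and to 96
categories once the 5' and 3' flanking reference bases are attached.  The
96-category layout is the conventional class-major ordering used by
published signature matrices: 16 contexts per class, 5' flank as the outer
key and 3' flank as the inner key, both in A,C,G,T order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The six pyrimidine-centred substitution classes, in canonical order.
CLASSES6 = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def _context_labels() -> tuple[str, ...]:
    labels = []
    for cls in CLASSES6:
        ref = cls[0]
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{cls}]{three}")
    return tuple(labels)


#: Labels for the 96 trinucleotide contexts, class-major ordering.
CONTEXTS96 = _context_labels()
_CONTEXT_INDEX = {lab: i for i, lab in enumerate(CONTEXTS96)}


class MalformedRecordError(ValueError):
    """Raised for substitution records that violate the format contract."""


def reverse_complement(seq: str) -> str:
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise MalformedRecordError(f"non-ACGT base in {seq!r}") from exc


@dataclass(frozen=True)
class SNVContext:
    """A single substitution normalized to the pyrimidine strand."""

    ref_base: str
    alt_base: str
    trinucleotide: str
    class6: str
    context96: int

    @property
    def label(self) -> str:
        return CONTEXTS96[self.context96]


def classify_snv(ref: str, alt: str, trinucleotide: str) -> SNVContext:
    """Classify one substitution into its class and 96-context index.

    ``trinucleotide`` is the reference-strand 3-mer centred on the variant;
    purine-reference substitutions are reverse-complemented so the central
    base is a pyrimidine.
    """
    ref, alt, trinucleotide = ref.upper(), alt.upper(), trinucleotide.upper()
    if len(ref) != 1 or len(alt) != 1 or len(trinucleotide) != 3:
        raise MalformedRecordError(
            f"expected single-base ref/alt and a 3-mer, got {ref!r}>{alt!r} in {trinucleotide!r}"
        )
    if ref == alt:
        raise MalformedRecordError(f"ref and alt are both {ref!r}")
    for b in (ref, alt, *trinucleotide):
        if b not in COMPLEMENT:
            raise MalformedRecordError(f"non-ACGT base {b!r}")
    if trinucleotide[1] != ref:
        raise MalformedRecordError(
            f"central base of {trinucleotide!r} does not match ref {ref!r}"
        )
    if ref in ("A", "G"):  # purine reference: flip to the pyrimidine strand
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
        trinucleotide = reverse_complement(trinucleotide)
    class6 = f"{ref}>{alt}"
    label = f"{trinucleotide[0]}[{class6}]{trinucleotide[2]}"
    return SNVContext(ref, alt, trinucleotide, class6, _CONTEXT_INDEX[label])


def attach_context(
    snvs: pd.DataFrame,
    reference_source: "Mapping[str, str] | str | None" = None,
) -> pd.DataFrame:
    """Fill the ``trinucleotide`` column of a substitution table.

    ``reference_source`` may be a FASTA path (random access through
    ``pyfaidx``), a mapping of contig name to sequence, or ``None`` when a
    ``trinucleotide`` column is already present (passthrough).  Variants at
    a contig edge cannot receive a full 3-mer; they are dropped with a
    warning column in the return value's attrs.
    """
    snvs = snvs.copy()
    if reference_source is None:
        if "trinucleotide" not in snvs.columns:
            raise MalformedRecordError(
                "no reference source and no trinucleotide column present"
            )
        return snvs

    if isinstance(reference_source, str):
        from pyfaidx import Fasta

        fasta = Fasta(reference_source, as_raw=True, sequence_always_upper=True)

        def fetch(chrom: str, pos: int) -> str | None:
            seq = fasta[chrom]
            if pos < 2 or pos > len(seq) - 1:
                return None
            return str(seq[pos - 2 : pos + 1])

    else:
        def fetch(chrom: str, pos: int) -> str | None:
            seq = reference_source[chrom].upper()
            if pos < 2 or pos > len(seq) - 1:
                return None
            return seq[pos - 2 : pos + 1]

    tri: list[str | None] = []
    for chrom, pos in zip(snvs["chrom"], snvs["pos"]):
        tri.append(fetch(str(chrom), int(pos)))
    snvs["trinucleotide"] = tri
    edge = snvs["trinucleotide"].isna()
    n_edge = int(edge.sum())
    if n_edge:
        import logging

        logging.getLogger(__name__).warning(
            "%d variant(s) at contig edges excluded from context assignment", n_edge
        )
    out = snvs.loc[~edge].reset_index(drop=True)
    out.attrs["n_edge_excluded"] = n_edge
    return out


def classify_table(snvs: pd.DataFrame) -> pd.DataFrame:
    """Add ``class6``, ``context96`` and ``context_label`` columns."""
    snvs = snvs.copy()
    ctx = [
        classify_snv(r, a, t)
        for r, a, t in zip(snvs["ref"], snvs["alt"], snvs["trinucleotide"])
    ]
    snvs["class6"] = [c.class6 for c in ctx]
    snvs["context96"] = [c.context96 for c in ctx]
    snvs["context_label"] = [c.label for c in ctx]
    return snvs


def build_spectra(snvs: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    """Per-sample 96-context count matrix (samples x 96).

    ``snvs`` must carry ``sample_id`` and ``context96`` (see
    :func:`classify_table`).  Samples with no SNVs get all-zero rows;
    an SNV whose sample is not in ``samples`` is an error.
    """
    samples = list(samples)
    index = pd.Index(samples, name="sample_id")
    counts = np.zeros((len(samples), 96), dtype=np.int64)
    pos = {s: i for i, s in enumerate(samples)}
    if len(snvs):
        unknown = set(snvs["sample_id"]) - set(samples)
        if unknown:
            raise KeyError(f"SNVs reference unknown sample(s): {sorted(unknown)[:5]}")
        for sid, c96 in zip(snvs["sample_id"], snvs["context96"]):
            counts[pos[sid], int(c96)] += 1
    return pd.DataFrame(counts, index=index, columns=list(CONTEXTS96))


def spectra_to_class6(spectra: pd.DataFrame) -> pd.DataFrame:
    """Marginalize a samples x 96 matrix over flanks to the 6 classes."""
    out = {}
    for i, cls in enumerate(CLASSES6):
        cols = list(CONTEXTS96[16 * i : 16 * (i + 1)])
        out[cls] = spectra[cols].sum(axis=1)
    return pd.DataFrame(out, index=spectra.index)


def class_of_context(idx: int) -> str:
    return CLASSES6[idx // 16]
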