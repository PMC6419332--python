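"""Biallelic SNV records and VCF input/output.

All positions are 0-based internally; the 1-based convention of VCF is applied
only at the file boundary. A diploid genotype is normalized to the dosage of
the record's alt allele: ``"0/1"`` (one copy) or ``"1/1"`` (two copies), which
makes genotype comparison phase-insensitive and invariant under strand
complementation of the alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True, order=True)
class SNVRecord:
    """One biallelic single-nucleotide variant with a diploid genotype."""

    seq_name: str
    pos: int  # 0-based
    ref: str
    alt: str
    genotype: str  # "0/1" or "1/1" (alt dosage 1 or 2)
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-ACGT allele in {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.seq_name}:{self.pos}")
        if self.genotype not in ("0/1", "1/1"):
            raise ValueError(f"unsupported genotype {self.genotype!r}")
        if self.depth is not None and self.depth < 0:
            raise ValueError("negative depth")

    @property
    def alt_dosage(self) -> int:
        return 2 if self.genotype == "1/1" else 1

    def complemented(self) -> "SNVRecord":
        """Alleles reverse-complemented (single base: complemented)."""
        return replace(self, ref=COMPLEMENT[self.ref], alt=COMPLEMENT[self.alt])

    @property
    def sort_key(self) -> tuple:
        return (self.seq_name, self.pos, self.ref, self.alt)


def _dosage_genotype(dosage: int) -> str:
    return "1/1" if dosage == 2 else "0/1"


@dataclass
class FilterTally:
    """Why records were removed (or split) on the way to a clean SNV stream."""

    n_kept: int = 0
    n_indel: int = 0
    n_symbolic: int = 0
    n_missing_genotype: int = 0
    n_hom_ref: int = 0
    n_multiallelic_split: int = 0
    n_duplicate: int = 0

    @property
    def n_removed(self) -> int:
        return (self.n_indel + self.n_symbolic + self.n_missing_genotype
                + self.n_hom_ref + self.n_duplicate)

    def as_dict(self) -> dict:
        return dict(self.__dict__, n_removed=self.n_removed)


def _record_depth(rec, sample) -> int | None:
    dp = sample.get("DP")
    if dp is None:
        dp = rec.info.get("DP")
    if isinstance(dp, tuple):
        dp = dp[0] if dp else None
    return int(dp) if dp is not None else None


def filter_snvs(vcf_path: str | Path) -> tuple[list[SNVRecord], FilterTally]:
    """Read a single-sample VCF and keep only biallelic SNV substitutions.

    Indels, symbolic/structural alleles and records with missing genotypes are
    dropped and tallied. Multi-allelic SNV records are split into biallelic
    records, each carrying the sample's dosage of that alt. Duplicate
    (seq, pos, ref, alt) entries keep the first occurrence.
    """
    records: list[SNVRecord] = []
    tally = FilterTally()
    seen: set[tuple] = set()
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if not alts:
                tally.n_missing_genotype += 1
                continue
            if any(a is None or a.startswith("<") or a in ("*", ".") for a in alts):
                tally.n_symbolic += 1
                continue
            if len(rec.ref) != 1 or any(len(a) != 1 for a in alts):
                tally.n_indel += 1
                continue
            if rec.ref not in BASES or any(a not in BASES for a in alts):
                tally.n_symbolic += 1
                continue
            if not rec.samples:
                tally.n_missing_genotype += 1
                continue
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or any(g is None for g in gt) or len(gt) != 2:
                tally.n_missing_genotype += 1
                continue
            if len(alts) > 1:
                tally.n_multiallelic_split += 1
            depth = _record_depth(rec, sample)
            emitted = False
            for alt_index, alt in enumerate(alts, start=1):
                dosage = sum(1 for g in gt if g == alt_index)
                if dosage == 0:
                    continue
                snv = SNVRecord(rec.contig, rec.start, rec.ref, alt,
                                _dosage_genotype(dosage), depth)
                if snv.sort_key in seen:
                    tally.n_duplicate += 1
                    continue
                seen.add(snv.sort_key)
                records.append(snv)
                tally.n_kept += 1
                emitted = True
            if not emitted and all(g == 0 for g in gt):
                tally.n_hom_ref += 1
    return records, tally


def _build_header(sequence_sizes: Mapping[str, int],
                  info_fields: Sequence[tuple[str, str, str, str]] = (),
                  sample: str = "SAMPLE") -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name in sorted(sequence_sizes):
        header.contigs.add(name, length=int(sequence_sizes[name]))
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "DP"), ("Number", "1"),
                                     ("Type", "Integer"), ("Description", "Read depth")])
    for fid, number, ftype, descr in info_fields:
        header.add_meta("INFO", items=[("ID", fid), ("Number", number),
                                       ("Type", ftype), ("Description", descr)])
    header.add_sample(sample)
    return header


def write_snv_vcf(records: Iterable[SNVRecord],
                  sequence_sizes: Mapping[str, int],
                  path: str | Path,
                  info: Mapping[tuple, Mapping[str, object]] | None = None,
                  info_fields: Sequence[tuple[str, str, str, str]] = (),
                  sort: bool = True) -> None:
    """Write SNV records as a single-sample uncompressed VCF.

    ``info`` maps a record's sort_key to extra INFO values declared in
    ``info_fields`` (id, number, type, description).
    """
    records = list(records)
    if sort:
        records.sort(key=lambda r: r.sort_key)
    header = _build_header(sequence_sizes, info_fields)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for snv in records:
            rec = out.new_record(contig=snv.seq_name, start=snv.pos,
                                 stop=snv.pos + 1, alleles=(snv.ref, snv.alt))
            rec.filter.add("PASS")
            if info:
                for key, value in (info.get(snv.sort_key) or {}).items():
                    rec.info[key] = value
            sample = rec.samples[0]
            sample["GT"] = (1, 1) if snv.genotype == "1/1" else (0, 1)
            sample.phased = False
            if snv.depth is not None:
                sample["DP"] = snv.depth
            out.write(rec)


def get_base(sequences, name: str, pos: int) -> str:
    """Fetch one uppercase base from a dict-of-strings or pyfaidx.Fasta."""
    try:
        seq = sequences[name]
    except KeyError as exc:
        raise KeyError(f"target sequence {name!r} missing from assembly") from exc
    base = str(seq[pos])
    return base.upper()


def log2_ratio(numerator: float, denominator: float) -> float | None:
    """log2(numerator/denominator) with undefined-safe sentinels.

    Returns None when both terms are zero, +/-inf when exactly one is.
    """
    if numerator > 0 and denominator > 0:
        return math.log2(numerator / denominator)
    if numerator > 0:
        return math.inf
    if denominator > 0:
        return -math.inf
    return None
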