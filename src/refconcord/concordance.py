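"""Call-set concordance between converted and directly-called SNVs.

Given a call set lifted from a source assembly and a call set obtained by
direct analysis on the target assembly, every converted SNV is classified as

* concordant — a direct SNV exists at the same (seq, pos, ref) with the same
  alt allele and genotype (alt-dosage comparison, phase-insensitive);
* genotype discordant (GD) — position and ref match but alt or genotype
  differ;
* position discordant (PD) — no direct SNV at that position/ref.

Rates follow the standard definitions: the conversion rate CR is the
percentage of source SNVs successfully lifted, and PDR/GDR are the
percentages of PD/GD SNVs among the converted SNVs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import chain_liftover as cl
from .variants import (SNVRecord, FilterTally, filter_snvs, log2_ratio,
                       write_snv_vcf)

__all__ = [
    "SNVRecord", "FilterTally", "MatchReport", "filter_snvs",
    "conversion_rate", "match_callsets", "compare_records", "run_comparison",
]


def conversion_rate(n_converted: int, n_source_total: int) -> float:
    """Percentage of source SNVs successfully converted (100 * c / n)."""
    if n_source_total <= 0:
        raise ValueError("conversion rate undefined for an empty source call set")
    if not 0 <= n_converted <= n_source_total:
        raise ValueError("converted count outside [0, source total]")
    return 100.0 * n_converted / n_source_total


@dataclass
class MatchReport:
    """Partition of converted SNVs into concordant / PD / GD, with rates."""

    n_source_total: int
    n_converted: int
    n_concordant: int
    n_position_discordant: int
    n_genotype_discordant: int
    pd_roster: list[SNVRecord] = field(default_factory=list, repr=False)
    gd_roster: list[SNVRecord] = field(default_factory=list, repr=False)
    converted_roster: list[SNVRecord] = field(default_factory=list, repr=False)
    unconverted_roster: list[SNVRecord] = field(default_factory=list, repr=False)
    tally: cl.ConversionTally | None = None

    def __post_init__(self) -> None:
        parts = self.n_concordant + self.n_position_discordant + self.n_genotype_discordant
        if parts != self.n_converted:
            raise ValueError(f"partition violated: {parts} classified vs "
                             f"{self.n_converted} converted")

    @property
    def conversion_rate_pct(self) -> float:
        return conversion_rate(self.n_converted, self.n_source_total)

    @property
    def pdr_pct(self) -> float | None:
        if self.n_converted == 0:
            return None
        return 100.0 * self.n_position_discordant / self.n_converted

    @property
    def gdr_pct(self) -> float | None:
        if self.n_converted == 0:
            return None
        return 100.0 * self.n_genotype_discordant / self.n_converted

    @property
    def pd_to_gd_log2_ratio(self) -> float | None:
        """log2(PD/GD); +/-inf when one class is empty, None when both are."""
        return log2_ratio(self.n_position_discordant, self.n_genotype_discordant)

    def summary(self) -> dict:
        out = {
            "n_source_total": self.n_source_total,
            "n_converted": self.n_converted,
            "n_concordant": self.n_concordant,
            "n_position_discordant": self.n_position_discordant,
            "n_genotype_discordant": self.n_genotype_discordant,
            "conversion_rate_pct": self.conversion_rate_pct,
            "pdr_pct": self.pdr_pct,
            "gdr_pct": self.gdr_pct,
            "pd_to_gd_log2_ratio": self.pd_to_gd_log2_ratio,
        }
        if self.tally is not None:
            out["conversion_tally"] = self.tally.as_dict()
        return out

    # -- report directory I/O ------------------------------------------------

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "summary.json", "w") as handle:
            json.dump(_jsonable(self.summary()), handle, indent=2, sort_keys=True)
            handle.write("\n")
        for name, roster in (("pd", self.pd_roster), ("gd", self.gd_roster),
                             ("converted", self.converted_roster),
                             ("unconverted", self.unconverted_roster)):
            _write_roster(roster, name, out_dir / f"{name}_roster.tsv")

    @classmethod
    def read(cls, out_dir: str | Path) -> "MatchReport":
        out_dir = Path(out_dir)
        with open(out_dir / "summary.json") as handle:
            summary = json.load(handle)
        rosters = {name: _read_roster(out_dir / f"{name}_roster.tsv")
                   for name in ("pd", "gd", "converted", "unconverted")}
        tally = None
        if "conversion_tally" in summary:
            tally = cl.ConversionTally(**summary["conversion_tally"])
        return cls(n_source_total=summary["n_source_total"],
                   n_converted=summary["n_converted"],
                   n_concordant=summary["n_concordant"],
                   n_position_discordant=summary["n_position_discordant"],
                   n_genotype_discordant=summary["n_genotype_discordant"],
                   pd_roster=rosters["pd"], gd_roster=rosters["gd"],
                   converted_roster=rosters["converted"],
                   unconverted_roster=rosters["unconverted"], tally=tally)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, float):
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        if math.isnan(obj):
            return None
    return obj


_ROSTER_COLUMNS = ["seq_name", "pos", "ref", "alt", "genotype", "depth", "class"]


def _write_roster(roster: Sequence[SNVRecord], klass: str, path: Path) -> None:
    frame = pd.DataFrame(
        [(r.seq_name, r.pos + 1, r.ref, r.alt, r.genotype,
          "" if r.depth is None else r.depth, klass) for r in roster],
        columns=_ROSTER_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def _read_roster(path: Path) -> list[SNVRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"seq_name": str})
    records = []
    for row in frame.itertuples(index=False):
        depth = None if pd.isna(row.depth) else int(row.depth)
        records.append(SNVRecord(str(row.seq_name), int(row.pos) - 1, row.ref,
                                 row.alt, row.genotype, depth))
    return records


def _check_sorted(records: Sequence[SNVRecord], label: str) -> None:
    for prev, cur in zip(records, records[1:]):
        if cur.sort_key < prev.sort_key:
            raise ValueError(f"{label} call set is not coordinate-sorted "
                             f"(at {cur.seq_name}:{cur.pos + 1})")


def match_callsets(converted: Sequence[SNVRecord], direct: Sequence[SNVRecord],
                   alt_mismatch_class: str = "gd",
                   n_source_total: int | None = None,
                   unconverted: Sequence[SNVRecord] = (),
                   tally: cl.ConversionTally | None = None) -> MatchReport:
    """Classify each converted SNV against the directly-called set.

    Both inputs must be coordinate-sorted. ``alt_mismatch_class`` decides
    how a converted SNV whose position+ref match a direct SNV but whose alt
    allele matches none is classed: ``"gd"`` (default) or ``"pd"``.
    """
    if alt_mismatch_class not in ("gd", "pd"):
        raise ValueError("alt_mismatch_class must be 'gd' or 'pd'")
    converted = list(converted)
    direct = list(direct)
    _check_sorted(converted, "converted")
    _check_sorted(direct, "direct")
    table: dict[tuple, list[tuple[str, str]]] = {}
    for rec in direct:
        table.setdefault((rec.seq_name, rec.pos, rec.ref), []).append(
            (rec.alt, rec.genotype))
    n_concordant = 0
    pd_roster: list[SNVRecord] = []
    gd_roster: list[SNVRecord] = []
    for rec in converted:
        entries = table.get((rec.seq_name, rec.pos, rec.ref))
        if entries is None:
            pd_roster.append(rec)
        elif (rec.alt, rec.genotype) in entries:
            n_concordant += 1
        elif any(alt == rec.alt for alt, _ in entries) or alt_mismatch_class == "gd":
            gd_roster.append(rec)
        else:
            pd_roster.append(rec)
    return MatchReport(
        n_source_total=len(converted) if n_source_total is None else n_source_total,
        n_converted=len(converted),
        n_concordant=n_concordant,
        n_position_discordant=len(pd_roster),
        n_genotype_discordant=len(gd_roster),
        pd_roster=pd_roster, gd_roster=gd_roster,
        converted_roster=converted,
        unconverted_roster=list(unconverted), tally=tally)


def compare_records(source_records: Iterable[SNVRecord],
                    direct_records: Iterable[SNVRecord],
                    chains: cl.ChainSet | cl.ChainIndex,
                    target_sequences,
                    on_ref_mismatch: str = "reject",
                    alt_mismatch_class: str = "gd") -> MatchReport:
    """In-memory pipeline: lift the source records, then match against the
    direct records. The file-based entry point is :func:`run_comparison`."""
    index = chains if isinstance(chains, cl.ChainIndex) else cl.ChainIndex(chains)
    source_records = list(source_records)
    converted, rejected, tally = cl.lift_records(index, source_records,
                                                 target_sequences, on_ref_mismatch)
    direct_sorted = sorted(direct_records, key=lambda r: r.sort_key)
    return match_callsets([moved for moved, _ in converted], direct_sorted,
                          alt_mismatch_class=alt_mismatch_class,
                          n_source_total=len(source_records),
                          unconverted=[res.source for res in rejected],
                          tally=tally)


def run_comparison(source_vcf: str | Path, direct_target_vcf: str | Path,
                   chains: str | Path | cl.ChainSet, target_fasta,
                   out_dir: str | Path | None = None,
                   on_ref_mismatch: str = "reject",
                   alt_mismatch_class: str = "gd") -> MatchReport:
    """One conversion direction end to end: filter -> lift -> match.

    Running both directions (A->B and B->A) is two independent invocations
    with the arguments and the chain direction swapped.
    """
    if isinstance(chains, (str, Path)):
        chains = cl.read_chain(chains)
    cl._check_direction(source_vcf, chains)
    if isinstance(target_fasta, (str, Path)):
        import pyfaidx
        target_fasta = pyfaidx.Fasta(str(target_fasta))
    source_records, _ = filter_snvs(source_vcf)
    direct_records, _ = filter_snvs(direct_target_vcf)
    report = compare_records(source_records, direct_records, chains, target_fasta,
                             on_ref_mismatch=on_ref_mismatch,
                             alt_mismatch_class=alt_mismatch_class)
    if out_dir is not None:
        report.write(out_dir)
    return report
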