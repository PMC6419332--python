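"""Profiling of discordant SNVs: confidence strata, depth, base composition.

Discordant SNVs from a cross-assembly comparison are characterized three
ways, mirroring the standard benchmarking workflow for the NA12878 sample:

* stratification into high-confidence (HC) vs low-confidence (LC) calls by
  interval membership in a benchmark HC BED, with the LC/HC enrichment
  ratios PR (position-discordant) and GR (genotype-discordant):
  PR = (lc_pd / lc_all) / (hc_pd / hc_all), and analogously for GR, where
  *all* counts are over the successfully converted SNVs;
* read-depth frequency tables per roster (converted, unconverted, PD, GD);
* reference-allele base composition (%A/T/G/C and combined G+C) of the PD
  and GD rosters, computed on the lifted (target-side) reference alleles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concordance import MatchReport
from .variants import SNVRecord, log2_ratio


class ConfidenceRegions:
    """Sorted, merged, half-open high-confidence intervals per sequence."""

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int]]]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for name, ivs in intervals.items():
            merged = _merge(ivs)
            self._starts[name] = np.array([s for s, _ in merged], dtype=np.int64)
            self._ends[name] = np.array([e for _, e in merged], dtype=np.int64)

    @classmethod
    def from_bed(cls, path: str | Path) -> "ConfidenceRegions":
        intervals: dict[str, list[tuple[int, int]]] = {}
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"BED line with fewer than 3 columns: {line!r}")
                intervals.setdefault(fields[0], []).append(
                    (int(fields[1]), int(fields[2])))
        return cls(intervals)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for name in sorted(self._starts):
                for start, end in zip(self._starts[name], self._ends[name]):
                    handle.write(f"{name}\t{start}\t{end}\n")

    def intervals(self, name: str) -> list[tuple[int, int]]:
        return list(zip(self._starts.get(name, ()), self._ends.get(name, ())))

    def contains(self, name: str, pos: int) -> bool:
        starts = self._starts.get(name)
        if starts is None or len(starts) == 0:
            return False
        idx = int(np.searchsorted(starts, pos, side="right")) - 1
        return idx >= 0 and pos < self._ends[name][idx]

    def contains_many(self, name: str, positions: np.ndarray) -> np.ndarray:
        starts = self._starts.get(name)
        if starts is None or len(starts) == 0:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] < self._ends[name][idx[ok]]
        return out

    def covered_bases(self, name: str) -> int:
        starts = self._starts.get(name)
        if starts is None:
            return 0
        return int((self._ends[name] - starts).sum())


def _merge(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted((int(s), int(e)) for s, e in intervals):
        if end < start:
            raise ValueError(f"interval end before start: ({start}, {end})")
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def stratify(snvs: Sequence[SNVRecord], regions: ConfidenceRegions
             ) -> tuple[list[SNVRecord], list[SNVRecord]]:
    """Partition a roster into (HC, LC) by interval membership of position."""
    hc: list[SNVRecord] = []
    lc: list[SNVRecord] = []
    for snv in snvs:
        (hc if regions.contains(snv.seq_name, snv.pos) else lc).append(snv)
    return hc, lc


@dataclass(frozen=True)
class StratifiedCounts:
    """HC/LC counts among all-converted, PD and GD SNVs."""

    hc_all: int
    lc_all: int
    hc_pd: int
    lc_pd: int
    hc_gd: int
    lc_gd: int

    def __post_init__(self) -> None:
        if self.hc_pd > self.hc_all or self.lc_pd > self.lc_all:
            raise ValueError("PD stratum exceeds all-converted stratum")
        if self.hc_gd > self.hc_all or self.lc_gd > self.lc_all:
            raise ValueError("GD stratum exceeds all-converted stratum")

    @classmethod
    def from_rosters(cls, converted: Sequence[SNVRecord], pd_roster: Sequence[SNVRecord],
                     gd_roster: Sequence[SNVRecord], regions: ConfidenceRegions
                     ) -> "StratifiedCounts":
        hc_all, lc_all = (len(r) for r in stratify(converted, regions))
        hc_pd, lc_pd = (len(r) for r in stratify(pd_roster, regions))
        hc_gd, lc_gd = (len(r) for r in stratify(gd_roster, regions))
        return cls(hc_all, lc_all, hc_pd, lc_pd, hc_gd, lc_gd)

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class DiscordanceRatios:
    """LC/HC enrichment ratios for discordant SNVs; None when undefined."""

    pr: float | None
    gr: float | None
    log2_pr: float | None
    log2_gr: float | None


def _lc_hc_ratio(lc_x: int, hc_x: int, lc_all: int, hc_all: int) -> float | None:
    if lc_all == 0 or hc_all == 0 or hc_x == 0:
        return None
    return (lc_x / lc_all) / (hc_x / hc_all)


def discordance_ratios(counts: StratifiedCounts) -> DiscordanceRatios:
    """PR and GR with their log2 values (undefined-safe sentinels)."""
    pr = _lc_hc_ratio(counts.lc_pd, counts.hc_pd, counts.lc_all, counts.hc_all)
    gr = _lc_hc_ratio(counts.lc_gd, counts.hc_gd, counts.lc_all, counts.hc_all)
    log2_pr = math.log2(pr) if pr else None
    log2_gr = math.log2(gr) if gr else None
    return DiscordanceRatios(pr, gr, log2_pr, log2_gr)


OVERFLOW_BIN = "overflow"
MISSING_BIN = "missing"


def depth_histogram(rosters: Mapping[str, Sequence[SNVRecord]],
                    max_depth: int = 60) -> pd.DataFrame:
    """Per-roster depth frequency table.

    One row per integer depth 0..max_depth, plus an overflow bin for larger
    depths and a separate bin for records without a depth. Each column sums
    to its roster size.
    """
    index = [str(d) for d in range(max_depth + 1)] + [OVERFLOW_BIN, MISSING_BIN]
    table = pd.DataFrame(0, index=index, columns=list(rosters), dtype=np.int64)
    for name, roster in rosters.items():
        for snv in roster:
            if snv.depth is None:
                table.loc[MISSING_BIN, name] += 1
            elif snv.depth > max_depth:
                table.loc[OVERFLOW_BIN, name] += 1
            else:
                table.loc[str(snv.depth), name] += 1
    table.index.name = "depth"
    return table


@dataclass(frozen=True)
class CompositionSummary:
    """Reference-allele base percentages over a roster (sums to 100)."""

    pct_a: float
    pct_t: float
    pct_g: float
    pct_c: float

    @property
    def pct_gc(self) -> float:
        return self.pct_g + self.pct_c

    def __post_init__(self) -> None:
        total = self.pct_a + self.pct_t + self.pct_g + self.pct_c
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"base percentages sum to {total}, not 100")

    def as_dict(self) -> dict:
        return {"pct_a": self.pct_a, "pct_t": self.pct_t, "pct_g": self.pct_g,
                "pct_c": self.pct_c, "pct_gc": self.pct_gc}


def base_composition(roster: Sequence[SNVRecord]) -> CompositionSummary:
    """Percentages of reference alleles A/T/G/C over a non-empty roster."""
    if not roster:
        raise ValueError("base composition undefined for an empty roster")
    counts = {b: 0 for b in "ATGC"}
    for snv in roster:
        counts[snv.ref] += 1
    n = len(roster)
    pct = {b: 100.0 * c / n for b, c in counts.items()}
    # Close the sum exactly to 100 against float round-off.
    residual = 100.0 - sum(pct.values())
    pct["A"] += residual
    return CompositionSummary(pct["A"], pct["T"], pct["G"], pct["C"])


@dataclass
class CharacterizationBundle:
    """Everything the characterization stage derives from one comparison."""

    counts: StratifiedCounts
    ratios: DiscordanceRatios
    depth_hist: pd.DataFrame = field(repr=False)
    composition_pd: CompositionSummary | None
    composition_gd: CompositionSummary | None

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = {
            "stratified_counts": self.counts.as_dict(),
            "ratios": {k: _num(v) for k, v in vars(self.ratios).items()},
            "composition_pd": self.composition_pd.as_dict() if self.composition_pd else None,
            "composition_gd": self.composition_gd.as_dict() if self.composition_gd else None,
        }
        with open(out_dir / "bundle.json", "w") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)
            handle.write("\n")
        self.depth_hist.to_csv(out_dir / "depth_hist.tsv", sep="\t")

    @classmethod
    def read(cls, out_dir: str | Path) -> "CharacterizationBundle":
        out_dir = Path(out_dir)
        with open(out_dir / "bundle.json") as handle:
            payload = json.load(handle)
        hist = pd.read_csv(out_dir / "depth_hist.tsv", sep="\t", index_col="depth",
                           converters={"depth": str}).astype(np.int64)
        hist.index.name = "depth"
        ratios = {k: _unnum(v) for k, v in payload["ratios"].items()}

        def comp(entry):
            if entry is None:
                return None
            return CompositionSummary(entry["pct_a"], entry["pct_t"],
                                      entry["pct_g"], entry["pct_c"])

        return cls(counts=StratifiedCounts(**payload["stratified_counts"]),
                   ratios=DiscordanceRatios(**ratios),
                   depth_hist=hist,
                   composition_pd=comp(payload["composition_pd"]),
                   composition_gd=comp(payload["composition_gd"]))


def _num(value):
    if value is None:
        return None
    if math.isinf(value):
        return "inf" if value > 0 else "-inf"
    return value


def _unnum(value):
    if value == "inf":
        return math.inf
    if value == "-inf":
        return -math.inf
    return value


def characterize(report: MatchReport, regions: ConfidenceRegions,
                 max_depth: int = 60) -> CharacterizationBundle:
    """Full characterization of one comparison's discordant SNVs."""
    counts = StratifiedCounts.from_rosters(report.converted_roster,
                                           report.pd_roster, report.gd_roster,
                                           regions)
    ratios = discordance_ratios(counts)
    hist = depth_histogram({
        "converted": report.converted_roster,
        "unconverted": report.unconverted_roster,
        "pd": report.pd_roster,
        "gd": report.gd_roster,
    }, max_depth=max_depth)
    comp_pd = base_composition(report.pd_roster) if report.pd_roster else None
    comp_gd = base_composition(report.gd_roster) if report.gd_roster else None
    return CharacterizationBundle(counts=counts, ratios=ratios, depth_hist=hist,
                                  composition_pd=comp_pd, composition_gd=comp_gd)
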