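"""Synthetic assembly pairs with known ground truth for pipeline testing.

The generator builds everything the cross-assembly comparison needs, all
derived from one edit script so that every downstream statistic has an exact
or closed-form expected value:

* a source assembly and a target assembly related by non-overlapping
  deletions, insertions and inversions;
* UCSC chain files in both directions, consistent with the base-level truth
  map by construction (and verified against it on every run);
* diploid SNV call sets on both coordinate systems with per-variant depth,
  including controlled injections of unconvertible variants (placed in
  deleted regions), position-discordant (PD) and genotype-discordant (GD)
  variants, and target-only variants (placed in inserted sequence);
* high-confidence (HC) region BEDs for both assemblies;
* a per-variant truth ledger recording every injected fact.

The injected discordances emulate the empirical profile of real discordant
SNVs: lower read depth (``depth_shift``), enrichment in low-confidence
regions (``lc_enrichment``), and elevated G/C reference-allele content
(``gc_bias_discordant``).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import chain_liftover as cl
from .characterization import ConfidenceRegions
from .variants import SNVRecord, write_snv_vcf

_BASES = "ACGT"
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
# complement: A<->T (0<->3), C<->G (1<->2)
_COMPLEMENT_CODE = 3


def decode(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


class FixtureError(ValueError):
    """Infeasible generator specification."""


@dataclass(frozen=True)
class EditSpec:
    """Edit script relating the two assemblies; all lengths in bases."""

    n_deletions: int = 0
    deletion_length_range: tuple[int, int] = (100, 1000)
    n_insertions: int = 0
    insertion_length_range: tuple[int, int] = (100, 1000)
    n_inversions: int = 0
    inversion_length_range: tuple[int, int] = (100, 1000)
    seed: int = 0


@dataclass(frozen=True)
class DiscordanceSpec:
    """Controlled discordance injections for the simulated call sets.

    ``lc_enrichment`` is the LC-vs-HC enrichment the injected discordances
    should show under the LC/HC rate-ratio statistic (the expected ratio of
    LC to HC discordance rates among converted SNVs equals this factor).
    ``depth_shift`` multiplies the mean read depth of unconvertible and
    discordant variants.
    """

    n_position_discordant: int = 0
    n_genotype_discordant: int = 0
    lc_enrichment: float = 1.0
    depth_shift: float = 1.0
    seed: int = 0


@dataclass(frozen=True)
class AlignedSegment:
    """One ungapped aligned segment; tgt_start is the plus-strand start.

    For strand '-', source base ``src_start + k`` pairs with target base
    ``tgt_start + (size - 1 - k)``.
    """

    src_start: int
    src_end: int
    tgt_start: int
    strand: str

    @property
    def size(self) -> int:
        return self.src_end - self.src_start


@dataclass
class AssemblyPair:
    source_name: str
    target_name: str
    source_codes: np.ndarray = field(repr=False)
    target_codes: np.ndarray = field(repr=False)
    truth_tgt: np.ndarray = field(repr=False)  # per source base: target pos or -1
    truth_strand: np.ndarray = field(repr=False)  # +1 / -1 (0 where deleted)
    segments: list[AlignedSegment] = field(repr=False)
    chain_fwd: cl.ChainSet = field(repr=False)
    chain_rev: cl.ChainSet = field(repr=False)
    edits: EditSpec = EditSpec()
    gc_fraction: float = 0.42

    @property
    def source_length(self) -> int:
        return len(self.source_codes)

    @property
    def target_length(self) -> int:
        return len(self.target_codes)

    @property
    def source_seq(self) -> str:
        return decode(self.source_codes)

    @property
    def target_seq(self) -> str:
        return decode(self.target_codes)

    @property
    def source_sequences(self) -> dict[str, str]:
        return {self.source_name: self.source_seq}

    @property
    def target_sequences(self) -> dict[str, str]:
        return {self.target_name: self.target_seq}


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return rng.choice(4, size=length, p=[at, gc / 2.0, gc / 2.0, at]).astype(np.uint8)


_MIN_EDIT_GAP = 30  # bases kept colinear between adjacent edits


def _place_edits(rng: np.random.Generator, length: int, edits: EditSpec
                 ) -> list[tuple[int, str, int]]:
    """Sample non-overlapping (position, kind, length) events on the source."""
    items: list[tuple[str, int]] = []
    for kind, count, lo_hi in (("del", edits.n_deletions, edits.deletion_length_range),
                               ("inv", edits.n_inversions, edits.inversion_length_range),
                               ("ins", edits.n_insertions, edits.insertion_length_range)):
        lo, hi = lo_hi
        if count and (lo < 1 or hi < lo):
            raise FixtureError(f"bad {kind} length range {lo_hi}")
        for _ in range(count):
            items.append((kind, int(rng.integers(lo, hi + 1))))
    if not items:
        return []
    order = rng.permutation(len(items))
    items = [items[i] for i in order]
    # source footprint: insertions occupy a point, deletions/inversions their length
    footprint = sum(n for kind, n in items if kind != "ins")
    free = length - footprint
    n_slots = len(items) + 1
    spare = free - n_slots * _MIN_EDIT_GAP
    if spare < 0:
        raise FixtureError(
            f"edits need {footprint + n_slots * _MIN_EDIT_GAP} bases but the "
            f"source has only {length}")
    extra = rng.multinomial(spare, [1.0 / n_slots] * n_slots)
    events: list[tuple[int, str, int]] = []
    cursor = 0
    for i, (kind, n) in enumerate(items):
        cursor += _MIN_EDIT_GAP + int(extra[i])
        events.append((cursor, kind, n))
        if kind != "ins":
            cursor += n
    return events


def _segments_to_chainset(segments: Sequence[AlignedSegment],
                          src_name: str, src_size: int,
                          tgt_name: str, tgt_size: int) -> cl.ChainSet:
    chains: list[cl.Chain] = []
    chain_id = 0
    i = 0
    while i < len(segments):
        chain_id += 1
        seg = segments[i]
        if seg.strand == "-":
            block = cl.ChainBlock(seg.size)
            chains.append(cl.Chain(
                score=seg.size, source_name=src_name, source_size=src_size,
                source_start=seg.src_start, source_end=seg.src_end,
                target_name=tgt_name, target_size=tgt_size, target_strand="-",
                target_start=tgt_size - (seg.tgt_start + seg.size),
                target_end=tgt_size - seg.tgt_start,
                blocks=[block], chain_id=chain_id))
            i += 1
            continue
        run = [seg]
        while i + len(run) < len(segments) and segments[i + len(run)].strand == "+":
            run.append(segments[i + len(run)])
        blocks = []
        for cur, nxt in zip(run, run[1:]):
            blocks.append(cl.ChainBlock(cur.size,
                                        source_gap=nxt.src_start - cur.src_end,
                                        target_gap=nxt.tgt_start - (cur.tgt_start + cur.size)))
        blocks.append(cl.ChainBlock(run[-1].size))
        chains.append(cl.Chain(
            score=sum(s.size for s in run), source_name=src_name, source_size=src_size,
            source_start=run[0].src_start, source_end=run[-1].src_end,
            target_name=tgt_name, target_size=tgt_size, target_strand="+",
            target_start=run[0].tgt_start,
            target_end=run[-1].tgt_start + run[-1].size,
            blocks=blocks, chain_id=chain_id))
        i += len(run)
    chainset = cl.ChainSet(chains=chains,
                           source_sequence_sizes={src_name: src_size},
                           target_sequence_sizes={tgt_name: tgt_size})
    for chain in chains:
        chain.validate()
    return chainset


def exhaustive_truth_map(chainset: cl.ChainSet, name: str, length: int
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Brute-force per-base lookup built by walking all blocks linearly.

    Returns (target position or -1, strand +1/-1/0, covered-by-chain-span)
    arrays over the named source sequence. Assumes chains do not overlap on
    the source side (always true for generator output); used as the
    independent oracle against the indexed query path.
    """
    tgt = np.full(length, -1, dtype=np.int64)
    strand = np.zeros(length, dtype=np.int8)
    in_span = np.zeros(length, dtype=bool)
    for chain in chainset.chains:
        if chain.source_name != name:
            continue
        in_span[chain.source_start:chain.source_end] = True
        src = chain.source_start
        local = chain.target_start
        sgn = 1 if chain.target_strand == "+" else -1
        for block in chain.blocks:
            offs = np.arange(block.size, dtype=np.int64)
            locals_ = local + offs
            plus = locals_ if sgn == 1 else chain.target_size - 1 - locals_
            tgt[src:src + block.size] = plus
            strand[src:src + block.size] = sgn
            src += block.size + block.source_gap
            local += block.size + block.target_gap
    return tgt, strand, in_span


def generate_assembly_pair(length: int, gc_fraction: float = 0.42,
                           edits: EditSpec = EditSpec(),
                           source_name: str = "chr1",
                           target_name: str = "chr1") -> AssemblyPair:
    """Generate a source/target assembly pair related by a known edit script.

    The returned pair carries the base-level truth map and chain files in
    both directions; the chains are checked against the truth map before
    returning. Fixed seed means byte-identical outputs.
    """
    if length < 1000:
        raise FixtureError("source length must be >= 1 kb")
    rng = np.random.default_rng(edits.seed)
    source = _random_sequence(rng, length, gc_fraction)
    events = _place_edits(rng, length, edits)

    segments: list[AlignedSegment] = []
    parts: list[np.ndarray] = []
    truth_tgt = np.full(length, -1, dtype=np.int64)
    truth_strand = np.zeros(length, dtype=np.int8)
    cursor_src = 0
    cursor_tgt = 0

    def emit_colinear(upto: int) -> None:
        nonlocal cursor_src, cursor_tgt
        if upto > cursor_src:
            size = upto - cursor_src
            segments.append(AlignedSegment(cursor_src, upto, cursor_tgt, "+"))
            parts.append(source[cursor_src:upto])
            truth_tgt[cursor_src:upto] = cursor_tgt + np.arange(size)
            truth_strand[cursor_src:upto] = 1
            cursor_src = upto
            cursor_tgt += size

    for pos, kind, n in events:
        emit_colinear(pos)
        if kind == "del":
            cursor_src += n
        elif kind == "ins":
            parts.append(_random_sequence(rng, n, gc_fraction))
            cursor_tgt += n
        else:  # inversion: reverse-complement in place
            segment = source[pos:pos + n]
            parts.append(_COMPLEMENT_CODE - segment[::-1])
            segments.append(AlignedSegment(pos, pos + n, cursor_tgt, "-"))
            truth_tgt[pos:pos + n] = cursor_tgt + (n - 1) - np.arange(n)
            truth_strand[pos:pos + n] = -1
            cursor_src += n
            cursor_tgt += n
    emit_colinear(length)

    target = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
    chain_fwd = _segments_to_chainset(segments, source_name, length,
                                      target_name, len(target))
    rev_segments = sorted(
        (AlignedSegment(s.tgt_start, s.tgt_start + s.size, s.src_start, s.strand)
         for s in segments), key=lambda s: s.src_start)
    chain_rev = _segments_to_chainset(rev_segments, target_name, len(target),
                                      source_name, length)

    pair = AssemblyPair(source_name=source_name, target_name=target_name,
                        source_codes=source, target_codes=target,
                        truth_tgt=truth_tgt, truth_strand=truth_strand,
                        segments=segments, chain_fwd=chain_fwd,
                        chain_rev=chain_rev, edits=edits, gc_fraction=gc_fraction)
    _verify_pair(pair)
    return pair


def _verify_pair(pair: AssemblyPair) -> None:
    """Internal consistency: both chains reproduce the base-level truth map."""
    tgt, strand, _ = exhaustive_truth_map(pair.chain_fwd, pair.source_name,
                                          pair.source_length)
    if not (np.array_equal(tgt, pair.truth_tgt)
            and np.array_equal(strand, pair.truth_strand)):
        raise AssertionError("forward chain disagrees with the truth map")
    rev_tgt = np.full(pair.target_length, -1, dtype=np.int64)
    rev_strand = np.zeros(pair.target_length, dtype=np.int8)
    mapped = pair.truth_tgt >= 0
    rev_tgt[pair.truth_tgt[mapped]] = np.flatnonzero(mapped)
    rev_strand[pair.truth_tgt[mapped]] = pair.truth_strand[mapped]
    got_tgt, got_strand, _ = exhaustive_truth_map(pair.chain_rev, pair.target_name,
                                                  pair.target_length)
    if not (np.array_equal(got_tgt, rev_tgt)
            and np.array_equal(got_strand, rev_strand)):
        raise AssertionError("reverse chain disagrees with the truth map")


# ---------------------------------------------------------------------------
# Call-set simulation

@dataclass
class TruthBundle:
    """Assembly pair + call sets + HC regions + per-variant truth ledger."""

    pair: AssemblyPair
    source_records: list[SNVRecord] = field(repr=False)
    target_records: list[SNVRecord] = field(repr=False)
    hc_source: ConfidenceRegions = field(repr=False)
    hc_target: ConfidenceRegions = field(repr=False)
    ledger: pd.DataFrame = field(repr=False)
    params: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.source_records)

    @property
    def n_convertible(self) -> int:
        return int((self.ledger["role"] != "target_only").sum()
                   - (self.ledger["role"] == "unconvertible").sum())

    @property
    def expected_conversion_rate_pct(self) -> float:
        return 100.0 * self.n_convertible / self.n_variants

    @property
    def expected_pdr_pct(self) -> float:
        return 100.0 * int((self.ledger["role"] == "pd").sum()) / self.n_convertible

    @property
    def expected_gdr_pct(self) -> float:
        return 100.0 * int((self.ledger["role"] == "gd").sum()) / self.n_convertible


def _draw_hc_regions(rng: np.random.Generator, name: str, length: int,
                     coverage: float, window: int) -> ConfidenceRegions:
    n_win = (length + window - 1) // window
    mask = rng.random(n_win) < coverage
    intervals: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i * window
        elif not flag and start is not None:
            intervals.append((start, i * window))
            start = None
    if start is not None:
        intervals.append((start, length))
    return ConfidenceRegions({name: intervals})


def _lc_draw_probability(f: float, n_hc_bg: float, n_lc_bg: float,
                         n_disc: int) -> float:
    """LC-class probability for injected discordances.

    Chosen so that the EXPECTED LC/HC discordance-rate ratio among all
    converted SNVs equals ``f`` exactly: the injected discordances sit in
    the all-converted denominators too, so the raw odds f*LC/(f*LC+HC) are
    corrected for that self-contamination by solving
    q*(N_h + n_d*(1-q)) = f*(1-q)*(N_l + n_d*q) for q in (0, 1).
    """
    if n_disc == 0:
        return 0.0
    if n_lc_bg == 0:
        return 0.0
    if f == 1.0:
        return n_lc_bg / (n_lc_bg + n_hc_bg)
    a = n_disc * (f - 1.0)
    b = n_hc_bg + n_disc - f * n_disc + f * n_lc_bg
    c = -f * n_lc_bg
    disc = b * b - 4.0 * a * c
    roots = [(-b + s * math.sqrt(disc)) / (2.0 * a) for s in (1.0, -1.0)]
    valid = [q for q in roots if 0.0 < q < 1.0]
    if not valid:
        raise FixtureError(f"no feasible LC draw probability for enrichment {f}")
    return valid[0]


def _nb_depths(rng: np.random.Generator, mean: float, dispersion: float,
               size: int) -> np.ndarray:
    if size == 0:
        return np.zeros(0, dtype=np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(np.int64)


def simulate_callsets(pair: AssemblyPair, n_variants: int,
                      spec: DiscordanceSpec = DiscordanceSpec(), *,
                      n_unconvertible: int = 0,
                      n_target_only: int = 0,
                      hc_coverage: float = 0.7,
                      hc_window: int = 500,
                      gc_bias_discordant: tuple[float, float, float, float]
                      = (0.24, 0.24, 0.26, 0.26),
                      depth_mean: float = 30.0,
                      depth_dispersion: float = 10.0,
                      p_het: float = 2.0 / 3.0) -> TruthBundle:
    """Simulate diploid SNV call sets on both assemblies with known truth.

    ``gc_bias_discordant`` gives the (A, T, G, C) probabilities for the
    target-side reference alleles of injected discordances; background
    variants are placed uniformly, so their composition follows the
    assembly's own base content.
    """
    rng = np.random.default_rng(spec.seed)
    n_pd = spec.n_position_discordant
    n_gd = spec.n_genotype_discordant
    n_disc = n_pd + n_gd
    n_bg = n_variants - n_unconvertible - n_disc
    if n_bg < 0:
        raise FixtureError("injection counts exceed the number of variants")
    if abs(sum(gc_bias_discordant) - 1.0) > 1e-9:
        raise FixtureError("gc_bias_discordant must sum to 1")

    hc_target = _draw_hc_regions(rng, pair.target_name, pair.target_length,
                                 hc_coverage, hc_window)
    hc_source = _draw_hc_regions(rng, pair.source_name, pair.source_length,
                                 hc_coverage, hc_window)

    conv_pos = np.flatnonzero(pair.truth_tgt >= 0)
    tgt_of = pair.truth_tgt[conv_pos]
    hc_flag = hc_target.contains_many(pair.target_name, tgt_of)
    tbase = pair.target_codes[tgt_of]

    # --- injected discordances: class (LC/HC) then target-side ref base ----
    h_frac = float(hc_flag.mean()) if len(conv_pos) else 0.0
    q = _lc_draw_probability(spec.lc_enrichment, n_bg * h_frac,
                             n_bg * (1.0 - h_frac), n_disc)
    lc_disc = rng.random(n_disc) < q
    # gc_bias order (A, T, G, C) -> base codes (A=0, C=1, G=2, T=3)
    pa, pt, pg, pc = gc_bias_discordant
    base_disc = rng.choice(4, size=n_disc, p=[pa, pc, pg, pt])
    pools: dict[tuple[bool, int], np.ndarray] = {}
    ptrs: dict[tuple[bool, int], int] = {}
    for hc in (False, True):
        for code in range(4):
            pool = conv_pos[(hc_flag == hc) & (tbase == code)]
            pools[(hc, code)] = rng.permutation(pool)
            ptrs[(hc, code)] = 0
    disc_pos = np.empty(n_disc, dtype=np.int64)
    for i in range(n_disc):
        key = (not lc_disc[i], int(base_disc[i]))
        if ptrs[key] >= len(pools[key]):
            raise FixtureError(
                f"exhausted candidate positions for stratum HC={key[0]} "
                f"base={_BASES[key[1]]}; use a longer genome or fewer injections")
        disc_pos[i] = pools[key][ptrs[key]]
        ptrs[key] += 1

    # --- background (concordant) and unconvertible variants ----------------
    used = np.zeros(pair.source_length, dtype=bool)
    used[disc_pos] = True
    bg_pool = conv_pos[~used[conv_pos]]
    if n_bg > len(bg_pool):
        raise FixtureError("not enough convertible positions for the call set")
    bg_pos = rng.choice(bg_pool, size=n_bg, replace=False)
    del_pool = np.flatnonzero(pair.truth_tgt < 0)
    if n_unconvertible > len(del_pool):
        raise FixtureError(
            f"{n_unconvertible} unconvertible variants requested but only "
            f"{len(del_pool)} deleted source bases exist")
    unconv_pos = rng.choice(del_pool, size=n_unconvertible, replace=False) \
        if n_unconvertible else np.zeros(0, dtype=np.int64)

    positions = np.concatenate([bg_pos, disc_pos, unconv_pos]).astype(np.int64)
    roles = np.array(["bg"] * n_bg + ["pd"] * n_pd + ["gd"] * n_gd
                     + ["unconvertible"] * n_unconvertible)
    n_total = len(positions)

    ref_code = pair.source_codes[positions]
    alt_code = (ref_code + 1 + rng.integers(0, 3, size=n_total)) % 4
    genotypes = np.where(rng.random(n_total) < p_het, "0/1", "1/1")
    shifted = roles != "bg"
    depths = np.empty(n_total, dtype=np.int64)
    depths[~shifted] = _nb_depths(rng, depth_mean, depth_dispersion,
                                  int((~shifted).sum()))
    depths[shifted] = _nb_depths(rng, depth_mean * spec.depth_shift,
                                 depth_dispersion, int(shifted.sum()))

    source_records = [
        SNVRecord(pair.source_name, int(positions[i]), _BASES[ref_code[i]],
                  _BASES[alt_code[i]], str(genotypes[i]), int(depths[i]))
        for i in range(n_total)]

    # --- direct target call set --------------------------------------------
    _, _, in_span = exhaustive_truth_map(pair.chain_fwd, pair.source_name,
                                         pair.source_length)
    tpos = np.where(pair.truth_tgt[positions] >= 0, pair.truth_tgt[positions], -1)
    minus = pair.truth_strand[positions] == -1
    t_ref = np.where(minus, _COMPLEMENT_CODE - ref_code, ref_code)
    t_alt = np.where(minus, _COMPLEMENT_CODE - alt_code, alt_code)

    gd_mask = roles == "gd"
    gd_flip_alt = rng.random(n_total) < 0.5  # consumed only where gd
    gd_alt_pick = rng.integers(0, 2, size=n_total)
    direct_depth = np.empty(n_total, dtype=np.int64)
    direct_depth[~shifted] = _nb_depths(rng, depth_mean, depth_dispersion,
                                        int((~shifted).sum()))
    direct_depth[shifted] = _nb_depths(rng, depth_mean * spec.depth_shift,
                                       depth_dispersion, int(shifted.sum()))

    target_records: list[SNVRecord] = []
    direct_alt = t_alt.copy()
    direct_gt = genotypes.copy()
    for i in range(n_total):
        role = roles[i]
        if role in ("pd", "unconvertible"):
            continue
        alt_i = int(t_alt[i])
        gt_i = str(genotypes[i])
        if role == "gd":
            if gd_flip_alt[i]:
                others = [c for c in range(4) if c not in (int(t_ref[i]), alt_i)]
                alt_i = others[int(gd_alt_pick[i])]
            else:
                gt_i = "1/1" if gt_i == "0/1" else "0/1"
            direct_alt[i] = alt_i
            direct_gt[i] = gt_i
        target_records.append(SNVRecord(pair.target_name, int(tpos[i]),
                                        _BASES[int(t_ref[i])], _BASES[alt_i],
                                        gt_i, int(direct_depth[i])))

    # target-only variants live in inserted (target-novel) sequence
    covered = np.zeros(pair.target_length, dtype=bool)
    covered[pair.truth_tgt[pair.truth_tgt >= 0]] = True
    ins_pool = np.flatnonzero(~covered)
    if n_target_only > len(ins_pool):
        raise FixtureError(
            f"{n_target_only} target-only variants requested but only "
            f"{len(ins_pool)} inserted target bases exist")
    to_pos = rng.choice(ins_pool, size=n_target_only, replace=False) \
        if n_target_only else np.zeros(0, dtype=np.int64)
    to_ref = pair.target_codes[to_pos]
    to_alt = (to_ref + 1 + rng.integers(0, 3, size=n_target_only)) % 4
    to_gt = np.where(rng.random(n_target_only) < p_het, "0/1", "1/1")
    to_depth = _nb_depths(rng, depth_mean, depth_dispersion, n_target_only)
    for i in range(n_target_only):
        target_records.append(SNVRecord(pair.target_name, int(to_pos[i]),
                                        _BASES[to_ref[i]], _BASES[to_alt[i]],
                                        str(to_gt[i]), int(to_depth[i])))

    source_records.sort(key=lambda r: r.sort_key)
    target_records.sort(key=lambda r: r.sort_key)

    # --- truth ledger -------------------------------------------------------
    expected_status = np.where(
        pair.truth_tgt[positions] >= 0, cl.CONVERTED,
        np.where(in_span[positions], cl.UNMAPPED_IN_GAP, cl.UNMAPPED_NO_CHAIN))
    strand_char = np.where(pair.truth_strand[positions] == 1, "+",
                           np.where(pair.truth_strand[positions] == -1, "-", ""))
    hc_of_variant = np.full(n_total, False)
    conv_mask = tpos >= 0
    hc_of_variant[conv_mask] = hc_target.contains_many(
        pair.target_name, tpos[conv_mask])
    rows = {
        "role": roles,
        "source_pos": positions,
        "target_pos": tpos,
        "strand": strand_char,
        "ref": [_BASES[c] for c in ref_code],
        "alt": [_BASES[c] for c in alt_code],
        "genotype": genotypes,
        "depth": depths,
        "target_ref": [_BASES[int(c)] if m else "" for c, m in zip(t_ref, conv_mask)],
        "direct_alt": [_BASES[int(c)] if m else "" for c, m in zip(direct_alt, conv_mask)],
        "direct_genotype": np.where(conv_mask, direct_gt, ""),
        "hc_target": np.where(conv_mask, np.where(hc_of_variant, "HC", "LC"), ""),
        "expected_status": expected_status,
    }
    ledger = pd.DataFrame(rows)
    if n_target_only:
        extra = pd.DataFrame({
            "role": ["target_only"] * n_target_only,
            "source_pos": [-1] * n_target_only,
            "target_pos": to_pos,
            "strand": [""] * n_target_only,
            "ref": [_BASES[c] for c in to_ref],
            "alt": [_BASES[c] for c in to_alt],
            "genotype": to_gt,
            "depth": to_depth,
            "target_ref": [_BASES[c] for c in to_ref],
            "direct_alt": [_BASES[c] for c in to_alt],
            "direct_genotype": to_gt,
            "hc_target": [""] * n_target_only,
            "expected_status": [""] * n_target_only,
        })
        ledger = pd.concat([ledger, extra], ignore_index=True)
    ledger = ledger.sort_values(["source_pos", "target_pos"],
                                kind="stable").reset_index(drop=True)

    params = {
        "n_variants": n_variants, "n_unconvertible": n_unconvertible,
        "n_target_only": n_target_only, "hc_coverage": hc_coverage,
        "hc_window": hc_window, "gc_bias_discordant": list(gc_bias_discordant),
        "depth_mean": depth_mean, "depth_dispersion": depth_dispersion,
        "p_het": p_het, "lc_draw_probability": q,
        "discordance_spec": asdict(spec), "edit_spec": asdict(pair.edits),
        "source_length": pair.source_length, "gc_fraction": pair.gc_fraction,
    }
    return TruthBundle(pair=pair, source_records=source_records,
                       target_records=target_records, hc_source=hc_source,
                       hc_target=hc_target, ledger=ledger, params=params)


# ---------------------------------------------------------------------------
# Fixture writing

def _write_fasta(path: Path, name: str, seq: str, width: int = 60) -> None:
    with open(path, "w") as handle:
        handle.write(f">{name}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i:i + width] + "\n")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_fixture(bundle: TruthBundle, out_dir: str | Path) -> dict:
    """Write the complete fixture tree; returns (and writes) the manifest.

    Re-running with the same specs and seeds reproduces byte-identical files.
    """
    import pyfaidx

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pair = bundle.pair
    _write_fasta(out_dir / "source.fa", pair.source_name, pair.source_seq)
    _write_fasta(out_dir / "target.fa", pair.target_name, pair.target_seq)
    for fasta in ("source.fa", "target.fa"):
        pyfaidx.Faidx(str(out_dir / fasta))  # builds .fai deterministically
    cl.write_chain(pair.chain_fwd, out_dir / "fwd.chain")
    cl.write_chain(pair.chain_rev, out_dir / "rev.chain")
    write_snv_vcf(bundle.source_records, {pair.source_name: pair.source_length},
                  out_dir / "source.vcf")
    write_snv_vcf(bundle.target_records, {pair.target_name: pair.target_length},
                  out_dir / "target.vcf")
    bundle.hc_source.to_bed(out_dir / "hc_source.bed")
    bundle.hc_target.to_bed(out_dir / "hc_target.bed")
    bundle.ledger.to_csv(out_dir / "ledger.tsv", sep="\t", index=False)
    files = ["source.fa", "source.fa.fai", "target.fa", "target.fa.fai",
             "fwd.chain", "rev.chain", "source.vcf", "target.vcf",
             "hc_source.bed", "hc_target.bed", "ledger.tsv"]
    manifest = {
        "seed": bundle.params.get("discordance_spec", {}).get("seed"),
        "params": bundle.params,
        "files": {name: _sha256(out_dir / name) for name in files},
    }
    with open(out_dir / "manifest.yaml", "w") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=True)
    return manifest


def derive_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]
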