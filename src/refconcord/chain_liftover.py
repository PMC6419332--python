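"""UCSC chain parsing and SNV liftover between assembly versions.

This module is the repository's own coordinate-conversion engine (the role
Picard LiftoverVcf or CrossMap play for real assemblies): it parses UCSC chain
files, builds a queryable interval index over the aligned blocks, maps single
positions between assemblies, and lifts biallelic SNVs with allele-level
checks (strand complementation across inverted blocks, reference-allele
verification against the target assembly).

Coordinate conventions
----------------------
A chain header reads ``chain score tName tSize tStrand tStart tEnd qName
qSize qStrand qStart qEnd id``. This module treats the chain's t-side as the
lift SOURCE and the q-side as the lift TARGET, matching how UCSC liftOver
consumes an ``oldToNew`` chain. All coordinates are 0-based half-open; the
q-side is strand-local per the UCSC spec (for a ``-`` strand chain,
``qStart``/``qEnd`` count from the far end of the target sequence). VCF's
1-based convention is applied only at file boundaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import pysam
from intervaltree import IntervalTree

from .variants import SNVRecord, get_base

# Lift / mapping statuses. All failure modes are statuses, not exceptions.
CONVERTED = "converted"
UNMAPPED_NO_CHAIN = "unmapped_no_chain"
UNMAPPED_IN_GAP = "unmapped_in_gap"
REJECTED_REF_MISMATCH = "rejected_ref_mismatch"
REJECTED_MULTIMAP = "rejected_multimap"

REJECT_STATUSES = (UNMAPPED_NO_CHAIN, UNMAPPED_IN_GAP,
                   REJECTED_REF_MISMATCH, REJECTED_MULTIMAP)


class ChainFormatError(ValueError):
    """Malformed chain text or block arithmetic inconsistency."""


@dataclass(frozen=True)
class ChainBlock:
    """One ungapped aligned block, plus the gaps that follow it.

    ``source_gap``/``target_gap`` are the bases skipped on either side before
    the next block (``dt``/``dq`` in the UCSC format); both are zero for the
    last block of a chain.
    """

    size: int
    source_gap: int = 0
    target_gap: int = 0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ChainFormatError(f"block size must be >= 1, got {self.size}")
        if self.source_gap < 0 or self.target_gap < 0:
            raise ChainFormatError("negative gap in chain block")


@dataclass
class Chain:
    """One colinear alignment between a source and a target interval."""

    score: int
    source_name: str
    source_size: int
    source_start: int
    source_end: int
    target_name: str
    target_size: int
    target_strand: str  # '+' or '-'; target_start/end are strand-local
    target_start: int
    target_end: int
    blocks: list[ChainBlock]
    chain_id: int

    def validate(self) -> None:
        if self.target_strand not in ("+", "-"):
            raise ChainFormatError(f"chain {self.chain_id}: bad strand {self.target_strand!r}")
        if self.blocks and (self.blocks[-1].source_gap or self.blocks[-1].target_gap):
            raise ChainFormatError(f"chain {self.chain_id}: last block carries gaps")
        src_span = sum(b.size + b.source_gap for b in self.blocks)
        tgt_span = sum(b.size + b.target_gap for b in self.blocks)
        if src_span != self.source_end - self.source_start:
            raise ChainFormatError(
                f"chain {self.chain_id}: blocks span {src_span} source bases but header "
                f"declares {self.source_end - self.source_start}")
        if tgt_span != self.target_end - self.target_start:
            raise ChainFormatError(
                f"chain {self.chain_id}: blocks span {tgt_span} target bases but header "
                f"declares {self.target_end - self.target_start}")
        if not (0 <= self.source_start <= self.source_end <= self.source_size):
            raise ChainFormatError(f"chain {self.chain_id}: source interval out of bounds")
        if not (0 <= self.target_start <= self.target_end <= self.target_size):
            raise ChainFormatError(f"chain {self.chain_id}: target interval out of bounds")


@dataclass
class ChainSet:
    """A parsed chain file: all chains plus per-assembly sequence sizes."""

    chains: list[Chain] = field(default_factory=list)
    source_sequence_sizes: dict[str, int] = field(default_factory=dict)
    target_sequence_sizes: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class MappedPosition:
    target_name: str
    target_pos: int  # 0-based, plus-strand coordinate
    strand: str  # '+' or '-' (orientation of the covering block)
    chain_id: int


@dataclass
class LiftResult:
    """Outcome of lifting one SNV; converted iff mapped+alleles present."""

    status: str
    source: SNVRecord
    mapped: MappedPosition | None = None
    lifted_ref: str | None = None
    lifted_alt: str | None = None

    @property
    def converted(self) -> bool:
        return self.status == CONVERTED


@dataclass
class ConversionTally:
    """Conversion bookkeeping; input always equals converted + all rejects."""

    n_input: int = 0
    n_converted: int = 0
    n_unmapped_no_chain: int = 0
    n_unmapped_in_gap: int = 0
    n_rejected_ref_mismatch: int = 0
    n_rejected_multimap: int = 0

    def count(self, status: str) -> None:
        self.n_input += 1
        attr = "n_converted" if status == CONVERTED else "n_" + status
        setattr(self, attr, getattr(self, attr) + 1)

    @property
    def n_rejected(self) -> int:
        return (self.n_unmapped_no_chain + self.n_unmapped_in_gap
                + self.n_rejected_ref_mismatch + self.n_rejected_multimap)

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# Parsing and writing

def parse_chain(stream: str | TextIO) -> ChainSet:
    """Parse UCSC chain text into a ChainSet, validating block arithmetic.

    Accepts a string of chain text or a text stream. An empty stream yields
    an empty ChainSet; malformed headers or arithmetic mismatches raise
    ChainFormatError naming the offending chain id.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    chainset = ChainSet()
    current: Chain | None = None

    def finish(chain: Chain | None) -> None:
        if chain is None:
            return
        if not chain.blocks:
            raise ChainFormatError(f"chain {chain.chain_id}: no alignment blocks")
        chain.validate()
        for side, name, size in ((chainset.source_sequence_sizes, chain.source_name,
                                  chain.source_size),
                                 (chainset.target_sequence_sizes, chain.target_name,
                                  chain.target_size)):
            if side.setdefault(name, size) != size:
                raise ChainFormatError(
                    f"chain {chain.chain_id}: sequence {name} declared with size {size}, "
                    f"previously {side[name]}")
        chainset.chains.append(chain)

    open_block = False  # inside a chain whose final bare-size line is pending
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0] == "chain":
            if open_block:
                raise ChainFormatError(f"line {lineno}: new chain before previous one ended")
            if len(fields) != 13:
                raise ChainFormatError(f"line {lineno}: chain header needs 13 fields, "
                                       f"got {len(fields)}")
            try:
                score = int(float(fields[1]))
                src_size, src_start, src_end = map(int, (fields[3], fields[5], fields[6]))
                tgt_size, tgt_start, tgt_end = map(int, (fields[8], fields[10], fields[11]))
                chain_id = int(fields[12])
            except ValueError as exc:
                raise ChainFormatError(f"line {lineno}: non-numeric chain header field") from exc
            if fields[4] != "+":
                raise ChainFormatError(f"line {lineno}: source strand must be '+', "
                                       f"got {fields[4]!r}")
            current = Chain(score=score,
                            source_name=fields[2], source_size=src_size,
                            source_start=src_start, source_end=src_end,
                            target_name=fields[7], target_size=tgt_size,
                            target_strand=fields[9],
                            target_start=tgt_start, target_end=tgt_end,
                            blocks=[], chain_id=chain_id)
            open_block = True
        else:
            if current is None:
                raise ChainFormatError(f"line {lineno}: alignment data before any chain header")
            try:
                nums = [int(f) for f in fields]
            except ValueError as exc:
                raise ChainFormatError(f"line {lineno}: non-integer block line") from exc
            if len(nums) == 3:
                current.blocks.append(ChainBlock(nums[0], nums[1], nums[2]))
            elif len(nums) == 1:
                current.blocks.append(ChainBlock(nums[0]))
                finish(current)
                current = None
                open_block = False
            else:
                raise ChainFormatError(f"line {lineno}: block line needs 1 or 3 integers")
    if open_block:
        raise ChainFormatError(f"chain {current.chain_id}: truncated (missing final block size)")
    return chainset


def read_chain(path: str | Path) -> ChainSet:
    with open(path) as handle:
        return parse_chain(handle)


def write_chain(chainset: ChainSet, path_or_stream: str | Path | TextIO) -> None:
    """Write a ChainSet in UCSC chain format (one blank line between chains)."""
    own = isinstance(path_or_stream, (str, Path))
    handle = open(path_or_stream, "w") if own else path_or_stream
    try:
        for chain in chainset.chains:
            chain.validate()
            handle.write(
                f"chain {chain.score} {chain.source_name} {chain.source_size} + "
                f"{chain.source_start} {chain.source_end} {chain.target_name} "
                f"{chain.target_size} {chain.target_strand} {chain.target_start} "
                f"{chain.target_end} {chain.chain_id}\n")
            for block in chain.blocks[:-1]:
                handle.write(f"{block.size} {block.source_gap} {block.target_gap}\n")
            handle.write(f"{chain.blocks[-1].size}\n\n")
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# Indexing and position mapping

class ChainIndex:
    """Point-queryable coordinate map over a ChainSet's aligned blocks."""

    def __init__(self, chainset: ChainSet):
        self.chainset = chainset
        self._blocks: dict[str, IntervalTree] = {}
        self._spans: dict[str, IntervalTree] = {}
        for chain in chainset.chains:
            blocks = self._blocks.setdefault(chain.source_name, IntervalTree())
            spans = self._spans.setdefault(chain.source_name, IntervalTree())
            if chain.source_end > chain.source_start:
                spans.addi(chain.source_start, chain.source_end, chain.chain_id)
            src = chain.source_start
            tgt = chain.target_start  # strand-local
            for block in chain.blocks:
                blocks.addi(src, src + block.size, (chain, tgt))
                src += block.size + block.source_gap
                tgt += block.size + block.target_gap

    @property
    def source_sequence_sizes(self) -> dict[str, int]:
        return self.chainset.source_sequence_sizes

    @property
    def target_sequence_sizes(self) -> dict[str, int]:
        return self.chainset.target_sequence_sizes

    def map_position(self, name: str, pos: int) -> tuple[str, MappedPosition | None]:
        """Map one source position; returns (status, MappedPosition-or-None).

        Multiple covering blocks resolve to the highest-score chain; distinct
        equal-score targets yield ``rejected_multimap``. A position inside a
        chain's span but not inside any aligned block is ``unmapped_in_gap``;
        a position no chain covers is ``unmapped_no_chain``.
        """
        if pos < 0:
            raise ValueError("position must be >= 0")
        tree = self._blocks.get(name)
        hits = tree[pos] if tree is not None else ()
        if not hits:
            spans = self._spans.get(name)
            if spans is not None and spans[pos]:
                return UNMAPPED_IN_GAP, None
            return UNMAPPED_NO_CHAIN, None
        best_score = max(iv.data[0].score for iv in hits)
        mapped: set[MappedPosition] = set()
        positions: set[tuple[str, int, str]] = set()
        for iv in hits:
            chain, tgt_local_start = iv.data
            if chain.score != best_score:
                continue
            local = tgt_local_start + (pos - iv.begin)
            if chain.target_strand == "+":
                plus = local
            else:
                plus = chain.target_size - 1 - local
            key = (chain.target_name, plus, chain.target_strand)
            if key not in positions:
                positions.add(key)
                mapped.add(MappedPosition(chain.target_name, plus,
                                          chain.target_strand, chain.chain_id))
        if len(positions) > 1:
            return REJECTED_MULTIMAP, None
        return CONVERTED, next(iter(mapped))


def build_index(chains: ChainSet) -> ChainIndex:
    return ChainIndex(chains)


# ---------------------------------------------------------------------------
# Variant lifting

def lift_variant(index: ChainIndex, snv: SNVRecord, target_sequences,
                 on_ref_mismatch: str = "reject") -> LiftResult:
    """Lift one biallelic SNV through the chain index.

    On a '-' strand block both alleles are complemented; the lifted ref is
    then compared against the target assembly base at the mapped position.
    A mismatch rejects the variant unless ``on_ref_mismatch="keep"``. The
    genotype is carried through unchanged (alt dosage is strand-invariant).
    """
    if on_ref_mismatch not in ("reject", "keep"):
        raise ValueError(f"on_ref_mismatch must be 'reject' or 'keep', got {on_ref_mismatch!r}")
    status, mapped = index.map_position(snv.seq_name, snv.pos)
    if status != CONVERTED:
        return LiftResult(status=status, source=snv)
    lifted = snv if mapped.strand == "+" else snv.complemented()
    target_base = get_base(target_sequences, mapped.target_name, mapped.target_pos)
    if target_base != lifted.ref and on_ref_mismatch == "reject":
        return LiftResult(status=REJECTED_REF_MISMATCH, source=snv, mapped=mapped,
                          lifted_ref=lifted.ref, lifted_alt=lifted.alt)
    return LiftResult(status=CONVERTED, source=snv, mapped=mapped,
                      lifted_ref=lifted.ref, lifted_alt=lifted.alt)


def lift_records(index: ChainIndex, records: Iterable[SNVRecord], target_sequences,
                 on_ref_mismatch: str = "reject"
                 ) -> tuple[list[tuple[SNVRecord, LiftResult]], list[LiftResult],
                            ConversionTally]:
    """Lift many SNVs; returns (converted, rejected, tally).

    Converted entries pair the target-coordinate SNVRecord with its
    LiftResult (carrying source coordinate and chain provenance); the
    converted list is sorted by target coordinate.
    """
    converted: list[tuple[SNVRecord, LiftResult]] = []
    rejected: list[LiftResult] = []
    tally = ConversionTally()
    for snv in records:
        result = lift_variant(index, snv, target_sequences, on_ref_mismatch)
        tally.count(result.status)
        if result.converted:
            moved = SNVRecord(result.mapped.target_name, result.mapped.target_pos,
                              result.lifted_ref, result.lifted_alt,
                              snv.genotype, snv.depth)
            converted.append((moved, result))
        else:
            rejected.append(result)
    converted.sort(key=lambda pair: pair[0].sort_key)
    return converted, rejected, tally


_LIFT_INFO_FIELDS = (
    ("SRC", "1", "String", "Source assembly coordinate (seq:pos, 1-based)"),
    ("CHAINID", "1", "Integer", "Chain id used for the conversion"),
)
_REJECT_INFO_FIELDS = (
    ("LSTAT", "1", "String", "Liftover rejection status"),
)


def _check_direction(vcf_path, chainset: ChainSet) -> None:
    """Sequence sizes shared between the VCF header and the chain source side
    must agree, else the chain direction does not match the call set."""
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for contig in vcf.header.contigs.values():
            declared = chainset.source_sequence_sizes.get(contig.name)
            if declared is not None and contig.length and contig.length != declared:
                raise ValueError(
                    f"chain direction mismatch: {contig.name} is {contig.length} bp in the "
                    f"VCF but {declared} bp on the chain source side")


def lift_callset(vcf_in: str | Path, chains: ChainSet | ChainIndex | str | Path,
                 target_fasta, vcf_converted_out: str | Path,
                 rejects_out: str | Path,
                 on_ref_mismatch: str = "reject") -> ConversionTally:
    """Lift a whole VCF call set, writing converted and rejected records.

    The converted VCF is coordinate-sorted on the target assembly and carries
    SRC/CHAINID INFO tags; every rejected record appears in ``rejects_out``
    with its status in the LSTAT INFO tag. The returned tally satisfies
    n_input = n_converted + sum of per-reason rejects.
    """
    from .variants import filter_snvs, write_snv_vcf  # local to avoid cycles

    if isinstance(chains, (str, Path)):
        chains = read_chain(chains)
    index = chains if isinstance(chains, ChainIndex) else ChainIndex(chains)
    _check_direction(vcf_in, index.chainset)
    if isinstance(target_fasta, (str, Path)):
        import pyfaidx
        target_fasta = pyfaidx.Fasta(str(target_fasta))
    records, _ = filter_snvs(vcf_in)
    converted, rejected, tally = lift_records(index, records, target_fasta,
                                              on_ref_mismatch)
    info = {moved.sort_key: {"SRC": f"{res.source.seq_name}:{res.source.pos + 1}",
                             "CHAINID": res.mapped.chain_id}
            for moved, res in converted}
    write_snv_vcf([moved for moved, _ in converted],
                  index.target_sequence_sizes, vcf_converted_out,
                  info=info, info_fields=_LIFT_INFO_FIELDS)
    reject_info = {res.source.sort_key: {"LSTAT": res.status} for res in rejected}
    write_snv_vcf([res.source for res in rejected],
                  index.source_sequence_sizes, rejects_out,
                  info=reject_info, info_fields=_REJECT_INFO_FIELDS)
    return tally
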