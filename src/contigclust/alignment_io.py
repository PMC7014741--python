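"""Parse multi-mapped SAM/BAM files into an in-memory read-to-contig table.

The clustering method treats a contig purely as the set of sequencing
fragments that align to it; nucleotide sequence and alignment positions are
never consulted.  This module reduces one or more alignment files (one per
sample, coordinate-sorted or not) to:

* a :class:`MappingTable` — which fragments map to which contigs, fragment
  lengths, and contig lengths from the headers; and
* :class:`ContigStats` — per-contig totals derived from the table: the number
  of distinct mapped fragments ``R_i``, the summed fragment length ``s_i``
  (the numerator of effective coverage), and per-sample fragment counts.

Paired mates are collapsed into a single *fragment* keyed by query name: a
fragment is associated with contig X iff at least one of its mates has a
mapped primary or secondary alignment to X.  Secondary alignments are
first-class evidence (multi-mapping is the signal of interest); supplementary
(chimeric) records and unmapped records are ignored.  No mapping-quality or
alignment-score filter is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import pysam

#: key identifying one sequencing fragment: (sample label, query name)
FragmentKey = Tuple[str, str]


class AlignmentInputError(ValueError):
    """A missing file, header-less SAM, or inconsistent reference dictionary."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One SAM record reduced to the fields the method consumes."""

    read_id: str
    contig_id: str
    sample_id: str
    read_length: int
    is_secondary: bool
    is_supplementary: bool
    is_unmapped: bool
    mate_index: int  # 1 or 2 for paired mates, 0 for unpaired


@dataclass
class MappingTable:
    """Fragment-to-contig map plus lengths, with sample origin preserved.

    Attributes
    ----------
    contig_lengths
        Length in bp of every contig declared in the headers (``c_i``).
        Contigs that receive no fragments stay here and later surface as
        low-evidence singletons, so the output partitions the full assembly.
    fragment_contigs
        ``(sample_id, fragment_id) -> set of contig ids`` the fragment maps to.
    fragment_lengths
        ``(sample_id, fragment_id) -> summed query length of its mapped
        mates`` in bases.
    samples
        Sample labels in input order.
    """

    contig_lengths: Dict[str, int] = field(default_factory=dict)
    fragment_contigs: Dict[FragmentKey, Set[str]] = field(default_factory=dict)
    fragment_lengths: Dict[FragmentKey, int] = field(default_factory=dict)
    samples: List[str] = field(default_factory=list)

    @property
    def n_contigs(self) -> int:
        return len(self.contig_lengths)

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_contigs)

    def merge(self, other: "MappingTable") -> "MappingTable":
        """Combine two tables parsed from disjoint sample sets."""
        merged = MappingTable(
            contig_lengths=dict(self.contig_lengths),
            fragment_contigs={k: set(v) for k, v in self.fragment_contigs.items()},
            fragment_lengths=dict(self.fragment_lengths),
            samples=list(self.samples),
        )
        for contig, length in other.contig_lengths.items():
            if merged.contig_lengths.get(contig, length) != length:
                raise AlignmentInputError(
                    f"contig {contig!r} declared with two different lengths "
                    f"({merged.contig_lengths[contig]} vs {length})"
                )
            merged.contig_lengths[contig] = length
        for key, contigs in other.fragment_contigs.items():
            merged.fragment_contigs.setdefault(key, set()).update(contigs)
        for key, length in other.fragment_lengths.items():
            merged.fragment_lengths[key] = max(merged.fragment_lengths.get(key, 0), length)
        for sample in other.samples:
            if sample not in merged.samples:
                merged.samples.append(sample)
        return merged

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MappingTable):
            return NotImplemented
        return (
            self.contig_lengths == other.contig_lengths
            and self.fragment_contigs == other.fragment_contigs
            and self.fragment_lengths == other.fragment_lengths
            and self.samples == other.samples
        )


@dataclass
class ContigStats:
    """Per-contig totals: R_i, s_i and per-sample fragment counts."""

    reads_total: Dict[str, int] = field(default_factory=dict)
    base_sum: Dict[str, int] = field(default_factory=dict)
    per_sample_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)


def _record_query_length(rec: pysam.AlignedSegment) -> int:
    # secondary records are allowed to omit SEQ; fall back to the CIGAR
    length = rec.query_length
    if not length:
        length = rec.infer_query_length() or 0
    return length


def _mate_index(rec: pysam.AlignedSegment) -> int:
    if not rec.is_paired:
        return 0
    return 1 if rec.is_read1 else 2


def parse_alignments(
    paths: Sequence[str], sample_ids: Sequence[str]
) -> MappingTable:
    """Parse SAM/BAM files (one sample label per file) into a MappingTable.

    A fragment is associated with a contig iff at least one of its mates has
    a mapped primary or secondary alignment to that contig.  Supplementary
    and unmapped records are skipped; duplicate (fragment, contig) pairs are
    collapsed.  Contig lengths come from the ``@SQ`` header lines; the same
    contig declared with two different lengths across files is an error.

    Raises
    ------
    AlignmentInputError
        For a missing file, a header without reference sequences, or
        conflicting contig lengths.
    """
    if len(paths) != len(sample_ids):
        raise AlignmentInputError(
            f"{len(paths)} input files but {len(sample_ids)} sample labels"
        )
    table = MappingTable()
    # (sample, fragment) -> {mate_index: read length}; summed at the end so a
    # mate seen through several (primary + secondary) records counts once
    mate_lengths: Dict[FragmentKey, Dict[int, int]] = {}

    for path, sample in zip(paths, sample_ids):
        if sample not in table.samples:
            table.samples.append(sample)
        try:
            handle = pysam.AlignmentFile(str(path), check_sq=False)
        except (FileNotFoundError, OSError) as exc:
            raise AlignmentInputError(f"cannot open alignment file {path!r}: {exc}") from exc
        with handle:
            if handle.nreferences == 0:
                raise AlignmentInputError(
                    f"{path!r} declares no reference sequences (@SQ); "
                    "a header with contig names and lengths is required"
                )
            for name, length in zip(handle.references, handle.lengths):
                known = table.contig_lengths.get(name)
                if known is not None and known != int(length):
                    raise AlignmentInputError(
                        f"contig {name!r} declared with two different lengths "
                        f"({known} vs {length})"
                    )
                table.contig_lengths[name] = int(length)
            for rec in handle.fetch(until_eof=True):
                if rec.is_unmapped or rec.is_supplementary:
                    continue
                key = (sample, rec.query_name)
                table.fragment_contigs.setdefault(key, set()).add(rec.reference_name)
                mate = _mate_index(rec)
                length = _record_query_length(rec)
                lengths = mate_lengths.setdefault(key, {})
                lengths[mate] = max(lengths.get(mate, 0), length)

    for key, lengths in mate_lengths.items():
        table.fragment_lengths[key] = sum(lengths.values())
    return table


def compute_contig_stats(table: MappingTable) -> ContigStats:
    """Derive R_i, s_i and per-sample counts for every contig in the table.

    ``R_i`` counts distinct fragments whose contig set contains ``i``;
    ``s_i`` sums those fragments' lengths.  A fragment that maps to several
    contigs contributes its full length to each of them.  Contigs with no
    mapped fragments get explicit zeros.
    """
    stats = ContigStats()
    for contig in table.contig_lengths:
        stats.reads_total[contig] = 0
        stats.base_sum[contig] = 0
        stats.per_sample_counts[contig] = {}
    for (sample, _), contigs in table.fragment_contigs.items():
        length = table.fragment_lengths.get((sample, _), 0)
        for contig in contigs:
            if contig not in stats.reads_total:
                # contig seen in alignments but absent from contig_lengths
                # violates the MappingTable invariant
                raise AlignmentInputError(
                    f"fragment maps to unknown contig {contig!r}"
                )
            stats.reads_total[contig] += 1
            stats.base_sum[contig] += length
            counts = stats.per_sample_counts[contig]
            counts[sample] = counts.get(sample, 0) + 1
    return stats
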