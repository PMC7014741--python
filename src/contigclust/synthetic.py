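"""Synthetic assemblies with known locus structure, emitted as SAM + truth.

The generator emulates the read-sharing structure that de novo transcriptome
assemblies exhibit: each locus emits several contigs (isoforms, alleles,
close paralogs) whose fragment sets overlap by a controllable fraction;
contigs from different loci may share a smaller fraction (motif-level
similarity creating false-positive pressure); reads multi-map accordingly;
and a configurable number of junk contigs receive almost no reads so they
fall below the default effective-coverage filter.  Reads are abstract
fragment identifiers — the clustering method never looks at nucleotide
sequence, so none is simulated.

Sharing is realized with shared fragment pools consumed as prefixes, which
makes pairwise overlap fractions hold by construction rather than in
expectation: a within-locus contig pair shares ≈ ``shared_fraction_within``
of the smaller contig's fragments, and a cross-locus pair
≈ ``shared_fraction_between``.

Emitted SAM files (one per sample) use a minimal dialect: unpaired reads,
FLAG 0 for the first listed contig and 256 (secondary) for the rest, POS 1,
MAPQ 0, CIGAR ``<len>M`` and a SEQ of ``N``s.  Re-parsing them reproduces
the truth's fragment-to-contig map exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Set, Tuple

import numpy as np

from .alignment_io import MappingTable


@dataclass
class SyntheticTruth:
    """Ground truth: loci, contigs with locus labels and lengths, fragments."""

    loci: List[str]
    #: contig_id -> (locus_id, length in bp)
    contigs: Dict[str, Tuple[str, int]]
    #: fragment_id -> (sample_id, length in bases, contigs it maps to)
    fragments: Dict[str, Tuple[str, int, FrozenSet[str]]]
    samples: List[str]
    seed: int

    def locus_of(self) -> Dict[str, str]:
        """contig -> locus map, the evaluation's ground-truth labels."""
        return {c: locus for c, (locus, _) in self.contigs.items()}

    def contig_lengths(self) -> Dict[str, int]:
        return {c: length for c, (_, length) in self.contigs.items()}

    def to_mapping_table(self) -> MappingTable:
        """The MappingTable that parsing the emitted SAM files yields."""
        table = MappingTable(
            contig_lengths=self.contig_lengths(), samples=list(self.samples)
        )
        for fid, (sample, length, contigs) in self.fragments.items():
            table.fragment_contigs[(sample, fid)] = set(contigs)
            table.fragment_lengths[(sample, fid)] = length
        return table


def generate_truth(
    n_loci: int = 20,
    isoforms_per_locus: Tuple[int, int] = (2, 4),
    shared_fraction_within: float = 0.6,
    shared_fraction_between: float = 0.0,
    reads_per_contig: Tuple[int, int] = (30, 60),
    read_length: int = 100,
    n_samples: int = 2,
    junk_contigs: int = 5,
    seed: int = 0,
) -> SyntheticTruth:
    """Generate a seeded synthetic assembly with known locus structure.

    Contig lengths are set to ``reads * read_length / 4`` so real contigs
    have effective coverage ≈ 4 (comfortably passing the default l = 2);
    junk contigs carry a single read on a contig ten read-lengths long
    (coverage 0.1) and therefore fail any l > 0.1.

    Raises
    ------
    ValueError
        If a fraction falls outside [0, 1] or within-locus sharing is below
        between-locus sharing (an infeasible overlap structure).
    """
    for name, frac in (
        ("shared_fraction_within", shared_fraction_within),
        ("shared_fraction_between", shared_fraction_between),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {frac}")
    if shared_fraction_within < shared_fraction_between:
        raise ValueError(
            "within-locus sharing below between-locus sharing is infeasible"
        )
    if n_samples < 1:
        raise ValueError("need at least one sample")

    rng = np.random.default_rng(seed)
    samples = [f"sample{s + 1}" for s in range(n_samples)]
    loci = [f"locus{t:03d}" for t in range(n_loci)]

    fragments: Dict[str, Tuple[str, int]] = {}  # fid -> (sample, length)
    frag_members: Dict[str, Set[str]] = {}
    counter = 0

    def new_fragment() -> str:
        nonlocal counter
        fid = f"F{counter:07d}"
        counter += 1
        sample = samples[int(rng.integers(0, n_samples))]
        fragments[fid] = (sample, read_length)
        frag_members[fid] = set()
        return fid

    def take_prefix(pool: List[str], n: int) -> List[str]:
        while len(pool) < n:
            pool.append(new_fragment())
        return pool[:n]

    contigs: Dict[str, Tuple[str, int]] = {}
    global_pool: List[str] = []
    lo, hi = isoforms_per_locus
    r_lo, r_hi = reads_per_contig

    for t, locus in enumerate(loci):
        locus_pool: List[str] = []
        k = int(rng.integers(lo, hi + 1))
        for iso in range(k):
            contig = f"L{t:03d}C{iso}"
            r_i = int(rng.integers(r_lo, r_hi + 1))
            n_between = math.floor(shared_fraction_between * r_i)
            n_within = math.floor(shared_fraction_within * r_i) - n_between
            n_unique = r_i - n_between - n_within
            members = take_prefix(global_pool, n_between) + take_prefix(
                locus_pool, n_within
            )
            members += [new_fragment() for _ in range(n_unique)]
            for fid in members:
                frag_members[fid].add(contig)
            length = max(1, (r_i * read_length) // 4)
            contigs[contig] = (locus, length)

    junk_loci = []
    for k in range(junk_contigs):
        locus = f"junk{k:03d}"
        contig = f"ZJUNK{k:03d}"
        junk_loci.append(locus)
        fid = new_fragment()
        frag_members[fid].add(contig)
        contigs[contig] = (locus, read_length * 10)

    frozen = {
        fid: (fragments[fid][0], fragments[fid][1], frozenset(members))
        for fid, members in frag_members.items()
        if members  # a pooled fragment never drawn maps nowhere: drop it
    }
    return SyntheticTruth(
        loci=loci + junk_loci,
        contigs=contigs,
        fragments=frozen,
        samples=samples,
        seed=seed,
    )


def emit_sam(truth: SyntheticTruth, out_dir: str) -> List[Path]:
    """Write one SAM file per sample; returns the paths in sample order.

    Every file's header declares all contigs (``@SQ``); each (fragment,
    contig) pair becomes one mapped record, the lexicographically first
    contig primary and the rest secondary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contig_order = sorted(truth.contigs)
    header_lines = ["@HD\tVN:1.6\tSO:unsorted"]
    header_lines += [
        f"@SQ\tSN:{c}\tLN:{truth.contigs[c][1]}" for c in contig_order
    ]
    paths = []
    for sample in truth.samples:
        path = out / f"{sample}.sam"
        with path.open("w", encoding="utf-8") as fh:
            for line in header_lines:
                fh.write(line + "\n")
            for fid in sorted(truth.fragments):
                f_sample, length, contigs = truth.fragments[fid]
                if f_sample != sample:
                    continue
                seq = "N" * length
                for idx, contig in enumerate(sorted(contigs)):
                    flag = 0 if idx == 0 else 256
                    fh.write(
                        f"{fid}\t{flag}\t{contig}\t1\t0\t{length}M\t*\t0\t0\t{seq}\t*\n"
                    )
        paths.append(path)
    return paths


def write_truth_tables(truth: SyntheticTruth, prefix: str) -> List[Path]:
    """Write the ground truth as TSV: contig table and fragment manifest."""
    contig_path = Path(f"{prefix}.truth_contigs.tsv")
    with contig_path.open("w", encoding="utf-8") as fh:
        fh.write("contig_id\tlocus_id\tlength\n")
        for contig in sorted(truth.contigs):
            locus, length = truth.contigs[contig]
            fh.write(f"{contig}\t{locus}\t{length}\n")
    frag_path = Path(f"{prefix}.truth_fragments.tsv")
    with frag_path.open("w", encoding="utf-8") as fh:
        fh.write("fragment_id\tsample_id\tlength\tcontigs\n")
        for fid in sorted(truth.fragments):
            sample, length, contigs = truth.fragments[fid]
            fh.write(f"{fid}\t{sample}\t{length}\t{','.join(sorted(contigs))}\n")
    return [contig_path, frag_path]


def read_truth_contigs(path: str) -> Dict[str, str]:
    """Re-read a truth contig table into a contig -> locus map."""
    mapping: Dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("contig_id\t"):
            raise ValueError(f"{path!r} is not a truth contig TSV")
        for line in fh:
            contig, locus, _ = line.rstrip("\n").split("\t")
            mapping[contig] = locus
    return mapping
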