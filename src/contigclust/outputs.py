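"""Representative selection and TSV output files.

Each cluster is summarized by two candidate representatives — its longest
member contig and the member with the most mapped reads — for downstream
identification (BLAST/BUSCO) and expression analysis.  Five newline-
terminated UTF-8 TSV files are written per run:

* ``<prefix>.clusters.tsv``   contig_id  cluster_id (one row per contig)
* ``<prefix>.counts.tsv``     cluster_id  <one raw count column per sample>
* ``<prefix>.types.tsv``      cluster_id  n_members  type
* ``<prefix>.reps_longest.tsv``    cluster_id  contig_id
* ``<prefix>.reps_mostreads.tsv``  cluster_id  contig_id

Row order is deterministic (cluster id order; contigs sorted within file).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set

from Bio import SeqIO

from .alignment_io import ContigStats
from .engine import ClusterSet


@dataclass(frozen=True)
class RepresentativeChoice:
    cluster_id: str
    longest_member: str
    most_reads_member: str


def select_representatives(
    clusters: ClusterSet,
    contig_lengths: Dict[str, int],
    stats: ContigStats,
) -> List[RepresentativeChoice]:
    """Pick per-cluster representatives: the longest member and the member
    with the largest pooled read count.  Ties break to the lexicographically
    smaller contig id."""
    choices = []
    for cid, members in clusters.clusters:
        longest = min(members, key=lambda m: (-contig_lengths[m], m))
        most_reads = min(members, key=lambda m: (-stats.reads_total.get(m, 0), m))
        choices.append(RepresentativeChoice(cid, longest, most_reads))
    return choices


def write_outputs(
    clusters: ClusterSet,
    reps: Iterable[RepresentativeChoice],
    prefix: str,
    groups: Optional[Dict[str, str]] = None,
) -> List[Path]:
    """Write the five TSV files under ``prefix``; returns the paths written.

    ``groups`` optionally maps sample id -> experimental group; group labels
    are carried to the counts file as a comment line.
    """
    prefix_path = Path(prefix)
    if prefix_path.parent != Path(""):
        prefix_path.parent.mkdir(parents=True, exist_ok=True)

    clusters_path = Path(f"{prefix}.clusters.tsv")
    mapping = clusters.as_mapping()
    with clusters_path.open("w", encoding="utf-8") as fh:
        fh.write("contig_id\tcluster_id\n")
        for contig in sorted(mapping):
            fh.write(f"{contig}\t{mapping[contig]}\n")

    counts_path = Path(f"{prefix}.counts.tsv")
    with counts_path.open("w", encoding="utf-8") as fh:
        if groups:
            labels = "\t".join(groups.get(s, "") for s in clusters.samples)
            fh.write(f"# groups\t{labels}\n")
        fh.write("cluster_id\t" + "\t".join(clusters.samples) + "\n")
        for cid, _ in clusters.clusters:
            row = clusters.per_sample_counts.get(cid, {})
            values = "\t".join(str(row.get(s, 0)) for s in clusters.samples)
            fh.write(f"{cid}\t{values}\n" if clusters.samples else f"{cid}\n")

    types_path = Path(f"{prefix}.types.tsv")
    with types_path.open("w", encoding="utf-8") as fh:
        fh.write("cluster_id\tn_members\ttype\n")
        for cid, members in clusters.clusters:
            fh.write(f"{cid}\t{len(members)}\t{clusters.types[cid]}\n")

    reps = list(reps)
    longest_path = Path(f"{prefix}.reps_longest.tsv")
    with longest_path.open("w", encoding="utf-8") as fh:
        fh.write("cluster_id\tcontig_id\n")
        for choice in reps:
            fh.write(f"{choice.cluster_id}\t{choice.longest_member}\n")

    mostreads_path = Path(f"{prefix}.reps_mostreads.tsv")
    with mostreads_path.open("w", encoding="utf-8") as fh:
        fh.write("cluster_id\tcontig_id\n")
        for choice in reps:
            fh.write(f"{choice.cluster_id}\t{choice.most_reads_member}\n")

    return [clusters_path, counts_path, types_path, longest_path, mostreads_path]


def read_clusters(path: str) -> Dict[str, str]:
    """Re-read a ``.clusters.tsv`` file into a contig -> cluster map."""
    mapping: Dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("contig_id\t"):
            raise ValueError(f"{path!r} is not a clusters TSV")
        for line in fh:
            contig, cid = line.rstrip("\n").split("\t")
            mapping[contig] = cid
    return mapping


def write_representative_fasta(
    assembly_fasta: str,
    reps: Iterable[RepresentativeChoice],
    out_path: str,
    which: str = "longest",
) -> int:
    """Extract representative sequences from the assembly FASTA.

    ``which`` selects the representative rule ("longest" or "most_reads").
    Returns the number of sequences written.
    """
    if which == "longest":
        wanted: Set[str] = {r.longest_member for r in reps}
    elif which == "most_reads":
        wanted = {r.most_reads_member for r in reps}
    else:
        raise ValueError(f"unknown representative rule {which!r}")
    records = (
        rec for rec in SeqIO.parse(assembly_fasta, "fasta") if rec.id in wanted
    )
    return SeqIO.write(records, out_path, "fasta")
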