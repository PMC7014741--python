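"""Pairwise recall and precision of a clustering against ground-truth loci.

Every pair of labeled contigs falls in one of four cells: clustered together
and from the same locus (``a``, true positive), clustered together but from
different loci (``b``, false positive), split apart despite sharing a locus
(``c``, false negative), or split and from different loci (``d``, true
negative).  Recall ``R = a/(a+c)`` and precision ``P = a/(a+b)``; a perfect
clustering has b = c = 0 and hence R = P = 1.

The counts are computed from the cluster × locus contingency table in time
proportional to the number of non-empty cells rather than by enumerating the
n(n−1)/2 pairs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import comb
from typing import Dict, Optional, Tuple


@dataclass(frozen=True)
class PairConfusion:
    """Pair counts a (TP), b (FP), c (FN), d_tn (TN); they sum to C(n, 2)."""

    a: int
    b: int
    c: int
    d_tn: int
    n: int  # number of labeled contigs

    @property
    def total_pairs(self) -> int:
        return self.a + self.b + self.c + self.d_tn


def pairwise_confusion(
    partition: Dict[str, str], truth: Dict[str, str]
) -> PairConfusion:
    """Count contig-pair outcomes of ``partition`` against locus ``truth``.

    Contigs missing from either map are excluded first; an empty overlap is
    an error.  Using the contingency table N with cells n_kl (cluster k,
    locus l):  a = Σ C(n_kl,2);  a+b = Σ C(row_k,2);  a+c = Σ C(col_l,2);
    d by complement against C(n,2).
    """
    keys = partition.keys() & truth.keys()
    if not keys:
        raise ValueError("no contig carries both a cluster and a locus label")
    cells: Counter = Counter()
    rows: Counter = Counter()
    cols: Counter = Counter()
    for contig in keys:
        k, l = partition[contig], truth[contig]
        cells[(k, l)] += 1
        rows[k] += 1
        cols[l] += 1
    a = sum(comb(v, 2) for v in cells.values())
    ab = sum(comb(v, 2) for v in rows.values())
    ac = sum(comb(v, 2) for v in cols.values())
    n = len(keys)
    total = comb(n, 2)
    b = ab - a
    c = ac - a
    return PairConfusion(a=a, b=b, c=c, d_tn=total - a - b - c, n=n)


def recall_precision(
    conf: PairConfusion,
) -> Tuple[Optional[float], Optional[float]]:
    """(R, P) = (a/(a+c), a/(a+b)); an undefined ratio comes back as None
    rather than being silently coerced to zero."""
    recall = conf.a / (conf.a + conf.c) if conf.a + conf.c > 0 else None
    precision = conf.a / (conf.a + conf.b) if conf.a + conf.b > 0 else None
    return recall, precision
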